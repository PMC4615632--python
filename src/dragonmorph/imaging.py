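"""Camera calibration and colour-layer segmentation of throat photographs.

The pipeline mirrors standard calibrated digital photography of animal
coloration:

1. *Linearisation* — per-channel power-law response curves fitted to the six
   grey squares of a colour-checker standard (known reflectances vs mean
   photographed responses), mapping raw camera responses to a linear
   reflectance scale.
2. *Equalisation* — channel gains set so a 30%-reflectance grey standard
   photographed in-frame reads exactly 0.30 in every channel, removing
   frame-to-frame lighting variation.
3. *Segmentation* — every throat pixel is luminance-standardised to
   chromaticity coordinates (r, g, b) = (R, G, B) / (R + G + B) and assigned
   to the red layer if its redness score r - g reaches the red threshold
   (default 0.20), else to the yellow layer if its yellowness score
   min(r, g) - b reaches the yellow threshold (default 0.15), else to grey.
   Red takes precedence: the deliberately conservative red threshold keeps
   orange and yellow colouration clearly distinguished.

Images are H x W x 3 arrays scaled to [0, 1]; masks are boolean H x W arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

__all__ = [
    "CalibrationModel",
    "SegmentationResult",
    "DEFAULT_THRESHOLDS",
    "fit_linearization",
    "apply_calibration",
    "equalize_to_standard",
    "segment_throat",
]

logger = logging.getLogger(__name__)

#: Chromatic-score thresholds for layer assignment.
DEFAULT_THRESHOLDS = {"red": 0.20, "yellow": 0.15}

_CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-channel power-law response model: reflectance = a_c * response**g_c."""

    gains: tuple[float, float, float]
    exponents: tuple[float, float, float]
    residuals: tuple[float, float, float]  # RMS log-space residual per channel

    def __post_init__(self):
        if any(a <= 0 for a in self.gains) or any(g <= 0 for g in self.exponents):
            raise ValueError("gains and exponents must be positive")


@dataclass(frozen=True)
class SegmentationResult:
    """Fractions of throat pixels assigned to the red/yellow/grey layers."""

    prop_red: float
    prop_yellow: float
    prop_grey: float
    n_pixels: int
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self):
        total = self.prop_red + self.prop_yellow + self.prop_grey
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"layer proportions must sum to 1, got {total}")
        if self.n_pixels < 1:
            raise ValueError("mask must contain at least one pixel")

    def as_dict(self) -> dict:
        return {
            "prop_red": self.prop_red,
            "prop_yellow": self.prop_yellow,
            "prop_grey": self.prop_grey,
            "n_pixels": self.n_pixels,
            "thresholds": dict(self.thresholds),
        }


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    return image


def _check_mask(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("mask contains no pixels")
    return mask


def fit_linearization(responses, known_reflectances) -> CalibrationModel:
    """Fit per-channel power-law response curves from a grey calibration ramp.

    Parameters
    ----------
    responses : array-like, shape (n, 3)
        Mean camera response of each grey square per channel, in [0, 1].
        Typically n = 6 (a six-step grey-scale ramp).
    known_reflectances : array-like, shape (n,)
        Measured reflectance fraction of each square.

    The model ``reflectance = a_c * response ** gamma_c`` is fitted by least
    squares in log-log space. If responses are not monotone increasing with
    reflectance a warning is issued and the responses are first projected to
    the nearest monotone sequence (isotonic regression) before fitting.
    """
    resp = np.asarray(responses, dtype=float)
    refl = np.asarray(known_reflectances, dtype=float)
    if resp.ndim != 2 or resp.shape[1] != 3:
        raise ValueError(f"responses must be (n, 3), got {resp.shape}")
    if refl.shape != (resp.shape[0],):
        raise ValueError("one known reflectance per grey square is required")
    order = np.argsort(refl)
    refl = refl[order]
    resp = resp[order]
    # collapse duplicated (response, reflectance) rows: weighting invariance
    uniq, idx = np.unique(np.column_stack([refl[:, None], resp]), axis=0,
                          return_index=True)
    refl = uniq[:, 0]
    resp = uniq[:, 1:]
    if refl.size < 3:
        raise ValueError("at least 3 distinct grey squares are required")
    if np.any(refl <= 0) or np.any(resp <= 0):
        raise ValueError("grey-square responses and reflectances must be > 0")

    gains, exponents, residuals = [], [], []
    for c in range(3):
        col = resp[:, c]
        if np.any(np.diff(col) <= 0):
            warnings.warn(
                f"channel {_CHANNELS[c]}: responses not monotone in "
                "reflectance; applying monotone-regression fallback",
                stacklevel=2,
            )
            col = isotonic_regression(col).x
            # isotonic output can introduce ties; nudge to keep logs distinct
            col = np.maximum.accumulate(col + np.arange(col.size) * 1e-12)
        # log(reflectance) = log(a) + gamma * log(response)
        X = np.column_stack([np.ones_like(col), np.log(col)])
        beta, res, *_ = np.linalg.lstsq(X, np.log(refl), rcond=None)
        log_a, gamma = beta
        fitted = X @ beta
        rms = float(np.sqrt(np.mean((fitted - np.log(refl)) ** 2)))
        gains.append(float(np.exp(log_a)))
        exponents.append(float(gamma))
        residuals.append(rms)
    return CalibrationModel(tuple(gains), tuple(exponents), tuple(residuals))


def apply_calibration(image: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Map raw channel responses through the fitted response curves.

    Output is on a linear reflectance scale, clipped to [0, 1.5] (specular
    highlights may exceed the white standard).
    """
    image = _check_image(image)
    out = np.empty_like(image)
    for c in range(3):
        out[..., c] = model.gains[c] * np.power(image[..., c], model.exponents[c])
    return np.clip(out, 0.0, 1.5)


def equalize_to_standard(
    image: np.ndarray, standard: np.ndarray, target_reflectance: float = 0.30
) -> np.ndarray:
    """Scale each channel so the grey-standard region means equal the
    standard's known reflectance (default 30%).

    Returns the equalised image; the applied scale factors are available via
    :func:`equalization_factors`.
    """
    image, factors = _equalize(image, standard, target_reflectance)
    return image


def equalization_factors(
    image: np.ndarray, standard: np.ndarray, target_reflectance: float = 0.30
) -> np.ndarray:
    """Per-channel scale factors the equalisation step would apply."""
    _, factors = _equalize(image, standard, target_reflectance)
    return factors


def _equalize(image, standard, target_reflectance):
    if target_reflectance <= 0:
        raise ValueError("target reflectance must be > 0")
    image = _check_image(image)
    standard = _check_mask(standard, image)
    means = image[standard].mean(axis=0)
    if np.any(means <= 0):
        raise ValueError(
            "grey-standard region has a zero-mean channel; cannot equalise"
        )
    factors = target_reflectance / means
    return image * factors, factors


def segment_throat(
    image: np.ndarray,
    throat: np.ndarray,
    thresholds: dict | None = None,
) -> SegmentationResult:
    """Assign throat pixels to red/yellow/grey layers and report proportions.

    Pixels are luminance-standardised to chromaticity coordinates
    ``(r, g, b) = (R, G, B) / (R + G + B)`` so classification is invariant to
    uniform brightness changes. A pixel is red when ``r - g >= red
    threshold``, else yellow when ``min(r, g) - b >= yellow threshold``, else
    grey. Pixels with zero total response carry no chromatic information and
    are counted as grey.
    """
    if thresholds is None:
        thresholds = dict(DEFAULT_THRESHOLDS)
    for key in ("red", "yellow"):
        if key not in thresholds:
            raise ValueError(f"thresholds must define {key!r}")
        if not 0.0 < thresholds[key] < 1.0:
            raise ValueError(f"{key} threshold must lie in (0, 1)")
    image = _check_image(image)
    throat = _check_mask(throat, image)

    px = image[throat]  # (n, 3)
    total = px.sum(axis=1)
    dark = total <= 0
    n_dark = int(dark.sum())
    if n_dark:
        logger.info("segment_throat: %d zero-response pixels assigned grey", n_dark)
    safe_total = np.where(dark, 1.0, total)
    chrom = px / safe_total[:, None]
    r, g, b = chrom[:, 0], chrom[:, 1], chrom[:, 2]
    redness = r - g
    yellowness = np.minimum(r, g) - b
    is_red = (redness >= thresholds["red"]) & ~dark
    is_yellow = (yellowness >= thresholds["yellow"]) & ~is_red & ~dark
    n = px.shape[0]
    n_red = int(is_red.sum())
    n_yellow = int(is_yellow.sum())
    return SegmentationResult(
        prop_red=n_red / n,
        prop_yellow=n_yellow / n,
        prop_grey=(n - n_red - n_yellow) / n,
        n_pixels=n,
        thresholds={"red": thresholds["red"], "yellow": thresholds["yellow"]},
    )
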