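"""Synthetic phenotype generators.

Every stage of the analysis is testable without the original measurements:
these generators produce reflectance spectra, calibrated-photography
fixtures, morph feature tables and longitudinal hormone/colour panels with
the statistical structure the study design assumes.

Study conditions emulated by the defaults:

* four throat morphs (orange, yellow, grey, orange+yellow) with distinct
  red/yellow/grey cover proportions and 10/7/7/11 females per morph;
* reflectance archetypes with minimal ultraviolet (300–400 nm) reflectance —
  a sigmoidal long-pass edge near 580 nm for orange, near 500 nm for yellow,
  and a flat cream/grey spectrum;
* a nonlinear (gamma) camera response with an in-frame 30% grey standard and
  a six-step grey calibration ramp;
* plasma testosterone rising roughly five-fold one week after the implant
  (about 56 -> 262 ng/mL) and partially declining by week four (about
  134 ng/mL), sampled for 18 females with missing cells matching the
  18/11/15 available records;
* quadratic morph-specific colour trajectories over weeks 1–6, 10 and 12
  with a per-female random intercept: the proportion of red rises in the
  orange-bearing morphs and stays flat for yellow and grey morphs.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import DEFAULT_GRID, Spectrum
from .stats import TIMEPOINT_ORDER

__all__ = [
    "MorphArchetype",
    "MORPH_ARCHETYPES",
    "MORPH_COUNTS",
    "DEFAULT_WEEKS",
    "gen_reflectance",
    "gen_throat_image",
    "gen_feature_table",
    "gen_hormone_panel",
    "gen_timecourse",
    "default_feature_means",
]

#: Females per morph after testosterone-induced colour expression.
MORPH_COUNTS = {"orange": 10, "yellow": 7, "grey": 7, "orange_yellow": 11}

#: Weekly photograph schedule (weeks 1-6, 10 and 12).
DEFAULT_WEEKS = (1, 2, 3, 4, 5, 6, 10, 12)


@dataclass(frozen=True)
class MorphArchetype:
    """Idealised spectral and cover parameters of one throat morph."""

    morph: str
    proportions: tuple[float, float, float]   # red, yellow, grey cover
    edge_nm: float | None       # long-pass midpoint; None = flat spectrum
    edge_slope: float = 0.08    # logistic steepness (1/nm)
    peak_reflectance: float = 0.55
    base_reflectance: float = 0.05
    uv_level: float = 0.04      # short-wave floor, keeps UV minimal

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("cover proportions must sum to 1")


MORPH_ARCHETYPES = {
    "orange": MorphArchetype("orange", (0.45, 0.10, 0.45), edge_nm=580.0),
    "yellow": MorphArchetype("yellow", (0.00, 0.40, 0.60), edge_nm=500.0),
    "grey": MorphArchetype("grey", (0.00, 0.00, 1.00), edge_nm=None,
                           peak_reflectance=0.30, base_reflectance=0.30),
    "orange_yellow": MorphArchetype("orange_yellow", (0.35, 0.30, 0.35),
                                    edge_nm=580.0),
}


def gen_reflectance(archetype: MorphArchetype, seed=None,
                    noise_sd: float = 0.02, grid=None) -> Spectrum:
    """One reflectance spectrum for a morph archetype.

    Long-pass morphs (orange, yellow) get a logistic reflectance edge at
    ``edge_nm``; flat morphs get a constant cream/grey level. Multiplicative
    lognormal noise (sd ``noise_sd`` on the log scale) emulates
    individual-to-individual and measurement variation.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if archetype.edge_nm is None:
        base = np.full(grid.shape, archetype.peak_reflectance)
    else:
        rise = 1.0 / (1.0 + np.exp(-archetype.edge_slope
                                   * (grid - archetype.edge_nm)))
        base = archetype.base_reflectance + (
            archetype.peak_reflectance - archetype.base_reflectance) * rise
    # keep the ultraviolet band at a low floor
    uv_taper = 1.0 / (1.0 + np.exp(-0.1 * (grid - 380.0)))
    base = archetype.uv_level + (base - archetype.uv_level) * uv_taper
    rng = np.random.default_rng(seed)
    noisy = base * np.exp(rng.normal(0.0, noise_sd, size=grid.shape))
    return Spectrum(grid, np.clip(noisy, 0.0, None), kind="reflectance")


# ---------------------------------------------------------------------------
# image fixtures

# linear-scale RGB of the composed patches; chromaticity scores by
# construction: orange r-g = 0.30 (>= 0.20), yellow min(r,g)-b = 0.25
# (>= 0.15), neutral scores = 0
_PATCH_RGB = {
    "red": (0.55, 0.25, 0.20),
    "yellow": (0.40, 0.40, 0.20),
    "grey": (0.30, 0.30, 0.30),
}
_GREY_RAMP = (0.05, 0.10, 0.20, 0.35, 0.55, 0.80)


@dataclass(frozen=True)
class ImageFixture:
    """A synthetic photograph plus its masks and ground truth."""

    image: np.ndarray            # raw (gamma-distorted, noisy) H x W x 3
    throat_mask: np.ndarray
    standard_mask: np.ndarray
    grey_squares: np.ndarray     # (6, 3) mean raw responses of the ramp
    grey_reflectances: tuple     # known reflectance of each ramp step
    truth: dict                  # generating proportions and parameters


def gen_throat_image(
    proportions,
    shape=(60, 60),
    camera_gamma: float = 2.2,
    noise_sd: float = 0.0,
    seed=None,
) -> ImageFixture:
    """Compose a synthetic throat photograph with known layer proportions.

    The throat region is a horizontal stack of red/yellow/grey patches sized
    by ``proportions``; a 30%-reflectance grey standard patch and a six-step
    grey ramp sit below it. The linear scene is passed through a per-channel
    power-law camera response (``response = reflectance ** (1/gamma)``) and
    additive Gaussian noise, emulating an uncalibrated camera.
    """
    prop = np.asarray(proportions, dtype=float)
    if prop.shape != (3,) or abs(prop.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be three values summing to 1")
    h, w = shape
    throat_h = h - 10
    if throat_h < 3 or w < 12:
        raise ValueError(f"layout {shape} too small for the requested scene")
    n_throat = throat_h * w
    n_red = int(round(prop[0] * n_throat))
    n_yellow = int(round(prop[1] * n_throat))
    if n_red + n_yellow > n_throat:
        n_yellow = n_throat - n_red

    linear = np.zeros((h, w, 3))
    flat = np.zeros(n_throat, dtype=int)     # 0 red, 1 yellow, 2 grey
    flat[n_red:n_red + n_yellow] = 1
    flat[n_red + n_yellow:] = 2
    colors = np.array([_PATCH_RGB["red"], _PATCH_RGB["yellow"],
                       _PATCH_RGB["grey"]])
    linear[:throat_h] = colors[flat].reshape(throat_h, w, 3)

    throat_mask = np.zeros((h, w), dtype=bool)
    throat_mask[:throat_h] = True

    # grey standard strip (30 %) and six-step calibration ramp
    standard_mask = np.zeros((h, w), dtype=bool)
    standard_mask[throat_h:throat_h + 5] = True
    linear[throat_h:throat_h + 5] = 0.30
    ramp_w = w // 6
    for i, refl in enumerate(_GREY_RAMP):
        x0 = i * ramp_w
        x1 = (i + 1) * ramp_w if i < 5 else w
        linear[throat_h + 5:, x0:x1] = refl

    raw = np.power(np.clip(linear, 0.0, None), 1.0 / camera_gamma)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    raw = np.clip(raw, 0.0, 1.0)

    squares = np.empty((6, 3))
    for i in range(6):
        x0 = i * ramp_w
        x1 = (i + 1) * ramp_w if i < 5 else w
        squares[i] = raw[throat_h + 5:, x0:x1].reshape(-1, 3).mean(axis=0)

    truth = {
        "prop_red": n_red / n_throat,
        "prop_yellow": n_yellow / n_throat,
        "prop_grey": (n_throat - n_red - n_yellow) / n_throat,
        "camera_gamma": camera_gamma,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return ImageFixture(
        image=raw,
        throat_mask=throat_mask,
        standard_mask=standard_mask,
        grey_squares=squares,
        grey_reflectances=_GREY_RAMP,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# feature tables


def default_feature_means() -> pd.DataFrame:
    """Per-morph mean vectors of the seven colour variables.

    Values are plausible for testosterone-induced morph expression: orange
    morphs carry red cover and strong throat chromatic contrast, yellow
    morphs carry yellow cover and bib contrast, grey morphs stay near the
    neutral background.
    """
    rows = {
        #            red   yel   grey  t_cc  t_ac  b_cc  b_ac
        "orange": [0.45, 0.08, 0.47, 9.0, 6.0, 3.0, 5.0],
        "yellow": [0.02, 0.40, 0.58, 5.0, 7.0, 6.5, 5.5],
        "grey": [0.01, 0.03, 0.96, 1.5, 9.0, 2.0, 6.5],
        "orange_yellow": [0.35, 0.30, 0.35, 8.5, 5.0, 6.0, 4.5],
    }
    from .classify import FEATURE_COLUMNS
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(FEATURE_COLUMNS))


def gen_feature_table(
    means: pd.DataFrame | None = None,
    covariance: np.ndarray | None = None,
    counts: dict | None = None,
    seed=None,
    sd_scale: float = 1.0,
) -> pd.DataFrame:
    """Multivariate-normal colour feature table with morph labels.

    ``means`` is a per-morph DataFrame (rows = morphs, columns = the seven
    colour variables); ``covariance`` the pooled within-morph covariance
    shared across morphs. Defaults give the four study morphs at counts
    10/7/7/11 with moderate within-morph spread.
    """
    from .classify import FEATURE_COLUMNS
    if means is None:
        means = default_feature_means()
    if counts is None:
        counts = dict(MORPH_COUNTS)
    p = means.shape[1]
    if covariance is None:
        sds = np.array([0.06, 0.06, 0.07, 1.0, 1.0, 1.0, 1.0])[:p] * sd_scale
        covariance = np.diag(sds ** 2)
    covariance = np.asarray(covariance, dtype=float)
    try:
        np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive-definite") from exc
    for morph, n in counts.items():
        if n < 2:
            raise ValueError(f"morph {morph!r} needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    frames = []
    idx = 0
    for morph in means.index:
        if morph not in counts:
            continue
        draws = rng.multivariate_normal(
            means.loc[morph].to_numpy(dtype=float), covariance,
            size=counts[morph], method="cholesky")
        df = pd.DataFrame(draws, columns=list(means.columns))
        df.insert(0, "morph", morph)
        df.insert(0, "id", [f"F{idx + i + 1:02d}" for i in range(counts[morph])])
        idx += counts[morph]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# hormone panels

#: Printed summary of the implant response: pre, week 1 and week 4 means.
DEFAULT_HORMONE_MEANS = {"pre": 55.95, "week1": 262.16, "week4": 134.02}

#: Available plasma samples per timepoint (of 18 implanted females).
DEFAULT_TIMEPOINT_N = {"pre": 18, "week1": 11, "week4": 15}


def gen_hormone_panel(
    means: dict | None = None,
    between_sd: float = 0.25,
    within_sd: float = 0.35,
    n_females: int = 18,
    timepoint_n: dict | None = None,
    seed=None,
) -> pd.DataFrame:
    """Longitudinal plasma-testosterone panel (ng/mL).

    Concentrations are lognormal: per-female random intercept (sd
    ``between_sd``) plus residual (sd ``within_sd``), both on the log scale,
    around the timepoint geometric means. ``timepoint_n`` fixes how many
    females have a record at each timepoint (missing cells are the females
    drawn beyond that count), matching the study's 18/11/15 samples.
    """
    if means is None:
        means = dict(DEFAULT_HORMONE_MEANS)
    if timepoint_n is None:
        timepoint_n = dict(DEFAULT_TIMEPOINT_N)
    if any(m <= 0 for m in means.values()):
        raise ValueError("hormone means must be positive")
    rng = np.random.default_rng(seed)
    females = [f"F{i + 1:02d}" for i in range(n_females)]
    intercepts = rng.normal(0.0, between_sd, size=n_females)
    records = []
    for t in TIMEPOINT_ORDER:
        if t not in means:
            continue
        n_t = min(timepoint_n.get(t, n_females), n_females)
        present = rng.permutation(n_females)[:n_t]
        for i in sorted(present):
            conc = float(means[t] * np.exp(intercepts[i]
                                           + rng.normal(0.0, within_sd)))
            records.append((females[i], t, conc))
    return pd.DataFrame(records, columns=["female_id", "timepoint",
                                          "testosterone"])


# ---------------------------------------------------------------------------
# colour time courses

#: Quadratic red-proportion trajectories per morph: (intercept, time, time^2).
#: Orange-bearing morphs rise over the 12 weeks; yellow and grey stay flat.
DEFAULT_TRAJECTORIES = {
    "orange": (0.02, 0.085, -0.0045),
    "orange_yellow": (0.02, 0.070, -0.0038),
    "yellow": (0.01, 0.0, 0.0),
    "grey": (0.01, 0.0, 0.0),
}


def gen_timecourse(
    coefficients: dict | None = None,
    intercept_sd: float = 0.03,
    residual_sd: float = 0.05,
    weeks=DEFAULT_WEEKS,
    counts: dict | None = None,
    seed=None,
) -> pd.DataFrame:
    """Longitudinal colour measurements with morph-specific quadratic trends.

    ``coefficients`` maps morph -> (intercept, linear, quadratic) for the
    mean trajectory ``b0 + b1 * week + b2 * week**2``; every female adds a
    Gaussian random intercept (sd ``intercept_sd``) and every record Gaussian
    residual noise (sd ``residual_sd``).
    """
    if coefficients is None:
        coefficients = dict(DEFAULT_TRAJECTORIES)
    if counts is None:
        counts = {m: MORPH_COUNTS[m] for m in coefficients}
    for morph, n in counts.items():
        if n < 2:
            raise ValueError(f"morph {morph!r} needs at least 2 females")
    weeks = np.asarray(weeks, dtype=float)
    rng = np.random.default_rng(seed)
    records = []
    fid = 0
    for morph, (b0, b1, b2) in coefficients.items():
        if morph not in counts:
            continue
        for _ in range(counts[morph]):
            fid += 1
            u = rng.normal(0.0, intercept_sd)
            for wk in weeks:
                mu = b0 + b1 * wk + b2 * wk ** 2 + u
                records.append((f"F{fid:02d}", wk, morph,
                                mu + rng.normal(0.0, residual_sd)))
    return pd.DataFrame(records, columns=["female_id", "week", "morph",
                                          "value"])
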