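"""Wavelength-indexed spectral curves.

A :class:`Spectrum` holds a reflectance, irradiance or sensitivity curve
sampled on a strictly increasing wavelength grid. The analysis grid used
throughout the package is 300–700 nm at 1-nm steps, the visual range of
most diurnal lizards; reflectance is expressed as a fraction of a diffuse
white standard.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["Spectrum", "DEFAULT_GRID", "flat_spectrum", "resample_spectrum"]

logger = logging.getLogger(__name__)

#: Default analysis grid: 300–700 nm inclusive, 1-nm steps.
DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

_KINDS = ("reflectance", "irradiance", "sensitivity")


class Spectrum:
    """A nonnegative spectral curve on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nanometres.
    values : array-like
        Nonnegative values, same length as ``wavelengths_nm``. Reflectance is
        a fraction of the white standard; irradiance is in arbitrary quantal
        units; sensitivity lies in [0, 1].
    kind : {"reflectance", "irradiance", "sensitivity"}
    """

    __slots__ = ("wavelengths_nm", "values", "kind")

    def __init__(self, wavelengths_nm, values, kind: str = "reflectance"):
        wl = np.asarray(wavelengths_nm, dtype=float)
        vals = np.asarray(values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be one-dimensional")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size < 1:
            raise ValueError("a spectrum needs at least one sample")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be nonnegative")
        if kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
        wl = wl.copy()
        vals = vals.copy()
        wl.setflags(write=False)
        vals.setflags(write=False)
        self.wavelengths_nm = wl
        self.values = vals
        self.kind = kind

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def __repr__(self) -> str:
        return (
            f"Spectrum(kind={self.kind!r}, "
            f"{self.wavelengths_nm[0]:g}-{self.wavelengths_nm[-1]:g} nm, "
            f"n={len(self)})"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.kind == other.kind
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.values, other.values)
        )

    def resample(self, grid) -> "Spectrum":
        """Linearly interpolate onto ``grid`` (no extrapolation).

        Raises
        ------
        ValueError
            If ``grid`` is empty or extends beyond the measured range.
        """
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("resampling grid is empty")
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if grid.min() < lo or grid.max() > hi:
            raise ValueError(
                f"grid [{grid.min()}, {grid.max()}] outside measured "
                f"range [{lo}, {hi}]; extrapolation is not supported"
            )
        vals = np.interp(grid, self.wavelengths_nm, self.values)
        return Spectrum(grid, np.clip(vals, 0.0, None), kind=self.kind)

    def on_default_grid(self) -> "Spectrum":
        return self.resample(DEFAULT_GRID)

    def band_mean(self, lo: float, hi: float) -> float:
        """Mean value over the closed wavelength band [lo, hi]."""
        sel = (self.wavelengths_nm >= lo) & (self.wavelengths_nm <= hi)
        if not sel.any():
            raise ValueError(f"no samples in band [{lo}, {hi}]")
        return float(self.values[sel].mean())


def resample_spectrum(spectrum: Spectrum, grid) -> Spectrum:
    """Functional alias for :meth:`Spectrum.resample`."""
    return spectrum.resample(grid)


def flat_spectrum(level: float, grid=None, kind: str = "reflectance") -> Spectrum:
    """A spectrally flat curve at ``level`` on ``grid`` (default 300–700 nm)."""
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    return Spectrum(grid, np.full(grid.shape, float(level)), kind=kind)
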