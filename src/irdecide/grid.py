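"""Wavenumber grids for mid-IR hyperspectral data.

All spectra in this package live on a :class:`SpectralGrid`: an inclusive,
strictly descending wavenumber axis (instrument convention, high wavenumber
first).  The FTIR reference grid used throughout is 4000-750 cm^-1 in 2 cm^-1
steps, 1626 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralGrid", "make_grid", "nearest_index", "REFERENCE_GRID_PARAMS"]

#: start, end, step (cm^-1) of the full-range FTIR acquisition grid.
REFERENCE_GRID_PARAMS = (4000.0, 750.0, 2.0)

_DIV_RTOL = 1e-9


@dataclass(frozen=True)
class SpectralGrid:
    """Inclusive descending wavenumber axis.

    Parameters
    ----------
    start
        High-wavenumber endpoint (cm^-1).
    end
        Low-wavenumber endpoint (cm^-1); ``end <= start``.
    step
        Spacing between adjacent points (cm^-1), > 0 (ignored when the grid
        has a single point).
    """

    start: float
    end: float
    step: float
    values: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.start < self.end:
            raise ValueError(
                f"grid start ({self.start}) must be >= end ({self.end})"
            )
        span = self.start - self.end
        n_float = span / self.step
        n = round(n_float)
        if abs(n_float - n) > _DIV_RTOL * max(1.0, n_float):
            remainder = span - n * self.step
            raise ValueError(
                f"grid span {span} cm^-1 is not divisible by step {self.step} "
                f"cm^-1 (remainder {remainder:g})"
            )
        vals = self.start - self.step * np.arange(n + 1)
        vals[-1] = self.end  # exact endpoint
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def count(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.count

    @property
    def span(self) -> float:
        """Range width start - end in cm^-1."""
        return self.start - self.end

    def with_values(self) -> np.ndarray:
        return self.values


def make_grid(start: float, end: float, step: float) -> SpectralGrid:
    """Build an inclusive descending wavenumber grid.

    Endpoints may be given in either order; they are normalized so that the
    grid runs from the higher to the lower wavenumber.  ``(start - end)``
    must be an integer multiple of ``step``.
    """
    lo, hi = sorted((float(start), float(end)))
    return SpectralGrid(start=hi, end=lo, step=float(step))


def nearest_index(grid: SpectralGrid, wavenumber: float) -> int:
    """Index of the grid value closest to ``wavenumber``.

    Queries exactly halfway between two grid points resolve to the
    higher-wavenumber index.  Queries farther than half a step outside the
    grid raise ``ValueError``.
    """
    w = float(wavenumber)
    half = grid.step / 2.0
    if w > grid.start + half or w < grid.end - half:
        raise ValueError(
            f"wavenumber {w} cm^-1 outside grid "
            f"[{grid.end} - {grid.step}/2, {grid.start} + {grid.step}/2]"
        )
    # values descend: index grows as wavenumber falls.  Compare the two
    # bracketing points; an exact tie goes to the smaller index, i.e. the
    # higher wavenumber.
    x = (grid.start - w) / grid.step
    lo_idx = min(max(int(np.floor(x)), 0), grid.count - 1)
    hi_idx = min(lo_idx + 1, grid.count - 1)
    vals = grid.values
    if abs(vals[hi_idx] - w) < abs(vals[lo_idx] - w):
        return hi_idx
    return lo_idx
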