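"""Spectral preconditioning.

Four options mirror the analysis variants used for tissue extinction
spectra:

- ``raw``       - no preconditioning;
- ``bc``        - rubber-band baseline correction (subtract the lower convex
                  hull of the spectrum over the wavenumber axis), removing
                  broad scattering offsets;
- ``bc_ratio``  - baseline correction, then division by the amide-I peak
                  height (search range 1600-1700 cm^-1);
- ``bc_norm``   - baseline correction, then unit-vector normalization,
                  removing absolute-thickness information.

The module also provides training-set standardization (mean/SD per spectral
step, the scaling that makes decision equations portable) and the display
5-point second derivative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .cube import LabeledSpectra, SpectrumCube
from .grid import SpectralGrid

__all__ = [
    "PreconditionOption",
    "TrainingScaler",
    "baseline_correct",
    "normalize",
    "amide_ratio",
    "apply_option",
    "fit_scaler",
    "scale",
    "second_derivative",
]

log = logging.getLogger(__name__)

AMIDE_I_RANGE = (1600.0, 1700.0)


@dataclass(frozen=True)
class PreconditionOption:
    """Named preconditioning recipe."""

    name: str = "bc_norm"
    norm: str = "vector"  # vector | area, used by bc_norm
    amide_range: tuple = AMIDE_I_RANGE  # used by bc_ratio

    def __post_init__(self):
        if self.name not in ("raw", "bc", "bc_ratio", "bc_norm"):
            raise ValueError(f"unknown preconditioning option {self.name!r}")
        if self.norm not in ("vector", "area"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass
class TrainingScaler:
    """Per-step training mean and SD used to standardize test spectra."""

    mean: np.ndarray
    sd: np.ndarray
    sd_floor: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have equal length")

    @property
    def effective_sd(self) -> np.ndarray:
        return np.maximum(self.sd, self.sd_floor)


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of the curve (x ascending, y), sampled at x."""
    n = x.size
    if n < 3:
        raise ValueError("baseline correction requires >= 3 grid points")
    pts = np.column_stack([x, y])
    try:
        hull = ConvexHull(pts)
        v = hull.vertices
        # vertices are counter-clockwise; lower envelope runs from the
        # min-x vertex to the max-x vertex in increasing x
        order = np.argsort(x[v])
        vx, vy = x[v][order], y[v][order]
        # keep only vertices on the lower chain: walk and drop any vertex
        # above the segment between its neighbors (upper-hull points)
        keep_x, keep_y = [vx[0]], [vy[0]]
        for xi, yi in zip(vx[1:], vy[1:]):
            while len(keep_x) >= 2:
                # cross product sign: require right turns only (convex below)
                x1, y1 = keep_x[-2], keep_y[-2]
                x2, y2 = keep_x[-1], keep_y[-1]
                if (x2 - x1) * (yi - y1) - (xi - x1) * (y2 - y1) <= 0:
                    keep_x.pop()
                    keep_y.pop()
                else:
                    break
            keep_x.append(xi)
            keep_y.append(yi)
        return np.interp(x, keep_x, keep_y)
    except QhullError:
        # degenerate (collinear) input: baseline is the straight chord
        return np.interp(x, [x[0], x[-1]], [y[0], y[-1]])


def baseline_correct(spectrum: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    """Rubber-band baseline correction of one spectrum.

    Subtracts the lower convex hull of (wavenumber, value); the result is
    zero at hull contact points (including both endpoints) and >= 0 up to
    floating-point error elsewhere.
    """
    y = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("baseline correction requires finite input")
    # work on ascending wavenumber
    x_asc = grid.values[::-1].astype(float)
    y_asc = y[::-1]
    base = _lower_hull_baseline(x_asc, y_asc)
    return (y_asc - base)[::-1]


def _baseline_correct_many(spectra: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    out = np.empty_like(spectra, dtype=float)
    for i in range(spectra.shape[0]):
        out[i] = baseline_correct(spectra[i], grid)
    return out


def normalize(spectrum: np.ndarray, grid: SpectralGrid, norm: str = "vector") -> np.ndarray:
    """Scale a spectrum to unit Euclidean norm or unit absolute area."""
    y = np.asarray(spectrum, dtype=float)
    if norm == "vector":
        denom = float(np.linalg.norm(y))
    elif norm == "area":
        denom = float(np.sum(np.abs(y)) * grid.step)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    if denom == 0.0:
        raise ValueError("cannot normalize an identically zero spectrum")
    return y / denom


def amide_ratio(
    spectrum: np.ndarray, grid: SpectralGrid, search_range=AMIDE_I_RANGE
) -> np.ndarray:
    """Divide a baseline-corrected spectrum by its amide-I peak height."""
    y = np.asarray(spectrum, dtype=float)
    lo, hi = sorted(search_range)
    mask = (grid.values >= lo) & (grid.values <= hi)
    if not mask.any():
        raise ValueError(f"grid has no points in amide range {search_range}")
    peak = float(y[mask].max())
    if peak <= 0:
        raise ValueError(
            f"no positive maximum in amide range {search_range}; cannot ratio"
        )
    return y / peak


def _apply_option_matrix(spectra: np.ndarray, grid: SpectralGrid, option: PreconditionOption):
    """Apply an option to an n x count matrix; returns (matrix, bad_row_mask)."""
    if option.name == "raw":
        return spectra.copy(), np.zeros(spectra.shape[0], dtype=bool)
    out = _baseline_correct_many(spectra, grid)
    bad = np.zeros(out.shape[0], dtype=bool)
    if option.name == "bc":
        return out, bad
    for i in range(out.shape[0]):
        try:
            if option.name == "bc_ratio":
                out[i] = amide_ratio(out[i], grid, option.amide_range)
            else:  # bc_norm
                out[i] = normalize(out[i], grid, option.norm)
        except ValueError:
            bad[i] = True
            out[i] = 0.0
    return out, bad


def apply_option(x, option: PreconditionOption):
    """Apply a preconditioning option per pixel/spectrum.

    Pixels that cannot be normalized or ratioed (all-zero after baseline
    correction) are zeroed and counted in a logged warning; for flat labeled
    matrices they are dropped instead.
    """
    if isinstance(x, SpectrumCube):
        r, c, n = x.data.shape
        flat, bad = _apply_option_matrix(x.data.reshape(r * c, n), x.grid, option)
        if bad.any():
            log.warning(
                "%d/%d pixels failed %s preconditioning and were zeroed",
                int(bad.sum()), r * c, option.name,
            )
        return replace(x, data=flat.reshape(r, c, n), precondition_tag=option.name)
    if isinstance(x, LabeledSpectra):
        out, bad = _apply_option_matrix(x.spectra, x.grid, option)
        if bad.any():
            log.warning(
                "%d/%d spectra failed %s preconditioning and were excluded",
                int(bad.sum()), x.n, option.name,
            )
        keep = ~bad
        return LabeledSpectra(
            out[keep], x.labels[keep], x.case_ids[keep], x.grid, option.name
        )
    raise TypeError(f"cannot precondition {type(x).__name__}")


def fit_scaler(train: LabeledSpectra, sd_floor: float | None = None) -> TrainingScaler:
    """Per-step mean and SD (n-1 denominator) over the training rows.

    ``sd_floor`` guards zero-variance steps; the default is
    ``1e-12 * max(sd)`` (or 1e-12 if the SD is identically zero).
    """
    if train.n < 2:
        raise ValueError("scaler requires at least 2 training spectra")
    mean = train.spectra.mean(axis=0)
    sd = train.spectra.std(axis=0, ddof=1)
    if sd_floor is None:
        top = float(sd.max())
        sd_floor = 1e-12 * top if top > 0 else 1e-12
    return TrainingScaler(mean=mean, sd=sd, sd_floor=float(sd_floor))


def scale(spectra: np.ndarray, scaler: TrainingScaler) -> np.ndarray:
    """Standardize spectra: (x - training mean) / max(training SD, floor)."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    return (x - scaler.mean) / scaler.effective_sd


def second_derivative(
    spectrum: np.ndarray, grid: SpectralGrid, display_scale: float = -250.0
) -> np.ndarray:
    """5-point finite-difference second derivative, times a display factor.

    Interior points use the exact-through-quartic central stencil
    (-f[j-2] + 16 f[j-1] - 30 f[j] + 16 f[j+1] - f[j+2]) / (12 h^2); the two
    points at each edge replicate the nearest interior value.  The default
    display scale of -250 flips the sign so that upgoing peaks mark band
    centers.
    """
    y = np.asarray(spectrum, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("second derivative requires >= 5 grid points")
    h = grid.step
    d2 = np.empty(n)
    d2[2:-2] = (-y[:-4] + 16 * y[1:-3] - 30 * y[2:-2] + 16 * y[3:-1] - y[4:]) / (
        12 * h * h
    )
    d2[0] = d2[1] = d2[2]
    d2[-1] = d2[-2] = d2[-3]
    return d2 * display_scale
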