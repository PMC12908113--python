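"""Minority-component mapping: reference spectra, Pearson images, masks.

Tissue extinction spectra are protein-dominated; minority biomolecules such
as lipids are isolated by *scaled subtraction*: subtract one tissue spectrum
from another after scaling so their amide-I responses cancel, leaving the
component that differs (e.g. a lipid-dominated difference spectrum).  Each
pixel is then scored by its Pearson correlation with that reference and
thresholded into a component mask.  Secondary binary decision equations
(e.g. lymphocyte vs nontumor) reuse the main training machinery with a
different positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import SpectrumCube, extract_windows
from .decision import DecisionEquation, train
from .grid import SpectralGrid
from .precondition import PreconditionOption, apply_option

__all__ = [
    "ReferenceSpectrum",
    "CorrelationImage",
    "derive_reference",
    "pearson_map",
    "threshold_mask",
    "train_secondary",
]

AMIDE_NULL_RANGE = (1600.0, 1700.0)


@dataclass
class ReferenceSpectrum:
    grid: SpectralGrid
    values: np.ndarray
    provenance: tuple = ("", "", 0.0)  # (source_a, source_b, subtraction scale)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.count,):
            raise ValueError("reference length must match grid")
        if not np.any(self.values != 0):
            raise ValueError("reference spectrum is identically zero")


@dataclass
class CorrelationImage:
    r: np.ndarray  # rows x cols Pearson values, NaN where undefined
    compute_range: tuple  # (wmin, wmax)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.r)


def derive_reference(
    spec_a: np.ndarray,
    spec_b: np.ndarray,
    grid: SpectralGrid,
    null_range=AMIDE_NULL_RANGE,
    names=("a", "b"),
) -> ReferenceSpectrum:
    """Scaled subtraction ``spec_a - s * spec_b`` cancelling the null range.

    ``s`` is the ratio of the two maxima inside ``null_range`` (default the
    amide-I band), so the protein response of ``spec_b`` nulls that of
    ``spec_a`` and the minority component remains.
    """
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    lo, hi = sorted(null_range)
    mask = (grid.values >= lo) & (grid.values <= hi)
    if not mask.any():
        raise ValueError(f"grid has no points inside null range {null_range}")
    pa, pb = float(a[mask].max()), float(b[mask].max())
    if pa <= 0 or pb <= 0:
        raise ValueError(
            f"both spectra need a positive maximum in the null range "
            f"{null_range} (got {pa:g} and {pb:g})"
        )
    s = pa / pb
    return ReferenceSpectrum(grid, a - s * b, provenance=(names[0], names[1], s))


def pearson_map(
    cube: SpectrumCube,
    reference: ReferenceSpectrum,
    wmin: float | None = None,
    wmax: float | None = None,
) -> CorrelationImage:
    """Per-pixel Pearson correlation with the reference over [wmin, wmax].

    Defaults to the full grid.  Zero-variance pixels are flagged undefined
    (NaN) and excluded from any downstream mask.
    """
    g = cube.grid
    if wmin is None:
        wmin = g.end
    if wmax is None:
        wmax = g.start
    wmin, wmax = sorted((float(wmin), float(wmax)))
    mask = (g.values >= wmin) & (g.values <= wmax)
    if mask.sum() < 3:
        raise ValueError("Pearson map needs >= 3 overlapping grid points")
    ref = reference.values[mask]
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    if ref_ss == 0:
        raise ValueError("reference has zero variance over the compute range")
    rows, cols, _ = cube.data.shape
    X = cube.data[:, :, mask].reshape(rows * cols, -1)
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    # a pixel is flat (undefined correlation) when its centered energy is at
    # rounding level relative to its magnitude
    scale = np.maximum(np.abs(X).max(axis=1), 1e-300)
    flat = np.sqrt(ss) <= 1e-10 * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ref_c) / np.sqrt(ss * ref_ss)
    r[flat] = np.nan
    return CorrelationImage(r.reshape(rows, cols), (wmin, wmax))


def threshold_mask(corr: CorrelationImage, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask where r > threshold (strict); undefined pixels are False."""
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(corr.r), corr.r > threshold, False)


def train_secondary(
    cube: SpectrumCube,
    windows,
    positive_label: str,
    negative_label: str = "nontumor",
    option: PreconditionOption | None = None,
    C: float = 1.0,
) -> DecisionEquation:
    """Binary decision equation with a minority component as positive class.

    Extracts the pixels of windows labeled ``positive_label`` (+1) and
    ``negative_label`` (-1) from the cube, preconditions them, and reuses the
    main SVM training.  The returned equation's positive class records the
    component name.
    """
    labeled = extract_windows(
        cube, windows, role_filter="both",
        positive_label=positive_label, negative_label=negative_label,
    )
    if option is not None and option.name != labeled.precondition_tag:
        labeled = apply_option(labeled, option)
    eq, _ = train(labeled, C=C)
    eq.positive_class = positive_label
    return eq
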