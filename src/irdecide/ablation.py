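"""Probe-design ablations: spectral sub-ranges, step decimation, sliding scans.

A tunable quantum cascade laser covers ~200-400 cm^-1 and steps coarsely but
fast; these experiments measure how much classification accuracy survives when
the full FTIR grid is cut down to what such a probe could measure.  Every
ablation restricts/decimates the spectra first and re-fits the training
scaler and SVM on the reduced grid, so no full-range statistics leak in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import LabeledSpectra, decimate as _decimate, restrict as _restrict
from .decision import decide, train
from .grid import make_grid, nearest_index
from .precondition import PreconditionOption, apply_option
from .validation import error_rate, run_loco

__all__ = [
    "AblationResult",
    "subrange_errors",
    "decimation_errors",
    "scan_windows",
    "probe_config_errors",
]


@dataclass
class AblationResult:
    descriptor: object  # (wmin, wmax) | keep_every | window center
    n_steps_used: int
    train_error: float  # percent
    test_error: float  # percent

    def __post_init__(self):
        if self.n_steps_used < 2:
            raise ValueError("an ablation needs at least 2 spectral steps")


def _evaluate(labeled: LabeledSpectra, C, eval_mode, seed, test_fraction):
    """Train/test errors under the chosen protocol on already-reduced data."""
    if eval_mode == "loco":
        res = run_loco(labeled, option=None, C=C)
        train_err = float(
            np.average(
                [f.train_error for f in res.folds],
                weights=[f.d_train.size for f in res.folds],
            )
        )
        return train_err, res.pooled_test_error
    if eval_mode == "pixel_split":
        rng = np.random.default_rng(seed)
        n = labeled.n
        n_test = int(round(test_fraction * n))
        perm = rng.permutation(n)
        te = np.zeros(n, dtype=bool)
        te[perm[:n_test]] = True
        tr_set, te_set = labeled.subset(~te), labeled.subset(te)
        eq, _ = train(tr_set, C=C)
        return (
            error_rate(decide(eq, tr_set.spectra), tr_set.labels),
            error_rate(decide(eq, te_set.spectra), te_set.labels),
        )
    raise ValueError(f"unknown eval_mode {eval_mode!r}")


def _preconditioned(labeled, option):
    if option is not None and option.name != labeled.precondition_tag:
        return apply_option(labeled, option)
    return labeled


def subrange_errors(
    labeled: LabeledSpectra,
    wmin: float,
    wmax: float,
    option: PreconditionOption | None = None,
    C: float = 1.0,
    eval_mode: str = "loco",
    seed: int = 0,
    test_fraction: float = 0.25,
) -> AblationResult:
    """Errors after discarding all spectral data outside [wmin, wmax] cm^-1.

    Preconditioning is applied on the full grid first (baseline and norm are
    whole-spectrum operations), then the spectra are restricted and the
    scaler/SVM re-fit on the restricted grid only.
    """
    labeled = _preconditioned(labeled, option)
    cut = _restrict(labeled, wmin, wmax)
    if cut.grid.count < 2:
        raise ValueError("restricted grid has fewer than 2 points")
    tr, te = _evaluate(cut, C, eval_mode, seed, test_fraction)
    return AblationResult((wmin, wmax), cut.grid.count, tr, te)


def decimation_errors(
    labeled: LabeledSpectra,
    keep_every_list,
    option: PreconditionOption | None = None,
    C: float = 1.0,
    eval_mode: str = "loco",
    seed: int = 0,
    test_fraction: float = 0.25,
):
    """One result per decimation factor; spectra are thinned before training."""
    labeled = _preconditioned(labeled, option)
    out = []
    for k in keep_every_list:
        cut = _decimate(labeled, k)
        if cut.grid.count < 2:
            raise ValueError(f"decimation by {k} leaves fewer than 2 points")
        tr, te = _evaluate(cut, C, eval_mode, seed, test_fraction)
        out.append(AblationResult(int(k), cut.grid.count, tr, te))
    return out


def scan_windows(
    labeled: LabeledSpectra,
    width: float = 200.0,
    stride: float = 100.0,
    option: PreconditionOption | None = None,
    C: float = 1.0,
    eval_mode: str = "loco",
    seed: int = 0,
    test_fraction: float = 0.25,
):
    """Slide a ``width`` cm^-1 window through the grid; errors per center.

    Results are ordered by descending window center.  ``stride`` must be a
    multiple of the grid step; windows are snapped to grid points and only
    positions fully inside the grid are evaluated.
    """
    labeled = _preconditioned(labeled, option)
    g = labeled.grid
    if width > g.span:
        raise ValueError(f"window width {width} exceeds grid span {g.span}")
    if width < 2 * g.step:
        raise ValueError("window width must be at least two grid steps")
    if abs(stride / g.step - round(stride / g.step)) > 1e-9:
        raise ValueError(f"stride {stride} is not a multiple of grid step {g.step}")
    out = []
    top = g.start
    while top - width >= g.end - 1e-9:
        wmin, wmax = top - width, top
        cut = _restrict(labeled, wmin, wmax)
        tr, te = _evaluate(cut, C, eval_mode, seed, test_fraction)
        center = (wmin + wmax) / 2.0
        out.append(AblationResult(center, cut.grid.count, tr, te))
        top -= stride
    return out


def probe_config_errors(
    labeled: LabeledSpectra,
    wmin: float,
    wmax: float,
    step: float,
    option: PreconditionOption | None = None,
    C: float = 1.0,
    eval_mode: str = "loco",
    seed: int = 0,
    test_fraction: float = 0.25,
) -> AblationResult:
    """Discrete-frequency probe configuration: a coarse grid snapped onto the
    native one (e.g. 54 wavenumbers, 1870 down to 1340 in 10 cm^-1 steps)."""
    labeled = _preconditioned(labeled, option)
    g = labeled.grid
    requested = make_grid(wmin, wmax, step)
    idx = []
    for w in requested.values:
        j = nearest_index(g, w)
        if abs(g.values[j] - w) > step / 2.0:
            raise ValueError(
                f"requested wavenumber {w} cm^-1 is farther than {step / 2} "
                f"from the native grid"
            )
        idx.append(j)
    idx = np.array(sorted(set(idx)))
    if idx.size < 2:
        raise ValueError("probe configuration selects fewer than 2 points")
    snapped = g.values[idx]
    spacing = -np.diff(snapped)
    if not np.allclose(spacing, spacing[0], rtol=0, atol=1e-9):
        raise ValueError("snapped probe wavenumbers are not uniformly spaced")
    sub = LabeledSpectra(
        labeled.spectra[:, idx],
        labeled.labels,
        labeled.case_ids,
        make_grid(snapped[0], snapped[-1], spacing[0]),
        labeled.precondition_tag,
    )
    tr, te = _evaluate(sub, C, eval_mode, seed, test_fraction)
    return AblationResult((wmin, wmax, step), sub.grid.count, tr, te)
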