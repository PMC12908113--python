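"""Leave-one-case-out validation and decision-value accounting.

Spectra from one patient/case share instrument session, section thickness and
biology; letting them appear on both sides of a train/test split ("case
leakage") lets a classifier score on patient-specific features rather than
cancer chemistry.  LOCO cross-validation holds out every spectrum of one case
per fold, giving an honest generalization estimate; `leakage_compare` runs the
leaky pixel-level split alongside it to quantify the inflation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cube import LabeledSpectra
from .decision import DecisionEquation, decide, train
from .precondition import PreconditionOption, apply_option

__all__ = [
    "LocoFold",
    "LocoResult",
    "DecisionHistogram",
    "split_loco",
    "error_rate",
    "run_loco",
    "leakage_compare",
    "decision_histogram",
]

log = logging.getLogger(__name__)


@dataclass
class LocoFold:
    held_out_case: str
    train_cases: tuple
    equation: DecisionEquation
    train_error: float  # percent
    test_error: float  # percent
    d_train: np.ndarray
    labels_train: np.ndarray
    d_test: np.ndarray
    labels_test: np.ndarray


@dataclass
class LocoResult:
    folds: list
    pooled_test_error: float  # percent, total errors / total tests
    total_errors: int
    total_tests: int


@dataclass
class DecisionHistogram:
    bin_edges: np.ndarray
    counts_tumor: np.ndarray
    counts_nontumor: np.ndarray
    boundary: float = 0.0
    sd_lines: tuple = (0.0, 0.0)  # +-1 scaled SD of the pooled d values


def split_loco(labeled: LabeledSpectra):
    """One (train_cases, test_case) fold per distinct case, sorted order."""
    cases = sorted(set(labeled.case_ids.tolist()))
    if len(cases) < 2:
        raise ValueError("leave-one-case-out requires >= 2 distinct cases")
    return [(tuple(c for c in cases if c != held), held) for held in cases]


def error_rate(d: np.ndarray, labels: np.ndarray) -> float:
    """Percent misclassified: d > 0 predicts +1 (tumor), d <= 0 predicts -1."""
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if d.size == 0:
        raise ValueError("cannot compute an error rate on empty input")
    if d.shape != labels.shape:
        raise ValueError("d values and labels must have equal length")
    pred = np.where(d > 0, 1, -1)
    return 100.0 * float(np.count_nonzero(pred != labels)) / d.size


def run_loco(
    labeled: LabeledSpectra,
    option: PreconditionOption | None = None,
    C: float = 1.0,
    sd_floor: float | None = None,
) -> LocoResult:
    """Train per fold on all-but-one case, test on the held-out case.

    Preconditioning (if an option is given) is per spectrum and therefore
    applied once up front.  The scaler is re-fit inside each fold's training.
    Pooled error is total errors over total tests, not the mean of per-fold
    percentages.  Folds whose training set lacks a class are skipped with a
    logged warning.
    """
    if option is not None and option.name != labeled.precondition_tag:
        labeled = apply_option(labeled, option)
    folds = []
    total_err = 0
    total_n = 0
    for train_cases, held in split_loco(labeled):
        tr_mask = labeled.case_ids != held
        te_mask = ~tr_mask
        tr = labeled.subset(tr_mask)
        te = labeled.subset(te_mask)
        if np.unique(tr.labels).size < 2:
            log.warning("fold %s skipped: training data contains one class", held)
            continue
        eq, _ = train(tr, C=C, sd_floor=sd_floor)
        d_tr = decide(eq, tr.spectra)
        d_te = decide(eq, te.spectra)
        tr_err = error_rate(d_tr, tr.labels)
        te_err = error_rate(d_te, te.labels)
        folds.append(
            LocoFold(
                held_out_case=held,
                train_cases=train_cases,
                equation=eq,
                train_error=tr_err,
                test_error=te_err,
                d_train=d_tr,
                labels_train=tr.labels,
                d_test=d_te,
                labels_test=te.labels,
            )
        )
        pred = np.where(d_te > 0, 1, -1)
        total_err += int(np.count_nonzero(pred != te.labels))
        total_n += te.n
    if total_n == 0:
        raise ValueError("no usable folds")
    pooled = 100.0 * total_err / total_n
    return LocoResult(folds, pooled, total_err, total_n)


def leakage_compare(
    labeled: LabeledSpectra,
    option: PreconditionOption | None = None,
    C: float = 1.0,
    test_fraction: float = 0.25,
    seed: int = 0,
    sd_floor: float | None = None,
):
    """Pixel-level random split (case-leaky) vs LOCO on the same data.

    Returns ``(pixel_split_error_pct, loco_error_pct)``.  The pixel split
    ignores case structure entirely, so spectra from every case appear on
    both sides; with per-case random effects present this inflates apparent
    accuracy.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if option is not None and option.name != labeled.precondition_tag:
        labeled = apply_option(labeled, option)
    rng = np.random.default_rng(seed)
    n = labeled.n
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError("degenerate split: adjust test_fraction or data size")
    perm = rng.permutation(n)
    te_idx = np.zeros(n, dtype=bool)
    te_idx[perm[:n_test]] = True
    tr = labeled.subset(~te_idx)
    te = labeled.subset(te_idx)
    if np.unique(tr.labels).size < 2 or te.n == 0:
        raise ValueError("degenerate split: a side lacks a class")
    eq, _ = train(tr, C=C, sd_floor=sd_floor)
    pixel_err = error_rate(decide(eq, te.spectra), te.labels)
    loco = run_loco(labeled, option=None, C=C, sd_floor=sd_floor)
    return pixel_err, loco.pooled_test_error


def decision_histogram(
    d: np.ndarray, labels: np.ndarray, n_bins: int = 100
) -> DecisionHistogram:
    """Class-resolved histogram of decision values on shared bin edges.

    Annotates the d = 0 boundary and +-1 standard deviation of the pooled
    d values (the dotted reference lines of the decision-value plots).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels, dtype=int)
    lo, hi = float(d.min()), float(d.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    ct, _ = np.histogram(d[labels == 1], bins=edges)
    cnt, _ = np.histogram(d[labels == -1], bins=edges)
    sd = float(d.std())
    return DecisionHistogram(
        bin_edges=edges,
        counts_tumor=ct,
        counts_nontumor=cnt,
        boundary=0.0,
        sd_lines=(-sd, sd),
    )
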