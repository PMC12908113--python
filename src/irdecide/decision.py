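"""Linear-SVM spectral decision equations and the Decision Contribution Spectrum.

A trained linear SVM on standardized spectra is expressed as a portable
*decision equation*: three spectra and a constant,

    d_k = b + < (Test_k,j - TrainMean_j) / TrainSD_j | beta_j >

where beta_j = sum_i alpha_i y_i (SV_i,j - TrainMean_j)/TrainSD_j is the SVM
beta spectrum (the primal weight vector of the standardized problem).  d_k is
the signed hyper-dimensional distance from the separating hyperplane; d > 0
classifies tumor (the positive class), d <= 0 nontumor.

The *Decision Contribution Spectrum* weighs beta by the standardized
difference of the class-mean spectra:

    DeltaD_j = ((TumorMean_j - NontumorMean_j) / TrainSD_j) * beta_j

Its per-step values sum to d(TumorMean) - d(NontumorMean) (bias cancels), so
it decomposes the average tumor/nontumor decision step by step — a simple,
physical feature-selection tool for probe design.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .cube import LabeledSpectra, NONTUMOR, TUMOR
from .grid import SpectralGrid, make_grid
from .precondition import TrainingScaler, fit_scaler, scale

__all__ = [
    "SupportVectorSet",
    "DecisionEquation",
    "DecisionContributionSpectrum",
    "train",
    "decide",
    "decide_sv_form",
    "class_means",
    "decision_contribution",
    "top_features",
    "export_equation",
    "import_equation",
]

log = logging.getLogger(__name__)


@dataclass
class SupportVectorSet:
    """Raw (unscaled) support vectors with dual weights alpha_i >= 0 and
    class memberships y_i in {-1,+1}."""

    sv: np.ndarray  # m x count, raw spectra
    alpha: np.ndarray  # m, nonnegative
    y: np.ndarray  # m, +-1

    def __post_init__(self):
        self.sv = np.atleast_2d(np.asarray(self.sv, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if np.any(self.alpha < -1e-12):
            raise ValueError("support-vector weights alpha must be >= 0")


@dataclass
class DecisionEquation:
    """Portable linear decision rule: mean, SD and beta spectra plus bias."""

    grid: SpectralGrid
    train_mean: np.ndarray
    train_sd: np.ndarray
    beta: np.ndarray
    bias: float
    positive_class: str = "tumor"
    precondition_tag: str = "bc_norm"
    sd_floor: float = 0.0

    def __post_init__(self):
        n = self.grid.count
        for name in ("train_mean", "train_sd", "beta"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have grid length {n}")
            setattr(self, name, arr)

    @property
    def scaler(self) -> TrainingScaler:
        return TrainingScaler(self.train_mean, self.train_sd, self.sd_floor)


@dataclass
class DecisionContributionSpectrum:
    """Per-step average contribution to the tumor/nontumor decision."""

    grid: SpectralGrid
    delta: np.ndarray
    tumor_mean: np.ndarray
    nontumor_mean: np.ndarray
    d_tumor_mean: float
    d_nontumor_mean: float


def train(
    labeled: LabeledSpectra,
    C: float = 1.0,
    sd_floor: float | None = None,
    tol: float = 1e-3,
) -> tuple[DecisionEquation, SupportVectorSet]:
    """Fit a soft-margin linear SVM on standardized spectra.

    Returns the portable decision equation together with the support-vector
    set (raw, unscaled spectra) so the dual form can be evaluated
    independently.  ``beta`` is the primal weight vector of the standardized
    problem, identical to the dual sum over standardized support vectors.
    """
    classes = np.unique(labeled.labels)
    if classes.size < 2:
        raise ValueError("training requires both classes present")
    scaler = fit_scaler(labeled, sd_floor)
    X = scale(labeled.spectra, scaler)
    svc = SVC(kernel="linear", C=C, tol=tol)
    svc.fit(X, labeled.labels)
    if svc.fit_status_ != 0:
        raise RuntimeError(
            f"SVM solver did not converge (libsvm status {svc.fit_status_})"
        )
    # sklearn orders classes ascending: [-1, +1]; coef_ points toward +1
    beta = svc.coef_.ravel().astype(float)
    bias = float(svc.intercept_[0])
    dual = svc.dual_coef_.ravel()  # alpha_i * y_i
    svs = SupportVectorSet(
        sv=labeled.spectra[svc.support_],
        alpha=np.abs(dual),
        y=np.sign(dual).astype(int),
    )
    eq = DecisionEquation(
        grid=labeled.grid,
        train_mean=scaler.mean,
        train_sd=scaler.sd,
        beta=beta,
        bias=bias,
        positive_class="tumor",
        precondition_tag=labeled.precondition_tag,
        sd_floor=scaler.sd_floor,
    )
    return eq, svs


def _check_grid(eq_grid: SpectralGrid, spectra: np.ndarray):
    if np.atleast_2d(spectra).shape[1] != eq_grid.count:
        raise ValueError(
            f"spectra have {np.atleast_2d(spectra).shape[1]} steps but the "
            f"equation grid has {eq_grid.count}"
        )


def decide(eq: DecisionEquation, spectra, precondition_tag: str | None = None) -> np.ndarray:
    """Evaluate the decision equation: d_k = b + <scaled spectrum | beta>.

    d > 0 classifies into the positive class (tumor), d <= 0 into the
    negative class.  A mismatched preconditioning tag is logged as a warning
    but evaluation proceeds.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    _check_grid(eq.grid, x)
    if precondition_tag is not None and precondition_tag != eq.precondition_tag:
        log.warning(
            "decision equation was trained on %r spectra but got %r",
            eq.precondition_tag, precondition_tag,
        )
    z = scale(x, eq.scaler)
    d = eq.bias + z @ eq.beta
    if np.asarray(spectra).ndim == 1:
        return float(d[0])
    return d


def decide_sv_form(
    svs: SupportVectorSet,
    scaler: TrainingScaler,
    bias: float,
    spectra,
) -> np.ndarray:
    """Dual (support-vector) evaluation of the decision value.

    d_k = b + sum_i alpha_i y_i <scaled SV_i | scaled Test_k>.  Exists as the
    independent oracle for the algebraic identity with :func:`decide`.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    z = scale(x, scaler)
    if svs.sv.size == 0:
        return np.full(z.shape[0], float(bias))
    zsv = scale(svs.sv, scaler)
    # sum_i (alpha_i y_i) <zsv_i | z_k>
    return bias + (z @ zsv.T) @ (svs.alpha * svs.y)


def class_means(labeled: LabeledSpectra) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean spectrum of each class: (tumor, nontumor)."""
    t_mask = labeled.labels == TUMOR
    nt_mask = labeled.labels == NONTUMOR
    if not t_mask.any() or not nt_mask.any():
        raise ValueError("both classes must be present to compute class means")
    return labeled.spectra[t_mask].mean(axis=0), labeled.spectra[nt_mask].mean(axis=0)


def decision_contribution(
    eq: DecisionEquation, tumor_mean: np.ndarray, nontumor_mean: np.ndarray
) -> DecisionContributionSpectrum:
    """Decision Contribution Spectrum from the class-mean spectra.

    delta_j = ((TumorMean_j - NontumorMean_j)/TrainSD_j) * beta_j; the bias
    and training mean cancel in the difference, and sum(delta) equals
    d(TumorMean) - d(NontumorMean).
    """
    t = np.asarray(tumor_mean, dtype=float)
    nt = np.asarray(nontumor_mean, dtype=float)
    _check_grid(eq.grid, t[None, :])
    _check_grid(eq.grid, nt[None, :])
    sd_eff = eq.scaler.effective_sd
    delta = ((t - nt) / sd_eff) * eq.beta
    d_t = float(decide(eq, t[None, :])[0])
    d_nt = float(decide(eq, nt[None, :])[0])
    return DecisionContributionSpectrum(
        grid=eq.grid,
        delta=delta,
        tumor_mean=t,
        nontumor_mean=nt,
        d_tumor_mean=d_t,
        d_nontumor_mean=d_nt,
    )


def top_features(dcs: DecisionContributionSpectrum, k: int):
    """k grid points of largest |delta|, ties toward higher wavenumber.

    Returns a list of (wavenumber, delta) sorted by |delta| descending.
    """
    n = dcs.grid.count
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds grid count {n}")
    mag = np.abs(dcs.delta)
    # grid values descend with index, so a stable sort on (-|delta|, index)
    # breaks ties toward the higher wavenumber
    order = np.lexsort((np.arange(n), -mag))
    return [(float(dcs.grid.values[i]), float(dcs.delta[i])) for i in order[:k]]


# ---------------------------------------------------------------------------
# Decision-equation file: three spectra and a constant
# ---------------------------------------------------------------------------

_EQ_COLUMNS = "wavenumber,train_mean,train_sd,beta,tumor_mean,nontumor_mean"


def export_equation(
    eq: DecisionEquation,
    tumor_mean: np.ndarray,
    nontumor_mean: np.ndarray,
    path,
) -> None:
    """Write the decision equation (plus class means) to a portable CSV.

    Values are written with 17 significant digits so the round trip
    preserves decisions bit-exactly.
    """
    t = np.asarray(tumor_mean, dtype=float)
    nt = np.asarray(nontumor_mean, dtype=float)
    _check_grid(eq.grid, t[None, :])
    buf = io.StringIO()
    buf.write("# decision equation v1\n")
    buf.write(f"# bias = {float(eq.bias)!r}\n")
    buf.write(f"# positive_class = {eq.positive_class}\n")
    buf.write(f"# precondition_tag = {eq.precondition_tag}\n")
    buf.write(f"# sd_floor = {float(eq.sd_floor)!r}\n")
    buf.write(_EQ_COLUMNS + "\n")
    for j in range(eq.grid.count):
        buf.write(
            f"{float(eq.grid.values[j])!r},{float(eq.train_mean[j])!r},"
            f"{float(eq.train_sd[j])!r},{float(eq.beta[j])!r},"
            f"{float(t[j])!r},{float(nt[j])!r}\n"
        )
    with open(path, "w") as f:
        f.write(buf.getvalue())


def import_equation(path):
    """Read a decision-equation CSV; returns (eq, tumor_mean, nontumor_mean)."""
    header = {}
    rows = []
    with open(path) as f:
        lines = f.readlines()
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
            continue
        if line.startswith("wavenumber"):
            if line != _EQ_COLUMNS:
                raise ValueError(f"line {ln}: unexpected column header {line!r}")
            continue
        parts = line.split(",")
        if len(parts) != 6:
            raise ValueError(f"line {ln}: expected 6 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"line {ln}: {exc}") from None
    if "bias" not in header:
        raise ValueError("decision-equation file is missing its bias header")
    if not rows:
        raise ValueError("decision-equation file contains no data rows")
    arr = np.array(rows)
    wn = arr[:, 0]
    if wn.size > 1:
        steps = np.diff(wn)
        step = -steps[0]
        if step <= 0 or not np.allclose(steps, -step, rtol=0, atol=1e-9 * max(1.0, step)):
            raise ValueError("wavenumber column is not uniformly descending")
        grid = make_grid(wn[0], wn[-1], step)
    else:
        grid = make_grid(wn[0], wn[0], 1.0)
    eq = DecisionEquation(
        grid=grid,
        train_mean=arr[:, 1],
        train_sd=arr[:, 2],
        beta=arr[:, 3],
        bias=float(header["bias"]),
        positive_class=header.get("positive_class", "tumor"),
        precondition_tag=header.get("precondition_tag", "bc_norm"),
        sd_floor=float(header.get("sd_floor", 0.0)),
    )
    return eq, arr[:, 4], arr[:, 5]
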