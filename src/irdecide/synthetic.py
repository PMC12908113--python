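"""Synthetic multi-case hyperspectral tissue scenes with known ground truth.

The real spectral library this package's methods were designed around
(hundreds of thousands of extinction spectra from frozen liver sections of a
handful of patients) is private, so every pipeline stage is exercised on
synthetic cubes that emulate its statistical structure:

- protein-dominated extinction spectra built from Gaussian/Lorentzian bands:
  amide I sub-bands (1694/1658/1646/1630 cm^-1) whose composition differs
  between tumor and nontumor, amide II (1547), lipid bands (1741/2925/2853),
  phosphate (1240/1083) and glycogen (1008);
- smooth scattering baselines (constant + slope + mild curvature) and
  multiplicative section-thickness variation per pixel;
- per-case random effects (log-normal band-amplitude multipliers and small
  center jitters) that make case leakage demonstrable;
- spatial layouts with a tumor region, a nontumor region, a linear-mixture
  transition band between them, lipid blobs gathered at the transition, and
  one lymphocyte-rich region — plus train/test windows strictly inside the
  pure-class regions and a ground-truth class image.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cube import RegionWindow, SpectrumCube
from .grid import REFERENCE_GRID_PARAMS, SpectralGrid, make_grid

__all__ = [
    "BandComponent",
    "SyntheticSceneConfig",
    "CaseEffects",
    "GroundTruth",
    "default_band_table",
    "spectrum_model",
    "generate_case",
    "generate_library",
    "null_config",
]

CLASS_NONTUMOR = 0
CLASS_TUMOR = 1
CLASS_TRANSITION = 2
CLASS_LIPID = 3
CLASS_LYMPHOCYTE = 4

_CLASS_NAMES = ("nontumor", "tumor", "transition", "lipid", "lymphocyte")


@dataclass(frozen=True)
class BandComponent:
    """One vibrational band: center/width plus per-class peak amplitude."""

    center: float  # cm^-1
    fwhm: float  # cm^-1
    amplitude_by_class: dict  # class name -> amplitude >= 0
    shape: str = "gaussian"  # gaussian | lorentzian

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        if not any(a > 0 for a in self.amplitude_by_class.values()):
            raise ValueError("band needs at least one positive amplitude")

    def amplitude(self, cls: str) -> float:
        return float(self.amplitude_by_class.get(cls, 0.0))


def _amps(tumor, nontumor, lipid, lymphocyte):
    return {
        "tumor": tumor,
        "nontumor": nontumor,
        "lipid": lipid,
        "lymphocyte": lymphocyte,
    }


def default_band_table():
    """Band table emulating frozen-section liver tissue extinction spectra.

    Tumor/nontumor differences are concentrated in the amide-I sub-band
    composition (secondary-structure changes with cancer transformation),
    with smaller differentials on the phosphate 1240 and glycogen 1008
    bands.  Lipid C-H and C=O bands are equal across tumor/nontumor tissue
    and dominate the lipid class; the lymphocyte class has its own
    nucleic-acid-heavy profile.
    """
    return (
        # amide I sub-bands: class-differential composition with alternating
        # sign (tumor up at 1694/1646, down at 1658/1630) so neighboring
        # differential lobes stay resolvable
        BandComponent(1694.0, 14.0, _amps(0.30, 0.22, 0.05, 0.24)),
        BandComponent(1658.0, 14.0, _amps(0.55, 0.65, 0.06, 0.50)),
        BandComponent(1646.0, 14.0, _amps(0.50, 0.38, 0.05, 0.45)),
        BandComponent(1630.0, 14.0, _amps(0.28, 0.38, 0.04, 0.42)),
        # amide II
        BandComponent(1547.0, 40.0, _amps(0.55, 0.55, 0.04, 0.55)),
        # lipid ester carbonyl and C-H stretches
        BandComponent(1741.0, 20.0, _amps(0.06, 0.06, 0.90, 0.05)),
        BandComponent(2925.0, 35.0, _amps(0.25, 0.25, 1.00, 0.25)),
        BandComponent(2853.0, 25.0, _amps(0.12, 0.12, 0.70, 0.12)),
        # phosphate (nucleic acids, phospholipids)
        BandComponent(1240.0, 30.0, _amps(0.30, 0.26, 0.08, 0.42)),
        BandComponent(1083.0, 30.0, _amps(0.28, 0.28, 0.10, 0.40)),
        # glycogen shoulder, higher in normal liver
        BandComponent(1008.0, 25.0, _amps(0.12, 0.16, 0.02, 0.08)),
    )


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Full description of a synthetic multi-case library."""

    grid_params: tuple = REFERENCE_GRID_PARAMS  # (start, end, step) cm^-1
    image_shape: tuple = (64, 64)  # rows, cols per case
    bands: tuple = field(default_factory=default_band_table)
    # baseline(nu) = b0 + b1*u + b2*u^2, u in [0,1] across the grid span;
    # per-pixel coefficients drawn uniformly from these (lo, hi) ranges
    baseline_b0: tuple = (0.05, 0.30)
    baseline_b1: tuple = (-0.10, 0.10)
    baseline_b2: tuple = (-0.05, 0.10)
    thickness_range: tuple = (0.8, 1.2)  # multiplicative, per pixel
    noise_sd: float = 0.02  # i.i.d. Gaussian, amide-I SNR ~ 50
    case_effect_sd: float = 0.12  # log-amplitude multiplier SD per (case, band)
    center_jitter_max: float = 2.0  # cm^-1, per (case, band)
    tumor_fraction: float = 0.42  # columns assigned to tumor (left side)
    transition_width: int = 8  # columns of linear tumor->nontumor mixing
    lipid_blob_count: int = 3
    lipid_blob_radius: int = 4
    lipid_mix: float = 0.7  # lipid weight inside a blob; rest is local tissue
    lymphocyte_shape: tuple = (10, 10)
    window_size: int = 6
    n_cases: int = 7
    seed: int = 0

    def grid(self) -> SpectralGrid:
        return make_grid(*self.grid_params)


@dataclass(frozen=True)
class CaseEffects:
    """Per-case random effects: one multiplier and jitter per band."""

    amplitude_factor: np.ndarray  # (n_bands,), log-normal
    center_jitter: np.ndarray  # (n_bands,), cm^-1


@dataclass
class GroundTruth:
    """Planted truth for recovery tests."""

    class_image: np.ndarray  # rows x cols of CLASS_* codes
    differential_band_centers: np.ndarray  # tumor amp != nontumor amp
    differential_band_weights: np.ndarray  # |tumor - nontumor| amplitude
    case_effects: CaseEffects
    lipid_mask: np.ndarray  # rows x cols bool
    lymphocyte_mask: np.ndarray

    @property
    def discriminative_cluster_center(self) -> float:
        """Weighted center of the dominant cluster of differential bands.

        Differential band centers closer than 100 cm^-1 are grouped into one
        cluster; the cluster with the largest total amplitude difference is
        the discriminative cluster, and its amplitude-weighted mean center is
        returned.  Weak isolated differentials elsewhere do not shift it.
        """
        order = np.argsort(self.differential_band_centers)
        c = self.differential_band_centers[order]
        w = self.differential_band_weights[order]
        clusters = [[0]]
        for i in range(1, c.size):
            if c[i] - c[i - 1] <= 100.0:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        best = max(clusters, key=lambda idx: w[idx].sum())
        return float(np.sum(c[best] * w[best]) / np.sum(w[best]))


def _lineshape(grid_values: np.ndarray, center: float, fwhm: float, shape: str):
    if shape == "gaussian":
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((grid_values - center) / sigma) ** 2)
    # lorentzian
    hwhm = fwhm / 2.0
    return hwhm**2 / ((grid_values - center) ** 2 + hwhm**2)


def _null_effects(n_bands: int) -> CaseEffects:
    return CaseEffects(np.ones(n_bands), np.zeros(n_bands))


def spectrum_model(
    bands,
    cls: str,
    case_effects: CaseEffects | None,
    thickness: float,
    baseline_coeffs,
    grid: SpectralGrid,
) -> np.ndarray:
    """Noise-free pixel model: thickness x sum of bands + baseline."""
    bands = tuple(bands)
    if case_effects is None:
        case_effects = _null_effects(len(bands))
    v = grid.values
    out = np.zeros(grid.count)
    for b, fac, jit in zip(bands, case_effects.amplitude_factor, case_effects.center_jitter):
        amp = b.amplitude(cls) * fac
        if amp > 0:
            out += amp * _lineshape(v, b.center + jit, b.fwhm, b.shape)
    out *= thickness
    b0, b1, b2 = baseline_coeffs
    u = (v - grid.end) / max(grid.span, 1.0)
    return out + b0 + b1 * u + b2 * u**2


def _class_models(config: SyntheticSceneConfig, effects: CaseEffects, grid: SpectralGrid):
    """Unit-thickness, zero-baseline model spectrum per class."""
    zero = (0.0, 0.0, 0.0)
    return {
        cls: spectrum_model(config.bands, cls, effects, 1.0, zero, grid)
        for cls in ("tumor", "nontumor", "lipid", "lymphocyte")
    }


def _layout(config: SyntheticSceneConfig):
    """Class image plus masks; deterministic given the config."""
    rows, cols = config.image_shape
    t_cols = int(round(config.tumor_fraction * cols))
    trans0, trans1 = t_cols, t_cols + config.transition_width
    if trans1 >= cols - 12:
        raise ValueError("layout infeasible: transition leaves no nontumor room")
    cls_img = np.full((rows, cols), CLASS_NONTUMOR, dtype=int)
    cls_img[:, :t_cols] = CLASS_TUMOR
    cls_img[:, trans0:trans1] = CLASS_TRANSITION

    # tumor weight: 1 in tumor, 0 in nontumor, linear ramp across transition
    w_t = np.zeros(cols)
    w_t[:t_cols] = 1.0
    ramp = np.linspace(1.0, 0.0, config.transition_width + 2)[1:-1]
    w_t[trans0:trans1] = ramp
    tumor_weight = np.broadcast_to(w_t, (rows, cols)).copy()

    # lipid blobs: disks centered on the transition band, spread over rows
    lipid_mask = np.zeros((rows, cols), dtype=bool)
    cx = (trans0 + trans1) // 2
    r = config.lipid_blob_radius
    centers = np.linspace(r + 4, rows - r - 5, config.lipid_blob_count).round().astype(int)
    yy, xx = np.mgrid[0:rows, 0:cols]
    for cy in centers:
        lipid_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    cls_img[lipid_mask] = CLASS_LIPID

    # lymphocyte-rich region in the nontumor corner
    lr, lc = config.lymphocyte_shape
    ly0, lx0 = rows - lr - 2, cols - lc - 2
    if ly0 < 0 or lx0 < trans1:
        raise ValueError("layout infeasible: lymphocyte region does not fit")
    lymph_mask = np.zeros((rows, cols), dtype=bool)
    lymph_mask[ly0 : ly0 + lr, lx0 : lx0 + lc] = True
    cls_img[lymph_mask] = CLASS_LYMPHOCYTE
    lipid_mask &= ~lymph_mask

    return cls_img, tumor_weight, lipid_mask, lymph_mask, (ly0, lx0)


def _windows(config: SyntheticSceneConfig, cls_img: np.ndarray, lymph_origin):
    """Train/test windows strictly inside pure-class regions."""
    rows, cols = cls_img.shape
    s = config.window_size

    def window_at(r0, c0, label, role):
        w = RegionWindow(r0, c0, r0 + s, c0 + s, label, role)
        want = CLASS_TUMOR if label == "tumor" else CLASS_NONTUMOR
        block = cls_img[w.row0 : w.row1, w.col0 : w.col1]
        if not np.all(block == want):
            raise ValueError(f"window {w} is not purely {label}")
        return w

    t_cols = int(round(config.tumor_fraction * cols))
    trans1 = t_cols + config.transition_width
    # keep clear of the transition/lipid column band and the lymphocyte corner
    tc = max(2, t_cols - config.lipid_blob_radius - 2 - s)
    nc = min(cols - s - 2, cols - s - 4)
    wins = [
        window_at(rows // 10, 4, "tumor", "train"),
        window_at(rows // 2 + 4, min(10, tc), "tumor", "train"),
        window_at(rows - s - 4, 4, "tumor", "test"),
        window_at(rows // 10, trans1 + config.lipid_blob_radius + 4, "nontumor", "train"),
        window_at(rows // 2 + 4, trans1 + config.lipid_blob_radius + 4, "nontumor", "train"),
        window_at(rows // 4, nc, "nontumor", "test"),
    ]
    # secondary-model windows (excluded from tumor/nontumor extraction)
    ly0, lx0 = lymph_origin
    lr, lc = config.lymphocyte_shape
    ws = min(s, lr - 2, lc - 2)
    wins.append(RegionWindow(ly0 + 1, lx0 + 1, ly0 + 1 + ws, lx0 + 1 + ws, "lymphocyte", "train"))
    lipid_px = np.argwhere(cls_img == CLASS_LIPID)
    if lipid_px.size:
        cy, cx = lipid_px.mean(axis=0).round().astype(int)
        half = max(1, config.lipid_blob_radius // 2)
        wins.append(
            RegionWindow(cy - half, cx - half, cy + half, cx + half, "lipid", "train")
        )
    return wins


def _case_effects(config: SyntheticSceneConfig, rng: np.random.Generator) -> CaseEffects:
    n = len(config.bands)
    if config.case_effect_sd > 0:
        fac = np.exp(rng.normal(0.0, config.case_effect_sd, size=n))
        jit = rng.uniform(-config.center_jitter_max, config.center_jitter_max, size=n)
    else:
        # case_effect_sd = 0 means no case-level structure at all
        fac = np.ones(n)
        jit = np.zeros(n)
    return CaseEffects(amplitude_factor=fac, center_jitter=jit)


def generate_case(config: SyntheticSceneConfig, case_index: int, seed: int | None = None):
    """Generate one case: (SpectrumCube, GroundTruth, windows).

    Deterministic in (config, case_index, seed); ``seed`` defaults to
    ``config.seed``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), int(case_index)])
    grid = config.grid()
    rows, cols = config.image_shape

    effects = _case_effects(config, rng)
    models = _class_models(config, effects, grid)
    cls_img, tumor_weight, lipid_mask, lymph_mask, lymph_origin = _layout(config)

    # per-pixel mixture weights over the four class models
    w = np.zeros((rows, cols, 4))  # tumor, nontumor, lipid, lymphocyte
    w[:, :, 0] = tumor_weight
    w[:, :, 1] = 1.0 - tumor_weight
    lm = config.lipid_mix
    w[lipid_mask] *= 1.0 - lm
    w[lipid_mask, 2] = lm
    w[lymph_mask] = 0.0
    w[lymph_mask, 3] = 1.0

    model_mat = np.stack(
        [models["tumor"], models["nontumor"], models["lipid"], models["lymphocyte"]]
    )  # 4 x count
    band_part = w.reshape(-1, 4) @ model_mat  # (rows*cols) x count

    thickness = rng.uniform(*config.thickness_range, size=(rows * cols, 1))
    b0 = rng.uniform(*config.baseline_b0, size=(rows * cols, 1))
    b1 = rng.uniform(*config.baseline_b1, size=(rows * cols, 1))
    b2 = rng.uniform(*config.baseline_b2, size=(rows * cols, 1))
    u = (grid.values - grid.end) / max(grid.span, 1.0)
    data = thickness * band_part + b0 + b1 * u + b2 * u**2
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    cube = SpectrumCube(
        grid=grid,
        data=data.reshape(rows, cols, grid.count),
        case_id=f"case{case_index + 1:02d}",
    )

    diff = np.array(
        [abs(b.amplitude("tumor") - b.amplitude("nontumor")) for b in config.bands]
    )
    planted = diff > 0
    truth = GroundTruth(
        class_image=cls_img,
        differential_band_centers=np.array(
            [b.center for b, p in zip(config.bands, planted) if p]
        ),
        differential_band_weights=diff[planted],
        case_effects=effects,
        lipid_mask=lipid_mask,
        lymphocyte_mask=lymph_mask,
    )
    windows = _windows(config, cls_img, lymph_origin)
    return cube, truth, windows


def generate_library(config: SyntheticSceneConfig):
    """Generate ``config.n_cases`` cases with independent case effects."""
    if config.n_cases < 2:
        raise ValueError("a library needs at least 2 cases")
    return [generate_case(config, i) for i in range(config.n_cases)]


def null_config(config: SyntheticSceneConfig) -> SyntheticSceneConfig:
    """Remove the planted class signal: equalize tumor/nontumor amplitudes.

    Each differential band's tumor and nontumor amplitudes are replaced by
    their mean; everything else (lipid/lymphocyte profiles, noise, case
    effects, layout) is unchanged.  Idempotent.
    """
    bands = []
    for b in config.bands:
        a = dict(b.amplitude_by_class)
        m = 0.5 * (b.amplitude(("tumor")) + b.amplitude("nontumor"))
        a["tumor"] = a["nontumor"] = m
        bands.append(replace(b, amplitude_by_class=a))
    return replace(config, bands=tuple(bands))
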