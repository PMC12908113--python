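"""Decision-equation imaging: render d values and masks as RGB images.

Conventions: positive decision values (tumor) in red scaled by the positive
max, negative values (nontumor) in green scaled by the negative extreme,
d = 0 black.  Values near the tumor/nontumor transition (-0.5 < d <= 0 and
0 < d <= +0.5) may be drawn in light green / light red; component overlays
use yellow (lipid) and purple (lymphocyte).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecisionImage",
    "RenderSpec",
    "render_decision",
    "render_transition",
    "overlay_mask",
    "COLOR_LIPID",
    "COLOR_LYMPHOCYTE",
]

COLOR_LIPID = (1.0, 1.0, 0.0)  # yellow
COLOR_LYMPHOCYTE = (0.5, 0.0, 0.5)  # purple


@dataclass
class DecisionImage:
    d: np.ndarray  # rows x cols decision values
    valid: np.ndarray | None = None  # bool mask; default all-valid

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.d)
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & np.isfinite(self.d)


@dataclass
class RenderSpec:
    scaling: str = "minmax"  # minmax | mean2sd
    transition_bounds: tuple = (-0.5, 0.0, 0.5)
    light_blend: float = 0.5  # white fraction for the "light" shades

    def __post_init__(self):
        if self.scaling not in ("minmax", "mean2sd"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        lo, mid, hi = self.transition_bounds
        if not lo < mid < hi:
            raise ValueError("transition bounds must be ordered")
        if not 0.0 < self.light_blend < 1.0:
            raise ValueError("light blend factor must lie in (0, 1)")


def _sign_scales(d: np.ndarray, valid: np.ndarray, scaling: str):
    """Positive and negative scale magnitudes per the chosen statistic."""
    pos = d[valid & (d > 0)]
    neg = d[valid & (d < 0)]
    if scaling == "minmax":
        pos_scale = float(pos.max()) if pos.size else 1.0
        neg_scale = float(-neg.min()) if neg.size else 1.0
    else:  # mean2sd: clamp at mean + 2 SD of each sign group
        pos_scale = float(pos.mean() + 2 * pos.std()) if pos.size else 1.0
        neg_scale = float(-(neg.mean() - 2 * neg.std())) if neg.size else 1.0
        pos_scale = pos_scale if pos_scale > 0 else 1.0
        neg_scale = neg_scale if neg_scale > 0 else 1.0
    return pos_scale, neg_scale


def render_decision(img: DecisionImage, spec: RenderSpec = RenderSpec()) -> np.ndarray:
    """RGB float image: red = d/d_max for d > 0, green = |d|/|d_min| for d < 0.

    ``mean2sd`` scaling clamps each sign group at its mean +- 2 SD so rare
    extreme values saturate instead of compressing the display range.
    Invalid pixels are black.
    """
    if not img.valid.any():
        raise ValueError("decision image has no valid pixels")
    d = img.d
    pos_scale, neg_scale = _sign_scales(d, img.valid, spec.scaling)
    rgb = np.zeros(d.shape + (3,))
    pos = img.valid & (d > 0)
    neg = img.valid & (d < 0)
    rgb[pos, 0] = np.clip(d[pos] / pos_scale, 0.0, 1.0)
    rgb[neg, 1] = np.clip(-d[neg] / neg_scale, 0.0, 1.0)
    return rgb


def render_transition(img: DecisionImage, spec: RenderSpec = RenderSpec()) -> np.ndarray:
    """Like :func:`render_decision` but shades the transition zone.

    Pixels with lo < d <= 0 are light green, 0 < d <= hi light red, where
    "light" blends the pure color with white at ``spec.light_blend``.
    """
    rgb = render_decision(img, spec)
    lo, mid, hi = spec.transition_bounds
    d = img.d
    b = spec.light_blend
    light_green = b * np.array([1.0, 1.0, 1.0]) + (1 - b) * np.array([0.0, 1.0, 0.0])
    light_red = b * np.array([1.0, 1.0, 1.0]) + (1 - b) * np.array([1.0, 0.0, 0.0])
    green_zone = img.valid & (d > lo) & (d <= mid)
    red_zone = img.valid & (d > mid) & (d <= hi)
    rgb[green_zone] = light_green
    rgb[red_zone] = light_red
    return rgb


def overlay_mask(rgb: np.ndarray, mask: np.ndarray, color) -> np.ndarray:
    """Replace masked pixels with a flat overlay color."""
    rgb = np.asarray(rgb, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if rgb.shape[:2] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {rgb.shape[:2]}"
        )
    out = rgb.copy()
    out[mask] = np.asarray(color, dtype=float)
    return out
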