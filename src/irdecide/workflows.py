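"""Convenience pipelines gluing generator, preconditioning and models.

These are the entry points the analysis drivers, the CLI and the acceptance
checks share: build a labeled window-spectra library from a synthetic config,
run the standard train + Decision Contribution Spectrum analysis, etc.
"""

from __future__ import annotations

import numpy as np

from .cube import LabeledSpectra, concat_labeled, extract_windows
from .decision import class_means, decision_contribution, train
from .precondition import PreconditionOption, apply_option
from .synthetic import SyntheticSceneConfig, generate_library

__all__ = [
    "library_spectra",
    "train_full",
    "default_option",
]


def default_option() -> PreconditionOption:
    """Baseline-corrected and normalized: the option used for probe work."""
    return PreconditionOption("bc_norm")


def library_spectra(
    config: SyntheticSceneConfig,
    option: PreconditionOption | None = None,
    role_filter: str = "both",
) -> LabeledSpectra:
    """Generate a library and flatten its tumor/nontumor window pixels.

    Returns one LabeledSpectra spanning all cases, optionally preconditioned
    (per spectrum, so it is safe to do once, before any train/test split).
    """
    parts = []
    for cube, _truth, windows in generate_library(config):
        parts.append(extract_windows(cube, windows, role_filter=role_filter))
    labeled = concat_labeled(parts)
    if option is not None and option.name != labeled.precondition_tag:
        labeled = apply_option(labeled, option)
    return labeled


def train_full(labeled: LabeledSpectra, C: float = 1.0):
    """Train on all cases and derive the Decision Contribution Spectrum.

    Returns (equation, support_vectors, dcs).
    """
    eq, svs = train(labeled, C=C)
    t_mean, nt_mean = class_means(labeled)
    dcs = decision_contribution(eq, t_mean, nt_mean)
    return eq, svs, dcs
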