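"""Train the tumor/nontumor decision equation and extract the Decision
Contribution Spectrum.

Trains a linear SVM on baseline-corrected, vector-normalized window spectra
from all 7 synthetic cases, exports the portable decision equation (three
spectra and a constant), and reports the wavenumbers contributing most to
the tumor/nontumor decision, which should recover the planted amide-I
sub-band differentials.
"""

from pathlib import Path

import pandas as pd

import irdecide as ir

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ir.SyntheticSceneConfig(n_cases=7, seed=SEED)
    lab = ir.library_spectra(cfg, ir.default_option())
    eq, svs, dcs = ir.train_full(lab)

    ir.export_equation(eq, dcs.tumor_mean, dcs.nontumor_mean, OUT / "decision_equation.csv")
    pd.DataFrame(
        {
            "wavenumber": dcs.grid.values,
            "delta": dcs.delta,
            "tumor_mean": dcs.tumor_mean,
            "nontumor_mean": dcs.nontumor_mean,
        }
    ).to_csv(OUT / "decision_contribution.csv", index=False)

    print(f"trained on {lab.n} spectra from 7 cases "
          f"({len(svs.alpha)} support vectors, bias {eq.bias:+.4f})")
    print("\nlargest contributions to the tumor/nontumor decision:")
    _, truth, _ = ir.generate_case(cfg, 0)
    for wn, delta in ir.top_features(dcs, 8):
        nearest = min(truth.differential_band_centers, key=lambda c: abs(c - wn))
        print(f"  {wn:7.1f} cm^-1  delta = {delta:+.4f}   "
              f"(planted differential at {nearest:.0f})")


if __name__ == "__main__":
    main()
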