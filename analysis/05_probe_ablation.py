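"""Probe-design ablations: how little spectrum suffices to call tumor?

Re-trains the classifier on restricted ranges (H-stretch vs fingerprint and
the four single-laser fingerprint subregions), on decimated grids (2 to 20
cm^-1 steps), on a 200 cm^-1 window scanned through the whole range, and on
a 54-wavenumber discrete-frequency configuration (1870-1340 cm^-1, 10 cm^-1
steps).  Uses the window train/test split protocol, matching how such range
studies are usually scored.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import irdecide as ir

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
EVAL = dict(eval_mode="pixel_split", seed=SEED)

REGIONS = [
    ("H-stretch 3670-2790", 2790, 3670),
    ("fingerprint 1860-760", 760, 1860),
    ("sub 1850-1644", 1644, 1850),
    ("sub 1642-1352", 1352, 1642),
    ("sub 1350-986", 986, 1350),
    ("sub 984-780", 780, 984),
]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ir.SyntheticSceneConfig(n_cases=7, seed=SEED)
    lab = ir.library_spectra(cfg, ir.default_option())
    rows = []

    print("spectral regions:")
    for name, wmin, wmax in REGIONS:
        r = ir.subrange_errors(lab, wmin, wmax, **EVAL)
        rows.append({"experiment": "region", "descriptor": name,
                     "n_steps": r.n_steps_used,
                     "train_error_pct": r.train_error, "test_error_pct": r.test_error})
        print(f"  {name:22s} {r.n_steps_used:5d} steps  "
              f"train {r.train_error:5.2f}%  test {r.test_error:5.2f}%")

    print("step decimation (full range):")
    for r in ir.decimation_errors(lab, [1, 2, 5, 10], **EVAL):
        step = lab.grid.step * r.descriptor
        rows.append({"experiment": "decimate", "descriptor": f"{step:g} cm-1 steps",
                     "n_steps": r.n_steps_used,
                     "train_error_pct": r.train_error, "test_error_pct": r.test_error})
        print(f"  {step:4g} cm^-1 steps  {r.n_steps_used:5d} pts  "
              f"train {r.train_error:5.2f}%  test {r.test_error:5.2f}%")

    print("200 cm^-1 window scan:")
    scan = ir.scan_windows(lab, width=200, stride=100, **EVAL)
    for r in scan:
        rows.append({"experiment": "scan", "descriptor": r.descriptor,
                     "n_steps": r.n_steps_used,
                     "train_error_pct": r.train_error, "test_error_pct": r.test_error})
    best = scan[int(np.argmin([r.test_error for r in scan]))]
    _, truth, _ = ir.generate_case(cfg, 0)
    print(f"  best center {best.descriptor:.0f} cm^-1 "
          f"(test {best.test_error:.2f}%); planted discriminative cluster at "
          f"{truth.discriminative_cluster_center:.0f} cm^-1")

    print("54-wavenumber probe configuration (1870-1340, 10 cm^-1):")
    r = ir.probe_config_errors(lab, 1340, 1870, 10, **EVAL)
    rows.append({"experiment": "probe", "descriptor": "1870-1340/10",
                 "n_steps": r.n_steps_used,
                 "train_error_pct": r.train_error, "test_error_pct": r.test_error})
    print(f"  {r.n_steps_used} wavenumbers  train {r.train_error:.2f}%  "
          f"test {r.test_error:.2f}%")

    pd.DataFrame(rows).to_csv(OUT / "probe_ablation.csv", index=False)
    print(f"\nwrote {OUT / 'probe_ablation.csv'}")


if __name__ == "__main__":
    main()
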