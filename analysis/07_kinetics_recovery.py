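"""Kinetic parameter recovery and the avidity contrast.

Simulates the standard biosensor design (180 s association/dissociation,
six-point 1:2 dilution from 500 nM, 2% Gaussian noise) from known 1:1
parameters and refits globally, over 100 noise realisations; then simulates
a bivalent analyte and fits it with the 1:1 model to quantify the apparent
affinity tightening that avidity produces.

Findings: median recovery errors are ~2% for kon and koff (well under 5%),
and the bivalent analyte's apparent KD is ~65x tighter than the intrinsic
per-site KD — the same order-of-magnitude contrast seen when a dimeric
receptor is flowed over an arrayed ligand instead of the reverse.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from epimimic.kinetics import (
    KineticModel,
    dilution_series,
    fit_1to1,
    simulate_bivalent,
    simulate_sensorgram,
)

OUT = Path(__file__).resolve().parent.parent / "results"
TRUTH = KineticModel(kon=2.2e5, koff=1.6e-1, rmax=1.0)


def main() -> None:
    design = dilution_series(500e-9, 6)
    rows = []
    for seed in range(100):
        data = simulate_sensorgram(TRUTH, design, noise_sd=0.02, seed=seed)
        fit = fit_1to1(data)
        if fit.converged:
            rows.append(
                {
                    "seed": seed,
                    "kon_err": abs(fit.model.kon / TRUTH.kon - 1),
                    "koff_err": abs(fit.model.koff / TRUTH.koff - 1),
                    "kd_err": abs(fit.model.kd / TRUTH.kd - 1),
                }
            )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "kinetics_recovery.csv", index=False, float_format="%.5f")
    med = frame[["kon_err", "koff_err", "kd_err"]].median() * 100
    print(f"converged fits: {len(frame)}/100")
    print("median recovery errors (%):")
    print(med.to_string(float_format="%.2f"))

    biv = simulate_bivalent(TRUTH, design)
    fit_biv = fit_1to1(biv)
    ratio = TRUTH.kd / fit_biv.model.kd
    print(f"\nintrinsic per-site KD: {TRUTH.kd * 1e9:.0f} nM")
    print(f"apparent 1:1 KD of the bivalent analyte: {fit_biv.model.kd * 1e9:.1f} nM")
    print(f"avidity tightening: {ratio:.0f}x")
    pd.DataFrame(
        [{"intrinsic_kd_nM": TRUTH.kd * 1e9, "apparent_kd_nM": fit_biv.model.kd * 1e9,
          "ratio": ratio}]
    ).to_csv(OUT / "avidity_contrast.csv", index=False, float_format="%.3f")


if __name__ == "__main__":
    main()
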