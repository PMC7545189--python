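"""Generate the synthetic study systems every later step analyses.

Writes PDB fixtures (two-sphere oracle system, toy interface, mimicry pair)
and a noisy multi-concentration sensorgram into results/fixtures/, each
bundled with its generating truth, so the whole analysis chain is
reproducible offline from plain-text inputs.
"""

import json
from pathlib import Path

from epimimic.structure_io import write_pdb
from epimimic.synthetic import (
    ToyComplexSpec,
    make_bli_dataset,
    make_mimicry_pair,
    make_toy_interface,
    two_sphere_model,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    model, params = two_sphere_model(1.8, 1.5, d=4.0)
    (OUT / "two_sphere.pdb").write_text(write_pdb(model))

    toy = make_toy_interface(ToyComplexSpec(n_residues=10, n_contacts=4, seed=0))
    (OUT / "toy_interface.pdb").write_text(write_pdb(toy.model))

    scenario = make_mimicry_pair(4, 3, seed=0)
    (OUT / "mimicry_natural.pdb").write_text(write_pdb(scenario.natural_model))
    (OUT / "mimicry_antibody.pdb").write_text(write_pdb(scenario.antibody_model))

    data, truth = make_bli_dataset(noise_sd=0.02, seed=0, dt=2.0)
    data.to_frame().to_csv(OUT / "bli_sensorgram.csv", index=False, float_format="%.5g")

    manifest = {
        "two_sphere": {"r1": 1.8, "r2": 1.5, "d": 4.0, "probe": params.probe_radius},
        "toy_interface": {"n_residues": 10, "n_contacts": 4,
                          "expected_footprint": list(toy.expected_footprint)},
        "mimicry_pair": {"n_interface": 4, "n_shared": 3,
                         "truth_fraction": scenario.truth_fraction},
        "bli": {"kon": truth.kon, "koff": truth.koff, "rmax": truth.rmax,
                "kd": truth.kd, "noise_sd": 0.02},
    }
    (OUT / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote {len(list(OUT.iterdir()))} fixture files to {OUT}")
    print("truths:", json.dumps(manifest, indent=2))


if __name__ == "__main__":
    main()
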