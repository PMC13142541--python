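"""Labeling-method FRC comparison on simulated two-channel fields.

Simulates punctate nuclear fields imaged in a target channel and a
deposition channel under three labeling regimes — a diffusion-free
photocatalytic regime, intermediate diffusion scales, and a
peroxidase-like regime with 800 nm diffusion plus a displaced-label halo
— alongside matched bead slides, then measures the 1/7-threshold FRC
crossing of each.  Findings: the crossing feature size grows
monotonically with labeling diffusion; the diffusion-free regime is
indistinguishable from the bead optical floor; the halo regime crosses at
several-fold coarser scales and its FRC turns negative below ~1 um.

Writes results/frc_sweep.tsv, results/frc_comparison.json and per-FOV
curves under results/frc/.
"""

import dataclasses
import json
import sys
from pathlib import Path

import pandas as pd

import poca

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    base = poca.ImageSimConfig()  # 110 nm pixels, ~300 puncta per field
    conditions = {
        "diffusion_0nm": base,
        "diffusion_200nm": dataclasses.replace(base, diffusion_sigma=200.0),
        "diffusion_400nm": dataclasses.replace(base, diffusion_sigma=400.0),
        "hrp_like_800nm_halo": dataclasses.replace(
            base, diffusion_sigma=800.0, halo_fraction=0.8, halo_radius=700.0),
    }
    report = poca.run_frc_comparison(conditions, n_fov=3, bead_config=base,
                                     seed=SEED, out_dir=OUT / "frc")

    rows = []
    for name, c in report["conditions"].items():
        rows.append({"condition": name, "mean_nm": c["mean_nm"],
                     "sd_nm": c["sd_nm"],
                     "ratio_to_bead": report["ratio_to_bead"][name]})
    rows.append({"condition": "beads", "mean_nm": report["bead_floor_nm"],
                 "sd_nm": report["bead_sd_nm"], "ratio_to_bead": 1.0})
    sweep = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    sweep.to_csv(OUT / "frc_sweep.tsv", sep="\t", index=False)
    (OUT / "frc_comparison.json").write_text(json.dumps(report, indent=2))

    print(sweep.to_string(index=False))
    poca_nm = report["conditions"]["diffusion_0nm"]["mean_nm"]
    hrp_nm = report["conditions"]["hrp_like_800nm_halo"]["mean_nm"]
    print(f"\nbead optical floor: {report['bead_floor_nm']:.0f} nm")
    print(f"diffusion-free crossing: {poca_nm:.0f} nm "
          f"({poca_nm / report['bead_floor_nm']:.2f}x the bead floor)")
    print(f"peroxidase-like crossing: {hrp_nm:.0f} nm "
          f"({hrp_nm / poca_nm:.1f}-fold coarser than diffusion-free)")


if __name__ == "__main__":
    sys.exit(main())
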