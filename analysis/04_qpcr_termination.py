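#!/usr/bin/env python
"""qPCR termination-rate readout on synthetic Ct quadruples.

Builds ideal Ct values from simulated cDNA copy numbers with known
termination fractions (three technical replicates with small Ct jitter),
applies the 1 - 2^-(ΔCt1-ΔCt2) formula, and summarizes per-site means and
standard deviations, including a near-zero negative-control site.
Writes results/qpcr_rates.tsv.
"""

from pathlib import Path

import numpy as np

from rips import QpcrAssay, summarize_replicates
from rips.qpcr import ideal_ct

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

#: injected termination fractions per assayed site; the last mimics a
#: site that is not modified (negative control)
SITES = {"site-A": 0.72, "site-B": 0.55, "control-site": 0.01}


def main() -> None:
    rng = np.random.default_rng(SEED)
    assays = []
    for site, f in SITES.items():
        for rep in range(3):
            jitter = rng.normal(0.0, 0.05, size=4)
            assays.append(
                QpcrAssay(
                    site,
                    ct_fp1rp1_treated=ideal_ct(8000 * (1 - f)) + jitter[0],
                    ct_fp1rp1_input=ideal_ct(12000) + jitter[1],
                    ct_fp2rp2_treated=ideal_ct(8000) + jitter[2],
                    ct_fp2rp2_input=ideal_ct(12000) + jitter[3],
                    replicate=rep,
                )
            )
    summary = summarize_replicates(assays)
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "qpcr_rates.tsv", sep="\t", index=False)
    for _, row in summary.iterrows():
        truth = SITES[row["site_label"]]
        print(f"{row['site_label']:>12}: rate {row['rate_mean']:.3f} ± "
              f"{row['rate_sd']:.3f} (injected {truth:.2f}, n={row['n']})")
    print("The spanning amplicon counts only read-through cDNAs, the")
    print("downstream amplicon counts all cDNAs; their ΔΔCt recovers the")
    print("injected termination fraction up to replicate jitter.")
    print(f"-> {OUT / 'qpcr_rates.tsv'}")


if __name__ == "__main__":
    main()
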