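#!/usr/bin/env python
"""Sequencing validation of the digestion uplift on a 60-nt Ψ oligo.

Simulates the input, CMC-only and CMC+XRN1 arms (20,000 molecules each),
maps the reads, computes per-site termination-rate profiles, calls Ψ sites
(treated vs control with the input filter), and plots the three profiles.
Writes results/termination_profiles.tsv, results/psi_calls.tsv and
results/termination_profiles.svg.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from rips.experiments import sequencing_validation
from rips.io import calls_to_frame

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    res = sequencing_validation(seed=SEED, n_molecules=20000)
    psi = res["psi"]
    OUT.mkdir(exist_ok=True)

    frames = [p.to_frame() for p in res["profiles"].values()]
    pd.concat(frames).to_csv(OUT / "termination_profiles.tsv", sep="\t", index=False)
    calls_to_frame(res["calls"]).to_csv(OUT / "psi_calls.tsv", sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(7, 3))
    for arm, prof in res["profiles"].items():
        ax.plot(range(1, prof.length), prof.rate, label=arm, lw=1.2)
    ax.axvline(psi, color="red", ls="--", lw=0.8, label=f"Ψ (position {psi})")
    ax.set_xlabel("template position")
    ax.set_ylabel("termination rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "termination_profiles.svg")

    print(f"T(Ψ={psi}) per arm:")
    for arm, t in res["T"].items():
        print(f"  {arm:>9}: {t:.3f}")
    print(f"calls: {[(c.ref_id, c.site) for c in res['calls']]}")
    print("Digestion removes unlabeled read-through molecules, lifting the")
    print("termination rate at the Ψ from the CMC-only to the CMC+XRN1 arm,")
    print("and the caller reports the Ψ position exactly once.")
    print(f"-> {OUT / 'termination_profiles.tsv'}, {OUT / 'psi_calls.tsv'}")


if __name__ == "__main__":
    main()
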