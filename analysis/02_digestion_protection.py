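#!/usr/bin/env python
"""Endpoint protection efficiency of the Ψ-CMC adduct against XRN1.

Simulates digestion of pre-labeled molecules (the HPLC-purified labeled
strand scenario) and estimates the probability that the adduct halts the
enzyme, which should recover the configured 95% protection endpoint.
Writes results/digestion_protection.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rips import SimParams, simulate_xrn1, validation_oligos
from rips.simulate import PROTECTED

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    t19 = validation_oligos()["19-RNA-psi"]
    rng = np.random.default_rng(SEED)
    rows = []
    for p_protect in (0.5, 0.8, 0.95):
        params = SimParams(p_engage=1.0, p_protect=p_protect, min_fragment_len=1)
        n = 20000
        protected = sum(
            simulate_xrn1({4}, t19, params, rng).fate == PROTECTED for _ in range(n)
        )
        est = protected / n
        se = np.sqrt(est * (1 - est) / n)
        rows.append({"p_protect_true": p_protect, "estimate": round(est, 4),
                     "se": round(se, 4), "n": n})
        print(f"p_protect={p_protect:.2f}: estimated protection {est:.3f} ± {se:.3f}")
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "digestion_protection.tsv", sep="\t", index=False)
    print("Every labeled molecule either survives as the [Ψ, 3'-end] fragment")
    print("or is fully degraded; the survivor fraction estimates the adduct's")
    print("protection probability (0.95 at the validated endpoint).")
    print(f"-> {OUT / 'digestion_protection.tsv'}")


if __name__ == "__main__":
    main()
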