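#!/usr/bin/env python
"""Structure selectivity: Ψ in ssRNA is called, duplexed Ψ is not.

Runs the duplex-blocking screen (single-stranded vs fully base-paired
60-mer twins across replicate seeds) and the ssRNA/dsRNA mixture
experiment (32-nt ss Ψ oligo + duplexed 60-nt Ψ oligo), where digestion
should concentrate the library on the single-stranded species.
Writes results/structure_selectivity.tsv and results/mixture_enrichment.tsv.
"""

from pathlib import Path

from rips.experiments import mixture_enrichment, structure_selectivity_screen

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)

    screen = structure_selectivity_screen(seed=SEED, n_seeds=25, n_molecules=4000)
    screen.to_csv(OUT / "structure_selectivity.tsv", sep="\t", index=False)
    for structure, grp in screen.groupby("structure"):
        called = int(grp["called_at_psi"].sum())
        print(f"{structure}: Ψ called in {called}/{len(grp)} replicates "
              f"({int(grp['n_calls'].sum())} calls total)")

    mix = mixture_enrichment(seed=SEED, n_molecules=4000)
    mix.to_csv(OUT / "mixture_enrichment.tsv", sep="\t", index=False)
    print("\nmixture read shares (CMC-only -> CMC+XRN1):")
    for _, row in mix.iterrows():
        print(f"  {row['ref']:>12}: {row['pre_share']:.3f} -> {row['post_share']:.3f} "
              f"(fold {row['fold_change']:.2f})")
    print("A base-paired Ψ cannot be labeled, so its strand is digested and")
    print("never called; the single-stranded Ψ dominates the post-digestion")
    print("library, reproducing the selective enrichment of ssRNA Ψ sites.")
    print(f"-> {OUT / 'structure_selectivity.tsv'}, {OUT / 'mixture_enrichment.tsv'}")


if __name__ == "__main__":
    main()
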