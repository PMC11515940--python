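import dataclasses

import numpy as np
import pytest

from rips import (
    RnaTemplate,
    SimParams,
    simulate_labeling,
    simulate_library,
    simulate_molecule,
    simulate_rt,
    simulate_xrn1,
    standin_oligo,
)
from rips.simulate import DEGRADED, INTACT, PROTECTED, MoleculeFate, SimulationError


def binom_3se(p: float, n: int) -> float:
    return 3 * np.sqrt(p * (1 - p) / n)


class TestLabeling:
    def test_certain_labeling_hits_every_molecule(self, oligo19, rng):
        p = SimParams(p_label_ss=1.0, n_molecules=50)
        sets = simulate_labeling(oligo19, p, rng)
        assert all(s == {4} for s in sets)

    def test_zero_labeling_hits_nothing(self, oligo19, rng):
        p = SimParams(p_label_ss=0.0, n_molecules=50)
        assert all(not s for s in simulate_labeling(oligo19, p, rng))

    def test_labeled_fraction_matches_binomial(self, oligo60, rng):
        p = SimParams(p_label_ss=0.8, n_molecules=10000)
        sets = simulate_labeling(oligo60, p, rng)
        frac = np.mean([30 in s for s in sets])
        assert abs(frac - 0.8) < binom_3se(0.8, 10000)

    def test_paired_psi_labels_at_ds_rate(self, rng):
        t = standin_oligo("t", 20, 10, seed=4).with_mask([True] * 20)
        p = SimParams(p_label_ss=1.0, p_label_ds=0.0, n_molecules=200)
        assert all(not s for s in simulate_labeling(t, p, rng))

    def test_residual_ug_labeling_targets_unpaired_u_and_g(self, rng):
        t = RnaTemplate("t", "AUGC", frozenset())
        p = SimParams(p_residual_ug=1.0, n_molecules=10)
        sets = simulate_labeling(t, p, rng)
        assert all(s == {2, 3} for s in sets)


class TestXrn1:
    def test_protected_fragment_is_16mer(self, oligo19, deterministic_params, rng):
        fate = simulate_xrn1({4}, oligo19, deterministic_params, rng)
        assert fate.fate == PROTECTED
        assert fate.fragment == (4, 19)
        assert fate.fragment[1] - fate.fragment[0] + 1 == 16

    def test_unlabeled_engaged_molecule_is_degraded(self, oligo19, deterministic_params, rng):
        fate = simulate_xrn1(set(), oligo19, deterministic_params, rng)
        assert fate.fate == DEGRADED
        assert fate.fragment is None and fate.cdna_stop is None

    def test_five_prime_oh_is_refractory(self, deterministic_params, rng):
        t = standin_oligo("blk", 19, 4, seed=6, five_prime_phosphate=False)
        fate = simulate_xrn1({4}, t, deterministic_params, rng)
        assert fate.fate == INTACT
        assert fate.fragment == (1, 19)

    def test_short_fragments_are_lost_to_size_selection(self, oligo19, rng):
        p = SimParams(p_engage=1.0, p_protect=1.0, min_fragment_len=17)
        fate = simulate_xrn1({4}, oligo19, p, rng)  # fragment would be 16 nt
        assert fate.fate == DEGRADED

    def test_protection_rate_matches_p_protect(self, oligo19, rng):
        p = SimParams(p_engage=1.0, p_protect=0.95, min_fragment_len=1)
        n = 10000
        protected = sum(
            simulate_xrn1({4}, oligo19, p, rng).fate == PROTECTED for _ in range(n)
        )
        assert abs(protected / n - 0.95) < binom_3se(0.95, n)


class TestRt:
    def test_forced_stop_lands_one_nt_threeprime_of_psi(self, oligo19, deterministic_params, rng):
        fate = MoleculeFate("o19", frozenset({4}), PROTECTED, (4, 19))
        done = simulate_rt(fate, oligo19, deterministic_params, rng)
        assert done.cdna_stop == 5

    def test_no_stops_gives_full_length_cdna(self, oligo19, rng):
        p = SimParams(p_rt_stop=0.0, p_bg_stop=0.0)
        fate = MoleculeFate("o19", frozenset(), INTACT, (1, 19))
        assert simulate_rt(fate, oligo19, p, rng).cdna_stop == 1

    def test_degraded_molecule_rejected(self, oligo19, deterministic_params, rng):
        with pytest.raises(SimulationError):
            simulate_rt(MoleculeFate("o19", frozenset(), DEGRADED), oligo19,
                        deterministic_params, rng)

    def test_stop_fraction_matches_p_rt_stop(self, oligo19, rng):
        p = SimParams(p_rt_stop=0.85, p_bg_stop=0.0)
        fate = MoleculeFate("o19", frozenset({4}), PROTECTED, (4, 19))
        n = 10000
        stops = sum(simulate_rt(fate, oligo19, p, rng).cdna_stop == 5 for _ in range(n))
        assert abs(stops / n - 0.85) < binom_3se(0.85, n)

    def test_halt_at_threeprime_most_base_is_discarded(self, rng):
        # Ψ at the fragment's 3' end: a stop there would leave no read
        t = RnaTemplate("t", "ACGU", frozenset({4}))
        p = SimParams(p_rt_stop=1.0, p_bg_stop=1.0)
        fate = MoleculeFate("t", frozenset({4}), INTACT, (1, 4))
        done = simulate_rt(fate, t, p, rng)
        assert done.cdna_stop == 4  # halted immediately after the 3' base


class TestLibrary:
    def test_input_arm_with_clean_chemistry_emits_full_templates(self, oligo60):
        p = SimParams(p_bg_stop=0.0, seq_error=0.0, n_molecules=20, seed=3)
        reads, truth = simulate_library([oligo60], p, "input")
        dna = oligo60.sequence.replace("U", "T")
        assert len(reads) == 20
        assert all(r.sequence == dna for r in reads)
        assert (truth["fate"] == INTACT).all()

    def test_digesting_psi_free_template_leaves_no_reads(self):
        t = RnaTemplate("nopsi", "ACG" * 20)
        p = SimParams(p_engage=1.0, n_molecules=50, seed=3)
        reads, truth = simulate_library([t], p, "cmc_xrn1")
        assert reads == []
        assert (truth["fate"] == DEGRADED).all()

    def test_each_molecule_has_one_fate_and_reads_match_survivors(self, oligo60):
        p = SimParams(n_molecules=2000, seed=5)
        reads, truth = simulate_library([oligo60], p, "cmc_xrn1")
        assert set(truth["fate"]).issubset({INTACT, PROTECTED, DEGRADED})
        assert len(truth) == 2000
        assert len(reads) == int((truth["fate"] != DEGRADED).sum())
        surv = truth[truth["fate"] != DEGRADED]
        # read sequence spans [cdna_stop, L]; frag end never trimmed
        assert (surv["frag_end"] == 60).all()
        assert (surv["cdna_stop"] >= surv["frag_start"]).all()
        by_id = {r.name: r for r in reads}
        for _, row in surv.head(50).iterrows():
            assert len(by_id[row["read_id"]].sequence) == 60 - row["cdna_stop"] + 1

    def test_same_seed_gives_byte_identical_fastq(self, oligo60, tmp_path):
        from rips.io import write_fastq

        p = SimParams(n_molecules=500, seed=42)
        paths = []
        for name in ("a.fastq", "b.fastq"):
            reads, _ = simulate_library([oligo60], p, "cmc_xrn1")
            write_fastq(reads, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_unknown_arm_and_empty_templates_rejected(self, oligo60):
        with pytest.raises(SimulationError):
            simulate_library([oligo60], SimParams(), "rnase")
        with pytest.raises(SimulationError):
            simulate_library([], SimParams(), "input")

    def test_protected_fraction_monotone_in_labeling_and_protection(self, oligo60):
        # matched seeds across the grid; expectation is nondecreasing
        def protected_frac(p_label, p_protect):
            p = SimParams(p_label_ss=p_label, p_protect=p_protect,
                          n_molecules=4000, seed=77)
            _, truth = simulate_library([oligo60], p, "cmc_xrn1")
            return (truth["fate"] == PROTECTED).mean()

        grid = [0.2, 0.5, 0.8]
        fracs_label = [protected_frac(x, 0.9) for x in grid]
        fracs_prot = [protected_frac(0.5, x) for x in grid]
        assert fracs_label == sorted(fracs_label)
        assert fracs_prot == sorted(fracs_prot)

    def test_fully_paired_psi_stops_at_background_rate(self):
        # structure selectivity: a duplexed Ψ leaves only background RT stops
        t = standin_oligo("ds", 60, 30, seed=8).with_mask([True] * 60)
        p = SimParams(p_label_ds=0.0, p_bg_stop=0.01, n_molecules=20000, seed=9)
        _, truth = simulate_library([t], p, "cmc_only")
        stops = (truth["cdna_stop"] == 31).sum()
        reached = (truth["cdna_stop"] <= 31).sum()  # molecules whose RT reached the site
        assert abs(stops / reached - 0.01) < binom_3se(0.01, int(reached))

    def test_mixture_reads_come_from_the_single_stranded_template(self, oligo32):
        # ssRNA 32-mer vs fully duplexed 60-mer under labeling + digestion
        ds60 = standin_oligo("ds60", 60, 30, seed=10).with_mask([True] * 60)
        p = SimParams(n_molecules=4000, seed=11)
        reads, _ = simulate_library([oligo32, ds60], p, "cmc_xrn1")
        from_ss = sum(r.name.startswith("o32") for r in reads)
        assert from_ss / len(reads) > 0.9

    def test_sequencing_errors_perturb_the_stated_fraction_of_bases(self, oligo60):
        p = SimParams(p_bg_stop=0.0, seq_error=0.05, n_molecules=400, seed=13)
        reads, _ = simulate_library([oligo60], p, "input")
        dna = oligo60.sequence.replace("U", "T")
        mism = sum(a != b for r in reads for a, b in zip(r.sequence, dna))
        total = sum(len(r.sequence) for r in reads)
        assert abs(mism / total - 0.05) < binom_3se(0.05, total)

    def test_params_validation(self):
        with pytest.raises(SimulationError):
            SimParams(p_label_ss=1.5)
        with pytest.raises(SimulationError):
            SimParams(n_molecules=0)


class TestMoleculePath:
    def test_single_molecule_arm_composition(self, oligo60):
        rng = np.random.default_rng(21)
        p = SimParams(p_label_ss=1.0, p_engage=1.0, p_protect=1.0,
                      p_rt_stop=1.0, p_bg_stop=0.0, min_fragment_len=1)
        m = simulate_molecule(oligo60, p, "cmc_xrn1", rng)
        assert m.fate == PROTECTED and m.fragment == (30, 60) and m.cdna_stop == 31
        m = simulate_molecule(oligo60, p, "input", rng)
        assert m.fate == INTACT and m.cdna_stop == 1
        m = simulate_molecule(oligo60, p, "xrn1_only", rng)
        assert m.fate == DEGRADED
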