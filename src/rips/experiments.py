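"""Study-level experiment drivers composing the pipeline end to end.

Each function reproduces one in-silico experiment of the assay-validation
study under its stated conditions: the protection-product geometry, the
sequencing validation of the digestion uplift, parameter recovery on a
labeling x RT-stop grid, and the single- vs double-stranded selectivity
screen.  The analysis scripts and the acceptance checks are thin wrappers
over these functions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .caller import PsiCall, TerminationProfile, call_sites, profile
from .simulate import Arm, SimParams, simulate_library, simulate_xrn1
from .stopmap import ReferenceSet, map_reads, pileup
from .templates import RnaTemplate, standin_oligo, validation_oligos


def arm_termination_profile(
    template: RnaTemplate,
    params: SimParams,
    arm: Arm,
    rng: np.random.Generator,
    min_cov: int = 50,
) -> TerminationProfile:
    """Simulate one arm and push it through map -> pileup -> profile."""
    reads, _ = simulate_library([template], params, arm, rng)
    pu = pileup(map_reads(reads, ReferenceSet([template])), template)
    return profile(pu, min_cov=min_cov, arm=arm)


def protection_fragment_length(template: RnaTemplate | None = None) -> int:
    """Length of the digestion product under deterministic chemistry.

    A 19-mer with its Ψ at position 4, fully labeled and digested with
    certain engagement and protection, leaves the [Ψ, 3'-end] fragment.
    """
    if template is None:
        template = validation_oligos()["19-RNA-psi"]
    params = SimParams(p_label_ss=1.0, p_engage=1.0, p_protect=1.0,
                       min_fragment_len=1)
    fate = simulate_xrn1(template.psi_positions, template, params,
                         np.random.default_rng(0))
    start, end = fate.fragment
    return end - start + 1


def sequencing_validation(
    seed: int,
    n_molecules: int = 20000,
    template: RnaTemplate | None = None,
) -> dict:
    """The digestion-uplift experiment on a 60-nt Ψ oligo.

    Simulates the input, CMC-only and CMC+XRN1 arms under the default
    chemistry, computes each arm's termination rate at the Ψ, and calls
    sites (treated = CMC+XRN1, control = CMC-only, input filter on).
    Returns the per-arm rates, the calls and the Ψ position.
    """
    if template is None:
        template = validation_oligos()["60-RNA-psi"]
    (psi,) = template.psi_positions
    params = replace(SimParams(), n_molecules=n_molecules, seed=seed)
    streams = np.random.SeedSequence(seed).spawn(3)
    profs = {
        arm: arm_termination_profile(template, params, arm, np.random.default_rng(s))
        for arm, s in zip(("input", "cmc_only", "cmc_xrn1"), streams)
    }
    calls = call_sites(profs["cmc_xrn1"], profs["cmc_only"], profs["input"])
    return {
        "psi": psi,
        "profiles": profs,
        "T": {arm: p.rate_at(psi) for arm, p in profs.items()},
        "calls": calls,
    }


def parameter_recovery_grid(
    seed: int,
    grid: tuple[float, ...] = (0.5, 0.8, 1.0),
    n_molecules: int = 20000,
) -> pd.DataFrame:
    """Recover p_label_ss * p_rt_stop from the CMC-only arm's T(Ψ).

    Background stops and sequencing errors are disabled so the composition
    T(Ψ) = p_label_ss * p_rt_stop holds exactly in expectation; the estimate
    must land within three binomial standard errors.
    """
    template = validation_oligos()["60-RNA-psi"]
    (psi,) = template.psi_positions
    rows = []
    streams = iter(np.random.SeedSequence(seed).spawn(len(grid) ** 2))
    for p_label in grid:
        for p_rt in grid:
            params = SimParams(p_label_ss=p_label, p_rt_stop=p_rt,
                               p_bg_stop=0.0, seq_error=0.0,
                               n_molecules=n_molecules, seed=seed)
            prof = arm_termination_profile(
                template, params, "cmc_only", np.random.default_rng(next(streams))
            )
            expected = p_label * p_rt
            n = prof.denominator(psi)
            se = np.sqrt(expected * (1 - expected) / n)
            est = prof.rate_at(psi)
            rows.append(
                {"p_label_ss": p_label, "p_rt_stop": p_rt, "expected": expected,
                 "estimate": est, "n": n, "se": se,
                 "within_3se": bool(abs(est - expected) <= 3 * se)}
            )
    return pd.DataFrame(rows)


def structure_selectivity_screen(
    seed: int,
    n_seeds: int = 100,
    n_molecules: int = 4000,
) -> pd.DataFrame:
    """Duplex blocking screen: ss twin vs fully base-paired twin, many seeds.

    For each replicate seed, both templates run through the CMC+XRN1 and
    CMC-only arms and the caller; the single-stranded template should be
    called at its Ψ while the duplexed one (whose Ψ cannot be labeled)
    should never be.  Returns one row per (replicate, structure).
    """
    ss = standin_oligo("ss60", 60, 30, seed=17)
    ds = ss.with_mask([True] * len(ss))
    rows = []
    reps = np.random.SeedSequence(seed).spawn(n_seeds)
    for i, rep in enumerate(reps):
        sub = rep.spawn(4)
        for tpl, structure, (s_t, s_c) in (
            (ss, "single-stranded", (sub[0], sub[1])),
            (ds, "double-stranded", (sub[2], sub[3])),
        ):
            params = replace(SimParams(), n_molecules=n_molecules)
            treated = arm_termination_profile(tpl, params, "cmc_xrn1",
                                              np.random.default_rng(s_t))
            control = arm_termination_profile(tpl, params, "cmc_only",
                                              np.random.default_rng(s_c))
            calls = call_sites(treated, control)
            rows.append(
                {"replicate": i, "structure": structure,
                 "called_at_psi": any(c.site == 30 for c in calls),
                 "n_calls": len(calls)}
            )
    return pd.DataFrame(rows)


def mixture_enrichment(seed: int, n_molecules: int = 4000) -> pd.DataFrame:
    """ssRNA/dsRNA mixture: digestion concentrates reads on the ss template.

    A single-stranded 32-nt Ψ oligo is mixed with a fully duplexed 60-nt Ψ
    oligo; only the ss Ψ can be labeled, so digestion removes the duplexed
    species.  Returns the per-reference read shares before (CMC-only) and
    after (CMC+XRN1) digestion.
    """
    from .caller import enrichment_ratio

    oligos = validation_oligos()
    ss32 = oligos["32-RNA-psi"]
    ds60 = oligos["60-RNA-psi"].with_mask([True] * 60)
    templates = [ss32, ds60]
    refs = ReferenceSet(templates)
    params = replace(SimParams(), n_molecules=n_molecules, seed=seed)
    streams = np.random.SeedSequence(seed).spawn(2)
    piles = {}
    for arm, s in zip(("cmc_only", "cmc_xrn1"), streams):
        reads, _ = simulate_library(templates, params, arm, np.random.default_rng(s))
        alns = map_reads(reads, refs)
        piles[arm] = [pileup(alns, t) for t in templates]
    return enrichment_ratio(piles["cmc_only"], piles["cmc_xrn1"])
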