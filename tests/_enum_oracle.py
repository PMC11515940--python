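"""Exhaustive enumeration oracle for the labeling/digestion/RT cascade.

For tiny templates the full distribution over (fate, fragment start, RT
stop) can be computed exactly by summing over every Bernoulli outcome:
each labeled-position subset, the engage/protect branches of digestion,
and the closed-form RT stop distribution.  This is independent of the
simulator's sampling code and serves as its goodness-of-fit reference.
"""

from itertools import chain, combinations

import numpy as np

from rips.simulate import DEGRADED, SimParams, label_probabilities
from rips.templates import RnaTemplate

#: outcome key for a fully degraded molecule
DEGRADED_KEY = ("degraded",)


def _subsets(items):
    items = list(items)
    return chain.from_iterable(combinations(items, k) for k in range(len(items) + 1))


def rt_stop_distribution(start: int, end: int, labeled: frozenset[int], params: SimParams):
    """Exact P(cdna_stop) for a fragment [start, end]: scan 3'->5'.

    A halt before copying position j yields cdna_stop j+1; a halt at the
    3'-most position is discarded; surviving the whole scan yields a
    full-length cDNA (cdna_stop = start).
    """
    out: dict[int, float] = {}
    surviving = 1.0
    for j in range(end - 1, start - 1, -1):
        r = params.p_rt_stop if j in labeled else 0.0
        q = 1.0 - (1.0 - r) * (1.0 - params.p_bg_stop)
        out[j + 1] = out.get(j + 1, 0.0) + surviving * q
        surviving *= 1.0 - q
    out[start] = out.get(start, 0.0) + surviving
    return out


def digestion_distribution(labeled: frozenset[int], template: RnaTemplate, params: SimParams):
    """Exact P(fragment start | labeled set); DEGRADED_KEY for total loss."""
    L = len(template)
    out: dict = {}

    def _add(start, prob):
        if L - start + 1 < params.min_fragment_len:
            out[DEGRADED_KEY] = out.get(DEGRADED_KEY, 0.0) + prob
        else:
            out[start] = out.get(start, 0.0) + prob

    if not template.five_prime_phosphate:
        _add(1, 1.0)
        return out
    _add(1, 1.0 - params.p_engage)
    remaining = params.p_engage
    for pos in sorted(labeled):
        _add(pos, remaining * params.p_protect)
        remaining *= 1.0 - params.p_protect
    out[DEGRADED_KEY] = out.get(DEGRADED_KEY, 0.0) + remaining
    return out


def outcome_distribution(template: RnaTemplate, params: SimParams, arm: str):
    """Exact joint distribution over (frag_start, cdna_stop) and degradation."""
    L = len(template)
    probs = label_probabilities(template, params)
    candidates = [int(i) + 1 for i in np.flatnonzero(probs)]
    if arm in ("input", "xrn1_only"):
        candidates = []
    out: dict = {}
    for subset in _subsets(candidates):
        labeled = frozenset(subset)
        p_lab = 1.0
        for pos in candidates:
            p = probs[pos - 1]
            p_lab *= p if pos in labeled else 1.0 - p
        if p_lab == 0.0:
            continue
        if arm in ("cmc_xrn1", "xrn1_only"):
            frag_dist = digestion_distribution(labeled, template, params)
        else:
            frag_dist = {1: 1.0}
        for start, p_frag in frag_dist.items():
            if start == DEGRADED_KEY:
                out[DEGRADED_KEY] = out.get(DEGRADED_KEY, 0.0) + p_lab * p_frag
                continue
            for stop, p_stop in rt_stop_distribution(start, L, labeled, params).items():
                key = (start, stop)
                out[key] = out.get(key, 0.0) + p_lab * p_frag * p_stop
    return out


def truth_to_outcome_counts(truth) -> dict:
    """Tally simulator truth-table rows into the oracle's outcome keys."""
    counts: dict = {}
    for fate, start, stop in zip(truth["fate"], truth["frag_start"], truth["cdna_stop"]):
        key = DEGRADED_KEY if fate == DEGRADED else (int(start), int(stop))
        counts[key] = counts.get(key, 0) + 1
    return counts


def chisquare_vs_oracle(counts: dict, expected_probs: dict, min_expected: float = 5.0):
    """Chi-square GOF of observed outcome counts against exact probabilities.

    Outcome categories with expected count below ``min_expected`` are lumped
    into one bin so the chi-square approximation holds.
    """
    from scipy import stats

    n = sum(counts.values())
    keys = sorted(expected_probs, key=lambda k: (len(k), k))
    obs, exp = [], []
    lump_obs = lump_exp = 0.0
    for k in keys:
        e = expected_probs[k] * n
        o = counts.get(k, 0)
        if e < min_expected:
            lump_obs += o
            lump_exp += e
        else:
            obs.append(o)
            exp.append(e)
    stray = sum(v for k, v in counts.items() if k not in expected_probs)
    if stray:
        raise AssertionError(f"simulator produced outcomes with zero probability: {stray}")
    if lump_exp > 0:
        obs.append(lump_obs)
        exp.append(lump_exp)
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    exp *= obs.sum() / exp.sum()  # guard rounding drift
    return stats.chisquare(obs, exp)
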