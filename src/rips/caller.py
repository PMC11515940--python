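"""Per-site RT termination rates and treated-vs-control Ψ calling.

The per-site statistic is the termination rate

    T(site) = stop5[site+1] / (stop5[site+1] + readthrough(site))

where ``readthrough(site)`` counts reads whose 5'-most aligned position is
at or 5' of the site.  The numerator sits one nucleotide 3' of the site
because RT terminates one nucleotide 3' of a Ψ-CMC adduct; reported site
coordinates are therefore already back-shifted to the Ψ itself.  The
denominator ignores reads that never reached the site (3'-truncated
molecules), making T invariant to upstream truncation.

A site is called when the treated (CMC, or CMC+XRN1) rate clears an
absolute threshold, the margin over the control arm clears a second
threshold, both denominators are adequately covered and, when an untreated
input profile is given, the input shows no intrinsic stop there.

After digestion the protected fragments *begin* at the Ψ, so their
full-length cDNAs pile 5' ends on the Ψ itself while their terminated
cDNAs pile one base 3' of it.  Both piles clear the thresholds, yielding a
doublet of passing sites (Ψ-1, Ψ) that is the signature of a single Ψ;
:func:`call_sites` collapses each run of adjacent passing sites to its
3'-most member by default.  The cost is that directly adjacent Ψs would be
merged into one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stopmap import StopPileup


class CallerError(ValueError):
    pass


@dataclass
class TerminationProfile:
    """Per-position termination rates on one reference, for one arm.

    Arrays are indexed by site (1-based positions 1..length-1; the last
    position has no 3' neighbor and therefore no rate).  ``rate`` is NaN
    where the denominator is below ``min_cov``.
    """

    ref_id: str
    length: int
    arm: str
    stops: np.ndarray        # stops[site-1] = stop5[site+1]
    readthrough: np.ndarray  # reads with 5' end <= site
    rate: np.ndarray
    min_cov: int

    def denominator(self, site: int) -> int:
        return int(self.stops[site - 1] + self.readthrough[site - 1])

    def rate_at(self, site: int) -> float:
        return float(self.rate[site - 1])

    def to_frame(self) -> pd.DataFrame:
        sites = np.arange(1, self.length)
        return pd.DataFrame(
            {
                "ref": self.ref_id,
                "site": sites,
                "stops": self.stops,
                "readthrough": self.readthrough,
                "rate": self.rate,
                "arm": self.arm,
            }
        )


@dataclass(frozen=True)
class PsiCall:
    """One called Ψ site with its treated/control evidence."""

    ref_id: str
    site: int
    T_treated: float
    T_control: float
    delta: float
    snr: float
    pvalue: float
    passed: bool = True
    T_input: float = float("nan")
    merged_sites: tuple[int, ...] = ()


def termination_rate(pileup: StopPileup, site: int, min_cov: int = 50) -> float | None:
    """T at one site; ``None`` when fewer than ``min_cov`` informative reads."""
    if not 1 <= site < pileup.length:
        raise CallerError(
            f"site {site} has no 3' neighbor on reference of length {pileup.length}"
        )
    stops = int(pileup.stop5[site])           # stop5 at site+1 (0-based site)
    readthrough = int(pileup.stop5[:site].sum())
    denom = stops + readthrough
    if denom < min_cov:
        return None
    return stops / denom


def profile(pileup: StopPileup, min_cov: int = 50, arm: str = "") -> TerminationProfile:
    """Apply the termination-rate statistic at every eligible site."""
    L = pileup.length
    stops = pileup.stop5[1:L].astype(np.int64)
    readthrough = np.cumsum(pileup.stop5)[: L - 1].astype(np.int64)
    denom = stops + readthrough
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(denom >= min_cov, stops / np.maximum(denom, 1), np.nan)
    return TerminationProfile(pileup.ref_id, L, arm, stops, readthrough, rate, min_cov)


def call_sites(
    treated: TerminationProfile,
    control: TerminationProfile,
    input_profile: TerminationProfile | None = None,
    tau_t: float = 0.3,
    tau_delta: float = 0.1,
    min_cov: int = 50,
    collapse_adjacent: bool = True,
) -> list[PsiCall]:
    """Call Ψ sites where the treated arm clears both thresholds.

    A site passes iff T_treated >= tau_t, T_treated - T_control >= tau_delta,
    both denominators >= min_cov and, when ``input_profile`` is given and
    covered there, T_input < tau_t.  Runs of adjacent passing sites collapse
    to the 3'-most site (the Ψ; see module docstring) unless disabled.
    Output is sorted by site.
    """
    if treated.ref_id != control.ref_id or treated.length != control.length:
        raise CallerError("treated and control profiles are on different references")
    if input_profile is not None and input_profile.ref_id != treated.ref_id:
        raise CallerError("input profile is on a different reference")

    passing: list[int] = []
    for site in range(1, treated.length):
        n_t = treated.denominator(site)
        n_c = control.denominator(site)
        if n_t < min_cov or n_c < min_cov:
            continue
        T_t, T_c = treated.rate_at(site), control.rate_at(site)
        if np.isnan(T_t) or np.isnan(T_c):
            continue
        if T_t < tau_t or (T_t - T_c) < tau_delta:
            continue
        if input_profile is not None:
            T_i = input_profile.rate_at(site)
            if np.isfinite(T_i) and T_i >= tau_t:
                continue
        passing.append(site)

    groups: list[list[int]]
    if collapse_adjacent:
        groups = []
        for s in passing:
            if groups and s == groups[-1][-1] + 1:
                groups[-1].append(s)
            else:
                groups.append([s])
    else:
        groups = [[s] for s in passing]

    calls = []
    for grp in groups:
        site = grp[-1]  # 3'-most member of the run is the Ψ
        T_t, T_c = treated.rate_at(site), control.rate_at(site)
        n_t, n_c = treated.denominator(site), control.denominator(site)
        eps_t, eps_c = 1.0 / (n_t + 1), 1.0 / (n_c + 1)
        snr = (T_t + eps_t) / (T_c + eps_c)
        null_p = max(T_c, eps_c)
        pvalue = float(stats.binom.sf(int(treated.stops[site - 1]) - 1, n_t, null_p))
        T_i = float("nan")
        if input_profile is not None:
            T_i = input_profile.rate_at(site)
        calls.append(
            PsiCall(
                ref_id=treated.ref_id,
                site=site,
                T_treated=T_t,
                T_control=T_c,
                delta=T_t - T_c,
                snr=snr,
                pvalue=pvalue,
                passed=True,
                T_input=T_i,
                merged_sites=tuple(grp),
            )
        )
    return calls


def enrichment_ratio(
    pre_pileups: list[StopPileup], post_pileups: list[StopPileup]
) -> pd.DataFrame:
    """Per-reference share of mapped reads before vs after digestion.

    Quantifies the enrichment of Ψ-carrying (CMC-protected) references:
    digestion removes unlabeled strands, so the protected reference's share
    of the library grows.  ``fold_change`` is post_share / pre_share (NaN
    when the reference had no reads before digestion).
    """
    pre = {p.ref_id: p.n_mapped for p in pre_pileups}
    post = {p.ref_id: p.n_mapped for p in post_pileups}
    refs = sorted(set(pre) | set(post))
    pre_tot = sum(pre.values()) or 1
    post_tot = sum(post.values()) or 1
    rows = []
    for r in refs:
        a = pre.get(r, 0) / pre_tot
        b = post.get(r, 0) / post_tot
        rows.append(
            {
                "ref": r,
                "pre_reads": pre.get(r, 0),
                "post_reads": post.get(r, 0),
                "pre_share": a,
                "post_share": b,
                "fold_change": b / a if a > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
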