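"""qPCR readout of the per-site RT termination rate.

Two amplicons interrogate one site: the FP1/RP1 pair spans the site, so
only cDNAs that read *through* it amplify; the FP2/RP2 pair sits entirely
3' of the site (toward the cDNA 5' primer-extension start), so every cDNA
amplifies regardless of termination.  With input (untreated) libraries as
the normalizer and assuming perfect doubling per cycle,

    ΔCt1 = Ct(FP1/RP1, treated) - Ct(FP1/RP1, input)
    ΔCt2 = Ct(FP2/RP2, treated) - Ct(FP2/RP2, input)
    termination rate = 1 - 2^-(ΔCt1 - ΔCt2)

A negative raw rate (the treated sample amplifying relatively better across
the site than the input) is biologically a near-zero termination; it is
clamped to 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrAssay:
    """Ct quadruple (two amplicons x treated/input) for one site, one replicate."""

    site_label: str
    ct_fp1rp1_treated: float
    ct_fp1rp1_input: float
    ct_fp2rp2_treated: float
    ct_fp2rp2_input: float
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_fp1rp1_treated", "ct_fp1rp1_input",
                     "ct_fp2rp2_treated", "ct_fp2rp2_input"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise QpcrError(f"{name}={v!r} is not a finite positive Ct")


@dataclass(frozen=True)
class QpcrRate:
    rate: float        # clamped to [0, 1]
    raw: float         # 1 - 2^-(dCt1 - dCt2), may be negative
    clamped: bool
    delta_ct1: float
    delta_ct2: float


def termination_rate_qpcr(assay: QpcrAssay) -> QpcrRate:
    """Termination rate 1 - 2^-(ΔCt1 - ΔCt2), clamped into [0, 1]."""
    d1 = assay.ct_fp1rp1_treated - assay.ct_fp1rp1_input
    d2 = assay.ct_fp2rp2_treated - assay.ct_fp2rp2_input
    raw = 1.0 - 2.0 ** (-(d1 - d2))
    clamped = raw < 0.0
    return QpcrRate(min(max(raw, 0.0), 1.0), raw, clamped, d1, d2)


def summarize_replicates(assays: list[QpcrAssay]) -> pd.DataFrame:
    """Mean and sample s.d. of per-replicate rates, one row per site."""
    if not assays:
        raise QpcrError("no assays supplied")
    rows = [
        {"site_label": a.site_label, "replicate": a.replicate,
         "rate": termination_rate_qpcr(a).rate}
        for a in assays
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby("site_label")["rate"]
        .agg(n="size", rate_mean="mean", rate_sd="std")
        .reset_index()
    )
    return out


def ideal_ct(copies: float, const: float = 40.0) -> float:
    """Ct of an ideal (doubling-per-cycle) reaction: const - log2(copies)."""
    if copies <= 0:
        raise QpcrError("copy number must be positive")
    return const - math.log2(copies)


def assays_from_table(df: pd.DataFrame) -> list[QpcrAssay]:
    """Build assays from a long-format Ct table.

    Expected columns: site_label, primer_pair (FP1RP1|FP2RP2), arm
    (treated|input), replicate, ct.  Every (site, replicate) must have all
    four Ct values.
    """
    required = {"site_label", "primer_pair", "arm", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    key = ["site_label", "replicate"]
    assays = []
    for (site, rep), grp in df.groupby(key, sort=True):
        cts = {}
        for _, row in grp.iterrows():
            pp = str(row["primer_pair"]).upper().replace("/", "").replace("_", "")
            arm = str(row["arm"]).lower()
            if pp not in ("FP1RP1", "FP2RP2") or arm not in ("treated", "input"):
                raise QpcrError(
                    f"unrecognized primer_pair/arm {row['primer_pair']!r}/{row['arm']!r}"
                )
            cts[(pp, arm)] = float(row["ct"])
        expected = {(p, a) for p in ("FP1RP1", "FP2RP2") for a in ("treated", "input")}
        if set(cts) != expected:
            raise QpcrError(f"site {site!r} replicate {rep!r}: incomplete Ct quadruple")
        assays.append(
            QpcrAssay(
                site_label=str(site),
                ct_fp1rp1_treated=cts[("FP1RP1", "treated")],
                ct_fp1rp1_input=cts[("FP1RP1", "input")],
                ct_fp2rp2_treated=cts[("FP2RP2", "treated")],
                ct_fp2rp2_input=cts[("FP2RP2", "input")],
                replicate=int(rep),
            )
        )
    return assays
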