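"""Readers and writers for the pipeline's plain-text formats.

FASTA/FASTQ go through Biopython; tabular outputs are TSV with a single
'#'-prefixed metadata line carrying run parameters as JSON, so every file
is greppable and self-describing.  Template annotation (Ψ positions,
paired regions or blocker strands, 5'-end chemistry) lives in a YAML
sidecar next to the FASTA.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import ReadRecord, SimParams
from .stopmap import StopPileup
from .caller import PsiCall, TerminationProfile
from .templates import RnaTemplate, TemplateError, build_duplex_mask


class IoError(ValueError):
    pass


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> list[tuple[str, str]]:
    try:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except ValueError as e:
        raise IoError(f"malformed FASTA {path}: {e}") from e


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    """Write 4-line FASTQ records; byte-stable for determinism checks."""
    with open(path, "w") as fh:
        for r in reads:
            head = f"@{r.name} {r.comment}" if r.comment else f"@{r.name}"
            fh.write(f"{head}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[ReadRecord]:
    out = []
    try:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                comment = rec.description.split(" ", 1)[1] if " " in rec.description else ""
                out.append(ReadRecord(rec.id, str(rec.seq), qual, comment))
    except ValueError as e:
        raise IoError(f"malformed FASTQ {path}: {e}") from e
    return out


# ------------------------------------------------------------- template meta

def read_template_meta(meta_path, fasta_path=None) -> list[RnaTemplate]:
    """Load templates from a YAML sidecar (sequences inline or from FASTA).

    Each entry: ``id``, ``sequence`` (optional when the id is in the FASTA),
    ``psi_positions`` (1-based), ``five_prime_phosphate`` (default true) and
    either explicit ``paired_regions: [[start, end], ...]`` or
    ``blockers: [{sequence: ..., min_match: 8}, ...]`` whose best antiparallel
    anneal defines the paired mask.
    """
    with open(meta_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "templates" not in doc:
        raise IoError(f"{meta_path}: expected a mapping with a 'templates' list")
    seqs = dict(read_fasta(fasta_path)) if fasta_path else {}
    templates = []
    for i, entry in enumerate(doc["templates"]):
        label = entry.get("id", f"entry {i}")
        try:
            rid = entry["id"]
            seq = entry.get("sequence") or seqs.get(rid)
            if seq is None:
                raise IoError(f"{label}: no sequence inline or in FASTA")
            psis = frozenset(int(p) for p in entry.get("psi_positions", []))
            tpl = RnaTemplate(
                rid, seq, psis,
                five_prime_phosphate=bool(entry.get("five_prime_phosphate", True)),
            )
            mask = np.zeros(len(tpl), dtype=bool)
            for start, end in entry.get("paired_regions", []):
                if not 1 <= start <= end <= len(tpl):
                    raise IoError(f"{label}: paired region [{start},{end}] out of bounds")
                mask[start - 1 : end] = True
            for blk in entry.get("blockers", []):
                mask |= build_duplex_mask(
                    tpl, blk["sequence"], min_match=int(blk.get("min_match", 8)),
                    allow_gu=bool(blk.get("allow_gu", False)),
                )
            templates.append(tpl.with_mask(mask))
        except (KeyError, TemplateError, ValueError, TypeError) as e:
            raise IoError(f"{meta_path}: template {label}: {e}") from e
    if not templates:
        raise IoError(f"{meta_path}: no templates declared")
    return templates


# ------------------------------------------------------------------ TSV + meta

def _write_tsv(df: pd.DataFrame, path, meta: dict | None) -> None:
    with open(path, "w") as fh:
        if meta is not None:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> tuple[pd.DataFrame, dict | None]:
    with open(path) as fh:
        first = fh.readline()
        meta = None
        if first.startswith("#"):
            meta = json.loads(first.lstrip("# ").strip())
            body = fh.read()
        else:
            body = first + fh.read()
    return pd.read_csv(_io.StringIO(body), sep="\t"), meta


def write_truth(truth: pd.DataFrame, path, params: SimParams, arm: str) -> None:
    _write_tsv(truth, path, {"arm": arm, "params": params.to_dict(), "seed": params.seed})


def read_truth(path) -> tuple[pd.DataFrame, dict | None]:
    df, meta = _read_tsv(path)
    df["read_id"] = df["read_id"].fillna("")
    return df, meta


def write_pileup_tsv(pileup: StopPileup, ref_seq: str, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "ref": pileup.ref_id,
            "pos": np.arange(1, pileup.length + 1),
            "base": list(ref_seq),
            "stop5": pileup.stop5,
            "cov": pileup.cov,
        }
    )
    full_meta = {
        "n_mapped": pileup.n_mapped,
        "n_unmapped": pileup.n_unmapped,
        "n_ambiguous": pileup.n_ambiguous,
        **(meta or {}),
    }
    _write_tsv(df, path, full_meta)


def read_pileup_tsv(path) -> StopPileup:
    df, meta = _read_tsv(path)
    meta = meta or {}
    ref = str(df["ref"].iloc[0])
    return StopPileup(
        ref_id=ref,
        length=len(df),
        stop5=df["stop5"].to_numpy(np.int64),
        cov=df["cov"].to_numpy(np.int64),
        n_mapped=int(meta.get("n_mapped", int(df["stop5"].sum()))),
        n_unmapped=int(meta.get("n_unmapped", 0)),
        n_ambiguous=int(meta.get("n_ambiguous", 0)),
    )


def write_profile_tsv(prof: TerminationProfile, path, meta: dict | None = None) -> None:
    _write_tsv(prof.to_frame(), path, {"min_cov": prof.min_cov, **(meta or {})})


def read_profile_tsv(path) -> TerminationProfile:
    df, meta = _read_tsv(path)
    meta = meta or {}
    length = int(df["site"].max()) + 1
    arm = str(df["arm"].iloc[0]) if "arm" in df and len(df) else ""
    return TerminationProfile(
        ref_id=str(df["ref"].iloc[0]),
        length=length,
        arm=arm,
        stops=df["stops"].to_numpy(np.int64),
        readthrough=df["readthrough"].to_numpy(np.int64),
        rate=df["rate"].to_numpy(float),
        min_cov=int(meta.get("min_cov", 0)),
    )


def calls_to_frame(calls: Sequence[PsiCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref": c.ref_id,
                "start": c.site - 1,  # BED-like half-open
                "end": c.site,
                "name": f"psi_{c.ref_id}_{c.site}",
                "score": round(min(c.delta, 1.0) * 1000),
                "strand": "+",
                "site": c.site,
                "T_treated": c.T_treated,
                "T_control": c.T_control,
                "T_input": c.T_input,
                "delta": c.delta,
                "snr": c.snr,
                "pvalue": c.pvalue,
                "merged_sites": ";".join(map(str, c.merged_sites)),
            }
            for c in calls
        ],
        columns=[
            "ref", "start", "end", "name", "score", "strand", "site",
            "T_treated", "T_control", "T_input", "delta", "snr", "pvalue",
            "merged_sites",
        ],
    )


def write_calls(calls: Sequence[PsiCall], path, meta: dict | None = None) -> None:
    _write_tsv(calls_to_frame(calls), path, meta or {})


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_ct_tsv(path) -> pd.DataFrame:
    df, _ = _read_tsv(path)
    return df
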