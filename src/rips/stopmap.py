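"""Gapless mapping of RT-stop reads and per-position 5'-end stop pileups.

The references here are short oligos (tens of nucleotides), so the mapper is
a deliberately simple, fully verifiable gapless semi-global scan: the whole
read is slid along each reference and scored +1 per match, -1 per mismatch.
Indels are not modeled (the simulator emits substitution errors only);
aligned real data enters through :func:`read_sam` instead.

The quantity of interest downstream is ``stop5``: for each reference
position, the number of reads whose 5'-most aligned base is that position.
A read's 5' end marks where reverse transcription stopped (one nucleotide
3' of a Ψ-CMC adduct) or, after digestion, where the protected fragment
begins (the Ψ itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .templates import RnaTemplate


class MappingError(ValueError):
    pass


_MISS = object()  # cache sentinel distinguishing "unseen" from "unmapped"


@dataclass(frozen=True)
class Alignment:
    """A gapless placement of a full read on one reference (1-based, closed)."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    n_mismatch: int = 0
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise MappingError("ref_start > ref_end")
        if self.n_mismatch < 0:
            raise MappingError("negative mismatch count")


@dataclass
class StopPileup:
    """Per-position 5'-end stop counts and coverage on one reference.

    ``stop5[i-1]`` counts reads whose 5'-most aligned position is ``i``;
    ``cov[i-1]`` counts reads covering ``i``.  Ambiguous placements are
    counted separately and excluded from the tallies unless requested,
    to avoid double-counting stops.
    """

    ref_id: str
    length: int
    stop5: np.ndarray
    cov: np.ndarray
    n_mapped: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0

    def stop_at(self, position: int) -> int:
        return int(self.stop5[position - 1])


class ReferenceSet:
    """References pre-encoded for the sliding-window scan (DNA alphabet)."""

    def __init__(self, references: Sequence[RnaTemplate | tuple[str, str]]):
        if not references:
            raise MappingError("empty reference list")
        self.ids: list[str] = []
        self.seqs: dict[str, str] = {}
        self._enc: dict[str, np.ndarray] = {}
        for ref in references:
            if isinstance(ref, RnaTemplate):
                rid, seq = ref.id, ref.sequence
            else:
                rid, seq = ref
            dna = seq.upper().replace("U", "T")
            if rid in self.seqs:
                raise MappingError(f"duplicate reference id {rid!r}")
            self.ids.append(rid)
            self.seqs[rid] = dna
            self._enc[rid] = np.frombuffer(dna.encode("ascii"), dtype=np.uint8)
        self.ids.sort()

    def length(self, ref_id: str) -> int:
        return len(self.seqs[ref_id])


def map_read(
    read: str,
    references: ReferenceSet | Sequence,
    read_id: str = "",
    min_read_len: int = 10,
    min_identity: float = 0.8,
) -> Alignment | None:
    """Best gapless semi-global placement of a read, or None if unmapped.

    The read must fit entirely within a reference.  Placements are scored by
    match count; the best must reach ``min_identity`` over the full read
    length.  Score ties are broken toward the lowest (ref_id, ref_start) and
    flagged ``ambiguous``.
    """
    refs = references if isinstance(references, ReferenceSet) else ReferenceSet(references)
    n = len(read)
    if n < min_read_len:
        return None
    enc_read = np.frombuffer(read.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)

    best_matches = -1
    best: tuple[str, int] | None = None
    n_best = 0
    for rid in refs.ids:  # sorted: ties resolve to lowest (ref_id, ref_start)
        enc_ref = refs._enc[rid]
        if n > enc_ref.size:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc_ref, n)
        matches = (windows == enc_read).sum(axis=1)
        m = int(matches.max())
        if m > best_matches:
            best_matches = m
            best = (rid, int(np.argmax(matches)))
            n_best = int((matches == m).sum())
        elif m == best_matches:
            n_best += int((matches == m).sum())
    if best is None or best_matches / n < min_identity:
        return None
    rid, start0 = best
    return Alignment(
        read_id=read_id,
        ref_id=rid,
        ref_start=start0 + 1,
        ref_end=start0 + n,
        n_mismatch=n - best_matches,
        ambiguous=n_best > 1,
    )


def map_reads(
    reads: Iterable,
    references: ReferenceSet | Sequence,
    min_read_len: int = 10,
    min_identity: float = 0.8,
) -> list[Alignment | None]:
    """Map a batch of reads (ReadRecord or (id, seq) pairs); order-preserving.

    Each read is placed independently, so the result is invariant to input
    order up to the same permutation.  Placements are memoized by read
    sequence: RT-stop libraries over short oligos contain few distinct
    sequences, so this is a large constant-factor win.
    """
    refs = references if isinstance(references, ReferenceSet) else ReferenceSet(references)
    cache: dict[str, tuple | None] = {}
    out: list[Alignment | None] = []
    for r in reads:
        rid, seq = (r.name, r.sequence) if hasattr(r, "sequence") else r
        hit = cache.get(seq, _MISS)
        if hit is _MISS:
            a = map_read(seq, refs, read_id=rid,
                         min_read_len=min_read_len, min_identity=min_identity)
            hit = None if a is None else (a.ref_id, a.ref_start, a.ref_end,
                                          a.n_mismatch, a.ambiguous)
            cache[seq] = hit
        out.append(None if hit is None else Alignment(rid, *hit))
    return out


def pileup(
    alignments: Iterable[Alignment | None],
    ref: RnaTemplate | tuple[str, str],
    include_ambiguous: bool = False,
) -> StopPileup:
    """Tally 5'-end stops and coverage for one reference.

    ``None`` entries (unmapped reads) and alignments to other references are
    counted but not tallied; ambiguous placements are excluded from the
    tallies unless ``include_ambiguous``.
    """
    rid, seq = (ref.id, ref.sequence) if isinstance(ref, RnaTemplate) else ref
    L = len(seq)
    stop5 = np.zeros(L, dtype=np.int64)
    cov = np.zeros(L, dtype=np.int64)
    n_mapped = n_unmapped = n_ambiguous = 0
    for a in alignments:
        if a is None:
            n_unmapped += 1
            continue
        if a.ref_id != rid:
            continue
        if not 1 <= a.ref_start <= a.ref_end <= L:
            raise MappingError(
                f"alignment [{a.ref_start},{a.ref_end}] outside reference {rid!r} (length {L})"
            )
        if a.ambiguous and not include_ambiguous:
            n_ambiguous += 1
            continue
        stop5[a.ref_start - 1] += 1
        cov[a.ref_start - 1 : a.ref_end] += 1
        n_mapped += 1
    return StopPileup(rid, L, stop5, cov, n_mapped, n_unmapped, n_ambiguous)


def read_sam(
    path,
    references: ReferenceSet | Sequence,
    include_reverse: bool = False,
) -> list[Alignment]:
    """Convert primary SAM records into :class:`Alignment` objects.

    Secondary, supplementary and unmapped records are skipped; reverse-strand
    records are skipped unless ``include_reverse`` (simulated reads are
    RNA-sense by construction; the flag exists for imported real data).
    Mismatch counts come from the NM tag when present.  A record naming a
    reference not in ``references`` is an input error.
    """
    import pysam

    refs = references if isinstance(references, ReferenceSet) else ReferenceSet(references)
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_reverse and not include_reverse:
                continue
            rid = rec.reference_name
            if rid not in refs.seqs:
                raise MappingError(f"SAM reference {rid!r} not among supplied references")
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    ref_id=rid,
                    ref_start=rec.reference_start + 1,
                    ref_end=rec.reference_end,
                    n_mismatch=int(nm),
                    ambiguous=rec.mapping_quality == 0,
                )
            )
    return out
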