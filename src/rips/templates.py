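"""Reference RNA templates for exonuclease-protection simulations.

A template is a short RNA oligo (5'->3') annotated with pseudouridine (Ψ)
positions, a per-base secondary-structure mask (paired / unpaired) and its
5'-end chemistry.  XRN1 is a processive 5'->3' exoribonuclease that requires
a 5'-monophosphate; a 5'-OH strand is refractory to digestion, which is why
the 5'-end chemistry is part of the template, not of the run parameters.

Ψ is an isomer of uridine: it pairs like U (and has the same mass), so it is
stored as ``U`` in the sequence and flagged by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

RNA_ALPHABET = frozenset("ACGU")
PSI_CHARS = frozenset("ΨψY")  # accepted aliases when parsing annotated strings

#: Watson-Crick pairs (template base, blocker base); Ψ pairs as U.
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


class TemplateError(ValueError):
    """Raised when a template or its annotation violates an invariant."""


@dataclass(frozen=True)
class RnaTemplate:
    """A reference RNA with Ψ annotation, structure mask and 5'-end chemistry.

    Positions are 1-based throughout. ``paired_mask[i-1]`` is True when
    position ``i`` is base-paired (double-stranded), in which case the Ψ N3-H
    is hydrogen-bonded and refractory to carbodiimide labeling.
    """

    id: str
    sequence: str
    psi_positions: frozenset[int] = field(default_factory=frozenset)
    paired_mask: tuple[bool, ...] | None = None
    five_prime_phosphate: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise TemplateError(f"invalid characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "psi_positions", frozenset(int(p) for p in self.psi_positions))
        for p in self.psi_positions:
            if not 1 <= p <= len(seq):
                raise TemplateError(f"Ψ position {p} outside [1, {len(seq)}]")
            if seq[p - 1] != "U":
                raise TemplateError(
                    f"Ψ declared at position {p} but base is {seq[p - 1]!r}, not U"
                )
        if self.paired_mask is None:
            object.__setattr__(self, "paired_mask", tuple([False] * len(seq)))
        else:
            mask = tuple(bool(b) for b in self.paired_mask)
            if len(mask) != len(seq):
                raise TemplateError(
                    f"paired_mask length {len(mask)} != sequence length {len(seq)}"
                )
            object.__setattr__(self, "paired_mask", mask)

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_annotated(
        cls,
        id: str,
        annotated_sequence: str,
        paired_mask=None,
        five_prime_phosphate: bool = True,
    ) -> "RnaTemplate":
        """Build a template from a sequence in which Ψ is written literally.

        ``'Ψ'`` (or the aliases ``'ψ'``/``'Y'``) marks a pseudouridine and is
        stored as U with the position recorded in ``psi_positions``.
        """
        seq_chars, psis = [], set()
        for i, c in enumerate(annotated_sequence, start=1):
            if c in PSI_CHARS:
                seq_chars.append("U")
                psis.add(i)
            else:
                seq_chars.append(c)
        return cls(id, "".join(seq_chars), frozenset(psis), paired_mask, five_prime_phosphate)

    def with_mask(self, paired_mask) -> "RnaTemplate":
        return replace(self, paired_mask=tuple(bool(b) for b in paired_mask))

    def is_paired(self, position: int) -> bool:
        return self.paired_mask[position - 1]


def build_duplex_mask(
    template: RnaTemplate | str,
    blocker_sequence: str,
    min_match: int = 4,
    allow_gu: bool = False,
) -> np.ndarray:
    """Mark template positions covered by the best gapless anneal of a blocker.

    The blocker anneals antiparallel; a "match" is a maximal run of
    consecutive Watson-Crick pairs (A-U, G-C; G·U wobble only when
    ``allow_gu``) at a fixed register.  The longest run of length >=
    ``min_match`` wins; ties go to the 5'-most template start.  Returns an
    all-False mask when no run qualifies.  Ψ pairs exactly as U does.
    """
    seq = template.sequence if isinstance(template, RnaTemplate) else template
    seq = seq.upper().replace("T", "U")
    for label, s in (("template", seq), ("blocker", blocker_sequence)):
        cleaned = "".join("U" if c in PSI_CHARS else c for c in s.upper().replace("T", "U"))
        if set(cleaned) - RNA_ALPHABET:
            raise TemplateError(f"invalid characters in {label} sequence")
        if label == "template":
            seq = cleaned
        else:
            blocker = cleaned
    if min_match < 4:
        raise TemplateError("min_match must be >= 4")

    pairs = _WC_PAIRS | (_WOBBLE_PAIRS if allow_gu else set())
    rev = blocker[::-1]  # walk the blocker 3'->5' alongside the template 5'->3'
    L, M = len(seq), len(rev)
    best: tuple[int, int] | None = None  # (length, template_start_0based), max-len min-start

    for offset in range(-(M - 1), L):
        run_len, run_start = 0, None
        lo = max(0, offset)
        hi = min(L, offset + M)
        for t in range(lo, hi):
            if (seq[t], rev[t - offset]) in pairs:
                if run_len == 0:
                    run_start = t
                run_len += 1
                if run_len >= min_match:
                    cand = (run_len, run_start)
                    if best is None or run_len > best[0] or (
                        run_len == best[0] and run_start < best[1]
                    ):
                        best = cand
            else:
                run_len, run_start = 0, None

    mask = np.zeros(L, dtype=bool)
    if best is not None:
        n, s = best
        mask[s : s + n] = True
    return mask


def standin_oligo(
    id: str,
    length: int,
    psi_position: int | None,
    seed: int = 0,
    five_prime_phosphate: bool = True,
) -> RnaTemplate:
    """Generate a synthetic stand-in oligo of a given length and Ψ offset.

    The validation oligos used on the bench (19-, 16-, 60- and 32-mers) are
    proprietary sequences; these stand-ins reproduce only their lengths and
    Ψ offsets, with the rest of the sequence drawn uniformly at random.
    """
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGU"), size=length)
    if psi_position is not None:
        if not 1 <= psi_position <= length:
            raise TemplateError(f"psi_position {psi_position} outside [1, {length}]")
        bases[psi_position - 1] = "U"
        psis = frozenset({psi_position})
    else:
        psis = frozenset()
    return RnaTemplate(id, "".join(bases), psis, None, five_prime_phosphate)


def validation_oligos(seed: int = 7) -> dict[str, RnaTemplate]:
    """Synthetic stand-ins for the bench validation oligos.

    Keys: ``"19-RNA-psi"`` (Ψ at 4), ``"16-RNA-psi"`` (Ψ at 1, the 19-mer
    minus its first three bases), ``"60-RNA-psi"`` (Ψ at 30) and
    ``"32-RNA-psi"`` (Ψ at 16).  Sequences are random stand-ins; only the
    lengths and Ψ offsets carry meaning.
    """
    o19 = standin_oligo("19-RNA-psi", 19, 4, seed=seed)
    o16 = RnaTemplate("16-RNA-psi", o19.sequence[3:], frozenset({1}))
    o60 = standin_oligo("60-RNA-psi", 60, 30, seed=seed + 1)
    o32 = standin_oligo("32-RNA-psi", 32, 16, seed=seed + 2)
    return {t.id: t for t in (o19, o16, o60, o32)}
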