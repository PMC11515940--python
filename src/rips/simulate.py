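"""Molecule-level simulation of carbodiimide labeling, XRN1 digestion and RT.

The generative model mirrors the bench assay arm by arm:

1. **Labeling.** CMC forms an alkaline-stable adduct at the N3 of Ψ.  Each
   single-stranded Ψ is labeled independently with probability
   ``p_label_ss``; a base-paired Ψ (N3-H in a hydrogen bond) with
   ``p_label_ds`` (0 by default); unpaired U/G may retain a residual adduct
   with ``p_residual_ug`` (0 by default, alkaline treatment removes them).

2. **Digestion.** XRN1 engages a 5'-monophosphorylated strand with
   probability ``p_engage`` (a 5'-OH strand is never digested) and removes
   nucleotides 5'->3'.  At each labeled position, in ascending order, the
   bulky Ψ-CMC adduct halts the enzyme with probability ``p_protect``,
   leaving the protected fragment [Ψ, L]: the nucleotide one 5' of the
   adduct is the last one removed, so the fragment starts at the Ψ itself
   (the protection product of a 19-mer with Ψ at 4 is the 16-mer [4, 19]).
   If the enzyme digests through every labeled position the molecule is
   degraded.  Digestion is all-or-nothing per molecule; endpoint digestion
   efficiency is captured by ``p_engage``/``p_protect``, not by kinetics.

3. **Reverse transcription.** RT copies the surviving strand 3'->5'.  Before
   copying a labeled position j it terminates with probability
   ``p_rt_stop``, leaving a cDNA whose 5'-most copied base is j+1 ("one
   nucleotide 3' of the Ψ-CMC site"); at every position it may also stop
   with the background probability ``p_bg_stop``.  A stop that would yield
   an empty cDNA (at the fragment's 3'-most base) is discarded.

Reads are emitted RNA-sense (template substring [cdna_stop, L] transcribed
to the DNA alphabet) with substitution-only sequencing errors and constant
quality 'I'.  Labeling honours the native structure mask while digestion and
RT do not: the bench protocol labels natively, then denatures before
digestion, so a paired mask only suppresses labeling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .templates import RnaTemplate

Arm = Literal["input", "cmc_only", "cmc_xrn1", "xrn1_only"]
ARMS: tuple[Arm, ...] = ("input", "cmc_only", "cmc_xrn1", "xrn1_only")

INTACT, PROTECTED, DEGRADED = "intact", "protected", "degraded"

QUALITY_CHAR = "I"  # Phred 40

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Stochastic parameters of one simulated labeling/digestion/RT run.

    All probabilities are per-event Bernoulli rates in [0, 1].  Defaults are
    the endpoint rates of the validated assay: a Ψ-CMC adduct impedes
    exonuclease cleavage with probability 0.95, paired Ψ and alkaline-treated
    U/G retain no adduct, unlabeled strands are almost completely digested
    (``p_engage`` = 0.98), single-stranded labeling and RT-stop efficiencies
    (0.35 and 0.8) put the CMC-only termination rate just under 30% while
    the digested arm exceeds 55%.
    """

    p_label_ss: float = 0.35
    p_label_ds: float = 0.0
    p_residual_ug: float = 0.0
    p_engage: float = 0.98
    p_protect: float = 0.95
    p_rt_stop: float = 0.8
    p_bg_stop: float = 0.005
    seq_error: float = 0.001
    n_molecules: int = 20000
    min_fragment_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_label_ss", "p_label_ds", "p_residual_ug", "p_engage",
            "p_protect", "p_rt_stop", "p_bg_stop", "seq_error",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_molecules < 1:
            raise SimulationError("n_molecules must be >= 1")
        if self.min_fragment_len < 1:
            raise SimulationError("min_fragment_len must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class MoleculeFate:
    """Outcome of one molecule through labeling -> digestion -> RT.

    ``fragment`` is the closed 1-based interval surviving digestion; its end
    is always the template length (XRN1 trims only from the 5' side).
    ``cdna_stop`` is the template position of the 5'-most base copied by RT
    (``fragment[0]`` for a full-length cDNA).
    """

    template_id: str
    labeled_positions: frozenset[int] = field(default_factory=frozenset)
    fate: str = INTACT
    fragment: tuple[int, int] | None = None
    cdna_stop: int | None = None

    def __post_init__(self) -> None:
        if self.fate == DEGRADED:
            if self.fragment is not None or self.cdna_stop is not None:
                raise SimulationError("degraded molecule carries no fragment or cdna_stop")
        elif self.fragment is not None:
            s, e = self.fragment
            if s < 1 or e < s:
                raise SimulationError(f"bad fragment {self.fragment}")
            if self.cdna_stop is not None and not s <= self.cdna_stop <= e:
                raise SimulationError(
                    f"cdna_stop {self.cdna_stop} outside fragment {self.fragment}"
                )


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (DNA alphabet, RNA-sense orientation)."""

    name: str
    sequence: str
    quality: str
    comment: str = "rna-sense"


def label_probabilities(template: RnaTemplate, params: SimParams) -> np.ndarray:
    """Per-position probability of carrying a stable CMC adduct."""
    L = len(template)
    p = np.zeros(L)
    paired = np.asarray(template.paired_mask, dtype=bool)
    for pos in template.psi_positions:
        p[pos - 1] = params.p_label_ds if paired[pos - 1] else params.p_label_ss
    if params.p_residual_ug > 0:
        for i, base in enumerate(template.sequence):
            if base in "UG" and (i + 1) not in template.psi_positions and not paired[i]:
                p[i] = params.p_residual_ug
    return p


def simulate_labeling(
    template: RnaTemplate, params: SimParams, rng: np.random.Generator
) -> list[frozenset[int]]:
    """Draw labeled-position sets for ``n_molecules`` molecules."""
    p = label_probabilities(template, params)
    hits = rng.random((params.n_molecules, len(template))) < p
    return [frozenset(np.flatnonzero(row) + 1) for row in hits]


def simulate_xrn1(
    labeled: Iterable[int],
    template: RnaTemplate,
    params: SimParams,
    rng: np.random.Generator,
) -> MoleculeFate:
    """Digest one molecule; returns its fate and surviving fragment."""
    labeled = frozenset(int(p) for p in labeled)
    L = len(template)

    def _sized(fate: str, start: int) -> MoleculeFate:
        # library size selection: fragments below min_fragment_len are lost
        if L - start + 1 < params.min_fragment_len:
            return MoleculeFate(template.id, labeled, DEGRADED)
        return MoleculeFate(template.id, labeled, fate, (start, L))

    if not template.five_prime_phosphate:
        return _sized(INTACT, 1)
    if rng.random() >= params.p_engage:
        return _sized(INTACT, 1)
    for pos in sorted(labeled):
        if rng.random() < params.p_protect:
            return _sized(PROTECTED, pos)
    return MoleculeFate(template.id, labeled, DEGRADED)


def simulate_rt(
    fate: MoleculeFate,
    template: RnaTemplate,
    params: SimParams,
    rng: np.random.Generator,
) -> MoleculeFate:
    """Reverse-transcribe one surviving molecule, setting ``cdna_stop``."""
    if fate.fate == DEGRADED:
        raise SimulationError("cannot reverse-transcribe a degraded molecule")
    start, end = fate.fragment
    stop = start
    for j in range(end, start - 1, -1):
        halt = (j in fate.labeled_positions and rng.random() < params.p_rt_stop)
        halt = bool(rng.random() < params.p_bg_stop) or halt
        if halt and j < end:  # a halt at the 3'-most base would leave no read
            stop = j + 1
            break
    return MoleculeFate(fate.template_id, fate.labeled_positions, fate.fate, fate.fragment, stop)


def simulate_molecule(
    template: RnaTemplate, params: SimParams, arm: Arm, rng: np.random.Generator
) -> MoleculeFate:
    """Run one molecule through the steps of an experimental arm.

    input: RT only; cmc_only: labeling + RT; cmc_xrn1: labeling + digestion +
    RT; xrn1_only: digestion (no labels) + RT.  Reference per-molecule path,
    used to validate the vectorized library engine.
    """
    _check_arm(arm)
    L = len(template)
    labeled: frozenset[int] = frozenset()
    if arm in ("cmc_only", "cmc_xrn1"):
        p = label_probabilities(template, params)
        labeled = frozenset(np.flatnonzero(rng.random(L) < p) + 1)
    if arm in ("cmc_xrn1", "xrn1_only"):
        fate = simulate_xrn1(labeled, template, params, rng)
    else:
        fate = MoleculeFate(template.id, labeled, INTACT, (1, L))
    if fate.fate == DEGRADED:
        return fate
    return simulate_rt(fate, template, params, rng)


def _check_arm(arm: str) -> None:
    if arm not in ARMS:
        raise SimulationError(f"unknown arm {arm!r}; expected one of {ARMS}")


def _simulate_template_arrays(
    template: RnaTemplate, params: SimParams, arm: Arm, rng: np.random.Generator
):
    """Vectorized engine: per-molecule (labeled matrix, fate, frag_start, cdna_stop)."""
    n, L = params.n_molecules, len(template)
    do_label = arm in ("cmc_only", "cmc_xrn1")
    do_digest = arm in ("cmc_xrn1", "xrn1_only")

    if do_label:
        labeled = rng.random((n, L)) < label_probabilities(template, params)
    else:
        labeled = np.zeros((n, L), dtype=bool)

    fate = np.full(n, 0, dtype=np.int8)  # 0=intact 1=protected 2=degraded
    frag_start = np.ones(n, dtype=np.int64)
    if do_digest and template.five_prime_phosphate:
        active = rng.random(n) < params.p_engage
        for c in np.flatnonzero(labeled.any(axis=0)):
            halt = active & labeled[:, c] & (rng.random(n) < params.p_protect)
            frag_start[halt] = c + 1
            fate[halt] = 1
            active &= ~halt
        fate[active] = 2
        short = (fate != 2) & (L - frag_start + 1 < params.min_fragment_len)
        fate[short] = 2
        frag_start[fate == 2] = 0

    # RT: last (3'-most) halt position j in [frag_start, L-1]; stop one 3' of it.
    halts = rng.random((n, L)) < params.p_bg_stop
    halts |= labeled & (rng.random((n, L)) < params.p_rt_stop)
    halts[:, L - 1] = False  # a halt before copying the 3'-most base is discarded
    cols = np.arange(1, L + 1)
    halts &= cols >= frag_start[:, None]
    any_halt = halts.any(axis=1)
    last = L - 1 - np.argmax(halts[:, ::-1], axis=1)  # 0-based column of last halt
    cdna_stop = np.where(any_halt, last + 2, frag_start)
    cdna_stop[fate == 2] = 0
    return labeled, fate, frag_start, cdna_stop


def _apply_sequencing_errors(
    seqs: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    joined = "".join(seqs).encode("ascii")
    arr = np.frombuffer(joined, dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(_DNA):
            lut[b] = i
        idx = lut[arr[hit]]
        arr[hit] = _DNA[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    out, off = [], 0
    buf = arr.tobytes()
    for s in seqs:
        out.append(buf[off : off + len(s)].decode("ascii"))
        off += len(s)
    return out


def simulate_library(
    templates: Sequence[RnaTemplate],
    params: SimParams,
    arm: Arm,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one sequencing library (one arm) over a set of templates.

    Returns the reads (one per molecule surviving digestion) and a truth
    table with every molecule's labeled positions, fate, fragment and RT
    stop.  With a fixed seed the output is byte-identical across runs.
    """
    _check_arm(arm)
    if not templates:
        raise SimulationError("empty template list")
    if rng is None:
        rng = params.rng()

    fate_names = np.array([INTACT, PROTECTED, DEGRADED])
    reads: list[ReadRecord] = []
    rows = []
    for template in templates:
        L = len(template)
        labeled, fate, frag_start, cdna_stop = _simulate_template_arrays(
            template, params, arm, rng
        )
        surv = np.flatnonzero(fate != 2)
        dna = template.sequence.replace("U", "T")
        seqs = [dna[cdna_stop[i] - 1 : L] for i in surv]
        seqs = _apply_sequencing_errors(seqs, params.seq_error, rng)
        read_ids = {}
        for k, i in enumerate(surv):
            name = f"{template.id}|{arm}|m{i}"
            read_ids[i] = name
            reads.append(ReadRecord(name, seqs[k], QUALITY_CHAR * len(seqs[k])))
        lab_strs = [";".join(map(str, np.flatnonzero(row) + 1)) for row in labeled]
        for i in range(params.n_molecules):
            dead = fate[i] == 2
            rows.append(
                {
                    "read_id": read_ids.get(i, ""),
                    "template_id": template.id,
                    "arm": arm,
                    "molecule": i,
                    "labeled_positions": lab_strs[i],
                    "fate": fate_names[fate[i]],
                    "frag_start": 0 if dead else int(frag_start[i]),
                    "frag_end": 0 if dead else L,
                    "cdna_stop": 0 if dead else int(cdna_stop[i]),
                }
            )
    truth = pd.DataFrame(rows)
    return reads, truth


def truth_header(params: SimParams, arm: Arm) -> str:
    """'#'-prefixed metadata line carrying the run parameters as JSON."""
    return "# " + json.dumps({"arm": arm, "params": params.to_dict()}, sort_keys=True)
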