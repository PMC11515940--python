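# Methods

## The assay being modeled

Pseudouridine (Ψ) is an isomer of uridine: identical mass and Watson–Crick
face, but with a free N3-H when single-stranded. The carbodiimide CMC forms
an alkaline-stable adduct at that N3, and the adduct (i) blocks reverse
transcription one nucleotide 3′ of the site and (ii) sterically halts the
processive 5′→3′ exoribonuclease XRN1. Digesting a CMC-treated library with
XRN1 therefore destroys unlabeled strands while converting labeled strands
into fragments that begin at the Ψ, enriching the signal and raising the
per-site RT termination rate relative to CMC-only treatment. Because a
base-paired Ψ has its N3-H in a hydrogen bond, only single-stranded Ψ is
labeled, which makes the assay structure-selective.

`rips` implements this as (a) a generative, molecule-level simulator of the
four experimental arms (input, CMC-only, CMC+XRN1, XRN1-only), (b) a
read-mapping and stop-pileup stage, (c) the termination-rate statistic and
threshold caller, (d) the qPCR ΔΔCt termination-rate formula, and (e) the
oligonucleotide/adduct mass arithmetic used to verify the protection
product's identity.

## Generative model

Each molecule passes through three Bernoulli stages (probabilities in
`SimParams`):

1. **Labeling.** Each unpaired Ψ gains a stable adduct with `p_label_ss`;
   paired Ψ with `p_label_ds`; unpaired U/G with `p_residual_ug`
   (leak-through past alkaline treatment). Labeling uses the native
   structure mask; digestion and RT do not, mirroring the bench order
   (label natively, denature, digest).
2. **Digestion.** XRN1 requires a 5′-monophosphate (a 5′-OH strand is
   returned intact) and engages with `p_engage`. The enzyme walks 5′→3′;
   at each labeled position, in ascending order, it halts with `p_protect`,
   leaving the fragment [Ψ, L]. Passing the last labeled position degrades
   the molecule. Digestion is all-or-nothing per molecule: endpoint
   digestion efficiencies stand in for kinetics, so time-gradient behavior
   is represented by moving `p_engage`/`p_protect`, not by a rate model.
3. **Reverse transcription.** Scanning 3′→5′, RT halts before copying a
   labeled position with `p_rt_stop` (cDNA 5′-most base = Ψ+1) and at any
   position with `p_bg_stop`. A halt at the fragment's 3′-most base is
   discarded (no empty cDNA).

The **fragment boundary** is [Ψ, L]: the protection product of a 19-mer
with Ψ at position 4 is the 16 3′-terminal nucleotides, and its mass is the
unlabeled 16-mer plus one intact CMC cation — the accounting that matches
the observed 5855.7 + 252.2 = 6107.9 Da. Descriptions of the halt as "one
nucleotide 5′ of the adduct" refer to the last nucleotide *removed*, which
is the position immediately 5′ of the Ψ.

Reads are emitted RNA-sense — the template substring [cdna_stop, L]
transcribed to DNA — with substitution-only errors at `seq_error` and
constant quality `I`. One seeded `numpy` generator drives a run; the
vectorized library engine is validated against the per-molecule reference
path and against exhaustive enumeration (below).

### Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `p_label_ss` | 0.35 | CMC labeling of unpaired Ψ; with `p_rt_stop`=0.8 puts the CMC-only termination rate just under 30%, the regime the sequencing validation operates in |
| `p_label_ds` | 0.0 | paired Ψ cannot be labeled (N3-H engaged) |
| `p_residual_ug` | 0.0 | alkaline treatment removes U/G adducts |
| `p_engage` | 0.98 | unlabeled strands are almost completely digested at the optimized endpoint |
| `p_protect` | 0.95 | measured probability that the adduct impedes cleavage |
| `p_rt_stop` | 0.8 | RT stop efficiency at a Ψ-CMC |
| `p_bg_stop` | 0.005 | per-base background RT stops |
| `seq_error` | 0.001 | per-base substitution rate |
| `n_molecules` | 20 000 | molecules per template per arm |
| `min_fragment_len` | 10 | library size selection; also the mapper's minimum read length |

## Mapping and pileups

References are short oligos, so mapping is an exact, gapless semi-global
scan (+1 match / −1 mismatch, full read inside the reference, ≥ 80%
identity, ties → lowest (ref, start) and flagged ambiguous; ambiguous
placements are excluded from tallies). This keeps the mapper provable
against the simulator's truth table; indels are not modeled, and externally
aligned data can be imported from SAM (primary, forward records by
default). Reads shorter than 10 nt are unmapped by design.

`stop5[i]` counts reads whose 5′-most aligned base is `i` — RT stops land
on Ψ+1, digestion fragment starts on Ψ itself.

## Termination rate and calling

    T(site) = stop5[site+1] / (stop5[site+1] + #reads with 5′ end ≤ site)

The denominator counts only reads that inform the site (stopped there or
read through it), making T invariant to 3′-truncation of other molecules.
T is reported at the Ψ coordinate (the stop observed one base 3′ is
back-shifted). Sites with denominator < `min_cov` (default 50) are missing.

A site is called when `T_treated ≥ tau_t` (0.3), `T_treated − T_control ≥
tau_delta` (0.1), both denominators ≥ `min_cov`, and — when an input
profile is supplied and covered — `T_input < tau_t`. `tau_t` sits between
the CMC-only (<30%) and CMC+XRN1 (>55%) regimes the assay produces.
The signal-to-noise ratio adds a pseudocount ε = 1/(denominator+1) to both
rates; T itself is unsmoothed. A one-sided binomial p-value against the
control rate is emitted for reference; calls are threshold-based and no
multiple-testing correction is applied.

**Doublet collapse.** After digestion, a protected fragment's full-length
cDNA starts at the Ψ while its terminated cDNA starts at Ψ+1, so the
treated arm shows two adjacent above-threshold sites, Ψ−1 (fed by the
fragment-start pile at Ψ) and Ψ (fed by the RT-stop pile at Ψ+1). This
doublet is the signature of a single Ψ, and the caller collapses each run
of adjacent passing sites to its 3′-most member by default
(`collapse_adjacent=False` restores the raw list). The cost: directly
adjacent Ψs would merge into one call.

## qPCR readout

With a spanning amplicon (only read-through cDNAs amplify) and a
downstream amplicon (all cDNAs amplify), input-normalized ΔCt values give
`rate = 1 − 2^−(ΔCt1 − ΔCt2)` under perfect doubling per cycle. Negative
raw rates are clamped to 0 and flagged — they indicate a near-zero site,
not negative biology. Amplification-efficiency calibration is out of scope.

## Mass arithmetic

Masses are elemental sums: ribonucleoside formulas + HPO3 − H2O per
phosphodiester bridge, + HPO3 for a 5′-monophosphate, Ψ ≡ U. The CMC label
adds the intact C14H26N3O⁺ cation (monoisotopic 252.21 Da; no proton
correction, electron mass ignored) — the only accounting consistent with
the observed labeled-product mass. Monoisotopic is the default mode.
Protection products are reported with a 5′-monophosphate (what XRN1
leaves); synthetic 5′-OH standards can be matched via the `five_prime`
option.

## Verification strategy

- **Exhaustive enumeration.** For a 6-nt template with two Ψ the full
  outcome distribution over (fragment start, RT stop, degradation) is
  computed exactly by summing all Bernoulli branches; 50 000 simulated
  molecules must pass a chi-square goodness-of-fit at α = 0.01. Both the
  vectorized engine and the per-molecule path are checked.
- **Truth-table oracles.** On error-free reads the pileup must reproduce
  the simulator's stop histogram exactly; with 1% errors ≥ 99% of
  mappable reads must recover their true positions.
- **Closed-form composition.** With background stops off, the CMC-only
  arm's T(Ψ) estimates `p_label_ss · p_rt_stop`; a 3×3 grid at 20 000
  molecules must land within 3 binomial SE.
- **Mass oracle.** Oligo masses are cross-checked against an independent
  elemental-formula computation (pyteomics) built from nucleotide
  monophosphate formulas.
- **Determinism.** Same seed ⇒ byte-identical FASTQ and pipeline
  artifacts (sha256 in the run manifest).

Problem sizes used throughout (20 000 molecules for rate estimates, 4 000
per replicate in the 100-seed selectivity screen, 50 000 for the
goodness-of-fit) were chosen so binomial standard errors are a few tenths
of a percent at the rates of interest.

## What the generator does and does not emulate

It emulates the stochastic chemistry/enzymology of the assay: selective
labeling by structure, 5′-phosphate-dependent all-or-nothing digestion
with probabilistic protection, offset RT stops, background stops,
substitution sequencing errors, and library size selection. It does not
emulate: digestion kinetics or partial processivity ladders (a single halt
point per molecule), CMC reaction-condition dependence, indels or
quality-score variation, adapter/primer artifacts, abundance heterogeneity
across a transcriptome, or RT fall-off unrelated to position. Passing
tests therefore demonstrate correctness of the statistics under the
declared generative model, not performance on transcriptome-scale real
libraries — for those, aligned SAM input is the entry point, and the
declared thresholds are starting points, not guarantees.

## Known limitations

- Adjacent Ψs merge under doublet collapse.
- Exactly one halt point per molecule; stalling >1 nt before the adduct
  would smear the fragment-start pile in real data.
- The gapless mapper is for short oligo references only.
- The qPCR model assumes perfect amplification efficiency.
- Stand-in oligo sequences reproduce only the validated lengths and Ψ
  offsets of the bench constructs, not their proprietary sequences.
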