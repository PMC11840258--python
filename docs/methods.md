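# Methods

## The system being modelled

Mouse Paneth cells transcribe a ~0.71 Mb locus of 28 highly similar,
two-exon alpha-defensin (*Defa*) genes at extreme levels — roughly 85% of
their mRNA.  Each gene encodes a ~92-aa pre-pro-protein: a 19-aa signal
peptide, a pro region, and a ~33-aa mature peptide with six conserved
cysteines, the biologically active part, encoded by exon 2.  A small
fraction of the family's mRNA (~0.24%) consists of *chimeric* transcripts
whose exon-2 sequence switches from one parental gene (the donor) to
another (the acceptor) at some breakpoint.  The package reconstructs the
computational arms of that analysis: annotation reconciliation, exhaustive
chimera enumeration, read-level quantification, junction-peptide evidence,
and dose-response activity — all runnable on synthetic data.

## Annotation reconciliation (`annotation`)

Gene models from several sources (RefSeq, GENCODE, MGI) disagree mostly in
their UTRs.  `merge_gene_models` takes, per gene, the earliest start and
latest end over all sources and records which source contributed each
boundary.  Coordinates are 1-based inclusive externally and 0-based
half-open internally; the converters are exact and tested both ways.
`filter_predictions` implements the non-mouse prediction filters: drop
genes outside 500–3000 bp, then collapse intervals with at least 75%
*reciprocal* overlap into their union span, iterating to a fixpoint so the
result is order-independent.  Reciprocal (both-interval) overlap is the
default because it prevents a tiny prediction from being absorbed by a
large one; a single-sided mode is available.  Merging never clips a gene
to its neighbours; whether a merged UTR can cross a neighbouring gene is
left to the caller.

## Chimera enumeration (`chimera`)

The crossover model is a single breakpoint restricted to the exon-2 CDS,
with the acceptor suffix taken at the same nucleotide offset (ungapped
homologous coordinates) — the simplest model consistent with an
equal-length, near-identical family.  Exon 1 always comes from the donor,
because only exon-2 events change the mature peptide.  For every ordered
pair and every breakpoint the candidate must:

1. be in frame with exactly one terminal stop codon;
2. keep the cysteine scaffold of the mature region (default `count6`:
   exactly six cysteines; a stricter `parental_pattern` mode also requires
   the offsets to match a parent);
3. differ from both parents at the nucleotide *and* protein level;
4. not repeat an earlier candidate of the same pair (the smallest
   breakpoint is kept — a deterministic tie-break, since all breakpoints
   between two adjacent parental differences give the same sequence).

Pooled candidates are then purged of anything protein-identical to *any*
parental and collapsed on identical nucleotide sequence; the provenance
map retains every (donor, acceptor, breakpoint) origin of each surviving
sequence, and a rejection ledger records every filtered candidate.
Correctness is established against an independently coded brute-force
oracle on dozens of random small families.

## Quantification (`quant`)

The quantifier is a self-contained emulation of decoy-aware selective
quantification.  A k-mer index (k = 21) maps each k-mer to the set of
transcripts containing it; a read's equivalence class is the intersection
of those sets over its k-mers.  Transcripts carry roles — `parental`,
`chimera`, or `decoy` — and decoys absorb reads without being reported,
which reproduces the four index configurations of the study (parentals
only; parentals + chimeras; chimeras as decoys; parentals as decoys).

Because the family is near-identical, almost every read is compatible with
many transcripts, and three refinements are needed before an EM estimate
is meaningful:

* **Window emission model.**  For the observed read length L, every
  transcript's `len − L + 1` windows are pre-classified with the same rule
  as reads, giving per-transcript emission probabilities
  P(class | t) = windows(t, class)/windows(t).  Without this, transcripts
  whose discriminating windows are never observed sit on a nearly flat
  likelihood ridge.
* **Error-model cross-emissions.**  A read matching a chimera's junction
  window exactly may equally be a parental read with a single sequencing
  error at the one discriminating site.  Junction (all-chimera) classes
  therefore also receive emissions from parentals whose homologous window
  lies within two substitutions, weighted (ε/3)^m per matching window
  relative to a perfect match, with ε the assumed per-base error rate
  (default 0.001).
* **Anchored classification with snapping.**  Reads are located by k-mer
  anchoring (a k-mer's known reference position fixes the offset) and
  verified by direct comparison; a read that matches no window exactly is
  Hamming-scored against every transcript at the anchored offset and
  snapped to the nearest transcript's window class (ties favour
  parentals).  At `max_mismatches = 0` such reads are left unassigned.

Class counts are resolved by EM accelerated with squared (SQUAREM-style)
extrapolation and a parsimony-informed start (each class's count seeded on
its non-chimeric members); the likelihood is concave, so the start affects
convergence speed, not the optimum.  Finally, because one free abundance
per enumerated chimera lets the likelihood overfit spurious junction reads
(a single error at an isolated variant site turns a parental read into a
perfect junction read, at roughly twice the true junction-read rate under
the default conditions), the *aggregate* chimeric mass is re-estimated
from background-free evidence:

    A = J_strong / f_strong

where `J_strong` counts reads in *strong* junction classes — those at
least two substitutions away from every parental window, unreachable by a
single error — and `f_strong` is the mean fraction of a chimera's windows
lying in strong junction classes.  Per-chimera EM abundances are rescaled
to this total, the difference returning to the parentals.  On truth-known
simulations the estimator is unbiased; its standard deviation is set by
the strong-junction-read Poisson noise scaled by 1/f_strong, which is near
the information floor of the problem — non-junction chimeric reads are
sequence-identical to parental windows and carry no signal.  TPM uses
effective length `len − read_len + 1` (floored at 1) and sums to one
million over non-decoy transcripts.

Detection ("found in a sample") is TPM > 0 by default, with a configurable
minimum.  `occurrence_summary` reports the never-found group, a low band
(default 1–50 samples), and the ≤ one-third / ≥ two-thirds thresholds;
because a published threshold phrased as "two thirds (>100)" of 148
samples conflicts with ceil(2·148/3) = 99, both thresholds can be
overridden explicitly.  Split-read support anchors a read in two parentals
by best ungapped offset and reports the breakpoint minimising total
mismatches (ties to the smallest breakpoint); it is "unsupported" when
either side needs more than ⌊L/4⌋ mismatches.  Indel-tolerant alignment is
out of scope: reads are 60–80 bp on a near-identical, equal-length family.

## Peptide evidence (`peptides`)

In-silico digestion uses simple protease rules: trypsin (after K/R, not
before P), Glu-C (after E; D optionally, as in phosphate buffers), and
elastase, whose specificity is not standardised — we use the common broad
rule (after A, V, S, G, L, I), configurable.  MS observability is
approximated by peptide length bounds (default 4–60 aa) rather than
mass/charge modelling.  A peptide supports a chimera if it spans the
junction with at least one residue strictly on each side *and* no window
of any parental protein matches it within `max_mismatches` substitutions
(an exhaustive blastp-like scan).  A chimera is "provable" when at least
one peptide from any enzyme has both properties.  The junction position in
protein space is `(exon1_len + breakpoint) // 3`.  Appending the GSG+His6
purification tag to acceptor-parent C-termini leaves the junction logic
unchanged, mirroring the pull-down design used to enrich Defa30-acceptor
chimeras.

## Dose-response activity (`activity`)

Survival is colonies(dose)/colonies(0-dose), using at each dose the
highest plated concentration whose plate is still countable (default ≤300
colonies), scaled by the dilution.  The four-parameter logistic

    s(x) = lower + (upper − lower) / (1 + exp(slope (ln x − ln midpoint)))

is fitted by least squares from a fixed multi-start grid (slopes ±0.5, ±1,
±2 × midpoints at the positive-dose quartiles), best SSE wins, ties to the
smallest midpoint; the fit is canonicalised to upper ≥ lower (the model is
invariant under swapping asymptotes and negating the slope).  IC50 is the
dose where *absolute* survival crosses 0.5 — "the dose that kills half the
bacteria" — not the curve midpoint; curves that never cross 0.5 within 10×
the maximal dose are flagged undefined.  Specific activity is defined as
U/mg = 1000/IC50(µg/ml), taking 1 U as the IC50 dose in the 1-ml assay
volume; the published table never states this conversion and its raw
counts are not available, so the formula is a package choice and is
pluggable.  Table aggregation reproduces the published row means exactly
(arithmetic mean, rounded half-up); the published per-bacterium column
means are *not* reproducible from the printed cells (e.g. 345 computed vs
348 printed for E. coli, with one peptide's row printed twice) and are
deliberately not matched.

## Synthetic data (`simulate`)

The generator works backwards from a random valid ancestor: a mature
peptide with six well-separated cysteines and a cationic (R/K-enriched)
bias is embedded in a 92-aa pre-pro-protein, reverse-translated with
random codons, and each gene mutates non-protected positions at a rate
calibrated so mean pairwise nucleotide identity hits the target (default
0.90); codons that would create a stop or touch the cysteine scaffold are
reverted, so every gene satisfies the gene-model invariants by
construction.  The CDS is split ~43:57 between the exons so the mature
region lies entirely in exon 2.

The transcript pool mirrors the study's abundance regime: the family takes
85.19% of all mRNA; one dominant gene is pinned to 16.4% of the family
(the remaining log-normal draws are temperature-flattened just enough that
none exceeds it, preserving a long near-zero tail); chimeras share 0.24%
of the family budget with log-normal weights; a few random background
transcripts (indexed as decoys) fill the rest.  Reads draw a molecule by
abundance and a start position uniformly, plant substitutions at the error
rate (default 0.001/base), and record a per-read truth table; paired mode
emits a reverse-complemented mate from the other fragment end.  A single
global seed derives per-stage seeds by fixed offsets.

What the generator does *not* emulate: positional coverage bias, quality
scores, indels, intron retention, library-specific error profiles, and any
relationship between a chimera's abundance and its sequence.  Passing
tests therefore demonstrate correctness of the algorithms under an
idealised read model, not performance on real libraries.

## Problem sizes and numerical choices

The full-scale synthetic run uses the 28-gene family (~9,000 enumerated
chimeras) and one million 70-bp reads; unit tests use 2–10-gene families
and 10³–10⁵ reads.  EM stops when the relative likelihood gain per
accelerated cycle falls below 1e-10 (at most 1000 cycles); 4PL fits use
`scipy.optimize.least_squares` (LM) with analytic-free residuals and are
bit-deterministic.  Degenerate inputs — empty read files, constant
survival, unreachable identity targets, conflicting gene records — return
flagged results or raise informative errors rather than guessing.

## Known limitations

* Recovery of the aggregate chimeric fraction from reads is at the
  information floor: with a 0.24% spike, ~10% pairwise divergence and
  70-bp reads, only ~a quarter of chimeric reads span a junction
  informatively, and single sequencing errors at isolated variant sites
  mimic junction reads at ~2× the true junction-read rate.  The calibrated
  estimator is unbiased but its standard error at one million reads is
  comparable to twice the binomial standard error of the spike itself.
* Cross-emissions and alignment rescue assume homologous (equal-offset)
  coordinates, exact for the synthetic family; real families with indels
  would need the alignment-based offset mapping hook.
* The uniqueness scan is exact but quadratic; it is meant for
  family-versus-family checks, not whole-proteome searches.
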