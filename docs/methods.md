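# Methods

## Data model and coordinate conventions

A `VariantCall` is one normalized ALT allele at one site with caller
provenance, quality metrics and annotations. VCF positions are 1-based;
copy-number bins/segments and BED intervals are 0-based half-open, and
conversion happens only at the I/O boundary. Metrics a caller did not
report are missing (`None`), never zero-filled: a filter cannot fire on
absent evidence, so missing metrics default to *keep* (configurable per
rule).

Indels are left-normalized at read time so allele identity is well
defined across callers: identical trailing bases are trimmed, extending
to the left with the reference base when an allele would become empty,
then identical leading bases are trimmed. Left extension needs reference
context; it is supplied as an optional base-lookup callable, and without
one only suffix/prefix trimming is performed (sufficient whenever both
callers emit the same representation, as the bundled simulator does).

## The filter cascade

Stage order is fixed and each stage is a pure subset operation:
intersection → initial filters → target mask (±10 bp padding, targets
must overlap annotated genes) → PoN subtraction → population germline →
VAF/LOH germline → heuristic profile → quality floor → cross-region
propagation → cross-patient recurrence. Gate-by-gate counts are recorded
as provenance.

Comparator strictness follows each rule's published wording: "greater
than" / "more than" / "lower than" are strict; "at least" / "greater or
equal" are inclusive. The boundary tests encode every comparator
explicitly. Note one deliberate asymmetry: the per-region VAF germline
rule fires at VAF ≥ 0.9 while its cross-region propagated form fires at
VAF > 0.9, matching the wording of each rule.

Built-in profiles:

| profile | rules |
|---|---|
| `gold_standard` | quality > 175, mismatches < 2.5, depth ≥ 25, pos-in-read > 20, MS length < 5, VAF > 0.14 |
| `ffpe_benchmark` | depth ≥ 5, MQ > 45, pos-in-read > 15, mismatches < 2.5, MS length < 5, TLOD > 10, FS < 10, VAF > 0.14 |
| `initial` | depth ≥ 4, quality > 0 (permissive stand-in for upstream tumor-only caller defaults; fully config-driven) |

On intersection, the retained record carries the first caller's
count-type metrics, the second caller fills metrics the first did not
report (e.g. tumor log-odds), and ensemble quality is the maximum across
callers; duplicate keys within one caller keep the higher-quality
record. `pop_af` is interpreted as the maximum across annotated
population databases. The cross-patient hotspot exemption is gene-level
(PIK3CA, TP53, GATA3 by default) because hotspots are named by gene.

## Copy-number post-processing

Bins with log2 < −15 are capture artifacts and removed. Segment QC fails
a segment on < 10 probes, biweight midvariance > 2, or a log2 confidence
interval containing 0. The CI criterion is **not** applied to the burden
denominator: on exome-scale profiles nearly every neutral segment has a
CI spanning 0, and removing them would leave an almost purely altered
denominator; burden therefore uses segments passing the probe-count and
variance filters only, while confident gain/loss calls (arms, genes)
additionally require the CI to exclude 0.

Arm calls use the arm length *covered by segments* as denominator
(targeted segments do not tile cytogenetic arms) and require strictly
more than half of it in a gained (log2 > 0.3) or lost (log2 < −0.3)
state. Gene calls require ≥ 3 overlapping bins and a covering segment
with ≥ 110 probes; with several covering segments the higher-confidence
one wins (narrower CI, then more probes). Because segmentation
breakpoints are imprecise, a gene overlapping a segment breakpoint in
any region of a patient is excluded from all regions of that patient.
Reporting thresholds are asymmetric: gain at log2 > 0.4, loss at
log2 < −0.6. LOH is called per segment at BAF < 0.3 or > 0.7; missing
BAF means not-LOH, flagged.

## Multi-region presence model

For each candidate mutation and region, given alt reads `a` out of depth
`d`:

* absent: `L0 = Binom(a; d, e)` with error rate `e` (default 0.02);
* present: allele fraction uniform on [0,1], so `L1 = 1/(d+1)`;
* posterior of presence = `p·L1 / (p·L1 + (1−p)·L0)` with prior
  `p = 0.5`.

Cells with depth below `min_depth` (default 5) or missing counts are
`unknown`. This is a transparent simplification of published
multi-region callers, which optimize a richer joint model; it preserves
the contract (posterior matrix + tree) while staying exactly
oracle-checkable.

Two numerical properties of this model are worth knowing:

* The posterior is **not** monotone in `a` near zero: `L0` rises from
  `a = 0` to its mode at ~`d·e`, so the posterior dips there before
  climbing. Monotonicity holds beyond the error mode.
* A site with *fewer* errors than `e` expects looks "too clean" for the
  error model and drifts toward *present* (the uniform alternative
  absorbs it at f ≈ 0). In particular `a = 0` classifies absent only
  while `(1−e)^d > 1/(d+1)` — about `d ≤ 270` at `e = 0.02`. The
  default joint-extraction depth in the simulator (200×) sits below this
  crossover; at that depth an absent cell misclassifies only when
  `a ≥ 11` (probability ≈ 2.5 × 10⁻³ under Binom(200, 0.02)).

The binarized matrix is summarized by parsimony. If all presence
patterns are pairwise nested or disjoint (a perfect phylogeny exists),
the nested-set hierarchy is returned with per-edge mutation counts.
Otherwise regions are agglomerated greedily — the pair of clusters
sharing the most mutations merges first, ties broken lexicographically,
so output is deterministic — and mutations whose pattern is not a clade
of the result are counted as homoplasies. Mutations with unknown cells
are placed on the smallest containing clade but define no clade;
mutations absent everywhere are reported unplaced.

## Benchmarking

Matching is exact allele-key equality after normalization — a deliberate
divergence from haplotype-aware matchers, chosen because it is
deterministic and brute-force checkable. SNVs and indels are reported
separately and combined. The threshold sweep evaluates every distinct
observed ensemble-quality score, retains calls scoring ≥ t, and returns
the F-optimal threshold (ties resolve to the lowest, most inclusive
threshold).

## The synthetic cohort generator

The generator's defaults are the study conditions the stack is verified
under: 3 patients × 3 regions, 80× region coverage, 100 germline
variants, ~50 clonal somatic mutations per region arranged on a random
rooted clone tree (30 truncal, 10 per internal node, 8 per leaf), and
10⁴ artifacts per region.

* **Genome**: 2 synthetic chromosomes × 50 Mb with arm boundaries at the
  midpoint; 1500 × 250 bp targets per chromosome grouped into 10-target
  genes, a few of which carry cancer-gene names (TP53, GATA3, PIK3CA,
  ERBB2, FGFR1). Reference bases are a deterministic hash of position,
  so no sequence is stored. Each target is split into a variant zone
  (germline/somatic) and an artifact zone so truth classes can never
  collide; somatic sites are globally unique across patients so that
  the cross-patient recurrence filter never removes planted truth.
* **Germline**: drawn from a shared 1500-site population catalog (95%
  common with AF log-uniform on [10⁻², 0.5], 5% rare below the MAF
  cut), ~10% homozygous. The PoN contains 90% of the catalog plus a
  300-site recurrent-artifact pool from which 10% of each region's
  artifacts are drawn.
* **Somatic**: true VAF uniform on [0.25, 0.55] (clonal mutations at
  realistic purity), inherited along the clone tree; ~8% indels.
  Observed counts are binomial at the region depth — a variant whose
  sampled alt count is 0 is dropped by the callers (allelic dropout).
* **Artifacts**: substitution classes drawn from the mode's spectrum
  (C>T weight 0.53 in FFPE mode; C>A weight 0.52 in frozen mode), true
  VAF ~ Beta(1.5, 70) (≈ 93% of mass below 0.05), one-sided strand
  support with high Fisher strand bias, low read-position and high
  mismatch metrics, and low caller concordance (0.15 per caller vs 0.97
  for real variants).
* **Quality scores**: real calls ~ N(200, 40), artifacts ~ N(60, 30) —
  overlapping by design so the threshold sweep has a nontrivial optimum.
* **Copy number**: segments realize a configured event list (default:
  1p loss at log2 −0.5 over 80% of the arm with LOH at BAF 0.2, plus a
  120-target focal gain at log2 0.8 on chr2); bins are one per target at
  the segment log2 plus N(0, 0.3) noise; segment CI and biweight
  midvariance are computed from the bins, so neutral segments naturally
  fail the CI criterion while altered segments pass it.
* **Counts**: the per-region joint-extraction tables cover every
  germline/somatic site of the patient at 200× with absent sites drawn
  at the model's error rate (see the crossover analysis above).

One root seed drives everything through per-patient and per-region
substreams (`default_rng([seed, patient, region])`), so identical
(seed, config) produce byte-identical files and region outputs do not
depend on patient ordering.

### What the simulator does not model

Read-level effects (no FASTQ/BAM), library-preparation chemistry
(duplicate-rate differences between ligation strategies act upstream of
these inputs), germline VAF shifts inside LOH segments, subclonal
somatic mutations, position-level hotspots, and sequence-context
dependence of artifacts beyond the class spectrum. Passing tests
therefore demonstrate the correctness and discriminative behavior of the
post-processing rules under the stated generative model, not calling
accuracy on real FFPE data.

## Problem sizes used in tests

The default verification cohort is 3 patients × 3 regions with 10⁴
artifacts per region (seconds to simulate and filter); clone-tree
recovery streams seeded single-patient, 4-region cohorts at 200× counts
coverage and evaluates the first 50 whose presence matrix is
conflict-free, per the model analysis above. Oracle-equivalence checks
run 100 random instances of ≤ 50 elements per operation against
brute-force reimplementations.

## Known limitations

* Upstream steps (alignment, duplicate removal, the callers themselves,
  circular binary segmentation, functional annotation) are out of scope;
  their outputs are inputs here.
* Exact INFO/FORMAT keys vary across caller versions; the field map is
  configurable and the defaults follow VarDict/Mutect2 conventions.
* Population-filter rescue requires tier-1 + COSMIC/ClinVar flags to be
  present as annotations; no live database lookup is performed.
* The presence model evaluates regions independently given the candidate
  list; it does not share haplotype or copy-number information across
  regions as richer joint callers do.
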