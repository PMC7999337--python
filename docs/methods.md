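# Methods

## Coordinate and naming conventions

All internal coordinates are 0-based half-open; the VCF boundary
(1-based POS, 1-based inclusive END) is converted exactly once, in
`io.read_sv_vcf`. An explicit INFO `END` is authoritative for the
interval end; when END is absent the end is derived from |SVLEN| for
DEL/DUP/INV. Records whose caller emitted a padded END (end − start =
|SVLEN| + 1) keep that padded span — the overlap arithmetic downstream
never assumes the two agree. Chromosome dialects are reconciled by a
prefix policy (default: strip a leading `chr`), applied uniformly to
VCFs, cytoband files, catalogs and truth tables.

Caller FILTER values are retained verbatim and never applied at read
time. A record is "passing" when its filter set is empty (`.`) or
`{PASS}`; each analysis stage takes an explicit `pass_only` switch
(default on for panel scoring and hotspot burdens, matching the
filtered-callset analyses; off for counting and composition, which
describe the full candidate output). Sub-50 bp records — below the
conventional SV size floor — are kept and flagged (`is_sub50`) rather
than dropped, because candidate callsets contain them and counting
semantics must reflect that.

## Callset comparison

Two same-type interval calls match under reciprocal overlap:
|a∩b| ≥ F·|a| and |a∩b| ≥ F·|b|, default F = 0.70. A one-sided mode
(the fraction required of the A interval only) is available because
published descriptions of bedtools-based comparisons often leave `-r`
ambiguous; reciprocal is the default here. Insertions are point events,
so span overlap is undefined; they match by insertion-point proximity
(|pos_a − pos_b| ≤ 50 bp by default). "Shared" counts unique A-side
features with at least one qualifying B match — directional,
unique-feature semantics, so one A call matching three B calls counts
once; both directions are reported. The production matcher indexes the
B side with an interval tree; a quadratic all-pairs matcher exists only
in the test suite as the oracle, and the two are asserted equal on
random instances at n up to 500 and F ∈ {0.5, 0.7, 0.9}.

Translocations arrive as breakend (BND) record pairs linked by mutual
`MATEID` references. Pairing is permutation-invariant and idempotent;
BNDs whose mate is absent or non-reciprocal are kept in an explicit
`unpaired_bnds` list, never silently dropped. Intra-chromosomal mutual
pairs are assembled like any other adjacency but only inter-chromosomal
events count as translocations for the clinical panel. Two events match
when their unordered chromosome pairs agree and each corresponding
breakend lies within a window W (default 10 kb per breakend — a
deliberately generous tolerance, configurable, since breakend placement
differs between platforms far more than interval boundaries do);
correspondence is chosen to minimize the maximum displacement, which
only matters for same-chromosome pairs.

## Clinical panel and ROC evaluation

The ten-event panel is built from a cytoband-derived arm map: arm
losses del(1p), del(13q), del(14q), del(17p) (the 17p arm — the short
arm carries TP53, and the panel follows the clinically assayed event),
arm gain gain(1q), and the five IGH translocations pairing chromosome
14 with 4, 6, 11, 16, 20. An arm event is supported by any passing
DEL (loss) or DUP (gain) call overlapping the arm by ≥ 1 bp; no minimum
size is imposed by default (`min_sv_size = 0`) because support here is
evidence counting, not CNV segmentation — both choices are exposed.
Translocation events are matched at chromosome-pair granularity; an
optional per-event breakend-region restriction can narrow this to the
locus level.

Scores are supporting-call counts, which makes the prediction a graded
classifier: sweeping a threshold t (predict positive iff score ≥ t)
over the sample × event grid yields sensitivity TP/P and specificity
TN/N, the ROC curve, and the trapezoid AUC. With tied scores the
trapezoid over the unique-score sweep assigns half credit, so the AUC
equals the Mann–Whitney concordance probability
P(S₊ > S₋) + ½P(S₊ = S₋); the test suite asserts this identity to
1e-12 against exhaustive pair enumeration, and cross-checks one
instance against scikit-learn. Confidence intervals are percentile
bootstrap over (sample, event) cells (default 2000 resamples;
degenerate resamples with no positives or no negatives are redrawn).
The bootstrap's coverage is itself checked by simulation in the test
suite (~95% nominal, Gaussian score model with known AUC).

P and N are defined over the full explicit grid — every (sample, event)
cell is labeled 0 or 1, and truth tables must be complete; there is no
implicit enumeration of negatives.

## Hotspot burdens

A call hits a hotspot when at least one of its breakpoints — the two
endpoints of an interval call, or either breakend of an adjacency —
lies inside the catalog region ("breakpoint containment"). This is the
default geometry because arm-scale SVs would otherwise blanket every
hotspot they span; a whole-interval-overlap mode is selectable. Each
hotspot counts once per sample regardless of supporting-call
multiplicity; supporting record ids are kept for reporting. Category
consistency (e.g., only DEL supporting a loss hotspot) is off by
default. Cohort summaries use the standard median (midpoint of the
middle pair for even cohorts). The catalog reader accepts any TSV of
(chrom, start, end, id, category ∈ {gain, loss, fragile}); the
published 68-region myeloma catalog is not redistributable here, so the
synthetic module provides `synthetic_hotspot_catalog`, a stand-in with
the same 49 gain / 19 loss category split, clearly labelled synthetic.

## Short-variant cascade

The somatic filter cascade applies eight rules: caller filters must
pass; intronic/intergenic variants drop; synonymous/non-frameshift
variants drop; any of three population allele frequencies above 1%
drops; QUAL below 40 drops; depth below 10 drops; VAF outside
[0.02, 0.30] drops; strand-odds-ratio above 3 (SNV) or 11 (indel)
drops. The kept set is the conjunction of all rules and is therefore
order-invariant (asserted under rule permutations); the removal trace
attributes each removed variant to its first failing rule in the
declared order, and kept + Σ removed = input always. Absent population
AFs are treated as 0 (novel variant, kept by that rule). Overlap
between datasets uses exact keyed identity on (chrom, pos, ref, alt)
after minimal-representation normalization (shared suffix then prefix
trimming) — reciprocal span overlap is ill-defined for substitutions.
The driver matrix marks presence/absence of kept variants in BRAF,
KRAS, NRAS, TP53 and FAM46C per (sample, dataset).

## Synthetic cohort model

The generator's purpose is statistical, not biological: it reproduces
the aggregate signatures the analysis stages consume, so every stage
can be validated end to end with no external data.

- **Genome model**: the arm map itself. Background calls are placed
  uniformly within arms, arm-weighted by length. The bundled
  `synthetic_arm_map` tapers 22 chromosomes from 240 Mb to 45 Mb with
  the centromere at 40% — human-karyotype scale without a reference
  FASTA, since coordinates alone drive every computation.
- **Type composition**: WES-like DEL 0.563 / INS 0.326 / BND 0.067 /
  DUP 0.033 / INV 0.012 (the published shares sum to 100.1%; they are
  renormalized with a warning); linked-read-like INV 0.924 with the
  non-INV residual split DUP-heavy (DUP 0.066 / DEL 0.003 / BND 0.003)
  and INS exactly 0. A translocation adjacency counts as one call and
  is emitted as a mutually MATEID-paired BND row pair.
- **Scale**: expected background calls per sample default to 4065
  (WES-like) and 18455 (linked-read-like), the platforms' mean
  candidate counts.
- **Quality thinning**: each background call is PASS with probability
  `pass_rate` (defaults 0.024 and 0.016 — the ratios of the platforms'
  filtered to candidate callset sizes); the rest carry a quality-fail
  filter and are retained, so pass-only stages see realistically thin
  callsets while counting stages see the full candidate volume.
- **Sizes**: log-normal per type (median 5 kb for DEL/DUP/INV, 100 bp
  for INS; σ = 1.0 and 0.8 on the log scale) — a generic heavy-tailed
  spectrum, since no per-platform size distributions are available. A
  `sub50_fraction` (default 5%) of calls draw uniform sizes of 1-49 bp
  to exercise the sub-50 flag.
- **Truth planting**: per (sample, event) Bernoulli with prevalence
  0.175 by default, giving an expected 14 positives on an 8 × 10 grid —
  the positive density of a small clinical cohort. Each planted event
  emits one supporting PASS call with probability s (the per-method
  detection sensitivity), placed inside the event's arm or joining its
  chromosome pair.

What passing tests show: the matchers, counters and estimators are
correct on data whose distributional structure (type mixture, placement,
quality thinning, planted signal) is fully known, and the pipeline
recovers planted sensitivities within binomial error while ranking a
0.9-sensitivity platform above a 0.5-sensitivity one by AUC in ≥95% of
replicates. What they do not show: robustness to real-data pathologies —
breakpoint imprecision correlated between callers, segmental-duplication
artifacts, clustered false positives, reference-dialect edge cases
beyond the chr-prefix, or any sequence-level effect. The parameter-
recovery experiments deliberately use a noise-free profile (no
background calls) so that detection of each planted event is exactly
Bernoulli(s) and the binomial interval check is exact; with background
noise enabled the sensitivity estimator is upward-biased by chance
overlaps, which is a property of the estimator, not a bug.

## Problem sizes and determinism

The validation suite runs the matcher oracle at n ≤ 500 over 100 random
instances, the AUC identity over 1000 vectors at n ≤ 50, composition
recovery at 10,000 calls, and 100 AUC-ordering replicates on 8 × 10
grids — sizes chosen to give the statistical assertions comfortable
power while keeping the full suite in the tens of seconds.
`scripts/acceptance.py` regenerates an 8-sample cohort at the
platforms' full per-sample call counts through the on-disk VCF layer.
Every random draw in the package flows through a `numpy` Generator
seeded from explicit arguments; the same seed reproduces callsets,
VCF bytes, bootstrap intervals and the acceptance JSON exactly.

## Known limitations

- Genotype fields beyond FILTER are ignored; somatic tumor-normal VCF
  semantics are out of scope.
- No multi-way (>2) merging; concordance is strictly pairwise.
- Insertion matching ignores inserted sequence; two nearby insertions
  of different content will match.
- The GRCh37→GRCh38 conversion of external catalogs is not performed;
  catalogs must be supplied in the working assembly.
- Hyperdiploidy/trisomy calling and CNV segmentation are intentionally
  absent; the panel covers the ten routinely assayed events only.
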