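# Methods

`sncaging` analyses sperm small non-coding RNA (sncRNA) profiles across
age and ships a synthetic-cohort generator whose statistical structure
matches what the analysis assumes, so every stage can be validated
against exact truth tables without any sequencing download.

## Annotation model

Reads (15–50 nt gel-window inserts, adapters already removed) are
collapsed to unique sequences and placed on a reference panel of parent
transcripts: cytosolic rRNAs, mitochondrial rRNAs, mature tRNAs
(spliced, CCA-terminated — fragments are only called tsRNAs when they
derive from the mature form), and miRNAs. Every placement with at most
one substitution on the sense strand is enumerated by a vectorized scan
over all offsets; this is definitionally the naive all-placements scan,
and the unit tests hold it to a pure-Python oracle.

Class assignment resolves ambiguity in two steps: placements at the
read's minimum achieved mismatch count are retained (a perfect match
anywhere pre-empts 1-mismatch placements everywhere), then the highest-
precedence class wins (miRNA > tRNA > rRNA > mt-tRNA > mt-rRNA; the
order is configurable). Within the winning class the read's count is
divided equally among its retained placements, so fractional counts
appear in the (class, parent, start, length) tensor while class totals
stay integral and counts are conserved exactly:
`unannotated + Σ class totals = total reads`.

Expression is reported as RPM per **total clean reads** (a switch allows
per-annotated-reads). Coverage tracks add a read's RPM to every parent
position it spans; group curves report mean ± SEM (SD/√n, 0 for n = 1).

## Aging index and length-shift test

For a samples × lengths RPM profile, the aging index `I_a(L)` is the
Spearman rank correlation between length `L`'s RPM and sample age.
Lengths with zero RPM in all samples are excluded (and listed); lengths
with constant nonzero RPM get an undefined (NaN) entry. The length-shift
statistic is Spearman's ρ between the `I_a` curve and `L`, with a
two-sided P; an OLS line is attached for display only. Because both
layers are rank-based, the statistics are invariant to strictly
increasing transformations of expression and of age — mouse weeks and
human years are interchangeable.

Spearman p-values use the asymptotic t approximation for n > 8 and full
permutation enumeration for n ≤ 8; ties get average ranks. Boxplot
summaries use linear-interpolation quartiles with whiskers at the most
extreme points inside Q1 − 1.5·IQR and Q3 + 1.5·IQR.

## Aging-cliff ordination

Samples are compared by Clark divergence,
`d_jk = sqrt((1/NZ) Σ_i ((x_ij − x_ik)/(x_ij + x_ik))²)` over the NZ
features with `x_ij + x_ik > 0` (double-zero features excluded); the
ratio form weights rare and dominant families equally, and its
per-feature terms saturate for extreme ratios. PCoA is classical metric
scaling: Gower double-centering of −½D², eigendecomposition, coordinates
scaled by √eigenvalue; negative eigenvalues are reported, not corrected
(no Cailliez/Lingoes); axis signs make the largest-magnitude loading
positive.

The cliff scan evaluates every contiguous early/late split of the
age-ordered groups by the one-way ANOVA F statistic of the Axis-1 scores
and returns the split maximizing F. Because the split is selected by
maximization, reported p-values carry a Bonferroni factor for the number
of candidate splits; the correction is conservative under the positive
dependence among splits. Which scores feed the F test is an open
analysis choice; Axis 1 is the default and a config key (`axis`) exposes
it.

## Co-expression and mitochondrial enrichment

Families are correlated pairwise by Spearman across samples
(zero-variance families excluded). The correlation-matrix **rows** are
clustered by complete linkage on Euclidean distances — the convention of
standard heatmap tooling — and cut into `k` clusters (default 5 for the
default 20-family panel, which resolves the expected structure:
up-shifted block, down-shifted block, weak responders, and the
mitochondrial block). The "center square" of a clustered heatmap is
formalized as the cluster with the highest mean intra-cluster
correlation among clusters with ≥ 3 members: a visually coherent block
is a group, not an incidental tight pair. That block is tested for
enrichment of mitochondria-derived families with a two-sided Fisher
exact test (hypergeometric enumeration); all clusters are also tested
with Bonferroni correction and reported.

## Synthetic cohort generator

The generator is first-class, tested code. It emulates:

* **Designs** — `mouse_5group`: ages 10/30/50/70/90 weeks, n = 4 per
  group; `human_longitudinal`: 8 donors × 2 samples, 6–23 years apart,
  ages 34–68; `human_crosssection`: 47 singleton donors aged 25–51.
  Default depth 200,000 reads/sample (a desk-scale stand-in for
  production sequencing depth; all statistics are rank- or
  proportion-based, so depth enters only through counting noise).
* **Composition** — class masses 73.7% genomic rsRNA, 26.0% tsRNA,
  0.14% mt-tsRNA, 0.11% mt-rsRNA, 0.05% miRNA; within a class,
  abundance decays geometrically in panel order (ratio 0.5, or 0.75 for
  the 12 tRNA isoacceptors, whose abundances are less skewed than rRNA
  parent contributions).
* **Fragment geometry** — per parent, fragments start at fixed cleavage
  hotspots (three start-anchored windows on rRNAs; a 5′ window and a
  CCA-3′-anchored window on tRNAs) with class-specific length mixtures:
  rsRNA lengths 15–46 nt with modes near 17 and 43 nt, tsRNA lengths
  18–40 nt with a mode near 34 nt, miRNA reads equal to the mature
  sequence. Reads are error-free exact substrings, so truth
  (parent, start, length) is exact; mismatch handling is tested with
  explicitly mutated fixtures instead of stochastic error.
* **Aging cliff** — a step in log-abundance at cutoff age 60 (between
  the 50- and 70-week groups). Genomic ts/rs families step with
  alternating sign and heterogeneous magnitude, 0.3–1.0 × ln 4 scaled
  so magnitude *rises as abundance falls* (a dominant family cannot
  multiply four-fold without rewriting the composition, and no two
  families in a class respond identically — a uniform coherent step
  would make responding families implausibly perfectly co-expressed).
  Deltas are centered so total shifted mass is conserved: the cliff is a
  compositional rearrangement, and unshifted miRNAs see no
  normalization step. Mitochondrial families step coordinately
  (one shared +0.5 ln 4 step), mirroring their coordinated age
  behaviour. Human scenarios have no cliff.
* **Length tilt** — rsRNA length pmfs are exponentially tilted,
  `w(L) ∝ base(L)·exp(β (age − age_ref)(L − 30))`, β = 0.004 per
  (age-unit·nt); β = 0 recovers the base distribution exactly. tsRNAs
  and miRNAs are untilted, matching the head-specific rsRNA phenomenon.
* **Noise** — per sample × family log-normal noise (σ = 0.25, mean-one);
  per sample × bin cleavage noise (σ = 0.15, mean-one) representing
  between-animal variation in cleavage-site efficiency — without it,
  length bins within a family would share all biological noise and the
  trend test would run conservative; a shared log-normal latent factor
  (σ = 1.4) multiplying all mitochondrial families, which
  makes the mt block "highly positively correlated" relative to the
  cliff-coupled genomic blocks; and multinomial counting noise at the
  design depth.

What the generator does **not** emulate: sequencing error and ligation
bias, RNA modifications and the enzymatic pretreatments that expose
them, isomiR or precursor-tRNA structure, genome-wide multi-mapping
(panel parents are the universe), or realistic per-family abundance
catalogs. A test that passes here therefore demonstrates that the
statistics recover the modeled signal under realistic noise geometry —
not that any particular biological dataset will show the signal.

## Calibration of defaults

Within-group variance is not identified by published summary statistics,
so the noise scales above are package defaults, exposed in `RunConfig`.
At those defaults (fresh seeds, 100–800 replicates per check): the
length-shift test rejects in 100% of tilted mouse cohorts
(median ρ ≈ 0.998) and in ≈ 5% of null cohorts at α = 0.05; the cliff
scan selects the {10,30,50} | {70,90} split in 100% of runs, the
ts/rs-RNA stage F exceeds the miRNA stage F in 100% of runs; and the top
co-expression block is mitochondria-enriched at Fisher P < 0.01 in ≈ 98%
of runs. `scripts/acceptance.py` recomputes all of these from scratch.

## Numerical choices

* PCoA eigenvalue threshold: |λ| > 10⁻⁹ × max|λ|; smaller magnitudes are
  treated as zero.
* Zero within-group variance in the F test reports F = ∞ with P = 0;
  identical constant groups report F = 0, P = 1.
* Spearman with a zero-variance argument is undefined (NaN), never an
  exception; downstream code treats NaN as "missing".
* Fisher's odds ratio is the sample ratio a·d/(b·c); zero cells give ∞
  (or NaN for 0/0); degenerate margins give P = 1 with a flag.
* Clustering ties break deterministically by processing families in
  lexicographic order.
* All randomness flows from one root seed per run (panel construction
  and cohort draw); re-running an identical config is byte-identical.

## Known limitations

* The annotator is a documented lightweight analogue of hierarchical
  sncRNA annotation pipelines, not a re-implementation of any specific
  tool; multi-locus handling (equal split at minimum mismatch) is a
  stated convention.
* Family = parent transcript in the generator; real family catalogs are
  finer-grained. The co-expression machinery takes any family list as
  input.
* The longitudinal human design is analyzed as pooled samples by
  default; a donor-stratified variant is out of scope here.
* Clark divergence is undefined for sample pairs with no shared nonzero
  feature; such pairs abort with a clear message rather than being
  imputed.
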