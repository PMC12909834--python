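# sncaging

Analysis toolkit for **sperm small non-coding RNA (sncRNA) aging
signatures**: hierarchical annotation of tRNA-derived and rRNA-derived
small RNAs (tsRNAs/rsRNAs), a per-length *aging index*, detection of an
abrupt *aging cliff* in composition space, and mitochondrial
co-expression enrichment — together with a synthetic cohort generator
that emulates the study conditions so the whole pipeline can be
validated against exact truth tables.

It is written for computational biologists working with small-RNA
sequencing of sperm (or other gel-selected 15–50 nt fractions) who want
these aging statistics as reusable, tested components rather than
one-off notebook code.

## The statistics

**Aging index.** For each fragment length `L`, the aging index is the
Spearman rank correlation between that length's expression (RPM) and
sample age:

&nbsp;&nbsp;&nbsp;&nbsp;`I_a(L) = ρ( RPM(·, L), age )`

The **length-shift statistic** is Spearman's ρ between the `I_a` curve
and `L` itself, with a two-sided P value: ρ > 0 means longer fragments
gain expression with age while shorter ones lose it. Both layers are
rank-based, so weeks and years, raw and re-scaled RPM, all give the
same answer.

**Aging cliff.** Samples are compared by Clark divergence,

&nbsp;&nbsp;&nbsp;&nbsp;`d_jk = sqrt( (1/NZ) Σ_i ((x_ij − x_ik)/(x_ij + x_ik))² )`

(double-zero features excluded), embedded by principal coordinate
analysis, and every contiguous early/late split of the age-ordered
groups is scored by the one-way ANOVA F statistic (between- over
within-group variance) of the Axis-1 scores. The winning split with
Bonferroni-adjusted P localizes the cliff.

**Mitochondrial block.** Family × family Spearman correlations are
clustered (complete linkage, Euclidean distance on correlation rows);
the block with the highest mean intra-cluster correlation is tested for
enrichment of mitochondria-derived families by a two-sided Fisher exact
test.

See `docs/methods.md` for the annotation model, the generator, and all
numerical conventions.

## Worked example

```python
from sncaging.config import RunConfig
from sncaging.pipeline import run_pipeline

cfg = RunConfig(seed=1, depth=50_000, outdir="sncaging_run")
r = run_pipeline(cfg)
print("cliff split:", tuple(r.cliff.early_ages), "|", tuple(r.cliff.late_ages))
print(f"cliff F = {r.cliff.F:.2f}, adjusted P = {r.cliff.p_adjusted:.3g}")
print(f"stage F  ts/rsRNA = {r.tsrs_f[0]:.1f}  vs  miRNA = {r.mirna_f[0]:.2f}")
print(f"length shift: rho = {r.shift.rho:.3f}, P = {r.shift.pvalue:.3g} "
      f"over {r.shift.n_lengths} lengths")
```

prints

```
cliff split: (10.0, 30.0, 50.0) | (70.0, 90.0)
cliff F = 212.85, adjusted P = 8.2e-11
stage F  ts/rsRNA = 212.9  vs  miRNA = 0.27
length shift: rho = 0.998, P = 3.73e-36 over 32 lengths
```

Reading: a simulated five-group mouse cohort (10–90 weeks, n = 4/group,
50k reads/sample) was annotated read-by-read and analyzed. The cliff
scan demarcates the early (10–50 wk) from the late (70–90 wk) samples
with a between/within variance ratio of ≈213 on the ts/rsRNA profile —
three orders of magnitude above the miRNA profile, which carries no
cliff in this cohort. The aging-index curve rises with fragment length
(ρ ≈ 1): longer rsRNAs gain and shorter rsRNAs lose expression with
age, exactly the signal the generator planted. `sncaging_run/` then
holds the TSV tables (`aging_index.tsv`, `cliff_scan.tsv`,
`enrichment.tsv`, …), figures, and a Markdown report.

The same is available from the shell:

```bash
sncaging all --seed 1 --outdir sncaging_run
sncaging simulate --scenario human_crosssection --seed 7 --outdir sim/
sncaging annotate --panel sim/panel.fasta --reads sim/S001.fasta --outdir ann/
sncaging cocktail
```

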