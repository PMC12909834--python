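"""End-to-end pipeline: simulate -> annotate -> aging index -> cliff ->
co-expression -> report.

The pipeline is deterministic given its :class:`~sncaging.config.RunConfig`
(one root seed drives the panel, the cohort draw, and nothing else is
random); re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aging import (AgingIndexCurve, LengthShiftResult, aging_index,
                    group_boxplot_stats, length_shift_test)
from .annotate import annotate_cohort, class_summary, family_matrix, \
    length_profile, species_matrix
from .cocktail import COCKTAILS, OLIGO_STRINGS, cocktail_proportions, \
    oligo_length
from .coexpression import cluster_families, enrich_all_clusters, \
    pairwise_spearman, top_cluster
from .config import RunConfig
from .ordination import CliffStat, PCoAResult, clark_divergence, pcoa, \
    scan_cliff, stage_f
from .reference import build_reference_panel
from .simulate import CohortDesign, SimulatedCohort, default_model, \
    simulate_cohort

logger = logging.getLogger(__name__)

TSRS_CLASSES = ("rRNA", "tRNA", "mt_rRNA", "mt_tRNA")
KEY_LENGTHS = (16, 17, 43, 44)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    cohort: SimulatedCohort
    feature_matrix: pd.DataFrame
    curve: AgingIndexCurve
    shift: LengthShiftResult
    pcoa_result: PCoAResult
    cliff: CliffStat
    mirna_f: tuple[float, float]
    tsrs_f: tuple[float, float]
    correlation: pd.DataFrame
    enrichment: pd.DataFrame
    top_cluster: int
    outdir: Path | None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute all stages in order and (optionally) write the report
    bundle under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir) if write else None
    if outdir is not None:
        (outdir / "figures").mkdir(parents=True, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    design = CohortDesign.preset(config.scenario, config.seed, config.depth)
    panel = _stage("simulate")(build_reference_panel)(config.seed)
    model = default_model(panel, config.scenario, beta=config.beta,
                          cliff_scale=config.cliff_scale,
                          cliff_cutoff=config.cliff_cutoff,
                          mt_factor_sd=config.mt_factor_sd,
                          noise_sd=config.noise_sd,
                          bin_noise_sd=config.bin_noise_sd)
    cohort = _stage("simulate")(simulate_cohort)(
        design, model, panel, materialize_reads=config.use_annotator)
    ages = cohort.ages()

    # -- annotate ----------------------------------------------------------
    if config.use_annotator:
        annotated = _stage("annotate")(annotate_cohort)(
            cohort.reads, panel, design.depth, max_mm=config.max_mismatch)
        fam = family_matrix(annotated, classes=TSRS_CLASSES)
        spc = species_matrix(annotated, classes=TSRS_CLASSES)
        mirna = family_matrix(annotated, classes=("miRNA",))
        rs_len = length_profile(annotated, classes=("rRNA",))
        summary = class_summary(annotated)
    else:
        fam = cohort.family_rpm(classes=TSRS_CLASSES)
        spc = cohort.species_rpm(classes=TSRS_CLASSES)
        mirna = cohort.family_rpm(classes=("miRNA",))
        rs_len = cohort.length_rpm(classes=("rRNA",))
        summary = None
    features = fam if config.granularity == "family" else spc

    # -- aging index & length shift ---------------------------------------
    curve = _stage("aging-index")(aging_index)(rs_len, ages)
    shift = _stage("aging-index")(length_shift_test)(curve)
    groups = cohort.sample_sheet["group"]
    boxes = {
        L: group_boxplot_stats(
            {g: rs_len.loc[groups.index[groups == g], L].tolist()
             for g in groups.unique()})
        for L in KEY_LENGTHS if L in rs_len.columns
    }

    # -- ordination / cliff ------------------------------------------------
    D = _stage("cliff")(clark_divergence)(features)
    pc = _stage("cliff")(pcoa)(D)
    axis = pc.axis(config.axis)
    cliff = _stage("cliff")(scan_cliff)(axis, ages)
    stage_labels = pd.Series(
        np.where(ages.isin(cliff.early_ages), "early", "late"),
        index=ages.index)
    tsrs_f = stage_f(axis, stage_labels)
    mir_axis = pcoa(clark_divergence(mirna)).axis(1)
    mirna_f = stage_f(mir_axis, stage_labels)

    # -- co-expression -----------------------------------------------------
    C = _stage("coexpr")(pairwise_spearman)(fam)
    assignment = _stage("coexpr")(cluster_families)(C, config.k_clusters)
    enr = enrich_all_clusters(assignment, pd.Series(panel.origins()))
    best_cl = top_cluster(C, assignment)

    result = PipelineResult(cohort, features, curve, shift, pc, cliff,
                            mirna_f, tsrs_f, C, enr, best_cl, outdir)
    if outdir is not None:
        _write_bundle(config, result, summary, boxes, assignment, fam)
    return result


# --------------------------------------------------------------------------
# output bundle


def _write_bundle(config, result, summary, boxes, assignment, fam) -> None:
    out = result.outdir
    cohort = result.cohort
    cohort.sample_sheet.to_csv(out / "samples.tsv", sep="\t")
    cohort.panel.to_fasta(str(out / "panel.fasta"))
    if summary is not None:
        summary.to_csv(out / "annotation_summary.tsv", sep="\t")
    result.feature_matrix.to_csv(out / "feature_matrix.tsv", sep="\t")

    curve, shift = result.curve, result.shift
    ia_rows = pd.DataFrame({
        "length": curve.lengths, "I_a": curve.values,
        "n": curve.n, "excluded": False,
    })
    if curve.excluded:
        ia_rows = pd.concat([ia_rows, pd.DataFrame({
            "length": curve.excluded, "I_a": np.nan, "n": curve.n,
            "excluded": True})], ignore_index=True)
    ia_rows.sort_values("length").to_csv(out / "aging_index.tsv", sep="\t",
                                         index=False)
    pd.DataFrame([{
        "feature_set": "rsRNA", "rho": shift.rho, "p": shift.pvalue,
        "slope": shift.slope, "intercept": shift.intercept,
        "n_lengths": shift.n_lengths,
    }]).to_csv(out / "length_shift.tsv", sep="\t", index=False)

    pc, cliff = result.pcoa_result, result.cliff
    pd.DataFrame(result.correlation).to_csv(out / "correlation_matrix.tsv",
                                            sep="\t")
    assignment.labels.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
    result.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    clark_D = clark_divergence(result.feature_matrix)
    clark_D.to_csv(out / "dissimilarity.tsv", sep="\t")
    pc.coordinates.to_csv(out / "pcoa_coords.tsv", sep="\t")
    pd.DataFrame({"eigenvalue": pc.eigenvalues}).to_csv(
        out / "pcoa_eigen.tsv", sep="\t", index=False)
    cliff.candidates.to_csv(out / "cliff_scan.tsv", sep="\t", index=False)

    rows = []
    for name, spec in COCKTAILS.items():
        cs = cocktail_proportions(spec)
        for comp, nm in cs.concentrations_nm.items():
            rows.append({"cocktail": name, "component": comp,
                         "length_nt": oligo_length(OLIGO_STRINGS[comp]),
                         "nM": nm, "percent": cs.proportions_pct[comp],
                         "total_nM": cs.total_nm})
    pd.DataFrame(rows).to_csv(out / "cocktails.tsv", sep="\t", index=False)

    box_rows = []
    for L, per_group in boxes.items():
        for g, b in per_group.items():
            box_rows.append({"length": L, "group": g, "median": b.median,
                             "q1": b.q1, "q3": b.q3,
                             "lower_whisker": b.lower_whisker,
                             "upper_whisker": b.upper_whisker,
                             "n_outliers": len(b.outliers)})
    pd.DataFrame(box_rows).to_csv(out / "length_boxplots.tsv", sep="\t",
                                  index=False)

    if config.figures:
        from . import plots
        ages = cohort.ages()
        plots.aging_index_scatter(curve, shift, out / "figures" / "aging_index",
                                  title="rsRNA")
        plots.pcoa_scatter(pc, ages, out / "figures" / "pcoa",
                           title="ts/rsRNA PCoA (Clark)")
        plots.coexpression_heatmap(result.correlation, assignment.leaf_order,
                                   pd.Series(cohort.panel.origins()),
                                   out / "figures" / "coexpression")

    log = {
        "sncaging_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "model_hash": cohort.provenance.get("config_hash"),
        "config": config.to_dict(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    config.to_yaml(out / "config.yaml")
    _write_report(out, config, result)


def _write_report(out: Path, config, result) -> None:
    cliff, shift = result.cliff, result.shift
    enr = result.enrichment
    top = enr.loc[result.top_cluster]
    lines = [
        "# sncaging run report", "",
        f"- scenario: `{config.scenario}`, seed {config.seed}, "
        f"depth {config.depth}, {len(result.cohort.sample_ids)} samples",
        f"- config hash `{config.config_hash()}`", "",
        "## Aging cliff (Clark divergence -> PCoA -> stage F)", "",
        f"- winning split: {cliff.early_ages} | {cliff.late_ages} "
        f"(F = {cliff.F:.2f}, adjusted P = {cliff.p_adjusted:.3g})",
        f"- stage F on Axis {config.axis}: ts/rsRNA {result.tsrs_f[0]:.2f} "
        f"vs miRNA {result.mirna_f[0]:.2f}", "",
        "## rsRNA length shift", "",
        f"- length-shift Spearman rho = {shift.rho:.3f} "
        f"(P = {shift.pvalue:.3g}) over {shift.n_lengths} lengths",
        f"- OLS display line: I_a = {shift.slope:.4f} x L "
        f"{shift.intercept:+.3f}", "",
        "## Mitochondrial co-expression", "",
        f"- top cluster {result.top_cluster}: {int(top['n_mt_in'])} of "
        f"{int(top['n_families'])} members mitochondrial "
        f"(Fisher P = {top['p']:.3g}, adjusted {top['p_adj']:.3g})", "",
        "See the TSV tables and `figures/` alongside this file.",
    ]
    (out / "report.md").write_text("\n".join(lines) + "\n")
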