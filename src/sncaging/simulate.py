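"""Synthetic sperm small-RNA cohorts with known truth.

The generator emulates the statistical structure of an aging sperm-head
sncRNA sequencing experiment without requiring any real data:

* age-graded samples (a five-group mouse design at 20-week intervals, a
  paired longitudinal human design, or a cross-sectional human design);
* a fragment pool dominated by genomic rRNA-derived fragments (rsRNAs,
  ~73.7%) and tRNA-derived fragments (tsRNAs, ~26.0%) with trace
  mitochondrial tsRNAs (~0.14%) and rsRNAs (~0.11%) and a sliver of
  miRNAs;
* an optional abrupt "aging cliff": a step in log-abundance of ts/rsRNA
  families for samples past a cutoff age (between the 50- and 70-week
  groups in the mouse preset);
* an optional age-monotone exponential tilt of the rsRNA fragment-length
  distribution (longer fragments gain weight with age, shorter ones lose
  it);
* a shared log-normal latent factor across mitochondrial families, so
  their abundances co-fluctuate as one correlated block.

Reads are emitted error-free as exact substrings of panel parents, so the
recorded truth (parent, start, length) is exact and annotation round-trips
can be checked bit-for-bit. Sequencing noise enters only through the
multinomial draw at finite depth; biological sample-to-sample variation
enters as i.i.d. log-normal perturbations of family abundances.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import ReferencePanel, build_reference_panel

SCENARIOS = ("mouse_5group", "human_longitudinal", "human_crosssection")

#: sperm-head class composition used as the generator default
DEFAULT_CLASS_PROPS = {
    "rRNA": 0.737,
    "tRNA": 0.260,
    "mt_tRNA": 0.0014,
    "mt_rRNA": 0.0011,
    "miRNA": 0.0005,
}

DEFAULT_DEPTH = 200_000


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# cohort designs


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of a cohort: who is sequenced, at what age and depth.

    ``ages`` holds one age per *sample* (already expanded by ``n_per_age``
    replicates when constructed through :meth:`preset`). ``donors`` links
    paired samples in the longitudinal scenario.
    """

    ages: tuple[float, ...]
    n_per_age: int
    depth: int
    seed: int
    scenario: str
    donors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        if not self.ages or any(a <= 0 for a in self.ages):
            raise SimulationError("ages must be non-empty and strictly positive")
        if self.n_per_age < 1:
            raise SimulationError("n_per_age must be >= 1")
        if self.depth < 1000:
            raise SimulationError("depth must be >= 1000")
        if self.donors is not None and len(self.donors) != len(self.ages):
            raise SimulationError("donors must align with ages")

    @property
    def sample_ages(self) -> np.ndarray:
        """Ages expanded to one entry per sample."""
        return np.repeat(np.asarray(self.ages, dtype=float), self.n_per_age)

    @property
    def n_samples(self) -> int:
        return len(self.ages) * self.n_per_age

    @property
    def age_unit(self) -> str:
        return "week" if self.scenario == "mouse_5group" else "year"

    @classmethod
    def preset(cls, scenario: str, seed: int = 0,
               depth: int = DEFAULT_DEPTH) -> "CohortDesign":
        """Cohort shapes matching the three study designs.

        * ``mouse_5group``: 10/30/50/70/90 weeks, 4 animals per group.
        * ``human_longitudinal``: 8 donors, two samples each, 6-23 years
          apart, ages 34-68 (ages drawn from ``seed``).
        * ``human_crosssection``: 47 singleton donors aged 25-51.
        """
        if scenario == "mouse_5group":
            return cls((10.0, 30.0, 50.0, 70.0, 90.0), 4, depth, seed, scenario)
        rng = np.random.default_rng(seed + 1_000_003)
        if scenario == "human_longitudinal":
            ages: list[float] = []
            donors: list[str] = []
            for d in range(8):
                first = float(rng.integers(34, 46))
                gap = float(rng.integers(6, 24))
                ages.extend([first, min(first + gap, 68.0)])
                donors.extend([f"D{d + 1}", f"D{d + 1}"])
            return cls(tuple(ages), 1, depth, seed, scenario, tuple(donors))
        if scenario == "human_crosssection":
            ages = sorted(float(a) for a in rng.integers(25, 52, size=47))
            return cls(tuple(ages), 1, depth, seed, scenario)
        raise SimulationError(f"unknown scenario {scenario!r}")


# --------------------------------------------------------------------------
# fragment model


@dataclass(frozen=True)
class Window:
    """Cleavage hotspot on a parent: a fixed fragment start, or a fixed
    fragment end at the parent 3' terminus (anchor='end', e.g. CCA-ending
    tRNA fragments)."""

    anchor: str  # 'start' | 'end'
    pos: int = 1  # 1-based fragment start when anchor == 'start'

    def __post_init__(self) -> None:
        if self.anchor not in ("start", "end"):
            raise SimulationError(f"bad window anchor {self.anchor!r}")
        if self.anchor == "start" and self.pos < 1:
            raise SimulationError("window start must be >= 1")


@dataclass
class FragmentModel:
    """Generative model for per-sample fragment proportions.

    Parameters
    ----------
    base_family_props:
        Family (= parent id) -> expected proportion of reads; sums to 1.
    cliff_delta:
        Family -> natural-log fold change applied when sample age exceeds
        ``cliff_cutoff`` (0 = no cliff for that family).
    cliff_cutoff:
        Age past which the cliff step applies.
    length_tilt_beta:
        Exponential-tilt slope coupling age to fragment length, in units
        of 1 / (age unit x nt): the length pmf of tilted families is
        reweighted by ``exp(beta * (age - age_ref) * (L - l_mid))``.
    mt_factor_sd:
        SD of the latent log-normal factor shared by all mitochondrial
        families (their co-expression block).
    noise_sd:
        SD of i.i.d. log-normal biological noise per sample x family.
    bin_noise_sd:
        SD of i.i.d. log-normal noise per sample x (window, length) bin:
        between-animal variation in cleavage efficiency at individual
        sites, which decorrelates length bins within a family.
    cleavage_windows / length_dists / tilt_families:
        Per-family fragmentation geometry: hotspot windows, the base
        length pmf, and which families feel the age tilt (rsRNAs do,
        tsRNAs and miRNAs do not, matching the observed phenomenon).
    """

    base_family_props: dict[str, float]
    cliff_delta: dict[str, float]
    cleavage_windows: dict[str, list[Window]]
    length_dists: dict[str, dict[int, float]]
    tilt_families: frozenset[str]
    cliff_cutoff: float = 60.0
    length_tilt_beta: float = 0.004
    length_support: tuple[int, int] = (15, 50)
    mt_factor_sd: float = 1.4
    noise_sd: float = 0.25
    bin_noise_sd: float = 0.15
    age_ref: float | None = None
    l_mid: float = 30.0

    def __post_init__(self) -> None:
        total = sum(self.base_family_props.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise SimulationError(f"base family proportions sum to {total}, not 1")
        lo, hi = self.length_support
        if lo < 15 or hi > 50 or lo > hi:
            raise SimulationError("length support must lie within [15, 50]")
        for fam in self.base_family_props:
            if fam not in self.cleavage_windows or fam not in self.length_dists:
                raise SimulationError(f"family {fam!r} lacks windows or lengths")
            if not self.length_dists[fam]:
                raise SimulationError(f"family {fam!r} has empty length support")
            for L in self.length_dists[fam]:
                if not lo <= L <= hi:
                    raise SimulationError(
                        f"family {fam!r} length {L} outside support {lo}-{hi}")

    @property
    def families(self) -> list[str]:
        return list(self.base_family_props)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "props": self.base_family_props,
                "cliff": self.cliff_delta,
                "cutoff": self.cliff_cutoff,
                "beta": self.length_tilt_beta,
                "mt_sd": self.mt_factor_sd,
                "noise_sd": self.noise_sd,
                "bin_noise_sd": self.bin_noise_sd,
                "tilt": sorted(self.tilt_families),
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _discrete_mixture(support: range, peaks: Sequence[tuple[float, float, float]],
                      uniform_weight: float) -> dict[int, float]:
    """Mixture of discretized Gaussians plus a uniform floor over support."""
    ls = np.asarray(support, dtype=float)
    pmf = np.full(len(ls), uniform_weight / len(ls))
    for weight, mu, sd in peaks:
        dens = np.exp(-0.5 * ((ls - mu) / sd) ** 2)
        pmf += weight * dens / dens.sum()
    pmf /= pmf.sum()
    return {int(l): float(p) for l, p in zip(ls, pmf)}


def age_length_weights(base_dist: Mapping[int, float], age: float, beta: float,
                       age_ref: float = 50.0, l_mid: float = 30.0,
                       ) -> dict[int, float]:
    """Exponentially tilt a fragment-length distribution by age.

    ``w(L) ~ base(L) * exp(beta * (age - age_ref) * (L - l_mid))``,
    renormalized. ``beta > 0`` moves probability mass toward longer
    fragments as age increases past ``age_ref``; ``beta = 0`` returns the
    base distribution unchanged.
    """
    if not base_dist:
        raise SimulationError("empty length support")
    total = sum(base_dist.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise SimulationError(f"base distribution sums to {total}, not 1")
    ls = np.array(list(base_dist), dtype=float)
    ps = np.array(list(base_dist.values()), dtype=float)
    w = ps * np.exp(beta * (age - age_ref) * (ls - l_mid))
    w /= w.sum()
    return {int(l): float(p) for l, p in zip(ls, w)}


def default_model(panel: ReferencePanel, scenario: str = "mouse_5group",
                  beta: float = 0.004, cliff_scale: float = math.log(4.0),
                  cliff_cutoff: float = 60.0, mt_factor_sd: float = 1.4,
                  noise_sd: float = 0.25,
                  bin_noise_sd: float = 0.15) -> FragmentModel:
    """Default fragment model over a panel, mirroring the study conditions.

    Family abundance within each class decays geometrically in panel order
    (so 28S-/18S-like parents dominate the rsRNA pool). In the mouse
    scenario genomic ts/rsRNA families take log-steps past
    ``cliff_cutoff`` of alternating sign and heterogeneous magnitude, up
    to ``cliff_scale`` (four-fold, matching the dramatic early/late
    separation the cliff produces); magnitudes grow as abundance shrinks,
    since the dominant families cannot multiply several-fold without
    rewriting the whole composition. Mitochondrial families respond as
    one coordinated block; miRNAs stay flat. Human scenarios keep the
    length tilt but no cliff, mirroring where each phenomenon was
    observed.
    """
    class_props = DEFAULT_CLASS_PROPS
    props: dict[str, float] = {}
    for rna_class, mass in class_props.items():
        members = panel.by_class(rna_class)
        if not members:
            raise SimulationError(f"panel has no {rna_class} parent")
        # geometric abundance decay in panel order; tRNA isoacceptor
        # abundances are less skewed than rRNA parent contributions
        ratio = 0.75 if rna_class == "tRNA" else 0.5
        weights = np.array([ratio ** i for i in range(len(members))])
        weights /= weights.sum()
        for rec, w in zip(members, weights):
            props[rec.id] = mass * w
    # exact unit sum despite float rounding
    total = sum(props.values())
    props = {f: p / total for f, p in props.items()}

    rs_len = _discrete_mixture(range(15, 47),
                               [(0.45, 17.0, 2.0), (0.35, 43.0, 2.0)], 0.20)
    ts_len = _discrete_mixture(range(18, 41), [(0.70, 34.0, 2.0)], 0.30)

    windows: dict[str, list[Window]] = {}
    lengths: dict[str, dict[int, float]] = {}
    tilt: set[str] = set()
    cliff: dict[str, float] = {}
    # cliff magnitude rises linearly with within-class abundance rank:
    # minor families swing hardest (the dominant ones cannot multiply
    # several-fold without rewriting the composition), and no two
    # families in a class respond identically; sign alternates within
    # class (rRNA starts up, tRNA down)
    _SIGN0 = {"rRNA": 1.0, "tRNA": -1.0}
    class_sizes = {c: len(panel.by_class(c)) for c in ("rRNA", "tRNA")}
    class_rank: dict[str, int] = {}
    for rec in panel:
        if rec.rna_class in ("rRNA", "mt_rRNA"):
            lmax = max(rs_len)
            last = max(1, len(rec) - lmax + 1)
            starts = sorted({max(1, min(last, round(f * len(rec))))
                             for f in (0.08, 0.45, 0.80)})
            windows[rec.id] = [Window("start", s) for s in starts]
            lengths[rec.id] = dict(rs_len)
            tilt.add(rec.id)
        elif rec.rna_class in ("tRNA", "mt_tRNA"):
            windows[rec.id] = [Window("start", 1), Window("end")]
            lengths[rec.id] = dict(ts_len)
        else:  # miRNA: the read is the full mature sequence
            windows[rec.id] = [Window("start", 1)]
            lengths[rec.id] = {len(rec): 1.0}
        if rec.rna_class == "miRNA" or scenario != "mouse_5group":
            cliff[rec.id] = 0.0
        elif rec.origin == "mitochondrial":
            # the mt block responds coordinately: one half-magnitude
            # step up shared by all mt families
            cliff[rec.id] = 0.5 * cliff_scale
        else:
            rank = class_rank.get(rec.rna_class, 0)
            class_rank[rec.rna_class] = rank + 1
            sign = _SIGN0[rec.rna_class] * (1.0 if rank % 2 == 0 else -1.0)
            n_cls = class_sizes[rec.rna_class]
            mag = 0.3 + 0.7 * rank / max(1, n_cls - 1)
            cliff[rec.id] = sign * mag * cliff_scale

    # center the cliff so total shifted mass is conserved: the cliff is a
    # compositional rearrangement, not a change in total sncRNA output,
    # so unshifted classes (miRNAs) see no normalization step
    shifted = [f for f, d in cliff.items() if d != 0.0]
    if shifted:
        mass = sum(props[f] for f in shifted)
        new_mass = sum(props[f] * math.exp(cliff[f]) for f in shifted)
        c = math.log(new_mass / mass)
        for f in shifted:
            cliff[f] -= c

    return FragmentModel(
        base_family_props=props,
        cliff_delta=cliff,
        cleavage_windows=windows,
        length_dists=lengths,
        tilt_families=frozenset(tilt),
        cliff_cutoff=cliff_cutoff,
        length_tilt_beta=beta,
        mt_factor_sd=mt_factor_sd,
        noise_sd=noise_sd,
        bin_noise_sd=bin_noise_sd,
    )


# --------------------------------------------------------------------------
# simulation


class _BinTable:
    """Flattened (family, window, length) bins with per-window base pmfs."""

    def __init__(self, model: FragmentModel, panel: ReferencePanel):
        fam_idx, win_idx, starts, lens, base_w, win_weight = [], [], [], [], [], []
        self.families = model.families
        self.parents = self.families  # family == parent id
        gw = 0
        for fi, fam in enumerate(self.families):
            if fam not in panel:
                raise SimulationError(f"family {fam!r} missing from panel")
            plen = len(panel[fam])
            wins = model.cleavage_windows[fam]
            pmf = model.length_dists[fam]
            for win in wins:
                feas: list[tuple[int, int, float]] = []
                for L, p in pmf.items():
                    start = win.pos if win.anchor == "start" else plen - L + 1
                    if start >= 1 and start + L - 1 <= plen:
                        feas.append((start, L, p))
                if not feas:
                    raise SimulationError(
                        f"window {win} of {fam!r} admits no feasible length")
                norm = sum(p for *_, p in feas)
                for start, L, p in feas:
                    fam_idx.append(fi)
                    win_idx.append(gw)
                    starts.append(start)
                    lens.append(L)
                    base_w.append(p / norm)
                    win_weight.append(1.0 / len(wins))
                gw += 1
        self.fam_idx = np.array(fam_idx)
        self.win_idx = np.array(win_idx)
        self.starts = np.array(starts)
        self.lengths = np.array(lens)
        self.base_w = np.array(base_w)
        self.win_weight = np.array(win_weight)
        self.n_windows = gw
        tilt_fams = np.array([f in model.tilt_families for f in self.families])
        self.tilted = tilt_fams[self.fam_idx]

    def probs(self, fam_props: np.ndarray, model: FragmentModel,
              age: float, age_ref: float) -> np.ndarray:
        """Per-bin probabilities for one sample (sum to 1)."""
        w = self.base_w
        if model.length_tilt_beta != 0.0:
            expo = (model.length_tilt_beta * (age - age_ref)
                    * (self.lengths - model.l_mid))
            w = np.where(self.tilted, w * np.exp(expo), w)
            denom = np.bincount(self.win_idx, weights=w,
                                minlength=self.n_windows)
            w = w / denom[self.win_idx]
        return fam_props[self.fam_idx] * self.win_weight * w


@dataclass
class SimulatedCohort:
    """A simulated cohort: reads, truth tables, sample sheet, provenance.

    Per-sample counts live in a dense samples x bins array (``bin_counts``)
    aligned with the flattened (family, window, length) bin table; the
    dict-of-cells ``truth_counts`` view is derived lazily for round-trip
    checks against the annotator.
    """

    design: CohortDesign
    model: FragmentModel
    panel: ReferencePanel
    sample_sheet: pd.DataFrame
    bins: "_BinTable"
    bin_counts: np.ndarray  # samples x bins, integer read counts
    expected_props: pd.DataFrame  # samples x (family, length), noise-free
    reads: dict[str, dict[str, int]] | None
    provenance: dict = field(default_factory=dict)
    _truth: dict[str, dict[tuple[str, int, int], int]] | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_sheet.index)

    def ages(self) -> pd.Series:
        return self.sample_sheet["age"]

    @property
    def truth_counts(self) -> dict[str, dict[tuple[str, int, int], int]]:
        """Sample -> {(parent, start, length): count}, nonzero cells only."""
        if self._truth is None:
            b = self.bins
            truth: dict[str, dict[tuple[str, int, int], int]] = {}
            for si, sid in enumerate(self.sample_ids):
                cells: dict[tuple[str, int, int], int] = {}
                for j in np.nonzero(self.bin_counts[si])[0]:
                    key = (b.families[b.fam_idx[j]], int(b.starts[j]),
                           int(b.lengths[j]))
                    cells[key] = cells.get(key, 0) + int(self.bin_counts[si, j])
                truth[sid] = cells
            self._truth = truth
        return self._truth

    # ------------------------------------------------- truth-based matrices

    def _bin_mask(self, classes=None, parents=None) -> np.ndarray:
        cls_of = self.panel.classes()
        fam_ok = np.array([
            (classes is None or cls_of[f] in classes)
            and (parents is None or f in parents)
            for f in self.bins.families
        ])
        return fam_ok[self.bins.fam_idx]

    def _group_rpm(self, group_codes: np.ndarray, n_groups: int,
                   mask: np.ndarray) -> np.ndarray:
        """Sum masked bin counts into groups per sample, scaled to RPM."""
        codes = np.where(mask, group_codes, n_groups)  # overflow bucket
        out = np.zeros((len(self.bin_counts), n_groups + 1))
        for si in range(len(self.bin_counts)):
            out[si] = np.bincount(codes, weights=self.bin_counts[si],
                                  minlength=n_groups + 1)
        return out[:, :n_groups] * (1e6 / self.design.depth)

    def family_rpm(self, classes: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples x families RPM table computed from the truth counts."""
        mask = self._bin_mask(classes)
        fams = [f for i, f in enumerate(self.bins.families)
                if mask[self.bins.fam_idx == i].any()]
        fmap = {f: i for i, f in enumerate(fams)}
        codes = np.array([fmap.get(f, len(fams))
                          for f in np.array(self.bins.families)[self.bins.fam_idx]])
        vals = self._group_rpm(codes, len(fams), mask)
        return pd.DataFrame(vals, index=self.sample_ids, columns=fams)

    def species_rpm(self, classes: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples x species RPM, species = (parent, start, length) bins."""
        mask = self._bin_mask(classes)
        idx = np.nonzero(mask)[0]
        names = [f"{self.bins.families[self.bins.fam_idx[j]]}:"
                 f"{self.bins.starts[j]}:{self.bins.lengths[j]}" for j in idx]
        vals = self.bin_counts[:, idx] * (1e6 / self.design.depth)
        return pd.DataFrame(vals, index=self.sample_ids, columns=names)

    def length_rpm(self, classes: Sequence[str] | None = None,
                   parents: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples x fragment-length RPM over the full 15-50 nt window."""
        lo, hi = self.model.length_support
        mask = self._bin_mask(classes, parents)
        codes = self.bins.lengths - lo
        vals = self._group_rpm(codes, hi - lo + 1, mask)
        return pd.DataFrame(vals, index=self.sample_ids,
                            columns=range(lo, hi + 1))

    # --------------------------------------------------------------- output

    def write(self, outdir: str | Path, fmt: str = "fasta") -> None:
        """Write per-sample reads, the sample sheet, truth tables and panel."""
        outdir = Path(outdir)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        self.panel.to_fasta(str(outdir / "panel.fasta"))
        self.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t")
        self.expected_props.to_csv(outdir / "truth" / "expected_props.tsv",
                                   sep="\t")
        for sample in self.sample_ids:
            rows = [(p, s, l, c) for (p, s, l), c in
                    sorted(self.truth_counts[sample].items())]
            pd.DataFrame(rows, columns=["parent", "start", "length", "count"]
                         ).to_csv(outdir / "truth" / f"{sample}.tsv",
                                  sep="\t", index=False)
        if self.reads is None:
            return
        for sample, readset in self.reads.items():
            if fmt == "fasta":
                with open(outdir / f"{sample}.fasta", "w") as fh:
                    i = 0
                    for seq, c in sorted(readset.items()):
                        for _ in range(c):
                            fh.write(f">{sample}_{i}\n{seq}\n")
                            i += 1
            elif fmt == "fastq.gz":
                with gzip.open(outdir / f"{sample}.fastq.gz", "wt") as fh:
                    i = 0
                    for seq, c in sorted(readset.items()):
                        for _ in range(c):
                            fh.write(f"@{sample}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                            i += 1
            else:
                raise SimulationError(f"unknown read format {fmt!r}")


def simulate_cohort(design: CohortDesign,
                    model: FragmentModel | None = None,
                    panel: ReferencePanel | None = None,
                    materialize_reads: bool = True) -> SimulatedCohort:
    """Draw one cohort from the generative model.

    Per sample: family proportions take the cliff step (if past the
    cutoff), are multiplied by the shared mitochondrial latent factor and
    by i.i.d. log-normal noise, renormalized, spread over (window, length)
    bins with the age-tilted length pmf, and read counts are drawn from a
    single multinomial at the design depth. With ``materialize_reads``
    the exact read sequences (substrings of panel parents) are built;
    statistics that only need counts can skip this.
    """
    if panel is None:
        panel = build_reference_panel(design.seed)
    if model is None:
        model = default_model(panel, design.scenario)
    rng = np.random.default_rng(design.seed)
    ages = design.sample_ages
    age_ref = model.age_ref if model.age_ref is not None else float(ages.mean())
    bins = _BinTable(model, panel)
    fam_list = bins.families
    origins = panel.origins()
    mt_mask = np.array([origins[f] == "mitochondrial" for f in fam_list])
    base = np.array([model.base_family_props[f] for f in fam_list])
    cliff = np.array([model.cliff_delta.get(f, 0.0) for f in fam_list])

    unit = design.age_unit
    sample_ids = []
    rows = []
    for i, age in enumerate(ages):
        sid = f"S{i + 1:03d}"
        sample_ids.append(sid)
        rows.append({
            "sample_id": sid,
            "age": float(age),
            "group": f"{age:g}{unit[0]}",
            "tissue": "sperm_head",
            "protocol": "PANDORA-seq",
            "donor": design.donors[i] if design.donors else sid,
        })
    sheet = pd.DataFrame(rows).set_index("sample_id")

    reads: dict[str, dict[str, int]] | None = {} if materialize_reads else None
    parent_seq = {f: panel[f].sequence for f in fam_list}
    n_bins = len(bins.fam_idx)
    bin_counts = np.zeros((len(sample_ids), n_bins), dtype=np.int64)
    for si, age in enumerate(ages):
        p = base.copy()
        p = np.where(age > model.cliff_cutoff, p * np.exp(cliff), p)
        u = rng.normal()
        eps = rng.normal(scale=model.noise_sd, size=len(fam_list))
        # mean-one log-normal factors so expected composition matches base
        log_noise = eps - model.noise_sd ** 2 / 2
        log_mt = model.mt_factor_sd * u - model.mt_factor_sd ** 2 / 2
        p = p * np.exp(log_noise + np.where(mt_mask, log_mt, 0.0))
        p /= p.sum()

        bin_p = bins.probs(p, model, age, age_ref)
        if model.bin_noise_sd > 0:
            xi = rng.normal(scale=model.bin_noise_sd, size=n_bins)
            bin_p = bin_p * np.exp(xi - model.bin_noise_sd ** 2 / 2)
        bin_counts[si] = rng.multinomial(design.depth, bin_p / bin_p.sum())
        if reads is not None:
            rs: dict[str, int] = {}
            for j in np.nonzero(bin_counts[si])[0]:
                parent = fam_list[bins.fam_idx[j]]
                start, L = int(bins.starts[j]), int(bins.lengths[j])
                seq = parent_seq[parent][start - 1:start - 1 + L]
                rs[seq] = rs.get(seq, 0) + int(bin_counts[si, j])
            reads[sample_ids[si]] = rs

    # noise-free expected (family, length) proportions, one row per
    # distinct age (identical-age samples share the row)
    lo, hi = model.length_support
    fam_arr = bins.fam_idx
    len_codes = bins.lengths - lo
    n_len = hi - lo + 1
    marg_codes = fam_arr * n_len + len_codes
    per_age: dict[float, np.ndarray] = {}
    for age in np.unique(ages):
        pe = np.where(age > model.cliff_cutoff, base * np.exp(cliff), base)
        exp_bin = bins.probs(pe / pe.sum(), model, float(age), age_ref)
        per_age[float(age)] = np.bincount(marg_codes, weights=exp_bin,
                                          minlength=len(fam_list) * n_len)
    expected = pd.DataFrame(
        [per_age[float(a)] for a in ages], index=sample_ids,
        columns=pd.MultiIndex.from_product(
            [fam_list, range(lo, hi + 1)], names=["family", "length"]))
    expected = expected.loc[:, (expected != 0).any(axis=0)]

    provenance = {"seed": design.seed, "scenario": design.scenario,
                  "config_hash": model.config_hash(), "age_ref": age_ref}
    return SimulatedCohort(design, model, panel, sheet, bins, bin_counts,
                           expected, reads, provenance)
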