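"""Lightweight hierarchical sncRNA annotator.

Collapses raw small-RNA inserts to unique sequences, places each one on
every reference parent with at most one mismatch, and assigns a single
RNA class per read by a fixed precedence (miRNA > tRNA > rRNA > mt_tRNA >
mt_rRNA), with perfect (0-mismatch) placements pre-empting 1-mismatch
placements across all classes. Multi-mapping reads split their count
equally among the winning class's best placements, so counts are
conserved exactly. Expression is reported in reads per million (RPM)
total clean reads.

Only placements on the sense strand of the mature parent are considered
by default; tRNA parents are expected to be mature (CCA-terminated)
sequences, so fragments of unprocessed precursors are outside the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference import RNA_CLASSES, ReferencePanel

logger = logging.getLogger(__name__)

LENGTH_WINDOW = (15, 50)  # nt retained by the gel size selection

DEFAULT_PRECEDENCE = RNA_CLASSES  # miRNA > tRNA > rRNA > mt_tRNA > mt_rRNA


class AnnotationError(ValueError):
    pass


@dataclass
class ReadSet:
    """Unique collapsed sequences with counts.

    ``counts`` holds only annotatable sequences (clean ACGT, length inside
    the 15-50 nt window); everything that came off the sequencer still
    counts toward ``total_clean_reads``, the RPM denominator.
    """

    counts: dict[str, int] = field(default_factory=dict)
    total_clean_reads: int = 0

    @property
    def n_annotatable(self) -> int:
        return sum(self.counts.values())


def collapse_reads(sequences: Iterable[str]) -> ReadSet:
    """Collapse an iterable of raw insert sequences into a :class:`ReadSet`.

    Uppercases, unifies U -> T, and drops reads outside the 15-50 nt
    window or containing non-ACGT characters from annotation (they remain
    in the clean-read total).
    """
    lo, hi = LENGTH_WINDOW
    counts: dict[str, int] = {}
    total = 0
    dropped = 0
    for seq in sequences:
        total += 1
        s = seq.strip().upper().replace("U", "T")
        if lo <= len(s) <= hi and set(s) <= set("ACGT"):
            counts[s] = counts.get(s, 0) + 1
        else:
            dropped += 1
    if dropped:
        logger.info("collapse_reads: %d/%d reads excluded from annotation",
                    dropped, total)
    return ReadSet(counts, total)


def read_sequences(path: str | Path) -> Iterable[str]:
    """Yield insert sequences from FASTA or FASTQ (optionally .gz)."""
    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq)


# --------------------------------------------------------------------------
# matching


@dataclass(frozen=True)
class AnnotationHit:
    """Placement of a read on a parent: 1-based inclusive start and the
    Hamming distance at that placement."""

    parent: str
    start: int
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def match_with_mismatch(read: str, parent: str, max_mm: int = 1,
                        parent_id: str = "") -> list[AnnotationHit]:
    """All placements of ``read`` on ``parent`` with <= ``max_mm``
    substitutions, sorted by start position (1-based).

    Scans every placement with a vectorized Hamming comparison; this is
    definitionally identical to the naive all-placements scan.
    """
    L, P = len(read), len(parent)
    if L > P:
        return []
    r = _encode(read)
    windows = np.lib.stride_tricks.sliding_window_view(_encode(parent), L)
    mm = (windows != r).sum(axis=1)
    hits = np.nonzero(mm <= max_mm)[0]
    return [AnnotationHit(parent_id, int(i) + 1, int(mm[i])) for i in hits]


# --------------------------------------------------------------------------
# assignment


@dataclass
class AnnotatedSample:
    """Per-sample annotation result.

    ``tensor`` maps (class, parent, start, length) to fractional counts
    (multi-mapping reads are split equally among best placements);
    ``class_totals`` are integral per-class read totals; unannotated reads
    plus class totals equal the read-set total.
    """

    assignments: dict[str, tuple[str, list[AnnotationHit]]]
    tensor: dict[tuple[str, str, int, int], float]
    class_totals: dict[str, int]
    unannotated: int
    total_clean_reads: int

    @property
    def annotated(self) -> int:
        return sum(self.class_totals.values())


def annotate(reads: ReadSet, panel: ReferencePanel, max_mm: int = 1,
             precedence: Sequence[str] = DEFAULT_PRECEDENCE) -> AnnotatedSample:
    """Assign every collapsed read to one RNA class.

    For each read all placements on all parents within ``max_mm`` are
    enumerated; only placements at the read's minimum achieved mismatch
    count are retained (a perfect match anywhere pre-empts 1-mismatch
    placements everywhere); among classes holding such placements the
    highest-precedence one wins; the read count is divided equally among
    the winning class's retained placements.
    """
    if len(panel) == 0:
        raise AnnotationError("empty panel")
    order = {c: i for i, c in enumerate(precedence)}
    cls_of = panel.classes()
    assignments: dict[str, tuple[str, list[AnnotationHit]]] = {}
    tensor: dict[tuple[str, str, int, int], float] = {}
    class_totals: dict[str, int] = {c: 0 for c in precedence}
    unannotated = reads.total_clean_reads - reads.n_annotatable

    for seq, count in reads.counts.items():
        hits: list[AnnotationHit] = []
        for rec in panel:
            hits.extend(match_with_mismatch(seq, rec.sequence, max_mm, rec.id))
        if not hits:
            unannotated += count
            continue
        best_mm = min(h.mismatches for h in hits)
        hits = [h for h in hits if h.mismatches == best_mm]
        win_class = min((cls_of[h.parent] for h in hits),
                        key=lambda c: order[c])
        win_hits = [h for h in hits if cls_of[h.parent] == win_class]
        assignments[seq] = (win_class, win_hits)
        class_totals[win_class] += count
        share = count / len(win_hits)
        L = len(seq)
        for h in win_hits:
            key = (win_class, h.parent, h.start, L)
            tensor[key] = tensor.get(key, 0.0) + share

    return AnnotatedSample(assignments, tensor, class_totals, unannotated,
                           reads.total_clean_reads)


# --------------------------------------------------------------------------
# normalization and summaries


def rpm_normalize(counts: Mapping, total_clean_reads: int) -> pd.Series:
    """Scale raw counts to reads per million total clean reads."""
    if total_clean_reads <= 0:
        raise AnnotationError("total_clean_reads must be positive")
    s = pd.Series(dict(counts), dtype=float)
    return s * (1e6 / total_clean_reads)


def class_summary(samples: Mapping[str, AnnotatedSample]) -> pd.DataFrame:
    """Per-sample class totals plus unannotated counts (reads, not RPM)."""
    rows = {}
    for sid, ann in samples.items():
        row = dict(ann.class_totals)
        row["unannotated"] = ann.unannotated
        row["total_clean_reads"] = ann.total_clean_reads
        rows[sid] = row
    return pd.DataFrame(rows).T.fillna(0).astype(int)


def family_matrix(samples: Mapping[str, AnnotatedSample],
                  classes: Sequence[str] | None = None) -> pd.DataFrame:
    """Samples x families RPM matrix (family = parent id)."""
    rows = {}
    for sid, ann in samples.items():
        acc: dict[str, float] = {}
        for (cls, parent, _s, _l), c in ann.tensor.items():
            if classes is not None and cls not in classes:
                continue
            acc[parent] = acc.get(parent, 0.0) + c
        rows[sid] = rpm_normalize(acc, ann.total_clean_reads)
    return pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)


def species_matrix(samples: Mapping[str, AnnotatedSample],
                   classes: Sequence[str] | None = None) -> pd.DataFrame:
    """Samples x species RPM, species = (parent, start, length)."""
    rows = {}
    for sid, ann in samples.items():
        acc: dict[str, float] = {}
        for (cls, parent, start, L), c in ann.tensor.items():
            if classes is not None and cls not in classes:
                continue
            acc[f"{parent}:{start}:{L}"] = acc.get(f"{parent}:{start}:{L}", 0.0) + c
        rows[sid] = rpm_normalize(acc, ann.total_clean_reads)
    return pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)


def length_profile(samples: Mapping[str, AnnotatedSample],
                   classes: Sequence[str] | None = None,
                   parents: Sequence[str] | None = None) -> pd.DataFrame:
    """Samples x fragment-length RPM table over the 15-50 nt window.

    The filter selects which reads contribute (by class and/or parent);
    an empty filter selection is rejected. Lengths with zero RPM in every
    sample are kept as zero columns; downstream statistics decide whether
    to exclude them.
    """
    if classes is not None and len(classes) == 0:
        raise AnnotationError("empty class filter")
    if parents is not None and len(parents) == 0:
        raise AnnotationError("empty parent filter")
    lo, hi = LENGTH_WINDOW
    out = pd.DataFrame(0.0, index=list(samples), columns=range(lo, hi + 1))
    for sid, ann in samples.items():
        scale = 1e6 / ann.total_clean_reads
        for (cls, parent, _s, L), c in ann.tensor.items():
            if classes is not None and cls not in classes:
                continue
            if parents is not None and parent not in parents:
                continue
            out.at[sid, L] += c * scale
    all_zero = [int(c) for c in out.columns if (out[c] == 0).all()]
    if all_zero:
        logger.debug("length_profile: %d lengths with zero RPM everywhere",
                     len(all_zero))
    return out


def coverage(samples: Mapping[str, AnnotatedSample], panel: ReferencePanel,
             parent: str, groups: Mapping[str, str],
             lengths: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-position, per-group mean RPM and SEM along one parent.

    A read contributes its RPM to every position it spans (start ..
    start+L-1). SEM is the sample standard deviation (ddof=1) over
    within-group samples divided by sqrt(n); groups of one sample report
    SEM 0. Positions are 1-based on the parent.
    """
    if parent not in panel:
        raise AnnotationError(f"unknown parent {parent!r}")
    missing = [s for s in samples if s not in groups]
    if missing:
        raise AnnotationError(f"samples without a group: {missing}")
    plen = len(panel[parent])
    per_sample = {}
    for sid, ann in samples.items():
        cov = np.zeros(plen)
        scale = 1e6 / ann.total_clean_reads
        for (_c, par, start, L), c in ann.tensor.items():
            if par != parent:
                continue
            if lengths is not None and L not in lengths:
                continue
            cov[start - 1:start - 1 + L] += c * scale
        per_sample[sid] = cov
    rows = []
    for group in sorted(set(groups[s] for s in samples)):
        members = np.array([per_sample[s] for s in samples
                            if groups[s] == group])
        mean = members.mean(axis=0)
        sem = (members.std(axis=0, ddof=1) / np.sqrt(len(members))
               if len(members) > 1 else np.zeros(plen))
        for pos in range(plen):
            rows.append((pos + 1, group, mean[pos], sem[pos]))
    return pd.DataFrame(rows, columns=["position", "group", "mean", "sem"])


def annotate_cohort(reads: Mapping[str, Mapping[str, int]],
                    panel: ReferencePanel, depth: Mapping[str, int] | int,
                    max_mm: int = 1) -> dict[str, AnnotatedSample]:
    """Annotate a collection of pre-collapsed samples.

    ``reads`` maps sample id -> {sequence: count}; ``depth`` gives the
    clean-read total per sample (one int applies to all).
    """
    out = {}
    for sid, counts in reads.items():
        total = depth if isinstance(depth, int) else depth[sid]
        rs = ReadSet(dict(counts), total)
        out[sid] = annotate(rs, panel, max_mm=max_mm)
    return out
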