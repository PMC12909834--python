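"""Reference panel of parent sncRNA sequences.

A panel is the set of "parent" transcripts that small-RNA fragments are
annotated against: cytosolic rRNAs (28S/18S/5.8S/5S-like), mitochondrial
rRNAs (12S/16S-like), mature tRNAs (spliced, CCA-terminated) from both
genomes, and miRNA hairpin products. Each record carries an RNA class and
a genomic/mitochondrial origin label; both travel in FASTA headers as
``>{id}|{class}|{origin}``.

Panels used in simulations are built from random sequence with a fixed
seed, so every cohort is reproducible from its design alone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: annotation classes, in default assignment precedence order
RNA_CLASSES = ("miRNA", "tRNA", "rRNA", "mt_tRNA", "mt_rRNA")

#: classes whose parents live on the mitochondrial genome
_MT_CLASSES = frozenset({"mt_tRNA", "mt_rRNA"})

_BASES = np.array(list("ACGT"))


class PanelError(ValueError):
    """Raised for malformed or inconsistent reference panels."""


@dataclass(frozen=True)
class PanelRecord:
    """One parent sequence with its class and genome of origin."""

    id: str
    rna_class: str
    origin: str
    sequence: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise PanelError(f"unknown RNA class {self.rna_class!r}")
        expected = "mitochondrial" if self.rna_class in _MT_CLASSES else "genomic"
        if self.origin != expected:
            raise PanelError(
                f"{self.id}: class {self.rna_class} implies origin {expected!r}, "
                f"got {self.origin!r}"
            )
        if not set(self.sequence) <= set("ACGT"):
            raise PanelError(f"{self.id}: sequence must be uppercase DNA (A/C/G/T)")

    def __len__(self) -> int:
        return len(self.sequence)


class ReferencePanel:
    """Ordered collection of :class:`PanelRecord` with unique identifiers."""

    def __init__(self, records: Iterable[PanelRecord]):
        self._records: dict[str, PanelRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise PanelError(f"duplicate parent identifier {rec.id!r}")
            self._records[rec.id] = rec
        if not self._records:
            raise PanelError("empty reference panel")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, parent_id: str) -> bool:
        return parent_id in self._records

    def __getitem__(self, parent_id: str) -> PanelRecord:
        return self._records[parent_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def by_class(self, rna_class: str) -> list[PanelRecord]:
        return [r for r in self if r.rna_class == rna_class]

    def origins(self) -> dict[str, str]:
        """Map parent id -> 'genomic' | 'mitochondrial'."""
        return {r.id: r.origin for r in self}

    def classes(self) -> dict[str, str]:
        """Map parent id -> RNA class."""
        return {r.id: r.rna_class for r in self}

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path | io.TextIOBase) -> None:
        records = [
            SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.rna_class}|{r.origin}",
                      description="")
            for r in self
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path | io.TextIOBase) -> "ReferencePanel":
        records = []
        for rec in SeqIO.parse(path, "fasta"):
            try:
                pid, rna_class, origin = rec.id.split("|")
            except ValueError as exc:
                raise PanelError(
                    f"panel header {rec.id!r} is not '{{id}}|{{class}}|{{origin}}'"
                ) from exc
            records.append(
                PanelRecord(pid, rna_class, origin,
                            str(rec.seq).upper().replace("U", "T"))
            )
        return cls(records)


#: default toy panel layout: class -> {parent id: length}
DEFAULT_PANEL_SPEC: dict[str, dict[str, int]] = {
    "rRNA": {"rRNA-28S": 400, "rRNA-18S": 250, "rRNA-5.8S": 150, "rRNA-5S": 120},
    "mt_rRNA": {"mt-rRNA-16S": 220, "mt-rRNA-12S": 180},
    "tRNA": {
        "tRNA-Gly-GCC": 76,
        "tRNA-Glu-CTC": 76,
        "tRNA-Arg-CCT": 76,
        "tRNA-Pro-CGG": 76,
        "tRNA-Val-CAC": 76,
        "tRNA-His-GTG": 76,
        "tRNA-Lys-CTT": 76,
        "tRNA-Ser-AGA": 82,
        "tRNA-Leu-CAG": 82,
        "tRNA-Asp-GTC": 76,
        "tRNA-Phe-GAA": 76,
        "tRNA-Ala-AGC": 76,
    },
    "mt_tRNA": {"mt-tRNA-Ser-GCT": 72, "mt-tRNA-Leu-TAG": 72},
    "miRNA": {"miR-34c": 22, "miR-10a": 22, "miR-191": 22, "let-7a": 22},
}


def build_reference_panel(
    seed: int,
    spec: Mapping[str, Mapping[str, int]] | None = None,
) -> ReferencePanel:
    """Build a random reference panel, deterministic for a fixed seed.

    Parameters
    ----------
    seed:
        Root seed for the sequence draw.
    spec:
        Mapping ``class -> {parent id: length}``; defaults to
        :data:`DEFAULT_PANEL_SPEC`. Every mature tRNA parent (classes
        ``tRNA`` and ``mt_tRNA``) is forced to end in the post-
        transcriptionally added CCA tail, the hallmark of the mature form.
    """
    spec = spec if spec is not None else DEFAULT_PANEL_SPEC
    rng = np.random.default_rng(seed)
    records: list[PanelRecord] = []
    for rna_class in RNA_CLASSES:  # fixed class order => reproducible draws
        for pid, length in spec.get(rna_class, {}).items():
            if length < 3:
                raise PanelError(f"{pid}: parent length {length} too short")
            seq = "".join(rng.choice(_BASES, size=length))
            if rna_class in ("tRNA", "mt_tRNA"):
                seq = seq[:-3] + "CCA"
            origin = "mitochondrial" if rna_class in _MT_CLASSES else "genomic"
            records.append(PanelRecord(pid, rna_class, origin, seq))
    return ReferencePanel(records)


def _sequences_for(panel: ReferencePanel, ids: Sequence[str]) -> dict[str, str]:
    return {pid: panel[pid].sequence for pid in ids}
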