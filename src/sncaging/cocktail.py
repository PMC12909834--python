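"""Synthetic small-RNA cocktail bookkeeping.

Transfection cocktails mimicking "young" and "old" sperm sncRNA profiles
are specified as per-component concentrations (nM) of chemically
synthesized oligos. Vendor order strings annotate each ribonucleotide
with an ``r`` prefix and carry 5'-phosphate / 2',3'-cyclic-phosphate
chemistry tags; this module parses those strings back to plain sequences
and recomputes component proportions from the concentrations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

#: vendor-format order strings for the five cocktail oligos
OLIGO_STRINGS: dict[str, str] = {
    "tsRNA-Pro-CGG": (
        "5’/Phos/rGrGrCrUrCrGrUrUrGrGrUrCrUrArGrGrGrGrUrArUrGrArUrUrC"
        "rUrCrGrCrUrU-2'3 c-Phos"
    ),
    "tsRNA-Arg-CCT": (
        "5’/Phos/rArGrGrGrArUrUrGrUrGrGrGrUrUrCrGrArGrUrCrCrCrArUrCrU"
        "rGrGrGrGrUrGrC-2'3 c-Phos"
    ),
    "28S-rsRNA-44nt": (
        "5’/Phos/rCrUrCrGrCrUrGrCrGrArUrCrUrArUrUrGrArArArGrUrCrArGrC"
        "rCrCrUrCrGrArCrArCrArArGrGrGrUrUrUrG-2'3 c-Phos"
    ),
    "28S-rsRNA-17nt": (
        "5’/Phos/rCrUrCrGrArCrArCrArArGrGrGrUrUrUrG-2'3 c-Phos"
    ),
    "5S-rsRNA-36nt": (
        "5’/Phos/rUrGrGrGrArGrArCrCrGrCrCrUrGrGrGrArArUrArCrCrGrGrGrU"
        "rGrCrUrGrUrArGrGrCrU-2'3 c-Phos"
    ),
}

#: component concentrations (nM) of the two transfection cocktails
COCKTAILS: dict[str, dict[str, float]] = {
    "young": {
        "28S-rsRNA-44nt": 80.0,
        "28S-rsRNA-17nt": 20.0,
        "5S-rsRNA-36nt": 60.0,
        "tsRNA-Arg-CCT": 30.0,
        "tsRNA-Pro-CGG": 10.0,
    },
    "old": {
        "28S-rsRNA-44nt": 160.0,
        "28S-rsRNA-17nt": 1.0,
        "5S-rsRNA-36nt": 30.0,
        "tsRNA-Arg-CCT": 6.0,
        "tsRNA-Pro-CGG": 3.0,
    },
}

_PREFIX = re.compile(r"^5['’]?/Phos/")
_SUFFIX = re.compile(r"-?2'3\s*c-Phos$")
_TOKEN = re.compile(r"r([ACGU])")


class OligoParseError(ValueError):
    pass


def oligo_sequence(oligo: str) -> str:
    """Extract the plain RNA sequence from a vendor-annotated order
    string (``5'/Phos/rN...rN-2'3 c-Phos``)."""
    body = _SUFFIX.sub("", _PREFIX.sub("", oligo.strip()))
    seq: list[str] = []
    pos = 0
    for m in _TOKEN.finditer(body):
        between = body[pos:m.start()]
        if between.strip():
            raise OligoParseError(f"unparseable token {between!r} in oligo")
        seq.append(m.group(1))
        pos = m.end()
    if body[pos:].strip():
        raise OligoParseError(f"unparseable tail {body[pos:]!r} in oligo")
    return "".join(seq)


def oligo_length(oligo: str) -> int:
    """Nucleotide count of a vendor-annotated oligo string."""
    return len(oligo_sequence(oligo))


@dataclass
class CocktailSpec:
    """Cocktail composition: nM per component, percent of total, and the
    total concentration."""

    concentrations_nm: dict[str, float]
    proportions_pct: dict[str, float]
    total_nm: float


def cocktail_proportions(spec: Mapping[str, float]) -> CocktailSpec:
    """Convert per-component concentrations (nM) into percent-of-total
    proportions."""
    if not spec:
        raise OligoParseError("empty cocktail specification")
    if any(v <= 0 for v in spec.values()):
        raise OligoParseError("concentrations must be positive")
    total = float(sum(spec.values()))
    props = {name: 100.0 * v / total for name, v in spec.items()}
    return CocktailSpec(dict(spec), props, total)
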