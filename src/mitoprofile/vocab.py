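"""Controlled vocabulary for insect mitochondrial gene names.

Canonical tokens, the synonym table used to normalize the many naming
dialects found in GenBank records (``CO1``/``COI``/``cox1`` ...), and the
ancestral insect gene order used as the reference arrangement.
"""

from __future__ import annotations

import re
from enum import Enum

__all__ = [
    "GeneClass",
    "Strand",
    "PCG_TOKENS",
    "TRNA_TOKENS",
    "RRNA_TOKENS",
    "ALL_TOKENS",
    "PCG_J_SET",
    "PCG_N_SET",
    "ANCESTRAL_INSECT_ORDER",
    "gene_class_of",
    "canonicalize_gene_name",
    "UNKNOWN",
]


class GeneClass(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CR = "CR"


class Strand(str, Enum):
    """J = majority strand (as deposited); N = minority strand (complement)."""

    J = "J"
    N = "N"


PCG_TOKENS = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COX1", "COX2", "COX3", "ATP6", "ATP8", "CYTB",
)

TRNA_TOKENS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_TOKENS = ("rrnL", "rrnS")

ALL_TOKENS = PCG_TOKENS + TRNA_TOKENS + RRNA_TOKENS + ("CR",)

UNKNOWN = "unknown"

#: PCGs transcribed from the majority (J) strand in the ancestral arrangement.
PCG_J_SET = frozenset(
    {"ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3", "ND6", "CYTB"}
)
#: PCGs transcribed from the minority (N) strand.
PCG_N_SET = frozenset({"ND1", "ND4L", "ND4", "ND5"})

#: The plesiomorphic arrangement of the 37 mt genes shared by most Diptera,
#: written as (canonical name, strand) pairs starting at trnI by convention.
ANCESTRAL_INSECT_ORDER: tuple[tuple[str, Strand], ...] = (
    ("trnI", Strand.J), ("trnQ", Strand.N), ("trnM", Strand.J),
    ("ND2", Strand.J), ("trnW", Strand.J), ("trnC", Strand.N),
    ("trnY", Strand.N), ("COX1", Strand.J), ("trnL2", Strand.J),
    ("COX2", Strand.J), ("trnK", Strand.J), ("trnD", Strand.J),
    ("ATP8", Strand.J), ("ATP6", Strand.J), ("COX3", Strand.J),
    ("trnG", Strand.J), ("ND3", Strand.J), ("trnA", Strand.J),
    ("trnR", Strand.J), ("trnN", Strand.J), ("trnS1", Strand.J),
    ("trnE", Strand.J), ("trnF", Strand.N), ("ND5", Strand.N),
    ("trnH", Strand.N), ("ND4", Strand.N), ("ND4L", Strand.N),
    ("trnT", Strand.J), ("trnP", Strand.N), ("ND6", Strand.J),
    ("CYTB", Strand.J), ("trnS2", Strand.J), ("ND1", Strand.N),
    ("trnL1", Strand.N), ("rrnL", Strand.N), ("trnV", Strand.N),
    ("rrnS", Strand.N), ("CR", Strand.J),
)


def gene_class_of(token: str) -> GeneClass:
    """Gene class implied by a canonical token."""
    if token in PCG_TOKENS:
        return GeneClass.PCG
    if token in TRNA_TOKENS:
        return GeneClass.TRNA
    if token in RRNA_TOKENS:
        return GeneClass.RRNA
    if token == "CR":
        return GeneClass.CR
    raise ValueError(f"not a canonical token: {token!r}")


# --- synonym table -----------------------------------------------------------

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V", "LEU": "L", "SER": "S",
}

# codon-family / anticodon hints that disambiguate Leu and Ser tRNAs
_LEU_SER_FAMILY = {
    ("L", "CUN"): "trnL1", ("L", "TAG"): "trnL1", ("L", "UAG"): "trnL1",
    ("L", "UUR"): "trnL2", ("L", "TAA"): "trnL2", ("L", "UAA"): "trnL2",
    ("S", "AGN"): "trnS1", ("S", "GCT"): "trnS1", ("S", "GCU"): "trnS1",
    ("S", "TCT"): "trnS1", ("S", "UCU"): "trnS1",
    ("S", "UCN"): "trnS2", ("S", "TGA"): "trnS2", ("S", "UGA"): "trnS2",
}


def _variants() -> dict[str, str]:
    table: dict[str, str] = {}

    def add(canon: str, *raws: str) -> None:
        for raw in raws:
            key = _normalize(raw)
            if key in table and table[key] != canon:
                raise RuntimeError(f"ambiguous synonym {raw!r}")
            table[key] = canon

    for i in (1, 2, 3):
        add(f"COX{i}", f"COX{i}", f"CO{i}", f"CO{'I' * i}", f"COX{'I' * i}",
            f"MT-CO{i}", f"cytochrome c oxidase subunit {i}",
            f"cytochrome oxidase subunit {i}",
            f"cytochrome c oxidase subunit {'I' * i}")
    for i in (1, 2, 3, 4, 5, 6):
        add(f"ND{i}", f"ND{i}", f"NAD{i}", f"NADH{i}",
            f"NADH dehydrogenase subunit {i}")
    add("ND4L", "ND4L", "NAD4L", "NADH4L", "NADH dehydrogenase subunit 4L")
    add("CYTB", "CYTB", "COB", "CYB", "CB", "cytochrome b",
        "cytochrome b apoenzyme")
    add("ATP6", "ATP6", "ATPASE6", "ATPASE 6", "ATP synthase F0 subunit 6",
        "ATPase subunit 6")
    add("ATP8", "ATP8", "ATPASE8", "ATPASE 8", "ATP synthase F0 subunit 8",
        "ATPase subunit 8")
    add("rrnL", "rrnL", "16S", "16S rRNA", "16S ribosomal RNA", "lrRNA",
        "l-rRNA", "large subunit ribosomal RNA", "rrn16", "LSU")
    add("rrnS", "rrnS", "12S", "12S rRNA", "12S ribosomal RNA", "srRNA",
        "s-rRNA", "small subunit ribosomal RNA", "rrn12", "SSU")
    add("CR", "CR", "D-loop", "control region", "A+T rich region",
        "AT rich region", "putative control region")
    for token in TRNA_TOKENS:
        add(token, token)
    return table


def _normalize(raw: str) -> str:
    s = raw.strip().upper()
    s = re.sub(r"[\s_\-*.]+", "", s)
    return s


_SYNONYMS = _variants()

_TRNA_RE = re.compile(
    r"^T?RNA\(?([A-Z]{3}|[A-Z])\)?(?:\(([A-Z]{3})\))?$"
)
# compact dialect: trnL(tag), trnS(gct), trnW ...
_TRN_COMPACT_RE = re.compile(r"^TRN([A-Z])(?:\(([A-Z]{3})\))?$")


def canonicalize_gene_name(raw: str) -> str:
    """Map a free-text gene label to its canonical token.

    Leucine/serine tRNAs are resolved only when the label carries a codon
    family (CUN/UUR/AGN/UCN) or anticodon; unknown labels return the
    sentinel ``"unknown"`` and the caller decides severity.
    """
    if not raw:
        return UNKNOWN
    key = _normalize(raw)
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = _TRNA_RE.match(key) or _TRN_COMPACT_RE.match(key)
    if m:
        aa, family = m.groups()
        if len(aa) == 3:
            aa = _AA3_TO_1.get(aa, "")
        if aa in ("L", "S"):
            if family and (aa, family) in _LEU_SER_FAMILY:
                return _LEU_SER_FAMILY[(aa, family)]
            return UNKNOWN
        if aa and f"trn{aa}" in TRNA_TOKENS:
            return f"trn{aa}"
    return UNKNOWN
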