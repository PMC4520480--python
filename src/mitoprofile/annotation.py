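"""Annotation-derived statistics: gene order, junctions, codons, structures.

All analyses take annotations as given — no re-annotation is attempted.
Biological oddities (non-canonical codons, nested features) surface as
report content or warnings, never as exceptions, so QC runs keep going on
imperfect records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .model import GeneFeature, GenomeRecord, feature_sequence
from .vocab import ANCESTRAL_INSECT_ORDER, GeneClass, Strand

__all__ = [
    "JunctionEntry", "JunctionReport", "CodonCall", "PairTypeCounts",
    "gene_order", "gene_order_string", "breakpoint_count", "junctions",
    "classify_codons", "validate_orf", "count_pair_types",
    "read_structure_file", "INVERTEBRATE_MITO_TABLE",
]

#: NCBI translation table for the invertebrate mitochondrial code.
INVERTEBRATE_MITO_TABLE = 5

_STOPS = ("TAA", "TAG")  # complete stops under table 5


# --- gene order --------------------------------------------------------------

def gene_order(record: GenomeRecord, *, rotate_to: str = "trnI"
               ) -> tuple[tuple[str, Strand], ...]:
    """Circular gene order as (name, strand) pairs, rotated to ``rotate_to``.

    Missing genes are simply absent; callers compare against
    :data:`~mitoprofile.vocab.ANCESTRAL_INSECT_ORDER`.
    """
    ordered = [(f.name, f.strand) for f in record.features]
    names = [n for n, _ in ordered]
    if rotate_to in names and record.is_circular:
        i = names.index(rotate_to)
        ordered = ordered[i:] + ordered[:i]
    return tuple(ordered)


def gene_order_string(record: GenomeRecord, *, rotate_to: str = "trnI") -> str:
    """Signed, space-separated gene-order string (N-strand genes prefixed '-')."""
    return " ".join(
        (name if strand == Strand.J else f"-{name}")
        for name, strand in gene_order(record, rotate_to=rotate_to))


def _adjacencies(order: tuple[tuple[str, Strand], ...]) -> set[frozenset]:
    pairs = set()
    n = len(order)
    for i in range(n):
        a, b = order[i][0], order[(i + 1) % n][0]
        pairs.add(frozenset((a, b)))
    return pairs


def breakpoint_count(order_a, order_b) -> int:
    """Unsigned adjacent-pair breakpoints between two circular gene orders."""
    return len(_adjacencies(tuple(order_a)) - _adjacencies(tuple(order_b)))


# --- junctions ---------------------------------------------------------------

@dataclass(frozen=True)
class JunctionEntry:
    upstream: str
    downstream: str
    relation: str  # overlap | spacer | abutting
    length: int


@dataclass
class JunctionReport:
    """Ordered inter-gene relations plus per-relation summaries."""

    entries: list[JunctionEntry] = field(default_factory=list)

    def of(self, relation: str) -> list[JunctionEntry]:
        return [e for e in self.entries if e.relation == relation]

    def count(self, relation: str) -> int:
        return len(self.of(relation))

    def extent(self, relation: str) -> tuple[int, int] | None:
        lengths = [e.length for e in self.of(relation)]
        if not lengths:
            return None
        return min(lengths), max(lengths)

    @property
    def overlaps(self) -> list[JunctionEntry]:
        return self.of("overlap")

    @property
    def spacers(self) -> list[JunctionEntry]:
        return self.of("spacer")


def _entry(prev: GeneFeature, nxt: GeneFeature, gap: int,
           nested: bool = False) -> JunctionEntry:
    if nested:
        return JunctionEntry(prev.name, nxt.name, "overlap", len(nxt))
    if gap < 0:
        return JunctionEntry(prev.name, nxt.name, "overlap", -gap)
    if gap > 0:
        return JunctionEntry(prev.name, nxt.name, "spacer", gap)
    return JunctionEntry(prev.name, nxt.name, "abutting", 0)


def junctions(record: GenomeRecord, *, include_cr: bool = False) -> JunctionReport:
    """Overlap/spacer/abutting relations between adjacent genes.

    Complete circular records get the wrap-around junction; near-complete
    records are treated as linear (no junction across the missing region).
    Junctions flanking the control region are excluded unless
    ``include_cr`` — the paper-style censuses count coding-gene junctions
    only.
    """
    feats = sorted(record.features, key=lambda f: (f.start, f.end))
    report = JunctionReport()
    if len(feats) < 2:
        return report
    n = len(feats)
    circular = record.is_circular and record.is_complete
    pairs = []
    prev = feats[0]
    for nxt in feats[1:]:
        nested = nxt.end <= prev.end
        if nested:
            warnings.warn(
                f"{nxt.name} nested inside {prev.name}; reporting overlap of "
                "the shorter feature's full length", stacklevel=2)
            pairs.append((prev, nxt, prev.end - nxt.start, True))
            continue  # keep prev as the running right boundary
        pairs.append((prev, nxt, nxt.start - prev.end, False))
        prev = nxt
    if circular and n >= 2:
        first, last = feats[0], prev
        gap = first.start + len(record.sequence) - last.end
        pairs.append((last, first, gap, False))
    for prev, nxt, gap, nested in pairs:
        if not include_cr and (prev.gene_class == GeneClass.CR
                               or nxt.gene_class == GeneClass.CR):
            continue
        report.entries.append(_entry(prev, nxt, gap, nested))
    return report


# --- codon calls -------------------------------------------------------------

@dataclass(frozen=True)
class CodonCall:
    gene: str
    start_codon: str
    start_class: str  # canonical_ATN | noncanonical
    stop_codon: str | None
    stop_class: str  # complete | partial | anomalous


def _call_for(feature: GeneFeature, sense: str) -> CodonCall:
    eff = sense[feature.frame_offset:]
    start = eff[:3]
    start_class = ("canonical_ATN"
                   if len(start) == 3 and start[:2] == "AT" else "noncanonical")
    rem = len(eff) % 3
    if rem == 0:
        last = eff[-3:]
        if last in _STOPS:
            return CodonCall(feature.name, start, start_class, last, "complete")
        stop, cls = None, "anomalous"
    elif rem == 1:
        if eff.endswith("T"):
            return CodonCall(feature.name, start, start_class, "T", "partial")
        stop, cls = None, "anomalous"
    else:
        if eff.endswith("TA"):
            return CodonCall(feature.name, start, start_class, "TA", "partial")
        stop, cls = None, "anomalous"
    warnings.warn(f"{feature.name}: anomalous 3' terminus "
                  f"(length mod 3 = {rem}, end {eff[-3:]!r})", stacklevel=3)
    return CodonCall(feature.name, start, start_class, stop, cls)


def classify_codons(record: GenomeRecord) -> list[CodonCall]:
    """Start/stop codon calls for every PCG, in genomic order.

    Stop calls follow the 3' end: a full TAA/TAG is complete; a trailing
    T or TA (completed to TAA by transcript polyadenylation) is partial;
    anything else is flagged anomalous with a warning.
    """
    calls = []
    for f in record.genes(GeneClass.PCG):
        sense = feature_sequence(record, f)
        if len(sense) < 6:
            raise ValueError(f"{f.name}: PCG shorter than 6 nt")
        calls.append(_call_for(f, sense))
    return calls


def validate_orf(record: GenomeRecord, gene: str) -> int:
    """Number of internal stop codons in a PCG (0 for a clean ORF).

    Translation uses the invertebrate mitochondrial code; the terminal
    complete or partial stop is excluded before translating.
    """
    feature = record.get(gene)
    if feature.gene_class != GeneClass.PCG:
        raise ValueError(f"{gene} is not a protein-coding gene")
    eff = feature_sequence(record, feature)[feature.frame_offset:]
    rem = len(eff) % 3
    if rem:
        eff = eff[:-rem]
    elif eff[-3:] in _STOPS:
        eff = eff[:-3]
    protein = str(Seq(eff).translate(table=INVERTEBRATE_MITO_TABLE))
    return protein.count("*")


# --- secondary-structure pair typing ----------------------------------------

_WC = {frozenset("AU"), frozenset("GC")}
_WOBBLE = frozenset("GU")


@dataclass
class PairTypeCounts:
    """Base-pair class census for one dot-bracket structure."""

    watson_crick: dict[str, int] = field(default_factory=dict)
    wobble: int = 0
    mismatches: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return (sum(self.watson_crick.values()) + self.wobble
                + sum(self.mismatches.values()))

    def mismatch_count(self, pair: str = None) -> int:
        if pair is None:
            return sum(self.mismatches.values())
        return self.mismatches.get(pair, 0)


def _pair_key(a: str, b: str) -> str:
    return "-".join(sorted((a, b)))


def count_pair_types(sequence: str, structure: str) -> PairTypeCounts:
    """Classify every paired position as Watson-Crick, G-U wobble or mismatch.

    ``sequence`` may be DNA or RNA (T is read as U); ``structure`` is a
    dot-bracket string of the same length using '(', ')' and '.'.
    """
    if len(sequence) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    rna = sequence.upper().replace("T", "U")
    counts = PairTypeCounts()
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {i}")
            j = stack.pop()
            a, b = rna[j], rna[i]
            key = _pair_key(a, b)
            pair = frozenset((a, b))
            if pair in _WC:
                counts.watson_crick[key] = counts.watson_crick.get(key, 0) + 1
            elif pair == _WOBBLE:
                counts.wobble += 1
            else:
                counts.mismatches[key] = counts.mismatches.get(key, 0) + 1
        elif ch != ".":
            raise ValueError(f"unexpected structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure: unclosed '('")
    return counts


def read_structure_file(path: str | Path) -> list[tuple[str, str, str]]:
    """Read "id <tab> sequence <tab> structure" records from a text file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ident, seq, struct = line.split("\t")
            out.append((ident, seq, struct))
    return out
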