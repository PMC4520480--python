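"""Strand-, gene-class- and codon-position-resolved composition statistics.

Every gene-class row is computed on the *sense* strand of each gene, then
concatenated — the only convention that reproduces the opposite GC-skew
signs of majority- vs minority-strand protein-coding genes. The whole-
genome row is computed on the deposited (J) strand.

Partial terminal codons are excluded from codon-position rows (a codon
position is undefined for an incomplete codon) but included in whole-PCG
composition; complete stop codons are included everywhere.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

from .annotation import CodonCall, classify_codons
from .model import GenomeRecord, feature_sequence
from .vocab import GeneClass, PCG_J_SET, PCG_N_SET

__all__ = [
    "BaseComposition", "CompositionProfile", "CodonUsageTable",
    "SpeciesAggregate", "base_composition", "skews", "profile_record",
    "codon_usage", "aggregate_species", "REGION_CLASSES",
]

REGION_CLASSES = (
    "PCG_J", "pos1_J", "pos2_J", "pos3_J",
    "PCG_N", "pos1_N", "pos2_N", "pos3_N",
    "tRNA", "rRNA_large", "rRNA_small", "CR", "whole_genome",
)


class BaseComposition(NamedTuple):
    a: float
    t: float
    g: float
    c: float
    at_percent: float
    gc_percent: float


def _counts(seq: str) -> tuple[int, int, int, int, int]:
    """(A, T, G, C, ambiguous) counts; U counts as T."""
    c = Counter(seq.upper())
    a, t, g, cc = c["A"], c["T"] + c["U"], c["G"], c["C"]
    ambiguous = sum(c.values()) - a - t - g - cc
    return a, t, g, cc, ambiguous


def base_composition(seq: str) -> BaseComposition:
    """Base fractions and A+T / G+C percentages over unambiguous bases."""
    if not seq:
        raise ValueError("empty sequence")
    a, t, g, c, _ = _counts(seq)
    n = a + t + g + c
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return BaseComposition(a / n, t / n, g / n, c / n,
                           100.0 * (a + t) / n, 100.0 * (g + c) / n)


def skews(seq: str) -> tuple[float | None, float | None]:
    """(AT-skew, GC-skew) = ((A-T)/(A+T), (G-C)/(G+C)); None on empty class."""
    a, t, g, c, _ = _counts(seq)
    at = (a - t) / (a + t) if a + t else None
    gc = (g - c) / (g + c) if g + c else None
    return at, gc


@dataclass(frozen=True)
class CompositionProfile:
    """One Table-2-style row block for a region class of one record."""

    label: str
    region_class: str
    a_count: int
    t_count: int
    g_count: int
    c_count: int
    ambiguous_count: int
    at_percent: float
    gc_percent: float
    at_skew: float | None
    gc_skew: float | None

    @property
    def total(self) -> int:
        return self.a_count + self.t_count + self.g_count + self.c_count


def _profile(label: str, region_class: str, seq: str) -> CompositionProfile:
    a, t, g, c, amb = _counts(seq)
    n = a + t + g + c
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionProfile(
        label, region_class, a, t, g, c, amb,
        100.0 * (a + t) / n if n else 0.0,
        100.0 * (g + c) / n if n else 0.0,
        at_skew, gc_skew)


def _coding_frame(record: GenomeRecord, feature) -> str:
    """Sense sequence trimmed to complete codons (partial stop dropped)."""
    eff = feature_sequence(record, feature)[feature.frame_offset:]
    rem = len(eff) % 3
    return eff[:-rem] if rem else eff


def profile_record(record: GenomeRecord) -> list[CompositionProfile]:
    """Compute every region-class composition row available for a record.

    Missing classes (no CR annotated, incomplete genome) are omitted with
    a warning, mirroring blank cells in published composition tables.
    """
    label = record.record_id
    strand_sets = (("J", [f for f in record.genes(GeneClass.PCG)
                          if f.name in PCG_J_SET]),
                   ("N", [f for f in record.genes(GeneClass.PCG)
                          if f.name in PCG_N_SET]))
    profiles: list[CompositionProfile] = []
    for tag, feats in strand_sets:
        if not feats:
            warnings.warn(f"{label}: no {tag}-strand PCGs annotated",
                          stacklevel=2)
            continue
        whole = "".join(feature_sequence(record, f) for f in feats)
        profiles.append(_profile(label, f"PCG_{tag}", whole))
        framed = [_coding_frame(record, f) for f in feats]
        for pos in (0, 1, 2):
            pooled = "".join(s[pos::3] for s in framed)
            profiles.append(_profile(label, f"pos{pos + 1}_{tag}", pooled))
    trnas = record.genes(GeneClass.TRNA)
    if trnas:
        profiles.append(_profile(
            label, "tRNA",
            "".join(feature_sequence(record, f) for f in trnas)))
    for name, cls in (("rrnL", "rRNA_large"), ("rrnS", "rRNA_small")):
        try:
            f = record.get(name)
        except KeyError:
            warnings.warn(f"{label}: {name} not annotated", stacklevel=2)
            continue
        profiles.append(_profile(label, cls, feature_sequence(record, f)))
    try:
        cr = record.get("CR")
    except KeyError:
        warnings.warn(f"{label}: no control region; CR row omitted",
                      stacklevel=2)
    else:
        profiles.append(_profile(label, "CR", feature_sequence(record, cr)))
    if record.is_complete:
        profiles.append(_profile(label, "whole_genome", record.sequence))
    else:
        warnings.warn(f"{label}: incomplete genome; whole-genome row omitted",
                      stacklevel=2)
    # stable presentation order
    rank = {c: i for i, c in enumerate(REGION_CLASSES)}
    profiles.sort(key=lambda p: rank[p.region_class])
    return profiles


# --- codon usage -------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Sense-strand codon counts per gene plus the genome-wide aggregate."""

    label: str
    per_gene: dict[str, dict[str, int]] = field(default_factory=dict)
    calls: list[CodonCall] = field(default_factory=list)

    @property
    def aggregate(self) -> dict[str, int]:
        total: Counter = Counter()
        for counts in self.per_gene.values():
            total.update(counts)
        return dict(total)

    def percentage(self, codon: str) -> float:
        agg = self.aggregate
        n = sum(agg.values())
        return 100.0 * agg.get(codon, 0) / n if n else 0.0

    def start_codon(self, gene: str) -> str:
        for call in self.calls:
            if call.gene == gene:
                return call.start_codon
        raise KeyError(gene)

    def stop_codon(self, gene: str) -> str | None:
        for call in self.calls:
            if call.gene == gene:
                return call.stop_codon
        raise KeyError(gene)


def codon_usage(record: GenomeRecord) -> CodonUsageTable:
    """Per-gene and aggregate codon counts (partial stops excluded).

    Per gene, the count total equals floor((length − frame_offset) / 3).
    """
    table = CodonUsageTable(record.record_id)
    table.calls = classify_codons(record)
    for f in record.genes(GeneClass.PCG):
        framed = _coding_frame(record, f)
        counts: Counter = Counter(
            framed[i:i + 3] for i in range(0, len(framed), 3))
        table.per_gene[f.name] = dict(counts)
    return table


# --- cross-species aggregation ----------------------------------------------

@dataclass(frozen=True)
class AggregateRow:
    region_class: str
    n: int
    at_percent: float
    gc_percent: float
    at_skew: float | None
    gc_skew: float | None


@dataclass
class SpeciesAggregate:
    """Unweighted cross-record means per region class and pooled positions."""

    rows: list[AggregateRow]
    pooled_position_at_percent: dict[str, float]
    n_records: int

    def row(self, region_class: str) -> AggregateRow:
        for r in self.rows:
            if r.region_class == region_class:
                return r
        raise KeyError(region_class)


def _mean(values: list[float]) -> float | None:
    vals = [v for v in values if v is not None]
    return sum(vals) / len(vals) if vals else None


def aggregate_species(per_record: list[list[CompositionProfile]]
                      ) -> SpeciesAggregate:
    """Average profiles across records (unweighted mean per metric).

    Also reports the per-codon-position A+T%% pooled over both strand
    classes (base counts summed within each record before the ratio).
    """
    if not per_record:
        raise ValueError("no profiles to aggregate")
    by_class: dict[str, list[CompositionProfile]] = {}
    for profiles in per_record:
        for p in profiles:
            by_class.setdefault(p.region_class, []).append(p)
    rows = []
    for cls in REGION_CLASSES:
        group = by_class.get(cls)
        if not group:
            continue
        rows.append(AggregateRow(
            cls, len(group),
            _mean([p.at_percent for p in group]),
            _mean([p.gc_percent for p in group]),
            _mean([p.at_skew for p in group]),
            _mean([p.gc_skew for p in group])))
    pooled: dict[str, float] = {}
    for pos in (1, 2, 3):
        per_rec_vals = []
        for profiles in per_record:
            sub = [p for p in profiles
                   if p.region_class in (f"pos{pos}_J", f"pos{pos}_N")]
            if not sub:
                continue
            at = sum(p.a_count + p.t_count for p in sub)
            tot = sum(p.total for p in sub)
            if tot:
                per_rec_vals.append(100.0 * at / tot)
        if per_rec_vals:
            pooled[f"pos{pos}"] = sum(per_rec_vals) / len(per_rec_vals)
    return SpeciesAggregate(rows, pooled, len(per_record))
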