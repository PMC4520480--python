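"""Internal data model: annotated genomes and per-gene alignments.

Coordinates are 0-based half-open on the J-strand (the deposited strand).
Features that wrap the circular origin are stored *unwrapped*, i.e. with
``end > len(sequence)``; :func:`feature_sequence` projects them back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .vocab import GeneClass, Strand, gene_class_of, ALL_TOKENS

__all__ = ["GeneFeature", "GenomeRecord", "AlignmentBlock",
           "reverse_complement", "feature_sequence"]

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a genome.

    ``start``/``end`` follow Python slice conventions on the J-strand;
    ``frame_offset`` is the reading-frame start offset (``codon_start - 1``
    in GenBank terms) and is meaningful for PCGs only.
    """

    name: str
    gene_class: GeneClass
    strand: Strand
    start: int
    end: int
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"{self.name}: invalid span [{self.start}, {self.end})")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"{self.name}: frame_offset {self.frame_offset}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_canonical(self) -> bool:
        return self.name in ALL_TOKENS


@dataclass
class GenomeRecord:
    """An annotated mitogenome: sequence, flags, ordered features."""

    record_id: str
    sequence: str
    is_circular: bool = True
    is_complete: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self._validate()

    def _validate(self) -> None:
        L = len(self.sequence)
        limit = 2 * L if self.is_circular else L
        seen: dict[str, GeneFeature] = {}
        for f in self.features:
            if f.end > limit:
                raise ValueError(
                    f"{self.record_id}: feature {f.name} span "
                    f"[{f.start}, {f.end}) outside sequence of length {L}")
            if f.end > L and not self.is_circular:
                raise ValueError(
                    f"{self.record_id}: wrap-around feature {f.name} on a "
                    "linear record")
            if f.is_canonical and f.name in seen:
                raise ValueError(
                    f"{self.record_id}: duplicate feature name {f.name}")
            seen[f.name] = f
        if self.is_complete:
            named = sum(1 for f in self.features
                        if f.is_canonical and f.name != "CR")
            if self.features and named not in (0, 37):
                warnings.warn(
                    f"{self.record_id}: complete record annotates {named} "
                    "canonical genes (expected 37)", stacklevel=3)

    def __len__(self) -> int:
        return len(self.sequence)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def genes(self, gene_class: GeneClass | None = None) -> list[GeneFeature]:
        if gene_class is None:
            return list(self.features)
        return [f for f in self.features if f.gene_class == gene_class]

    def rotated(self, offset: int) -> "GenomeRecord":
        """Rotate the circular origin by ``offset`` bases (testing aid)."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear record")
        L = len(self.sequence)
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            start = (f.start - offset) % L
            feats.append(replace(f, start=start, end=start + len(f)))
        return GenomeRecord(self.record_id, seq, self.is_circular,
                            self.is_complete, feats)


def feature_sequence(record: GenomeRecord, feature: GeneFeature) -> str:
    """Sense-strand nucleotide sequence of a feature.

    Handles unwrapped circular spans; N-strand features are
    reverse-complemented so the result reads 5'→3' on the coding strand.
    """
    L = len(record.sequence)
    if feature.end <= L:
        raw = record.sequence[feature.start:feature.end]
    else:
        raw = record.sequence[feature.start:] + record.sequence[:feature.end - L]
    return raw if feature.strand == Strand.J else reverse_complement(raw)


def make_feature(name: str, strand: Strand | str, start: int, end: int,
                 frame_offset: int = 0,
                 gene_class: GeneClass | None = None) -> GeneFeature:
    """Convenience constructor inferring the gene class from the name."""
    if gene_class is None:
        gene_class = gene_class_of(name)
    return GeneFeature(name, gene_class, Strand(strand), start, end,
                       frame_offset)


@dataclass
class AlignmentBlock:
    """A per-gene multiple alignment (rows over a shared taxon set)."""

    gene_name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.gene_name}: duplicate taxon labels")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError(f"{self.gene_name}: ragged alignment rows")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]
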