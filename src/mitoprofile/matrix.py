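"""Concatenated phylogenetic datasets from per-gene alignments.

Four schemes are supported: PCG123 and PCG12 (all 13 protein-coding genes
with or without third codon positions) and their RNA-extended variants
(plus 22 tRNA and 2 rRNA blocks). Each emitted matrix carries a charset
map — one partition per codon position per PCG and one per RNA gene — in
the notation shared by NEXUS sets blocks and RAxML partition files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .model import AlignmentBlock
from .vocab import ANCESTRAL_INSECT_ORDER, GeneClass, gene_class_of

__all__ = [
    "SCHEMES", "Charset", "Supermatrix", "concatenate",
    "drop_third_positions", "mask_ambiguous_columns", "export",
    "parse_nexus_charsets",
]

SCHEMES = ("PCG123", "PCG123RNA", "PCG12", "PCG12RNA")

_GAPS = {"-", "?"}

#: concatenation rank: PCGs in ancestral-order rank, then tRNAs, then rRNAs
_CLASS_RANK = {GeneClass.PCG: 0, GeneClass.TRNA: 1, GeneClass.RRNA: 2}
_ORDER_RANK = {name: i for i, (name, _) in enumerate(ANCESTRAL_INSECT_ORDER)}


@dataclass(frozen=True)
class Charset:
    """A named partition: 1-based inclusive column intervals with a stride."""

    label: str
    intervals: tuple[tuple[int, int, int], ...]  # (start, end, step)

    def columns(self) -> list[int]:
        out = []
        for start, end, step in self.intervals:
            out.extend(range(start, end + 1, step))
        return out

    def spec(self) -> str:
        parts = []
        for start, end, step in self.intervals:
            s = f"{start}-{end}"
            if step != 1:
                s += f"\\{step}"
            parts.append(s)
        return " ".join(parts)


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    charsets: list[Charset]
    scheme: str

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def charset(self, label: str) -> Charset:
        for cs in self.charsets:
            if cs.label == label:
                return cs
        raise KeyError(label)

    def check_tiling(self) -> None:
        """Every column must belong to exactly one partition."""
        seen: list[int] = []
        for cs in self.charsets:
            seen.extend(cs.columns())
        if sorted(seen) != list(range(1, self.length + 1)):
            raise AssertionError("charsets do not tile the matrix")


def drop_third_positions(block: AlignmentBlock) -> AlignmentBlock:
    """Remove every third codon position (alignment assumed in frame)."""
    if block.length % 3:
        raise ValueError(
            f"{block.gene_name}: length {block.length} not divisible by 3")
    keep = [i for i in range(block.length) if i % 3 != 2]
    rows = ["".join(r[i] for i in keep) for r in block.rows]
    return AlignmentBlock(block.gene_name, list(block.taxa), rows)


def mask_ambiguous_columns(block: AlignmentBlock,
                           max_gap_fraction: float = 1.0) -> AlignmentBlock:
    """Drop columns whose gap fraction exceeds the threshold (default: none)."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be within [0, 1]")
    n = len(block.rows)
    keep = []
    for i in range(block.length):
        gaps = sum(1 for r in block.rows if r[i] in _GAPS)
        if gaps / n <= max_gap_fraction:
            keep.append(i)
    rows = ["".join(r[i] for i in keep) for r in block.rows]
    return AlignmentBlock(block.gene_name, list(block.taxa), rows)


def _block_rank(block: AlignmentBlock) -> tuple[int, int]:
    cls = gene_class_of(block.gene_name)
    return _CLASS_RANK[cls], _ORDER_RANK[block.gene_name]


def concatenate(blocks: list[AlignmentBlock], scheme: str, *,
                fill_missing: bool = False) -> Supermatrix:
    """Concatenate per-gene blocks into a supermatrix under a scheme.

    Blocks are reordered canonically; RNA blocks are ignored by the
    PCG-only schemes. With ``fill_missing``, taxa absent from a block are
    padded with gaps; otherwise all blocks must share one taxon set.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    include_rna = scheme.endswith("RNA")
    drop3 = scheme in ("PCG12", "PCG12RNA")
    chosen = []
    for b in blocks:
        cls = gene_class_of(b.gene_name)
        if cls == GeneClass.CR:
            raise ValueError("control region blocks are not alignable input")
        if cls in (GeneClass.TRNA, GeneClass.RRNA) and not include_rna:
            continue
        if cls == GeneClass.PCG and b.length % 3:
            raise ValueError(
                f"{b.gene_name}: PCG alignment length {b.length} not "
                "divisible by 3")
        chosen.append(b)
    if not chosen:
        raise ValueError("no alignment blocks after scheme filtering")
    chosen.sort(key=_block_rank)

    taxa = list(chosen[0].taxa)
    taxon_set = set(taxa)
    for b in chosen[1:]:
        extra = [t for t in b.taxa if t not in taxon_set]
        if (extra or set(b.taxa) != taxon_set) and not fill_missing:
            raise ValueError(
                f"{b.gene_name}: taxon set differs (use fill_missing to pad)")
        for t in extra:
            taxa.append(t)
            taxon_set.add(t)

    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    charsets: list[Charset] = []
    offset = 0
    for b in chosen:
        cls = gene_class_of(b.gene_name)
        eff = drop_third_positions(b) if (drop3 and cls == GeneClass.PCG) else b
        for t in taxa:
            if t in b.taxa:
                pieces[t].append(eff.row(t))
            else:
                pieces[t].append("-" * eff.length)
        start, end = offset + 1, offset + eff.length
        if cls == GeneClass.PCG:
            npos = 2 if drop3 else 3
            for k in range(npos):
                charsets.append(Charset(
                    f"{b.gene_name}_pos{k + 1}",
                    ((start + k, end, npos),)))
        else:
            charsets.append(Charset(b.gene_name, ((start, end, 1),)))
        offset = end
    rows = ["".join(pieces[t]) for t in taxa]
    matrix = Supermatrix(taxa, rows, charsets, scheme)
    matrix.check_tiling()
    return matrix


# --- export ------------------------------------------------------------------

def _sanitize(label: str) -> str:
    return re.sub(r"[\s,;:()\[\]]+", "_", label)


def export(matrix: Supermatrix, out_dir: str | Path, basename: str) -> dict[str, Path]:
    """Write FASTA, relaxed PHYLIP, NEXUS sets block, RAxML partition file
    and a PartitionFinder configuration stub. Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clean = [_sanitize(t) for t in matrix.taxa]
    if len(set(clean)) != len(clean):
        raise ValueError("taxon labels collide after PHYLIP sanitation")
    paths = {}

    fasta = out_dir / f"{basename}.fasta"
    with open(fasta, "w") as fh:
        for taxon, row in zip(matrix.taxa, matrix.rows):
            fh.write(f">{taxon}\n{row}\n")
    paths["fasta"] = fasta

    phylip = out_dir / f"{basename}.phy"
    with open(phylip, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.length}\n")
        for taxon, row in zip(clean, matrix.rows):
            fh.write(f"{taxon}  {row}\n")
    paths["phylip"] = phylip

    nexus = out_dir / f"{basename}.charsets.nex"
    with open(nexus, "w") as fh:
        fh.write("#NEXUS\nbegin sets;\n")
        for cs in matrix.charsets:
            fh.write(f"    charset {cs.label} = {cs.spec()};\n")
        fh.write("end;\n")
    paths["nexus"] = nexus

    raxml = out_dir / f"{basename}.partitions.txt"
    with open(raxml, "w") as fh:
        for cs in matrix.charsets:
            fh.write(f"DNA, {cs.label} = {cs.spec()}\n")
    paths["raxml"] = raxml

    cfg = out_dir / f"{basename}.partition_finder.cfg"
    with open(cfg, "w") as fh:
        fh.write(f"alignment = {basename}.phy;\n")
        fh.write("branchlengths = unlinked;\n")
        fh.write("models = all;\n")
        fh.write("model_selection = BIC;\n\n[data_blocks]\n")
        for cs in matrix.charsets:
            fh.write(f"{cs.label} = {cs.spec()};\n")
        fh.write("\n[schemes]\nsearch = greedy;\n")
    paths["cfg"] = cfg
    return paths


_CHARSET_RE = re.compile(r"charset\s+(\S+)\s*=\s*([^;]+);", re.IGNORECASE)
_INTERVAL_RE = re.compile(r"(\d+)-(\d+)(?:\\(\d+))?")


def parse_nexus_charsets(path: str | Path) -> dict[str, tuple[tuple[int, int, int], ...]]:
    """Re-read a NEXUS sets block into a charset map (round-trip aid)."""
    text = Path(path).read_text()
    out = {}
    for label, body in _CHARSET_RE.findall(text):
        intervals = tuple(
            (int(s), int(e), int(step) if step else 1)
            for s, e, step in _INTERVAL_RE.findall(body))
        out[label] = intervals
    return out
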