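"""Readers and writers for annotated mitogenomes and reports.

GenBank flat files and FASTA are handled through Biopython; the plain
feature-table dialect (TSV: name, start, end, strand in 1-based inclusive
coordinates) mirrors the gene-organization tables distributed with
mitogenome papers.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import AlignmentBlock, GeneFeature, GenomeRecord
from .vocab import (GeneClass, Strand, UNKNOWN, canonicalize_gene_name,
                    gene_class_of)

__all__ = [
    "read_genbank", "read_feature_table", "write_feature_table",
    "read_gene_alignment", "write_profile_report", "write_junction_report",
    "write_codon_report", "write_genbank", "write_fasta",
]

_KEY_TO_CLASS = {
    "CDS": GeneClass.PCG,
    "tRNA": GeneClass.TRNA,
    "rRNA": GeneClass.RRNA,
    "D-loop": GeneClass.CR,
    "misc_feature": GeneClass.CR,
}


def _feature_label(qualifiers: dict) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        for value in qualifiers.get(key, []):
            if value:
                return value
    return ""


def _span_of(location, genome_length: int) -> tuple[int, int]:
    """0-based half-open span; origin-spanning joins are unwrapped."""
    if isinstance(location, CompoundLocation):
        parts = sorted(location.parts, key=lambda p: int(p.start))
        if (len(parts) == 2 and int(parts[1].end) == genome_length
                and int(parts[0].start) == 0):
            return int(parts[1].start), genome_length + int(parts[0].end)
    return int(location.start), int(location.end)


def read_genbank(path: str | Path, *, is_complete: bool | None = None) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    Gene labels are resolved through the synonym table; features whose
    label cannot be canonicalized are retained under their raw label with
    the gene class inferred from the feature key, and a warning is issued.
    """
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
    sequence = str(seqrec.seq).upper()
    circular = seqrec.annotations.get("topology", "") == "circular"
    if is_complete is None:
        desc = (seqrec.description or "").lower()
        if "partial" in desc or "nearly complete" in desc:
            is_complete = False
        else:
            is_complete = circular
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for f in seqrec.features:
        if f.type not in _KEY_TO_CLASS:
            continue
        label = _feature_label(f.qualifiers)
        name = canonicalize_gene_name(label)
        if name == UNKNOWN:
            warnings.warn(
                f"{seqrec.id}: cannot canonicalize {f.type} label {label!r}; "
                "keeping raw name", stacklevel=2)
            name = label or f"{f.type}@{int(f.location.start)}"
            gene_class = _KEY_TO_CLASS[f.type]
        else:
            if name in seen:
                continue  # duplicate annotation (e.g. gene + CDS pair)
            gene_class = gene_class_of(name)
        seen.add(name)
        start, end = _span_of(f.location, len(sequence))
        strand = Strand.N if f.location.strand == -1 else Strand.J
        frame = 0
        if gene_class == GeneClass.PCG:
            cs = f.qualifiers.get("codon_start", ["1"])[0]
            frame = int(cs) - 1
        features.append(GeneFeature(name, gene_class, strand, start, end, frame))
    return GenomeRecord(seqrec.id or str(path), sequence, circular,
                        is_complete, features)


def _read_fasta_single(path: str | Path) -> tuple[str, str]:
    rec = SeqIO.read(str(path), "fasta")
    return rec.id, str(rec.seq).upper()


def read_feature_table(path: str | Path, fasta: str | Path, *,
                       is_circular: bool = False,
                       is_complete: bool | None = None) -> GenomeRecord:
    """Read a TSV gene table (name, start, end, strand; 1-based inclusive)
    paired with a FASTA sequence.

    ``end < start`` on a circular record denotes a wrap-around feature.
    """
    record_id, sequence = _read_fasta_single(fasta)
    L = len(sequence)
    features: list[GeneFeature] = []
    names: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and not row[1].strip().lstrip("-").isdigit():
                continue  # header line
            raw_name, s, e, strand_txt = (c.strip() for c in row[:4])
            frame = int(row[4]) if len(row) > 4 and row[4].strip() else 0
            start1, end1 = int(s), int(e)
            strand = Strand.J if strand_txt in ("J", "+", "1") else Strand.N
            name = canonicalize_gene_name(raw_name)
            if name == UNKNOWN:
                warnings.warn(f"unrecognized gene name {raw_name!r}",
                              stacklevel=2)
                name = raw_name
                gene_class = GeneClass.CR
            else:
                gene_class = gene_class_of(name)
            if name in names:
                raise ValueError(f"duplicate gene name {name} in {path}")
            names.add(name)
            if not (1 <= start1 <= L) or end1 > L or end1 < 1:
                raise ValueError(
                    f"{name}: coordinates ({start1}, {end1}) outside "
                    f"sequence of length {L}")
            start, end = start1 - 1, end1
            if end <= start:
                if not is_circular:
                    raise ValueError(
                        f"{name}: end < start on a non-circular record")
                end += L
            features.append(
                GeneFeature(name, gene_class, strand, start, end, frame))
    if is_complete is None:
        is_complete = is_circular
    return GenomeRecord(record_id, sequence, is_circular, is_complete, features)


def write_feature_table(record: GenomeRecord, path: str | Path) -> None:
    """Export features as the 1-based inclusive TSV dialect."""
    L = len(record.sequence)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "start", "end", "strand", "frame"])
        for f in record.features:
            end1 = f.end if f.end <= L else f.end - L
            writer.writerow([f.name, f.start + 1, end1, f.strand.value,
                             f.frame_offset])


def read_gene_alignment(path: str | Path, gene_name: str | None = None) -> AlignmentBlock:
    """Read an aligned FASTA file as one per-gene alignment block."""
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not taxa:
        raise ValueError(f"no sequences in {path}")
    if gene_name is None:
        gene_name = Path(path).stem
    return AlignmentBlock(gene_name, taxa, rows)


# --- report writers ----------------------------------------------------------

def _rows_of(profile) -> list[dict]:
    d = dataclasses.asdict(profile)
    label = d.pop("label", "")
    region = d.pop("region_class")
    rows = []
    for metric, value in d.items():
        display = value
        if isinstance(value, float):
            nd = 1 if metric.endswith("percent") else 3
            display = round(value, nd)
        rows.append({"label": label, "region_class": region,
                     "metric": metric, "value": value, "display": display})
    return rows


def write_profile_report(profiles, tsv_path: str | Path,
                         json_path: str | Path | None = None) -> None:
    """Write composition profiles as twin TSV/JSON reports.

    One TSV row per (region class, metric), full precision plus a rounded
    display column; the JSON twin carries the same values.
    """
    tsv_path = Path(tsv_path)
    if json_path is None:
        json_path = tsv_path.with_suffix(".json")
    rows = [r for p in profiles for r in _rows_of(p)]
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["label", "region_class", "metric", "value",
                            "display"],
            delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    with open(json_path, "w") as fh:
        json.dump(rows, fh, indent=1, default=str)
        fh.write("\n")


def write_junction_report(report, path: str | Path) -> None:
    data = dataclasses.asdict(report)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, default=str)
        fh.write("\n")


def write_codon_report(calls, path: str | Path) -> None:
    data = [dataclasses.asdict(c) for c in calls]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, default=str)
        fh.write("\n")


_CLASS_TO_KEY = {
    GeneClass.PCG: "CDS",
    GeneClass.TRNA: "tRNA",
    GeneClass.RRNA: "rRNA",
    GeneClass.CR: "D-loop",
}


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Write a GenBank-like flat file (round-trips through read_genbank)."""
    L = len(record.sequence)
    seqrec = SeqRecord(Seq(record.sequence), id=record.record_id,
                       name=record.record_id[:16].replace(" ", "_"),
                       description=("complete genome" if record.is_complete
                                    else "nearly complete genome"))
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = ("circular" if record.is_circular
                                      else "linear")
    for f in record.features:
        strand = 1 if f.strand == Strand.J else -1
        if f.end <= L:
            loc = SimpleLocation(f.start, f.end, strand)
        else:
            parts = [SimpleLocation(f.start, L, strand),
                     SimpleLocation(0, f.end - L, strand)]
            if strand == -1:
                parts.reverse()
            loc = CompoundLocation(parts)
        quals = {"gene": [f.name]}
        if f.gene_class == GeneClass.PCG:
            quals["codon_start"] = [str(f.frame_offset + 1)]
        seqrec.features.append(
            SeqFeature(loc, type=_CLASS_TO_KEY[f.gene_class],
                       qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def write_fasta(record: GenomeRecord, path: str | Path) -> None:
    seqrec = SeqRecord(Seq(record.sequence), id=record.record_id,
                       description="")
    SeqIO.write([seqrec], str(path), "fasta")
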