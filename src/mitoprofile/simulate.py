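"""Synthetic annotated mitogenome generator with ground-truth manifests.

Emits circular 37-gene insect mitogenomes in the ancestral arrangement
with controlled per-class composition (A+T%, AT/GC skews), exact junction
structure, and specified start/stop codons. Protein-coding genes are
drawn codon-by-codon with in-frame stops rejected, so every simulated ORF
translates cleanly under the invertebrate mitochondrial code.

All randomness flows through one integer-state ``random.Random`` seeded
explicitly; draws use integer ranges only, so output is byte-identical
across platforms for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .annotation import CodonCall, JunctionEntry, classify_codons, junctions
from .model import (GeneFeature, GenomeRecord, feature_sequence,
                    reverse_complement)
from .vocab import (ANCESTRAL_INSECT_ORDER, GeneClass, Strand, PCG_J_SET,
                    gene_class_of)

__all__ = ["SimulationParams", "Manifest", "SimulationError",
           "simulate_genome", "degrade", "TA_REPEAT_SPACER",
           "DEFAULT_GENE_LENGTHS", "DEFAULT_COMPOSITION"]


class SimulationError(ValueError):
    """Raised when a junction/codon specification cannot be realized."""


#: 27-bp microsatellite-like TA-repeat spacer placed between trnS1 and trnE.
TA_REPEAT_SPACER = "GATATAAATTATATATATATATATATA"

_STOPS = ("TAA", "TAG")

#: default gene lengths (bp); PCG lengths are consistent with the default
#: stop spec (complete TAA needs length % 3 == 0, partial T needs % 3 == 1).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND2": 1023, "COX1": 1536, "COX2": 688, "ATP8": 162, "ATP6": 675,
    "COX3": 789, "ND3": 354, "ND5": 1720, "ND4": 1341, "ND4L": 291,
    "ND6": 525, "CYTB": 1137, "ND1": 939,
    "rrnL": 1325, "rrnS": 786, "CR": 1042,
    "trnI": 66, "trnQ": 69, "trnM": 68, "trnW": 67, "trnC": 64,
    "trnY": 66, "trnL2": 66, "trnK": 71, "trnD": 68, "trnG": 65,
    "trnA": 64, "trnR": 65, "trnN": 66, "trnS1": 67, "trnE": 66,
    "trnF": 65, "trnH": 66, "trnT": 64, "trnP": 65, "trnS2": 68,
    "trnL1": 64, "trnV": 72,
}

#: per-class (A+T %, AT-skew, GC-skew) targets, muscoid-like.
DEFAULT_COMPOSITION: dict[str, tuple[float, float, float]] = {
    "PCG_J": (74.3, -0.12, -0.09),
    "PCG_N": (78.9, -0.19, 0.25),
    "tRNA": (77.0, -0.01, 0.11),
    "rRNA": (81.0, -0.03, 0.30),
    "CR": (89.7, 0.04, -0.17),
}

#: default inter-gene gaps keyed by (upstream, downstream); an int is a gap
#: in bp (negative = overlap), a string is a literal spacer sequence.
DEFAULT_JUNCTIONS: dict[tuple[str, str], int | str] = {
    ("ATP8", "ATP6"): -7,
    ("trnS1", "trnE"): TA_REPEAT_SPACER,
    ("trnE", "trnF"): 18,
}

DEFAULT_STARTS: dict[str, str] = {
    "ND2": "ATT", "COX1": "TCG", "COX2": "ATG", "ATP8": "ATC",
    "ATP6": "ATG", "COX3": "ATG", "ND3": "ATT", "ND5": "ATT",
    "ND4": "ATG", "ND4L": "ATG", "ND6": "ATT", "CYTB": "ATG",
    "ND1": "TTG",
}

DEFAULT_STOPS: dict[str, str] = {
    "ND2": "TAA", "COX1": "TAA", "COX2": "T", "ATP8": "TAA",
    "ATP6": "TAA", "COX3": "TAA", "ND3": "TAA", "ND5": "T",
    "ND4": "TAA", "ND4L": "TAA", "ND6": "TAA", "CYTB": "TAA",
    "ND1": "TAA",
}


@dataclass
class SimulationParams:
    seed: int
    gene_order: tuple[tuple[str, Strand], ...] = ANCESTRAL_INSECT_ORDER
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    composition: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    junction_spec: dict[tuple[str, str], int | str] = field(
        default_factory=lambda: dict(DEFAULT_JUNCTIONS))
    start_spec: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STARTS))
    stop_spec: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STOPS))
    include_cr: bool = True
    genome_length_target: int | None = None
    record_id: str = ""


@dataclass
class Manifest:
    """Ground truth for a simulated genome."""

    seed: int
    genome_length: int
    is_circular: bool
    is_complete: bool
    features: list[GeneFeature]
    junctions: list[JunctionEntry]
    codon_calls: list[CodonCall]
    composition: dict[str, tuple[float, float | None, float | None]]


# --- base drawing ------------------------------------------------------------

_SCALE = 1_000_000


def _weights(at_percent: float, at_skew: float, gc_skew: float
             ) -> tuple[tuple[str, int], ...]:
    at = at_percent / 100.0
    gc = 1.0 - at
    probs = (
        ("A", at * (1 + at_skew) / 2), ("T", at * (1 - at_skew) / 2),
        ("G", gc * (1 + gc_skew) / 2), ("C", gc * (1 - gc_skew) / 2),
    )
    ints = [(b, round(p * _SCALE)) for b, p in probs]
    drift = _SCALE - sum(w for _, w in ints)
    ints[0] = (ints[0][0], ints[0][1] + drift)  # keep the total exact
    if any(w < 0 for _, w in ints):
        raise SimulationError("composition targets are not valid probabilities")
    return tuple(ints)


def _draw(rng: random.Random, weights) -> str:
    r = rng.randrange(_SCALE)
    acc = 0
    for base, w in weights:
        acc += w
        if r < acc:
            return base
    return weights[-1][0]


def _gen_seq(rng: random.Random, weights, length: int) -> str:
    return "".join(_draw(rng, weights) for _ in range(length))


def _gen_pcg(rng: random.Random, weights, length: int, start: str,
             stop: str) -> str:
    tail = len(stop) if stop in ("T", "TA") else 3
    middle = length - 3 - tail
    if middle < 0 or middle % 3:
        raise SimulationError(
            f"gene length {length} incompatible with start {start!r} / "
            f"stop {stop!r}")
    codons = []
    for _ in range(middle // 3):
        while True:
            codon = _draw(rng, weights) + _draw(rng, weights) + _draw(rng, weights)
            if codon not in _STOPS:
                break
        codons.append(codon)
    terminal = stop if tail < 3 else (stop if stop in _STOPS else "TAA")
    return start + "".join(codons) + terminal


# --- assembly ----------------------------------------------------------------

def _class_key(name: str, strand: Strand) -> str:
    cls = gene_class_of(name)
    if cls == GeneClass.PCG:
        return "PCG_J" if name in PCG_J_SET else "PCG_N"
    if cls == GeneClass.TRNA:
        return "tRNA"
    if cls == GeneClass.RRNA:
        return "rRNA"
    return "CR"


def _gap_of(params: SimulationParams, up: str, down: str) -> tuple[int, str | None]:
    spec = params.junction_spec.get((up, down), 0)
    if isinstance(spec, str):
        return len(spec), spec
    return int(spec), None


def _resolve_cr_length(params: SimulationParams,
                       order: list[tuple[str, Strand]]) -> dict[str, int]:
    lengths = dict(params.gene_lengths)
    if params.genome_length_target is None:
        return lengths
    other = 0
    names = [n for n, _ in order]
    for i, name in enumerate(names):
        if name != "CR":
            other += lengths[name]
        gap, _ = _gap_of(params, names[i - 1], name)
        other += gap
    cr = params.genome_length_target - other
    if "CR" in names:
        if cr < 50:
            raise SimulationError(
                "genome_length_target leaves no room for a control region")
        lengths["CR"] = cr
    return lengths


def _anchor_positions(feature: GeneFeature,
                      spec: tuple[str | None, str | None]) -> set[int]:
    """J-strand positions pinned by a PCG's start/stop codon specification."""
    start_c, stop_c = spec
    if start_c is None:
        return set()
    L = len(feature)
    tail = len(stop_c) if stop_c in ("T", "TA") else 3
    sense_idx = set(range(3)) | set(range(L - tail, L))
    if feature.strand == Strand.J:
        return {feature.start + i for i in sense_idx}
    return {feature.end - 1 - i for i in sense_idx}


def _first_bad_codon(sense: str, spec: tuple[str | None, str | None]
                     ) -> int | None:
    """Sense index of the first internal stop codon, or None."""
    _, stop_c = spec
    tail = len(stop_c) if stop_c in ("T", "TA") else 3
    body = sense[:len(sense) - tail]
    body = body[:len(body) - len(body) % 3]
    for i in range(3, len(body), 3):
        if body[i:i + 3] in _STOPS:
            return i
    return None


def _repair_overlap(rng: random.Random, genome: str, up: GeneFeature,
                    down: GeneFeature,
                    specs: dict[str, tuple[str | None, str | None]],
                    gene_weights) -> str:
    """Redraw free bases until neither flanking gene has an internal stop.

    Sharing bases across an overlap can create a stop in one gene's frame
    (e.g. an imposed start codon completing a TA- prefix to TAA). Bases not
    pinned by either gene's codon anchors are redrawn deterministically.
    """
    anchors = (_anchor_positions(up, specs[up.name])
               | _anchor_positions(down, specs[down.name]))
    seq = list(genome)
    for _ in range(2000):
        bad = None
        for f in (up, down):
            if specs[f.name][0] is None:
                continue
            raw = "".join(seq[f.start:f.end])
            sense = raw if f.strand == Strand.J else reverse_complement(raw)
            i = _first_bad_codon(sense, specs[f.name])
            if i is not None:
                bad = (f, i)
                break
        if bad is None:
            return "".join(seq)
        f, i = bad
        if f.strand == Strand.J:
            jpos = [f.start + i + k for k in range(3)]
        else:
            jpos = [f.end - 1 - (i + k) for k in range(3)]
        free = [p for p in jpos if p not in anchors]
        if not free:
            raise SimulationError(
                f"{f.name}: internal stop pinned by overlapping anchors")
        for p in free:
            base = _draw(rng, gene_weights[f.name])
            seq[p] = base if f.strand == Strand.J else reverse_complement(base)
    raise SimulationError(f"could not reconcile overlap {up.name}/{down.name}")


def _check_gene(genome: str, feature: GeneFeature, start: str | None,
                stop: str | None) -> None:
    """Verify codon anchors and ORF cleanliness after overlap resolution."""
    if feature.gene_class != GeneClass.PCG:
        return
    raw = genome[feature.start:feature.end]
    sense = raw if feature.strand == Strand.J else reverse_complement(raw)
    if start and not sense.startswith(start):
        raise SimulationError(f"{feature.name}: start codon clobbered")
    tail = len(stop) if stop in ("T", "TA") else 3
    if stop and not sense.endswith(stop if tail < 3 else stop):
        raise SimulationError(f"{feature.name}: stop codon clobbered")
    body = sense[:-tail] if tail else sense
    body = body[:len(body) - len(body) % 3]
    for i in range(3, len(body) - 2, 3):
        if body[i:i + 3] in _STOPS:
            raise SimulationError(f"{feature.name}: internal stop introduced")


def simulate_genome(params: SimulationParams) -> tuple[GenomeRecord, Manifest]:
    """Generate one annotated genome plus its ground-truth manifest.

    Overlap junctions share bases: the upstream gene's tail is kept and the
    downstream gene's codon anchors are re-imposed on the shared window,
    then both genes are re-validated; an irreconcilable specification
    raises :class:`SimulationError`.
    """
    rng = random.Random(params.seed)
    order = [(n, s) for n, s in params.gene_order
             if params.include_cr or n != "CR"]
    lengths = _resolve_cr_length(params, order)
    weights = {key: _weights(*vals) for key, vals in params.composition.items()}
    cr_weights = weights.get("CR", weights["tRNA"])

    genome = ""
    features: list[GeneFeature] = []
    sense_specs: dict[str, tuple[str | None, str | None]] = {}
    prev_name = None
    for name, strand in order:
        L_g = lengths[name]
        cls = gene_class_of(name)
        if prev_name is None:
            gap, literal = 0, None
        else:
            gap, literal = _gap_of(params, prev_name, name)
        start_pos = len(genome) + gap
        if start_pos < 0:
            raise SimulationError(f"overlap before origin at {name}")
        if cls == GeneClass.PCG:
            start_c = params.start_spec.get(name, "ATT")
            stop_c = params.stop_spec.get(name, "TAA")
            sense = _gen_pcg(rng, weights[_class_key(name, strand)], L_g,
                             start_c, stop_c)
            sense_specs[name] = (start_c, stop_c)
        else:
            sense = _gen_seq(rng, weights[_class_key(name, strand)], L_g)
            sense_specs[name] = (None, None)
        jproj = sense if strand == Strand.J else reverse_complement(sense)
        if gap > 0:
            genome += literal if literal is not None else _gen_seq(
                rng, cr_weights, gap)
        elif gap < 0:
            k = -gap
            if prev_name and k >= min(L_g, lengths[prev_name]):
                raise SimulationError(
                    f"overlap {k} bp swallows {prev_name} or {name}")
            # upstream tail wins the shared window, then this gene's codon
            # anchors are re-imposed on top of it
            shared = genome[start_pos:]
            jproj = shared + jproj[k:]
            if cls == GeneClass.PCG:
                anchored = jproj if strand == Strand.J else reverse_complement(jproj)
                start_c, stop_c = sense_specs[name]
                tail = len(stop_c) if stop_c in ("T", "TA") else 3
                anchored = start_c + anchored[3:]
                anchored = anchored[:L_g - tail] + (
                    stop_c if tail < 3 else stop_c)
                jproj = (anchored if strand == Strand.J
                         else reverse_complement(anchored))
            genome = genome[:start_pos]
        feature = GeneFeature(name, cls if cls != GeneClass.CR else GeneClass.CR,
                              strand, start_pos, start_pos + L_g)
        genome += jproj
        features.append(feature)
        if gap < 0:
            up, down = features[-2], features[-1]
            gene_weights = {
                g.name: weights[_class_key(g.name, g.strand)]
                for g in (up, down)}
            genome = _repair_overlap(rng, genome, up, down, sense_specs,
                                     gene_weights)
            # both flanks must satisfy their codon specs exactly
            for f in (up, down):
                _check_gene(genome, f, *sense_specs[f.name])
        prev_name = name

    # wrap junction (last gene back to the first) closes the circle
    if params.include_cr:
        wrap_gap, wrap_literal = _gap_of(params, order[-1][0], order[0][0])
        if wrap_gap < 0:
            raise SimulationError("overlap across the origin is not supported")
        if wrap_gap > 0:
            genome += (wrap_literal if wrap_literal is not None
                       else _gen_seq(rng, cr_weights, wrap_gap))

    record = GenomeRecord(
        params.record_id or f"sim_seed{params.seed}",
        genome,
        is_circular=params.include_cr,
        is_complete=params.include_cr,
        features=features)
    manifest = _build_manifest(params, record)
    return record, manifest


def _realized_composition(record: GenomeRecord
                          ) -> dict[str, tuple[float, float | None, float | None]]:
    from .composition import base_composition, skews  # local: avoid cycle
    groups: dict[str, list[str]] = {}
    for f in record.features:
        groups.setdefault(_class_key(f.name, f.strand), []).append(
            feature_sequence(record, f))
    out = {}
    for key, seqs in groups.items():
        pooled = "".join(seqs)
        bc = base_composition(pooled)
        at_skew, gc_skew = skews(pooled)
        out[key] = (bc.at_percent, at_skew, gc_skew)
    return out


def _build_manifest(params: SimulationParams, record: GenomeRecord) -> Manifest:
    return Manifest(
        seed=params.seed,
        genome_length=len(record.sequence),
        is_circular=record.is_circular,
        is_complete=record.is_complete,
        features=list(record.features),
        junctions=list(junctions(record, include_cr=True).entries),
        codon_calls=classify_codons(record),
        composition=_realized_composition(record),
    )


def degrade(record: GenomeRecord, manifest: Manifest, mode: str
            ) -> tuple[GenomeRecord, Manifest]:
    """Produce a near-complete record (unsequenced control region).

    ``drop_cr`` excises the CR and linearizes; ``truncate_ends``
    additionally trims residual non-genic bases at both ends.
    """
    if mode not in ("drop_cr", "truncate_ends"):
        raise ValueError(f"unknown degrade mode {mode!r}")
    try:
        cr = record.get("CR")
    except KeyError as exc:
        raise ValueError("record has no control region to drop") from exc
    L = len(record.sequence)
    rotated = record.rotated(cr.end % L) if record.is_circular else record
    cr = rotated.get("CR")
    sequence = rotated.sequence[:cr.start]
    feats = [f for f in rotated.features if f.name != "CR"]
    if mode == "truncate_ends" and feats:
        lo = min(f.start for f in feats)
        hi = max(f.end for f in feats)
        sequence = sequence[lo:hi]
        feats = [replace(f, start=f.start - lo, end=f.end - lo) for f in feats]
    degraded = GenomeRecord(record.record_id + "_nearcomplete", sequence,
                            is_circular=False, is_complete=False,
                            features=feats)
    new_manifest = Manifest(
        seed=manifest.seed,
        genome_length=len(sequence),
        is_circular=False,
        is_complete=False,
        features=list(degraded.features),
        junctions=list(junctions(degraded, include_cr=True).entries),
        codon_calls=classify_codons(degraded),
        composition=_realized_composition(degraded),
    )
    return degraded, new_manifest
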