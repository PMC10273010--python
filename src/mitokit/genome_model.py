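"""Annotated circular mitogenome model and feature-table / GenBank / FASTA IO.

Coordinate convention: 1-based, fully inclusive on the forward strand of the
deposited sequence; a feature spanning positions ``start..end`` has length
``end - start + 1``.  Features may wrap the circular origin, in which case
``end < start`` and ``wraps_origin`` is set.

Strand bookkeeping: the authoritative field is ``direction`` (forward =
majority/gene-rich strand here).  ``strand_label`` (``N``/``J``) is a
presentation label; within one genome each label must map to exactly one
direction, but which label means forward is not assumed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .vocabulary import (
    CONTROL_NAME,
    GENE_NAMES,
    GENE_TYPES,
    GeneType,
    canonical_name,
    gene_type,
)

__all__ = [
    "Direction",
    "GeneFeature",
    "MitoGenome",
    "AnnotationError",
    "FeatureTableError",
    "feature_length",
    "extract_sequence",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "validate_annotation",
]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotations."""


class FeatureTableError(ValueError):
    """Raised for malformed feature-table files."""


class Direction(enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: coordinates, strand label, direction, type."""

    name: str
    gene_type: GeneType
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand_label: str = "N"
    direction: Direction = Direction.FORWARD
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"{self.name}: start must be >= 1, got {self.start}")
        if not self.wraps_origin and self.end < self.start:
            raise AnnotationError(
                f"{self.name}: end {self.end} < start {self.start} without wraps_origin"
            )

    def length(self, genome_length: int | None = None) -> int:
        return feature_length(self, genome_length)


def feature_length(f: GeneFeature, genome_length: int | None = None) -> int:
    """Wrap-aware inclusive span length in bp."""
    if not f.wraps_origin:
        return f.end - f.start + 1
    if genome_length is None:
        raise ValueError("genome_length required for a wrapping feature")
    return genome_length - f.start + 1 + f.end


@dataclass
class MitoGenome:
    """Circular annotated mitochondrial genome."""

    accession: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    genetic_code_id: int = 5
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise AnnotationError("empty genome sequence")
        for f in self.features:
            hi = f.start if f.wraps_origin else f.end
            if hi > len(self.sequence):
                raise AnnotationError(
                    f"{f.name}: coordinate {hi} exceeds sequence length {len(self.sequence)}"
                )
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(f"duplicate feature names: {sorted(dupes)}")
        _check_label_consistency(self.features)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def gene_sequence(self, name: str) -> str:
        return extract_sequence(self, self.feature(name))

    def pcg_sequences(self) -> dict[str, str]:
        """Oriented CDS per protein-coding gene, in feature order."""
        return {
            f.name: extract_sequence(self, f)
            for f in self.features
            if f.gene_type is GeneType.PCG
        }


def _check_label_consistency(features: Sequence[GeneFeature]) -> None:
    seen: dict[str, Direction] = {}
    for f in features:
        prev = seen.setdefault(f.strand_label, f.direction)
        if prev is not f.direction:
            raise AnnotationError(
                f"strand label {f.strand_label!r} maps to both directions "
                f"(first seen {prev.value}, {f.name} is {f.direction.value})"
            )


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(g: MitoGenome, f: GeneFeature) -> str:
    """Feature sequence in reading direction (wrap-aware)."""
    n = g.length
    hi = f.start if f.wraps_origin else f.end
    if hi > n or f.end > n:
        raise AnnotationError(f"{f.name}: out of bounds for genome of {n} bp")
    if f.wraps_origin:
        seq = g.sequence[f.start - 1:] + g.sequence[: f.end]
    else:
        seq = g.sequence[f.start - 1 : f.end]
    if f.direction is Direction.REVERSE:
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# Feature tables (TSV: gene, start, end, strand, direction; header required)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("gene", "start", "end", "strand", "direction")


def read_feature_table(path: str | Path, genome_length: int | None = None) -> list[GeneFeature]:
    """Read a tab-separated feature table, returning features sorted by start.

    Extra columns are ignored.  Lengths are always recomputed from the
    coordinates; a ``size`` column, if present, is not trusted.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        warnings.warn(f"{path}: empty feature table", stacklevel=2)
        return []
    header = [c.strip().lower() for c in lines[0].split("\t")]
    missing = [c for c in _TABLE_COLUMNS if c not in header]
    if missing:
        raise FeatureTableError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in _TABLE_COLUMNS}
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        cells = ln.split("\t")
        raw_name = cells[idx["gene"]].strip()
        name = canonical_name(raw_name) or raw_name
        if name in seen:
            raise FeatureTableError(f"{path}: duplicate gene {name!r}")
        seen.add(name)
        try:
            start = int(cells[idx["start"]])
            end = int(cells[idx["end"]])
        except ValueError as exc:
            raise FeatureTableError(f"{path}: non-numeric coordinates for {name!r}") from exc
        direction = Direction(cells[idx["direction"]].strip().lower())
        wraps = end < start
        if wraps and genome_length is None:
            raise FeatureTableError(
                f"{path}: {name} appears to wrap the origin; genome_length required"
            )
        gt = gene_type(name) or GeneType.CONTROL
        if canonical_name(raw_name) is None:
            warnings.warn(f"{path}: unknown gene name {raw_name!r} preserved", stacklevel=2)
        feats.append(
            GeneFeature(
                name=name,
                gene_type=gt,
                start=start,
                end=end,
                strand_label=cells[idx["strand"]].strip(),
                direction=direction,
                wraps_origin=wraps,
            )
        )
    feats.sort(key=lambda f: (f.start, f.end, f.name))
    _check_label_consistency(feats)
    return feats


def write_feature_table(features: Iterable[GeneFeature], path: str | Path) -> None:
    path = Path(path)
    rows = ["\t".join(_TABLE_COLUMNS)]
    for f in features:
        rows.append(
            f"{f.name}\t{f.start}\t{f.end}\t{f.strand_label}\t{f.direction.value}"
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GenBank / FASTA
# ---------------------------------------------------------------------------

_GB_TYPES = {"CDS": GeneType.PCG, "tRNA": GeneType.TRNA, "rRNA": GeneType.RRNA,
             "D-loop": GeneType.CONTROL, "misc_feature": GeneType.CONTROL}


def read_genbank(path: str | Path) -> MitoGenome:
    """Parse a GenBank flat file with CDS/tRNA/rRNA (and D-loop) features."""
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad format
        raise FeatureTableError(f"{path}: not a parseable GenBank file: {exc}") from exc
    feats: list[GeneFeature] = []
    notes: list[str] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type not in _GB_TYPES:
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [feat.type])[0]
        canon = canonical_name(raw)
        name = canon or raw
        if name in seen:
            notes.append(f"duplicate feature {name!r} skipped")
            continue
        seen.add(name)
        if canon is None:
            notes.append(f"unknown gene name {raw!r} preserved")
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        rev = feat.location.strand == -1
        feats.append(
            GeneFeature(
                name=name,
                gene_type=GENE_TYPES.get(name, _GB_TYPES[feat.type]),
                start=start,
                end=end,
                strand_label="J" if rev else "N",
                direction=Direction.REVERSE if rev else Direction.FORWARD,
            )
        )
    if not feats:
        raise AnnotationError(f"{path}: GenBank record has no gene features")
    feats.sort(key=lambda f: (f.start, f.end, f.name))
    code = 5
    for feat in record.features:
        if feat.type == "CDS" and "transl_table" in feat.qualifiers:
            code = int(feat.qualifiers["transl_table"][0])
            break
    return MitoGenome(
        accession=record.id or record.name,
        sequence=str(record.seq),
        features=feats,
        genetic_code_id=code,
        warnings=notes,
    )


def write_genbank(g: MitoGenome, path: str | Path) -> None:
    """Write a minimal GenBank flat file (sequence + gene features)."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(g.sequence), id=g.accession, name=g.accession[:16],
                    description="synthetic circular mitogenome",
                    annotations={"molecule_type": "DNA", "topology": "circular"})
    type_of = {GeneType.PCG: "CDS", GeneType.TRNA: "tRNA",
               GeneType.RRNA: "rRNA", GeneType.CONTROL: "D-loop"}
    for f in g.features:
        strand = -1 if f.direction is Direction.REVERSE else 1
        loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        quals = {"gene": [f.name]}
        if f.gene_type is GeneType.PCG:
            quals["transl_table"] = [str(g.genetic_code_id)]
        rec.features.append(SeqFeature(loc, type=type_of[f.gene_type], qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    counts_by_type: dict[str, int]
    missing_genes: list[str]
    extra_names: list[str]
    duplicates: list[str]
    findings: list[str]

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_annotation(g: MitoGenome | Sequence[GeneFeature],
                        genome_length: int | None = None) -> ValidationReport:
    """Report missing/extra/duplicate genes and bound violations.

    Accepts a genome or a bare feature collection (report-only; never raises).
    """
    if isinstance(g, MitoGenome):
        features: Sequence[GeneFeature] = g.features
        genome_length = g.length
    else:
        features = list(g)
    findings: list[str] = []
    names = [f.name for f in features]
    counted = [n for n in names if n in GENE_TYPES and n != CONTROL_NAME]
    counts: dict[str, int] = {t.value: 0 for t in GeneType}
    for n in set(counted):
        counts[GENE_TYPES[n].value] += 1
    missing = [n for n in GENE_NAMES if n not in names]
    extra = [n for n in names if n not in GENE_TYPES]
    dupes = sorted({n for n in names if names.count(n) > 1})
    for n in missing:
        findings.append(f"missing gene: {n}")
    for n in extra:
        findings.append(f"unknown gene name: {n}")
    for n in dupes:
        findings.append(f"duplicate: {n}")
    if genome_length is not None:
        for f in features:
            hi = f.start if f.wraps_origin else f.end
            if hi > genome_length:
                findings.append(f"out of bounds: {f.name} ({hi} > {genome_length})")
    return ValidationReport(
        counts_by_type=counts,
        missing_genes=missing,
        extra_names=extra,
        duplicates=dupes,
        findings=findings,
    )
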