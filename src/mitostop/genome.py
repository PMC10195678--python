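"""Circular mitochondrial genome handling and translation.

Vertebrate mitochondrial genomes are small, circular, and densely packed
with 13 protein-coding genes translated with genetic code table 2, in
which TGA encodes tryptophan and AGA/AGG are stop codons.  This module
provides the genome/annotation I/O, circular coordinate arithmetic and
translation machinery that the edit enumeration and TALE design modules
build on.

Coordinates are 0-based half-open internally.  Human-facing reports use
the 1-based closed ``m.N`` convention common in mitochondrial genetics
(e.g. ``m.8069``); :func:`m_coordinate` / :func:`parse_m_coordinate`
convert between the two.  Features on a circular genome may wrap the
origin, represented by ``end > genome.length``.

Strand nomenclature: mtDNA strands are conventionally called light (L)
and heavy (H).  Here ``L`` is mapped to the reference (+) strand and
``H`` to its complement; the mapping is configurable because the
convention varies between annotation sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

from .errors import AlphabetError, CoordinateError, FrameError, ParseError

NUCLEOTIDES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation table for vertebrate mitochondria.
VERTEBRATE_MITO_TABLE = 2


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (alphabet {A,C,G,T,N})."""
    seq = seq.upper()
    if not set(seq) <= NUCLEOTIDES:
        bad = sorted(set(seq) - NUCLEOTIDES)
        raise AlphabetError(f"non-nucleotide characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    if base not in NUCLEOTIDES:
        raise AlphabetError(f"non-nucleotide base {base!r}")
    return base.translate(_COMPLEMENT)


def m_coordinate(pos0: int) -> str:
    """0-based position -> 1-based mitochondrial ``m.N`` notation."""
    if pos0 < 0:
        raise CoordinateError(f"negative position {pos0}")
    return f"m.{pos0 + 1}"


def parse_m_coordinate(text: str) -> int:
    """Inverse of :func:`m_coordinate`."""
    if not text.startswith("m."):
        raise CoordinateError(f"not an m. coordinate: {text!r}")
    return int(text[2:]) - 1


@dataclass(frozen=True)
class CodonTable:
    """A genetic code: codon->amino-acid map plus stop and start sets.

    The default is NCBI table 2 (vertebrate mitochondrial), where TGA
    encodes Trp and the stop set is {TAA, TAG, AGA, AGG}.
    """

    table_id: int
    forward: dict[str, str]
    stop_set: frozenset[str]
    start_set: frozenset[str]

    @classmethod
    def from_ncbi_id(cls, table_id: int = VERTEBRATE_MITO_TABLE) -> "CodonTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            forward=dict(bio.forward_table),
            stop_set=frozenset(bio.stop_codons),
            start_set=frozenset(bio.start_codons),
        )

    def amino_acid(self, codon: str) -> str:
        """Single-letter amino acid, '*' for stop, 'X' for N-containing."""
        codon = codon.upper()
        if len(codon) != 3 or not set(codon) <= NUCLEOTIDES:
            raise AlphabetError(f"invalid codon {codon!r}")
        if "N" in codon:
            return "X"
        if codon in self.stop_set:
            return "*"
        return self.forward[codon]


#: Module-level default: vertebrate mitochondrial code.
MITO_TABLE = CodonTable.from_ncbi_id(VERTEBRATE_MITO_TABLE)


def translate(cds: str, table: CodonTable = MITO_TABLE) -> str:
    """Translate a frame-valid CDS; stops render as '*' and do not halt.

    The full-length translation is returned so callers can inspect
    internal stops — the core question this package asks.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(table.amino_acid(cds[i : i + 3]) for i in range(0, len(cds), 3))


@dataclass
class MitoGenome:
    """A (by default circular) mitochondrial genome sequence."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= NUCLEOTIDES:
            bad = sorted(set(self.sequence) - NUCLEOTIDES)
            raise AlphabetError(f"genome {self.name}: invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at ``pos``; negative/overflowing positions wrap if circular."""
        if 0 <= pos < self.length:
            return self.sequence[pos]
        if not self.circular:
            raise CoordinateError(
                f"position {pos} outside linear genome of length {self.length}"
            )
        return self.sequence[pos % self.length]

    def slice(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin when circular.

        ``end`` may exceed the genome length (or ``start`` be negative)
        to denote a wrap, which is only legal on a circular genome.
        """
        if end < start:
            raise CoordinateError(f"inverted interval [{start}, {end})")
        if end - start > self.length:
            raise CoordinateError("interval longer than genome")
        if 0 <= start and end <= self.length:
            return self.sequence[start:end]
        if not self.circular:
            raise CoordinateError(
                f"interval [{start}, {end}) wraps a linear genome"
            )
        return "".join(self.base(p) for p in range(start, end))


@dataclass
class GeneFeature:
    """One protein-coding gene on the genome.

    ``start``/``end`` are 0-based half-open on the reference; ``end`` may
    exceed the genome length for origin-spanning genes.  ``coding_strand``
    is '+' or '-' relative to the reference; ``strand_label`` carries the
    light/heavy nomenclature.
    """

    gene_name: str
    start: int
    end: int
    coding_strand: str
    strand_label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.coding_strand not in {"+", "-"}:
            raise CoordinateError(f"bad strand {self.coding_strand!r}")
        if not self.strand_label:
            self.strand_label = strand_to_label(self.coding_strand)

    @property
    def length(self) -> int:
        return self.end - self.start


def strand_to_label(strand: str, l_is_reference: bool = True) -> str:
    """Map a reference strand sign to the light/heavy label."""
    if l_is_reference:
        return "L" if strand == "+" else "H"
    return "H" if strand == "+" else "L"


def extract_cds(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-strand sequence of a gene ('-' features reverse-complemented)."""
    seq = genome.slice(feature.start, feature.end)
    return revcomp(seq) if feature.coding_strand == "-" else seq


def coding_index_to_genome(feature: GeneFeature, idx: int, genome_length: int) -> int:
    """Map an index on the coding strand of a feature to a genome position."""
    if not 0 <= idx < feature.length:
        raise CoordinateError(f"coding index {idx} outside feature")
    if feature.coding_strand == "+":
        pos = feature.start + idx
    else:
        pos = feature.end - 1 - idx
    return pos % genome_length


def validate_feature(
    genome: MitoGenome, feature: GeneFeature, table: CodonTable = MITO_TABLE
) -> list[str]:
    """Frame / internal-stop checks; returns (and attaches) warnings."""
    notes: list[str] = []
    if feature.length % 3 != 0:
        notes.append(f"CDS length {feature.length} not divisible by 3")
    else:
        aa = translate(extract_cds(genome, feature), table)
        if "*" in aa[:-1]:
            notes.append(f"internal stop at codon {aa.index('*') + 1}")
    feature.warnings.extend(notes)
    return notes


# ---------------------------------------------------------------------------
# File loading


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "genbank" if line.startswith("LOCUS") else "fasta"
    raise ParseError(f"{path}: empty file")


def _features_from_genbank(record, genome_length: int) -> list[GeneFeature]:
    feats = []
    for f in record.features:
        if f.type != "CDS":
            continue
        name = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag") or ["?"])[0]
        parts = f.location.parts
        start = int(parts[0].start)
        end = int(parts[-1].end)
        if len(parts) > 1 and end < start:  # origin-spanning join
            end += genome_length
        else:
            end = start + sum(len(p) for p in parts)
        strand = "+" if f.location.strand != -1 else "-"
        feats.append(GeneFeature(name, start, int(end), strand))
    return feats


def _features_from_bed(path: Path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >=4 columns")
            strand = cols[5] if len(cols) >= 6 else "+"
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            feats.append(GeneFeature(cols[3], start, end, strand))
    return feats


def _features_from_gff3(path: Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = []
    for f in db.features_of_type("CDS"):
        name = f.attributes.get("gene", f.attributes.get("Name", ["?"]))[0]
        feats.append(GeneFeature(name, f.start - 1, f.end, f.strand))
    return feats


def load_genome(
    path: str | Path,
    annotation: str | Path | None = None,
    record_name: str | None = None,
    circular: bool = True,
    validate: bool = True,
) -> tuple[MitoGenome, list[GeneFeature]]:
    """Load a genome (FASTA or GenBank) plus CDS features.

    GenBank records carry their own CDS features; FASTA requires a
    separate ``annotation`` file (GFF3 or BED).  Multi-record FASTA is
    rejected unless ``record_name`` selects one record.  Feature
    validation issues warnings (collected on the features), never
    errors: real annotations occasionally contain incomplete stops.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    fmt = _sniff_format(path)
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # biopython raises assorted ValueError subclasses
        raise ParseError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no sequence records")
    if record_name is not None:
        matches = [r for r in records if r.id == record_name or r.name == record_name]
        if not matches:
            raise ParseError(f"{path}: no record named {record_name!r}")
        record = matches[0]
    elif len(records) > 1:
        raise ParseError(
            f"{path}: {len(records)} records; pass record_name to select one"
        )
    else:
        record = records[0]

    genome = MitoGenome(record.id, str(record.seq), circular=circular)

    features: list[GeneFeature] = []
    if fmt == "genbank":
        features = _features_from_genbank(record, genome.length)
    if annotation is not None:
        annotation = Path(annotation)
        if not annotation.exists():
            raise ParseError(f"{annotation}: no such file")
        with open(annotation) as fh:
            first = fh.readline()
        if first.startswith("##gff") or annotation.suffix.lower() in {".gff", ".gff3"}:
            features = _features_from_gff3(annotation)
        else:
            features = _features_from_bed(annotation)

    seen: dict[str, GeneFeature] = {}
    for f in features:
        if f.start % genome.length != f.start and not circular:
            raise ParseError(f"feature {f.gene_name} outside linear genome")
        if f.gene_name in seen:
            raise ParseError(f"duplicate feature for gene {f.gene_name}")
        seen[f.gene_name] = f
        if validate:
            for note in validate_feature(genome, f):
                warnings.warn(f"{f.gene_name}: {note}", stacklevel=2)
    return genome, features
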