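"""Deterministic synthetic genomes and sequencing count tables.

The generator builds small circular genomes organized like a vertebrate
mitochondrial genome — a ring of short intergenic spacers and
protein-coding ORFs on either strand, valid under translation table 2 —
with chosen codons planted at chosen positions (a Trp TGA, or the
GTC-CAA dicodon that admits the cascade route to a stop).  Random
codons are drawn from a pool that excludes the stop set and TGA, so a
planted TGA is always the gene's only one and enumeration results are
known by construction.

Count tables emulate deep amplicon sequencing of a heteroplasmic
sample: at each position the alt-allele count is binomial at the stated
depth and true frequency.  Background C:G->T:A heteroplasmy (0.02% by
default, the level seen in untreated cultured cells) is applied at
every C/G reference position.  Both generators are bit-reproducible
from their seed and never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .errors import SpecError
from .genome import MITO_TABLE, GeneFeature, MitoGenome

# codons excluded from random draws: the table-2 stop set plus TGA (Trp),
# so planted TGAs stay unique, plus ATG to keep start codons planted only
_EXCLUDED = set(MITO_TABLE.stop_set) | {"TGA", "ATG"}
_CODON_POOL = sorted(
    c for c in ("".join(t) for t in product("ACGT", repeat=3)) if c not in _EXCLUDED
)


@dataclass
class GeneSpec:
    """One synthetic ORF: name, length in codons (incl. start and stop),
    coding strand, and planted codons as {1-based codon index: codon}."""

    name: str
    n_codons: int
    strand: str = "+"
    planted: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_codons < 4:
            raise SpecError(f"{self.name}: gene needs >= 4 codons")
        if self.strand not in "+-":
            raise SpecError(f"{self.name}: bad strand {self.strand!r}")
        for idx, codon in self.planted.items():
            if not 1 < idx < self.n_codons:
                raise SpecError(
                    f"{self.name}: planted codon index {idx} outside (1, n)"
                )
            if codon in MITO_TABLE.stop_set:
                raise SpecError(f"{self.name}: cannot plant stop codon {codon}")


@dataclass
class GenomeSpec:
    """A full synthetic genome: genes in ring order plus spacer lengths."""

    genes: Sequence[GeneSpec]
    intergenic: int = 40
    seed: int = 0
    name: str = "synthetic-mtDNA"

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise SpecError("duplicate gene names")


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_CODON_POOL[i] for i in rng.integers(0, len(_CODON_POOL), size=n)]


def make_toy_genome(spec: GenomeSpec) -> tuple[MitoGenome, list[GeneFeature]]:
    """Build the genome and features; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for gene in spec.genes:
        spacer = "".join(rng.choice(list("ACGT"), size=spec.intergenic))
        chunks.append(spacer)
        pos += spec.intergenic
        codons = _random_codons(rng, gene.n_codons)
        codons[0] = "ATG"
        codons[-1] = "TAA"
        for idx, codon in gene.planted.items():
            codons[idx - 1] = codon
        coding = "".join(codons)
        start, end = pos, pos + len(coding)
        if gene.strand == "+":
            chunks.append(coding)
        else:
            from .genome import revcomp

            chunks.append(revcomp(coding))
        features.append(GeneFeature(gene.name, start, end, gene.strand))
        pos = end
    genome = MitoGenome(spec.name, "".join(chunks), circular=True)
    return genome, features


def library_like_spec(seed: int = 0) -> GenomeSpec:
    """A 13-gene genome organized like the mouse mtDNA coding complement.

    Twelve genes carry a planted Trp TGA codon (earliest at codon 6,
    latest at codon 146, the truncation range of the real knockout
    library); one light-strand gene carries the GTC-CAA dicodon at
    codons 90-91 instead (the cascade route); one gene sits on the
    heavy strand, like Nd6.
    """
    rng = np.random.default_rng(seed)
    genes = []
    tga_at = [6, 25, 40, 55, 70, 85, 100, 115, 125, 135, 140, 146]
    for i, k in enumerate(tga_at):
        strand = "-" if i == 5 else "+"  # one heavy-strand gene
        n_codons = int(k + rng.integers(20, 80))
        genes.append(
            GeneSpec(f"g{i + 1:02d}", n_codons, strand=strand, planted={k: "TGA"})
        )
    genes.append(
        GeneSpec("g13", 160, strand="+", planted={90: "GTC", 91: "CAA"})
    )
    return GenomeSpec(genes=genes, intergenic=60, seed=seed)


# ---------------------------------------------------------------------------
# Count tables


@dataclass
class TruthTable:
    """True per-position variant frequencies for a simulated sample.

    ``variants`` maps 1-based position to frequency in percent (the alt
    allele is the deaminase one: T at ref C, A at ref G).
    ``background_pct`` applies at every other C/G reference position.
    """

    depth: int
    variants: dict[int, float] = field(default_factory=dict)
    background_pct: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise SpecError("depth must be positive")
        for pos, f in self.variants.items():
            if not 0 <= f <= 100:
                raise SpecError(f"frequency {f} at position {pos} outside [0, 100]")
        if not 0 <= self.background_pct <= 100:
            raise SpecError("background outside [0, 100]")


def make_count_table(genome: MitoGenome, truth: TruthTable, sample_id: str = "sim"):
    """Binomially sampled count table for one sample; seeded and exact.

    Positions listed in ``truth.variants`` must be C/G reference sites;
    the deaminase alt allele is sampled at the stated frequency, the
    reference fills the remainder.
    """
    import pandas as pd

    from .scoring import BASES, SampleCounts

    rng = np.random.default_rng(truth.seed)
    n = genome.length
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1").astype("U1")
    freqs = np.zeros(n)
    is_cg = (seq == "C") | (seq == "G")
    freqs[is_cg] = truth.background_pct
    for pos, f in truth.variants.items():
        if not 1 <= pos <= n:
            raise SpecError(f"variant position {pos} outside genome")
        if seq[pos - 1] not in "CG":
            raise SpecError(
                f"variant at position {pos} needs a C/G reference base"
            )
        freqs[pos - 1] = f
    alt_counts = rng.binomial(truth.depth, freqs / 100.0)
    counts = {b: np.zeros(n, dtype=int) for b in BASES}
    for i in range(n):
        base = seq[i]
        if base == "N":
            continue
        alt = {"C": "T", "G": "A"}.get(base)
        if alt is not None and alt_counts[i]:
            counts[alt][i] = alt_counts[i]
            counts[base][i] = truth.depth - alt_counts[i]
        else:
            counts[base][i] = truth.depth
    df = pd.DataFrame(
        {
            "contig": genome.name,
            "pos": np.arange(1, n + 1),
            "ref": seq,
            **counts,
        }
    )
    df = df[df["ref"] != "N"]
    return SampleCounts.from_frame(df, sample_id)
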