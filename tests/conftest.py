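"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own enumeration
machinery: editability is decided by sequentially applying single
edits to a mutable sequence (breadth-first over edit sets), and
translation in the oracle goes through Bio.Seq rather than the
package's codon table.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mitostop import (
    GeneSpec,
    GenomeSpec,
    extract_cds,
    library_like_spec,
    make_toy_genome,
)

# ---------------------------------------------------------------------------
# Genome fixtures


@pytest.fixture(scope="session")
def toy_library():
    """13-gene synthetic genome organized like the mouse mtDNA ORF set."""
    return make_toy_genome(library_like_spec(seed=7))


@pytest.fixture(scope="session")
def toy_genome(toy_library):
    return toy_library[0]


@pytest.fixture(scope="session")
def toy_features(toy_library):
    return toy_library[1]


def random_orf_genome(seed: int, n_codons: int = 40, n_tga: int = 2,
                      n_tgg: int = 0, strand: str = "+"):
    """Single-gene circular genome with TGA/TGG codons planted at random
    internal positions; all other codons avoid Trp and stop codons."""
    rng = np.random.default_rng(seed)
    planted = {}
    slots = rng.permutation(np.arange(3, n_codons - 1))
    take = list(slots[: n_tga + n_tgg])
    for idx in take[:n_tga]:
        planted[int(idx)] = "TGA"
    for idx in take[n_tga:]:
        planted[int(idx)] = "TGG"
    spec = GenomeSpec(
        genes=[GeneSpec("orf1", n_codons, strand=strand, planted=planted)],
        intergenic=30,
        seed=seed,
    )
    return make_toy_genome(spec)


# ---------------------------------------------------------------------------
# Brute-force oracles


def oracle_closure(seq: str, flank5: str = "N") -> set[int]:
    """Editable-C closure on one strand by iterated single-edit application."""
    seq = list(seq)
    editable: set[int] = set()
    changed = True
    while changed:
        changed = False
        for i, b in enumerate(seq):
            prev = seq[i - 1] if i > 0 else flank5
            if b == "C" and prev == "T" and i not in editable:
                editable.add(i)
                seq[i] = "T"
                changed = True
    return editable


def _single_edits(seq: list[str], flank5: str, flank3: str):
    """All TC-context edits applicable to the current sequence state."""
    n = len(seq)
    out = []
    for i, b in enumerate(seq):
        if b == "C":
            prev = seq[i - 1] if i > 0 else flank5
            if prev == "T":
                out.append(("coding", i))
        if b == "G":
            nxt = seq[i + 1] if i < n - 1 else flank3
            if nxt == "A":  # template strand reads 5'-TC-3'
                out.append(("template", i))
    return out


def _apply(seq: list[str], edit) -> None:
    strand, i = edit
    seq[i] = "T" if strand == "coding" else "A"


def reachable_edit_sets(cds: str, flank5: str, flank3: str, max_edits: int = 4):
    """All edit sets reachable by sequential context-valid application."""
    frontier = {frozenset()}
    seen = {frozenset()}
    for _ in range(max_edits):
        nxt = set()
        for state in frontier:
            seq = list(cds)
            for e in state:
                _apply(seq, e)
            for e in _single_edits(seq, flank5, flank3):
                new = state | {e}
                if new not in seen:
                    seen.add(new)
                    nxt.add(new)
        frontier = nxt
    return seen


def oracle_candidates(genome, feature, max_edits: int = 4, strict: bool = True):
    """Stop-gain plans by exhaustive search; independent of the enumerator.

    Returns a set of (codon_index_1based, frozenset primary coding
    indices, frozenset bystander coding indices) tuples.
    """
    cds = extract_cds(genome, feature)
    n = len(cds)
    ncod = n // 3
    if feature.coding_strand == "+":
        flank5 = genome.base(feature.start - 1)
        flank3 = genome.base(feature.end % genome.length)
    else:
        from mitostop import revcomp

        flank5 = revcomp(genome.base(feature.end % genome.length))
        flank3 = revcomp(genome.base(feature.start - 1))

    stops = {"TAA", "TAG", "AGA", "AGG"}
    reachable = reachable_edit_sets(cds, flank5, flank3, max_edits)
    found = {}
    for state in reachable:
        if not state:
            continue
        seq = list(cds)
        for e in state:
            _apply(seq, e)
        mutated = "".join(seq)
        touched = {i // 3 for _, i in state}
        if 0 in touched or (ncod - 1) in touched:
            continue
        for k in sorted(touched):
            if mutated[3 * k : 3 * k + 3] not in stops:
                continue
            primary = frozenset(i for _, i in state if i // 3 == k)
            bystander = frozenset(i for _, i in state if i // 3 != k)
            # reject states carrying edits unrelated to codon k: every
            # bystander codon must lose at least one edit in some smaller
            # reachable state with the same primary set
            key = (k + 1, primary)
            if key not in found or len(bystander) < len(found[key][0]):
                found[key] = (bystander, mutated)
    results = set()
    for (k1, primary), (bystander, mutated) in found.items():
        if strict:
            ok = True
            for c in {i // 3 for i in bystander}:
                before = str(Seq(cds[3 * c : 3 * c + 3]).translate(table=2))
                after = str(Seq(mutated[3 * c : 3 * c + 3]).translate(table=2))
                if before != after:
                    ok = False
            if not ok:
                continue
        results.add((k1, primary, frozenset(bystander)))
    return results


def candidate_key(candidate, genome, feature):
    """Project an EditCandidate onto the oracle's coding-index key."""
    L = genome.length

    def coding_index(pos):
        if feature.coding_strand == "+":
            return (pos - feature.start) % L
        return (feature.end - 1 - pos) % L

    return (
        candidate.stop_codon_index,
        frozenset(coding_index(e.ref_pos) for e in candidate.primary_edits),
        frozenset(coding_index(e.ref_pos) for e, _ in candidate.bystander_edits),
    )
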