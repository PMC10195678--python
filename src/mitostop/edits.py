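"""Enumeration of stop-gain C:G->T:A base edits in mitochondrial ORFs.

Double-stranded-DNA cytosine deaminase (DddA)-derived base editors
convert C:G pairs to T:A, but only where the edited C sits in a
5'-TC-3' context on its own strand.  Because editing a C turns it into
a T, two (or more) consecutive Cs can be edited in cascade: the first
edit creates the TC context for the next.  This module computes the
closure of context-editable Cs over both strands of a coding sequence
and enumerates every combination that converts an in-frame codon into
a stop codon of the vertebrate mitochondrial code (TAA, TAG, AGA, AGG),
classifying every other induced change as synonymous/missense/etc.

The workhorse observation: a Trp codon TGA always admits a stop-gain
edit, because its template-strand triplet is 5'-TCA-3' — the C opposite
the G is always preceded by T.  A Trp codon TGG never does through its
middle position alone (the opposite-strand context is CC), though a
two-step cascade through the third position can reach TAA when the
following base is an A.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .errors import AlphabetError, FrameError
from .genome import (
    MITO_TABLE,
    CodonTable,
    GeneFeature,
    MitoGenome,
    coding_index_to_genome,
    complement,
    extract_cds,
    m_coordinate,
    translate,
)

Consequence = Literal["synonymous", "missense", "nonsense", "stop_loss"]


@dataclass(frozen=True)
class ContextRule:
    """Sequence-context model for the deaminase.

    ``motif``: 'TC' (strict; the default editor chemistry) or 'HC'
    (relaxed variants; H = A, C or T).  ``cascade`` allows consecutive-C
    chains, bounded by ``max_run`` Cs per chain.  ``max_edits`` bounds
    the total number of deaminations per candidate plan.
    """

    motif: str = "TC"
    cascade: bool = True
    max_run: int = 4
    max_edits: int = 4

    def __post_init__(self) -> None:
        if self.motif not in {"TC", "HC"}:
            raise ValueError(f"unknown motif {self.motif!r}")

    def motif_ok(self, five_prime_base: Optional[str]) -> bool:
        if five_prime_base is None:
            return False
        if self.motif == "TC":
            return five_prime_base == "T"
        return five_prime_base in "ACT"


@dataclass(frozen=True)
class SingleEdit:
    """One C->T deamination, located on the reference genome.

    ``ref_pos`` is 0-based; ``edited_strand`` is the reference strand
    carrying the edited C ('+' means the reference base is C, '-' means
    it is G and the C sits on the complement).  ``prerequisite`` links
    to the upstream cascade edit whose application creates this edit's
    TC context, if the context is not present in the unedited genome.
    """

    ref_pos: int
    edited_strand: str
    ref_base_on_ref: str
    context_ok: bool = True
    prerequisite: Optional["SingleEdit"] = None

    @property
    def alt_base_on_ref(self) -> str:
        return "T" if self.ref_base_on_ref == "C" else "A"

    @property
    def ref_alt(self) -> str:
        return f"{self.ref_base_on_ref}>{self.alt_base_on_ref}"

    @property
    def m_pos(self) -> str:
        return m_coordinate(self.ref_pos)

    def chain(self) -> list["SingleEdit"]:
        """Prerequisites first, self last (application order)."""
        out = [] if self.prerequisite is None else self.prerequisite.chain()
        out.append(self)
        return out


@dataclass(frozen=True)
class EditCandidate:
    """A complete plan to install a premature stop codon in one gene."""

    gene: str
    stop_codon_index: int  # 1-based codon number of the created stop
    primary_edits: tuple[SingleEdit, ...]  # edits inside the stop codon
    bystander_edits: tuple[tuple[SingleEdit, str], ...]  # (edit, consequence)
    all_bystanders_synonymous: bool
    created_stop: str
    original_codon: str
    truncation_fraction: float
    feature: GeneFeature = field(compare=False, hash=False, default=None)

    @property
    def route(self) -> str:
        return f"{self.original_codon}>{self.created_stop}"

    @property
    def edited_strand(self) -> str:
        """Reference strand carrying the stop-forming edited C(s)."""
        return self.primary_edits[-1].edited_strand

    def all_edits(self) -> list[SingleEdit]:
        return list(self.primary_edits) + [e for e, _ in self.bystander_edits]

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "stop_codon_index": self.stop_codon_index,
            "route": self.route,
            "created_stop": self.created_stop,
            "truncation_fraction": round(self.truncation_fraction, 4),
            "primary_edits": [
                {"m_pos": e.m_pos, "pos0": e.ref_pos, "change": e.ref_alt,
                 "strand": e.edited_strand}
                for e in self.primary_edits
            ],
            "bystander_edits": [
                {"m_pos": e.m_pos, "pos0": e.ref_pos, "change": e.ref_alt,
                 "strand": e.edited_strand, "consequence": c}
                for e, c in self.bystander_edits
            ],
            "all_bystanders_synonymous": self.all_bystanders_synonymous,
        }


DEFAULT_RULE = ContextRule()


def cascade_editable_set(
    strand_seq: str,
    window: Optional[tuple[int, int]] = None,
    rule: ContextRule = DEFAULT_RULE,
) -> dict[int, SingleEdit]:
    """Closure of editable Cs on one strand, keyed by sequence offset.

    A C is editable if its 5' neighbour matches the motif in the given
    sequence, or becomes a T through an editable C immediately 5' of it
    (cascade), computed to fixpoint.  Offsets are relative to
    ``strand_seq``; the returned edits use ``edited_strand='+'`` and may
    carry prerequisite links within the window.
    """
    seq = strand_seq.upper()
    n = len(seq)
    lo, hi = window if window is not None else (0, n)
    if not (0 <= lo <= hi <= n):
        raise ValueError(f"window ({lo}, {hi}) outside sequence of length {n}")
    edits: dict[int, SingleEdit] = {}
    depth: dict[int, int] = {}
    for i in range(lo, hi):
        if seq[i] != "C":
            continue
        prev = seq[i - 1] if i > 0 else None
        if rule.motif_ok(prev):
            edits[i] = SingleEdit(i, "+", "C")
            depth[i] = 1
        elif (
            rule.cascade
            and prev == "C"
            and (i - 1) in edits
            and depth[i - 1] < rule.max_run
        ):
            edits[i] = SingleEdit(i, "+", "C", prerequisite=edits[i - 1])
            depth[i] = depth[i - 1] + 1
    return edits


def enumerate_trp_tga(cds: str) -> list[int]:
    """1-based indices of in-frame TGA (Trp) codons, ascending."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    return [i // 3 + 1 for i in range(0, len(cds), 3) if cds[i : i + 3] == "TGA"]


def classify_consequence(
    codon_before: str, codon_after: str, table: CodonTable = MITO_TABLE
) -> Consequence:
    """Consequence of a codon change under the given genetic code."""
    aa1 = table.amino_acid(codon_before)
    aa2 = table.amino_acid(codon_after)
    if aa1 == aa2:
        return "synonymous"
    if aa2 == "*":
        return "nonsense"
    if aa1 == "*":
        return "stop_loss"
    return "missense"


# ---------------------------------------------------------------------------
# Per-gene enumeration


@dataclass(frozen=True)
class _CdsEdit:
    """An editable C in CDS coordinates, on the coding or template strand."""

    strand: str  # 'coding' | 'template'
    index: int  # coding-strand index of the affected base
    chain: tuple  # application-ordered (strand, index) incl. self


def _coding_flank5(genome: MitoGenome, feature: GeneFeature) -> str:
    """Base immediately 5' of the CDS on the coding strand ('N' if unknown)."""
    try:
        if feature.coding_strand == "+":
            return genome.base(feature.start - 1)
        return complement(genome.base(feature.end % genome.length))
    except Exception:
        return "N"


def _coding_flank3(genome: MitoGenome, feature: GeneFeature) -> str:
    try:
        if feature.coding_strand == "+":
            return genome.base(feature.end % genome.length)
        return complement(genome.base(feature.start - 1))
    except Exception:
        return "N"


def editable_cds_positions(
    genome: MitoGenome, feature: GeneFeature, rule: ContextRule = DEFAULT_RULE
) -> list[_CdsEdit]:
    """Cascade closure of editable Cs over both strands of a CDS.

    Context bases immediately outside the CDS (the 5' flank of each
    strand) are read from the genome so edge codons are handled
    correctly.
    """
    cds = extract_cds(genome, feature)
    n = len(cds)
    out: list[_CdsEdit] = []

    # coding strand: prepend the 5' flank base, offsets shift by one
    ext = _coding_flank5(genome, feature) + cds
    for off, edit in cascade_editable_set(ext, (1, n + 1), rule).items():
        chain = tuple(("coding", e.ref_pos - 1) for e in edit.chain())
        out.append(_CdsEdit("coding", off - 1, chain))

    # template strand: reverse complement of CDS plus the coding 3' flank,
    # whose complement is the template strand's 5' flank
    from .genome import revcomp

    t_ext = revcomp(cds + _coding_flank3(genome, feature))
    for off, edit in cascade_editable_set(t_ext, (1, n + 1), rule).items():
        chain = tuple(("template", n - e.ref_pos) for e in edit.chain())
        out.append(_CdsEdit("template", n - off, chain))
    return out


def _to_genome_edit(
    feature: GeneFeature,
    genome: MitoGenome,
    strand_tag: str,
    idx: int,
    prerequisite: Optional[SingleEdit],
) -> SingleEdit:
    gpos = coding_index_to_genome(feature, idx, genome.length)
    if feature.coding_strand == "+":
        edited_strand = "+" if strand_tag == "coding" else "-"
    else:
        edited_strand = "-" if strand_tag == "coding" else "+"
    ref_base = "C" if edited_strand == "+" else "G"
    return SingleEdit(gpos, edited_strand, ref_base, prerequisite=prerequisite)


def _apply_cds_edits(cds: str, applied: Iterable[tuple[str, int]]) -> str:
    seq = list(cds)
    for strand_tag, i in applied:
        if strand_tag == "coding":
            if seq[i] != "C":
                raise AlphabetError(f"expected C at coding index {i}")
            seq[i] = "T"
        else:
            if seq[i] != "G":
                raise AlphabetError(f"expected G at coding index {i}")
            seq[i] = "A"
    return "".join(seq)


def enumerate_stop_gain_candidates(
    genome: MitoGenome,
    feature: GeneFeature,
    rule: ContextRule = DEFAULT_RULE,
    policy: str = "strict",
    table: CodonTable = MITO_TABLE,
) -> list[EditCandidate]:
    """All context-valid edit plans creating a premature stop in a gene.

    For every combination of cascade-reachable edits within one codon
    (plus the prerequisite edits their contexts require), the CDS is
    mutated in silico, translated, and kept when the codon becomes a
    stop.  Under ``policy='strict'`` (default) only plans whose every
    bystander change is synonymous are returned; ``policy='permissive'``
    returns all plans with consequences labelled.  Plans touching the
    start codon or the natural stop are excluded.  Results are ordered
    by stop codon index, then by bystander count.
    """
    if policy not in {"strict", "permissive"}:
        raise ValueError(f"unknown policy {policy!r}")
    cds = extract_cds(genome, feature)
    n = len(cds)
    if n % 3 != 0:
        raise FrameError(f"{feature.gene_name}: CDS length {n} not divisible by 3")
    ncod = n // 3

    editable = editable_cds_positions(genome, feature, rule)
    by_codon: dict[int, list[_CdsEdit]] = {}
    for e in editable:
        by_codon.setdefault(e.index // 3, []).append(e)

    seen: set[tuple] = set()
    results: list[EditCandidate] = []
    for k in range(1, ncod - 1):  # never the start or the natural stop
        in_codon = by_codon.get(k, [])
        for r in range(1, len(in_codon) + 1):
            for subset in itertools.combinations(in_codon, r):
                applied: list[tuple[str, int]] = []
                for e in subset:
                    for step in e.chain:
                        if step not in applied:
                            applied.append(step)
                if len(applied) > rule.max_edits:
                    continue
                touched = {i // 3 for _, i in applied}
                if 0 in touched or (ncod - 1) in touched:
                    continue
                if any("N" in cds[3 * c : 3 * c + 3] for c in touched):
                    continue
                mutated = _apply_cds_edits(cds, applied)
                new_codon = mutated[3 * k : 3 * k + 3]
                if new_codon not in table.stop_set:
                    continue
                primary_steps = [s for s in applied if s[1] // 3 == k]
                key = (
                    k,
                    frozenset(
                        coding_index_to_genome(feature, i, genome.length)
                        for _, i in primary_steps
                    ),
                )
                if key in seen:
                    continue
                bystander_pairs: list[tuple[tuple[str, int], str]] = []
                for step in applied:
                    c = step[1] // 3
                    if c == k:
                        continue
                    cons = classify_consequence(
                        cds[3 * c : 3 * c + 3], mutated[3 * c : 3 * c + 3], table
                    )
                    bystander_pairs.append((step, cons))
                all_syn = all(c == "synonymous" for _, c in bystander_pairs)
                if policy == "strict" and not all_syn:
                    continue
                seen.add(key)

                chain_of = {e.chain[-1]: e.chain for e in editable}
                genome_edits: dict[tuple[str, int], SingleEdit] = {}
                for step in applied:  # application order: prereqs first
                    own = chain_of[step]
                    prereq = genome_edits.get(own[-2]) if len(own) > 1 else None
                    genome_edits[step] = _to_genome_edit(
                        feature, genome, step[0], step[1], prereq
                    )
                primary = tuple(genome_edits[s] for s in primary_steps)
                bystanders = tuple(
                    (genome_edits[s], cons) for s, cons in bystander_pairs
                )
                results.append(
                    EditCandidate(
                        gene=feature.gene_name,
                        stop_codon_index=k + 1,
                        primary_edits=primary,
                        bystander_edits=bystanders,
                        all_bystanders_synonymous=all_syn,
                        created_stop=new_codon,
                        original_codon=cds[3 * k : 3 * k + 3],
                        truncation_fraction=(k + 1) / max(ncod - 1, 1),
                        feature=feature,
                    )
                )
    results.sort(key=lambda c: (c.stop_codon_index, len(c.bystander_edits)))
    return results


def candidates_to_json(candidates: list[EditCandidate]) -> str:
    return json.dumps([c.to_dict() for c in candidates], indent=2)


def candidates_to_tsv(candidates: list[EditCandidate]) -> str:
    """Flat TSV, one row per candidate, edits comma-joined."""
    header = (
        "gene\tstop_codon_index\troute\ttruncation_fraction\t"
        "primary_edits\tbystander_edits\tall_bystanders_synonymous"
    )
    rows = [header]
    for c in candidates:
        prim = ",".join(f"{e.m_pos}{e.ref_alt}" for e in c.primary_edits)
        bys = ",".join(
            f"{e.m_pos}{e.ref_alt}({cons})" for e, cons in c.bystander_edits
        )
        rows.append(
            f"{c.gene}\t{c.stop_codon_index}\t{c.route}\t"
            f"{c.truncation_fraction:.4f}\t{prim}\t{bys or '-'}\t"
            f"{c.all_bystanders_synonymous}"
        )
    return "\n".join(rows) + "\n"
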