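"""TALE window placement, RVD strings and split-deaminase pair design.

A DdCBE is a pair of TALE proteins binding opposite strands of mtDNA,
each fused to one half of the split deaminase (the G1333 split yields an
N-terminal and a C-terminal half).  Deamination happens in the spacer
between the two binding sites, which must be 14-20 bp long.  For every
stop-gain candidate this module proposes two alternative binding
windows per strand (L1/L2 on the light strand, H1/H2 on the heavy
strand), enumerates the eight pair configurations (four TALE pairings
times two split orientations), profiles every context-editable C in
each spacer, and ranks the designs.

TALE recognition is encoded as one repeat-variable diresidue (RVD) per
base: NI->A, NG->T, NN->G, HD->C, with a T conventionally required
immediately 5' of the binding site (the "T0" rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .edits import (
    DEFAULT_RULE,
    ContextRule,
    EditCandidate,
    SingleEdit,
    cascade_editable_set,
    classify_consequence,
)
from .errors import AlphabetError, DesignInfeasibleError
from .genome import (
    MITO_TABLE,
    GeneFeature,
    MitoGenome,
    m_coordinate,
    revcomp,
    strand_to_label,
)

RVD_OF_BASE = {"A": "NI", "T": "NG", "G": "NN", "C": "HD"}
BASE_OF_RVD = {v: k for k, v in RVD_OF_BASE.items()}

ARCHITECTURES = ("two_plasmid", "two_plasmid_HHR", "tandem", "tandem_HHR")


def rvd_string(binding_seq: str) -> str:
    """Space-separated RVD string recognizing ``binding_seq``."""
    seq = binding_seq.upper()
    try:
        return " ".join(RVD_OF_BASE[b] for b in seq)
    except KeyError as exc:
        raise AlphabetError(f"cannot encode base {exc.args[0]!r} as an RVD") from exc


def rvd_decode(rvd: str) -> str:
    """Inverse of :func:`rvd_string`."""
    if not rvd:
        return ""
    try:
        return "".join(BASE_OF_RVD[r] for r in rvd.split(" "))
    except KeyError as exc:
        raise AlphabetError(f"unknown RVD {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class DesignParams:
    """Geometric constraints for TALE window placement.

    ``tale_length`` is the binding-site length in nt (16 by default, the
    canonical TALE array length).  ``spacer_min``/``spacer_max`` bound
    the distance between the two binding sites; ``min_edge_offset``
    keeps every intended edit away from the spacer edges, where the
    deaminase is least active.  ``require_t0`` enforces the canonical T
    immediately 5' of each binding site.
    """

    tale_length: int = 16
    spacer_min: int = 14
    spacer_max: int = 20
    min_edge_offset: int = 4
    require_t0: bool = True

    def __post_init__(self) -> None:
        if not 14 <= self.tale_length <= 18:
            raise ValueError("tale_length must be within [14, 18]")
        if not 0 < self.spacer_min <= self.spacer_max:
            raise ValueError("invalid spacer bounds")


@dataclass(frozen=True)
class TaleWindow:
    """One TALE binding site.

    ``start``/``end`` are reference-strand coordinates of the bound
    duplex region; ``binding_seq`` is read 5'->3' on the bound strand
    (for H-strand windows this is the reverse complement of the
    reference slice).
    """

    label: str  # L1 | L2 | H1 | H2
    bound_strand: str  # 'L' | 'H'
    start: int  # unwrapped: may be negative or exceed the genome length
    end: int
    binding_seq: str
    rvd: str
    t0_ok: bool
    start_m: str = ""  # normalized 1-based display coordinate

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "bound_strand": self.bound_strand,
            "start_m": self.start_m,
            "start0": self.start,
            "end0": self.end,
            "binding_seq": self.binding_seq,
            "rvd": self.rvd,
            "t0_ok": self.t0_ok,
        }


@dataclass
class DdCBEPair:
    """One of the eight TALE-pair / split-orientation configurations."""

    pair_id: str
    left: TaleWindow  # L-strand window (5' side on the reference)
    right: TaleWindow  # H-strand window (3' side)
    left_split: str  # '1333N' | '1333C'
    right_split: str
    spacer_start: int
    spacer_end: int
    candidate: EditCandidate
    architecture: str = "two_plasmid"
    recommended: bool = False
    profile: Optional["SpacerProfile"] = None
    genome_length: Optional[int] = None

    @property
    def spacer_len(self) -> int:
        return self.spacer_end - self.spacer_start

    def to_dict(self) -> dict:
        disp = (
            self.spacer_start % self.genome_length
            if self.genome_length
            else max(self.spacer_start, 0)
        )
        d = {
            "pair_id": self.pair_id,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
            "left_split": self.left_split,
            "right_split": self.right_split,
            "spacer_start_m": m_coordinate(disp),
            "spacer_len": self.spacer_len,
            "architecture": self.architecture,
            "recommended": self.recommended,
        }
        if self.profile is not None:
            d["profile"] = self.profile.to_dict()
        return d


@dataclass
class SpacerProfile:
    """Editable-C census of a spacer under the deaminase context rule."""

    editable: list[tuple[SingleEdit, str]]  # (edit, consequence label)
    n_context_cs: int
    clean: bool

    @property
    def n_non_synonymous(self) -> int:
        return sum(
            1 for _, c in self.editable if c not in {"synonymous", "intended"}
        )

    def to_dict(self) -> dict:
        return {
            "n_context_cs": self.n_context_cs,
            "clean": self.clean,
            "editable": [
                {"m_pos": e.m_pos, "strand": e.edited_strand, "consequence": c}
                for e, c in self.editable
            ],
        }


# ---------------------------------------------------------------------------
# Window placement


def _left_window_ok(genome: MitoGenome, s: int, params: DesignParams) -> bool:
    """L-strand window occupying [s - tale_length, s) with optional T0."""
    seq = genome.slice(s - params.tale_length, s)
    if "N" in seq:
        return False
    if params.require_t0 and genome.base(s - params.tale_length - 1) != "T":
        return False
    return True


def _right_window_ok(genome: MitoGenome, e: int, params: DesignParams) -> bool:
    """H-strand window occupying [e, e + tale_length); T0 reads A on the reference."""
    seq = genome.slice(e, e + params.tale_length)
    if "N" in seq:
        return False
    if params.require_t0 and genome.base(e + params.tale_length) != "A":
        return False
    return True


def _make_left(genome: MitoGenome, label: str, s: int, params: DesignParams) -> TaleWindow:
    seq = genome.slice(s - params.tale_length, s)
    start = s - params.tale_length
    return TaleWindow(
        label=label,
        bound_strand="L",
        start=start,
        end=s,
        binding_seq=seq,
        rvd=rvd_string(seq),
        t0_ok=genome.base(s - params.tale_length - 1) == "T",
        start_m=m_coordinate(start % genome.length),
    )


def _make_right(genome: MitoGenome, label: str, e: int, params: DesignParams) -> TaleWindow:
    ref = genome.slice(e, e + params.tale_length)
    seq = revcomp(ref)
    return TaleWindow(
        label=label,
        bound_strand="H",
        start=e,
        end=e + params.tale_length,
        binding_seq=seq,
        rvd=rvd_string(seq),
        t0_ok=genome.base(e + params.tale_length) == "A",
        start_m=m_coordinate(e % genome.length),
    )


def propose_windows(
    candidate: EditCandidate,
    genome: MitoGenome,
    params: DesignParams = DesignParams(),
) -> dict[str, TaleWindow]:
    """Two L-strand and two H-strand windows bracketing the target.

    All four (L, H) combinations yield a spacer of length
    [spacer_min, spacer_max] containing every primary edit at least
    ``min_edge_offset`` nt from each spacer edge.  L1/H1 are the
    placements giving the shortest feasible spacer, L2/H2 the longest;
    the search is deterministic.  Raises
    :class:`DesignInfeasibleError` naming the violated constraint when
    no placement exists.
    """
    positions = sorted(e.ref_pos for e in candidate.all_edits())
    pmin, pmax = positions[0], positions[-1]
    off = params.min_edge_offset
    # spacer [s, e): s <= pmin - off, e >= pmax + off + 1
    s_hi = pmin - off
    s_lo = pmax + off + 1 - params.spacer_max
    if s_hi < s_lo:
        raise DesignInfeasibleError(
            f"edits span {pmax - pmin + 1} nt; no spacer of <= "
            f"{params.spacer_max} bp holds them {off} nt from both edges"
        )
    s_feasible = [s for s in range(s_hi, s_lo - 1, -1) if _left_window_ok(genome, s, params)]
    e_lo = pmax + off + 1
    e_hi = pmin - off + params.spacer_max
    e_feasible = [e for e in range(e_lo, e_hi + 1) if _right_window_ok(genome, e, params)]
    if not s_feasible:
        raise DesignInfeasibleError("no valid L-strand window placement (T0/N constraints)")
    if not e_feasible:
        raise DesignInfeasibleError("no valid H-strand window placement (T0/N constraints)")

    def span_ok(s: int, e: int) -> bool:
        return params.spacer_min <= e - s <= params.spacer_max

    # shortest-spacer anchor first, then the most-bracketing distinct pair
    for s1 in s_feasible:  # descending s: shortest spacer side
        for e1 in e_feasible:  # ascending e
            if not span_ok(s1, e1):
                continue
            for s2 in reversed(s_feasible):  # ascending s: longest side
                if s2 == s1:
                    continue
                for e2 in reversed(e_feasible):
                    if e2 == e1:
                        continue
                    if span_ok(s2, e2) and span_ok(s1, e2) and span_ok(s2, e1):
                        return {
                            "L1": _make_left(genome, "L1", s1, params),
                            "L2": _make_left(genome, "L2", s2, params),
                            "H1": _make_right(genome, "H1", e1, params),
                            "H2": _make_right(genome, "H2", e2, params),
                        }
    raise DesignInfeasibleError(
        "no pair of distinct window placements with all spacer lengths in "
        f"[{params.spacer_min}, {params.spacer_max}]"
    )


def recommended_split(candidate: EditCandidate) -> str:
    """Favoured split orientation: which strand's TALE carries 1333C.

    The C-terminal deaminase half goes on the TALE bound to the strand
    opposite the edited C.  This single rule reproduces the observed
    optima for light-strand genes (edited C on H => 1333C on the L
    TALE), the heavy-strand gene Nd6 (edited C on L => 1333C on the H
    TALE), and the coding-strand dicodon route (edited Cs on L =>
    1333C on the H TALE).  Returns 'C_on_L' or 'C_on_H'.
    """
    edited_label = strand_to_label(candidate.edited_strand)
    return "C_on_H" if edited_label == "L" else "C_on_L"


def enumerate_pairs(
    windows: dict[str, TaleWindow],
    candidate: EditCandidate,
    architecture: str = "two_plasmid",
    genome_length: Optional[int] = None,
) -> list[DdCBEPair]:
    """The eight pair configurations for one window set.

    Four TALE pairings (L1-H1, L2-H2 from the first screen; L1-H2,
    L2-H1 from the second) times both split orientations, each with
    exactly one 1333N and one 1333C half.  The two pairs matching the
    recommended split orientation are flagged.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    rec = recommended_split(candidate)
    pairs = []
    for l_lab, h_lab in (("L1", "H1"), ("L2", "H2"), ("L1", "H2"), ("L2", "H1")):
        left, right = windows[l_lab], windows[h_lab]
        for l_split, h_split in (("1333C", "1333N"), ("1333N", "1333C")):
            orient = "C_on_L" if l_split == "1333C" else "C_on_H"
            pairs.append(
                DdCBEPair(
                    pair_id=f"{l_lab}-{l_split[-1]}+{h_lab}-{h_split[-1]}",
                    left=left,
                    right=right,
                    left_split=l_split,
                    right_split=h_split,
                    spacer_start=left.end,
                    spacer_end=right.start,
                    candidate=candidate,
                    architecture=architecture,
                    recommended=(orient == rec),
                    genome_length=genome_length,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Spacer profiling and ranking


def spacer_profile(
    pair: DdCBEPair,
    genome: MitoGenome,
    rule: ContextRule = DEFAULT_RULE,
    feature: Optional[GeneFeature] = None,
    table=MITO_TABLE,
) -> SpacerProfile:
    """Census of every context-editable C in a pair's spacer.

    The cascade closure is computed on both strands of the spacer
    (context bases just outside the spacer are read from the genome).
    Each editable C is labelled 'intended' if it belongs to the
    candidate's plan, with its coding consequence otherwise
    ('noncoding' outside the gene).  ``clean`` means nothing outside
    the plan is editable except synonymous changes.
    """
    feature = feature or pair.candidate.feature
    s, e = pair.spacer_start, pair.spacer_end
    n = e - s
    L = genome.length

    plus_ext = genome.slice(s - 1, e)  # one 5' context base
    plus_edits = cascade_editable_set(plus_ext, (1, n + 1), rule)
    minus_ext = revcomp(genome.slice(s, e + 1))  # 5' context on the complement
    minus_edits = cascade_editable_set(minus_ext, (1, n + 1), rule)

    intended = {(ed.ref_pos, ed.edited_strand) for ed in pair.candidate.all_edits()}
    intended_cons = {
        (ed.ref_pos, ed.edited_strand): cons
        for ed, cons in pair.candidate.bystander_edits
    }

    found: list[tuple[SingleEdit, str]] = []
    for off, strand in [(o, "+") for o in plus_edits] + [(o, "-") for o in minus_edits]:
        gpos = (s + off - 1) % L if strand == "+" else (e - off) % L
        edit = SingleEdit(gpos, strand, "C" if strand == "+" else "G")
        key = (gpos, strand)
        if key in intended:
            label = "intended" if key not in intended_cons else intended_cons[key]
        else:
            label = _single_edit_consequence(genome, feature, edit, table)
        found.append((edit, label))
    found.sort(key=lambda t: (t[0].ref_pos, t[0].edited_strand))

    clean = all(
        label in {"intended", "synonymous"}
        or (ed.ref_pos, ed.edited_strand) in intended
        for ed, label in found
    )
    return SpacerProfile(editable=found, n_context_cs=len(found), clean=clean)


def _single_edit_consequence(
    genome: MitoGenome, feature: GeneFeature, edit: SingleEdit, table
) -> str:
    """Coding consequence of one reference edit within ``feature``."""
    from .genome import extract_cds

    L = genome.length
    pos = edit.ref_pos
    in_feature = feature.start <= pos < feature.end or (
        feature.end > L and feature.start <= pos + L < feature.end
    )
    if not in_feature:
        return "noncoding"
    if feature.coding_strand == "+":
        idx = (pos - feature.start) % L
    else:
        idx = (feature.end - 1 - pos) % L
    cds = extract_cds(genome, feature)
    k = idx // 3
    codon = cds[3 * k : 3 * k + 3]
    mut = list(codon)
    base_on_coding = cds[idx]
    mut[idx % 3] = "T" if base_on_coding == "C" else "A"
    return classify_consequence(codon, "".join(mut), table)


def rank_designs(pairs: list[DdCBEPair]) -> list[DdCBEPair]:
    """Stable sort: fewest non-synonymous editable bystanders, fewest
    editable Cs overall, earliest stop codon, shortest spacer."""
    if not pairs:
        raise ValueError("no pairs to rank")

    def key(p: DdCBEPair):
        prof = p.profile
        nonsyn = prof.n_non_synonymous if prof else 0
        total = prof.n_context_cs if prof else 0
        return (nonsyn, total, p.candidate.stop_codon_index, p.spacer_len)

    return sorted(pairs, key=key)


def design_gene(
    genome: MitoGenome,
    feature: GeneFeature,
    rule: ContextRule = DEFAULT_RULE,
    params: DesignParams = DesignParams(),
    policy: str = "strict",
    max_candidates: Optional[int] = None,
) -> list[DdCBEPair]:
    """End-to-end design for one gene: candidates -> windows -> ranked pairs.

    Candidates whose surroundings admit no feasible window placement are
    silently dropped; an empty list means the gene is undesignable under
    the given constraints.
    """
    from .edits import enumerate_stop_gain_candidates

    candidates = enumerate_stop_gain_candidates(genome, feature, rule, policy)
    if max_candidates is not None:
        candidates = candidates[:max_candidates]
    all_pairs: list[DdCBEPair] = []
    for cand in candidates:
        try:
            windows = propose_windows(cand, genome, params)
        except DesignInfeasibleError:
            continue
        pairs = enumerate_pairs(windows, cand, genome_length=genome.length)
        for p in pairs:
            p.profile = spacer_profile(p, genome, rule, feature)
        all_pairs.extend(pairs)
    return rank_designs(all_pairs) if all_pairs else []
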