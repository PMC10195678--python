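"""Heteroplasmy and mtDNA-wide off-target scoring from count tables.

Inputs are per-base nucleotide count tables (one row per genome
position: reference base plus A/C/G/T read counts), the standard
digest of an alignment pileup.  From these the module computes

* on-target heteroplasmy — the variant allele frequency (VAF, in
  percent of read depth) of the stop-creating edit;
* mtDNA-wide C:G->T:A single-nucleotide variants, with the depth and
  wild-type-background filters and the TC/TCC deaminase-context
  classification applied;
* the off-target penalty score
  ``(sum of off-target frequencies > 5% + 25 * sum of frequencies
  > 20%) / on-target frequency squared``, which penalizes off-target
  burden and rewards on-target efficiency when comparing editor pairs;
* the mean mtDNA-wide off-target frequency over all C/G reference
  positions and its fold change versus an untreated control.

All frequencies are handled in percent throughout; thresholds are
strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .edits import EditCandidate
from .errors import (
    CoverageError,
    ParseError,
    UndefinedFrequencyError,
)
from .genome import MitoGenome, m_coordinate

COUNT_COLUMNS = ["contig", "pos", "ref", "A", "C", "G", "T"]
BASES = ["A", "C", "G", "T"]


@dataclass
class SampleCounts:
    """Per-position base counts for one sample.

    ``table`` is indexed by 1-based position (single contig assumed,
    matching a mitochondrial pileup) with columns ref, A, C, G, T and
    depth.
    """

    sample_id: str
    contig: str
    table: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str) -> "SampleCounts":
        contigs = df["contig"].unique()
        if len(contigs) != 1:
            raise ParseError(f"expected a single contig, got {list(contigs)}")
        if df.duplicated(subset=["contig", "pos"]).any():
            dup = df[df.duplicated(subset=["contig", "pos"])]["pos"].iloc[0]
            raise ParseError(f"duplicate position {dup}")
        t = df.set_index("pos")[["ref"] + BASES].copy()
        if (t[BASES] < 0).any().any():
            raise ParseError("negative count")
        bad = ~t["ref"].isin(list("ACGTN"))
        if bad.any():
            raise ParseError(f"unknown ref base at position {t.index[bad][0]}")
        t["depth"] = t[BASES].sum(axis=1)
        return cls(sample_id=sample_id, contig=str(contigs[0]), table=t)

    @property
    def positions(self) -> pd.Index:
        return self.table.index

    def row(self, pos: int) -> pd.Series:
        if pos not in self.table.index:
            raise CoverageError(f"{self.sample_id}: no counts at position {pos}")
        return self.table.loc[pos]


def read_count_table(path: str | Path, sample_id: Optional[str] = None) -> SampleCounts:
    """Read the TSV dialect ``contig<TAB>pos<TAB>ref<TAB>A<TAB>C<TAB>G<TAB>T``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != COUNT_COLUMNS:
        raise ParseError(
            f"{path}: expected header {COUNT_COLUMNS}, got {list(df.columns)}"
        )
    try:
        return SampleCounts.from_frame(df, sample_id or path.stem)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_count_table(sample: SampleCounts, path: str | Path) -> None:
    df = sample.table.reset_index()[["pos", "ref"] + BASES]
    df.insert(0, "contig", sample.contig)
    df.to_csv(path, sep="\t", index=False)


def vaf(row: pd.Series, alt_base: str) -> float:
    """Percent of reads carrying ``alt_base``; errors at zero depth."""
    depth = int(row["depth"])
    if depth == 0:
        raise UndefinedFrequencyError("zero depth")
    return 100.0 * float(row[alt_base]) / depth


def on_target_heteroplasmy(
    sample: SampleCounts, candidate: EditCandidate
) -> tuple[float, dict[str, float]]:
    """Headline on-target VAF plus a per-edit breakdown.

    The headline value is the VAF of the stop-creating edit (the last
    primary edit in application order); cascade prerequisites and
    bystanders are reported alongside, keyed by m. coordinate.
    """
    breakdown: dict[str, float] = {}
    for edit in candidate.all_edits():
        row = sample.row(edit.ref_pos + 1)
        breakdown[edit.m_pos] = vaf(row, edit.alt_base_on_ref)
    headline = breakdown[candidate.primary_edits[-1].m_pos]
    return headline, breakdown


# ---------------------------------------------------------------------------
# SNV calling


@dataclass(frozen=True)
class FilterParams:
    """SNV filters: depth must exceed ``min_depth`` in every sample; a
    variant at >= ``wt_max_pct`` in any control is treated as a
    genome difference, not an induced edit."""

    min_depth: int = 30
    wt_max_pct: float = 45.0


@dataclass
class SnvCall:
    pos: int  # 1-based
    ref: str
    alt: str
    frequency: float  # percent, mean over treated samples
    is_cg_ta: bool
    is_tc: bool
    is_tcc: bool
    context_class: str  # TC | TCC | other
    passed_filters: bool
    filter_reasons: list[str] = field(default_factory=list)
    control_frequency: float = 0.0

    @property
    def m_pos(self) -> str:
        return m_coordinate(self.pos - 1)


def snv_context(genome: MitoGenome, pos: int, ref: str) -> tuple[bool, bool, str]:
    """Deaminase context of a C>T (ref C) or G>A (ref G) variant.

    Read on the strand carrying the edited C: the reference strand for
    ref C, the complement for ref G.  ``is_tc`` means the 5' neighbour
    is T; ``is_tcc`` additionally requires the edited C to begin a CC
    (i.e. 5'-TCC-3' with the edited C in the middle position of the
    motif's first TC).  TCC implies TC; both flags are returned with a
    single headline class.  ``pos`` is 1-based.
    """
    p = pos - 1
    if ref == "C":
        is_tc = genome.base(p - 1) == "T"
        is_tcc = is_tc and genome.base(p + 1) == "C"
    elif ref == "G":
        # complement strand: 5' neighbour is reference p+1, next C is p-1
        is_tc = genome.base(p + 1) == "A"
        is_tcc = is_tc and genome.base(p - 1) == "G"
    else:
        return False, False, "other"
    cls = "TCC" if is_tcc else ("TC" if is_tc else "other")
    return is_tc, is_tcc, cls


def call_cg_ta_snvs(
    treated: Iterable[SampleCounts],
    controls: Iterable[SampleCounts],
    genome: MitoGenome,
    filters: FilterParams = FilterParams(),
    min_frequency_pct: float = 0.0,
) -> list[SnvCall]:
    """C:G->T:A variants across the genome with filter annotations.

    A position is reported when any treated sample shows the deaminase
    alt allele (T for ref C, A for ref G) above ``min_frequency_pct``.
    Calls failing the depth or wild-type-background filters are
    returned with ``passed_filters=False`` and the reasons recorded,
    so callers can inspect what was removed.
    """
    treated = list(treated)
    controls = list(controls)
    if not treated:
        raise ValueError("no treated samples")
    everyone = treated + controls
    common = treated[0].positions
    for s in everyone[1:]:
        common = common.intersection(s.positions)
    if len(common) == 0:
        raise CoverageError("no genome position covered in all samples")

    calls: list[SnvCall] = []
    for pos in sorted(common):
        p = pos - 1
        ref = genome.base(p)
        if ref not in "CG":
            continue
        alt = "T" if ref == "C" else "A"
        t_freqs = [vaf(s.row(pos), alt) for s in treated]
        freq = float(np.mean(t_freqs))
        if freq <= min_frequency_pct:
            continue
        reasons = []
        if any(int(s.row(pos)["depth"]) <= filters.min_depth for s in everyone):
            reasons.append("depth")
        c_freqs = [vaf(s.row(pos), alt) for s in controls] if controls else [0.0]
        if controls and max(c_freqs) >= filters.wt_max_pct:
            reasons.append("wt_background")
        is_tc, is_tcc, cls = snv_context(genome, pos, ref)
        calls.append(
            SnvCall(
                pos=pos,
                ref=ref,
                alt=alt,
                frequency=freq,
                is_cg_ta=True,
                is_tc=is_tc,
                is_tcc=is_tcc,
                context_class=cls,
                passed_filters=not reasons,
                filter_reasons=reasons,
                control_frequency=float(np.mean(c_freqs)),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Scores


@dataclass(frozen=True)
class PenaltyParams:
    """Thresholds (percent) and weight of the off-target penalty."""

    low_threshold: float = 5.0
    high_threshold: float = 20.0
    high_multiplier: float = 25.0

    def __post_init__(self) -> None:
        if not 0 <= self.low_threshold < self.high_threshold:
            raise ValueError("need 0 <= low_threshold < high_threshold")
        if self.high_multiplier <= 0:
            raise ValueError("high_multiplier must be positive")


def penalty_score(
    on_target_pct: float,
    offtarget_pcts: Iterable[float],
    params: PenaltyParams = PenaltyParams(),
) -> float:
    """Off-target penalty of one editor pair.

    ``(sum of frequencies > low) + multiplier * (sum of frequencies >
    high)``, divided by the squared on-target frequency; frequencies
    above the high threshold contribute to both sums.  All inputs in
    percent.
    """
    if on_target_pct <= 0:
        raise UndefinedFrequencyError("penalty score undefined at 0% on-target")
    offs = np.asarray(list(offtarget_pcts), dtype=float)
    low = offs[offs > params.low_threshold].sum()
    high = offs[offs > params.high_threshold].sum()
    return float((low + params.high_multiplier * high) / on_target_pct**2)


def mean_offtarget_and_fold(
    treated: SampleCounts,
    control: SampleCounts,
    genome: MitoGenome,
    exclude: Optional[tuple[int, int]] = None,
    exclude_margin: int = 5,
) -> tuple[float, float]:
    """Mean C:G->T:A frequency over all C/G positions, and its fold change.

    The mean runs over every C/G reference position covered in both
    samples, excluding the on-target interval (0-based half-open)
    widened by ``exclude_margin`` on each side.  The fold change is
    treated mean / control mean (``inf`` for a zero control mean).
    """
    excluded = set()
    if exclude is not None:
        lo, hi = exclude
        excluded = {
            p % genome.length for p in range(lo - exclude_margin, hi + exclude_margin)
        }
    common = treated.positions.intersection(control.positions)
    t_vals, c_vals = [], []
    for pos in common:
        p = pos - 1
        if p in excluded:
            continue
        ref = genome.base(p)
        if ref not in "CG":
            continue
        alt = "T" if ref == "C" else "A"
        trow, crow = treated.row(pos), control.row(pos)
        if int(trow["depth"]) == 0 or int(crow["depth"]) == 0:
            continue
        t_vals.append(vaf(trow, alt))
        c_vals.append(vaf(crow, alt))
    if not t_vals:
        raise CoverageError("no C/G positions covered in both samples")
    mean_t = float(np.mean(t_vals))
    mean_c = float(np.mean(c_vals))
    fold = math.inf if mean_c == 0 else mean_t / mean_c
    return mean_t, fold


@dataclass
class OffTargetReport:
    """Full per-sample evaluation of one editor pair."""

    sample_id: str
    on_target_pct: float
    on_target_breakdown: dict[str, float]
    snvs: list[SnvCall]
    mean_offtarget_pct: float
    fold_vs_control: float
    penalty: float

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "on_target_pct": self.on_target_pct,
            "on_target_breakdown": self.on_target_breakdown,
            "mean_offtarget_pct": self.mean_offtarget_pct,
            "fold_vs_control": (
                "inf" if math.isinf(self.fold_vs_control) else self.fold_vs_control
            ),
            "penalty_score": self.penalty,
            "n_snvs_passing": sum(1 for s in self.snvs if s.passed_filters),
            "snvs": [
                {
                    "m_pos": s.m_pos,
                    "change": f"{s.ref}>{s.alt}",
                    "frequency_pct": s.frequency,
                    "context": s.context_class,
                    "passed_filters": s.passed_filters,
                    "filter_reasons": s.filter_reasons,
                }
                for s in self.snvs
            ],
        }


def evaluate_pair(
    treated: SampleCounts,
    controls: list[SampleCounts],
    genome: MitoGenome,
    candidate: EditCandidate,
    filters: FilterParams = FilterParams(),
    penalty_params: PenaltyParams = PenaltyParams(),
    exclude_margin: int = 5,
    min_frequency_pct: float = 0.0,
) -> OffTargetReport:
    """On-target, SNV list, mean off-target, fold change and penalty."""
    on_pct, breakdown = on_target_heteroplasmy(treated, candidate)
    positions = [e.ref_pos for e in candidate.all_edits()]
    exclude = (min(positions), max(positions) + 1)
    snvs = call_cg_ta_snvs(
        [treated], controls, genome, filters, min_frequency_pct=min_frequency_pct
    )
    on_positions = {
        p % genome.length
        for p in range(exclude[0] - exclude_margin, exclude[1] + exclude_margin)
    }
    off_freqs = [
        s.frequency for s in snvs if s.passed_filters and (s.pos - 1) not in on_positions
    ]
    pen = penalty_score(on_pct, off_freqs, penalty_params) if on_pct > 0 else math.nan
    mean_off, fold = mean_offtarget_and_fold(
        treated, controls[0], genome, exclude, exclude_margin
    )
    return OffTargetReport(
        sample_id=treated.sample_id,
        on_target_pct=on_pct,
        on_target_breakdown=breakdown,
        snvs=snvs,
        mean_offtarget_pct=mean_off,
        fold_vs_control=fold,
        penalty=pen,
    )


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(
    snvs: list[SnvCall], genome: MitoGenome, path: str | Path, source: str = "mitostop"
) -> None:
    """VCF 4.2 with VAF/CTX INFO fields and filter reasons."""
    snvs = sorted(snvs, key=lambda s: s.pos)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        f"##contig=<ID={genome.name},length={genome.length}>",
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency, percent">',
        '##INFO=<ID=CTX,Number=1,Type=String,Description="Deaminase sequence context (TC/TCC/other)">',
        '##FILTER=<ID=depth,Description="Read depth not above threshold in all samples">',
        '##FILTER=<ID=wt_background,Description="Present in control samples at high frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for s in snvs:
        filt = "PASS" if s.passed_filters else ";".join(s.filter_reasons)
        info = f"VAF={s.frequency:.4f};CTX={s.context_class}"
        lines.append(
            f"{genome.name}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t{filt}\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
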