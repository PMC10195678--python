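"""Count tables, heteroplasmy, SNV filters, penalty score, VCF output."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitostop import (
    FilterParams,
    MitoGenome,
    PenaltyParams,
    SampleCounts,
    TruthTable,
    call_cg_ta_snvs,
    enumerate_stop_gain_candidates,
    make_count_table,
    mean_offtarget_and_fold,
    on_target_heteroplasmy,
    penalty_score,
    read_count_table,
    snv_context,
    vaf,
    write_count_table,
    write_vcf,
)
from mitostop.errors import (
    CoverageError,
    ParseError,
    UndefinedFrequencyError,
)


def _table(rows, sample_id="s"):
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "A", "C", "G", "T"])
    return SampleCounts.from_frame(df, sample_id)


def _uniform_counts(genome, depth=1000, sample_id="s", overrides=None):
    """Deterministic count table: reference-only reads, plus overrides
    {pos: (alt_base, alt_count)}."""
    rows = []
    overrides = overrides or {}
    for pos in range(1, genome.length + 1):
        ref = genome.base(pos - 1)
        counts = {b: 0 for b in "ACGT"}
        counts[ref] = depth
        if pos in overrides:
            alt, k = overrides[pos]
            counts[alt] += k
            counts[ref] -= k
        rows.append([genome.name, pos, ref, counts["A"], counts["C"],
                     counts["G"], counts["T"]])
    return _table(rows, sample_id)


class TestCountTableIO:
    def test_round_trip(self, tmp_path, toy_genome):
        truth = TruthTable(depth=200, variants={}, background_pct=0.5, seed=5)
        sample = make_count_table(toy_genome, truth, "sim")
        path = tmp_path / "c.tsv"
        write_count_table(sample, path)
        back = read_count_table(path, "sim")
        pd.testing.assert_frame_equal(sample.table, back.table)

    def test_well_formed(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "contig\tpos\tref\tA\tC\tG\tT\n"
            "chrM\t1\tA\t10\t0\t0\t0\n"
            "chrM\t2\tC\t0\t9\t0\t1\n"
            "chrM\t3\tG\t0\t0\t10\t0\n"
        )
        s = read_count_table(p)
        assert len(s.positions) == 3
        assert s.row(2)["depth"] == 10

    @pytest.mark.parametrize(
        "body",
        [
            "chrM\t1\tA\t10\t0\t0\t0\nchrM\t1\tA\t10\t0\t0\t0\n",  # duplicate
            "chrM\t1\tA\t-1\t0\t0\t0\n",  # negative count
            "chrM\t1\tZ\t10\t0\t0\t0\n",  # unknown ref
        ],
    )
    def test_invalid_tables_rejected(self, tmp_path, body):
        p = tmp_path / "bad.tsv"
        p.write_text("contig\tpos\tref\tA\tC\tG\tT\n" + body)
        with pytest.raises(ParseError):
            read_count_table(p)

    def test_wrong_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tposition\tref\tA\tC\tG\tT\nchrM\t1\tA\t1\t0\t0\t0\n")
        with pytest.raises(ParseError):
            read_count_table(p)


class TestVaf:
    def test_simple(self):
        s = _table([["chrM", 1, "C", 0, 50, 0, 50]])
        assert vaf(s.row(1), "T") == 50.0
        assert vaf(s.row(1), "C") == 50.0

    def test_zero_depth(self):
        s = _table([["chrM", 1, "C", 0, 0, 0, 0]])
        with pytest.raises(UndefinedFrequencyError):
            vaf(s.row(1), "T")

    @given(st.lists(st.integers(0, 1000), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_base_frequencies_sum_to_100(self, counts):
        if sum(counts) == 0:
            return
        s = _table([["chrM", 1, "A", *counts]])
        total = sum(vaf(s.row(1), b) for b in "ACGT")
        assert total == pytest.approx(100.0)


class TestOnTarget:
    def test_planted_fifty_percent_recovered(self, toy_genome, toy_features):
        cand = enumerate_stop_gain_candidates(toy_genome, toy_features[0])[0]
        pos = cand.primary_edits[-1].ref_pos + 1
        depth = 10_000
        truth = TruthTable(depth=depth, variants={pos: 50.0}, seed=11)
        sample = make_count_table(toy_genome, truth)
        het, breakdown = on_target_heteroplasmy(sample, cand)
        se = 100 * math.sqrt(0.5 * 0.5 / depth)
        assert abs(het - 50.0) <= 3 * se
        assert breakdown[cand.primary_edits[-1].m_pos] == het

    def test_zero_alt_gives_zero(self, toy_genome, toy_features):
        cand = enumerate_stop_gain_candidates(toy_genome, toy_features[0])[0]
        sample = _uniform_counts(toy_genome, depth=100)
        het, _ = on_target_heteroplasmy(sample, cand)
        assert het == 0.0

    def test_dicodon_reports_both_positions(self, toy_genome, toy_features):
        g13 = next(f for f in toy_features if f.gene_name == "g13")
        cand = next(
            c
            for c in enumerate_stop_gain_candidates(toy_genome, g13)
            if c.stop_codon_index == 91
        )
        sample = _uniform_counts(toy_genome, depth=100)
        _, breakdown = on_target_heteroplasmy(sample, cand)
        assert len(breakdown) == 2

    def test_missing_position_is_coverage_error(self, toy_genome, toy_features):
        cand = enumerate_stop_gain_candidates(toy_genome, toy_features[0])[0]
        sample = _table([["chrM", 1, toy_genome.base(0), 10, 0, 0, 0]])
        with pytest.raises(CoverageError):
            on_target_heteroplasmy(sample, cand)


class TestSnvCallingFilters:
    def test_planted_offtarget_recovered(self, toy_genome):
        pos = next(
            p for p in range(100, toy_genome.length) if toy_genome.base(p - 1) == "C"
        )
        treated = _uniform_counts(toy_genome, 1000, "t", {pos: ("T", 100)})
        control = _uniform_counts(toy_genome, 1000, "c")
        calls = call_cg_ta_snvs([treated], [control], toy_genome)
        hit = [c for c in calls if c.pos == pos]
        assert hit and hit[0].passed_filters
        assert hit[0].frequency == pytest.approx(10.0)

    def test_wt_background_removed(self, toy_genome):
        pos = next(
            p for p in range(100, toy_genome.length) if toy_genome.base(p - 1) == "G"
        )
        treated = _uniform_counts(toy_genome, 1000, "t", {pos: ("A", 600)})
        control = _uniform_counts(toy_genome, 1000, "c", {pos: ("A", 600)})
        calls = call_cg_ta_snvs([treated], [control], toy_genome)
        hit = [c for c in calls if c.pos == pos][0]
        assert not hit.passed_filters
        assert "wt_background" in hit.filter_reasons

    def test_low_depth_excluded(self, toy_genome):
        pos = next(
            p for p in range(100, toy_genome.length) if toy_genome.base(p - 1) == "C"
        )
        treated = _uniform_counts(toy_genome, 1000, "t", {pos: ("T", 100)})
        control = _uniform_counts(toy_genome, 1000, "c")
        # drop the control's depth at the variant position to 20
        control.table.loc[pos, "C"] = 20
        control.table.loc[pos, "depth"] = 20
        calls = call_cg_ta_snvs([treated], [control], toy_genome)
        hit = [c for c in calls if c.pos == pos][0]
        assert not hit.passed_filters
        assert "depth" in hit.filter_reasons

    def test_filter_order_independence(self, toy_genome):
        """Depth and background filters are set intersections; both
        reasons are recorded when both apply."""
        pos = next(
            p for p in range(100, toy_genome.length) if toy_genome.base(p - 1) == "C"
        )
        treated = _uniform_counts(toy_genome, 1000, "t", {pos: ("T", 500)})
        control = _uniform_counts(toy_genome, 25, "c", {pos: ("T", 13)})
        calls = call_cg_ta_snvs([treated], [control], toy_genome)
        hit = [c for c in calls if c.pos == pos][0]
        assert set(hit.filter_reasons) == {"depth", "wt_background"}

    def test_no_common_positions(self, toy_genome):
        a = _table([["chrM", 1, toy_genome.base(0), 100, 0, 0, 0]], "a")
        b = _table([["chrM", 2, toy_genome.base(1), 100, 0, 0, 0]], "b")
        with pytest.raises(CoverageError):
            call_cg_ta_snvs([a], [b], toy_genome)


class TestSnvContext:
    def test_g_in_tga_codon_is_tc(self):
        """The G of a reference TGA reads 5'-TCA-3' on the other strand."""
        g = MitoGenome("g", "AATGAAA", circular=False)
        is_tc, is_tcc, cls = snv_context(g, 4, "G")  # the G of TGA (1-based 4)
        assert is_tc and cls == "TC"

    def test_c_preceded_by_a_is_other(self):
        g = MitoGenome("g", "AACAA", circular=False)
        assert snv_context(g, 3, "C") == (False, False, "other")

    def test_first_c_of_tcc_flags_both(self):
        g = MitoGenome("g", "ATCCA", circular=False)
        is_tc, is_tcc, cls = snv_context(g, 3, "C")
        assert is_tc and is_tcc and cls == "TCC"

    def test_minus_strand_tcc(self):
        # reference GGA: complement reads TCC; the middle G is the first C
        g = MitoGenome("g", "AGGAA", circular=False)
        is_tc, is_tcc, cls = snv_context(g, 3, "G")
        assert is_tc and is_tcc and cls == "TCC"


class TestPenaltyScore:
    def test_no_offtargets_above_low(self):
        assert penalty_score(40.0, [1.0, 4.9, 5.0]) == 0.0

    def test_worked_example(self):
        # offs {6, 21}, on-target 50: (6 + 21 + 25*21) / 2500
        assert penalty_score(50.0, [6.0, 21.0]) == pytest.approx(0.2208)

    def test_decreases_with_on_target(self):
        offs = [6.0, 30.0]
        scores = [penalty_score(x, offs) for x in (10, 20, 40, 80)]
        assert scores == sorted(scores, reverse=True)

    @given(
        st.lists(st.floats(0, 100), min_size=1, max_size=20),
        st.integers(0, 19),
        st.floats(0.1, 50),
    )
    @settings(max_examples=300, deadline=None)
    def test_monotone_in_each_frequency(self, offs, idx, bump):
        """Raising any off-target frequency never lowers the score."""
        idx = idx % len(offs)
        bumped = list(offs)
        bumped[idx] = min(100.0, bumped[idx] + bump)
        assert penalty_score(50.0, bumped) >= penalty_score(50.0, offs)

    def test_zero_on_target_undefined(self):
        with pytest.raises(UndefinedFrequencyError):
            penalty_score(0.0, [10.0])

    def test_params_validated(self):
        with pytest.raises(ValueError):
            PenaltyParams(low_threshold=30, high_threshold=20)


class TestMeanOfftargetAndFold:
    def test_worked_fold_change(self, toy_genome):
        """Planted means of 0.29% vs 0.02% give a 14.5-fold change."""
        depth = 10_000
        cg = [p for p in range(1, toy_genome.length + 1)
              if toy_genome.base(p - 1) in "CG"]
        t_over = {p: ("T" if toy_genome.base(p - 1) == "C" else "A", 29)
                  for p in cg}  # 29 / 10000 reads = 0.29% at every site
        c_over = {p: ("T" if toy_genome.base(p - 1) == "C" else "A", 2)
                  for p in cg}  # 2 / 10000 = 0.02%
        treated = _uniform_counts(toy_genome, depth, "t", t_over)
        control = _uniform_counts(toy_genome, depth, "c", c_over)
        mean_t, fold = mean_offtarget_and_fold(treated, control, toy_genome)
        assert mean_t == pytest.approx(0.29)
        assert fold == pytest.approx(14.5)

    def test_identical_samples_fold_one(self, toy_genome):
        cg = [p for p in range(1, toy_genome.length + 1)
              if toy_genome.base(p - 1) in "CG"]
        over = {p: ("T" if toy_genome.base(p - 1) == "C" else "A", 3) for p in cg}
        a = _uniform_counts(toy_genome, 1000, "a", over)
        b = _uniform_counts(toy_genome, 1000, "b", over)
        _, fold = mean_offtarget_and_fold(a, b, toy_genome)
        assert fold == pytest.approx(1.0)

    def test_zero_control_is_infinite(self, toy_genome):
        pos = next(p for p in range(1, toy_genome.length)
                   if toy_genome.base(p - 1) == "C")
        a = _uniform_counts(toy_genome, 1000, "a", {pos: ("T", 10)})
        b = _uniform_counts(toy_genome, 1000, "b")
        _, fold = mean_offtarget_and_fold(a, b, toy_genome)
        assert math.isinf(fold)

    def test_excluded_interval_ignored(self, toy_genome):
        pos = next(p for p in range(200, toy_genome.length)
                   if toy_genome.base(p - 1) == "C")
        a = _uniform_counts(toy_genome, 1000, "a", {pos: ("T", 500)})
        b = _uniform_counts(toy_genome, 1000, "b")
        mean_in, _ = mean_offtarget_and_fold(a, b, toy_genome)
        mean_out, _ = mean_offtarget_and_fold(
            a, b, toy_genome, exclude=(pos - 1, pos)
        )
        assert mean_out == 0.0 and mean_in > 0.0

    def test_background_recovered_from_simulation(self, toy_genome):
        """0.02% background at depth 1e4 over all C/G sites is recovered
        within 3 standard errors of the mean."""
        depth = 10_000
        truth_t = TruthTable(depth=depth, background_pct=0.02, seed=21)
        truth_c = TruthTable(depth=depth, background_pct=0.02, seed=22)
        treated = make_count_table(toy_genome, truth_t, "t")
        control = make_count_table(toy_genome, truth_c, "c")
        mean_t, _ = mean_offtarget_and_fold(treated, control, toy_genome)
        n_sites = sum(1 for b in toy_genome.sequence if b in "CG")
        p = 0.0002
        se = 100 * math.sqrt(p * (1 - p) / (depth * n_sites))
        assert abs(mean_t - 0.02) <= 3 * se


class TestVcf:
    def test_round_trip_through_pysam(self, tmp_path, toy_genome):
        pos1 = next(p for p in range(100, toy_genome.length)
                    if toy_genome.base(p - 1) == "C")
        pos2 = next(p for p in range(pos1 + 10, toy_genome.length)
                    if toy_genome.base(p - 1) == "G")
        treated = _uniform_counts(toy_genome, 1000, "t",
                                  {pos1: ("T", 100), pos2: ("A", 80)})
        control = _uniform_counts(toy_genome, 1000, "c")
        calls = call_cg_ta_snvs([treated], [control], toy_genome)
        out = tmp_path / "calls.vcf"
        write_vcf(calls, toy_genome, out)

        import pysam

        with pysam.VariantFile(str(out)) as vcf:
            records = list(vcf)
        assert [(r.pos, r.ref, r.alts[0]) for r in records] == [
            (c.pos, c.ref, c.alt) for c in sorted(calls, key=lambda c: c.pos)
        ]
        assert records[0].info["VAF"] == pytest.approx(10.0)

    def test_empty_call_set_header_only(self, tmp_path, toy_genome):
        out = tmp_path / "empty.vcf"
        write_vcf([], toy_genome, out)
        lines = out.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert any("contig" in l for l in lines)
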