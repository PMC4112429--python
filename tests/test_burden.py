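"""Binomial burden test, gene-level filters and the small utilities."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fhburden.burden import (
    binomial_burden_p,
    expected_carriers,
    maf_from_count,
    round_sig,
    run_burden_scan,
    run_gene_list_burden,
)
from fhburden.filtering import GeneCounts

N_CASE, N_CONTROL = 71, 1926


def tail_sum_oracle(k_case: int, k_control: int, n_case: int, n_control: int) -> float:
    """Independent brute-force oracle: exact rational tail sum
    sum_{j>=k} C(n,j) pi^j (1-pi)^(n-j) with pi = n_case/(n_case+n_control)."""
    n = k_case + k_control
    if n == 0 or k_case == 0:
        return 1.0
    pi = Fraction(n_case, n_case + n_control)
    total = Fraction(0)
    for j in range(k_case, n + 1):
        total += comb(n, j) * pi**j * (1 - pi) ** (n - j)
    return float(total)


class TestBinomialBurdenP:
    @pytest.mark.parametrize(
        "k_case,k_control,expected_2sf",
        [
            (3, 2, 4.3e-4),
            (2, 0, 1.3e-3),
            (3, 4, 1.4e-3),
            (2, 1, 3.7e-3),
        ],
    )
    def test_published_count_pairs(self, k_case, k_control, expected_2sf):
        p = binomial_burden_p(k_case, k_control, N_CASE, N_CONTROL)
        assert round_sig(p, 2) == pytest.approx(expected_2sf)

    def test_two_case_zero_control_closed_form(self):
        """With two pooled events both in cases, p = pi^2."""
        pi = N_CASE / (N_CASE + N_CONTROL)
        assert binomial_burden_p(2, 0, N_CASE, N_CONTROL) == pytest.approx(pi**2, rel=1e-12)

    def test_no_case_signal_is_one(self):
        assert binomial_burden_p(0, 5, N_CASE, N_CONTROL) == 1.0
        assert binomial_burden_p(0, 0, N_CASE, N_CONTROL) == 1.0

    def test_negative_counts_fatal(self):
        with pytest.raises(ValueError):
            binomial_burden_p(-1, 0, N_CASE, N_CONTROL)
        with pytest.raises(ValueError):
            binomial_burden_p(1, 0, 0, N_CONTROL)

    def test_oracle_equivalence_sample(self):
        for k_case, k_control in [(1, 0), (2, 3), (5, 5), (10, 40), (25, 25), (50, 0)]:
            p = binomial_burden_p(k_case, k_control, N_CASE, N_CONTROL)
            expected = tail_sum_oracle(k_case, k_control, N_CASE, N_CONTROL)
            assert p == pytest.approx(expected, rel=1e-12)

    def test_symmetric_half_probability(self):
        """Equal arms give pi = 1/2: the standard symmetric binomial tail."""
        p = binomial_burden_p(7, 3, 500, 500)
        expected = sum(comb(10, j) for j in range(7, 11)) / 2**10
        assert p == pytest.approx(expected, rel=1e-12)

    @given(
        k_case=st.integers(min_value=0, max_value=30),
        k_control=st.integers(min_value=0, max_value=30),
    )
    def test_monotone_in_case_share(self, k_case, k_control):
        """For fixed pooled total, shifting one event from controls to cases
        never increases p."""
        if k_case + k_control == 0:
            return
        p = binomial_burden_p(k_case, k_control, N_CASE, N_CONTROL)
        if k_control > 0:
            p_shifted = binomial_burden_p(k_case + 1, k_control - 1, N_CASE, N_CONTROL)
            assert p_shifted <= p + 1e-15


def _counts(gene, chrom, k_case, k_control):
    return GeneCounts(gene=gene, chrom=chrom, case_events=k_case, control_events=k_control)


class TestBurdenScan:
    def test_filters_and_flagging(self):
        counts = {
            "CH25H": _counts("CH25H", "10", 3, 2),
            "MANY": _counts("MANY", "1", 3, 5),  # >4 control events
            "EDGE": _counts("EDGE", "2", 3, 4),  # exactly 4: still tested
            "XGENE": _counts("XGENE", "X", 3, 0),
            "SILENT": _counts("SILENT", "3", 0, 2),
        }
        results = {r.gene: r for r in run_burden_scan(counts, N_CASE, N_CONTROL)}
        assert results["MANY"].status == "excluded_control_count"
        assert results["MANY"].p_value is None and not results["MANY"].flagged
        assert results["XGENE"].status == "excluded_x_chromosome"
        assert results["SILENT"].status == "excluded_no_variants"
        assert results["EDGE"].status == "tested"
        assert round_sig(results["EDGE"].p_value, 2) == pytest.approx(1.4e-3)
        assert results["EDGE"].flagged
        assert results["CH25H"].flagged

    def test_flag_threshold_is_strict(self):
        p21 = binomial_burden_p(2, 1, N_CASE, N_CONTROL)
        counts = {"G": _counts("G", "1", 2, 1)}
        (r,) = run_burden_scan(counts, N_CASE, N_CONTROL, p_flag_threshold=p21)
        assert r.status == "tested" and not r.flagged  # p == threshold: not flagged
        (r2,) = run_burden_scan(counts, N_CASE, N_CONTROL, p_flag_threshold=p21 * 1.0001)
        assert r2.flagged

    def test_sorted_by_p_then_gene(self):
        counts = {
            "B": _counts("B", "1", 2, 1),
            "A": _counts("A", "2", 2, 1),
            "TOP": _counts("TOP", "3", 3, 2),
            "OUT": _counts("OUT", "4", 1, 5),
        }
        genes = [r.gene for r in run_burden_scan(counts, N_CASE, N_CONTROL)]
        assert genes == ["TOP", "A", "B", "OUT"]

    def test_chrx_label_variants_excluded(self):
        counts = {"G1": _counts("G1", "chrX", 2, 0)}
        (r,) = run_burden_scan(counts, N_CASE, N_CONTROL)
        assert r.status == "excluded_x_chromosome"


class TestGeneListBurden:
    def test_pooling_is_addition(self):
        counts = {
            "G1": _counts("G1", "1", 1, 10),
            "G2": _counts("G2", "2", 1, 10),
        }
        combined, per_gene = run_gene_list_burden(counts, ["G1", "G2"], N_CASE, N_CONTROL)
        assert (combined.k_case, combined.k_control) == (2, 20)
        assert combined.p_value == pytest.approx(tail_sum_oracle(2, 20, N_CASE, N_CONTROL), rel=1e-12)
        assert len(per_gene) == 2

    def test_no_filters_in_list_mode(self):
        counts = {"G1": _counts("G1", "X", 2, 30)}  # would fail both scan filters
        combined, (r,) = run_gene_list_burden(counts, ["G1"], N_CASE, N_CONTROL)
        assert r.status == "tested"

    def test_single_gene_list_matches_per_gene(self):
        counts = {"G1": _counts("G1", "1", 3, 2)}
        combined, (r,) = run_gene_list_burden(counts, ["G1"], N_CASE, N_CONTROL)
        assert combined.p_value == r.p_value
        assert (combined.k_case, combined.k_control) == (r.k_case, r.k_control)

    def test_listed_gene_without_calls_reported(self):
        combined, (r,) = run_gene_list_burden({}, ["GHOST"], N_CASE, N_CONTROL)
        assert r.p_value == 1.0 and combined.p_value == 1.0

    def test_empty_list_fatal(self):
        with pytest.raises(ValueError):
            run_gene_list_burden({}, [], N_CASE, N_CONTROL)


class TestUtilities:
    def test_expected_carriers(self):
        value = expected_carriers(1926, 1 / 500)
        assert value == pytest.approx(3.852)
        assert round(value) == 4
        assert expected_carriers(0, 0.5) == 0.0
        with pytest.raises(ValueError):
            expected_carriers(100, 0.0)

    def test_maf_from_count(self):
        assert maf_from_count(1, 6503) == pytest.approx(7.69e-5, rel=1e-3)
        assert round_sig(maf_from_count(1, 6503), 1) == pytest.approx(8e-5)
        assert maf_from_count(0, 10) == 0.0
        assert maf_from_count(20, 10) == 1.0
        with pytest.raises(ValueError):
            maf_from_count(3, 1)
        with pytest.raises(ValueError):
            maf_from_count(1, 0)

    def test_round_sig(self):
        assert round_sig(0.00042578, 2) == 4.3e-4
        assert round_sig(0.0012640, 2) == 1.3e-3
        assert round_sig(0.0, 2) == 0.0
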