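"""Polygenic LDL-C score arithmetic, APOE scoring and group comparisons."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fhburden.genescore import (
    APOE_SCORES,
    DEFAULT_CUTOFF,
    GeneScoreResult,
    SnpWeight,
    apoe_from_snps,
    apoe_score,
    classify_polygenic,
    compare_groups,
    gene_score,
    load_genotypes,
    load_weights,
)


class TestApoeScore:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("e2", "e2"), -0.9),
            (("e2", "e3"), -0.4),
            (("e2", "e4"), -0.2),
            (("e3", "e3"), 0.0),
            (("e3", "e4"), 0.1),
            (("e4", "e4"), 0.2),
        ],
    )
    def test_table(self, pair, expected):
        assert apoe_score(pair) == expected
        assert apoe_score(pair[::-1]) == expected  # unordered pair

    def test_epsilon_spelling_accepted(self):
        assert apoe_score(("ε2", "ε4")) == -0.2

    def test_invalid_haplotype_rejected(self):
        with pytest.raises(ValueError):
            apoe_score(("e1", "e3"))


class TestApoeFromSnps:
    @pytest.mark.parametrize(
        "rs429358,rs7412,expected",
        [
            (("T", "T"), ("C", "C"), ("e3", "e3")),
            (("C", "C"), ("C", "C"), ("e4", "e4")),
            (("T", "T"), ("T", "T"), ("e2", "e2")),
            (("C", "T"), ("C", "C"), ("e3", "e4")),
            (("T", "T"), ("C", "T"), ("e2", "e3")),
            (("C", "T"), ("C", "T"), ("e2", "e4")),  # double het resolved without e1
        ],
    )
    def test_diplotype_derivation(self, rs429358, rs7412, expected):
        assert apoe_from_snps(rs429358, rs7412) == expected

    def test_missing_genotype_gives_none(self):
        assert apoe_from_snps(None, ("C", "C")) is None

    def test_e1_implied_counts_rejected(self):
        with pytest.raises(ValueError, match="e1"):
            apoe_from_snps(("C", "C"), ("T", "T"))

    def test_invalid_allele_rejected(self):
        with pytest.raises(ValueError, match="rs7412"):
            apoe_from_snps(("C", "T"), ("A", "C"))


W3 = [
    SnpWeight("snp1", "A", 0.1, other_allele="G"),
    SnpWeight("snp2", "C", 0.2, other_allele="T"),
    SnpWeight("snp3", "G", 0.3, other_allele="A"),
]


def _geno(d1, d2, d3):
    def pair(w, d):
        return tuple([w.effect_allele] * d + [w.other_allele] * (2 - d))

    return {"snp1": pair(W3[0], d1), "snp2": pair(W3[1], d2), "snp3": pair(W3[2], d3)}


class TestGeneScore:
    def test_hand_sum(self):
        # 0.1*2 + 0.2*1 + 0.3*0 + apoe(e3e4)=0.1 -> 0.5
        r = gene_score(_geno(2, 1, 0), W3, ("e3", "e4"))
        assert r.total == pytest.approx(0.5)
        assert r.complete and r.snp_component == pytest.approx(0.4)

    def test_zero_dosage_apoe_only(self):
        assert gene_score(_geno(0, 0, 0), W3, ("e3", "e3")).total == pytest.approx(0.0)
        assert gene_score(_geno(0, 0, 0), W3, ("e2", "e2")).total == pytest.approx(-0.9)

    def test_missing_snp_means_unscored(self):
        g = _geno(2, 1, 0)
        del g["snp2"]
        r = gene_score(g, W3, ("e3", "e3"))
        assert not r.complete and r.classification == "unscored"
        assert np.isnan(r.total)

    def test_missing_apoe_means_unscored(self):
        assert gene_score(_geno(1, 1, 1), W3, None).classification == "unscored"

    def test_foreign_allele_fatal_names_snp(self):
        g = _geno(1, 1, 1)
        g["snp2"] = ("C", "G")  # G is neither effect C nor other T
        with pytest.raises(ValueError, match="snp2"):
            gene_score(g, W3, ("e3", "e3"))

    @given(st.lists(st.integers(min_value=0, max_value=2), min_size=3, max_size=3))
    def test_snp_order_irrelevant(self, dosages):
        g = _geno(*dosages)
        r1 = gene_score(g, W3, ("e3", "e4"))
        r2 = gene_score(g, list(reversed(W3)), ("e3", "e4"))
        assert r1.total == pytest.approx(r2.total)

    @given(
        st.lists(st.integers(min_value=0, max_value=2), min_size=3, max_size=3),
        st.sampled_from(sorted(APOE_SCORES)),
    )
    def test_additivity(self, dosages, apoe):
        """Total = per-SNP contributions + APOE table value."""
        r = gene_score(_geno(*dosages), W3, apoe)
        expected = sum(w.weight * d for w, d in zip(W3, dosages)) + APOE_SCORES[apoe]
        assert r.total == pytest.approx(expected)


class TestClassification:
    @pytest.mark.parametrize(
        "total,cutoff,expected",
        [
            (1.17, 1.16, "polygenic"),
            (1.16, 1.16, "not_polygenic"),  # strictly above only
            (0.90, 1.16, "not_polygenic"),
            (1.10, 1.08, "polygenic"),  # 9th-decile alternative cutoff
        ],
    )
    def test_cutoff_strictness(self, total, cutoff, expected):
        r = GeneScoreResult("S", total, 0.0, total, True, "not_polygenic")
        assert classify_polygenic(r, cutoff) == expected

    def test_incomplete_never_classified(self):
        r = GeneScoreResult("S", float("nan"), float("nan"), float("nan"), False, "unscored")
        assert classify_polygenic(r, 0.0) == "unscored"

    @given(
        total=st.floats(min_value=-1, max_value=3, allow_nan=False),
        cutoffs=st.tuples(st.floats(0, 2), st.floats(0, 2)),
    )
    def test_monotone_in_cutoff(self, total, cutoffs):
        """Raising the cutoff never turns a non-polygenic sample polygenic."""
        lo, hi = sorted(cutoffs)
        r = GeneScoreResult("S", total, 0.0, total, True, "not_polygenic")
        if classify_polygenic(r, hi) == "polygenic":
            assert classify_polygenic(r, lo) == "polygenic"


class TestCompareGroups:
    def test_identical_groups_uninformative(self):
        rng = np.random.default_rng(0)
        x = list(rng.normal(1.0, 0.2, 100))
        cmp = compare_groups({"a": x, "b": list(x)})
        assert cmp.welch_p[("a", "b")] == pytest.approx(1.0)

    def test_shifted_groups_detected(self):
        """Means 1.08 vs 0.90 at sd 0.23 with n=83/3020 are clearly separated
        by the Welch test."""
        rng = np.random.default_rng(42)
        neg = rng.normal(1.08, 0.23, 83)
        ctrl = rng.normal(0.90, 0.23, 3020)
        cmp = compare_groups({"mutation_negative": neg, "control": ctrl})
        assert cmp.welch_p[("control", "mutation_negative")] < 0.01

    def test_three_groups_anova(self):
        rng = np.random.default_rng(1)
        groups = {
            "control": rng.normal(0.90, 0.23, 500),
            "mutation_negative": rng.normal(1.08, 0.23, 83),
            "mutation_positive": rng.normal(0.96, 0.23, 21),
        }
        cmp = compare_groups(groups)
        assert cmp.anova_p is not None and cmp.anova_p < 0.01

    def test_null_anova_not_significant_on_average(self):
        """Calibration at small scale: equal-mean groups rarely reach p<0.05."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(40):
            groups = {g: rng.normal(1.0, 0.2, 50) for g in ("a", "b", "c")}
            if compare_groups(groups).anova_p < 0.05:
                hits += 1
        assert hits <= 6  # ~2 expected at the 5% level

    def test_tiny_group_not_computable(self):
        cmp = compare_groups({"a": [1.0], "b": [0.5, 0.6, 0.7]})
        assert cmp.welch_p[("a", "b")] is None
        assert cmp.anova_p is None


class TestIO:
    def test_weights_and_genotypes_round_trip(self, tmp_path):
        wpath = tmp_path / "w.tsv"
        wpath.write_text(
            "snp_id\tchrom\tpos\teffect_allele\tother_allele\tweight\n"
            "snp1\t1\t100\tA\tG\t0.1\n"
            "snp2\t2\t200\tC\tT\t0.2\n"
        )
        gpath = tmp_path / "g.tsv"
        gpath.write_text(
            "sample_id\tsnp_id\tallele1\tallele2\n"
            "S1\tsnp1\tA\tA\n"
            "S1\tsnp2\tC\tT\n"
        )
        weights = load_weights(wpath)
        assert [w.snp_id for w in weights] == ["snp1", "snp2"]
        genotypes = load_genotypes(gpath)
        assert genotypes["S1"]["snp1"] == ("A", "A")
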