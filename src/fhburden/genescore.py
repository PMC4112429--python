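"""Weighted LDL-C polygenic SNP score with the APOE haplotype component.

The score for a sample is

    score = sum_i w_i * d_i  +  apoe(h1, h2)

where ``d_i`` in {0,1,2} is the dosage of the LDL-raising effect allele at
SNP *i*, ``w_i`` its published per-allele weight (in mmol/L of LDL-C), and
``apoe`` a fixed lookup on the epsilon-haplotype diplotype:

    e2e2 = -0.9   e2e3 = -0.4   e2e4 = -0.2
    e3e3 =  0.0   e3e4 =  0.1   e4e4 =  0.2

A sample missing any of the 12 score SNPs or the APOE genotype is left
unscored rather than imputed.  A complete score above the healthy-population
top-decile cutoff (default 1.16) classifies the sample as polygenic
hypercholesterolaemia; the comparison is strict, so a score exactly at the
cutoff does not qualify.

The shipped 12-SNP weight table (see :mod:`fhburden.synthetic_data`) is a
synthetic placeholder: real analyses must supply the published GWAS
consortium weights via the weights TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "APOE_SCORES",
    "DEFAULT_CUTOFF",
    "NINTH_DECILE_CUTOFF",
    "SnpWeight",
    "GeneScoreResult",
    "GroupComparison",
    "apoe_score",
    "apoe_from_snps",
    "gene_score",
    "classify_polygenic",
    "score_cohort",
    "compare_groups",
    "load_weights",
    "load_genotypes",
]

#: APOE diplotype component, unordered pair lookup
APOE_SCORES: dict[tuple[str, str], float] = {
    ("e2", "e2"): -0.9,
    ("e2", "e3"): -0.4,
    ("e2", "e4"): -0.2,
    ("e3", "e3"): 0.0,
    ("e3", "e4"): 0.1,
    ("e4", "e4"): 0.2,
}

#: top-decile cutoff of the healthy reference population
DEFAULT_CUTOFF = 1.16
#: 9th-decile alternative cutoff discussed for a more permissive triage
NINTH_DECILE_CUTOFF = 1.08

_EPSILON = {"ε2": "e2", "ε3": "e3", "ε4": "e4", "e2": "e2", "e3": "e3", "e4": "e4"}


def _canon_apoe(genotype: tuple[str, str]) -> tuple[str, str]:
    canon = []
    for h in genotype:
        mapped = _EPSILON.get(h) or _EPSILON.get(str(h).lower())
        if mapped is None:
            raise ValueError(f"invalid APOE haplotype {h!r} in {genotype!r}")
        canon.append(mapped)
    return tuple(sorted(canon))  # type: ignore[return-value]


@dataclass(frozen=True)
class SnpWeight:
    """Per-allele effect weight for one score SNP."""

    snp_id: str
    effect_allele: str
    weight: float
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in "ACGT":
            raise ValueError(f"effect allele must be A/C/G/T, got {self.effect_allele!r}")
        if not np.isfinite(self.weight):
            raise ValueError(f"weight for {self.snp_id} is not finite")


@dataclass
class GeneScoreResult:
    sample_id: str
    snp_component: float
    apoe_component: float
    total: float
    complete: bool
    classification: str  # "polygenic" | "not_polygenic" | "unscored"


def apoe_score(genotype: tuple[str, str]) -> float:
    """Score an APOE diplotype by table lookup; the pair is unordered."""
    return APOE_SCORES[_canon_apoe(genotype)]


def apoe_from_snps(
    rs429358: tuple[str, str] | None, rs7412: tuple[str, str] | None
) -> tuple[str, str] | None:
    """Derive the epsilon diplotype from the two APOE coding SNPs.

    Per haplotype: rs429358=T & rs7412=T -> e2, T & C -> e3, C & C -> e4.
    With unphased genotypes the diplotype follows from the two allele
    counts; the one ambiguous case — both SNPs heterozygous — is resolved
    as e2/e4, the phase consistent with the absence of the essentially
    unobserved e1 haplotype (rs429358=C & rs7412=T).

    Returns ``None`` when either genotype is missing (sample unscored);
    raises ``ValueError`` for allele counts only an e1 haplotype could
    produce.
    """
    if rs429358 is None or rs7412 is None:
        return None
    for snp, gt, valid in (("rs429358", rs429358, "CT"), ("rs7412", rs7412, "CT")):
        for allele in gt:
            if allele not in valid:
                raise ValueError(f"invalid allele {allele!r} for {snp}")
    n_c = sum(1 for a in rs429358 if a == "C")  # C at rs429358 pushes toward e4
    n_t = sum(1 for a in rs7412 if a == "T")  # T at rs7412 pushes toward e2
    if n_c == 1 and n_t == 1:
        return ("e2", "e4")
    n_e3 = 2 - n_c - n_t
    if n_e3 < 0:
        raise ValueError(
            f"allele counts rs429358 C={n_c}, rs7412 T={n_t} imply an e1 haplotype"
        )
    haplos = ["e4"] * n_c + ["e2"] * n_t + ["e3"] * n_e3
    return tuple(sorted(haplos))  # type: ignore[return-value]


def _dosage(snp: SnpWeight, genotype: tuple[str, str]) -> int:
    d = 0
    for allele in genotype:
        if allele == snp.effect_allele:
            d += 1
        elif snp.other_allele is not None and allele != snp.other_allele:
            raise ValueError(
                f"allele {allele!r} at {snp.snp_id} matches neither effect "
                f"({snp.effect_allele}) nor other ({snp.other_allele}) allele"
            )
    return d


def gene_score(
    genotypes: Mapping[str, tuple[str, str]],
    weights: Sequence[SnpWeight],
    apoe: tuple[str, str] | None,
    sample_id: str = "",
    cutoff: float = DEFAULT_CUTOFF,
) -> GeneScoreResult:
    """Compute the weighted SNP score plus APOE component for one sample.

    ``genotypes`` maps snp_id to an allele pair; any score SNP absent from
    the mapping, or a missing APOE diplotype, makes the sample unscored.
    """
    missing = [w.snp_id for w in weights if w.snp_id not in genotypes]
    if missing or apoe is None:
        return GeneScoreResult(
            sample_id=sample_id,
            snp_component=float("nan"),
            apoe_component=float("nan"),
            total=float("nan"),
            complete=False,
            classification="unscored",
        )
    snp_component = float(sum(w.weight * _dosage(w, genotypes[w.snp_id]) for w in weights))
    apoe_component = apoe_score(apoe)
    total = snp_component + apoe_component
    result = GeneScoreResult(
        sample_id=sample_id,
        snp_component=snp_component,
        apoe_component=apoe_component,
        total=total,
        complete=True,
        classification="not_polygenic",
    )
    result.classification = classify_polygenic(result, cutoff)
    return result


def classify_polygenic(result: GeneScoreResult, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Classify a scored sample; strictly above the cutoff is polygenic."""
    if not result.complete:
        return "unscored"
    return "polygenic" if result.total > cutoff else "not_polygenic"


def score_cohort(
    genotypes_by_sample: Mapping[str, Mapping[str, tuple[str, str]]],
    weights: Sequence[SnpWeight],
    cutoff: float = DEFAULT_CUTOFF,
    rs429358: str = "rs429358",
    rs7412: str = "rs7412",
) -> dict[str, GeneScoreResult]:
    """Score every sample, deriving APOE from its two coding SNPs."""
    results: dict[str, GeneScoreResult] = {}
    for sample_id in sorted(genotypes_by_sample):
        genotypes = genotypes_by_sample[sample_id]
        apoe = apoe_from_snps(genotypes.get(rs429358), genotypes.get(rs7412))
        results[sample_id] = gene_score(genotypes, weights, apoe, sample_id=sample_id, cutoff=cutoff)
    return results


@dataclass
class GroupComparison:
    """Welch pairwise t tests and one-way ANOVA over score groups."""

    welch_p: dict[tuple[str, str], float | None]
    anova_p: float | None
    group_n: dict[str, int]
    group_mean: dict[str, float]


def compare_groups(scores_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare complete scores between groups (e.g. population controls,
    mutation-positive and mutation-negative cases).

    Pairwise comparisons use the Welch unequal-variance two-sample t test;
    the overall comparison is a one-way ANOVA.  A group with fewer than two
    scores makes its comparisons not computable (``None``).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in scores_by_group.items()}
    groups = {g: v[~np.isnan(v)] for g, v in groups.items()}
    names = sorted(groups)
    welch: dict[tuple[str, str], float | None] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                welch[(a, b)] = None
            else:
                welch[(a, b)] = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
    eligible = [groups[g] for g in names if len(groups[g]) >= 2]
    anova_p = float(stats.f_oneway(*eligible).pvalue) if len(eligible) >= 2 else None
    return GroupComparison(
        welch_p=welch,
        anova_p=anova_p,
        group_n={g: int(len(v)) for g, v in groups.items()},
        group_mean={g: float(np.mean(v)) if len(v) else float("nan") for g, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# file interfaces


def load_weights(path: str | Path) -> list[SnpWeight]:
    """Weights TSV: snp_id, chrom, pos, effect_allele, other_allele, weight."""
    table = pd.read_csv(path, sep="\t")
    weights = [
        SnpWeight(
            snp_id=str(r.snp_id),
            effect_allele=str(r.effect_allele),
            other_allele=None if pd.isna(r.other_allele) else str(r.other_allele),
            weight=float(r.weight),
        )
        for r in table.itertuples(index=False)
    ]
    return weights


def load_genotypes(path: str | Path) -> dict[str, dict[str, tuple[str, str]]]:
    """Genotypes TSV (long): sample_id, snp_id, allele1, allele2."""
    table = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for r in table.itertuples(index=False):
        if pd.isna(r.allele1) or pd.isna(r.allele2):
            continue
        out.setdefault(str(r.sample_id), {})[str(r.snp_id)] = (str(r.allele1), str(r.allele2))
    return out
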