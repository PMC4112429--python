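"""Gene-by-gene case/control burden test.

For a gene with ``k_case`` qualifying carrier events in cases and
``k_control`` in controls, the pooled ``n = k_case + k_control`` events are
treated as Bernoulli trials landing in a case with probability
``pi = n_case / (n_case + n_control)`` under the null of no enrichment, and
the evidence for excess in cases is the one-sided upper tail

    p = P(X >= k_case),   X ~ Binomial(n, pi).

Gene-level filters applied before testing in whole-exome mode: genes with
more than ``max_control_variants`` qualifying control events are dropped
(a true dominant FH gene cannot be common in population controls given a
disease prevalence around 1/500), as are genes on the X chromosome.  A p
value strictly below the flag threshold (default 4e-3) marks a gene for
follow-up; no multiple-testing correction is applied, the threshold being a
triage device rather than a claim of exome-wide significance (a Bonferroni
column is emitted for information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .filtering import GeneCounts
from .variant_model import Variant, normalize_chrom

__all__ = [
    "MAX_CONTROL_VARIANTS",
    "P_FLAG_THRESHOLD",
    "DEFAULT_EXCLUDED_CHROMS",
    "GeneBurdenResult",
    "binomial_burden_p",
    "run_burden_scan",
    "run_gene_list_burden",
    "expected_carriers",
    "maf_from_count",
    "round_sig",
]

MAX_CONTROL_VARIANTS = 4
P_FLAG_THRESHOLD = 4e-3
#: sex chromosomes and mitochondrion are excluded by default: the burden
#: comparison assumes equal diploid opportunity in both cohort arms
DEFAULT_EXCLUDED_CHROMS = frozenset({"X", "Y", "MT"})


def binomial_burden_p(k_case: int, k_control: int, n_case: int, n_control: int) -> float:
    """One-sided upper-tail exact binomial p for case excess.

    ``k_case = 0`` (or no events at all) returns 1.0: there is no case
    signal to assess.
    """
    if k_case < 0 or k_control < 0:
        raise ValueError("carrier counts must be non-negative")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("cohort sizes must be positive")
    n = k_case + k_control
    if n == 0 or k_case == 0:
        return 1.0
    pi = n_case / (n_case + n_control)
    return float(stats.binom.sf(k_case - 1, n, pi))


@dataclass
class GeneBurdenResult:
    """Burden-test outcome for one gene."""

    gene: str
    chrom: str
    k_case: int
    k_control: int
    p_value: float | None
    status: str  # tested | excluded_control_count | excluded_x_chromosome | excluded_no_variants
    flagged: bool
    p_bonferroni: float | None = None
    case_variants: list[Variant] = field(default_factory=list)
    control_variants: list[Variant] = field(default_factory=list)


def _sort_results(results: list[GeneBurdenResult]) -> list[GeneBurdenResult]:
    return sorted(results, key=lambda r: (r.p_value if r.p_value is not None else 2.0, r.gene))


def run_burden_scan(
    gene_counts: Mapping[str, GeneCounts],
    n_case: int,
    n_control: int,
    max_control_variants: int = MAX_CONTROL_VARIANTS,
    p_flag_threshold: float = P_FLAG_THRESHOLD,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> list[GeneBurdenResult]:
    """Whole-exome scan: filter genes, test the remainder, flag and sort.

    Filter boundaries are strict in the directions stated by the design:
    exactly ``max_control_variants`` control events is still tested
    ("more than four" excludes), and a p value exactly at the threshold is
    not flagged ("lower than" flags).
    """
    excluded = {normalize_chrom(c) for c in exclude_chroms}
    n_tested = sum(
        1
        for gc in gene_counts.values()
        if normalize_chrom(gc.chrom) not in excluded
        and gc.control_events <= max_control_variants
        and gc.case_events > 0
    )
    results: list[GeneBurdenResult] = []
    for gene in sorted(gene_counts):
        gc = gene_counts[gene]
        common = dict(
            gene=gc.gene,
            chrom=gc.chrom,
            k_case=gc.case_events,
            k_control=gc.control_events,
            case_variants=list(gc.case_variants),
            control_variants=list(gc.control_variants),
        )
        if gc.control_events > max_control_variants:
            results.append(GeneBurdenResult(p_value=None, status="excluded_control_count", flagged=False, **common))
        elif normalize_chrom(gc.chrom) in excluded:
            results.append(GeneBurdenResult(p_value=None, status="excluded_x_chromosome", flagged=False, **common))
        elif gc.case_events == 0:
            results.append(GeneBurdenResult(p_value=None, status="excluded_no_variants", flagged=False, **common))
        else:
            p = binomial_burden_p(gc.case_events, gc.control_events, n_case, n_control)
            results.append(
                GeneBurdenResult(
                    p_value=p,
                    status="tested",
                    flagged=p < p_flag_threshold,
                    p_bonferroni=min(1.0, p * n_tested) if n_tested else None,
                    **common,
                )
            )
    return _sort_results(results)


def run_gene_list_burden(
    gene_counts: Mapping[str, GeneCounts],
    gene_list: Sequence[str],
    n_case: int,
    n_control: int,
    p_flag_threshold: float = P_FLAG_THRESHOLD,
) -> tuple[GeneBurdenResult, list[GeneBurdenResult]]:
    """Candidate-gene-list mode: pooled test plus per-gene tests.

    The combined result pools carrier events across all listed genes into a
    single binomial test.  Per-gene results apply no control-count or
    chromosome filter — the list is the hypothesis, every member is tested
    (a listed gene with no case events is still reported, with p = 1).
    """
    if not gene_list:
        raise ValueError("gene list must be non-empty")
    per_gene: list[GeneBurdenResult] = []
    k_case_total = 0
    k_control_total = 0
    for gene in sorted(set(gene_list)):
        gc = gene_counts.get(gene, GeneCounts(gene=gene, chrom="?"))
        k_case_total += gc.case_events
        k_control_total += gc.control_events
        p = binomial_burden_p(gc.case_events, gc.control_events, n_case, n_control)
        per_gene.append(
            GeneBurdenResult(
                gene=gene,
                chrom=gc.chrom,
                k_case=gc.case_events,
                k_control=gc.control_events,
                p_value=p,
                status="tested",
                flagged=p < p_flag_threshold,
                case_variants=list(gc.case_variants),
                control_variants=list(gc.control_variants),
            )
        )
    p_comb = binomial_burden_p(k_case_total, k_control_total, n_case, n_control)
    combined = GeneBurdenResult(
        gene="COMBINED",
        chrom="*",
        k_case=k_case_total,
        k_control=k_control_total,
        p_value=p_comb,
        status="tested",
        flagged=p_comb < p_flag_threshold,
    )
    return combined, _sort_results(per_gene)


def expected_carriers(n_controls: int, prevalence: float) -> float:
    """Expected number of true-disease carriers lurking in the control arm.

    With FH prevalence around 1/500, a 1926-sample control panel is expected
    to hide about four undiagnosed carriers — the rationale for tolerating a
    few qualifying control events per gene rather than requiring zero.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0,1), got {prevalence}")
    if n_controls < 0:
        raise ValueError("n_controls must be non-negative")
    return n_controls * prevalence


def maf_from_count(allele_count: int, n_individuals: int) -> float:
    """Minor allele frequency from an allele count over diploid individuals."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if not (0 <= allele_count <= 2 * n_individuals):
        raise ValueError("allele_count must be between 0 and 2 * n_individuals")
    return allele_count / (2 * n_individuals)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (display convention for p values)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)
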