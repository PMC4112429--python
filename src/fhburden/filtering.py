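"""Rare / novel / functional variant flags and per-gene carrier counts.

The discovery pipeline works on *novel functional* variants: absent from
every reference panel and in a consequence class that plausibly alters the
protein.  A *rare* variant instead only needs a panel frequency below 0.5%.
Frequency is aggregated over panels by taking the maximum — a variant that
is common in any panel is not rare — and a panel in which the variant is
unobserved contributes zero.

Counts are carrier events: one sample carrying one qualifying variant in
one gene counts once, so a variant seen in two cases contributes two case
events to its gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .variant_model import CohortDataset, Consequence, Variant

__all__ = [
    "RARE_THRESHOLD",
    "FUNCTIONAL_CLASSES",
    "VariantFlags",
    "GeneCounts",
    "flag_frequency",
    "flag_functional",
    "variant_flags",
    "novel_functional",
    "rare_functional",
    "collect_gene_counts",
]

#: default frequency threshold below which a variant counts as rare
RARE_THRESHOLD = 0.005

#: consequence classes with a plausible effect on the protein product
FUNCTIONAL_CLASSES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.STOP_GAIN,
        Consequence.STOP_LOSS,
        Consequence.FRAMESHIFT_INS,
        Consequence.FRAMESHIFT_DEL,
        Consequence.SPLICE_SITE,
    }
)


@dataclass(frozen=True)
class VariantFlags:
    is_rare: bool
    is_novel: bool
    is_functional: bool


def flag_frequency(variant: Variant, rare_threshold: float = RARE_THRESHOLD) -> tuple[bool, bool]:
    """Return ``(is_rare, is_novel)`` from the variant's panel frequencies.

    The frequency used is the maximum over all panels in which the variant
    was observed; ``is_rare`` is a strict comparison against the threshold
    and ``is_novel`` requires frequency zero everywhere.
    """
    if not (0.0 < rare_threshold < 1.0):
        raise ValueError(f"rare_threshold must be in (0,1), got {rare_threshold}")
    freq = max(variant.ref_freqs.values(), default=0.0)
    is_rare = freq < rare_threshold
    is_novel = freq == 0.0
    return is_rare, is_novel


def flag_functional(consequence: Consequence) -> bool:
    """True iff the consequence class plausibly affects the protein."""
    return Consequence(consequence) in FUNCTIONAL_CLASSES


def variant_flags(variant: Variant, rare_threshold: float = RARE_THRESHOLD) -> VariantFlags:
    is_rare, is_novel = flag_frequency(variant, rare_threshold)
    return VariantFlags(
        is_rare=is_rare,
        is_novel=is_novel,
        is_functional=flag_functional(variant.consequence),
    )


def novel_functional(variant: Variant, rare_threshold: float = RARE_THRESHOLD) -> bool:
    """Predicate for the whole-exome scan: novel AND functional."""
    flags = variant_flags(variant, rare_threshold)
    return flags.is_novel and flags.is_functional


def rare_functional(variant: Variant, rare_threshold: float = RARE_THRESHOLD) -> bool:
    """Predicate for candidate-gene-list mode: rare AND functional."""
    flags = variant_flags(variant, rare_threshold)
    return flags.is_rare and flags.is_functional


@dataclass
class GeneCounts:
    """Qualifying carrier events in one gene, split by cohort arm."""

    gene: str
    chrom: str
    case_events: int = 0
    control_events: int = 0
    case_variants: list[Variant] = field(default_factory=list)
    control_variants: list[Variant] = field(default_factory=list)


def collect_gene_counts(
    dataset: CohortDataset,
    predicate: Callable[[Variant], bool] = novel_functional,
) -> dict[str, GeneCounts]:
    """Count predicate-passing carrier events gene by gene.

    The variant lists retain one entry per carrier event (a variant carried
    by two samples appears twice), mirroring how the per-gene evidence is
    reported.  Genes with no qualifying call are absent from the result.
    """
    counts: dict[str, GeneCounts] = {}
    for call in dataset.calls:
        v = call.variant
        if not v.gene or not predicate(v):
            continue
        gc = counts.get(v.gene)
        if gc is None:
            gc = counts[v.gene] = GeneCounts(gene=v.gene, chrom=v.chrom)
        if dataset.is_case(call.sample_id):
            gc.case_events += 1
            gc.case_variants.append(v)
        else:
            gc.control_events += 1
            gc.control_variants.append(v)
    return counts
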