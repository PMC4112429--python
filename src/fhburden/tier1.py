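"""Screening against a catalogue of known FH mutations.

Tier 1 genes are the established FH loci: *LDLR*, *APOB* and *PCSK9*
(dominant) and *LDLRAP1* (recessive).  A case sample carrying a catalogued
pathogenic mutation in a dominant gene is considered explained and is
removed before the discovery burden scan.  For the recessive gene a single
heterozygous hit is reported but does not explain the phenotype; that needs
a homozygous call or two distinct heterozygous catalogue hits in the gene.

Matching is by normalized coordinate key, with exact HGVS-c string equality
as a fallback for catalogue rows that carry no coordinates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .variant_model import CohortDataset, VariantKey, normalize_variant

__all__ = [
    "TIER1_GENES",
    "RECESSIVE_GENES",
    "KnownMutation",
    "Tier1Match",
    "SampleTriage",
    "load_catalogue",
    "screen_tier1",
    "explained_samples",
]

TIER1_GENES = frozenset({"LDLR", "APOB", "PCSK9", "LDLRAP1"})
RECESSIVE_GENES = frozenset({"LDLRAP1"})

PATHOGENICITY_CLASSES = ("known_fh", "unknown_effect")


@dataclass(frozen=True)
class KnownMutation:
    """One catalogue entry.  ``unknown_effect`` rows (e.g. novel APOB
    variants whose pathogenicity is untested) are reported on match but
    never explain a sample."""

    gene: str
    key: VariantKey | None
    hgvs_c: str | None = None
    pathogenicity: str = "known_fh"

    def __post_init__(self) -> None:
        if self.pathogenicity not in PATHOGENICITY_CLASSES:
            raise ValueError(f"pathogenicity must be one of {PATHOGENICITY_CLASSES}")
        if self.key is None and not self.hgvs_c:
            raise ValueError("catalogue entry needs coordinates or an HGVS-c string")


@dataclass(frozen=True)
class Tier1Match:
    sample_id: str
    mutation: KnownMutation
    zygosity: str
    matched_by: str  # "key" | "hgvs"


@dataclass
class SampleTriage:
    """Final disposition of one case sample before the burden scan."""

    sample_id: str
    status: str  # "tier1_mutation" | "polygenic" | "unexplained"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("tier1_mutation", "polygenic", "unexplained"):
            raise ValueError(f"invalid triage status {self.status!r}")


def load_catalogue(
    path: str | Path, tier1_genes: frozenset[str] = TIER1_GENES
) -> list[KnownMutation]:
    """Load the known-mutation catalogue TSV.

    Columns: gene, chrom, pos, ref, alt, hgvs_c, pathogenicity.  Coordinate
    columns may be empty when only an HGVS string is curated.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    entries: list[KnownMutation] = []
    for row in table.itertuples(index=False):
        gene = str(row.gene)
        if gene not in tier1_genes:
            raise ValueError(
                f"catalogue entry in non-Tier-1 gene {gene!r}; allowed: {sorted(tier1_genes)}"
            )
        key = None
        if pd.notna(row.chrom) and pd.notna(row.pos):
            key = normalize_variant(row.chrom, int(row.pos), str(row.ref), str(row.alt))
        hgvs = None if pd.isna(row.hgvs_c) else str(row.hgvs_c)
        patho = str(row.pathogenicity) if pd.notna(row.pathogenicity) else "known_fh"
        entries.append(KnownMutation(gene=gene, key=key, hgvs_c=hgvs, pathogenicity=patho))
    return entries


def screen_tier1(
    dataset: CohortDataset,
    catalogue: list[KnownMutation],
    tier1_genes: frozenset[str] = TIER1_GENES,
    recessive_genes: frozenset[str] = RECESSIVE_GENES,
) -> dict[str, list[Tier1Match]]:
    """Match every case sample's calls against the catalogue.

    Returns all matches per sample (including reported-only recessive
    heterozygotes and ``unknown_effect`` hits); whether a sample counts as
    explained is decided by :func:`explained_samples`.
    """
    for entry in catalogue:
        if entry.gene not in tier1_genes:
            raise ValueError(f"catalogue entry in non-Tier-1 gene {entry.gene!r}")
    by_key = {e.key: e for e in catalogue if e.key is not None}
    by_hgvs = {e.hgvs_c: e for e in catalogue if e.hgvs_c}
    matches: dict[str, list[Tier1Match]] = defaultdict(list)
    for call in dataset.calls:
        if not dataset.is_case(call.sample_id):
            continue
        entry = by_key.get(call.variant.key)
        matched_by = "key"
        if entry is None and call.variant.hgvs_c:
            entry = by_hgvs.get(call.variant.hgvs_c)
            matched_by = "hgvs"
        if entry is not None:
            matches[call.sample_id].append(
                Tier1Match(
                    sample_id=call.sample_id,
                    mutation=entry,
                    zygosity=call.zygosity,
                    matched_by=matched_by,
                )
            )
    return dict(matches)


def explained_samples(
    matches: dict[str, list[Tier1Match]],
    recessive_genes: frozenset[str] = RECESSIVE_GENES,
) -> set[str]:
    """Samples whose phenotype the Tier-1 screen explains.

    Dominant genes: any ``known_fh`` match suffices.  Recessive genes: a
    homozygous ``known_fh`` match, or two distinct heterozygous ``known_fh``
    matches in the same gene (compound-heterozygote model).
    """
    explained: set[str] = set()
    for sample, hits in matches.items():
        per_recessive_gene: dict[str, set[VariantKey | str]] = defaultdict(set)
        for hit in hits:
            if hit.mutation.pathogenicity != "known_fh":
                continue
            if hit.mutation.gene not in recessive_genes:
                explained.add(sample)
            elif hit.zygosity == "hom":
                explained.add(sample)
            else:
                ident = hit.mutation.key if hit.mutation.key is not None else hit.mutation.hgvs_c
                per_recessive_gene[hit.mutation.gene].add(ident)
        for gene, idents in per_recessive_gene.items():
            if len(idents) >= 2:
                explained.add(sample)
    return explained
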