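"""Shared fixtures: tiny hand-built cohorts and the study-scale fixture
(125 cases, 25 mutation carriers, 31 high-score samples of which 2 overlap)
used by the pipeline and acceptance tests."""

from __future__ import annotations

import pytest
from hypothesis import settings

from fhburden.genescore import SnpWeight
from fhburden.synthetic_data import default_catalogue, default_score_model, _spike_variant
from fhburden.variant_model import CohortDataset, Consequence, SampleCall, Variant

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_variant(
    gene: str = "GENE1",
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    consequence: Consequence = Consequence.MISSENSE,
    freqs: dict | None = None,
    hgvs_c: str | None = None,
) -> Variant:
    return Variant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        hgvs_c=hgvs_c,
        consequence=consequence,
        ref_freqs={} if freqs is None else freqs,
    )


@pytest.fixture(scope="session")
def score_weights() -> list[SnpWeight]:
    return default_score_model().weights()


def _genotypes_for(weights: list[SnpWeight], high: bool) -> dict[str, tuple[str, str]]:
    """Deterministic score genotypes: all-effect hom + e4e4 (score ~1.5) or
    all-other hom + e3e3 (score 0)."""
    g = {}
    for w in weights:
        allele = w.effect_allele if high else (w.other_allele or "N")
        g[w.snp_id] = (allele, allele)
    if high:
        g["rs429358"] = ("C", "C")
        g["rs7412"] = ("C", "C")  # e4e4 -> +0.2
    else:
        g["rs429358"] = ("T", "T")
        g["rs7412"] = ("C", "C")  # e3e3 -> 0
    return g


@pytest.fixture(scope="session")
def study_fixture(score_weights):
    """The discovery-cascade fixture at published scale.

    125 cases / 1926 controls; cases[0:25] carry a catalogued dominant
    mutation; cases[23:54] (31 samples, 2 of them mutation carriers) have a
    gene score above the cutoff; cases[54:70] (16 samples) are unscorable.
    Among the 71 remaining cases, three carry a novel functional CH25H
    variant; two controls do as well.
    """
    catalogue = default_catalogue()
    dominant = [e for e in catalogue if e.pathogenicity == "known_fh" and e.gene != "LDLRAP1"]
    cases = [f"CASE{i + 1:04d}" for i in range(125)]
    controls = [f"CTRL{i + 1:04d}" for i in range(1926)]

    calls: list[SampleCall] = []
    for i, sample in enumerate(cases[:25]):
        variant = _spike_variant(dominant[i % len(dominant)])
        calls.append(SampleCall(sample_id=sample, variant=variant, zygosity="het"))

    remaining = cases[70:]  # disjoint from tier1 (0:25), high-score (23:54), unscored (54:70)
    ch25h = [
        make_variant("CH25H", "10", 90965000 + i, "C", "T",
                     Consequence.MISSENSE if i else Consequence.STOP_GAIN,
                     freqs={"kg1000": 0.0, "esp6500": 0.0})
        for i in range(3)
    ]
    for sample, variant in zip(remaining[:3], ch25h):
        calls.append(SampleCall(sample_id=sample, variant=variant, zygosity="het"))
    ch25h_ctrl = [
        make_variant("CH25H", "10", 90966000 + i, "G", "A", Consequence.MISSENSE,
                     freqs={"kg1000": 0.0, "esp6500": 0.0})
        for i in range(2)
    ]
    for sample, variant in zip(controls[:2], ch25h_ctrl):
        calls.append(SampleCall(sample_id=sample, variant=variant, zygosity="het"))

    dataset = CohortDataset(cases=frozenset(cases), controls=frozenset(controls), calls=calls)

    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    high_score = set(cases[23:54])
    unscored = set(cases[54:70])
    for sample in cases:
        g = _genotypes_for(score_weights, high=sample in high_score)
        if sample in unscored:
            g.pop(score_weights[0].snp_id)
        genotypes[sample] = g
    return dataset, catalogue, genotypes, score_weights
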