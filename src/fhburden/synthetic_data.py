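"""Synthetic FH exome cohorts with known planted truth.

The generator emulates the statistical structure the discovery pipeline
assumes, at the study's scale — 125 unrelated definite-FH cases against
1926 population controls:

* per gene and sample, an at-most-one qualifying novel-functional carrier
  event drawn Bernoulli from a per-gene background rate, with optional
  case-rate multipliers for enriched genes;
* known FH mutations from a catalogue spiked into a configured fraction of
  cases (default 20%, i.e. 25 of 125);
* 12 independent score SNPs drawn binomially from effect-allele
  frequencies, APOE haplotypes drawn from haplotype frequencies, with the
  weight/frequency table calibrated so the control score distribution has
  mean ~= 0.90 and 90th percentile ~= 1.16;
* a fraction of cases (default 12.8%, i.e. 16 of 125) left with incomplete
  score genotypes, hence unscorable;
* polygenic hypercholesterolaemia planted into score-attainable
  mutation-negative cases at a configured fraction of the scored cases
  (default 27%, i.e. 29 of 109): their score genotypes are drawn
  conditional on the total exceeding the top-decile cutoff, the remaining
  mutation-negative scored cases conditional on not exceeding it.  Spiked
  mutation carriers draw background scores, so carriers above the cutoff
  arise at the population rate (~10%), mirroring how monogenic and
  polygenic aetiologies coincide only by chance.

Everything is reproducible from the seed, and every planted signal is
recorded in a truth table so that recovery can be checked exactly.

No attempt is made at realistic site-frequency spectra, linkage
disequilibrium or sequencing error; see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .genescore import (
    DEFAULT_CUTOFF,
    APOE_SCORES,
    SnpWeight,
    apoe_from_snps,
    gene_score,
)
from .tier1 import KnownMutation
from .variant_model import (
    CohortDataset,
    Consequence,
    SampleCall,
    Variant,
    normalize_variant,
)

__all__ = [
    "ScoreSnp",
    "ScoreModel",
    "GeneSpec",
    "SimConfig",
    "SimResult",
    "RecoveryReport",
    "default_score_model",
    "default_catalogue",
    "default_gene_panel",
    "default_config",
    "simulate_gene_counts",
    "simulate_cohort",
    "recover_parameters",
    "write_simulated_inputs",
]

_Z90 = 1.2815515655446004  # standard-normal 90th percentile


# ---------------------------------------------------------------------------
# score model


@dataclass(frozen=True)
class ScoreSnp:
    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    freq: float  # effect-allele frequency
    weight: float


@dataclass
class ScoreModel:
    """Generative model for the polygenic score: independent score SNPs in
    Hardy-Weinberg proportions plus an APOE diplotype drawn from haplotype
    frequencies."""

    snps: list[ScoreSnp]
    apoe_freqs: dict[str, float]  # haplotype -> frequency, keys e2/e3/e4
    target_mean: float = 0.90
    target_p90: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        total = sum(self.apoe_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"APOE haplotype frequencies must sum to 1, got {total}")

    # -- analytic moments -------------------------------------------------

    def apoe_moments(self) -> tuple[float, float]:
        mean = var = 0.0
        haplos = sorted(self.apoe_freqs)
        for i, a in enumerate(haplos):
            for b in haplos[i:]:
                prob = self.apoe_freqs[a] * self.apoe_freqs[b]
                if a != b:
                    prob *= 2
                val = APOE_SCORES[tuple(sorted((a, b)))]
                mean += prob * val
                var += prob * val * val
        return mean, var - mean * mean

    def moments(self) -> tuple[float, float]:
        """Analytic (mean, variance) of the total score."""
        w = np.array([s.weight for s in self.snps])
        p = np.array([s.freq for s in self.snps])
        mu_a, var_a = self.apoe_moments()
        mean = float(np.sum(w * 2 * p)) + mu_a
        var = float(np.sum(w * w * 2 * p * (1 - p))) + var_a
        return mean, var

    def calibrated(self, mc_n: int = 200_000, mc_seed: int = 1902, max_iter: int = 8) -> "ScoreModel":
        """Rescale weights and shift allele frequencies so the score has
        the target mean and 90th percentile.

        The mean is matched analytically.  A normal approximation places the
        90th percentile first, then a Monte Carlo fixed-point refinement
        corrects for the skew the discrete APOE component introduces (the
        e2-carrying diplotypes put ~13% of mass well below the mean, which
        pulls the true upper decile boundary under mean + z90*sd).
        """
        base_w = np.array([s.weight for s in self.snps])
        base_logit = special.logit(np.array([s.freq for s in self.snps]))
        mu_a, var_a = self.apoe_moments()

        def solve_moments(p90_target: float) -> tuple[float, np.ndarray]:
            def residual(params: np.ndarray) -> np.ndarray:
                s, t = params
                p = special.expit(base_logit + t)
                mean = s * float(np.sum(base_w * 2 * p)) + mu_a
                var = s * s * float(np.sum(base_w**2 * 2 * p * (1 - p))) + var_a
                return np.array([mean - self.target_mean, mean + _Z90 * np.sqrt(var) - p90_target])

            (s, t), _, ok, msg = optimize.fsolve(residual, [1.0, 0.0], full_output=True)
            if ok != 1:
                raise RuntimeError(f"score-model calibration failed: {msg}")
            return float(s), special.expit(base_logit + t)

        internal_target = self.target_p90
        s, p = solve_moments(internal_target)
        for _ in range(max_iter):
            rng = np.random.default_rng(mc_seed)
            totals = _fast_sample_totals(s * base_w, p, self.apoe_freqs, rng, mc_n)
            gap = float(np.quantile(totals, 0.9)) - self.target_p90
            if abs(gap) < 1e-3:
                break
            internal_target -= gap
            s, p = solve_moments(internal_target)
        snps = [
            replace(snp, weight=float(s * w0), freq=float(pi))
            for snp, w0, pi in zip(self.snps, base_w, p)
        ]
        return ScoreModel(
            snps=snps,
            apoe_freqs=dict(self.apoe_freqs),
            target_mean=self.target_mean,
            target_p90=self.target_p90,
        )

    # -- sampling ----------------------------------------------------------

    def weights(self) -> list[SnpWeight]:
        """The model's SNP table as scoring weights."""
        return [
            SnpWeight(
                snp_id=s.snp_id,
                effect_allele=s.effect_allele,
                other_allele=s.other_allele,
                weight=s.weight,
            )
            for s in self.snps
        ]


def _model_weights(model: ScoreModel) -> list[SnpWeight]:
    return model.weights()


def _fast_sample_totals(
    weights: np.ndarray,
    freqs: np.ndarray,
    apoe_freqs: Mapping[str, float],
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Vectorised draws of the total score (calibration internals)."""
    dosages = rng.binomial(2, freqs, size=(n, len(freqs)))
    snp = dosages @ weights
    haplos = sorted(apoe_freqs)
    probs = np.array([apoe_freqs[h] for h in haplos])
    h1 = rng.choice(len(haplos), size=n, p=probs)
    h2 = rng.choice(len(haplos), size=n, p=probs)
    table = np.array(
        [[APOE_SCORES[tuple(sorted((a, b)))] for b in haplos] for a in haplos]
    )
    return snp + table[h1, h2]


_APOE_SNP_ALLELES = {
    # per-haplotype alleles at (rs429358, rs7412)
    "e2": ("T", "T"),
    "e3": ("T", "C"),
    "e4": ("C", "C"),
}


def _sample_score_genotypes(
    model: ScoreModel, rng: np.random.Generator
) -> dict[str, tuple[str, str]]:
    genotypes: dict[str, tuple[str, str]] = {}
    for snp in model.snps:
        dosage = rng.binomial(2, snp.freq)
        alleles = [snp.effect_allele] * dosage + [snp.other_allele] * (2 - dosage)
        genotypes[snp.snp_id] = (alleles[0], alleles[1])
    haplos = sorted(model.apoe_freqs)
    probs = [model.apoe_freqs[h] for h in haplos]
    h1, h2 = rng.choice(haplos, size=2, p=probs)
    a1 = _APOE_SNP_ALLELES[h1]
    a2 = _APOE_SNP_ALLELES[h2]
    genotypes["rs429358"] = (a1[0], a2[0])
    genotypes["rs7412"] = (a1[1], a2[1])
    return genotypes


def _sample_conditional(
    model: ScoreModel,
    rng: np.random.Generator,
    above: bool | None,
    cutoff: float,
    max_tries: int = 10_000,
) -> dict[str, tuple[str, str]]:
    """Draw score genotypes, optionally conditioned on the total score
    falling strictly above (or at/below) the cutoff."""
    weights = _model_weights(model)
    for _ in range(max_tries):
        genotypes = _sample_score_genotypes(model, rng)
        if above is None:
            return genotypes
        apoe = apoe_from_snps(genotypes["rs429358"], genotypes["rs7412"])
        total = gene_score(genotypes, weights, apoe).total
        if (total > cutoff) == above:
            return genotypes
    raise RuntimeError("conditional score sampling did not converge")


_MODEL_CACHE: dict[tuple[float, float], ScoreModel] = {}


def default_score_model(target_mean: float = 0.90, target_p90: float = DEFAULT_CUTOFF) -> ScoreModel:
    """Calibrated 12-SNP score model.

    The SNP identifiers and effect sizes are synthetic stand-ins shaped
    like the published LDL-C GWAS loci (one strong LDLR-like SNP, one
    SORT1-like, a tail of small effects); only the moments of the resulting
    score are calibrated, to the printed healthy-population summary
    statistics (mean 0.90, top-decile cutoff 1.16).
    """
    base = [
        # snp_id, chrom, pos, effect, other, freq, base weight
        ("rs_sim_pcsk9", "1", 55505647, "G", "A", 0.30, 0.052),
        ("rs_sim_sort1", "1", 109818306, "G", "T", 0.78, 0.150),
        ("rs_sim_apob", "2", 21263900, "A", "G", 0.30, 0.100),
        ("rs_sim_abcg8", "2", 44072576, "G", "T", 0.30, 0.071),
        ("rs_sim_hfe", "6", 26093141, "G", "A", 0.93, 0.057),
        ("rs_sim_slc22a1", "6", 160578860, "C", "T", 0.17, 0.014),
        ("rs_sim_ldlr", "19", 11202306, "G", "T", 0.89, 0.180),
        ("rs_sim_cetp", "16", 56993324, "C", "A", 0.32, 0.048),
        ("rs_sim_tm6sf2", "19", 19379549, "C", "T", 0.46, 0.076),
        ("rs_sim_mylip", "6", 16127245, "C", "T", 0.25, 0.042),
        ("rs_sim_st3gal4", "11", 126243952, "G", "A", 0.62, 0.083),
        ("rs_sim_nynrin", "14", 24883887, "C", "G", 0.40, 0.061),
    ]
    key = (target_mean, target_p90)
    if key not in _MODEL_CACHE:
        model = ScoreModel(
            snps=[ScoreSnp(*row) for row in base],
            apoe_freqs={"e2": 0.08, "e3": 0.77, "e4": 0.15},
            target_mean=target_mean,
            target_p90=target_p90,
        )
        _MODEL_CACHE[key] = model.calibrated()
    return _MODEL_CACHE[key]


# ---------------------------------------------------------------------------
# cohort model


@dataclass(frozen=True)
class GeneSpec:
    gene: str
    chrom: str
    rate: float  # per-sample probability of a qualifying carrier event

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"rate for {self.gene} outside [0,1]: {self.rate}")


@dataclass(frozen=True)
class SpikeSpec:
    """One catalogue mutation planted into the case arm."""

    mutation: KnownMutation
    n_carriers: int
    zygosity: str = "het"


@dataclass
class SimConfig:
    seed: int
    n_cases: int = 125
    n_controls: int = 1926
    genes: list[GeneSpec] = field(default_factory=list)
    enrichment: dict[str, float] = field(default_factory=dict)  # gene -> case multiplier
    tier1_spikes: list[SpikeSpec] = field(default_factory=list)
    score_model: ScoreModel | None = None
    polygenic_case_fraction: float = 0.27
    unscored_case_fraction: float = 16 / 125
    noise_rate: float = 2e-4  # per-gene rate of non-qualifying decoy calls

    def __post_init__(self) -> None:
        for gene, mult in self.enrichment.items():
            if mult < 0:
                raise ValueError(f"multiplier for {gene} must be >= 0")
        rates = {g.gene: g.rate for g in self.genes}
        for gene, mult in self.enrichment.items():
            if gene in rates and rates[gene] * mult > 1.0:
                raise ValueError(
                    f"case rate for {gene} exceeds 1 after multiplier {mult}"
                )


def default_gene_panel(n_genes: int = 500) -> list[GeneSpec]:
    """Background gene panel with heterogeneous carrier rates.

    Rates are log-spaced between 5e-5 and 2e-3 per sample per gene, the
    range over which expected control counts run from ~0.1 to ~4 in a
    1926-sample panel; chromosomes cycle through the autosomes with every
    23rd gene placed on X so that the chromosome filter is exercised.
    """
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    rates = np.geomspace(5e-5, 2e-3, n_genes)
    return [
        GeneSpec(gene=f"GENE{i + 1:04d}", chrom=chroms[i % len(chroms)], rate=float(r))
        for i, r in enumerate(rates)
    ]


#: padded VCF spellings of the synthetic catalogue entries, keyed by HGVS-c
_CATALOGUE_ROWS: tuple[tuple[str, str, int, str, str, str, str], ...] = (
    # gene, chrom, pos, ref, alt (padded VCF form), hgvs_c, pathogenicity
    ("LDLR", "19", 11216260, "G", "A", "c.1060G>A", "known_fh"),
    ("LDLR", "19", 11221327, "C", "T", "c.1444C>T", "known_fh"),
    ("LDLR", "19", 11224012, "CTG", "C", "c.1706_1707del", "known_fh"),
    ("APOB", "2", 21229160, "C", "T", "c.10580G>A", "known_fh"),
    ("PCSK9", "1", 55505647, "A", "T", "c.381A>T", "known_fh"),
    ("LDLRAP1", "1", 25870542, "C", "CA", "c.432_433insA", "known_fh"),
    ("APOB", "2", 21232045, "T", "C", "c.9110A>G", "unknown_effect"),
)


def default_catalogue() -> list[KnownMutation]:
    """Synthetic known-FH-mutation catalogue used for spiking.

    Entries are shaped like curated FH database rows (dominant LDLR / APOB /
    PCSK9 mutations, one recessive LDLRAP1 frameshift, one APOB variant of
    unknown effect); coordinates are synthetic.
    """
    return [
        KnownMutation(
            gene=gene,
            key=normalize_variant(chrom, pos, ref, alt),
            hgvs_c=hgvs,
            pathogenicity=patho,
        )
        for gene, chrom, pos, ref, alt, hgvs, patho in _CATALOGUE_ROWS
    ]


def default_config(seed: int, n_genes: int = 500) -> SimConfig:
    """Study-scale default: 125 cases / 1926 controls, 20% of cases spiked
    with a dominant Tier-1 mutation, one reported-only recessive
    heterozygote, 16 cases unscorable, and 27% of the scored cases (29 of
    109) planted polygenic among the mutation-negatives."""
    catalogue = default_catalogue()
    dominant = [e for e in catalogue if e.pathogenicity == "known_fh" and e.gene != "LDLRAP1"]
    spikes = []
    n_tier1 = round(0.20 * 125)  # 25 carriers split across dominant entries
    base, extra = divmod(n_tier1, len(dominant))
    for i, entry in enumerate(dominant):
        spikes.append(SpikeSpec(mutation=entry, n_carriers=base + (1 if i < extra else 0)))
    recessive = next(e for e in catalogue if e.gene == "LDLRAP1")
    spikes.append(SpikeSpec(mutation=recessive, n_carriers=1, zygosity="het"))
    return SimConfig(
        seed=seed,
        genes=default_gene_panel(n_genes),
        tier1_spikes=spikes,
        score_model=default_score_model(),
    )


# ---------------------------------------------------------------------------
# simulation


def simulate_gene_counts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fast path: per-gene qualifying carrier counts without materialising
    calls.  Used for burden-test calibration at many replicates."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rates = np.array([g.rate for g in config.genes])
    mult = np.array([config.enrichment.get(g.gene, 1.0) for g in config.genes])
    case_rates = rates * mult
    if np.any(case_rates > 1.0):
        raise ValueError("case carrier rate exceeds 1 after enrichment multiplier")
    k_case = rng.binomial(config.n_cases, case_rates)
    k_control = rng.binomial(config.n_controls, rates)
    return pd.DataFrame(
        {
            "gene": [g.gene for g in config.genes],
            "chrom": [g.chrom for g in config.genes],
            "k_case": k_case,
            "k_control": k_control,
        }
    )


_FUNCTIONAL_CYCLE = (
    Consequence.MISSENSE,
    Consequence.STOP_GAIN,
    Consequence.FRAMESHIFT_DEL,
    Consequence.SPLICE_SITE,
    Consequence.MISSENSE,
    Consequence.FRAMESHIFT_INS,
)

_BASES = "ACGT"


@dataclass
class SimResult:
    config: SimConfig
    dataset: CohortDataset
    annotation: dict  # VariantKey -> Variant for every emitted variant
    genotypes: dict[str, dict[str, tuple[str, str]]]
    catalogue: list[KnownMutation]
    truth: "TruthTable"


@dataclass
class TruthTable:
    spiked_tier1: dict[str, KnownMutation]  # sample -> planted mutation
    tier1_explained: set[str]  # spiked samples that should triage as explained
    planted_polygenic: set[str]
    unscored: set[str]
    enriched_genes: set[str]
    gene_rates: dict[str, float]


def _spike_variant(mutation: KnownMutation) -> Variant:
    """Materialise a catalogue mutation in its padded VCF spelling so the
    emitted VCF stays valid and the normalized key still matches."""
    for gene, chrom, pos, ref, alt, hgvs, _ in _CATALOGUE_ROWS:
        if gene == mutation.gene and hgvs == mutation.hgvs_c:
            consequence = Consequence.MISSENSE
            if len(ref) != len(alt):
                consequence = (
                    Consequence.FRAMESHIFT_INS if len(alt) > len(ref) else Consequence.FRAMESHIFT_DEL
                )
            return Variant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                hgvs_c=hgvs,
                consequence=consequence,
                ref_freqs={"kg1000": 0.0, "esp6500": 0.0},
            )
    raise ValueError(f"no padded spelling known for catalogue entry {mutation}")


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate a full cohort: calls, annotation, score genotypes, truth."""
    if config.score_model is None:
        raise ValueError("config.score_model is required for full cohort simulation")
    rng = np.random.default_rng(config.seed)
    cases = [f"CASE{i + 1:04d}" for i in range(config.n_cases)]
    controls = [f"CTRL{i + 1:04d}" for i in range(config.n_controls)]
    calls: list[SampleCall] = []
    annotation: dict = {}

    # --- tier-1 spikes ----------------------------------------------------
    total_spiked = sum(s.n_carriers for s in config.tier1_spikes)
    if total_spiked > config.n_cases:
        raise ValueError("more spiked carriers than cases")
    spiked_samples = list(rng.choice(cases, size=total_spiked, replace=False))
    spiked_tier1: dict[str, KnownMutation] = {}
    tier1_explained: set[str] = set()
    cursor = 0
    for spike in config.tier1_spikes:
        for _ in range(spike.n_carriers):
            sample = spiked_samples[cursor]
            cursor += 1
            variant = _spike_variant(spike.mutation)
            annotation[variant.key] = variant
            calls.append(SampleCall(sample_id=sample, variant=variant, zygosity=spike.zygosity))
            spiked_tier1[sample] = spike.mutation
            dominant = spike.mutation.gene != "LDLRAP1"
            if spike.mutation.pathogenicity == "known_fh" and (dominant or spike.zygosity == "hom"):
                tier1_explained.add(sample)

    # --- background carrier events ---------------------------------------
    case_arr = np.array(cases)
    control_arr = np.array(controls)
    variant_serial = 0
    for gi, gene in enumerate(config.genes):
        mult = config.enrichment.get(gene.gene, 1.0)
        case_rate = gene.rate * mult
        if case_rate > 1.0:
            raise ValueError(f"case rate for {gene.gene} exceeds 1")
        carriers = list(case_arr[rng.random(config.n_cases) < case_rate]) + list(
            control_arr[rng.random(config.n_controls) < gene.rate]
        )
        base_pos = 1_000_000 + gi * 10_000
        for sample in carriers:
            variant_serial += 1
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            variant = Variant(
                chrom=gene.chrom,
                pos=base_pos + variant_serial % 9_999,
                ref=str(ref),
                alt=str(alt),
                gene=gene.gene,
                consequence=_FUNCTIONAL_CYCLE[variant_serial % len(_FUNCTIONAL_CYCLE)],
                ref_freqs={"kg1000": 0.0, "esp6500": 0.0},
            )
            annotation[variant.key] = variant
            calls.append(SampleCall(sample_id=sample, variant=variant, zygosity="het"))
        # decoy calls that the filters must remove: a synonymous novel
        # variant and a functional-but-common variant
        for decoy_cons, freqs in (
            (Consequence.SYNONYMOUS, {"kg1000": 0.0, "esp6500": 0.0}),
            (Consequence.MISSENSE, {"kg1000": 0.012, "esp6500": 0.008}),
        ):
            decoys = list(case_arr[rng.random(config.n_cases) < config.noise_rate]) + list(
                control_arr[rng.random(config.n_controls) < config.noise_rate]
            )
            for sample in decoys:
                variant_serial += 1
                ref, alt = rng.choice(list(_BASES), size=2, replace=False)
                variant = Variant(
                    chrom=gene.chrom,
                    pos=base_pos + variant_serial % 9_999,
                    ref=str(ref),
                    alt=str(alt),
                    gene=gene.gene,
                    consequence=decoy_cons,
                    ref_freqs=freqs,
                )
                annotation[variant.key] = variant
                calls.append(SampleCall(sample_id=sample, variant=variant, zygosity="het"))

    # --- score genotypes ---------------------------------------------------
    # unscored samples (poor DNA) are drawn from all cases; the polygenic
    # fraction applies to score-attainable cases, and is planted only in
    # mutation-negative ones — spiked carriers draw background scores, so
    # the occasional carrier above the cutoff arises at the population rate
    model = config.score_model
    cutoff = model.target_p90
    spiked_set = set(spiked_tier1)
    n_unscored = round(config.unscored_case_fraction * config.n_cases)
    unscored = set(rng.choice(cases, size=n_unscored, replace=False))
    eligible = [s for s in cases if s not in unscored and s not in spiked_set]
    n_poly = round(config.polygenic_case_fraction * (config.n_cases - n_unscored))
    if n_poly > len(eligible):
        raise ValueError("polygenic fraction exceeds the scored mutation-negative pool")
    planted_polygenic = set(rng.choice(eligible, size=n_poly, replace=False))

    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    snp_ids = [s.snp_id for s in model.snps]
    for sample in cases:
        if sample in spiked_set or sample in unscored:
            above = None  # background draw
        else:
            above = sample in planted_polygenic
        g = _sample_conditional(model, rng, above, cutoff)
        if sample in unscored:
            g.pop(snp_ids[int(rng.integers(len(snp_ids)))])
        genotypes[sample] = g
    for sample in controls:
        genotypes[sample] = _sample_conditional(model, rng, None, cutoff)

    dataset = CohortDataset(cases=frozenset(cases), controls=frozenset(controls), calls=calls)
    truth = TruthTable(
        spiked_tier1=spiked_tier1,
        tier1_explained=tier1_explained,
        planted_polygenic=planted_polygenic,
        unscored=unscored,
        enriched_genes={g for g, m in config.enrichment.items() if m > 1.0},
        gene_rates={g.gene: g.rate for g in config.genes},
    )
    return SimResult(
        config=config,
        dataset=dataset,
        annotation=annotation,
        genotypes=genotypes,
        catalogue=default_catalogue() if not config.tier1_spikes else [s.mutation for s in config.tier1_spikes],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery


@dataclass
class RecoveryReport:
    tier1_planted: int
    tier1_recovered: int
    tier1_recall: float
    polygenic_planted_fraction: float
    polygenic_recovered_fraction: float
    n_polygenic_base: int
    polygenic_sensitivity: float
    polygenic_specificity: float
    control_decile_fraction: float
    power: float | None
    type_i_rate: float | None


def recover_parameters(result: SimResult, p_flag_threshold: float = 4e-3) -> RecoveryReport:
    """Re-detect every planted signal with the analysis modules themselves.

    Tier-1 recall runs the catalogue screen and compares the explained set
    against the planted one.  Polygenic recovery scores every sample, sets
    the cutoff at the empirical control 90th percentile, and compares
    classifications of scored cases against the planted labels.  Power and
    type-I error come from a burden scan over the gene panel when
    enrichment was planted (``None`` otherwise for power).
    """
    from .burden import run_burden_scan
    from .filtering import collect_gene_counts, novel_functional
    from .tier1 import explained_samples, screen_tier1

    # tier-1
    matches = screen_tier1(result.dataset, result.catalogue)
    explained = explained_samples(matches)
    planted = result.truth.tier1_explained
    recovered = len(explained & planted)
    extra = explained - planted
    if extra:
        raise AssertionError(f"screen explained unplanted samples: {sorted(extra)[:5]}")

    # polygenic
    model = result.config.score_model
    assert model is not None
    weights = _model_weights(model)
    totals: dict[str, float] = {}
    for sample, g in result.genotypes.items():
        apoe = apoe_from_snps(g.get("rs429358"), g.get("rs7412"))
        r = gene_score(g, weights, apoe, sample_id=sample)
        if r.complete:
            totals[sample] = r.total
    control_scores = np.array([totals[s] for s in sorted(result.dataset.controls) if s in totals])
    cutoff = float(np.quantile(control_scores, 0.9))
    control_decile_fraction = float(np.mean(control_scores > cutoff))
    # polygenic planting targets score-attainable mutation-negative cases;
    # recovery is judged on that same base
    spiked = set(result.truth.spiked_tier1)
    scored_cases = [s for s in sorted(result.dataset.cases) if s in totals and s not in spiked]
    classified = {s for s in scored_cases if totals[s] > cutoff}
    planted_poly = result.truth.planted_polygenic & set(scored_cases)
    tp = len(classified & planted_poly)
    fp = len(classified - planted_poly)
    fn = len(planted_poly - classified)
    tn = len(scored_cases) - tp - fp - fn
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")

    # burden power / type-I over the panel
    counts = collect_gene_counts(result.dataset, novel_functional)
    scan = run_burden_scan(counts, result.dataset.case_n, result.dataset.control_n,
                           p_flag_threshold=p_flag_threshold)
    enriched = result.truth.enriched_genes
    flagged = {r.gene for r in scan if r.flagged}
    null_genes = set(result.truth.gene_rates) - enriched
    type_i = len(flagged & null_genes) / len(null_genes) if null_genes else None
    power = len(flagged & enriched) / len(enriched) if enriched else None

    return RecoveryReport(
        tier1_planted=len(planted),
        tier1_recovered=recovered,
        tier1_recall=recovered / len(planted) if planted else float("nan"),
        polygenic_planted_fraction=len(planted_poly) / len(scored_cases) if scored_cases else float("nan"),
        polygenic_recovered_fraction=len(classified) / len(scored_cases) if scored_cases else float("nan"),
        n_polygenic_base=len(scored_cases),
        polygenic_sensitivity=sens,
        polygenic_specificity=spec,
        control_decile_fraction=control_decile_fraction,
        power=power,
        type_i_rate=type_i,
    )


def null_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    n_cases: int = 71,
    n_controls: int = 1926,
    n_genes: int = 500,
    alpha: float = 4e-3,
) -> dict[str, float]:
    """Type-I behaviour of the burden p under the no-enrichment null.

    Simulates per-gene carrier counts at the study's arm sizes over many
    replicate exome scans and measures, per replicate, the fraction of
    genes whose one-sided p falls below ``alpha`` (genes with no case
    event have p = 1).  For a valid — and, with discrete counts,
    conservative — test the mean fraction stays at or below ``alpha``.

    Returns the mean fraction, its standard error over replicates, and
    ``alpha``.
    """
    from .burden import binomial_burden_p

    rng = np.random.default_rng(seed)
    config = SimConfig(seed=seed, n_cases=n_cases, n_controls=n_controls, genes=default_gene_panel(n_genes))
    p_cache: dict[tuple[int, int], float] = {}

    def p_of(kc: int, kn: int) -> float:
        pair = (kc, kn)
        if pair not in p_cache:
            p_cache[pair] = binomial_burden_p(kc, kn, n_cases, n_controls)
        return p_cache[pair]

    fractions = np.empty(n_replicates)
    for i in range(n_replicates):
        counts = simulate_gene_counts(config, rng)
        below = [
            p_of(int(kc), int(kn)) < alpha
            for kc, kn in zip(counts["k_case"], counts["k_control"])
        ]
        fractions[i] = float(np.mean(below))
    return {
        "mean_fraction": float(np.mean(fractions)),
        "se": float(np.std(fractions, ddof=1) / np.sqrt(n_replicates)),
        "alpha": alpha,
        "n_replicates": float(n_replicates),
    }


# ---------------------------------------------------------------------------
# file emission (same formats the pipeline consumes)


def write_simulated_inputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCFs, annotation, catalogue, weights, genotypes and truth
    tables so the file-based pipeline can run on the simulated cohort."""
    from .variant_model import write_cohort_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "case_vcf": outdir / "cases.vcf",
        "control_vcf": outdir / "controls.vcf",
        "annotation": outdir / "annotation.tsv",
        "catalogue": outdir / "catalogue.tsv",
        "weights": outdir / "weights.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "truth": outdir / "truth.tsv",
    }
    ds = result.dataset
    case_ds = CohortDataset(cases=ds.cases, controls=frozenset(), calls=[c for c in ds.calls if ds.is_case(c.sample_id)])
    ctrl_ds = CohortDataset(cases=frozenset(), controls=ds.controls, calls=[c for c in ds.calls if not ds.is_case(c.sample_id)])
    write_cohort_vcf(case_ds, paths["case_vcf"])
    write_cohort_vcf(ctrl_ds, paths["control_vcf"])

    rows = []
    for key in sorted(result.annotation):
        v = result.annotation[key]
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "transcript": v.transcript or "",
                "hgvs_c": v.hgvs_c or "",
                "consequence": v.consequence.value,
                "kg1000": v.ref_freqs.get("kg1000", 0.0),
                "esp6500": v.ref_freqs.get("esp6500", 0.0),
            }
        )
    pd.DataFrame(rows).to_csv(paths["annotation"], sep="\t", index=False)

    cat_rows = []
    for m in result.catalogue:
        key = m.key
        cat_rows.append(
            {
                "gene": m.gene,
                "chrom": key.chrom if key else "",
                "pos": key.pos if key else "",
                "ref": key.ref if key else "",
                "alt": key.alt if key else "",
                "hgvs_c": m.hgvs_c or "",
                "pathogenicity": m.pathogenicity,
            }
        )
    pd.DataFrame(cat_rows).to_csv(paths["catalogue"], sep="\t", index=False)

    model = result.config.score_model
    assert model is not None
    pd.DataFrame(
        [
            {
                "snp_id": s.snp_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "weight": s.weight,
            }
            for s in model.snps
        ]
    ).to_csv(paths["weights"], sep="\t", index=False)

    geno_rows = [
        {"sample_id": sample, "snp_id": snp, "allele1": a1, "allele2": a2}
        for sample in sorted(result.genotypes)
        for snp, (a1, a2) in sorted(result.genotypes[sample].items())
    ]
    pd.DataFrame(geno_rows).to_csv(paths["genotypes"], sep="\t", index=False)

    truth_rows = [
        {
            "sample_id": s,
            "spiked_tier1": s in result.truth.spiked_tier1,
            "tier1_explained": s in result.truth.tier1_explained,
            "planted_polygenic": s in result.truth.planted_polygenic,
            "unscored": s in result.truth.unscored,
        }
        for s in sorted(result.dataset.cases)
    ]
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
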