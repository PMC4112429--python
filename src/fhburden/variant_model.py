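"""Domain types and cohort ingestion.

A cohort is a set of case samples and a disjoint set of control samples,
each carrying a collection of variant calls.  Variants are normalized to a
canonical coordinate key so that the same biological event — however it was
written in the input VCF — always compares equal, which is what the
known-mutation catalogue matching and the carrier-event counting both rely
on.

Coordinates are 1-based throughout, as in VCF.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "Variant",
    "VariantKey",
    "SampleCall",
    "CohortDataset",
    "normalize_chrom",
    "normalize_variant",
    "read_annotation",
    "read_cohort",
    "write_cohort_vcf",
]


class Consequence(str, Enum):
    """Coding-consequence class of a variant, as supplied by the annotation."""

    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "Consequence":
        try:
            return cls(label.strip().lower())
        except ValueError:
            return cls.OTHER


class VariantKey(NamedTuple):
    """Canonical identity of a variant after normalization.

    ``ref`` or ``alt`` may be the empty string for a parsimonious indel
    representation (pure insertion / pure deletion after trimming).
    """

    chrom: str
    pos: int
    ref: str
    alt: str


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and canonicalise sex/mito labels."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in {"X", "Y", "MT", "M"}:
        return "MT" if c.upper() in {"MT", "M"} else c.upper()
    return c


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Reduce a (chrom, pos, ref, alt) record to its canonical key.

    Shared sequence is trimmed from the right, then from the left (advancing
    ``pos``), so equivalent right-shifted indel spellings that overlap in
    their reference span collapse to the same key.  Full left-alignment
    against a reference genome is intentionally not attempted: the inputs
    here are exome call sets where the padded-VCF spelling plus trimming is
    sufficient for identity.

    Raises
    ------
    ValueError
        if the alleles are empty or identical after trimming (non-variant).
    """
    ref = str(ref).upper().strip()
    alt = str(alt).upper().strip()
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty allele strings")
    pos = int(pos)
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    # trim shared suffix
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix, advancing the coordinate
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:  # both empty: the record described no change
        raise ValueError("ref == alt after trimming: not a variant")
    return VariantKey(normalize_chrom(chrom), pos, ref, alt)


@dataclass(frozen=True)
class Variant:
    """One normalized alternate allele with its annotation.

    Equality and hashing use the coordinate key only; annotation fields are
    carried along but do not participate in identity.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = field(default="", compare=False)
    transcript: str | None = field(default=None, compare=False)
    hgvs_c: str | None = field(default=None, compare=False)
    consequence: Consequence = field(default=Consequence.OTHER, compare=False)
    ref_freqs: Mapping[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for panel, freq in self.ref_freqs.items():
            if not (0.0 <= freq <= 1.0):
                raise ValueError(f"frequency for panel {panel!r} outside [0,1]: {freq}")

    @property
    def key(self) -> VariantKey:
        if not self.ref or not self.alt:
            # already a parsimonious indel key (empty allele); pass through
            return VariantKey(normalize_chrom(self.chrom), self.pos, self.ref, self.alt)
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleCall:
    """One sample carrying one variant; the counting unit of the burden test."""

    sample_id: str
    variant: Variant
    zygosity: str  # "het" | "hom"

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het or hom, got {self.zygosity!r}")


@dataclass
class CohortDataset:
    """Case and control sample sets with their variant calls."""

    cases: frozenset[str]
    controls: frozenset[str]
    calls: list[SampleCall]
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cases = frozenset(self.cases)
        self.controls = frozenset(self.controls)
        overlap = self.cases & self.controls
        if overlap:
            raise ValueError(
                f"samples present in both cases and controls: {sorted(overlap)[:5]}"
            )
        known = self.cases | self.controls
        for call in self.calls:
            if call.sample_id not in known:
                raise ValueError(f"call for unknown sample {call.sample_id!r}")

    @property
    def case_n(self) -> int:
        return len(self.cases)

    @property
    def control_n(self) -> int:
        return len(self.controls)

    def is_case(self, sample_id: str) -> bool:
        return sample_id in self.cases

    def subset_cases(self, keep: Iterable[str]) -> "CohortDataset":
        """Restrict the case arm to ``keep``; controls are untouched."""
        keep = frozenset(keep)
        missing = keep - self.cases
        if missing:
            raise ValueError(f"not case samples: {sorted(missing)[:5]}")
        calls = [
            c
            for c in self.calls
            if c.sample_id in keep or c.sample_id in self.controls
        ]
        return CohortDataset(cases=keep, controls=self.controls, calls=calls)


# ---------------------------------------------------------------------------
# ingestion


#: required leading columns of the annotation table
ANNOTATION_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c", "consequence")


def read_annotation(path: str | Path) -> dict[VariantKey, Variant]:
    """Load the variant annotation TSV into a key -> Variant lookup.

    Columns after the fixed leading set are treated as reference-panel
    frequency columns (e.g. ``kg1000``, ``esp6500``); empty cells mean the
    variant was not observed in that panel.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except OSError as exc:
        raise RuntimeError(f"cannot read annotation file {path}: {exc}") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {missing}")
    panels = [c for c in table.columns if c not in ANNOTATION_COLUMNS]
    lookup: dict[VariantKey, Variant] = {}
    for row in table.itertuples(index=False):
        freqs = {}
        for panel in panels:
            val = getattr(row, panel)
            if pd.notna(val):
                freqs[panel] = float(val)
        transcript = getattr(row, "transcript")
        hgvs = getattr(row, "hgvs_c")
        var = Variant(
            chrom=normalize_chrom(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            gene=str(row.gene),
            transcript=None if pd.isna(transcript) else str(transcript),
            hgvs_c=None if pd.isna(hgvs) else str(hgvs),
            consequence=Consequence.parse(str(row.consequence)),
            ref_freqs=freqs,
        )
        lookup[var.key] = var
    return lookup


def _calls_from_vcf(
    path: str | Path,
    annotation: Mapping[VariantKey, Variant],
    unannotated: set[VariantKey],
) -> tuple[list[str], list[tuple[str, VariantKey, str]]]:
    """Yield (samples, [(sample, key, zygosity), ...]) for one VCF file.

    Multi-allelic records are decomposed into one variant per ALT allele; a
    genotype carrying two different ALTs yields one het call for each.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise RuntimeError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    out: list[tuple[str, VariantKey, str]] = []
    for record in vcf:
        alts = record.ALT or []
        keys = []
        for alt in alts:
            try:
                keys.append(normalize_variant(record.CHROM, record.POS, record.REF, alt))
            except ValueError:
                keys.append(None)  # symbolic / non-variant ALT: skip
        genotypes = record.genotypes  # [[a0, a1, phased], ...]
        for sample, gt in zip(samples, genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if not alleles:
                continue
            for alt_index in sorted({a for a in alleles if a > 0}):
                key = keys[alt_index - 1]
                if key is None:
                    continue
                zyg = "hom" if alleles.count(alt_index) == len(alleles) >= 2 else "het"
                if key not in annotation:
                    unannotated.add(key)
                out.append((sample, key, zyg))
    return samples, out


def read_cohort(
    case_vcf_paths: Sequence[str | Path],
    control_vcf_paths: Sequence[str | Path],
    annotation_path: str | Path,
) -> CohortDataset:
    """Read case and control VCFs plus the annotation TSV into a cohort.

    Every non-reference genotype becomes one :class:`SampleCall`.  Variants
    missing from the annotation table are kept with ``consequence=other``
    and no reference frequencies, and listed in the run log.
    """
    annotation = read_annotation(annotation_path)
    unannotated: set[VariantKey] = set()
    log: list[str] = []

    def load(paths: Sequence[str | Path]) -> tuple[set[str], list[tuple[str, VariantKey, str]]]:
        sample_ids: set[str] = set()
        calls: list[tuple[str, VariantKey, str]] = []
        for p in paths:
            samples, file_calls = _calls_from_vcf(p, annotation, unannotated)
            sample_ids.update(samples)
            calls.extend(file_calls)
        return sample_ids, calls

    case_ids, case_calls = load(case_vcf_paths)
    control_ids, control_calls = load(control_vcf_paths)
    overlap = case_ids & control_ids
    if overlap:
        raise ValueError(
            f"sample ids appear in both case and control VCFs: {sorted(overlap)[:5]}"
        )

    def materialise(key: VariantKey) -> Variant:
        if key in annotation:
            return annotation[key]
        return Variant(chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt)

    calls = [
        SampleCall(sample_id=s, variant=materialise(k), zygosity=z)
        for s, k, z in case_calls + control_calls
    ]
    for key in sorted(unannotated):
        msg = f"unannotated variant {key.chrom}:{key.pos}:{key.ref}>{key.alt}; consequence set to 'other'"
        logger.warning(msg)
        log.append(msg)
    return CohortDataset(cases=frozenset(case_ids), controls=frozenset(control_ids), calls=calls, log=log)


def write_cohort_vcf(dataset: CohortDataset, path: str | Path) -> None:
    """Write the cohort as one multi-sample VCF 4.2 file (text, GT only)."""
    samples = sorted(dataset.cases) + sorted(dataset.controls)
    index = {s: i for i, s in enumerate(samples)}
    # group calls by variant
    by_variant: dict[tuple[str, int, str, str], dict[int, str]] = defaultdict(dict)
    for call in dataset.calls:
        v = call.variant
        by_variant[(v.chrom, v.pos, v.ref, v.alt)][index[call.sample_id]] = call.zygosity

    def chrom_order(c: str) -> tuple[int, str]:
        return (0, f"{int(c):03d}") if c.isdigit() else (1, c)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt) in sorted(by_variant, key=lambda k: (chrom_order(k[0]), k[1], k[2], k[3])):
            carriers = by_variant[(chrom, pos, ref, alt)]
            gts = ["0/0"] * len(samples)
            for i, zyg in carriers.items():
                gts[i] = "1/1" if zyg == "hom" else "0/1"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
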