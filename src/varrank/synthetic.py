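"""Synthetic cohort generator.

Produces genotype matrices, annotations, population frequencies, gene sizes
and truth labels with the statistical structure the pipeline assumes:
Hardy-Weinberg genotypes at stated MAFs, resistant-group enrichment at
stated allele-level odds ratios, a controllable fraction of variants with
missing AltAF and a fraction recorded against the major allele (AltAF >= 0.5,
complemented genotypes) that the adjustment step must fold back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    GeneSizeTable,
    GenotypeMatrix,
    Group,
    Sample,
    VariantKey,
    VariantRecord,
)
from .errors import ValidationError
from .io import PopulationFrequencies

__all__ = [
    "VariantSpec",
    "SimulationSpec",
    "SimulatedCohort",
    "enriched_allele_frequency",
    "simulate_cohort",
    "paperlike_fixture",
    "PAPERLIKE_ENRICHED_GENES",
]


@dataclass
class VariantSpec:
    """Blueprint for one simulated polymorphism."""

    gene: str
    maf: float
    odds_ratio: float = 1.0
    functional_class: str = "exonic"
    exonic_subtype: Optional[str] = "non-synonymous"
    altaf_missing: bool = False
    altaf_major_oriented: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValidationError(f"MAF must lie in (0, 0.5], got {self.maf}")
        if self.odds_ratio <= 0:
            raise ValidationError(f"odds ratio must be positive, got {self.odds_ratio}")


@dataclass
class SimulationSpec:
    n_sensitive: int
    n_resistant: int
    variants: Sequence[VariantSpec]
    n_reference_individuals: int = 503
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensitive < 1 or self.n_resistant < 1:
            raise ValidationError("sample counts must be >= 1")
        if self.n_reference_individuals < 1:
            raise ValidationError("n_reference_individuals must be >= 1")

    @classmethod
    def from_json(cls, path) -> "SimulationSpec":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["variants"] = [VariantSpec(**v) for v in raw["variants"]]
        return cls(**raw)

    def to_json(self, path) -> None:
        raw = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(raw, fh, indent=2)


@dataclass
class SimulatedCohort:
    matrix: GenotypeMatrix
    annotations: pd.DataFrame
    popfreq: PopulationFrequencies
    gene_sizes: GeneSizeTable
    truth: pd.DataFrame  # per variant: gene, maf, odds_ratio, q_star, enriched


def enriched_allele_frequency(maf: float, odds_ratio: float) -> float:
    """Allele frequency q* whose odds are `odds_ratio` times the MAF's odds."""
    odds = odds_ratio * maf / (1.0 - maf)
    q = odds / (1.0 + odds)
    if not 0.0 < q < 1.0:
        raise ValidationError(f"enriched frequency {q} outside (0, 1)")
    return q


def _hw_genotypes(rng: np.random.Generator, freq: float, n: int) -> np.ndarray:
    """Hardy-Weinberg diploid dosages: Binomial(2, freq) per sample."""
    return rng.binomial(2, freq, size=n).astype(np.int8)


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    rng = np.random.default_rng(spec.seed)
    n_s, n_r = spec.n_sensitive, spec.n_resistant
    samples = [Sample(f"S{i + 1:02d}", Group.SENSITIVE) for i in range(n_s)] + [
        Sample(f"R{i + 1:02d}", Group.RESISTANT) for i in range(n_r)
    ]
    records: list[VariantRecord] = []
    dosages = np.empty((len(spec.variants), n_s + n_r), dtype=np.int8)
    freq_table: dict[str, float] = {}
    truth_rows = []
    ann_rows = []
    genes_seen: dict[str, int] = {}
    for i, vs in enumerate(spec.variants):
        q_star = enriched_allele_frequency(vs.maf, vs.odds_ratio)
        row = np.concatenate(
            [_hw_genotypes(rng, vs.maf, n_s), _hw_genotypes(rng, q_star, n_r)]
        )
        # stable synthetic coordinates: one variant per position on chrS
        key = VariantKey("chrS", i + 1, "A", "G", rsid=f"sv{i + 1}")
        alt_af = vs.maf
        if vs.altaf_major_oriented:
            # record against the major allele: swap labels, complement calls
            key = key.swapped()
            row = 2 - row
            alt_af = 1.0 - vs.maf
        dosages[i, :] = row
        records.append(
            VariantRecord(
                key=key,
                gene=vs.gene,
                functional_class=vs.functional_class,
                exonic_subtype=vs.exonic_subtype if vs.functional_class in ("exonic", "exonic_splicing") else None,
            )
        )
        if not vs.altaf_missing:
            freq_table[key.canonical] = alt_af
        ann_rows.append(
            {
                "key": key.canonical,
                "gene": vs.gene,
                "functional_class": vs.functional_class,
                "exonic_subtype": records[-1].exonic_subtype or "",
                "rsid": key.rsid or "",
            }
        )
        truth_rows.append(
            {
                "key": key.canonical,
                "gene": vs.gene,
                "maf": vs.maf,
                "odds_ratio": vs.odds_ratio,
                "q_star": q_star,
                "enriched": vs.odds_ratio > 1.0,
                "altaf_missing": vs.altaf_missing,
                "altaf_major_oriented": vs.altaf_major_oriented,
            }
        )
        genes_seen[vs.gene] = genes_seen.get(vs.gene, 0) + 1
    # captured size grows with the number of variants the gene carries
    sizes = GeneSizeTable({g: 1500 + 250 * count for g, count in sorted(genes_seen.items())})
    matrix = GenotypeMatrix(records, samples, dosages)
    annotations = pd.DataFrame(ann_rows).set_index("key")
    truth = pd.DataFrame(truth_rows).set_index("key")
    return SimulatedCohort(
        matrix=matrix,
        annotations=annotations,
        popfreq=PopulationFrequencies(freq_table),
        gene_sizes=sizes,
        truth=truth,
    )


#: genes the bundled deterministic fixture enriches in the resistant group
PAPERLIKE_ENRICHED_GENES = ("G07", "G21", "G33")

_CLASS_POOL = [
    ("intronic", None, 0.60),
    ("exonic", "non-synonymous", 0.12),
    ("exonic", "synonymous", 0.10),
    ("UTR5", None, 0.08),
    ("UTR3", None, 0.05),
    ("splicing", None, 0.01),
    ("upstream", None, 0.01),
    ("downstream", None, 0.01),
    ("exonic_splicing", "non-synonymous", 0.01),
    ("exonic", "frameshift", 0.01),
]


def paperlike_fixture(seed: int = 11, n_variants: int = 700) -> tuple[SimulatedCohort, SimulationSpec]:
    """Deterministic bundled cohort: 48 genes, 12+12 samples, ~700 variants.

    Roughly 18% of variants lack a recorded AltAF and ~20% are recorded
    against the major allele. Three genes each carry three protein-altering
    variants enriched in the resistant group at allele odds ratio 8.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:02d}" for i in range(48)]
    classes, subtypes, weights = zip(*_CLASS_POOL)
    variants: list[VariantSpec] = []
    for g in PAPERLIKE_ENRICHED_GENES:
        for _ in range(3):
            variants.append(
                VariantSpec(
                    gene=g,
                    maf=float(rng.uniform(0.02, 0.06)),
                    odds_ratio=12.0,
                    functional_class="exonic",
                    exonic_subtype="non-synonymous",
                )
            )
    while len(variants) < n_variants:
        gene = genes[int(rng.integers(0, len(genes)))]
        ci = int(rng.choice(len(classes), p=np.array(weights) / sum(weights)))
        maf = float(np.clip(rng.beta(0.8, 3.0) * 0.5, 0.004, 0.5))
        missing = bool(rng.random() < 0.18)
        # only variants with a recorded AltAF can be major-oriented
        major = bool((not missing) and rng.random() < 0.24)
        variants.append(
            VariantSpec(
                gene=gene,
                maf=maf,
                odds_ratio=1.0,
                functional_class=classes[ci],
                exonic_subtype=subtypes[ci],
                altaf_missing=missing,
                altaf_major_oriented=major,
            )
        )
    spec = SimulationSpec(
        n_sensitive=12, n_resistant=12, variants=variants, n_reference_individuals=503, seed=seed
    )
    return simulate_cohort(spec), spec
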