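"""Core domain types: genotypes, variants, genotype matrices and derived tables.

Genotype calls are held internally as alternate-allele dosages (0, 1, 2) in a
dense ``int8`` array; the three-state categorical view (``0_0``, ``0_1``,
``1_1``) is reconstructed on demand.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Genotype",
    "Group",
    "EnrichmentLabel",
    "VariantKey",
    "VariantRecord",
    "Sample",
    "GenotypeMatrix",
    "ContingencyTable",
    "GeneSizeTable",
    "FUNCTIONAL_CLASSES",
    "EXONIC_SUBTYPES",
    "PROTEIN_ALTERING_SUBTYPES",
    "CONTINGENCY_COLUMNS",
]

FUNCTIONAL_CLASSES = frozenset(
    {
        "exonic",
        "exonic_splicing",
        "splicing",
        "intronic",
        "UTR5",
        "UTR3",
        "upstream",
        "downstream",
        "intergenic",
        "ncRNA_exonic",
    }
)

EXONIC_SUBTYPES = frozenset(
    {
        "synonymous",
        "non-synonymous",
        "frameshift",
        "non-frameshift",
        "stop-gain",
        "stop-loss",
    }
)

#: Exonic subtypes that alter the encoded protein.
PROTEIN_ALTERING_SUBTYPES = frozenset(
    {"non-synonymous", "frameshift", "non-frameshift", "stop-gain", "stop-loss"}
)

CONTINGENCY_COLUMNS = ("VAF_sensitive", "VAF_resistant", "MAF_population")


class Genotype(enum.Enum):
    """Diploid genotype relative to the current reference/alternate labels."""

    REF_HOM = "0_0"
    HET = "0_1"
    VAR_HOM = "1_1"

    @property
    def dosage(self) -> int:
        """Number of alternate alleles carried (0, 1 or 2)."""
        return _GT_TO_DOSAGE[self]

    def complement(self) -> "Genotype":
        """Swap reference and alternate alleles: 0_0 <-> 1_1, 0_1 fixed."""
        return _DOSAGE_TO_GT[2 - self.dosage]

    @classmethod
    def from_string(cls, text: str) -> "Genotype":
        try:
            return cls(text)
        except ValueError:
            raise ValidationError(f"unknown genotype code {text!r}; expected one of 0_0, 0_1, 1_1") from None

    @classmethod
    def from_dosage(cls, dosage: int) -> "Genotype":
        try:
            return _DOSAGE_TO_GT[dosage]
        except KeyError:
            raise ValidationError(f"dosage must be 0, 1 or 2, got {dosage}") from None


_GT_TO_DOSAGE = {Genotype.REF_HOM: 0, Genotype.HET: 1, Genotype.VAR_HOM: 2}
_DOSAGE_TO_GT = {0: Genotype.REF_HOM, 1: Genotype.HET, 2: Genotype.VAR_HOM}


class Group(enum.Enum):
    SENSITIVE = "sensitive"
    RESISTANT = "resistant"

    @classmethod
    def from_string(cls, text: str) -> "Group":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValidationError(f"unknown group {text!r}; expected 'sensitive' or 'resistant'") from None


class EnrichmentLabel(enum.Enum):
    SENSITIVE_ENRICHED = "sensitive_enriched"
    NEUTRAL = "neutral"
    RESISTANT_ENRICHED = "resistant_enriched"


_KEY_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[ACGTNacgtn\-]+):(?P<alt>[ACGTNacgtn\-]+)$")


@dataclass(frozen=True)
class VariantKey:
    """Canonical variant identity: 1-based coordinates plus explicit alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1 (1-based), got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt alleles must be nonempty")

    @property
    def canonical(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def swapped(self) -> "VariantKey":
        """Key with reference and alternate allele labels exchanged."""
        return replace(self, ref=self.alt, alt=self.ref)

    @property
    def variant_class(self) -> str:
        """'SNP', 'insertion' or 'deletion' from allele lengths."""
        if len(self.ref) == len(self.alt):
            return "SNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @classmethod
    def parse(cls, text: str, rsid: Optional[str] = None) -> "VariantKey":
        m = _KEY_RE.match(text.strip())
        if m is None:
            raise ValidationError(
                f"cannot parse variant key {text!r}; expected 'chrom:pos:ref:alt'"
            )
        return cls(m["chrom"], int(m["pos"]), m["ref"].upper(), m["alt"].upper(), rsid)

    def __str__(self) -> str:
        return self.canonical


@dataclass
class VariantRecord:
    """One polymorphism: identity, annotation and optional reference-population AltAF."""

    key: VariantKey
    gene: Optional[str] = None
    functional_class: Optional[str] = None
    exonic_subtype: Optional[str] = None
    alt_af: Optional[float] = None
    maf_imputed: bool = False
    oriented: bool = False
    inverted: bool = False

    def __post_init__(self) -> None:
        if self.alt_af is not None and not 0.0 <= self.alt_af <= 1.0:
            raise ValidationError(f"alt_af must lie in [0, 1], got {self.alt_af} for {self.key}")
        if self.functional_class is not None and self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValidationError(
                f"unknown functional class {self.functional_class!r} for {self.key}"
            )
        if self.exonic_subtype is not None and self.exonic_subtype not in EXONIC_SUBTYPES:
            raise ValidationError(f"unknown exonic subtype {self.exonic_subtype!r} for {self.key}")
        if self.functional_class not in (None, "intergenic") and self.gene == "":
            raise ValidationError(f"gene symbol must be nonempty for non-intergenic {self.key}")

    @property
    def is_exonic(self) -> bool:
        return self.functional_class in ("exonic", "exonic_splicing")


@dataclass(frozen=True)
class Sample:
    id: str
    group: Group


class GenotypeMatrix:
    """Variants x samples genotype table with per-sample group labels.

    Every cell must be populated; missing calls are rejected upstream at load.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[Sample],
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(variants), len(samples)):
            raise ValidationError(
                f"dosage array shape {dosages.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        keys = [v.key.canonical for v in variants]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate variant keys: {dup[:5]}")
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        if dosages.size and not np.isin(dosages, (0, 1, 2)).all():
            raise ValidationError("genotype dosages must be 0, 1 or 2 everywhere")
        self.variants = list(variants)
        self.samples = list(samples)
        self.dosages = dosages

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def variant_keys(self) -> list[str]:
        return [v.key.canonical for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def group_indices(self, group: Group) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.group is group], dtype=int)

    def group_dosages(self, group: Group) -> np.ndarray:
        idx = self.group_indices(group)
        return self.dosages[:, idx]

    def calls(self) -> pd.DataFrame:
        """Categorical view: DataFrame of '0_0'/'0_1'/'1_1' strings."""
        lut = np.array(["0_0", "0_1", "1_1"])
        return pd.DataFrame(lut[self.dosages], index=self.variant_keys, columns=self.sample_ids)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        variants = [v for v, keep in zip(self.variants, mask) if keep]
        return GenotypeMatrix(variants, self.samples, self.dosages[mask, :])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix([replace(v) for v in self.variants], list(self.samples), self.dosages.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.dosages, other.dosages)
        )


class ContingencyTable:
    """Per-variant VAF of both patient groups plus the population MAF.

    Rows are variant keys; columns are ``VAF_sensitive``, ``VAF_resistant``
    and ``MAF_population``, all fractions in [0, 1] with the MAF folded to
    <= 0.5.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True) -> None:
        missing = [c for c in CONTINGENCY_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"contingency table missing columns {missing}")
        data = data.loc[:, list(CONTINGENCY_COLUMNS)].astype(float)
        if validate:
            self._validate(data)
        self.data = data

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        vals = data.to_numpy()
        if vals.size == 0:
            return
        if np.isnan(vals).any():
            raise ValidationError("contingency table contains missing values")
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("contingency table entries must lie in [0, 1]")
        if (data["MAF_population"] > 0.5 + 1e-12).any():
            bad = data.index[data["MAF_population"] > 0.5 + 1e-12][0]
            raise ValidationError(f"MAF_population exceeds 0.5 for {bad}; table is not oriented")
        zero = (data["VAF_sensitive"] == 0) & (data["VAF_resistant"] == 0)
        if zero.any():
            bad = data.index[zero][0]
            raise ValidationError(f"variant {bad} has zero VAF in both groups; prune monomorphic rows first")

    @property
    def variant_keys(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        if list(self.data.index) != list(other.data.index):
            return False
        return np.allclose(self.data.to_numpy(), other.data.to_numpy(), atol=1e-12)


class GeneSizeTable:
    """Gene symbol -> captured size in base pairs."""

    def __init__(self, sizes: Mapping[str, int]) -> None:
        clean: dict[str, int] = {}
        for gene, size in sizes.items():
            size = int(size)
            if size <= 0:
                raise ValidationError(f"gene size must be positive, got {size} for {gene}")
            clean[str(gene)] = size
        self.sizes = clean

    def __getitem__(self, gene: str) -> int:
        return self.sizes[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.sizes

    def __len__(self) -> int:
        return len(self.sizes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSizeTable):
            return NotImplemented
        return self.sizes == other.sizes

    def items(self) -> Iterable[tuple[str, int]]:
        return self.sizes.items()
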