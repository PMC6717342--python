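"""Genotype-matrix adjustment: theoretical-MAF imputation, minor-allele
orientation, monomorphic pruning and VAF computation into the three-group
contingency table.

The VAF of a patient group is allele-counting:
``(n_het + 2 * n_var_hom) / (2 * n_samples)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    ContingencyTable,
    Genotype,
    GenotypeMatrix,
    Group,
    VariantRecord,
)
from .errors import ConfigurationError, ValidationError
from .io import PopulationFrequencies

__all__ = [
    "AdjustmentReport",
    "impute_theoretical_maf",
    "orient_to_minor_allele",
    "drop_monomorphic",
    "compute_vaf",
    "build_contingency_table",
    "adjust_pipeline",
]


@dataclass
class AdjustmentReport:
    """Book-keeping for the four-step adjustment workflow."""

    n_input: int
    n_imputed_maf: int
    n_inverted: int
    n_removed_monomorphic: int
    n_output: int

    def __post_init__(self) -> None:
        counts = (self.n_input, self.n_imputed_maf, self.n_inverted,
                  self.n_removed_monomorphic, self.n_output)
        if any(c < 0 for c in counts):
            raise ValidationError("adjustment counts must be nonnegative")
        if self.n_output != self.n_input - self.n_removed_monomorphic:
            raise ValidationError(
                f"inconsistent report: {self.n_output} != {self.n_input} - {self.n_removed_monomorphic}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_imputed_maf": self.n_imputed_maf,
            "n_inverted": self.n_inverted,
            "n_removed_monomorphic": self.n_removed_monomorphic,
            "n_output": self.n_output,
        }


def impute_theoretical_maf(
    records: Sequence[VariantRecord], n_reference_individuals: int
) -> list[VariantRecord]:
    """Replace every absent AltAF by the theoretical floor 1/N.

    The floor treats the minor allele as carried by fewer than one individual
    of the N-person reference cohort. Present values are untouched; imputed
    values are below 0.5 for N >= 3, so they never trigger inversion.
    """
    if n_reference_individuals < 1:
        raise ValueError("n_reference_individuals must be a positive integer")
    floor = 1.0 / n_reference_individuals
    out = []
    for rec in records:
        if rec.alt_af is None:
            out.append(replace(rec, alt_af=floor, maf_imputed=True))
        else:
            out.append(replace(rec))
    return out


def orient_to_minor_allele(
    matrix: GenotypeMatrix,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Fold every variant onto the population minor allele.

    Variants with AltAF >= 0.5 get MAF = 1 - AltAF, complemented genotypes
    and swapped ref/alt labels; the rest keep MAF = AltAF and their calls.
    Records already carrying the ``oriented`` flag are passed through, which
    makes the operation idempotent (relevant at the AltAF = 0.5 boundary).

    Returns (oriented matrix, per-variant MAF array, inversion flags).
    """
    for rec in matrix.variants:
        if rec.alt_af is None:
            raise ValidationError(f"{rec.key} has no alt_af; impute or drop before orienting")
    out = matrix.copy()
    mafs = np.empty(out.n_variants)
    inverted = np.zeros(out.n_variants, dtype=bool)
    for i, rec in enumerate(out.variants):
        if rec.oriented:
            mafs[i] = rec.alt_af  # an oriented record's alt_af is already the MAF
            continue
        if rec.alt_af >= 0.5:
            out.dosages[i, :] = 2 - out.dosages[i, :]
            rec.key = rec.key.swapped()
            rec.alt_af = 1.0 - rec.alt_af
            rec.inverted = True
            inverted[i] = True
        mafs[i] = rec.alt_af
        rec.oriented = True
    return out, mafs, inverted


def drop_monomorphic(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Remove variants that are reference-homozygous in every sample."""
    mono = matrix.dosages.sum(axis=1) == 0
    removed = [v.key.canonical for v, m in zip(matrix.variants, mono) if m]
    return matrix.subset_variants(~mono), removed


def compute_vaf(calls: Union[Sequence[Genotype], np.ndarray]) -> float:
    """Allele-counting variant allele frequency of one group of calls."""
    if isinstance(calls, np.ndarray):
        dosages = calls.astype(float)
    else:
        dosages = np.array([g.dosage for g in calls], dtype=float)
    if dosages.size == 0:
        raise ValueError("cannot compute a VAF for an empty group")
    return float(dosages.sum() / (2 * dosages.size))


def build_contingency_table(
    matrix: GenotypeMatrix,
    mafs: np.ndarray,
    n_imputed: int = 0,
    n_inverted: int = 0,
    n_removed: int = 0,
) -> tuple[ContingencyTable, AdjustmentReport]:
    """Assemble the three-column table from a pruned, oriented matrix."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (matrix.n_variants,):
        raise ConfigurationError("one MAF per retained variant is required")
    for group in Group:
        if matrix.group_indices(group).size == 0:
            raise ConfigurationError(f"matrix has no samples in group {group.value!r}")
    sens = matrix.group_dosages(Group.SENSITIVE)
    res = matrix.group_dosages(Group.RESISTANT)
    frame = pd.DataFrame(
        {
            "VAF_sensitive": sens.sum(axis=1) / (2 * sens.shape[1]),
            "VAF_resistant": res.sum(axis=1) / (2 * res.shape[1]),
            "MAF_population": mafs,
        },
        index=matrix.variant_keys,
    )
    n_input = matrix.n_variants + n_removed
    report = AdjustmentReport(
        n_input=n_input,
        n_imputed_maf=n_imputed,
        n_inverted=n_inverted,
        n_removed_monomorphic=n_removed,
        n_output=matrix.n_variants,
    )
    return ContingencyTable(frame), report


def adjust_pipeline(
    matrix: GenotypeMatrix,
    popfreq: Optional[PopulationFrequencies] = None,
    n_reference_individuals: int = 503,
    drop_missing_af: bool = False,
) -> tuple[ContingencyTable, AdjustmentReport, GenotypeMatrix, np.ndarray]:
    """Full four-step adjustment.

    Looks up AltAF for every variant (if `popfreq` given), imputes the
    theoretical MAF for absent ones (or drops them when `drop_missing_af`),
    orients to the minor allele, prunes monomorphic rows and builds the
    contingency table.

    Returns (table, report, adjusted matrix, per-variant MAFs).
    """
    work = matrix.copy()
    if popfreq is not None:
        for rec in work.variants:
            if rec.alt_af is None:
                rec.alt_af = popfreq.lookup(rec.key)
    if drop_missing_af:
        keep = np.array([rec.alt_af is not None for rec in work.variants])
        work = work.subset_variants(keep)
        records = [replace(r) for r in work.variants]
        n_imputed = 0
    else:
        records = impute_theoretical_maf(work.variants, n_reference_individuals)
        n_imputed = sum(r.maf_imputed for r in records)
    work = GenotypeMatrix(records, work.samples, work.dosages)
    oriented, mafs, inverted = orient_to_minor_allele(work)
    pruned, removed = drop_monomorphic(oriented)
    kept_mask = ~np.isin(oriented.variant_keys, removed)
    table, report = build_contingency_table(
        pruned,
        mafs[kept_mask],
        n_imputed=n_imputed,
        n_inverted=int(inverted.sum()),
        n_removed=len(removed),
    )
    return table, report, pruned, mafs[kept_mask]
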