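"""Readers and writers for every pipeline input and output.

All formats are plain delimited text. Genotype matrices can be loaded either
from the ``matrix_csv`` layout (first column variant key, header row sample
ids, cells in {0_0, 0_1, 1_1}) or from a multi-sample VCF via pysam.
"""

from __future__ import annotations

import csv
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .datamodel import (
    CONTINGENCY_COLUMNS,
    ContingencyTable,
    GeneSizeTable,
    Genotype,
    GenotypeMatrix,
    Group,
    Sample,
    VariantKey,
    VariantRecord,
)
from .errors import ConfigurationError, LoadError, ValidationError

__all__ = [
    "read_sample_groups",
    "read_genotype_matrix",
    "read_annotation_table",
    "attach_annotations",
    "PopulationFrequencies",
    "read_population_frequencies",
    "read_gene_sizes",
    "write_gene_sizes",
    "write_contingency_table",
    "read_contingency_table",
    "write_table",
]

PathLike = Union[str, Path]

_GT_CODES = {"0_0": 0, "0_1": 1, "1_1": 2}


def read_sample_groups(path: PathLike, sep: str = ",") -> dict[str, Group]:
    """Side-car sample-group file: two columns, sample id and group."""
    groups: dict[str, Group] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            raise LoadError(f"{path}: empty sample-group file")
        # accept both headered and headerless two-column files
        rows = list(reader)
        if header[0].strip().lower() not in ("sample", "sample_id", "id"):
            rows.insert(0, header)
        for row in rows:
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise LoadError(f"{path}: row {row!r} lacks a group column")
            sid = row[0].strip()
            if sid in groups:
                raise LoadError(f"{path}: duplicate sample id {sid!r}")
            groups[sid] = Group.from_string(row[1])
    return groups


def read_genotype_matrix(
    path: PathLike,
    dialect: str = "matrix_csv",
    groups: Optional[Mapping[str, Group]] = None,
    sep: str = ",",
) -> GenotypeMatrix:
    if groups is None:
        raise ConfigurationError("a sample -> group mapping is required to load a genotype matrix")
    if dialect == "matrix_csv":
        return _read_matrix_csv(path, groups, sep)
    if dialect == "vcf":
        return _read_matrix_vcf(path, groups)
    raise ConfigurationError(f"unknown genotype dialect {dialect!r}; expected 'matrix_csv' or 'vcf'")


def _resolve_group(sample_id: str, groups: Mapping[str, Group], path: PathLike) -> Group:
    try:
        return groups[sample_id]
    except KeyError:
        raise ConfigurationError(f"{path}: sample {sample_id!r} has no group assignment") from None


def _read_matrix_csv(path: PathLike, groups: Mapping[str, Group], sep: str) -> GenotypeMatrix:
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoadError(f"{path}: cannot parse matrix file ({exc})") from exc
    samples = [Sample(str(sid), _resolve_group(str(sid), groups, path)) for sid in frame.columns]
    variants = []
    dosages = np.empty(frame.shape, dtype=np.int8)
    for i, (key_text, row) in enumerate(frame.iterrows()):
        key = VariantKey.parse(str(key_text))
        variants.append(VariantRecord(key=key))
        for j, cell in enumerate(row):
            code = _GT_CODES.get(str(cell).strip())
            if code is None:
                raise LoadError(
                    f"{path}: unknown genotype {cell!r} for variant {key_text} "
                    f"sample {frame.columns[j]}"
                )
            dosages[i, j] = code
    return GenotypeMatrix(variants, samples, dosages)


def _read_matrix_vcf(path: PathLike, groups: Mapping[str, Group]) -> GenotypeMatrix:
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    samples = [Sample(sid, _resolve_group(sid, groups, path)) for sid in sample_ids]
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        alts = rec.alts or ()
        # multiallelic rows are split into one biallelic record per alternate
        for alt_index, alt in enumerate(alts, start=1):
            key = VariantKey(rec.chrom, rec.pos, rec.ref, alt, rsid=rec.id)
            row = np.zeros(len(sample_ids), dtype=np.int8)
            for j, sid in enumerate(sample_ids):
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    raise LoadError(f"{path}: missing genotype call for {key} sample {sid}")
                row[j] = sum(1 for a in gt if a == alt_index)
            variants.append(VariantRecord(key=key))
            rows.append(row)
    vf.close()
    dosages = np.vstack(rows) if rows else np.empty((0, len(sample_ids)), dtype=np.int8)
    return GenotypeMatrix(variants, samples, dosages)


def read_annotation_table(path: PathLike, sep: str = ",") -> pd.DataFrame:
    """Annotation table: columns key, gene, functional_class, exonic_subtype[, rsid]."""
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"key", "gene", "functional_class"}
    missing = required - set(frame.columns)
    if missing:
        raise LoadError(f"{path}: annotation table missing columns {sorted(missing)}")
    if "exonic_subtype" not in frame.columns:
        frame["exonic_subtype"] = ""
    if "rsid" not in frame.columns:
        frame["rsid"] = ""
    return frame.set_index("key")


def attach_annotations(matrix: GenotypeMatrix, annotations: pd.DataFrame) -> GenotypeMatrix:
    """Return a copy of `matrix` with gene / class / subtype / rsid filled in."""
    out = matrix.copy()
    for record in out.variants:
        canon = record.key.canonical
        if canon not in annotations.index:
            continue
        row = annotations.loc[canon]
        record.gene = row["gene"] or None
        record.functional_class = row["functional_class"] or None
        record.exonic_subtype = row["exonic_subtype"] or None
        rsid = row.get("rsid", "") or None
        if rsid:
            record.key = replace(record.key, rsid=rsid)
        # re-run field validation on the mutated record
        record.__post_init__()
    return out


class PopulationFrequencies:
    """Reference-population AltAF lookup; unlisted keys report ABSENT (None).

    Lookup first tries the canonical (chrom:pos:ref:alt) key, then the rsID
    alias, so 1000G-style tables keyed either way resolve.
    """

    def __init__(self, table: Mapping[str, float]) -> None:
        self._table: dict[str, float] = {}
        for key, af in table.items():
            af = float(af)
            if not 0.0 <= af <= 1.0:
                raise LoadError(f"AltAF {af} for {key} outside [0, 1]")
            self._table[str(key)] = af

    def lookup(self, key: Union[VariantKey, str]) -> Optional[float]:
        if isinstance(key, VariantKey):
            hit = self._table.get(key.canonical)
            if hit is None and key.rsid:
                hit = self._table.get(key.rsid)
            return hit
        return self._table.get(str(key))

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, key: Union[VariantKey, str]) -> bool:
        return self.lookup(key) is not None

    def items(self):
        return self._table.items()


def read_population_frequencies(path: PathLike, sep: str = ",") -> PopulationFrequencies:
    frame = pd.read_csv(path, sep=sep, dtype={0: str}, keep_default_na=False)
    if not {"key", "alt_af"} <= set(frame.columns):
        raise LoadError(f"{path}: population-frequency table needs columns 'key' and 'alt_af'")
    table: dict[str, float] = {}
    for _, row in frame.iterrows():
        try:
            af = float(row["alt_af"])
        except ValueError:
            raise LoadError(f"{path}: non-numeric alt_af {row['alt_af']!r} for {row['key']}") from None
        if not 0.0 <= af <= 1.0:
            raise LoadError(f"{path}: alt_af {af} for {row['key']} outside [0, 1]")
        table[str(row["key"])] = af
    return PopulationFrequencies(table)


def read_gene_sizes(path: PathLike, sep: str = ",") -> GeneSizeTable:
    frame = pd.read_csv(path, sep=sep, dtype={0: str})
    if not {"gene", "size_bp"} <= set(frame.columns):
        raise LoadError(f"{path}: gene-size table needs columns 'gene' and 'size_bp'")
    try:
        return GeneSizeTable(dict(zip(frame["gene"], frame["size_bp"])))
    except ValidationError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def write_gene_sizes(sizes: GeneSizeTable, path: PathLike) -> None:
    pd.DataFrame(sizes.items(), columns=["gene", "size_bp"]).to_csv(path, index=False)


def write_contingency_table(table: ContingencyTable, path: PathLike) -> None:
    out = table.data.copy()
    out.index.name = "variant"
    out.to_csv(path, float_format="%.10g")


def read_contingency_table(path: PathLike) -> ContingencyTable:
    frame = pd.read_csv(path, index_col=0)
    missing = [c for c in CONTINGENCY_COLUMNS if c not in frame.columns]
    if missing:
        raise LoadError(f"{path}: contingency table missing columns {missing}")
    return ContingencyTable(frame)


def write_table(obj, path: PathLike) -> None:
    """Dispatch writer: contingency tables, rank tables and cluster assignments."""
    from .hcpc import ClusterAssignment, write_cluster_assignment
    from .rankprod import GeneRankTable, write_gene_rank_table

    if isinstance(obj, ContingencyTable):
        write_contingency_table(obj, path)
    elif isinstance(obj, GeneRankTable):
        write_gene_rank_table(obj, path)
    elif isinstance(obj, ClusterAssignment):
        write_cluster_assignment(obj, path)
    else:
        raise ConfigurationError(f"no writer registered for {type(obj).__name__}")
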