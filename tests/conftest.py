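import numpy as np
import pandas as pd
import pytest

from varrank.adjust import adjust_pipeline
from varrank.datamodel import (
    ContingencyTable,
    GenotypeMatrix,
    Group,
    Sample,
    VariantKey,
    VariantRecord,
)
from varrank.io import attach_annotations
from varrank.synthetic import paperlike_fixture


def make_matrix(dosages, groups=None, alt_afs=None, genes=None):
    """Small GenotypeMatrix from a dosage array (variants x samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_var, n_samp = dosages.shape
    if groups is None:
        half = n_samp // 2
        groups = [Group.SENSITIVE] * half + [Group.RESISTANT] * (n_samp - half)
    samples = [Sample(f"P{j + 1:02d}", g) for j, g in enumerate(groups)]
    variants = []
    for i in range(n_var):
        rec = VariantRecord(
            key=VariantKey("chr1", i + 1, "A", "G"),
            gene=(genes[i] if genes else f"GENE{i + 1}"),
            functional_class="exonic",
            exonic_subtype="non-synonymous",
        )
        if alt_afs is not None:
            rec.alt_af = alt_afs[i]
        variants.append(rec)
    return GenotypeMatrix(variants, samples, dosages)


def make_contingency(rows, keys=None):
    """ContingencyTable from a list of (vaf_s, vaf_r, maf) triples."""
    keys = keys or [f"chr1:{i + 1}:A:G" for i in range(len(rows))]
    return ContingencyTable(
        pd.DataFrame(rows, index=keys, columns=["VAF_sensitive", "VAF_resistant", "MAF_population"])
    )


@pytest.fixture(scope="session")
def paperlike():
    cohort, spec = paperlike_fixture()
    return cohort


@pytest.fixture(scope="session")
def paperlike_adjusted(paperlike):
    matrix = attach_annotations(paperlike.matrix, paperlike.annotations)
    table, report, adjusted, mafs = adjust_pipeline(matrix, paperlike.popfreq)
    return {"table": table, "report": report, "matrix": adjusted, "mafs": mafs}
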