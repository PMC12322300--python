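"""Shared fixtures: hand-built tiny matrices and the standard simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnfprot import (
    GOAnnotationMap,
    GOTerm,
    ProteinQuantMatrix,
    SampleTable,
    fixture_small,
)


def make_matrix(
    quantities: np.ndarray | list,
    protein_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    id_pvalue: list[float] | None = None,
    peptide_counts: np.ndarray | None = None,
) -> ProteinQuantMatrix:
    """Build a ProteinQuantMatrix from a plain array; NaN marks missing."""
    q = np.asarray(quantities, dtype=float)
    n_prot, n_samp = q.shape
    protein_ids = protein_ids or [f"P{i + 1}" for i in range(n_prot)]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(n_samp)]
    pv = pd.Series(id_pvalue or [0.01] * n_prot, index=protein_ids, dtype=float)
    if peptide_counts is None:
        peptide_counts = np.where(np.isnan(q), 0, 3).astype(int)
    pep = pd.DataFrame(peptide_counts, index=protein_ids, columns=sample_ids)
    return ProteinQuantMatrix(
        pd.DataFrame(q, index=protein_ids, columns=sample_ids), pv, pep
    )


def make_design(n_patients: int, lesions_per_patient: list[int]) -> SampleTable:
    """Paired design table with sample ids '<patient>-L<k>-<tissue>'."""
    rows = []
    for pi in range(n_patients):
        pat = f"pt{pi + 1}"
        for li in range(lesions_per_patient[pi]):
            lesion = f"{pat}-L{li + 1}"
            for tissue in ("cNF", "skin"):
                rows.append(
                    {
                        "sample_id": f"{lesion}-{tissue}",
                        "patient_id": pat,
                        "lesion_id": lesion,
                        "tissue": tissue,
                        "growing": "unknown",
                    }
                )
    return SampleTable(pd.DataFrame(rows))


def make_annotations(term_proteins: dict[str, list[str]]) -> GOAnnotationMap:
    return GOAnnotationMap(
        {
            tid: GOTerm(tid, f"term {tid}", "biological_process", frozenset(prots))
            for tid, prots in term_proteins.items()
        }
    )


@pytest.fixture(scope="session")
def study():
    """The deterministic standard study: 4 patients, 15 pairs, 20 terms x 10."""
    return fixture_small()


@pytest.fixture
def paired_design_15():
    """The emulated design: 4 patients with 3, 4, 4, 4 lesion pairs."""
    return make_design(4, [3, 4, 4, 4])
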