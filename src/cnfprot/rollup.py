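"""Assemble per-GO-term observation tables for mixed-model testing.

Only terms associated with more than four distinct proteins in the dataset
are analyzed. A term table holds one row per (member protein, sample) with
a non-missing quantity — below-LOD cells carry their imputed value, while
missing-at-random cells are excluded row-wise. Quantities enter on the
natural-log scale; the exponentiated tissue coefficient is base-invariant,
so the log base only affects internal coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GOAnnotationMap, ProteinQuantMatrix, SampleTable


@dataclass
class TermObservationTable:
    term_id: str
    data: pd.DataFrame  # protein_id, sample_id, patient_id, lesion_id, tissue, log_quantity

    @property
    def n_proteins(self) -> int:
        return int(self.data["protein_id"].nunique())

    @property
    def n_observations(self) -> int:
        return len(self.data)


def eligible_terms(annotations: GOAnnotationMap, min_proteins: int = 5) -> list[str]:
    """Term ids whose dataset-protein set has at least ``min_proteins`` members."""
    return sorted(
        t.term_id for t in annotations if len(t.proteins) >= min_proteins
    )


def build_long_table(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    proteins: list[str] | None = None,
) -> pd.DataFrame:
    """Long (protein, sample) table of non-missing log quantities with design columns."""
    q = matrix.quantities if proteins is None else matrix.quantities.loc[proteins]
    stacked = q.stack(future_stack=True).rename("quantity").reset_index()
    stacked.columns = ["protein_id", "sample_id", "quantity"]
    stacked = stacked[stacked["quantity"].notna()]
    merged = stacked.merge(
        samples.data[["sample_id", "patient_id", "lesion_id", "tissue"]],
        on="sample_id",
        how="left",
    )
    if merged["tissue"].isna().any():
        missing = merged.loc[merged["tissue"].isna(), "sample_id"].unique().tolist()
        raise ValueError(f"samples absent from the design table: {missing}")
    merged["log_quantity"] = np.log(merged["quantity"].to_numpy())
    return merged.drop(columns="quantity").reset_index(drop=True)


def build_term_table(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    annotations: GOAnnotationMap,
    term_id: str,
) -> TermObservationTable:
    """Observation table for one term; errors if the term has no observations."""
    if term_id not in annotations:
        raise KeyError(f"unknown term {term_id!r}")
    members = sorted(annotations[term_id].proteins)
    members = [p for p in members if p in matrix.quantities.index]
    data = build_long_table(matrix, samples, members) if members else pd.DataFrame()
    if len(data) == 0:
        raise ValueError(f"term {term_id!r} has zero observations in the matrix")
    return TermObservationTable(term_id, data)


def export_term_table(table: TermObservationTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
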