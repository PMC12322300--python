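"""Sample-specific GO-term indices and between-process correlations.

The index for a GO term in a sample is the mean, over the term's proteins,
of each protein's quantity divided by that protein's average over *all*
samples (both tissues). The construction is scale-invariant and centered
near 1; for complete data each protein's normalized mean over samples is
exactly 1. Correlations between two process indices are assessed within
one tissue by regressing the log response index on the log predictor index
with a random intercept per patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .io import GOAnnotationMap, ProteinQuantMatrix, SampleTable

#: process groups the published panel correlates (response x predictor)
DEFAULT_Y_TERMS = ["GO:0001525", "GO:0008283", "GO:0043410"]
DEFAULT_X_TERMS = ["GO:0022617", "GO:0044267", "GO:0005975", "GO:0006629"]


@dataclass
class GOIndex:
    term_id: str
    values: pd.Series  # per-sample index; NaN where no term protein observed
    n_proteins_used: pd.Series  # per-sample count of contributing proteins


def compute_term_index(
    matrix: ProteinQuantMatrix,
    annotations: GOAnnotationMap,
    term_id: str,
) -> GOIndex:
    """Per-sample mean of protein quantities normalized to all-sample averages."""
    if term_id not in annotations:
        raise KeyError(f"unknown term {term_id!r}")
    members = [
        p for p in sorted(annotations[term_id].proteins)
        if p in matrix.quantities.index
    ]
    if not members:
        raise ValueError(f"term {term_id!r} has no proteins in the matrix")
    q = matrix.quantities.loc[members]
    protein_mean = q.mean(axis=1, skipna=True)
    normalized = q.div(protein_mean, axis=0)
    values = normalized.mean(axis=0, skipna=True)
    n_used = normalized.notna().sum(axis=0)
    if (n_used == 0).any():
        empty = list(values.index[n_used == 0])
        warnings.warn(
            f"term {term_id}: no observed protein in sample(s) {empty}; index missing"
        )
    return GOIndex(term_id, values, n_used)


def correlate_indices(
    index_y: GOIndex,
    index_x: GOIndex,
    samples: SampleTable,
    tissue: str,
) -> tuple[float, float]:
    """Slope and two-sided P of log(y-index) on log(x-index) within a tissue.

    A random intercept per patient absorbs donor-level shifts; inference is
    a Wald z test on the slope.
    """
    ids = [s for s in samples.tissue_samples(tissue)]
    df = pd.DataFrame(
        {
            "y": np.log(index_y.values.reindex(ids).to_numpy(dtype=float)),
            "x": np.log(index_x.values.reindex(ids).to_numpy(dtype=float)),
            "patient_id": samples.data.set_index("sample_id")
            .loc[ids, "patient_id"]
            .to_numpy(),
        }
    ).dropna()
    if len(df) < 3:
        raise ValueError(
            f"need at least 3 {tissue} samples with defined indices, got {len(df)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        if df["patient_id"].nunique() > 1:
            try:
                model = smf.mixedlm("y ~ x", df, groups="patient_id")
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                if not (np.isfinite(res.bse["x"]) and res.bse["x"] > 0):
                    res = None
            except (np.linalg.LinAlgError, ValueError):
                res = None
        if res is None:
            # degenerate mixed fit (e.g. a perfectly collinear index pair):
            # plain regression still yields the Wald limit
            res = smf.ols("y ~ x", df).fit()
    slope = float(res.params["x"])
    se = float(res.bse["x"])
    if se == 0 or not np.isfinite(se):
        return slope, (0.0 if abs(slope) > 0 else 1.0)
    p = float(2 * stats.norm.sf(abs(slope / se)))
    return slope, p


def correlation_panel(
    matrix: ProteinQuantMatrix,
    annotations: GOAnnotationMap,
    samples: SampleTable,
    y_terms: list[str] | None = None,
    x_terms: list[str] | None = None,
    tissue: str = "cNF",
) -> pd.DataFrame:
    """Full response x predictor grid of (slope, p); plain P values, no correction."""
    y_terms = DEFAULT_Y_TERMS if y_terms is None else y_terms
    x_terms = DEFAULT_X_TERMS if x_terms is None else x_terms
    indices = {
        tid: compute_term_index(matrix, annotations, tid)
        for tid in dict.fromkeys(y_terms + x_terms)
    }
    rows = []
    for yt in y_terms:
        for xt in x_terms:
            slope, p = correlate_indices(indices[yt], indices[xt], samples, tissue)
            rows.append(
                {"y_term": yt, "x_term": xt, "tissue": tissue, "slope": slope, "p": p}
            )
    return pd.DataFrame(rows)
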