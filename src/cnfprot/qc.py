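"""Confidence filtering and informative-missingness imputation.

Two-stage QC: (1) drop low-confidence identifications — a protein is kept
only if its identification P value is < 0.05 (strict) and it was identified
from at least two peptides in at least one sample; (2) classify remaining
missing cells.  A protein quantified in >=80% of the samples of one tissue
type is considered reliably detected there; missing values in excess of 20%
in the *other* tissue are then attributed to expression below the limit of
detection (missing not at random) and imputed with the single minimum
quantity observed anywhere in the dataset.  Proteins detected in <80% of
samples in both tissues are never imputed.  All remaining missing cells are
treated as missing at random and stay missing.

Threshold comparisons use exact rational arithmetic: detection reliability
is ``>= 8/10`` and excess missingness is ``> 2/10``, so boundary cases like
12 detected of 15 (missing fraction exactly 1/5) are decided exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import TISSUES, ProteinQuantMatrix, SampleTable

IMPUTE_LOD = "impute_lod"
LEAVE_MAR = "leave_mar"


@dataclass
class MissingnessClassification:
    """Cell-level missingness labels plus the imputation value.

    ``labels`` is a protein × sample grid holding ``impute_lod`` or
    ``leave_mar`` for missing cells and the empty string for observed ones;
    ``detection_fraction`` is a protein × tissue table of exact detection
    fractions.
    """

    labels: pd.DataFrame
    detection_fraction: pd.DataFrame  # protein x tissue, Fraction-valued
    global_minimum: float
    mode: str = "all"

    def n_labeled(self, label: str) -> int:
        return int((self.labels.to_numpy() == label).sum())


@dataclass
class ImputationReport:
    n_imputed_total: int = 0
    n_imputed_by_tissue: dict = field(default_factory=lambda: {"cNF": 0, "skin": 0})
    n_proteins_touched: int = 0
    n_remaining_missing: int = 0
    n_proteins_with_remaining_missing: int = 0
    per_sample_missing_before: dict = field(default_factory=dict)
    per_sample_missing_after: dict = field(default_factory=dict)
    imputation_value: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_imputed_total": self.n_imputed_total,
            "n_imputed_by_tissue": dict(self.n_imputed_by_tissue),
            "n_proteins_touched": self.n_proteins_touched,
            "n_remaining_missing": self.n_remaining_missing,
            "n_proteins_with_remaining_missing": self.n_proteins_with_remaining_missing,
            "per_sample_missing_before": dict(self.per_sample_missing_before),
            "per_sample_missing_after": dict(self.per_sample_missing_after),
            "imputation_value": self.imputation_value,
        }


# ---------------------------------------------------------------------------
# confidence filter
# ---------------------------------------------------------------------------


def filter_low_confidence(
    matrix: ProteinQuantMatrix, p_max: float = 0.05, min_peptides: int = 2
) -> ProteinQuantMatrix:
    """Keep proteins with id P value < p_max and >= min_peptides peptides somewhere."""
    pv_ok = matrix.id_pvalue < p_max
    pep_ok = matrix.peptide_counts.max(axis=1) >= min_peptides
    keep = matrix.quantities.index[pv_ok & pep_ok]
    if len(keep) == 0:
        raise ValueError("confidence filter removed every protein")
    return matrix.subset_proteins(keep)


class ConfidenceFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`filter_low_confidence`.

    Parameters
    ----------
    p_max : float
        Exclusive upper bound on the identification P value.
    min_peptides : int
        Minimum peptide count required in at least one sample.
    """

    def __init__(self, p_max: float = 0.05, min_peptides: int = 2):
        self.p_max = p_max
        self.min_peptides = min_peptides

    def fit(self, X: ProteinQuantMatrix, y=None) -> "ConfidenceFilter":
        filtered = filter_low_confidence(X, self.p_max, self.min_peptides)
        self.kept_proteins_ = filtered.protein_ids
        self.n_dropped_ = X.n_proteins - filtered.n_proteins
        return self

    def transform(self, X: ProteinQuantMatrix) -> ProteinQuantMatrix:
        return filter_low_confidence(X, self.p_max, self.min_peptides)


# ---------------------------------------------------------------------------
# missingness classification and imputation
# ---------------------------------------------------------------------------


def _tissue_columns(matrix: ProteinQuantMatrix, samples: SampleTable) -> dict[str, list[str]]:
    cols = {t: [s for s in samples.tissue_samples(t) if s in matrix.sample_ids]
            for t in TISSUES}
    for t, cc in cols.items():
        if not cc:
            raise ValueError(f"no {t} samples cover the matrix columns")
    covered = set(cols["cNF"]) | set(cols["skin"])
    uncovered = [s for s in matrix.sample_ids if s not in covered]
    if uncovered:
        raise ValueError(f"samples missing from the design table: {uncovered}")
    return cols


def classify_missingness(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    reliable_fraction: float = 0.8,
    mode: str = "all",
) -> MissingnessClassification:
    """Label every missing cell as below-LOD (to impute) or missing at random.

    For each protein and tissue T: if the *other* tissue detects the protein
    in >= ``reliable_fraction`` of its samples and T's missing fraction
    strictly exceeds ``1 - reliable_fraction``, the missing cells of T are
    attributed to a below-LOD expression level.  ``mode='all'`` labels all
    such cells for imputation; ``mode='excess'`` labels only the count above
    the random-missingness allowance (cells taken in sample order).
    """
    if mode not in ("all", "excess"):
        raise ValueError(f"mode must be 'all' or 'excess', got {mode!r}")
    rel = Fraction(str(reliable_fraction))
    cols = _tissue_columns(matrix, samples)
    q = matrix.quantities
    labels = pd.DataFrame("", index=q.index, columns=q.columns, dtype=object)
    detfrac = pd.DataFrame(index=q.index, columns=list(TISSUES), dtype=object)

    observed = q.notna()
    for protein in q.index:
        det = {
            t: Fraction(int(observed.loc[protein, cols[t]].sum()), len(cols[t]))
            for t in TISSUES
        }
        for t in TISSUES:
            detfrac.loc[protein, t] = det[t]
        for t, other in (("cNF", "skin"), ("skin", "cNF")):
            missing_frac = 1 - det[t]
            if det[other] >= rel and missing_frac > (1 - rel):
                miss_cols = [c for c in cols[t] if not observed.loc[protein, c]]
                if mode == "excess":
                    allowance = int((1 - rel) * len(cols[t]))  # floor
                    n_to_label = len(miss_cols) - allowance
                    miss_cols = miss_cols[:n_to_label]
                for c in miss_cols:
                    labels.loc[protein, c] = IMPUTE_LOD
    # everything still missing and unlabeled is MAR
    mar_mask = q.isna() & (labels == "")
    labels = labels.mask(mar_mask, LEAVE_MAR)

    observed_vals = q.to_numpy()
    finite = observed_vals[np.isfinite(observed_vals)]
    global_min = float(finite.min()) if finite.size else float("nan")
    return MissingnessClassification(labels, detfrac, global_min, mode)


def impute_below_lod(
    matrix: ProteinQuantMatrix, classification: MissingnessClassification
) -> tuple[ProteinQuantMatrix, ImputationReport]:
    """Replace below-LOD cells with the dataset-minimum quantity.

    Observed cells are never modified; missing-at-random cells stay missing.
    """
    q = matrix.quantities
    labels = classification.labels
    if not labels.index.equals(q.index) or not labels.columns.equals(q.columns):
        raise ValueError("classification was not computed on this matrix")

    impute_mask = (labels == IMPUTE_LOD) & q.isna()
    report = ImputationReport(imputation_value=classification.global_minimum)
    report.per_sample_missing_before = {
        s: float(q[s].isna().sum() / q.shape[0]) for s in q.columns
    }

    out = q.where(~impute_mask, classification.global_minimum)
    remaining = out.isna()
    report.n_imputed_total = int(impute_mask.to_numpy().sum())
    # per-tissue attribution needs the sample design; LodMinimumImputer fills
    # it in, standalone callers get zeros
    report.n_imputed_by_tissue = {"cNF": 0, "skin": 0}
    report.n_proteins_touched = int((impute_mask.sum(axis=1) > 0).sum())
    report.n_remaining_missing = int(remaining.to_numpy().sum())
    report.n_proteins_with_remaining_missing = int((remaining.sum(axis=1) > 0).sum())
    report.per_sample_missing_after = {
        s: float(remaining[s].sum() / q.shape[0]) for s in q.columns
    }

    imputed = ProteinQuantMatrix(
        quantities=out,
        id_pvalue=matrix.id_pvalue.copy(),
        peptide_counts=matrix.peptide_counts.copy(),
        sequence_coverage=(
            None if matrix.sequence_coverage is None else matrix.sequence_coverage.copy()
        ),
    )
    return imputed, report


def _count_by_tissue(
    impute_mask: pd.DataFrame, samples: SampleTable
) -> dict[str, int]:
    out = {}
    for t in TISSUES:
        cols = [s for s in samples.tissue_samples(t) if s in impute_mask.columns]
        out[t] = int(impute_mask[cols].to_numpy().sum())
    return out


class LodMinimumImputer(BaseEstimator, TransformerMixin):
    """Classify missingness against the sample design and impute below-LOD cells.

    Parameters
    ----------
    reliable_fraction : float
        Detection fraction at which one tissue is considered reliable (>=).
    mode : {'all', 'excess'}
        Whether all missing cells of a flagged (protein, tissue) are imputed
        or only those beyond the random-missingness allowance.

    Attributes
    ----------
    classification_ : MissingnessClassification
    report_ : ImputationReport
    global_minimum_ : float
    """

    def __init__(self, reliable_fraction: float = 0.8, mode: str = "all"):
        self.reliable_fraction = reliable_fraction
        self.mode = mode

    def fit(self, X: ProteinQuantMatrix, y: SampleTable = None) -> "LodMinimumImputer":
        if y is None:
            raise ValueError("LodMinimumImputer.fit requires the SampleTable as y")
        self.samples_ = y
        self.classification_ = classify_missingness(
            X, y, self.reliable_fraction, self.mode
        )
        self.global_minimum_ = self.classification_.global_minimum
        return self

    def transform(self, X: ProteinQuantMatrix) -> ProteinQuantMatrix:
        imputed, report = impute_below_lod(X, self.classification_)
        impute_mask = (self.classification_.labels == IMPUTE_LOD) & X.quantities.isna()
        report.n_imputed_by_tissue = _count_by_tissue(impute_mask, self.samples_)
        self.report_ = report
        return imputed

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y).transform(X)


def missingness_summary(
    matrix: ProteinQuantMatrix, samples: SampleTable | None = None
) -> dict:
    """Per-sample missing fractions and, with a design table, per-donor coverage.

    Per-donor coverage reports, separately for each tissue, the fraction of
    proteins observed in at least one sample of the donor and in all samples
    of the donor.
    """
    q = matrix.quantities
    out = {
        "per_sample_missing_fraction": {
            s: float(q[s].isna().sum() / q.shape[0]) for s in q.columns
        }
    }
    if samples is not None:
        donor = {}
        for t in TISSUES:
            for pat in samples.patients:
                cols = [
                    s
                    for s in samples.data.loc[
                        (samples.data["patient_id"] == pat)
                        & (samples.data["tissue"] == t),
                        "sample_id",
                    ]
                    if s in q.columns
                ]
                if not cols:
                    continue
                obs = q[cols].notna()
                donor[f"{pat}/{t}"] = {
                    "frac_in_any_sample": float(obs.any(axis=1).mean()),
                    "frac_in_all_samples": float(obs.all(axis=1).mean()),
                }
        out["per_donor_detection"] = donor
    return out


def median_normalize(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Optional generic normalization: equalize per-sample median quantities."""
    q = matrix.quantities
    med = q.median(axis=0, skipna=True)
    target = float(np.nanmedian(q.to_numpy()))
    scaled = q * (target / med)
    return ProteinQuantMatrix(
        scaled,
        matrix.id_pvalue.copy(),
        matrix.peptide_counts.copy(),
        None if matrix.sequence_coverage is None else matrix.sequence_coverage.copy(),
    )
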