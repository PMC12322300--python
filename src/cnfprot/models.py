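"""Linear mixed-effects differential abundance with a convergence fallback.

Tumor/skin contrasts are estimated on the natural-log scale with a fixed
tissue effect (cNF = 1, skin = 0) and random intercepts. GO-term models
include a random intercept per protein plus nested random intercepts per
patient and per excision unit; on non-convergence the model is simplified
by first dropping the patient intercept and then, if necessary, the
excision-unit intercept. Single-protein models use the same cascade minus
the protein intercept (its minimal form is ordinary least squares). Crossed
random intercepts are expressed as variance components over a single
trivial grouping factor in statsmodels' MixedLM, estimated by REML; tests
and confidence intervals are Wald-type with normal critical values.

Ratios are exponentiated coefficients, so 0.41 means a 59% lower level in
the tumor than in the overlying skin. P values are Bonferroni corrected
(multiplied by the family size and capped at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Collection, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .io import EffectEstimate, GOAnnotationMap, ProteinQuantMatrix, SampleTable
from .rollup import TermObservationTable, build_long_table, build_term_table, eligible_terms

GO_STRUCTURES = ("full", "no_patient", "minimal")
PROTEIN_STRUCTURES = ("patient_lesion", "lesion", "none")

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class TissueFit:
    """Tissue fixed-effect on the log scale with Wald inference metadata."""

    coef: float
    se: float
    n_observations: int
    structure: str
    converged: bool

    @property
    def ratio(self) -> float:
        return float(np.exp(self.coef))

    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.coef - _Z975 * self.se)),
            float(np.exp(self.coef + _Z975 * self.se)),
        )

    @property
    def p_value(self) -> float:
        if self.se <= 0:
            return float("nan")
        z = self.coef / self.se
        return float(2 * stats.norm.sf(abs(z)))


def _vc_formula(structure: str, sample_unit: str, data: pd.DataFrame) -> dict[str, str]:
    """Variance components for a structure, skipping factors with <2 levels."""
    unit_col = "lesion_id" if sample_unit == "lesion" else "sample_id"
    wanted: list[tuple[str, str]] = []
    if structure == "full":
        wanted = [("protein", "protein_id"), ("patient", "patient_id"), ("unit", unit_col)]
    elif structure == "no_patient":
        wanted = [("protein", "protein_id"), ("unit", unit_col)]
    elif structure == "minimal":
        wanted = [("protein", "protein_id")]
    elif structure == "patient_lesion":
        wanted = [("patient", "patient_id"), ("unit", unit_col)]
    elif structure == "lesion":
        wanted = [("unit", unit_col)]
    elif structure == "none":
        wanted = []
    else:
        raise ValueError(f"unknown random structure {structure!r}")
    return {
        name: f"0 + C({col})"
        for name, col in wanted
        if data[col].nunique() > 1
    }


def fit_tissue_model(
    table: TermObservationTable | pd.DataFrame,
    structure: str = "full",
    sample_unit: str = "lesion",
) -> TissueFit:
    """Fit one mixed (or plain) regression of log quantity on tissue.

    ``sample_unit`` selects whether the nested within-patient intercept is
    placed on the excision (lesion pair, default) or on the individual
    specimen.
    """
    data = table.data if isinstance(table, TermObservationTable) else table
    data = data.copy()
    tissues = set(data["tissue"])
    if len(tissues) < 2:
        raise ValueError(f"need both tissues, got {sorted(tissues)}")
    if len(data) < 3:
        raise ValueError("fewer observations than model parameters")
    if sample_unit not in ("lesion", "specimen"):
        raise ValueError("sample_unit must be 'lesion' or 'specimen'")
    data["is_cnf"] = (data["tissue"] == "cNF").astype(float)

    vc = _vc_formula(structure, sample_unit, data)
    if not vc:
        res = smf.ols("log_quantity ~ is_cnf", data).fit()
        return TissueFit(
            coef=float(res.params["is_cnf"]),
            se=float(res.bse["is_cnf"]),
            n_observations=len(data),
            structure=structure,
            converged=True,
        )

    data["_one_group"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                "log_quantity ~ is_cnf",
                data,
                groups="_one_group",
                vc_formula=vc,
                re_formula="0",
            )
            res = model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=300)
        except (np.linalg.LinAlgError, ValueError):
            return TissueFit(np.nan, np.nan, len(data), structure, converged=False)
    coef = float(res.params["is_cnf"])
    se = float(res.bse["is_cnf"])
    # a boundary (zero-variance, "singular") fit counts as converged; only an
    # optimizer failure leaving non-finite estimates or SEs triggers fallback
    ok = np.isfinite(coef) and np.isfinite(se) and se > 0
    return TissueFit(coef, se, len(data), structure, converged=ok)


def fit_with_fallback(
    table: TermObservationTable | pd.DataFrame,
    structures: Sequence[str],
    sample_unit: str = "lesion",
    force_fail: Collection[str] = (),
) -> TissueFit:
    """Try each random structure in order until one converges.

    ``force_fail`` is an injectable failure hook naming structures to treat
    as non-converged, used to exercise the cascade deterministically.
    """
    last: TissueFit | None = None
    for structure in structures:
        fit = fit_tissue_model(table, structure, sample_unit)
        if structure in force_fail:
            fit = TissueFit(fit.coef, fit.se, fit.n_observations, structure, False)
        last = fit
        if fit.converged:
            return fit
    raise RuntimeError(
        f"no model structure converged (tried {list(structures)}); last: {last}"
    )


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """min(1, p * m) for each p, order preserved."""
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return [min(1.0, float(p) * m) for p in p_values]


def _to_estimate(
    target_id: str, fit: TissueFit, n_proteins: int, family_size: int
) -> EffectEstimate:
    lo, hi = fit.ci()
    p = fit.p_value
    return EffectEstimate(
        target_id=target_id,
        ratio=fit.ratio,
        ci_low=lo,
        ci_high=hi,
        p_plain=p,
        p_corrected=bonferroni_adjust([p], family_size)[0],
        n_proteins=n_proteins,
        n_observations=fit.n_observations,
        model_structure_used=fit.structure,
    )


def test_go_term(
    table: TermObservationTable,
    correction_family_size: int = 1,
    sample_unit: str = "lesion",
    force_fail: Collection[str] = (),
) -> EffectEstimate:
    """Mixed-model tissue contrast for one GO term, with Bonferroni correction."""
    fit = fit_with_fallback(table, GO_STRUCTURES, sample_unit, force_fail)
    return _to_estimate(table.term_id, fit, table.n_proteins, correction_family_size)


def test_protein(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    protein_id: str,
    correction_family_size: int = 1,
    sample_unit: str = "lesion",
    force_fail: Collection[str] = (),
) -> EffectEstimate:
    """Single-protein tissue contrast (no protein random intercept)."""
    if protein_id not in matrix.quantities.index:
        raise KeyError(f"protein {protein_id!r} absent from matrix")
    data = build_long_table(matrix, samples, [protein_id])
    if len(data) == 0:
        raise ValueError(f"protein {protein_id!r} has no observations")
    fit = fit_with_fallback(data, PROTEIN_STRUCTURES, sample_unit, force_fail)
    return _to_estimate(protein_id, fit, 1, correction_family_size)


def go_differential_abundance(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    annotations: GOAnnotationMap,
    min_proteins: int = 5,
    family_size: int | None = None,
    sample_unit: str = "lesion",
    term_ids: Sequence[str] | None = None,
) -> list[EffectEstimate]:
    """Test every eligible GO term; the default Bonferroni family is the
    number of terms actually tested in the run."""
    terms = list(term_ids) if term_ids is not None else eligible_terms(
        annotations, min_proteins
    )
    m = family_size if family_size is not None else max(1, len(terms))
    out = []
    for tid in terms:
        table = build_term_table(matrix, samples, annotations, tid)
        out.append(test_go_term(table, m, sample_unit))
    return out


def protein_differential_abundance(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    protein_ids: Sequence[str],
    family_size: int | None = None,
    sample_unit: str = "lesion",
) -> list[EffectEstimate]:
    m = family_size if family_size is not None else max(1, len(protein_ids))
    return [
        test_protein(matrix, samples, p, m, sample_unit) for p in protein_ids
    ]


# ---------------------------------------------------------------------------
# sensitivity subsets
# ---------------------------------------------------------------------------


def select_subset(samples: SampleTable, subset: str | Callable) -> SampleTable:
    """Restrict the design to a lesion subset, keeping matched pairs intact.

    ``subset`` is ``"all"``, ``"growing"`` (lesions reported as growing),
    ``"patient:<id>"``, or a predicate over sample-table rows; a lesion is
    kept when all of its rows satisfy the predicate.
    """
    if subset == "all":
        return samples
    if subset == "growing":
        pred = lambda row: row["growing"] == "yes"  # noqa: E731
    elif isinstance(subset, str) and subset.startswith("patient:"):
        pid = subset.split(":", 1)[1]
        pred = lambda row: row["patient_id"] == pid  # noqa: E731
    elif callable(subset):
        pred = subset
    else:
        raise ValueError(f"unrecognized subset {subset!r}")
    lesions = samples.lesions_where(pred)
    keep = samples.data[samples.data["lesion_id"].isin(lesions)]
    sub = SampleTable(keep.copy())
    for t in ("cNF", "skin"):
        if not sub.tissue_samples(t):
            raise ValueError(f"subset {subset!r} removes every {t} sample")
    return sub


def run_sensitivity(
    matrix: ProteinQuantMatrix,
    samples: SampleTable,
    subset: str | Callable,
    analysis: Callable[[ProteinQuantMatrix, SampleTable], list[EffectEstimate]],
) -> list[EffectEstimate]:
    """Re-run an analysis on a lesion subset (matched skin samples retained)."""
    sub = select_subset(samples, subset)
    sub_matrix = matrix.subset_samples(sub.sample_ids)
    return analysis(sub_matrix, sub)
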