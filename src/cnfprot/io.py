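"""Tabular input/output and shared domain containers.

The pipeline consumes three linked tables: a protein-by-sample quantity
matrix with identification metadata, a sample design table describing the
matched tumor/skin pairs, and a GO annotation map restricted to the
proteins actually present in the matrix. Quantities are normalized DIA
intensities; missing cells are encoded as empty TSV fields (never 0 —
zero is not a valid intensity) and held as NaN in memory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("cnfprot")

TISSUES = ("cNF", "skin")
GROWING_LEVELS = ("yes", "no", "unknown")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ProteinQuantMatrix:
    """Protein × sample quantity grid with identification metadata.

    Attributes
    ----------
    quantities : DataFrame, proteins × samples
        Positive normalized intensities; NaN marks a missing cell.
    id_pvalue : Series indexed by protein
        Identification P value in [0, 1].
    peptide_counts : DataFrame, proteins × samples
        Non-negative peptide counts supporting each quantification.
    sequence_coverage : Series or None
        Optional per-protein sequence-coverage fraction (descriptive only).
    """

    quantities: pd.DataFrame
    id_pvalue: pd.Series
    peptide_counts: pd.DataFrame
    sequence_coverage: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        q = self.quantities
        if q.index.has_duplicates:
            dupes = q.index[q.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate protein identifiers: {dupes}")
        if q.columns.has_duplicates:
            dupes = q.columns[q.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample identifiers: {dupes}")
        bad = (q <= 0) & q.notna()
        if bad.to_numpy().any():
            pi, si = np.argwhere(bad.to_numpy())[0]
            raise DataValidationError(
                "non-positive quantity at cell "
                f"(protein={q.index[pi]!r}, sample={q.columns[si]!r})"
            )
        if self.peptide_counts.shape != q.shape:
            raise DataValidationError(
                f"peptide_counts shape {self.peptide_counts.shape} "
                f"!= quantities shape {q.shape}"
            )
        if not self.peptide_counts.index.equals(q.index) or not (
            self.peptide_counts.columns.equals(q.columns)
        ):
            raise DataValidationError("peptide_counts axes differ from quantities")
        if not self.id_pvalue.index.equals(q.index):
            raise DataValidationError("id_pvalue index differs from protein index")
        pv = self.id_pvalue.to_numpy(dtype=float)
        if np.any((pv < 0) | (pv > 1)):
            raise DataValidationError("id_pvalue outside [0, 1]")
        if (self.peptide_counts.to_numpy() < 0).any():
            raise DataValidationError("negative peptide count")

    # -- conveniences -------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.quantities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.quantities.columns)

    @property
    def n_proteins(self) -> int:
        return self.quantities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.quantities.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean grid, True where the quantity is missing."""
        return self.quantities.isna()

    def n_missing(self) -> int:
        return int(self.quantities.isna().to_numpy().sum())

    def subset_proteins(self, proteins: Iterable[str]) -> "ProteinQuantMatrix":
        keep = [p for p in self.protein_ids if p in set(proteins)]
        return ProteinQuantMatrix(
            quantities=self.quantities.loc[keep].copy(),
            id_pvalue=self.id_pvalue.loc[keep].copy(),
            peptide_counts=self.peptide_counts.loc[keep].copy(),
            sequence_coverage=(
                None
                if self.sequence_coverage is None
                else self.sequence_coverage.loc[keep].copy()
            ),
        )

    def subset_samples(self, samples: Iterable[str]) -> "ProteinQuantMatrix":
        keep = [s for s in self.sample_ids if s in set(samples)]
        return ProteinQuantMatrix(
            quantities=self.quantities[keep].copy(),
            id_pvalue=self.id_pvalue.copy(),
            peptide_counts=self.peptide_counts[keep].copy(),
            sequence_coverage=(
                None
                if self.sequence_coverage is None
                else self.sequence_coverage.copy()
            ),
        )

    def copy(self) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(
            quantities=self.quantities.copy(),
            id_pvalue=self.id_pvalue.copy(),
            peptide_counts=self.peptide_counts.copy(),
            sequence_coverage=(
                None if self.sequence_coverage is None else self.sequence_coverage.copy()
            ),
        )

    def equals(self, other: "ProteinQuantMatrix") -> bool:
        same_cov = (
            (self.sequence_coverage is None) == (other.sequence_coverage is None)
        ) and (
            self.sequence_coverage is None
            or self.sequence_coverage.equals(other.sequence_coverage)
        )
        return (
            self.quantities.equals(other.quantities)
            and self.id_pvalue.equals(other.id_pvalue)
            and self.peptide_counts.equals(other.peptide_counts)
            and same_cov
        )


@dataclass
class SampleTable:
    """Per-sample design metadata for the matched tumor/skin pairing.

    Each lesion_id names one excision event that yielded a cNF sample and
    its matched overlying-skin sample; lesions are nested within patients.
    """

    data: pd.DataFrame  # columns: sample_id, patient_id, lesion_id, tissue, growing

    def __post_init__(self) -> None:
        required = ["sample_id", "patient_id", "lesion_id", "tissue", "growing"]
        df = self.data
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise DataValidationError(f"sample table missing columns: {missing_cols}")
        df = df[required].astype(str).reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            raise DataValidationError("duplicate sample_id in sample table")
        bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise DataValidationError(f"unknown tissue label(s): {bad_tissue}")
        bad_grow = sorted(set(df["growing"]) - set(GROWING_LEVELS))
        if bad_grow:
            raise DataValidationError(f"unknown growing label(s): {bad_grow}")
        for (lesion, tissue), grp in df.groupby(["lesion_id", "tissue"]):
            if len(grp) > 1:
                raise DataValidationError(
                    f"lesion {lesion!r} has {len(grp)} {tissue} samples (max 1)"
                )
        n_pat = df.groupby("lesion_id")["patient_id"].nunique()
        if (n_pat > 1).any():
            bad = n_pat[n_pat > 1].index.tolist()
            raise DataValidationError(f"lesion(s) mapped to multiple patients: {bad}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def patients(self) -> list[str]:
        return sorted(self.data["patient_id"].unique())

    def tissue_samples(self, tissue: str) -> list[str]:
        if tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {tissue!r}")
        return list(self.data.loc[self.data["tissue"] == tissue, "sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        keep = set(sample_ids)
        return SampleTable(self.data[self.data["sample_id"].isin(keep)].copy())

    def lesions_where(self, predicate) -> list[str]:
        """Lesion ids whose rows all satisfy ``predicate(row)``."""
        ok = []
        for lesion, grp in self.data.groupby("lesion_id"):
            if all(predicate(row) for _, row in grp.iterrows()):
                ok.append(lesion)
        return sorted(ok)


@dataclass(frozen=True)
class GOTerm:
    term_id: str
    name: str
    namespace: str
    proteins: frozenset[str]


@dataclass
class GOAnnotationMap:
    """GO term → set of protein accessions present in the dataset."""

    terms: dict[str, GOTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, term in self.terms.items():
            if tid != term.term_id:
                raise DataValidationError(f"term key {tid!r} != term_id {term.term_id!r}")

    def restricted_to(self, proteins: Iterable[str]) -> "GOAnnotationMap":
        keep = set(proteins)
        out: dict[str, GOTerm] = {}
        for tid, term in self.terms.items():
            inter = frozenset(term.proteins & keep)
            if inter:
                out[tid] = GOTerm(tid, term.name, term.namespace, inter)
        return GOAnnotationMap(out)

    def __getitem__(self, term_id: str) -> GOTerm:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())


@dataclass
class EffectEstimate:
    """Exponentiated tissue effect (cNF/skin ratio) with Wald CI and P values."""

    target_id: str
    ratio: float
    ci_low: float
    ci_high: float
    p_plain: float
    p_corrected: float
    n_proteins: int
    n_observations: int
    model_structure_used: str  # full | no_patient | minimal (GO) / patient_lesion | lesion | none

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ratio <= self.ci_high):
            raise DataValidationError(
                f"{self.target_id}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket ratio {self.ratio}"
            )
        if self.p_corrected < self.p_plain - 1e-12 or self.p_corrected > 1:
            raise DataValidationError(
                f"{self.target_id}: corrected P {self.p_corrected} inconsistent "
                f"with plain P {self.p_plain}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_quant_matrix(
    path,
    layout: str = "wide",
    peptide_path=None,
) -> ProteinQuantMatrix:
    """Read a protein-quantity matrix from TSV.

    ``wide``: one row per protein with columns ``protein_id``, ``id_pvalue``,
    optionally ``sequence_coverage``, then one column per sample; a companion
    peptide-count table (same sample columns) is read from ``peptide_path``.
    ``long``: one row per (protein, sample) with columns ``protein_id``,
    ``sample_id``, ``quantity``, ``peptide_count``, ``id_pvalue``; a missing
    cell is an absent row or an empty quantity field.
    """
    if layout == "wide":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        if df["protein_id"].duplicated().any():
            raise DataValidationError(f"duplicate protein_id in {path}")
        meta_cols = ["protein_id", "id_pvalue"]
        cov = None
        if "sequence_coverage" in df.columns:
            meta_cols.append("sequence_coverage")
            cov = df.set_index("protein_id")["sequence_coverage"].astype(float)
        sample_cols = [c for c in df.columns if c not in meta_cols]
        if len(sample_cols) != len(set(sample_cols)):
            raise DataValidationError(f"duplicate sample columns in {path}")
        q = df.set_index("protein_id")[sample_cols].astype(float)
        pv = df.set_index("protein_id")["id_pvalue"].astype(float)
        if peptide_path is None:
            raise ValueError("wide layout requires a companion peptide-count table")
        pep = pd.read_csv(peptide_path, sep="\t", dtype={"protein_id": str})
        pep = pep.set_index("protein_id")[sample_cols].fillna(0).astype(int)
        pep = pep.reindex(index=q.index, columns=q.columns, fill_value=0)
        return ProteinQuantMatrix(q, pv, pep, cov)

    if layout == "long":
        df = pd.read_csv(
            path, sep="\t", dtype={"protein_id": str, "sample_id": str}
        )
        if df.duplicated(["protein_id", "sample_id"]).any():
            raise DataValidationError(f"duplicate (protein, sample) rows in {path}")
        q = df.pivot(index="protein_id", columns="sample_id", values="quantity")
        pep = (
            df.pivot(index="protein_id", columns="sample_id", values="peptide_count")
            .fillna(0)
            .astype(int)
        )
        pv = df.groupby("protein_id")["id_pvalue"].first().reindex(q.index)
        q.index.name = None
        q.columns.name = None
        pep.index.name = None
        pep.columns.name = None
        pv.index.name = None
        pv.name = None
        return ProteinQuantMatrix(q, pv.astype(float), pep)

    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def write_quant_matrix(matrix: ProteinQuantMatrix, path, layout: str = "wide",
                       peptide_path=None) -> None:
    """Write a matrix back to TSV; empty fields encode missing cells."""
    if layout == "wide":
        out = matrix.quantities.copy()
        out.insert(0, "id_pvalue", matrix.id_pvalue)
        if matrix.sequence_coverage is not None:
            out.insert(1, "sequence_coverage", matrix.sequence_coverage)
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="")
        if peptide_path is not None:
            pep = matrix.peptide_counts.copy()
            pep.index.name = "protein_id"
            pep.to_csv(peptide_path, sep="\t")
    elif layout == "long":
        q = matrix.quantities.stack(future_stack=True)
        pep = matrix.peptide_counts.stack(future_stack=True)
        df = pd.DataFrame(
            {
                "protein_id": q.index.get_level_values(0),
                "sample_id": q.index.get_level_values(1),
                "quantity": q.to_numpy(),
                "peptide_count": pep.to_numpy(),
            }
        )
        df = df[df["quantity"].notna()]  # absent row == missing cell
        df["id_pvalue"] = matrix.id_pvalue.reindex(df["protein_id"]).to_numpy()
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_sample_metadata(path) -> SampleTable:
    """Read the sample design TSV; a missing ``growing`` column defaults to unknown."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "growing" not in df.columns:
        df["growing"] = "unknown"
    return SampleTable(df)


def write_sample_metadata(table: SampleTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


_GAF_COLUMNS = 17


def read_go_annotations(
    path,
    format: str = "tsv",
    matrix: ProteinQuantMatrix | None = None,
) -> GOAnnotationMap:
    """Read GO annotations and restrict them to the matrix proteins.

    ``gaf``: GAF 2.2 — 17 tab-separated columns, '!' comment lines; the DB
    object ID (column 2) is the join key and rows whose qualifier contains
    NOT are excluded. ``tsv``: two or more columns with a header line
    (protein_id, term_id[, term_name, namespace]).
    """
    terms: dict[str, dict] = {}

    def add(term_id, protein, name="", namespace=""):
        rec = terms.setdefault(
            term_id, {"name": name, "namespace": namespace, "proteins": set()}
        )
        if name and not rec["name"]:
            rec["name"] = name
        if namespace and not rec["namespace"]:
            rec["namespace"] = namespace
        rec["proteins"].add(protein)

    if format == "gaf":
        n_bad = 0
        aspect_map = {
            "P": "biological_process",
            "F": "molecular_function",
            "C": "cellular_component",
        }
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("!"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < _GAF_COLUMNS:
                    n_bad += 1
                    continue
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                protein = fields[1]
                go_id = fields[4]
                aspect = aspect_map.get(fields[8], fields[8])
                if not protein or not go_id.startswith("GO:"):
                    n_bad += 1
                    continue
                add(go_id, protein, namespace=aspect)
        if n_bad:
            msg = f"skipped {n_bad} malformed GAF line(s) in {path}"
            logger.warning(msg)
            warnings.warn(msg)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns)
        if len(cols) < 2:
            raise DataValidationError("annotation TSV needs protein and term columns")
        for _, row in df.iterrows():
            add(
                row[cols[1]],
                row[cols[0]],
                name=row[cols[2]] if len(cols) > 2 and pd.notna(row[cols[2]]) else "",
                namespace=(
                    row[cols[3]] if len(cols) > 3 and pd.notna(row[cols[3]]) else ""
                ),
            )
    else:
        raise ValueError(f"format must be 'gaf' or 'tsv', got {format!r}")

    amap = GOAnnotationMap(
        {
            tid: GOTerm(tid, rec["name"], rec["namespace"], frozenset(rec["proteins"]))
            for tid, rec in terms.items()
        }
    )
    if matrix is not None:
        amap = amap.restricted_to(matrix.protein_ids)
        if len(amap) == 0:
            raise DataValidationError(
                "no annotated protein overlaps the quantity matrix"
            )
    return amap


def write_go_annotations(annotations: GOAnnotationMap, path) -> None:
    rows = [
        (p, t.term_id, t.name, t.namespace)
        for t in annotations
        for p in sorted(t.proteins)
    ]
    pd.DataFrame(rows, columns=["protein_id", "term_id", "term_name", "namespace"]).to_csv(
        path, sep="\t", index=False
    )


def format_ratio_ci(ratio: float, ci_low: float, ci_high: float) -> str:
    """Render "0.41 (0.32 to 0.52)" in the published table style.

    Two decimals below 10, one decimal up to 100, integers above — the
    precision the source tables print (e.g. 0.41, 1.13, 19.4, 356, 6543).
    """

    def fmt(x: float) -> str:
        if not np.isfinite(x):
            return str(x)
        if abs(x) < 10:
            return f"{x:.2f}"
        if abs(x) < 100:
            return f"{x:.1f}"
        return f"{x:.0f}"

    return f"{fmt(ratio)} ({fmt(ci_low)} to {fmt(ci_high)})"


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    return f"{min(p, 1.0):.3f}"


def write_results_table(estimates: list[EffectEstimate], path) -> None:
    """Write effect estimates as a TSV mirroring the published table layout."""
    if not estimates:
        warnings.warn("no estimates to write; skipping output")
        return
    rows = []
    for e in estimates:
        rows.append(
            {
                "target": e.target_id,
                "n_proteins": e.n_proteins,
                "n_observations": e.n_observations,
                "ratio": e.ratio,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "estimate_95ci": format_ratio_ci(e.ratio, e.ci_low, e.ci_high),
                "p_plain": _fmt_p(e.p_plain),
                "p_corrected": _fmt_p(e.p_corrected),
                "model_structure_used": e.model_structure_used,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
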