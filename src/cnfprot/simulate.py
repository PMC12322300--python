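"""Synthetic paired tumor/skin proteomics datasets with ground truth.

The generator mirrors the statistical structure the downstream analysis
assumes: for protein p (annotated to GO-like group g) in sample s,

    log q_ps = mu_p + beta_g * 1[tissue(s) = cNF] + a_patient(s) + b_lesion(s) + eps_ps

with mu_p = m_g + delta_p, m_g ~ N(baseline_mean, baseline_sd^2) a group-level
mean and delta_p ~ N(0, sd_protein^2) the within-group protein intercept.
Realized log quantities below the limit of detection (lod) are censored
(missing not at random); surviving cells are dropped completely at random
with probability mar_rate. Quantities are emitted on the natural scale
(exp of the log model), already normalized — no per-sample loading factors
unless ``sample_scale_sd`` is set to exercise optional median normalization.

A single RNG stream seeded from the config is consumed in a fixed draw
order (group effects -> protein intercepts -> patient -> lesion effects ->
residuals -> MAR mask -> identification metadata), so equal configs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GOAnnotationMap,
    GOTerm,
    ProteinQuantMatrix,
    SampleTable,
)

#: seed of the committed deterministic test fixture
FIXTURE_SEED = 20210702

OBSERVED = "observed"
CENSORED_LOD = "censored_lod"
DROPOUT_MAR = "dropout_mar"


@dataclass
class SimulationConfig:
    """Study-design and variance parameters for :func:`simulate_study`.

    Defaults reproduce the study design being emulated: 4 patients
    contributing 3, 4, 4 and 4 matched cNF/skin lesion pairs (15 pairs, 30
    samples), proteins grouped into GO-like terms, log-scale tissue effects
    spanning the reported fold-change range, and an absolute-intensity
    detection limit producing informative missingness on top of a small
    completely-at-random dropout.
    """

    n_patients: int = 4
    lesions_per_patient: list[int] = field(default_factory=lambda: [3, 4, 4, 4])
    n_terms: int = 20
    proteins_per_term: int = 10
    n_background_proteins: int = 50
    #: per-term log-scale cNF effect; None -> geometric grid over 0.4x..2.1x
    term_log_ratio: list[float] | None = None
    protein_baseline_mean: float = 18.0  # ln-intensity units
    protein_baseline_sd: float = 1.5  # between-term spread
    sd_protein: float = 0.5  # within-term protein intercept SD
    sd_patient: float = 0.15
    sd_lesion: float = 0.2
    sd_residual: float = 0.35
    lod: float = 13.9  # ln-intensity censoring threshold
    mar_rate: float = 0.02
    sample_scale_sd: float = 0.0  # >0 adds per-sample loading factors
    n_contaminants: int = 0  # extra proteins that fail the confidence filter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_terms <= 0 or self.proteins_per_term <= 0:
            raise ValueError("dimensions must be positive")
        if len(self.lesions_per_patient) != self.n_patients:
            raise ValueError("lesions_per_patient length must equal n_patients")
        if any(k <= 0 for k in self.lesions_per_patient):
            raise ValueError("each patient needs at least one lesion pair")
        if self.n_background_proteins < 0 or self.n_contaminants < 0:
            raise ValueError("protein counts must be non-negative")
        for name in ("protein_baseline_sd", "sd_protein", "sd_patient",
                     "sd_lesion", "sd_residual", "sample_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.mar_rate <= 1:
            raise ValueError("mar_rate must lie in [0, 1]")

    def resolved_term_log_ratios(self) -> np.ndarray:
        if self.term_log_ratio is not None:
            arr = np.asarray(self.term_log_ratio, dtype=float)
            if arr.shape != (self.n_terms,):
                raise ValueError("term_log_ratio length must equal n_terms")
            return arr
        # span the reported effect range 0.4x .. 2.1x
        return np.log(np.geomspace(0.4, 2.1, self.n_terms))

    def marginal_log_sd(self) -> float:
        """SD of the marginal log-quantity under the null (beta = 0)."""
        return float(
            np.sqrt(
                self.protein_baseline_sd**2
                + self.sd_protein**2
                + self.sd_patient**2
                + self.sd_lesion**2
                + self.sd_residual**2
            )
        )


@dataclass
class GroundTruth:
    """Simulation truth for recovery tests: effects, draws, missingness causes."""

    config: SimulationConfig
    term_true_ratio: dict[str, float]
    protein_term: dict[str, str | None]
    protein_intercepts: pd.Series
    patient_effects: dict[str, float]
    lesion_effects: dict[str, float]
    missingness_cause: pd.DataFrame  # protein x sample, values in {observed,...}

    def cause_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.missingness_cause.to_numpy(), return_counts=True)
        out = {OBSERVED: 0, CENSORED_LOD: 0, DROPOUT_MAR: 0}
        out.update(dict(zip(vals.tolist(), counts.tolist())))
        return out

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "term_true_ratio": self.term_true_ratio,
            "patient_effects": self.patient_effects,
            "lesion_effects": self.lesion_effects,
            "missingness_counts": self.cause_counts(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _term_id(g: int) -> str:
    return f"GO:SIM{g:04d}"


def simulate_study(
    config: SimulationConfig,
) -> tuple[ProteinQuantMatrix, SampleTable, GOAnnotationMap, GroundTruth]:
    """Draw one paired-design study from the generative model.

    Returns the quantity matrix (with identification metadata constructed so
    every non-contaminant protein passes the default confidence filter), the
    sample design table, the GO annotation map restricted to the matrix, and
    the ground truth needed for recovery tests.
    """
    rng = np.random.default_rng(config.seed)

    # design ---------------------------------------------------------------
    patients = [f"patient{i + 1}" for i in range(config.n_patients)]
    # growth status mirrors the emulated study: the two patients with the
    # most lesions carry the presumed-growing tumors
    order = np.argsort(config.lesions_per_patient)[::-1]
    growing_patients = {patients[i] for i in order[:2]}
    sample_rows = []
    lesion_ids = []
    lesion_patient_idx = []
    for pi, (pat, n_lesions) in enumerate(zip(patients, config.lesions_per_patient)):
        for li in range(n_lesions):
            lesion = f"{pat}-L{li + 1}"
            lesion_ids.append(lesion)
            lesion_patient_idx.append(pi)
            grow = "yes" if pat in growing_patients else "no"
            for tissue in ("cNF", "skin"):
                sample_rows.append(
                    {
                        "sample_id": f"{lesion}-{tissue}",
                        "patient_id": pat,
                        "lesion_id": lesion,
                        "tissue": tissue,
                        "growing": grow,
                    }
                )
    samples = SampleTable(pd.DataFrame(sample_rows))
    sample_ids = samples.sample_ids
    n_samples = len(sample_ids)
    tissue_is_cnf = np.array(
        [row == "cNF" for row in samples.data["tissue"]], dtype=float
    )
    sample_lesion_idx = np.array(
        [lesion_ids.index(l) for l in samples.data["lesion_id"]]
    )
    sample_patient_idx = np.array([lesion_patient_idx[i] for i in sample_lesion_idx])

    # proteins and annotation groups --------------------------------------
    n_grouped = config.n_terms * config.proteins_per_term
    n_total = n_grouped + config.n_background_proteins + config.n_contaminants
    protein_ids = [f"PROT{i + 1:05d}" for i in range(n_total)]
    protein_term: dict[str, str | None] = {}
    term_members: dict[str, list[str]] = {}
    for g in range(config.n_terms):
        tid = _term_id(g)
        members = protein_ids[
            g * config.proteins_per_term : (g + 1) * config.proteins_per_term
        ]
        term_members[tid] = members
        for p in members:
            protein_term[p] = tid
    for p in protein_ids[n_grouped:]:
        protein_term[p] = None

    # fixed draw order: term effects -> term means -> protein intercepts ->
    # patient -> lesion -> residuals -> MAR mask -> identification metadata
    log_ratios = config.resolved_term_log_ratios()
    beta_by_protein = np.zeros(n_total)
    for g in range(config.n_terms):
        beta_by_protein[
            g * config.proteins_per_term : (g + 1) * config.proteins_per_term
        ] = log_ratios[g]

    term_means = rng.normal(
        config.protein_baseline_mean, config.protein_baseline_sd, config.n_terms
    )
    mu = np.empty(n_total)
    for g in range(config.n_terms):
        sl = slice(g * config.proteins_per_term, (g + 1) * config.proteins_per_term)
        mu[sl] = term_means[g]
    n_free = n_total - n_grouped
    mu[n_grouped:] = rng.normal(
        config.protein_baseline_mean, config.protein_baseline_sd, n_free
    )
    delta = rng.normal(0.0, config.sd_protein, n_total)
    mu = mu + delta

    a = rng.normal(0.0, config.sd_patient, config.n_patients)
    b = rng.normal(0.0, config.sd_lesion, len(lesion_ids))
    eps = rng.normal(0.0, config.sd_residual, size=(n_total, n_samples))

    y = (
        mu[:, None]
        + beta_by_protein[:, None] * tissue_is_cnf[None, :]
        + a[sample_patient_idx][None, :]
        + b[sample_lesion_idx][None, :]
        + eps
    )

    censored = y < config.lod
    mar_draw = rng.random(size=y.shape) < config.mar_rate
    mar = mar_draw & ~censored

    cause = np.full(y.shape, OBSERVED, dtype=object)
    cause[censored] = CENSORED_LOD
    cause[mar] = DROPOUT_MAR

    quantities = np.exp(y)
    if config.sample_scale_sd > 0:
        scale = np.exp(rng.normal(0.0, config.sample_scale_sd, n_samples))
        quantities = quantities * scale[None, :]
    quantities = np.where(cause == OBSERVED, quantities, np.nan)

    # identification metadata ----------------------------------------------
    id_pvalue = rng.uniform(0.001, 0.045, n_total)
    pep = 1 + rng.poisson(4.0, size=y.shape)
    pep = np.where(cause == OBSERVED, pep, 0)
    observed_any = (cause == OBSERVED).any(axis=1)
    for i in np.nonzero(observed_any)[0]:
        row = pep[i]
        if row.max() < 2:
            row[np.argmax(row > 0)] = 2
    # contaminants deliberately fail the confidence filter (alternating mode)
    for k in range(config.n_contaminants):
        i = n_grouped + config.n_background_proteins + k
        if k % 2 == 0:
            id_pvalue[i] = rng.uniform(0.05, 0.5)
        else:
            pep[i] = np.minimum(pep[i], 1)

    qdf = pd.DataFrame(quantities, index=protein_ids, columns=sample_ids)
    pepdf = pd.DataFrame(pep, index=protein_ids, columns=sample_ids)
    pvs = pd.Series(id_pvalue, index=protein_ids)
    matrix = ProteinQuantMatrix(qdf, pvs, pepdf)

    annotations = GOAnnotationMap(
        {
            tid: GOTerm(tid, f"simulated process {tid[-4:]}", "biological_process",
                        frozenset(members))
            for tid, members in term_members.items()
        }
    ).restricted_to(protein_ids)

    truth = GroundTruth(
        config=config,
        term_true_ratio={
            _term_id(g): float(np.exp(log_ratios[g])) for g in range(config.n_terms)
        },
        protein_term=protein_term,
        protein_intercepts=pd.Series(mu, index=protein_ids),
        patient_effects=dict(zip(patients, a.tolist())),
        lesion_effects=dict(zip(lesion_ids, b.tolist())),
        missingness_cause=pd.DataFrame(cause, index=protein_ids, columns=sample_ids),
    )
    return matrix, samples, annotations, truth


def fixture_small() -> tuple[ProteinQuantMatrix, SampleTable, GOAnnotationMap, GroundTruth]:
    """Deterministic small dataset: 4 patients, 15 pairs, 20 terms x 10 proteins."""
    return simulate_study(SimulationConfig(seed=FIXTURE_SEED))
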