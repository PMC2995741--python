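"""Synthetic breast-cancer cohorts with the structure the classifiers assume.

The generator produces log2 expression matrices, IHC-style clinical tables
and compartment-dissected datasets in which the ground truth is known:

* a latent binary ER state per tumour (prevalence ~0.7, as in typical
  breast-cancer series);
* signature-like genes whose expression is a two-component Gaussian mixture
  conditioned on the latent state (lower mode ~6, upper mode separated by a
  configurable number of component SDs), with both +1- and -1-oriented
  genes; ESR1 is the first +1 gene;
* a continuous proliferation score expressed as the MKI67 row;
* stromal-contamination genes that mimic the signature genes in the tumour
  cohort but are strongly elevated in stroma in the paired
  epithelium/stroma compartment dataset;
* background genes of low dispersion, some with poor detection rates to
  exercise the present-call filter;
* IHC labels equal to the latent state corrupted at configurable false
  negative / false positive rates.  Validation cohorts default to a 15%
  IHC false negative rate — the mislabelling regime the expression
  classifiers are meant to detect — while the
  :meth:`SimulationConfig.reference_cohort` preset uses 1% label noise,
  reflecting the carefully reviewed annotation a derivation cohort needs
  (a gene cannot pass a 5% error screen against labels that are 15% wrong);
* exponential survival whose hazard is multiplied by ``hr_er_negative`` for
  latent-ER-negative tumours and by ``hr_mki67_within_erpos ** z`` for the
  proliferation z-score within latent-ER-positive tumours only, with
  independent exponential censoring and an administrative follow-up cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .data import ClinicalTable, CompartmentDataset, ExpressionMatrix

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_compartment_data"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Expression is on log2 scale.  ``mixture_separation`` is the distance
    between the two component means of informative genes in units of the
    component SD (default 5, a clearly bimodal regime).  Hazard-ratio
    parameters are multiplicative effects on an exponential baseline.
    """

    n_samples: int = 600
    n_genes: int = 2000
    n_signature_genes: int = 23
    frac_negative_weight: float = 0.3   # fraction of signature genes oriented -1
    er_prevalence: float = 0.7
    mixture_separation: float = 5.0     # component-mean separation, in SD units
    component_sd: float = 1.0
    low_mean: float = 6.0               # lower component mean (log2)
    background_mean: float = 8.0
    background_sd: float = 0.5
    frac_absent_background: float = 0.15  # background genes with poor detection
    present_rate_expressed: float = 0.98
    present_rate_absent: float = 0.25
    ihc_fnr: float = 0.15               # latent ER+ labelled IHC-negative
    ihc_fpr: float = 0.05               # latent ER- labelled IHC-positive
    n_stromal_genes: int = 30
    stromal_effect_size: float = 3.0    # log2 stroma-minus-epithelium shift
    n_compartment_patients: int = 10
    patient_effect_sd: float = 0.5
    compartment_residual_sd: float = 0.5
    baseline_hazard: float = 0.08       # events per year, latent ER+ reference
    hr_er_negative: float = 2.0
    hr_mki67_within_erpos: float = 3.0
    censoring_rate: float = 0.05        # exponential censoring, events per year
    follow_up_max_years: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("er_prevalence", "ihc_fnr", "ihc_fpr", "frac_negative_weight",
                     "frac_absent_background", "present_rate_expressed", "present_rate_absent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_hazard", "hr_er_negative", "hr_mki67_within_erpos",
                     "component_sd", "background_sd", "follow_up_max_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_signature_genes + self.n_stromal_genes + 1 > self.n_genes:
            raise ValueError("n_genes too small for the requested planted genes")
        if self.n_samples < 20:
            raise ValueError("n_samples too small for a meaningful cohort")

    @classmethod
    def reference_cohort(cls, **overrides: Any) -> "SimulationConfig":
        """Preset for a derivation cohort with carefully reviewed ER annotation."""
        cfg = cls(ihc_fnr=0.01, ihc_fpr=0.01)
        return replace(cfg, **overrides)


@dataclass
class CohortTruth:
    """Ground truth latents of a simulated cohort."""

    latent_er: pd.Series            # bool, True = ER positive
    signature_gene_ids: list[str]
    signature_weights: dict[str, int]
    stromal_gene_ids: list[str]
    esr1_gene_id: str
    mki67_gene_id: str
    mki67_z: pd.Series
    config: SimulationConfig = field(repr=False, default=None)


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    n_sig = config.n_signature_genes
    sig = ["ESR1"] + [f"SIG{i:04d}" for i in range(1, n_sig)]
    stromal = [f"STR{i:04d}" for i in range(config.n_stromal_genes)]
    n_bg = config.n_genes - n_sig - config.n_stromal_genes - 1
    background = [f"BG{i:05d}" for i in range(n_bg)]
    return sig, stromal, background


def _signature_weights(config: SimulationConfig, sig_ids: list[str]) -> dict[str, int]:
    # ESR1 is +1 by definition; a fixed fraction of the rest are -1,
    # deterministically placed at the tail of the id list.
    n_neg = int(round(config.frac_negative_weight * (len(sig_ids) - 1)))
    weights = {g: 1 for g in sig_ids}
    for g in sig_ids[len(sig_ids) - n_neg:]:
        weights[g] = -1
    return weights


def _bimodal_rows(rng: np.random.Generator, er_pos: np.ndarray,
                  weights: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Mixture expression for planted genes: rows x samples."""
    mu_low = config.low_mean
    mu_high = config.low_mean + config.mixture_separation * config.component_sd
    high = np.where(weights[:, None] > 0, er_pos[None, :], ~er_pos[None, :])
    means = np.where(high, mu_high, mu_low)
    return rng.normal(means, config.component_sd)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Simulate one cohort: expression matrix, clinical table, ground truth.

    Bit-reproducible given ``config.seed``.  The truth record carries the
    latent ER state, the planted signature genes and weights, the stromal
    gene ids and the proliferation z-scores, which is enough to score every
    downstream stage of the pipeline.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    sig_ids, stromal_ids, bg_ids = _gene_ids(config)
    weights = _signature_weights(config, sig_ids)

    er_pos = rng.random(n) < config.er_prevalence

    sig_w = np.array([weights[g] for g in sig_ids])
    sig_expr = _bimodal_rows(rng, er_pos, sig_w, config)

    # stromal-contamination genes: ER-correlated and bimodal in the tumour
    # cohort (they would pass every in-cohort screen) but stroma-elevated in
    # the compartment data, so only the stromal exclusion removes them
    str_expr = _bimodal_rows(rng, er_pos, np.ones(len(stromal_ids), dtype=int), config)

    mki67_z = rng.standard_normal(n)
    mki67_expr = config.background_mean + config.component_sd * mki67_z

    bg_expr = rng.normal(config.background_mean, config.background_sd,
                         size=(len(bg_ids), n))

    gene_order = sig_ids + ["MKI67"] + stromal_ids + bg_ids
    values = np.vstack([sig_expr, mki67_expr[None, :], str_expr, bg_expr])
    expr = pd.DataFrame(values, index=gene_order, columns=samples)

    # detection mask: expressed genes detected almost everywhere; a fraction
    # of background genes are poorly detected and should fail the 50% filter
    n_absent = int(round(config.frac_absent_background * len(bg_ids)))
    absent = set(bg_ids[:n_absent])
    p_present = np.array([
        config.present_rate_absent if g in absent else config.present_rate_expressed
        for g in gene_order
    ])
    mask = rng.random(values.shape) < p_present[:, None]
    matrix = ExpressionMatrix(expr, pd.DataFrame(mask, index=gene_order, columns=samples))

    # IHC labels: latent state corrupted at the configured error rates
    flip = np.where(er_pos, rng.random(n) < config.ihc_fnr, rng.random(n) < config.ihc_fpr)
    ihc_pos = np.where(flip, ~er_pos, er_pos)
    ihc = np.where(ihc_pos, "positive", "negative")

    # survival: exponential hazard with multiplicative ER and proliferation
    # effects; proliferation only matters within latent ER-positive disease
    log_hr = (np.log(config.hr_er_negative) * (~er_pos)
              + np.log(config.hr_mki67_within_erpos) * mki67_z * er_pos)
    hazard = config.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.minimum(rng.exponential(1.0 / config.censoring_rate, size=n),
                             config.follow_up_max_years)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clinical = ClinicalTable(pd.DataFrame({
        "ihc_er": ihc,
        "time_years": time,
        "event": event,
        "endpoint": "DFS",
        "systemic_treatment": "none",
        "ln_status": np.where(rng.random(n) < 0.4, "positive", "negative"),
    }, index=samples))

    truth = CohortTruth(
        latent_er=pd.Series(er_pos, index=samples),
        signature_gene_ids=sig_ids,
        signature_weights=weights,
        stromal_gene_ids=stromal_ids,
        esr1_gene_id="ESR1",
        mki67_gene_id="MKI67",
        mki67_z=pd.Series(mki67_z, index=samples),
        config=config,
    )
    return matrix, clinical, truth


def simulate_compartment_data(config: SimulationConfig
                              ) -> tuple[CompartmentDataset, list[str]]:
    """Paired epithelium/stroma profiles with planted stroma-elevated genes.

    Each of ``n_compartment_patients`` donors contributes one epithelial and
    one stromal profile.  All genes share a patient random intercept
    (SD ``patient_effect_sd``); the ``n_stromal_genes`` planted genes are
    shifted up by ``stromal_effect_size`` log2 units in the stromal
    profiles.  Returns the dataset and the list of planted stromal gene ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sig_ids, stromal_ids, bg_ids = _gene_ids(config)
    gene_order = sig_ids + ["MKI67"] + stromal_ids + bg_ids
    n_pat = config.n_compartment_patients
    samples, compartment, patients = [], [], []
    for p in range(n_pat):
        for comp in ("epithelium", "stroma"):
            samples.append(f"P{p:02d}_{comp[:3]}")
            compartment.append(comp)
            patients.append(f"P{p:02d}")
    n_obs = len(samples)
    is_stroma = np.array([c == "stroma" for c in compartment])
    patient_idx = np.array([int(p[1:]) for p in patients])

    base = np.full((len(gene_order), n_obs), config.background_mean)
    stromal_set = set(stromal_ids)
    effect = np.array([config.stromal_effect_size if g in stromal_set else 0.0
                       for g in gene_order])
    base = base + effect[:, None] * is_stroma[None, :]
    pat_int = rng.normal(0.0, config.patient_effect_sd, size=(len(gene_order), n_pat))
    base = base + pat_int[:, patient_idx]
    values = base + rng.normal(0.0, config.compartment_residual_sd, size=base.shape)

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_order, columns=samples))
    ds = CompartmentDataset(
        expression=matrix,
        compartment=pd.Series(compartment, index=samples),
        patient_id=pd.Series(patients, index=samples),
    )
    return ds, stromal_ids
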