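"""Derivation of a weighted bimodal gene signature for ER status.

The pipeline mirrors how epithelial ER-associated signatures are built from
a reference breast-cancer cohort with IHC annotation:

1. keep genes detected ("present call") in more than half the samples;
2. drop genes significantly over-expressed in tumour stroma relative to
   epithelium, estimated from compartment-dissected profiles with a
   mixed-effects model (patient random intercept);
3. keep genes whose expression is dispersed (SD > 1 on log2 scale) and
   bimodal (coefficient of bimodality > 0.555);
4. for each survivor, fit the two-Gaussian mixture, derive its cutoff,
   orient it by the sign of its correlation with the IHC ER label, and keep
   genes whose empirical false positive and false negative rates against
   IHC are both below 0.05.

Each retained gene carries a weight of +1 (high expression marks ER+) or -1
(high expression marks ER-).  A sample is later called ER positive when a
strict majority of signature genes vote positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .data import CompartmentDataset, ExpressionMatrix
from .mixture import (
    BIMODALITY_THRESHOLD,
    _bimodality_coefficient_rows,
    fit_gene,
)

__all__ = [
    "SignatureGene",
    "Signature",
    "present_call_filter",
    "stromal_exclusion",
    "bimodal_gene_screen",
    "error_rate_screen",
    "derive_signature",
]

logger = logging.getLogger(__name__)


@dataclass
class SignatureGene:
    """One signature member with its orientation and reference-cohort stats."""

    gene_id: str
    weight: int  # +1: high expression marks ER positive; -1: marks ER negative
    ref_fpr: float
    ref_fnr: float
    ref_cutoff: float

    def __post_init__(self) -> None:
        if self.weight not in (+1, -1):
            raise ValueError("weight must be +1 or -1")


@dataclass
class Signature:
    """Ordered, weighted gene set plus the vote threshold for an ER+ call."""

    genes: list[SignatureGene]
    vote_threshold: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in signature")
        if not 1 <= self.vote_threshold <= len(self.genes):
            raise ValueError("vote_threshold must be in [1, number of genes]")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def weights(self) -> dict[str, int]:
        return {g.gene_id: g.weight for g in self.genes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.weight, g.ref_cutoff, g.ref_fpr, g.ref_fnr) for g in self.genes],
            columns=["gene_id", "weight", "ref_cutoff", "ref_fpr", "ref_fnr"],
        ).set_index("gene_id")


def majority_threshold(n_genes: int) -> int:
    """Strict-majority vote threshold: floor(k/2) + 1 (12 for 23 genes)."""
    return n_genes // 2 + 1


def present_call_filter(matrix: ExpressionMatrix, min_fraction: float = 0.5) -> list[str]:
    """Genes detected in strictly more than ``min_fraction`` of samples."""
    if matrix.present_mask is None:
        raise ValueError("no present-call mask on this matrix")
    frac = matrix.present_mask.mean(axis=1)
    keep = frac.index[frac > min_fraction]
    return list(keep)


def _one_sided_stroma_p(values: np.ndarray, stroma: np.ndarray, groups: np.ndarray) -> float:
    """One-sided p-value (stroma > epithelium) from a random-intercept model.

    The Wald statistic for the compartment effect is referred to a t
    distribution with (number of patients - 1) degrees of freedom rather
    than the asymptotic normal, which is anti-conservative with the dozen
    or so donors typical of microdissection studies.
    """
    exog = np.column_stack([np.ones_like(stroma, dtype=float), stroma.astype(float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(values, exog, groups=groups)
            res = model.fit(reml=True)
            coef = float(res.params[1])
            bse = float(res.bse[1])
        except Exception:  # singular fits on degenerate genes
            return 1.0
    if not np.isfinite(coef) or not np.isfinite(bse) or bse <= 0:
        return 1.0
    df = max(len(np.unique(groups)) - 1, 1)
    tstat = coef / bse
    return float(stats.t.sf(tstat, df))


def stromal_exclusion(compartments: CompartmentDataset, alpha: float = 0.05) -> list[str]:
    """Genes significantly over-expressed in stroma relative to epithelium.

    Per gene, fits expression ~ compartment with a per-patient random
    intercept, takes the one-sided p-value for a positive stroma effect, and
    flags genes significant at level ``alpha`` after Benjamini-Hochberg
    correction across genes.
    """
    if compartments.n_patients_with_both < 2:
        raise ValueError("cannot estimate compartment effect: need >= 2 patients with both compartments")
    expr = compartments.expression.values
    stroma = (compartments.compartment == "stroma").to_numpy()
    groups = compartments.patient_id.to_numpy()
    pvals = np.array([
        _one_sided_stroma_p(expr.loc[g].to_numpy(dtype=float), stroma, groups)
        for g in expr.index
    ])
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    flagged = list(expr.index[reject])
    logger.info("stromal exclusion: %d of %d genes flagged", len(flagged), len(expr.index))
    return flagged


def bimodal_gene_screen(matrix: ExpressionMatrix, sd_min: float = 1.0,
                        b_min: float = BIMODALITY_THRESHOLD) -> list[str]:
    """Genes with sample SD > ``sd_min`` and bimodality coefficient > ``b_min``."""
    arr = matrix.values.to_numpy(dtype=float)
    if arr.shape[1] < 4:
        raise ValueError("insufficient sample: bimodality screen needs >= 4 samples")
    sd = arr.std(axis=1, ddof=1)
    b = _bimodality_coefficient_rows(arr)
    keep = (sd > sd_min) & (b > b_min)
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def _gene_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def error_rate_screen(matrix: ExpressionMatrix, ihc_labels: pd.Series,
                      max_rate: float = 0.05, seed: int | None = 0,
                      weight_reference: str = "ihc",
                      esr1_gene_id: str | None = None) -> list[SignatureGene]:
    """Screen bimodal candidate genes by empirical error rates against IHC.

    For each gene: fit the two-component mixture and derive its cutoff;
    orient the gene by the sign of the point-biserial correlation between
    its expression and the binary IHC label (``weight_reference="ihc"``) or
    by the sign of its Pearson correlation with ESR1 expression
    (``weight_reference="esr1"``); call each sample positive when the
    oriented expression exceeds the cutoff, i.e. weight * (x - cutoff) > 0;
    and keep genes whose empirical FPR (IHC-negative samples called
    positive) and FNR (IHC-positive called negative) are both strictly
    below ``max_rate``.
    """
    labels = ihc_labels.reindex(matrix.sample_ids)
    y = (labels == "positive").to_numpy()
    neg = (labels == "negative").to_numpy()
    if y.sum() == 0 or neg.sum() == 0:
        raise ValueError("labels not informative: need both ER classes")
    if weight_reference == "esr1":
        if esr1_gene_id is None:
            raise ValueError("weight_reference='esr1' requires esr1_gene_id")
        ref_vec = matrix.gene(esr1_gene_id).to_numpy(dtype=float)
    elif weight_reference == "ihc":
        ref_vec = y.astype(float)
    else:
        raise ValueError(f"unknown weight_reference: {weight_reference!r}")

    retained: list[SignatureGene] = []
    for gene, gene_seed in zip(matrix.gene_ids, _gene_seeds(seed, matrix.n_genes)):
        x = matrix.values.loc[gene].to_numpy(dtype=float)
        try:
            fit = fit_gene(x, seed=gene_seed)
        except ValueError:
            continue
        r = np.corrcoef(x, ref_vec)[0, 1]
        if not np.isfinite(r) or r == 0.0:
            continue  # orientation undefined
        w = 1 if r > 0 else -1
        call_pos = w * (x - fit.cutoff) > 0
        fpr = float(call_pos[neg].mean())
        fnr = float((~call_pos)[y].mean())
        if fpr < max_rate and fnr < max_rate:
            retained.append(SignatureGene(gene, w, ref_fpr=fpr, ref_fnr=fnr,
                                          ref_cutoff=fit.cutoff))
    return retained


def derive_signature(matrix: ExpressionMatrix, ihc_labels: pd.Series,
                     compartments: CompartmentDataset | None = None,
                     *, min_fraction: float = 0.5, alpha: float = 0.05,
                     sd_min: float = 1.0, b_min: float = BIMODALITY_THRESHOLD,
                     max_rate: float = 0.05, seed: int | None = 0,
                     weight_reference: str = "ihc",
                     esr1_gene_id: str | None = None) -> Signature:
    """Run the full derivation pipeline on a reference cohort.

    Stages: present-call filter -> stromal exclusion -> SD/bimodality screen
    -> FPR/FNR screen against IHC.  The vote threshold is the strict
    majority of the retained genes.  Per-stage gene counts and all
    parameters are recorded in the signature's provenance.
    """
    counts: dict[str, int] = {"input": matrix.n_genes}

    if matrix.present_mask is not None:
        genes = present_call_filter(matrix, min_fraction)
    else:
        genes = matrix.gene_ids
    counts["present_call"] = len(genes)
    logger.info("present-call filter: %d genes retained", len(genes))
    if not genes:
        raise ValueError("stage produced no genes: present_call_filter")

    if compartments is not None:
        stromal = set(stromal_exclusion(compartments, alpha=alpha))
        genes = [g for g in genes if g not in stromal]
    counts["after_stromal_exclusion"] = len(genes)
    logger.info("stromal exclusion: %d genes retained", len(genes))
    if not genes:
        raise ValueError("stage produced no genes: stromal_exclusion")

    sub = matrix.subset_genes(genes)
    genes = bimodal_gene_screen(sub, sd_min=sd_min, b_min=b_min)
    counts["bimodal_screen"] = len(genes)
    logger.info("SD/bimodality screen: %d genes retained", len(genes))
    if not genes:
        raise ValueError("stage produced no genes: bimodal_gene_screen")

    sub = matrix.subset_genes(genes)
    sig_genes = error_rate_screen(sub, ihc_labels, max_rate=max_rate, seed=seed,
                                  weight_reference=weight_reference,
                                  esr1_gene_id=esr1_gene_id)
    counts["error_rate_screen"] = len(sig_genes)
    logger.info("FPR/FNR screen: %d genes retained", len(sig_genes))
    if not sig_genes:
        raise ValueError("stage produced no genes: error_rate_screen")

    provenance = {
        "stage_counts": counts,
        "params": {
            "min_fraction": min_fraction, "alpha": alpha, "sd_min": sd_min,
            "b_min": b_min, "max_rate": max_rate, "seed": seed,
            "weight_reference": weight_reference,
        },
    }
    return Signature(genes=sig_genes,
                     vote_threshold=majority_threshold(len(sig_genes)),
                     provenance=provenance)
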