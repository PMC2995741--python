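"""Apply ER classifiers to a target cohort and compare call sets.

Two classifiers are provided.  The single-gene classifier fits the bimodal
ESR1 expression in the target cohort itself and thresholds at the derived
cohort-specific cutoff.  The signature classifier re-derives a cutoff for
every signature gene in the target cohort and lets the genes vote: gene g
with weight w_g and cutoff c_g casts a positive vote for sample s when
w_g * (x_gs - c_g) > 0, and a sample is called ER positive when at least
``vote_threshold`` genes (12 of 23 by default) vote positive.

Cutoffs are always re-derived per dataset because absolute log2 levels are
not comparable across platforms or normalisations; only the bimodal split
is assumed portable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ER_NEGATIVE, ER_POSITIVE, ExpressionMatrix
from .mixture import BIMODALITY_THRESHOLD, bimodality_coefficient, fit_gene
from .signature import Signature, majority_threshold

__all__ = ["ERCallSet", "classify_esr1", "classify_signature", "concordance"]

logger = logging.getLogger(__name__)


@dataclass
class ERCallSet:
    """Per-sample binary ER calls with optional vote detail."""

    call: pd.Series  # per-sample, "positive" / "negative"
    method: str      # "esr1" | "signature" | "ihc"
    votes: pd.Series | None = None
    per_gene_votes: pd.DataFrame | None = None  # genes x samples booleans
    n_genes_used: int | None = None
    vote_threshold: int | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.call.index)

    def as_binary(self) -> pd.Series:
        """1 for ER positive, 0 for ER negative."""
        return (self.call == ER_POSITIVE).astype(int)

    @classmethod
    def from_labels(cls, labels: pd.Series, method: str = "ihc") -> "ERCallSet":
        known = labels[labels.isin([ER_POSITIVE, ER_NEGATIVE])]
        return cls(call=known.astype(str), method=method)


def classify_esr1(matrix: ExpressionMatrix, esr1_gene_id: str, seed: int | None = 0,
                  strict: bool = False, cutoff_rule: str = "mahalanobis") -> ERCallSet:
    """Call ER status from the bimodal ESR1 expression in this cohort.

    Fits a two-component Gaussian mixture to the ESR1 row, derives the
    cohort-specific cutoff and calls a sample positive when its expression
    exceeds it.  If ESR1 is not bimodal in this cohort (coefficient of
    bimodality <= 0.555, as in an all-ER-negative series), a warning is
    raised — or, in strict mode, the cohort is refused.
    """
    if esr1_gene_id not in matrix.values.index:
        raise KeyError(f"ESR1 row not found: {esr1_gene_id!r}")
    x = matrix.gene(esr1_gene_id)
    b = bimodality_coefficient(x.to_numpy(dtype=float))
    if b <= BIMODALITY_THRESHOLD:
        msg = (f"ESR1 not bimodal in this cohort (b = {b:.3f} <= "
               f"{BIMODALITY_THRESHOLD}); the mixture cutoff is unreliable")
        if strict:
            raise ValueError(f"cohort not separable: {msg}")
        warnings.warn(msg, stacklevel=2)
    fit = fit_gene(x.to_numpy(dtype=float), seed=seed, cutoff_rule=cutoff_rule)
    call = pd.Series(np.where(x > fit.cutoff, ER_POSITIVE, ER_NEGATIVE), index=x.index)
    return ERCallSet(call=call, method="esr1")


def classify_signature(matrix: ExpressionMatrix, signature: Signature,
                       seed: int | None = 0, fallback: str = "median",
                       cutoff_rule: str = "mahalanobis") -> ERCallSet:
    """Call ER status by the weighted vote of the signature genes.

    Cutoffs are re-derived per gene from the bimodal distribution in this
    dataset.  Genes that are not bimodal here (coefficient <= 0.555, or the
    fitted components overlap) fall back per ``fallback``:

    * ``"median"`` (default): use the cohort median as the cutoff;
    * ``"reference"``: reuse the cutoff from the derivation cohort;
    * ``"drop"``: exclude the gene; the vote threshold is rescaled to a
      strict majority of the genes actually used.

    Missing (NaN) expression makes the gene abstain for that sample;
    abstentions count toward neither side and the threshold is unchanged.
    """
    if fallback not in ("median", "reference", "drop"):
        raise ValueError(f"unknown fallback: {fallback!r}")
    present = [g for g in signature.genes if g.gene_id in matrix.values.index]
    if len(present) < len(signature) / 2:
        raise ValueError(
            f"signature coverage insufficient: {len(present)} of {len(signature)} genes in matrix")

    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(present))]
    used: list[str] = []
    vote_rows: dict[str, np.ndarray] = {}
    n_fallback = 0
    for g, gene_seed in zip(present, seeds):
        x = matrix.values.loc[g.gene_id].to_numpy(dtype=float)
        finite = np.isfinite(x)
        cutoff = None
        try:
            b = bimodality_coefficient(x[finite])
            fit = fit_gene(x[finite], seed=gene_seed, cutoff_rule=cutoff_rule)
            if b > BIMODALITY_THRESHOLD and not fit.overlapping:
                cutoff = fit.cutoff
        except ValueError:
            pass
        if cutoff is None:
            n_fallback += 1
            if fallback == "drop":
                continue
            cutoff = float(np.nanmedian(x)) if fallback == "median" else g.ref_cutoff
        votes = g.weight * (x - cutoff) > 0
        votes = np.where(finite, votes, False)  # abstain on missing values
        vote_rows[g.gene_id] = votes
        used.append(g.gene_id)

    if not used:
        raise ValueError("signature coverage insufficient: no usable genes")
    per_gene = pd.DataFrame(vote_rows, index=matrix.sample_ids).T
    votes = per_gene.sum(axis=0)
    if fallback == "drop" and len(used) < len(signature):
        threshold = majority_threshold(len(used))
    else:
        threshold = signature.vote_threshold
    logger.info("signature classification: %d/%d genes usable (%d via fallback), threshold %d",
                len(used), len(signature), n_fallback, threshold)
    call = pd.Series(np.where(votes >= threshold, ER_POSITIVE, ER_NEGATIVE),
                     index=matrix.sample_ids)
    return ERCallSet(call=call, method="signature", votes=votes, per_gene_votes=per_gene,
                     n_genes_used=len(used), vote_threshold=threshold)


def concordance(calls_a: ERCallSet, calls_b: ERCallSet) -> tuple[float, pd.DataFrame, float]:
    """Agreement between two call sets on their shared samples.

    Returns the overall agreement fraction, the 2x2 contingency table
    (rows: method a, columns: method b) and the two-sided Fisher exact
    p-value.  Samples missing from either set are excluded.
    """
    shared = [s for s in calls_a.sample_ids if s in set(calls_b.sample_ids)]
    if not shared:
        raise ValueError("disjoint sample sets: no shared samples to compare")
    n_excluded = (len(calls_a.sample_ids) - len(shared)) + (len(calls_b.sample_ids) - len(shared))
    if n_excluded:
        logger.info("concordance: %d samples present in only one call set were excluded",
                    n_excluded)
    a = calls_a.call.loc[shared]
    b = calls_b.call.loc[shared]
    levels = [ER_POSITIVE, ER_NEGATIVE]
    table = pd.crosstab(a, b).reindex(index=levels, columns=levels, fill_value=0)
    table.index.name = calls_a.method
    table.columns.name = calls_b.method
    frac = float((a.to_numpy() == b.to_numpy()).mean())
    _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return frac, table, float(p)
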