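"""In-memory containers for expression, compartment and clinical data.

Everything is a thin, validated wrapper around pandas objects so that the
rest of the package can rely on a few invariants (unique identifiers, finite
values, congruent masks) without re-checking them at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "CompartmentDataset", "ClinicalTable"]

ER_POSITIVE = "positive"
ER_NEGATIVE = "negative"
ER_UNKNOWN = "unknown"

TREATMENTS = {"none", "endocrine", "chemo", "both", "unknown"}


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, with an optional present-call mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns; finite floats.
    present_mask : pandas.DataFrame, optional
        Boolean detection flags of identical shape and labels; True means the
        transcript was reliably measured ("present") in that sample.
    """

    values: pd.DataFrame
    present_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr) | np.isnan(arr)):
            raise ValueError("expression values must be finite (or NaN for missing)")
        if self.present_mask is not None:
            m = self.present_mask
            if m.shape != v.shape or list(m.index) != list(v.index) \
                    or list(m.columns) != list(v.columns):
                raise ValueError("mask shape mismatch: present mask must be congruent with values")
            self.present_mask = m.astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # alias used where ``.values`` would shadow the numpy accessor of a frame
    @property
    def values_frame(self) -> pd.DataFrame:
        return self.values

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        mask = self.present_mask.loc[gene_ids] if self.present_mask is not None else None
        return ExpressionMatrix(self.values.loc[gene_ids], mask)

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not found in matrix")
        return self.values.loc[gene_id]


@dataclass
class CompartmentDataset:
    """Expression profiles labelled by tissue compartment and donor.

    Emulates laser-capture-microdissection style data: per patient, one or
    more profiles from tumour epithelium and from stroma, used to identify
    and exclude stromally expressed genes from epithelial signatures.
    """

    expression: ExpressionMatrix
    compartment: pd.Series  # per-sample, in {"epithelium", "stroma"}
    patient_id: pd.Series   # per-sample donor identifier

    def __post_init__(self) -> None:
        samples = self.expression.sample_ids
        self.compartment = self.compartment.reindex(samples)
        self.patient_id = self.patient_id.reindex(samples)
        if self.compartment.isna().any() or self.patient_id.isna().any():
            raise ValueError("every sample needs a compartment label and a patient id")
        bad = set(self.compartment.unique()) - {"epithelium", "stroma"}
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")
        if self.compartment.nunique() < 2:
            raise ValueError("cannot estimate compartment effect: single-compartment data")

    @property
    def n_patients_with_both(self) -> int:
        by = pd.crosstab(self.patient_id, self.compartment)
        return int(((by.get("epithelium", 0) > 0) & (by.get("stroma", 0) > 0)).sum())


@dataclass
class ClinicalTable:
    """Clinical annotation: IHC ER status, treatment, survival endpoint.

    The underlying frame is indexed by sample id with columns ``ihc_er``
    (positive/negative/unknown), ``time_years``, ``event`` (0/1),
    ``endpoint`` (DFS/DMFS), ``systemic_treatment`` and ``ln_status``.
    """

    df: pd.DataFrame

    REQUIRED = ("ihc_er", "time_years", "event")
    DEFAULTS = {"endpoint": "DFS", "systemic_treatment": "unknown", "ln_status": "unknown"}

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing required clinical columns: {missing}")
        for col, default in self.DEFAULTS.items():
            if col not in df.columns:
                df[col] = default
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        df["time_years"] = df["time_years"].astype(float)
        if (df["time_years"] < 0).any():
            raise ValueError("negative follow-up time")
        ev = df["event"].astype(int)
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        df["event"] = ev
        bad = set(df["ihc_er"].unique()) - {ER_POSITIVE, ER_NEGATIVE, ER_UNKNOWN}
        if bad:
            raise ValueError(f"unknown ER status labels: {sorted(bad)}")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.df.loc[list(sample_ids)])

    def untreated(self) -> "ClinicalTable":
        """Patients who received no systemic (hormone or chemo) therapy."""
        return ClinicalTable(self.df[self.df["systemic_treatment"] == "none"])
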