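"""Reading and writing the tab-delimited formats used by the toolkit.

Expression matrices are plain TSV: first column gene id, header row of
sample ids.  An optional companion present-call file of identical shape
carries dChip-style P/A/M codes (or 1/0).  Clinical tables are TSV with a
``sample_id`` column; unrecognised category tokens map to ``unknown`` with
a warning.  Signatures round-trip as a TSV of (gene_id, weight, ref_cutoff,
ref_fpr, ref_fnr) plus a JSON provenance sidecar.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ERCallSet
from .data import ClinicalTable, CompartmentDataset, ExpressionMatrix
from .signature import Signature, SignatureGene

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_signature",
    "write_signature",
    "read_compartments",
    "write_calls",
    "read_calls",
]

_PRESENT_CODES = {"P": True, "A": False, "M": False, "1": True, "0": False,
                  "TRUE": True, "FALSE": False}


def read_expression(path, mask_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV, optionally with a present-call companion."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene id in {path}: {dup[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
        df[col] = coerced
    mask = None
    if mask_path is not None:
        raw = pd.read_csv(mask_path, sep="\t", index_col=0, dtype=str)
        if raw.shape != df.shape:
            raise ValueError("mask shape mismatch: present-call file does not match expression")
        try:
            mask = raw.apply(lambda c: c.str.strip().str.upper().map(_PRESENT_CODES))
        except Exception as err:
            raise ValueError(f"unreadable present-call codes: {err}") from err
        if mask.isna().any().any():
            raise ValueError("unreadable present-call codes (expected P/A/M or 1/0)")
        mask.index = df.index
        mask.columns = df.columns
    return ExpressionMatrix(df, mask)


def write_expression(matrix: ExpressionMatrix, path, mask_path=None) -> None:
    matrix.values.to_csv(path, sep="\t")
    if mask_path is not None and matrix.present_mask is not None:
        matrix.present_mask.replace({True: "P", False: "A"}).to_csv(mask_path, sep="\t")


_ER_TOKENS = {"positive": "positive", "pos": "positive", "+": "positive", "1": "positive",
              "negative": "negative", "neg": "negative", "-": "negative", "0": "negative",
              "unknown": "unknown", "na": "unknown", "": "unknown"}


def _map_tokens(series: pd.Series, mapping: dict, column: str) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    out = s.map(mapping)
    unknown = out.isna()
    if unknown.any():
        vals = sorted(s[unknown].unique())
        warnings.warn(f"unrecognised {column} values mapped to 'unknown': {vals[:5]}")
        out = out.fillna("unknown")
    return out


def read_clinical(path) -> ClinicalTable:
    """Read a clinical annotation TSV (sample_id, ihc_er, time_years, event, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("missing required clinical column: sample_id")
    df = df.set_index("sample_id")
    missing = [c for c in ClinicalTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required clinical columns: {missing}")
    df["ihc_er"] = _map_tokens(df["ihc_er"], _ER_TOKENS, "ihc_er")
    if "systemic_treatment" in df.columns:
        allowed = {t: t for t in ("none", "endocrine", "chemo", "both", "unknown")}
        df["systemic_treatment"] = _map_tokens(df["systemic_treatment"], allowed,
                                               "systemic_treatment")
    if "ln_status" in df.columns:
        df["ln_status"] = _map_tokens(df["ln_status"], _ER_TOKENS, "ln_status")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.df.rename_axis("sample_id").to_csv(path, sep="\t")


def write_signature(signature: Signature, path) -> None:
    """Write the signature TSV and a JSON provenance sidecar next to it."""
    path = Path(path)
    signature.to_frame().to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"vote_threshold": signature.vote_threshold, "provenance": signature.provenance},
        indent=2, default=str))


def read_signature(path) -> Signature:
    path = Path(path)
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    genes = [SignatureGene(g, int(r["weight"]), ref_fpr=float(r["ref_fpr"]),
                           ref_fnr=float(r["ref_fnr"]), ref_cutoff=float(r["ref_cutoff"]))
             for g, r in df.iterrows()]
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        threshold = int(meta["vote_threshold"])
        provenance = meta.get("provenance", {})
    else:
        threshold = len(genes) // 2 + 1
        provenance = {}
    return Signature(genes=genes, vote_threshold=threshold, provenance=provenance)


def read_compartments(expression_path, annotation_path) -> CompartmentDataset:
    """Read a compartment dataset: expression TSV + per-sample annotation TSV.

    The annotation file needs columns sample_id, compartment
    (epithelium/stroma) and patient_id.
    """
    matrix = read_expression(expression_path)
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str).set_index("sample_id")
    for col in ("compartment", "patient_id"):
        if col not in ann.columns:
            raise ValueError(f"missing required compartment column: {col}")
    return CompartmentDataset(expression=matrix,
                              compartment=ann["compartment"].str.strip().str.lower(),
                              patient_id=ann["patient_id"])


def write_calls(calls: ERCallSet, path) -> None:
    df = pd.DataFrame({"call": calls.call})
    if calls.votes is not None:
        df["votes"] = calls.votes
    df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_calls(path, method: str = "ihc") -> ERCallSet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    if "call" not in df.columns:
        raise ValueError("missing required column: call")
    calls = ERCallSet(call=df["call"].astype(str), method=method)
    if "votes" in df.columns:
        calls.votes = df["votes"].astype(int)
    return calls
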