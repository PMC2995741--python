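"""Survival-based evaluation of ER classifiers.

ER-negative breast cancer carries most of its excess recurrence risk early,
so hazard ratios for ER status are estimated on follow-up capped at two
years.  Classifiers are compared through

* per-cohort univariate Cox hazard ratios (ER negative vs positive) pooled
  across cohorts by fixed-effect inverse-variance meta-analysis;
* a flip null: the expression-based classifier disagrees with IHC on d
  samples, and its hazard ratio is referred to the distribution obtained by
  flipping d randomly chosen IHC calls;
* a stratified patient-level bootstrap comparing the pooled hazard ratios
  of two classifications of the same patients;
* proliferation (MKI67) hazard ratios within ER strata, an interaction
  model, and Kaplan-Meier export.

The heavy resampling loops use an internal Newton solver for the
single-binary-covariate Cox model (Efron tie handling); it is checked
against lifelines in the test suite and exists purely for speed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .classify import ERCallSet
from .data import ER_NEGATIVE, ER_POSITIVE, ClinicalTable, ExpressionMatrix

__all__ = [
    "HazardEstimate",
    "MetaResult",
    "cap_follow_up",
    "cox_hr",
    "meta_pool",
    "flip_null_test",
    "resample_comparison",
    "stratified_mki67",
    "interaction_model",
    "km_export",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class HazardEstimate:
    """A Cox log hazard ratio with its normal-theory confidence interval."""

    log_hr: float
    se: float
    n: int
    n_events: int
    cap_years: float | None = None
    p_value: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.p_value) and np.isfinite(self.se) and self.se > 0:
            self.p_value = 2.0 * stats.norm.sf(abs(self.log_hr) / self.se)

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_hr - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_hr + Z95 * self.se))

    def __str__(self) -> str:
        return f"HR = {self.hr:.2f} (95% CI {self.ci_low:.2f}-{self.ci_high:.2f}), p = {self.p_value:.2g}"


@dataclass
class MetaResult:
    """Fixed-effect inverse-variance pooled hazard estimate across cohorts."""

    pooled: HazardEstimate
    per_cohort: list[tuple[str, HazardEstimate]]
    weights: dict[str, float]
    heterogeneity_q: float
    heterogeneity_p: float


def cap_follow_up(clinical: ClinicalTable, cap_years: float) -> ClinicalTable:
    """Administratively censor all follow-up at ``cap_years``.

    Subjects observed beyond the cap are censored at the cap (their later
    events are discarded); subjects within the cap are unchanged.  The
    operation is idempotent and never increases the event count.
    """
    if cap_years <= 0:
        raise ValueError("cap_years must be positive")
    df = clinical.df.copy()
    over = df["time_years"] > cap_years
    df.loc[over, "event"] = 0
    df.loc[over, "time_years"] = cap_years
    return ClinicalTable(df)


def _prepare_cox_frame(clinical: ClinicalTable, covariate: pd.Series,
                       cap_years: float | None) -> pd.DataFrame:
    if cap_years is not None:
        clinical = cap_follow_up(clinical, cap_years)
    df = clinical.df[["time_years", "event"]].copy()
    df["x"] = covariate.reindex(df.index).astype(float)
    df = df.dropna()
    if df["event"].sum() < 2:
        raise ValueError("no events in window: need >= 2 events")
    if df["x"].nunique() < 2:
        raise ValueError("degenerate covariate: no variation")
    return df


def cox_hr(clinical: ClinicalTable, covariate: pd.Series,
           cap_years: float | None = None) -> HazardEstimate:
    """Univariate Cox proportional-hazards estimate on (optionally capped) data.

    ``covariate`` is aligned by sample id; code ER negative as 1 and ER
    positive as 0 so that HR > 1 means worse outcome for ER-negative
    disease.  Ties are handled by Efron's method (lifelines default).
    """
    df = _prepare_cox_frame(clinical, covariate, cap_years)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time_years", event_col="event")
    row = cph.summary.loc["x"]
    return HazardEstimate(log_hr=float(row["coef"]), se=float(row["se(coef)"]),
                          n=len(df), n_events=int(df["event"].sum()),
                          cap_years=cap_years, p_value=float(row["p"]))


def meta_pool(estimates: dict[str, HazardEstimate] | list[tuple[str, HazardEstimate]]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of per-cohort hazard estimates.

    pooled log HR = sum(w_i * log HR_i) / sum(w_i) with w_i = 1/se_i^2 and
    pooled se = sqrt(1 / sum(w_i)).  Cochran's Q (with k-1 df) quantifies
    between-cohort heterogeneity.
    """
    if isinstance(estimates, dict):
        items = list(estimates.items())
    else:
        items = list(estimates)
    if len(items) < 2:
        raise ValueError("nothing to pool: need >= 2 estimates")
    loghr = np.array([e.log_hr for _, e in items])
    se = np.array([e.se for _, e in items])
    if not np.all(np.isfinite(se) & (se > 0)):
        raise ValueError("nothing to pool: non-finite standard errors")
    w = 1.0 / se**2
    pooled_log = float(np.sum(w * loghr) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (loghr - pooled_log) ** 2))
    q_p = float(stats.chi2.sf(q, df=len(items) - 1))
    pooled = HazardEstimate(
        log_hr=pooled_log, se=pooled_se,
        n=sum(e.n for _, e in items), n_events=sum(e.n_events for _, e in items),
        cap_years=items[0][1].cap_years,
    )
    wsum = w / w.sum()
    return MetaResult(pooled=pooled, per_cohort=items,
                      weights={cid: float(wi) for (cid, _), wi in zip(items, wsum)},
                      heterogeneity_q=q, heterogeneity_p=q_p)


# ---------------------------------------------------------------------------
# Fast Cox solver for a single binary covariate (Efron ties), used by the
# resampling procedures.  Validated against lifelines in the tests.
# ---------------------------------------------------------------------------

class _BinaryCoxData:
    """Pre-sorted risk-set structure for repeated fits with flipped covariates.

    With a binary covariate the Efron partial likelihood depends on the data
    only through, per distinct event time: the number of subjects at risk
    with x = 1 and x = 0, and the number of tied events with x = 1 and
    x = 0.  Those counts are cheap to recompute for each flipped or
    bootstrapped covariate vector, and Newton's method then runs vectorised
    across all replicates at once.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        order = np.argsort(time, kind="stable")
        self.order = order
        self.t = np.asarray(time, float)[order]
        self.e = np.asarray(event, int)[order]
        self.n = self.t.size
        ev_idx = np.flatnonzero(self.e == 1)
        if ev_idx.size == 0:
            raise ValueError("no events in window")
        ev_times = self.t[ev_idx]
        # groups of tied event times
        starts = np.flatnonzero(np.r_[True, np.diff(ev_times) > 0])
        self.group_first_event = ev_idx[starts]          # index of first event in group
        counts = np.diff(np.r_[starts, ev_times.size])
        self.d = counts                                   # tied events per group
        # risk-set start: first index with t >= group time
        self.risk_start = np.searchsorted(self.t, self.t[self.group_first_event], side="left")
        # expansion over l = 0..d-1 per group for the Efron correction
        self.expand_group = np.repeat(np.arange(len(self.d)), self.d)
        self.frac = (np.concatenate([np.arange(di) for di in self.d]) /
                     np.repeat(self.d, self.d))
        # membership matrix pieces for tied-event sums
        self.event_group = np.repeat(np.arange(len(self.d)), self.d)  # per event, its group
        self.ev_idx = ev_idx

    def _counts(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per replicate: at-risk x=1 counts (B, G) and tied-event x=1 counts (B, G)."""
        Xs = X[:, self.order]
        suffix = np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1]
        n1_risk = suffix[:, self.risk_start]
        ev_x = Xs[:, self.ev_idx]
        G = len(self.d)
        d1 = np.zeros((X.shape[0], G))
        np.add.at(d1.T, self.event_group, ev_x.T)
        return n1_risk, d1

    def fit(self, X: np.ndarray, max_iter: int = 40, tol: float = 1e-8
            ) -> tuple[np.ndarray, np.ndarray]:
        """Newton solve for each row of X; returns (beta, se), NaN on failure."""
        X = np.asarray(X, float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        B = X.shape[0]
        n1_risk, d1 = self._counts(X)
        n_risk = self.n - self.risk_start
        n0_risk = n_risk[None, :] - n1_risk
        d = self.d[None, :]
        d0 = d - d1
        # expanded over Efron steps l
        eg = self.expand_group
        frac = self.frac[None, :]
        N1 = n1_risk[:, eg]
        N0 = n0_risk[:, eg]
        D1 = d1[:, eg]
        D0 = d0[:, eg]
        d1_total = d1.sum(axis=1)

        beta = np.zeros(B)
        ok = np.ones(B, dtype=bool)
        info = np.full(B, np.nan)
        for _ in range(max_iter):
            r = np.exp(beta)[:, None]
            A0 = (N1 - frac * D1) * r + (N0 - frac * D0)
            A1 = (N1 - frac * D1) * r
            with np.errstate(divide="ignore", invalid="ignore"):
                mu = A1 / A0
            score = d1_total - np.nansum(mu, axis=1)
            I = np.nansum(mu * (1.0 - mu), axis=1)
            bad = ~np.isfinite(score) | ~np.isfinite(I) | (I <= 1e-12)
            ok &= ~bad
            step = np.where(ok, score / np.where(I > 1e-12, I, 1.0), 0.0)
            step = np.clip(step, -2.0, 2.0)
            beta = np.clip(beta + step, -20.0, 20.0)
            info = I
            if np.all(np.abs(step[ok]) < tol) if ok.any() else True:
                break
        # divergent fits (separation): mark as NaN
        diverged = np.abs(beta) >= 20.0 - 1e-9
        ok &= ~diverged
        se = np.where(ok & (info > 0), 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.nan)
        beta = np.where(ok, beta, np.nan)
        if single:
            return float(beta[0]), float(se[0])
        return beta, se


def _binary_calls_vector(calls, index) -> np.ndarray:
    if isinstance(calls, ERCallSet):
        s = calls.as_binary()
    else:
        s = pd.Series(calls)
        if s.dtype == object:
            s = (s == ER_POSITIVE).astype(int)
    return s.reindex(index).to_numpy(dtype=float)


def flip_null_test(clinical: ClinicalTable, ihc_calls, expr_calls,
                   B: int = 1000, seed: int | None = 0,
                   cap_years: float = 2.0) -> float:
    """Flip-null significance of an expression-based classifier's hazard ratio.

    The expression classifier disagrees with IHC on d samples.  Under the
    null that those reassignments are uninformative, flipping d randomly
    chosen IHC calls should yield hazard ratios as large as the observed
    one.  Returns the add-one-corrected permutation p-value
    (1 + #{null HR >= observed}) / (B + 1).
    """
    capped = cap_follow_up(clinical, cap_years)
    idx = capped.df.index
    ihc = _binary_calls_vector(ihc_calls, idx)   # 1 = ER positive
    expr = _binary_calls_vector(expr_calls, idx)
    keep = np.isfinite(ihc) & np.isfinite(expr)
    ihc, expr = ihc[keep], expr[keep]
    t = capped.df.loc[keep, "time_years"].to_numpy()
    e = capped.df.loc[keep, "event"].to_numpy()
    d = int(np.sum(ihc != expr))
    if d == 0:
        warnings.warn("expression calls identical to IHC: flip-null p = 1")
        return 1.0

    data = _BinaryCoxData(t, e)
    obs_beta, _ = data.fit(1.0 - expr)  # covariate: ER negative = 1
    rng = np.random.default_rng(seed)
    n = ihc.size
    flips = np.empty((B, n))
    for b in range(B):
        x = ihc.copy()
        sel = rng.choice(n, size=d, replace=False)
        x[sel] = 1.0 - x[sel]
        flips[b] = 1.0 - x
    null_beta, _ = data.fit(flips)
    # failed null fits are counted as exceeding (conservative)
    exceed = np.sum(~np.isfinite(null_beta) | (null_beta >= obs_beta))
    return float((1 + exceed) / (B + 1))


def resample_comparison(cohorts: dict[str, ClinicalTable], calls_a: dict, calls_b: dict,
                        B: int = 1000, seed: int | None = 0,
                        cap_years: float = 2.0) -> float:
    """Bootstrap comparison of pooled hazard ratios under two classifications.

    Patients are resampled with replacement within each cohort; in every
    replicate the 2-year-capped pooled HR is recomputed under both
    classifications of the same resampled patients.  Returns the one-sided
    bootstrap p-value for classification b improving on a: the fraction of
    replicates with HR_b <= HR_a, with exact ties counted half.
    """
    if B < 100:
        warnings.warn("unstable p: fewer than 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    prepared = []
    for cid, clin in cohorts.items():
        capped = cap_follow_up(clin, cap_years)
        idx = capped.df.index
        xa = 1.0 - _binary_calls_vector(calls_a[cid], idx)
        xb = 1.0 - _binary_calls_vector(calls_b[cid], idx)
        keep = np.isfinite(xa) & np.isfinite(xb)
        prepared.append((capped.df.loc[keep, "time_years"].to_numpy(),
                         capped.df.loc[keep, "event"].to_numpy(),
                         xa[keep], xb[keep]))

    n_b_worse = 0.0
    n_used = 0
    for _ in range(B):
        num_a = den_a = num_b = den_b = 0.0
        valid = True
        for t, e, xa, xb in prepared:
            ii = rng.integers(0, t.size, size=t.size)
            tt, ee = t[ii], e[ii]
            if ee.sum() < 2:
                valid = False
                break
            try:
                data = _BinaryCoxData(tt, ee)
                ba, sa = data.fit(xa[ii])
                bb, sb = data.fit(xb[ii])
            except ValueError:
                valid = False
                break
            if not (np.isfinite(ba) and np.isfinite(bb) and np.isfinite(sa) and np.isfinite(sb)):
                valid = False
                break
            num_a += ba / sa**2
            den_a += 1.0 / sa**2
            num_b += bb / sb**2
            den_b += 1.0 / sb**2
        if not valid:
            continue
        n_used += 1
        pa, pb = num_a / den_a, num_b / den_b
        if pb < pa:
            n_b_worse += 1.0
        elif pb == pa:
            n_b_worse += 0.5
    if n_used == 0:
        raise ValueError("no valid bootstrap replicates")
    if n_used < B:
        logger.info("resample_comparison: %d of %d replicates usable", n_used, B)
    return float(n_b_worse / n_used)


def _standardized_gene(matrix: ExpressionMatrix, gene_id: str) -> pd.Series:
    x = matrix.gene(gene_id).astype(float)
    return (x - x.mean()) / x.std(ddof=1)


def stratified_mki67(clinical: ClinicalTable, matrix: ExpressionMatrix,
                     mki67_gene_id: str, er_calls: ERCallSet,
                     horizon_years: float = 5.0
                     ) -> tuple[HazardEstimate | None, HazardEstimate | None]:
    """Prognostic power of proliferation (MKI67) within ER strata.

    MKI67 expression is standardised within the cohort (z-score) and entered
    as a continuous Cox covariate on follow-up capped at ``horizon_years``,
    separately within the ER-positive and ER-negative strata of
    ``er_calls``.  A stratum with fewer than two events yields None with a
    warning.  A well-behaved ER classifier concentrates the prognostic
    power of proliferation in the ER-positive stratum.
    """
    z = _standardized_gene(matrix, mki67_gene_id)
    out: list[HazardEstimate | None] = []
    for status in (ER_POSITIVE, ER_NEGATIVE):
        ids = [s for s in er_calls.sample_ids
               if er_calls.call.loc[s] == status and s in clinical.df.index]
        try:
            sub = clinical.subset(ids)
            out.append(cox_hr(sub, z, cap_years=horizon_years))
        except ValueError as err:
            warnings.warn(f"insufficient events in ER {status} stratum: {err}")
            out.append(None)
    return out[0], out[1]


def interaction_model(clinical: ClinicalTable, matrix: ExpressionMatrix,
                      er_calls: ERCallSet, mki67_gene_id: str,
                      horizon_years: float = 5.0) -> dict[str, HazardEstimate]:
    """Multivariate Cox model: LN status, ER status, MKI67, and ER x MKI67.

    Complete-case analysis on follow-up capped at ``horizon_years``.
    Covariates: LN positive (1/0), ER negative (1/0), standardised MKI67,
    and their product ER-negative x MKI67.  An interaction HR below 1
    means the proliferation effect is attenuated in ER-negative disease.
    Returns estimates keyed "ln_positive", "er_negative", "mki67",
    "er_negative:mki67".
    """
    capped = cap_follow_up(clinical, horizon_years)
    df = capped.df.copy()
    z = _standardized_gene(matrix, mki67_gene_id)
    er_neg = 1.0 - _binary_calls_vector(er_calls, df.index)
    design = pd.DataFrame({
        "time_years": df["time_years"],
        "event": df["event"],
        "ln_positive": np.where(df["ln_status"] == "positive", 1.0,
                                np.where(df["ln_status"] == "negative", 0.0, np.nan)),
        "er_negative": er_neg,
        "mki67": z.reindex(df.index),
    })
    design["er_negative:mki67"] = design["er_negative"] * design["mki67"]
    design = design.dropna()
    covs = ["ln_positive", "er_negative", "mki67", "er_negative:mki67"]
    X = design[covs].to_numpy()
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(covs):
        raise ValueError("collinear covariates: design matrix is rank deficient")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(design, duration_col="time_years", event_col="event")
    out = {}
    for term in covs:
        row = cph.summary.loc[term]
        out[term] = HazardEstimate(log_hr=float(row["coef"]), se=float(row["se(coef)"]),
                                   n=len(design), n_events=int(design["event"].sum()),
                                   cap_years=horizon_years, p_value=float(row["p"]))
    return out


def km_export(clinical: ClinicalTable, group_labels: pd.Series,
              out_path=None) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier step functions per group, plus the log-rank p-value.

    Returns a long table (group, time, at_risk, events, survival,
    ci_low, ci_high) using Greenwood confidence intervals, and the
    (multivariate) log-rank p across groups.  Empty groups are excluded
    with a warning.  If ``out_path`` is given the table is written
    tab-delimited.
    """
    labels = group_labels.reindex(clinical.df.index)
    frames = []
    for grp, ids in labels.groupby(labels).groups.items():
        sub = clinical.df.loc[ids]
        if len(sub) == 0:
            warnings.warn(f"empty group {grp!r} excluded from KM export")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], sub["event"], label=str(grp))
        tbl = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        frames.append(pd.DataFrame({
            "group": str(grp),
            "time": tbl.index,
            "at_risk": tbl["at_risk"].to_numpy(),
            "events": tbl["observed"].to_numpy(),
            "survival": surv.reindex(tbl.index).to_numpy(),
            "ci_low": ci.iloc[:, 0].reindex(tbl.index).to_numpy(),
            "ci_high": ci.iloc[:, 1].reindex(tbl.index).to_numpy(),
        }))
    if not frames:
        raise ValueError("no non-empty groups")
    table = pd.concat(frames, ignore_index=True)
    used = labels.dropna()
    sub = clinical.df.loc[used.index]
    if used.nunique() > 1:
        res = multivariate_logrank_test(sub["time_years"], used, sub["event"])
        p = float(res.p_value)
    else:
        p = float("nan")
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table, p
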