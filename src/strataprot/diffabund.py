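"""Empirical-Bayes moderated two-group differential abundance.

Per protein, a pooled (equal-variance) two-sample model is fitted on the
complete cases of a contrast: ``log2fc`` is the difference of group means
on the log2 scale, ``s2`` the pooled residual variance with
``df = n_used - 2``. Across proteins a scaled inverse-chi-square prior
(d0, s0^2) is fitted to the variances by the method of moments on
log-variances, and each protein's variance is shrunk to the posterior

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df)

giving the moderated statistic ``t = log2fc / (s_tilde * sqrt(1/n_t + 1/n_r))``
referred to a t distribution with ``df + d0`` degrees of freedom
(standard normal when d0 is infinite). Benjamini-Hochberg correction and
FDR/fold-change calling produce the differentially-abundant-protein (DAP)
tables; proteins with fewer than two present values on either side are
reported as untestable, never dropped.

The prior is fitted separately per comparison: each contrast restricts to
a different stage stratum with different samples and missingness, so the
variance population differs between contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .comparisons import ComparisonSpec, full_comparison_plan
from .data_io import AbundanceMatrix, SampleMetadata, ValidationError

logger = logging.getLogger("strataprot")

DA_COLUMNS = ["protein_id", "log2fc", "t_mod", "df_total", "p", "q", "call",
              "n_target_used", "n_reference_used"]


@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square variance prior: d0 = prior degrees of
    freedom (may be ``inf``), s0_sq = prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("prior degrees of freedom must be >= 0")
        if not self.s0_sq > 0:
            raise ValidationError("prior variance must be > 0")


# ---------------------------------------------------------------------------
# per-protein two-group fits
# ---------------------------------------------------------------------------

def per_protein_two_group_fit(values: pd.DataFrame, target_ids: Sequence[str],
                              reference_ids: Sequence[str]) -> pd.DataFrame:
    """Complete-case pooled two-group fit for every protein (vectorized).

    Returns a frame indexed by protein with columns log2fc, s2, df,
    n_target_used, n_reference_used, testable. A protein is testable iff
    both sides have >= 2 present values.
    """
    t = values.loc[:, list(target_ids)].to_numpy()
    r = values.loc[:, list(reference_ids)].to_numpy()
    if t.shape[1] == 0 or r.shape[1] == 0:
        raise ValidationError("empty target or reference sample set")
    n_t = np.sum(~np.isnan(t), axis=1)
    n_r = np.sum(~np.isnan(r), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m_t = np.nansum(t, axis=1) / np.where(n_t > 0, n_t, np.nan)
        m_r = np.nansum(r, axis=1) / np.where(n_r > 0, n_r, np.nan)
        ss_t = np.nansum((t - m_t[:, None]) ** 2, axis=1)
        ss_r = np.nansum((r - m_r[:, None]) ** 2, axis=1)
    df = n_t + n_r - 2
    testable = (n_t >= 2) & (n_r >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df > 0, (ss_t + ss_r) / np.maximum(df, 1), np.nan)
    out = pd.DataFrame({
        "log2fc": m_t - m_r, "s2": s2, "df": df.astype(float),
        "n_target_used": n_t, "n_reference_used": n_r, "testable": testable,
    }, index=values.index)
    out.loc[~testable, ["log2fc", "s2", "df"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-10:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Method-of-moments fit of the (d0, s0^2) prior on log variances.

    Uses the bias-corrected log variances
    ``e = log(s2) - digamma(df/2) + log(df/2)`` whose model mean is
    ``log(s0^2) + digamma(d0/2) - log(d0/2)`` and whose excess variance
    over the chi-square sampling term ``trigamma(df/2)`` equals
    ``trigamma(d0/2)``. When the observed dispersion of e is at or below
    the sampling term, d0 is infinite (no protein-to-protein variance
    heterogeneity beyond sampling noise).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & np.isfinite(df) & (df > 0) & (s2 >= 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 10:
        raise ValidationError(
            f"need >= 10 testable proteins to fit the variance prior, got {s2.size}")
    if np.all(s2 == 0):
        raise ValidationError("all residual variances are exactly zero; "
                              "cannot fit a variance prior")
    if np.any(s2 == 0):
        # zero variances carry no log information; nudge to smallest positive
        s2 = np.where(s2 == 0, s2[s2 > 0].min() * 1e-2, s2)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if np.ptp(e) == 0.0:
        # degenerate: identical variances -> no shrinkage target dispersion;
        # the common value is the exact prior variance
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(np.mean(z))))
    evar = float(np.sum((e - emean) ** 2) / (e.size - 1))
    evar -= float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(log2fc: np.ndarray, s2: np.ndarray, df: np.ndarray,
                params: ModerationParams, n_target: np.ndarray,
                n_reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t statistic, total df and two-sided p for each protein.

    d0 = 0 reduces to the ordinary pooled two-sample t; d0 = inf shrinks
    every variance fully to s0^2 and uses the standard normal reference.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    n_t = np.asarray(n_target, dtype=float)
    n_r = np.asarray(n_reference, dtype=float)
    if np.isinf(params.d0):
        s_tilde2 = np.full_like(s2, params.s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s_tilde2 = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        df_total = df + params.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s_tilde2 * (1.0 / n_t + 1.0 / n_r))
        t = log2fc / se
    # zero posterior variance with zero difference is "no evidence", not infinite
    t = np.where((se == 0) & (log2fc == 0), 0.0, t)
    p = np.where(np.isinf(df_total),
                 2.0 * stats.norm.sf(np.abs(t)),
                 2.0 * stats.t.sf(np.abs(t), np.maximum(df_total, 1e-300)))
    return t, df_total, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to BH adjustment")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_daps(table: pd.DataFrame, fdr_threshold: float = 0.05,
              fc_threshold: float = 1.5, fc_scale: str = "linear") -> pd.DataFrame:
    """Add up/down/ns calls from the FDR and fold-change thresholds.

    ``fc_scale="linear"`` interprets the threshold as a linear fold change
    (|log2fc| must exceed log2(fc_threshold)); ``"log2"`` applies it to
    log2fc directly. Untestable rows keep their 'untestable' call.
    """
    if fc_scale not in ("linear", "log2"):
        raise ValueError(f"fc_scale must be 'linear' or 'log2', got {fc_scale!r}")
    cut = np.log2(fc_threshold) if fc_scale == "linear" else fc_threshold
    out = table.copy()
    testable = out["call"] != "untestable" if "call" in out else pd.Series(True, index=out.index)
    sig = (out["q"] < fdr_threshold) & testable
    call = np.where(sig & (out["log2fc"] > cut), "up",
                    np.where(sig & (out["log2fc"] < -cut), "down", "ns"))
    out["call"] = np.where(testable, call, "untestable")
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-group test as a fit(X, y) estimator.

    Parameters
    ----------
    fdr_threshold, fc_threshold, fc_scale
        Calling thresholds (FDR < 0.05 and linear fold change > 1.5 /
        < 1/1.5 by default).
    d0 : optional float
        Fix the prior degrees of freedom instead of estimating them
        (0 = ordinary pooled t-test; mainly for validation).

    ``fit(X, y)`` takes samples x proteins and binary labels
    (1 = target, 0 = reference). Fitted attributes: ``log2fc_``, ``s2_``,
    ``df_residual_``, ``t_``, ``df_total_``, ``p_``, ``q_``,
    ``testable_``, ``d0_``, ``s0_sq_``, and ``results_`` (the DAP table).
    """

    def __init__(self, fdr_threshold: float = 0.05, fc_threshold: float = 1.5,
                 fc_scale: str = "linear", d0: float | None = None):
        self.fdr_threshold = fdr_threshold
        self.fc_threshold = fc_threshold
        self.fc_scale = fc_scale
        self.d0 = d0

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValidationError(f"need exactly two classes, got {classes.tolist()}")
        pos = classes.max()
        target = X.index[y == pos]
        reference = X.index[y != pos]
        fits = per_protein_two_group_fit(X.T, list(target), list(reference))

        ok = fits["testable"].to_numpy()
        if self.d0 is not None:
            if self.d0 == 0:
                params = ModerationParams(d0=0.0, s0_sq=1.0)  # s0 unused at d0=0
            else:
                est = estimate_moderation(fits.loc[ok, "s2"], fits.loc[ok, "df"])
                params = ModerationParams(d0=self.d0, s0_sq=est.s0_sq)
        else:
            params = estimate_moderation(fits.loc[ok, "s2"], fits.loc[ok, "df"])

        n = len(fits)
        t = np.full(n, np.nan)
        dft = np.full(n, np.nan)
        p = np.full(n, np.nan)
        t[ok], dft[ok], p[ok] = moderated_t(
            fits.loc[ok, "log2fc"], fits.loc[ok, "s2"], fits.loc[ok, "df"],
            params, fits.loc[ok, "n_target_used"], fits.loc[ok, "n_reference_used"])
        q = np.full(n, np.nan)
        if ok.any():
            q[ok] = bh_adjust(p[ok])

        self.d0_ = params.d0
        self.s0_sq_ = params.s0_sq
        self.log2fc_ = fits["log2fc"].to_numpy()
        self.s2_ = fits["s2"].to_numpy()
        self.df_residual_ = fits["df"].to_numpy()
        self.testable_ = ok
        self.t_ = t
        self.df_total_ = dft
        self.p_ = p
        self.q_ = q
        res = pd.DataFrame({
            "protein_id": fits.index, "log2fc": self.log2fc_, "t_mod": t,
            "df_total": dft, "p": p, "q": q,
            "call": np.where(ok, "ns", "untestable"),
            "n_target_used": fits["n_target_used"].to_numpy(),
            "n_reference_used": fits["n_reference_used"].to_numpy(),
        })
        self.results_ = call_daps(res, self.fdr_threshold, self.fc_threshold,
                                  self.fc_scale)[DA_COLUMNS]
        return self


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def run_comparison(matrix: AbundanceMatrix, metadata: SampleMetadata,
                   spec: ComparisonSpec, fdr_threshold: float = 0.05,
                   fc_threshold: float = 1.5, fc_scale: str = "linear",
                   min_side: int = 3) -> pd.DataFrame | None:
    """One contrast's DAP table, or None if a side is below ``min_side``."""
    if matrix.scale != "log2":
        raise ValidationError("differential abundance requires a log2-scale matrix")
    target, reference = spec.resolve(metadata)
    if len(target) < min_side or len(reference) < min_side:
        logger.warning("comparison %s skipped: sides %d vs %d below minimum %d",
                       spec.label, len(target), len(reference), min_side)
        return None
    X = matrix.values.loc[:, target + reference].T
    y = np.r_[np.ones(len(target)), np.zeros(len(reference))]
    est = ModeratedTTest(fdr_threshold=fdr_threshold, fc_threshold=fc_threshold,
                         fc_scale=fc_scale).fit(X, y)
    res = est.results_.copy()
    res.attrs["label"] = spec.label
    res.attrs["d0"] = est.d0_
    res.attrs["s0_sq"] = est.s0_sq_
    return res


def run_all_comparisons(matrix: AbundanceMatrix, metadata: SampleMetadata,
                        plan: Sequence[ComparisonSpec] | None = None,
                        fdr_threshold: float = 0.05, fc_threshold: float = 1.5,
                        fc_scale: str = "linear", min_side: int = 3,
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Run the full stratified plan; returns per-label tables and a summary.

    The variance prior is estimated per comparison. The summary counts
    up/down DAPs, testable and untestable proteins per comparison; skipped
    comparisons (a side smaller than ``min_side``) appear with
    ``skipped=True``.
    """
    if plan is None:
        plan = full_comparison_plan()
    tables: dict[str, pd.DataFrame] = {}
    rows = []
    for spec in plan:
        res = run_comparison(matrix, metadata, spec, fdr_threshold, fc_threshold,
                             fc_scale, min_side)
        if res is None:
            rows.append((spec.label, spec.kind, 0, 0, 0, 0, 0, True))
            continue
        tables[spec.label] = res
        counts = res["call"].value_counts()
        n_up, n_down = int(counts.get("up", 0)), int(counts.get("down", 0))
        rows.append((spec.label, spec.kind, n_up, n_down, n_up + n_down,
                     int((res["call"] != "untestable").sum()),
                     int((res["call"] == "untestable").sum()), False))
    summary = pd.DataFrame(rows, columns=["comparison", "kind", "n_up", "n_down",
                                          "n_dap", "n_testable", "n_untestable",
                                          "skipped"])
    return tables, summary
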