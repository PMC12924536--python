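"""Proteome-wide prognostic screening within histotype / stage-group strata.

For one endpoint (overall or disease-specific survival) and one
(histotype, stage-group) stratum:

1. a LASSO-penalized Cox model over all proteins plus the age and
   sub-stage covariates picks the features with non-zero coefficients
   (penalty chosen by cross-validated held-out partial log-likelihood);
2. each screened protein is median-dichotomized (high/low log2 abundance
   within the stratum) and fitted in a Cox proportional-hazards model
   adjusted for whichever covariates the LASSO retained, giving the
   hazard ratio, 95% Wald CI, Wald p and concordance index;
3. Wald p-values are BH-adjusted across the screen;
4. model robustness is assessed by refitting on bootstrap resamples of
   patients and averaging the abundance-coefficient Wald p-values
   ("bootstrap p-value");
5. a protein is called prognostic when FDR < 0.05, bootstrap p < 0.2 and
   the CI does not span 1 (HR < 1 decreased, HR > 1 increased risk).

Per-protein fits use lifelines (Efron tie handling). Kaplan-Meier
summaries with a global log-rank test support the median-dichotomized
survival curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._coxfit import concordance_index, cox_newton, wald_p
from .data_io import AbundanceMatrix, SampleMetadata, ValidationError
from .diffabund import bh_adjust

logger = logging.getLogger("strataprot")

COX_COLUMNS = ["protein_id", "coding", "beta", "hr", "ci_low", "ci_high", "wald_p",
               "fdr", "boot_p", "boot_reliable", "c_index", "n", "n_events",
               "covariates", "call"]


@dataclass(frozen=True)
class SurvivalTask:
    """One screen: endpoint (OS/DSS) within a (histotype, stage-group) stratum."""

    endpoint: str  # "os" | "dss"
    histotype: str
    stage_group: str

    def __post_init__(self) -> None:
        if self.endpoint not in ("os", "dss"):
            raise ValueError("endpoint must be 'os' or 'dss'")

    @property
    def label(self) -> str:
        return f"{self.histotype}_{self.stage_group}_{self.endpoint}"

    def resolve(self, metadata: SampleMetadata) -> tuple[list[str], np.ndarray, np.ndarray]:
        ids = metadata.select(histotype=self.histotype, stage_group=self.stage_group)
        sub = metadata.df.loc[ids]
        time = sub[f"{self.endpoint}_time"].to_numpy(float)
        event = sub[f"{self.endpoint}_event"].to_numpy(int)
        return ids, time, event


def substage_indicator(metadata: SampleMetadata, ids: list[str]) -> np.ndarray:
    """Binary sub-stage within a stage group (II vs I, or IV vs III).

    The coarse early/late group is constant within a screen, so the
    informative stage covariate is the finer split.
    """
    stage = metadata.df.loc[ids, "stage"]
    return stage.isin(["II", "IV"]).to_numpy(int)


# ---------------------------------------------------------------------------
# LASSO-Cox selection
# ---------------------------------------------------------------------------

def _partial_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                    event: np.ndarray) -> float:
    """Breslow partial log-likelihood at fixed coefficients (for CV scoring)."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending time
    eta_o, ev_o = eta[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)  # log sum exp over risk set
    # risk set of subject i = all with time >= t_i; with descending order that
    # is the prefix up to the last subject sharing t_i
    t_o = time[order]
    # map each position to the largest prefix index with the same time
    last_same = np.searchsorted(-t_o, -t_o, side="right") - 1
    ll = np.sum(ev_o * (eta_o - log_cum[last_same]))
    return float(ll)


def lasso_cox_select(X: pd.DataFrame, time: np.ndarray, event: np.ndarray,
                     l1_ratio: float = 1.0, cv: int = 5, n_alphas: int = 30,
                     seed: int = 0) -> list[str]:
    """Features with non-zero coefficients at the CV-optimal LASSO penalty.

    The penalty path comes from a full-data coxnet fit; each fold refits
    the path on the training part and scores every penalty by the
    held-out Breslow partial log-likelihood; the penalty maximizing the
    mean held-out likelihood is kept ("lambda min" under deviance).
    """
    if int(np.sum(event)) < 2:
        raise ValidationError("LASSO-Cox selection needs at least 2 events")
    X = X.astype(float)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Xs, y)
    alphas = path.alphas_

    folds = KFold(n_splits=min(cv, max(2, int(np.sum(event)))), shuffle=True,
                  random_state=seed)
    scores = np.zeros((folds.get_n_splits(), len(alphas)))
    scores[:] = -np.inf
    for k, (tr, te) in enumerate(folds.split(Xs)):
        if np.sum(event[tr]) < 2 or np.sum(event[te]) < 1:
            continue
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                          fit_baseline_model=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold_fit.fit(Xs[tr], y[tr])
        except Exception as exc:  # non-convergence on a fold: skip it, log
            logger.warning("lasso_cox_select: fold %d failed (%s); skipped", k, exc)
            continue
        for j, a in enumerate(fold_fit.alphas_):
            col = np.searchsorted(-alphas, -a)
            if col >= len(alphas):
                continue
            beta = fold_fit.coef_[:, j]
            scores[k, col] = _partial_loglik(beta, Xs[te], time[te], event[te])
    valid = np.isfinite(scores)
    counts = valid.sum(axis=0)
    mean_scores = np.where(counts > 0,
                           np.where(valid, scores, 0.0).sum(axis=0)
                           / np.maximum(counts, 1), -np.inf)
    if np.all(np.isinf(mean_scores)):
        logger.warning("lasso_cox_select: no penalty could be cross-validated; "
                       "falling back to the sparsest non-null path solution")
        best_alpha = alphas[0]
    else:
        best_alpha = alphas[int(np.argmax(mean_scores))]
    coefs = path.coef_[:, int(np.flatnonzero(path.alphas_ == best_alpha)[0])]
    return [c for c, b in zip(X.columns, coefs) if b != 0]


# ---------------------------------------------------------------------------
# per-protein Cox fits
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    wald_p: float
    c_index: float
    n: int
    n_events: int
    covariates: tuple[str, ...]


def fit_cox(time: np.ndarray, event: np.ndarray, abundance: np.ndarray,
            covariates: pd.DataFrame | None = None,
            compute_c_index: bool = True) -> CoxFit | None:
    """Cox PH fit of one protein's (coded) abundance with optional covariates.

    Efron tie handling; the 95% CI is exp(beta +- 1.96 se); the C-index is
    the concordance of the full linear predictor on the fitted data.
    Returns None when the partial likelihood is monotone (perfect
    separation) or otherwise non-estimable; constant covariates are
    dropped with a warning. Solved by the package's Newton-Raphson core
    (cross-checked against lifelines in the test suite), with Wald
    inference on the abundance coefficient.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    abundance = np.asarray(abundance, float)
    cols = [abundance]
    used: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            vals = covariates[c].to_numpy(float)
            if np.ptp(vals) == 0:
                logger.warning("fit_cox: constant covariate %r dropped", c)
                continue
            cols.append(vals)
            used.append(c)
    if np.ptp(abundance) == 0 or event.sum() < 1:
        return None
    X = np.column_stack(cols)
    res = cox_newton(X, time, event)
    if res is None:
        return None
    beta, se = float(res.beta[0]), float(res.se[0])
    z95 = 1.959963984540054
    return CoxFit(beta=beta, hr=float(np.exp(beta)),
                  ci_low=float(np.exp(beta - z95 * se)),
                  ci_high=float(np.exp(beta + z95 * se)),
                  se=se, wald_p=wald_p(res, 0),
                  c_index=(concordance_index(time, res.eta, event)
                           if compute_c_index else np.nan),
                  n=len(time), n_events=int(event.sum()),
                  covariates=tuple(used))


def bootstrap_pvalue(time: np.ndarray, event: np.ndarray, abundance: np.ndarray,
                     covariates: pd.DataFrame | None = None, B: int = 1000,
                     seed: int = 0) -> tuple[float, int, bool]:
    """Mean abundance-coefficient Wald p over B patient resamples.

    Patients are resampled with replacement at the original n; resamples
    where the model does not converge (or the abundance/events become
    degenerate) are skipped and counted. Returns (boot_p, n_converged,
    reliable) with reliable=False when more than half the resamples were
    skipped.
    """
    rng = np.random.default_rng(seed)
    n = len(time)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    abundance = np.asarray(abundance, float)
    cols = [abundance]
    if covariates is not None:
        cols += [covariates[c].to_numpy(float) for c in covariates.columns
                 if np.ptp(covariates[c].to_numpy(float)) > 0]
    X = np.column_stack(cols)
    ps = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        Xb, tb, eb = X[idx], time[idx], event[idx]
        if np.ptp(Xb[:, 0]) == 0 or eb.sum() < 1:
            continue
        keep = [j for j in range(Xb.shape[1]) if np.ptp(Xb[:, j]) > 0]
        res = cox_newton(Xb[:, keep], tb, eb)
        if res is not None:
            ps.append(wald_p(res, 0))
    n_conv = len(ps)
    if n_conv == 0:
        return np.nan, 0, False
    reliable = n_conv >= B / 2
    if not reliable:
        logger.warning("bootstrap_pvalue: only %d/%d resamples converged", n_conv, B)
    return float(np.mean(ps)), n_conv, reliable


# ---------------------------------------------------------------------------
# the proteome screen
# ---------------------------------------------------------------------------

def _composite_call(fdr: float, boot_p: float, ci_low: float, ci_high: float,
                    fdr_threshold: float, boot_threshold: float) -> str:
    if np.isnan(fdr) or np.isnan(boot_p):
        return "ns"
    if fdr < fdr_threshold and boot_p < boot_threshold:
        if ci_high < 1.0:
            return "decreased_risk"
        if ci_low > 1.0:
            return "increased_risk"
    return "ns"


def screen_proteome(matrix: AbundanceMatrix, metadata: SampleMetadata,
                    task: SurvivalTask, fdr_threshold: float = 0.05,
                    boot_threshold: float = 0.2, B: int = 1000, seed: int = 0,
                    min_presence: float = 0.7,
                    abundance_coding: str = "dichotomized_median",
                    restrict_to_lasso: bool = False,
                    force_covariates: bool = False,
                    bootstrap_all_threshold: int = 500) -> pd.DataFrame:
    """Run the full prognostic screen for one stratum and endpoint.

    ``abundance_coding`` is ``"dichotomized_median"`` (high vs low within
    the stratum; the published default) or ``"continuous"`` (standardized
    log2 abundance). By default every adequately-present protein is fitted
    and enters one BH family, with the LASSO step deciding only which
    covariates (age, sub-stage) the models retain; ``restrict_to_lasso``
    instead limits the screen and the FDR family to the LASSO-selected
    proteins — that variant inherits a post-selection optimism (the same
    data pick the family and supply the p-values), which inflates the
    false-call rate under the null, so it is opt-in.
    Bootstrap p-values are computed for every fitted protein when the
    screen is small (< ``bootstrap_all_threshold``), else only for
    FDR-passing proteins — final calls are unchanged because the
    composite rule requires both.
    """
    if matrix.scale != "log2":
        raise ValidationError("survival screen requires a log2-scale matrix")
    if abundance_coding not in ("dichotomized_median", "continuous"):
        raise ValueError(f"unknown abundance coding {abundance_coding!r}")
    ids, time, event = task.resolve(metadata)
    if len(ids) == 0 or event.sum() < 1:
        logger.warning("screen %s: no samples or no events; empty table", task.label)
        return pd.DataFrame(columns=COX_COLUMNS)

    sub = matrix.values.loc[:, ids]
    presence = sub.notna().mean(axis=1)
    proteins = [p for p in sub.index
                if presence[p] >= min_presence and np.nanstd(sub.loc[p]) > 0]
    n_skipped = matrix.n_proteins - len(proteins)
    if n_skipped:
        logger.info("screen %s: %d proteins skipped (presence < %.2f or constant)",
                    task.label, n_skipped, min_presence)
    if not proteins:
        return pd.DataFrame(columns=COX_COLUMNS)

    covs = pd.DataFrame({"age": metadata.df.loc[ids, "age"].to_numpy(float),
                         "substage": substage_indicator(metadata, ids)},
                        index=ids)
    design = pd.concat([sub.loc[proteins].T.fillna(sub.loc[proteins].T.mean()), covs],
                       axis=1)
    design = design.loc[:, design.std() > 0]
    try:
        selected = lasso_cox_select(design, time, event, seed=seed)
    except ValidationError as exc:
        logger.warning("screen %s: LASSO step failed (%s); screening all proteins",
                       task.label, exc)
        selected = list(proteins)
    retained_covs = [c for c in ("age", "substage") if c in selected]
    if force_covariates:
        retained_covs = [c for c in ("age", "substage") if c in design.columns]
    screen_set = [p for p in selected if p in set(proteins)]
    if not restrict_to_lasso or not screen_set:
        screen_set = list(proteins)
    cov_df = covs[retained_covs] if retained_covs else None

    rows = []
    rng = np.random.default_rng(seed)
    boot_seeds = {}
    for prot in screen_set:
        vals = sub.loc[prot]
        present = vals.dropna()
        keep = list(present.index)
        if abundance_coding == "dichotomized_median":
            coded = (present > present.median()).astype(float)
        else:
            coded = (present - present.mean()) / present.std()
        cov_k = None if cov_df is None else cov_df.loc[keep]
        t_k = metadata.df.loc[keep, f"{task.endpoint}_time"].to_numpy(float)
        e_k = metadata.df.loc[keep, f"{task.endpoint}_event"].to_numpy(int)
        boot_seeds[prot] = int(rng.integers(2 ** 31))
        fit = fit_cox(t_k, e_k, coded.to_numpy(), cov_k)
        rows.append((prot, fit, keep, coded, cov_k, t_k, e_k))

    fitted = [r for r in rows if r[1] is not None]
    n_failed = len(rows) - len(fitted)
    if n_failed:
        logger.info("screen %s: %d proteins non-estimable, excluded from FDR",
                    task.label, n_failed)
    if not fitted:
        return pd.DataFrame(columns=COX_COLUMNS)
    fdr = bh_adjust(np.array([r[1].wald_p for r in fitted]))

    boot_all = len(fitted) < bootstrap_all_threshold
    out = []
    for (prot, fit, keep, coded, cov_k, t_k, e_k), q in zip(fitted, fdr):
        if boot_all or q < fdr_threshold:
            boot_p, n_conv, reliable = bootstrap_pvalue(
                t_k, e_k, coded.to_numpy(), cov_k, B=B, seed=boot_seeds[prot])
        else:
            boot_p, reliable = np.nan, False
        call = _composite_call(q, boot_p, fit.ci_low, fit.ci_high,
                               fdr_threshold, boot_threshold)
        out.append((prot, abundance_coding, fit.beta, fit.hr, fit.ci_low,
                    fit.ci_high, fit.wald_p, q, boot_p, reliable, fit.c_index,
                    fit.n, fit.n_events, ";".join(fit.covariates), call))
    res = pd.DataFrame(out, columns=COX_COLUMNS)
    res.attrs["task"] = task.label
    res.attrs["n_non_estimable"] = n_failed
    res.attrs["retained_covariates"] = retained_covs
    return res


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMSummary:
    """Per-group product-limit curves and the global log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> (time, survival, at_risk)
    logrank_p: float
    logrank_stat: float
    group_sizes: dict[str, int]


def km_logrank(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> KMSummary:
    """Kaplan-Meier estimate per group plus the global log-rank p-value."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    nonempty = [g for g in labels if np.sum(groups == g) > 0]
    if len(nonempty) < len(labels):
        logger.warning("km_logrank: dropped empty groups")
    if len(nonempty) < 2:
        raise ValidationError("log-rank needs at least 2 non-empty groups")
    curves = {}
    sizes = {}
    for g in nonempty:
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m])
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        curves[str(g)] = pd.DataFrame({"time": sf.index.to_numpy(),
                                       "survival": sf.to_numpy(),
                                       "at_risk": at_risk.to_numpy()})
        sizes[str(g)] = int(m.sum())
    mask = np.isin(groups, nonempty)
    res = multivariate_logrank_test(time[mask], groups[mask], event[mask])
    return KMSummary(curves=curves, logrank_p=float(res.p_value),
                     logrank_stat=float(res.test_statistic), group_sizes=sizes)


def km_by_median_abundance(matrix: AbundanceMatrix, metadata: SampleMetadata,
                           task: SurvivalTask, protein_id: str) -> KMSummary:
    """High/low KM summary for one protein, dichotomized at the stratum median."""
    ids, _, _ = task.resolve(metadata)
    vals = matrix.values.loc[protein_id, ids].dropna()
    keep = list(vals.index)
    groups = np.where(vals > vals.median(), "high", "low")
    t = metadata.df.loc[keep, f"{task.endpoint}_time"].to_numpy(float)
    e = metadata.df.loc[keep, f"{task.endpoint}_event"].to_numpy(int)
    return km_logrank(t, e, groups)


def all_survival_tasks(endpoints=("os", "dss")) -> list[SurvivalTask]:
    from .data_io import HISTOTYPES
    return [SurvivalTask(ep, h, sg) for ep in endpoints for h in HISTOTYPES
            for sg in ("early", "late")]
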