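"""Cox proportional-hazards gene selection, risk scoring and KM stratification.

Gene screening uses a vectorized single-covariate Newton solver for the Cox
partial likelihood with Efron's tie correction — the screening step runs
over hundreds of genes inside a tuning loop, so all genes are fitted
simultaneously on numpy arrays. The joint (multivariate) model, Kaplan-Meier
curves and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """A Cox gene signature: per-gene coefficients plus a risk-score cutoff."""

    gene_ids: list
    betas: np.ndarray
    cutoff: float | None = None
    fit_mode: str = "standard"          # or "penalized"
    penalty: float | None = None
    p_values: np.ndarray | None = None

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.gene_ids) != len(self.betas):
            raise ValueError("one beta per signature gene required")

    def to_json(self, path):
        payload = {
            "gene_ids": list(self.gene_ids),
            "betas": self.betas.tolist(),
            "cutoff": self.cutoff,
            "fit_mode": self.fit_mode,
            "penalty": self.penalty,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["gene_ids"], np.array(d["betas"]), d["cutoff"], d["fit_mode"], d.get("penalty"))


# ---------------------------------------------------------------------------
# univariate screening (vectorized Newton, Efron ties)
# ---------------------------------------------------------------------------

def _efron_blocks(os_days, event):
    """Sort samples by descending time and index the tied death blocks."""
    os_days = np.asarray(os_days, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-os_days, kind="mergesort")
    t = os_days[order]
    e = event[order]
    blocks = []  # (risk_end, death_idx) per distinct event time, descending t
    for ut in np.unique(t)[::-1]:
        idx = np.where(t == ut)[0]
        deaths = idx[e[idx] == 1]
        if deaths.size:
            blocks.append((idx[-1] + 1, deaths))
    return order, blocks


def _cox_score_hessian(beta, Z, blocks):
    """Score and Hessian of the Efron partial log-likelihood, per gene.

    Z is (genes, samples) in descending-time order; beta is (genes,).
    """
    eta = beta[:, None] * Z
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wz = w * Z
    wzz = wz * Z
    cw = np.cumsum(w, axis=1)
    cwz = np.cumsum(wz, axis=1)
    cwzz = np.cumsum(wzz, axis=1)

    score = np.zeros(beta.shape[0])
    hess = np.zeros(beta.shape[0])
    loglik = np.zeros(beta.shape[0])
    for risk_end, deaths in blocks:
        d = deaths.size
        S0 = cw[:, risk_end - 1]
        S1 = cwz[:, risk_end - 1]
        S2 = cwzz[:, risk_end - 1]
        D0 = w[:, deaths].sum(axis=1)
        D1 = wz[:, deaths].sum(axis=1)
        D2 = wzz[:, deaths].sum(axis=1)
        zsum = Z[:, deaths].sum(axis=1)
        score += zsum
        loglik += eta[:, deaths].sum(axis=1)
        for l in range(d):
            frac = l / d
            phi0 = S0 - frac * D0
            phi1 = S1 - frac * D1
            phi2 = S2 - frac * D2
            score -= phi1 / phi0
            hess -= phi2 / phi0 - (phi1 / phi0) ** 2
            loglik -= np.log(phi0)
    return loglik, score, hess


def efron_partial_loglik(beta, z, os_days, event):
    """Efron partial log-likelihood of a single covariate at a given beta."""
    order, blocks = _efron_blocks(os_days, event)
    z = np.asarray(z, dtype=float)[order][None, :]
    ll, _, _ = _cox_score_hessian(np.atleast_1d(float(beta)), z, blocks)
    return float(ll[0])


def univariate_cox(
    expr: pd.DataFrame,
    os_days,
    event,
    alpha: float = 0.05,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Single-gene Cox fits for every row of a genes x samples frame.

    Returns a DataFrame with columns gene_id, coef, hazard_ratio, se,
    p_value (Wald) and selected (p < alpha). Genes with a constant
    expression value, or whose fit does not converge, are skipped with a
    warning (NaN coefficients, selected=False).
    """
    os_days = np.asarray(os_days, dtype=float)
    event = np.asarray(event, dtype=int)
    if expr.shape[1] != os_days.size:
        raise ValueError("expression columns must match survival-data length")
    if event.sum() < 2:
        raise ValueError("need at least 2 events for Cox regression")

    order, blocks = _efron_blocks(os_days, event)
    Zall = expr.to_numpy(dtype=float)[:, order]
    # center covariates for numerical stability (shift leaves beta unchanged)
    Zall = Zall - Zall.mean(axis=1, keepdims=True)
    sd = Zall.std(axis=1)
    degenerate = sd == 0

    G = Zall.shape[0]
    beta = np.zeros(G)
    active = ~degenerate
    for _ in range(max_iter):
        if not active.any():
            break
        _, score, hess = _cox_score_hessian(beta[active], Zall[active], blocks)
        step = score / np.where(hess < -1e-12, -hess, np.inf)
        step = np.clip(step, -2.0, 2.0)
        beta[active] += step
        done = np.abs(step) < tol
        idx = np.where(active)[0]
        active[idx[done]] = False

    nonconv = active | degenerate | ~np.isfinite(beta) | (np.abs(beta) > 100)
    if nonconv.any() and not degenerate.all():
        n_deg = int(degenerate.sum())
        n_fail = int(nonconv.sum()) - n_deg
        if n_deg:
            logger.warning("univariate_cox: skipped %d constant genes", n_deg)
        if n_fail > 0:
            logger.warning("univariate_cox: %d gene fits did not converge; skipped", n_fail)

    _, _, hess = _cox_score_hessian(np.where(nonconv, 0.0, beta), Zall, blocks)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(hess < -1e-300, 1.0 / np.sqrt(np.abs(hess)), np.nan)
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    beta = np.where(nonconv, np.nan, beta)
    pvals = np.where(nonconv, np.nan, pvals)
    se = np.where(nonconv, np.nan, se)
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "coef": beta,
            "hazard_ratio": np.exp(beta),
            "se": se,
            "p_value": pvals,
            "selected": pvals < alpha,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# multivariate signature
# ---------------------------------------------------------------------------

def _fit_cph(df, penalizer=0.0):
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="os_days", event_col="event")
    return cph


def multivariate_cox(
    expr: pd.DataFrame,
    os_days,
    event,
    alpha: float = 0.05,
    penalties=(0.01, 0.1, 1.0),
    cv_folds: int = 3,
    random_state: int = 0,
) -> RiskModel:
    """Joint Cox fit over the univariately selected genes.

    Genes with joint Wald p < alpha form the signature; betas come from a
    refit on that subset. If the standard fit fails to converge or produces
    non-finite standard errors, the model falls back to ridge-penalized
    partial likelihood with the penalty chosen by cross-validated partial
    log-likelihood; in that mode all provided genes are kept (penalized
    Wald p-values are not trustworthy for pruning).
    """
    genes = list(expr.index)
    if not genes:
        raise ValueError("no genes provided to the multivariate fit")
    df = expr.T.copy()
    df["os_days"] = np.asarray(os_days, dtype=float)
    df["event"] = np.asarray(event, dtype=int)

    def try_standard(frame):
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph = _fit_cph(frame)
        se = cph.standard_errors_
        if not (np.isfinite(cph.params_).all() and np.isfinite(se).all()):
            raise ConvergenceError("non-finite coefficients or standard errors")
        return cph

    try:
        cph = try_standard(df)
    except (ConvergenceError, ConvergenceWarning, Exception) as exc:  # lifelines raises various
        if not isinstance(exc, (ConvergenceError, ConvergenceWarning, np.linalg.LinAlgError, ValueError)):
            raise
        logger.warning("multivariate Cox did not converge (%s); using penalized fallback", type(exc).__name__)
        best = None
        for lam in penalties:
            ll = _cv_partial_loglik(df, lam, cv_folds, random_state)
            if best is None or ll > best[0]:
                best = (ll, lam)
        lam = best[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = _fit_cph(df, penalizer=lam)
        return RiskModel(genes, cph.params_.loc[genes].to_numpy(), fit_mode="penalized",
                         penalty=lam, p_values=cph.summary["p"].loc[genes].to_numpy())

    pvals = cph.summary["p"]
    keep = [g for g in genes if pvals.loc[g] < alpha]
    if not keep:
        raise ValueError(
            "no gene reached joint significance; consider a larger cohort or a different endpoint"
        )
    if len(keep) < len(genes):
        refit_df = df[keep + ["os_days", "event"]]
        try:
            cph = try_standard(refit_df)
        except Exception:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = _fit_cph(refit_df, penalizer=penalties[0])
    return RiskModel(keep, cph.params_.loc[keep].to_numpy(), fit_mode="standard",
                     p_values=cph.summary["p"].loc[keep].to_numpy())


def _cv_partial_loglik(df, penalizer, folds, random_state):
    rng = np.random.default_rng(random_state)
    idx = rng.permutation(len(df))
    parts = np.array_split(idx, folds)
    total = 0.0
    for k in range(folds):
        test = df.iloc[parts[k]]
        train = df.iloc[np.concatenate([parts[j] for j in range(folds) if j != k])]
        if test["event"].sum() == 0 or train["event"].sum() < 2:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = _fit_cph(train, penalizer=penalizer)
                total += cph.score(test, scoring_method="log_likelihood") * len(test)
        except Exception:
            total += -np.inf
    return total


# ---------------------------------------------------------------------------
# risk scores, cutoff, stratification, KM
# ---------------------------------------------------------------------------

def risk_score(model: RiskModel, expr: pd.DataFrame) -> np.ndarray:
    """Linear predictor sum_i beta_i * x_i for each sample (columns of expr)."""
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"expression values missing for signature genes: {missing[:5]}")
    X = expr.loc[list(model.gene_ids)].to_numpy(dtype=float)
    return model.betas @ X


def choose_cutoff_roc(scores, labels) -> float:
    """ROC-optimal cutoff by Youden's J with strict '>' classification.

    Every observed score is a candidate threshold t; a sample is called
    positive when its score exceeds t. The t maximizing
    sensitivity + specificity - 1 is returned, ties resolved toward the
    lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) != 2:
        raise ValueError("both classes required to choose a cutoff")
    uniq = np.unique(scores)
    if uniq.size == 1:
        raise ValueError("constant scores; no informative cutoff exists")
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    # candidates: each unique score and one value below the minimum
    cands = np.concatenate([[uniq[0] - 1.0], uniq])
    sens = 1.0 - np.searchsorted(pos, cands, side="right") / pos.size
    spec = np.searchsorted(neg, cands, side="right") / neg.size
    J = sens + spec - 1.0
    return float(cands[np.argmax(J)])  # argmax takes the first (lowest) maximizer


def stratify(scores, cutoff: float) -> np.ndarray:
    """1 = high risk where score > cutoff (strictly), else 0."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return (np.asarray(scores, dtype=float) > cutoff).astype(int)


@dataclass
class KMResult:
    curves: dict            # group -> DataFrame(time, survival)
    medians: dict           # group -> median survival (inf if never reached)
    statistic: float
    p_value: float


def km_logrank(groups, os_days, event) -> KMResult:
    """Kaplan-Meier curves per group, medians, and the two-group log-rank test."""
    groups = np.asarray(groups, dtype=int)
    os_days = np.asarray(os_days, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two non-empty groups required")
    curves, medians = {}, {}
    for g in labels:
        m = groups == g
        if event[m].sum() == 0:
            logger.warning("km_logrank: group %s has zero events", g)
        kmf = KaplanMeierFitter()
        kmf.fit(os_days[m], event[m])
        sf = kmf.survival_function_
        curves[int(g)] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
        medians[int(g)] = float(kmf.median_survival_time_)
    res = logrank_test(os_days[groups == labels[0]], os_days[groups == labels[1]],
                       event_observed_A=event[groups == labels[0]],
                       event_observed_B=event[groups == labels[1]])
    return KMResult(curves, medians, float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# top-n tuning
# ---------------------------------------------------------------------------

def tune_top_n(
    expr: pd.DataFrame,
    score_table: pd.DataFrame,
    os_days,
    event,
    labels,
    grid=tuple(range(100, 1001, 100)),
    inner_fraction: float = 0.7,
    random_state: int = 0,
    alpha: float = 0.05,
) -> int:
    """Pick the score-ranked gene-list size n maximizing inner-validation AUC.

    For each n in the grid the univariate -> multivariate -> risk-score chain
    is fitted on an inner split of the provided (training) cohort and scored
    by AUC against the binary endpoint labels on the inner validation part.
    Grid values that fail to produce a signature are skipped; ties go to the
    smallest n.
    """
    from .metrics import auc
    from .scoring import top_n_genes

    os_days = np.asarray(os_days, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels, dtype=int)
    n = expr.shape[1]
    rng = np.random.default_rng(random_state)
    n_inner = int(np.floor(inner_fraction * n))
    for _ in range(100):
        perm = rng.permutation(n)
        tr, va = perm[:n_inner], perm[n_inner:]
        if len(set(labels[tr])) == 2 and len(set(labels[va])) == 2 and event[tr].sum() >= 2:
            break
    else:
        raise RuntimeError("could not draw an inner split with both classes")

    best = None
    for n_genes in grid:
        if n_genes > len(score_table):
            continue
        try:
            genes = top_n_genes(score_table, n_genes)
            sub = expr.loc[genes]
            uni = univariate_cox(sub.iloc[:, tr], os_days[tr], event[tr], alpha=alpha)
            sel = uni.loc[uni["selected"], "gene_id"].tolist()
            if not sel:
                raise ValueError("no univariately significant gene")
            model = multivariate_cox(sub.loc[sel].iloc[:, tr], os_days[tr], event[tr],
                                     alpha=alpha, random_state=random_state)
            val_auc = auc(labels[va], risk_score(model, sub.iloc[:, va]))
        except (ValueError, RuntimeError) as exc:
            logger.info("tune_top_n: n=%d failed (%s)", n_genes, exc)
            continue
        if best is None or val_auc > best[0]:
            best = (val_auc, n_genes)
    if best is None:
        raise ValueError("every candidate n failed to yield a signature")
    return best[1]
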