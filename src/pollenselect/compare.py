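"""Covariate-controlled group comparison machinery.

The comparison of a selection statistic (dN/dS, θ_n, π_n, deleterious-
allele frequency) between two gene groups proceeds in three layers:

1. a two-sided Mann-Whitney U test with Bonferroni correction over the
   declared test family;
2. a principal-component regression (PCR) of the log statistic on the six
   log-transformed genomic covariates, with a leave-one-out jackknife
   significance test per predictor and iterative pruning of
   nonsignificant predictors;
3. an ANCOVA of the log statistic on the best-explaining principal
   component crossed with group membership; when the slopes differ
   significantly, the Mann-Whitney comparison is repeated within five
   equal-count bins along the component axis.

Partial Spearman correlations (rank residual correlations) quantify each
covariate's marginal association with the statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

#: log offsets the length-type covariates receive before transformation
DEFAULT_LOG_OFFSETS = {"gene_length": 1e-4, "avg_intron_length": 1e-4}


def bonferroni(p: float, family_size: int) -> float:
    return min(1.0, p * family_size)


def mann_whitney_bonferroni(
    values_a: Sequence[float],
    values_b: Sequence[float],
    family_size: int = 1,
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with Bonferroni adjustment.

    Returns (U, raw p, adjusted p).  Exact p for small tie-free samples,
    normal approximation otherwise (scipy's automatic switch).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(a.size * b.size / 2), 1.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue), bonferroni(float(res.pvalue), family_size)


# ---------------------------------------------------------------------------
# partial Spearman
# ---------------------------------------------------------------------------


def _rank_residuals(r: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(r)), controls])
    beta, *_ = np.linalg.lstsq(design, r, rcond=None)
    return r - design @ beta


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    controls: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Spearman rank partial correlation of x and y given controls.

    Implemented as the Pearson correlation of the residuals of the ranks
    of x and y after linear regression on the ranks of the controls;
    p from the t distribution with n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: partial correlation undefined")
    if controls is None:
        k = 0
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    C = np.asarray(controls, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    k = C.shape[1]
    n = len(x)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} controls")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([stats.rankdata(C[:, j]) for j in range(k)])
    ex = _rank_residuals(rx, rc)
    ey = _rank_residuals(ry, rc)
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - k
    t = rho * math.sqrt(df / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


# ---------------------------------------------------------------------------
# principal-component regression with jackknife pruning
# ---------------------------------------------------------------------------


@dataclass
class PCRModel:
    dependent: str
    predictors: list[str]
    log_offsets: dict[str, float]
    dependent_offset: float
    loadings: pd.DataFrame  # predictors x components, final model
    explained_pct: np.ndarray  # per-component % of dependent variance
    selected_component: int  # 0-based index of the best-explaining PC
    jackknife_p: dict[str, float]
    pruning_history: list[dict] = field(default_factory=list)
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    index: np.ndarray = field(default_factory=lambda: np.array([]))
    y_log: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def total_explained_pct(self) -> float:
        return float(self.explained_pct.sum())


def _log_transform(
    y: pd.Series, X: pd.DataFrame, log_offsets: Mapping[str, float]
) -> tuple[np.ndarray, pd.DataFrame, float, np.ndarray]:
    """Log-transform dependent and predictors; zero dependent values are
    offset by half the smallest positive observed value."""
    y = y.astype(float)
    dep_offset = 0.0
    if (y <= 0).any():
        positive = y[y > 0]
        if positive.empty:
            raise ValueError("dependent variable has no positive values")
        dep_offset = float(positive.min()) / 2.0
    y_log = np.log(y + dep_offset)
    X_log = pd.DataFrame(index=X.index)
    for col in X.columns:
        off = log_offsets.get(col, 0.0)
        with np.errstate(divide="ignore"):
            X_log[col] = np.log(X[col].astype(float) + off)
    ok = np.isfinite(y_log) & np.isfinite(X_log).all(axis=1)
    return y_log[ok.values], X_log.loc[ok.values], dep_offset, ok.values


def _pcr_fit(y_log: np.ndarray, X_log: pd.DataFrame):
    """Standardise predictors, PCA by SVD, regress the dependent on each
    orthogonal component.  Returns (loadings, explained %, slopes, scores)."""
    Xs = (X_log - X_log.mean()) / X_log.std(ddof=1)
    U, s, Vt = np.linalg.svd(Xs.values, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
    scores = Xs.values @ Vt.T
    yc = y_log - y_log.mean()
    explained = np.zeros(scores.shape[1])
    slopes = np.zeros(scores.shape[1])
    for j in range(scores.shape[1]):
        t = scores[:, j]
        vt = float(t @ t)
        if vt <= 0:
            continue
        slopes[j] = float(t @ yc) / vt
        explained[j] = 100.0 * (float(t @ yc) ** 2) / (vt * float(yc @ yc))
    loadings = pd.DataFrame(Vt.T, index=X_log.columns,
                            columns=[f"PC{j + 1}" for j in range(Vt.shape[0])])
    return loadings, explained, slopes, scores


def _pcr_coefficients(y_log: np.ndarray, X_log: pd.DataFrame) -> np.ndarray:
    """Loading-weighted regression coefficients per predictor, aggregated
    over all components: beta_p = sum_j slope_j * loading_{p,j}.  The sum
    over components is invariant to component sign and ordering."""
    loadings, _, slopes, _ = _pcr_fit(y_log, X_log)
    return loadings.values @ slopes


def _jackknife_p(y_log: np.ndarray, X_log: pd.DataFrame) -> dict[str, float]:
    """Leave-one-observation-out jackknife of the loading-weighted
    predictor coefficients; normal-approximation two-sided p."""
    m = len(y_log)
    full_beta = _pcr_coefficients(y_log, X_log)
    betas = np.empty((m, X_log.shape[1]))
    idx = np.arange(m)
    for i in range(m):
        keep = idx != i
        betas[i] = _pcr_coefficients(y_log[keep], X_log.iloc[keep])
    mean_b = betas.mean(axis=0)
    var = (m - 1) / m * np.sum((betas - mean_b) ** 2, axis=0)
    se = np.sqrt(np.maximum(var, 1e-300))
    z = full_beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return dict(zip(X_log.columns, p))


def pc_regression(
    dependent: pd.Series,
    predictors: pd.DataFrame,
    alpha: float = 0.05,
    log_offsets: Mapping[str, float] | None = None,
) -> PCRModel:
    """Principal-component regression with jackknife predictor pruning.

    All variables are log transformed (configurable offsets for the
    length-type predictors; a zero-replacing offset for the dependent).
    The dependent is regressed on each principal component of the
    standardised predictors; the component explaining the most dependent
    variance carries the jackknife test.  Predictors whose jackknife p is
    >= alpha are removed and the model refit until all remaining
    predictors are significant (or only one is left).
    """
    if len(dependent) < 10:
        raise ValueError("need at least 10 complete cases")
    offsets = dict(DEFAULT_LOG_OFFSETS if log_offsets is None else log_offsets)
    y_log, X_log, dep_offset, ok = _log_transform(dependent, predictors, offsets)
    if len(y_log) < 10:
        raise ValueError("fewer than 10 complete cases after transformation")
    history: list[dict] = []
    current = list(X_log.columns)
    while True:
        loadings, explained, slopes, scores = _pcr_fit(y_log, X_log[current])
        comp = int(np.argmax(explained))
        pvals = _jackknife_p(y_log, X_log[current])
        history.append(
            {
                "predictors": list(current),
                "selected_component": comp,
                "explained_pct": float(explained[comp]),
                "total_explained_pct": float(explained.sum()),
                "jackknife_p": dict(pvals),
            }
        )
        drop = [name for name, p in pvals.items() if p >= alpha]
        if not drop:
            break
        keep = [name for name in current if name not in drop]
        if not keep:
            logger.warning("all predictors pruned from PCR of %s", dependent.name)
            current = []
            break
        current = keep
    if not current:
        return PCRModel(
            dependent=str(dependent.name), predictors=[], log_offsets=offsets,
            dependent_offset=dep_offset, loadings=pd.DataFrame(),
            explained_pct=np.array([]), selected_component=-1,
            jackknife_p={}, pruning_history=history,
            index=np.flatnonzero(ok), y_log=y_log,
        )
    loadings, explained, slopes, scores = _pcr_fit(y_log, X_log[current])
    comp = int(np.argmax(explained))
    return PCRModel(
        dependent=str(dependent.name),
        predictors=current,
        log_offsets=offsets,
        dependent_offset=dep_offset,
        loadings=loadings,
        explained_pct=explained,
        selected_component=comp,
        jackknife_p=history[-1]["jackknife_p"],
        pruning_history=history,
        scores=scores[:, comp],
        index=np.flatnonzero(ok),
        y_log=y_log,
    )


# ---------------------------------------------------------------------------
# ANCOVA with quantile bins
# ---------------------------------------------------------------------------


@dataclass
class BinResult:
    bin_index: int
    pc_range: tuple[float, float]
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    U: float = math.nan
    raw_p: float = math.nan
    adj_p: float = math.nan
    tested: bool = False


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    U: float
    raw_p: float
    adj_p: float
    slope_a: float = math.nan
    slope_b: float = math.nan
    group_p: float = math.nan
    interaction_p: float = math.nan
    bins: list[BinResult] = field(default_factory=list)
    bins_triggered: bool = False


def ancova_with_bins(
    dependent: np.ndarray,
    pc_scores: np.ndarray,
    group_labels: Sequence[str],
    n_bins: int = 5,
    interaction_alpha: float = 0.05,
    statistic: str = "statistic",
    family_size: int = 1,
) -> GroupComparison:
    """Linear model dependent ~ pc * group (dependent already on the log
    scale), plus five equal-count bins along the pooled PC axis.

    The per-bin Mann-Whitney tests (Bonferroni family = n_bins) are always
    computed; ``bins_triggered`` records whether the slope difference was
    significant, i.e. whether the binned comparison is the appropriate
    summary.  Bins where either group is empty are reported untested.
    """
    labels = np.asarray(group_labels)
    names = sorted(set(labels))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    ga, gb = names
    df = pd.DataFrame({"y": dependent, "pc": pc_scores, "group": labels})
    model = smf.ols("y ~ pc * C(group)", data=df).fit()
    # slope per group: pc coefficient, plus interaction for the second level
    slope_a = float(model.params["pc"])
    inter_name = [k for k in model.params.index if k.startswith("pc:")]
    slope_b = slope_a + (float(model.params[inter_name[0]]) if inter_name else 0.0)
    group_name = [k for k in model.params.index if k.startswith("C(group)")]
    group_p = float(model.pvalues[group_name[0]]) if group_name else math.nan
    interaction_p = float(model.pvalues[inter_name[0]]) if inter_name else math.nan

    a_vals = df.loc[df["group"] == ga, "y"].values
    b_vals = df.loc[df["group"] == gb, "y"].values
    U, raw_p, adj_p = mann_whitney_bonferroni(a_vals, b_vals, family_size)

    # rank-based equal-count bins (sizes differ by at most one)
    order = np.argsort(np.argsort(pc_scores, kind="stable"), kind="stable")
    bin_idx = (order * n_bins) // len(pc_scores)
    bins: list[BinResult] = []
    for k in range(n_bins):
        sel = bin_idx == k
        members = np.asarray(pc_scores)[sel]
        lo = float(members.min()) if members.size else math.nan
        hi = float(members.max()) if members.size else math.nan
        av = df.loc[sel & (df["group"] == ga).values, "y"].values
        bv = df.loc[sel & (df["group"] == gb).values, "y"].values
        res = BinResult(
            bin_index=k,
            pc_range=(lo, hi),
            n_a=len(av), n_b=len(bv),
            median_a=float(np.median(av)) if len(av) else math.nan,
            median_b=float(np.median(bv)) if len(bv) else math.nan,
            mean_a=float(np.mean(av)) if len(av) else math.nan,
            mean_b=float(np.mean(bv)) if len(bv) else math.nan,
        )
        if len(av) and len(bv):
            res.U, res.raw_p, res.adj_p = mann_whitney_bonferroni(av, bv, n_bins)
            res.tested = True
        bins.append(res)
    return GroupComparison(
        group_a=ga, group_b=gb, statistic=statistic,
        n_a=len(a_vals), n_b=len(b_vals),
        median_a=float(np.median(a_vals)), median_b=float(np.median(b_vals)),
        U=U, raw_p=raw_p, adj_p=adj_p,
        slope_a=slope_a, slope_b=slope_b,
        group_p=group_p, interaction_p=interaction_p,
        bins=bins, bins_triggered=bool(interaction_p < interaction_alpha),
    )


# ---------------------------------------------------------------------------
# pipeline-level comparison of one statistic between two gene groups
# ---------------------------------------------------------------------------


def compare_statistic(
    values: pd.Series,
    covariates: pd.DataFrame,
    groups: Mapping[str, set],
    family_size: int = 1,
    alpha: float = 0.05,
    statistic: str = "",
) -> tuple[GroupComparison, PCRModel]:
    """Mann-Whitney + PCR + ANCOVA for one statistic between two groups.

    ``values`` is indexed by gene id; ``covariates`` must be indexed by
    gene id with one column per predictor; ``groups`` maps the two group
    names to gene-id sets (as from ``select_comparison_groups``).
    """
    (name_a, ids_a), (name_b, ids_b) = sorted(groups.items())
    ids = [g for g in values.index if g in ids_a or g in ids_b]
    y = values.loc[ids]
    X = covariates.loc[ids]
    labels = np.array([name_a if g in ids_a else name_b for g in ids])
    pcr = pc_regression(y, X, alpha=alpha)
    if not pcr.predictors:
        # nothing to control for: report the rank test alone
        a_vals = y.values[labels == name_a]
        b_vals = y.values[labels == name_b]
        U, raw_p, adj_p = mann_whitney_bonferroni(a_vals, b_vals, family_size)
        return (
            GroupComparison(
                group_a=name_a, group_b=name_b,
                statistic=statistic or str(values.name),
                n_a=len(a_vals), n_b=len(b_vals),
                median_a=float(np.median(a_vals)), median_b=float(np.median(b_vals)),
                U=U, raw_p=raw_p, adj_p=adj_p,
            ),
            pcr,
        )
    kept = pcr.index  # complete cases used inside the PCR
    comparison = ancova_with_bins(
        pcr.y_log,
        pcr.scores,
        labels[kept],
        statistic=statistic or str(values.name),
        family_size=family_size,
    )

    # medians transform exactly through the monotone log map; bin "means"
    # become geometric means on the raw scale
    def back(v: float) -> float:
        return float(np.exp(v) - pcr.dependent_offset) if np.isfinite(v) else v

    comparison.median_a = back(comparison.median_a)
    comparison.median_b = back(comparison.median_b)
    for b in comparison.bins:
        b.median_a, b.median_b = back(b.median_a), back(b.median_b)
        b.mean_a, b.mean_b = back(b.mean_a), back(b.mean_b)
    return comparison, pcr
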