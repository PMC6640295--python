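"""Gamma distribution of fitness effects (DFE) fitted to paired
synonymous/nonsynonymous site-frequency spectra.

Model
-----
New nonsynonymous mutations draw a scaled selection strength S = 4*Ne*s
(deleterious magnitude, no beneficial mass) from a gamma distribution with
shape ``b`` and mean ``mean_S``.  Under mutation-selection-drift balance
the density of segregating mutants at population frequency x is
proportional to H(x; S) = (1 - e^{S(1-x)}) / [x (1-x) (1 - e^{S})] for a
deleterious mutation of magnitude S, with the neutral limit H(x; 0) = 1/x.
Binomial sampling of n haploid genomes gives the expected number of sites
at derived-allele count i:

    E[count_i] = theta * L * r_i * E_gamma[ integral_0^1 C(n,i) x^i (1-x)^{n-i} H(x;S) dx ]

Synonymous sites use S = 0.  The r_i are per-frequency-class nuisance
multipliers shared between the two categories (r_1 = 1) that absorb
demography and ascertainment distortions.  Fitting maximises the Poisson
log-likelihood of both spectra jointly; for fixed (b, mean_S) the
conditional maxima of theta and r are closed-form, so the optimisation is
a two-parameter profile-likelihood search (Nelder-Mead, multi-start on the
log scale).

Reported quantities: gamma parameters, discretised proportions of
mutations in Nes bins (Nes = S/4; default bins [0,2), [2,10), [10,100),
[100,inf)), and the adaptive proportion alpha computed from divergence
counts via the expected non-adaptive dN/dS, E_gamma[S / (e^S - 1)].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .diversity import SFSPair, fold_sfs

logger = logging.getLogger(__name__)

#: internal scaled-selection parameter is S = 4*Ne*s; reported bins are on
#: the Nes scale, hence this conversion factor.
S_PER_NES = 4.0

DEFAULT_NES_BINS = (0.0, 2.0, 10.0, 100.0, math.inf)

_LEG_CACHE: dict[tuple[int, float, float], tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(k: int, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    key = (k, a, b)
    if key not in _LEG_CACHE:
        x, w = np.polynomial.legendre.leggauss(k)
        _LEG_CACHE[key] = (0.5 * (b - a) * (x + 1) + a, 0.5 * (b - a) * w)
    return _LEG_CACHE[key]


def _log_binom(n: int) -> np.ndarray:
    i = np.arange(1, n)
    return special.gammaln(n + 1) - special.gammaln(i + 1) - special.gammaln(n - i + 1)


def selected_weights(S: float, n: int, x_nodes: int = 80) -> np.ndarray:
    """Expected sampled-frequency weights for classes i = 1..n-1 at fixed
    deleterious magnitude S >= 0 (S = 0 gives the neutral 1/i exactly)."""
    if S < 1e-9:
        return 1.0 / np.arange(1, n)
    # boundary layer of width ~1/S at x=0: split the integral there
    c = min(0.5, 8.0 / S) if S > 16 else 0.5
    x1, w1 = _gl_nodes(x_nodes, 0.0, c)
    x2, w2 = _gl_nodes(x_nodes // 2, c, 1.0)
    x = np.concatenate([x1, x2])
    w = np.concatenate([w1, w2])
    # H(x; S deleterious) * x * (1-x) = e^{-Sx} expm1(-S(1-x)) / expm1(-S)
    g = np.exp(-S * x) * np.expm1(-S * (1.0 - x)) / np.expm1(-S)
    h = g / (x * (1.0 - x))
    i = np.arange(1, n)[:, None]
    log_pmf = _log_binom(n)[:, None] + i * np.log(x)[None, :] + (n - i) * np.log1p(-x)[None, :]
    return np.exp(log_pmf) @ (w * h)


def _gamma_s_nodes(shape: float, mean_S: float, k: int = 32):
    """Quadrature nodes/weights for E over the gamma DFE, via the CDF
    substitution (Gauss-Legendre in probability space)."""
    u, w = _gl_nodes(k, 0.0, 1.0)
    S = stats.gamma.ppf(u, shape, scale=mean_S / shape)
    return S, w


_WEIGHT_GRID: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_GRID_LO, _GRID_HI, _GRID_K = 1e-4, 3e8, 512


def _weight_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """log-S grid and log selected weights, precomputed once per n.

    The weights are smooth, asymptotically power-law functions of S, so
    log-log linear interpolation on a dense grid reproduces the direct
    quadrature to ~1e-4 relative while making likelihood evaluations cheap.
    """
    if n not in _WEIGHT_GRID:
        logS = np.linspace(math.log(_GRID_LO), math.log(_GRID_HI), _GRID_K)
        logW = np.empty((_GRID_K, n - 1))
        with np.errstate(divide="ignore"):
            for j, ls in enumerate(logS):
                logW[j] = np.log(np.maximum(selected_weights(math.exp(ls), n), 1e-320))
        _WEIGHT_GRID[n] = (logS, logW)
    return _WEIGHT_GRID[n]


def _weights_at(S: np.ndarray, n: int) -> np.ndarray:
    """Selected weights for an array of S values via grid interpolation."""
    logS_grid, logW = _weight_grid(n)
    S = np.clip(S, _GRID_LO, _GRID_HI)
    t = np.clip(np.log(S), logS_grid[0], logS_grid[-1])
    pos = (t - logS_grid[0]) / (logS_grid[1] - logS_grid[0])
    j = np.clip(pos.astype(int), 0, _GRID_K - 2)
    frac = pos - j
    out = np.exp(logW[j] * (1 - frac[:, None]) + logW[j + 1] * frac[:, None])
    neutral = 1.0 / np.arange(1, n)
    out[S <= _GRID_LO] = neutral  # below the grid the spectrum is neutral
    return out


def gamma_weights(shape: float, mean_S: float, n: int, k_s: int = 32) -> np.ndarray:
    """E_gamma over S of the selected sampling weights, classes 1..n-1."""
    if mean_S < 1e-9:
        return 1.0 / np.arange(1, n)
    S, w = _gamma_s_nodes(shape, mean_S, k_s)
    return w @ _weights_at(S, n)


def _maybe_fold(weights: np.ndarray, n: int, fold: bool) -> np.ndarray:
    return fold_sfs(weights, n) if fold else weights


def expected_sfs(
    shape: float,
    mean_S: float,
    theta: float,
    r: np.ndarray | None,
    n: int,
    L: float,
    fold: bool = True,
) -> np.ndarray:
    """Expected SFS counts per frequency class for a site category whose
    mutations draw S from Gamma(shape, mean_S); mean_S = 0 is neutral."""
    w = _maybe_fold(gamma_weights(shape, mean_S, n), n, fold)
    if r is None:
        r = np.ones_like(w)
    return theta * L * np.asarray(r) * w


@dataclass
class DFEFit:
    shape: float
    mean_S: float  # E[4 Ne s], deleterious magnitude
    theta_hat: float
    r: np.ndarray  # per-frequency-class nuisance multipliers, r[0] == 1
    log_likelihood: float
    n: int
    folded: bool
    bin_edges: tuple = DEFAULT_NES_BINS
    bin_proportions: np.ndarray = field(default_factory=lambda: np.array([]))
    alpha: float | None = None
    at_boundary: bool = False
    converged: bool = True


def _profile(params: np.ndarray, data: dict) -> float:
    """Negative profile log-likelihood over (log shape, log mean_S)."""
    log_b, log_ms = params
    if not (-7.0 <= log_b <= 5.0) or not (-20.0 <= log_ms <= 17.0):
        return 1e12
    b, ms = math.exp(log_b), math.exp(log_ms)
    w = _maybe_fold(gamma_weights(b, ms, data["n"]), data["n"], data["folded"])
    v, s_obs, n_obs, L_s, L_n = data["v"], data["s_obs"], data["n_obs"], data["L_s"], data["L_n"]
    denom = L_s * v + L_n * w
    r = np.ones_like(w)
    if data["fix_r"]:
        theta = (s_obs.sum() + n_obs.sum()) / denom.sum()
    else:
        theta = (s_obs[0] + n_obs[0]) / denom[0]
        r[1:] = (s_obs[1:] + n_obs[1:]) / (theta * denom[1:])
    e_s = theta * L_s * r * v
    e_n = theta * L_n * r * w
    ll = 0.0
    for obs, exp in ((s_obs, e_s), (n_obs, e_n)):
        pos = exp > 0
        if np.any(obs[~pos] > 0):
            return 1e12
        ll += float(np.sum(obs[pos] * np.log(exp[pos]) - exp[pos]))
    return -ll


def _prepare_data(pair: SFSPair, fold: bool, fix_r: bool = False) -> dict:
    n = pair.n
    if fold and not pair.folded:
        s_obs, n_obs = fold_sfs(pair.sfs_s, n), fold_sfs(pair.sfs_n, n)
    elif not fold and pair.folded:
        raise ValueError("cannot unfold a folded spectrum")
    else:
        s_obs, n_obs = pair.sfs_s, pair.sfs_n
    v = _maybe_fold(1.0 / np.arange(1, n), n, fold)
    return {
        "n": n,
        "folded": fold,
        "s_obs": np.asarray(s_obs, dtype=float),
        "n_obs": np.asarray(n_obs, dtype=float),
        "v": v,
        "L_s": float(pair.L_s),
        "L_n": float(pair.L_n),
        "fix_r": fix_r,
    }

#: dispersed (shape, mean_S) starting points for the profile search
_STARTS = ((0.3, 100.0), (1.0, 10.0), (0.1, 1000.0), (0.5, 5000.0), (2.0, 1.0))


def fit_gamma_dfe(
    pair: SFSPair,
    fold: bool = True,
    bin_edges: tuple = DEFAULT_NES_BINS,
    starts: Sequence[tuple[float, float]] = _STARTS,
    x0: tuple[float, float] | None = None,
    fix_r: bool = False,
) -> DFEFit:
    """Maximum-likelihood gamma DFE from a paired SFS.

    ``x0`` replaces the multi-start list with a single warm start (used by
    the bootstrap).  Degenerate data (no segregating sites in the first
    frequency class) raises ValueError.
    """
    if pair.L_n <= 0 or pair.L_s <= 0:
        raise ValueError("need positive site tallies L_n and L_s")
    data = _prepare_data(pair, fold, fix_r=fix_r)
    if data["s_obs"][0] + data["n_obs"][0] <= 0:
        raise ValueError("no segregating sites in the singleton class")
    start_list = [x0] if x0 is not None else list(starts)
    best = None
    for b0, ms0 in start_list:
        res = optimize.minimize(
            _profile,
            np.array([math.log(b0), math.log(ms0)]),
            args=(data,),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimisation starts failed")
    log_b, log_ms = best.x
    b, ms = math.exp(log_b), math.exp(log_ms)
    at_boundary = log_b < -6.5 or log_b > 4.5 or log_ms < -19.0 or log_ms > 16.0
    if at_boundary:
        logger.warning("DFE fit at parameter boundary: shape=%g mean_S=%g", b, ms)
    # recover theta and r at the optimum
    w = _maybe_fold(gamma_weights(b, ms, data["n"]), data["n"], fold)
    denom = data["L_s"] * data["v"] + data["L_n"] * w
    r = np.ones_like(w)
    if fix_r:
        theta = (data["s_obs"].sum() + data["n_obs"].sum()) / denom.sum()
    else:
        theta = (data["s_obs"][0] + data["n_obs"][0]) / denom[0]
        r[1:] = (data["s_obs"][1:] + data["n_obs"][1:]) / (theta * denom[1:])
    fit = DFEFit(
        shape=b,
        mean_S=ms,
        theta_hat=float(theta),
        r=r,
        log_likelihood=-float(best.fun),
        n=data["n"],
        folded=fold,
        bin_edges=tuple(bin_edges),
        at_boundary=at_boundary,
        converged=bool(best.success),
    )
    fit.bin_proportions = discretize(fit, bin_edges)
    return fit


def discretize(fit: DFEFit, bin_edges: tuple = DEFAULT_NES_BINS) -> np.ndarray:
    """Proportions of new mutations in Nes intervals from the fitted gamma
    (Nes = S / 4); proportions sum to 1."""
    edges_S = np.asarray(bin_edges, dtype=float) * S_PER_NES
    if fit.mean_S < 1e-12:
        cdf = (edges_S > 0).astype(float)  # point mass at 0: all in first bin
        cdf[np.isinf(edges_S)] = 1.0
    else:
        cdf = stats.gamma.cdf(edges_S, fit.shape, scale=fit.mean_S / fit.shape)
    return np.diff(cdf)


def _relative_fixation(S: np.ndarray) -> np.ndarray:
    """Fixation probability of a deleterious mutation of magnitude S
    relative to neutral: S / (e^S - 1); -> 1 as S -> 0."""
    S = np.asarray(S, dtype=float)
    out = np.ones_like(S)
    big = S > 1e-8
    with np.errstate(over="ignore"):
        out[big] = S[big] / np.expm1(S[big])
    return out


def expected_nonadaptive_omega(fit: DFEFit, k_s: int = 64) -> float:
    """E_gamma of the relative fixation probability: the dN/dS expected
    from deleterious mutations alone."""
    if fit.mean_S < 1e-9:
        return 1.0
    S, w = _gamma_s_nodes(fit.shape, fit.mean_S, k_s)
    return float(np.sum(w * _relative_fixation(S)))


def estimate_alpha(fit: DFEFit, pair: SFSPair) -> float:
    """Adaptive proportion of nonsynonymous substitutions:
    alpha = 1 - (D_s L_n / (D_n L_s)) * E_gamma[S / (e^S - 1)]."""
    if pair.D_n <= 0:
        raise ValueError("alpha undefined: no nonsynonymous substitutions")
    if pair.D_s <= 0:
        raise ValueError("alpha undefined: no synonymous substitutions")
    expectation = expected_nonadaptive_omega(fit)
    return 1.0 - (pair.D_s * pair.L_n) / (pair.D_n * pair.L_s) * expectation


@dataclass
class BootstrapResult:
    point: DFEFit
    intervals: dict[str, tuple[float, float]]
    B: int
    n_failed: int = 0
    replicates: dict[str, np.ndarray] = field(default_factory=dict)


def bootstrap(
    gene_pairs: Sequence[SFSPair],
    B: int = 1000,
    seed: int = 0,
    fold: bool = True,
    bin_edges: tuple = DEFAULT_NES_BINS,
    resample: bool = True,
    compute_alpha: bool = False,
) -> BootstrapResult:
    """Gene-level bootstrap of the DFE fit.

    Each replicate resamples genes with replacement, sums their spectra,
    site tallies and divergence counts, and refits (warm-started at the
    point estimate).  95% percentile intervals are reported per quantity.
    ``resample=False`` keeps the original gene set in every replicate
    (degenerate intervals; useful for determinism checks).
    """
    rng = np.random.default_rng(seed)
    G = len(gene_pairs)
    n, folded = gene_pairs[0].n, gene_pairs[0].folded
    sfs_n_mat = np.stack([p.sfs_n for p in gene_pairs])
    sfs_s_mat = np.stack([p.sfs_s for p in gene_pairs])
    L_n = np.array([p.L_n for p in gene_pairs])
    L_s = np.array([p.L_s for p in gene_pairs])
    D_n = np.array([p.D_n for p in gene_pairs])
    D_s = np.array([p.D_s for p in gene_pairs])

    def summed(weights: np.ndarray) -> SFSPair:
        return SFSPair(
            n=n, folded=folded,
            sfs_n=weights @ sfs_n_mat, sfs_s=weights @ sfs_s_mat,
            L_n=float(weights @ L_n), L_s=float(weights @ L_s),
            D_n=float(weights @ D_n), D_s=float(weights @ D_s),
        )

    total = summed(np.ones(G))
    point = fit_gamma_dfe(total, fold=fold, bin_edges=bin_edges)
    if compute_alpha:
        point.alpha = estimate_alpha(point, total)
    rows: dict[str, list[float]] = {"shape": [], "mean_S": [], "theta": [], "alpha": []}
    for k in range(len(bin_edges) - 1):
        rows[f"bin_{k}"] = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, G, G) if resample else np.arange(G)
        resampled = summed(np.bincount(idx, minlength=G).astype(float))
        try:
            fit = fit_gamma_dfe(
                resampled, fold=fold, bin_edges=bin_edges,
                x0=(point.shape, point.mean_S),
            )
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        rows["shape"].append(fit.shape)
        rows["mean_S"].append(fit.mean_S)
        rows["theta"].append(fit.theta_hat)
        for k, prop in enumerate(fit.bin_proportions):
            rows[f"bin_{k}"].append(float(prop))
        if compute_alpha:
            rows["alpha"].append(estimate_alpha(fit, resampled))
    if n_failed > 0.05 * B:
        logger.warning("bootstrap: %d of %d replicate fits failed", n_failed, B)
    intervals = {}
    replicates = {}
    for name, vals in rows.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        replicates[name] = arr
        lo, hi = np.percentile(arr, [2.5, 97.5])
        intervals[name] = (float(lo), float(hi))
    return BootstrapResult(
        point=point, intervals=intervals, B=B, n_failed=n_failed, replicates=replicates
    )
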