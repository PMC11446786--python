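"""TMM normalization and negative-binomial differential expression.

Normalization is the trimmed mean of M-values: against a reference sample
(the one whose upper-quartile abundance is closest to the mean), per-gene
log ratios M are doubly trimmed (30% on M, 5% on mean abundance A) and the
precision-weighted mean of the survivors gives the log2 scaling factor.
Factors are rescaled to geometric mean 1.

Expression testing is a per-gene negative-binomial likelihood-ratio test
of equal means between two groups, with log effective library size
(library size x TMM factor) as offset and a common dispersion estimated
across genes by maximizing the Cox-Reid adjusted profile likelihood on a
dispersion grid.  A gene is called up when fold change > fc_min and
(p < p_max or q < fdr_max); down symmetrically.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import chi2

from .containers import CountMatrix
from .diff_ir import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["tmm_factors", "estimate_common_dispersion", "deg_test", "call_degs"]


def _as_counts(matrix) -> pd.DataFrame:
    return matrix.counts if isinstance(matrix, CountMatrix) else matrix


def tmm_factors(matrix, lib_sizes=None, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1).

    ``lib_sizes`` defaults to column sums; pass explicit (e.g. equal nominal)
    library sizes to make the factors absorb depth differences directly.
    """
    counts = _as_counts(matrix)
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (y.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts")
    if lib_sizes is None:
        lib = y.sum(axis=0)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
        if len(lib) != y.shape[1] or (lib <= 0).any():
            raise ValueError("need one positive library size per sample")

    scaled = y / lib
    f75 = np.array([np.quantile(scaled[:, j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        ok = (y[:, j] > 0) & (y[:, ref] > 0)
        yj, yr = y[ok, j], y[ok, ref]
        m = np.log2((yj / lib[j]) / (yr / lib[ref]))
        a = 0.5 * (np.log2(yj / lib[j]) + np.log2(yr / lib[ref]))
        w = (lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr)
        n = len(m)
        if n == 0:
            continue
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        keep = (
            (rank_m >= lo_m)
            & (rank_m <= n + 1 - lo_m)
            & (rank_a >= lo_a)
            & (rank_a <= n + 1 - lo_a)
        )
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        with np.errstate(divide="ignore"):
            log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _fit_nb_beta(y: np.ndarray, offsets: np.ndarray, alpha: float, max_iter: int = 60) -> np.ndarray:
    """Fisher-scoring fit of a single log-scale intercept per gene."""
    eo = np.exp(offsets)
    beta = np.log(np.maximum((y / eo).mean(axis=1), 1e-8))
    for _ in range(max_iter):
        mu = np.exp(beta[:, None] + offsets[None, :])
        score = ((y - mu) / (1 + alpha * mu)).sum(axis=1)
        info = (mu / (1 + alpha * mu)).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -3, 3)
        beta = np.clip(beta + step, -30, 30)
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + xlogy(y, mu / (r + mu))
    ).sum(axis=1)


def _group_profile(y, offsets, group_cols, alpha):
    """Fitted loglik and Cox-Reid adjustment for group-wise means."""
    ll = np.zeros(y.shape[0])
    adj = np.zeros(y.shape[0])
    for cols in group_cols:
        yg = y[:, cols]
        og = offsets[cols]
        beta = _fit_nb_beta(yg, og, alpha)
        mu = np.exp(beta[:, None] + og[None, :])
        ll += _nb_loglik(yg, mu, alpha)
        adj += 0.5 * np.log(np.maximum((mu / (1 + alpha * mu)).sum(axis=1), 1e-12))
    return ll, adj


def estimate_common_dispersion(y: np.ndarray, offsets: np.ndarray, group_cols) -> float:
    """Common NB dispersion maximizing the Cox-Reid adjusted profile likelihood.

    Grid search on log-spaced dispersions with a parabolic refinement around
    the best grid point.
    """
    grid = np.logspace(-4, 0.7, 25)
    apls = np.empty(grid.size)
    for i, alpha in enumerate(grid):
        ll, adj = _group_profile(y, offsets, group_cols, alpha)
        apls[i] = (ll - adj).sum()
    i = int(np.argmax(apls))
    if 0 < i < grid.size - 1:
        x = np.log(grid[i - 1 : i + 2])
        f = apls[i - 1 : i + 2]
        denom = (f[0] - 2 * f[1] + f[2])
        if denom < 0:
            x_star = x[1] - 0.5 * (x[2] - x[1]) * (f[2] - f[0]) / denom
            return float(np.exp(x_star))
    return float(grid[i])


def deg_test(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    min_cpm: float = 1.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of equal means between two groups.

    Genes must have counts-per-million above ``min_cpm`` in at least
    min(group sizes) samples to be tested; all-zero genes are excluded.
    Returns a DataFrame with ``gene, log2fc, p, q`` sorted by p.
    """
    cols_a = matrix.samples_in_group(group_a)
    cols_b = matrix.samples_in_group(group_b)
    counts = matrix.counts[cols_a + cols_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per group")

    lib = counts.sum(axis=0).to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    min_n = min(len(cols_a), len(cols_b))
    keep = (cpm > min_cpm).sum(axis=1) >= min_n
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("deg_test: filtered %d low-expression genes", n_drop)
    counts = counts.loc[keep]
    if counts.empty:
        raise ValueError("no genes pass the expression filter")

    factors = matrix.tmm_factors
    if factors is None:
        factors = tmm_factors(counts)
    factors = factors.reindex(counts.columns)
    offsets = np.log(lib * factors.to_numpy())
    y = counts.to_numpy(dtype=float)
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols_a) + len(cols_b))

    if dispersion is None:
        dispersion = estimate_common_dispersion(y, offsets, (ia, ib))
        logger.info("deg_test: common dispersion %.4g", dispersion)

    beta_a = _fit_nb_beta(y[:, ia], offsets[ia], dispersion)
    beta_b = _fit_nb_beta(y[:, ib], offsets[ib], dispersion)
    mu1 = np.empty_like(y)
    mu1[:, ia] = np.exp(beta_a[:, None] + offsets[ia][None, :])
    mu1[:, ib] = np.exp(beta_b[:, None] + offsets[ib][None, :])
    ll1 = _nb_loglik(y, mu1, dispersion)

    beta0 = _fit_nb_beta(y, offsets, dispersion)
    mu0 = np.exp(beta0[:, None] + offsets[None, :])
    ll0 = _nb_loglik(y, mu0, dispersion)

    stat = np.maximum(0.0, 2.0 * (ll1 - ll0))
    p = chi2.sf(stat, df=1)
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": (beta_b - beta_a) / np.log(2),
            "p": p,
            "q": bh_fdr(p),
        }
    )
    return out.sort_values(["p", "gene"]).reset_index(drop=True)


def call_degs(
    records: pd.DataFrame,
    p_max: float = 0.05,
    fdr_max: float = 0.1,
    fc_min: float = 1.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split tested genes into up/down lists under the dual significance rule.

    Up requires fold change strictly greater than ``fc_min`` (log2fc >
    log2 fc_min) and (p < p_max or q < fdr_max); down is symmetric.
    """
    if records.empty:
        empty = records.copy()
        return empty, empty
    thr = np.log2(fc_min)
    sig = (records["p"] < p_max) | (records["q"] < fdr_max)
    up = records[sig & (records["log2fc"] > thr)].reset_index(drop=True)
    down = records[sig & (records["log2fc"] < -thr)].reset_index(drop=True)
    return up, down
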