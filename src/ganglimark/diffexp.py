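"""Dual-engine negative-binomial differential expression with consensus.

The study calls a gene differentially expressed for a given high/low
partition of the ganglia only when **two independent NB test families**
agree at FDR q <= 0.05:

* engine 1 — a conditional exact test: conditioning the high-group count sum
  on the total, the conditional law is a negative hypergeometric that does
  not depend on the (nuisance) mean, and the two-sided p-value sums the
  probabilities of all splits no more likely than the observed one;
* engine 2 — an NB log-link GLM likelihood-ratio test of the group term,
  fitted by Fisher scoring with log size-factor offsets, with the statistic
  referred to chi-square(1).

Both engines share one dispersion model: per-gene dispersions maximise the
Cox-Reid adjusted profile likelihood, a parametric trend
``alpha(mu) = a0 + a1/mu`` is fitted across genes with MAD-based outlier
exclusion, and per-gene values are shrunk towards the trend on the log scale
with a prior weight of ``d0`` effective degrees of freedom.  Sharing the
model keeps disagreement between the engines attributable to the test
statistics rather than to dispersion estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from ganglimark.containers import CountMatrix, SampleDesign

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0


# ---------------------------------------------------------------------------
# dispersion estimation


def _fit_group_means_matrix(
    Y: np.ndarray, s: np.ndarray, group_idx: list[np.ndarray], alpha: np.ndarray
) -> np.ndarray:
    """Fitted NB means (genes x samples) with group-specific expression and
    per-gene dispersion; Newton on the log group mean, vectorised over genes."""
    MU = np.zeros_like(Y, dtype=float)
    a = alpha[:, None]
    for idx in group_idx:
        y = Y[:, idx]
        sj = s[idx][None, :]
        tot = y.sum(axis=1)
        pos = tot > 0
        eta = np.where(pos, np.log(np.maximum(tot, 1e-300) / sj.sum()), -np.inf)
        for _ in range(40):
            mu = sj * np.exp(eta)[:, None]
            denom = 1.0 + a * mu
            score = np.sum((y - mu) / denom, axis=1)
            info = np.sum(mu / denom, axis=1)
            step = np.clip(score / np.maximum(info, 1e-300), -5.0, 5.0)
            eta = np.where(pos, eta + step, eta)
            if np.max(np.abs(score[pos]) / np.maximum(tot[pos], 1.0), initial=0.0) < 1e-12:
                break
        MU[:, idx] = np.where(pos[:, None], sj * np.exp(eta)[:, None], 0.0)
    return MU


def _cr_pll_matrix(
    log_alpha: np.ndarray, Y: np.ndarray, s: np.ndarray, group_idx: list[np.ndarray]
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at per-gene alpha.

    Group means are re-fitted at each alpha; the adjustment subtracts half
    the log determinant of the expected information of the mean parameters,
    which for a one-hot group design is a sum over groups.
    """
    alpha = np.exp(log_alpha)
    MU = np.maximum(_fit_group_means_matrix(Y, s, group_idx, alpha), 1e-10)
    r = (1.0 / alpha)[:, None]
    ll = np.sum(
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1)
        + Y * np.log(MU / (MU + r)) + r * np.log(r / (MU + r)),
        axis=1,
    )
    adj = np.zeros(Y.shape[0])
    a = alpha[:, None]
    for idx in group_idx:
        w = MU[:, idx] / (1.0 + a * MU[:, idx])
        adj += np.log(np.sum(w, axis=1) + 1e-300)
    return ll - 0.5 * adj


def estimate_dispersions_matrix(
    Y: np.ndarray, size_factors: np.ndarray, group_labels: np.ndarray
) -> np.ndarray:
    """Raw Cox-Reid dispersion per row of ``Y``, vectorised.

    The adjusted profile likelihood is maximised over ``alpha`` in
    ``[1e-8, 10]`` on the log scale: a coarse grid brackets the optimum and
    golden-section search refines every gene simultaneously.  All-zero rows
    get ``nan`` (dispersion undefined; excluded from trend fitting).
    """
    Y = np.asarray(Y, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    labels = np.asarray(group_labels)
    group_idx = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    if min(len(ix) for ix in group_idx) < 2:
        raise ValueError("dispersion estimation needs >= 2 samples per group")
    G = Y.shape[0]

    def f(log_a: np.ndarray) -> np.ndarray:
        return _cr_pll_matrix(log_a, Y, s, group_idx)

    lo, hi = np.log(ALPHA_MIN), np.log(ALPHA_MAX)
    grid = np.linspace(lo, hi, 25)
    vals = np.stack([f(np.full(G, x)) for x in grid])      # n_grid x G
    k = np.argmax(vals, axis=0)
    a = grid[np.maximum(k - 1, 0)]
    b = grid[np.minimum(k + 1, grid.size - 1)]

    invphi = (np.sqrt(5.0) - 1) / 2
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    n_iter = int(np.ceil(np.log(1e-4 / (grid[1] - grid[0]) / 2) / np.log(invphi)))
    for _ in range(max(n_iter, 1)):
        left = fc >= fd
        a = np.where(left, a, c)
        b = np.where(left, d, b)
        c_new = np.where(left, b - invphi * (b - a), d)
        d_new = np.where(left, c, a + invphi * (b - a))
        x_eval = np.where(left, c_new, d_new)
        fx = f(x_eval)
        fc_old = fc
        fc = np.where(left, fx, fd)
        fd = np.where(left, fc_old, fx)
        c, d = c_new, d_new
    log_alpha = (a + b) / 2
    # genes whose likelihood is maximal at the lower boundary sit at the floor
    at_floor = vals[0] >= f(log_alpha)
    alpha = np.where(at_floor, ALPHA_MIN, np.exp(log_alpha))
    alpha = np.maximum(alpha, ALPHA_MIN)
    alpha[Y.sum(axis=1) == 0] = np.nan
    return alpha


def estimate_gene_dispersion(
    counts_row: np.ndarray,
    size_factors: np.ndarray,
    group_labels: np.ndarray,
) -> float:
    """Raw dispersion for one gene (see :func:`estimate_dispersions_matrix`)."""
    return float(
        estimate_dispersions_matrix(
            np.asarray(counts_row, dtype=float)[None, :], size_factors, group_labels
        )[0]
    )


def fit_dispersion_trend(
    means: np.ndarray, raw_alphas: np.ndarray
) -> tuple[float, float]:
    """Fit the parametric trend ``alpha(mu) = a0 + a1/mu``.

    Least squares of raw dispersion on ``1/mu`` over genes with positive
    mean and finite dispersion.  Because the sampling noise of a dispersion
    estimate scales with the dispersion itself, the fit is iteratively
    reweighted by the inverse squared fitted trend (relative-error least
    squares), with two rounds of outlier exclusion on the scaled residuals
    (above 3 robust MADs).  Coefficients are clamped to be non-negative.
    """
    mu = np.asarray(means, dtype=float)
    al = np.asarray(raw_alphas, dtype=float)
    use = np.isfinite(mu) & np.isfinite(al) & (mu > 0)
    if use.sum() < 10:
        raise ValueError(
            "dispersion trend needs >= 10 genes with positive mean; "
            "provide more genes"
        )
    x, ysub = 1.0 / mu[use], al[use]
    keep = np.ones(x.size, dtype=bool)
    # unweighted initial fit, then relative-error reweighting
    w = np.ones(x.size)
    a0 = a1 = 0.0
    for round_ in range(3):
        X = np.column_stack([np.ones(x.size), x])
        Xk, yk, wk = X[keep], ysub[keep], w[keep]
        coef, *_ = np.linalg.lstsq(Xk * wk[:, None] ** 0.5,
                                   yk * wk ** 0.5, rcond=None)
        a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
        fitted = np.maximum(a0 + a1 * x, 1e-6)
        w = 1.0 / fitted ** 2
        scaled = (ysub - (a0 + a1 * x)) / fitted
        mad = 1.4826 * np.median(np.abs(scaled[keep] - np.median(scaled[keep])))
        if mad <= 0:
            break
        new_keep = np.abs(scaled) <= 3 * mad
        if new_keep.sum() < 10:
            break
        keep = new_keep
    return a0, a1


def shrink_dispersions(
    raw_alphas: np.ndarray,
    trend: tuple[float, float],
    means: np.ndarray,
    residual_df: float,
    d0: float = 10.0,
) -> np.ndarray:
    """Shrink per-gene dispersions towards the fitted trend on the log scale.

    ``log alpha* = (d_g log alpha_raw + d0 log alpha_trend) / (d_g + d0)``
    with ``d_g`` the residual degrees of freedom of the design
    (n_samples - n_groups) and ``d0`` the prior weight.  Genes with
    undefined raw dispersion (all-zero rows) take the trend value.
    """
    a0, a1 = trend
    mu = np.asarray(means, dtype=float)
    with np.errstate(divide="ignore"):
        trend_alpha = np.maximum(a0 + a1 / np.maximum(mu, 1e-300), ALPHA_MIN)
    raw = np.maximum(np.asarray(raw_alphas, dtype=float), ALPHA_MIN)
    log_star = (
        residual_df * np.log(raw) + d0 * np.log(trend_alpha)
    ) / (residual_df + d0)
    star = np.exp(log_star)
    star = np.where(np.isfinite(raw), star, trend_alpha)
    return star


@dataclass
class DispersionModel:
    """Shared per-gene dispersion model used by both DE engines."""

    gene_ids: list
    mean: np.ndarray          # mean of size-factor-normalised counts
    raw_alpha: np.ndarray
    a0: float
    a1: float
    shrunken_alpha: np.ndarray
    d0: float

    def trend(self, mu: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.maximum(self.a0 + self.a1 / np.maximum(mu, 1e-300), 0.0)


def fit_dispersion_model(
    cm: CountMatrix,
    size_factors: pd.Series,
    design: SampleDesign,
    d0: float = 10.0,
) -> DispersionModel:
    """Estimate raw dispersions per gene, fit the trend and shrink.

    The design used for estimation is the full one-hot ganglion design, so
    one model serves every high/low partition downstream.
    """
    s = size_factors.loc[cm.sample_ids].to_numpy(dtype=float)
    labels = design.table.loc[cm.sample_ids, "ganglion"].to_numpy()
    Y = cm.values
    norm_mean = (Y / s[None, :]).mean(axis=1)
    raw = estimate_dispersions_matrix(Y, s, labels)
    ok = np.isfinite(raw) & (norm_mean > 0)
    a0, a1 = fit_dispersion_trend(norm_mean[ok], raw[ok])
    resid_df = Y.shape[1] - len(pd.unique(labels))
    star = shrink_dispersions(raw, (a0, a1), norm_mean, resid_df, d0)
    logger.info(
        "dispersion model: %d genes, trend a0=%.4g a1=%.4g, d0=%.1f",
        Y.shape[0], a0, a1, d0,
    )
    return DispersionModel(cm.gene_ids, norm_mean, raw, a0, a1, star, d0)


# ---------------------------------------------------------------------------
# engine 1: conditional exact test


def _conditional_logpmf(total: int, n_high: int, n_low: int, alpha: float) -> np.ndarray:
    """Unnormalised log pmf of the high-group sum given the total.

    Group sums of i.i.d. NB counts at a common effective library size share
    the NB success probability, so conditioning on the total cancels it:
    ``P(x | T) proportional to C(x+r_h-1, x) * C(T-x+r_l-1, T-x)`` with
    ``r = n / alpha`` per group (negative hypergeometric).  In the Poisson
    limit ``alpha -> 0`` this becomes binomial with success fraction
    ``n_high / (n_high + n_low)``.

    Computed by a log-ratio recurrence anchored at x = 0 (no special
    functions), which is exact up to cumulative-sum rounding.
    """
    x = np.arange(total, dtype=float)
    if alpha == 0:
        ratio = np.log((total - x) * n_high) - np.log((x + 1.0) * n_low)
    else:
        r_h, r_l = n_high / alpha, n_low / alpha
        ratio = np.log((x + r_h) * (total - x)) - np.log(
            (x + 1.0) * (total - x - 1.0 + r_l)
        )
    out = np.empty(total + 1)
    out[0] = 0.0
    np.cumsum(ratio, out=out[1:])
    return out


def _twosided_from_logpmf(logpmf: np.ndarray, obs_index) -> np.ndarray:
    """Two-sided p for each observed index: total probability of outcomes no
    more likely than the observed one (1e-7 relative tie tolerance)."""
    ref = logpmf.max()
    pmf = np.exp(logpmf - ref)
    z = pmf.sum()
    obs = np.atleast_1d(obs_index)
    thresh = logpmf[obs] + np.log1p(1e-7)
    if obs.size == 1:
        psum = pmf[logpmf <= thresh[0]].sum()
        pvals = np.array([psum / z])
    else:
        order = np.argsort(logpmf, kind="stable")
        csum = np.cumsum(pmf[order])
        pos = np.searchsorted(logpmf[order], thresh, side="right") - 1
        pvals = csum[np.maximum(pos, 0)] / z
    return np.minimum(np.maximum(pvals, 1e-300), 1.0)


def exact_test_all_splits(
    total: int, n_high: int, n_low: int, alpha: float
) -> np.ndarray:
    """Two-sided conditional exact p-values for every split of ``total``.

    Returns ``p[x]`` for observed high-group sums x = 0..total.  With
    ``alpha == 0`` the conditional law is binomial (Poisson limit).
    """
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")
    logpmf = _conditional_logpmf(total, n_high, n_low, alpha)
    return _twosided_from_logpmf(logpmf, np.arange(total + 1))


def nb_exact_test(
    high_counts: np.ndarray,
    low_counts: np.ndarray,
    alpha: float,
    size_factors_high: np.ndarray,
    size_factors_low: np.ndarray,
) -> float:
    """Conditional NB exact test, two-sided.

    Counts are first rescaled to a common effective library size (divide by
    the sample's size factor, multiply by the geometric mean factor, round
    half to even) — a documented approximation that makes the group sums
    exchangeable; the test then enumerates every split of the conditional
    total.
    """
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")
    yh = np.asarray(high_counts, dtype=float)
    yl = np.asarray(low_counts, dtype=float)
    sh = np.asarray(size_factors_high, dtype=float)
    sl = np.asarray(size_factors_low, dtype=float)
    sbar = np.exp(np.mean(np.log(np.concatenate([sh, sl]))))
    rh_counts = _round_half_even(yh / sh * sbar)
    rl_counts = _round_half_even(yl / sl * sbar)
    s_high = int(rh_counts.sum())
    total = s_high + int(rl_counts.sum())
    if total == 0:
        return 1.0
    logpmf = _conditional_logpmf(total, yh.size, yl.size, alpha)
    return float(_twosided_from_logpmf(logpmf, s_high)[0])


def _round_half_even(v: np.ndarray) -> np.ndarray:
    return np.rint(v)


# ---------------------------------------------------------------------------
# engine 2: NB GLM likelihood-ratio test


def _nb_loglik_matrix(Y: np.ndarray, MU: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    r = 1.0 / np.maximum(alpha, 1e-12)[:, None]
    MU = np.maximum(MU, 1e-300)
    return np.sum(
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1)
        + Y * np.log(MU / (MU + r)) + r * np.log(r / (MU + r)),
        axis=1,
    )


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    log_s: np.ndarray,
    alpha: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Fisher scoring for NB log-link GLMs, one per matrix row.

    Returns (coefficients, log-likelihoods, converged flags).  Convergence
    is a score-vector norm below ``tol``; rows still moving after
    ``max_iter`` iterations are flagged unconverged.
    """
    G, n = Y.shape
    p = X.shape[1]
    a = np.maximum(np.asarray(alpha, dtype=float), 1e-12)
    # moment-based start: per-column-of-X group means where X is one-hot-ish
    beta = np.zeros((G, p))
    beta[:, 0] = np.log((Y.sum(axis=1) + 0.5) / np.exp(log_s).sum())
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = beta @ X.T + log_s[None, :]
        MU = np.exp(np.clip(eta, -60, 60))
        resid = (Y - MU) / (1.0 + a[:, None] * MU)
        U = resid @ X                                  # score, G x p
        W = MU / (1.0 + a[:, None] * MU)
        grad_norm = np.linalg.norm(U, axis=1)
        newly = grad_norm < tol
        converged |= newly
        active = ~converged
        if not active.any():
            break
        if p == 1:
            J = W @ (X[:, 0] ** 2)
            step = U[:, 0] / np.maximum(J, 1e-300)
            beta[active, 0] += np.clip(step[active], -10, 10)
        else:
            # explicit 2x2 (or small p) normal equations per row
            XW = np.einsum("gn,np,nq->gpq", W, X, X)
            XW += 1e-12 * np.eye(p)[None, :, :]
            step = np.linalg.solve(XW, U[:, :, None])[:, :, 0]
            beta[active] += np.clip(step[active], -10, 10)
    eta = beta @ X.T + log_s[None, :]
    MU = np.exp(np.clip(eta, -60, 60))
    ll = _nb_loglik_matrix(Y, MU, a)
    return beta, ll, converged


def nb_glm_lrt_matrix(
    Y: np.ndarray,
    group_mask: np.ndarray,
    size_factors: np.ndarray,
    alpha: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """LRT p-values for a two-level group factor, one per row of ``Y``.

    Null model: intercept + offsets; alternative adds the group indicator.
    Statistic ``D = 2 (l_alt - l_null)`` (clamped at 0) is referred to
    chi-square(1).  Rows where either fit fails to converge get ``nan``.
    """
    log_s = np.log(np.asarray(size_factors, dtype=float))
    X0 = np.ones((Y.shape[1], 1))
    X1 = np.column_stack([np.ones(Y.shape[1]), group_mask.astype(float)])
    _, ll0, conv0 = _irls_nb(Y, X0, log_s, alpha)
    beta1, ll1, conv1 = _irls_nb(Y, X1, log_s, alpha)
    D = np.maximum(2.0 * (ll1 - ll0), 0.0)
    pvals = chi2.sf(D, df=1)
    # a perfect null fit gives D ~ 0 -> p 1; keep in (0, 1]
    pvals = np.minimum(np.maximum(pvals, 1e-300), 1.0)
    bad = ~(conv0 & conv1)
    if bad.any():
        logger.warning("nb_glm_lrt: %d rows did not converge; p set to NaN", bad.sum())
        pvals = pvals.astype(float)
        pvals[bad] = np.nan
    return pvals, D


def nb_glm_lrt(
    counts_row: np.ndarray,
    group_mask: np.ndarray,
    size_factors: np.ndarray,
    alpha: float,
) -> float:
    """Single-gene convenience wrapper around :func:`nb_glm_lrt_matrix`."""
    p, _ = nb_glm_lrt_matrix(
        np.asarray(counts_row, dtype=float)[None, :],
        np.asarray(group_mask, dtype=bool),
        size_factors,
        np.array([alpha]),
    )
    return float(p[0])


# ---------------------------------------------------------------------------
# multiple testing and consensus


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN entries are ignored for the correction and returned as NaN; ``m``
    is the number of non-NaN p-values.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qs = np.empty(m)
    qs[order] = q
    out[ok] = qs
    return out


def consensus_flags(
    q_exact: np.ndarray,
    q_glm: np.ndarray,
    log2fc: np.ndarray,
    threshold: float = 0.05,
) -> np.ndarray:
    """Both-engines consensus: up in the high group at q <= threshold twice.

    NaN q-values (unconverged fits) never pass.
    """
    qe = np.asarray(q_exact, dtype=float)
    qg = np.asarray(q_glm, dtype=float)
    fc = np.asarray(log2fc, dtype=float)
    with np.errstate(invalid="ignore"):
        return (fc > 0) & (qe <= threshold) & (qg <= threshold)


def de_for_grouping(
    cm: CountMatrix,
    design: SampleDesign,
    high_labels: frozenset,
    dispersion: DispersionModel,
    sf_exact: pd.Series,
    sf_glm: pd.Series,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run both engines for one high/low partition of the ganglion labels.

    Returns a per-gene table with log2 fold change (high vs low, of
    size-factor-normalised means with pseudo-count 0.5), both engines'
    p- and q-values, and the consensus flag.
    """
    labels = design.table.loc[cm.sample_ids, "ganglion"]
    mask = labels.isin(high_labels).to_numpy()
    if mask.all() or not mask.any():
        raise ValueError("high/low partition must leave both sides non-empty")
    Y = cm.values.astype(float)
    se = sf_exact.loc[cm.sample_ids].to_numpy(dtype=float)
    sg = sf_glm.loc[cm.sample_ids].to_numpy(dtype=float)
    norm = Y / se[None, :]
    mean_high = norm[:, mask].mean(axis=1)
    mean_low = norm[:, ~mask].mean(axis=1)
    log2fc = np.log2((mean_high + 0.5) / (mean_low + 0.5))

    alpha = dispersion.shrunken_alpha
    p_exact = np.array(
        [
            nb_exact_test(Y[i, mask], Y[i, ~mask], alpha[i], se[mask], se[~mask])
            for i in range(Y.shape[0])
        ]
    )
    p_glm, _ = nb_glm_lrt_matrix(Y, mask, sg, alpha)
    q_exact = bh_adjust(p_exact)
    q_glm = bh_adjust(p_glm)
    cons = consensus_flags(q_exact, q_glm, log2fc, q_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_exact": p_exact,
            "q_exact": q_exact,
            "p_glm": p_glm,
            "q_glm": q_glm,
            "consensus": cons,
        },
        index=cm.gene_ids,
    )
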