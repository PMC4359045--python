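"""Phylogenetically informed scaling analyses (PISA).

Model-I log–log regressions fit by generalized least squares under three
error-correlation structures: independent errors (OLS), Brownian motion
(covariance between two species equal to their shared root-to-ancestor
path length), and an Ornstein–Uhlenbeck process (correlation decaying as
exp(-alpha * patristic distance), the Martins–Hansen structure).  Fits
maximize the restricted log-likelihood (REML) by default.  Competing fits
are compared by a three-step rule: (1) if no significant phylogenetic
signal (Blomberg's K, tip-permutation test) is detected in the response,
keep OLS; (2) drop fits whose residuals fail a runs test for randomness;
(3) among survivors pick the lowest small-sample-corrected AIC (AICc).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import comb
from scipy.stats import norm, t as t_dist

log = logging.getLogger(__name__)

#: relative ridge added to a covariance diagonal that fails to factor
#: (zero-length branches from polytomy resolution can duplicate rows)
SINGULARITY_RIDGE = 1e-10


# ---------------------------------------------------------------------------
# trees


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree from a file path or a Newick string."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    return dendropy.Tree.get(data=text, schema="newick")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Prune a tree to a species set, preserving root-to-tip path lengths."""
    present = set(tip_labels(tree))
    missing = sorted(set(species) - present)
    if missing:
        raise KeyError(f"species not in tree: {', '.join(missing)}")
    return tree.extract_tree_with_taxa_labels(labels=list(species))


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Replace polytomies with zero-length branches (binary output)."""
    out = tree.clone(depth=1)
    out.resolve_polytomies()
    for edge in out.preorder_edge_iter():
        if edge.length is None and edge.head_node is not out.seed_node:
            edge.length = 0.0
    return out


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip (any stem/root edge included)."""
    return {leaf.taxon.label: leaf.distance_from_root()
            for leaf in tree.leaf_node_iter()}


def patristic_distances(tree: dendropy.Tree, order: list[str] | None = None):
    """(labels, D) with D the matrix of tip-to-tip path lengths."""
    labels = order or sorted(tip_labels(tree))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, d


def vcv_brownian(tree: dendropy.Tree, order: list[str] | None = None):
    """(labels, V) under Brownian motion: V_ij = shared root-to-MRCA length."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    labels, d = patristic_distances(tree, order)
    depths = tip_depths(tree)
    t_arr = np.array([depths[lbl] for lbl in labels])
    v = 0.5 * (t_arr[:, None] + t_arr[None, :] - d)
    np.fill_diagonal(v, t_arr)
    return labels, v


def vcv_ou(tree: dendropy.Tree, alpha: float, order: list[str] | None = None):
    """(labels, C) under an OU process: C_ij = exp(-alpha * d_ij), C_ii = 1.

    alpha = 0 degenerates to an all-ones matrix (flagged); large alpha
    approaches the identity, i.e. the OLS limit.  Non-ultrametric trees
    are accepted with a warning, since the stationary-OU correlation only
    depends on patristic distance.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    depths = tip_depths(tree)
    vals = np.array(list(depths.values()))
    if np.ptp(vals) > 1e-6 * max(vals.max(), 1e-12):
        log.warning("tree is not ultrametric; OU correlations use patristic distance")
    labels, d = patristic_distances(tree, order)
    if alpha == 0:
        log.warning("alpha = 0: OU correlation matrix is singular (all ones)")
    c = np.exp(-alpha * d)
    np.fill_diagonal(c, 1.0)
    return labels, c


# ---------------------------------------------------------------------------
# generalized least squares


@dataclass
class RegressionFit:
    model: str
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    loglik: float                 # REML (default) or ML log-likelihood
    method: str
    n: int
    k: int                        # parameter count for AICc
    aicc: float
    sigma2: float
    residuals: np.ndarray
    fitted: np.ndarray
    residual_random: bool | None = None
    residual_runs_p: float | None = None
    alpha: float | None = None    # OU strength when applicable


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _chol_with_ridge(v: np.ndarray):
    try:
        return cho_factor(v, lower=True), 0.0
    except np.linalg.LinAlgError:
        ridge = SINGULARITY_RIDGE * float(np.mean(np.diag(v)))
        log.warning("covariance matrix singular; adding ridge %.3g to diagonal", ridge)
        try:
            return cho_factor(v + ridge * np.eye(len(v)), lower=True), ridge
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "covariance matrix singular even after ridge; check for "
                "duplicated tips joined by zero-length branches"
            ) from err


def fit_gls(
    x: np.ndarray,
    y: np.ndarray,
    cov: np.ndarray | None = None,
    method: str = "REML",
    model: str = "OLS",
    k: int = 3,
    confidence: float = 0.95,
    alpha: float | None = None,
) -> RegressionFit:
    """Model-I GLS regression of y on x with error covariance ``cov``.

    With ``cov=None`` (identity) this reproduces ordinary least squares
    exactly.  Confidence intervals are t-based Wald intervals with n-2
    degrees of freedom.  ``k`` is the parameter count used for AICc
    (slope, intercept, residual variance = 3; +1 when an OU alpha was
    estimated from the data).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    X = np.column_stack([np.ones(n), x])
    p = 2
    v = np.eye(n) if cov is None else np.asarray(cov, float)
    factor, _ = _chol_with_ridge(v)
    vinv_X = cho_solve(factor, X)
    vinv_y = cho_solve(factor, y)
    xtvx = X.T @ vinv_X
    beta = np.linalg.solve(xtvx, X.T @ vinv_y)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ cho_solve(factor, resid))
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if method == "REML":
        sigma2 = rss / (n - p)
        loglik = -0.5 * ((n - p) * math.log(2 * math.pi * sigma2) + (n - p)
                         + logdet_v + logdet_xtvx)
    else:
        sigma2 = rss / n
        loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + n + logdet_v)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtvx)))
    tcrit = t_dist.ppf(0.5 + confidence / 2.0, df=n - 2)
    fit = RegressionFit(
        model=model,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_ci=(float(beta[1] - tcrit * se[1]), float(beta[1] + tcrit * se[1])),
        intercept_ci=(float(beta[0] - tcrit * se[0]), float(beta[0] + tcrit * se[0])),
        loglik=float(loglik),
        method=method,
        n=n,
        k=k,
        aicc=aicc(float(loglik), k, n) if n > k + 1 else float("nan"),
        sigma2=float(sigma2),
        residuals=resid,
        fitted=fitted,
        alpha=alpha,
    )
    try:
        fit.residual_random, fit.residual_runs_p, _ = residual_randomness(resid, fitted)
    except ValueError:
        fit.residual_random = None
    return fit


# ---------------------------------------------------------------------------
# runs test for residual randomness


def _runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact distribution of the number of runs in a random arrangement."""
    total = comb(n1 + n2, n1, exact=True)
    pmf: dict[int, float] = {}
    for r in range(2, n1 + n2 + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n1 - 1, k - 1, exact=True) * comb(n2 - 1, k - 1, exact=True)
        else:
            k = (r - 1) // 2
            ways = comb(n1 - 1, k, exact=True) * comb(n2 - 1, k - 1, exact=True) \
                + comb(n1 - 1, k - 1, exact=True) * comb(n2 - 1, k, exact=True)
        if ways:
            pmf[r] = ways / total
    return pmf


def runs_test(signs: np.ndarray, exact_max_n: int = 30) -> tuple[float, int]:
    """Two-sided Wald–Wolfowitz runs test on a boolean sign sequence.

    Returns (p_value, n_runs).  Uses the exact conditional runs
    distribution up to ``exact_max_n`` observations and the normal
    approximation beyond.
    """
    signs = np.asarray(signs, bool)
    n = signs.size
    n1 = int(signs.sum())
    n2 = n - n1
    if n < 5:
        raise ValueError("runs test indeterminate for fewer than 5 residuals")
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    if n1 == 0 or n2 == 0:
        return 0.0 if n >= 5 else 1.0, runs
    if n <= exact_max_n:
        pmf = _runs_pmf(n1, n2)
        lo = sum(p for r, p in pmf.items() if r <= runs)
        hi = sum(p for r, p in pmf.items() if r >= runs)
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        mu = 1.0 + 2.0 * n1 * n2 / n
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
        z = (runs - mu) / math.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return float(p), runs


def residual_randomness(
    residuals: np.ndarray, fitted: np.ndarray, threshold: float = 0.05
) -> tuple[bool, float, int]:
    """Runs test on residual signs ordered by fitted value.

    Returns (random_flag, p_value, n_runs); the flag is advisory and
    true when p >= ``threshold``.
    """
    residuals = np.asarray(residuals, float)
    fitted = np.asarray(fitted, float)
    order = np.argsort(fitted, kind="stable")
    r = residuals[order]
    signs = r[r != 0] > 0
    p, runs = runs_test(signs)
    return bool(p >= threshold), p, runs


# ---------------------------------------------------------------------------
# phylogenetic signal


@dataclass
class SignalTestResult:
    k_statistic: float
    p_value: float
    n_permutations: int
    seed: int


def phylo_signal_K(
    trait: np.ndarray,
    tree: dendropy.Tree | None = None,
    cov: np.ndarray | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> SignalTestResult:
    """Blomberg's K with a tip-permutation significance test.

    K compares the observed ratio of tip variance (about the
    phylogenetic mean) to phylogenetically corrected variance against its
    Brownian-motion expectation on the same tree; K ~ 1 under BM, K -> 0
    with no signal.  The p-value ranks the observed phylogenetic mean
    squared error among tip-shuffled permutations (small MSE = signal).
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    y = np.asarray(trait, float)
    n = y.size
    if np.allclose(y, y[0]):
        raise ValueError("constant trait: K undefined")
    if cov is None:
        if tree is None:
            raise ValueError("need a tree or a covariance matrix")
        _, cov = vcv_brownian(tree)
    factor, _ = _chol_with_ridge(np.asarray(cov, float))
    ones = np.ones(n)
    vinv_1 = cho_solve(factor, ones)
    denom_1 = float(ones @ vinv_1)

    def mse_pair(vals: np.ndarray) -> tuple[float, float]:
        a = float(vals @ vinv_1) / denom_1
        d = vals - a
        mse0 = float(d @ d) / (n - 1)
        mse = float(d @ cho_solve(factor, d)) / (n - 1)
        return mse0, mse

    mse0, mse = mse_pair(y)
    expected = (float(np.trace(cov)) - n / denom_1) / (n - 1)
    k_stat = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        _, mse_perm = mse_pair(rng.permutation(y))
        if mse_perm <= mse:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return SignalTestResult(k_statistic=float(k_stat), p_value=float(p),
                            n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# model batteries and selection


def fit_models(
    x: np.ndarray,
    y: np.ndarray,
    tree: dendropy.Tree | None = None,
    labels: list[str] | None = None,
    alphas: tuple[float, ...] = (),
    estimate_alpha: bool = False,
    method: str = "REML",
) -> dict[str, RegressionFit]:
    """Fit OLS and, given a tree, PGLS-BM and PGLS-OU at each alpha.

    ``labels`` gives the species order of x/y and must match the tree
    tips.  With ``estimate_alpha`` the OU strength is profiled over the
    REML likelihood (parameter count k = 4 for that fit).
    """
    fits = {"OLS": fit_gls(x, y, None, method=method, model="OLS")}
    if tree is None:
        return fits
    if labels is None:
        raise ValueError("labels are required for PGLS fits")
    _, v_bm = vcv_brownian(tree, order=labels)
    fits["PGLS-BM"] = fit_gls(x, y, v_bm, method=method, model="PGLS-BM")
    for a in alphas:
        _, c = vcv_ou(tree, a, order=labels)
        lbl = f"PGLS-OU(alpha={a:g})"
        fits[lbl] = fit_gls(x, y, c, method=method, model=lbl, alpha=a)
    if estimate_alpha:
        from scipy.optimize import minimize_scalar

        depth = max(tip_depths(tree).values())

        def neg_ll(log_a: float) -> float:
            _, c = vcv_ou(tree, math.exp(log_a), order=labels)
            return -fit_gls(x, y, c, method=method, k=4).loglik

        res = minimize_scalar(neg_ll, bounds=(math.log(1e-4 / depth), math.log(1e3 / depth)),
                              method="bounded")
        a_hat = math.exp(res.x)
        _, c = vcv_ou(tree, a_hat, order=labels)
        lbl = f"PGLS-OU(alpha={a_hat:.3g}, ML)"
        fits[lbl] = fit_gls(x, y, c, method=method, model=lbl, k=4, alpha=a_hat)
    return fits


def select_model(
    fits: dict[str, RegressionFit],
    signal: SignalTestResult | None,
    signal_threshold: float = 0.05,
) -> tuple[RegressionFit, list[str]]:
    """Three-criterion model choice; returns (chosen fit, decision trace).

    No detectable phylogenetic signal in the response selects OLS
    outright; otherwise fits with non-random residuals are dropped and
    the lowest-AICc survivor wins.  If everything is eliminated, OLS is
    returned with a warning.
    """
    if not fits:
        raise ValueError("no candidate fits")
    trace = []
    ols = fits.get("OLS")
    if signal is not None:
        trace.append(
            f"phylogenetic signal: K = {signal.k_statistic:.3f}, "
            f"p = {signal.p_value:.4f} ({signal.n_permutations} permutations)"
        )
        if signal.p_value >= signal_threshold and ols is not None:
            trace.append("no significant signal detected -> OLS selected")
            return ols, trace
    survivors = {}
    for name, f in fits.items():
        if f.residual_random is False:
            p_txt = "n/a" if f.residual_runs_p is None else f"{f.residual_runs_p:.4f}"
            trace.append(f"{name}: dropped (non-random residuals, runs p = {p_txt})")
        else:
            survivors[name] = f
    if not survivors:
        log.warning("all candidate models eliminated; falling back to OLS")
        trace.append("all candidates eliminated -> OLS with warning")
        return ols if ols is not None else next(iter(fits.values())), trace
    name = min(survivors, key=lambda nm: survivors[nm].aicc)
    for nm, f in survivors.items():
        trace.append(f"{nm}: AICc = {f.aicc:.2f}")
    trace.append(f"lowest AICc -> {name}")
    return survivors[name], trace
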