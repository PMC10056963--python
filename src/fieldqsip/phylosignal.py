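"""Phylogenetic signal of tip traits: Blomberg's K and Pagel's lambda.

Both statistics are computed from first principles on the Brownian-motion
covariance matrix ``C`` implied by the phylogeny (``C_ij`` = shared
root-to-MRCA branch length).  K is a variance-ratio index with a tip-label
permutation test; lambda is estimated by maximum likelihood (off-diagonal
shrinkage of ``C``) with a likelihood-ratio test against ``lambda = 0``.

All linear algebra goes through Cholesky factorisations; explicit inverses
are never formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "tree_to_covariance",
    "blomberg_k",
    "blomberg_k_test",
    "pagel_lambda",
    "lambda_lr_test",
    "phylogenetic_signal",
    "SignalResult",
]


@dataclass
class SignalResult:
    """One signal statistic for one trait."""

    statistic: str          # "K" or "lambda"
    estimate: float
    pvalue: float
    n_tips: int
    meta: dict

    def __repr__(self):
        return (f"SignalResult({self.statistic}={self.estimate:.4g}, "
                f"p={self.pvalue:.4g}, n={self.n_tips})")


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def tree_to_covariance(tree, tip_subset=None, zero_branch_eps: float = 1e-8):
    """Brownian-motion covariance matrix of tip values implied by a phylogeny.

    ``C_ij`` is the root-to-MRCA distance of tips *i* and *j*; ``C_ii`` is the
    root-to-tip depth.  Zero-length terminal branches are perturbed by
    ``zero_branch_eps`` x tree height (with a warning) so that ``C`` stays
    positive-definite.

    Returns ``(C, labels)`` with rows/columns ordered as ``labels``.
    """
    tips = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if tip_subset is None:
        labels = sorted(tips)
    else:
        labels = list(tip_subset)
        unknown = [t for t in labels if t not in tips]
        if unknown:
            raise KeyError(f"tips not in tree: {unknown[:5]}")
    tree.calc_node_root_distances()
    height = max(lf.root_distance for lf in tree.leaf_node_iter())
    n_zero = 0
    for lab in labels:
        lf = tips[lab]
        if not (lf.edge.length or 0.0) > 0:
            lf.edge.length = (lf.edge.length or 0.0) + zero_branch_eps * height
            n_zero += 1
    if n_zero:
        warnings.warn(f"{n_zero} zero-length terminal branch(es) perturbed by "
                      f"{zero_branch_eps:g} x tree height", stacklevel=2)
        tree.calc_node_root_distances()

    # depth of every node, then C_ij = depth(MRCA) via ancestor sets
    ancestors = {}
    for lab in labels:
        chain = []
        nd = tips[lab]
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        ancestors[lab] = chain
    n = len(labels)
    C = np.empty((n, n))
    for i, a in enumerate(labels):
        C[i, i] = tips[a].root_distance
        set_a = set(id(nd) for nd in ancestors[a])
        for j in range(i + 1, n):
            mrca = next(nd for nd in ancestors[labels[j]] if id(nd) in set_a)
            C[i, j] = C[j, i] = mrca.root_distance
    try:
        linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        d = np.sqrt(np.diag(C))
        corr = C / np.outer(d, d)
        bad = [(labels[i], labels[j])
               for i in range(n) for j in range(i + 1, n)
               if corr[i, j] > 1 - 1e-12]
        raise ValueError(
            "phylogenetic covariance is not positive-definite; tips at zero "
            f"distance: {bad[:5]}")
    return C, labels


def _is_star(C: np.ndarray, rtol: float = 1e-10) -> bool:
    off = C - np.diag(np.diag(C))
    return np.abs(off).max() <= rtol * np.abs(np.diag(C)).max()


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def _k_ingredients(C: np.ndarray):
    L = linalg.cholesky(C, lower=True)
    one = np.ones(C.shape[0])
    Lone = linalg.solve_triangular(L, one, lower=True)   # L^-1 1
    denom_exp = (np.trace(C) - C.shape[0] / (Lone @ Lone)) / (C.shape[0] - 1)
    return L, Lone, denom_exp


def blomberg_k(x, C) -> float:
    """Blomberg's K for trait ``x`` on the phylogeny with BM covariance ``C``.

    K compares the observed ratio of the ordinary mean squared error to the
    phylogenetically corrected one against its Brownian-motion expectation;
    K = 1 matches BM, K < 1 means less signal than BM.  Invariant to positive
    affine transforms of ``x``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; phylogenetic signal undefined")
    L, Lone, denom_exp = _k_ingredients(C)
    Lx = linalg.solve_triangular(L, x, lower=True)
    a_hat = (Lone @ Lx) / (Lone @ Lone)                  # GLS grand mean
    r = x - a_hat
    mse0 = r @ r
    mse = (Lx - a_hat * Lone) @ (Lx - a_hat * Lone)      # r' C^-1 r
    return float((mse0 / mse) / denom_exp)


def blomberg_k_test(x, C, n_perm: int = 999, seed=None) -> SignalResult:
    """Permutation test of Blomberg's K (shuffling trait values across tips).

    ``p = (1 + #{K_perm >= K_obs}) / (1 + n_perm)``; deterministic given seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    k_obs = blomberg_k(x, C)
    L, Lone, denom_exp = _k_ingredients(C)
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = rng.permutation(x)
    LX = linalg.solve_triangular(L, perms, lower=True)
    a_hat = (Lone @ LX) / (Lone @ Lone)
    R = perms - a_hat[None, :]
    mse0 = np.einsum("ij,ij->j", R, R)
    Rw = LX - np.outer(Lone, a_hat)
    mse = np.einsum("ij,ij->j", Rw, Rw)
    k_perm = (mse0 / mse) / denom_exp
    p = (1 + int(np.sum(k_perm >= k_obs))) / (1 + n_perm)
    return SignalResult("K", k_obs, p, n, {"n_perm": n_perm})


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

def _lambda_loglik(lam: float, x: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of lambda (sigma^2 and the GLS mean profiled out)."""
    n = x.size
    Cl = lam * C + (1 - lam) * np.diag(np.diag(C))
    L = linalg.cholesky(Cl, lower=True)
    one = np.ones(n)
    Lone = linalg.solve_triangular(L, one, lower=True)
    Lx = linalg.solve_triangular(L, x, lower=True)
    a_hat = (Lone @ Lx) / (Lone @ Lone)
    rw = Lx - a_hat * Lone
    s2 = (rw @ rw) / n
    logdet = 2 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * np.log(2 * np.pi * s2) + logdet + n))


def pagel_lambda(x, C, lambda_max: float = 1.0, allow_lambda_gt1: bool = False):
    """ML estimate of Pagel's lambda.

    ``lambda`` multiplies the off-diagonal of ``C`` (tip variances unchanged);
    ``lambda = 0`` removes all phylogenetic covariance, ``lambda = 1`` is plain
    Brownian motion.  Returns ``(lambda_hat, loglik_hat, loglik0)``.

    With ``allow_lambda_gt1`` the upper bound is raised to the largest value
    (found by bisection, capped at 2) keeping ``C(lambda)`` positive-definite.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; phylogenetic signal undefined")
    if _is_star(C):
        raise ValueError("star phylogeny: lambda is unidentifiable")

    upper = lambda_max
    if allow_lambda_gt1:
        lo, hi = lambda_max, 2.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            try:
                linalg.cholesky(mid * C + (1 - mid) * np.diag(np.diag(C)),
                                lower=True)
                lo = mid
            except linalg.LinAlgError:
                hi = mid
        upper = max(lambda_max, lo * 0.999)

    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, x, C),
        bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"lambda optimisation failed: {res.message}")
    candidates = [(0.0, _lambda_loglik(0.0, x, C)),
                  (float(res.x), -res.fun),
                  (upper, _lambda_loglik(upper, x, C))]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = candidates[0][1]
    return lam_hat, ll_hat, ll0


def lambda_lr_test(loglik_hat: float, loglik0: float) -> float:
    """Likelihood-ratio p-value of lambda against lambda = 0 (chi-square, 1 df)."""
    lr = 2.0 * (loglik_hat - loglik0)
    if lr < -1e-8:
        raise ValueError(f"negative likelihood ratio ({lr:.3g}): "
                         "alternative fit worse than the null")
    lr = max(lr, 0.0)
    return float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0


# ---------------------------------------------------------------------------
# convenience front end
# ---------------------------------------------------------------------------

def phylogenetic_signal(tree, trait: pd.Series, n_perm: int = 999, seed=None,
                        lambda_max: float = 1.0,
                        allow_lambda_gt1: bool = False) -> pd.DataFrame:
    """Blomberg's K and Pagel's lambda for one trait on one tree.

    ``trait`` is indexed by tip label; tips without a trait value are pruned
    from the covariance (not the tree).  Returns a two-row table
    (statistic, estimate, pvalue, n_tips).
    """
    trait = trait.dropna()
    C, labels = tree_to_covariance(tree, tip_subset=list(trait.index))
    x = trait.loc[labels].to_numpy(dtype=float)
    k_res = blomberg_k_test(x, C, n_perm=n_perm, seed=seed)
    lam, ll1, ll0 = pagel_lambda(x, C, lambda_max=lambda_max,
                                 allow_lambda_gt1=allow_lambda_gt1)
    lam_res = SignalResult("lambda", lam, lambda_lr_test(ll1, ll0), x.size,
                           {"loglik": ll1, "loglik0": ll0, "df": 1})
    return pd.DataFrame(
        [
            {"statistic": "K", "estimate": k_res.estimate,
             "pvalue": k_res.pvalue, "n_tips": k_res.n_tips},
            {"statistic": "lambda", "estimate": lam_res.estimate,
             "pvalue": lam_res.pvalue, "n_tips": lam_res.n_tips},
        ]
    )
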