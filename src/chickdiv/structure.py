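"""Population structure: IBS distances, neighbor-joining, PCA, admixture.

The distance between two varieties is 1 - IBS (identity by state), the
standard SNP allele-sharing distance for dosage data.  Trees are built with
the Saitou–Nei neighbor-joining algorithm (exact on additive matrices);
PCA uses Patterson normalization with Tracy–Widom significance for the
leading eigenvalues; admixture proportions are estimated by maximum
likelihood EM on the binomial admixture model
``g_ij ~ Binomial(2, sum_k q_ik f_kj)`` — the likelihood maximised by
STRUCTURE/Frappe-style programs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from skbio import TreeNode

from .core import MISSING, PanelGenotypes

__all__ = [
    "distance_matrix",
    "nj_tree",
    "pca_genotypes",
    "tracy_widom",
    "AdmixtureResult",
    "admixture_em",
    "align_admixture",
    "TW1_95",
    "TW1_99",
]

#: tabulated Tracy–Widom (TW1) upper quantiles at alpha = 0.05 and 0.01
TW1_95 = 0.9793
TW1_99 = 2.0234

# Chiani (2014) shifted-gamma approximation of the TW1 distribution
_TW1_GAMMA_K = 46.44604884387787
_TW1_GAMMA_SCALE = 0.18605402228279682
_TW1_GAMMA_LOC = -9.848007781128567


def distance_matrix(panel: PanelGenotypes) -> pd.DataFrame:
    """Allele-sharing distance 1 - IBS between all sample pairs.

    Per shared non-missing site the IBS of dosages a, b is
    ``1 - |a - b| / 2`` (1 for identical genotypes, 0.5 for one shared
    allele, 0 for opposite homozygotes); the pair distance is one minus the
    mean.  Raises if a pair shares no non-missing site.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = panel.geno.astype(float)
    g[panel.geno == MISSING] = np.nan
    n = panel.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[:, i][:, None] - g[:, i + 1 :])
        shared = ~np.isnan(diff)
        if shared.size and not shared.any(axis=0).all():
            raise ValueError("sample pair with no shared non-missing sites")
        with np.errstate(invalid="ignore"):
            dij = np.nanmean(diff / 2.0, axis=0)
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
    return pd.DataFrame(d, index=panel.sample_ids, columns=panel.sample_ids)


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Saitou–Nei neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch, preserving the pair's summed path
    length.  Returns an unrooted tree (trifurcating root) as a scikit-bio
    TreeNode.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=str(label)) for label in dist.index]
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        i, j = active[i_loc], active[j_loc]
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # final trifurcation via the three-point formulas
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = float(max(lk, 0.0))
        root.append(nodes[k])
    return root


# ---------------------------------------------------------------------------
# PCA


def pca_genotypes(panel: PanelGenotypes) -> dict:
    """PCA of the genotype matrix with Patterson normalization.

    Sites are mean-centered and scaled by sqrt(p(1-p)); missing dosages are
    imputed with the site mean.  Returns eigenvalues (descending),
    eigenvectors (samples x components) and the Tracy–Widom table of the
    leading eigenvalues.
    """
    if panel.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    g = panel.geno.astype(float).T  # samples x sites
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    p = mu / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic sites")
    g = g[:, poly]
    mu = mu[poly]
    p = p[poly]
    g = np.where(np.isnan(g), mu[None, :], g)
    x = (g - mu[None, :]) / np.sqrt(p * (1 - p))[None, :]
    m_sites = x.shape[1]
    cov = x @ x.T / m_sites
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    tw = tracy_widom(eigval[: panel.n_samples - 1], m_sites)
    return {"eigenvalues": eigval, "eigenvectors": eigvec, "tracy_widom": tw}


def tracy_widom(eigenvalues: np.ndarray, n_markers: int) -> pd.DataFrame:
    """Tracy–Widom statistics for leading eigenvalues (moment matching).

    At step i the i-th eigenvalue is tested against the remaining spectrum
    using the effective-marker correction
    ``n_eff = (m + 1) S1^2 / ((m - 1) S2 - S1^2)`` with S1, S2 the sums of
    the remaining eigenvalues and their squares; p-values come from the
    Chiani shifted-gamma approximation of TW1.  ``n_markers`` caps n_eff.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    rows = []
    tw_dist = stats.gamma(_TW1_GAMMA_K, loc=_TW1_GAMMA_LOC, scale=_TW1_GAMMA_SCALE)
    for i in range(len(lam)):
        rest = lam[i:]
        m = len(rest)
        if m < 2 or rest.sum() <= 0:
            break
        s1, s2 = rest.sum(), (rest**2).sum()
        denom = (m - 1) * s2 - s1**2
        n_eff = ((m + 1) * s1**2 / denom) if denom > 0 else float(n_markers)
        n_eff = float(min(max(n_eff, 2.0), n_markers))
        l_norm = m * rest[0] / s1
        mu = (np.sqrt(n_eff - 1) + np.sqrt(m)) ** 2 / n_eff
        sigma = (
            (np.sqrt(n_eff - 1) + np.sqrt(m))
            / n_eff
            * (1.0 / np.sqrt(n_eff - 1) + 1.0 / np.sqrt(m)) ** (1.0 / 3.0)
        )
        x = (l_norm - mu) / sigma
        rows.append(
            {
                "component": i + 1,
                "eigenvalue": float(lam[i]),
                "tw_stat": float(x),
                "p_value": float(tw_dist.sf(x)),
                "significant_05": bool(x > TW1_95),
                "significant_01": bool(x > TW1_99),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# admixture EM


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # (n_samples, K) ancestry fractions
    F: np.ndarray  # (K, n_sites) subpopulation allele frequencies
    log_likelihood: float
    log_likelihoods: np.ndarray  # per-iteration trace (non-decreasing)
    n_iter: int

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")


def _admixture_loglik(g, called, Q, F, eps=1e-12):
    P = np.clip(Q @ F, eps, 1 - eps)
    ll = np.where(called, g * np.log(P) + (2 - g) * np.log1p(-P), 0.0)
    return float(ll.sum())


def admixture_em(
    panel: PanelGenotypes,
    K: int,
    max_iter: int = 10_000,
    tol: float = 1e-4,
    seed: int = 0,
    restarts: int = 5,
) -> AdmixtureResult:
    """Maximum-likelihood admixture proportions by EM.

    Model: ``g_ij ~ Binomial(2, p_ij)`` with ``p_ij = sum_k q_ik f_kj``.
    The EM updates distribute each observed allele across source
    populations in proportion to ``q_ik f_kj / p_ij`` and re-estimate Q and
    F from the expected counts; the log-likelihood is non-decreasing at
    every iteration.  Runs ``restarts`` seeded random starts and keeps the
    best likelihood.  Missing genotypes are ignored in all sums.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > panel.n_samples:
        raise ValueError("K cannot exceed the number of samples")
    g = panel.geno.astype(float).T  # (n, m)
    called = g >= 0
    g = np.where(called, g, 0.0)
    n, m = g.shape
    m_i = called.sum(axis=1).astype(float)
    if (m_i == 0).any():
        raise ValueError("a sample has no called genotypes")

    if K == 1:
        # closed form: F is the observed allele frequency vector
        freq = g.sum(axis=0) / np.maximum(2.0 * called.sum(axis=0), 1.0)
        Q = np.ones((n, 1))
        F = freq[None, :]
        ll = _admixture_loglik(g, called, Q, F)
        return AdmixtureResult(Q, F, ll, np.array([ll]), 1)

    rng = np.random.default_rng(seed)
    eps = 1e-9
    best: AdmixtureResult | None = None
    for _ in range(max(restarts, 1)):
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(rng.random((K, m)), 0.05, 0.95)
        trace = []
        ll_prev = -np.inf
        for it in range(1, max_iter + 1):
            P = np.clip(Q @ F, eps, 1 - eps)
            R = np.where(called, g / P, 0.0)
            S = np.where(called, (2.0 - g) / (1.0 - P), 0.0)
            qa = Q * (R @ F.T)
            qb = Q * (S @ (1.0 - F).T)
            Q_new = (qa + qb) / (2.0 * m_i[:, None])
            Q_new /= Q_new.sum(axis=1, keepdims=True)
            f_num = F * (Q.T @ R)
            f_den = f_num + (1.0 - F) * (Q.T @ S)
            F_new = np.where(f_den > 0, f_num / np.maximum(f_den, eps), F)
            Q, F = Q_new, np.clip(F_new, eps, 1 - eps)
            ll = _admixture_loglik(g, called, Q, F)
            trace.append(ll)
            if ll - ll_prev < tol and it > 1:
                break
            ll_prev = ll
        result = AdmixtureResult(Q, F, trace[-1], np.asarray(trace), len(trace))
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    return best


def align_admixture(Q: np.ndarray, Q0: np.ndarray) -> np.ndarray:
    """Permute the columns of Q to best match Q0 (Hungarian matching)."""
    K = Q.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.abs(Q[:, a] - Q0[:, b]).mean()
    row, col = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[col] = row
    return Q[:, perm]
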