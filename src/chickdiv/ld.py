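"""Pairwise linkage disequilibrium, LD-decay profiles and haplotype blocks.

Haplotype frequencies for a SNP pair are estimated from unphased diploid
genotypes: all genotype-pair categories except the double heterozygote are
phase-certain; the double heterozygote is resolved by a two-locus EM.  In
a predominantly selfing panel double heterozygotes are rare, so the EM
touches only a small minority of pairs.  From the estimated haplotype
frequencies: ``D = f11 - pA*pB``, ``r^2 = D^2/(pA(1-pA)pB(1-pB))`` and
``D' = D/Dmax``.

Haplotype blocks use the Gabriel confidence-interval method: the 90% CI of
|D'| is obtained by likelihood profiling over a |D'| grid (Wall & Pritchard
style, matching Haploview defaults); a pair is "strong LD" when the CI lies
within [0.70, 0.98] (low >= 0.70 and high >= 0.98) and "strong
recombination" when the CI upper bound is < 0.90.  A candidate span is a
block when >= 95% of its informative pairs are strong LD; blocks are
selected greedily, longest first, non-overlapping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, PanelGenotypes

__all__ = ["pair_ld", "pairwise_ld", "ld_decay", "haplotype_blocks"]

STRONG_LD_LOW = 0.70
STRONG_LD_HIGH = 0.98
RECOMB_HIGH = 0.90
BLOCK_STRONG_FRACTION = 0.95


def _pair_table(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair count table over samples called at both loci."""
    ok = (ga != MISSING) & (gb != MISSING)
    t = np.zeros((3, 3))
    np.add.at(t, (ga[ok], gb[ok]), 1)
    return t


def _hap_freqs_em(t: np.ndarray, n_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """EM haplotype frequencies [f11, f10, f01, f00] from a 3x3 table."""
    n = t.sum()
    if n == 0:
        return np.full(4, np.nan)
    n_dh = t[1, 1]
    # phase-certain haplotype counts
    base11 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    base10 = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    base01 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
    base00 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    x = n_dh / 2.0  # double hets assigned to the 11/00 phase
    for _ in range(n_iter):
        c = np.array([base11 + x, base10 + n_dh - x, base01 + n_dh - x, base00 + x])
        f = c / (2.0 * n)
        if n_dh == 0:
            break
        num = f[0] * f[3]
        den = num + f[1] * f[2]
        x_new = n_dh * (num / den) if den > 0 else n_dh / 2.0
        if abs(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    c = np.array([base11 + x, base10 + n_dh - x, base01 + n_dh - x, base00 + x])
    return c / (2.0 * n)


def _d_dprime_r2(f: np.ndarray) -> tuple[float, float, float]:
    f11, f10, f01, f00 = f
    pa = f11 + f10
    pb = f11 + f01
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan, np.nan, np.nan
    d = f11 - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d * d / denom
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = d / dmax if dmax > 0 else np.nan
    return d, dprime, r2


def pair_ld(ga: np.ndarray, gb: np.ndarray) -> dict:
    """LD summary (D, D', r^2, n) for one genotype-dosage pair of loci.

    Returns nan statistics when either locus is monomorphic among the
    jointly called samples.
    """
    t = _pair_table(ga, gb)
    f = _hap_freqs_em(t)
    d, dprime, r2 = _d_dprime_r2(f)
    return {"D": d, "dprime": dprime, "r2": r2, "n": int(t.sum()), "hap_freqs": f}


def pairwise_ld(
    panel: PanelGenotypes, max_distance: int = 500_000, snps_only: bool = True
) -> pd.DataFrame:
    """LD for all same-chromosome SNP pairs within ``max_distance``.

    Columns: chrom, pos_a, pos_b, distance, D, dprime, r2.  Pairs with a
    monomorphic member carry nan statistics (undefined sentinel).
    """
    sites = panel.sites
    mask = np.ones(len(sites), bool)
    if snps_only:
        mask = (sites["vclass"] == "SNP").to_numpy()
    rows = []
    for chrom in sites["chrom"].unique():
        sel = np.flatnonzero(mask & (sites["chrom"] == chrom).to_numpy())
        pos = sites["pos"].to_numpy()[sel]
        order = np.argsort(pos)
        sel, pos = sel[order], pos[order]
        for ii in range(len(sel)):
            jj = ii + 1
            while jj < len(sel) and pos[jj] - pos[ii] <= max_distance:
                res = pair_ld(panel.geno[sel[ii]], panel.geno[sel[jj]])
                rows.append(
                    {
                        "chrom": chrom,
                        "pos_a": int(pos[ii]),
                        "pos_b": int(pos[jj]),
                        "distance": int(pos[jj] - pos[ii]),
                        "D": res["D"],
                        "dprime": res["dprime"],
                        "r2": res["r2"],
                    }
                )
                jj += 1
    return pd.DataFrame(
        rows, columns=["chrom", "pos_a", "pos_b", "distance", "D", "dprime", "r2"]
    )


def _monotone_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a non-increasing curve."""
    y = y.astype(float).copy()
    w = np.ones_like(y)
    blocks = [[i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] < vals[i + 1] - 1e-15:
            merged = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / (wts[i] + wts[i + 1])
            vals[i] = merged
            wts[i] += wts[i + 1]
            blocks[i].extend(blocks[i + 1])
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty_like(y)
    for v, idxs in zip(vals, blocks):
        out[idxs] = v
    return out


def ld_decay(
    pairs: pd.DataFrame, bin_width: int = 10_000, label: str = "all"
) -> pd.DataFrame:
    """Mean r^2 per distance bin plus the half-maximum decay distance.

    The decay distance is the start of the first bin where the
    monotone-smoothed mean-r^2 curve falls below half of its maximum bin
    value; it is attached to every row in the ``decay_distance`` column.
    """
    usable = pairs.dropna(subset=["r2"])
    if usable.empty:
        raise ValueError("no usable pairs")
    dist = usable["distance"].to_numpy()
    r2 = usable["r2"].to_numpy()
    b = dist // bin_width
    nb = int(b.max()) + 1
    mean_r2 = np.bincount(b, weights=r2, minlength=nb)
    counts = np.bincount(b, minlength=nb)
    present = counts > 0
    out = pd.DataFrame(
        {
            "bin_start": np.arange(nb)[present] * bin_width,
            "bin_end": (np.arange(nb)[present] + 1) * bin_width,
            "n_pairs": counts[present],
            "mean_r2": mean_r2[present] / counts[present],
        }
    )
    smooth = _monotone_decreasing(out["mean_r2"].to_numpy())
    out["smoothed_r2"] = smooth
    half = smooth.max() / 2.0
    below = np.flatnonzero(smooth < half)
    decay = int(out["bin_start"].iloc[below[0]]) if below.size else int(out["bin_end"].iloc[-1])
    out["decay_distance"] = decay
    out["group"] = label
    return out


# ---------------------------------------------------------------------------
# haplotype blocks (Gabriel CI method)


def _genotype_pair_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair probabilities from haplotype frequencies."""
    f11, f10, f01, f00 = np.maximum(f, 1e-12)
    p = np.empty((3, 3))
    p[0, 0] = f00 * f00
    p[0, 1] = 2 * f00 * f01
    p[0, 2] = f01 * f01
    p[1, 0] = 2 * f00 * f10
    p[1, 1] = 2 * f11 * f00 + 2 * f10 * f01
    p[1, 2] = 2 * f01 * f11
    p[2, 0] = f10 * f10
    p[2, 1] = 2 * f10 * f11
    p[2, 2] = f11 * f11
    return p


def dprime_ci(ga: np.ndarray, gb: np.ndarray, grid: int = 101) -> tuple[float, float]:
    """90% confidence interval of |D'| by likelihood profiling.

    The likelihood of the genotype-pair table is evaluated on a |D'| grid
    with allele frequencies fixed at their estimates and the sign of D
    fixed at its point estimate; grid likelihoods are normalized to a
    weight distribution and the 5th and 95th percentiles are returned
    (Haploview's procedure).
    """
    t = _pair_table(ga, gb)
    f_hat = _hap_freqs_em(t)
    pa = f_hat[0] + f_hat[1]
    pb = f_hat[0] + f_hat[2]
    if not (0 < pa < 1 and 0 < pb < 1):
        return (np.nan, np.nan)
    d_hat = f_hat[0] - pa * pb
    if d_hat >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    if dmax <= 0:
        return (np.nan, np.nan)
    ds = np.linspace(0.0, 1.0, grid)
    logl = np.empty(grid)
    for i, dp in enumerate(ds):
        d = sign * dp * dmax
        f = np.array(
            [
                pa * pb + d,
                pa * (1 - pb) - d,
                (1 - pa) * pb - d,
                (1 - pa) * (1 - pb) + d,
            ]
        )
        probs = _genotype_pair_probs(f)
        logl[i] = float((t * np.log(probs)).sum())
    w = np.exp(logl - logl.max())
    w /= w.sum()
    cum = np.cumsum(w)
    lo = ds[int(np.searchsorted(cum, 0.05))]
    hi = ds[min(int(np.searchsorted(cum, 0.95)), grid - 1)]
    return float(lo), float(hi)


def haplotype_blocks(
    panel: PanelGenotypes, max_span: int = 500_000, snps_only: bool = True
) -> pd.DataFrame:
    """Gabriel-style haplotype blocks; greedy longest-first, non-overlapping.

    Returns a table (chrom, start, end, span, n_snps) sorted by position;
    fewer than two SNPs yield an empty table.
    """
    sites = panel.sites
    mask = np.ones(len(sites), bool)
    if snps_only:
        mask = (sites["vclass"] == "SNP").to_numpy()
    blocks = []
    for chrom in sites["chrom"].unique():
        sel = np.flatnonzero(mask & (sites["chrom"] == chrom).to_numpy())
        pos = sites["pos"].to_numpy()[sel]
        order = np.argsort(pos)
        sel, pos = sel[order], pos[order]
        k = len(sel)
        if k < 2:
            continue
        # classify every in-range pair once
        strong = {}
        for i in range(k):
            for j in range(i + 1, k):
                if pos[j] - pos[i] > max_span:
                    break
                lo, hi = dprime_ci(panel.geno[sel[i]], panel.geno[sel[j]])
                if np.isnan(lo):
                    cls = "uninformative"
                elif lo >= STRONG_LD_LOW and hi >= STRONG_LD_HIGH:
                    cls = "strong_ld"
                elif hi < RECOMB_HIGH:
                    cls = "recomb"
                else:
                    cls = "uninformative"
                strong[(i, j)] = cls
        # candidate spans, longest (bp) first
        cands = []
        for i in range(k):
            for j in range(i + 1, k):
                if pos[j] - pos[i] > max_span:
                    break
                n_ld = n_rec = 0
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        cls = strong.get((a, b), "uninformative")
                        if cls == "strong_ld":
                            n_ld += 1
                        elif cls == "recomb":
                            n_rec += 1
                informative = n_ld + n_rec
                if informative == 0:
                    continue
                if n_ld / informative >= BLOCK_STRONG_FRACTION and strong.get(
                    (i, j)
                ) == "strong_ld":
                    cands.append((pos[j] - pos[i], i, j))
        cands.sort(key=lambda c: (-c[0], c[1]))
        taken = np.zeros(k, bool)
        for span, i, j in cands:
            if taken[i : j + 1].any():
                continue
            taken[i : j + 1] = True
            blocks.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i]),
                    "end": int(pos[j]) + 1,
                    "span": int(pos[j] - pos[i]),
                    "n_snps": int(j - i + 1),
                }
            )
    out = pd.DataFrame(blocks, columns=["chrom", "start", "end", "span", "n_snps"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)
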