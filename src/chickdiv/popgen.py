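"""Windowed diversity statistics and selection-signature scans.

Implements the classical frequency-spectrum statistics on sliding windows of
a biallelic genotype panel: nucleotide diversity (theta_pi), Watterson's
theta_w, Tajima's D, Fu & Li's D* (the no-outgroup, singleton-based
variant), Hudson's FST (ratio-of-sums form), and the two scan styles built
on them: the joint top-FST/top-|delta pi| differentiation scan and the
Tajima's-D region scan for sweeps (negative D) and balancing selection
(positive D).

Missing genotypes are handled by pairwise deletion: every site contributes
its non-missing haplotypes, and the per-window effective sample size used
in the D constants is the window-average non-missing haplotype count,
rounded.  Diploid dosages are haploidized as two identical haplotypes for a
homozygote and one of each allele for a heterozygote.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PanelGenotypes

__all__ = [
    "make_windows",
    "site_allele_counts",
    "window_diversity",
    "window_fst",
    "delta_pi",
    "differentiation_scan",
    "tajima_region_scan",
    "tajima_constants",
    "fu_li_dstar_constants",
]


# ---------------------------------------------------------------------------
# constants of the neutrality statistics


def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _a2(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


def tajima_constants(n: int) -> dict[str, float]:
    """Standard a1, a2, b1, b2, c1, c2, e1, e2 for haploid sample size n."""
    if n < 4:
        raise ValueError("Tajima's D requires haploid sample size >= 4")
    a1, a2 = _a1(n), _a2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def fu_li_dstar_constants(n: int) -> dict[str, float]:
    """u* and v* of Fu & Li's D* (no outgroup), haploid sample size n."""
    if n < 4:
        raise ValueError("Fu & Li's D* requires haploid sample size >= 4")
    nf = float(n)
    a = _a1(n)
    b = _a2(n)
    c = 2.0 * (nf * a - 2.0 * (nf - 1)) / ((nf - 1) * (nf - 2))
    d = (
        c
        + (nf - 2) / (nf - 1) ** 2
        + (2.0 / (nf - 1)) * (1.5 - (2.0 * (a + 1.0 / nf) - 3.0) / (nf - 2) - 1.0 / nf)
    )
    v = ((nf / (nf - 1)) ** 2 * b + a**2 * d - 2.0 * nf * a * (a + 1) / (nf - 1) ** 2) / (
        a**2 + b
    )
    u = (nf / (nf - 1)) * (a - nf / (nf - 1)) - v
    return {"a1": a, "a2": b, "u_star": u, "v_star": v}


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating sites and the window pairwise-diff sum.

    ``pi_sum`` is the summed per-site mean pairwise difference (i.e. pi * L).
    Returns nan when S == 0.
    """
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_sum - S / k["a1"]) / np.sqrt(var))


def fu_li_dstar(S: int, eta1: int, n: int) -> float:
    """Fu & Li's D* from segregating sites and singleton count."""
    if S == 0:
        return float("nan")
    k = fu_li_dstar_constants(n)
    nf = float(n)
    num = (nf / (nf - 1)) * S - k["a1"] * eta1
    var = k["u_star"] * S + k["v_star"] * S * S
    return float(num / np.sqrt(var))


# ---------------------------------------------------------------------------
# windows and per-site counts


def make_windows(
    chromosomes: list[tuple[str, int]], size: int = 10_000
) -> pd.DataFrame:
    """Non-overlapping windows tiling the given chromosomes."""
    rows = []
    for chrom, length in chromosomes:
        starts = np.arange(0, length, size)
        ends = np.minimum(starts + size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def site_allele_counts(
    panel: PanelGenotypes, group: np.ndarray | None = None, snps_only: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt haplotype count, non-missing haplotype count, site mask).

    Haploidization: dosage g contributes g alt haplotypes out of 2.  The
    returned mask selects the sites counted (SNPs by default).
    """
    geno = panel.geno if group is None else panel.geno[:, np.asarray(group)]
    called = geno >= 0
    alt = np.where(called, geno, 0).sum(axis=1)
    m = 2 * called.sum(axis=1)
    mask = np.ones(panel.n_sites, bool)
    if snps_only:
        mask = (panel.sites["vclass"] == "SNP").to_numpy()
    return alt, m, mask


def _window_index(sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Map each site to its window row (-1 if uncovered)."""
    idx = np.full(len(sites), -1, dtype=int)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        smask = (sites["chrom"] == chrom).to_numpy()
        if not smask.any():
            continue
        pos = sites.loc[smask, "pos"].to_numpy()
        starts = wsub["start"].to_numpy()
        ends = wsub["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        rows = wsub.index.to_numpy()
        idx[np.flatnonzero(smask)[ok]] = rows[j[ok]]
    return idx


def _stats_from_counts(widx, alt, m, L, nw, strict=False):
    """Aggregate per-site counts into per-window diversity statistics."""
    seg = (alt > 0) & (alt < m)
    minor = np.minimum(alt, m - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(m > 1, 2.0 * alt * (m - alt) / (m * (m - 1.0)), 0.0)
    S = np.bincount(widx[seg], minlength=nw)
    eta1 = np.bincount(widx[seg & (minor == 1)], minlength=nw)
    pi_sum = np.bincount(widx, weights=site_pi, minlength=nw)
    m_sum = np.bincount(widx, weights=m.astype(float), minlength=nw)
    m_cnt = np.bincount(widx, minlength=nw)
    n_eff = np.zeros(nw, dtype=int)
    has = m_cnt > 0
    n_eff[has] = np.round(m_sum[has] / m_cnt[has]).astype(int)
    theta_w = np.zeros(nw)
    tajd = np.full(nw, np.nan)
    dstar = np.full(nw, np.nan)
    for i in range(nw):
        if m_cnt[i] == 0:
            continue
        n = int(n_eff[i])
        if n < 4:
            if strict:
                raise ValueError(f"window {i}: effective haploid sample size {n} < 4")
            continue
        theta_w[i] = S[i] / (_a1(n) * L[i])
        if S[i] > 0:
            tajd[i] = tajimas_d(int(S[i]), float(pi_sum[i]), n)
            dstar[i] = fu_li_dstar(int(S[i]), int(eta1[i]), n)
    return S, eta1, pi_sum, n_eff, theta_w, tajd, dstar


def window_diversity(
    panel: PanelGenotypes,
    windows: pd.DataFrame,
    group: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-window S, singletons, pi, theta_w, Tajima's D and Fu & Li's D*.

    ``group`` selects sample columns (indices); None uses the full panel.
    Windows without segregating sites report D and D* as nan.
    """
    if group is not None and len(group) < 2:
        raise ValueError("need at least 2 diploid samples (n >= 4 haplotypes)")
    alt, m, mask = site_allele_counts(panel, group)
    widx = _window_index(panel.sites, windows)
    use = mask & (widx >= 0) & (m >= 2)
    alt, m, widx = alt[use], m[use], widx[use]

    L = (windows["end"] - windows["start"]).to_numpy(float)
    S, eta1, pi_sum, n_eff, theta_w, tajd, dstar = _stats_from_counts(
        widx, alt, m, L, len(windows), strict=True
    )

    out = windows.copy()
    out["L"] = L.astype(int)
    out["n"] = n_eff
    out["S"] = S
    out["eta1"] = eta1
    out["pi"] = pi_sum / L
    out["theta_w"] = theta_w
    out["tajima_d"] = tajd
    out["fu_li_dstar"] = dstar
    return out


# ---------------------------------------------------------------------------
# differentiation


def _group_freqs(panel, group):
    alt, m, mask = site_allele_counts(panel, group)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
    return p, m, mask


def window_fst(
    panel: PanelGenotypes,
    windows: pd.DataFrame,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> pd.DataFrame:
    """Hudson's FST per window, averaged as ratio of sums over sites.

    Per site, with allele frequencies p1, p2 on n1, n2 haplotypes:
    ``N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
    ``D = p1(1-p2) + p2(1-p1)``; the window estimate is sum(N)/sum(D).
    Windows where no site has both groups called on >= 2 haplotypes get nan.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    p1, m1, mask = _group_freqs(panel, group_a)
    p2, m2, _ = _group_freqs(panel, group_b)
    widx = _window_index(panel.sites, windows)
    use = mask & (widx >= 0) & (m1 >= 2) & (m2 >= 2)
    p1, p2, m1, m2, widx = p1[use], p2[use], m1[use], m2[use], widx[use]

    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (m1 - 1) - p2 * (1 - p2) / (m2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)

    nw = len(windows)
    num_sum = np.bincount(widx, weights=num, minlength=nw)
    den_sum = np.bincount(widx, weights=den, minlength=nw)
    out = windows.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(den_sum > 0, num_sum / den_sum, np.nan)
    return out


def delta_pi(
    panel: PanelGenotypes,
    windows: pd.DataFrame,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> pd.DataFrame:
    """Per-window pi(group A) - pi(group B)."""
    da = window_diversity(panel, windows, group_a)
    db = window_diversity(panel, windows, group_b)
    out = windows.copy()
    out["pi_a"] = da["pi"]
    out["pi_b"] = db["pi"]
    out["delta_pi"] = da["pi"] - db["pi"]
    return out


def _merge_adjacent(windows: pd.DataFrame, flags: np.ndarray) -> pd.DataFrame:
    """Merge runs of flagged, genomically adjacent windows into regions."""
    rows = []
    cur = None
    for i in np.flatnonzero(flags):
        w = windows.iloc[i]
        if (
            cur is not None
            and w["chrom"] == cur["chrom"]
            and w["start"] == cur["end"]
        ):
            cur["end"] = w["end"]
            cur["n_windows"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": w["chrom"],
                "start": int(w["start"]),
                "end": int(w["end"]),
                "n_windows": 1,
            }
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])


def differentiation_scan(
    fst_windows: pd.DataFrame,
    dpi_windows: pd.DataFrame,
    top_fraction: float = 0.02,
) -> pd.DataFrame:
    """Regions in the top fraction by FST AND by |delta pi| (the overlap).

    Mirrors the between-market-type differentiation scan: windows ranking in
    the top ``top_fraction`` of both statistics are kept and merged into
    regions; the default fraction is tuned so the selected span is a small
    percent of the genome.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(fst_windows) != len(dpi_windows):
        raise ValueError("FST and delta-pi must be computed on the same windows")
    fst = fst_windows["fst"].to_numpy()
    dpi = np.abs(dpi_windows["delta_pi"].to_numpy())
    ok = ~np.isnan(fst) & ~np.isnan(dpi)
    if not ok.any():
        return _merge_adjacent(fst_windows, np.zeros(len(fst), bool))
    fst_cut = np.nanquantile(fst[ok], 1 - top_fraction)
    dpi_cut = np.nanquantile(dpi[ok], 1 - top_fraction)
    flags = ok & (fst >= fst_cut) & (dpi >= dpi_cut)
    out = _merge_adjacent(fst_windows, flags)
    out["class"] = "differentiation"
    return out


def _permutation_null_d(
    panel: PanelGenotypes, stats: pd.DataFrame, n_perm: int, seed: int,
    group: np.ndarray | None = None,
) -> np.ndarray:
    """Null window-D sample obtained by permuting site-to-window labels.

    Shuffling which window each segregating site belongs to destroys the
    spatial clustering that selection creates while preserving the
    genome-wide frequency spectrum, giving a within-genome null for the
    per-window statistic.
    """
    alt, m, mask = site_allele_counts(panel, group)
    widx = _window_index(panel.sites, stats)
    use = mask & (widx >= 0) & (m >= 2)
    alt, m, widx = alt[use], m[use], widx[use]
    L = (stats["end"] - stats["start"]).to_numpy(float)
    rng = np.random.default_rng(seed)
    null: list[np.ndarray] = []
    for _ in range(n_perm):
        perm = rng.permutation(widx)
        d = _stats_from_counts(perm, alt, m, L, len(stats))[5]
        null.append(d[~np.isnan(d)])
    return np.concatenate(null) if null else np.array([])


def tajima_region_scan(
    stats: pd.DataFrame,
    direction: str = "negative",
    min_span: int = 150_000,
    null_method: str = "permutation",
    alpha: float = 0.05,
    n_perm: int = 50,
    seed: int = 0,
    panel: PanelGenotypes | None = None,
    group: np.ndarray | None = None,
) -> pd.DataFrame:
    """Contiguous runs of significantly extreme Tajima's D windows.

    ``permutation`` (needs ``panel``): each window's D is compared against
    a null distribution built by shuffling site-to-window labels within the
    genome and recomputing the statistic; ``empirical-quantile``: the
    genome-wide empirical distribution of window D stands in as the null
    (an outlier criterion).  Two-sided p-values are Benjamini–Hochberg
    adjusted; runs of significant windows of the requested sign whose
    merged span reaches ``min_span`` are reported.  Sweeps depress D
    (``negative``); balancing selection inflates it (``positive``).
    """
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    if null_method not in ("permutation", "empirical-quantile"):
        raise ValueError(f"unknown null_method {null_method!r}")
    d = stats["tajima_d"].to_numpy(float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("all windows have undefined Tajima's D")
    dv = d[ok]
    if null_method == "permutation":
        if panel is None:
            raise ValueError("permutation null requires the genotype panel")
        null = _permutation_null_d(panel, stats, n_perm, seed, group)
    else:
        null = dv
    # two-sided empirical p-value per window against the null sample
    lo = (null[None, :] <= dv[:, None]).mean(axis=1)
    hi = (null[None, :] >= dv[:, None]).mean(axis=1)
    p = np.minimum(1.0, 2.0 * np.minimum(lo, hi) + 1.0 / (len(null) + 1))
    p_adj = _bh_adjust(p)
    sig = np.zeros(len(stats), bool)
    signed = dv < 0 if direction == "negative" else dv > 0
    sig[np.flatnonzero(ok)] = (p_adj <= alpha) & signed
    regions = _merge_adjacent(stats, sig)
    regions = regions[(regions["end"] - regions["start"]) >= min_span].reset_index(
        drop=True
    )
    regions["class"] = "sweep" if direction == "negative" else "balancing"
    return regions


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
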