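"""Synthetic variety-panel generator with a planted-truth ledger.

The generator emulates the data substrate of a crop re-sequencing panel: a
small multi-chromosome reference with CDS-bearing gene models, a mostly
homozygous (selfing) diploid panel drawn from a few admixed subpopulations,
a neutral mutation background with planted low-diversity sweep regions and
excess-intermediate-frequency balancing regions, per-sample Poisson
sequencing depth with planted copy-number multipliers and presence/absence
dropouts, and genotype missingness.

Neutral background model
------------------------
Candidate variant sites arise at rate ``theta * a1(n_pool)`` per bp, where
``a1(n) = sum_{i<n} 1/i`` and ``n_pool`` is a large notional population
(default 1000 haplotypes).  Each site's ancestral allele frequency is drawn
from the discrete neutral frequency spectrum ``P(k) proportional to 1/k``.
Because binomial subsampling preserves the neutral spectrum, a sample of
``n`` haplotypes then shows ``E[S] = theta * L * a1(n)`` segregating sites
and ``E[pi] = theta * L`` — i.e. the background is calibrated so that the
standard estimators recover the configured theta without any coalescent
machinery.  Subpopulation differentiation uses the Balding–Nichols Beta
model around the ancestral frequency; per-sample ancestry is Dirichlet.

Selfing is applied as genotype collapse: a heterozygote becomes a random
homozygote with probability equal to the selfing rate, which makes realized
heterozygosity decline monotonically with that rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import DepthTrack, Gene, GenomeModel, PanelGenotypes, make_sample_sheet

__all__ = [
    "PanelConfig",
    "TruthSet",
    "simulate_genome",
    "simulate_panel",
    "simulate_haplotype_mosaic",
    "neutral_config",
    "demo_config",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: notional population size (haplotypes) behind the neutral spectrum
N_POOL = 1000


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass
class PanelConfig:
    """All knobs of the synthetic panel, with chickpea-panel-like defaults.

    Depth is mean per-base sequencing depth per sample (the study's panel
    averaged ~10x); theta is the scaled mutation rate per bp; selfing is
    the probability that a heterozygous call collapses to a homozygote
    (chickpea is a predominantly selfing species, so the default is high).
    """

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("Ca1", 500_000), ("Ca2", 500_000)]
    )
    cds_fraction: float = 0.25
    n_genes: Optional[int] = None  # if set, overrides cds_fraction targeting
    samples_per_group: int | dict = 4
    n_subpops: int = 3
    theta: float = 0.002
    divergence: float = 0.15  # Balding-Nichols F between subpopulations
    admixture_alpha: float = 0.2
    selfing: float = 0.9
    missing_rate: float = 0.05
    mean_depth: float = 10.0
    bin_width: int = 1000
    indel_fraction: float = 0.1
    pav_dropout_multiplier: float = 0.05
    # planted features
    sweeps: list[tuple] = field(default_factory=list)  # (chrom, start, end, factor)
    balancing: list[tuple] = field(default_factory=list)  # (chrom, start, end, weight)
    cnv_events: list[tuple] = field(default_factory=list)  # (sample, chrom, s, e, CN)
    pav_events: list[tuple] = field(
        default_factory=list
    )  # (samples: tuple, chrom, s, e, region_class)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length < 10_000:
                raise ConfigError(f"chromosome {name} shorter than 10 kb")
        if not 0.0 <= self.cds_fraction <= 1.0:
            raise ConfigError("cds_fraction must be in [0, 1]")
        for rate, label in [
            (self.selfing, "selfing"),
            (self.missing_rate, "missing_rate"),
            (self.indel_fraction, "indel_fraction"),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{label} must be in [0, 1]")
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be >= 1")
        if not 0.0 < self.divergence < 1.0:
            raise ConfigError("divergence must be in (0, 1)")

    def sample_sheet(self) -> pd.DataFrame:
        return make_sample_sheet(self.samples_per_group)


@dataclass
class TruthSet:
    """Planted ground truth returned alongside every simulated panel."""

    site_freqs: pd.DataFrame  # chrom, pos + one frequency column per subpop
    sweeps: pd.DataFrame  # chrom, start, end, factor
    balancing: pd.DataFrame  # chrom, start, end, weight
    cnv_events: pd.DataFrame  # sample, chrom, start, end, copy_number
    pav_regions: pd.DataFrame  # chrom, start, end, region_class
    pav_states: pd.DataFrame  # region index, sample, state (absent/present)
    Q0: np.ndarray  # true admixture proportions (n_samples, K)
    F0: np.ndarray  # true subpop allele frequencies (K, n_sites)

    def __post_init__(self) -> None:
        if self.Q0.size and not np.allclose(self.Q0.sum(axis=1), 1.0):
            raise ValueError("Q0 rows must sum to 1")


def neutral_config(
    theta: float = 0.002,
    n_samples: int = 20,
    length: int = 1_000_000,
    seed: int = 0,
    **kwargs,
) -> PanelConfig:
    """Single-population neutral preset used for estimator calibration.

    One panmictic subpopulation, no selfing collapse, no missingness and no
    planted features: the conditions under which the sampling theory of
    Tajima's D and the theta estimators applies.  (Under the chickpea-like
    default selfing of 0.9 the naive 2N-haplotype Tajima's D is positively
    biased by design — a property of selfing, not of the estimators.)
    """
    per_group, rem = divmod(n_samples, 6)
    counts = {}
    i = 0
    from .core import MARKET_TYPES, RELEASE_PERIODS

    for m in MARKET_TYPES:
        for r in RELEASE_PERIODS:
            counts[(m, r)] = per_group + (1 if i < rem else 0)
            i += 1
    return PanelConfig(
        chromosomes=[("Ca1", length)],
        cds_fraction=kwargs.pop("cds_fraction", 0.0),
        samples_per_group=counts,
        n_subpops=1,
        theta=theta,
        selfing=0.0,
        missing_rate=0.0,
        indel_fraction=0.0,
        seed=seed,
        **kwargs,
    )


def demo_config(seed: int = 0) -> PanelConfig:
    """Structured demo panel with one planted feature of every kind."""
    return PanelConfig(
        chromosomes=[("Ca1", 200_000), ("Ca2", 200_000)],
        samples_per_group=4,
        seed=seed,
        sweeps=[("Ca1", 20_000, 60_000, 0.1)],
        balancing=[("Ca2", 100_000, 140_000, 0.9)],
        cnv_events=[("v000", "Ca1", 120_000, 150_000, 3.0)],
        pav_events=[
            (("v001", "v002", "v003", "v004"), "Ca2", 20_000, 40_000, "deletion"),
        ],
    )


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: PanelConfig) -> GenomeModel:
    """Generate a toy reference: random sequence plus spaced gene models.

    Deterministic for a given ``config.seed`` and independent of the panel
    draws (genome and panel use separate child seeds).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sequences = {
        name: rng.choice(BASES, size=length).tobytes().decode()
        for name, length in config.chromosomes
    }
    genes: list[Gene] = []
    if config.cds_fraction > 0 or config.n_genes:
        genes = _place_genes(config, rng)
    return GenomeModel(
        chromosomes=list(config.chromosomes), sequences=sequences, genes=genes
    )


def _place_genes(config: PanelConfig, rng: np.random.Generator) -> list[Gene]:
    mean_cds, mean_introns = 1650.0, 900.0
    frac = config.cds_fraction if config.cds_fraction > 0 else 0.25
    mean_gap = max(100.0, mean_cds * (1.0 / frac - 1.0) - mean_introns)
    genes: list[Gene] = []
    gid = 0
    for chrom, length in config.chromosomes:
        pos = int(rng.exponential(mean_gap)) + 1
        while pos < length:
            if config.n_genes is not None and gid >= config.n_genes:
                return genes
            cds_total = int(np.clip(rng.normal(mean_cds, 400), 300, 3000))
            cds_total -= cds_total % 3
            n_exons = min(1 + rng.poisson(2), cds_total // 30)
            cuts = np.sort(rng.choice(np.arange(1, cds_total), n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
            exon_lens = np.diff(np.concatenate([[0], cuts, [cds_total]]))
            intron_lens = rng.integers(80, 800, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if pos + span > length:
                break
            cds = []
            p = pos
            for i, el in enumerate(exon_lens):
                cds.append((p, p + int(el)))
                p += int(el)
                if i < len(intron_lens):
                    p += int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"g{gid:04d}", chrom, strand, tuple(cds)))
            gid += 1
            pos = p + int(rng.exponential(mean_gap)) + 1
    return genes


# ---------------------------------------------------------------------------
# panel


def _neutral_counts(rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw allele counts k in 1..N_POOL-1 with P(k) proportional to 1/k."""
    k = np.arange(1, N_POOL)
    p = (1.0 / k) / np.sum(1.0 / k)
    return rng.choice(k, size=size, p=p)


def _events_overlap(intervals: list[tuple[str, int, int]]) -> bool:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                return True
    return False


def simulate_panel(
    genome: GenomeModel, config: PanelConfig
) -> tuple[PanelGenotypes, DepthTrack, TruthSet]:
    """Simulate genotypes, depth tracks and the truth ledger for one panel."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = config.sample_sheet()
    n = len(samples)
    K = config.n_subpops

    # ancestry: Dirichlet admixture over K source subpopulations
    if K == 1:
        Q0 = np.ones((n, 1))
    else:
        Q0 = rng.dirichlet([config.admixture_alpha] * K, size=n)

    # --- sites ------------------------------------------------------------
    chrom_arr, pos_arr = [], []
    for chrom, length in genome.chromosomes:
        rate = config.theta * length * _a1(N_POOL)
        m = rng.poisson(rate)
        pos = np.sort(rng.choice(length - 12, size=min(m, length - 12), replace=False))
        chrom_arr.append(np.full(len(pos), chrom))
        pos_arr.append(pos)
    chrom_sites = np.concatenate(chrom_arr)
    pos_sites = np.concatenate(pos_arr)

    # sweep thinning: inside a sweep, site density is multiplied by `factor`
    keep = np.ones(len(pos_sites), bool)
    for chrom, s, e, factor in config.sweeps:
        inside = (chrom_sites == chrom) & (pos_sites >= s) & (pos_sites < e)
        keep[inside] &= rng.random(inside.sum()) < factor
    chrom_sites, pos_sites = chrom_sites[keep], pos_sites[keep]
    m_sites = len(pos_sites)

    p_anc = _neutral_counts(rng, m_sites) / N_POOL

    # subpopulation frequencies: Balding-Nichols Beta around the ancestral p
    if K == 1:
        F0 = p_anc[None, :].copy()
    else:
        c = (1.0 - config.divergence) / config.divergence
        F0 = rng.beta(
            np.maximum(p_anc * c, 1e-6), np.maximum((1 - p_anc) * c, 1e-6), size=(K, m_sites)
        )

    # planted selection: scale minor-allele frequency down inside sweeps,
    # pull frequencies toward 0.5 inside balancing regions
    for chrom, s, e, factor in config.sweeps:
        inside = (chrom_sites == chrom) & (pos_sites >= s) & (pos_sites < e)
        f = F0[:, inside]
        F0[:, inside] = np.where(f <= 0.5, f * factor, 1 - (1 - f) * factor)
    for chrom, s, e, weight in config.balancing:
        inside = (chrom_sites == chrom) & (pos_sites >= s) & (pos_sites < e)
        F0[:, inside] = (1 - weight) * F0[:, inside] + weight * 0.5

    # --- genotypes ---------------------------------------------------------
    P = np.clip(Q0 @ F0, 0.0, 1.0)  # (n, m) individual allele frequencies
    geno = rng.binomial(2, P).astype(np.int8).T  # (m, n)
    if config.selfing > 0:
        het = geno == 1
        collapse = het & (rng.random(geno.shape) < config.selfing)
        geno[collapse] = 2 * rng.integers(0, 2, size=int(collapse.sum()), dtype=np.int8)

    # --- alleles and variant classes ---------------------------------------
    sites = _assign_alleles(genome, chrom_sites, pos_sites, config, rng)

    # --- depth track with planted CNV / PAV multipliers --------------------
    track, mult, pav_regions, pav_states = _depth_track(genome, config, samples, rng)

    # per-site per-sample depth follows the local bin multiplier
    bin_key = {
        (c, s): i for i, (c, s) in enumerate(zip(track.bins["chrom"], track.bins["start"]))
    }
    site_bin = np.array(
        [bin_key[(c, (p // config.bin_width) * config.bin_width)] for c, p in zip(chrom_sites, pos_sites)],
        dtype=int,
    ) if m_sites else np.array([], dtype=int)
    site_mult = mult[site_bin, :] if m_sites else np.zeros((0, n))
    depth = rng.poisson(config.mean_depth * site_mult).astype(np.int32)

    # genotypes are uncallable where the sample lacks the sequence
    absent_mult = config.pav_dropout_multiplier
    geno[site_mult <= absent_mult] = -1
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = -1

    panel = PanelGenotypes(sites=sites, geno=geno, depth=depth, samples=samples)
    truth = TruthSet(
        site_freqs=pd.concat(
            [
                pd.DataFrame({"chrom": chrom_sites, "pos": pos_sites}),
                pd.DataFrame(F0.T, columns=[f"subpop{k}" for k in range(K)]),
            ],
            axis=1,
        ),
        sweeps=pd.DataFrame(config.sweeps, columns=["chrom", "start", "end", "factor"]),
        balancing=pd.DataFrame(
            config.balancing, columns=["chrom", "start", "end", "weight"]
        ),
        cnv_events=pd.DataFrame(
            config.cnv_events, columns=["sample", "chrom", "start", "end", "copy_number"]
        ),
        pav_regions=pav_regions,
        pav_states=pav_states,
        Q0=Q0,
        F0=F0,
    )
    return panel, track, truth


def simulate_haplotype_mosaic(
    genome: GenomeModel,
    config: PanelConfig,
    n_founders: int = 8,
    switch_rate: float = 5e-5,
) -> PanelGenotypes:
    """Panel with genuine linkage: samples are mosaics of founder haplotypes.

    The main generator draws every site independently, which is the right
    null for frequency-spectrum statistics but carries no linkage at all.
    For LD work this variant builds ``n_founders`` founder haplotypes over
    the site list and lets each sampled haplotype copy one founder at a
    time, switching to a random founder between consecutive sites with
    probability ``1 - exp(-switch_rate * gap)``.  Pairwise r^2 then decays
    with physical distance on the scale of ``1/switch_rate`` bp toward the
    founder-panel floor (~``1/n_founders``).  Selfing makes a sample's two
    haplotypes identical with the equilibrium autozygosity probability
    ``s/(2-s)``.
    """
    if n_founders < 2:
        raise ConfigError("need at least 2 founder haplotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = config.sample_sheet()
    n = len(samples)

    chrom_arr, pos_arr = [], []
    for chrom, length in genome.chromosomes:
        m = rng.poisson(config.theta * length * _a1(N_POOL))
        pos = np.sort(rng.choice(length - 12, size=min(m, length - 12), replace=False))
        chrom_arr.append(np.full(len(pos), chrom))
        pos_arr.append(pos)
    chrom_sites = np.concatenate(chrom_arr)
    pos_sites = np.concatenate(pos_arr)
    m_sites = len(pos_sites)

    p_anc = _neutral_counts(rng, m_sites) / N_POOL
    founders = (rng.random((n_founders, m_sites)) < p_anc[None, :]).astype(np.int8)

    autozygous = rng.random(n) < config.selfing / (2.0 - config.selfing)
    hap = np.empty((2 * n, m_sites), dtype=np.int8)
    for h in range(2 * n):
        sample_i = h // 2
        if h % 2 == 1 and autozygous[sample_i]:
            hap[h] = hap[h - 1]
            continue
        cur = int(rng.integers(n_founders))
        out = np.empty(m_sites, dtype=np.int8)
        for chrom, _ in genome.chromosomes:
            idx = np.flatnonzero(chrom_sites == chrom)
            if idx.size == 0:
                continue
            gaps = np.diff(pos_sites[idx], prepend=pos_sites[idx[0]])
            switch = rng.random(idx.size) < -np.expm1(-switch_rate * gaps)
            for k, site in enumerate(idx):
                if switch[k]:
                    cur = int(rng.integers(n_founders))
                out[site] = founders[cur, site]
        hap[h] = out
    geno = (hap[0::2] + hap[1::2]).T.astype(np.int8)  # (m, n)
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = -1

    sites = _assign_alleles(genome, chrom_sites, pos_sites, config, rng)
    depth = rng.poisson(config.mean_depth, size=geno.shape).astype(np.int32)
    return PanelGenotypes(sites=sites, geno=geno, depth=depth, samples=samples)


def _assign_alleles(
    genome: GenomeModel,
    chrom_sites: np.ndarray,
    pos_sites: np.ndarray,
    config: PanelConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    m = len(pos_sites)
    vclass = np.full(m, "SNP", dtype=object)
    is_indel = rng.random(m) < config.indel_fraction
    ins = rng.random(m) < 0.5
    vclass[is_indel & ins] = "insertion"
    vclass[is_indel & ~ins] = "deletion"
    # 1-bp indels most abundant, geometric tail capped at 10 bp
    ilen = np.minimum(rng.geometric(0.5, size=m), 10)
    ref, alt = [], []
    for i in range(m):
        seq = genome.sequences[chrom_sites[i]]
        p = int(pos_sites[i])
        base = seq[p]
        if vclass[i] == "SNP":
            others = [b for b in "ACGT" if b != base]
            ref.append(base)
            alt.append(others[rng.integers(0, 3)])
        elif vclass[i] == "insertion":
            ref.append(base)
            alt.append(base + "".join(rng.choice(list("ACGT"), size=ilen[i])))
        else:  # deletion of ilen bases after the anchor
            ref.append(seq[p : p + 1 + ilen[i]])
            alt.append(base)
    return pd.DataFrame(
        {"chrom": chrom_sites, "pos": pos_sites, "ref": ref, "alt": alt, "vclass": vclass}
    )


def _depth_track(
    genome: GenomeModel,
    config: PanelConfig,
    samples: pd.DataFrame,
    rng: np.random.Generator,
):
    ids = list(samples["sample"])
    n = len(ids)
    rows = []
    for chrom, length in genome.chromosomes:
        starts = np.arange(0, length, config.bin_width)
        ends = np.minimum(starts + config.bin_width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    mult = np.ones((len(bins), n))

    # validate no overlapping planted structural events within one sample
    per_sample: dict[str, list[tuple[str, int, int]]] = {}
    for sample, chrom, s, e, _cn in config.cnv_events:
        per_sample.setdefault(sample, []).append((chrom, s, e))
    for members, chrom, s, e, _cls in config.pav_events:
        for sample in members:
            per_sample.setdefault(sample, []).append((chrom, s, e))
    for sample, ivs in per_sample.items():
        if _events_overlap(ivs):
            raise ConfigError(f"overlapping planted structural events in {sample}")

    idx = {sid: j for j, sid in enumerate(ids)}
    bstart = bins["start"].to_numpy()
    bend = bins["end"].to_numpy()
    bchrom = bins["chrom"].to_numpy()

    def region_bins(chrom, s, e):
        return (bchrom == chrom) & (bstart < e) & (bend > s)

    for sample, chrom, s, e, cn in config.cnv_events:
        if sample not in idx:
            raise ConfigError(f"unknown sample {sample} in cnv_events")
        mult[region_bins(chrom, s, e), idx[sample]] = cn

    preg_rows, pstate_rows = [], []
    for ri, (members, chrom, s, e, region_class) in enumerate(config.pav_events):
        if region_class not in ("deletion", "insertion"):
            raise ConfigError(f"bad PAV region class {region_class!r}")
        preg_rows.append(
            {"chrom": chrom, "start": s, "end": e, "region_class": region_class}
        )
        sel = region_bins(chrom, s, e)
        for sid in ids:
            carrier = sid in members
            if region_class == "deletion":
                absent = carrier  # listed samples lost the segment
            else:
                absent = not carrier  # only listed samples carry the insertion
            if absent:
                mult[sel, idx[sid]] = config.pav_dropout_multiplier
            pstate_rows.append(
                {"region": ri, "sample": sid, "state": "absent" if absent else "present"}
            )
    pav_regions = pd.DataFrame(
        preg_rows, columns=["chrom", "start", "end", "region_class"]
    )
    pav_states = pd.DataFrame(pstate_rows, columns=["region", "sample", "state"])

    depth = rng.poisson(config.mean_depth * mult).astype(float)
    return DepthTrack(bins=bins, depth=depth, sample_ids=ids), mult, pav_regions, pav_states
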