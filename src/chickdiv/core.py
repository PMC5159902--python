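"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; conversion to
1-based happens only at the VCF/GFF boundary (see :mod:`chickdiv.io`).
Genotypes are stored as alt-allele dosage (0/1/2) with -1 for missing, the
natural encoding for a predominantly selfing diploid panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: canonical cohort labels used throughout: market type x release period
MARKET_TYPES = ("desi", "kabuli")
RELEASE_PERIODS = ("RP1", "RP2", "RP3")


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene model on the toy reference.

    ``cds`` holds 0-based half-open intervals, non-overlapping and sorted in
    genomic order; the reading frame starts at the first CDS base in strand
    order (frame offset 0).
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        last = -1
        for start, end in self.cds:
            if start < 0 or end <= start:
                raise ValueError(f"bad CDS interval ({start}, {end})")
            if start < last:
                raise ValueError("CDS intervals overlap or are unsorted")
            last = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"total CDS length {self.cds_length} of {self.gene_id} "
                "is not divisible by 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first CDS start, last CDS end)."""
        return self.cds[0][0], self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GenomeModel:
    """Toy reference genome: chromosome sequences plus gene models."""

    chromosomes: list[tuple[str, int]]
    sequences: dict[str, str]
    genes: list[Gene]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length < 10_000:
                raise ValueError(f"chromosome {name} shorter than 10 kb")
            if len(self.sequences[name]) != length:
                raise ValueError(f"sequence length mismatch on {name}")
        for gene in self.genes:
            if gene.chrom not in lengths:
                raise ValueError(f"{gene.gene_id} on unknown chromosome")
            if gene.span[1] > lengths[gene.chrom]:
                raise ValueError(f"{gene.gene_id} extends past chromosome end")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def cds_fraction(self) -> float:
        return sum(g.cds_length for g in self.genes) / self.total_length


@dataclass
class PanelGenotypes:
    """Sites x samples biallelic genotype matrix with metadata.

    ``sites``: DataFrame with columns chrom, pos (0-based), ref, alt, vclass
    (one of ``SNP``/``insertion``/``deletion``).
    ``geno``: int8 array (n_sites, n_samples), alt dosage or -1.
    ``depth``: int32 array (n_sites, n_samples), per-sample site depth.
    ``samples``: DataFrame with columns sample, market_type, release_period,
    country.
    """

    sites: pd.DataFrame
    geno: np.ndarray
    depth: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        n_sites, n_samples = self.geno.shape
        if len(self.sites) != n_sites:
            raise ValueError("site table / genotype matrix row mismatch")
        if len(self.samples) != n_samples:
            raise ValueError("sample sheet / genotype matrix column mismatch")
        if self.depth.shape != self.geno.shape:
            raise ValueError("depth matrix shape mismatch")
        bad = (self.geno < -1) | (self.geno > 2)
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return self.geno.shape[0]

    @property
    def n_samples(self) -> int:
        return self.geno.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample"])

    def subset_sites(self, mask: np.ndarray) -> "PanelGenotypes":
        mask = np.asarray(mask)
        return PanelGenotypes(
            sites=self.sites.loc[mask].reset_index(drop=True),
            geno=self.geno[mask],
            depth=self.depth[mask],
            samples=self.samples,
        )

    def subset_samples(self, idx: Sequence[int]) -> "PanelGenotypes":
        idx = np.asarray(idx)
        return PanelGenotypes(
            sites=self.sites.copy(),
            geno=self.geno[:, idx],
            depth=self.depth[:, idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
        )

    def group_indices(self, by: str) -> dict[str, np.ndarray]:
        """Column-index arrays for each level of a sample-sheet column."""
        out: dict[str, np.ndarray] = {}
        for level, sub in self.samples.groupby(by, sort=True):
            out[str(level)] = np.asarray(sub.index)
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing calls.

        Monomorphic-by-missingness sites (no calls at all) yield nan.
        """
        called = self.geno >= 0
        alt = np.where(called, self.geno, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def missing_ratio(self) -> np.ndarray:
        return (self.geno == MISSING).mean(axis=1)


@dataclass
class DepthTrack:
    """Per-sample mean sequencing depth in fixed genomic bins.

    ``bins``: DataFrame (chrom, start, end), sorted, non-overlapping, shared
    by all samples. ``depth``: float array (n_bins, n_samples).
    """

    bins: pd.DataFrame
    depth: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.depth.shape != (len(self.bins), len(self.sample_ids)):
            raise ValueError("depth matrix shape mismatch")
        if (self.depth < 0).any():
            raise ValueError("negative depths")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (ends <= starts).any() or (starts[1:] < ends[:-1]).any():
                raise ValueError(f"bins on {chrom} unsorted or overlapping")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample: str) -> int:
        return self.sample_ids.index(sample)

    def genome_mean(self) -> np.ndarray:
        """Genome-wide mean depth per sample (length-weighted over bins)."""
        w = (self.bins["end"] - self.bins["start"]).to_numpy(float)
        return (self.depth * w[:, None]).sum(axis=0) / w.sum()

    def modal_depth(self) -> np.ndarray:
        """Per-sample modal bin depth (rounded)."""
        out = np.empty(self.n_samples)
        for j in range(self.n_samples):
            vals, counts = np.unique(np.round(self.depth[:, j]), return_counts=True)
            out[j] = vals[np.argmax(counts)]
        return out

    def baseline_depth(self) -> np.ndarray:
        """Per-sample diploid baseline: the median bin depth.

        Like the mode, the median resists contamination by large
        amplifications (breakdown point 50%), but it is far more stable at
        typical 10x coverage where integer Poisson bin counts make the
        sample mode jitter over several adjacent values.
        """
        return np.median(self.depth, axis=0)

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        b = self.bins
        return np.asarray(
            (b["chrom"] == chrom) & (b["start"] < end) & (b["end"] > start)
        )

    def region_mean(self, sample: str, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean depth of a region for one sample."""
        mask = self.bins_overlapping(chrom, start, end)
        if not mask.any():
            raise ValueError(f"region {chrom}:{start}-{end} covered by no bins")
        sub = self.bins.loc[mask]
        ov = np.minimum(sub["end"], end) - np.maximum(sub["start"], start)
        d = self.depth[mask, self.sample_index(sample)]
        return float((d * ov).sum() / ov.sum())


def make_sample_sheet(samples_per_group: int | dict = 4) -> pd.DataFrame:
    """Build a variety sample sheet over market type x release period.

    ``samples_per_group`` is either a flat count applied to all six cells or
    a mapping ``{(market_type, release_period): n}``.
    """
    if isinstance(samples_per_group, int):
        counts = {
            (m, r): samples_per_group for m in MARKET_TYPES for r in RELEASE_PERIODS
        }
    else:
        counts = dict(samples_per_group)
    countries = ("India", "Canada", "Australia", "Ethiopia")
    rows = []
    i = 0
    for (market, rp), n in counts.items():
        for _ in range(n):
            rows.append(
                {
                    "sample": f"v{i:03d}",
                    "market_type": market,
                    "release_period": rp,
                    "country": countries[i % len(countries)],
                }
            )
            i += 1
    return pd.DataFrame(rows)
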