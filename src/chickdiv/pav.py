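"""Presence/absence variation and gene-loss calling from depth coverage.

A deletion-type region is called absent in a sample when its mean depth is
under 10% of the sample's genome-wide mean; an insertion-type region is
called present when its mean depth exceeds 50% of the genome-wide mean.
Both thresholds are strict inequalities and scale with the sample's own
mean depth, so calls are invariant under uniform depth rescaling.  A group
carries a region-level PAV when strictly more than three of its samples
share the same state.  Gene loss uses bin-approximated coverage: a gene is
lost in a sample when under 10% of its span lies in bins with depth >= 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import DepthTrack, GenomeModel

__all__ = [
    "call_sample_pav",
    "call_panel_pav",
    "call_group_pav",
    "call_gene_loss",
    "absence_spectrum",
]

log = logging.getLogger(__name__)

ABSENCE_FRACTION = 0.10  # deletion-type absence threshold (of genome mean)
PRESENCE_FRACTION = 0.50  # insertion-type presence threshold
GROUP_MIN_SHARED = 3  # group flagged when strictly more than this many agree
GENE_LOSS_COVERAGE = 0.10  # covered fraction below which a gene is lost


def call_sample_pav(
    track: DepthTrack,
    sample: str,
    chrom: str,
    start: int,
    end: int,
    region_class: str,
) -> str:
    """State (``present``/``absent``) of one region in one sample."""
    if region_class not in ("deletion", "insertion"):
        raise ValueError(f"unknown region class {region_class!r}")
    mean = track.region_mean(sample, chrom, start, end)  # raises if no bins
    genome_mean = track.genome_mean()[track.sample_index(sample)]
    if region_class == "deletion":
        return "absent" if mean < ABSENCE_FRACTION * genome_mean else "present"
    return "present" if mean > PRESENCE_FRACTION * genome_mean else "absent"


def call_panel_pav(track: DepthTrack, regions: pd.DataFrame) -> pd.DataFrame:
    """States for every region x sample.

    ``regions`` needs columns chrom, start, end, region_class; the result
    adds one state column per sample.
    """
    out = regions.copy().reset_index(drop=True)
    for sample in track.sample_ids:
        out[sample] = [
            call_sample_pav(
                track, sample, r.chrom, int(r.start), int(r.end), r.region_class
            )
            for r in regions.itertuples(index=False)
        ]
    return out


def call_group_pav(
    calls: pd.DataFrame, sample_groups: pd.Series | dict
) -> pd.DataFrame:
    """Group-level PAV flags: > GROUP_MIN_SHARED samples share the state.

    ``calls`` is the region x sample state table from :func:`call_panel_pav`;
    ``sample_groups`` maps sample id -> group label.  Returns one row per
    region x group with the consistently-shared state (or ``none``).
    Groups smaller than 4 can never be flagged; a warning is logged.
    """
    groups = dict(sample_groups)
    missing = [s for s in calls.columns if s in groups and groups[s] is None]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    by_group: dict[str, list[str]] = {}
    for sample, g in groups.items():
        by_group.setdefault(str(g), []).append(sample)
    for g, members in by_group.items():
        if len(members) <= GROUP_MIN_SHARED:
            log.warning("group %s has %d samples; can never be flagged", g, len(members))
    rows = []
    meta = [c for c in ("chrom", "start", "end", "region_class") if c in calls.columns]
    for ri, region in calls.iterrows():
        # only the variant (non-reference) state constitutes "having the PAV":
        # absent at a deletion-type region, present at an insertion-type one
        rc = region.get("region_class", "deletion")
        variant_state = "absent" if rc == "deletion" else "present"
        for g, members in by_group.items():
            states = [region[s] for s in members if s in calls.columns]
            n_shared = sum(s == variant_state for s in states)
            flagged_state = variant_state if n_shared > GROUP_MIN_SHARED else "none"
            rows.append(
                {"region": ri, **{c: region[c] for c in meta}, "group": g, "state": flagged_state}
            )
    return pd.DataFrame(rows)


def call_gene_loss(track: DepthTrack, genome: GenomeModel) -> pd.DataFrame:
    """Per sample x gene loss calls from bin-approximated coverage.

    A bin counts as covered when its mean depth is >= 1; the covered
    fraction of the gene span is the length-weighted share of covered
    overlapping bins.  Fraction < 10% => lost.
    """
    rows = []
    bstart = track.bins["start"].to_numpy()
    bend = track.bins["end"].to_numpy()
    bchrom = track.bins["chrom"].to_numpy()
    for gene in genome.genes:
        s, e = gene.span
        mask = (bchrom == gene.chrom) & (bstart < e) & (bend > s)
        if not mask.any():
            raise ValueError(f"gene {gene.gene_id} outside track coverage")
        ov = np.minimum(bend[mask], e) - np.maximum(bstart[mask], s)
        for j, sample in enumerate(track.sample_ids):
            covered = (track.depth[mask, j] >= 1.0) @ ov / ov.sum()
            rows.append(
                {
                    "gene": gene.gene_id,
                    "chrom": gene.chrom,
                    "start": s,
                    "end": e,
                    "sample": sample,
                    "covered_fraction": float(covered),
                    "lost": bool(covered < GENE_LOSS_COVERAGE),
                }
            )
    return pd.DataFrame(rows)


def absence_spectrum(gene_loss: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample absence spectrum: genes lost in exactly 1, 2, 3, >3 varieties."""
    lost_counts = gene_loss[gene_loss["lost"]].groupby("gene").size()
    return pd.DataFrame(
        {
            "n_varieties": ["1", "2", "3", ">3"],
            "n_genes": [
                int((lost_counts == 1).sum()),
                int((lost_counts == 2).sum()),
                int((lost_counts == 3).sum()),
                int((lost_counts > 3).sum()),
            ],
        }
    )
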