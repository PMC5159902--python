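"""Summary tables and the end-to-end pipeline runner.

The summary table mirrors the genome-wide variation bookkeeping of a
re-sequenced variety panel: per cohort (all varieties, each market type,
each release period), SNP and indel counts split by genic context with
their totals, plus CNV and PAV call counts.  The module also ships, as a
small worked-example dataset, the published category counts from the
129-variety chickpea panel, which the additivity checks recompute totals
from.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import io as io_mod
from . import ld as ld_mod
from . import pav as pav_mod
from . import popgen, structure, variants
from .core import PanelGenotypes
from .simulate import PanelConfig, demo_config, simulate_genome, simulate_panel

__all__ = [
    "reference_panel_counts",
    "reference_indel_breakdown",
    "add_totals",
    "build_summary",
    "PipelineConfig",
    "run_pipeline",
]

_CATEGORY_COLS = [
    "snp_exon",
    "snp_intron",
    "snp_intergenic",
    "indel_exon",
    "indel_intron",
    "indel_intergenic",
]


def reference_panel_counts() -> pd.DataFrame:
    """Published per-category variation counts of the 129-variety panel.

    One row per cohort; SNP and indel counts split by genic context, plus
    CNV and PAV counts.  Totals are deliberately not included — they are
    recomputed by :func:`add_totals` (the additivity identity).
    """
    rows = [
        ("all_129", 129, 46387, 115360, 1217043, 1229, 17222, 132989, 3822, 24603),
        ("desi", 88, 44859, 110908, 1167349, 1154, 16399, 126493, 2954, 23160),
        ("kabuli", 41, 38964, 94971, 1016430, 808, 11482, 90746, 3273, 21706),
        ("year_wise_124", 124, 46309, 115007, 1212774, 1211, 17107, 131928, 3811, 24249),
        ("RP1", 38, 39789, 97459, 1035388, 984, 14476, 108089, 2315, 20734),
        ("RP2", 40, 40380, 99195, 1055415, 810, 11412, 91292, 2318, 21150),
        ("RP3", 46, 42210, 104952, 1095817, 861, 12386, 99123, 3511, 22045),
    ]
    return pd.DataFrame(
        rows,
        columns=["cohort", "n_genotypes"] + _CATEGORY_COLS + ["cnv", "pav"],
    )


def reference_indel_breakdown() -> dict[str, int]:
    """Published insertion/deletion split of the 151,440 indels."""
    return {"insertions": 77446, "deletions": 73994}


def add_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Append snp_total and indel_total columns (sum of context categories)."""
    out = counts.copy()
    out["snp_total"] = out[["snp_exon", "snp_intron", "snp_intergenic"]].sum(axis=1)
    out["indel_total"] = out[["indel_exon", "indel_intron", "indel_intergenic"]].sum(
        axis=1
    )
    return out


def build_summary(
    panel: PanelGenotypes,
    annotations: pd.DataFrame,
    cnv_calls: pd.DataFrame,
    pav_calls: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cohort variation counts with enforced additivity.

    A variant belongs to a cohort when at least one non-missing call among
    the cohort's samples carries the alt allele.  CNV counts are calls in
    cohort samples; PAV counts are sample-level states departing from the
    reference (absent at a deletion-type region, present at an
    insertion-type region).  Raises if the sample sheet does not match the
    panel.
    """
    if list(sample_sheet["sample"]) != panel.sample_ids:
        raise ValueError("sample sheet does not match the panel")
    if len(annotations) != panel.n_sites:
        raise ValueError("annotation table does not match the panel")

    cohorts: list[tuple[str, np.ndarray]] = [("all", np.arange(panel.n_samples))]
    for col in ("market_type", "release_period"):
        for level, idx in panel.group_indices(col).items():
            cohorts.append((level, idx))

    is_snp = (panel.sites["vclass"] == "SNP").to_numpy()
    ctx = annotations["context"].to_numpy()
    sample_states = _pav_sample_states(pav_calls, panel.sample_ids)

    rows = []
    for name, idx in cohorts:
        members = set(np.asarray(panel.sample_ids)[idx])
        sub = panel.geno[:, idx]
        carried = (sub > 0).any(axis=1)
        row = {"cohort": name, "n_genotypes": len(idx)}
        for label, vmask in (("snp", is_snp), ("indel", ~is_snp)):
            for c in ("exon", "intron", "intergenic"):
                cmask = ctx == {"exon": "exonic", "intron": "intronic"}.get(c, "intergenic")
                row[f"{label}_{c}"] = int((carried & vmask & cmask).sum())
            row[f"{label}_total"] = sum(
                row[f"{label}_{c}"] for c in ("exon", "intron", "intergenic")
            )
        row["cnv"] = int(cnv_calls["sample"].isin(members).sum()) if len(cnv_calls) else 0
        row["pav"] = int(
            sum(n for s, n in sample_states.items() if s in members)
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    for label in ("snp", "indel"):
        parts = out[[f"{label}_exon", f"{label}_intron", f"{label}_intergenic"]].sum(axis=1)
        if not (parts == out[f"{label}_total"]).all():
            raise AssertionError("additivity violated")  # pragma: no cover
    return out


def _pav_sample_states(pav_calls: pd.DataFrame, sample_ids: list[str]) -> dict[str, int]:
    """Per sample, number of regions whose state departs from the reference."""
    counts = {s: 0 for s in sample_ids}
    if pav_calls is None or pav_calls.empty:
        return counts
    for row in pav_calls.itertuples(index=False):
        rc = getattr(row, "region_class", "deletion")
        variant_state = "absent" if rc == "deletion" else "present"
        for s in sample_ids:
            if getattr(row, s, None) == variant_state:
                counts[s] += 1
    return counts


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Panel generation plus analysis knobs for the end-to-end run."""

    panel: PanelConfig = field(default_factory=demo_config)
    window_size: int = 10_000
    cnv_alpha: float = 0.01
    cnv_passes: int = 2
    top_fraction: float = 0.02
    scan_min_span: int = 30_000
    scan_alpha: float = 0.05
    admixture_k: int = 3
    admixture_restarts: int = 2
    admixture_max_iter: int = 300
    ld_max_dist: int = 20_000
    ld_thin: int = 5
    block_max_span: int = 2_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        panel_kw = raw.pop("panel", {})
        for key in ("sweeps", "balancing", "cnv_events", "pav_events"):
            if key in panel_kw:
                panel_kw[key] = [tuple(x) for x in panel_kw[key]]
        if "chromosomes" in panel_kw:
            panel_kw["chromosomes"] = [tuple(x) for x in panel_kw["chromosomes"]]
        if "samples_per_group" in panel_kw and isinstance(
            panel_kw["samples_per_group"], dict
        ):
            panel_kw["samples_per_group"] = {
                tuple(k.split("/")): v for k, v in panel_kw["samples_per_group"].items()
            }
        if "pav_events" in panel_kw:
            panel_kw["pav_events"] = [
                (tuple(ev[0]), *ev[1:]) for ev in panel_kw["pav_events"]
            ]
        return cls(panel=PanelConfig(**panel_kw), **raw)


STAGES = [
    "simulate",
    "filter",
    "annotate",
    "cnv",
    "pav",
    "stats",
    "scan",
    "structure",
    "ld",
    "report",
]

_STAGE_OUTPUTS = {
    "simulate": ["genome.gff3", "genome.fa", "samples.tsv", "panel.vcf", "truth.json"],
    "filter": ["filtered.vcf", "filter_ledger.tsv"],
    "annotate": ["annotations.tsv"],
    "cnv": ["cnv_calls.tsv"],
    "pav": ["pav_calls.tsv", "gene_loss.tsv", "pav_group_flags.tsv"],
    "stats": ["window_stats.tsv"],
    "scan": ["selection_regions.tsv"],
    "structure": ["tree.nwk", "pca.tsv", "admixture_q.tsv", "distances.tsv"],
    "ld": ["ld_pairs.tsv", "ld_decay.tsv", "haplotype_blocks.tsv"],
    "report": ["summary.tsv", "manifest.json"],
}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run simulate -> filter -> annotate -> cnv -> pav -> stats -> scan ->
    structure -> ld -> report, writing every stage's outputs under outdir.

    All randomness derives from ``config.panel.seed``, so a rerun over an
    intact directory is a no-op and a rerun from the written manifest is
    byte-identical.  A stage executes only when one of its output files is
    missing or an upstream stage executed; its execution invalidates all
    downstream stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config

    def outputs(stage: str) -> list[Path]:
        paths = [outdir / name for name in _STAGE_OUTPUTS[stage]]
        if stage == "simulate":
            paths += [
                outdir / "depth" / f"{sid}.depth.bed"
                for sid in cfg.panel.sample_sheet()["sample"]
            ]
        return paths

    dirty = False
    to_run: dict[str, bool] = {}
    for stage in STAGES:
        if not all(p.exists() for p in outputs(stage)):
            dirty = True
        to_run[stage] = dirty

    # everything is recomputed in memory (cheap and deterministic); only the
    # stages marked dirty have their files (re)written.
    state: dict = {}
    for stage in STAGES:
        try:
            _STAGE_FUNCS[stage](cfg, state, outdir, write=to_run[stage])
        except Exception as exc:  # pragma: no cover - error surface
            manifest = {
                "failed_stage": stage,
                "error": str(exc),
                "completed": [s for s in STAGES if STAGES.index(s) < STAGES.index(stage)],
            }
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def _stage_simulate(cfg, state, outdir, write):
    genome = simulate_genome(cfg.panel)
    panel, track, truth = simulate_panel(genome, cfg.panel)
    state.update(genome=genome, panel=panel, track=track, truth=truth)
    if write:
        io_mod.write_gff3(genome, outdir / "genome.gff3")
        io_mod.write_fasta(genome, outdir / "genome.fa")
        io_mod.write_sample_sheet(panel.samples, outdir / "samples.tsv")
        io_mod.write_vcf(panel, outdir / "panel.vcf", chromosomes=genome.chromosomes)
        io_mod.write_depth_beds(track, outdir / "depth")
        io_mod.write_truth_json(truth, outdir / "truth.json")


def _stage_filter(cfg, state, outdir, write):
    policy = variants.FilterPolicy.for_panel(state["panel"])
    filtered, ledger = variants.filter_variants(state["panel"], policy, state["track"])
    state["filtered"] = filtered
    if write:
        io_mod.write_vcf(
            filtered, outdir / "filtered.vcf", chromosomes=state["genome"].chromosomes
        )
        ledger.to_csv(outdir / "filter_ledger.tsv", sep="\t", index=False)


def _stage_annotate(cfg, state, outdir, write):
    ann = variants.annotate(state["filtered"], state["genome"])
    state["annotations"] = ann
    if write:
        ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)


def _stage_cnv(cfg, state, outdir, write):
    calls = []
    for sid in state["track"].sample_ids:
        calls.extend(
            cnv_mod.call_sample_cnvs(state["track"], sid, cfg.cnv_alpha, cfg.cnv_passes)
        )
    df = cnv_mod.calls_to_frame(calls)
    state["cnv_calls"] = df
    if write:
        df.to_csv(outdir / "cnv_calls.tsv", sep="\t", index=False)


def _stage_pav(cfg, state, outdir, write):
    truth = state["truth"]
    regions = truth.pav_regions
    if regions.empty:
        calls = pd.DataFrame(columns=["chrom", "start", "end", "region_class"])
        flags = pd.DataFrame(columns=["region", "group", "state"])
    else:
        calls = pav_mod.call_panel_pav(state["track"], regions)
        groups = dict(
            zip(state["panel"].samples["sample"], state["panel"].samples["market_type"])
        )
        flags = pav_mod.call_group_pav(calls, groups)
    loss = pav_mod.call_gene_loss(state["track"], state["genome"])
    state["pav_calls"] = calls
    state["gene_loss"] = loss
    if write:
        calls.to_csv(outdir / "pav_calls.tsv", sep="\t", index=False)
        flags.to_csv(outdir / "pav_group_flags.tsv", sep="\t", index=False)
        loss.to_csv(outdir / "gene_loss.tsv", sep="\t", index=False)


def _stage_stats(cfg, state, outdir, write):
    panel = state["filtered"]
    windows = popgen.make_windows(state["genome"].chromosomes, cfg.window_size)
    stats = popgen.window_diversity(panel, windows)
    groups = panel.group_indices("market_type")
    (ga, gb) = (groups.get("desi"), groups.get("kabuli"))
    if ga is not None and gb is not None and len(ga) >= 2 and len(gb) >= 2:
        stats["fst"] = popgen.window_fst(panel, windows, ga, gb)["fst"]
        stats["delta_pi"] = popgen.delta_pi(panel, windows, ga, gb)["delta_pi"]
    state["window_stats"] = stats
    if write:
        stats.to_csv(outdir / "window_stats.tsv", sep="\t", index=False)


def _stage_scan(cfg, state, outdir, write):
    stats = state["window_stats"]
    parts = []
    if "fst" in stats.columns:
        parts.append(popgen.differentiation_scan(stats, stats, cfg.top_fraction))
    for direction in ("negative", "positive"):
        parts.append(
            popgen.tajima_region_scan(
                stats, direction, cfg.scan_min_span, alpha=cfg.scan_alpha,
                seed=cfg.panel.seed, panel=state["filtered"],
            )
        )
    regions = pd.concat(parts, ignore_index=True)
    state["selection_regions"] = regions
    if write:
        regions.to_csv(outdir / "selection_regions.tsv", sep="\t", index=False)


def _stage_structure(cfg, state, outdir, write):
    panel = state["filtered"]
    dist = structure.distance_matrix(panel)
    tree = structure.nj_tree(dist)
    pca = structure.pca_genotypes(panel)
    adm = structure.admixture_em(
        panel,
        K=cfg.admixture_k,
        max_iter=cfg.admixture_max_iter,
        restarts=cfg.admixture_restarts,
        seed=cfg.panel.seed,
    )
    state.update(tree=tree, pca=pca, admixture=adm, distances=dist)
    if write:
        tree.write(str(outdir / "tree.nwk"))
        pca["tracy_widom"].to_csv(outdir / "pca.tsv", sep="\t", index=False)
        pd.DataFrame(
            adm.Q, index=panel.sample_ids,
            columns=[f"K{k+1}" for k in range(adm.Q.shape[1])],
        ).to_csv(outdir / "admixture_q.tsv", sep="\t")
        dist.to_csv(outdir / "distances.tsv", sep="\t")


def _stage_ld(cfg, state, outdir, write):
    panel = state["filtered"]
    thin = panel.subset_sites(np.arange(panel.n_sites) % cfg.ld_thin == 0)
    pairs = ld_mod.pairwise_ld(thin, cfg.ld_max_dist)
    decay = ld_mod.ld_decay(pairs, bin_width=max(cfg.ld_max_dist // 10, 1))
    blocks = ld_mod.haplotype_blocks(thin, cfg.block_max_span)
    state.update(ld_pairs=pairs, ld_decay=decay, blocks=blocks)
    if write:
        pairs.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
        decay.to_csv(outdir / "ld_decay.tsv", sep="\t", index=False)
        blocks.to_csv(outdir / "haplotype_blocks.tsv", sep="\t", index=False)


def _stage_report(cfg, state, outdir, write):
    summary = build_summary(
        state["filtered"],
        state["annotations"],
        state["cnv_calls"],
        state["pav_calls"],
        state["panel"].samples,
    )
    state["summary"] = summary
    if write:
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        manifest = {
            "stages": STAGES,
            "seed": cfg.panel.seed,
            "config": {
                "panel": {
                    k: v
                    for k, v in dataclasses.asdict(cfg.panel).items()
                    if k != "samples_per_group" or isinstance(v, int)
                },
                "analysis": {
                    f.name: getattr(cfg, f.name)
                    for f in dataclasses.fields(cfg)
                    if f.name != "panel"
                },
            },
            "outputs": {s: _STAGE_OUTPUTS[s] for s in STAGES},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "annotate": _stage_annotate,
    "cnv": _stage_cnv,
    "pav": _stage_pav,
    "stats": _stage_stats,
    "scan": _stage_scan,
    "structure": _stage_structure,
    "ld": _stage_ld,
    "report": _stage_report,
}
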