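"""Readers and writers for the standard interchange formats.

Internal coordinates are 0-based half-open; VCF and GFF3 are written
1-based at this boundary.  VCF goes through pysam; GFF3, BED depth tracks,
sample sheets and the truth ledger are small text files written directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import DepthTrack, Gene, GenomeModel, PanelGenotypes

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "write_fasta",
    "write_depth_beds",
    "read_depth_beds",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_truth_json",
]


def write_vcf(
    panel: PanelGenotypes,
    path: str | Path,
    chromosomes: list[tuple[str, int]] | None = None,
    annotations: pd.DataFrame | None = None,
) -> None:
    """Write the panel as VCF 4.2 with GT:DP per sample.

    If an annotation table is given, genic context and coding effect are
    emitted as INFO keys CTX and EFF.
    """
    header = pysam.VariantHeader()
    if chromosomes is None:
        seen = {}
        for chrom, pos, ref in zip(
            panel.sites["chrom"], panel.sites["pos"], panel.sites["ref"]
        ):
            seen[chrom] = max(seen.get(chrom, 0), int(pos) + len(ref) + 1)
        chromosomes = sorted(seen.items())
    for chrom, length in chromosomes:
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.info.add("CTX", 1, "String", "Genic context")
    header.info.add("EFF", 1, "String", "Coding effect")
    for sid in panel.sample_ids:
        header.add_sample(sid)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in enumerate(panel.sites.itertuples(index=False)):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            if annotations is not None:
                rec.info["CTX"] = str(annotations["context"].iloc[i])
                rec.info["EFF"] = str(annotations["effect"].iloc[i])
            for j, sid in enumerate(panel.sample_ids):
                rec.samples[sid]["GT"] = gt_map[int(panel.geno[i, j])]
                rec.samples[sid]["DP"] = int(panel.depth[i, j])
            vcf.write(rec)


def read_vcf(path: str | Path, sample_sheet: pd.DataFrame | None = None) -> PanelGenotypes:
    """Read a GT:DP VCF back into a panel.

    Multi-allelic records are split into biallelic rows.  If no sample
    sheet is given a minimal one (ids only) is synthesized.
    """
    rows, genos, depths = [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or (), start=1):
                g_row, d_row = [], []
                for sid in sample_ids:
                    gt = rec.samples[sid]["GT"]
                    if gt is None or any(a is None for a in gt):
                        g_row.append(-1)
                    else:
                        g_row.append(sum(1 for a in gt if a == ai))
                    dp = rec.samples[sid].get("DP")
                    d_row.append(int(dp) if dp is not None else 0)
                if len(rec.ref) == len(alt) == 1:
                    vclass = "SNP"
                elif len(alt) > len(rec.ref):
                    vclass = "insertion"
                else:
                    vclass = "deletion"
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.start,
                        "ref": rec.ref,
                        "alt": alt,
                        "vclass": vclass,
                    }
                )
                genos.append(g_row)
                depths.append(d_row)
    if sample_sheet is None:
        sample_sheet = pd.DataFrame(
            {
                "sample": sample_ids,
                "market_type": pd.NA,
                "release_period": pd.NA,
                "country": pd.NA,
            }
        )
    return PanelGenotypes(
        sites=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass"]),
        geno=np.asarray(genos, dtype=np.int8),
        depth=np.asarray(depths, dtype=np.int32),
        samples=sample_sheet,
    )


def write_gff3(genome: GenomeModel, path: str | Path) -> None:
    """Write gene models as GFF3 (1-based, inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in genome.genes:
            s, e = gene.span
            fh.write(
                f"{gene.chrom}\tchickdiv\tgene\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            fh.write(
                f"{gene.chrom}\tchickdiv\tmRNA\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}.t1;Parent={gene.gene_id}\n"
            )
            cds = gene.cds if gene.strand == "+" else gene.cds[::-1]
            phase = 0
            for cs, ce in cds:
                fh.write(
                    f"{gene.chrom}\tchickdiv\tCDS\t{cs + 1}\t{ce}\t.\t{gene.strand}\t"
                    f"{phase}\tID={gene.gene_id}.cds;Parent={gene.gene_id}.t1\n"
                )
                phase = (3 - ((ce - cs) - phase) % 3) % 3


def write_fasta(genome: GenomeModel, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, _ in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_depth_beds(track: DepthTrack, outdir: str | Path) -> list[Path]:
    """One 4-column BED per sample: chrom, start, end, mean depth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sid in enumerate(track.sample_ids):
        p = outdir / f"{sid}.depth.bed"
        df = track.bins.copy()
        df["depth"] = track.depth[:, j]
        df.to_csv(p, sep="\t", header=False, index=False)
        paths.append(p)
    return paths


def read_depth_beds(paths: list[str | Path]) -> DepthTrack:
    """Assemble a DepthTrack from per-sample 4-column BED files."""
    depth_cols, bins, ids = [], None, []
    for p in paths:
        p = Path(p)
        df = pd.read_csv(p, sep="\t", names=["chrom", "start", "end", "depth"])
        if bins is None:
            bins = df[["chrom", "start", "end"]].copy()
        elif not bins.equals(df[["chrom", "start", "end"]]):
            raise ValueError(f"bin layout of {p} differs from the first sample")
        depth_cols.append(df["depth"].to_numpy(float))
        ids.append(p.name.replace(".depth.bed", ""))
    if bins is None:
        raise ValueError("no depth files given")
    return DepthTrack(bins=bins, depth=np.column_stack(depth_cols), sample_ids=ids)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize the planted-truth ledger as JSON."""
    payload = {
        "site_freqs": truth.site_freqs.to_dict(orient="list"),
        "sweeps": truth.sweeps.to_dict(orient="records"),
        "balancing": truth.balancing.to_dict(orient="records"),
        "cnv_events": truth.cnv_events.to_dict(orient="records"),
        "pav_regions": truth.pav_regions.to_dict(orient="records"),
        "pav_states": truth.pav_states.to_dict(orient="records"),
        "Q0": truth.Q0.tolist(),
        "F0": truth.F0.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
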