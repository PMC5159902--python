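"""Filtering cascade and annotation: brute-force oracles and boundary cases."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from chickdiv.core import DepthTrack, Gene, GenomeModel, PanelGenotypes, make_sample_sheet
from chickdiv.variants import (
    FilterPolicy,
    annotate,
    classify_coding_effect,
    classify_genic_context,
    dnds_summary,
    filter_variants,
    ng86_sites,
    partition_by_groups,
)


def _toy_panel(geno, depth=None, n_samples=None):
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n = geno.shape
    if depth is None:
        depth = np.full_like(geno, 10, dtype=np.int32)
    samples = make_sample_sheet(
        {("desi", "RP1"): n // 2, ("kabuli", "RP2"): n - n // 2}
    )
    sites = pd.DataFrame(
        {
            "chrom": "c1",
            "pos": np.arange(n_sites) * 100,
            "ref": "A",
            "alt": "G",
            "vclass": "SNP",
        }
    )
    return PanelGenotypes(sites=sites, geno=geno, depth=np.asarray(depth, np.int32), samples=samples)


def _flat_track(n_samples, depth=10.0, length=100_000, ids=None):
    starts = np.arange(0, length, 1000)
    bins = pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 1000})
    ids = ids or [f"v{i:03d}" for i in range(n_samples)]
    return DepthTrack(bins=bins, depth=np.full((len(bins), n_samples), depth), sample_ids=ids)


class TestFilter:
    def test_high_missing_site_removed_with_reason(self):
        geno = np.ones((1, 20), dtype=np.int8)
        geno[0, :11] = -1  # missing ratio 0.55 > 0.5
        panel = _toy_panel(geno)
        policy = FilterPolicy.for_panel(panel)
        kept, ledger = filter_variants(panel, policy, _flat_track(20))
        assert kept.n_sites == 0
        assert ledger["reason"].iloc[0] == "missing"

    def test_half_missing_site_kept(self):
        geno = np.ones((1, 20), dtype=np.int8)
        geno[0, :10] = -1  # exactly 0.5: retained
        geno[0, 10] = 0  # keep it polymorphic
        panel = _toy_panel(geno)
        kept, ledger = filter_variants(panel, FilterPolicy.for_panel(panel), _flat_track(20))
        assert kept.n_sites == 1

    def test_fixed_site_removed(self):
        panel = _toy_panel(np.full((1, 20), 2, dtype=np.int8))
        kept, ledger = filter_variants(panel, FilterPolicy.for_panel(panel), _flat_track(20))
        assert kept.n_sites == 0
        assert ledger["reason"].iloc[0] == "fixed"

    def test_brute_force_recheck_on_100_sites(self):
        """7 planted single-rule violations among 100 sites -> 93 retained."""
        rng = np.random.default_rng(0)
        n = 20
        geno = rng.integers(0, 2, size=(100, n)).astype(np.int8) * 2
        geno[:, 0] = 1  # guarantee polymorphism everywhere
        depth = np.full((100, n), 10, dtype=np.int32)
        # violations, one rule each
        for i in (3, 17, 42):  # missing
            geno[i, : int(n * 0.55)] = -1
        geno[55] = 2  # fixed
        geno[68] = 0  # fixed (freq 0)
        depth[71] = 300  # pooled depth too high and CN too high
        depth[88] = 2  # pooled depth too low
        panel = _toy_panel(geno, depth)
        policy = FilterPolicy.for_panel(panel)
        track = _flat_track(n)
        kept, ledger = filter_variants(panel, policy, track)
        assert kept.n_sites == 93
        # independent re-application of every rule, site by site
        gm = track.genome_mean()
        for i in range(100):
            g = geno[i]
            called = g >= 0
            af = g[called].sum() / (2 * called.sum())
            ok = (
                policy.depth_min <= depth[i].sum() <= policy.depth_max
                and (depth[i] / gm).mean() <= policy.cn_ceiling
                and (~called).mean() <= policy.max_missing
                and 0.0 < af < 1.0
            )
            assert (ledger["reason"].iloc[i] == "pass") == ok

    def test_filter_is_idempotent(self, demo):
        panel, track = demo["panel"], demo["track"]
        policy = FilterPolicy.for_panel(panel)
        once, _ = filter_variants(panel, policy, track)
        twice, ledger = filter_variants(once, policy, track)
        assert twice.n_sites == once.n_sites
        assert (ledger["reason"] == "pass").all()

    def test_errors(self):
        with pytest.raises(ValueError, match="inverted"):
            FilterPolicy(depth_min=100, depth_max=50)
        panel = _toy_panel(np.ones((1, 4), dtype=np.int8))
        with pytest.raises(ValueError, match="empty"):
            filter_variants(panel.subset_sites(np.zeros(1, bool)), FilterPolicy(), _flat_track(4))

    def test_literal_bounds_kept_for_129_samples(self):
        geno = np.ones((2, 129), dtype=np.int8)
        samples = make_sample_sheet({("desi", "RP1"): 129})
        sites = pd.DataFrame(
            {"chrom": "c1", "pos": [0, 100], "ref": "A", "alt": "G", "vclass": "SNP"}
        )
        panel = PanelGenotypes(
            sites=sites, geno=geno, depth=np.full((2, 129), 8, np.int32), samples=samples
        )
        policy = FilterPolicy.for_panel(panel)
        assert (policy.depth_min, policy.depth_max) == (78.0, 2500.0)


class TestContext:
    def test_definitions(self, gene_genome):
        gene = gene_genome.genes[0]
        cds_pos = gene.cds[0][0]
        assert classify_genic_context(gene_genome, gene.chrom, cds_pos)[0] == "exonic"
        if len(gene.cds) > 1:
            intron_pos = gene.cds[0][1]  # first base after the first CDS chunk
            assert classify_genic_context(gene_genome, gene.chrom, intron_pos)[0] == "intronic"
        assert classify_genic_context(gene_genome, gene.chrom, 0)[0] == "intergenic"

    def test_outside_chromosome_raises(self, gene_genome):
        with pytest.raises(ValueError):
            classify_genic_context(gene_genome, "Ca1", 10**9)

    def test_random_positions_vs_naive_scan(self, gene_genome):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 100_000, size=1000)
        for p in pos:
            got, _ = classify_genic_context(gene_genome, "Ca1", int(p))
            expect = "intergenic"
            for gene in gene_genome.genes:
                s, e = gene.span
                if s <= p < e:
                    expect = "exonic" if any(cs <= p < ce for cs, ce in gene.cds) else "intronic"
            assert got == expect


def _one_gene_genome(coding: str, strand: str = "+") -> GenomeModel:
    """Genome with a single single-exon gene whose CDS is `coding`."""
    pad = "A" * 100
    if strand == "+":
        seq = pad + coding + pad
    else:
        seq = pad + str(Seq(coding).reverse_complement()) + pad
    seq = seq + "T" * (10_000 - len(seq))
    gene = Gene("g1", "c1", strand, ((100, 100 + len(coding)),))
    return GenomeModel(chromosomes=[("c1", len(seq))], sequences={"c1": seq}, genes=[gene])


class TestEffect:
    def test_silent_and_nonsense_examples(self):
        g = _one_gene_genome("GAAGGG")
        # GAA -> GAG at codon position 3: Glu -> Glu, silent
        assert classify_coding_effect(g, "c1", 102, "A", "G") == "silent"
        # GAA -> TAA at codon position 1: Glu -> stop
        assert classify_coding_effect(g, "c1", 100, "G", "T") == "nonsense"

    def test_indel_returns_not_applicable(self):
        g = _one_gene_genome("GAAGGG")
        assert classify_coding_effect(g, "c1", 100, "GA", "G") == "not-applicable"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_mutations_of_trp_codon_match_enumeration(self, strand):
        """All 9 single-base changes of TGG vs exhaustive codon-table check."""
        g = _one_gene_genome("TGGGCA", strand)
        codon = "TGG"
        comp = str.maketrans("ACGT", "TGCA")
        for within in range(3):
            for b in "ACGT":
                if b == codon[within]:
                    continue
                mut = codon[:within] + b + codon[within + 1 :]
                aa_ref, aa_alt = str(Seq(codon).translate()), str(Seq(mut).translate())
                expect = (
                    "silent"
                    if aa_alt == aa_ref
                    else "nonsense" if aa_alt == "*" else "missense"
                )
                if strand == "+":
                    pos, ref, alt = 100 + within, codon[within], b
                else:
                    # genome holds the reverse complement; the variant is
                    # reported on the forward strand
                    pos = 100 + (5 - within)
                    ref, alt = codon[within].translate(comp), b.translate(comp)
                assert classify_coding_effect(g, "c1", pos, ref, alt) == expect

    def test_effect_classes_partition_exonic_snps(self, demo):
        ann = annotate(demo["panel"], demo["genome"])
        exonic_snp = (ann["context"] == "exonic") & (
            demo["panel"].sites["vclass"] == "SNP"
        )
        assert set(ann.loc[exonic_snp, "effect"]) <= {"silent", "missense", "nonsense"}
        assert (ann.loc[~exonic_snp, "effect"] == "not-applicable").all()
        assert set(ann["context"]) <= {"exonic", "intronic", "intergenic"}


class TestDnds:
    def test_single_gene_against_per_codon_oracle(self):
        g = _one_gene_genome("ATGGCTAAA")  # Met-Ala-Lys
        # per-codon NG86 site counting, independent enumeration
        syn = nonsyn = 0.0
        for codon in ("ATG", "GCT", "AAA"):
            aa = str(Seq(codon).translate())
            for i in range(3):
                fs = sum(
                    str(Seq(codon[:i] + b + codon[i + 1 :]).translate()) == aa
                    for b in "ACGT"
                    if b != codon[i]
                ) / 3.0
                syn += fs
                nonsyn += 1 - fs
        got_syn, got_nonsyn = ng86_sites(g)
        assert got_syn == pytest.approx(syn, abs=1e-9)
        assert got_nonsyn == pytest.approx(nonsyn, abs=1e-9)
        # 1 nonsyn + 1 syn SNP -> ratio matches the oracle arithmetic
        sites = pd.DataFrame(
            {
                "chrom": "c1",
                "pos": [104, 105],  # GCT codon: pos2 (nonsyn), pos3 (syn)
                "ref": ["C", "T"],
                "alt": ["T", "C"],
                "vclass": "SNP",
            }
        )
        geno = np.array([[1, 1, 0, 0], [1, 1, 0, 0]], dtype=np.int8)
        samples = make_sample_sheet({("desi", "RP1"): 4})
        panel = PanelGenotypes(
            sites=sites, geno=geno, depth=np.full((2, 4), 10, np.int32), samples=samples
        )
        ann = annotate(panel, g)
        assert list(ann["effect"]) == ["missense", "silent"]
        table = dnds_summary(panel, g, ann, by="release_period")
        expect = (1 / nonsyn) / (1 / syn)
        assert table["dnds"].iloc[0] == pytest.approx(expect, abs=1e-9)

    def test_silent_only_group_gives_zero(self):
        g = _one_gene_genome("ATGGCTAAA")
        sites = pd.DataFrame(
            {"chrom": "c1", "pos": [105], "ref": ["T"], "alt": ["C"], "vclass": "SNP"}
        )
        geno = np.array([[1, 1, 1, 1]], dtype=np.int8)
        samples = make_sample_sheet({("desi", "RP1"): 4})
        panel = PanelGenotypes(
            sites=sites, geno=geno, depth=np.full((1, 4), 10, np.int32), samples=samples
        )
        table = dnds_summary(panel, g, annotate(panel, g))
        assert table["dnds"].iloc[0] == 0.0

    def test_identical_groups_identical_ratios(self, demo):
        ann = annotate(demo["panel"], demo["genome"])
        table = dnds_summary(demo["panel"], demo["genome"], ann, by="market_type")
        # two cohorts drawn from the same process: both ratios finite & positive
        assert (table["dnds"] >= 0).all()
        # exact symmetry: duplicate group labels give identical rows
        panel = demo["panel"]
        dup = panel.samples.copy()
        dup["market_type"] = "desi"
        from chickdiv.core import PanelGenotypes as PG

        p2 = PG(sites=panel.sites, geno=panel.geno, depth=panel.depth, samples=dup)
        t2 = dnds_summary(p2, demo["genome"], ann, by="market_type")
        assert len(t2) == 1


class TestPartition:
    def test_single_group_site(self):
        geno = np.zeros((1, 6), dtype=np.int8)
        geno[0, 5] = 2  # alt only in the kabuli/RP2 half
        panel = _toy_panel(geno)
        cells = partition_by_groups(panel, "release_period")
        assert cells == {("RP2",): 1}

    def test_shared_site_in_full_cell(self):
        geno = np.ones((1, 6), dtype=np.int8)
        panel = _toy_panel(geno)
        cells = partition_by_groups(panel, "release_period")
        assert cells == {("RP1", "RP2"): 1}

    def test_brute_force_30_sites(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
        geno[:, 0] = np.maximum(geno[:, 0], 1)  # every site carried somewhere
        panel = _toy_panel(geno)
        cells = partition_by_groups(panel, "market_type")
        assert sum(cells.values()) == 30
        # independent per-site set construction
        expect = {}
        groups = {
            "desi": list(range(6)),
            "kabuli": list(range(6, 12)),
        }
        for i in range(30):
            key = tuple(
                sorted(g for g, idx in groups.items() if (geno[i, idx] > 0).any())
            )
            expect[key] = expect.get(key, 0) + 1
        assert cells == expect

    def test_unfiltered_panel_rejected(self):
        panel = _toy_panel(np.zeros((1, 6), dtype=np.int8))
        with pytest.raises(ValueError, match="filter"):
            partition_by_groups(panel, "market_type")
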