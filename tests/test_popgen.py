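"""Diversity statistics vs independent oracles; selection-scan recovery."""

import numpy as np
import pandas as pd
import pytest

import oracles
from chickdiv.core import PanelGenotypes, make_sample_sheet
from chickdiv.popgen import (
    delta_pi,
    differentiation_scan,
    make_windows,
    tajima_constants,
    tajima_region_scan,
    window_diversity,
    window_fst,
)
from chickdiv.simulate import PanelConfig, neutral_config, simulate_genome, simulate_panel


def _panel_from_geno(geno, positions=None, chrom="c1", n_split=None):
    geno = np.asarray(geno, dtype=np.int8)
    m, n = geno.shape
    if positions is None:
        positions = np.arange(m) * 10
    half = n // 2 if n_split is None else n_split
    samples = make_sample_sheet({("desi", "RP1"): half, ("kabuli", "RP2"): n - half})
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G", "vclass": "SNP"}
    )
    return PanelGenotypes(
        sites=sites, geno=geno, depth=np.full((m, n), 10, np.int32), samples=samples
    )


class TestWindowDiversity:
    def test_monomorphic_window(self):
        panel = _panel_from_geno(np.full((5, 6), 2))
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        st = window_diversity(panel, w)
        assert st["pi"].iloc[0] == 0
        assert st["theta_w"].iloc[0] == 0
        assert np.isnan(st["tajima_d"].iloc[0])
        assert np.isnan(st["fu_li_dstar"].iloc[0])

    def test_watterson_closed_form_n4(self):
        """n=4 haplotypes, S=3, L=100 -> theta_w = 3 / (1+1/2+1/3) / 100."""
        geno = np.array([[1, 0], [0, 1], [2, 1]], dtype=np.int8)
        panel = _panel_from_geno(geno)
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        st = window_diversity(panel, w)
        assert st["S"].iloc[0] == 3
        assert st["theta_w"].iloc[0] == pytest.approx(3 / (11 / 6) / 100, abs=1e-9)
        assert st["theta_w"].iloc[0] == pytest.approx(0.016364, abs=1e-6)

    def test_fifty_random_windows_match_formula_oracle(self):
        """pi, theta_w, D, D* equal the straight-from-formula oracle to 1e-9."""
        rng = np.random.default_rng(17)
        for trial in range(50):
            m = int(rng.integers(5, 40))
            geno = rng.integers(0, 3, size=(m, 10)).astype(np.int8)
            geno[rng.random(geno.shape) < 0.1] = -1
            panel = _panel_from_geno(geno)
            L = 1000.0
            w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [int(L)]})
            st = window_diversity(panel, w).iloc[0]
            hap = oracles.haploidize(geno)
            assert st["pi"] == pytest.approx(oracles.pi_pairwise(hap, L), abs=1e-9)
            S, eta1 = oracles.segregating_and_singletons(hap)
            assert st["S"] == S and st["eta1"] == eta1
            n_eff = int(st["n"])
            assert st["theta_w"] == pytest.approx(
                oracles.watterson_theta(S, n_eff, L), abs=1e-9
            )
            if S > 0:
                assert st["tajima_d"] == pytest.approx(
                    oracles.tajimas_d(S, st["pi"] * L, n_eff), abs=1e-9
                )
                assert st["fu_li_dstar"] == pytest.approx(
                    oracles.fu_li_dstar(S, eta1, n_eff), abs=1e-9
                )

    def test_invariance_to_order_and_allele_swap(self):
        rng = np.random.default_rng(23)
        geno = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        panel = _panel_from_geno(geno)
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [1000]})
        st = window_diversity(panel, w)
        perm = rng.permutation(8)
        st_perm = window_diversity(_panel_from_geno(geno[:, perm]), w)
        st_swap = window_diversity(_panel_from_geno(2 - geno), w)
        for col in ("pi", "theta_w", "S"):
            assert st[col].iloc[0] == pytest.approx(st_perm[col].iloc[0], abs=1e-12)
            assert st[col].iloc[0] == pytest.approx(st_swap[col].iloc[0], abs=1e-12)

    def test_too_few_samples_error(self):
        panel = _panel_from_geno(np.ones((3, 4), dtype=np.int8))
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            window_diversity(panel, w, group=np.array([0]))

    def test_neutral_pi_thetaw_agree(self):
        ratios = []
        for seed in range(3):
            cfg = neutral_config(theta=0.002, n_samples=20, length=500_000, seed=60 + seed)
            genome = simulate_genome(cfg)
            panel, _, _ = simulate_panel(genome, cfg)
            st = window_diversity(panel, make_windows(genome.chromosomes, 10_000))
            ratios.append(st["pi"].mean() / st["theta_w"].mean())
        assert 0.9 < np.mean(ratios) < 1.1


class TestFst:
    def test_identical_frequencies_near_zero(self):
        # large groups: Hudson's unbiased estimator is slightly negative on
        # finite identical samples (~ -1/(n-1) scale), shrinking with n
        geno = np.tile(np.tile(np.array([2, 0], dtype=np.int8), 60)[None, :], (20, 1))
        panel = _panel_from_geno(geno)
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [1000]})
        fst = window_fst(panel, w, np.arange(60), np.arange(60, 120))["fst"].iloc[0]
        assert abs(fst) < 0.02

    def test_fixed_difference_is_one(self):
        geno = np.zeros((10, 8), dtype=np.int8)
        geno[:, 4:] = 2
        panel = _panel_from_geno(geno)
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [1000]})
        fst = window_fst(panel, w, np.arange(4), np.arange(4, 8))["fst"].iloc[0]
        assert fst == pytest.approx(1.0, abs=1e-12)

    def test_toy_window_matches_hand_arithmetic(self):
        """5-site window vs the per-site ratio-of-sums oracle."""
        rng = np.random.default_rng(31)
        geno = rng.integers(0, 3, size=(5, 12)).astype(np.int8)
        panel = _panel_from_geno(geno)
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [1000]})
        got = window_fst(panel, w, np.arange(6), np.arange(6, 12))["fst"].iloc[0]
        hap = oracles.haploidize(geno)
        expect = oracles.hudson_fst(hap[:, :12], hap[:, 12:])
        assert got == pytest.approx(expect, abs=1e-9)

    def test_random_split_fst_near_zero(self):
        cfg = neutral_config(theta=0.002, n_samples=20, length=500_000, seed=77)
        genome = simulate_genome(cfg)
        panel, _, _ = simulate_panel(genome, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(20)
        w = pd.DataFrame({"chrom": ["Ca1"], "start": [0], "end": [500_000]})
        fst = window_fst(panel, w, perm[:10], perm[10:])["fst"].iloc[0]
        assert abs(fst) < 0.02


class TestScans:
    def test_forced_overlap_returns_the_window(self):
        w = make_windows([("c1", 50_000)], 10_000)
        w["fst"] = [0.1, 0.1, 0.9, 0.1, 0.1]
        d = w.copy()
        d["delta_pi"] = [0.0, 0.0, 0.01, 0.0, 0.0]
        regions = differentiation_scan(w, d, top_fraction=0.2)
        assert len(regions) == 1
        assert (regions["start"].iloc[0], regions["end"].iloc[0]) == (20_000, 30_000)

    def test_disjoint_rankings_empty(self):
        w = make_windows([("c1", 40_000)], 10_000)
        w["fst"] = [0.9, 0.1, 0.1, 0.1]
        d = w.copy()
        d["delta_pi"] = [0.0, 0.02, 0.0, 0.0]
        assert len(differentiation_scan(w, d, top_fraction=0.25)) == 0

    def test_bad_fraction(self):
        w = make_windows([("c1", 40_000)], 10_000)
        w["fst"] = 0.0
        d = w.copy()
        d["delta_pi"] = 0.0
        with pytest.raises(ValueError):
            differentiation_scan(w, d, top_fraction=0.0)

    def _sweep_panel(self, seed):
        cfg = neutral_config(theta=0.002, n_samples=20, length=1_000_000, seed=seed)
        cfg.sweeps = [("Ca1", 400_000, 600_000, 0.1)]
        genome = simulate_genome(cfg)
        panel, _, _ = simulate_panel(genome, cfg)
        return genome, panel

    def test_sweep_scan_covers_planted_interval(self):
        hits = 0
        for seed in range(3):
            genome, panel = self._sweep_panel(900 + seed)
            # 50 kb windows: the right scale for >=150 kb selection regions
            st = window_diversity(panel, make_windows(genome.chromosomes, 50_000))
            regions = tajima_region_scan(st, "negative", min_span=100_000, seed=seed, panel=panel)
            covered = sum(
                min(r.end, 600_000) - max(r.start, 400_000)
                for r in regions.itertuples(index=False)
                if r.end > 400_000 and r.start < 600_000
            )
            hits += covered >= 0.8 * 200_000
        assert hits >= 2

    def test_balancing_scan_finds_positive_region(self):
        cfg = neutral_config(theta=0.002, n_samples=20, length=1_000_000, seed=41)
        cfg.balancing = [("Ca1", 300_000, 500_000, 0.95)]
        genome = simulate_genome(cfg)
        panel, _, _ = simulate_panel(genome, cfg)
        st = window_diversity(panel, make_windows(genome.chromosomes, 50_000))
        regions = tajima_region_scan(st, "positive", min_span=100_000, seed=1, panel=panel)
        assert any(
            r.end > 300_000 and r.start < 500_000 for r in regions.itertuples(index=False)
        )

    def test_neutral_panel_scan_is_quiet(self):
        n_regions = 0
        n_windows = 0
        for seed in range(5):
            cfg = neutral_config(theta=0.002, n_samples=20, length=500_000, seed=1300 + seed)
            genome = simulate_genome(cfg)
            panel, _, _ = simulate_panel(genome, cfg)
            st = window_diversity(panel, make_windows(genome.chromosomes, 10_000))
            regions = tajima_region_scan(st, "negative", min_span=0, alpha=0.05, seed=seed, panel=panel)
            n_regions += len(regions)
            n_windows += len(st)
        assert n_regions <= 0.05 * n_windows

    def test_differentiation_scan_recovers_group_specific_sweep(self):
        hits = 0
        for seed in range(3):
            cfg = PanelConfig(
                chromosomes=[("Ca1", 500_000)],
                cds_fraction=0.0,
                samples_per_group=4,
                n_subpops=2,
                divergence=0.1,
                admixture_alpha=5.0,
                selfing=0.5,
                missing_rate=0.0,
                theta=0.004,
                seed=1500 + seed,
            )
            genome = simulate_genome(cfg)
            panel, _, _ = simulate_panel(genome, cfg)
            # plant the sweep in the desi group only: zero their minor dosages
            sweep = (panel.sites["pos"] >= 200_000) & (panel.sites["pos"] < 300_000)
            desi = panel.group_indices("market_type")["desi"]
            geno = panel.geno.copy()
            rows = np.flatnonzero(sweep.to_numpy())
            for i in rows:
                geno[i, desi] = 0
            panel = PanelGenotypes(
                sites=panel.sites, geno=geno, depth=panel.depth, samples=panel.samples
            )
            kabuli = panel.group_indices("market_type")["kabuli"]
            w = make_windows(genome.chromosomes, 10_000)
            fst = window_fst(panel, w, desi, kabuli)
            dpi = delta_pi(panel, w, desi, kabuli)
            regions = differentiation_scan(fst, dpi, top_fraction=0.2)
            covered = sum(
                min(r.end, 300_000) - max(r.start, 200_000)
                for r in regions.itertuples(index=False)
                if r.end > 200_000 and r.start < 300_000
            )
            hits += covered >= 0.8 * 100_000
        assert hits >= 2


def test_neutral_tajima_d_centered():
    ds = []
    for seed in range(5):
        cfg = neutral_config(theta=0.002, n_samples=20, length=500_000, seed=2000 + seed)
        genome = simulate_genome(cfg)
        panel, _, _ = simulate_panel(genome, cfg)
        st = window_diversity(panel, make_windows(genome.chromosomes, 10_000))
        ds.append(np.nanmean(st["tajima_d"]))
    assert abs(np.mean(ds)) < 0.3


def test_tajima_constants_textbook_values():
    k = tajima_constants(10)
    assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)), abs=1e-12)
    assert k["b1"] == pytest.approx(11 / 27, abs=1e-12)
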