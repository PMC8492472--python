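import itertools

import msprime
import numpy as np
import pytest

from allokit.popgen import (
    _harmonic,
    call_selective_sweeps,
    diversity_reduction_percent,
    ld_decay_curve,
    two_population_scan,
    weir_cockerham_fst,
    window_diversity_stats,
    zfst_transform,
)
from allokit.synthetic_data import simulate_two_population_genotypes
from conftest import haplotypes_to_genotype_matrix, treeseq_to_genotype_matrix


class TestDiversity:
    def test_monomorphic_window(self):
        hap = np.zeros((3, 12), dtype=np.int8)
        hap[0, 0] = 0  # no variation at all
        gm = haplotypes_to_genotype_matrix(hap, [10, 20, 30])
        w = window_diversity_stats(gm, gm.sample_ids, window_size=1000, step=1000,
                                   chromosome_lengths={"chr1": 1000})[0]
        assert w.pi == 0.0 and w.theta_w == 0.0
        assert w.tajima_d is None and w.fu_li_d_star is None

    def test_single_pair_forced_pi(self):
        # 2 diploid samples sharing haplotypes is below the sample floor; use
        # 4 samples where the pairwise arithmetic is still checkable by hand
        hap = np.zeros((3, 8), dtype=np.int8)
        hap[:, 0] = 1  # one haplotype carries all three derived alleles
        gm = haplotypes_to_genotype_matrix(hap, [100, 200, 300])
        w = window_diversity_stats(gm, gm.sample_ids, window_size=1000, step=1000,
                                   chromosome_lengths={"chr1": 1000})[0]
        # per site: 2*1*7/(8*7) = 0.25 -> 3 sites / 1000 bp
        assert w.pi == pytest.approx(3 * 0.25 / 1000)

    def test_brute_force_pairwise_oracle(self, rng):
        """π equals the average over all haplotype pairs; θw = S/(a_n L)."""
        assert _harmonic(6) == pytest.approx(137 / 60)
        n_hap = 12
        for _ in range(20):
            hap = (rng.random((15, n_hap)) < rng.uniform(0.1, 0.9, (15, 1))).astype(np.int8)
            gm = haplotypes_to_genotype_matrix(hap, list(range(0, 1500, 100)))
            w = window_diversity_stats(gm, gm.sample_ids, window_size=2000, step=2000,
                                       chromosome_lengths={"chr1": 2000})[0]
            diffs = [
                np.sum(hap[:, i] != hap[:, j])
                for i, j in itertools.combinations(range(n_hap), 2)
            ]
            assert w.pi * 2000 == pytest.approx(np.mean(diffs))
            s = int(np.sum((hap.sum(axis=1) > 0) & (hap.sum(axis=1) < n_hap)))
            assert w.theta_w * 2000 == pytest.approx(s / _harmonic(n_hap))

    def test_matches_tskit_on_coalescent_data(self):
        ts = msprime.sim_ancestry(
            samples=10, sequence_length=100_000, recombination_rate=1e-8,
            population_size=1e4, random_seed=5,
        )
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=5)
        gm = treeseq_to_genotype_matrix(ts)
        w = window_diversity_stats(gm, gm.sample_ids, window_size=100_000,
                                   step=100_000,
                                   chromosome_lengths={"chr1": 100_000})[0]
        assert w.pi == pytest.approx(float(ts.diversity()), rel=1e-6)
        assert w.tajima_d == pytest.approx(float(ts.Tajimas_D()), abs=1e-6)

    def test_fu_li_star_reasonable_under_neutrality(self):
        values_d, values_f = [], []
        for seed in range(40):
            ts = msprime.sim_ancestry(
                samples=20, sequence_length=50_000, recombination_rate=1e-8,
                population_size=1e4, random_seed=1000 + seed,
            )
            ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=2000 + seed)
            gm = treeseq_to_genotype_matrix(ts)
            w = window_diversity_stats(gm, gm.sample_ids, window_size=50_000,
                                       step=50_000,
                                       chromosome_lengths={"chr1": 50_000})[0]
            if w.fu_li_d_star is not None:
                values_d.append(w.fu_li_d_star)
                values_f.append(w.fu_li_f_star)
        assert abs(np.mean(values_d)) < 0.4
        assert abs(np.mean(values_f)) < 0.4


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------


def _wc84_reference(gcounts1, gcounts2):
    """Independent per-site WC84 estimate from genotype count triples
    (n_hom_ref, n_het, n_hom_alt) per population."""
    pops = [gcounts1, gcounts2]
    n = [sum(g) for g in pops]
    p = [(g[1] + 2 * g[2]) / (2 * nn) for g, nn in zip(pops, n)]
    h = [g[1] / nn for g, nn in zip(pops, n)]
    r = 2
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def _gm_from_counts(gcounts1, gcounts2):
    dosages = (
        [0] * gcounts1[0] + [1] * gcounts1[1] + [2] * gcounts1[2]
        + [0] * gcounts2[0] + [1] * gcounts2[1] + [2] * gcounts2[2]
    )
    hap = np.zeros((1, 2 * len(dosages)), dtype=np.int8)
    for i, d in enumerate(dosages):
        hap[0, 2 * i] = 1 if d >= 1 else 0
        hap[0, 2 * i + 1] = 1 if d == 2 else 0
    gm = haplotypes_to_genotype_matrix(hap, [500])
    n1 = sum(gcounts1)
    pop1 = gm.sample_ids[:n1]
    pop2 = gm.sample_ids[n1:]
    return gm, pop1, pop2


class TestFst:
    def test_identical_populations_near_zero(self, rng):
        hap = (rng.random((50, 80)) < 0.3).astype(np.int8)
        gm = haplotypes_to_genotype_matrix(hap, list(range(0, 5000, 100)))
        pop1, pop2 = gm.sample_ids[:20], gm.sample_ids[20:]
        w = weir_cockerham_fst(gm, pop1, pop2, window_size=5000, step=5000,
                               chromosome_lengths={"chr1": 5000})[0]
        assert w.fst < 0.05

    def test_fixed_difference_approaches_one(self):
        hap = np.zeros((20, 80), dtype=np.int8)
        hap[:, :40] = 1
        gm = haplotypes_to_genotype_matrix(hap, list(range(0, 2000, 100)))
        pop1, pop2 = gm.sample_ids[:20], gm.sample_ids[20:]
        w = weir_cockerham_fst(gm, pop1, pop2, window_size=2000, step=2000,
                               chromosome_lengths={"chr1": 2000})[0]
        assert w.fst > 0.95

    @pytest.mark.parametrize(
        "g1,g2",
        [
            ((4, 4, 2), (7, 2, 1)),   # alt 8/20 vs 4/20
            ((2, 4, 4), (8, 0, 2)),   # alt 12/20 vs 4/20
            ((5, 5, 0), (1, 3, 6)),
        ],
    )
    def test_hand_computed_components(self, g1, g2):
        gm, pop1, pop2 = _gm_from_counts(g1, g2)
        w = weir_cockerham_fst(gm, pop1, pop2, window_size=1000, step=1000,
                               chromosome_lengths={"chr1": 1000})[0]
        expected = _wc84_reference(g1, g2)
        assert w.fst == pytest.approx(max(expected, 0.0), abs=1e-12)

    def test_population_swap_symmetry(self, rng):
        hap = (rng.random((30, 80)) < 0.4).astype(np.int8)
        gm = haplotypes_to_genotype_matrix(hap, list(range(0, 3000, 100)))
        pop1, pop2 = gm.sample_ids[:20], gm.sample_ids[20:]
        w12 = weir_cockerham_fst(gm, pop1, pop2, window_size=3000, step=3000,
                                 chromosome_lengths={"chr1": 3000})[0]
        w21 = weir_cockerham_fst(gm, pop2, pop1, window_size=3000, step=3000,
                                 chromosome_lengths={"chr1": 3000})[0]
        assert w12.fst == pytest.approx(w21.fst, abs=1e-12)


class TestZFst:
    def test_three_values(self):
        assert zfst_transform([1, 2, 3]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        z = zfst_transform(rng.gamma(2.0, 0.05, size=500))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zfst_transform([0.5, 0.5, 0.5])


class TestSweepCalling:
    def _scan(self, **kwargs):
        defaults = dict(
            n_samples_per_pop=20, chrom_length=10_000_000, n_sweep_windows=5,
            pi_background=2e-3, pi_sweep=5e-4, seed=9,
        )
        defaults.update(kwargs)
        ds = simulate_two_population_genotypes(**defaults)
        gm = ds.genotype_matrix()
        windows = two_population_scan(
            gm, "pop1", "pop2", window_size=100_000, step=100_000,
            chromosome_lengths={"chr1": defaults["chrom_length"]},
        )
        return ds, windows

    def test_counting_bound(self, rng):
        import pandas as pd

        windows = pd.DataFrame(
            {
                "chromosome": "chr1",
                "start": np.arange(1000) * 100_000,
                "end": (np.arange(1000) + 1) * 100_000,
                "pi_ratio": rng.gamma(4, 0.25, 1000),
                "zfst": rng.normal(size=1000),
            }
        )
        res = call_selective_sweeps(windows, quantile=0.05)
        per_dir = {
            d: sum(1 for c in res.calls if c.direction == d)
            for d in ("selected_in_pop1", "selected_in_pop2")
        }
        assert all(v <= 50 for v in per_dir.values())

    def test_degenerate_input_flagged(self):
        import pandas as pd

        windows = pd.DataFrame(
            {
                "chromosome": "chr1", "start": np.arange(100) * 100_000,
                "end": (np.arange(100) + 1) * 100_000,
                "pi_ratio": 1.0, "zfst": 0.0,
            }
        )
        res = call_selective_sweeps(windows, quantile=0.05)
        assert res.degenerate and res.calls == []

    def test_too_few_windows_rejected(self):
        import pandas as pd

        windows = pd.DataFrame(
            {"chromosome": "chr1", "start": [0], "end": [1],
             "pi_ratio": [1.0], "zfst": [0.0]}
        )
        with pytest.raises(ValueError):
            call_selective_sweeps(windows, quantile=0.05)

    def test_directions_disjoint_and_subset(self):
        _, windows = self._scan()
        res = call_selective_sweeps(windows, quantile=0.05)
        keys = [(c.chromosome, c.start, c.direction) for c in res.calls]
        coords = [(c.chromosome, c.start) for c in res.calls]
        assert len(set(coords)) == len(coords)  # a window gets one direction
        starts = set(windows["start"])
        assert all(s in starts for _, s in coords)


def test_diversity_reduction_headline():
    assert diversity_reduction_percent(1.57e-3, 1.99e-3) == 21.1


class TestLDDecay:
    def test_duplicated_site_perfect_ld(self, rng):
        hap = (rng.random((2, 80)) < 0.4).astype(np.int8)
        hap[1] = hap[0]
        gm = haplotypes_to_genotype_matrix(hap, [100, 5100])
        curve = ld_decay_curve(gm, gm.sample_ids, max_distance=10_000, bin_size=1000)
        b = (5100 - 100 - 1) // 1000
        assert curve.mean_r2[b] == pytest.approx(1.0)

    def test_unlinked_sites_r2_near_1_over_n(self, rng):
        n = 100
        hap = (rng.random((200, 2 * n)) < 0.5).astype(np.int8)
        gm = haplotypes_to_genotype_matrix(hap, list(range(0, 20_000, 100)))
        curve = ld_decay_curve(gm, gm.sample_ids, max_distance=20_000, bin_size=20_000)
        assert np.nansum(curve.mean_r2 * curve.n_pairs) / curve.n_pairs.sum() == pytest.approx(
            1 / n, rel=0.25
        )

    def test_planted_half_decay_distance(self, rng):
        """Correlation decaying linearly with distance puts the half-maximum
        of r² at a predictable bin."""
        n_hap = 400
        base_positions = np.arange(0, 100_000, 10_000)
        rows, positions = [], []
        for start in range(0, 1_000_000, 100_000):
            anchor = (rng.random(n_hap) < 0.5).astype(np.int8)
            for k, off in enumerate(base_positions):
                if k == 0:
                    rows.append(anchor.copy())
                else:
                    keep = rng.random(n_hap) < max(1 - 0.15 * k, 0.0)
                    site = np.where(keep, anchor, (rng.random(n_hap) < 0.5)).astype(np.int8)
                    rows.append(site)
                positions.append(start + off)
        hap = np.asarray(rows)
        gm = haplotypes_to_genotype_matrix(hap, positions)
        curve = ld_decay_curve(gm, gm.sample_ids, max_distance=95_000, bin_size=10_000)
        # r(d) ~ 1 - 0.15k so r2 halves around k ~ 2 (r2: 1, .72, .49, .30...)
        assert curve.half_decay_distance == pytest.approx(25_000, abs=10_000)
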