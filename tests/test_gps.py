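"""Graded pools, Ridit statistic and window scanning."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binqtl.core import ConfigError, InputError
from binqtl.gps import (
    build_pools,
    pool_allele_counts,
    ridit_scan,
    ridit_test,
    window_scan,
)
from binqtl.simulate import (
    QTL,
    SimConfig,
    additive_effect_for_pve,
    simulate_f2_population,
    simulate_observations,
)


def _phenotypes(values, ids=None):
    ids = ids or [f"i{k}" for k in range(len(values))]
    return pd.DataFrame({"id": ids, "trait": "t", "value": values})


class TestBuildPools:
    def test_balanced_quarters(self, rng):
        pools = build_pools(_phenotypes(rng.normal(size=200)), k=4)
        assert [len(m) for m in pools.members] == [50, 50, 50, 50]

    def test_uneven_split_sizes(self, rng):
        pools = build_pools(_phenotypes(rng.normal(size=10)), k=4)
        assert [len(m) for m in pools.members] == [3, 3, 2, 2]

    def test_pools_partition_population(self, rng):
        phen = _phenotypes(rng.normal(size=57))
        pools = build_pools(phen, k=4)
        everyone = [m for pool in pools.members for m in pool]
        assert sorted(everyone) == sorted(phen["id"])
        assert len(set(everyone)) == len(everyone)

    def test_pools_ordered_by_phenotype_with_ranges(self, rng):
        values = rng.normal(size=40)
        pools = build_pools(_phenotypes(values), k=4)
        highs = [r[1] for r in pools.ranges]
        lows = [r[0] for r in pools.ranges]
        assert highs == sorted(highs)
        assert all(lows[j + 1] >= highs[j] for j in range(3))

    def test_too_few_pools_rejected(self, rng):
        with pytest.raises(ConfigError):
            build_pools(_phenotypes(rng.normal(size=10)), k=1)


class TestPoolAlleleCounts:
    def test_single_member_pools_passthrough(self, small_population):
        truth, obs = small_population
        phen = _phenotypes(
            np.arange(4, dtype=float), ids=list(obs.individuals[:4])
        )
        pools = build_pools(phen, k=4)
        pooled = pool_allele_counts(obs, pools, min_total_depth=0)
        order = [obs.individuals.index(m[0]) for m in pools.members]
        for j, i in enumerate(order):
            assert np.array_equal(pooled[f"a_pool{j + 1}"].to_numpy(), obs.n_a[i])
            assert np.array_equal(pooled[f"b_pool{j + 1}"].to_numpy(), obs.n_b[i])

    def test_zero_depth_variant_filtered(self, small_population):
        truth, obs = small_population
        obs.n_a[:, 0] = 0
        obs.n_b[:, 0] = 0
        phen = _phenotypes(np.arange(len(obs.individuals), dtype=float),
                           ids=list(obs.individuals))
        pooled = pool_allele_counts(obs, build_pools(phen))
        assert bool(pooled["filtered"].iat[0])

    def test_qtl_linked_frequency_is_monotone_in_expectation(self):
        a = additive_effect_for_pve(0.3, 1.0)
        slopes = []
        for seed in range(10):
            cfg = SimConfig(
                chrom_lengths_bp=(10_000_000,),
                n_markers_per_chrom=5,
                n_individuals=200,
                qtls=[QTL(chrom=1, pos_bp=5_000_000, additive=a)],
                noise_sd=1.0,
                baseline=0.0,
                seed=800 + seed,
            )
            truth = simulate_f2_population(cfg)
            obs = simulate_observations(truth)
            pools = build_pools(truth.phenotypes)
            pooled = pool_allele_counts(obs, pools)
            pos = truth.markers["pos"].to_numpy()
            j = int(np.argmin(np.abs(pos - 5_000_000)))
            freqs = [
                pooled[f"a_pool{p + 1}"].iat[j]
                / (pooled[f"a_pool{p + 1}"].iat[j] + pooled[f"b_pool{p + 1}"].iat[j])
                for p in range(4)
            ]
            slopes.append(np.polyfit(range(4), freqs, 1)[0])
        assert np.mean(slopes) > 0.02  # A allele raises the trait

    def test_unknown_unit_rejected(self, small_population):
        truth, obs = small_population
        phen = _phenotypes(np.arange(len(obs.individuals), dtype=float),
                           ids=list(obs.individuals))
        with pytest.raises(ConfigError):
            pool_allele_counts(obs, build_pools(phen), unit="bases")


class TestRiditTest:
    def test_identical_rows_are_null(self):
        z, p = ridit_test(np.array([[10, 20, 20, 10], [10, 20, 20, 10]]))
        assert z == 0 and p == 1

    def test_extreme_monotone_table(self):
        z, p = ridit_test(np.array([[0, 0, 0, 50], [50, 0, 0, 0]]))
        assert z > 8 and p < 1e-15

    def test_matches_midrank_mannwhitney_oracle(self, rng):
        for _ in range(500):
            table = rng.integers(0, 30, size=(2, 4))
            if table[0].sum() == 0 or table[1].sum() == 0:
                continue
            z, p = ridit_test(table)
            x = np.repeat(np.arange(4), table[0])
            y = np.repeat(np.arange(4), table[1])
            ref = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert math.isclose(p, ref.pvalue, abs_tol=1e-9)

    def test_row_swap_flips_sign(self, rng):
        table = rng.integers(1, 30, size=(2, 4))
        z1, p1 = ridit_test(table)
        z2, p2 = ridit_test(table[::-1])
        assert math.isclose(z1, -z2, abs_tol=1e-12)
        assert math.isclose(p1, p2, abs_tol=1e-12)

    def test_pool_reversal_flips_sign(self, rng):
        table = rng.integers(1, 30, size=(2, 4))
        z1, _ = ridit_test(table)
        z2, _ = ridit_test(table[:, ::-1])
        assert math.isclose(z1, -z2, abs_tol=1e-12)

    def test_zero_row_is_flagged_null(self):
        z, p = ridit_test(np.array([[0, 0, 0, 0], [5, 5, 5, 5]]))
        assert z == 0 and p == 1

    def test_vectorised_scan_matches_scalar(self, rng):
        k = 4
        rows = []
        for v in range(50):
            rows.append(
                {"chrom": "chr1", "pos": v + 1, "filtered": False}
                | {f"a_pool{j + 1}": int(rng.integers(0, 30)) for j in range(k)}
                | {f"b_pool{j + 1}": int(rng.integers(0, 30)) for j in range(k)}
            )
        pooled = pd.DataFrame(rows)
        res = ridit_scan(pooled)
        for v in range(50):
            table = np.array(
                [
                    [pooled[f"a_pool{j + 1}"].iat[v] for j in range(k)],
                    [pooled[f"b_pool{j + 1}"].iat[v] for j in range(k)],
                ]
            )
            z, p = ridit_test(table)
            assert math.isclose(res["z"].iat[v], z, abs_tol=1e-9)
            assert math.isclose(res["p"].iat[v], p, abs_tol=1e-9)

    def test_read_level_pooling_is_anticonservative_at_depth(self):
        # reads of one individual are clustered -> the z statistic is
        # overdispersed at ~7x depth; the allele-dosage unit is calibrated
        cfg = SimConfig(
            chrom_lengths_bp=(1_000_000,) * 100,
            n_markers_per_chrom=1,
            n_individuals=200,
            noise_sd=1.0,
            baseline=0.0,
            seed=77,
        )
        truth = simulate_f2_population(cfg)
        obs = simulate_observations(truth)
        pools = build_pools(truth.phenotypes)
        z_reads = ridit_scan(pool_allele_counts(obs, pools, unit="reads"))["z"]
        z_alleles = ridit_scan(pool_allele_counts(obs, pools, unit="alleles"))["z"]
        assert z_reads.std() > 1.5
        assert 0.8 < z_alleles.std() < 1.25


class TestWindowScan:
    def _results(self, positions, pvalues, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos": positions, "p": pvalues, "filtered": False}
        )

    def test_single_variant_window_score(self):
        res = self._results([200_000], [1e-4])
        windows, cand = window_scan(res, min_variants=1)
        assert math.isclose(windows["score"].iat[0], 4.0)
        assert cand is not None

    def test_min_variant_filter_skips_sparse_windows(self):
        res = self._results([100_000, 150_000], [1e-3, 1e-3])
        windows, cand = window_scan(res, min_variants=5)
        assert len(windows) == 0 and cand is None

    def test_candidate_clipped_to_chromosome(self):
        res = self._results([100_000], [1e-6])
        _, cand = window_scan(
            res, min_variants=1, chrom_lengths={"chr1": 450_000}
        )
        assert cand["start"] == 1
        assert cand["end"] == 450_000

    def test_no_usable_variants_is_an_error(self):
        res = self._results([100], [np.nan])
        res["filtered"] = True
        with pytest.raises(InputError):
            window_scan(res)

    def test_candidate_extends_peak_by_flank(self):
        pos = np.arange(1, 30) * 100_000
        p = np.full(len(pos), 0.5)
        p[14] = 1e-8
        res = self._results(pos, p)
        _, cand = window_scan(res, min_variants=2, chrom_lengths={"chr1": 3_000_000})
        assert cand["start"] == cand["peak_start"] - 200_000
        assert cand["end"] == min(cand["peak_end"] + 200_000, 3_000_000)
        assert cand["start"] <= 1_500_000 <= cand["end"]
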