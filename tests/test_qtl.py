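"""QTL scan LOD, CIM covariates, permutation thresholds and joint fits."""

import math

import numpy as np
import pandas as pd
import pytest

from binqtl.core import AB, UNKNOWN, ConfigError
from binqtl.qtl import (
    call_qtl_peaks,
    cim_covariates,
    fit_qtl,
    genotype_codes,
    permutation_threshold,
    qtl_table,
    scan_lod,
)
from binqtl.simulate import (
    QTL,
    SimConfig,
    additive_effect_for_pve,
    simulate_f2_population,
)


def oracle_lod(y, g, cov_geno=()):
    """Two-model least-squares LOD, written independently of the package."""
    mask = g != UNKNOWN
    for c in cov_geno:
        mask &= c != UNKNOWN
    ym = y[mask]
    n = mask.sum()
    cols0 = [np.ones(n)]
    for c in cov_geno:
        cols0 += [1.0 - c[mask], (c[mask] == 1).astype(float)]
    X0 = np.column_stack(cols0)
    X1 = np.column_stack(cols0 + [1.0 - g[mask], (g[mask] == 1).astype(float)])
    rss0 = np.sum((ym - X0 @ np.linalg.pinv(X0) @ ym) ** 2)
    rss1 = np.sum((ym - X1 @ np.linalg.pinv(X1) @ ym) ** 2)
    return (n / 2) * math.log10(rss0 / rss1)


@pytest.fixture()
def worked_dataset(rng):
    """Small fixed dataset: 14 individuals x 6 bins with missing cells."""
    geno = rng.integers(0, 3, size=(6, 14))
    geno[2, 3] = UNKNOWN
    geno[4, 0] = UNKNOWN
    y = rng.normal(0, 1, size=14) + (1.0 - geno[1]) * 0.8
    return y, geno


class TestCodes:
    @pytest.mark.parametrize(
        "g,expected", [(0, (1.0, 0.0)), (1, (0.0, 1.0)), (2, (-1.0, 0.0))]
    )
    def test_codes(self, g, expected):
        assert genotype_codes(g) == expected

    def test_unknown_excluded(self):
        assert genotype_codes(UNKNOWN) is None


class TestScan:
    def test_matches_regression_oracle(self, worked_dataset):
        y, geno = worked_dataset
        scan = scan_lod(y, geno)
        for b in range(geno.shape[0]):
            assert math.isclose(scan["lod"].iat[b], oracle_lod(y, geno[b]), abs_tol=1e-9)

    def test_matches_oracle_with_covariates(self, worked_dataset):
        y, geno = worked_dataset
        scan = scan_lod(y, geno, covariate_bins=(0,))
        for b in range(1, geno.shape[0]):
            assert math.isclose(
                scan["lod"].iat[b], oracle_lod(y, geno[b], (geno[0],)), abs_tol=1e-9
            )

    def test_constant_phenotype_gives_zero_lod(self, worked_dataset):
        _, geno = worked_dataset
        scan = scan_lod(np.ones(geno.shape[1]), geno)
        assert (scan["lod"] == 0).all()

    def test_lod_affine_invariant(self, worked_dataset):
        y, geno = worked_dataset
        base = scan_lod(y, geno)["lod"]
        shifted = scan_lod(3.0 * y - 7.0, geno)["lod"]
        assert np.allclose(base, shifted, atol=1e-9)

    def test_covariate_coinciding_with_tested_bin_is_excluded(self, worked_dataset):
        y, geno = worked_dataset
        simple = scan_lod(y, geno)["lod"].iat[1]
        with_self = scan_lod(y, geno, covariate_bins=(1,))["lod"].iat[1]
        assert math.isclose(simple, with_self, abs_tol=1e-12)

    def test_nested_models_monotone_rss(self, worked_dataset):
        y, geno = worked_dataset
        # adding a covariate can only decrease the null RSS, so the
        # covariate-only LOD against the plain mean model is >= 0
        from binqtl.qtl import _rss

        n = geno.shape[1]
        X0 = np.ones((n, 1))
        X1 = np.column_stack([np.ones(n), 1.0 - geno[0], (geno[0] == 1).astype(float)])
        assert _rss(X1, y[:, None])[0] <= _rss(X0, y[:, None])[0] + 1e-12


class TestCim:
    def test_zero_covariates_reduces_to_simple_scan(self, worked_dataset):
        y, geno = worked_dataset
        assert cim_covariates(y, geno, n_cov=0) == ()
        simple = scan_lod(y, geno)
        composite = scan_lod(y, geno, covariate_bins=())
        assert np.allclose(simple["lod"], composite["lod"])

    def test_forward_selection_picks_the_signal_bin(self, worked_dataset):
        y, geno = worked_dataset
        covs = cim_covariates(y, geno, n_cov=1)
        assert covs == (1,)


class TestPermutationThreshold:
    def test_identical_seed_identical_threshold(self, worked_dataset):
        y, geno = worked_dataset
        t1 = permutation_threshold(y, geno, n_perm=50, seed=5)
        t2 = permutation_threshold(y, geno, n_perm=50, seed=5)
        assert t1["threshold"] == t2["threshold"]

    def test_alpha_zero_limit_is_max(self, worked_dataset):
        y, geno = worked_dataset
        res = permutation_threshold(y, geno, n_perm=50, alpha=1e-12, seed=5)
        assert math.isclose(res["threshold"], res["max_lods"].max())

    def test_too_few_permutations_refused(self, worked_dataset):
        y, geno = worked_dataset
        with pytest.raises(ConfigError):
            permutation_threshold(y, geno, n_perm=10)

    def test_threshold_stable_across_seeds(self):
        cfg = SimConfig(
            chrom_lengths_bp=(30_000_000,) * 2,
            n_markers_per_chrom=25,
            n_individuals=150,
            noise_sd=1.0,
            baseline=0.0,
            seed=13,
        )
        truth = simulate_f2_population(cfg)
        y = truth.phenotypes["value"].to_numpy()
        thresholds = [
            permutation_threshold(y, truth.genotypes.T, n_perm=1000, seed=s)["threshold"]
            for s in range(10)
        ]
        assert np.std(thresholds) < 0.15


class TestFitQtl:
    def test_noise_free_single_qtl_explains_everything(self, rng):
        g = rng.integers(0, 3, size=80)
        y = 5.0 + (1.0 - g) * 2.0 + (g == 1) * 0.5
        out = fit_qtl(y, g[None, :], [0])
        assert math.isclose(out["pve"], 100.0, abs_tol=1e-6)
        assert math.isclose(out["qtls"][0]["additive"], 2.0, abs_tol=1e-9)

    def test_pve_recovery_near_target(self):
        # average estimated PVE over replicates near the simulated 20%
        a = additive_effect_for_pve(0.2, 1.0)
        pves = []
        for seed in range(10):
            cfg = SimConfig(
                chrom_lengths_bp=(30_000_000,),
                n_markers_per_chrom=30,
                n_individuals=200,
                qtls=[QTL(chrom=1, pos_bp=15_000_000, additive=a)],
                noise_sd=1.0,
                baseline=0.0,
                seed=100 + seed,
            )
            truth = simulate_f2_population(cfg)
            y = truth.phenotypes["value"].to_numpy()
            geno = truth.genotypes.T
            peak = int(np.argmax(scan_lod(y, geno)["lod"].to_numpy()))
            pves.append(fit_qtl(y, geno, [peak])["pve"])
        assert abs(np.mean(pves) - 20.0) < 6.0

    def test_insufficient_df_raises(self):
        g = np.zeros((1, 3), dtype=int)
        with pytest.raises(ConfigError):
            fit_qtl(np.array([1.0, 2.0, 3.0]), g, [0])


class TestQtlTable:
    def _bins(self, n, chrom="chr1"):
        return pd.DataFrame(
            {
                "bin_id": [f"bin{k}" for k in range(n)],
                "chrom": chrom,
                "start": np.arange(n) * 100 + 1,
                "end": (np.arange(n) + 1) * 100,
            }
        )

    def test_peaks_on_separate_chromosomes_reported_separately(self, rng):
        geno = rng.integers(0, 3, size=(6, 120))
        y = (1.0 - geno[1]) * 1.5 + (1.0 - geno[4]) * 1.5 + rng.normal(0, 0.5, 120)
        bins = self._bins(6)
        bins.loc[3:, "chrom"] = "chr2"
        lod = scan_lod(y, geno)["lod"].to_numpy()
        table = qtl_table("t", y, geno, bins, lod, threshold=2.0)
        assert len(table) == 2
        assert set(table["chrom"]) == {"chr1", "chr2"}

    def test_support_interval_is_peak_plus_flanks(self, rng):
        geno = rng.integers(0, 3, size=(5, 120))
        y = (1.0 - geno[2]) * 2.0 + rng.normal(0, 0.5, 120)
        lod = scan_lod(y, geno)["lod"].to_numpy()
        table = qtl_table("t", y, geno, self._bins(5), lod, threshold=2.0)
        row = table.iloc[0]
        assert row["peak_bin"] == "bin2"
        assert row["interval_start_bin"] == "bin1"
        assert row["interval_end_bin"] == "bin3"

    def test_edge_peak_interval_clipped_to_chromosome(self, rng):
        geno = rng.integers(0, 3, size=(4, 120))
        y = (1.0 - geno[0]) * 2.0 + rng.normal(0, 0.5, 120)
        lod = scan_lod(y, geno)["lod"].to_numpy()
        table = qtl_table("t", y, geno, self._bins(4), lod, threshold=2.0)
        assert table.iloc[0]["interval_start_bin"] == "bin0"

    def test_no_peak_above_threshold_empty_table(self, rng):
        geno = rng.integers(0, 3, size=(4, 60))
        y = rng.normal(0, 1, 60)
        lod = scan_lod(y, geno)["lod"].to_numpy()
        table = qtl_table("t", y, geno, self._bins(4), lod, threshold=1e6)
        assert len(table) == 0

    def test_call_peaks_one_per_chromosome(self):
        lod = np.array([1.0, 5.0, 2.0, 7.0, 6.0])
        chroms = np.array(["chr1", "chr1", "chr1", "chr2", "chr2"])
        assert call_qtl_peaks(lod, chroms, threshold=3.0) == [1, 3]
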