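"""HMM emissions/transitions, Viterbi decoding, crossovers and bins."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from binqtl.core import AA, AB, BB, UNKNOWN, ConfigError
from binqtl.binmap import (
    GenotypeBlock,
    HMMParams,
    build_bins,
    call_crossovers,
    decode_chromosome,
    decode_population,
    emission_log_probs,
    emission_probs,
    transition_matrix,
    viterbi,
)
from binqtl.studies import accuracy_grid, bin_genotype_accuracy, crossover_recovery

_LOG_START = np.log([0.25, 0.5, 0.25])


def brute_force_best_loglik(log_emit, log_trans):
    """Exhaustive maximisation over all 3^m state paths."""
    m = log_emit.shape[0]
    best = -np.inf
    for path in itertools.product(range(3), repeat=m):
        lp = _LOG_START[path[0]] + log_emit[0, path[0]]
        for t in range(1, m):
            lp += log_trans[t - 1, path[t - 1], path[t]] + log_emit[t, path[t]]
        best = max(best, lp)
    return best


def path_loglik(path, log_emit, log_trans):
    lp = _LOG_START[path[0]] + log_emit[0, path[0]]
    for t in range(1, len(path)):
        lp += log_trans[t - 1, path[t - 1], path[t]] + log_emit[t, path[t]]
    return lp


class TestEmissions:
    def test_clean_homozygote_likelihoods(self):
        p = emission_probs(5, 0, 0.01)
        raw = np.array([0.99**5, 0.5**5, 0.01**5])
        assert np.allclose(p, raw / raw.sum(), atol=1e-12)

    def test_no_data_is_uninformative(self):
        assert np.allclose(emission_probs(0, 0, 0.01), [1 / 3] * 3)

    def test_balanced_counts_favour_heterozygote(self):
        p = emission_probs(3, 3, 0.01)
        assert p[AB] > p[AA] and p[AB] > p[BB]

    @pytest.mark.parametrize("eps", [0.0, 0.5, -0.1, 0.7])
    def test_error_rate_domain(self, eps):
        with pytest.raises(ConfigError):
            emission_log_probs(np.array([1]), np.array([1]), eps)


class TestTransitions:
    def test_zero_gap_is_identity(self):
        assert np.allclose(transition_matrix(0, 3.0), np.eye(3))

    def test_known_switch_probability(self):
        # choose the physical gap whose Haldane r is exactly 0.1
        d_morgan = -math.log(1 - 0.2) / 2
        gap = d_morgan * 1e8 / 3.0
        T = transition_matrix(gap, 3.0)
        assert np.allclose(T[0], [0.81, 0.18, 0.01], atol=1e-9)
        assert np.isclose(T[1, 1], 0.82, atol=1e-9)

    def test_infinite_gap_reaches_f2_stationary_distribution(self):
        T = transition_matrix(1e12, 3.0)
        assert np.allclose(T, np.tile([0.25, 0.5, 0.25], (3, 1)), atol=1e-9)

    @given(gap=st.floats(0, 1e8), rho=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rows_are_distributions(self, gap, rho):
        T = transition_matrix(gap, rho)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert (T >= 0).all()


class TestViterbi:
    def test_matches_exhaustive_maximisation(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 9))
            n_b = rng.integers(0, 4, size=m)
            n_a = rng.integers(0, 4, size=m)
            log_emit = emission_log_probs(n_a, n_b, 0.01)
            gaps = rng.uniform(1e4, 2e6, size=m - 1)
            log_trans = np.log(np.stack([transition_matrix(g, 3.0) for g in gaps]))
            path = viterbi(log_emit, log_trans)
            assert np.isclose(
                path_loglik(path, log_emit, log_trans),
                brute_force_best_loglik(log_emit, log_trans),
                atol=1e-9,
            )

    def test_clean_chromosome_is_one_block(self):
        pos = np.arange(1, 11) * 100_000
        blocks = decode_chromosome(
            np.full(10, 3), np.zeros(10, dtype=int), pos, HMMParams()
        )
        assert len(blocks) == 1 and blocks[0].state == AA

    def test_isolated_discordant_marker_is_absorbed(self):
        # one depth-1 discordant read inside a concordant run
        n_a = np.array([3, 3, 3, 0, 3, 3, 3])
        n_b = np.array([0, 0, 0, 1, 0, 0, 0])
        pos = np.arange(1, 8) * 200_000
        blocks = decode_chromosome(n_a, n_b, pos, HMMParams())
        assert len(blocks) == 1 and blocks[0].state == AA

    def test_constructed_switch_is_recovered(self):
        n_a = np.array([4, 4, 4, 4, 0, 0, 0, 0])
        n_b = np.array([0, 0, 0, 0, 4, 4, 4, 4])
        pos = np.arange(1, 9) * 300_000
        blocks = decode_chromosome(n_a, n_b, pos, HMMParams())
        assert [b.state for b in blocks] == [AA, BB]

    def test_all_missing_chromosome_is_unknown(self):
        pos = np.arange(1, 6) * 100_000
        blocks = decode_chromosome(
            np.zeros(5, dtype=int), np.zeros(5, dtype=int), pos, HMMParams()
        )
        assert len(blocks) == 1 and blocks[0].state == UNKNOWN


class TestCrossovers:
    def test_block_boundaries_become_crossovers(self):
        blocks = {
            (0, "chr1"): [
                GenotypeBlock(0, "chr1", 1, 100, AA),
                GenotypeBlock(0, "chr1", 200, 300, AB),
                GenotypeBlock(0, "chr1", 400, 500, BB),
            ],
            (1, "chr1"): [GenotypeBlock(1, "chr1", 1, 500, AA)],
        }
        xo = call_crossovers(blocks)
        assert len(xo) == 2
        assert xo["mid_bp"].tolist() == [150.0, 350.0]

    def test_population_crossover_recovery(self):
        out = crossover_recovery(seed=1)
        assert out["recall"] >= 0.99
        assert out["mean_position_error_bp"] < out["mean_marker_gap_bp"]


def _uniform_markers(n, length, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.linspace(1, length, n).astype(int)}
    )


class TestBins:
    def _blocks_for_breakpoints(self, ind, breaks, length=30_000_000):
        states = [AA, BB, AA, BB]
        edges = [1] + list(breaks) + [length]
        blocks = []
        for k in range(len(edges) - 1):
            start = edges[k] if k == 0 else edges[k] + 1000
            end = edges[k + 1] - 1000 if k < len(edges) - 2 else edges[k + 1]
            blocks.append(GenotypeBlock(ind, "chr1", start, end, states[k]))
        return blocks

    def test_breakpoints_define_bins(self):
        markers = _uniform_markers(31, 30_000_000)
        blocks = {
            (0, "chr1"): self._blocks_for_breakpoints(0, [10_000_000]),
            (1, "chr1"): self._blocks_for_breakpoints(1, [20_000_000]),
        }
        binmat = build_bins(blocks, markers, ["i0", "i1"], min_bin_bp=30_000)
        assert binmat.n_bins == 3
        assert binmat.bins["start"].iat[0] == 1
        assert binmat.bins["end"].iat[2] == 30_000_000
        # partition: no overlap, no gaps
        assert (
            binmat.bins["start"].iloc[1:].to_numpy()
            == binmat.bins["end"].iloc[:-1].to_numpy() + 1
        ).all()

    def test_short_bins_are_merged(self):
        markers = _uniform_markers(601, 30_000_000)
        near = {
            (0, "chr1"): self._blocks_for_breakpoints(0, [15_000_000]),
            (1, "chr1"): self._blocks_for_breakpoints(1, [15_025_000]),
        }
        merged = build_bins(near, markers, ["i0", "i1"], min_bin_bp=30_000)
        assert merged.n_bins == 2  # 25 kb candidate merged away
        apart = {
            (0, "chr1"): self._blocks_for_breakpoints(0, [15_000_000]),
            (1, "chr1"): self._blocks_for_breakpoints(1, [15_040_000]),
        }
        kept = build_bins(apart, markers, ["i0", "i1"], min_bin_bp=30_000)
        assert kept.n_bins == 3  # 40 kb >= threshold
        assert (kept.lengths_bp() >= 30_000).all()

    def test_no_crossovers_single_bin(self):
        markers = _uniform_markers(10, 1_000_000)
        blocks = {(0, "chr1"): [GenotypeBlock(0, "chr1", 1, 1_000_000, AB)]}
        binmat = build_bins(blocks, markers, ["i0"])
        assert binmat.n_bins == 1 and binmat.genotypes[0, 0] == AB

    def test_bins_partition_marker_span(self, small_population):
        truth, obs = small_population
        blocks = decode_population(obs, HMMParams())
        binmat = build_bins(blocks, obs.markers, obs.individuals)
        for chrom, grp in binmat.bins.groupby("chrom"):
            pos = obs.markers.loc[obs.markers["chrom"] == chrom, "pos"]
            lengths = (grp["end"] - grp["start"] + 1).sum()
            assert lengths == pos.max() - pos.min() + 1
            assert (grp["start"].iloc[1:].to_numpy() == grp["end"].iloc[:-1].to_numpy() + 1).all()


class TestAccuracy:
    def test_accuracy_monotone_in_depth_and_error(self):
        grid = accuracy_grid(seed=5, n_individuals=80, n_markers=60)
        piv = grid.pivot(index="depth", columns="error_rate", values="accuracy")
        tol = 0.005  # Monte-Carlo slack on ~5k genotype cells
        for eps in piv.columns:
            col = piv[eps].to_numpy()
            assert (np.diff(col) >= -tol).all(), f"not monotone in depth at eps={eps}"
        for lam in piv.index:
            row = piv.loc[lam].to_numpy()
            assert (np.diff(row) <= tol).all(), f"not monotone in error at depth={lam}"

    def test_study_conditions_accuracy(self):
        # 200 individuals, 7x, 1% error: bin genotypes >= 99% correct
        assert bin_genotype_accuracy(seed=3) >= 0.99
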