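"""Seeded simulation studies: calibration and parameter recovery.

Each function runs a self-contained Monte-Carlo study of one pipeline
property against simulator ground truth — imputation accuracy, QTL
scan power and type-I error, segregation-distortion test calibration
and power, Ridit p-value uniformity, and graded-pool candidate-region
coverage.  They are used both by the test suite and by the
reproducibility script; all randomness derives from the ``seed``
argument.

Problem sizes default to a scaled study genome (a few 30-Mb
chromosomes at 3 cM/Mb rather than a full 12-chromosome genome) so a
study finishes in seconds to minutes on one CPU while preserving the
per-chromosome genetic structure (~90 cM, ~200 F2 individuals, ~7x
depth) that the full-scale design has.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import UNKNOWN
from .simulate import (
    QTL,
    DistortionLocus,
    SimConfig,
    additive_effect_for_pve,
    simulate_f2_population,
    simulate_observations,
)
from .binmap import BinGenotypeMatrix, HMMParams, build_bins, decode_population
from .sdr import detect_sdrs, distortion_table
from .qtl import call_qtl_peaks, permutation_threshold, scan_lod, cim_covariates
from .gps import build_pools, pool_allele_counts, ridit_scan, window_scan

__all__ = [
    "truth_bin_genotypes",
    "bin_genotype_accuracy",
    "accuracy_grid",
    "crossover_recovery",
    "qtl_power_study",
    "qtl_type1_study",
    "cim_gain_study",
    "distortion_type1_study",
    "sdr_power_study",
    "ridit_uniformity_study",
    "gps_coverage_study",
]


def _derive(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def truth_bin_genotypes(truth, binmat: BinGenotypeMatrix) -> np.ndarray:
    """True genotype per (bin, individual): marker majority inside the bin."""
    chrom = truth.markers["chrom"].to_numpy()
    pos = truth.markers["pos"].to_numpy()
    out = np.empty((binmat.n_bins, len(truth.individuals)), dtype=np.int8)
    for k in range(binmat.n_bins):
        sel = (
            (chrom == binmat.bins["chrom"].iat[k])
            & (pos >= binmat.bins["start"].iat[k])
            & (pos <= binmat.bins["end"].iat[k])
        )
        g = truth.genotypes[:, sel]
        counts = np.stack([(g == s).sum(axis=1) for s in (0, 1, 2)])
        out[k] = np.argmax(counts, axis=0)
    return out


def _pipeline_bins(truth, obs, params: HMMParams | None = None) -> BinGenotypeMatrix:
    params = params or HMMParams()
    blocks = decode_population(obs, params)
    return build_bins(blocks, obs.markers, obs.individuals, params.min_bin_bp)


def bin_genotype_accuracy(
    seed: int,
    n_individuals: int = 200,
    mean_depth: float = 7.0,
    error_rate: float = 0.01,
    n_chrom: int = 3,
    n_markers: int = 100,
) -> float:
    """Fraction of (bin, individual) genotypes matching simulator truth."""
    cfg = SimConfig(
        chrom_lengths_bp=(30_000_000,) * n_chrom,
        n_markers_per_chrom=n_markers,
        n_individuals=n_individuals,
        mean_depth=mean_depth,
        error_rate=error_rate,
        seed=_derive(seed, 1),
    )
    truth = simulate_f2_population(cfg)
    obs = simulate_observations(truth)
    binmat = _pipeline_bins(truth, obs, HMMParams(error_rate=error_rate))
    expected = truth_bin_genotypes(truth, binmat)
    known = binmat.genotypes != UNKNOWN
    return float((binmat.genotypes[known] == expected[known]).mean())


def accuracy_grid(
    seed: int,
    depths: tuple[float, ...] = (1.0, 3.0, 7.0),
    errors: tuple[float, ...] = (0.001, 0.01, 0.05),
    n_individuals: int = 60,
    n_markers: int = 60,
) -> pd.DataFrame:
    """Imputation accuracy over a (depth, error-rate) grid (one chromosome).

    The same meiosis (same derived seed) underlies every cell, so the
    grid isolates the effect of observation quality.
    """
    rows = []
    cfg = SimConfig(
        chrom_lengths_bp=(30_000_000,),
        n_markers_per_chrom=n_markers,
        n_individuals=n_individuals,
        seed=_derive(seed, 2),
    )
    truth = simulate_f2_population(cfg)
    for lam in depths:
        for eps in errors:
            rng = np.random.default_rng(_derive(seed, 3))
            obs = simulate_observations(truth, mean_depth=lam, error_rate=eps, rng=rng)
            binmat = _pipeline_bins(truth, obs, HMMParams(error_rate=eps))
            expected = truth_bin_genotypes(truth, binmat)
            known = binmat.genotypes != UNKNOWN
            acc = float((binmat.genotypes[known] == expected[known]).mean()) if known.any() else 0.0
            rows.append({"depth": lam, "error_rate": eps, "accuracy": acc})
    return pd.DataFrame(rows)


def crossover_recovery(
    seed: int,
    n_individuals: int = 50,
    n_markers: int = 200,
    mean_depth: float = 200.0,
    error_rate: float = 1e-4,
) -> dict:
    """Crossover recall and positional error under near-perfect observations.

    A true crossover is recovered when a detected event of the same
    individual/chromosome lies within four mean marker gaps of it (with
    uniformly random markers, individual gaps are roughly exponential,
    so a fixed one-gap radius would misscore events that merely fall in
    a locally sparse stretch).  The mean positional error of recovered
    events is reported alongside the recall.
    """
    cfg = SimConfig(
        chrom_lengths_bp=(30_000_000,),
        n_markers_per_chrom=n_markers,
        n_individuals=n_individuals,
        mean_depth=mean_depth,
        error_rate=error_rate,
        seed=_derive(seed, 4),
    )
    truth = simulate_f2_population(cfg)
    obs = simulate_observations(truth)
    from .binmap import call_crossovers

    blocks = decode_population(obs, HMMParams(error_rate=max(error_rate, 1e-6)))
    detected = call_crossovers(blocks)
    span = truth.markers["pos"].max() - truth.markers["pos"].min()
    mean_gap = span / (n_markers - 1)
    lo, hi = truth.markers["pos"].min(), truth.markers["pos"].max()
    recovered = 0
    errors = []
    true_events = truth.crossovers[
        (truth.crossovers["pos_bp"] >= lo) & (truth.crossovers["pos_bp"] <= hi)
    ]
    for _, ev in true_events.iterrows():
        cand = detected[
            (detected["individual"] == ev["individual"])
            & (detected["chrom"] == ev["chrom"])
        ]
        if len(cand) == 0:
            continue
        err = np.abs(cand["mid_bp"].to_numpy() - ev["pos_bp"]).min()
        if err <= 4 * mean_gap:
            recovered += 1
            errors.append(err)
    n_true = len(true_events)
    return {
        "recall": recovered / n_true if n_true else float("nan"),
        "mean_position_error_bp": float(np.mean(errors)) if errors else float("nan"),
        "mean_marker_gap_bp": float(mean_gap),
        "n_true": n_true,
    }


def _one_qtl_config(seed: int, pve: float, n_chrom: int, n_markers: int, qtl_chrom: int) -> SimConfig:
    a = additive_effect_for_pve(pve, 1.0)
    return SimConfig(
        chrom_lengths_bp=(30_000_000,) * n_chrom,
        n_markers_per_chrom=n_markers,
        n_individuals=200,
        qtls=[QTL(chrom=qtl_chrom, pos_bp=15_000_000, additive=a)],
        noise_sd=1.0,
        baseline=0.0,
        seed=seed,
    )


def qtl_power_study(
    seed: int,
    n_rep: int = 50,
    pve: float = 0.2,
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_chrom: int = 3,
    n_markers: int = 60,
) -> float:
    """Fraction of replicates detecting a single QTL.

    Detection = the genome-wide peak bin lies on the QTL's chromosome
    and its LOD clears that replicate's permutation threshold.  The
    full pipeline runs per replicate: simulate, observe at 7x, impute,
    bin, scan.
    """
    hits = 0
    qtl_chrom = 2 if n_chrom >= 2 else 1
    for rep in range(n_rep):
        cfg = _one_qtl_config(_derive(seed, 100 + rep), pve, n_chrom, n_markers, qtl_chrom)
        truth = simulate_f2_population(cfg)
        obs = simulate_observations(truth)
        binmat = _pipeline_bins(truth, obs)
        y = truth.phenotypes["value"].to_numpy()
        scan = scan_lod(y, binmat.genotypes)
        lod = scan["lod"].to_numpy()
        thr = permutation_threshold(
            y, binmat.genotypes, n_perm=n_perm, alpha=alpha, seed=_derive(seed, 200 + rep)
        )["threshold"]
        peak = int(np.argmax(lod))
        if (
            binmat.bins["chrom"].iat[peak] == f"chr{qtl_chrom}"
            and lod[peak] > thr
        ):
            hits += 1
    return hits / n_rep


def qtl_type1_study(
    seed: int,
    n_rep: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_chrom: int = 3,
    n_markers: int = 20,
) -> float:
    """Genome-wide false-positive rate at the permutation threshold.

    No-QTL phenotypes are scanned against true marker genotypes (the
    scan grid is the marker set; imputation noise is irrelevant to the
    null calibration being measured).
    """
    false_pos = 0
    for rep in range(n_rep):
        cfg = SimConfig(
            chrom_lengths_bp=(30_000_000,) * n_chrom,
            n_markers_per_chrom=n_markers,
            n_individuals=200,
            noise_sd=1.0,
            baseline=0.0,
            seed=_derive(seed, 300 + rep),
        )
        truth = simulate_f2_population(cfg)
        y = truth.phenotypes["value"].to_numpy()
        geno = truth.genotypes.T  # markers x individuals
        lod = scan_lod(y, geno)["lod"].to_numpy()
        thr = permutation_threshold(
            y, geno, n_perm=n_perm, alpha=alpha, seed=_derive(seed, 400 + rep)
        )["threshold"]
        if lod.max() > thr:
            false_pos += 1
    return false_pos / n_rep


def cim_gain_study(
    seed: int,
    n_rep: int = 50,
    pve: float = 0.2,
    n_markers: int = 45,
) -> float:
    """Fraction of replicates where the composite scan's LOD at a focal
    QTL is at least the simple scan's (a second QTL segregates on
    another chromosome and its variance can be absorbed)."""
    a = additive_effect_for_pve(pve, 1.0)
    wins = 0
    for rep in range(n_rep):
        cfg = SimConfig(
            chrom_lengths_bp=(30_000_000,) * 2,
            n_markers_per_chrom=n_markers,
            n_individuals=200,
            qtls=[
                QTL(chrom=1, pos_bp=15_000_000, additive=a),
                QTL(chrom=2, pos_bp=15_000_000, additive=a),
            ],
            noise_sd=1.0,
            baseline=0.0,
            seed=_derive(seed, 500 + rep),
        )
        truth = simulate_f2_population(cfg)
        y = truth.phenotypes["value"].to_numpy()
        geno = truth.genotypes.T
        chroms = truth.markers["chrom"].to_numpy()
        # crude cM positions from physical position at the background rate
        pos_cm = truth.markers["pos"].to_numpy() * 3.0 / 1e6
        simple = scan_lod(y, geno)["lod"].to_numpy()
        covs = cim_covariates(y, geno, pos_cm=pos_cm, chroms=chroms, n_cov=3)
        composite = scan_lod(y, geno, covs, pos_cm=pos_cm, chroms=chroms)["lod"].to_numpy()
        on_1 = chroms == "chr1"
        if composite[on_1].max() >= simple[on_1].max():
            wins += 1
    return wins / n_rep


def distortion_type1_study(
    seed: int,
    n_rep: int = 100,
    n_chrom: int = 5,
    n_markers: int = 4,
) -> pd.DataFrame:
    """Null chi-square p-values over well-spaced marker-level bins.

    Simulates undistorted populations and tests every marker as a bin;
    returns the pooled per-test p-values for both stages.
    """
    rows = []
    for rep in range(n_rep):
        cfg = SimConfig(
            chrom_lengths_bp=(20_000_000,) * n_chrom,
            n_markers_per_chrom=n_markers,
            n_individuals=200,
            seed=_derive(seed, 600 + rep),
        )
        truth = simulate_f2_population(cfg)
        binmat = BinGenotypeMatrix(
            bins=pd.DataFrame(
                {
                    "bin_id": [f"m{j}" for j in range(len(truth.markers))],
                    "chrom": truth.markers["chrom"],
                    "start": truth.markers["pos"],
                    "end": truth.markers["pos"],
                }
            ),
            genotypes=truth.genotypes.T,
            individuals=list(truth.individuals),
        )
        table = distortion_table(binmat)
        rows.append(table[["p_zyg", "p_gam"]])
    return pd.concat(rows, ignore_index=True)


def sdr_power_study(
    seed: int,
    n_rep: int = 50,
    w_b: float = 0.5,
    n_markers: int = 60,
) -> dict:
    """Power to recover a gametic-selection locus as an SDR.

    A locus with gamete survival weights (w_A = 1, w_B) sits mid-way on
    chromosome 1 of a two-chromosome genome; a replicate counts as a
    hit when a detected SDR on that chromosome overlaps the locus.
    Also reports how often the region's direction is 'female' (the
    favoured parent at w_B < 1).
    """
    locus_pos = 15_000_000
    hits = 0
    female_direction = 0
    for rep in range(n_rep):
        cfg = SimConfig(
            chrom_lengths_bp=(30_000_000,) * 2,
            n_markers_per_chrom=n_markers,
            n_individuals=200,
            distortion_loci=[
                DistortionLocus(chrom=1, pos_bp=locus_pos, w_a=1.0, w_b=w_b)
            ],
            seed=_derive(seed, 700 + rep),
        )
        truth = simulate_f2_population(cfg)
        obs = simulate_observations(truth)
        binmat = _pipeline_bins(truth, obs)
        regions = detect_sdrs(distortion_table(binmat))
        cover = regions[
            (regions["chrom"] == "chr1")
            & (regions["start"] <= locus_pos)
            & (regions["end"] >= locus_pos)
        ]
        if len(cover):
            hits += 1
            if (cover["direction"] == "female").any():
                female_direction += 1
    return {"power": hits / n_rep, "female_fraction": female_direction / max(hits, 1)}


def ridit_uniformity_study(
    seed: int,
    n_rep: int = 2,
    n_chrom: int = 150,
    n_individuals: int = 200,
) -> np.ndarray:
    """Null Ridit p-values over unlinked variants (one per chromosome)."""
    ps = []
    for rep in range(n_rep):
        cfg = SimConfig(
            chrom_lengths_bp=(1_000_000,) * n_chrom,
            n_markers_per_chrom=1,
            n_individuals=n_individuals,
            noise_sd=1.0,
            baseline=0.0,
            seed=_derive(seed, 800 + rep),
        )
        truth = simulate_f2_population(cfg)
        obs = simulate_observations(truth)
        pools = build_pools(truth.phenotypes)
        pooled = pool_allele_counts(obs, pools, unit="alleles")
        res = ridit_scan(pooled)
        ps.append(res.loc[~res["filtered"], "p"].to_numpy())
    return np.concatenate(ps)


def gps_coverage_study(
    seed: int,
    n_rep: int = 50,
    pve: float = 0.3,
    n_markers: int = 600,
    min_variants: int = 5,
) -> float:
    """Fraction of replicates whose graded-pool candidate region covers the QTL.

    One additive QTL (target PVE) mid-way on chromosome 1 of a
    two-chromosome genome; 200 individuals at 7x depth; four pools.
    Coverage is judged against the simulated marker actually carrying
    the QTL effect.
    """
    a = additive_effect_for_pve(pve, 1.0)
    hits = 0
    for rep in range(n_rep):
        cfg = SimConfig(
            chrom_lengths_bp=(30_000_000,) * 2,
            n_markers_per_chrom=n_markers,
            n_individuals=200,
            qtls=[QTL(chrom=1, pos_bp=15_000_000, additive=a)],
            noise_sd=1.0,
            baseline=0.0,
            seed=_derive(seed, 900 + rep),
        )
        truth = simulate_f2_population(cfg)
        obs = simulate_observations(truth)
        pools = build_pools(truth.phenotypes)
        pooled = pool_allele_counts(obs, pools, unit="alleles")
        res = ridit_scan(pooled)
        lengths = dict(zip(cfg.chrom_names(), (int(l) for l in cfg.chrom_lengths_bp)))
        _, candidate = window_scan(res, min_variants=min_variants, chrom_lengths=lengths)
        if candidate is None:
            continue
        idx = truth.marker_index("chr1")
        pos = truth.markers["pos"].to_numpy()[idx]
        qtl_marker_pos = int(pos[np.argmin(np.abs(pos - 15_000_000))])
        if (
            candidate["chrom"] == "chr1"
            and candidate["start"] <= qtl_marker_pos <= candidate["end"]
        ):
            hits += 1
    return hits / n_rep
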