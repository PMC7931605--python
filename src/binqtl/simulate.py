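"""Synthetic F2 mapping populations with ground truth.

Models the meiosis, genotyping noise and phenotype architecture that a
low-coverage resequencing pipeline for an F2 cross has to cope with:

* Each F2 individual is the union of two independent gametes per
  chromosome.  Crossovers per gamete follow a Poisson process with mean
  ``L/100`` events, where ``L`` is the chromosome's genetic length in cM
  (no crossover interference), and crossover positions are uniform on
  the chromosome.
* Markers are parent-homozygous bi-allelic SNPs placed uniformly at
  random (1-based bp), so inter-marker gaps vary as they do in real
  resequencing data.
* Sequencing observations at a marker are a Poisson read depth with a
  per-read miscall probability, optionally thinned by an extra dropout
  probability.
* Transmission-ratio distortion can act at the gametic stage (a gamete
  carrying allele A survives with probability ``w_A``, allele B with
  ``w_B``) or at the zygotic stage (zygote survival weight
  ``w_A**(2-g) * w_B**g`` for a genotype carrying ``g`` copies of B).
  Both are implemented by rejection sampling so population size stays
  exact.
* Quantitative phenotypes are ``y = mu + sum_q (a_q x_q + d_q z_q) + e``
  with additive dosage ``x in {-1, 0, +1}`` (BB, AB, AA), heterozygosity
  indicator ``z``, and Gaussian residual noise.  QTLs act through the
  simulated marker nearest the requested position, which keeps the
  ground truth discrete and recovery tests unambiguous.

All randomness flows through one :class:`numpy.random.Generator` seeded
from :attr:`SimConfig.seed`; identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AB, ConfigError
from .variants import ObservationMatrix

__all__ = [
    "DistortionLocus",
    "QTL",
    "SimConfig",
    "TruthSet",
    "simulate_gamete",
    "simulate_f2_population",
    "simulate_observations",
    "simulate_phenotypes",
    "additive_effect_for_pve",
]


@dataclass(frozen=True)
class DistortionLocus:
    """A transmission-ratio distortion locus.

    ``chrom`` is the 1-based chromosome number, ``pos_bp`` the physical
    position, ``w_a``/``w_b`` the survival weights of the two parental
    alleles (in ``(0, 1]``), and ``stage`` either ``"gametic"`` or
    ``"zygotic"``.
    """

    chrom: int
    pos_bp: int
    w_a: float
    w_b: float
    stage: str = "gametic"

    def validate(self) -> None:
        if self.stage not in ("gametic", "zygotic"):
            raise ConfigError(f"unknown distortion stage {self.stage!r}")
        for w in (self.w_a, self.w_b):
            if not (0.0 < w <= 1.0) or not math.isfinite(w):
                raise ConfigError("survival weights must lie in (0, 1]")


@dataclass(frozen=True)
class QTL:
    """A simulated QTL: additive effect ``a`` and dominance ``d`` in trait units."""

    chrom: int
    pos_bp: int
    additive: float
    dominance: float = 0.0


@dataclass
class SimConfig:
    """Study design for one synthetic F2 population.

    Defaults emulate the design the pipeline targets: 200 F2
    individuals genotyped at ~7x mean depth with a 1% per-read error
    rate, on chromosomes with a uniform genetic rate of 3 cM/Mb.
    """

    chrom_lengths_bp: Sequence[int] = (30_000_000,) * 3
    cm_per_mb: float = 3.0
    n_markers_per_chrom: int = 100
    n_individuals: int = 200
    mean_depth: float = 7.0
    error_rate: float = 0.01
    missing_extra: float = 0.0
    distortion_loci: list[DistortionLocus] = field(default_factory=list)
    qtls: list[QTL] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline: float = 100.0
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.chrom_lengths_bp) == 0 or any(l <= 0 for l in self.chrom_lengths_bp):
            raise ConfigError("chromosome lengths must be positive")
        if not math.isfinite(self.cm_per_mb) or self.cm_per_mb < 0:
            raise ConfigError("cm_per_mb must be finite and >= 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ConfigError("error_rate must lie in [0, 0.5)")
        if self.mean_depth < 0 or not math.isfinite(self.mean_depth):
            raise ConfigError("mean_depth must be finite and >= 0")
        if not (0.0 <= self.missing_extra <= 1.0):
            raise ConfigError("missing_extra must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_individuals < 1 or self.n_markers_per_chrom < 1:
            raise ConfigError("population and marker counts must be >= 1")
        for locus in self.distortion_loci:
            locus.validate()
            self._check_on_genome(locus.chrom, locus.pos_bp, "distortion locus")
        for q in self.qtls:
            self._check_on_genome(q.chrom, q.pos_bp, "QTL")

    def _check_on_genome(self, chrom: int, pos: int, what: str) -> None:
        if not (1 <= chrom <= len(self.chrom_lengths_bp)):
            raise ConfigError(f"{what} on unknown chromosome {chrom}")
        if not (1 <= pos <= self.chrom_lengths_bp[chrom - 1]):
            raise ConfigError(f"{what} position {pos} outside chromosome {chrom}")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths_bp))]


@dataclass
class TruthSet:
    """Ground truth of one simulated population.

    ``genotypes`` is individuals x markers with the number of
    male-parent (B) alleles (0 = AA, 1 = AB, 2 = BB).  ``crossovers``
    records every meiotic breakpoint (individual, chrom, gamete 0/1,
    pos_bp).  ``phenotypes`` holds ``id, trait, value`` rows and
    ``genetic_values`` the noise-free genetic component per individual.
    """

    config: SimConfig
    markers: pd.DataFrame
    genotypes: np.ndarray
    crossovers: pd.DataFrame
    individuals: list[str]
    phenotypes: pd.DataFrame | None = None
    genetic_values: np.ndarray | None = None

    def marker_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.markers["chrom"].to_numpy() == chrom)


def _origin_at(start: int, breaks: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Parental origin (0 = A, 1 = B) of a gamete at given positions."""
    parity = np.searchsorted(breaks, positions, side="left") % 2
    return (start + parity) % 2


def simulate_gamete(
    chrom_length_bp: int,
    cm_per_mb: float,
    rng: np.random.Generator,
    distortion_loci: Sequence[DistortionLocus] = (),
) -> tuple[int, np.ndarray]:
    """Draw one gamete for a chromosome.

    Returns ``(start_origin, breakpoints)``: the parental origin at the
    chromosome start (0 = female/A, 1 = male/B) and the sorted crossover
    positions in bp.  Crossover counts are Poisson with mean ``L/100``
    (``L`` in cM), positions uniform.  Gametic distortion loci are
    honoured by rejection sampling: a drawn gamete carrying allele A
    (resp. B) at the locus is kept with probability ``w_a`` (``w_b``),
    otherwise the whole gamete is redrawn.
    """
    if not math.isfinite(cm_per_mb) or cm_per_mb < 0:
        raise ConfigError("cm_per_mb must be finite and >= 0")
    length_cm = chrom_length_bp * cm_per_mb / 1e6
    mean_events = length_cm / 100.0
    gametic = [d for d in distortion_loci if d.stage == "gametic"]
    while True:
        n_xo = rng.poisson(mean_events) if mean_events > 0 else 0
        breaks = np.sort(rng.uniform(0, chrom_length_bp, size=n_xo))
        start = int(rng.integers(2))
        ok = True
        for locus in gametic:
            allele = _origin_at(start, breaks, np.array([locus.pos_bp]))[0]
            w = locus.w_a if allele == 0 else locus.w_b
            if rng.random() >= w:
                ok = False
                break
        if ok:
            return start, breaks


def _draw_marker_positions(length_bp: int, n: int, rng: np.random.Generator) -> np.ndarray:
    if n > length_bp:
        raise ConfigError("more markers requested than base pairs")
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length_bp + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


def simulate_f2_population(config: SimConfig) -> TruthSet:
    """Simulate an F2 population and return its ground truth.

    Each individual is built from two independent gametes per
    chromosome.  Zygotic distortion loci reject the gamete pair of the
    affected chromosome with probability ``1 - w_a**(2-g) * w_b**g`` and
    redraw it.  Phenotypes (and genetic values) are attached via
    :func:`simulate_phenotypes` using the config's QTLs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = config.chrom_names()

    marker_frames = []
    for name, length in zip(chrom_names, config.chrom_lengths_bp):
        pos = _draw_marker_positions(int(length), config.n_markers_per_chrom, rng)
        marker_frames.append(pd.DataFrame({"chrom": name, "pos": pos}))
    markers = pd.concat(marker_frames, ignore_index=True)

    per_chrom_dist: dict[int, list[DistortionLocus]] = {}
    for locus in config.distortion_loci:
        per_chrom_dist.setdefault(locus.chrom, []).append(locus)

    n_ind = config.n_individuals
    n_mark = len(markers)
    genotypes = np.empty((n_ind, n_mark), dtype=np.int8)
    xo_rows: list[tuple[int, str, int, float]] = []
    individuals = [f"F2_{i + 1:03d}" for i in range(n_ind)]

    offset = 0
    marker_pos_by_chrom = [
        markers.loc[markers["chrom"] == name, "pos"].to_numpy() for name in chrom_names
    ]
    for ci, (name, length) in enumerate(zip(chrom_names, config.chrom_lengths_bp)):
        positions = marker_pos_by_chrom[ci]
        loci = per_chrom_dist.get(ci + 1, [])
        zygotic = [d for d in loci if d.stage == "zygotic"]
        for i in range(n_ind):
            while True:
                gametes = [
                    simulate_gamete(int(length), config.cm_per_mb, rng, loci)
                    for _ in range(2)
                ]
                if not zygotic:
                    break
                accept = True
                for locus in zygotic:
                    g = sum(
                        int(_origin_at(s, b, np.array([locus.pos_bp]))[0])
                        for s, b in gametes
                    )
                    w = locus.w_a ** (2 - g) * locus.w_b ** g
                    if rng.random() >= w:
                        accept = False
                        break
                if accept:
                    break
            origin = sum(_origin_at(s, b, positions) for s, b in gametes)
            genotypes[i, offset : offset + len(positions)] = origin.astype(np.int8)
            for gi, (_, breaks) in enumerate(gametes):
                for bp in breaks:
                    xo_rows.append((i, name, gi, float(bp)))
        offset += len(positions)

    crossovers = pd.DataFrame(
        xo_rows, columns=["individual", "chrom", "gamete", "pos_bp"]
    )
    truth = TruthSet(
        config=config,
        markers=markers,
        genotypes=genotypes,
        crossovers=crossovers,
        individuals=individuals,
    )
    simulate_phenotypes(
        truth,
        config.qtls,
        baseline=config.baseline,
        noise_sd=config.noise_sd,
        rng=rng,
    )
    return truth


def simulate_observations(
    truth: TruthSet,
    mean_depth: float | None = None,
    error_rate: float | None = None,
    missing_extra: float | None = None,
    rng: np.random.Generator | None = None,
) -> ObservationMatrix:
    """Draw sequencing observations (parental-allele read counts).

    Depth per (individual, marker) is Poisson(``mean_depth``), then
    zeroed with probability ``missing_extra``.  Given depth ``d``, the
    count of reads supporting the male-parent allele is Binomial with
    success probability ``error_rate`` (true AA), 0.5 (AB) or
    ``1 - error_rate`` (BB).
    """
    cfg = truth.config
    lam = cfg.mean_depth if mean_depth is None else mean_depth
    eps = cfg.error_rate if error_rate is None else error_rate
    drop = cfg.missing_extra if missing_extra is None else missing_extra
    if lam < 0 or not math.isfinite(lam):
        raise ConfigError("mean depth must be finite and >= 0")
    if not (0.0 <= eps < 0.5):
        raise ConfigError("error rate must lie in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    depth = rng.poisson(lam, size=truth.genotypes.shape)
    if drop > 0:
        depth = np.where(rng.random(depth.shape) < drop, 0, depth)
    p_b = np.choose(truth.genotypes, [eps, 0.5, 1.0 - eps])
    n_b = rng.binomial(depth, p_b)
    n_a = depth - n_b
    return ObservationMatrix(
        individuals=list(truth.individuals),
        markers=truth.markers.copy(),
        n_a=n_a.astype(np.int32),
        n_b=n_b.astype(np.int32),
    )


def simulate_phenotypes(
    truth: TruthSet,
    qtls: Sequence[QTL],
    baseline: float | None = None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach phenotypes ``y = mu + sum(a x + d z) + N(0, sigma^2)``.

    Each QTL acts through the simulated marker nearest its position.
    Updates ``truth.phenotypes`` / ``truth.genetic_values`` and returns
    the phenotype table (``id, trait, value``).
    """
    cfg = truth.config
    mu = cfg.baseline if baseline is None else baseline
    sigma = cfg.noise_sd if noise_sd is None else noise_sd
    if sigma < 0:
        raise ConfigError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)

    genetic = np.zeros(len(truth.individuals))
    chrom_names = cfg.chrom_names()
    for q in qtls:
        cfg._check_on_genome(q.chrom, q.pos_bp, "QTL")
        idx = truth.marker_index(chrom_names[q.chrom - 1])
        if idx.size == 0:
            raise ConfigError(f"no markers on chromosome {q.chrom}")
        pos = truth.markers["pos"].to_numpy()[idx]
        nearest = idx[np.argmin(np.abs(pos - q.pos_bp))]
        g = truth.genotypes[:, nearest]
        x = 1.0 - g  # +1 AA, 0 AB, -1 BB
        z = (g == AB).astype(float)
        genetic += q.additive * x + q.dominance * z

    noise = rng.normal(0.0, sigma, size=len(truth.individuals)) if sigma > 0 else 0.0
    values = mu + genetic + noise
    table = pd.DataFrame(
        {"id": truth.individuals, "trait": cfg.trait, "value": values}
    )
    truth.phenotypes = table
    truth.genetic_values = genetic
    return table


def additive_effect_for_pve(pve: float, noise_sd: float) -> float:
    """Additive effect giving a lone additive QTL the target PVE.

    In an infinite F2 an additive effect ``a`` contributes genetic
    variance ``a^2 / 2``, so ``a = sigma * sqrt(2 pve / (1 - pve))``.
    """
    if not (0.0 < pve < 1.0):
        raise ConfigError("pve must lie in (0, 1)")
    return noise_sd * math.sqrt(2.0 * pve / (1.0 - pve))
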