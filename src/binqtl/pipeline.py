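"""End-to-end orchestration of the mapping pipeline.

Stages: (optional) simulate -> informative-SNP selection -> HMM bin
map -> linkage map -> segregation-distortion scan -> QTL scan (with
permutation thresholds) -> graded-pool mapping -> summary report.
Artifacts are plain-text tables with provenance headers (package
version, seed, config hash), so identical config + seed reproduces
byte-identical outputs.  Requesting a stage before the stage it
depends on raises :class:`~binqtl.core.DependencyError` naming the
missing artifact.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DependencyError, InputError
from . import io as bio
from .simulate import QTL, DistortionLocus, SimConfig, simulate_f2_population, simulate_observations
from .variants import ObservationMatrix, encode_observations, select_informative_snps
from .binmap import HMMParams, bin_summary, build_bins, call_crossovers, decode_population
from .linkmap import build_linkage_map, map_summary
from .sdr import detect_sdrs, distortion_table
from .qtl import cim_covariates, permutation_threshold, qtl_table, scan_lod
from .gps import build_pools, pool_allele_counts, ridit_scan, window_scan
from .report import population_averages

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_STAGES = ("simulate", "filter", "binmap", "map", "sdr", "qtl", "gps", "report")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    out_dir: str = "binqtl_out"
    vcf: str | None = None
    phenotypes: str | None = None
    parent_female: str = "P1"
    parent_male: str = "P2"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    simulate: dict = field(default_factory=dict)
    hmm: dict = field(default_factory=dict)
    missing_threshold: float = 0.2
    sdr_alpha: float = 0.01
    trait: str | None = None
    n_perm: int = 1000
    qtl_alpha: float = 0.05
    n_cov: int = 3
    window_cm: float = 10.0
    n_pools: int = 4
    window_kb: int = 400
    step_kb: int = 100
    min_variants: int = 5
    gps_unit: str = "alleles"
    gps_agg: str = "mean"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    raw = dict(cfg.simulate)
    raw.setdefault("seed", cfg.seed)
    if "distortion_loci" in raw:
        raw["distortion_loci"] = [DistortionLocus(**d) for d in raw["distortion_loci"]]
    if "qtls" in raw:
        raw["qtls"] = [QTL(**q) for q in raw["qtls"]]
    return SimConfig(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the requested stages; returns artifact paths and key objects."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = cfg.as_dict()
    artifacts: dict = {"out_dir": str(out)}
    stages = tuple(cfg.stages)
    t0 = time.time()

    vcf_path = cfg.vcf
    pheno_path = cfg.phenotypes

    if "simulate" in stages:
        sim_cfg = _sim_config(cfg)
        truth = simulate_f2_population(sim_cfg)
        obs_true = simulate_observations(truth)
        vcf_path = str(out / "simulated.vcf")
        pheno_path = str(out / "phenotypes.csv")
        bio.write_vcf(truth, obs_true, vcf_path)
        bio.write_phenotypes_csv(truth.phenotypes, pheno_path)
        bio.write_truth_json(truth, out / "truth.json")
        artifacts["truth"] = truth
        logger.info("simulate: %d individuals, %d markers [%.1fs]",
                    len(truth.individuals), len(truth.markers), time.time() - t0)

    markers = None
    obs: ObservationMatrix | None = None
    if "filter" in stages:
        if vcf_path is None:
            raise DependencyError("filter stage needs a VCF (run simulate or set vcf)")
        if not Path(vcf_path).exists():
            raise InputError(f"VCF not found: {vcf_path}")
        markers = select_informative_snps(vcf_path, cfg.parent_female, cfg.parent_male)
        obs = encode_observations(vcf_path, markers, cfg.parent_female, cfg.parent_male)
        bio.write_table(markers, out / "markers.tsv", sep="\t", seed=cfg.seed, config=meta)
        artifacts["markers"] = markers
        artifacts["observations"] = obs

    binmat = None
    if "binmap" in stages:
        if obs is None:
            raise DependencyError("binmap stage needs observations (run filter first)")
        params = HMMParams(**cfg.hmm)
        blocks = decode_population(obs, params)
        crossovers = call_crossovers(blocks)
        binmat = build_bins(blocks, obs.markers, obs.individuals, params.min_bin_bp)
        bio.write_table(binmat.to_frame(), out / "binmap.tsv", sep="\t", seed=cfg.seed, config=meta)
        bio.write_bed(
            crossovers.rename(columns={"left_bp": "start", "right_bp": "end"})[
                ["chrom", "start", "end", "individual"]
            ],
            out / "crossovers.bed",
        )
        events = crossovers.groupby("individual").size().rename("n_events").reset_index()
        bio.write_table(events, out / "events_per_individual.csv", seed=cfg.seed, config=meta)
        bio.write_table(bin_summary(binmat), out / "bin_summary.csv", seed=cfg.seed, config=meta)
        artifacts["binmat"] = binmat
        artifacts["crossovers"] = crossovers

    map_df = None
    if "map" in stages:
        if binmat is None:
            raise DependencyError("map stage needs a bin map (run binmap first)")
        map_df = build_linkage_map(binmat, missing_threshold=cfg.missing_threshold)
        bio.write_table(map_df, out / "linkage_map.tsv", sep="\t", seed=cfg.seed, config=meta)
        bio.write_table(map_summary(map_df), out / "map_summary.csv", seed=cfg.seed, config=meta)
        artifacts["map"] = map_df

    if "sdr" in stages:
        if binmat is None:
            raise DependencyError("sdr stage needs a bin map (run binmap first)")
        table = distortion_table(binmat, alpha=cfg.sdr_alpha)
        regions = detect_sdrs(table, alpha=cfg.sdr_alpha)
        bio.write_table(table, out / "sdr_bins.csv", seed=cfg.seed, config=meta)
        if len(regions):
            bio.write_bed(regions[["chrom", "start", "end", "direction"]], out / "sdr_regions.bed")
        bio.write_table(regions, out / "sdr_regions.csv", seed=cfg.seed, config=meta)
        artifacts["sdr"] = regions

    phenotypes = None
    if pheno_path is not None and ("qtl" in stages or "gps" in stages):
        if not Path(pheno_path).exists():
            raise InputError(f"phenotype file not found: {pheno_path}")
        phenotypes = bio.read_phenotypes_csv(pheno_path)

    if "qtl" in stages:
        if binmat is None or map_df is None:
            raise DependencyError("qtl stage needs binmap and map stages")
        if phenotypes is None:
            raise DependencyError("qtl stage needs a phenotype table")
        traits = [cfg.trait] if cfg.trait else sorted(phenotypes["trait"].unique())
        pos_cm = _bin_positions_cm(binmat, map_df)
        chroms = binmat.bins["chrom"].to_numpy()
        all_qtls = []
        for trait in traits:
            y = _trait_vector(phenotypes, trait, binmat.individuals)
            covs = cim_covariates(
                y, binmat.genotypes, pos_cm=pos_cm, chroms=chroms,
                n_cov=cfg.n_cov, window_cm=cfg.window_cm,
            )
            scan = scan_lod(
                y, binmat.genotypes, covs, pos_cm=pos_cm, chroms=chroms,
                window_cm=cfg.window_cm,
            )
            scan.insert(0, "trait", trait)
            scan.insert(1, "chrom", chroms)
            scan.insert(2, "bin_id", binmat.bins["bin_id"])
            scan.insert(3, "pos_cm", pos_cm)
            thr = permutation_threshold(
                y, binmat.genotypes, n_perm=cfg.n_perm, alpha=cfg.qtl_alpha,
                seed=cfg.seed, covariate_bins=covs, pos_cm=pos_cm, chroms=chroms,
                window_cm=cfg.window_cm,
            )
            qtls = qtl_table(trait, y, binmat.genotypes, binmat.bins,
                             scan["lod"].to_numpy(), thr["threshold"])
            qtls["lod_threshold"] = thr["threshold"]
            bio.write_table(scan, out / f"scan_{trait}.csv", seed=cfg.seed, config=meta)
            all_qtls.append(qtls)
        qtl_df = pd.concat(all_qtls, ignore_index=True) if all_qtls else pd.DataFrame()
        bio.write_table(qtl_df, out / "qtl_table.csv", seed=cfg.seed, config=meta)
        artifacts["qtl"] = qtl_df

    if "gps" in stages:
        if obs is None:
            raise DependencyError("gps stage needs observations (run filter first)")
        if phenotypes is None:
            raise DependencyError("gps stage needs a phenotype table")
        traits = [cfg.trait] if cfg.trait else sorted(phenotypes["trait"].unique())
        candidates = []
        for trait in traits:
            sub = phenotypes[phenotypes["trait"] == trait][["id", "value"]]
            pools = build_pools(sub, k=cfg.n_pools)
            pool_rows = [
                {"pool": j + 1, "n": len(m), "value_min": r[0], "value_max": r[1],
                 "members": ";".join(m)}
                for j, (m, r) in enumerate(zip(pools.members, pools.ranges))
            ]
            bio.write_table(pd.DataFrame(pool_rows), out / f"pools_{trait}.csv",
                            seed=cfg.seed, config=meta)
            pooled = pool_allele_counts(obs, pools, unit=cfg.gps_unit)
            res = ridit_scan(pooled)
            bio.write_table(res, out / f"ridit_{trait}.csv", seed=cfg.seed, config=meta)
            windows, candidate = window_scan(
                res, window_bp=cfg.window_kb * 1000, step_bp=cfg.step_kb * 1000,
                min_variants=cfg.min_variants, agg=cfg.gps_agg,
            )
            if len(windows):
                bg = windows.copy()
                bg["start"] = bg["start"] - 1
                bg[["chrom", "start", "end", "score"]].to_csv(
                    out / f"windows_{trait}.bedgraph", sep="\t", index=False, header=False
                )
            if candidate is not None:
                candidate["trait"] = trait
                candidates.append(candidate)
        cand_df = pd.DataFrame(candidates)
        bio.write_table(cand_df, out / "gps_candidates.csv", seed=cfg.seed, config=meta)
        if len(cand_df):
            bio.write_bed(cand_df[["chrom", "start", "end", "trait"]],
                          out / "gps_candidates.bed")
        artifacts["gps"] = cand_df

    if "report" in stages:
        if map_df is None or binmat is None:
            raise DependencyError("report stage needs binmap and map stages")
        summary = map_summary(map_df)
        crossovers = artifacts.get("crossovers")
        n_events = len(crossovers) if crossovers is not None else 0
        covered_mb = float(binmat.lengths_bp().sum() / 1e6)
        total_bins = binmat.n_bins
        averages = population_averages(
            n_events, len(binmat.individuals), covered_mb, total_bins
        )
        lines = summary.to_string(index=False).splitlines()
        lines.append("")
        lines.append(f"total recombination events: {n_events}")
        lines.append(
            "mean events per individual: "
            f"{averages['mean_events_per_individual']:.1f}"
        )
        lines.append(f"covered genome: {covered_mb:.1f} Mb in {total_bins} bins")
        if "mean_bin_kb" in averages:
            lines.append(f"mean bin size: {averages['mean_bin_kb']:.1f} Kb")
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        bio.write_table(summary, out / "report_summary.csv", seed=cfg.seed, config=meta)
        artifacts["report"] = averages

    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return artifacts


def _bin_positions_cm(binmat, map_df: pd.DataFrame) -> np.ndarray:
    pos = pd.Series(
        map_df["pos_cm"].to_numpy(), index=map_df["bin_id"]
    ).reindex(binmat.bins["bin_id"])
    # bins filtered from the map get an interpolated/neighbour position
    return pos.ffill().bfill().fillna(0.0).to_numpy()


def _trait_vector(phenotypes: pd.DataFrame, trait: str, individuals: list[str]) -> np.ndarray:
    sub = phenotypes[phenotypes["trait"] == trait].set_index("id")["value"]
    return sub.reindex(individuals).to_numpy(dtype=float)
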