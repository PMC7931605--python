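"""Text-format readers/writers and provenance headers.

The simulator exports a minimal VCF 4.2 (GT:AD for two parents plus
progeny, INFO/MQ), a phenotype CSV and a ground-truth JSON; downstream
stages exchange plain TSV/CSV/BED.  Internal coordinates are 1-based
inclusive; BED and BedGraph exports are 0-based half-open.

Every tabular output can carry a provenance header (``# key: value``
comment lines with package version, seed and a config hash) so a run
is reproducible from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GENOTYPE_LETTER

__all__ = [
    "write_vcf",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_truth_json",
    "provenance_lines",
    "write_table",
    "write_bed",
]

_BASES = np.array(list("ACGT"))


def provenance_lines(seed: int | None = None, config: dict | None = None) -> list[str]:
    from . import __version__

    lines = [f"# binqtl_version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_hash: {digest}")
        for key, value in sorted(config.items()):
            lines.append(f"# param {key}: {value}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sep: str = ",",
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a DataFrame with an optional provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write chrom/start/end (1-based inclusive) rows as 0-based half-open BED."""
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False, header=False)


def _naive_gt(n_ref: int, n_alt: int) -> str:
    if n_ref == 0 and n_alt == 0:
        return "./."
    if n_ref > 0 and n_alt > 0:
        return "0/1"
    return "0/0" if n_ref > 0 else "1/1"


def write_vcf(
    truth,
    obs,
    path: str | Path,
    female: str = "P1",
    male: str = "P2",
    parent_depth: int = 30,
    qual: float = 60.0,
    mq: float = 60.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Write a minimal VCF 4.2 for two parents plus the progeny.

    REF/ALT bases are drawn (seeded from the simulation config) with
    the female allele randomly assigned to REF or ALT, so readers must
    handle both orientations.  Parents are written homozygous at full
    ``parent_depth``; progeny GT is a naive call from the simulated
    allele depths and AD carries the exact counts.
    """
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 7)
    markers = obs.markers
    n_mark = len(markers)
    base_f = _BASES[rng.integers(0, 4, size=n_mark)]
    shift = rng.integers(1, 4, size=n_mark)
    base_m = _BASES[(np.searchsorted(_BASES, base_f) + shift) % 4]
    female_is_ref = rng.random(n_mark) < 0.5

    chrom_lengths = dict(
        zip(truth.config.chrom_names(), truth.config.chrom_lengths_bp)
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=binqtl-simulate\n")
        for name, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        samples = [female, male] + list(obs.individuals)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(n_mark):
            if female_is_ref[j]:
                ref, alt = base_f[j], base_m[j]
                gt_f, gt_m = "0/0", "1/1"
                ad_f = f"{parent_depth},0"
                ad_m = f"0,{parent_depth}"
            else:
                ref, alt = base_m[j], base_f[j]
                gt_f, gt_m = "1/1", "0/0"
                ad_f = f"0,{parent_depth}"
                ad_m = f"{parent_depth},0"
            fields = [
                str(markers["chrom"].iat[j]),
                str(int(markers["pos"].iat[j])),
                ".",
                ref,
                alt,
                f"{qual:g}",
                "PASS",
                f"MQ={mq:g}",
                "GT:AD",
                f"{gt_f}:{ad_f}",
                f"{gt_m}:{ad_m}",
            ]
            for i in range(obs.n_individuals):
                na, nb = int(obs.n_a[i, j]), int(obs.n_b[i, j])
                n_ref, n_alt = (na, nb) if female_is_ref[j] else (nb, na)
                fields.append(f"{_naive_gt(n_ref, n_alt)}:{n_ref},{n_alt}")
            fh.write("\t".join(fields) + "\n")


def write_phenotypes_csv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"id", "trait", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return df


def write_truth_json(truth, path: str | Path) -> None:
    """Serialise simulator ground truth (genotypes as A/H/B letters)."""
    letters = np.vectorize(GENOTYPE_LETTER.get)(truth.genotypes)
    payload = {
        "individuals": list(truth.individuals),
        "markers": truth.markers.to_dict(orient="list"),
        "genotypes": ["".join(row) for row in letters],
        "crossovers": truth.crossovers.to_dict(orient="list"),
        "genetic_values": (
            list(map(float, truth.genetic_values))
            if truth.genetic_values is not None
            else None
        ),
        "seed": truth.config.seed,
    }
    Path(path).write_text(json.dumps(payload))
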