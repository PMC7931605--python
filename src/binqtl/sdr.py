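"""Segregation-distortion scans at the zygotic and gametic stages.

Every bin of an F2 bin map is tested against the Mendelian
expectations:

* **zygotic** — genotype counts (AA, AB, BB) against 1:2:1, Pearson
  chi-square with 2 degrees of freedom;
* **gametic** — allele counts ``a = 2 n_AA + n_AB`` and
  ``b = 2 n_BB + n_AB`` against 1:1 on ``2n`` alleles, 1 degree of
  freedom.

The gametic test treats the ``2n`` alleles as independent, which
overstates significance when the distortion is truly zygotic; the two
tests together nevertheless separate the stages, because a pure
heterozygote deficit leaves the allele ratio balanced.  No continuity
correction and no multiple-testing correction are applied (a raw
``P = 0.01`` line is the conventional display threshold; a Bonferroni
column is emitted for reference).  Runs of consecutive significant
bins form segregation-distortion regions (SDRs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import AA, AB, BB, UNKNOWN
from .binmap import BinGenotypeMatrix

__all__ = [
    "zygotic_chi2",
    "gametic_chi2",
    "distortion_table",
    "detect_sdrs",
]


def zygotic_chi2(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson chi-square of genotype counts against 1:2:1 (df = 2)."""
    n = n_aa + n_ab + n_bb
    if n <= 0:
        return float("nan"), float("nan")
    expected = np.array([n / 4.0, n / 2.0, n / 4.0])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=2))


def gametic_chi2(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson chi-square of allele counts against 1:1 (df = 1)."""
    n = n_aa + n_ab + n_bb
    if n <= 0:
        return float("nan"), float("nan")
    a = 2 * n_aa + n_ab
    b = 2 * n_bb + n_ab
    expected = (a + b) / 2.0
    chi2 = float((a - expected) ** 2 / expected + (b - expected) ** 2 / expected)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def distortion_table(binmat: BinGenotypeMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Per-bin distortion statistics.

    UNKNOWN genotypes are excluded from the counts.  ``direction`` is
    the over-represented parental allele ('female' when the
    female-parent allele frequency exceeds 0.5, 'male' below, 'none' at
    exactly 0.5 or for empty bins).  ``signed_logp_zyg`` is
    ``-log10(p)`` for plotting the zygotic track above the axis and
    ``signed_logp_gam`` is ``+log10(p)`` for the gametic track below
    it.  A Bonferroni-adjusted zygotic p-value column is included for
    reference.
    """
    rows = []
    n_tests = max(binmat.n_bins, 1)
    for k in range(binmat.n_bins):
        g = binmat.genotypes[k]
        n_aa = int((g == AA).sum())
        n_ab = int((g == AB).sum())
        n_bb = int((g == BB).sum())
        n = n_aa + n_ab + n_bb
        chi2_z, p_z = zygotic_chi2(n_aa, n_ab, n_bb)
        chi2_g, p_g = gametic_chi2(n_aa, n_ab, n_bb)
        if n == 0:
            direction = "none"
        else:
            freq_a = (2 * n_aa + n_ab) / (2.0 * n)
            direction = "female" if freq_a > 0.5 else ("male" if freq_a < 0.5 else "none")
        rows.append(
            {
                "bin_id": binmat.bins["bin_id"].iat[k],
                "chrom": binmat.bins["chrom"].iat[k],
                "start": int(binmat.bins["start"].iat[k]),
                "end": int(binmat.bins["end"].iat[k]),
                "n_aa": n_aa,
                "n_ab": n_ab,
                "n_bb": n_bb,
                "chi2_zyg": chi2_z,
                "p_zyg": p_z,
                "chi2_gam": chi2_g,
                "p_gam": p_g,
                "p_zyg_bonferroni": min(p_z * n_tests, 1.0) if np.isfinite(p_z) else p_z,
                "direction": direction,
                "signed_logp_zyg": -np.log10(p_z) if p_z > 0 else np.inf,
                "signed_logp_gam": np.log10(p_g) if p_g > 0 else -np.inf,
            }
        )
    return pd.DataFrame(rows)


def detect_sdrs(table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Maximal runs of consecutive significant bins (either stage).

    Bins are taken in map order within each chromosome; a bin is
    significant when ``p_zyg < alpha`` or ``p_gam < alpha`` (empty bins
    never are).  Single-bin regions are allowed.  Each region reports
    its span, the significant stage(s) and the modal bin direction.
    """
    regions = []
    for chrom, grp in table.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        sig = (
            grp["p_zyg"].fillna(1.0).lt(alpha) | grp["p_gam"].fillna(1.0).lt(alpha)
        ).to_numpy()
        k = 0
        while k < len(grp):
            if not sig[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(grp) and sig[j + 1]:
                j += 1
            run = grp.iloc[k : j + 1]
            stages = []
            if (run["p_zyg"].fillna(1.0) < alpha).any():
                stages.append("zygotic")
            if (run["p_gam"].fillna(1.0) < alpha).any():
                stages.append("gametic")
            directions = run["direction"][run["direction"] != "none"]
            direction = directions.mode().iat[0] if len(directions) else "none"
            regions.append(
                {
                    "chrom": chrom,
                    "first_bin": run["bin_id"].iat[0],
                    "last_bin": run["bin_id"].iat[-1],
                    "n_bins": len(run),
                    "start": int(run["start"].iat[0]),
                    "end": int(run["end"].iat[-1]),
                    "span_bp": int(run["end"].iat[-1] - run["start"].iat[0] + 1),
                    "stages": "+".join(stages),
                    "direction": direction,
                }
            )
            k = j + 1
    return pd.DataFrame(
        regions,
        columns=[
            "chrom",
            "first_bin",
            "last_bin",
            "n_bins",
            "start",
            "end",
            "span_bp",
            "stages",
            "direction",
        ],
    )
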