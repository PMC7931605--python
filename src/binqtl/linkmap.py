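"""Recombination-fraction estimation and Kosambi linkage maps.

Adjacent-bin recombination fractions are estimated by maximum
likelihood for codominant F2 markers.  The only non-trivial genotype
class is the double heterozygote, which can arise from two parental or
two recombinant gametes; an EM iteration splits that class by its
expected recombinant-gamete content.  Distances use the Kosambi map
function ``d = 25 ln((1+2r)/(1-2r))`` cM, whose inverse is
``r = 0.5 tanh(0.02 d)``.

De novo marker ordering is deliberately not performed: bins inherit the
reference physical order, which resequencing-based maps themselves use
to validate their linkage ordering.  A diagnostic flags adjacent bins
with ``r > 0.3`` as potential ordering conflicts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UNKNOWN, ConfigError
from .binmap import BinGenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RFEstimate",
    "estimate_rf_f2",
    "f2_joint_probs",
    "f2_pair_loglik",
    "kosambi_cm",
    "kosambi_r",
    "build_linkage_map",
    "map_summary",
    "retabulate",
]

# gamete haplotypes over two loci: allele at locus 1, allele at locus 2,
# and whether the gamete is recombinant (0 = A, 1 = B)
_GAMETES = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)]


@dataclass(frozen=True)
class RFEstimate:
    """Pairwise recombination fraction estimate."""

    r_hat: float
    loglik: float
    n_informative: int
    ok: bool = True


def f2_joint_probs(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities of two F2 loci at fraction ``r``.

    Rows/columns index the number of B alleles (0, 1, 2) at each locus.
    Built from two independent gametes with parental haplotype
    probability ``(1-r)/2`` and recombinant probability ``r/2``.
    """
    p, q = (1.0 - r) / 2.0, r / 2.0
    w = [p, p, q, q]
    out = np.zeros((3, 3))
    for i, (a1, b1, _k1) in enumerate(_GAMETES):
        for j, (a2, b2, _k2) in enumerate(_GAMETES):
            out[a1 + a2, b1 + b2] += w[i] * w[j]
    return out


def _expected_recombinants(r: float) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and expected recombinant gametes per class."""
    p, q = (1.0 - r) / 2.0, r / 2.0
    w = [p, p, q, q]
    prob = np.zeros((3, 3))
    rec = np.zeros((3, 3))
    for i, (a1, b1, k1) in enumerate(_GAMETES):
        for j, (a2, b2, k2) in enumerate(_GAMETES):
            pr = w[i] * w[j]
            prob[a1 + a2, b1 + b2] += pr
            rec[a1 + a2, b1 + b2] += pr * (k1 + k2)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_rec = np.where(prob > 0, rec / prob, 0.0)
    return prob, e_rec


def f2_pair_loglik(table: np.ndarray, r: float) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table at fraction ``r``."""
    probs = f2_joint_probs(r)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = np.asarray(table) > 0
    return float((np.asarray(table)[mask] * logp[mask]).sum())


def estimate_rf_f2(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RFEstimate:
    """ML recombination fraction between two codominant F2 marker columns.

    UNKNOWN genotypes are excluded pairwise.  EM starts at ``r = 0.25``
    and iterates the expected recombinant-gamete count over the 3x3
    genotype table; the estimate is clamped to [0, 0.5].  With fewer
    than two informative individuals the estimate is flagged undefined.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ConfigError("genotype columns must have equal length")
    mask = (g1 != UNKNOWN) & (g2 != UNKNOWN)
    n = int(mask.sum())
    if n < 2:
        return RFEstimate(r_hat=float("nan"), loglik=float("nan"), n_informative=n, ok=False)
    table = np.zeros((3, 3))
    np.add.at(table, (g1[mask], g2[mask]), 1.0)

    r = 0.25
    for _ in range(max_iter):
        _, e_rec = _expected_recombinants(r)
        r_new = float((table * e_rec).sum() / (2.0 * n))
        r_new = min(max(r_new, 1e-12), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    r = min(max(r, 0.0), 0.5)
    return RFEstimate(r_hat=r, loglik=f2_pair_loglik(table, r), n_informative=n)


def kosambi_cm(r: float) -> float:
    """Kosambi map distance (cM) for recombination fraction ``r``.

    ``r >= 0.5`` maps to infinity (unlinked).
    """
    if r < 0:
        raise ConfigError("recombination fraction must be >= 0")
    if r >= 0.5:
        return math.inf
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(d_cm: float) -> float:
    """Inverse Kosambi: recombination fraction at map distance ``d_cm``."""
    if d_cm < 0:
        raise ConfigError("map distance must be >= 0")
    return 0.5 * math.tanh(0.02 * d_cm)


def build_linkage_map(
    binmat: BinGenotypeMatrix,
    missing_threshold: float = 0.2,
    conflict_r: float = 0.3,
) -> pd.DataFrame:
    """Physical-order Kosambi linkage map from a bin genotype matrix.

    Bins with more than ``missing_threshold`` UNKNOWN genotypes are
    excluded.  Within each chromosome, adjacent-bin recombination
    fractions become Kosambi cM increments accumulated along physical
    order.  Returns columns ``chrom, bin_id, start, end, r_prev,
    cm_prev, pos_cm, order_conflict``.
    """
    missing_frac = (binmat.genotypes == UNKNOWN).mean(axis=1)
    keep = missing_frac <= missing_threshold
    rows = []
    for chrom in dict.fromkeys(binmat.bins["chrom"]):
        sel = np.flatnonzero((binmat.bins["chrom"] == chrom).to_numpy() & keep)
        if sel.size == 0:
            logger.warning("chromosome %s: all bins filtered; empty group", chrom)
            continue
        pos_cm = 0.0
        prev = None
        for b in sel:
            if prev is None:
                r_prev, cm_prev, conflict = float("nan"), 0.0, False
            else:
                est = estimate_rf_f2(binmat.genotypes[prev], binmat.genotypes[b])
                r_prev = est.r_hat if est.ok else 0.5
                cm_prev = kosambi_cm(min(r_prev, 0.499999)) if est.ok else float("nan")
                conflict = bool(est.ok and r_prev > conflict_r)
                pos_cm += cm_prev if math.isfinite(cm_prev) else 0.0
            rows.append(
                {
                    "chrom": chrom,
                    "bin_id": binmat.bins["bin_id"].iat[b],
                    "start": int(binmat.bins["start"].iat[b]),
                    "end": int(binmat.bins["end"].iat[b]),
                    "r_prev": r_prev,
                    "cm_prev": cm_prev,
                    "pos_cm": pos_cm,
                    "order_conflict": conflict,
                }
            )
            prev = b
    return pd.DataFrame(rows)


def retabulate(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Append a Total row to a per-chromosome (n_bins, length_cm) table."""
    out = per_chrom.copy().reset_index(drop=True)
    total = {"chrom": "Total"}
    for col in out.columns:
        if col == "chrom":
            continue
        total[col] = out[col].sum()
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def map_summary(map_df: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome bin counts and genetic lengths with a Total row."""
    rows = []
    for chrom, grp in map_df.groupby("chrom", sort=False):
        rows.append(
            {
                "chrom": chrom,
                "n_bins": len(grp),
                "length_cm": float(grp["pos_cm"].max()),
            }
        )
    return retabulate(pd.DataFrame(rows))
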