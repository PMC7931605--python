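"""LOD-based QTL scans on a bin map with permutation thresholds.

Because a bin map has no within-bin marker information, bins are the
scan grid and the model is a Haley–Knott-style regression on genotype
codes.  At each bin the phenotype is fitted as::

    y = mu + a * x + d * z (+ covariates)      x in {+1, 0, -1}, z = [het]

and compared with the covariate-only null on the same individuals:

    LOD = (n / 2) * log10(RSS0 / RSS1)

Composite interval mapping adds forward-selected background bins as
covariates, excluding any covariate within a cM window of the tested
bin.  Genome-wide significance comes from permuting phenotypes against
whole genotype rows (which preserves the genotype correlation
structure) and taking the empirical ``1 - alpha`` quantile of the
per-permutation maximum LOD.  Declared QTLs are re-fitted jointly to
estimate effects and the percentage of phenotypic variance explained
(PVE); the support interval of a peak is the peak bin plus its two
flanking bins, and overlapping same-trait intervals merge into one
QTL.

Individuals with UNKNOWN genotype at a tested bin (or at an active
covariate) are dropped at that bin only (pairwise-complete scanning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AB, UNKNOWN, ConfigError

__all__ = [
    "genotype_codes",
    "codes_matrix",
    "scan_lod",
    "cim_covariates",
    "permutation_threshold",
    "fit_qtl",
    "call_qtl_peaks",
    "qtl_table",
]

_SVD_TOL = 1e-10


def genotype_codes(genotype: int) -> tuple[float, float] | None:
    """F2 regression codes (x, z) for one genotype; None for UNKNOWN."""
    if genotype == UNKNOWN:
        return None
    if genotype not in (0, 1, 2):
        raise ConfigError(f"invalid genotype code {genotype}")
    return 1.0 - genotype, 1.0 if genotype == AB else 0.0


def codes_matrix(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised codes: additive x, dominance z, and a validity mask."""
    geno = np.asarray(geno)
    mask = geno != UNKNOWN
    x = np.where(mask, 1.0 - geno, 0.0)
    z = np.where(mask, (geno == AB).astype(float), 0.0)
    return x, z, mask


def _ortho_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-robust, via SVD)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0:
        return u[:, :0]
    rank = int((s > _SVD_TOL * s[0]).sum())
    return u[:, :rank]


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y regressed on X."""
    U = _ortho_basis(X)
    total = (Y * Y).sum(axis=0)
    fitted = (U.T @ Y) ** 2
    return np.maximum(total - fitted.sum(axis=0), 0.0)


def _active_covariates(
    b: int,
    covariate_bins: tuple[int, ...],
    pos_cm: np.ndarray | None,
    chroms: np.ndarray | None,
    window_cm: float,
) -> tuple[int, ...]:
    if not covariate_bins:
        return ()
    if pos_cm is None or chroms is None:
        return tuple(c for c in covariate_bins if c != b)
    active = []
    for c in covariate_bins:
        if c == b:
            continue
        if chroms[c] == chroms[b] and abs(pos_cm[c] - pos_cm[b]) <= window_cm:
            continue
        active.append(c)
    return tuple(active)


def scan_lod(
    y: np.ndarray,
    geno: np.ndarray,
    covariate_bins: tuple[int, ...] = (),
    pos_cm: np.ndarray | None = None,
    chroms: np.ndarray | None = None,
    window_cm: float = 10.0,
) -> pd.DataFrame:
    """Single-trait LOD scan over all bins.

    ``geno`` is bins x individuals.  Returns per-bin ``lod``, additive
    effect ``a``, dominance effect ``d`` and the informative count
    ``n``.  With ``covariate_bins`` this is a composite scan: covariate
    bins within ``window_cm`` of the tested bin are excluded from the
    model at that bin.
    """
    y = np.asarray(y, dtype=float)
    geno = np.asarray(geno)
    n_bins = geno.shape[0]
    if y.shape[0] != geno.shape[1]:
        raise ConfigError("phenotype length must match individuals")
    x_all, z_all, mask_all = codes_matrix(geno)

    rows = []
    for b in range(n_bins):
        active = _active_covariates(b, covariate_bins, pos_cm, chroms, window_cm)
        mask = mask_all[b] & np.isfinite(y)
        for c in active:
            mask &= mask_all[c]
        n = int(mask.sum())
        if n < 10:
            rows.append({"lod": 0.0, "a": np.nan, "d": np.nan, "n": n})
            continue
        ym = y[mask]
        cov_cols = [np.ones(n)]
        for c in active:
            cov_cols += [x_all[c, mask], z_all[c, mask]]
        X0 = np.column_stack(cov_cols)
        X1 = np.column_stack(cov_cols + [x_all[b, mask], z_all[b, mask]])
        rss0 = _rss(X0, ym[:, None])[0]
        rss1 = _rss(X1, ym[:, None])[0]
        tiny = 1e-12 * max(1.0, float(ym @ ym))
        if rss0 <= tiny:  # degenerate null fit (e.g. constant phenotype)
            lod = 0.0
        elif rss1 <= tiny:
            lod = float("inf")
        else:
            lod = max((n / 2.0) * math.log10(rss0 / rss1), 0.0)
        beta, *_ = np.linalg.lstsq(X1, ym, rcond=None)
        rows.append({"lod": lod, "a": float(beta[-2]), "d": float(beta[-1]), "n": n})
    return pd.DataFrame(rows)


def cim_covariates(
    y: np.ndarray,
    geno: np.ndarray,
    pos_cm: np.ndarray | None = None,
    chroms: np.ndarray | None = None,
    n_cov: int = 3,
    window_cm: float = 10.0,
) -> tuple[int, ...]:
    """Forward-select up to ``n_cov`` background covariate bins.

    Repeatedly scans with the covariates selected so far and adds the
    genome-wide peak bin, skipping bins within ``window_cm`` of an
    already-selected covariate.  With ``n_cov = 0`` the composite scan
    reduces to the simple scan.
    """
    selected: list[int] = []
    for _ in range(n_cov):
        scan = scan_lod(
            y, geno, tuple(selected), pos_cm=pos_cm, chroms=chroms, window_cm=window_cm
        )
        lod = scan["lod"].to_numpy().copy()
        for c in selected:
            if pos_cm is not None and chroms is not None:
                near = (chroms == chroms[c]) & (np.abs(pos_cm - pos_cm[c]) <= window_cm)
                lod[near] = -np.inf
            else:
                lod[c] = -np.inf
        b = int(np.argmax(lod))
        if not np.isfinite(lod[b]) or lod[b] <= 0:
            break
        selected.append(b)
    return tuple(selected)


def permutation_threshold(
    y: np.ndarray,
    geno: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    covariate_bins: tuple[int, ...] = (),
    pos_cm: np.ndarray | None = None,
    chroms: np.ndarray | None = None,
    window_cm: float = 10.0,
) -> dict:
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotype labels are permuted against whole genotype rows
    ``n_perm`` times; the threshold is the empirical ``1 - alpha``
    quantile (linear/type-7 interpolation) of the per-permutation
    genome-wide maximum LOD.  Returns a dict with ``threshold``,
    ``max_lods``, ``n_perm``, ``alpha`` and ``seed``.
    """
    if n_perm < 20:
        raise ConfigError("n_perm < 20 gives an unstable quantile; refuse")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = np.asarray(y, dtype=float)
    geno = np.asarray(geno)
    n_ind = y.shape[0]
    perms = np.stack([rng.permutation(n_ind) for _ in range(n_perm)], axis=1)
    Y = y[perms]  # individuals x permutations

    x_all, z_all, mask_all = codes_matrix(geno)
    max_lod = np.zeros(n_perm)
    for b in range(geno.shape[0]):
        active = _active_covariates(b, covariate_bins, pos_cm, chroms, window_cm)
        mask = mask_all[b]
        for c in active:
            mask &= mask_all[c]
        n = int(mask.sum())
        if n < 10:
            continue
        Ym = Y[mask]
        cov_cols = [np.ones(n)]
        for c in active:
            cov_cols += [x_all[c, mask], z_all[c, mask]]
        X0 = np.column_stack(cov_cols)
        X1 = np.column_stack(cov_cols + [x_all[b, mask], z_all[b, mask]])
        rss0 = _rss(X0, Ym)
        rss1 = _rss(X1, Ym)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = (n / 2.0) * np.log10(np.where(rss1 > 0, rss0 / rss1, np.inf))
        lod = np.nan_to_num(np.maximum(lod, 0.0), posinf=np.inf)
        max_lod = np.maximum(max_lod, lod)
    threshold = float(np.quantile(max_lod, 1.0 - alpha))
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return {
        "threshold": threshold,
        "max_lods": max_lod,
        "n_perm": n_perm,
        "alpha": alpha,
        "seed": seed_val,
    }


def fit_qtl(y: np.ndarray, geno: np.ndarray, peak_bins: list[int]) -> dict:
    """Joint fit of the declared QTL bins.

    Returns overall ``pve`` (percent), the residual df, and per-QTL
    additive/dominance effects with drop-one PVE contributions.
    Individuals missing at any declared bin are excluded from the joint
    model.
    """
    if not peak_bins:
        raise ConfigError("at least one QTL bin must be declared")
    y = np.asarray(y, dtype=float)
    geno = np.asarray(geno)
    x_all, z_all, mask_all = codes_matrix(geno)
    mask = np.isfinite(y)
    for b in peak_bins:
        mask &= mask_all[b]
    n = int(mask.sum())
    n_par = 1 + 2 * len(peak_bins)
    if n <= n_par:
        raise ConfigError("fewer residual df than parameters in joint QTL model")
    ym = y[mask]
    cols = [np.ones(n)]
    for b in peak_bins:
        cols += [x_all[b, mask], z_all[b, mask]]
    X = np.column_stack(cols)
    rss_null = float(((ym - ym.mean()) ** 2).sum())
    rss_full = float(_rss(X, ym[:, None])[0])
    beta, *_ = np.linalg.lstsq(X, ym, rcond=None)
    pve = 100.0 * (1.0 - rss_full / rss_null) if rss_null > 0 else 0.0

    per_qtl = []
    for k, b in enumerate(peak_bins):
        keep = [0] + [
            1 + 2 * j + d for j in range(len(peak_bins)) if j != k for d in (0, 1)
        ]
        rss_drop = float(_rss(X[:, keep], ym[:, None])[0])
        per_qtl.append(
            {
                "bin": b,
                "additive": float(beta[1 + 2 * k]),
                "dominance": float(beta[2 + 2 * k]),
                "pve": 100.0 * (rss_drop - rss_full) / rss_null if rss_null > 0 else 0.0,
            }
        )
    return {"pve": pve, "n": n, "rss_full": rss_full, "rss_null": rss_null, "qtls": per_qtl}


def call_qtl_peaks(
    lod: np.ndarray, chroms: np.ndarray, threshold: float
) -> list[int]:
    """One peak bin per chromosome whose maximum LOD clears the threshold."""
    lod = np.asarray(lod, dtype=float)
    peaks = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(np.asarray(chroms) == chrom)
        b = idx[int(np.argmax(lod[idx]))]
        if lod[b] > threshold:
            peaks.append(int(b))
    return peaks


def qtl_table(
    trait: str,
    y: np.ndarray,
    geno: np.ndarray,
    bins: pd.DataFrame,
    lod: np.ndarray,
    threshold: float,
) -> pd.DataFrame:
    """Declared-QTL table with support intervals, effects and PVE.

    Support interval = peak bin plus both flanking bins (clipped to the
    chromosome); overlapping intervals for the same trait are merged,
    keeping the higher peak.
    """
    chroms = bins["chrom"].to_numpy()
    peaks = call_qtl_peaks(lod, chroms, threshold)
    intervals = []
    for b in peaks:
        idx = np.flatnonzero(chroms == chroms[b])
        lo = max(b - 1, idx[0])
        hi = min(b + 1, idx[-1])
        intervals.append([b, lo, hi])
    # merge overlapping same-trait intervals (same chromosome by construction)
    intervals.sort(key=lambda iv: (str(chroms[iv[0]]), iv[1]))
    merged: list[list[int]] = []
    for iv in intervals:
        if merged and chroms[merged[-1][0]] == chroms[iv[0]] and iv[1] <= merged[-1][2]:
            prev = merged[-1]
            prev[2] = max(prev[2], iv[2])
            if lod[iv[0]] > lod[prev[0]]:
                prev[0] = iv[0]
        else:
            merged.append(iv)
    if not merged:
        return pd.DataFrame(
            columns=[
                "trait", "chrom", "peak_bin", "interval_start_bin", "interval_end_bin",
                "start_bp", "end_bp", "lod", "pve", "additive", "dominance",
            ]
        )
    fit = fit_qtl(y, geno, [iv[0] for iv in merged])
    rows = []
    for iv, q in zip(merged, fit["qtls"]):
        b, lo, hi = iv
        rows.append(
            {
                "trait": trait,
                "chrom": chroms[b],
                "peak_bin": bins["bin_id"].iat[b],
                "interval_start_bin": bins["bin_id"].iat[lo],
                "interval_end_bin": bins["bin_id"].iat[hi],
                "start_bp": int(bins["start"].iat[lo]),
                "end_bp": int(bins["end"].iat[hi]),
                "lod": float(lod[b]),
                "pve": q["pve"],
                "additive": q["additive"],
                "dominance": q["dominance"],
            }
        )
    return pd.DataFrame(rows)
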