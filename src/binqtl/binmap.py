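"""HMM genotype imputation, crossover calling and bin-map construction.

Low-coverage F2 data cannot be genotyped marker by marker: at ~7x depth
a heterozygote frequently shows reads from only one parent.  Instead a
three-state hidden Markov chain (AA, AB, BB) is decoded along each
chromosome of each individual:

* **Emissions** — given read counts ``(n_a, n_b)`` with depth
  ``d = n_a + n_b`` and per-read error ``eps``::

      P(obs | AA) = C(d, n_b) eps^n_b (1-eps)^n_a
      P(obs | AB) = C(d, n_a) 0.5^d
      P(obs | BB) = C(d, n_a) eps^n_a (1-eps)^n_b

  ``d = 0`` is uninformative (uniform emission).
* **Transitions** — a physical gap of ``g`` bp at a background rate
  ``rho`` cM/Mb corresponds to ``d = g * rho / 1e8`` Morgans and a
  per-gamete switch probability ``r = (1 - exp(-2d)) / 2`` (Haldane).
  The diploid chain is the product of two independent gametes, e.g.
  ``AA -> (AA, AB, BB) = ((1-r)^2, 2r(1-r), r^2)``.
* **Decoding** — Viterbi with a uniform (1/4, 1/2, 1/4) start, in log
  space, ties broken toward keeping the current state.  Maximal
  same-state runs become genotype blocks; the interval between two
  adjacent blocks with different states is a crossover.

Breakpoint midpoints pooled over the population partition each
chromosome into recombination bins; candidate bins shorter than
``min_bin_bp`` (default 30 kb) are merged into the flanking bin whose
individual genotypes they match best, guarding against spurious
crossovers from residual genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import AA, AB, BB, UNKNOWN, ConfigError
from .variants import ObservationMatrix

__all__ = [
    "HMMParams",
    "GenotypeBlock",
    "BinGenotypeMatrix",
    "emission_probs",
    "emission_log_probs",
    "transition_matrix",
    "viterbi",
    "decode_chromosome",
    "decode_population",
    "call_crossovers",
    "build_bins",
    "bin_summary",
]

_STATES = (AA, AB, BB)


@dataclass(frozen=True)
class HMMParams:
    """Imputation parameters.

    ``error_rate`` is the per-read miscall probability, ``background_rate``
    the genome-wide genetic rate (cM/Mb) used to convert physical gaps
    into transition probabilities, and ``min_bin_bp`` the minimum
    retained bin length.
    """

    error_rate: float = 0.01
    background_rate: float = 3.0
    min_bin_bp: int = 30_000

    def __post_init__(self) -> None:
        if not (0.0 < self.error_rate < 0.5):
            raise ConfigError("error_rate must lie in (0, 0.5)")
        if self.background_rate <= 0:
            raise ConfigError("background_rate must be > 0")
        if self.min_bin_bp < 0:
            raise ConfigError("min_bin_bp must be >= 0")


@dataclass(frozen=True)
class GenotypeBlock:
    """A maximal same-state run of markers for one individual."""

    individual: int
    chrom: str
    start_bp: int
    end_bp: int
    state: int  # AA/AB/BB or UNKNOWN


@dataclass
class BinGenotypeMatrix:
    """Recombination bins x individuals genotype matrix.

    ``bins`` has columns ``bin_id, chrom, start, end`` (1-based
    inclusive); ``genotypes[b, i]`` is the genotype code of individual
    ``i`` across bin ``b`` (AA/AB/BB or UNKNOWN).
    """

    bins: pd.DataFrame
    genotypes: np.ndarray
    individuals: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def lengths_bp(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"] + 1).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        from .core import GENOTYPE_LETTER

        letters = np.vectorize(GENOTYPE_LETTER.get)(self.genotypes)
        geno = pd.DataFrame(letters, columns=self.individuals, index=self.bins.index)
        return pd.concat([self.bins.copy(), geno], axis=1)


def emission_log_probs(
    n_a: np.ndarray, n_b: np.ndarray, error_rate: float
) -> np.ndarray:
    """Log emission probabilities, shape (n_obs, 3) for (AA, AB, BB).

    Includes the shared binomial coefficient (it cancels in decoding).
    Zero-depth observations get a uniform log(1/3) row.
    """
    if not (0.0 < error_rate < 0.5):
        raise ConfigError("error_rate must lie in (0, 0.5)")
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if (n_a < 0).any() or (n_b < 0).any():
        raise ConfigError("read counts must be >= 0")
    d = n_a + n_b
    coeff = gammaln(d + 1) - gammaln(n_a + 1) - gammaln(n_b + 1)
    log_eps, log_1meps = np.log(error_rate), np.log1p(-error_rate)
    out = np.empty(n_a.shape + (3,))
    out[..., AA] = coeff + n_b * log_eps + n_a * log_1meps
    out[..., AB] = coeff + d * np.log(0.5)
    out[..., BB] = coeff + n_a * log_eps + n_b * log_1meps
    out[d == 0] = np.log(1.0 / 3.0)
    return out


def emission_probs(n_a: int, n_b: int, error_rate: float) -> np.ndarray:
    """Normalised emission probability triple over (AA, AB, BB)."""
    logp = emission_log_probs(np.array([n_a]), np.array([n_b]), error_rate)[0]
    p = np.exp(logp - logp.max())
    return p / p.sum()


def haldane_r(gap_bp: float, background_rate: float) -> float:
    """Per-gamete switch probability across a physical gap (Haldane)."""
    d_morgan = gap_bp * background_rate / 1e6 / 100.0
    return 0.5 * -np.expm1(-2.0 * d_morgan)


def transition_matrix(gap_bp: float, background_rate: float) -> np.ndarray:
    """3x3 F2 transition matrix across a physical gap.

    The diploid chain is the product of two independent gametes each
    switching with the Haldane probability ``r``; rows sum to 1 and the
    ``gap -> inf`` limit is the stationary (1/4, 1/2, 1/4) distribution.
    """
    if gap_bp < 0:
        raise ConfigError("gap must be >= 0")
    r = haldane_r(gap_bp, background_rate)
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


_LOG_START = np.log(np.array([0.25, 0.5, 0.25]))


def viterbi(log_emit: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """Most likely state path.

    ``log_emit`` is (m, 3); ``log_trans`` is (m-1, 3, 3) between
    consecutive markers.  Ties in the backpointer are broken toward
    staying in the current state, which avoids manufacturing spurious
    block switches from flat likelihoods.
    """
    m = log_emit.shape[0]
    score = _LOG_START + log_emit[0]
    back = np.zeros((m, 3), dtype=np.int8)
    for t in range(1, m):
        cand = score[:, None] + log_trans[t - 1]  # prev state x next state
        best_prev = np.argmax(cand, axis=0)
        best_score = cand[best_prev, np.arange(3)]
        # tie toward the diagonal (predecessor == state)
        diag = cand[np.arange(3), np.arange(3)]
        stay = diag >= best_score - 1e-12
        best_prev = np.where(stay, np.arange(3), best_prev)
        best_score = np.where(stay, diag, best_score)
        score = best_score + log_emit[t]
        back[t] = best_prev
    path = np.empty(m, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(m - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_chromosome(
    n_a: np.ndarray,
    n_b: np.ndarray,
    positions: np.ndarray,
    params: HMMParams,
    individual: int = 0,
    chrom: str = "chr1",
) -> list[GenotypeBlock]:
    """Viterbi-decode one individual's chromosome into genotype blocks.

    A chromosome with no sequenced marker at all yields a single
    UNKNOWN block (excluded from crossover counting).
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        raise ConfigError("chromosome has no markers")
    if (n_a + n_b).sum() == 0:
        return [
            GenotypeBlock(individual, chrom, int(positions[0]), int(positions[-1]), UNKNOWN)
        ]
    log_emit = emission_log_probs(n_a, n_b, params.error_rate)
    gaps = np.diff(positions)
    log_trans = np.log(
        np.stack([transition_matrix(g, params.background_rate) for g in gaps])
    ) if gaps.size else np.empty((0, 3, 3))
    path = viterbi(log_emit, log_trans)
    blocks: list[GenotypeBlock] = []
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            blocks.append(
                GenotypeBlock(
                    individual,
                    chrom,
                    int(positions[start]),
                    int(positions[t - 1]),
                    int(path[start]),
                )
            )
            start = t
    return blocks


def decode_population(
    obs: ObservationMatrix, params: HMMParams | None = None
) -> dict[tuple[int, str], list[GenotypeBlock]]:
    """Decode every (individual, chromosome) of an observation matrix."""
    params = params or HMMParams()
    chroms = list(dict.fromkeys(obs.markers["chrom"]))
    blocks: dict[tuple[int, str], list[GenotypeBlock]] = {}
    for chrom in chroms:
        idx = obs.marker_index(chrom)
        positions = obs.markers["pos"].to_numpy()[idx]
        gaps = np.diff(positions)
        log_trans = (
            np.log(np.stack([transition_matrix(g, params.background_rate) for g in gaps]))
            if gaps.size
            else np.empty((0, 3, 3))
        )
        for i in range(obs.n_individuals):
            na, nb = obs.n_a[i, idx], obs.n_b[i, idx]
            if (na + nb).sum() == 0:
                blocks[(i, chrom)] = [
                    GenotypeBlock(i, chrom, int(positions[0]), int(positions[-1]), UNKNOWN)
                ]
                continue
            log_emit = emission_log_probs(na, nb, params.error_rate)
            path = viterbi(log_emit, log_trans)
            runs: list[GenotypeBlock] = []
            start = 0
            for t in range(1, len(path) + 1):
                if t == len(path) or path[t] != path[start]:
                    runs.append(
                        GenotypeBlock(
                            i, chrom, int(positions[start]), int(positions[t - 1]), int(path[start])
                        )
                    )
                    start = t
            blocks[(i, chrom)] = runs
    return blocks


def call_crossovers(
    blocks: dict[tuple[int, str], list[GenotypeBlock]]
) -> pd.DataFrame:
    """Crossovers = boundaries between adjacent blocks with different states.

    Returns one row per event with the flanking-marker interval
    (``left_bp`` = last marker of the left block, ``right_bp`` = first
    marker of the right block) and the midpoint point estimate.
    """
    rows = []
    for (i, chrom), blist in blocks.items():
        for left, right in zip(blist, blist[1:]):
            if left.state == UNKNOWN or right.state == UNKNOWN:
                continue
            mid = 0.5 * (left.end_bp + right.start_bp)
            rows.append((i, chrom, left.end_bp, right.start_bp, mid))
    return pd.DataFrame(
        rows, columns=["individual", "chrom", "left_bp", "right_bp", "mid_bp"]
    ).sort_values(["chrom", "mid_bp"], kind="stable").reset_index(drop=True)


def _block_state_in_interval(
    blist: list[GenotypeBlock], start: int, end: int
) -> int:
    """State with the largest overlap with [start, end] (bp, inclusive)."""
    best_state, best_len = UNKNOWN, -1.0
    for b in blist:
        lo, hi = max(b.start_bp, start), min(b.end_bp, end)
        if hi < lo:
            continue
        span = hi - lo + 1
        if span > best_len:
            best_len, best_state = span, b.state
    return best_state


def build_bins(
    blocks: dict[tuple[int, str], list[GenotypeBlock]],
    markers: pd.DataFrame,
    individuals: list[str],
    min_bin_bp: int = 30_000,
) -> BinGenotypeMatrix:
    """Partition the marker-covered genome into recombination bins.

    Per chromosome, the midpoints of all crossover intervals in the
    population are pooled, de-duplicated and sorted; consecutive
    breakpoints delimit candidate bins spanning the marker-covered
    interval.  A candidate shorter than ``min_bin_bp`` is merged into
    the flanking bin with which it shares the larger number of
    identical individual genotypes (tie toward the left neighbour), and
    the bin's genotypes are re-derived from the block structure.  With
    no crossovers a chromosome is one bin.
    """
    crossovers = call_crossovers(blocks)
    chroms = list(dict.fromkeys(markers["chrom"]))
    n_ind = len(individuals)

    bin_rows = []
    geno_rows = []
    for chrom in chroms:
        pos = markers.loc[markers["chrom"] == chrom, "pos"].to_numpy()
        span_start, span_end = int(pos[0]), int(pos[-1])
        mids = np.unique(
            crossovers.loc[crossovers["chrom"] == chrom, "mid_bp"].to_numpy()
        )
        mids = mids[(mids > span_start) & (mids < span_end)]
        edges = [span_start - 1] + [int(np.floor(m)) for m in mids] + [span_end]
        # candidate bins (start, end) 1-based inclusive
        cand = [(edges[k] + 1, edges[k + 1]) for k in range(len(edges) - 1)]
        cand = [(s, e) for s, e in cand if e >= s]

        chrom_blocks = [blocks.get((i, chrom), []) for i in range(n_ind)]

        def genotype_row(start: int, end: int) -> np.ndarray:
            return np.array(
                [
                    _block_state_in_interval(chrom_blocks[i], start, end)
                    for i in range(n_ind)
                ],
                dtype=np.int8,
            )

        genos = [genotype_row(s, e) for s, e in cand]

        # merge short candidate bins into the better-matching neighbour
        changed = True
        while changed and len(cand) > 1:
            changed = False
            for k, (s, e) in enumerate(cand):
                if e - s + 1 >= min_bin_bp:
                    continue
                left_match = (
                    int((genos[k] == genos[k - 1]).sum()) if k > 0 else -1
                )
                right_match = (
                    int((genos[k] == genos[k + 1]).sum())
                    if k < len(cand) - 1
                    else -1
                )
                if left_match >= right_match:
                    tgt = k - 1
                else:
                    tgt = k + 1
                lo = min(cand[k][0], cand[tgt][0])
                hi = max(cand[k][1], cand[tgt][1])
                a, b = sorted((k, tgt))
                cand[a] = (lo, hi)
                genos[a] = genotype_row(lo, hi)
                del cand[b], genos[b]
                changed = True
                break

        for (s, e), g in zip(cand, genos):
            bin_rows.append((chrom, s, e))
            geno_rows.append(g)

    bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end"])
    bins.insert(0, "bin_id", [f"bin{k + 1:04d}" for k in range(len(bins))])
    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.empty((0, n_ind), dtype=np.int8)
    )
    return BinGenotypeMatrix(bins=bins, genotypes=genotypes, individuals=list(individuals))


def bin_summary(binmat: BinGenotypeMatrix) -> pd.DataFrame:
    """Per-chromosome bin counts and size statistics (plus a Total row)."""
    df = binmat.bins.copy()
    df["length"] = df["end"] - df["start"] + 1
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        rows.append(
            {
                "chrom": chrom,
                "n_bins": len(grp),
                "min_bp": int(grp["length"].min()),
                "mean_bp": float(grp["length"].mean()),
                "max_bp": int(grp["length"].max()),
                "covered_mb": float(grp["length"].sum() / 1e6),
            }
        )
    out = pd.DataFrame(rows)
    total = {
        "chrom": "Total",
        "n_bins": int(out["n_bins"].sum()),
        "min_bp": int(df["length"].min()) if len(df) else 0,
        "mean_bp": float(df["length"].mean()) if len(df) else 0.0,
        "max_bp": int(df["length"].max()) if len(df) else 0,
        "covered_mb": float(out["covered_mb"].sum()),
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)
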