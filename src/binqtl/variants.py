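"""Parent-informative SNP selection and allele-depth encoding from VCF.

The mapping pipeline only uses loci where the two inbred parents are
homozygous for different alleles, so every progeny read can be assigned
to a parental haplotype.  :func:`select_informative_snps` applies the
site filters (bi-allelic SNP, both parents homozygous and polymorphic,
QUAL >= 20, INFO/MQ >= 20) and orients each marker by the female
parent's allele.  :func:`encode_observations` then turns progeny AD
fields into per-marker counts of reads supporting the female (``n_a``)
and male (``n_b``) parental alleles.

Coordinates are 1-based inclusive (VCF convention) throughout; BED
exports elsewhere convert to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InputError

logger = logging.getLogger(__name__)

__all__ = ["ObservationMatrix", "select_informative_snps", "encode_observations"]

MARKER_COLUMNS = ["chrom", "pos", "allele_female", "allele_male", "qual", "mq"]


@dataclass
class ObservationMatrix:
    """Per-individual, per-marker parental-allele read counts.

    ``n_a[i, j]`` / ``n_b[i, j]`` are the reads of individual ``i`` at
    marker ``j`` supporting the female / male parental allele; zero
    total depth means missing.  ``pseudo`` marks matrices built from
    genotype calls rather than real depths (see
    :func:`encode_observations`).
    """

    individuals: list[str]
    markers: pd.DataFrame
    n_a: np.ndarray
    n_b: np.ndarray
    pseudo: bool = False

    def __post_init__(self) -> None:
        shape = (len(self.individuals), len(self.markers))
        if self.n_a.shape != shape or self.n_b.shape != shape:
            raise InputError(
                f"count matrices must be individuals x markers {shape}"
            )
        if (self.n_a < 0).any() or (self.n_b < 0).any():
            raise InputError("read counts must be >= 0")

    @property
    def depth(self) -> np.ndarray:
        return self.n_a + self.n_b

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.markers["chrom"].to_numpy() == chrom)


def _is_snp_allele(a: str) -> bool:
    return len(a) == 1 and a in "ACGT"


def select_informative_snps(
    vcf_path: str,
    female: str,
    male: str,
    min_qual: float = 20.0,
    min_mq: float = 20.0,
) -> pd.DataFrame:
    """Select parent-informative SNPs from a VCF.

    Keeps exactly the bi-allelic SNP sites where both parents carry
    called homozygous genotypes for different alleles, with
    ``QUAL >= min_qual`` and ``INFO/MQ >= min_mq`` (records lacking MQ
    are dropped).  Returns a marker table sorted by (chrom, pos) with
    unique positions and columns ``chrom, pos, allele_female,
    allele_male, qual, mq``.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    for parent in (female, male):
        if parent not in samples:
            raise InputError(f"parent sample {parent!r} not in VCF header")
    fi, mi = samples.index(female), samples.index(male)

    rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if not (_is_snp_allele(v.REF) and _is_snp_allele(v.ALT[0])):
            continue
        qual = v.QUAL
        mq = v.INFO.get("MQ")
        if qual is None or qual < min_qual or mq is None or mq < min_mq:
            continue
        gts = v.genotypes
        gf, gm = gts[fi], gts[mi]
        if gf[0] < 0 or gm[0] < 0:  # missing parental call
            continue
        if gf[0] != gf[1] or gm[0] != gm[1]:  # heterozygous parent
            continue
        if gf[0] == gm[0]:  # not polymorphic between parents
            continue
        alleles = [v.REF, v.ALT[0]]
        rows.append(
            (v.CHROM, v.POS, alleles[gf[0]], alleles[gm[0]], float(qual), float(mq))
        )
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    markers = (
        markers.drop_duplicates(subset=["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    return markers


_PSEUDO_DEPTHS = {0: (2, 0), 1: (1, 1), 2: (0, 2)}


def encode_observations(
    vcf_path: str,
    markers: pd.DataFrame,
    female: str,
    male: str,
) -> ObservationMatrix:
    """Orient progeny allele depths onto the parental alleles.

    For every marker and progeny sample, ``n_a`` is the AD entry of the
    female-parent allele and ``n_b`` that of the male-parent allele
    (swapped when the female allele is the ALT).  Records without an AD
    field fall back to pseudo-depths derived from GT (hom-ref (2,0),
    het (1,1), hom-alt (0,2)); the returned matrix is then flagged
    ``pseudo`` so downstream emission models can inflate uncertainty.
    Markers absent from the VCF stay missing (zero counts).
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    for parent in (female, male):
        if parent not in samples:
            raise InputError(f"parent sample {parent!r} not in VCF header")
    progeny_idx = [i for i, s in enumerate(samples) if s not in (female, male)]
    progeny = [samples[i] for i in progeny_idx]

    index = {
        (c, p): j
        for j, (c, p) in enumerate(zip(markers["chrom"], markers["pos"]))
    }
    n_a = np.zeros((len(progeny), len(markers)), dtype=np.int32)
    n_b = np.zeros_like(n_a)
    seen = np.zeros(len(markers), dtype=bool)
    any_pseudo = False

    for v in vcf:
        j = index.get((v.CHROM, v.POS))
        if j is None:
            continue
        if len(v.ALT) != 1:
            continue
        female_allele = markers["allele_female"].iat[j]
        if v.REF == female_allele:
            ref_is_female = True
        elif v.ALT[0] == female_allele:
            ref_is_female = False
        else:
            logger.warning("alleles at %s:%d do not match marker set", v.CHROM, v.POS)
            continue
        seen[j] = True
        ad = v.format("AD")
        if ad is not None:
            ad = np.asarray(ad)
            ref_counts = np.clip(ad[progeny_idx, 0], 0, None)
            alt_counts = np.clip(ad[progeny_idx, 1], 0, None)
        else:
            any_pseudo = True
            gts = v.genotypes
            ref_counts = np.zeros(len(progeny_idx), dtype=np.int32)
            alt_counts = np.zeros_like(ref_counts)
            for k, si in enumerate(progeny_idx):
                a1, a2 = gts[si][0], gts[si][1]
                if a1 < 0 or a2 < 0:
                    continue
                r, a = _PSEUDO_DEPTHS[a1 + a2]
                ref_counts[k], alt_counts[k] = r, a
        if ref_is_female:
            n_a[:, j], n_b[:, j] = ref_counts, alt_counts
        else:
            n_a[:, j], n_b[:, j] = alt_counts, ref_counts

    missing = int((~seen).sum())
    if missing:
        logger.warning("%d markers absent from progeny VCF; recorded as missing", missing)
    return ObservationMatrix(
        individuals=progeny,
        markers=markers.reset_index(drop=True),
        n_a=n_a,
        n_b=n_b,
        pseudo=any_pseudo,
    )
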