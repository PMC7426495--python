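"""Genotype dosage matrices with per-call read depth, and SNP filtering.

Genotyping-by-sequencing (GBS) yields, for every individual × SNP call, a
read depth ``k`` and an observed fractional allele dosage
``x = 2 * (alt reads) / k`` in [0, 2].  Depth 0 means the call is missing
(coded ``NaN`` in the dosage matrix).  At low depth the observed dosage is
a noisy binomial estimate of the true dosage in {0, 1, 2}; downstream GRM
construction (:mod:`mtgp.grm`) corrects for that noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "FilterLog", "filter_snps"]


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs fractional dosages with per-call read depth.

    Parameters
    ----------
    dosages : ndarray, shape (n, m)
        Fractional allele dosages in [0, 2]; ``NaN`` where missing.
    depths : ndarray, shape (n, m)
        Reads per call (>= 0); depth 0 if and only if the dosage is missing.
    sample_ids, snp_ids : sequence of str, optional
        Row / column labels; generated if omitted.
    """

    dosages: np.ndarray
    depths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.dosages.shape != self.depths.shape:
            raise ValueError("dosages and depths must have the same shape")
        n, m = self.dosages.shape
        if not self.sample_ids:
            self.sample_ids = [f"F{i + 1:04d}" for i in range(n)]
        if not self.snp_ids:
            self.snp_ids = [f"S{j + 1:06d}" for j in range(m)]
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("label lengths do not match matrix shape")
        miss = np.isnan(self.dosages)
        if np.any(miss != (self.depths == 0)):
            raise ValueError("depth 0 must coincide exactly with missing dosage")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean individuals × SNPs mask, True where the call is missing."""
        return np.isnan(self.dosages)

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency p̂ from non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the SNP columns in ``index``."""
        return replace(
            self,
            dosages=self.dosages[:, index],
            depths=self.depths[:, index],
            snp_ids=[self.snp_ids[j] for j in np.atleast_1d(index)],
        )


@dataclass
class FilterLog:
    """Per-filter SNP removal counts, in the order the filters were applied."""

    n_input: int
    removed_missing: int
    removed_maf: int
    removed_depth: int
    removed_hw: int
    n_retained: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _hw_disequilibrium(g: GenotypeMatrix, min_depth: float = 2.0) -> np.ndarray:
    """Hardy-Weinberg disequilibrium D = ĥ − 2p̂(1−p̂) per SNP.

    A call is observed heterozygous when its fractional dosage lies
    strictly inside (0, 2) — both alleles were read.  Under the binomial
    read model a true heterozygote at depth k is *detected* with
    probability 1 − 2^(1−k), so the raw heterozygote count is deflated at
    low depth; ĥ therefore divides the count by the summed detection
    probabilities over calls with depth >= ``min_depth`` (at high depth
    this reduces to the plain heterozygote fraction).  Negative D means a
    heterozygote deficit.  SNPs with no qualifying call get D = 0 (no
    evidence against them).
    """
    deep = (g.depths >= min_depth) & ~g.missing_mask
    with np.errstate(invalid="ignore"):
        het = (g.dosages > 0.0) & (g.dosages < 2.0) & deep
    detect = np.where(deep, 1.0 - 2.0 ** (1.0 - g.depths), 0.0)
    denom = detect.sum(axis=0)
    p = g.allele_freqs
    with np.errstate(invalid="ignore", divide="ignore"):
        h_hat = np.where(denom > 0, het.sum(axis=0) / np.maximum(denom, 1e-300), np.nan)
    d = h_hat - 2.0 * p * (1.0 - p)
    return np.where(np.isnan(d), 0.0, d)


def filter_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.50,
    min_mean_depth: float = 2.0,
    hwdis_min: float = -0.05,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Apply the standard GBS SNP filters, in a fixed order.

    Order: missingness fraction <= ``max_missing``, then minor allele
    frequency >= ``maf_min``, then mean read depth over non-missing calls >
    ``min_mean_depth``, then Hardy-Weinberg disequilibrium D > ``hwdis_min``
    (D computed on calls with depth >= 2; see :func:`_hw_disequilibrium`).
    Returns the filtered panel and a :class:`FilterLog` with per-filter
    removal counts.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype panel")
    miss_frac = g.missing_mask.mean(axis=0)
    keep = miss_frac <= max_missing
    n_missing = int((~keep).sum())

    p = g.allele_freqs
    maf = np.minimum(p, 1.0 - p)
    maf_ok = (maf >= maf_min) & ~np.isnan(maf)
    n_maf = int((keep & ~maf_ok).sum())
    keep &= maf_ok

    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            (~g.missing_mask).sum(axis=0) > 0,
            g.depths.sum(axis=0) / np.maximum((~g.missing_mask).sum(axis=0), 1),
            0.0,
        )
    depth_ok = mean_depth > min_mean_depth
    n_depth = int((keep & ~depth_ok).sum())
    keep &= depth_ok

    hw = _hw_disequilibrium(g)
    hw_ok = hw > hwdis_min
    n_hw = int((keep & ~hw_ok).sum())
    keep &= hw_ok

    log = FilterLog(
        n_input=g.n_snps,
        removed_missing=n_missing,
        removed_maf=n_maf,
        removed_depth=n_depth,
        removed_hw=n_hw,
        n_retained=int(keep.sum()),
    )
    logger.info("SNP filters: %s", log.as_dict())
    if log.n_retained == 0:
        raise ValueError(f"all SNPs removed by filters: {log.as_dict()}")
    return g.take_snps(np.flatnonzero(keep)), log
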