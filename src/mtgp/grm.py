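"""Depth-aware genomic relationship matrices and principal-coordinate MDS.

The GRM estimator is "KGD-style": it operates directly on fractional
GBS dosages without imputation, uses pairwise-complete loci with matched
denominators, and corrects the self-relationship diagonal for the extra
binomial sampling variance introduced by finite read depth.  Under the
read model x = 2·Binomial(k, g/2)/k the per-locus term
(x − 2p)² − x(2 − x)/(k − 1) is unbiased for (g − 2p)², so the corrected
diagonal estimates the true-genotype VanRaden diagonal; at infinite depth
the whole estimator reduces exactly to VanRaden's first method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtgp.genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["GRM", "compute_grm", "mds"]


@dataclass
class GRM:
    """Square symmetric relationship matrix with sample labels."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRM entries must be finite")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-8:
            logger.warning("GRM asymmetric beyond tolerance (%.3g); symmetrized", asym)
        self.values = 0.5 * (self.values + self.values.T)
        if not self.sample_ids:
            self.sample_ids = [f"F{i + 1:04d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"sample id {e.args[0]!r} not in GRM") from None

    def subset(self, ids) -> "GRM":
        idx = self.index_of(ids)
        return GRM(self.values[np.ix_(idx, idx)], [self.sample_ids[i] for i in idx])

    def bend(self, min_eig: float = 1e-8) -> tuple["GRM", float]:
        """Return a positive-definite copy (diagonal shift) and the shift used."""
        w = np.linalg.eigvalsh(self.values)
        shift = max(0.0, min_eig - float(w[0]))
        if shift > 0:
            logger.info("GRM bent: +%.3g added to diagonal (min eigenvalue %.3g)", shift, w[0])
            return GRM(self.values + shift * np.eye(self.n), list(self.sample_ids)), shift
        return self, 0.0


def compute_grm(g: GenotypeMatrix, depth_correct: bool = True) -> GRM:
    """Estimate the genomic relationship matrix from fractional dosages.

    Off-diagonals: K_ij = Σ_l (x_il − 2p_l)(x_jl − 2p_l) / Σ_l 2p_l(1 − p_l),
    both sums over loci non-missing in *both* individuals
    (pairwise-complete; no imputation).  With ``depth_correct`` the
    diagonal uses the per-locus unbiased term
    (x − 2p)² − x(2 − x)/(k − 1) over loci with depth >= 2; without it the
    diagonal is the plain VanRaden (x − 2p)² over non-missing loci.
    Pairs with zero overlapping loci get relationship 0 with a warning.
    """
    p = g.allele_freqs
    w = 2.0 * p * (1.0 - p)
    obs = (~g.missing_mask).astype(float)
    xc = np.where(g.missing_mask, 0.0, g.dosages - 2.0 * p)

    num = xc @ xc.T
    den = (obs * w) @ obs.T
    zero_overlap = den <= 0
    if np.any(zero_overlap):
        logger.warning(
            "%d individual pairs share no informative loci; relationship set to 0",
            int(np.sum(zero_overlap) // 2),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(zero_overlap, 0.0, num / np.where(zero_overlap, 1.0, den))

    if depth_correct:
        deep = (g.depths >= 2.0) & ~g.missing_mask
        x = np.where(deep, g.dosages, 0.0)
        kk = np.where(deep, g.depths, 2.0)
        term = np.where(deep, xc**2 - x * (2.0 - x) / (kk - 1.0), 0.0)
        num_d = term.sum(axis=1)
        den_d = (deep * w).sum(axis=1)
        good = den_d > 0
        diag = np.where(good, num_d / np.where(good, den_d, 1.0), np.diag(K))
        K = K.copy()
        np.fill_diagonal(K, diag)

    K = 0.5 * (K + K.T)
    return GRM(K, list(g.sample_ids))


def mds(K: GRM, n_axes: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal-coordinates analysis of genetic distances.

    The squared distance between individuals is
    d²_ij = K_ii + K_jj − 2 K_ij; classical scaling double-centres −½ d²
    and returns the top ``n_axes`` coordinate axes plus all eigenvalues.
    Axis signs are fixed by making the largest-magnitude loading of each
    axis positive, so plots are reproducible across runs.
    """
    n = K.n
    if n_axes > n - 1:
        raise ValueError("n_axes must be at most n − 1")
    V = K.values
    d2 = np.add.outer(np.diag(V), np.diag(V)) - 2.0 * V
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = 0.5 * (B + B.T)
    w, vec = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, vec = w[order], vec[:, order]
    coords = vec[:, :n_axes] * np.sqrt(np.clip(w[:n_axes], 0.0, None))
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    df = pd.DataFrame(
        coords,
        index=pd.Index(K.sample_ids, name="family"),
        columns=[f"axis{j + 1}" for j in range(n_axes)],
    )
    return df, w
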