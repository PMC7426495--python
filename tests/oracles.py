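"""Independent reference implementations used only to check the package."""

import numpy as np


def weir_cockerham_fst(genotypes: np.ndarray, pop_idx: np.ndarray) -> float:
    """Multi-locus Weir & Cockerham (1984) theta from integer genotypes.

    ``genotypes``: individuals × loci dosages in {0, 1, 2};
    ``pop_idx``: integer population assignment per individual.
    Ratio-of-averages estimator over loci, ignoring the within-individual
    (F_IS) level beyond observed heterozygosity.
    """
    pops = np.unique(pop_idx)
    r = pops.size
    n_i = np.array([(pop_idx == k).sum() for k in pops], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)

    a_sum = b_sum = c_sum = 0.0
    for l in range(genotypes.shape[1]):
        g = genotypes[:, l]
        p_i = np.array([g[pop_idx == k].mean() / 2.0 for k in pops])
        h_i = np.array([(g[pop_idx == k] == 1).mean() for k in pops])
        pbar = np.sum(n_i * p_i) / (r * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum / (a_sum + b_sum + c_sum)


def vanraden_reference(X: np.ndarray) -> np.ndarray:
    """Loop-written VanRaden GRM for small hand-checked panels."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    p = X.mean(axis=0) / 2.0
    denom = sum(2 * p[l] * (1 - p[l]) for l in range(m))
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = sum((X[i, l] - 2 * p[l]) * (X[j, l] - 2 * p[l]) for l in range(m)) / denom
    return K


def oneway_anova_reml(y_groups: list[np.ndarray]) -> tuple[float, float]:
    """Closed-form REML (= ANOVA) estimators for a balanced one-way layout.

    Returns (sigma2_between, sigma2_within) from the classic
    (MSB − MSW)/r and MSW moment identities, which coincide with REML in
    the balanced case with both estimates interior.
    """
    f = len(y_groups)
    r = len(y_groups[0])
    means = np.array([g.mean() for g in y_groups])
    grand = np.concatenate(y_groups).mean()
    msb = r * np.sum((means - grand) ** 2) / (f - 1)
    msw = sum(((g - g.mean()) ** 2).sum() for g in y_groups) / (f * (r - 1))
    return (msb - msw) / r, msw
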