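"""Cross-validation schemes, predictive ability, and design experiments.

Four Monte-Carlo cross-validation schemes over a family BLUP table and a
GRM, following the standard trait-assisted genomic-selection layout:

* **ST-CV1** — single-trait: primary trait observed in the training set
  only; the test set has no phenotypes.
* **MT-CV1** — bivariate: both traits observed in the training set only.
* **MT-CV2** — bivariate: primary trait in the training set; the
  secondary trait observed everywhere (training *and* test).
* **MT-CV3** — bivariate: primary trait in the training set; secondary
  trait in the test set only.

Each iteration draws a random unstratified train/test split (default
70/30), fits the appropriate prediction model, and scores the test-set
GEBVs against the held-out primary-trait BLUPs: predictive ability r_p is
the Pearson correlation, and bias is the slope of the regression of
observed on GEBV (1 = unbiased, > 1 = predictions under-dispersed).

Also provided: leave-one-population-out evaluation (train on all but one
breeding population, predict the fifth) and training-size sweeps (test
set drawn first, nested training subsets from the remainder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mtgp.gblup import GBLUP, RKHSRegression
from mtgp.grm import GRM
from mtgp.multitrait import MultiTraitGBLUP

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "CVResult",
    "predictive_ability_and_bias",
    "monte_carlo_cv",
    "leave_one_population_out",
    "training_size_sweep",
]

SCHEMES = ("ST-CV1", "MT-CV1", "MT-CV2", "MT-CV3")


@dataclass
class CVScheme:
    """A cross-validation configuration.

    ``st_engine`` selects the single-trait fitter: the closed-form REML
    GBLUP (default, exact and fast) or the Gibbs RKHS sampler — the two
    are the same model with a linear kernel.
    """

    name: str
    train_fraction: float = 0.7
    n_iterations: int = 100
    secondary: "str | None" = None
    base_seed: int = 0
    st_engine: str = "gblup"
    n_iter_gibbs: int = 3000
    burn_in: int = 1500

    def __post_init__(self) -> None:
        if self.name not in SCHEMES:
            raise ValueError(f"unknown scheme {self.name!r}; choose from {SCHEMES}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.is_multitrait and self.secondary is None:
            raise ValueError(f"{self.name} requires a secondary trait")

    @property
    def is_multitrait(self) -> bool:
        return self.name.startswith("MT")


@dataclass
class CVResult:
    """Per-iteration predictive abilities and bias for one scheme run."""

    scheme: CVScheme
    primary: str
    table: pd.DataFrame  # iteration, r_p, bias
    test_ids: list[list] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(self.table["r_p"].mean())

    @property
    def sd(self) -> float:
        return float(self.table["r_p"].std(ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(len(self.table))

    def summary(self) -> str:
        return (
            f"{self.scheme.name} [{self.primary}"
            + (f" | {self.scheme.secondary}" if self.scheme.secondary else "")
            + f"]: r_p = {self.mean:.3f} ± {self.sd:.3f} "
            f"(bias {self.table['bias'].mean():.2f}, {len(self.table)} iterations)"
        )

    def to_tidy(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "scheme", self.scheme.name)
        out.insert(1, "primary", self.primary)
        out.insert(2, "secondary", self.scheme.secondary or "")
        return out


def predictive_ability_and_bias(gebv, observed) -> tuple[float, float]:
    """Pearson correlation and observed-on-GEBV regression slope."""
    g = np.asarray(gebv, dtype=float)
    o = np.asarray(observed, dtype=float)
    if g.size != o.size or g.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(g) == 0 or np.std(o) == 0:
        raise ValueError("zero variance; predictive ability undefined")
    r_p = float(np.corrcoef(g, o)[0, 1])
    slope = float(np.cov(o, g, ddof=1)[0, 1] / np.var(g, ddof=1))
    return r_p, slope


def _mask_for_scheme(
    scheme: CVScheme,
    blups: pd.DataFrame,
    primary: str,
    train: np.ndarray,
    test: np.ndarray,
) -> pd.DataFrame:
    """Build the masked phenotype table the scheme prescribes."""
    if scheme.is_multitrait:
        Y = blups[[primary, scheme.secondary]].copy()
        Y.loc[test, primary] = np.nan
        if scheme.name == "MT-CV1":
            Y.loc[test, scheme.secondary] = np.nan
        elif scheme.name == "MT-CV3":
            Y.loc[train, scheme.secondary] = np.nan
        return Y
    y = blups[[primary]].copy()
    y.loc[test, primary] = np.nan
    return y


def _fit_predict(
    scheme: CVScheme,
    Y_masked: pd.DataFrame,
    K: GRM,
    test: np.ndarray,
    seed: int,
) -> pd.Series:
    """Fit the scheme's model on the masked table; GEBVs for the test ids."""
    if scheme.is_multitrait:
        fit = MultiTraitGBLUP(Y_masked, K).fit(
            n_iter=scheme.n_iter_gibbs, burn_in=scheme.burn_in, seed=seed
        )
        return fit.predict_primary(test)
    y = Y_masked.iloc[:, 0]
    if scheme.st_engine == "rkhs":
        fit = RKHSRegression(y, K).fit(
            n_iter=scheme.n_iter_gibbs, burn_in=scheme.burn_in, seed=seed
        )
    else:
        fit = GBLUP(y, K).fit()
    return fit.gebv.loc[list(test)]


def monte_carlo_cv(
    blups: pd.DataFrame,
    K: GRM,
    primary: str,
    scheme: CVScheme,
) -> CVResult:
    """Monte-Carlo cross-validation of one scheme.

    Each iteration draws round(train_fraction · n) training families
    uniformly without replacement (unstratified), masks phenotypes per
    the scheme, fits, and scores test-set GEBVs against the held-out
    primary BLUPs.  Iteration ``i`` uses seed ``base_seed + i`` for both
    the split and the sampler, so runs with equal base seeds share their
    split sequences exactly (paired comparisons across schemes).
    """
    _check_traits(blups, primary, scheme)
    fams = blups.index[blups[primary].notna()].to_numpy()
    n = fams.size
    n_train = int(round(scheme.train_fraction * n))
    rows, test_sets = [], []
    for it in range(scheme.n_iterations):
        rng = np.random.default_rng(scheme.base_seed + it)
        train = rng.choice(fams, size=n_train, replace=False)
        test = np.setdiff1d(fams, train)
        Y = _mask_for_scheme(scheme, blups, primary, train, test)
        gebv = _fit_predict(scheme, Y, K, test, seed=scheme.base_seed + it)
        r_p, bias = predictive_ability_and_bias(gebv, blups.loc[test, primary])
        rows.append((it, r_p, bias))
        test_sets.append(list(test))
    table = pd.DataFrame(rows, columns=["iteration", "r_p", "bias"])
    return CVResult(scheme=scheme, primary=primary, table=table, test_ids=test_sets)


def _check_traits(blups: pd.DataFrame, primary: str, scheme: CVScheme) -> None:
    if primary not in blups.columns:
        raise ValueError(f"primary trait {primary!r} not in BLUP table")
    if scheme.is_multitrait:
        if scheme.secondary not in blups.columns:
            raise ValueError(f"secondary trait {scheme.secondary!r} not in BLUP table")
        if scheme.secondary == primary:
            raise ValueError("secondary trait must differ from the primary")


def leave_one_population_out(
    blups: pd.DataFrame,
    K: GRM,
    pop_labels: pd.Series,
    primary: str,
    scheme: CVScheme,
) -> pd.DataFrame:
    """Across-population prediction: train on all but one population.

    One deterministic fold per population (seed = base_seed + fold
    index); populations with fewer than 3 phenotyped families are skipped
    with a warning.  Returns a tidy per-fold table.
    """
    _check_traits(blups, primary, scheme)
    pops = list(pd.unique(pop_labels))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    rows = []
    for fold, pop in enumerate(pops):
        fams = blups.index[blups[primary].notna()]
        test = np.array([f for f in fams if pop_labels.get(f) == pop])
        train = np.array([f for f in fams if pop_labels.get(f) != pop])
        if test.size < 3:
            logger.warning("population %r skipped: fewer than 3 families", pop)
            continue
        if train.size < 3:
            logger.warning("population %r skipped: fewer than 3 training families", pop)
            continue
        Y = _mask_for_scheme(scheme, blups, primary, train, test)
        gebv = _fit_predict(scheme, Y, K, test, seed=scheme.base_seed + fold)
        r_p, bias = predictive_ability_and_bias(gebv, blups.loc[test, primary])
        rows.append((pop, test.size, r_p, bias))
    return pd.DataFrame(rows, columns=["population", "n_test", "r_p", "bias"])


def training_size_sweep(
    blups: pd.DataFrame,
    K: GRM,
    primary: str,
    scheme: CVScheme,
    fractions: "np.ndarray | None" = None,
    test_fraction: float = 0.2,
    n_replicates: int = 50,
    min_train: int = 10,
) -> pd.DataFrame:
    """Predictive ability as a function of training-set size.

    Per replicate: a test set of ``test_fraction`` of the phenotyped
    families is drawn first; nested training subsets of each requested
    size (fractions of the remaining pool) are taken from one permutation
    of the remainder, so curves within a replicate are nested.  The model
    at each size sees only the training subset and the test set.  Sizes
    below ``min_train`` families are skipped with a warning.  Returns a
    tidy table (replicate × fraction) of abilities and biases.
    """
    _check_traits(blups, primary, scheme)
    if fractions is None:
        fractions = np.round(np.arange(0.1, 1.01, 0.1), 10)
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions <= 0) | (fractions > 1)):
        raise ValueError("fractions are proportions of the non-test pool, in (0, 1]")
    fams = blups.index[blups[primary].notna()].to_numpy()
    n = fams.size
    n_test = int(round(test_fraction * n))
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(scheme.base_seed + rep)
        test = rng.choice(fams, size=n_test, replace=False)
        pool = rng.permutation(np.setdiff1d(fams, test))
        for frac in fractions:
            n_train = int(round(frac * pool.size))
            if n_train < min_train:
                logger.warning("size fraction %.2f skipped: < %d families", frac, min_train)
                continue
            train = pool[:n_train]
            subset = np.concatenate([train, test])
            sub_blups = blups.loc[subset]
            sub_K = K.subset(subset)
            Y = _mask_for_scheme(scheme, sub_blups, primary, train, test)
            gebv = _fit_predict(scheme, Y, sub_K, test, seed=scheme.base_seed + rep)
            r_p, bias = predictive_ability_and_bias(gebv, blups.loc[test, primary])
            rows.append((rep, float(frac), n_train, r_p, bias))
    return pd.DataFrame(rows, columns=["replicate", "fraction", "n_train", "r_p", "bias"])


def percent_improvement(result_mt: CVResult, result_st: CVResult) -> float:
    """100 × (mean r_p(MT) − mean r_p(ST)) / mean r_p(ST), paired splits."""
    return 100.0 * (result_mt.mean - result_st.mean) / result_st.mean
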