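"""Simulation of multi-population half-sib trials with known genetic truth.

The generator emulates a forage-breeding training population: maternal
parents of half-sib families drawn from several discrete breeding
populations (Balding-Nichols allele-frequency model at a specified FST,
with one pair of populations sharing recent lineage), genotyped at low
read depth by genotyping-by-sequencing, and phenotyped in replicated
row-column trials at multiple locations over repeated seasonal measures.

Every stage records its truth (ancestral and per-population allele
frequencies, integer genotypes, breeding values, fixed-effect offsets) so
that downstream estimators — the depth-aware GRM, REML variance
components, genomic heritability, genetic correlations and the
cross-validation schemes — can be tested against known values.

Randomness uses a single master seed; child streams are spawned in a fixed
documented order (allele frequencies & genotypes, read observation,
breeding values, trial effects), so any subset of the pipeline is
replayable in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtgp.genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_genotypes",
    "simulate_breeding_values",
    "simulate_plot_trial",
    "simulate_study",
]

#: Random-effect variance-component names of the plot model, in model order.
ENV_VC_NAMES = ("gs", "gm", "rep", "row", "col", "resid")


@dataclass
class SimConfig:
    """Configuration of a synthetic half-sib trial study.

    Genetic truth is carried by ``G0_true`` (t × t genetic covariance of
    family effects, trait units²); non-genetic plot variance components by
    ``env_vc`` (name → per-trait variances, names from
    :data:`ENV_VC_NAMES`: family×location ``gs``, family×measure ``gm``,
    replicate ``rep``, row ``row``, column ``col``, residual ``resid``).
    """

    n_families: int = 463
    n_snps: int = 3000
    n_pops: int = 5
    fst: float = 0.10
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 6.0
    missing_rate: float = 0.05
    n_traits: int = 2
    G0_true: np.ndarray = field(default_factory=lambda: np.eye(2))
    env_vc: dict[str, np.ndarray] = field(default_factory=dict)
    n_locations: int = 2
    n_measures: int = 2
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.G0_true = np.atleast_2d(np.asarray(self.G0_true, dtype=float))
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.G0_true.shape != (self.n_traits, self.n_traits):
            raise ValueError("G0_true must be n_traits × n_traits")
        if not np.allclose(self.G0_true, self.G0_true.T):
            raise ValueError("G0_true must be symmetric")
        if np.min(np.linalg.eigvalsh(self.G0_true)) < -1e-10:
            raise ValueError("G0_true must be positive semi-definite")
        if not self.env_vc:
            self.env_vc = self.default_env_vc()
        vc = {}
        for name in ENV_VC_NAMES:
            if name not in self.env_vc:
                raise ValueError(f"missing variance component '{name}' in env_vc")
            v = np.broadcast_to(np.asarray(self.env_vc[name], dtype=float), (self.n_traits,)).copy()
            if np.any(v < 0):
                raise ValueError(f"negative variance for component '{name}'")
            vc[name] = v
        extra = set(self.env_vc) - set(ENV_VC_NAMES)
        if extra:
            raise ValueError(f"unknown variance component(s): {sorted(extra)}")
        self.env_vc = vc

    def default_env_vc(self) -> dict[str, np.ndarray]:
        """Non-genetic variances scaled to the per-trait genetic variance.

        Defaults mirror the relative magnitudes seen in replicated
        multi-harvest ryegrass yield trials: family×location ≈ 0.67 σ²g,
        family×measure ≈ 0.12 σ²g, residual ≈ 11.5 σ²g, with modest
        replicate/row/column nuisance variation (0.25 σ²g each).
        """
        sg = np.diag(self.G0_true).astype(float)
        return {
            "gs": 0.67 * sg,
            "gm": 0.12 * sg,
            "rep": 0.25 * sg,
            "row": 0.25 * sg,
            "col": 0.25 * sg,
            "resid": 11.5 * sg,
        }

    @classmethod
    def from_heritability(
        cls,
        h2: "np.ndarray | list[float]",
        rg: float = 0.0,
        sigma2_g: "np.ndarray | list[float] | float" = 1.0,
        **kwargs,
    ) -> "SimConfig":
        """Build a config whose genomic heritabilities equal ``h2``.

        Keeps the default family×location and family×measure ratios
        (0.67 σ²g and 0.12 σ²g) and solves the residual variance from the
        genomic-heritability identity
        h² = σ²g / (σ²g + σ²gs/s + σ²gm/m + σ²ε/(s·m·b)).  If a target h²
        is too high for those interaction ratios the interactions are
        shrunk proportionally so a non-negative residual exists.
        """
        h2 = np.atleast_1d(np.asarray(h2, dtype=float))
        t = h2.size
        sg = np.broadcast_to(np.asarray(sigma2_g, dtype=float), (t,)).copy()
        if np.any((h2 <= 0) | (h2 >= 1)):
            raise ValueError("heritabilities must lie in (0, 1)")
        R = np.eye(t) + rg * (np.ones((t, t)) - np.eye(t))
        sd = np.sqrt(sg)
        G0 = R * np.outer(sd, sd)
        cfg_tmp = dict(kwargs)
        s = cfg_tmp.get("n_locations", 2)
        m = cfg_tmp.get("n_measures", 2)
        b = cfg_tmp.get("n_reps", 3)
        # an interaction with a single-level factor is confounded with the
        # family main effect; give it zero variance so the target h2 holds
        gs = 0.67 * sg if s > 1 else 0.0 * sg
        gm = 0.12 * sg if m > 1 else 0.0 * sg
        denom_target = sg / h2
        interaction = gs / s + gm / m
        headroom = denom_target - sg
        shrink = np.minimum(1.0, 0.9 * headroom / np.maximum(interaction, 1e-12))
        gs, gm = gs * shrink, gm * shrink
        resid = (denom_target - sg - gs / s - gm / m) * (s * m * b)
        env = {
            "gs": gs,
            "gm": gm,
            "rep": 0.25 * sg,
            "row": 0.25 * sg,
            "col": 0.25 * sg,
            "resid": resid,
        }
        return cls(n_traits=t, G0_true=G0, env_vc=env, **kwargs)

    def expected_h2(self) -> np.ndarray:
        """Genomic heritability implied by the config, per trait."""
        sg = np.diag(self.G0_true)
        s, m, b = self.n_locations, self.n_measures, self.n_reps
        denom = sg + self.env_vc["gs"] / s + self.env_vc["gm"] / m + self.env_vc["resid"] / (s * m * b)
        return sg / denom

    def seed_streams(self) -> dict[str, np.random.Generator]:
        """Child generators spawned from the master seed, in fixed order."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genotypes", "reads", "breeding_values", "trial")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for oracle-based testing."""

    true_allele_freqs: np.ndarray  # n_pops × n_snps
    ancestral_freqs: np.ndarray  # n_snps
    true_genotypes: np.ndarray  # n_families × n_snps, integers {0,1,2}
    pop_labels: np.ndarray  # n_families, strings
    true_breeding_values: "pd.DataFrame | None" = None  # family × trait
    fixed_offsets: "dict | None" = None


@dataclass
class SimStudy:
    """Bundle returned by :func:`simulate_study`: data plus truth."""

    genotypes: GenotypeMatrix
    truth: SimTruth
    breeding_values: pd.DataFrame  # family × trait, trait columns "T1", ...
    plots: pd.DataFrame  # long-format plot records
    kinship_true: np.ndarray  # VanRaden GRM of the true genotypes
    config: SimConfig


def _population_sizes(n_families: int, n_pops: int) -> np.ndarray:
    sizes = np.full(n_pops, n_families // n_pops)
    sizes[: n_families % n_pops] += 1
    return sizes


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, fst: float) -> np.ndarray:
    """Draw drifted frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F)."""
    if fst == 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate GBS genotype observations for the maternal parents.

    Ancestral frequencies are uniform on ``cfg.maf_range``; each
    population's frequencies drift from them under the Balding-Nichols
    beta model at ``cfg.fst``.  When there are >= 2 populations the last
    two share recent lineage: their frequencies drift in two stages via a
    common intermediate population (FST/2 at each stage), which places
    them closest together in relationship space.  True genotypes are
    Binomial(2, p_pop).  Read depth per call is Poisson(``mean_depth``),
    zeroed with probability ``missing_rate``; alternate-allele reads are
    Binomial(depth, dosage/2) and the observed fractional dosage is
    2·alt/depth (missing where depth 0).
    """
    streams = cfg.seed_streams()
    rng_g, rng_r = streams["genotypes"], streams["reads"]
    n, m, npop = cfg.n_families, cfg.n_snps, cfg.n_pops
    lo, hi = cfg.maf_range

    p_anc = rng_g.uniform(lo, hi, size=m)
    pop_freqs = np.empty((npop, m))
    shared = (npop - 2, npop - 1) if npop >= 2 else ()
    if shared:
        # two-stage drift for the shared-lineage pair: ancestral -> common
        # intermediate -> each population, FST/2 per stage
        half = cfg.fst / 2.0
        p_mid = _balding_nichols(rng_g, p_anc, half)
    for k in range(npop):
        if k in shared:
            pop_freqs[k] = _balding_nichols(rng_g, p_mid, half)
        else:
            pop_freqs[k] = _balding_nichols(rng_g, p_anc, cfg.fst)
    np.clip(pop_freqs, 1e-6, 1.0 - 1e-6, out=pop_freqs)

    sizes = _population_sizes(n, npop)
    pop_idx = np.repeat(np.arange(npop), sizes)
    geno = rng_g.binomial(2, pop_freqs[pop_idx, :]).astype(np.int8)

    depth = rng_r.poisson(cfg.mean_depth, size=(n, m)).astype(float)
    if cfg.missing_rate > 0:
        depth[rng_r.random((n, m)) < cfg.missing_rate] = 0.0
    alt = rng_r.binomial(depth.astype(np.int64), geno / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dosage = np.where(depth > 0, 2.0 * alt / np.maximum(depth, 1.0), np.nan)

    pop_labels = np.array([f"B{k + 1}" for k in pop_idx])
    gm = GenotypeMatrix(dosages=dosage, depths=depth)
    truth = SimTruth(
        true_allele_freqs=pop_freqs,
        ancestral_freqs=p_anc,
        true_genotypes=geno.astype(np.int64),
        pop_labels=pop_labels,
    )
    return gm, truth


def _psd_factor(a: np.ndarray, name: str, repair: bool = False) -> np.ndarray:
    """Symmetric square root via eigendecomposition; optionally repair PSD."""
    w, v = np.linalg.eigh(a)
    if np.min(w) < -1e-8 * max(1.0, np.max(np.abs(w))):
        if not repair:
            raise ValueError(f"{name} is not positive semi-definite")
        warnings.warn(f"{name} not PSD; repaired by clipping negative eigenvalues")
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_breeding_values(
    K: np.ndarray,
    G0_true: np.ndarray,
    seed: "int | np.random.Generator" = 0,
    repair: bool = False,
) -> np.ndarray:
    """Draw family breeding values u ~ MVN(0, G0_true ⊗ K), returned n × t.

    Column-major vec of the returned matrix has covariance G0_true ⊗ K:
    trait columns share the relationship structure K and covary with the
    genetic covariance G0_true.
    """
    K = np.asarray(K, dtype=float)
    G0 = np.atleast_2d(np.asarray(G0_true, dtype=float))
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be square symmetric")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Lk = _psd_factor(K, "K", repair=True)
    Lg = _psd_factor(G0, "G0_true", repair=repair)
    z = rng.standard_normal((K.shape[0], G0.shape[0]))
    return Lk @ z @ Lg.T


def _grid_shape(n_plots: int) -> tuple[int, int]:
    rows = int(np.ceil(np.sqrt(n_plots)))
    cols = int(np.ceil(n_plots / rows))
    return rows, cols


def simulate_plot_trial(
    u: np.ndarray,
    cfg: SimConfig,
    pop_labels: "np.ndarray | None" = None,
    rng: "np.random.Generator | None" = None,
) -> pd.DataFrame:
    """Generate long-format plot records from family breeding values.

    One record per family × location × measure × replicate × trait.  Each
    record is the sum of the overall mean, fixed location / measure /
    population offsets (drawn once from N(0, 1) and recorded in
    ``DataFrame.attrs['fixed_offsets']``), the family breeding value, and
    i.i.d. normal random effects at the variances in ``cfg.env_vc``:
    family×location, family×measure, replicate, row, column and residual.
    Families are laid out on a fresh row-column grid per (location,
    replicate); row/column effects are redrawn per measure.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[0] == 1 and cfg.n_families > 1:
        u = u.T
    n, t = u.shape
    if t != cfg.n_traits:
        raise ValueError("breeding-value matrix does not match cfg.n_traits")
    if rng is None:
        rng = cfg.seed_streams()["trial"]
    if pop_labels is None:
        sizes = _population_sizes(n, cfg.n_pops)
        pop_labels = np.array([f"B{k + 1}" for k in np.repeat(np.arange(cfg.n_pops), sizes)])
    pops, pop_idx = np.unique(pop_labels, return_inverse=True)
    s, m, b = cfg.n_locations, cfg.n_measures, cfg.n_reps
    vc = cfg.env_vc

    mu = rng.standard_normal(t)
    loc_off = rng.standard_normal((s, t))
    meas_off = rng.standard_normal((m, t))
    pop_off = rng.standard_normal((len(pops), t))

    gs = rng.standard_normal((n, s, t)) * np.sqrt(vc["gs"])
    gmx = rng.standard_normal((n, m, t)) * np.sqrt(vc["gm"])
    rep_eff = rng.standard_normal((s, m, b, t)) * np.sqrt(vc["rep"])

    n_rows, n_cols = _grid_shape(n)
    # plot positions: one permutation per (location, replicate), reused
    # across measures (the physical layout does not change between harvests)
    pos = np.empty((s, b, n), dtype=np.int64)
    for i_s in range(s):
        for i_b in range(b):
            pos[i_s, i_b] = rng.permutation(n)
    row_of = pos // n_cols
    col_of = pos % n_cols
    row_eff = rng.standard_normal((s, m, b, n_rows, t)) * np.sqrt(vc["row"])
    col_eff = rng.standard_normal((s, m, b, n_cols, t)) * np.sqrt(vc["col"])
    resid = rng.standard_normal((n, s, m, b, t)) * np.sqrt(vc["resid"])

    fam = np.arange(n)
    F, S, M, B = np.meshgrid(fam, np.arange(s), np.arange(m), np.arange(b), indexing="ij")
    F, S, M, B = F.ravel(), S.ravel(), M.ravel(), B.ravel()
    R = row_of[S, B, F]
    C = col_of[S, B, F]

    frames = []
    fam_ids = np.array([f"F{i + 1:04d}" for i in range(n)])
    for j in range(t):
        y = (
            mu[j]
            + loc_off[S, j]
            + meas_off[M, j]
            + pop_off[pop_idx[F], j]
            + u[F, j]
            + gs[F, S, j]
            + gmx[F, M, j]
            + rep_eff[S, M, B, j]
            + row_eff[S, M, B, R, j]
            + col_eff[S, M, B, C, j]
            + resid[F, S, M, B, j]
        )
        frames.append(
            pd.DataFrame(
                {
                    "family": fam_ids[F],
                    "population": pop_labels[F],
                    "location": np.char.add("L", (S + 1).astype(str)),
                    "measure": np.char.add("M", (M + 1).astype(str)),
                    "replicate": B + 1,
                    "row": R + 1,
                    "column": C + 1,
                    "trait": f"T{j + 1}",
                    "value": y,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    # realized variances of the drawn effects (per trait) — the sharpest
    # oracle for variance-component recovery on a single seed
    out.attrs["realized_vc"] = {
        "gs": gs.reshape(-1, t).var(axis=0),
        "gm": gmx.reshape(-1, t).var(axis=0),
        "rep": rep_eff.reshape(-1, t).var(axis=0),
        "row": row_eff.reshape(-1, t).var(axis=0),
        "col": col_eff.reshape(-1, t).var(axis=0),
        "resid": resid.reshape(-1, t).var(axis=0),
        "family": u.var(axis=0),
    }
    out.attrs["fixed_offsets"] = {
        "mu": mu,
        "location": loc_off,
        "measure": meas_off,
        "population": pop_off,
    }
    return out


def vanraden_grm(genotypes: np.ndarray, freqs: "np.ndarray | None" = None) -> np.ndarray:
    """Plain VanRaden GRM of complete integer/fractional dosages.

    K = (X − 2p)(X − 2p)' / Σ 2p(1−p); used here as the truth kernel for
    breeding-value simulation and as a high-depth reference in tests.
    """
    X = np.asarray(genotypes, dtype=float)
    p = X.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    Xc = X - 2.0 * p
    denom = np.sum(2.0 * p * (1.0 - p))
    return (Xc @ Xc.T) / denom


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Run the full generator: genotypes → truth GRM → breeding values → plots."""
    gm, truth = simulate_genotypes(cfg)
    K_true = vanraden_grm(truth.true_genotypes)
    streams = cfg.seed_streams()
    u = simulate_breeding_values(K_true, cfg.G0_true, seed=streams["breeding_values"])
    fam_ids = gm.sample_ids
    trait_ids = [f"T{j + 1}" for j in range(cfg.n_traits)]
    u_df = pd.DataFrame(u, index=pd.Index(fam_ids, name="family"), columns=trait_ids)
    plots = simulate_plot_trial(u, cfg, pop_labels=truth.pop_labels, rng=streams["trial"])
    truth.true_breeding_values = u_df
    truth.fixed_offsets = plots.attrs["fixed_offsets"]
    return SimStudy(
        genotypes=gm,
        truth=truth,
        breeding_values=u_df,
        plots=plots,
        kinship_true=K_true,
        config=cfg,
    )
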