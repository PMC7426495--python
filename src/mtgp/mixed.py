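"""Stage-1 linear mixed model for replicated half-sib plot trials.

The plot model decomposes a phenotypic record into an overall mean, fixed
location / measure / population (and optional check) effects, and random
family, family×location, family×measure, replicate, row and column
effects plus residual:

    y = mu + g_i + s_m + (gs)_im + (gm)_in + p_o + b_onml + r_onmlj
        + c_onmlk + eps

The family term may carry a genomic relationship structure
g ~ N(0, K sigma2_g); all other random terms are i.i.d. normal.  Variance
components are estimated by average-information REML with EM fallback,
solved through Henderson's mixed-model equations; family BLUPs are the
solutions of those equations at the converged variances.

Genomic heritability of family means follows
h2_g = sigma2_g / (sigma2_g + sigma2_gs/s + sigma2_gm/m
                   + sigma2_eps/(s*m*b)),
with s, m, b the numbers of locations, measures and replicates of the
fitted data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from mtgp.grm import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "RandomTerm",
    "HalfSibTrialModel",
    "TrialResults",
    "fit_stage1",
    "genomic_heritability",
    "blup_correlation",
]

#: canonical stage-1 random terms: name -> factor columns crossed to form levels
_RANDOM_FACTORS = {
    "family": ("family",),
    "gs": ("family", "location"),
    "gm": ("family", "measure"),
    "rep": ("location", "measure", "replicate"),
    "row": ("location", "measure", "replicate", "row"),
    "col": ("location", "measure", "replicate", "column"),
}


@dataclass
class RandomTerm:
    """One random term: crossed factors and an optional covariance structure."""

    name: str
    factors: tuple[str, ...]
    structure: "np.ndarray | None" = None  # None = identity
    structure_ids: "list[str] | None" = None  # level order of `structure`


@dataclass
class ModelSpec:
    """Fixed factors and random terms of the stage-1 plot model."""

    fixed: tuple[str, ...] = ("location", "measure", "population")
    random: list[RandomTerm] = field(default_factory=list)

    @classmethod
    def default(cls, data: pd.DataFrame, grm: "GRM | None" = None) -> "ModelSpec":
        """Eq.-style spec adapted to the columns and factor levels present.

        Terms whose factors are absent or single-level are dropped (e.g. a
        one-location trial has no family×location term and no fixed
        location effect).
        """
        fixed = []
        for f in ("location", "measure", "population"):
            if f in data.columns and data[f].nunique() > 1:
                fixed.append(f)
        random: list[RandomTerm] = []
        for name, factors in _RANDOM_FACTORS.items():
            if any(f not in data.columns for f in factors):
                continue
            if name == "gs" and data["location"].nunique() < 2:
                continue
            if name == "gm" and data["measure"].nunique() < 2:
                continue
            n_levels = data.groupby(list(factors), observed=True).ngroups
            if n_levels < 2:
                logger.warning("random term %r dropped: fewer than 2 levels", name)
                continue
            if name == "family" and grm is not None:
                random.append(
                    RandomTerm(name, factors, structure=grm.values, structure_ids=list(grm.sample_ids))
                )
            else:
                random.append(RandomTerm(name, factors))
        return cls(fixed=tuple(fixed), random=random)


def _one_hot(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = codes.size
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent fixed-effect columns (QR with pivoting)."""
    if X.shape[1] == 0:
        return X, names
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
        logger.warning("dropped aliased fixed-effect columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


class HalfSibTrialModel:
    """REML mixed model for one trait of a long-format plot table.

    Parameters
    ----------
    data : DataFrame
        Plot records with columns ``family, location, measure, replicate,
        row, column, value`` (plus optional ``population`` and ``check``).
        If a ``trait`` column is present it must hold a single trait.
    grm : GRM, optional
        Genomic relationship structure for the family term (genomic fit);
        identity structure when omitted.
    spec : ModelSpec, optional
        Overrides the default term set.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grm: "GRM | None" = None,
        spec: "ModelSpec | None" = None,
    ) -> None:
        data = data.copy()
        if "trait" in data.columns:
            traits = data["trait"].unique()
            if len(traits) > 1:
                raise ValueError("one trait per model; subset the table first")
        required = {"family", "replicate", "value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        if data["value"].isna().any():
            data = data.dropna(subset=["value"])
        self.data = data.reset_index(drop=True)
        self.grm = grm
        self.spec = spec if spec is not None else ModelSpec.default(self.data, grm)
        self._build_design()

    # -- design -----------------------------------------------------------
    def _build_design(self) -> None:
        d = self.data
        n = len(d)
        self.y = d["value"].to_numpy(dtype=float)

        check_mask = np.zeros(n, dtype=bool)
        if "check" in d.columns:
            check_mask = d["check"].fillna(False).astype(bool).to_numpy()
        self._check_mask = check_mask

        cols = [np.ones(n)]
        names = ["intercept"]
        for f in self.spec.fixed:
            levels = pd.unique(d[f])
            codes = pd.Categorical(d[f], categories=levels).codes
            for j, lev in enumerate(levels[1:], start=1):
                cols.append((codes == j).astype(float))
                names.append(f"{f}[{lev}]")
        if check_mask.any():
            # repeated checks: a fixed class per check family
            chk = d.loc[check_mask, "family"]
            for lev in pd.unique(chk):
                cols.append(((d["family"] == lev) & check_mask).astype(float))
                names.append(f"check[{lev}]")
        X = np.column_stack(cols)
        self.X, self.fixed_names = _drop_aliased(X, names)

        self.Z: list[sp.csr_matrix] = []
        self.terms: list[RandomTerm] = []
        self.level_labels: list[list] = []
        self._struct_inv: list["np.ndarray | None"] = []
        self._struct_logdet: list[float] = []
        genetic = {"family", "gs", "gm"}
        for term in self.spec.random:
            key = d[list(term.factors)].astype(str).agg("|".join, axis=1)
            if term.name in genetic and check_mask.any():
                key = key.where(~check_mask, other=None)
            present = key.dropna()
            if term.name == "family" and term.structure is not None:
                fams = pd.unique(present)
                order = [s for s in term.structure_ids if s in set(fams)]
                extra = set(fams) - set(order)
                if extra:
                    raise KeyError(f"families absent from GRM: {sorted(extra)[:5]}")
                levels = order
                idx = [term.structure_ids.index(s) for s in order]
                A = term.structure[np.ix_(idx, idx)]
                w, V = np.linalg.eigh(A)
                shift = max(0.0, 1e-8 - float(w[0]))
                if shift > 0:
                    logger.info("family structure bent by +%.3g for inversion", shift)
                    w = w + shift
                Ainv = (V / w) @ V.T
                logdet = float(np.sum(np.log(w)))
            else:
                levels = list(pd.unique(present))
                Ainv, logdet = None, 0.0
            lookup = {lev: j for j, lev in enumerate(levels)}
            codes = np.array([lookup.get(k, -1) for k in key.fillna("\0missing")])
            rows = np.flatnonzero(codes >= 0)
            Zi = sp.csr_matrix(
                (np.ones(rows.size), (rows, codes[rows])), shape=(n, len(levels))
            )
            if len(levels) < 2:
                logger.warning("random term %r dropped: fewer than 2 levels", term.name)
                continue
            self.Z.append(Zi)
            self.terms.append(term)
            self.level_labels.append(levels)
            self._struct_inv.append(Ainv)
            self._struct_logdet.append(logdet)

        if not self.terms:
            raise ValueError("no usable random terms")
        self.W = sp.hstack([sp.csr_matrix(self.X)] + self.Z, format="csr")
        self.p = self.X.shape[1]
        self.q_sizes = [Zi.shape[1] for Zi in self.Z]
        offsets = np.cumsum([self.p] + self.q_sizes)
        self._slices = [slice(a, b) for a, b in zip(offsets[:-1], offsets[1:])]
        self.WtW = (self.W.T @ self.W).toarray()
        self.Wty = self.W.T @ self.y
        self.yty = float(self.y @ self.y)

    # -- REML -------------------------------------------------------------
    def fit(
        self,
        start: "np.ndarray | None" = None,
        max_iter: int = 200,
        tol_loglik: float = 1e-8,
        tol_params: float = 1e-6,
    ) -> "TrialResults":
        """Estimate variance components by AI-REML with EM fallback.

        Iterates average-information (quasi-Newton) updates; whenever an AI
        step would leave the parameter space (a variance below its lower
        bound of 1e-8 × phenotypic variance) or fails to improve the
        restricted likelihood, an EM step is taken instead.  Converges when
        |Δ logL| < ``tol_loglik`` or the relative parameter change is below
        ``tol_params``.
        """
        n, p = len(self.y), self.p
        k = len(self.terms)
        vary = float(np.var(self.y))
        lb = 1e-8 * vary
        if start is None:
            theta = np.full(k + 1, 0.5 * vary / max(k, 1))
            theta[-1] = 0.5 * vary
        else:
            theta = np.asarray(start, dtype=float).copy()
        theta = np.maximum(theta, lb)

        state = self._solve_mme(theta)
        ll = state["loglik"]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            score, AI = self._score_and_ai(theta, state)
            step_ok = False
            # components pinned at the bound that want to shrink further are
            # held fixed; the AI step is taken in the free coordinates, with
            # step-halving if the restricted likelihood would decrease
            free = ~((theta <= lb * (1 + 1e-6)) & (score < 0))
            try:
                if free.any():
                    delta = np.zeros_like(theta)
                    delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                    for _ in range(6):
                        cand = np.maximum(theta + delta, lb)
                        if np.all(np.isfinite(cand)):
                            cand_state = self._solve_mme(cand)
                            if (
                                np.isfinite(cand_state["loglik"])
                                and cand_state["loglik"] >= ll - 1e-10
                            ):
                                step_ok = True
                                break
                        delta *= 0.5
            except np.linalg.LinAlgError:
                pass
            if not step_ok:
                cand = np.maximum(self._em_update(theta, state), lb)
                cand_state = self._solve_mme(cand)
            dl = cand_state["loglik"] - ll
            rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), lb))
            theta, state, ll = cand, cand_state, cand_state["loglik"]
            if abs(dl) < tol_loglik or rel < tol_params:
                converged = True
                break
        if not converged:
            logger.warning("REML did not converge in %d iterations", max_iter)

        _, AI = self._score_and_ai(theta, state)
        try:
            se = np.sqrt(np.clip(np.diag(np.linalg.inv(AI)), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(k + 1, np.nan)

        sol = state["sol"]
        blup_series = {}
        for i, term in enumerate(self.terms):
            u = sol[self._slices[i]]
            blup_series[term.name] = pd.Series(u, index=self.level_labels[i])
        counts = {
            "s": self.data["location"].nunique() if "location" in self.data else 1,
            "m": self.data["measure"].nunique() if "measure" in self.data else 1,
            "b": self.data["replicate"].nunique(),
        }
        return TrialResults(
            model=self,
            params=pd.Series(theta, index=[t.name for t in self.terms] + ["resid"]),
            bse=pd.Series(se, index=[t.name for t in self.terms] + ["resid"]),
            loglik=ll,
            converged=converged,
            n_iter=n_iter,
            fe=pd.Series(sol[:p], index=self.fixed_names),
            random_effects=blup_series,
            design_counts=counts,
        )

    # internals ------------------------------------------------------------
    def _assemble_C(self, theta: np.ndarray) -> np.ndarray:
        sig_e = theta[-1]
        C = self.WtW.copy()
        for i, sl in enumerate(self._slices):
            lam = sig_e / theta[i]
            Ainv = self._struct_inv[i]
            if Ainv is None:
                C[sl, sl] += lam * np.eye(self.q_sizes[i])
            else:
                C[sl, sl] += lam * Ainv
        return C

    def _solve_mme(self, theta: np.ndarray) -> dict:
        n, p = len(self.y), self.p
        sig_e = theta[-1]
        C = self._assemble_C(theta)
        try:
            cho = sla.cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.mean(np.diag(C))
            logger.warning("singular mixed-model equations; ridge %.3g added", ridge)
            C = C + ridge * np.eye(C.shape[0])
            cho = sla.cho_factor(C, lower=True, check_finite=False)
        sol = sla.cho_solve(cho, self.Wty, check_finite=False)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        yPy = (self.yty - sol @ self.Wty) / sig_e
        q_tot = sum(self.q_sizes)
        neg2ll = (n - p - q_tot) * np.log(sig_e) + logdetC + yPy
        for i, qi in enumerate(self.q_sizes):
            neg2ll += qi * np.log(theta[i]) + self._struct_logdet[i]
        # inverse of C via the Cholesky factor (LAPACK dpotri)
        Cinv, info = sla.lapack.dpotri(cho[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        traces = []
        for i, sl in enumerate(self._slices):
            block = Cinv[sl, sl]
            Ainv = self._struct_inv[i]
            traces.append(float(np.trace(block)) if Ainv is None else float(np.sum(Ainv * block)))
        uAu = []
        for i, sl in enumerate(self._slices):
            u = sol[sl]
            Ainv = self._struct_inv[i]
            uAu.append(float(u @ u) if Ainv is None else float(u @ Ainv @ u))
        resid = self.y - self.W @ sol
        return {
            "sol": sol,
            "cho": cho,
            "loglik": -0.5 * neg2ll,
            "yPy": yPy,
            "traces": traces,
            "uAu": uAu,
            "resid": resid,
        }

    def _em_update(self, theta: np.ndarray, state: dict) -> np.ndarray:
        n, p = len(self.y), self.p
        sig_e = theta[-1]
        new = theta.copy()
        for i, qi in enumerate(self.q_sizes):
            new[i] = (state["uAu"][i] + state["traces"][i] * sig_e) / qi
        new[-1] = (self.yty - state["sol"] @ self.Wty) / (n - p)
        return new

    def _score_and_ai(self, theta: np.ndarray, state: dict) -> tuple[np.ndarray, np.ndarray]:
        n, p = len(self.y), self.p
        k = len(self.terms)
        sig_e = theta[-1]
        resid = state["resid"]
        Py = resid / sig_e

        tr_PVi = np.empty(k)
        yPViPy = np.empty(k)
        ws = []
        for i, sl in enumerate(self._slices):
            lam = sig_e / theta[i]
            tr_PVi[i] = (self.q_sizes[i] - lam * state["traces"][i]) / theta[i]
            yPViPy[i] = state["uAu"][i] / theta[i] ** 2
            ws.append(self.Z[i] @ state["sol"][sl] / theta[i])
        tr_P = (n - p - float(np.dot(theta[:k], tr_PVi))) / sig_e
        yPPy = float(resid @ resid) / sig_e**2
        ws.append(Py)

        score = np.empty(k + 1)
        score[:k] = -0.5 * (tr_PVi - yPViPy)
        score[-1] = -0.5 * (tr_P - yPPy)

        Wmat = np.column_stack(ws)
        WtB = self.W.T @ Wmat
        solB = sla.cho_solve(state["cho"], WtB, check_finite=False)
        PB = (Wmat - self.W @ solB) / sig_e
        AI = 0.5 * (Wmat.T @ PB)
        AI = 0.5 * (AI + AI.T)
        return score, AI


@dataclass
class TrialResults:
    """Converged stage-1 fit: variance components, BLUPs, heritability."""

    model: HalfSibTrialModel
    params: pd.Series  # sigma2 per random term + "resid"
    bse: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    fe: pd.Series
    random_effects: dict[str, pd.Series]
    design_counts: dict[str, int]

    @property
    def blups(self) -> pd.Series:
        """Predicted family effects ĝ_i (one value per non-check family)."""
        s = self.random_effects["family"].copy()
        s.index.name = "family"
        return s

    def genomic_heritability(
        self, s: "int | None" = None, m: "int | None" = None, b: "int | None" = None
    ) -> float:
        """h²_g of family means from the fitted variance components."""
        s = self.design_counts["s"] if s is None else s
        m = self.design_counts["m"] if m is None else m
        b = self.design_counts["b"] if b is None else b
        return genomic_heritability(self.params.to_dict(), s=s, m=m, b=b)

    def summary(self) -> str:
        lines = [
            "Stage-1 half-sib trial model (REML)",
            f"  observations: {len(self.model.y)}   fixed effects: {self.model.p}",
            f"  converged: {self.converged} in {self.n_iter} iterations; "
            f"REML logL = {self.loglik:.3f}",
            "",
            f"  {'term':<10}{'sigma2':>12}{'SE':>12}",
        ]
        for name, v in self.params.items():
            lines.append(f"  {name:<10}{v:>12.4f}{self.bse[name]:>12.4f}")
        try:
            h2 = self.genomic_heritability()
            lines.append("")
            lines.append(f"  genomic heritability h2_g = {h2:.3f}")
        except (KeyError, ZeroDivisionError):
            pass
        return "\n".join(lines)


def genomic_heritability(
    vc: dict[str, float], s: int, m: int, b: int
) -> float:
    """h²_g = σ²g / (σ²g + σ²gs/s + σ²gm/m + σ²ε/(s·m·b)).

    Interaction components absent from ``vc`` (e.g. a single-measure fit
    has no family×measure term) contribute zero.
    """
    sg = vc["family"]
    denom = (
        sg
        + vc.get("gs", 0.0) / s
        + vc.get("gm", 0.0) / m
        + vc["resid"] / (s * m * b)
    )
    if denom <= 0:
        raise ZeroDivisionError("non-positive denominator in heritability")
    return float(sg / denom)


def fit_stage1(
    plots: pd.DataFrame,
    grm: "GRM | None" = None,
    traits: "list[str] | None" = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[str, TrialResults]]:
    """Fit the stage-1 model per trait and assemble the family BLUP table.

    Returns a family × trait DataFrame of BLUPs (the stage-2 response) and
    the per-trait :class:`TrialResults`.
    """
    if "trait" not in plots.columns:
        plots = plots.assign(trait="trait")
    if traits is None:
        traits = list(pd.unique(plots["trait"]))
    results: dict[str, TrialResults] = {}
    cols = {}
    for tr in traits:
        model = HalfSibTrialModel(plots[plots["trait"] == tr], grm=grm)
        res = model.fit(**fit_kwargs)
        results[tr] = res
        cols[tr] = res.blups
    table = pd.DataFrame(cols)
    table.index.name = "family"
    return table, results


def blup_correlation(blups: pd.DataFrame, trait_x: str, trait_y: str) -> float:
    """Genetic correlation proxy: Pearson correlation of paired family BLUPs.

    Families missing either trait are excluded pairwise; at least three
    shared families with non-zero variance in both traits are required.
    """
    pair = blups[[trait_x, trait_y]].dropna()
    if len(pair) < 3:
        raise ValueError("fewer than 3 families shared between traits")
    x, y = pair[trait_x].to_numpy(), pair[trait_y].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the traits")
    return float(np.corrcoef(x, y)[0, 1])
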