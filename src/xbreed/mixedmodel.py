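"""Multi-trait animal-model REML, mixed-model solutions and derived parameters.

The engine fits models of the form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, Gamma_k (x) K_k),
    e ~ N(0, diag(sigma2_e by trait))

where each random term couples an estimable trait-covariance block
``Gamma_k`` (full, or diagonal with the cross-trait covariance
structurally zero) with a fixed relationship matrix ``K_k`` (pedigree
NRM or genomic GRM).  Records are assigned to traits -- in the
across-breed application the same measurement is a different trait in
each breed, so the genomic cross-trait covariance is exactly the
cross-breed genomic covariance and

    r_G = sigma_u(1,2) / sqrt(sigma2_u(1) * sigma2_u(2))

is the genomic correlation, while the pedigree block has its
off-diagonal fixed at zero because disconnected populations share no
ancestors.  The fraction of genetic variance the fitted SNP set fails to
capture ("missing heritability") is

    C_miss = 1 - sigma2_u / (sigma2_u + sigma2_a).

Estimation is average-information REML on the observation covariance
V = sum_k Z_k (Gamma_k (x) K_k) Z_k' + R, with an exact EM step as a
fallback whenever the AI proposal (after step halving) fails to improve
the restricted likelihood, so the restricted log-likelihood trace is
non-decreasing.  Variances are floored at 1e-6 of the phenotypic
variance and trait blocks are kept positive semidefinite by eigenvalue
clipping; identifiability of fixed effects uses drop-first (first level
of every factor constrained to zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .kinship import ConfigurationError, RelationshipMatrix

logger = logging.getLogger(__name__)

RESIDUAL = "__residual__"

#: default variance floor, as a fraction of the phenotypic variance
VARIANCE_FLOOR_FRACTION = 1e-6


class IdentifiabilityError(ValueError):
    """Model structure that cannot be estimated (aliased random terms)."""


class NumericalError(RuntimeError):
    """Singular system encountered while solving the model equations."""


# ---------------------------------------------------------------------------
# Model description
# ---------------------------------------------------------------------------


@dataclass
class RandomTerm:
    """One random effect: a relationship matrix plus a trait-covariance rule.

    ``structure`` is ``"full"`` (all variances and covariances
    estimated) or ``"diagonal"`` (cross-trait covariances structurally
    zero, as for a pedigree term linking disconnected populations).
    """

    name: str
    matrix: RelationshipMatrix
    structure: str = "full"

    def __post_init__(self) -> None:
        if self.structure not in ("full", "diagonal"):
            raise ConfigurationError(
                f"random-term structure must be 'full' or 'diagonal', got {self.structure!r}"
            )


@dataclass
class ModelSpec:
    """Declarative mixed-model description.

    ``trait_column`` maps each record to one trait (``None`` for a
    univariate model); fixed effects are fitted per trait (block-diagonal
    design): an intercept, drop-first dummies for each factor and the
    covariates.
    """

    response: str
    random_terms: tuple
    trait_column: str | None = None
    traits: tuple = ()
    animal_column: str = "animal"
    factors: tuple = ()
    covariates: tuple = ()

    def __post_init__(self) -> None:
        self.random_terms = tuple(self.random_terms)
        if not self.random_terms:
            raise ConfigurationError("at least one random term is required")
        names = [t.name for t in self.random_terms]
        if len(set(names)) != len(names):
            raise ConfigurationError("random-term names must be unique")
        for a in range(len(self.random_terms)):
            for b in range(a + 1, len(self.random_terms)):
                ta, tb = self.random_terms[a], self.random_terms[b]
                if (
                    ta.structure == tb.structure
                    and ta.matrix.n_animals == tb.matrix.n_animals
                    and np.array_equal(ta.matrix.values, tb.matrix.values)
                ):
                    raise IdentifiabilityError(
                        f"random terms {ta.name!r} and {tb.name!r} share the same "
                        "relationship matrix and covariance structure"
                    )


@dataclass
class VarianceComponents:
    """Estimated (co)variance parameters of a fitted model."""

    traits: tuple
    terms: dict  # name -> (T, T) trait-covariance block
    residual: np.ndarray  # (T,) residual variances
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    variance_floor: np.ndarray | None = None
    standard_errors: dict | None = None  # approximate, from the AI matrix

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def trait_index(self, trait) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None

    def phenotypic_variance(self, trait) -> float:
        t = self.trait_index(trait)
        return float(sum(g[t, t] for g in self.terms.values()) + self.residual[t])

    def at_floor(self, term: str, trait) -> bool:
        t = self.trait_index(trait)
        if self.variance_floor is None:
            return False
        return self.terms[term][t, t] <= self.variance_floor[t] * (1 + 1e-6)

    def validate(self) -> None:
        for name, g in self.terms.items():
            if np.any(np.diag(g) < -1e-12):
                raise ValueError(f"negative variance in term {name!r}")
            w = np.linalg.eigvalsh(g)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValueError(f"trait block of term {name!r} is not PSD")
        if np.any(self.residual < 0):
            raise ValueError("negative residual variance")


@dataclass
class MixedModelSolution:
    """BLUE fixed-effect solutions and BLUP random-effect predictions."""

    beta: pd.Series
    random: dict  # term name -> DataFrame (animals x traits)
    fitted_fixed: pd.Series  # indexed like the used data rows

    def predictions(self, term: str) -> pd.DataFrame:
        return self.random[term]


@dataclass
class ParameterSummary:
    """Per-breed heritability partition and across-breed genomic correlation."""

    table: pd.DataFrame  # index traits, columns h2_P, h2_G, C_miss
    r_G: float


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def build_design(spec: ModelSpec, data: pd.DataFrame):
    """Response, block-diagonal fixed design and bookkeeping for a fit.

    Records with a missing response are excluded.  Records are sorted by
    trait so covariance blocks are contiguous.  Returns a dict with
    ``y, X, labels, trait_slices, traits, animals, rows`` (original row
    labels of the used records, in fit order).
    """
    if spec.response not in data.columns:
        raise ConfigurationError(f"response column {spec.response!r} missing from data")
    keep = data[spec.response].notna()
    if not keep.any():
        raise ConfigurationError("no records with an observed response")
    df = data.loc[keep]
    if spec.trait_column is None:
        traits = (spec.response,)
        trait_idx = np.zeros(len(df), dtype=np.int64)
    else:
        traits = tuple(spec.traits) or tuple(sorted(df[spec.trait_column].unique()))
        lut = {t: i for i, t in enumerate(traits)}
        try:
            trait_idx = df[spec.trait_column].map(lut).to_numpy()
        except KeyError:
            raise ConfigurationError("record with a trait label outside spec.traits")
        if pd.isna(trait_idx).any():
            raise ConfigurationError("record with a trait label outside spec.traits")
        trait_idx = trait_idx.astype(np.int64)
    order = np.argsort(trait_idx, kind="stable")
    df = df.iloc[order]
    trait_idx = trait_idx[order]
    counts = np.bincount(trait_idx, minlength=len(traits))
    if (counts == 0).any():
        empty = traits[int(np.argmin(counts))]
        raise ConfigurationError(f"trait {empty!r} has no records")
    bounds = np.concatenate([[0], np.cumsum(counts)])
    trait_slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(traits))]

    y = df[spec.response].to_numpy(dtype=np.float64)
    cols, labels = [], []
    n = len(df)
    for i, trait in enumerate(traits):
        sl = trait_slices[i]
        ind = np.zeros(n)
        ind[sl] = 1.0
        cols.append(ind)
        labels.append(f"{trait}:(Intercept)")
        for fac in spec.factors:
            levels = pd.unique(df[fac].iloc[sl].astype(str))
            levels = sorted(levels)
            for lev in levels[1:]:  # first level constrained to zero
                col = np.zeros(n)
                col[sl] = (df[fac].iloc[sl].astype(str) == lev).to_numpy(float)
                cols.append(col)
                labels.append(f"{trait}:{fac}={lev}")
        for cov in spec.covariates:
            col = np.zeros(n)
            col[sl] = df[cov].iloc[sl].to_numpy(dtype=np.float64)
            cols.append(col)
            labels.append(f"{trait}:{cov}")
    X = np.column_stack(cols)
    # drop aliased columns (confounded levels) by pivoted QR
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
    if rank < X.shape[1]:
        keep_cols = np.sort(piv[:rank])
        dropped = [labels[j] for j in piv[rank:]]
        logger.info("build_design: dropping aliased fixed-effect columns %s", dropped)
        X = X[:, keep_cols]
        labels = [labels[j] for j in keep_cols]
    return {
        "y": y,
        "X": X,
        "labels": labels,
        "traits": traits,
        "trait_slices": trait_slices,
        "animals": df[spec.animal_column].to_numpy(dtype=object),
        "rows": df.index,
        "data": df,
    }


# ---------------------------------------------------------------------------
# REML internals
# ---------------------------------------------------------------------------


class _Problem:
    """Precomputed quantities for one REML problem."""

    def __init__(self, spec: ModelSpec, design: dict):
        self.spec = spec
        self.y = design["y"]
        self.X = design["X"]
        self.traits = design["traits"]
        self.T = len(self.traits)
        self.slices = design["trait_slices"]
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ConfigurationError("fewer records than fixed-effect parameters")
        self.animals = design["animals"]
        # per-term record-space covariance blocks K[rows_s, rows_t]
        self.blocks = {}
        self.term_q = {}
        for term in spec.random_terms:
            a_idx = term.matrix.indexer(self.animals)
            K = term.matrix.values[np.ix_(a_idx, a_idx)]
            self.term_q[term.name] = term.matrix.n_animals
            for s in range(self.T):
                for t in range(s, self.T):
                    self.blocks[(term.name, s, t)] = K[self.slices[s], self.slices[t]]
        # parameter layout
        self.params = []
        for term in spec.random_terms:
            if term.structure == "diagonal" or self.T == 1:
                self.params += [(term.name, t, t) for t in range(self.T)]
            else:
                for s in range(self.T):
                    for t in range(s, self.T):
                        self.params.append((term.name, s, t))
        self.params += [(RESIDUAL, t, t) for t in range(self.T)]
        self.n_params = len(self.params)
        vy = np.array([np.var(self.y[sl], ddof=1) for sl in self.slices])
        self.pheno_var = np.where(vy > 0, vy, 1.0)
        self.floor = VARIANCE_FLOOR_FRACTION * self.pheno_var

    # -- theta <-> blocks ---------------------------------------------

    def theta_to_components(self, theta: np.ndarray):
        gammas = {t.name: np.zeros((self.T, self.T)) for t in self.spec.random_terms}
        resid = np.zeros(self.T)
        for val, (name, s, t) in zip(theta, self.params):
            if name == RESIDUAL:
                resid[t] = val
            else:
                gammas[name][s, t] = val
                gammas[name][t, s] = val
        return gammas, resid

    def components_to_theta(self, gammas: dict, resid: np.ndarray) -> np.ndarray:
        theta = np.empty(self.n_params)
        for m, (name, s, t) in enumerate(self.params):
            theta[m] = resid[t] if name == RESIDUAL else gammas[name][s, t]
        return theta

    def start_values(self) -> np.ndarray:
        k = len(self.spec.random_terms)
        gammas = {
            t.name: np.diag(0.5 * self.pheno_var / k) for t in self.spec.random_terms
        }
        resid = 0.5 * self.pheno_var
        return self.components_to_theta(gammas, resid)

    def project(self, theta: np.ndarray) -> np.ndarray:
        """Eigenvalue-clip trait blocks onto the PSD cone; floor variances.

        Boundary solutions keep |correlation| = 1 exactly (singular
        block); the identity part of the residual keeps V positive
        definite there.
        """
        gammas, resid = self.theta_to_components(theta)
        for term in self.spec.random_terms:
            g = gammas[term.name]
            if term.structure == "full" and self.T > 1:
                w, V = np.linalg.eigh(g)
                if w.min() < 0:
                    g = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
            np.fill_diagonal(g, np.maximum(np.diag(g), self.floor))
            gammas[term.name] = g
        resid = np.maximum(resid, self.floor)
        return self.components_to_theta(gammas, resid)

    def active_mask(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        """Parameters free to move: not pinned at a variance floor against the gradient."""
        gammas, resid = self.theta_to_components(theta)
        active = np.ones(self.n_params, dtype=bool)
        for m, (name, s, t) in enumerate(self.params):
            if name == RESIDUAL:
                if resid[t] <= self.floor[t] * (1 + 1e-9) and grad[m] < 0:
                    active[m] = False
            elif s == t:
                if gammas[name][t, t] <= self.floor[t] * (1 + 1e-9) and grad[m] < 0:
                    active[m] = False
        return active

    # -- likelihood machinery -----------------------------------------

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        gammas, resid = self.theta_to_components(theta)
        V = np.zeros((self.n, self.n))
        for term in self.spec.random_terms:
            g = gammas[term.name]
            for s in range(self.T):
                for t in range(s, self.T):
                    if g[s, t] == 0.0:
                        continue
                    B = self.blocks[(term.name, s, t)]
                    V[self.slices[s], self.slices[t]] += g[s, t] * B
                    if s != t:
                        V[self.slices[t], self.slices[s]] += g[s, t] * B.T
        d = np.empty(self.n)
        for t in range(self.T):
            d[self.slices[t]] = resid[t]
        V[np.diag_indices_from(V)] += d
        return V

    def state(self, theta: np.ndarray):
        """Factorise V and return the pieces of the restricted likelihood."""
        V = self.build_V(theta)
        L, info = linalg.lapack.dpotrf(V, lower=1, overwrite_a=1)
        if info != 0:
            return None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        Vinv, info = linalg.lapack.dpotri(L, lower=1)
        if info != 0:
            return None
        Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
        W = Vinv @ self.X
        C = self.X.T @ W
        try:
            Cf = linalg.cho_factor(C)
        except linalg.LinAlgError:
            raise NumericalError(
                "singular fixed-effect coefficient block X' V^-1 X"
            ) from None
        logdetC = 2.0 * float(np.sum(np.log(np.diag(Cf[0]))))
        Wty = W.T @ self.y
        beta = linalg.cho_solve(Cf, Wty)
        Py = Vinv @ self.y - W @ beta
        ll = -0.5 * (logdetV + logdetC + float(self.y @ Py))
        return {
            "theta": theta,
            "ll": ll,
            "Vinv": Vinv,
            "W": W,
            "Cf": Cf,
            "Py": Py,
            "beta": beta,
        }

    def loglik(self, theta: np.ndarray) -> float:
        st = self.state(theta)
        return -np.inf if st is None else st["ll"]

    def _apply_P(self, state, v: np.ndarray) -> np.ndarray:
        W = state["W"]
        return state["Vinv"] @ v - W @ linalg.cho_solve(state["Cf"], W.T @ v)

    def _B_dot(self, name, s, t, v: np.ndarray) -> np.ndarray:
        """(symmetrised) dV/d(theta_{name,s,t}) times a vector."""
        out = np.zeros(self.n)
        if name == RESIDUAL:
            out[self.slices[t]] = v[self.slices[t]]
            return out
        B = self.blocks[(name, s, t)]
        out[self.slices[s]] += B @ v[self.slices[t]]
        if s != t:
            out[self.slices[t]] += B.T @ v[self.slices[s]]
        return out

    def derivatives(self, state):
        """Gradient, AI matrix and the per-term F/W matrices for EM."""
        Vinv, W, Cf, Py = state["Vinv"], state["W"], state["Cf"], state["Py"]
        # F[name][s,t] = Py' B_st Py ; TR[name][s,t] = tr(P B_st) (base, unsymmetrised)
        F, TR = {}, {}
        term_names = [t.name for t in self.spec.random_terms] + [RESIDUAL]
        for name in term_names:
            F[name] = np.zeros((self.T, self.T))
            TR[name] = np.zeros((self.T, self.T))
        diagV = np.diag(Vinv)
        for t in range(self.T):
            sl = self.slices[t]
            F[RESIDUAL][t, t] = float(Py[sl] @ Py[sl])
            Wt = W[sl]
            TR[RESIDUAL][t, t] = float(diagV[sl].sum()) - float(
                np.sum(linalg.cho_solve(Cf, Wt.T @ Wt) * np.eye(self.p))
            )
        for term in self.spec.random_terms:
            for s in range(self.T):
                for t in range(s, self.T):
                    B = self.blocks[(term.name, s, t)]
                    f = float(Py[self.slices[s]] @ (B @ Py[self.slices[t]]))
                    trv = float(np.sum(Vinv[self.slices[s], self.slices[t]] * B))
                    M = W[self.slices[s]].T @ (B @ W[self.slices[t]])
                    corr = float(np.trace(linalg.cho_solve(Cf, M.T)))
                    F[term.name][s, t] = F[term.name][t, s] = f
                    TR[term.name][s, t] = TR[term.name][t, s] = trv - corr
        grad = np.empty(self.n_params)
        for m, (name, s, t) in enumerate(self.params):
            sym = 1.0 if s == t else 2.0
            grad[m] = -0.5 * sym * (TR[name][s, t] - F[name][s, t])
        # average information
        ws = [self._B_dot(name, s, t, Py) for (name, s, t) in self.params]
        Pws = [self._apply_P(state, w) for w in ws]
        AI = np.empty((self.n_params, self.n_params))
        for a in range(self.n_params):
            for b in range(a, self.n_params):
                AI[a, b] = AI[b, a] = 0.5 * float(ws[a] @ Pws[b])
        return grad, AI, F, TR

    def em_step(self, theta: np.ndarray, F: dict, TR: dict) -> np.ndarray:
        """Exact EM update (non-decreasing restricted likelihood)."""
        gammas, resid = self.theta_to_components(theta)
        new_gammas = {}
        for term in self.spec.random_terms:
            g = gammas[term.name]
            q = self.term_q[term.name]
            D = F[term.name] - TR[term.name]
            if term.structure == "full" and self.T > 1:
                new_gammas[term.name] = g + g @ D @ g / q
            else:
                ng = g.copy()
                for t in range(self.T):
                    ng[t, t] = g[t, t] + g[t, t] ** 2 * D[t, t] / q
                new_gammas[term.name] = ng
        new_resid = resid.copy()
        for t in range(self.T):
            n_t = self.slices[t].stop - self.slices[t].start
            d = F[RESIDUAL][t, t] - TR[RESIDUAL][t, t]
            new_resid[t] = resid[t] + resid[t] ** 2 * d / n_t
        return self.components_to_theta(new_gammas, new_resid)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    start: VarianceComponents | None = None,
    max_iter: int = 200,
    ll_tol: float = 1e-8,
    par_tol: float = 1e-6,
) -> VarianceComponents:
    """Average-information REML with exact-EM fallback.

    Deterministic given the data and starting values; the returned
    components carry the restricted log-likelihood trace (non-decreasing
    by construction), the iteration count and a convergence flag --
    non-convergence within ``max_iter`` is flagged, never silent.
    """
    design = build_design(spec, data)
    prob = _Problem(spec, design)
    if start is not None:
        theta = prob.components_to_theta(
            {k: np.asarray(v, dtype=float).reshape(prob.T, prob.T) for k, v in start.terms.items()},
            np.asarray(start.residual, dtype=float),
        )
    else:
        theta = prob.start_values()
    theta = prob.project(theta)
    state = prob.state(theta)
    if state is None:
        raise NumericalError("initial covariance matrix is not positive definite")
    trace = [state["ll"]]
    converged = False
    scale = float(np.mean(prob.pheno_var))
    n_iter = 0
    n_stalled = 0
    for n_iter in range(1, max_iter + 1):
        grad, AI, F, TR = prob.derivatives(state)
        # active set: hold parameters pinned at a boundary with the
        # gradient pointing outward, so the AI step is not mangled by the
        # subsequent projection
        active = prob.active_mask(theta, grad)
        delta = None
        if active.any():
            idx = np.flatnonzero(active)
            sub = AI[np.ix_(idx, idx)]
            ridge = 1e-8 * max(np.max(np.abs(np.diag(sub))), 1.0)
            try:
                delta = np.zeros(prob.n_params)
                delta[idx] = np.linalg.solve(sub + ridge * np.eye(len(idx)), grad[idx])
            except np.linalg.LinAlgError:
                delta = None
        new_state = None
        if delta is not None:
            for step in (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125):
                cand = prob.project(theta + step * delta)
                st = prob.state(cand)
                if st is not None and st["ll"] >= state["ll"] - 1e-9 * max(1.0, abs(state["ll"])):
                    new_state, new_theta = st, cand
                    break
        if new_state is None:
            cand = prob.project(prob.em_step(theta, F, TR))
            st = prob.state(cand)
            if st is None or st["ll"] < state["ll"] - 1e-7 * max(1.0, abs(state["ll"])):
                # EM blocked by the variance floor: constrained optimum reached
                converged = True
                break
            new_state, new_theta = st, cand
        dll = new_state["ll"] - state["ll"]
        dpar = float(np.max(np.abs(new_theta - theta)))
        theta, state = new_theta, new_state
        trace.append(state["ll"])
        if abs(dll) < ll_tol * max(1.0, abs(state["ll"])) and dpar < par_tol * scale:
            converged = True
            break
        # a boundary solution (variance floor or singular trait block) can
        # keep sliding along a likelihood ridge in vanishing increments; a
        # run of negligible improvements counts as converged
        if abs(dll) < max(100.0 * ll_tol * max(1.0, abs(state["ll"])), 1e-6):
            n_stalled += 1
            if n_stalled >= 5:
                converged = True
                break
        else:
            n_stalled = 0
    if not converged:
        warnings.warn(
            f"REML did not converge within {n_iter} iterations "
            f"(last restricted log-likelihood change "
            f"{trace[-1] - trace[-2] if len(trace) > 1 else np.nan:.3g})",
            RuntimeWarning,
        )
    gammas, resid = prob.theta_to_components(theta)
    # approximate standard errors from the inverse AI matrix
    se = None
    try:
        grad, AI, _, _ = prob.derivatives(state)
        cov = np.linalg.inv(AI + 1e-10 * np.eye(prob.n_params))
        diag = np.clip(np.diag(cov), 0.0, None)
        se = {}
        for m, (name, s, t) in enumerate(prob.params):
            se.setdefault(name, np.full((prob.T, prob.T), np.nan))[s, t] = np.sqrt(diag[m])
            se[name][t, s] = se[name][s, t]
    except np.linalg.LinAlgError:
        pass
    return VarianceComponents(
        traits=prob.traits,
        terms=gammas,
        residual=resid,
        loglik=state["ll"],
        n_iter=n_iter,
        converged=converged,
        ll_trace=np.asarray(trace),
        variance_floor=prob.floor,
        standard_errors=se,
    )


def reml_loglik(spec: ModelSpec, data: pd.DataFrame, components: VarianceComponents) -> float:
    """Restricted log-likelihood at the supplied components (up to a constant)."""
    design = build_design(spec, data)
    prob = _Problem(spec, design)
    theta = prob.components_to_theta(
        {k: np.asarray(v, float).reshape(prob.T, prob.T) for k, v in components.terms.items()},
        np.asarray(components.residual, float),
    )
    return prob.loglik(theta)


def solve_mme(
    spec: ModelSpec, data: pd.DataFrame, components: VarianceComponents
) -> MixedModelSolution:
    """BLUE/BLUP solutions of the mixed-model equations at fixed components.

    Solved through the equivalent generalised-least-squares identities
    (beta = (X'V^-1 X)^-1 X'V^-1 y, u_k = (Gamma_k (x) K_k) Z_k' P y),
    which coincide with Henderson's equations.  Animals in a term's
    relationship matrix without an observed record -- including records
    masked by setting the response to missing -- are predicted through
    their relationships.  The fixed-effect labels record the applied
    drop-first identifiability constraint.
    """
    components.validate()
    design = build_design(spec, data)
    prob = _Problem(spec, design)
    theta = prob.components_to_theta(
        {k: np.asarray(v, float).reshape(prob.T, prob.T) for k, v in components.terms.items()},
        np.asarray(components.residual, float),
    )
    state = prob.state(theta)
    if state is None:
        raise NumericalError("covariance matrix not positive definite at the supplied components")
    Py = state["Py"]
    beta = pd.Series(state["beta"], index=design["labels"], name="BLUE")
    random = {}
    gammas, _ = prob.theta_to_components(theta)
    for term in spec.random_terms:
        Kfull = term.matrix.values
        a_idx = term.matrix.indexer(prob.animals)
        g = gammas[term.name]
        # M_s = K[:, records of trait s] @ Py_s
        M = np.zeros((term.matrix.n_animals, prob.T))
        for s in range(prob.T):
            sl = prob.slices[s]
            M[:, s] = Kfull[:, a_idx[sl]] @ Py[sl]
        U = M @ g.T
        random[term.name] = pd.DataFrame(
            U, index=list(term.matrix.ids), columns=list(prob.traits)
        )
    fitted = pd.Series(design["X"] @ state["beta"], index=design["rows"], name="fitted_fixed")
    return MixedModelSolution(beta=beta, random=random, fitted_fixed=fitted)


def genomic_correlation(
    components: VarianceComponents, term: str = "genomic", pair=(0, 1)
) -> float:
    """r_G = cross-trait genomic covariance over the geometric-mean variance.

    Returns NaN (with a warning) when either genomic variance sits at
    the floor, where the ratio is undefined.
    """
    g = components.terms[term]
    s, t = pair
    v1, v2 = g[s, s], g[t, t]
    if v1 <= 0 or v2 <= 0:
        raise ConfigurationError("genomic variances must be positive")
    for idx in pair:
        if components.at_floor(term, components.traits[idx]):
            warnings.warn(
                "genomic variance at the floor: genomic correlation undefined",
                RuntimeWarning,
            )
            return np.nan
    r = float(g[s, t] / np.sqrt(v1 * v2))
    return float(np.clip(r, -1.0, 1.0))


def missing_heritability(
    components: VarianceComponents,
    trait,
    pedigree_term: str = "pedigree",
    genomic_term: str = "genomic",
) -> float:
    """C_miss = 1 - sigma2_u / (sigma2_u + sigma2_a) for one trait (breed)."""
    t = components.trait_index(trait)
    su = components.terms[genomic_term][t, t]
    sa = components.terms[pedigree_term][t, t]
    if su + sa <= 0:
        raise ConfigurationError("total genetic variance must be positive")
    if components.at_floor(genomic_term, trait) and components.at_floor(pedigree_term, trait):
        warnings.warn("both genetic variances at the floor: C_miss undefined", RuntimeWarning)
        return np.nan
    return float(1.0 - su / (su + sa))


def parameter_summary(
    components: VarianceComponents,
    pedigree_term: str = "pedigree",
    genomic_term: str = "genomic",
) -> ParameterSummary:
    """h2_P, h2_G and C_miss per trait plus the across-trait r_G."""
    rows = {}
    for trait in components.traits:
        t = components.trait_index(trait)
        tot = components.phenotypic_variance(trait)
        h2p = components.terms[pedigree_term][t, t] / tot
        h2g = components.terms[genomic_term][t, t] / tot
        rows[trait] = {
            "h2_P": h2p,
            "h2_G": h2g,
            "C_miss": missing_heritability(components, trait, pedigree_term, genomic_term),
        }
    r_G = (
        genomic_correlation(components, genomic_term)
        if components.n_traits == 2
        else np.nan
    )
    return ParameterSummary(table=pd.DataFrame(rows).T, r_G=r_G)
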