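"""Separable temporal ERGM (STERGM) machinery.

A network transition y_prev -> y_next is decomposed into two conditionally
independent half-steps: a *formation* network y_plus = y_prev ∪ y_next (which
empty dyads gained a tie) and a *persistence* network y_minus = y_prev ∩ y_next
(which existing ties survived).  Each half-step follows its own exponential
random graph model over the free dyads, with the other dyads pinned at their
y_prev state, and the observed transition is recovered as
``y_next = y_minus ∪ (y_plus \\ y_prev)``.

Model terms: ``edges`` (intercept), endpoint counts for parity classes 2 and
3+ (class 1 is the reference), a same-parity homophily indicator, the additive
genetic relationship and the kindergarten indicator as edge covariates, and —
for the M2 variant — ``triangles``, whose change statistic for dyad (i, j) is
the number of common neighbors of i and j.

Estimation is pooled maximum pseudolikelihood (conditional logistic regression
on change statistics), which is the exact conditional MLE whenever the term
set is dyad-independent (the M1 case).  Simulation is Metropolis–Hastings with
uniform single-dyad toggle proposals, 20 burn-in sweeps, and one sample per
independent chain; the inner loop is numba-compiled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numba import njit
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .covariates import DyadCovariateSet, PARITY_CLASSES
from .network import DailyNetwork, dyads

EXOGENOUS_TERMS = (
    "edges",
    "parity_2",
    "parity_3plus",
    "parity_match",
    "kinship",
    "kindergarten",
)
ALL_TERMS = EXOGENOUS_TERMS + ("triangles",)

DEFAULT_BURN_IN = 20  # full MH sweeps before reading a sample


class ModelSpecError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term list for both STERGM phases.

    ``edges`` must be present (it is the intercept).  The M1 variant uses only
    exogenous, dyad-independent terms; M2 adds ``triangles``.
    """

    terms: tuple

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        unknown = [t for t in terms if t not in ALL_TERMS]
        if unknown:
            raise ModelSpecError(f"unknown model terms: {unknown}")
        if "edges" not in terms:
            raise ModelSpecError("the edges term is required")
        if len(set(terms)) != len(terms):
            raise ModelSpecError("duplicate model terms")
        object.__setattr__(self, "terms", terms)

    @property
    def variant(self) -> str:
        return "M2" if "triangles" in self.terms else "M1"

    @property
    def dyad_independent(self) -> bool:
        return "triangles" not in self.terms

    @classmethod
    def m1(cls) -> "ModelSpec":
        return cls(EXOGENOUS_TERMS)

    @classmethod
    def m2(cls) -> "ModelSpec":
        return cls(ALL_TERMS)

    @classmethod
    def from_coef_names(cls, names) -> "ModelSpec":
        return cls(tuple(names))


def exogenous_stat_matrices(spec: ModelSpec, cov: DyadCovariateSet) -> dict[str, np.ndarray]:
    """Per-term (n, n) dyad-statistic matrices for the exogenous terms."""
    n = cov.n
    parity = np.asarray(cov.parity, dtype=object)
    mats: dict[str, np.ndarray] = {}
    for term in spec.terms:
        if term == "edges":
            m = np.ones((n, n))
        elif term == "parity_2":
            ind = (parity == "2").astype(float)
            m = ind[:, None] + ind[None, :]
        elif term == "parity_3plus":
            ind = (parity == "3+").astype(float)
            m = ind[:, None] + ind[None, :]
        elif term == "parity_match":
            m = (parity[:, None] == parity[None, :]).astype(float)
        elif term == "kinship":
            m = cov.kinship.astype(float)
        elif term == "kindergarten":
            m = cov.kindergarten.astype(float)
        elif term == "triangles":
            continue
        else:  # pragma: no cover
            raise ModelSpecError(term)
        np.fill_diagonal(m, 0.0)
        mats[term] = m
    return mats


def change_statistics(
    network: DailyNetwork, dyad: tuple[int, int], spec: ModelSpec, cov: DyadCovariateSet
) -> np.ndarray:
    """Change in each model statistic from toggling ``dyad`` on.

    ``dyad`` is a pair of roster indices.  The triangles change statistic is
    the number of common neighbors of i and j in ``network`` (the rest of the
    network state; the (i, j) tie itself does not affect it).
    """
    i, j = dyad
    if i == j:
        raise ValueError("dyad endpoints must differ")
    mats = exogenous_stat_matrices(spec, cov)
    out = []
    for term in spec.terms:
        if term == "triangles":
            out.append(float(np.dot(network.adjacency[i], network.adjacency[j])))
        else:
            out.append(float(mats[term][i, j]))
    return np.array(out)


def network_statistics(network: DailyNetwork, spec: ModelSpec, cov: DyadCovariateSet) -> np.ndarray:
    """Sufficient statistics g(y) of a network under the model."""
    iu, ju = dyads(network.n)
    vec = network.adjacency[iu, ju].astype(float)
    mats = exogenous_stat_matrices(spec, cov)
    out = []
    for term in spec.terms:
        if term == "triangles":
            A = network.adjacency.astype(np.int64)
            out.append(float(np.trace(A @ A @ A) / 6.0))
        else:
            out.append(float(mats[term][iu, ju] @ vec))
    return np.array(out)


# -- transition decomposition -------------------------------------------------

@dataclass(frozen=True)
class TransitionPair:
    """One day-to-day transition with its formation/persistence targets."""

    y_prev: DailyNetwork
    y_next: DailyNetwork
    y_plus: DailyNetwork  # union: formation target
    y_minus: DailyNetwork  # intersection: persistence target


def decompose_transition(y_prev: DailyNetwork, y_next: DailyNetwork) -> TransitionPair:
    """Split a transition into formation (union) and persistence (intersection)."""
    y_prev.require_same_roster(y_next)
    plus = np.maximum(y_prev.adjacency, y_next.adjacency)
    minus = np.minimum(y_prev.adjacency, y_next.adjacency)
    return TransitionPair(
        y_prev=y_prev,
        y_next=y_next,
        y_plus=y_prev.with_adjacency(plus, day=y_next.day),
        y_minus=y_prev.with_adjacency(minus, day=y_next.day),
    )


# -- fitting ------------------------------------------------------------------

@dataclass
class PhaseFit:
    coefs: pd.Series
    se: pd.Series
    converged: bool
    n_rows: int
    n_free_dyads: int
    separation: bool
    max_abs_score: float
    obs_stats: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class StergmFit:
    """Formation + persistence coefficient vectors for one window fit."""

    spec: ModelSpec
    formation: PhaseFit
    persistence: PhaseFit

    @property
    def converged(self) -> bool:
        return self.formation.converged and self.persistence.converged

    @property
    def diagnostics(self) -> dict:
        def d(p: PhaseFit) -> dict:
            return {
                "converged": p.converged,
                "n_rows": p.n_rows,
                "n_free_dyads": p.n_free_dyads,
                "separation": p.separation,
                "max_abs_score": p.max_abs_score,
            }

        return {"formation": d(self.formation), "persistence": d(self.persistence)}

    def to_json(self, path=None) -> str:
        payload = {
            "terms": list(self.spec.terms),
            "variant": self.spec.variant,
            "converged": self.converged,
            "formation": {
                "coefs": self.formation.coefs.to_dict(),
                "se": self.formation.se.to_dict(),
            },
            "persistence": {
                "coefs": self.persistence.coefs.to_dict(),
                "se": self.persistence.se.to_dict(),
            },
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _phase_rows(
    transitions: Sequence[TransitionPair],
    spec: ModelSpec,
    cov: DyadCovariateSet,
    phase: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled (X, y) logistic-regression rows for one phase over a window."""
    mats = exogenous_stat_matrices(spec, cov)
    n = cov.n
    iu, ju = dyads(n)
    X_parts, y_parts = [], []
    n_free = 0
    for tr in transitions:
        prev = tr.y_prev.adjacency[iu, ju]
        target = tr.y_plus if phase == "formation" else tr.y_minus
        free = prev == 0 if phase == "formation" else prev == 1
        n_free += int(free.sum())
        if not free.any():
            continue
        cols = []
        for term in spec.terms:
            if term == "triangles":
                A = target.adjacency.astype(np.int64)
                common = (A @ A)[iu, ju].astype(float)
                cols.append(common[free])
            else:
                cols.append(mats[term][iu, ju][free])
        X_parts.append(np.column_stack(cols))
        y_parts.append(target.adjacency[iu, ju][free].astype(float))
    if not X_parts:
        return np.empty((0, len(spec.terms))), np.empty(0), n_free
    return np.vstack(X_parts), np.concatenate(y_parts), n_free


def _fit_phase(X: np.ndarray, y: np.ndarray, spec: ModelSpec, n_free: int) -> PhaseFit:
    terms = list(spec.terms)
    nan = pd.Series(np.nan, index=terms)
    if X.shape[0] == 0:
        raise FitError("no free dyads in this phase over the window")
    if np.all(y == y[0]):
        return PhaseFit(nan, nan, False, len(y), n_free, True, np.inf)
    sep = False
    max_score = np.inf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coefs = pd.Series(res.params, index=terms)
        se = pd.Series(res.bse, index=terms)
        score = res.model.score(res.params)
        max_score = float(np.max(np.abs(score)))
        ok = bool(res.mle_retvals.get("converged", False)) and bool(
            np.isfinite(se).all() and np.isfinite(coefs).all()
        )
        return PhaseFit(coefs, se, ok, len(y), n_free, False, max_score)
    except (PerfectSeparationError, PerfectSeparationWarning):
        sep = True
    except np.linalg.LinAlgError:
        sep = False
    return PhaseFit(nan, nan, False, len(y), n_free, sep, max_score)


def fit_mple(
    transitions: Sequence[TransitionPair], spec: ModelSpec, cov: DyadCovariateSet
) -> StergmFit:
    """Pooled maximum-pseudolikelihood STERGM fit over a window of transitions.

    Formation: logistic regression of the next-day state on change statistics,
    over all (transition, dyad) rows with no tie on the previous day, with the
    triangles statistic (if present) evaluated in the formation target network.
    Persistence: analogous over previously tied dyads, statistics in the
    persistence target.  Separation or a non-finite curvature marks the fit
    non-converged (diagnosed, not raised).
    """
    if not transitions:
        raise FitError("need at least one transition")
    rosters = {tr.y_prev.roster for tr in transitions} | {tr.y_next.roster for tr in transitions}
    if len(rosters) != 1:
        raise FitError("all transitions must share one roster")
    if rosters.pop() != cov.roster:
        raise FitError("covariate roster does not match the networks")
    phases = {}
    for phase in ("formation", "persistence"):
        X, y, n_free = _phase_rows(transitions, spec, cov, phase)
        pf = _fit_phase(X, y, spec, n_free)
        stats = [
            network_statistics(tr.y_plus if phase == "formation" else tr.y_minus, spec, cov)
            for tr in transitions
        ]
        pf.obs_stats = np.mean(stats, axis=0)
        phases[phase] = pf
    return StergmFit(spec=spec, formation=phases["formation"], persistence=phases["persistence"])


# -- simulation ---------------------------------------------------------------

@njit(cache=True)
def _mh_kernel(adj, free_i, free_j, eta, tri_coef, picks, unifs):  # pragma: no cover
    n = adj.shape[0]
    for s in range(picks.shape[0]):
        k = picks[s]
        i = free_i[k]
        j = free_j[k]
        logr = eta[i, j]
        if tri_coef != 0.0:
            common = 0.0
            for v in range(n):
                common += adj[i, v] * adj[j, v]
            logr += tri_coef * common
        if adj[i, j] == 1:
            logr = -logr
        if logr >= 0.0 or unifs[s] < np.exp(logr):
            t = 1 - adj[i, j]
            adj[i, j] = t
            adj[j, i] = t


def _linear_predictor(theta: pd.Series, spec: ModelSpec, cov: DyadCovariateSet) -> tuple[np.ndarray, float]:
    """(n, n) exogenous linear predictor and the triangles coefficient."""
    mats = exogenous_stat_matrices(spec, cov)
    eta = np.zeros((cov.n, cov.n))
    tri = 0.0
    for term in spec.terms:
        val = float(theta[term])
        if term == "triangles":
            tri = val
        else:
            eta += val * mats[term]
    return eta, tri


def _run_phase_chain(
    y_prev_adj: np.ndarray,
    phase: str,
    eta: np.ndarray,
    tri: float,
    burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    iu, ju = dyads(y_prev_adj.shape[0])
    prev = y_prev_adj[iu, ju]
    free = prev == 0 if phase == "formation" else prev == 1
    fi = iu[free].astype(np.int64)
    fj = ju[free].astype(np.int64)
    adj = y_prev_adj.astype(np.float64).copy()
    m = fi.size
    if m == 0:
        return y_prev_adj.copy()
    steps = burn_in * m
    picks = rng.integers(0, m, size=steps)
    unifs = rng.random(steps)
    _mh_kernel(adj, fi, fj, eta, tri, picks, unifs)
    return adj.astype(np.int8)


def sample_transition(
    y_prev: DailyNetwork,
    formation_theta: pd.Series,
    persistence_theta: pd.Series,
    spec: ModelSpec,
    cov: DyadCovariateSet,
    n_samples: int,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
) -> list[DailyNetwork]:
    """Draw next-day networks from a STERGM with explicit coefficients.

    One independent MH chain per sample, per phase, each started at ``y_prev``
    and run for ``burn_in`` full sweeps; per-sample RNG streams derive from
    ``seed`` by counter.  The composed sample takes the persistence chain's
    state on previously tied dyads and the formation chain's state elsewhere.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    missing = [t for t in spec.terms if t not in formation_theta or t not in persistence_theta]
    if missing:
        raise ModelSpecError(f"coefficients missing for terms: {missing}")
    if y_prev.roster != cov.roster:
        raise FitError("covariate roster does not match the network")
    eta_f, tri_f = _linear_predictor(formation_theta, spec, cov)
    eta_p, tri_p = _linear_predictor(persistence_theta, spec, cov)
    prev_adj = y_prev.adjacency
    out = []
    for s in range(n_samples):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), s]))
        plus = _run_phase_chain(prev_adj, "formation", eta_f, tri_f, burn_in, rng)
        minus = _run_phase_chain(prev_adj, "persistence", eta_p, tri_p, burn_in, rng)
        nxt = np.where(prev_adj == 1, minus, plus).astype(np.int8)
        day = None if y_prev.day is None else y_prev.day + 1
        out.append(y_prev.with_adjacency(nxt, day=day))
    return out


def simulate_transition(
    y_prev: DailyNetwork,
    fit: StergmFit,
    spec: ModelSpec,
    cov: DyadCovariateSet,
    n_samples: int,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
    allow_nonconverged: bool = False,
) -> list[DailyNetwork]:
    """Draw next-day networks at a fit's coefficients (see :func:`sample_transition`)."""
    if not fit.converged and not allow_nonconverged:
        raise FitError("fit did not converge; pass allow_nonconverged=True to simulate anyway")
    return sample_transition(
        y_prev,
        fit.formation.coefs,
        fit.persistence.coefs,
        spec,
        cov,
        n_samples,
        burn_in=burn_in,
        seed=seed,
    )


def assess_degeneracy(
    fit: StergmFit,
    y_prev: DailyNetwork,
    spec: ModelSpec,
    cov: DyadCovariateSet,
    seed: int = 0,
    n_sim: int = 100,
    burn_in: int = DEFAULT_BURN_IN,
) -> dict:
    """Simulation-based degeneracy check at the fitted coefficients.

    Simulates from ``y_prev``, compares simulated mean formation/persistence
    sufficient statistics to the window means stored on the fit, and flags the
    model when any statistic sits more than 3 simulated SDs from its observed
    mean, or when the simulated networks are near-uniform (> 95% of dyads all
    tied or all empty).  A fit with non-finite SEs is flagged without
    simulating.
    """
    report: dict = {"degenerate": False, "flags": [], "n_sim": n_sim}
    finite = all(
        np.isfinite(p.se).all() and np.isfinite(p.coefs).all()
        for p in (fit.formation, fit.persistence)
    )
    if not finite:
        report["degenerate"] = True
        report["flags"].append("non-finite coefficients or standard errors")
        return report
    samples = simulate_transition(
        y_prev, fit, spec, cov, n_sim, burn_in=burn_in, seed=seed, allow_nonconverged=True
    )
    for phase, pf in (("formation", fit.formation), ("persistence", fit.persistence)):
        stats = []
        for net in samples:
            tr = decompose_transition(y_prev, net)
            target = tr.y_plus if phase == "formation" else tr.y_minus
            stats.append(network_statistics(target, spec, cov))
        stats = np.asarray(stats)
        mean = stats.mean(axis=0)
        sd = stats.std(axis=0, ddof=1)
        z = np.abs(mean - pf.obs_stats) / np.where(sd > 0, sd, np.inf)
        report[phase] = {
            "sim_mean": mean.tolist(),
            "sim_sd": sd.tolist(),
            "observed": pf.obs_stats.tolist(),
            "z": z.tolist(),
        }
        for term, zval in zip(spec.terms, z):
            if zval > 3:
                report["degenerate"] = True
                report["flags"].append(f"{phase}:{term} off by {zval:.1f} simulated SDs")
    dens = np.array([net.density for net in samples])
    if dens.mean() > 0.95 or dens.mean() < 0.05:
        mean_dens = dens.mean()
        report["degenerate"] = True
        report["flags"].append(f"near-uniform simulated networks (mean density {mean_dens:.3f})")
    return report
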