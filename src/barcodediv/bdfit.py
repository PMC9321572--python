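"""Likelihood-based diversification inference on ultrametric trees.

Implements the reconstructed-tree birth-death likelihood with
time-varying rates and incomplete sampling.  Writing t for age (Myr
before present) and f for the sampling fraction, the extinction/
non-sampling probability E(t) solves

    dE/dt = mu(t) - (lambda(t) + mu(t)) E + lambda(t) E^2,   E(0) = 1 - f,

integrated from the present into the past.  The log-likelihood of a
crown-conditioned tree with n tips and branching ages t_1 >= ... >= t_{n-1}
(t_1 = crown age T) is

    logL = sum_i log lambda(t_i)
         - sum_branches [Lambda(t_parent) - Lambda(t_child)]
         + n log f - 2 log(1 - E(T)),

with Lambda'(t) = lambda(t) + mu(t) - 2 lambda(t) E(t): each branch
carries the factor exp(-int (lambda+mu-2*lambda*E) dt), and the final term
conditions on survival of both crown lineages.  Closed forms are used when
rates are constant (logistic solution of the Riccati equation) or when
mu = 0 and f = 1 (E = 0); an adaptive Runge-Kutta integration (rtol 1e-8)
covers the rest.

Speciation-rate families: constant lambda0; time-exponential
lambda0 * exp(alpha * t) (alpha > 0 means higher rates in the past, i.e. a
decline toward the present); environment-driven b * exp(a * env(t)) (a > 0
means the rate increases with the environmental value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .envcurve import EnvCurve
from .trees import TimeTree, set_edge_lengths_from_ages

__all__ = [
    "RateModelSpec",
    "FitResult",
    "SlicedForest",
    "compute_ltt",
    "bd_loglik",
    "fit_bd",
    "fit_env",
    "aicc_compare",
    "slice_tree",
    "decline_statistic",
]

_PENALTY = 1e10


@dataclass
class RateModelSpec:
    """A parametric speciation/extinction model with sampling fraction."""

    speciation: str  # "constant" | "exponential" | "environmental"
    extinction: str = "none"  # "none" | "constant" | "fixed"
    params: dict = field(default_factory=dict)
    env: EnvCurve | None = None
    f: float = 1.0

    def __post_init__(self) -> None:
        if self.speciation not in ("constant", "exponential", "environmental"):
            raise ValueError(f"unknown speciation form {self.speciation!r}")
        if self.extinction not in ("none", "constant", "fixed"):
            raise ValueError(f"unknown extinction form {self.extinction!r}")
        if not (0 < self.f <= 1):
            raise ValueError("sampling fraction f must be in (0, 1]")
        if self.speciation == "environmental" and self.env is None:
            raise ValueError("environmental model requires an EnvCurve")

    # -- rate functions (vectorised over age) -------------------------

    def lambda_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        p = self.params
        if self.speciation == "constant":
            lam0 = p["lambda0"]
            return lambda t: np.full_like(np.asarray(t, dtype=float), lam0)
        if self.speciation == "exponential":
            lam0, alpha = p["lambda0"], p["alpha"]
            return lambda t: lam0 * np.exp(alpha * np.asarray(t, dtype=float))
        a, b = p["a"], p["b"]
        env = self.env
        return lambda t: b * np.exp(a * np.asarray(env(t), dtype=float))

    def mu_value(self) -> float:
        if self.extinction == "none":
            return 0.0
        return float(self.params["mu"])

    @property
    def k(self) -> int:
        """Number of free parameters."""
        k = 1 if self.speciation == "constant" else 2
        if self.extinction == "constant":
            k += 1
        return k

    @property
    def model_id(self) -> str:
        ext = {"none": "mu0", "constant": "mu", "fixed": "mufix"}[self.extinction]
        return f"{self.speciation}.{ext}"


@dataclass
class FitResult:
    model_id: str
    params: dict
    loglik: float
    k: int
    n_branching: int
    aicc: float
    converged: bool
    crown_age: float
    n_tips: int
    model: RateModelSpec = field(repr=False, default=None)


@dataclass
class SlicedForest:
    slice_age: float
    subtrees: list[TimeTree]
    retained: list[bool]

    def retained_subtrees(self) -> list[TimeTree]:
        return [t for t, r in zip(self.subtrees, self.retained) if r]


# ---------------------------------------------------------------------
# LTT
# ---------------------------------------------------------------------


def compute_ltt(tree: TimeTree) -> pd.DataFrame:
    """Lineage-through-time table: ``age`` (desc) and ``lineages``.

    Two lineages at the crown, +1 at each subsequent branching, ending at
    the tip count at age 0.
    """
    if not tree.is_ultrametric(tol=1e-6):
        raise ValueError("LTT requires an ultrametric tree")
    bt = tree.branching_times()
    counts = np.arange(2, 2 + bt.size)
    ages = np.append(bt, 0.0)
    counts = np.append(counts, tree.n_tips)
    return pd.DataFrame({"age": ages, "lineages": counts})


# ---------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------


def _tree_arrays(tree: TimeTree):
    """Cache (branching ages, edge parent/child ages) on the TimeTree."""
    cached = getattr(tree, "_bd_arrays", None)
    if cached is not None:
        return cached
    internal_ages = []
    parent_ages = []
    child_ages = []
    for node in tree.tree.preorder_node_iter():
        if not node.is_leaf():
            internal_ages.append(node.age)
        if node.parent_node is not None:
            parent_ages.append(node.parent_node.age)
            child_ages.append(node.age)
    arrays = (
        np.asarray(internal_ages),
        np.asarray(parent_ages),
        np.asarray(child_ages),
    )
    tree._bd_arrays = arrays
    return arrays


def _closed_form_constant(lam: float, mu: float, f: float, ages: np.ndarray):
    """E and Lambda at ``ages`` for constant rates (logistic solution)."""
    r = lam - mu
    ages = np.asarray(ages, dtype=float)
    if abs(r) < 1e-12:
        denom = 1.0 + lam * f * ages
        u = f / denom
        Lam = 2.0 * np.log(denom)
    else:
        ert = np.exp(r * ages)
        denom = 1.0 + lam * f * (ert - 1.0) / r
        u = f * ert / denom
        Lam = -r * ages + 2.0 * np.log(denom)
    return 1.0 - u, Lam


def _E_Lambda(model: RateModelSpec, crown_age: float, ages: np.ndarray):
    """Evaluate E(t) and Lambda(t) at ``ages`` (plus the crown age).

    Returns (E_at_ages, Lambda_at_ages, E_at_crown).
    """
    lam_fn = model.lambda_fn()
    mu = model.mu_value()
    f = model.f
    all_ages = np.append(np.asarray(ages, dtype=float), crown_age)

    if mu == 0.0 and f == 1.0:
        # E == 0; Lambda = int lambda
        if model.speciation == "constant":
            Lam = model.params["lambda0"] * all_ages
        elif model.speciation == "exponential":
            lam0, alpha = model.params["lambda0"], model.params["alpha"]
            if abs(alpha) < 1e-14:
                Lam = lam0 * all_ages
            else:
                Lam = lam0 * np.expm1(alpha * all_ages) / alpha
        else:
            grid = np.linspace(0.0, crown_age, 2049)
            vals = lam_fn(grid)
            cum = np.concatenate(
                [[0.0], np.cumsum(np.diff(grid) * 0.5 * (vals[1:] + vals[:-1]))]
            )
            Lam = np.interp(all_ages, grid, cum)
        E = np.zeros_like(all_ages)
        return E[:-1], Lam[:-1], 0.0

    if model.speciation == "constant":
        lam0 = model.params["lambda0"]
        E, Lam = _closed_form_constant(lam0, mu, f, all_ages)
        return E[:-1], Lam[:-1], float(E[-1])

    # general case: integrate [E, Lambda] from the present into the past
    def rhs(t, y):
        lam = float(lam_fn(t))
        E = y[0]
        return [
            mu - (lam + mu) * E + lam * E * E,
            lam + mu - 2.0 * lam * E,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, crown_age),
        [1.0 - f, 0.0],
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"E(t) integration failed: {sol.message}")
    y = sol.sol(all_ages)
    E, Lam = y[0], y[1]
    if np.any(E < -1e-6) or np.any(E > 1.0 + 1e-6):
        raise RuntimeError(
            f"E(t) left [0,1]: range [{E.min():.3g}, {E.max():.3g}]"
        )
    return E[:-1], Lam[:-1], float(E[-1])


def bd_loglik(tree: TimeTree, model: RateModelSpec) -> float:
    """Log-likelihood of the reconstructed tree under ``model``.

    Crown-conditioned (survival of both basal lineages).  The parameter-
    free labelling constant is fixed to 0, identically across all models,
    so log-likelihoods are comparable whenever the branching times agree.
    """
    internal_ages, parent_ages, child_ages = _tree_arrays(tree)
    T = tree.crown_age
    lam_fn = model.lambda_fn()
    lam_at_nodes = np.asarray(lam_fn(internal_ages), dtype=float)
    if np.any(lam_at_nodes <= 0) or not np.all(np.isfinite(lam_at_nodes)):
        return -np.inf
    edge_ages = np.concatenate([parent_ages, child_ages])
    _, Lam_edges, E_T = _E_Lambda(model, T, edge_ages)
    ne = parent_ages.size
    branch_term = float(np.sum(Lam_edges[:ne] - Lam_edges[ne:]))
    if E_T >= 1.0:
        return -np.inf
    logL = (
        float(np.sum(np.log(lam_at_nodes)))
        - branch_term
        + tree.n_tips * math.log(model.f)
        - 2.0 * math.log(1.0 - E_T)
    )
    return logL


# ---------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _optimise(tree, build_model, theta0_list) -> tuple[dict, float, bool]:
    """Multi-start Nelder-Mead on -logL; returns (best theta, logL, ok)."""

    def objective(theta):
        try:
            model = build_model(theta)
            ll = bd_loglik(tree, model)
        except (RuntimeError, OverflowError, ValueError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    best = None
    ok = False
    for theta0 in theta0_list:
        res = minimize(
            objective,
            np.asarray(theta0, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or (res.success and res.fun < _PENALTY / 2)
    return best.x, -best.fun, ok


def _lambda0_guess(tree: TimeTree) -> float:
    n = tree.n_tips
    tl = tree.total_branch_length()
    return max((n - 1) / tl, 1e-8) if tl > 0 else 1e-3


def fit_bd(
    tree: TimeTree,
    models: Sequence[str] = ("constant", "exponential"),
    f: float = 1.0,
    extinction: str = "none",
    fixed_mu: float | Sequence[float] | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> list[FitResult]:
    """Maximum-likelihood time-dependent birth-death fits.

    ``models`` selects speciation families ("constant", "exponential");
    ``extinction`` is "none" or "constant" (free mu); passing ``fixed_mu``
    (scalar or sequence) instead fits each model with extinction pinned at
    the given value(s) — the usual robustness sweep against arbitrarily
    high extinction.  Positive parameters are optimised on the log scale
    with ``n_starts`` jittered restarts.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips to fit a birth-death model")
    rng = np.random.default_rng(seed)
    lam_init = _lambda0_guess(tree)
    T = tree.crown_age
    n_branch = tree.n_tips - 1
    mu_list: list[float | None]
    if fixed_mu is None:
        mu_list = [None]
    else:
        mu_list = list(np.atleast_1d(np.asarray(fixed_mu, dtype=float)))
    results: list[FitResult] = []
    for name in models:
        if name not in ("constant", "exponential"):
            raise ValueError(f"unknown model family {name!r}")
        for mu_star in mu_list:
            ext = "fixed" if mu_star is not None else extinction

            def build(theta, _name=name, _ext=ext, _mu=mu_star):
                params = {"lambda0": math.exp(theta[0])}
                i = 1
                if _name == "exponential":
                    params["alpha"] = theta[i]
                    i += 1
                if _ext == "constant":
                    params["mu"] = math.exp(theta[i])
                elif _ext == "fixed":
                    params["mu"] = _mu
                return RateModelSpec(
                    speciation=_name, extinction=_ext, params=params, f=f
                )

            starts = []
            for j in range(n_starts):
                th = [math.log(lam_init) + (0.0 if j == 0 else rng.normal(0, 1))]
                if name == "exponential":
                    th.append(0.0 if j == 0 else rng.normal(0, 2.0 / T))
                if ext == "constant":
                    th.append(math.log(lam_init / 2) + (0.0 if j == 0 else rng.normal(0, 1)))
                starts.append(th)
            theta, ll, ok = _optimise(tree, build, starts)
            model = build(theta)
            results.append(
                FitResult(
                    model_id=model.model_id
                    + (f"={mu_star:g}" if mu_star is not None else ""),
                    params=dict(model.params),
                    loglik=ll,
                    k=model.k,
                    n_branching=n_branch,
                    aicc=_aicc(ll, model.k, n_branch),
                    converged=ok,
                    crown_age=T,
                    n_tips=tree.n_tips,
                    model=model,
                )
            )
    return results


def fit_env(
    tree: TimeTree,
    env: EnvCurve,
    f: float = 1.0,
    extinction: str = "none",
    fixed_mu: float | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood environment-driven speciation fit.

    Speciation rate b * exp(a * env(t)); a > 0 means speciation increases
    with the environmental value.  ``env`` must be non-constant (otherwise
    a and b are not jointly identifiable) and should cover the tree span
    after smoothing.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips to fit a birth-death model")
    if env.is_constant():
        raise ValueError(
            "constant environment curve: parameters (a, b) are not identifiable"
        )
    rng = np.random.default_rng(seed)
    lam_init = _lambda0_guess(tree)
    grid = np.linspace(0.0, tree.crown_age, 256)
    env_vals = np.asarray(env(grid), dtype=float)
    env_mean, env_sd = float(env_vals.mean()), float(env_vals.std())
    a_scale = 1.0 / max(env_sd, 1e-8)
    ext = "fixed" if fixed_mu is not None else extinction

    def build(theta):
        params = {"a": theta[0], "b": math.exp(theta[1])}
        if ext == "constant":
            params["mu"] = math.exp(theta[2])
        elif ext == "fixed":
            params["mu"] = fixed_mu
        return RateModelSpec(
            speciation="environmental", extinction=ext, params=params, env=env, f=f
        )

    starts = []
    for j in range(n_starts):
        a0 = 0.0 if j == 0 else rng.normal(0, 0.5) * a_scale
        th = [a0, math.log(lam_init) - a0 * env_mean]
        if ext == "constant":
            th.append(math.log(lam_init / 2) + (0.0 if j == 0 else rng.normal(0, 1)))
        starts.append(th)
    theta, ll, ok = _optimise(tree, build, starts)
    model = build(theta)
    return FitResult(
        model_id=model.model_id + (f"={fixed_mu:g}" if fixed_mu is not None else ""),
        params=dict(model.params),
        loglik=ll,
        k=model.k,
        n_branching=tree.n_tips - 1,
        aicc=_aicc(ll, model.k, tree.n_tips - 1),
        converged=ok,
        crown_age=tree.crown_age,
        n_tips=tree.n_tips,
        model=model,
    )


def aicc_compare(results: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits by AICc; a model is supported iff every rival trails by
    at least 2 AICc units.  All fits must share the same branching-time
    set (checked via branching count and crown age)."""
    if not results:
        raise ValueError("no results to compare")
    n_set = {(r.n_branching, round(r.crown_age, 6)) for r in results}
    if len(n_set) > 1:
        raise ValueError("fits come from different trees; AICc not comparable")
    tab = pd.DataFrame(
        {
            "model": [r.model_id for r in results],
            "loglik": [r.loglik for r in results],
            "k": [r.k for r in results],
            "aicc": [r.aicc for r in results],
        }
    )
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    deltas = np.sort(tab["delta_aicc"].to_numpy())
    best_supported = len(tab) > 1 and deltas[1] >= 2.0
    tab["supported"] = (tab["delta_aicc"] == 0.0) & best_supported
    return tab.sort_values("aicc").reset_index(drop=True)


# ---------------------------------------------------------------------
# tree slicing and decline statistics
# ---------------------------------------------------------------------


def _clone_below(node: dendropy.Node, taxa: dendropy.TaxonNamespace) -> dendropy.Node:
    clone = dendropy.Node()
    clone.age = node.age
    if node.is_leaf():
        clone.taxon = taxa.new_taxon(label=node.taxon.label)
    for c in node.child_nodes():
        clone.add_child(_clone_below(c, taxa))
    return clone


def slice_tree(tree: TimeTree, slice_age: float, min_tips: int = 50) -> SlicedForest:
    """Cut the tree at ``slice_age`` into the clades of crossing lineages.

    One subtree per lineage alive at the slice (stem above the slice
    discarded); a subtree is retained for downstream fitting iff it has
    more than ``min_tips`` tips.  A slice at or above the crown age
    returns the whole tree as a single subtree.
    """
    if slice_age < 0:
        raise ValueError("slice_age must be >= 0")
    if slice_age >= tree.crown_age:
        return SlicedForest(
            slice_age, [tree], [tree.n_tips > min_tips]
        )
    subtrees: list[TimeTree] = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.age <= slice_age < node.parent_node.age:
            taxa = dendropy.TaxonNamespace()
            sub = dendropy.Tree(taxon_namespace=taxa)
            sub.seed_node = _clone_below(node, taxa)
            set_edge_lengths_from_ages(sub)
            subtrees.append(TimeTree(sub))
    retained = [t.n_tips > min_tips for t in subtrees]
    return SlicedForest(slice_age, subtrees, retained)


def decline_statistic(
    fit: FitResult, reference_ages: Sequence[float] = (150.0, 100.0, 50.0)
) -> dict[float, float]:
    """Speciation-rate change toward the present.

    For each reference age returns lambda_hat(0) - lambda_hat(age); a
    negative value means the fitted speciation rate declines toward the
    present.
    """
    if fit.model is None:
        raise ValueError("FitResult carries no evaluable model")
    lam = fit.model.lambda_fn()
    out = {}
    for age in reference_ages:
        if age > fit.crown_age:
            raise ValueError(
                f"reference age {age} exceeds crown age {fit.crown_age}"
            )
        out[float(age)] = float(lam(0.0)) - float(lam(float(age)))
    return out
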