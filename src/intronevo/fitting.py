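"""Maximum-likelihood fitting of the gain/loss model and model comparison.

The free parameters are the per-branch gain and loss intensities, the root
presence probability, and (for the rate-variation model) the shape alpha
of the mean-one Gamma law behind the K = 2 discrete loss-rate categories.
Optimization runs in a transformed space (log intensities, logit root
probability, log alpha) with box constraints mapped from the natural-scale
bounds: intensities in [1e-8, 20], pi_root in [1e-6, 1 - 1e-6], alpha in
[0.01, 100].  Multi-start L-BFGS-B is used; the rate-variation fit is
always additionally started from the constant-rate optimum with a large
alpha, which guarantees L2 >= L1 up to optimizer tolerance.

The likelihood-ratio statistic between the nested models is
Delta = -2 (L1 - L2), compared with a chi-square distribution with one
degree of freedom (the rate-variation model adds the single parameter
alpha).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from .likelihood import PruningEngine
from .model import FitResult, GainLossModel
from .sites import IntronSiteTable
from .tree import PhyloTree

__all__ = ["fit_ml", "lrt", "lrt_statistic"]

INTENSITY_BOUNDS = (1e-8, 20.0)
PI_BOUNDS = (1e-6, 1.0 - 1e-6)
# the upper alpha bound must place the constant model (alpha -> inf)
# within optimizer reach: at alpha = 1e5 the two category multipliers are
# within 0.3% of 1, so the nested-model ordering L2 >= L1 holds to
# far below the convergence tolerance
ALPHA_BOUNDS = (0.01, 1e5)
# convergence: stop when the log-likelihood improves by < 0.001
LOGLIK_TOL = 1e-3
MAX_ROUNDS = 1000


def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


class _Objective:
    """Negative conditioned log-likelihood over transformed parameters."""

    def __init__(self, tree: PhyloTree, table: IntronSiteTable, variation: bool):
        self.tree = tree
        self.variation = variation
        self.branches = [i for i in range(tree.n_nodes) if i != tree.root]
        self.n_branches = len(self.branches)
        patterns, counts = np.unique(table.states, axis=0, return_counts=True)
        self.patterns = patterns
        self.counts = counts.astype(float)
        self.n_sites = table.n_sites

    @property
    def n_params(self) -> int:
        return 2 * self.n_branches + 1 + (1 if self.variation else 0)

    def bounds(self):
        lo_i, hi_i = np.log(INTENSITY_BOUNDS[0]), np.log(INTENSITY_BOUNDS[1])
        b = [(lo_i, hi_i)] * (2 * self.n_branches)
        b.append((_logit(PI_BOUNDS[0]), _logit(PI_BOUNDS[1])))
        if self.variation:
            b.append((math.log(ALPHA_BOUNDS[0]), math.log(ALPHA_BOUNDS[1])))
        return b

    def to_model(self, x: np.ndarray) -> GainLossModel:
        nb = self.n_branches
        gain = np.zeros(self.tree.n_nodes)
        loss = np.zeros(self.tree.n_nodes)
        gain[self.branches] = np.exp(x[:nb])
        loss[self.branches] = np.exp(x[nb : 2 * nb])
        pi = _expit(x[2 * nb])
        if self.variation:
            return GainLossModel(
                gain=gain, loss=loss, pi_root=pi, alpha=math.exp(x[2 * nb + 1]), K=2
            )
        return GainLossModel(gain=gain, loss=loss, pi_root=pi)

    def from_model(self, model: GainLossModel) -> np.ndarray:
        lo, hi = INTENSITY_BOUNDS
        g = np.clip(model.gain[self.branches], lo, hi)
        m = np.clip(model.loss[self.branches], lo, hi)
        x = np.concatenate([np.log(g), np.log(m)])
        pi = min(max(model.pi_root, PI_BOUNDS[0]), PI_BOUNDS[1])
        x = np.append(x, _logit(pi))
        if self.variation:
            alpha = model.alpha if math.isfinite(model.alpha) else ALPHA_BOUNDS[1]
            alpha = min(max(alpha, ALPHA_BOUNDS[0]), ALPHA_BOUNDS[1])
            x = np.append(x, math.log(alpha))
        return x

    def loglik(self, x: np.ndarray) -> float:
        engine = PruningEngine(self.tree, self.to_model(x))
        return float(engine.site_logliks(self.patterns) @ self.counts)

    @staticmethod
    def _transition_derivatives(G: np.ndarray, M_eff: np.ndarray):
        """d p01 / d{G, M_eff} and d p10 / d{G, M_eff} elementwise."""
        T = np.maximum(G + M_eff, 1e-300)
        E = np.exp(-T)
        Dv = -np.expm1(-T)
        dp01_dG = Dv * M_eff / T**2 + G * E / T
        dp01_dM = G * (E / T - Dv / T**2)
        dp10_dM = Dv * G / T**2 + M_eff * E / T
        dp10_dG = M_eff * (E / T - Dv / T**2)
        return dp01_dG, dp01_dM, dp10_dG, dp10_dM

    def _grad_natural(self, model, C, dpi):
        """Gradient of a flow-decomposed log-likelihood in natural scale.

        C and dpi are the sufficient statistics from
        :meth:`PruningEngine.flows`; returns (dG, dM, dpi) with per-branch
        arrays over self.branches.
        """
        r = model.rate_multipliers
        idx = np.asarray(self.branches)
        G = model.gain[idx]
        M = model.loss[idx]
        dG = np.zeros(len(idx))
        dM = np.zeros(len(idx))
        for c, rc in enumerate(r):
            d01G, d01M, d10G, d10M = self._transition_derivatives(G, rc * M)
            a = C[c, idx, 0, 1] - C[c, idx, 0, 0]
            b = C[c, idx, 1, 0] - C[c, idx, 1, 1]
            dG += a * d01G + b * d10G
            dM += rc * (a * d01M + b * d10M)
        return dG, dM, dpi

    def value_and_grad(self, x: np.ndarray):
        """Negative conditioned log-likelihood and its gradient.

        The gradient over branch intensities and pi_root is analytic (from
        the expected transition flows of the up-down pass); the alpha
        component uses a central finite difference in log space.
        """
        model = self.to_model(x)
        engine = PruningEngine(self.tree, model)
        fd = engine.flows(self.patterns, self.counts)
        absent = np.zeros((1, self.tree.n_leaves), dtype=np.int8)
        f0 = engine.flows(absent)
        P0 = min(np.exp(f0["loglik"]), 1.0 - 1e-15)
        n_tot = float(self.counts.sum())
        ll = fd["loglik"] - n_tot * math.log1p(-P0)

        scale0 = n_tot * P0 / (1.0 - P0)
        dG_d, dM_d, dpi_d = self._grad_natural(model, fd["C"], fd["dpi"])
        dG_0, dM_0, dpi_0 = self._grad_natural(model, f0["C"], f0["dpi"])
        dG = dG_d + scale0 * dG_0
        dM = dM_d + scale0 * dM_0
        dpi = dpi_d + scale0 * dpi_0

        nb = self.n_branches
        grad = np.empty(self.n_params)
        idx = np.asarray(self.branches)
        grad[:nb] = dG * model.gain[idx]          # chain rule for log G
        grad[nb : 2 * nb] = dM * model.loss[idx]  # log M
        pi = model.pi_root
        grad[2 * nb] = dpi * pi * (1.0 - pi)      # logit pi
        if self.variation:
            h = 1e-5
            xp, xm = x.copy(), x.copy()
            xp[2 * nb + 1] += h
            xm[2 * nb + 1] -= h
            grad[2 * nb + 1] = (self.loglik(xp) - self.loglik(xm)) / (2 * h)
        return -ll, -grad

    def __call__(self, x: np.ndarray) -> float:
        return -self.loglik(x)


def _random_start(obj: _Objective, rng: np.random.Generator) -> np.ndarray:
    nb = obj.n_branches
    x = np.empty(obj.n_params)
    x[: 2 * nb] = np.log(rng.uniform(0.02, 2.0, size=2 * nb))
    x[2 * nb] = _logit(rng.uniform(0.1, 0.9))
    if obj.variation:
        x[2 * nb + 1] = math.log(rng.uniform(0.2, 10.0))
    return x


def fit_ml(
    tree: PhyloTree,
    table: IntronSiteTable,
    model_kind: str = "rate_variation",
    restarts: int = 1,
    seed: int = 0,
    constant_fit: FitResult | None = None,
) -> FitResult:
    """Fit the gain/loss model by maximum likelihood.

    Parameters
    ----------
    model_kind
        "constant" (K = 1) or "rate_variation" (K = 2 loss-rate
        categories, one extra shape parameter alpha).
    restarts
        Number of seeded random starting points (>= 1).
    constant_fit
        Optional previously fitted constant-rate result; when fitting the
        rate-variation model it seeds an extra start so the nested model
        ordering L2 >= L1 holds up to tolerance.  If omitted it is fitted
        internally for the rate-variation case.
    """
    if model_kind not in ("constant", "rate_variation"):
        raise ValueError("model_kind must be 'constant' or 'rate_variation'")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if table.n_sites == 0:
        raise ValueError("empty site table")
    missing = [s for s in tree.leaf_names if s not in table.species]
    if missing:
        raise ValueError(f"table lacks tree species {missing}")
    table = table.reorder_species(tree.leaf_names)

    variation = model_kind == "rate_variation"
    obj = _Objective(tree, table, variation)
    rng = np.random.default_rng(seed)

    starts = [_random_start(obj, rng) for _ in range(restarts)]
    # a moment-flavoured start: observed presence fraction for pi
    x0 = starts[0].copy()
    frac_present = float(np.mean(table.states == 1))
    x0[2 * obj.n_branches] = _logit(min(max(frac_present, 0.05), 0.95))
    starts[0] = x0
    if variation:
        if constant_fit is None:
            constant_fit = fit_ml(
                tree, table, "constant", restarts=restarts, seed=seed
            )
        xc = obj.from_model(
            GainLossModel(
                gain=constant_fit.model.gain,
                loss=constant_fit.model.loss,
                pi_root=constant_fit.model.pi_root,
                alpha=ALPHA_BOUNDS[1],
                K=2,
            )
        )
        starts.append(xc)

    # absolute log-likelihood tolerance 0.001 mapped to L-BFGS-B's relative ftol
    best = None
    n_iter = 0
    any_converged = False
    for x_start in starts:
        probe = abs(obj(x_start))
        ftol = LOGLIK_TOL / max(probe, 1.0)
        res = optimize.minimize(
            obj.value_and_grad,
            x_start,
            jac=True,
            method="L-BFGS-B",
            bounds=obj.bounds(),
            options={"maxiter": MAX_ROUNDS, "ftol": ftol, "maxfun": 100000},
        )
        n_iter += res.nit
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:  # ties: first-found wins
            best = res

    model = obj.to_model(best.x)
    return FitResult(
        model=model,
        loglik=-float(best.fun),
        n_sites=table.n_sites,
        restarts=len(starts),
        converged=any_converged,
        n_iterations=n_iter,
        metadata={"model_kind": model_kind, "n_patterns": len(obj.counts)},
    )


def lrt_statistic(L1: float, L2: float) -> float:
    """Likelihood-ratio statistic Delta = -2 (L1 - L2) for nested models."""
    return -2.0 * (L1 - L2)


def lrt(constant_fit: FitResult, variation_fit: FitResult, tol: float = 1e-6) -> dict:
    """Compare the constant-rate and rate-variation fits.

    Returns ``{"delta": ..., "df": 1, "p": ...}`` with the upper chi-square
    tail probability at one degree of freedom.  A slightly negative
    statistic (within optimizer tolerance) is clipped to zero; a grossly
    negative one indicates a failed rate-variation fit and raises.
    """
    if constant_fit.n_sites != variation_fit.n_sites:
        raise ValueError("fits use different site counts")
    delta = lrt_statistic(constant_fit.loglik, variation_fit.loglik)
    if delta < 0:
        if delta < -max(tol, LOGLIK_TOL * 10):
            raise ValueError(
                f"rate-variation fit worse than constant fit (delta={delta:g})"
            )
        delta = 0.0
    return {"delta": delta, "df": 1, "p": float(stats.chi2.sf(delta, df=1))}
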