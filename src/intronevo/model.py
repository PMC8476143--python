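"""Two-state Markov model of intron gain and loss.

Each intron site evolves independently along the species tree between the
states absent (0) and present (1).  Every branch b carries its own gain
intensity G_b and loss intensity M_b (rate x branch-duration products, so
the newick branch lengths play no role in inference).  Under the
rate-variation model each site additionally belongs to one of K equally
probable discrete loss-rate categories whose multipliers r_1..r_K come from
a mean-one Gamma(alpha) distribution; gain intensities are shared across
categories.  K = 1 (equivalently alpha = inf) recovers the constant-rate
model, and the rate-variation model therefore adds exactly one free
parameter (alpha).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tree import PhyloTree

__all__ = [
    "GainLossModel",
    "FitResult",
    "branch_transition",
    "discretize_gamma",
]


def branch_transition(G: float, M_eff: float) -> np.ndarray:
    """2x2 transition matrix for one branch and one loss category.

    With total intensity T = G + M_eff the off-diagonal probabilities are

        P(0 -> 1) = (G / T) (1 - exp(-T))
        P(1 -> 0) = (M_eff / T) (1 - exp(-T))

    which is the exact solution of the two-state continuous-time chain with
    gain rate G and loss rate M_eff run for unit time.  T = 0 gives the
    identity matrix.
    """
    if G < 0 or M_eff < 0:
        raise ValueError("intensities must be nonnegative")
    T = G + M_eff
    if T == 0.0:
        return np.eye(2)
    decay = -np.expm1(-T)  # 1 - exp(-T), accurate for small T
    p01 = (G / T) * decay
    p10 = (M_eff / T) * decay
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def discretize_gamma(alpha: float, K: int) -> np.ndarray:
    """Mean-of-equal-probability-interval discretization of Gamma(alpha, mean 1).

    Returns K multipliers with equal prior weight 1/K and mean exactly 1.
    This is the standard discrete approximation of continuous rate
    variation across sites.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1 or not math.isfinite(alpha):
        return np.ones(K)
    dist = stats.gamma(a=alpha, scale=1.0 / alpha)
    edges = dist.ppf(np.linspace(0.0, 1.0, K + 1))
    # mean of Gamma(a, scale) truncated to [lo, hi]:
    #   E[X; lo<X<hi] / P(lo<X<hi) with E[X; .] = scale*a*(F_{a+1}(hi)-F_{a+1}(lo))
    upper = stats.gamma(a=alpha + 1.0, scale=1.0 / alpha)
    partial = upper.cdf(edges)  # F_{a+1} at the edges, times mean 1
    r = (partial[1:] - partial[:-1]) * K  # divide by interval mass 1/K
    return r / r.mean()  # exact mean-1 normalization of rounding error


@dataclass
class GainLossModel:
    """Full parameter set of the gain/loss model on a fixed tree.

    ``gain`` and ``loss`` are arrays indexed by tree node (the entry at the
    root index is unused and kept at 0).  ``alpha = inf`` together with
    K = 1 denotes the constant-rate model.
    """

    gain: np.ndarray
    loss: np.ndarray
    pi_root: float
    alpha: float = math.inf
    K: int = 1

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        if np.any(self.gain < 0) or np.any(self.loss < 0):
            raise ValueError("intensities must be nonnegative")
        if not 0.0 <= self.pi_root <= 1.0:
            raise ValueError("pi_root must lie in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.K == 1 and not math.isfinite(self.alpha):
            pass  # constant-rate model
        elif self.K > 1 and not (self.alpha > 0):
            raise ValueError("alpha must be > 0 for the rate-variation model")
        r = self.rate_multipliers
        if abs(r.mean() - 1.0) > 1e-9:
            raise AssertionError("category multipliers must average to 1")

    @property
    def is_constant_rate(self) -> bool:
        return self.K == 1

    @property
    def rate_multipliers(self) -> np.ndarray:
        return discretize_gamma(self.alpha, self.K)

    @classmethod
    def constant(cls, tree: PhyloTree, gain: float, loss: float, pi_root: float):
        """Constant-rate model with one shared gain/loss intensity value."""
        g = np.full(tree.n_nodes, float(gain))
        m = np.full(tree.n_nodes, float(loss))
        g[tree.root] = m[tree.root] = 0.0
        return cls(gain=g, loss=m, pi_root=pi_root)

    @classmethod
    def rate_variation(
        cls, tree: PhyloTree, gain: float, loss: float, pi_root: float,
        alpha: float, K: int = 2,
    ):
        g = np.full(tree.n_nodes, float(gain))
        m = np.full(tree.n_nodes, float(loss))
        g[tree.root] = m[tree.root] = 0.0
        return cls(gain=g, loss=m, pi_root=pi_root, alpha=alpha, K=K)

    # -- serialization -----------------------------------------------------

    def to_dict(self, tree: PhyloTree) -> dict:
        return {
            "model": "constant" if self.is_constant_rate else "rate_variation",
            "pi_root": float(self.pi_root),
            "alpha": None if not math.isfinite(self.alpha) else float(self.alpha),
            "K": int(self.K),
            "rate_multipliers": [float(r) for r in self.rate_multipliers],
            "branches": {
                tree.names[i]: {
                    "gain": float(self.gain[i]),
                    "loss": float(self.loss[i]),
                }
                for i in range(tree.n_nodes)
                if i != tree.root
            },
        }

    @classmethod
    def from_dict(cls, d: dict, tree: PhyloTree) -> "GainLossModel":
        gain = np.zeros(tree.n_nodes)
        loss = np.zeros(tree.n_nodes)
        for name, pars in d["branches"].items():
            i = tree.index_of(name)
            gain[i] = pars["gain"]
            loss[i] = pars["loss"]
        alpha = d.get("alpha")
        return cls(
            gain=gain,
            loss=loss,
            pi_root=d["pi_root"],
            alpha=math.inf if alpha is None else float(alpha),
            K=int(d.get("K", 1)),
        )

    def write_json(self, path, tree: PhyloTree, extra: dict | None = None) -> None:
        payload = self.to_dict(tree)
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def read_json(cls, path, tree: PhyloTree) -> "GainLossModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), tree)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: GainLossModel
    loglik: float
    n_sites: int
    restarts: int = 1
    converged: bool = True
    n_iterations: int = 0
    metadata: dict = field(default_factory=dict)
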