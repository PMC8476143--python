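"""Felsenstein pruning for the intron gain/loss model.

All quantities are computed with an *observability conditioning*: the site
table only ever contains sites where an intron is present in at least one
species, so every site likelihood is divided by 1 - P(absent in every
leaf), evaluated under the same model mixture.  The conditioning constant
does not depend on the observed states, so it is computed once per model.

Per-site probabilities are mixed over the K equal-weight loss-rate
categories.  The recursions are vectorized across sites (and categories),
with per-node rescaling of the partial likelihoods to avoid underflow.

Posterior decoding (node presence probabilities and joint parent/child
event probabilities) uses the standard up-down algorithm; the
observability-conditioning constant cancels in all posteriors.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .model import GainLossModel, branch_transition
from .sites import MISSING, IntronSiteTable, SiteRecord
from .tree import PhyloTree

__all__ = [
    "PruningEngine",
    "site_loglik",
    "total_loglik",
    "posterior_node_presence",
    "branch_event_posteriors",
]

# leaf partial likelihoods by state code (0, 1, '?')
_LEAF_PARTIAL = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])

_TINY = 1e-300


class PruningEngine:
    """Reusable pruning machinery for one (tree, model) pair.

    ``states`` arguments are int8 arrays of shape (n_sites, n_leaves) whose
    columns follow the tree's leaf order (``tree.leaf_names``).
    """

    def __init__(self, tree: PhyloTree, model: GainLossModel):
        if len(model.gain) != tree.n_nodes:
            raise ValueError("model branch arrays do not match tree size")
        self.tree = tree
        self.model = model
        r = model.rate_multipliers
        self.K = len(r)
        N = tree.n_nodes
        P = np.empty((self.K, N, 2, 2))
        for c, rc in enumerate(r):
            P[c, tree.root] = np.eye(2)
            for i in range(N):
                if i == tree.root:
                    continue
                P[c, i] = branch_transition(model.gain[i], rc * model.loss[i])
        self.P = P
        # column of each leaf node in the states matrix
        self.leaf_col = np.full(N, -1, dtype=np.int64)
        for col, i in enumerate(tree.leaf_indices):
            self.leaf_col[i] = col
        self.pi = np.array([1.0 - model.pi_root, model.pi_root])
        self.log_p_unobserved = self._log_p_all_absent()

    # -- upward (postorder) pass ------------------------------------------

    def _up(self, states: np.ndarray, keep_messages: bool = False):
        """Partial likelihoods F (K,S,N,2), per-site log scale (K,S).

        When ``keep_messages`` is set, also returns the per-branch upward
        messages M (K,S,N,2) indexed by the *parent* state, needed by the
        downward pass.
        """
        tree = self.tree
        K, N = self.K, tree.n_nodes
        S = states.shape[0]
        F = np.empty((K, S, N, 2))
        logscale = np.zeros((K, S))
        M = np.empty((K, S, N, 2)) if keep_messages else None
        for v in tree.postorder():
            if tree.is_leaf(v):
                F[:, :, v, :] = _LEAF_PARTIAL[states[:, self.leaf_col[v]]]
            else:
                prod = np.ones((K, S, 2))
                for c in tree.children[v]:
                    msg = np.einsum("kab,ksb->ksa", self.P[:, c], F[:, :, c])
                    if keep_messages:
                        M[:, :, c] = msg
                    prod *= msg
                scale = np.maximum(prod.max(axis=2), _TINY)
                F[:, :, v] = prod / scale[..., None]
                logscale += np.log(scale)
        return (F, logscale, M) if keep_messages else (F, logscale)

    def _site_logliks_by_category(self, states: np.ndarray) -> np.ndarray:
        """log L_c per category and site, unconditioned: (K, S)."""
        F, logscale = self._up(states)
        root_lik = F[:, :, self.tree.root] @ self.pi
        return np.log(np.maximum(root_lik, _TINY)) + logscale

    def _log_p_all_absent(self) -> float:
        all_zero = np.zeros((1, self.tree.n_leaves), dtype=np.int8)
        logs = self._site_logliks_by_category(all_zero)[:, 0]
        return float(logsumexp(logs) - np.log(self.K))

    # -- public likelihood API --------------------------------------------

    def site_logliks(self, states: np.ndarray, conditioned: bool = True) -> np.ndarray:
        """Observability-conditioned log-likelihood of each site: (S,)."""
        logs = self._site_logliks_by_category(states)
        logmix = logsumexp(logs, axis=0) - np.log(self.K)
        if not conditioned:
            return logmix
        log_denominator = np.log1p(-min(np.exp(self.log_p_unobserved), 1.0 - 1e-15))
        return logmix - log_denominator

    def total_loglik(self, table: IntronSiteTable, deduplicate: bool = True) -> float:
        if table.n_sites == 0:
            raise ValueError("empty site table")
        states = table.states
        if deduplicate:
            patterns, counts = np.unique(states, axis=0, return_counts=True)
            return float(self.site_logliks(patterns) @ counts)
        return float(self.site_logliks(states).sum())

    # -- posterior decoding ------------------------------------------------

    def _down(self, F, M):
        """Outside probabilities D (K,S,N,2), normalized per node."""
        tree = self.tree
        K, S = F.shape[0], F.shape[1]
        D = np.empty_like(F)
        D[:, :, tree.root] = self.pi
        for v in tree.preorder():
            kids = tree.children[v]
            for c in kids:
                excl = D[:, :, v].copy()
                for w in kids:
                    if w != c:
                        excl *= M[:, :, w]
                down = np.einsum("ksa,kab->ksb", excl, self.P[:, c])
                norm = np.maximum(down.sum(axis=2), _TINY)
                D[:, :, c] = down / norm[..., None]
        return D

    def _category_weights(self, states: np.ndarray) -> np.ndarray:
        """Posterior weight of each loss-rate category per site: (K, S)."""
        logs = self._site_logliks_by_category(states)
        logs = logs - logs.max(axis=0, keepdims=True)
        w = np.exp(logs)
        return w / w.sum(axis=0, keepdims=True)

    def node_posteriors(self, states: np.ndarray) -> np.ndarray:
        """P(node state = 1 | leaf data) for every site and node: (S, N)."""
        F, _, M = self._up(states, keep_messages=True)
        D = self._down(F, M)
        num = F * D  # (K,S,N,2)
        denom = np.maximum(num.sum(axis=3), _TINY)
        post_c = num[..., 1] / denom  # (K,S,N)
        w = self._category_weights(states)  # (K,S)
        return np.einsum("ks,ksn->sn", w, post_c)

    # -- sufficient statistics for the likelihood gradient -----------------

    def flows(self, states: np.ndarray, counts: np.ndarray | None = None):
        """Weighted log-likelihood and its sufficient statistics.

        For site weights ``counts`` (default all ones) returns a dict with

        * ``loglik``: sum of counts * unconditioned per-site log mixture
          likelihood;
        * ``dpi``: derivative of that sum with respect to pi_root;
        * ``C``: array (K, N, 2, 2) of expected transition flows,
          C[c,v,a,b] = sum_s counts_s w_cs J_cs(a,b) / P[c,v,a,b], so that
          d loglik / d P[c,v,a,b] = C[c,v,a,b] at fixed row sums.

        These are the ingredients of the analytic gradient of the pruning
        likelihood with respect to the per-branch intensities.
        """
        tree = self.tree
        S = states.shape[0]
        if counts is None:
            counts = np.ones(S)
        F, logscale, M = self._up(states, keep_messages=True)
        root_lik = np.maximum(F[:, :, tree.root] @ self.pi, _TINY)  # (K,S)
        logs = np.log(root_lik) + logscale
        logmix = logsumexp(logs, axis=0) - np.log(self.K)
        shifted = np.exp(logs - logs.max(axis=0, keepdims=True))
        w = shifted / shifted.sum(axis=0, keepdims=True)  # (K,S)

        # d logmix / d pi = sum_c w_c (F1 - F0) / (pi . F)
        dpi_site = np.einsum(
            "ks,ks->s", w, (F[:, :, tree.root, 1] - F[:, :, tree.root, 0]) / root_lik
        )
        D = self._down(F, M)
        C = np.zeros((self.K, tree.n_nodes, 2, 2))
        wc = w * counts  # (K,S)
        for v in tree.preorder():
            kids = tree.children[v]
            for c in kids:
                excl = D[:, :, v].copy()
                for x in kids:
                    if x != c:
                        excl *= M[:, :, x]
                J = np.einsum("ksa,kab,ksb->ksab", excl, self.P[:, c], F[:, :, c])
                norm = np.maximum(J.sum(axis=(2, 3)), _TINY)
                J /= norm[..., None, None]
                C[:, c] = np.einsum("ks,ksab->kab", wc, J) / np.maximum(
                    self.P[:, c], _TINY
                )
        return {
            "loglik": float(logmix @ counts),
            "dpi": float(dpi_site @ counts),
            "C": C,
            "logmix": logmix,
        }

    def branch_event_posteriors(self, states: np.ndarray):
        """Posterior gain/loss probability on every branch, per site.

        Returns (P_gain, P_loss), each (S, N); entries at the root index
        are zero.  P_gain is the posterior probability that the parent was
        absent and the child present across the branch above each node,
        category-marginalized with the per-site posterior category weights.
        """
        tree = self.tree
        F, _, M = self._up(states, keep_messages=True)
        D = self._down(F, M)
        w = self._category_weights(states)
        S, N = states.shape[0], tree.n_nodes
        p_gain = np.zeros((S, N))
        p_loss = np.zeros((S, N))
        for v in tree.preorder():
            kids = tree.children[v]
            for c in kids:
                excl = D[:, :, v].copy()
                for x in kids:
                    if x != c:
                        excl *= M[:, :, x]
                # joint over (parent state a, child state b)
                J = np.einsum(
                    "ksa,kab,ksb->ksab", excl, self.P[:, c], F[:, :, c]
                )
                norm = np.maximum(J.sum(axis=(2, 3)), _TINY)
                J /= norm[..., None, None]
                p_gain[:, c] = np.einsum("ks,ks->s", w, J[..., 0, 1])
                p_loss[:, c] = np.einsum("ks,ks->s", w, J[..., 1, 0])
        return p_gain, p_loss


def _states_for(tree: PhyloTree, site: SiteRecord) -> np.ndarray:
    states = np.asarray(site.states, dtype=np.int8)[None, :]
    if np.all(states == MISSING):
        raise ValueError("site with all states ambiguous (filter upstream)")
    return states


def site_loglik(tree: PhyloTree, model: GainLossModel, site: SiteRecord) -> float:
    """Observability-conditioned log-likelihood of a single site."""
    engine = PruningEngine(tree, model)
    return float(engine.site_logliks(_states_for(tree, site))[0])


def total_loglik(
    tree: PhyloTree, model: GainLossModel, table: IntronSiteTable,
    deduplicate: bool = True,
) -> float:
    """Sum of conditioned site log-likelihoods over the table."""
    return PruningEngine(tree, model).total_loglik(table, deduplicate=deduplicate)


def posterior_node_presence(
    tree: PhyloTree, model: GainLossModel, site: SiteRecord
) -> np.ndarray:
    """P(state = 1 | data) at every node for one site."""
    engine = PruningEngine(tree, model)
    return engine.node_posteriors(_states_for(tree, site))[0]


def branch_event_posteriors(
    tree: PhyloTree, model: GainLossModel, site: SiteRecord
):
    """Per-branch posterior gain and loss probabilities for one site."""
    engine = PruningEngine(tree, model)
    g, l = engine.branch_event_posteriors(_states_for(tree, site))
    return g[0], l[0]
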