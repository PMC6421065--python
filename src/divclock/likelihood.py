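"""Felsenstein pruning likelihood for GTR + discrete-Gamma, with gradients.

Inference in this package evaluates alignment likelihoods on rooted trees
(multifurcations allowed) under the GTR model with a K-category discrete
gamma (median per category, normalized to mean 1).  Site patterns are
compressed once; conditional likelihoods are propagated with per-pattern
scaling.  A reverse (preorder) pass yields the exact derivative of the
log-likelihood with respect to every branch length in O(tree) — this is what
makes joint optimization of node ages and rates in :mod:`.treeinfer` cheap.

Arrays are laid out (K categories, P patterns, 4 states) so that all inner
products are batched matmuls.  Branch lengths are addressed by node index:
node ``i``'s entry in the length vector is the edge above it; the root's
entry is ignored.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as _gamma_dist

from .seqsim import Alignment, GTRParams, _Propagator

#: hard bounds for maximum-likelihood branch lengths (substitutions/site)
MIN_BRANCH_LENGTH = 1e-9
MAX_BRANCH_LENGTH = 20.0


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """K-category discrete gamma rate multipliers (median rule, mean 1)."""
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.array([1.0])
    q = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    rates = _gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha)
    return rates * (k / rates.sum())


class PruningLikelihood:
    """Likelihood engine bound to one (tree topology, alignment) pair.

    The topology is fixed at construction; branch lengths are free inputs so
    the same engine serves both unconstrained ML and clock-constrained
    dating.  Substitution parameters are fixed (not co-estimated).
    """

    def __init__(self, tree, aln: Alignment, params: GTRParams, n_categories: int = 4):
        self.params = params
        self.prop = _Propagator(params)
        self.rho = discrete_gamma_rates(params.alpha, n_categories)
        self.K = n_categories
        self.pi = self.prop.pi

        # --- node indexing: postorder
        self.nodes = list(tree.postorder_node_iter())
        self.index = {nd: i for i, nd in enumerate(self.nodes)}
        self.root = self.index[tree.seed_node]
        self.children: list[list[int]] = [
            [self.index[c] for c in nd.child_nodes()] for nd in self.nodes
        ]
        self.parent = np.full(len(self.nodes), -1, dtype=int)
        for i, kids in enumerate(self.children):
            for c in kids:
                self.parent[c] = i
        self.n_nodes = len(self.nodes)

        # --- pattern compression
        tip_rows = [i for i, nd in enumerate(self.nodes) if nd.is_leaf()]
        order = [aln.taxa.index(self.nodes[i].taxon.label) for i in tip_rows]
        patterns, weights = np.unique(aln.data[order, :], axis=1, return_counts=True)
        self.weights = weights.astype(float)
        self.P_count = patterns.shape[1]
        self.tip_states = {tip_rows[r]: patterns[r] for r in range(len(tip_rows))}

        self.n_sites = aln.length
        self.initial_lengths = np.array(
            [nd.edge.length if nd.edge.length is not None else 0.0 for nd in self.nodes]
        )
        self.initial_lengths[self.root] = 0.0

    # ------------------------------------------------------------------
    def _edge_pmat(self, b: float, deriv: bool = False):
        """P(b * rho_k) for one edge, shape (K, 4, 4); optionally d/db."""
        E = np.exp(np.multiply.outer(b * self.rho, self.prop.w))  # (K, 4)
        P = np.clip((self.prop.U[None] * E[:, None, :]) @ self.prop.Uinv, 0.0, None)
        if not deriv:
            return P, None
        dE = E * (self.prop.w[None, :] * self.rho[:, None])
        dP = (self.prop.U[None] * dE[:, None, :]) @ self.prop.Uinv
        return P, dP

    def _pmats(self, b: np.ndarray, deriv: bool = False):
        """Per-edge transition matrices, shape (n_nodes, K, 4, 4)."""
        T = np.multiply.outer(np.clip(b, 0.0, None), self.rho)  # (n, K)
        E = np.exp(T[..., None] * self.prop.w)  # (n, K, 4)
        P = np.clip((self.prop.U[None, None] * E[:, :, None, :]) @ self.prop.Uinv, 0.0, None)
        if not deriv:
            return P, None
        dE = E * (self.prop.w[None, None, :] * self.rho[None, :, None])
        dP = (self.prop.U[None, None] * dE[:, :, None, :]) @ self.prop.Uinv
        return P, dP

    def _tip_msg(self, M: np.ndarray, node: int) -> np.ndarray:
        """Message (K, P, 4) from a tip given its per-category matrices (K,4,4)."""
        return M[:, :, self.tip_states[node]].transpose(0, 2, 1)

    def _up_pass(self, P):
        """Conditional likelihoods F and child->parent messages, with scaling."""
        F = [None] * self.n_nodes
        msg = [None] * self.n_nodes
        logscale = np.zeros(self.P_count)
        for i in range(self.n_nodes):
            kids = self.children[i]
            if not kids:
                continue
            f = None
            for c in kids:
                m = msg[c] if msg[c] is not None else self._tip_msg(P[c], c)
                msg[c] = m
                f = m.copy() if f is None else f * m
            scale = f.max(axis=(0, 2))
            scale = np.where(scale > 0, scale, 1.0)
            f /= scale[None, :, None]
            logscale += np.log(scale)
            F[i] = f
            if i != self.root:
                msg[i] = f @ np.swapaxes(P[i], 1, 2)
        return F, msg, logscale

    def loglik(self, b: np.ndarray) -> float:
        P, _ = self._pmats(np.asarray(b, dtype=float))
        F, _, logscale = self._up_pass(P)
        site = (F[self.root] @ self.pi).sum(axis=0) / self.K
        return float(np.dot(self.weights, np.log(site) + logscale))

    def loglik_grad(self, b: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and its exact gradient w.r.t. every branch length."""
        b = np.asarray(b, dtype=float)
        P, dP = self._pmats(b, deriv=True)
        F, msg, logscale = self._up_pass(P)
        site = (F[self.root] @ self.pi).sum(axis=0) / self.K
        ll = float(np.dot(self.weights, np.log(site) + logscale))

        grad = np.zeros(self.n_nodes)
        # A[i]: outside-subtree partial at node i (arbitrary per-pattern scale)
        A = [None] * self.n_nodes
        A[self.root] = np.broadcast_to(self.pi, (self.K, self.P_count, 4))
        for i in range(self.n_nodes - 1, -1, -1):
            kids = self.children[i]
            if not kids:
                continue
            for j, c in enumerate(kids):
                sib = A[i]
                for jj, cc in enumerate(kids):
                    if jj != j:
                        sib = sib * msg[cc]
                if self.children[c]:
                    dmsg = F[c] @ np.swapaxes(dP[c], 1, 2)
                else:
                    dmsg = self._tip_msg(dP[c], c)
                den = np.einsum("kpx,kpx->p", sib, msg[c])
                num = np.einsum("kpx,kpx->p", sib, dmsg)
                grad[c] = float(np.dot(self.weights, num / den))
                if self.children[c]:
                    a = sib @ P[c]
                    amax = a.max(axis=(0, 2))
                    A[c] = a / np.where(amax > 0, amax, 1.0)[None, :, None]
        return ll, grad

    # ------------------------------------------------------------------
    def optimize_branch_lengths(
        self,
        b0: np.ndarray | None = None,
        tol: float = 1e-6,
        max_sweeps: int = 50,
    ) -> tuple[np.ndarray, float, bool]:
        """Coordinate-wise (per-edge Brent) ML branch lengths.

        Each sweep recomputes the conditional likelihoods, then optimizes
        every edge length in turn against its one-dimensional profile
        (Gauss-Seidel: the edge's upward message is refreshed immediately so
        later edges see the new value); iterates until the relative
        log-likelihood change drops below ``tol``.
        """
        b = np.array(self.initial_lengths if b0 is None else b0, dtype=float)
        b = np.clip(b, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH)
        b[self.root] = 0.0
        prev = self.loglik(b)
        converged = False
        for _ in range(max_sweeps):
            P, _ = self._pmats(b)
            F, msg, _ = self._up_pass(P)
            A = [None] * self.n_nodes
            A[self.root] = np.broadcast_to(self.pi, (self.K, self.P_count, 4))
            for i in range(self.n_nodes - 1, -1, -1):
                kids = self.children[i]
                if not kids:
                    continue
                for j, c in enumerate(kids):
                    sib = A[i]
                    for jj, cc in enumerate(kids):
                        if jj != j:
                            sib = sib * msg[cc]
                    fc = F[c] if self.children[c] else None
                    states = None if fc is not None else self.tip_states[c]

                    def negll(x):
                        Pc, _ = self._edge_pmat(x)
                        if fc is not None:
                            t = fc @ np.swapaxes(Pc, 1, 2)
                        else:
                            t = Pc[:, :, states].transpose(0, 2, 1)
                        den = np.einsum("kpx,kpx->p", sib, t)
                        return -float(
                            np.dot(self.weights, np.log(np.maximum(den, 1e-300)))
                        )

                    res = minimize_scalar(
                        negll,
                        bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                        method="bounded",
                        options={"xatol": 1e-10},
                    )
                    b[c] = float(res.x)
                    Pc, _ = self._edge_pmat(b[c])
                    if fc is not None:
                        msg[c] = fc @ np.swapaxes(Pc, 1, 2)
                        a = sib @ Pc
                        amax = a.max(axis=(0, 2))
                        A[c] = a / np.where(amax > 0, amax, 1.0)[None, :, None]
                    else:
                        msg[c] = self._tip_msg(Pc, c)
            cur = self.loglik(b)
            if abs(cur - prev) <= tol * max(abs(cur), 1.0):
                converged = True
                prev = cur
                break
            prev = cur
        return b, prev, converged
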