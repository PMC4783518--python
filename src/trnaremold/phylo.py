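"""Phylogenetic likelihood engine (pruning algorithm, branch optimization).

Implements time-reversible nucleotide models (JC69 and GTR, optional
discrete-gamma rate variation) on rooted binary trees, the Felsenstein
pruning log-likelihood, and round-robin per-branch length optimization.
Gaps and N are treated as missing data.  The rate matrix is scaled to one
expected substitution per unit branch length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _opt
from scipy.special import gammainc, logsumexp

from .core import TreeNode

logger = logging.getLogger(__name__)

_STATE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_EXCH_ORDER = ("AC", "AG", "AU", "CG", "CU", "GU")


def encode_alignment_row(seq: str) -> np.ndarray:
    """Map a gapped RNA/DNA row to state indices; 4 marks missing (gap/N)."""
    return np.array([_STATE.get(c.upper(), 4) for c in seq], dtype=np.int64)


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean-per-quantile-class discretization of a mean-1 gamma."""
    if ncat == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=shape, scale=1.0 / shape)
    upper = np.concatenate([edges, [np.inf]])
    lower = np.concatenate([[0.0], edges])
    # mean of a mean-1 gamma over [l, u) via the regularized incomplete gamma
    seg = gammainc(shape + 1, shape * np.where(np.isinf(upper), 1e12, upper)) \
        - gammainc(shape + 1, shape * lower)
    return ncat * seg


@dataclass
class SubstitutionModel:
    """Reversible substitution model with eigendecomposed rate matrix."""

    freqs: np.ndarray
    exch: np.ndarray                  # AC, AG, AU, CG, CU, GU
    gamma_shape: float | None = None
    ncat: int = 4
    name: str = "gtr"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exch = np.asarray(self.exch, dtype=float)
        if self.freqs.shape != (4,) or not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("base frequencies must be 4 values summing to 1")
        if self.exch.shape != (6,) or np.any(self.exch <= 0):
            raise ValueError("exchangeabilities must be 6 positive values")
        R = np.zeros((4, 4))
        k = 0
        for i in range(4):
            for j in range(i + 1, 4):
                R[i, j] = R[j, i] = self.exch[k]
                k += 1
        Q = R * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.freqs * np.diag(Q)).sum()
        Q /= mu
        self.Q = Q
        # reversible: symmetrize and use a real eigendecomposition
        sq = np.sqrt(self.freqs)
        S = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._eigvals = w
        self._left = U / sq[:, None]       # D^{-1/2} U
        self._right = U.T * sq[None, :]    # U^T D^{1/2}
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self.rates = (discrete_gamma_rates(self.gamma_shape, self.ncat)
                      if self.gamma_shape is not None else np.ones(1))

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), clipped to non-negative for numerical safety."""
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        return np.clip(P, 0.0, None)

    def transition_many(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for several branch lengths, shape (len(ts), 4, 4)."""
        expwt = np.exp(np.outer(ts, self._eigvals))           # (K, 4)
        P = np.einsum("xe,ke,ey->kxy", self._left, expwt, self._right)
        return np.clip(P, 0.0, None)

    @classmethod
    def jc69(cls, gamma_shape: float | None = None, ncat: int = 4):
        return cls(freqs=np.full(4, 0.25), exch=np.ones(6),
                   gamma_shape=gamma_shape, ncat=ncat, name="jc69")

    @classmethod
    def gtr(cls, freqs=None, exch=None, gamma_shape: float | None = None,
            ncat: int = 4):
        return cls(
            freqs=np.full(4, 0.25) if freqs is None else freqs,
            exch=np.ones(6) if exch is None else exch,
            gamma_shape=gamma_shape, ncat=ncat, name="gtr",
        )

    @classmethod
    def empirical_gtr(cls, sequences, gamma_shape: float | None = None,
                      ncat: int = 4):
        """GTR with empirical base frequencies from ungapped characters."""
        counts = np.zeros(4)
        for s in sequences:
            enc = encode_alignment_row(s)
            for k in range(4):
                counts[k] += (enc == k).sum()
        total = counts.sum()
        freqs = counts / total if total else np.full(4, 0.25)
        freqs = np.clip(freqs, 1e-3, None)
        freqs /= freqs.sum()
        return cls(freqs=freqs, exch=np.ones(6), gamma_shape=gamma_shape,
                   ncat=ncat, name="gtr")


class LikelihoodEngine:
    """Pruning likelihood and branch-length optimization on one topology.

    The tree is flattened into post-order arrays once; leaf partials are
    one-hot vectors (all-ones for missing states).  ``optimize`` performs
    round-robin Brent optimization of each branch using up/down conditional
    likelihoods that are refreshed once per sweep; a best-seen guard makes
    the returned log-likelihood monotone in the starting point.
    """

    MIN_BL = 1e-6
    MAX_BL = 10.0

    def __init__(self, root: TreeNode, leaf_seqs: dict[str, str],
                 model: SubstitutionModel):
        self.model = model
        self.nodes: list[TreeNode] = list(root.postorder())
        self.index = {id(n): k for k, n in enumerate(self.nodes)}
        self.parent = np.array([
            self.index[id(n.parent)] if n.parent is not None else -1
            for n in self.nodes
        ])
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.root_idx = len(self.nodes) - 1
        self.lengths = np.array([
            (n.length if n.length is not None else 0.1)
            if n.parent is not None else 0.0
            for n in self.nodes
        ])
        self.lengths = np.clip(self.lengths, self.MIN_BL, self.MAX_BL)
        self.lengths[self.root_idx] = 0.0
        self.leaf_partial: dict[int, np.ndarray] = {}
        n_sites = None
        for k, node in enumerate(self.nodes):
            if node.children:
                continue
            if node.name not in leaf_seqs:
                raise ValueError(f"leaf {node.name!r} has no sequence")
            enc = encode_alignment_row(leaf_seqs[node.name])
            if n_sites is None:
                n_sites = enc.size
            elif enc.size != n_sites:
                raise ValueError("aligned sequences differ in length")
            part = np.zeros((enc.size, 4))
            known = enc < 4
            part[np.arange(enc.size)[known], enc[known]] = 1.0
            part[~known, :] = 1.0
            self.leaf_partial[k] = part
        if n_sites is None:
            raise ValueError("tree has no leaves")
        self.n_sites = n_sites

    # -- likelihood ------------------------------------------------------
    def _down(self, lengths, rate):
        """Post-order partials and per-edge child contributions, one rate."""
        down = [None] * len(self.nodes)
        contrib = [None] * len(self.nodes)   # P(t_k) applied to down[k]
        for k, node in enumerate(self.nodes):
            if not self.children[k]:
                down[k] = self.leaf_partial[k]
            else:
                prod = None
                for c in self.children[k]:
                    P = self.model.transition(rate * lengths[c])
                    contrib[c] = down[c] @ P.T
                    prod = contrib[c] if prod is None else prod * contrib[c]
                down[k] = prod
        return down, contrib

    def loglik(self, lengths=None) -> float:
        lengths = self.lengths if lengths is None else lengths
        pi = self.model.freqs
        if len(self.model.rates) == 1:
            down, _ = self._down(lengths, 1.0 * self.model.rates[0])
            site = down[self.root_idx] @ pi
            return float(np.log(np.clip(site, 1e-300, None)).sum())
        per_rate = np.empty((len(self.model.rates), self.n_sites))
        for r, rate in enumerate(self.model.rates):
            down, _ = self._down(lengths, rate)
            site = down[self.root_idx] @ pi
            per_rate[r] = np.log(np.clip(site, 1e-300, None))
        w = np.log(1.0 / len(self.model.rates))
        return float(logsumexp(per_rate + w, axis=0).sum())

    def _up(self, down, contrib, lengths, rate):
        """Pre-order conditionals; up[k] includes the root frequencies."""
        up = [None] * len(self.nodes)
        up[self.root_idx] = np.broadcast_to(
            self.model.freqs, (self.n_sites, 4)).copy()
        for k in range(len(self.nodes) - 1, -1, -1):
            for c in self.children[k]:
                prod = up[k]
                for s in self.children[k]:
                    if s != c:
                        prod = prod * contrib[s]
                up[c] = prod
        return up

    def _edge_loglik(self, up_c, down_c, t):
        """log-likelihood as a function of one branch length."""
        if len(self.model.rates) == 1:
            P = self.model.transition(self.model.rates[0] * t)
            site = np.einsum("sx,xy,sy->s", up_c[0], P, down_c[0])
            return float(np.log(np.clip(site, 1e-300, None)).sum())
        per_rate = np.empty((len(self.model.rates), self.n_sites))
        for r, (rate, U, Dn) in enumerate(zip(self.model.rates, up_c, down_c)):
            P = self.model.transition(rate * t)
            per_rate[r] = np.log(
                np.clip(np.einsum("sx,xy,sy->s", U, P, Dn), 1e-300, None))
        w = np.log(1.0 / len(self.model.rates))
        return float(logsumexp(per_rate + w, axis=0).sum())

    def _edge_loglik_many(self, up_c, down_c, ts: np.ndarray) -> np.ndarray:
        """Vectorized edge log-likelihood over several candidate lengths."""
        R = len(self.model.rates)
        acc = np.empty((R, len(ts), self.n_sites))
        for r, (rate, U, Dn) in enumerate(zip(self.model.rates, up_c, down_c)):
            P = self.model.transition_many(rate * ts)        # (K, 4, 4)
            acc[r] = np.clip(np.einsum("sx,kxy,sy->ks", U, P, Dn),
                             1e-300, None)
        if R == 1:
            return np.log(acc[0]).sum(axis=1)
        w = np.log(1.0 / R)
        return logsumexp(np.log(acc) + w, axis=0).sum(axis=1)

    def _optimize_edge(self, up_c, down_c, t0: float,
                       xatol: float = 1e-5) -> tuple[float, float]:
        """Best length for one edge: staged geometric grids + Brent refine.

        Returns ``(t, loglik)``; never worse than the starting length.
        """
        grid = np.geomspace(self.MIN_BL, self.MAX_BL, 16)
        ts = np.append(grid, t0)
        ll = self._edge_loglik_many(up_c, down_c, ts)
        k = int(np.argmax(ll))
        best_t, best_ll = float(ts[k]), float(ll[k])
        ratio = (self.MAX_BL / self.MIN_BL) ** (1.0 / 15)
        lo = max(self.MIN_BL, best_t / ratio)
        hi = min(self.MAX_BL, best_t * ratio)
        if hi / lo > 1.001:
            ts2 = np.geomspace(lo, hi, 10)
            ll2 = self._edge_loglik_many(up_c, down_c, ts2)
            k2 = int(np.argmax(ll2))
            if ll2[k2] > best_ll:
                best_t, best_ll = float(ts2[k2]), float(ll2[k2])
            r2 = (hi / lo) ** (1.0 / 9)
            res = _opt.minimize_scalar(
                lambda t: -self._edge_loglik(up_c, down_c, t),
                bounds=(max(self.MIN_BL, best_t / r2),
                        min(self.MAX_BL, best_t * r2)),
                method="bounded", options={"xatol": xatol, "maxiter": 25},
            )
            if -res.fun > best_ll:
                best_t, best_ll = float(res.x), float(-res.fun)
        return best_t, best_ll

    def optimize(self, tol: float = 1e-4, max_sweeps: int = 20,
                 xatol: float = 1e-5):
        """Round-robin branch-length optimization.

        Each sweep computes fresh post-order partials, then walks the tree
        in pre-order maintaining up-conditionals incrementally: when an edge
        is optimized, every quantity it sees is exact for the current state
        of all other edges (descendant edges are untouched, ancestor edges
        were refreshed on the way down, sibling contributions carry their
        current lengths), so every single-edge step is monotone in the true
        log-likelihood.  Returns ``(lengths, loglik, converged)``.
        """
        R = len(self.model.rates)
        lengths = self.lengths.copy()
        prev_ll = self.loglik(lengths)
        converged = False
        for sweep in range(max_sweeps):
            downs, contribs = [], []
            for rate in self.model.rates:
                down, contrib = self._down(lengths, rate)
                downs.append(down)
                contribs.append(contrib)
            ups = [[None] * len(self.nodes) for _ in range(R)]
            for r in range(R):
                ups[r][self.root_idx] = np.broadcast_to(
                    self.model.freqs, (self.n_sites, 4))
            stack = [self.root_idx]
            while stack:
                k = stack.pop()
                for c in self.children[k]:
                    for r in range(R):
                        prod = ups[r][k]
                        for s in self.children[k]:
                            if s != c:
                                prod = prod * contribs[r][s]
                        ups[r][c] = prod
                    up_c = [ups[r][c] for r in range(R)]
                    down_c = [downs[r][c] for r in range(R)]
                    lengths[c], _ = self._optimize_edge(up_c, down_c,
                                                        lengths[c],
                                                        xatol=xatol)
                    for r, rate in enumerate(self.model.rates):
                        P = self.model.transition(rate * lengths[c])
                        contribs[r][c] = downs[r][c] @ P.T
                    stack.append(c)
            ll = self.loglik(lengths)
            improvement = ll - prev_ll
            prev_ll = ll
            if improvement < tol:
                converged = True
                break
        if not converged:
            logger.warning("branch-length optimization: no convergence "
                           "after %d sweeps", max_sweeps)
        self.lengths = lengths
        return lengths, prev_ll, converged

    def write_lengths(self):
        """Copy optimized lengths back onto the tree nodes."""
        for k, node in enumerate(self.nodes):
            if node.parent is not None:
                node.length = float(self.lengths[k])


def felsenstein_loglik(root: TreeNode, leaf_seqs: dict[str, str],
                       model: SubstitutionModel) -> float:
    """Pruning-algorithm log-likelihood of aligned sequences on a tree."""
    if root.is_leaf:
        # degenerate single-leaf tree: logL = sum of log pi over known sites
        enc = encode_alignment_row(leaf_seqs[root.name])
        pi = model.freqs
        return float(sum(np.log(pi[s]) if s < 4 else 0.0 for s in enc))
    return LikelihoodEngine(root, leaf_seqs, model).loglik()


def optimize_branch_lengths(root: TreeNode, leaf_seqs: dict[str, str],
                            model: SubstitutionModel, tol: float = 1e-4,
                            max_sweeps: int = 20):
    """Optimize every branch of ``root`` in place; returns (root, logL)."""
    engine = LikelihoodEngine(root, leaf_seqs, model)
    _, ll, _ = engine.optimize(tol=tol, max_sweeps=max_sweeps)
    engine.write_lengths()
    return root, ll
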