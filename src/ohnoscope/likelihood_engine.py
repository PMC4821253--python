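"""Felsenstein-pruning site likelihoods and fixed-topology optimization.

Per-site likelihoods are computed by the pruning algorithm under a
reversible rate matrix with discrete-gamma rate mixing.  Identical site
patterns are collapsed once and expanded on output.  Underflow is
controlled by per-node, per-category scaling factors.  Branch lengths are
optimized by exact coordinate ascent: a depth-first sweep keeps the
"outside" partial of each edge current, so every one-dimensional Brent
search maximizes the true likelihood in that branch, and the total
log-likelihood is nondecreasing across sweeps.

Sites whose likelihood underflows to zero (possible only at hard zero
branch lengths with conflicting states) report a configurable log floor
(default -745, just inside float64 range) so that downstream RELL
resampling stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import Alignment, GAP, AMBIG
from .subst_model import GammaRates, RateModel, discrete_gamma, transition_matrices
from .tree import Node, Tree

LOG_FLOOR = -745.0
MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0


@dataclass(frozen=True)
class SiteLoglikMatrix:
    """Per-topology, per-site log-likelihoods (the object RELL resamples)."""

    topology_ids: tuple[str, ...]
    values: np.ndarray  # (n_topologies, n_sites)

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("topology\t" + "\t".join(
                f"site{i+1}" for i in range(self.n_sites)) + "\n")
            for tid, row in zip(self.topology_ids, self.values):
                fh.write(tid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "SiteLoglikMatrix":
        ids, rows = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("topology"):
                raise ValueError("not a site log-likelihood TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(tuple(ids), np.array(rows))


class PruningEngine:
    """Pruning machinery bound to one (tree, alignment, model, gamma)."""

    def __init__(self, tree: Tree, aln: Alignment, model: RateModel,
                 gamma: GammaRates, log_floor: float = LOG_FLOOR,
                 dtype=np.float64):
        self.tree = tree
        self.model = model
        self.gamma = gamma
        self.log_floor = log_floor
        self.dtype = np.dtype(dtype)
        self.S = model.n_states

        self.nodes: list[Node] = list(tree.postorder())
        self.idx = {id(n): i for i, n in enumerate(self.nodes)}
        self.root_i = self.idx[id(tree.root)]

        leaves = [n for n in self.nodes if n.is_leaf]
        missing = [n.name for n in leaves if n.name not in aln.names]
        if missing:
            raise ValueError(f"missing leaf sequence(s): {missing}")
        lut = np.full(256, -1, dtype=np.int16)
        for i, ch in enumerate(model.alphabet):
            lut[ord(ch)] = i
        lut[ord(GAP)] = lut[ord(AMBIG)] = -1
        codes = np.empty((len(leaves), aln.n_cols), dtype=np.int16)
        for r, leaf in enumerate(leaves):
            raw = np.frombuffer(aln.seq(leaf.name).encode("ascii"), dtype=np.uint8)
            codes[r] = lut[raw]
        # collapse identical site patterns
        pats, inverse, counts = np.unique(codes, axis=1, return_inverse=True,
                                          return_counts=True)
        self.pattern_inverse = inverse.ravel()
        self.pattern_counts = counts.astype(float)
        self.n_pat = pats.shape[1]
        self.n_sites = aln.n_cols

        self.leaf_partial: dict[int, np.ndarray] = {}
        for r, leaf in enumerate(leaves):
            L = np.zeros((self.n_pat, self.S), dtype=self.dtype)
            obs = pats[r]
            L[obs < 0] = 1.0  # gap / X: flat conditional likelihood
            seen = obs >= 0
            L[np.arange(self.n_pat)[seen], obs[seen]] = 1.0
            self.leaf_partial[self.idx[id(leaf)]] = L

        k = gamma.k
        self.D = [None] * len(self.nodes)      # (k, n_pat, S) down partials
        self.lsD = [None] * len(self.nodes)    # (k, n_pat) log scale factors
        self.U = [None] * len(self.nodes)      # outside partials (root: pi)
        self.lsU = [None] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                self.D[i] = np.broadcast_to(self.leaf_partial[i],
                                            (k, self.n_pat, self.S))
                self.lsD[i] = np.zeros((k, self.n_pat))

    # ------------------------------------------------------------- passes

    def _trans(self, t: float) -> np.ndarray:
        P = transition_matrices(self.model, t, self.gamma.rates)
        return P.astype(self.dtype, copy=False)

    def _edge_matrix(self, i: int) -> np.ndarray:
        """M_i(x) = sum_y P(t_i)[x,y] D_i(y), the child i's message to its
        parent."""
        P = self._trans(self.nodes[i].length)
        return self.D[i] @ P.transpose(0, 2, 1)

    def down_pass(self) -> None:
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                continue
            prod = None
            ls = np.zeros((self.gamma.k, self.n_pat))
            for c in n.children:
                ci = self.idx[id(c)]
                M = self._edge_matrix(ci)
                prod = M if prod is None else prod * M
                ls += self.lsD[ci]
            m = prod.max(axis=2)
            safe = np.where(m > 0, m, 1.0)
            prod = prod / safe[..., None]
            with np.errstate(divide="ignore"):
                ls += np.where(m > 0, np.log(safe), 0.0)
            self.D[i] = prod
            self.lsD[i] = ls

    def up_pass(self) -> None:
        """Outside partials U_v(x) = P(data outside subtree(v) | state v=x),
        with the stationary prior folded into U_root."""
        k = self.gamma.k
        self.U[self.root_i] = np.broadcast_to(
            self.model.frequencies.astype(self.dtype),
            (k, self.n_pat, self.S)).copy()
        self.lsU[self.root_i] = np.zeros((k, self.n_pat))
        for n in self.tree.preorder():
            i = self.idx[id(n)]
            if n.is_leaf:
                continue
            msgs = {}
            for c in n.children:
                ci = self.idx[id(c)]
                msgs[ci] = self._edge_matrix(ci)
            for c in n.children:
                ci = self.idx[id(c)]
                E = self.U[i].copy()
                ls = self.lsU[i].copy()
                for s in n.children:
                    si = self.idx[id(s)]
                    if si != ci:
                        E = E * msgs[si]
                        ls = ls + self.lsD[si]
                P = self._trans(self.nodes[ci].length)
                Uc = E @ P
                m = Uc.max(axis=2)
                safe = np.where(m > 0, m, 1.0)
                Uc /= safe[..., None]
                with np.errstate(divide="ignore"):
                    ls = ls + np.where(m > 0, np.log(safe), 0.0)
                self.U[ci] = Uc
                self.lsU[ci] = ls

    # ---------------------------------------------------------- likelihood

    def _pattern_logliks(self) -> np.ndarray:
        ri = self.root_i
        L = self.D[ri] @ self.model.frequencies
        return self._mix(L, self.lsD[ri])

    def _mix(self, L: np.ndarray, ls: np.ndarray) -> np.ndarray:
        """Log of the gamma mixture sum_k w_k L_k exp(ls_k), per pattern."""
        logw = -np.log(self.gamma.k)
        if L.min() > 0.0:
            logL = np.log(L)
            logL += ls
            m = logL.max(axis=0)
            out = logw + m + np.log(np.exp(logL - m[None, :]).sum(axis=0))
            return np.maximum(out, self.log_floor)
        with np.errstate(divide="ignore"):
            logL = np.where(L > 0, np.log(np.where(L > 0, L, 1.0)), -np.inf) + ls
        m = logL.max(axis=0)
        finite = np.isfinite(m)
        out = np.full(self.n_pat, self.log_floor)
        if finite.any():
            z = np.exp(logL[:, finite] - m[finite])
            out[finite] = logw + m[finite] + np.log(z.sum(axis=0))
        return np.maximum(out, self.log_floor)

    def site_logliks(self) -> np.ndarray:
        self.down_pass()
        return self._pattern_logliks()[self.pattern_inverse]

    def total_loglik(self) -> float:
        self.down_pass()
        return float(self._pattern_logliks() @ self.pattern_counts)

    def _edge_loglik(self, ci: int, E: np.ndarray, lsE: np.ndarray,
                     t: float) -> float:
        P = self._trans(t)
        PD = self.D[ci] @ P.transpose(0, 2, 1)
        L = (E * PD).sum(axis=2)
        pat = self._mix(L, lsE + self.lsD[ci])
        return float(pat @ self.pattern_counts)

    # -------------------------------------------------------- optimization

    def optimize_lengths(self, tol: float = 1e-6, max_rounds: int = 50,
                         xatol: float = 1e-6,
                         min_len: float = MIN_BRANCH_LENGTH,
                         max_len: float = MAX_BRANCH_LENGTH) -> float:
        """Coordinate-ascent ML branch lengths on the fixed topology.
        Returns the final total log-likelihood."""
        for n in self.nodes:
            if n.parent is not None and n.length is None:
                n.length = 0.1
        self.down_pass()
        total = float(self._pattern_logliks() @ self.pattern_counts)
        if not np.isfinite(total):
            raise ValueError(
                "non-finite log-likelihood at initialization; check that the "
                "data match the model alphabet")
        for _ in range(max_rounds):
            self._sweep(xatol, min_len, max_len)
            self.down_pass()
            new_total = float(self._pattern_logliks() @ self.pattern_counts)
            if new_total - total < tol:
                total = max(total, new_total)
                break
            total = new_total
        return total

    def _sweep(self, xatol: float, min_len: float, max_len: float) -> None:
        k = self.gamma.k
        self.U[self.root_i] = np.broadcast_to(
            self.model.frequencies.astype(self.dtype),
            (k, self.n_pat, self.S)).copy()
        self.lsU[self.root_i] = np.zeros((k, self.n_pat))

        def visit(v: Node) -> None:
            vi = self.idx[id(v)]
            for c in v.children:
                ci = self.idx[id(c)]
                E = self.U[vi].copy()
                ls = self.lsU[vi].copy()
                for s in v.children:
                    si = self.idx[id(s)]
                    if si != ci:
                        E = E * self._edge_matrix(si)
                        ls = ls + self.lsD[si]
                m = E.max(axis=2)
                safe = np.where(m > 0, m, 1.0)
                E /= safe[..., None]
                with np.errstate(divide="ignore"):
                    ls += np.where(m > 0, np.log(safe), 0.0)

                current = self._edge_loglik(ci, E, ls, c.length)
                lo = max(min_len, c.length * 0.2)
                hi = min(max_len, c.length * 5.0 + 0.05)
                res = minimize_scalar(
                    lambda t: -self._edge_loglik(ci, E, ls, t),
                    bounds=(lo, hi), method="bounded",
                    options={"xatol": xatol})
                # rerun on the full interval if the local bracket was active
                if ((res.x < lo * 1.05 and lo > min_len)
                        or (res.x > hi * 0.95 and hi < max_len)):
                    res = minimize_scalar(
                        lambda t: -self._edge_loglik(ci, E, ls, t),
                        bounds=(min_len, max_len), method="bounded",
                        options={"xatol": xatol})
                if -res.fun > current:
                    c.length = float(res.x)

                P = self._trans(c.length)
                Uc = E @ P
                mc = Uc.max(axis=2)
                safec = np.where(mc > 0, mc, 1.0)
                Uc /= safec[..., None]
                with np.errstate(divide="ignore"):
                    self.lsU[ci] = ls + np.where(mc > 0, np.log(safec), 0.0)
                self.U[ci] = Uc

                if not c.is_leaf:
                    visit(c)
                    # refresh c's down partial after its subtree moved
                    prod = None
                    lsd = np.zeros((k, self.n_pat))
                    for gc in c.children:
                        gi = self.idx[id(gc)]
                        M = self._edge_matrix(gi)
                        prod = M if prod is None else prod * M
                        lsd += self.lsD[gi]
                    md = prod.max(axis=2)
                    safed = np.where(md > 0, md, 1.0)
                    prod = prod / safed[..., None]
                    with np.errstate(divide="ignore"):
                        lsd += np.where(md > 0, np.log(safed), 0.0)
                    self.D[ci] = prod
                    self.lsD[ci] = lsd

        visit(self.tree.root)

    # ----------------------------------------------------------- posteriors

    def node_posteriors(self, node: Node) -> np.ndarray:
        """Marginal posterior over states at ``node``, per site (expanded
        back from patterns), mixing rate categories by their per-site
        posterior weight."""
        i = self.idx[id(node)]
        if self.U[i] is None:
            raise RuntimeError("up_pass() must run before node_posteriors()")
        A = self.D[i] * self.U[i]                   # (k, n_pat, S)
        ls = self.lsD[i] + self.lsU[i]              # (k, n_pat)
        m = ls.max(axis=0)
        w = np.exp(ls - m[None, :])                 # finite, <= 1
        post = np.einsum("kps,kp->ps", A, w, optimize=True)
        norm = post.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        post = post / norm
        return post[self.pattern_inverse]


# ------------------------------------------------------------------ public


def site_logliks(tree: Tree, aln: Alignment, model: RateModel,
                 gamma: GammaRates, log_floor: float = LOG_FLOOR) -> np.ndarray:
    """Per-site log-likelihoods of the alignment on the given tree."""
    return PruningEngine(tree, aln, model, gamma, log_floor).site_logliks()


def total_loglik(tree: Tree, aln: Alignment, model: RateModel,
                 gamma: GammaRates) -> float:
    return PruningEngine(tree, aln, model, gamma).total_loglik()


def optimize_branch_lengths(tree: Tree, aln: Alignment, model: RateModel,
                            gamma: GammaRates, tol: float = 1e-6,
                            max_rounds: int = 50, xatol: float = 1e-6,
                            dtype=np.float64) -> tuple[Tree, float]:
    """ML branch lengths on a fixed topology (in place on a copy);
    returns (tree, final log-likelihood)."""
    work = tree.copy()
    eng = PruningEngine(work, aln, model, gamma, dtype=dtype)
    ll = eng.optimize_lengths(tol=tol, max_rounds=max_rounds, xatol=xatol)
    return work, ll


ALPHA_BOUNDS = (0.05, 50.0)


def estimate_alpha(tree: Tree, aln: Alignment, model: RateModel, k: int = 4,
                   bounds: tuple[float, float] = ALPHA_BOUNDS,
                   outer_cycles: int = 3, tol: float = 1e-6,
                   xatol: float = 1e-6, dtype=np.float64) -> dict:
    """Estimate the gamma shape by bounded 1-D search in log-alpha,
    alternating with branch-length optimization."""
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError(f"invalid alpha bounds {bounds}")
    work = tree.copy()
    alpha = 1.0 if lo <= 1.0 <= hi else np.sqrt(lo * hi)
    ll = -np.inf
    for _ in range(outer_cycles):
        gamma = discrete_gamma(alpha, k)
        work, ll = optimize_branch_lengths(work, aln, model, gamma,
                                           tol=tol, xatol=xatol, dtype=dtype)

        def nll(log_a: float) -> float:
            g = discrete_gamma(float(np.exp(log_a)), k)
            return -total_loglik(work, aln, model, g)

        res = minimize_scalar(nll, bounds=(np.log(lo), np.log(hi)),
                              method="bounded", options={"xatol": 1e-3})
        alpha, ll = float(np.exp(res.x)), -float(res.fun)
    # effectively homogeneous when the fitted shape is not meaningfully
    # better than the rate-homogeneous limit (LRT-style, ~chi2 1df)
    ll_flat = total_loglik(work, aln, model, discrete_gamma(hi, k))
    at_upper = alpha > hi * 0.95 or ll - ll_flat < 2.0
    return {
        "alpha": alpha,
        "gamma": discrete_gamma(alpha, k),
        "tree": work,
        "loglik": ll,
        "effectively_homogeneous": bool(at_upper),
    }


def site_loglik_matrix(topologies, aln: Alignment, model: RateModel,
                       gamma_policy: str = "shared-estimate", k: int = 4,
                       alpha: float | None = None, tol: float = 1e-6,
                       xatol: float = 1e-6,
                       opt_dtype=np.float32) -> SiteLoglikMatrix:
    """Optimize each topology independently and record per-site logliks.

    ``topologies`` is a sequence of (id, Tree) pairs over one leaf set.
    ``gamma_policy``: "fixed" (requires ``alpha``), "shared-estimate"
    (shape estimated on the first topology, reused), or
    "per-topology-estimate".
    """
    topologies = list(topologies)
    ids = [tid for tid, _ in topologies]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate topology ids")
    if gamma_policy not in ("fixed", "shared-estimate", "per-topology-estimate"):
        raise ValueError(f"unknown gamma policy {gamma_policy!r}")
    if gamma_policy == "fixed" and alpha is None:
        raise ValueError("gamma_policy='fixed' requires alpha")

    shared_gamma = discrete_gamma(alpha, k) if gamma_policy == "fixed" else None
    rows = []
    for tid, topo in topologies:
        if gamma_policy == "per-topology-estimate" or (
                gamma_policy == "shared-estimate" and shared_gamma is None):
            est = estimate_alpha(topo, aln, model, k=k, tol=tol, xatol=xatol,
                                 dtype=opt_dtype)
            gamma, fitted = est["gamma"], est["tree"]
            if gamma_policy == "shared-estimate":
                shared_gamma = gamma
        else:
            gamma = shared_gamma
            fitted, _ = optimize_branch_lengths(topo, aln, model, gamma,
                                                tol=tol, xatol=xatol,
                                                dtype=opt_dtype)
        rows.append(site_logliks(fitted, aln, model, gamma))
    return SiteLoglikMatrix(tuple(ids), np.vstack(rows))
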