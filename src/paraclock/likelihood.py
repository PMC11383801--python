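"""Phylogenetic likelihoods: exact pruning and the quadratic approximation.

The exact route evaluates Felsenstein's pruning algorithm over alignment
site patterns for JC69 (nucleotides), a Poisson amino-acid model (uniform
exchangeabilities and frequencies) or LG (+F), optionally with discrete-
gamma rate variation (4 categories by default, mean-of-category rates).

The approximate route expands the log-likelihood to second order around
the branch-length maximum ``b_hat``::

    logL(b) ~= logL0 + g.(b - b_hat) + 0.5 (b - b_hat)' H (b - b_hat)

with the gradient ``g`` and Hessian ``H`` computed here by analytic
per-branch derivatives and finite differences of the gradient.  This is
the standard device that lets the dating MCMC avoid re-evaluating the full
likelihood at every step.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import BracedTree, Node

__all__ = [
    "SubstitutionModel",
    "Alignment",
    "ApproxLikSpec",
    "exact_log_likelihood",
    "log_likelihood_and_gradient",
    "optimize_branch_lengths",
    "build_approx_spec",
    "approx_log_likelihood",
    "read_alignment",
    "read_in_bv",
    "discrete_gamma_rates",
]

NUC_STATES = "TCAG"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

# LG amino-acid exchangeabilities (lower triangle, column-major over the
# residue order above) and stationary frequencies: standard published
# constants for the LG replacement model.
_LG_Q_TEXT = """
0.425093 0.276818 0.395144 2.489084 0.969894 1.038545 2.066040 0.358858
0.149830 0.395337 0.536518 1.124035 0.253701 1.177651 4.727182 2.139501
0.180717 0.218959 2.547870 0.751878 0.123954 0.534551 2.807908 0.363970
0.390192 2.426601 0.126991 0.301848 6.326067 0.484133 0.052722 0.332533
0.858151 0.578987 0.593607 0.314440 0.170887 5.076149 0.528768 1.695752
0.541712 1.437645 4.509238 0.191503 0.068427 2.145078 0.371004 0.089525
0.161787 4.008358 2.000679 0.045376 0.612025 0.083688 0.062556 0.523386
5.243870 0.844926 0.927114 0.010690 0.015076 0.282959 0.025548 0.017416
0.394456 1.240275 0.425860 0.029890 0.135107 0.037967 0.084808 0.003499
0.569265 0.640543 0.320627 0.594007 0.013266 0.893680 1.105251 0.075382
2.784478 1.143480 0.670128 1.165532 1.959291 4.128591 0.267959 4.813505
0.072854 0.582457 3.234294 1.672569 0.035855 0.624294 1.223828 1.080136
0.236199 0.257336 0.210332 0.348847 0.423881 0.044265 0.069673 1.807177
0.173735 0.018811 0.419409 0.611973 0.604545 0.077852 0.120037 0.245034
0.311484 0.008705 0.044261 0.296636 0.139538 0.089586 0.196961 1.739990
0.129836 0.268491 0.054679 0.076701 0.108882 0.366317 0.697264 0.442472
0.682139 0.508851 0.990012 0.584262 0.597054 5.306834 0.119013 4.145067
0.159069 4.273607 1.112727 0.078281 0.064105 1.033739 0.111660 0.232523
10.649107 0.137500 6.312358 2.592692 0.249060 0.182287 0.302936 0.619632
0.299648 1.702745 0.656604 0.023918 0.390322 0.748683 1.136863 0.049906
0.131932 0.185202 1.798853 0.099849 0.346960 2.020366 0.696175 0.481306
1.898718 0.094464 0.361819 0.165001 2.457121 7.803902 0.654683 1.338132
0.571468 0.095131 0.089613 0.296501 6.472279 0.248862 0.400547 0.098369
0.140825 0.245841 2.188158 3.151815 0.189510 0.249313
"""
_LG_BF_TEXT = """
0.0790659209 0.0559409441 0.0419769580 0.0530519469 0.0129369871
0.0407669592 0.0715859284 0.0573369427 0.0223549776 0.0621569378
0.0990809009 0.0645999354 0.0229509770 0.0423019577 0.0440399560
0.0611969388 0.0532869467 0.0120659879 0.0341549658 0.0691469309
"""


def discrete_gamma_rates(alpha: float, n_cats: int = 4) -> np.ndarray:
    """Mean-of-category discrete-gamma rates (shape = rate = alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    edges = gamma_dist.ppf(np.linspace(0, 1, n_cats + 1), alpha, scale=1.0 / alpha)
    # mean within each quantile bin via the incomplete gamma identity
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    return (upper - lower) * n_cats


class SubstitutionModel:
    """A reversible substitution model with eigendecomposed rate matrix."""

    def __init__(self, name: str, freqs: Optional[np.ndarray] = None):
        name = name.upper()
        if name == "JC69":
            states = NUC_STATES
            n = 4
            S = np.ones((n, n)) - np.eye(n)
            pi = np.full(n, 0.25)
        elif name in ("POISSON", "POISSON-AA"):
            name = "POISSON"
            states = AA_STATES
            n = 20
            S = np.ones((n, n)) - np.eye(n)
            pi = np.full(n, 0.05)
        elif name == "LG":
            states = AA_STATES
            n = 20
            vals = np.array([float(x) for x in _LG_Q_TEXT.split()])
            S = np.zeros((n, n))
            k = 0
            for j in range(n - 1):  # column-major lower triangle
                for i in range(j + 1, n):
                    S[i, j] = S[j, i] = vals[k]
                    k += 1
            pi = np.array([float(x) for x in _LG_BF_TEXT.split()])
        else:
            raise ValueError(f"unknown substitution model {name!r}")
        if freqs is not None:
            pi = np.asarray(freqs, dtype=float)
            if len(pi) != n or abs(pi.sum() - 1.0) > 1e-8 or np.any(pi <= 0):
                raise ValueError("invalid state frequencies")
        self.name = name
        self.states = states
        self.n_states = n
        self.freqs = pi
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize to one expected substitution per unit branch length
        Q /= -np.sum(pi * np.diag(Q))
        self.Q = Q
        # symmetric decomposition for fast transition matrices
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        self._w = w
        self._left = U / sq[None, :].T  # diag(pi^-1/2) U
        self._right = U.T * sq[None, :]  # U' diag(pi^1/2)
        self._index = {s: i for i, s in enumerate(states)}

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * t)) @ self._right
        return np.clip(P, 0.0, None)

    def encode(self, seq: str) -> np.ndarray:
        """Sequence to integer states; unknown characters become -1."""
        idx = self._index
        return np.array([idx.get(ch.upper(), -1) for ch in seq], dtype=np.int64)


@dataclass
class Alignment:
    """A site-pattern-compressed multiple sequence alignment."""

    names: list[str]
    patterns: np.ndarray  # (n_seqs, n_patterns) integer states, -1 = missing
    weights: np.ndarray  # pattern multiplicities
    n_sites: int

    @classmethod
    def from_sequences(
        cls, names: Sequence[str], seqs: Sequence[str], model: SubstitutionModel
    ) -> "Alignment":
        if not names or not seqs or not len(seqs[0]):
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        mat = np.stack([model.encode(s) for s in seqs])
        cols, weights = np.unique(mat, axis=1, return_counts=True)
        return cls(list(names), cols, weights.astype(float), mat.shape[1])

    @property
    def n_seqs(self) -> int:
        return len(self.names)


def read_alignment(
    path: str | Path, fmt: str, model: SubstitutionModel
) -> Alignment:
    """Read a FASTA or sequential PHYLIP alignment via Biopython."""
    from Bio import AlignIO

    bio_fmt = {"fasta": "fasta", "phylip": "phylip-sequential"}.get(fmt)
    if bio_fmt is None:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    aln = AlignIO.read(str(path), bio_fmt)
    return Alignment.from_sequences(
        [rec.id for rec in aln], [str(rec.seq) for rec in aln], model
    )


# ---------------------------------------------------------------------------
# Pruning likelihood and gradient
# ---------------------------------------------------------------------------


def _tip_partials(
    aln: Alignment, tree: BracedTree, model: SubstitutionModel
) -> dict[int, np.ndarray]:
    order = {name: i for i, name in enumerate(aln.names)}
    missing = set(t.name for t in tree.tips()) - set(aln.names)
    if missing:
        raise ValueError(f"alignment lacks sequences for tips: {sorted(missing)}")
    partials = {}
    n = model.n_states
    for tip in tree.tips():
        states = aln.patterns[order[tip.name]]
        P = np.zeros((n, aln.patterns.shape[1]))
        known = states >= 0
        P[states[known], np.nonzero(known)[0]] = 1.0
        P[:, ~known] = 1.0
        partials[tip.index] = P
    return partials


def _edge_order(tree: BracedTree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def _site_likelihoods(
    tree: BracedTree,
    tips: dict[int, np.ndarray],
    model: SubstitutionModel,
    blen: dict[int, float],
    rate: float,
) -> tuple[np.ndarray, dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Post-order pass: per-pattern likelihood plus down partials and the
    per-edge transition matrices (for the gradient pass)."""
    down: dict[int, np.ndarray] = {}
    P_edge: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            down[node.index] = tips[node.index]
            continue
        part = None
        for ch in node.children:
            P = model.transition_matrix(rate * blen[ch.index])
            P_edge[ch.index] = P
            contrib = P @ down[ch.index]
            part = contrib if part is None else part * contrib
        down[node.index] = part
    site_lik = model.freqs @ down[tree.root.index]
    return site_lik, down, P_edge


def exact_log_likelihood(
    alignment: Alignment,
    tree: BracedTree,
    branch_lengths,
    subst_model: SubstitutionModel | str,
    gamma_alpha: Optional[float] = None,
    n_cats: int = 4,
) -> float:
    """Felsenstein pruning log-likelihood.

    ``branch_lengths`` is ordered like the non-root postorder nodes (the
    edge above each node); see :func:`paraclock.priors.edge_nodes`.
    """
    model = (
        SubstitutionModel(subst_model) if isinstance(subst_model, str) else subst_model
    )
    edges = _edge_order(tree)
    b = np.asarray(branch_lengths, dtype=float)
    if len(b) != len(edges):
        raise ValueError(f"expected {len(edges)} branch lengths, got {len(b)}")
    if np.any(b < 0):
        raise ValueError("negative branch length")
    blen = {node.index: b[i] for i, node in enumerate(edges)}
    tips = _tip_partials(alignment, tree, model)
    rates = (
        discrete_gamma_rates(gamma_alpha, n_cats) if gamma_alpha else np.array([1.0])
    )
    site = np.zeros(alignment.patterns.shape[1])
    for r in rates:
        sl, _, _ = _site_likelihoods(tree, tips, model, blen, r)
        site += sl / len(rates)
    if np.any(site <= 0):
        return float("-inf")
    return float(np.sum(alignment.weights * np.log(site)))


def log_likelihood_and_gradient(
    alignment: Alignment,
    tree: BracedTree,
    branch_lengths,
    subst_model: SubstitutionModel | str,
    gamma_alpha: Optional[float] = None,
    n_cats: int = 4,
) -> tuple[float, np.ndarray]:
    """Pruning log-likelihood plus its analytic branch-length gradient.

    Uses outside (pre-order) partials: for an edge above node ``v`` with
    transition matrix P(rb), d site-lik / db = up_v . (rQ P(rb)) down_v.
    """
    model = (
        SubstitutionModel(subst_model) if isinstance(subst_model, str) else subst_model
    )
    edges = _edge_order(tree)
    b = np.asarray(branch_lengths, dtype=float)
    blen = {node.index: b[i] for i, node in enumerate(edges)}
    tips = _tip_partials(alignment, tree, model)
    rates = (
        discrete_gamma_rates(gamma_alpha, n_cats) if gamma_alpha else np.array([1.0])
    )
    n_pat = alignment.patterns.shape[1]
    site = np.zeros(n_pat)
    dsite = np.zeros((len(edges), n_pat))
    pos = {node.index: i for i, node in enumerate(edges)}
    for r in rates:
        sl, down, P_edge = _site_likelihoods(tree, tips, model, blen, r)
        site += sl / len(rates)
        # up[v]: outside partial on the parent side of the edge above v;
        # descending through v requires a push through P(edge above v)
        up: dict[int, np.ndarray] = {tree.root.index: np.tile(model.freqs[:, None], (1, n_pat))}
        for node in tree.preorder():
            if node.is_tip:
                continue
            if node.parent is None:
                base = up[node.index]
            else:
                base = P_edge[node.index].T @ up[node.index]
            contribs = {ch.index: P_edge[ch.index] @ down[ch.index] for ch in node.children}
            for ch in node.children:
                u = base.copy()
                for other in node.children:
                    if other is not ch:
                        u *= contribs[other.index]
                up[ch.index] = u
        for node in edges:
            QP = (r * model.Q) @ P_edge[node.index]
            d = np.einsum("ij,ik,jk->k", QP, up[node.index], down[node.index])
            dsite[pos[node.index]] += d / len(rates)
    w = alignment.weights
    logl = float(np.sum(w * np.log(site)))
    grad = dsite @ (w / site)
    return logl, grad


def _ols_initial_branch_lengths(
    alignment: Alignment, tree: BracedTree, model: SubstitutionModel
) -> np.ndarray:
    """Least-squares branch lengths from pairwise corrected distances.

    A robust starting point for the likelihood optimizer: without it a
    quasi-Newton step can jump onto the saturation plateau, where the
    projected gradient vanishes and the search stalls.
    """
    edges = _edge_order(tree)
    tips = tree.tips()
    row = {name: i for i, name in enumerate(alignment.names)}
    # tip sets below each edge
    below: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[node.index] = {node.name}
        else:
            below[node.index] = set().union(*(below[c.index] for c in node.children))
    n_states = model.n_states
    # saturation-corrected pairwise distances under the equal-rates analogue
    c = (n_states - 1) / n_states
    pairs = []
    dists = []
    pat = alignment.patterns
    w = alignment.weights
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            a = pat[row[tips[i].name]]
            b = pat[row[tips[j].name]]
            ok = (a >= 0) & (b >= 0)
            tot = w[ok].sum()
            if tot == 0:
                continue
            p = float(w[ok][a[ok] != b[ok]].sum() / tot)
            p = min(p, c * 0.98)
            dists.append(-c * math.log(1.0 - p / c))
            pairs.append((tips[i].name, tips[j].name))
    A = np.zeros((len(pairs), len(edges)))
    for k, (na, nb) in enumerate(pairs):
        for e, node in enumerate(edges):
            inside = below[node.index]
            if (na in inside) != (nb in inside):
                A[k, e] = 1.0
    b0, *_ = np.linalg.lstsq(A, np.array(dists), rcond=None)
    return np.clip(b0, 1e-4, None)


def optimize_branch_lengths(
    alignment: Alignment,
    tree: BracedTree,
    subst_model: SubstitutionModel | str,
    gamma_alpha: Optional[float] = None,
    n_cats: int = 4,
    b0: Optional[np.ndarray] = None,
    min_b: float = 1e-6,
    max_b: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood branch lengths by bounded quasi-Newton search."""
    model = (
        SubstitutionModel(subst_model) if isinstance(subst_model, str) else subst_model
    )
    n_edges = len(_edge_order(tree))
    if b0 is None:
        x0 = np.clip(_ols_initial_branch_lengths(alignment, tree, model), min_b, max_b)
    else:
        x0 = np.asarray(b0, dtype=float)

    def negloglik(b):
        ll, g = log_likelihood_and_gradient(
            alignment, tree, b, model, gamma_alpha, n_cats
        )
        return -ll, -g

    res = minimize(
        negloglik,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(min_b, max_b)] * n_edges,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    return res.x, -float(res.fun)


# ---------------------------------------------------------------------------
# Quadratic (gradient + Hessian) approximation
# ---------------------------------------------------------------------------


@dataclass
class ApproxLikSpec:
    """Second-order expansion of one partition's log-likelihood.

    ``edge_names`` records which non-root node each branch-length entry
    belongs to (the edge above that node), in order.
    """

    b_hat: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray
    logL0: float
    edge_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        n = len(self.b_hat)
        if self.gradient.shape != (n,) or self.hessian.shape != (n, n):
            raise ValueError("gradient/Hessian dimensions do not match b_hat")
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-6):
            raise ValueError("Hessian must be symmetric")
        self.hessian = 0.5 * (self.hessian + self.hessian.T)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "b_hat": self.b_hat.tolist(),
            "gradient": self.gradient.tolist(),
            "hessian": self.hessian.tolist(),
            "logL0": self.logL0,
            "edge_names": self.edge_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ApproxLikSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["b_hat"]),
            np.array(d["gradient"]),
            np.array(d["hessian"]),
            float(d["logL0"]),
            list(d.get("edge_names", [])),
        )


def approx_log_likelihood(b, spec: ApproxLikSpec) -> float:
    """Quadratic approximation logL0 + g.d + d'Hd/2 with d = b - b_hat."""
    b = np.asarray(b, dtype=float)
    if b.shape != spec.b_hat.shape:
        raise ValueError(
            f"branch-length vector has shape {b.shape}, spec expects {spec.b_hat.shape}"
        )
    d = b - spec.b_hat
    return float(spec.logL0 + spec.gradient @ d + 0.5 * d @ spec.hessian @ d)


def build_approx_spec(
    alignment: Alignment,
    tree: BracedTree,
    subst_model: SubstitutionModel | str,
    gamma_alpha: Optional[float] = None,
    n_cats: int = 4,
    fd_step: float = 1e-4,
) -> ApproxLikSpec:
    """Optimize branch lengths, then expand the likelihood around the MLE.

    The Hessian comes from central finite differences of the analytic
    gradient (step ``fd_step`` on each coordinate).
    """
    model = (
        SubstitutionModel(subst_model) if isinstance(subst_model, str) else subst_model
    )
    b_hat, logL0 = optimize_branch_lengths(alignment, tree, model, gamma_alpha, n_cats)
    _, g = log_likelihood_and_gradient(alignment, tree, b_hat, model, gamma_alpha, n_cats)
    n = len(b_hat)
    H = np.zeros((n, n))
    for i in range(n):
        step = fd_step * max(1.0, abs(b_hat[i]))
        bp = b_hat.copy()
        bp[i] += step
        bm = b_hat.copy()
        bm[i] = max(bm[i] - step, 1e-9)
        _, gp = log_likelihood_and_gradient(alignment, tree, bp, model, gamma_alpha, n_cats)
        _, gm = log_likelihood_and_gradient(alignment, tree, bm, model, gamma_alpha, n_cats)
        H[:, i] = (gp - gm) / (bp[i] - bm[i])
    H = 0.5 * (H + H.T)
    edge_names = [n_.name for n_ in _edge_order(tree)]
    return ApproxLikSpec(b_hat, g, H, logL0, edge_names)


# ---------------------------------------------------------------------------
# PAML in.BV (rst2) dialect, best effort
# ---------------------------------------------------------------------------


def read_in_bv(path: str | Path) -> list[ApproxLikSpec]:
    """Best-effort reader for PAML's in.BV / rst2 container.

    Each block holds the taxon count, a tree, the branch-length MLE vector,
    the gradient and (after a line containing "Hessian") the row-major
    Hessian.  Several blocks may be concatenated (one per partition).
    Bit-exact agreement with PAML internals is not attempted; the log-
    likelihood at the optimum is not stored in the file and is set to 0.
    """
    text = Path(path).read_text()
    blocks = re.split(r"(?i)hessian", text)
    if len(blocks) < 2:
        raise ValueError("no 'Hessian' marker found; not an in.BV file?")
    specs = []
    pending_head = blocks[0]
    for tail in blocks[1:]:
        # numbers before the marker: ... b-vector, gradient (last 2n floats)
        head_nums = [float(x) for x in re.findall(r"-?\d+\.?\d*(?:[eE][+-]?\d+)?", pending_head)]
        # the Hessian occupies the leading n*n floats of the tail
        tail_nums = [float(x) for x in re.findall(r"-?\d+\.?\d*(?:[eE][+-]?\d+)?", tail)]
        # infer n from the largest square fitting the tail while 2n fits the head
        n = None
        for cand in range(int(math.isqrt(len(tail_nums))), 0, -1):
            if cand * cand <= len(tail_nums) and 2 * cand <= len(head_nums):
                n = cand
                break
        if not n:
            raise ValueError("could not infer branch count from in.BV block")
        H = np.array(tail_nums[: n * n]).reshape(n, n)
        g = np.array(head_nums[-n:])
        b = np.array(head_nums[-2 * n : -n])
        specs.append(ApproxLikSpec(b, g, 0.5 * (H + H.T), 0.0))
        # numbers after the Hessian belong to the next block's header
        pending_head = " ".join(repr(x) for x in tail_nums[n * n :])
    return specs
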