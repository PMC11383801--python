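"""MCMC sampling of node ages under cross-bracing and relaxed clocks.

The sampler is a component-wise Metropolis-Hastings scheme:

* each free node age (drivers of active brace groups, unbraced internal
  nodes, the root) takes a sliding-window proposal reflected into its
  currently feasible interval; mirrored nodes are written simultaneously,
  so driver and mirror ages are bit-identical in every sample;
* node/branch rates, the partition mean rate and sigma2 take log-scale
  multiplier proposals;
* step widths are auto-tuned during burn-in toward 20-40% acceptance.

Cross-bracing strategies: ``"A"`` braces every labelled group, ``"B"``
only groups carrying a fossil calibration, ``"none"`` disables bracing.

Likelihood per partition is either the quadratic approximation around the
branch-length MLE (the fast path; incremental updates against the cached
Hessian residual) or exact pruning (small problems, tests), or absent
(prior-only sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import Alignment, ApproxLikSpec, SubstitutionModel, exact_log_likelihood
from .priors import (
    BDParams,
    ClockParams,
    NEG_INF,
    TimePrior,
    apply_braces,
)
from .trees import BraceMap, BracedTree, assign_driver_mirrors

__all__ = [
    "McmcSettings",
    "Partition",
    "ChainTrace",
    "InfeasibleCalibrationError",
    "run_mcmc",
    "sample_prior",
    "summarize_posterior",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_summary_tree",
    "active_brace_map",
]


class InfeasibleCalibrationError(ValueError):
    """Hard calibration bounds cannot be satisfied jointly."""


@dataclass
class McmcSettings:
    """Chain settings; the defaults match a production run, tests shrink them."""

    n_chains: int = 4
    burn_in: int = 10_000
    n_iter: int = 100_000
    thin: int = 10
    seed: int = 0
    strategy: str = "A"  # A | B | none
    tune: bool = True
    tune_interval: int = 100
    store_rates: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in ("A", "B", "none"):
            raise ValueError(f"unknown cross-bracing strategy {self.strategy!r}")
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("invalid chain settings")


@dataclass
class Partition:
    """One alignment partition: its clock prior and likelihood provider."""

    clock: ClockParams
    approx: Optional[ApproxLikSpec] = None
    alignment: Optional[Alignment] = None
    subst_model: Optional[SubstitutionModel | str] = None
    gamma_alpha: Optional[float] = None
    name: str = ""

    @property
    def has_data(self) -> bool:
        return self.approx is not None or self.alignment is not None


@dataclass
class ChainTrace:
    """Thinned post-burn-in samples of one chain, with provenance."""

    chain_id: int
    seed: int
    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def parameters(self) -> list[str]:
        skip = {"iteration", "lnprior", "lnlike"}
        return [c for c in self.df.columns if c not in skip]


def active_brace_map(tree: BracedTree, strategy: str) -> BraceMap:
    """The brace groups in force under a cross-bracing strategy."""
    bm = assign_driver_mirrors(tree)
    if strategy == "A":
        return bm
    if strategy == "none":
        return BraceMap({})
    groups = {
        label: pair
        for label, pair in bm.items()
        if pair[0].calibration is not None
    }
    return BraceMap(groups)


# ---------------------------------------------------------------------------
# per-partition state
# ---------------------------------------------------------------------------


def _lognorm_term(x: float, mlog: float, v: float) -> float:
    return -math.log(x) - 0.5 * math.log(2.0 * math.pi * v) - (math.log(x) - mlog) ** 2 / (2.0 * v)


class _QuadLik:
    """Quadratic log-likelihood with O(k) incremental branch updates."""

    def __init__(self, spec: ApproxLikSpec, b0: np.ndarray):
        self.spec = spec
        self.b = b0.copy()
        d = self.b - spec.b_hat
        self.resid = spec.hessian @ d
        self.value = float(spec.logL0 + spec.gradient @ d + 0.5 * d @ self.resid)

    def delta(self, J: np.ndarray, nb: np.ndarray) -> float:
        d = nb - self.b[J]
        HJJ = self.spec.hessian[np.ix_(J, J)]
        return float(
            (self.spec.gradient[J] + self.resid[J]) @ d + 0.5 * d @ HJJ @ d
        )

    def commit(self, J: np.ndarray, nb: np.ndarray, dval: float) -> None:
        d = nb - self.b[J]
        self.resid += self.spec.hessian[:, J] @ d
        self.b[J] = nb
        self.value += dval

    def refresh(self) -> None:
        d = self.b - self.spec.b_hat
        self.resid = self.spec.hessian @ d
        self.value = float(
            self.spec.logL0 + self.spec.gradient @ d + 0.5 * d @ self.resid
        )


class _ExactLik:
    """Full pruning recomputation on every proposal (small problems only)."""

    def __init__(self, part: Partition, tree: BracedTree, b0: np.ndarray):
        self.part = part
        self.tree = tree
        self.model = (
            SubstitutionModel(part.subst_model)
            if isinstance(part.subst_model, str)
            else part.subst_model
        )
        self.b = b0.copy()
        self.value = self._eval(self.b)

    def _eval(self, b: np.ndarray) -> float:
        return exact_log_likelihood(
            self.part.alignment, self.tree, np.maximum(b, 0.0), self.model,
            self.part.gamma_alpha,
        )

    def delta(self, J: np.ndarray, nb: np.ndarray) -> float:
        trial = self.b.copy()
        trial[J] = nb
        self._trial_value = self._eval(trial)
        return self._trial_value - self.value

    def commit(self, J: np.ndarray, nb: np.ndarray, dval: float) -> None:
        self.b[J] = nb
        self.value += dval

    def refresh(self) -> None:
        self.value = self._eval(self.b)


class _PartState:
    """Rates, clock hyperparameters and cached prior/likelihood terms."""

    def __init__(self, part: Partition, st: "_Structure", ages: np.ndarray):
        self.part = part
        self.clock = part.clock
        self.model = part.clock.model
        self.st = st
        self.mu = part.clock.mean_rate
        # sigma2 is sampled on the log scale; start strictly positive
        self.s2 = max(part.clock.sigma2, 1e-3) if self.model != "strict" else 0.0
        n_nodes, n_edges = st.n_nodes, st.n_edges
        if self.model == "GBM":
            self.rates = np.full(n_nodes, self.mu)
        elif self.model == "ILN":
            self.rates = np.full(n_edges, self.mu)
        else:
            self.rates = None
        self.lik = None
        if part.approx is not None:
            self.lik = _QuadLik(part.approx, self._branch_lengths(ages))
        elif part.alignment is not None:
            self.lik = _ExactLik(part, st.tree, self._branch_lengths(ages))
        self._recompute_prior(ages)

    # -- branch lengths ------------------------------------------------

    def _edge_rate(self, e: int) -> float:
        st = self.st
        if self.model == "GBM":
            return 0.5 * (self.rates[st.edge_child[e]] + self.rates[st.edge_par[e]])
        if self.model == "ILN":
            return self.rates[e]
        return self.mu

    def _branch_lengths(self, ages: np.ndarray) -> np.ndarray:
        st = self.st
        dt = ages[st.edge_par] - ages[st.edge_child]
        if self.model == "GBM":
            rate = 0.5 * (self.rates[st.edge_child] + self.rates[st.edge_par])
        elif self.model == "ILN":
            rate = self.rates
        else:
            rate = self.mu
        return dt * rate

    # -- rate prior ----------------------------------------------------

    def _edge_term(self, e: int, ages: np.ndarray) -> float:
        st = self.st
        if self.model == "GBM":
            dt = max(ages[st.edge_par[e]] - ages[st.edge_child[e]], 1e-12)
            v = max(self.s2 * dt, 1e-300)
            mlog = math.log(self.rates[st.edge_par[e]]) - v / 2.0
            return _lognorm_term(self.rates[st.edge_child[e]], mlog, v)
        if self.model == "ILN":
            v = max(self.s2, 1e-300)
            return _lognorm_term(self.rates[e], math.log(self.mu) - v / 2.0, v)
        return 0.0

    def _hyper_term(self) -> float:
        a, b = self.clock.rate_prior
        lp = (a - 1.0) * math.log(self.mu) - b * self.mu + a * math.log(b) - math.lgamma(a)
        if self.model != "strict":
            a2, b2 = self.clock.sigma2_prior
            lp += (
                (a2 - 1.0) * math.log(max(self.s2, 1e-300))
                - b2 * self.s2
                + a2 * math.log(b2)
                - math.lgamma(a2)
            )
        return lp

    def _root_term(self) -> float:
        if self.model != "GBM":
            return 0.0
        v = max(self.s2, 1e-300)
        return _lognorm_term(
            self.rates[self.st.root_index], math.log(self.mu) - v / 2.0, v
        )

    def _recompute_prior(self, ages: np.ndarray) -> None:
        self.edge_terms = np.array(
            [self._edge_term(e, ages) for e in range(self.st.n_edges)]
        )
        self.root_term = self._root_term()
        self.hyper_term = self._hyper_term()

    @property
    def log_rate_prior(self) -> float:
        return float(self.edge_terms.sum() + self.root_term + self.hyper_term)

    @property
    def log_lik(self) -> float:
        return self.lik.value if self.lik is not None else 0.0


# ---------------------------------------------------------------------------
# tree structure cache
# ---------------------------------------------------------------------------


class _Structure:
    def __init__(self, tree: BracedTree, brace_map: BraceMap):
        self.tree = tree
        self.brace_map = brace_map
        nodes = tree.postorder()
        self.n_nodes = len(nodes)
        self.root_index = tree.root.index
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for n in nodes:
            if n.parent is not None:
                self.parent[n.index] = n.parent.index
                self.children[n.parent.index].append(n.index)
        edges = [n for n in nodes if n.parent is not None]
        self.n_edges = len(edges)
        self.edge_child = np.array([n.index for n in edges])
        self.edge_par = np.array([n.parent.index for n in edges])
        self.edge_pos = {n.index: i for i, n in enumerate(edges)}
        self.is_tip = np.array([n.is_tip for n in nodes])

        mirrors = {m.index for _, (_, ms) in brace_map.items() for m in ms}
        groups: list[list[int]] = []
        for n in nodes:
            if n.is_tip or n.index in mirrors:
                continue
            members = [n.index]
            if n.brace_label is not None and n.brace_label in brace_map:
                d, ms = brace_map.groups[n.brace_label]
                if d.index == n.index:
                    members += [m.index for m in ms]
            groups.append(members)
        # free age parameters: driver + its mirror aliases
        self.age_groups = groups
        # edges whose duration changes when a group's age moves
        self.group_edges: list[np.ndarray] = []
        for members in groups:
            es = set()
            for i in members:
                if self.parent[i] >= 0:
                    es.add(self.edge_pos[i])
                for c in self.children[i]:
                    es.add(self.edge_pos[c])
            self.group_edges.append(np.array(sorted(es), dtype=int))
        self.node_names = [n.name for n in nodes]


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------


def _initial_ages(tree: BracedTree, brace_map: BraceMap) -> np.ndarray:
    floor = np.zeros(tree.n_nodes)
    for node in tree.postorder():
        f = max((floor[c.index] for c in node.children), default=0.0)
        c = node.calibration
        if c is not None and c.has_min:
            f = max(f, c.t_min)
        floor[node.index] = f

    ages = np.zeros(tree.n_nodes)
    driver_of = {}
    for _, (d, ms) in brace_map.items():
        for m in ms:
            driver_of[m.index] = d.index

    for node in tree.preorder():
        if node.is_tip:
            continue
        i = node.index
        if i in driver_of and ages[driver_of[i]] > 0:
            ages[i] = ages[driver_of[i]]
            continue
        c = node.calibration
        if node.parent is None:
            if c is not None and c.has_min and c.has_max:
                ages[i] = 0.5 * (c.t_min + c.t_max)
            elif c is not None and c.has_max:
                ages[i] = 0.9 * c.t_max
            elif c is not None and c.has_min:
                ages[i] = 1.2 * c.t_min
            else:
                ages[i] = max(1.5 * floor[i], 1.0)
            ages[i] = max(ages[i], 1.05 * floor[i] + 1e-9)
            continue
        hi = ages[node.parent.index]
        lo = floor[i]
        if c is not None and c.has_max:
            hi = min(hi, c.t_max)
        if hi <= lo:
            hi = ages[node.parent.index]
        ages[i] = lo + 0.6 * (hi - lo)

    # repair any residual parent<=child violations (partial bracing)
    for _ in range(50):
        ok = True
        for node in tree.preorder():
            if node.parent is None or node.is_tip:
                continue
            i, p = node.index, node.parent.index
            if ages[i] >= ages[p]:
                ages[i] = 0.95 * ages[p]
                ok = False
        apply_braces(ages, brace_map)
        if ok:
            break
    return ages


class _Chain:
    def __init__(
        self,
        tree: BracedTree,
        partitions: Sequence[Partition],
        settings: McmcSettings,
        bd: Optional[BDParams],
        chain_id: int,
    ):
        self.tree = tree
        self.settings = settings
        self.chain_id = chain_id
        ss = np.random.SeedSequence(entropy=settings.seed, spawn_key=(chain_id,))
        self.seed = int(ss.generate_state(1)[0] % (2**31))
        self.rng = np.random.default_rng(ss)

        self.brace_map = active_brace_map(tree, settings.strategy)
        self.st = _Structure(tree, self.brace_map)
        self.time_prior = TimePrior(tree, bd, self.brace_map)
        self.time_prior.check_feasible()

        self.ages = _initial_ages(tree, self.brace_map)
        self.lp_time = self.time_prior(self.ages)
        if self.lp_time == NEG_INF:
            raise RuntimeError("failed to find a feasible starting age vector")
        self.parts = [_PartState(p, self.st, self.ages) for p in partitions]

        # proposal widths
        root_age = self.ages[self.st.root_index]
        self._w_age = [0.08 * max(root_age, 1e-3) for _ in self.st.age_groups]
        self._w_rate = [0.5 for _ in self.parts]
        self._w_mu = [0.3 for _ in self.parts]
        self._w_s2 = [0.5 for _ in self.parts]
        self._w_scale = 0.1
        self._acc = {}

    # -- bookkeeping ---------------------------------------------------

    def _count(self, key, accepted: bool) -> None:
        a, t = self._acc.get(key, (0, 0))
        self._acc[key] = (a + int(accepted), t + 1)

    def _tune(self) -> None:
        def adjust(widths, key_prefix):
            for k in range(len(widths)):
                a, t = self._acc.get((key_prefix, k), (0, 0))
                if t == 0:
                    continue
                rate = a / t
                if rate > 0.4:
                    widths[k] *= 1.4
                elif rate < 0.2:
                    widths[k] /= 1.4

        adjust(self._w_age, "age")
        adjust(self._w_rate, "rate")
        adjust(self._w_mu, "mu")
        adjust(self._w_s2, "s2")
        a, t = self._acc.get(("scale", 0), (0, 0))
        if t:
            if a / t > 0.4:
                self._w_scale *= 1.4
            elif a / t < 0.2:
                self._w_scale /= 1.4
        self._acc = {}

    # -- updates -------------------------------------------------------

    def _update_age(self, gi: int) -> None:
        st = self.st
        members = st.age_groups[gi]
        t = self.ages[members[0]]
        lo = 0.0
        hi = math.inf
        for i in members:
            for c in st.children[i]:
                lo = max(lo, self.ages[c])
            p = st.parent[i]
            if p >= 0:
                hi = min(hi, self.ages[p])
        w = self._w_age[gi]
        tp = t + self.rng.uniform(-w, w)
        for _ in range(100):
            if tp < lo:
                tp = 2.0 * lo - tp
            elif tp > hi:
                tp = 2.0 * hi - tp
            else:
                break
        if not (lo < tp < hi):
            self._count(("age", gi), False)
            return
        old = self.ages[members].copy()
        self.ages[members] = tp
        new_lp_time = self.time_prior(self.ages)
        if new_lp_time == NEG_INF:
            self.ages[members] = old
            self._count(("age", gi), False)
            return
        log_alpha = new_lp_time - self.lp_time
        J = st.group_edges[gi]
        deltas = []
        for ps in self.parts:
            d_prior = 0.0
            if ps.model == "GBM":
                for e in J:
                    d_prior += ps._edge_term(e, self.ages) - ps.edge_terms[e]
            d_lik = 0.0
            nb = None
            if ps.lik is not None:
                dt = self.ages[st.edge_par[J]] - self.ages[st.edge_child[J]]
                if ps.model == "GBM":
                    rate = 0.5 * (
                        ps.rates[st.edge_child[J]] + ps.rates[st.edge_par[J]]
                    )
                elif ps.model == "ILN":
                    rate = ps.rates[J]
                else:
                    rate = ps.mu
                nb = dt * rate
                d_lik = ps.lik.delta(J, nb)
            deltas.append((d_prior, d_lik, nb))
            log_alpha += d_prior + d_lik
        if math.log(self.rng.uniform()) < log_alpha:
            self.lp_time = new_lp_time
            for ps, (d_prior, d_lik, nb) in zip(self.parts, deltas):
                if ps.model == "GBM":
                    for e in J:
                        ps.edge_terms[e] = ps._edge_term(e, self.ages)
                if ps.lik is not None:
                    ps.lik.commit(J, nb, d_lik)
            self._count(("age", gi), True)
        else:
            self.ages[members] = old
            self._count(("age", gi), False)

    def _update_rate(self, pi: int, which: int) -> None:
        st = self.st
        ps = self.parts[pi]
        w = self._w_rate[pi]
        old = ps.rates[which]
        new = old * math.exp(self.rng.uniform(-w, w))
        log_alpha = math.log(new / old)  # multiplier Hastings term
        if ps.model == "GBM":
            i = which  # node index
            affected = []
            if st.parent[i] >= 0:
                affected.append(st.edge_pos[i])
            affected += [st.edge_pos[c] for c in st.children[i]]
            ps.rates[i] = new
            d_prior = 0.0
            new_terms = {}
            for e in affected:
                nt = ps._edge_term(e, self.ages)
                new_terms[e] = nt
                d_prior += nt - ps.edge_terms[e]
            new_root = ps.root_term
            if i == st.root_index:
                new_root = ps._root_term()
                d_prior += new_root - ps.root_term
            J = np.array(affected, dtype=int)
            d_lik = 0.0
            nb = None
            if ps.lik is not None and len(J):
                dt = self.ages[st.edge_par[J]] - self.ages[st.edge_child[J]]
                rate = 0.5 * (ps.rates[st.edge_child[J]] + ps.rates[st.edge_par[J]])
                nb = dt * rate
                d_lik = ps.lik.delta(J, nb)
            if math.log(self.rng.uniform()) < log_alpha + d_prior + d_lik:
                for e, nt in new_terms.items():
                    ps.edge_terms[e] = nt
                ps.root_term = new_root
                if ps.lik is not None and len(J):
                    ps.lik.commit(J, nb, d_lik)
                self._count(("rate", pi), True)
            else:
                ps.rates[i] = old
                self._count(("rate", pi), False)
        else:  # ILN: which = edge position
            e = which
            ps.rates[e] = new
            nt = ps._edge_term(e, self.ages)
            d_prior = nt - ps.edge_terms[e]
            J = np.array([e], dtype=int)
            d_lik = 0.0
            nb = None
            if ps.lik is not None:
                dt = self.ages[st.edge_par[e]] - self.ages[st.edge_child[e]]
                nb = np.array([dt * new])
                d_lik = ps.lik.delta(J, nb)
            if math.log(self.rng.uniform()) < log_alpha + d_prior + d_lik:
                ps.edge_terms[e] = nt
                if ps.lik is not None:
                    ps.lik.commit(J, nb, d_lik)
                self._count(("rate", pi), True)
            else:
                ps.rates[e] = old
                self._count(("rate", pi), False)

    def _update_scalar(self, pi: int, which: str) -> None:
        ps = self.parts[pi]
        st = self.st
        w = self._w_mu[pi] if which == "mu" else self._w_s2[pi]
        old = ps.mu if which == "mu" else ps.s2
        new = old * math.exp(self.rng.uniform(-w, w))
        log_alpha = math.log(new / old)
        old_terms = ps.edge_terms
        old_root, old_hyper = ps.root_term, ps.hyper_term
        if which == "mu":
            ps.mu = new
        else:
            ps.s2 = new
        d_lik = 0.0
        nb = None
        J = None
        if which == "mu" and ps.model == "strict" and ps.lik is not None:
            J = np.arange(st.n_edges)
            dt = self.ages[st.edge_par] - self.ages[st.edge_child]
            nb = dt * new
            d_lik = ps.lik.delta(J, nb)
        ps._recompute_prior(self.ages)
        d_prior = (
            ps.edge_terms.sum() + ps.root_term + ps.hyper_term
            - old_terms.sum() - old_root - old_hyper
        )
        if math.log(self.rng.uniform()) < log_alpha + d_prior + d_lik:
            if nb is not None:
                ps.lik.commit(J, nb, d_lik)
            self._count((which, pi), True)
        else:
            if which == "mu":
                ps.mu = old
            else:
                ps.s2 = old
            ps.edge_terms = old_terms
            ps.root_term, ps.hyper_term = old_root, old_hyper
            self._count((which, pi), False)

    def _update_scale(self) -> None:
        """Rate-time scaling move: ages *= c, rates and mean rates /= c.

        Branch lengths (duration x rate) are invariant, so the likelihood
        does not change; only the time and rate priors and the Jacobian
        c^(n_ages - n_rates) enter the acceptance ratio.  This move mixes
        the slow joint drift of all ages against all rates.
        """
        u = self.rng.uniform(-self._w_scale, self._w_scale)
        c = math.exp(u)
        old_ages = self.ages.copy()
        new_ages = self.ages * c
        try:
            new_lp_time = self.time_prior(new_ages)
        except ValueError:
            new_lp_time = NEG_INF
        if new_lp_time == NEG_INF:
            self._count(("scale", 0), False)
            return
        n_up = len(self.st.age_groups)
        n_down = 0
        log_alpha = new_lp_time - self.lp_time
        saved = []
        self.ages = new_ages
        for ps in self.parts:
            old = (
                None if ps.rates is None else ps.rates.copy(),
                ps.mu,
                ps.edge_terms.copy(),
                ps.root_term,
                ps.hyper_term,
            )
            saved.append(old)
            if ps.rates is not None:
                ps.rates = ps.rates / c
                n_down += len(ps.rates)
            ps.mu /= c
            n_down += 1
            old_prior = old[2].sum() + old[3] + old[4]
            ps._recompute_prior(self.ages)
            log_alpha += ps.edge_terms.sum() + ps.root_term + ps.hyper_term - old_prior
        log_alpha += (n_up - n_down) * u
        if math.log(self.rng.uniform()) < log_alpha:
            self.lp_time = new_lp_time
            for ps in self.parts:
                if ps.lik is not None:
                    # durations x rates are analytically invariant; refresh
                    # to kill floating-point drift
                    ps.lik.b = ps._branch_lengths(self.ages)
                    ps.lik.refresh()
            self._count(("scale", 0), True)
        else:
            self.ages = old_ages
            for ps, old in zip(self.parts, saved):
                if old[0] is not None:
                    ps.rates = old[0]
                ps.mu = old[1]
                ps.edge_terms, ps.root_term, ps.hyper_term = old[2], old[3], old[4]
            self._count(("scale", 0), False)

    def sweep(self) -> None:
        for gi in range(len(self.st.age_groups)):
            self._update_age(gi)
        self._update_scale()
        for pi, ps in enumerate(self.parts):
            if ps.model == "GBM":
                for i in range(self.st.n_nodes):
                    self._update_rate(pi, i)
            elif ps.model == "ILN":
                for e in range(self.st.n_edges):
                    self._update_rate(pi, e)
            self._update_scalar(pi, "mu")
            if ps.model != "strict":
                self._update_scalar(pi, "s2")

    # -- main loop -----------------------------------------------------

    def run(self) -> ChainTrace:
        s = self.settings
        rows = []
        internal = [
            n for n in self.tree.postorder() if not n.is_tip
        ]
        for it in range(s.burn_in):
            self.sweep()
            if s.tune and (it + 1) % s.tune_interval == 0:
                self._tune()
        # refresh caches after burn-in to kill numerical drift
        for ps in self.parts:
            if ps.lik is not None:
                ps.lik.refresh()
            ps._recompute_prior(self.ages)
        self.lp_time = self.time_prior(self.ages)
        for it in range(s.n_iter):
            self.sweep()
            if (it + 1) % s.thin == 0:
                row = {"iteration": it + 1}
                for n in internal:
                    row[f"t_{n.name}"] = self.ages[n.index]
                for pi, ps in enumerate(self.parts):
                    tag = ps.part.name or f"p{pi}"
                    row[f"mu_{tag}"] = ps.mu
                    if ps.model != "strict":
                        row[f"sigma2_{tag}"] = ps.s2
                    if s.store_rates and ps.rates is not None:
                        for k, r in enumerate(ps.rates):
                            row[f"r_{tag}_{k}"] = r
                row["lnprior"] = self.lp_time + sum(
                    ps.log_rate_prior for ps in self.parts
                )
                row["lnlike"] = sum(ps.log_lik for ps in self.parts)
                rows.append(row)
        df = pd.DataFrame(rows)
        return ChainTrace(self.chain_id, self.seed, df)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def run_mcmc(
    partitions: Sequence[Partition] | Partition,
    tree: BracedTree,
    settings: Optional[McmcSettings] = None,
    bd: Optional[BDParams] = None,
) -> list[ChainTrace]:
    """Sample node ages (and clock parameters) for one or more partitions.

    Every sampled age vector satisfies parent > child; mirrored nodes are
    exactly equal within each sample.  Raises
    :class:`InfeasibleCalibrationError` before sampling if hard bounds
    conflict.
    """
    if isinstance(partitions, Partition):
        partitions = [partitions]
    settings = settings or McmcSettings()
    traces = []
    for chain_id in range(settings.n_chains):
        chain = _Chain(tree, partitions, settings, bd, chain_id)
        traces.append(chain.run())
    return traces


def sample_prior(
    tree: BracedTree,
    settings: Optional[McmcSettings] = None,
    clock: Optional[ClockParams] = None,
    bd: Optional[BDParams] = None,
) -> list[ChainTrace]:
    """Sample from the joint prior (no sequence data).

    Used to inspect marginal (effective) priors against the user-specified
    calibration densities.
    """
    parts = [Partition(clock)] if clock is not None else []
    return run_mcmc(parts, tree, settings, bd)


def summarize_posterior(
    traces: Sequence[ChainTrace], level: float = 0.95
) -> pd.DataFrame:
    """Pooled per-parameter mean, equal-tail CI and HPD interval."""
    from .diagnostics import hpd_interval

    if not traces or all(len(t) == 0 for t in traces):
        raise ValueError("no retained samples to summarize")
    pooled = pd.concat([t.df for t in traces], ignore_index=True)
    alpha = (1.0 - level) / 2.0
    out = {}
    for col in traces[0].parameters():
        x = pooled[col].to_numpy()
        lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
        if len(x) >= 20 and np.ptp(x) > 0:
            h_lo, h_hi = hpd_interval(x, level)
        else:
            h_lo, h_hi = float(x.min()), float(x.max())
        out[col] = {
            "mean": float(x.mean()),
            f"{100 * alpha:g}%q": float(lo),
            f"{100 * (1 - alpha):g}%q": float(hi),
            "hpd_low": h_lo,
            "hpd_high": h_hi,
            "n": len(x),
        }
    return pd.DataFrame(out).T


def write_trace_tsv(trace: ChainTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chain={trace.chain_id} seed={trace.seed}\n")
        trace.df.to_csv(fh, sep="\t", index=False)


def read_trace_tsv(path: str | Path) -> ChainTrace:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    return ChainTrace(int(meta["chain"]), int(meta["seed"]), df)


def write_summary_tree(
    tree: BracedTree, summary: pd.DataFrame, path: Optional[str | Path] = None
) -> str:
    """Newick with mean node ages as heights and CI annotations."""

    def mean_age(node) -> float:
        if node.is_tip:
            return 0.0
        return float(summary.loc[f"t_{node.name}", "mean"])

    def render(node) -> str:
        if node.is_tip:
            s = node.name
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            key = f"t_{node.name}"
            lo = summary.loc[key].iloc[1]
            hi = summary.loc[key].iloc[2]
            s += f"[&age_mean={mean_age(node):.6g},age_95%={{{lo:.6g},{hi:.6g}}}]"
        if node.parent is not None:
            s += f":{mean_age(node.parent) - mean_age(node):.6g}"
        return s

    text = render(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
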