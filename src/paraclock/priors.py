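"""Prior densities for node ages and evolutionary rates.

Ages are in Ga (1 time unit = 10**9 years); rates in substitutions/site/Ga.

Calibration densities
---------------------
A two-sided calibration (min, max) is a uniform core holding
``1 - left_tail - right_tail`` of the mass, with exponential tails beyond
each *soft* bound calibrated to hold exactly ``tail_prob`` mass each while
keeping the density continuous at the bound.  A *hard* bound admits zero
mass beyond it.  One-sided minima use an exponential body above the bound
(decay length half the bound age); one-sided maxima use a uniform body on
(0, max).  Every density integrates to 1.

Time prior
----------
Calibrated driver nodes contribute their calibration log-density.
Uncalibrated free node ages are uniform between the age of the nearest
calibrated (or root) ancestor and the largest minimum-age constraint among
their calibrated descendants, conditional on the parent-older-than-child
ordering; any ordering violation has zero density.  When cross-bracing is
active the birth-death parameters are ignored (the uniform kernel is the
lambda = mu special case).

Rate priors
-----------
GBM: log rates evolve along the tree by Brownian motion with variance
``sigma2`` per Ga and drift ``-sigma2*dt/2`` so the child rate is
mean-preserving; the root rate is lognormal about the partition mean rate.
ILN: branch rates are i.i.d. lognormal with expectation ``mean_rate`` and
log-variance ``sigma2``.  Both add the gamma hyperpriors on ``mean_rate``
(shape 2, rate 2.5; mean 0.8) and ``sigma2`` (shape 1, rate 10; mean 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .trees import BraceMap, BracedTree, Calibration, Node, assign_driver_mirrors

__all__ = [
    "BDParams",
    "ClockParams",
    "AgeVector",
    "CalibrationDensity",
    "log_calibration_density",
    "TimePrior",
    "log_time_prior",
    "gbm_log_rate_prior",
    "iln_log_rate_prior",
    "expected_branch_lengths",
    "apply_braces",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class BDParams:
    """Birth-death-sampling parameters; ignored whenever bracing is active.

    The defaults (lambda = mu = 1, rho = 0.1) select the uniform kernel
    for uncalibrated node ages.
    """

    lam: float = 1.0
    mu: float = 1.0
    rho: float = 0.1

    def __post_init__(self) -> None:
        if min(self.lam, self.mu, self.rho) < 0:
            raise ValueError("birth-death parameters must be >= 0")


@dataclass
class ClockParams:
    """Per-partition relaxed-clock parameters and their hyperpriors."""

    model: str = "GBM"  # GBM | ILN | strict
    mean_rate: float = 0.8  # substitutions/site/Ga
    sigma2: float = 0.1  # log-rate variance (per Ga for GBM)
    rate_prior: tuple[float, float] = (2.0, 2.5)  # gamma shape, rate
    sigma2_prior: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        if self.model not in ("GBM", "ILN", "strict"):
            raise ValueError(f"unknown clock model {self.model!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be > 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")

    def log_hyperprior(self) -> float:
        a, b = self.rate_prior
        lp = gamma_dist.logpdf(self.mean_rate, a, scale=1.0 / b)
        if self.model != "strict":
            a2, b2 = self.sigma2_prior
            lp += gamma_dist.logpdf(self.sigma2, a2, scale=1.0 / b2)
        return float(lp)


class AgeVector:
    """Node ages in Ga, indexed by the tree's postorder node index.

    Tips have age 0.  Mirrored nodes alias their driver's age; use
    :func:`apply_braces` after writing a driver age to keep mirrors in sync.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)

    @classmethod
    def from_dict(cls, tree: BracedTree, ages: dict[str, float]) -> "AgeVector":
        v = np.zeros(tree.n_nodes)
        for node in tree.internal_nodes():
            v[node.index] = ages[node.name]
        return cls(v)

    def __getitem__(self, idx: int) -> float:
        return float(self.values[idx])

    def age_of(self, tree: BracedTree, name: str) -> float:
        return float(self.values[tree.node_by_name(name).index])

    def check_order(self, tree: BracedTree) -> bool:
        """True iff age(parent) > age(child) on every edge."""
        for node in tree.postorder():
            if node.parent is not None:
                if not self.values[node.parent.index] > self.values[node.index]:
                    return False
        return True


def apply_braces(values: np.ndarray, brace_map: BraceMap) -> np.ndarray:
    """Copy each driver age onto its mirrors (in place); returns the array."""
    for _, (driver, mirrors) in brace_map.items():
        for m in mirrors:
            values[m.index] = values[driver.index]
    return values


# ---------------------------------------------------------------------------
# Calibration densities
# ---------------------------------------------------------------------------


class CalibrationDensity:
    """Normalized density for one calibration; precomputes tail parameters."""

    def __init__(self, c: Calibration, min_decay_frac: float = 0.5):
        self.calibration = c
        eps = c.tail_prob
        self.eps_left = eps if (c.has_min and c.left_soft) else 0.0
        self.eps_right = eps if (c.has_max and c.right_soft) else 0.0
        if c.has_min and c.has_max:
            core_mass = 1.0 - self.eps_left - self.eps_right
            self.h = core_mass / (c.t_max - c.t_min)
            self.scale_right = None
        elif c.has_max:  # pure maximum: uniform body on (0, t_max)
            core_mass = 1.0 - self.eps_right
            self.h = core_mass / c.t_max
            self.scale_right = None
        else:  # pure minimum: exponential body above t_min
            body_mass = 1.0 - self.eps_left
            self.scale_right = min_decay_frac * c.t_min if c.t_min > 0 else 1.0
            self.h = body_mass / self.scale_right
        # right tail beyond a soft maximum: rate h/eps gives mass eps exactly
        self.lam_right = self.h / self.eps_right if self.eps_right > 0 else None
        # left tail on (0, t_min): solve for the rate that fits mass eps
        self.lam_left = None
        self._left_uniform_height = None
        if self.eps_left > 0:
            tmin, h, eps_l = c.t_min, self.h, self.eps_left
            if h * tmin > eps_l:
                # continuous exponential rise toward the bound
                f = lambda lam: h * (1.0 - math.exp(-lam * tmin)) / lam - eps_l
                lo, hi = 1e-12, 1.0
                while f(hi) > 0:
                    hi *= 4.0
                self.lam_left = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
            else:
                # bound too close to 0 for a continuous tail of that mass:
                # fall back to a flat left tail holding exactly eps
                self._left_uniform_height = eps_l / tmin

    def logpdf(self, t: float) -> float:
        if t <= 0:
            raise ValueError(f"age must be > 0, got {t}")
        c = self.calibration
        if c.has_min and t < c.t_min:
            if self.eps_left == 0.0:
                return NEG_INF
            if self.lam_left is not None:
                return math.log(self.h) + self.lam_left * (t - c.t_min)
            return math.log(self._left_uniform_height)
        if c.has_max and t > c.t_max:
            if self.eps_right == 0.0:
                return NEG_INF
            return math.log(self.h) - self.lam_right * (t - c.t_max)
        if not c.has_min:  # body of a pure maximum
            return math.log(self.h)
        if not c.has_max:  # exponential body of a pure minimum
            return math.log(self.h) - (t - c.t_min) / self.scale_right
        return math.log(self.h)

    def pdf(self, t):
        tv = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.array([math.exp(self.logpdf(x)) if x > 0 else 0.0 for x in tv])
        return out if np.ndim(t) else float(out[0])

    def support_hint(self) -> tuple[float, float]:
        """A generous interval containing essentially all the mass."""
        c = self.calibration
        hi = c.t_max if c.has_max else c.t_min + 60.0 * self.scale_right
        if self.eps_right and self.lam_right:
            hi += 60.0 / self.lam_right
        return (0.0, hi)

    def quad_breakpoints(self) -> list[float]:
        """Segment boundaries for accurate piecewise quadrature: the bounds
        themselves plus points bracketing any narrow exponential tail."""
        c = self.calibration
        lo, hi = 1e-12, self.support_hint()[1]
        pts = {lo, hi}
        if c.has_min:
            pts.add(c.t_min)
            if self.lam_left:
                pts.add(max(lo, c.t_min - 40.0 / self.lam_left))
        if c.has_max:
            pts.add(c.t_max)
            if self.lam_right:
                pts.add(min(hi, c.t_max + 40.0 / self.lam_right))
        return sorted(pts)


@lru_cache(maxsize=256)
def _density_for(c: Calibration) -> CalibrationDensity:
    return CalibrationDensity(c)


def log_calibration_density(t: float, c: Calibration) -> float:
    """Log density of one calibrated node age; -inf beyond a hard bound."""
    return _density_for(c).logpdf(t)


# ---------------------------------------------------------------------------
# Time prior
# ---------------------------------------------------------------------------


class TimePrior:
    """Joint prior over node ages for a braced tree.

    Precomputes, per uncalibrated free node, the nearest calibrated-or-root
    ancestor (whose current age caps the uniform envelope) and the largest
    minimum-age constraint among calibrated descendants (its floor).
    """

    def __init__(
        self,
        tree: BracedTree,
        bd: Optional[BDParams] = None,
        brace_map: Optional[BraceMap] = None,
    ):
        self.tree = tree
        self.bd = bd or BDParams()
        self.brace_map = brace_map if brace_map is not None else assign_driver_mirrors(tree)
        # bracing active => birth-death parameters ignored (uniform kernel
        # is also what the defaults lambda = mu select)
        self.bracing_active = len(self.brace_map) > 0

        mirrors = {
            m.index for _, (_, ms) in self.brace_map.items() for m in ms
        }
        self.calibrated: list[tuple[int, CalibrationDensity]] = []
        self.uncalibrated: list[tuple[int, int, float]] = []  # (node, anc, floor)

        floor = {}
        for node in tree.postorder():
            f = 0.0
            for ch in node.children:
                f = max(f, floor[ch.index])
            c = node.calibration
            if c is not None and c.has_min:
                f = max(f, c.t_min)
            floor[node.index] = f

        for node in tree.internal_nodes():
            if node.index in mirrors:
                continue  # aliases its driver
            if node.calibration is not None:
                self.calibrated.append((node.index, _density_for(node.calibration)))
            elif node.parent is None:
                # uncalibrated root: improper-flat guard; give it a vague
                # envelope above its descendants' floor
                self.uncalibrated.append((node.index, -1, max(floor[node.index], 0.0)))
            else:
                anc = node.parent
                while anc.parent is not None and anc.calibration is None:
                    anc = anc.parent
                child_floor = max(floor[ch.index] for ch in node.children)
                self.uncalibrated.append((node.index, anc.index, child_floor))

        par = np.full(tree.n_nodes, -1, dtype=int)
        for node in tree.postorder():
            if node.parent is not None:
                par[node.index] = node.parent.index
        self._parent = par
        self._is_tip = np.array([n.is_tip for n in tree.postorder()])

    def __call__(self, node_ages: np.ndarray) -> float:
        ages = np.asarray(node_ages, dtype=float)
        for _, (driver, mirrors) in self.brace_map.items():
            for m in mirrors:
                if ages[m.index] != ages[driver.index]:
                    raise ValueError(
                        f"age of mirrored node {m.name!r} differs from its "
                        f"driver {driver.name!r}; mirrors are not free parameters"
                    )
        internal = (self._parent >= 0) & ~self._is_tip
        if np.any(ages[self._parent[internal]] <= ages[internal]):
            return NEG_INF
        # tips at age 0 must be younger than their parents
        if np.any(ages[self._parent[self._is_tip]] <= 0):
            return NEG_INF
        lp = 0.0
        for idx, dens in self.calibrated:
            t = ages[idx]
            if t <= 0:
                return NEG_INF
            v = dens.logpdf(t)
            if v == NEG_INF:
                return NEG_INF
            lp += v
        for idx, anc, floor in self.uncalibrated:
            if anc < 0:
                # uncalibrated root: improper-flat above its floor
                if ages[idx] <= floor:
                    return NEG_INF
                continue
            # flat within the envelope; ordering is enforced globally above,
            # so an age may sit in a neighbour's soft tail without vetoing
            width = ages[anc] - floor
            if width <= 0:
                return NEG_INF
            lp -= math.log(width)
        return lp

    def check_feasible(self) -> None:
        """Raise if hard calibration bounds are jointly unsatisfiable."""
        from .mcmc import InfeasibleCalibrationError  # local to avoid cycle

        hard_max = {}
        for node in self.tree.postorder():
            c = node.calibration
            if c is not None and c.has_max and not c.right_soft:
                hard_max[node.index] = c.t_max
        for node in self.tree.postorder():
            c = node.calibration
            if c is None or not c.has_min or c.left_soft:
                continue
            anc = node.parent
            while anc is not None:
                if anc.index in hard_max and hard_max[anc.index] <= c.t_min:
                    raise InfeasibleCalibrationError(
                        f"hard minimum {c.t_min} Ga on node {node.name!r} is not "
                        f"below the hard maximum {hard_max[anc.index]} Ga on its "
                        f"ancestor {anc.name!r}"
                    )
                anc = anc.parent


def log_time_prior(
    ages,
    tree: BracedTree,
    bd: Optional[BDParams] = None,
    brace_map: Optional[BraceMap] = None,
) -> float:
    """Convenience wrapper; for repeated evaluation build a TimePrior once."""
    values = ages.values if isinstance(ages, AgeVector) else np.asarray(ages, float)
    return TimePrior(tree, bd, brace_map)(values)


# ---------------------------------------------------------------------------
# Rate priors
# ---------------------------------------------------------------------------


def _lognorm_logpdf(x: np.ndarray, mean_log: np.ndarray, var_log) -> np.ndarray:
    return (
        -np.log(x)
        - 0.5 * np.log(2.0 * np.pi * var_log)
        - (np.log(x) - mean_log) ** 2 / (2.0 * var_log)
    )


def gbm_log_rate_prior(
    node_rates,
    ages,
    p: ClockParams,
    tree: BracedTree,
    include_hyperprior: bool = True,
) -> float:
    """Autocorrelated (geometric Brownian motion) log prior on node rates.

    ``node_rates`` holds one rate per node (postorder index).  The child
    log rate is Normal(log r_parent - sigma2*dt/2, sigma2*dt); the root
    rate is lognormal about ``p.mean_rate`` with one unit of variance
    sigma2, so the strict-clock limit sigma2 -> 0 pins every rate to the
    mean rate.
    """
    if p.sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    r = np.asarray(node_rates, dtype=float)
    t = ages.values if isinstance(ages, AgeVector) else np.asarray(ages, float)
    if np.any(r <= 0):
        return NEG_INF
    lp = p.log_hyperprior() if include_hyperprior else 0.0
    root = tree.root
    if p.sigma2 == 0.0:
        ok = np.isclose(r, r[root.index]).all() and math.isclose(
            r[root.index], p.mean_rate
        )
        return lp if ok else NEG_INF
    lp += float(
        _lognorm_logpdf(
            r[root.index], math.log(p.mean_rate) - p.sigma2 / 2.0, p.sigma2
        )
    )
    child_idx = []
    parent_idx = []
    for node in tree.postorder():
        if node.parent is not None:
            child_idx.append(node.index)
            parent_idx.append(node.parent.index)
    ci = np.array(child_idx)
    pi = np.array(parent_idx)
    dt = t[pi] - t[ci]
    if np.any(dt < 0):
        return NEG_INF
    dt = np.maximum(dt, 1e-12)
    var = p.sigma2 * dt
    mean_log = np.log(r[pi]) - var / 2.0
    lp += float(np.sum(_lognorm_logpdf(r[ci], mean_log, var)))
    return lp


def iln_log_rate_prior(
    branch_rates, p: ClockParams, include_hyperprior: bool = True
) -> float:
    """Independent lognormal prior on branch rates (expectation mean_rate)."""
    r = np.asarray(branch_rates, dtype=float)
    if np.any(r <= 0):
        return NEG_INF
    lp = p.log_hyperprior() if include_hyperprior else 0.0
    if p.sigma2 == 0.0:
        return lp if np.allclose(r, p.mean_rate) else NEG_INF
    mean_log = math.log(p.mean_rate) - p.sigma2 / 2.0
    lp += float(np.sum(_lognorm_logpdf(r, mean_log, p.sigma2)))
    return lp


# ---------------------------------------------------------------------------
# Linking times and rates to branch lengths
# ---------------------------------------------------------------------------


def expected_branch_lengths(
    ages,
    rates,
    model: str,
    tree: BracedTree,
    mean_rate: Optional[float] = None,
) -> np.ndarray:
    """Branch lengths (substitutions/site) implied by ages and rates.

    Returns one entry per non-root node (the edge above it), ordered by
    node postorder index skipping the root.  GBM uses the arithmetic mean
    of the endpoint node rates; ILN uses the branch's own rate; strict uses
    ``mean_rate`` everywhere.
    """
    t = ages.values if isinstance(ages, AgeVector) else np.asarray(ages, float)
    out = []
    r = None if rates is None else np.asarray(rates, dtype=float)
    for node in tree.postorder():
        if node.parent is None:
            continue
        dur = t[node.parent.index] - t[node.index]
        if dur < 0:
            raise ValueError(
                f"negative duration on edge above {node.name!r}: {dur}"
            )
        if model == "GBM":
            rate = 0.5 * (r[node.index] + r[node.parent.index])
        elif model == "ILN":
            rate = r[node.index]
        elif model == "strict":
            rate = mean_rate if mean_rate is not None else float(r)
        else:
            raise ValueError(f"unknown clock model {model!r}")
        out.append(dur * rate)
    return np.array(out)


def edge_nodes(tree: BracedTree) -> list[Node]:
    """Non-root nodes in the order used by expected_branch_lengths."""
    return [n for n in tree.postorder() if n.parent is not None]
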