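"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of the real inputs: gene trees rooted
at a pre-LUCA duplication whose two (or more) paralogue subtrees repeat the
same species divergences at identical true ages; branch rates under strict,
autocorrelated (GBM) or independent-lognormal (ILN) clocks; alignments
evolved under a stationary reversible substitution model; truth-containing
soft calibration windows; and genome statistics linking KO-family counts to
proteome and genome size, plus a presence-probability vector whose implied
expected family count matches a chosen true genome.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import Alignment, SubstitutionModel
from .trees import BracedTree, Calibration, Node
from .priors import edge_nodes

__all__ = [
    "SyntheticTruth",
    "simulate_braced_timetree",
    "simulate_rates_and_alignment",
    "make_calibrations",
    "simulate_content_tables",
]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators (ages in Ga)."""

    seed: int
    node_ages: dict[str, float] = field(default_factory=dict)
    luca_nodes: list[str] = field(default_factory=list)  # mirrored species roots
    luca_age: Optional[float] = None
    clock_model: Optional[str] = None
    mean_rate: Optional[float] = None
    sigma2: Optional[float] = None
    subst_model: Optional[str] = None
    branch_lengths: Optional[np.ndarray] = None
    edge_rates: Optional[np.ndarray] = None
    # gene-content truth
    true_size_mb: Optional[float] = None
    true_protein_count: Optional[int] = None
    true_ko_count: Optional[int] = None
    true_presence: Optional[np.ndarray] = None


def simulate_braced_timetree(
    n_species: int,
    n_paralogues: int = 2,
    root_age: float = 4.5,
    seed: int = 0,
    species_root_frac: float = 0.8,
) -> tuple[BracedTree, SyntheticTruth]:
    """A duplication-rooted tree whose paralogue subtrees mirror one
    species history.

    The species tree topology comes from uniformly random joins (the Yule
    labelled-history distribution); its internal ages are uniform order
    statistics below the species root, which sits at
    ``species_root_frac * root_age``.  Each of the ``n_paralogues`` copies
    carries tips ``S{i}_P{j}`` and brace label ``#k`` on the k-th join, so
    mirrored divergences share one age by construction.
    """
    if n_species < 3:
        raise ValueError("need n_species >= 3")
    if n_paralogues < 2:
        raise ValueError("need n_paralogues >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    rng = np.random.default_rng(seed)
    sp_root_age = species_root_frac * root_age
    inner = np.sort(rng.uniform(0.05, 0.95, size=n_species - 2)) * sp_root_age
    join_ages = np.append(inner, sp_root_age)

    # join plan shared by all paralogue copies: (lineage slots merged per join)
    slots: list[int] = list(range(n_species))
    plan: list[tuple[int, int]] = []
    for _ in range(n_species - 1):
        i, j = sorted(rng.choice(len(slots), size=2, replace=False))
        plan.append((slots[i], slots[j]))
        slots[j:j + 1] = []
        slots[i] = n_species + len(plan) - 1  # new lineage id

    truth = SyntheticTruth(seed=seed)
    root = Node()
    for p in range(1, n_paralogues + 1):
        nodes: dict[int, Node] = {
            i: Node(name=f"S{i + 1}_P{p}") for i in range(n_species)
        }
        for k, (a, b) in enumerate(plan, start=1):
            join = Node(name=f"x{k}_P{p}", brace_label=k)
            join.add_child(nodes.pop(a))
            join.add_child(nodes.pop(b))
            nodes[n_species + k - 1] = join
            truth.node_ages[join.name] = float(join_ages[k - 1])
        (subtree_root,) = nodes.values()
        root.add_child(subtree_root)
    root.name = "dup_root"
    truth.node_ages["dup_root"] = float(root_age)
    truth.luca_nodes = [f"x{n_species - 1}_P{p}" for p in range(1, n_paralogues + 1)]
    truth.luca_age = float(sp_root_age)

    paralogue_of = {
        f"S{i + 1}_P{p}": f"S{i + 1}"
        for i in range(n_species)
        for p in range(1, n_paralogues + 1)
    }
    return BracedTree(root, paralogue_of), truth


def _truth_age_vector(tree: BracedTree, truth: SyntheticTruth) -> np.ndarray:
    ages = np.zeros(tree.n_nodes)
    for node in tree.internal_nodes():
        ages[node.index] = truth.node_ages[node.name]
    return ages


def simulate_rates_and_alignment(
    tree: BracedTree,
    truth: SyntheticTruth,
    model: str = "GBM",
    mean_rate: float = 0.8,
    sigma2: float = 0.1,
    subst_model: str = "JC69",
    n_sites: int = 500,
    seed: int = 0,
    gamma_alpha: Optional[float] = None,
) -> tuple[Alignment, np.ndarray]:
    """Draw branch rates under the named clock, then evolve sequences.

    Returns the alignment and the true branch lengths (rate x duration per
    edge, non-root postorder order); both are also recorded in ``truth``.
    GBM uses the arithmetic-mean endpoint rate per edge and the
    mean-preserving drift, with the root rate pinned at ``mean_rate``.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    if model not in ("GBM", "ILN", "strict"):
        raise ValueError(f"unknown clock model {model!r}")
    rng = np.random.default_rng(seed)
    ages = _truth_age_vector(tree, truth)
    edges = edge_nodes(tree)
    dt = np.array([ages[n.parent.index] - ages[n.index] for n in edges])
    if model == "strict" or sigma2 == 0.0:
        edge_rates = np.full(len(edges), mean_rate)
    elif model == "GBM":
        node_rates = np.empty(tree.n_nodes)
        node_rates[tree.root.index] = mean_rate
        for node in tree.preorder():
            if node.parent is None:
                continue
            d = ages[node.parent.index] - ages[node.index]
            v = sigma2 * max(d, 1e-12)
            node_rates[node.index] = node_rates[node.parent.index] * np.exp(
                rng.normal(-v / 2.0, np.sqrt(v))
            )
        edge_rates = np.array(
            [0.5 * (node_rates[n.index] + node_rates[n.parent.index]) for n in edges]
        )
    else:  # ILN
        edge_rates = mean_rate * np.exp(
            rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(edges))
        )
    blen = dt * edge_rates

    sm = SubstitutionModel(subst_model)
    if gamma_alpha:
        site_rates = rng.gamma(gamma_alpha, 1.0 / gamma_alpha, size=n_sites)
    else:
        site_rates = np.ones(n_sites)
    seqs: dict[int, np.ndarray] = {}
    root_states = rng.choice(sm.n_states, size=n_sites, p=sm.freqs)
    seqs[tree.root.index] = root_states
    epos = {n.index: i for i, n in enumerate(edges)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        b = blen[epos[node.index]]
        parent_states = seqs[node.parent.index]
        child = np.empty(n_sites, dtype=np.int64)
        u = rng.random(n_sites)
        if gamma_alpha:
            for s in range(n_sites):
                P = sm.transition_matrix(b * site_rates[s])
                child[s] = np.searchsorted(np.cumsum(P[parent_states[s]]), u[s])
        else:
            P = sm.transition_matrix(b)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            for st in range(sm.n_states):
                mask = parent_states == st
                child[mask] = np.searchsorted(cum[st], u[mask])
        seqs[node.index] = child
    names = [t.name for t in tree.tips()]
    strings = [
        "".join(sm.states[s] for s in seqs[t.index]) for t in tree.tips()
    ]
    aln = Alignment.from_sequences(names, strings, sm)
    truth.clock_model = model
    truth.mean_rate = mean_rate
    truth.sigma2 = sigma2
    truth.subst_model = subst_model
    truth.branch_lengths = blen
    truth.edge_rates = edge_rates
    return aln, blen


def make_calibrations(
    tree: BracedTree,
    truth: SyntheticTruth,
    relative_width: float = 0.2,
    which_nodes: Optional[Sequence[str]] = None,
    seed: int = 0,
    tail_prob: float = 0.025,
) -> BracedTree:
    """Attach truth-containing soft uniform calibration windows.

    Windows span ``true_age * (1 -/+ relative_width * u)`` with u drawn in
    (0.5, 1), so the true age always lies inside.  The root is always
    calibrated; further nodes come from ``which_nodes`` (names) or default
    to the mirrored species-root (LUCA-analogue) drivers.  Returns a
    calibrated copy of the tree.
    """
    if relative_width <= 0:
        raise ValueError("relative_width must be > 0")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    targets = list(which_nodes) if which_nodes is not None else list(truth.luca_nodes[:1])
    names = set(targets) | {out.root.name}
    for name in sorted(names):
        t = truth.node_ages[name]
        lo = t * (1.0 - relative_width * rng.uniform(0.5, 1.0))
        hi = t * (1.0 + relative_width * rng.uniform(0.5, 1.0))
        node = out.node_by_name(name)
        node.calibration = Calibration(
            t_min=max(lo, 1e-6), t_max=hi, tail_prob=tail_prob
        )
    return out


def simulate_content_tables(
    n_genomes: int = 100,
    n_families: int = 7467,
    size_range_mb: tuple[float, float] = (1.0, 8.0),
    seed: int = 0,
    protein_density: float = 900.0,  # protein-coding genes per Mb
    detection_p: float = 0.35,  # chance a protein maps to a counted KO family
    noise: float = 0.05,  # lognormal spread of proteins around density*size
    pp_noise: float = 0.15,  # 0 = presence probabilities exactly 0/1
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Genome-statistics training table plus an ancestral PP vector.

    Genome sizes are uniform over ``size_range_mb``; protein counts scale
    with size (lognormal noise); KO-family counts are binomial detections
    from the protein count (deterministic expectations when ``noise`` is
    0).  The "ancestral" genome sits mid-range; its presence-probability
    vector is beta-noised around the true presence indicators and rescaled
    so the implied expected family count equals the true KO count, which
    is what calibrated reconciliation probabilities should satisfy.
    """
    if n_genomes < 30:
        raise ValueError("need n_genomes >= 30")
    lo, hi = size_range_mb
    if not 0 < lo < hi:
        raise ValueError("degenerate size range")
    rng = np.random.default_rng(seed)
    sizes = rng.uniform(lo, hi, size=n_genomes)
    if noise > 0:
        proteins = np.round(
            protein_density * sizes * np.exp(rng.normal(0.0, noise, n_genomes))
        ).astype(int)
        kos = rng.binomial(proteins, detection_p)
    else:
        proteins = np.round(protein_density * sizes).astype(int)
        kos = np.round(proteins * detection_p).astype(int)
    training = pd.DataFrame(
        {
            "ko_count": kos,
            "protein_count": proteins,
            "genome_size_mb": sizes,
        }
    )

    true_size = 0.5 * (lo + hi)
    true_proteins = int(round(protein_density * true_size))
    true_ko = int(round(true_proteins * detection_p))
    true_ko = min(true_ko, n_families)
    presence = np.zeros(n_families, dtype=bool)
    presence[rng.choice(n_families, size=true_ko, replace=False)] = True
    if pp_noise > 0:
        conc = 1.0 / pp_noise
        pps = np.where(
            presence,
            rng.beta(0.8 * conc, 0.2 * conc, n_families),
            rng.beta(0.1 * conc, 0.9 * conc, n_families),
        )
        # rescale so the expected family count equals the true KO count
        for _ in range(8):
            s = pps.sum()
            if abs(s - true_ko) < 1e-9:
                break
            pps = np.clip(pps * (true_ko / s), 0.0, 1.0)
    else:
        pps = presence.astype(float)
    table = pd.DataFrame(
        {
            "family": [f"K{i:05d}" for i in range(n_families)],
            "pp": pps,
            "arc_prop": np.where(presence, rng.uniform(0.02, 0.5, n_families),
                                 rng.uniform(0.0, 0.05, n_families)),
            "bac_prop": np.where(presence, rng.uniform(0.02, 0.5, n_families),
                                 rng.uniform(0.0, 0.05, n_families)),
        }
    )
    truth = SyntheticTruth(
        seed=seed,
        true_size_mb=true_size,
        true_protein_count=true_proteins,
        true_ko_count=true_ko,
        true_presence=presence,
    )
    return training, table, truth
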