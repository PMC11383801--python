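"""Reproducible validation experiments for the dating and content pipelines.

Each function runs a self-contained study on synthetic data — mirror
equality under cross-bracing, marginal-prior recovery of calibration
quantiles, calibration-density normalization, pruning-vs-enumeration
agreement, the quadratic-likelihood contract, simulation-based coverage of
posterior intervals, diagnostics against analytic oracles, and end-to-end
genome-size recovery — and returns plain numbers.  They power both the
acceptance script and the heavier end of the test suite.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad

from .content import fit_size_model, predict_size, sample_genomes
from .diagnostics import ess_bulk, hpd_interval, split_rhat
from .likelihood import (
    Alignment,
    SubstitutionModel,
    approx_log_likelihood,
    build_approx_spec,
    exact_log_likelihood,
)
from .mcmc import McmcSettings, Partition, run_mcmc, sample_prior, summarize_posterior
from .priors import CalibrationDensity, ClockParams, edge_nodes
from .simulate import (
    SyntheticTruth,
    make_calibrations,
    simulate_braced_timetree,
    simulate_content_tables,
    simulate_rates_and_alignment,
)
from .trees import Calibration, parse_braced_newick

WORKED_EXAMPLE = (
    "(((A1, A2) #1, A3) #2, ((B1, B2) [#1 B{0.2, 0.4}], B3) #2) 'B(0.9,1.1)';"
)


def _mirror_pairs(tree):
    pairs = []
    for label, nodes in tree.brace_labels().items():
        base = nodes[0]
        pairs.extend((base.name, m.name) for m in nodes[1:])
    return pairs


def mirror_equality(seed: int = 0) -> dict:
    """Max |driver - mirror| age over prior and posterior samples on the
    six-tip worked-example tree (0 when bracing is exact)."""
    tree = parse_braced_newick(WORKED_EXAMPLE)
    pairs = _mirror_pairs(tree)

    prior_traces = sample_prior(
        tree, McmcSettings(n_chains=2, burn_in=300, n_iter=3000, thin=3, seed=seed)
    )
    # posterior: simulate data on the same topology at the stated truth
    truth = SyntheticTruth(seed=seed)
    a = tree.mrca(["A1", "A2"]).name
    b = tree.mrca(["B1", "B2"]).name
    u = tree.mrca(["A1", "A3"]).name
    v = tree.mrca(["B1", "B3"]).name
    truth.node_ages = {a: 0.3, b: 0.3, u: 0.6, v: 0.6, tree.root.name: 1.0}
    aln, _ = simulate_rates_and_alignment(
        tree, truth, "GBM", 0.8, 0.05, "JC69", 500, seed=seed
    )
    spec = build_approx_spec(aln, tree, "JC69")
    post_traces = run_mcmc(
        Partition(ClockParams("GBM", 0.8, 0.05), approx=spec),
        tree,
        McmcSettings(n_chains=2, burn_in=300, n_iter=3000, thin=3, seed=seed + 1),
    )
    worst = 0.0
    n = 0
    for traces in (prior_traces, post_traces):
        for t in traces:
            n += len(t)
            for da, mb in pairs:
                worst = max(
                    worst, float(np.abs(t.df[f"t_{da}"] - t.df[f"t_{mb}"]).max())
                )
    return {"max_mirror_age_diff": worst, "n_samples": n}


def prior_recovery(seed: int = 0, n_samples: int = 100_000) -> dict:
    """Marginal-prior quantiles of an isolated soft-calibrated node versus
    its calibration bounds (0.2, 0.4)."""
    tree = parse_braced_newick("((A,B) B{0.2,0.4}, C) 'B(0.9,1.1)';")
    per_chain = n_samples // 2
    traces = sample_prior(
        tree,
        McmcSettings(
            n_chains=2, burn_in=2000, n_iter=per_chain, thin=1, seed=seed,
            strategy="none",
        ),
    )
    col = f"t_{tree.mrca(['A', 'B']).name}"
    x = np.concatenate([t.df[col].to_numpy() for t in traces])
    lo, hi = np.quantile(x, [0.025, 0.975])
    return {
        "q025": float(lo),
        "q975": float(hi),
        "q025_error": float(abs(lo - 0.2)),
        "q975_error": float(abs(hi - 0.4)),
        "n_samples": len(x),
    }


def calibration_normalization() -> dict:
    """Quadrature check that calibration densities integrate to one and
    soft tails hold their stated mass (includes the root-maximum and
    oxygenic-photosynthesis-minimum style bounds)."""
    cals = [
        Calibration(0.2, 0.4),
        Calibration(0.9, 1.1),
        Calibration(4.50, 4.52),
        Calibration(2.945, 2.963, left_soft=False),
        Calibration(t_min=2.954),
        Calibration(t_max=4.51),
        Calibration(0.5, 3.5, tail_prob=0.05),
    ]
    worst_norm = 0.0
    worst_tail = 0.0
    for c in cals:
        dens = CalibrationDensity(c)
        _, hi = dens.support_hint()
        # piecewise so bound steps and narrow tails do not defeat quadrature
        cuts = dens.quad_breakpoints()
        total = sum(
            quad(dens.pdf, a, b, limit=400)[0] for a, b in zip(cuts, cuts[1:])
        )
        worst_norm = max(worst_norm, abs(total - 1.0))
        if c.has_min and c.left_soft:
            left, _ = quad(dens.pdf, 1e-12, c.t_min, limit=200)
            worst_tail = max(worst_tail, abs(left - c.tail_prob))
        if c.has_max and c.right_soft:
            right, _ = quad(dens.pdf, c.t_max, hi, limit=400)
            worst_tail = max(worst_tail, abs(right - c.tail_prob))
    return {
        "max_normalization_error": float(worst_norm),
        "max_tail_mass_error": float(worst_tail),
        "n_calibrations": len(cals),
    }


def _enumeration_loglik(aln, tree, blen, model) -> float:
    edges = edge_nodes(tree)
    b = {n.index: blen[i] for i, n in enumerate(edges)}
    P = {i: model.transition_matrix(b[i]) for i in b}
    internals = [n for n in tree.postorder() if not n.is_tip]
    tips = {name: i for i, name in enumerate(aln.names)}
    total = 0.0
    for pat in range(aln.patterns.shape[1]):
        lik = 0.0
        for assign in itertools.product(range(model.n_states), repeat=len(internals)):
            states = {n.index: s for n, s in zip(internals, assign)}
            for t in tree.tips():
                states[t.index] = aln.patterns[tips[t.name], pat]
            term = model.freqs[states[tree.root.index]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                term *= P[node.index][states[node.parent.index], states[node.index]]
            lik += term
        total += aln.weights[pat] * math.log(lik)
    return total


def likelihood_oracle(seed: int = 0) -> dict:
    """Pruning vs exhaustive ancestral-state enumeration on all small
    (3-5 tip) test topologies."""
    topologies = ["((A,B),C);", "((A,B),(C,D));", "(((A,B),C),(D,E));"]
    model = SubstitutionModel("JC69")
    rng = np.random.default_rng(seed)
    worst = 0.0
    for text in topologies:
        tree = parse_braced_newick(text)
        names = [t.name for t in tree.tips()]
        seqs = [
            "".join(model.states[s] for s in rng.integers(0, 4, 10))
            for _ in names
        ]
        aln = Alignment.from_sequences(names, seqs, model)
        blen = rng.uniform(0.05, 0.9, size=len(edge_nodes(tree)))
        got = exact_log_likelihood(aln, tree, blen, model)
        want = _enumeration_loglik(aln, tree, blen, model)
        worst = max(worst, abs(got - want))
    return {"max_abs_loglik_error": float(worst), "n_trees": len(topologies)}


def quadratic_contract(seed: int = 0) -> dict:
    """The quadratic expansion equals the exact log-likelihood at the
    branch-length MLE and its error scales as the third power nearby."""
    tree, truth = simulate_braced_timetree(4, 2, root_age=1.0, seed=seed)
    aln, _ = simulate_rates_and_alignment(
        tree, truth, "GBM", 0.8, 0.05, "JC69", 300, seed=seed
    )
    spec = build_approx_spec(aln, tree, "JC69")
    err_at_bhat = abs(approx_log_likelihood(spec.b_hat, spec) - spec.logL0)
    rng = np.random.default_rng(seed + 1)
    ratios = []
    for _ in range(5):
        d = rng.normal(0.0, 0.004, size=len(spec.b_hat))
        d[spec.b_hat < 0.02] = np.abs(d[spec.b_hat < 0.02])
        e1 = abs(
            approx_log_likelihood(spec.b_hat + d, spec)
            - exact_log_likelihood(aln, tree, spec.b_hat + d, "JC69")
        )
        e2 = abs(
            approx_log_likelihood(spec.b_hat + 2 * d, spec)
            - exact_log_likelihood(aln, tree, spec.b_hat + 2 * d, "JC69")
        )
        if e1 > 1e-9:
            ratios.append(e2 / e1)
    return {
        "error_at_bhat": float(err_at_bhat),
        "taylor_ratio_min": float(min(ratios)),
        "taylor_ratio_max": float(max(ratios)),
    }


def coverage_experiment(
    seed: int = 0,
    n_replicates: int = 40,
    models: tuple[str, ...] = ("GBM", "ILN"),
    n_species: int = 10,
    n_sites: int = 500,
) -> dict:
    """Simulation-based coverage: does the 95% CI of the braced
    LUCA-analogue node (the mirrored species root below the duplication
    root) contain the true age?"""
    out = {}
    for model in models:
        hits = 0
        for rep in range(n_replicates):
            rseed = seed * 10_000 + rep
            tree, truth = simulate_braced_timetree(
                n_species, 2, root_age=1.0, seed=rseed
            )
            aln, _ = simulate_rates_and_alignment(
                tree, truth, model, 0.8, 0.05, "JC69", n_sites, seed=rseed
            )
            cal = make_calibrations(tree, truth, 0.25, seed=rseed)
            spec = build_approx_spec(aln, tree, "JC69")
            traces = run_mcmc(
                Partition(ClockParams(model, 0.8, 0.05), approx=spec),
                cal,
                McmcSettings(
                    n_chains=1, burn_in=400, n_iter=1600, thin=4, seed=rseed
                ),
            )
            s = summarize_posterior(traces)
            row = s.loc[f"t_{truth.luca_nodes[0]}"]
            if row["2.5%q"] <= truth.luca_age <= row["97.5%q"]:
                hits += 1
        out[f"coverage_{model.lower()}"] = hits / n_replicates
    out["n_replicates"] = n_replicates
    return out


def diagnostics_oracles(seed: int = 0) -> dict:
    """ESS of an AR(1) chain vs the analytic value, R-hat on a shifted
    chain, and HPD vs exhaustive window search."""
    rng = np.random.default_rng(seed)
    phi, n = 0.5, 30_000
    x = np.zeros((1, n))
    e = rng.normal(size=(1, n))
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + e[:, t]
    expected = n * (1 - phi) / (1 + phi)
    ess = ess_bulk(x)

    chains = rng.normal(size=(2, 2000))
    chains[1] += 3.0
    rhat = split_rhat(chains)

    samples = rng.gamma(2.0, 1.0, size=397)
    lo, hi = hpd_interval(samples, 0.95)
    xs = np.sort(samples)
    k = int(math.ceil(0.95 * len(xs)))
    widths = xs[k - 1 :] - xs[: len(xs) - k + 1]
    i = int(np.argmin(widths))
    oracle = (float(xs[i]), float(xs[i + k - 1]))
    return {
        "ar1_ess": float(ess),
        "ar1_ess_expected": float(expected),
        "ar1_ess_rel_error": float(abs(ess - expected) / expected),
        "rhat_shifted_chain": float(rhat),
        "hpd_oracle_max_diff": float(max(abs(lo - oracle[0]), abs(hi - oracle[1]))),
    }


def content_recovery(seed: int = 0, n_seeds: int = 50) -> dict:
    """End-to-end genome-size recovery: fraction of synthetic worlds whose
    true size falls inside the predicted 95% interval."""
    hits = 0
    for k in range(n_seeds):
        s = seed * 1000 + k
        training, table, truth = simulate_content_tables(
            n_genomes=80, n_families=2000, seed=s
        )
        _, summary = sample_genomes(table["pp"].to_numpy(), n=100, seed=s)
        model = fit_size_model(training, "size")
        pred = predict_size(model, summary["counts"])
        if pred["low"] <= truth.true_size_mb <= pred["high"]:
            hits += 1
    return {"coverage": hits / n_seeds, "n_seeds": n_seeds}


def bernoulli_check(seed: int = 0) -> dict:
    """Mean sampled-genome family count vs the analytic Bernoulli sum."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=5000)
    n = 100
    _, summary = sample_genomes(p, n=n, seed=seed + 1)
    se = math.sqrt(float(np.sum(p * (1 - p))) / n)
    z = abs(summary["mean_count"] - float(p.sum())) / se
    return {
        "mean_count": summary["mean_count"],
        "expected_count": float(p.sum()),
        "z_score": float(z),
        "hpd": [summary["hpd_low"], summary["hpd_high"]],
    }
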