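"""Pruning likelihood against exhaustive enumeration; quadratic expansion."""

import itertools
import math

import numpy as np
import pytest

from paraclock.likelihood import (
    Alignment,
    ApproxLikSpec,
    SubstitutionModel,
    approx_log_likelihood,
    build_approx_spec,
    discrete_gamma_rates,
    exact_log_likelihood,
    log_likelihood_and_gradient,
    optimize_branch_lengths,
    read_in_bv,
)
from paraclock.priors import edge_nodes
from paraclock.simulate import simulate_braced_timetree, simulate_rates_and_alignment
from paraclock.trees import parse_braced_newick


def brute_force_loglik(aln, tree, blen, model, gamma_alpha=None, n_cats=4):
    """Independent oracle: sum over all internal-state assignments per site."""
    edges = edge_nodes(tree)
    b = {n.index: blen[i] for i, n in enumerate(edges)}
    internals = [n for n in tree.postorder() if not n.is_tip]
    tips = {name: i for i, name in enumerate(aln.names)}
    tip_nodes = tree.tips()
    rates = discrete_gamma_rates(gamma_alpha, n_cats) if gamma_alpha else [1.0]
    total = 0.0
    for pat in range(aln.patterns.shape[1]):
        site_lik = 0.0
        for r in rates:
            P = {i: model.transition_matrix(r * b[i]) for i in b}
            lik = 0.0
            for assign in itertools.product(range(model.n_states), repeat=len(internals)):
                states = {n.index: s for n, s in zip(internals, assign)}
                for t in tip_nodes:
                    states[t.index] = aln.patterns[tips[t.name], pat]
                term = model.freqs[states[tree.root.index]]
                for node in tree.postorder():
                    if node.parent is None:
                        continue
                    s = states[node.index]
                    if s < 0:  # missing data: sum over states = row sum = 1
                        continue
                    term *= P[node.index][states[node.parent.index], s]
                lik += term
            site_lik += lik / len(rates)
        total += aln.weights[pat] * math.log(site_lik)
    return total


TOPOLOGIES = {
    3: "((A,B),C);",
    4: "((A,B),(C,D));",
    5: "(((A,B),C),(D,E));",
}


class TestPruningOracle:
    @pytest.mark.parametrize("n_tips", [3, 4, 5])
    @pytest.mark.parametrize("model_name,alpha", [
        ("JC69", None), ("JC69", 0.5), ("POISSON", None),
    ])
    def test_matches_enumeration(self, n_tips, model_name, alpha):
        model = SubstitutionModel(model_name)
        tree = parse_braced_newick(TOPOLOGIES[n_tips])
        rng = np.random.default_rng(n_tips)
        n_sites = 8
        names = [t.name for t in tree.tips()]
        seqs = [
            "".join(model.states[s] for s in rng.integers(0, model.n_states, n_sites))
            for _ in names
        ]
        aln = Alignment.from_sequences(names, seqs, model)
        blen = rng.uniform(0.05, 0.8, size=len(edge_nodes(tree)))
        got = exact_log_likelihood(aln, tree, blen, model, alpha)
        want = brute_force_loglik(aln, tree, blen, model, alpha)
        assert got == pytest.approx(want, abs=1e-10)

    def test_missing_data_treated_as_sum_over_states(self):
        model = SubstitutionModel("JC69")
        tree = parse_braced_newick(TOPOLOGIES[4])
        aln = Alignment.from_sequences(
            ["A", "B", "C", "D"], ["ACGT", "AC-T", "ANGT", "ACGA"], model
        )
        blen = np.full(6, 0.2)
        got = exact_log_likelihood(aln, tree, blen, model)
        want = brute_force_loglik(aln, tree, blen, model)
        assert got == pytest.approx(want, abs=1e-10)

    def test_identical_single_site_zero_branches(self):
        model = SubstitutionModel("JC69")
        tree = parse_braced_newick("((A,B),C);")
        aln = Alignment.from_sequences(["A", "B", "C"], ["A", "A", "A"], model)
        ll = exact_log_likelihood(aln, tree, np.zeros(4), model)
        assert ll == pytest.approx(math.log(0.25), abs=1e-12)

    def test_two_tip_mle_matches_jc_distance(self):
        # observed difference fraction p -> d_hat = -(3/4) ln(1 - 4p/3)
        model = SubstitutionModel("JC69")
        tree = parse_braced_newick("(A, B);")
        n, diff = 100, 10
        seq_a = "A" * n
        seq_b = "C" * diff + "A" * (n - diff)
        aln = Alignment.from_sequences(["A", "B"], [seq_a, seq_b], model)
        b_hat, _ = optimize_branch_lengths(aln, tree, model)
        p = diff / n
        d_expected = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
        assert b_hat.sum() == pytest.approx(d_expected, rel=1e-3)

    def test_tip_mismatch_and_empty_alignment_errors(self):
        model = SubstitutionModel("JC69")
        tree = parse_braced_newick("((A,B),C);")
        aln = Alignment.from_sequences(["A", "B", "X"], ["AC", "AC", "AC"], model)
        with pytest.raises(ValueError, match="tips"):
            exact_log_likelihood(aln, tree, np.full(4, 0.1), model)
        with pytest.raises(ValueError, match="empty"):
            Alignment.from_sequences([], [], model)

    def test_analytic_gradient_matches_finite_differences(self):
        tree, truth = simulate_braced_timetree(4, 2, root_age=1.0, seed=2)
        aln, _ = simulate_rates_and_alignment(
            tree, truth, "strict", 0.8, 0.0, "JC69", 100, seed=2
        )
        b = np.full(len(edge_nodes(tree)), 0.15)
        _, g = log_likelihood_and_gradient(aln, tree, b, "JC69")
        for i in range(len(b)):
            bp, bm = b.copy(), b.copy()
            bp[i] += 1e-6
            bm[i] -= 1e-6
            fd = (
                exact_log_likelihood(aln, tree, bp, "JC69")
                - exact_log_likelihood(aln, tree, bm, "JC69")
            ) / 2e-6
            assert g[i] == pytest.approx(fd, abs=1e-4)


@pytest.fixture(scope="module")
def eight_tip_spec():
    tree, truth = simulate_braced_timetree(4, 2, root_age=1.0, seed=8)
    aln, _ = simulate_rates_and_alignment(
        tree, truth, "GBM", 0.8, 0.05, "JC69", 300, seed=8
    )
    spec = build_approx_spec(aln, tree, "JC69")
    return tree, aln, spec


class TestQuadraticApproximation:
    def test_exact_at_expansion_point(self, eight_tip_spec):
        _, _, spec = eight_tip_spec
        assert approx_log_likelihood(spec.b_hat, spec) == pytest.approx(
            spec.logL0, abs=1e-12
        )

    def test_close_to_exact_near_optimum(self, eight_tip_spec):
        tree, aln, spec = eight_tip_spec
        rng = np.random.default_rng(0)
        for _ in range(5):
            delta = rng.uniform(-0.01, 0.01, size=len(spec.b_hat))
            b = np.maximum(spec.b_hat + delta, 1e-8)
            err = abs(
                approx_log_likelihood(b, spec)
                - exact_log_likelihood(aln, tree, b, "JC69")
            )
            assert err < 0.1

    def test_third_order_error_scaling(self, eight_tip_spec):
        tree, aln, spec = eight_tip_spec
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(5):
            delta = rng.normal(0.0, 0.004, size=len(spec.b_hat))
            # keep 2*delta inside the positive orthant for short branches
            delta[spec.b_hat < 0.02] = np.abs(delta[spec.b_hat < 0.02])
            e1 = abs(
                approx_log_likelihood(spec.b_hat + delta, spec)
                - exact_log_likelihood(aln, tree, spec.b_hat + delta, "JC69")
            )
            e2 = abs(
                approx_log_likelihood(spec.b_hat + 2 * delta, spec)
                - exact_log_likelihood(aln, tree, spec.b_hat + 2 * delta, "JC69")
            )
            if e1 > 1e-9:
                ratios.append(e2 / e1)
        assert ratios and all(4.0 <= r <= 16.0 for r in ratios)

    def test_dimension_mismatch_rejected(self, eight_tip_spec):
        _, _, spec = eight_tip_spec
        with pytest.raises(ValueError):
            approx_log_likelihood(spec.b_hat[:-1], spec)

    def test_spec_validates_shapes_and_symmetry(self):
        with pytest.raises(ValueError):
            ApproxLikSpec(np.ones(3), np.ones(2), np.eye(3), 0.0)
        H = np.eye(3)
        H[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError):
            ApproxLikSpec(np.ones(3), np.ones(3), H, 0.0)

    def test_json_round_trip(self, eight_tip_spec, tmp_path):
        _, _, spec = eight_tip_spec
        path = tmp_path / "spec.json"
        spec.to_json(path)
        again = ApproxLikSpec.from_json(path)
        np.testing.assert_allclose(again.b_hat, spec.b_hat)
        np.testing.assert_allclose(again.hessian, spec.hessian)
        assert again.logL0 == spec.logL0
        assert again.edge_names == spec.edge_names


class TestInBvReader:
    def test_reads_synthetic_rst2_block(self, tmp_path):
        # synthetic stand-in for a PAML rst2 / in.BV block
        n = 4
        rng = np.random.default_rng(3)
        b = rng.uniform(0.01, 0.5, n)
        g = rng.normal(0, 1e-3, n)
        A = rng.normal(size=(n, n))
        H = -(A @ A.T)
        lines = [" 4", "", "((A: 0.1, B: 0.2): 0.05, C: 0.3);", ""]
        lines.append(" ".join(f"{x:.6f}" for x in b))
        lines.append("")
        lines.append(" ".join(f"{x:.6f}" for x in g))
        lines.append("")
        lines.append("Hessian")
        lines.append("")
        for row in H:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        path = tmp_path / "in.BV"
        path.write_text("\n".join(lines) + "\n")
        (spec,) = read_in_bv(path)
        np.testing.assert_allclose(spec.b_hat, np.round(b, 6))
        np.testing.assert_allclose(spec.gradient, np.round(g, 6))
        np.testing.assert_allclose(spec.hessian, np.round(H, 6), atol=1e-6)

    def test_rejects_non_bv_text(self, tmp_path):
        path = tmp_path / "x.txt"
        path.write_text("1 2 3\n")
        with pytest.raises(ValueError):
            read_in_bv(path)
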