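"""Sampler behaviour: mirror aliasing, prior recovery, determinism, summaries."""

import numpy as np
import pandas as pd
import pytest

from paraclock.mcmc import (
    ChainTrace,
    InfeasibleCalibrationError,
    McmcSettings,
    Partition,
    read_trace_tsv,
    run_mcmc,
    sample_prior,
    summarize_posterior,
    write_summary_tree,
    write_trace_tsv,
)
from paraclock.priors import ClockParams
from paraclock.trees import parse_braced_newick


def _mirror_columns(tree):
    a = tree.mrca(["A1", "A2"]).name
    b = tree.mrca(["B1", "B2"]).name
    u = tree.mrca(["A1", "A3"]).name
    v = tree.mrca(["B1", "B3"]).name
    return (f"t_{a}", f"t_{b}", f"t_{u}", f"t_{v}")


class TestBracing:
    def test_prior_only_mirror_ages_identical_every_sample(self, worked_tree):
        traces = sample_prior(
            worked_tree,
            McmcSettings(n_chains=2, burn_in=200, n_iter=1500, thin=3, seed=2),
        )
        ta, tb, tu, tv = _mirror_columns(worked_tree)
        for t in traces:
            assert (t.df[ta] == t.df[tb]).all()
            assert (t.df[tu] == t.df[tv]).all()

    def test_unbraced_strategy_samples_mirrors_independently(self, worked_tree):
        traces = sample_prior(
            worked_tree,
            McmcSettings(n_chains=1, burn_in=300, n_iter=4000, thin=4, seed=2,
                         strategy="none"),
        )
        ta, tb, tu, tv = _mirror_columns(worked_tree)
        df = traces[0].df
        assert (df[tu] != df[tv]).any()
        r = np.corrcoef(df[tu], df[tv])[0, 1]
        assert r < 0.99

    def test_strategy_b_braces_only_calibrated_groups(self, worked_tree):
        traces = sample_prior(
            worked_tree,
            McmcSettings(n_chains=1, burn_in=200, n_iter=2000, thin=4, seed=4,
                         strategy="B"),
        )
        ta, tb, tu, tv = _mirror_columns(worked_tree)
        df = traces[0].df
        assert (df[ta] == df[tb]).all()  # calibrated group braced
        assert (df[tu] != df[tv]).any()  # uncalibrated group free

    def test_posterior_run_keeps_mirrors_aliased(self, posterior_traces, small_dataset):
        tree = small_dataset["calibrated"]
        for label, nodes in tree.brace_labels().items():
            cols = [f"t_{n.name}" for n in nodes]
            for t in posterior_traces:
                base = t.df[cols[0]]
                for c in cols[1:]:
                    assert (t.df[c] == base).all()


class TestInvariants:
    def test_age_ordering_in_every_sample(self, posterior_traces, small_dataset):
        tree = small_dataset["calibrated"]
        for t in posterior_traces:
            for node in tree.internal_nodes():
                if node.parent is None:
                    continue
                child = t.df[f"t_{node.name}"].to_numpy()
                parent = t.df[f"t_{node.parent.name}"].to_numpy()
                assert (parent > child).all()

    def test_fixed_seed_reproduces_trace_exactly(self, worked_tree):
        settings = McmcSettings(n_chains=2, burn_in=100, n_iter=500, thin=5, seed=9)
        t1 = sample_prior(worked_tree, settings)
        t2 = sample_prior(worked_tree, settings)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.df, b.df)
            assert a.seed == b.seed

    def test_infeasible_hard_bounds_rejected_before_sampling(self):
        text = "((A,B) B{3.0,3.2,0,0}, C) 'B(1.9,2.0,0,0)';"
        tree = parse_braced_newick(text)
        with pytest.raises(InfeasibleCalibrationError):
            sample_prior(tree, McmcSettings(n_chains=1, n_iter=10, burn_in=0))


class TestPriorRecovery:
    def test_isolated_soft_calibration_quantiles(self):
        # marginal prior of an isolated calibrated node reproduces the
        # calibration's 2.5%/97.5% points (the window bounds)
        tree = parse_braced_newick("((A,B) B{0.2,0.4}, C) 'B(0.9,1.1)';")
        traces = sample_prior(
            tree,
            McmcSettings(n_chains=2, burn_in=1000, n_iter=15000, thin=1, seed=6,
                         strategy="none"),
        )
        x = np.concatenate(
            [t.df[f"t_{tree.mrca(['A', 'B']).name}"].to_numpy() for t in traces]
        )
        lo, hi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(0.2, abs=0.015)
        assert hi == pytest.approx(0.4, abs=0.015)

    def test_nested_overlapping_calibrations_truncate_child(self):
        # overlapping windows: every draw keeps child < parent
        tree = parse_braced_newick("(((A,B) B{0.3,0.8}, C) , D) 'B(0.5,0.9)';")
        traces = sample_prior(
            tree, McmcSettings(n_chains=2, burn_in=500, n_iter=4000, thin=2, seed=8),
        )
        child = tree.mrca(["A", "B"]).name
        for t in traces:
            assert (t.df[f"t_{child}"] < t.df[f"t_{tree.root.name}"]).all()


class TestSummaries:
    def test_constant_trace_collapses(self):
        df = pd.DataFrame({"iteration": [1, 2, 3], "t_x": [2.0, 2.0, 2.0]})
        trace = ChainTrace(0, 1, df)
        s = summarize_posterior([trace])
        assert s.loc["t_x", "mean"] == 2.0
        assert s.loc["t_x", "2.5%q"] == 2.0 and s.loc["t_x", "97.5%q"] == 2.0

    def test_normal_samples_equal_tail_interval(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"iteration": np.arange(100000),
                           "t_x": rng.normal(size=100000)})
        s = summarize_posterior([ChainTrace(0, 0, df)])
        assert s.loc["t_x", "2.5%q"] == pytest.approx(-1.96, abs=0.05)
        assert s.loc["t_x", "97.5%q"] == pytest.approx(1.96, abs=0.05)

    def test_mirror_summaries_identical(self, worked_tree):
        traces = sample_prior(
            worked_tree, McmcSettings(n_chains=1, burn_in=100, n_iter=800, thin=4, seed=3),
        )
        s = summarize_posterior(traces)
        ta, tb, tu, tv = _mirror_columns(worked_tree)
        pd.testing.assert_series_equal(s.loc[ta], s.loc[tb], check_names=False)
        pd.testing.assert_series_equal(s.loc[tu], s.loc[tv], check_names=False)

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior([])

    def test_trace_tsv_round_trip(self, worked_tree, tmp_path):
        (trace,) = sample_prior(
            worked_tree, McmcSettings(n_chains=1, burn_in=50, n_iter=200, thin=4, seed=1),
        )
        path = tmp_path / "trace.tsv"
        write_trace_tsv(trace, path)
        again = read_trace_tsv(path)
        assert again.chain_id == trace.chain_id and again.seed == trace.seed
        pd.testing.assert_frame_equal(again.df, trace.df)

    def test_summary_tree_annotated(self, worked_tree, tmp_path):
        traces = sample_prior(
            worked_tree, McmcSettings(n_chains=1, burn_in=100, n_iter=500, thin=5, seed=2),
        )
        s = summarize_posterior(traces)
        text = write_summary_tree(worked_tree, s, tmp_path / "tt.nwk")
        assert "age_mean" in text and text.endswith(";")
        assert (tmp_path / "tt.nwk").exists()


class TestClockModels:
    @pytest.mark.parametrize("model", ["ILN", "strict"])
    def test_other_clocks_run_and_recover_sane_ages(self, small_dataset, model):
        part = Partition(ClockParams(model, 0.8, 0.05), approx=small_dataset["spec"])
        traces = run_mcmc(
            part,
            small_dataset["calibrated"],
            McmcSettings(n_chains=1, burn_in=300, n_iter=1200, thin=4, seed=13),
        )
        s = summarize_posterior(traces)
        truth = small_dataset["truth"]
        root_mean = s.loc["t_dup_root", "mean"]
        assert 0.5 < root_mean < 2.0  # truth is 1.0

    def test_exact_likelihood_path(self, small_dataset):
        # tiny run evaluating the pruning likelihood inside the sampler
        part = Partition(
            ClockParams("ILN", 0.8, 0.05),
            alignment=small_dataset["aln"],
            subst_model="JC69",
        )
        traces = run_mcmc(
            part,
            small_dataset["calibrated"],
            McmcSettings(n_chains=1, burn_in=30, n_iter=120, thin=4, seed=3),
        )
        assert len(traces[0]) == 30
        assert np.isfinite(traces[0].df["lnlike"]).all()
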