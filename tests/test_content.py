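"""Presence-probability post-processing, LOESS, and size prediction."""

import numpy as np
import pandas as pd
import pytest

from paraclock.content import (
    classify_families,
    fit_size_model,
    loess,
    median_pp,
    predict_size,
    read_presence_table,
    sample_genomes,
    topology_agreement,
)
from paraclock.simulate import simulate_content_tables


class TestMedianPP:
    def test_five_run_median(self):
        assert median_pp([0.1, 0.9, 0.9, 0.9, 0.2]) == 0.9

    def test_single_run_passthrough(self):
        assert median_pp([0.42]) == 0.42

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        tuples = rng.uniform(size=(1000, 5))
        got = median_pp(tuples)
        want = np.array([sorted(row)[2] for row in tuples])
        np.testing.assert_allclose(got, want)

    def test_missing_rows_excluded_with_warning(self):
        rows = np.array([[0.2, 0.4, np.nan], [np.nan] * 3])
        with pytest.warns(UserWarning, match="excluded"):
            out = median_pp(rows)
        assert out[0] == pytest.approx(0.3)
        assert np.isnan(out[1])


def _table(pp, arc=0.02, bac=0.02):
    return pd.DataFrame(
        {"family": [f"K{i}" for i in range(len(pp))], "pp": pp,
         "arc_prop": arc if np.ndim(arc) else [arc] * len(pp),
         "bac_prop": bac if np.ndim(bac) else [bac] * len(pp)}
    )


class TestClassification:
    def test_pp_threshold_inclusive_and_sampling_strict(self):
        out = classify_families(_table([0.75], arc=0.02, bac=0.02))
        assert bool(out["strict_sampled"][0])
        # sampling exactly at 1% in one domain fails the strict-> rule
        out = classify_families(_table([0.75], arc=0.01, bac=0.02))
        assert not bool(out["strict_sampled"][0])
        assert bool(out["strict"][0])

    def test_low_pp_in_no_category(self):
        out = classify_families(_table([0.49]))
        assert not out[["strict_sampled", "strict", "relaxed_sampled", "relaxed"]].any().any()

    def test_category_nesting_on_random_tables(self):
        rng = np.random.default_rng(1)
        t = _table(rng.uniform(size=500), arc=rng.uniform(0, 0.05, 500),
                   bac=rng.uniform(0, 0.05, 500))
        out = classify_families(t)
        c = out.attrs["counts"]
        assert c["strict_sampled"] <= c["strict"] <= c["relaxed"]
        assert c["strict_sampled"] <= c["relaxed_sampled"] <= c["relaxed"]
        assert (out["strict_sampled"] <= out["strict"]).all()
        assert (out["relaxed_sampled"] <= out["relaxed"]).all()

    def test_reader_accepts_common_header_spellings(self, tmp_path):
        df = pd.DataFrame({
            "KO": ["K1", "K2"], "constrained_median": [0.8, 0.3],
            "ML_median": [0.7, 0.2], "Arc_prop": [0.1, 0.0], "Bac_prop": [0.2, 0.05],
        })
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        got = read_presence_table(path)
        assert {"family", "pp", "pp_alt", "arc_prop", "bac_prop"} <= set(got.columns)
        bad = df.assign(constrained_median=[1.2, 0.3])
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_presence_table(path)


class TestSampleGenomes:
    def test_certain_families_always_present(self):
        matrix, summary = sample_genomes(np.ones(50), n=30, seed=0)
        assert matrix.all()
        assert summary["hpd_low"] == summary["hpd_high"] == 50

    def test_mean_count_matches_bernoulli_moments(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=3000)
        _, summary = sample_genomes(p, n=100, seed=3)
        se = np.sqrt(np.sum(p * (1 - p)) / 100)
        assert abs(summary["mean_count"] - p.sum()) < 3 * se

    def test_seed_reproducible(self):
        p = np.linspace(0.1, 0.9, 100)
        m1, _ = sample_genomes(p, n=10, seed=7)
        m2, _ = sample_genomes(p, n=10, seed=7)
        np.testing.assert_array_equal(m1, m2)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            sample_genomes(np.array([]))


class TestLoess:
    def test_exact_on_linear_data(self):
        x = np.linspace(1, 100, 80)
        y = 2.0 * x
        grid = np.linspace(10, 90, 25)
        fit, _ = loess(x, y, grid, span=0.75, degree=2)
        np.testing.assert_allclose(fit, 2.0 * grid, rtol=1e-2)

    def test_matches_statsmodels_lowess_at_degree_one(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 120))
        y = np.sin(x / 3) + rng.normal(0, 0.05, 120)
        ours, _ = loess(x, y, x, span=0.5, degree=1)
        theirs = sm.nonparametric.lowess(y, x, frac=0.5, it=0, return_sorted=False)
        # same estimator family; small differences at the window edges
        assert np.median(np.abs(ours - theirs)) < 0.02

    def test_permutation_invariant_fit(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 50, 100)
        y = x**1.5 + rng.normal(0, 1, 100)
        grid = np.linspace(5, 45, 10)
        f1, _ = loess(x, y, grid)
        perm = rng.permutation(100)
        f2, _ = loess(x[perm], y[perm], grid)
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_monotone_truth_gives_monotone_fit(self):
        rng = np.random.default_rng(5)
        x = np.linspace(1, 100, 150)
        y = np.sqrt(x) + rng.normal(0, 0.01, 150)
        grid = np.linspace(10, 90, 30)
        fit, _ = loess(x, y, grid)
        assert (np.diff(fit) > 0).all()


class TestSizeModel:
    def _training(self, n=60, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ko = np.linspace(200, 2000, n) + rng.uniform(0, 5, n)
        size = 0.003 * ko + rng.normal(0, noise, n)
        proteins = (2.8 * ko).astype(int)
        return pd.DataFrame({
            "ko_count": ko.astype(int), "protein_count": proteins,
            "genome_size_mb": size,
        })

    def test_noiseless_linear_recovery(self):
        model = fit_size_model(self._training(), "size")
        pred = predict_size(model, np.full(10, 1000.0))
        assert pred["estimate"] == pytest.approx(3.0, rel=0.02)

    def test_interval_collapses_without_noise_or_spread(self):
        model = fit_size_model(self._training(), "size")
        pred = predict_size(model, np.full(10, 1000.0))
        assert pred["high"] - pred["low"] < 0.05

    def test_interval_grows_with_training_noise(self):
        widths = []
        for noise in (0.01, 0.2, 0.6):
            model = fit_size_model(self._training(noise=noise, seed=6), "size")
            pred = predict_size(model, np.full(20, 1000.0))
            widths.append(pred["high"] - pred["low"])
        assert widths[0] < widths[1] < widths[2]

    def test_extrapolation_guard(self):
        model = fit_size_model(self._training(), "size")
        with pytest.raises(ValueError, match="extrapolation"):
            predict_size(model, [5000.0])
        pred = predict_size(model, [5000.0], allow_extrapolation=True)
        assert np.isfinite(pred["estimate"])

    def test_needs_thirty_genomes(self):
        with pytest.raises(ValueError):
            fit_size_model(self._training(n=10), "size")

    def test_end_to_end_recovery_on_synthetic_truth(self):
        hits = 0
        for seed in range(10):
            training, table, truth = simulate_content_tables(
                n_genomes=80, n_families=2000, seed=seed
            )
            _, summary = sample_genomes(table["pp"].to_numpy(), n=100, seed=seed)
            model = fit_size_model(training, "size")
            pred = predict_size(model, summary["counts"])
            if pred["low"] <= truth.true_size_mb <= pred["high"]:
                hits += 1
        assert hits >= 9


class TestTopologyAgreement:
    def test_identical_columns_r_one(self):
        t = _table([0.1, 0.5, 0.9, 0.3])
        t["pp_alt"] = t["pp"]
        r, p = topology_agreement(t)
        assert r == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(8)
        t = _table(rng.uniform(size=10000))
        t["pp_alt"] = rng.uniform(size=10000)
        r, _ = topology_agreement(t)
        assert abs(r) < 0.05

    def test_zero_variance_rejected(self):
        t = _table([0.5, 0.5, 0.5])
        t["pp_alt"] = [0.1, 0.2, 0.3]
        with pytest.raises(ValueError, match="variance"):
            topology_agreement(t)

    def test_incomplete_pairs_dropped(self):
        t = _table([0.1, 0.5, 0.9, 0.3])
        t["pp_alt"] = [0.2, np.nan, 0.8, 0.4]
        r, p = topology_agreement(t)
        assert np.isfinite(r) and 0 < p <= 1
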