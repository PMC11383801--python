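import pytest

from paraclock.likelihood import build_approx_spec
from paraclock.mcmc import McmcSettings, Partition, run_mcmc
from paraclock.priors import ClockParams
from paraclock.simulate import (
    make_calibrations,
    simulate_braced_timetree,
    simulate_rates_and_alignment,
)
from paraclock.trees import parse_braced_newick

WORKED_EXAMPLE = (
    "(((A1, A2) #1, A3) #2, ((B1, B2) [#1 B{0.2, 0.4}], B3) #2) 'B(0.9,1.1)';"
)


@pytest.fixture
def worked_tree():
    return parse_braced_newick(WORKED_EXAMPLE)


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-species, 2-paralogue simulated dataset with truth and approx spec."""
    tree, truth = simulate_braced_timetree(6, 2, root_age=1.0, seed=11)
    aln, blen = simulate_rates_and_alignment(
        tree, truth, "GBM", 0.8, 0.05, "JC69", 400, seed=11
    )
    spec = build_approx_spec(aln, tree, "JC69")
    cal = make_calibrations(tree, truth, 0.25, seed=11)
    return {"tree": tree, "truth": truth, "aln": aln, "blen": blen,
            "spec": spec, "calibrated": cal}


@pytest.fixture(scope="session")
def posterior_traces(small_dataset):
    """A short posterior run shared by invariant and summary tests."""
    part = Partition(ClockParams("GBM", 0.8, 0.05), approx=small_dataset["spec"])
    settings = McmcSettings(n_chains=2, burn_in=300, n_iter=1500, thin=5, seed=5)
    return run_mcmc(part, small_dataset["calibrated"], settings)
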