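"""End-to-end orchestration: config, provenance, and the full run layout.

A run directory contains::

    manifest.json        config hash, seeds, versions (provenance)
    trace_chain<k>.tsv   thinned samples per chain
    diagnostics.json     R-hat / ESS / chain-filter report
    summary.tsv          per-parameter mean, CIs, HPD
    timetree.nwk         summary tree with age annotations
    content/...          gene-content outputs when that stage runs

The 12-configuration benchmark grid of clock model x partitioning x
cross-bracing strategy is expressible as {GBM, ILN} x {concatenated,
partitioned} x {A, B, none}; leave-one-out runs re-date the data with one
partition removed, honouring per-subset rate-prior overrides.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .content import (
    classify_families,
    fit_size_model,
    predict_size,
    sample_genomes,
)
from .diagnostics import filter_chains
from .likelihood import build_approx_spec, read_alignment
from .mcmc import (
    McmcSettings,
    Partition,
    run_mcmc,
    summarize_posterior,
    write_summary_tree,
    write_trace_tsv,
)
from .priors import BDParams, ClockParams
from .simulate import (
    make_calibrations,
    simulate_braced_timetree,
    simulate_content_tables,
    simulate_rates_and_alignment,
)
from .trees import parse_braced_newick

__all__ = ["RunConfig", "run_pipeline", "WORKED_EXAMPLE_NEWICK"]

WORKED_EXAMPLE_NEWICK = (
    "(((A1, A2) #1, A3) #2, ((B1, B2) [#1 B{0.2, 0.4}], B3) #2) 'B(0.9,1.1)';"
)

SCENARIOS = ("worked-example", "five-paralogue", "content-recovery")


@dataclass
class RunConfig:
    """One analysis configuration (YAML-loadable)."""

    # dataset: exactly one source
    scenario: Optional[str] = None  # synthetic preset
    tree_file: Optional[str] = None
    alignment_files: dict[str, str] = field(default_factory=dict)  # name -> path
    alignment_format: str = "fasta"

    clock_model: str = "GBM"
    bracing: str = "A"  # A | B | none
    partitioning: str = "partitioned"  # concatenated | partitioned
    subst_model: str = "JC69"
    gamma_alpha: Optional[float] = None
    rate_prior: tuple[float, float] = (2.0, 2.5)
    sigma2_prior: tuple[float, float] = (1.0, 10.0)
    rate_prior_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    prior_only: bool = False
    leave_one_out: bool = False

    n_chains: int = 4
    burn_in: int = 2000
    n_iter: int = 10000
    thin: int = 10
    seed: int = 0

    run_content: bool = False
    loess_span: float = 0.75
    n_sampled_genomes: int = 100

    out_dir: str = "paraclock_run"

    # synthetic scenario knobs
    n_species: int = 10
    n_paralogues: int = 2
    root_age: float = 1.0
    mean_rate: float = 0.8
    sigma2: float = 0.05
    n_sites: int = 500
    n_partitions: int = 5
    calibration_width: float = 0.25

    def __post_init__(self) -> None:
        sources = int(self.scenario is not None) + int(bool(self.alignment_files) or self.tree_file is not None)
        if sources != 1:
            raise ValueError("config needs exactly one dataset source "
                             "(a scenario, or tree/alignment files)")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.bracing not in ("A", "B", "none"):
            raise ValueError(f"unknown bracing strategy {self.bracing!r}")
        if self.partitioning not in ("concatenated", "partitioned"):
            raise ValueError(f"unknown partitioning {self.partitioning!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("rate_prior", "sigma2_prior"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "rate_prior_overrides" in raw:
            raw["rate_prior_overrides"] = {
                k: tuple(v) for k, v in raw["rate_prior_overrides"].items()
            }
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _settings(config: RunConfig) -> McmcSettings:
    return McmcSettings(
        n_chains=config.n_chains,
        burn_in=config.burn_in,
        n_iter=config.n_iter,
        thin=config.thin,
        seed=config.seed,
        strategy=config.bracing,
    )


def _clock(config: RunConfig, name: str) -> ClockParams:
    prior = config.rate_prior_overrides.get(name, config.rate_prior)
    return ClockParams(
        model=config.clock_model,
        mean_rate=prior[0] / prior[1],
        sigma2=max(config.sigma2, 1e-3),
        rate_prior=prior,
        sigma2_prior=config.sigma2_prior,
    )


def _resolve_dataset(config: RunConfig):
    """Returns (tree, partitions: dict name -> Alignment | None, truth)."""
    if config.scenario == "worked-example":
        tree = parse_braced_newick(WORKED_EXAMPLE_NEWICK)
        return tree, {}, None
    if config.scenario == "five-paralogue":
        tree, truth = simulate_braced_timetree(
            config.n_species, config.n_paralogues, config.root_age, config.seed
        )
        parts = {}
        for k in range(config.n_partitions):
            aln, _ = simulate_rates_and_alignment(
                tree, truth, config.clock_model, config.mean_rate,
                config.sigma2, config.subst_model, config.n_sites,
                seed=config.seed * 1000 + k,
            )
            parts[f"g{k + 1}"] = aln
        tree = make_calibrations(
            tree, truth, config.calibration_width, seed=config.seed
        )
        return tree, parts, truth
    # file-based dataset
    from .likelihood import SubstitutionModel

    if config.tree_file is None:
        raise ValueError("file-based runs need tree_file")
    tree = parse_braced_newick(Path(config.tree_file).read_text())
    model = SubstitutionModel(config.subst_model)
    parts = {
        name: read_alignment(path, config.alignment_format, model)
        for name, path in config.alignment_files.items()
    }
    return tree, parts, None


def _concatenate(parts: dict) -> dict:
    if len(parts) <= 1:
        return parts
    from .likelihood import Alignment

    names = None
    merged = None
    total = 0
    for aln in parts.values():
        if names is None:
            names = aln.names
        elif names != aln.names:
            raise ValueError("partitions must share the same taxa to concatenate")
        block = np.repeat(aln.patterns, aln.weights.astype(int), axis=1)
        merged = block if merged is None else np.concatenate([merged, block], axis=1)
        total += aln.n_sites
    cols, weights = np.unique(merged, axis=1, return_counts=True)
    return {"concat": Alignment(list(names), cols, weights.astype(float), total)}


def _date_once(
    config: RunConfig,
    tree,
    parts: dict,
    out: Path,
    exclude: Optional[str] = None,
) -> dict:
    use = {k: v for k, v in parts.items() if k != exclude}
    if config.partitioning == "concatenated":
        use = _concatenate(use)
    partitions = []
    for name, aln in use.items():
        clock = _clock(config, name if exclude is None else f"no{exclude}")
        if aln is None or config.prior_only:
            partitions.append(Partition(clock, name=name))
        else:
            spec = build_approx_spec(aln, tree, config.subst_model, config.gamma_alpha)
            partitions.append(Partition(clock, approx=spec, name=name))
    if config.prior_only or not use:
        partitions = partitions or [Partition(_clock(config, "prior"))]
        for p in partitions:
            p.approx = None
            p.alignment = None
    traces = run_mcmc(partitions, tree, _settings(config), BDParams())
    out.mkdir(parents=True, exist_ok=True)
    for t in traces:
        write_trace_tsv(t, out / f"trace_chain{t.chain_id}.tsv")
    retained, report = filter_chains(traces)
    report.to_json(out / "diagnostics.json")
    report.to_frame().to_csv(out / "diagnostics.tsv", sep="\t")
    summary = summarize_posterior(retained)
    summary.to_csv(out / "summary.tsv", sep="\t")
    write_summary_tree(tree, summary, out / "timetree.nwk")
    return {
        "traces": traces,
        "retained": retained,
        "report": report,
        "summary": summary,
        "partitions": partitions,
    }


def _content_stage(config: RunConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    training, table, truth = simulate_content_tables(seed=config.seed)
    classified = classify_families(table)
    classified.to_csv(out / "categories.tsv", sep="\t", index=False)
    matrix, summary = sample_genomes(
        table["pp"].to_numpy(), n=config.n_sampled_genomes, seed=config.seed
    )
    model_size = fit_size_model(training, "size", span=config.loess_span)
    model_prot = fit_size_model(training, "proteins", span=config.loess_span)
    pred_size = predict_size(model_size, summary["counts"])
    pred_prot = predict_size(model_prot, summary["counts"])
    results = {
        "category_counts": classified.attrs["counts"],
        "sampled_mean_families": summary["mean_count"],
        "sampled_hpd": [summary["hpd_low"], summary["hpd_high"]],
        "genome_size_mb": {
            k: pred_size[k] for k in ("estimate", "low", "high")
        },
        "protein_count": {
            k: pred_prot[k] for k in ("estimate", "low", "high")
        },
        "true_size_mb": truth.true_size_mb,
        "true_protein_count": truth.true_protein_count,
    }
    (out / "content.json").write_text(json.dumps(results, indent=1))
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> date -> diagnose -> summarize (-> content).

    Returns the in-memory results; everything is also written under
    ``config.out_dir`` together with a provenance manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    if config.scenario == "content-recovery" or config.run_content:
        results["content"] = _content_stage(config, out / "content")
    if config.scenario != "content-recovery":
        tree, parts, truth = _resolve_dataset(config)
        results["main"] = _date_once(config, tree, parts, out)
        if config.leave_one_out and len(parts) > 1:
            results["leave_one_out"] = {}
            for name in parts:
                results["leave_one_out"][name] = _date_once(
                    config, tree, parts, out / f"loo_{name}", exclude=name
                )
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "chain_seeds": [t.seed for t in results.get("main", {}).get("traces", [])]
        if "main" in results
        else [],
        "versions": {"paraclock": __version__, "numpy": np.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results["manifest"] = manifest
    return results
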