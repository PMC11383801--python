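"""Ancestral gene-content post-processing and genome-size prediction.

Gene-tree/species-tree reconciliation (run upstream) yields, per gene
family, the posterior probability (PP) that the family was present in the
ancestor of interest, typically across several replicate runs and per
species-tree topology, together with the fraction of archaeal and
bacterial genomes sampling the family.  This module

* collapses per-run PPs to a per-family median,
* assigns families to four nested confidence categories
  (PP >= 0.75 / 0.50, with or without >1% sampling in both domains),
* draws Bernoulli "sampled ancestral genomes" from the PP vector and
  summarizes family counts with a 95% HPD interval,
* fits a LOESS curve (tricube-weighted local polynomial) of genome size
  or proteome size against KO-family count on modern genomes, and
  propagates the sampled family counts through it to a point estimate
  with a 95% interval, and
* computes the Pearson correlation of PPs between two reconciliation
  columns (topology agreement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import hpd_interval

__all__ = [
    "PRESENCE_COLUMNS",
    "read_presence_table",
    "median_pp",
    "classify_families",
    "sample_genomes",
    "SizeModel",
    "fit_size_model",
    "predict_size",
    "topology_agreement",
    "loess",
]

# tolerated header spellings for per-family presence tables
PRESENCE_COLUMNS = {
    "family": ["family", "id", "KO", "ko", "COG", "cog", "gene_family"],
    "pp": ["pp", "constrained_median", "median_pp", "PP"],
    "pp_alt": ["ML_median", "ml_median", "pp_alt"],
    "arc_prop": ["Arc_prop", "arc_prop", "archaea_sampling"],
    "bac_prop": ["Bac_prop", "bac_prop", "bacteria_sampling"],
}


def read_presence_table(
    path, column_map: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Read a per-family presence-probability TSV.

    Recognizes common header spellings; ``column_map`` overrides them
    (role -> actual column name).  The result has canonical columns
    ``family``, ``pp`` and, when present, ``pp_alt``, ``arc_prop``,
    ``bac_prop``, plus any extra annotation columns unchanged.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for role, aliases in PRESENCE_COLUMNS.items():
        if column_map and role in column_map:
            rename[column_map[role]] = role
            continue
        for a in aliases:
            if a in df.columns:
                rename[a] = role
                break
    df = df.rename(columns=rename)
    if "family" not in df.columns or "pp" not in df.columns:
        raise ValueError("presence table needs family-id and PP columns")
    if df["family"].duplicated().any():
        raise ValueError("family ids must be unique")
    for col in ("pp", "pp_alt", "arc_prop", "bac_prop"):
        if col in df.columns:
            bad = df[col].dropna()
            if ((bad < 0) | (bad > 1)).any():
                raise ValueError(f"column {col!r} has values outside [0, 1]")
    return df


def median_pp(per_run_pps) -> np.ndarray | float:
    """Median presence probability across replicate reconciliation runs.

    Accepts a 1-D vector (one family) or a DataFrame/2-D array with one
    row per family; rows with missing values use the median of the
    remaining runs (all-missing rows are dropped with a warning).
    """
    arr = np.asarray(
        per_run_pps if not isinstance(per_run_pps, pd.DataFrame) else per_run_pps.values,
        dtype=float,
    )
    if arr.ndim == 1:
        vals = arr[~np.isnan(arr)]
        if len(vals) == 0:
            raise ValueError("no run values")
        return float(np.median(vals))
    out = np.full(arr.shape[0], np.nan)
    n_missing = 0
    for i, row in enumerate(arr):
        vals = row[~np.isnan(row)]
        if len(vals) == 0:
            n_missing += 1
            continue
        out[i] = np.median(vals)
    if n_missing:
        warnings.warn(f"{n_missing} families had no run values and were excluded")
    return out


def classify_families(
    table: pd.DataFrame,
    pp_thresholds: tuple[float, float] = (0.75, 0.50),
    sampling: float = 0.01,
    pp_col: str = "pp",
) -> pd.DataFrame:
    """Four nested confidence categories per family.

    PP thresholds are inclusive (>=); the domain-sampling requirement is
    strict (> ``sampling`` in both Archaea and Bacteria).  Returns the
    table with boolean columns ``strict_sampled``, ``strict``,
    ``relaxed_sampled``, ``relaxed`` and records the counts in
    ``result.attrs["counts"]``.
    """
    hi, lo = pp_thresholds
    pp = table[pp_col].to_numpy(dtype=float)
    if {"arc_prop", "bac_prop"} <= set(table.columns):
        sampled = (table["arc_prop"].to_numpy() > sampling) & (
            table["bac_prop"].to_numpy() > sampling
        )
    else:
        sampled = np.zeros(len(table), dtype=bool)
    out = table.copy()
    out["strict_sampled"] = (pp >= hi) & sampled
    out["strict"] = pp >= hi
    out["relaxed_sampled"] = (pp >= lo) & sampled
    out["relaxed"] = pp >= lo
    out.attrs["counts"] = {
        c: int(out[c].sum())
        for c in ("strict_sampled", "strict", "relaxed_sampled", "relaxed")
    }
    return out


def sample_genomes(
    pps, n: int = 100, seed: Optional[int] = None
) -> tuple[np.ndarray, dict]:
    """Draw ``n`` Bernoulli genomes from a family PP vector.

    Families are independent Bernoulli(p_i) draws per replicate genome.
    Returns the (n, n_families) boolean presence matrix and a summary with
    the per-replicate family counts, their mean and 95% HPD interval.
    """
    p = np.asarray(pps, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    matrix = rng.random((n, p.size)) < p[None, :]
    counts = matrix.sum(axis=1)
    if n >= 20 and np.ptp(counts) > 0:
        lo, hi = hpd_interval(counts.astype(float), 0.95)
    else:
        lo, hi = float(counts.min()), float(counts.max())
    summary = {
        "counts": counts,
        "mean_count": float(counts.mean()),
        "hpd_low": lo,
        "hpd_high": hi,
        "expected_count": float(p.sum()),
    }
    return matrix, summary


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_new: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local polynomial regression.

    Returns fitted values and the pointwise standard-error factors
    ||l(x0)|| such that SE(x0) = sigma * ||l(x0)|| for residual scale
    sigma.  ``span`` is the fraction of points in each local window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    fit = np.empty(len(x_new))
    senorm = np.empty(len(x_new))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for j, x0 in enumerate(x_new):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            fit[j] = ys[idx].mean()
            senorm[j] = 1.0 / np.sqrt(len(idx))
            continue
        w = (1.0 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        X = np.vander(xs[idx] - x0, degree + 1, increasing=True)
        WX = X * w[:, None]
        A = X.T @ WX
        # l(x0) row vector: e0' (X'WX)^-1 X'W
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        l_row = Ainv[0] @ WX.T
        fit[j] = l_row @ ys[idx]
        senorm[j] = float(np.sqrt(l_row @ l_row))
    return fit, senorm


@dataclass
class SizeModel:
    """A fitted KO-count -> genome-feature local-regression model."""

    x: np.ndarray
    y: np.ndarray
    response: str  # "proteins" or "size"
    span: float
    degree: int
    residual_scale: float
    x_range: tuple[float, float]
    interval_method: str = "normal(smoother SE + replicate spread)"

    def predict(
        self, x_new, allow_extrapolation: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        lo, hi = self.x_range
        if not allow_extrapolation and (np.any(x_new < lo) or np.any(x_new > hi)):
            raise ValueError(
                f"prediction point outside the training KO-count range "
                f"[{lo:g}, {hi:g}]; pass allow_extrapolation=True to override"
            )
        fit, senorm = loess(self.x, self.y, x_new, self.span, self.degree)
        return fit, senorm * self.residual_scale


def fit_size_model(
    training: pd.DataFrame,
    response: str = "size",
    span: float = 0.75,
    degree: int = 2,
    ko_col: str = "ko_count",
) -> SizeModel:
    """Fit the LOESS relationship between KO-family count and genome size
    (Mb) or protein-coding gene count over a genome training table."""
    if response not in ("size", "proteins"):
        raise ValueError("response must be 'size' or 'proteins'")
    col = {"size": "genome_size_mb", "proteins": "protein_count"}[response]
    if len(training) < 30:
        raise ValueError("need >= 30 training genomes")
    x = training[ko_col].to_numpy(dtype=float)
    y = training[col].to_numpy(dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("counts and sizes must be positive")
    fitted, _ = loess(x, y, x, span, degree)
    resid = y - fitted
    dof = max(len(x) - (degree + 1), 1)
    scale = float(np.sqrt(np.sum(resid**2) / dof))
    return SizeModel(
        x=x,
        y=y,
        response=response,
        span=span,
        degree=degree,
        residual_scale=scale,
        x_range=(float(x.min()), float(x.max())),
    )


def predict_size(
    model: SizeModel,
    ko_counts,
    level: float = 0.95,
    allow_extrapolation: bool = False,
) -> dict:
    """Point estimate and interval for the ancestral genome feature.

    ``ko_counts`` are the per-replicate family counts from
    :func:`sample_genomes`.  The point estimate is the mean prediction
    over replicates; the interval is a normal approximation combining the
    smoother standard error with the across-replicate spread.
    """
    ko = np.atleast_1d(np.asarray(ko_counts, dtype=float))
    fit, se = model.predict(ko, allow_extrapolation)
    point = float(fit.mean())
    spread2 = float(fit.var(ddof=1)) if len(fit) > 1 else 0.0
    se2 = float(np.mean(se**2))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(se2 + spread2)
    return {
        "estimate": point,
        "low": point - half,
        "high": point + half,
        "per_replicate": fit,
        "smoother_se": float(np.sqrt(se2)),
        "replicate_sd": float(np.sqrt(spread2)),
        "level": level,
    }


def topology_agreement(
    table: pd.DataFrame, col_a: str = "pp", col_b: str = "pp_alt"
) -> tuple[float, float]:
    """Pearson correlation of presence probabilities between two columns
    (e.g. constrained vs ML species-tree topologies) on complete pairs."""
    sub = table[[col_a, col_b]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete pairs")
    a = sub[col_a].to_numpy(dtype=float)
    b = sub[col_b].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: a column has zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
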