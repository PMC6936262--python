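"""Gene expression plasticity (GEP) scoring and its quality controls.

A gene's plasticity is the log2 of its mean squared log2 fold change across
conditions::

    GEP(g) = log2( mean_c (log2FC_{g,c})^2 )

computed over the gene's non-missing conditions.  High GEP marks genes whose
expression responds strongly to genetic or environmental perturbation
(stress response, immunity); low GEP marks stable genes (homeobox,
housekeeping).  The companions implemented here are the randomized null
(per-condition label shuffles), a condition-subsampling stability curve,
percentile-rank normalization, per-cell-group GEP, and baseline expression
level / broadness measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import FoldChangeMatrix, ValidationError

__all__ = [
    "compute_gep",
    "percentile_rank",
    "gep_null",
    "stability_curve",
    "subset_gep",
    "level_and_broadness",
    "gep_from_expression",
    "default_min_conditions",
    "StabilityCurve",
]


def default_min_conditions(n_conditions: int) -> int:
    """Minimum non-missing conditions required per gene.

    max(10, 25% of conditions), capped at the number of conditions so tiny
    matrices remain scoreable.
    """
    return min(n_conditions, max(10, int(np.ceil(0.25 * n_conditions))))


def compute_gep(fc: FoldChangeMatrix, min_conditions: int | None = None) -> pd.DataFrame:
    """Score plasticity per gene: ``gep = log2(mean (log2FC)^2)``.

    Returns a DataFrame indexed by gene id with columns ``gep`` and
    ``n_conditions``.  Genes with fewer than ``min_conditions`` observed
    values, or with an exactly zero mean square (GEP undefined), are
    excluded; their counts are stored in ``result.attrs`` and reported via
    warnings.
    """
    if fc.shape[0] == 0 or fc.shape[1] == 0:
        raise ValidationError("empty fold-change matrix")
    if min_conditions is None:
        min_conditions = default_min_conditions(fc.shape[1])
    if min_conditions < 1:
        raise ValueError("min_conditions must be >= 1")

    values = fc.values.to_numpy()
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_sq = np.nanmean(np.square(values), axis=1)

    enough = n_obs >= min_conditions
    defined = enough & (mean_sq > 0)
    n_below = int((~enough).sum())
    n_zero = int((enough & (mean_sq == 0)).sum())
    if n_below:
        warnings.warn(
            f"{n_below} gene(s) below min_conditions={min_conditions} omitted"
        )
    if n_zero:
        warnings.warn(f"{n_zero} gene(s) with all-zero fold changes: GEP undefined")

    out = pd.DataFrame(
        {
            "gep": np.log2(mean_sq[defined]),
            "n_conditions": n_obs[defined].astype(int),
        },
        index=fc.genes[defined],
    )
    out.index.name = "gene_id"
    out.attrs["n_below_min_conditions"] = n_below
    out.attrs["n_undefined"] = n_zero
    out.attrs["min_conditions"] = min_conditions
    return out


def percentile_rank(gep: pd.DataFrame, column: str = "gep") -> pd.DataFrame:
    """Add a ``percentile`` column: (average rank - 0.5) / n * 100.

    Ties share their average rank, so equal scores get equal percentiles and
    the transform is order preserving.
    """
    vals = gep[column].to_numpy(float)
    if np.isfinite(vals).sum() < 2:
        raise ValidationError("percentile rank needs >= 2 defined GEP values")
    ranks = stats.rankdata(vals, method="average")
    out = gep.copy()
    out["percentile"] = (ranks - 0.5) / len(vals) * 100.0
    return out


def gep_null(
    fc: FoldChangeMatrix,
    n_permutations: int = 1,
    seed: int = 0,
    min_conditions: int | None = None,
) -> list[pd.DataFrame]:
    """Null GEP distributions from per-condition gene-label shuffles.

    Each permutation independently shuffles the gene labels of every
    condition column, preserving each condition's value multiset exactly
    (missing entries travel with their values), then rescores GEP.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    values = fc.values.to_numpy()
    n_genes, n_cond = values.shape
    out = []
    for _ in range(n_permutations):
        perm = np.empty_like(values)
        for j in range(n_cond):
            perm[:, j] = values[rng.permutation(n_genes), j]
        shuffled = FoldChangeMatrix(
            pd.DataFrame(perm, index=fc.genes, columns=fc.conditions),
            fc.condition_meta,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(compute_gep(shuffled, min_conditions=min_conditions))
    return out


@dataclass
class StabilityCurve:
    """Mean correlation of subsampled-condition GEP with full-data GEP."""

    n_grid: list[int]
    mean_r: list[float]
    n_replicates: int
    seed: int
    per_replicate: dict[int, list[float]] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_conditions": self.n_grid, "mean_r": self.mean_r})


def stability_curve(
    fc: FoldChangeMatrix,
    n_grid,
    n_replicates: int = 20,
    seed: int = 0,
    min_conditions: int = 1,
) -> StabilityCurve:
    """How stable is GEP as the number of conditions grows?

    For each n in ``n_grid``, draws ``n_replicates`` random condition
    subsets (without replacement within a subset), recomputes GEP, and
    Pearson-correlates it with the full-data GEP over genes defined in both.
    At n = total conditions the subset is the full set and r = 1 exactly.
    """
    n_grid = [int(n) for n in n_grid]
    if any(n < 1 for n in n_grid):
        raise ValueError("n_grid entries must be >= 1")
    total = fc.shape[1]
    if max(n_grid) > total:
        raise ValueError("n_grid exceeds the number of conditions")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = compute_gep(fc, min_conditions=min_conditions)["gep"]
    mean_r, per_rep = [], {}
    for n in n_grid:
        rs = []
        for _ in range(n_replicates):
            if n == total:
                cols = fc.conditions
            else:
                cols = fc.conditions[rng.choice(total, size=n, replace=False)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = compute_gep(
                    fc.subset_conditions(cols),
                    min_conditions=min(min_conditions, n),
                )["gep"]
            common = full.index.intersection(sub.index)
            rs.append(
                1.0
                if n == total
                else float(stats.pearsonr(full.loc[common], sub.loc[common])[0])
            )
        per_rep[n] = rs
        mean_r.append(float(np.mean(rs)))
    return StabilityCurve(n_grid, mean_r, n_replicates, seed, per_rep)


def subset_gep(
    fc: FoldChangeMatrix,
    group_by: str,
    min_conditions: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """GEP per condition group (e.g. cell line) plus pairwise Spearman matrix.

    ``group_by`` names a column of the condition metadata.  Groups with
    fewer conditions than the minimum-condition rule are skipped with a
    warning.  The correlation between two groups is computed over genes
    scored in both.
    """
    if fc.condition_meta is None or group_by not in fc.condition_meta.columns:
        raise ValueError(f"unknown condition metadata key {group_by!r}")
    groups = fc.condition_meta.groupby(group_by).groups
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in groups.items():
        sub = fc.subset_conditions(list(cols))
        mc = (
            default_min_conditions(sub.shape[1])
            if min_conditions is None
            else min_conditions
        )
        if sub.shape[1] < mc:
            warnings.warn(f"group {name!r} has < {mc} conditions; skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables[str(name)] = compute_gep(sub, min_conditions=mc)
    names = sorted(tables)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            common = tables[a].index.intersection(tables[b].index)
            rho = stats.spearmanr(
                tables[a].loc[common, "gep"], tables[b].loc[common, "gep"]
            )[0]
            corr.loc[a, b] = corr.loc[b, a] = rho
    return tables, corr


def level_and_broadness(
    expr: pd.DataFrame,
    expressed_cutoff: float = 0.1,
    specificity_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Baseline expression level and the two broadness measures.

    ``expr`` is a TPM-like gene x sample matrix (values >= 0).  Per gene:

    * ``mean_level`` — mean of log2(TPM + 1) across samples;
    * ``broadness_freq`` — fraction of samples with log2(TPM + 1) above
      ``expressed_cutoff``;
    * ``broadness_spec`` — fraction of samples where expression exceeds
      ``specificity_cutoff`` times the gene's cross-sample mean.

    Genes with a zero cross-sample mean have undefined specificity and get
    ``broadness_spec = 0``.
    """
    if expressed_cutoff <= 0 or specificity_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    vals = expr.to_numpy(float)
    if (vals < 0).any():
        raise ValidationError("negative expression values")
    log_expr = np.log2(vals + 1.0)
    mean_level = log_expr.mean(axis=1)
    broadness_freq = (log_expr > expressed_cutoff).mean(axis=1)
    row_mean = vals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        specificity = vals / row_mean[:, None]
    broadness_spec = np.where(
        row_mean > 0,
        np.nan_to_num(specificity > specificity_cutoff).mean(axis=1),
        0.0,
    )
    out = pd.DataFrame(
        {
            "mean_level": mean_level,
            "broadness_freq": broadness_freq,
            "broadness_spec": broadness_spec,
        },
        index=expr.index,
    )
    out.index.name = "gene_id"
    return out


def gep_from_expression(
    expr: pd.DataFrame, pseudo_count: float = 1.0
) -> FoldChangeMatrix:
    """Build a fold-change matrix from baseline expression across samples.

    The per-sample fold change is log2((TPM + pseudo) / row mean of
    (TPM + pseudo)) — the normal-condition plasticity variant scored against
    the cross-sample average rather than a matched control.
    """
    vals = expr.to_numpy(float) + pseudo_count
    if (vals <= 0).any():
        raise ValidationError("expression + pseudo_count must be positive")
    fc = np.log2(vals / vals.mean(axis=1, keepdims=True))
    return FoldChangeMatrix(pd.DataFrame(fc, index=expr.index, columns=expr.columns))
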