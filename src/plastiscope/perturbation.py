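"""Causal validation of predicted regulators from perturbation experiments.

Given expression assayed under (at least) two conditions in both a control
genotype and a loss/gain-of-function mutant, the analysis compares the
magnitude of expression change (|log2 fold change| between conditions) for
the most dynamically expressed genes in each genotype.  A factor predicted
to promote plasticity should, when inactivated, shrink those magnitudes:
the top-dynamic mutant distribution shifts down, and among genes changing
co-directionally in both genotypes most show a lower magnitude in the
mutant (a lower:higher ratio well above 1, Fisher exact p < 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .types import ValidationError

__all__ = [
    "PerturbationExperiment",
    "collapse_probes",
    "eligibility_check",
    "magnitude_validation",
    "ValidationResult",
]


@dataclass
class PerturbationExperiment:
    """Expression for two genotypes across >= 2 conditions with replicates.

    ``control`` and ``mutant`` map condition label -> gene x replicate
    DataFrame of log2 expression; gene ids must agree across genotypes.
    ``gene_universe`` optionally restricts all analyses (e.g. to genes
    enriched for a histone mark in the gene body).
    """

    control: dict[str, pd.DataFrame]
    mutant: dict[str, pd.DataFrame]
    gene_universe: list | None = None

    def __post_init__(self) -> None:
        if len(self.control) < 2 or len(self.mutant) < 2:
            raise ValidationError("need >= 2 conditions per genotype")
        if set(self.control) != set(self.mutant):
            raise ValidationError("condition labels differ between genotypes")
        idx = None
        for mats in (self.control, self.mutant):
            for df in mats.values():
                if idx is None:
                    idx = df.index
                elif not idx.equals(df.index):
                    raise ValidationError("gene ids differ across matrices")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.control)

    def restricted(self, genotype: str, condition: str) -> pd.DataFrame:
        df = (self.control if genotype == "CTR" else self.mutant)[condition]
        if self.gene_universe is not None:
            df = df.loc[df.index.intersection(pd.Index(self.gene_universe))]
        return df

    def swapped(self) -> "PerturbationExperiment":
        """Relabel genotypes (mutant becomes control and vice versa)."""
        return PerturbationExperiment(
            control=self.mutant, mutant=self.control, gene_universe=self.gene_universe
        )


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_map: dict[str, list[str]]
) -> pd.DataFrame:
    """Collapse a probe x sample matrix to genes.

    Probes mapping to multiple genes are discarded; multiple probes for the
    same gene are averaged.  Drop/merge counts land in ``result.attrs``.
    """
    if probe_matrix.index.has_duplicates:
        raise ValidationError("duplicate probe ids")
    keep_rows = []
    gene_of = {}
    n_multi = 0
    for probe in probe_matrix.index:
        genes = probe_map.get(probe, [])
        if len(genes) == 1:
            keep_rows.append(probe)
            gene_of[probe] = genes[0]
        elif len(genes) > 1:
            n_multi += 1
    sub = probe_matrix.loc[keep_rows]
    grouped = sub.groupby([gene_of[p] for p in sub.index]).mean()
    grouped.index.name = "gene_id"
    grouped.attrs["n_multi_gene_probes_dropped"] = n_multi
    grouped.attrs["n_probes_averaged"] = int(len(sub) - len(grouped))
    return grouped


def _de_test(
    a: pd.DataFrame, b: pd.DataFrame, moderated: bool, prior_df: float = 4.0
) -> pd.DataFrame:
    """Per-gene two-sample t between two replicate matrices.

    ``moderated=True`` shrinks per-gene variances toward the mean variance
    (empirical-Bayes pooling with ``prior_df`` prior degrees of freedom), a
    simplified moderated t for small replicate numbers.
    """
    x, y = a.to_numpy(float), b.to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            "t-test needs >= 2 replicates per condition; consider fold-change-only mode"
        )
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if moderated:
        s0 = float(np.mean(pooled))
        pooled = (prior_df * s0 + df * pooled) / (prior_df + df)
        df = df + prior_df
    se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2 * stats.t.sf(np.abs(t), df)
    # degenerate zero-variance genes: any nonzero difference is unambiguous
    p = np.where(np.isfinite(t), p, np.where(diff != 0, 0.0, 1.0))
    return pd.DataFrame({"log2fc": diff, "t": t, "p": p}, index=a.index)


def eligibility_check(
    exp: PerturbationExperiment,
    de_alpha: float = 0.01,
    share_threshold: float = 0.6,
    conditions: tuple[str, str] | None = None,
    moderated: bool = False,
) -> dict:
    """Is the perturbation mild enough for magnitude comparisons?

    Differential expression between the two conditions is called per
    genotype (two-sample t, BH q < ``de_alpha``); the dataset is eligible
    when the fraction of union DE genes that are DE with the same sign in
    both genotypes exceeds ``share_threshold``.
    """
    c1, c2 = conditions or tuple(exp.conditions[:2])
    frames = {}
    for genotype in ("CTR", "MUT"):
        de = _de_test(
            exp.restricted(genotype, c1), exp.restricted(genotype, c2), moderated
        )
        de["q"] = bh_adjust(de["p"])
        de["is_de"] = de["q"] < de_alpha
        frames[genotype] = de
    de_ctr = set(frames["CTR"].index[frames["CTR"]["is_de"]])
    de_mut = set(frames["MUT"].index[frames["MUT"]["is_de"]])
    union = de_ctr | de_mut
    shared = {
        g
        for g in de_ctr & de_mut
        if np.sign(frames["CTR"].loc[g, "log2fc"])
        == np.sign(frames["MUT"].loc[g, "log2fc"])
    }
    fraction = len(shared) / len(union) if union else np.nan
    return {
        "n_de_ctr": len(de_ctr),
        "n_de_mut": len(de_mut),
        "n_union": len(union),
        "n_shared": len(shared),
        "shared_fraction": fraction,
        "eligible": bool(union) and fraction > share_threshold,
        "conditions": (c1, c2),
    }


@dataclass
class ValidationResult:
    """Magnitude-of-change comparison between control and mutant."""

    magnitudes_ctr: pd.Series
    magnitudes_mut: pd.Series
    unpaired_p: float
    median_ctr: float
    median_mut: float
    n_paired: int
    paired_p: float | None
    n_lower: int
    n_higher: int
    ratio_lower_higher: float
    fisher_p: float | None
    binomial_p: float | None
    verdict: bool


def magnitude_validation(
    exp: PerturbationExperiment,
    top_fraction: float = 0.2,
    expected_direction: str = "decrease",
    conditions: tuple[str, str] | None = None,
    alpha: float = 0.001,
) -> ValidationResult:
    """Compare expression-change magnitudes between genotypes.

    Per genotype the change magnitude is |mean log2 expression difference|
    between the two conditions; the top ``top_fraction`` of genes by
    magnitude (ties broken by gene id) forms each genotype's top-dynamic
    set.  The unpaired comparison is a Mann-Whitney between the two top
    sets' magnitudes.  The paired analysis uses genes in both top sets that
    change co-directionally in both genotypes: a Wilcoxon signed-rank test
    on the magnitude pairs, the count of genes with lower vs higher
    magnitude in the mutant, a Fisher exact test of that split against an
    equal split, and an exact binomial alternative.  The verdict requires
    the median shift to match ``expected_direction`` with Fisher
    p < ``alpha``.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if expected_direction not in ("decrease", "increase"):
        raise ValueError("expected_direction must be 'decrease' or 'increase'")
    c1, c2 = conditions or tuple(exp.conditions[:2])
    fc = {}
    for genotype in ("CTR", "MUT"):
        a = exp.restricted(genotype, c1).mean(axis=1)
        b = exp.restricted(genotype, c2).mean(axis=1)
        fc[genotype] = b - a
    mags = {g: fc[g].abs() for g in fc}
    k = max(1, int(round(top_fraction * len(mags["CTR"]))))
    tops = {}
    for genotype, m in mags.items():
        order = m.sort_values(ascending=False, kind="mergesort")
        # deterministic tie-break: stable sort, then gene id among equals
        cutoff = order.iloc[k - 1]
        certain = order[order > cutoff].index.tolist()
        tied = sorted(order[order == cutoff].index)
        tops[genotype] = pd.Index(certain + tied[: k - len(certain)])

    x = mags["CTR"].loc[tops["CTR"]].to_numpy()
    y = mags["MUT"].loc[tops["MUT"]].to_numpy()
    unpaired_p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    co = tops["CTR"].intersection(tops["MUT"])
    co = pd.Index(
        [g for g in co if np.sign(fc["CTR"][g]) == np.sign(fc["MUT"][g]) != 0]
    )
    if len(co):
        diffs = (mags["MUT"].loc[co] - mags["CTR"].loc[co]).to_numpy()
        nonzero = diffs[diffs != 0]
        paired_p = (
            float(stats.wilcoxon(nonzero).pvalue) if len(nonzero) else None
        )
        n_lower = int((diffs < 0).sum())
        n_higher = int((diffs > 0).sum())
        n = n_lower + n_higher
        if n:
            fisher_p = float(
                stats.fisher_exact(
                    [[n_lower, n_higher], [math.ceil(n / 2), n // 2]]
                )[1]
            )
            binomial_p = float(stats.binomtest(n_lower, n, 0.5).pvalue)
            ratio = n_lower / n_higher if n_higher else np.inf
        else:
            fisher_p = binomial_p = None
            ratio = np.nan
    else:
        paired_p = fisher_p = binomial_p = None
        n_lower = n_higher = 0
        ratio = np.nan

    median_ctr, median_mut = float(np.median(x)), float(np.median(y))
    shift_matches = (
        median_mut < median_ctr
        if expected_direction == "decrease"
        else median_mut > median_ctr
    )
    verdict = bool(shift_matches and fisher_p is not None and fisher_p < alpha)
    return ValidationResult(
        magnitudes_ctr=mags["CTR"].loc[tops["CTR"]],
        magnitudes_mut=mags["MUT"].loc[tops["MUT"]],
        unpaired_p=unpaired_p,
        median_ctr=median_ctr,
        median_mut=median_mut,
        n_paired=int(len(co)),
        paired_p=paired_p,
        n_lower=n_lower,
        n_higher=n_higher,
        ratio_lower_higher=float(ratio),
        fisher_p=fisher_p,
        binomial_p=binomial_p,
        verdict=verdict,
    )
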