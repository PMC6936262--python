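"""Peak-to-gene assignment and the trans-factor / histone-mark screens.

ChIP-seq peaks are intersected with strand-aware promoter windows (default
-500..+500 around the TSS) or with gene bodies via interval trees.  A factor
or mark is called plasticity-associated only when the bound-vs-unbound GEP
difference is Benjamini-Hochberg significant with the majority direction in
at least 80% of at least four independent samples — the consistency screen.
The loop-anchor analysis asks whether CTCF/cohesin effects track chromatin
topology, and the mark-combination test asks whether multiple gene-body
marks restrict plasticity beyond a single one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._stats import bh_adjust, mwu_with_direction
from .types import BindingProfile, GeneAnnotation, GenomicInterval, ValidationError

__all__ = [
    "assign_peaks",
    "consistency_screen",
    "loop_anchor_analysis",
    "mark_combination_test",
    "ScreenResult",
]


def _region(gene: GeneAnnotation, region_kind: str, promoter_window) -> tuple[int, int]:
    if region_kind == "promoter":
        return gene.promoter(promoter_window)
    if region_kind == "gene_body":
        return gene.body
    raise ValueError(f"unknown region_kind {region_kind!r}")


def assign_peaks(
    peaks: list[GenomicInterval],
    annotation: list[GeneAnnotation],
    region_kind: str = "promoter",
    promoter_window: tuple[int, int] = (-500, 500),
    factor: str = "factor",
    sample_id: str = "sample",
) -> BindingProfile:
    """Genes whose region overlaps at least one peak by >= 1 bp.

    Promoter windows are strand-aware (upstream means 5' of the TSS in the
    direction of transcription); gene bodies span TSS to TES.  Lookup uses a
    per-chromosome interval tree and is equivalent to a brute-force overlap
    scan.
    """
    if not annotation:
        raise ValidationError("empty gene annotation")
    trees: dict[str, IntervalTree] = {}
    for pk in peaks:
        trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end)
    bound = set()
    for gene in annotation:
        start, end = _region(gene, region_kind, promoter_window)
        tree = trees.get(gene.chrom)
        if tree is not None and tree.overlap(start, end):
            bound.add(gene.gene_id)
    return BindingProfile(factor, sample_id, frozenset(bound), region_kind)


@dataclass
class ScreenResult:
    """Per-factor verdict of the multi-sample consistency screen."""

    factor: str
    n_samples: int
    n_supporting: int
    direction: str  # promoting | repressing | none
    verdict: bool
    per_sample: pd.DataFrame = field(default_factory=pd.DataFrame)


def consistency_screen(
    profiles: list[BindingProfile],
    gep: pd.DataFrame,
    alpha: float = 0.01,
    consistency: float = 0.8,
    min_samples: int = 4,
    min_group: int = 20,
) -> dict[str, ScreenResult]:
    """Screen factors for a consistent association between binding and GEP.

    Per factor x sample: two-sided Mann-Whitney of GEP for bound vs unbound
    genes and the direction of the median difference.  Benjamini-Hochberg
    runs across all factor x sample tests in the screen.  A sample supports
    its factor when it is BH-significant (q < alpha) with the factor's
    majority direction; the verdict is true iff the factor was assayed in at
    least ``min_samples`` samples and the supporting fraction reaches
    ``consistency``.
    """
    rows = []
    gep_vals = gep["gep"]
    for prof in profiles:
        bound_mask = gep_vals.index.isin(prof.bound_genes)
        x = gep_vals[bound_mask].to_numpy()
        y = gep_vals[~bound_mask].to_numpy()
        if len(x) < min_group or len(y) < min_group:
            warnings.warn(
                f"{prof.factor}/{prof.sample_id}: bound or unbound group below "
                f"{min_group}; sample untested"
            )
            continue
        _, p, direction = mwu_with_direction(x, y)
        rows.append(
            {
                "factor": prof.factor,
                "sample_id": prof.sample_id,
                "p": p,
                "direction": direction,
                "median_bound": float(np.median(x)),
                "median_unbound": float(np.median(y)),
                "n_bound": len(x),
                "n_unbound": len(y),
            }
        )
    if not rows:
        return {}
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])

    results: dict[str, ScreenResult] = {}
    for factor, sub in table.groupby("factor"):
        n_samples = len(sub)
        pos = int((sub["direction"] > 0).sum())
        neg = int((sub["direction"] < 0).sum())
        majority = 1 if pos > neg else (-1 if neg > pos else 0)
        supporting = int(((sub["q"] < alpha) & (sub["direction"] == majority)).sum())
        verdict = (
            majority != 0
            and n_samples >= min_samples
            and supporting / n_samples >= consistency
        )
        direction = (
            "none"
            if majority == 0 or not verdict
            else ("promoting" if majority > 0 else "repressing")
        )
        results[factor] = ScreenResult(
            factor=factor,
            n_samples=n_samples,
            n_supporting=supporting,
            direction=direction,
            verdict=bool(verdict),
            per_sample=sub.reset_index(drop=True),
        )
    return results


def loop_anchor_analysis(
    gep: pd.DataFrame,
    annotation: list[GeneAnnotation],
    loops: list[tuple[GenomicInterval, GenomicInterval]],
    factor_peaks: list[GenomicInterval],
    promoter_window: tuple[int, int] = (-500, 500),
    test: str = "mwu",
) -> dict:
    """Does the factor's plasticity association track chromatin topology?

    Classifies each gene's promoter as anchor (overlapping a loop anchor),
    loop-interior (inside the span between paired anchors but not an
    anchor), or outside; compares GEP anchor vs loop-interior; then restricts
    the factor's peaks to those outside loop spans and re-runs the
    bound-vs-unbound GEP comparison.  ``test`` selects 'mwu' (unpaired,
    default) or 'signed_rank' (pairs anchor/loop genes by rank order) for
    the anchor-vs-loop comparison.
    """
    if not loops:
        raise ValidationError("no chromatin loops provided")
    anchor_trees: dict[str, IntervalTree] = {}
    span_trees: dict[str, IntervalTree] = {}
    for a1, a2 in loops:
        for a in (a1, a2):
            anchor_trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end)
        if a1.chrom == a2.chrom:
            lo = min(a1.start, a2.start)
            hi = max(a1.end, a2.end)
            span_trees.setdefault(a1.chrom, IntervalTree()).addi(lo, hi)

    label: dict[str, str] = {}
    for gene in annotation:
        start, end = gene.promoter(promoter_window)
        at = anchor_trees.get(gene.chrom)
        st = span_trees.get(gene.chrom)
        if at is not None and at.overlap(start, end):
            label[gene.gene_id] = "anchor"
        elif st is not None and st.overlap(start, end):
            label[gene.gene_id] = "loop"
        else:
            label[gene.gene_id] = "outside"
    labels = pd.Series(label).reindex(gep.index)

    anchor_vals = gep.loc[labels == "anchor", "gep"].to_numpy()
    loop_vals = gep.loc[labels == "loop", "gep"].to_numpy()
    if len(anchor_vals) and len(loop_vals):
        if test == "signed_rank":
            k = min(len(anchor_vals), len(loop_vals))
            a = np.sort(anchor_vals)[:k]
            b = np.sort(loop_vals)[:k]
            anchor_p = float(stats.wilcoxon(a, b).pvalue) if k >= 5 else np.nan
        else:
            anchor_p = float(
                stats.mannwhitneyu(anchor_vals, loop_vals, alternative="two-sided").pvalue
            )
    else:
        anchor_p = np.nan

    outside_peaks = []
    for pk in factor_peaks:
        st = span_trees.get(pk.chrom)
        if st is None or not st.overlap(pk.start, pk.end):
            outside_peaks.append(pk)
    profile = assign_peaks(
        outside_peaks, annotation, "promoter", promoter_window, "factor", "outside"
    )
    bound_mask = gep.index.isin(profile.bound_genes)
    x = gep.loc[bound_mask, "gep"].to_numpy()
    y = gep.loc[~bound_mask, "gep"].to_numpy()
    if len(x) >= 2 and len(y) >= 2:
        _, outside_p, outside_dir = mwu_with_direction(x, y)
    else:
        outside_p, outside_dir = np.nan, 0
    return {
        "labels": labels,
        "n_anchor": int(len(anchor_vals)),
        "n_loop": int(len(loop_vals)),
        "anchor_vs_loop_p": anchor_p,
        "anchor_median": float(np.median(anchor_vals)) if len(anchor_vals) else np.nan,
        "loop_median": float(np.median(loop_vals)) if len(loop_vals) else np.nan,
        "n_outside_peaks": len(outside_peaks),
        "outside_binding_p": outside_p,
        "outside_binding_direction": outside_dir,
    }


def mark_combination_test(
    profiles: list[BindingProfile],
    gep: pd.DataFrame,
    max_count: int = 3,
) -> pd.DataFrame:
    """Do co-occurring gene-body marks restrict plasticity further?

    Genes carrying at least one mark are stratified by the number of
    distinct marks (1, 2, ..., ``max_count``+ pooled); all pairwise strata
    are compared by Mann-Whitney with Benjamini-Hochberg correction.  A
    single usable stratum yields an 'undetermined' report (empty test
    table).
    """
    marks = sorted({p.factor for p in profiles})
    if len(marks) < 2:
        raise ValidationError("need >= 2 marks")
    per_mark: dict[str, set] = {m: set() for m in marks}
    for prof in profiles:
        per_mark[prof.factor] |= set(prof.bound_genes)
    counts = pd.Series(0, index=gep.index, dtype=int)
    for genes in per_mark.values():
        counts[counts.index.isin(genes)] += 1
    counts = counts.clip(upper=max_count)
    marked = counts[counts >= 1]
    if marked.empty:
        raise ValidationError("no gene carries any mark")
    strata = {
        int(level): gep.loc[marked.index[marked == level], "gep"].to_numpy()
        for level in sorted(marked.unique())
    }
    rows = []
    levels = sorted(strata)
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if len(strata[a]) < 2 or len(strata[b]) < 2:
                continue
            _, p, direction = mwu_with_direction(strata[b], strata[a])
            rows.append(
                {
                    "strata": f"{a}_vs_{b}",
                    "n_lo": len(strata[a]),
                    "n_hi": len(strata[b]),
                    "median_lo": float(np.median(strata[a])),
                    "median_hi": float(np.median(strata[b])),
                    "direction": direction,
                    "p": p,
                }
            )
    out = pd.DataFrame(
        rows, columns=["strata", "n_lo", "n_hi", "median_lo", "median_hi", "direction", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
        out.attrs["undetermined"] = True
    return out
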