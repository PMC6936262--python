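"""Profiling plasticity against conservation, function and disease burden.

These analyses treat the GEP table as the response: Mann-Whitney tests of
curated gene sets against the rest of the genome, Spearman correlation of
plasticity between one-to-one orthologues, mean plasticity per ontology term
after recursive annotation propagation, disease-burden binning along the
GEP ranking, and a hypergeometric over-representation test for functional
gene-set collections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, mwu_with_direction
from .types import ValidationError

__all__ = [
    "gene_set_gep_test",
    "orthologue_correlation",
    "term_gep_profile",
    "term_gep_correlation",
    "disease_burden_bins",
    "hypergeometric_enrichment",
    "high_gep_set",
]


def gene_set_gep_test(
    gep: pd.DataFrame, gene_set, alternative: str = "two-sided"
) -> dict:
    """Mann-Whitney U of GEP inside a curated gene set vs all other genes."""
    in_set = gep.index.intersection(pd.Index(gene_set))
    out_set = gep.index.difference(in_set)
    if len(in_set) == 0:
        raise ValidationError("gene set shares no genes with the GEP table")
    if len(out_set) == 0:
        raise ValidationError("gene set covers every scored gene")
    x = gep.loc[in_set, "gep"].to_numpy()
    y = gep.loc[out_set, "gep"].to_numpy()
    u, p, direction = mwu_with_direction(x, y, alternative=alternative)
    return {
        "U": u,
        "p": p,
        "direction": direction,
        "median_set": float(np.median(x)),
        "median_rest": float(np.median(y)),
        "n_set": int(len(in_set)),
        "n_rest": int(len(out_set)),
    }


def orthologue_correlation(
    gep_a: pd.DataFrame, gep_b: pd.DataFrame, pairs: pd.DataFrame
) -> dict:
    """Spearman correlation of plasticity across one-to-one orthologues.

    ``pairs`` has columns ``a`` and ``b`` (ids in the two species' GEP
    tables), already restricted to one-to-one pairs by the reader.
    """
    mask = pairs["a"].isin(gep_a.index) & pairs["b"].isin(gep_b.index)
    sub = pairs[mask]
    if len(sub) < 3:
        raise ValidationError("fewer than 3 orthologue pairs with defined GEP")
    rho, p = stats.spearmanr(
        gep_a.loc[sub["a"], "gep"].to_numpy(),
        gep_b.loc[sub["b"], "gep"].to_numpy(),
    )
    return {"rho": float(rho), "p": float(p), "n": int(len(sub))}


def term_gep_profile(
    gep: pd.DataFrame,
    ontology,
    annotations: dict[str, list[str]],
    size_range: tuple[int, int] = (20, 500),
) -> pd.DataFrame:
    """Mean plasticity per ontology term after recursive propagation.

    Gene annotations are propagated from each annotated term to all of its
    ancestors (edges point child -> parent), so a gene annotated to a leaf
    counts in every parent up to the root.  Terms whose propagated gene
    count falls outside ``size_range`` are dropped.
    """
    import networkx as nx

    if not nx.is_directed_acyclic_graph(ontology):
        raise ValidationError("ontology contains a cycle")
    ancestors_cache: dict[str, set] = {}

    def up(term: str) -> set:
        if term not in ancestors_cache:
            ancestors_cache[term] = {term} | nx.descendants(ontology, term)
        return ancestors_cache[term]

    members: dict[str, set] = {}
    for gene, terms in annotations.items():
        if gene not in gep.index:
            continue
        for term in terms:
            if term not in ontology:
                continue
            for anc in up(term):
                members.setdefault(anc, set()).add(gene)

    lo, hi = size_range
    rows = []
    for term, genes in members.items():
        if not lo <= len(genes) <= hi:
            continue
        rows.append(
            {
                "term_id": term,
                "n_genes": len(genes),
                "gep_go": float(gep.loc[sorted(genes), "gep"].mean()),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "n_genes", "gep_go"])
    return out.set_index("term_id").sort_index()


def term_gep_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Spearman correlation of per-term GEP between two species.

    Joins two ``term_gep_profile`` outputs on term id; only terms retained
    in both species contribute.
    """
    common = table_a.index.intersection(table_b.index)
    if len(common) < 3:
        raise ValidationError("fewer than 3 shared ontology terms")
    rho, p = stats.spearmanr(
        table_a.loc[common, "gep_go"], table_b.loc[common, "gep_go"]
    )
    return {"rho": float(rho), "p": float(p), "n": int(len(common))}


def disease_burden_bins(
    gep: pd.DataFrame, burden: pd.Series, bin_size: int = 100
) -> tuple[pd.DataFrame, dict]:
    """Disease burden along the plasticity ranking.

    Genes are sorted by GEP ascending and cut into consecutive bins of
    ``bin_size`` (a final partial bin is kept and flagged).  The per-bin
    statistic is the mean burden — a disease count per gene, or a 0/1 flag
    whose mean is the fraction of flagged genes.  The trend is the Spearman
    correlation of bin index vs statistic.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    common = gep.index.intersection(burden.index)
    ranked = gep.loc[common].sort_values("gep", kind="mergesort")
    values = burden.loc[ranked.index].to_numpy(float)
    n = len(values)
    if n < 2 * bin_size:
        raise ValidationError("need at least two bins of genes")
    rows = []
    for i, start in enumerate(range(0, n, bin_size)):
        chunk = values[start : start + bin_size]
        rows.append(
            {
                "bin_index": i,
                "bin_size": len(chunk),
                "statistic": float(chunk.mean()),
                "partial": len(chunk) < bin_size,
            }
        )
    profile = pd.DataFrame(rows)
    rho, p = stats.spearmanr(profile["bin_index"], profile["statistic"])
    return profile, {"rho": float(rho), "p": float(p), "n_bins": len(profile)}


def hypergeometric_enrichment(
    foreground,
    background,
    collections: dict[str, list[str]],
) -> pd.DataFrame:
    """Over-representation of named gene sets in a foreground gene list.

    Per set: ``fold = (k/n) / (K/N)`` and an upper-tail hypergeometric p,
    where N = background size, K = set size within background, n =
    foreground size, k = overlap; q-values are Benjamini-Hochberg across
    the sets tested.
    """
    bg = set(background)
    fg = set(foreground)
    if not fg <= bg:
        raise ValidationError("foreground must be a subset of background")
    big_n, small_n = len(bg), len(fg)
    rows = []
    for name, genes in collections.items():
        big_k = len(bg & set(genes))
        k = len(fg & set(genes))
        if big_k == 0:
            fold, p = np.nan, np.nan
        else:
            fold = (k / small_n) / (big_k / big_n) if small_n else np.nan
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, small_n))
        rows.append({"set": name, "K": big_k, "k": k, "fold": fold, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"])
    return out


def high_gep_set(gep: pd.DataFrame, top_fraction: float = 0.10) -> pd.Index:
    """Genes in the top ``top_fraction`` of the plasticity ranking."""
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    k = max(1, int(round(top_fraction * len(gep))))
    return gep.sort_values("gep", ascending=False).index[:k]
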