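"""Promoter motif analysis: PWM scanning and the motif-centric statistics.

The scanner assigns each promoter position a log-odds score
``sum_i log2(p_i,base / bg_base)`` and calls a hit when the exact background
tail probability of that score (computed by dynamic programming over the
quantized score distribution, the FIMO-style criterion) falls below
``match_p`` on either strand.  Downstream, motif presence/absence is tested
against plasticity (Mann-Whitney + Benjamini-Hochberg), significant motifs
are collapsed into classes via cluster tables, and class effects are
dissected by stepwise AIC selection, cumulative-count trends, co-occurrence
enrichment, and pairwise interaction typing
(additivity / enhancement / dominance).

The interaction decision rules are a documented reconstruction: effects are
median-based and the expected-additive comparison is a location-shift
Mann-Whitney test (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, mwu_with_direction
from .types import Pwm, ValidationError

__all__ = [
    "scan_pwm",
    "pwm_hit_threshold",
    "association_screen",
    "collapse_classes",
    "stepwise_aic",
    "cumulative_effects",
    "cooccurrence_optimization",
    "classify_interaction",
    "MotifClass",
    "InteractionCall",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PROB_FLOOR = 1e-4  # floor for zero PWM entries before log-odds
_QUANT = 1000.0  # score quantization (1/1000 bit) for the exact DP null


# ---------------------------------------------------------------------------
# PWM scanning


def _log_odds(pwm: Pwm) -> np.ndarray:
    probs = np.maximum(pwm.matrix, _PROB_FLOOR)
    bg = np.maximum(pwm.background, _PROB_FLOOR)
    return np.log2(probs / bg[None, :])


def pwm_hit_threshold(pwm: Pwm, match_p: float) -> float:
    """Smallest score whose exact background tail probability is < match_p.

    The null distribution of the log-odds score of a random background
    k-mer is computed exactly by dynamic programming after quantizing
    per-position scores to 1/1000 bit.  Returns the threshold on the
    quantized scale (in bits).
    """
    if not 0.0 < match_p < 1.0:
        raise ValueError("match_p must be in (0, 1)")
    lom = np.round(_log_odds(pwm) * _QUANT).astype(np.int64)
    bg = np.maximum(pwm.background, _PROB_FLOOR)
    bg = bg / bg.sum()
    # exact pmf over achievable integer scores, starting from a point mass at 0
    cur = {0: 1.0}
    for i in range(pwm.width):
        nxt: dict[int, float] = {}
        for s, prob in cur.items():
            for b in range(4):
                key = s + int(lom[i, b])
                nxt[key] = nxt.get(key, 0.0) + prob * bg[b]
        cur = nxt
    scores = np.array(sorted(cur), dtype=np.int64)
    probs = np.array([cur[s] for s in scores])
    tail = np.cumsum(probs[::-1])[::-1]
    below = tail < match_p
    if not below.any():
        return np.inf  # no achievable score is that improbable
    return float(scores[below.argmax()]) / _QUANT


def _window_scores(seq_idx: np.ndarray, lom_int: np.ndarray) -> np.ndarray:
    """Quantized log-odds score of every motif placement in an index array."""
    w = lom_int.shape[0]
    n = len(seq_idx) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, w)
    return lom_int[np.arange(w)[None, :], windows].sum(axis=1)


def scan_pwm(
    promoters: dict[str, str],
    pwms: list[Pwm],
    window: tuple[int, int] = (-200, 100),
    match_p: float = 1e-4,
    offsets: dict[str, int] | None = None,
    max_n_fraction: float = 0.1,
) -> pd.DataFrame:
    """Scan promoter sequences for motif occurrences.

    ``promoters`` maps gene id to sequence given 5'->3' in the direction of
    transcription; ``offsets`` gives the position of each sequence's first
    base relative to the TSS (default: the sequence is assumed to start at
    ``window[0]``).  A gene gets presence 1 for a motif when at least one
    placement within the window, on either strand, scores above the exact
    background threshold for ``match_p``.  Windows extending beyond a
    sequence are clamped with a warning; genes with too many non-ACGT bases
    are skipped.

    Returns a binary gene x motif DataFrame; the scan window is stored in
    ``result.attrs["window"]``.
    """
    a, b = window
    if not a < b:
        raise ValueError("window start must be below window end")
    offsets = offsets or {}
    loms = {p.motif_id: np.round(_log_odds(p) * _QUANT).astype(np.int64) for p in pwms}
    loms_rc = {
        p.motif_id: np.round(_log_odds(p.reverse_complement()) * _QUANT).astype(
            np.int64
        )
        for p in pwms
    }
    thresholds = {}
    for p in pwms:
        thr = pwm_hit_threshold(p, match_p)
        thresholds[p.motif_id] = (
            np.int64(round(thr * _QUANT)) if np.isfinite(thr) else None
        )
    genes, rows = [], []
    clamped = 0
    for gene_id, seq in promoters.items():
        off = offsets.get(gene_id, a)
        start = a - off
        end = b - off
        if start < 0 or end > len(seq):
            clamped += 1
        sub = seq[max(start, 0) : min(end, len(seq))].upper()
        idx = np.fromiter(
            (_BASE_INDEX.get(ch, -1) for ch in sub), dtype=np.int64, count=len(sub)
        )
        bad = idx < 0
        if len(idx) == 0 or bad.mean() > max_n_fraction:
            warnings.warn(f"gene {gene_id}: skipped (short or too many non-ACGT)")
            continue
        idx = idx.copy()
        # non-ACGT positions poison any window they fall in via a -inf proxy
        presence = []
        for pwm in pwms:
            thr = thresholds[pwm.motif_id]
            if thr is None:
                presence.append(0)
                continue
            hit = 0
            for lom_int in (loms[pwm.motif_id], loms_rc[pwm.motif_id]):
                if hit:
                    break
                w = lom_int.shape[0]
                if len(idx) < w:
                    continue
                safe = idx.copy()
                safe[bad] = 0
                scores = _window_scores(safe, lom_int)
                if bad.any():
                    poisoned = (
                        np.lib.stride_tricks.sliding_window_view(bad, w).any(axis=1)
                    )
                    scores = np.where(poisoned, np.iinfo(np.int64).min, scores)
                if (scores >= thr).any():
                    hit = 1
            presence.append(hit)
        genes.append(gene_id)
        rows.append(presence)
    if clamped:
        warnings.warn(f"{clamped} promoter(s) did not cover the full scan window")
    out = pd.DataFrame(
        rows, index=pd.Index(genes, name="gene_id"), columns=[p.motif_id for p in pwms]
    )
    out.attrs["window"] = window
    out.attrs["match_p"] = match_p
    return out


# ---------------------------------------------------------------------------
# association screen


def association_screen(
    occ: pd.DataFrame,
    response: pd.DataFrame | pd.Series,
    alpha: float = 0.01,
    min_group: int = 20,
    consistency: float = 0.8,
) -> pd.DataFrame:
    """Test every feature's presence against the response.

    Single-response mode (``response`` is a GEP table or Series): per
    feature a two-sided Mann-Whitney U between genes with and without the
    feature, direction by median difference, Benjamini-Hochberg across all
    tested features; significant iff q < alpha.

    Multi-sample mode (``response`` a gene x sample DataFrame without a
    'gep' column): the per-sample tests are combined with the consistency
    rule — significant iff BH-significant with the majority direction in at
    least ``consistency`` of the samples.

    Features with fewer than ``min_group`` genes on either side are marked
    untested (p = NaN).
    """
    if isinstance(response, pd.DataFrame) and "gep" in response.columns:
        response = response["gep"]
    if isinstance(response, pd.Series):
        common = occ.index.intersection(response.index)
        resp = response.loc[common].to_numpy(float)
        if np.nanstd(resp) == 0:
            raise ValidationError("constant response")
        occm = occ.loc[common]
        rows = []
        for feat in occm.columns:
            present = occm[feat].to_numpy() > 0
            n1, n0 = int(present.sum()), int((~present).sum())
            if n1 < min_group or n0 < min_group:
                rows.append((feat, n1, n0, np.nan, 0, False))
                continue
            _, p, direction = mwu_with_direction(resp[present], resp[~present])
            rows.append((feat, n1, n0, p, direction, True))
        out = pd.DataFrame(
            rows, columns=["feature", "n_with", "n_without", "p", "direction", "tested"]
        ).set_index("feature")
        out["q"] = bh_adjust(out["p"])
        out["significant"] = out["q"] < alpha
        out["direction_label"] = np.where(
            ~out["significant"],
            "none",
            np.where(out["direction"] > 0, "promoting", "repressing"),
        )
        return out
    # multi-sample responses: one test per feature x sample + consistency rule
    samples = list(response.columns)
    per_sample = {
        s: association_screen(
            occ, response[s], alpha=alpha, min_group=min_group
        )
        for s in samples
    }
    # re-do BH across the whole feature x sample family
    stacked = pd.concat(per_sample, names=["sample", "feature"])
    stacked["q"] = bh_adjust(stacked["p"])
    rows = []
    for feat in occ.columns:
        sub = stacked.xs(feat, level="feature")
        tested = sub[sub["tested"]]
        n_samples = len(tested)
        if n_samples == 0:
            rows.append((feat, 0, 0, "none", False))
            continue
        dirs = tested["direction"].to_numpy()
        majority = 1 if (dirs > 0).sum() > (dirs < 0).sum() else (
            -1 if (dirs < 0).sum() > (dirs > 0).sum() else 0
        )
        supporting = int(
            ((tested["q"] < alpha) & (tested["direction"] == majority)).sum()
        )
        verdict = majority != 0 and supporting / n_samples >= consistency
        label = (
            "none"
            if not verdict
            else ("promoting" if majority > 0 else "repressing")
        )
        rows.append((feat, n_samples, supporting, label, verdict))
    return pd.DataFrame(
        rows, columns=["feature", "n_samples", "n_supporting", "direction_label", "significant"]
    ).set_index("feature")


# ---------------------------------------------------------------------------
# class collapsing


@dataclass
class MotifClass:
    """A set of similar motifs merged across taxonomic-group clusters."""

    class_id: str
    member_motifs: frozenset
    directions: dict[str, str] = field(default_factory=dict)  # species -> label

    def direction(self) -> str:
        """Consensus direction across species: promoting/repressing/inconsistent."""
        labels = {d for d in self.directions.values() if d not in ("absent", "none")}
        if not labels:
            return "absent"
        if labels == {"promoting"}:
            return "promoting"
        if labels == {"repressing"}:
            return "repressing"
        return "inconsistent"


def collapse_classes(
    results: dict[str, pd.DataFrame],
    clusters: dict[tuple[str, str], list[str]],
) -> list[MotifClass]:
    """Collapse significant motifs into classes via cluster tables.

    ``results`` maps species -> association_screen output (single-response
    mode); ``clusters`` maps (taxonomic group, cluster id) -> motif ids.
    Significant motifs sharing a cluster are merged; clusters from different
    groups sharing a motif id merge transitively (union-find).  Unclustered
    significant motifs become singleton classes.  Per-species direction is
    the common sign of the members, else "inconsistent".
    """
    significant: dict[str, set] = {}
    for species, table in results.items():
        significant[species] = set(table.index[table["significant"]])
    all_sig = set().union(*significant.values()) if significant else set()

    parent: dict[str, str] = {m: m for m in all_sig}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((rx, ry))
            parent[hi] = lo

    for (_group, _cid), motifs in sorted(clusters.items()):
        sig_members = sorted(m for m in motifs if m in all_sig)
        for m1, m2 in zip(sig_members, sig_members[1:]):
            union(m1, m2)

    groups: dict[str, set] = {}
    for m in all_sig:
        groups.setdefault(find(m), set()).add(m)

    classes = []
    for i, root in enumerate(sorted(groups), 1):
        members = groups[root]
        directions = {}
        for species, table in results.items():
            labels = {
                table.loc[m, "direction_label"]
                for m in members
                if m in table.index and bool(table.loc[m, "significant"])
            }
            if not labels:
                directions[species] = "absent"
            elif len(labels) == 1:
                directions[species] = labels.pop()
            else:
                directions[species] = "inconsistent"
        classes.append(MotifClass(f"C{i}", frozenset(members), directions))
    return classes


def class_presence(occ: pd.DataFrame, classes: list[MotifClass]) -> pd.DataFrame:
    """Gene x class presence: OR over member motif columns."""
    cols = {}
    for cls in classes:
        members = [m for m in cls.member_motifs if m in occ.columns]
        if not members:
            continue
        cols[cls.class_id] = (occ[members].to_numpy() > 0).any(axis=1).astype(int)
    return pd.DataFrame(cols, index=occ.index)


# ---------------------------------------------------------------------------
# stepwise AIC


def _ols_aic(y: np.ndarray, x_cols: list[np.ndarray]) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n)] + x_cols)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    k = len(x_cols)
    return n * np.log(rss / n) + 2 * (k + 1)


def stepwise_aic(
    gep: pd.DataFrame, presence: pd.DataFrame
) -> tuple[list[str], pd.DataFrame]:
    """Bidirectional stepwise selection of motif classes by AIC.

    Fits the Gaussian linear model GEP ~ class indicators, starting from the
    full model, and at each iteration performs the single add-or-drop move
    that lowers ``AIC = n ln(RSS/n) + 2(k+1)`` the most, stopping when no
    move improves it.  Ties break deterministically by feature id.  Exactly
    duplicated indicator columns are dropped up front with a warning.

    Returns (retained feature ids, coefficient table for the final model).
    """
    common = gep.index.intersection(presence.index)
    y = gep.loc[common, "gep"].to_numpy(float)
    x = presence.loc[common].astype(float)
    if len(common) < x.shape[1] + 2:
        raise ValidationError("need n genes >= n classes + 2")
    # drop exact duplicate columns (collinear indicators)
    seen: dict[bytes, str] = {}
    keep = []
    for col in x.columns:
        key = x[col].to_numpy().tobytes()
        if key in seen:
            warnings.warn(f"dropping duplicate indicator {col!r} (== {seen[key]!r})")
            continue
        seen[key] = col
        keep.append(col)
    x = x[keep]
    features = sorted(x.columns)
    cols = {f: x[f].to_numpy() for f in features}

    included = list(features)
    current = _ols_aic(y, [cols[f] for f in included])
    while True:
        best_move, best_aic = None, current
        candidates = [("drop", f) for f in included] + [
            ("add", f) for f in features if f not in included
        ]
        for action, f in sorted(candidates):
            trial = (
                [g for g in included if g != f]
                if action == "drop"
                else included + [f]
            )
            aic = _ols_aic(y, [cols[g] for g in sorted(trial)])
            if aic < best_aic - 1e-10:
                best_move, best_aic = (action, f), aic
        if best_move is None:
            break
        action, f = best_move
        included = (
            [g for g in included if g != f] if action == "drop" else included + [f]
        )
        included = sorted(included)
        current = best_aic

    design = np.column_stack([np.ones(len(y))] + [cols[f] for f in included])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef = pd.DataFrame(
        {"coef": beta}, index=pd.Index(["intercept"] + included, name="feature")
    )
    coef.attrs["aic"] = current
    return included, coef


# ---------------------------------------------------------------------------
# cumulative effects


def cumulative_effects(
    gep: pd.DataFrame,
    presence: pd.DataFrame,
    classes: list[MotifClass],
    direction: str,
    max_count: int = 4,
) -> pd.DataFrame:
    """GEP as a function of how many same-direction motif classes co-occur.

    Genes are grouped by the number of classes of the requested direction
    present in their promoter (counts above ``max_count`` pooled); each
    adjacent pair of groups is compared by a one-sided Mann-Whitney test in
    the direction of the expected trend (a Jonckheere-style monotone check).
    """
    if direction not in ("promoting", "repressing"):
        raise ValueError("direction must be 'promoting' or 'repressing'")
    ids = [c.class_id for c in classes if c.direction() == direction]
    ids = [c for c in ids if c in presence.columns]
    if not ids:
        raise ValidationError(f"no classes with direction {direction!r}")
    common = gep.index.intersection(presence.index)
    counts = presence.loc[common, ids].sum(axis=1).clip(upper=max_count)
    gvals = gep.loc[common, "gep"]
    alt = "greater" if direction == "promoting" else "less"
    rows = []
    levels = sorted(counts.unique())
    for level in levels:
        grp = gvals[counts == level]
        rows.append(
            {"n_classes": int(level), "n_genes": len(grp), "median_gep": float(grp.median())}
        )
    out = pd.DataFrame(rows).set_index("n_classes")
    trend_p = []
    for lo, hi in zip(levels, levels[1:]):
        a = gvals[counts == hi].to_numpy()
        b = gvals[counts == lo].to_numpy()
        if len(a) == 0 or len(b) == 0:
            trend_p.append(np.nan)
            continue
        trend_p.append(float(stats.mannwhitneyu(a, b, alternative=alt).pvalue))
    out.attrs["adjacent_trend_p"] = trend_p
    return out


# ---------------------------------------------------------------------------
# co-occurrence


def cooccurrence_optimization(
    presence: pd.DataFrame,
    directions: dict[str, str],
    pair_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Is promoter architecture optimized in its motif pairings?

    Every unordered pair of directed classes gets a 2x2 Fisher exact test of
    co-occurrence over genes; a pair is enriched (odds ratio > 1) or
    depleted (< 1) at ``pair_alpha``.  Enriched:depleted counts are then
    compared between same-direction and opposite-direction pairs, and each
    against all pairs, by further Fisher tests.
    """
    ids = sorted(c for c in directions if c in presence.columns)
    if len(ids) < 2:
        raise ValidationError("need >= 2 directed classes")
    mat = presence[ids].to_numpy() > 0
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = mat[:, i], mat[:, j]
        table = [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
        odds, p = stats.fisher_exact(table)
        call = "neither"
        if p < pair_alpha:
            call = "enriched" if odds > 1 else "depleted"
        same = directions[ids[i]] == directions[ids[j]]
        rows.append(
            {
                "class_1": ids[i],
                "class_2": ids[j],
                "same_direction": same,
                "odds_ratio": float(odds),
                "p": float(p),
                "call": call,
            }
        )
    pairs = pd.DataFrame(rows)

    def counts(sub: pd.DataFrame) -> tuple[int, int]:
        return int((sub["call"] == "enriched").sum()), int(
            (sub["call"] == "depleted").sum()
        )

    e_same, d_same = counts(pairs[pairs["same_direction"]])
    e_opp, d_opp = counts(pairs[~pairs["same_direction"]])
    e_all, d_all = counts(pairs)
    report: dict = {
        "same": {"enriched": e_same, "depleted": d_same},
        "opposite": {"enriched": e_opp, "depleted": d_opp},
        "all": {"enriched": e_all, "depleted": d_all},
    }
    if (e_same + d_same) == 0 or (e_opp + d_opp) == 0:
        report["same_vs_opposite_p"] = None  # degenerate; undetermined
    else:
        report["same_vs_opposite_p"] = float(
            stats.fisher_exact([[e_same, d_same], [e_opp, d_opp]])[1]
        )
    for key, (e, d) in (("same", (e_same, d_same)), ("opposite", (e_opp, d_opp))):
        if (e + d) == 0 or (e_all + d_all) == 0:
            report[f"{key}_vs_all_p"] = None
        else:
            report[f"{key}_vs_all_p"] = float(
                stats.fisher_exact([[e, d], [e_all, d_all]])[1]
            )
    return pairs, report


# ---------------------------------------------------------------------------
# interaction classification


@dataclass
class InteractionCall:
    """Typed interaction between two motif classes on plasticity."""

    pair: tuple[str, str]
    call: str  # additive | enhancement | dominance_of_1 | dominance_of_2 |
    #           undetermined | skipped
    baseline: float | None = None
    effect_1: float | None = None
    effect_2: float | None = None
    median_both: float | None = None
    expected_both: float | None = None
    p_additive: float | None = None
    p_vs_only1: float | None = None
    p_vs_only2: float | None = None
    n_strata: dict = field(default_factory=dict)


def _interaction_contrast_p(strata: dict, rng, n_boot: int = 200) -> float:
    """Two-sided p for the median interaction contrast by studentized bootstrap.

    The contrast is ``median(both) - median(only1) - median(only2) +
    median(neither)``; its standard error is estimated by resampling each
    stratum independently.  This accounts for the sampling error of all four
    medians, which a naive location-shift comparison against the point
    estimate of e1 + e2 would ignore.
    """
    obs = (
        np.median(strata["both"])
        - np.median(strata["only_1"])
        - np.median(strata["only_2"])
        + np.median(strata["neither"])
    )
    boots = np.empty(n_boot)
    arrays = {k: np.asarray(v) for k, v in strata.items()}
    for b in range(n_boot):
        meds = {
            k: np.median(rng.choice(a, size=len(a), replace=True))
            for k, a in arrays.items()
        }
        boots[b] = meds["both"] - meds["only_1"] - meds["only_2"] + meds["neither"]
    se = boots.std(ddof=1)
    if se == 0:
        return 1.0 if obs == 0 else 0.0
    return float(2 * stats.norm.sf(abs(obs) / se))


def classify_interaction(
    gep: pd.DataFrame,
    presence: pd.DataFrame,
    pair: tuple[str, str],
    alpha: float = 0.05,
    min_group: int = 20,
    seed: int = 0,
) -> InteractionCall:
    """Type the joint effect of two motif classes on plasticity.

    Genes are stratified by presence of the two classes (neither, only-1,
    only-2, both).  With B the median GEP of the neither stratum and
    ``e_i = median(only-i) - B`` the single-motif effects, the expected
    both-motif location is ``B + e1 + e2``.  The additivity test asks
    whether the observed joint median departs from that expectation, using
    a studentized bootstrap of the interaction contrast (see
    ``_interaction_contrast_p``; ``seed`` fixes the resampling):

    * additive — the contrast is indistinguishable from zero (p >= alpha);
    * enhancement — same-direction pair, non-zero contrast, and the
      observed joint effect overshoots ``e1 + e2`` in the same direction;
    * dominance of i — opposite-direction pair whose both stratum matches
      the only-i stratum (Mann-Whitney p >= alpha) but not the only-j
      stratum (p < alpha);
    * otherwise undetermined.

    Strata below ``min_group`` genes yield a 'skipped' call.
    """
    c1, c2 = pair
    common = gep.index.intersection(presence.index)
    g = gep.loc[common, "gep"].to_numpy(float)
    p1 = presence.loc[common, c1].to_numpy() > 0
    p2 = presence.loc[common, c2].to_numpy() > 0
    strata = {
        "neither": g[~p1 & ~p2],
        "only_1": g[p1 & ~p2],
        "only_2": g[~p1 & p2],
        "both": g[p1 & p2],
    }
    n_strata = {k: int(len(v)) for k, v in strata.items()}
    if min(n_strata.values()) < min_group:
        return InteractionCall(pair=pair, call="skipped", n_strata=n_strata)

    baseline = float(np.median(strata["neither"]))
    e1 = float(np.median(strata["only_1"])) - baseline
    e2 = float(np.median(strata["only_2"])) - baseline
    expected = baseline + e1 + e2
    median_both = float(np.median(strata["both"]))

    p_additive = _interaction_contrast_p(strata, np.random.default_rng(seed))
    p_vs1 = float(
        stats.mannwhitneyu(strata["both"], strata["only_1"], alternative="two-sided").pvalue
    )
    p_vs2 = float(
        stats.mannwhitneyu(strata["both"], strata["only_2"], alternative="two-sided").pvalue
    )

    same_direction = e1 * e2 > 0
    call = "undetermined"
    if p_additive >= alpha:
        call = "additive"
    elif same_direction:
        joint = median_both - baseline
        if abs(joint) > abs(e1 + e2) and joint * (e1 + e2) > 0:
            call = "enhancement"
    else:
        if p_vs1 >= alpha and p_vs2 < alpha:
            call = "dominance_of_1"
        elif p_vs2 >= alpha and p_vs1 < alpha:
            call = "dominance_of_2"
    return InteractionCall(
        pair=pair,
        call=call,
        baseline=baseline,
        effect_1=e1,
        effect_2=e2,
        median_both=median_both,
        expected_both=expected,
        p_additive=p_additive,
        p_vs_only1=p_vs1,
        p_vs_only2=p_vs2,
        n_strata=n_strata,
    )
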