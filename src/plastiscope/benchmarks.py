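"""End-to-end recovery benchmarks on synthetic data.

Each function generates its own inputs with the package's synthetic-data
module (or plain seeded draws where the benchmark concerns a numeric
identity), runs the relevant pipeline stage, and measures a recovery or
error statistic.  These are the quantities the acceptance checks assert
and the acceptance script reports; sizes follow the standard study
conditions documented in docs/methods.md.
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .binding import assign_peaks, consistency_screen
from .gep import compute_gep, gep_null, stability_curve
from .motifs import association_screen, classify_interaction
from .perturbation import magnitude_validation
from .properties import hypergeometric_enrichment
from .simulate import (
    SyntheticTruth,
    simulate_binding,
    simulate_core,
    simulate_perturbation,
)
from .types import FoldChangeMatrix, GeneAnnotation, GenomicInterval

__all__ = [
    "gep_oracle_benchmark",
    "null_validity_benchmark",
    "stability_benchmark",
    "screen_type1_benchmark",
    "screen_power_benchmark",
    "interaction_recovery_benchmark",
    "consistency_recovery_benchmark",
    "perturbation_benchmark",
    "exact_test_benchmark",
    "peak_assignment_benchmark",
]


def _subseed(seed: int, offset: int) -> int:
    return (seed * 1_000_003 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# 1. score oracle


def gep_oracle_benchmark(seed: int, n_genes: int = 50, n_conditions: int = 20) -> dict:
    """Plasticity score vs an independent per-gene loop, plus the worked row."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0, 1.5, size=(n_genes, n_conditions))
    values[rng.random(values.shape) < 0.1] = np.nan
    values[:, 0] = rng.normal(size=n_genes)
    fc = FoldChangeMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)])
    )
    table = compute_gep(fc, min_conditions=1)
    max_err = 0.0
    for gene, row in fc.values.iterrows():
        obs = [v for v in row if not np.isnan(v)]
        expected = np.log2(sum(v * v for v in obs) / len(obs))
        max_err = max(max_err, abs(table.loc[gene, "gep"] - expected))
    worked = compute_gep(
        FoldChangeMatrix(
            pd.DataFrame([[1.0, -1.0, 2.0, 0.0]], index=["g"], columns=list("abcd"))
        ),
        min_conditions=1,
    ).loc["g", "gep"]
    return {"max_abs_error": float(max_err), "worked_gep": float(worked)}


# ---------------------------------------------------------------------------
# 2. randomized null


def null_validity_benchmark(
    seed: int, n_seeds: int = 100, n_genes: int = 100, n_conditions: int = 30
) -> dict:
    """Permutation-null behaviour under fully exchangeable rows.

    Checks that every shuffle preserves the per-condition value multiset
    exactly, and collects the two-sample KS p-value of observed vs null GEP
    per seed.  Because the null preserves the observed value multiset by
    construction, the KS test is conservative: the meaningful property is
    the absence of small p-values (the null is never spuriously rejected).
    """
    pvalues = []
    multiset_ok = True
    for i in range(n_seeds):
        rng = np.random.default_rng(_subseed(seed, i))
        fc = FoldChangeMatrix(
            pd.DataFrame(
                rng.normal(0, 1, size=(n_genes, n_conditions)),
                index=[f"g{j}" for j in range(n_genes)],
            )
        )
        obs = compute_gep(fc, min_conditions=1)["gep"].to_numpy()
        # reproduce the seeded shuffle independently to verify the multiset
        shuffle_seed = _subseed(seed, 10_000 + i)
        (null,) = gep_null(fc, 1, seed=shuffle_seed, min_conditions=1)
        check_rng = np.random.default_rng(shuffle_seed)
        vals = fc.values.to_numpy()
        for j in range(n_conditions):
            col = vals[check_rng.permutation(n_genes), j]
            if not np.array_equal(np.sort(col), np.sort(vals[:, j])):
                multiset_ok = False
        pvalues.append(stats.ks_2samp(obs, null["gep"].to_numpy()).pvalue)
    pvalues = np.asarray(pvalues)
    return {
        "multiset_preserved": bool(multiset_ok),
        "mean_ks_p": float(pvalues.mean()),
        "fraction_rejected_at_5pct": float((pvalues < 0.05).mean()),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 3. condition-count stability


def stability_benchmark(
    seed: int,
    n_runs: int = 100,
    n_genes: int = 200,
    n_conditions: int = 300,
    n_replicates: int = 20,
) -> dict:
    """Stability of the score as condition count grows (r at 10 vs 100 vs all)."""
    wins = 0
    r_full = []
    for i in range(n_runs):
        rng = np.random.default_rng(_subseed(seed, i))
        sigma = np.exp2(rng.normal(0, 0.5, n_genes))
        fc = FoldChangeMatrix(
            pd.DataFrame(
                rng.normal(0, 1, (n_genes, n_conditions)) * sigma[:, None],
                index=[f"g{j}" for j in range(n_genes)],
            )
        )
        curve = stability_curve(
            fc, [10, 100, n_conditions], n_replicates=n_replicates,
            seed=_subseed(seed, 5000 + i),
        )
        r10, r100, rfull = curve.mean_r
        wins += r100 > r10
        r_full.append(rfull)
    return {
        "fraction_r100_gt_r10": wins / n_runs,
        "mean_r_full": float(np.mean(r_full)),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# 4./5. motif screen calibration and power


def screen_type1_benchmark(
    seed: int,
    n_seeds: int = 100,
    n_genes: int = 1000,
    n_motifs: int = 50,
    n_conditions: int = 50,
) -> dict:
    """False-call rate of the association screen with zero planted effects."""
    fractions = []
    for i in range(n_seeds):
        truth = SyntheticTruth(
            motif_effects={f"M{m:02d}": 0.0 for m in range(n_motifs)},
            factor_shifts={},
            mark_shifts={},
            seed=_subseed(seed, i),
        )
        core = simulate_core(truth, n_genes=n_genes, n_conditions=n_conditions, sequences=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gep = compute_gep(core.fc, min_conditions=10)
        res = association_screen(core.presence, gep)
        tested = res[res["tested"]]
        fractions.append(float((tested["q"] < 0.01).mean()))
    return {"mean_significant_fraction": float(np.mean(fractions)), "n_seeds": n_seeds}


def screen_power_benchmark(
    seed: int,
    n_seeds: int = 100,
    n_genes: int = 5000,
    n_conditions: int = 50,
    shift: float = 0.5,
    rate: float = 0.3,
) -> dict:
    """Recovery of one motif shifting log2 sigma by ``shift`` in ``rate`` of genes."""
    hits = 0
    for i in range(n_seeds):
        effects = {"M00": shift, **{f"M{m:02d}": 0.0 for m in range(1, 10)}}
        truth = SyntheticTruth(
            motif_effects=effects,
            motif_rate=rate,
            factor_shifts={},
            mark_shifts={},
            seed=_subseed(seed, i),
        )
        core = simulate_core(truth, n_genes=n_genes, n_conditions=n_conditions, sequences=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gep = compute_gep(core.fc, min_conditions=10)
        res = association_screen(core.presence, gep)
        hits += bool(
            res.loc["M00", "q"] < 0.01
            and res.loc["M00", "direction_label"] == "promoting"
        )
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# 6. interaction recovery


def interaction_recovery_benchmark(
    seed: int,
    n_seeds: int = 50,
    n_genes: int = 2000,
    n_conditions: int = 100,
    delta: float = 0.5,
) -> dict:
    """Recovery of planted additive / enhancement / dominance motif pairs.

    Motif occupancy 0.5 per motif gives ~25% of genes in each of the four
    presence strata; ``delta`` = 0.5 on log2 sigma is ~1 SD on the score.
    """
    plans = {
        "additive": ({"A": delta, "B": delta}, {}),
        "enhancement": (
            {"A": delta, "B": delta},
            {("A", "B"): ("enhancement", 2.0)},
        ),
        "dominance_of_1": (
            {"A": delta, "B": -delta},
            {("A", "B"): ("dominance", "A")},
        ),
    }
    counts = {k: 0 for k in plans}
    for i in range(n_seeds):
        for label, (effects, inter) in plans.items():
            truth = SyntheticTruth(
                motif_effects=effects,
                motif_rate=0.5,
                interactions=inter,
                factor_shifts={},
                mark_shifts={},
                seed=_subseed(seed, 97 * i + hash(label) % 97),
            )
            core = simulate_core(truth, n_genes=n_genes, n_conditions=n_conditions, sequences=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gep = compute_gep(core.fc, min_conditions=10)
            call = classify_interaction(gep, core.presence, ("A", "B"))
            counts[label] += call.call == label
    return {
        **{f"recovery_{k}": v / n_seeds for k, v in counts.items()},
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 7. consistency-screen recovery


def consistency_recovery_benchmark(
    seed: int,
    n_seeds: int = 100,
    n_genes: int = 1000,
    n_conditions: int = 50,
    n_samples: int = 10,
    label_noise: float = 0.05,
) -> dict:
    """Planted factor (+0.5 SD target GEP shift) vs direction-randomized factor."""
    planted_pass = 0
    random_pass = 0
    for i in range(n_seeds):
        truth = SyntheticTruth(
            motif_effects={},
            factor_shifts={"TF": 0.25},  # ~0.5 SD on the score scale
            mark_shifts={},
            seed=_subseed(seed, i),
        )
        core = simulate_core(truth, n_genes=n_genes, n_conditions=n_conditions, sequences=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gep = compute_gep(core.fc, min_conditions=10)
        good, _ = simulate_binding(
            core, n_samples=n_samples, label_noise=label_noise,
            seed=_subseed(seed, 3000 + i),
        )
        noise, _ = simulate_binding(
            core, n_samples=n_samples, label_noise=0.5,
            seed=_subseed(seed, 6000 + i),
        )
        noise = [
            type(p)("RANDOM", p.sample_id, p.bound_genes, p.region_kind)
            for p in noise
        ]
        results = consistency_screen(good + noise, gep)
        planted_pass += results["TF"].verdict
        random_pass += results["RANDOM"].verdict if "RANDOM" in results else 0
    return {
        "planted_recovery_rate": planted_pass / n_seeds,
        "randomized_pass_rate": random_pass / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 8. perturbation validation


def perturbation_benchmark(
    seed: int, n_seeds: int = 60, n_genes: int = 2000
) -> dict:
    """Shrunk mutants detected, intact mutants not, label swap exact."""
    shrink_hits = 0
    null_ok = 0
    swap_exact = True
    ratios = []
    for i in range(n_seeds):
        exp = simulate_perturbation(
            n_genes=n_genes, seed=_subseed(seed, i), shrink=0.5
        )
        res = magnitude_validation(exp, expected_direction="decrease")
        ratios.append(res.ratio_lower_higher)
        shrink_hits += bool(
            res.ratio_lower_higher > 1 and res.fisher_p is not None
            and res.fisher_p < 0.001
        )
        null_exp = simulate_perturbation(
            n_genes=n_genes, seed=_subseed(seed, 7000 + i), shrink=1.0
        )
        null_res = magnitude_validation(null_exp, expected_direction="decrease")
        null_ok += bool(null_res.fisher_p is None or null_res.fisher_p >= 0.01)
        if i < 5:
            sw = magnitude_validation(
                exp.swapped(), expected_direction="increase"
            )
            if (sw.n_lower, sw.n_higher) != (res.n_higher, res.n_lower):
                swap_exact = False
    finite = [r for r in ratios if np.isfinite(r)]
    return {
        "shrink_detection_rate": shrink_hits / n_seeds,
        "null_nonsignificant_rate": null_ok / n_seeds,
        "swap_inverts_ratio": bool(swap_exact),
        "median_ratio_lower_higher": float(np.median(finite)) if finite else np.inf,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 9. exact-test fidelity


def exact_test_benchmark(seed: int) -> dict:
    """Small-sample agreement of the exact tests with direct enumeration."""
    out = {}
    # Mann-Whitney {3,4} vs {1,2}
    mwu_p = float(
        stats.mannwhitneyu([3, 4], [1, 2], alternative="two-sided", method="exact").pvalue
    )
    out["mwu_small_p"] = mwu_p
    out["mwu_matches"] = bool(abs(mwu_p - 1 / 3) < 1e-12)
    # Fisher on a perfectly concordant 10+10 table
    fisher_p = float(stats.fisher_exact([[10, 0], [0, 10]])[1])
    out["fisher_concordant_p"] = fisher_p
    out["fisher_matches"] = bool(abs(fisher_p - 2 / comb(20, 10)) < 1e-12)
    # hypergeometric enrichment vs combinatorial count (N=20, K=5, n=4, k=4)
    genes = [f"g{i}" for i in range(20)]
    table = hypergeometric_enrichment(genes[:4], genes, {"s": genes[:5]})
    out["hypergeom_p"] = float(table.loc["s", "p"])
    out["hypergeom_matches"] = bool(abs(table.loc["s", "p"] - 5 / 4845) < 1e-12)
    # signed-rank vs sign-flip enumeration at n <= 8
    rng = np.random.default_rng(seed)
    ok = True
    for n in (5, 6, 7, 8):
        diffs = rng.normal(0.4, 1, n)
        ranks = stats.rankdata(np.abs(diffs))
        stat_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
        count = sum(
            1
            for signs in itertools.product([1, -1], repeat=n)
            if min(
                ranks[np.array(signs) > 0].sum(), ranks[np.array(signs) < 0].sum()
            )
            <= stat_obs
        )
        expected = count / 2**n
        got = float(stats.wilcoxon(diffs, method="exact").pvalue)
        ok = ok and abs(got - expected) < 1e-12
    out["signed_rank_matches"] = bool(ok)
    out["all_match"] = bool(
        out["mwu_matches"]
        and out["fisher_matches"]
        and out["hypergeom_matches"]
        and out["signed_rank_matches"]
    )
    return out


# ---------------------------------------------------------------------------
# 10. peak assignment fidelity


def peak_assignment_benchmark(
    seed: int, n_peaks: int = 200, n_genes: int = 100
) -> dict:
    """Interval-tree assignment vs O(n*m) brute force, both region kinds."""
    rng = np.random.default_rng(seed)
    annotation = []
    for i in range(n_genes):
        left = int(rng.integers(10_000, 900_000))
        length = int(rng.integers(500, 5_000))
        if rng.random() < 0.5:
            annotation.append(GeneAnnotation(f"g{i}", "chr1", "+", left, left + length))
        else:
            annotation.append(GeneAnnotation(f"g{i}", "chr1", "-", left + length, left))
    peaks = []
    for _ in range(n_peaks):
        start = int(rng.integers(0, 999_000))
        peaks.append(GenomicInterval("chr1", start, start + int(rng.integers(1, 800))))
    # deliberate 1-bp-overlap edge cases at the first two promoters
    for gene in annotation[:2]:
        s, e = gene.promoter((-500, 500))
        peaks.append(GenomicInterval("chr1", max(0, s - 100), s + 1))
        peaks.append(GenomicInterval("chr1", e - 1, e + 100))
    mismatches = 0
    for kind in ("promoter", "gene_body"):
        tree_bound = assign_peaks(peaks, annotation, kind).bound_genes
        brute = set()
        for gene in annotation:
            s, e = gene.promoter((-500, 500)) if kind == "promoter" else gene.body
            if any(
                pk.chrom == gene.chrom and pk.start < e and s < pk.end for pk in peaks
            ):
                brute.add(gene.gene_id)
        mismatches += len(tree_bound ^ brute)
    return {"n_mismatches": mismatches, "n_peaks": len(peaks), "n_genes": n_genes}
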