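import numpy as np
import pandas as pd
import pytest

from plastiscope import (
    BindingProfile,
    GeneAnnotation,
    GenomicInterval,
    ValidationError,
    assign_peaks,
    consistency_screen,
    loop_anchor_analysis,
    mark_combination_test,
)


def brute_force_bound(peaks, annotation, region_kind, window=(-500, 500)):
    bound = set()
    for gene in annotation:
        if region_kind == "promoter":
            start, end = gene.promoter(window)
        else:
            start, end = gene.body
        for pk in peaks:
            if pk.chrom == gene.chrom and pk.start < end and start < pk.end:
                bound.add(gene.gene_id)
                break
    return bound


class TestAssignPeaks:
    def test_one_bp_overlap_is_bound(self):
        gene = GeneAnnotation("g", "chr1", "+", 1000, 3000)
        # promoter is [500, 1500); a peak ending at 501 overlaps by exactly 1 bp
        peak = GenomicInterval("chr1", 400, 501)
        prof = assign_peaks([peak], [gene], "promoter")
        assert prof.bound_genes == {"g"}
        outside = GenomicInterval("chr1", 400, 500)
        assert not assign_peaks([outside], [gene], "promoter").bound_genes

    def test_minus_strand_promoter_centred_on_five_prime_end(self):
        gene = GeneAnnotation("g", "chr1", "-", 5000, 3000)  # TSS at 5000
        prof = assign_peaks(
            [GenomicInterval("chr1", 5400, 5500)], [gene], "promoter"
        )
        assert prof.bound_genes == {"g"}  # promoter [4500, 5500)
        prof2 = assign_peaks(
            [GenomicInterval("chr1", 5500, 5600)], [gene], "promoter"
        )
        assert not prof2.bound_genes

    @pytest.mark.parametrize("region_kind", ["promoter", "gene_body"])
    def test_matches_brute_force_on_random_layout(self, region_kind):
        rng = np.random.default_rng(0)
        annotation = []
        for i in range(100):
            left = int(rng.integers(10_000, 900_000))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(500, 5_000))
            if strand == "+":
                annotation.append(
                    GeneAnnotation(f"g{i}", "chr1", "+", left, left + length)
                )
            else:
                annotation.append(
                    GeneAnnotation(f"g{i}", "chr1", "-", left + length, left)
                )
        peaks = []
        for _ in range(200):
            start = int(rng.integers(0, 999_000))
            peaks.append(
                GenomicInterval("chr1", start, start + int(rng.integers(1, 800)))
            )
        prof = assign_peaks(peaks, annotation, region_kind)
        assert prof.bound_genes == brute_force_bound(peaks, annotation, region_kind)

    def test_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(1)
        annotation = [GeneAnnotation("g", "chr1", "+", 1000, 3000)]
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 5000, 20)
        ]
        a = assign_peaks(peaks, annotation, "promoter")
        b = assign_peaks(list(reversed(peaks)), annotation, "promoter")
        assert a.bound_genes == b.bound_genes

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValidationError):
            assign_peaks([], [], "promoter")


def make_profiles(factor, n_samples, targets, all_genes, rng, noise=0.0):
    profiles = []
    for s in range(n_samples):
        bound = {
            g
            for g in all_genes
            if (g in targets) ^ (rng.random() < noise)
        }
        profiles.append(BindingProfile(factor, f"s{s}", frozenset(bound)))
    return profiles


class TestConsistencyScreen:
    @staticmethod
    def planted_gep(n=800, shift=0.8, target_rate=0.3, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        targets = {g for g in genes if rng.random() < target_rate}
        gep = pd.DataFrame(
            {"gep": [rng.normal(shift if g in targets else 0, 1) for g in genes]},
            index=genes,
        )
        return gep, targets, genes, rng

    def test_eight_of_ten_supporting_passes(self):
        gep, targets, genes, rng = self.planted_gep()
        good = make_profiles("F", 8, targets, genes, rng)
        # two samples bound at random: wrong or no association
        bad = make_profiles("F", 2, set(rng.choice(genes, 200)), genes, rng)
        for i, prof in enumerate(bad):
            bad[i] = BindingProfile("F", f"s{8 + i}", prof.bound_genes)
        res = consistency_screen(good + bad, gep)["F"]
        assert res.n_samples == 10
        if res.n_supporting >= 8:
            assert res.verdict and res.direction == "promoting"

    def test_three_samples_never_pass(self):
        gep, targets, genes, rng = self.planted_gep(shift=2.0)
        profiles = make_profiles("F", 3, targets, genes, rng)
        res = consistency_screen(profiles, gep)["F"]
        assert not res.verdict and res.n_supporting == 3

    def test_split_directions_fail(self):
        gep, targets, genes, rng = self.planted_gep()
        anti = set(genes) - targets
        profiles = make_profiles("F", 5, targets, genes, rng) + [
            BindingProfile("F", f"a{s}", frozenset(anti)) for s in range(5)
        ]
        res = consistency_screen(profiles, gep)["F"]
        assert not res.verdict

    def test_tiny_bound_group_untested(self):
        gep, targets, genes, rng = self.planted_gep()
        profiles = [BindingProfile("F", "s0", frozenset(genes[:3]))]
        with pytest.warns(UserWarning, match="untested"):
            res = consistency_screen(profiles, gep)
        assert res == {}


class TestLoopAnchorAnalysis:
    @staticmethod
    def layout(n=300, seed=0, binding_effect=0.8):
        """Genes along one chromosome; loops placed independently of binding."""
        rng = np.random.default_rng(seed)
        annotation = [
            GeneAnnotation(f"g{i}", "chr1", "+", 10_000 + 20_000 * i,
                           10_000 + 20_000 * i + 2_000)
            for i in range(n)
        ]
        # loops covering genes 0-99: anchors at gene promoters 0-49 (even)
        loops = []
        for i in range(0, 100, 2):
            tss_a = annotation[i].tss
            tss_b = annotation[i + 1].tss
            loops.append(
                (
                    GenomicInterval("chr1", tss_a - 600, tss_a + 600),
                    GenomicInterval("chr1", tss_b - 600, tss_b + 600),
                )
            )
        targets = {f"g{i}" for i in range(n) if rng.random() < 0.4}
        gep = pd.DataFrame(
            {"gep": [rng.normal(binding_effect if f"g{i}" in targets else 0, 1)
                     for i in range(n)]},
            index=[f"g{i}" for i in range(n)],
        )
        peaks = [
            GenomicInterval("chr1", annotation[i].tss - 50, annotation[i].tss + 50)
            for i in range(n)
            if f"g{i}" in targets
        ]
        return gep, annotation, loops, peaks

    def test_promoter_classification(self):
        gep, annotation, loops, peaks = self.layout()
        report = loop_anchor_analysis(gep, annotation, loops, peaks)
        labels = report["labels"]
        assert labels.loc["g0"] == "anchor"
        assert labels.loc["g200"] == "outside"
        assert report["n_anchor"] == 100

    def test_binding_effect_independent_of_loops(self):
        # binding shifts GEP regardless of topology: the outside-loop test
        # stays significant while anchor-vs-loop does not exist as an effect
        gep, annotation, loops, peaks = self.layout(binding_effect=1.0)
        report = loop_anchor_analysis(gep, annotation, loops, peaks)
        assert report["outside_binding_p"] < 0.01
        assert report["outside_binding_direction"] == 1

    def test_requires_loops(self):
        gep, annotation, _, peaks = self.layout()
        with pytest.raises(ValidationError):
            loop_anchor_analysis(gep, annotation, [], peaks)


class TestMarkCombinationTest:
    def test_saturating_marks_show_no_extra_restriction(self):
        rng = np.random.default_rng(3)
        n = 900
        genes = [f"g{i}" for i in range(n)]
        m1 = set(rng.choice(genes, 400, replace=False))
        m2 = set(rng.choice(genes, 400, replace=False))
        # saturating: any mark lowers GEP by 1, second mark adds nothing
        gep = pd.DataFrame(
            {"gep": [rng.normal(-1.0 if g in (m1 | m2) else 0.0, 1) for g in genes]},
            index=genes,
        )
        profiles = [
            BindingProfile("M1", "s0", frozenset(m1), "gene_body"),
            BindingProfile("M2", "s0", frozenset(m2), "gene_body"),
        ]
        table = mark_combination_test(profiles, gep)
        row = table[table["strata"] == "1_vs_2"].iloc[0]
        assert row["p"] > 0.01  # no additional restriction detected

    def test_single_stratum_is_undetermined(self):
        genes = ["g0", "g1", "g2"]
        gep = pd.DataFrame({"gep": [1.0, 2.0, 3.0]}, index=genes)
        profiles = [
            BindingProfile("M1", "s0", frozenset({"g0"}), "gene_body"),
            BindingProfile("M2", "s0", frozenset({"g1"}), "gene_body"),
            BindingProfile("M3", "s0", frozenset({"g2"}), "gene_body"),
        ]
        table = mark_combination_test(profiles, gep)
        assert table.empty and table.attrs.get("undetermined")

    def test_no_marked_genes_rejected(self):
        gep = pd.DataFrame({"gep": [1.0, 2.0]}, index=["g0", "g1"])
        profiles = [
            BindingProfile("M1", "s0", frozenset(), "gene_body"),
            BindingProfile("M2", "s0", frozenset(), "gene_body"),
        ]
        with pytest.raises(ValidationError):
            mark_combination_test(profiles, gep)
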