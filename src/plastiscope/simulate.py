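"""Synthetic data with planted, recoverable regulatory architecture.

The generative model mirrors what the plasticity score measures: each gene
has a latent per-condition dispersion sigma_g, and its log2 fold change in
condition c is drawn Normal(0, sigma_g).  Since E[(log2FC)^2] = sigma_g^2,
the expected plasticity of a gene is log2(sigma_g^2) = 2 log2 sigma_g, so
regulatory effects are planted as additive shifts on log2 sigma_g:

* motif m present in the promoter adds delta_m;
* an interaction plan replaces the additive pair sum by boost * (d1 + d2)
  (enhancement) or by the winner's delta alone (dominance);
* factor binding and gene-body marks add their association shifts;
* loss-of-function perturbations multiply the per-gene condition effect by
  a shrink factor k in (0, 1].

Every generator is deterministic given its seed; regenerating with the same
configuration reproduces outputs byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .perturbation import PerturbationExperiment
from .types import (
    BindingProfile,
    FoldChangeMatrix,
    GeneAnnotation,
    GenomicInterval,
    Pwm,
)

__all__ = [
    "SyntheticTruth",
    "CoreSimulation",
    "simulate_core",
    "simulate_binding",
    "simulate_perturbation",
    "simulate_annotations",
    "write_core",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SyntheticTruth:
    """Planted regulatory architecture and noise levels.

    Defaults reproduce the standard study conditions: five plasticity-
    promoting and three repressing promoter motifs (log2 sigma shifts of
    +/-0.5 at 30% promoter occupancy), one promoting and one repressing
    trans-factor (+/-0.5), two repressive gene-body marks (-0.5), gene-level
    noise SD 0.5 on log2 sigma, and a loss-of-function shrink factor of 0.5.
    """

    motif_effects: dict = field(
        default_factory=lambda: {
            **{f"M{i:02d}": 0.5 for i in range(1, 6)},
            **{f"M{i:02d}": -0.5 for i in range(6, 9)},
        }
    )
    motif_rate: float = 0.3
    interactions: dict = field(default_factory=dict)  # (m1, m2) -> plan
    factor_shifts: dict = field(
        default_factory=lambda: {"TF_plus": 0.5, "TF_minus": -0.5}
    )
    factor_rate: float = 0.3
    mark_shifts: dict = field(
        default_factory=lambda: {"H3K36me3": -0.5, "H3K79me2": -0.5}
    )
    mark_rate: float = 0.3
    base_log2_sigma: float = 0.0
    gene_noise_sd: float = 0.5
    lof_shrink: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lof_shrink <= 1.0:
            raise ValueError("lof_shrink must be in (0, 1]")
        for pair, plan in self.interactions.items():
            for motif in pair:
                if motif not in self.motif_effects:
                    raise ValueError(f"interaction references unknown motif {motif!r}")
            kind = plan[0]
            if kind not in ("additive", "enhancement", "dominance"):
                raise ValueError(f"unknown interaction kind {kind!r}")
            if kind == "dominance" and plan[1] not in pair:
                raise ValueError("dominance winner must be one of the pair")


@dataclass
class CoreSimulation:
    """Everything simulate_core produced, including the hidden truth."""

    truth: SyntheticTruth
    fc: FoldChangeMatrix
    log2_sigma: pd.Series
    presence: pd.DataFrame  # gene x motif ground truth
    promoters: dict
    promoter_offset: int
    annotation: list
    pwms: list
    factor_targets: dict
    mark_targets: dict


def _random_sequences(rng, n: int, length: int) -> list[str]:
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[row]) for row in draws]


def _make_pwms(rng, motif_ids, width: int = 8, major: float = 0.85) -> list[Pwm]:
    pwms = []
    minor = (1.0 - major) / 3.0
    for motif_id in motif_ids:
        consensus = rng.integers(0, 4, size=width)
        matrix = np.full((width, 4), minor)
        matrix[np.arange(width), consensus] = major
        pwms.append(Pwm(motif_id, matrix))
    return pwms


def simulate_core(
    truth: SyntheticTruth | None = None,
    n_genes: int = 5000,
    n_conditions: int = 200,
    seed: int | None = None,
    promoter_span: tuple[int, int] = (-250, 150),
    scan_window: tuple[int, int] = (-200, 100),
    sequences: bool = True,
) -> CoreSimulation:
    """Generate the core bundle: fold changes, promoters, annotation, PWMs.

    ``seed`` overrides ``truth.seed``.  Motif consensus sequences are
    embedded at random positions inside the scan window (on either strand)
    of genes carrying the motif; the rest of each promoter is background.
    """
    truth = truth or SyntheticTruth()
    if n_genes < 1 or n_conditions < 1:
        raise ValueError("n_genes and n_conditions must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    motif_ids = sorted(truth.motif_effects)

    presence = pd.DataFrame(
        (rng.random((n_genes, len(motif_ids))) < truth.motif_rate).astype(int),
        index=pd.Index(genes, name="gene_id"),
        columns=motif_ids,
    )

    deltas = np.array([truth.motif_effects[m] for m in motif_ids])
    log2_sigma = truth.base_log2_sigma + presence.to_numpy() @ deltas

    for (m1, m2), plan in truth.interactions.items():
        both = (presence[m1] & presence[m2]).to_numpy().astype(bool)
        d1, d2 = truth.motif_effects[m1], truth.motif_effects[m2]
        if plan[0] == "enhancement":
            boost = plan[1]
            log2_sigma[both] += (boost - 1.0) * (d1 + d2)
        elif plan[0] == "dominance":
            winner = plan[1]
            loser_delta = d2 if winner == m1 else d1
            log2_sigma[both] -= loser_delta

    factor_targets = {}
    for factor, shift in sorted(truth.factor_shifts.items()):
        members = rng.random(n_genes) < truth.factor_rate
        factor_targets[factor] = frozenset(np.array(genes)[members])
        log2_sigma = log2_sigma + shift * members
    mark_targets = {}
    for mark, shift in sorted(truth.mark_shifts.items()):
        members = rng.random(n_genes) < truth.mark_rate
        mark_targets[mark] = frozenset(np.array(genes)[members])
        log2_sigma = log2_sigma + shift * members

    log2_sigma = log2_sigma + rng.normal(0.0, truth.gene_noise_sd, size=n_genes)
    sigma = np.exp2(log2_sigma)

    fc_values = rng.normal(0.0, 1.0, size=(n_genes, n_conditions)) * sigma[:, None]
    fc = FoldChangeMatrix(
        pd.DataFrame(
            fc_values,
            index=pd.Index(genes, name="gene_id"),
            columns=[f"cond{j:04d}" for j in range(n_conditions)],
        )
    )

    # toy genome: genes every 5 kb on one chromosome, alternating strands
    annotation = []
    for i, gene_id in enumerate(genes):
        left = 10_000 + i * 5_000
        if i % 2 == 0:
            annotation.append(GeneAnnotation(gene_id, "chrS", "+", left, left + 2_000, 1))
        else:
            annotation.append(GeneAnnotation(gene_id, "chrS", "-", left + 2_000, left, 1))

    pwms = _make_pwms(rng, motif_ids)
    span_a, span_b = promoter_span
    promoters: dict[str, str] = {}
    if not sequences:
        return CoreSimulation(
            truth=truth,
            fc=fc,
            log2_sigma=pd.Series(log2_sigma, index=fc.genes, name="log2_sigma"),
            presence=presence,
            promoters=promoters,
            promoter_offset=span_a,
            annotation=annotation,
            pwms=pwms,
            factor_targets=factor_targets,
            mark_targets=mark_targets,
        )
    length = span_b - span_a
    seqs = _random_sequences(rng, n_genes, length)
    for gi, gene_id in enumerate(genes):
        seq = seqs[gi]
        for mi, motif_id in enumerate(motif_ids):
            if not presence.iat[gi, mi]:
                continue
            word = pwms[mi].consensus()
            if rng.random() < 0.5:
                word = word.translate(_COMPLEMENT)[::-1]
            lo = scan_window[0] - span_a
            hi = scan_window[1] - span_a - len(word)
            pos = int(rng.integers(lo, hi + 1))
            seq = seq[:pos] + word + seq[pos + len(word) :]
        promoters[gene_id] = seq

    return CoreSimulation(
        truth=truth,
        fc=fc,
        log2_sigma=pd.Series(log2_sigma, index=fc.genes, name="log2_sigma"),
        presence=presence,
        promoters=promoters,
        promoter_offset=span_a,
        annotation=annotation,
        pwms=pwms,
        factor_targets=factor_targets,
        mark_targets=mark_targets,
    )


def simulate_binding(
    core: CoreSimulation,
    n_samples: int = 10,
    label_noise: float = 0.05,
    seed: int = 1,
    factors: list[str] | None = None,
    region_kind: str = "promoter",
) -> tuple[list[BindingProfile], dict]:
    """Replicated binding profiles (and peak tracks) for the planted factors.

    Each sample's bound set is the factor's target set with independent
    per-gene label flips at rate ``label_noise`` (``label_noise=0.5`` makes
    binding independent of the targets).  Peaks are placed inside the bound
    genes' promoter windows or gene bodies.  ``n_samples=0`` returns empty
    outputs.
    """
    rng = np.random.default_rng(seed)
    target_map = core.factor_targets if region_kind == "promoter" else core.mark_targets
    names = factors if factors is not None else sorted(target_map)
    genes = list(core.fc.genes)
    by_id = {a.gene_id: a for a in core.annotation}
    profiles: list[BindingProfile] = []
    peaks: dict[tuple[str, str], list[GenomicInterval]] = {}
    for factor in names:
        targets = target_map[factor]
        base = np.array([g in targets for g in genes])
        for s in range(n_samples):
            flips = rng.random(len(genes)) < label_noise
            bound_mask = base ^ flips
            bound = [g for g, m in zip(genes, bound_mask) if m]
            sample_id = f"sample{s:02d}"
            profiles.append(
                BindingProfile(factor, sample_id, frozenset(bound), region_kind)
            )
            track = []
            for g in bound:
                ann = by_id[g]
                if region_kind == "promoter":
                    start, end = ann.promoter((-500, 500))
                else:
                    start, end = ann.body
                mid = (start + end) // 2
                track.append(GenomicInterval(ann.chrom, mid - 50, mid + 50))
            peaks[(factor, sample_id)] = track
    return profiles, peaks


def simulate_perturbation(
    truth: SyntheticTruth | None = None,
    n_genes: int = 2000,
    n_replicates: int = 3,
    seed: int = 2,
    replicate_sd: float = 0.1,
    shrink: float | None = None,
) -> PerturbationExperiment:
    """A two-condition control/mutant experiment with a planted shrink.

    Per gene: dispersion sigma_g ~ 2^N(0, 0.5); the control condition
    effect beta_g ~ N(0, sigma_g); the mutant effect is ``k * beta_g`` with
    k = ``shrink`` (default ``truth.lof_shrink``).  Expression is
    baseline + effect + replicate noise (SD ``replicate_sd``), on a log2
    scale.  ``replicate_sd=0`` makes fold-change directions deterministic.
    """
    truth = truth or SyntheticTruth()
    k = truth.lof_shrink if shrink is None else shrink
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    sigma = np.exp2(rng.normal(0.0, 0.5, size=n_genes))
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    beta = rng.normal(0.0, 1.0, size=n_genes) * sigma

    def reps(effect: np.ndarray) -> pd.DataFrame:
        noise = rng.normal(0.0, replicate_sd, size=(n_genes, n_replicates))
        return pd.DataFrame(
            baseline[:, None] + effect[:, None] + noise,
            index=genes,
            columns=[f"rep{r}" for r in range(n_replicates)],
        )

    zero = np.zeros(n_genes)
    return PerturbationExperiment(
        control={"condA": reps(zero), "condB": reps(beta)},
        mutant={"condA": reps(zero), "condB": reps(k * beta)},
    )


def simulate_annotations(
    core: CoreSimulation,
    seed: int = 3,
    disease_coupling: float = 0.5,
    species_noise_sd: float = 0.25,
    n_leaf_terms: int = 20,
    leaf_size: int = 60,
) -> dict:
    """Ontology, gene sets, orthologues and disease burden for one core sim.

    * ontology — a three-level DAG (root, branches, leaves) with genes
      annotated to leaves; leaf size is configurable so the 20-500 retention
      band can be exercised from both sides.
    * orthologues — a second species sharing log2 sigma up to Gaussian
      species noise, returned as a fold-change matrix plus an id-mapping
      table.
    * disease burden — Poisson counts whose log rate couples to the gene's
      log2 sigma with weight ``disease_coupling`` (0 = independent).
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    genes = list(core.fc.genes)
    n_genes = len(genes)

    ontology = nx.DiGraph()
    ontology.add_node("T:root")
    leaves = []
    for b in range(4):
        branch = f"T:branch{b}"
        ontology.add_edge(branch, "T:root")
        for l in range(n_leaf_terms // 4):
            leaf = f"T:leaf{b}_{l}"
            ontology.add_edge(leaf, branch)
            leaves.append(leaf)
    annotations: dict[str, list[str]] = {}
    for leaf in leaves:
        members = rng.choice(n_genes, size=min(leaf_size, n_genes), replace=False)
        for gi in members:
            annotations.setdefault(genes[gi], []).append(leaf)

    z = (core.log2_sigma - core.log2_sigma.mean()) / core.log2_sigma.std()
    latent = disease_coupling * z.to_numpy() + np.sqrt(
        max(0.0, 1.0 - disease_coupling**2)
    ) * rng.normal(size=n_genes)
    disease = pd.Series(
        rng.poisson(np.exp(0.5 + 0.5 * latent)), index=core.fc.genes, name="count"
    )

    order = np.argsort(-core.log2_sigma.to_numpy(), kind="stable")
    top = [genes[i] for i in order[: max(10, n_genes // 10)]]
    gene_sets = {
        "planted_high_plasticity": top,
        "random_set": sorted(rng.choice(genes, size=min(100, n_genes), replace=False)),
    }

    species_log2_sigma = core.log2_sigma.to_numpy() + rng.normal(
        0.0, species_noise_sd, size=n_genes
    )
    sigma_b = np.exp2(species_log2_sigma)
    n_cond = core.fc.shape[1]
    fc_b = FoldChangeMatrix(
        pd.DataFrame(
            rng.normal(0.0, 1.0, size=(n_genes, n_cond)) * sigma_b[:, None],
            index=pd.Index([f"s2_{g}" for g in genes], name="gene_id"),
            columns=[f"cond{j:04d}" for j in range(n_cond)],
        )
    )
    orthologues = pd.DataFrame({"a": genes, "b": [f"s2_{g}" for g in genes]})

    return {
        "ontology": ontology,
        "annotations": annotations,
        "gene_sets": gene_sets,
        "disease_burden": disease,
        "species_b_fc": fc_b,
        "orthologues": orthologues,
    }


def write_core(core: CoreSimulation, outdir) -> dict:
    """Write a core simulation to plain-text files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_fold_change_matrix(core.fc, outdir / "fold_changes.tsv")
    pio.write_gene_annotation(core.annotation, outdir / "genes.gtf_lite.tsv")
    pio.write_promoter_fasta(
        core.promoters, outdir / "promoters.fasta", offset=core.promoter_offset
    )
    pio.write_meme_motifs(core.pwms, outdir / "motifs.meme")
    core.presence.to_csv(outdir / "motif_presence_truth.tsv", sep="\t")
    manifest = {
        "seed": core.truth.seed,
        "n_genes": int(core.fc.shape[0]),
        "n_conditions": int(core.fc.shape[1]),
        "truth": {
            k: v
            for k, v in asdict(core.truth).items()
            if k != "interactions"
        },
        "interactions": {
            f"{a}+{b}": list(plan) for (a, b), plan in core.truth.interactions.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
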