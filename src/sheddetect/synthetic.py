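"""Synthetic paired knockdown-vs-control transcriptome + proteome generator.

Emulates the study design the pipeline targets: 6+6 RNA-seq replicates
(negative-binomial counts with log-normal library sizes) and 5+5 TMT
proteome replicates (log-normal reporter intensities), with a planted bait
knockdown and planted target classes:

* ``transcriptional_target`` — mRNA and protein share the same log2 fold
  change (the protein change is transcription-driven);
* ``post_transcriptional_target`` — protein changes, mRNA stays flat;
* ``substrate`` — post-transcriptional, protein *up* on knockdown (shed
  substrates accumulate when the protease falls), surface-annotated with a
  membrane topology;
* ``null`` — no planted effect.

A shared per-sample latent factor loads on every feature of both blocks
with small random log2 loadings.  It models sample-level covariation
(harvest density, input amount) and is what gives the two blocks genuine
joint structure for the O2PLS step beyond the condition contrast itself.

Protein samples reuse the ids of the first replicates of each RNA condition,
so pairing the blocks by sample id reproduces the drop-unpaired default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FeatureAnnotation, SampleDesign, GeneSetLibrary, build_annotation

__all__ = ["SimConfig", "SyntheticTruth", "generate_paired_omics",
           "synthetic_gene_sets", "evaluate_recovery"]

ROLES = ("bait", "transcriptional_target", "post_transcriptional_target", "substrate", "null")

_SURFACE_TOPOLOGIES = (
    ("Cell membrane", "Single-pass type I membrane protein", 0.50),
    ("Cell membrane", "Single-pass type II membrane protein", 0.12),
    ("Cell membrane", "Single-pass type IV membrane protein", 0.05),
    ("Cell membrane", "Single-pass membrane protein", 0.08),
    ("Cell membrane", "Multi-pass membrane protein", 0.20),
    ("Cell membrane; Lipid-anchor, GPI-anchor", "", 0.05),
)

_INTRACELLULAR_LOCATIONS = (
    ("Cytoplasm", ""),
    ("Nucleus", ""),
    ("Cytoplasm; Nucleus", ""),
    ("Mitochondrion inner membrane", "Multi-pass membrane protein"),
    ("Endoplasmic reticulum membrane", "Multi-pass membrane protein"),
    ("Golgi apparatus membrane", "Single-pass type II membrane protein"),
)


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic paired-omics benchmark.

    Scale is a desk-scale stand-in for a full experiment: 2,000 genes and
    1,500 proteins of which 1,200 are gene-paired.  Effect sizes |log2FC|
    draw from N(1.0, 0.2); NB dispersion 0.05 (biological CV ~22%, typical
    for cell-line RNA-seq); protein log2 noise sd 0.25 (~19% CV, typical
    TMT); library sizes log-normal with sigma 0.15; latent-factor loadings
    N(0, 0.25) on the log2 scale in both blocks.
    """

    n_genes: int = 2000
    n_proteins: int = 1500
    n_paired: int = 1200
    rna_replicates: tuple[int, int] = (6, 6)       # (control, knockdown)
    protein_replicates: tuple[int, int] = (5, 5)
    frac_transcriptional: float = 0.05
    frac_post_transcriptional: float = 0.04
    frac_substrate: float = 0.02
    lfc_mean: float = 1.0
    lfc_sd: float = 0.2
    bait_lfc: float = -2.0
    nb_dispersion: float = 0.05
    protein_noise_sd: float = 0.25
    latent_sd: float = 0.25
    library_size: float = 3.0e5
    library_sigma: float = 0.15
    baseline_abundance_sd: float = 1.5
    protein_baseline_mean: float = 18.0
    protein_baseline_sd: float = 1.5
    surface_decoy_fraction: float = 0.10
    bait_id: str = "ADAM9"
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_transcriptional, self.frac_post_transcriptional, self.frac_substrate)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("role fractions must be non-negative and sum to <= 1")
        if min(*self.rna_replicates, *self.protein_replicates) < 2:
            raise ValueError("replicate counts must be >= 2")
        if any(s < 0 for s in (self.lfc_sd, self.nb_dispersion, self.protein_noise_sd,
                               self.latent_sd, self.library_sigma)):
            raise ValueError("spread parameters must be >= 0")
        if self.n_paired > min(self.n_genes, self.n_proteins):
            raise ValueError("n_paired exceeds available genes or proteins")
        needed = round(sum(fracs) * self.n_proteins) + 1
        if needed > self.n_paired:
            raise ValueError("planted roles exceed the paired feature pool")


@dataclass
class SyntheticTruth:
    """Planted ground truth: one row per protein plus a per-gene frame."""

    proteins: pd.DataFrame  # protein_id, gene_id, role, mrna_log2fc, protein_log2fc,
    #                         bait_correlation_sign, is_surface, topology
    genes: pd.DataFrame     # gene_id, role, mrna_log2fc
    config: dict = field(default_factory=dict)

    def of_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        sel = self.proteins.loc[self.proteins["role"] == role, "protein_id"]
        return list(sel)


def _sample_ids(prefix_counts) -> list[str]:
    (nc, nk) = prefix_counts
    return [f"ctrl_{i+1}" for i in range(nc)] + [f"kd_{i+1}" for i in range(nk)]


def generate_paired_omics(config: SimConfig):
    """Generate (counts, intensities, design, annotation, truth), reproducibly.

    Returns
    -------
    counts : ExpressionMatrix (kind="counts"), RNA samples x genes
    intensities : ExpressionMatrix (kind="intensities"), protein samples x proteins
    design : SampleDesign covering the union of sample ids
    annotation : FeatureAnnotation for every protein
    truth : SyntheticTruth
    """
    rng = np.random.default_rng(config.seed)
    nc_r, nk_r = config.rna_replicates
    nc_p, nk_p = config.protein_replicates
    if nc_p > nc_r or nk_p > nk_r:
        raise ValueError("protein replicates must be a subset of RNA replicates for pairing")

    rna_samples = _sample_ids(config.rna_replicates)
    prot_samples = [f"ctrl_{i+1}" for i in range(nc_p)] + [f"kd_{i+1}" for i in range(nk_p)]
    z_rna = np.array([0] * nc_r + [1] * nk_r)               # 1 = knockdown
    z_prot = np.array([0] * nc_p + [1] * nk_p)

    # shared latent sample factor; protein samples inherit their RNA sample's value
    g_rna = rng.normal(0.0, 1.0, size=len(rna_samples))
    g_lut = dict(zip(rna_samples, g_rna))
    g_prot = np.array([g_lut[s] for s in prot_samples])

    # ---- feature bookkeeping -------------------------------------------------
    genes = [f"G{i+1:05d}" for i in range(config.n_genes)]
    paired_prot = [f"P{i+1:05d}" for i in range(config.n_paired)]
    unpaired_prot = [f"PU{i+1:05d}" for i in range(config.n_proteins - config.n_paired)]
    proteins = paired_prot + unpaired_prot
    prot_gene = {p: genes[i] for i, p in enumerate(paired_prot)}
    prot_gene.update({p: f"GU{i+1:05d}" for i, p in enumerate(unpaired_prot)})

    # bait occupies the first paired slot under its real ids
    proteins[0] = config.bait_id
    genes[0] = config.bait_id
    prot_gene[config.bait_id] = config.bait_id
    del prot_gene[paired_prot[0]]
    paired_prot[0] = config.bait_id

    n_tr = round(config.frac_transcriptional * config.n_proteins)
    n_post = round(config.frac_post_transcriptional * config.n_proteins)
    n_sub = round(config.frac_substrate * config.n_proteins)
    pool = rng.permutation(np.arange(1, config.n_paired))  # paired indices minus bait
    idx_tr = pool[:n_tr]
    idx_post = pool[n_tr:n_tr + n_post]
    idx_sub = pool[n_tr + n_post:n_tr + n_post + n_sub]

    role = np.array(["null"] * config.n_proteins, dtype=object)
    role[0] = "bait"
    role[idx_tr] = "transcriptional_target"
    role[idx_post] = "post_transcriptional_target"
    role[idx_sub] = "substrate"

    def draw_lfc(size):
        mag = rng.normal(config.lfc_mean, config.lfc_sd, size=size)
        sign = rng.choice([-1.0, 1.0], size=size)
        return np.abs(mag) * sign

    protein_lfc = np.zeros(config.n_proteins)
    mrna_lfc_by_gene = np.zeros(config.n_genes)
    protein_lfc[0] = config.bait_lfc
    mrna_lfc_by_gene[0] = config.bait_lfc
    tr_effects = draw_lfc(len(idx_tr))
    protein_lfc[idx_tr] = tr_effects
    mrna_lfc_by_gene[idx_tr] = tr_effects        # paired index == gene index
    protein_lfc[idx_post] = draw_lfc(len(idx_post))
    protein_lfc[idx_sub] = np.abs(draw_lfc(len(idx_sub)))   # substrates accumulate on KD

    # ---- annotation ----------------------------------------------------------
    locations = np.empty(config.n_proteins, dtype=object)
    topologies = np.empty(config.n_proteins, dtype=object)
    surf_locs = [(l, t) for l, t, _ in _SURFACE_TOPOLOGIES]
    surf_probs = np.array([w for _, _, w in _SURFACE_TOPOLOGIES])
    for j in range(config.n_proteins):
        if role[j] == "substrate":
            k = rng.choice(len(surf_locs), p=surf_probs)
            locations[j], topologies[j] = surf_locs[k]
        elif role[j] == "bait":
            locations[j], topologies[j] = "Cell membrane", "Single-pass type I membrane protein"
        elif rng.random() < config.surface_decoy_fraction:
            k = rng.choice(len(surf_locs), p=surf_probs)
            locations[j], topologies[j] = surf_locs[k]
        else:
            locations[j], topologies[j] = _INTRACELLULAR_LOCATIONS[
                rng.integers(len(_INTRACELLULAR_LOCATIONS))
            ]
    annotation = build_annotation(
        proteins, [prot_gene[p] for p in proteins], locations, topologies
    )
    is_surface = annotation.table.set_index("protein_id")["is_surface"]

    # ---- RNA counts ----------------------------------------------------------
    base_log2 = rng.normal(0.0, config.baseline_abundance_sd, size=config.n_genes)
    rel = 2.0 ** base_log2
    rel /= rel.sum()
    lam_rna = rng.normal(0.0, config.latent_sd, size=config.n_genes)
    lib = config.library_size * np.exp(
        rng.normal(0.0, config.library_sigma, size=len(rna_samples))
    )
    log2_shift = (
        np.outer(z_rna, mrna_lfc_by_gene) + np.outer(g_rna, lam_rna)
    )
    mu = lib[:, None] * rel[None, :] * 2.0 ** log2_shift
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        mu = rng.gamma(shape, 1.0, size=mu.shape) * (mu / shape)
    counts = rng.poisson(mu).astype(float)
    counts_em = ExpressionMatrix(counts, rna_samples, genes, "counts")

    # ---- protein intensities -------------------------------------------------
    base_prot = rng.normal(config.protein_baseline_mean, config.protein_baseline_sd,
                           size=config.n_proteins)
    lam_prot = rng.normal(0.0, config.latent_sd, size=config.n_proteins)
    # transcriptionally driven proteins (and the knocked-down bait) track their
    # mRNA's sample-to-sample variation, so they inherit its latent loading;
    # post-transcriptional and null proteins respond to the sample factor
    # independently of their mRNA.
    coupled = np.concatenate([[0], idx_tr]).astype(int)
    lam_prot[coupled] = lam_rna[coupled]  # paired protein index == gene index
    log2_int = (
        base_prot[None, :]
        + np.outer(z_prot, protein_lfc)
        + np.outer(g_prot, lam_prot)
        + rng.normal(0.0, config.protein_noise_sd, size=(len(prot_samples), config.n_proteins))
    )
    intens_em = ExpressionMatrix(2.0 ** log2_int, prot_samples, proteins, "intensities")

    # ---- design and truth ----------------------------------------------------
    design = SampleDesign(pd.DataFrame({
        "sample_id": rna_samples,
        "condition": ["control"] * nc_r + ["knockdown"] * nk_r,
    }))

    gene_pos = {g: i for i, g in enumerate(genes)}
    mrna_lfc_of_protein = np.array([
        mrna_lfc_by_gene[gene_pos[prot_gene[p]]] if prot_gene[p] in gene_pos else np.nan
        for p in proteins
    ])
    bait_sign = np.where(
        protein_lfc == 0, 0, np.sign(protein_lfc) * np.sign(config.bait_lfc)
    ).astype(int)
    bait_sign[0] = 1  # the bait trivially co-varies with itself

    topology_of = annotation.table.set_index("protein_id")["topology"]
    truth_prot = pd.DataFrame({
        "protein_id": proteins,
        "gene_id": [prot_gene[p] for p in proteins],
        "role": role,
        "mrna_log2fc": mrna_lfc_of_protein,
        "protein_log2fc": protein_lfc,
        "bait_correlation_sign": bait_sign,
        "is_surface": [bool(is_surface[p]) for p in proteins],
        "topology": [topology_of[p] for p in proteins],
    })
    gene_role = np.array(["null"] * config.n_genes, dtype=object)
    gene_role[0] = "bait"
    gene_role[idx_tr] = "transcriptional_target"
    truth_gene = pd.DataFrame({
        "gene_id": genes,
        "role": gene_role,
        "mrna_log2fc": mrna_lfc_by_gene,
    })
    truth = SyntheticTruth(truth_prot, truth_gene, asdict(config))
    return counts_em, intens_em, design, annotation, truth


def synthetic_gene_sets(
    truth: SyntheticTruth,
    seed: int = 0,
    n_random_sets: int = 20,
    set_size: int = 50,
) -> GeneSetLibrary:
    """A small gene-set library: one set enriched for planted DE genes plus
    random sets, for exercising the enrichment stage on synthetic data."""
    rng = np.random.default_rng(seed)
    genes = list(truth.genes["gene_id"])
    de_genes = list(truth.genes.loc[truth.genes["mrna_log2fc"] != 0, "gene_id"])
    planted = list(rng.choice(de_genes, size=min(set_size // 2, len(de_genes)), replace=False))
    filler = [g for g in genes if g not in set(planted)]
    planted += list(rng.choice(filler, size=set_size - len(planted), replace=False))
    sets = {"PLANTED_RESPONSE": sorted(planted)}
    descriptions = {"PLANTED_RESPONSE": "enriched for planted differential genes"}
    for i in range(n_random_sets):
        name = f"RANDOM_{i+1:02d}"
        sets[name] = sorted(rng.choice(genes, size=set_size, replace=False))
        descriptions[name] = "uniform random gene set"
    return GeneSetLibrary(sets, descriptions)


def evaluate_recovery(
    targets: pd.DataFrame,
    truth: SyntheticTruth,
    candidates: pd.DataFrame | None = None,
    eligible: set | None = None,
) -> dict:
    """Precision/recall/F1 of class calls (and substrate candidates) vs truth.

    ``eligible`` restricts the recall denominator to planted features that
    were classifiable at all (e.g. the set that survived the upstream
    differential-protein gate); by default recall is measured over every
    planted feature of the class.  Empty prediction sets give recall 0 and
    precision NaN.
    """
    known = set(truth.proteins["protein_id"])
    extra = set(targets["protein_id"]) - known
    if extra:
        raise ValueError(f"predictions contain unknown feature ids: {sorted(extra)[:5]}")

    truth_tr = set(truth.of_role("transcriptional_target"))
    truth_post = set(truth.of_role("post_transcriptional_target")) | set(truth.of_role("substrate"))
    if eligible is not None:
        truth_tr &= eligible
        truth_post &= eligible

    def prf(predicted: set, actual: set) -> dict:
        tp = len(predicted & actual)
        recall = tp / len(actual) if actual else np.nan
        precision = tp / len(predicted) if predicted else np.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if predicted and actual and (precision + recall) > 0
            else (0.0 if actual else np.nan)
        )
        return {"precision": precision, "recall": recall, "f1": f1,
                "n_predicted": len(predicted), "n_true": len(actual)}

    pred_tr = set(targets.loc[targets["regulation_class"] == "transcriptional", "protein_id"])
    pred_post = set(targets.loc[targets["regulation_class"] == "post_transcriptional", "protein_id"])
    out = {
        "transcriptional": prf(pred_tr, truth_tr),
        "post_transcriptional": prf(pred_post, truth_post),
    }
    if candidates is not None:
        subs = set(truth.of_role("substrate"))
        if eligible is not None:
            subs &= eligible
        cand = set(candidates["protein_id"])
        out["substrate"] = prf(cand, subs)
        decoys = cand & set(
            truth.proteins.loc[~truth.proteins["is_surface"], "protein_id"]
        )
        out["substrate"]["decoys_admitted"] = len(decoys)
    return out
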