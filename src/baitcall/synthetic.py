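"""Synthetic AP-MS spectral-count matrices and RNA-seq count tables with
known ground truth.

Every downstream stage of the pipeline is testable without any data
download: the AP-MS generator emulates the study design of five mock
(control) captures, four wild-type bait captures, three captures per point
mutant and two per domain-deletion mutant, split over two batches (A/B),
with sticky background preys and bait-dependent enrichment; the RNA-seq
generator emulates a four-condition transient-transfection design with
planted tag-responsive genes, bait-specific genes, and a cDNA transgene
that shares exons with its endogenous gene.

Counts follow a negative-binomial law (Poisson in the zero-dispersion
limit) because both spectral counts and read counts are over-dispersed;
dispersion is a single shared parameter per matrix.  Batch effects are
multiplicative on the mean.  Seeds are explicit arguments; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import CONTROL_LABEL, SpectralCountMatrix
from .rnaseq import ExonCountTable, GeneCountTable

CONSTRUCTS = ("control", "WT", "S85C", "F115C", "dRRM1", "dRRM2", "dZnF1", "dZnF2")
RNASEQ_CONDITIONS = ("untransfected", "YFP", "WT", "F115C")

__all__ = [
    "ApmsDesign",
    "ApmsTruthConfig",
    "RnaseqTruthConfig",
    "default_design",
    "default_apms_truth",
    "simulate_apms",
    "default_rnaseq_truth",
    "default_groups",
    "simulate_rnaseq",
    "write_apms",
]


# ---------------------------------------------------------------------------
# AP-MS
# ---------------------------------------------------------------------------

@dataclass
class ApmsDesign:
    """Run layout: (run_id, construct, batch) triples plus protein space."""

    runs: list[tuple[str, str, str]]
    n_proteins: int
    bait_protein_id: int

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ValueError("run ids must be unique")
        bad = [c for _, c, _ in self.runs if c not in CONSTRUCTS]
        if bad:
            raise ValueError(f"unknown construct labels: {bad}")
        n_ctrl = sum(1 for _, c, _ in self.runs if c == CONTROL_LABEL)
        if n_ctrl < 2:
            raise ValueError("at least 2 control runs are required")
        if not 0 <= self.bait_protein_id < self.n_proteins:
            raise ValueError("bait_protein_id must index into the protein space")


@dataclass
class ApmsTruthConfig:
    """Generating parameters of the spectral-count model.

    Per-run mean for a prey = background_mean * batch multiplier (batch B)
    * enrichment_factor if the prey truly interacts with that run's
    construct; the bait's own row scales with the construct's capture
    level instead.
    """

    background_mean: np.ndarray            # per protein, > 0
    background_dispersion: float           # alpha; var = mu + alpha mu^2
    true_interactors: dict[str, set[int]]  # construct -> protein indices
    enrichment_factor: float = 8.0
    batch_multiplier: float = 1.0          # applied to batch "B"; batch "A" = 1
    bait_capture_level: dict[str, float] = field(default_factory=dict)
    # construct -> {protein index -> enrichment factor} overriding the global
    # factor, e.g. to plant domain-dependent binding (lost or enhanced under
    # a particular deletion construct)
    enrichment_overrides: dict[str, dict[int, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.background_mean = np.asarray(self.background_mean, dtype=float)
        if (self.background_mean <= 0).any():
            raise ValueError("background means must be positive")
        if self.background_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.batch_multiplier <= 0:
            raise ValueError("batch_multiplier must be positive")
        if CONTROL_LABEL in self.true_interactors and self.true_interactors[
            CONTROL_LABEL
        ]:
            raise ValueError("controls cannot have true interactors")


def default_design(n_proteins: int = 200, bait_protein_id: int = 0) -> ApmsDesign:
    """The study's capture layout: 5 controls, 4 WT, 3 per point mutant,
    2 per deletion mutant, in batches A and B."""
    runs = [
        ("ctrl_1A", "control", "A"), ("ctrl_2A", "control", "A"),
        ("ctrl_3B", "control", "B"), ("ctrl_4B", "control", "B"),
        ("ctrl_5B", "control", "B"),
        ("WT_1A", "WT", "A"), ("WT_2A", "WT", "A"),
        ("WT_3B", "WT", "B"), ("WT_4B", "WT", "B"),
        ("S85C_1A", "S85C", "A"), ("S85C_2A", "S85C", "A"),
        ("S85C_3B", "S85C", "B"),
        ("F115C_1A", "F115C", "A"), ("F115C_2A", "F115C", "A"),
        ("F115C_3B", "F115C", "B"),
        ("dRRM1_1A", "dRRM1", "A"), ("dRRM1_2B", "dRRM1", "B"),
        ("dRRM2_1A", "dRRM2", "A"), ("dRRM2_2B", "dRRM2", "B"),
        ("dZnF1_1A", "dZnF1", "A"), ("dZnF1_2B", "dZnF1", "B"),
        ("dZnF2_1A", "dZnF2", "A"), ("dZnF2_2B", "dZnF2", "B"),
    ]
    return ApmsDesign(runs=runs, n_proteins=n_proteins, bait_protein_id=bait_protein_id)


def default_apms_truth(
    design: ApmsDesign,
    n_interactors: int = 20,
    enrichment_factor: float = 8.0,
    dispersion: float = 0.02,
    batch_multiplier: float = 1.2,
    seed: int = 0,
) -> ApmsTruthConfig:
    """Sticky-background truth: lognormal background means (most preys are
    low-abundance bead binders, a few are sticky and abundant) and the
    first ``n_interactors`` non-bait proteins planted as interactors of
    every bait construct."""
    rng = np.random.default_rng(seed)
    bg = rng.lognormal(mean=1.0, sigma=0.8, size=design.n_proteins)
    bg = np.clip(bg, 0.3, None)
    bg[design.bait_protein_id] = 5.0  # background bead-binding of the bait
    pool = [i for i in range(design.n_proteins) if i != design.bait_protein_id]
    interactors = set(pool[:n_interactors])
    # True interactors sit in the moderate-background regime of the strongest
    # observed co-captures (a few control spectra per run, so bait-run counts
    # reach the tens at the configured enrichment), not at the detection floor.
    bg[np.fromiter(interactors, dtype=int)] = rng.uniform(
        1.5, 6.0, size=len(interactors)
    )
    baits = sorted({c for _, c, _ in design.runs if c != CONTROL_LABEL})
    capture = {c: 25.0 for c in baits}
    capture[CONTROL_LABEL] = 1.0
    return ApmsTruthConfig(
        background_mean=bg,
        background_dispersion=dispersion,
        true_interactors={c: set(interactors) for c in baits},
        enrichment_factor=enrichment_factor,
        batch_multiplier=batch_multiplier,
        bait_capture_level=capture,
        seed=seed,
    )


def default_domain_truth(
    design: ApmsDesign,
    n_interactors: int = 20,
    reduced_construct: str = "dRRM1",
    enhanced_construct: str = "dRRM2",
    reduced_factor: float = 0.1,
    enhanced_factor: float = 4.0,
    seed: int = 0,
) -> tuple[ApmsTruthConfig, int, int]:
    """Truth with one planted selective-reduced and one selective-enhanced prey.

    The first planted interactor loses its binding under ``reduced_construct``
    (its mean drops to ``reduced_factor`` x its WT-bound mean); the second
    binds ``enhanced_construct`` ``enhanced_factor`` x more strongly than WT.
    All other interactors bind every construct equally.  Returns the truth
    plus the protein indices of the reduced and enhanced preys.
    """
    truth = default_apms_truth(design, n_interactors=n_interactors, seed=seed)
    ordered = sorted(truth.true_interactors["WT"])
    reduced_prey, enhanced_prey = ordered[0], ordered[1]
    truth.enrichment_overrides = {
        reduced_construct: {
            reduced_prey: truth.enrichment_factor * reduced_factor
        },
        enhanced_construct: {
            enhanced_prey: truth.enrichment_factor * enhanced_factor
        },
    }
    return truth, reduced_prey, enhanced_prey


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-10:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_apms(
    design: ApmsDesign, truth: ApmsTruthConfig
) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Draw a spectral-count matrix and its ground-truth protein labels.

    Labels: ``bait`` for the bait's own row, ``interactor`` (with the
    constructs it binds) for planted interactors, ``background`` otherwise.
    Identical (design, truth) pairs give identical matrices.
    """
    rng = np.random.default_rng(truth.seed)
    protein_ids = [f"P{i:04d}" for i in range(design.n_proteins)]
    cols = {}
    meta_rows = []
    for run_id, construct, batch in design.runs:
        mult = truth.batch_multiplier if batch == "B" else 1.0
        mu = truth.background_mean * mult
        members = truth.true_interactors.get(construct, set())
        mu = mu.copy()
        if construct != CONTROL_LABEL:
            if members:
                idx = np.fromiter(members, dtype=int)
                mu[idx] *= truth.enrichment_factor
            for i, factor in truth.enrichment_overrides.get(construct, {}).items():
                mu[i] = truth.background_mean[i] * mult * factor
        level = truth.bait_capture_level.get(
            construct, 1.0 if construct == CONTROL_LABEL else None
        )
        if level is None:
            raise ValueError(f"no bait capture level for construct '{construct}'")
        if level <= 0:
            raise ValueError("bait capture levels must be positive")
        mu[design.bait_protein_id] = (
            truth.background_mean[design.bait_protein_id] * level * mult
        )
        cols[run_id] = _nb_draw(rng, mu, truth.background_dispersion)
        meta_rows.append(
            {"run_id": run_id, "construct": construct, "batch": batch}
        )
    counts = pd.DataFrame(cols, index=protein_ids)
    meta = pd.DataFrame(meta_rows).set_index("run_id")
    meta["replicate"] = meta.groupby("construct").cumcount() + 1

    labels = []
    for i, pid in enumerate(protein_ids):
        if i == design.bait_protein_id:
            labels.append({"protein_id": pid, "label": "bait", "interactor_of": ""})
            continue
        bound = sorted(
            c for c, mem in truth.true_interactors.items() if i in mem
        )
        if bound:
            labels.append(
                {
                    "protein_id": pid,
                    "label": "interactor",
                    "interactor_of": ",".join(bound),
                }
            )
        else:
            labels.append(
                {"protein_id": pid, "label": "background", "interactor_of": ""}
            )
    truth_table = pd.DataFrame(labels).set_index("protein_id")
    return SpectralCountMatrix(counts, meta), truth_table


def write_apms(
    matrix: SpectralCountMatrix, truth_table: pd.DataFrame, out_dir
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "spectral_counts.tsv",
        "run_meta": out / "run_meta.tsv",
        "truth": out / "truth.tsv",
    }
    matrix.to_tsv(paths["counts"], paths["run_meta"])
    truth_table.to_csv(paths["truth"], sep="\t", index_label="protein_id")
    return paths


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------

@dataclass
class RnaseqTruthConfig:
    """Generating parameters for the four-condition RNA-seq design.

    ``baseline_rpkm`` sets each gene's expression in untransfected cells;
    ``tag_effects`` (log2) apply to every transfected condition (the
    transfection/tag artifact), ``bait_effects`` (log2) apply only to the
    bait-expressing conditions.  ``transgene`` = (endogenous gene index,
    shared exon positions within that gene, expression multiplier) adds
    cDNA reads to the shared exons in bait-expressing samples only.
    """

    n_genes: int
    gene_lengths: np.ndarray              # bases
    baseline_rpkm: np.ndarray
    library_sizes: dict[str, float] | float
    dispersion: float = 0.01
    tag_effects: dict[int, float] = field(default_factory=dict)
    bait_effects: dict[int, float] = field(default_factory=dict)
    transgene: tuple[int, tuple[int, ...], float] | None = None
    exons_per_gene: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=int)
        self.baseline_rpkm = np.asarray(self.baseline_rpkm, dtype=float)
        if (self.gene_lengths < 1).any():
            raise ValueError("gene lengths must be >= 1")
        if (self.baseline_rpkm < 0).any():
            raise ValueError("baseline expression must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.transgene is not None:
            gi, shared, mult = self.transgene
            if not 0 <= gi < self.n_genes:
                raise ValueError("transgene host gene index out of range")
            if not shared or max(shared) >= self.exons_per_gene:
                raise ValueError("shared exon positions out of range")
            if len(set(shared)) == self.exons_per_gene:
                raise ValueError(
                    "at least one exon must be transgene-free for the "
                    "endogenous estimator to exist"
                )
            if mult < 0:
                raise ValueError("transgene multiplier must be non-negative")


def default_rnaseq_truth(
    n_genes: int = 2000,
    n_tag_genes: int = 40,
    n_bait_genes: int = 23,
    transgene_multiplier: float = 30.0,
    seed: int = 0,
) -> RnaseqTruthConfig:
    """Planted truth mirroring the study's structure at reduced depth.

    A block of tag-responsive genes (transfection artifacts, |log2FC| in
    [1, 2]), a block of bait-specific genes changing by at least 1.6-fold
    and expressed above the 100-RPKM filter floor, and one highly expressed
    host gene whose first three (of four) exons are shared with a cDNA
    transgene expressed ~30-fold over the endogenous level, with a 1.4-fold
    endogenous suppression upon transfection.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.integers(500, 5000, size=n_genes)
    baseline = np.clip(rng.lognormal(mean=3.0, sigma=1.2, size=n_genes), 0.05, None)
    # gene 0 hosts the transgene at endogenous-gene-like expression
    baseline[0] = 800.0
    lengths[0] = 3600
    tag_idx = range(1, 1 + n_tag_genes)
    bait_idx = range(1 + n_tag_genes, 1 + n_tag_genes + n_bait_genes)
    tag_effects = {}
    for j, i in enumerate(tag_idx):
        sign = 1.0 if j % 2 == 0 else -1.0
        tag_effects[i] = sign * float(rng.uniform(1.0, 2.0))
    bait_effects = {}
    for j, i in enumerate(bait_idx):
        sign = 1.0 if j % 3 else -1.0
        bait_effects[i] = sign * float(rng.uniform(1.0, 1.8))
        baseline[i] = float(rng.uniform(150.0, 600.0))  # above the RPKM floor
    # endogenous host is suppressed 1.4-fold by transfection (tag effect)
    tag_effects[0] = -float(np.log2(1.4))
    return RnaseqTruthConfig(
        n_genes=n_genes,
        gene_lengths=lengths,
        baseline_rpkm=baseline,
        library_sizes=5e6,
        dispersion=0.01,
        tag_effects=tag_effects,
        bait_effects=bait_effects,
        transgene=(0, (0, 1, 2), transgene_multiplier),
        seed=seed,
    )


def default_groups(replicates: int = 3) -> dict[str, str]:
    """Sample-to-condition map: triplicates of each of the four conditions."""
    groups = {}
    for cond in RNASEQ_CONDITIONS:
        for r in range(1, replicates + 1):
            groups[f"{cond}_{r}"] = cond
    return groups


def _exon_lengths(total: int, k: int) -> np.ndarray:
    """Split a gene length into k contiguous exon lengths (fixed shares)."""
    shares = np.linspace(1.5, 0.5, k)
    shares /= shares.sum()
    lens = np.maximum((shares * total).astype(int), 1)
    lens[-1] += total - lens.sum()
    lens[-1] = max(lens[-1], 1)
    return lens


def simulate_rnaseq(
    truth: RnaseqTruthConfig, groups: dict[str, str]
) -> tuple[GeneCountTable, ExonCountTable, pd.DataFrame]:
    """Draw gene- and exon-level count tables with ground-truth labels.

    Exon counts are drawn per exon (mean proportional to exon length);
    gene counts are their sums, so gene and exon tables are consistent.
    Transgene reads are added only to the shared exons of the host gene in
    bait-expressing (WT / F115C) samples.
    """
    unknown = {s: c for s, c in groups.items() if c not in RNASEQ_CONDITIONS}
    if unknown:
        raise ValueError(f"samples mapped to unknown conditions: {unknown}")
    by_cond: dict[str, list[str]] = {c: [] for c in RNASEQ_CONDITIONS}
    for s, c in groups.items():
        by_cond[c].append(s)
    short = {c: len(v) for c, v in by_cond.items() if len(v) < 2}
    if short:
        raise ValueError(f"need >= 2 replicates per condition; got {short}")

    rng = np.random.default_rng(truth.seed)
    samples = list(groups)
    if isinstance(truth.library_sizes, dict):
        lib = {s: float(truth.library_sizes[s]) for s in samples}
    else:
        lib = {s: float(truth.library_sizes) for s in samples}

    k = truth.exons_per_gene
    exon_ids, ann_rows = [], []
    exon_len = np.empty((truth.n_genes, k), dtype=float)
    for g in range(truth.n_genes):
        lens = _exon_lengths(int(truth.gene_lengths[g]), k)
        exon_len[g] = lens
        pos = 0
        for e in range(k):
            exon_ids.append(f"G{g:05d}_E{e}")
            ann_rows.append(
                {
                    "exon_id": f"G{g:05d}_E{e}",
                    "chrom": "chr1",
                    "start": pos,
                    "end": pos + int(lens[e]),
                    "gene_id": f"G{g:05d}",
                }
            )
            pos += int(lens[e])
    annotation = pd.DataFrame(ann_rows).set_index("exon_id")
    gene_ids = [f"G{g:05d}" for g in range(truth.n_genes)]

    bait_conditions = {"WT", "F115C"}
    exon_counts = {}
    for s in samples:
        cond = groups[s]
        log2eff = np.zeros(truth.n_genes)
        if cond != "untransfected":
            for i, e in truth.tag_effects.items():
                log2eff[i] += e
        if cond in bait_conditions:
            for i, e in truth.bait_effects.items():
                log2eff[i] += e
        gene_rpkm = truth.baseline_rpkm * np.exp2(log2eff)
        # expected exon reads: rpkm * (exon_kb) * (lib millions)
        mu = gene_rpkm[:, None] * (exon_len / 1000.0) * (lib[s] / 1e6)
        if truth.transgene is not None and cond in bait_conditions:
            gi, shared, mult = truth.transgene
            extra = (
                mult
                * truth.baseline_rpkm[gi]
                * (exon_len[gi] / 1000.0)
                * (lib[s] / 1e6)
            )
            for e in shared:
                mu[gi, e] += extra[e]
        exon_counts[s] = _nb_draw(rng, mu.ravel(), truth.dispersion)
    exon_df = pd.DataFrame(exon_counts, index=exon_ids)
    gene_df = exon_df.groupby(annotation["gene_id"]).sum().loc[gene_ids]

    conditions = pd.Series(groups, name="condition")
    # The simulated genes stand for a subsample of the transcriptome; the
    # configured library size is the total mapped reads and is therefore the
    # RPKM denominator, not the column sum over the simulated subset.
    lib_series = pd.Series(lib, dtype=float)
    gene_table = GeneCountTable(
        counts=gene_df,
        gene_lengths=pd.Series(truth.gene_lengths, index=gene_ids, dtype=float),
        conditions=conditions,
        library_sizes=lib_series,
    )
    exon_table = ExonCountTable(
        counts=exon_df,
        annotation=annotation,
        conditions=conditions,
        library_sizes=lib_series.copy(),
    )

    labels = []
    for g, gid in enumerate(gene_ids):
        if truth.transgene is not None and g == truth.transgene[0]:
            label = "transgene_host"
        elif g in truth.bait_effects:
            label = "bait_specific"
        elif g in truth.tag_effects:
            label = "tag_responsive"
        else:
            label = "background"
        labels.append(
            {
                "gene_id": gid,
                "label": label,
                "tag_log2fc": truth.tag_effects.get(g, 0.0),
                "bait_log2fc": truth.bait_effects.get(g, 0.0),
            }
        )
    truth_table = pd.DataFrame(labels).set_index("gene_id")
    return gene_table, exon_table, truth_table
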