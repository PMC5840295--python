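"""RNA-seq filters: RPKM, a lightweight NB differential-expression test,
the transfection-artifact filter cascade, endogenous-vs-transgene
expression, and replicate concordance.

The experimental design behind these tools is a transient-transfection
study with four conditions — untransfected cells, cells expressing the
fluorescent tag (YFP) alone, and cells expressing a tagged bait (wild-type
or mutant).  Genes that respond to the tag alone are transfection
artifacts; the cascade keeps genes that change specifically when the bait
is expressed, are not tag-responsive, and are expressed above an RPKM
floor.  Because the transfected cDNA transgene shares coding exons with
the endogenous gene, the endogenous transcript level is estimated from
reads on the exons the transgene does not contain.

The differential test is a documented lightweight stand-in for a full
count-model package: per-gene negative-binomial likelihood-ratio test with
a single moment-matched common dispersion and library-size normalisation.
The filter cascade also accepts externally computed (log2FC, adj_p) tables
so output from a dedicated DE package can be plugged in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .saint import nb_logpmf

__all__ = [
    "GeneCountTable",
    "ExonCountTable",
    "FilterConfig",
    "rpkm",
    "nb_de_test",
    "bh_adjust",
    "matr3_specific_filter",
    "endogenous_expression",
    "fold_reduction",
    "pairwise_pearson",
]


@dataclass
class GeneCountTable:
    """Read counts (genes x samples) with gene lengths and condition labels.

    ``library_sizes`` defaults to column sums when not supplied.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series           # bases
    conditions: pd.Series             # sample -> condition label
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.gene_lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 base")
        missing = self.counts.columns.difference(self.conditions.index)
        if len(missing):
            raise ValueError(f"samples without condition labels: {list(missing)}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)

    def samples_for(self, condition: str) -> list[str]:
        return [
            s for s in self.counts.columns if self.conditions.loc[s] == condition
        ]

    def condition_mean_rpkm(self) -> pd.DataFrame:
        """Mean RPKM per condition (genes x conditions)."""
        r = rpkm(self)
        cond = {c: r[self.samples_for(c)].mean(axis=1)
                for c in pd.unique(self.conditions.loc[self.counts.columns])}
        return pd.DataFrame(cond)


@dataclass
class ExonCountTable:
    """Exon-level read counts with a BED-like annotation.

    ``annotation`` is indexed by exon id with columns ``chrom``, ``start``,
    ``end`` (0-based half-open) and ``gene_id``; exon length = end - start.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    conditions: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("chrom", "start", "end", "gene_id"):
            if col not in self.annotation.columns:
                raise ValueError(f"annotation missing column '{col}'")
        if (self.annotation["end"] <= self.annotation["start"]).any():
            raise ValueError("exon end must exceed start (0-based half-open)")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)

    @property
    def exon_lengths(self) -> pd.Series:
        return (self.annotation["end"] - self.annotation["start"]).astype(float)

    def exons_of(self, gene_id: str) -> pd.Index:
        return self.annotation.index[self.annotation["gene_id"] == gene_id]


@dataclass
class FilterConfig:
    """Thresholds of the transfection-artifact filter cascade."""

    primary_lfc: float = 1.0       # |log2FC| bound for the artifact comparison
    primary_alpha: float = 0.01    # adjusted-p bound, artifact comparison
    secondary_alpha: float = 0.05  # adjusted-p bound, bait-specific comparison
    specific_fold: float = 1.6     # linear fold bound, bait-specific comparison
    min_rpkm: float = 100.0        # expression floor on the max condition mean

    def __post_init__(self) -> None:
        if not (0 < self.primary_alpha < 1 and 0 < self.secondary_alpha < 1):
            raise ValueError("alphas must be in (0, 1)")
        if self.primary_lfc <= 0 or self.specific_fold <= 0 or self.min_rpkm < 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def rpkm(table: GeneCountTable) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    lib = table.library_sizes.loc[table.counts.columns]
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"library sizes must be positive; offending: {bad}")
    kb = table.gene_lengths.loc[table.counts.index].astype(float) / 1000.0
    millions = lib.astype(float) / 1e6
    return table.counts.div(kb, axis=0).div(millions, axis=1)


# ---------------------------------------------------------------------------
# NB likelihood-ratio DE test
# ---------------------------------------------------------------------------

def _moment_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Common dispersion alpha pooled over genes: sum(var-mean)/sum(mean^2)."""
    num = 0.0
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float((v - m).sum())
        den += float((m**2).sum())
    if den == 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 10.0))


def nb_de_test(
    table: GeneCountTable,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential expression of ``condition_a`` relative to ``condition_b``.

    Per gene: log2FC of library-size-normalised means (pseudocount added),
    and a likelihood-ratio p-value from a negative-binomial model with a
    common moment-matched dispersion (null: one mean shared by both
    conditions; alternative: one mean per condition; library sizes enter as
    offsets).  Returns a DataFrame with ``log2FC``, ``p``, ``adj_p`` (BH)
    and the mean RPKM of each condition.
    """
    sa = table.samples_for(condition_a)
    sb = table.samples_for(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition; got {len(sa)} for "
            f"'{condition_a}' and {len(sb)} for '{condition_b}'"
        )
    samples = sa + sb
    x = table.counts[samples].to_numpy(dtype=float)
    lib = table.library_sizes.loc[samples].to_numpy(dtype=float)
    offsets = lib / lib.mean()
    norm = x / offsets

    ia = np.arange(len(sa))
    ib = np.arange(len(sa), len(samples))
    alpha = _moment_dispersion(norm, [ia, ib])

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    # expected-count rates under null and alternative (offset-weighted means)
    q0 = x.sum(axis=1) / offsets.sum()
    qa = x[:, ia].sum(axis=1) / offsets[ia].sum()
    qb = x[:, ib].sum(axis=1) / offsets[ib].sum()

    eps = 1e-8
    mu0 = np.maximum(q0[:, None] * offsets[None, :], eps)
    mu1 = np.maximum(
        np.concatenate(
            [qa[:, None] * offsets[None, ia], qb[:, None] * offsets[None, ib]],
            axis=1,
        ),
        eps,
    )
    ll0 = nb_logpmf(x, mu0, alpha).sum(axis=1)
    ll1 = nb_logpmf(x, mu1, alpha).sum(axis=1)
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    r = rpkm(table)
    out = pd.DataFrame(index=table.counts.index)
    out["log2FC"] = log2fc
    out["p"] = p
    out["adj_p"] = bh_adjust(p)
    out[f"mean_rpkm_{condition_a}"] = r[sa].mean(axis=1)
    out[f"mean_rpkm_{condition_b}"] = r[sb].mean(axis=1)
    out.attrs["dispersion"] = alpha
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# transfection-artifact filter cascade
# ---------------------------------------------------------------------------

def matr3_specific_filter(
    de_bait_vs_tag: pd.DataFrame,
    de_tag_vs_untransfected: pd.DataFrame,
    condition_mean_rpkm: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> pd.Index:
    """Genes changing specifically under the bait, not the tag alone.

    Keeps genes that (1) change by >= ``specific_fold`` (linear, either
    direction) with adjusted p <= ``secondary_alpha`` in the bait-vs-tag
    comparison, (2) are NOT significant transfection artifacts
    (|log2FC| >= ``primary_lfc`` and adjusted p <= ``primary_alpha``) in
    the tag-vs-untransfected comparison, and (3) reach ``min_rpkm`` in at
    least one condition mean.  Gene universes of the two DE tables must
    match.
    """
    cfg = cfg or FilterConfig()
    if not de_bait_vs_tag.index.sort_values().equals(
        de_tag_vs_untransfected.index.sort_values()
    ):
        raise ValueError("gene universes of the two DE tables differ")
    lfc_specific = np.log2(cfg.specific_fold)
    specific = (de_bait_vs_tag["log2FC"].abs() >= lfc_specific) & (
        de_bait_vs_tag["adj_p"] <= cfg.secondary_alpha
    )
    artifact = (de_tag_vs_untransfected["log2FC"].abs() >= cfg.primary_lfc) & (
        de_tag_vs_untransfected["adj_p"] <= cfg.primary_alpha
    )
    expressed = condition_mean_rpkm.max(axis=1) >= cfg.min_rpkm
    keep = specific & ~artifact.loc[specific.index] & expressed.loc[specific.index]
    return keep.index[keep].sort_values()


# ---------------------------------------------------------------------------
# endogenous expression behind a co-expressed transgene
# ---------------------------------------------------------------------------

def endogenous_expression(
    exon_table: ExonCountTable,
    gene_id: str,
    transgene_shared_exons,
) -> pd.Series:
    """Per-sample endogenous RPKM from exons absent from the transgene.

    The transfected cDNA contributes reads only to the exons it contains;
    restricting the RPKM formula to the gene's remaining exons (summed
    counts over summed length) estimates the endogenous transcript level.
    Raises when no exon of the gene lies outside the shared set.
    """
    shared = set(transgene_shared_exons)
    exons = exon_table.exons_of(gene_id)
    if len(exons) == 0:
        raise ValueError(f"gene '{gene_id}' has no exons in the annotation")
    own = [e for e in exons if e not in shared]
    if not own:
        raise ValueError(
            f"all exons of '{gene_id}' are shared with the transgene; "
            "the endogenous level cannot be separated"
        )
    lengths = exon_table.exon_lengths.loc[own]
    kb = float(lengths.sum()) / 1000.0
    reads = exon_table.counts.loc[own].sum(axis=0)
    millions = exon_table.library_sizes.loc[reads.index].astype(float) / 1e6
    return reads / kb / millions


def fold_reduction(mean_a: float, mean_b: float) -> float:
    """Ratio mean_a / mean_b rounded to 1 decimal."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    return round(mean_a / mean_b, 1)


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

def pairwise_pearson(
    rpkm_table: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """All pairwise Pearson correlations between samples, clustered.

    Returns the symmetric correlation matrix (unit diagonal), the
    deterministic leaf order from average-linkage clustering on 1 - r, and
    the linkage matrix.  A zero-variance sample makes the correlation
    undefined and is rejected.
    """
    if rpkm_table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = rpkm_table.std(axis=0, ddof=0)
    flat = list(sd.index[sd == 0])
    if flat:
        raise ValueError(f"zero-variance samples (correlation undefined): {flat}")
    corr = rpkm_table.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [corr.columns[i] for i in hierarchy.leaves_list(link)]
    return corr, order, link
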