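"""Per-prey enrichment statistics for label-free AP-MS spectral counts.

A tagged bait is affinity-captured alongside mock (control) captures; the
number of MS/MS spectra assigned to each prey protein in each run is a proxy
for its abundance in the capture.  This module computes, per prey:

* fold change of mean bait counts over mean control counts (pseudocounted),
* a one-sided Welch t-test (bait > control) on replicate counts,
* a per-run G-test of over-representation against the pooled controls,
* bait-level correction factors that compensate for different amounts of
  captured bait between constructs, and their application to prey counts.

The G-test compares a 2x2 table (spectra for this prey vs. all other spectra,
in a bait run vs. the pooled controls).  Each bait run is tested against the
pooled controls: the pairing of bait and control runs is not part of the
experimental design, and pooling maximises control depth while staying
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTROL_LABEL = "control"

__all__ = [
    "SpectralCountMatrix",
    "EnrichmentRecord",
    "CorrectionFactors",
    "read_matrix",
    "pool_controls",
    "g_test",
    "g_test_arrays",
    "fold_change",
    "welch_t",
    "enrichment_table",
    "bait_correction",
    "apply_correction",
]


@dataclass
class SpectralCountMatrix:
    """Spectral counts (proteins x runs) with per-run metadata.

    ``counts`` is indexed by protein id with one column per run id; entries
    are non-negative (integers as generated, reals after correction).
    ``run_meta`` is indexed by run id with columns ``construct``, ``batch``
    and ``replicate``.
    """

    counts: pd.DataFrame
    run_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("spectral counts must be non-negative")
        missing = [r for r in self.counts.columns if r not in self.run_meta.index]
        if missing:
            raise ValueError(f"runs without metadata: {missing}")
        if "construct" not in self.run_meta.columns:
            raise ValueError("run_meta must have a 'construct' column")

    @property
    def protein_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def constructs(self) -> list[str]:
        order: list[str] = []
        for run in self.counts.columns:
            c = self.run_meta.loc[run, "construct"]
            if c not in order:
                order.append(c)
        return order

    def runs_for(self, construct: str) -> list[str]:
        """Run ids with the given construct label, in column order."""
        return [
            r
            for r in self.counts.columns
            if self.run_meta.loc[r, "construct"] == construct
        ]

    def submatrix(self, constructs: list[str]) -> "SpectralCountMatrix":
        runs = [r for c in constructs for r in self.runs_for(c)]
        return SpectralCountMatrix(self.counts[runs], self.run_meta.loc[runs])

    def to_tsv(self, counts_path, meta_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="protein_id")
        self.run_meta.to_csv(meta_path, sep="\t", index_label="run_id")


def read_matrix(counts_path, meta_path) -> SpectralCountMatrix:
    """Read a tab-separated count matrix and its run-metadata table."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="protein_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="run_id")
    return SpectralCountMatrix(counts, meta)


@dataclass
class EnrichmentRecord:
    """Enrichment summary for one prey against the pooled controls."""

    protein_id: str
    fold_change: float
    t_p: float
    per_run_G: list[tuple[str, float, float]]
    n_runs_significant: int


@dataclass
class CorrectionFactors:
    """Multiplicative bait-level normalisation per construct.

    Factors are stored at full precision and applied at full precision;
    ``rounded`` gives the one-decimal view used for reporting.
    """

    factors: dict[str, float]
    reference: str

    def __post_init__(self) -> None:
        if self.factors.get(self.reference) != 1.0:
            raise ValueError("reference construct must have factor 1")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("correction factors must be positive")

    @property
    def rounded(self) -> dict[str, float]:
        return {c: round(f, 1) for c, f in self.factors.items()}


# ---------------------------------------------------------------------------
# control pooling
# ---------------------------------------------------------------------------

def pool_controls(
    matrix: SpectralCountMatrix, control_label: str = CONTROL_LABEL
) -> tuple[pd.Series, float]:
    """Sum counts across control runs.

    Returns the per-protein pooled control count and the pooled control
    total (sum of control column totals).  Raises if there is no control
    run or the pooled total is zero.
    """
    runs = matrix.runs_for(control_label)
    if not runs:
        raise ValueError(
            f"no runs labelled '{control_label}' in the matrix; control captures "
            "are required for enrichment statistics"
        )
    pooled = matrix.counts[runs].sum(axis=1)
    total = float(pooled.sum())
    if total == 0:
        raise ValueError("pooled control total is zero; cannot form proportions")
    return pooled, total


# ---------------------------------------------------------------------------
# G-test
# ---------------------------------------------------------------------------

def _xlogx(x: np.ndarray) -> np.ndarray:
    # x*ln(x) with the limit 0 at x=0
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def g_test_arrays(
    k_bait, n_bait, k_ctrl, n_ctrl
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised G-test on 2x2 tables (prey vs rest) x (bait vs control).

    G = 2 * sum O ln(O/E) over the four cells, zero-count cells contributing
    zero; p from chi-square with 1 df.  Accepts real-valued (corrected)
    counts.
    """
    k1, n1, k2, n2 = np.broadcast_arrays(
        np.asarray(k_bait, dtype=float),
        np.asarray(n_bait, dtype=float),
        np.asarray(k_ctrl, dtype=float),
        np.asarray(n_ctrl, dtype=float),
    )
    if np.any(k1 > n1) or np.any(k2 > n2):
        raise ValueError("prey count exceeds the run total")
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("totals must be positive")
    obs = np.stack([k1, n1 - k1, k2, n2 - k2])
    # G = 2 [ sum O ln O - sum(row tot ln row tot) - sum(col tot ln col tot)
    #         + N ln N ]  -- identical to 2*sum O ln(O/E) with margin E's
    rows = np.stack([k1 + k2, (n1 - k1) + (n2 - k2)])
    cols = np.stack([n1, n2])
    n = n1 + n2
    g = 2.0 * (
        _xlogx(obs).sum(axis=0)
        - _xlogx(rows).sum(axis=0)
        - _xlogx(cols).sum(axis=0)
        + _xlogx(n)
    )
    g = np.maximum(g, 0.0)  # guard tiny negative round-off
    p = stats.chi2.sf(g, df=1)
    return g, p


def g_test(
    prey_count_bait: float,
    total_bait: float,
    prey_count_ctrl: float,
    total_ctrl: float,
) -> tuple[float, float]:
    """G-test for one prey in one bait run against the (pooled) controls.

    Returns ``(G, p)`` where p is the two-sided chi-square tail; callers
    flag significance one-sidedly by additionally requiring the bait
    proportion to exceed the control proportion.
    """
    g, p = g_test_arrays(
        [prey_count_bait], [total_bait], [prey_count_ctrl], [total_ctrl]
    )
    return float(g[0]), float(p[0])


# ---------------------------------------------------------------------------
# fold change and t-test
# ---------------------------------------------------------------------------

def fold_change(bait_counts, ctrl_counts, pseudocount: float = 0.5) -> float:
    """(mean bait + pseudocount) / (mean control + pseudocount)."""
    bait = np.asarray(bait_counts, dtype=float)
    ctrl = np.asarray(ctrl_counts, dtype=float)
    if bait.size == 0 or ctrl.size == 0:
        raise ValueError("replicate lists must be non-empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = ctrl.mean() + pseudocount
    if denom == 0:
        raise ValueError(
            "control mean plus pseudocount is zero; set pseudocount > 0 to "
            "compute a finite fold change for preys absent from controls"
        )
    return float((bait.mean() + pseudocount) / denom)


def welch_t(bait_counts, ctrl_counts, alternative: str = "greater") -> float:
    """One-sided Welch t-test p-value for bait counts exceeding control counts.

    Requires >= 2 replicates per group.  If both groups have zero variance the
    t statistic is undefined; the deterministic limit is returned (0.5 for
    equal means, 0 or 1 for a strict ordering).
    """
    bait = np.asarray(bait_counts, dtype=float)
    ctrl = np.asarray(ctrl_counts, dtype=float)
    if bait.size < 2 or ctrl.size < 2:
        raise ValueError(
            "Welch t-test needs at least 2 replicates in each group; got "
            f"{bait.size} bait and {ctrl.size} control"
        )
    if bait.var(ddof=1) == 0 and ctrl.var(ddof=1) == 0:
        d = bait.mean() - ctrl.mean()
        if alternative == "greater":
            return 0.5 if d == 0 else (0.0 if d > 0 else 1.0)
        return 1.0 if d == 0 else 0.0
    res = stats.ttest_ind(bait, ctrl, equal_var=False, alternative=alternative)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# per-construct enrichment table
# ---------------------------------------------------------------------------

def enrichment_table(
    matrix: SpectralCountMatrix,
    construct: str,
    control_label: str = CONTROL_LABEL,
    pseudocount: float = 0.5,
    g_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-prey enrichment statistics for one bait construct.

    Returns a DataFrame indexed by protein id with columns ``fold_change``,
    ``t_p``, ``n_runs_significant`` and one ``g_p_<run>`` column per bait
    run.  A run counts as significant when its G-test p is <= ``g_alpha``
    AND the prey's share of spectra in that run exceeds its share in the
    pooled controls (one-sided over-representation).
    """
    bait_runs = matrix.runs_for(construct)
    if not bait_runs:
        raise ValueError(f"no runs for construct '{construct}'")
    ctrl_runs = matrix.runs_for(control_label)
    pooled, pooled_total = pool_controls(matrix, control_label)

    bait = matrix.counts[bait_runs]
    ctrl = matrix.counts[ctrl_runs]

    out = pd.DataFrame(index=matrix.protein_ids)
    out["fold_change"] = [
        fold_change(bait.loc[p].to_numpy(), ctrl.loc[p].to_numpy(), pseudocount)
        for p in matrix.protein_ids
    ]
    if len(bait_runs) >= 2 and len(ctrl_runs) >= 2:
        out["t_p"] = [
            welch_t(bait.loc[p].to_numpy(), ctrl.loc[p].to_numpy())
            for p in matrix.protein_ids
        ]
    else:
        out["t_p"] = np.nan

    nsig = np.zeros(len(out), dtype=int)
    ctrl_prop = pooled.to_numpy() / pooled_total
    for run in bait_runs:
        col = bait[run].to_numpy(dtype=float)
        total = float(col.sum())
        if total == 0:
            raise ValueError(f"run '{run}' has zero total spectra")
        _, p = g_test_arrays(col, total, pooled.to_numpy(), pooled_total)
        out[f"g_p_{run}"] = p
        nsig += (p <= g_alpha) & (col / total > ctrl_prop)
    out["n_runs_significant"] = nsig
    return out


def records_from_table(table: pd.DataFrame) -> list[EnrichmentRecord]:
    """Convert an enrichment table into per-prey records."""
    g_cols = [c for c in table.columns if c.startswith("g_p_")]
    recs = []
    for pid, row in table.iterrows():
        per_run = [(c[len("g_p_"):], float("nan"), float(row[c])) for c in g_cols]
        recs.append(
            EnrichmentRecord(
                protein_id=pid,
                fold_change=float(row["fold_change"]),
                t_p=float(row["t_p"]),
                per_run_G=per_run,
                n_runs_significant=int(row["n_runs_significant"]),
            )
        )
    return recs


# ---------------------------------------------------------------------------
# bait-level normalisation
# ---------------------------------------------------------------------------

def bait_correction(
    matrix: SpectralCountMatrix,
    bait_protein_id: str,
    reference_construct: str,
    control_label: str = CONTROL_LABEL,
) -> CorrectionFactors:
    """Correction factors from the bait's own spectral counts.

    factor(construct) = mean bait counts in the reference construct's runs /
    mean bait counts in that construct's runs.  Different constructs capture
    different amounts of bait; multiplying a construct's prey counts by its
    factor puts them on the reference construct's capture scale.  Controls
    (mock captures with no bait) get factor 1.
    """
    if bait_protein_id not in matrix.protein_ids:
        raise ValueError(f"bait protein '{bait_protein_id}' not in matrix")
    bait_row = matrix.counts.loc[bait_protein_id]
    ref_runs = matrix.runs_for(reference_construct)
    if not ref_runs:
        raise ValueError(f"no runs for reference construct '{reference_construct}'")
    ref_mean = float(bait_row[ref_runs].mean())
    factors: dict[str, float] = {}
    for construct in matrix.constructs:
        if construct == control_label:
            factors[construct] = 1.0
            continue
        mean = float(bait_row[matrix.runs_for(construct)].mean())
        if mean == 0:
            raise ValueError(
                f"bait has zero mean spectral counts in construct '{construct}'; "
                "cannot derive a capture-level correction factor"
            )
        factors[construct] = ref_mean / mean
    factors[reference_construct] = 1.0
    return CorrectionFactors(factors=factors, reference=reference_construct)


def apply_correction(
    matrix: SpectralCountMatrix,
    factors: CorrectionFactors,
    bait_protein_id: str | None = None,
) -> SpectralCountMatrix:
    """Multiply each construct's prey counts by its correction factor.

    The bait's own row, when given, is left unscaled (the factors were
    derived from it).  Output counts are non-negative reals carried at full
    precision for downstream statistics.
    """
    missing = [c for c in matrix.constructs if c not in factors.factors]
    if missing:
        raise ValueError(f"no correction factor for constructs: {missing}")
    corrected = matrix.counts.astype(float).copy()
    for construct in matrix.constructs:
        runs = matrix.runs_for(construct)
        corrected[runs] = corrected[runs] * factors.factors[construct]
    if bait_protein_id is not None:
        corrected.loc[bait_protein_id] = matrix.counts.loc[bait_protein_id].astype(
            float
        )
    return SpectralCountMatrix(corrected, matrix.run_meta.copy())
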