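"""Consensus interactor calls, domain-deletion dependence, network export.

A prey is called an interactor of a bait construct only when it passes every
one of four criteria: mean fold change over controls >= 2, one-sided t-test
p <= 0.05, G-test over-representation in at least 2 runs, and SAINT-style
score >= 0.90.  Domain dependence compares each WT-called prey's
capture-corrected counts under each deletion construct with its WT counts,
classifying the pair as reduced (ratio <= 0.5 with at least one significant
run), enhanced (ratio >= 2, same rule) or unchanged, and marking selective
losses/gains (no comparable trend in any other deletion).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import SpectralCountMatrix, g_test_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "CallCriteria",
    "InteractionCall",
    "DomainDependenceRecord",
    "call_interactors",
    "classify_domain_dependence",
    "export_network",
]


@dataclass
class CallCriteria:
    """Thresholds of the consensus interactor-calling rule."""

    min_fold: float = 2.0
    max_t_p: float = 0.05
    min_significant_runs: int = 2
    min_saint: float = 0.90
    g_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.min_fold > 0 and 0 < self.max_t_p <= 1):
            raise ValueError("invalid fold/t-test thresholds")
        if not (0 <= self.min_saint <= 1 and 0 < self.g_alpha <= 1):
            raise ValueError("invalid SAINT/G thresholds")
        if self.min_significant_runs < 0:
            raise ValueError("min_significant_runs must be >= 0")


@dataclass
class InteractionCall:
    protein_id: str
    construct: str
    called: bool
    criteria_passed: dict[str, bool]
    fold_change: float
    saint_score: float


@dataclass
class DomainDependenceRecord:
    """Per-prey normalized fold ratios and classes across deletion constructs."""

    protein_id: str
    ratios: dict[str, float]
    classes: dict[str, str]          # construct -> reduced|enhanced|unchanged
    selective_reduced: bool
    selective_enhanced: bool
    reduced_in: tuple[str, ...] = field(default_factory=tuple)
    enhanced_in: tuple[str, ...] = field(default_factory=tuple)


def call_interactors(
    records: pd.DataFrame,
    scores: pd.DataFrame,
    criteria: CallCriteria,
    construct: str = "WT",
) -> pd.DataFrame:
    """Combine enrichment statistics and SAINT-style scores into calls.

    ``records`` is an enrichment table (``fold_change``, ``t_p``,
    ``n_runs_significant``); ``scores`` carries ``saint_score``.  Both must
    cover the same protein set.  Returns one row per protein with the four
    per-criterion booleans and ``called`` = their conjunction.
    """
    only_rec = records.index.difference(scores.index)
    only_sc = scores.index.difference(records.index)
    if len(only_rec) or len(only_sc):
        raise ValueError(
            "protein sets differ between enrichment records and scores; "
            f"records-only={list(only_rec[:5])}, scores-only={list(only_sc[:5])}"
        )
    out = pd.DataFrame(index=records.index.sort_values())
    out["construct"] = construct
    out["fold_change"] = records["fold_change"]
    out["saint_score"] = scores["saint_score"]
    out["pass_fold"] = records["fold_change"] >= criteria.min_fold
    out["pass_t"] = records["t_p"] <= criteria.max_t_p
    out["pass_runs"] = records["n_runs_significant"] >= criteria.min_significant_runs
    out["pass_saint"] = scores["saint_score"] >= criteria.min_saint
    out["called"] = (
        out["pass_fold"] & out["pass_t"] & out["pass_runs"] & out["pass_saint"]
    )
    return out


def calls_to_records(calls: pd.DataFrame) -> list[InteractionCall]:
    return [
        InteractionCall(
            protein_id=pid,
            construct=row["construct"],
            called=bool(row["called"]),
            criteria_passed={
                k: bool(row[k])
                for k in ("pass_fold", "pass_t", "pass_runs", "pass_saint")
            },
            fold_change=float(row["fold_change"]),
            saint_score=float(row["saint_score"]),
        )
        for pid, row in calls.iterrows()
    ]


def classify_domain_dependence(
    wt_called: list[str],
    corrected: SpectralCountMatrix,
    deletion_constructs: list[str],
    wt_construct: str = "WT",
    g_alpha: float = 0.05,
    reduced_ratio: float = 0.5,
    enhanced_ratio: float = 2.0,
) -> list[DomainDependenceRecord]:
    """Classify each WT-called prey's dependence on each deleted domain.

    ``corrected`` must already carry capture-corrected counts
    (apply_correction).  For each prey and deletion construct the ratio is
    corrected deletion mean / WT mean.  ``reduced`` needs ratio <=
    ``reduced_ratio`` plus G-test significance (deletion run vs pooled WT,
    under-representation) in >= 1 deletion run; ``enhanced`` is symmetric
    with ratio >= ``enhanced_ratio`` and over-representation.  Selective
    reduction for the set S of reduced constructs requires every construct
    outside S to show no >2-fold downward trend (ratio > reduced_ratio);
    selective enhancement mirrors this with ratio < enhanced_ratio.
    Preys with zero WT mean are skipped with a warning.
    """
    wt_runs = corrected.runs_for(wt_construct)
    if not wt_runs:
        raise ValueError(f"no runs for WT construct '{wt_construct}'")
    for c in deletion_constructs:
        if not corrected.runs_for(c):
            raise ValueError(f"no runs for deletion construct '{c}'")

    wt = corrected.counts[wt_runs]
    wt_pooled = wt.sum(axis=1)
    wt_total = float(wt_pooled.sum())
    wt_prop = wt_pooled / wt_total

    records: list[DomainDependenceRecord] = []
    skipped: list[str] = []
    for pid in sorted(wt_called):
        wt_mean = float(wt.loc[pid].mean())
        if wt_mean == 0:
            skipped.append(pid)
            continue
        ratios: dict[str, float] = {}
        classes: dict[str, str] = {}
        for construct in deletion_constructs:
            runs = corrected.runs_for(construct)
            cols = corrected.counts.loc[pid, runs].to_numpy(dtype=float)
            totals = corrected.counts[runs].sum(axis=0).to_numpy(dtype=float)
            ratio = float(cols.mean() / wt_mean)
            _, p = g_test_arrays(cols, totals, float(wt_pooled.loc[pid]), wt_total)
            props = cols / totals
            n_under = int(((p <= g_alpha) & (props < wt_prop.loc[pid])).sum())
            n_over = int(((p <= g_alpha) & (props > wt_prop.loc[pid])).sum())
            ratios[construct] = ratio
            if ratio <= reduced_ratio and n_under >= 1:
                classes[construct] = "reduced"
            elif ratio >= enhanced_ratio and n_over >= 1:
                classes[construct] = "enhanced"
            else:
                classes[construct] = "unchanged"
        reduced_in = tuple(c for c in deletion_constructs if classes[c] == "reduced")
        enhanced_in = tuple(c for c in deletion_constructs if classes[c] == "enhanced")
        sel_red = bool(reduced_in) and all(
            ratios[c] > reduced_ratio
            for c in deletion_constructs
            if c not in reduced_in
        )
        sel_enh = bool(enhanced_in) and all(
            ratios[c] < enhanced_ratio
            for c in deletion_constructs
            if c not in enhanced_in
        )
        records.append(
            DomainDependenceRecord(
                protein_id=pid,
                ratios=ratios,
                classes=classes,
                selective_reduced=sel_red,
                selective_enhanced=sel_enh,
                reduced_in=reduced_in,
                enhanced_in=enhanced_in,
            )
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} preys with zero WT mean: {skipped[:5]}",
            stacklevel=2,
        )
    return records


def dependence_table(records: list[DomainDependenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {"protein_id": r.protein_id}
        for c, ratio in r.ratios.items():
            row[f"ratio_{c}"] = ratio
            row[f"class_{c}"] = r.classes[c]
        row["selective_reduced"] = r.selective_reduced
        row["selective_enhanced"] = r.selective_enhanced
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein_id")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def _shade(fold: pd.Series) -> pd.Series:
    """Monotone map of fold change to a shade value in (0, 1].

    Uses log-scaled min-max normalisation over the called preys so shading
    spreads over the observed dynamic range.
    """
    lf = np.log2(fold.astype(float))
    lo, hi = float(lf.min()), float(lf.max())
    if hi == lo:
        return pd.Series(1.0, index=fold.index)
    return 0.1 + 0.9 * (lf - lo) / (hi - lo)


def export_network(
    calls: pd.DataFrame,
    out_dir,
    bait_label: str = "BAIT",
    interaction_type: str = "pp",
) -> dict[str, Path]:
    """Write the called bait-prey network as SIF, GraphML and node TSV.

    Nodes carry ``fold_change``, ``saint_score`` and a ``shade`` value
    mapped monotonically from fold change (higher fold = higher shade).
    Output ordering is deterministic (protein id ascending); an empty call
    set writes header-only files with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    called = calls[calls["called"]].sort_index()
    paths = {
        "sif": out_dir / "network.sif",
        "graphml": out_dir / "network.graphml",
        "nodes": out_dir / "nodes.tsv",
    }
    if called.empty:
        logger.warning("no called interactions; writing empty network files")
        paths["sif"].write_text("")
        nx.write_graphml(nx.Graph(), paths["graphml"])
        pd.DataFrame(
            columns=["protein_id", "fold_change", "saint_score", "shade"]
        ).to_csv(paths["nodes"], sep="\t", index=False)
        return paths

    shade = _shade(called["fold_change"])
    with open(paths["sif"], "w") as fh:
        for pid in called.index:
            fh.write(f"{bait_label}\t{interaction_type}\t{pid}\n")

    g = nx.Graph()
    g.add_node(bait_label, node_type="bait")
    for pid in called.index:
        g.add_node(
            pid,
            node_type="prey",
            fold_change=float(called.loc[pid, "fold_change"]),
            saint_score=float(called.loc[pid, "saint_score"]),
            shade=float(shade.loc[pid]),
        )
        g.add_edge(bait_label, pid, interaction=interaction_type)
    nx.write_graphml(g, paths["graphml"])

    nodes = pd.DataFrame(
        {
            "protein_id": called.index,
            "fold_change": called["fold_change"].to_numpy(),
            "saint_score": called["saint_score"].to_numpy(),
            "shade": shade.to_numpy(),
        }
    )
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    return paths
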