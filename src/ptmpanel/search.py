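"""Exhaustive enumeration and scoring of protease combinations, plus the
multi-protein summarizer and ranking.

Enumeration is exhaustive (no pruning): realistic panels (<= 14 agents,
<= 6 parallel digestions) stay below ten thousand combinations.
"""

from __future__ import annotations

from itertools import combinations as _combinations
from typing import Mapping, Sequence

import pandas as pd

from .filters import FilterConfig
from .io_formats import PredictionTable, ProteinRecord, TargetList
from .proteases import DigestionSetting, ProteaseRule
from .scoring import ScoreRecord, score_setting

SCORE_COLUMNS = [
    "combination",
    "n_proteases",
    "maximal",
    "etd",
    "cid",
    "predicted_matched",
    "predicted_unmatched",
    "mono_modified_count",
    "n_targets_covered",
    "covered_positions",
    "uncovered_positions",
]


def enumerate_combinations(
    panel: Sequence[ProteaseRule] | Sequence[str], max_size: int
) -> list[tuple]:
    """All subsets of 1..max_size proteases, each sorted by name, the list
    ordered by (size, lexicographic label)."""
    names = sorted(r.name if isinstance(r, ProteaseRule) else str(r) for r in panel)
    if len(set(names)) != len(names):
        raise ValueError("duplicate protease names in panel")
    if not 1 <= max_size <= len(names):
        raise ValueError(
            f"max_size {max_size} outside [1, panel size {len(names)}]"
        )
    out: list[tuple] = []
    for k in range(1, max_size + 1):
        out.extend(sorted(_combinations(names, k)))
    return out


def score_all_combinations(
    protein: ProteinRecord,
    panel: Sequence[ProteaseRule],
    config: FilterConfig,
    prediction_table: PredictionTable | None = None,
    targets: TargetList | None = None,
    max_size: int | None = None,
    missed_cleavages: Mapping[str, int] | None = None,
) -> list[ScoreRecord]:
    """Score every combination of 1..max_size proteases from the panel.

    ``missed_cleavages`` optionally overrides per-protease allowances.
    Output order matches :func:`enumerate_combinations`; identical inputs
    give identical outputs (no randomness anywhere in the pipeline).
    """
    if max_size is None:
        max_size = len(panel)
    records = []
    for combo in enumerate_combinations(panel, max_size):
        setting = DigestionSetting(
            combination=combo, missed_cleavages=missed_cleavages or {}
        )
        records.append(
            score_setting(
                protein,
                setting,
                config,
                prediction_table=prediction_table,
                targets=targets,
                panel=panel,
            )
        )
    return records


def scores_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Tabulate score records, one row per combination, ordered by
    (panel size, label)."""
    rows = [
        {
            "combination": r.label,
            "n_proteases": r.n_proteases,
            "maximal": r.maximal,
            "etd": r.etd,
            "cid": r.cid,
            "predicted_matched": r.predicted_matched,
            "predicted_unmatched": r.predicted_unmatched,
            "mono_modified_count": r.mono_modified_count,
            "n_targets_covered": len(r.targets_covered),
            "covered_positions": ";".join(map(str, sorted(r.targets_covered))),
            "uncovered_positions": ";".join(map(str, sorted(r.targets_uncovered))),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    if not df.empty:
        df = df.sort_values(
            ["n_proteases", "combination"], kind="stable"
        ).reset_index(drop=True)
    return df


NUMERIC_SUM_COLUMNS = [
    "maximal",
    "etd",
    "cid",
    "predicted_matched",
    "predicted_unmatched",
    "mono_modified_count",
]


def _positions(cell) -> frozenset:
    if isinstance(cell, float) and pd.isna(cell):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(";"))


def summarize(
    score_tables: Sequence[pd.DataFrame],
    protein_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Merge per-protein score tables into one summary table.

    Numeric scores are summed element-wise per combination. For each target
    site of each protein, a boolean column ``<protein>:<position>`` records
    whether the combination covers it; ``n_target_sites_covered`` and
    ``n_target_proteins_hit`` aggregate them (a protein is "hit" when at
    least one of its targets is covered). All tables must cover the same
    combination set.
    """
    if not score_tables:
        raise ValueError("no score tables to summarize")
    if protein_ids is None:
        protein_ids = [f"protein{i + 1}" for i in range(len(score_tables))]
    if len(protein_ids) != len(score_tables):
        raise ValueError("one protein id per score table required")

    frames = [
        df.sort_values(["n_proteases", "combination"], kind="stable").reset_index(
            drop=True
        )
        for df in score_tables
    ]
    combos = list(frames[0]["combination"])
    for pid, df in zip(protein_ids, frames[1:], strict=False):
        if list(df["combination"]) != combos:
            raise ValueError(
                "score tables cover different combination sets; "
                "re-run all proteins with the same panel and max size"
            )

    summary = frames[0][["combination", "n_proteases"]].copy()
    for col in NUMERIC_SUM_COLUMNS:
        summary[col] = sum(df[col] for df in frames)

    site_cols: list[str] = []
    hit_mask = []
    for pid, df in zip(protein_ids, frames):
        covered = df["covered_positions"].map(_positions)
        uncovered = df["uncovered_positions"].map(_positions)
        all_targets = sorted(frozenset().union(*covered, *uncovered))
        if not all_targets:
            continue
        for pos in all_targets:
            col = f"{pid}:{pos}"
            summary[col] = [pos in c for c in covered]
            site_cols.append(col)
        hit_mask.append([len(c) > 0 for c in covered])

    if site_cols:
        summary["n_target_sites_covered"] = summary[site_cols].sum(axis=1)
        summary["n_target_proteins_hit"] = [
            sum(col[i] for col in hit_mask) for i in range(len(summary))
        ]
    else:
        summary["n_target_sites_covered"] = 0
        summary["n_target_proteins_hit"] = 0
    return summary


RANK_CRITERIA = {
    "targets": "n_target_sites_covered",
    "etd": "etd",
    "cid": "cid",
    "predicted": "predicted_matched",
}


def rank_settings(summary: pd.DataFrame, criterion: str = "targets") -> pd.DataFrame:
    """Sort a summary table by the chosen criterion, descending.

    Ties break toward fewer proteases (fewer wet-lab experiments), then
    higher CID score, then the combination label; the sort is stable.
    """
    if criterion not in RANK_CRITERIA:
        raise ValueError(
            f"criterion must be one of {sorted(RANK_CRITERIA)}, got {criterion!r}"
        )
    col = RANK_CRITERIA[criterion]
    if summary.empty:
        return summary.copy()
    if col not in summary.columns:
        raise ValueError(f"summary table lacks column {col!r}")
    return (
        summary.sort_values(
            by=[col, "n_proteases", "cid", "combination"],
            ascending=[False, True, False, True],
            kind="stable",
        ).reset_index(drop=True)
    )
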