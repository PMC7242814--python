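"""Behavioral scoring: trial validity filters, item recognition (pR), source
memory under the single high-threshold model (pSR), participant exclusion,
and study-phase summaries binned by subsequent memory.

Item memory is hit rate minus false-alarm rate, per image category.  Source
memory collapses across categories and corrects source hits for guessing:

    pSR = (h - 0.5 * (1 - k)) / (1 - 0.5 * (1 - k))

where ``h`` is the proportion of recognized-old items with a correct source
judgment and ``k`` the proportion with a don't-know response: don't-know
responses remove trials from the two-alternative guessing pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STUDY_WINDOW_MS = (450.0, 4500.0)
TEST_WINDOW_MS = (500.0, 4500.0)
PSR_CUTOFF = 0.1


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ItemCounts:
    """Recognition tallies for one participant (and optionally one category)."""

    n_old: int
    n_new: int
    hits: int
    false_alarms: int

    def __post_init__(self) -> None:
        if self.hits > self.n_old:
            raise ScoringError("hits exceed old-trial count")
        if self.false_alarms > self.n_new:
            raise ScoringError("false alarms exceed new-trial count")


@dataclass(frozen=True)
class SourceCounts:
    """Source-judgment tallies over correctly recognized old items."""

    n_recognized_old: int
    source_hits: int
    source_dk: int

    def __post_init__(self) -> None:
        if self.source_hits + self.source_dk > self.n_recognized_old:
            raise ScoringError("source hits + don't-knows exceed recognized count")


def _validity_mask(records: pd.DataFrame, window_ms: tuple[float, float]) -> np.ndarray:
    rt = records["rt_ms"].to_numpy(dtype=float)
    n_resp = records.get("n_responses", pd.Series(1, index=records.index)).to_numpy()
    with np.errstate(invalid="ignore"):
        in_window = (rt >= window_ms[0]) & (rt <= window_ms[1])
    return np.nan_to_num(in_window) & (n_resp == 1)


def filter_study_trials(
    records: pd.DataFrame, window_ms: tuple[float, float] = STUDY_WINDOW_MS
) -> np.ndarray:
    """Valid iff exactly one response with 450 <= RT <= 4500 ms (inclusive)."""
    return _validity_mask(records, window_ms)


def filter_test_trials(
    records: pd.DataFrame, window_ms: tuple[float, float] = TEST_WINDOW_MS
) -> np.ndarray:
    """Valid iff exactly one response with 500 <= RT <= 4500 ms (inclusive)."""
    return _validity_mask(records, window_ms)


def score_item_memory(counts: ItemCounts) -> float:
    """Item pR = hit rate - false-alarm rate."""
    if counts.n_old == 0 or counts.n_new == 0:
        raise ScoringError("cannot score item memory with zero old or new trials")
    return counts.hits / counts.n_old - counts.false_alarms / counts.n_new


def score_source_memory(counts: SourceCounts) -> float:
    """pSR under the modified single high-threshold model."""
    if counts.n_recognized_old == 0:
        raise ScoringError("participant unscorable: no recognized old items")
    h = counts.source_hits / counts.n_recognized_old
    k = counts.source_dk / counts.n_recognized_old
    return (h - 0.5 * (1.0 - k)) / (1.0 - 0.5 * (1.0 - k))


def exclude_participants(psr_by_participant: dict, cutoff: float = PSR_CUTOFF) -> list:
    """Retain participants with pSR >= cutoff (strict < excludes)."""
    return [p for p, v in psr_by_participant.items() if v >= cutoff]


def tally_test_phase(records: pd.DataFrame) -> tuple[dict, SourceCounts]:
    """Count item and source outcomes for one participant's test trials.

    Returns (``{category: ItemCounts}``, :class:`SourceCounts`).  Invalid
    trials (out-of-window or multiple responses) are dropped first.  New
    trials carry no category, so each category's ItemCounts shares the
    participant's full false-alarm tally.  Items missed at Old/New contribute
    to neither the SourceCounts numerator nor denominator.
    """
    rec = records[records["trial_type"].isin(["critical", "new"])]
    rec = rec[filter_test_trials(rec)]
    new = rec[rec["trial_type"] == "new"]
    n_new = len(new)
    fas = int((new["response_old"] == "old").sum())

    item: dict = {}
    old = rec[rec["trial_type"] == "critical"]
    for cat, grp in old.groupby("category"):
        item[cat] = ItemCounts(
            n_old=len(grp),
            n_new=n_new,
            hits=int((grp["response_old"] == "old").sum()),
            false_alarms=fas,
        )
    recognized = old[old["response_old"] == "old"]
    source = SourceCounts(
        n_recognized_old=len(recognized),
        source_hits=int((recognized["source_resp"] == recognized["category"]).sum()),
        source_dk=int((recognized["source_resp"] == "dk").sum()),
    )
    return item, source


def score_participants(events: pd.DataFrame) -> pd.DataFrame:
    """Per-participant memory scores: item pR per category and collapsed pSR.

    Returns a tidy table with one row per participant: ``item_pr_face``,
    ``item_pr_scene``, ``psr``, plus the underlying rates (hit/FA/source
    proportions) mirroring the memory-performance summary table layout.
    """
    rows = []
    for pid, grp in events.groupby("participant", sort=True):
        test = grp[grp["phase"] == "test"]
        item, source = tally_test_phase(test)
        row = {"participant": pid}
        for cat, c in item.items():
            row[f"hit_rate_{cat}"] = c.hits / c.n_old
            row[f"item_pr_{cat}"] = score_item_memory(c)
        if item:
            row["fa_rate"] = next(iter(item.values())).false_alarms / next(
                iter(item.values())
            ).n_new
        n = source.n_recognized_old
        if n > 0:
            row["p_source_hit"] = source.source_hits / n
            row["p_source_dk"] = source.source_dk / n
            row["psr"] = score_source_memory(source)
        else:
            row["psr"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_study_behavior(events: pd.DataFrame) -> pd.DataFrame:
    """Median RT and mean vividness per participant x category x memory bin.

    The memory bin is ``source_correct`` vs ``other`` (source incorrect or
    don't-know, item misses, and unscorable trials).  Only valid study trials
    (single response inside the 450-4500 ms window) enter; empty cells are
    reported with NaN, never zero.
    """
    study = events[
        (events["phase"] == "study") & (events["trial_type"] == "critical")
    ].copy()
    study = study[filter_study_trials(study)]
    if "memory_status" not in study.columns:
        raise ScoringError("study trials lack subsequent-memory status")
    study["memory_status"] = study["memory_status"].replace("", "other")

    cells = []
    for pid, pgrp in study.groupby("participant", sort=True):
        for cat in ("face", "scene"):
            for status in ("source_correct", "other"):
                cell = pgrp[
                    (pgrp["category"] == cat) & (pgrp["memory_status"] == status)
                ]
                cells.append(
                    {
                        "participant": pid,
                        "category": cat,
                        "memory": status,
                        "n_trials": len(cell),
                        "median_rt_ms": cell["rt_ms"].median() if len(cell) else np.nan,
                        "mean_vividness": cell["vividness"].mean() if len(cell) else np.nan,
                    }
                )
    return pd.DataFrame(cells)
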