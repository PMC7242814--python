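"""Multivoxel pattern similarity: cross-session within- and between-category
correlations and the within - between similarity index.

For every unordered pair of trials from *different* scanning sessions (the
restriction guards against within-session carry-over inflating similarity),
the Pearson correlation of the two voxel patterns is Fisher z-transformed
(atanh).  The within-category metric averages same-category pairs, the
between-category metric averages cross-category pairs, and the similarity
index is their difference.  Like the differentiation index, the metric is
invariant to per-trial affine transforms of the patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .selectivity import condition_on_memory


class SimilarityError(ValueError):
    pass


class NoCrossSessionPairs(SimilarityError):
    """All trials fall in a single session; no valid pairs exist."""


@dataclass(frozen=True)
class SimilarityResult:
    within_z: float
    between_z: float
    index: float
    n_within_pairs: int
    n_between_pairs: int
    condition: str
    within_scope: str
    roi: str

    def to_dict(self) -> dict:
        return {
            "roi": self.roi,
            "condition": self.condition,
            "within_scope": self.within_scope,
            "within_z": self.within_z,
            "between_z": self.between_z,
            "index": self.index,
            "n_within_pairs": self.n_within_pairs,
            "n_between_pairs": self.n_between_pairs,
        }


def _pairwise_z(betas: BetaMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-z correlation matrix plus masks of cross-session pairs."""
    X = betas.values
    if X.shape[1] < 2:
        raise SimilarityError("need at least 2 voxels for pattern correlations")
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise SimilarityError(f"zero-variance pattern in trial(s) {dead.tolist()}")
    r = np.corrcoef(X)
    np.fill_diagonal(r, 0.0)

    sessions = betas.meta["session"].to_numpy()
    cross = sessions[:, None] != sessions[None, :]
    upper = np.triu(np.ones_like(cross, dtype=bool), k=1)
    if not (cross & upper).any():
        raise NoCrossSessionPairs("all trials belong to a single session")
    if np.any(np.abs(r[cross & upper]) >= 1.0 - 1e-15):
        raise SimilarityError(
            "a trial pair correlates at |r| = 1 (infinite Fisher z); "
            "inject noise or drop duplicate patterns"
        )
    return np.arctanh(r), cross, upper


def within_between_similarity(
    betas: BetaMatrix,
    within_scope: str = "both_categories",
    condition: str = "all_trials",
) -> SimilarityResult:
    """Within-category, between-category, and within - between similarity.

    ``within_scope`` selects whether the within-category average pools both
    categories' same-category pairs (default, following the letter of the
    procedure) or only the ROI's preferred category (``"preferred_only"``).
    """
    if condition == "source_correct_only":
        betas = condition_on_memory(betas, "source_correct")
    elif condition != "all_trials":
        raise SimilarityError(f"unknown condition {condition!r}")
    if within_scope not in ("both_categories", "preferred_only"):
        raise SimilarityError(f"unknown within_scope {within_scope!r}")

    z, cross, upper = _pairwise_z(betas)
    cats = betas.meta["category"].to_numpy()
    same_cat = cats[:, None] == cats[None, :]
    valid = cross & upper

    within_mask = valid & same_cat
    if within_scope == "preferred_only":
        pref = cats == betas.roi.preferred
        within_mask &= pref[:, None] & pref[None, :]
    between_mask = valid & ~same_cat

    n_w, n_b = int(within_mask.sum()), int(between_mask.sum())
    if n_w == 0 or n_b == 0:
        raise NoCrossSessionPairs(
            f"no cross-session {'within' if n_w == 0 else 'between'}-category pairs"
        )
    within_z = float(z[within_mask].mean())
    between_z = float(z[between_mask].mean())
    return SimilarityResult(
        within_z=within_z,
        between_z=between_z,
        index=within_z - between_z,
        n_within_pairs=n_w,
        n_between_pairs=n_b,
        condition=condition,
        within_scope=within_scope,
        roi=betas.roi.name,
    )


def memory_conditioned_similarity(
    betas: BetaMatrix,
    status: str = "source_correct",
    within_scope: str = "both_categories",
) -> SimilarityResult:
    """Similarity computed on the subset with the given memory status."""
    sub = condition_on_memory(betas, status)
    res = within_between_similarity(sub, within_scope=within_scope)
    label = "source_correct_only" if status == "source_correct" else f"{status}_only"
    return SimilarityResult(
        within_z=res.within_z,
        between_z=res.between_z,
        index=res.index,
        n_within_pairs=res.n_within_pairs,
        n_between_pairs=res.n_between_pairs,
        condition=label,
        within_scope=within_scope,
        roi=res.roi,
    )


def similarity_table(
    betas_by_participant: dict[str, BetaMatrix],
    within_scope: str = "both_categories",
    conditions: tuple[str, ...] = ("all_trials", "source_correct_only"),
) -> pd.DataFrame:
    """Tidy participant x condition similarity table for one ROI."""
    rows = []
    for pid, bm in betas_by_participant.items():
        for cond in conditions:
            res = within_between_similarity(bm, within_scope=within_scope, condition=cond)
            rows.append({"participant": pid, **res.to_dict()})
    return pd.DataFrame(rows)
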