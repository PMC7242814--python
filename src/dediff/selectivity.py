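"""Univariate category selectivity: the differentiation index and the mean
category-beta decomposition (attenuation vs broadening).

The differentiation index standardizes the difference between a region's mean
response to its preferred and non-preferred stimulus categories:

    DI = (mu_pref - mu_nonpref) / sqrt((sd_pref^2 + sd_nonpref^2) / 2)

where mu and sd are taken across trials of per-trial ROI-mean responses.
Because of the scaling, DI is insensitive to additive offsets and to positive
gain differences between individuals or groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix


class SelectivityError(ValueError):
    pass


@dataclass(frozen=True)
class DifferentiationResult:
    di: float
    mu_pref: float
    mu_nonpref: float
    sd_pref: float
    sd_nonpref: float
    n_pref: int
    n_nonpref: int
    condition: str
    roi: str
    preferred: str

    def to_dict(self) -> dict:
        return {
            "roi": self.roi,
            "condition": self.condition,
            "di": self.di,
            "mu_pref": self.mu_pref,
            "mu_nonpref": self.mu_nonpref,
            "sd_pref": self.sd_pref,
            "sd_nonpref": self.sd_nonpref,
            "n_pref": self.n_pref,
            "n_nonpref": self.n_nonpref,
        }


def condition_on_memory(betas: BetaMatrix, status: str = "source_correct") -> BetaMatrix:
    """Subset to trials of the given subsequent-memory status."""
    if "memory_status" not in betas.meta.columns:
        raise SelectivityError("beta metadata lacks memory_status")
    mask = (betas.meta["memory_status"] == status).to_numpy()
    if not mask.any():
        raise SelectivityError(f"no trials with memory_status == {status!r}")
    return betas.subset(mask)


def _per_trial_responses(betas: BetaMatrix, voxelwise: bool) -> dict[str, np.ndarray]:
    """Per-category response samples: ROI-mean per trial (default) or the
    pooled voxel-level responses (documented alternative)."""
    out = {}
    cats = betas.meta["category"].to_numpy()
    for c in ("face", "scene"):
        rows = betas.values[cats == c]
        out[c] = rows.ravel() if voxelwise else rows.mean(axis=1)
    return out


def differentiation_index(
    betas: BetaMatrix,
    condition: str = "all_trials",
    voxelwise: bool = False,
) -> DifferentiationResult:
    """Differentiation index for one participant and ROI.

    ``condition`` is ``"all_trials"`` or ``"source_correct_only"`` (the
    memory-conditioned variant).  With ``voxelwise=True`` the mean/SD are
    computed over pooled voxel-level responses instead of per-trial ROI means.
    """
    if condition == "source_correct_only":
        betas = condition_on_memory(betas, "source_correct")
    elif condition != "all_trials":
        raise SelectivityError(f"unknown condition {condition!r}")

    pref = betas.roi.preferred
    nonpref = "scene" if pref == "face" else "face"
    resp = _per_trial_responses(betas, voxelwise)
    n_trials = {c: int((betas.meta["category"] == c).sum()) for c in (pref, nonpref)}
    for c in (pref, nonpref):
        if n_trials[c] < 2:
            raise SelectivityError(
                f"cell {betas.roi.name}/{condition}/{c}: fewer than 2 trials"
            )
    mu = {c: float(resp[c].mean()) for c in (pref, nonpref)}
    sd = {c: float(resp[c].std(ddof=1)) for c in (pref, nonpref)}
    pooled = np.sqrt((sd[pref] ** 2 + sd[nonpref] ** 2) / 2.0)
    if pooled == 0:
        raise SelectivityError(f"zero pooled SD in {betas.roi.name}/{condition}")
    return DifferentiationResult(
        di=(mu[pref] - mu[nonpref]) / pooled,
        mu_pref=mu[pref],
        mu_nonpref=mu[nonpref],
        sd_pref=sd[pref],
        sd_nonpref=sd[nonpref],
        n_pref=n_trials[pref],
        n_nonpref=n_trials[nonpref],
        condition=condition,
        roi=betas.roi.name,
        preferred=pref,
    )


def mean_category_betas(betas: BetaMatrix) -> dict[str, float]:
    """Mean beta per category: average over voxels, then over trials.

    Missing categories are reported as NaN rather than raising, so callers
    can flag incomplete cells.
    """
    out = {}
    cats = betas.meta["category"].to_numpy()
    for c in ("face", "scene"):
        rows = betas.values[cats == c]
        out[c] = float(rows.mean()) if rows.size else float("nan")
    return out


def di_table(
    betas_by_participant: dict[str, BetaMatrix],
    conditions: tuple[str, ...] = ("all_trials", "source_correct_only"),
) -> pd.DataFrame:
    """Tidy participant x condition differentiation table for one ROI."""
    rows = []
    for pid, bm in betas_by_participant.items():
        for cond in conditions:
            res = differentiation_index(bm, cond)
            rows.append({"participant": pid, **res.to_dict()})
    return pd.DataFrame(rows)
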