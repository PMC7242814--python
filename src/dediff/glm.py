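"""Least-squares-all single-trial GLM estimation and ROI definition.

Every modeled trial receives its own regressor: a 2-s boxcar at the trial
onset convolved with the canonical double-gamma HRF, sampled at the scan TR.
Sessions are concatenated in scan order; nuisance regressors comprise the six
rigid-body motion parameters, one mean column per session, and (optionally) a
rest-block regressor.  Betas are estimated in one simultaneous ordinary
least-squares fit and only the trial columns are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import BetaMatrix, ROISpec

#: Kernel support of the canonical HRF in seconds.
HRF_LENGTH_S = 32.0


class GLMError(ValueError):
    pass


class EmptyROIError(ValueError):
    """No voxel survived thresholding/masking."""


def canonical_hrf(tr_s: float, oversample: int = 16) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr_s`` over 32 s, peak 1.

    Double-gamma in the convention of common SPM-style analyses: response
    gamma with delay 6 s, undershoot gamma with delay 16 s, both unit
    dispersion, undershoot ratio 1/6.
    """
    if tr_s <= 0:
        raise GLMError("tr_s must be positive")
    dt = tr_s / oversample
    t = np.arange(0, HRF_LENGTH_S + dt / 2, dt)
    h = sps.gamma.pdf(t, a=6.0, scale=1.0) - sps.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    h /= h.max()
    return h[::oversample].copy()


def boxcar_hrf_regressor(
    onset_s: float, duration_s: float, n_scans: int, tr_s: float, oversample: int = 16
) -> np.ndarray:
    """Convolved-boxcar regressor for a single event, sampled at scan times.

    The boxcar and HRF are built on an oversampled grid (``tr_s/oversample``)
    and the convolution is downsampled at scan acquisition times.
    """
    dt = tr_s / oversample
    n_fine = n_scans * oversample
    box = np.zeros(n_fine)
    i0 = int(np.round(onset_s / dt))
    i1 = int(np.round((onset_s + duration_s) / dt))
    if i0 >= n_fine:
        raise GLMError(f"event onset {onset_s}s beyond series end ({n_scans} scans)")
    box[i0 : min(i1, n_fine)] = 1.0
    h = sps.gamma.pdf(np.arange(0, HRF_LENGTH_S + dt / 2, dt), a=6.0, scale=1.0)
    h -= sps.gamma.pdf(np.arange(0, HRF_LENGTH_S + dt / 2, dt), a=16.0, scale=1.0) / 6.0
    h /= h.max()
    reg = np.convolve(box, h)[:n_fine]
    return reg[::oversample].copy()


@dataclass
class GLMDesign:
    """A concatenated-session design matrix with labeled columns.

    ``trial_columns`` maps trial identifiers to column indices;
    ``session_blocks`` maps session number to its (start, stop) scan range in
    the concatenated matrix.
    """

    matrix: np.ndarray
    labels: list[str]
    trial_columns: dict
    session_blocks: dict
    tr_s: float

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def trial_column_indices(self) -> np.ndarray:
        return np.array(list(self.trial_columns.values()), dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)


def build_lsa_design(
    events: pd.DataFrame,
    n_scans_per_session: dict,
    tr_s: float,
    motion: np.ndarray | None = None,
    rest_blocks: dict | None = None,
) -> GLMDesign:
    """Build the least-squares-all design matrix for one participant.

    ``events`` holds the trials to model (one convolved-boxcar column each),
    with columns session/onset/duration and a unique trial id per row
    (``word_id`` if present, else the row position).  ``n_scans_per_session``
    maps session number to scan count; sessions are concatenated in ascending
    session order.  ``motion`` is an optional scans x 6 nuisance table aligned
    to the concatenated scans; ``rest_blocks`` optionally maps session to a
    (start_s, stop_s) rest interval modeled by a single boxcar nuisance
    column.  Nuisance columns are always: motion (6, if given), then one mean
    column per session, then the rest regressor (if given).
    """
    sessions = sorted(n_scans_per_session)
    offsets = {}
    start = 0
    for s in sessions:
        offsets[s] = start
        start += int(n_scans_per_session[s])
    total_scans = start

    ev = events.sort_values(["session", "onset"]).reset_index(drop=True)
    ids = (
        ev["word_id"].tolist()
        if "word_id" in ev.columns and ev["word_id"].astype(bool).all()
        else list(range(len(ev)))
    )
    if len(set(ids)) != len(ids):
        ids = list(range(len(ev)))

    cols: list[np.ndarray] = []
    labels: list[str] = []
    trial_columns: dict = {}
    for i, row in ev.iterrows():
        s = row["session"]
        if s not in offsets:
            raise GLMError(f"trial {ids[i]}: unknown session {s}")
        ns = int(n_scans_per_session[s])
        if row["onset"] >= ns * tr_s:
            raise GLMError(
                f"trial {ids[i]}: onset {row['onset']}s beyond end of session {s} "
                f"({ns} scans x {tr_s}s)"
            )
        reg = np.zeros(total_scans)
        reg[offsets[s] : offsets[s] + ns] = boxcar_hrf_regressor(
            float(row["onset"]), float(row["duration"]), ns, tr_s
        )
        trial_columns[ids[i]] = len(cols)
        labels.append(f"trial_{ids[i]}")
        cols.append(reg)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (total_scans, 6):
            raise GLMError(
                f"motion table must be {total_scans} x 6, got {motion.shape}"
            )
        for j in range(6):
            labels.append(f"motion_{j + 1}")
            cols.append(motion[:, j])

    for s in sessions:
        mean_col = np.zeros(total_scans)
        ns = int(n_scans_per_session[s])
        mean_col[offsets[s] : offsets[s] + ns] = 1.0
        labels.append(f"session_mean_{s}")
        cols.append(mean_col)

    if rest_blocks:
        rest = np.zeros(total_scans)
        for s, (t0, t1) in rest_blocks.items():
            ns = int(n_scans_per_session[s])
            i0 = offsets[s] + int(np.floor(t0 / tr_s))
            i1 = offsets[s] + min(int(np.ceil(t1 / tr_s)), ns)
            rest[i0:i1] = 1.0
        labels.append("rest")
        cols.append(rest)

    session_blocks = {s: (offsets[s], offsets[s] + int(n_scans_per_session[s])) for s in sessions}
    return GLMDesign(np.column_stack(cols), labels, trial_columns, session_blocks, tr_s)


def fit_lsa(
    series: np.ndarray,
    design: GLMDesign,
    meta: pd.DataFrame | None = None,
    roi: ROISpec | None = None,
    cond_threshold: float = 1e8,
) -> BetaMatrix:
    """Ordinary least-squares single-trial betas; nuisance columns discarded.

    ``series`` is the concatenated scans x voxels data matrix.  ``meta``
    (optional, one row per modeled trial in design order) and ``roi`` are
    attached to the returned :class:`~dediff.containers.BetaMatrix`.
    """
    series = np.asarray(series, dtype=float)
    X = design.matrix
    if series.shape[0] != X.shape[0]:
        raise GLMError(
            f"series has {series.shape[0]} scans but design has {X.shape[0]}"
        )
    cond = np.linalg.cond(X)
    if cond > cond_threshold:
        raise GLMError(
            f"design is rank-deficient or ill-conditioned (cond={cond:.3g}); "
            "space events further apart or drop collinear regressors"
        )
    beta_all, *_ = np.linalg.lstsq(X, series, rcond=None)
    idx = design.trial_column_indices()
    betas = beta_all[idx]
    if meta is None:
        meta = pd.DataFrame(
            {"category": "none", "session": 0, "trial_id": list(design.trial_columns)}
        )
    if roi is None:
        roi = ROISpec("series", "face", np.arange(series.shape[1]), "fit_lsa default")
    return BetaMatrix(betas, meta, roi)


def flag_high_motion_trials(
    motion: np.ndarray,
    events: pd.DataFrame,
    session_blocks: dict,
    tr_s: float,
    trans_mm: float = 1.0,
    rot_deg: float = 1.0,
    hrf_peak_lag_s: float = 5.0,
) -> np.ndarray:
    """Boolean mask over trials: True where the trial overlaps excess motion.

    A trial is flagged when any scan in its modeled window - from the trial
    onset to onset + duration + ``hrf_peak_lag_s`` - strictly exceeds
    ``trans_mm`` on any translation axis (columns 0-2, mm) or ``rot_deg`` on
    any rotation axis (columns 3-5, degrees).  Displacements exactly at
    threshold are not flagged.
    """
    motion = np.asarray(motion, dtype=float)
    total = max(stop for _, stop in session_blocks.values())
    if motion.shape[0] < total or motion.shape[1] != 6:
        raise GLMError(
            f"motion table must cover {total} scans x 6 axes, got {motion.shape}"
        )
    bad_scan = (np.abs(motion[:, :3]) > trans_mm).any(axis=1) | (
        np.abs(motion[:, 3:]) > rot_deg
    ).any(axis=1)

    flags = np.zeros(len(events), dtype=bool)
    ev = events.reset_index(drop=True)
    for i, row in ev.iterrows():
        s = row["session"]
        if s not in session_blocks:
            raise GLMError(f"trial {i}: session {s} missing from session_blocks")
        start, stop = session_blocks[s]
        i0 = start + int(np.floor(row["onset"] / tr_s))
        i1 = start + int(
            np.ceil((row["onset"] + row["duration"] + hrf_peak_lag_s) / tr_s)
        )
        flags[i] = bad_scan[i0 : min(i1, stop)].any()
    return flags


def second_level_category_tmap(
    face_means: np.ndarray, scene_means: np.ndarray
) -> tuple[np.ndarray, int]:
    """Per-voxel paired t statistic on face - scene difference scores.

    ``face_means`` and ``scene_means`` are participants x voxels category-mean
    response maps pooled over groups.  Returns (t map, df)."""
    d = np.asarray(face_means, float) - np.asarray(scene_means, float)
    n = d.shape[0]
    t = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(n))
    return t, n - 1


def roi_from_contrast(
    tmap: np.ndarray,
    df: int,
    direction: str,
    mask: np.ndarray,
    alpha: float = 0.01,
    name: str = "roi",
) -> ROISpec:
    """Define an ROI by thresholding a second-level category-contrast map.

    ``direction`` is ``"face>scene"`` (positive t) or ``"scene>face"``;
    voxels with one-sided uncorrected p < ``alpha`` are intersected with the
    boolean (or index) ``mask``.  Raises :class:`EmptyROIError` when nothing
    survives.
    """
    tmap = np.asarray(tmap, dtype=float)
    if direction == "face>scene":
        p = sps.t.sf(tmap, df)
        preferred = "face"
    elif direction == "scene>face":
        p = sps.t.sf(-tmap, df)
        preferred = "scene"
    else:
        raise GLMError("direction must be 'face>scene' or 'scene>face'")
    mask = np.asarray(mask)
    if mask.dtype == bool:
        in_mask = mask
    else:  # index set
        in_mask = np.zeros(tmap.size, dtype=bool)
        in_mask[mask.astype(int)] = True
    keep = (p < alpha) & in_mask
    if not keep.any():
        raise EmptyROIError(
            f"no voxel survives p<{alpha} ({direction}) within the mask"
        )
    return ROISpec(
        name, preferred, np.flatnonzero(keep), f"contrast {direction}, p<{alpha} unc."
    )
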