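"""Table I/O: events TSV (BIDS-events-like), delimited beta matrices with a
sidecar metadata table, factor-loading tables, and optional NIfTI export.

Events are tab-separated with one row per trial (columns ``onset``,
``duration``, ``trial_type``, ``category``, ``session`` plus identifiers and
responses).  Beta matrices are written as a plain numeric TSV (trials x
voxels) plus ``<stem>_meta.tsv`` with per-trial metadata and ROI attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ROISpec


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


_NUMERIC_EVENT_COLUMNS = [
    "session", "trial_index", "onset", "duration",
    "vividness", "rt_ms", "n_responses",
]


def read_events(path) -> pd.DataFrame:
    """Read an events TSV; label columns keep empty strings (no NaN
    coercion), numeric columns are parsed with empty cells as NaN."""
    ev = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["n/a"])
    for col in _NUMERIC_EVENT_COLUMNS:
        if col in ev.columns:
            ev[col] = pd.to_numeric(ev[col], errors="coerce")
    return ev


def write_beta_matrix(betas: BetaMatrix, stem) -> None:
    """Write values to ``<stem>.tsv`` and metadata to ``<stem>_meta.tsv``."""
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".tsv"), betas.values, delimiter="\t")
    meta = betas.meta.copy()
    meta.attrs = {}
    meta.to_csv(stem.parent / f"{stem.name}_meta.tsv", sep="\t", index=False)
    sidecar = {
        "roi_name": betas.roi.name,
        "preferred": betas.roi.preferred,
        "voxel_ids": betas.roi.voxel_ids.tolist(),
        "source": betas.roi.source,
    }
    (stem.parent / f"{stem.name}_roi.json").write_text(json.dumps(sidecar))


def read_beta_matrix(stem) -> BetaMatrix:
    stem = Path(stem)
    values = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = pd.read_csv(stem.parent / f"{stem.name}_meta.tsv", sep="\t")
    sidecar = json.loads((stem.parent / f"{stem.name}_roi.json").read_text())
    roi = ROISpec(
        sidecar["roi_name"],
        sidecar["preferred"],
        np.asarray(sidecar["voxel_ids"]),
        sidecar.get("source", ""),
    )
    return BetaMatrix(values, meta, roi)


def read_loadings(path) -> pd.DataFrame:
    """Read a factor-loading table: first column = test name, remaining
    columns = rotated components."""
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


# Rotated component loadings of the neuropsychological battery (speed, memory,
# crystallized intelligence, fluency), treated as a fixed input: the PCA they
# come from was fit on a prior independent dataset and is out of scope here.
NEUROPSYCH_LOADINGS = pd.DataFrame(
    {
        "RC1_speed": [-0.19, -0.20, 0.21, 0.10, 0.91, 0.85, -0.59, -0.16, -0.34, -0.12, -0.12, -0.33],
        "RC2_memory": [0.84, 0.42, -0.69, 0.67, -0.09, -0.09, 0.40, 0.01, 0.23, 0.06, 0.12, 0.48],
        "RC3_crystallized": [0.08, 0.23, 0.26, 0.18, -0.05, -0.28, 0.08, 0.80, 0.14, 0.46, 0.79, 0.10],
        "RC4_fluency": [-0.15, -0.64, -0.17, 0.02, -0.14, 0.08, 0.30, -0.08, 0.63, 0.57, 0.21, 0.05],
    },
    index=[
        "cvlt_composite",
        "cvlt_recognition_hits",
        "cvlt_recognition_fa",
        "logical_memory_composite",
        "trails_a",
        "trails_b",
        "sdmt",
        "digit_span",
        "category_fluency",
        "fas",
        "wtar",
        "ravens",
    ],
)


def export_betas_nifti(betas: BetaMatrix, path, shape=None) -> None:
    """Optional NIfTI export: one 3-D volume per trial (4-D image) with the
    ROI's voxels placed at their flat indices.  Requires nibabel."""
    import nibabel as nib

    n_vox_total = int(betas.roi.voxel_ids.max()) + 1
    if shape is None:
        side = int(np.ceil(n_vox_total ** (1 / 3)))
        shape = (side, side, side)
    vol = np.zeros((betas.n_trials, int(np.prod(shape))))
    vol[:, betas.roi.voxel_ids] = betas.values
    data = vol.reshape(betas.n_trials, *shape).transpose(1, 2, 3, 0)
    nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), str(path))


def export_roi_mask_nifti(roi: ROISpec, path, shape=None) -> None:
    import nibabel as nib

    n_vox_total = int(roi.voxel_ids.max()) + 1
    if shape is None:
        side = int(np.ceil(n_vox_total ** (1 / 3)))
        shape = (side, side, side)
    mask = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    mask[roi.voxel_ids] = 1
    nib.save(nib.Nifti1Image(mask.reshape(shape), np.eye(4)), str(path))
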