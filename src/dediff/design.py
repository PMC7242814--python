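"""Experiment-design generation for the associative face/scene encoding study.

The study comprises two study-test cycles; each cycle contributes two study
blocks (one block per scanning session) of 48 critical word-image pairs, half
paired with a face and half with a scene, interleaved with 24 null (fixation)
trials.  Each test sub-list probes the studied words of its paired study
sub-list together with 24 new words and 24 null trials.  Trial orders are
pseudorandomized so that no more than three consecutive trials share an image
category and no more than two null trials occur in a row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("face", "scene")

#: Column order of the event tables produced by :func:`generate_design`.
EVENT_COLUMNS = [
    "participant",
    "phase",
    "session",
    "trial_index",
    "onset",
    "duration",
    "trial_type",
    "category",
    "word_id",
    "image_id",
]


class DesignError(ValueError):
    """Raised when design parameters are inconsistent or unsatisfiable."""


@dataclass(frozen=True)
class DesignParams:
    """List-structure and timing constants of the study/test design.

    Durations are in milliseconds except ``tr_s`` (seconds).  The defaults
    reproduce the published design: 2 cycles x 2 blocks x 48 critical pairs,
    24 null trials per sub-list, 24 new words per test sub-list, 500 ms
    fixation + 2000 ms stimulus + 2000 ms ITI, run-length caps of 3
    (category) and 2 (null).
    """

    n_cycles: int = 2
    blocks_per_cycle: int = 2
    critical_per_block: int = 48
    null_per_sublist: int = 24
    new_words_per_test_sublist: int = 24
    categories: tuple[str, str] = CATEGORIES
    fixation_ms: float = 500.0
    stim_ms: float = 2000.0
    iti_ms: float = 2000.0
    max_category_run: int = 3
    max_null_run: int = 2
    tr_s: float = 2.0
    fillers_per_segment: int = 2
    rest_duration_s: float = 30.0
    retry_budget: int = 1000

    def __post_init__(self) -> None:
        if self.critical_per_block % 2 != 0:
            raise DesignError("critical_per_block must be even (half per category)")
        if self.max_category_run < 1:
            raise DesignError("max_category_run must be >= 1")
        if self.max_null_run < 1:
            raise DesignError("max_null_run must be >= 1")
        for name in ("fixation_ms", "stim_ms", "iti_ms", "tr_s"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")
        if min(self.n_cycles, self.blocks_per_cycle, self.critical_per_block) < 1:
            raise DesignError("design counts must be positive")

    @property
    def n_sessions(self) -> int:
        return self.n_cycles * self.blocks_per_cycle

    @property
    def n_critical_study(self) -> int:
        return self.n_sessions * self.critical_per_block

    @property
    def trial_slot_s(self) -> float:
        """Total duration of one trial slot in seconds."""
        return (self.fixation_ms + self.stim_ms + self.iti_ms) / 1000.0


def max_run_length(labels: list[str] | np.ndarray, target: str) -> int:
    """Longest run of consecutive entries equal to ``target``."""
    best = run = 0
    for lab in labels:
        run = run + 1 if lab == target else 0
        best = max(best, run)
    return best


def _order_ok(labels: list[str], params: DesignParams) -> bool:
    """Check the run-length constraints on a list of trial class labels.

    Class labels are the image category for critical/new trials and ``"null"``
    for null trials; fillers reset runs (they bound each segment).
    """
    run_label, run = None, 0
    for lab in labels:
        if lab == run_label:
            run += 1
        else:
            run_label, run = lab, 1
        if lab == "null" and run > params.max_null_run:
            return False
        if lab not in ("null", "filler") and run > params.max_category_run:
            return False
    return True


def _pseudorandom_order(
    classes: list[str], params: DesignParams, rng: np.random.Generator, list_name: str
) -> list[str]:
    """Rejection-sample a permutation of ``classes`` obeying the run caps."""
    classes = list(classes)
    for _ in range(params.retry_budget):
        perm = [classes[i] for i in rng.permutation(len(classes))]
        if _order_ok(perm, params):
            return perm
    raise DesignError(
        f"could not order list '{list_name}' within {params.retry_budget} retries; "
        "relax max_category_run / max_null_run or reduce null density"
    )


def session_segments(grp: pd.DataFrame, params: DesignParams) -> list[pd.DataFrame]:
    """Split one session's trials at presentation breaks (onset gaps larger
    than the trial slot, i.e. the mid-session rest period)."""
    grp = grp.sort_values("onset")
    gaps = grp["onset"].diff().to_numpy()
    seg_id = np.cumsum(np.nan_to_num(gaps) > params.trial_slot_s + 1e-6)
    return [seg for _, seg in grp.groupby(seg_id)]


def check_design(events: pd.DataFrame, params: DesignParams | None = None) -> None:
    """Validate the run-length constraints on every presented list.

    Runs are counted over presented trials (fillers included, by their image
    category) and reset at presentation breaks (session starts and the
    mid-session rest).  Raises :class:`DesignError` on the first violation.
    """
    params = params or DesignParams()
    for (pid, phase, sess), grp in events.groupby(
        ["participant", "phase", "session"], sort=True
    ):
        grp = grp.sort_values("onset")
        onsets = grp["onset"].to_numpy()
        if not np.all(np.diff(onsets) > 0):
            raise DesignError(f"onsets not strictly increasing in {pid}/{phase}/session {sess}")
        for seg in session_segments(grp, params):
            labels = [
                "null" if t == "null" else c
                for t, c in zip(seg["trial_type"], seg["category"])
            ]
            if max_run_length(labels, "null") > params.max_null_run:
                raise DesignError(f"null-run violation in {pid}/{phase}/session {sess}")
            for cat in params.categories + ("new",):
                if max_run_length(labels, cat) > params.max_category_run:
                    raise DesignError(
                        f"{cat}-run violation in {pid}/{phase}/session {sess}"
                    )


def _filler_categories(n: int, segment: list[str], categories: tuple[str, str]) -> list[str]:
    """Categories for a filler block so the block never extends a run: the
    last filler is the opposite of the segment's first critical category and
    the block alternates backwards from it."""
    first_crit = next((c for c in segment if c in categories), categories[0])
    other = categories[1] if first_crit == categories[0] else categories[0]
    cats = []
    for k in range(n):
        cats.append(other if (n - 1 - k) % 2 == 0 else first_crit)
    return cats


def _assemble_session(
    pid: str,
    phase: str,
    session: int,
    rows: list[dict],
    order: list[str],
    pools: dict[str, list[dict]],
    params: DesignParams,
    rng: np.random.Generator,
    filler_counter: list[int],
) -> None:
    """Lay out one session's trials, inserting fillers and the mid-session rest."""
    slot = params.trial_slot_s
    half = len(order) // 2  # rest period midway through the session
    segments = [order[:half], order[half:]]

    def filler_row(cat: str) -> dict:
        filler_counter[0] += 1
        return {
            "trial_type": "filler",
            "category": cat if phase == "study" else "none",
            "word_id": f"fill{filler_counter[0]:03d}",
            "image_id": f"fillimg{filler_counter[0]:03d}" if phase == "study" else "",
        }

    t = 0.0

    def emit(spec: dict) -> None:
        nonlocal t
        rows.append(
            {
                "participant": pid,
                "phase": phase,
                "session": session,
                "onset": round(t + params.fixation_ms / 1000.0, 3),
                "duration": params.stim_ms / 1000.0,
                **spec,
            }
        )
        t += slot

    for si, segment in enumerate(segments):
        if si > 0:
            t += params.rest_duration_s
        for cat in _filler_categories(params.fillers_per_segment, segment, params.categories):
            emit(filler_row(cat))
        for cls in segment:
            if cls == "null":
                emit({"trial_type": "null", "category": "none", "word_id": "", "image_id": ""})
            else:
                emit(pools[cls].pop())


def generate_design(
    params: DesignParams | None = None,
    n_participants: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate study and test event tables for a cohort.

    Returns a tidy table (one row per trial) with columns
    :data:`EVENT_COLUMNS`.  Word and image identifiers are shared across
    participants (stimulus sets are yoked); trial orders are per-participant
    pseudorandomizations.  Deterministic given ``seed``.
    """
    params = params or DesignParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_participants)

    n_crit = params.n_critical_study
    per_cat = n_crit // 2
    n_new = params.n_sessions * params.new_words_per_test_sublist
    words = [f"w{i:04d}" for i in range(n_crit + n_new)]
    face_imgs = [f"face{i:03d}" for i in range(per_cat)]
    scene_imgs = [f"scene{i:03d}" for i in range(per_cat)]

    all_rows: list[dict] = []
    for p in range(n_participants):
        rng = np.random.default_rng(child_seeds[p])
        pid = f"sub{p + 1:03d}"
        filler_counter = [0]

        # assign stimuli to sub-lists: each study session gets half faces, half scenes
        word_perm = [words[i] for i in rng.permutation(n_crit)]
        new_perm = [words[n_crit + i] for i in rng.permutation(n_new)]
        fperm = [face_imgs[i] for i in rng.permutation(per_cat)]
        sperm = [scene_imgs[i] for i in rng.permutation(per_cat)]

        half_block = params.critical_per_block // 2
        studied_by_session: dict[int, list[dict]] = {}
        for s in range(params.n_sessions):
            sess = s + 1
            faces = [
                {
                    "trial_type": "critical",
                    "category": "face",
                    "word_id": word_perm.pop(),
                    "image_id": fperm.pop(),
                }
                for _ in range(half_block)
            ]
            scenes = [
                {
                    "trial_type": "critical",
                    "category": "scene",
                    "word_id": word_perm.pop(),
                    "image_id": sperm.pop(),
                }
                for _ in range(half_block)
            ]
            studied_by_session[sess] = faces + scenes
            classes = (
                ["face"] * half_block
                + ["scene"] * half_block
                + ["null"] * params.null_per_sublist
            )
            order = _pseudorandom_order(
                classes, params, rng, f"{pid}/study/session{sess}"
            )
            pools = {"face": list(faces), "scene": list(scenes)}
            _assemble_session(
                pid, "study", sess, all_rows, order, pools, params, rng, filler_counter
            )

        for s in range(params.n_sessions):
            sess = s + 1
            old = [
                {
                    "trial_type": "critical",
                    "category": d["category"],
                    "word_id": d["word_id"],
                    "image_id": "",
                }
                for d in studied_by_session[sess]
            ]
            new = [
                {
                    "trial_type": "new",
                    "category": "new",
                    "word_id": new_perm.pop(),
                    "image_id": "",
                }
                for _ in range(params.new_words_per_test_sublist)
            ]
            classes = [d["category"] for d in old] + ["new"] * len(new) + [
                "null"
            ] * params.null_per_sublist
            order = _pseudorandom_order(classes, params, rng, f"{pid}/test/session{sess}")
            pools = {
                "face": [d for d in old if d["category"] == "face"],
                "scene": [d for d in old if d["category"] == "scene"],
                "new": new,
            }
            _assemble_session(
                pid, "test", sess, all_rows, order, pools, params, rng, filler_counter
            )

    events = pd.DataFrame(all_rows)
    events["trial_index"] = events.groupby(
        ["participant", "phase", "session"], sort=False
    ).cumcount()
    events = events[EVENT_COLUMNS]
    check_design(events, params)
    return events
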