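"""Synthetic behavioral outcomes, trial-wise beta patterns, and BOLD series.

The generators realize the statistical structure the downstream analyses
assume.  Behavior follows the experiment's response model: an Old/New
recognition judgment on every test word, a three-way source judgment
(face / scene / don't-know) for items endorsed Old, and a vividness rating
plus RT on every study trial, with vividness conditioned on subsequent source
memory.  Neural patterns decompose category selectivity into a mean-amplitude
(univariate) component ``amp`` and a pattern-reliability (multivariate)
component ``kappa`` weighting a per-participant unit-norm category template:

    beta[trial of category c] = amp[c] + kappa[c] * template_c + noise

with white trial noise of standard deviation ``sigma``.  Group differences
are expressed as attenuation of the preferred-category amplitude, broadening
(elevation) of the non-preferred amplitude, and/or reduced preferred-category
pattern reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ROISpec
from .design import DesignParams


class ParameterError(ValueError):
    """Raised for out-of-range generator parameters."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class BehaviorParams:
    """Response-model parameters for one participant group.

    ``p_hit`` and ``p_source_correct`` are per image category;
    ``p_source_correct[c] + p_dk`` may not exceed 1.  ``vividness_dist`` maps
    subsequent-memory bin (``source_correct`` / ``other``) to a probability
    triplet over ratings 1-3.  RTs follow a log-normal law parameterized by
    its median (ms) and log-scale spread.  With probability ``p_invalid`` a
    trial's response is made invalid (out-of-window RT or a double press).
    """

    p_hit: dict = field(default_factory=lambda: {"face": 0.82, "scene": 0.81})
    p_fa: float = 0.13
    p_source_correct: dict = field(default_factory=lambda: {"face": 0.83, "scene": 0.79})
    p_dk: float = 0.14
    vividness_dist: dict = field(
        default_factory=lambda: {
            "source_correct": (0.10, 0.38, 0.52),
            "other": (0.22, 0.41, 0.37),
        }
    )
    rt_median_ms: float = 2350.0
    rt_log_sd: float = 0.35
    p_invalid: float = 0.02

    def __post_init__(self) -> None:
        for cat, p in self.p_hit.items():
            _check_prob(f"p_hit[{cat}]", p)
        _check_prob("p_fa", self.p_fa)
        _check_prob("p_dk", self.p_dk)
        _check_prob("p_invalid", self.p_invalid)
        for cat, p in self.p_source_correct.items():
            _check_prob(f"p_source_correct[{cat}]", p)
            if p + self.p_dk > 1.0 + 1e-12:
                raise ParameterError(
                    f"p_source_correct[{cat}] + p_dk exceeds 1 ({p} + {self.p_dk})"
                )
        for bin_, dist in self.vividness_dist.items():
            if len(dist) != 3 or any(q < 0 for q in dist):
                raise ParameterError(f"vividness_dist[{bin_}] must be 3 nonnegative weights")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ParameterError(f"vividness_dist[{bin_}] must sum to 1")
        if self.rt_median_ms <= 0 or self.rt_log_sd <= 0:
            raise ParameterError("rt_median_ms and rt_log_sd must be positive")


@dataclass(frozen=True)
class NeuralGenParams:
    """Generative parameters for one ROI in one participant group.

    ``amp`` and ``kappa`` are per category (keys 'face', 'scene'); ``sigma``
    is the white trial-noise SD in beta units.  Category templates are drawn
    fresh (unit-norm) for every participant.
    """

    roi_name: str
    preferred: str
    n_voxels: int
    amp: dict = field(default_factory=lambda: {"face": 1.0, "scene": 1.0})
    kappa: dict = field(default_factory=lambda: {"face": 0.0, "scene": 0.0})
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ParameterError("n_voxels must be >= 2")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        for cat in ("face", "scene"):
            if cat not in self.amp or cat not in self.kappa:
                raise ParameterError(f"amp and kappa must define category '{cat}'")
            if self.kappa[cat] < 0:
                raise ParameterError("kappa must be nonnegative")
        if self.preferred not in ("face", "scene"):
            raise ParameterError("preferred must be 'face' or 'scene'")

    @property
    def nonpreferred(self) -> str:
        return "scene" if self.preferred == "face" else "face"

    def population_di(self) -> float:
        """Population differentiation index over ROI-mean responses when
        kappa = 0: amplitude difference over the ROI-mean noise SD
        sigma / sqrt(n_voxels)."""
        sd = self.sigma / np.sqrt(self.n_voxels)
        return (self.amp[self.preferred] - self.amp[self.nonpreferred]) / sd


# response-window constants (ms poststimulus); study and test differ
STUDY_WINDOW_MS = (450.0, 4500.0)
TEST_WINDOW_MS = (500.0, 4500.0)

RESPONSE_COLUMNS = [
    "response_old",
    "source_resp",
    "vividness",
    "rt_ms",
    "n_responses",
    "memory_status",
]


def _draw_rt(rng: np.random.Generator, bp: BehaviorParams, size: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(bp.rt_median_ms), bp.rt_log_sd, size=size))


def _invalidate(
    rng: np.random.Generator,
    rt: np.ndarray,
    n_resp: np.ndarray,
    p_invalid: float,
    window: tuple[float, float],
) -> None:
    """In place: with probability ``p_invalid`` make a trial invalid, half the
    time via an out-of-window (too fast) RT, half via a double press."""
    bad = rng.random(rt.size) < p_invalid
    fast = bad & (rng.random(rt.size) < 0.5)
    double = bad & ~fast
    rt[fast] = rng.uniform(50.0, window[0] - 1.0, size=int(fast.sum()))
    n_resp[double] = 2


def simulate_behavior(
    design: pd.DataFrame, bp: BehaviorParams, seed: int
) -> pd.DataFrame:
    """Fill behavioral responses into a design table.

    Test critical trials receive Old/New and (if endorsed Old) source
    responses; new trials receive false-alarm draws; study trials receive
    vividness and RT, with vividness conditioned on the trial's subsequent
    source-memory outcome.  Adds a ``memory_status`` column
    (``source_correct`` / ``other``) on study critical trials.  Deterministic
    given ``seed``; vectorized over the whole cohort.
    """
    events = design.copy().reset_index(drop=True)
    events["response_old"] = ""
    events["source_resp"] = ""
    events["vividness"] = np.nan
    events["rt_ms"] = np.nan
    events["n_responses"] = 0
    events["memory_status"] = ""

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE4A]))

    # --- test critical (old) trials ------------------------------------------
    tc = events.index[
        (events["phase"] == "test") & (events["trial_type"] == "critical")
    ].to_numpy()
    cats = events.loc[tc, "category"].to_numpy()
    n = tc.size
    rt = _draw_rt(rng, bp, n)
    n_resp = np.ones(n, dtype=int)
    _invalidate(rng, rt, n_resp, bp.p_invalid, TEST_WINDOW_MS)
    p_hit = np.array([bp.p_hit[c] for c in cats])
    hit = rng.random(n) < p_hit
    p_sc = np.array([bp.p_source_correct[c] for c in cats])
    u = rng.random(n)
    source = np.where(u < p_sc, cats, np.where(u < p_sc + bp.p_dk, "dk", ""))
    wrong = hit & (source == "")
    source[wrong] = np.where(cats[wrong] == "face", "scene", "face")
    source[~hit] = ""
    valid = (n_resp == 1) & (rt >= TEST_WINDOW_MS[0]) & (rt <= TEST_WINDOW_MS[1])
    status = np.where(valid & hit & (source == cats), "source_correct", "other")
    events.loc[tc, "response_old"] = np.where(hit, "old", "new")
    events.loc[tc, "source_resp"] = source
    events.loc[tc, "rt_ms"] = rt
    events.loc[tc, "n_responses"] = n_resp

    # --- test new trials ------------------------------------------------------
    tn = events.index[
        (events["phase"] == "test") & (events["trial_type"] == "new")
    ].to_numpy()
    m = tn.size
    rt_n = _draw_rt(rng, bp, m)
    n_resp_n = np.ones(m, dtype=int)
    _invalidate(rng, rt_n, n_resp_n, bp.p_invalid, TEST_WINDOW_MS)
    fa = rng.random(m) < bp.p_fa
    u = rng.random(m)
    fa_source = np.where(u < bp.p_dk, "dk", np.where(u < (1 + bp.p_dk) / 2, "face", "scene"))
    events.loc[tn, "response_old"] = np.where(fa, "old", "new")
    events.loc[tn, "source_resp"] = np.where(fa, fa_source, "")
    events.loc[tn, "rt_ms"] = rt_n
    events.loc[tn, "n_responses"] = n_resp_n

    # --- study critical trials: join subsequent-memory outcome ----------------
    sc = events.index[
        (events["phase"] == "study") & (events["trial_type"] == "critical")
    ].to_numpy()
    outcome = pd.Series(
        status,
        index=pd.MultiIndex.from_arrays(
            [events.loc[tc, "participant"], events.loc[tc, "word_id"]]
        ),
    )
    key = pd.MultiIndex.from_arrays(
        [events.loc[sc, "participant"], events.loc[sc, "word_id"]]
    )
    s_status = outcome.reindex(key).fillna("other").to_numpy()

    k = sc.size
    rt_s = _draw_rt(rng, bp, k)
    n_resp_s = np.ones(k, dtype=int)
    _invalidate(rng, rt_s, n_resp_s, bp.p_invalid, STUDY_WINDOW_MS)
    viv = np.empty(k, dtype=int)
    u = rng.random(k)
    for bin_, dist in bp.vividness_dist.items():
        rows = s_status == bin_
        viv[rows] = 1 + np.searchsorted(np.cumsum(dist), u[rows], side="right").clip(0, 2)
    events.loc[sc, "vividness"] = viv
    events.loc[sc, "rt_ms"] = rt_s
    events.loc[sc, "n_responses"] = n_resp_s
    events.loc[sc, "memory_status"] = s_status
    return events


# Synthetic stand-in for the neuropsychological battery: per-test group means
# and SDs (young, older) matching the cohort's demographic profile.  Tests are
# drawn independently per participant, so the true inter-test correlation
# structure (what the factor loadings summarize) is NOT reproduced; factor
# scores computed from these data exercise the projection numerically only.
NEUROPSYCH_NORMS = {
    "cvlt_composite": ((14.02, 2.1), (12.80, 2.4)),
    "cvlt_recognition_hits": ((15.71, 0.46), (15.25, 1.07)),
    "cvlt_recognition_fa": ((0.33, 0.70), (1.67, 1.61)),
    "logical_memory_composite": ((32.5, 4.8), (26.9, 4.8)),
    "trails_a": ((20.20, 5.26), (25.11, 6.46)),
    "trails_b": ((44.12, 10.18), (62.48, 16.77)),
    "sdmt": ((62.33, 11.27), (49.29, 7.91)),
    "digit_span": ((19.71, 4.14), (18.79, 3.49)),
    "category_fluency": ((23.71, 4.91), (22.46, 5.35)),
    "fas": ((49.17, 12.85), (46.29, 12.75)),
    "wtar": ((42.42, 3.46), (44.54, 4.06)),
    "ravens": ((11.04, 0.86), (9.50, 1.89)),
}


def synthetic_neuropsych_scores(group_of: dict, seed: int) -> pd.DataFrame:
    """Synthetic neuropsychological test scores, one row per participant.

    Groups must be labeled 'young' / 'older'; each test is an independent
    normal draw from that group's published mean/SD norms (see
    :data:`NEUROPSYCH_NORMS` for the caveat about correlation structure).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C07]))
    pids = sorted(group_of)
    rows = {}
    for test, (young, older) in NEUROPSYCH_NORMS.items():
        vals = []
        for p in pids:
            mean, sd = young if group_of[p] == "young" else older
            vals.append(rng.normal(mean, sd))
        rows[test] = vals
    return pd.DataFrame(rows, index=pd.Index(pids, name="participant"))


def _unit_template(rng: np.random.Generator, n_voxels: int) -> np.ndarray:
    v = rng.standard_normal(n_voxels)
    return v / np.linalg.norm(v)


def simulate_betas(
    design: pd.DataFrame,
    neural: NeuralGenParams,
    seed: int,
    participant: str | None = None,
) -> BetaMatrix:
    """Generate a trial-by-voxel beta matrix for one participant and ROI.

    Operates on the participant's study critical trials (ordered by session
    and onset).  Each trial's voxel vector is
    ``amp[c] + kappa[c] * template_c + noise`` with per-participant unit-norm
    category templates and iid N(0, sigma^2) noise.  Trial metadata
    (category, session, memory status if present) is attached.
    """
    ev = design
    if participant is not None:
        ev = ev[ev["participant"] == participant]
    ev = ev[(ev["phase"] == "study") & (ev["trial_type"] == "critical")]
    if len(ev) == 0:
        raise ParameterError("design contains no study critical trials")
    if ev["participant"].nunique() > 1:
        raise ParameterError(
            "simulate_betas operates on one participant; pass participant=..."
        )
    ev = ev.sort_values(["session", "onset"]).reset_index(drop=True)

    rng = np.random.default_rng(seed)
    templates = {c: _unit_template(rng, neural.n_voxels) for c in ("face", "scene")}
    cats = ev["category"].to_numpy()
    values = rng.standard_normal((len(ev), neural.n_voxels)) * neural.sigma
    for c in ("face", "scene"):
        rows = cats == c
        values[rows] += neural.amp[c] + neural.kappa[c] * templates[c]

    meta_cols = ["participant", "category", "session", "word_id"]
    meta = ev[meta_cols].copy()
    meta["memory_status"] = (
        ev["memory_status"].replace("", "other")
        if "memory_status" in ev.columns
        else "other"
    )
    roi = ROISpec(neural.roi_name, neural.preferred, np.arange(neural.n_voxels), "synthetic")
    return BetaMatrix(values, meta, roi)


def simulate_bold(
    design: pd.DataFrame,
    neural: NeuralGenParams,
    seed: int,
    tr_s: float = 2.0,
    noise_sd: float | None = None,
    participant: str | None = None,
):
    """Generate per-session BOLD series from the convolved forward model.

    Each session's series is ``X_session @ B_true + white noise`` where
    ``X_session`` holds one convolved 2-s boxcar regressor per study critical
    trial and ``B_true`` are single-trial voxel amplitudes drawn from the same
    amp/kappa/template model as :func:`simulate_betas`.  Returns
    ``(series_by_session, truth)`` where ``truth`` is the ground-truth
    BetaMatrix; scan counts cover the last event plus the HRF kernel length.
    """
    from .glm import boxcar_hrf_regressor, HRF_LENGTH_S

    if tr_s <= 0:
        raise ParameterError("tr_s must be positive")
    truth = simulate_betas(design, neural, seed, participant=participant)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B01D]))
    sd = neural.sigma if noise_sd is None else noise_sd

    ev = design
    if participant is not None:
        ev = ev[ev["participant"] == participant]
    ev = ev[(ev["phase"] == "study") & (ev["trial_type"] == "critical")]
    ev = ev.sort_values(["session", "onset"]).reset_index(drop=True)

    series: dict[int, np.ndarray] = {}
    row = 0
    for sess, grp in ev.groupby("session", sort=True):
        onsets = grp["onset"].to_numpy(float)
        durs = grp["duration"].to_numpy(float)
        n_scans = int(np.ceil((onsets.max() + durs.max() + HRF_LENGTH_S) / tr_s))
        X = np.column_stack(
            [boxcar_hrf_regressor(o, d, n_scans, tr_s) for o, d in zip(onsets, durs)]
        )
        B = truth.values[row : row + len(grp)]
        Y = X @ B + rng.standard_normal((n_scans, truth.n_voxels)) * sd
        series[int(sess)] = Y
        row += len(grp)
    return series, truth
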