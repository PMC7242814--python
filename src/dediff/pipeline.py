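"""End-to-end synthetic replication: cohort generation, behavioral scoring,
differentiation index, pattern similarity, and the group-level statistical
battery, emitting tidy CSV tables plus a machine-readable run manifest.

Stage seeds are derived from the master seed by numpy's SeedSequence
spawning in a fixed, documented order (design, behavior, betas), so any
stage can be reproduced in isolation from the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import exclude_participants, score_participants, summarize_study_behavior
from .containers import BetaMatrix
from .design import DesignParams, generate_design
from .selectivity import differentiation_index, mean_category_betas
from .similarity import within_between_similarity
from .simulate import BehaviorParams, NeuralGenParams, simulate_behavior, simulate_betas
from .stats import interaction_screen_regression, mixed_anova, welch_t


def kappa_for_reliability(r: float, n_voxels: int, sigma: float) -> float:
    """Pattern-reliability weight giving an expected within-category trial
    correlation of ``r``: kappa = sqrt(r/(1-r) * n_voxels * sigma^2)."""
    if not 0 <= r < 1:
        raise ValueError("target correlation must be in [0, 1)")
    return float(np.sqrt(r / (1.0 - r) * n_voxels * sigma**2))


@dataclass(frozen=True)
class GroupSpec:
    behavior: BehaviorParams
    neural: dict  # roi name -> NeuralGenParams


@dataclass(frozen=True)
class RunConfig:
    design: DesignParams
    groups: dict  # group label -> GroupSpec (exactly two groups)
    n_per_group: int
    seed: int
    within_scope: str = "both_categories"
    memory_conditioning: bool = True
    epsilon_method: str = "gg"
    psr_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ValueError("RunConfig requires exactly two groups")
        rois = [set(g.neural) for g in self.groups.values()]
        if rois[0] != rois[1]:
            raise ValueError("both groups must define the same ROIs")

    @property
    def roi_names(self) -> list[str]:
        return sorted(next(iter(self.groups.values())).neural)

    def config_hash(self) -> str:
        blob = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ----------------------------------------------------------------------------
# The stated world: defaults emulating the published study's conditions.
# Voxel counts are bilateral ROI sizes; sigma is the trial-noise SD in beta
# units; amplitudes place the young-adult differentiation indices near the
# 1-2 range the study displays, with older-group dedifferentiation in the
# scene ROIs realized as preferred-amplitude attenuation + non-preferred
# broadening + reduced preferred-pattern reliability.  Face-ROI parameters
# are identical across groups (the null the study reports).
# ----------------------------------------------------------------------------
SIGMA = 5.0
ROI_DEFS = {  # name -> (preferred, n_voxels)
    "PPA": ("scene", 468),
    "RSC": ("scene", 379),
    "FFA": ("face", 44),
    "OFA": ("face", 122),
}


def _neural_defaults(group: str) -> dict:
    dediff = group == "older"
    spec: dict[str, NeuralGenParams] = {}
    for name, (pref, nv) in ROI_DEFS.items():
        nonpref = "scene" if pref == "face" else "face"
        if pref == "scene":
            amp = {pref: 1.31 if dediff else 1.40, nonpref: 1.09 if dediff else 1.00}
            r_pref = (0.07 if dediff else 0.15) if name == "PPA" else (0.06 if dediff else 0.12)
        else:
            amp = {pref: 1.90 if name == "FFA" else 1.55, nonpref: 1.00}
            r_pref = 0.12
        kappa = {
            pref: kappa_for_reliability(r_pref, nv, SIGMA),
            nonpref: kappa_for_reliability(0.03, nv, SIGMA),
        }
        spec[name] = NeuralGenParams(name, pref, nv, amp=amp, kappa=kappa, sigma=SIGMA)
    return spec


def default_config(seed: int = 0, n_per_group: int = 24) -> RunConfig:
    young_bp = BehaviorParams()  # young-adult cell means
    older_bp = BehaviorParams(
        p_hit={"face": 0.70, "scene": 0.66},
        p_fa=0.13,
        p_source_correct={"face": 0.75, "scene": 0.68},
        p_dk=0.13,
        vividness_dist={
            "source_correct": (0.14, 0.44, 0.42),
            "other": (0.26, 0.45, 0.29),
        },
        rt_median_ms=2250.0,
    )
    return RunConfig(
        design=DesignParams(),
        groups={
            "young": GroupSpec(young_bp, _neural_defaults("young")),
            "older": GroupSpec(older_bp, _neural_defaults("older")),
        },
        n_per_group=n_per_group,
        seed=seed,
    )


def config_from_dict(d: dict, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a plain (YAML-loadable) mapping.

    Unspecified values fall back to the defaults of :func:`default_config`.
    Recognized keys: ``seed``, ``n_per_group``, ``within_scope``,
    ``memory_conditioning``, ``epsilon_method``, ``psr_cutoff``, ``design``
    (DesignParams kwargs) and ``groups`` (per group label: ``behavior`` kwargs
    and ``neural`` as per-ROI NeuralGenParams kwargs).
    """
    d = dict(d or {})
    seed = int(d.pop("seed", 0)) if seed is None else int(seed)
    base = default_config(seed=seed, n_per_group=int(d.pop("n_per_group", 24)))
    design = DesignParams(**d.pop("design", {})) if "design" in d else base.design

    groups = dict(base.groups)
    for label, gspec in (d.pop("groups", None) or {}).items():
        ref = groups.get(label, next(iter(groups.values())))
        behavior = (
            BehaviorParams(**gspec["behavior"]) if "behavior" in gspec else ref.behavior
        )
        neural = dict(ref.neural)
        for roi, nkw in (gspec.get("neural") or {}).items():
            prev = neural.get(roi)
            kwargs = {
                "roi_name": roi,
                "preferred": prev.preferred if prev else nkw.get("preferred"),
                "n_voxels": prev.n_voxels if prev else nkw.get("n_voxels"),
                "amp": prev.amp if prev else None,
                "kappa": prev.kappa if prev else None,
                "sigma": prev.sigma if prev else 1.0,
            }
            kwargs.update(nkw)
            kwargs = {k: v for k, v in kwargs.items() if v is not None}
            neural[roi] = NeuralGenParams(**kwargs)
        groups[label] = GroupSpec(behavior, neural)

    return RunConfig(
        design=design,
        groups=groups,
        n_per_group=base.n_per_group,
        seed=seed,
        within_scope=d.pop("within_scope", base.within_scope),
        memory_conditioning=bool(d.pop("memory_conditioning", base.memory_conditioning)),
        epsilon_method=d.pop("epsilon_method", base.epsilon_method),
        psr_cutoff=float(d.pop("psr_cutoff", base.psr_cutoff)),
    )


@dataclass
class Cohort:
    """Simulated cohort: events with behavior, group assignment, and betas."""

    events: pd.DataFrame
    group_of: dict  # participant -> group label
    betas: dict  # roi name -> {participant -> BetaMatrix}
    config: RunConfig


def simulate_cohort(config: RunConfig, with_betas: bool = True) -> Cohort:
    """Generate design, behavior, and (optionally) beta patterns for both groups."""
    master = np.random.SeedSequence(config.seed)
    seed_design, seed_behavior, seed_betas = master.spawn(3)

    n_total = 2 * config.n_per_group
    design = generate_design(config.design, n_total, seed=seed_design)

    participants = sorted(design["participant"].unique())
    labels = sorted(config.groups)
    group_of = {
        p: labels[0] if i < config.n_per_group else labels[1]
        for i, p in enumerate(participants)
    }

    beh_seeds = {g: s for g, s in zip(labels, seed_behavior.spawn(2))}
    parts = []
    for g in labels:
        members = [p for p in participants if group_of[p] == g]
        sub = design[design["participant"].isin(members)]
        parts.append(
            simulate_behavior(sub, config.groups[g].behavior, seed=int(beh_seeds[g].generate_state(1)[0] % 2**31))
        )
    events = pd.concat(parts, ignore_index=True)

    betas: dict = {}
    if with_betas:
        by_participant = {p: grp for p, grp in events.groupby("participant")}
        beta_children = seed_betas.spawn(len(config.roi_names) * len(participants))
        i = 0
        for roi in config.roi_names:
            betas[roi] = {}
            for p in participants:
                neural = config.groups[group_of[p]].neural[roi]
                betas[roi][p] = simulate_betas(
                    by_participant[p], neural, seed=beta_children[i]
                )
                i += 1
    return Cohort(events, group_of, betas, config)


def _group_col(df: pd.DataFrame, group_of: dict) -> pd.Series:
    return df["participant"].map(group_of)


def analyze_cohort(cohort: Cohort) -> dict:
    """Run the full analysis battery; returns a dict of tidy tables."""
    cfg = cohort.config
    tables: dict[str, pd.DataFrame] = {}

    # ---- behavioral scoring (memory-performance analog) ---------------------
    scores = score_participants(cohort.events)
    scores["group"] = _group_col(scores, cohort.group_of)
    retained = set(
        exclude_participants(
            dict(zip(scores["participant"], scores["psr"])), cfg.psr_cutoff
        )
    )
    scores["retained"] = scores["participant"].isin(retained)
    tables["memory_scores"] = scores

    study = summarize_study_behavior(cohort.events)
    study["group"] = _group_col(study, cohort.group_of)
    tables["study_behavior"] = study

    kept = scores[scores["retained"]]

    # item-memory ANOVA: 2 (group) x 2 (category)
    item_long = kept.melt(
        id_vars=["participant", "group"],
        value_vars=["item_pr_face", "item_pr_scene"],
        var_name="category",
        value_name="item_pr",
    )
    item_long["category"] = item_long["category"].str.replace("item_pr_", "")
    anovas = []
    a = mixed_anova(item_long, "item_pr", "group", "category", "participant",
                    epsilon_method=cfg.epsilon_method)
    a.insert(0, "analysis", "item_memory")
    anovas.append(a)

    # pSR group comparison
    g1, g2 = sorted(cfg.groups)
    psr1 = kept.loc[kept["group"] == g1, "psr"].to_numpy()
    psr2 = kept.loc[kept["group"] == g2, "psr"].to_numpy()
    pairwise = [{"analysis": "psr", "contrast": f"{g1} vs {g2}",
                 **welch_t(psr1, psr2).to_dict()}]

    # study RT / vividness ANOVAs: 2 x 2 x 2
    study_kept = study[study["participant"].isin(retained)]
    for dv, col in (("median_rt_ms", "rt"), ("mean_vividness", "vividness")):
        long = study_kept.dropna(subset=[dv])
        complete = long.groupby("participant").size()
        long = long[long["participant"].isin(complete[complete == 4].index)]
        if long["participant"].nunique() >= 4 and _balanced_groups(long, cohort.group_of):
            a = mixed_anova(long, dv, "group", ["category", "memory"], "participant",
                            epsilon_method=cfg.epsilon_method)
            a.insert(0, "analysis", f"study_{col}")
            anovas.append(a)

    # ---- differentiation index and similarity -------------------------------
    conditions = ["all_trials"] + (
        ["source_correct_only"] if cfg.memory_conditioning else []
    )
    di_rows, sim_rows, beta_rows = [], [], []
    for roi in cfg.roi_names:
        for p, bm in cohort.betas[roi].items():
            if p not in retained:
                continue
            mb = mean_category_betas(bm)
            beta_rows.append(
                {"participant": p, "group": cohort.group_of[p], "roi": roi,
                 "preferred": bm.roi.preferred,
                 "mean_beta_face": mb["face"], "mean_beta_scene": mb["scene"]}
            )
            for cond in conditions:
                res = differentiation_index(bm, cond)
                di_rows.append({"participant": p, "group": cohort.group_of[p],
                                **res.to_dict()})
                sim = within_between_similarity(bm, cfg.within_scope, cond)
                sim_rows.append({"participant": p, "group": cohort.group_of[p],
                                 **sim.to_dict()})
    di = pd.DataFrame(di_rows)
    sim = pd.DataFrame(sim_rows)
    mean_betas = pd.DataFrame(beta_rows)
    tables["di"] = di
    tables["similarity"] = sim
    tables["mean_betas"] = mean_betas

    # ---- group-level fMRI statistics ---------------------------------------
    for metric, tab, value in (("di", di, "di"), ("similarity", sim, "index")):
        for cond in conditions:
            sub = tab[tab["condition"] == cond]
            a = mixed_anova(sub, value, "group", "roi", "participant",
                            epsilon_method=cfg.epsilon_method)
            a.insert(0, "analysis", f"{metric}_{cond}_group_x_roi")
            anovas.append(a)
            scene_rois = [r for r in cfg.roi_names if ROI_PREF(cfg, r) == "scene"]
            face_rois = [r for r in cfg.roi_names if ROI_PREF(cfg, r) == "face"]
            for fam, fam_rois in (("scene", scene_rois), ("face", face_rois)):
                if len(fam_rois) == 2:
                    a = mixed_anova(sub[sub["roi"].isin(fam_rois)], value, "group",
                                    "roi", "participant", epsilon_method=cfg.epsilon_method)
                    a.insert(0, "analysis", f"{metric}_{cond}_{fam}_rois")
                    anovas.append(a)
            for roi in cfg.roi_names:
                x = sub[(sub["roi"] == roi) & (sub["group"] == g1)][value].to_numpy()
                y = sub[(sub["roi"] == roi) & (sub["group"] == g2)][value].to_numpy()
                pairwise.append({"analysis": f"{metric}_{cond}", "contrast":
                                 f"{roi}: {g1} vs {g2}", **welch_t(x, y).to_dict()})

    # mean-beta decomposition (attenuation vs broadening) per ROI family
    beta_long = mean_betas.melt(
        id_vars=["participant", "group", "roi", "preferred"],
        value_vars=["mean_beta_face", "mean_beta_scene"],
        var_name="category", value_name="mean_beta",
    )
    beta_long["category"] = beta_long["category"].str.replace("mean_beta_", "")
    for fam in ("scene", "face"):
        fam_rois = [r for r in cfg.roi_names if ROI_PREF(cfg, r) == fam]
        sub = beta_long[beta_long["roi"].isin(fam_rois)]
        if len(fam_rois) == 2:
            a = mixed_anova(sub, "mean_beta", "group", ["roi", "category"],
                            "participant", epsilon_method=cfg.epsilon_method)
            a.insert(0, "analysis", f"mean_beta_{fam}_rois")
            anovas.append(a)
        for cat in ("face", "scene"):
            collapsed = (sub[sub["category"] == cat]
                         .groupby(["participant", "group"], as_index=False)["mean_beta"].mean())
            x = collapsed[collapsed["group"] == g1]["mean_beta"].to_numpy()
            y = collapsed[collapsed["group"] == g2]["mean_beta"].to_numpy()
            pairwise.append({"analysis": f"mean_beta_{fam}_rois",
                             "contrast": f"{cat} trials: {g1} vs {g2}",
                             **welch_t(x, y).to_dict()})

    tables["anova"] = pd.concat(anovas, ignore_index=True)
    tables["pairwise"] = pd.DataFrame(pairwise)

    # ---- neural-behavior partial correlations (memory-prediction analog) ----
    kept_sorted = kept.sort_values("participant")
    item_overall = kept_sorted[["item_pr_face", "item_pr_scene"]].mean(axis=1).to_numpy()
    psr_vec = kept_sorted["psr"].to_numpy()
    grp_vec = kept_sorted["group"].to_numpy()
    pc_rows = []
    pc_cols = ["metric", "condition", "roi", "memory_measure", "kept_model",
               "interaction_p", "r_partial", "p", "df"]
    if len(kept_sorted) < 8:  # too few participants for the screen
        tables["partial_correlations"] = pd.DataFrame(columns=pc_cols)
        return tables
    for metric, tab, value in (("di", di, "di"), ("similarity", sim, "index")):
        for cond in conditions:
            for roi in cfg.roi_names:
                sub = (tab[(tab["condition"] == cond) & (tab["roi"] == roi)]
                       .sort_values("participant"))
                pred = sub[value].to_numpy()
                for memname, mem in (("item_memory", item_overall),
                                     ("source_memory", psr_vec)):
                    screen = interaction_screen_regression(mem, pred, grp_vec)
                    row = {"metric": metric, "condition": cond, "roi": roi,
                           "memory_measure": memname,
                           "kept_model": screen.kept_model,
                           "interaction_p": screen.interaction_p}
                    if screen.partial is not None:
                        row.update({"r_partial": screen.partial.effect_size,
                                    "p": screen.partial.p, "df": screen.partial.df})
                    else:
                        row.update({"r_partial": np.nan, "p": np.nan, "df": np.nan})
                    pc_rows.append(row)
    tables["partial_correlations"] = pd.DataFrame(pc_rows)
    return tables


def ROI_PREF(cfg: RunConfig, roi: str) -> str:
    return next(iter(cfg.groups.values())).neural[roi].preferred


def _balanced_groups(long: pd.DataFrame, group_of: dict) -> bool:
    counts = (long.drop_duplicates("participant")["participant"]
              .map(group_of).value_counts())
    return len(counts) == 2 and counts.nunique() == 1


TABLE_SCHEMAS = {
    "memory_scores": {"participant", "psr", "group", "retained"},
    "study_behavior": {"participant", "category", "memory", "n_trials",
                       "median_rt_ms", "mean_vividness", "group"},
    "di": {"participant", "group", "roi", "condition", "di", "mu_pref",
           "mu_nonpref", "sd_pref", "sd_nonpref", "n_pref", "n_nonpref"},
    "similarity": {"participant", "group", "roi", "condition", "within_scope",
                   "within_z", "between_z", "index", "n_within_pairs",
                   "n_between_pairs"},
    "mean_betas": {"participant", "group", "roi", "preferred",
                   "mean_beta_face", "mean_beta_scene"},
    "anova": {"analysis", "effect", "SS", "df1", "df2", "epsilon", "F", "p",
              "partial_eta_sq"},
    "pairwise": {"analysis", "contrast", "statistic", "df", "p", "effect_size"},
    "partial_correlations": {"metric", "condition", "roi", "memory_measure",
                             "kept_model", "interaction_p", "r_partial", "p"},
}


def validate_tables(tables: dict) -> None:
    """Check every output table against its documented column schema."""
    for name, required in TABLE_SCHEMAS.items():
        if name not in tables:
            raise ValueError(f"missing output table {name!r}")
        missing = required - set(tables[name].columns)
        if missing:
            raise ValueError(f"table {name!r} lacks columns {sorted(missing)}")


def run_synthetic_study(config: RunConfig, out_dir=None) -> dict:
    """Simulate a cohort, run every analysis, optionally write CSV outputs.

    Writes one CSV per table plus ``manifest.json`` (seed, config hash,
    package and library versions).  Byte-identical outputs for identical
    config + seed.
    """
    cohort = simulate_cohort(config)
    tables = analyze_cohort(cohort)
    validate_tables(tables)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "seed": config.seed,
            "n_per_group": config.n_per_group,
            "config_hash": config.config_hash(),
            "within_scope": config.within_scope,
            "epsilon_method": config.epsilon_method,
            "versions": {
                "dediff": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": platform.python_version(),
            },
            "tables": sorted(tables),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables
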