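"""Group-level inference: mixed ANOVAs, partial correlations with memory,
and neuropsychological factor scores.

Reads the tables written by scripts 02-04 and runs the statistical battery:
2 (age group) x 4 (ROI) mixed ANOVAs with Greenhouse-Geisser correction for
the differentiation and similarity indices, follow-up 2 x 2 ANOVAs per ROI
family, interaction-screened regressions of memory on each neural metric
(reporting the partial correlation controlling for age group), and factor
scores from the rotated-component loadings applied to synthetic
neuropsychological data.  Writes results/anova.csv,
results/partial_correlations.csv and results/factor_scores.csv.
"""

import json
from pathlib import Path

import pandas as pd

from dediff.io import NEUROPSYCH_LOADINGS
from dediff.simulate import synthetic_neuropsych_scores
from dediff.stats import apply_factor_loadings, interaction_screen_regression, mixed_anova, welch_t

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    di = pd.read_csv(BASE / "di.csv")
    sim = pd.read_csv(BASE / "similarity.csv")
    scores = pd.read_csv(BASE / "memory_scores.csv")
    group_of = json.loads((BASE / "cohort" / "groups.json").read_text())
    kept = scores[scores.retained].sort_values("participant")

    anovas, pc_rows = [], []
    for metric, tab, value in (("di", di, "di"), ("similarity", sim, "index")):
        tab = tab[tab.participant.isin(kept.participant)]
        for cond in ("all_trials", "source_correct_only"):
            sub = tab[tab.condition == cond]
            a = mixed_anova(sub, value, "group", "roi", "participant")
            a.insert(0, "analysis", f"{metric}_{cond}")
            anovas.append(a)
            for roi in sorted(sub.roi.unique()):
                s = sub[sub.roi == roi].sort_values("participant")
                for mem_name, mem in (
                    ("item_memory", kept[["item_pr_face", "item_pr_scene"]].mean(axis=1)),
                    ("source_memory", kept.psr),
                ):
                    screen = interaction_screen_regression(
                        mem.to_numpy(), s[value].to_numpy(), s["group"].to_numpy()
                    )
                    pc_rows.append({
                        "metric": metric, "condition": cond, "roi": roi,
                        "memory_measure": mem_name, "kept_model": screen.kept_model,
                        "interaction_p": round(screen.interaction_p, 4),
                        "r_partial": None if screen.partial is None
                        else round(screen.partial.effect_size, 3),
                        "p": None if screen.partial is None else round(screen.partial.p, 4),
                    })

    anova = pd.concat(anovas, ignore_index=True)
    pc = pd.DataFrame(pc_rows)
    anova.to_csv(BASE / "anova.csv", index=False)
    pc.to_csv(BASE / "partial_correlations.csv", index=False)

    print("2 (age group) x 4 (ROI) mixed ANOVA on the differentiation index:")
    print(anova[anova.analysis == "di_all_trials"]
          [["effect", "df1_corr", "df2_corr", "epsilon", "F", "p", "partial_eta_sq"]]
          .round(3).to_string(index=False))
    print("\npartial correlations (controlling age group), differentiation index:")
    print(pc[(pc.metric == "di") & (pc.condition == "all_trials")]
          [["roi", "memory_measure", "r_partial", "p"]].to_string(index=False))

    # factor scores on synthetic neuropsychological data
    np_scores = synthetic_neuropsych_scores(group_of, seed=SEED)
    fscores = apply_factor_loadings(np_scores, NEUROPSYCH_LOADINGS)
    fscores["group"] = fscores.index.map(group_of)
    fscores.to_csv(BASE / "factor_scores.csv")
    print("\nfactor-score group means (synthetic neuropsych battery):")
    print(fscores.groupby("group").mean().round(2).to_string())
    for comp in ("RC1_speed", "RC2_memory"):
        res = welch_t(fscores[fscores.group == "young"][comp],
                      fscores[fscores.group == "older"][comp])
        print(f"  {comp}: young vs older t({res.df:.1f}) = {res.statistic:.2f}, p = {res.p:.2g}")
    print(f"\nwrote {BASE}/anova.csv, partial_correlations.csv, factor_scores.csv")


if __name__ == "__main__":
    main()
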