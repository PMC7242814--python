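"""Score the cohort's behavior: item recognition (pR), source memory (pSR),
and study-phase RT/vividness binned by subsequent memory.

Reads results/cohort/events.tsv (script 01), applies the response-validity
windows (450-4500 ms study, 500-4500 ms test), scores each participant, and
writes per-participant scores plus group-mean summaries mirroring the
memory-performance and study-performance table layouts.
"""

import json
from pathlib import Path

import pandas as pd

from dediff import io as dio
from dediff.behavior import exclude_participants, score_participants, summarize_study_behavior

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    events = dio.read_events(BASE / "cohort" / "events.tsv")
    group_of = json.loads((BASE / "cohort" / "groups.json").read_text())

    scores = score_participants(events)
    scores["group"] = scores["participant"].map(group_of)
    retained = exclude_participants(dict(zip(scores.participant, scores.psr)))
    scores["retained"] = scores["participant"].isin(retained)
    scores.to_csv(BASE / "memory_scores.csv", index=False)

    study = summarize_study_behavior(events)
    study["group"] = study["participant"].map(group_of)
    study.to_csv(BASE / "study_behavior.csv", index=False)

    kept = scores[scores.retained]
    summary = kept.groupby("group")[
        ["hit_rate_face", "hit_rate_scene", "fa_rate",
         "item_pr_face", "item_pr_scene", "p_source_hit", "p_source_dk", "psr"]
    ].mean().round(3)
    print("group mean memory performance:")
    print(summary.to_string())
    n_excl = (~scores.retained).sum()
    print(f"\nparticipants excluded at pSR < 0.1: {n_excl}")
    pd.set_option("display.width", 120)
    cells = (study[study.participant.isin(retained)]
             .groupby(["group", "category", "memory"])
             [["median_rt_ms", "mean_vividness"]].mean().round(2))
    print("\nstudy-phase performance (group means):")
    print(cells.to_string())
    print(f"\nwrote {BASE}/memory_scores.csv and study_behavior.csv")


if __name__ == "__main__":
    main()
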