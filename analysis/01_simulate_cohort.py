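"""Simulate the synthetic cohort: 24 young + 24 older adults.

Generates the full two-cycle study/test design (192 study pairs, 96 new test
words, 96 null trials per phase per participant), fills in behavioral
responses with the group-specific accuracy parameters, and writes the event
table and group assignment under results/cohort/.  Beta patterns are
regenerated deterministically by the later scripts rather than stored (the
full set is ~300 MB as text).
"""

import json
from pathlib import Path

from dediff import io as dio
from dediff.design import check_design
from dediff.pipeline import default_config, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1


def main() -> None:
    cfg = default_config(seed=SEED, n_per_group=24)
    cohort = simulate_cohort(cfg, with_betas=False)
    check_design(cohort.events, cfg.design)
    OUT.mkdir(parents=True, exist_ok=True)
    dio.write_events(cohort.events, OUT / "events.tsv")
    (OUT / "groups.json").write_text(json.dumps(cohort.group_of, indent=0, sort_keys=True))

    ev = cohort.events
    study = ev[(ev.phase == "study") & (ev.trial_type == "critical")]
    print(f"cohort: {ev.participant.nunique()} participants "
          f"({sum(g == 'young' for g in cohort.group_of.values())} young)")
    print(f"study critical trials/participant: "
          f"{study.groupby('participant').size().unique().tolist()}")
    print(f"unique critical nouns: {ev[ev.trial_type.isin(['critical', 'new'])].word_id.nunique()}")
    print("run-length constraints verified on every list")
    print(f"wrote {OUT}/events.tsv and groups.json")


if __name__ == "__main__":
    main()
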