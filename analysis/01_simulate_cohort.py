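#!/usr/bin/env python
"""Simulate a desk-scale homecage NOR cohort and write example artifacts.

Twenty mice, novel side counterbalanced, with minutes-scale phases (10 min
habituation, 2 h sample, 30 min retention, 40 min test) in place of the full
multi-day schedule; hazards, novelty boost/decay and the f = 1.67 novel-side
factor are the study-scale values.  Writes a cohort summary table under
results/ and, for the first mouse, the full keypoint/label/schedule artifact
set under scratch/ (bulky, regenerated on demand).
"""

from pathlib import Path

import pandas as pd

from kagenor import io
from kagenor.synthetic import SessionSimConfig, simulate_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1


def main() -> None:
    cfg = SessionSimConfig(
        habituation_s=600.0, sample_s=7200.0, retention_s=1800.0, test_s=2400.0,
        seed=SEED,
    )
    sessions = simulate_cohort(cfg, 20)

    OUT.mkdir(exist_ok=True)
    example = SCRATCH / "example_session"
    example.mkdir(parents=True, exist_ok=True)
    io.write_keypoints_dlc(sessions[0].keypoints, example / "keypoints.csv")
    io.write_labels(sessions[0].labels, example / "labels.csv")
    io.write_schedule(sessions[0].schedule, example / "schedule.yaml")
    io.write_visits(sessions[0].corridor_visits, example / "corridor_visits.csv")

    rows = []
    for i, s in enumerate(sessions):
        rows.append(
            {
                "mouse": i,
                "novel_side": s.schedule.novel_side,
                "n_frames": s.keypoints.n_frames,
                "explore_left_s": s.labels.seconds("left"),
                "explore_right_s": s.labels.seconds("right"),
                "n_corridor_visits": len(s.corridor_visits),
                "n_nest_intervals": len(s.nest_intervals),
            }
        )
    summary = pd.DataFrame(rows)
    io.write_report(summary, OUT / "cohort_summary.csv", metadata={"seed": SEED})
    print(f"simulated {len(sessions)} mice "
          f"({summary['n_frames'].iloc[0]} frames each at 2 fps)")
    print(f"mean exploration: left {summary['explore_left_s'].mean():.1f} s, "
          f"right {summary['explore_right_s'].mean():.1f} s")
    print(f"example artifacts for mouse 0 in {example}")


if __name__ == "__main__":
    main()
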