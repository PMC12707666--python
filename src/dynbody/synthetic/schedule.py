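"""Event-related experimental design generation.

One run presents 20 stimuli (10 possible, 10 impossible) three times each,
plus 3 target trials, for 63 trials; 3 blank trials lengthen the baseline.
Two sessions of six runs share identical run content, so each stimulus is
presented 6 times across the 12 runs.  The inter-stimulus interval is
pseudo-randomised over 2, 3 or 4 TRs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["make_event_schedule", "default_stimulus_pool", "n_trs_per_run"]

EVENT_COLUMNS = ["run", "onset_s", "duration_s", "stimulus_id", "condition"]


def default_stimulus_pool(n_pairs: int = 60) -> pd.DataFrame:
    """Stimulus pool of possible/impossible twins (default 60 + 60 = 120)."""
    rows = []
    for k in range(n_pairs):
        rows.append({"stimulus_id": f"pos{k:03d}", "plausibility": "possible"})
        rows.append({"stimulus_id": f"imp{k:03d}", "plausibility": "impossible"})
    return pd.DataFrame(rows)


def make_event_schedule(
    pool: pd.DataFrame | None = None,
    n_runs: int = 12,
    n_sessions: int = 2,
    stimuli_per_run: int = 20,
    reps: int = 3,
    n_targets: int = 3,
    n_blanks: int = 3,
    tr_s: float = 2.3,
    isi_trs: tuple[int, ...] = (2, 3, 4),
    lead_in_trs: int = 4,
    stim_dur_trs: int = 1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate the full multi-run event table.

    The pool is partitioned into run-sets of ``stimuli_per_run`` stimuli with
    balanced plausibility; session 2 reuses session 1's run content so each
    stimulus appears ``reps * n_sessions`` times in total.  Onsets fall on
    the TR grid; each trial occupies ``stim_dur_trs`` TRs followed by a blank
    interval drawn from ``isi_trs``.
    """
    if pool is None:
        pool = default_stimulus_pool()
    rng = np.random.default_rng(seed)

    if n_runs % n_sessions:
        raise ValueError("n_runs must divide evenly into sessions")
    runs_per_session = n_runs // n_sessions
    n_pool = len(pool)
    if n_pool != runs_per_session * stimuli_per_run:
        raise ValueError(
            f"pool of {n_pool} stimuli does not partition into "
            f"{runs_per_session} run-sets of {stimuli_per_run}"
        )
    half = stimuli_per_run // 2
    pos = pool[pool["plausibility"] == "possible"]["stimulus_id"].tolist()
    imp = pool[pool["plausibility"] == "impossible"]["stimulus_id"].tolist()
    if len(pos) != n_pool // 2 or len(imp) != n_pool // 2:
        raise ValueError("pool must be half possible / half impossible")

    run_sets = [
        pos[r * half:(r + 1) * half] + imp[r * half:(r + 1) * half]
        for r in range(runs_per_session)
    ]

    session_tables = []
    for r, ids in enumerate(run_sets):
        trials = [(sid, "stimulus") for sid in ids for _ in range(reps)]
        trials += [("target", "target")] * n_targets
        trials += [("blank", "blank")] * n_blanks
        order = rng.permutation(len(trials))
        trials = [trials[i] for i in order]

        onset_tr = lead_in_trs
        rows = []
        for sid, cond in trials:
            rows.append(
                {
                    "run": r,
                    "onset_s": onset_tr * tr_s,
                    "duration_s": stim_dur_trs * tr_s,
                    "stimulus_id": sid,
                    "condition": cond,
                }
            )
            onset_tr += stim_dur_trs + int(rng.choice(isi_trs))
        session_tables.append(pd.DataFrame(rows))

    tables = []
    for s in range(n_sessions):
        for r, tab in enumerate(session_tables):
            t = tab.copy()
            t["run"] = s * runs_per_session + r
            tables.append(t)
    events = pd.concat(tables, ignore_index=True)[EVENT_COLUMNS]
    events.attrs["tr_s"] = tr_s
    return events


def n_trs_per_run(events: pd.DataFrame, tr_s: float = 2.3, tail_trs: int = 8) -> int:
    """Number of TRs per run covering the longest run plus a fixed tail."""
    end = (events["onset_s"] + events["duration_s"]).max()
    return int(np.ceil(end / tr_s)) + tail_trs
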