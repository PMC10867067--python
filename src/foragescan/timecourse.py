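"""Two-bin time-course splitting and the long-format score table.

Each trial's target-pick sequence is split into two halves ("bins"): the
first ceil(n/2) picks and the rest (the extra pick of an odd-length trial
goes to bin 1).  Bins are scored as self-contained sequences — the hop
between the last bin-1 pick and the first bin-2 pick belongs to neither —
and the per-bin organization scores feed the mixed-model comparison as one
row per trial x bin.  Age enters downstream models as ln(years), so the
table carries ``log_age`` alongside the raw age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import Pick, TrialRecord
from .org_metrics import score_sequence

MIN_PICKS_PER_BIN = 4  # default: smallest n at which all four indicators exist


@dataclass
class BinnedTrial:
    trial: TrialRecord
    bin1: list[Pick]
    bin2: list[Pick]
    excluded: bool = False
    reason: str = ""


def split_bins(trial: TrialRecord,
               min_picks_per_bin: int = MIN_PICKS_PER_BIN) -> BinnedTrial:
    """Split a trial's target picks into first/second halves.

    Trials with fewer than 2 target picks, or whose smaller bin falls below
    ``min_picks_per_bin``, are marked excluded with a reason code (they are
    still returned, so callers can audit exclusions).
    """
    picks = trial.target_picks
    n = len(picks)
    if n < 2:
        return BinnedTrial(trial, picks, [], excluded=True,
                           reason="too_few_picks")
    half = (n + 1) // 2
    b = BinnedTrial(trial, picks[:half], picks[half:])
    if min(len(b.bin1), len(b.bin2)) < min_picks_per_bin:
        b.excluded, b.reason = True, "bin_too_small"
    return b


@dataclass
class ScoreTable:
    """Long score table plus the exclusion ledger."""

    scores: pd.DataFrame
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)


_SCORE_COLS = ["best_r", "mean_itd", "pao", "intersection_rate"]


def build_score_table(trials,
                      min_picks_per_bin: int = MIN_PICKS_PER_BIN,
                      exact_threshold: int = 10,
                      include_whole: bool = False) -> ScoreTable:
    """Score every trial per bin and assemble the long table.

    One row per trial x bin (plus optional whole-trial rows) with columns
    participant, age, log_age, condition, set_size, trial, bin, n_picks and
    the four indicators; undefined indicators are NaN with their reason
    codes in ``reason_<indicator>`` columns.  Rows of excluded trials go to
    the exclusion ledger instead.
    """
    rows, excl = [], []
    for tr in trials:
        binned = split_bins(tr, min_picks_per_bin)
        if binned.excluded:
            excl.append({"participant": tr.participant_id,
                         "condition": tr.condition, "trial": tr.trial_index,
                         "reason": binned.reason})
            continue
        parts = [("bin1", binned.bin1), ("bin2", binned.bin2)]
        if include_whole:
            parts.append(("whole", tr.target_picks))
        for label, picks in parts:
            sc = score_sequence(picks, bin_label=label,
                                exact_threshold=exact_threshold)
            row = {"participant": tr.participant_id, "age": tr.age_years,
                   "log_age": float(np.log(tr.age_years)),
                   "condition": tr.condition, "set_size": tr.set_size,
                   "trial": tr.trial_index, "bin": label,
                   "n_picks": sc.n_picks}
            for col in _SCORE_COLS:
                v = getattr(sc, col)
                row[col] = np.nan if v is None else v
                row[f"reason_{col}"] = sc.reasons.get(col, "")
            rows.append(row)
    return ScoreTable(scores=pd.DataFrame(rows),
                      exclusions=pd.DataFrame(
                          excl, columns=["participant", "condition",
                                         "trial", "reason"]))
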