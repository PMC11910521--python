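"""Courtship and memory (courtship suppression) indices.

In courtship conditioning, a male fly exposed to unreceptive mated
females suppresses subsequent courtship; the strength of that suppression
measures memory. The courtship index (CI) of a fly is the fraction of the
scoring window it spends courting (scored from t = 2.5 min to the end of
the 12.5-min recording), and the memory index of a trained fly is

    MI = 1 − CI_trained / mean(CI_naive),

where the denominator is the mean CI of the naive (untrained) group. MI
is 1 for complete suppression, 0 for no suppression, and may be negative
for flies courting more than the naive average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: scoring window in seconds (2.5 min to 12.5 min, half-open)
DEFAULT_WINDOW = (150.0, 750.0)


@dataclass
class CourtshipRecord:
    """Per-frame courting indicators for one fly."""

    fly_id: str
    group: str  # 'naive' or 'trained'
    times: np.ndarray  # frame start times, seconds
    courting: np.ndarray  # boolean per frame
    genotype: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.courting = np.asarray(self.courting, dtype=bool)
        if self.times.shape != self.courting.shape:
            raise ValueError("times and courting must have equal length")
        if self.times.size == 0:
            raise ValueError("empty recording")


def courtship_index(record: CourtshipRecord,
                    window_start: float = DEFAULT_WINDOW[0],
                    window_end: float = DEFAULT_WINDOW[1]) -> float:
    """Fraction of frames spent courting within [window_start, window_end).

    Frame membership is by frame start time; the recording must cover the
    whole window.
    """
    t = record.times
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    if t[0] > window_start or t[-1] + dt < window_end:
        raise ValueError(
            f"recording [{t[0]}, {t[-1] + dt}) s does not cover the scoring "
            f"window [{window_start}, {window_end}) s"
        )
    sel = (t >= window_start) & (t < window_end)
    if not sel.any():
        raise ValueError("no frames fall inside the scoring window")
    return float(record.courting[sel].mean())


def memory_index(ci_trained: float, naive_cis) -> float:
    """Memory (courtship suppression) index: 1 − CI_trained / mean(CI_naive).

    Not clipped — a trained fly courting more than the naive average gets
    a negative MI.
    """
    naive_mean = float(np.mean(naive_cis))
    if naive_mean == 0:
        raise ValueError("naive mean courtship index is zero; MI undefined")
    return 1.0 - float(ci_trained) / naive_mean


def memory_table(trained_cis, naive_cis, fly_ids=None) -> pd.DataFrame:
    """Per-fly memory indices against a shared naive reference mean."""
    trained_cis = np.asarray(trained_cis, dtype=float)
    ids = fly_ids if fly_ids is not None else [f"fly{i + 1}" for i in range(len(trained_cis))]
    mis = [memory_index(ci, naive_cis) for ci in trained_cis]
    return pd.DataFrame({"fly_id": ids, "ci": trained_cis, "mi": mis,
                         "naive_mean": float(np.mean(naive_cis))})


def records_from_frame(df: pd.DataFrame) -> list[CourtshipRecord]:
    """Build records from a long table (fly_id, group, frame_time_s, courting)."""
    records = []
    for (fly, group), sub in df.groupby(["fly_id", "group"], sort=True):
        sub = sub.sort_values("frame_time_s")
        records.append(CourtshipRecord(
            fly_id=str(fly), group=str(group),
            times=sub["frame_time_s"].to_numpy(),
            courting=sub["courting"].to_numpy().astype(bool),
        ))
    return records


# thin wrappers over standard tests, for report generation only
def compare_groups(a, b, test: str = "mannwhitney"):
    """Two-group comparison: 'ttest' (Welch) or 'mannwhitney' (two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
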