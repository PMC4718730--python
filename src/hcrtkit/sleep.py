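"""Sleep-architecture scoring for zebrafish larvae from minute-binned activity.

Sleep in larval zebrafish is defined behaviorally: one or more consecutive
minutes of immobility counts as a sleep bout.  From a per-larva minute-binned
locomotor trace recorded under a light/dark cycle (default 14 h light : 10 h
dark) this module derives

* sleep bouts (maximal immobile runs, :func:`call_sleep_bouts`);
* per-hour sleep minutes, wake->sleep transition counts, mean bout length
  and mean activity, plus day/night aggregates (:func:`summarize_sleep`,
  :func:`score_cohort`);
* genotype comparisons of per-larva phase aggregates by a permutation test
  on the difference of group means (:func:`compare_genotypes`), exact by
  enumeration when feasible;
* post-sleep-deprivation rebound comparisons (:func:`rebound_analysis`).

A bout that spans an hour or light-phase boundary is attributed to the hour
and phase of its onset, which keeps per-hour transition counts additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTrace",
    "SleepBout",
    "SleepSummary",
    "call_sleep_bouts",
    "summarize_sleep",
    "score_cohort",
    "compare_genotypes",
    "rebound_analysis",
    "permutation_diff_test",
]


@dataclass
class ActivityTrace:
    """One larva's minute-binned activity values under a light/dark cycle.

    ``start_minute`` is the first sample's clock time in minutes after
    lights-on, so phase can be derived for recordings that do not start at
    dawn.  ``acclimation_min`` leading minutes are dropped before scoring.
    """

    larva_id: str
    genotype: str
    activity: np.ndarray
    light_hours: float = 14.0
    dark_hours: float = 10.0
    start_minute: int = 0
    acclimation_min: int = 0

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 1:
            raise ValueError("activity must be a 1-D minute series")
        if (self.activity < 0).any():
            raise ValueError("activity values must be non-negative")
        if self.acclimation_min:
            self.activity = self.activity[self.acclimation_min:]
            self.start_minute += self.acclimation_min
            self.acclimation_min = 0

    @property
    def n_minutes(self) -> int:
        return len(self.activity)

    @property
    def cycle_minutes(self) -> int:
        return int(round((self.light_hours + self.dark_hours) * 60))

    def light_phase(self) -> np.ndarray:
        """Per-minute phase label ('light' or 'dark')."""
        minutes = (self.start_minute + np.arange(self.n_minutes)) % self.cycle_minutes
        return np.where(minutes < self.light_hours * 60, "light", "dark")

    def phase_of_minute(self, minute: int) -> str:
        m = (self.start_minute + minute) % self.cycle_minutes
        return "light" if m < self.light_hours * 60 else "dark"


@dataclass(frozen=True)
class SleepBout:
    """Maximal run of consecutive immobile minutes."""

    larva_id: str
    start_minute: int
    length_min: int
    phase: str  # light phase at onset


@dataclass
class SleepSummary:
    """Hourly and day/night sleep metrics for one larva.

    ``hourly`` has one row per recording hour: sleep_min, n_transitions
    (wake->sleep onsets), mean_bout_len (NaN when no bout starts in the
    hour), mean_activity, phase.  ``day``/``night`` hold per-hour means over
    the respective phase (light = day).
    """

    larva_id: str
    genotype: str
    hourly: pd.DataFrame
    day: dict[str, float]
    night: dict[str, float]


def call_sleep_bouts(
    trace: ActivityTrace, immobility_epsilon: float = 0.0
) -> list[SleepBout]:
    """Sleep bouts under the one-minute immobility rule.

    A minute is immobile iff its activity is <= ``immobility_epsilon``
    (default 0: strict immobility).  Bouts are maximal runs of >= 1
    immobile minute, attributed to the phase of their onset minute.
    """
    a = trace.activity
    if a.size == 0:
        return []
    immobile = a <= immobility_epsilon
    padded = np.concatenate(([False], immobile, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [
        SleepBout(trace.larva_id, int(s), int(e - s), trace.phase_of_minute(int(s)))
        for s, e in zip(starts, ends)
    ]


def summarize_sleep(
    bouts: Sequence[SleepBout],
    trace: ActivityTrace,
    immobility_epsilon: float = 0.0,
) -> SleepSummary:
    """Hourly sleep metrics and day/night aggregates for one trace."""
    n_hours = math.ceil(trace.n_minutes / 60)
    immobile = trace.activity <= immobility_epsilon
    rows = []
    bout_starts = np.array([b.start_minute for b in bouts], dtype=int)
    bout_lengths = np.array([b.length_min for b in bouts], dtype=int)
    for h in range(n_hours):
        lo, hi = h * 60, min((h + 1) * 60, trace.n_minutes)
        in_hour = (bout_starts >= lo) & (bout_starts < hi)
        n_trans = int(in_hour.sum())
        rows.append(
            {
                "hour": h,
                "sleep_min": int(immobile[lo:hi].sum()),
                "n_transitions": n_trans,
                "mean_bout_len": float(bout_lengths[in_hour].mean()) if n_trans else np.nan,
                "mean_activity": float(trace.activity[lo:hi].mean()),
                "phase": trace.phase_of_minute(lo),
            }
        )
    hourly = pd.DataFrame(rows)

    def _phase_agg(phase: str) -> dict[str, float]:
        sub = hourly[hourly["phase"] == phase]
        if sub.empty:
            return {k: float("nan") for k in
                    ("sleep_min_per_h", "transitions_per_h", "bout_len", "activity_mean")}
        with np.errstate(invalid="ignore"):
            bout_len = float(sub["mean_bout_len"].mean())  # NaN hours skipped by pandas
        return {
            "sleep_min_per_h": float(sub["sleep_min"].mean()),
            "transitions_per_h": float(sub["n_transitions"].mean()),
            "bout_len": bout_len,
            "activity_mean": float(sub["mean_activity"].mean()),
        }

    return SleepSummary(
        larva_id=trace.larva_id,
        genotype=trace.genotype,
        hourly=hourly,
        day=_phase_agg("light"),
        night=_phase_agg("dark"),
    )


def score_cohort(
    traces: Iterable[ActivityTrace], immobility_epsilon: float = 0.0
) -> pd.DataFrame:
    """Per-larva day/night aggregates for a cohort, one row per larva.

    Columns: larva_id, genotype, then ``{day,night}_{sleep_min_per_h,
    transitions_per_h,bout_len,activity_mean}``.
    """
    rows = []
    for trace in traces:
        bouts = call_sleep_bouts(trace, immobility_epsilon)
        s = summarize_sleep(bouts, trace, immobility_epsilon)
        row: dict[str, object] = {"larva_id": s.larva_id, "genotype": s.genotype}
        for phase, agg in (("day", s.day), ("night", s.night)):
            for key, value in agg.items():
                row[f"{phase}_{key}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_diff_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_permutations: int = 10000,
    seed: int | None = None,
    max_exact: int = 20000,
) -> tuple[float, float]:
    """Two-sided permutation test of a difference in group means.

    Returns ``(observed difference of means a - b, p)``.  When the number of
    distinct label assignments C(n, n_a) is at most ``max_exact`` the null
    distribution is enumerated exhaustively and the p-value is exact;
    otherwise ``n_permutations`` Monte-Carlo draws are used with the
    add-one correction.  Ties are counted as at-least-as-extreme with a
    small numerical tolerance.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    obs = a.mean() - b.mean()
    tol = 1e-12 * max(1.0, abs(obs))
    total_mean_term = pooled.sum()

    if math.comb(n, na) <= max_exact:
        count = 0
        total = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = sa / na - (total_mean_term - sa) / (n - na)
            if abs(stat) >= abs(obs) - tol:
                count += 1
            total += 1
        return float(obs), count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = perm[:na].mean() - perm[na:].mean()
        if abs(stat) >= abs(obs) - tol:
            count += 1
    return float(obs), (1 + count) / (n_permutations + 1)


def compare_genotypes(
    cohort: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    phase: str = "night",
    metric: str = "sleep_min_per_h",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Difference of per-larva phase aggregates between genotypes + permutation p.

    ``cohort`` is the frame from :func:`score_cohort`; ``phase`` is 'day' or
    'night'; ``metric`` one of the aggregate names.  Returns
    ``(mean_a - mean_b, p)``.
    """
    col = f"{phase}_{metric}"
    if col not in cohort.columns:
        raise KeyError(f"no column {col!r} in cohort summary")
    va = cohort.loc[cohort["genotype"] == genotype_a, col].dropna().to_numpy()
    vb = cohort.loc[cohort["genotype"] == genotype_b, col].dropna().to_numpy()
    if va.size < 2 or vb.size < 2:
        raise ValueError("each genotype needs at least 2 larvae")
    return permutation_diff_test(va, vb, n_permutations=n_permutations, seed=seed)


def rebound_analysis(
    post_sleep_deprived: Sequence[float],
    post_sleep_control: Sequence[float],
    window_min_deprived: int | None = None,
    window_min_control: int | None = None,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Post-deprivation sleep rebound: deprived minus control sleep time.

    Inputs are per-larva total sleep minutes scored over matched recording
    windows following the deprivation period.  When window lengths are
    provided they must match.  Returns ``(mean difference, permutation p)``;
    a positive difference indicates rebound sleep in the deprived group.
    """
    if (
        window_min_deprived is not None
        and window_min_control is not None
        and window_min_deprived != window_min_control
    ):
        raise ValueError(
            "post-deprivation windows differ between groups "
            f"({window_min_deprived} vs {window_min_control} min)"
        )
    return permutation_diff_test(
        post_sleep_deprived, post_sleep_control, n_permutations=n_permutations, seed=seed
    )
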