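"""Rolling-window predictive evaluation of threshold models.

The protocol: pick a sequence of test-window start hours spaced 6 hours
apart.  For each window, everything strictly before the start is training
data; thresholds are (re)fitted on it, the simulator is initialised from the
observed history, rolled 24 hours forward fully self-driven, and the
predicted number of active users in each of the window's four 6-hour
subintervals is scored against the observed count with the absolute
percentage error ``100 |n_hat - n| / n``; the window score is the mean of the
four.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import ThresholdProfile, simulate
from .estimation import TreeOptions, fit_profile
from .network_io import ActivityLog, WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationWindow:
    """One training interval plus a tiled 24-hour test span."""

    test_start: int
    test_hours: int = 24
    sub_hours: int = 6

    def __post_init__(self):
        if self.test_hours % self.sub_hours != 0:
            raise ValueError("test_hours must be a multiple of sub_hours")

    @property
    def n_sub(self) -> int:
        return self.test_hours // self.sub_hours

    @property
    def test_end(self) -> int:
        return self.test_start + self.test_hours

    def subintervals(self) -> list[tuple[int, int]]:
        return [
            (self.test_start + k * self.sub_hours, self.test_start + (k + 1) * self.sub_hours)
            for k in range(self.n_sub)
        ]


def make_windows(
    first_test_start: int,
    last_test_start: int,
    *,
    shift_hours: int = 6,
    test_hours: int = 24,
    sub_hours: int = 6,
) -> list[EvaluationWindow]:
    """Windows at ``first, first+shift, ..., last`` (hours from episode start).

    The bounds must be aligned: ``last - first`` divisible by the shift.
    """
    if last_test_start < first_test_start:
        raise ValueError("last_test_start must be >= first_test_start")
    span = last_test_start - first_test_start
    if span % shift_hours != 0:
        raise ValueError(
            f"window span {span}h is not a multiple of the {shift_hours}h shift"
        )
    return [
        EvaluationWindow(first_test_start + k * shift_hours, test_hours, sub_hours)
        for k in range(span // shift_hours + 1)
    ]


def count_active(log: ActivityLog, interval: tuple[int, int]) -> int:
    """Distinct users with at least one active hour in ``[a, b)``."""
    a, b = interval
    if a < 0 or b > log.T or a > b:
        raise ValueError(f"interval {interval} outside log horizon [0, {log.T}]")
    return int(log.matrix[:, a:b].any(axis=1).sum())


def mape_interval(n_hat: int, n: int) -> float | None:
    """``100 |n_hat - n| / n``; 0 when both counts are 0, None (excluded)
    when the observed count is 0 but the prediction is not."""
    if n == 0:
        return 0.0 if n_hat == 0 else None
    return 100.0 * abs(n_hat - n) / n


def evaluate_model(
    model: str,
    wnet: WeightedNetwork,
    log: ActivityLog,
    windows: list[EvaluationWindow],
    *,
    features: pd.DataFrame | None = None,
    feature_builder=None,
    t_login: int = 24,
    pattern: str = "constant",
    t_effect: float = math.inf,
    tree_options: TreeOptions | None = None,
    profile: ThresholdProfile | None = None,
    train_hours: int | None = None,
) -> pd.DataFrame:
    """Fit-and-forecast over every window; returns a tidy score table.

    Per window: thresholds are fitted on ``log[:, :test_start)`` (skipped
    with a flag if that prefix holds no activity), the simulator is seeded
    with the observed prefix and rolled to the window end, and the four
    subinterval active-user counts are scored.  ``features`` fixes one
    feature table for all windows; ``feature_builder(interval) ->
    DataFrame`` recomputes per window; ``profile`` skips fitting entirely
    (e.g. to replay known thresholds).  ``train_hours`` restricts each fit
    to the trailing ``train_hours`` of decisions before the test start
    (equal-sized training sets across windows) instead of the full history.

    Columns: window_start, model, subinterval, n_hat, n, ape, window_mape.
    """
    opts = tree_options or TreeOptions()
    opts = TreeOptions(**{**opts.__dict__, "model": model})
    rows = []
    for win in windows:
        ts = win.test_start
        if win.test_end > log.T:
            raise ValueError(f"window ending at {win.test_end}h exceeds log horizon {log.T}h")
        train = log.prefix(ts)
        if train.matrix.sum() == 0:
            logger.warning("window %dh skipped: no training activity", ts)
            continue
        if profile is not None:
            prof = profile
        else:
            if feature_builder is not None:
                feats = feature_builder((0, ts))
            elif features is not None:
                feats = features
            else:
                raise ValueError("provide features, feature_builder, or profile")
            prof, _ = fit_profile(
                wnet,
                train,
                feats,
                t_login=t_login,
                pattern=pattern,
                t_effect=t_effect,
                options=opts,
                obs_min_hour=0 if train_hours is None else max(0, ts - train_hours),
            )
        sim = simulate(
            model,
            wnet,
            prof,
            train,
            t_login=t_login,
            pattern=pattern,
            t_effect=t_effect,
            horizon=win.test_end,
        )
        apes = []
        sub_rows = []
        for k, (a, b) in enumerate(win.subintervals()):
            n_hat = count_active(sim, (a, b))
            n = count_active(log, (a, b))
            ape = mape_interval(n_hat, n)
            if ape is not None:
                apes.append(ape)
            sub_rows.append((ts, model, k, n_hat, n, ape))
        window_mape = float(np.mean(apes)) if apes else float("nan")
        for r in sub_rows:
            rows.append(r + (window_mape,))
    return pd.DataFrame(
        rows,
        columns=["window_start", "model", "subinterval", "n_hat", "n", "ape", "window_mape"],
    )


def compare_models(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Side-by-side per-window errors for two result tables.

    Returns the comparison table (one row per window) and a summary with
    overall means and per-window win counts.  The window sets must match.
    """
    def _per_window(df: pd.DataFrame) -> pd.Series:
        return df.groupby("window_start")["window_mape"].first()

    a, b = _per_window(results_a), _per_window(results_b)
    if not a.index.equals(b.index):
        raise ValueError("window sets differ between the two result tables")
    name_a = results_a["model"].iloc[0] if len(results_a) else "a"
    name_b = results_b["model"].iloc[0] if len(results_b) else "b"
    table = pd.DataFrame(
        {f"mape_{name_a}": a, f"mape_{name_b}": b}
    )
    table["winner"] = np.where(
        a < b, name_a, np.where(b < a, name_b, "tie")
    )
    summary = {
        f"mean_mape_{name_a}": float(a.mean()),
        f"mean_mape_{name_b}": float(b.mean()),
        f"wins_{name_a}": int((a < b).sum()),
        f"wins_{name_b}": int((b < a).sum()),
        "ties": int((a == b).sum()),
        "n_windows": int(len(a)),
    }
    return table.reset_index(), summary


def threshold_summary(
    profiles: dict[object, ThresholdProfile]
) -> pd.DataFrame:
    """Joint (theta_lower, theta_upper) frequency table per stage.

    ``profiles`` maps a stage label (e.g. a window start) to the profile
    fitted there; the output has one row per (stage, band) cell with the
    user count and within-stage frequency, the tabular analogue of a
    bubble plot of threshold distributions over an episode.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for stage, prof in profiles.items():
        pairs = pd.DataFrame(
            {"theta_lower": prof.lower, "theta_upper": prof.upper}
        )
        counts = pairs.value_counts().sort_index()
        for (lo, hi), n in counts.items():
            rows.append(
                {
                    "stage": stage,
                    "theta_lower": lo,
                    "theta_upper": hi,
                    "n_users": int(n),
                    "frequency": float(n / len(pairs)),
                }
            )
    return pd.DataFrame(rows)
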