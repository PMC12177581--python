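"""Behavioral forgetting metrics for IGT sessions.

Two quantities summarize how exploration and memory shape a choice sequence:

* **SE events / SED.** A sequential-exploration (SE) event is four
  consecutive trials selecting four distinct decks. Under uniform random
  choice the per-window rate is 4!/4^4 = 9.375%. The Sequential Exploration
  Decay (SED) ratio divides the SE-event count in the first half of the task
  (trials 1-50 of a 100-trial session) by the count in the second half; a
  ratio above 1 means exploration wanes as the task progresses.

* **Forgetting Interval (FI).** After a negative-feedback trial (the chosen
  deck's net outcome is below zero, by default), the FI is the number of
  trials until that deck is next reselected. Under uniform random choice the
  interval is geometric with mean 1/p = 4 trials; longer intervals indicate
  persistent avoidance, shorter ones faster forgetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .env import Cohort, Session

__all__ = [
    "MetricsReport",
    "se_events",
    "sed_ratio",
    "forgetting_intervals",
    "fi_summary",
    "random_baselines",
    "cohort_metrics",
    "model_metric_profile",
    "chi_square_uniform",
    "one_sample_t",
    "welch_t",
    "fisher_z",
    "binomial_test",
]

RANDOM_FI = 4.0          # geometric mean 1/p at p = 1/4
RANDOM_SE_RATE = 0.09375 # 4!/4^4


@dataclass
class MetricsReport:
    """SED and FI summary for one session or a pooled cohort."""

    se_count_first: int
    se_count_last: int
    sed_ratio: float          # inf when the late window has no events
    sed_infinite: bool
    fi_intervals: list[int]
    fi_mean: float
    fi_sd: float
    n_censored: int
    fi_events: list[tuple[int, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "se_count_first": self.se_count_first,
            "se_count_last": self.se_count_last,
            "sed_ratio": self.sed_ratio,
            "sed_infinite": self.sed_infinite,
            "fi_mean": self.fi_mean,
            "fi_sd": self.fi_sd,
            "n_fi_events": len(self.fi_intervals),
            "n_censored": self.n_censored,
        }


def se_events(choices, trial_range: tuple[int, int]) -> int:
    """Count of 4-trial windows with four distinct decks, fully inside the
    1-based inclusive window ``trial_range``. Overlapping windows count."""
    choices = np.asarray(choices)
    lo, hi = trial_range
    if lo < 1 or hi > len(choices):
        raise ValueError(f"window {trial_range} outside session of {len(choices)} trials")
    if hi - lo + 1 < 4:
        raise ValueError("window must span at least 4 trials")
    count = 0
    for start in range(lo - 1, hi - 3):
        if len(set(choices[start:start + 4].tolist())) == 4:
            count += 1
    return count


def sed_ratio(data: Session | Cohort, split: tuple[tuple[int, int], tuple[int, int]] | None = None,
              pooling: str = "pooled-counts") -> tuple[float, bool]:
    """SED = SE events in the early window / SE events in the late window.

    ``split`` defaults to ((1, T//2), (T//2+1, T)). For a cohort,
    ``pooled-counts`` (default) sums events across sessions before dividing;
    ``per-session-mean`` averages finite per-session ratios. Returns
    (ratio, infinite_flag); the flag marks a zero late-window count.
    """
    sessions = [data] if isinstance(data, Session) else list(data)
    T = sessions[0].n_trials
    if split is None:
        split = ((1, T // 2), (T // 2 + 1, T))
    first_win, last_win = split

    if pooling == "pooled-counts":
        first = sum(se_events(s.choices, first_win) for s in sessions)
        last = sum(se_events(s.choices, last_win) for s in sessions)
        if last == 0:
            return math.inf, True
        return first / last, False
    if pooling == "per-session-mean":
        ratios = []
        any_inf = False
        for s in sessions:
            f = se_events(s.choices, first_win)
            l = se_events(s.choices, last_win)
            if l == 0:
                any_inf = True
                continue
            ratios.append(f / l)
        if not ratios:
            return math.inf, True
        return float(np.mean(ratios)), any_inf
    raise ValueError(f"unknown pooling {pooling!r}")


def forgetting_intervals(session: Session, feedback_rule: str = "net") -> tuple[list[int], int, list[tuple[int, int, int]]]:
    """Reselection intervals after negative feedback.

    A feedback trial t is one where the chosen deck's outcome is negative:
    net < 0 under rule ``"net"`` (default; deck C's small losses net >= 0 and
    are excluded) or loss > 0 under rule ``"any-loss"``. Its interval is
    t' - t for the first later trial t' choosing the same deck; events with
    no reselection are censored. Returns (intervals, n_censored, events)
    with events as 1-based (feedback trial, reselect trial, interval).
    """
    if feedback_rule == "net":
        neg = session.nets < 0
    elif feedback_rule == "any-loss":
        neg = session.losses > 0
    else:
        raise ValueError(f"unknown feedback_rule {feedback_rule!r}")
    choices = session.choices
    intervals: list[int] = []
    events: list[tuple[int, int, int]] = []
    n_censored = 0
    T = session.n_trials
    for t in np.flatnonzero(neg):
        deck = choices[t]
        later = np.flatnonzero(choices[t + 1:] == deck)
        if later.size:
            dt = int(later[0]) + 1
            intervals.append(dt)
            events.append((t + 1, t + 1 + dt, dt))
        else:
            n_censored += 1
    return intervals, n_censored, events


def fi_summary(data: Session | Cohort, feedback_rule: str = "net") -> tuple[float, float, int, int]:
    """(mean, sd, n_intervals, n_censored) of FIs pooled over sessions."""
    sessions = [data] if isinstance(data, Session) else list(data)
    all_iv: list[int] = []
    censored = 0
    for s in sessions:
        iv, c, _ = forgetting_intervals(s, feedback_rule)
        all_iv.extend(iv)
        censored += c
    if not all_iv:
        return math.nan, math.nan, 0, censored
    arr = np.asarray(all_iv, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, len(all_iv), censored


def random_baselines() -> tuple[float, float]:
    """(expected FI, expected SE-event rate) under uniform random choice:
    (4.0 trials, 0.09375)."""
    return RANDOM_FI, RANDOM_SE_RATE


def cohort_metrics(data: Session | Cohort, feedback_rule: str = "net",
                   pooling: str = "pooled-counts") -> MetricsReport:
    """Full SED + FI report for a session or (pooled) cohort."""
    sessions = [data] if isinstance(data, Session) else list(data)
    T = sessions[0].n_trials
    first_win, last_win = (1, T // 2), (T // 2 + 1, T)
    first = sum(se_events(s.choices, first_win) for s in sessions)
    last = sum(se_events(s.choices, last_win) for s in sessions)
    ratio, inf_flag = sed_ratio(data, pooling=pooling)
    mean, sd, n_iv, censored = fi_summary(data, feedback_rule)
    events = []
    if isinstance(data, Session):
        _, _, events = forgetting_intervals(data, feedback_rule)
    intervals = []
    for s in sessions:
        iv, _, _ = forgetting_intervals(s, feedback_rule)
        intervals.extend(iv)
    return MetricsReport(
        se_count_first=first,
        se_count_last=last,
        sed_ratio=ratio,
        sed_infinite=inf_flag,
        fi_intervals=intervals,
        fi_mean=mean,
        fi_sd=sd,
        n_censored=censored,
        fi_events=events,
    )


def model_metric_profile(model: str, fitted_params: pd.DataFrame, scheme,
                         n_trials: int = 100, reps: int = 10, seed: int = 0,
                         feedback_rule: str = "net") -> dict:
    """SED and FI of a model simulated from per-session fitted parameters.

    For each parameter row, ``reps`` sessions are simulated; SE counts and
    FIs are pooled over everything. Returns pooled sed_ratio, fi_mean/fi_sd
    and the per-rep SED spread. Fully seeded.
    """
    from .env import generate_synthetic_cohort, simulate_session
    from .models import get_model

    spec = get_model(model)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(reps * len(fitted_params)) % 2**31
    sessions = []
    i = 0
    for rep in range(reps):
        for sid, row in fitted_params.iterrows():
            params = {n: float(row[n]) for n in spec.param_names}
            agent = spec.make_agent(params, scheme=scheme)
            sessions.append(simulate_session(agent, scheme, n_trials=n_trials,
                                             seed=int(seeds[i]), subject_id=f"{sid}-r{rep}"))
            i += 1
    cohort = Cohort(sessions, provenance=f"profile:{model} reps={reps} seed={seed}")
    ratio, inf_flag = sed_ratio(cohort)
    fi_mean, fi_sd, n_iv, censored = fi_summary(cohort, feedback_rule)
    per_rep = []
    n_per = len(fitted_params)
    for rep in range(reps):
        chunk = Cohort(sessions[rep * n_per:(rep + 1) * n_per])
        r, f = sed_ratio(chunk)
        if not f:
            per_rep.append(r)
    return {
        "model": model,
        "sed_ratio": ratio,
        "sed_infinite": inf_flag,
        "sed_per_rep": per_rep,
        "fi_mean": fi_mean,
        "fi_sd": fi_sd,
        "n_fi_events": n_iv,
        "n_censored": censored,
        "reps": reps,
        "seed": seed,
    }


# ------------------------------------------------------------ group tests

def chi_square_uniform(counts) -> tuple[float, int, float]:
    """Goodness of fit of observed counts against a uniform distribution."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    res = stats.chisquare(counts)
    return float(res.statistic), counts.size - 1, float(res.pvalue)


def one_sample_t(values, popmean: float, alternative: str = "two-sided") -> tuple[float, int, float]:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need n >= 2")
    res = stats.ttest_1samp(values, popmean, alternative=alternative)
    return float(res.statistic), values.size - 1, float(res.pvalue)


def welch_t(a, b, alternative: str = "two-sided") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fisher_z(r1: float, n1: int, r2: float, n2: int,
             alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher z-test comparing two independent Pearson correlations."""
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 per correlation")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def binomial_test(k: int, n: int, p: float = 0.5,
                  alternative: str = "two-sided") -> float:
    return float(stats.binomtest(k, n, p, alternative=alternative).pvalue)
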