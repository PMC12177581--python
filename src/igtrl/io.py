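"""Reading and writing IGT cohorts.

Two on-disk layouts are supported:

* **wide** — three participants x trials CSV matrices (choices, wins,
  losses), the layout of the public IGT repositories. Losses may be stored as
  negative numbers; they are normalized to magnitudes on read.
* **long** — one tidy CSV with columns subject, trial, deck, gain, loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .env import Cohort, Session

__all__ = ["read_wide_cohort", "write_wide_cohort", "read_long_cohort", "write_long_cohort"]


def _read_matrix(path, header) -> pd.DataFrame:
    df = pd.read_csv(path, header=0 if header else None)
    return df.apply(pd.to_numeric)


def read_wide_cohort(choice_table, wins_table, losses_table, header: bool = True) -> Cohort:
    """Build a cohort from three equally shaped participants x trials tables.

    Rows pair up across the three files in order; row i becomes session
    ``subj-i`` (or the index label if the choices file has one). Loss signs
    are normalized to magnitudes.
    """
    choices = _read_matrix(choice_table, header)
    wins = _read_matrix(wins_table, header)
    losses = _read_matrix(losses_table, header)
    if not (choices.shape == wins.shape == losses.shape):
        raise ValueError(
            f"shape mismatch: choices {choices.shape}, wins {wins.shape}, losses {losses.shape}"
        )
    cvals = choices.to_numpy(dtype=np.int64)
    if not np.all((cvals >= 1) & (cvals <= 4)):
        raise ValueError("choice values must be deck indices in 1..4")
    sessions = []
    for i in range(len(choices)):
        sessions.append(
            Session(
                subject_id=f"subj-{i}",
                choices=cvals[i],
                gains=np.abs(wins.to_numpy(dtype=float)[i]),
                losses=np.abs(losses.to_numpy(dtype=float)[i]),
            )
        )
    return Cohort(sessions, provenance=f"wide:{choice_table}")


def write_wide_cohort(cohort: Cohort, choice_table, wins_table, losses_table) -> None:
    """Write the three wide matrices (losses as magnitudes, header = trial
    numbers). Round-trips through :func:`read_wide_cohort`."""
    T = cohort.n_trials
    cols = [f"trial_{t}" for t in range(1, T + 1)]
    pd.DataFrame([s.choices for s in cohort], columns=cols).to_csv(choice_table, index=False)
    pd.DataFrame([s.gains for s in cohort], columns=cols).to_csv(wins_table, index=False)
    pd.DataFrame([s.losses for s in cohort], columns=cols).to_csv(losses_table, index=False)


def read_long_cohort(path) -> Cohort:
    """Tidy CSV with columns subject, trial, deck, gain, loss (loss sign
    normalized). Trials are sorted within subject."""
    df = pd.read_csv(path)
    required = {"subject", "trial", "deck", "gain", "loss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long cohort missing columns {sorted(missing)}")
    sessions = []
    for sid, grp in df.groupby("subject", sort=False):
        grp = grp.sort_values("trial")
        sessions.append(
            Session(
                subject_id=str(sid),
                choices=grp["deck"].to_numpy(dtype=np.int64),
                gains=np.abs(grp["gain"].to_numpy(dtype=float)),
                losses=np.abs(grp["loss"].to_numpy(dtype=float)),
            )
        )
    return Cohort(sessions, provenance=f"long:{path}")


def write_long_cohort(cohort: Cohort, path) -> None:
    rows = []
    for s in cohort:
        for t in range(s.n_trials):
            rows.append({"subject": s.subject_id, "trial": t + 1,
                         "deck": int(s.choices[t]), "gain": float(s.gains[t]),
                         "loss": float(s.losses[t])})
    pd.DataFrame(rows).to_csv(path, index=False)
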