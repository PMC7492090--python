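"""Trial-level choice data containers and CSV round-tripping.

A :class:`ChoiceDataset` is one subject's worth of two-alternative
forced-choice trials: the pair of dot counts shown, the side chosen
(1 = left, 0 = right), and whether the choice was correct.  Option 1 is the
left cloud throughout; correctness is derived from the dot counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CSV_COLUMNS", "ChoiceDataset"]

CSV_COLUMNS = ["subject", "day", "run", "trial", "condition",
               "dots_left", "dots_right", "choice", "correct"]

_INT_COLUMNS = ["subject", "day", "run", "trial",
                "dots_left", "dots_right", "choice", "correct"]


@dataclass
class ChoiceDataset:
    """Per-trial stimuli, choices and correctness for one subject.

    Attributes
    ----------
    df
        One row per trial with columns :data:`CSV_COLUMNS`.  ``choice`` is
        1 for left, 0 for right; ``correct`` is 1 iff the chosen cloud had
        more dots.
    meta
        Free-form metadata; for synthetic data, the generating model name
        and parameters.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"ChoiceDataset missing columns: {missing}")
        if self.df["choice"].isna().any():
            raise ValueError("missing choice entries")
        if not self.df["choice"].isin([0, 1]).all():
            raise ValueError("choice must be 0 (right) or 1 (left)")
        if (self.df["dots_left"] == self.df["dots_right"]).any():
            raise ValueError("trials must have unequal dot counts")
        self.df = self.df[CSV_COLUMNS].reset_index(drop=True)
        for c in _INT_COLUMNS:
            self.df[c] = self.df[c].astype(np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def subject(self) -> int:
        return int(self.df["subject"].iloc[0])

    @property
    def accuracy(self) -> float:
        return float(self.df["correct"].mean())

    def history_regressors(self) -> tuple[np.ndarray, np.ndarray]:
        """Previous-trial choice side a and outcome r, reset per run.

        a = +1 left / -1 right, r = +1 correct / -1 incorrect; the first
        trial of each (day, run) has a = r = 0.
        """
        a_cur = np.where(self.df["choice"].to_numpy() == 1, 1.0, -1.0)
        r_cur = np.where(self.df["correct"].to_numpy() == 1, 1.0, -1.0)
        a = np.roll(a_cur, 1)
        r = np.roll(r_cur, 1)
        run_key = self.df[["day", "run"]].to_numpy()
        first = np.ones(len(self.df), dtype=bool)
        if len(self.df) > 1:
            first[1:] = (run_key[1:] != run_key[:-1]).any(axis=1)
        a[first] = 0.0
        r[first] = 0.0
        return a, r

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "ChoiceDataset":
        df = pd.read_csv(path)
        return cls(df=df, meta=meta or {})

    @staticmethod
    def correctness(dots_left: np.ndarray, dots_right: np.ndarray,
                    choice: np.ndarray) -> np.ndarray:
        """1 iff the chosen cloud contains more dots."""
        left_larger = dots_left > dots_right
        return np.where(choice == 1, left_larger, ~left_larger).astype(np.int64)
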