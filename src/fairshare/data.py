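"""Trial-level choice dataset: validation, CSV dialect, and accessors.

The on-disk dialect is a UTF-8 CSV with header::

    participant_id,group,role,frame,block,round,r_self,r_other,total_tokens,tokens_kept

with ``role`` in {first, third} and ``frame`` in {gain, loss}.  A dataset may
carry ground-truth generating parameters (from the synthetic cohort
generator) in a sidecar table with columns
``participant_id,k,parameter,value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .task import Allocation, Condition, ExchangeRatio, Frame, Role, Trial

__all__ = ["ChoiceDataset", "read_dataset", "write_dataset", "COLUMNS"]

COLUMNS = [
    "participant_id",
    "group",
    "role",
    "frame",
    "block",
    "round",
    "r_self",
    "r_other",
    "total_tokens",
    "tokens_kept",
]

_ROLES = {r.value for r in Role}
_FRAMES = {f.value for f in Frame}


class DatasetError(ValueError):
    """Raised when a choice table violates the dataset invariants."""


@dataclass
class ChoiceDataset:
    """A flat table of dictator-game trials with the allocation made on each.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per trial with the canonical columns (see module docstring).
    ground_truth : pandas.DataFrame, optional
        Long-format generating parameters (participant_id, k, parameter,
        value) when the dataset was simulated.
    """

    table: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.table
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        bad_role = ~df["role"].isin(_ROLES)
        if bad_role.any():
            raise DatasetError(
                f"row {bad_role.idxmax()}: unknown role {df.loc[bad_role.idxmax(), 'role']!r}"
            )
        bad_frame = ~df["frame"].isin(_FRAMES)
        if bad_frame.any():
            raise DatasetError(
                f"row {bad_frame.idxmax()}: unknown frame {df.loc[bad_frame.idxmax(), 'frame']!r}"
            )
        for col in ("block", "round", "r_self", "r_other", "total_tokens", "tokens_kept"):
            if not np.issubdtype(df[col].dtype, np.number):
                raise DatasetError(f"column {col} must be numeric")
        if (df[["r_self", "r_other"]] <= 0).any().any():
            bad = int((df[["r_self", "r_other"]] <= 0).any(axis=1).idxmax())
            raise DatasetError(f"row {bad}: nonpositive exchange ratio")
        out = (df["tokens_kept"] < 0) | (df["tokens_kept"] > df["total_tokens"])
        if out.any():
            bad = int(out.idxmax())
            raise DatasetError(
                f"row {bad}: tokens_kept={df.loc[bad, 'tokens_kept']} outside "
                f"[0, {df.loc[bad, 'total_tokens']}]"
            )
        dup = df.duplicated(subset=["participant_id", "block", "round"])
        if dup.any():
            bad = int(dup.idxmax())
            raise DatasetError(f"row {bad}: duplicate (participant, block, round)")

    # ------------------------------------------------------------------ access
    def __len__(self) -> int:
        return len(self.table)

    @property
    def participants(self) -> list:
        return list(pd.unique(self.table["participant_id"]))

    @property
    def groups(self) -> list:
        return list(pd.unique(self.table["group"]))

    def for_group(self, group: str) -> "ChoiceDataset":
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise KeyError(f"no trials for group {group!r}")
        gt = None
        if self.ground_truth is not None:
            gt = self.ground_truth[
                self.ground_truth["participant_id"].isin(sub["participant_id"])
            ].reset_index(drop=True)
        return ChoiceDataset(sub.copy(), gt)

    def for_participant(self, pid) -> "ChoiceDataset":
        sub = self.table[self.table["participant_id"] == pid]
        if sub.empty:
            raise KeyError(f"no trials for participant {pid!r}")
        return ChoiceDataset(sub.copy())

    def iter_trials(self) -> Iterator[tuple[Trial, int]]:
        """Yield (Trial, tokens_kept) pairs in row order."""
        for row in self.table.itertuples(index=False):
            cond = Condition(Role(row.role), Frame(row.frame))
            trial = Trial(
                condition=cond,
                ratio=ExchangeRatio(int(row.r_self), int(row.r_other)),
                total_tokens=int(row.total_tokens),
                block=int(row.block),
                round=int(row.round),
            )
            yield trial, int(row.tokens_kept)

    def with_condition_index(self) -> pd.DataFrame:
        """Table plus a ``k`` column (1..4 condition index)."""
        df = self.table.copy()
        kmap = {
            ("first", "gain"): 1,
            ("first", "loss"): 2,
            ("third", "gain"): 3,
            ("third", "loss"): 4,
        }
        df["k"] = [kmap[(r, f)] for r, f in zip(df["role"], df["frame"])]
        return df

    def true_params(self, pid) -> dict:
        """Ground-truth parameters for one participant as
        {name: length-4 array} plus {'lam': float}; raises if absent."""
        if self.ground_truth is None:
            raise ValueError("dataset carries no ground truth")
        gt = self.ground_truth[self.ground_truth["participant_id"] == pid]
        if gt.empty:
            raise KeyError(f"no ground truth for participant {pid!r}")
        out: dict = {}
        for name, sub in gt.groupby("parameter"):
            if name == "lam":
                out["lam"] = float(sub["value"].iloc[0])
            else:
                arr = np.full(4, np.nan)
                for _, r in sub.iterrows():
                    arr[int(r["k"]) - 1] = r["value"]
                out[name] = arr
        return out


def write_dataset(dataset: ChoiceDataset, path: "str | Path") -> None:
    """Write a dataset to CSV; ground truth goes to a ``*.truth.csv`` sidecar."""
    path = Path(path)
    dataset.table.to_csv(path, index=False)
    if dataset.ground_truth is not None:
        dataset.ground_truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def read_dataset(path: "str | Path", strict_design: bool = False) -> ChoiceDataset:
    """Read a trial-level CSV, validating every dataset invariant.

    With ``strict_design=True``, exchange ratios outside the five-ratio study
    design raise a warning-level :class:`DatasetError` annotation via
    ``warnings``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    gt_path = path.with_suffix(".truth.csv")
    gt = pd.read_csv(gt_path) if gt_path.exists() else None
    ds = ChoiceDataset(table, gt)
    if strict_design:
        from .task import DESIGN_RATIOS

        pairs = set(zip(ds.table["r_self"].astype(int), ds.table["r_other"].astype(int)))
        off = pairs - set(DESIGN_RATIOS)
        if off:
            import warnings

            warnings.warn(f"ratios outside the study design: {sorted(off)}", stacklevel=2)
    return ds
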