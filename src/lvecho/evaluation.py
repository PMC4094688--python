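"""Dice overlap between semiautomatic and reference masks, and its binning.

The agreement between the automatic delineation A and the expert reference B
is the Dice value D(A, B) = 2|A∩B| / (|A| + |B|): 1 is a perfect match, 0 no
overlap. Values are reported in three clinical quality intervals
(<0.8, 0.8–0.9, >0.9); both interval boundaries belong to the middle bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DICE_BINS = ("<0.8", "0.8–0.9", ">0.9")


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice value 2|A∩B| / (|A| + |B|) of two binary masks on one grid.

    Symmetric in its arguments. If both masks are empty the value is defined
    as 0 and a warning is emitted (degenerate comparison).
    """
    A = np.asarray(A).astype(bool)
    B = np.asarray(B).astype(bool)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    size = int(A.sum()) + int(B.sum())
    if size == 0:
        warnings.warn("dice of two empty masks is undefined; returning 0", stacklevel=2)
        return 0.0
    return 2.0 * int((A & B).sum()) / size


def bin_dice(d: float) -> str:
    """Clinical quality bin of a Dice value (boundaries 0.8 and 0.9 → middle bin)."""
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"Dice value {d} outside [0, 1]")
    if d < 0.8:
        return DICE_BINS[0]
    if d <= 0.9:
        return DICE_BINS[1]
    return DICE_BINS[2]


@dataclass(frozen=True)
class DelineationRecord:
    """One semiautomatic-vs-reference comparison."""

    animal: int
    observer: int
    dose_label: str
    dice: float
    dice_bin: str = ""

    def __post_init__(self) -> None:
        expected = bin_dice(self.dice)
        if self.dice_bin == "":
            object.__setattr__(self, "dice_bin", expected)
        elif self.dice_bin != expected:
            raise ValueError(
                f"dice_bin {self.dice_bin!r} inconsistent with dice={self.dice}"
            )


def tabulate(records) -> pd.DataFrame:
    """Counts of delineations per (dose, Dice bin); one row per dose, one
    column per bin, rows summing to the number of records for that dose."""
    records = list(records)
    if not records:
        raise ValueError("no delineation records")
    df = pd.DataFrame(
        [
            {"dose": r.dose_label, "bin": r.dice_bin}
            for r in records
        ]
    )
    out = (
        df.groupby(["dose", "bin"]).size().unstack(fill_value=0)
        .reindex(columns=list(DICE_BINS), fill_value=0)
    )
    out.columns.name = None
    return out.reset_index()


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal": r.animal,
                "observer": r.observer,
                "dose": r.dose_label,
                "dice": r.dice,
                "bin": r.dice_bin,
            }
            for r in records
        ]
    )


def records_from_frame(df: pd.DataFrame) -> list[DelineationRecord]:
    return [
        DelineationRecord(
            animal=int(row.animal),
            observer=int(row.observer),
            dose_label=str(row.dose),
            dice=float(row.dice),
        )
        for row in df.itertuples()
    ]
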