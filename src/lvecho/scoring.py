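"""Six-segment visual-scoring data model and its aggregation.

One apical two-chamber view of the left ventricle is divided into six wall
segments — two per region (apical, mid, base), one on each lateral wall — and
each segment is graded on an ordinal visibility scale:

    0 = not visible, 1 = weakly visible, 2 = visible.

The table is long-form: one record per (animal, observer, dose, segment).
With 8 animals and 3 independent observers this gives 144 records per dose
overall and 48 per region, the sample sizes the paired rank statistics use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REGIONS = ("apical", "mid", "base")
#: wall-segment → region map: segments 1–3 run apex→base on one wall, 4–6 on the other
REGION_OF_SEGMENT = {1: "apical", 2: "mid", 3: "base", 4: "apical", 5: "mid", 6: "base"}
SCORES = (0, 1, 2)

COLUMNS = ["animal", "observer", "dose", "segment", "region", "score"]


class UnpairedDesignError(ValueError):
    """Raised when a paired comparison is requested on an incomplete design."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "unpaired design; missing (animal, observer, segment) keys: "
            + ", ".join(map(str, self.missing))
        )


@dataclass
class SegmentScoreTable:
    """Long-form segment visibility scores with design-validity checks."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing_cols = set(COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"score table missing columns: {sorted(missing_cols)}")
        if not df["score"].isin(SCORES).all():
            raise ValueError("scores must be in {0, 1, 2}")
        if not df["segment"].isin(REGION_OF_SEGMENT).all():
            raise ValueError("segments must be in 1..6")
        bad = df[df["region"] != df["segment"].map(REGION_OF_SEGMENT)]
        if len(bad):
            raise ValueError("region labels inconsistent with the 6-segment layout")
        keys = df[["animal", "observer", "dose", "segment"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (animal, observer, dose, segment) records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def doses(self) -> list:
        return sorted(self.records["dose"].unique().tolist())

    def to_csv(self, path) -> None:
        self.records[COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SegmentScoreTable":
        return cls(pd.read_csv(path))


def score_distribution(
    table: SegmentScoreTable, dose, region: str = "all"
) -> tuple[int, int, int]:
    """Counts (n0, n1, n2) of visibility scores for one dose, overall or per region."""
    df = table.records
    if dose not in set(df["dose"].unique()):
        raise ValueError(f"unknown dose {dose!r}")
    sel = df[df["dose"] == dose]
    if region != "all":
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        sel = sel[sel["region"] == region]
    counts = sel["score"].value_counts()
    return tuple(int(counts.get(s, 0)) for s in SCORES)


def paired_scores(
    table: SegmentScoreTable, dose_a, dose_b, region: str | None = None
) -> list[tuple[int, int]]:
    """Score pairs matched on (animal, observer, segment) — the pairing the
    Wilcoxon signed-rank test requires.

    Raises :class:`UnpairedDesignError` naming the keys whose counterpart is
    missing in either dose.
    """
    df = table.records
    if region is not None:
        df = df[df["region"] == region]
    key = ["animal", "observer", "segment"]
    a = df[df["dose"] == dose_a].set_index(key)["score"]
    b = df[df["dose"] == dose_b].set_index(key)["score"]
    missing = sorted(set(a.index.tolist()) ^ set(b.index.tolist()))
    if missing:
        raise UnpairedDesignError(missing)
    b = b.reindex(a.index)
    return list(zip(a.astype(int).tolist(), b.astype(int).tolist()))


def distribution_table(table: SegmentScoreTable) -> pd.DataFrame:
    """Per-dose score distributions, overall and per region (wide summary)."""
    rows = []
    for dose in table.doses:
        row: dict = {"dose": dose}
        for region in ("all",) + REGIONS:
            n0, n1, n2 = score_distribution(table, dose, region)
            for s, n in zip(SCORES, (n0, n1, n2)):
                row[f"{region}_{s}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
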