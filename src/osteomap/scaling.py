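"""Complementary high/low node encoding.

Every continuous variable is min–max scaled to [0,1] and expanded into two
complementary node columns: "high" carries the scaled value and "low" its
complement 1 − scaled.  Binary variables are already 0/1 and expand directly
into a "yes"/"no" (or "positive"/"negative") pair.  The expansion lets the
association learner see where a variable sits when its values run high
separately from where it sits when they run low, which need not be symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BINARY, CohortTable


class ScalingError(ValueError):
    """A column cannot be min–max scaled (zero observed range)."""


@dataclass
class ScaledMatrix:
    """Records × expanded-node matrix in [0,1].

    ``provenance`` maps every node label back to its source variable and
    polarity ("high"/"low"); ``high + low = 1`` holds exactly per cell.
    """

    node_labels: list[str]
    values: np.ndarray
    provenance: dict[str, tuple[str, str]]
    record_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.record_ids), len(self.node_labels)):
            raise ValueError("values shape does not match labels/ids")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("scaled values must lie in [0,1]")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.node_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.node_labels)
        df.insert(0, "record_id", self.record_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def minmax_scale(column: np.ndarray, name: str = "") -> np.ndarray:
    """(x − min)/(max − min); errors on a constant column."""
    x = np.asarray(column, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ScalingError(
            f"column {name or '<unnamed>'!r} is constant (zero range); cannot scale"
        )
    return (x - lo) / (hi - lo)


def expand_complementary(
    table: CohortTable,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> ScaledMatrix:
    """Expand a cohort table into the complementary node matrix.

    Scaling uses the observed per-column min/max by default (within-sample
    scaling); pass ``bounds`` to scale selected variables against fixed
    external ranges instead.  Binary variables skip scaling.
    """
    table.validate()
    labels: list[str] = []
    cols: list[np.ndarray] = []
    provenance: dict[str, tuple[str, str]] = {}
    for v in table.schema.variables:
        raw = table.values(v.name).astype(float)
        if v.kind == BINARY:
            high = raw
        elif bounds and v.name in bounds:
            lo, hi = bounds[v.name]
            if hi <= lo:
                raise ScalingError(f"invalid external bounds for {v.name!r}")
            high = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
        else:
            high = minmax_scale(raw, v.name)
        low = 1.0 - high
        labels += [v.high_label, v.low_label]
        cols += [high, low]
        provenance[v.high_label] = (v.name, "high")
        provenance[v.low_label] = (v.name, "low")
    return ScaledMatrix(
        node_labels=labels,
        values=np.column_stack(cols),
        provenance=provenance,
        record_ids=[str(i) for i in table.ids],
    )
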