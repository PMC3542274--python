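"""The RH genotype matrix: lines x markers presence/absence calls.

Calls live in {retained, lost, missing}.  Internally the grid is a float
array with 1.0 = retained, 0.0 = lost, NaN = missing, which makes the
counting operations vectorizable; the public accessors speak in call names.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RETAINED = 1.0
LOST = 0.0

CALL_TO_CODE = {"retained": 1.0, "lost": 0.0, "missing": np.nan}
CODE_TO_SYMBOL = {1.0: "1", 0.0: "0"}


class GenotypeMatrix:
    """Rectangular grid of calls with line and marker labels.

    Parameters
    ----------
    calls
        Array-like of shape (n_lines, n_markers) with values in
        {1.0, 0.0, NaN}.
    line_ids, marker_ids
        Unique labels for rows and columns.
    family_of
        Optional mapping line_id -> RH1 family id.
    """

    def __init__(
        self,
        calls,
        line_ids: Sequence[str],
        marker_ids: Sequence[str],
        family_of: Mapping[str, str] | None = None,
    ) -> None:
        arr = np.asarray(calls, dtype=float)
        if arr.ndim != 2:
            raise ValueError("calls must be a 2-D grid")
        if arr.shape != (len(line_ids), len(marker_ids)):
            raise ValueError(
                f"calls shape {arr.shape} does not match "
                f"{len(line_ids)} lines x {len(marker_ids)} markers"
            )
        valid = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid call {arr[i, j]!r} at line {line_ids[i]!r}, "
                f"marker {marker_ids[j]!r}; calls must be 1, 0 or NaN"
            )
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("duplicate line ids")
        if len(set(marker_ids)) != len(marker_ids):
            raise ValueError("duplicate marker ids")
        self.calls = arr
        self.line_ids = list(line_ids)
        self.marker_ids = list(marker_ids)
        self.family_of = dict(family_of) if family_of else {}
        self._line_index = {l: i for i, l in enumerate(self.line_ids)}
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}

    # -- shape ---------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_lines} lines x {self.n_markers} markers)"
        )

    # -- indexing ------------------------------------------------------
    def line_index(self, line_id: str) -> int:
        return self._line_index[line_id]

    def marker_index(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def marker_calls(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker_id)]

    def line_calls(self, line_id: str) -> np.ndarray:
        return self.calls[self.line_index(line_id), :]

    def call(self, line_id: str, marker_id: str) -> str:
        v = self.calls[self.line_index(line_id), self.marker_index(marker_id)]
        if np.isnan(v):
            return "missing"
        return "retained" if v == RETAINED else "lost"

    # -- masks ---------------------------------------------------------
    @property
    def is_lost(self) -> np.ndarray:
        return self.calls == LOST

    @property
    def is_retained(self) -> np.ndarray:
        return self.calls == RETAINED

    @property
    def is_scored(self) -> np.ndarray:
        return ~np.isnan(self.calls)

    # -- subsetting ----------------------------------------------------
    def subset_lines(self, line_ids: Iterable[str]) -> "GenotypeMatrix":
        keep = [self.line_index(l) for l in line_ids]
        ids = [self.line_ids[i] for i in keep]
        return GenotypeMatrix(
            self.calls[keep, :],
            ids,
            self.marker_ids,
            {l: self.family_of[l] for l in ids if l in self.family_of},
        )

    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        keep = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(
            self.calls[:, keep],
            self.line_ids,
            [self.marker_ids[j] for j in keep],
            self.family_of,
        )

    def lines_in_family(self, family_id: str) -> list[str]:
        return [l for l in self.line_ids if self.family_of.get(l) == family_id]

    @property
    def family_ids(self) -> list[str]:
        seen: list[str] = []
        for l in self.line_ids:
            f = self.family_of.get(l)
            if f is not None and f not in seen:
                seen.append(f)
        return seen

    # -- conversions ---------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.line_ids, columns=self.marker_ids
        )

    @classmethod
    def from_calls(
        cls,
        rows: Mapping[str, Sequence[str]],
        marker_ids: Sequence[str],
        family_of: Mapping[str, str] | None = None,
    ) -> "GenotypeMatrix":
        """Build from named call strings, e.g. {'L1': ['lost', 'retained']}."""
        line_ids = list(rows)
        grid = np.empty((len(line_ids), len(marker_ids)))
        for i, line in enumerate(line_ids):
            calls = rows[line]
            if len(calls) != len(marker_ids):
                raise ValueError(f"line {line!r} has {len(calls)} calls")
            for j, c in enumerate(calls):
                try:
                    grid[i, j] = CALL_TO_CODE[c]
                except KeyError:
                    raise ValueError(f"unknown call {c!r}") from None
        return cls(grid, line_ids, marker_ids, family_of)
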