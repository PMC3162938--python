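"""Core containers for replicated time-series expression data.

Expression is measured on a shared, non-uniform time grid (hours) with one
or more replicates per time point.  All downstream analysis (correlation
screening, dynamic-model fitting) works on replicate-averaged profiles;
replicates are kept so that measurement noise can be characterised and so
that file round-trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesExpression",
    "ExpressionDataset",
    "normalize_gene_id",
]


def normalize_gene_id(gene_id: str) -> str:
    """Canonicalise a gene identifier: strip whitespace, upper-case.

    Identifier matching throughout the package is case-insensitive (AGI
    locus tags such as ``At3g01470`` appear with mixed casing in the wild).
    """
    return str(gene_id).strip().upper()


@dataclass(frozen=True, eq=False)
class TimeSeriesExpression:
    """One gene's expression over a strictly increasing time grid.

    Parameters
    ----------
    gene : str
        Gene identifier (canonicalised on construction).
    times : ndarray of shape (T,)
        Time grid in hours, strictly increasing.
    values : array-like
        Either a (T, R) array (R replicates, shared across time points) or
        a length-T sequence of 1-D arrays, allowing the replicate count to
        vary per time point (every point needs at least one measurement).
    """

    gene: str
    times: np.ndarray
    values: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene_id(self.gene))
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"time grid for {self.gene!r} is not strictly increasing")

        raw = self.values
        try:
            arr = np.asarray(raw, dtype=float)
            rectangular = arr.ndim <= 2
        except ValueError:  # ragged replicate counts
            rectangular = False
        if rectangular:
            if arr.ndim == 1:
                arr = arr[:, None]
            reps = tuple(arr[i, :].copy() for i in range(arr.shape[0]))
        else:
            reps = tuple(np.atleast_1d(np.asarray(v, dtype=float)) for v in raw)
        if len(reps) != times.shape[0]:
            raise ValueError(
                f"{self.gene!r}: {len(reps)} value rows for {times.shape[0]} time points"
            )
        for i, v in enumerate(reps):
            if v.size == 0:
                raise ValueError(f"{self.gene!r}: no replicate at time {times[i]}")
            if np.isnan(v).any():
                raise ValueError(f"{self.gene!r}: missing values are not accepted at ingest")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", reps)

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    @property
    def replicate_counts(self) -> tuple[int, ...]:
        return tuple(v.size for v in self.values)

    @property
    def n_replicates(self) -> int:
        """Replicate count when uniform across time points (raises otherwise)."""
        counts = set(self.replicate_counts)
        if len(counts) != 1:
            raise ValueError(f"{self.gene!r}: replicate count varies per time point")
        return counts.pop()

    def value_matrix(self) -> np.ndarray:
        """(T, R) array of replicate values; requires a uniform replicate count."""
        self.n_replicates  # validates uniformity
        return np.vstack(self.values)

    def mean_profile(self) -> np.ndarray:
        """Replicate-averaged expression, shape (T,)."""
        return np.array([v.mean() for v in self.values])

    def with_values(self, values) -> "TimeSeriesExpression":
        return TimeSeriesExpression(self.gene, self.times, values)


class ExpressionDataset:
    """A condition-labelled collection of :class:`TimeSeriesExpression`.

    All member profiles share the same time grid.  Gene lookup is
    case-insensitive.
    """

    def __init__(self, condition: str, profiles: Iterable[TimeSeriesExpression]):
        self.condition = condition
        self._profiles: dict[str, TimeSeriesExpression] = {}
        grid: np.ndarray | None = None
        for prof in profiles:
            if grid is None:
                grid = prof.times
            elif not np.array_equal(grid, prof.times):
                raise ValueError(
                    f"profile {prof.gene!r} is not on the dataset's shared time grid"
                )
            if prof.gene in self._profiles:
                raise ValueError(f"duplicate gene identifier {prof.gene!r}")
            self._profiles[prof.gene] = prof
        self._grid = grid if grid is not None else np.empty(0)

    @property
    def times(self) -> np.ndarray:
        return self._grid

    @property
    def genes(self) -> list[str]:
        return list(self._profiles)

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[TimeSeriesExpression]:
        return iter(self._profiles.values())

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_id(gene) in self._profiles

    def __getitem__(self, gene: str) -> TimeSeriesExpression:
        key = normalize_gene_id(gene)
        try:
            return self._profiles[key]
        except KeyError:
            raise KeyError(f"no expression profile for gene {gene!r}") from None

    def mean_matrix(self) -> pd.DataFrame:
        """Replicate-averaged expression as a genes x times DataFrame."""
        return pd.DataFrame(
            {g: p.mean_profile() for g, p in self._profiles.items()},
            index=pd.Index(self._grid, name="time_h"),
        ).T

    def to_frame(self) -> pd.DataFrame:
        """Wide on-disk layout: one row per gene, columns ``t<hours>_r<rep>``.

        Requires a replicate count that is shared by all genes and time
        points (which everything this package writes satisfies).
        """
        columns: list[str] = []
        if self._profiles:
            first = next(iter(self._profiles.values()))
            n_rep = first.n_replicates
            for t in self._grid:
                for r in range(n_rep):
                    columns.append(f"t{format_time(t)}_r{r + 1}")
        data = {g: p.value_matrix().reshape(-1) for g, p in self._profiles.items()}
        frame = pd.DataFrame.from_dict(data, orient="index", columns=columns)
        frame.index.name = "gene_id"
        return frame


def format_time(t: float) -> str:
    """Render 0.5 -> ``"0.5"`` and 2.0 -> ``"2"`` for column headers."""
    return f"{t:g}"
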