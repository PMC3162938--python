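"""Readers and writers for the pipeline's file contracts.

Expression matrices are TSV/CSV with a ``gene_id`` first column and
replicate columns headered ``t<hours>_r<rep>`` (e.g. ``t0_r1`` ...
``t48_r3``); time is encoded in the header so a single file is
self-describing.  Candidate predictions are two-column TSV (``tf_id``,
``target_id``); scored rough-network edge lists add ``abs_pearson_r`` and
``condition`` columns.  Every writer's output is readable by the matching
reader.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, TimeSeriesExpression, format_time, normalize_gene_id
from .errors import LightGRNError
from .rough import CandidateEdge, RoughNetwork

__all__ = [
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_candidate_table",
    "write_candidate_table",
    "read_gene_list",
    "write_gene_list",
    "write_rough_network",
    "read_rough_network",
]

_HEADER_RE = re.compile(r"^t(?P<time>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


class ParseError(LightGRNError):
    """Malformed input file."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_expression_matrix(path, condition: str | None = None) -> ExpressionDataset:
    """Parse an expression TSV/CSV into an :class:`ExpressionDataset`.

    The time grid is inferred from the column headers and sorted, so
    out-of-order headers are realigned on ingest.  Replicate counts may
    vary per time point but every point needs at least one column.
    """
    path = Path(path)
    frame = _read_table(path)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene_id column plus value columns")
    columns: list[tuple[float, int, str]] = []
    for name in frame.columns[1:]:
        m = _HEADER_RE.match(name.strip())
        if not m:
            raise ParseError(
                f"{path}: malformed column header {name!r} (expected t<hours>_r<rep>)"
            )
        columns.append((float(m.group("time")), int(m.group("rep")), name))
    times = sorted({t for t, _, _ in columns})
    by_time: dict[float, list[str]] = {t: [] for t in times}
    for t, rep, name in sorted(columns):
        by_time[t].append(name)

    profiles: list[TimeSeriesExpression] = []
    seen: set[str] = set()
    for row_idx, row in frame.iterrows():
        gene = normalize_gene_id(row.iloc[0])
        if gene in seen:
            raise ParseError(f"{path}: duplicate gene id {gene!r} at row {row_idx}")
        seen.add(gene)
        reps = []
        for t in times:
            vals = []
            for name in by_time[t]:
                cell = row[name]
                try:
                    vals.append(float(cell))
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric cell at row {row_idx}, column {name!r}: {cell!r}"
                    ) from None
            reps.append(np.asarray(vals))
        profiles.append(TimeSeriesExpression(gene, np.asarray(times), reps))
    label = condition if condition is not None else path.stem
    return ExpressionDataset(label, profiles)


def write_expression_matrix(dataset: ExpressionDataset, path) -> Path:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    dataset.to_frame().to_csv(path, sep=sep)
    return path


def read_candidate_table(path) -> list[CandidateEdge]:
    """Two-column TSV (``tf_id``, ``target_id``) of predicted bindings."""
    frame = _read_table(path)
    required = {"tf_id", "target_id"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: candidate table needs columns {sorted(required)}")
    return [CandidateEdge(row.tf_id, row.target_id) for row in frame.itertuples()]


def write_candidate_table(edges: Iterable[CandidateEdge], path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [{"tf_id": e.tf, "target_id": e.target} for e in edges],
        columns=["tf_id", "target_id"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(normalize_gene_id(line))
    return out


def write_gene_list(genes: Iterable[str], path) -> Path:
    path = Path(path)
    path.write_text("\n".join(normalize_gene_id(g) for g in genes) + "\n")
    return path


def write_rough_network(net: RoughNetwork, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "tf_id": e.tf,
                "target_id": e.target,
                "abs_pearson_r": e.score,
                "condition": net.condition,
            }
            for e in net.edges
        ],
        columns=["tf_id", "target_id", "abs_pearson_r", "condition"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_rough_network(path, genes: Iterable[str] = ()) -> RoughNetwork:
    frame = _read_table(path)
    edges = tuple(
        CandidateEdge(row.tf_id, row.target_id, score=float(row.abs_pearson_r))
        for row in frame.itertuples()
    )
    condition = frame["condition"].iloc[0] if len(frame) else ""
    pool = frozenset(normalize_gene_id(g) for g in genes) or frozenset(
        g for e in edges for g in e.pair
    )
    return RoughNetwork(condition=condition, edges=edges, genes=pool)
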