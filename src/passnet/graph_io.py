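"""Reading, validating, aggregating and serializing weighted digraphs and metric reports.

The orientation convention is fixed everywhere in this package: the ROW index
of an adjacency matrix is the sender (passer) and the COLUMN index is the
receiver, so ``W[i, j]`` is the weight of the arc ``i -> j`` (number of passes
from player *i* to player *j*).

Two validation profiles exist.  The default ``"sports"`` profile forbids
self-loops (a player cannot pass to themself), so the diagonal must be zero
and self-pass events are rejected.  The ``"general"`` profile admits
self-loops, for which every metric formula remains well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Profile = Literal["sports", "general"]

__all__ = [
    "WeightedDigraph",
    "PassEvent",
    "MetricReport",
    "ValidationError",
    "NonSquareError",
    "NegativeWeightError",
    "MissingWeightError",
    "SelfLoopError",
    "DuplicateLabelError",
    "EmptyGraphError",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "read_events_csv",
    "read_edgelist_tsv",
    "aggregate_events",
    "write_report",
    "read_report_json",
]


class ValidationError(ValueError):
    """Base class for all input-validation failures."""


class NonSquareError(ValidationError):
    pass


class NegativeWeightError(ValidationError):
    pass


class MissingWeightError(ValidationError):
    """A weight is NaN or otherwise absent."""


class SelfLoopError(ValidationError):
    """Nonzero diagonal entry / self-pass under the sports profile."""


class DuplicateLabelError(ValidationError):
    pass


class EmptyGraphError(ValidationError):
    """Graph has no weight at all, or fewer than two nodes."""


@dataclass(frozen=True)
class WeightedDigraph:
    """A weighted directed network: node labels plus a square weight matrix.

    ``W[i, j]`` is the non-negative weight of the arc from ``labels[i]``
    (sender) to ``labels[j]`` (receiver).  This object is the single source
    of truth for every metric in :mod:`passnet.metrics`.
    """

    labels: tuple[str, ...]
    W: np.ndarray
    profile: Profile = "sports"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        validate_graph(self.labels, W, self.profile)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def total_weight(self) -> float:
        """Total weight L of the network (total completed passes)."""
        return float(self.W.sum())

    def out_strengths(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def in_strengths(self) -> np.ndarray:
        return self.W.sum(axis=0)

    def transpose(self) -> "WeightedDigraph":
        """The reversed network (every arc i->j becomes j->i)."""
        return WeightedDigraph(self.labels, self.W.T.copy(), self.profile)

    def scaled(self, c: float) -> "WeightedDigraph":
        if c <= 0:
            raise ValidationError(f"scale factor must be > 0, got {c}")
        return WeightedDigraph(self.labels, self.W * c, self.profile)


def validate_graph(labels: Sequence[str], W: np.ndarray, profile: Profile) -> None:
    if profile not in ("sports", "general"):
        raise ValidationError(f"unknown profile {profile!r}")
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise NonSquareError(f"weight matrix must be square, got shape {W.shape}")
    n = W.shape[0]
    if len(labels) != n:
        raise NonSquareError(
            f"{len(labels)} labels for a {n}x{n} matrix"
        )
    if n < 2:
        raise EmptyGraphError(f"need at least 2 nodes, got {n}")
    if len(set(labels)) != n:
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise DuplicateLabelError(f"duplicate node label {lab!r}")
            seen.add(lab)
    if np.isnan(W).any():
        i, j = map(int, np.argwhere(np.isnan(W))[0])
        raise MissingWeightError(
            f"missing/NaN weight at cell ({labels[i]!r}, {labels[j]!r})"
        )
    if (W < 0).any():
        i, j = map(int, np.argwhere(W < 0)[0])
        raise NegativeWeightError(
            f"negative weight {W[i, j]} at cell ({labels[i]!r}, {labels[j]!r})"
        )
    if profile == "sports":
        diag = np.diagonal(W)
        if (diag != 0).any():
            i = int(np.nonzero(diag)[0][0])
            raise SelfLoopError(
                f"nonzero diagonal entry {diag[i]} for node {labels[i]!r} "
                "under the sports profile (self-passes are not allowed)"
            )
    if W.sum() <= 0:
        raise EmptyGraphError("total weight must be positive")


@dataclass(frozen=True)
class PassEvent:
    """One completed pass: sender -> receiver, with an optional timestamp.

    The timestamp (seconds) is ignored by all metrics; it is kept so that
    event logs can later be windowed before aggregation.
    """

    sender: str
    receiver: str
    timestamp: float | None = None


@dataclass
class MetricReport:
    """Full per-node + network metric record for one network.

    ``per_node`` has exactly ``n`` entries in label order.  ``variant``
    records which reception reading ("literal" or "conditional") produced
    the in-direction numbers, so values are never ambiguous downstream.
    """

    per_node: list  # list[NodeMetrics]; typed loosely to avoid an import cycle
    network: object  # NetworkMetrics
    variant: str
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Adjacency CSV
# ---------------------------------------------------------------------------

def read_adjacency_csv(path: str | Path, profile: Profile = "sports") -> WeightedDigraph:
    """Load a labelled square adjacency matrix from CSV.

    Layout: a header row with receiver labels, a first column of sender
    labels, numeric body; row = sender, column = receiver.  Labels are kept
    in file order.
    """
    # read the header line raw: pandas would mangle duplicate column labels
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    col_labels = [c.strip() for c in header.split(",")[1:]]
    if len(set(col_labels)) != len(col_labels):
        dup = next(c for c in col_labels if col_labels.count(c) > 1)
        raise DuplicateLabelError(f"{path}: duplicate node label {dup!r} in header")
    df = pd.read_csv(path, index_col=0)
    row_labels = [str(x) for x in df.index]
    if row_labels != col_labels:
        if len(row_labels) != len(col_labels):
            raise NonSquareError(
                f"{path}: {len(row_labels)} rows but {len(col_labels)} columns"
            )
        raise ValidationError(
            f"{path}: row labels {row_labels} do not match column labels {col_labels}"
        )
    try:
        W = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric matrix body: {exc}") from exc
    return WeightedDigraph(tuple(row_labels), W, profile)


def write_adjacency_csv(G: WeightedDigraph, path: str | Path) -> None:
    """Write the adjacency matrix as labelled CSV (row = sender, column = receiver).

    Weights are serialized with ``%.15g`` so a read/write round trip is exact
    for integer counts and equal to 15 significant digits otherwise.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sender\\receiver," + ",".join(G.labels) + "\n")
        for lab, row in zip(G.labels, G.W):
            fh.write(lab + "," + ",".join(f"{w:.15g}" for w in row) + "\n")


# ---------------------------------------------------------------------------
# Event logs and edge lists
# ---------------------------------------------------------------------------

def read_events_csv(path: str | Path) -> list[PassEvent]:
    """Read a pass-event log with columns ``sender,receiver[,timestamp]``."""
    df = pd.read_csv(path, dtype={"sender": str, "receiver": str})
    if "sender" not in df.columns or "receiver" not in df.columns:
        raise ValidationError(
            f"{path}: event CSV must have 'sender' and 'receiver' columns, "
            f"got {list(df.columns)}"
        )
    has_ts = "timestamp" in df.columns
    events = []
    for rec in df.itertuples(index=False):
        ts = float(rec.timestamp) if has_ts and not pd.isna(rec.timestamp) else None
        events.append(PassEvent(str(rec.sender), str(rec.receiver), ts))
    return events


def write_events_csv(events: Sequence[PassEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sender,receiver,timestamp\n")
        for e in events:
            ts = "" if e.timestamp is None else f"{e.timestamp:.15g}"
            fh.write(f"{e.sender},{e.receiver},{ts}\n")


def read_edgelist_tsv(path: str | Path, profile: Profile = "sports") -> WeightedDigraph:
    """Import a weighted edge list (TSV: source, target, weight) as a digraph.

    Node labels are the sorted distinct identifiers; parallel entries for the
    same arc are summed.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: edge list needs 3 columns (source, target, weight)")
    src = df.iloc[:, 0].astype(str)
    dst = df.iloc[:, 1].astype(str)
    wts = df.iloc[:, 2].astype(float)
    labels = sorted(set(src) | set(dst))
    idx = {lab: k for k, lab in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for s, d, w in zip(src, dst, wts):
        W[idx[s], idx[d]] += w
    return WeightedDigraph(tuple(labels), W, profile)


def aggregate_events(
    events: Iterable[PassEvent],
    labels: Sequence[str] | None = None,
    profile: Profile = "sports",
    label_order: Literal["sorted", "first_appearance"] = "sorted",
) -> WeightedDigraph:
    """Count pass events into a weighted adjacency matrix.

    ``W[i, j]`` becomes the number of events with ``sender == labels[i]`` and
    ``receiver == labels[j]``.  When ``labels`` is omitted they are the
    distinct identifiers seen in the events, sorted by default or in order of
    first appearance when ``label_order="first_appearance"``.
    """
    events = list(events)
    if not events:
        raise EmptyGraphError("cannot aggregate an empty event list")
    if labels is None:
        if label_order == "sorted":
            labels = sorted({e.sender for e in events} | {e.receiver for e in events})
        else:
            seen: dict[str, None] = {}
            for e in events:
                seen.setdefault(e.sender)
                seen.setdefault(e.receiver)
            labels = list(seen)
    idx = {lab: k for k, lab in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for e in events:
        if e.sender not in idx:
            raise ValidationError(f"unknown sender {e.sender!r} not in labels")
        if e.receiver not in idx:
            raise ValidationError(f"unknown receiver {e.receiver!r} not in labels")
        if profile == "sports" and e.sender == e.receiver:
            raise SelfLoopError(
                f"self-pass event {e.sender!r} -> {e.receiver!r} under the sports profile"
            )
        W[idx[e.sender], idx[e.receiver]] += 1
    return WeightedDigraph(tuple(labels), W, profile)


# ---------------------------------------------------------------------------
# Metric report serialization
# ---------------------------------------------------------------------------

_NODE_CSV_HEADER = "node,R_out,R_in,IndR_out,IndR_in"
_NETWORK_FIELDS = (
    "RN_out", "RN_in", "IndRN_out", "IndRN_in",
    "EN_out", "EN_in", "CN_out", "CN_in",
    "IndCN_out", "IndCN_in", "L",
)


def _g15(x: float) -> float:
    """Round-trip a float through 15 significant digits (serialization precision)."""
    return float(f"{x:.15g}")


def report_to_dict(report: MetricReport) -> dict:
    """JSON-stable dict form of a report.

    Schema (stable):
      {"variant": str, "meta": {...},
       "per_node": [{"label","R_out","R_in","IndR_out","IndR_in"}, ...],
       "network": {"RN_out",...,"IndCN_in","L"}}
    """
    return {
        "variant": report.variant,
        "meta": dict(report.meta),
        "per_node": [
            {
                "label": nm.label,
                "R_out": _g15(nm.R_out),
                "R_in": _g15(nm.R_in),
                "IndR_out": _g15(nm.IndR_out),
                "IndR_in": _g15(nm.IndR_in),
            }
            for nm in report.per_node
        ],
        "network": {k: _g15(getattr(report.network, k)) for k in _NETWORK_FIELDS},
    }


def write_report(report: MetricReport, path: str | Path, format: str = "json") -> None:
    """Serialize a :class:`MetricReport` as JSON or CSV at 15 significant digits.

    The CSV form emits the per-node table (header ``node,R_out,R_in,
    IndR_out,IndR_in``) followed by a blank line and a network table
    (``metric,value``).
    """
    path = Path(path)
    if format == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(report_to_dict(report), fh, indent=2)
            fh.write("\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(_NODE_CSV_HEADER + "\n")
            for nm in report.per_node:
                fh.write(
                    f"{nm.label},{nm.R_out:.15g},{nm.R_in:.15g},"
                    f"{nm.IndR_out:.15g},{nm.IndR_in:.15g}\n"
                )
            fh.write("\nmetric,value\n")
            for k in _NETWORK_FIELDS:
                fh.write(f"{k},{getattr(report.network, k):.15g}\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> dict:
    """Load a JSON report back as the dict produced by :func:`report_to_dict`."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return json.load(fh)
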