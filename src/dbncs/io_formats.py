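"""Domain containers and file formats for expression matrices and networks.

The shared in-memory types live here: :class:`ExpressionMatrix` (genes x
ordered time points), :class:`Network` (directed or undirected edge set over a
gene universe) and :class:`TimeDelayedGRN` (a prior directed network paired
with an integer transcription-delay matrix, i.e. the two halves of a dynamic
Bayesian network structure).

Supported on-disk formats
-------------------------
* expression tables: TSV/CSV with one header line; genes in rows (first
  column = gene id) or genes in columns (first column = time label).
* edge lists: whitespace-separated ``regulator target [delay [score]]``.
* DREAM-style gold standards: three columns ``regulator target {0,1}``; only
  label-1 rows are edges, absent pairs count as 0.
* SIF: ``regulator\tregulates_d<delay>\ttarget`` for Cytoscape interop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Network",
    "TimeDelayedGRN",
    "read_expression",
    "read_network",
    "read_grn",
    "write_network",
]


class ParseError(ValueError):
    """A table cell or row could not be interpreted."""


@dataclass
class ExpressionMatrix:
    """Genes x time-points real matrix with ordered, equally spaced time labels.

    ``values[i, t]`` is the expression of gene ``gene_ids[i]`` at the t-th
    sampling time. Columns are assumed chronological and equally spaced, so
    transcriptional delays are integer counts of the sampling interval.
    """

    gene_ids: list[str]
    values: np.ndarray
    time_ordered: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, _ = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} matrix rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def series(self, gene: int | str) -> np.ndarray:
        """Time series of one gene, by index or id."""
        if isinstance(gene, str):
            gene = self.gene_ids.index(gene)
        return self.values[gene]

    def constant_genes(self) -> list[str]:
        """Ids of genes whose series has zero variance."""
        flat = np.ptp(self.values, axis=1) == 0.0
        return [g for g, c in zip(self.gene_ids, flat) if c]


@dataclass
class Network:
    """Edge set over a gene universe, directed or undirected.

    Edges are ordered ``(regulator, target)`` pairs. For an undirected
    network the edge set is kept closed under reversal so membership tests
    work either way round.
    """

    gene_ids: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)
    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    directed: bool = True

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed")
            if u not in universe or v not in universe:
                raise ValueError(f"edge ({u}, {v}) has endpoint outside gene universe")
        if not self.directed:
            self.edges = self.edges | {(v, u) for (u, v) in self.edges}

    @property
    def n_edges(self) -> int:
        if self.directed:
            return len(self.edges)
        return len(self.edges) // 2

    def undirected_pairs(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.edges}


@dataclass
class TimeDelayedGRN:
    """A time-delayed GRN: prior directed network + transition (delay) network.

    The prior network holds the regulator->target edges; the transfer network
    is the integer transcription-delay matrix restricted to those edges
    (delay in sampling-interval units, in ``[1, k_max]``). ``edge_scores``
    carries the comprehensive score of each directed edge.
    """

    prior: Network
    delays: "DelayMatrix"
    edge_scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = {g: i for i, g in enumerate(self.prior.gene_ids)}
        for u, v in self.prior.edges:
            d = int(self.delays.delays[idx[u], idx[v]])
            if not 1 <= d <= self.delays.k_max:
                raise ValueError(
                    f"edge {u}->{v} has delay {d} outside [1, {self.delays.k_max}]"
                )


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path: str | Path, layout: str = "genes_in_rows") -> ExpressionMatrix:
    """Read an expression table into an :class:`ExpressionMatrix`.

    ``layout="genes_in_rows"``: first column gene ids, header = time labels.
    ``layout="genes_in_columns"``: header = gene ids, first column time
    labels (DREAM3-style). Either layout of the same data yields an
    identical matrix. Time order is the column (row) order of the file.
    """
    path = Path(path)
    if layout not in ("genes_in_rows", "genes_in_columns"):
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, header=0)
    if layout == "genes_in_columns":
        df = df.T
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().values)[0]
        raise ParseError(
            f"non-numeric cell at gene {df.index[bad[0]]!r}, "
            f"time column {df.columns[bad[1]]!r} in {path}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index], values=numeric.values
    )


def read_network(
    path: str | Path,
    fmt: str = "edge_list",
    gene_ids: list[str] | None = None,
) -> Network:
    """Read a directed network from an edge list or DREAM gold standard.

    ``edge_list`` rows are ``regulator target [delay [score]]``; a header
    line starting with ``regulator`` or ``#`` is skipped. ``dream_gold``
    rows are ``regulator target {0,1}`` and only label-1 rows become edges.
    Self-loop rows are dropped with a warning. When ``gene_ids`` is given,
    edges mentioning unknown genes are an error; otherwise the universe is
    the genes seen in the file (order of first appearance).
    """
    path = Path(path)
    if fmt not in ("edge_list", "dream_gold"):
        raise ValueError(f"unknown network format {fmt!r}")
    edges: set[tuple[str, str]] = set()
    scores: dict[tuple[str, str], float] = {}
    seen: list[str] = []
    seen_set: set[str] = set()
    n_self = 0

    def note(g: str) -> None:
        if g not in seen_set:
            seen_set.add(g)
            seen.append(g)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0].lower() == "regulator":
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            u, v = parts[0], parts[1]
            if fmt == "dream_gold":
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: dream_gold needs a 0/1 label")
                label = parts[2]
                if label not in ("0", "1"):
                    raise ParseError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
                note(u)
                note(v)
                if label == "0":
                    continue
            else:
                note(u)
                note(v)
            if u == v:
                n_self += 1
                continue
            edges.add((u, v))
            if fmt == "edge_list" and len(parts) >= 4:
                scores[(u, v)] = float(parts[3])
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-loop row(s)")
    if gene_ids is not None:
        unknown = seen_set - set(gene_ids)
        if unknown:
            raise ValueError(f"unknown genes in {path}: {sorted(unknown)}")
        universe = list(gene_ids)
    else:
        universe = seen
    return Network(gene_ids=universe, edges=edges, scores=scores, directed=True)


def write_network(net: TimeDelayedGRN, path: str | Path, fmt: str = "tsv") -> None:
    """Write a time-delayed GRN as a 4-column TSV or a SIF file.

    TSV columns: regulator, target, delay, score. SIF interaction strings
    encode the delay as ``regulates_d<delay>``. Edges are written in sorted
    order so identical networks serialize byte-identically.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {fmt!r}")
    path = Path(path)
    idx = {g: i for i, g in enumerate(net.prior.gene_ids)}
    lines: list[str] = []
    if fmt == "tsv":
        lines.append("regulator\ttarget\tdelay\tscore")
    for u, v in sorted(net.prior.edges):
        d = int(net.delays.delays[idx[u], idx[v]])
        s = net.edge_scores.get((u, v), float("nan"))
        if fmt == "tsv":
            lines.append(f"{u}\t{v}\t{d}\t{s:.6g}")
        else:
            lines.append(f"{u}\tregulates_d{d}\t{v}")
    path.write_text("\n".join(lines) + "\n")


def read_grn(path: str | Path, fmt: str = "tsv") -> TimeDelayedGRN:
    """Read back a TSV or SIF file written by :func:`write_network`."""
    from .temporal import DelayMatrix  # local import to avoid a cycle

    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {fmt!r}")
    path = Path(path)
    rows: list[tuple[str, str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].lower() == "regulator" and parts[1].lower() == "target":
                continue
            if fmt == "tsv":
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
                score = float(parts[3]) if len(parts) >= 4 else float("nan")
                rows.append((parts[0], parts[1], int(parts[2]), score))
            else:
                if len(parts) != 3 or not parts[1].startswith("regulates_d"):
                    raise ParseError(f"{path}:{lineno}: not a delay SIF row")
                rows.append((parts[0], parts[2], int(parts[1][len("regulates_d"):]), float("nan")))
    seen: list[str] = []
    for u, v, _, _ in rows:
        for g in (u, v):
            if g not in seen:
                seen.append(g)
    n = len(seen)
    idx = {g: i for i, g in enumerate(seen)}
    k_max = max((d for _, _, d, _ in rows), default=1)
    delays = np.zeros((n, n), dtype=int)
    edges: set[tuple[str, str]] = set()
    scores: dict[tuple[str, str], float] = {}
    for u, v, d, s in rows:
        edges.add((u, v))
        delays[idx[u], idx[v]] = d
        if np.isfinite(s):
            scores[(u, v)] = s
    prior = Network(gene_ids=seen, edges=edges, directed=True)
    return TimeDelayedGRN(
        prior=prior, delays=DelayMatrix(delays=delays, k_max=k_max), edge_scores=scores
    )
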