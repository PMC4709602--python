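"""Readers and writers for the three input tables and prediction output.

All inputs are plain TSV. Lines starting with ``#`` are comments; a single
header row is permitted. Node orderings are fixed by lexicographic sort at
registry construction so every matrix index is reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "NodeRegistry",
    "InteractionTable",
    "ExpressionMatrix",
    "WeightedPPITable",
    "read_interactions",
    "read_expression",
    "read_ppi",
    "write_interactions",
    "write_expression",
    "write_ppi",
    "write_predictions",
]

INTERACTION_HEADER = ("lncrna_id", "protein_id")
PPI_HEADER = ("protein_a", "protein_b", "score")


class ParseError(ValueError):
    """Malformed input table; message names the offending line."""


@dataclass(frozen=True)
class NodeRegistry:
    """Stable index sets for the m proteins and n lncRNAs of the network.

    Identifiers are sorted lexicographically at construction, so the same
    set of input files always yields identical matrix indices.
    """

    protein_ids: tuple[str, ...]
    lncrna_ids: tuple[str, ...]
    _pidx: dict[str, int] = field(init=False, repr=False, compare=False)
    _lidx: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids in registry")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA ids in registry")
        object.__setattr__(self, "_pidx", {p: i for i, p in enumerate(self.protein_ids)})
        object.__setattr__(self, "_lidx", {l: i for i, l in enumerate(self.lncrna_ids)})

    @classmethod
    def from_tables(
        cls,
        interactions: "InteractionTable | None" = None,
        expression: "ExpressionMatrix | None" = None,
        ppi: "WeightedPPITable | None" = None,
    ) -> "NodeRegistry":
        proteins: set[str] = set()
        lncrnas: set[str] = set()
        if interactions is not None:
            lncrnas.update(l for l, _ in interactions.edges)
            proteins.update(p for _, p in interactions.edges)
        if expression is not None:
            lncrnas.update(expression.lncrna_ids)
        if ppi is not None:
            for a, b, _ in ppi.edges:
                proteins.add(a)
                proteins.add(b)
        return cls(tuple(sorted(proteins)), tuple(sorted(lncrnas)))

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    def protein_index(self, pid: str) -> int:
        try:
            return self._pidx[pid]
        except KeyError:
            raise KeyError(f"protein id not registered: {pid!r}") from None

    def lncrna_index(self, lid: str) -> int:
        try:
            return self._lidx[lid]
        except KeyError:
            raise KeyError(f"lncRNA id not registered: {lid!r}") from None


@dataclass(frozen=True)
class InteractionTable:
    """Known lncRNA-protein interaction pairs, deduplicated."""

    edges: tuple[tuple[str, str], ...]
    n_duplicates_dropped: int = 0

    def partners_of(self, lncrna_id: str) -> tuple[str, ...]:
        return tuple(p for l, p in self.edges if l == lncrna_id)


@dataclass(frozen=True)
class ExpressionMatrix:
    """lncRNA expression profiles over tissues/cell types (rows x conditions)."""

    lncrna_ids: tuple[str, ...]
    condition_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape != (len(self.lncrna_ids), len(self.condition_labels)):
            raise ValueError("expression value shape does not match ids/conditions")
        if np.isnan(v).any():
            raise ValueError("expression matrix contains missing values")


@dataclass(frozen=True)
class WeightedPPITable:
    """Undirected weighted protein-protein interaction edges, scores >= 0."""

    edges: tuple[tuple[str, str, float], ...]


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a two-column lncRNA/protein edge list; duplicate pairs collapse."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dupes = 0
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if first and tuple(f.strip() for f in fields[:2]) == INTERACTION_HEADER:
            first = False
            continue
        first = False
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        pair = (fields[0].strip(), fields[1].strip())
        if pair in seen:
            dupes += 1
            continue
        seen.add(pair)
        edges.append(pair)
    if not edges:
        raise ParseError(f"{path}: no interaction records found")
    return InteractionTable(tuple(edges), n_duplicates_dropped=dupes)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression table: header of condition labels, one row per lncRNA.

    Rows with non-numeric or missing cells are dropped with a warning;
    duplicate lncRNA ids are an error.
    """
    header: tuple[str, ...] | None = None
    ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: header needs >=1 condition label")
            header = tuple(fields[1:])
            continue
        if len(fields) != len(header) + 1:
            raise ParseError(
                f"{path}: line {lineno}: ragged row "
                f"({len(fields)} fields, expected {len(header) + 1})"
            )
        lid = fields[0]
        if lid in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate lncRNA id {lid!r}")
        seen.add(lid)
        try:
            vals = [float(x) for x in fields[1:]]
        except ValueError:
            warnings.warn(f"{path}: line {lineno}: dropped row {lid!r} (non-numeric cell)")
            continue
        if any(np.isnan(vals)):
            warnings.warn(f"{path}: line {lineno}: dropped row {lid!r} (missing value)")
            continue
        ids.append(lid)
        rows.append(vals)
    if header is None:
        raise ParseError(f"{path}: empty expression file")
    if not rows:
        raise ParseError(f"{path}: no usable expression rows")
    return ExpressionMatrix(tuple(ids), header, np.array(rows, dtype=float))


def read_ppi(path: str | Path) -> WeightedPPITable:
    """Read a weighted PPI edge list (protein, protein, score).

    Self-edges are dropped with a warning; duplicate unordered pairs keep
    the maximum score; negative scores are an error.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    first = True
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if first and tuple(fields[:3]) == PPI_HEADER:
            first = False
            continue
        first = False
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 tab-separated fields")
        a, b = fields[0], fields[1]
        try:
            score = float(fields[2])
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: score {fields[2]!r} is not a number")
        if np.isnan(score) or score < 0:
            raise ParseError(f"{path}: line {lineno}: negative or missing score {fields[2]!r}")
        if a == b:
            warnings.warn(f"{path}: line {lineno}: dropped self-edge on {a!r}")
            continue
        key = (a, b) if a <= b else (b, a)
        if key in best:
            best[key] = max(best[key], score)
        else:
            best[key] = score
            order.append(key)
    if not order:
        raise ParseError(f"{path}: no PPI records found")
    return WeightedPPITable(tuple((a, b, best[(a, b)]) for a, b in order))


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(INTERACTION_HEADER) + "\n")
        for l, p in table.edges:
            fh.write(f"{l}\t{p}\n")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncrna_id\t" + "\t".join(expr.condition_labels) + "\n")
        for lid, row in zip(expr.lncrna_ids, expr.values):
            fh.write(lid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def write_ppi(ppi: WeightedPPITable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PPI_HEADER) + "\n")
        for a, b, s in ppi.edges:
            fh.write(f"{a}\t{b}\t{s!r}\n")


def write_predictions(ranked: "RankedPredictions | Sequence[RankedPredictions]", path: str | Path) -> None:
    """Write ranked candidate proteins, one block per query lncRNA.

    Columns: query_lncrna, protein_id, score, rank (1-based, score
    non-increasing within a query).
    """
    from .rwr import RankedPredictions  # local import: avoid cycle

    if isinstance(ranked, RankedPredictions):
        ranked = [ranked]
    if not ranked or any(not r.entries for r in ranked):
        raise ValueError("ranked prediction list is empty")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query_lncrna\tprotein_id\tscore\trank\n")
        for block in ranked:
            for pid, score, rank in block.entries:
                fh.write(f"{block.query}\t{pid}\t{score!r}\t{rank}\n")
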