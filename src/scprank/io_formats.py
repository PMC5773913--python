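"""Readers and writers for the four input kinds and the ranked output.

Formats are deliberately minimal plain-text tables:

* edge list — two whitespace/tab-separated protein IDs per line, ``#`` comments;
* BioGRID-style interaction table — header-bearing TSV with configurable
  interactor-ID columns;
* localization — 2–3 column TSV (protein, compartment[, confidence]);
* expression — TSV/CSV, first column protein ID, remaining columns numeric,
  header optional, possibly several probe rows per gene;
* essential list — one ID per line;
* ranking — TSV with rank, protein, score and an optional essentiality flag.

Protein IDs are matched across files by exact string equality after stripping
surrounding whitespace; no aliasing layer is applied.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (CompartmentAnnotation, EssentialSet, ExpressionMatrix,
                        PPINetwork, ScoreVector)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "load_edgelist",
    "load_biogrid_tab",
    "load_localization",
    "load_expression",
    "load_essential",
    "load_essential_list",
    "write_ranking",
    "read_ranking",
    "write_weighted_edgelist",
]


class ParseError(ValueError):
    """Raised on malformed input; the message names the offending line."""


def _clean_pairs(pairs: Iterable[Tuple[str, str]]) -> PPINetwork:
    """Drop self-loops, collapse duplicate unordered pairs, build the graph."""
    seen = set()
    edges = []
    n_self = n_dup = 0
    for u, v in pairs:
        if u == v:
            n_self += 1
            continue
        key = (u, v) if u < v else (v, u)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(key)
    if n_self:
        logger.info("dropped %d self-loop line(s)", n_self)
    if n_dup:
        logger.info("collapsed %d duplicate pair(s)", n_dup)
    if not edges:
        raise ParseError("no edges remain after cleaning")
    return PPINetwork.from_edges(edges)


def load_edgelist(path, comment_prefix: str = "#") -> PPINetwork:
    """Read a two-column edge list into an undirected simple graph.

    Self-loops are dropped and duplicate pairs (in either order) collapsed,
    with counts reported via logging.  Lines with fewer than two tokens raise
    :class:`ParseError` naming the line number.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}: line {lineno}: expected at least 2 "
                                 f"fields, got {len(tokens)}")
            pairs.append((tokens[0].strip(), tokens[1].strip()))
    if not pairs:
        raise ParseError(f"{path}: no interaction lines found")
    return _clean_pairs(pairs)


def load_biogrid_tab(
    path,
    id_column_pair: Tuple[str, str] = ("Systematic Name Interactor A",
                                       "Systematic Name Interactor B"),
) -> PPINetwork:
    """Read a BioGRID-style tab-delimited interaction table.

    The two configured interactor-ID columns must exist in the header.  Rows
    with a missing ID (``-`` or empty) are skipped with a logged count; the
    cleaning contract (self-loops, duplicates) matches :func:`load_edgelist`.
    """
    col_a, col_b = id_column_pair
    pairs = []
    n_missing = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, no header row")
        missing_cols = [c for c in (col_a, col_b) if c not in reader.fieldnames]
        if missing_cols:
            raise ParseError(f"{path}: header lacks column(s) {missing_cols}")
        for row in reader:
            a = (row[col_a] or "").strip()
            b = (row[col_b] or "").strip()
            if a in ("", "-") or b in ("", "-"):
                n_missing += 1
                continue
            pairs.append((a, b))
    if n_missing:
        logger.info("skipped %d row(s) with missing interactor IDs", n_missing)
    if not pairs:
        raise ParseError(f"{path}: no usable interaction rows")
    return _clean_pairs(pairs)


def load_localization(
    path,
    size_source: str = "from_annotations",
    min_confidence: Optional[float] = None,
    restrict_to: Optional[Iterable[str]] = None,
) -> CompartmentAnnotation:
    """Read protein->compartment annotations from a 2–3 column TSV.

    An optional numeric third column is read as a confidence score and rows
    below ``min_confidence`` are dropped.  Compartment sizes default to the
    count of distinct annotated proteins per compartment
    (``size_source="from_annotations"``); ``"from_column"`` instead takes the
    maximum of the numeric third column per compartment as its size.  With
    ``restrict_to`` the size counts consider only the given proteins (the
    annotation map itself is not filtered).
    """
    if size_source not in ("from_annotations", "from_column"):
        raise ValueError(f"unknown size_source {size_source!r}")
    pairs: List[Tuple[str, str]] = []
    column_sizes = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            n_lines += 1
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}: line {lineno}: expected protein and "
                                 "compartment fields")
            protein, comp = fields[0], fields[1]
            third = None
            if len(fields) >= 3 and fields[2]:
                try:
                    third = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: non-numeric "
                                     f"third column {fields[2]!r}") from exc
            if (min_confidence is not None and third is not None
                    and third < min_confidence):
                continue
            if size_source == "from_column":
                if third is None:
                    raise ParseError(f"{path}: line {lineno}: size_source="
                                     "'from_column' requires a numeric third column")
                column_sizes[comp] = max(column_sizes.get(comp, 0), int(third))
            pairs.append((protein, comp))
    if n_lines == 0:
        raise ParseError(f"{path}: empty localization file")
    if not pairs:
        raise ParseError(f"{path}: no annotation rows pass the filters")
    ann = CompartmentAnnotation.from_pairs(pairs)
    if size_source == "from_column":
        ann = CompartmentAnnotation(ann.scl, column_sizes)
    elif restrict_to is not None:
        keep = frozenset(restrict_to)
        counts = {}
        for p, comps in ann.scl.items():
            if p in keep:
                for c in comps:
                    counts[c] = counts.get(c, 0) + 1
        # every annotated compartment keeps a size >= 1 so ISC stays defined
        sizes = {c: max(1, counts.get(c, 0)) for c in ann.sizes}
        ann = CompartmentAnnotation(ann.scl, sizes)
    if size_source == "from_annotations" and restrict_to is None:
        ann.validate()
    return ann


def _sniff_delimiter(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_expression(path) -> ExpressionMatrix:
    """Read an expression table; one profile per gene is retained.

    First column is the protein/gene ID, the remaining ``m`` columns are
    numeric.  A header row is auto-detected (first row whose value cells do
    not all parse as numbers).  When an ID occurs on several rows (multiple
    probes), the row with the maximum arithmetic mean is kept; ties keep the
    first occurrence in file order.
    """
    delim = _sniff_delimiter(path)
    rows: List[Tuple[str, np.ndarray]] = []
    m = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        for lineno, rec in enumerate(reader, start=1):
            if not rec or not "".join(rec).strip():
                continue
            cells = [c.strip() for c in rec]
            if lineno == 1 and len(cells) >= 2:
                try:
                    [float(c) for c in cells[1:]]
                except ValueError:
                    continue  # header row
            if len(cells) < 3:
                raise ParseError(f"{path}: line {lineno}: expected an ID and "
                                 "at least 2 numeric values")
            values = np.empty(len(cells) - 1)
            for j, c in enumerate(cells[1:], start=2):
                try:
                    values[j - 2] = float(c)
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}, column {j}: "
                                     f"non-numeric cell {c!r}") from exc
            if m is None:
                m = values.size
            elif values.size != m:
                raise ParseError(f"{path}: line {lineno}: row has {values.size} "
                                 f"values, expected {m}")
            rows.append((cells[0], values))
    if not rows:
        raise ParseError(f"{path}: no expression rows found")
    best: dict = {}
    n_multi = 0
    for pid, values in rows:
        mean = float(values.mean())
        if pid not in best:
            best[pid] = (mean, values)
        else:
            n_multi += 1
            if mean > best[pid][0]:  # strict: ties keep the first occurrence
                best[pid] = (mean, values)
    if n_multi:
        logger.info("resolved %d extra probe row(s) by maximum-mean rule", n_multi)
    return ExpressionMatrix.from_dict({p: v for p, (_, v) in best.items()})


def load_essential(path) -> EssentialSet:
    """Read a one-ID-per-line essential-protein list (duplicates collapsed)."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token:
                ids.add(token)
    if not ids:
        raise ParseError(f"{path}: empty essential-protein list")
    return EssentialSet(frozenset(ids))


# alias used by older call sites
load_essential_list = load_essential


def write_ranking(scores: ScoreVector, path,
                  essential: Optional[EssentialSet] = None) -> None:
    """Write a ranking TSV: rank, protein, score[, is_essential].

    Rows are sorted by descending score, ties broken by ascending protein ID.
    Scores are printed with 10 significant digits so a rewrite of a re-read
    file is byte-identical.
    """
    if len(scores) == 0:
        raise ValueError("cannot write an empty ranking")
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    path = Path(path)
    with open(path, "w") as fh:
        header = ["rank", "protein", "score"]
        if essential is not None:
            header.append("is_essential")
        fh.write("\t".join(header) + "\n")
        for rank, (pid, score) in enumerate(order, start=1):
            row = [str(rank), pid, format(score, ".10g")]
            if essential is not None:
                row.append("1" if pid in essential else "0")
            fh.write("\t".join(row) + "\n")


def read_ranking(path) -> List[Tuple[int, str, float]]:
    """Read back a ranking TSV written by :func:`write_ranking`."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("rank\t"):
            raise ParseError(f"{path}: not a ranking file")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            out.append((int(fields[0]), fields[1], float(fields[2])))
    return out


def write_weighted_edgelist(network: PPINetwork, path) -> None:
    """Export the weighted edge list (protein_a, protein_b, weight) as TSV."""
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tweight\n")
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u}\t{v}\t{format(network.weight(u, v), '.10g')}\n")
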