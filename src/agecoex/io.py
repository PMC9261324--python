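"""Readers and writers for the delimited-text formats the pipeline touches.

TSV is the default dialect; a comma-separated file is auto-detected by
sniffing the header line.  Gene and sample IDs are matched case-sensitively
and never aliased.  Writers emit >= 12 significant digits so every
read/write pair is a lossless round trip on valid inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TraitTable

log = logging.getLogger("agecoex")

#: Float format giving value-exact text round trips.
FLOAT_FMT = "%.12g"


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty file: {path}")
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    scale_tag: str = "normalized_intensity",
) -> ExpressionMatrix:
    """Read a delimited expression table into a genes x samples matrix.

    Parameters
    ----------
    orientation : {"genes_in_rows", "samples_in_rows"}
        Layout of the file; the result is always genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"no data rows/columns in {path}")
    if orientation == "samples_in_rows":
        df = df.T
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene IDs in {path}: {dup}")
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate sample IDs in {path}: {dup}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError):
        for j, col in enumerate(df.columns):
            conv = pd.to_numeric(df[col], errors="coerce")
            if conv.isna().any() and not df[col].isna().any():
                i = int(np.argmax(conv.isna().to_numpy()))
                raise ValueError(
                    f"non-numeric cell at gene {df.index[i]!r}, sample {col!r} in {path}"
                ) from None
        raise
    m = ExpressionMatrix(df, scale_tag=scale_tag)
    log.info("read_expression: %d genes x %d samples from %s", m.n_genes, m.n_samples, path)
    return m


def write_expression(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    m.data.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="gene_id")


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def read_traits(path: str | Path) -> TraitTable:
    """Read a sample trait table (sample_id, age, sex, ethnicity, group...)."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return TraitTable(df)


def write_traits(t: TraitTable, path: str | Path, sep: str = "\t") -> None:
    t.data.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into a mapping set-name -> member set.

    Duplicate members within a line are deduplicated; empty sets are dropped
    with a logged warning.  A line with fewer than 3 fields is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields, got {len(fields)}")
            name = fields[0]
            members = {g for g in fields[2:] if g}
            if not members:
                log.warning("read_gmt: dropping empty set %r (%s:%d)", name, path, ln)
                continue
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    score_column: str | None = None,
    min_score: float | None = None,
) -> nx.Graph:
    """Read a STRING-style edge list into an undirected simple graph.

    The first two columns name the interacting genes.  If `min_score` is
    given, `score_column` must name a numeric column on the file's own scale
    (STRING combined_score convention: 0-1000); edges below the cut are
    excluded.  Self-loops are removed and duplicate/reciprocal rows collapse
    to one undirected edge (the maximum score is kept).
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"edge list {path} needs at least two node columns")
    if min_score is not None:
        if score_column is None or score_column not in df.columns:
            raise ValueError(
                f"score filtering requested but column {score_column!r} absent from {path}"
            )
        n0 = len(df)
        df = df[pd.to_numeric(df[score_column]) >= min_score]
        log.info("read_edge_list: %d/%d edges pass score >= %s", len(df), n0, min_score)
    g = nx.Graph()
    u_col, v_col = df.columns[:2]
    if score_column is not None and score_column in df.columns:
        for u, v, s in zip(df[u_col], df[v_col], df[score_column]):
            u, v = str(u), str(v)
            if u == v:
                continue
            if g.has_edge(u, v):
                g[u][v]["score"] = max(g[u][v].get("score", -np.inf), float(s))
            else:
                g.add_edge(u, v, score=float(s))
    else:
        for u, v in zip(df[u_col], df[v_col]):
            u, v = str(u), str(v)
            if u != v:
                g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        has_score = any("score" in d for _, _, d in g.edges(data=True))
        fh.write("protein1\tprotein2" + ("\tcombined_score\n" if has_score else "\n"))
        for u, v, d in sorted(g.edges(data=True)):
            if has_score:
                fh.write(f"{u}\t{v}\t{FLOAT_FMT % d.get('score', 0.0)}\n")
            else:
                fh.write(f"{u}\t{v}\n")
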