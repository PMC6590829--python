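"""Metadata-attributed dataset containers and lossless ASCII I/O.

The central objects are :class:`DataSet` — a rectangular block of numeric
columns plus named metadata attributes, free-text comments and a column-role
map (``X``/``Y``/``eY``) — and :class:`DataCollection`, an ordered list of
(possibly differently shaped) DataSets with attribute-based filtering.

The ASCII dialect is line-oriented and decided by the first words of a line:

* two leading numbers            -> a data row of the current block
* identifier followed by a float -> an attribute line (``name value(s)``)
* anything else                  -> a comment, kept verbatim

A new block starts when attributes, comments or blank lines follow numeric
rows (or when a user-chosen separator keyword appears).  Reserved
``#@roles``/``#@s`` comment lines carry the role map and string-valued
attributes so that a write -> parse round trip is the identity.
"""

from __future__ import annotations

import io
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.interpolate import splev, splrep

__all__ = [
    "DataSet",
    "DataCollection",
    "MISSING",
    "parse_ascii",
    "write_ascii",
    "filter_collection",
    "prune",
    "interpolate",
]

logger = logging.getLogger(__name__)

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_ROLE_NAMES = ("X", "Y", "eY")

# number of significant digits used by the writer; repr-roundtrip exact
_FMT = "%.17g"


class _Missing:
    """Explicit marker for an absent attribute in a collection query."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


MISSING = _Missing()


def _is_float(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return not math.isnan(float(tok)) if tok.lower() in ("nan",) else True


def _parse_value(tokens: Sequence[str]) -> float | np.ndarray | str:
    """All-float token list -> scalar or vector; otherwise the raw string."""
    vals = []
    for t in tokens:
        try:
            vals.append(float(t))
        except ValueError:
            return " ".join(tokens)
    if len(vals) == 1:
        return vals[0]
    return np.asarray(vals, dtype=float)


@dataclass
class DataSet:
    """Numeric column matrix with named metadata and column roles.

    Parameters
    ----------
    data : (nrows, ncols) array_like
        The numeric block; all columns share the same length.
    attributes : mapping
        name -> scalar, 1-d float vector or string.
    comments : list of str
        Free-text lines kept verbatim.
    roles : mapping
        ``{"X": ix, "Y": iy}`` and optionally ``"eY"``.  Defaults to
        X=0, Y=1 and eY=2 when at least three columns exist.
    """

    data: np.ndarray
    attributes: dict = field(default_factory=dict)
    comments: list = field(default_factory=list)
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.size == 0:
            raise ValueError("DataSet requires at least one data row")
        if not self.roles:
            self.roles = {"X": 0, "Y": min(1, self.ncols - 1)}
            if self.ncols >= 3:
                self.roles["eY"] = 2
        self._validate()

    def _validate(self) -> None:
        idx = list(self.roles.values())
        if len(set(idx)) != len(idx) and self.ncols > 1:
            raise ValueError(f"role indices must be distinct, got {self.roles}")
        for name, i in self.roles.items():
            if name not in _ROLE_NAMES:
                raise ValueError(f"unknown role {name!r}")
            if not 0 <= i < self.ncols:
                raise ValueError(f"role {name}={i} outside {self.ncols} columns")
        for name in self.attributes:
            if not _IDENT.match(name) or name in _ROLE_NAMES:
                raise ValueError(f"invalid attribute name {name!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.data[:, self.roles["X"]]

    @property
    def Y(self) -> np.ndarray:
        return self.data[:, self.roles["Y"]]

    @property
    def eY(self) -> np.ndarray | None:
        i = self.roles.get("eY")
        return None if i is None else self.data[:, i]

    def __getattr__(self, name: str):
        # dataclass machinery guarantees __dict__ entries exist before use
        attrs = self.__dict__.get("attributes")
        if attrs is not None and name in attrs:
            return attrs[name]
        raise AttributeError(name)

    def copy(self) -> "DataSet":
        return DataSet(
            self.data.copy(),
            {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in self.attributes.items()},
            list(self.comments),
            dict(self.roles),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataSet):
            return NotImplemented
        if self.data.shape != other.data.shape or not np.array_equal(self.data, other.data):
            return False
        if self.roles != other.roles or self.comments != other.comments:
            return False
        if set(self.attributes) != set(other.attributes):
            return False
        for k, v in self.attributes.items():
            w = other.attributes[k]
            if isinstance(v, np.ndarray) or isinstance(w, np.ndarray):
                if not (np.ndim(v) == np.ndim(w) and np.array_equal(v, w)):
                    return False
            elif v != w:
                return False
        return True


class DataCollection(list):
    """Ordered list of :class:`DataSet` with attribute queries and filtering."""

    def __init__(self, items: Iterable[DataSet] = ()) -> None:
        super().__init__(items)

    def attr(self, name: str) -> list:
        """One value per item; :data:`MISSING` where the attribute is absent."""
        return [ds.attributes.get(name, MISSING) for ds in self]

    def filter(self, predicate: Callable[[DataSet], bool]) -> "DataCollection":
        return filter_collection(self, predicate)

    def copy(self) -> "DataCollection":
        return DataCollection(ds.copy() for ds in self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, (DataCollection, list)):
            return NotImplemented
        return len(self) == len(other) and all(a == b for a, b in zip(self, other))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _apply_replacements(line: str, replace: Mapping[str, str] | None) -> str:
    if not replace:
        return line
    for old, new in replace.items():
        line = line.replace(old, new)
    return line


def parse_ascii(
    source,
    *,
    replace: Mapping[str, str] | None = None,
    usecols: Sequence[int] | None = None,
    separator_keyword: str | None = None,
    roles: Mapping[str, int] | None = None,
) -> DataCollection:
    """Parse the ASCII dialect into a :class:`DataCollection`.

    Parameters
    ----------
    source : str, path or file-like
        Text, a path to a text file, or an open file object.
    replace : mapping, optional
        Literal character/word replacements applied to every line before
        interpretation (e.g. ``{",": "."}`` for decimal-comma files).
    usecols : sequence of int, optional
        Column selection applied to each numeric block.
    separator_keyword : str, optional
        A line starting with this word always begins a new block.
    roles : mapping, optional
        Role indices forced onto every parsed DataSet (overrides both the
        defaults and any ``#@roles`` line).
    """
    text = _read_text(source)
    collection = DataCollection()

    rows: list[list[float]] = []
    attrs: dict = {}
    comments: list[str] = []
    file_roles: dict | None = None
    seen_data = False
    pending_new_block = False

    def flush(lineno: int) -> None:
        nonlocal rows, attrs, comments, file_roles, seen_data, pending_new_block
        if rows:
            ncols = {len(r) for r in rows}
            if len(ncols) != 1:
                raise ValueError(
                    f"ragged numeric rows before line {lineno}: column counts {sorted(ncols)}"
                )
            data = np.asarray(rows, dtype=float)
            if usecols is not None:
                data = data[:, list(usecols)]
            use_roles = dict(roles) if roles else (dict(file_roles) if file_roles else {})
            collection.append(DataSet(data, attrs, comments, use_roles))
        rows, attrs, comments = [], {}, []
        file_roles = None
        seen_data = False
        pending_new_block = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _apply_replacements(raw, replace).strip()
        if not line:
            if seen_data:
                pending_new_block = True
            continue
        toks = line.split()
        if separator_keyword and toks[0] == separator_keyword:
            flush(lineno)
            continue
        # reserved writer lines
        if toks[0] == "#@roles":
            if pending_new_block:
                flush(lineno)
            file_roles = {}
            for rname, ridx in zip(toks[1::2], toks[2::2]):
                file_roles[rname] = int(ridx)
            continue
        if toks[0] == "#@s" and len(toks) >= 3:
            if pending_new_block:
                flush(lineno)
            attrs[toks[1]] = " ".join(toks[2:])
            continue
        numeric_row = len(toks) >= 2 and _is_float(toks[0]) and _is_float(toks[1])
        if numeric_row:
            if pending_new_block:
                flush(lineno)
            rows.append([float(t) for t in toks])
            seen_data = True
            continue
        # attribute or comment: either way, after data it opens a new block
        if seen_data:
            flush(lineno)
        if (
            len(toks) >= 2
            and _IDENT.match(toks[0])
            and toks[0] not in _ROLE_NAMES
            and _is_float(toks[1])
        ):
            attrs[toks[0]] = _parse_value(toks[1:])
        else:
            comment = raw.strip()
            if comment.startswith("# "):
                comment = comment[2:]
            elif comment == "#":
                comment = ""
            comments.append(comment)
    flush(-1)
    return collection


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        # heuristics: treat as path when it exists or has no newline and endswith-like path
        if source and "\n" not in source and Path(source).is_file():
            return Path(source).read_text()
        return source
    raise TypeError(f"cannot read from {type(source)!r}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_value(value) -> str:
    if isinstance(value, np.ndarray):
        return " ".join(_FMT % v for v in value)
    return _FMT % value


def write_ascii(collection, sink=None) -> str:
    """Serialize a DataCollection (or single DataSet) to the ASCII dialect.

    Returns the text; when *sink* is given the text is also written there.
    ``parse_ascii(write_ascii(c)) == c`` holds exactly.
    """
    if isinstance(collection, DataSet):
        collection = DataCollection([collection])
    blocks = []
    for ds in collection:
        lines = []
        for c in ds.comments:
            lines.append(f"# {c}" if c else "#")
        for name, value in ds.attributes.items():
            if isinstance(value, str) or (
                isinstance(value, np.ndarray) and value.size == 0
            ):
                lines.append(f"#@s {name} {value}")
            else:
                lines.append(f"{name} {_format_value(value)}")
        lines.append("#@roles " + " ".join(f"{k} {v}" for k, v in ds.roles.items()))
        for row in ds.data:
            lines.append(" ".join(_FMT % v for v in row))
        blocks.append("\n".join(lines))
    text = ("\n\n".join(blocks) + "\n") if blocks else ""
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)
    return text


# ---------------------------------------------------------------------------
# filtering / binning / interpolation
# ---------------------------------------------------------------------------

def filter_collection(
    collection: DataCollection, predicate: Callable[[DataSet], bool]
) -> DataCollection:
    """Sub-collection of items where *predicate(ds)* is true, order kept.

    A predicate that raises (e.g. on a missing attribute) excludes the item
    with a logged warning instead of aborting the query.
    """
    out = DataCollection()
    for i, ds in enumerate(collection):
        try:
            keep = bool(predicate(ds))
        except Exception as exc:  # noqa: BLE001 - per-item isolation is the contract
            logger.warning("filter predicate failed on item %d (%s); excluded", i, exc)
            continue
        if keep:
            out.append(ds)
    return out


def prune(
    ds: DataSet,
    n_bins: int,
    scale: str = "linear",
    range: Sequence[float] | None = None,
) -> DataSet:
    """Average rows into *n_bins* intervals on a linear or log X grid.

    Within each bin the output X and Y are plain means of the members.  The
    error column becomes the standard error of the mean when the input has
    no eY column and the bin holds at least two points, otherwise the
    propagated ``sqrt(sum eY^2)/n``.  Empty bins are dropped; attributes,
    comments and roles are preserved.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = ds.X
    lo, hi = (float(np.min(x)), float(np.max(x))) if range is None else map(float, range)
    if scale == "log":
        if lo <= 0:
            raise ValueError("log scale requires positive X in range")
        edges = np.geomspace(lo, hi, n_bins + 1)
    elif scale == "linear":
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if n_bins > ds.nrows:
        warnings.warn("more bins than rows; empty bins are dropped", stacklevel=2)

    sel = (x >= lo) & (x <= hi)
    idx = np.clip(np.searchsorted(edges, x[sel], side="right") - 1, 0, n_bins - 1)
    data = ds.data[sel]
    iey = ds.roles.get("eY")
    iy = ds.roles["Y"]

    out_rows = []
    for b in np.unique(idx):
        members = data[idx == b]
        n = len(members)
        row = members.mean(axis=0)
        if iey is not None:
            row[iey] = np.sqrt(np.sum(members[:, iey] ** 2)) / n
        out_rows.append((row, members[:, iy], n))

    ncols = ds.ncols
    add_err = iey is None and ncols >= 2
    new = []
    for row, yvals, n in out_rows:
        if add_err:
            sem = yvals.std(ddof=1) / math.sqrt(n) if n >= 2 else 0.0
            row = np.append(row, sem)
        new.append(row)
    roles = dict(ds.roles)
    if add_err:
        roles["eY"] = ncols
    return DataSet(np.asarray(new), dict(ds.attributes), list(ds.comments), roles)


def interpolate(
    ds: DataSet,
    new_x: Sequence[float],
    method: str = "linear",
    degree: int = 3,
    extrapolate: bool = False,
) -> DataSet:
    """Interpolate Y onto *new_x*; linear, global polynomial or B-spline."""
    if ds.nrows < 2:
        raise ValueError("interpolation requires at least 2 rows")
    new_x = np.asarray(new_x, dtype=float)
    order = np.argsort(ds.X)
    x, y = ds.X[order], ds.Y[order]
    if not extrapolate and (new_x.min() < x.min() or new_x.max() > x.max()):
        raise ValueError("new_x outside data range; pass extrapolate=True to allow")
    if method == "linear":
        new_y = np.interp(new_x, x, y)
    elif method == "polynomial":
        coeff = np.polynomial.Polynomial.fit(x, y, deg=degree)
        new_y = coeff(new_x)
    elif method == "bspline":
        k = min(degree, ds.nrows - 1)
        tck = splrep(x, y, k=k, s=0)
        new_y = splev(new_x, tck)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DataSet(
        np.column_stack([new_x, new_y]),
        dict(ds.attributes),
        list(ds.comments),
        {"X": 0, "Y": 1},
    )
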