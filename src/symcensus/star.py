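"""Particle-metadata I/O in the STAR dialect used by single-particle processing.

Supports the two layouts found in deposited particle metadata: a single
``data_`` block holding one ``loop_`` of tagged columns (legacy layout), and
the two-block layout in which a ``data_optics`` block precedes the
``data_particles`` block.  The particles block is always the processing
target; the optics block, when present, is carried through unmodified.

Only whitespace-delimited tokens are supported (the dialect emitted by
particle-processing suites); quoted CIF strings and multi-loop blocks are out
of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParticleTable",
    "StarError",
    "StarParseError",
    "MissingColumnsError",
    "read_star",
    "write_star",
    "require_columns",
]


class StarError(Exception):
    """Base class for STAR-handling errors."""


class StarParseError(StarError):
    """Raised for malformed STAR input; the message names the offending line."""


class MissingColumnsError(StarError):
    """Raised when required column tags are absent from a table."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__("missing required column(s): " + ", ".join(self.missing))


@dataclass
class ParticleTable:
    """Ordered per-particle metadata records (one STAR loop).

    Parameters
    ----------
    df : pandas.DataFrame
        One row per particle record, one column per STAR tag, in file order.
        Numeric-looking columns are numeric dtypes; everything else is text.
    block_name : str
        Name of the data block (without the ``data_`` prefix).
    optics : pandas.DataFrame, optional
        Optics-group rows from a ``data_optics`` block, carried unmodified.
    optics_first : bool
        Whether the optics block preceded the particles block in the source
        file (preserved on write).
    """

    df: pd.DataFrame
    block_name: str = "particles"
    optics: pd.DataFrame | None = None
    optics_first: bool = True
    optics_block_name: str = "optics"

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ParticleTable":
        return ParticleTable(
            df=self.df.copy(),
            block_name=self.block_name,
            optics=None if self.optics is None else self.optics.copy(),
            optics_first=self.optics_first,
            optics_block_name=self.optics_block_name,
        )


@dataclass
class _RawBlock:
    name: str
    tags: list[str] = field(default_factory=list)
    rows: list[list[str]] = field(default_factory=list)


def _parse_blocks(path: Path) -> list[_RawBlock]:
    blocks: list[_RawBlock] = []
    state = "idle"  # idle -> in_block -> in_loop_tags -> in_loop_rows
    block: _RawBlock | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                block = _RawBlock(name=line[len("data_"):])
                blocks.append(block)
                state = "in_block"
                continue
            if block is None:
                raise StarParseError(
                    f"line {lineno}: content before any data_ block: {line!r}"
                )
            if line == "loop_":
                if block.tags:
                    raise StarParseError(
                        f"line {lineno}: multiple loops in block data_{block.name} "
                        "are not supported"
                    )
                state = "in_loop_tags"
                continue
            if line.startswith("_"):
                tag = line.split()[0]  # drop any trailing "#N" column comment
                if state == "in_loop_tags":
                    if tag in block.tags:
                        raise StarParseError(
                            f"line {lineno}: duplicate column tag {tag}"
                        )
                    block.tags.append(tag)
                else:
                    # key-value pair outside a loop (e.g. single-row metadata):
                    # not part of the supported dialect for particle tables.
                    raise StarParseError(
                        f"line {lineno}: key-value item {tag} outside loop_ is "
                        "not supported"
                    )
                continue
            # data row
            if not block.tags:
                raise StarParseError(
                    f"line {lineno}: data row before loop_ header: {line!r}"
                )
            state = "in_loop_rows"
            tokens = line.split()
            if len(tokens) != len(block.tags):
                raise StarParseError(
                    f"line {lineno}: row has {len(tokens)} values but "
                    f"{len(block.tags)} column tags are declared"
                )
            block.rows.append(tokens)

    if not blocks:
        raise StarParseError(f"{path}: no data_ block found (empty file?)")
    return blocks


def _coerce_numeric(values: list[str]) -> np.ndarray | list[str]:
    """Parse a column to int64/float64 if every token is numeric, else text."""
    try:
        ints = [int(v) for v in values]
    except ValueError:
        pass
    else:
        return np.asarray(ints, dtype=np.int64)
    try:
        floats = [float(v) for v in values]
    except ValueError:
        return values
    if not all(math.isfinite(v) for v in floats):
        return values
    return np.asarray(floats, dtype=np.float64)


def _block_to_df(block: _RawBlock) -> pd.DataFrame:
    data = {}
    for j, tag in enumerate(block.tags):
        col = [row[j] for row in block.rows]
        data[tag] = _coerce_numeric(col)
    return pd.DataFrame(data, columns=block.tags)


def read_star(path) -> ParticleTable:
    """Read a STAR particle file.

    The particles block (``data_particles``, or the sole block in legacy
    files) becomes the main table; a ``data_optics`` block, if present, is
    retained on the returned table.
    """
    path = Path(path)
    blocks = _parse_blocks(path)

    optics_block = None
    main_block = None
    for b in blocks:
        if b.name == "optics" and optics_block is None:
            optics_block = b
        elif main_block is None:
            main_block = b
    if main_block is None:
        raise StarParseError(f"{path}: only an optics block found, no particle block")

    optics_first = optics_block is not None and blocks.index(optics_block) < blocks.index(
        main_block
    )
    return ParticleTable(
        df=_block_to_df(main_block),
        block_name=main_block.name,
        optics=None if optics_block is None else _block_to_df(optics_block),
        optics_first=optics_first,
        optics_block_name="optics" if optics_block is None else optics_block.name,
    )


def _format_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        # repr round-trips exactly; the contract only demands 6 significant digits
        return repr(float(v))
    return str(v)


def _write_block(fh, name: str, df: pd.DataFrame) -> None:
    fh.write(f"data_{name}\n\nloop_\n")
    for i, tag in enumerate(df.columns, start=1):
        fh.write(f"{tag} #{i}\n")
    cols = [df[c].to_numpy() for c in df.columns]
    for i in range(len(df)):
        fh.write(" ".join(_format_value(col[i]) for col in cols) + "\n")
    fh.write("\n")


def write_star(table: ParticleTable, path) -> None:
    """Write a ParticleTable so that :func:`read_star` round-trips it.

    Token sequence (not exact spacing) is the contract; values are written so
    numeric fields round-trip to full precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# written by symcensus\n\n")
        blocks: list[tuple[str, pd.DataFrame]] = []
        if table.optics is not None and table.optics_first:
            blocks.append((table.optics_block_name, table.optics))
        blocks.append((table.block_name, table.df))
        if table.optics is not None and not table.optics_first:
            blocks.append((table.optics_block_name, table.optics))
        for name, df in blocks:
            _write_block(fh, name, df)


def require_columns(table: ParticleTable, tags: Iterable[str]) -> None:
    """Validate that every tag in ``tags`` is a column of ``table``.

    Raises :class:`MissingColumnsError` listing *all* missing tags at once.
    """
    present = set(table.columns)
    missing = [t for t in tags if t not in present]
    if missing:
        raise MissingColumnsError(missing)
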