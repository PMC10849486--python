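"""Minimal STAR-dialect parser/writer: one data block, one loop, named columns.

Covers the subset of STAR used for particle metadata interchange (a single
``data_`` block whose columns are declared with ``_tag #n`` lines under a
``loop_``). Multi-block files, mid-loop comments and quoted multi-word fields
are out of scope.
"""

from __future__ import annotations

import pandas as pd


class StarFormatError(ValueError):
    """Raised when a file does not conform to the supported STAR subset."""


def read_star(path) -> pd.DataFrame:
    """Parse the first loop of the first data block into a DataFrame of strings.

    Column names are the STAR tags without the leading underscore.
    """
    tags: list[str] = []
    rows: list[list[str]] = []
    state = "preamble"  # -> in_block -> in_loop -> in_header -> in_data
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if state == "preamble":
                if line.startswith("data_"):
                    state = "in_block"
                continue
            if state == "in_block":
                if line == "loop_":
                    state = "in_header"
                continue
            if state == "in_header":
                if line.startswith("_"):
                    tags.append(line.split()[0].lstrip("_"))
                    continue
                state = "in_data"
            if state == "in_data":
                if line.startswith("data_"):
                    break  # only the first block is read
                fields = line.split()
                if len(fields) != len(tags):
                    raise StarFormatError(
                        f"{path}: line {lineno}: expected {len(tags)} fields, got {len(fields)}"
                    )
                rows.append(fields)
    if not tags:
        raise StarFormatError(f"{path}: no loop_ column declarations found")
    return pd.DataFrame(rows, columns=tags, dtype=str)


def write_star(df: pd.DataFrame, path, block_name: str = "particles") -> None:
    """Write a DataFrame as a single-block STAR loop, columns in df order."""
    with open(path, "w") as fh:
        fh.write(f"data_{block_name}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for row in df.itertuples(index=False):
            fh.write(" ".join(_format(v) for v in row) + "\n")


def _format(value) -> str:
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)
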