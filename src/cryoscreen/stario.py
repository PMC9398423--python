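"""Minimal STAR (Self-defining Text Archive and Retrieval) table I/O.

Covers the subset used for cryo-EM metadata interchange: named data
blocks each holding one ``loop_`` table.  Tables round-trip losslessly
through :class:`pandas.DataFrame` objects — floats are written in
shortest-round-trip form, so ``write(parse(text)) == text`` for files
this module produced.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd


def _format_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "nan"
        return repr(float(v))
    s = str(v)
    return s if s and " " not in s else f'"{s}"'


def write_star(blocks: dict[str, pd.DataFrame]) -> str:
    """Serialize named DataFrames as STAR data blocks with loop_ tables."""
    out = StringIO()
    for name, df in blocks.items():
        out.write(f"data_{name}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            out.write(f"_{col} #{i}\n")
        for _, row in df.iterrows():
            out.write(" ".join(_format_value(v) for v in row) + "\n")
        out.write("\n")
    return out.getvalue()


def _coerce(values: list[str]) -> list:
    def one(s: str):
        if s.startswith('"') and s.endswith('"'):
            return s[1:-1]
        try:
            return int(s)
        except ValueError:
            pass
        try:
            return float(s)
        except ValueError:
            return s

    return [one(v) for v in values]


def parse_star(text: str) -> dict[str, pd.DataFrame]:
    """Parse STAR text produced by :func:`write_star` (loop tables only)."""
    blocks: dict[str, pd.DataFrame] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("data_"):
            name = line[len("data_") :]
            i += 1
            cols: list[str] = []
            rows: list[list] = []
            in_loop = False
            while i < len(lines):
                ln = lines[i].strip()
                if ln.startswith("data_"):
                    break
                if ln == "loop_":
                    in_loop = True
                    cols, rows = [], []
                elif in_loop and ln.startswith("_"):
                    cols.append(ln.split()[0][1:])
                elif in_loop and ln:
                    rows.append(_coerce(_split_row(ln)))
                i += 1
            df = pd.DataFrame(rows, columns=cols)
            blocks[name] = df
        else:
            i += 1
    return blocks


def _split_row(line: str) -> list[str]:
    out: list[str] = []
    cur = ""
    quoted = False
    for ch in line:
        if ch == '"':
            quoted = not quoted
            cur += ch
        elif ch == " " and not quoted:
            if cur:
                out.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        out.append(cur)
    return out
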