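"""Relion-dialect STAR metadata I/O.

Ground-truth metadata is written with the Relion column names
(`_rlnImageName`, `_rlnAngleRot`, `_rlnAngleTilt`, `_rlnAnglePsi`) so the
files can feed real external heterogeneity tools, plus namespaced custom
columns (`_elbCc1`, `_elbCc2`, `_elbWellLabel`) carrying the benchmark's
ground truth.  A plain-CSV mirror is provided for consumers outside the
cryo-EM ecosystem.  Writers use fixed float formatting so identical inputs
give byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_star", "read_star", "metadata_to_dataframe", "StarFormatError"]

REQUIRED_COLUMNS = (
    "_rlnImageName",
    "_rlnAngleRot",
    "_rlnAngleTilt",
    "_rlnAnglePsi",
    "_elbCc1",
    "_elbCc2",
    "_elbWellLabel",
)

_FLOAT_COLUMNS = {
    "_rlnAngleRot": "{:.6f}",
    "_rlnAngleTilt": "{:.6f}",
    "_rlnAnglePsi": "{:.6f}",
    "_elbCc1": "{:.8f}",
    "_elbCc2": "{:.8f}",
    "_elbNoiseSigma": "{:.8f}",
    "_elbDefocus": "{:.3f}",
}


class StarFormatError(ValueError):
    pass


def metadata_to_dataframe(metadata, image_file: str = "stack.mrcs") -> pd.DataFrame:
    """Relion-style metadata table for a list of particle metadata records."""
    rows = []
    for m in metadata:
        rows.append(
            {
                "_rlnImageName": f"{m.index + 1:06d}@{image_file}",
                "_rlnAngleRot": m.euler[0],
                "_rlnAngleTilt": m.euler[1],
                "_rlnAnglePsi": m.euler[2],
                "_elbCc1": m.cc[0],
                "_elbCc2": m.cc[1],
                "_elbWellLabel": m.well_label,
                "_elbNoiseSigma": m.noise_sigma,
            }
        )
    return pd.DataFrame(rows)


def write_star(df: pd.DataFrame, path, block_name: str = "particles") -> None:
    """Write a metadata table as a Relion-dialect STAR loop block."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StarFormatError(f"missing required column(s): {', '.join(missing)}")
    cols = list(df.columns)
    lines = [f"data_{block_name}", "", "loop_"]
    lines += [f"{c} #{i + 1}" for i, c in enumerate(cols)]
    for _, row in df.iterrows():
        fields = []
        for c in cols:
            v = row[c]
            if c in _FLOAT_COLUMNS:
                fields.append(_FLOAT_COLUMNS[c].format(float(v)))
            elif isinstance(v, (int, np.integer)):
                fields.append(str(int(v)))
            elif isinstance(v, (float, np.floating)):
                fields.append(f"{float(v):.8f}")
            else:
                fields.append(str(v))
        lines.append(" ".join(fields))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_star(path) -> pd.DataFrame:
    """Read the first loop block of a STAR file into a typed DataFrame.

    Raises :class:`StarFormatError` naming the column if a required ground
    truth column is absent.
    """
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    header_done = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("data_"):
                continue
            if s == "loop_":
                in_loop = True
                continue
            if in_loop and s.startswith("_"):
                if header_done:
                    break  # a second loop block begins
                cols.append(s.split()[0])
                continue
            if in_loop and cols:
                header_done = True
                parts = s.split()
                if len(parts) != len(cols):
                    raise StarFormatError(
                        f"row has {len(parts)} fields, expected {len(cols)}: {s[:60]!r}"
                    )
                rows.append(parts)
    if not cols:
        raise StarFormatError("no loop block found")
    df = pd.DataFrame(rows, columns=cols)
    for c in REQUIRED_COLUMNS:
        if c not in df.columns:
            raise StarFormatError(f"missing required column: {c}")
    for c in df.columns:
        if c == "_rlnImageName":
            continue
        if c == "_elbWellLabel":
            df[c] = df[c].astype(int)
        else:
            df[c] = df[c].astype(float)
    return df


def star_to_csv(df: pd.DataFrame, path) -> None:
    """CSV mirror of the STAR table with plain column names."""
    renames = {
        "_rlnImageName": "image_name",
        "_rlnAngleRot": "rot",
        "_rlnAngleTilt": "tilt",
        "_rlnAnglePsi": "psi",
        "_elbCc1": "cc1",
        "_elbCc2": "cc2",
        "_elbWellLabel": "well_label",
        "_elbNoiseSigma": "noise_sigma",
        "_elbDefocus": "defocus",
    }
    df.rename(columns=renames).to_csv(path, index=False, float_format="%.8f")
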