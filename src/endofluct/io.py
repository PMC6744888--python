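"""Delimited-text readers and writers for the package's tabular formats.

All artifacts are plain TSV (or JSON) so that runs are diffable and
reproducible bit for bit.  The BOLD format is two columns
(``volume_index``, ``value``) preceded by a comment header carrying the
repetition time, e.g. ``# tr_seconds=1.75``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .timeseries import BoldTimeSeries

_FLOAT_FMT = "%.6f"


def write_bold(path, bold: BoldTimeSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tr_seconds={bold.tr_seconds}\n")
        fh.write(f"# origin_time_s={bold.origin_time_s}\n")
        fh.write("volume_index\tvalue\n")
        for i, v in enumerate(bold.values):
            fh.write(f"{i}\t{_FLOAT_FMT % v}\n")


def read_bold(path) -> BoldTimeSeries:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
            body_start += 1
        else:
            break
    if "tr_seconds" not in meta:
        raise InputError(f"{path}: missing '# tr_seconds=' header")
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    return BoldTimeSeries(
        values=df["value"].to_numpy(float),
        tr_seconds=meta["tr_seconds"],
        origin_time_s=meta.get("origin_time_s", 0.0),
    )


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_events(path, events) -> None:
    df = pd.DataFrame(
        [
            {
                "volume_index": e.volume_index,
                "time_s": e.time_s,
                "label": e.label,
                "forced": e.forced,
                "percentile": e.percentile,
            }
            for e in events
        ]
    )
    write_table(path, df)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
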