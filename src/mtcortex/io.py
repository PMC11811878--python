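"""Writers for metrics CSV, snapshot CSV and the JSON-lines event log."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Iterable, Union

import pandas as pd


def write_metrics(rows: Union[Iterable[Dict[str, Any]], pd.DataFrame], path) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)


def write_snapshot(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_snapshot(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def write_events(events: Iterable[Dict[str, Any]], path) -> None:
    with open(path, "w") as fh:
        for rec in events:
            fh.write(json.dumps(rec, default=_jsonable) + "\n")


def _jsonable(x: Any):
    try:
        return float(x)
    except (TypeError, ValueError):
        return str(x)
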