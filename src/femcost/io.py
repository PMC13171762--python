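"""Reading and writing brood tables, configs and result documents."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any, Dict

import pandas as pd
import yaml

from .synthetic import REQUIRED_COLUMNS


class SchemaError(ValueError):
    """The brood table does not match the documented schema."""


def read_brood_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a delimited brood table (comma default, tab accepted).

    Validates the documented header and the per-row conservation law
    ``eggs_developed + eggs_undeveloped == eggs_laid``; violations are
    reported with 1-based data row numbers.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if table.empty:
        warnings.warn(f"{path}: brood table is empty (header only)", UserWarning,
                      stacklevel=2)
        return table
    bad = table.index[table["eggs_developed"] + table["eggs_undeveloped"]
                      != table["eggs_laid"]]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:10])
        raise SchemaError(
            f"{path}: developed + undeveloped != laid in data row(s) {rows}")
    neg = table.index[(table[["eggs_laid", "eggs_developed",
                              "eggs_undeveloped"]] < 0).any(axis=1)]
    if len(neg):
        raise SchemaError(f"{path}: negative egg counts in data row(s) "
                          f"{', '.join(str(i + 1) for i in neg[:10])}")
    return table


def write_brood_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_csv(path, sep=sep, index=False)


def load_config(path: str | Path) -> Dict[str, Any]:
    """Flat key -> value YAML config (JSON is valid YAML and also accepted)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def write_results(results: Dict[str, Any], path: str | Path | None) -> str:
    """Serialise a results document as JSON; write to path if given."""
    text = json.dumps(results, indent=2, default=_jsonable)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _jsonable(obj: Any) -> Any:
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
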