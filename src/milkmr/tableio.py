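"""Deterministic TSV input/output helpers.

All tabular results are written as tab-separated text with a fixed float
format and Unix line endings, so identical analyses produce byte-identical
files (the basis of the pipeline's determinism contract).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping (canonical JSON form)."""
    canonical = json.dumps(config, sort_keys=True, default=str, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()
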