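"""TSV serialization with provenance headers.

Every table written by the package carries comment lines recording the
tool version, a configuration hash, and the seed, so that any output
file can be traced back to the run that produced it and re-running a
stage on unchanged inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    cfg_hash: str = "",
    seed: int | None = None,
) -> Path:
    """Write a DataFrame as TSV with provenance comment headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# sipturnover {__version__}\n")
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment headers skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    """Raise with a column diagnostic when a table misses schema columns."""
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} is missing column(s) {missing}; found {list(df.columns)}"
        )
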