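"""TSV/BED interchange with '#'-prefixed metadata headers."""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from . import __version__

__all__ = ["write_tsv", "read_tsv", "config_hash"]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, stage: str | None = None,
              seed: int | None = None, cfg_hash: str | None = None,
              index: bool = False) -> None:
    """Write a TSV with provenance header comments (version, seed, config
    hash, stage).  No timestamps, so identical runs are byte-identical."""
    with open(path, "w") as fh:
        fh.write(f"# tfdose_version: {__version__}\n")
        if stage is not None:
            fh.write(f"# stage: {stage}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
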