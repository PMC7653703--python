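"""Plain-text readers and writers for pipeline artifacts.

All tables are tab-separated; lines starting with '#' are metadata
comments (run provenance such as the configuration hash) and are skipped
on read. Coordinates in all outputs are 1-based and inclusive at both
ends, the cytogenetic convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .genome import ProbeMap
from .synthetic_data import TruthSet

__all__ = [
    "write_tsv", "read_tsv",
    "write_probe_map", "read_probe_map",
    "write_matrix", "read_matrix",
    "write_clinical", "read_clinical",
    "write_truth", "read_truth",
]


def _header_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in metadata.items())


def write_tsv(df: pd.DataFrame, path, index: bool = False, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(metadata))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_probe_map(pm: ProbeMap, path, metadata: dict | None = None) -> None:
    # 4-column layout: chrom, pos, probe_id, class
    write_tsv(pm.table[["chrom", "pos", "probe_id", "probe_class"]], path,
              metadata=metadata)


def read_probe_map(path) -> ProbeMap:
    t = read_tsv(path)
    return ProbeMap(t[["probe_id", "chrom", "pos", "probe_class"]])


def write_matrix(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Matrix with row labels in the first column and sample ids as header."""
    write_tsv(df, path, index=True, metadata=metadata)


def read_matrix(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def write_clinical(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_tsv(df.reset_index(), path, metadata=metadata)


def read_clinical(path) -> pd.DataFrame:
    return read_tsv(path, index_col="sample_id")


def write_truth(truth: TruthSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth(path) -> TruthSet:
    return TruthSet.from_dict(json.loads(Path(path).read_text()))
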