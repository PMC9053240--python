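"""Delimited-text readers/writers and run provenance.

The pipeline consumes exported matrices, never scanner formats: a
connectome is a labelled square CSV/TSV (first row and first column are
region names), a BOLD series is a labelled regions × timepoints matrix
with the TR supplied alongside (sidecar or flag). Dialect (comma or tab)
is auto-detected on read and preserved on write. Every CLI run emits a
:class:`RunManifest` recording the command, configuration, seeds and
input digests so deterministic stages can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from neurogsp.bold import BoldSeries
from neurogsp.graph_spectrum import Connectome, validate_connectome


class ParseError(ValueError):
    """Delimited-text parse failure, locating the offending cell."""


def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
    return "\t" if "\t" in head else ","


def _read_labelled(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    return df


def read_matrix(path, kind: str, tr_seconds: float = None,
                subject_id: str = None):
    """Read and validate a labelled delimited matrix.

    ``kind='connectome'`` routes through connectome validation (symmetry,
    nonnegativity, labels); ``kind='bold'`` returns a raw-stage
    :class:`BoldSeries` (``tr_seconds`` required).
    """
    df = _read_labelled(path)
    sid = subject_id or Path(path).stem
    if kind == "connectome":
        labels = [str(x) for x in df.index]
        if [str(c) for c in df.columns] != labels:
            raise ParseError(f"{path}: row and column labels disagree")
        return validate_connectome(df.to_numpy(), labels, subject_id=sid)
    if kind == "bold":
        if tr_seconds is None:
            raise ValueError("tr_seconds is required for BOLD matrices")
        return BoldSeries(values=df.to_numpy(), tr_seconds=tr_seconds,
                          region_labels=tuple(str(x) for x in df.index),
                          subject_id=sid, stage="raw")
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_connectome(c: Connectome, path, sep: str = ","):
    pd.DataFrame(c.weights, index=list(c.region_labels),
                 columns=list(c.region_labels)).to_csv(path, sep=sep)


def write_bold(s: BoldSeries, path, sep: str = ","):
    pd.DataFrame(s.values, index=list(s.region_labels),
                 columns=[f"t{j}" for j in range(s.n_timepoints)]) \
        .to_csv(path, sep=sep)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one CLI invocation."""

    command: str
    config: dict = dataclasses.field(default_factory=dict)
    seeds: dict = dataclasses.field(default_factory=dict)
    input_digests: dict = dataclasses.field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.package_version:
            from neurogsp import __version__
            self.package_version = __version__

    def write(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")

    @classmethod
    def read(cls, path):
        return cls(**json.loads(Path(path).read_text()))
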