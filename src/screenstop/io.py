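"""Corpus readers/writers and run-artefact serialisation.

Corpora travel as delimited UTF-8 text with a header row and columns
``id,title,abstract,label`` (label strictly 0/1).  Traces are written as
JSON-lines, one record per run, with the resolved configuration and seed
embedded so any single iteration can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from .corpus import ScreeningDataset
from .simulate import ScreeningTrace
from .stopping import StoppingConfig

__all__ = ["read_corpus", "write_corpus", "trace_record", "write_traces"]

_COLUMNS = ["id", "title", "abstract", "label"]


def read_corpus(path: str | Path, sep: str | None = None) -> ScreeningDataset:
    """Load a labelled screening corpus from CSV/TSV.

    The header must contain ``id,title,abstract,label``; labels must parse
    as exactly 0 or 1 and identifiers must be unique.  The separator is
    inferred from the file extension unless given (``.tsv`` → tab).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    labels = []
    for row, raw in enumerate(df["label"], start=2):  # header is line 1
        if raw not in ("0", "1"):
            raise ValueError(f"{path}: line {row}: label must be 0 or 1, got {raw!r}")
        labels.append(int(raw))
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate document id(s): {dupes}")
    return ScreeningDataset(
        ids=df["id"].tolist(),
        titles=df["title"].tolist(),
        abstracts=df["abstract"].tolist(),
        labels=labels,
    )


def write_corpus(dataset: ScreeningDataset, path: str | Path, sep: str | None = None) -> None:
    """Write a corpus in the same delimited format :func:`read_corpus` reads."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def _config_dict(config: StoppingConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


def trace_record(trace: ScreeningTrace, tau_tar: float) -> dict[str, Any]:
    """JSON-serialisable summary of one run: firing points plus metrics."""
    target_idx = trace.target_recall_index(tau_tar)
    criteria = {}
    for name, stop in trace.stop_indices.items():
        criteria[name] = {
            "stop_index": stop,
            "actual_recall": trace.recall_at(stop) if stop is not None else 1.0,
            "ws_sc": trace.work_saved_at(stop) if stop is not None else 0.0,
        }
    return {
        "seed": trace.seed,
        "config": _config_dict(trace.config),
        "N_total": trace.N_total,
        "rho_total": trace.rho_total,
        "seed_end": trace.seed_end,
        "switch_index": trace.switch_index,
        "target_recall_index": target_idx,
        "ws_at_target": trace.work_saved_at(target_idx),
        "criteria": criteria,
    }


def write_traces(
    traces: Iterable[ScreeningTrace], path: str | Path, tau_tar: float
) -> None:
    """One JSON-lines record per run."""
    with open(path, "w", encoding="utf-8") as fh:
        for trace in traces:
            fh.write(json.dumps(trace_record(trace, tau_tar)) + "\n")
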