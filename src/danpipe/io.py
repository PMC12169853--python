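"""Table readers/writers and provenance headers shared by all stages.

All tabular files are UTF-8 CSV (annotations: TSV) with a single header
row; files written by this package start with a ``#`` provenance
comment recording the tool version, the seed and a hash of the
configuration, and readers skip such comments.  Nested reports are
JSON with a ``provenance`` key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import PlateCount, ReciprocalPair
from .imaging import FluorescenceTrace, TraceError

EDGE_COLUMNS = ["pre_id", "post_id", "synapse_count"]
ANNOTATION_COLUMNS = [
    "neuron_id", "name", "neuron_class", "dan_cluster",
    "sensory_modality", "hemisphere", "pair_id",
]
COUNTS_COLUMNS = [
    "experiment", "genotype", "group", "replicate", "role",
    "n_side1", "n_side2", "n_neutral",
]
TRACE_COLUMNS = ["larva_id", "stimulus_label", "time_s", "fluorescence", "stimulus_on"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config) -> str:
    """Short stable hash of any (dataclass or dict) configuration."""
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def provenance(seed: int | None, config=None) -> dict:
    return {
        "tool": "danpipe",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }


def _header_comment(seed: int | None, config=None) -> str:
    p = provenance(seed, config)
    return (f"# danpipe v{p['version']} seed={p['seed']} "
            f"config_hash={p['config_hash']}\n")


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None,
    config=None, sep: str = ",",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(seed, config))
        df.to_csv(fh, index=False, sep=sep)
    return path


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", keep_default_na=False,
                       na_values=[""])


def write_edges(df: pd.DataFrame, path, seed=None, config=None) -> Path:
    return write_table(df[EDGE_COLUMNS], path, seed, config)


def read_edges(path) -> pd.DataFrame:
    return read_table(path)


def write_annotations(df: pd.DataFrame, path, seed=None, config=None) -> Path:
    return write_table(df[ANNOTATION_COLUMNS], path, seed, config, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    return read_table(path, sep="\t")


def write_counts(df: pd.DataFrame, path, seed=None, config=None) -> Path:
    return write_table(df[COUNTS_COLUMNS], path, seed, config)


def read_counts(path) -> pd.DataFrame:
    return read_table(path)


def write_traces(df: pd.DataFrame, path, seed=None, config=None) -> Path:
    return write_table(df[TRACE_COLUMNS], path, seed, config)


def read_traces(path) -> pd.DataFrame:
    return read_table(path)


def write_json(obj, path: str | Path, seed: int | None = None, config=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": provenance(seed, config), **_jsonable(obj)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# converters from tidy tables to domain objects


def reciprocal_pairs_from_counts(
    counts: pd.DataFrame,
) -> dict[str, list[ReciprocalPair]]:
    """Pair reciprocal plate counts per group, in replicate order.

    Rows with role ``O1_O2plus`` are matched to rows with role
    ``O1plus_O2`` within the same (experiment, genotype, group) by
    replicate number (acquisition order); unmatched replicates raise.
    """
    pairs: dict[str, list[ReciprocalPair]] = {}
    keys = ["experiment", "genotype", "group"]
    for (_, _, group), sub in counts.groupby(keys, sort=True):
        a = sub[sub.role == "O1_O2plus"].set_index("replicate").sort_index()
        b = sub[sub.role == "O1plus_O2"].set_index("replicate").sort_index()
        if not a.index.equals(b.index):
            raise ValueError(
                f"group {group!r}: reciprocal replicates do not match "
                f"({list(a.index)} vs {list(b.index)})"
            )
        plist = []
        for rep in a.index:
            ra, rb = a.loc[rep], b.loc[rep]
            plist.append(ReciprocalPair(
                count_O1_O2plus=PlateCount(int(ra.n_side1), int(ra.n_side2),
                                           int(ra.n_neutral)),
                count_O1plus_O2=PlateCount(int(rb.n_side1), int(rb.n_side2),
                                           int(rb.n_neutral)),
            ))
        pairs.setdefault(group, []).extend(plist)
    return pairs


def traces_from_table(table: pd.DataFrame) -> list[FluorescenceTrace]:
    """Split a long-format trace table into per-larva traces.

    The stimulus window is inferred from the ``stimulus_on`` flag (first
    to last flagged sample).
    """
    traces = []
    for (larva, label), sub in table.groupby(
        ["larva_id", "stimulus_label"], sort=True
    ):
        sub = sub.sort_values("time_s")
        on = sub[sub.stimulus_on == 1]
        if on.empty:
            raise TraceError(f"trace {larva!r}/{label!r} has no stimulus_on samples")
        traces.append(FluorescenceTrace(
            times=sub.time_s.to_numpy(float),
            values=sub.fluorescence.to_numpy(float),
            stimulus_onset=float(on.time_s.iloc[0]),
            stimulus_offset=float(on.time_s.iloc[-1]),
            larva_id=str(larva),
            stimulus_label=str(label),
        ))
    return traces
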