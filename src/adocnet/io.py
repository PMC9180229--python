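"""Readers and writers for the package's plain-text formats.

Edge lists are TSV/CSV with ``source``/``target`` header columns (an
optional ``count`` column is ignored beyond binarization).  User records are
a pair of CSVs: a user table (user_id, gender, registration_time) and a
long-format text table (user_id, sentiment, topic).  Malformed rows are
reported with 1-based file line numbers (header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import RawRecords
from .errors import ValidationError
from .network import DirectedNetwork, NodeAttributeTable


def _read_table(path, required, label):
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{label} file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"could not parse {label} file {path}: {exc}") from None
    if len(frame.columns) == 1 and sep == ",":
        # tolerate tab-delimited content with a .csv suffix
        frame = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{label} file {path} missing column(s): {missing}")
    return frame


def read_edge_list(path) -> list:
    """(source_id, target_id) records from a TSV/CSV edge list."""
    frame = _read_table(path, ("source", "target"), "edge list")
    bad = frame.index[frame["source"].isna() | frame["target"].isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValidationError(f"edge list has empty endpoint(s) at line(s) {lines}")
    return list(zip(frame["source"].astype(str), frame["target"].astype(str)))


def write_edge_list(network: DirectedNetwork, path) -> None:
    frame = pd.DataFrame(network.edge_id_pairs(), columns=["source", "target"])
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    frame.to_csv(path, sep=sep, index=False)


def read_user_records(users_path, texts_path) -> RawRecords:
    """Validated raw records from the user/text CSV pair."""
    users = _read_table(users_path, ("user_id", "gender", "registration_time"), "users")
    texts = _read_table(texts_path, ("user_id", "sentiment", "topic"), "texts")
    users["user_id"] = users["user_id"].astype(str)
    texts["user_id"] = texts["user_id"].astype(str)
    bad = texts.index[~texts["topic"].isin(range(1, 8))]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValidationError(
            f"texts file {texts_path}: topic label outside 1..7 at line(s) {lines}"
        )
    sentiment = pd.to_numeric(texts["sentiment"], errors="coerce")
    bad = texts.index[sentiment.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValidationError(
            f"texts file {texts_path}: non-numeric sentiment at line(s) {lines}"
        )
    texts["sentiment"] = sentiment.astype(float)
    texts["topic"] = texts["topic"].astype(np.int64)
    return RawRecords(users, texts)


def write_user_records(records: RawRecords, users_path, texts_path) -> None:
    records.users.to_csv(users_path, index=False)
    records.texts.to_csv(texts_path, index=False)


def write_graphml(network: DirectedNetwork, path, attrs: NodeAttributeTable | None = None):
    import networkx as nx

    nx.write_graphml(network.to_networkx(attrs), path)


def write_theta_json(theta: dict, path) -> None:
    Path(path).write_text(json.dumps({k: float(v) for k, v in theta.items()}, indent=2))


def read_theta_json(path) -> dict:
    return {k: float(v) for k, v in json.loads(Path(path).read_text()).items()}
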