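"""Readers and writers: EDF recordings, feature CSVs, connectivity CSVs.

All tabular artifacts are plain CSV with a JSON sidecar (``<file>.json``)
carrying the provenance a rerun needs: measure, band, channel labels, and
the generating configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import ConnectivityMatrix, EEGRecording, FeatureDataset

__all__ = ["read_edf", "features_to_csv", "features_from_csv",
           "matrix_to_csv", "matrix_from_csv", "matrix_csv_to_graphml",
           "write_provenance"]


def read_edf(path: str | Path, stimulus_onset: int = 0) -> EEGRecording:
    """Load a (possibly multi-channel) EDF file as one recording."""
    import mne  # heavy import; EDF support only

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(samples=raw.get_data(), sampling_rate=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names),
                        stimulus_onset=stimulus_onset)


def write_provenance(artifact: str | Path, config: dict, seed: int | None = None) -> None:
    """Sidecar JSON sufficient to regenerate the artifact."""
    artifact = Path(artifact)
    payload = json.dumps(config, sort_keys=True, default=str)
    prov = {"artifact": artifact.name, "version": __version__, "seed": seed,
            "config": config,
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest()}
    Path(str(artifact) + ".prov.json").write_text(json.dumps(prov, indent=1,
                                                             default=str))


def features_to_csv(dataset: FeatureDataset, path: str | Path) -> None:
    """Rows = trials; first column = label; remaining headers = "i-j" edges."""
    path = Path(path)
    df = pd.DataFrame(dataset.X, columns=dataset.edge_names())
    df.insert(0, "label", dataset.y)
    df.to_csv(path, index=False)
    sidecar = {"channel_labels": dataset.channel_labels, **dataset.provenance}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def features_from_csv(path: str | Path) -> FeatureDataset:
    path = Path(path)
    df = pd.read_csv(path)
    y = df.pop("label").to_numpy(dtype=int)
    edge_index = []
    for name in df.columns:
        i, j = name.split("-")
        edge_index.append((int(i), int(j)))
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    channels = sidecar.pop("channel_labels", [])
    if not channels:
        n = max(j for _, j in edge_index) + 1 if edge_index else 0
        channels = [f"ch{i:02d}" for i in range(n)]
    return FeatureDataset(X=df.to_numpy(dtype=float), y=y, edge_index=edge_index,
                          channel_labels=channels, provenance=sidecar)


def matrix_to_csv(matrix: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.channel_labels,
                 columns=matrix.channel_labels).to_csv(path)
    Path(str(path) + ".json").write_text(json.dumps(
        {"measure": matrix.measure,
         "band": matrix.band.name if matrix.band else None}, indent=1))


def matrix_from_csv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return ConnectivityMatrix(values=df.to_numpy(dtype=float),
                              measure=meta.get("measure", "correlation"),
                              channel_labels=[str(c) for c in df.columns])


def matrix_csv_to_graphml(csv_path: str | Path, out_path: str | Path) -> None:
    """One weighted edge per strict upper-triangle entry."""
    import networkx as nx

    m = matrix_from_csv(csv_path)
    g = nx.Graph()
    for idx, label in enumerate(m.channel_labels):
        g.add_node(idx, label=label)
    n = m.n_channels
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(m.values[i, j]))
    nx.write_graphml(g, str(out_path))
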