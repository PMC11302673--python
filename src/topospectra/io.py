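"""Plain-text I/O for matrices, centrality vectors and spectra (TSV)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import CentralityVector, FunctionalConnectome
from .homology import Barcode, PersistentFeature

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_connectome",
    "read_connectome",
    "write_centrality",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_barcode",
    "read_barcode",
    "write_cycles",
]


def write_matrix_tsv(path, matrix: np.ndarray, labels: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_connectome(path, G: FunctionalConnectome) -> None:
    write_matrix_tsv(path, G.r, G.region_labels)


def read_connectome(path) -> FunctionalConnectome:
    r, labels = read_matrix_tsv(path)
    return FunctionalConnectome.from_matrix(r, labels)


def write_centrality(path, vectors: Sequence[CentralityVector], names: Sequence[str]) -> None:
    data = {name: v.values for name, v in zip(names, vectors)}
    df = pd.DataFrame(data, index=list(vectors[0].region_labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_timeseries_tsv(path, data: np.ndarray, labels: Sequence[str]) -> None:
    """One (regions x time) matrix as TSV with a region-label header row."""
    df = pd.DataFrame(np.asarray(data).T, columns=list(labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float).T, [str(c) for c in df.columns]


def write_barcode(path, barcode: Barcode) -> None:
    """Barcode as TSV: dim, birth, death (inf allowed), creator/destroyer."""
    rows = []
    for iv in list(barcode.intervals) + list(barcode.infinite_intervals):
        i, j = iv.birth_edge
        t = iv.death_triangle
        rows.append(
            {
                "dim": barcode.dimension,
                "birth": iv.birth,
                "death": iv.death,
                "birth_edge_i": i,
                "birth_edge_j": j,
                "death_triangle": "-" if t is None else f"{t[0]},{t[1]},{t[2]}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_barcode(path) -> Barcode:
    from .homology import PersistenceInterval

    df = pd.read_csv(path, sep="\t")
    finite, infinite = [], []
    for _, row in df.iterrows():
        tri = row["death_triangle"]
        iv = PersistenceInterval(
            birth=float(row["birth"]),
            death=float(row["death"]),
            birth_edge=(int(row["birth_edge_i"]), int(row["birth_edge_j"])),
            death_triangle=None if tri == "-" else tuple(int(v) for v in tri.split(",")),
        )
        (finite if iv.finite else infinite).append(iv)
    dim = int(df["dim"].iloc[0]) if len(df) else 1
    return Barcode(
        intervals=tuple(finite), infinite_intervals=tuple(infinite), dimension=dim
    )


def write_cycles(path, features: Sequence[PersistentFeature]) -> None:
    """Optimal cycles as edge-list TSV, one row per (interval, edge)."""
    rows = []
    for k, feat in enumerate(features):
        for (i, j) in sorted(feat.cycle_edges):
            rows.append(
                {
                    "interval": k,
                    "birth": feat.interval.birth,
                    "death": feat.interval.death,
                    "edge_i": i,
                    "edge_j": j,
                    "volume": feat.volume,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
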