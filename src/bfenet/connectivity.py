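"""Post-hoc analysis and export of learned channel graphs.

After training, the per-trial sparse adjacencies of a chosen band and depth
can be averaged per emotion class, min-max normalized, and reduced to a
node-activation vector (the diagonal) keyed by electrode names — the raw
material for scalp topography plots, which are deliberately left to external
tools (we export plain CSV/TSV tables instead of rendering).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ConnectivitySummary:
    class_label: int
    mean_adjacency: np.ndarray  # (N, N), min-max normalized
    node_activation: np.ndarray  # (N,) diagonal of mean_adjacency
    montage: pd.DataFrame | None = None


def average_adjacency(adjacencies, normalize: bool = True) -> np.ndarray:
    """Element-wise mean of a stack of adjacencies, optionally min-max scaled.

    A constant mean matrix maps to all zeros under normalization (degenerate
    range guard).
    """
    adjacencies = list(adjacencies)
    if not adjacencies:
        raise ValueError("need at least one adjacency matrix")
    mean = np.mean([np.asarray(a, dtype=np.float64) for a in adjacencies], axis=0)
    if not normalize:
        return mean
    lo, hi = mean.min(), mean.max()
    if hi == lo:
        return np.zeros_like(mean)
    return (mean - lo) / (hi - lo)


def summarize_class(
    adjacency_stack: np.ndarray,
    labels: np.ndarray,
    class_label: int,
    montage: pd.DataFrame | None = None,
) -> ConnectivitySummary:
    """Average the adjacencies of one class's trials and extract the diagonal."""
    labels = np.asarray(labels)
    sel = adjacency_stack[labels == class_label]
    if len(sel) == 0:
        raise ValueError(f"no trials with label {class_label}")
    mean = average_adjacency(sel, normalize=True)
    return ConnectivitySummary(
        class_label=int(class_label),
        mean_adjacency=mean,
        node_activation=np.diag(mean).copy(),
        montage=montage,
    )


def top_edges(
    adjacency: np.ndarray, node: str, m: int, montage: pd.DataFrame
) -> list[tuple[str, str, float]]:
    """The m strongest edges incident to an electrode, by symmetrized weight.

    Ties are broken by electrode-name order. Returns (node, other, weight)
    triples in descending weight order.
    """
    names = list(montage["name"])
    if node not in names:
        raise ValueError(f"unknown electrode {node!r}; valid names: {names}")
    A = np.asarray(adjacency, dtype=np.float64)
    if not 1 <= m < len(names):
        raise ValueError(f"need 1 <= m < {len(names)}, got m={m}")
    sym = (A + A.T) / 2.0
    i = names.index(node)
    others = [(names[j], float(sym[i, j])) for j in range(len(names)) if j != i]
    others.sort(key=lambda t: (-t[1], t[0]))
    return [(node, name, w) for name, w in others[:m]]


# ---------------------------------------------------------------------------
# Table I/O


def write_adjacency_csv(adjacency: np.ndarray, names, path) -> None:
    pd.DataFrame(np.asarray(adjacency), index=list(names), columns=list(names)).to_csv(
        path, index_label="electrode"
    )


def read_adjacency_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col="electrode")
    return df.to_numpy(dtype=np.float64), list(df.columns)


def write_edge_list_tsv(adjacency: np.ndarray, names, path,
                        include_zeros: bool = False) -> None:
    """source / target / weight rows (upper triangle of the symmetrized graph)."""
    A = np.asarray(adjacency, dtype=np.float64)
    sym = (A + A.T) / 2.0
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if include_zeros or sym[i, j] != 0:
                rows.append((names[i], names[j], sym[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_node_activation_csv(summary: ConnectivitySummary, path) -> None:
    """electrode, x, y, z, activation table for external topography tools."""
    if summary.montage is None:
        raise ValueError("summary has no montage attached")
    df = summary.montage[["name", "x", "y", "z"]].copy()
    df["activation"] = summary.node_activation
    df.to_csv(path, index=False)


def make_synthetic_montage(n_channels: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic electrode layout: deterministic points on the upper unit
    hemisphere (Fibonacci spiral). A stand-in for a real cap geometry in
    tests and ablations; coordinates carry no anatomical meaning."""
    i = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = i / max(n_channels - 1, 1) * 0.95  # upper hemisphere only
    r = np.sqrt(1.0 - z ** 2)
    theta = golden * i
    return pd.DataFrame(
        {
            "name": [f"ch{j:02d}" for j in i],
            "x": r * np.cos(theta),
            "y": r * np.sin(theta),
            "z": z,
        }
    )
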