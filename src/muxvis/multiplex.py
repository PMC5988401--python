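"""Multiplex visibility graphs and interlayer mutual information.

Each column (ROI) of a T x M signal matrix is mapped to one visibility-graph
layer over the shared node set of time stamps; the layers are node-aligned by
the time arrow, so the collection is a multiplex network.  The dependence
between two layers is measured as the mutual information between their degree
sequences,

    MI(a, b) = sum_{k, k'} P(k, k') log[ P(k, k') / (P(k) P(k')) ],

where the joint distribution pairs the degree of node t in layer ``a`` with
the degree of node t in layer ``b`` over all time stamps t, and P(k), P(k')
are the plug-in (empirical) degree distributions of each layer.  No binning,
smoothing or bias correction is applied; values are reported in nats by
default (a base-2 option exists).  Averaging MI over all unordered ROI pairs
inside one labelled network yields the per-network scalar <MI>.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vg import (
    VisibilityGraph,
    hvg,
    hvg_degree_matrix,
    nvg_degree_matrix,
    nvg_fast,
)

__all__ = [
    "MultiplexVG",
    "DegreePMF",
    "MIMatrix",
    "build_multiplex",
    "degree_pmf",
    "interlayer_mi",
    "mi_matrix",
    "network_avg_mi",
    "subject_network_mi",
    "write_mi_matrix",
    "read_mi_matrix",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DegreePMF:
    """Empirical probability mass function over exact integer degrees."""

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.support, dtype=np.int64)
        p = np.asarray(self.probabilities, dtype=float)
        if s.size != p.size or np.unique(s).size != s.size:
            raise ValueError("support/probability mismatch or duplicate support")
        if abs(p.sum() - 1.0) > 1e-12 or np.any(p < 0):
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "probabilities", p)

    def entropy(self, base: float | None = None) -> float:
        p = self.probabilities[self.probabilities > 0]
        h = float(-(p * np.log(p)).sum())
        return h / np.log(base) if base else h

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.support.tolist(), self.probabilities.tolist()))


@dataclass(frozen=True)
class MultiplexVG:
    """Ordered visibility-graph layers over a shared set of time-stamp nodes."""

    layers: tuple[VisibilityGraph, ...]
    roi_labels: tuple[str, ...]
    network_labels: tuple[str, ...]
    method: str

    def __post_init__(self):
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        object.__setattr__(self, "network_labels", tuple(self.network_labels))
        if not layers:
            raise ValueError("multiplex needs at least one layer")
        n = layers[0].n_nodes
        if any(l.n_nodes != n for l in layers):
            raise ValueError("all layers must share the same number of nodes")
        m = len(layers)
        if len(self.roi_labels) != m or len(self.network_labels) != m:
            raise ValueError("label sequences must have one entry per layer")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    def degree_matrix(self) -> np.ndarray:
        """(N, M) matrix of node degrees, one column per layer."""
        return np.column_stack([l.degree_sequence() for l in self.layers])


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric M x M interlayer mutual information matrix.

    Diagonal entries equal the Shannon entropy of each layer's degree
    distribution (the plug-in identity MI(a, a) = H(a)).
    """

    values: np.ndarray = field(repr=False)
    roi_labels: tuple[str, ...]
    network_labels: tuple[str, ...]
    units: str = "nats"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("MI matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("MI matrix must be symmetric")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        object.__setattr__(self, "network_labels", tuple(self.network_labels))

    @property
    def size(self) -> int:
        return self.values.shape[0]


def build_multiplex(data, method: str = "natural", roi_labels=None,
                    network_labels=None) -> MultiplexVG:
    """Map each column of a T x M matrix to one visibility-graph layer.

    Layer order preserves column order; all layers share the time-stamp node
    set, aligned by index.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[1] < 1:
        raise ValueError(f"expected a T x M matrix with M >= 1, got shape {y.shape}")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    if not np.all(np.isfinite(y)):
        t, m = np.argwhere(~np.isfinite(y))[0]
        raise ValueError(f"non-finite value at row {t}, column {m}")
    m = y.shape[1]
    if roi_labels is None:
        roi_labels = [f"roi{j}" for j in range(m)]
    if network_labels is None:
        network_labels = ["all"] * m
    if len(roi_labels) != m or len(network_labels) != m:
        raise ValueError("label length must equal the number of columns")
    build = {"natural": nvg_fast, "horizontal": hvg}[method]
    layers = tuple(build(y[:, j]) for j in range(m))
    return MultiplexVG(layers, tuple(roi_labels), tuple(network_labels), method)


def degree_pmf(layer: VisibilityGraph) -> DegreePMF:
    """Plug-in PMF of a layer's exact integer degrees."""
    vals, cnt = np.unique(layer.degree_sequence(), return_counts=True)
    return DegreePMF(vals, cnt / cnt.sum())


def _mi_from_degrees(ka: np.ndarray, kb: np.ndarray, base: float | None) -> float:
    """Plug-in mutual information between two paired degree sequences."""
    _, ia = np.unique(ka, return_inverse=True)
    _, ib = np.unique(kb, return_inverse=True)
    na, nb = ia.max() + 1, ib.max() + 1
    joint = np.bincount(ia * nb + ib, minlength=na * nb).reshape(na, nb)
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    nz = pj > 0
    mi = float((pj[nz] * np.log(pj[nz] / np.outer(pa, pb)[nz])).sum())
    mi = max(mi, 0.0)  # clamp float round-off on independent layers
    return mi / np.log(base) if base else mi


def interlayer_mi(layer_a: VisibilityGraph, layer_b: VisibilityGraph,
                  base: float | None = None) -> float:
    """MI between two layers' degree sequences, paired by time stamp.

    Natural log (nats) unless ``base`` is given (e.g. 2 for bits).
    Symmetric, non-negative; a layer with a constant degree sequence gives 0.
    """
    if layer_a.n_nodes != layer_b.n_nodes:
        raise ValueError("layers must share the same number of nodes")
    return _mi_from_degrees(layer_a.degree_sequence(),
                            layer_b.degree_sequence(), base)


def mi_matrix(mvg: MultiplexVG, base: float | None = None) -> MIMatrix:
    """All-pairs interlayer MI; diagonal = per-layer degree entropies."""
    deg = mvg.degree_matrix()
    m = mvg.n_layers
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            out[a, b] = out[b, a] = _mi_from_degrees(deg[:, a], deg[:, b], base)
    units = "nats" if base is None else f"log base {base:g}"
    return MIMatrix(out, mvg.roi_labels, mvg.network_labels, units)


def network_avg_mi(mi: MIMatrix, network: str) -> float:
    """<MI>: mean interlayer MI over unordered ROI pairs within one network.

    The diagonal (self-information, i.e. layer entropy) is excluded; each
    unordered pair is counted once.  A network needs at least two ROIs.
    """
    idx = np.flatnonzero(np.asarray(mi.network_labels) == network)
    if idx.size == 0:
        raise KeyError(f"unknown network {network!r}")
    if idx.size < 2:
        raise ValueError(f"network {network!r} has a single ROI; <MI> undefined")
    block = mi.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(block[iu].mean())


def subject_network_mi(data, network_labels, method: str = "natural",
                       base: float | None = None) -> dict[str, float]:
    """Per-network <MI> of one subject, computed from degree sequences only.

    Shortcut for the pipeline's per-subject summary: extracts all layer
    degree sequences in one vectorised pass and evaluates MI only on the
    within-network pairs that the averages need.  Numerically identical to
    ``network_avg_mi(mi_matrix(build_multiplex(...)), net)`` for every net.
    """
    deg = nvg_degree_matrix(data) if method == "natural" else hvg_degree_matrix(data)
    labels = np.asarray(network_labels)
    if labels.size != deg.shape[1]:
        raise ValueError("one network label per column required")
    out: dict[str, float] = {}
    for net in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        idx = np.flatnonzero(labels == net)
        if idx.size < 2:
            continue
        vals = [_mi_from_degrees(deg[:, a], deg[:, b], base)
                for i, a in enumerate(idx) for b in idx[i + 1:]]
        out[str(net)] = float(np.mean(vals))
    return out


def write_mi_matrix(mi: MIMatrix, csv_path, json_path=None, *, method=None,
                    n_nodes=None, extra=None) -> None:
    """Labelled CSV plus a JSON sidecar with units and provenance fields."""
    df = pd.DataFrame(mi.values, index=list(mi.roi_labels),
                      columns=list(mi.roi_labels))
    df.to_csv(csv_path)
    meta = {
        "units": mi.units,
        "roi_labels": list(mi.roi_labels),
        "network_labels": list(mi.network_labels),
        "method": method,
        "n_nodes": n_nodes,
    }
    if extra:
        meta.update(extra)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_mi_matrix(csv_path, json_path) -> MIMatrix:
    df = pd.read_csv(csv_path, index_col=0)
    with open(json_path) as fh:
        meta = json.load(fh)
    return MIMatrix(df.to_numpy(), tuple(meta["roi_labels"]),
                    tuple(meta["network_labels"]), meta.get("units", "nats"))
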