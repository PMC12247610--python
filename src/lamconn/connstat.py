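"""Laminar functional connectivity strength (FCS).

FCS of a source series is the mean of the strictly positive Fisher-z
transformed Pearson correlations with a target set: all other vertices of a
network (network FCS), all series of a seed region (seed-based FCS), or the
representative series of a whole-cortex columnar parcellation (global
hubness).  Because the target sets span all cortical depths, the FCS of one
vertex across depths forms a laminar profile whose peak depth separates
feedforward-type (middle-peak) from feedback-type (superficial-peak)
connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph
from sklearn.cluster import KMeans

from .lamsurf import LaminarDataset, LaminarMesh

logger = logging.getLogger(__name__)

__all__ = [
    "FCSProfileMap",
    "NodeParcellation",
    "fisher_z",
    "network_fcs",
    "seed_fcs",
    "columnar_parcellation",
    "global_hubness",
    "extract_profile",
]

R_CLIP = 1.0 - 1e-7
MIN_TIMEPOINTS = 8


@dataclass
class FCSProfileMap:
    """Vertex-by-depth map of mean positive Fisher z (NaN where undefined)."""

    values: np.ndarray  # (V, D)
    network_id: str = ""
    n_timepoints: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("FCS values must be nonnegative")


@dataclass
class NodeParcellation:
    """Columnar (depth-invariant) node label per vertex; -1 outside the mask."""

    labels: np.ndarray  # (V,) int
    n_nodes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        inside = self.labels >= 0
        if inside.any():
            used = np.unique(self.labels[inside])
            if used.min() < 0 or used.max() >= self.n_nodes:
                raise ValueError("node labels out of range")


def fisher_z(r):
    """Fisher z transform atanh(r), with |r| clipped to 1 - 1e-7.

    Inner products of unit vectors can exceed 1 by float rounding; values
    within 1e-6 of the interval are treated as boundary values, anything
    further out is a caller error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1.0 + 1e-6):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return out if out.ndim else float(out)


def _standardize_rows(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean + unit-norm rows; returns (Z, valid) where invalid rows are zero."""
    Z = S - S.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Z, axis=1)
    valid = norm > 1e-12
    Z[valid] /= norm[valid][:, None]
    Z[~valid] = 0.0
    return Z, valid


def _kept_series(values: np.ndarray, keep: np.ndarray | None) -> np.ndarray:
    """Restrict the time axis to kept time points and drop globally-missing ones."""
    T = values.shape[-1]
    k = np.ones(T, dtype=bool) if keep is None else np.asarray(keep, dtype=bool)
    out = values[..., k]
    # drop time points missing everywhere (censored pairs stored as NaN)
    flat = out.reshape(-1, out.shape[-1])
    usable = ~np.all(~np.isfinite(flat), axis=0)
    return out[..., usable]


def _mean_positive_z(corr: np.ndarray, exclude: np.ndarray | None = None) -> np.ndarray:
    """Row-wise mean of strictly positive Fisher-z values; 0 when none positive.

    ``exclude`` is an optional boolean matrix of entries to ignore.
    """
    z = fisher_z(corr)
    pos = z > 0
    if exclude is not None:
        pos &= ~exclude
    valid = pos & np.isfinite(z)
    sums = np.where(valid, z, 0.0).sum(axis=1)
    counts = valid.sum(axis=1)
    out = np.zeros(len(z))
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def network_fcs(
    data: LaminarDataset | np.ndarray,
    network: np.ndarray,
    keep: np.ndarray | None = None,
    same_depth_only: bool = False,
    network_id: str = "",
) -> FCSProfileMap:
    """Network FCS: for every (vertex, depth) in the network, the mean
    positive Fisher z of its correlations with every series of every *other*
    network vertex (all depths by default, same depth only as an option).

    All depths of the source vertex itself are excluded from its target set.
    Series with zero variance (or fewer than 8 finite time points) get NaN.
    """
    values = data.values if isinstance(data, LaminarDataset) else np.asarray(data, float)
    V, D = values.shape[:2]
    network = np.asarray(network, dtype=bool)
    if not network.any():
        raise ValueError("network mask is empty")
    vals = _kept_series(values[network], keep)  # (n, D, Tk)
    n, _, Tk = vals.shape
    if Tk < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} kept time points, got {Tk}")
    S = vals.reshape(n * D, Tk)
    finite = np.all(np.isfinite(S), axis=1)
    S = np.where(finite[:, None], S, 0.0)
    Z, valid = _standardize_rows(S)
    valid &= finite
    C = Z @ Z.T
    vid = np.repeat(np.arange(n), D)
    did = np.tile(np.arange(D), n)
    exclude = vid[:, None] == vid[None, :]  # self vertex, every depth
    if same_depth_only:
        exclude |= did[:, None] != did[None, :]
    exclude |= ~valid[None, :]
    fcs = _mean_positive_z(C, exclude)
    fcs[~valid] = np.nan
    out = np.full((V, D), np.nan)
    out[network] = fcs.reshape(n, D)
    return FCSProfileMap(values=out, network_id=network_id, n_timepoints=Tk)


def seed_fcs(
    data: LaminarDataset | np.ndarray,
    seed: np.ndarray,
    targets: np.ndarray,
    keep: np.ndarray | None = None,
    network_id: str = "",
) -> FCSProfileMap:
    """Seed-based FCS: mean positive Fisher z of each target (vertex, depth)
    series against every seed series.

    ``seed`` is either a per-vertex boolean mask (the seed spans all depths)
    or an explicit (n_seed, T) series matrix (e.g. a volumetric seed such as
    a thalamic nucleus).  Seed and target vertex sets must be disjoint.
    """
    values = data.values if isinstance(data, LaminarDataset) else np.asarray(data, float)
    V, D = values.shape[:2]
    targets = np.asarray(targets, dtype=bool)
    seed = np.asarray(seed)
    if seed.dtype == bool:
        if not seed.any():
            raise ValueError("seed is empty")
        if np.any(seed & targets):
            raise ValueError("seed and targets must be disjoint")
        seed_series = values[seed].reshape(-1, values.shape[-1])
    else:
        seed_series = np.atleast_2d(np.asarray(seed, dtype=float))
        if seed_series.shape[0] == 0:
            raise ValueError("seed is empty")
    tvals = _kept_series(values[targets], keep)
    n, _, Tk = tvals.shape
    if Tk < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} kept time points, got {Tk}")
    svals = _kept_series(seed_series[:, None, :], keep)[:, 0, :]
    S_t = tvals.reshape(n * D, Tk)
    fin_t = np.all(np.isfinite(S_t), axis=1)
    Zt, vt = _standardize_rows(np.where(fin_t[:, None], S_t, 0.0))
    vt &= fin_t
    fin_s = np.all(np.isfinite(svals), axis=1)
    Zs, vs = _standardize_rows(np.where(fin_s[:, None], svals, 0.0))
    vs &= fin_s
    if not vs.any():
        raise ValueError("no usable seed series")
    C = Zt @ Zs.T
    fcs = _mean_positive_z(C, exclude=np.broadcast_to(~vs[None, :], C.shape))
    fcs[~vt] = np.nan
    out = np.full((V, D), np.nan)
    out[targets] = fcs.reshape(n, D)
    return FCSProfileMap(values=out, network_id=network_id, n_timepoints=Tk)


def columnar_parcellation(
    lmesh: LaminarMesh,
    n_nodes: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> NodeParcellation:
    """Parcellate the cortex evenly into columnar nodes.

    k-means on mid-depth vertex coordinates, followed by a contiguity repair
    that reassigns disconnected fragments of a node to the neighbouring node
    most common on the fragment border.  Each node spans all depths.
    """
    V = lmesh.n_vertices
    mask = np.ones(V, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    idx = np.where(mask)[0]
    if n_nodes > len(idx):
        raise ValueError("more nodes requested than vertices available")
    coords = lmesh.coords[idx, lmesh.n_depths // 2, :]
    km = KMeans(n_clusters=n_nodes, random_state=seed, n_init=4).fit(coords)
    lab = km.labels_.copy()
    adj = lmesh.base.adjacency()[idx][:, idx].tocsr()
    for _ in range(20):  # contiguity repair
        changed = False
        for node in range(n_nodes):
            members = np.where(lab == node)[0]
            if len(members) == 0:
                continue
            sub = adj[members][:, members]
            n_comp, comp = csgraph.connected_components(sub, directed=False)
            if n_comp <= 1:
                continue
            sizes = np.bincount(comp)
            main = np.argmax(sizes)
            for c in range(n_comp):
                if c == main:
                    continue
                frag = members[comp == c]
                nb = adj[frag].nonzero()[1]
                nb_labels = lab[nb]
                nb_labels = nb_labels[nb_labels != node]
                if len(nb_labels):
                    lab[frag] = np.bincount(nb_labels).argmax()
                    changed = True
        if not changed:
            break
    labels = np.full(V, -1, dtype=int)
    labels[idx] = lab
    return NodeParcellation(labels=labels, n_nodes=n_nodes)


def global_hubness(
    data: LaminarDataset | np.ndarray,
    nodes: NodeParcellation,
    keep: np.ndarray | None = None,
    exclude_own_node: bool = False,
) -> FCSProfileMap:
    """Global hubness: mean positive Fisher z of every (vertex, depth) series
    against the representative series of every node.

    A node's representative series is the mean over all its (vertex, depth)
    series.  By default the vertex's own node is included in the target set.
    """
    values = data.values if isinstance(data, LaminarDataset) else np.asarray(data, float)
    V, D = values.shape[:2]
    vals = _kept_series(values, keep)
    Tk = vals.shape[-1]
    if Tk < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} kept time points, got {Tk}")
    K = nodes.n_nodes
    node_series = np.zeros((K, Tk))
    for k in range(K):
        member = nodes.labels == k
        if not member.any():
            raise ValueError(f"node {k} is empty")
        node_series[k] = np.nanmean(vals[member].reshape(-1, Tk), axis=0)
    S = vals.reshape(V * D, Tk)
    finite = np.all(np.isfinite(S), axis=1)
    Zv, vv = _standardize_rows(np.where(finite[:, None], S, 0.0))
    vv &= finite
    Zn, vn = _standardize_rows(node_series)
    C = Zv @ Zn.T
    exclude = np.broadcast_to(~vn[None, :], C.shape).copy()
    if exclude_own_node:
        own = np.repeat(nodes.labels, D)
        ok = own >= 0
        exclude[np.where(ok)[0], own[ok]] = True
    fcs = _mean_positive_z(C, exclude)
    fcs[~vv] = np.nan
    out = fcs.reshape(V, D)
    return FCSProfileMap(values=out, network_id="hubness", n_timepoints=Tk)


def extract_profile(
    maps,
    roi: np.ndarray,
    normalize: bool = False,
):
    """ROI-mean laminar profile per session, with across-session mean and SEM.

    ``maps`` is one FCSProfileMap/(V, D) array or a list of them (sessions).
    With ``normalize=True`` each session profile is scaled to the 0-1 range
    (presentation only); a constant profile is set to 0.5 and flagged.
    Returns (mean, sem, session_profiles, flags).
    """
    if isinstance(maps, (FCSProfileMap, np.ndarray)):
        maps = [maps]
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("roi mask is empty")
    profiles = []
    flags = []
    for m in maps:
        vals = m.values if isinstance(m, FCSProfileMap) else np.asarray(m, float)
        p = np.nanmean(vals[roi], axis=0)
        flag = False
        if normalize:
            rng = np.nanmax(p) - np.nanmin(p)
            if rng <= 0 or not np.isfinite(rng):
                p = np.full_like(p, 0.5)
                flag = True
            else:
                p = (p - np.nanmin(p)) / rng
        profiles.append(p)
        flags.append(flag)
    profiles = np.array(profiles)
    mean = profiles.mean(axis=0)
    n = len(profiles)
    sem = profiles.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem, profiles, flags
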