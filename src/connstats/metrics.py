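"""Weighted-network graph-theory metrics.

The edge length between connected regions is the reciprocal of the edge
weight, ``l_ij = 1/w_ij`` (more streamlines = shorter, "stronger" link), and
the shortest path length ``L_ij`` is the minimum total length over all paths.
On top of ``L`` the module computes

* global / nodal shortest path ``S_p`` — mean ``L_ij`` over (reachable) pairs,
* global / nodal efficiency ``E_glob``, ``E_nodal_i`` — mean ``1/L_ij``, with
  unreachable pairs contributing zero,
* the weighted clustering coefficient ``C_p(i)`` — geometric-mean triangle
  intensity over mean-scaled weights ``ŵ = w / mean(nonzero w)``,

and bundles them, together with the small-world coefficient sigma from
:mod:`connstats.nullmodels`, into per-subject results.

Conventions for degenerate inputs: ``S_p`` averages over reachable pairs only
and carries an explicit ``disconnected`` flag; efficiency counts unreachable
pairs as zero (Latora–Marchiori); ``C_p(i) = 0`` for nodes of degree < 2, and
those zeros stay in the global average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .io import Connectome

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "edge_length_matrix",
    "shortest_paths",
    "global_shortest_path",
    "global_efficiency",
    "nodal_efficiency",
    "nodal_shortest_path",
    "nodal_clustering",
    "global_clustering",
    "scaled_weights",
    "subject_metrics",
    "cohort_metrics",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ("Sp", "Eglob", "Cp", "sigma")
NODAL_METRIC_NAMES = ("nodal_efficiency", "nodal_shortest_path", "nodal_clustering")


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network measures for one subject; ``sigma`` is None until null
    reference networks have been run."""

    Sp: float
    Eglob: float
    Cp: float
    sigma: float | None = None
    disconnected: bool = False


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node measures for one subject (arrays in node order).

    ``sp_nodal`` is NaN for isolated nodes (mean path from nowhere is
    undefined); ``e_nodal`` is 0 there.
    """

    e_nodal: np.ndarray
    sp_nodal: np.ndarray
    cp_nodal: np.ndarray


def edge_length_matrix(c: Connectome) -> np.ndarray:
    """Direct edge lengths: ``1/w_ij`` for positive weights, +inf for absent
    edges, 0 on the diagonal."""
    with np.errstate(divide="ignore"):
        length = np.where(c.W > 0, 1.0 / np.where(c.W > 0, c.W, 1.0), np.inf)
    np.fill_diagonal(length, 0.0)
    return length


def shortest_paths(c: Connectome) -> np.ndarray:
    """All-pairs shortest path lengths L over edge lengths 1/w (exact Dijkstra).

    Unreachable pairs are +inf; the diagonal is 0.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(c.W > 0, 1.0 / np.where(c.W > 0, c.W, 1.0), 0.0)
    graph = csr_matrix(lengths)
    L = dijkstra(graph, directed=False)
    return L


def global_shortest_path(L: np.ndarray) -> tuple[float, bool]:
    """Mean L_ij over reachable ordered pairs i≠j.

    Returns ``(Sp, disconnected)``; the flag is True when any pair was
    unreachable and therefore excluded from the average.  Raises if no pair
    is reachable at all (edgeless network).
    """
    off = ~np.eye(L.shape[0], dtype=bool)
    vals = L[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no reachable node pair: shortest path undefined")
    return float(vals[finite].mean()), bool((~finite).any())


def global_efficiency(L: np.ndarray) -> float:
    """E_glob = mean of 1/L_ij over all ordered pairs; unreachable pairs add 0."""
    n = L.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(L) & (L > 0), 1.0 / np.where(L > 0, L, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def nodal_efficiency(L: np.ndarray, i: int | None = None) -> np.ndarray | float:
    """E_nodal_i = mean of 1/L_ij over j≠i (0 for an isolated node).

    With *i* given returns a scalar, otherwise the full per-node vector.
    """
    n = L.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(L) & (L > 0), 1.0 / np.where(L > 0, L, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    e = inv.sum(axis=1) / (n - 1)
    return float(e[i]) if i is not None else e


def nodal_shortest_path(L: np.ndarray, i: int | None = None) -> np.ndarray | float:
    """Mean L_ij over reachable j≠i; NaN for an isolated node (flagged sentinel)."""
    n = L.shape[0]
    Lm = L.copy()
    np.fill_diagonal(Lm, np.nan)
    Lm[~np.isfinite(Lm)] = np.nan
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(Lm), axis=1)
        sums = np.nansum(Lm, axis=1)
        sp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return float(sp[i]) if i is not None else sp


def scaled_weights(c: Connectome) -> np.ndarray:
    """ŵ = w / mean(w), the mean taken over nonzero off-diagonal weights with
    each undirected edge counted once.  All-zero matrices return zeros."""
    iu = np.triu_indices(c.n_nodes, k=1)
    w = c.W[iu]
    nz = w[w > 0]
    if nz.size == 0:
        return np.zeros_like(c.W)
    return c.W / nz.mean()


def nodal_clustering(c: Connectome, i: int | None = None) -> np.ndarray | float:
    """Weighted clustering C_p(i) = (2 / k_i(k_i-1)) Σ_{j<k} (ŵ_ij ŵ_ik ŵ_jk)^{1/3}.

    The sum runs over unordered neighbour pairs {j, k} of node i; nodes with
    degree k_i < 2 get C_p(i) = 0.
    """
    w_hat = scaled_weights(c)
    cube = np.cbrt(w_hat)
    # diag(cube^3)[i] counts every ordered (j, k) pair, i.e. 2 × unordered sums
    triangle_sum = np.diag(cube @ cube @ cube)
    k = c.degrees.astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = np.where(denom > 0, triangle_sum / np.maximum(denom, 1), 0.0)
    return float(cp[i]) if i is not None else cp


def global_clustering(c: Connectome) -> float:
    """C_p = unweighted mean of C_p(i) over all N nodes (zeros included)."""
    return float(np.mean(nodal_clustering(c)))


def subject_metrics(
    c: Connectome,
    null_cfg=None,
) -> tuple[GlobalMetrics, NodalMetrics]:
    """All global and nodal metrics for one subject.

    When *null_cfg* (a :class:`connstats.nullmodels.NullModelConfig`) is given,
    sigma is computed against degree-preserving random references; otherwise it
    is left as None.  Deterministic given the config's seed.
    """
    L = shortest_paths(c)
    sp, disconnected = global_shortest_path(L)
    glob = GlobalMetrics(
        Sp=sp,
        Eglob=global_efficiency(L),
        Cp=global_clustering(c),
        sigma=None,
        disconnected=disconnected,
    )
    if null_cfg is not None:
        from .nullmodels import sigma as sigma_fn

        glob = GlobalMetrics(
            Sp=glob.Sp,
            Eglob=glob.Eglob,
            Cp=glob.Cp,
            sigma=sigma_fn(c, null_cfg).sigma,
            disconnected=disconnected,
        )
    nodal = NodalMetrics(
        e_nodal=nodal_efficiency(L),
        sp_nodal=nodal_shortest_path(L),
        cp_nodal=nodal_clustering(c),
    )
    return glob, nodal


def cohort_metrics(cohort, null_cfg=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy metric tables for a whole cohort.

    Returns ``(global_df, nodal_df)``: one row per subject for global metrics,
    one row per subject × node for nodal metrics (with the region name).
    """
    glob_rows, nodal_rows = [], []
    labels = cohort.labels
    for s in cohort.subjects:
        g, nd = subject_metrics(s.connectome, null_cfg)
        glob_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "gender": s.gender,
                "gender_code": s.gender_code,
                "pdss": s.pdss,
                "hamd": s.hamd,
                "duration_months": s.duration_months,
                "Sp": g.Sp,
                "Eglob": g.Eglob,
                "Cp": g.Cp,
                "sigma": g.sigma,
                "disconnected": g.disconnected,
            }
        )
        for i, name in enumerate(labels):
            nodal_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age": s.age,
                    "gender": s.gender,
                    "gender_code": s.gender_code,
                    "node": i + 1,
                    "region": name,
                    "nodal_efficiency": nd.e_nodal[i],
                    "nodal_shortest_path": nd.sp_nodal[i],
                    "nodal_clustering": nd.cp_nodal[i],
                }
            )
    return pd.DataFrame(glob_rows), pd.DataFrame(nodal_rows)
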