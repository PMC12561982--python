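"""Cluster-based sign-flip permutation tests on an adjacency graph.

Group-level inference for per-node maps (e.g., encoding-model correlation
maps): a one-sample t statistic is computed per node, nodes exceeding the
two-sided cluster-forming threshold are grouped into signed connected
clusters, and each cluster's summed t is compared against a Monte-Carlo null
distribution of maximal cluster sums obtained by randomly sign-flipping each
participant's map.  Keeping only the largest cluster statistic per resample
controls the family-wise error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

#: Voxel grid of the standard (MNI) brain volume used for source maps.
MNI_VOXEL_GRID = (181, 217, 181)


def lattice_adjacency(shape: Sequence[int]) -> dict[int, frozenset[int]]:
    """Minimal lattice adjacency: 4-neighbor in 2-D, 6-neighbor in 3-D."""
    shape = tuple(int(s) for s in shape)
    if len(shape) not in (2, 3):
        raise ValueError("lattice must be 2-D or 3-D")
    strides = np.zeros(shape, dtype=int)
    strides.flat = np.arange(strides.size)
    adj: dict[int, set[int]] = {i: set() for i in range(strides.size)}
    for axis in range(len(shape)):
        a = np.moveaxis(strides, axis, 0)
        for u, v in zip(a[:-1].ravel(), a[1:].ravel()):
            adj[int(u)].add(int(v))
            adj[int(v)].add(int(u))
    return {k: frozenset(v) for k, v in adj.items()}


def validate_graph(graph: Mapping[int, frozenset[int]], n_nodes: int) -> None:
    for node in range(n_nodes):
        if node not in graph:
            raise ValueError(f"graph is missing node {node}")
    for node, nbrs in graph.items():
        if node in nbrs:
            raise ValueError(f"self-loop at node {node}")
        for m in nbrs:
            if node not in graph[m]:
                raise ValueError(f"asymmetric edge {node}-{m}")


@dataclass(frozen=True)
class Cluster:
    nodes: tuple[int, ...]
    sum_t: float
    p: float

    @property
    def sign(self) -> int:
        return 1 if self.sum_t > 0 else -1


@dataclass(frozen=True)
class ClusterTestResult:
    t_values: np.ndarray
    clusters: tuple[Cluster, ...]
    null_max: np.ndarray
    alpha: float
    cluster_alpha: float
    n_perm: int
    seed: object
    excluded_nodes: tuple[int, ...] = ()
    provenance: dict = field(default_factory=dict)

    @property
    def significant(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.p <= self.alpha)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "cluster_alpha": self.cluster_alpha,
            "n_perm": self.n_perm, "seed": self.seed,
            "excluded_nodes": list(self.excluded_nodes),
            "clusters": [
                {"nodes": list(c.nodes), "sum_t": c.sum_t, "p": c.p}
                for c in self.clusters
            ],
        }


def _connected_components(nodes: np.ndarray, graph: Mapping[int, frozenset[int]]):
    """Connected components of the subgraph induced by `nodes`."""
    node_set = set(int(n) for n in nodes)
    seen: set[int] = set()
    for start in sorted(node_set):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            u = stack.pop()
            for v in graph[u]:
                if v in node_set and v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        yield sorted(comp)


def _t_onesample(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean / (sd / np.sqrt(n))


def cluster_permutation_test(
    data: np.ndarray,
    graph: Mapping[int, frozenset[int]] | None = None,
    grid_shape: Sequence[int] | None = None,
    alpha: float = 0.05,
    cluster_alpha: float = 0.025,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: str = "monte_carlo",
) -> ClusterTestResult:
    """One-sample cluster-based sign-flip permutation test.

    ``data`` is participants x nodes (values tested against zero, e.g. mean
    reconstruction correlations or paired differences).  Per-node t values
    are thresholded two-sided at ``cluster_alpha`` per tail; supra-threshold
    nodes of equal sign are grouped into connected clusters whose summed t is
    compared with the null distribution of maximum absolute cluster sums over
    sign-flip resamples.  Cluster p values are (1 + #{null >= observed}) /
    (1 + n_perm), so p is never below 1/(n_perm + 1).

    ``mode='exhaustive'`` enumerates all 2^n sign assignments (n <= 12).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("data must be participants x nodes with >= 2 participants")
    n_sub, n_nodes = data.shape
    if graph is None:
        if grid_shape is None:
            raise ValueError("provide an adjacency graph or a lattice grid_shape")
        graph = lattice_adjacency(grid_shape)
    validate_graph(graph, n_nodes)

    sd = data.std(axis=0, ddof=1)
    excluded = tuple(int(i) for i in np.flatnonzero(sd == 0))
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-variance node(s): {excluded[:10]}")
    keep = np.flatnonzero(sd > 0)
    kept_graph = {
        int(i): frozenset(int(v) for v in graph[int(i)] if sd[v] > 0) for i in keep
    }

    sub = data[:, keep]
    t_full = np.full(n_nodes, np.nan)
    t_obs = _t_onesample(sub)
    t_full[keep] = t_obs
    thresh = stats.t.ppf(1 - cluster_alpha, df=n_sub - 1)

    # observed clusters, on original node ids
    t_masked = np.zeros(n_nodes)
    t_masked[keep] = t_obs
    observed = _cluster_sums_masked(t_masked, keep, thresh, kept_graph)

    if mode == "exhaustive":
        if n_sub > 12:
            raise ValueError("exhaustive enumeration is limited to <= 12 participants")
        flips = np.array(list(product((1.0, -1.0), repeat=n_sub)))
        n_eff = len(flips)
    elif mode == "monte_carlo":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        flips = rng.choice([1.0, -1.0], size=(n_perm, n_sub))
        n_eff = n_perm
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # vectorized sign-flip t statistics: flipping signs leaves sum of squares
    # unchanged, so only the mean needs recomputing per resample
    ss = (sub ** 2).sum(axis=0)
    means = flips @ sub / n_sub
    var = (ss[None, :] - n_sub * means ** 2) / (n_sub - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = means / np.sqrt(var / n_sub)

    null_max = np.zeros(n_eff)
    for i in range(n_eff):
        tp = np.zeros(n_nodes)
        tp[keep] = t_perm[i]
        sums = _cluster_sums_masked(tp, keep, thresh, kept_graph)
        if sums:
            null_max[i] = max(abs(s) for _, s in sums)

    clusters = []
    for comp, s in observed:
        if mode == "exhaustive":
            p = float((null_max >= abs(s) - 1e-12).mean())
        else:
            p = (1.0 + float((null_max >= abs(s) - 1e-12).sum())) / (1.0 + n_eff)
        clusters.append(Cluster(tuple(comp), s, p))
    clusters.sort(key=lambda c: c.p)

    return ClusterTestResult(
        t_values=t_full, clusters=tuple(clusters), null_max=null_max,
        alpha=alpha, cluster_alpha=cluster_alpha, n_perm=n_eff,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        excluded_nodes=excluded,
        provenance={"mode": mode, "threshold_t": float(thresh), "n_participants": n_sub},
    )


def _cluster_sums_masked(t_full: np.ndarray, keep: np.ndarray, thresh: float, graph):
    out = []
    for sign in (1, -1):
        supra = keep[np.flatnonzero(sign * t_full[keep] > thresh)]
        for comp in _connected_components(supra, graph):
            out.append((comp, float(t_full[comp].sum())))
    return out


def paired_map_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    graph: Mapping[int, frozenset[int]] | None = None,
    **kwargs,
) -> ClusterTestResult:
    """Cluster permutation test on per-participant difference maps (a - b)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"score maps differ in shape: {a.shape} vs {b.shape}")
    return cluster_permutation_test(a - b, graph=graph, **kwargs)
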