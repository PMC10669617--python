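"""Data-driven sub-regions and the greedy sub-region combination search.

Anatomically defined regions are rarely uniformly engaged by a task, so
each region is split into k sub-regions (default 5) by k-means clustering
of its voxel time series concatenated across runs and participants — the
clustering groups voxels by similarity of response, not location.  The
network is then fitted with one sub-region per region; with 10 regions
and 5 clusters there are 5**10 = 9,765,625 possible combinations, so
exhaustive evaluation is impractical and a coordinate-ascent search is
used instead: visit the regions in random order, try each cluster while
holding the others fixed, keep the best, and sweep until a full pass
yields no improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .engine import BoldDataset, FitConfig, fit_sapm
from .network import NetworkModel

__all__ = [
    "RegionClusters",
    "SubRegionMap",
    "SubRegionSelection",
    "cluster_region_voxels",
    "participant_cluster_means",
    "greedy_subregion_search",
]


@dataclass
class RegionClusters:
    """Voxel-to-cluster assignment for one region."""

    labels: np.ndarray  # (n_voxels,)
    k: int
    cluster_means: np.ndarray  # (k, T) over the concatenated axis

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    @property
    def size_balance(self) -> float:
        """Largest-to-smallest cluster size ratio (1.0 = perfectly equal)."""
        s = self.sizes
        return float(s.max() / s.min()) if s.min() > 0 else float("inf")


@dataclass
class SubRegionMap:
    entries: dict[str, RegionClusters] = field(default_factory=dict)

    def to_records(self) -> list[tuple[str, int, int]]:
        """(region, voxel index, cluster) triples for CSV persistence."""
        return [
            (region, int(v), int(c))
            for region, rc in self.entries.items()
            for v, c in enumerate(rc.labels)
        ]


def _means_by_label(voxels: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    means = np.empty((k, voxels.shape[1]))
    for c in range(k):
        means[c] = voxels[labels == c].mean(axis=0)
    return means


def cluster_region_voxels(
    voxel_timeseries: np.ndarray,
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
    metric: str = "euclidean",
    balance: bool = False,
    max_restarts: int = 10,
) -> RegionClusters:
    """k-means clustering of one region's voxel time series.

    ``metric='euclidean'`` clusters the raw percent-signal-change courses;
    ``metric='correlation'`` z-scores each voxel first so Euclidean
    distance orders like correlation distance.  With ``balance`` an
    iterative reassignment caps the largest cluster at twice the smallest
    (plain k-means only approximates the near-equal volumes the method
    aims for).  Deterministic given ``seed``.
    """
    x = np.asarray(voxel_timeseries, dtype=float)
    if x.ndim != 2:
        raise ValueError("voxel_timeseries must be 2-D (voxels x time)")
    n_vox = x.shape[0]
    if n_vox < k:
        raise ValueError(f"{n_vox} voxels cannot form {k} clusters")
    if metric == "correlation":
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        feats = (x - x.mean(axis=1, keepdims=True)) / sd
    elif metric == "euclidean":
        feats = x
    else:
        raise ValueError(f"unknown metric {metric!r}")

    labels = None
    for attempt in range(max_restarts):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt)
        cand = km.fit_predict(feats)
        if np.bincount(cand, minlength=k).min() > 0:
            labels = cand
            break
    if labels is None:
        raise RuntimeError(f"k-means produced an empty cluster in {max_restarts} restarts")

    if balance:
        labels = _rebalance(feats, labels, k)
    return RegionClusters(labels=labels, k=k, cluster_means=_means_by_label(x, labels, k))


def _rebalance(feats: np.ndarray, labels: np.ndarray, k: int, cap_ratio: float = 2.0) -> np.ndarray:
    """Move boundary voxels from over-full to under-full clusters until the
    largest cluster is at most ``cap_ratio`` times the smallest."""
    labels = labels.copy()
    centroids = _means_by_label(feats, labels, k)
    for _ in range(10 * labels.size):
        sizes = np.bincount(labels, minlength=k)
        if sizes.max() <= cap_ratio * sizes.min():
            break
        big = int(np.argmax(sizes))
        small = int(np.argmin(sizes))
        members = np.nonzero(labels == big)[0]
        d = np.sum((feats[members] - centroids[small]) ** 2, axis=1)
        labels[members[np.argmin(d)]] = small
        centroids = _means_by_label(feats, labels, k)
    return labels


def participant_cluster_means(
    voxel_timeseries: np.ndarray,
    labels: np.ndarray,
    participant_slices: Sequence[tuple[int, int]],
    k: int | None = None,
) -> list[np.ndarray]:
    """Per-participant (k x T_p) cluster mean time courses.

    ``participant_slices`` are (start, stop) column ranges of the
    concatenated time axis belonging to each participant; the voxel
    labels are shared across participants (clustering pooled the group).
    """
    labels = np.asarray(labels)
    k = int(labels.max()) + 1 if k is None else k
    out = []
    for start, stop in participant_slices:
        out.append(_means_by_label(voxel_timeseries[:, start:stop], labels, k))
    return out


@dataclass
class SubRegionSelection:
    selection: dict[str, int]
    r2_average: float
    trace: list[dict] = field(default_factory=list)
    n_sweeps: int = 0


def _evaluate_selection(
    selection: Mapping[str, int],
    participant_data: Sequence[Mapping[str, np.ndarray]],
    model: NetworkModel,
    runs: list[tuple[int, int]],
    fit_config: FitConfig,
) -> float:
    """Mean (over participants) average R^2 of fitting the selected
    cluster time courses to the network."""
    r2 = []
    for pdata in participant_data:
        series = np.vstack([pdata[r][selection[r]] for r in model.regions])
        dataset = BoldDataset(data=series, runs=runs, regions=list(model.regions))
        fit = fit_sapm(dataset, model, fit_config)
        r2.append(fit.metrics.r2_average)
    return float(np.mean(r2))


def greedy_subregion_search(
    participant_data: Sequence[Mapping[str, np.ndarray]],
    model: NetworkModel,
    runs: list[tuple[int, int]],
    fit_config: FitConfig | None = None,
    final_config: FitConfig | None = None,
    fixed: Mapping[str, int] | None = None,
    seed: int = 0,
    max_sweeps: int = 20,
) -> SubRegionSelection:
    """Coordinate-ascent search for the sub-region combination that best
    fits the network.

    ``participant_data`` maps, per participant, each region name to its
    (k x T) cluster-mean array.  Starting from a random selection, regions
    are visited in random order; for each free region every cluster is
    scored by the group-mean average R^2 of a network fit (others held
    fixed) and the best is kept; sweeps repeat until none improves.
    Regions in ``fixed`` are pinned, which supports repeated searches with
    e.g. different spinal-cord sub-regions held at chosen values.
    Candidate fits may use a reduced iteration budget (``fit_config``);
    the returned ``r2_average`` is a fresh evaluation of the final
    selection at ``final_config`` (defaults to ``fit_config``).
    """
    cfg = fit_config or FitConfig(n_starts=3, explore_iters=5, refine_iters=30)
    fixed = dict(fixed or {})
    rng = np.random.default_rng(seed)

    k_per_region: dict[str, int] = {}
    for region in model.regions:
        for pdata in participant_data:
            if region not in pdata:
                raise ValueError(f"missing cluster data for region {region!r}")
        k_per_region[region] = participant_data[0][region].shape[0]

    selection = {
        r: fixed.get(r, int(rng.integers(k_per_region[r]))) for r in model.regions
    }
    cache: dict[tuple[int, ...], float] = {}

    def score(sel: Mapping[str, int]) -> float:
        key = tuple(sel[r] for r in model.regions)
        if key not in cache:
            cache[key] = _evaluate_selection(sel, participant_data, model, runs, cfg)
        return cache[key]

    best = score(selection)
    trace: list[dict] = [{"event": "start", "selection": dict(selection), "r2": best}]
    sweeps = 0
    for _ in range(max_sweeps):
        improved = False
        order = rng.permutation(len(model.regions))
        for ridx in order:
            region = model.regions[int(ridx)]
            if region in fixed:
                continue
            current = selection[region]
            best_cluster, best_r2 = current, best
            for c in range(k_per_region[region]):
                if c == current:
                    continue
                cand = dict(selection)
                cand[region] = c
                r2 = score(cand)
                if r2 > best_r2:
                    best_cluster, best_r2 = c, r2
            if best_cluster != current:
                selection[region] = best_cluster
                best = best_r2
                improved = True
                trace.append(
                    {"event": "improve", "region": region, "cluster": best_cluster, "r2": best}
                )
        sweeps += 1
        if not improved:
            break

    final_cfg = final_config or cfg
    final_r2 = _evaluate_selection(selection, participant_data, model, runs, final_cfg)
    trace.append({"event": "final", "selection": dict(selection), "r2": final_r2})
    return SubRegionSelection(
        selection=dict(selection), r2_average=final_r2, trace=trace, n_sweeps=sweeps
    )
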