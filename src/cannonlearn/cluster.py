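"""Mass-univariate GLM and spatiotemporal cluster-permutation statistics.

Per subject, the trial series at every (channel, time) point is regressed
onto a trial-wise design (intercept, changepoint, oddball, condition,
block/hit).  Changepoint and oddball coefficient maps are combined into a
*surprise* contrast (their sum) and a *learning* contrast (their
difference), aggregated across subjects into a one-sample t map, and
thresholded; contiguous same-sign suprathreshold points form spatiotemporal
clusters whose mass (mean |t| times size) is tested against a sign-flip
permutation distribution of the maximum cluster mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import sparse, spatial, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "EpochArray",
    "GLMDesign",
    "ClusterResult",
    "delaunay_adjacency",
    "massunivariate_fit",
    "make_contrasts",
    "group_tmap",
    "find_clusters",
    "signflip_permutation",
]


@dataclass
class EpochArray:
    """Channel x time x trial container for outcome-locked epochs.

    ``times`` are milliseconds relative to outcome onset; ``channel_positions``
    are 2-D schematic head coordinates used to build the spatial adjacency.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    channel_names: list[str]
    channel_positions: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, times, trials)")
        n_ch, n_t, _ = self.data.shape
        if len(self.times) != n_t:
            raise ValueError("times length must match data's time axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length must match data's channel axis")
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        if self.channel_positions.shape[0] != n_ch:
            raise ValueError("channel_positions must cover all channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must not contain missing values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean mask over the time axis for [start_ms, stop_ms)."""
        return (self.times >= start_ms) & (self.times < stop_ms)

    def baseline_correct(self, window=(-100.0, 0.0)) -> "EpochArray":
        """Subtract the per-trial, per-channel mean over ``window`` (ms)."""
        mask = self.time_mask(*window)
        if not mask.any():
            raise ValueError(f"baseline window {window} outside epoch range")
        baseline = self.data[:, mask, :].mean(axis=1, keepdims=True)
        return EpochArray(
            data=self.data - baseline,
            times=self.times,
            srate=self.srate,
            channel_names=list(self.channel_names),
            channel_positions=self.channel_positions,
        )

    def save_h5(self, path) -> None:
        with h5py.File(Path(path), "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.attrs["srate"] = self.srate
            f.create_dataset(
                "channel_names",
                data=np.array(self.channel_names, dtype=h5py.string_dtype()),
            )
            f.create_dataset("channel_positions", data=self.channel_positions)

    @classmethod
    def load_h5(cls, path) -> "EpochArray":
        with h5py.File(Path(path), "r") as f:
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                srate=float(f.attrs["srate"]),
                channel_names=[s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_names"][()]],
                channel_positions=f["channel_positions"][()],
            )


@dataclass
class GLMDesign:
    """Trial-wise explanatory matrix for the mass-univariate GLM."""

    columns: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("matrix must be (trials, columns)")

    @classmethod
    def from_behavior(cls, behavior) -> "GLMDesign":
        """Standard design from a tidy behavior table.

        Uses columns ``is_changepoint``/``is_oddball`` (0/1), ``condition``
        (+1 changepoint / -1 oddball) and ``hit`` (+1 blocked / -1 missed).
        """
        mat = np.column_stack(
            [
                np.ones(len(behavior)),
                behavior["is_changepoint"].to_numpy(float),
                behavior["is_oddball"].to_numpy(float),
                behavior["condition"].to_numpy(float),
                behavior["hit"].to_numpy(float),
            ]
        )
        return cls(
            columns=("intercept", "changepoint", "oddball", "condition", "block"),
            matrix=mat,
        )


@dataclass
class ClusterResult:
    """One signed spatiotemporal cluster."""

    channels: np.ndarray  # member channel indices
    time_indices: np.ndarray  # member time indices, aligned with channels
    sign: int
    mass: float
    peak: tuple[int, int]  # (channel, time index) of max |t|
    p_perm: float | None = None

    @property
    def size(self) -> int:
        return len(self.channels)

    def to_dict(self) -> dict:
        return {
            "channels": self.channels.tolist(),
            "time_indices": self.time_indices.tolist(),
            "sign": int(self.sign),
            "mass": float(self.mass),
            "peak": [int(self.peak[0]), int(self.peak[1])],
            "p_perm": None if self.p_perm is None else float(self.p_perm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterResult":
        return cls(
            channels=np.asarray(d["channels"], dtype=int),
            time_indices=np.asarray(d["time_indices"], dtype=int),
            sign=int(d["sign"]),
            mass=float(d["mass"]),
            peak=(int(d["peak"][0]), int(d["peak"][1])),
            p_perm=d.get("p_perm"),
        )


def save_clusters(clusters: list[ClusterResult], path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in clusters], indent=1))


def load_clusters(path) -> list[ClusterResult]:
    return [ClusterResult.from_dict(d) for d in json.loads(Path(path).read_text())]


def delaunay_adjacency(positions, dist_factor: float = 1.5) -> np.ndarray:
    """Channel adjacency from a Delaunay triangulation of 2-D positions.

    Edges longer than ``dist_factor`` times the median edge length are
    dropped.  Degenerate layouts (fewer than 4 channels, or collinear ones)
    fall back to linking each channel to its neighbours within that distance
    cutoff of the full pairwise median.
    """
    positions = np.asarray(positions, dtype=float)[:, :2]
    n = len(positions)
    adj = np.zeros((n, n), dtype=bool)
    if n <= 1:
        return adj
    try:
        tri = spatial.Delaunay(positions)
        edges = set()
        for simplex in tri.simplices:
            for i in range(3):
                a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
                edges.add((min(a, b), max(a, b)))
        edges = np.array(sorted(edges))
        lengths = np.linalg.norm(positions[edges[:, 0]] - positions[edges[:, 1]], axis=1)
        keep = lengths <= dist_factor * np.median(lengths)
        for (a, b) in edges[keep]:
            adj[a, b] = adj[b, a] = True
    except (spatial.QhullError, ValueError):
        dists = spatial.distance.squareform(spatial.distance.pdist(positions))
        cutoff = dist_factor * np.median(dists[np.triu_indices(n, k=1)]) if n > 1 else 0.0
        adj = (dists <= cutoff) & ~np.eye(n, dtype=bool)
    np.fill_diagonal(adj, False)
    return adj


def massunivariate_fit(epochs: EpochArray, design: GLMDesign) -> np.ndarray:
    """OLS coefficients at every (channel, time): (terms, channels, times)."""
    X = design.matrix
    if X.shape[0] != epochs.n_trials:
        raise ValueError(
            f"design rows ({X.shape[0]}) must match epoch trials ({epochs.n_trials})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            name
            for j, name in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    pinv = np.linalg.pinv(X)  # (terms, trials)
    n_ch, n_t, n_trials = epochs.data.shape
    flat = epochs.data.reshape(n_ch * n_t, n_trials).T  # (trials, points)
    coefs = pinv @ flat  # (terms, points)
    return coefs.reshape(X.shape[1], n_ch, n_t)


def make_contrasts(coef_maps: np.ndarray, design: GLMDesign):
    """Surprise (cp + odd) and learning (cp - odd) maps from coefficient maps."""
    try:
        i_cp = design.columns.index("changepoint")
        i_odd = design.columns.index("oddball")
    except ValueError as err:
        raise ValueError("design must contain changepoint and oddball columns") from err
    surprise = coef_maps[i_cp] + coef_maps[i_odd]
    learning = coef_maps[i_cp] - coef_maps[i_odd]
    return surprise, learning


def group_tmap(contrast_maps: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t map across subjects; returns (t map, dof).

    ``contrast_maps`` stacks per-subject maps on axis 0.  Points where all
    subjects agree exactly (zero variance) come out as +/-inf.
    """
    maps = np.asarray(contrast_maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.sign(mean) * np.inf, t)
        t = np.where((sd == 0) & (mean == 0), 0.0, t)
    return t, n - 1


def _cluster_from_points(t_map, channels, times_idx, sign):
    tvals = t_map[channels, times_idx]
    mass = float(np.abs(tvals).mean() * len(tvals))
    peak_i = int(np.argmax(np.abs(tvals)))
    return ClusterResult(
        channels=np.asarray(channels, dtype=int),
        time_indices=np.asarray(times_idx, dtype=int),
        sign=sign,
        mass=mass,
        peak=(int(channels[peak_i]), int(times_idx[peak_i])),
    )


def find_clusters(
    t_map: np.ndarray,
    dof: int,
    alpha_form: float,
    adjacency: np.ndarray,
) -> list[ClusterResult]:
    """Threshold a t map and group suprathreshold points into signed clusters.

    Points with |t| above the two-tailed ``alpha_form`` quantile of
    t(``dof``) are linked when they share a time index on adjacent channels
    or are consecutive samples on the same channel, and carry the same sign.
    Cluster mass is mean |t| times cluster size.  Clusters are returned
    sorted by decreasing mass; an empty threshold set gives an empty list.
    """
    t_map = np.asarray(t_map, dtype=float)
    n_ch, n_t = t_map.shape
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency must be (channels, channels)")
    if adjacency.diagonal().any() or not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric and irreflexive")
    thresh = stats.t.ppf(1.0 - alpha_form / 2.0, dof)

    clusters: list[ClusterResult] = []
    for sign in (1, -1):
        supra = (sign * t_map) > thresh
        if not supra.any():
            continue
        idx = np.flatnonzero(supra.ravel())  # point id = ch * n_t + t
        pos = -np.ones(n_ch * n_t, dtype=int)
        pos[idx] = np.arange(len(idx))
        rows, cols = [], []
        ch_i, t_i = np.unravel_index(idx, (n_ch, n_t))
        # temporal links: consecutive samples on the same channel
        nxt = idx + 1
        ok = (t_i + 1 < n_t) & (pos[np.minimum(nxt, n_ch * n_t - 1)] >= 0)
        rows.extend(pos[idx[ok]])
        cols.extend(pos[nxt[ok]])
        # spatial links: same time on adjacent channels
        a_src, a_dst = np.nonzero(adjacency)
        for s, d in zip(a_src, a_dst):
            if s >= d:
                continue
            src_pts = idx[ch_i == s]
            src_t = src_pts % n_t
            dst_pts = d * n_t + src_t
            ok = pos[dst_pts] >= 0
            rows.extend(pos[src_pts[ok]])
            cols.extend(pos[dst_pts[ok]])
        graph = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(idx), len(idx))
        )
        n_comp, labels = connected_components(graph, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            clusters.append(
                _cluster_from_points(t_map, members // n_t, members % n_t, sign)
            )
    clusters.sort(key=lambda c: -c.mass)
    return clusters


def _max_cluster_mass(t_map, dof, alpha_form, adjacency) -> float:
    clusters = find_clusters(t_map, dof, alpha_form, adjacency)
    return clusters[0].mass if clusters else 0.0


def signflip_permutation(
    contrast_maps: np.ndarray,
    observed_clusters: list[ClusterResult],
    adjacency: np.ndarray,
    alpha_form: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[ClusterResult]:
    """Attach permutation p-values (max cluster-mass null) to observed clusters.

    Each permutation flips the sign of whole per-subject contrast maps and
    records the maximum cluster mass of the resulting group t map.  When
    ``2**n_subjects <= n_perm`` all sign patterns are enumerated and the
    p-value is the exact fraction ``#(max >= observed) / 2**n``; otherwise
    ``n_perm`` random patterns are drawn and the Monte-Carlo p-value uses
    the +1 correction ``(1 + #(max >= observed)) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    maps = np.asarray(contrast_maps, dtype=float)
    n_sub = maps.shape[0]
    _, dof = group_tmap(maps)
    shape = maps.shape[1:]
    flat = maps.reshape(n_sub, -1)
    sum_sq = (flat**2).sum(axis=0)  # invariant under sign flips

    exact = 2**n_sub <= n_perm
    if exact:
        signs = np.array(
            [[1 if (k >> s) & 1 else -1 for s in range(n_sub)] for k in range(2**n_sub)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))

    thresh = stats.t.ppf(1.0 - alpha_form / 2.0, dof)
    max_masses = np.zeros(len(signs))
    # chunk the vectorized t computation to bound memory on large maps
    chunk = max(1, int(2e7 // max(flat.shape[1], 1)))
    for start in range(0, len(signs), chunk):
        block = signs[start : start + chunk]
        mean = block @ flat / n_sub
        var = (sum_sq - n_sub * mean**2) / (n_sub - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = mean / np.sqrt(var / n_sub)
            t_all = np.where(var == 0, np.sign(mean) * np.inf, t_all)
            t_all = np.where((var == 0) & (mean == 0), 0.0, t_all)
        any_supra = (np.abs(t_all) > thresh).any(axis=1)
        for i in np.flatnonzero(any_supra):
            max_masses[start + i] = _max_cluster_mass(
                t_all[i].reshape(shape), dof, alpha_form, adjacency
            )

    out = []
    for c in observed_clusters:
        # tolerate float jitter between the observed and permutation t paths
        # (the identity flip must always count as an exceedance)
        hits = (max_masses >= c.mass) | np.isclose(max_masses, c.mass, rtol=1e-9)
        exceed = int(hits.sum())
        p = exceed / len(signs) if exact else (1 + exceed) / (1 + len(signs))
        out.append(
            ClusterResult(
                channels=c.channels,
                time_indices=c.time_indices,
                sign=c.sign,
                mass=c.mass,
                peak=c.peak,
                p_perm=float(p),
            )
        )
    return out
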