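"""Trajectory observables: density profiles, gyration-tensor shape factors,
leaflet mixing counts, cluster analysis and a heuristic phase classifier.

The shape factor of a chain is built from the eigenvalues L1^2 >= L2^2 >=
L3^2 of its gyration tensor:

    delta = 1 - 3 (L1^2 L2^2 + L2^2 L3^2 + L1^2 L3^2) / (L1^2 + L2^2 + L3^2)^2

delta = 0 for an isotropic (spherical) mass distribution and 1 for a perfect
rod.  (For a uniform planar ring the value is 0.25; the model literature
sometimes quotes 0.5 for "circular", but direct evaluation of the formula
gives 0.25 -- the formula is implemented literally.)  Chains are unwrapped
across periodic images along their bonds before the tensor is formed.

Phase classification operates on the largest connected cluster of lipid
beads (contact graph at a cutoff, minimum-image distances): a cluster whose
periodic images connect in >= 2 dimensions is a double layer (DL, or PDL if
the in-plane occupancy map contains a pore); in exactly 1 dimension a
cylinder-like aggregate, subdivided into hierarchical discs (HD) when the
head density oscillates along the axis; in 0 dimensions a micelle, or a
vesicle when the tail shell encloses interior water.  Thresholds are
configurable approximations of published visual criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .builder import ParticleSystem, Topology, minimum_image
from .forcefield import SPECIES, SPECIES_INDEX

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
_TAIL_CODES = (SPECIES_INDEX["T1"], SPECIES_INDEX["T2"])
_HEAD_CODES = (SPECIES_INDEX["H1"], SPECIES_INDEX["H2"])
_WATER = SPECIES_INDEX["W"]


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Per-species 1D number density along one box axis."""

    axis: str
    edges: np.ndarray  # (n_bins + 1,)
    density: dict[str, np.ndarray]  # species label -> (n_bins,) in rc^-3
    box: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def integrate(self, label: str) -> float:
        """Integrated bead count for one species (density x bin volume)."""
        widths = np.diff(self.edges)
        return float(np.sum(self.density[label] * widths * self.box**2))


def density_profile(
    system: ParticleSystem,
    axis: str = "z",
    n_bins: int = 60,
    species: list[str] | None = None,
) -> DensityProfile:
    """Histogram bead positions along an axis, normalized to number density."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    ax = AXIS_INDEX[axis]
    L = system.box
    edges = np.linspace(0.0, L, n_bins + 1)
    slab_volume = (L / n_bins) * L * L
    labels = species if species is not None else list(SPECIES)
    out: dict[str, np.ndarray] = {}
    coords = system.positions[:, ax] % L
    for label in labels:
        mask = system.species == SPECIES_INDEX[label]
        counts, _ = np.histogram(coords[mask], bins=edges)
        out[label] = counts / slab_volume
    return DensityProfile(axis, edges, out, L)


def density_map_2d(
    system: ParticleSystem,
    plane: str = "xy",
    n_bins: int = 30,
    species: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Projected 2D bead counts per species over a plane of the box."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins per axis")
    ax0, ax1 = AXIS_INDEX[plane[0]], AXIS_INDEX[plane[1]]
    L = system.box
    edges = np.linspace(0.0, L, n_bins + 1)
    labels = species if species is not None else list(SPECIES)
    out: dict[str, np.ndarray] = {}
    for label in labels:
        mask = system.species == SPECIES_INDEX[label]
        h, _, _ = np.histogram2d(
            system.positions[mask, ax0] % L, system.positions[mask, ax1] % L, bins=(edges, edges)
        )
        out[label] = h
    return out


# ---------------------------------------------------------------------------
# gyration tensor and shape factor
# ---------------------------------------------------------------------------


def unwrap_chain(positions: np.ndarray, box: float) -> np.ndarray:
    """Unwrap a bonded chain across periodic images by walking its bonds."""
    out = np.empty_like(positions)
    out[0] = positions[0]
    for k in range(1, len(positions)):
        d = minimum_image(positions[k] - positions[k - 1], box)
        out[k] = out[k - 1] + d
    return out


def gyration_tensor(coords: np.ndarray) -> np.ndarray:
    """3x3 gyration tensor about the centroid (coords must be unwrapped)."""
    if len(coords) == 0:
        raise ValueError("empty chain")
    x = coords - coords.mean(axis=0)
    return (x.T @ x) / len(coords)


def gyration_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of the gyration tensor, descending, clipped at zero."""
    vals = np.linalg.eigvalsh(tensor)[::-1]
    return np.clip(vals, 0.0, None)


def shape_factor(eigenvalues: np.ndarray) -> float:
    """Asphericity delta in [0, 1]; 0 by convention for a point chain."""
    l1, l2, l3 = eigenvalues
    s = l1 + l2 + l3
    if s <= 0.0:
        return 0.0
    return float(1.0 - 3.0 * (l1 * l2 + l2 * l3 + l1 * l3) / (s * s))


def chain_shape_factors(system: ParticleSystem, topo: Topology) -> np.ndarray:
    """delta for every chain of the frame."""
    out = np.empty(topo.n_chains)
    for c in range(topo.n_chains):
        coords = unwrap_chain(system.positions[topo.chain_indices(c)], system.box)
        out[c] = shape_factor(gyration_eigenvalues(gyration_tensor(coords)))
    return out


@dataclass
class ShapeFactorSeries:
    """Per-frame chain-averaged delta per lipid type, plus per-chain values."""

    times: np.ndarray  # (n_frames,)
    mean_delta: dict[int, np.ndarray]  # lipid type (0/1) -> (n_frames,)
    per_chain: np.ndarray  # (n_frames, n_chains)
    chain_type: np.ndarray

    def stable_mean(self, lipid_type: int, window: float = 1.0 / 3.0) -> float:
        """Mean over the final ``window`` fraction of frames (stable stage)."""
        n = len(self.times)
        k = max(1, int(math.ceil(n * window)))
        return float(np.mean(self.mean_delta[lipid_type][n - k :]))

    def stable_mean_pooled(self, window: float = 1.0 / 3.0) -> float:
        """Stable-stage mean pooled over every chain of both types."""
        n = len(self.times)
        k = max(1, int(math.ceil(n * window)))
        return float(np.mean(self.per_chain[n - k :]))


def mean_shape_factor(frames, topo: Topology) -> ShapeFactorSeries:
    """Shape-factor series over a trajectory (both lipid types)."""
    times = []
    rows = []
    for fr in frames:
        times.append(fr.time)
        rows.append(chain_shape_factors(fr, topo))
    per_chain = np.asarray(rows)
    mean_delta = {}
    for t in (0, 1):
        mask = topo.chain_type == t
        mean_delta[t] = (
            per_chain[:, mask].mean(axis=1) if mask.any() else np.full(len(times), np.nan)
        )
    return ShapeFactorSeries(np.asarray(times), mean_delta, per_chain, topo.chain_type.copy())


# ---------------------------------------------------------------------------
# leaflet mixing
# ---------------------------------------------------------------------------


def _circular_mean_and_spread(coords: np.ndarray, box: float) -> tuple[float, float]:
    """Mean position and spread of periodic coordinates via circular stats."""
    theta = coords / box * 2.0 * np.pi
    z = np.exp(1j * theta).mean()
    mean = (np.angle(z) % (2.0 * np.pi)) / (2.0 * np.pi) * box
    spread = 1.0 - np.abs(z)  # 0 = concentrated, 1 = uniform
    return float(mean), float(spread)


@dataclass
class MixingCounts:
    """Chains of each type found on their initial side of the bilayer."""

    n_type_I_right: int
    n_type_II_left: int
    n_type_I: int
    n_type_II: int
    normal_axis: str = "z"
    midplane: float = 0.0


def bilayer_normal(system: ParticleSystem, topo: Topology) -> str:
    """Axis along which the tail beads are most concentrated."""
    tails = np.isin(system.species, _TAIL_CODES)
    if not tails.any():
        raise ValueError("no tail beads present; not a lipid system")
    spreads = [
        _circular_mean_and_spread(system.positions[tails, ax] % system.box, system.box)[1]
        for ax in range(3)
    ]
    return "xyz"[int(np.argmin(spreads))]


def mixing_counts(
    system: ParticleSystem,
    topo: Topology,
    normal_axis: str | None = None,
) -> MixingCounts:
    """Count type-I chains in the right (+normal) leaflet and type-II chains
    in the left leaflet.

    The midplane passes through the circular mean of the tail-bead positions
    along the bilayer normal; a chain belongs to the leaflet containing its
    first head bead.
    """
    if normal_axis is None:
        normal_axis = bilayer_normal(system, topo)
    ax = AXIS_INDEX[normal_axis]
    L = system.box
    tails = np.isin(system.species, _TAIL_CODES)
    mid, _ = _circular_mean_and_spread(system.positions[tails, ax] % L, L)
    first_heads = topo.chain_start  # bead 0 of each chain is the first head bead
    offs = minimum_image(system.positions[first_heads, ax] - mid, L)
    right = offs > 0
    type_I = topo.chain_type == 0
    type_II = topo.chain_type == 1
    return MixingCounts(
        n_type_I_right=int(np.sum(right & type_I)),
        n_type_II_left=int(np.sum(~right & type_II)),
        n_type_I=int(np.sum(type_I)),
        n_type_II=int(np.sum(type_II)),
        normal_axis=normal_axis,
        midplane=mid,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    """Connected components of the periodic contact graph of a bead subset."""

    labels: np.ndarray  # (n_subset,) component id
    sizes: np.ndarray  # (n_clusters,)
    spans: np.ndarray  # (n_clusters, 3) bool: connects to own image along axis
    unwrapped: np.ndarray  # (n_subset, 3) BFS-unwrapped coordinates

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def largest(self) -> int:
        return int(np.argmax(self.sizes))


def cluster_beads(positions: np.ndarray, box: float, cutoff: float = 1.0) -> ClusterSet:
    """Cluster beads whose minimum-image distance is <= cutoff.

    Periodic spanning is detected during a BFS unwrap of each component: a
    contact whose unwrapped end points disagree by ~one box length in some
    axis means the cluster touches its own periodic image along that axis.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(positions)
    if n == 0:
        return ClusterSet(
            np.zeros(0, dtype=int), np.zeros(0, dtype=int),
            np.zeros((0, 3), dtype=bool), np.zeros((0, 3)),
        )
    pos = positions % box
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)

    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        adjacency[i].append(j)
        adjacency[j].append(i)

    unwrapped = np.full((n, 3), np.nan)
    spans = np.zeros((n_comp, 3), dtype=bool)
    visited = np.zeros(n, dtype=bool)
    for root in range(n):
        if visited[root]:
            continue
        comp = labels[root]
        unwrapped[root] = pos[root]
        visited[root] = True
        stack = [root]
        while stack:
            i = stack.pop()
            for j in adjacency[i]:
                target = unwrapped[i] + minimum_image(pos[j] - pos[i], box)
                if not visited[j]:
                    unwrapped[j] = target
                    visited[j] = True
                    stack.append(j)
                else:
                    mismatch = np.abs(unwrapped[j] - target) > box / 2.0
                    spans[comp] |= mismatch
    sizes = np.bincount(labels, minlength=n_comp)
    return ClusterSet(labels, sizes, spans, unwrapped)


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------

PHASES = ("DL", "PDL", "HD", "micelle", "vesicle", "unclassified")


@dataclass
class PhaseLabel:
    label: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in PHASES:
            raise ValueError(f"unknown phase label {self.label!r}")


def _pore_cells(
    positions: np.ndarray, box: float, plane_axes: tuple[int, int], cell: float = 1.0
) -> int:
    """Size (in cells) of the largest connected empty patch of the in-plane
    occupancy grid, with periodic connectivity."""
    n_bins = max(2, int(round(box / cell)))
    edges = np.linspace(0.0, box, n_bins + 1)
    h, _, _ = np.histogram2d(
        positions[:, plane_axes[0]] % box, positions[:, plane_axes[1]] % box, bins=(edges, edges)
    )
    empty = h == 0
    if not empty.any():
        return 0
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    lab, n_lab = ndimage.label(empty, structure=structure)
    if n_lab == 0:
        return 0
    # merge labels across the periodic seam
    merge = {}

    def find(x):
        while merge.get(x, x) != x:
            x = merge[x]
        return x

    for k in range(n_bins):
        for a, b in ((lab[0, k], lab[-1, k]), (lab[k, 0], lab[k, -1])):
            if a > 0 and b > 0:
                ra, rb = find(a), find(b)
                if ra != rb:
                    merge[ra] = rb
    counts = np.zeros(n_lab + 1, dtype=int)
    for v in range(1, n_lab + 1):
        counts[find(v)] += int(np.sum(lab == v))
    return int(counts.max())


def _head_axis_peaks(
    coords: np.ndarray, box: float, bin_width: float = 1.0
) -> int:
    """Number of pronounced peaks in a periodic 1D head-density profile."""
    n_bins = max(4, int(round(box / bin_width)))
    counts, _ = np.histogram(coords % box, bins=np.linspace(0.0, box, n_bins + 1))
    smoothed = np.convolve(
        np.concatenate([counts[-2:], counts, counts[:2]]), np.ones(3) / 3.0, mode="same"
    )[2:-2]
    # wrap-pad so peaks at the seam are found
    padded = np.concatenate([smoothed[-3:], smoothed, smoothed[:3]])
    prominence = max(0.5 * smoothed.mean(), 1.0)
    peaks, _ = signal.find_peaks(padded, prominence=prominence)
    peaks = peaks[(peaks >= 3) & (peaks < 3 + n_bins)]
    return int(len(peaks))


def classify_phase(
    system: ParticleSystem,
    topo: Topology,
    cutoff: float = 1.0,
    pore_min_cells: int = 4,
    min_core_water: int = 5,
    core_margin: float = 0.5,
) -> PhaseLabel:
    """Heuristic decision tree over the largest lipid aggregate."""
    lipid_mask = system.species != _WATER
    if not lipid_mask.any():
        return PhaseLabel("unclassified", {"reason": "no lipid beads"})
    lipid_idx = np.flatnonzero(lipid_mask)
    clusters = cluster_beads(system.positions[lipid_idx], system.box, cutoff)
    big = clusters.largest()
    member = clusters.labels == big
    diag: dict = {
        "n_clusters": clusters.n_clusters,
        "largest_size": int(clusters.sizes[big]),
        "spans": clusters.spans[big].tolist(),
    }
    sorted_sizes = np.sort(clusters.sizes)[::-1]
    if len(sorted_sizes) > 1 and sorted_sizes[1] > 0.5 * sorted_sizes[0]:
        diag["ambiguous"] = True

    span_dims = int(np.sum(clusters.spans[big]))
    species_sub = system.species[lipid_idx][member]
    pos_sub = system.positions[lipid_idx][member]
    unwrapped_sub = clusters.unwrapped[member]
    tails_sub = np.isin(species_sub, _TAIL_CODES)
    heads_sub = np.isin(species_sub, _HEAD_CODES)

    if span_dims >= 2:
        # membrane: the (first) non-spanning axis is the normal
        non_span = np.flatnonzero(~clusters.spans[big])
        if len(non_span) > 0:
            normal = int(non_span[0])
        else:
            spreads = [
                _circular_mean_and_spread(pos_sub[tails_sub, ax] % system.box, system.box)[1]
                for ax in range(3)
            ]
            normal = int(np.argmin(spreads))
        plane_axes = tuple(ax for ax in range(3) if ax != normal)
        pore = _pore_cells(pos_sub, system.box, plane_axes)
        diag["normal_axis"] = "xyz"[normal]
        diag["pore_cells"] = pore
        label = "PDL" if pore >= pore_min_cells else "DL"
        return PhaseLabel(label, diag)

    if span_dims == 1:
        axis = int(np.argmax(clusters.spans[big]))
        n_peaks = _head_axis_peaks(pos_sub[heads_sub, axis], system.box)
        diag["axis"] = "xyz"[axis]
        diag["head_axis_peaks"] = n_peaks
        label = "HD" if n_peaks >= 2 else "micelle"
        return PhaseLabel(label, diag)

    # compact aggregate: vesicle iff the tail shell is hollow and holds water
    centroid = unwrapped_sub.mean(axis=0)
    tail_r = np.linalg.norm(unwrapped_sub[tails_sub] - centroid, axis=1)
    r_inner = float(tail_r.min()) if tails_sub.any() else 0.0
    water_pos = system.positions[system.species == _WATER]
    d = minimum_image(water_pos - (centroid % system.box), system.box)
    core_water = int(np.sum(np.linalg.norm(d, axis=1) < r_inner - core_margin))
    diag["tail_inner_radius"] = r_inner
    diag["core_water"] = core_water
    label = "vesicle" if core_water >= min_core_water else "micelle"
    return PhaseLabel(label, diag)


# ---------------------------------------------------------------------------
# energy-stage segmentation
# ---------------------------------------------------------------------------


@dataclass
class StageSegmentation:
    """Changepoint split of an energy series into 1-3 stages."""

    boundaries: list[float]  # times of the stage boundaries
    n_stages: int
    warning: str | None = None


def _piecewise_sse(t: np.ndarray, y: np.ndarray, breaks: list[int]) -> float:
    sse = 0.0
    idx = [0, *breaks, len(t)]
    for a, b in zip(idx[:-1], idx[1:]):
        seg_t, seg_y = t[a:b], y[a:b]
        if len(seg_t) < 2:
            return math.inf
        A = np.stack([seg_t, np.ones_like(seg_t)], axis=1)
        coef, *_ = np.linalg.lstsq(A, seg_y, rcond=None)
        sse += float(np.sum((seg_y - A @ coef) ** 2))
    return sse


def segment_stages(
    times: np.ndarray,
    energy: np.ndarray,
    min_samples: int = 100,
    n_candidates: int = 40,
) -> StageSegmentation:
    """Split an energy series into decay / adjustment / plateau stages.

    Piecewise-linear fits with 1, 2 or 3 segments compete by BIC; the
    boundary times of the winner are returned.  A series without a clear
    changepoint structure collapses to a single stage with a warning.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(energy, dtype=float)
    if len(t) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {len(t)}")
    ys = y
    n = len(t)
    # SSE floor tied to the data scale: exactly-piecewise (noiseless) fits
    # all bottom out here, so the BIC penalty then prefers fewer stages
    scale = max(float(np.ptp(ys)), 1e-3 * float(np.max(np.abs(ys))), 1e-30)
    floor = n * (1e-7 * scale) ** 2

    min_seg = max(5, n // 20)
    cand = np.unique(np.linspace(min_seg, n - min_seg, n_candidates).astype(int))
    step = max(1, (n - 2 * min_seg) // max(len(cand) - 1, 1))

    def bic(sse: float, k: int) -> float:
        return n * math.log(max(sse, floor) / n) + k * math.log(n)

    def refine(breaks: list[int]) -> tuple[float, list[int]]:
        """Coordinate-descent exact search around coarse breakpoints."""
        breaks = list(breaks)
        best_sse = _piecewise_sse(t, ys, breaks)
        for _ in range(2):
            for bi in range(len(breaks)):
                lo = max(min_seg, breaks[bi] - step)
                hi = min(n - min_seg, breaks[bi] + step)
                for c in range(lo, hi + 1):
                    trial = sorted(set(breaks[:bi] + [c] + breaks[bi + 1 :]))
                    if len(trial) != len(breaks):
                        continue
                    sse = _piecewise_sse(t, ys, trial)
                    if sse < best_sse:
                        best_sse, breaks = sse, trial
        return best_sse, breaks

    best = {1: (_piecewise_sse(t, ys, []), [])}
    b2 = min(((_piecewise_sse(t, ys, [c]), [c]) for c in cand), key=lambda x: x[0])
    best[2] = refine(b2[1])
    b3_sse, b3_breaks = math.inf, []
    for i, c1 in enumerate(cand):
        for c2 in cand[i + 1 :]:
            if c2 - c1 < min_seg:
                continue
            sse = _piecewise_sse(t, ys, [c1, c2])
            if sse < b3_sse:
                b3_sse, b3_breaks = sse, [c1, c2]
    best[3] = refine(b3_breaks) if b3_breaks else (b3_sse, b3_breaks)

    scores = {k: bic(sse, 2 * k + (k - 1)) for k, (sse, _) in best.items()}
    k_best = min(scores, key=scores.get)
    warning = None
    if k_best == 1:
        warning = "no clear changepoint structure; treating the series as one stage"
    breaks = best[k_best][1]
    return StageSegmentation([float(t[b]) for b in breaks], k_best, warning)


# ---------------------------------------------------------------------------
# run summary
# ---------------------------------------------------------------------------


def summarize_run(frames, topo: Topology, energies=None) -> dict:
    """Single structured summary: phase label, stable shape factors, stages."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to summarize")
    series = mean_shape_factor(frames, topo)
    label = classify_phase(frames[-1], topo)
    out = {
        "phase": label.label,
        "phase_diagnostics": label.diagnostics,
        "delta_type_I": series.stable_mean(0) if (topo.chain_type == 0).any() else None,
        "delta_type_II": series.stable_mean(1) if (topo.chain_type == 1).any() else None,
        "delta_pooled": series.stable_mean_pooled(),
    }
    if energies is not None and len(energies) >= 100:
        seg = segment_stages(energies[:, 1], energies[:, 6])
        out["stage_boundaries_tau"] = seg.boundaries
        out["n_stages"] = seg.n_stages
    return out
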