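"""Voronoi-tessellation density clustering of localization point clouds.

A vesicle immobilized on the coverslip produces a tight clump of antibody
blinking localizations against sparse uniform background. The detector:

1. tessellates the ROI — one Voronoi cell per (deduplicated) localization,
   clipped exactly to the ROI rectangle;
2. keeps localizations whose first-rank cell area — the median area over
   the cell and its edge-sharing neighbors — is at most ``alpha`` times the
   mean cell area of the ROI (small cell ⇔ high local density; the mean
   cell area is ROI area / n, so the rule is scale-free and the same
   ``alpha`` works at any density; the neighborhood median keeps the rim
   localizations of a cluster, whose own cells flare out into empty
   surroundings but whose neighbors are mostly dense cluster cells);
3. groups retained localizations into connected components under the
   shared-Voronoi-edge adjacency relation and reports components with at
   least ``M`` member localizations as candidate vesicles.

Clipping is done by the mirror-point construction: the point set is
reflected across each ROI edge before tessellating, which makes every
original cell finite and bounded exactly by the rectangle — the cells then
partition the ROI area to floating-point accuracy, with no polygon-clipping
library needed. Mirroring is restricted to a boundary margin for speed and
falls back to full mirroring whenever the partition check fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi, cKDTree

from .config import AssayConfig, ConfigurationError
from .io import RegionOfInterest

log = logging.getLogger(__name__)


@dataclass
class VoronoiCell:
    """Voronoi cell of one (deduplicated) localization, clipped to the ROI."""

    loc_id: int  # representative localization id
    point_xy: tuple[float, float]
    vertices: np.ndarray  # (k, 2) polygon vertices
    area: float  # nm²
    neighbor_ids: set[int] = field(default_factory=set)
    member_ids: tuple[int, ...] = ()  # all loc ids at this coordinate
    touches_boundary: bool = False

    @property
    def multiplicity(self) -> int:
        return len(self.member_ids)


@dataclass
class EvCluster:
    """A detected candidate vesicle."""

    cluster_id: int
    roi_id: str
    member_loc_ids: frozenset[int]
    n_loc: int
    centroid_xy: tuple[float, float]
    touches_boundary: bool


@dataclass
class ClusterExtraction:
    clusters: list[EvCluster]
    n_boundary_excluded: int = 0
    n_below_min: int = 0


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _region_geometry(
    vor: Voronoi, n: int
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, np.ndarray] | None:
    """Vectorized per-region polygons, areas and bounding boxes.

    Returns ``None`` when any of the first ``n`` regions is unbounded or
    degenerate (signal to retry with a wider mirror margin).
    """
    regions = [vor.regions[vor.point_region[i]] for i in range(n)]
    lens = np.array([len(r) for r in regions])
    if (lens < 3).any():
        return None
    flat = np.concatenate(regions)
    if flat.min() < 0:
        return None
    starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
    v = vor.vertices[flat]
    nxt = np.arange(flat.size) + 1
    nxt[np.cumsum(lens) - 1] = starts  # wrap each polygon
    cross = v[:, 0] * v[nxt, 1] - v[nxt, 0] * v[:, 1]
    areas = 0.5 * np.abs(np.add.reduceat(cross, starts))
    mins = np.column_stack(
        (np.minimum.reduceat(v[:, 0], starts), np.minimum.reduceat(v[:, 1], starts))
    )
    maxs = np.column_stack(
        (np.maximum.reduceat(v[:, 0], starts), np.maximum.reduceat(v[:, 1], starts))
    )
    polys = [v[s : s + k] for s, k in zip(starts, lens)]
    return polys, areas, mins, maxs


def _mirror(pts: np.ndarray, width: float, height: float, margin: float) -> np.ndarray:
    """Reflect points within ``margin`` of each edge across that edge."""
    parts = [pts]
    for axis, limit in ((0, width), (1, height)):
        for lo in (True, False):
            sel = pts[:, axis] <= margin if lo else pts[:, axis] >= limit - margin
            refl = pts[sel].copy()
            refl[:, axis] = -refl[:, axis] if lo else 2 * limit - refl[:, axis]
            parts.append(refl)
    return np.vstack(parts)


def tessellate(roi: RegionOfInterest, rel_tol: float = 1e-9) -> list[VoronoiCell]:
    """Tessellate one ROI into Voronoi cells clipped to its rectangle.

    Exact duplicate coordinates are merged beforehand (the tessellation is
    undefined for coincident seeds) with their localization ids recorded as
    the cell's ``member_ids`` — multiplicity counts toward cluster size.
    Degenerate geometry (fewer than 4 distinct points, or all collinear)
    returns an empty list with a warning.
    """
    width, height = roi.width, roi.height
    pts_all = roi.locs[["x", "y"]].to_numpy(dtype=float)
    ids_all = roi.locs["id"].to_numpy()
    if len(pts_all) < 4:
        log.warning("%s: %d localizations, too few to tessellate", roi.roi_id, len(pts_all))
        return []

    uniq, inverse = np.unique(pts_all, axis=0, return_inverse=True)
    members: list[list[int]] = [[] for _ in range(len(uniq))]
    for row, cell_idx in enumerate(inverse):
        members[cell_idx].append(int(ids_all[row]))
    n = len(uniq)
    if n < 4 or np.linalg.matrix_rank(uniq - uniq.mean(axis=0)) < 2:
        log.warning("%s: degenerate point geometry, no tessellation", roi.roi_id)
        return []

    # data-driven mirror margin: a Voronoi cell reaches edge position s only
    # for the seed nearest to s, which lies within dist(s, seeds) of the
    # edge — so mirroring everything within twice the largest such distance
    # (plus sampling slack) clips every boundary cell exactly
    tree = cKDTree(uniq)
    k = 512
    xs = np.linspace(0.0, width, k)
    ys = np.linspace(0.0, height, k)
    edge_samples = np.concatenate(
        [
            np.column_stack((xs, np.full(k, 0.0))),
            np.column_stack((xs, np.full(k, height))),
            np.column_stack((np.full(k, 0.0), ys)),
            np.column_stack((np.full(k, width), ys)),
        ]
    )
    step = max(width, height) / (k - 1)
    max_reach = float(tree.query(edge_samples)[0].max())
    base = 2.1 * (max_reach + step)
    for margin in (base, max(width, height)):
        mirrored = _mirror(uniq, width, height, margin)
        vor = Voronoi(mirrored)
        geom = _region_geometry(vor, n)
        if geom is None:
            continue
        polys, areas, mins, maxs = geom
        if abs(areas.sum() - width * height) <= rel_tol * width * height:
            break
    else:
        raise RuntimeError(f"{roi.roi_id}: Voronoi partition failed the area check")

    tol = 1e-6 * max(width, height)
    touches_arr = (
        (mins[:, 0] < tol)
        | (maxs[:, 0] > width - tol)
        | (mins[:, 1] < tol)
        | (maxs[:, 1] > height - tol)
    )
    cells = [
        VoronoiCell(
            loc_id=members[i][0],
            point_xy=(float(uniq[i, 0]), float(uniq[i, 1])),
            vertices=polys[i],
            area=float(areas[i]),
            member_ids=tuple(members[i]),
            touches_boundary=bool(touches_arr[i]),
        )
        for i in range(n)
    ]

    # adjacency: ridges between two original points with positive-length
    # shared edge (vertex-only contact does not connect)
    eps = 1e-9 * max(width, height)
    rp = np.asarray(vor.ridge_points)
    rv = np.asarray(vor.ridge_vertices)
    mask = (rp < n).all(axis=1) & (rv >= 0).all(axis=1)
    seg = vor.vertices[rv[mask, 0]] - vor.vertices[rv[mask, 1]]
    positive = np.hypot(seg[:, 0], seg[:, 1]) > eps
    for p, q in rp[mask][positive]:
        cells[p].neighbor_ids.add(cells[q].loc_id)
        cells[q].neighbor_ids.add(cells[p].loc_id)
    return cells


def threshold_density(cells: list[VoronoiCell], alpha: float) -> set[int]:
    """Retain localizations by first-rank Voronoi density.

    A localization is kept when the median area over its own cell and its
    edge-sharing neighbors is at most ``alpha`` times the mean cell area of
    the ROI (equivalently, when its neighborhood density is at least
    ``1/alpha`` times the ROI average density). The neighborhood median is
    robust both ways: a cluster-rim cell flaring into empty space is kept
    because most of its neighbors are dense, while a background cell
    brushing a cluster is dropped because most of its neighbors are sparse.
    Returns the retained representative loc_ids. Monotone in ``alpha``: a
    smaller threshold retains a subset of a larger one.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha: must be > 0")
    if not cells:
        return set()
    index = {c.loc_id: i for i, c in enumerate(cells)}
    areas = np.array([c.area for c in cells])
    threshold = alpha * float(areas.mean())
    retained = set()
    for c in cells:
        hood = areas[[index[c.loc_id]] + [index[j] for j in c.neighbor_ids]]
        hood.sort()
        if hood[(len(hood) - 1) // 2] <= threshold:  # lower median
            retained.add(c.loc_id)
    # single closing pass: annex cells most of whose neighbors are retained
    # (recovers cluster-edge localizations without letting sparse background
    # percolate — an isolated annexed background cell stays a singleton)
    annexed = {
        c.loc_id
        for c in cells
        if c.loc_id not in retained
        and c.neighbor_ids
        and sum(j in retained for j in c.neighbor_ids) >= 0.5 * len(c.neighbor_ids)
    }
    return retained | annexed


def extract_clusters(
    retained: set[int],
    cells: list[VoronoiCell],
    M: int,
    exclude_boundary: bool = True,
    roi_id: str = "",
    width: float | None = None,
    height: float | None = None,
    max_edge_nm: float | None = None,
    boundary_guard_nm: float = 100.0,
) -> ClusterExtraction:
    """Group retained localizations into candidate vesicles.

    Clusters are connected components of the retained set under shared-edge
    adjacency; when ``max_edge_nm`` is given, adjacencies between
    localizations farther apart than that are cut (two points separated by
    more than the linear scale of the density threshold cannot belong to one
    vesicle, which stops stray retained background points from bridging
    distinct clusters). Components with fewer than ``M`` member
    localizations (duplicate multiplicity included) are discarded, as are —
    when ``exclude_boundary`` — clusters whose point cloud reaches within
    ``boundary_guard_nm`` of the ROI rectangle edge and may therefore be
    truncated (requires ``width``/``height``; without them the test falls
    back to member-cell contact with the edge). Centroids are the
    arithmetic mean of member positions.
    """
    sub = [c for c in cells if c.loc_id in retained]
    if not sub:
        return ClusterExtraction([])
    index = {c.loc_id: i for i, c in enumerate(sub)}
    rows, cols = [], []
    for i, c in enumerate(sub):
        for nb in c.neighbor_ids:
            j = index.get(nb)
            if j is None:
                continue
            if max_edge_nm is not None:
                d = sub[j]
                if np.hypot(
                    c.point_xy[0] - d.point_xy[0], c.point_xy[1] - d.point_xy[1]
                ) > max_edge_nm:
                    continue
            rows.append(i)
            cols.append(j)
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(sub), len(sub))
    )
    n_comp, labels = connected_components(adj, directed=False)

    clusters: list[EvCluster] = []
    n_boundary = n_small = 0
    for comp in range(n_comp):
        comp_cells = [sub[i] for i in np.flatnonzero(labels == comp)]
        n_loc = sum(c.multiplicity for c in comp_cells)
        if n_loc < M:
            n_small += 1
            continue
        if width is not None and height is not None:
            pts = np.array([c.point_xy for c in comp_cells])
            touches = bool(
                (pts[:, 0] < boundary_guard_nm).any()
                or (pts[:, 0] > width - boundary_guard_nm).any()
                or (pts[:, 1] < boundary_guard_nm).any()
                or (pts[:, 1] > height - boundary_guard_nm).any()
            )
        else:
            touches = any(c.touches_boundary for c in comp_cells)
        if exclude_boundary and touches:
            n_boundary += 1
            continue
        w = np.array([c.multiplicity for c in comp_cells], dtype=float)
        xy = np.array([c.point_xy for c in comp_cells])
        centroid = tuple((xy * w[:, None]).sum(axis=0) / w.sum())
        member_ids = frozenset(i for c in comp_cells for i in c.member_ids)
        clusters.append(
            EvCluster(
                cluster_id=len(clusters),
                roi_id=roi_id,
                member_loc_ids=member_ids,
                n_loc=n_loc,
                centroid_xy=(float(centroid[0]), float(centroid[1])),
                touches_boundary=touches,
            )
        )
    if n_boundary:
        log.info("%s: %d boundary-touching clusters excluded", roi_id, n_boundary)
    # deterministic ordering regardless of input row order
    clusters.sort(key=lambda c: (c.centroid_xy[0], c.centroid_xy[1]))
    for k, c in enumerate(clusters):
        c.cluster_id = k
    return ClusterExtraction(clusters, n_boundary, n_small)


def detect_clusters(roi: RegionOfInterest, cfg: AssayConfig) -> ClusterExtraction:
    """Full per-ROI detection: tessellate → density threshold → components."""
    cells = tessellate(roi)
    if not cells:
        return ClusterExtraction([])
    retained = threshold_density(cells, cfg.alpha)
    mean_area = roi.width * roi.height / len(cells)
    return extract_clusters(
        retained,
        cells,
        cfg.M,
        cfg.exclude_boundary_clusters,
        roi.roi_id,
        width=roi.width,
        height=roi.height,
        max_edge_nm=float(np.sqrt(cfg.alpha * mean_area)),
        boundary_guard_nm=cfg.boundary_guard_nm,
    )
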