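"""First-generation hull/cluster home-range estimators.

All three estimators here (k-LoCoH, single-linkage cluster analysis, and the
characteristic hull) share one structure: they build an ordered sequence of
small polygons, progressively union them, and read home-range isopleths off
the percent of relocations covered by each prefix of the union.  The minimum
convex polygon (MCP) is the common limit: LoCoH with k = n, and the
characteristic hull with no triangles removed, both collapse to the MCP.

For AUC scoring, every cell of the reference grid is assigned
``100 - (smallest percent-of-points level whose union covers the cell
center)``, so more intensely used cells rank higher; cells outside the 100%
region score -inf (always ranked below any covered cell).  AUC only uses the
ranking, so this monotone mapping is all that is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .core_io import CellScoreField, DegenerateGeometryError, ReferenceGrid

__all__ = ["HullSequence", "mcp", "locoh_k", "slca", "char_hull"]


@dataclass
class HullSequence:
    """Ordered hulls with the percent of points covered after each union step.

    ``geoms[i]`` is the polygon added at step i and ``percents[i]`` the
    percent of relocations covered by the union of steps 0..i.  Percents are
    non-decreasing and end at 100.
    """

    geoms: list
    percents: np.ndarray
    source_tag: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.percents = np.asarray(self.percents, dtype=float)
        if len(self.geoms) != self.percents.size:
            raise ValueError("geoms and percents must align")
        if np.any(np.diff(self.percents) < -1e-9):
            raise ValueError("percents must be non-decreasing")
        if self.percents.size and abs(self.percents[-1] - 100.0) > 1e-9:
            raise ValueError("final percent must be 100")

    def union_at(self, percent: float):
        """Union of the shortest prefix of hulls covering >= *percent* points.

        The 100% level is the union of *all* hulls (for the characteristic
        hull this is the full triangulation, i.e. the MCP), not just the
        shortest prefix touching every point.
        """
        if percent >= 100.0 - 1e-12:
            return unary_union(self.geoms)
        idx = int(np.searchsorted(self.percents, percent - 1e-9, side="left"))
        idx = min(idx, len(self.geoms) - 1)
        return unary_union(self.geoms[: idx + 1])


def _hull_of(points: np.ndarray):
    """Convex hull as a shapely geometry; degenerate sets give lines/points."""
    return MultiPoint(points).convex_hull


def mcp(points) -> Polygon:
    """Minimum convex polygon of >= 3 non-collinear points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("MCP needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set for MCP: {exc}") from exc
    verts = pts[hull.vertices]
    return Polygon(verts)


def _score_from_sequence(seq: HullSequence, grid: ReferenceGrid) -> CellScoreField:
    """Rasterize a hull sequence into per-cell scores.

    A cell's covering level is the percent attached to the first step whose
    geometry covers its center (unions only grow, so the first covering step
    gives the smallest covering level).  Score = 100 - level; uncovered cells
    get -inf.
    """
    cx, cy = grid.cell_centers()
    cx = cx.ravel()
    cy = cy.ravel()
    pts = shapely.points(np.column_stack([cx, cy]))
    score = np.full(cx.size, -np.inf)
    unassigned = np.ones(cx.size, dtype=bool)
    for geom, pct in zip(seq.geoms, seq.percents):
        if geom.is_empty:
            continue
        minx, miny, maxx, maxy = geom.bounds
        cand = unassigned & (cx >= minx) & (cx <= maxx) & (cy >= miny) & (cy <= maxy)
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            continue
        covered = shapely.covers(geom, pts[idx])
        hit = idx[covered]
        score[hit] = 100.0 - pct
        unassigned[hit] = False
    return CellScoreField(
        grid=grid,
        score=score.reshape(grid.shape),
        estimator_tag=seq.source_tag,
        params=dict(seq.params),
    )


def _coverage_order(geoms, pts: np.ndarray) -> np.ndarray:
    """Percent of *pts* covered after each progressive union step."""
    n = pts.shape[0]
    covered = np.zeros(n, dtype=bool)
    pgeoms = shapely.points(pts)
    percents = np.empty(len(geoms))
    for i, geom in enumerate(geoms):
        if not geom.is_empty:
            minx, miny, maxx, maxy = geom.bounds
            cand = (
                ~covered
                & (pts[:, 0] >= minx)
                & (pts[:, 0] <= maxx)
                & (pts[:, 1] >= miny)
                & (pts[:, 1] <= maxy)
            )
            idx = np.flatnonzero(cand)
            if idx.size:
                covered[idx[shapely.covers(geom, pgeoms[idx])]] = True
        percents[i] = 100.0 * covered.sum() / n
    return percents


# ---------------------------------------------------------------------------
# k-LoCoH
# ---------------------------------------------------------------------------


def default_k(n: int) -> int:
    """k = round(sqrt(n)), floored at 3 (the smallest hull-forming set)."""
    return max(3, int(round(np.sqrt(n))))


def locoh_k(points, k: int | None = None, grid: ReferenceGrid | None = None):
    """k-nearest-neighbour local convex hull estimator.

    For each relocation, the convex hull of the point plus its k-1 nearest
    neighbours is built; hulls are sorted by area ascending (ties by point
    index) and progressively unioned.  Duplicate points are retained:
    zero-area hulls are legal and sort first.

    Returns ``(HullSequence, CellScoreField or None)``.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if k is None:
        k = default_k(n)
    if k < 3:
        raise ValueError("k must be >= 3")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    tree = cKDTree(pts)
    _, nbrs = tree.query(pts, k=k)
    nbrs = np.atleast_2d(nbrs)
    hulls = [_hull_of(pts[nbrs[i]]) for i in range(n)]
    areas = np.array([h.area for h in hulls])
    order = np.lexsort((np.arange(n), areas))
    geoms = [hulls[i] for i in order]
    percents = _coverage_order(geoms, pts)
    seq = HullSequence(
        geoms=geoms, percents=percents, source_tag="locoh", params={"k": k}
    )
    fld = _score_from_sequence(seq, grid) if grid is not None else None
    return seq, fld


# ---------------------------------------------------------------------------
# Single-linkage cluster analysis (SLCA)
# ---------------------------------------------------------------------------


class _Top3:
    """Keep the 3 smallest values seen, supporting merge and insert."""

    __slots__ = ("vals",)

    def __init__(self, vals=()):
        self.vals = sorted(vals)[:3]

    def insert(self, v):
        vals = self.vals
        if len(vals) < 3:
            vals.append(v)
            vals.sort()
        elif v < vals[2]:
            vals[2] = v
            vals.sort()

    def merged(self, other):
        t = _Top3()
        t.vals = sorted(self.vals + other.vals)[:3]
        return t

    def mean(self, limit=3):
        take = self.vals[: min(limit, len(self.vals))]
        return sum(take) / len(take)


def _slca_events(pts: np.ndarray):
    """Run the SLCA clustering loop; return the event trace.

    Moves, costed and compared globally each step (cheapest wins, ties broken
    by move type join < merge < seed, then by index):

    * ``seed``  — start a new cluster from an unassigned point and its 2
      nearest unassigned neighbours; cost = mean pairwise distance of the
      triple.  The first seed is the global minimum-mean-distance triple of
      this family.
    * ``join``  — attach an unassigned point to a cluster; cost = mean
      distance from the point to its min(3, |cluster|) nearest members.
    * ``merge`` — fuse two clusters; cost = mean of the 3 smallest
      inter-cluster point distances.

    The loop ends when every point is assigned and one cluster remains.
    """
    n = pts.shape[0]
    if n < 3:
        raise ValueError("SLCA needs at least 3 points")
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    unassigned_mask = np.ones(n, dtype=bool)
    clusters: dict[int, list[int]] = {}
    col_of: dict[int, int] = {}  # cluster id -> column slot in the arrays below
    cap = 8
    # 3 smallest distances from each point to each cluster (inf padded)
    top3 = np.full((n, cap, 3), np.inf)
    jcost = np.full((n, cap), np.inf)  # mean of the 3 smallest
    # 3 smallest inter-cluster distances per cluster-pair slot, and their mean
    pair3 = np.full((cap, cap, 3), np.inf)
    mcost = np.full((cap, cap), np.inf)
    cid_at = np.full(cap, -1)  # cluster id occupying each slot (-1 free)
    next_id = 0
    n_alloc = 0
    _free_cols: list[int] = []
    events = []

    def best_seed():
        """Cheapest (cost, point triple) among each unassigned point + its
        2 nearest unassigned neighbours."""
        idx = np.flatnonzero(unassigned_mask)
        if idx.size < 3:
            return None
        tree = cKDTree(pts[idx])
        _, nn = tree.query(pts[idx], k=3)
        nn = np.atleast_2d(nn)
        a_, b_, c_ = idx[nn[:, 0]], idx[nn[:, 1]], idx[nn[:, 2]]
        costs = (dist[a_, b_] + dist[a_, c_] + dist[b_, c_]) / 3.0
        cmin = costs.min()
        best = None
        for k in np.flatnonzero(costs == cmin):
            trip = tuple(sorted((int(a_[k]), int(b_[k]), int(c_[k]))))
            if best is None or trip < best[1]:
                best = (float(cmin), trip)
        return best

    def _pair_insert(ca, cb, vals):
        merged = np.sort(np.concatenate([pair3[ca, cb], vals]))[:3]
        pair3[ca, cb] = pair3[cb, ca] = merged
        finite = merged[merged < np.inf]
        mcost[ca, cb] = mcost[cb, ca] = finite.mean() if finite.size else np.inf

    def add_point(p, cid):
        """Bookkeeping for point *p* entering cluster *cid*."""
        unassigned_mask[p] = False
        col = col_of[cid]
        d = dist[:, p]
        t = top3[:, col, :]
        # insert d into each row's sorted 3-list (vectorized)
        repl = d < t[:, 2]
        if np.any(repl):
            t[repl, 2] = d[repl]
            top3[:, col, :] = np.sort(t, axis=1)
        jcost[:, col] = top3[:, col, :].mean(axis=1)
        for other, members in clusters.items():
            if other == cid:
                continue
            dm = dist[p, members]
            k = min(2, dm.size - 1)
            _pair_insert(col, col_of[other], np.partition(dm, k)[: k + 1])
        clusters[cid].append(p)

    def new_slot():
        nonlocal top3, jcost, pair3, mcost, cid_at, cap, n_alloc
        if n_alloc >= cap:
            top3 = np.concatenate([top3, np.full((n, cap, 3), np.inf)], axis=1)
            jcost = np.concatenate([jcost, np.full((n, cap), np.inf)], axis=1)
            p3 = np.full((2 * cap, 2 * cap, 3), np.inf)
            p3[:cap, :cap] = pair3
            pair3 = p3
            mc = np.full((2 * cap, 2 * cap), np.inf)
            mc[:cap, :cap] = mcost
            mcost = mc
            cid_at = np.concatenate([cid_at, np.full(cap, -1)])
            cap *= 2
        n_alloc += 1
        return n_alloc - 1

    while np.any(unassigned_mask) or len(clusters) > 1:
        best_key = None
        action = None
        if clusters:
            cids = sorted(clusters)
            cols = [col_of[c] for c in cids]
            sub = jcost[np.ix_(unassigned_mask, cols)]
            if sub.size:
                flat = int(np.argmin(sub))
                qi, ci = divmod(flat, len(cols))
                q = int(np.flatnonzero(unassigned_mask)[qi])
                best_key = (float(sub[qi, ci]), 0, (q, cids[ci]))
                action = ("join", q, cids[ci])
        if len(clusters) > 1:
            mmin = mcost.min()
            if np.isfinite(mmin):
                ia, ib = np.unravel_index(int(np.argmin(mcost)), mcost.shape)
                # resolve float ties on the cluster-id pair ordering
                ties = np.argwhere(mcost == mmin)
                pair = min(
                    tuple(sorted((int(cid_at[i]), int(cid_at[j]))))
                    for i, j in ties
                )
                key = (float(mmin), 1, pair)
                if best_key is None or key < best_key:
                    best_key = key
                    action = ("merge", pair[0], pair[1])
        seed = best_seed()
        if seed is not None:
            cost, trip = seed
            key = (cost, 2, trip)
            if best_key is None or key < best_key:
                best_key = key
                action = ("seed", trip)
        if action is None:
            break
        if action[0] == "join":
            _, q, cid = action
            add_point(q, cid)
            events.append(("join", q, cid))
        elif action[0] == "merge":
            _, a, b = action
            ca, cb = col_of[a], col_of[b]
            # fold b's structures into a's
            merged = np.sort(
                np.concatenate([top3[:, ca, :], top3[:, cb, :]], axis=1), axis=1
            )[:, :3]
            top3[:, ca, :] = merged
            jcost[:, ca] = merged.mean(axis=1)
            top3[:, cb, :] = np.inf
            jcost[:, cb] = np.inf
            for other in clusters:
                if other in (a, b):
                    continue
                co = col_of[other]
                _pair_insert(ca, co, pair3[cb, co])
                pair3[cb, co] = pair3[co, cb] = np.inf
                mcost[cb, co] = mcost[co, cb] = np.inf
            pair3[ca, cb] = pair3[cb, ca] = np.inf
            mcost[ca, cb] = mcost[cb, ca] = np.inf
            cid_at[cb] = -1
            _free_cols.append(col_of.pop(b))
            clusters[a].extend(clusters.pop(b))
            events.append(("merge", a, b))
        else:
            trip = action[1]
            cid = next_id
            next_id += 1
            clusters[cid] = []
            col = _free_cols.pop() if _free_cols else new_slot()
            col_of[cid] = col
            cid_at[col] = cid
            top3[:, col, :] = np.inf
            jcost[:, col] = np.inf
            pair3[col, :, :] = pair3[:, col, :] = np.inf
            mcost[col, :] = mcost[:, col] = np.inf
            for p in trip:
                add_point(p, cid)
            events.append(("seed", trip, cid))
    return events


def slca(points, grid: ReferenceGrid | None = None):
    """Single-linkage cluster analysis estimator.

    Clusters are grown from a seed triple with minimum mean pairwise distance;
    each step makes the globally cheapest assignment (see ``_slca_events``).
    The isopleth at P% is the union of convex hulls of the clusters restricted
    to the first ceil(P% * n) assigned points, so the hull-sequence steps are
    the per-event cluster hulls tagged with the percent of points assigned.

    Returns ``(HullSequence, CellScoreField or None)``.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    events = _slca_events(pts)
    members: dict[int, list[int]] = {}
    geoms = []
    percents = []
    assigned = 0
    for ev in events:
        if ev[0] == "seed":
            _, trip, cid = ev
            members[cid] = list(trip)
            assigned += 3
            changed = cid
        elif ev[0] == "join":
            _, q, cid = ev
            members[cid].append(q)
            assigned += 1
            changed = cid
        else:
            _, a, b = ev
            members[a].extend(members.pop(b))
            changed = a
        geoms.append(_hull_of(pts[np.array(members[changed])]))
        percents.append(100.0 * assigned / n)
    percents = np.asarray(percents)
    seq = HullSequence(geoms=geoms, percents=percents, source_tag="slca")
    fld = _score_from_sequence(seq, grid) if grid is not None else None
    return seq, fld


# ---------------------------------------------------------------------------
# Characteristic hull (Delaunay)
# ---------------------------------------------------------------------------


def char_hull(points, grid: ReferenceGrid | None = None):
    """Characteristic hull estimator from the Delaunay triangulation.

    Triangles are ordered smallest to largest (ties by simplex index); the
    isopleth at P% is the union of the shortest prefix of triangles covering
    >= P% of the points, and the 100% level (all triangles) equals the MCP.

    Returns ``(HullSequence, CellScoreField or None)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("characteristic hull needs >= 3 points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    simplices = tri.simplices
    ntri = simplices.shape[0]
    p = pts[simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    order = np.lexsort((np.arange(ntri), areas))
    n = pts.shape[0]
    # coverage: a triangulation vertex is covered when its first incident
    # triangle enters; merged/coplanar points via their containing simplex
    used = np.unique(simplices)
    is_vertex = np.zeros(n, dtype=bool)
    is_vertex[used] = True
    incident_step = np.full(n, np.inf)
    step_of_tri = np.empty(ntri, dtype=int)
    step_of_tri[order] = np.arange(ntri)
    for t_idx in range(ntri):
        s = step_of_tri[t_idx]
        for v in simplices[t_idx]:
            if s < incident_step[v]:
                incident_step[v] = s
    non_vertex = np.flatnonzero(~is_vertex)
    if non_vertex.size:
        simp = tri.find_simplex(pts[non_vertex])
        for pt_i, t_idx in zip(non_vertex, simp):
            if t_idx >= 0:
                incident_step[pt_i] = step_of_tri[t_idx]
    # percent covered after each step
    counts = np.zeros(ntri)
    finite = np.isfinite(incident_step)
    np.add.at(counts, incident_step[finite].astype(int), 1)
    percents = 100.0 * np.cumsum(counts) / n
    percents[-1] = 100.0
    geoms = [Polygon(pts[simplices[i]]) for i in order]
    seq = HullSequence(geoms=geoms, percents=percents, source_tag="char")
    fld = _score_from_sequence(seq, grid) if grid is not None else None
    return seq, fld
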