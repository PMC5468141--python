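"""Circuit-theory connectivity on conductance rasters.

Cells are electrical nodes joined to their neighbors by resistors; for a
unit current injected between two terminal regions, per-cell current
density is proportional to the probability that a random walker moving
from source to destination passes through the cell, and concentrates at
pinch points where alternative routes are scarce.

The omnidirectional ("wall-to-wall") protocol avoids arbitrary habitat
cores: the map rectangle's west and east single-cell-wide edge strips act
as one source/ground pair, north and south as the other, and the two
current maps are summed. Cells between the rectangle and the irregular
study boundary are first filled with draws from a normal distribution
matching the observed conductance distribution, letting current percolate
evenly across the boundary without edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import cg, factorized

from .raster import RasterGrid

SQRT2 = np.sqrt(2.0)


@dataclass
class ConductanceGraph:
    """Resistor network over valid raster cells.

    ``node_of`` maps (row, col) to node index (-1 for excluded cells);
    edges hold (a, b, conductance). Edge conductance is the arithmetic
    mean of the two cell conductances, additionally divided by sqrt(2)
    for diagonal neighbors (center-to-center distance).
    """

    node_of: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray
    edges_g: np.ndarray
    n_nodes: int
    shape: tuple[int, int]
    neighborhood: int


@dataclass
class CurrentMap:
    """Per-cell current density for a unit injected current."""

    current: RasterGrid
    run: str                      # "EW", "NS" or "SUM"
    effective_resistance: float | None = None


def build_graph(conductance: RasterGrid, neighborhood: int = 8
                ) -> ConductanceGraph:
    """Resistor network from a strictly positive conductance raster."""
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    v = conductance.values
    valid = conductance.mask
    if not valid.any():
        raise ValueError("all-nodata conductance grid")
    if (v[valid] <= 0).any():
        raise ValueError("conductances must be strictly positive")
    nr, nc = v.shape
    node_of = np.full((nr, nc), -1, dtype=int)
    node_of[valid] = np.arange(valid.sum())

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        offsets += [(1, 1, SQRT2), (1, -1, SQRT2)]
    ea, eb, eg = [], [], []
    for dr, dc, dist in offsets:
        r0s, r0e = max(0, -dr), min(nr, nr - dr)
        c0s, c0e = max(0, -dc), min(nc, nc - dc)
        a = node_of[r0s:r0e, c0s:c0e]
        b = node_of[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        va = v[r0s:r0e, c0s:c0e]
        vb = v[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        ok = (a >= 0) & (b >= 0)
        ea.append(a[ok])
        eb.append(b[ok])
        eg.append(0.5 * (va[ok] + vb[ok]) / dist)
    return ConductanceGraph(node_of, np.concatenate(ea), np.concatenate(eb),
                            np.concatenate(eg), int(valid.sum()), (nr, nc),
                            neighborhood)


def _solve_laplacian(L: sparse.csc_matrix, b: np.ndarray,
                     solver: str = "direct") -> np.ndarray:
    if solver == "direct":
        try:
            return factorized(L)(b)
        except RuntimeError:
            solver = "cg"
    x, info = cg(L, b, rtol=1e-12, atol=0.0, maxiter=20000)
    if info != 0:
        raise RuntimeError(f"conjugate-gradient solver failed (info={info})")
    return x


def solve_strip_pair(graph: ConductanceGraph, source_cells: np.ndarray,
                     ground_cells: np.ndarray, injected: float = 1.0,
                     solver: str = "direct") -> tuple[np.ndarray, float]:
    """Current density for unit current between two collapsed terminals.

    Source and ground cell sets (boolean masks over the raster) are each
    collapsed to a supernode; the ground supernode is fixed at 0 V and
    ``injected`` amps enter at the source supernode. Returns the per-cell
    current array (half the summed absolute edge currents at each cell)
    and the effective resistance between the terminals.
    """
    src = np.asarray(source_cells, dtype=bool)
    gnd = np.asarray(ground_cells, dtype=bool)
    if not src.any() or not gnd.any():
        raise ValueError("empty terminal region")
    if (src & gnd).any():
        raise ValueError("source and ground overlap")

    # map graph nodes to solver unknowns: ordinary cells keep distinct
    # unknowns, source cells share one supernode, ground is eliminated
    node_of = graph.node_of
    n = graph.n_nodes
    group = np.full(n, -1, dtype=int)       # solver index per graph node
    src_nodes = node_of[src & (node_of >= 0)]
    gnd_nodes = node_of[gnd & (node_of >= 0)]
    if len(src_nodes) == 0 or len(gnd_nodes) == 0:
        raise ValueError("terminal region contains no valid cells")
    is_src = np.zeros(n, dtype=bool); is_src[src_nodes] = True
    is_gnd = np.zeros(n, dtype=bool); is_gnd[gnd_nodes] = True
    ordinary = ~(is_src | is_gnd)
    group[ordinary] = np.arange(ordinary.sum())
    source_idx = int(ordinary.sum())
    group[is_src] = source_idx
    n_unknown = source_idx + 1

    a = group[graph.edges_a]
    b = group[graph.edges_b]
    g = graph.edges_g
    # assemble reduced Laplacian (ground rows/cols dropped)
    keep = ~((a == -1) & (b == -1))
    a, b, g = a[keep], b[keep], g[keep]
    rows, cols, vals = [], [], []
    both = (a >= 0) & (b >= 0) & (a != b)
    rows += [a[both], b[both], a[both], b[both]]
    cols += [b[both], a[both], a[both], b[both]]
    vals += [-g[both], -g[both], g[both], g[both]]
    # edges internal to the source supernode contribute nothing
    one = ((a >= 0) & (b == -1))
    rows.append(a[one]); cols.append(a[one]); vals.append(g[one])
    one = ((b >= 0) & (a == -1))
    rows.append(b[one]); cols.append(b[one]); vals.append(g[one])
    L = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown))

    # source must reach ground once each terminal is collapsed, else the
    # reduced Laplacian is singular; chain the terminal cells with virtual
    # edges so a strip spanning several components still counts as one node
    va = np.concatenate([graph.edges_a, src_nodes[:-1], gnd_nodes[:-1]])
    vb = np.concatenate([graph.edges_b, src_nodes[1:], gnd_nodes[1:]])
    adj = sparse.coo_matrix((np.ones(len(va)), (va, vb)), shape=(n, n))
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    if n_comp > 1 and labels[src_nodes[0]] != labels[gnd_nodes[0]]:
        raise RuntimeError("source and ground are not connected")

    rhs = np.zeros(n_unknown)
    rhs[source_idx] = injected
    try:
        volt = _solve_laplacian(L, rhs, solver)
    except RuntimeError as exc:
        raise RuntimeError("terminals appear disconnected from the graph"
                           ) from exc
    if not np.isfinite(volt).all():
        raise RuntimeError("singular system: terminals disconnected")

    # node voltages: ground at 0
    v_node = np.zeros(n)
    v_node[ordinary] = volt[group[ordinary]]
    v_node[is_src] = volt[source_idx]

    # per-cell current: half the sum of |edge current| over incident edges
    cell_current = np.zeros(n)
    dv = np.abs(v_node[graph.edges_a] - v_node[graph.edges_b]) * graph.edges_g
    np.add.at(cell_current, graph.edges_a, dv)
    np.add.at(cell_current, graph.edges_b, dv)
    cell_current *= 0.5

    out = np.zeros(graph.shape)
    valid = node_of >= 0
    out[valid] = cell_current[node_of[valid]]
    r_eff = float(volt[source_idx] / injected)
    return out, r_eff


def random_fill(conductance: RasterGrid, boundary_mask: np.ndarray,
                seed: int, epsilon: float = 1e-6) -> RasterGrid:
    """Fill cells outside the study boundary with normal draws.

    Draws come from Normal(mean, SD) of the in-boundary conductances,
    truncated to (epsilon, max] to keep the network strictly positive.
    In-boundary cells are untouched.
    """
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if not boundary_mask.any():
        raise ValueError("empty in-boundary region")
    inside = conductance.values[boundary_mask]
    mu, sd, hi = float(inside.mean()), float(inside.std()), float(inside.max())
    rng = np.random.default_rng(seed)
    out = conductance.values.copy()
    fill = ~boundary_mask
    n_fill = int(fill.sum())
    if n_fill:
        draws = rng.normal(mu, sd, size=n_fill)
        out[fill] = np.clip(draws, epsilon, hi)
    return conductance.like(out)


def edge_strips(shape: tuple[int, int]):
    """Boolean masks of the four single-cell-wide rectangle edge strips."""
    nr, nc = shape
    west = np.zeros(shape, dtype=bool); west[:, 0] = True
    east = np.zeros(shape, dtype=bool); east[:, -1] = True
    north = np.zeros(shape, dtype=bool); north[0, :] = True
    south = np.zeros(shape, dtype=bool); south[-1, :] = True
    return west, east, north, south


def omnidirectional(conductance: RasterGrid, boundary_mask: np.ndarray,
                    seed: int, neighborhood: int = 8,
                    solver: str = "direct", fill: str = "normal"
                    ) -> dict[str, CurrentMap]:
    """Random boundary fill, then summed east-west + north-south runs.

    Returns {"EW", "NS", "SUM"} current maps; the summed map is reported
    on in-boundary cells only (filled cells are zeroed in "SUM" but kept
    in the directional maps for inspection).
    """
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if fill == "normal":
        filled = random_fill(conductance, boundary_mask, seed)
    else:
        filled = conductance
    graph = build_graph(filled, neighborhood)
    west, east, north, south = edge_strips(filled.shape)
    ew, r_ew = solve_strip_pair(graph, west, east, solver=solver)
    ns, r_ns = solve_strip_pair(graph, north, south, solver=solver)
    total = np.where(boundary_mask, ew + ns, 0.0)
    return {"EW": CurrentMap(filled.like(ew), "EW", r_ew),
            "NS": CurrentMap(filled.like(ns), "NS", r_ns),
            "SUM": CurrentMap(filled.like(total), "SUM", None)}
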