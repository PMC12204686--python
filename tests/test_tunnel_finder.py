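"""Grid-probe tunnel detection against shortest-path and flood-fill oracles."""

from collections import deque

import numpy as np
import pytest

from spiroscan.structure_model import Structure, Residue
from spiroscan.synthetic_data import (
    _arc_lengths, make_channel_phantom, sine_centerline, straight_centerline,
)
from spiroscan.trajectory_channeling import point_to_polyline_distance
from spiroscan.tunnel_finder import (
    COST_EPS, Tunnel, build_grid, enclosure_profile, find_tunnel,
    lining_residues, widest_point,
)


def empty_structure():
    return Structure(id="empty", chains={"A": [Residue("A", 1, "", "GLY", [])]})


def at_arc(centerline, s):
    arcs = _arc_lengths(centerline)
    return np.array([np.interp(s, arcs, centerline[:, d]) for d in range(3)])


def path_cost(grid, centerline):
    """Recompute a path's cost from the grid's clearance field."""
    idx = np.rint((centerline - grid.origin) / grid.spacing).astype(int)
    node_cost = 1.0 / (np.maximum(grid.clearance - grid.probe, 0.0) + COST_EPS)
    total = 0.0
    for a, b in zip(idx[:-1], idx[1:]):
        step = np.linalg.norm((b - a).astype(float)) * grid.spacing
        total += step * 0.5 * (node_cost[tuple(a)] + node_cost[tuple(b)])
    return total


def dijkstra_oracle_cost(grid, start_xyz, end_xyz):
    """Independent shortest-path cost via scipy's sparse-graph Dijkstra."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra as sp_dijkstra

    open_grid = grid.open
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    node_cost = (1.0 / (np.maximum(grid.clearance - grid.probe, 0.0) + COST_EPS)).ravel()
    open_flat = open_grid.ravel()
    rows, cols, weights = [], [], []
    idx3 = np.arange(n).reshape(grid.shape)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) <= (0, 0, 0):
                    continue  # undirected graph: each edge once
                src = idx3[max(0, -dx):nx - max(0, dx),
                           max(0, -dy):ny - max(0, dy),
                           max(0, -dz):nz - max(0, dz)].ravel()
                dst = idx3[max(0, dx):nx - max(0, -dx),
                           max(0, dy):ny - max(0, -dy),
                           max(0, dz):nz - max(0, -dz)].ravel()
                ok = open_flat[src] & open_flat[dst]
                src, dst = src[ok], dst[ok]
                step = np.sqrt(dx * dx + dy * dy + dz * dz) * grid.spacing
                w = step * 0.5 * (node_cost[src] + node_cost[dst])
                rows.append(src); cols.append(dst); weights.append(w)
    g = coo_matrix((np.concatenate(weights),
                    (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
    # anchors snap under the package's documented rule (shared, like the grid)
    from spiroscan.tunnel_finder import _snap_to_open
    s = _snap_to_open(grid, start_xyz, "start")
    e = _snap_to_open(grid, end_xyz, "end")
    dist = sp_dijkstra(g, directed=False, indices=idx3[s])
    return dist[idx3[e]]


def flood_fill_exposure_oracle(structure, tunnel, probe=1.4):
    """Independent BFS re-derivation of the per-point enclosure flags."""
    pad = max(4.0, float(tunnel.radii.max()) + 4.0 * tunnel.grid_spacing)
    grid = build_grid(structure, tunnel.grid_spacing, probe, pad=pad,
                      extra_points=tunnel.centerline)
    open_grid = grid.open
    nx, ny, nz = grid.shape
    axes = [grid.origin[d] + np.arange(grid.shape[d]) * grid.spacing for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1)
    in_zone = np.zeros(grid.shape, dtype=bool)
    for point, radius in zip(tunnel.centerline, tunnel.radii):
        d2 = ((nodes - point) ** 2).sum(axis=-1)
        in_zone |= d2 <= radius * radius
    allowed = open_grid & ~in_zone
    seen = np.zeros(grid.shape, dtype=bool)
    q = deque()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if (i in (0, nx - 1) or j in (0, ny - 1) or k in (0, nz - 1)) and allowed[i, j, k]:
                    seen[i, j, k] = True
                    q.append((i, j, k))
    while q:
        i, j, k = q.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    a, b, c = i + di, j + dj, k + dk
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz \
                            and allowed[a, b, c] and not seen[a, b, c]:
                        seen[a, b, c] = True
                        q.append((a, b, c))
    bulk_pts = nodes[seen]
    touch = np.sqrt(3.0) * grid.spacing + 1e-9
    flags = []
    for point, radius in zip(tunnel.centerline, tunnel.radii):
        if len(bulk_pts):
            near = (np.linalg.norm(bulk_pts - point, axis=1) <= radius + touch).any()
        else:
            near = False
        flags.append("exposed" if near else "enclosed")
    return flags


class TestFindTunnel:
    def test_unobstructed_straight_path(self):
        tun = find_tunnel(empty_structure(), np.zeros(3), np.array([10.0, 0, 0]))
        assert tun is not None
        assert tun.length == pytest.approx(10.0, abs=0.6)
        # all points on (snapped) straight segment
        d = point_to_polyline_distance(
            tun.centerline, np.array([[-1.0, 0, 0], [11.0, 0, 0]]))
        assert d.max() <= 0.6

    def test_blocked_by_sealed_wall_reports_no_tunnel(self, sealed_phantom):
        st, truth = sealed_phantom
        cl = np.asarray(truth.truth["centerline"])
        inside = cl[0] + [2.5, 0, 0]
        outside = cl[-1] + [20.0, 0, 0]
        assert find_tunnel(st, inside, outside) is None

    def test_anchor_inside_atom_is_an_error(self, sealed_phantom):
        st, truth = sealed_phantom
        wall_atom = next(st.atoms(["T"]))
        with pytest.raises(Exception, match="inside an atom"):
            find_tunnel(st, wall_atom.coord, wall_atom.coord + [40.0, 0, 0])

    @pytest.mark.parametrize("centerline", [
        straight_centerline(length=30.0),
        sine_centerline(length=36.0, amplitude=2.0, period=72.0),
    ], ids=["straight", "sine"])
    def test_phantom_centerline_recovery_and_dijkstra_oracle(self, centerline):
        st, truth = make_channel_phantom(seed=41, centerline_spec=centerline)
        arcs = _arc_lengths(centerline)
        start, end = at_arc(centerline, 3.0), at_arc(centerline, arcs[-1] - 3.0)
        grid = build_grid(st, 0.6, 1.4, extra_points=np.array([start, end]))
        tun = find_tunnel(st, start, end, grid=grid)
        assert tun is not None
        dev = point_to_polyline_distance(tun.centerline, centerline)
        assert dev.max() <= 0.6  # within one grid spacing everywhere
        # lowest-cost path: total cost equals the independent Dijkstra oracle
        assert path_cost(grid, tun.centerline) == pytest.approx(
            dijkstra_oracle_cost(grid, start, end), rel=1e-9)

    def test_radii_never_exceed_true_clearance(self, sealed_phantom, sealed_tunnel):
        st, _ = sealed_phantom
        coords, radii = st.coordinates()
        for point, r in zip(sealed_tunnel.centerline, sealed_tunnel.radii):
            true_clearance = (np.linalg.norm(coords - point, axis=1) - radii).min()
            assert r <= true_clearance + 1e-9
            assert r >= 1.4  # open nodes admit the probe

    def test_grid_refinement_changes_length_mildly(self):
        st, truth = make_channel_phantom(seed=42, with_decoy=False)
        cl = np.asarray(truth.truth["centerline"])
        start, end = cl[0] + [2.5, 0, 0], cl[-1] - [2.5, 0, 0]
        coarse = find_tunnel(st, start, end, grid_spacing=0.6)
        fine = find_tunnel(st, start, end, grid_spacing=0.3)
        assert coarse is not None and fine is not None
        assert abs(fine.length - coarse.length) / coarse.length < 0.10


class TestLiningResidues:
    def test_phantom_lining_set_matches_design(self, sealed_phantom, sealed_tunnel):
        st, truth = sealed_phantom
        lining = lining_residues(st, sealed_tunnel)
        assert sorted(lining) == [tuple(i) for i in truth.truth["lining_ids"]]
        for decoy in truth.truth["decoy_ids"]:
            assert tuple(decoy) not in lining

    def test_tunnel_far_from_protein_lines_nothing(self, sealed_phantom):
        st, _ = sealed_phantom
        far = Tunnel(centerline=np.array([[0, 0, 200.0], [10, 0, 200.0]]),
                     radii=np.array([3.0, 3.0]), grid_spacing=0.6)
        assert lining_residues(st, far) == set()

    def test_matches_brute_force_distance_scan(self, sealed_phantom, sealed_tunnel):
        st, _ = sealed_phantom
        margin = 3.0
        expected = set()
        for res in st.residues():
            for atom in res.atoms:
                d = np.linalg.norm(sealed_tunnel.centerline - atom.coord, axis=1)
                if (d <= sealed_tunnel.radii + margin).any():
                    expected.add(res.id)
                    break
        assert lining_residues(st, sealed_tunnel, margin=margin) == expected


class TestWidestPoint:
    def test_simple_maxima(self):
        tun = Tunnel(centerline=np.zeros((3, 3)), radii=np.array([1.0, 3.0, 2.0]),
                     grid_spacing=0.6)
        assert widest_point(tun)[0] == 1

    def test_tie_takes_first(self):
        tun = Tunnel(centerline=np.zeros((4, 3)), radii=np.full(4, 2.0),
                     grid_spacing=0.6)
        assert widest_point(tun)[0] == 0

    def test_programmed_bulge_is_found_at_midpoint(self):
        st, truth = make_channel_phantom(
            seed=43, bulge={"s": 0.5, "extra": 1.2, "sigma": 3.0})
        cl = np.asarray(truth.truth["centerline"])
        tun = find_tunnel(st, cl[0] + [2.5, 0, 0], cl[-1] - [2.5, 0, 0])
        _, point, _ = widest_point(tun)
        # straight tube along x: arc position == x coordinate
        assert point[0] == pytest.approx(truth.truth["bulge_arc_s"], abs=0.6)


class TestEnclosure:
    def test_sealed_phantom_fully_enclosed(self, sealed_phantom, sealed_tunnel):
        st, _ = sealed_phantom
        flags = enclosure_profile(st, sealed_tunnel)
        assert flags == ["enclosed"] * len(sealed_tunnel)

    def test_no_protein_all_exposed(self):
        st = empty_structure()
        tun = find_tunnel(st, np.zeros(3), np.array([8.0, 0, 0]))
        assert set(enclosure_profile(st, tun)) == {"exposed"}

    def test_windowed_phantom_flags_match_flood_fill_oracle(
            self, windowed_phantom, windowed_tunnel):
        st, truth = windowed_phantom
        flags = enclosure_profile(st, windowed_tunnel)
        assert flags == flood_fill_exposure_oracle(st, windowed_tunnel)
        # exposure appears, and only near the carved window
        exposed_x = [windowed_tunnel.centerline[i][0]
                     for i, f in enumerate(flags) if f == "exposed"]
        assert exposed_x, "windowed phantom must show exposure"
        win_x = truth.truth["window_arc_s"]  # straight tube: arc == x
        reach = 1.5 + 1.7 + 1.4 + max(windowed_tunnel.radii) + 2 * 0.6
        assert all(abs(x - win_x) <= reach for x in exposed_x)
        assert flags[0] == "enclosed" and flags[-1] == "enclosed"
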