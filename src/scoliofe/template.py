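"""Reduced parametric normative T1-L5 hexahedral spine model.

The model stacks one hex block per vertebral body (default 4x4x2 elements),
one tapered hex block per IVD sharing interface nodes with the adjacent
bodies (tied contact by construction), a posterior spring chain standing in
for the posterior bony elements, and tension-only ligament springs.  The
caudal base is fully fixed and the T1 top-center node is restricted to
vertical translation.

Also provides hex mesh-quality metrics (scaled Jacobian, aspect ratio,
skewness, warpage, quad corner angles) with configurable acceptance
thresholds, and VTK-legacy export.
"""

from __future__ import annotations

import copy as _copy
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import defaults
from .landmarks import LEVELS, LandmarkSet3D

log = logging.getLogger(__name__)

#: 13 named regions per vertebra.  Only the four body quadrants are
#: stress-modulatable; the other nine are posterior structures represented
#: by the spring chain.
REGION_IDS: Tuple[str, ...] = (
    "body_ant_left", "body_ant_right", "body_post_left", "body_post_right",
    "pedicle_left", "pedicle_right", "lamina_left", "lamina_right",
    "transverse_left", "transverse_right", "spinous",
    "facet_left", "facet_right",
)

BODY_QUADRANTS: Tuple[str, ...] = REGION_IDS[:4]

#: Quadrant tags shared by body and IVD elements: (ant|post, left|right).
QUADRANTS: Tuple[str, ...] = ("ant_left", "ant_right", "post_left", "post_right")


@dataclass(frozen=True)
class RegionPartition:
    region_ids: Tuple[str, ...] = REGION_IDS

    def __post_init__(self) -> None:
        if len(self.region_ids) != 13:
            raise ValueError("partition requires exactly 13 region ids")

    @property
    def modulatable(self) -> Tuple[str, ...]:
        return self.region_ids[:4]


@dataclass
class Spring:
    node_a: int
    node_b: int
    stiffness: float  # N/mm
    tension_only: bool
    label: str  # ligament | posterior | costovertebral


@dataclass
class HexMeshModel:
    """Nodes + 8-node hexes + springs with per-element labels and constraints."""

    nodes: np.ndarray                      # (n, 3) mm
    hexes: np.ndarray                      # (m, 8) int, VTK corner order
    structure: np.ndarray                  # (m,) str: vertebra | ivd
    level: np.ndarray                      # (m,) str: vertebral level / ivd pair
    region: np.ndarray                     # (m,) str: quadrant region id
    springs: List[Spring] = field(default_factory=list)
    fixed: np.ndarray = None               # (n, 3) bool, constrained directions
    groups: Dict[str, dict] = field(default_factory=dict)
    ivd_pairs: List[Tuple[str, str]] = field(default_factory=list)
    elem_E: Optional[np.ndarray] = None    # set by materials.assign_materials
    elem_nu: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.hexes = np.asarray(self.hexes, dtype=int)
        if self.fixed is None:
            self.fixed = np.zeros((len(self.nodes), 3), dtype=bool)
        if self.hexes.size and (self.hexes.min() < 0
                                or self.hexes.max() >= len(self.nodes)):
            raise ValueError("hex node index out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_hexes(self) -> int:
        return len(self.hexes)

    def copy(self) -> "HexMeshModel":
        out = HexMeshModel(
            nodes=self.nodes.copy(),
            hexes=self.hexes.copy(),
            structure=self.structure.copy(),
            level=self.level.copy(),
            region=self.region.copy(),
            springs=[_copy.copy(s) for s in self.springs],
            fixed=self.fixed.copy(),
            groups=_copy.deepcopy(self.groups),
            ivd_pairs=list(self.ivd_pairs),
        )
        out.elem_E = None if self.elem_E is None else self.elem_E.copy()
        out.elem_nu = None if self.elem_nu is None else self.elem_nu.copy()
        return out

    def hexes_of(self, structure: str | None = None,
                 level: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_hexes, dtype=bool)
        if structure is not None:
            mask &= self.structure == structure
        if level is not None:
            mask &= self.level == level
        return np.nonzero(mask)[0]

    def ivd_level_label(self, level: str) -> str:
        """Label of the IVD below the given vertebra (above, for L5)."""
        for upper, lower in self.ivd_pairs:
            if upper == level:
                return f"{upper}/{lower}"
        for upper, lower in self.ivd_pairs:
            if lower == level:
                return f"{upper}/{lower}"
        raise ValueError(f"no IVD adjacent to level {level}")


def _block_node_grid(x0: np.ndarray, dx: float, wy: float, hz: float,
                     nx: int, ny: int, nz: int,
                     start_index: int) -> Tuple[np.ndarray, np.ndarray]:
    """Regular grid of (nz+1, ny+1, nx+1) nodes centered in x/y at x0."""
    xs = np.linspace(-dx / 2.0, dx / 2.0, nx + 1)
    ys = np.linspace(-wy / 2.0, wy / 2.0, ny + 1)
    zs = np.linspace(0.0, hz, nz + 1)
    pts = np.array([[x0[0] + x, x0[1] + y, x0[2] + z]
                    for z in zs for y in ys for x in xs])
    ids = start_index + np.arange(pts.shape[0]).reshape(nz + 1, ny + 1, nx + 1)
    return pts, ids


def _grid_hexes(ids: np.ndarray) -> np.ndarray:
    nzp, nyp, nxp = ids.shape
    cells = []
    for iz in range(nzp - 1):
        for iy in range(nyp - 1):
            for ix in range(nxp - 1):
                cells.append([
                    ids[iz, iy, ix], ids[iz, iy, ix + 1],
                    ids[iz, iy + 1, ix + 1], ids[iz, iy + 1, ix],
                    ids[iz + 1, iy, ix], ids[iz + 1, iy, ix + 1],
                    ids[iz + 1, iy + 1, ix + 1], ids[iz + 1, iy + 1, ix],
                ])
    return np.array(cells, dtype=int)


def _quadrant(center_x: float, center_y: float) -> Tuple[str, str]:
    return ("ant" if center_x > 0 else "post",
            "left" if center_y > 0 else "right")


def build_template(
    dims: Dict[str, Dict[str, float]] | None = None,
    ivd_heights: Dict[str, float] | None = None,
    refinement: Sequence[int] = (4, 4, 2),
    ligament_k: float = 20.0,
    posterior_k: float = 60.0,
    posterior_offset: float = 10.0,
) -> HexMeshModel:
    """Build the straight normative template from per-level dimension tables.

    ``refinement`` = hexes per vertebral body along (x, y, z); the in-plane
    counts must be even and >= 2 so the four body quadrants exist and the
    mid-plane landmark nodes are grid nodes.
    """
    dims = dims if dims is not None else defaults.default_dimension_table()
    ivd_heights = (ivd_heights if ivd_heights is not None
                   else defaults.default_ivd_heights())
    nx, ny, nz = (int(v) for v in refinement)
    if nx < 2 or ny < 2 or nx % 2 or ny % 2:
        raise ValueError("in-plane refinement must be even and >= 2")
    for level in LEVELS:
        if level not in dims:
            raise ValueError(f"dimension table missing level {level}")
        d = dims[level]
        if min(d["width"], d["depth"], d["height"]) <= 0:
            raise ValueError(f"non-positive dimension at level {level}")

    bottom_up = list(reversed(LEVELS))  # L5 ... T1
    nodes_chunks: List[np.ndarray] = []
    hex_chunks: List[np.ndarray] = []
    structure: List[str] = []
    level_lbl: List[str] = []
    region: List[str] = []
    springs: List[Spring] = []
    groups: Dict[str, dict] = {}
    ivd_pairs: List[Tuple[str, str]] = []

    grid_ids: Dict[str, np.ndarray] = {}
    n_nodes = 0
    z_cursor = 0.0
    for level in bottom_up:
        d = dims[level]
        pts, ids = _block_node_grid(
            np.array([0.0, 0.0, z_cursor]), d["depth"], d["width"], d["height"],
            nx, ny, nz, n_nodes)
        nodes_chunks.append(pts)
        grid_ids[level] = ids
        n_nodes += pts.shape[0]
        cells = _grid_hexes(ids)
        hex_chunks.append(cells)
        # quadrant labels from element centers in the body-local frame
        xs = np.linspace(-d["depth"] / 2, d["depth"] / 2, nx + 1)
        ys = np.linspace(-d["width"] / 2, d["width"] / 2, ny + 1)
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    a, s = _quadrant(0.5 * (xs[ix] + xs[ix + 1]),
                                     0.5 * (ys[iy] + ys[iy + 1]))
                    structure.append("vertebra")
                    level_lbl.append(level)
                    region.append(f"body_{a}_{s}")
        groups[level] = {
            "body_nodes": ids.ravel(),
            "top_face": ids[-1].ravel(),
            "bottom_face": ids[0].ravel(),
            "landmark_nodes": {
                "sup_left": int(ids[-1, ny, nx // 2]),
                "sup_right": int(ids[-1, 0, nx // 2]),
                "inf_left": int(ids[0, ny, nx // 2]),
                "inf_right": int(ids[0, 0, nx // 2]),
                "sup_ant": int(ids[-1, ny // 2, nx]),
                "sup_post": int(ids[-1, ny // 2, 0]),
                "inf_ant": int(ids[0, ny // 2, nx]),
                "inf_post": int(ids[0, ny // 2, 0]),
            },
        }
        z_cursor += d["height"]
        if level != bottom_up[-1]:
            upper = bottom_up[bottom_up.index(level) + 1]
            gap = ivd_heights.get(upper, ivd_heights.get(level, 5.0))
            z_cursor += gap

    nodes = np.vstack(nodes_chunks)

    # IVD blocks: one z-layer of hexes whose bottom face is the lower body's
    # top face and top face is the upper body's bottom face (shared nodes).
    for i in range(len(bottom_up) - 1):
        lower, upper = bottom_up[i], bottom_up[i + 1]
        ids_low = grid_ids[lower][-1]   # (ny+1, nx+1)
        ids_up = grid_ids[upper][0]
        cells = []
        for iy in range(ny):
            for ix in range(nx):
                cells.append([
                    ids_low[iy, ix], ids_low[iy, ix + 1],
                    ids_low[iy + 1, ix + 1], ids_low[iy + 1, ix],
                    ids_up[iy, ix], ids_up[iy, ix + 1],
                    ids_up[iy + 1, ix + 1], ids_up[iy + 1, ix],
                ])
        hex_chunks.append(np.array(cells, dtype=int))
        ivd_pairs.append((upper, lower))
        label = f"{upper}/{lower}"
        for iy in range(ny):
            for ix in range(nx):
                cy = 0.5 * (nodes[ids_low[iy, ix], 1]
                            + nodes[ids_low[iy + 1, ix + 1], 1])
                cx = 0.5 * (nodes[ids_low[iy, ix], 0]
                            + nodes[ids_low[iy, ix + 1], 0])
                a, s = _quadrant(cx, cy)
                structure.append("ivd")
                level_lbl.append(label)
                region.append(f"{a}_{s}")

    # posterior chain nodes (one per level, behind the body)
    chain_nodes = {}
    extra_pts = []
    for level in bottom_up:
        d = dims[level]
        ids = grid_ids[level]
        zc = 0.5 * (nodes[ids[0, 0, 0], 2] + nodes[ids[-1, 0, 0], 2])
        extra_pts.append([-(d["depth"] / 2.0 + posterior_offset), 0.0, zc])
        chain_nodes[level] = len(nodes) + len(extra_pts) - 1
    nodes = np.vstack([nodes, np.array(extra_pts)])

    for level in bottom_up:
        ids = grid_ids[level]
        cn = chain_nodes[level]
        groups[level]["chain_node"] = int(cn)
        # anchor the chain node to the 4 posterior-face corners (span 3D)
        for iy in (0, ny):
            for iz in (0, nz):
                springs.append(Spring(cn, int(ids[iz, iy, 0]),
                                      posterior_k, False, "posterior"))
    for i in range(len(bottom_up) - 1):
        lower, upper = bottom_up[i], bottom_up[i + 1]
        springs.append(Spring(chain_nodes[lower], chain_nodes[upper],
                              posterior_k, False, "posterior"))

    # 7 tension-only ligament sets per level pair
    for i in range(len(bottom_up) - 1):
        lower, upper = bottom_up[i], bottom_up[i + 1]
        lo, up = grid_ids[lower], grid_ids[upper]
        pairs = {
            "all": (lo[-1, ny // 2, nx], up[0, ny // 2, nx]),
            "pll": (lo[-1, ny // 2, 0], up[0, ny // 2, 0]),
            "lf": (chain_nodes[lower], chain_nodes[upper]),
            "isl": (chain_nodes[lower], chain_nodes[upper]),
            "ssl": (chain_nodes[lower], chain_nodes[upper]),
            "itl_left": (lo[-1, ny, nx // 2], up[0, ny, nx // 2]),
            "itl_right": (lo[-1, 0, nx // 2], up[0, 0, nx // 2]),
        }
        for _name, (a, b) in pairs.items():
            springs.append(Spring(int(a), int(b), ligament_k, True, "ligament"))

    model = HexMeshModel(
        nodes=nodes,
        hexes=np.vstack(hex_chunks),
        structure=np.array(structure, dtype=object),
        level=np.array(level_lbl, dtype=object),
        region=np.array(region, dtype=object),
        springs=springs,
        groups=groups,
        ivd_pairs=ivd_pairs,
    )
    # constraints: caudal base fully fixed; T1 top-center vertical-only
    base = groups[bottom_up[0]]["bottom_face"]
    model.fixed[base, :] = True
    t1_center = int(grid_ids["T1"][-1, ny // 2, nx // 2])
    model.fixed[t1_center, 0] = True
    model.fixed[t1_center, 1] = True
    groups["T1"]["top_center"] = t1_center
    return model


def extract_landmarks(model: HexMeshModel) -> LandmarkSet3D:
    """Read the 9-per-level landmark set off the (possibly deformed) mesh."""
    coords = {}
    for level in LEVELS:
        lm = model.groups[level]["landmark_nodes"]
        pts = []
        for lid, nid in lm.items():
            p = model.nodes[nid]
            coords[(level, lid)] = p.copy()
            pts.append(p)
        coords[(level, "centroid")] = np.mean(pts, axis=0)
    return LandmarkSet3D(coords)


# ---------------------------------------------------------------------------
# Mesh quality
# ---------------------------------------------------------------------------

# corner -> the three adjacent corners, ordered so a unit cube gives det +1
_CORNER_TRIADS = (
    (0, (1, 3, 4)), (1, (2, 0, 5)), (2, (3, 1, 6)), (3, (0, 2, 7)),
    (4, (7, 5, 0)), (5, (4, 6, 1)), (6, (5, 7, 2)), (7, (6, 4, 3)),
)

_EDGES = ((0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
          (0, 4), (1, 5), (2, 6), (3, 7))

_FACES = ((0, 1, 2, 3), (4, 7, 6, 5), (0, 4, 5, 1),
          (1, 5, 6, 2), (2, 6, 7, 3), (3, 7, 4, 0))

DEFAULT_QUALITY_THRESHOLDS = {
    "jacobian": 0.5,     # >=
    "aspect": 5.0,       # <=
    "skewness": 60.0,    # <= deg
    "warpage": 40.0,     # <= deg
    "quad_min_angle": 30.0,   # >= deg
    "quad_max_angle": 150.0,  # <= deg
}


@dataclass
class QualityReport:
    jacobian: np.ndarray
    aspect: np.ndarray
    skewness: np.ndarray
    warpage: np.ndarray
    quad_min_angle: np.ndarray
    quad_max_angle: np.ndarray

    def metric(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    return v / n


def mesh_quality(model_or_nodes, hexes: np.ndarray | None = None) -> QualityReport:
    """Per-hex quality metrics.

    Scaled Jacobian = min over corners of det of the unit-normalized edge
    triad; aspect = max/min edge length; skewness = max deviation of the
    face-diagonal crossing angle from 90 deg; warpage = max angle between
    the two triangle planes of each quad face; quad angles = extreme
    interior corner angles over the six faces.
    """
    if hexes is None:
        nodes, hexes = model_or_nodes.nodes, model_or_nodes.hexes
    else:
        nodes = np.asarray(model_or_nodes, dtype=float)
    X = nodes[hexes]  # (m, 8, 3)
    m = X.shape[0]

    jac = np.full(m, np.inf)
    for corner, (a, b, c) in _CORNER_TRIADS:
        ea = _unit(X[:, a] - X[:, corner])
        eb = _unit(X[:, b] - X[:, corner])
        ec = _unit(X[:, c] - X[:, corner])
        det = np.einsum("ij,ij->i", np.cross(ea, eb), ec)
        jac = np.minimum(jac, det)

    edge_len = np.stack(
        [np.linalg.norm(X[:, b] - X[:, a], axis=1) for a, b in _EDGES], axis=1)
    aspect = edge_len.max(axis=1) / edge_len.min(axis=1)

    skew = np.zeros(m)
    warp = np.zeros(m)
    qmin = np.full(m, 180.0)
    qmax = np.zeros(m)
    for f in _FACES:
        p = [X[:, i] for i in f]
        d1 = _unit(p[2] - p[0])
        d2 = _unit(p[3] - p[1])
        ang = np.degrees(np.arccos(np.clip(np.abs(
            np.einsum("ij,ij->i", d1, d2)), 0.0, 1.0)))
        skew = np.maximum(skew, np.abs(90.0 - ang))
        # warpage via both diagonal splits
        for (t1, t2) in (((0, 1, 2), (0, 2, 3)), ((0, 1, 3), (1, 2, 3))):
            n1 = _unit(np.cross(p[t1[1]] - p[t1[0]], p[t1[2]] - p[t1[0]]))
            n2 = _unit(np.cross(p[t2[1]] - p[t2[0]], p[t2[2]] - p[t2[0]]))
            w = np.degrees(np.arccos(np.clip(
                np.einsum("ij,ij->i", n1, n2), -1.0, 1.0)))
            warp = np.maximum(warp, w)
        for k in range(4):
            e1 = _unit(p[(k + 1) % 4] - p[k])
            e2 = _unit(p[(k - 1) % 4] - p[k])
            a = np.degrees(np.arccos(np.clip(
                np.einsum("ij,ij->i", e1, e2), -1.0, 1.0)))
            qmin = np.minimum(qmin, a)
            qmax = np.maximum(qmax, a)

    inverted = np.nonzero(jac <= 0)[0]
    for idx in inverted:
        log.warning("inverted element %d (scaled Jacobian %.3f)", idx, jac[idx])
    return QualityReport(jacobian=jac, aspect=aspect, skewness=skew,
                         warpage=warp, quad_min_angle=qmin, quad_max_angle=qmax)


def check_quality(report: QualityReport,
                  thresholds: Dict[str, float] | None = None,
                  floor: float = 0.97) -> Dict[str, object]:
    """Pass fractions per criterion; overall pass if all fractions >= floor."""
    th = dict(DEFAULT_QUALITY_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    geq = {"jacobian", "quad_min_angle"}
    fractions = {}
    for name, limit in th.items():
        vals = report.metric(name)
        ok = vals >= limit if name in geq else vals <= limit
        fractions[name] = float(np.mean(ok)) if len(vals) else 1.0
    return {
        "fractions": fractions,
        "pass": all(f >= floor for f in fractions.values()),
        "floor": floor,
    }


# ---------------------------------------------------------------------------
# VTK legacy export + JSON sidecar for full model round-trip
# ---------------------------------------------------------------------------

_STRUCT_CODE = {"vertebra": 0, "ivd": 1}


def write_vtk(model: HexMeshModel, path,
              cell_data: Dict[str, np.ndarray] | None = None,
              point_data: Dict[str, np.ndarray] | None = None) -> None:
    """Write an ASCII VTK legacy unstructured grid (hexes + spring lines)."""
    levels = sorted(set(model.level))
    regions = sorted(set(model.region))
    lvl_idx = {l: i for i, l in enumerate(levels)}
    reg_idx = {r: i for i, r in enumerate(regions)}
    n_cells = model.n_hexes + len(model.springs)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nscoliofe spine model\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {model.n_nodes} double\n")
        for p in model.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        size = model.n_hexes * 9 + len(model.springs) * 3
        fh.write(f"CELLS {n_cells} {size}\n")
        for h in model.hexes:
            fh.write("8 " + " ".join(str(i) for i in h) + "\n")
        for s in model.springs:
            fh.write(f"2 {s.node_a} {s.node_b}\n")
        fh.write(f"CELL_TYPES {n_cells}\n")
        fh.write("\n".join(["12"] * model.n_hexes + ["3"] * len(model.springs)))
        fh.write("\n")
        fh.write(f"CELL_DATA {n_cells}\n")
        spring_pad = [-1] * len(model.springs)
        arrays = {
            "structure": [_STRUCT_CODE[s] for s in model.structure]
                         + [2] * len(model.springs),
            "level": [lvl_idx[l] for l in model.level] + spring_pad,
            "region": [reg_idx[r] for r in model.region] + spring_pad,
        }
        if cell_data:
            for name, vals in cell_data.items():
                vals = list(np.asarray(vals).ravel())
                if len(vals) == model.n_hexes:
                    vals = vals + [0.0] * len(model.springs)
                arrays[name] = vals
        for name, vals in arrays.items():
            is_int = all(float(v).is_integer() for v in vals[:8])
            dtype = "int" if is_int and name in ("structure", "level",
                                                 "region") else "double"
            fh.write(f"SCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.9g}" if dtype == "double" else str(int(v))
                               for v in vals))
            fh.write("\n")
        if point_data:
            fh.write(f"POINT_DATA {model.n_nodes}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals, dtype=float)
                if vals.ndim == 2 and vals.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in vals:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in vals.ravel()))
                    fh.write("\n")


def save_model(model: HexMeshModel, path) -> None:
    """Write <path> (VTK) plus <path>.meta.json for lossless reload."""
    write_vtk(model, path)
    meta = {
        "structure": list(model.structure),
        "level": list(model.level),
        "region": list(model.region),
        "springs": [[s.node_a, s.node_b, s.stiffness, bool(s.tension_only),
                     s.label] for s in model.springs],
        "fixed": model.fixed.astype(int).tolist(),
        "ivd_pairs": [list(p) for p in model.ivd_pairs],
        "groups": {
            lvl: {
                "body_nodes": [int(i) for i in g["body_nodes"]],
                "top_face": [int(i) for i in g["top_face"]],
                "bottom_face": [int(i) for i in g["bottom_face"]],
                "landmark_nodes": {k: int(v)
                                   for k, v in g["landmark_nodes"].items()},
                **({"chain_node": int(g["chain_node"])}
                   if "chain_node" in g else {}),
                **({"top_center": int(g["top_center"])}
                   if "top_center" in g else {}),
            }
            for lvl, g in model.groups.items()
        },
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh)


def load_model(path) -> HexMeshModel:
    """Reload a model written by :func:`save_model`."""
    nodes, hexes = _read_vtk_geometry(path)
    with open(str(path) + ".meta.json") as fh:
        meta = json.load(fh)
    groups = {}
    for lvl, g in meta["groups"].items():
        groups[lvl] = {
            "body_nodes": np.array(g["body_nodes"], dtype=int),
            "top_face": np.array(g["top_face"], dtype=int),
            "bottom_face": np.array(g["bottom_face"], dtype=int),
            "landmark_nodes": {k: int(v)
                               for k, v in g["landmark_nodes"].items()},
        }
        if "chain_node" in g:
            groups[lvl]["chain_node"] = int(g["chain_node"])
        if "top_center" in g:
            groups[lvl]["top_center"] = int(g["top_center"])
    return HexMeshModel(
        nodes=nodes,
        hexes=hexes,
        structure=np.array(meta["structure"], dtype=object),
        level=np.array(meta["level"], dtype=object),
        region=np.array(meta["region"], dtype=object),
        springs=[Spring(int(a), int(b), float(k), bool(t), lbl)
                 for a, b, k, t, lbl in meta["springs"]],
        fixed=np.array(meta["fixed"], dtype=bool),
        groups=groups,
        ivd_pairs=[tuple(p) for p in meta["ivd_pairs"]],
    )


def _read_vtk_geometry(path) -> Tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        tokens = fh.read().split()
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
    j = tokens.index("CELLS")
    n_cells = int(tokens[j + 1])
    k = j + 3
    hexes = []
    for _ in range(n_cells):
        cnt = int(tokens[k])
        conn = [int(t) for t in tokens[k + 1:k + 1 + cnt]]
        if cnt == 8:
            hexes.append(conn)
        k += 1 + cnt
    return pts, np.array(hexes, dtype=int)
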