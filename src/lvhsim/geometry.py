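"""Idealized biventricular anatomy.

The ventricles are modelled as two truncated ellipsoidal shells: a thick-walled
left ventricle centred at the origin and a thinner right-ventricular shell
placed adjacent to it on the patient's right-anterior side.  Each shell is a
structured parametric mesh in (transmural u, apicobasal v, azimuth phi), split
into tetrahedra, watertight up to its basal plane.  Because nodes are generated
from their parametric coordinates, the universal ventricular coordinates
(apicobasal z, transmural t, rotational phi, chamber) are known exactly; a
finite-element Laplace solve is provided as a fallback for meshes loaded
without parametric metadata.

Axes follow the usual patient convention: +x left, +y anterior, +z towards the
base.  All lengths are metres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "GeometryParams",
    "ShellSpec",
    "VentricularMesh",
    "VentricularCoords",
    "FascicleSpec",
    "FascicleSet",
    "ElectrodeSet",
    "TorsoParams",
    "build_idealized_biventricle",
    "assign_fibres",
    "compute_ventricular_coordinates",
    "laplace_coordinates",
    "map_points_by_coordinates",
    "place_fascicles",
    "default_fascicle_specs",
    "torso_electrodes",
    "truncated_ellipsoid_volume",
    "analytic_shell_volume",
    "box_bar_mesh",
]

LV, RV = 0, 1
REGION_NAMES = ("LV_free_wall", "septum", "RV_free_wall")
REGION_LV_FREE, REGION_SEPTUM, REGION_RV_FREE = 0, 1, 2


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellSpec:
    """One truncated ellipsoidal shell (semi-axes in metres).

    ``a_endo``/``c_endo`` are the short/long cavity semi-axes, ``wall`` the
    transmural thickness added to both, and ``base_z`` the height (above the
    shell centre) of the flat basal truncation plane.
    """

    a_endo: float
    c_endo: float
    wall: float
    base_z: float
    # concentric-remodelling perturbation: extra thickness delta(phi) =
    # (amp_in + amp_out) * w(phi), split between inward and outward motion.
    thick_in_amp: float = 0.0
    thick_out_amp: float = 0.0
    w_min: float = 1.0
    phi_width: float = np.pi / 3

    def weighting(self, phi: np.ndarray) -> np.ndarray:
        """Rotational thickening weight, 1 at mid-septum (phi = 0)."""
        if self.w_min >= 1.0:
            return np.ones_like(phi)
        return self.w_min + (1.0 - self.w_min) * np.exp(-((phi / self.phi_width) ** 2))


@dataclass(frozen=True)
class GeometryParams:
    """Full biventricular configuration."""

    lv: ShellSpec = ShellSpec(a_endo=0.028, c_endo=0.050, wall=0.011, base_z=0.011)
    rv: ShellSpec = ShellSpec(a_endo=0.034, c_endo=0.044, wall=0.005, base_z=0.009)
    rv_gap: float = 0.002
    septal_half_angle: float = np.deg2rad(60.0)
    # unit vector (xy-plane) from the LV axis towards the RV centre
    septum_direction: tuple[float, float] = (-0.64278761, 0.76604444)

    def rv_center(self) -> np.ndarray:
        d = self.lv.a_endo + self.lv.wall + self.rv.a_endo + self.rv.wall + self.rv_gap
        e = np.array([*self.septum_direction, 0.0])
        return d * e


@dataclass
class VentricularCoords:
    """Universal ventricular coordinates per node."""

    z: np.ndarray      # apicobasal, 0 apex .. 1 base
    t: np.ndarray      # transmural, 0 endo .. 1 epi
    phi: np.ndarray    # rotational, (-pi, pi], 0 at mid-septum
    chamber: np.ndarray  # LV = 0, RV = 1


@dataclass
class VentricularMesh:
    """Tetrahedral biventricle with optional fibre triads.

    ``surfaces`` maps tag -> (F, 3) arrays of boundary triangles; tags are
    ``LV_endo``, ``RV_endo``, ``epi`` and ``base``.
    """

    nodes: np.ndarray                 # (N, 3)
    elems: np.ndarray                 # (E, 4)
    elem_region: np.ndarray           # (E,) indices into REGION_NAMES
    elem_chamber: np.ndarray          # (E,) LV/RV
    surfaces: dict[str, np.ndarray]
    geometry_params: GeometryParams | None = None
    resolution: tuple | None = None   # ((nu, nv, nphi) per chamber)
    node_u: np.ndarray | None = None
    node_v: np.ndarray | None = None
    node_phi: np.ndarray | None = None
    node_chamber: np.ndarray | None = None
    f0: np.ndarray | None = None      # (E, 3) fibre
    s0: np.ndarray | None = None      # (E, 3) sheet
    n0: np.ndarray | None = None      # (E, 3) sheet-normal
    et: np.ndarray | None = None      # (E, 3) outward transmural direction
    fibre_angles: tuple | None = None

    # -- derived quantities ------------------------------------------------
    def element_volumes(self) -> np.ndarray:
        n = self.nodes
        e = self.elems
        a = n[e[:, 1]] - n[e[:, 0]]
        b = n[e[:, 2]] - n[e[:, 0]]
        c = n[e[:, 3]] - n[e[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def tissue_volume(self) -> float:
        return float(self.element_volumes().sum())

    def elem_coord(self, arr: np.ndarray, circular: bool = False) -> np.ndarray:
        """Average a per-node quantity onto elements (circular mean for phi)."""
        if circular:
            s = np.sin(arr[self.elems]).mean(axis=1)
            c = np.cos(arr[self.elems]).mean(axis=1)
            return np.arctan2(s, c)
        return arr[self.elems].mean(axis=1)

    def surface_nodes(self, tag: str) -> np.ndarray:
        return np.unique(self.surfaces[tag])


# ---------------------------------------------------------------------------
# analytic volumes
# ---------------------------------------------------------------------------

def truncated_ellipsoid_volume(a: float, c: float, base_z: float) -> float:
    """Volume of the ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 <= 1 below z = base_z."""
    zb = min(base_z, c)
    return float(np.pi * a**2 * ((zb + c) - (zb**3 + c**3) / (3 * c**2)))


def _shell_volume(s: ShellSpec) -> float:
    outer = truncated_ellipsoid_volume(s.a_endo + s.wall, s.c_endo + s.wall, s.base_z)
    inner = truncated_ellipsoid_volume(s.a_endo, s.c_endo, s.base_z)
    return outer - inner


def analytic_shell_volume(params: GeometryParams) -> float:
    """Closed-form tissue volume of both shells (no thickening perturbation)."""
    return _shell_volume(params.lv) + _shell_volume(params.rv)


# ---------------------------------------------------------------------------
# structured shell construction
# ---------------------------------------------------------------------------

def _shell_points(spec: ShellSpec, u: np.ndarray, v: np.ndarray, phi: np.ndarray,
                  e1: np.ndarray, e2: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Positions for parametric coordinates (broadcastable arrays).

    The base point interpolates linearly between the endocardial and
    epicardial ellipsoid surfaces; the concentric-thickening perturbation then
    moves the endo surface inward and the epi surface outward along the local
    transmural direction.
    """
    a_i, c_i = spec.a_endo, spec.c_endo
    a_o, c_o = a_i + spec.wall, c_i + spec.wall

    def surf(a, c):
        th_base = np.arccos(np.clip(spec.base_z / c, -1.0, 1.0))
        th = np.pi - v * (np.pi - th_base)
        r_xy = a * np.sin(th)
        dirs = (np.cos(phi)[..., None] * e1 + np.sin(phi)[..., None] * e2)
        p = dirs * r_xy[..., None]
        p[..., 2] += c * np.cos(th)
        return p

    p_i, p_o = surf(a_i, c_i), surf(a_o, c_o)
    p = (1.0 - u)[..., None] * p_i + u[..., None] * p_o
    if spec.thick_in_amp > 0 or spec.thick_out_amp > 0:
        et = p_o - p_i
        et /= np.linalg.norm(et, axis=-1, keepdims=True)
        w = spec.weighting(np.arctan2(np.sin(phi), np.cos(phi)))
        off = (-spec.thick_in_amp * (1.0 - u) + spec.thick_out_amp * u) * w
        p = p + off[..., None] * et
    return p + center


def _build_shell(spec: ShellSpec, nu: int, nv: int, nphi: int,
                 e1: np.ndarray, e2: np.ndarray, center: np.ndarray):
    """Structured tet mesh of one shell.

    Node grid: apex column (one node per u layer) + rings for v = 1..nv.
    Cells: wedges next to the apex, hexahedra elsewhere; every cell is split
    into tetrahedra around its centroid so neighbouring cells always share
    conforming faces.
    Returns nodes, tets, node parametric (u, v, phi) and index helpers.
    """
    us = np.linspace(0.0, 1.0, nu + 1)
    vs = np.linspace(0.0, 1.0, nv + 1)
    phis = -np.pi + 2 * np.pi * np.arange(nphi) / nphi

    nodes, pu, pv, pphi = [], [], [], []
    # apex column: v = 0 collapses all phi
    apex_idx = np.empty(nu + 1, dtype=int)
    for iu, u in enumerate(us):
        p = _shell_points(spec, np.array(u), np.array(0.0), np.array(0.0), e1, e2, center)
        apex_idx[iu] = len(nodes)
        nodes.append(p)
        pu.append(u); pv.append(0.0); pphi.append(0.0)
    ring_idx = np.empty((nu + 1, nv, nphi), dtype=int)
    U, V, P = np.meshgrid(us, vs[1:], phis, indexing="ij")
    pts = _shell_points(spec, U, V, P, e1, e2, center)
    base = len(nodes)
    for iu in range(nu + 1):
        for iv in range(nv):
            for ip in range(nphi):
                ring_idx[iu, iv, ip] = base
                base += 1
    nodes = np.vstack([np.asarray(nodes).reshape(-1, 3), pts.reshape(-1, 3)])
    pu = np.concatenate([np.asarray(pu), U.ravel()])
    pv = np.concatenate([np.asarray(pv), V.ravel()])
    pphi = np.concatenate([np.asarray(pphi), P.ravel()])

    tets = []
    tet_cell_phi = []   # representative phi per tet (for region labels)
    tet_cell_u = []
    extra_nodes = []    # cell centroids appended after grid nodes
    next_id = len(nodes)

    def emit(cell_corner_ids, faces, phi_c, u_c):
        """Split a cell into tets around its centroid. ``faces`` lists the
        boundary polygons (triangles/quads) of the cell as node-id tuples."""
        nonlocal next_id
        centroid = nodes[cell_corner_ids].mean(axis=0)
        cid = next_id
        extra_nodes.append(centroid)
        next_id += 1
        for f in faces:
            if len(f) == 3:
                tris = [f]
            else:  # quad: split along the diagonal through its min-id corner
                k = int(np.argmin(f))
                f = f[k:] + f[:k]
                tris = [(f[0], f[1], f[2]), (f[0], f[2], f[3])]
            for tri in tris:
                tets.append((tri[0], tri[1], tri[2], cid))
                tet_cell_phi.append(phi_c)
                tet_cell_u.append(u_c)

    for iu in range(nu):
        for ip in range(nphi):
            ipn = (ip + 1) % nphi
            # apex wedge between u layers iu, iu+1 and ring v=1
            a0, a1 = apex_idx[iu], apex_idx[iu + 1]
            q00, q01 = ring_idx[iu, 0, ip], ring_idx[iu, 0, ipn]
            q10, q11 = ring_idx[iu + 1, 0, ip], ring_idx[iu + 1, 0, ipn]
            faces = [
                (a0, q00, q01),            # inner u face (triangle)
                (a1, q11, q10),            # outer u face
                [a0, a1, q10, q00],        # side at phi
                [a0, q01, q11, a1],        # side at phi + dphi
                [q00, q10, q11, q01],      # ring-side quad (towards v=1 cells)
            ]
            phi_c = phis[ip] + np.pi / nphi
            phi_c = np.arctan2(np.sin(phi_c), np.cos(phi_c))
            emit(np.array([a0, a1, q00, q01, q10, q11]), faces, phi_c,
                 0.5 * (us[iu] + us[iu + 1]))
            for iv in range(nv - 1):
                c = [ring_idx[iu, iv, ip], ring_idx[iu, iv, ipn],
                     ring_idx[iu, iv + 1, ip], ring_idx[iu, iv + 1, ipn],
                     ring_idx[iu + 1, iv, ip], ring_idx[iu + 1, iv, ipn],
                     ring_idx[iu + 1, iv + 1, ip], ring_idx[iu + 1, iv + 1, ipn]]
                faces = [
                    [c[0], c[1], c[3], c[2]],  # inner (u = iu)
                    [c[4], c[6], c[7], c[5]],  # outer
                    [c[0], c[2], c[6], c[4]],  # phi side
                    [c[1], c[5], c[7], c[3]],  # phi + dphi side
                    [c[0], c[4], c[5], c[1]],  # apical v side
                    [c[2], c[3], c[7], c[6]],  # basal v side
                ]
                emit(np.array(c), faces, phi_c, 0.5 * (us[iu] + us[iu + 1]))

    all_nodes = np.vstack([nodes, np.asarray(extra_nodes)])
    ncent = len(extra_nodes)
    pu = np.concatenate([pu, np.full(ncent, np.nan)])
    pv = np.concatenate([pv, np.full(ncent, np.nan)])
    pphi = np.concatenate([pphi, np.full(ncent, np.nan)])
    # centroid parametric coords: interpolate from corner grid values
    tets = np.asarray(tets, dtype=int)
    return all_nodes, tets, pu, pv, pphi, np.asarray(tet_cell_phi), np.asarray(tet_cell_u), apex_idx, ring_idx


def _fill_centroid_params(nodes_n, tets, pu, pv, pphi):
    """Centroid nodes inherit parametric coords by averaging their cell corners."""
    miss = np.isnan(pu)
    if not miss.any():
        return pu, pv, pphi
    # every centroid node appears as the 4th node of its tets; corners are the rest
    for tet in tets:
        cid = tet[3]
        if not miss[cid]:
            continue
        corners = tet[:3]
        pu[cid] = np.nanmean(pu[corners])
        pv[cid] = np.nanmean(pv[corners])
        s = np.nanmean(np.sin(pphi[corners]))
        c = np.nanmean(np.cos(pphi[corners]))
        pphi[cid] = np.arctan2(s, c)
        miss[cid] = False
    return pu, pv, pphi


def _resolution_for(spec: ShellSpec, h: float) -> tuple[int, int, int]:
    a_mid = spec.a_endo + 0.5 * spec.wall
    c_mid = spec.c_endo + 0.5 * spec.wall
    nu = max(2, round(spec.wall / h))
    # meridian arc length, apex to base (crude ellipse quarter-arc estimate)
    arc = 0.5 * np.pi * (3 * (a_mid + c_mid) / 2 - np.sqrt(a_mid * c_mid)) / 2
    nv = max(6, round(arc / h))
    nphi = max(24, round(2 * np.pi * a_mid / h))
    return nu, nv, nphi


def _extract_boundary(tets: np.ndarray) -> np.ndarray:
    faces = np.concatenate([tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
                            tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]])
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def build_idealized_biventricle(
    geometry_params: GeometryParams | None = None,
    target_edge_length: float = 0.005,
    resolution: tuple | None = None,
) -> VentricularMesh:
    """Generate the labelled, fibre-less tetrahedral biventricle.

    ``target_edge_length`` (m) controls the grid spacing; it must not exceed
    half the LV wall thickness so that at least two element layers span the
    wall.  ``resolution`` optionally fixes ((nu, nv, nphi)_LV, (..)_RV)
    explicitly (used for very coarse test fixtures and to keep the element
    count constant while a geometry is regrown).
    """
    params = geometry_params or GeometryParams()
    for name, s in (("LV", params.lv), ("RV", params.rv)):
        if s.wall <= 0 or s.a_endo <= 0 or s.c_endo <= 0:
            raise ValueError(f"degenerate {name} shell: non-positive dimensions")
        if s.base_z >= s.c_endo:
            raise ValueError(f"{name} base plane above the cavity apex-base span")
        if s.thick_in_amp >= s.a_endo * 0.9:
            raise ValueError(f"{name} inward thickening would invert the cavity; "
                             "use a smaller per-cycle growth increment")
    if target_edge_length > params.lv.wall / 2:
        raise ValueError("target_edge_length must be <= LV wall thickness / 2")

    if resolution is None:
        res_lv = _resolution_for(params.lv, target_edge_length)
        # RV wall is thin; resolve it with 2 transmural layers at this scale
        nu, nv, nphi = _resolution_for(params.rv, target_edge_length)
        res_rv = (2, nv, nphi)
    else:
        res_lv, res_rv = resolution

    e_sep = np.array([*params.septum_direction, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    e2_lv = np.cross(ez, e_sep)
    rvc = params.rv_center()
    e1_rv = -e_sep
    e2_rv = np.cross(ez, e1_rv)

    offset = 0
    all_nodes, all_tets = [], []
    u_l, v_l, phi_l, ch_l, ech_l, ephi_l, eu_l = [], [], [], [], [], [], []
    for chamber, (spec, res, e1, e2, center) in enumerate([
            (params.lv, res_lv, e_sep, e2_lv, np.zeros(3)),
            (params.rv, res_rv, e1_rv, e2_rv, rvc)]):
        nodes, tets, pu, pv, pphi, tphi, tu, *_ = _build_shell(spec, *res, e1, e2, center)
        pu, pv, pphi = _fill_centroid_params(nodes, tets, pu, pv, pphi)
        all_nodes.append(nodes)
        all_tets.append(tets + offset)
        u_l.append(pu); v_l.append(pv); phi_l.append(pphi)
        ch_l.append(np.full(len(nodes), chamber, dtype=np.int8))
        ech_l.append(np.full(len(tets), chamber, dtype=np.int8))
        ephi_l.append(tphi); eu_l.append(tu)
        offset += len(nodes)

    nodes = np.vstack(all_nodes)
    tets = np.vstack(all_tets)
    # enforce positive orientation
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    vol6 = np.einsum("ij,ij->i", np.cross(a, b), c)
    flip = np.where(vol6 < 0)[0]
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]

    node_u = np.concatenate(u_l)
    node_v = np.concatenate(v_l)
    node_phi = np.concatenate(phi_l)
    node_ch = np.concatenate(ch_l)
    elem_ch = np.concatenate(ech_l)
    elem_phi = np.concatenate(ephi_l)

    elem_region = np.where(elem_ch == RV, REGION_RV_FREE,
                           np.where(np.abs(elem_phi) <= params.septal_half_angle,
                                    REGION_SEPTUM, REGION_LV_FREE)).astype(np.int8)

    bfaces = _extract_boundary(tets)
    fu = node_u[bfaces]
    fch = node_ch[bfaces]
    fv = node_v[bfaces]
    is_base = np.nanmin(fv, axis=1) > 1 - 1e-9
    is_endo = (np.nanmax(fu, axis=1) < 1e-9) & ~is_base
    is_epi = (np.nanmin(fu, axis=1) > 1 - 1e-9) & ~is_base
    surfaces = {
        "LV_endo": bfaces[is_endo & (fch[:, 0] == LV)],
        "RV_endo": bfaces[is_endo & (fch[:, 0] == RV)],
        "epi": bfaces[is_epi],
        "base": bfaces[is_base],
    }

    mesh = VentricularMesh(
        nodes=nodes, elems=tets, elem_region=elem_region, elem_chamber=elem_ch,
        surfaces=surfaces, geometry_params=params, resolution=(res_lv, res_rv),
        node_u=node_u, node_v=node_v, node_phi=node_phi, node_chamber=node_ch,
    )
    if mesh.element_volumes().min() <= 0:
        raise RuntimeError("mesh generation produced a non-positive tetrahedron")
    return mesh


# ---------------------------------------------------------------------------
# fibres
# ---------------------------------------------------------------------------

def assign_fibres(mesh: VentricularMesh,
                  coords: VentricularCoords | None = None,
                  alpha_endo: float = 60.0, alpha_epi: float = -60.0,
                  beta_endo: float = -65.0, beta_epi: float = 25.0) -> VentricularMesh:
    """Rule-based fibre triads.

    The helix angle rotates linearly from ``alpha_endo`` at the endocardium to
    ``alpha_epi`` at the epicardium; the transverse (sheet) angle from
    ``beta_endo`` to ``beta_epi``.  f0 lies in the local wall-tangent plane,
    s0 is obtained by rotating the transmural direction about f0 by the
    transverse angle, and n0 completes the right-handed orthonormal triad.
    """
    if coords is None:
        coords = compute_ventricular_coordinates(mesh)
    for ang in (alpha_endo, alpha_epi, beta_endo, beta_epi):
        if not (-90.0 < ang < 90.0):
            raise ValueError("fibre angles must lie in (-90, 90) degrees")
    params = mesh.geometry_params
    if params is None:
        raise ValueError("fibre assignment requires geometry parameters")

    t_e = mesh.elem_coord(coords.t)
    v_e = mesh.elem_coord(coords.z)
    phi_e = mesh.elem_coord(coords.phi, circular=True)
    ch_e = mesh.elem_chamber

    e_sep = np.array([*params.septum_direction, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    frames = {
        LV: (params.lv, e_sep, np.cross(ez, e_sep), np.zeros(3)),
        RV: (params.rv, -e_sep, np.cross(ez, -e_sep), params.rv_center()),
    }

    E = len(mesh.elems)
    et = np.empty((E, 3))
    ec = np.empty((E, 3))
    el = np.empty((E, 3))
    h = 1e-4
    for ch, (spec, e1, e2, center) in frames.items():
        m = ch_e == ch
        u, v, phi = t_e[m], v_e[m], phi_e[m]
        p_i = _shell_points(spec, np.zeros_like(u), v, phi, e1, e2, center)
        p_o = _shell_points(spec, np.ones_like(u), v, phi, e1, e2, center)
        d = p_o - p_i
        et[m] = d / np.linalg.norm(d, axis=-1, keepdims=True)
        pc = _shell_points(spec, u, v, phi, e1, e2, center)
        dpdphi = (_shell_points(spec, u, v, phi + h, e1, e2, center) - pc) / h
        dpdv = (_shell_points(spec, u, np.clip(v + h, 0, 1), phi, e1, e2, center) - pc)
        ecl = dpdphi - np.einsum("ij,ij->i", dpdphi, et[m])[:, None] * et[m]
        ecl /= np.linalg.norm(ecl, axis=-1, keepdims=True)
        ec[m] = ecl
        ell = np.cross(et[m], ecl)
        sign = np.sign(np.einsum("ij,ij->i", ell, dpdv))
        sign[sign == 0] = 1.0
        el[m] = ell * sign[:, None]

    alpha = np.deg2rad(alpha_endo + (alpha_epi - alpha_endo) * t_e)
    beta = np.deg2rad(beta_endo + (beta_epi - beta_endo) * t_e)
    f0 = np.cos(alpha)[:, None] * ec + np.sin(alpha)[:, None] * el
    s0 = np.cos(beta)[:, None] * et + np.sin(beta)[:, None] * np.cross(f0, et)
    n0 = np.cross(f0, s0)

    mesh.f0, mesh.s0, mesh.n0, mesh.et = f0, s0, n0, et
    mesh.fibre_angles = (alpha_endo, alpha_epi, beta_endo, beta_epi)
    return mesh


# ---------------------------------------------------------------------------
# ventricular coordinates
# ---------------------------------------------------------------------------

def compute_ventricular_coordinates(mesh: VentricularMesh) -> VentricularCoords:
    """Exact coordinates from the stored parametric metadata.

    Falls back to :func:`laplace_coordinates` when the mesh was loaded without
    parametric information.
    """
    if mesh.node_u is None:
        return laplace_coordinates(mesh)
    return VentricularCoords(z=mesh.node_v.copy(), t=mesh.node_u.copy(),
                             phi=mesh.node_phi.copy(), chamber=mesh.node_chamber.copy())


def _p1_stiffness(mesh: VentricularMesh) -> sparse.csr_matrix:
    n = mesh.nodes
    e = mesh.elems
    x = n[e]                                    # (E,4,3)
    vol = mesh.element_volumes()
    # shape-function gradients
    grads = np.empty((len(e), 4, 3))
    for i in range(4):
        others = [j for j in range(4) if j != i]
        a, b, c = (x[:, others[0]], x[:, others[1]], x[:, others[2]])
        nvec = np.cross(b - a, c - a)
        # orient towards node i
        s = np.sign(np.einsum("ij,ij->i", x[:, i] - a, nvec))
        s[s == 0] = 1.0
        nvec *= s[:, None]
        grads[:, i] = nvec / (6.0 * vol)[:, None]
    K = np.einsum("eik,ejk,e->eij", grads, grads, vol)
    rows = np.repeat(e, 4, axis=1).reshape(len(e), 4, 4)
    cols = np.tile(e[:, None, :], (1, 4, 1))
    return sparse.coo_matrix((K.ravel(), (rows.ravel(), cols.ravel())),
                             shape=(len(n), len(n))).tocsr()


def _solve_dirichlet(K: sparse.csr_matrix, fixed: np.ndarray, values: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), fixed)
    x = np.zeros(n)
    x[fixed] = values
    rhs = -K[free][:, fixed] @ values
    x[free] = spsolve(K[free][:, free].tocsc(), rhs)
    return x


def laplace_coordinates(mesh: VentricularMesh) -> VentricularCoords:
    """Laplace-solve coordinates for meshes without parametric metadata.

    Transmural t: harmonic interpolation between endocardium (0) and
    epicardium (1).  Apicobasal z: harmonic between the apex (geometric low
    point per chamber) and the base surface, rescaled to [0, 1].  The
    rotational coordinate and chamber labels are computed geometrically.
    """
    if not mesh.surfaces:
        raise ValueError("laplace coordinates require tagged surfaces")
    K = _p1_stiffness(mesh)

    # chamber by connected components of the element graph
    chamber = _node_chambers(mesh)

    endo = np.concatenate([mesh.surface_nodes("LV_endo"), mesh.surface_nodes("RV_endo")])
    epi = mesh.surface_nodes("epi")
    fixed = np.concatenate([endo, epi])
    vals = np.concatenate([np.zeros(len(endo)), np.ones(len(epi))])
    t = _solve_dirichlet(K, fixed, vals)

    base = mesh.surface_nodes("base")
    apex = []
    for ch in (LV, RV):
        m = np.where(chamber == ch)[0]
        if len(m):
            apex.append(m[np.argmin(mesh.nodes[m, 2])])
    fixed = np.concatenate([base, np.asarray(apex)])
    vals = np.concatenate([np.ones(len(base)), np.zeros(len(apex))])
    z = np.clip(_solve_dirichlet(K, fixed, vals), 0.0, 1.0)

    phi = np.empty(len(mesh.nodes))
    params = mesh.geometry_params or GeometryParams()
    e_sep = np.array([*params.septum_direction, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    for ch, (e1, center) in {LV: (e_sep, np.zeros(3)),
                             RV: (-e_sep, params.rv_center())}.items():
        m = chamber == ch
        rel = mesh.nodes[m] - center
        e2 = np.cross(ez, e1)
        phi[m] = np.arctan2(rel @ e2, rel @ e1)
    return VentricularCoords(z=z, t=np.clip(t, 0, 1), phi=phi, chamber=chamber)


def _node_chambers(mesh: VentricularMesh) -> np.ndarray:
    if mesh.node_chamber is not None:
        return mesh.node_chamber
    from scipy.sparse.csgraph import connected_components
    e = mesh.elems
    i = np.concatenate([e[:, 0], e[:, 0], e[:, 0], e[:, 1], e[:, 1], e[:, 2]])
    j = np.concatenate([e[:, 1], e[:, 2], e[:, 3], e[:, 2], e[:, 3], e[:, 3]])
    g = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(len(mesh.nodes),) * 2)
    ncomp, labels = connected_components(g, directed=False)
    # the component containing the lowest-index LV element node is LV
    lv_label = labels[mesh.elems[mesh.elem_chamber == LV][0, 0]]
    return np.where(labels == lv_label, LV, RV).astype(np.int8)


# ---------------------------------------------------------------------------
# coordinate-based point mapping
# ---------------------------------------------------------------------------

def _coord_distance2(z1, t1, p1, z2, t2, p2, weights=(1.0, 1.0, 1.0)):
    dphi = np.arctan2(np.sin(p1 - p2), np.cos(p1 - p2))
    wz, wt, wp = weights
    return wz * (z1 - z2) ** 2 + wt * (t1 - t2) ** 2 + wp * (dphi / np.pi) ** 2


def map_points_by_coordinates(src_coords_of_points: VentricularCoords,
                              dst_mesh: VentricularMesh,
                              dst_coords: VentricularCoords,
                              weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
                              ) -> np.ndarray:
    """Map points given by their (z, t, phi, chamber) onto nodes of ``dst_mesh``.

    Each point maps to the destination node of the same chamber minimising the
    weighted squared distance in normalized-coordinate space; chambers are
    never crossed.
    """
    out = np.empty(len(src_coords_of_points.z), dtype=int)
    for ch in (LV, RV):
        sm = src_coords_of_points.chamber == ch
        if not sm.any():
            continue
        dm = np.where(dst_coords.chamber == ch)[0]
        if len(dm) == 0:
            raise ValueError(f"destination mesh has no nodes in chamber {ch}")
        d2 = _coord_distance2(
            src_coords_of_points.z[sm][:, None], src_coords_of_points.t[sm][:, None],
            src_coords_of_points.phi[sm][:, None],
            dst_coords.z[dm][None, :], dst_coords.t[dm][None, :],
            dst_coords.phi[dm][None, :], weights)
        out[sm] = dm[np.argmin(d2, axis=1)]
    return out


# ---------------------------------------------------------------------------
# fascicles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FascicleSpec:
    name: str
    chamber: int
    z: float
    phi: float          # radians
    radius: float       # in normalized (z, phi/pi) coordinate units
    t0: float = 0.0     # initiation time, ms


@dataclass
class FascicleSet:
    """Named sub-endocardial root regions with initiation times (ms)."""

    regions: dict[str, np.ndarray]      # name -> node indices
    times: dict[str, float]

    def __len__(self) -> int:
        return len(self.regions)

    def source_nodes(self) -> np.ndarray:
        return np.concatenate(list(self.regions.values()))

    def source_times(self) -> np.ndarray:
        return np.concatenate([np.full(len(v), self.times[k])
                               for k, v in self.regions.items()])

    def coords_of(self, coords: VentricularCoords) -> VentricularCoords:
        idx = self.source_nodes()
        return VentricularCoords(z=coords.z[idx], t=coords.t[idx],
                                 phi=coords.phi[idx], chamber=coords.chamber[idx])


def default_fascicle_specs() -> list[FascicleSpec]:
    """Anatomical approximations of the five earliest-activation regions.

    Exact root locations in a personalised model are subject-specific; these
    defaults place three LV fascicles (anterior, posterior, septal) and two RV
    fascicles (moderator band, septal) at textbook positions and are intended
    to be overridden from configuration when better estimates exist.
    """
    return [
        FascicleSpec("LV_anterior", LV, z=0.60, phi=np.deg2rad(-45.0), radius=0.14),
        FascicleSpec("LV_posterior", LV, z=0.35, phi=np.deg2rad(135.0), radius=0.14),
        FascicleSpec("LV_septal", LV, z=0.50, phi=0.0, radius=0.14),
        FascicleSpec("RV_moderator_band", RV, z=0.35, phi=np.deg2rad(150.0), radius=0.18),
        FascicleSpec("RV_septal", RV, z=0.55, phi=0.0, radius=0.18),
    ]


def place_fascicles(mesh: VentricularMesh, coords: VentricularCoords,
                    fascicle_spec: Sequence[FascicleSpec] | None = None) -> FascicleSet:
    """Select sub-endocardial node patches for each fascicle."""
    specs = list(fascicle_spec) if fascicle_spec is not None else default_fascicle_specs()
    endo = {LV: mesh.surface_nodes("LV_endo"), RV: mesh.surface_nodes("RV_endo")}
    regions, times = {}, {}
    for fs in specs:
        if fs.radius <= 0:
            raise ValueError(f"fascicle {fs.name}: radius must be positive")
        if fs.t0 < 0:
            raise ValueError(f"fascicle {fs.name}: initiation time must be >= 0")
        cand = endo[fs.chamber]
        d2 = _coord_distance2(coords.z[cand], coords.t[cand] * 0.0, coords.phi[cand],
                              fs.z, 0.0, fs.phi)
        sel = cand[d2 <= fs.radius ** 2]
        if len(sel) == 0:
            raise ValueError(f"fascicle {fs.name}: radius captures zero nodes")
        regions[fs.name] = sel
        times[fs.name] = fs.t0
    return FascicleSet(regions=regions, times=times)


# ---------------------------------------------------------------------------
# torso electrodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsoParams:
    """Cylindrical torso surrogate for electrode placement.

    ``precordial_angles`` are leftward angles (deg) measured from the anterior
    (+y) direction towards the patient's left (+x) for V1..V6;
    ``precordial_heights`` the corresponding z positions (m).
    """

    radius: float = 0.14
    precordial_angles: tuple = (-10.0, 10.0, 25.0, 40.0, 60.0, 80.0)
    precordial_heights: tuple = (0.01, 0.01, -0.01, -0.02, -0.03, -0.03)
    limb_positions: dict | None = None

    def limbs(self) -> dict[str, np.ndarray]:
        if self.limb_positions is not None:
            return {k: np.asarray(v, float) for k, v in self.limb_positions.items()}
        return {
            "RA": np.array([-0.25, 0.06, 0.35]),
            "LA": np.array([0.25, 0.06, 0.35]),
            "LL": np.array([0.12, 0.04, -0.50]),
            "RL": np.array([-0.12, 0.04, -0.50]),
        }


@dataclass
class ElectrodeSet:
    positions: dict[str, np.ndarray]
    bspm_grid: np.ndarray | None = None    # (n*m, 3)

    REQUIRED = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")

    def require_complete(self):
        missing = [k for k in self.REQUIRED if k not in self.positions]
        if missing:
            raise ValueError(f"missing electrodes: {missing}")


def torso_electrodes(mesh: VentricularMesh, torso_params: TorsoParams | None = None,
                     bspm_grid: tuple[int, int] | None = None,
                     bspm_heights: tuple[float, float] = (-0.12, 0.12)) -> ElectrodeSet:
    """Standard 9 electrodes (plus RL) on a cylindrical torso surrogate.

    Raises if the torso radius places precordial electrodes inside the
    myocardium.
    """
    tp = torso_params or TorsoParams()
    max_r = float(np.linalg.norm(mesh.nodes[:, :2], axis=1).max())
    if tp.radius <= max_r:
        raise ValueError("torso radius smaller than the heart's lateral extent")
    pos = dict(tp.limbs())
    for i, (ang, hz) in enumerate(zip(tp.precordial_angles, tp.precordial_heights), start=1):
        a = np.deg2rad(ang)
        pos[f"V{i}"] = np.array([tp.radius * np.sin(a), tp.radius * np.cos(a), hz])
    grid = None
    if bspm_grid is not None:
        nang, nh = bspm_grid
        angs = np.linspace(-np.pi, np.pi, nang, endpoint=False)
        hs = np.linspace(*bspm_heights, nh)
        A, H = np.meshgrid(angs, hs, indexing="ij")
        grid = np.column_stack([tp.radius * np.sin(A).ravel(),
                                tp.radius * np.cos(A).ravel(), H.ravel()])
    es = ElectrodeSet(positions=pos, bspm_grid=grid)
    es.require_complete()
    # electrodes must sit strictly outside the tissue
    for name, p in pos.items():
        if np.min(np.linalg.norm(mesh.nodes - p, axis=1)) < 1e-3:
            raise ValueError(f"electrode {name} lies inside or on the myocardium")
    return es


# ---------------------------------------------------------------------------
# calibration phantom
# ---------------------------------------------------------------------------

def box_bar_mesh(length: float = 0.06, width: float = 0.01,
                 n: tuple[int, int, int] = (12, 2, 2)) -> VentricularMesh:
    """Rectangular tissue bar, fibres along +x; a conduction phantom.

    Useful for analytic eikonal checks (far-end activation time equals
    length / velocity along straight axial edges).
    """
    nx, ny, nz = n
    xs = np.linspace(0, length, nx + 1)
    ys = np.linspace(0, width, ny + 1)
    zs = np.linspace(0, width, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(len(nodes)).reshape(nx + 1, ny + 1, nz + 1)
    tets, extra = [], []
    nid = len(nodes)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = [idx[i, j, k], idx[i + 1, j, k], idx[i, j + 1, k], idx[i + 1, j + 1, k],
                     idx[i, j, k + 1], idx[i + 1, j, k + 1], idx[i, j + 1, k + 1], idx[i + 1, j + 1, k + 1]]
                faces = [[c[0], c[1], c[3], c[2]], [c[4], c[6], c[7], c[5]],
                         [c[0], c[4], c[5], c[1]], [c[2], c[3], c[7], c[6]],
                         [c[0], c[2], c[6], c[4]], [c[1], c[5], c[7], c[3]]]
                centroid = nodes[c].mean(axis=0)
                extra.append(centroid)
                for f in faces:
                    kk = int(np.argmin(f))
                    f = f[kk:] + f[:kk]
                    for tri in [(f[0], f[1], f[2]), (f[0], f[2], f[3])]:
                        tets.append((*tri, nid))
                nid += 1
    nodes = np.vstack([nodes, np.asarray(extra)])
    tets = np.asarray(tets)
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    cc = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    vol6 = np.einsum("ij,ij->i", np.cross(a, b), cc)
    tets[vol6 < 0] = tets[vol6 < 0][:, [0, 2, 1, 3]]
    E = len(tets)
    mesh = VentricularMesh(
        nodes=nodes, elems=tets,
        elem_region=np.zeros(E, dtype=np.int8),
        elem_chamber=np.zeros(E, dtype=np.int8),
        surfaces={"base": _extract_boundary(tets)},
        node_u=None, node_v=None, node_phi=None,
        node_chamber=np.zeros(len(nodes), dtype=np.int8),
    )
    mesh.f0 = np.tile([1.0, 0.0, 0.0], (E, 1))
    mesh.s0 = np.tile([0.0, 1.0, 0.0], (E, 1))
    mesh.n0 = np.tile([0.0, 0.0, 1.0], (E, 1))
    mesh.et = mesh.s0.copy()
    return mesh
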