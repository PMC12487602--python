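"""Kinematic growth of the left ventricle.

Hypertrophy is produced by a stretch-driven kinematic growth law: a per-element
growth multiplier theta increases whenever the pressure-induced stretch along
the driving direction exceeds a regionally varying critical stretch lambda_crit
(the baseline stretch under a physiological inflation of p_inflate).  A sigmoid
limiter caps the total extent of growth.  Serial sarcomere deposition (growth
along the fibre, theta_f) dilates the cavity while preserving the
wall-thickness-to-radius ratio h/R -- eccentric hypertrophy; parallel
deposition (growth across the fibre, theta_t) thickens the wall -- concentric
hypertrophy, either uniformly or concentrated on the septum through a
rotational weighting.

The load model is a reduced surrogate for a full finite-element inflation: the
cavity volume increment is pressure times a scalar compliance, distributed
through the wall by the incompressible thick-shell map
r(R) = (r_i^3 + R^3 - R_i^3)^(1/3).  Under this map every wall-tangent
direction stretches by r/R and the radial direction by (R/r)^2, so det F = 1
exactly.  The fibre and the in-plane cross-fibre direction are both
wall-tangent; their stretches coincide in the surrogate, and the radial
thinning is reported separately.

Pressures are in mmHg, volumes in ml at the user interface; the growth
protocol runs in normalised time units.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    GeometryParams,
    REGION_RV_FREE,
    REGION_SEPTUM,
    ShellSpec,
    VentricularMesh,
    assign_fibres,
    build_idealized_biventricle,
    compute_ventricular_coordinates,
    truncated_ellipsoid_volume,
)

__all__ = [
    "GrowthParams",
    "GrowthState",
    "StretchField",
    "MassReport",
    "GROWTH_TYPES",
    "inflation_stretch",
    "baseline_critical_stretch",
    "growth_rate",
    "run_growth_cycle",
    "apply_growth_to_geometry",
    "grow_to_threshold",
    "grow_series",
    "lv_mass",
    "mass_index",
    "classify_lvh_by_mass",
    "mass_report",
]

GROWTH_TYPES = ("eccentric", "concentric_symmetric", "concentric_asymmetric")

MYOCARDIAL_DENSITY = 1.053          # g/ml
MASS_INDEX_EXPONENT = 2.7
MASS_INDEX_THRESHOLD_MALE = 51.0    # g m^-2.7


@dataclass(frozen=True)
class GrowthParams:
    """Protocol and rate constants for the growth engine.

    ``k`` is the growth-rate constant per normalised time unit; concentric
    growth uses a larger default because wall thickening raises mass only
    linearly in theta whereas dilation raises it with theta cubed.
    ``compliance`` (ml/mmHg) is the scalar knob of the reduced inflation
    surrogate, sized so that the overload pressure stretches the endocardium
    by roughly 10% above baseline.
    """

    p_inflate: float = 5.0        # mmHg
    p_overload: float = 10.0      # mmHg
    t_increase: float = 100.0     # normalised time units
    t_growth: float = 600.0
    t_decrease: float = 100.0
    dt: float = 1.0
    k_eccentric: float = 6e-4
    k_concentric: float = 2.5e-3
    theta_max: float = 4.0
    gamma: float = 10.0
    compliance: float = 6.0       # ml/mmHg
    inward_fraction: float = 0.7  # share of wall thickening taken inward
    w_min: float = 0.25           # free-wall floor of the septal weighting
    phi_width: float = np.deg2rad(60.0)
    max_cycles: int = 80

    def k_for(self, growth_type: str) -> float:
        return self.k_eccentric if growth_type == "eccentric" else self.k_concentric


@dataclass
class StretchField:
    """Per-element stretches of an incompressible inflation state."""

    lam_f: np.ndarray      # along the fibre (wall-tangent)
    lam_t: np.ndarray      # along the in-plane cross-fibre direction
    lam_rad: np.ndarray    # transmural (radial) direction
    pressure: float        # mmHg

    def stretch_along(self, mesh: VentricularMesh, directions: np.ndarray) -> np.ndarray:
        """|F d| for unit directions d given per element.

        F is diagonal in the local (radial, tangent, tangent) frame with
        entries (lam_rad, lam_tan, lam_tan), lam_tan = lam_f.
        """
        cr = np.einsum("ij,ij->i", directions, mesh.et)
        return np.sqrt(self.lam_rad**2 * cr**2 + self.lam_f**2 * (1.0 - cr**2))

    def det_F(self) -> np.ndarray:
        return self.lam_rad * self.lam_f * self.lam_t


@dataclass
class MassReport:
    tissue_volume: float      # ml (LV wall + septum)
    mass: float               # g
    mass_index: float         # g m^-2.7
    hypertrophy_flag: bool


@dataclass
class GrowthState:
    """Growth multipliers and protocol bookkeeping for one model."""

    growth_type: str
    theta_f: np.ndarray
    theta_t: np.ndarray
    lam_crit: np.ndarray | None
    cycle_count: int
    params: GrowthParams
    healthy_params: GeometryParams
    resolution: tuple
    fibre_angles: tuple

    @classmethod
    def fresh(cls, mesh: VentricularMesh, growth_type: str,
              params: GrowthParams | None = None) -> "GrowthState":
        if growth_type not in GROWTH_TYPES:
            raise ValueError(f"unknown growth type {growth_type!r}")
        if mesh.f0 is None:
            raise ValueError("growth requires a mesh with fibres")
        E = len(mesh.elems)
        return cls(growth_type=growth_type,
                   theta_f=np.ones(E), theta_t=np.ones(E), lam_crit=None,
                   cycle_count=0, params=params or GrowthParams(),
                   healthy_params=mesh.geometry_params,
                   resolution=mesh.resolution,
                   fibre_angles=mesh.fibre_angles or (60.0, -60.0, -65.0, 25.0))

    @property
    def theta_driver(self) -> np.ndarray:
        return self.theta_f if self.growth_type == "eccentric" else self.theta_t


# ---------------------------------------------------------------------------
# inflation surrogate
# ---------------------------------------------------------------------------

def _lv_cavity_and_tissue(mesh: VentricularMesh) -> tuple[float, float]:
    """LV cavity volume (analytic, from geometry params) and LV tissue volume, ml."""
    s = mesh.geometry_params.lv
    vcav = truncated_ellipsoid_volume(s.a_endo, s.c_endo, s.base_z) * 1e6
    lv = mesh.elem_region != REGION_RV_FREE
    vtis = mesh.element_volumes()[lv].sum() * 1e6
    return vcav, vtis


def inflation_stretch(mesh: VentricularMesh, cavity_pressure: float,
                      compliance: float = GrowthParams.compliance) -> StretchField:
    """Stretch field of the incompressible thick-shell inflation surrogate.

    The LV cavity gains a volume ``compliance * pressure``; each LV element is
    assigned an unloaded radius from its transmural coordinate on the
    equivalent spherical shell and stretched by the incompressible map.  RV
    elements are not pressurised and remain unstretched.
    """
    if cavity_pressure < 0:
        raise ValueError("cavity pressure must be non-negative")
    E = len(mesh.elems)
    lam_tan = np.ones(E)
    lam_rad = np.ones(E)
    if cavity_pressure > 0:
        vcav, vtis = _lv_cavity_and_tissue(mesh)
        Ri = (3.0 * vcav / (4 * np.pi)) ** (1 / 3)
        Ro = (3.0 * (vcav + vtis) / (4 * np.pi)) ** (1 / 3)
        dv = compliance * cavity_pressure
        ri3 = Ri**3 + 3.0 * dv / (4 * np.pi)
        coords_t = mesh.elem_coord(mesh.node_u) if mesh.node_u is not None else None
        if coords_t is None:
            raise ValueError("inflation surrogate requires transmural coordinates")
        lv = mesh.elem_region != REGION_RV_FREE
        R = Ri + coords_t[lv] * (Ro - Ri)
        r = (ri3 + R**3 - Ri**3) ** (1 / 3)
        lam_tan[lv] = r / R
        lam_rad[lv] = (R / r) ** 2
    return StretchField(lam_f=lam_tan, lam_t=lam_tan.copy(), lam_rad=lam_rad,
                        pressure=cavity_pressure)


def baseline_critical_stretch(mesh: VentricularMesh,
                              p_inflate: float = GrowthParams.p_inflate,
                              compliance: float = GrowthParams.compliance) -> np.ndarray:
    """Critical stretch field: fibre stretch at the physiological pressure."""
    return inflation_stretch(mesh, p_inflate, compliance).lam_f


# ---------------------------------------------------------------------------
# growth law
# ---------------------------------------------------------------------------

def growth_rate(lam_driver: np.ndarray, lam_crit: np.ndarray, theta: np.ndarray,
                k: float, theta_max: float, gamma: float) -> np.ndarray:
    """d(theta)/dt = k * sigma(theta) * max(lam_driver - lam_crit, 0).

    sigma(theta) = 1 / (1 + exp(gamma * (theta - theta_max))) saturates the
    growth as theta approaches theta_max.
    """
    if theta_max <= 1.0:
        raise ValueError("theta_max must exceed 1")
    sigma = 1.0 / (1.0 + np.exp(gamma * (np.asarray(theta) - theta_max)))
    return k * sigma * np.maximum(np.asarray(lam_driver) - np.asarray(lam_crit), 0.0)


def _protocol_pressure(t: np.ndarray, p: GrowthParams) -> np.ndarray:
    t1, t2 = p.t_increase, p.t_increase + p.t_growth
    t3 = t2 + p.t_decrease
    up = np.clip(t / t1, 0, 1)
    down = np.clip((t3 - t) / p.t_decrease, 0, 1)
    return p.p_overload * np.minimum(up, down) * (t < t3)


def run_growth_cycle(mesh: VentricularMesh, state: GrowthState) -> GrowthState:
    """One pressure-overload experiment: ramp up, hold, ramp down.

    theta is integrated with explicit Euler at fixed step dt while the
    pressure-induced stretch exceeds lambda_crit.  For asymmetric concentric
    growth the rate is additionally weighted by the septal rotational profile
    (the analogue of restricting free-wall stretch).
    """
    if state.lam_crit is None:
        state.lam_crit = baseline_critical_stretch(mesh, state.params.p_inflate,
                                                   state.params.compliance)
    p = state.params
    k = p.k_for(state.growth_type)
    ts = np.arange(0.0, p.t_increase + p.t_growth + p.t_decrease, p.dt)
    pressures = _protocol_pressure(ts, p)

    vcav, vtis = _lv_cavity_and_tissue(mesh)
    Ri = (3.0 * vcav / (4 * np.pi)) ** (1 / 3)
    Ro = (3.0 * (vcav + vtis) / (4 * np.pi)) ** (1 / 3)
    lv = mesh.elem_region != REGION_RV_FREE
    t_e = mesh.elem_coord(mesh.node_u)[lv]
    R = Ri + t_e * (Ro - Ri)
    R3 = R**3

    theta = state.theta_driver.copy()
    th_lv = theta[lv]
    lam_crit = state.lam_crit[lv]
    if state.growth_type == "concentric_asymmetric":
        phi_e = mesh.elem_coord(mesh.node_phi, circular=True)[lv]
        wspec = ShellSpec(a_endo=1, c_endo=1, wall=1, base_z=0,
                          w_min=p.w_min, phi_width=p.phi_width)
        weight = wspec.weighting(phi_e)
    else:
        weight = 1.0

    for press in pressures:
        if press <= 0:
            continue
        dv = p.compliance * press
        ri3 = Ri**3 + 3.0 * dv / (4 * np.pi)
        lam = ((ri3 + R3 - Ri**3) ** (1 / 3)) / R
        th_lv += p.dt * weight * growth_rate(lam, lam_crit, th_lv,
                                             k, p.theta_max, p.gamma)
    if not np.all(np.isfinite(th_lv)):
        raise RuntimeError(
            f"non-finite growth multiplier after cycle {state.cycle_count + 1}; "
            f"min={np.nanmin(th_lv)}, max={np.nanmax(th_lv)}")
    theta[lv] = th_lv
    new = copy.copy(state)
    if state.growth_type == "eccentric":
        new.theta_f = theta
    else:
        new.theta_t = theta
    new.cycle_count = state.cycle_count + 1
    return new


# ---------------------------------------------------------------------------
# geometry update
# ---------------------------------------------------------------------------

def _wall_mean(mesh: VentricularMesh, theta: np.ndarray,
               region_mask: np.ndarray) -> float:
    w = mesh.element_volumes()[region_mask]
    return float(np.average(theta[region_mask], weights=w))


def apply_growth_to_geometry(mesh: VentricularMesh, state: GrowthState) -> VentricularMesh:
    """Regenerate the mesh for the current growth multipliers.

    eccentric: every LV dimension (cavity semi-axes, wall, base height)
    scales with the wall-averaged theta_f, preserving h/R exactly.
    concentric: the wall thickens by (wall-averaged theta_t - 1) * h0, split
    between inward and outward motion; the asymmetric form modulates the
    thickening with the rotational weighting w(phi), referenced to the septal
    average of theta_t.  The RV is left unchanged.  Fibres and coordinates are
    recomputed on the regenerated mesh.
    """
    if not np.all(np.isfinite(state.theta_f)) or not np.all(np.isfinite(state.theta_t)):
        raise ValueError("growth multipliers must be finite")
    hp = state.healthy_params
    lv0 = hp.lv
    lv_mask = mesh.elem_region != REGION_RV_FREE
    p = state.params

    if state.growth_type == "eccentric":
        g = _wall_mean(mesh, state.theta_f, lv_mask)
        lv = replace(lv0, a_endo=lv0.a_endo * g, c_endo=lv0.c_endo * g,
                     wall=lv0.wall * g, base_z=lv0.base_z * g)
    else:
        if state.growth_type == "concentric_symmetric":
            gbar = _wall_mean(mesh, state.theta_t, lv_mask)
            w_min, phi_width = 1.0, lv0.phi_width
        else:
            sept = mesh.elem_region == REGION_SEPTUM
            gbar = _wall_mean(mesh, state.theta_t, sept)
            w_min, phi_width = p.w_min, p.phi_width
        dh = max(gbar - 1.0, 0.0) * lv0.wall
        lv = replace(lv0,
                     thick_in_amp=p.inward_fraction * dh,
                     thick_out_amp=(1.0 - p.inward_fraction) * dh,
                     w_min=w_min, phi_width=phi_width)
        if lv.thick_in_amp >= 0.9 * lv0.a_endo:
            raise RuntimeError("inward wall growth would invert the cavity; "
                               "use a smaller per-cycle growth increment")
    new_params = replace(hp, lv=lv)
    grown = build_idealized_biventricle(new_params, resolution=state.resolution)
    grown = assign_fibres(grown, compute_ventricular_coordinates(grown),
                          *state.fibre_angles)
    return grown


# ---------------------------------------------------------------------------
# mass bookkeeping
# ---------------------------------------------------------------------------

def lv_mass(mesh: VentricularMesh, density: float = MYOCARDIAL_DENSITY
            ) -> tuple[float, float]:
    """LV tissue volume (ml) and mass (g); LV free wall + septum only."""
    lv = mesh.elem_region != REGION_RV_FREE
    vol_ml = float(mesh.element_volumes()[lv].sum() * 1e6)
    return vol_ml, vol_ml * density


def mass_index(mass: float, height: float,
               exponent: float = MASS_INDEX_EXPONENT) -> float:
    """Height-indexed LV mass, g m^-exponent."""
    if height <= 0:
        raise ValueError("height must be positive")
    return mass / height**exponent


def classify_lvh_by_mass(index: float, sex: str = "male",
                         male_threshold: float = MASS_INDEX_THRESHOLD_MALE,
                         female_threshold: float = 47.0) -> bool:
    """Image-based LVH call: true iff the index strictly exceeds the cutoff.

    The male cutoff of 51 g m^-2.7 is standard; the female default is
    configurable and must be checked against the population in use.
    """
    if index < 0:
        raise ValueError("mass index must be non-negative")
    thr = male_threshold if sex == "male" else female_threshold
    return bool(index > thr)


def mass_report(mesh: VentricularMesh, height: float = 1.75,
                sex: str = "male") -> MassReport:
    vol, m = lv_mass(mesh)
    idx = mass_index(m, height)
    return MassReport(tissue_volume=vol, mass=m, mass_index=idx,
                      hypertrophy_flag=classify_lvh_by_mass(idx, sex))


# ---------------------------------------------------------------------------
# driver loops
# ---------------------------------------------------------------------------

def grow_to_threshold(mesh: VentricularMesh, growth_type: str,
                      mass_increase_threshold: float,
                      params: GrowthParams | None = None,
                      height: float = 1.75, sex: str = "male"
                      ) -> tuple[VentricularMesh, GrowthState, MassReport]:
    """Repeat growth cycles until LV mass exceeds the requested increase.

    lambda_crit is recomputed on the grown geometry after every cycle, so the
    homeostatic setpoint tracks the new anatomy.  The overshoot is bounded by
    a single cycle's increment.
    """
    if mass_increase_threshold < 0:
        raise ValueError("mass increase threshold must be >= 0")
    state = GrowthState.fresh(mesh, growth_type, params)
    _, m0 = lv_mass(mesh)
    current = mesh
    if mass_increase_threshold == 0:
        return current, state, mass_report(current, height, sex)
    while True:
        state.lam_crit = baseline_critical_stretch(
            current, state.params.p_inflate, state.params.compliance)
        state = run_growth_cycle(current, state)
        current = apply_growth_to_geometry(current, state)
        _, m = lv_mass(current)
        if m / m0 - 1.0 >= mass_increase_threshold:
            return current, state, mass_report(current, height, sex)
        if state.cycle_count >= state.params.max_cycles:
            raise RuntimeError(
                f"{growth_type}: mass increase {m / m0 - 1.0:.3f} after "
                f"{state.cycle_count} cycles did not reach the threshold "
                f"{mass_increase_threshold}; growth parameters cannot reach it")


def grow_series(mesh: VentricularMesh, growth_type: str,
                thresholds: list[float],
                params: GrowthParams | None = None,
                height: float = 1.75, sex: str = "male"):
    """Snapshot grown models at a sorted list of mass-increase thresholds.

    Growth is deterministic, so growing once and snapshotting when each
    threshold is first exceeded yields the same models as independent
    grow-to-threshold runs.  Yields (threshold, mesh, state, MassReport).
    """
    thresholds = sorted(thresholds)
    state = GrowthState.fresh(mesh, growth_type, params)
    _, m0 = lv_mass(mesh)
    current = mesh
    pending = list(thresholds)
    while pending and pending[0] == 0:
        yield 0.0, current, state, mass_report(current, height, sex)
        pending.pop(0)
    while pending:
        state.lam_crit = baseline_critical_stretch(
            current, state.params.p_inflate, state.params.compliance)
        state = run_growth_cycle(current, state)
        current = apply_growth_to_geometry(current, state)
        _, m = lv_mass(current)
        ratio = m / m0 - 1.0
        while pending and ratio >= pending[0]:
            yield pending[0], current, state, mass_report(current, height, sex)
            pending.pop(0)
        if pending and state.cycle_count >= state.params.max_cycles:
            raise RuntimeError(
                f"{growth_type}: stalled at mass increase {ratio:.3f} after "
                f"{state.cycle_count} cycles; cannot reach {pending[0]}")
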