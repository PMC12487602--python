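"""ECG forward model: template, dipole sum, lead algebra, BSPM."""

import numpy as np
import pytest

from lvhsim import activation as act, ecg_forward as fwd, geometry as geo


def _simple_amap(n, lat):
    return act.ActivationMap(lat=np.asarray(lat, float),
                             source_nodes=np.array([0]),
                             source_times=np.array([0.0]))


# ---------------------------------------------------------------------------
# action-potential template / movie
# ---------------------------------------------------------------------------

def test_movie_resting_and_plateau_limits(rod_mesh):
    lat = np.linspace(10, 40, len(rod_mesh.nodes))
    times, vm = fwd.transmembrane_movie(_simple_amap(len(lat), lat),
                                        dt_ms=0.5, pad_ms=30.0)
    tpl = fwd.ActionPotentialTemplate()
    assert np.all(np.abs(tpl(np.array([-30.0])) - (-85.0)) < 1e-6)
    assert np.all(np.abs(tpl(np.array([60.0])) - 25.0) < 1e-6)
    assert vm.max() <= 25.0 + 1e-9 and vm.min() >= -85.0 - 1e-9


def test_template_midpoint_at_lat_plus_half_upstroke():
    """Vm crosses -30 mV (the -85/+25 midpoint) at LAT + upstroke/2."""
    tpl = fwd.ActionPotentialTemplate(upstroke_ms=2.0)
    assert tpl(np.array([1.0]))[0] == pytest.approx(-30.0, abs=1e-9)
    lat = 30.0
    t = np.linspace(0, 60, 6001)
    vm = tpl(t - lat)
    crossing = t[np.argmin(np.abs(vm - (-30.0)))]
    assert crossing == pytest.approx(31.0, abs=0.01)


def test_template_monotone_upstroke():
    tpl = fwd.ActionPotentialTemplate()
    tau = np.linspace(-10, 10, 400)
    v = tpl(tau)
    assert np.all(np.diff(v) >= 0)                 # flat only in saturated tails
    mid = (tau > -1) & (tau < 3)
    assert np.all(np.diff(v[mid]) > 0)


# ---------------------------------------------------------------------------
# extracellular potentials
# ---------------------------------------------------------------------------

def test_uniform_vm_gives_zero_potential(rod_mesh):
    vm = np.full((len(rod_mesh.nodes), 3), -85.0)
    pts = np.array([[0.2, 0.0, 0.0]])
    phi = fwd.extracellular_potentials(vm, rod_mesh, None, pts)
    assert np.allclose(phi, 0.0, atol=1e-12)


def test_planar_front_antisymmetric_potentials(rod_mesh):
    """A half-depolarised bar seen from mirror points: equal magnitude,
    opposite sign."""
    x = rod_mesh.nodes[:, 0]
    vm = np.where(x < 0.03, 25.0, -85.0)[:, None]
    center = _dipole_centroid(rod_mesh, vm)
    offset = np.array([0.3, 0.0, 0.0])   # far compared with the front extent
    pts = np.vstack([center + offset, center - offset])
    phi = fwd.extracellular_potentials(vm, rod_mesh, None, pts)
    assert phi[0, 0] == pytest.approx(-phi[1, 0], rel=0.02)
    assert abs(phi[0, 0]) > 0


def _dipole_centroid(mesh, vm):
    cond = fwd.ConductivitySet()
    grads = fwd._element_gradients(mesh)
    G = fwd._intracellular_tensor(mesh, cond)
    vol = mesh.element_volumes()
    gvm = np.einsum("eid,eit->edt", grads, vm[mesh.elems])
    p = (-vol[:, None, None] * np.einsum("eij,ejt->eit", G, gvm))[:, :, 0]
    w = np.abs(p).sum(axis=1)
    return (mesh.element_centroids() * w[:, None]).sum(axis=0) / w.sum()


def test_point_dipole_closed_form(rod_mesh):
    """A single compact source matches |p|/(4 pi sigma r^2) on axis to 1%."""
    cond = fwd.ConductivitySet()
    vm = np.full((len(rod_mesh.nodes), 1), -85.0)
    # depolarise one end: the net dipole is sum of element dipoles
    x = rod_mesh.nodes[:, 0]
    vm[x < 0.005, 0] = 25.0
    grads = fwd._element_gradients(rod_mesh)
    G = fwd._intracellular_tensor(rod_mesh, cond)
    vol = rod_mesh.element_volumes()
    gvm = np.einsum("eid,eit->edt", grads, vm[rod_mesh.elems])
    p = (-vol[:, None, None] * np.einsum("eij,ejt->eit", G, gvm))[:, :, 0]
    p_net = p.sum(axis=0)
    w = np.abs(p).sum(axis=1)
    src = (rod_mesh.element_centroids() * w[:, None]).sum(axis=0) / w.sum()
    r = 0.5                                    # far compared with source extent
    pt = src + np.array([r, 0.0, 0.0])
    phi = fwd.extracellular_potentials(vm, rod_mesh, cond, pt[None])[0, 0]
    expected = p_net[0] / (4 * np.pi * cond.sigma_torso * r**2)
    assert phi == pytest.approx(expected, rel=0.01)


def test_far_field_inverse_square_decay(rod_mesh):
    x = rod_mesh.nodes[:, 0]
    vm = np.where(x < 0.01, 25.0, -85.0)[:, None]
    src = np.array([0.01, 0.005, 0.005])
    r1, r2 = 0.4, 0.8
    pts = np.vstack([src + [r1, 0, 0], src + [r2, 0, 0]])
    phi = fwd.extracellular_potentials(vm, rod_mesh, None, pts)
    ratio = phi[0, 0] / phi[1, 0]
    assert ratio == pytest.approx((r2 / r1) ** 2, rel=0.10)


def test_point_inside_tissue_rejected(rod_mesh):
    vm = np.full((len(rod_mesh.nodes), 1), -85.0)
    with pytest.raises(ValueError, match="inside"):
        fwd.extracellular_potentials(vm, rod_mesh, None,
                                     np.array([[0.03, 0.005, 0.005]]))


# ---------------------------------------------------------------------------
# lead derivation and scaling
# ---------------------------------------------------------------------------

def test_lead_definitions_constant_inputs():
    n = 5
    pots = {k: np.zeros(n) for k in ("RA", "LA", "LL",
                                     "V1", "V2", "V3", "V4", "V5", "V6")}
    pots["LA"] = np.ones(n)
    ecg = fwd.derive_12lead(pots, fs=500.0)
    assert np.allclose(ecg.leads["I"], 1.0)
    assert np.allclose(ecg.leads["II"], 0.0)
    assert np.allclose(ecg.leads["III"], -1.0)
    ecg.validate_identities()


def test_all_equal_electrodes_give_zero_leads():
    pots = {k: np.full(4, 3.7) for k in ("RA", "LA", "LL",
                                         "V1", "V2", "V3", "V4", "V5", "V6")}
    ecg = fwd.derive_12lead(pots, fs=500.0)
    assert all(np.allclose(v, 0.0) for v in ecg.leads.values())


def test_lead_identities_hold_for_random_inputs():
    rng = np.random.default_rng(7)
    pots = {k: rng.normal(size=64) for k in ("RA", "LA", "LL",
                                             "V1", "V2", "V3", "V4", "V5", "V6")}
    ecg = fwd.derive_12lead(pots, fs=500.0)
    ecg.validate_identities()


def test_scale_ecg_composition():
    pots = {k: np.linspace(-1, 1, 8) for k in ("RA", "LA", "LL",
                                               "V1", "V2", "V3", "V4", "V5", "V6")}
    pots["V5"] = np.array([10.0] * 8)
    ecg = fwd.derive_12lead(pots, fs=500.0)
    once = fwd.scale_ecg(fwd.scale_ecg(ecg, 0.5), 0.5)
    direct = fwd.scale_ecg(ecg, 0.25)
    assert np.allclose(once.leads["V5"], direct.leads["V5"])
    scaled = fwd.scale_ecg(ecg, 0.28)
    assert scaled.leads["V5"][0] == pytest.approx(0.28 * ecg.leads["V5"][0])
    with pytest.raises(ValueError):
        fwd.scale_ecg(ecg, 0.0)


# ---------------------------------------------------------------------------
# BSPM
# ---------------------------------------------------------------------------

def test_bspm_zero_before_and_after_activation(rod_mesh):
    lat = np.full(len(rod_mesh.nodes), 20.0)
    times, vm = fwd.transmembrane_movie(_simple_amap(len(lat), lat), dt_ms=1.0)
    grid = np.array([[0.3, 0.0, 0.0], [-0.3, 0.0, 0.0]])
    frames = fwd.bspm(vm, rod_mesh, None, grid, times,
                      [times[0], times[-1]])
    assert np.allclose(frames[times[0]], 0.0, atol=1e-9)
    assert np.allclose(frames[times[-1]], 0.0, atol=1e-9)


def test_closed_grid_dipole_sum_near_zero(rod_mesh):
    """Potentials summed over a symmetric closed shell around a central
    dipole cancel to within 1% of their absolute sum."""
    x = rod_mesh.nodes[:, 0]
    vm = np.where(x < 0.03, 25.0, -85.0)[:, None]
    center = np.array([0.03, 0.005, 0.005])
    R = 0.5
    u = np.linspace(-1 + 1e-3, 1 - 1e-3, 24)
    th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    U, TH = np.meshgrid(u, th, indexing="ij")
    pts = center + R * np.column_stack([
        U.ravel(), np.sqrt(1 - U.ravel()**2) * np.cos(TH.ravel()),
        np.sqrt(1 - U.ravel()**2) * np.sin(TH.ravel())])
    phi = fwd.extracellular_potentials(vm, rod_mesh, None, pts,
                                       check_points=False)[:, 0]
    assert abs(phi.sum()) < 0.01 * np.abs(phi).sum()
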