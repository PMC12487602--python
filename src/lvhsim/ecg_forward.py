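"""From activation map to 12-lead ECG.

The transmembrane voltage at each node is an action-potential upstroke
template shifted to its local activation time.  Extracellular potentials are
computed with an infinite homogeneous volume-conductor source sum: each
tetrahedron contributes a current dipole p = -V_e * sigma_i grad(Vm) (linear
shape functions, centroid source location, sigma_i the intracellular
conductivity tensor in fibre coordinates), and

    phi_e(y, t) = 1/(4 pi sigma_bath) sum_e  p_e(t) . (y - x_e) / |y - x_e|^3

with sigma_bath the bulk torso conductivity.  The bounded, heterogeneous
torso of a full pseudo-bidomain solve is deliberately not modelled; the
infinite-conductor sum preserves the dipolar far field (1/r^2 decay) that
drives the lead-amplitude behaviour of interest.  Standard Einthoven /
Goldberger / Wilson definitions turn the nine electrode potentials into the
12 leads, and a global scaling factor (default 0.28) calibrates simulated
amplitudes against a measured R wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ActivationMap
from .geometry import ElectrodeSet, VentricularMesh

__all__ = [
    "ActionPotentialTemplate",
    "ConductivitySet",
    "ECG12",
    "LEAD_NAMES",
    "transmembrane_movie",
    "extracellular_potentials",
    "derive_12lead",
    "scale_ecg",
    "bspm",
    "simulate_ecg12",
]

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class ActionPotentialTemplate:
    """Sigmoidal depolarisation upstroke (repolarisation is out of scope).

    The logistic midpoint sits half an upstroke after the activation time, so
    Vm crosses the midpoint voltage (-30 mV for the default -85/+25 range)
    exactly at LAT + upstroke/2.
    """

    v_rest: float = -85.0         # mV
    v_plateau: float = 25.0       # mV
    upstroke_ms: float = 2.0
    steepness: float = 8.0        # logistic slope scale, per upstroke

    def __call__(self, tau_ms: np.ndarray) -> np.ndarray:
        x = self.steepness * (np.asarray(tau_ms) - self.upstroke_ms / 2) / self.upstroke_ms
        return self.v_rest + (self.v_plateau - self.v_rest) / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ConductivitySet:
    """Monodomain/bidomain conductivities (S/m).

    Only the intracellular tensor and the torso bulk value enter the
    infinite-conductor source model; the extracellular and blood values are
    carried for documentation and future bounded-torso extensions.
    """

    sigma_il: float = 0.34
    sigma_it: float = 0.6
    sigma_in: float = 0.6
    sigma_el: float = 0.12
    sigma_et: float = 0.8
    sigma_en: float = 0.8
    sigma_blood: float = 0.7
    sigma_torso: float = 0.22

    def __post_init__(self):
        vals = (self.sigma_il, self.sigma_it, self.sigma_in, self.sigma_el,
                self.sigma_et, self.sigma_en, self.sigma_blood, self.sigma_torso)
        if min(vals) <= 0:
            raise ValueError("conductivities must be positive")


@dataclass
class ECG12:
    """12 named lead traces (mV), uniformly sampled; t = 0 is QRS onset."""

    leads: dict[str, np.ndarray]
    fs: float                    # Hz
    scale_factor: float = 1.0

    @property
    def time_ms(self) -> np.ndarray:
        n = len(next(iter(self.leads.values())))
        return np.arange(n) * 1000.0 / self.fs

    def stack(self) -> np.ndarray:
        return np.vstack([self.leads[k] for k in LEAD_NAMES])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.time_ms})
        for k in LEAD_NAMES:
            df[k] = self.leads[k]
        return df

    def validate_identities(self, atol: float = 1e-9):
        lead = self.leads
        if not np.allclose(lead["I"] + lead["III"], lead["II"], atol=atol):
            raise AssertionError("Einthoven identity I + III = II violated")
        s = lead["aVR"] + lead["aVL"] + lead["aVF"]
        if not np.allclose(s, 0.0, atol=atol):
            raise AssertionError("augmented leads do not sum to zero")


# ---------------------------------------------------------------------------

def transmembrane_movie(activation_map: ActivationMap,
                        template: ActionPotentialTemplate | None = None,
                        dt_ms: float = 1.0,
                        pad_ms: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Vm(node, t) in mV; returns (times_ms, Vm[N, T]).

    The time base starts at the earliest initiation time (QRS onset) and
    covers the last activation plus the full upstroke.
    """
    template = template or ActionPotentialTemplate()
    lat = activation_map.lat
    if not np.all(np.isfinite(lat)):
        raise ValueError("activation map contains non-finite LATs")
    t0 = float(lat.min())
    t1 = float(lat.max()) + template.upstroke_ms + pad_ms
    times = np.arange(t0, t1 + dt_ms, dt_ms)
    vm = template(times[None, :] - lat[:, None])
    return times, vm


def _element_gradients(mesh: VentricularMesh) -> np.ndarray:
    """P1 shape-function gradients, (E, 4, 3)."""
    x = mesh.nodes[mesh.elems]
    vol = mesh.element_volumes()
    grads = np.empty((len(mesh.elems), 4, 3))
    for i in range(4):
        others = [j for j in range(4) if j != i]
        a, b, c = x[:, others[0]], x[:, others[1]], x[:, others[2]]
        nvec = np.cross(b - a, c - a)
        s = np.sign(np.einsum("ij,ij->i", x[:, i] - a, nvec))
        s[s == 0] = 1.0
        grads[:, i] = nvec * s[:, None] / (6.0 * vol)[:, None]
    return grads


def _intracellular_tensor(mesh: VentricularMesh, cond: ConductivitySet) -> np.ndarray:
    if mesh.f0 is None:
        raise ValueError("conductivity tensor requires fibre triads")
    return (cond.sigma_il * np.einsum("ei,ej->eij", mesh.f0, mesh.f0)
            + cond.sigma_it * np.einsum("ei,ej->eij", mesh.s0, mesh.s0)
            + cond.sigma_in * np.einsum("ei,ej->eij", mesh.n0, mesh.n0))


def _check_points_outside(mesh: VentricularMesh, points: np.ndarray):
    """Reject evaluation points that fall inside a tetrahedron."""
    from scipy.spatial import cKDTree
    cents = mesh.element_centroids()
    sizes = np.abs(mesh.element_volumes()) ** (1 / 3)
    tree = cKDTree(cents)
    k = min(12, len(cents))
    dist, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    x = mesh.nodes[mesh.elems]
    for pi, row in enumerate(idx):
        near = row[dist[pi] < 4 * sizes[row]] if k > 1 else row
        for e in np.atleast_1d(near):
            v0 = x[e, 0]
            T = np.column_stack([x[e, 1] - v0, x[e, 2] - v0, x[e, 3] - v0])
            try:
                lam = np.linalg.solve(T, points[pi] - v0)
            except np.linalg.LinAlgError:
                continue
            if lam.min() >= -1e-9 and lam.sum() <= 1 + 1e-9:
                raise ValueError(f"evaluation point {pi} lies inside the myocardium")


def extracellular_potentials(vm: np.ndarray, mesh: VentricularMesh,
                             conductivities: ConductivitySet | None = None,
                             points: np.ndarray | None = None,
                             check_points: bool = True) -> np.ndarray:
    """phi_e(point, t) in mV via the infinite-conductor dipole sum.

    ``vm`` is (N, T) in mV; ``points`` is (P, 3) in metres, outside the
    tissue.  Returns (P, T).
    """
    cond = conductivities or ConductivitySet()
    points = np.atleast_2d(np.asarray(points, float))
    if check_points:
        _check_points_outside(mesh, points)
    grads = _element_gradients(mesh)                       # (E,4,3)
    G = _intracellular_tensor(mesh, cond)                  # (E,3,3)
    vol = mesh.element_volumes()
    cents = mesh.element_centroids()
    # dipole moment: p_e(t) = -V_e * G_e . grad(Vm)_e(t); with Vm in mV the
    # result is directly in mV: (S/m * mV/m * m^3) / (S/m * m^2) = mV.
    grad_vm = np.einsum("eid,eit->edt", grads, vm[mesh.elems])   # (E,3,T)
    p = -vol[:, None, None] * np.einsum("eij,ejt->eit", G, grad_vm)  # (E,3,T)
    rvec = points[:, None, :] - cents[None, :, :]          # (P,E,3)
    r = np.linalg.norm(rvec, axis=2)
    kernel = rvec / r[:, :, None] ** 3                     # (P,E,3)
    return np.einsum("ped,edt->pt", kernel, p) / (4 * np.pi * cond.sigma_torso)


def derive_12lead(electrode_potentials: dict[str, np.ndarray], fs: float) -> ECG12:
    """Standard 12 leads from the 9 electrode potentials.

    I = LA - RA, II = LL - RA, III = LL - LA; augmented leads reference the
    mean of the two remaining limb electrodes; precordial leads reference the
    Wilson central terminal (RA + LA + LL)/3.
    """
    need = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")
    missing = [k for k in need if k not in electrode_potentials]
    if missing:
        raise ValueError(f"missing electrode traces: {missing}")
    ra, la, ll = (np.asarray(electrode_potentials[k], float) for k in ("RA", "LA", "LL"))
    wct = (ra + la + ll) / 3.0
    leads = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for i in range(1, 7):
        leads[f"V{i}"] = np.asarray(electrode_potentials[f"V{i}"], float) - wct
    return ECG12(leads=leads, fs=fs)


def scale_ecg(ecg: ECG12, factor: float = 0.28) -> ECG12:
    """Multiply every lead by a calibration factor (recorded in metadata)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return ECG12(leads={k: v * factor for k, v in ecg.leads.items()},
                 fs=ecg.fs, scale_factor=ecg.scale_factor * factor)


def bspm(vm: np.ndarray, mesh: VentricularMesh,
         conductivities: ConductivitySet | None, grid: np.ndarray,
         times_ms: np.ndarray, frame_times_ms: list[float]) -> dict[float, np.ndarray]:
    """Body-surface potential frames on a torso grid at selected times."""
    idx = [int(np.argmin(np.abs(times_ms - ft))) for ft in frame_times_ms]
    phi = extracellular_potentials(vm[:, idx], mesh, conductivities, grid)
    return {float(ft): phi[:, k] for k, ft in enumerate(frame_times_ms)}


def simulate_ecg12(mesh: VentricularMesh, activation_map: ActivationMap,
                   electrodes: ElectrodeSet,
                   template: ActionPotentialTemplate | None = None,
                   conductivities: ConductivitySet | None = None,
                   dt_ms: float = 1.0, scale_factor: float = 0.28) -> ECG12:
    """Activation map -> scaled 12-lead ECG at the standard electrodes."""
    electrodes.require_complete()
    times, vm = transmembrane_movie(activation_map, template, dt_ms)
    names = list(electrodes.positions)
    pts = np.vstack([electrodes.positions[k] for k in names])
    phi = extracellular_potentials(vm, mesh, conductivities, pts)
    traces = {k: phi[i] for i, k in enumerate(names)}
    ecg = derive_12lead(traces, fs=1000.0 / dt_ms)
    return scale_ecg(ecg, scale_factor)
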