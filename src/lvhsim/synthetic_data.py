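"""Synthetic inputs: 12-lead ECG cohorts and small fixture meshes.

The cohort generator emulates 500 Hz clinical 12-lead records in two groups
(control vs LVH).  Each lead is a train of QRS complexes -- a positive R
Gaussian minus a delayed S Gaussian, with a lead-specific polarity mix --
plus baseline wander, 50 Hz powerline interference and white noise.  Record
amplitudes are lognormally distributed around lead-specific medians; the LVH
cohort multiplies lead i by a scale factor s_i, so the population value of
the cohort statistic D_i is s_i - 1 by construction.  The default scale
factors encode the lead-sensitivity pattern reported for large clinical LVH
cohorts (aVL most affected, then III and V1, with I/V5/V6 above +50%).

Everything is reproducible: per-record generators are spawned from the master
seed with ``numpy.random.SeedSequence`` so records are independent and the
whole cohort is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg_forward import ECG12, LEAD_NAMES
from . import geometry as geo
from . import growth as gro

__all__ = [
    "SynthCohortSpec",
    "SynthRecord",
    "DEFAULT_LEAD_MEDIANS",
    "DEFAULT_LVH_SCALES",
    "synth_record",
    "synth_cohort",
    "fixture_mesh_resolution",
    "fixture_healthy_mesh",
    "fixture_grown_meshes",
]

# typical max |QRS| per lead in a normal adult ECG, mV
DEFAULT_LEAD_MEDIANS = {
    "I": 0.8, "II": 1.0, "III": 0.5, "aVR": 0.7, "aVL": 0.4, "aVF": 0.7,
    "V1": 0.9, "V2": 1.5, "V3": 1.3, "V4": 1.2, "V5": 1.1, "V6": 0.9,
}

# LVH-to-control amplitude ratios per lead (population D_i = s_i - 1)
DEFAULT_LVH_SCALES = {
    "aVL": 1.937, "III": 1.773, "V1": 1.69,
    "I": 1.55, "V5": 1.52, "V6": 1.50,
    "aVR": 1.30, "II": 1.20, "aVF": 1.25,
    "V2": 1.35, "V3": 1.30, "V4": 1.40,
}

# share of the R (positive) deflection in each lead's QRS template
_R_FRACTION = {
    "I": 0.8, "II": 0.85, "III": 0.7, "aVR": 0.2, "aVL": 0.65, "aVF": 0.8,
    "V1": 0.25, "V2": 0.35, "V3": 0.5, "V4": 0.65, "V5": 0.8, "V6": 0.85,
}


@dataclass(frozen=True)
class SynthCohortSpec:
    """Study conditions for a synthetic two-cohort ECG data set."""

    n_ctrl: int = 50
    n_lvh: int = 50
    fs: float = 500.0                 # Hz
    beats: int = 3
    beat_interval_s: float = 0.8
    lead_medians: dict = field(default_factory=lambda: dict(DEFAULT_LEAD_MEDIANS))
    lvh_scales: dict = field(default_factory=lambda: dict(DEFAULT_LVH_SCALES))
    sigma_log: float = 0.30           # lognormal spread of record amplitudes
    sigma_log_lead: float = 0.10      # extra per-lead spread
    r_width_ms: float = 12.0          # FWHM-ish width of the R Gaussian
    s_delay_ms: float = 14.0
    noise_white_mv: float = 0.01
    wander_amp_mv: float = 0.10
    wander_freq_hz: float = 0.33
    powerline_amp_mv: float = 0.02
    powerline_freq_hz: float = 50.0
    seed: int = 0

    @property
    def duration_s(self) -> float:
        return self.beats * self.beat_interval_s + 0.4


@dataclass
class SynthRecord:
    """One synthetic record plus ground-truth sidecar metadata."""

    ecg: ECG12
    cohort: str                         # 'ctrl' or 'lvh'
    truth_max_abs: dict[str, float]     # noiseless per-lead max |amplitude|
    beat_samples: np.ndarray            # sample index of each R peak
    seed_entropy: tuple


def _qrs_template(t_ms: np.ndarray, amp: float, r_frac: float,
                  r_width_ms: float, s_delay_ms: float) -> np.ndarray:
    """Difference-of-Gaussians QRS: R deflection minus delayed S deflection.

    ``amp`` sets the larger of the two deflections; ``r_frac`` the polarity
    mix (1 = purely positive).
    """
    sd = r_width_ms / 2.355
    r_amp = amp if r_frac >= 0.5 else amp * r_frac / (1 - r_frac)
    s_amp = amp * (1 - r_frac) / r_frac if r_frac >= 0.5 else amp
    r = r_amp * np.exp(-0.5 * (t_ms / sd) ** 2)
    s = s_amp * np.exp(-0.5 * ((t_ms - s_delay_ms) / sd) ** 2)
    return r - s


def synth_record(spec: SynthCohortSpec, cohort: str,
                 rng: np.random.Generator | None = None) -> SynthRecord:
    """Generate one 12-lead record for the given cohort."""
    if cohort not in ("ctrl", "lvh"):
        raise ValueError("cohort must be 'ctrl' or 'lvh'")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = int(round(spec.duration_s * spec.fs))
    t_s = np.arange(n) / spec.fs
    beat_t = (np.arange(spec.beats) + 0.5) * spec.beat_interval_s
    beat_samples = np.round(beat_t * spec.fs).astype(int)

    size_factor = np.exp(rng.normal(0.0, spec.sigma_log))
    clean = {}
    truth = {}
    for k in LEAD_NAMES:
        amp = (spec.lead_medians[k] * size_factor
               * np.exp(rng.normal(0.0, spec.sigma_log_lead)))
        if cohort == "lvh":
            amp *= spec.lvh_scales[k]
        x = np.zeros(n)
        for bt in beat_t:
            x += _qrs_template((t_s - bt) * 1000.0, amp, _R_FRACTION[k],
                               spec.r_width_ms, spec.s_delay_ms)
        clean[k] = x
        truth[k] = float(np.abs(x).max())

    leads = {}
    for k in LEAD_NAMES:
        noise = rng.normal(0.0, spec.noise_white_mv, n) if spec.noise_white_mv > 0 else 0.0
        wander = (spec.wander_amp_mv
                  * np.sin(2 * np.pi * spec.wander_freq_hz * t_s + rng.uniform(0, 2 * np.pi))
                  if spec.wander_amp_mv > 0 else 0.0)
        mains = (spec.powerline_amp_mv
                 * np.sin(2 * np.pi * spec.powerline_freq_hz * t_s + rng.uniform(0, 2 * np.pi))
                 if spec.powerline_amp_mv > 0 else 0.0)
        leads[k] = clean[k] + noise + wander + mains
    ecg = ECG12(leads=leads, fs=spec.fs)
    return SynthRecord(ecg=ecg, cohort=cohort, truth_max_abs=truth,
                       beat_samples=beat_samples, seed_entropy=(spec.seed,))


def synth_cohort(spec: SynthCohortSpec) -> tuple[list[SynthRecord], pd.DataFrame]:
    """Reproducible two-cohort data set.

    Per-record generators are spawned from the master seed; the labels frame
    has columns ``record`` and ``cohort`` and records the seed in its attrs.
    """
    if spec.n_ctrl < 1 or spec.n_lvh < 1:
        raise ValueError("both cohorts need at least one record")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_ctrl + spec.n_lvh)
    records = []
    rows = []
    for i, child in enumerate(children):
        cohort = "ctrl" if i < spec.n_ctrl else "lvh"
        rec = synth_record(spec, cohort, np.random.default_rng(child))
        rec.seed_entropy = (spec.seed, i)
        records.append(rec)
        rows.append({"record": f"rec{i:04d}", "cohort": cohort})
    labels = pd.DataFrame(rows).set_index("record")
    labels.attrs["seed"] = spec.seed
    return records, labels["cohort"]


# ---------------------------------------------------------------------------
# fixture meshes
# ---------------------------------------------------------------------------

def fixture_mesh_resolution() -> tuple:
    """Coarse structured resolution used by desk-scale fixtures (<5k tets)."""
    return ((2, 6, 14), (2, 6, 14))


def fixture_healthy_mesh() -> geo.VentricularMesh:
    """Coarse healthy biventricle with fibres, regenerated deterministically."""
    mesh = geo.build_idealized_biventricle(resolution=fixture_mesh_resolution())
    return geo.assign_fibres(mesh, geo.compute_ventricular_coordinates(mesh))


def fixture_grown_meshes(level: float = 0.5) -> dict[str, geo.VentricularMesh]:
    """One pre-grown coarse mesh per growth type at the given mass increase."""
    healthy = fixture_healthy_mesh()
    out = {}
    for gt in gro.GROWTH_TYPES:
        mesh, _, _ = gro.grow_to_threshold(healthy, gt, level)
        out[gt] = mesh
    return out
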