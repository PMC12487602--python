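"""Plain-text I/O: legacy VTK, cardiac triple (pts/elem/lon), ECG CSV, JSON.

The VTK writer emits legacy ASCII unstructured grids readable by ParaView and
friends.  The "cardiac triple" mirrors the nodes/elements/fibres layout common
in cardiac simulation toolchains: ``.pts`` (count, then x y z per line, in um),
``.elem`` (count, then ``Tt n0 n1 n2 n3 region``), ``.lon`` (fibre and sheet
vectors per element).  Node and element indices are 0-based everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg_forward import ECG12, LEAD_NAMES
from .geometry import ElectrodeSet, VentricularMesh

__all__ = [
    "write_vtk",
    "write_cardiac_triple",
    "read_cardiac_triple",
    "write_electrodes_json",
    "read_electrodes_json",
    "write_ecg_csv",
    "read_ecg_csv",
]


def write_vtk(mesh: VentricularMesh, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None):
    """Legacy ASCII VTK unstructured grid (tetrahedra, cell type 10)."""
    path = Path(path)
    n, e = mesh.nodes, mesh.elems
    lines = ["# vtk DataFile Version 3.0", "lvhsim mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(n)} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in n]
    lines.append(f"CELLS {len(e)} {5 * len(e)}")
    lines += ["4 " + " ".join(map(str, row)) for row in e]
    lines.append(f"CELL_TYPES {len(e)}")
    lines += ["10"] * len(e)

    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.elem_region)
    if cell_data:
        lines.append(f"CELL_DATA {len(e)}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
    if point_data:
        lines.append(f"POINT_DATA {len(n)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in arr]
    path.write_text("\n".join(lines) + "\n")


def write_cardiac_triple(mesh: VentricularMesh, stem: str | Path):
    """Write ``stem.pts`` / ``stem.elem`` / ``stem.lon`` (coordinates in um)."""
    stem = Path(stem)
    pts = mesh.nodes * 1e6
    with open(stem.with_suffix(".pts"), "w") as f:
        f.write(f"{len(pts)}\n")
        for p in pts:
            f.write(f"{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
    with open(stem.with_suffix(".elem"), "w") as f:
        f.write(f"{len(mesh.elems)}\n")
        for row, reg in zip(mesh.elems, mesh.elem_region):
            f.write("Tt " + " ".join(map(str, row)) + f" {int(reg)}\n")
    with open(stem.with_suffix(".lon"), "w") as f:
        f.write("2\n")
        if mesh.f0 is None:
            for _ in range(len(mesh.elems)):
                f.write("1 0 0 0 1 0\n")
        else:
            for fv, sv in zip(mesh.f0, mesh.s0):
                f.write(" ".join(f"{v:.6f}" for v in (*fv, *sv)) + "\n")


def read_cardiac_triple(stem: str | Path) -> VentricularMesh:
    """Read a cardiac triple back into a mesh (no parametric metadata).

    Surfaces are re-derived from the boundary; ventricular coordinates for
    such meshes come from the Laplace fallback.
    """
    from .geometry import _extract_boundary  # shared boundary extraction

    stem = Path(stem)
    with open(stem.with_suffix(".pts")) as f:
        npts = int(f.readline())
        nodes = np.loadtxt(f, max_rows=npts) * 1e-6
    with open(stem.with_suffix(".elem")) as f:
        ne = int(f.readline())
        elems = np.empty((ne, 4), dtype=int)
        regions = np.empty(ne, dtype=np.int8)
        for i in range(ne):
            parts = f.readline().split()
            elems[i] = [int(v) for v in parts[1:5]]
            regions[i] = int(parts[5])
    f0 = s0 = None
    lon = stem.with_suffix(".lon")
    if lon.exists():
        with open(lon) as f:
            f.readline()
            arr = np.loadtxt(f)
        f0, s0 = arr[:, :3], arr[:, 3:6]
    from .geometry import REGION_RV_FREE
    mesh = VentricularMesh(
        nodes=nodes, elems=elems, elem_region=regions,
        elem_chamber=(regions == REGION_RV_FREE).astype(np.int8),
        surfaces={"boundary": _extract_boundary(elems)})
    if f0 is not None:
        mesh.f0, mesh.s0 = f0, s0
        mesh.n0 = np.cross(f0, s0)
    return mesh


def write_electrodes_json(electrodes: ElectrodeSet, path: str | Path):
    data = {k: list(map(float, v)) for k, v in electrodes.positions.items()}
    out = {"positions": data}
    if electrodes.bspm_grid is not None:
        out["bspm_grid"] = electrodes.bspm_grid.tolist()
    Path(path).write_text(json.dumps(out, indent=1))


def read_electrodes_json(path: str | Path) -> ElectrodeSet:
    data = json.loads(Path(path).read_text())
    grid = np.asarray(data["bspm_grid"]) if "bspm_grid" in data else None
    return ElectrodeSet(
        positions={k: np.asarray(v, float) for k, v in data["positions"].items()},
        bspm_grid=grid)


def write_ecg_csv(ecg: ECG12, path: str | Path):
    """One column per lead (header exactly I,II,...,V6), time in ms, mV."""
    ecg.to_frame().to_csv(path, index=False)


def read_ecg_csv(path: str | Path) -> ECG12:
    df = pd.read_csv(path)
    missing = [k for k in LEAD_NAMES if k not in df.columns]
    if missing:
        raise ValueError(f"ECG CSV missing leads: {missing}")
    t = df["time_ms"].to_numpy()
    if len(t) < 2:
        raise ValueError("ECG CSV must contain at least two samples")
    fs = 1000.0 / float(np.median(np.diff(t)))
    return ECG12(leads={k: df[k].to_numpy(float) for k in LEAD_NAMES}, fs=fs)
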