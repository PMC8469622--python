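"""File formats: OVF 2.0 magnetization snapshots, CSV/JSON helpers.

OVF (OOMMF Vector Field) 2.0 text is the lingua franca of micromagnetic
codes; snapshots written here load in OOMMF/mumax viewers.  Loop and trace
CSVs live on the objects themselves (``HysteresisLoop.to_csv``,
``ThermometryTrace.to_csv``); JSON sidecars carry geometry and loop-property
metadata in explicit units (keys suffixed _nm, _kA_per_m, _kJ_per_m3).
"""

from __future__ import annotations

import json

import numpy as np

from .geometry import DiscretizedGeometry

__all__ = ["write_ovf", "read_ovf", "properties_json"]


def write_ovf(path, m: np.ndarray, geom: DiscretizedGeometry,
              title: str = "cubemag snapshot", valueunits: str = "1") -> None:
    """Write a vector field (nx, ny, nz, 3) as OVF 2.0 text."""
    nx, ny, nz = geom.grid_shape
    step = geom.ds * 1e-9
    base = geom.origin * 1e-9
    lines = [
        "# OOMMF OVF 2.0",
        "# Segment count: 1",
        "# Begin: Segment",
        "# Begin: Header",
        f"# Title: {title}",
        "# meshtype: rectangular",
        "# meshunit: m",
        f"# xmin: {base[0] - step / 2:.9e}",
        f"# ymin: {base[1] - step / 2:.9e}",
        f"# zmin: {base[2] - step / 2:.9e}",
        f"# xmax: {base[0] + (nx - 0.5) * step:.9e}",
        f"# ymax: {base[1] + (ny - 0.5) * step:.9e}",
        f"# zmax: {base[2] + (nz - 0.5) * step:.9e}",
        f"# xbase: {base[0]:.9e}",
        f"# ybase: {base[1]:.9e}",
        f"# zbase: {base[2]:.9e}",
        f"# xstepsize: {step:.9e}",
        f"# ystepsize: {step:.9e}",
        f"# zstepsize: {step:.9e}",
        f"# xnodes: {nx}",
        f"# ynodes: {ny}",
        f"# znodes: {nz}",
        "# valuedim: 3",
        f"# valueunits: {valueunits} {valueunits} {valueunits}",
        "# valuelabels: m_x m_y m_z",
        "# End: Header",
        "# Begin: Data Text",
    ]
    body = [
        f"{m[i, j, k, 0]:.9e} {m[i, j, k, 1]:.9e} {m[i, j, k, 2]:.9e}"
        for k in range(nz) for j in range(ny) for i in range(nx)
    ]
    lines += body + ["# End: Data Text", "# End: Segment", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_ovf(path):
    """Read an OVF 2.0 text file back into (array, header dict)."""
    header, data = {}, []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "Begin: Data Text" in line:
                    in_data = True
                elif "End: Data Text" in line:
                    in_data = False
                elif ":" in line:
                    k, _, v = line[1:].partition(":")
                    header[k.strip()] = v.strip()
            elif in_data and line:
                data.append([float(x) for x in line.split()])
    nx, ny, nz = (int(header[k]) for k in ("xnodes", "ynodes", "znodes"))
    arr = np.array(data).reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
    return arr, header


def properties_json(props, meta: dict | None = None, path=None) -> str:
    """Loop-property JSON: {l_nm, direction, Mr_kA_per_m, Hc_kA_per_m, E_kJ_per_m3}."""
    out = dict(meta or {})
    out.update(props.as_dict_pretty())
    s = json.dumps(out, indent=2, default=_jsonable)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
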