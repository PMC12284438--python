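"""Readers and writers for the pipeline's file formats.

Trees: CSV (``id,parent_id,length_cm,radius_cm[,wall_ratio]``, root has an
empty parent) or nested JSON.  Windkessel maps: CSV
(``terminal_id,R1,R2,Cd``).  Waveforms: CSV (``time_s,value``).  Uniaxial
data: CSV (``green_strain,pk2_stress_kPa``).  Constitutive parameters: JSON
(``c_kPa,k1_kPa,k2,beta_deg``).  Simulation results: HDF5 plus flat CSV
station exports.  Impedance spectra: CSV plus a JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, UniaxialDataset
from .solver import SimulationResult, WindkesselParams
from .tree import DEFAULT_WALL_RATIO, VascularTree, VesselSegment
from .wall import ConstitutiveParams
from .waveform import Waveform

__all__ = [
    "read_tree_csv", "write_tree_csv", "read_tree_json", "write_tree_json",
    "read_windkessel_csv", "write_windkessel_csv",
    "read_waveform_csv", "write_waveform_csv",
    "read_uniaxial_csv", "write_uniaxial_csv",
    "read_constitutive_json", "write_constitutive_json", "write_fit_result_json",
    "write_result_h5", "write_station_csv",
    "write_spectrum_csv", "read_scenario_config",
]


# -- trees -------------------------------------------------------------------

def read_tree_csv(path) -> VascularTree:
    df = pd.read_csv(path, dtype={"id": str, "parent_id": str})
    segs = []
    for row in df.itertuples(index=False):
        parent = None if (pd.isna(row.parent_id) or row.parent_id == "") else str(row.parent_id)
        wr = getattr(row, "wall_ratio", DEFAULT_WALL_RATIO)
        if pd.isna(wr):
            wr = DEFAULT_WALL_RATIO
        segs.append(VesselSegment(str(row.id), parent, float(row.length_cm),
                                  float(row.radius_cm), float(wr)))
    return VascularTree.binarize(segs)


def write_tree_csv(tree: VascularTree, path) -> None:
    pd.DataFrame([
        {"id": s.id, "parent_id": s.parent_id or "", "length_cm": s.length,
         "radius_cm": s.radius, "wall_ratio": s.wall_ratio}
        for s in tree.segments
    ]).to_csv(path, index=False)


def _collect_json(node, parent, segs):
    segs.append(VesselSegment(str(node["id"]), parent, float(node["length_cm"]),
                              float(node["radius_cm"]),
                              float(node.get("wall_ratio", DEFAULT_WALL_RATIO))))
    for child in node.get("children", []):
        _collect_json(child, str(node["id"]), segs)


def read_tree_json(path) -> VascularTree:
    with open(path) as fh:
        root = json.load(fh)
    segs: list = []
    _collect_json(root, None, segs)
    return VascularTree.binarize(segs)


def write_tree_json(tree: VascularTree, path) -> None:
    def node(sid):
        s = tree.segment(sid)
        return {"id": s.id, "length_cm": s.length, "radius_cm": s.radius,
                "wall_ratio": s.wall_ratio,
                "children": [node(k) for k in tree.children(sid)]}
    with open(path, "w") as fh:
        json.dump(node(tree.root_id), fh, indent=1)


# -- Windkessel maps ---------------------------------------------------------

def read_windkessel_csv(path) -> dict:
    df = pd.read_csv(path, dtype={"terminal_id": str})
    return {
        str(r.terminal_id): WindkesselParams(float(r.R1), float(r.R2), float(r.Cd),
                                             allow_unequal=float(r.R1) != float(r.R2))
        for r in df.itertuples(index=False)
    }


def write_windkessel_csv(wk_map: dict, path) -> None:
    pd.DataFrame([
        {"terminal_id": tid, "R1": wk.R1, "R2": wk.R2, "Cd": wk.Cd}
        for tid, wk in wk_map.items()
    ]).to_csv(path, index=False)


# -- waveforms ---------------------------------------------------------------

def read_waveform_csv(path) -> Waveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"waveform file {path} needs at least 2 samples")
    dt = t[1] - t[0]
    return Waveform(t - t[0], v, float(t[-1] - t[0] + dt))


def write_waveform_csv(w: Waveform, path) -> None:
    pd.DataFrame({"time_s": w.time, "value": w.values}).to_csv(path, index=False)


# -- uniaxial data and constitutive parameters ------------------------------

def read_uniaxial_csv(path, direction: str) -> UniaxialDataset:
    df = pd.read_csv(path)
    return UniaxialDataset(direction, df["green_strain"].to_numpy(dtype=float),
                           df["pk2_stress_kPa"].to_numpy(dtype=float))


def write_uniaxial_csv(data: UniaxialDataset, path) -> None:
    pd.DataFrame({"green_strain": data.strain,
                  "pk2_stress_kPa": data.stress}).to_csv(path, index=False)


def read_constitutive_json(path) -> ConstitutiveParams:
    with open(path) as fh:
        d = json.load(fh)
    return ConstitutiveParams(c=d["c_kPa"], k1=d["k1_kPa"], k2=d["k2"], beta=d["beta_deg"])


def write_constitutive_json(params: ConstitutiveParams, path) -> None:
    with open(path, "w") as fh:
        json.dump({"c_kPa": params.c, "k1_kPa": params.k1, "k2": params.k2,
                   "beta_deg": params.beta}, fh, indent=1)


def write_fit_result_json(result: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "c_kPa": result.params.c, "k1_kPa": result.params.k1,
            "k2": result.params.k2, "beta_deg": result.params.beta,
            "residual_sse_kPa2": result.residual_sse,
            "n_restarts_converged": result.n_restarts_converged,
            "per_direction_rmse_kPa": result.per_direction_rmse,
        }, fh, indent=1)


# -- simulation results ------------------------------------------------------

def write_result_h5(result: SimulationResult, path) -> None:
    """Final-cycle space-time fields per segment, with diagnostics attrs."""
    with h5py.File(path, "w") as fh:
        fh.attrs["converged"] = result.converged
        fh.attrs["n_cycles"] = result.n_cycles
        fh.attrs["max_junction_defect_ml_s"] = result.max_junction_defect
        fh.attrs["volume_balance_frac_sv"] = result.volume_balance
        fh.create_dataset("time_s", data=result.time)
        for sid in result.A:
            g = fh.create_group(f"segments/{sid}")
            g.create_dataset("x_cm", data=result.x[sid])
            g.create_dataset("A_cm2", data=result.A[sid])
            g.create_dataset("Q_ml_s", data=result.Q[sid])
            g.create_dataset("P_mmHg", data=result.P[sid])


def write_station_csv(result: SimulationResult, segment_id: str, path,
                      position: str = "proximal") -> None:
    from .solver import extract_waveforms
    p, q = extract_waveforms(result, segment_id, position)
    pd.DataFrame({"time_s": p.time, "P_mmHg": p.values,
                  "Q_ml_s": q.values}).to_csv(path, index=False)


# -- impedance ---------------------------------------------------------------

def write_spectrum_csv(spec, path, summary_path=None, f_max: float = 250.0) -> None:
    from .impedance import z0 as _z0, zc as _zc
    pd.DataFrame({
        "freq_hz": spec.frequencies,
        "re_z": np.real(spec.z), "im_z": np.imag(spec.z),
        "abs_z": np.abs(spec.z), "masked": spec.masked,
    }).to_csv(path, index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump({"Z0": _z0(spec), "Zc": _zc(spec, f_max)}, fh, indent=1)


# -- scenario configuration --------------------------------------------------

def read_scenario_config(path) -> dict:
    """YAML/JSON scenario settings: scales, flows, optional labels."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
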