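"""File formats: synapse-model JSON, plain-text point listings, traces.

The synapse model schema (``"schema": "ribbonquant-model/1"``) stores
coordinates in nm directly:

.. code-block:: json

    {
      "schema": "ribbonquant-model/1",
      "model_id": "tomo-01",
      "condition": "ChR2_LongStim",
      "voxel_nm": 1.18,
      "az_membrane": {"vertices": [[x,y,z], ...], "faces": [[i,j,k], ...]},
      "pd":          {"vertices": [[x,y,z], ...]},
      "ribbon":      {"vertices": ..., "faces": ...},
      "vesicles": [
        {"id": "v1", "center_nm": [x,y,z], "radius_nm": 24.5,
         "shape": "sphere", "tethers": ["membrane"], "clathrin_coated": false}
      ]
    }

A plain-text point-listing importer (``object contour x y z [size]``
per line, pixel units) supports the semi-automatic segmentation
workflow; pixel coordinates are multiplied by ``voxel_nm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import EphysTrace, LightPulse
from .geometry import Surface
from .hpf_timing import SensorShot
from .tomo_quant import SynapseModel, Vesicle

__all__ = [
    "save_model",
    "load_model",
    "import_point_listing",
    "point_listing_to_model",
    "load_shot_csv",
    "load_trace",
]

MODEL_SCHEMA = "ribbonquant-model/1"


def _surface_to_json(s: Surface | None):
    if s is None:
        return None
    out = {"vertices": s.vertices.tolist()}
    if s.is_mesh:
        out["faces"] = s.faces.tolist()
    return out


def _surface_from_json(obj) -> Surface | None:
    if obj is None:
        return None
    return Surface(np.asarray(obj["vertices"], dtype=float), obj.get("faces"))


def save_model(model: SynapseModel, path) -> None:
    doc = {
        "schema": MODEL_SCHEMA,
        "model_id": model.model_id,
        "condition": model.condition,
        "voxel_nm": model.voxel_nm,
        "az_membrane": _surface_to_json(model.az_membrane),
        "pd": _surface_to_json(model.pd),
        "ribbon": _surface_to_json(model.ribbon),
        "vesicles": [
            {
                "id": v.id,
                "center_nm": v.center_nm.tolist(),
                "radius_nm": v.radius_nm,
                "shape": v.shape,
                "long_axis_nm": v.long_axis_nm,
                "short_axis_nm": v.short_axis_nm,
                "tethers": list(v.tethers),
                "clathrin_coated": v.clathrin_coated,
            }
            for v in model.vesicles
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> SynapseModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema: {doc.get('schema')!r}")
    vesicles = [
        Vesicle(
            id=str(v["id"]),
            center_nm=np.asarray(v["center_nm"], dtype=float),
            radius_nm=float(v["radius_nm"]),
            shape=v.get("shape", "sphere"),
            long_axis_nm=v.get("long_axis_nm"),
            short_axis_nm=v.get("short_axis_nm"),
            tethers=list(v.get("tethers", [])),
            clathrin_coated=bool(v.get("clathrin_coated", False)),
        )
        for v in doc.get("vesicles", [])
    ]
    return SynapseModel(
        model_id=str(doc["model_id"]),
        az_membrane=_surface_from_json(doc["az_membrane"]),
        pd=_surface_from_json(doc.get("pd")),
        ribbon=_surface_from_json(doc.get("ribbon")),
        vesicles=vesicles,
        condition=doc.get("condition", "custom"),
        voxel_nm=float(doc.get("voxel_nm", 1.18)),
    )


def import_point_listing(path_or_text, voxel_nm: float = 1.18) -> dict[int, dict]:
    """Parse an ASCII point listing (one point per line).

    Accepted line format: ``object contour x y z [size]`` with pixel
    coordinates; comment lines start with ``#``.  Returns a mapping
    ``object_index -> {"points": (n,3) nm array, "sizes": (n,) nm array
    or None, "contours": (n,) int array}``.
    """
    text = (
        Path(path_or_text).read_text()
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text) and Path(path_or_text).exists()
        else str(path_or_text)
    )
    objects: dict[int, dict] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"malformed point line: {line!r}")
        obj, contour = int(parts[0]), int(parts[1])
        x, y, z = (float(p) * voxel_nm for p in parts[2:5])
        size = float(parts[5]) * voxel_nm if len(parts) > 5 else None
        entry = objects.setdefault(obj, {"points": [], "sizes": [], "contours": []})
        entry["points"].append([x, y, z])
        entry["sizes"].append(size)
        entry["contours"].append(contour)
    for entry in objects.values():
        entry["points"] = np.asarray(entry["points"], dtype=float)
        entry["contours"] = np.asarray(entry["contours"], dtype=int)
        entry["sizes"] = (
            None
            if all(s is None for s in entry["sizes"])
            else np.asarray([np.nan if s is None else s for s in entry["sizes"]])
        )
    return objects


def point_listing_to_model(
    objects: dict[int, dict],
    object_roles: dict[int, str],
    model_id: str = "imported",
    condition: str = "custom",
    voxel_nm: float = 1.18,
) -> SynapseModel:
    """Build a SynapseModel from imported point objects.

    ``object_roles`` maps object index → role in
    {az_membrane, pd, ribbon, vesicles, cc_vesicles}; structural roles
    become point-cloud surfaces, vesicle roles need a size column
    (point radius in pixels, scaled to nm).
    """
    surfaces: dict[str, Surface] = {}
    vesicles: list[Vesicle] = []
    for idx, role in object_roles.items():
        entry = objects[idx]
        if role in ("az_membrane", "pd", "ribbon"):
            surfaces[role] = Surface(entry["points"], None)
        elif role in ("vesicles", "cc_vesicles"):
            if entry["sizes"] is None:
                raise ValueError(f"object {idx} ({role}) needs a size column")
            for k, (pt, r) in enumerate(zip(entry["points"], entry["sizes"])):
                vesicles.append(
                    Vesicle(
                        id=f"o{idx}p{k}",
                        center_nm=pt,
                        radius_nm=float(r),
                        clathrin_coated=(role == "cc_vesicles"),
                    )
                )
        else:
            raise ValueError(f"unknown role {role!r}")
    if "az_membrane" not in surfaces:
        raise ValueError("object_roles must include an az_membrane object")
    return SynapseModel(
        model_id=model_id,
        az_membrane=surfaces["az_membrane"],
        pd=surfaces.get("pd"),
        ribbon=surfaces.get("ribbon"),
        vesicles=vesicles,
        condition=condition,
        voxel_nm=voxel_nm,
    )


def load_shot_csv(path, shot_id: str | None = None, stim_start_ms: float = 0.0) -> SensorShot:
    """Read a freezing-shot CSV.

    Either a single CSV with columns ``time_ms,pneumatic_bar`` plus
    optional ``internal_time_ms,internal_pressure_bar,
    internal_temp_C`` or just the two-column ``time_ms,value`` pneumatic
    form.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "pneumatic_bar" in cols:
        pneumatic = df[[cols["time_ms"], cols["pneumatic_bar"]]].dropna().to_numpy()
    else:
        pneumatic = df.iloc[:, :2].dropna().to_numpy()
    kwargs = {}
    if "internal_time_ms" in cols and "internal_pressure_bar" in cols:
        sub = df[[cols["internal_time_ms"], cols["internal_pressure_bar"]]].dropna()
        kwargs["internal_pressure"] = sub.to_numpy()
    if "internal_time_ms" in cols and "internal_temp_c" in cols:
        sub = df[[cols["internal_time_ms"], cols["internal_temp_c"]]].dropna()
        kwargs["internal_temperature"] = sub.to_numpy()
    return SensorShot(
        shot_id=shot_id or Path(path).stem,
        pneumatic=pneumatic,
        stim_start_ms=stim_start_ms,
        **kwargs,
    )


def load_trace(csv_path, sidecar_json=None) -> tuple[EphysTrace, LightPulse | None]:
    """Read a trace CSV (``time_ms,value``) plus its sidecar JSON."""
    df = pd.read_csv(csv_path)
    meta = {}
    if sidecar_json is None:
        candidate = Path(csv_path).with_suffix(".json")
        sidecar_json = candidate if candidate.exists() else None
    if sidecar_json is not None:
        meta = json.loads(Path(sidecar_json).read_text())
    light = None
    if "light" in meta:
        light = LightPulse(
            onset_ms=float(meta["light"]["onset_ms"]),
            duration_ms=float(meta["light"]["duration_ms"]),
            irradiance_mW_mm2=meta["light"].get("irradiance"),
        )
    trace = EphysTrace(
        time_ms=df.iloc[:, 0].to_numpy(),
        values=df.iloc[:, 1].to_numpy(),
        mode=meta.get("mode", "voltage_clamp"),
        holding_mV=meta.get("holding_mV"),
        leak_pA=meta.get("leak_pA"),
        series_resistance_MOhm=meta.get("rs_MOhm"),
        cell_type=meta.get("cell_type", "bouton"),
        trace_id=meta.get("trace_id", Path(csv_path).stem),
        series_index=meta.get("series_index"),
    )
    return trace, light
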