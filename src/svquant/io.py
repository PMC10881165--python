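"""Reading and writing of annotation documents, images, and tables.

Annotations travel as one JSON document per axon (or per export) with
embedded per-synapse records; polylines do not fit rectangular CSV
naturally.  The schema is versioned through the ``schema`` key.  Geometry
may be stored in nm (canonical) or µm (``"unit": "um"``); it is normalized
to nm on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .datamodel import CCPVRecord, ImageStack, SynapseAnnotation

SCHEMA = "svquant-annotations-1"

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when an annotation document does not match the schema."""


_REQUIRED_FIELDS = ("synapse_id", "az_polyline", "sv_centers", "sv_diameters")


def _annotation_to_record(a: SynapseAnnotation) -> dict:
    return {
        "synapse_id": a.synapse_id,
        "axon_id": a.axon_id,
        "condition": a.condition,
        "distance_from_injection_um": a.distance_from_injection_um,
        "az_polyline": a.az_polyline.tolist(),
        "sv_centers": a.sv_centers.tolist(),
        "sv_diameters": a.sv_diameters.tolist(),
        "pm_traces": [t.tolist() for t in a.pm_traces],
        "cisterna_perimeters_um": a.cisterna_perimeters_um.tolist(),
        "ccpv_records": [
            {"stage": r.stage, "diameter_nm": r.diameter_nm} for r in a.ccpv_records
        ],
        "section_thickness_nm": a.section_thickness_nm,
    }


def _record_to_annotation(rec: Mapping, scale: float, index: int) -> SynapseAnnotation:
    for field in _REQUIRED_FIELDS:
        if field not in rec:
            raise SchemaError(f"record {index}: missing required field '{field}'")

    def _coords(key, default):
        raw = rec.get(key, default)
        try:
            arr = np.asarray(raw, dtype=float)
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"record {index} ('{rec.get('synapse_id')}'): "
                f"non-numeric value in '{key}': {exc}"
            ) from None
        return arr * scale

    try:
        return SynapseAnnotation(
            synapse_id=str(rec["synapse_id"]),
            axon_id=str(rec.get("axon_id", "")),
            condition=str(rec.get("condition", "control")),
            distance_from_injection_um=rec.get("distance_from_injection_um"),
            az_polyline=_coords("az_polyline", []),
            sv_centers=_coords("sv_centers", []),
            sv_diameters=_coords("sv_diameters", []),
            pm_traces=[
                np.asarray(t, dtype=float) * scale for t in rec.get("pm_traces", [])
            ],
            cisterna_perimeters_um=np.asarray(
                rec.get("cisterna_perimeters_um", []), dtype=float
            ),
            ccpv_records=[
                CCPVRecord(stage=int(r["stage"]), diameter_nm=float(r["diameter_nm"]) * scale)
                for r in rec.get("ccpv_records", [])
            ],
            section_thickness_nm=float(rec.get("section_thickness_nm", 70.0)) * scale,
        )
    except ValueError as exc:
        raise SchemaError(f"record {index}: {exc}") from exc


def read_annotations(path: str | Path) -> list[SynapseAnnotation]:
    """Read a JSON annotation document and return validated annotations.

    Geometry stored in µm (``"unit": "um"``) is converted to nm.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA:
        raise SchemaError(
            f"{path}: unrecognized schema "
            f"{doc.get('schema') if isinstance(doc, dict) else type(doc)}"
        )
    unit = doc.get("unit", "nm")
    if unit == "nm":
        scale = 1.0
    elif unit in ("um", "µm"):
        scale = 1000.0
    else:
        raise SchemaError(f"{path}: unknown coordinate unit '{unit}'")
    return [
        _record_to_annotation(rec, scale, i)
        for i, rec in enumerate(doc.get("synapses", []))
    ]


def write_annotations(
    annotations: Sequence[SynapseAnnotation], path: str | Path
) -> None:
    """Write annotations as a schema-versioned JSON document (nm units)."""
    doc = {
        "schema": SCHEMA,
        "unit": "nm",
        "synapses": [_annotation_to_record(a) for a in annotations],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_image(
    path: str | Path,
    pixel_size_um: float = 1.0,
    frame_interval_s: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a (multi-page) TIFF into an :class:`ImageStack`.

    The TIFF page layout is taken at face value; calibration is supplied by
    the caller because plain TIFF fixtures carry none.  Axis convention:
    see :class:`ImageStack`.
    """
    pixels = tifffile.imread(str(path))
    return ImageStack(
        pixels=pixels,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_names=list(channel_names) if channel_names is not None else None,
    )


def write_image(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.pixels)


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a summary table as UTF-8 CSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
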