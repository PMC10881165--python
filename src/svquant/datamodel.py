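"""Core data containers for presynaptic ultrastructure and imaging data.

All geometry is stored internally in nanometres with y increasing away from
the axolemma into the axoplasm.  Image data carry their own physical
calibration (``pixel_size_um``, ``frame_interval_s``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SynapseAnnotation",
    "ImageStack",
    "AnalysisConfig",
    "CCPVRecord",
    "KNOWN_CONDITIONS",
]

#: Condition labels with defined semantics.  Unknown labels are carried
#: through all stages untouched so that new experimental groups can be
#: analysed without code changes.
KNOWN_CONDITIONS = (
    "control",
    "low",
    "high",
    "unstimulated_control",
    "unstimulated_low",
    "unstimulated_high",
)


@dataclass(frozen=True)
class CCPVRecord:
    """One clathrin-coated pit or vesicle.

    ``stage`` follows the conventional four-step progression of
    clathrin-mediated endocytosis: 1 initiation of pit formation,
    2 pit maturation, 3 fission, 4 free coated vesicle / uncoating.
    """

    stage: int
    diameter_nm: float

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4):
            raise ValueError(f"CCP/V stage must be 1-4, got {self.stage}")
        if not self.diameter_nm > 0:
            raise ValueError("CCP/V diameter must be positive")


@dataclass
class SynapseAnnotation:
    """Hand-annotated geometry of a single presynaptic EM section.

    Parameters
    ----------
    synapse_id, axon_id
        Free-form identifiers.
    az_polyline
        Ordered (n, 2) vertices of the active-zone trace, nm.
    sv_centers, sv_diameters
        Vesicle centre coordinates (n, 2) in nm and outer diameters in nm,
        parallel arrays.
    pm_traces
        Up to two ordered polylines (left/right of the AZ) tracing the
        plasma membrane away from the AZ edges, nm.  Each trace starts at
        its AZ edge.
    cisterna_perimeters_um
        Perimeter of each traced cisterna (presumptive endosome), µm.
    ccpv_records
        Clathrin-coated pit/vesicle records.
    distance_from_injection_um
        Distance of the synapse from the protein injection site along the
        axon, µm; used to assign exposure condition.
    section_thickness_nm
        EM section thickness, default 70 nm.
    """

    synapse_id: str
    axon_id: str = ""
    condition: str = "control"
    distance_from_injection_um: float | None = None
    az_polyline: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    sv_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    sv_diameters: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pm_traces: list[np.ndarray] = field(default_factory=list)
    cisterna_perimeters_um: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ccpv_records: list[CCPVRecord] = field(default_factory=list)
    section_thickness_nm: float = 70.0

    def __post_init__(self) -> None:
        self.az_polyline = np.asarray(self.az_polyline, dtype=float)
        self.sv_centers = np.asarray(self.sv_centers, dtype=float).reshape(-1, 2)
        self.sv_diameters = np.asarray(self.sv_diameters, dtype=float)
        self.pm_traces = [np.asarray(t, dtype=float) for t in self.pm_traces]
        self.cisterna_perimeters_um = np.asarray(
            self.cisterna_perimeters_um, dtype=float
        )
        self.validate()

    def validate(self) -> None:
        if self.az_polyline.ndim != 2 or self.az_polyline.shape[0] < 2:
            raise ValueError(
                f"{self.synapse_id}: az_polyline needs >=2 points, "
                f"got shape {self.az_polyline.shape}"
            )
        if len(self.sv_centers) != len(self.sv_diameters):
            raise ValueError(
                f"{self.synapse_id}: sv_centers ({len(self.sv_centers)}) and "
                f"sv_diameters ({len(self.sv_diameters)}) differ in length"
            )
        if len(self.sv_diameters) and not np.all(self.sv_diameters > 0):
            raise ValueError(f"{self.synapse_id}: all SV diameters must be > 0")
        if not self.section_thickness_nm > 0:
            raise ValueError(f"{self.synapse_id}: section_thickness must be > 0")
        if len(self.pm_traces) > 2:
            raise ValueError(f"{self.synapse_id}: at most two PM traces (left/right)")
        if (
            self.distance_from_injection_um is not None
            and self.distance_from_injection_um < 0
        ):
            raise ValueError(f"{self.synapse_id}: negative injection distance")

    @property
    def n_sv_annotated(self) -> int:
        return len(self.sv_centers)

    def scaled(self, factor: float) -> "SynapseAnnotation":
        """Return a copy with all nm coordinates multiplied by ``factor``."""
        return replace(
            self,
            az_polyline=self.az_polyline * factor,
            sv_centers=self.sv_centers * factor,
            sv_diameters=self.sv_diameters * factor,
            pm_traces=[t * factor for t in self.pm_traces],
        )


@dataclass
class ImageStack:
    """Calibrated intensity data: a 2-D image, a multichannel image, or a
    time-lapse movie.

    Axis convention: ``(Y, X)`` for 2-D; ``(C, Y, X)`` when ``channel_names``
    is set; ``(T, Y, X)`` for a time series; ``(T, C, Y, X)`` when both
    apply.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_s: float | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be >= 0")
        if self.channel_names is not None:
            axis = 0 if self.pixels.ndim == 3 else 1
            if self.pixels.ndim not in (3, 4) or self.pixels.shape[axis] != len(
                self.channel_names
            ):
                raise ValueError(
                    "channel_names length does not match the channel axis"
                )

    @property
    def n_frames(self) -> int:
        if self.frame_interval_s is None:
            return 1
        return self.pixels.shape[0]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a (Y, X) or (T, Y, X) array."""
        if isinstance(name_or_index, str):
            if self.channel_names is None:
                raise KeyError("stack has no named channels")
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        if self.channel_names is None:
            raise KeyError("stack has no channel axis")
        if self.pixels.ndim == 3:
            return self.pixels[idx]
        return self.pixels[:, idx]


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across analysis stages.

    Defaults follow the study protocol where one is stated (2000-distance
    bootstrap samples, five-frame motility rule, ten baseline frames,
    50 µm × 200 s motility window) and field-standard values elsewhere.
    """

    distribution_bin_width_nm: float = 50.0
    az_discretization_step_nm: float = 5.0
    ellipse_scale: float = 2.0
    bootstrap_n: int = 2000
    bootstrap_reps: int = 1000
    seed: int = 0
    membrane_convention: str = "sphere_sv"
    # motility
    min_sequential_frames: int = 5
    baseline_frames: int = 10
    roi_length_um: float = 50.0
    window_s: float = 200.0
    max_speed_um_s: float = 1.5
    ratio_threshold: float = 1.3
    spot_sigma_um: float = 0.5

    def __post_init__(self) -> None:
        for name in ("bootstrap_n", "bootstrap_reps", "min_sequential_frames",
                     "baseline_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.distribution_bin_width_nm > 0:
            raise ValueError("distribution_bin_width_nm must be > 0")
        if not self.az_discretization_step_nm > 0:
            raise ValueError("az_discretization_step_nm must be > 0")
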