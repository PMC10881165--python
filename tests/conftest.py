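import numpy as np
import pytest

from svquant.datamodel import CCPVRecord, SynapseAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_annotation(rng, i=0, n_sv=None):
    """A structurally valid random annotation for round-trip tests."""
    n_sv = int(rng.integers(2, 30)) if n_sv is None else n_sv
    az = np.column_stack([np.linspace(0, 900, 5), rng.normal(0, 10, 5)])
    return SynapseAnnotation(
        synapse_id=f"syn_{i}",
        axon_id=f"axon_{i % 3}",
        condition=rng.choice(["control", "low", "high"]),
        distance_from_injection_um=float(rng.uniform(0, 600)),
        az_polyline=az,
        sv_centers=rng.uniform(0, 1000, (n_sv, 2)),
        sv_diameters=rng.uniform(40, 70, n_sv),
        pm_traces=[
            np.column_stack([np.linspace(0, -1200, 30), rng.normal(0, 5, 30)]),
            np.column_stack([np.linspace(900, 2100, 30), rng.normal(0, 5, 30)]),
        ],
        cisterna_perimeters_um=rng.uniform(0.2, 0.6, int(rng.integers(0, 4))),
        ccpv_records=[
            CCPVRecord(stage=int(rng.integers(1, 5)), diameter_nm=float(rng.uniform(60, 95)))
            for _ in range(int(rng.integers(0, 5)))
        ],
    )


@pytest.fixture
def annotations(rng):
    return [random_annotation(rng, i) for i in range(10)]
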