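"""Synthetic data with the statistical structure the analyses assume.

The generator stands in for raw micrographs and movies: it emits EM
synapse annotations (clustered vs. dispersed SV point patterns),
two-channel fluorescence images with a controllable colocalized fraction
and channel offset, and FM destain movies with known decay constants and
moving puncta, each with ground truth attached.

Population presets encode the published group means of the lamprey
reticulospinal synapse experiments (SVs per synapse, SV diameter, PM
evagination length, cisterna counts and perimeters, CCP/V counts), so
morphometry recovery tests are anchored to those values.  Per-synapse
standard deviations are back-computed from the printed standard errors
and sample sizes.

SV placement emulates what the micrographs show: a dense main cluster
packed against the active zone thinning with distance (half-Gaussian in
distance from the axolemma with a hard-core exclusion of one vesicle
diameter, so nearest-neighbour distances are realistic), with a
controllable fraction of SVs re-assigned to small distant microclusters
of a few vesicles — the declustering phenotype.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import CCPVRecord, ImageStack, SynapseAnnotation

__all__ = [
    "PopulationSpec",
    "ImageSpec",
    "MovieSpec",
    "POPULATION_PRESETS",
    "gen_synapse_population",
    "gen_two_channel_image",
    "gen_destain_movie",
    "make_destain_trace",
]


@dataclass
class PopulationSpec:
    """Parameters of a synthetic synapse population.

    Means are per synapse; SDs describe across-synapse variability.
    ``cluster_sd_nm`` sets the cohesion of the main SV cluster about the
    AZ; ``dispersed_fraction`` re-assigns that fraction of SVs to distant
    microclusters of ``microcluster_size`` vesicles.
    """

    condition: str = "control"
    n_synapses: int = 50
    sv_count_mean: float = 135.9
    sv_count_sd: float = 56.4
    sv_diameter_mean_nm: float = 53.2
    sv_diameter_sd_nm: float = 8.8
    cluster_sd_nm: float = 150.0
    dispersed_fraction: float = 0.02
    microcluster_size: int = 3
    pm_length_mean_um: float = 2.07
    pm_length_sd_um: float = 0.40
    cist_count_mean: float = 3.02
    cist_count_sd: float = 2.4
    cist_perimeter_mean_um: float = 0.41
    cist_perimeter_sd_um: float = 0.14
    ccpv_count_mean: float = 3.16
    ccpv_count_sd: float = 2.0
    az_length_nm: float = 1000.0
    distance_from_injection_um: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dispersed_fraction <= 1:
            raise ValueError("dispersed_fraction must be in [0, 1]")
        for name in ("sv_count_mean", "sv_diameter_mean_nm", "cluster_sd_nm",
                     "pm_length_mean_um", "cist_perimeter_mean_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        # a spec whose truncation at zero would discard most of the mass
        # cannot reproduce its own mean
        for mean, sd, name in (
            (self.sv_count_mean, self.sv_count_sd, "sv_count"),
            (self.sv_diameter_mean_nm, self.sv_diameter_sd_nm, "sv_diameter"),
        ):
            if sd > 0 and mean / sd < 0.0:  # pragma: no cover - guarded above
                raise ValueError(f"infeasible {name} spec")
        if self.sv_count_sd > 0 and self.sv_count_mean < 0.5 * self.sv_count_sd:
            raise ValueError("infeasible sv_count spec: truncation mass > 50%")


#: Presets anchored to the published group means.  Stimulated groups from
#: the 20 Hz experiments; ``control_unstim`` from the unstimulated series.
#: WT-like per-synapse SV count is the published pooled count divided by
#: the number of synapses (3016 SVs / 30 synapses).
POPULATION_PRESETS: dict[str, PopulationSpec] = {
    "control_unstim": PopulationSpec(
        condition="unstimulated_control",
        sv_count_mean=145.5, sv_count_sd=63.7,
        sv_diameter_mean_nm=53.2,
        pm_length_mean_um=1.91, pm_length_sd_um=0.44,
        cist_count_mean=3.0, cist_perimeter_mean_um=0.41,
        ccpv_count_mean=3.0,
        cluster_sd_nm=150.0, dispersed_fraction=0.01,
        distance_from_injection_um=500.0,
    ),
    "control_stim": PopulationSpec(
        condition="control",
        sv_count_mean=135.9, sv_count_sd=56.4,
        sv_diameter_mean_nm=53.20,
        pm_length_mean_um=2.07, pm_length_sd_um=0.52,
        cist_count_mean=3.02, cist_count_sd=2.45,
        cist_perimeter_mean_um=0.41, cist_perimeter_sd_um=0.148,
        ccpv_count_mean=3.16, ccpv_count_sd=2.2,
        cluster_sd_nm=150.0, dispersed_fraction=0.02,
        distance_from_injection_um=500.0,
    ),
    "wt_high": PopulationSpec(
        condition="high",
        sv_count_mean=100.5, sv_count_sd=45.0,
        sv_diameter_mean_nm=53.2,
        pm_length_mean_um=2.07, pm_length_sd_um=0.5,
        cist_count_mean=3.5, cist_count_sd=2.5,
        cist_perimeter_mean_um=0.41,
        ccpv_count_mean=4.0, ccpv_count_sd=2.5,
        cluster_sd_nm=200.0, dispersed_fraction=0.10,
        distance_from_injection_um=100.0,
    ),
    "ps129_low": PopulationSpec(
        condition="low",
        sv_count_mean=103.1, sv_count_sd=43.0,
        sv_diameter_mean_nm=53.23,
        pm_length_mean_um=1.98, pm_length_sd_um=0.70,
        cist_count_mean=3.72, cist_count_sd=3.0,
        cist_perimeter_mean_um=0.41, cist_perimeter_sd_um=0.156,
        ccpv_count_mean=2.83, ccpv_count_sd=2.2,
        cluster_sd_nm=190.0, dispersed_fraction=0.08,
        distance_from_injection_um=250.0,
    ),
    "ps129_high": PopulationSpec(
        condition="high",
        sv_count_mean=51.03, sv_count_sd=34.1,
        sv_diameter_mean_nm=55.65,
        pm_length_mean_um=2.48, pm_length_sd_um=1.06,
        cist_count_mean=6.3, cist_count_sd=5.7,
        cist_perimeter_mean_um=0.52, cist_perimeter_sd_um=0.164,
        ccpv_count_mean=2.93, ccpv_count_sd=2.5,
        cluster_sd_nm=280.0, dispersed_fraction=0.30, microcluster_size=3,
        distance_from_injection_um=100.0,
    ),
}


def _trunc_normal(rng, mean, sd, low, size=None):
    """Normal draw(s) truncated below ``low`` with the *truncated* mean
    matched to ``mean``.

    Plain rejection sampling inflates the mean whenever the lower tail is
    cut; here the location parameter is solved so the truncated
    distribution has exactly the requested mean, keeping population
    moments faithful to the spec.
    """
    if sd <= 0:
        val = max(mean, low + 1e-9)
        return val if size is None else np.full(size, val)
    if mean <= low:
        raise ValueError(f"infeasible truncation: mean {mean} <= bound {low}")
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    def shifted_mean(loc):
        a = (low - loc) / sd
        return truncnorm.mean(a, np.inf, loc=loc, scale=sd) - mean

    # truncated mean is increasing in loc and >= max(loc, low)
    loc = brentq(shifted_mean, mean - 20 * sd, mean)
    a = (low - loc) / sd
    x = truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=size, random_state=rng)
    return x


def _place_main_cluster(rng, n, az_length, cluster_sd, min_spacing):
    """Hard-core half-Gaussian placement of the main SV cluster.

    Candidates are drawn with x centred on the AZ and y a half-normal of
    SD ``cluster_sd`` above the axolemma; a candidate closer than
    ``min_spacing`` to an accepted vesicle is rejected.  When the cluster
    is too crowded to accept a point the spread inflates by 10% — dense
    clusters swell rather than overlap.
    """
    accepted = np.empty((n, 2))
    count = 0
    sd = cluster_sd
    while count < n:
        placed = False
        for _ in range(30):
            x = rng.normal(az_length / 2.0, az_length / 4.0)
            y = min_spacing / 2.0 + abs(rng.normal(0.0, sd))
            if y > min_spacing / 2.0 + 4.0 * sd:  # bounded cluster extent
                continue
            if count:
                d2 = np.sum((accepted[:count] - (x, y)) ** 2, axis=1)
                if d2.min() < min_spacing**2:
                    continue
            accepted[count] = (x, y)
            count += 1
            placed = True
            break
        if not placed:
            sd *= 1.1
    return accepted


def _place_microclusters(rng, n, clump_size, az_length, min_spacing, existing):
    """Dispersed SVs in compact clumps up to 2 µm from the synapse.

    Hard-core spacing is enforced against every previously placed SV,
    including the main cluster.
    """
    pts: list[tuple[float, float]] = []
    placed = np.asarray(existing, dtype=float).reshape(-1, 2)
    while len(pts) < n:
        k = min(clump_size, n - len(pts))
        r = rng.uniform(600.0, 2000.0)
        theta = rng.uniform(np.pi / 6, 5 * np.pi / 6)  # above the axolemma
        cx = az_length / 2.0 + r * np.cos(theta)
        cy = 50.0 + r * np.sin(theta)
        clump: list[tuple[float, float]] = []
        for _ in range(k):
            spread = 60.0
            while True:
                p = (cx + rng.normal(0, spread), cy + rng.normal(0, spread))
                if p[1] < min_spacing / 2:
                    continue
                pieces = [a for a in (placed, np.asarray(clump).reshape(-1, 2)) if len(a)]
                if pieces:
                    neighbors = np.vstack(pieces)
                    d2 = np.sum((neighbors - p) ** 2, axis=1)
                    if d2.min() < min_spacing**2:
                        spread *= 1.05
                        continue
                clump.append(p)
                break
        pts.extend(clump)
        placed = np.vstack([placed, np.asarray(clump).reshape(-1, 2)])
    return np.asarray(pts[:n])


def _arc_length_to_shell_dense(path: np.ndarray, edge: np.ndarray, shell: float) -> float:
    radii = np.linalg.norm(path - edge, axis=1)
    idx = np.nonzero(radii >= shell)[0]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    if len(idx) == 0:
        return float(seg.sum())
    k = idx[0]
    return float(seg[: max(k, 1)].sum())


def _make_pm_trace(rng, edge, direction, target_um, n_cycles=4, n_pts=60):
    """PM polyline from an AZ edge whose evagination length matches
    ``target_um``.

    A straight baseline of 1.2 µm along ``direction`` carries a sinusoidal
    perpendicular ripple; the amplitude is solved by bisection against a
    densely sampled arc length to the 1 µm shell.
    """
    edge = np.asarray(edge, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    nvec = np.array([-u[1], u[0]])
    tt = np.linspace(0.0, 1.0, 2000)
    phase = rng.uniform(0, 2 * np.pi)

    def path(amp, t):
        base = edge + np.outer(t * 1200.0, u)
        ripple = amp * np.sin(2 * np.pi * n_cycles * t + phase) * np.sin(np.pi * t)
        return base + np.outer(ripple, nvec)

    def length(amp):
        return _arc_length_to_shell_dense(path(amp, tt), edge, 1000.0) / 1000.0

    target = max(float(target_um), 1.0)
    lo, hi = 0.0, 50.0
    while length(hi) < target and hi < 5000.0:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if length(mid) < target:
            lo = mid
        else:
            hi = mid
    amp = 0.5 * (lo + hi)
    return path(amp, np.linspace(0.0, 1.0, n_pts))


def gen_synapse_population(
    spec: PopulationSpec, seed: int | None = None
) -> list[SynapseAnnotation]:
    """Generate a population of annotated synapse sections.

    Per synapse: an AZ polyline of ~1 µm, a hard-core half-Gaussian main
    SV cluster of SD ``cluster_sd_nm``, a ``dispersed_fraction`` of SVs in
    distant microclusters, PM traces on both sides of the AZ matching the
    target evagination length, and cisterna / CCP/V records drawn from
    the stated truncated normals.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out = []
    for i in range(spec.n_synapses):
        az_len = spec.az_length_nm * rng.uniform(0.9, 1.1)
        xs = np.linspace(0.0, az_len, 9)
        az = np.column_stack([xs, 15.0 * np.sin(np.pi * xs / az_len)])

        n_sv = max(int(round(_trunc_normal(rng, spec.sv_count_mean, spec.sv_count_sd, 0.5))), 1)
        n_disp = int(round(spec.dispersed_fraction * n_sv))
        n_main = n_sv - n_disp
        spacing = spec.sv_diameter_mean_nm
        parts = []
        if n_main:
            parts.append(_place_main_cluster(rng, n_main, az_len, spec.cluster_sd_nm, spacing))
        if n_disp:
            parts.append(
                _place_microclusters(
                    rng, n_disp, spec.microcluster_size, az_len, spacing,
                    parts[0] if parts else np.zeros((0, 2)),
                )
            )
        centers = np.vstack(parts) if parts else np.zeros((0, 2))
        diams = _trunc_normal(rng, spec.sv_diameter_mean_nm, spec.sv_diameter_sd_nm, 20.0, size=n_sv)

        pm_left = _make_pm_trace(
            rng, az[0], (-1.0, 0.0),
            _trunc_normal(rng, spec.pm_length_mean_um, spec.pm_length_sd_um, 0.99),
        )
        pm_right = _make_pm_trace(
            rng, az[-1], (1.0, 0.0),
            _trunc_normal(rng, spec.pm_length_mean_um, spec.pm_length_sd_um, 0.99),
        )

        n_cist = max(int(round(_trunc_normal(rng, spec.cist_count_mean, spec.cist_count_sd, -0.49))), 0)
        cist_perims = _trunc_normal(
            rng, spec.cist_perimeter_mean_um, spec.cist_perimeter_sd_um, 0.05,
            size=n_cist,
        ) if n_cist else np.zeros(0)

        n_ccpv = max(int(round(_trunc_normal(rng, spec.ccpv_count_mean, spec.ccpv_count_sd, -0.49))), 0)
        stages = rng.choice([1, 2, 3, 4], size=n_ccpv, p=[0.3, 0.3, 0.15, 0.25])
        ccpv = [
            CCPVRecord(stage=int(s), diameter_nm=float(_trunc_normal(rng, 80.0, 8.0, 30.0)))
            for s in stages
        ]

        out.append(
            SynapseAnnotation(
                synapse_id=f"{spec.condition}_{i:04d}",
                axon_id=f"axon_{i % 4}",
                condition=spec.condition,
                distance_from_injection_um=spec.distance_from_injection_um,
                az_polyline=az,
                sv_centers=centers,
                sv_diameters=diams,
                pm_traces=[pm_left, pm_right],
                cisterna_perimeters_um=cist_perims,
                ccpv_records=ccpv,
            )
        )
    return out


# ---------------------------------------------------------------------------
# two-channel IF images


@dataclass
class ImageSpec:
    """Synthetic two-channel IF image parameters.

    The default geometry emulates the analysis ROIs of the IF protocol
    (a few tens of µm² of axon containing several synapses, so synapse
    blobs occupy a realistic ~15% of the axon area); synapse blobs sit in
    a horizontal axon band.  ``density_ratio`` is the true
    axoplasm:synapse fluorescence-density ratio of the signal channel.
    """

    size_px: int = 128
    pixel_size_um: float = 0.2
    n_synapses: int = 8
    blob_radius_um: float = 1.2
    axon_halfwidth_um: float = 5.0
    marker_amplitude: float = 1000.0
    signal_synaptic_density: float = 1000.0
    density_ratio: float = 0.15
    colocalized_fraction: float = 1.0
    channel_offset_um: float = 0.0
    bleedthrough_pct: float = 0.0
    snr: float = 10.0
    seed: int = 0


def gen_two_channel_image(spec: ImageSpec) -> tuple[ImageStack, dict]:
    """Generate a marker/signal channel pair with ground truth.

    Returns the stack (channels ``["marker", "signal"]``) and a dict with
    the axon mask, true synapse mask, and true density ratio.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    px = spec.pixel_size_um
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    cy = n / 2.0
    halfwidth_px = spec.axon_halfwidth_um / px
    axon_mask = np.abs(yy - cy) <= halfwidth_px

    r_px = spec.blob_radius_um / px
    centers = []
    attempts = 0
    while len(centers) < spec.n_synapses and attempts < 1000:
        attempts += 1
        c = (
            rng.uniform(cy - halfwidth_px + r_px + 2, cy + halfwidth_px - r_px - 2),
            rng.uniform(r_px + 8, n - r_px - 8),
        )
        if all(np.hypot(c[0] - a, c[1] - b) > 3.2 * r_px for a, b in centers):
            centers.append(c)
    centers = np.asarray(centers)

    def discs(cs):
        img = np.zeros((n, n))
        for a, b in cs:
            img[(yy - a) ** 2 + (xx - b) ** 2 <= r_px**2] = 1.0
        return img

    synapse_mask = discs(centers) > 0.5
    from scipy.ndimage import gaussian_filter, shift as nd_shift

    marker = gaussian_filter(discs(centers) * spec.marker_amplitude, 0.7)
    marker += 0.02 * spec.marker_amplitude * axon_mask

    n_coloc = int(round(spec.colocalized_fraction * len(centers)))
    sig_centers = centers[:n_coloc]
    axo_density = spec.density_ratio * spec.signal_synaptic_density
    signal = gaussian_filter(
        discs(sig_centers) * (spec.signal_synaptic_density - axo_density), 0.7
    )
    if spec.channel_offset_um != 0.0:
        signal = nd_shift(signal, (0.0, spec.channel_offset_um / px), order=1)
    signal = signal + axo_density * axon_mask
    signal = signal + (spec.bleedthrough_pct / 100.0) * marker

    # photon-counting (shot) noise: the gain maps the synaptic peak to
    # snr^2 expected photons so that peak SNR = sqrt(N) = snr; Poisson is
    # nonnegative by construction, so no clipping bias enters densities
    for img, amp in ((marker, spec.marker_amplitude), (signal, spec.signal_synaptic_density)):
        gain = spec.snr**2 / amp
        img[:] = rng.poisson(np.clip(img, 0, None) * gain) / gain

    stack = ImageStack(
        pixels=np.stack([marker, signal]),
        pixel_size_um=px,
        channel_names=["marker", "signal"],
    )
    truth = {
        "axon_mask": axon_mask,
        "synapse_mask": synapse_mask,
        "synapse_centers_px": centers,
        "density_ratio_pct": 100.0 * spec.density_ratio,
        "channel_offset_um": spec.channel_offset_um,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# FM destain movies


@dataclass
class MovieSpec:
    """Synthetic FM destain movie parameters.

    Default geometry mirrors the acquisition: a ~51 µm field imaged for
    220 s.  Stationary SV-cluster ROIs decay exponentially with the given
    per-ROI decay constants after stimulus onset; movers are
    diffraction-limited puncta following straight tracks at the given
    speeds (µm/s).  Noise is Poisson shot noise plus Gaussian read noise
    scaled to ``snr`` (spot amplitude over read-noise SD).
    """

    n_frames: int = 110
    size_px: int = 128
    pixel_size_um: float = 0.4
    frame_interval_s: float = 2.0
    stim_onset_frame: int = 10
    roi_taus_s: tuple = (213.0, 213.0, 213.0)
    roi_amplitude: float = 1000.0
    baseline: float = 500.0
    mover_speeds_um_s: tuple = ()
    mover_amplitude: float = 800.0
    mover_start_frame: int = 15
    mover_n_frames: int = 40
    spot_sigma_um: float = 0.5
    snr: float = 10.0
    seed: int = 0


def _gaussian_spot(yy, xx, cy, cx, sigma_px):
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))


def gen_destain_movie(spec: MovieSpec) -> tuple[ImageStack, dict]:
    """Generate an FM destain movie with ground truth.

    Returns the movie and a dict with ROI centres (µm), per-ROI decay
    constants, mover tracks (start, velocity) and the mover count.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    px = spec.pixel_size_um
    sigma_px = spec.spot_sigma_um / px
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    t_frames = np.arange(spec.n_frames)
    t_s = t_frames * spec.frame_interval_s
    onset_s = spec.stim_onset_frame * spec.frame_interval_s

    # stationary ROIs on a loose grid
    n_roi = len(spec.roi_taus_s)
    grid = max(int(np.ceil(np.sqrt(n_roi))), 1)
    margin = 6 * sigma_px
    pos = []
    for k in range(n_roi):
        gy, gx = divmod(k, grid)
        pos.append(
            (
                margin + (n - 2 * margin) * (gy + 0.5) / grid + rng.uniform(-2, 2),
                margin + (n - 2 * margin) * (gx + 0.5) / grid + rng.uniform(-2, 2),
            )
        )
    pos = np.asarray(pos)

    movers = []
    for speed in spec.mover_speeds_um_s:
        theta = rng.uniform(0, 2 * np.pi)
        vel_px = speed * spec.frame_interval_s / px * np.array(
            [np.sin(theta), np.cos(theta)]
        )
        # clip track length so the full excursion stays inside the field
        step = float(np.abs(vel_px).max())
        n_frames = spec.mover_n_frames
        if step > 0:
            n_frames = min(n_frames, int((n - 2 * margin - 2) / step))
        n_frames = max(n_frames, 2)
        travel = vel_px * n_frames
        start = np.array(
            [
                rng.uniform(
                    max(margin, margin - min(travel[0], 0)),
                    min(n - margin, n - margin - max(travel[0], 0)),
                ),
                rng.uniform(
                    max(margin, margin - min(travel[1], 0)),
                    min(n - margin, n - margin - max(travel[1], 0)),
                ),
            ]
        )
        movers.append(
            {
                "start_px": start,
                "vel_px_per_frame": vel_px,
                "speed_um_s": speed,
                "n_frames": n_frames,
            }
        )

    frames = np.empty((spec.n_frames, n, n))
    for ti, t in enumerate(t_s):
        img = np.full((n, n), spec.baseline, dtype=float)
        for (ry, rx), tau in zip(pos, spec.roi_taus_s):
            amp = spec.roi_amplitude * (
                1.0 if t < onset_s else np.exp(-(t - onset_s) / tau)
            )
            img += amp * _gaussian_spot(yy, xx, ry, rx, sigma_px)
        for m in movers:
            f0 = spec.mover_start_frame
            if f0 <= ti < f0 + m["n_frames"]:
                c = m["start_px"] + m["vel_px_per_frame"] * (ti - f0)
                img += spec.mover_amplitude * _gaussian_spot(yy, xx, c[0], c[1], sigma_px)
        read_sd = spec.mover_amplitude / spec.snr if spec.snr > 0 else 0.0
        noisy = rng.poisson(img).astype(float)
        if read_sd:
            noisy += rng.normal(0, read_sd, img.shape)
        frames[ti] = np.clip(noisy, 0, None)

    movie = ImageStack(
        pixels=frames,
        pixel_size_um=px,
        frame_interval_s=spec.frame_interval_s,
    )
    truth = {
        "roi_centers_um": pos * px,
        "roi_taus_s": np.asarray(spec.roi_taus_s, dtype=float),
        "stim_onset_s": onset_s,
        "movers": movers,
        "n_movers": len(movers),
    }
    return movie, truth


def make_destain_trace(
    tau_s: float,
    amplitude: float = 1000.0,
    baseline: float = 100.0,
    background: float = 50.0,
    duration_s: float = 200.0,
    dt_s: float = 2.0,
    stim_onset_s: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Single synthetic destain trace (no imaging), for fit validation."""
    from .kinetics import DestainTrace

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + stim_onset_s, dt_s)
    decay = np.where(t < stim_onset_s, 1.0, np.exp(-(t - stim_onset_s) / tau_s))
    intensity = background + baseline + amplitude * decay
    if noise_sd > 0:
        intensity = intensity + rng.normal(0, noise_sd, t.shape)
    return DestainTrace(
        time_s=t,
        intensity=intensity,
        background=background,
        stim_window_s=(stim_onset_s, t[-1]),
    )
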