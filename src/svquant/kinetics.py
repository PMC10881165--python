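"""FM-dye destaining kinetics and mobile-puncta detection.

Destaining of FM-labeled SV clusters during high-frequency stimulation is
summarized by a single-exponential fit to each background-subtracted
trace restricted to the stimulation window; group heterogeneity of decay
constants is tested with a variance-ratio F test (two groups) or a
Brown–Forsythe test (more groups).

Mobile FM-labeled puncta (dispersing SV microclusters) are detected on a
ratio movie — each frame divided by the mean of the ten preceding frames
— where a moving diffraction-limited spot produces a bright leading edge.
Tracks must span a minimum number of *consecutive* frames (five by
default) and show a net displacement larger than one spot radius, so
blinking stationary spots do not count as mobile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy import stats as sps
from skimage.feature import peak_local_max

from .datamodel import AnalysisConfig, ImageStack

__all__ = [
    "DestainTrace",
    "DestainFit",
    "fit_destain",
    "decay_variance_test",
    "ratio_stack",
    "detect_mobile_puncta",
    "PunctaTrack",
    "MotilityResult",
    "VarianceTestResult",
]

#: τ reported for traces with no measurable decay, s.
NON_DECAY_TAU_S = 1e6


@dataclass
class DestainTrace:
    """One FM destaining trace from a single SV-cluster ROI."""

    time_s: np.ndarray
    intensity: np.ndarray
    background: "np.ndarray | float" = 0.0
    stim_window_s: tuple[float, float] = (0.0, np.inf)

    def background_subtracted(self) -> np.ndarray:
        return np.asarray(self.intensity, float) - np.asarray(self.background, float)


@dataclass
class DestainFit:
    tau_s: float
    tau_se_s: float
    amplitude: float
    baseline: float
    r_squared: float
    converged: bool
    non_decay: bool = False
    message: str = ""


def _exp_decay(t, A, tau, C):
    return A * np.exp(-t / tau) + C


def fit_destain(trace: DestainTrace) -> DestainFit:
    """Fit ``I(t) = A·exp(-(t - t0)/τ) + baseline`` to the
    background-subtracted trace within the stimulation window.

    The time origin is stimulus onset.  Traces without measurable decay
    are reported with a very large τ and flagged rather than raising.
    """
    t = np.asarray(trace.time_s, dtype=float)
    y = trace.background_subtracted()
    t0, t1 = trace.stim_window_s
    sel = (t >= t0) & (t <= t1)
    if sel.sum() < 10:
        raise ValueError("destain fit needs >= 10 samples inside the stimulation window")
    ts = t[sel] - t0
    ys = y[sel]

    span = float(np.ptp(ys))
    if span == 0:
        return DestainFit(
            NON_DECAY_TAU_S, np.inf, 0.0, float(ys[0]), np.nan,
            converged=False, non_decay=True, message="flat trace",
        )
    # initial guesses: amplitude from end-to-end drop, tau from 1/e point
    A0 = float(ys[0] - ys[-1])
    C0 = float(ys[-1])
    tau0 = max(float(ts[-1]) / 3.0, 1e-3)
    try:
        popt, pcov = optimize.curve_fit(
            _exp_decay, ts, ys,
            p0=[A0 if A0 != 0 else span, tau0, C0],
            bounds=([-10 * span, 1e-6, -np.inf], [10 * span, 10 * NON_DECAY_TAU_S, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return DestainFit(
            NON_DECAY_TAU_S, np.inf, np.nan, np.nan, np.nan,
            converged=False, non_decay=True, message=str(exc),
        )
    A, tau, C = popt
    resid = ys - _exp_decay(ts, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    tau_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    non_decay = A <= 0 or tau > 0.5 * NON_DECAY_TAU_S
    return DestainFit(
        tau_s=float(tau),
        tau_se_s=tau_se,
        amplitude=float(A),
        baseline=float(C),
        r_squared=r2,
        converged=True,
        non_decay=bool(non_decay),
        message="no measurable decay" if non_decay else "",
    )


@dataclass
class VarianceTestResult:
    statistic: float
    p_value: float
    method: str
    flagged: bool = False
    message: str = ""


def decay_variance_test(
    taus_by_group: dict[str, np.ndarray], method: str = "auto"
) -> VarianceTestResult:
    """Test for unequal variance of decay constants across groups.

    Two groups: variance-ratio F test (larger variance over smaller,
    two-sided p).  More than two groups (or ``method='brown_forsythe'``):
    Brown–Forsythe test (median-centred Levene).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in taus_by_group.items()}
    if len(groups) < 2:
        raise ValueError("variance test needs >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            return VarianceTestResult(
                np.inf, np.nan, "f_ratio", flagged=True,
                message=f"group '{name}' has n < 2",
            )
    variances = {k: float(np.var(v, ddof=1)) for k, v in groups.items()}
    if min(variances.values()) == 0:
        return VarianceTestResult(
            np.inf, 0.0, "f_ratio", flagged=True, message="zero-variance group",
        )
    if method == "brown_forsythe" or (method == "auto" and len(groups) > 2):
        stat, p = sps.levene(*groups.values(), center="median")
        return VarianceTestResult(float(stat), float(p), "brown_forsythe")
    (ka, va), (kb, vb) = sorted(variances.items(), key=lambda kv: -kv[1])[:2]
    na, nb = len(groups[ka]), len(groups[kb])
    F = va / vb
    p = 2.0 * min(
        sps.f.sf(F, na - 1, nb - 1), sps.f.cdf(F, na - 1, nb - 1)
    )
    return VarianceTestResult(float(F), float(min(p, 1.0)), "f_ratio")


def ratio_stack(
    movie: ImageStack, baseline_frames: int = 10, eps_fraction: float = 0.01
) -> ImageStack:
    """Express each frame as a ratio of the mean of the ``baseline_frames``
    frames immediately prior.

    The first ``baseline_frames`` frames are omitted from the output.  The
    denominator is floored at ``eps_fraction`` of the movie median to
    avoid division blow-ups in dark regions.
    """
    px = np.asarray(movie.pixels, dtype=float)
    if px.ndim != 3:
        raise ValueError("ratio_stack expects a (T, Y, X) movie")
    T = px.shape[0]
    if T <= baseline_frames:
        raise ValueError(
            f"movie has {T} frames; needs more than baseline_frames={baseline_frames}"
        )
    eps = max(eps_fraction * float(np.median(px)), np.finfo(float).tiny)
    # running mean of the previous `baseline_frames` frames via cumulative sum
    csum = np.cumsum(px, axis=0)
    out = np.empty((T - baseline_frames,) + px.shape[1:])
    for i, t in enumerate(range(baseline_frames, T)):
        prior = (csum[t - 1] - (csum[t - baseline_frames - 1] if t > baseline_frames else 0)) / baseline_frames
        out[i] = px[t] / np.maximum(prior, eps)
    return ImageStack(
        pixels=out,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )


@dataclass
class PunctaTrack:
    frames: list[int]              # frame indices in the *original* movie
    positions_um: np.ndarray       # (n, 2) as (y, x)
    mean_speed_um_s: float
    max_speed_um_s: float

    @property
    def net_displacement_um(self) -> float:
        return float(np.linalg.norm(self.positions_um[-1] - self.positions_um[0]))


@dataclass
class MotilityResult:
    tracks: list[PunctaTrack]
    n_mobile: int
    config: AnalysisConfig


def _detect_spots(
    frame: np.ndarray, sigma_px: float, threshold: float
) -> np.ndarray:
    """Detect diffraction-limited spots in one ratio frame.

    Difference-of-Gaussian band-pass then local maxima above the ratio
    threshold; returns (n, 2) pixel coordinates (row, col).
    """
    lo = ndimage.gaussian_filter(frame, sigma_px)
    hi = ndimage.gaussian_filter(frame, 2.0 * sigma_px)
    dog = lo - hi
    # the DoG of a unit-contrast Gaussian spot peaks well below 1; gate
    # candidate maxima on the smoothed ratio level instead
    peaks = peak_local_max(
        dog, min_distance=max(int(round(2 * sigma_px)), 1), threshold_abs=0.0
    )
    if len(peaks) == 0:
        return np.zeros((0, 2))
    keep = lo[peaks[:, 0], peaks[:, 1]] >= threshold
    return peaks[keep]


def detect_mobile_puncta(
    movie: ImageStack, config: AnalysisConfig | None = None
) -> MotilityResult:
    """Detect and count mobile puncta in an FM movie.

    Spots are detected per ratio frame, linked across consecutive frames
    by nearest-position gating (maximum displacement =
    ``max_speed_um_s``·Δt), and a track counts as mobile when it spans at
    least ``min_sequential_frames`` consecutive frames *and* its net
    displacement exceeds one spot radius.  Only tracks starting within
    the counting window (``window_s``) contribute to ``n_mobile``.
    Linking is deterministic given the movie.
    """
    if config is None:
        config = AnalysisConfig()
    if movie.frame_interval_s is None:
        raise ValueError("movie needs frame_interval_s calibration")
    dt = movie.frame_interval_s
    px_um = movie.pixel_size_um
    sigma_px = config.spot_sigma_um / px_um
    gate_px = config.max_speed_um_s * dt / px_um
    spot_radius_um = 2.0 * config.spot_sigma_um

    ratios = ratio_stack(movie, config.baseline_frames)
    frames = ratios.pixels

    # active: list of dicts with frames, positions (pixel coords)
    active: list[dict] = []
    finished: list[dict] = []
    for i in range(frames.shape[0]):
        detections = _detect_spots(frames[i], sigma_px, config.ratio_threshold)
        matched = set()
        next_active = []
        if len(detections) and active:
            # greedy assignment by ascending link distance
            cand = []
            for ti, tr in enumerate(active):
                deltas = detections - tr["positions"][-1]
                dists = np.linalg.norm(deltas, axis=1)
                for di in np.nonzero(dists <= gate_px)[0]:
                    cand.append((dists[di], ti, int(di)))
            used_tracks = set()
            for _, ti, di in sorted(cand, key=lambda c: c[0]):
                if ti in used_tracks or di in matched:
                    continue
                tr = active[ti]
                tr["frames"].append(i)
                tr["positions"] = np.vstack([tr["positions"], detections[di]])
                used_tracks.add(ti)
                matched.add(di)
                next_active.append(tr)
            finished.extend(tr for ti, tr in enumerate(active) if ti not in used_tracks)
        else:
            finished.extend(active)
        # spawn new tracks, except for satellite detections hugging a
        # track that was already extended this frame
        suppress_px = max(3.0 * sigma_px, 2.0)
        extended_pos = [tr["positions"][-1] for tr in next_active]
        for di in range(len(detections)):
            if di in matched:
                continue
            if extended_pos and np.min(
                np.linalg.norm(np.asarray(extended_pos) - detections[di], axis=1)
            ) <= suppress_px:
                continue
            next_active.append(
                {"frames": [i], "positions": detections[di][None, :]}
            )
        active = next_active
    finished.extend(active)

    # merge runs split by a missed detection (gap <= 2 frames within the
    # linking gate) so one punctum is not counted as several tracks
    finished.sort(key=lambda tr: tr["frames"][0])
    merged: list[dict] = []
    for tr in finished:
        host = None
        for m in merged:
            gap = tr["frames"][0] - m["frames"][-1]
            if 1 <= gap <= 3 and (
                np.linalg.norm(tr["positions"][0] - m["positions"][-1])
                <= min(gate_px * gap, 1.5 * gate_px)
            ):
                host = m
                break
        if host is None:
            merged.append(tr)
        else:
            host["frames"].extend(tr["frames"])
            host["positions"] = np.vstack([host["positions"], tr["positions"]])

    def _longest_run(frames: list[int]) -> int:
        best = run = 1
        for a, b in zip(frames, frames[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        return best

    tracks: list[PunctaTrack] = []
    for tr in merged:
        if _longest_run(tr["frames"]) < config.min_sequential_frames:
            continue
        pos_um = tr["positions"] * px_um
        frames_arr = np.asarray(tr["frames"], dtype=float)
        # speeds over >=4-frame windows so localization jitter does not
        # inflate them the way raw frame-to-frame steps would
        w = min(4, len(frames_arr) - 1)
        disp = np.linalg.norm(pos_um[w:] - pos_um[:-w], axis=1)
        span = (frames_arr[w:] - frames_arr[:-w]) * dt
        speeds = disp / span
        track = PunctaTrack(
            frames=[f + config.baseline_frames for f in tr["frames"]],
            positions_um=pos_um,
            mean_speed_um_s=float(speeds.mean()),
            max_speed_um_s=float(speeds.max()),
        )
        if track.net_displacement_um > spot_radius_um:
            tracks.append(track)

    window_frames = config.window_s / dt
    n_mobile = sum(
        1 for tr in tracks if tr.frames[0] - config.baseline_frames <= window_frames
    )
    return MotilityResult(tracks=tracks, n_mobile=n_mobile, config=config)
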