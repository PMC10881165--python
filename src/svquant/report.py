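"""Pipeline orchestration and derived headline quantities.

``worked_examples`` recomputes every derived headline number (fold
changes, percent depletion, percent membrane loss, nearest-neighbour
distance shifts) from the published group means; ``run_pipeline``
executes simulate → morphometry → spatial → colocalization → kinetics on
synthetic populations and writes one CSV per stage plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc, kinetics, morphometry, spatial, synthetic
from .datamodel import AnalysisConfig, SynapseAnnotation
from .io import write_annotations, write_table
from .reference import PUBLISHED_MEANS
from .stats import fold_change, group_compare, percent_change

log = logging.getLogger(__name__)

__all__ = [
    "worked_examples",
    "morphometry_table",
    "spatial_battery",
    "SpatialBatteryResult",
    "run_pipeline",
]


def worked_examples(means: dict | None = None) -> dict[str, float]:
    """Derived headline quantities recomputed from the published group
    means.

    Fold change = B/A; percent change = (A − B)/A × 100; distance shifts
    are plain differences of group means.
    """
    m = PUBLISHED_MEANS if means is None else means
    return {
        "membrane_recruitment_fold": fold_change(
            m["membrane_binding"]["ps129"], m["membrane_binding"]["wt"]
        ),
        "oligomer_monomer_fold": fold_change(
            m["oligomer_monomer_ratio"]["ps129"], m["oligomer_monomer_ratio"]["wt"]
        ),
        "sv_depletion_pct": percent_change(
            m["sv_per_synapse"]["control"], m["sv_per_synapse"]["high"]
        ),
        "total_membrane_loss_pct": percent_change(
            m["total_membrane_um2"]["control"], m["total_membrane_um2"]["high"]
        ),
        "cisterna_increase_fold": fold_change(
            m["cist_per_synapse"]["high"], m["cist_per_synapse"]["control"]
        ),
        "nn_increase_wt_nm": m["nn_mean_nm"]["wt"] - m["nn_mean_nm"]["control"],
        "nn_increase_ps129_nm": m["nn_mean_nm"]["ps129"] - m["nn_mean_nm"]["control"],
        "mobile_puncta_fold": fold_change(
            m["mobile_puncta"]["ps129"], m["mobile_puncta"]["control"]
        ),
    }


def morphometry_table(
    annotations: list[SynapseAnnotation], convention: str = "sphere_sv"
) -> pd.DataFrame:
    """Per-synapse morphometry summaries as a flat table."""
    rows = []
    for a in annotations:
        s = morphometry.summarize_synapse(a, convention=convention)
        row = asdict(s)
        stage = row.pop("ccpv_stage_counts")
        for k, c in enumerate(stage, start=1):
            row[f"n_ccpv_stage{k}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SpatialBatteryResult:
    """Pooled spatial statistics of one condition."""

    condition: str
    az_distances_nm: np.ndarray
    nn_distances_nm: np.ndarray
    nn_mean_nm: float
    nn_se_nm: float
    distribution: spatial.DistanceDistribution
    regression: spatial.RegressionResult
    gaussian_fit: spatial.TwoGaussianFit
    ellipse: spatial.EllipseFit
    bootstrap: spatial.BootstrapCI | None = None
    n_synapses: int = 0
    n_excluded: int = 0


def spatial_battery(
    annotations: list[SynapseAnnotation],
    config: AnalysisConfig | None = None,
    bootstrap: bool = False,
) -> SpatialBatteryResult:
    """Run the full SV spatial-statistics battery on one condition.

    SVs are pooled across synapses; nearest-neighbour distances are
    computed within each section only.  Sections with fewer than two SVs
    are excluded from NN statistics.
    """
    cfg = config or AnalysisConfig()
    az_all, nn_all, az_per_syn = [], [], []
    n_excluded = 0
    for a in annotations:
        if len(a.sv_centers) == 0:
            n_excluded += 1
            continue
        az = spatial.sv_to_az_distances(
            a.sv_centers, a.az_polyline, step_nm=cfg.az_discretization_step_nm
        )
        az_per_syn.append(az)
        if len(a.sv_centers) < 2:
            n_excluded += 1
            continue
        nn = spatial.nearest_neighbor(a.sv_centers)
        az_all.append(az)
        nn_all.append(nn)
    az_pooled = np.concatenate(az_all)
    nn_pooled = np.concatenate(nn_all)

    dist = spatial.distance_distribution(
        az_per_syn, bin_width_nm=cfg.distribution_bin_width_nm
    )
    reg = spatial.nn_vs_az_regression(az_pooled, nn_pooled)

    nn_hist_edges = np.arange(0.0, nn_pooled.max() + 10.0, 10.0)
    counts, edges = np.histogram(nn_pooled, bins=nn_hist_edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gfit = spatial.fit_two_gaussian_sum(centers, counts, seed=cfg.seed)

    ell = spatial.loglog_ellipse(az_pooled, nn_pooled, scale=cfg.ellipse_scale)
    boot = None
    if bootstrap:
        boot = spatial.bootstrap_ellipse(
            az_pooled, nn_pooled,
            n_sample=min(cfg.bootstrap_n, len(az_pooled)),
            reps=cfg.bootstrap_reps,
            seed=cfg.seed,
            scale=cfg.ellipse_scale,
        )
    cond = annotations[0].condition if annotations else ""
    return SpatialBatteryResult(
        condition=cond,
        az_distances_nm=az_pooled,
        nn_distances_nm=nn_pooled,
        nn_mean_nm=float(nn_pooled.mean()),
        nn_se_nm=float(nn_pooled.std(ddof=1) / np.sqrt(len(nn_pooled))),
        distribution=dist,
        regression=reg,
        gaussian_fit=gfit,
        ellipse=ell,
        bootstrap=boot,
        n_synapses=len(az_per_syn),
        n_excluded=n_excluded,
    )


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_synapses: int = 40,
    presets: tuple[str, ...] = ("control_stim", "wt_high", "ps129_high"),
    config: AnalysisConfig | None = None,
) -> dict:
    """Execute the full synthetic pipeline and write a report bundle.

    Stages: population simulation per preset, per-synapse morphometry,
    per-condition spatial battery, colocalization on a synthetic
    two-channel image, and destain/motility kinetics on a synthetic
    movie.  Writes one CSV per stage plus ``summary.json`` holding the
    group statistics and the derived headline quantities.  A stage
    failure is logged and the bundle marked partial.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or AnalysisConfig(seed=seed)
    rng = np.random.default_rng(seed)
    summary: dict = {"seed": seed, "n_synapses": n_synapses, "partial": False}

    populations: dict[str, list[SynapseAnnotation]] = {}
    try:
        for i, name in enumerate(presets):
            from dataclasses import replace

            spec = replace(
                synthetic.POPULATION_PRESETS[name],
                n_synapses=n_synapses,
                seed=seed + i,
            )
            populations[name] = synthetic.gen_synapse_population(spec)
            write_annotations(populations[name], outdir / f"annotations_{name}.json")
    except Exception:
        log.exception("simulation stage failed")
        summary["partial"] = True

    try:
        morph_tables = {
            name: morphometry_table(pop) for name, pop in populations.items()
        }
        morph_all = pd.concat(
            [t.assign(preset=name) for name, t in morph_tables.items()]
        )
        write_table(morph_all, outdir / "morphometry.csv")
        sv_by_group = {n: t["n_sv"].to_numpy(float) for n, t in morph_tables.items()}
        anova = group_compare(sv_by_group, "one_way_anova_tukey")
        summary["morphometry"] = {
            "sv_means": anova.means,
            "anova_F": anova.statistic,
            "anova_p": anova.p_value,
            "total_membrane_means": {
                n: float(t["total_membrane_um2"].mean()) for n, t in morph_tables.items()
            },
        }
        if len(presets) >= 2:
            first, last = presets[0], presets[-1]
            summary["morphometry"]["sv_depletion_pct"] = percent_change(
                anova.means[first], anova.means[last]
            )
            tm = summary["morphometry"]["total_membrane_means"]
            summary["morphometry"]["total_membrane_loss_pct"] = percent_change(
                tm[first], tm[last]
            )
    except Exception:
        log.exception("morphometry stage failed")
        summary["partial"] = True

    try:
        rows = []
        spatial_results = {}
        for name, pop in populations.items():
            res = spatial_battery(pop, cfg)
            spatial_results[name] = res
            rows.append(
                {
                    "preset": name,
                    "nn_mean_nm": res.nn_mean_nm,
                    "nn_se_nm": res.nn_se_nm,
                    "slope": res.regression.slope,
                    "slope_se": res.regression.slope_se,
                    "r_squared": res.regression.r_squared,
                    "ellipse_area": res.ellipse.area,
                    "eccentricity": res.ellipse.eccentricity,
                    "gaussian_r_squared": res.gaussian_fit.r_squared,
                    "n_sv": len(res.nn_distances_nm),
                }
            )
        write_table(pd.DataFrame(rows), outdir / "spatial.csv")
        summary["spatial"] = {r["preset"]: r for r in rows}
    except Exception:
        log.exception("spatial stage failed")
        summary["partial"] = True

    try:
        img_spec = synthetic.ImageSpec(seed=seed, density_ratio=0.15)
        stack, truth = synthetic.gen_two_channel_image(img_spec)
        marker, signal = stack.channel("marker"), stack.channel("signal")
        mask = truth["axon_mask"]  # ROI protocol: analyse within the axon
        thr = coloc.costes_thresholds(marker[mask], signal[mask])
        m1, m2 = coloc.manders(
            signal[mask], marker[mask], thr.threshold_other, thr.threshold_ref
        )
        part = coloc.density_partition(
            signal, marker, mask, stack.pixel_size_um, seed=seed
        )
        coloc_row = {
            "threshold_marker": thr.threshold_ref,
            "threshold_signal": thr.threshold_other,
            "mcc_signal_to_marker": m1,
            "mcc_marker_to_signal": m2,
            "density_ratio_pct": part.ratio_pct,
            "true_density_ratio_pct": truth["density_ratio_pct"],
        }
        write_table(pd.DataFrame([coloc_row]), outdir / "coloc.csv")
        summary["coloc"] = coloc_row
    except Exception:
        log.exception("colocalization stage failed")
        summary["partial"] = True

    try:
        taus = {}
        for name, tau_true, movers in (
            ("control", 213.0, 0),
            ("ps129", 4000.0, 8),
        ):
            mv_spec = synthetic.MovieSpec(
                seed=seed,
                roi_taus_s=(tau_true,) * 3,
                mover_speeds_um_s=tuple(rng.uniform(0.2, 1.2, movers)),
            )
            movie, mtruth = synthetic.gen_destain_movie(mv_spec)
            fits = [
                kinetics.fit_destain(
                    extract_roi_trace(movie, c, 1.2, mtruth["stim_onset_s"])
                )
                for c in mtruth["roi_centers_um"]
            ]
            mot = kinetics.detect_mobile_puncta(movie, cfg)
            taus[name] = {
                "tau_mean_s": float(np.mean([f.tau_s for f in fits])),
                "tau_true_s": tau_true,
                "n_mobile": mot.n_mobile,
                "n_movers_true": mtruth["n_movers"],
            }
        write_table(
            pd.DataFrame(taus).T.reset_index(names="group"), outdir / "kinetics.csv"
        )
        summary["kinetics"] = taus
    except Exception:
        log.exception("kinetics stage failed")
        summary["partial"] = True

    summary["worked_examples"] = worked_examples()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def extract_roi_trace(
    movie,
    center_um: np.ndarray,
    radius_um: float,
    stim_onset_s: float,
) -> kinetics.DestainTrace:
    """Mean-intensity trace of a circular ROI, with the background taken
    as the per-frame median outside a 2× radius."""
    px = movie.pixel_size_um
    n = movie.pixels.shape[1]
    yy, xx = np.mgrid[0:n, 0: movie.pixels.shape[2]].astype(float)
    cy, cx = np.asarray(center_um, dtype=float) / px
    r_px = radius_um / px
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    roi = d2 <= r_px**2
    bg_region = d2 >= (2 * r_px) ** 2
    t = np.arange(movie.pixels.shape[0]) * movie.frame_interval_s
    intensity = movie.pixels[:, roi].mean(axis=1)
    background = np.median(movie.pixels[:, bg_region], axis=1)
    return kinetics.DestainTrace(
        time_s=t,
        intensity=intensity,
        background=background,
        stim_window_s=(stim_onset_s, t[-1]),
    )
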