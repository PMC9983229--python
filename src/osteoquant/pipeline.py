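"""End-to-end runs: simulate cohorts, quantify, compare groups.

`run_pipeline` drives the whole chain from one configuration: for every
group and synthetic mouse it simulates osteoclast movies (resorption,
deformation and TRAP⁺-area read-outs) and precursor movies (tracking-speed
and bone-adhesion read-outs), renders and quantifies them, and then applies
the group comparisons.  All tabular outputs are CSV and reruns with the
same configuration are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as mx
from . import preprocess as pp
from . import segmentation as seg
from . import synthetic as syn
from . import tracking as trk
from .stats import ALPHA, compare_groups

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "cohort_study_config",
    "analyze_osteoclast_movie",
    "analyze_precursor_movie",
    "run_pipeline",
]

#: Analysis parameters echoed into every run log.
ANALYSIS_DEFAULTS = dict(
    gamma_tdtomato=pp.GAMMA_TDTOMATO,
    gamma_phocas=pp.GAMMA_PHOCAS,
    otsu_bins=256,
    min_volume_exclusive_um3=50.0,
    max_link_distance_um=6.0,
    max_gap_frames=3,
    motion_model="autoregressive",
    bone_dilation_vox=1,
    cdi_match_gate_um=20.0,
    min_detection_area_um2=10.0,
    alpha=ALPHA,
)

METRICS = ("bri", "cdi", "speed", "adhesion_fraction", "trap_area_rel")


class ConfigError(ValueError):
    """Invalid run configuration."""


def cohort_study_config(
    n_mice: int = 5,
    n_osteoclast_images: int = 3,
    n_precursor_movies: int = 2,
    field_size_px: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> dict:
    """Three-cohort configuration (steady / vehicle / JAK inhibitor)
    mirroring the inflammatory bone-destruction study design, scaled to
    fields that run end-to-end in minutes."""
    return {
        "seed": seed,
        "control_group": "vehicle",
        "groups": [
            {
                "label": label,
                "preset": label,
                "n_mice": n_mice,
                "n_osteoclast_images": n_osteoclast_images,
                "n_precursor_movies": n_precursor_movies,
                "scene": {"field_size_px": list(field_size_px)},
            }
            for label in ("steady", "vehicle", "jaki")
        ],
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cfg
    if isinstance(config, dict):
        return config
    raise ConfigError(f"unsupported config type {type(config)!r}")


def _validate_config(cfg: dict) -> None:
    if "groups" not in cfg or not cfg["groups"]:
        raise ConfigError(
            "config needs a non-empty 'groups' generator block (no external "
            "input path mode is available)"
        )
    for i, grp in enumerate(cfg["groups"]):
        for key in ("label", "n_mice"):
            if key not in grp:
                raise ConfigError(f"groups[{i}]: missing required key {key!r}")
        if grp["n_mice"] < 1:
            raise ConfigError(f"groups[{i}]: n_mice must be >= 1")


def _scene_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Per-movie analyses
# ---------------------------------------------------------------------------


def analyze_osteoclast_movie(
    stack,
    library: pp.SpectralLibrary,
    cdi_window: tuple[int, int] | None = None,
    image_id: str | None = None,
) -> dict:
    """Quantify one osteoclast movie.

    Unmix, gamma-correct (tdTomato 0.9, pHocas-3 2.5), maximum-project,
    Otsu-binarise the tdTomato channel, then compute the resorption index
    on frame 0, per-cell deformation indices over the 10-min window
    (default: first and last frame), and the total TRAP⁺ area.
    """
    unmixed = pp.unmix(stack, library)
    td = pp.gamma_correct(unmixed.channel("tdTomato"), pp.GAMMA_TDTOMATO)
    ph = pp.gamma_correct(unmixed.channel("pHocas3"), pp.GAMMA_PHOCAS)
    td_mip = td.max(axis=1)  # (t, y, x)
    ph_mip = ph.max(axis=1)
    px = stack.pixel_size_um
    if cdi_window is None:
        cdi_window = (0, stack.n_frames - 1)

    def labels_at(t: int) -> seg.RegionLabels:
        frame = td_mip[t]
        thr = seg.otsu_threshold(frame, nbins=ANALYSIS_DEFAULTS["otsu_bins"])
        return seg.binarize_and_label(frame, thr, pixel_size_um=px, frame=t)

    labels0 = labels_at(0)
    bri = mx.bone_resorption_index(ph_mip[0], labels0.mask(), image_id=image_id)
    cdis = mx.deformation_indices(
        labels_at(cdi_window[0]),
        labels_at(cdi_window[1]),
        max_match_um=ANALYSIS_DEFAULTS["cdi_match_gate_um"],
        window=cdi_window,
    )
    return dict(
        bri=bri.bri,
        cdi_values=[c.cdi for c in cdis],
        trap_total_area_um2=labels0.total_measure(),
    )


def analyze_precursor_movie(
    stack,
    library: pp.SpectralLibrary,
    image_id: str | None = None,
) -> dict:
    """Quantify one precursor movie.

    Unmix, correct field drift against the bone (SHG) channel, detect
    EGFP⁺ cells per frame via Otsu on the projection, link them with the
    6 µm / gap-3 tracker and compute per-track mean speeds; on the frame-0
    volume, segment EGFP⁺ objects in 3D, drop objects <= 50 µm³, and
    measure their colocalization with the (dilated) SHG bone mask.
    """
    unmixed = pp.unmix(stack, library)
    corrected, drift = pp.correct_drift(unmixed, reference_channel="SHG")
    egfp = corrected.channel("EGFP")  # (t, z, y, x)
    px = stack.pixel_size_um
    min_area = ANALYSIS_DEFAULTS["min_detection_area_um2"]

    labels_by_frame = []
    for t in range(stack.n_frames):
        frame = egfp[t].max(axis=0)
        thr = seg.otsu_threshold(frame, nbins=ANALYSIS_DEFAULTS["otsu_bins"])
        labels = seg.binarize_and_label(frame, thr, pixel_size_um=px, frame=t)
        labels.table = labels.table[labels.table["area_um2"] > min_area].reset_index(
            drop=True
        )
        labels_by_frame.append(labels)
    detections = trk.detections_from_labels(labels_by_frame)
    trackset = trk.link_frames(
        detections,
        max_distance_um=ANALYSIS_DEFAULTS["max_link_distance_um"],
        max_gap_frames=ANALYSIS_DEFAULTS["max_gap_frames"],
        motion_model=ANALYSIS_DEFAULTS["motion_model"],
    )
    speeds = trackset.speed_table(stack.frame_interval_s)

    # bone adhesion on the frame-0 volume
    egfp0 = egfp[0]
    thr3 = seg.otsu_threshold(egfp0, nbins=ANALYSIS_DEFAULTS["otsu_bins"])
    labels3 = seg.binarize_and_label(
        egfp0, thr3, pixel_size_um=px, z_step_um=stack.z_step_um
    )
    labels3 = seg.filter_by_volume(
        labels3, ANALYSIS_DEFAULTS["min_volume_exclusive_um3"]
    )
    shg0 = corrected.channel("SHG")[0]
    shg_thr = seg.otsu_threshold(shg0, nbins=ANALYSIS_DEFAULTS["otsu_bins"])
    bone = seg.dilated_bone_mask(
        shg0 > shg_thr, radius_vox=ANALYSIS_DEFAULTS["bone_dilation_vox"]
    )
    coloc, _ = seg.colocalize(
        labels3.mask(), bone, pixel_size_um=px, z_step_um=stack.z_step_um
    )
    if labels3.n_objects:
        adhesion = mx.adhesion_ratio(labels3, coloc, image_id=image_id)
        adhesion_fraction = adhesion.adhesion_fraction
        printed_ratio = adhesion.printed_ratio
    else:
        logger.warning("%s: no precursor objects survived the volume filter", image_id)
        adhesion_fraction = np.nan
        printed_ratio = np.nan
    return dict(
        speeds_um_min=speeds["speed_um_min"].tolist(),
        adhesion_fraction=adhesion_fraction,
        printed_ratio=printed_ratio,
        drift_shifts_px=drift.shifts_px.tolist(),
        n_tracks=len(trackset.tracks),
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_pipeline(config, seed: int | None = None, outdir: str | Path = "run") -> Path:
    """Execute generate -> preprocess -> segment -> metrics/tracking ->
    statistics for every group/mouse in the configuration.

    Returns the run directory, which contains ``metrics.csv`` (long-format
    observations), ``comparisons.csv`` and ``posthoc.csv`` (statistics),
    ``run_log.jsonl`` (every analysis parameter and scene seed), and
    optionally ``figures/``.
    """
    cfg = _load_config(config)
    _validate_config(cfg)
    base_seed = int(seed if seed is not None else cfg.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = pp.default_library()

    log_path = outdir / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(record: dict) -> None:
        log_fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")

    log(dict(event="start", seed=base_seed, analysis=ANALYSIS_DEFAULTS))

    rows = []
    trap_raw = []  # (group, mouse, image, raw total area)
    for gi, grp in enumerate(cfg["groups"]):
        label = grp["label"]
        preset = dict(syn.GROUP_PRESETS.get(grp.get("preset", ""), {}))
        preset["group_label"] = label
        preset.update(grp.get("scene", {}))
        if "field_size_px" in preset:
            preset["field_size_px"] = tuple(preset["field_size_px"])
        if "precursor_speed_um_min" in preset:
            preset["precursor_speed_um_min"] = tuple(preset["precursor_speed_um_min"])
        for mouse in range(int(grp["n_mice"])):
            for img in range(int(grp.get("n_osteoclast_images", 1))):
                scn_seed = _scene_seed(base_seed, gi, mouse, 0, img)
                oc_cfg = syn.osteoclast_movie_config(seed=scn_seed, **{
                    k: v for k, v in preset.items()
                    if k not in ("precursor_speed_um_min", "adhesion_probability")
                })
                scene = syn.simulate_trajectories(oc_cfg)
                stack = syn.render_stack(scene, spectral_library=library)
                image_id = f"{label}/m{mouse}/oc{img}"
                res = analyze_osteoclast_movie(stack, library, image_id=image_id)
                log(dict(event="osteoclast_movie", image=image_id, seed=scn_seed,
                         config=oc_cfg.__dict__))
                rows.append(dict(group=label, mouse=mouse, image=image_id,
                                 metric="bri", value=res["bri"]))
                for k, cdi in enumerate(res["cdi_values"]):
                    rows.append(dict(group=label, mouse=mouse,
                                     image=f"{image_id}/cell{k}",
                                     metric="cdi", value=cdi))
                trap_raw.append((label, mouse, image_id, res["trap_total_area_um2"]))
            for img in range(int(grp.get("n_precursor_movies", 1))):
                scn_seed = _scene_seed(base_seed, gi, mouse, 1, img)
                pc_cfg = syn.precursor_movie_config(seed=scn_seed, **{
                    k: v for k, v in preset.items()
                    if k not in ("r_type_fraction", "n_osteoclasts")
                })
                scene = syn.simulate_trajectories(pc_cfg)
                stack = syn.render_stack(scene, spectral_library=library)
                image_id = f"{label}/m{mouse}/pc{img}"
                res = analyze_precursor_movie(stack, library, image_id=image_id)
                log(dict(event="precursor_movie", image=image_id, seed=scn_seed,
                         config=pc_cfg.__dict__, n_tracks=res["n_tracks"]))
                for k, v in enumerate(res["speeds_um_min"]):
                    rows.append(dict(group=label, mouse=mouse,
                                     image=f"{image_id}/track{k}",
                                     metric="speed", value=v))
                if np.isfinite(res["adhesion_fraction"]):
                    rows.append(dict(group=label, mouse=mouse, image=image_id,
                                     metric="adhesion_fraction",
                                     value=res["adhesion_fraction"]))

    # TRAP area relative to the reference (first) group's mean
    reference_label = cfg.get("reference_group", cfg["groups"][0]["label"])
    ref_areas = [a for g, _, _, a in trap_raw if g == reference_label]
    ref_mean = float(np.mean(ref_areas))
    for g, mouse, image_id, area in trap_raw:
        rows.append(dict(group=g, mouse=mouse, image=image_id,
                         metric="trap_area_rel", value=area / ref_mean))

    metrics_df = pd.DataFrame(rows, columns=["group", "mouse", "image", "metric", "value"])
    metrics_df.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")

    # ---- statistics -----------------------------------------------------
    labels = [g["label"] for g in cfg["groups"]]
    control = cfg.get("control_group")
    comp_rows, post_rows = [], []
    if len(labels) >= 2:
        design = (
            "multi_group_nonparametric" if len(labels) >= 3 else "two_group_nonparametric"
        )
        for metric in METRICS:
            sub = metrics_df[metrics_df["metric"] == metric]
            if sub.empty:
                continue
            try:
                result = compare_groups(sub, metric, labels, design, control=None)
            except ValueError as exc:
                logger.warning("comparison for %s skipped: %s", metric, exc)
                continue
            comp_rows.append(dict(
                metric=metric,
                test=result.test,
                statistic=result.statistic,
                pvalue=result.pvalue,
                significant=result.significant,
                **{f"n_{g}": result.n_per_group[g] for g in labels},
            ))
            for (a, b), padj in sorted(result.posthoc.items()):
                post_rows.append(dict(metric=metric, group_a=a, group_b=b,
                                      p_adjusted=padj,
                                      significant=padj < ALPHA))
    pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False,
                                   float_format="%.10g")
    pd.DataFrame(post_rows).to_csv(outdir / "posthoc.csv", index=False,
                                   float_format="%.10g")
    log(dict(event="done", control_group=control,
             n_observations=len(metrics_df)))
    log_fh.close()

    if cfg.get("make_figures"):
        _summary_figures(metrics_df, outdir / "figures")
    return outdir


def _summary_figures(metrics_df: pd.DataFrame, figdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    for metric, sub in metrics_df.groupby("metric"):
        fig, ax = plt.subplots(figsize=(4, 3))
        groups = list(sub["group"].unique())
        data = [sub.loc[sub["group"] == g, "value"] for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(figdir / f"{metric}.png", dpi=120)
        plt.close(fig)
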