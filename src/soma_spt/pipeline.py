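"""End-to-end orchestration: simulate → detect → track → analyze → evaluate.

Two modes mirror the two acquisition geometries: "movie" analyses a
fixed-z time series (detection per frame, trajectory linking, dynamics),
"zstack" analyses a two-channel z-stack (membrane segmentation,
per-plane QD localization, z-linking, membrane/internal classification).
Every output CSV/JSON carries the seed and a hash of the configuration,
and identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_analyzer, detection, dynamics, synthetic_data, tracking
from .synthetic_data import BlinkModel, CameraModel, MotionPhase, PSFModel

log = logging.getLogger("soma_spt")


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run."""

    mode: str = "movie"  # "movie" | "zstack"
    seed: int = 0
    # simulation
    simulate: bool = True
    n_frames: int = 100
    image_shape: tuple[int, int] = (64, 64)
    dt_s: float = 1.0 / 9.0
    camera: dict = field(default_factory=dict)
    psf: dict = field(default_factory=dict)
    blink: dict = field(default_factory=dict)
    phases: list = field(default_factory=lambda: [{"kind": "brownian", "duration": 10.0, "D": 0.29}])
    n_particles: int = 3
    min_separation_um: float = 2.0
    # zstack simulation
    n_qd: int = 50
    frac_internal: float = 0.9
    n_planes: int = 15
    cell_radius_um: float = 6.0
    membrane_label_photons: float = 300.0
    # detection
    detect: bool = True
    psf_sigma: float = 1.2
    intensity_min: float = 100.0
    llr_pvalue_max: float = 1e-3
    # tracking
    track: bool = True
    max_disp_um: float = 0.64
    max_gap: int = 5
    # dynamics / classification
    analyze: bool = True
    d_mem_um: float = 0.25
    # inputs when not simulating
    input_path: str | None = None
    membrane_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.mode not in ("movie", "zstack"):
            raise ValueError("mode must be 'movie' or 'zstack'")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def camera_model(self) -> CameraModel:
        return CameraModel(**self.camera)

    def psf_model(self) -> PSFModel:
        return PSFModel(**self.psf)

    def blink_model(self) -> BlinkModel:
        return BlinkModel(**self.blink)


@dataclass
class EvaluationReport:
    """Accuracy of the pipeline against simulator ground truth."""

    detection_precision: float = np.nan
    detection_recall: float = np.nan
    localization_rmse_um: float = np.nan
    trajectory_purity: float = np.nan
    confusion: dict = field(default_factory=dict)  # truth label -> {pred: n}
    fraction_internal_error: float = np.nan

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sidecar(cfg: RunConfig) -> dict:
    return {"seed": cfg.seed, "config_hash": cfg.config_hash()}


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={cfg.seed} config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order; return the result bundle.

    Writes localizations.csv, trajectories.csv, msd_fits.json,
    phases.csv (movie mode) or qd_locations.csv + internalization.json
    (zstack mode), and evaluation.json when ground truth is available.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    camera = config.camera_model()
    psf = config.psf_model()
    bundle: dict = {"config_hash": config.config_hash()}
    try:
        if config.mode == "movie":
            _run_movie(config, outdir, camera, psf, bundle)
        else:
            _run_zstack(config, outdir, camera, psf, bundle)
    except Exception as exc:  # noqa: BLE001 - stage attribution on failure
        stage = bundle.get("stage", "setup")
        log.error("stage %r failed: %s", stage, exc)
        raise
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(_sidecar(config), fh, indent=2, sort_keys=True)
    return bundle


def _run_movie(config, outdir, camera, psf, bundle) -> None:
    rng = np.random.default_rng(config.seed)
    truth = None
    if config.simulate:
        bundle["stage"] = "simulate"
        phases = [MotionPhase(**p) for p in config.phases]
        h, w = config.image_shape
        p = camera.pixel_size
        truths = []
        origins: list[np.ndarray] = []
        for i in range(config.n_particles):
            for _ in range(500):
                cand = np.array(
                    [rng.uniform(0.2 * w * p, 0.8 * w * p),
                     rng.uniform(0.2 * h * p, 0.8 * h * p)]
                )
                if all(
                    np.linalg.norm(cand - o) >= config.min_separation_um for o in origins
                ):
                    break
            else:
                raise ValueError("field too small for the requested particle separation")
            origins.append(cand)
            # resample walks that would exit the field of view
            margin = 8 * p
            for _ in range(200):
                tr = synthetic_data.simulate_trajectory(
                    phases, config.dt_s, (cand[0], cand[1], 0.0), rng, particle_id=i
                )
                xy = tr.positions[:, :2]
                if (
                    xy[:, 0].min() >= margin
                    and xy[:, 1].min() >= margin
                    and xy[:, 0].max() <= w * p - margin
                    and xy[:, 1].max() <= h * p - margin
                ):
                    break
            else:
                raise ValueError("could not keep a trajectory inside the field of view")
            truths.append(tr)
        movie, truth = synthetic_data.render_movie(
            truths, camera, psf, config.blink_model(), config.n_frames,
            tuple(config.image_shape), rng,
        )
        synthetic_data.write_stack(
            outdir / "movie.tif", movie,
            {"pixel_size_um": camera.pixel_size, "dt_s": config.dt_s, **_sidecar(config)},
            truth,
        )
    else:
        if not config.input_path:
            raise ValueError("input_path required when simulate is off")
        movie, _ = synthetic_data.read_stack(config.input_path)
    bundle["movie_shape"] = movie.shape
    if not config.detect:
        return

    bundle["stage"] = "detect"
    per_frame = [
        detection.detect_frame(
            movie[f], camera, psf_sigma=config.psf_sigma, frame_index=f,
            intensity_min=config.intensity_min, llr_pvalue_max=config.llr_pvalue_max,
        )
        for f in range(movie.shape[0])
    ]
    loc_rows = [
        dict(frame=f.frame, x_um=f.x_um, y_um=f.y_um, photons=f.photons,
             bg=f.background, crlb_um=f.crlb_xy_um, accepted=f.accepted)
        for fits in per_frame for f in fits
    ]
    loc_df = pd.DataFrame(
        loc_rows, columns=["frame", "x_um", "y_um", "photons", "bg", "crlb_um", "accepted"]
    )
    _write_csv(loc_df, outdir / "localizations.csv", config)
    bundle["localizations"] = loc_df
    if not config.track:
        return

    bundle["stage"] = "track"
    trajs = tracking.link_trajectories(
        per_frame, config.dt_s, config.max_disp_um, config.max_gap
    )
    traj_rows = [
        dict(particle_id=tr.particle_id, frame=int(fr), t_s=float(ts),
             x_um=float(x), y_um=float(y), gap=bool(g))
        for tr in trajs
        for fr, ts, (x, y), g in zip(tr.frames, tr.times, tr.xy, tr.gap)
    ]
    traj_df = pd.DataFrame(
        traj_rows, columns=["particle_id", "frame", "t_s", "x_um", "y_um", "gap"]
    )
    _write_csv(traj_df, outdir / "trajectories.csv", config)
    bundle["trajectories"] = trajs
    if not config.analyze:
        return

    bundle["stage"] = "analyze"
    msd_fits, phase_rows = {}, []
    for tr in trajs:
        if tr.n_observed >= 10:
            try:
                fit = dynamics.fit_msd(dynamics.compute_msd(tr))
            except ValueError:  # too short for a stable fit
                pass
            else:
                msd_fits[tr.particle_id] = dict(
                    model=fit.model, D_um2_s=fit.D,
                    L_um=None if np.isnan(fit.L) else fit.L,
                    offset_um2=fit.offset, r2=fit.r2, model_ok=fit.model_ok,
                )
        if tr.times[-1] - tr.times[0] >= 4.0:
            try:
                segs = dynamics.segment_phases(tr)
            except ValueError:
                segs = []
            for seg in segs:
                phase_rows.append(
                    dict(particle_id=tr.particle_id, start_s=seg.start_s,
                         end_s=seg.end_s, kind=seg.kind, v_um_s=seg.v)
                )
    with open(outdir / "msd_fits.json", "w") as fh:
        json.dump({**_sidecar(config), "fits": msd_fits}, fh, indent=2, sort_keys=True)
    phase_df = pd.DataFrame(
        phase_rows, columns=["particle_id", "start_s", "end_s", "kind", "v_um_s"]
    )
    _write_csv(phase_df, outdir / "phases.csv", config)
    bundle["msd_fits"] = msd_fits
    bundle["phases"] = phase_df

    if truth is not None:
        bundle["stage"] = "evaluate"
        report = evaluate_against_truth(bundle, truth, pixel_size_um=camera.pixel_size)
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump({**_sidecar(config), **report.as_dict()}, fh, indent=2, sort_keys=True)
        bundle["evaluation"] = report


def _run_zstack(config, outdir, camera, psf, bundle) -> None:
    rng = np.random.default_rng(config.seed)
    truth = None
    if config.simulate:
        bundle["stage"] = "simulate"
        geom = synthetic_data.make_cell_geometry(
            center_um=(config.image_shape[1] * camera.pixel_size / 2,
                       config.image_shape[0] * camera.pixel_size / 2),
            mean_radius_um=config.cell_radius_um,
            n_planes=config.n_planes,
            seed=rng,
        )
        qd_stack, mem_stack, truth = synthetic_data.simulate_cell_zstack(
            geom, config.n_qd, config.frac_internal,
            config.membrane_label_photons, camera, psf, rng,
            image_shape=tuple(config.image_shape),
        )
        meta = {"pixel_size_um": camera.pixel_size, "z_step_um": geom.z_step,
                **_sidecar(config)}
        synthetic_data.write_stack(outdir / "qd_stack.tif", qd_stack, meta, truth)
        synthetic_data.write_stack(outdir / "membrane_stack.tif", mem_stack, meta)
        z_step = geom.z_step
    else:
        if not (config.input_path and config.membrane_path):
            raise ValueError("input_path and membrane_path required when simulate is off")
        qd_stack, meta = synthetic_data.read_stack(config.input_path)
        mem_stack, _ = synthetic_data.read_stack(config.membrane_path)
        z_step = meta.get("z_step_um", 0.300)
    if not config.detect:
        return

    bundle["stage"] = "segment_membrane"
    mem_cal = np.stack(
        [detection.calibrate(pl, camera).counts for pl in mem_stack]
    )
    membrane = cell_analyzer.segment_membrane(
        mem_cal, pixel_size_um=camera.pixel_size, z_step=z_step
    )
    bundle["membrane"] = membrane

    bundle["stage"] = "localize"
    roi_half = detection.DEFAULT_ROI_HALF
    per_plane: list[list[tuple[float, float]]] = []
    for j in range(qd_stack.shape[0]):
        frame = detection.calibrate(qd_stack[j], camera)
        cands = detection.find_candidates(frame, roi_half=roi_half)
        locs = []
        for r, c in cands:
            roi = frame.counts[r - roi_half : r + roi_half + 1, c - roi_half : c + roi_half + 1]
            try:
                locs.append(
                    cell_analyzer.localize_radial_symmetry(
                        roi, camera.pixel_size, roi_origin=(r - roi_half, c - roi_half)
                    )
                )
            except ValueError:
                continue
        per_plane.append(locs)

    bundle["stage"] = "link_z"
    qds = cell_analyzer.link_z(
        per_plane, z_step=z_step, pixel_size_um=camera.pixel_size
    )
    qds = [cell_analyzer.classify_location(q, membrane, config.d_mem_um) for q in qds]
    qd_df = pd.DataFrame(
        [dict(x_um=q.x_um, y_um=q.y_um, z_um=q.z_um, n_planes=q.n_planes,
              label=q.label, dist_membrane_um=q.dist_membrane) for q in qds],
        columns=["x_um", "y_um", "z_um", "n_planes", "label", "dist_membrane_um"],
    )
    _write_csv(qd_df, outdir / "qd_locations.csv", config)
    frac = cell_analyzer.internalization_fraction(qds) if qds else {}
    with open(outdir / "internalization.json", "w") as fh:
        json.dump({**_sidecar(config), **frac}, fh, indent=2, sort_keys=True)
    bundle["qd_locations"] = qds
    bundle["internalization"] = frac

    if truth is not None:
        bundle["stage"] = "evaluate"
        report = EvaluationReport()
        report.confusion = _label_confusion(qds, truth)
        truth_frac = (truth["label"] == "internal").mean()
        if frac.get("defined"):
            report.fraction_internal_error = float(
                abs(frac["fraction_internal"] - truth_frac)
            )
        prec, rec, rmse = _match_points(
            np.array([[q.x_um, q.y_um] for q in qds]) if qds else np.empty((0, 2)),
            truth[["x_um", "y_um"]].to_numpy(),
            tol_um=2 * camera.pixel_size,
        )
        report.detection_precision, report.detection_recall = prec, rec
        report.localization_rmse_um = rmse
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump({**_sidecar(config), **report.as_dict()}, fh, indent=2, sort_keys=True)
        bundle["evaluation"] = report


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------


def _match_points(
    pred: np.ndarray, truth: np.ndarray, tol_um: float
) -> tuple[float, float, float]:
    """Greedy nearest matching (each truth used once): precision, recall, RMSE."""
    if len(pred) == 0 or len(truth) == 0:
        return (np.nan, 0.0 if len(truth) else np.nan, np.nan)
    d = np.linalg.norm(pred[:, None, :] - truth[None, :, :], axis=-1)
    pairs = sorted(
        ((d[i, j], i, j) for i in range(len(pred)) for j in range(len(truth))),
    )
    used_p, used_t, errs = set(), set(), []
    for dist, i, j in pairs:
        if dist > tol_um:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        errs.append(dist)
    tp = len(errs)
    precision = tp / len(pred)
    recall = tp / len(truth)
    rmse = float(np.sqrt(np.mean(np.square(errs)))) if errs else np.nan
    return precision, recall, rmse


def _label_confusion(qds, truth: pd.DataFrame) -> dict:
    """Confusion of predicted labels vs truth labels by nearest position."""
    conf: dict[str, dict[str, int]] = {}
    if not qds:
        return conf
    pred_xy = np.array([[q.x_um, q.y_um] for q in qds])
    for _, row in truth.iterrows():
        d = np.linalg.norm(pred_xy - np.array([row.x_um, row.y_um]), axis=1)
        i = int(np.argmin(d))
        pred_label = qds[i].label if d[i] <= 0.5 else "missed"
        conf.setdefault(row.label, {})
        conf[row.label][pred_label] = conf[row.label].get(pred_label, 0) + 1
    return conf


def evaluate_against_truth(
    bundle: dict, truth: pd.DataFrame, pixel_size_um: float = 0.127
) -> EvaluationReport:
    """Score movie-mode detections and trajectories against the truth table.

    Detections are matched per frame to on-state truth positions within
    2 pixels (greedy nearest, each truth point used once). Trajectory
    purity is the mean, over trajectories, of the fraction of observed
    localizations whose nearest truth particle equals the trajectory's
    majority particle.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    report = EvaluationReport()
    tol = 2 * pixel_size_um

    loc_df = bundle.get("localizations")
    if loc_df is not None and not loc_df.empty:
        precs, recs, errs = [], [], []
        for f, grp in loc_df.groupby("frame"):
            tf = truth[(truth.frame == f) & truth.on]
            if tf.empty:
                continue
            p, r, rmse = _match_points(
                grp[["x_um", "y_um"]].to_numpy(), tf[["x_um", "y_um"]].to_numpy(), tol
            )
            if not np.isnan(p):
                precs.append(p)
            recs.append(r)
            if not np.isnan(rmse):
                errs.append(rmse)
        report.detection_precision = float(np.mean(precs)) if precs else np.nan
        report.detection_recall = float(np.mean(recs)) if recs else np.nan
        report.localization_rmse_um = float(np.sqrt(np.mean(np.square(errs)))) if errs else np.nan

    trajs = bundle.get("trajectories")
    if trajs:
        purities = []
        for tr in trajs:
            ids = []
            for fr, (x, y), g in zip(tr.frames, tr.xy, tr.gap):
                if g:
                    continue
                tf = truth[(truth.frame == fr) & truth.on]
                if tf.empty:
                    continue
                d = np.hypot(tf.x_um.to_numpy() - x, tf.y_um.to_numpy() - y)
                if d.min() <= tol:
                    ids.append(int(tf.particle_id.to_numpy()[np.argmin(d)]))
            if ids:
                vals, counts = np.unique(ids, return_counts=True)
                purities.append(counts.max() / len(ids))
        report.trajectory_purity = float(np.mean(purities)) if purities else np.nan
    return report
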