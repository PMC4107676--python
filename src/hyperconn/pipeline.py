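"""End-to-end pipeline: simulate, model, track, connect, measure, predict.

The pipeline has two arms sharing one global seed.  The phantom arm
exercises the imaging chain: simulated DWI -> tensor scalar maps and Q-Ball
peaks -> streamline tractography -> connectome -> graph metrics.  The cohort
arm exercises the statistical chain: synthetic two-group cohort -> per-subject
network metrics -> group discrimination (Mann-Whitney U, AUROC) -> iterated
cross-validated behavior prediction.

Every stage derives its seed deterministically from the global seed and the
stage name, so a report is byte-identical across runs with the same seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__, io
from .connectome import build_connectome
from .diffusion import extract_peaks, fit_tensor, gfa, qball_odf, scalar_maps
from .graphs import network_metrics
from .predict import CVConfig, FeatureMatrix, auroc, mann_whitney_u, run_cv_prediction
from .synthetic import (
    Bundle,
    CohortSpec,
    PhantomSpec,
    make_cohort,
    make_dwi_phantom,
    phantom_parcellation,
)
from .tracking import TrackingConfig, filter_fibers, seed_and_track, wm_mask
from .connectome import assign_endpoints

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return (int(global_seed) * 1_000_003 + h) % (2**31)


def _default_bundles() -> list[Bundle]:
    # two straight bundles crossing at 90 degrees in distinct z-slabs
    return [
        Bundle(center=(11.5, 11.5, 3.0), orientation=(1, 0, 0), radius=1.6),
        Bundle(center=(11.5, 11.5, 7.0), orientation=(0, 1, 0), radius=1.6),
    ]


@dataclass
class PipelineConfig:
    """Configuration of the full run; stage seeds come from ``seed``."""

    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        grid_shape=(24, 24, 11), bundles=_default_bundles(), snr=50.0
    ))
    tracking: TrackingConfig = field(default_factory=lambda: TrackingConfig(
        max_batches=3
    ))
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cv: CVConfig = field(default_factory=lambda: CVConfig(
        scheme="integral", n_iterations=200
    ))
    sh_order: int = 8
    qball_regularization: float = 0.006
    n_restarts: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        kwargs = {}
        if "phantom" in cfg:
            ph = dict(cfg["phantom"])
            if "bundles" in ph:
                ph["bundles"] = [Bundle(**b) for b in ph["bundles"]]
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            kwargs["phantom"] = PhantomSpec(**ph)
        if "tracking" in cfg:
            kwargs["tracking"] = TrackingConfig(**cfg["tracking"])
        if "cohort" in cfg:
            co = dict(cfg["cohort"])
            for key in ("weeks", "informative_regions"):
                if key in co and co[key] is not None:
                    co[key] = tuple(co[key])
            kwargs["cohort"] = CohortSpec(**co)
        if "cv" in cfg:
            kwargs["cv"] = CVConfig(**cfg["cv"])
        for key in ("sh_order", "qball_regularization", "n_restarts", "seed"):
            if key in cfg:
                kwargs[key] = cfg[key]
        return cls(**kwargs)


def _phantom_arm(config: PipelineConfig, out_dir: Path | None) -> dict:
    spec = replace(config.phantom, seed=stage_seed(config.seed, "phantom"))
    dwi = make_dwi_phantom(spec)
    tensors = fit_tensor(dwi)
    maps = scalar_maps(tensors)
    odf = qball_odf(dwi, config.sh_order, config.qball_regularization)
    gfa_map = gfa(odf)
    peaks = extract_peaks(odf, voxel_size=dwi.voxel_size)

    cfg = replace(config.tracking, seed=stage_seed(config.seed, "tracking"))
    wm = wm_mask(gfa_map, peaks, cfg, dwi.mask)
    tracks = seed_and_track(peaks, cfg, wm)
    parc = phantom_parcellation(spec)
    pairs = [assign_endpoints(t, parc) for t in tracks]
    tracks = filter_fibers(tracks, cfg, pairs)
    conn, report = build_connectome(tracks, parc, int(wm.sum()))
    metrics = network_metrics(
        conn, n_restarts=config.n_restarts, seed=stage_seed(config.seed, "metrics")
    )
    if out_dir is not None:
        io.save_dwi(out_dir, dwi)
        io.save_nifti(out_dir / "fa.nii.gz", maps.fa, dwi.voxel_size)
        io.save_nifti(out_dir / "gfa.nii.gz", gfa_map, dwi.voxel_size)
        io.save_tck(out_dir / "tracks.tck", tracks, dwi.voxel_size)
        io.save_connectome_tsv(out_dir / "phantom_connectome.tsv", conn)
    nz = np.triu(conn.weights, 1) > 0
    return {
        "n_wm_voxels": int(wm.sum()),
        "n_streamlines": len(tracks),
        "track_report": report,
        "n_edges": int(nz.sum()),
        "mean_fa_wm": float(maps.fa[wm].mean()) if wm.any() else 0.0,
        "mean_gfa_wm": float(gfa_map[wm].mean()) if wm.any() else 0.0,
        "Q": metrics.Q,
        "E_glob": metrics.E_glob,
        "E_loc": metrics.E_loc,
    }


def _cohort_arm(config: PipelineConfig, out_dir: Path | None) -> dict:
    spec = replace(config.cohort, seed=stage_seed(config.seed, "cohort"))
    records = make_cohort(spec)
    if out_dir is not None:
        io.save_cohort(out_dir / "cohort", records)

    week0 = min(spec.weeks)
    subset = [r for r in records if r.week == week0]
    metric_values: dict[str, dict[str, list[float]]] = {
        "Q": {"control": [], "disease": []},
        "E_glob": {"control": [], "disease": []},
        "E_loc": {"control": [], "disease": []},
    }
    for r in subset:
        m = network_metrics(
            r.connectome,
            n_restarts=config.n_restarts,
            seed=stage_seed(config.seed, f"metrics:{r.subject_id}"),
        )
        metric_values["Q"][r.group].append(m.Q)
        metric_values["E_glob"][r.group].append(m.E_glob)
        metric_values["E_loc"][r.group].append(m.E_loc)

    group_stats = {}
    for name, groups in metric_values.items():
        ctrl, dis = groups["control"], groups["disease"]
        u, p = mann_whitney_u(ctrl, dis)
        # orient: probability a control subject outranks a disease subject
        labels = np.array([1] * len(ctrl) + [0] * len(dis))
        group_stats[name] = {
            "control_mean": float(np.mean(ctrl)),
            "disease_mean": float(np.mean(dis)),
            "mannwhitney_U": float(u),
            "mannwhitney_p": float(p),
            "auroc_control_over_disease": float(auroc(np.array(ctrl + dis), labels)),
        }

    data = FeatureMatrix.from_records(records)
    cv = replace(config.cv, seed=stage_seed(config.seed, "predict"))
    result = run_cv_prediction(data, cv)
    order = np.argsort(-result.selection_frequency)
    top = [
        {
            "region": result.region_names[int(i)],
            "selection_frequency": float(result.selection_frequency[int(i)]),
        }
        for i in order[:16]
    ]
    return {
        "n_subjects": len(records),
        "weeks": list(spec.weeks),
        "group_stats_week0": group_stats,
        "pooled_r": result.pooled_r,
        "per_iteration_r_median": float(np.nanmedian(result.per_iteration_r)),
        "n_folds_skipped": result.n_folds_skipped,
        "top_regions": top,
    }


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run both arms and return (and optionally write) the machine-readable
    report.  Identical config and seed give a byte-identical report."""
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    report = {
        "version": __version__,
        "seed": config.seed,
        "phantom_arm": _phantom_arm(config, out),
        "cohort_arm": _cohort_arm(config, out),
    }
    if out is not None:
        io.write_report(out / "report.json", report)
    return report
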