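"""Readers and writers for the on-disk formats of the pipeline.

NIfTI volumes (via nibabel, diagonal affine from the voxel size), FSL-style
bvec/bval text files, TCK streamline files, TSV connectivity matrices
(tab-delimited, '.' decimal, node names in header row and first column),
cohort manifests (CSV) and YAML configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectome import Connectome
from .diffusion import DWIVolume
from .tracking import Streamline

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_gradient_table",
    "load_gradient_table",
    "save_dwi",
    "load_dwi",
    "save_tck",
    "load_tck",
    "save_connectome_tsv",
    "load_connectome_tsv",
    "save_matrix_tsv",
    "load_matrix_tsv",
    "save_cohort",
    "load_features",
    "load_config",
    "write_report",
]


# ---------------------------------------------------------------------------
# NIfTI and gradient tables


def save_nifti(path, data: np.ndarray, voxel_size) -> None:
    """Write a volume with a diagonal scaling affine (no rotation)."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    affine = np.diag(np.concatenate([voxel_size, [1.0]]))
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data, voxel_size_per_spatial_axis)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.header.get_zooms()[:3])


def save_gradient_table(bval_path, bvec_path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """FSL dialect: bval one row; bvec three rows (x, y, z)."""
    np.savetxt(bval_path, np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.9g")


def load_gradient_table(bval_path, bvec_path, n_volumes: int | None = None):
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError(f"{bvec_path}: expected a 3-row (or 3-column) bvec table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"gradient table mismatch: {len(bvals)} b-values but {len(bvecs)} b-vectors"
        )
    if n_volumes is not None and len(bvals) != n_volumes:
        raise ValueError(
            f"gradient table lists {len(bvals)} volumes but the image has {n_volumes}"
        )
    return bvals, bvecs


def save_dwi(out_dir, dwi: DWIVolume, stem: str = "dwi") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(out / f"{stem}.nii.gz", dwi.signal, dwi.voxel_size)
    save_nifti(out / f"{stem}_mask.nii.gz", dwi.mask.astype(np.uint8), dwi.voxel_size)
    save_gradient_table(out / f"{stem}.bval", out / f"{stem}.bvec", dwi.bvals, dwi.bvecs)


def load_dwi(dwi_path, bval_path, bvec_path, mask_path=None) -> DWIVolume:
    signal, voxel_size = load_nifti(dwi_path)
    bvals, bvecs = load_gradient_table(bval_path, bvec_path, signal.shape[3])
    if mask_path is None:
        mask = np.ones(signal.shape[:3], dtype=bool)
    else:
        mask = load_nifti(mask_path)[0] > 0.5
    return DWIVolume(signal, bvals, bvecs, mask, voxel_size)


# ---------------------------------------------------------------------------
# streamlines


def save_tck(path, tracks: list[Streamline], voxel_size) -> None:
    """Write streamlines as TCK (points converted to world mm)."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    tractogram = nib.streamlines.Tractogram(
        [t.points * voxel_size for t in tracks], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(tractogram, str(path))


def load_tck(path, voxel_size) -> list[Streamline]:
    voxel_size = np.asarray(voxel_size, dtype=float)
    tck = nib.streamlines.load(str(path))
    out = []
    for pts in tck.streamlines:
        vox = np.asarray(pts) / voxel_size
        out.append(Streamline(vox, tuple(np.round(vox[0]).astype(int))))
    return out


def save_track_table(path, tracks: list[Streamline]) -> None:
    """Plain TSV of per-track endpoints and lengths (for inspection/tests)."""
    rows = []
    for i, t in enumerate(tracks):
        a, b = t.points[0], t.points[-1]
        rows.append(
            {
                "track": i,
                "x0": a[0], "y0": a[1], "z0": a[2],
                "x1": b[0], "y1": b[1], "z1": b[2],
                "length_voxels": t.length_voxels,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices, cohorts, configuration


def save_matrix_tsv(path, matrix: np.ndarray, names: list[str]) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=names, columns=names)
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column names differ; not a square matrix")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def save_connectome_tsv(path, conn: Connectome) -> None:
    save_matrix_tsv(path, conn.weights, conn.node_names)


def load_connectome_tsv(path) -> Connectome:
    w, names = load_matrix_tsv(path)
    return Connectome(w, names)


def save_cohort(out_dir, records) -> Path:
    """One weights TSV per subject plus a CSV manifest; returns the manifest
    path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        fname = f"connectome_{r.subject_id}.tsv"
        save_connectome_tsv(out / fname, r.connectome)
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "week": r.week,
                "behavior_score": r.behavior_score,
                "connectome": fname,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    features = pd.DataFrame(
        np.stack([r.regional_features for r in records]),
        index=[r.subject_id for r in records],
        columns=records[0].connectome.node_names,
    )
    features.to_csv(out / "features.tsv", sep="\t", float_format="%.17g")
    return manifest


def load_features(features_path, manifest_path):
    """Features TSV + manifest CSV -> arrays for the prediction model."""
    feats = pd.read_csv(
        features_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    manifest = pd.read_csv(manifest_path, float_precision="round_trip").set_index(
        "subject_id"
    )
    missing = [s for s in feats.index if s not in manifest.index]
    if missing:
        raise ValueError(f"subjects missing from manifest: {missing[:5]}")
    manifest = manifest.loc[feats.index]
    return (
        feats.to_numpy(dtype=float),
        manifest["behavior_score"].to_numpy(dtype=float),
        manifest["group"].to_numpy(),
        manifest["week"].to_numpy(dtype=int),
        [str(c) for c in feats.columns],
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg


def write_report(path, report: dict) -> None:
    """Deterministic JSON (sorted keys, plain floats) so identical runs are
    byte-identical."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
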