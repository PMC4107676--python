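"""Connectome construction: streamline endpoints onto a parcellation, and
regional summaries of DTI scalar maps.

Edge weights follow the fiber-density convention: the number of streamlines
connecting two parcels divided by the total white-matter volume (the number
of voxels that permitted seed placement).  Each streamline contributes
exactly once to one unordered parcel pair; self-loops are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "Connectome",
    "assign_endpoints",
    "build_connectome",
    "regional_dti_summary",
]


@dataclass
class Parcellation:
    """Integer label volume (0 = background) with region names.

    ``names`` maps each nonzero label to a region name; ``hemispheres``
    optionally tags each label "L"/"R".
    """

    labels: np.ndarray
    names: dict[int, str]
    hemispheres: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")

    @property
    def region_labels(self) -> np.ndarray:
        return np.array(sorted(self.names), dtype=int)


@dataclass
class Connectome:
    """Symmetric weighted adjacency matrix over named parcels.

    When built from tractography, ``weights = fiber_counts / wm_volume``
    exactly; synthetic cohort connectomes carry continuous weights and leave
    ``fiber_counts`` as None.
    """

    weights: np.ndarray
    node_names: list[str]
    wm_volume: int | None = None
    fiber_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.node_names) != w.shape[0]:
            raise ValueError("node_names length must match the matrix size")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        self.weights = w
        if self.fiber_counts is not None:
            c = np.asarray(self.fiber_counts)
            if self.wm_volume is None or self.wm_volume <= 0:
                raise ValueError("fiber_counts requires a positive wm_volume")
            if not np.array_equal(c / self.wm_volume, w):
                raise ValueError("weights must equal fiber_counts / wm_volume")
            self.fiber_counts = c

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)


def _label_at(point: np.ndarray, parcellation: Parcellation) -> int | None:
    """Label at a streamline endpoint; background falls back to the nearest
    labeled voxel within a 1-voxel neighborhood (ties -> lowest label)."""
    labels = parcellation.labels
    vox = np.clip(np.round(point).astype(int), 0, np.array(labels.shape) - 1)
    lab = int(labels[tuple(vox)])
    if lab != 0:
        return lab
    best: tuple[float, int] | None = None
    for off in _NEIGHBOR_OFFSETS:
        nb = vox + off
        if np.any(nb < 0) or np.any(nb >= labels.shape):
            continue
        lab = int(labels[tuple(nb)])
        if lab == 0:
            continue
        dist = float(np.linalg.norm(nb - point))
        key = (dist, lab)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]


def assign_endpoints(track, parcellation: Parcellation) -> tuple[int | None, int | None]:
    """Map a streamline's two endpoints to parcel labels (None if unlabeled)."""
    pts = np.asarray(track.points, dtype=float)
    return _label_at(pts[0], parcellation), _label_at(pts[-1], parcellation)


def build_connectome(
    tracks,
    parcellation: Parcellation,
    wm_volume: int,
) -> tuple[Connectome, dict]:
    """Count streamlines per unordered parcel pair and weight by 1/wm_volume.

    Returns the connectome and a report with the numbers of assigned,
    self-loop and unassigned tracks.
    """
    if wm_volume <= 0:
        raise ValueError("wm_volume must be positive")
    tracks = list(tracks)
    region_labels = parcellation.region_labels
    index = {int(lab): i for i, lab in enumerate(region_labels)}
    n = len(region_labels)
    counts = np.zeros((n, n), dtype=int)
    n_self = n_unassigned = n_edges = 0
    for track in tracks:
        a, b = assign_endpoints(track, parcellation)
        if a is None or b is None:
            n_unassigned += 1
        elif a == b:
            n_self += 1
        else:
            i, j = index[a], index[b]
            counts[i, j] += 1
            counts[j, i] += 1
            n_edges += 1
    weights = counts / wm_volume
    names = [parcellation.names[int(lab)] for lab in region_labels]
    conn = Connectome(weights, names, wm_volume=wm_volume, fiber_counts=counts)
    report = {
        "n_tracks": len(tracks),
        "n_connecting": n_edges,
        "n_self_loop": n_self,
        "n_unassigned": n_unassigned,
    }
    return conn, report


def regional_dti_summary(
    maps,
    parcellation: Parcellation,
    min_inplane_voxels: int = 5,
    plane_axis: int = 2,
) -> pd.DataFrame:
    """Per-region means of FA/MD/AD/RD with the small-VOI exclusion rule.

    A region is flagged ``discarded`` (means reported as NaN) when no single
    plane perpendicular to ``plane_axis`` contains at least
    ``min_inplane_voxels`` of its voxels — small VOIs whose placement cannot
    be trusted after registration.  Only voxels with a valid tensor fit enter
    the means.
    """
    labels = parcellation.labels
    if labels.shape != maps.fa.shape:
        raise ValueError("scalar maps and parcellation must share a grid")
    rows = []
    for lab in parcellation.region_labels:
        sel = labels == lab
        n_vox = int(sel.sum())
        if n_vox:
            axes = tuple(a for a in range(3) if a != plane_axis)
            max_inplane = int(sel.sum(axis=axes).max())
        else:
            max_inplane = 0
        discarded = max_inplane < min_inplane_voxels
        use = sel & maps.valid
        means = {}
        for name in ("fa", "md", "ad", "rd"):
            vals = getattr(maps, name)[use]
            means[name] = np.nan if (discarded or vals.size == 0) else float(vals.mean())
        rows.append(
            {
                "label": int(lab),
                "region": parcellation.names[int(lab)],
                "n_voxels": n_vox,
                "max_inplane_voxels": max_inplane,
                "discarded": discarded,
                **means,
            }
        )
    return pd.DataFrame(rows, columns=[
        "label", "region", "n_voxels", "max_inplane_voxels", "discarded",
        "fa", "md", "ad", "rd",
    ])
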