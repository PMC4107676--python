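"""Synthetic data: multi-fiber DWI phantoms and two-group longitudinal cohorts.

The phantom generator emulates the acquisition geometry of a high-field
rodent diffusion protocol (b = 1000 s/mm^2, 126 quasi-uniform gradient
directions, five b0 volumes, ~0.3 mm isotropic voxels) over simple fiber
bundles with known geometry, so tensor fitting, Q-Ball reconstruction and
tractography can be validated against ground truth.

The cohort generator emulates the statistical design of a two-group
(control vs disease) longitudinal connectome study: modular planted-partition
connectomes whose disease versions are rewired and weight-scaled so that
modularity and the efficiencies are expected lower in the disease group, and
behavior scores (trials-to-criteria style, higher = worse) that depend
linearly on a sparse set of regional efficiencies plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome, Parcellation
from .diffusion import DWIVolume
from .graphs import regional_efficiency

__all__ = [
    "default_informative_regions",
    "Bundle",
    "PhantomSpec",
    "CohortSpec",
    "SubjectRecord",
    "fibonacci_hemisphere",
    "gradient_table",
    "make_dwi_phantom",
    "bundle_geometry",
    "phantom_parcellation",
    "make_modular_connectome",
    "rewire_connectome",
    "make_cohort",
]

PROLATE_EVALS = (1.7e-3, 0.3e-3, 0.3e-3)  # mm^2/s, typical coherent white matter
D_ISO = 0.7e-3  # mm^2/s, isotropic tissue background


# ---------------------------------------------------------------------------
# phantom


@dataclass
class Bundle:
    """One fiber bundle: a straight cylinder or a circular arc tube.

    Geometry is expressed in voxel units.  ``orientation`` is the axis of a
    straight bundle; arcs lie in the xy-plane around ``center`` with
    in-plane radius ``arc_radius`` between polar angles ``theta0`` and
    ``theta1`` (radians).  ``radius`` is the tube radius; ``eigenvalues``
    are the per-fiber tensor eigenvalues in mm^2/s and ``fraction`` the
    volume fraction contributed inside the tube.
    """

    geometry: str = "straight"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    radius: float = 2.0
    length: float | None = None
    arc_radius: float = 8.0
    theta0: float = 0.0
    theta1: float = np.pi / 2
    eigenvalues: tuple[float, float, float] = PROLATE_EVALS
    fraction: float = 1.0


@dataclass
class PhantomSpec:
    """Phantom geometry plus acquisition parameters.

    Defaults mirror the emulated acquisition: b = 1000 s/mm^2, 126
    diffusion directions, five b0 images, 0.309 mm isotropic voxels.
    ``snr`` is S0 over the Rician noise sigma; ``inf`` disables noise.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 10)
    voxel_size: float = 0.309
    bundles: list[Bundle] = field(default_factory=list)
    n_directions: int = 126
    n_b0: int = 5
    b_value: float = 1000.0
    snr: float = np.inf
    s0: float = 100.0
    d_iso: float = D_ISO
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 3 for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 3 voxels per axis")
        if self.n_directions < 6:
            raise ValueError("need at least 6 diffusion directions")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not self.bundles:
            cx, cy, cz = (s / 2.0 - 0.5 for s in self.grid_shape)
            self.bundles = [Bundle(center=(cx, cy, cz))]


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions on the upper hemisphere (spiral scheme)."""
    i = np.arange(n) + 0.5
    z = i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def gradient_table(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(bvals, bvecs) with the b0 volumes first."""
    dirs = fibonacci_hemisphere(spec.n_directions)
    bvals = np.concatenate(
        [np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)]
    )
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), dirs])
    return bvals, bvecs


def _orthonormal_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors perpendicular to each row of t."""
    ref = np.where(np.abs(t[:, [2]]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e2 = np.cross(t, ref)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(t, e2)
    return e2, e3


def bundle_geometry(bundle: Bundle, grid_shape) -> tuple[np.ndarray, np.ndarray]:
    """Boolean membership mask and per-member unit tangent for one bundle."""
    grid = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    c = np.asarray(bundle.center, dtype=float)
    q = grid - c
    if bundle.geometry == "straight":
        u = np.asarray(bundle.orientation, dtype=float)
        u = u / np.linalg.norm(u)
        s = q @ u
        perp = q - s[:, None] * u
        inside = np.linalg.norm(perp, axis=1) <= bundle.radius
        if bundle.length is not None:
            inside &= np.abs(s) <= bundle.length / 2.0
        tangents = np.tile(u, (int(inside.sum()), 1))
    elif bundle.geometry == "arc":
        r_xy = np.hypot(q[:, 0], q[:, 1])
        theta = np.mod(np.arctan2(q[:, 1], q[:, 0]), 2 * np.pi)
        t0 = np.mod(bundle.theta0, 2 * np.pi)
        t1 = np.mod(bundle.theta1, 2 * np.pi)
        if t0 <= t1:
            in_angle = (theta >= t0) & (theta <= t1)
        else:
            in_angle = (theta >= t0) | (theta <= t1)
        dist = np.hypot(r_xy - bundle.arc_radius, q[:, 2])
        inside = in_angle & (dist <= bundle.radius)
        th = theta[inside]
        tangents = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], axis=1)
    else:
        raise ValueError(f"unknown bundle geometry {bundle.geometry!r}")
    mask = np.zeros(int(np.prod(grid_shape)), dtype=bool)
    mask[np.flatnonzero(inside)] = True
    return mask.reshape(grid_shape), tangents


def _tensor_attenuation(
    tangents: np.ndarray, eigenvalues, bvecs: np.ndarray, b: float
) -> np.ndarray:
    """exp(-b g^T D g) for axially framed tensors; (n_voxels, n_dirs)."""
    l1, l2, l3 = eigenvalues
    e2, e3 = _orthonormal_frame(tangents)
    proj1 = tangents @ bvecs.T
    proj2 = e2 @ bvecs.T
    proj3 = e3 @ bvecs.T
    adc = l1 * proj1**2 + l2 * proj2**2 + l3 * proj3**2
    return np.exp(-b * adc)


def make_dwi_phantom(spec: PhantomSpec) -> DWIVolume:
    """Simulate the multi-compartment DWI signal of a phantom.

    Per voxel the noise-free signal is ``S0 * sum_f frac_f exp(-b g^T D_f g)``
    over the bundles covering the voxel, with the remaining volume fraction
    filled by an isotropic compartment of diffusivity ``d_iso``; Rician noise
    (magnitude of a complex Gaussian perturbation, sigma = S0/snr) is added
    when ``snr`` is finite.  Raises if overlapping bundle fractions exceed 1
    anywhere.
    """
    bvals, bvecs = gradient_table(spec)
    shape = spec.grid_shape
    n_vox = int(np.prod(shape))
    n_vol = len(bvals)
    dw = bvals > 0

    frac_total = np.zeros(n_vox)
    att = np.zeros((n_vox, int(dw.sum())))
    for bundle in spec.bundles:
        mask, tangents = bundle_geometry(bundle, shape)
        flat = mask.reshape(-1)
        frac_total[flat] += bundle.fraction
        att[flat] += bundle.fraction * _tensor_attenuation(
            tangents, bundle.eigenvalues, bvecs[dw], spec.b_value
        )
    if np.any(frac_total > 1.0 + 1e-12):
        worst = float(frac_total.max())
        raise ValueError(
            f"overlapping bundle volume fractions sum to {worst:.3f} > 1; "
            "reduce per-bundle fractions where bundles cross"
        )
    iso = np.exp(-spec.b_value * spec.d_iso)
    att += (1.0 - frac_total)[:, None] * iso

    signal = np.empty((n_vox, n_vol))
    signal[:, ~dw] = spec.s0
    signal[:, dw] = spec.s0 * att
    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    mask = np.ones(shape, dtype=bool)
    return DWIVolume(
        signal.reshape(shape + (n_vol,)),
        bvals,
        bvecs,
        mask,
        np.full(3, spec.voxel_size),
    )


def phantom_parcellation(spec: PhantomSpec, cap_length: float = 3.0) -> Parcellation:
    """Label the two end caps of every bundle as parcellation regions.

    Bundle ``k`` contributes labels ``2k+1`` and ``2k+2`` covering the
    first/last ``cap_length`` voxels of the bundle along its course — the
    regions its streamlines should connect.
    """
    shape = spec.grid_shape
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    flat_labels = labels.reshape(-1)
    for k, bundle in enumerate(spec.bundles):
        mask, _ = bundle_geometry(bundle, shape)
        flat = np.flatnonzero(mask.reshape(-1))
        pts = grid[flat]
        c = np.asarray(bundle.center, dtype=float)
        if bundle.geometry == "straight":
            u = np.asarray(bundle.orientation, dtype=float)
            u = u / np.linalg.norm(u)
            s = (pts - c) @ u
        else:
            theta = np.mod(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]), 2 * np.pi)
            t0 = np.mod(bundle.theta0, 2 * np.pi)
            s = np.mod(theta - t0, 2 * np.pi) * bundle.arc_radius
        lo, hi = s.min(), s.max()
        lab_a, lab_b = 2 * k + 1, 2 * k + 2
        flat_labels[flat[s <= lo + cap_length]] = lab_a
        flat_labels[flat[s >= hi - cap_length]] = lab_b
        names[lab_a] = f"bundle{k}_end0"
        names[lab_b] = f"bundle{k}_end1"
    return Parcellation(labels, names)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Design of a synthetic two-group longitudinal cohort.

    All animals of a cohort share one template connectome (a planted-partition
    modular graph), individualized by multiplicative node factors and weekly
    jitter.  Disease connectomes are additionally (a) degree-preservingly
    rewired on a fraction of edges, which lowers modularity and local
    efficiency, (b) globally weight-scaled, which lowers global efficiency,
    and (c) weight-scaled on the edges among the informative regions, which
    lowers those regions' efficiencies specifically so the group signature
    concentrates where the behavior model reads its features.

    Regional features are the per-node efficiencies plus independent
    measurement noise (``feature_noise_sd``, emulating estimation error of
    the tractography pipeline).  Behavior scores are
    ``intercept + beta * sum_r features[r] + N(0, noise_sd)``, clipped at
    zero; with negative ``beta`` the disease group scores stochastically
    higher (worse), in trials-to-criteria fashion.
    """

    n_per_group: int = 8
    weeks: tuple[int, ...] = (10, 22, 40)
    n_nodes: int = 84
    n_modules: int = 4
    p_in: float = 0.9
    p_out: float = 0.05
    unit_weights: bool = False
    weight_scale_control: float = 1.0
    weight_scale_disease: float = 0.8
    rewire_fraction_disease: float = 0.3
    regional_effect_disease: float = 0.5
    informative_regions: tuple[int, ...] | None = None
    beta: float = -40.0
    intercept: float = 350.0
    noise_sd: float = 10.0
    node_noise_sd: float = 0.05
    week_noise_sd: float = 0.02
    feature_noise_sd: float = 0.008
    developmental_slope: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weeks) == 0:
            raise ValueError("weeks must be a nonempty list")
        if not (0.0 <= self.p_out <= 1.0 and 0.0 <= self.p_in <= 1.0):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out for a modular graph")
        if not (0.0 <= self.rewire_fraction_disease <= 1.0):
            raise ValueError("rewire_fraction_disease must lie in [0, 1]")
        if self.informative_regions is None:
            self.informative_regions = default_informative_regions(
                self.n_nodes, self.n_modules
            )
        if any(not (0 <= r < self.n_nodes) for r in self.informative_regions):
            raise ValueError("informative_regions must index nodes in range")

    @classmethod
    def recovery_benchmark(cls, seed: int = 0) -> "CohortSpec":
        """Noiseless planted cohort for testing feature-selection recovery.

        The disease effect is confined to the informative subnetwork
        (edges among informative regions scaled by 0.5) on a fully connected
        within-module template with unit weights; subject variability is pure
        feature measurement noise and the score noise is zero, so behavior is
        an exact linear function of the recorded informative features.
        """
        return cls(
            p_in=1.0,
            unit_weights=True,
            weight_scale_disease=1.0,
            rewire_fraction_disease=0.0,
            regional_effect_disease=0.5,
            intercept=700.0,  # efficiencies run high on the dense template
            noise_sd=0.0,
            node_noise_sd=0.0,
            week_noise_sd=0.0,
            seed=seed,
        )

    @classmethod
    def exchangeable_null(cls, seed: int = 0) -> "CohortSpec":
        """Two groups with identical generating distributions (no disease
        effect); group comparisons should reject at the nominal rate."""
        return cls(
            weight_scale_disease=1.0,
            rewire_fraction_disease=0.0,
            regional_effect_disease=1.0,
            seed=seed,
        )


def default_informative_regions(n_nodes: int, n_modules: int, n_info: int = 16):
    """Informative set balanced across modules (evenly spaced within each)."""
    size = max(1, n_nodes // n_modules)
    per_mod = max(1, n_info // n_modules)
    stride = max(1, size // per_mod)
    regions = [
        m * size + j * stride
        for m in range(n_modules)
        for j in range(per_mod)
        if m * size + j * stride < n_nodes
    ]
    return tuple(sorted(regions[:n_info]))


@dataclass
class SubjectRecord:
    """One animal at one week."""

    subject_id: str
    group: str
    week: int
    connectome: Connectome
    behavior_score: float
    regional_features: np.ndarray


def _default_weight_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.5, 1.5, size)


def _unit_weight_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    return np.ones(size)


def make_modular_connectome(
    n_nodes: int,
    n_modules: int,
    p_in: float,
    p_out: float,
    weight_dist=None,
    rng: np.random.Generator | int = 0,
) -> tuple[Connectome, np.ndarray]:
    """Planted-partition weighted graph; returns (connectome, partition).

    Nodes are split into ``n_modules`` near-equal blocks (remainder to the
    last); edges appear with probability ``p_in`` within and ``p_out``
    between blocks, with weights drawn from ``weight_dist`` (default
    Uniform(0.5, 1.5)).
    """
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ValueError("edge probabilities must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    weight_dist = weight_dist or _default_weight_dist
    size = max(1, n_nodes // n_modules)
    partition = np.minimum(np.arange(n_nodes) // size, n_modules - 1)
    iu, ju = np.triu_indices(n_nodes, k=1)
    p_edge = np.where(partition[iu] == partition[ju], p_in, p_out)
    present = rng.random(len(iu)) < p_edge
    w = np.zeros((n_nodes, n_nodes))
    w[iu[present], ju[present]] = weight_dist(rng, int(present.sum()))
    w += w.T
    names = [f"R{k:02d}" for k in range(n_nodes)]
    return Connectome(w, names), partition


def rewire_connectome(
    weights: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Degree-preserving double-edge swaps touching ~``fraction`` of edges.

    Each successful swap replaces edges (a,b), (c,d) by (a,d), (c,b),
    carrying their weights, so the binary degree sequence is preserved while
    triangles (and with them modular structure) are destroyed.
    """
    w = weights.copy()
    iu, ju = np.nonzero(np.triu(w, k=1))
    n_edges = len(iu)
    target = int(round(fraction * n_edges))
    edges = list(zip(iu.tolist(), ju.tolist()))
    rewired = 0
    attempts = 0
    while rewired < target and attempts < 200 * max(target, 1):
        attempts += 1
        e1, e2 = rng.integers(0, len(edges), 2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if len({a, b, c, d}) < 4:
            continue
        if w[a, d] > 0 or w[c, b] > 0:
            continue
        w_ab, w_cd = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = w_ab
        w[c, b] = w[b, c] = w_cd
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        rewired += 2
    return w


def _node_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    if sd <= 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, sd, n))


def make_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full two-group longitudinal cohort.

    All animals individualize one template connectome; disease
    transformations are applied once per animal (persistent condition) and
    weeks differ by developmental weight growth plus weekly node jitter.
    Deterministic given ``spec.seed``.
    """
    n = spec.n_nodes
    info = np.array(spec.informative_regions, dtype=int)
    info_mask = np.zeros(n, dtype=bool)
    info_mask[info] = True
    pair_mask = info_mask[:, None] & info_mask[None, :]
    week0 = min(spec.weeks)

    rng0 = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(2, 0))
    )
    template, _ = make_modular_connectome(
        n,
        spec.n_modules,
        spec.p_in,
        spec.p_out,
        weight_dist=_unit_weight_dist if spec.unit_weights else _default_weight_dist,
        rng=rng0,
    )

    records: list[SubjectRecord] = []
    for g_idx, (group, scale) in enumerate(
        [("control", spec.weight_scale_control), ("disease", spec.weight_scale_disease)]
    ):
        for a in range(spec.n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(g_idx, a))
            )
            s = _node_jitter(rng, n, spec.node_noise_sd)
            w = template.weights * np.outer(s, s) * scale
            if group == "disease":
                if spec.rewire_fraction_disease > 0:
                    w = rewire_connectome(w, spec.rewire_fraction_disease, rng)
                if spec.regional_effect_disease != 1.0:
                    w = np.where(pair_mask, w * spec.regional_effect_disease, w)
            for week in spec.weeks:
                growth = 1.0 + spec.developmental_slope * (week - week0)
                sw = _node_jitter(rng, n, spec.week_noise_sd)
                w_week = w * np.outer(sw, sw) * growth
                c_week = Connectome(w_week, template.node_names)
                features = np.asarray(regional_efficiency(c_week))
                if spec.feature_noise_sd > 0:
                    features = features + rng.normal(0.0, spec.feature_noise_sd, n)
                score = spec.intercept + spec.beta * features[info].sum()
                if spec.noise_sd > 0:
                    score += rng.normal(0.0, spec.noise_sd)
                records.append(
                    SubjectRecord(
                        subject_id=f"{group[0].upper()}{a:02d}w{week}",
                        group=group,
                        week=int(week),
                        connectome=c_week,
                        behavior_score=float(max(0.0, score)),
                        regional_features=features,
                    )
                )
    return records
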