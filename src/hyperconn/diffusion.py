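"""Diffusion modelling: tensor fit, scalar maps, Q-Ball ODFs, GFA, peaks.

Conventions used throughout the package: voxel coordinates are 0-based in
array order ``(x, y, z)``; world coordinates are ``voxel * voxel_size``.
Diffusivities are in mm^2/s, b-values in s/mm^2.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "DWIVolume",
    "TensorField",
    "ScalarMaps",
    "ODFField",
    "PeakField",
    "Sphere",
    "default_sphere",
    "fit_tensor",
    "scalar_maps",
    "qball_odf",
    "gfa",
    "extract_peaks",
]

B0_TOL = 1e-6  # b-values below this count as b=0


# ---------------------------------------------------------------------------
# containers


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its gradient scheme and brain mask.

    Attributes
    ----------
    signal : (X, Y, Z, V) array
        Nonnegative signal, last axis over acquired volumes.
    bvals : (V,) array
        b-value per volume in s/mm^2; 0 marks a b0 volume.
    bvecs : (V, 3) array
        Unit gradient direction per volume; the zero vector for b0 volumes.
    mask : (X, Y, Z) bool array
        Brain mask.
    voxel_size : (3,) array
        Voxel edge lengths in mm.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and nonnegative")
        n_vol = self.signal.shape[3]
        if self.bvals.shape != (n_vol,) or self.bvecs.shape != (n_vol, 3):
            raise ValueError(
                f"gradient table size mismatch: {n_vol} volumes but "
                f"{self.bvals.shape[0]} b-values / {self.bvecs.shape[0]} b-vectors"
            )
        dw = self.bvals > B0_TOL
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 gradient directions must be unit vectors")
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must match the signal grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals <= B0_TOL))

    def b0_mean(self) -> np.ndarray:
        """Mean of the b0 volumes, the S0 reference for all model fits."""
        return self.signal[..., self.bvals <= B0_TOL].mean(axis=3)


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with sorted eigensystem.

    ``eigenvalues[..., 0] >= eigenvalues[..., 1] >= eigenvalues[..., 2]``;
    column ``j`` of ``eigenvectors`` belongs to ``eigenvalues[..., j]``.
    ``valid`` is False where the fit was impossible (S0 <= 0, empty signal);
    ``negative_eig`` flags voxels whose fitted tensor is not positive
    semi-definite.
    """

    tensors: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    valid: np.ndarray
    negative_eig: np.ndarray

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


@dataclass
class ScalarMaps:
    """DTI scalar maps: FA (unitless), MD/AD/RD (mm^2/s)."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    valid: np.ndarray


class Sphere:
    """Antipodally symmetric sphere tessellation with vertex adjacency."""

    def __init__(self, vertices: np.ndarray, neighbors: list[np.ndarray]):
        self.vertices = np.asarray(vertices, dtype=float)
        self.neighbors = [np.asarray(n, dtype=int) for n in neighbors]
        tree = cKDTree(self.vertices)
        dist, idx = tree.query(-self.vertices)
        if np.max(dist) > 1e-8:
            raise ValueError("sphere tessellation is not antipodally symmetric")
        self.antipodal_index = idx

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@functools.lru_cache(maxsize=4)
def default_sphere(subdivisions: int = 3) -> Sphere:
    """Icosphere tessellation (642 vertices at 3 subdivisions, ~4 deg)."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    return Sphere(mesh.vertices.copy(), [np.array(n) for n in mesh.vertex_neighbors])


@dataclass
class ODFField:
    """Per-voxel orientation distribution function on a shared tessellation.

    ``values[x, y, z, k]`` is psi at ``sphere.vertices[k]``, clamped >= 0 and
    sum-normalized per voxel (all-zero where no fit was possible).  Antipodal
    symmetry psi(u) = psi(-u) holds by construction of the even SH basis.
    """

    values: np.ndarray
    sphere: Sphere
    valid: np.ndarray


@dataclass
class PeakField:
    """Per-voxel fiber-orientation peaks.

    ``directions[x, y, z, p]`` is a unit vector (NaN padding past
    ``n_peaks``); ``magnitudes`` carries a GFA-like value per peak: the voxel
    GFA scaled by the peak's ODF value relative to the voxel ODF maximum, so
    the strongest peak carries the voxel GFA itself.
    """

    directions: np.ndarray
    magnitudes: np.ndarray
    n_peaks: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.directions.shape[:3]

    @property
    def max_magnitude(self) -> np.ndarray:
        return self.magnitudes.max(axis=3)


# ---------------------------------------------------------------------------
# tensor model


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map the 6 unique tensor elements to b * g^T D g."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    cols = np.stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1
    )
    return bvals[:, None] * cols


def _tensor_from_elements(d: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (..., 3, 3) symmetric."""
    out = np.empty(d.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d[..., 0]
    out[..., 1, 1] = d[..., 1]
    out[..., 2, 2] = d[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
    return out


def fit_tensor(dwi: DWIVolume, method: str = "ols") -> TensorField:
    """Fit the diffusion tensor per masked voxel by log-linear least squares.

    The model is ``ln(S/S0) = -b g^T D g`` with S0 the mean of the b0
    volumes.  ``method="ols"`` (default) is the unweighted log-linear fit;
    ``method="wls"`` weights each equation by the squared signal (the
    classical variance correction for log-transformed data; note that at low
    SNR it interacts with the Rician noise floor and can bias the leading
    eigenvalue low).

    Voxels with S0 <= 0 or an all-zero diffusion signal are marked invalid
    and excluded from downstream maps.
    """
    if method not in ("wls", "ols"):
        raise ValueError(f"unknown tensor fit method {method!r}")
    dw = dwi.bvals > B0_TOL
    if dw.sum() < 6:
        raise ValueError("tensor fit needs at least 6 diffusion-weighted volumes")
    if (~dw).sum() < 1:
        raise ValueError("tensor fit needs at least one b0 volume")

    shape = dwi.grid_shape
    s0 = dwi.b0_mean()
    sig = dwi.signal[..., dw]
    valid = dwi.mask & (s0 > 0) & (sig.sum(axis=3) > 0)

    X = _design_matrix(dwi.bvals[dw], dwi.bvecs[dw])  # (n, 6)
    s = sig[valid]  # (v, n)
    s0v = s0[valid][:, None]
    y = np.log(np.clip(s, 1e-300, None) / s0v)  # (v, n)

    if method == "wls":
        w = s * s  # (v, n)
        A = np.einsum("vn,ni,nj->vij", w, X, X)
        rhs = -np.einsum("vn,ni,vn->vi", w, X, y)
        # guard singular systems (e.g. zero-weight voxels)
        ok = np.linalg.matrix_rank(A) == 6
        d = np.zeros((len(s), 6))
        if np.any(ok):
            d[ok] = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
        if not np.all(ok):
            pinv = np.linalg.pinv(X)
            d[~ok] = -(pinv @ y[~ok].T).T
    else:
        pinv = np.linalg.pinv(X)
        d = -(pinv @ y.T).T

    tensors = np.zeros(shape + (3, 3))
    tensors[valid] = _tensor_from_elements(d)
    evals_asc, evecs = np.linalg.eigh(tensors)
    eigenvalues = evals_asc[..., ::-1]
    eigenvectors = evecs[..., :, ::-1]
    eigenvalues = np.where(valid[..., None], eigenvalues, 0.0)
    negative = valid & (eigenvalues[..., 2] < 0)
    return TensorField(tensors, eigenvalues, eigenvectors, valid, negative)


def scalar_maps(tensors: TensorField) -> ScalarMaps:
    """FA, MD, AD, RD from the tensor eigenvalues.

    FA = sqrt(3/2) * ||lam - MD|| / ||lam||, defined as 0 for the all-zero
    tensor.  MD = mean(lam), AD = lam1, RD = (lam2 + lam3) / 2.
    """
    lam = tensors.eigenvalues
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = (lam[..., 1] + lam[..., 2]) / 2.0
    num = np.sum((lam - md[..., None]) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    fa = np.where(den > 0, fa, 0.0)
    return ScalarMaps(fa, md, ad, rd, tensors.valid.copy())


# ---------------------------------------------------------------------------
# Q-Ball


def _sh_index(sh_order: int) -> list[tuple[int, int]]:
    return [(l, m) for l in range(0, sh_order + 1, 2) for m in range(-l, l + 1)]


def n_sh_coefficients(sh_order: int) -> int:
    return (sh_order + 1) * (sh_order + 2) // 2


def real_sh_basis(sh_order: int, directions: np.ndarray) -> np.ndarray:
    """Real, even-order, antipodally symmetric spherical-harmonic basis.

    Returns a (n_directions, n_coefficients) matrix.  For m != 0 the basis
    functions are sqrt(2) times the real/imaginary parts of Y_l^|m|, giving
    an orthonormal real basis on the sphere.
    """
    if sh_order % 2 != 0:
        raise ValueError("sh_order must be even")
    d = np.asarray(directions, dtype=float)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols = []
    for l, m in _sh_index(sh_order):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2) * (-1) ** m * y.imag)
        elif m == 0:
            cols.append(y.real)
        else:
            cols.append(np.sqrt(2) * (-1) ** m * y.real)
    return np.stack(cols, axis=1)


def qball_odf(
    dwi: DWIVolume,
    sh_order: int = 8,
    regularization: float = 0.006,
    sphere: Sphere | None = None,
) -> ODFField:
    """Analytic Q-Ball reconstruction of the diffusion ODF.

    The normalized diffusion signal E = S/S0 on the shell is fit with a real
    symmetric spherical-harmonic basis under Laplace-Beltrami regularization,
    and the Funk-Radon transform is applied analytically by scaling the order-l
    coefficients with 2*pi*P_l(0).  The resulting ODF is clamped at zero and
    sum-normalized per voxel.
    """
    if sh_order % 2 != 0:
        raise ValueError("sh_order must be even")
    sphere = sphere or default_sphere()
    dw = dwi.bvals > B0_TOL
    n_dir = int(dw.sum())
    n_coef = n_sh_coefficients(sh_order)
    if n_coef > n_dir:
        raise ValueError(
            f"sh_order={sh_order} needs {n_coef} directions but only {n_dir} "
            f"are available; use sh_order <= the largest even L with "
            f"(L+1)(L+2)/2 <= {n_dir}"
        )

    B = real_sh_basis(sh_order, dwi.bvecs[dw])
    ls = np.array([l for l, _ in _sh_index(sh_order)], dtype=float)
    lb = np.diag((ls * (ls + 1.0)) ** 2)
    fit = np.linalg.solve(B.T @ B + regularization * lb, B.T)  # (coef, n_dir)
    frt = 2.0 * np.pi * eval_legendre(ls.astype(int), 0.0)  # P_l(0) per coefficient
    Bv = real_sh_basis(sh_order, sphere.vertices)  # (n_vert, coef)
    # signal -> ODF samples in one matrix
    project = Bv @ (frt[:, None] * fit)  # (n_vert, n_dir)

    s0 = dwi.b0_mean()
    valid = dwi.mask & (s0 > 0)
    e = dwi.signal[..., dw][valid] / s0[valid][:, None]  # (v, n_dir)
    psi = e @ project.T  # (v, n_vert)
    psi = np.clip(psi, 0.0, None)
    tot = psi.sum(axis=1, keepdims=True)
    nonzero = tot[:, 0] > 0
    psi[nonzero] /= tot[nonzero]

    values = np.zeros(dwi.grid_shape + (sphere.n_vertices,))
    values[valid] = psi
    return ODFField(values, sphere, valid)


def gfa(odf: ODFField | np.ndarray) -> np.ndarray:
    """Generalized fractional anisotropy: std(psi) / rms(psi) per voxel.

    Uses the population standard deviation over the sphere samples; an
    all-zero ODF scores 0.  Values lie in [0, 1].
    """
    psi = odf.values if isinstance(odf, ODFField) else np.asarray(odf, dtype=float)
    if psi.shape[-1] < 20:
        raise ValueError("GFA needs an ODF sampled on at least 20 sphere points")
    mean = psi.mean(axis=-1)
    var = np.mean((psi - mean[..., None]) ** 2, axis=-1)
    ms = np.mean(psi**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(ms > 0, var / np.where(ms > 0, ms, 1.0), 0.0))
    return np.where(ms > 0, out, 0.0)


def _canonical_hemisphere(vertices: np.ndarray) -> np.ndarray:
    """Boolean selector keeping one vertex of each antipodal pair."""
    v = vertices
    return (v[:, 2] > 1e-12) | (
        (np.abs(v[:, 2]) <= 1e-12)
        & ((v[:, 1] > 1e-12) | ((np.abs(v[:, 1]) <= 1e-12) & (v[:, 0] > 0)))
    )


def extract_peaks(
    odf: ODFField,
    min_separation_deg: float = 25.0,
    max_peaks: int = 3,
    rel_threshold: float = 0.5,
    voxel_size: np.ndarray | None = None,
) -> PeakField:
    """Fiber orientations as local maxima of the ODF over the tessellation.

    A vertex is a candidate peak when its ODF value strictly exceeds all
    tessellation neighbors (so a constant ODF yields no peaks).  Candidates
    below ``rel_threshold`` times the voxel maximum are discarded; survivors
    are sorted by magnitude (ties broken by vertex index) and greedily
    suppressed within ``min_separation_deg`` of a stronger peak, counting
    antipodal directions as identical.
    """
    sphere = odf.sphere
    verts = sphere.vertices
    hemi = _canonical_hemisphere(verts)
    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    gfa_map = gfa(odf)

    shape = odf.values.shape[:3]
    directions = np.full(shape + (max_peaks, 3), np.nan)
    magnitudes = np.zeros(shape + (max_peaks,))
    n_peaks = np.zeros(shape, dtype=int)

    vox_idx = np.argwhere(odf.valid)
    for x, y, z in vox_idx:
        psi = odf.values[x, y, z]
        top = psi.max()
        if top <= 0 or top - psi.min() <= 1e-12 * top:
            continue  # empty or numerically uniform ODF: no orientation
        cand = []
        for i in np.flatnonzero(hemi):
            vi = psi[i]
            if vi < rel_threshold * top:
                continue
            nb = sphere.neighbors[i]
            if np.all(vi > psi[nb]):
                cand.append(i)
        if not cand:
            continue
        cand = sorted(cand, key=lambda i: (-psi[i], i))
        kept: list[int] = []
        for i in cand:
            if len(kept) >= max_peaks:
                break
            u = verts[i]
            if all(abs(u @ verts[j]) < cos_sep for j in kept):
                kept.append(i)
        for p, i in enumerate(kept):
            directions[x, y, z, p] = verts[i]
            magnitudes[x, y, z, p] = gfa_map[x, y, z] * psi[i] / top
        n_peaks[x, y, z] = len(kept)

    vs = np.ones(3) if voxel_size is None else np.asarray(voxel_size, dtype=float)
    return PeakField(directions, magnitudes, n_peaks, vs)
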