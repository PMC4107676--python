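"""Shared fixtures: small gradient schemes and single-voxel DWI signals."""

from __future__ import annotations

import numpy as np
import pytest

from hyperconn.diffusion import DWIVolume
from hyperconn.synthetic import PROLATE_EVALS, fibonacci_hemisphere


def tensor_signal(D, bvals, bvecs, s0=100.0):
    """Noise-free single-tensor signal for a gradient table."""
    att = np.exp(-bvals * np.einsum("ni,ij,nj->n", bvecs, D, bvecs))
    sig = s0 * att
    sig[bvals == 0] = s0
    return sig


def voxel_dwi(signals, bvals, bvecs, voxel_size=0.309):
    """Wrap per-voxel signal rows into a (n, 1, 1) DWIVolume."""
    arr = np.atleast_2d(np.asarray(signals))
    n = arr.shape[0]
    return DWIVolume(
        arr.reshape(n, 1, 1, -1),
        bvals,
        bvecs,
        np.ones((n, 1, 1), dtype=bool),
        np.full(3, voxel_size),
    )


@pytest.fixture(scope="session")
def scheme126():
    """b=1000 s/mm^2 over 126 spiral directions plus five b0 volumes."""
    dirs = fibonacci_hemisphere(126)
    bvals = np.concatenate([np.zeros(5), np.full(126, 1000.0)])
    bvecs = np.vstack([np.zeros((5, 3)), dirs])
    return bvals, bvecs


@pytest.fixture(scope="session")
def prolate_tensor():
    return np.diag(PROLATE_EVALS)


@pytest.fixture(scope="session")
def crossing_signal(scheme126):
    """Equal-fraction 90-degree crossing of x- and y-aligned fibers."""
    bvals, bvecs = scheme126
    dx = np.diag(PROLATE_EVALS)
    dy = np.diag([PROLATE_EVALS[1], PROLATE_EVALS[0], PROLATE_EVALS[2]])
    return 0.5 * (tensor_signal(dx, bvals, bvecs) + tensor_signal(dy, bvals, bvecs))
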