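"""Phantom and cohort generators: forward-model exactness, planted structure,
group contrasts, determinism."""

import numpy as np
import pytest

from hyperconn import graphs
from hyperconn import synthetic as syn
from tests.conftest import tensor_signal


# ---------------------------------------------------------------------------
# phantom


def test_phantom_volume_count_matches_acquisition():
    """126 directions + 5 b0 -> 131 volumes."""
    dwi = syn.make_dwi_phantom(syn.PhantomSpec(grid_shape=(6, 6, 4)))
    assert dwi.signal.shape[3] == 131
    assert dwi.n_b0 == 5
    assert np.sum(dwi.bvals > 0) == 126
    assert np.allclose(dwi.bvals[dwi.bvals > 0], 1000.0)


def test_phantom_noise_free_signal_matches_closed_form():
    """Single straight bundle along x: every bundle voxel carries the exact
    single-tensor attenuation; background is the isotropic compartment."""
    spec = syn.PhantomSpec(grid_shape=(12, 8, 6), bundles=[
        syn.Bundle(center=(5.5, 3.5, 2.5), orientation=(1, 0, 0), radius=1.5)
    ])
    dwi = syn.make_dwi_phantom(spec)
    inside, _ = syn.bundle_geometry(spec.bundles[0], spec.grid_shape)
    expected = tensor_signal(np.diag(spec.bundles[0].eigenvalues), dwi.bvals, dwi.bvecs)
    for vox in np.argwhere(inside)[:5]:
        np.testing.assert_allclose(dwi.signal[tuple(vox)], expected, atol=1e-12)
    bg = np.argwhere(~inside)[0]
    iso = tensor_signal(spec.d_iso * np.eye(3), dwi.bvals, dwi.bvecs)
    np.testing.assert_allclose(dwi.signal[tuple(bg)], iso, atol=1e-12)


def test_phantom_b0_equals_s0_before_noise():
    dwi = syn.make_dwi_phantom(syn.PhantomSpec(grid_shape=(5, 5, 3)))
    np.testing.assert_array_equal(dwi.signal[..., dwi.bvals == 0], 100.0)


def test_phantom_rejects_overfull_fractions():
    spec = syn.PhantomSpec(
        grid_shape=(8, 8, 4),
        bundles=[
            syn.Bundle(center=(3.5, 3.5, 1.5), orientation=(1, 0, 0), radius=3, fraction=0.7),
            syn.Bundle(center=(3.5, 3.5, 1.5), orientation=(0, 1, 0), radius=3, fraction=0.7),
        ],
    )
    with pytest.raises(ValueError, match="fraction"):
        syn.make_dwi_phantom(spec)


def test_phantom_noise_reproducible_and_rician():
    spec = syn.PhantomSpec(grid_shape=(6, 6, 4), snr=20.0, seed=5)
    a = syn.make_dwi_phantom(spec)
    b = syn.make_dwi_phantom(spec)
    np.testing.assert_array_equal(a.signal, b.signal)
    assert np.all(a.signal >= 0)  # magnitude signal
    assert not np.allclose(a.signal[..., 0], 100.0)  # noise actually applied


def test_gradient_scheme_unit_hemisphere():
    dirs = syn.fibonacci_hemisphere(126)
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
    assert np.all(dirs[:, 2] >= 0)
    # quasi-uniform: nearest-neighbour angles concentrate
    dots = dirs @ dirs.T
    np.fill_diagonal(dots, -1)
    nn = np.degrees(np.arccos(np.clip(dots.max(axis=1), -1, 1)))
    assert nn.max() < 3 * nn.min()


def test_phantom_parcellation_labels_bundle_ends():
    spec = syn.PhantomSpec(grid_shape=(16, 8, 6), bundles=[
        syn.Bundle(center=(7.5, 3.5, 2.5), orientation=(1, 0, 0), radius=1.5)
    ])
    parc = syn.phantom_parcellation(spec)
    labels = parc.labels
    assert set(np.unique(labels)) == {0, 1, 2}
    xs1 = np.argwhere(labels == 1)[:, 0]
    xs2 = np.argwhere(labels == 2)[:, 0]
    assert xs1.max() < xs2.min()  # opposite ends along the bundle axis


# ---------------------------------------------------------------------------
# modular connectomes


def test_two_modules_disconnected_cliques():
    conn, part = syn.make_modular_connectome(
        8, 2, 1.0, 0.0, weight_dist=lambda rng, k: np.ones(k), rng=0
    )
    w = conn.weights
    assert np.all(w[:4, :4] + np.eye(4) == 1.0)
    assert np.all(w[4:, :4] == 0.0)
    np.testing.assert_array_equal(part, [0, 0, 0, 0, 1, 1, 1, 1])


def test_connectome_symmetric_zero_diagonal_many_draws():
    rng = np.random.default_rng(3)
    for _ in range(20):
        conn, _ = syn.make_modular_connectome(30, 3, 0.8, 0.1, rng=rng)
        assert np.allclose(conn.weights, conn.weights.T)
        assert np.all(np.diag(conn.weights) == 0)
        assert np.all(conn.weights >= 0)


def test_expected_edge_count():
    """Mean edge count over repeated draws matches the binomial expectation
    4*C(21,2)*p_in + (C(84,2)-4*C(21,2))*p_out within 3 standard errors."""
    n_in_pairs = 4 * 21 * 20 // 2
    n_pairs = 84 * 83 // 2
    expect = n_in_pairs * 0.9 + (n_pairs - n_in_pairs) * 0.05
    var = n_in_pairs * 0.9 * 0.1 + (n_pairs - n_in_pairs) * 0.05 * 0.95
    rng = np.random.default_rng(10)
    counts = []
    for _ in range(200):
        conn, _ = syn.make_modular_connectome(84, 4, 0.9, 0.05, rng=rng)
        counts.append(np.count_nonzero(np.triu(conn.weights, 1)))
    se = np.sqrt(var / 200)
    assert abs(np.mean(counts) - expect) < 3 * se


def test_louvain_recovers_planted_partition():
    """NMI >= 0.9 against the planted partition in at least 95% of seeds."""
    hits = 0
    n_seeds = 40
    for s in range(n_seeds):
        conn, planted = syn.make_modular_connectome(84, 4, 0.9, 0.05, rng=s)
        _, levels, _ = graphs.louvain_modularity(conn, n_restarts=5, seed=s)
        nmi = graphs.partition_similarity(levels[0], planted, metric="nmi")
        hits += nmi >= 0.9
    assert hits >= 0.95 * n_seeds


def test_rewiring_preserves_degrees_and_weights():
    conn, _ = syn.make_modular_connectome(40, 4, 0.9, 0.05, rng=1)
    rng = np.random.default_rng(2)
    w2 = syn.rewire_connectome(conn.weights, 0.4, rng)
    deg1 = np.count_nonzero(conn.weights, axis=1)
    deg2 = np.count_nonzero(w2, axis=1)
    np.testing.assert_array_equal(deg1, deg2)
    assert np.allclose(sorted(conn.weights[np.triu_indices(40, 1)]),
                       sorted(w2[np.triu_indices(40, 1)]))
    assert not np.array_equal(conn.weights, w2)


# ---------------------------------------------------------------------------
# cohorts


def test_cohort_shapes_and_determinism():
    spec = syn.CohortSpec(seed=4)
    recs = syn.make_cohort(spec)
    assert len(recs) == 2 * spec.n_per_group * len(spec.weeks)
    assert all(r.behavior_score >= 0 for r in recs)
    assert all(len(r.regional_features) == spec.n_nodes for r in recs)
    recs2 = syn.make_cohort(syn.CohortSpec(seed=4))
    for a, b in zip(recs, recs2):
        assert a.subject_id == b.subject_id
        assert a.behavior_score == b.behavior_score
        np.testing.assert_array_equal(a.connectome.weights, b.connectome.weights)


def test_cohort_rejects_bad_specs():
    with pytest.raises(ValueError):
        syn.CohortSpec(weeks=())
    with pytest.raises(ValueError):
        syn.CohortSpec(p_in=0.05, p_out=0.9)
    with pytest.raises(ValueError):
        syn.CohortSpec(rewire_fraction_disease=1.5)
    with pytest.raises(ValueError):
        syn.CohortSpec(informative_regions=(100,))


def test_disease_group_lower_network_metrics():
    """Expected control-minus-disease differences in Q, E_glob, E_loc are all
    positive under the default contrast (one-sided check over seeds)."""
    diffs = {"Q": [], "E_glob": [], "E_loc": []}
    for s in range(8):
        spec = syn.CohortSpec(seed=s, weeks=(10,))
        recs = syn.make_cohort(spec)
        for name, fn in (
            ("Q", lambda c: graphs.louvain_modularity(c, n_restarts=3, seed=0)[0]),
            ("E_glob", graphs.global_efficiency),
            ("E_loc", graphs.local_efficiency),
        ):
            ctrl = np.mean([fn(r.connectome) for r in recs if r.group == "control"])
            dis = np.mean([fn(r.connectome) for r in recs if r.group == "disease"])
            diffs[name].append(ctrl - dis)
    for name, vals in diffs.items():
        assert np.mean(vals) > 0, name
        assert np.mean(np.array(vals) > 0) >= 0.9, name


def test_disease_scores_higher():
    recs = syn.make_cohort(syn.CohortSpec(seed=6))
    ctrl = np.mean([r.behavior_score for r in recs if r.group == "control"])
    dis = np.mean([r.behavior_score for r in recs if r.group == "disease"])
    assert dis > ctrl


def test_noiseless_scores_exactly_linear_in_features():
    spec = syn.CohortSpec.recovery_benchmark(seed=2)
    recs = syn.make_cohort(spec)
    info = np.array(spec.informative_regions)
    for r in recs[:6]:
        expect = spec.intercept + spec.beta * r.regional_features[info].sum()
        assert r.behavior_score == pytest.approx(expect, abs=1e-12)


def test_exchangeable_null_groups_indistinguishable():
    """Null preset: group labels carry no information about E_loc."""
    from hyperconn.predict import mann_whitney_u

    rejections = 0
    n = 60
    for s in range(n):
        recs = syn.make_cohort(syn.CohortSpec.exchangeable_null(seed=s + 1000))
        w10 = [r for r in recs if r.week == 10]
        el = {g: [graphs.local_efficiency(r.connectome) for r in w10 if r.group == g]
              for g in ("control", "disease")}
        _, p = mann_whitney_u(el["control"], el["disease"])
        rejections += p < 0.05
    assert rejections <= 0.15 * n  # nominal 5%, generous bound at this n


def test_default_informative_regions_balanced():
    regions = syn.default_informative_regions(84, 4)
    assert len(regions) == 16
    per_module = np.bincount(np.array(regions) // 21, minlength=4)
    assert np.all(per_module == 4)
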