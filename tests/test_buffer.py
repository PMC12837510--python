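"""Replay buffer: k-means selection oracle, replay semantics, archives."""

import numpy as np
import pytest

from cssl_ct.buffer import (
    MemoryBuffer,
    build_buffer,
    load_buffer,
    merge_buffers,
    pool_features,
    replay_batch,
    save_buffer,
)
from cssl_ct.exceptions import (
    BufferStateError,
    ConfigurationError,
    CorruptArchiveError,
    InvalidInputError,
)
from cssl_ct.mae import round_half_up


def _cluster_features(rng, centers, per_cluster, t=4, e=3, spread=0.05):
    """Token-feature list whose pooled vectors form tight clusters."""
    feats = []
    for c in centers:
        for _ in range(per_cluster):
            pooled = np.asarray(c) + rng.normal(0, spread, e)
            feats.append(np.tile(pooled, (t, 1)))  # all tokens equal → pool = pooled
    return feats


def test_pool_features_examples(rng):
    v = rng.normal(size=8)
    np.testing.assert_array_equal(pool_features(np.tile(v, (5, 1))), v)
    np.testing.assert_array_equal(
        pool_features(np.array([[0.0, 0.0], [2.0, 2.0]])), [1.0, 1.0]
    )
    f = rng.normal(size=(64, 64))
    np.testing.assert_allclose(pool_features(f), f.sum(axis=0) / 64, atol=1e-12)


def test_buffer_counts_match_sampling_rule(rng):
    feats = [rng.normal(size=(4, 6)) for _ in range(200)]
    buf = build_buffer(feats, alpha=0.05, beta=0.25, rng=rng)
    assert len(buf) == round_half_up(200 * 0.25) == 50
    assert all(r.cluster_id < round_half_up(200 * 0.05) for r in buf.records)
    assert buf.mode == "latent"


def test_two_group_selection_matches_bruteforce(rng):
    centers = [np.array([0.0, 0.0, 0.0]), np.array([10.0, 10.0, 10.0])]
    feats = _cluster_features(rng, centers, per_cluster=5)
    buf = build_buffer(feats, alpha=0.2, beta=0.4, rng=rng)
    assert len(buf) == 4
    pooled = np.stack([pool_features(f) for f in feats])
    selected = {r.source_id for r in buf.records}
    expected = set()
    for lo in (0, 5):
        group = pooled[lo : lo + 5]
        center = group.mean(axis=0)  # converged k-means center of a tight group
        nearest = np.argsort(np.linalg.norm(group - center, axis=1))[:2] + lo
        expected |= set(int(i) for i in nearest)
    assert selected == expected


def test_percluster_selection_is_exact_nearest(rng):
    """On a 200-point mixture the stored members are exactly the q nearest
    to their k-means center (brute-force distance oracle)."""
    centers = [rng.normal(0, 1, 5) + 8 * i for i in range(10)]
    feats = _cluster_features(rng, centers, per_cluster=20, t=3, e=5, spread=0.3)
    buf = build_buffer(feats, alpha=0.05, beta=0.25, rng=np.random.default_rng(42))
    assert len(buf) == 50
    pooled = np.stack([pool_features(f) for f in feats])
    # independent oracle: rerun the same seeded clustering, then brute-force
    # the q nearest members of every cluster
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=10, n_init=10,
                random_state=int(np.random.default_rng(42).integers(0, 2**31)))
    labels = km.fit_predict(pooled)
    dist = np.linalg.norm(pooled - km.cluster_centers_[labels], axis=1)
    for c in range(10):
        members = np.where(labels == c)[0]
        nearest = set(members[np.lexsort((members, dist[members]))][:5])
        stored = {r.source_id for r in buf.records if r.cluster_id == c}
        assert stored == set(int(i) for i in nearest)


def test_identical_points_tie_break_lowest_source_id(rng):
    feats = [np.ones((2, 3)) for _ in range(10)]
    buf = build_buffer(feats, alpha=0.1, beta=0.3, rng=rng)
    assert len(buf) == 3
    assert sorted(r.source_id for r in buf.records) == [0, 1, 2]


def test_buffer_config_errors(rng):
    with pytest.raises(InvalidInputError):
        build_buffer([], alpha=0.1, beta=0.2, rng=rng)
    feats = [rng.normal(size=(2, 2)) for _ in range(4)]
    with pytest.raises(ConfigurationError):
        build_buffer(feats, alpha=0.01, beta=0.05, rng=rng)  # round(4*0.01) = 0
    with pytest.raises(ConfigurationError):
        build_buffer(feats, alpha=0.5, beta=0.25, rng=rng)  # beta < alpha
    with pytest.raises(ConfigurationError):
        build_buffer(feats, alpha=0.5, beta=0.5, rng=rng, mode="experience")


def test_replay_without_replacement_when_large_enough(rng):
    feats = [rng.normal(size=(2, 3)) for _ in range(50)]
    buf = build_buffer(feats, alpha=0.1, beta=1.0, rng=rng)
    batch = replay_batch(buf, 32, np.random.default_rng(0))
    ids = [r.source_id for r in batch]
    assert len(ids) == 32
    assert len(set(ids)) == 32


def test_replay_with_replacement_fallback(rng):
    feats = [rng.normal(size=(2, 3)) for _ in range(8)]
    buf = build_buffer(feats, alpha=0.25, beta=0.5, rng=rng)
    batch = replay_batch(buf, 8, np.random.default_rng(0))
    assert len(batch) == 8  # only 4 records → repetitions allowed


def test_replay_deterministic_under_seed(rng):
    feats = [rng.normal(size=(2, 3)) for _ in range(50)]
    buf = build_buffer(feats, alpha=0.1, beta=1.0, rng=rng)
    a = [r.source_id for r in replay_batch(buf, 16, np.random.default_rng(3))]
    b = [r.source_id for r in replay_batch(buf, 16, np.random.default_rng(3))]
    assert a == b


def test_replay_empty_buffer_errors():
    empty = MemoryBuffer(records=[], alpha=0.1, beta=0.2, n_source=0)
    with pytest.raises(BufferStateError):
        replay_batch(empty, 4, np.random.default_rng(0))


def test_archive_roundtrip_and_metadata(tmp_path, rng):
    feats = [rng.normal(size=(4, 6)) for _ in range(20)]
    buf = build_buffer(feats, alpha=0.1, beta=0.5, rng=rng, stage_id=2)
    path = save_buffer(buf, tmp_path / "buf.npz")
    loaded = load_buffer(path)
    assert (loaded.alpha, loaded.beta, loaded.n_source) == (0.1, 0.5, 20)
    assert loaded.mode == "latent" and loaded.stage_id == 2
    assert len(loaded) == len(buf)
    for a, b in zip(buf.records, loaded.records):
        np.testing.assert_array_equal(a.features, b.features)
        assert (a.source_id, a.cluster_id, a.stage_id) == (
            b.source_id, b.cluster_id, b.stage_id,
        )


def test_truncated_archive_raises(tmp_path, rng):
    feats = [rng.normal(size=(4, 6)) for _ in range(20)]
    buf = build_buffer(feats, alpha=0.1, beta=0.5, rng=rng)
    path = save_buffer(buf, tmp_path / "buf.npz")
    raw = path.read_bytes()
    path.write_bytes(raw[: len(raw) // 2])
    with pytest.raises(CorruptArchiveError):
        load_buffer(path)


def test_latent_archive_contains_no_image_shaped_arrays(tmp_path):
    """Privacy contract: only T×E feature matrices are stored, never pixels."""
    from cssl_ct.mae import MAEConfig, MaskedAutoencoder

    # embed dim chosen ≠ image side so feature and pixel shapes are distinct
    cfg = MAEConfig(embed_dim=32, decoder_dim=32)
    model = MaskedAutoencoder(cfg, rng=np.random.default_rng(0))
    rng = np.random.default_rng(1)
    images = rng.uniform(0, 1, (20, 64, 64))
    feats = [model.extract_token_features(im) for im in images]
    buf = build_buffer(feats, alpha=0.1, beta=0.5, rng=rng)
    path = save_buffer(buf, tmp_path / "buf.npz")
    with np.load(path) as npz:
        for key in npz.files:
            if key == "__meta__":
                continue
            arr = npz[key]
            assert arr.shape == (cfg.n_patches, cfg.embed_dim)
            assert arr.shape != images[0].shape


def test_merge_concatenates_and_preserves_stage_ids(rng):
    f1 = [rng.normal(size=(2, 3)) for _ in range(20)]
    f2 = [rng.normal(size=(2, 3)) for _ in range(20)]
    b1 = build_buffer(f1, alpha=0.1, beta=0.5, rng=rng, stage_id=1)
    b2 = build_buffer(f2, alpha=0.1, beta=0.5, rng=rng, stage_id=2)
    merged = merge_buffers(b1, b2)
    assert len(merged) == 20
    assert {r.stage_id for r in merged.records} == {1, 2}
    empty = MemoryBuffer(records=[], alpha=0.1, beta=0.5, n_source=0)
    assert merge_buffers(merged, empty) is merged
    assert merge_buffers(empty, merged) is merged


def test_merge_shape_mismatch(rng):
    b1 = build_buffer([rng.normal(size=(2, 3)) for _ in range(10)],
                      alpha=0.2, beta=0.4, rng=rng)
    b2 = build_buffer([rng.normal(size=(2, 5)) for _ in range(10)],
                      alpha=0.2, beta=0.4, rng=rng)
    with pytest.raises(BufferStateError):
        merge_buffers(b1, b2)


def test_replay_from_merged_draws_both_stages(rng):
    f1 = [rng.normal(size=(2, 3)) for _ in range(20)]
    f2 = [rng.normal(size=(2, 3)) for _ in range(20)]
    merged = merge_buffers(
        build_buffer(f1, alpha=0.1, beta=0.5, rng=rng, stage_id=1),
        build_buffer(f2, alpha=0.1, beta=0.5, rng=rng, stage_id=2),
    )
    draw_rng = np.random.default_rng(0)
    seen = set()
    for _ in range(100):
        seen |= {r.stage_id for r in replay_batch(merged, 4, draw_rng)}
    assert seen == {1, 2}
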