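"""The latent-replay memory buffer.

After the first pretraining stage, every first-domain image is encoded into a
T×E token-feature matrix.  The token-mean pooled vectors are clustered with
k-means into k = round(N·α) clusters, and from each cluster the
q = round(β/α) members closest to its center are kept, so that round(N·β)
records total are stored.  Deficits from small clusters are backfilled with
the globally nearest unselected members.  The stored records — full T×E
feature matrices, never pixels — are the memory buffer B that later stages
replay as the distillation teacher.  Storing features instead of images is
the privacy mechanism: the archive contains no image-shaped arrays.

An ``experience`` mode stores the raw windowed images instead (the ablation
baseline); everything else is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import (
    BufferStateError,
    ConfigurationError,
    CorruptArchiveError,
    InvalidInputError,
)
from .mae import round_half_up

__all__ = [
    "FeatureRecord",
    "MemoryBuffer",
    "pool_features",
    "build_buffer",
    "replay_batch",
    "save_buffer",
    "load_buffer",
    "merge_buffers",
]

_FORMAT_VERSION = 1


@dataclass
class FeatureRecord:
    """One stored item: a T×E feature matrix (or an image in experience mode)."""

    features: np.ndarray
    source_id: int
    cluster_id: int
    stage_id: int = 1


@dataclass
class MemoryBuffer:
    """The buffer B with its sampling metadata."""

    records: list[FeatureRecord]
    alpha: float
    beta: float
    n_source: int
    mode: str = "latent"  # "latent" | "experience"
    stage_id: int = 1

    def __len__(self) -> int:
        return len(self.records)

    @property
    def feature_shape(self) -> tuple:
        return self.records[0].features.shape if self.records else ()


def pool_features(features: np.ndarray) -> np.ndarray:
    """Token-mean pooling: (T, E) → (E,)."""
    features = np.asarray(features, dtype=np.float64)
    return features.mean(axis=0)


def build_buffer(
    features: list[np.ndarray],
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    mode: str = "latent",
    images: list[np.ndarray] | None = None,
    stage_id: int = 1,
) -> MemoryBuffer:
    """Cluster pooled features and keep the members nearest each center.

    Parameters
    ----------
    features : list of (T, E) arrays
        One token-feature matrix per source image.
    alpha, beta : float
        Sampling-ratio controls: k = round(N·α) clusters, round(N·β) stored.
    mode : str
        ``latent`` stores the features; ``experience`` stores ``images``.
    images : list of 2-D arrays, optional
        Required in experience mode; the raw windowed images to store.
    """
    if not features:
        raise InvalidInputError("empty feature list")
    if mode not in ("latent", "experience"):
        raise ConfigurationError(f"unknown buffer mode {mode!r}")
    if mode == "experience" and (images is None or len(images) != len(features)):
        raise ConfigurationError("experience mode needs one image per feature")
    if beta < alpha:
        raise ConfigurationError(f"beta ({beta}) must be ≥ alpha ({alpha})")
    n = len(features)
    k = round_half_up(n * alpha)
    if k == 0:
        raise ConfigurationError(f"round(N·alpha) = 0 for N={n}, alpha={alpha}")
    total = round_half_up(n * beta)
    quota = round_half_up(beta / alpha)

    pooled = np.stack([pool_features(f) for f in features])
    km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(0, 2**31)))
    labels = km.fit_predict(pooled)
    centers = km.cluster_centers_
    dist = np.linalg.norm(pooled - centers[labels], axis=1)

    # per-cluster quota, nearest-first; ties broken by lowest source index
    order = np.lexsort((np.arange(n), dist))
    selected = [i for c in range(k) for i in order[labels[order] == c][:quota]]
    if len(selected) > total:
        # rounding can overshoot round(N·beta); drop the farthest selections
        selected = sorted(selected, key=lambda i: (dist[i], i))[:total]
    elif len(selected) < total:
        # backfill deficits with the globally nearest unselected points
        chosen = np.zeros(n, dtype=bool)
        chosen[selected] = True
        for i in order:
            if not chosen[i]:
                selected.append(i)
                chosen[i] = True
                if len(selected) == total:
                    break
    selected = sorted(int(i) for i in selected)

    records = []
    for i in selected:
        payload = images[i] if mode == "experience" else features[i]
        records.append(
            FeatureRecord(
                features=np.asarray(payload, dtype=np.float32),
                source_id=int(i),
                cluster_id=int(labels[i]),
                stage_id=stage_id,
            )
        )
    return MemoryBuffer(
        records=records, alpha=alpha, beta=beta, n_source=n, mode=mode, stage_id=stage_id
    )


def replay_batch(
    buffer: MemoryBuffer, batch_size: int, rng: np.random.Generator
) -> list[FeatureRecord]:
    """Uniform random replay; without replacement when the buffer is big enough."""
    if len(buffer) == 0:
        raise BufferStateError("cannot replay from an empty buffer")
    n = len(buffer)
    replace = n < batch_size
    idx = rng.choice(n, size=batch_size, replace=replace)
    return [buffer.records[i] for i in idx]


def merge_buffers(old: MemoryBuffer, new: MemoryBuffer) -> MemoryBuffer:
    """Cumulative multi-stage memory: concatenate records, keep per-record stage ids."""
    if len(old) == 0:
        return new
    if len(new) == 0:
        return old
    if old.mode != new.mode:
        raise BufferStateError(f"mode mismatch: {old.mode} vs {new.mode}")
    if old.feature_shape != new.feature_shape:
        raise BufferStateError(
            f"record shape mismatch: {old.feature_shape} vs {new.feature_shape}"
        )
    return MemoryBuffer(
        records=old.records + new.records,
        alpha=new.alpha,
        beta=new.beta,
        n_source=old.n_source + new.n_source,
        mode=new.mode,
        stage_id=new.stage_id,
    )


def save_buffer(buffer: MemoryBuffer, path: str | Path) -> Path:
    """Archive as a single .npz of named arrays plus a JSON metadata block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": _FORMAT_VERSION,
        "alpha": buffer.alpha,
        "beta": buffer.beta,
        "n_source": buffer.n_source,
        "mode": buffer.mode,
        "stage_id": buffer.stage_id,
        "records": [
            {"source_id": r.source_id, "cluster_id": r.cluster_id, "stage_id": r.stage_id}
            for r in buffer.records
        ],
    }
    arrays = {f"rec_{i:06d}": r.features for i, r in enumerate(buffer.records)}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_buffer(path: str | Path) -> MemoryBuffer:
    path = Path(path)
    try:
        with np.load(path) as npz:
            meta = json.loads(npz["__meta__"].tobytes().decode())
            if meta.get("version") != _FORMAT_VERSION:
                raise CorruptArchiveError(
                    f"buffer archive version {meta.get('version')} unsupported"
                )
            records = [
                FeatureRecord(
                    features=npz[f"rec_{i:06d}"],
                    source_id=m["source_id"],
                    cluster_id=m["cluster_id"],
                    stage_id=m["stage_id"],
                )
                for i, m in enumerate(meta["records"])
            ]
    except CorruptArchiveError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize to archive error
        raise CorruptArchiveError(f"cannot load buffer archive {path}: {exc}") from exc
    return MemoryBuffer(
        records=records,
        alpha=meta["alpha"],
        beta=meta["beta"],
        n_source=meta["n_source"],
        mode=meta["mode"],
        stage_id=meta["stage_id"],
    )
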