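"""Staged continual pretraining: SSL → buffer → continual SSL (+ fine-tune).

Stage 1 trains a masked autoencoder on the first-domain images.  Stage 2
encodes the whole first-domain set and samples the latent-replay buffer by
k-means.  Stage 3 continues masked-autoencoder training on the second domain,
initialized from the stage-1 weights, while a feature-distillation loss ties
the student's token features to those replayed from the buffer:

    L_total = L_SSL + λ_fd · L_FD .

Each iteration runs (a) a masked forward pass on the mini-batch for L_SSL,
(b) an unmasked forward pass on the same mini-batch for the student features
P_S, (c) a replay draw of equal size for the teacher features P_T, and
(d) the configured distillation loss.  With λ_fd = 0 the stage reduces
exactly — same random stream, same arithmetic — to sequential masked
autoencoding on the new domain, which is the no-replay ablation baseline.

Sequences of more than two domains alternate training and buffer building,
with buffers merged cumulatively.  Everything is deterministic under its
seed: pure numpy single-threaded arithmetic, no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, layer_norm, log_softmax
from .buffer import MemoryBuffer, build_buffer, merge_buffers, replay_batch
from .distill import FDConfig, fd_loss
from .exceptions import BufferStateError, ConfigurationError, InvalidInputError
from .mae import Checkpoint, MAEConfig, MaskedAutoencoder, mae_loss, select_mask
from .windowing import WindowedImage

__all__ = [
    "StageConfig",
    "RunManifest",
    "AdamW",
    "learning_rate",
    "run_stage1",
    "run_stage2",
    "run_stage3",
    "run_sequence",
    "finetune",
    "ClassifierCheckpoint",
]


@dataclass(frozen=True)
class StageConfig:
    """One pretraining stage.

    Defaults mirror the reference study conditions (stage-1 batch 64,
    stage-3 batch 32, warm-up to 1.5e-4 then cosine decay); tests and the
    bundled tiny pipeline override epochs and sizes downward.
    """

    kind: str = "ssl"  # "ssl" | "continual"
    epochs: int = 30
    batch_size: int = 64
    warmup_epochs: int = 4
    peak_lr: float = 1.5e-4
    weight_decay: float = 0.01
    augment: bool = True
    fd: FDConfig | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("ssl", "continual"):
            raise ConfigurationError(f"unknown stage kind {self.kind!r}")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be ≥ 1")
        if self.batch_size < 2:
            raise ConfigurationError("batch size must be ≥ 2")
        if self.warmup_epochs > self.epochs:
            raise ConfigurationError("warm-up cannot exceed total epochs")


@dataclass
class RunManifest:
    """Artifacts of a multi-stage run."""

    checkpoints: list[Checkpoint] = field(default_factory=list)
    buffers: list[MemoryBuffer] = field(default_factory=list)
    traces: list[list[dict]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)


def learning_rate(epoch: int, cfg: StageConfig) -> float:
    """Linear warm-up to the peak rate, then cosine decay toward zero."""
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        return cfg.peak_lr * (epoch + 1) / cfg.warmup_epochs
    span = max(cfg.epochs - cfg.warmup_epochs, 1)
    progress = (epoch - cfg.warmup_epochs) / span
    return cfg.peak_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


class AdamW(object):
    """Adam with decoupled weight decay over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            if self.weight_decay:
                p.data *= 1.0 - lr * self.weight_decay
            p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
            p.grad = None


def _pixels(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        return images
    return np.stack([im.pixels if isinstance(im, WindowedImage) else im for im in images])


def _augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random crop-resize (scale 0.8–1.0) and horizontal flip."""
    from skimage.transform import resize

    out = np.empty_like(batch)
    s = batch.shape[1]
    for i, im in enumerate(batch):
        scale = rng.uniform(0.8, 1.0)
        cs = max(int(round(s * scale)), 8)
        y0 = rng.integers(0, s - cs + 1)
        x0 = rng.integers(0, s - cs + 1)
        crop = im[y0 : y0 + cs, x0 : x0 + cs]
        if cs != s:
            crop = resize(crop, (s, s), order=1, anti_aliasing=False, preserve_range=True)
        if rng.uniform() < 0.5:
            crop = crop[:, ::-1]
        out[i] = crop
    return out


def _train_mae(
    images,
    cfg: StageConfig,
    model: MaskedAutoencoder,
    buffer: MemoryBuffer | None = None,
    teacher: MaskedAutoencoder | None = None,
) -> list[dict]:
    """Shared training loop for stage 1 and stage 3.

    With ``buffer`` set and a distillation config carrying λ_fd > 0, each
    iteration adds λ_fd·L_FD; otherwise the loop is plain masked-autoencoder
    training and consumes exactly the same random stream either way.
    """
    if len(images) == 0:
        raise InvalidInputError("empty training dataset")
    arr = _pixels(images)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.params, weight_decay=cfg.weight_decay)
    c = model.config
    distilling = (
        buffer is not None and cfg.fd is not None and cfg.fd.lambda_fd > 0
    )
    if distilling and buffer is not None and len(buffer) == 0:
        raise BufferStateError("distillation requested with an empty buffer")
    trace: list[dict] = []
    n = arr.shape[0]
    for epoch in range(cfg.epochs):
        lr = learning_rate(epoch, cfg)
        perm = rng.permutation(n)
        ep_ssl, ep_fd, ep_total = [], [], []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            batch = arr[idx]
            if cfg.augment:
                batch = _augment_batch(batch, rng)
            mask = select_mask(c.n_patches, c.mask_ratio, rng)
            y_m, _ = model.forward_reconstruct(batch, mask)
            pb = model._patch_batch(batch)
            x_m = pb[:, np.array(mask.masked_indices)]
            l_ssl = mae_loss(y_m, x_m, c.patch_size, c.channels)
            if distilling:
                p_s = model.token_features(batch, grad=True)
                records = replay_batch(buffer, batch.shape[0], rng)
                if buffer.mode == "experience":
                    enc = teacher if teacher is not None else model
                    imgs_t = np.stack([r.features for r in records])
                    p_t = enc.token_features(imgs_t, grad=False).data
                else:
                    p_t = np.stack([r.features for r in records])
                l_fd = fd_loss(p_t, p_s, cfg.fd)
                total = l_ssl + l_fd * cfg.fd.lambda_fd
                ep_fd.append(l_fd.item())
            else:
                total = l_ssl
                ep_fd.append(0.0)
            total.backward()
            opt.step(lr)
            ep_ssl.append(l_ssl.item())
            ep_total.append(total.item())
        trace.append(
            {
                "epoch": epoch,
                "lr": lr,
                "loss_ssl": float(np.mean(ep_ssl)),
                "loss_fd": float(np.mean(ep_fd)),
                "loss_total": float(np.mean(ep_total)),
            }
        )
    return trace


def run_stage1(
    images,
    cfg: StageConfig,
    model_config: MAEConfig | None = None,
    stage_id: int = 1,
) -> Checkpoint:
    """First-stage self-supervised pretraining on one domain."""
    if cfg.kind != "ssl":
        raise ConfigurationError("run_stage1 requires an ssl-kind stage config")
    model_config = model_config or MAEConfig()
    model = MaskedAutoencoder(model_config, rng=np.random.default_rng(cfg.seed))
    trace = _train_mae(images, cfg, model)
    manifest = {"seed": cfg.seed, "epochs": cfg.epochs, "loss_trace": trace}
    return Checkpoint(model=model, stage_id=stage_id, manifest=manifest)


def run_stage2(
    ckpt: Checkpoint,
    images,
    alpha: float,
    beta: float,
    seed: int,
    mode: str = "latent",
    batch_size: int = 64,
) -> MemoryBuffer:
    """Encode the stage's images and sample the memory buffer by k-means."""
    arr = _pixels(images)
    feats = []
    for lo in range(0, arr.shape[0], batch_size):
        feats.extend(ckpt.model.token_features(arr[lo : lo + batch_size]).data)
    rng = np.random.default_rng(seed)
    return build_buffer(
        feats,
        alpha=alpha,
        beta=beta,
        rng=rng,
        mode=mode,
        images=list(arr) if mode == "experience" else None,
        stage_id=ckpt.stage_id,
    )


def run_stage3(
    ckpt_prev: Checkpoint,
    buffer: MemoryBuffer | None,
    images,
    cfg: StageConfig,
    stage_id: int | None = None,
) -> Checkpoint:
    """Continual pretraining on a new domain with feature distillation."""
    if cfg.kind != "continual":
        raise ConfigurationError("run_stage3 requires a continual-kind stage config")
    if buffer is not None and len(buffer) > 0 and buffer.mode == "latent":
        t, e = buffer.feature_shape
        c = ckpt_prev.model.config
        if (t, e) != (c.n_patches, c.embed_dim):
            raise BufferStateError(
                f"buffer records are {t}×{e}, model produces "
                f"{c.n_patches}×{c.embed_dim}"
            )
    model = ckpt_prev.model.copy()
    trace = _train_mae(images, cfg, model, buffer=buffer, teacher=ckpt_prev.model)
    manifest = {
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "loss_trace": trace,
        "fd": None if cfg.fd is None else asdict(cfg.fd),
    }
    return Checkpoint(
        model=model,
        stage_id=stage_id if stage_id is not None else ckpt_prev.stage_id + 1,
        manifest=manifest,
    )


def run_sequence(
    stages: list[tuple[StageConfig, list]],
    alpha: float = 0.01,
    beta: float = 0.05,
    buffer_mode: str = "latent",
    model_config: MAEConfig | None = None,
) -> RunManifest:
    """Run an ordered multi-stage curriculum with cumulative buffer merging.

    ``stages`` pairs each stage config with its (domain-specific) image set;
    the first stage must be ``ssl``-kind.  After every pretraining stage the
    stage's own data is sampled into a buffer which is merged into the
    cumulative memory used by all later stages.
    """
    if not stages:
        raise ConfigurationError("need at least one stage")
    if stages[0][0].kind != "ssl":
        raise ConfigurationError("the first stage must be ssl-kind")
    manifest = RunManifest()
    memory: MemoryBuffer | None = None
    ckpt: Checkpoint | None = None
    for i, (cfg, images) in enumerate(stages):
        if i == 0:
            ckpt = run_stage1(images, cfg, model_config=model_config, stage_id=1)
        else:
            if cfg.kind != "continual":
                raise ConfigurationError("stages after the first must be continual-kind")
            ckpt = run_stage3(ckpt, memory, images, cfg, stage_id=i + 1)
        manifest.checkpoints.append(ckpt)
        manifest.traces.append(ckpt.manifest["loss_trace"])
        manifest.seeds.append(cfg.seed)
        if i < len(stages) - 1:  # no buffer needed after the final stage
            new_buf = run_stage2(
                ckpt, images, alpha=alpha, beta=beta, seed=cfg.seed, mode=buffer_mode
            )
            memory = new_buf if memory is None else merge_buffers(memory, new_buf)
            manifest.buffers.append(memory)
    return manifest


# -- fine-tuning ----------------------------------------------------------------

@dataclass
class ClassifierCheckpoint:
    """Encoder + MLP-head classifier."""

    encoder: MaskedAutoencoder
    head: dict[str, Tensor]
    classes: list[int]
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, images) -> np.ndarray:
        arr = _pixels(images)
        feats = self.encoder.token_features(arr)  # (B, T, E), no grad
        logits = _head_forward(_pool_tokens(feats), self.head)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, images) -> np.ndarray:
        proba = self.predict_proba(images)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)])

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        Checkpoint(model=self.encoder, stage_id=-1, manifest=self.manifest).save(
            path / "encoder"
        )
        np.savez(path / "head.npz", **{k.replace("/", "__"): v.data for k, v in self.head.items()})
        (path / "classifier.json").write_text(
            json.dumps({"classes": self.classes, "manifest": self.manifest}, indent=2)
        )

    @classmethod
    def load(cls, path) -> "ClassifierCheckpoint":
        import json
        from pathlib import Path

        path = Path(path)
        ckpt = Checkpoint.load(path / "encoder")
        with np.load(path / "head.npz") as npz:
            head = {k.replace("__", "/"): Tensor(npz[k], requires_grad=True) for k in npz.files}
        meta = json.loads((path / "classifier.json").read_text())
        return cls(encoder=ckpt.model, head=head, classes=meta["classes"],
                   manifest=meta["manifest"])


#: temperature of the smooth-max pooling channel (token units)
_POOL_TAU = 0.1


def _pool_tokens(feats: Tensor) -> Tensor:
    """Token pooling for classification: mean ⊕ smooth max per channel.

    The mean channel summarizes global context; the log-sum-exp channel
    (temperature ``_POOL_TAU``) approximates a per-channel max over tokens,
    which keeps small focal findings — a nodule occupies a handful of patch
    tokens — visible after pooling.  The shift is a constant, so the gradient
    is the exact softmax-weighted token average.
    """
    shift = Tensor(feats.data.max(axis=1, keepdims=True))
    z = ((feats - shift) * (1.0 / _POOL_TAU)).exp().mean(axis=1)
    smooth_max = z.log() * _POOL_TAU + shift.reshape(shift.shape[0], shift.shape[2])
    from .autodiff import concat

    return concat([feats.mean(axis=1), smooth_max], axis=1)


def _head_params(embed_dim: int, n_classes: int, rng) -> dict[str, Tensor]:
    pooled_dim = 2 * embed_dim  # mean ⊕ smooth-max pooling
    scale = 1.0 / math.sqrt(pooled_dim)
    return {
        "ln/g": Tensor(np.ones(pooled_dim, dtype=np.float32), requires_grad=True),
        "ln/b": Tensor(np.zeros(pooled_dim, dtype=np.float32), requires_grad=True),
        "fc1/w": Tensor(rng.normal(0, scale, (pooled_dim, embed_dim)).astype(np.float32),
                        requires_grad=True),
        "fc1/b": Tensor(np.zeros(embed_dim, dtype=np.float32), requires_grad=True),
        "fc2/w": Tensor(rng.normal(0, scale, (embed_dim, n_classes)).astype(np.float32),
                        requires_grad=True),
        "fc2/b": Tensor(np.zeros(n_classes, dtype=np.float32), requires_grad=True),
    }


def _head_forward(pooled: Tensor, head: dict[str, Tensor]) -> Tensor:
    """Pooled features → LayerNorm → one-hidden-layer MLP logits."""
    h = layer_norm(pooled, head["ln/g"], head["ln/b"])
    h = (h @ head["fc1/w"] + head["fc1/b"]).gelu()
    return h @ head["fc2/w"] + head["fc2/b"]


def finetune(
    ckpt: Checkpoint,
    train_data: list[tuple[WindowedImage, int]],
    val_data: list[tuple[WindowedImage, int]],
    epochs: int = 80,
    batch_size: int = 32,
    lr: float = 5e-5,
    weight_decay: float = 0.01,
    freeze_encoder: bool = False,
    seed: int = 0,
) -> ClassifierCheckpoint:
    """Fine-tune the pretrained encoder with an MLP head (cross-entropy).

    The head is one hidden layer of the embedding width with GELU.  The
    best-validation-accuracy parameters are retained.  ``freeze_encoder``
    trains the head only (linear/MLP-probe setting).
    """
    x_tr = _pixels([im for im, _ in train_data])
    y_tr = np.array([lab for _, lab in train_data])
    x_va = _pixels([im for im, _ in val_data])
    y_va = np.array([lab for _, lab in val_data])
    classes = sorted(set(int(y) for y in y_tr))
    if len(classes) < 2:
        raise InvalidInputError("fine-tuning needs at least two classes")
    cls_index = {c: i for i, c in enumerate(classes)}
    y_tr_idx = np.array([cls_index[int(y)] for y in y_tr])

    rng = np.random.default_rng(seed)
    encoder = ckpt.model.copy()
    head = _head_params(encoder.config.embed_dim, len(classes), rng)
    trainable = dict(head)
    if not freeze_encoder:
        trainable.update(encoder.params)
    opt = AdamW(trainable, weight_decay=weight_decay)

    best_acc, best_state = -1.0, None
    trace = []
    n = x_tr.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = perm[lo : lo + batch_size]
            feats = encoder.token_features(x_tr[idx], grad=not freeze_encoder)
            logits = _head_forward(_pool_tokens(feats), head)
            logp = log_softmax(logits, axis=-1)
            picked = (logp * Tensor(np.eye(len(classes))[y_tr_idx[idx]])).sum()
            loss = -picked / float(len(idx))
            loss.backward()
            opt.step(lr)
            losses.append(loss.item())
        clf = ClassifierCheckpoint(encoder=encoder, head=head, classes=classes)
        val_acc = float(np.mean(clf.predict(x_va) == y_va))
        trace.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = (
                {k: v.data.copy() for k, v in encoder.params.items()},
                {k: v.data.copy() for k, v in head.items()},
            )
    enc_state, head_state = best_state
    for k, v in encoder.params.items():
        v.data = enc_state[k]
    for k, v in head.items():
        v.data = head_state[k]
    return ClassifierCheckpoint(
        encoder=encoder,
        head=head,
        classes=classes,
        manifest={"seed": seed, "epochs": epochs, "trace": trace, "best_val_acc": best_acc},
    )
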