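"""Masked-autoencoder pretraining over a compact vision transformer.

The self-supervised objective: an image is tiled into n patches of size
(V, V); m = round(n·r) patches are masked; the encoder sees only the n−m
visible patch tokens; a light decoder, given the encoded visible tokens plus
a shared learnable mask token at each masked position (all with positional
encodings), predicts the pixel content of the masked patches; the loss is the
mean squared error over masked-patch pixels,

    L_SSL = ||Y_m − X_m||² / (m · V² · C).

The encoder is a standard pre-norm ViT (patch embedding + learnable
positional encodings = the tokenizer; a class token is kept in the
architecture but excluded from extracted token features, so the feature
matrix has exactly T = n rows).  The decoder never receives masked-patch
pixel content — the information-hiding premise of masked autoencoding — and
the encoder is provably blind to masked pixels.

All tensors run on the package's own numpy autodiff engine; the default
configuration (64-px images, patch 8, embed 64, depth 2) trains in seconds
per epoch on one CPU core.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, broadcast_to, concat, layer_norm, no_grad, softmax
from .exceptions import (
    ConfigurationError,
    CorruptArchiveError,
    DegenerateMaskError,
    ShapeError,
)

__all__ = [
    "MAEConfig",
    "MaskSet",
    "Checkpoint",
    "MaskedAutoencoder",
    "patchify",
    "unpatchify",
    "select_mask",
    "mae_loss",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """round(x) with ties going up: round_half_up(2.5) == 3."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MAEConfig:
    """Architecture and masking hyperparameters.

    ``tiny()`` is the test-scale default; ``vit_b()`` mirrors the usual
    ViT-B/16 at 224 px and is provided for completeness, not exercised in CI.
    """

    image_size: int = 64
    patch_size: int = 8
    channels: int = 1
    embed_dim: int = 64
    encoder_depth: int = 2
    encoder_heads: int = 4
    decoder_dim: int = 48
    decoder_depth: int = 1
    decoder_heads: int = 4
    mask_ratio: float = 0.75
    mlp_ratio: int = 4

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ConfigurationError("image side must be divisible by patch size")
        if not 0 < self.mask_ratio < 1:
            raise ConfigurationError("mask ratio must be in (0, 1)")
        if self.embed_dim % self.encoder_heads or self.decoder_dim % self.decoder_heads:
            raise ConfigurationError("embed dims must be divisible by head counts")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size**2 * self.channels

    @classmethod
    def tiny(cls, **overrides) -> "MAEConfig":
        return cls(**overrides)

    @classmethod
    def vit_b(cls) -> "MAEConfig":
        return cls(
            image_size=224, patch_size=16, embed_dim=768, encoder_depth=12,
            encoder_heads=12, decoder_dim=512, decoder_depth=8, decoder_heads=16,
        )


@dataclass(frozen=True)
class MaskSet:
    """The sorted indices of the m masked patches out of n."""

    masked_indices: tuple[int, ...]
    n: int

    @property
    def m(self) -> int:
        return len(self.masked_indices)

    @property
    def visible_indices(self) -> tuple[int, ...]:
        masked = set(self.masked_indices)
        return tuple(i for i in range(self.n) if i not in masked)


def patchify(pixels: np.ndarray, patch_size: int) -> np.ndarray:
    """Tile an image row-major into an n×(V²·C) patch matrix.

    Accepts (H, W) or (H, W, C) arrays; the inverse is :func:`unpatchify`.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim == 2:
        pixels = pixels[:, :, None]
    h, w, c = pixels.shape
    v = patch_size
    if h % v or w % v:
        raise ShapeError(f"image sides ({h},{w}) not divisible by patch size {v}")
    gh, gw = h // v, w // v
    patches = pixels.reshape(gh, v, gw, v, c).transpose(0, 2, 1, 3, 4)
    return patches.reshape(gh * gw, v * v * c)


def unpatchify(patches: np.ndarray, patch_size: int, image_size: int, channels: int = 1) -> np.ndarray:
    """Invert :func:`patchify` (lossless round-trip)."""
    v = patch_size
    g = image_size // v
    if patches.shape != (g * g, v * v * channels):
        raise ShapeError(f"patch matrix shape {patches.shape} inconsistent with geometry")
    img = patches.reshape(g, g, v, v, channels).transpose(0, 2, 1, 3, 4)
    img = img.reshape(image_size, image_size, channels)
    return img[:, :, 0] if channels == 1 else img


def select_mask(n: int, r: float, rng: np.random.Generator) -> MaskSet:
    """Draw m = round(n·r) distinct patch indices uniformly without replacement."""
    if not 0 < r < 1:
        raise ConfigurationError(f"mask ratio must be in (0,1), got {r}")
    if n < 2:
        raise ConfigurationError(f"need at least 2 patches, got {n}")
    m = round_half_up(n * r)
    if m == 0 or m == n:
        raise DegenerateMaskError(
            f"mask ratio {r} with n={n} leaves {'no masked' if m == 0 else 'no visible'} patches"
        )
    idx = rng.choice(n, size=m, replace=False)
    return MaskSet(masked_indices=tuple(int(i) for i in np.sort(idx)), n=n)


def mae_loss(y_m, x_m, patch_size: int, channels: int = 1):
    """Eq-style masked reconstruction MSE: ||Y_m − X_m||² / (m·V²·C).

    Accepts autodiff Tensors (returns a Tensor on the graph) or plain arrays
    (returns a float).  Batched (B, m, V²·C) inputs average over the batch.
    """
    is_tensor = isinstance(y_m, Tensor) or isinstance(x_m, Tensor)
    yt = y_m if isinstance(y_m, Tensor) else Tensor(y_m)
    xt = x_m if isinstance(x_m, Tensor) else Tensor(x_m)
    if yt.shape != xt.shape:
        raise ShapeError(f"shape mismatch {yt.shape} vs {xt.shape}")
    if yt.ndim not in (2, 3):
        raise ShapeError("expected (m, V²·C) or (B, m, V²·C)")
    m = yt.shape[-2]
    denom = float(m * patch_size**2 * channels)
    if yt.ndim == 3:
        denom *= yt.shape[0]
    diff = yt - xt
    out = (diff * diff).sum() / denom
    return out if is_tensor else out.item()


# -- parameter initialization -------------------------------------------------

_DTYPE = np.float32  # weights and activations; float64 only in oracle paths


def _linear_params(rng, fan_in: int, fan_out: int, prefix: str, params: dict):
    params[f"{prefix}/w"] = Tensor(
        rng.normal(0.0, 0.02, (fan_in, fan_out)).astype(_DTYPE), requires_grad=True
    )
    params[f"{prefix}/b"] = Tensor(np.zeros(fan_out, dtype=_DTYPE), requires_grad=True)


def _ln_params(dim: int, prefix: str, params: dict):
    params[f"{prefix}/g"] = Tensor(np.ones(dim, dtype=_DTYPE), requires_grad=True)
    params[f"{prefix}/b"] = Tensor(np.zeros(dim, dtype=_DTYPE), requires_grad=True)


def _block_params(rng, dim: int, mlp_ratio: int, prefix: str, params: dict):
    _ln_params(dim, f"{prefix}/ln1", params)
    _linear_params(rng, dim, 3 * dim, f"{prefix}/qkv", params)
    _linear_params(rng, dim, dim, f"{prefix}/proj", params)
    _ln_params(dim, f"{prefix}/ln2", params)
    _linear_params(rng, dim, mlp_ratio * dim, f"{prefix}/fc1", params)
    _linear_params(rng, mlp_ratio * dim, dim, f"{prefix}/fc2", params)


class MaskedAutoencoder:
    """The MAE model: tokenizer + ViT encoder + lightweight decoder."""

    def __init__(self, config: MAEConfig, rng: np.random.Generator | None = None,
                 params: dict[str, Tensor] | None = None):
        self.config = config
        if params is not None:
            self.params = params
            return
        if rng is None:
            rng = np.random.default_rng(0)
        c, p = config, {}
        _linear_params(rng, c.patch_dim, c.embed_dim, "tok/embed", p)
        p["tok/pos"] = Tensor(
            rng.normal(0, 0.02, (1, c.n_patches, c.embed_dim)).astype(_DTYPE), requires_grad=True
        )
        p["tok/cls"] = Tensor(rng.normal(0, 0.02, (1, 1, c.embed_dim)).astype(_DTYPE), requires_grad=True)
        for i in range(c.encoder_depth):
            _block_params(rng, c.embed_dim, c.mlp_ratio, f"enc/{i}", p)
        _ln_params(c.embed_dim, "enc/ln", p)
        _linear_params(rng, c.embed_dim, c.decoder_dim, "dec/embed", p)
        p["dec/mask"] = Tensor(rng.normal(0, 0.02, (1, 1, c.decoder_dim)).astype(_DTYPE), requires_grad=True)
        p["dec/pos"] = Tensor(
            rng.normal(0, 0.02, (1, c.n_patches, c.decoder_dim)).astype(_DTYPE), requires_grad=True
        )
        for i in range(c.decoder_depth):
            _block_params(rng, c.decoder_dim, c.mlp_ratio, f"dec/{i}", p)
        _ln_params(c.decoder_dim, "dec/ln", p)
        _linear_params(rng, c.decoder_dim, c.patch_dim, "dec/pred", p)
        self.params = p

    # -- building blocks ------------------------------------------------------
    def _linear(self, x: Tensor, prefix: str) -> Tensor:
        return x @ self.params[f"{prefix}/w"] + self.params[f"{prefix}/b"]

    def _block(self, x: Tensor, prefix: str, heads: int) -> Tensor:
        p = self.params
        b, t, e = x.shape
        dh = e // heads
        h = layer_norm(x, p[f"{prefix}/ln1/g"], p[f"{prefix}/ln1/b"])
        qkv = self._linear(h, f"{prefix}/qkv").reshape(b, t, 3, heads, dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, T, dh)
        q = qkv.take([0], axis=0).reshape(b, heads, t, dh)
        k = qkv.take([1], axis=0).reshape(b, heads, t, dh)
        v = qkv.take([2], axis=0).reshape(b, heads, t, dh)
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh)), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, e)
        x = x + self._linear(out, f"{prefix}/proj")
        h = layer_norm(x, p[f"{prefix}/ln2/g"], p[f"{prefix}/ln2/b"])
        h = self._linear(h, f"{prefix}/fc1").gelu()
        return x + self._linear(h, f"{prefix}/fc2")

    def _encode_tokens(self, tokens: Tensor) -> Tensor:
        """Prepend class token, run encoder blocks, final layer norm."""
        b = tokens.shape[0]
        cls = broadcast_to(self.params["tok/cls"], (b, 1, self.config.embed_dim))
        x = concat([cls, tokens], axis=1)
        for i in range(self.config.encoder_depth):
            x = self._block(x, f"enc/{i}", self.config.encoder_heads)
        return layer_norm(x, self.params["enc/ln/g"], self.params["enc/ln/b"])

    def _embed_patches(self, patch_batch: np.ndarray) -> Tensor:
        """Patch matrix batch (B, n, V²·C) → embedded tokens with position."""
        x = Tensor(patch_batch)
        return self._linear(x, "tok/embed") + self.params["tok/pos"]

    # -- public API ------------------------------------------------------------
    def _patch_batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.shape[1] != self.config.image_size or images.shape[2] != self.config.image_size:
            raise ShapeError(
                f"image shape {images.shape[1:]} does not match config "
                f"size {self.config.image_size}"
            )
        return np.stack([patchify(im, self.config.patch_size) for im in images]).astype(_DTYPE)

    def forward_reconstruct(self, images: np.ndarray, mask: MaskSet):
        """Masked forward pass.

        Returns ``(y_m, latent)`` where ``y_m`` is the (B, m, V²·C) Tensor of
        reconstructed masked patches and ``latent`` the encoder output for the
        visible tokens (class token first).
        """
        c = self.config
        if mask.n != c.n_patches:
            raise ShapeError(f"mask over {mask.n} patches, model has {c.n_patches}")
        patches = self._patch_batch(images)
        vis_idx = np.array(mask.visible_indices)
        mask_idx = np.array(mask.masked_indices)

        tokens = self._embed_patches(patches)
        visible = tokens.take(vis_idx, axis=1)  # encoder never sees masked content
        latent = self._encode_tokens(visible)

        b = patches.shape[0]
        enc_tok = latent.take(np.arange(1, latent.shape[1]), axis=1)  # drop cls
        dec_vis = self._linear(enc_tok, "dec/embed")
        mask_tok = broadcast_to(self.params["dec/mask"], (b, len(mask_idx), c.decoder_dim))
        perm = np.concatenate([vis_idx, mask_idx])
        inv = np.argsort(perm)
        x = concat([dec_vis, mask_tok], axis=1).take(inv, axis=1)
        x = x + self.params["dec/pos"]
        for i in range(c.decoder_depth):
            x = self._block(x, f"dec/{i}", c.decoder_heads)
        x = layer_norm(x, self.params["dec/ln/g"], self.params["dec/ln/b"])
        pred = self._linear(x, "dec/pred")
        y_m = pred.take(mask_idx, axis=1)
        return y_m, latent

    def token_features(self, images: np.ndarray, grad: bool = False) -> Tensor:
        """Full unmasked encoder pass → (B, T, E) final-layer patch tokens.

        The class token is excluded so T equals the patch count.  With
        ``grad=False`` the pass runs in inference mode off the graph.
        """
        if grad:
            tokens = self._embed_patches(self._patch_batch(images))
            latent = self._encode_tokens(tokens)
            return latent.take(np.arange(1, latent.shape[1]), axis=1)
        with no_grad():
            tokens = self._embed_patches(self._patch_batch(images))
            latent = self._encode_tokens(tokens)
            return latent.take(np.arange(1, latent.shape[1]), axis=1)

    def extract_token_features(self, image: np.ndarray) -> np.ndarray:
        """Single-image convenience: (T, E) numpy feature matrix."""
        return self.token_features(image).data[0]

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def copy(self) -> "MaskedAutoencoder":
        params = {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()}
        return MaskedAutoencoder(self.config, params=params)


@dataclass
class Checkpoint:
    """A trained model plus its provenance manifest."""

    model: MaskedAutoencoder
    stage_id: int = 0
    manifest: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {k.replace("/", "__"): v.data for k, v in self.model.params.items()}
        np.savez(path / "params.npz", **arrays)
        meta = {
            "config": asdict(self.model.config),
            "stage_id": self.stage_id,
            "manifest": self.manifest,
        }
        (path / "manifest.json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        try:
            meta = json.loads((path / "manifest.json").read_text())
            with np.load(path / "params.npz") as npz:
                params = {
                    k.replace("__", "/"): Tensor(npz[k], requires_grad=True) for k in npz.files
                }
        except Exception as exc:  # noqa: BLE001 - normalize to archive error
            raise CorruptArchiveError(f"cannot load checkpoint at {path}: {exc}") from exc
        config = MAEConfig(**meta["config"])
        model = MaskedAutoencoder(config, params=params)
        return cls(model=model, stage_id=meta["stage_id"], manifest=meta["manifest"])
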