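"""Procedural chest-CT phantoms in Hounsfield units.

The generator draws a cartoon axial chest slice: an air background
(≈ −1000 HU), a soft-tissue body ellipse (≈ 40 HU), two aerated lung
ellipses (≈ −750 HU), and a bone disc for the spine (≈ 700 HU).  Lesion
classes perturb one lung:

* class 0 — normal, no lesion;
* class 1 — a solid nodule: a small disc (radius 3–6 px) of soft-tissue-like
  density (≈ 30 HU) fully inside a lung;
* class 2 — ground-glass opacity: a Gaussian-profile HU elevation of the lung
  parenchyma, with peak amplitude set by ``lesion_contrast``.

Per-pixel Gaussian noise with a per-compartment standard deviation is added
last.  Every sample is a pure function of (spec, label, seed), which makes the
whole training pipeline testable without any real CT data.  The phantoms make
no claim of anatomical realism — no ribs, no projection physics, no scanner
noise model — they exist to give the pipeline HU content in which the two
window settings reveal genuinely different structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, GenerationError, InvalidInputError
from .windowing import Domain, WindowedImage, apply_window, hu_to_png16, sample_window_params

__all__ = [
    "PhantomSpec",
    "LabeledSample",
    "generate_phantom_hu",
    "make_pretrain_dataset",
    "make_finetune_dataset",
    "write_dataset",
]

#: Default compartment densities as (mean HU, noise sd HU).
DEFAULT_TISSUE_HU: dict[str, tuple[float, float]] = {
    "air": (-1000.0, 10.0),
    "lung": (-750.0, 30.0),
    "body": (40.0, 15.0),
    "bone": (700.0, 30.0),
    "nodule": (30.0, 15.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom family.

    ``lesion_contrast`` is the peak HU elevation of the ground-glass blob;
    at the default 300 HU a lung-window image shows a clearly brighter
    region while a mediastinal window still saturates it to black, so the
    two domains carry genuinely different class information.
    """

    size: int = 64
    tissue_hu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_HU)
    )
    lesion_contrast: float = 300.0
    nodule_radius: tuple[int, int] = (3, 6)

    def __post_init__(self):
        if self.size < 32:
            raise ConfigurationError(f"phantom size must be ≥ 32, got {self.size}")
        for name, (mu, sd) in self.tissue_hu.items():
            if sd < 0:
                raise ConfigurationError(f"negative noise sd for {name!r}")
        order = [self.tissue_hu[k][0] for k in ("air", "lung", "body", "bone")]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ConfigurationError("compartment means must be ordered air<lung<body<bone")


@dataclass
class LabeledSample:
    """One phantom: HU image, class id, lesion support mask."""

    hu: np.ndarray
    label: int
    lesion_mask: np.ndarray
    compartments: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom_hu(
    spec: PhantomSpec, label: int, rng: np.random.Generator
) -> LabeledSample:
    """Generate one labeled HU phantom.

    Parameters
    ----------
    spec : PhantomSpec
    label : int
        0 = normal, 1 = solid nodule, 2 = ground-glass opacity.
    rng : numpy Generator
        Seeded generator; identical seeds give bit-identical samples.
    """
    if label not in (0, 1, 2):
        raise InvalidInputError(f"label must be in {{0,1,2}}, got {label}")
    s = spec.size
    hu = np.full((s, s), spec.tissue_hu["air"][0], dtype=np.float64)

    c = s / 2.0
    body = _ellipse_mask(
        s,
        cy=c + rng.uniform(-0.02, 0.02) * s,
        cx=c,
        ry=(0.40 + rng.uniform(-0.02, 0.02)) * s,
        rx=(0.44 + rng.uniform(-0.02, 0.02)) * s,
    )
    hu[body] = spec.tissue_hu["body"][0]

    lungs = np.zeros((s, s), dtype=bool)
    for side in (-1.0, 1.0):
        lung = _ellipse_mask(
            s,
            cy=c + rng.uniform(-0.02, 0.02) * s,
            cx=c + side * (0.20 + rng.uniform(-0.01, 0.01)) * s,
            ry=(0.26 + rng.uniform(-0.02, 0.02)) * s,
            rx=(0.15 + rng.uniform(-0.01, 0.01)) * s,
        )
        lungs |= lung & body
    hu[lungs] = spec.tissue_hu["lung"][0]

    bone = _ellipse_mask(s, cy=c + 0.30 * s, cx=c, ry=0.07 * s, rx=0.07 * s) & body & ~lungs
    hu[bone] = spec.tissue_hu["bone"][0]

    lesion_mask = np.zeros((s, s), dtype=bool)
    if label == 1:
        r = int(rng.integers(spec.nodule_radius[0], spec.nodule_radius[1] + 1))
        lung_px = np.argwhere(lungs)
        for _ in range(100):
            cy, cx = lung_px[rng.integers(0, len(lung_px))]
            disc = _ellipse_mask(s, float(cy), float(cx), r, r)
            if disc.any() and np.all(lungs[disc]):
                lesion_mask = disc
                hu[disc] = spec.tissue_hu["nodule"][0]
                break
        else:
            raise GenerationError("could not place a nodule inside a lung in 100 tries")
    elif label == 2:
        amp = spec.lesion_contrast
        for _ in range(100):
            yy, xx = np.mgrid[0:s, 0:s]
            cy = rng.uniform(0.25 * s, 0.75 * s)
            cx = rng.uniform(0.15 * s, 0.85 * s)
            if not lungs[int(cy), int(cx)]:
                continue
            sigma = rng.uniform(0.06, 0.10) * s
            blob = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            blob[~lungs] = 0.0
            lesion_mask = blob > 0.25 * amp if amp > 0 else np.zeros_like(lungs)
            hu += blob
            break
        else:
            raise GenerationError("could not center a ground-glass blob in a lung in 100 tries")

    # per-compartment noise, one pass, deterministic order
    compartments = {
        "air": ~body,
        "body": body & ~lungs & ~bone,
        "lung": lungs & ~lesion_mask if label == 1 else lungs,
        "bone": bone,
    }
    if label == 1:
        compartments["nodule"] = lesion_mask
    noise = np.zeros((s, s))
    for name, mask in compartments.items():
        sd = spec.tissue_hu.get(name, spec.tissue_hu["lung"])[1]
        if sd > 0:
            noise[mask] = rng.normal(0.0, sd, size=int(mask.sum()))
    hu = hu + noise
    return LabeledSample(hu=hu, label=label, lesion_mask=lesion_mask, compartments=compartments)


def make_pretrain_dataset(
    n: int,
    domain: Domain | str,
    spec: PhantomSpec,
    rng: np.random.Generator,
    preset: str | None = None,
) -> list[WindowedImage]:
    """n unlabeled windowed phantoms for one domain (labels drawn, discarded)."""
    if n < 1:
        raise InvalidInputError(f"need n ≥ 1, got {n}")
    out = []
    for _ in range(n):
        label = int(rng.integers(0, 3))
        sample = generate_phantom_hu(spec, label, rng)
        wspec = sample_window_params(domain, rng, preset=preset)
        out.append(apply_window(sample.hu, wspec))
    return out


def make_finetune_dataset(
    n_per_class: int,
    classes: set[int] | tuple[int, ...],
    domain: Domain | str,
    spec: PhantomSpec,
    rng: np.random.Generator,
    preset: str | None = None,
) -> list[tuple[WindowedImage, int]]:
    """A balanced labeled set: ``n_per_class`` windowed phantoms per class."""
    classes = sorted(set(classes))
    if not classes:
        raise ConfigurationError("empty class set")
    if n_per_class < 1:
        raise InvalidInputError(f"need n_per_class ≥ 1, got {n_per_class}")
    out = []
    for label in classes:
        for _ in range(n_per_class):
            sample = generate_phantom_hu(spec, label, rng)
            wspec = sample_window_params(domain, rng, preset=preset)
            out.append((apply_window(sample.hu, wspec), label))
    return out


def write_dataset(
    samples: list[tuple[WindowedImage, int]] | list[WindowedImage],
    out_dir: str | Path,
    spec: PhantomSpec,
    seed: int,
) -> Path:
    """Write windowed images as 8-bit PNG plus labels.csv and manifest.json."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(samples):
        img, label = item if isinstance(item, tuple) else (item, -1)
        fname = f"img_{i:05d}.png"
        png = np.round(255.0 * img.pixels).astype(np.uint8)
        Image.fromarray(png, mode="L").save(out_dir / fname)
        rows.append((fname, label, img.domain.value))
    with open(out_dir / "labels.csv", "w") as fh:
        fh.write("filename,label,domain\n")
        for fname, label, dom in rows:
            fh.write(f"{fname},{label},{dom}\n")
    manifest = {
        "seed": seed,
        "n": len(samples),
        "spec": {
            "size": spec.size,
            "tissue_hu": spec.tissue_hu,
            "lesion_contrast": spec.lesion_contrast,
            "nodule_radius": list(spec.nodule_radius),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
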