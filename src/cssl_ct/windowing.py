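"""Hounsfield-unit window/level transforms.

A CT scanner reports attenuation in Hounsfield units (HU): air ≈ −1000, water
= 0, dense bone ≫ 0.  Radiologists view a slice through a *window* defined by
a level WL (the HU value mapped to mid-gray) and a width WW (the HU span
mapped onto the display range).  Mediastinal windows (WL ≈ 40, WW ≈ 350)
resolve soft tissue and saturate aerated lung to black; lung windows
(WL ≈ −625, WW ≈ 1350) do the opposite.  The two window settings define the
two training domains of the continual-learning pipeline: the same anatomy
rendered through different windows is a controlled, physically meaningful
domain shift.

The transform is the standard linear window map normalized to [0, 1]:

    windowed(hu) = clip((hu − (WL − WW/2)) / WW, 0, 1)

Window parameters are sampled per image, uniformly from preset ranges, to
emulate the inter-scan variability of clinical viewing presets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "Domain",
    "WindowSpec",
    "WindowedImage",
    "WINDOW_PRESETS",
    "apply_window",
    "sample_window_params",
    "hu_from_png16",
    "hu_to_png16",
    "read_hu_image",
]

#: Offset convention for storing signed HU in unsigned 16-bit PNG.
PNG16_HU_OFFSET = 1024


class Domain(str, Enum):
    """The two window-setting domains of a multi-window chest-CT study."""

    MEDIASTINAL = "mediastinal"
    LUNG = "lung"


@dataclass(frozen=True)
class WindowSpec:
    """One concrete (WL, WW) window with its domain tag.

    Parameters
    ----------
    wl : float
        Window level, the HU value mapped to 0.5.
    ww : float
        Window width in HU; must be positive.
    domain : Domain
        Whether this is a mediastinal or lung window.
    """

    wl: float
    ww: float
    domain: Domain

    def __post_init__(self):
        if not self.ww > 0:
            raise ConfigurationError(f"window width must be positive, got {self.ww}")


@dataclass(frozen=True)
class WindowRange:
    """Uniform sampling ranges [lo, hi] for WL and WW."""

    wl_lo: float
    wl_hi: float
    ww_lo: float
    ww_hi: float
    domain: Domain


#: Clinical presets, stated as center±half-range for the two source studies.
#: J-MID mediastinal 40±20 / 350±50; J-MID lung −625±75 / 1350±350;
#: RICORD mediastinal 40±20 / 350±50; RICORD lung −600±100 / 1300±300.
WINDOW_PRESETS: dict[str, WindowRange] = {
    "jmid_mediastinal": WindowRange(20, 60, 300, 400, Domain.MEDIASTINAL),
    "jmid_lung": WindowRange(-700, -550, 1000, 1700, Domain.LUNG),
    "ricord_mediastinal": WindowRange(20, 60, 300, 400, Domain.MEDIASTINAL),
    "ricord_lung": WindowRange(-700, -500, 1000, 1600, Domain.LUNG),
}


@dataclass
class WindowedImage:
    """A windowed slice: float pixels in [0, 1] plus its provenance."""

    pixels: np.ndarray
    domain: Domain
    source_spec: WindowSpec


def apply_window(hu: np.ndarray, spec: WindowSpec) -> WindowedImage:
    """Apply a linear HU window, clipping to [0, 1].

    Parameters
    ----------
    hu : ndarray
        2-D array of Hounsfield units.
    spec : WindowSpec
        The window to apply.

    Returns
    -------
    WindowedImage
        Same shape as ``hu``; monotone non-decreasing in the HU value.
    """
    hu = np.asarray(hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise InvalidInputError("HU image contains non-finite values")
    lo = spec.wl - spec.ww / 2.0
    out = np.clip((hu - lo) / spec.ww, 0.0, 1.0)
    return WindowedImage(pixels=out, domain=spec.domain, source_spec=spec)


def sample_window_params(
    domain: Domain | str,
    rng: np.random.Generator,
    preset: str | None = None,
    ranges: dict[str, WindowRange] | None = None,
) -> WindowSpec:
    """Draw one (WL, WW) pair uniformly from a domain's preset range.

    ``preset`` selects a named range (default ``jmid_<domain>``); ``ranges``
    overrides the preset table entirely (e.g. from a YAML config).
    """
    domain = Domain(domain)
    table = WINDOW_PRESETS if ranges is None else ranges
    key = preset if preset is not None else f"jmid_{domain.value}"
    if key not in table:
        raise ConfigurationError(
            f"unknown window preset {key!r}; available: {sorted(table)}"
        )
    r = table[key]
    if r.domain != domain:
        raise ConfigurationError(
            f"preset {key!r} is a {r.domain.value} preset, requested {domain.value}"
        )
    wl = rng.uniform(r.wl_lo, r.wl_hi)
    ww = rng.uniform(r.ww_lo, r.ww_hi)
    return WindowSpec(wl=wl, ww=ww, domain=domain)


# -- PNG round-trip for HU content --------------------------------------------

def hu_to_png16(hu: np.ndarray) -> np.ndarray:
    """Encode HU as uint16 with the documented +1024 offset."""
    shifted = np.asarray(hu, dtype=np.float64) + PNG16_HU_OFFSET
    return np.clip(np.round(shifted), 0, 65535).astype(np.uint16)


def hu_from_png16(png: np.ndarray) -> np.ndarray:
    """Decode the uint16 PNG convention back to HU."""
    return np.asarray(png, dtype=np.float64) - PNG16_HU_OFFSET


def read_hu_image(path, slice_index: int | None = None) -> np.ndarray:
    """Read a HU slice from a 16-bit PNG (+1024 offset) or a NIfTI file.

    NIfTI volumes are reduced to 2-D by ``slice_index`` along the last axis
    (default: the middle slice).  PNG files are assumed to follow the
    documented value = HU + 1024 convention.
    """
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
        return hu_from_png16(arr)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
        data = np.squeeze(data)
        if data.ndim == 3:
            k = data.shape[-1] // 2 if slice_index is None else slice_index
            data = data[..., k]
        if data.ndim != 2:
            raise InvalidInputError(
                f"cannot reduce {path.name} to a 2-D slice (shape {data.shape})"
            )
        return data
    raise InvalidInputError(f"unsupported HU image format: {path.suffix!r}")
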