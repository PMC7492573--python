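"""Image-derived physiological read-outs for multispectral plant phenotyping.

Three per-pixel indices are computed from named bands of a multispectral
stack:

* **Fv/Fm** — maximum quantum efficiency of photosystem II in dark-adapted
  tissue, ``(Fm - F0) / Fm`` from the minimal (F0) and maximal (Fm)
  chlorophyll-fluorescence images;
* **AriIdx** — the modified anthocyanin reflectance index,
  ``(1/R550 - 1/R700) * R_NIR``;
* **ChlIdx** — a chlorophyll index; the exact formula used by commercial
  phenotyping software is unpublished, so the default here is the analogous
  reciprocal-reflectance form ``(1/R700 - 1/R_NIR) * R_NIR`` and any other
  per-band expression can be injected.

Each index image is then summarized as the relative distribution of plant
pixels over custom value classes, the representation used for stacked-bar
reporting of whole-rosette physiology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "MultispectralStack",
    "ClassDistribution",
    "EmptyMaskError",
    "DEFAULT_FVFM_EDGES",
    "DEFAULT_ARI_EDGES",
    "DEFAULT_CHL_EDGES",
    "fvfm_image",
    "ari_image",
    "chl_index",
    "class_distribution",
    "save_stack",
    "load_stack",
]

# Default class edges: five Fv/Fm classes on [0, 1]; eight classes for the
# reflectance indices.  The commercial platform's edges are user-defined and
# unpublished, so these are overridable defaults on plausible ranges.
DEFAULT_FVFM_EDGES: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 6))
DEFAULT_ARI_EDGES: tuple[float, ...] = tuple(np.linspace(0.0, 4.0, 9))
DEFAULT_CHL_EDGES: tuple[float, ...] = tuple(np.linspace(0.0, 4.0, 9))

REFLECTANCE_BANDS = ("R550", "R700", "RNIR")
FLUORESCENCE_BANDS = ("F0", "Fm")


class EmptyMaskError(ValueError):
    """Raised when an index image has no plant pixels (empty mask)."""


@dataclass
class MultispectralStack:
    """Named image bands plus a plant/background mask.

    Reflectance bands (R550, R700, RNIR) are fractions in (0, 1]; F0/Fm are
    non-negative fluorescence counts.  All bands and the mask share one shape.
    """

    bands: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(img).shape for name, img in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"bands have mismatched shapes: {shapes}")
        self.bands = {name: np.asarray(img, dtype=float) for name, img in self.bands.items()}
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.bands and self.mask.shape != next(iter(self.bands.values())).shape:
            raise ValueError("mask shape does not match band shape")
        for name in REFLECTANCE_BANDS:
            if name in self.bands:
                vals = self.bands[name][self.mask]
                if vals.size and (vals <= 0).any():
                    raise ValueError(f"non-positive reflectance inside mask in band {name}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


@dataclass
class ClassDistribution:
    """Relative pixel fractions over value classes, plus the masked mean."""

    edges: tuple[float, ...]
    fractions: np.ndarray
    total_value: float

    def __post_init__(self) -> None:
        self.edges = tuple(float(e) for e in self.edges)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.fractions) != len(self.edges) - 1:
            raise ValueError("need len(fractions) == len(edges) - 1")

    def to_dict(self) -> dict:
        return {
            "edges": list(self.edges),
            "fractions": self.fractions.tolist(),
            "total_value": self.total_value,
        }


def _check_shapes(*images: np.ndarray) -> None:
    shapes = {np.asarray(img).shape for img in images}
    if len(shapes) > 1:
        raise ValueError(f"image shapes differ: {shapes}")


def fvfm_image(
    f0: np.ndarray,
    fm: np.ndarray,
    mask: np.ndarray,
    fm_floor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Fv/Fm = (Fm - F0)/Fm over the mask.

    Pixels with ``Fm <= fm_floor`` carry no usable fluorescence signal and are
    dropped from the returned effective mask.  Values outside [0, 1] (F0 > Fm)
    are kept as-is so corrupt input stays visible; they are not clipped.
    Returns ``(index_image, effective_mask)`` with NaN outside the mask.
    """
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(f0, fm, mask)
    if fm_floor <= 0:
        raise ValueError("fm_floor must be positive")
    eff = mask & (fm > fm_floor)
    out = np.full(fm.shape, np.nan)
    out[eff] = (fm[eff] - f0[eff]) / fm[eff]
    return out, eff


def ari_image(
    r550: np.ndarray,
    r700: np.ndarray,
    rnir: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Modified anthocyanin reflectance index (1/R550 - 1/R700) * R_NIR."""
    r550 = np.asarray(r550, dtype=float)
    r700 = np.asarray(r700, dtype=float)
    rnir = np.asarray(rnir, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(r550, r700, rnir, mask)
    for name, band in (("R550", r550), ("R700", r700)):
        if (band[mask] <= 0).any():
            raise ValueError(f"non-positive reflectance inside mask in band {name}")
    out = np.full(r550.shape, np.nan)
    out[mask] = (1.0 / r550[mask] - 1.0 / r700[mask]) * rnir[mask]
    return out


def chl_index(
    r700: np.ndarray,
    rnir: np.ndarray,
    mask: np.ndarray,
    formula: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Chlorophyll index under a configurable per-pixel formula.

    The default, ``(1/R700 - 1/R_NIR) * R_NIR``, is a stand-in reciprocal-
    reflectance index in the mARI family; pass ``formula`` to use another
    expression of the two bands.
    """
    r700 = np.asarray(r700, dtype=float)
    rnir = np.asarray(rnir, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(r700, rnir, mask)
    if (r700[mask] <= 0).any() or (rnir[mask] <= 0).any():
        raise ValueError("non-positive reflectance inside mask")
    if formula is None:
        formula = lambda a, b: (1.0 / a - 1.0 / b) * b  # noqa: E731
    out = np.full(r700.shape, np.nan)
    out[mask] = formula(r700[mask], rnir[mask])
    return out


def class_distribution(
    index_image: np.ndarray,
    mask: np.ndarray,
    edges: Sequence[float],
) -> ClassDistribution:
    """Relative pixel counts of an index image over classes [e_i, e_{i+1}).

    The final class is closed on the right; out-of-range pixels are clipped
    into the end classes so fractions always sum to 1.  ``total_value`` is the
    unclipped mean over the masked pixels.
    """
    values = np.asarray(index_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(values, mask)
    edges_arr = np.asarray(edges, dtype=float)
    if edges_arr.size < 2 or not np.all(np.diff(edges_arr) > 0):
        raise ValueError("edges must be strictly increasing with at least 2 entries")
    vals = values[mask & np.isfinite(values)]
    if vals.size == 0:
        raise EmptyMaskError("no plant pixels in mask")
    clipped = np.clip(vals, edges_arr[0], edges_arr[-1])
    counts, _ = np.histogram(clipped, bins=edges_arr)
    return ClassDistribution(
        edges=tuple(edges_arr),
        fractions=counts / vals.size,
        total_value=float(vals.mean()),
    )


def save_stack(stack: MultispectralStack, path) -> None:
    """Write a stack as a multi-page TIFF with band names in the description."""
    import tifffile

    names = sorted(stack.bands)
    arr = np.stack([stack.bands[n] for n in names] + [stack.mask.astype(float)])
    tifffile.imwrite(
        path,
        arr.astype(np.float32),
        photometric="minisblack",
        description=json.dumps({"bands": names + ["MASK"]}),
    )


def load_stack(path) -> MultispectralStack:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    names = meta["bands"]
    bands = {n: arr[i] for i, n in enumerate(names) if n != "MASK"}
    mask = arr[names.index("MASK")] > 0.5
    return MultispectralStack(bands=bands, mask=mask)
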