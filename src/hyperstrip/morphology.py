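"""Flat grayscale morphology over configurable structuring elements.

Erosion, dilation, openings/closings, geodesic reconstruction by dilation,
and the reconstruction-based smoothing filter used as pipeline preprocessing.
All operators work on 8-bit volumes (``uint8``, intensities in [0, 255]);
2D images are accepted everywhere and are handled as single-slice volumes,
so the default 3D element degrades to its nine in-plane offsets.

Border policy: out-of-domain neighbours are ignored — erosion pads with 255
and dilation pads with 0, which keeps anti-extensivity/extensivity exact at
the borders for 8-bit data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction as _sk_reconstruction

__all__ = [
    "StructuringElement",
    "fig1_se",
    "box26_se",
    "cross6_se",
    "get_se",
    "connectivity_footprint",
    "as_volume",
    "check_gray",
    "erode",
    "dilate",
    "open_",
    "close_",
    "reconstruct_by_dilation",
    "reconstruct_by_erosion",
    "smooth_by_reconstruction",
]


# --------------------------------------------------------------------------
# structuring elements
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuringElement:
    """A flat structuring element: a finite set of integer voxel offsets
    (dz, dy, dx) containing the origin.

    Homothetic sizes are realised by iterating the unit element, so a single
    instance describes the unit shape only.
    """

    offsets: tuple[tuple[int, int, int], ...]
    name: str = field(default="custom", compare=False)

    def __post_init__(self):
        if len(self.offsets) == 0:
            raise ValueError("structuring element must not be empty")
        if (0, 0, 0) not in self.offsets:
            raise ValueError("structuring element must contain the origin")

    @property
    def transpose(self) -> "StructuringElement":
        """B-breve: the reflection {-b : b in B}."""
        return StructuringElement(
            tuple(sorted((-a, -b, -c) for (a, b, c) in self.offsets)),
            name=self.name + "_t",
        )

    @property
    def is_symmetric(self) -> bool:
        return set(self.offsets) == {(-a, -b, -c) for (a, b, c) in self.offsets}

    def footprint(self) -> np.ndarray:
        """Boolean footprint array centred on the origin (odd shape)."""
        r = max(max(abs(d) for d in off) for off in self.offsets)
        r = max(r, 1)
        fp = np.zeros((2 * r + 1,) * 3, dtype=bool)
        for dz, dy, dx in self.offsets:
            fp[r + dz, r + dy, r + dx] = True
        return fp

    def neighbor_offsets(self) -> np.ndarray:
        """Offsets without the origin, as an (k, 3) int array — the adjacency
        graph induced by the element."""
        offs = [o for o in self.offsets if o != (0, 0, 0)]
        return np.asarray(offs, dtype=np.int64)


def fig1_se() -> StructuringElement:
    """The 11-neighbour 3D element: the full 3x3 in-plane square plus the two
    face-adjacent voxels in the slices above and below (axial centres)."""
    offs = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    offs += [(-1, 0, 0), (1, 0, 0)]
    return StructuringElement(tuple(sorted(offs)), name="fig1_11")


def box26_se() -> StructuringElement:
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
    ]
    return StructuringElement(tuple(sorted(offs)), name="box26")


def cross6_se() -> StructuringElement:
    offs = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
            (0, 0, 1), (0, 0, -1)]
    return StructuringElement(tuple(sorted(offs)), name="cross6")


_SE_REGISTRY = {"fig1_11": fig1_se, "box26": box26_se, "cross6": cross6_se}


def get_se(se=None) -> StructuringElement:
    """Resolve a structuring element spec: None -> the 11-neighbour default,
    a registry name, or a StructuringElement passed through."""
    if se is None:
        return fig1_se()
    if isinstance(se, StructuringElement):
        return se
    if isinstance(se, str):
        try:
            return _SE_REGISTRY[se]()
        except KeyError:
            raise ValueError(
                f"unknown structuring element {se!r}; "
                f"choose from {sorted(_SE_REGISTRY)}"
            ) from None
    raise TypeError(f"cannot interpret {se!r} as a structuring element")


def connectivity_footprint(connectivity) -> np.ndarray:
    """3x3x3 boolean footprint for a flat-zone connectivity.

    Accepts 6/18/26 (3D), 4/8 (2D, in-plane only), a StructuringElement
    (its own support), or an explicit boolean footprint.
    """
    if isinstance(connectivity, StructuringElement):
        return connectivity.footprint()
    if isinstance(connectivity, np.ndarray):
        fp = connectivity.astype(bool)
        if fp.ndim == 2:
            out = np.zeros((3,) + fp.shape, dtype=bool)
            out[1] = fp
            return out
        return fp
    table = {6: 1, 18: 2, 26: 3}
    if connectivity in table:
        return ndimage.generate_binary_structure(3, table[connectivity])
    if connectivity in (4, 8):
        fp2 = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
        out = np.zeros((3, 3, 3), dtype=bool)
        out[1] = fp2
        return out
    raise ValueError(f"unsupported connectivity {connectivity!r}")


# --------------------------------------------------------------------------
# volume handling
# --------------------------------------------------------------------------

def as_volume(f) -> tuple[np.ndarray, bool]:
    """Return ``f`` as a 3D uint8 array plus a flag telling whether the input
    was 2D (a single-slice volume)."""
    arr = check_gray(f)
    if arr.ndim == 2:
        return arr[np.newaxis], True
    return arr, False


def check_gray(f) -> np.ndarray:
    """Validate a 2D/3D integer-intensity image in [0, 255]; returns uint8."""
    arr = np.asarray(f)
    if arr.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D array, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype == np.uint8:
        return arr
    lo, hi = arr.min(), arr.max()
    if lo < 0 or hi > 255:
        raise ValueError(f"intensities outside [0, 255]: min={lo}, max={hi}")
    if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.round(arr)):
        raise ValueError("non-integer intensities; quantize on load")
    return arr.astype(np.uint8)


def _restore(arr3d: np.ndarray, was_2d: bool) -> np.ndarray:
    return arr3d[0] if was_2d else arr3d


# --------------------------------------------------------------------------
# erosion / dilation / opening / closing
# --------------------------------------------------------------------------

def _check_lam(lam) -> int:
    lam = int(lam)
    if lam < 0:
        raise ValueError(f"size lam must be >= 0, got {lam}")
    return lam


def erode(f, se=None, lam: int = 1) -> np.ndarray:
    """Flat erosion at homothetic size ``lam`` (lam-fold iteration of the
    unit element); lam = 0 is the identity."""
    lam = _check_lam(lam)
    se = get_se(se)
    g, was_2d = as_volume(f)
    fp = se.footprint()
    for _ in range(lam):
        g = ndimage.grey_erosion(g, footprint=fp, mode="constant", cval=255)
    return _restore(np.ascontiguousarray(g, dtype=np.uint8), was_2d)


def dilate(f, se=None, lam: int = 1) -> np.ndarray:
    """Flat dilation at size ``lam``, adjoint of :func:`erode` (max over the
    transposed support)."""
    lam = _check_lam(lam)
    se = get_se(se)
    g, was_2d = as_volume(f)
    fp = se.footprint()
    for _ in range(lam):
        g = ndimage.grey_dilation(g, footprint=fp, mode="constant", cval=0)
    return _restore(np.ascontiguousarray(g, dtype=np.uint8), was_2d)


def open_(f, se=None, lam: int = 1) -> np.ndarray:
    """Morphological opening: dilation after erosion, both at size lam."""
    return dilate(erode(f, se, lam), se, lam)


def close_(f, se=None, lam: int = 1) -> np.ndarray:
    """Morphological closing: erosion after dilation, both at size lam."""
    return erode(dilate(f, se, lam), se, lam)


# --------------------------------------------------------------------------
# geodesic reconstruction
# --------------------------------------------------------------------------

def _resolve_conn(connectivity, se) -> np.ndarray:
    """Footprint for reconstruction: explicit connectivity wins; None falls
    back to the SE-induced graph when an SE is given, else 26-connected."""
    if connectivity is None:
        return get_se(se).footprint() if se is not None else connectivity_footprint(26)
    return connectivity_footprint(connectivity)


def reconstruct_by_dilation(marker, reference, connectivity=26, se=None) -> np.ndarray:
    """Geodesic reconstruction by dilation of ``marker`` under ``reference``:
    the smallest fixpoint g >= marker of g -> reference ^ delta_1(g).

    ``connectivity`` may be 6/18/26 (or 4/8 for 2D); pass ``connectivity=None``
    together with ``se`` to propagate along the SE-induced graph instead.
    """
    m, was_2d = as_volume(marker)
    r, _ = as_volume(reference)
    if m.shape != r.shape:
        raise ValueError(f"marker shape {m.shape} != reference shape {r.shape}")
    bad = m > r
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"marker exceeds reference, first offending voxel at {idx}: "
            f"{int(m[idx])} > {int(r[idx])}"
        )
    fp = _resolve_conn(connectivity, se)
    out = _sk_reconstruction(m, r, method="dilation", footprint=fp)
    return _restore(out.astype(np.uint8), was_2d)


def reconstruct_by_erosion(marker, reference, connectivity=26, se=None) -> np.ndarray:
    """Dual reconstruction: largest fixpoint g <= marker of
    g -> reference v epsilon_1(g); requires marker >= reference."""
    m, was_2d = as_volume(marker)
    r, _ = as_volume(reference)
    if m.shape != r.shape:
        raise ValueError(f"marker shape {m.shape} != reference shape {r.shape}")
    bad = m < r
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"marker below reference, first offending voxel at {idx}: "
            f"{int(m[idx])} < {int(r[idx])}"
        )
    fp = _resolve_conn(connectivity, se)
    out = _sk_reconstruction(m, r, method="erosion", footprint=fp)
    return _restore(out.astype(np.uint8), was_2d)


def smooth_by_reconstruction(f, mu: int = 2, se=None, connectivity=26) -> np.ndarray:
    """Reconstruction smoothing: opening by reconstruction composed after
    closing by reconstruction, both at size ``mu``.

    Removes bright and dark structures thinner than ``mu`` without shifting
    contours, which reduces the number of regional extrema before a max-tree
    is built. ``mu = 0`` is the identity.
    """
    mu = _check_lam(mu)
    if mu == 0:
        return check_gray(f).copy()
    se = get_se(se)
    # closing by reconstruction: marker = dilation, reconstruct by erosion
    closed = reconstruct_by_erosion(dilate(f, se, mu), f, connectivity=connectivity)
    # opening by reconstruction: marker = erosion, reconstruct by dilation
    return reconstruct_by_dilation(erode(closed, se, mu), closed,
                                   connectivity=connectivity)
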