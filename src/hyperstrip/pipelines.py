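"""The two skull-stripping procedures and their plumbing.

MHF (maximum hyperconnected function) pipeline, for a T1 head volume f:

    0. optional reconstruction smoothing at size smooth_mu
    1. erosion at viscosity lam        — separates brain from skull
    2. extreme hyperconnected opening  — keeps the greatest-volume maximum
    3. dilation at viscosity lam       — restores the viscous component
    4. Otsu threshold                  — removes low-intensity residue
    5. mask ∧ original                 — the stripped brain

HLL (hyperconnected lower leveling) pipeline replaces steps 2–3's full
reconstruction with a lower leveling at slope alpha iterated from the
selected maximum against the eroded image, so the marker stops in the dark
dura instead of climbing back into the skull; with alpha = 0 the two
pipelines coincide exactly.

Defaults are lam = 3, alpha = 3 and smoothing size 2 — the settings the
method was designed around.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .leveling import iterate_lower_leveling
from .maxtree import _select_leaves, _selection_image, build_maxtree
from .morphology import (
    as_volume,
    check_gray,
    connectivity_footprint,
    dilate,
    erode,
    get_se,
    smooth_by_reconstruction,
)

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "StageError",
    "otsu_threshold",
    "mhf_pipeline",
    "hll_pipeline",
    "strip",
    "load_volume",
    "save_like",
]

logger = logging.getLogger("hyperstrip")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the MHF/HLL pipelines.

    lam : viscosity — size of the erosion/dilation envelope (default 3).
    alpha : leveling slope in [0, 255], HLL only (default 3).
    smooth_mu : reconstruction-smoothing size, 0 disables (default 2).
    criterion : 'extreme' (greatest-volume maximum) or 'threshold' with mu_v.
    se : structuring element name or instance (default the 11-neighbour one).
    connectivity : flat-zone adjacency for the max-tree and reconstructions;
        None means the SE-induced graph.
    threshold_policy : 'otsu' or 'fixed' (with fixed_threshold).
    otsu_nonzero : compute Otsu over positive voxels only.
    largest_cc : keep only the largest connected component of the mask.
    """

    lam: int = 3
    alpha: int = 3
    smooth_mu: int = 2
    criterion: str = "extreme"
    mu_v: int | None = None
    se: object = "fig1_11"
    connectivity: object = None
    threshold_policy: str = "otsu"
    fixed_threshold: int | None = None
    otsu_nonzero: bool = False
    largest_cc: bool = False


@dataclass
class SegmentationResult:
    """Output of one pipeline run."""

    mask: np.ndarray
    stripped: np.ndarray
    threshold: int
    method: str
    config: PipelineConfig
    intermediates: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)


# --------------------------------------------------------------------------
# Otsu threshold
# --------------------------------------------------------------------------

def otsu_threshold(f, nonzero: bool = False):
    """Otsu threshold over the 256-bin histogram of all voxels.

    Returns ``(t, mask)`` with ``t`` maximising the between-class variance of
    the split {levels <= t} vs {levels > t} and ties broken toward the lowest
    t; the mask is the strict upper set {f > t}, so background 0 never enters
    it. Raises on images with fewer than two distinct levels.
    """
    arr = check_gray(f)
    values = arr[arr > 0] if nonzero else arr.ravel()
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined: fewer than 2 distinct levels")
    hist = np.bincount(values, minlength=256).astype(np.float64)
    total = hist.sum()
    p = hist / total
    omega = np.cumsum(p)                  # w0 for split at t = 0..255
    mu = np.cumsum(p * np.arange(256))    # class-0 mass-weighted mean
    mu_t = mu[-1]
    w0 = omega[:-1]
    w1 = 1.0 - w0
    num = (mu_t * w0 - mu[:-1]) ** 2
    denom = w0 * w1
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(denom > 0, num / denom, 0.0)
    t = int(np.argmax(sigma_b))           # argmax returns the lowest tie
    return t, arr > t


# --------------------------------------------------------------------------
# pipelines
# --------------------------------------------------------------------------

def _stage(log, name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(name, exc) from exc
    dt = time.perf_counter() - t0
    log.append((name, dt))
    logger.debug("stage %-12s %.3f s", name, dt)
    return out


def _largest_cc(mask: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    se = get_se(cfg.se)
    fp = (se.footprint() if cfg.connectivity is None
          else connectivity_footprint(cfg.connectivity))
    m3, was_2d = as_volume(mask.astype(np.uint8) * 255)
    labels, n = ndimage.label(m3 > 0, structure=fp)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = labels == np.argmax(sizes)
    return (keep[0] if was_2d else keep)


def _run_pipeline(f, cfg: PipelineConfig, method: str,
                  keep_intermediates: bool = False) -> SegmentationResult:
    original = check_gray(f)
    se = get_se(cfg.se)
    log: list = []
    inter: dict = {}

    work = original
    if cfg.smooth_mu:
        work = _stage(log, "smooth", smooth_by_reconstruction, work,
                      cfg.smooth_mu, se=se,
                      connectivity=(se if cfg.connectivity is None
                                    else cfg.connectivity))
        if keep_intermediates:
            inter["smoothed"] = work

    eroded = _stage(log, "erode", erode, work, se, cfg.lam)
    if keep_intermediates:
        inter["eroded"] = eroded

    tree = _stage(log, "maxtree", build_maxtree, eroded,
                  connectivity=cfg.connectivity, se=se)
    selected = _stage(log, "select", _select_leaves, tree, cfg.criterion,
                      cfg.mu_v)

    if method == "mhf":
        gray = _stage(log, "reconstruct", _selection_image, tree, selected)
    elif method == "hll":
        def _level():
            marker = np.where(np.isin(tree.pixel_node, selected), eroded, 0)
            marker = marker.astype(np.uint8)
            if selected.size == 0:
                return marker
            return iterate_lower_leveling(eroded, marker, cfg.alpha, se=se)

        gray = _stage(log, "leveling", _level)
    else:
        raise ValueError(f"unknown method {method!r}")
    if keep_intermediates:
        inter["selected"] = gray

    dilated = _stage(log, "dilate", dilate, gray, se, cfg.lam)
    if keep_intermediates:
        inter["dilated"] = dilated

    if cfg.threshold_policy == "otsu":
        t, mask = _stage(log, "threshold", otsu_threshold, dilated,
                         nonzero=cfg.otsu_nonzero)
    elif cfg.threshold_policy == "fixed":
        if cfg.fixed_threshold is None:
            raise StageError("threshold",
                             ValueError("fixed policy requires fixed_threshold"))
        t = int(cfg.fixed_threshold)
        mask = dilated > t
    else:
        raise StageError("threshold",
                         ValueError(f"unknown policy {cfg.threshold_policy!r}"))

    if cfg.largest_cc:
        mask = _stage(log, "largest_cc", _largest_cc, mask, cfg)

    stripped = np.where(mask, original, 0).astype(np.uint8)
    logger.info("%s pipeline done: otsu t=%d, mask voxels=%d",
                method.upper(), t, int(mask.sum()))
    return SegmentationResult(mask=mask, stripped=stripped, threshold=t,
                              method=method, config=cfg, intermediates=inter,
                              stage_log=log)


def mhf_pipeline(f, cfg: PipelineConfig | None = None,
                 keep_intermediates: bool = False) -> SegmentationResult:
    """Skull stripping by the maximum hyperconnected function."""
    return _run_pipeline(f, cfg or PipelineConfig(), "mhf",
                         keep_intermediates)


def hll_pipeline(f, cfg: PipelineConfig | None = None,
                 keep_intermediates: bool = False) -> SegmentationResult:
    """Skull stripping by the hyperconnected lower leveling."""
    return _run_pipeline(f, cfg or PipelineConfig(), "hll",
                         keep_intermediates)


# --------------------------------------------------------------------------
# file I/O and the strip() entry point
# --------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz", ".img", ".hdr")
_IMAGE_SUFFIXES = (".png", ".pgm", ".ppm", ".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def load_volume(path, quantize: bool = True):
    """Read a 2D/3D grayscale image and its spatial metadata.

    NIfTI-1 / Analyze 7.5 volumes load through nibabel (the metadata is the
    nibabel image, carried through unchanged); PNG/PGM toys load through
    imageio with no metadata. Intensities outside [0, 255] are min-max
    rescaled to the 8-bit range when ``quantize``.
    """
    path = Path(path)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        data = np.squeeze(data)
        meta = img
    elif sfx in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        data = np.asarray(iio.imread(str(path))).astype(np.float64)
        if data.ndim == 3 and data.shape[-1] in (3, 4):  # RGB(A) -> gray
            data = data[..., :3].mean(axis=-1)
        meta = None
    else:
        raise IOError(f"unsupported input format {sfx!r} for {path}")
    if data.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D volume, got shape {data.shape}")
    if quantize:
        lo, hi = data.min(), data.max()
        if lo < 0 or hi > 255:
            data = (data - lo) / max(hi - lo, 1e-12) * 255.0
        data = np.round(data)
    return data.astype(np.uint8), meta


def save_like(data: np.ndarray, meta, path) -> Path:
    """Write ``data`` next to the metadata of the volume it derives from,
    preserving header and affine for NIfTI/Analyze inputs."""
    path = Path(path)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        import nibabel as nib

        if meta is not None:
            hdr = meta.header.copy()
            hdr.set_data_dtype(np.uint8)
            out = meta.__class__(data.astype(np.uint8), meta.affine, hdr)
        else:
            out = nib.Nifti1Image(data.astype(np.uint8), np.eye(4))
        nib.save(out, str(path))
    elif sfx in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        iio.imwrite(str(path), data.astype(np.uint8))
    else:
        raise IOError(f"unsupported output format {sfx!r} for {path}")
    return path


def strip(volume_path, cfg: PipelineConfig | None = None,
          method: str = "mhf", out=None, mask_out=None,
          intermediates_dir=None) -> SegmentationResult:
    """Run a skull-stripping pipeline on a volume file.

    Loads the whole 3D volume (or a 2D toy image), runs the selected
    pipeline, and, when requested, writes the stripped volume and the 0/1
    mask preserving the input header/affine. Per-stage timings and the Otsu
    threshold are logged; written paths are recorded in
    ``result.intermediates['written']``.
    """
    if method not in ("mhf", "hll"):
        raise ValueError(f"method must be 'mhf' or 'hll', got {method!r}")
    data, meta = load_volume(volume_path)
    result = _run_pipeline(data, cfg or PipelineConfig(), method,
                           keep_intermediates=intermediates_dir is not None)
    written = {}
    if out is not None:
        written["stripped"] = save_like(result.stripped, meta, out)
    if mask_out is not None:
        written["mask"] = save_like(result.mask.astype(np.uint8), meta,
                                    mask_out)
    if intermediates_dir is not None:
        d = Path(intermediates_dir)
        d.mkdir(parents=True, exist_ok=True)
        ext = _suffix(Path(volume_path))
        for name, arr in result.intermediates.items():
            if isinstance(arr, np.ndarray):
                written[name] = save_like(np.asarray(arr, dtype=np.uint8),
                                          meta, d / f"{name}{ext}")
    result.intermediates["written"] = written
    for name, dt in result.stage_log:
        logger.info("  %-12s %.3f s", name, dt)
    return result
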