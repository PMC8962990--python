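"""Synthetic head phantoms and small constructed fixtures.

The phantom emulates the geometry that makes T1 skull stripping hard: a
bright brain ellipsoid, a dark dura gap, bright skull and scalp shells, and
bright eye spheres that bridge the brain margin and the skull shell so that,
in the binary sense (intensity above the dura level), brain and skull form a
single hyperconnected component. The eyes sit in carved orbits — cylindrical
openings through dura/skull/scalp slightly narrower than the eye — so each
bridge is a thin neck (about one voxel of overlap at the brain cap and at the
orbit rim) that an erosion at viscosity 3 severs, while the raw volume stays
one component. Intensities follow the T1 ordering (brain bright, dura/CSF
dark, skull mid, eyes bright); they are fixture constants, not claims about
real MR physics.

Ground truth is the exact brain-ellipsoid lattice set, disjoint from every
shell. Identical spec + seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomSpec", "generate_phantom", "validate_phantom",
           "make_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic head volume."""

    shape: tuple = (64, 80, 64)          # (nz, ny, nx)
    brain_axes: tuple = (18.0, 26.0, 18.0)
    brain_intensity: int = 140           # mean over the brain compartment
    # T1 white matter is brighter than peripheral gray matter: the brain
    # interior is a parabolic dome, brain_intensity + wm_gm_contrast*(3/5 -
    # rho^2) with rho the normalised ellipsoid radius (mean rho^2 = 3/5, so
    # the mean stays brain_intensity: centre ~149, cortical edge ~134).
    # This keeps the global maximum central, as in real T1, instead of
    # leaving its position to the noise.
    wm_gm_contrast: float = 15.0
    # the dark gap must outlive the pipelines' size-2 reconstruction
    # smoothing (which seals dark sheets thinner than ~2 SE sizes), as the
    # CSF/dura gap does in real T1 volumes: 5 voxels is the minimum width
    # whose dark core survives the closing half of that filter
    dura_width: float = 5.0
    dura_intensity: int = 25
    skull_width: float = 3.0
    skull_intensity: int = 120
    scalp_width: float = 5.0
    scalp_intensity: int = 90
    eye_radius: float = 5.0
    eye_intensity: int = 160
    eye_brain_overlap: float = 1.0       # depth the eye pokes into the brain
    orbit_radius: float = 4.0            # carved opening, < eye_radius
    eye_angle: float = 0.35              # radians off the -y axis, in-plane
    noise_sd: float = 5.0
    texture_amplitude: float = 0.0
    seed: int = 0


def _ellipsoid_mask(coords, axes, grow: float) -> np.ndarray:
    zz, yy, xx = coords
    az, ay, ax = (a + grow for a in axes)
    return (zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax) ** 2 <= 1.0


def _regions(spec: PhantomSpec):
    """Noiseless volume plus the exact region masks it was painted from."""
    if min(spec.dura_width, spec.skull_width, spec.scalp_width) <= 0:
        raise ValueError("shell widths must be positive; shells would "
                         "overlap the brain ground truth")
    if spec.eye_radius > 0 and not spec.orbit_radius < spec.eye_radius:
        raise ValueError("orbit_radius must be smaller than eye_radius for "
                         "the eye to touch the skull shell")
    nz, ny, nx = spec.shape
    center = np.array([nz // 2, ny // 2, nx // 2], dtype=np.float64)
    outer = spec.dura_width + spec.skull_width + spec.scalp_width
    for c, a, n in zip(center, spec.brain_axes, spec.shape):
        if c - a - outer < 0 or c + a + outer > n - 1:
            raise ValueError("phantom shells do not fit inside the grid; "
                             "shrink brain_axes or the shell widths")

    idx = np.indices(spec.shape, dtype=np.float64)
    coords = tuple(idx[i] - center[i] for i in range(3))

    vol = np.zeros(spec.shape, dtype=np.float64)
    # paint outermost first so inner shells overwrite
    t_skull = spec.dura_width + spec.skull_width
    vol[_ellipsoid_mask(coords, spec.brain_axes, outer)] = spec.scalp_intensity
    vol[_ellipsoid_mask(coords, spec.brain_axes, t_skull)] = spec.skull_intensity
    vol[_ellipsoid_mask(coords, spec.brain_axes, spec.dura_width)] = spec.dura_intensity
    brain = _ellipsoid_mask(coords, spec.brain_axes, 0.0)
    rho2 = sum((coords[i] / spec.brain_axes[i]) ** 2 for i in range(3))
    dome = spec.brain_intensity + spec.wm_gm_contrast * (0.6 - rho2)
    vol[brain] = dome[brain]

    # eyes: spheres in carved orbits, bridging brain margin and skull shell
    eyes = np.zeros(spec.shape, dtype=bool)
    carved = np.zeros(spec.shape, dtype=bool)
    if spec.eye_radius > 0:
        pts = np.stack([c.ravel() for c in coords])  # (3, N) relative coords
        for sign in (+1.0, -1.0):
            d = np.array([0.0, -np.cos(spec.eye_angle),
                          sign * np.sin(spec.eye_angle)])
            # distance from centre to the brain surface along d
            t_star = 1.0 / np.sqrt(sum((d[i] / spec.brain_axes[i]) ** 2
                                       for i in range(3)))
            eye_c = d * (t_star + spec.eye_radius - spec.eye_brain_overlap)
            u = pts - eye_c[:, None]
            axial = d @ u
            lat2 = np.sum(u * u, axis=0) - axial ** 2
            # carve the orbit: outside the brain, within the cylinder
            carve = ((lat2 <= spec.orbit_radius ** 2)
                     & (axial >= -(spec.eye_radius + 1.0))
                     & ~brain.ravel())
            vol.ravel()[carve] = spec.dura_intensity
            eye = np.sum(u * u, axis=0) <= spec.eye_radius ** 2
            vol.ravel()[eye] = spec.eye_intensity
            eyes.ravel()[eye] = True
            carved.ravel()[carve] = True

    dura = (_ellipsoid_mask(coords, spec.brain_axes, spec.dura_width)
            & ~brain & ~eyes)
    return vol, {"brain": brain, "dura": dura, "eyes": eyes, "carved": carved}


def generate_phantom(spec: PhantomSpec | None = None):
    """Build one phantom volume and its ground-truth brain mask.

    Returns ``(volume, truth)`` with ``volume`` uint8 and ``truth`` boolean.
    Raises when the shells do not fit inside the grid or when a width is
    non-positive (shells would overlap the brain truth).
    """
    spec = spec or PhantomSpec()
    vol, regions = _regions(spec)
    truth = regions["brain"]
    nz, ny, nx = spec.shape
    center = np.array([nz // 2, ny // 2, nx // 2], dtype=np.float64)
    idx = np.indices(spec.shape, dtype=np.float64)
    coords = tuple(idx[i] - center[i] for i in range(3))

    rng = np.random.default_rng(spec.seed)
    if spec.texture_amplitude > 0:
        # smooth low-frequency texture (simple separable cosine mix)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        tex = sum(np.cos(2 * np.pi * coords[i] / spec.shape[i] + phases[i])
                  for i in range(3))
        vol = vol + spec.texture_amplitude * tex / 3.0
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    vol = np.clip(np.round(vol), 0, 255).astype(np.uint8)
    return vol, truth


def validate_phantom(vol: np.ndarray, truth: np.ndarray,
                     spec: PhantomSpec) -> None:
    """Assert the noise left the max-tree selection well-posed: every dura
    voxel (outside the eye spheres) stays below the brain's 5th-percentile
    intensity."""
    _, regions = _regions(spec)
    dura = regions["dura"]
    brain_p5 = np.percentile(vol[truth], 5)
    dura_max = vol[dura].max() if dura.any() else 0
    if not dura_max < brain_p5:
        raise AssertionError(
            f"dura intensities reach {dura_max}, above the brain 5th "
            f"percentile {brain_p5}; selection is ill-posed at this noise sd"
        )


# --------------------------------------------------------------------------
# constructed fixtures for unit tests and toy examples
# --------------------------------------------------------------------------

def _two_peak_2d() -> np.ndarray:
    img = np.zeros((10, 10), dtype=np.uint8)
    img[2:4, 2:4] = 20   # plateau A: 4 px at 20
    img[6:8, 6:8] = 10   # plateau B: 4 px at 10
    return img


def _cone_3d() -> np.ndarray:
    n = 15
    c = n // 2
    idx = np.indices((n, n, n))
    cheb = np.max(np.abs(idx - c), axis=0)
    return np.clip(180 - 14 * cheb, 1, 255).astype(np.uint8)


def _impulse_noise() -> np.ndarray:
    vol = np.full((12, 12, 6), 100, dtype=np.uint8)
    rng = np.random.default_rng(7)
    spots = [(2, 2, 1), (2, 8, 4), (6, 5, 2), (9, 3, 4), (9, 9, 1), (5, 10, 4)]
    for i, (z, y, x) in enumerate(spots):
        vol[z, y, x] = 140 if i % 2 == 0 else 60
    return vol


def _ramp() -> np.ndarray:
    line = np.arange(0, 201, 5, dtype=np.uint8)          # 0..200 in steps of 5
    return np.broadcast_to(line, (3, 4, line.size)).copy()


def _flat() -> np.ndarray:
    return np.full((5, 6, 7), 37, dtype=np.uint8)


_FIXTURES = {
    "two_peak_2d": _two_peak_2d,
    "cone_3d": _cone_3d,
    "impulse_noise": _impulse_noise,
    "ramp": _ramp,
    "flat": _flat,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> np.ndarray:
    """Return one of the hard-coded example arrays by name."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}"
        ) from None
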