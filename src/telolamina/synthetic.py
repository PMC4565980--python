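"""Synthetic 3D-SIM-like volumes with known ground truth.

The generator emulates the structures the analysis quantifies in a single
nucleus imaged by three-channel 3D structured illumination microscopy:

* an ellipsoidal nucleus whose boundary carries a thin lamina shell
  (``lamin`` channel);
* punctate telomere foci (``trf1`` channel), a tunable fraction of which is
  placed within a proximity band of the lamina;
* a granular nucleoplasmic LAP2alpha texture (``lap2a`` channel) made of
  foci that are either associated with a telomere — offset from its center
  by a tunable distance in a random direction, in the section plane by
  default — or free background granules, whose number is scaled so the
  binarized LAP2alpha mask covers a target fraction of the nucleus section
  area.

An offset of 0 nm emulates the wild-type situation (LAP2alpha directly on
telomeres); offsets of 360-400 nm emulate the progeria-like displacement.
The image is blurred with an anisotropic Gaussian PSF and degraded with
Poisson (shot) and additive Gaussian (camera) noise.  Ground truth is
recorded before blur and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq

from .image_io import MultiChannelVolume, ValidationError

__all__ = [
    "SyntheticParams",
    "NoiseParams",
    "SyntheticGroundTruth",
    "GenerationError",
    "ellipsoid_surface_distance",
    "sample_telomere_centers",
    "generate_nucleus_volume",
    "generate_intensity_field",
]

_MAX_ATTEMPTS = 1000
# painted (pre-blur) channel amplitudes, arbitrary camera units
_AMP_LAMIN, _AMP_TRF1, _AMP_LAP2 = 80.0, 100.0, 100.0


class GenerationError(RuntimeError):
    """Raised when a placement constraint cannot be satisfied."""


@dataclass
class NoiseParams:
    """Fluorescence noise model: Poisson shot noise, then additive Gaussian.

    ``poisson_scale`` is the photon count corresponding to one intensity
    unit (0 disables shot noise); ``gaussian_sd`` is the camera read-noise
    standard deviation in intensity units (0 disables it).
    """

    poisson_scale: float = 1.0
    gaussian_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValidationError("noise parameters must be >= 0")


@dataclass
class SyntheticParams:
    """Study conditions for one synthetic nucleus.

    Defaults describe a scaled-down fibroblast nucleus at 3D-SIM sampling:
    125 nm axial pitch, 40 nm lateral pitch, ~150 nm-radius telomere foci,
    and a peripheral telomere fraction tuned so that about half of all
    telomeres fall within 250 nm of the lamina.
    """

    nucleus_radii_nm: tuple[float, float, float] = (2000.0, 3000.0, 3000.0)
    lamina_thickness_nm: float = 100.0
    lamin_interior_fraction: float = 0.25
    n_telomeres: int = 40
    lamina_fraction: float = 0.32
    placement_margin_nm: float = 0.0
    lamina_proximity_nm: float = 250.0
    lap2_offset_nm: float = 0.0
    lap2_offset_mode: str = "in_plane"
    lap2_association_fraction: float = 0.9
    lap2_background_foci: int = 0
    lap2_target_coverage: float = 0.157
    lap2_focus_radius_nm: float = 150.0
    spot_radius_nm: float = 150.0
    min_spot_separation_nm: float = 0.0
    psf_sigma_nm: tuple[float, float, float] = (125.0, 50.0, 50.0)
    noise: NoiseParams = field(default_factory=NoiseParams)
    voxel_size_nm: tuple[float, float, float] = (125.0, 40.0, 40.0)
    section_thickness_nm: float = 544.0
    margin_voxels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lamina_fraction", "lap2_association_fraction",
                     "lap2_target_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("lamina_thickness_nm", "lamina_proximity_nm",
                     "lap2_focus_radius_nm", "spot_radius_nm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.lap2_offset_nm < 0:
            raise ValidationError("lap2_offset_nm must be >= 0")
        if self.placement_margin_nm < 0:
            raise ValidationError("placement_margin_nm must be >= 0")
        if not 0.0 <= self.lamin_interior_fraction < 1.0:
            raise ValidationError("lamin_interior_fraction must be in [0, 1)")
        if self.lap2_offset_mode not in ("in_plane", "isotropic"):
            raise ValidationError(
                "lap2_offset_mode must be 'in_plane' or 'isotropic'")
        if self.n_telomeres < 1:
            raise ValidationError("n_telomeres must be >= 1")
        if self.lap2_background_foci < 0:
            raise ValidationError("lap2_background_foci must be >= 0")
        if any(r <= 0 for r in self.nucleus_radii_nm):
            raise ValidationError("nucleus radii must be > 0")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValidationError("voxel sizes must be > 0")
        if self.margin_voxels < 2:
            raise ValidationError("margin_voxels must be >= 2 so the "
                                  "ellipsoid fits with a margin")


@dataclass
class SyntheticGroundTruth:
    """True geometry recorded before blur and noise."""

    telomere_centers_nm: np.ndarray          # (n, 3) z,y,x
    telomere_lamina_distance_nm: np.ndarray  # (n,) analytic surface distance
    lap2_focus_centers_nm: np.ndarray        # (m, 3) z,y,x
    telomere_to_lap2_assignment: dict[int, int]
    true_nucleus_coverage_fraction: float
    nucleus_center_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def mean_nearest_lap2_distance_nm(self) -> float:
        """Mean distance from each telomere to its nearest LAP2alpha focus."""
        if len(self.lap2_focus_centers_nm) == 0:
            return float("nan")
        d = np.linalg.norm(
            self.telomere_centers_nm[:, None, :]
            - self.lap2_focus_centers_nm[None, :, :],
            axis=2,
        )
        return float(d.min(axis=1).mean())


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def ellipsoid_surface_distance(
    point_nm: np.ndarray, radii_nm: tuple[float, float, float]
) -> float:
    """Exact Euclidean distance from a point to an ellipsoid surface.

    The point is given relative to the ellipsoid center.  Uses the standard
    Lagrange parametrization: the closest surface point satisfies
    ``x_i = a_i^2 p_i / (t + a_i^2)`` where ``t`` is the unique root of
    ``sum(a_i^2 p_i^2 / (t + a_i^2)^2) = 1`` on ``(-min(a_i^2), inf)``.
    Falls back to the smallest semi-axis for points on the center.
    """
    p = np.asarray(point_nm, dtype=float)
    a = np.asarray(radii_nm, dtype=float)
    if np.allclose(a, a[0]):  # sphere: closed form
        return abs(a[0] - float(np.linalg.norm(p)))
    nz = np.abs(p) > 1e-12
    if not nz.any():
        return float(a.min())
    a2, p2 = a[nz] ** 2, p[nz] ** 2

    def f(t: float) -> float:
        return float(np.sum(a2 * p2 / (t + a2) ** 2) - 1.0)

    lo = -a2.min()
    # bracket: f -> +inf at lo, f < 0 for large t
    hi = float(np.sqrt(np.sum(a2 * p2)))  # f(hi) <= sum(a2 p2)/hi^2 ... expand
    while f(hi) > 0:
        hi = 2 * hi + a2.max()
    eps = 1e-9 * a2.min()
    t = brentq(f, lo + eps, hi, xtol=1e-12, rtol=1e-15, maxiter=200)
    return float(np.sqrt(np.sum(t**2 * p2 / (t + a2) ** 2)))


def _uniform_in_ellipsoid(rng: np.random.Generator, radii: np.ndarray) -> np.ndarray:
    for _ in range(_MAX_ATTEMPTS):
        p = rng.uniform(-1.0, 1.0, size=3)
        if (p**2).sum() <= 1.0:
            return p * radii
    raise GenerationError("uniform ellipsoid sampling failed")  # pragma: no cover


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _inside(point: np.ndarray, radii: np.ndarray) -> bool:
    return float(np.sum((point / radii) ** 2)) <= 1.0


def _paint_ball(
    canvas: np.ndarray,
    center_nm: np.ndarray,
    radius_nm: float,
    voxel: np.ndarray,
    origin_nm: np.ndarray,
    amplitude: float,
) -> None:
    """Set voxels within ``radius_nm`` of ``center_nm`` to ``amplitude`` (max)."""
    c_vox = (center_nm - origin_nm) / voxel
    half = np.ceil(radius_nm / voxel).astype(int) + 1
    lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
    hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, canvas.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, c_vox, voxel))
    region = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(region, np.where(d2 <= radius_nm**2, amplitude, 0.0), out=region)


def _ball_projection_pixels(
    center_nm: np.ndarray,
    radius_nm: float,
    voxel: np.ndarray,
    origin_nm: np.ndarray,
    shape: tuple[int, int, int],
    z_planes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray] | None:
    """(y, x) index arrays of the ball's projection onto the given z-planes."""
    c_vox = (center_nm - origin_nm) / voxel
    dz2 = ((z_planes - c_vox[0]) * voxel[0]) ** 2
    keep = dz2 <= radius_nm**2
    if not keep.any():
        return None
    # lateral radius of the widest in-window cross-section
    r_lat = float(np.sqrt(radius_nm**2 - dz2[keep].min()))
    half = int(np.ceil(r_lat / voxel[1])) + 1, int(np.ceil(r_lat / voxel[2])) + 1
    lo = (max(int(c_vox[1]) - half[0], 0), max(int(c_vox[2]) - half[1], 0))
    hi = (min(int(c_vox[1]) + half[0] + 1, shape[1]),
          min(int(c_vox[2]) + half[1] + 1, shape[2]))
    yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    d2 = ((yy - c_vox[1]) * voxel[1]) ** 2 + ((xx - c_vox[2]) * voxel[2]) ** 2
    sel = d2 <= r_lat**2
    return yy[sel], xx[sel]


# ---------------------------------------------------------------------------
# nucleus volume generator
# ---------------------------------------------------------------------------

def sample_telomere_centers(
    params: SyntheticParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample telomere centers (nucleus-centered frame) and their analytic
    distances to the ellipsoid surface.

    With ``lamina_fraction=0`` placement is uniform over the nucleus volume;
    a positive fraction constrains that share of telomeres to lie within
    ``lamina_proximity_nm`` of the surface by rejection sampling.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    radii = np.asarray(params.nucleus_radii_nm, dtype=float)
    n_peripheral = int(round(params.lamina_fraction * params.n_telomeres))
    centers: list[np.ndarray] = []
    distances: list[float] = []
    for i in range(params.n_telomeres):
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            p = _uniform_in_ellipsoid(rng, radii)
            d = ellipsoid_surface_distance(p, tuple(radii))
            if d < params.placement_margin_nm:
                continue
            if i < n_peripheral and d > params.lamina_proximity_nm:
                continue
            if params.min_spot_separation_nm > 0 and centers and (
                np.linalg.norm(np.array(centers) - p, axis=1).min()
                < params.min_spot_separation_nm
            ):
                continue
            placed = True
            break
        if not placed:
            parts = [f"margin >= {params.placement_margin_nm} nm"]
            if i < n_peripheral:
                parts.append(
                    f"lamina proximity <= {params.lamina_proximity_nm} nm")
            if params.min_spot_separation_nm > 0:
                parts.append(
                    f"min separation {params.min_spot_separation_nm} nm")
            constraint = ", ".join(parts)
            raise GenerationError(
                f"telomere {i}: no valid position in {_MAX_ATTEMPTS} "
                f"attempts (constraint: {constraint})"
            )
        centers.append(p)
        distances.append(d)
    return np.asarray(centers), np.asarray(distances)


def generate_nucleus_volume(
    params: SyntheticParams,
) -> tuple[MultiChannelVolume, SyntheticGroundTruth]:
    """Generate one three-channel nucleus volume plus its ground truth.

    Channels are ``lamin`` (boundary shell), ``lap2a`` (granular texture)
    and ``trf1`` (telomere foci).  Identical parameters and seed give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    radii = np.asarray(params.nucleus_radii_nm, dtype=float)
    voxel = np.asarray(params.voxel_size_nm, dtype=float)

    half_vox = np.ceil(radii / voxel).astype(int) + params.margin_voxels
    shape = tuple(2 * half_vox + 1)
    origin_nm = -half_vox * voxel  # voxel (0,0,0) center in nucleus coords

    zz, yy, xx = [
        (np.arange(n) * v + o).astype(float)
        for n, v, o in zip(shape, voxel, origin_nm)
    ]
    rho2 = (
        (zz[:, None, None] / radii[0]) ** 2
        + (yy[None, :, None] / radii[1]) ** 2
        + (xx[None, None, :] / radii[2]) ** 2
    )
    nucleus = rho2 <= 1.0

    centers, distances = sample_telomere_centers(params, rng)

    # --- LAP2alpha foci ---------------------------------------------------
    n_assoc = int(round(params.lap2_association_fraction * params.n_telomeres))
    assoc_idx = rng.choice(params.n_telomeres, size=n_assoc, replace=False)
    lap2_centers: list[np.ndarray] = []
    assignment: dict[int, int] = {}
    for ti in sorted(int(i) for i in assoc_idx):
        if params.lap2_offset_nm == 0:
            focus = centers[ti].copy()
        else:
            focus = None
            for _ in range(_MAX_ATTEMPTS):
                # in_plane: displacement in the lateral (section) plane, so
                # the offset is what the 2-D section measurement sees;
                # isotropic: uniformly random 3-D direction
                if params.lap2_offset_mode == "in_plane":
                    phi = rng.uniform(0.0, 2.0 * np.pi)
                    direction = np.array([0.0, np.sin(phi), np.cos(phi)])
                else:
                    direction = _unit_vector(rng)
                cand = centers[ti] + params.lap2_offset_nm * direction
                if _inside(cand, radii):
                    focus = cand
                    break
            if focus is None:
                raise GenerationError(
                    f"LAP2alpha focus for telomere {ti}: offset "
                    f"{params.lap2_offset_nm} nm leaves the nucleus in all "
                    f"{_MAX_ATTEMPTS} direction attempts"
                )
        assignment[ti] = len(lap2_centers)
        lap2_centers.append(focus)

    # fixed background granules
    for _ in range(params.lap2_background_foci):
        lap2_centers.append(_uniform_in_ellipsoid(rng, radii))

    # --- coverage control -------------------------------------------------
    # The coverage target refers to the *binarized* LAP2alpha mask, i.e. the
    # mask the analysis recovers (PSF blur, then a within-nucleus Otsu cut),
    # measured on the central optical section.  Extra background foci are
    # therefore calibrated against exactly that binarization: coverage is
    # near-monotone in the focus count, so the count is found by doubling
    # plus bisection on the rendered, blurred, thresholded channel.
    sigma_vox = np.asarray(params.psf_sigma_nm) / voxel
    half_w = params.section_thickness_nm / 2.0
    z_planes = np.where(np.abs(zz - 0.0) <= half_w)[0]
    nuc_proj = nucleus[z_planes].any(axis=0)
    nuc_area = int(nuc_proj.sum())

    def _render_lap2(foci: list[np.ndarray]) -> np.ndarray:
        img = np.zeros(shape, dtype=float)
        for c in foci:
            _paint_ball(img, c, params.lap2_focus_radius_nm, voxel, origin_nm,
                        _AMP_LAP2)
        return ndi.gaussian_filter(img, sigma=sigma_vox)

    def _binarized_coverage(blurred: np.ndarray) -> float:
        vals = blurred[nucleus]
        if vals.max() == vals.min():
            return 0.0
        from skimage.filters import threshold_otsu

        mask = (blurred > threshold_otsu(vals)) & nucleus
        return float((mask[z_planes].any(axis=0) & nuc_proj).sum()) / nuc_area

    extras: list[np.ndarray] = []
    cache: dict[int, tuple[np.ndarray, float]] = {}

    def _eval(k: int) -> float:
        if k not in cache:
            while len(extras) < k:
                extras.append(_uniform_in_ellipsoid(rng, radii))
            blurred = _render_lap2(lap2_centers + extras[:k])
            cache[k] = (blurred, _binarized_coverage(blurred))
        return cache[k][1]

    extra_cap = 4096
    k_hi = 0
    while _eval(k_hi) < params.lap2_target_coverage:
        if k_hi >= extra_cap:
            raise GenerationError(
                f"could not reach lap2_target_coverage="
                f"{params.lap2_target_coverage} with {extra_cap} background "
                f"foci (reached {_eval(k_hi):.3f})"
            )
        k_hi = max(1, 2 * k_hi)
    k_lo = k_hi // 2 if k_hi else 0
    while k_hi - k_lo > 1 and k_hi > 0:
        mid = (k_lo + k_hi) // 2
        if _eval(mid) < params.lap2_target_coverage:
            k_lo = mid
        else:
            k_hi = mid
    # pick the bracket endpoint closest to the target
    k_best = min(
        {k_lo, k_hi},
        key=lambda k: abs(_eval(k) - params.lap2_target_coverage),
    )
    lap2_blurred, achieved = cache[k_best]
    lap2_centers = lap2_centers + extras[:k_best]
    lap2_centers_arr = (
        np.asarray(lap2_centers) if lap2_centers else np.empty((0, 3))
    )

    # ground truth is reported in the volume's grid frame (voxel i at
    # coordinate i * voxel_size); placement above used nucleus-centered
    # coordinates, so shift by the grid position of the nucleus center
    shift = -origin_nm
    truth = SyntheticGroundTruth(
        telomere_centers_nm=centers + shift,
        telomere_lamina_distance_nm=distances,
        lap2_focus_centers_nm=(
            lap2_centers_arr + shift if len(lap2_centers_arr) else
            lap2_centers_arr
        ),
        telomere_to_lap2_assignment=assignment,
        true_nucleus_coverage_fraction=achieved,
        nucleus_center_nm=tuple(shift),
    )

    # --- render channels --------------------------------------------------
    # lamin: bright shell on the boundary plus a dim nucleoplasmic pool
    # (lamin A is not exclusively peripheral; the interior signal is also
    # what makes whole-nucleus segmentation of real stacks work)
    lamin = np.zeros(shape, dtype=float)
    lamin[nucleus] = params.lamin_interior_fraction * _AMP_LAMIN
    edt = ndi.distance_transform_edt(nucleus, sampling=voxel)
    lamin[(edt > 0) & (edt <= params.lamina_thickness_nm)] = _AMP_LAMIN

    trf1 = np.zeros(shape, dtype=float)
    for c in centers:
        _paint_ball(trf1, c, params.spot_radius_nm, voxel, origin_nm, _AMP_TRF1)

    channels = []
    for img in (lamin, None, trf1):
        blurred = (
            lap2_blurred if img is None
            else ndi.gaussian_filter(img, sigma=sigma_vox)
        )
        channels.append(_apply_noise(blurred, params.noise, rng))
    volume = MultiChannelVolume(
        np.stack(channels),
        ["lamin", "lap2a", "trf1"],
        tuple(voxel),
    )
    return volume, truth


def _apply_noise(
    img: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    if noise.poisson_scale > 0:
        img = rng.poisson(img * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        img = img + rng.normal(0.0, noise.gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# 2-D intensity field generator (per-nucleus correlation stage)
# ---------------------------------------------------------------------------

def generate_intensity_field(
    n_nuclei: int,
    target_r: float,
    noise_sd: float,
    seed: int,
    mean_intensity: float = 100.0,
    intensity_sd: float = 20.0,
    nucleus_radius_px: tuple[int, int] = (8, 14),
    canvas_px: int | None = None,
):
    """Generate a 2-D DAPI + two-stain field of non-overlapping nuclei.

    Per-nucleus mean intensities of ``stain_a`` and ``stain_b`` are drawn
    from a bivariate normal with correlation ``target_r``, emulating e.g.
    anticorrelated H3K27me3 and progerin levels across a cell population.

    Returns
    -------
    (field, truth):
        ``field`` is a 2-D :class:`MultiChannelVolume` (``nz == 1``) with
        channels ``dapi``, ``stain_a``, ``stain_b``; ``truth`` is a pandas
        DataFrame with one row per nucleus (position, radii, true means).
    """
    import pandas as pd

    if n_nuclei < 3:
        raise ValidationError("n_nuclei must be >= 3")
    if not -1.0 <= target_r <= 1.0:
        raise ValidationError("target_r must be in [-1, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    r_max = nucleus_radius_px[1]
    cell = 4 * r_max  # one nucleus per grid cell guarantees non-overlap
    n_side = int(np.ceil(np.sqrt(n_nuclei)))
    needed = n_side * cell
    if canvas_px is None:
        canvas_px = needed
    elif canvas_px < needed:
        raise GenerationError(
            f"canvas {canvas_px}px too small for {n_nuclei} non-overlapping "
            f"nuclei (needs >= {needed}px)"
        )
    n_side = canvas_px // cell

    z1 = rng.normal(size=n_nuclei)
    z2 = rng.normal(size=n_nuclei)
    a = mean_intensity + intensity_sd * z1
    b = mean_intensity + intensity_sd * (
        target_r * z1 + np.sqrt(max(0.0, 1.0 - target_r**2)) * z2
    )
    a = np.maximum(a, 0.1)
    b = np.maximum(b, 0.1)

    dapi = np.zeros((canvas_px, canvas_px))
    stain_a = np.zeros_like(dapi)
    stain_b = np.zeros_like(dapi)
    rows = []
    cells = [(i, j) for i in range(n_side) for j in range(n_side)]
    if len(cells) < n_nuclei:
        raise GenerationError("canvas too small for requested nucleus count")
    for k, (ci, cj) in enumerate(cells[:n_nuclei]):
        ry, rx = rng.integers(nucleus_radius_px[0], r_max + 1, size=2)
        jy = rng.integers(r_max + 1, cell - r_max)
        jx = rng.integers(r_max + 1, cell - r_max)
        cy, cx = ci * cell + jy, cj * cell + jx
        yy, xx = np.ogrid[-ry:ry + 1, -rx:rx + 1]
        disk = (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0
        sl = (slice(cy - ry, cy + ry + 1), slice(cx - rx, cx + rx + 1))
        dapi[sl][disk] = 200.0
        stain_a[sl][disk] = a[k]
        stain_b[sl][disk] = b[k]
        rows.append({
            "nucleus_id": k, "center_y": int(cy), "center_x": int(cx),
            "radius_y": int(ry), "radius_x": int(rx),
            "true_mean_a": float(a[k]), "true_mean_b": float(b[k]),
        })

    channels = np.stack([dapi, stain_a, stain_b])[:, None]  # (C, 1, Y, X)
    if noise_sd > 0:
        channels = np.clip(
            channels + rng.normal(0.0, noise_sd, size=channels.shape), 0.0, None
        )
    field = MultiChannelVolume(
        channels, ["dapi", "stain_a", "stain_b"], (1.0, 1.0, 1.0)
    )
    return field, pd.DataFrame(rows)
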