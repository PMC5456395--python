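"""Synthetic nucleus images with controlled sub-compartment intensities.

Builds circular-nucleus single optical sections in which stated
fractions of the total nuclear intensity are deposited into the lamina
shell and the perinucleolar shell (the same 240 nm / 3 px bands the
quantification module measures), on top of multiplicative pixel noise
and bright heterochromatic foci.  After noise and foci the region
intensities are rescaled so the deposited fractions hold exactly,
making shell-fraction recovery a closed-loop test of the ROI machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging import (
    LAMINA,
    PERINUCLEOLAR,
    NucleusImage,
    shell_roi,
)


@dataclass(frozen=True)
class NucleusSimParams:
    """Geometry and intensity model of one simulated nucleus.

    Physical units: nm.  ``lamina_fraction`` / ``perinucleolar_fraction``
    are the target shares of total nuclear intensity deposited in the
    two shells (None = uniform field).  Defaults echo a proliferating
    human fibroblast: ~7.5 µm nuclear radius, three nucleoli, and shell
    intensity shares of 9.5% (lamina) and 5.2% (perinucleolar).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 80.25
    nucleus_radius: float = 7_500.0
    nucleolus_radii: tuple[float, ...] = (1_300.0, 1_100.0, 900.0)
    n_nucleoli: int = 3
    lamina_fraction: float | None = 0.095
    perinucleolar_fraction: float | None = 0.052
    shell_depth: float = 240.0
    focus_count: int = 15
    focus_brightness: float = 2.0
    focus_radius_px: int = 2
    noise_cv: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.lamina_fraction, self.perinucleolar_fraction):
            if f is not None and not (0 <= f <= 1):
                raise ValueError("shell fractions must lie in [0, 1]")
        total = (self.lamina_fraction or 0) + (self.perinucleolar_fraction or 0)
        if total > 1:
            raise ValueError("shell fractions must sum to at most 1")
        if self.n_nucleoli < 0 or self.n_nucleoli > len(self.nucleolus_radii):
            raise ValueError("n_nucleoli must not exceed len(nucleolus_radii)")
        r_px = self.nucleus_radius / self.pixel_size
        if 2 * r_px + 4 > min(self.image_shape):
            raise ValueError("nucleus does not fit in the image")


@dataclass
class SimulatedNucleus:
    image: NucleusImage
    truth: dict = field(default_factory=dict)


def _disk(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def simulate_nucleus_image(params: NucleusSimParams) -> SimulatedNucleus:
    """Simulate one 2D nucleus section plus its ground-truth metrics."""
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    center = (shape[0] / 2, shape[1] / 2)
    r_nuc_px = params.nucleus_radius / params.pixel_size
    nucleus = _disk(shape, center, r_nuc_px)

    depth_px = int(round(params.shell_depth / params.pixel_size))
    radii = params.nucleolus_radii[: params.n_nucleoli]
    nucleolus = np.zeros(shape, dtype=bool)
    placed: list[tuple[float, float, float]] = []
    for r_nm in radii:
        r_px = r_nm / params.pixel_size
        # keep nucleoli clear of the lamina shell so the two shells stay disjoint
        max_off = r_nuc_px - r_px - 2 * depth_px - 2
        if max_off <= 0:
            raise ValueError("nucleolus does not fit inside the nucleus")
        for _ in range(200):
            ang = rng.uniform(0, 2 * np.pi)
            off = np.sqrt(rng.uniform(0, 1)) * max_off
            cy = center[0] + off * np.sin(ang)
            cx = center[1] + off * np.cos(ang)
            if all(
                np.hypot(cy - py, cx - px) > r_px + pr + 2 for py, px, pr in placed
            ):
                placed.append((cy, cx, r_px))
                nucleolus |= _disk(shape, (cy, cx), r_px)
                break
        else:
            raise ValueError("could not place disjoint nucleoli; reduce count/radii")
    if np.any(nucleolus & ~nucleus):
        raise ValueError("nucleolus extends outside the nucleus")

    base_img = NucleusImage(
        intensity=np.zeros(shape, dtype=float),
        nucleus_mask=nucleus,
        nucleolus_mask=nucleolus,
        pixel_size_xy=params.pixel_size,
    )
    lam = shell_roi(base_img, LAMINA, params.shell_depth).mask
    if params.n_nucleoli > 0:
        peri = shell_roi(base_img, PERINUCLEOLAR, params.shell_depth).mask
    else:
        peri = np.zeros(shape, dtype=bool)
    rest = nucleus & ~lam & ~peri

    intensity = np.zeros(shape, dtype=float)
    n_total = int(nucleus.sum())
    total = float(n_total)  # mean nuclear intensity 1 by construction
    f_lam = params.lamina_fraction
    f_peri = params.perinucleolar_fraction if params.n_nucleoli > 0 else 0.0
    if f_lam is None and params.perinucleolar_fraction is None:
        intensity[nucleus] = 1.0
        targets = None
    else:
        f_lam = f_lam if f_lam is not None else lam.sum() / n_total
        f_peri = f_peri if f_peri is not None else peri.sum() / n_total
        intensity[lam] = f_lam * total / max(int(lam.sum()), 1)
        intensity[peri] = f_peri * total / max(int(peri.sum()), 1)
        intensity[rest] = (1 - f_lam - f_peri) * total / max(int(rest.sum()), 1)
        targets = (float(f_lam), float(f_peri))

    if params.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
        noise = np.exp(sigma * rng.standard_normal(shape) - sigma**2 / 2)
        intensity *= noise

    focus_centers = []
    if params.focus_count > 0:
        ys, xs = np.nonzero(nucleus)
        pick = rng.choice(len(ys), size=params.focus_count, replace=False)
        for k in pick:
            focus_centers.append((int(ys[k]), int(xs[k])))
            spot = _disk(shape, (ys[k], xs[k]), params.focus_radius_px) & nucleus
            intensity[spot] *= params.focus_brightness

    if targets is not None:
        # rescale regions so the deposited shell fractions hold exactly
        for region, share in ((lam, targets[0]), (peri, targets[1]),
                              (rest, 1 - targets[0] - targets[1])):
            cur = intensity[region].sum()
            if cur > 0:
                intensity[region] *= share * total / cur

    image = NucleusImage(
        intensity=intensity,
        nucleus_mask=nucleus,
        nucleolus_mask=nucleolus,
        pixel_size_xy=params.pixel_size,
    )

    def _frac(mask: np.ndarray) -> float:
        return float(intensity[mask].sum() / intensity[nucleus].sum())

    def _cv(mask: np.ndarray) -> float:
        vals = intensity[mask]
        return float(vals.std(ddof=0) / vals.mean()) if vals.size else float("nan")

    truth = {
        "target_lamina_fraction": None if targets is None else targets[0],
        "target_perinucleolar_fraction": None if targets is None else targets[1],
        "lamina_fraction": _frac(lam),
        "perinucleolar_fraction": _frac(peri) if peri.any() else float("nan"),
        "lamina_cv": _cv(lam),
        "perinucleolar_cv": _cv(peri),
        "nucleus_cv": _cv(nucleus),
        "n_nucleoli": len(placed),
        "focus_centers": focus_centers,
        "shell_depth_px": depth_px,
    }
    return SimulatedNucleus(image=image, truth=truth)


def simulate_nucleus_stack(
    params: NucleusSimParams, n_z: int = 24, z_step: float = 500.0
) -> SimulatedNucleus:
    """3D mask stack (nucleus ellipsoid + nucleolar spheres) for
    object counting and volume measurements; intensity is uniform."""
    rng = np.random.default_rng(params.seed)
    shape = (n_z, *params.image_shape)
    zc, yc, xc = n_z / 2, shape[1] / 2, shape[2] / 2
    r_xy = params.nucleus_radius / params.pixel_size
    r_z = min(params.nucleus_radius / z_step, n_z / 2 - 1)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    nucleus = ((zz - zc) / r_z) ** 2 + ((yy - yc) / r_xy) ** 2 + (
        (xx - xc) / r_xy
    ) ** 2 <= 1

    nucleolus = np.zeros(shape, dtype=bool)
    placed = 0
    for r_nm in params.nucleolus_radii[: params.n_nucleoli]:
        r_px = r_nm / params.pixel_size
        r_vz = r_nm / z_step
        for _ in range(200):
            cy = yc + rng.uniform(-0.5, 0.5) * r_xy
            cx = xc + rng.uniform(-0.5, 0.5) * r_xy
            cz = zc + rng.uniform(-0.3, 0.3) * r_z
            cand = ((zz - cz) / r_vz) ** 2 + ((yy - cy) / r_px) ** 2 + (
                (xx - cx) / r_px
            ) ** 2 <= 1
            if cand.any() and not np.any(cand & nucleolus) and not np.any(
                cand & ~nucleus
            ):
                nucleolus |= cand
                placed += 1
                break
        else:
            raise ValueError("could not place disjoint nucleoli in the stack")

    intensity = nucleus.astype(float)
    image = NucleusImage(
        intensity=intensity,
        nucleus_mask=nucleus,
        nucleolus_mask=nucleolus,
        pixel_size_xy=params.pixel_size,
        z_step=z_step,
    )
    truth = {
        "n_nucleoli": placed,
        "nucleus_voxels": int(nucleus.sum()),
        "nucleolus_voxels": int(nucleolus.sum()),
        "voxel_dims_um": (z_step / 1000, params.pixel_size / 1000, params.pixel_size / 1000),
    }
    return SimulatedNucleus(image=image, truth=truth)
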