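"""Synthetic fluorescence scenes with exactly recorded ground truth.

Two scene flavours feed the morphometry pipeline:

* **cross-sections** — non-overlapping filled ellipses (myotube profiles)
  rendered into a myosin channel; the actin channel adds a diffuse
  background field; nuclei are small disks.  Ground truth records the
  exact rasterised area of every object.
* **culture scenes** — curved tube-like desmin+ objects of analytically
  known centerline arc length, with nuclei assigned to objects (on the
  centerline) or to the background.  Ground truth records each object's
  arc length and the nucleus-to-object assignment, from which conversion
  efficiency and fusion index follow exactly.

All randomness flows from ``params.seed``; with ``noise_sd=0`` every
rendered image is a deterministic function of the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import draw

from ..morphometry import MultiChannelImage

__all__ = ["ImageSceneParams", "gen_cross_section", "gen_culture_scene"]


def _sample(rng: np.random.Generator, dist: dict, size=None):
    """Draw from a named distribution spec, e.g. {'name': 'uniform', ...}."""
    name = dist["name"]
    if name == "constant":
        val = dist["value"]
        return val if size is None else np.full(size, val)
    if name == "uniform":
        return rng.uniform(dist["low"], dist["high"], size=size)
    if name == "normal":
        return rng.normal(dist["mean"], dist["sd"], size=size)
    if name == "lognormal":
        return rng.lognormal(dist["mean"], dist["sd"], size=size)
    if name == "poisson":
        return rng.poisson(dist["lam"], size=size)
    raise ValueError(f"unknown distribution {name!r}")


@dataclass
class ImageSceneParams:
    """Geometry, staining and noise parameters of a rendered scene.

    Lengths/radii are in pixels; ``pixel_size`` (um/px, default 0.65 —
    a typical 20x widefield scale) converts ground truth to physical
    units.  ``object_specs`` / ``tube_specs`` override random placement
    with explicit geometry (used heavily by tests).
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65
    n_objects: int = 8
    radius_distribution: dict = field(
        default_factory=lambda: {"name": "uniform", "low": 15, "high": 40})
    aspect_distribution: dict = field(
        default_factory=lambda: {"name": "uniform", "low": 0.6, "high": 1.0})
    length_distribution: dict = field(
        default_factory=lambda: {"name": "uniform", "low": 250, "high": 550})
    tube_width_distribution: dict = field(
        default_factory=lambda: {"name": "uniform", "low": 8, "high": 14})
    nuclei_per_object_distribution: dict = field(
        default_factory=lambda: {"name": "poisson", "lam": 3.0})
    n_background_nuclei: int = 20
    nucleus_radius_px: int = 4
    channel_gains: dict = field(default_factory=lambda: {
        "myosin": 200.0, "actin": 160.0, "nuclei": 220.0,
        "desmin": 200.0, "mhc": 160.0})
    background_level: float = 8.0
    noise_sd: float = 0.0
    seed: int = 0
    min_gap_px: int = 3
    max_place_tries: int = 300
    object_specs: list[dict] | None = None   # cross-section geometry override
    tube_specs: list[dict] | None = None     # culture geometry override

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")


def _finalise(channels: dict[str, np.ndarray], params: ImageSceneParams,
              rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for name, img in channels.items():
        img = img + params.background_level
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        out[name] = np.clip(img, 0.0, None)
    return out


def _too_dense(n_placed: int, wanted: int, shape) -> ValueError:
    return ValueError(
        f"could only place {n_placed}/{wanted} non-overlapping objects in a "
        f"{shape[0]}x{shape[1]} frame; reduce n_objects or object size "
        f"(density limit reached)")


# ----------------------------------------------------------------------
def gen_cross_section(params: ImageSceneParams) -> tuple[MultiChannelImage, dict]:
    """Render a transverse-section scene; return image + exact ground truth.

    Ground truth: per-object rasterised area (um^2) and equivalent-circle
    diameter (um), total area, effective CSA (mm^2) and the nucleus
    positions/assignment.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_size
    occupancy = np.zeros(shape, dtype=bool)

    specs = params.object_specs
    object_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    if specs is not None:
        for s in specs:
            r0, c0 = s["center"]
            if "radius_px" in s:
                a = b = float(s["radius_px"])
                theta = 0.0
            else:
                a, b = s["axes"]
                theta = s.get("orientation", 0.0)
            rr, cc = draw.ellipse(r0, c0, a, b, shape=shape, rotation=theta)
            object_pixels.append((rr, cc))
            occupancy[rr, cc] = True
    else:
        tries = 0
        while len(object_pixels) < params.n_objects:
            tries += 1
            if tries > params.max_place_tries * max(1, params.n_objects):
                raise _too_dense(len(object_pixels), params.n_objects, shape)
            a = float(_sample(rng, params.radius_distribution))
            b = a * float(_sample(rng, params.aspect_distribution))
            theta = rng.uniform(0, math.pi)
            margin = a + params.min_gap_px + 1
            if 2 * margin >= min(shape):
                raise _too_dense(len(object_pixels), params.n_objects, shape)
            r0 = rng.uniform(margin, shape[0] - margin)
            c0 = rng.uniform(margin, shape[1] - margin)
            rr, cc = draw.ellipse(r0, c0, a, b, shape=shape, rotation=theta)
            cand = np.zeros(shape, dtype=bool)
            cand[rr, cc] = True
            grown = ndi.binary_dilation(cand, iterations=params.min_gap_px)
            if (grown & occupancy).any():
                continue
            object_pixels.append((rr, cc))
            occupancy |= cand

    myosin = np.zeros(shape)
    actin = np.zeros(shape)
    nuclei_ch = np.zeros(shape)
    areas_px = []
    for rr, cc in object_pixels:
        gain = params.channel_gains["myosin"] * rng.uniform(0.85, 1.15)
        myosin[rr, cc] += gain
        actin[rr, cc] += params.channel_gains["actin"] * rng.uniform(0.85, 1.15)
        areas_px.append(rr.size)

    # diffuse non-myotube cellularity in the actin channel
    blur = ndi.gaussian_filter(rng.random(shape), 12.0)
    blur = (blur - blur.min()) / max(float(np.ptp(blur)), 1e-12)
    actin += 0.15 * params.channel_gains["actin"] * blur

    # nuclei: inside objects plus scattered background nuclei
    nuc_pos: list[tuple[float, float]] = []
    nuc_assign: list[int] = []
    for i, (rr, cc) in enumerate(object_pixels):
        k = int(_sample(rng, params.nuclei_per_object_distribution))
        for _ in range(k):
            j = rng.integers(rr.size)
            nuc_pos.append((float(rr[j]), float(cc[j])))
            nuc_assign.append(i)
    bg_free = ~ndi.binary_dilation(occupancy,
                                   iterations=params.nucleus_radius_px + 2)
    free_idx = np.argwhere(bg_free)
    if free_idx.size:
        pick = rng.choice(free_idx.shape[0], size=min(params.n_background_nuclei,
                                                      free_idx.shape[0]),
                          replace=False)
        for p in np.atleast_1d(pick):
            r, c = free_idx[p]
            nuc_pos.append((float(r), float(c)))
            nuc_assign.append(-1)
    for r, c in nuc_pos:
        rr, cc = draw.disk((r, c), params.nucleus_radius_px, shape=shape)
        nuclei_ch[rr, cc] = params.channel_gains["nuclei"]

    channels = _finalise({"myosin": myosin, "actin": actin,
                          "nuclei": nuclei_ch}, params, rng)
    px2 = params.pixel_size ** 2
    areas_um2 = np.asarray(areas_px, dtype=float) * px2
    gt = {
        "n_objects": len(object_pixels),
        "areas_um2": areas_um2.tolist(),
        "equivalent_diameters_um": (
            2.0 * np.sqrt(np.asarray(areas_px) / math.pi) * params.pixel_size
        ).tolist() if areas_px else [],
        "total_area_um2": float(areas_um2.sum()),
        "csa_mm2": float(areas_um2.sum()) / 1e6,
        "nuclei_centroids": [list(p) for p in nuc_pos],
        "nuclei_assignment": nuc_assign,
    }
    img = MultiChannelImage(channels=channels, pixel_size=params.pixel_size,
                            metadata={"scene": "cross_section",
                                      "seed": params.seed})
    return img, gt


# ----------------------------------------------------------------------
def _centerline(spec: dict, n_steps_per_px: float = 2.0) -> tuple[np.ndarray, float]:
    """Centerline points (row, col) and the analytic arc length in px."""
    kind = spec.get("kind", "straight")
    if kind == "straight":
        r0, c0 = spec["start"]
        ang = math.radians(spec.get("angle_deg", 0.0))
        length = float(spec["length_px"])
        ts = np.linspace(0.0, length, max(2, int(length * n_steps_per_px)))
        pts = np.stack([r0 + ts * math.sin(ang), c0 + ts * math.cos(ang)], axis=1)
        return pts, length
    if kind == "arc":
        rc, cc_ = spec["center"]
        radius = float(spec["radius_px"])
        th0 = math.radians(spec["theta0_deg"])
        th1 = math.radians(spec["theta1_deg"])
        length = abs(th1 - th0) * radius
        ts = np.linspace(th0, th1, max(2, int(length * n_steps_per_px)))
        pts = np.stack([rc + radius * np.sin(ts), cc_ + radius * np.cos(ts)], axis=1)
        return pts, length
    raise ValueError(f"unknown tube kind {kind!r}")


def _random_tube_spec(rng: np.random.Generator, params: ImageSceneParams,
                      shape: tuple[int, int]) -> dict | None:
    """Propose a random tube; None when it cannot fit (caller retries)."""
    length = float(_sample(rng, params.length_distribution))
    width = float(_sample(rng, params.tube_width_distribution))
    if rng.random() < 0.5:
        margin = width / 2 + params.min_gap_px + 2
        ang = rng.uniform(0, 360.0)
        a = math.radians(ang)
        dr, dc = length * math.sin(a), length * math.cos(a)
        r_lo, r_hi = max(margin, margin - dr), min(shape[0] - margin,
                                                   shape[0] - margin - dr)
        c_lo, c_hi = max(margin, margin - dc), min(shape[1] - margin,
                                                   shape[1] - margin - dc)
        if r_lo >= r_hi or c_lo >= c_hi:
            return None
        return {"kind": "straight",
                "start": (rng.uniform(r_lo, r_hi), rng.uniform(c_lo, c_hi)),
                "angle_deg": ang, "length_px": length, "width_px": width}
    radius = rng.uniform(length / (0.9 * math.pi), length / 0.8)
    span = math.degrees(length / radius)
    th0 = rng.uniform(0, 360.0)
    margin = radius + width / 2 + params.min_gap_px + 2
    if 2 * margin >= min(shape):
        # arc bounding circle larger than the frame; centre it and rely on
        # the caller's clipped-centerline rejection
        rc, cc_ = shape[0] / 2, shape[1] / 2
    else:
        rc = rng.uniform(margin, shape[0] - margin)
        cc_ = rng.uniform(margin, shape[1] - margin)
    return {"kind": "arc", "center": (rc, cc_), "radius_px": radius,
            "theta0_deg": th0, "theta1_deg": th0 + span, "width_px": width}


def _render_tube(spec: dict, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, float]:
    """Rasterise a tube; returns (mask, centerline points, arc length px)."""
    pts, length = _centerline(spec)
    width = float(spec["width_px"])
    mask = np.zeros(shape, dtype=bool)
    rad = width / 2.0
    for r, c in pts:
        rr, cc = draw.disk((r, c), rad, shape=shape)
        mask[rr, cc] = True
    return mask, pts, length


def gen_culture_scene(params: ImageSceneParams) -> tuple[MultiChannelImage, dict]:
    """Render a 2D culture scene; return image + exact ground truth.

    Ground truth: per-object arc length (um), nucleus counts and the full
    nucleus-to-object assignment, plus the implied conversion efficiency
    and fusion index.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_size

    specs = list(params.tube_specs) if params.tube_specs is not None else None
    occupancy = np.zeros(shape, dtype=bool)
    tubes: list[tuple[np.ndarray, np.ndarray, float]] = []
    if specs is not None:
        for s in specs:
            mask, pts, length = _render_tube(s, shape)
            tubes.append((mask, pts, length))
            occupancy |= mask
    else:
        tries = 0
        while len(tubes) < params.n_objects:
            tries += 1
            if tries > params.max_place_tries * max(1, params.n_objects):
                raise _too_dense(len(tubes), params.n_objects, shape)
            spec = _random_tube_spec(rng, params, shape)
            if spec is None:
                continue
            mask, pts, length = _render_tube(spec, shape)
            # reject clipped or touching tubes so ground truth stays exact
            if mask.sum() == 0:
                continue
            if (pts[:, 0].min() < 1 or pts[:, 1].min() < 1
                    or pts[:, 0].max() > shape[0] - 2
                    or pts[:, 1].max() > shape[1] - 2):
                continue
            grown = ndi.binary_dilation(mask, iterations=params.min_gap_px)
            if (grown & occupancy).any():
                continue
            tubes.append((mask, pts, length))
            occupancy |= mask

    desmin = np.zeros(shape)
    mhc = np.zeros(shape)
    nuclei_ch = np.zeros(shape)
    for mask, _, _ in tubes:
        desmin[mask] = params.channel_gains["desmin"] * rng.uniform(0.85, 1.15)
        mhc[mask] = params.channel_gains["mhc"] * rng.uniform(0.85, 1.15)

    nuc_pos: list[tuple[float, float]] = []
    nuc_assign: list[int] = []
    for i, (mask, pts, _) in enumerate(tubes):
        spec_n = (params.tube_specs[i].get("n_nuclei")
                  if params.tube_specs is not None else None)
        k = int(spec_n) if spec_n is not None else int(
            _sample(rng, params.nuclei_per_object_distribution))
        if k <= 0:
            continue
        # spread nuclei along the centerline, keeping them inside the mask
        sel = np.linspace(0.15, 0.85, k) * (pts.shape[0] - 1)
        for j in np.round(sel).astype(int):
            nuc_pos.append((float(pts[j, 0]), float(pts[j, 1])))
            nuc_assign.append(i)
    bg_free = ~ndi.binary_dilation(occupancy,
                                   iterations=params.nucleus_radius_px + 2)
    bg_free[:params.nucleus_radius_px + 1, :] = False
    bg_free[-(params.nucleus_radius_px + 1):, :] = False
    bg_free[:, :params.nucleus_radius_px + 1] = False
    bg_free[:, -(params.nucleus_radius_px + 1):] = False
    free_idx = np.argwhere(bg_free)
    if free_idx.size and params.n_background_nuclei > 0:
        pick = rng.choice(free_idx.shape[0],
                          size=min(params.n_background_nuclei, free_idx.shape[0]),
                          replace=False)
        for p in np.atleast_1d(pick):
            r, c = free_idx[p]
            nuc_pos.append((float(r), float(c)))
            nuc_assign.append(-1)
    for r, c in nuc_pos:
        rr, cc = draw.disk((r, c), params.nucleus_radius_px, shape=shape)
        nuclei_ch[rr, cc] = params.channel_gains["nuclei"]

    channels = _finalise({"desmin": desmin, "mhc": mhc, "nuclei": nuclei_ch},
                         params, rng)
    counts = np.bincount([a for a in nuc_assign if a >= 0],
                         minlength=len(tubes)) if tubes else np.empty(0, int)
    total_nuclei = len(nuc_pos)
    assigned = sum(1 for a in nuc_assign if a >= 0)
    fused = sum(1 for a in nuc_assign if a >= 0 and counts[a] >= 2)
    gt = {
        "n_objects": len(tubes),
        "lengths_um": [length * params.pixel_size for _, _, length in tubes],
        "widths_um": [(params.tube_specs[i]["width_px"] * params.pixel_size)
                      for i in range(len(tubes))] if params.tube_specs is not None else None,
        "nuclei_centroids": [list(p) for p in nuc_pos],
        "nuclei_assignment": nuc_assign,
        "nuclei_per_object": counts.tolist(),
        "total_nuclei": total_nuclei,
        "conversion_efficiency": assigned / total_nuclei if total_nuclei else 0.0,
        "fusion_index": fused / total_nuclei if total_nuclei else 0.0,
        "desmin_area_um2": float(occupancy.sum()) * params.pixel_size ** 2,
        "desmin_area_fraction": float(occupancy.mean()),
    }
    img = MultiChannelImage(channels=channels, pixel_size=params.pixel_size,
                            metadata={"scene": "culture", "seed": params.seed})
    return img, gt
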