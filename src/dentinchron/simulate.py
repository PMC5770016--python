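"""Synthetic dentin: ground-truth spacing tables and micrograph-like images.

The simulator emulates what stained beluga dentin sections look like
along the growth direction: dark daily incremental lines ~1.3–2.3 μm
apart, grouped into GLGs a few hundred μm thick with a GLG-scale
brightness modulation, lines warped into arcs around calcospheres
(unfused spherical mineralization centres), faint tubule streaks along
the growth axis, patchy readability, and additive sensor noise.

Daily spacings are drawn from a lognormal (positive support, mild right
skew); each GLG's thickness is *exactly* the sum of its daily spacings,
so recovery tests have an exact ground truth. Readability masking drops
contiguous blocks of days rather than independent days, mirroring how
legibility comes and goes in patches across a real section.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .model import (
    GLGRecord,
    ImageWithScale,
    SpacingMeasurement,
    ValidationError,
)

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "simulate_spacing_table",
    "simulate_micrograph",
    "simulate_focus_stack",
    "render_profile",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic-dentin generator.

    Defaults match the measured beluga material: 7 GLGs of 365 daily
    lines at mean spacing 1.65 μm, roughly a third of each GLG readable,
    imaged at 0.1 μm/px so one daily period spans ~16 px.
    """

    n_glgs: int = 7
    days_per_glg: int = 365
    mean_spacing_um: float = 1.65
    cv: float = 0.2
    readable_fraction: float = 0.35
    seed: int = 0
    um_per_px: float = 0.1
    line_width_um: float = 0.4
    line_depth: float = 0.25
    glg_modulation_depth: float = 0.15
    calcosphere_density: float = 0.3  # spheres per 1000 μm²
    calcosphere_radius_um: tuple[float, float] = (2.0, 6.0)
    tubule_density: float = 2.0  # streaks per 100 μm transverse
    noise_sd: float = 0.05
    field_height_um: float = 50.0
    margin_um: float = 10.0
    readability_range: tuple[float, float] = (0.4, 1.0)

    def __post_init__(self) -> None:
        if self.n_glgs < 1 or self.days_per_glg < 2:
            raise ValidationError("need n_glgs >= 1 and days_per_glg >= 2")
        if not (self.mean_spacing_um > 0):
            raise ValidationError("mean_spacing_um must be > 0")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if not (0 < self.readable_fraction <= 1):
            raise ValidationError("readable_fraction must be in (0, 1]")
        if not (self.um_per_px > 0 and self.line_width_um > 0):
            raise ValidationError("um_per_px and line_width_um must be > 0")
        if not (0 <= self.line_depth <= 1 and 0 <= self.glg_modulation_depth <= 1):
            raise ValidationError("line_depth and glg_modulation_depth must be in [0, 1]")
        if self.calcosphere_density < 0 or self.tubule_density < 0 or self.noise_sd < 0:
            raise ValidationError("densities and noise_sd must be >= 0")
        rmin, rmax = self.calcosphere_radius_um
        if not (0 < rmin <= rmax):
            raise ValidationError("calcosphere_radius_um must satisfy 0 < min <= max")
        if not (self.field_height_um > 0 and self.margin_um >= 0):
            raise ValidationError("field_height_um must be > 0 and margin_um >= 0")


@dataclass
class SyntheticTruth:
    """Everything the simulator knows: per-GLG line positions (global μm
    from the start of the first GLG), GLG boundaries, calcosphere
    geometry, and the true mean spacing and days per GLG."""

    line_positions_um: list[np.ndarray]
    glg_boundaries_um: np.ndarray
    calcospheres: np.ndarray  # (k, 3): x_um, y_um, radius_um
    mean_spacing_true_um: float
    days_true: int
    seed: int

    @property
    def glg_thicknesses_um(self) -> np.ndarray:
        return np.diff(self.glg_boundaries_um)

    @property
    def all_line_positions_um(self) -> np.ndarray:
        if not self.line_positions_um:
            return np.empty(0)
        return np.concatenate(self.line_positions_um)


def _glg_labels(n: int) -> list[str]:
    letters = string.ascii_lowercase
    out = []
    for i in range(n):
        lab = ""
        j = i
        while True:
            lab = letters[j % 26] + lab
            j = j // 26 - 1
            if j < 0:
                break
        out.append(lab)
    return out


def _draw_spacings(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _readable_mask(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Contiguous-block readability mask keeping ≈ frac of n days."""
    target = int(round(n * frac))
    if target >= n:
        return np.ones(n, dtype=bool)
    if target < 2:
        raise ValidationError(
            f"readable_fraction {frac:.3f} keeps {target} < 2 spacings per GLG"
        )
    k = int(rng.integers(2, 6))
    k = min(k, target)
    blocks = rng.multinomial(target - k, np.full(k, 1.0 / k)) + 1
    gaps = rng.multinomial(n - target, np.full(k + 1, 1.0 / (k + 1)))
    mask = np.zeros(n, dtype=bool)
    pos = 0
    for b, g in zip(blocks, gaps[:-1]):
        pos += int(g)
        mask[pos : pos + int(b)] = True
        pos += int(b)
    return mask


def simulate_spacing_table(
    params: SimParams,
) -> tuple[list[GLGRecord], list[SpacingMeasurement], SyntheticTruth]:
    """Simulate daily deposition as a measurement table with known truth.

    Per GLG: ``days_per_glg`` lognormal daily spacings (thickness is
    their exact sum), a contiguous-block readability mask retaining
    about ``readable_fraction`` of days (with a small per-GLG wobble),
    and only readable spacings emitted as measurements at their true
    positions.
    """
    rng = np.random.default_rng(params.seed)
    labels = _glg_labels(params.n_glgs)
    specimen = f"SIM{params.seed}"
    records: list[GLGRecord] = []
    measurements: list[SpacingMeasurement] = []
    line_positions: list[np.ndarray] = []
    boundaries = [0.0]
    all_spacings: list[np.ndarray] = []
    for g in range(params.n_glgs):
        spacings = _draw_spacings(rng, params.days_per_glg, params.mean_spacing_um, params.cv)
        thickness = float(spacings.sum())
        ends = np.cumsum(spacings)
        centers_local = ends - spacings / 2.0
        frac = float(np.clip(params.readable_fraction + rng.uniform(-0.03, 0.03), 0.01, 1.0))
        if params.readable_fraction >= 1.0:
            frac = 1.0
        mask = _readable_mask(rng, params.days_per_glg, frac)
        key = (specimen, labels[g])
        records.append(
            GLGRecord(specimen_id=specimen, glg_label=labels[g], thickness_um=thickness)
        )
        for p, s in zip(centers_local[mask], spacings[mask]):
            measurements.append(
                SpacingMeasurement(glg_ref=key, position_um=float(p), spacing_um=float(s))
            )
        line_positions.append(boundaries[-1] + centers_local)
        boundaries.append(boundaries[-1] + thickness)
        all_spacings.append(spacings)
    truth = SyntheticTruth(
        line_positions_um=line_positions,
        glg_boundaries_um=np.asarray(boundaries),
        calcospheres=np.empty((0, 3)),
        mean_spacing_true_um=float(np.concatenate(all_spacings).mean()),
        days_true=params.days_per_glg,
        seed=params.seed,
    )
    return records, measurements, truth


def _deposition_field(
    x_um: np.ndarray, y_um: np.ndarray, spheres: np.ndarray
) -> np.ndarray:
    """Deposition coordinate u(x, y): distance the front has travelled.

    The planar front contributes u = x; each calcosphere nucleus at
    (xc, yc) with radius r contributes ``xc − r + ‖p − c‖`` (a spherical
    wavefront seeded slightly ahead of the plane). The field is the
    minimum over all sources — a 1-Lipschitz envelope whose iso-lines
    are the incremental lines: planar far from spheres, arcuate around
    them, and never crossing.
    """
    u = np.broadcast_to(x_um, (y_um.size, x_um.size)).astype(np.float32).copy()
    for xc, yc, r in spheres:
        cand = (xc - r) + np.hypot(x_um[None, :] - xc, y_um[:, None] - yc)
        np.minimum(u, cand.astype(np.float32), out=u)
    return u


def _nearest_line_distance(u: np.ndarray, centers: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(centers, u.ravel())
    left = np.clip(idx - 1, 0, centers.size - 1)
    right = np.clip(idx, 0, centers.size - 1)
    d = np.minimum(
        np.abs(u.ravel() - centers[left]), np.abs(centers[right] - u.ravel())
    )
    return d.reshape(u.shape)


def simulate_micrograph(params: SimParams) -> tuple[ImageWithScale, SyntheticTruth]:
    """Render a stained-section-like grayscale image with known truth.

    The growth direction is +x (columns); GLG 0 starts ``margin_um``
    from the left edge. Intensity = bright matrix − Gaussian dips at
    each daily line (amplitude scaled by a smooth readability field) −
    GLG-scale darkening − tubule streaks along x + Gaussian noise.
    """
    rng = np.random.default_rng(params.seed)
    # same draw order as simulate_spacing_table for the spacing part
    labels = _glg_labels(params.n_glgs)
    line_positions: list[np.ndarray] = []
    boundaries = [0.0]
    all_spacings = []
    for g in range(params.n_glgs):
        spacings = _draw_spacings(rng, params.days_per_glg, params.mean_spacing_um, params.cv)
        ends = np.cumsum(spacings)
        line_positions.append(boundaries[-1] + ends - spacings / 2.0)
        boundaries.append(boundaries[-1] + float(spacings.sum()))
        all_spacings.append(spacings)
    boundaries = np.asarray(boundaries)
    total_um = float(boundaries[-1])
    centers = np.concatenate(line_positions)

    width_um = total_um + 2 * params.margin_um
    W = int(round(width_um / params.um_per_px))
    H = int(round(params.field_height_um / params.um_per_px))
    if W < 4 or H < 4:
        raise ValidationError("field too small to hold one GLG at this scale")
    x_um = np.arange(W, dtype=np.float64) * params.um_per_px - params.margin_um
    y_um = np.arange(H, dtype=np.float64) * params.um_per_px

    area_um2 = width_um * params.field_height_um
    n_sph = int(rng.poisson(params.calcosphere_density * area_um2 / 1000.0))
    if n_sph > 0:
        xc = rng.uniform(x_um[0], x_um[-1], n_sph)
        yc = rng.uniform(0.0, params.field_height_um, n_sph)
        rr = rng.uniform(*params.calcosphere_radius_um, n_sph)
        spheres = np.column_stack([xc, yc, rr])
    else:
        spheres = np.empty((0, 3))

    # smooth readability field on a coarse (~50 μm) grid
    gw = max(2, int(np.ceil(width_um / 50.0)) + 1)
    gh = max(2, int(np.ceil(params.field_height_um / 50.0)) + 1)
    lo, hi = params.readability_range
    grid = rng.uniform(lo, hi, size=(gh, gw))
    readability = ndimage.zoom(grid, (H / gh, W / gw), order=1, mode="nearest")
    readability = readability[:H, :W]

    # tubule streaks: dark lines running along the growth direction
    n_tub = int(round(params.tubule_density * params.field_height_um / 100.0))
    tubule_col = np.zeros(H)
    if n_tub > 0:
        ty = rng.uniform(0.0, params.field_height_um, n_tub)
        tsig = 0.3  # μm
        for t in ty:
            tubule_col += 0.06 * np.exp(-0.5 * ((y_um - t) / tsig) ** 2)

    sigma_line = params.line_width_um / 2.355  # FWHM -> sd
    img = np.empty((H, W), dtype=np.float32)
    block = max(1, int(2e6 // W))
    for r0 in range(0, H, block):
        r1 = min(H, r0 + block)
        u = _deposition_field(x_um, y_um[r0:r1], spheres)
        d = _nearest_line_distance(u, centers)
        line_term = (
            params.line_depth
            * readability[r0:r1]
            * np.exp(-0.5 * (d / sigma_line) ** 2)
        )
        g_idx = np.clip(np.searchsorted(boundaries, u.ravel(), side="right") - 1, 0, len(boundaries) - 2)
        t_g = np.diff(boundaries)[g_idx]
        frac = np.clip((u.ravel() - boundaries[g_idx]) / t_g, 0.0, 1.0).reshape(u.shape)
        glg_term = params.glg_modulation_depth * 0.5 * (1.0 - np.cos(2 * np.pi * frac))
        img[r0:r1] = 1.0 - line_term - glg_term - tubule_col[r0:r1, None]
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape).astype(np.float32)

    truth = SyntheticTruth(
        line_positions_um=line_positions,
        glg_boundaries_um=boundaries,
        calcospheres=spheres,
        mean_spacing_true_um=float(np.concatenate(all_spacings).mean()),
        days_true=params.days_per_glg,
        seed=params.seed,
    )
    return ImageWithScale(pixels=img, um_per_px=params.um_per_px), truth


def simulate_focus_stack(
    params: SimParams, n_planes: int, blur_px_per_plane: float = 2.5
) -> ImageWithScale:
    """Turn the simulated micrograph into an out-of-focus z-stack.

    A smooth depth map assigns each region a focal plane; plane k is the
    micrograph blurred with sigma ``blur_px_per_plane * |depth − k|``
    (approximated by interpolating between pre-blurred levels), so each
    region is sharp in exactly one plane. ``n_planes == 1`` returns the
    micrograph itself as a single-plane stack.
    """
    if n_planes < 1:
        raise ValidationError("n_planes must be >= 1")
    base_img, _ = simulate_micrograph(params)
    base = np.asarray(base_img.pixels, dtype=np.float32)
    if n_planes == 1 or blur_px_per_plane == 0:
        stack = np.repeat(base[None], n_planes, axis=0)
        return ImageWithScale(pixels=stack, um_per_px=params.um_per_px)
    rng = np.random.default_rng(params.seed + 7_654_321)
    H, W = base.shape
    gw = max(2, W // 400 + 2)
    gh = max(2, H // 400 + 2)
    depth_grid = rng.uniform(0, n_planes - 1, size=(gh, gw))
    depth = ndimage.zoom(depth_grid, (H / gh, W / gw), order=1, mode="nearest")[:H, :W]
    sigma_max = 8.0
    levels = np.arange(0, int(np.ceil(sigma_max)) + 1)
    blurred = [base] + [ndimage.gaussian_filter(base, s) for s in levels[1:]]
    stack = np.empty((n_planes, H, W), dtype=np.float32)
    for k in range(n_planes):
        sig = np.minimum(blur_px_per_plane * np.abs(depth - k), sigma_max)
        lo = np.floor(sig).astype(int)
        w = (sig - lo).astype(np.float32)
        hi = np.minimum(lo + 1, len(levels) - 1)
        plane = np.empty_like(base)
        for lev in np.unique(lo):
            m = lo == lev
            plane[m] = (1 - w[m]) * blurred[lev][m] + w[m] * blurred[min(lev + 1, len(levels) - 1)][m]
        stack[k] = plane
    return ImageWithScale(pixels=stack, um_per_px=params.um_per_px)


def render_profile(
    line_positions_um: np.ndarray,
    length_um: float,
    step_um: float = 0.1,
    line_width_um: float = 0.4,
    line_depth: float = 0.25,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """1-D analogue of the micrograph: Gaussian dips at given positions.

    Handy for profile-level tests and oracle checks without rendering a
    full image.
    """
    from .model import Profile

    s = np.arange(0.0, length_um + step_um / 2, step_um)
    centers = np.sort(np.asarray(line_positions_um, dtype=float))
    if centers.size:
        idx = np.searchsorted(centers, s)
        left = np.clip(idx - 1, 0, centers.size - 1)
        right = np.clip(idx, 0, centers.size - 1)
        d = np.minimum(np.abs(s - centers[left]), np.abs(centers[right] - s))
        y = 1.0 - line_depth * np.exp(-0.5 * (d / (line_width_um / 2.355)) ** 2)
    else:
        y = np.ones_like(s)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + rng.normal(0, noise_sd, size=s.size)
    return Profile(s_um=s, intensity=y)


def write_truth(truth: SyntheticTruth, params: SimParams, path) -> Path:
    """Persist ground truth and parameters as structured JSON text."""
    path = Path(path)
    payload = {
        "params": dataclasses.asdict(params),
        "seed": truth.seed,
        "days_true": truth.days_true,
        "mean_spacing_true_um": truth.mean_spacing_true_um,
        "glg_boundaries_um": truth.glg_boundaries_um.tolist(),
        "line_positions_um": [a.tolist() for a in truth.line_positions_um],
        "calcospheres": truth.calcospheres.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth(path) -> tuple[SyntheticTruth, SimParams]:
    payload = json.loads(Path(path).read_text())
    raw = dict(payload["params"])
    for key in ("calcosphere_radius_um", "readability_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    params = SimParams(**raw)
    truth = SyntheticTruth(
        line_positions_um=[np.asarray(a) for a in payload["line_positions_um"]],
        glg_boundaries_um=np.asarray(payload["glg_boundaries_um"]),
        calcospheres=np.asarray(payload["calcospheres"]).reshape(-1, 3),
        mean_spacing_true_um=float(payload["mean_spacing_true_um"]),
        days_true=int(payload["days_true"]),
        seed=int(payload["seed"]),
    )
    return truth, params
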