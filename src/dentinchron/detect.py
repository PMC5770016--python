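"""Extract daily incremental-line spacings from micrographs.

Stages: focus-project a z-stack, sample an intensity profile along a
tubule-direction polyline, remove the GLG-scale baseline, pick dark-line
centres as prominent local minima with sub-sample parabolic refinement,
and difference consecutive centres into spacings. A periodogram period
estimate serves as an independent cross-check of the mean spacing.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft
from scipy import ndimage, signal

from .model import (
    DetectionParams,
    GrowthPath,
    ImageWithScale,
    LineCenters,
    Profile,
    SpacingMeasurement,
    ValidationError,
)

__all__ = [
    "focus_project",
    "extract_profile",
    "detrend",
    "detect_line_centers",
    "spacings_from_centers",
    "measure_glg_thickness",
    "estimate_period_spectral",
]


def focus_project(stack: ImageWithScale, window_px: int = 9) -> ImageWithScale:
    """Merge a z-stack into one composite keeping locally sharpest planes.

    Each output pixel is copied from the plane that maximizes local
    intensity variance in a ``window_px`` neighbourhood — a simple focus
    measure that mimics extended-depth-of-field compositing.
    """
    px = np.asarray(stack.pixels, dtype=float)
    if px.ndim == 2:
        return ImageWithScale(pixels=px.copy(), um_per_px=stack.um_per_px)
    if px.shape[0] == 1:
        return ImageWithScale(pixels=px[0].copy(), um_per_px=stack.um_per_px)
    sharp = np.empty_like(px)
    for k in range(px.shape[0]):
        m = ndimage.uniform_filter(px[k], size=window_px)
        m2 = ndimage.uniform_filter(px[k] ** 2, size=window_px)
        sharp[k] = np.maximum(m2 - m**2, 0.0)
    best = np.argmax(sharp, axis=0)
    out = np.take_along_axis(px, best[None], axis=0)[0]
    return ImageWithScale(pixels=out, um_per_px=stack.um_per_px)


def extract_profile(
    image: ImageWithScale,
    path: GrowthPath,
    step_um: float | None = None,
    normal_window_px: int = 1,
) -> Profile:
    """Sample intensity along a polyline, averaged across the path normal.

    The profile is parameterized by arc length (μm, starting at 0) and
    sampled every ``step_um`` (default: one pixel) by bilinear
    interpolation; at each sample the intensity is averaged over
    ``normal_window_px`` points spaced one pixel apart perpendicular to
    the local path direction. The path (and its normal window) must stay
    inside the image.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.ndim != 2:
        raise ValidationError("extract_profile needs a 2-D image (focus-project stacks first)")
    h, w = px.shape
    v = path.vertices
    inside = (v[:, 0] >= 0) & (v[:, 0] <= w - 1) & (v[:, 1] >= 0) & (v[:, 1] <= h - 1)
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise ValidationError(
            f"path vertex {bad} at ({v[bad, 0]:.1f}, {v[bad, 1]:.1f}) is outside "
            f"the {w}x{h} image"
        )
    if step_um is None:
        step_um = image.um_per_px
    if not (step_um > 0):
        raise ValidationError("step_um must be > 0")
    normal_window_px = int(normal_window_px)
    if normal_window_px < 1:
        raise ValidationError("normal_window_px must be >= 1")

    seg = np.diff(v, axis=0)
    seg_len_px = np.hypot(seg[:, 0], seg[:, 1])
    cum_px = np.concatenate([[0.0], np.cumsum(seg_len_px)])
    total_um = cum_px[-1] * image.um_per_px

    s = np.arange(0.0, total_um, step_um)
    if total_um - s[-1] > 1e-9:
        s = np.append(s, total_um)
    s_px = s / image.um_per_px

    idx = np.clip(np.searchsorted(cum_px, s_px, side="right") - 1, 0, len(seg) - 1)
    frac = (s_px - cum_px[idx]) / seg_len_px[idx]
    pts = v[idx] + frac[:, None] * seg[idx]
    tang = seg[idx] / seg_len_px[idx, None]
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    offsets = np.arange(normal_window_px, dtype=float) - (normal_window_px - 1) / 2.0
    acc = np.zeros(len(s))
    eps = 1e-6  # tolerate round-off at the image border
    for off in offsets:
        q = pts + off * norm
        if np.any(
            (q[:, 0] < -eps) | (q[:, 0] > w - 1 + eps)
            | (q[:, 1] < -eps) | (q[:, 1] > h - 1 + eps)
        ):
            raise ValidationError(
                f"normal window (±{offsets[-1]:.1f} px) leaves the image along the path"
            )
        qx = np.clip(q[:, 0], 0, w - 1)
        qy = np.clip(q[:, 1], 0, h - 1)
        acc += ndimage.map_coordinates(px, [qy, qx], order=1, mode="nearest")
    return Profile(s_um=s, intensity=acc / normal_window_px)


def detrend(profile: Profile, window_um: float) -> Profile:
    """Subtract a running-mean baseline of width ``window_um``.

    Removes GLG-scale intensity modulation so dip prominences are
    comparable along the profile; the window must span at least 3
    samples (and should be much longer than the line period, which a
    running mean leaves essentially untouched).
    """
    if profile.n < 3:
        raise ValidationError("profile too short to detrend")
    step = profile.median_step_um()
    size = int(round(window_um / step))
    if size % 2 == 0:
        size += 1  # odd window keeps the running mean centred
    if size < 3:
        raise ValidationError(
            f"detrend window {window_um} μm spans {size} samples; need >= 3"
        )
    baseline = ndimage.uniform_filter1d(profile.intensity, size=size, mode="nearest")
    return Profile(s_um=profile.s_um.copy(), intensity=profile.intensity - baseline)


def detect_line_centers(profile: Profile, params: DetectionParams) -> LineCenters:
    """Locate dark incremental-line centres on a detrended profile.

    Dark lines are local intensity minima with prominence at least
    ``prominence_rel`` times the interquartile intensity range and
    pairwise separation at least ``min_separation_um`` (the more
    prominent minimum wins a conflict). The profile is first low-passed
    with a Gaussian of sigma ``smooth_um`` (matched to the line width)
    so single-pixel noise cannot seed minima. Each centre is refined to
    sub-sample precision by a parabola through the three samples around
    the minimum.
    """
    if profile.n == 0:
        raise ValidationError("empty profile")
    y = profile.intensity
    step0 = profile.median_step_um() if profile.n >= 2 else None
    if params.smooth_um > 0 and step0 is not None and params.smooth_um > 0.25 * step0:
        y = ndimage.gaussian_filter1d(y, params.smooth_um / step0)
    iqr = float(np.subtract(*np.percentile(y, [75, 25])))
    if iqr <= 0:
        return LineCenters(s_um=np.empty(0), prominence=np.empty(0))
    step = profile.median_step_um()
    distance = max(1, int(round(params.min_separation_um / step)))
    idx, props = signal.find_peaks(
        -y, prominence=params.prominence_rel * iqr, distance=distance
    )
    if idx.size == 0:
        return LineCenters(s_um=np.empty(0), prominence=np.empty(0))
    centers = profile.s_um[idx].astype(float)
    interior = (idx > 0) & (idx < profile.n - 1)
    ii = idx[interior]
    denom = y[ii - 1] - 2 * y[ii] + y[ii + 1]
    delta = np.zeros(ii.size)
    ok = denom > 0
    delta[ok] = 0.5 * (y[ii - 1] - y[ii + 1])[ok] / denom[ok]
    delta = np.clip(delta, -0.5, 0.5)
    centers[interior] += delta * step
    order = np.argsort(centers)
    return LineCenters(s_um=centers[order], prominence=props["prominences"][order])


def spacings_from_centers(
    centers: LineCenters, glg_ref: tuple[str, str]
) -> list[SpacingMeasurement]:
    """Consecutive centre-to-centre differences, one per line pair.

    ``position_um`` is the midpoint of each pair; k centres yield k − 1
    spacings.
    """
    if centers.n < 2:
        raise ValidationError(f"need >= 2 centres to form spacings, got {centers.n}")
    s = centers.s_um
    gaps = np.diff(s)
    mids = 0.5 * (s[:-1] + s[1:])
    return [
        SpacingMeasurement(glg_ref=glg_ref, position_um=float(p), spacing_um=float(g))
        for p, g in zip(mids, gaps)
    ]


def measure_glg_thickness(profile: Profile, start_um: float, end_um: float) -> float:
    """GLG thickness as arc length between two boundaries on the profile.

    Measured along the growth path (the tubule direction), not as a
    straight chord, so a curved path yields the longer, correct arc.
    """
    lo, hi = float(profile.s_um[0]), float(profile.s_um[-1])
    if not (lo <= start_um < end_um <= hi):
        raise ValidationError(
            f"boundaries [{start_um}, {end_um}] must satisfy "
            f"{lo:.3f} <= start < end <= {hi:.3f} (profile extent, μm)"
        )
    return float(end_um - start_um)


def estimate_period_spectral(
    profile: Profile,
    period_range_um: tuple[float, float],
    min_peak_snr: float = 10.0,
) -> float:
    """Dominant period (μm) of a profile via a Welch periodogram.

    Searches the zero-padded averaged periodogram inside
    ``period_range_um`` and returns the period of the highest peak,
    provided it stands at least ``min_peak_snr`` times above the median
    in-band power; otherwise raises (no admissible peak — e.g. white
    noise). The profile must be uniformly sampled and cover at least 10
    periods of the longest admissible period.
    """
    pmin, pmax = period_range_um
    if not (0 < pmin < pmax):
        raise ValidationError("period_range_um must satisfy 0 < min < max")
    if profile.n < 16:
        raise ValidationError("profile too short for a periodogram")
    d = np.diff(profile.s_um)
    step = float(np.median(d))
    if np.max(np.abs(d - step)) > 1e-6 * max(step, 1.0) + 1e-9:
        raise ValidationError("profile must be uniformly sampled")
    if profile.length_um < 10 * pmax:
        raise ValidationError(
            f"profile length {profile.length_um:.1f} μm covers fewer than 10 "
            f"periods of {pmax} μm"
        )
    y = profile.intensity - profile.intensity.mean()
    fs = 1.0 / step
    nperseg = min(profile.n, max(256, profile.n // 4))
    nfft = int(sfft.next_fast_len(8 * profile.n))
    freqs, power = signal.welch(y, fs=fs, nperseg=nperseg, nfft=nfft, detrend="linear")
    band = (freqs >= 1.0 / pmax) & (freqs <= 1.0 / pmin)
    if not np.any(band):
        raise ValidationError("no periodogram frequencies inside the period range")
    fb, pb = freqs[band], power[band]
    k = int(np.argmax(pb))
    med = float(np.median(pb))
    if med <= 0 or pb[k] < min_peak_snr * med:
        raise ValidationError(
            "no admissible spectral peak in the requested period range"
        )
    return float(1.0 / fb[k])
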