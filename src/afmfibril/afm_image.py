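"""Experimental AFM image preparation.

Polynomial background flattening, ridge tracing and digital
straightening of individual fibrils, centre-line height profiles and
cross-over distance measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, signal

from .errors import AperiodicProfileError, TraceFailedError
from .tipsim import HeightMap


def flatten_image(img: HeightMap, order: int = 1) -> HeightMap:
    """Remove per-row polynomial background (scan-line tilt and bow).

    Pixels above a robust height threshold (median + 3 * 1.4826 * MAD of
    the whole image) are excluded from each row's fit so the fibril does
    not bias the background estimate; afterwards the substrate median is
    shifted to 0.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    h = img.heights
    med = np.median(h)
    mad = np.median(np.abs(h - med))
    background = h <= med + 3.0 * 1.4826 * mad + 1e-12
    x = np.arange(h.shape[1], dtype=float)
    out = np.empty_like(h)
    for i in range(h.shape[0]):
        m = background[i]
        if m.sum() < order + 2:
            m = np.ones_like(m)
        coef = np.polynomial.polynomial.polyfit(x[m], h[i, m], order)
        out[i] = h[i] - np.polynomial.polynomial.polyval(x, coef)
    out -= np.median(out[background])
    return HeightMap(
        heights=out,
        pixel_size_nm=img.pixel_size_nm,
        axis_height_nm=img.axis_height_nm,
        x0=img.x0,
        y0=img.y0,
    )


@dataclass
class FibrilTrace:
    """Traced fibril: sub-pixel centre line plus the straightened strip."""

    centerline_px: np.ndarray  # ordered (row, col) polyline, sub-pixel
    straightened: HeightMap  # fibril along y (axis 0), centred column
    length_nm: float

    def save(self, out_prefix) -> None:
        from .tipsim import save_heightmap_tsv

        prefix = Path(out_prefix)
        prefix.with_suffix(".centerline.json").write_text(
            json.dumps({"centerline_px": self.centerline_px.tolist(),
                        "length_nm": self.length_nm})
        )
        save_heightmap_tsv(self.straightened, prefix.with_suffix(".straightened.tsv"))


def _bilinear(h: np.ndarray, pts_rc: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(h, [pts_rc[:, 0], pts_rc[:, 1]], order=1, mode="nearest")


def _ridge_centre(
    h: np.ndarray, pos: np.ndarray, normal: np.ndarray, half_width: float
) -> Tuple[np.ndarray, float]:
    """Intensity-weighted sub-pixel centre of the perpendicular profile."""
    offs = np.arange(-half_width, half_width + 0.5, 0.5)
    pts = pos[None, :] + offs[:, None] * normal[None, :]
    vals = _bilinear(h, pts)
    peak = vals.max()
    w = np.clip(vals - 0.5 * peak, 0.0, None)
    if w.sum() <= 0:
        return pos, peak
    centre_off = float((w * offs).sum() / w.sum())
    return pos + centre_off * normal, peak


def estimate_half_width_px(img: HeightMap, row: int) -> float:
    """Apparent fibril half-width (above half max) on one image row."""
    line = img.heights[row]
    peak = line.max()
    above = np.flatnonzero(line >= 0.5 * peak)
    return max((above[-1] - above[0]) / 2.0, 2.0)


def trace_and_straighten(
    img: HeightMap,
    seed_endpoints: Sequence[Sequence[float]],
    half_width_px: Optional[float] = None,
    step_px: float = 1.0,
    min_height_frac: float = 0.2,
) -> FibrilTrace:
    """Follow a fibril ridge between two seed points and straighten it.

    The tracer marches from one endpoint towards the other in steps of
    ``step_px``, re-centring on the ridge at each step via the
    intensity-weighted centroid of the perpendicular height profile.  The
    smoothed centre line is then resampled at uniform arc length and the
    image interpolated perpendicular to the local tangent (bicubic) into
    a straightened strip whose width defaults to 4x the apparent fibril
    half-width.  Arc length is preserved.
    """
    h = img.heights
    p0 = np.asarray(seed_endpoints[0], dtype=float)
    p1 = np.asarray(seed_endpoints[1], dtype=float)
    if half_width_px is None:
        half_width_px = estimate_half_width_px(img, int(round(p0[0])))
    peak0 = float(h[int(round(p0[0])), int(round(p0[1]))])
    stop_height = min_height_frac * max(peak0, float(h.max()))

    pts = []
    direction = p1 - p0
    direction = direction / np.linalg.norm(direction)
    pos = p0.copy()
    normal = np.array([-direction[1], direction[0]])
    pos, _ = _ridge_centre(h, pos, normal, 2.0 * half_width_px)
    pts.append(pos.copy())
    max_steps = int(4 * np.linalg.norm(p1 - p0) / step_px) + 10
    for _ in range(max_steps):
        nxt = pos + step_px * direction
        normal = np.array([-direction[1], direction[0]])
        nxt, peak = _ridge_centre(h, nxt, normal, 2.0 * half_width_px)
        if peak < stop_height:
            if np.linalg.norm(pos - p1) > 3 * half_width_px + 2 * step_px:
                raise TraceFailedError(
                    f"ridge height {peak:.2f} dropped below threshold "
                    f"{stop_height:.2f} before reaching the end point"
                )
            break
        new_dir = nxt - pos
        norm = np.linalg.norm(new_dir)
        if norm > 0:
            direction = 0.7 * direction + 0.3 * new_dir / norm
            direction /= np.linalg.norm(direction)
        pos = nxt
        pts.append(pos.copy())
        if (pos - p1) @ (p1 - p0) / np.linalg.norm(p1 - p0) > -step_px:
            break
    centerline = np.asarray(pts)
    if len(centerline) < 2:
        raise TraceFailedError("trace produced fewer than 2 points")

    # smooth the centre line (moving average, window ~ half width)
    win = max(3, int(half_width_px) | 1)
    if len(centerline) > win:
        kernel = np.ones(win) / win
        pad = win // 2
        sm = np.empty_like(centerline)
        for k in range(2):
            padded = np.pad(centerline[:, k], pad, mode="edge")
            sm[:, k] = np.convolve(padded, kernel, mode="valid")
        centerline = sm

    # uniform arc-length resampling
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_samples = max(int(np.floor(s[-1] / step_px)) + 1, 2)
    si = np.linspace(0, s[-1], n_samples)
    cl = np.column_stack(
        [np.interp(si, s, centerline[:, 0]), np.interp(si, s, centerline[:, 1])]
    )

    # straightened strip: sample along local normals, odd width, centre col = ridge
    strip_half = int(np.ceil(4 * half_width_px))
    offs = np.arange(-strip_half, strip_half + 1, dtype=float)
    tangents = np.gradient(cl, si, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    rows = cl[:, None, :] + offs[None, :, None] * normals[:, None, :]
    strip = ndimage.map_coordinates(
        h, [rows[..., 0], rows[..., 1]], order=3, mode="nearest"
    )
    straightened = HeightMap(
        heights=strip,
        pixel_size_nm=img.pixel_size_nm,
        x0=-strip_half * img.pixel_size_nm,
        y0=0.0,
    )
    return FibrilTrace(
        centerline_px=cl,
        straightened=straightened,
        length_nm=float(s[-1] * img.pixel_size_nm),
    )


def centerline_profile(trace: FibrilTrace) -> Tuple[np.ndarray, np.ndarray]:
    """Heights along the central column of the straightened strip.

    Returns (axial positions nm, heights nm).
    """
    strip = trace.straightened.heights
    col = strip.shape[1] // 2
    y = np.arange(strip.shape[0]) * trace.straightened.pixel_size_nm
    return y, strip[:, col].copy()


def crossover_distance(
    profile: np.ndarray,
    pixel_size_nm: float,
    min_peak_factor: float = 3.0,
) -> Tuple[float, List[float]]:
    """Average cross-over distance from the centre-line height profile.

    The average is the period of the dominant non-DC peak of the Fourier
    transform of the profile (with quadratic sub-bin refinement); the
    per-period list holds the axial distances between successive
    centre-line minima.  Raises :class:`AperiodicProfileError` when the
    dominant peak does not rise ``min_peak_factor``-fold above the median
    spectral background.
    """
    profile = np.asarray(profile, dtype=float)
    x = profile - profile.mean()
    n = x.size
    if n < 8:
        raise AperiodicProfileError("profile too short")
    # significance test on the unpadded spectrum
    raw_power = np.abs(np.fft.rfft(x)) ** 2
    raw_power[0] = 0.0
    background = np.median(raw_power[1:])
    if background <= 0 or raw_power.max() < min_peak_factor * background:
        raise AperiodicProfileError("no significant non-DC spectral peak")
    # zero-padded spectrum for sub-bin frequency resolution
    pad = 8
    power = np.abs(np.fft.rfft(x, n=pad * n)) ** 2
    power[: pad] = 0.0  # suppress DC leakage below one cycle per record
    k = int(np.argmax(power))
    if 1 <= k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        la, lb, lc = np.log(power[k - 1 : k + 2])
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = (k + delta) / (pad * n * pixel_size_nm)
    cod = 1.0 / freq

    distance = max(int(0.5 * cod / pixel_size_nm), 1)
    minima, _ = signal.find_peaks(-x, distance=distance)
    per_period = list(np.diff(minima) * pixel_size_nm)
    return float(cod), per_period
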