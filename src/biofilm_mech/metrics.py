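"""Colony pattern and contour morphometrics.

Implements the image-analysis chain used to quantify wrinkled/delaminated
biofilm colonies from transmission images: intensity normalisation and
valley thresholding, ring-FFT counting of radial features and the linear
fit ``N(r) = 2 pi r / lambda`` for the intrinsic wavelength, edge-profile
peak prominence, acircularity ``alpha = P^2 / (4 pi A)``, two-segment
expansion kinematics, local contour curvature/velocity, and side-view
blister height/width.

Coordinates are pixel-centred with origin at the top-left corner
(row = y, column = x, 0-based); physical outputs use the supplied pixel
size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import measure

from .mechanics import InterfacialEnergySet

__all__ = [
    "NormalizedImage",
    "ColonyMask",
    "WavelengthFit",
    "ContourKinematics",
    "BlisterProfile",
    "SegmentationError",
    "normalize_and_segment",
    "colony_center",
    "count_ring_features",
    "fit_wavelength",
    "edge_amplitude_peaks",
    "contour_metrics",
    "expansion_fit",
    "resample_contour",
    "local_kinematics",
    "blister_metrics",
    "interface_hierarchy",
]

BACKGROUND_LEVEL = 0.9      #: normalised background intensity I_b
MIN_PROMINENCE = 0.02       #: default edge-peak prominence threshold
EDGE_RADIUS_FRAC = 0.9      #: default edge-profile radius as fraction of <R_f>


class SegmentationError(ValueError):
    """Raised when an image cannot be normalised or segmented."""


@dataclass
class NormalizedImage:
    """Intensity image rescaled so min -> 0 and background mode -> 0.9."""

    intensity: np.ndarray
    valley_threshold: float     #: I_V used for binarisation
    pixel_size: float = 1.0     #: m per pixel
    timestamp: float = 0.0      #: hours


@dataclass
class ColonyMask:
    """Binary colony object with centre and boundary measures."""

    mask: np.ndarray            #: boolean, True inside the colony
    center: tuple[float, float]  #: (x, y) pixel coordinates of O_F
    pixel_size: float = 1.0

    @property
    def area_px(self) -> float:
        return float(self.mask.sum())


@dataclass
class WavelengthFit:
    """Intrinsic wavelength from the through-origin fit N(r) = 2 pi r / lambda."""

    wavelength: float           #: lambda, same units as r
    samples: np.ndarray         #: (r, t, N) rows used in the fit
    residual: float             #: sum of squared residuals in N
    pattern_radius: dict[float, float] = field(default_factory=dict)  #: R_p per time


@dataclass
class ContourKinematics:
    """Per-point curvature, normals and local expansion velocity."""

    points: np.ndarray          #: resampled contour (n, 2)
    curvature: np.ndarray       #: kappa_i (1/length); positive = bulging outward
    normals: np.ndarray         #: outward unit normals (n, 2)
    velocity: np.ndarray | None  #: V_f,i = |r_i(t+dt) - r_i(t)| / dt


@dataclass
class BlisterProfile:
    """Side-view blister profile z(x)."""

    x: np.ndarray
    z: np.ndarray
    flank_fraction: float = 0.1  #: fraction of samples per side used as baseline


# ---------------------------------------------------------------------------
# normalisation & segmentation

def _background_peak_and_valley(img: np.ndarray, bins: int = 256) -> tuple[float, float]:
    """Locate the background histogram peak — the *brightest* substantial
    mode, since the background transmits the most light — and the first
    local minimum below it (the valley threshold).

    The histogram is smoothed (Gaussian, 2 bins) before peak and valley
    detection so that intensity noise inside a mode cannot masquerade as
    the inter-mode valley.
    """
    raw_hist, edges = np.histogram(img.ravel(), bins=bins)
    hist = ndimage.gaussian_filter1d(raw_hist.astype(float), 2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate([[-1.0], hist.astype(float), [-1.0]])
    is_peak = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] >= padded[2:])
    substantial = hist >= max(1, 0.05 * hist.max())
    candidates = np.flatnonzero(is_peak & substantial)
    if candidates.size == 0:
        raise SegmentationError("degenerate histogram: no substantial peak")
    peak_idx = int(candidates[-1])       # rightmost = highest intensity
    # scan downward from the peak for the first local minimum
    valley_idx = None
    for i in range(peak_idx - 1, 0, -1):
        if hist[i] <= hist[i - 1] and hist[i] <= hist[i + 1]:
            valley_idx = i
            break
    if valley_idx is None:
        raise SegmentationError(
            "no histogram valley below the background peak; "
            "supply a manual threshold"
        )
    return float(centers[peak_idx]), float(centers[valley_idx])


def normalize_and_segment(raw: np.ndarray, pixel_size: float = 1.0,
                          timestamp: float = 0.0,
                          ) -> tuple[NormalizedImage, ColonyMask]:
    """Normalise a transmission image and segment the colony object.

    The image is affinely rescaled so its minimum maps to 0 and the
    background histogram mode to 0.9, median-filtered (3x3), and
    thresholded at the valley ``I_V`` immediately below the background
    peak.  The colony is the largest below-threshold connected component,
    holes filled.
    """
    img = np.asarray(raw, dtype=float)
    if img.ndim != 2:
        raise SegmentationError("expected a single-channel 2-D image")
    mn = float(img.min())
    peak, _ = _background_peak_and_valley(img)
    if peak <= mn:
        raise SegmentationError("background peak coincides with the minimum")
    norm = (img - mn) * (BACKGROUND_LEVEL / (peak - mn))
    norm = ndimage.median_filter(norm, size=3)
    _, valley = _background_peak_and_valley(norm)

    binary = norm < valley
    labels, n = ndimage.label(binary)
    if n == 0:
        raise SegmentationError("no object below the valley threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < 9:
        raise SegmentationError("no object: largest dark component is below 9 px")
    cy, cx = ndimage.center_of_mass(mask)
    nimg = NormalizedImage(intensity=norm, valley_threshold=valley,
                           pixel_size=pixel_size, timestamp=timestamp)
    return nimg, ColonyMask(mask=mask, center=(float(cx), float(cy)),
                            pixel_size=pixel_size)


def colony_center(masks: list[ColonyMask], times_hr: list[float],
                  reference_hr: float = 12.0) -> tuple[float, float]:
    """Colony centre O_F from the frame at (or nearest) t = 12 hr.

    The same centre is reused for every time point.  If no frame lies
    within +/- 3 hr of the reference a warning is emitted and the earliest
    frame is used.
    """
    import warnings
    times = np.asarray(times_hr, dtype=float)
    idx = int(np.argmin(np.abs(times - reference_hr)))
    if abs(times[idx] - reference_hr) > 3.0:
        warnings.warn(
            f"no frame within 3 hr of t = {reference_hr} hr; "
            "using the earliest frame to define the centre", stacklevel=2)
        idx = int(np.argmin(times))
    cy, cx = ndimage.center_of_mass(masks[idx].mask)
    return float(cx), float(cy)


# ---------------------------------------------------------------------------
# ring counting and the wavelength fit

def _sample_ring(intensity: np.ndarray, center: tuple[float, float],
                 radius_px: float, n_samples: int) -> np.ndarray:
    """Bilinear samples of the image on a circle (periodic in theta)."""
    cx, cy = center
    theta = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    xs = cx + radius_px * np.cos(theta)
    ys = cy + radius_px * np.sin(theta)
    h, w = intensity.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
        raise ValueError(
            f"ring of radius {radius_px:.1f} px exits the image bounds")
    return ndimage.map_coordinates(intensity, np.vstack([ys, xs]), order=1,
                                   mode="nearest")


def _autocorr_count(profile: np.ndarray) -> int | None:
    """Dominant angular repeat count from the circular autocorrelation."""
    h = profile - profile.mean()
    if np.allclose(h, 0):
        return None
    ac = np.fft.irfft(np.abs(np.fft.rfft(h)) ** 2, n=len(h))
    half = ac[1: len(ac) // 2]
    peaks, _ = signal.find_peaks(half)
    if len(peaks) == 0:
        return None
    # multiples of the fundamental lag peak equally high: take the first
    # peak comparable to the best one
    heights = half[peaks]
    significant = peaks[heights >= 0.5 * heights.max()]
    lag = 1 + int(significant[0])
    return int(round(len(h) / lag))


def count_ring_features(image: NormalizedImage, center: tuple[float, float],
                        radius_px: float, n_samples: int = 1024,
                        min_harmonic: int = 3,
                        ) -> tuple[int, bool]:
    """Count periodic features N on a ring by FFT of I(theta).

    Returns ``(N, flagged)``: N is the dominant FFT harmonic in
    ``[min_harmonic, n_samples/2)``; ``flagged`` is True when the
    autocorrelation cross-check disagrees by more than one harmonic or the
    ring carries no periodic signal (N is then 0).

    The search starts at harmonic 3 to exclude centring/ellipticity
    artefacts.
    """
    prof = _sample_ring(image.intensity, center, radius_px, n_samples)
    h = prof - prof.mean()
    power = np.abs(np.fft.rfft(h)) ** 2
    lo = min_harmonic
    hi = n_samples // 2
    band = power[lo:hi]
    total = float(np.sum(power[1:]))
    if total <= 0 or np.max(band) < 0.05 * total or np.std(prof) < 1e-4:
        return 0, True  # no periodic signal
    N = lo + int(np.argmax(band))
    n_ac = _autocorr_count(prof)
    flagged = n_ac is None or abs(n_ac - N) > 1
    return N, flagged


def fit_wavelength(samples: np.ndarray) -> WavelengthFit:
    """Fit the intrinsic wavelength from pooled (r, t, N) ring counts.

    All time points are pooled and fitted through the origin with
    ``N(r) = 2 pi r / lambda``, giving the closed form
    ``lambda = 2 pi sum(r N) / sum(N^2)``.  ``R_p``, the innermost radius
    of the patterned annulus (where N rises from zero), is reported per
    frame.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be rows of (r, t, N)")
    if samples.shape[0] < 5:
        raise ValueError(f"need >= 5 samples, got {samples.shape[0]}")
    if len(np.unique(samples[:, 0])) < 2:
        raise ValueError("samples must span at least two radii")
    r, t, N = samples.T
    if np.all(N == 0):
        raise ValueError("no pattern: all ring counts are zero")
    lam = 2.0 * math.pi * float(np.sum(r * N)) / float(np.sum(N**2))
    resid = float(np.sum((N - 2.0 * math.pi * r / lam) ** 2))

    r_p: dict[float, float] = {}
    for tv in np.unique(t):
        sel = t == tv
        rr, nn = r[sel], N[sel]
        order = np.argsort(rr)
        rr, nn = rr[order], nn[order]
        trans = [rr[i + 1] for i in range(len(rr) - 1) if nn[i] == 0 and nn[i + 1] > 0]
        if trans:
            r_p[float(tv)] = float(max(trans))
        elif np.any(nn > 0):
            r_p[float(tv)] = float(rr[nn > 0].min())
    return WavelengthFit(wavelength=lam, samples=samples, residual=resid,
                         pattern_radius=r_p)


def edge_amplitude_peaks(image: NormalizedImage, center: tuple[float, float],
                         radius_px: float, n_samples: int = 1024,
                         min_prominence: float = MIN_PROMINENCE,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Positions (theta) and prominences of dips in the edge profile.

    Peaks of ``-I(theta)`` on a circle near the colony edge, with the
    profile treated as periodic; dips shallower than ``min_prominence``
    are rejected as noise.
    """
    prof = _sample_ring(image.intensity, center, radius_px, n_samples)
    neg = -prof
    ext = np.concatenate([neg, neg, neg])            # periodic handling
    peaks, props = signal.find_peaks(ext, prominence=min_prominence)
    sel = (peaks >= n_samples) & (peaks < 2 * n_samples)
    idx = peaks[sel] - n_samples
    theta = 2.0 * np.pi * idx / n_samples
    return theta, props["prominences"][sel]


# ---------------------------------------------------------------------------
# contours

def _gaussian_smooth_periodic(arr: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(arr, sigma=sigma, mode="wrap", axis=0)


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel closed boundary of a binary mask as (x, y) points."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    outer = max(contours, key=len)
    # find_contours yields (row, col); convert to (x, y) and drop the
    # duplicated closing point
    pts = np.column_stack([outer[:, 1], outer[:, 0]])
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def resample_contour(points: np.ndarray, n: int = 512, smooth_sigma: float = 2.0
                     ) -> np.ndarray:
    """Resample a closed contour to ``n`` uniform arc-length points.

    The resampled contour is smoothed with a periodic Gaussian
    (sigma in samples) and oriented counter-clockwise, so that positive
    curvature means bulging outward.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need a closed contour of >= 4 (x, y) points")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour of zero length")
    si = np.linspace(0.0, total, n, endpoint=False)
    res = np.column_stack([np.interp(si, s, closed[:, 0]),
                           np.interp(si, s, closed[:, 1])])
    if smooth_sigma > 0:
        res = _gaussian_smooth_periodic(res, smooth_sigma)
    # enforce CCW orientation (positive shoelace area)
    area2 = float(np.sum(res[:, 0] * np.roll(res[:, 1], -1)
                         - np.roll(res[:, 0], -1) * res[:, 1]))
    if area2 < 0:
        res = res[::-1].copy()
    return res


def contour_metrics(mask_or_points: np.ndarray | ColonyMask,
                    center: tuple[float, float] | None = None,
                    smooth_px: float = 1.5,
                    ) -> tuple[float, float, float, float]:
    """Perimeter P, area A, acircularity alpha = P^2/(4 pi A), mean radius.

    ``alpha = 1`` for a perfect circle and grows with boundary undulation
    (isoperimetric inequality).  The mean radius ``<R_f>`` averages the
    distance of boundary points to the colony centre.

    The sub-pixel boundary is resampled at ~2 samples per unit arc length
    and smoothed with a Gaussian of ``smooth_px`` (input coordinate units,
    i.e. pixels for a mask): wide enough to suppress the marching-squares
    staircase that inflates digitised perimeters, narrow enough to keep
    real corners (a square stays within 1% of 4/pi).  Pass 0 for exact
    analytic contours.
    """
    if isinstance(mask_or_points, ColonyMask):
        labels, ncomp = ndimage.label(mask_or_points.mask)
        if ncomp != 1:
            raise ValueError(f"mask must be a single connected component, got {ncomp}")
        pts = extract_contour(mask_or_points.mask)
        if center is None:
            center = mask_or_points.center
        scale = mask_or_points.pixel_size
    else:
        pts = np.asarray(mask_or_points, dtype=float)
        scale = 1.0
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour of zero length")
    n = max(512, int(2 * total))
    si = np.linspace(0.0, total, n, endpoint=False)
    res = np.column_stack([np.interp(si, s, closed[:, 0]),
                           np.interp(si, s, closed[:, 1])])
    if smooth_px > 0:
        res = _gaussian_smooth_periodic(res, smooth_px * n / total)
    poly = Polygon(res)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("contour is not a simple closed polygon")
    P = float(poly.length) * scale
    A = float(poly.area) * scale**2
    alpha = P**2 / (4.0 * math.pi * A)
    if center is None:
        cx, cy = poly.centroid.x, poly.centroid.y
    else:
        cx, cy = center
    rf = float(np.mean(np.hypot(res[:, 0] - cx, res[:, 1] - cy))) * scale
    return P, A, alpha, rf


def expansion_fit(times: np.ndarray, radii: np.ndarray,
                  ) -> tuple[float | None, float, float]:
    """Two-segment continuous linear fit of <R_f>(t): (t_c, V_before, V_after).

    The breakpoint is grid-searched over interior sample times; the fit is
    continuous (hinge basis).  Returns ``t_c = None`` (with the single-line
    slope in both velocity slots) when no break is detected — breakpoint at
    the boundary of the candidate set or negligible slope change.
    """
    t = np.asarray(times, dtype=float)
    R = np.asarray(radii, dtype=float)
    if t.size != R.size or t.size < 8:
        raise ValueError(f"need >= 8 matched time points, got {t.size}")
    order = np.argsort(t)
    t, R = t[order], R[order]

    best = None
    candidates = t[2:-2]
    for tc in candidates:
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - tc, 0.0)])
        coef, *_ = np.linalg.lstsq(X, R, rcond=None)
        sse = float(np.sum((X @ coef - R) ** 2))
        if best is None or sse < best[0]:
            best = (sse, tc, coef)
    sse, tc, coef = best
    v1, v2 = float(coef[1]), float(coef[1] + coef[2])
    scale = max(abs(v1), abs(v2), 1e-300)
    at_boundary = tc in (candidates[0], candidates[-1])
    if abs(v2 - v1) / scale < 1e-6 or at_boundary:
        slope = float(np.polyfit(t, R, 1)[0])
        return None, slope, slope
    return float(tc), v1, v2


def local_kinematics(contour_t: np.ndarray, contour_next: np.ndarray | None = None,
                     dt: float = 1.0, n_resample: int = 512,
                     smooth_sigma: float = 2.0, window: int = 9,
                     ) -> ContourKinematics:
    """Local curvature, outward normals and expansion velocity of a contour.

    Each resampled boundary point is approximated by Gaussian-weighted
    quadratic fits of x(s), y(s) over a symmetric ``window``; the fitted
    derivatives give the analytic curvature
    ``kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2)`` (positive where the
    boundary bulges outward) and the normal.  Velocities join each point to
    its nearest neighbour on the next contour: ``V_i = |r_i(t+dt)-r_i(t)|/dt``.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 5")
    res = resample_contour(contour_t, n=n_resample, smooth_sigma=smooth_sigma)
    n = len(res)
    if window >= n:
        raise ValueError("window larger than the resampled contour")
    half = window // 2
    offs = np.arange(-half, half + 1, dtype=float)
    wts = np.exp(-0.5 * (offs / (half / 2.0)) ** 2)
    # quadratic design in the local arc-length parameter
    Xd = np.column_stack([np.ones_like(offs), offs, offs**2])
    W = np.diag(wts)
    proj = np.linalg.solve(Xd.T @ W @ Xd, Xd.T @ W)   # (3, window)

    idx = (np.arange(n)[:, None] + offs.astype(int)[None, :]) % n
    loc_x = res[idx, 0]
    loc_y = res[idx, 1]
    cx = loc_x @ proj.T       # (n, 3): value, first, second derivative / 2
    cy = loc_y @ proj.T
    xp, xpp = cx[:, 1], 2.0 * cx[:, 2]
    yp, ypp = cy[:, 1], 2.0 * cy[:, 2]
    denom = (xp**2 + yp**2) ** 1.5
    kappa = (xp * ypp - yp * xpp) / denom
    # CCW tangent (xp, yp): outward normal is (yp, -xp) normalised
    nrm = np.column_stack([yp, -xp])
    nrm /= np.linalg.norm(nrm, axis=1)[:, None]

    vel = None
    if contour_next is not None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        nxt = resample_contour(contour_next, n=n_resample, smooth_sigma=smooth_sigma)
        dist, _ = cKDTree(nxt).query(res)
        vel = dist / dt
    return ContourKinematics(points=res, curvature=kappa, normals=nrm, velocity=vel)


# ---------------------------------------------------------------------------
# blisters and interfacial energies

def blister_metrics(profile: BlisterProfile) -> tuple[float, float]:
    """Blister height H and width W at half height from a side profile.

    The baseline averages z over the outer flank regions on both sides;
    ``H`` is the peak height above the baseline and ``W`` the distance
    between the two half-height crossings (linearly interpolated).
    Invariant under horizontal translation and baseline offset.
    """
    x = np.asarray(profile.x, dtype=float)
    z = np.asarray(profile.z, dtype=float)
    if x.size != z.size or x.size < 8:
        raise ValueError("profile needs >= 8 matched (x, z) samples")
    order = np.argsort(x)
    x, z = x[order], z[order]
    k = max(1, int(round(profile.flank_fraction * x.size)))
    baseline = 0.5 * (float(np.mean(z[:k])) + float(np.mean(z[-k:])))
    ipk = int(np.argmax(z))
    H = float(z[ipk]) - baseline
    if H <= 0 or ipk in (0, x.size - 1):
        raise ValueError("profile has no interior peak above the baseline")
    half = baseline + 0.5 * H

    def cross(side: str) -> float:
        rng = range(ipk, 0, -1) if side == "left" else range(ipk, x.size - 1)
        for i in rng:
            j = i - 1 if side == "left" else i + 1
            if (z[i] - half) * (z[j] - half) <= 0 and z[i] != z[j]:
                f = (half - z[i]) / (z[j] - z[i])
                return float(x[i] + f * (x[j] - x[i]))
        raise ValueError(f"no half-height crossing on the {side} flank")

    W = cross("right") - cross("left")
    return H, W


def interface_hierarchy(energies: InterfacialEnergySet) -> list[str]:
    """Predicted sequence of interface events from the energy hierarchy.

    Creating a cheap interface while annihilating an expensive one is
    favourable, so the ordering of the adhesion energy ``Gamma`` and the
    film–liquid / film–air surface energies dictates the blister life
    cycle: delamination happens first (immediately, skipping wrinkling,
    when adhesion is unmeasurably small); blister walls then make internal
    contact when the film–liquid interface is dearer than film–air
    (annihilating film–liquid area pays); in the opposite, mutant regime
    neighbouring blisters merge and collapse laterally instead.
    """
    ev: list[str] = []
    if energies.Gamma == 0:
        ev.append("delaminate immediately (skip wrinkling)")
    elif energies.Gamma <= min(energies.gamma_fl, energies.gamma_fa):
        ev.append("delaminate")
    else:
        ev.append("wrinkle (delamination disfavoured)")
    if energies.gamma_fl > energies.gamma_fa:
        ev.append("internal contact")
        ev.append("merge peaks")
    elif energies.gamma_fa > energies.gamma_fl:
        ev.append("lateral collapse of neighbors")
    else:
        ev.append("tie: internal contact and lateral collapse co-favored")
    return ev
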