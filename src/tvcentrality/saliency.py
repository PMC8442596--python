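"""Bottom-up visual saliency (Itti-Koch) and the mean saliency signal.

Each RGB frame is decomposed into intensity, colour-opponency (RG, BY)
and four Gabor orientation channels on a 9-level dyadic Gaussian
pyramid.  Centre-surround contrast maps |centre - surround| are taken
for centre levels {2, 3, 4} against surrounds {c+3, c+4}, normalised
with the closed-form max-norm operator (scale to [0, 1], weight by
(M - mean-of-other-local-maxima)^2), combined into per-channel
conspicuity maps at pyramid level 4, and averaged into the saliency
map.  A 1024 x 720 frame therefore yields a 64 x 45 map (scale 16).

The per-TR mean saliency signal averages the maps spatially and over
the F frames falling in each TR (F = fps * TR, e.g. 24 at 24 fps and
TR 1 s), and is low-pass filtered at 0.1 Hz with a zero-phase
Butterworth filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.ndimage as ndi
import scipy.signal
from skimage.filters import gabor_kernel
from skimage.transform import resize

from .connectome import ValidationError

__all__ = [
    "SaliencyMap",
    "SaliencySignal",
    "gaussian_pyramid",
    "compute_feature_maps",
    "normalize_map",
    "compute_saliency_map",
    "mean_saliency_signal",
    "lowpass_filter",
    "DEFAULT_LOWPASS_HZ",
]

DEFAULT_LOWPASS_HZ = 0.1

N_PYRAMID_LEVELS = 9          # levels 0..8, dyadic
CENTER_LEVELS = (2, 3, 4)
SURROUND_DELTAS = (3, 4)
OUTPUT_LEVEL = 4              # conspicuity/saliency scale (factor 16)
ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
GABOR_WAVELENGTH_PX = 7.0
FILTER_ORDER = 5

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class SaliencyMap:
    """Non-negative conspicuity map at 1/16 of the frame resolution."""

    values: np.ndarray
    scale_factor: int = 16

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValidationError("saliency map must be non-negative")
        self.values = np.clip(self.values, 0.0, None)


@dataclass
class SaliencySignal:
    """Mean visual saliency, one sample per TR."""

    values: np.ndarray
    tr_seconds: float
    filtered: bool = False
    cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.filtered and self.cutoff_hz is None:
            raise ValidationError("filtered signal must record its cutoff")


# ---------------------------------------------------------------- pyramid

def _smooth(img: np.ndarray) -> np.ndarray:
    out = ndi.correlate1d(img, _BINOMIAL5, axis=0, mode="reflect")
    return ndi.correlate1d(out, _BINOMIAL5, axis=1, mode="reflect")


def gaussian_pyramid(img: np.ndarray, levels: int = N_PYRAMID_LEVELS) -> list[np.ndarray]:
    """Dyadic Gaussian pyramid: 5-tap binomial smoothing + 2x decimation.

    Odd dimensions shrink by ceiling division, so level k of an
    (H, W) image has shape (ceil(H/2^k), ceil(W/2^k)).
    """
    pyr = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        pyr.append(_smooth(pyr[-1])[::2, ::2])
    return pyr


def _upsample_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(img, shape, order=1, mode="reflect", anti_aliasing=False)


def _center_surround(pyr: list[np.ndarray]) -> list[np.ndarray]:
    """|centre - surround| maps for all (c, s) scale pairs, at level 4.

    The surround is upsampled to the centre's resolution before
    differencing, so a spatially uniform channel (e.g. a pure colour
    field) carries no contrast.
    """
    out_shape = pyr[OUTPUT_LEVEL].shape
    maps = []
    for c in CENTER_LEVELS:
        for d in SURROUND_DELTAS:
            s = c + d
            diff = np.abs(pyr[c] - _upsample_to(pyr[s], pyr[c].shape))
            maps.append(_upsample_to(diff, out_shape)
                        if diff.shape != out_shape else diff)
    return maps


# ----------------------------------------------------------- raw channels

def _split_channels(frame: np.ndarray):
    """Intensity and clamped colour-opponency channels in [0, 1] units."""
    f = np.asarray(frame, dtype=float)
    if f.ndim != 3 or f.shape[2] != 3:
        raise ValidationError("frame must be H x W x 3 (RGB)")
    if f.max() > 1.5:      # 8-bit input
        f = f / 255.0
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    I = (r + g + b) / 3.0
    # broadly tuned channels, suppressed at low luminance
    R = np.clip(r - (g + b) / 2.0, 0, None)
    G = np.clip(g - (r + b) / 2.0, 0, None)
    B = np.clip(b - (r + g) / 2.0, 0, None)
    Y = np.clip((r + g) / 2.0 - np.abs(r - g) / 2.0 - b, 0, None)
    lum_mask = I < I.max() / 10.0 if I.max() > 0 else np.ones_like(I, bool)
    for ch in (R, G, B, Y):
        ch[lum_mask] = 0.0
    return I, R - G, B - Y


@lru_cache(maxsize=8)
def _gabor_bank(wavelength: float = GABOR_WAVELENGTH_PX):
    """Zero-mean even/odd Gabor kernels at the four orientations."""
    bank = []
    for theta_deg in ORIENTATIONS:
        k = gabor_kernel(frequency=1.0 / wavelength,
                         theta=np.deg2rad(theta_deg), n_stds=3)
        even = np.real(k)
        even = even - even.mean()   # remove DC so flat regions score 0
        odd = np.imag(k)
        bank.append((even, odd))
    return bank


def _gabor_energy(img: np.ndarray, even: np.ndarray, odd: np.ndarray) -> np.ndarray:
    # 'nearest' extension: exact on flat regions even when the kernel
    # exceeds the image (coarse pyramid levels), unlike 'reflect'
    e = ndi.correlate(img, even, mode="nearest")
    o = ndi.correlate(img, odd, mode="nearest")
    return np.hypot(e, o)


# ------------------------------------------------------------- operations

def _check_frame_size(frame: np.ndarray) -> None:
    h, w = frame.shape[:2]
    need = 2 ** (N_PYRAMID_LEVELS - 1)
    if min(h, w) < need:
        raise ValidationError(
            f"frame {w}x{h} too small for {N_PYRAMID_LEVELS} pyramid "
            f"levels; minimum dimension is {need} px")


def compute_feature_maps(frame: np.ndarray) -> dict[str, list[np.ndarray]]:
    """Centre-surround feature maps of one RGB frame, at level-4 scale.

    Returns 6 intensity maps, 12 colour maps (RG and BY opponency) and
    24 orientation maps (four Gabor orientations), keyed by channel.
    """
    _check_frame_size(frame)
    I, rg, by = _split_channels(frame)
    pyr_I = gaussian_pyramid(I)
    maps = {"intensity": _center_surround(pyr_I)}
    color = []
    for chan in (rg, by):
        color.extend(_center_surround(gaussian_pyramid(chan)))
    maps["color"] = color
    orient = []
    lo = min(CENTER_LEVELS)
    for even, odd in _gabor_bank():
        # energy is only consumed at levels >= the smallest centre level
        opyr = [np.zeros((1, 1))] * lo + [
            _gabor_energy(pyr_I[lv], even, odd)
            for lv in range(lo, N_PYRAMID_LEVELS)]
        orient.extend(_center_surround(opyr))
    maps["orientation"] = orient
    return maps


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Max-norm operator promoting maps with one dominant peak.

    The map is rescaled to [0, 1] and multiplied by (M - mbar)^2,
    where M is the global maximum (1 after rescaling) and mbar the mean
    of all *other* local maxima (strict 3 x 3 neighbourhood maxima
    below the global value).  Maps with many comparable peaks are
    suppressed; all-zero (or constant) maps pass through as zeros.
    """
    m = np.asarray(m, dtype=float)
    lo, hi = m.min(), m.max()
    if hi == lo:
        return m - lo   # constant map carries no contrast
    r = (m - lo) / (hi - lo)
    footprint = np.ones((3, 3), bool)
    footprint[1, 1] = False
    neigh = ndi.maximum_filter(r, footprint=footprint,
                               mode="constant", cval=-np.inf)
    local_max = r > neigh
    others = r[local_max & (r < 1.0)]
    mbar = others.mean() if others.size else 0.0
    return r * (1.0 - mbar) ** 2


def compute_saliency_map(frame: np.ndarray) -> SaliencyMap:
    """Saliency map of one frame: normalise, combine, normalise again.

    Normalised feature maps are summed within each channel into a
    conspicuity map, each conspicuity map is normalised once more, and
    the three channels are averaged.
    """
    fmaps = compute_feature_maps(frame)
    conspicuity = []
    for channel in ("intensity", "color", "orientation"):
        summed = np.sum([normalize_map(f) for f in fmaps[channel]], axis=0)
        conspicuity.append(normalize_map(summed))
    return SaliencyMap(values=np.mean(conspicuity, axis=0),
                       scale_factor=2 ** OUTPUT_LEVEL)


def mean_saliency_signal(
    maps,
    fps: float,
    tr_seconds: float,
) -> SaliencySignal:
    """Spatio-temporal mean saliency, one sample per TR.

    s(t) is the grand mean over the F = fps * TR frames of bin t and
    all map pixels; F must be integral and a trailing partial bin is
    dropped.
    """
    F_exact = fps * tr_seconds
    F = int(round(F_exact))
    if abs(F_exact - F) > 1e-9 or F < 1:
        raise ValidationError(
            f"fps * tr_seconds = {F_exact} is not a positive integer")
    frame_means = np.array([
        np.mean(m.values if isinstance(m, SaliencyMap) else m) for m in maps])
    n_bins = frame_means.size // F
    if n_bins == 0:
        raise ValidationError("fewer frames than one TR bin")
    vals = frame_means[: n_bins * F].reshape(n_bins, F).mean(axis=1)
    return SaliencySignal(values=vals, tr_seconds=tr_seconds)


def lowpass_filter(
    signal: SaliencySignal, cutoff_hz: float = DEFAULT_LOWPASS_HZ
) -> SaliencySignal:
    """Zero-phase Butterworth low-pass (order 5, forward-backward).

    Reflective padding avoids edge transients; the DC component (signal
    mean) is preserved.
    """
    fs = 1.0 / signal.tr_seconds
    if cutoff_hz >= fs / 2.0:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {fs / 2.0} Hz")
    x = signal.values
    if x.size <= 6 * FILTER_ORDER:
        raise ValidationError(
            f"signal of {x.size} samples too short for an order-"
            f"{FILTER_ORDER} zero-phase filter")
    b, a = scipy.signal.butter(FILTER_ORDER, cutoff_hz, fs=fs)
    y = scipy.signal.filtfilt(b, a, x, padtype="even")
    return SaliencySignal(values=y, tr_seconds=signal.tr_seconds,
                          filtered=True, cutoff_hz=cutoff_hz)
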