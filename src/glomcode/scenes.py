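"""Panoramic background scenes with natural-image-like statistics.

Natural scenes are dominated by low spatial frequencies: their radially
averaged power spectra fall off approximately as ``p ∝ 1/f^2``.  This module
synthesises grayscale panoramas with a prescribed power-law spectrum (used as
surrogates for photographic natural images throughout the package), applies
spatial-frequency filtering (whitening, high-pass, low-pass), and estimates
radially averaged power spectra with a log–log slope fit.

All spatial frequencies are in cycles per degree of visual angle; the pixel
scale of an :class:`ImageScene` converts between pixels and degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "ImageScene",
    "SpectrumEstimate",
    "generate_pink_image",
    "filter_image",
    "estimate_spectrum",
    "save_scene",
    "load_scene",
    "export_png",
]


@dataclass
class ImageScene:
    """A 2D luminance panorama.

    Parameters
    ----------
    pixels
        2D array (elevation x azimuth) of non-negative luminance values.
    pixel_scale
        Degrees of visual angle per pixel, ``(azimuth, elevation)``.
    wrap
        Whether azimuth is periodic (cylindrical panorama).  A wrapping scene
        must span at least 360 deg of azimuth.
    """

    pixels: np.ndarray
    pixel_scale: tuple[float, float] = (1.0, 1.0)
    wrap: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        az, el = self.pixel_scale
        if az <= 0 or el <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.wrap and self.pixels.shape[1] * az < 360.0 - 1e-9:
            raise ValueError("wrapping scene must cover at least 360 deg of azimuth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_deg(self) -> tuple[float, float]:
        """(azimuth span, elevation span) in degrees."""
        return (
            self.pixels.shape[1] * self.pixel_scale[0],
            self.pixels.shape[0] * self.pixel_scale[1],
        )


@dataclass
class SpectrumEstimate:
    """Radially averaged power spectrum plus a power-law slope fit."""

    frequency: np.ndarray  # cycles/degree, strictly increasing
    power: np.ndarray  # mean power per radial bin, >= 0
    fitted_slope: float  # log-log slope over the requested band
    band: tuple[float, float] = (0.01, 0.2)


def _radial_frequency_grid(shape: tuple[int, int], pixel_scale: tuple[float, float]) -> np.ndarray:
    """|f| in cycles/degree for each 2D DFT coefficient."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_scale[1])
    fx = np.fft.fftfreq(nx, d=pixel_scale[0])
    return np.hypot(fy[:, None], fx[None, :])


def generate_pink_image(
    height_px: int,
    width_px: int,
    pixel_scale: tuple[float, float] = (0.703125, 0.703125),
    slope: float = -2.0,
    seed: int | None = 0,
    wrap: bool = True,
) -> ImageScene:
    """Synthesise a panorama whose power spectrum follows ``p ∝ f**slope``.

    Spectral synthesis: white Gaussian noise is transformed to the frequency
    domain, its amplitudes are shaped as ``|f|**(slope/2)`` (power goes as the
    square), and the result is transformed back with the random phases intact.
    Pixels are rescaled to mean 0.5 and clipped to [0, 1].

    The default pixel scale (360/512 deg per pixel) makes a 512-pixel-wide
    image span a full cylinder.
    """
    if slope >= 0 and slope != 0:
        raise ValueError("slope must be <= 0")
    if height_px < 32 or width_px < 32:
        raise ValueError("image dimensions must be at least 32 px")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height_px, width_px))
    spectrum = np.fft.fft2(white)
    f = _radial_frequency_grid((height_px, width_px), pixel_scale)
    shaping = np.zeros_like(f)
    nonzero = f > 0
    # cap power growth below f_floor (cycles/deg): without a cap the handful
    # of lowest-frequency modes dominate the pixel variance, making surrogate
    # images from different seeds substantially correlated by chance
    f_floor = 0.02
    shaping[nonzero] = np.maximum(f[nonzero], f_floor) ** (slope / 2.0)
    img = np.fft.ifft2(spectrum * shaping).real
    sd = img.std()
    if sd == 0:
        raise FloatingPointError("degenerate spectral synthesis output")
    # mean 0.5, std 0.3: the tails clip, producing saturated patches that make
    # local contrast spatially heterogeneous, as in photographic scenes
    img = 0.5 + (img - img.mean()) / sd * 0.3
    img = np.clip(img, 0.0, 1.0)
    if not np.all(np.isfinite(img)):
        raise FloatingPointError("non-finite pixels in synthesised image")
    return ImageScene(img, pixel_scale=pixel_scale, wrap=wrap)


def estimate_spectrum(
    image: ImageScene,
    band: tuple[float, float] = (0.01, 0.2),
    n_bins: int = 48,
) -> SpectrumEstimate:
    """Radially averaged 2D periodogram with a log-log slope fit in ``band``.

    The DC component is excluded, so the estimate is invariant to adding a
    constant to the image.
    """
    f_lo, f_hi = band
    nyquist = 0.5 / max(image.pixel_scale)
    if not (0 < f_lo < f_hi <= nyquist):
        raise ValueError(
            f"band {band} outside resolvable frequencies (Nyquist {nyquist:.4g} cyc/deg)"
        )
    power2d = np.abs(np.fft.fft2(image.pixels)) ** 2
    f = _radial_frequency_grid(image.shape, image.pixel_scale)
    mask = f > 0
    f_flat = f[mask]
    p_flat = power2d[mask]
    edges = np.geomspace(f_flat.min(), f_flat.max(), n_bins + 1)
    which = np.digitize(f_flat, edges) - 1
    which = np.clip(which, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    freq = np.bincount(which, weights=f_flat, minlength=n_bins)[occupied] / counts[occupied]
    pwr = np.bincount(which, weights=p_flat, minlength=n_bins)[occupied] / counts[occupied]
    n_modes = counts[occupied]

    in_band = (freq >= f_lo) & (freq <= f_hi) & (pwr > 0)
    if in_band.sum() < 2:
        raise ValueError("fewer than two spectral bins with power in the fit band")
    # weight bins by sqrt(mode count): sparse low-frequency bins are noisy
    slope = np.polyfit(
        np.log10(freq[in_band]), np.log10(pwr[in_band]), 1, w=np.sqrt(n_modes[in_band])
    )[0]
    return SpectrumEstimate(frequency=freq, power=pwr, fitted_slope=float(slope), band=band)


def _lowpass_transfer(f: np.ndarray, cutoff: float) -> np.ndarray:
    # Gaussian transfer, half-power (|H|^2 = 1/2) at f = cutoff
    return np.exp(-np.log(2.0) / 2.0 * (f / cutoff) ** 2)


def filter_image(
    image: ImageScene,
    mode: str,
    cutoff: float = 0.1,
    _skip_rescale: bool = False,
) -> ImageScene:
    """Spatial-frequency filter a scene.

    Modes
    -----
    ``original``
        Return the input unchanged.
    ``lowpass`` / ``highpass``
        Radially symmetric Gaussian transfer in the frequency domain with
        half-power at ``cutoff`` (cycles/degree); the highpass transfer is the
        amplitude complement of the lowpass one, so the two branches sum to
        the original image before rescaling.  Outputs are rescaled to the
        input's mean and standard deviation.
    ``whitened``
        Flatten the amplitude spectrum (unit amplitude at all non-DC
        frequencies, epsilon floor 1e-8 on the original amplitudes), keep the
        phases and the DC component, then scale so the peak pixel intensity
        matches the input's.

    ``_skip_rescale`` disables the final moment-matching step (used to verify
    exact highpass + lowpass reconstruction).
    """
    if mode == "original":
        return replace(image, pixels=image.pixels.copy())
    if mode not in ("whitened", "highpass", "lowpass"):
        raise ValueError(f"unknown filter mode {mode!r}")
    px = image.pixels
    if mode in ("whitened", "highpass") and px.std() == 0:
        raise ValueError(f"zero-variance image has no structure to {mode[:-2]}")
    spectrum = np.fft.fft2(px)
    f = _radial_frequency_grid(image.shape, image.pixel_scale)

    if mode == "whitened":
        amplitude = np.abs(spectrum)
        flat = spectrum / np.maximum(amplitude, 1e-8)
        flat[0, 0] = spectrum[0, 0]  # preserve DC
        out = np.fft.ifft2(flat).real
        if out.max() > 0:
            out = out * (px.max() / out.max())
        return replace(image, pixels=out)

    if cutoff <= 0:
        raise ValueError("cutoff must be positive for highpass/lowpass")
    h = _lowpass_transfer(f, cutoff)
    if mode == "highpass":
        h = 1.0 - h
    h[0, 0] = 1.0 if mode == "lowpass" else 0.0
    out = np.fft.ifft2(spectrum * h).real
    if _skip_rescale:
        return replace(image, pixels=out)
    sd = out.std()
    if sd == 0:
        raise ValueError("filtered image is constant; cannot match input moments")
    out = (out - out.mean()) / sd * px.std() + px.mean()
    return replace(image, pixels=out)


# ---------------------------------------------------------------------------
# I/O


def save_scene(path, scene: ImageScene, name: str = "scene") -> None:
    with h5py.File(path, "a") as h5:
        if name in h5:
            del h5[name]
        ds = h5.create_dataset(name, data=scene.pixels)
        ds.attrs["pixel_scale"] = scene.pixel_scale
        ds.attrs["wrap"] = scene.wrap


def load_scene(path, name: str = "scene") -> ImageScene:
    with h5py.File(path, "r") as h5:
        ds = h5[name]
        return ImageScene(
            ds[()],
            pixel_scale=tuple(float(v) for v in ds.attrs["pixel_scale"]),
            wrap=bool(ds.attrs["wrap"]),
        )


def export_png(path, scene: ImageScene) -> None:
    """8-bit PNG export with min-max scaling (for inspection only)."""
    from matplotlib.image import imsave

    px = scene.pixels
    span = px.max() - px.min()
    scaled = (px - px.min()) / span if span > 0 else np.zeros_like(px)
    imsave(path, scaled, cmap="gray", vmin=0.0, vmax=1.0)
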