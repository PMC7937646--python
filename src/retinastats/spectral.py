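"""Second-order image statistics: windowed power spectra and elliptical fits.

The ensemble power spectrum of N luminance patches is the average squared
magnitude of the orthonormal 2D DFT of the contrast images
``(I_i - mu_i) / mu_i * w``, where ``mu_i`` is the Hamming-weighted mean of
patch i and ``w`` a radially symmetric Hamming window (attenuates the
rectangular-grid boundary).  The orthonormal transform convention makes total
spectral power equal the windowed-contrast energy (Parseval).

Spectra are summarized two ways: a radially averaged profile with a
log-log power-law slope ``alpha`` (natural images: alpha ~ 2), and a
four-parameter oriented elliptical power law

    ``Gamma(u_r, v_r) = A / (u_r^2 + v_r^2 / b)^beta``

with rotated frequency coordinates at angle ``theta``.  ``b < 1`` elongates
the spectral ellipse along the rotated u axis (an orientation bias at image
orientation ``theta``); ``beta = 1`` is the classic isotropic ``1/f^2`` law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PowerSpectrum",
    "RadialProfile",
    "EllipticalFit",
    "radial_hamming_window",
    "mean_power_spectrum",
    "radial_average",
    "elliptical_model",
    "fit_elliptical_powerlaw",
    "synthesize_spectrum",
    "random_phase_image",
]


def radial_hamming_window(size_px: int) -> np.ndarray:
    """2D radially symmetric Hamming window, zero outside radius size/2."""
    if size_px < 8:
        raise ValueError("window size must be >= 8")
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    rho = np.hypot(xx - c, yy - c)
    rho_max = size_px / 2.0
    w = 0.54 + 0.46 * np.cos(np.pi * rho / rho_max)
    w[rho > rho_max] = 0.0
    return w


@dataclass
class PowerSpectrum:
    """DC-centered average power spectrum with frequency coordinates."""

    power: np.ndarray  # (n, n), fftshifted
    n_images: int
    window: str = "radial-hamming"

    @property
    def size(self) -> int:
        return self.power.shape[0]

    def freq_grids(self):
        """(u, v) in cycles/pixel, DC-centered, matching ``power``."""
        f = np.fft.fftshift(np.fft.fftfreq(self.size))
        u, v = np.meshgrid(f, f)
        return u, v

    def freq_magnitude(self) -> np.ndarray:
        u, v = self.freq_grids()
        return np.hypot(u, v)


def mean_power_spectrum(patches, window: np.ndarray | None = None) -> PowerSpectrum:
    """Average windowed power spectrum over an ensemble of patches.

    Accepts 2D arrays or ``ImagePatch`` objects (gray).  All patches must
    match the window size and have positive mean.
    """
    arrays = [p.gray if hasattr(p, "gray") else np.asarray(p, float) for p in patches]
    if not arrays:
        raise ValueError("empty patch list")
    n = arrays[0].shape[0]
    if window is None:
        window = radial_hamming_window(n)
    if window.shape != arrays[0].shape:
        raise ValueError("window/patch size mismatch")
    wsum = window.sum()
    acc = np.zeros_like(window)
    for img in arrays:
        if img.shape != window.shape:
            raise ValueError("patch size mismatch")
        mu = (img * window).sum() / wsum
        if mu <= 0:
            raise ValueError("patch has nonpositive weighted mean")
        x = (img - mu) / mu * window
        F = np.fft.fft2(x, norm="ortho")
        acc += np.abs(F) ** 2
    return PowerSpectrum(np.fft.fftshift(acc / len(arrays)), len(arrays))


@dataclass
class RadialProfile:
    """Radially averaged spectrum and its fitted power-law slope."""

    freqs: np.ndarray  # bin-mean radial frequency (cycles/px)
    power: np.ndarray  # bin-mean power
    alpha: float       # negative log-log slope over the fit band
    band: tuple


def radial_average(
    ps: PowerSpectrum,
    band: tuple = (0.05, 0.4),
    n_bins: int = 40,
) -> RadialProfile:
    """Radial binning of the spectrum plus a log-log slope fit.

    The slope is fit by least squares on the unbinned (log f, log P) pixel
    pairs inside the band (DC and nonpositive power excluded); the binned
    profile is returned for plotting/inspection.
    """
    f = ps.freq_magnitude()
    p = ps.power
    nz = (f > 0) & (p > 0)
    edges = np.linspace(f[nz].min(), f.max(), n_bins + 1)
    which = np.digitize(f[nz], edges) - 1
    freqs = np.array([
        f[nz][which == i].mean() if np.any(which == i) else np.nan
        for i in range(n_bins)
    ])
    power = np.array([
        p[nz][which == i].mean() if np.any(which == i) else np.nan
        for i in range(n_bins)
    ])
    sel = nz & (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        raise ValueError("no frequencies in fit band")
    slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
    return RadialProfile(freqs, power, float(-slope), band)


def elliptical_model(u, v, A, b, beta, theta, b_mode: str = "divide"):
    """Oriented elliptical power law on frequency coordinates (cycles/px)."""
    ur = u * np.cos(theta) + v * np.sin(theta)
    vr = -u * np.sin(theta) + v * np.cos(theta)
    if b_mode == "divide":
        q = ur**2 + vr**2 / b
    elif b_mode == "multiply":
        q = ur**2 + vr**2 * b
    else:
        raise ValueError(f"unknown b_mode {b_mode!r}")
    return A / np.maximum(q, 1e-12) ** beta


@dataclass
class EllipticalFit:
    """Best-fit elliptical power-law parameters for a power spectrum."""

    A: float
    b: float
    beta: float
    theta_deg: float  # reported modulo 180
    residual: float   # RMS log-power residual
    isotropic: bool   # theta unidentifiable (b at the isotropic boundary)
    b_mode: str = "divide"

    @property
    def theta_rad(self) -> float:
        return np.radians(self.theta_deg)


_BOUNDS_LO = np.array([1e-3, 1e-3, 0.5, 0.0])
_BOUNDS_HI = np.array([1.0, 1.0, 2.0, np.pi])


def fit_elliptical_powerlaw(
    ps: PowerSpectrum,
    fmax: float = 0.45,
    b_mode: str = "divide",
    isotropy_b: float = 0.98,
) -> EllipticalFit:
    """Least-squares fit of the elliptical power law in the log-power domain.

    All non-DC frequencies below ``fmax`` cycles/px enter with uniform
    weights.  The orientation is multi-started at 0/45/90/135 degrees; the
    best residual wins, ties broken toward the smallest angle.  When ``b``
    ends at the isotropic boundary the orientation is unidentifiable and the
    ``isotropic`` flag is set.
    """
    u, v = ps.freq_grids()
    f = np.hypot(u, v)
    sel = (f > 0) & (f < fmax) & (ps.power > 0)
    if not np.any(sel):
        raise ValueError("spectrum has no usable power off DC")
    uu, vv, logp = u[sel], v[sel], np.log(ps.power[sel])

    def resid(params):
        A, b, beta, theta = params
        return np.log(elliptical_model(uu, vv, A, b, beta, theta, b_mode)) - logp

    # Amplitude init from the mid-band level assuming beta ~ 1.
    fmid = 0.15
    A0 = float(np.clip(np.exp(np.interp(
        np.log(fmid), np.log(f[sel]), logp,
    )) * fmid**2, 2e-3, 0.99))
    best = None
    for th0 in np.radians([0.0, 45.0, 90.0, 135.0]):
        x0 = np.clip([A0, 0.7, 1.0, th0], _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(_BOUNDS_LO, _BOUNDS_HI))
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-12 or (
            abs(sol.cost - best.cost) <= 1e-12 and sol.x[3] < best.x[3]
        ):
            best = sol
    if best is None:
        raise RuntimeError("elliptical power-law fit failed on all starts")
    A, b, beta, theta = best.x
    rms = float(np.sqrt(2 * best.cost / len(logp)))
    return EllipticalFit(
        float(A), float(b), float(beta), float(np.degrees(theta) % 180.0),
        rms, bool(b >= isotropy_b), b_mode,
    )


def synthesize_spectrum(
    size: int, A: float, b: float, beta: float, theta_deg: float,
    noise_sd: float = 0.0, seed: int | None = None, n_average: int = 1,
    b_mode: str = "divide",
) -> PowerSpectrum:
    """Power spectrum sampled from the elliptical model (for recovery tests).

    With ``noise_sd`` > 0, each of ``n_average`` realizations multiplies the
    model by i.i.d. lognormal-ish noise ``(1 + noise_sd * eps)`` clipped
    positive, emulating averaged periodogram scatter.
    """
    f = np.fft.fftshift(np.fft.fftfreq(size))
    u, v = np.meshgrid(f, f)
    model = elliptical_model(u, v, A, b, beta, np.radians(theta_deg), b_mode)
    model[size // 2, size // 2] = 0.0
    if noise_sd <= 0:
        return PowerSpectrum(model, n_average, window="synthetic")
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(model)
    for _ in range(n_average):
        acc += model * np.clip(1.0 + noise_sd * rng.standard_normal(model.shape), 0.05, None)
    return PowerSpectrum(acc / n_average, n_average, window="synthetic")


def random_phase_image(
    size: int, exponent: float = 2.0, seed: int | None = None
) -> np.ndarray:
    """Random-phase field with isotropic power ~ 1/f^exponent, zero mean, unit SD."""
    rng = np.random.default_rng(seed)
    f = np.sqrt(
        np.add.outer(np.fft.fftfreq(size) ** 2, np.fft.fftfreq(size) ** 2)
    )
    amp = np.zeros_like(f)
    amp[f > 0] = f[f > 0] ** (-exponent / 2.0)
    spec = amp * np.exp(2j * np.pi * rng.random(f.shape))
    img = np.real(np.fft.ifft2(spec))
    return (img - img.mean()) / img.std()
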