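"""Zero-DC complex Gabor filter bank and feature extraction.

A Gabor kernel is a complex sinusoid under an isotropic Gaussian window,

    G(x, y) = 1/(2 pi sigma^2) exp(-(x^2+y^2)/(2 sigma^2))
              exp(2 pi i u (x cos(theta) + y sin(theta))),

sampled on the integer grid [-n, n]^2 (q = (2n+1)^2 taps).  Subtracting the
mean of the real taps sets the filter to zero direct current, so a constant
(illumination) image produces no response.  The default bank covers 8
orientations {0, pi/8, ..., 7 pi/8} and 5 scales; the scale values
{4, 4 sqrt 2, 8, 8 sqrt 2, 16} are wavelengths lambda in pixels with
u = 1/lambda, sigma = lambda/2 and support n = ceil(2.5 sigma).

The magnitude response sqrt(G1^2 + G2^2) of the real and imaginary responses
forms the feature vector fed to the classifier; the two-bit phase code
(x1, x2) = ([G1 >= 0], [G2 >= 0]) is available as a compact descriptor.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "GaborKernel",
    "GaborBank",
    "BankConfig",
    "FeatureVector",
    "make_kernel",
    "make_bank",
    "respond",
    "phase_code",
    "feature_vector",
    "feature_dimension",
    "DEFAULT_ORIENTATIONS",
    "DEFAULT_SCALES",
]

DEFAULT_ORIENTATIONS: tuple[float, ...] = tuple(k * math.pi / 8 for k in range(8))
DEFAULT_SCALES: tuple[float, ...] = (4.0, 4.0 * math.sqrt(2), 8.0, 8.0 * math.sqrt(2), 16.0)


@dataclass(frozen=True)
class GaborKernel:
    """One complex Gabor tap grid with its generating parameters."""

    theta: float  # orientation, radians
    u: float  # spatial frequency, cycles/pixel
    sigma: float  # Gaussian std, pixels
    n: int  # half-support; grid is (2n+1) x (2n+1)
    taps: np.ndarray  # complex (2n+1, 2n+1)

    @property
    def q(self) -> int:
        return (2 * self.n + 1) ** 2

    @property
    def wavelength(self) -> float:
        return 1.0 / self.u


def make_kernel(theta: float, u: float, sigma: float, n: int) -> GaborKernel:
    """Build one zero-DC Gabor kernel on the integer grid [-n, n]^2."""
    if sigma <= 0 or u <= 0 or n < 1:
        raise InvalidParameterError(
            f"require sigma > 0, u > 0, n >= 1; got {(theta, u, sigma, n)}"
        )
    coords = np.arange(-n, n + 1, dtype=float)
    x = coords[None, :]  # column direction
    y = coords[:, None]  # row direction
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2)) / (2.0 * math.pi * sigma**2)
    phase = 2.0 * math.pi * u * (x * math.cos(theta) + y * math.sin(theta))
    taps = envelope * np.exp(1j * phase)
    taps = taps - taps.real.mean()  # zero direct current
    return GaborKernel(theta=theta, u=u, sigma=sigma, n=n, taps=taps)


@dataclass(frozen=True)
class BankConfig:
    """Filter-bank configuration; defaults give the standard 40-kernel bank."""

    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    scales: tuple[float, ...] = DEFAULT_SCALES  # wavelengths lambda, pixels
    sigma_per_lambda: float = 0.5  # sigma = lambda * this
    support_per_sigma: float = 2.5  # n = ceil(sigma * this)
    downsample: int = 4  # grid step rho for feature vectors

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise InvalidParameterError("downsample must be >= 1")
        if any(s <= 0 for s in self.scales):
            raise InvalidParameterError("scales (wavelengths) must be positive")

    def hash(self) -> str:
        payload = json.dumps(
            {
                "orientations": list(self.orientations),
                "scales": list(self.scales),
                "sigma_per_lambda": self.sigma_per_lambda,
                "support_per_sigma": self.support_per_sigma,
                "downsample": self.downsample,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GaborBank:
    """Ordered kernel list, scale-major then orientation-minor."""

    config: BankConfig
    kernels: list[GaborKernel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def max_half_support(self) -> int:
        return max(k.n for k in self.kernels)


def make_bank(config: BankConfig | None = None) -> GaborBank:
    """Build the filter bank: Cartesian product of scales and orientations."""
    cfg = config or BankConfig()
    kernels = []
    for lam in cfg.scales:
        sigma = cfg.sigma_per_lambda * lam
        n = max(1, math.ceil(cfg.support_per_sigma * sigma))
        for theta in cfg.orientations:
            kernels.append(make_kernel(theta, 1.0 / lam, sigma, n))
    return GaborBank(config=cfg, kernels=kernels)


def respond(image: np.ndarray, kernel: GaborKernel) -> tuple[np.ndarray, np.ndarray]:
    """Valid-region convolution with the real and imaginary tap grids."""
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("image must be 2D")
    k = 2 * kernel.n + 1
    if img.shape[0] < k or img.shape[1] < k:
        raise InvalidInputError(
            f"image {img.shape} smaller than kernel ({k}x{k})"
        )
    real = signal.convolve2d(img, kernel.taps.real, mode="valid")
    imag = signal.convolve2d(img, kernel.taps.imag, mode="valid")
    return real, imag


def phase_code(real, imag) -> tuple:
    """Two-bit phase quantization: x1 = [real >= 0], x2 = [imag >= 0]."""
    x1 = (np.asarray(real) >= 0).astype(np.uint8)
    x2 = (np.asarray(imag) >= 0).astype(np.uint8)
    if x1.ndim == 0:
        return int(x1), int(x2)
    return x1, x2


@dataclass
class FeatureVector:
    """Flat Gabor magnitude descriptor with provenance metadata."""

    values: np.ndarray
    source_id: str = ""
    bank_hash: str = ""


def _center_crop(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    dr = (arr.shape[0] - shape[0]) // 2
    dc = (arr.shape[1] - shape[1]) // 2
    return arr[dr : dr + shape[0], dc : dc + shape[1]]


def feature_vector(
    image: np.ndarray,
    bank: GaborBank,
    downsample: int | None = None,
    source_id: str = "",
    normalize: bool = True,
) -> FeatureVector:
    """Magnitude feature vector of ``image`` under the bank.

    Per kernel the magnitude map sqrt(real^2 + imag^2) is computed on the
    valid convolution region, center-cropped to the smallest valid region in
    the bank (so every kernel contributes the same grid), subsampled on a
    ``downsample``-strided grid, concatenated scale-major, and z-score
    normalized over the whole vector.
    """
    rho = downsample if downsample is not None else bank.config.downsample
    if rho < 1:
        raise InvalidParameterError("downsample must be >= 1")
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    n_max = bank.max_half_support
    out_shape = (img.shape[0] - 2 * n_max, img.shape[1] - 2 * n_max)
    if out_shape[0] < 1 or out_shape[1] < 1:
        raise InvalidInputError(
            f"image {img.shape} smaller than the largest kernel "
            f"({2 * n_max + 1} px support)"
        )
    parts = []
    for kernel in bank.kernels:
        real, imag = respond(img, kernel)
        mag = np.hypot(real, imag)
        mag = _center_crop(mag, out_shape)
        parts.append(mag[::rho, ::rho].ravel())
    values = np.concatenate(parts)
    if normalize:
        std = values.std()
        values = (values - values.mean()) / (std if std > 0 else 1.0)
    return FeatureVector(values=values, source_id=source_id, bank_hash=bank.config.hash())


def feature_dimension(bank: GaborBank, image_shape: tuple[int, int],
                      downsample: int | None = None) -> int:
    """Descriptor length for an image of ``image_shape`` under ``bank``."""
    rho = downsample if downsample is not None else bank.config.downsample
    n_max = bank.max_half_support
    h = image_shape[0] - 2 * n_max
    w = image_shape[1] - 2 * n_max
    if h < 1 or w < 1:
        raise InvalidInputError("image smaller than the largest kernel")
    return len(bank) * math.ceil(h / rho) * math.ceil(w / rho)
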