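"""Synthetic single-particle image formation.

Each particle is one noisy 2-D projection of the phantom in one
conformation and one viewing orientation.  Because the phantom is a
Gaussian-blob mixture, projection is analytic: a 3-D isotropic Gaussian of
amplitude ``a`` and width ``sigma`` projects along any axis to a 2-D
Gaussian of the same ``sigma`` with amplitude ``a * sigma * sqrt(2 pi)``.

Orientations use the Relion ZYZ Euler convention (rot, tilt, psi):
``A = Rz(psi) @ Ry(tilt) @ Rz(rot)`` maps reference-frame coordinates into
the projection frame, and the image is the line integral along the
projection frame's z axis.

Noise is additive white Gaussian, calibrated so the stack-wide
signal-variance / noise-variance ratio matches the target SNR (SNR = 1 by
default).  An optional phase CTF stage exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .landscape import EnergyLandscape, sample_conformations
from .phantom import TwoBodyPhantom, conformed_blobs

__all__ = [
    "ParticleMetadata",
    "ParticleStack",
    "project",
    "calibrate_noise_sigma",
    "add_noise",
    "generate_dataset",
    "euler_to_matrix",
]

# per-particle substream identifiers (mixed into the RNG seed sequence)
_STREAM_ORIENT = 0
_STREAM_NOISE = 1


@dataclass(frozen=True)
class ParticleMetadata:
    """Ground truth for one particle."""

    index: int
    euler: tuple[float, float, float]  # (rot, tilt, psi) degrees, ZYZ
    cc: tuple[float, float]
    well_label: int
    noise_sigma: float
    seed_offset: int
    defocus: float = 0.0  # A; 0 when the CTF stage is off


@dataclass
class ParticleStack:
    """An image stack plus per-particle ground-truth metadata."""

    images: np.ndarray  # (n, box, box) float32
    pixel_size: float  # A
    metadata: list[ParticleMetadata]
    snr_target: float
    global_seed: int

    def __post_init__(self) -> None:
        if self.images.shape[0] != len(self.metadata):
            raise ValueError("images and metadata length mismatch")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("stack contains non-finite pixels")

    @property
    def n_particles(self) -> int:
        return self.images.shape[0]

    @property
    def box_size(self) -> int:
        return self.images.shape[1]


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Relion projection matrix A = Rz(psi) @ Ry(tilt) @ Rz(rot) (degrees)."""
    return Rotation.from_euler("ZYZ", [psi, tilt, rot], degrees=True).as_matrix()


def _axis_coords(box_size: int) -> np.ndarray:
    return np.arange(box_size, dtype=float) - box_size / 2.0 + 0.5


def project(phantom: TwoBodyPhantom, cc, euler) -> np.ndarray:
    """Noise-free orthographic projection of the conformed phantom.

    Parameters
    ----------
    cc : (cc1, cc2) in [0,1]^2
    euler : (rot, tilt, psi) degrees, ZYZ

    Returns a (box, box) float array indexed (y, x); pixel values are line
    integrals of the density in voxel-length units.
    """
    blobs = conformed_blobs(phantom, cc)
    a_mat = euler_to_matrix(*euler)
    centers = blobs.centers @ a_mat.T  # coordinates in the projection frame
    ax = _axis_coords(phantom.box_size)
    img = np.zeros((phantom.box_size, phantom.box_size))
    amp2d = blobs.amplitudes * blobs.sigmas * np.sqrt(2.0 * np.pi)
    for c, s, a in zip(centers, blobs.sigmas, amp2d):
        gx = np.exp(-((ax - c[0]) ** 2) / (2 * s * s))
        gy = np.exp(-((ax - c[1]) ** 2) / (2 * s * s))
        img += a * np.outer(gy, gx)
    return img


def calibrate_noise_sigma(noise_free_images: np.ndarray, snr_target: float, mask: str = "frame") -> float:
    """Noise standard deviation achieving the target SNR for a stack.

    SNR is defined as pooled signal variance over noise variance; by the
    default whole-``frame`` convention the signal variance pools every
    pixel of every image.  ``mask="circular"`` restricts signal pixels to
    the inscribed circle of the frame instead.
    """
    imgs = np.asarray(noise_free_images, dtype=float)
    if imgs.ndim == 2:
        imgs = imgs[None, ...]
    if imgs.ndim != 3:
        raise ValueError("expected an image or a stack of images")
    if snr_target <= 0:
        raise ValueError("snr_target must be > 0")
    if mask == "frame":
        pix = imgs.reshape(-1)
    elif mask == "circular":
        box = imgs.shape[-1]
        ax = _axis_coords(box)
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        inside = (yy**2 + xx**2) <= (box / 2.0) ** 2
        pix = imgs[..., inside].reshape(-1)
    else:
        raise ValueError(f"unknown mask convention {mask!r}")
    var = float(np.var(pix))
    if var == 0.0:
        raise ValueError("signal variance is zero; cannot calibrate noise")
    return float(np.sqrt(var / snr_target))


def add_noise(image: np.ndarray, sigma: float, seed) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian pixel noise, deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.array(image, copy=True)
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma, image.shape)


def _ctf_multiply(image: np.ndarray, defocus: float, pixel_size: float, voltage_kv: float = 300.0, amplitude_contrast: float = 0.1) -> np.ndarray:
    """Apply a two-parameter phase CTF in Fourier space (optional stage)."""
    wavelength = 12.2639 / np.sqrt(voltage_kv * 1e3 + 0.97845e-6 * (voltage_kv * 1e3) ** 2)  # A
    box = image.shape[0]
    freq = np.fft.fftfreq(box, d=pixel_size)
    k2 = freq[:, None] ** 2 + freq[None, :] ** 2
    chi = np.pi * wavelength * defocus * k2
    ctf = -(np.sqrt(1 - amplitude_contrast**2) * np.sin(chi) + amplitude_contrast * np.cos(chi))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * ctf))


def _sample_orientation(rng: np.random.Generator) -> tuple[float, float, float]:
    """Haar-uniform SO(3) orientation via a random unit quaternion,
    returned as ZYZ (rot, tilt, psi) degrees."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    psi, tilt, rot = Rotation.from_quat(q).as_euler("ZYZ", degrees=True)
    return float(rot), float(tilt), float(psi)


def generate_dataset(
    landscape: EnergyLandscape,
    phantom: TwoBodyPhantom,
    n: int,
    snr_target: float = 1.0,
    seed: int = 0,
    orientation_mode: str = "uniform",
    ctf: bool = False,
    ctf_defocus_range: tuple[float, float] = (5000.0, 25000.0),
    noise_mask: str = "frame",
) -> ParticleStack:
    """Generate a fully labelled synthetic particle stack.

    Conformations are Boltzmann samples from the landscape; orientations
    are Haar-uniform over SO(3) (``orientation_mode="uniform"``) or a
    single identity view (``"fixed"``).  Noise sigma is calibrated once on
    the noise-free pass so the whole stack meets ``snr_target``, then each
    particle receives its own deterministic noise stream derived from
    ``(seed, index)`` — generation is order-independent.

    ``snr_target=np.inf`` yields a clean stack.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if orientation_mode not in ("uniform", "fixed"):
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")

    samples = sample_conformations(landscape, n, seed)
    box = phantom.box_size
    clean = np.empty((n, box, box), dtype=float)
    eulers: list[tuple[float, float, float]] = []
    defoci = np.zeros(n)
    for i, s in enumerate(samples):
        if orientation_mode == "uniform":
            rng_o = np.random.default_rng([seed, i, _STREAM_ORIENT])
            euler = _sample_orientation(rng_o)
            if ctf:
                defoci[i] = rng_o.uniform(*ctf_defocus_range)
        else:
            euler = (0.0, 0.0, 0.0)
            if ctf:
                defoci[i] = np.random.default_rng([seed, i, _STREAM_ORIENT]).uniform(*ctf_defocus_range)
        eulers.append(euler)
        img = project(phantom, s.cc, euler)
        if ctf:
            img = _ctf_multiply(img, defoci[i], phantom.voxel_size)
        clean[i] = img

    if np.isinf(snr_target):
        sigma = 0.0
    else:
        sigma = calibrate_noise_sigma(clean, snr_target, mask=noise_mask)

    images = np.empty((n, box, box), dtype=np.float32)
    meta: list[ParticleMetadata] = []
    for i, s in enumerate(samples):
        noisy = add_noise(clean[i], sigma, [seed, i, _STREAM_NOISE])
        images[i] = noisy.astype(np.float32)
        meta.append(
            ParticleMetadata(
                index=i,
                euler=eulers[i],
                cc=s.cc,
                well_label=s.well_label,
                noise_sigma=sigma,
                seed_offset=i,
                defocus=float(defoci[i]),
            )
        )
    return ParticleStack(
        images=images,
        pixel_size=phantom.voxel_size,
        metadata=meta,
        snr_target=snr_target,
        global_seed=seed,
    )
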