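"""Scan simulation: protocol resampling, NEX averaging, and magnitude noise.

A scan of the ground-truth phantom applies, in order:

1. a rigid repositioning shift (test-retest: the phantom is taken out of the
   scanner and put back, so the second scan sees it slightly translated);
2. in-plane resampling to the protocol's pixel size, FOV / matrix mm, with
   linear interpolation on a matrix x matrix grid centered on the phantom;
3. through-plane box averaging into slices of the protocol's thickness
   (the partial-volume model of slice-selective acquisition);
4. magnitude noise: each voxel is replaced by |s + n_r + i n_i| with
   n_r, n_i ~ N(0, sigma_eff) and sigma_eff = noise_sigma / sqrt(NEX).
   Averaging NEX independent complex acquisitions scales the complex noise
   SD by 1/sqrt(NEX); at the phantom's high signal-to-noise the magnitude
   is approximately Gaussian, while pure-background voxels are Rayleigh.
   Both regimes keep the SD proportional to sigma_eff, so the 1/sqrt(NEX)
   law holds everywhere.

Scanner hardware differences are modeled as configured (noise level,
intensity scale) pairs, not physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image import ImageVolume

__all__ = [
    "ScanProtocol",
    "SCANNER_PRESETS",
    "simulate_scan",
    "one_factor_grid",
    "DEFAULT_FAMILIES",
]

#: (noise_sigma in signal units, multiplicative intensity scale)
SCANNER_PRESETS: dict[str, tuple[float, float]] = {
    "siemens": (4.0, 1.0),
    "philips": (5.0, 0.92),
}

#: One-factor-at-a-time study families: parameter -> (settings, default).
DEFAULT_FAMILIES: dict[str, tuple[tuple[float, ...], float]] = {
    "nex": ((1, 2, 3), 2),
    "slice_thickness": ((2.0, 3.0, 4.0), 3.0),
    "fov": ((192.0, 256.0, 500.0), 256.0),
}


@dataclass(frozen=True)
class ScanProtocol:
    """One acquisition condition.

    ``fov / matrix`` sets the in-plane pixel size in mm.  ``noise_sigma`` is
    the complex-channel noise SD at NEX = 1, in signal units;
    ``intensity_scale`` models scanner-specific signal gain.
    """

    sequence: str = "T1like"
    nex: int = 2
    slice_thickness: float = 3.0
    fov: float = 256.0
    matrix: int = 192
    scanner_tag: str = "siemens"
    noise_sigma: float = 4.0
    intensity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequence not in ("T1like", "T2like"):
            raise ValueError(f"unknown sequence {self.sequence!r}")
        if self.nex < 1:
            raise ValueError("nex must be >= 1")
        if self.slice_thickness <= 0 or self.fov <= 0 or self.matrix < 1:
            raise ValueError("slice_thickness, fov and matrix must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def pixel_size(self) -> float:
        """In-plane pixel size in mm (fov / matrix, exact)."""
        return self.fov / self.matrix

    def condition_key(self) -> str:
        return (
            f"{self.scanner_tag}|{self.sequence}|nex={self.nex}"
            f"|st={self.slice_thickness:g}|fov={self.fov:g}|mat={self.matrix}"
        )

    @classmethod
    def for_scanner(cls, scanner_tag: str, **kwargs) -> "ScanProtocol":
        """A protocol with the scanner preset's noise and intensity scale."""
        sigma, scale = SCANNER_PRESETS[scanner_tag]
        kwargs.setdefault("noise_sigma", sigma)
        kwargs.setdefault("intensity_scale", scale)
        return cls(scanner_tag=scanner_tag, **kwargs)


def _rigid_shift(truth: ImageVolume, shift_mm: tuple[float, float, float]) -> np.ndarray:
    shift = np.asarray(shift_mm, dtype=float)
    if shift.shape != (3,) or not np.isfinite(shift).all():
        raise ValueError(f"reposition shift must be 3 finite mm components, got {shift_mm}")
    if not shift.any():
        return truth.data
    shift_vox = shift / np.asarray(truth.spacing)
    return ndimage.shift(truth.data, shift_vox, order=1, mode="constant", cval=0.0)


def _inplane_resample(
    data: np.ndarray, truth: ImageVolume, protocol: ScanProtocol
) -> tuple[np.ndarray, tuple[float, float]]:
    """Sample a matrix x matrix in-plane grid (pixel = fov/matrix) centered on the volume."""
    p = protocol.pixel_size
    eps = 1e-9
    if p < min(truth.spacing[0], truth.spacing[1]) - eps:
        raise ValueError(
            f"target pixel {p:.3f} mm is finer than the truth grid "
            f"{truth.spacing[:2]}; simulate the truth at higher resolution"
        )
    m = protocol.matrix
    ext = [truth.spacing[a] * truth.shape[a] for a in range(2)]
    center = [truth.origin[a] - truth.spacing[a] / 2 + ext[a] / 2 for a in range(2)]
    # world coordinates of output pixel centers
    out_x = center[0] - protocol.fov / 2 + p * (np.arange(m) + 0.5)
    out_y = center[1] - protocol.fov / 2 + p * (np.arange(m) + 0.5)
    ix = (out_x - truth.origin[0]) / truth.spacing[0]
    iy = (out_y - truth.origin[1]) / truth.spacing[1]
    IX, IY = np.meshgrid(ix, iy, indexing="ij")
    nz = data.shape[2]
    out = np.empty((m, m, nz))
    coords = np.stack([IX.ravel(), IY.ravel()])
    for k in range(nz):  # linear interpolation per axial slice
        out[:, :, k] = ndimage.map_coordinates(
            data[:, :, k], coords, order=1, mode="constant", cval=0.0
        ).reshape(m, m)
    return out, (float(out_x[0]), float(out_y[0]))


def _slice_average(
    data: np.ndarray, truth: ImageVolume, thickness: float
) -> tuple[np.ndarray, float]:
    """Box-average truth z-samples into slices of the given thickness."""
    dz = truth.spacing[2]
    if thickness < dz - 1e-9:
        raise ValueError(f"slice thickness {thickness} mm finer than truth z-grid {dz} mm")
    extent = dz * truth.shape[2]
    n_slices = math.ceil(extent / thickness - 1e-9)
    z0 = truth.origin[2] - dz / 2  # volume start in world z
    zs = truth.voxel_centers(2)
    out = np.empty(data.shape[:2] + (n_slices,))
    centers = np.empty(n_slices)
    for k in range(n_slices):
        lo, hi = z0 + k * thickness, z0 + (k + 1) * thickness
        sel = (zs >= lo) & (zs < hi)
        out[:, :, k] = data[:, :, sel].mean(axis=2)
        centers[k] = (lo + min(hi, z0 + extent)) / 2
    return out, float(centers[0])


def _magnitude_noise(
    data: np.ndarray, sigma_eff: float, rng: np.random.Generator
) -> np.ndarray:
    if sigma_eff == 0:
        return data
    nr = rng.normal(0.0, sigma_eff, data.shape)
    ni = rng.normal(0.0, sigma_eff, data.shape)
    return np.sqrt((data + nr) ** 2 + ni**2)


def simulate_scan(
    truth: ImageVolume,
    protocol: ScanProtocol,
    reposition: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int | None = None,
) -> ImageVolume:
    """Simulate one acquisition of the ground-truth volume under a protocol.

    ``reposition`` is a rigid translation in mm applied to the object before
    sampling.  ``seed`` drives the noise; it is required whenever
    ``protocol.noise_sigma > 0`` (no implicit randomness).
    """
    if protocol.noise_sigma > 0 and seed is None:
        raise ValueError("a seed is required when noise_sigma > 0")
    shifted = _rigid_shift(truth, reposition)
    inplane, (x0, y0) = _inplane_resample(shifted, truth, protocol)
    averaged, zc0 = _slice_average(inplane, truth, protocol.slice_thickness)
    signal = averaged * protocol.intensity_scale
    sigma_eff = protocol.noise_sigma / math.sqrt(protocol.nex)
    if sigma_eff > 0:
        rng = np.random.default_rng(seed)
        signal = _magnitude_noise(signal, sigma_eff, rng)
    p = protocol.pixel_size
    return ImageVolume(
        signal, spacing=(p, p, protocol.slice_thickness), origin=(x0, y0, zc0)
    )


def one_factor_grid(
    base: ScanProtocol,
    families: dict[str, tuple[tuple[float, ...], float]] | None = None,
) -> tuple[dict[str, ScanProtocol], dict[str, list[str]]]:
    """Build the default-anchored one-factor-at-a-time protocol grid.

    One parameter family at a time is swept over its settings while the other
    parameters stay at their defaults; the all-default condition is shared
    between families, so three 3-level families yield 7 distinct conditions.

    Returns ``(conditions, family_members)``: unique protocols keyed by
    condition, and for each family the ordered condition keys of its sweep.
    """
    families = dict(DEFAULT_FAMILIES if families is None else families)
    defaults = {fam: default for fam, (_, default) in families.items()}
    conditions: dict[str, ScanProtocol] = {}
    members: dict[str, list[str]] = {}
    for fam, (settings, _) in families.items():
        keys = []
        for value in settings:
            params = dict(defaults)
            params[fam] = value
            if "nex" in params:
                params["nex"] = int(params["nex"])
            proto = replace(base, **params)
            key = proto.condition_key()
            conditions.setdefault(key, proto)
            keys.append(key)
        members[fam] = keys
    return conditions, members
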