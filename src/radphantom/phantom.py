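"""Digital radiomics phantom: a water-filled box with 20 textured cylindrical inserts.

The physical object emulated here is a rectangular acrylic phantom
(145 x 178 x 103 mm) holding 20 cylinders (24 mm diameter, full-length in z),
each filled with a different material so that the inserts span a wide range
of mean signal and texture.  Material chemistry is abstracted into three
texture parameters per insert: a base signal intensity per sequence
(T1-like / T2-like), a texture amplitude (the SD of a zero-mean stationary
random field added on top of the base intensity), and a correlation length
(the Gaussian kernel scale, in mm, of that field).  Texture fields are
white noise convolved with a Gaussian kernel and rescaled so their in-insert
SD equals the requested amplitude.

Ground truth is rasterized at 1 mm isotropic resolution by default; all
randomness is driven by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import ImageVolume, ROIMask

__all__ = [
    "MaterialSpec",
    "PhantomSpec",
    "PopulationBounds",
    "build_phantom",
    "make_cylindrical_roi",
    "default_materials",
    "default_phantom_spec",
    "synth_population_bounds",
]


@dataclass(frozen=True)
class MaterialSpec:
    """Texture description of one phantom insert material.

    base_intensity maps sequence tag -> mean signal (arbitrary units, > 0);
    texture_amplitude is the SD of the correlated texture field (>= 0);
    texture_correlation_length is the Gaussian kernel sigma in mm (> 0).
    """

    material_id: int
    base_intensity: dict[str, float]
    texture_amplitude: float
    texture_correlation_length: float

    def __post_init__(self) -> None:
        if not 1 <= self.material_id <= 20:
            raise ValueError(f"material_id must be in 1..20, got {self.material_id}")
        if any(v <= 0 for v in self.base_intensity.values()):
            raise ValueError("base_intensity values must be > 0")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")
        if self.texture_correlation_length <= 0:
            raise ValueError("texture_correlation_length must be > 0")

    def intensity_for(self, sequence: str) -> float:
        try:
            return self.base_intensity[sequence]
        except KeyError:
            raise KeyError(
                f"material {self.material_id} has no intensity for sequence {sequence!r}"
            ) from None


def default_materials(n: int = 20) -> list[MaterialSpec]:
    """Twenty insert materials spanning a wide range of mean signal and texture.

    The T1-like and T2-like intensity columns are independent orderings so
    the two sequences produce different contrast between inserts, mimicking
    materials whose relaxation properties differ per weighting.  Amplitudes
    run from perfectly homogeneous (0) to strongly textured (30% of a typical
    base intensity); correlation lengths from fine (1 mm) to coarse (6 mm).
    """
    if n != 20:
        raise ValueError("the phantom design uses exactly 20 materials")
    mats = []
    for i in range(1, 21):
        # deterministic, spread-out parameter ladder; pairwise distinct
        t1 = 60.0 + 22.0 * ((i * 7) % 20)  # 60 .. 478, permuted order
        t2 = 60.0 + 22.0 * ((i * 13) % 20)
        # amplitude 2%..25% of the weaker base keeps the truth strictly positive
        amp = (0.02 + 0.012 * ((i * 3) % 20)) * min(t1, t2)
        corr = 1.0 + 0.25 * ((i * 11) % 20)  # 1 .. 5.75 mm
        mats.append(
            MaterialSpec(
                material_id=i,
                base_intensity={"T1like": t1, "T2like": t2},
                texture_amplitude=amp,
                texture_correlation_length=corr,
            )
        )
    return mats


def _default_insert_centers(
    outer: tuple[float, float, float], n_x: int = 4, n_y: int = 5
) -> list[tuple[float, float, float]]:
    """A 4 x 5 in-plane lattice of insert centers, centered in the box."""
    cx = [(j + 0.5) * outer[0] / n_x for j in range(n_x)]
    cy = [(j + 0.5) * outer[1] / n_y for j in range(n_y)]
    cz = outer[2] / 2.0
    return [(x, y, cz) for y in cy for x in cx]


@dataclass
class PhantomSpec:
    """Geometry and material loading of the phantom.

    Defaults follow the physical design: outer box 145 x 178 x 103 mm,
    20 inserts of 24 mm diameter running the full 103 mm length.
    """

    outer_dimensions: tuple[float, float, float] = (145.0, 178.0, 103.0)
    insert_diameter: float = 24.0
    insert_length: float = 103.0
    insert_centers: list[tuple[float, float, float]] = field(default_factory=list)
    background_intensity: float = 20.0
    materials: list[MaterialSpec] = field(default_factory=default_materials)
    resolution: float = 1.0  # mm, isotropic rasterization grid

    def __post_init__(self) -> None:
        if not self.insert_centers:
            self.insert_centers = _default_insert_centers(self.outer_dimensions)
        if len(self.materials) != 20 or len(self.insert_centers) != 20:
            raise ValueError("the phantom holds exactly 20 inserts")
        if self.insert_diameter <= 0 or self.insert_length <= 0:
            raise ValueError("insert dimensions must be positive")
        self._check_geometry()

    def _check_geometry(self) -> None:
        r = self.insert_diameter / 2.0
        ox, oy, oz = self.outer_dimensions
        for cx, cy, cz in self.insert_centers:
            if not (r <= cx <= ox - r and r <= cy <= oy - r):
                raise ValueError(
                    f"insert at ({cx:.1f}, {cy:.1f}) extends outside the outer box"
                )
            if cz - self.insert_length / 2 < -1e-9 or cz + self.insert_length / 2 > oz + 1e-9:
                raise ValueError("insert length extends outside the outer box in z")
        centers = np.asarray(self.insert_centers)[:, :2]
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if (d < self.insert_diameter).any():
            raise ValueError("inserts overlap in plane")


def default_phantom_spec() -> PhantomSpec:
    return PhantomSpec()


def _correlated_texture(
    shape: tuple[int, int, int], sigma_vox: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean stationary field: white noise * Gaussian kernel, SD = amplitude."""
    white = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = fieldv.std()
    if sd == 0:  # pragma: no cover - degenerate only for pathological shapes
        return np.zeros(shape)
    return amplitude * (fieldv - fieldv.mean()) / sd


def build_phantom(
    spec: PhantomSpec, seed: int, sequence: str = "T1like"
) -> tuple[ImageVolume, list[ROIMask]]:
    """Rasterize the noise-free ground-truth phantom volume and its insert masks.

    Each insert region is filled with its material's base intensity plus a
    zero-mean correlated texture field scaled to the material's amplitude.
    The texture field of each insert gets its own seed derived from ``seed``
    so inserts are statistically independent.

    Returns the volume and the 20 insert label masks (labels = material ids).
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    res = spec.resolution
    shape = tuple(int(round(d / res)) for d in spec.outer_dimensions)
    spacing = (res, res, res)
    origin = (res / 2.0, res / 2.0, res / 2.0)  # voxel centers
    vol = np.full(shape, float(spec.background_intensity))
    grid = ImageVolume(vol, spacing, origin)

    xs = grid.voxel_centers(0)
    ys = grid.voxel_centers(1)
    zs = grid.voxel_centers(2)
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(spec.materials))

    masks: list[ROIMask] = []
    r2 = (spec.insert_diameter / 2.0) ** 2
    occupied = np.zeros(shape, dtype=bool)
    for mat, center, child in zip(spec.materials, spec.insert_centers, child_seeds):
        cx, cy, cz = center
        in_plane = (X - cx) ** 2 + (Y - cy) ** 2 <= r2
        in_z = np.abs(zs - cz) <= spec.insert_length / 2.0
        mask = in_plane[:, :, None] & in_z[None, None, :]
        if (occupied & mask).any():
            raise ValueError("inserts overlap after rasterization")
        occupied |= mask
        base = mat.intensity_for(sequence)
        if mat.texture_amplitude > 0:
            rng = np.random.default_rng(child)
            tex = _correlated_texture(
                shape, mat.texture_correlation_length / res, mat.texture_amplitude, rng
            )
            vol[mask] = base + tex[mask]
        else:
            vol[mask] = base
        masks.append(ROIMask(mask, mat.material_id, spacing, origin))
    return ImageVolume(vol, spacing, origin), masks


def make_cylindrical_roi(
    center: tuple[float, float, float],
    diameter: float,
    height: float,
    grid: ImageVolume,
    label: int = 1,
) -> ROIMask:
    """Rasterize a z-axis-aligned cylinder onto a volume's grid.

    A voxel belongs to the ROI iff its center lies inside the closed
    cylinder.  The analysis ROIs of the study are 18 mm diameter x 100 mm
    (regular) or 12 mm diameter (small), centered on each insert.
    """
    if diameter <= 0 or height <= 0:
        raise ValueError("diameter and height must be positive")
    cx, cy, cz = (float(c) for c in center)
    xs, ys, zs = (grid.voxel_centers(a) for a in range(3))
    lo = (cx - diameter / 2, cy - diameter / 2, cz - height / 2)
    hi = (cx + diameter / 2, cy + diameter / 2, cz + height / 2)
    for a, (axis_lo, axis_hi) in enumerate(zip(lo, hi)):
        ext_lo = grid.origin[a] - grid.spacing[a] / 2
        ext_hi = grid.origin[a] + grid.spacing[a] * (grid.shape[a] - 0.5)
        if axis_lo < ext_lo - 1e-9 or axis_hi > ext_hi + 1e-9:
            raise ValueError(
                f"cylinder extends outside the grid along axis {a}: "
                f"[{axis_lo:.1f}, {axis_hi:.1f}] vs [{ext_lo:.1f}, {ext_hi:.1f}]"
            )
    in_plane = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= (diameter / 2) ** 2
    in_z = np.abs(zs - cz) <= height / 2
    mask = in_plane[:, :, None] & in_z[None, None, :]
    if not mask.any():
        raise ValueError("cylinder contains no voxel centers")
    return ROIMask(mask, label, grid.spacing, grid.origin)


class PopulationBounds:
    """Per-feature reference-population envelopes: mean +/- 2 SD.

    Stands in for a patient cohort whose lesion feature values define the
    plausible range a phantom material should fall in to be considered a
    suitable surrogate for that feature.
    """

    def __init__(self, means: dict[str, float], sds: dict[str, float]):
        if set(means) != set(sds):
            raise ValueError("means and sds must cover the same features")
        if any(s < 0 for s in sds.values()):
            raise ValueError("population SDs must be >= 0")
        self.means = dict(means)
        self.sds = dict(sds)

    def __contains__(self, feature: str) -> bool:
        return feature in self.means

    @property
    def feature_names(self) -> list[str]:
        return list(self.means)

    def lower(self, feature: str) -> float:
        return self.means[feature] - 2.0 * self.sds[feature]

    def upper(self, feature: str) -> float:
        return self.means[feature] + 2.0 * self.sds[feature]

    def contains_value(self, feature: str, value: float) -> bool:
        """Closed-interval membership in [mean - 2 SD, mean + 2 SD]."""
        if feature not in self.means:
            raise KeyError(f"no population bounds for feature {feature!r}")
        return self.lower(feature) <= value <= self.upper(feature)


def synth_population_bounds(
    feature_names: list[str],
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
    reference_values: "object | None" = None,
    sd_inflation: float = 1.0,
    seed: int | None = None,
) -> PopulationBounds:
    """Build synthetic population bounds for the suitability test.

    Either pass explicit per-feature ``means``/``sds``, or a
    ``reference_values`` DataFrame (rows = subjects/ROIs, columns include the
    feature names) from which mean and SD are estimated per feature, with the
    SD optionally inflated to emulate a heterogeneous patient cohort.  When
    sampling-based jitter is requested (``seed`` with reference values), a
    reproducible perturbation of the means by 0.1 SD emulates cohort-vs-phantom
    mismatch.
    """
    if means is not None or sds is not None:
        if means is None or sds is None:
            raise ValueError("pass both means and sds, or neither")
        missing = [f for f in feature_names if f not in means]
        if missing:
            raise KeyError(f"no mean/sd provided for features: {missing[:5]}")
        return PopulationBounds(
            {f: float(means[f]) for f in feature_names},
            {f: float(sds[f]) for f in feature_names},
        )
    if reference_values is None:
        raise ValueError("need explicit means/sds or a reference table")
    import pandas as pd  # local import keeps module load light

    ref = pd.DataFrame(reference_values)
    missing = [f for f in feature_names if f not in ref.columns]
    if missing:
        raise KeyError(f"reference table lacks features: {missing[:5]}")
    mu = ref[feature_names].mean()
    sd = ref[feature_names].std(ddof=1).fillna(0.0) * float(sd_inflation)
    if seed is not None:
        rng = np.random.default_rng(seed)
        mu = mu + 0.1 * sd * rng.standard_normal(len(feature_names))
    return PopulationBounds(
        {f: float(mu[f]) for f in feature_names}, {f: float(sd[f]) for f in feature_names}
    )
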