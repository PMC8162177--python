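"""Synthetic generative 3D face space.

Emulates the structure of a generative morphable face model: each face is a
categorical average (one per ethnicity x sex cell at a fixed age) plus an
identity residual expressed in orthonormal bases — one basis for 3D shape
(vertex displacements) and one basis per spatial-frequency band for
complexion (L*a*b* texture deviations).  Residual coefficients are sampled
independently per dimension with a decaying scale, mimicking a PCA spectrum.

The same residual coefficient set can be rendered against any cell average,
so stimuli built on different ethnic averages share identical identity
variation and differ only by the constant average difference.

Nothing here is fitted to real scans; the geometry (an ellipsoidal head with
smooth per-cell deformations) exists to give the bases and averages realistic
structure, not to look like a face.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .errors import InvalidConfigError, InvalidInputError

VIEWPOINTS = (-30, 0, 30)


@dataclass
class SpaceConfig:
    """Dimensions and sampling scales of the generative space.

    Defaults are the desk scale used throughout the package; the full-scale
    configuration (4,735 vertices, 467 shape dims, 800x600 texture, 467x5
    complexion dims) is expressible but slow to build.
    """

    n_vertices: int = 500
    n_shape_dims: int = 40
    n_complexion_dims: int = 40
    n_sf_bands: int = 5
    texture_shape: tuple[int, int] = (60, 80)  # (height, width)
    ethnicities: tuple[str, ...] = ("WE", "EA")
    sexes: tuple[str, ...] = ("female", "male")
    age: int = 25
    # Identity-coefficient sampling scales: amplitude * (j+1)**(-decay),
    # per-band attenuation band_atten**band for complexion.
    shape_scale_amplitude: float = 15.0   # mm-scale vertex displacement budget
    complexion_scale_amplitude: float = 8.0  # L*a*b* units
    scale_decay: float = 0.6
    band_attenuation: float = 0.75
    cell_shape_deviation: float = 4.0     # mm, smooth cross-cell deformation
    cell_tint_deviation: float = 3.0      # L*a*b*, cross-cell tint shift


@dataclass
class Cell:
    ethnicity: str
    sex: str
    avg_mesh: np.ndarray      # (n_vertices, 3)
    avg_texture: np.ndarray   # (h, w, 3) L*a*b*


@dataclass
class GenerativeSpaceSpec:
    config: SpaceConfig
    seed: int
    cells: dict[str, Cell]
    faces: np.ndarray                    # (n_faces, 3) triangle indices, shared topology
    shape_basis: np.ndarray              # (n_vertices*3, n_shape_dims), orthonormal columns
    complexion_bases: list[np.ndarray]   # per band: (h*w*3, n_complexion_dims)
    band_edges: list[tuple[float, float]]  # (low, high] cycles/pixel per band
    shape_coeff_scale: np.ndarray        # (n_shape_dims,)
    complexion_coeff_scale: np.ndarray   # (n_complexion_dims, n_sf_bands)

    @property
    def n_vertices(self) -> int:
        return self.config.n_vertices

    @property
    def texture_shape(self) -> tuple[int, int]:
        return self.config.texture_shape

    def cell(self, label: str) -> Cell:
        try:
            return self.cells[label]
        except KeyError:
            raise KeyError(f"unknown cell label {label!r}; have {sorted(self.cells)}")


@dataclass
class TrialRecord:
    """One stimulus: cell-free identity coefficients plus viewpoint and rating."""

    trial_id: int
    shape_coeffs: np.ndarray       # (n_shape_dims,)
    complexion_coeffs: np.ndarray  # (n_complexion_dims, n_sf_bands)
    viewpoint: int
    rating: Optional[int] = None


def cell_label(ethnicity: str, sex: str) -> str:
    return f"{ethnicity}_{sex}"


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Evenly spread unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _smooth_radial_field(unit: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Low-order polynomial field on the sphere: smooth by construction."""
    x, y, z = unit.T
    basis = np.column_stack([
        x, y, z, x * y, x * z, y * z,
        x ** 2 - y ** 2, 3 * z ** 2 - 1, x * y * z,
    ])
    return basis @ coeffs


def _band_edges(n_bands: int) -> list[tuple[float, float]]:
    """Octave band edges in cycles/pixel, band 0 coarsest (includes DC)."""
    edges = []
    for b in range(n_bands):
        hi = 0.5 / 2 ** (n_bands - 1 - b)
        lo = 0.0 if b == 0 else hi / 2.0
        edges.append((lo, hi))
    return edges


def band_mask(texture_shape: tuple[int, int], lo: float, hi: float) -> np.ndarray:
    """Boolean FFT-domain mask selecting radial frequencies in (lo, hi]."""
    h, w = texture_shape
    fy = np.fft.fftfreq(h)
    fx = np.fft.fftfreq(w)
    r = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    if lo == 0.0:
        return r <= hi
    return (r > lo) & (r <= hi)


def _orthonormalize(m: np.ndarray, what: str) -> np.ndarray:
    q, r = np.linalg.qr(m)
    diag = np.diag(r)
    if np.min(np.abs(diag)) < 1e-10 * max(np.max(np.abs(diag)), 1.0):
        raise InvalidConfigError(
            f"{what}: requested dimensionality exceeds the rank of the "
            f"available subspace"
        )
    return q * np.sign(diag)[None, :]


def build_generative_space(config: SpaceConfig | None = None, seed: int = 0) -> GenerativeSpaceSpec:
    """Construct a deterministic generative space from a config and seed.

    The shape basis is a column-orthonormalized Gaussian matrix; complexion
    bases are built per spatial-frequency band by masking Gaussian textures
    in the FFT domain before orthonormalization, so each band's columns live
    exactly in that band's frequency annulus (orthonormalization preserves
    the subspace).
    """
    cfg = config or SpaceConfig()
    h, w = cfg.texture_shape
    grid3 = h * w * 3
    if min(cfg.n_vertices, cfg.n_shape_dims, cfg.n_complexion_dims, cfg.n_sf_bands, h, w) <= 0:
        raise InvalidConfigError("all dimensions must be positive")
    if cfg.n_shape_dims > cfg.n_vertices * 3:
        raise InvalidConfigError("n_shape_dims exceeds ambient shape dimension")
    if cfg.n_complexion_dims > grid3:
        raise InvalidConfigError("n_complexion_dims exceeds ambient texture dimension")
    scalars = [cfg.shape_scale_amplitude, cfg.complexion_scale_amplitude,
               cfg.scale_decay, cfg.band_attenuation,
               cfg.cell_shape_deviation, cfg.cell_tint_deviation]
    if not np.all(np.isfinite(scalars)):
        raise InvalidConfigError("non-finite value in configuration")

    rng = np.random.default_rng(seed)

    # --- cell averages -----------------------------------------------------
    unit = _fibonacci_sphere(cfg.n_vertices)
    radii = np.array([90.0, 110.0, 100.0])  # head-like ellipsoid, mm
    base_mesh = unit * radii[None, :]
    faces = ConvexHull(unit).simplices.astype(np.int64)

    base_l, base_a, base_b = 62.0, 14.0, 16.0  # skin-tone-ish L*a*b* baseline
    smooth_sigma = max(min(h, w) / 8.0, 1.0)
    base_field = ndimage.gaussian_filter(rng.standard_normal((h, w, 3)), sigma=(smooth_sigma, smooth_sigma, 0))
    base_field /= max(base_field.std(), 1e-12)
    base_texture = np.stack([
        base_l + 5.0 * base_field[..., 0],
        base_a + 2.0 * base_field[..., 1],
        base_b + 2.0 * base_field[..., 2],
    ], axis=-1)

    cells: dict[str, Cell] = {}
    for eth in cfg.ethnicities:
        for sex in cfg.sexes:
            defo = _smooth_radial_field(unit, rng.standard_normal(9))
            defo = defo / max(np.abs(defo).max(), 1e-12) * cfg.cell_shape_deviation
            sex_gain = 1.05 if sex == "male" else 1.0
            mesh = base_mesh * sex_gain + unit * defo[:, None]
            tint = rng.normal(0.0, 1.0, size=3) * cfg.cell_tint_deviation
            tint_field = ndimage.gaussian_filter(
                rng.standard_normal((h, w, 3)), sigma=(smooth_sigma, smooth_sigma, 0))
            tint_field /= max(tint_field.std(), 1e-12)
            texture = base_texture + tint[None, None, :] + cfg.cell_tint_deviation * 0.5 * tint_field
            cells[cell_label(eth, sex)] = Cell(eth, sex, mesh, texture)

    # --- bases -------------------------------------------------------------
    shape_basis = _orthonormalize(
        rng.standard_normal((cfg.n_vertices * 3, cfg.n_shape_dims)), "shape basis")

    edges = _band_edges(cfg.n_sf_bands)
    complexion_bases = []
    for lo, hi in edges:
        mask = band_mask((h, w), lo, hi)
        noise = rng.standard_normal((cfg.n_complexion_dims, h, w, 3))
        spec = np.fft.fft2(noise, axes=(1, 2)) * mask[None, :, :, None]
        banded = np.fft.ifft2(spec, axes=(1, 2)).real
        cols = banded.reshape(cfg.n_complexion_dims, grid3).T
        complexion_bases.append(_orthonormalize(cols, f"complexion band ({lo:.4g},{hi:.4g}]"))

    j = np.arange(cfg.n_shape_dims, dtype=float)
    shape_scale = cfg.shape_scale_amplitude * (j + 1.0) ** (-cfg.scale_decay)
    jc = np.arange(cfg.n_complexion_dims, dtype=float)
    band_gain = cfg.band_attenuation ** np.arange(cfg.n_sf_bands, dtype=float)
    complexion_scale = (cfg.complexion_scale_amplitude
                        * ((jc + 1.0) ** (-cfg.scale_decay))[:, None] * band_gain[None, :])

    return GenerativeSpaceSpec(
        config=cfg, seed=seed, cells=cells, faces=faces,
        shape_basis=shape_basis, complexion_bases=complexion_bases,
        band_edges=edges, shape_coeff_scale=shape_scale,
        complexion_coeff_scale=complexion_scale,
    )


def synthesize_stimuli(space: GenerativeSpaceSpec, n_trials: int, seed: int = 0) -> list[TrialRecord]:
    """Draw cell-free random identity residuals and cycle viewpoints evenly.

    Coefficients are independent zero-mean Gaussians with per-dimension scale
    ``coeff_scale``; the emitted set can be rendered against any cell average.
    """
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    k = space.config.n_shape_dims
    kc, nb = space.config.n_complexion_dims, space.config.n_sf_bands
    shape = rng.standard_normal((n_trials, k)) * space.shape_coeff_scale[None, :]
    comp = rng.standard_normal((n_trials, kc, nb)) * space.complexion_coeff_scale[None, :, :]
    return [
        TrialRecord(
            trial_id=t,
            shape_coeffs=shape[t],
            complexion_coeffs=comp[t],
            viewpoint=VIEWPOINTS[t % 3],
        )
        for t in range(n_trials)
    ]


def render_stimulus(space: GenerativeSpaceSpec, trial: TrialRecord, cell: str):
    """Render one trial against a cell average.

    Returns ``(mesh, texture)`` with mesh ``(n_vertices, 3)`` and texture
    ``(h, w, 3)`` in L*a*b*.  The map is affine in the coefficients:
    average + shape_basis @ shape_coeffs, average + sum_b band_basis_b @ c_b.
    """
    c = space.cell(cell)
    mesh = c.avg_mesh + (space.shape_basis @ np.asarray(trial.shape_coeffs, float)).reshape(-1, 3)
    h, w = space.texture_shape
    tex_dev = np.zeros(h * w * 3)
    for b, basis in enumerate(space.complexion_bases):
        tex_dev += basis @ np.asarray(trial.complexion_coeffs[:, b], float)
    texture = c.avg_texture + tex_dev.reshape(h, w, 3)
    return mesh, texture


# --- array views over trial lists ------------------------------------------

def shape_matrix(trials: Sequence[TrialRecord]) -> np.ndarray:
    return np.stack([t.shape_coeffs for t in trials])


def complexion_matrix(trials: Sequence[TrialRecord]) -> np.ndarray:
    """(n_trials, n_complexion_dims, n_sf_bands)."""
    return np.stack([t.complexion_coeffs for t in trials])


def ratings_array(trials: Sequence[TrialRecord]) -> np.ndarray:
    if any(t.rating is None for t in trials):
        raise InvalidInputError("trials are missing ratings")
    return np.array([t.rating for t in trials], dtype=float)


def with_ratings(trials: Sequence[TrialRecord], ratings: np.ndarray) -> list[TrialRecord]:
    return [replace(t, rating=int(r)) for t, r in zip(trials, ratings)]
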