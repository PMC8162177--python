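"""Reverse correlation: per-participant preference models.

The central measurement is a robust linear regression of each stimulus
dimension on the participant's ratings,

    coefficient_j = beta1_j + beta2_j * rating,

run independently for every shape and complexion dimension.  The beta2 map is
the participant's preference model: the direction in identity-coefficient
space along which faces look more attractive to them.

The same regression repeated at vertex/pixel granularity (with a joint
Benjamini-Hochberg FDR mask) gives a local model; a binned-average k-means
diagnostic checks that the coefficient-rating relation is near-linear; a
Gaussian-copula mutual-information model provides a nonlinearity-robust
cross-check on the linear fit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from ._robust import RobustLineFit, robust_line_fit
from .errors import (
    BinningError,
    DegenerateDesignError,
    DimensionMismatchError,
    InvalidInputError,
)
from .space import (
    GenerativeSpaceSpec,
    TrialRecord,
    complexion_matrix,
    ratings_array,
    shape_matrix,
)

#: rating levels 1..9 collapsed into the 5 linearity-check bins
LINEARITY_BINS = ((1, 2), (3, 4), (5, 5), (6, 7), (8, 9))

PIXEL_DOWNSAMPLE = 4  # per-axis block-mean factor for local/pixel analyses


@dataclass
class PreferenceModel:
    """Per-dimension intercepts (beta1) and slopes (beta2) of one rater."""

    participant_id: str
    condition: str
    method: str  # "robust_linear" | "mi_signed"
    shape_beta1: np.ndarray        # (n_shape_dims,)
    shape_beta2: np.ndarray        # (n_shape_dims,)
    complexion_beta1: np.ndarray   # (n_complexion_dims, n_sf_bands)
    complexion_beta2: np.ndarray   # (n_complexion_dims, n_sf_bands)
    n_trials: int

    def concat_beta2(self) -> np.ndarray:
        return np.concatenate([self.shape_beta2, self.complexion_beta2.ravel()])


@dataclass
class LocalModel:
    """Vertex- and pixel-granularity slopes with joint FDR masks."""

    vertex_beta2: np.ndarray   # (n_vertices, 3)
    vertex_p: np.ndarray
    vertex_mask: np.ndarray
    pixel_beta2: np.ndarray    # (h_ds, w_ds, 3)
    pixel_p: np.ndarray
    pixel_mask: np.ndarray
    fdr_q: float


@dataclass
class LinearityReport:
    bins: tuple = LINEARITY_BINS
    bin_mean_faces: np.ndarray = None        # (n_bins, n_vertices, 3) or (n_bins, h, w, 3)
    distance_matrix: np.ndarray = None       # (n_locations, n_bins)
    k_selected: int = 1
    cluster_centroids: np.ndarray = None     # (k, n_bins)
    max_deviation_from_line: np.ndarray = None  # (k,)


def _validate_trials(trials: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(trials) < 10:
        raise InvalidInputError("need at least 10 rated trials")
    r = ratings_array(trials)
    if np.ptp(r) == 0:
        raise DegenerateDesignError("ratings are constant; regression design is degenerate")
    s = shape_matrix(trials)
    c = complexion_matrix(trials)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(c))):
        raise InvalidInputError("non-finite stimulus coefficients")
    return r, s, c


def fit_preference_model(
    trials: Sequence[TrialRecord],
    participant_id: str = "",
    condition: str = "",
) -> PreferenceModel:
    """Robustly regress every stimulus dimension on the ratings.

    Ratings enter raw (integers 1..9); each dimension is fitted independently
    with bisquare IRLS.  A dimension whose coefficients are constant across
    trials comes out with beta2 = 0 and beta1 equal to that constant.
    """
    r, s, c = _validate_trials(trials)
    n, k = s.shape
    kc, nb = c.shape[1], c.shape[2]
    y = np.concatenate([s, c.reshape(n, kc * nb)], axis=1)
    fit = robust_line_fit(r, y)
    return PreferenceModel(
        participant_id=participant_id,
        condition=condition,
        method="robust_linear",
        shape_beta1=fit.beta1[:k],
        shape_beta2=fit.beta2[:k],
        complexion_beta1=fit.beta1[k:].reshape(kc, nb),
        complexion_beta2=fit.beta2[k:].reshape(kc, nb),
        n_trials=n,
    )


def downsample_texture(tex: np.ndarray, factor: int = PIXEL_DOWNSAMPLE) -> np.ndarray:
    """Block-mean downsample of (..., h, w, 3) textures; trims remainders."""
    h, w = tex.shape[-3], tex.shape[-2]
    f = max(1, min(factor, h, w))
    hh, ww = (h // f) * f, (w // f) * f
    t = tex[..., :hh, :ww, :]
    lead = t.shape[:-3]
    t = t.reshape(*lead, hh // f, f, ww // f, f, 3)
    return t.mean(axis=(-2, -4))


def fit_local_model(
    trials: Sequence[TrialRecord],
    space: GenerativeSpaceSpec,
    cell: str,
    fdr_q: float = 0.05,
) -> LocalModel:
    """Vertex- and pixel-wise robust regressions with joint BH-FDR masks.

    Each trial is rendered against ``cell``; every vertex coordinate and
    every down-sampled pixel channel is regressed on the ratings.  Two-tailed
    slope p-values are corrected jointly across all vertex-coordinate tests
    and, separately, jointly across all pixel-channel tests.
    """
    r, s, c = _validate_trials(trials)
    cellobj = space.cell(cell)
    n = len(trials)
    nv = space.n_vertices
    h, w = space.texture_shape

    # meshes: (n, nv*3) = avg + S @ B^T; rendering is affine so this equals
    # per-trial render_stimulus but in one matmul.
    meshes = cellobj.avg_mesh.ravel()[None, :] + s @ space.shape_basis.T
    vfit = robust_line_fit(r, meshes)

    kc = c.shape[1]
    tex_dev = np.zeros((n, h * w * 3))
    for b, basis in enumerate(space.complexion_bases):
        tex_dev += c[:, :, b] @ basis.T
    textures = cellobj.avg_texture.ravel()[None, :] + tex_dev
    tex_ds = downsample_texture(textures.reshape(n, h, w, 3))
    hd, wd = tex_ds.shape[1], tex_ds.shape[2]
    pfit = robust_line_fit(r, tex_ds.reshape(n, hd * wd * 3))

    vmask = multipletests(vfit.pvals, alpha=fdr_q, method="fdr_bh")[0]
    pmask = multipletests(pfit.pvals, alpha=fdr_q, method="fdr_bh")[0]
    return LocalModel(
        vertex_beta2=vfit.beta2.reshape(nv, 3),
        vertex_p=vfit.pvals.reshape(nv, 3),
        vertex_mask=vmask.reshape(nv, 3),
        pixel_beta2=pfit.beta2.reshape(hd, wd, 3),
        pixel_p=pfit.pvals.reshape(hd, wd, 3),
        pixel_mask=pmask.reshape(hd, wd, 3),
        fdr_q=fdr_q,
    )


def _rating_bin_index(ratings: np.ndarray) -> np.ndarray:
    idx = np.full(ratings.shape, -1, dtype=int)
    for b, (lo, hi) in enumerate(LINEARITY_BINS):
        idx[(ratings >= lo) & (ratings <= hi)] = b
    return idx


def check_linearity(
    trials: Sequence[TrialRecord],
    space: GenerativeSpaceSpec,
    cell: str,
    n_bins: int = 5,
    domain: str = "shape",
    seed: int = 0,
) -> LinearityReport:
    """Binned-average linearity diagnostic.

    Step 1: mean rendered face per rating bin (bins {1-2, 3-4, 5, 6-7, 8-9}).
    Step 2: per-location signed deviation of each bin mean from the cell
    average (for shape, displacement projected on the vertex's outward radial
    direction, so inward deviations are negative; for complexion, the signed
    per-pixel-channel difference).  Step 3: k-means over location rows with k
    chosen by the elbow rule on within-cluster dispersion (k = 1..8); each
    centroid's maximum deviation from the straight line joining its bin-1 and
    bin-5 values summarizes departure from linearity.

    Signed deviations are what can be linear in the rating bin: a linear
    preference moves bin means from one side of the average to the other, so
    an unsigned distance would fold into a V shape regardless of linearity.
    """
    if n_bins != len(LINEARITY_BINS):
        raise InvalidInputError("only the 5-bin scheme {1-2,3-4,5,6-7,8-9} is supported")
    if len(trials) < 10:
        raise InvalidInputError("need at least 10 rated trials")
    r = ratings_array(trials)
    s = shape_matrix(trials)
    c = complexion_matrix(trials)
    cellobj = space.cell(cell)
    bidx = _rating_bin_index(r)
    for b, (lo, hi) in enumerate(LINEARITY_BINS):
        if not np.any(bidx == b):
            raise BinningError(f"rating bin {lo}-{hi} (bin {b + 1}) is empty")

    # Mean of renders == render of mean coefficients (rendering is affine).
    if domain == "shape":
        mean_faces = np.stack([
            cellobj.avg_mesh + (space.shape_basis @ s[bidx == b].mean(axis=0)).reshape(-1, 3)
            for b in range(n_bins)])
        center = cellobj.avg_mesh.mean(axis=0)
        radial = cellobj.avg_mesh - center[None, :]
        radial /= np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-12)
        dist = np.stack([
            np.sum((mean_faces[b] - cellobj.avg_mesh) * radial, axis=1)
            for b in range(n_bins)], axis=1)  # (nv, 5), signed outward/inward
    elif domain == "complexion":
        h, w = space.texture_shape
        mean_faces = []
        for b in range(n_bins):
            dev = np.zeros(h * w * 3)
            cb = c[bidx == b].mean(axis=0)
            for bb, basis in enumerate(space.complexion_bases):
                dev += basis @ cb[:, bb]
            mean_faces.append(cellobj.avg_texture + dev.reshape(h, w, 3))
        mean_faces = np.stack(mean_faces)
        dist = np.stack([
            (mean_faces[b] - cellobj.avg_texture).reshape(-1)
            for b in range(n_bins)], axis=1)  # (h*w*3, 5), signed
    else:
        raise InvalidInputError(f"unknown domain {domain!r}")

    from .repspace import elbow_select  # local import to avoid a cycle

    ks = range(1, min(8, dist.shape[0]) + 1)
    wcss = []
    fits = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(dist)
        wcss.append(km.inertia_)
        fits[k] = km
    k_selected = elbow_select(np.maximum.accumulate(wcss[::-1])[::-1])
    km = fits[k_selected]
    centroids = km.cluster_centers_
    line = np.linspace(centroids[:, 0], centroids[:, -1], n_bins, axis=1)
    max_dev = np.abs(centroids - line).max(axis=1)
    return LinearityReport(
        bin_mean_faces=mean_faces,
        distance_matrix=dist,
        k_selected=k_selected,
        cluster_centroids=centroids,
        max_deviation_from_line=max_dev,
    )


def gaussian_copula_mi(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gaussian-copula mutual information between ``x`` and each column of ``y``.

    Both variables are rank-normalized (empirical CDF -> inverse normal), and
    MI is computed in closed form from the Pearson correlation of the
    transformed variables: -0.5 * ln(1 - rho^2), in nats.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.size

    def rank_gauss(a, axis=0):
        r = stats.rankdata(a, axis=axis, method="average")
        return special.ndtri(r / (n + 1.0))

    zx = rank_gauss(x)
    zy = rank_gauss(y, axis=0)
    zx = (zx - zx.mean()) / zx.std()
    zy = (zy - zy.mean(axis=0)) / np.where(zy.std(axis=0) > 0, zy.std(axis=0), 1.0)
    rho = zy.T @ zx / n
    rho = np.clip(rho, -0.99999, 0.99999)
    return -0.5 * np.log1p(-rho ** 2)


def fit_mi_model(
    trials: Sequence[TrialRecord],
    participant_id: str = "",
    condition: str = "",
) -> PreferenceModel:
    """Signed mutual-information preference model.

    Per dimension, Gaussian-copula MI between coefficient and rating, signed
    by the slope of the robust linear fit, stored in the beta2 slots (beta1
    slots zero).  Captures monotone nonlinear preference structure the linear
    slope might understate.
    """
    r, s, c = _validate_trials(trials)
    n, k = s.shape
    kc, nb = c.shape[1], c.shape[2]
    y = np.concatenate([s, c.reshape(n, kc * nb)], axis=1)
    linear = robust_line_fit(r, y)
    mi = gaussian_copula_mi(r, y)
    signed = np.sign(linear.beta2) * mi
    return PreferenceModel(
        participant_id=participant_id,
        condition=condition,
        method="mi_signed",
        shape_beta1=np.zeros(k),
        shape_beta2=signed[:k],
        complexion_beta1=np.zeros((kc, nb)),
        complexion_beta2=signed[k:].reshape(kc, nb),
        n_trials=n,
    )


def model_vertex_map(model: PreferenceModel, space: GenerativeSpaceSpec) -> np.ndarray:
    """beta2 mapped to per-vertex-coordinate space, flattened (n_vertices*3,)."""
    return space.shape_basis @ model.shape_beta2


def model_pixel_map(model: PreferenceModel, space: GenerativeSpaceSpec,
                    downsample: int = PIXEL_DOWNSAMPLE) -> np.ndarray:
    """beta2 mapped to down-sampled pixel L*a*b* space, flattened."""
    h, w = space.texture_shape
    dev = np.zeros(h * w * 3)
    for b, basis in enumerate(space.complexion_bases):
        dev += basis @ model.complexion_beta2[:, b]
    return downsample_texture(dev.reshape(1, h, w, 3), downsample).ravel()


@dataclass
class SimilarityReport:
    spearman_shape: float
    spearman_complexion: float
    threshold_shape: float
    threshold_complexion: float
    significant_shape: bool
    significant_complexion: bool
    n_perm: int


def compare_model_similarity(
    model_a: PreferenceModel,
    model_b: PreferenceModel,
    space: GenerativeSpaceSpec,
    n_perm: int = 200,
    seed: int = 0,
) -> SimilarityReport:
    """Spearman similarity of two models in vertex/pixel space, with a
    magnitude-shuffle null.

    The null shuffles model_b's per-dimension magnitudes across dimensions
    while keeping each dimension's sign, maps to vertex/pixel space, and
    recomputes the correlation; significance is one-sided at the 95th
    percentile of ``n_perm`` shuffles.
    """
    if (model_a.shape_beta2.shape != model_b.shape_beta2.shape
            or model_a.complexion_beta2.shape != model_b.complexion_beta2.shape):
        raise DimensionMismatchError("models do not share dimensions")
    rng = np.random.default_rng(seed)

    va = model_vertex_map(model_a, space)
    vb = model_vertex_map(model_b, space)
    pa = model_pixel_map(model_a, space)
    pb = model_pixel_map(model_b, space)
    r_shape = stats.spearmanr(va, vb).statistic
    r_comp = stats.spearmanr(pa, pb).statistic

    def shuffled_model() -> PreferenceModel:
        sb = model_b.shape_beta2
        cb = model_b.complexion_beta2.ravel()
        sperm = rng.permutation(sb.size)
        cperm = rng.permutation(cb.size)
        return PreferenceModel(
            participant_id=model_b.participant_id, condition=model_b.condition,
            method=model_b.method,
            shape_beta1=model_b.shape_beta1,
            shape_beta2=np.sign(sb) * np.abs(sb)[sperm],
            complexion_beta1=model_b.complexion_beta1,
            complexion_beta2=(np.sign(cb) * np.abs(cb)[cperm]).reshape(
                model_b.complexion_beta2.shape),
            n_trials=model_b.n_trials,
        )

    null_shape = np.empty(n_perm)
    null_comp = np.empty(n_perm)
    for i in range(n_perm):
        mb = shuffled_model()
        null_shape[i] = stats.spearmanr(va, model_vertex_map(mb, space)).statistic
        null_comp[i] = stats.spearmanr(pa, model_pixel_map(mb, space)).statistic
    thr_shape = float(np.percentile(null_shape, 95))
    thr_comp = float(np.percentile(null_comp, 95))
    return SimilarityReport(
        spearman_shape=float(r_shape), spearman_complexion=float(r_comp),
        threshold_shape=thr_shape, threshold_complexion=thr_comp,
        significant_shape=bool(r_shape > thr_shape),
        significant_complexion=bool(r_comp > thr_comp),
        n_perm=n_perm,
    )
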