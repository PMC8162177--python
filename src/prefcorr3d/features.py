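"""Interpretable feature analyses of fitted preference models.

Turns beta2 maps into things one can look at and test: group-average models,
attractive/unattractive face reconstructions, z-scores of the modal
attractive face against the stimulus distribution, and the comparison of the
attractiveness direction with the sexual-dimorphism direction via a
bootstrap vector-cosine test.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from ._robust import robust_line_fit
from .errors import (
    DimensionMismatchError,
    InvalidInputError,
    ThresholdError,
    ZeroNormError,
)
from .repspace import elbow_select
from .revcorr import PreferenceModel
from .space import (
    GenerativeSpaceSpec,
    TrialRecord,
    complexion_matrix,
    ratings_array,
    shape_matrix,
)

#: default reconstruction gain — beta2 evaluated at the rating extremes
#: (scale midpoint 5 +/- 4 rating steps)
DEFAULT_GAIN = 4.0


def average_group_model(models: Sequence[PreferenceModel],
                        condition: Optional[str] = None) -> PreferenceModel:
    """Elementwise mean of beta1 and beta2 across individual models."""
    if len(models) < 1:
        raise InvalidInputError("need at least 1 model")
    methods = {m.method for m in models}
    if len(methods) != 1:
        raise InvalidInputError(f"mixed methods: {sorted(methods)}")
    shapes = {(m.shape_beta2.shape, m.complexion_beta2.shape) for m in models}
    if len(shapes) != 1:
        raise DimensionMismatchError("models have inconsistent dimensions")
    return PreferenceModel(
        participant_id="group",
        condition=condition if condition is not None else models[0].condition,
        method=models[0].method,
        shape_beta1=np.mean([m.shape_beta1 for m in models], axis=0),
        shape_beta2=np.mean([m.shape_beta2 for m in models], axis=0),
        complexion_beta1=np.mean([m.complexion_beta1 for m in models], axis=0),
        complexion_beta2=np.mean([m.complexion_beta2 for m in models], axis=0),
        n_trials=int(np.sum([m.n_trials for m in models])),
    )


@dataclass
class ExtremeFaces:
    attractive_mesh: np.ndarray
    attractive_texture: np.ndarray
    average_mesh: np.ndarray
    average_texture: np.ndarray
    unattractive_mesh: np.ndarray
    unattractive_texture: np.ndarray
    vertex_deviation: np.ndarray   # (n_vertices, 3), attractive - average
    pixel_deviation: np.ndarray    # (h, w, 3) L*a*b*
    gain: float


def reconstruct_extreme_faces(
    space: GenerativeSpaceSpec,
    cell: str,
    model: PreferenceModel,
    gain: float = DEFAULT_GAIN,
) -> ExtremeFaces:
    """Render the cell average with +/- gain * beta2 amplification.

    ``gain`` is in rating units: the default renders the model at the rating
    extremes, 4 steps either side of the scale midpoint.
    """
    if gain <= 0:
        raise InvalidInputError("gain must be positive")
    c = space.cell(cell)
    h, w = space.texture_shape

    def render(sign: float):
        mesh = c.avg_mesh + sign * gain * (
            space.shape_basis @ model.shape_beta2).reshape(-1, 3)
        dev = np.zeros(h * w * 3)
        for b, basis in enumerate(space.complexion_bases):
            dev += basis @ model.complexion_beta2[:, b]
        tex = c.avg_texture + sign * gain * dev.reshape(h, w, 3)
        return mesh, tex

    att_mesh, att_tex = render(+1.0)
    una_mesh, una_tex = render(-1.0)
    return ExtremeFaces(
        attractive_mesh=att_mesh, attractive_texture=att_tex,
        average_mesh=c.avg_mesh.copy(), average_texture=c.avg_texture.copy(),
        unattractive_mesh=una_mesh, unattractive_texture=una_tex,
        vertex_deviation=att_mesh - c.avg_mesh,
        pixel_deviation=att_tex - c.avg_texture,
        gain=gain,
    )


@dataclass
class ZScoreMap:
    vertex_z: np.ndarray          # (n_vertices, 3); NaN where SD == 0
    pixel_z: np.ndarray           # (h, w, 3); NaN where SD == 0
    vertex_undefined: np.ndarray  # boolean masks flagging zero-SD locations
    pixel_undefined: np.ndarray
    attractive_set_size: int
    modal_shape_coeffs: np.ndarray
    modal_complexion_coeffs: np.ndarray


def default_top_rule(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Highly attractive stimuli: rating >= 8, else the rater's top decile."""
    top = [t for t in trials if t.rating is not None and t.rating >= 8]
    if top:
        return top
    rated = [t for t in trials if t.rating is not None]
    if not rated:
        return []
    n_top = max(1, len(rated) // 10)
    order = np.argsort([-t.rating for t in rated], kind="stable")
    return [rated[i] for i in order[:n_top]]


def _kde_mode(samples: np.ndarray, n_grid: int = 512) -> float:
    """Mode via Gaussian KDE (Silverman bandwidth) on a grid over the range."""
    samples = np.asarray(samples, float)
    if samples.size == 1 or np.ptp(samples) == 0:
        return float(samples[0])
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(samples.min(), samples.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def zscore_attractive_features(
    trials_by_participant: Sequence[Sequence[TrialRecord]],
    space: GenerativeSpaceSpec,
    cell: str,
    top_rule: Callable[[Sequence[TrialRecord]], list[TrialRecord]] = default_top_rule,
) -> ZScoreMap:
    """Locate the modal attractive face within the stimulus distribution.

    Step 1 pools each participant's top-rated stimuli; Step 2 takes the
    per-dimension modal coefficient (KDE peak) of the pooled attractive set
    and renders the modal face; Step 3 computes per-vertex-coordinate and
    per-pixel-channel mean and SD over the full stimulus set; Step 4 z-scores
    the modal face against those moments.  Zero-SD locations are flagged as
    undefined (NaN), not silently zeroed.
    """
    if len(trials_by_participant) == 0:
        raise InvalidInputError("no participants supplied")
    attractive: list[TrialRecord] = []
    for trials in trials_by_participant:
        attractive.extend(top_rule(trials))
    if not attractive:
        raise ThresholdError("attractive set is empty after applying the top rule")

    s_att = shape_matrix(attractive)
    c_att = complexion_matrix(attractive)
    k = s_att.shape[1]
    kc, nb = c_att.shape[1], c_att.shape[2]
    modal_shape = np.array([_kde_mode(s_att[:, j]) for j in range(k)])
    modal_comp = np.array(
        [[_kde_mode(c_att[:, j, b]) for b in range(nb)] for j in range(kc)])

    cellobj = space.cell(cell)
    h, w = space.texture_shape
    modal_mesh = cellobj.avg_mesh + (space.shape_basis @ modal_shape).reshape(-1, 3)
    dev = np.zeros(h * w * 3)
    for b, basis in enumerate(space.complexion_bases):
        dev += basis @ modal_comp[:, b]
    modal_tex = cellobj.avg_texture + dev.reshape(h, w, 3)

    # Step 3: moments over the full stimulus set (shared across participants;
    # use the union of distinct trial ids).
    seen: dict[int, TrialRecord] = {}
    for trials in trials_by_participant:
        for t in trials:
            seen.setdefault(t.trial_id, t)
    all_trials = list(seen.values())
    s_all = shape_matrix(all_trials)
    c_all = complexion_matrix(all_trials)
    n = len(all_trials)
    meshes = cellobj.avg_mesh.ravel()[None, :] + s_all @ space.shape_basis.T
    tex_dev = np.zeros((n, h * w * 3))
    for b, basis in enumerate(space.complexion_bases):
        tex_dev += c_all[:, :, b] @ basis.T
    textures = cellobj.avg_texture.ravel()[None, :] + tex_dev

    def zmap(modal_flat, stack):
        mu = stack.mean(axis=0)
        sd = stack.std(axis=0)
        undefined = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (modal_flat - mu) / np.where(undefined, 1.0, sd)
        z = np.where(undefined, np.nan, z)
        return z, undefined

    vz, vu = zmap(modal_mesh.ravel(), meshes)
    pz, pu = zmap(modal_tex.ravel(), textures)
    return ZScoreMap(
        vertex_z=vz.reshape(-1, 3), pixel_z=pz.reshape(h, w, 3),
        vertex_undefined=vu.reshape(-1, 3), pixel_undefined=pu.reshape(h, w, 3),
        attractive_set_size=len(attractive),
        modal_shape_coeffs=modal_shape, modal_complexion_coeffs=modal_comp,
    )


@dataclass
class DimorphismDirection:
    ethnicity: str
    vertex_delta: np.ndarray        # (n_vertices, 3), female - male
    pixel_delta: np.ndarray         # (h, w, 3)
    coeff_shape: np.ndarray         # (n_shape_dims,)
    coeff_complexion: np.ndarray    # (n_complexion_dims, n_sf_bands)
    reduced_shape_dims: int
    reduced_complexion_dims: list[int]  # per band


def compute_dimorphism_direction(space: GenerativeSpaceSpec, ethnicity: str) -> DimorphismDirection:
    """Female-minus-male average difference, reparametrized in the bases.

    The reduced dimension sets (for cosine comparisons and the dimorphism
    predictor) keep the leading dimensions selected by the elbow rule on the
    coefficient-scale spectrum (the generative model's eigenvalue analogue),
    per band for complexion.
    """
    from .space import cell_label

    female = space.cell(cell_label(ethnicity, "female"))
    male = space.cell(cell_label(ethnicity, "male"))
    vdelta = female.avg_mesh - male.avg_mesh
    pdelta = female.avg_texture - male.avg_texture
    coeff_shape = space.shape_basis.T @ vdelta.ravel()
    coeff_comp = np.stack(
        [basis.T @ pdelta.ravel() for basis in space.complexion_bases], axis=1)
    k_shape = elbow_select(space.shape_coeff_scale ** 2)
    k_bands = [elbow_select(space.complexion_coeff_scale[:, b] ** 2)
               for b in range(space.config.n_sf_bands)]
    return DimorphismDirection(
        ethnicity=ethnicity, vertex_delta=vdelta, pixel_delta=pdelta,
        coeff_shape=coeff_shape, coeff_complexion=coeff_comp,
        reduced_shape_dims=k_shape, reduced_complexion_dims=k_bands,
    )


def reduced_model_vector(model: PreferenceModel, direction: DimorphismDirection,
                         domain: str) -> np.ndarray:
    if domain == "shape":
        return model.shape_beta2[: direction.reduced_shape_dims]
    if domain == "complexion":
        return np.concatenate([
            model.complexion_beta2[:kb, b]
            for b, kb in enumerate(direction.reduced_complexion_dims)])
    raise InvalidInputError(f"unknown domain {domain!r}")


def reduced_direction_vector(direction: DimorphismDirection, domain: str) -> np.ndarray:
    if domain == "shape":
        return direction.coeff_shape[: direction.reduced_shape_dims]
    if domain == "complexion":
        return np.concatenate([
            direction.coeff_complexion[:kb, b]
            for b, kb in enumerate(direction.reduced_complexion_dims)])
    raise InvalidInputError(f"unknown domain {domain!r}")


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroNormError("cosine undefined for a zero-norm vector")
    return float(a @ b / (na * nb))


@dataclass
class CosineTestResult:
    domain: str
    cosine: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool  # attractiveness direction differs from the comparison direction
    seed: int


def cosine_similarity_test(
    trials: Sequence[TrialRecord],
    model: PreferenceModel,
    direction: DimorphismDirection,
    domain: str = "shape",
    n_boot: int = 1000,
    seed: int = 0,
) -> CosineTestResult:
    """Bootstrap test of whether a preference direction differs from dimorphism.

    The observed statistic is the cosine between the reduced-dimension beta2
    and the reduced dimorphism direction.  The null of self-similarity is the
    distribution of cosines between bootstrap refits (trials resampled with
    replacement) and the original model; the model is declared different from
    the dimorphism direction when the observed cosine falls below the 2.5th
    percentile of that null.
    """
    ref_model = reduced_model_vector(model, direction, domain)
    ref_dir = reduced_direction_vector(direction, domain)
    cosine = _cosine(ref_model, ref_dir)

    r = ratings_array(trials)
    s = shape_matrix(trials)
    c = complexion_matrix(trials)
    n, k = s.shape
    kc, nb = c.shape[1], c.shape[2]
    y = np.concatenate([s, c.reshape(n, kc * nb)], axis=1)

    rng = np.random.default_rng(seed)
    boot_cos = np.empty(n_boot)
    for bi in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fit = robust_line_fit(r[idx], y[idx])
        bm = PreferenceModel(
            participant_id=model.participant_id, condition=model.condition,
            method="robust_linear",
            shape_beta1=fit.beta1[:k], shape_beta2=fit.beta2[:k],
            complexion_beta1=fit.beta1[k:].reshape(kc, nb),
            complexion_beta2=fit.beta2[k:].reshape(kc, nb),
            n_trials=n,
        )
        boot_cos[bi] = _cosine(reduced_model_vector(bm, direction, domain), ref_model)
    ci_low, ci_high = np.percentile(boot_cos, [2.5, 97.5])
    return CosineTestResult(
        domain=domain, cosine=cosine, ci_low=float(ci_low), ci_high=float(ci_high),
        n_boot=n_boot, significant=bool(cosine < ci_low), seed=seed,
    )
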