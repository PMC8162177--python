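"""The attractiveness representation space and its variance decomposition.

Individual preference models (beta2 maps) are vectorized at vertex/pixel
granularity and submitted to a PCA; the retained components (elbow rule on
the eigenvalue curve) span the "attractiveness space" in which cultural and
individual preference structure is measured.

Variance of per-component scores is decomposed into a group (condition)
share and an individual (participant) share:

    R2_group       = 1 - SSresi1 / SStotal
    R2_participant = SSresi1 / SStotal * (1 - SSresi2 / SSresi1)

where SStotal is the sum of squared scores about 0 (the no-effect point),
SSresi1 the residual sum of squares after removing condition means, and
SSresi2 after further removing participant means of those residuals.
Significance thresholds come from permutation nulls that respect the
participant-block structure of bootstrap-resampled models.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import DimensionMismatchError, InvalidInputError
from .revcorr import (
    PIXEL_DOWNSAMPLE,
    PreferenceModel,
    fit_preference_model,
    model_pixel_map,
    model_vertex_map,
)
from .space import GenerativeSpaceSpec, TrialRecord


def elbow_select(values: Sequence[float]) -> int:
    """Index (1-based) of the elbow of a nonincreasing positive curve.

    The elbow is the point with the largest perpendicular distance to the
    chord joining the first and last points; exact ties resolve to the
    smallest index (so a perfectly linear curve returns 1).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise InvalidInputError("need at least 3 values for elbow selection")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("non-finite values")
    x = np.arange(1, v.size + 1, dtype=float)
    dx, dy = x[-1] - x[0], v[-1] - v[0]
    norm = np.hypot(dx, dy)
    # |cross product| of (point - first) with the chord direction
    dist = np.abs(dx * (v[0] - v) - (x[0] - x) * dy) / max(norm, np.finfo(float).tiny)
    return int(np.argmax(dist)) + 1


@dataclass
class AttractivenessSpace:
    """PCA over vectorized individual models, one per domain."""

    domain: str                    # "shape" | "complexion"
    mean: np.ndarray               # (ambient_dim,) center used before PCA
    loadings: np.ndarray           # (ambient_dim, n_components), orthonormal cols
    eigenvalues: np.ndarray        # (n_components,)
    var_explained: np.ndarray      # fractions, nonincreasing
    n_kept: int
    scores: np.ndarray             # (n_models, n_kept)
    model_ids: list[str]
    group_labels: list[str]
    participant_labels: list[str]

    def project(self, vectors: np.ndarray, centered: bool = False) -> np.ndarray:
        """Scores of arbitrary ambient vectors on the kept components.

        Stimulus residuals are projected raw (``centered=False``); model
        vectors should be centered with the space's own mean first.
        """
        v = np.atleast_2d(vectors)
        if centered:
            v = v - self.mean[None, :]
        return v @ self.loadings[:, : self.n_kept]


def _model_vector(model: PreferenceModel, space: GenerativeSpaceSpec, domain: str,
                  downsample: int) -> np.ndarray:
    if domain == "shape":
        return model_vertex_map(model, space)
    if domain == "complexion":
        return model_pixel_map(model, space, downsample)
    raise InvalidInputError(f"unknown domain {domain!r}")


def build_attractiveness_space(
    models: Sequence[PreferenceModel],
    space: GenerativeSpaceSpec,
    domain: str = "shape",
    downsample: int = PIXEL_DOWNSAMPLE,
    n_kept: Optional[int] = None,
) -> AttractivenessSpace:
    """PCA over individual models vectorized at vertex/pixel granularity.

    Models are mean-centered across models (variables are not scaled) and
    decomposed by SVD; ``n_kept`` defaults to the elbow of the eigenvalue
    curve.
    """
    if len(models) < 2:
        raise InvalidInputError("need at least 2 models")
    shapes = {(m.shape_beta2.shape, m.complexion_beta2.shape) for m in models}
    if len(shapes) != 1:
        raise DimensionMismatchError("models have inconsistent dimensions")
    mat = np.stack([_model_vector(m, space, domain, downsample) for m in models])
    mean = mat.mean(axis=0)
    centered = mat - mean[None, :]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n = len(models)
    eig = s ** 2 / max(n - 1, 1)
    total = eig.sum()
    var_explained = eig / total if total > 0 else np.zeros_like(eig)
    if n_kept is None:
        n_kept = elbow_select(eig) if eig.size >= 3 else eig.size
    n_kept = min(n_kept, eig.size)
    scores_full = centered @ vt.T
    return AttractivenessSpace(
        domain=domain, mean=mean, loadings=vt.T, eigenvalues=eig,
        var_explained=var_explained, n_kept=n_kept,
        scores=scores_full[:, :n_kept],
        model_ids=[m.participant_id for m in models],
        group_labels=[m.condition for m in models],
        participant_labels=[m.participant_id for m in models],
    )


def bootstrap_models(
    trials: Sequence[TrialRecord],
    n_boot: int,
    seed: int = 0,
    participant_id: str = "",
    condition: str = "",
    fitter: Callable[..., PreferenceModel] = fit_preference_model,
) -> list[PreferenceModel]:
    """Refit on ``n_boot`` with-replacement resamples of the trial set."""
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(trials)
    out = []
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = [trials[i] for i in idx]
        out.append(fitter(resample, participant_id=participant_id, condition=condition))
    return out


@dataclass
class VarianceDecomposition:
    ss_total: np.ndarray       # per component
    ss_resi1: np.ndarray
    ss_resi2: np.ndarray
    r2_group: np.ndarray
    r2_participant: np.ndarray
    weights: np.ndarray        # var_explained weights, normalized over kept comps
    weighted_r2_group: float
    weighted_r2_participant: float


def decompose_variance(
    scores: np.ndarray,
    groups: Sequence[str],
    participants: Sequence[str],
    var_explained: Optional[np.ndarray] = None,
) -> VarianceDecomposition:
    """Group-vs-participant variance decomposition of per-component scores.

    SStotal is measured from 0 (no preference), not the grand mean; removing
    condition means gives SSresi1, further removing participant means of the
    residuals gives SSresi2.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n, k = scores.shape
    groups = list(groups)
    participants = list(participants)
    if len(groups) != n or len(participants) != n:
        raise InvalidInputError("every model needs a group and a participant label")
    if len(set(groups)) < 2:
        raise InvalidInputError("need at least 2 groups")

    ss_total = (scores ** 2).sum(axis=0)
    resi1 = scores.copy()
    for g in set(groups):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        resi1[idx] -= scores[idx].mean(axis=0, keepdims=True)
    ss_resi1 = (resi1 ** 2).sum(axis=0)
    resi2 = resi1.copy()
    for p in set(participants):
        idx = [i for i, pp in enumerate(participants) if pp == p]
        resi2[idx] -= resi1[idx].mean(axis=0, keepdims=True)
    ss_resi2 = (resi2 ** 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        r2_group = np.where(ss_total > 0, 1.0 - ss_resi1 / np.where(ss_total > 0, ss_total, 1.0), 0.0)
        frac1 = np.where(ss_total > 0, ss_resi1 / np.where(ss_total > 0, ss_total, 1.0), 0.0)
        r2_participant = frac1 * np.where(
            ss_resi1 > 0, 1.0 - ss_resi2 / np.where(ss_resi1 > 0, ss_resi1, 1.0), 0.0)

    if var_explained is None:
        weights = np.full(k, 1.0 / k)
    else:
        w = np.asarray(var_explained, dtype=float)[:k]
        weights = w / w.sum()
    return VarianceDecomposition(
        ss_total=ss_total, ss_resi1=ss_resi1, ss_resi2=ss_resi2,
        r2_group=r2_group, r2_participant=r2_participant, weights=weights,
        weighted_r2_group=float(weights @ r2_group),
        weighted_r2_participant=float(weights @ r2_participant),
    )


@dataclass
class PermutationThresholds:
    mode: str
    percentile: float
    thresholds: np.ndarray      # per component
    observed: np.ndarray        # per component
    significant: np.ndarray     # per component, observed > threshold
    weighted_threshold: float
    weighted_observed: float
    weighted_significant: bool
    n_perm: int


def permutation_thresholds(
    scores: np.ndarray,
    groups: Sequence[str],
    participants: Sequence[str],
    var_explained: Optional[np.ndarray] = None,
    mode: str = "group",
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationThresholds:
    """Permutation null thresholds for the R2 shares.

    group mode: participant blocks (a participant's bootstrap models move
    together) are shuffled across conditions and R2_group recomputed.
    participant mode: conditions stay fixed; participant labels are shuffled
    across models within each condition and R2_participant recomputed.
    Per-component thresholds are the (100 - 100*alpha/n_components) percentile
    of the null (one-tailed, Bonferroni over components); the overall
    threshold applies the var_explained weights to each permutation's
    per-component null values.
    """
    if n_perm < 100:
        raise InvalidInputError("n_perm must be >= 100")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n, k = scores.shape
    groups = np.asarray(list(groups))
    participants = np.asarray(list(participants))
    if groups.size != n or participants.size != n:
        raise InvalidInputError("labels do not match score rows")
    # every participant must sit inside exactly one condition
    for p in np.unique(participants):
        if len(set(groups[participants == p])) != 1:
            raise InvalidInputError(f"participant {p!r} spans multiple conditions")

    rng = np.random.default_rng(seed)
    obs = decompose_variance(scores, groups, participants, var_explained)
    observed = obs.r2_group if mode == "group" else obs.r2_participant
    weighted_observed = (obs.weighted_r2_group if mode == "group"
                         else obs.weighted_r2_participant)
    weights = obs.weights

    uniq_p = np.unique(participants)
    p_group = {p: groups[participants == p][0] for p in uniq_p}
    null = np.empty((n_perm, k))
    for it in range(n_perm):
        if mode == "group":
            # reassign condition labels across participant blocks
            permuted = rng.permutation([p_group[p] for p in uniq_p])
            new_group_of_p = dict(zip(uniq_p, permuted))
            g_perm = np.asarray([new_group_of_p[p] for p in participants])
            d = decompose_variance(scores, g_perm, participants, var_explained)
            null[it] = d.r2_group
        elif mode == "participant":
            p_perm = participants.copy()
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                p_perm[idx] = p_perm[idx[rng.permutation(idx.size)]]
            d = decompose_variance(scores, groups, p_perm, var_explained)
            null[it] = d.r2_participant
        else:
            raise InvalidInputError(f"unknown mode {mode!r}")

    percentile = 100.0 - 100.0 * alpha / k
    thresholds = np.percentile(null, percentile, axis=0)
    # overall threshold: variance-weighted sum of the per-component thresholds
    weighted_threshold = float(weights @ thresholds)
    return PermutationThresholds(
        mode=mode, percentile=percentile, thresholds=thresholds,
        observed=observed, significant=observed > thresholds,
        weighted_threshold=weighted_threshold,
        weighted_observed=float(weighted_observed),
        weighted_significant=bool(weighted_observed > weighted_threshold),
        n_perm=n_perm,
    )


TRANSFER_CLASSES = ("neither", "transferred", "interactive", "both")


@dataclass
class TransferInteractiveMap:
    """Per-location class codes: 0 neither, 1 transferred, 2 interactive, 3 both."""

    vertex_class: np.ndarray   # (n_vertices, 3) int codes
    pixel_class: np.ndarray    # (h_ds, w_ds, 3) int codes
    classes: tuple = TRANSFER_CLASSES
    source_conditions: tuple = ()


def classify_transfer_interactive(
    own_same: PreferenceModel,
    own_other: PreferenceModel,
    other_same: PreferenceModel,
    space: GenerativeSpaceSpec,
    downsample: int = PIXEL_DOWNSAMPLE,
) -> TransferInteractiveMap:
    """Sign-sharing classification of other-ethnicity preference features.

    At each vertex coordinate / pixel channel: transferred iff the
    other-ethnicity model shares the sign of the rater group's own-ethnicity
    model; interactive iff it shares the sign of the other culture's
    own-ethnicity model; both/neither accordingly.  Zero slopes carry sign 0,
    which matches nothing.
    """
    for m in (own_other, other_same):
        if (m.shape_beta2.shape != own_same.shape_beta2.shape
                or m.complexion_beta2.shape != own_same.complexion_beta2.shape):
            raise DimensionMismatchError("models do not share dimensions")

    def codes(vec_fn):
        s_own_same = np.sign(vec_fn(own_same))
        s_own_other = np.sign(vec_fn(own_other))
        s_other_same = np.sign(vec_fn(other_same))
        nz = s_own_other != 0
        t = nz & (s_own_other == s_own_same)
        i = nz & (s_own_other == s_other_same)
        return (np.where(t & i, 3, np.where(t, 1, np.where(i, 2, 0)))).astype(np.int8)

    nv = space.n_vertices
    vclass = codes(lambda m: model_vertex_map(m, space)).reshape(nv, 3)
    pflat = codes(lambda m: model_pixel_map(m, space, downsample))
    h, w = space.texture_shape
    f = max(1, min(downsample, h, w))
    pclass = pflat.reshape(h // f, w // f, 3)
    return TransferInteractiveMap(
        vertex_class=vclass, pixel_class=pclass,
        source_conditions=(own_same.condition, own_other.condition, other_same.condition),
    )
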