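"""Cross-validated prediction of held-out ratings.

For each participant, trials are randomly segmented into k contiguous blocks
(default 13) and cross-validated: on each fold the participant's preference
model is refitted on the training trials, the attractiveness space is
rebuilt from that model plus the context models of the other participants,
each stimulus's identity residual is expressed as kept-component scores, and
a Gamma GLM with log link predicts the (positive, right-skewed) ratings from
those scores.  Prediction quality on the held-out fold is Kendall's tau
between actual and predicted ratings.

Two alternative predictor families are evaluated the same way: averageness
(Euclidean distance of the stimulus from the space's center) and sexual
dimorphism (scalar projection of the stimulus coefficients onto the
dimorphism direction in its reduced dimension set).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidInputError, ZeroNormError
from .features import DimorphismDirection, reduced_direction_vector
from .repspace import build_attractiveness_space
from .revcorr import PreferenceModel, fit_preference_model
from .space import (
    GenerativeSpaceSpec,
    TrialRecord,
    complexion_matrix,
    ratings_array,
    shape_matrix,
)

PREDICTOR_FAMILIES = (
    "attractiveness_shape", "attractiveness_complexion",
    "averageness_shape", "averageness_complexion",
    "dimorphism_shape", "dimorphism_complexion",
)


@dataclass
class ValidationResult:
    participant_id: str
    k_folds: int
    taus: dict[str, np.ndarray]          # family -> (k_folds,), NaN for flagged folds
    fold_assignments: np.ndarray         # (n_trials,) fold index per trial
    glm_coefficients: dict[str, list]    # family -> per-fold coefficient arrays
    flagged_folds: dict[str, list[int]]  # family -> folds where the GLM failed
    seed: int

    def mean_tau(self, family: str) -> float:
        t = self.taus[family]
        valid = t[~np.isnan(t)]
        return float(valid.mean()) if valid.size else float("nan")


def averageness_predictor(trial: TrialRecord, domain: str = "shape") -> float:
    """Distance of a stimulus from the center of the generative space."""
    if domain == "shape":
        v = np.asarray(trial.shape_coeffs, float)
    elif domain == "complexion":
        v = np.asarray(trial.complexion_coeffs, float).ravel()
    else:
        raise InvalidInputError(f"unknown domain {domain!r}")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("non-finite coefficients")
    return float(np.linalg.norm(v))


def dimorphism_predictor(trial: TrialRecord, direction: DimorphismDirection,
                         domain: str = "shape") -> float:
    """Scalar projection of the stimulus onto the reduced dimorphism vector."""
    d = reduced_direction_vector(direction, domain)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ZeroNormError("dimorphism direction has zero norm")
    if domain == "shape":
        v = np.asarray(trial.shape_coeffs, float)[: direction.reduced_shape_dims]
    else:
        v = np.concatenate([
            np.asarray(trial.complexion_coeffs, float)[:kb, b]
            for b, kb in enumerate(direction.reduced_complexion_dims)])
    return float(v @ d / nd)


def make_folds(n_trials: int, k_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of trials into k contiguous blocks."""
    perm = rng.permutation(n_trials)
    folds = np.empty(n_trials, dtype=int)
    for f, block in enumerate(np.array_split(perm, k_folds)):
        folds[block] = f
    return folds


def _fit_gamma_glm(x_train, y_train, x_test):
    """Gamma GLM with log link via IRLS; returns (predictions, params) or None."""
    xt = sm.add_constant(x_train, has_constant="add")
    xs = sm.add_constant(x_test, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y_train, xt, family=sm.families.Gamma(link=sm.families.links.Log()))
            res = glm.fit(maxiter=100, tol=1e-8)
        if not np.all(np.isfinite(res.params)):
            return None
        return np.asarray(res.predict(xs)), np.asarray(res.params)
    except Exception:
        return None


def _stimulus_scores(trials, att_space, space, domain):
    """Kept-component scores of each stimulus's rendered identity residual."""
    if domain == "shape":
        s = shape_matrix(trials)
        resid = s @ space.shape_basis.T            # (n, nv*3)
    else:
        from .revcorr import downsample_texture
        c = complexion_matrix(trials)
        h, w = space.texture_shape
        dev = np.zeros((len(trials), h * w * 3))
        for b, basis in enumerate(space.complexion_bases):
            dev += c[:, :, b] @ basis.T
        resid = downsample_texture(dev.reshape(-1, h, w, 3)).reshape(len(trials), -1)
    return att_space.project(resid)


def crossval_predict(
    trials: Sequence[TrialRecord],
    context_models: Sequence[PreferenceModel],
    space: GenerativeSpaceSpec,
    direction: DimorphismDirection,
    k_folds: int = 13,
    seed: int = 0,
    participant_id: str = "",
    condition: str = "",
) -> ValidationResult:
    """k-fold cross-validated rating prediction for one participant."""
    if k_folds < 2:
        raise InvalidInputError("k_folds must be >= 2")
    if len(trials) < 10 * k_folds:
        raise InvalidInputError("need at least 10 trials per fold")
    ratings = ratings_array(trials)
    if np.any(ratings <= 0):
        raise InvalidInputError("ratings must be positive for the Gamma GLM")
    rng = np.random.default_rng(seed)
    folds = make_folds(len(trials), k_folds, rng)

    taus = {f: np.full(k_folds, np.nan) for f in PREDICTOR_FAMILIES}
    coefs = {f: [None] * k_folds for f in PREDICTOR_FAMILIES}
    flagged = {f: [] for f in PREDICTOR_FAMILIES}

    avg_shape = np.array([averageness_predictor(t, "shape") for t in trials])
    avg_comp = np.array([averageness_predictor(t, "complexion") for t in trials])
    dim_shape = np.array([dimorphism_predictor(t, direction, "shape") for t in trials])
    dim_comp = np.array([dimorphism_predictor(t, direction, "complexion") for t in trials])

    for f in range(k_folds):
        train = np.flatnonzero(folds != f)
        test = np.flatnonzero(folds == f)
        train_trials = [trials[i] for i in train]
        fold_model = fit_preference_model(train_trials, participant_id, condition)

        predictors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for domain in ("shape", "complexion"):
            att_space = build_attractiveness_space(
                [fold_model, *context_models], space, domain=domain)
            scores = _stimulus_scores(trials, att_space, space, domain)
            predictors[f"attractiveness_{domain}"] = (scores[train], scores[test])
        predictors["averageness_shape"] = (avg_shape[train, None], avg_shape[test, None])
        predictors["averageness_complexion"] = (avg_comp[train, None], avg_comp[test, None])
        predictors["dimorphism_shape"] = (dim_shape[train, None], dim_shape[test, None])
        predictors["dimorphism_complexion"] = (dim_comp[train, None], dim_comp[test, None])

        for family, (x_train, x_test) in predictors.items():
            out = _fit_gamma_glm(x_train, ratings[train], x_test)
            if out is None:
                flagged[family].append(f)
                continue
            pred, params = out
            coefs[family][f] = params
            taus[family][f] = stats.kendalltau(ratings[test], pred).statistic

    return ValidationResult(
        participant_id=participant_id, k_folds=k_folds, taus=taus,
        fold_assignments=folds, glm_coefficients=coefs, flagged_folds=flagged,
        seed=seed,
    )


@dataclass
class PredictorComparison:
    mean_taus: dict[str, np.ndarray]   # family -> per-participant mean tau
    tests: dict[str, dict]             # comparison name -> {t, p_raw, p_corrected}
    n_comparisons: int


def compare_predictors(results: Sequence[ValidationResult]) -> PredictorComparison:
    """Paired t-tests of the attractiveness predictor against both alternatives.

    The paired unit is the participant's mean tau across folds; the four
    tests (attractiveness vs averageness and vs dimorphism, for shape and
    complexion) are Bonferroni-corrected.
    """
    if len(results) < 2:
        raise InvalidInputError("need at least 2 participants")
    mean_taus = {
        fam: np.array([r.mean_tau(fam) for r in results])
        for fam in PREDICTOR_FAMILIES
    }
    for fam, v in mean_taus.items():
        if np.any(np.isnan(v)):
            raise InvalidInputError(f"incomplete fold results for family {fam!r}")

    comparisons = {
        "attractiveness_vs_averageness_shape": ("attractiveness_shape", "averageness_shape"),
        "attractiveness_vs_dimorphism_shape": ("attractiveness_shape", "dimorphism_shape"),
        "attractiveness_vs_averageness_complexion": ("attractiveness_complexion", "averageness_complexion"),
        "attractiveness_vs_dimorphism_complexion": ("attractiveness_complexion", "dimorphism_complexion"),
    }
    n_comp = len(comparisons)
    tests = {}
    for name, (a, b) in comparisons.items():
        diff = mean_taus[a] - mean_taus[b]
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(mean_taus[a], mean_taus[b])
        tests[name] = {
            "t": float(t), "p_raw": float(p),
            "p_corrected": float(min(1.0, p * n_comp)),
        }
    return PredictorComparison(mean_taus=mean_taus, tests=tests, n_comparisons=n_comp)
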