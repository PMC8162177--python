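"""Simulated raters with planted linear preferences.

A participant's internal drive for a stimulus is the inner product of their
true preference vectors with the stimulus's identity coefficients, plus
Gaussian noise.  Drives are mapped onto the 9-point rating scale by empirical
quantiles (nine equal-count bins, ties broken by trial order), which
guarantees full use of the scale and a monotone, near-linear relation between
coefficients and ratings — the regime the downstream linear modeling assumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError
from .space import GenerativeSpaceSpec, TrialRecord, complexion_matrix, shape_matrix, with_ratings

N_RATING_LEVELS = 9


@dataclass
class ParticipantSpec:
    """Ground-truth description of one simulated rater."""

    participant_id: str
    culture: str
    face_ethnicity: str
    true_shape_pref: np.ndarray        # (n_shape_dims,)
    true_complexion_pref: np.ndarray   # (n_complexion_dims, n_sf_bands)
    noise_sd: float
    seed: int

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")


def preference_drive(participant: ParticipantSpec, trials: Sequence[TrialRecord]) -> np.ndarray:
    s = shape_matrix(trials)
    c = complexion_matrix(trials)
    return (s @ np.asarray(participant.true_shape_pref, float)
            + np.tensordot(c, np.asarray(participant.true_complexion_pref, float), axes=([1, 2], [0, 1])))


def quantile_ratings(drive: np.ndarray, n_levels: int = N_RATING_LEVELS) -> np.ndarray:
    """Map drives to integer ratings by equal-count quantile binning.

    Ties are broken by trial order (stable sort); a constant drive collapses
    to the scale midpoint rather than being spread over bins.
    """
    drive = np.asarray(drive, float)
    n = drive.size
    if np.ptp(drive) == 0:
        return np.full(n, (n_levels + 1) // 2, dtype=int)
    order = np.argsort(drive, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    return 1 + (rank * n_levels) // n


def simulate_ratings(
    participant: ParticipantSpec,
    stimuli: Sequence[TrialRecord],
    space: GenerativeSpaceSpec,
) -> list[TrialRecord]:
    """Fill in ratings for a stimulus list according to the planted preference."""
    if len(stimuli) == 0:
        raise InvalidInputError("stimulus list is empty")
    rng = np.random.default_rng(participant.seed)
    drive = preference_drive(participant, stimuli)
    if participant.noise_sd > 0:
        drive = drive + rng.normal(0.0, participant.noise_sd, size=drive.shape)
    return with_ratings(stimuli, quantile_ratings(drive))


def drive_signal_sd(space: GenerativeSpaceSpec, shape_pref: np.ndarray,
                    complexion_pref: np.ndarray) -> float:
    """Population SD of the noiseless drive under the space's coefficient law."""
    var = float(np.sum((np.asarray(shape_pref) * space.shape_coeff_scale) ** 2))
    var += float(np.sum((np.asarray(complexion_pref) * space.complexion_coeff_scale) ** 2))
    return np.sqrt(var)


def noise_sd_for_snr(space: GenerativeSpaceSpec, shape_pref: np.ndarray,
                     complexion_pref: np.ndarray, snr: float) -> float:
    """Noise SD that puts the drive's signal-to-noise ratio (SD ratio) at ``snr``."""
    if snr <= 0:
        raise InvalidInputError("snr must be positive")
    return drive_signal_sd(space, shape_pref, complexion_pref) / snr


def random_preference(
    space: GenerativeSpaceSpec,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a random preference: iid Gaussian weight per dimension.

    Weights are independent of the coefficient scales, so the preference
    drive is dominated by the leading (high-variance) identity components —
    the same components that dominate visible face variation.
    """
    k = space.config.n_shape_dims
    kc, nb = space.config.n_complexion_dims, space.config.n_sf_bands
    w_shape = rng.standard_normal(k) * scale
    w_comp = rng.standard_normal((kc, nb)) * scale
    return w_shape, w_comp


def expected_slope_direction(space: GenerativeSpaceSpec, shape_pref: np.ndarray,
                             complexion_pref: np.ndarray) -> np.ndarray:
    """Population direction of the reverse-regression slopes for a preference.

    The slope of coefficient on rating is proportional to
    cov(coefficient, rating); for Gaussian coefficients and any monotone
    rating link this is the preference weight scaled by the coefficient
    variance (Stein's lemma), so the recoverable direction is w * sigma^2
    per dimension, concatenated over shape then complexion.
    """
    s = np.asarray(shape_pref, float) * space.shape_coeff_scale ** 2
    c = np.asarray(complexion_pref, float) * space.complexion_coeff_scale ** 2
    return np.concatenate([s, c.ravel()])


def make_participant(
    space: GenerativeSpaceSpec,
    participant_id: str,
    culture: str,
    face_ethnicity: str,
    shape_pref: np.ndarray,
    complexion_pref: np.ndarray,
    snr: float,
    seed: int,
) -> ParticipantSpec:
    """Convenience constructor fixing noise_sd from a target drive SNR."""
    noise = noise_sd_for_snr(space, shape_pref, complexion_pref, snr)
    return ParticipantSpec(
        participant_id=participant_id, culture=culture, face_ethnicity=face_ethnicity,
        true_shape_pref=np.asarray(shape_pref, float),
        true_complexion_pref=np.asarray(complexion_pref, float),
        noise_sd=noise, seed=seed,
    )
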