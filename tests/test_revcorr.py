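import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from prefcorr3d import (
    check_linearity,
    compare_model_similarity,
    fit_local_model,
    fit_mi_model,
    fit_preference_model,
    simulate_ratings,
)
from prefcorr3d.errors import BinningError, DegenerateDesignError, InvalidInputError
from prefcorr3d.raters import ParticipantSpec, expected_slope_direction
from prefcorr3d.revcorr import PreferenceModel, gaussian_copula_mi
from prefcorr3d.space import TrialRecord

from conftest import make_identity_space


def _toy_trials(coeffs, ratings, kc=2, nb=2):
    """Trials with given shape coefficients (n, k) and ratings."""
    coeffs = np.asarray(coeffs, float)
    n = coeffs.shape[0]
    return [
        TrialRecord(i, coeffs[i], np.zeros((kc, nb)), 0, int(ratings[i]))
        for i in range(n)
    ]


def bh_mask_oracle(pvals, q):
    """Exhaustive BH: largest k with p_(k) <= k*q/m; reject the k smallest."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


# --- fit_preference_model ---------------------------------------------------

def test_fit_shapes_match_space(linear_rater):
    _, rated = linear_rater
    m = fit_preference_model(rated, "p", "c")
    assert m.shape_beta2.shape == (8,)
    assert m.complexion_beta2.shape == (6, 3)
    assert m.method == "robust_linear"
    assert np.all(np.isfinite(m.concat_beta2()))


def test_noiseless_affine_coefficient_recovered_exactly():
    rng = np.random.default_rng(0)
    ratings = rng.integers(1, 10, size=100)
    coeffs = np.column_stack([0.2 + 0.5 * ratings, np.full(100, 3.3)])
    m = fit_preference_model(_toy_trials(coeffs, ratings))
    assert m.shape_beta1[0] == pytest.approx(0.2, abs=1e-6)
    assert m.shape_beta2[0] == pytest.approx(0.5, abs=1e-6)
    # constant dimension: slope 0, intercept = the constant
    assert m.shape_beta2[1] == pytest.approx(0.0, abs=1e-9)
    assert m.shape_beta1[1] == pytest.approx(3.3, abs=1e-9)


def test_slope_matches_covariance_closed_form():
    """On clean data the reverse slope is cov(coeff, rating)/var(rating)."""
    rng = np.random.default_rng(1)
    ratings = rng.integers(1, 10, size=2000)
    coeffs = 0.4 * ratings[:, None] + rng.standard_normal((2000, 3))
    m = fit_preference_model(_toy_trials(coeffs, ratings))
    closed = np.cov(coeffs.T, ratings)[:-1, -1] / np.var(ratings, ddof=1)
    assert np.allclose(m.shape_beta2, closed, atol=0.02)


def test_constant_ratings_rejected():
    coeffs = np.random.default_rng(0).normal(size=(50, 2))
    with pytest.raises(DegenerateDesignError):
        fit_preference_model(_toy_trials(coeffs, np.full(50, 5)))


def test_too_few_trials_rejected():
    coeffs = np.random.default_rng(0).normal(size=(5, 2))
    with pytest.raises(InvalidInputError):
        fit_preference_model(_toy_trials(coeffs, [1, 2, 3, 4, 5]))


def test_nonfinite_coefficients_rejected():
    coeffs = np.random.default_rng(0).normal(size=(50, 2))
    coeffs[3, 1] = np.nan
    with pytest.raises(InvalidInputError):
        fit_preference_model(_toy_trials(coeffs, np.tile([1, 9], 25)))


# --- BH / local model -------------------------------------------------------

@pytest.mark.parametrize("seed", range(20))
def test_bh_implementation_equals_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 51))
    p = rng.uniform(size=m)
    if seed % 3 == 0:
        p[: m // 2] **= 4  # inject signal
    ours = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    assert np.array_equal(ours, bh_mask_oracle(p, 0.05))


def test_local_model_masks_planted_preference(small_space, small_stimuli, linear_rater):
    _, rated = linear_rater
    lm = fit_local_model(rated, small_space, "WE_female", fdr_q=0.05)
    assert lm.vertex_beta2.shape == (60, 3)
    assert lm.vertex_p.min() >= 0 and lm.vertex_p.max() <= 1
    # a real preference at SNR 2 lights up a nontrivial share of vertices
    assert lm.vertex_mask.mean() > 0.2
    assert lm.pixel_mask.mean() > 0.05


def test_local_model_fdr_controlled_under_null(small_space, small_stimuli):
    k = small_space.config.n_shape_dims
    kc, nb = small_space.config.n_complexion_dims, small_space.config.n_sf_bands
    fracs = []
    for seed in range(5):
        null = ParticipantSpec(f"null{seed}", "WE", "WE", np.zeros(k),
                               np.zeros((kc, nb)), 1.0, seed=seed)
        rated = simulate_ratings(null, small_stimuli, small_space)
        lm = fit_local_model(rated, small_space, "WE_female", fdr_q=0.05)
        fracs.append(lm.vertex_mask.mean())
    assert np.mean(fracs) <= 0.05 + 0.02


# --- linearity check --------------------------------------------------------

def test_linear_rater_yields_near_linear_centroids(small_space, small_stimuli):
    """With a low-noise linear rater every centroid tracks its bin1-bin5 line."""
    from prefcorr3d import make_participant, random_preference

    rng = np.random.default_rng(31)
    ws, wc = random_preference(small_space, rng)
    p = make_participant(small_space, "p_quiet", "WE", "WE", ws, wc, snr=5.0, seed=13)
    rated = simulate_ratings(p, small_stimuli, small_space)
    rep = check_linearity(rated, small_space, "WE_female")
    assert rep.distance_matrix.shape == (60, 5)
    assert rep.k_selected >= 1

    # Analytic oracle: with Gaussian drives and equal-count rating bins of
    # probability {2,2,1,2,2}/9, bin-conditional drive means are truncated
    # normal means; their own deviation from the bin1-bin5 straight line is
    # the intrinsic floor any linear rater shows.
    edges = stats.norm.ppf(np.array([0, 2, 4, 5, 7, 9]) / 9)
    probs = np.diff(stats.norm.cdf(edges))
    cond = (stats.norm.pdf(edges[:-1]) - stats.norm.pdf(edges[1:])) / probs
    line = np.linspace(cond[0], cond[-1], 5)
    intrinsic = np.abs(cond - line).max() / (cond[-1] - cond[0])

    global_range = rep.cluster_centroids.max() - rep.cluster_centroids.min()
    rel = rep.max_deviation_from_line / global_range
    assert np.all(rel < intrinsic + 0.05)
    # the profile itself should track the analytic bin-mean curve closely
    main = np.argmax(np.abs(rep.cluster_centroids).max(axis=1))
    c = rep.cluster_centroids[main]
    c_norm = c / np.abs(c).max() * np.abs(cond).max() * np.sign(c[-1])
    assert np.abs(c_norm - cond).max() < 0.25


def test_empty_bin_raises_named_error(small_space, small_stimuli):
    import dataclasses
    rated = [dataclasses.replace(t, rating=5) for t in small_stimuli[:100]]
    with pytest.raises(BinningError, match="bin"):
        check_linearity(rated, small_space, "WE_female")


def test_structureless_distances_select_one_cluster(small_space, small_stimuli):
    """A null rater's distance rows have no cluster structure -> small k."""
    k = small_space.config.n_shape_dims
    kc, nb = small_space.config.n_complexion_dims, small_space.config.n_sf_bands
    null = ParticipantSpec("null", "WE", "WE", np.zeros(k), np.zeros((kc, nb)),
                           1.0, seed=3)
    rated = simulate_ratings(null, small_stimuli, small_space)
    rep = check_linearity(rated, small_space, "WE_female")
    assert rep.k_selected <= 3


# --- mutual information -----------------------------------------------------

def histogram_mi_oracle(x, y, bins=8):
    """Plug-in MI from a 2D histogram (nats)."""
    pxy, _, _ = np.histogram2d(x, y, bins=bins)
    pxy /= pxy.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def test_gcmi_tracks_histogram_oracle_ranking():
    rng = np.random.default_rng(0)
    n = 4000
    r = rng.integers(1, 10, size=n).astype(float)
    strong = 0.9 * r + 0.3 * rng.standard_normal(n)
    weak = 0.2 * r + 1.0 * rng.standard_normal(n)
    none = rng.standard_normal(n)
    y = np.column_stack([strong, weak, none])
    mi = gaussian_copula_mi(r, y)
    oracle = [histogram_mi_oracle(r, y[:, j]) for j in range(3)]
    assert np.argsort(mi).tolist() == np.argsort(oracle).tolist() == [2, 1, 0]
    assert mi[0] > 10 * mi[2]


def test_independent_dimension_mi_below_shuffle_null():
    rng = np.random.default_rng(5)
    n = 2000
    r = rng.integers(1, 10, size=n).astype(float)
    x = rng.standard_normal(n)
    observed = gaussian_copula_mi(r, x)[0]
    null = np.array([gaussian_copula_mi(r, rng.permutation(x))[0] for _ in range(200)])
    assert observed < np.percentile(null, 95)


def test_monotone_noiseless_dimension_has_maximal_mi(linear_rater):
    _, rated = linear_rater
    import dataclasses
    # splice a perfectly rating-locked dimension into slot 0
    spiked = [dataclasses.replace(
        t, shape_coeffs=np.concatenate([[float(t.rating) ** 3], t.shape_coeffs[1:]]))
        for t in rated]
    mi_model = fit_mi_model(spiked, "p", "c")
    assert np.argmax(np.abs(mi_model.shape_beta2)) == 0
    assert mi_model.method == "mi_signed"
    assert np.all(mi_model.shape_beta1 == 0)


def test_mi_and_linear_models_agree_for_linear_rater(small_space, linear_rater):
    _, rated = linear_rater
    lin = fit_preference_model(rated, "p", "c")
    mi = fit_mi_model(rated, "p", "c")
    rho = stats.spearmanr(lin.concat_beta2(), mi.concat_beta2()).statistic
    assert rho >= 0.95


# --- model similarity -------------------------------------------------------

def _identity_model(shape_beta2, complexion_beta2, method="robust_linear"):
    shape_beta2 = np.asarray(shape_beta2, float)
    complexion_beta2 = np.asarray(complexion_beta2, float)
    return PreferenceModel(
        participant_id="m", condition="c", method=method,
        shape_beta1=np.zeros_like(shape_beta2), shape_beta2=shape_beta2,
        complexion_beta1=np.zeros_like(complexion_beta2),
        complexion_beta2=complexion_beta2, n_trials=100,
    )


def test_self_similarity_is_one_and_significant():
    space = make_identity_space()
    rng = np.random.default_rng(0)
    m = _identity_model(rng.normal(size=6), rng.normal(size=(6, 1)))
    rep = compare_model_similarity(m, m, space, n_perm=100, seed=0)
    assert rep.spearman_shape == pytest.approx(1.0)
    assert rep.spearman_complexion == pytest.approx(1.0)
    assert rep.significant_shape and rep.significant_complexion


def test_similarity_equals_hand_rank_correlation():
    """6-dim fixture: Spearman equals the rank-Pearson formula by hand."""
    space = make_identity_space()
    a = _identity_model([3.0, -1.0, 2.0, 0.5, -2.5, 1.5],
                        np.arange(6.0).reshape(6, 1))
    b = _identity_model([2.0, -0.5, 2.5, 0.1, -3.0, 0.9],
                        np.arange(6.0)[::-1].reshape(6, 1))
    rep = compare_model_similarity(a, b, space, n_perm=100, seed=0)

    def ranks(v):
        order = np.argsort(np.argsort(v))
        return order.astype(float)

    ra, rb = ranks(a.shape_beta2), ranks(b.shape_beta2)
    hand = np.corrcoef(ra, rb)[0, 1]
    assert rep.spearman_shape == pytest.approx(hand, abs=1e-12)


def test_magnitude_shuffle_null_calibrated():
    """A magnitude-shuffled model is called similar only at chance rate."""
    space = make_identity_space()
    rng = np.random.default_rng(1)
    hits = 0
    n_rep = 40
    for i in range(n_rep):
        sb = rng.normal(size=6)
        cb = rng.normal(size=(6, 1))
        a = _identity_model(sb, cb)
        shuffled = _identity_model(np.sign(sb) * np.abs(sb)[rng.permutation(6)],
                                   np.sign(cb) * np.abs(cb)[rng.permutation(6)].reshape(6, 1))
        rep = compare_model_similarity(a, shuffled, space, n_perm=100, seed=100 + i)
        hits += rep.significant_shape
    assert hits / n_rep <= 0.15


def test_dimension_mismatch_rejected(linear_rater):
    _, rated = linear_rater
    m = fit_preference_model(rated)
    other = _identity_model(np.ones(3), np.ones((2, 1)))
    space = make_identity_space()
    from prefcorr3d.errors import DimensionMismatchError
    with pytest.raises(DimensionMismatchError):
        compare_model_similarity(m, other, space)
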