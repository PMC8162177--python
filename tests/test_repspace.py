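import dataclasses

import numpy as np
import pytest

from prefcorr3d import (
    bootstrap_models,
    build_attractiveness_space,
    classify_transfer_interactive,
    decompose_variance,
    elbow_select,
    fit_preference_model,
    permutation_thresholds,
)
from prefcorr3d.errors import InvalidInputError
from prefcorr3d.revcorr import PreferenceModel

from conftest import make_identity_space


def elbow_oracle(values):
    """Brute force: perpendicular distance of each point to the chord."""
    v = np.asarray(values, float)
    x = np.arange(1, v.size + 1, dtype=float)
    p1 = np.array([x[0], v[0]])
    p2 = np.array([x[-1], v[-1]])
    chord = p2 - p1
    norm = np.linalg.norm(chord)
    best, best_d = 0, -1.0
    for i in range(v.size):
        rel = np.array([x[i], v[i]]) - p1
        d = abs(chord[0] * rel[1] - chord[1] * rel[0]) / max(norm, 1e-300)
        if d > best_d + 1e-15:
            best, best_d = i, d
    return best + 1


# --- elbow ------------------------------------------------------------------

@pytest.mark.parametrize("values,expected", [
    ([10, 5, 1, 0.9, 0.8, 0.7], 3),
    ([100, 1, 0.99, 0.98], 2),
    ([4.0, 3.0, 2.0, 1.0], 1),   # exactly linear decay -> tie-break to first
])
def test_elbow_worked_examples(values, expected):
    assert elbow_select(values) == expected
    assert elbow_oracle(values) == expected


@pytest.mark.parametrize("seed", range(30))
def test_elbow_matches_brute_force_on_random_spectra(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    v = np.sort(rng.exponential(size=n))[::-1]
    assert elbow_select(v) == elbow_oracle(v)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.floats(0.01, 100.0, allow_nan=False, allow_infinity=False),
                min_size=3, max_size=30))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_elbow_selects_a_maximal_chord_distance_point(vals):
    v = np.sort(np.asarray(vals, float))[::-1]
    idx = elbow_select(v)
    assert 1 <= idx <= v.size
    # the selected point attains the maximal perpendicular distance
    x = np.arange(1, v.size + 1, dtype=float)
    dx, dy = x[-1] - x[0], v[-1] - v[0]
    norm = max(np.hypot(dx, dy), 1e-300)
    dist = np.abs(dx * (v[0] - v) - (x[0] - x) * dy) / norm
    assert dist[idx - 1] >= dist.max() - 1e-12
    # ties resolve to the earliest index
    assert not np.any(dist[: idx - 1] >= dist[idx - 1] + 1e-12)


def test_elbow_needs_three_values():
    with pytest.raises(InvalidInputError):
        elbow_select([3.0, 1.0])


# --- attractiveness space ---------------------------------------------------

def _random_models(space, n, rng, center=None, spread=1.0, condition="c"):
    k = space.config.n_shape_dims
    kc, nb = space.config.n_complexion_dims, space.config.n_sf_bands
    out = []
    for i in range(n):
        sb = (center if center is not None else 0) + spread * rng.normal(size=k)
        out.append(PreferenceModel(f"p{i}", condition, "robust_linear",
                                   np.zeros(k), sb, np.zeros((kc, nb)),
                                   rng.normal(size=(kc, nb)), 100))
    return out


def test_pca_reconstruction_is_lossless(small_space):
    rng = np.random.default_rng(0)
    models = _random_models(small_space, 6, rng)
    att = build_attractiveness_space(models, small_space, domain="shape")
    from prefcorr3d.revcorr import model_vertex_map
    mat = np.stack([model_vertex_map(m, small_space) for m in models])
    centered = mat - att.mean[None, :]
    recon = (centered @ att.loadings) @ att.loadings.T
    assert np.abs(recon - centered).max() < 1e-8
    assert np.all(np.diff(att.var_explained) <= 1e-12)
    assert att.n_kept <= att.eigenvalues.size


def test_duplicated_models_duplicate_scores(small_space):
    rng = np.random.default_rng(1)
    models = _random_models(small_space, 5, rng)
    att1 = build_attractiveness_space(models, small_space, domain="shape", n_kept=3)
    att2 = build_attractiveness_space(models * 2, small_space, domain="shape", n_kept=3)
    # same component directions up to sign; scores repeat
    for j in range(3):
        s1, s2 = att1.scores[:, j], att2.scores[:5, j]
        sign = np.sign(s1 @ s2)
        assert np.allclose(s1 * sign, s2, atol=1e-8)
        assert np.allclose(att2.scores[:5, j], att2.scores[5:, j], atol=1e-10)


def test_two_planted_groups_are_linearly_separable(small_space):
    rng = np.random.default_rng(2)
    c1 = 3.0 * rng.normal(size=8)
    c2 = -c1
    ga = _random_models(small_space, 10, rng, center=c1, spread=0.3, condition="A")
    gb = _random_models(small_space, 10, rng, center=c2, spread=0.3, condition="B")
    att = build_attractiveness_space(ga + gb, small_space, domain="shape")
    labels = np.array([1] * 10 + [-1] * 10)
    # project onto the centroid-difference axis in kept-score space
    mu_a = att.scores[:10].mean(axis=0)
    mu_b = att.scores[10:].mean(axis=0)
    axis = mu_a - mu_b
    proj = att.scores @ axis
    margin = proj[labels == 1].min() - proj[labels == -1].max()
    assert margin > 0


def test_space_requires_two_models(small_space):
    with pytest.raises(InvalidInputError):
        build_attractiveness_space(
            _random_models(small_space, 1, np.random.default_rng(0)), small_space)


# --- bootstrap --------------------------------------------------------------

def test_noiseless_rater_bootstraps_to_original(small_space, small_stimuli):
    """With a deterministic rating rule, resampled refits equal the original."""
    import dataclasses as dc
    # ratings are an exact linear function of one coefficient
    trials = [dc.replace(t) for t in small_stimuli[:200]]
    vals = np.array([t.shape_coeffs[0] for t in trials])
    order = np.argsort(np.argsort(vals))
    ratings = 1 + (order * 9) // len(trials)
    trials = [dc.replace(t, rating=int(r)) for t, r in zip(trials, ratings)]
    original = fit_preference_model(trials, "p")
    boots = bootstrap_models(trials, n_boot=3, seed=0, participant_id="p")
    for b in boots:
        # dimension 0 drives ratings deterministically; its slope is stable
        assert abs(b.shape_beta2[0] - original.shape_beta2[0]) < 0.15 * abs(
            original.shape_beta2[0])


def test_bootstrap_spread_shrinks_with_trials(small_space):
    from prefcorr3d import make_participant, random_preference, simulate_ratings, synthesize_stimuli
    rng = np.random.default_rng(3)
    ws, wc = random_preference(small_space, rng)
    spreads = []
    for n in (500, 2000):
        stim = synthesize_stimuli(small_space, n, seed=50 + n)
        p = make_participant(small_space, "p", "WE", "WE", ws, wc, snr=2.0, seed=9)
        rated = simulate_ratings(p, stim, small_space)
        boots = bootstrap_models(rated, n_boot=12, seed=1, participant_id="p")
        b2 = np.stack([b.shape_beta2 for b in boots])
        spreads.append(b2.std(axis=0).mean())
    ratio = spreads[0] / spreads[1]
    assert 1.4 < ratio < 2.9  # ~sqrt(2000/500) = 2


# --- variance decomposition -------------------------------------------------

def test_decomposition_matches_hand_arithmetic():
    """8-model fixture with listed scores vs hand-computed SS terms."""
    scores = np.array([[2.0], [4.0], [3.0], [5.0], [-1.0], [-3.0], [-2.0], [-4.0]])
    groups = ["A"] * 4 + ["B"] * 4
    parts = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
    d = decompose_variance(scores, groups, parts)
    # SStotal = 4+16+9+25+1+9+4+16 = 84
    assert d.ss_total[0] == pytest.approx(84.0)
    # group means: A=3.5, B=-2.5 -> resi1 = [-1.5,.5,-.5,1.5,1.5,-.5,.5,-1.5]
    assert d.ss_resi1[0] == pytest.approx(2 * (2.25 + 0.25 + 0.25 + 2.25))
    # participant means of resi1: a1=-0.5, a2=0.5, b1=0.5, b2=-0.5
    # resi2 = [-1,1,-1,1,1,-1,1,-1] -> SS = 8
    assert d.ss_resi2[0] == pytest.approx(8.0)
    assert d.r2_group[0] == pytest.approx(1 - 10.0 / 84.0)
    assert d.r2_participant[0] == pytest.approx((10.0 / 84.0) * (1 - 8.0 / 10.0))


def test_decomposition_identity_holds():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=(40, 5))
    groups = [f"g{i % 4}" for i in range(40)]
    parts = [f"p{i // 2}" for i in range(40)]
    d = decompose_variance(scores, groups, parts)
    lhs = d.ss_resi2 / d.ss_total + d.r2_group + d.r2_participant
    assert np.abs(lhs - 1.0).max() < 1e-10
    assert np.all(d.ss_resi2 <= d.ss_resi1 + 1e-12)
    assert np.all(d.ss_resi1 <= d.ss_total + 1e-12)


def test_pure_group_structure_fully_explained():
    scores = np.array([[1.0], [1.0], [-1.0], [-1.0]])
    d = decompose_variance(scores, ["A", "A", "B", "B"], ["a", "a", "b", "b"])
    assert d.r2_group[0] == pytest.approx(1.0)
    assert d.r2_participant[0] == pytest.approx(0.0)


def test_identical_groups_distinct_participants():
    scores = np.array([[2.0], [2.0], [-2.0], [-2.0], [2.0], [2.0], [-2.0], [-2.0]])
    groups = ["A"] * 4 + ["B"] * 4
    parts = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
    d = decompose_variance(scores, groups, parts)
    assert abs(d.r2_group[0]) < 1e-12
    assert d.r2_participant[0] == pytest.approx(1.0)


# --- permutation thresholds -------------------------------------------------

def test_bonferroni_percentiles_match_component_counts():
    rng = np.random.default_rng(5)
    parts = [f"p{i // 5}" for i in range(40)]
    groups = ["A" if i < 20 else "B" for i in range(40)]
    r8 = permutation_thresholds(rng.normal(size=(40, 8)), groups, parts,
                                mode="group", n_perm=100, alpha=0.05, seed=0)
    assert r8.percentile == pytest.approx(99.375)
    r3 = permutation_thresholds(rng.normal(size=(40, 3)), groups, parts,
                                mode="group", n_perm=100, alpha=0.05, seed=0)
    assert r3.percentile == pytest.approx(100 - 5 / 3, abs=0.01)


def test_participant_blocks_move_together():
    with pytest.raises(InvalidInputError):
        # participant straddling two conditions is inconsistent block structure
        permutation_thresholds(np.zeros((4, 2)), ["A", "A", "B", "B"],
                               ["p1", "p2", "p2", "p3"], mode="group", n_perm=100)


# --- transferred vs interactive --------------------------------------------

def _sign_model(space, signs_shape, signs_comp, condition):
    k = space.config.n_shape_dims
    return PreferenceModel("m", condition, "robust_linear", np.zeros(k),
                           np.asarray(signs_shape, float),
                           np.zeros_like(np.asarray(signs_comp, float)),
                           np.asarray(signs_comp, float), 100)


def test_transfer_classification_hand_fixture():
    """Signs W_same=[+,-,+,...], E_same=[-,-,+...], W_other=[+,-,-...]."""
    space = make_identity_space()
    wsame = _sign_model(space, [+1, -1, +1, +1, -1, +1], np.ones((6, 1)), "WE_same")
    esame = _sign_model(space, [-1, -1, +1, -1, +1, -1], -np.ones((6, 1)), "EA_same")
    wother = _sign_model(space, [+1, -1, -1, 0, +1, -1], np.ones((6, 1)), "WE_other")
    tmap = classify_transfer_interactive(wsame, wother, esame, space)
    # per location: transferred(1), both(3), neither(0), zero->neither(0),
    # interactive(2), interactive(2)
    assert tmap.vertex_class.ravel().tolist() == [1, 3, 0, 0, 2, 2]
    # complexion: wother shares sign with wsame everywhere, opposite to esame
    assert np.all(tmap.pixel_class == 1)


def test_full_agreement_is_all_transferred():
    space = make_identity_space()
    wsame = _sign_model(space, [+1, -1, +1, -1, +1, -1], np.ones((6, 1)), "WE_same")
    esame = _sign_model(space, [-1, +1, -1, +1, -1, +1], -np.ones((6, 1)), "EA_same")
    tmap = classify_transfer_interactive(wsame, wsame, esame, space)
    assert np.all(tmap.vertex_class == 1)
    assert np.all(tmap.pixel_class == 1)
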