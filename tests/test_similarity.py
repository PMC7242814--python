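"""Pattern similarity: exact constructed correlations, cross-session rule,
naive pair-enumeration oracle, and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dediff.similarity import (
    NoCrossSessionPairs,
    SimilarityError,
    memory_conditioned_similarity,
    within_between_similarity,
)
from dediff.simulate import NeuralGenParams, simulate_betas
from tests.conftest import make_beta_matrix
from tests.test_simulate import _mini_study_design


def _orthonormal_centered_basis(n_voxels, k, seed=0):
    """k orthonormal vectors, each orthogonal to the constant vector."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n_voxels, k))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return Q.T


def gram_schmidt_patterns(n_voxels=8):
    """Four trials over two sessions with exact pair correlations:
    cross-session same-category r = 0.5, cross-category r = 0."""
    e = _orthonormal_centered_basis(n_voxels, 4)
    a1, b1 = e[0], e[2]
    a2 = 0.5 * e[0] + np.sqrt(0.75) * e[1]
    b2 = 0.5 * e[2] + np.sqrt(0.75) * e[3]
    values = np.stack([a1, b1, a2, b2])
    return make_beta_matrix(values, ["scene", "face", "scene", "face"],
                            [1, 1, 2, 2], preferred="scene")


def naive_similarity(bm, within_scope="both_categories"):
    """Independent oracle: double loop over all unordered pairs."""
    X, meta = bm.values, bm.meta
    wz, bz = [], []
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            if meta.session[i] == meta.session[j]:
                continue
            r = np.corrcoef(X[i], X[j])[0, 1]
            if meta.category[i] == meta.category[j]:
                if within_scope == "preferred_only" and meta.category[i] != bm.roi.preferred:
                    continue
                wz.append(np.arctanh(r))
            else:
                bz.append(np.arctanh(r))
    return np.mean(wz), np.mean(bz), np.mean(wz) - np.mean(bz)


class TestExactConstruction:
    def test_index_equals_atanh_half(self):
        res = within_between_similarity(gram_schmidt_patterns())
        assert res.within_z == pytest.approx(np.arctanh(0.5), abs=1e-6)
        assert res.between_z == pytest.approx(0.0, abs=1e-6)
        assert res.index == pytest.approx(np.arctanh(0.5), abs=1e-6)
        assert res.n_within_pairs == 2 and res.n_between_pairs == 2

    def test_same_session_pairs_never_counted(self):
        res = within_between_similarity(gram_schmidt_patterns())
        # 4 trials -> 6 unordered pairs, 2 of them same-session
        assert res.n_within_pairs + res.n_between_pairs == 4


class TestOracleEquivalence:
    @pytest.mark.parametrize("scope", ["both_categories", "preferred_only"])
    def test_matches_naive_enumeration(self, rng, scope):
        """Transform-then-average order verified against the pair loop."""
        n = 20
        values = rng.normal(size=(n, 12))
        cats = list(np.where(rng.random(n) < 0.5, "scene", "face"))
        cats[:2] = ["scene", "face"]  # ensure both present
        sessions = list(rng.integers(1, 5, size=n))
        sessions[:2] = [1, 2]
        bm = make_beta_matrix(values, cats, sessions, preferred="scene")
        res = within_between_similarity(bm, within_scope=scope)
        wz, bz, idx = naive_similarity(bm, scope)
        assert res.within_z == pytest.approx(wz, abs=1e-12)
        assert res.between_z == pytest.approx(bz, abs=1e-12)
        assert res.index == pytest.approx(idx, abs=1e-12)


class TestInvariances:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(gain=st.floats(0.01, 50), shift=st.floats(-20, 20),
           trial=st.integers(0, 3))
    def test_per_trial_affine_invariance(self, gain, shift, trial):
        bm = gram_schmidt_patterns()
        base = within_between_similarity(bm)
        values = bm.values.copy()
        values[trial] = values[trial] * gain + shift
        tr = make_beta_matrix(values, bm.meta.category, bm.meta.session,
                              preferred="scene")
        res = within_between_similarity(tr)
        assert res.index == pytest.approx(base.index, abs=1e-9)

    def test_label_permutation_null(self, rng):
        """Random category relabeling: mean index ~ 0 (exchangeability)."""
        values = rng.normal(size=(16, 10))
        sessions = [1, 2, 3, 4] * 4
        idxs = []
        for _ in range(300):
            cats = list(rng.permutation(["scene"] * 8 + ["face"] * 8))
            bm = make_beta_matrix(values, cats, sessions, preferred="scene")
            idxs.append(within_between_similarity(bm).index)
        idxs = np.asarray(idxs)
        assert abs(idxs.mean()) < 3 * idxs.std(ddof=1) / np.sqrt(len(idxs)) + 1e-3

    def test_noise_decreases_within_similarity(self):
        """Doubling voxel noise at fixed kappa lowers expected within_z."""
        design = _mini_study_design(n_per_cat=16)
        means = []
        for sigma in (1.0, 2.0):
            npar = NeuralGenParams("R", "scene", 24,
                                   kappa={"face": 2.0, "scene": 2.0}, sigma=sigma)
            wz = [within_between_similarity(simulate_betas(design, npar, seed=s)).within_z
                  for s in range(200)]
            means.append(np.mean(wz))
        assert means[1] < means[0]


class TestCrossSessionRule:
    def test_session_noise_inflates_only_same_session_pairs(self, rng):
        """Shared session components inflate same-session similarity; the
        reported metrics exclude those pairs and match the naive
        cross-session oracle exactly."""
        n, v = 24, 40
        base = rng.normal(size=(n, v))
        sessions = np.repeat([1, 2, 3, 4], 6)
        session_noise = {s: rng.normal(size=v) * 1.5 for s in (1, 2, 3, 4)}
        inflated = base + np.stack([session_noise[s] for s in sessions])
        cats = ["scene", "face"] * 12
        bm = make_beta_matrix(inflated, cats, sessions, preferred="scene")

        r = np.corrcoef(inflated)
        same = sessions[:, None] == sessions[None, :]
        upper = np.triu(np.ones((n, n), bool), 1)
        z_same = np.arctanh(r[same & upper]).mean()
        z_cross = np.arctanh(r[~same & upper]).mean()
        assert z_same > z_cross + 0.2  # the confound the rule avoids

        res = within_between_similarity(bm)
        wz, bz, idx = naive_similarity(bm)
        assert res.index == pytest.approx(idx, abs=1e-12)

    def test_single_session_raises(self):
        bm = make_beta_matrix(np.random.default_rng(0).normal(size=(4, 6)),
                              ["scene", "face", "scene", "face"], [1, 1, 1, 1])
        with pytest.raises(NoCrossSessionPairs):
            within_between_similarity(bm)

    def test_zero_variance_pattern_raises(self):
        values = np.random.default_rng(0).normal(size=(4, 6))
        values[2] = 5.0
        bm = make_beta_matrix(values, ["scene", "face", "scene", "face"],
                              [1, 1, 2, 2])
        with pytest.raises(SimilarityError, match="zero-variance"):
            within_between_similarity(bm)

    def test_perfect_correlation_raises(self):
        values = np.random.default_rng(0).normal(size=(4, 6))
        values[2] = values[0] * 2.0  # r = 1 across sessions
        bm = make_beta_matrix(values, ["scene", "face", "scene", "face"],
                              [1, 1, 2, 2])
        with pytest.raises(SimilarityError, match="r"):
            within_between_similarity(bm)


class TestMemoryConditioned:
    def test_subset_equals_full_when_identical(self):
        bm = gram_schmidt_patterns()
        bm.meta["memory_status"] = "source_correct"
        full = within_between_similarity(bm)
        sub = memory_conditioned_similarity(bm)
        assert sub.index == pytest.approx(full.index)
        assert sub.condition == "source_correct_only"

    def test_subset_single_session_raises(self):
        bm = gram_schmidt_patterns()
        bm.meta["memory_status"] = ["source_correct", "source_correct",
                                    "other", "other"]
        with pytest.raises(NoCrossSessionPairs):
            memory_conditioned_similarity(bm)

    def test_homogeneous_subset_close_to_full(self):
        design = _mini_study_design(n_per_cat=48)
        npar = NeuralGenParams("R", "scene", 24,
                               kappa={"face": 2.0, "scene": 2.0}, sigma=1.0)
        rng = np.random.default_rng(3)
        diffs = []
        for s in range(60):
            bm = simulate_betas(design, npar, seed=s)
            bm.meta["memory_status"] = np.where(rng.random(bm.n_trials) < 0.7,
                                                "source_correct", "other")
            full = within_between_similarity(bm).index
            sub = memory_conditioned_similarity(bm).index
            diffs.append(sub - full)
        assert abs(np.mean(diffs)) < 0.02
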