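"""Multivariate scorers (combinedZ, pca1, plage, ssgsea, gsva) against
independent staged reference implementations."""

import math

import numpy as np
import pandas as pd
import pytest

from sigscore import Signature, score_signature
from sigscore.scorers import (
    combined_z_scores,
    feature_id_rank,
    gsva_scores,
    pca1_scores,
    plage_scores,
    ssgsea_scores,
)

from conftest import random_matrix


# ---------------------------------------------------------------------------
# independent oracles


def orient(scores, reference):
    s, r = scores - scores.mean(), reference - reference.mean()
    return -scores if float(np.dot(s, r)) < 0 else scores


def pca1_oracle(sub):
    """Eigen-decomposition of the sample covariance (samples = observations)."""
    d = sub.T - sub.mean(axis=1)  # n_samples x k, feature-centered
    cov = d.T @ d / (d.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    scores = d @ evecs[:, -1]
    return orient(scores, sub.mean(axis=0))


def plage_oracle(sub):
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
    _, _, vt = np.linalg.svd(z)
    return orient(vt[0].copy(), z.mean(axis=0))


def ssgsea_oracle(values, fids, sig_features, alpha):
    """Literal per-position enumeration of the running-sum difference."""
    n_feat, n_samp = values.shape
    in_sig = [f in sig_features for f in fids]
    out = []
    for j in range(n_samp):
        order = sorted(range(n_feat), key=lambda i: (-values[i, j], fids[i]))
        total_in = sum(
            (n_feat - pos) ** alpha for pos, i in enumerate(order) if in_sig[i]
        )
        total_out = sum(1 for i in order if not in_sig[i])
        es, cin, cout = 0.0, 0.0, 0.0
        for pos, i in enumerate(order):
            if in_sig[i]:
                cin += (n_feat - pos) ** alpha
            else:
                cout += 1
            es += cin / total_in - cout / total_out
        out.append(es)
    return np.array(out)


def phi(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def gsva_oracle(values, fids, sig_features, tau=1.0):
    """Literal three-stage reference: kernel CDF -> rank stat -> KS walk."""
    n_feat, n_samp = values.shape
    # stage 1: Gaussian-kernel CDF estimate, bandwidth sd/4
    zhat = np.empty_like(values, dtype=float)
    for i in range(n_feat):
        sd = float(np.std(values[i], ddof=1))
        mu = float(np.mean(values[i]))
        if sd == 0:
            zhat[i] = 0.5
            continue
        h = max(sd / 4.0, 1e-12 * max(1.0, abs(mu)))
        for j in range(n_samp):
            zhat[i, j] = sum(phi((values[i, j] - values[i, k]) / h) for k in range(n_samp)) / n_samp
    in_sig = [f in sig_features for f in fids]
    k = sum(in_sig)
    out = []
    for j in range(n_samp):
        # stage 2: descending ranks (tie: ascending feature id), symmetric stat
        order = sorted(range(n_feat), key=lambda i: (-zhat[i, j], fids[i]))
        rank = {i: pos + 1 for pos, i in enumerate(order)}
        t = {i: abs(n_feat / 2.0 - rank[i]) for i in range(n_feat)}
        # stage 3: KS-like walk down the ranked list
        denom = sum(t[i] ** tau for i in order if in_sig[i])
        walk, mx, mn = 0.0, 0.0, 0.0
        for i in order:
            if in_sig[i]:
                walk += t[i] ** tau / denom if denom > 0 else 0.0
            else:
                walk += -1.0 / (n_feat - k)
            mx, mn = max(mx, walk), min(mn, walk)
        out.append(mx + mn)
    return np.array(out)


def make_inputs(rng, n_feat, n_samp, k):
    m = random_matrix(rng, n_feat, n_samp)
    feats = tuple(rng.choice(m.index.to_numpy(), size=k, replace=False))
    sig = Signature("s", feats)
    in_mask = np.array([f in feats for f in m.index])
    return m, sig, in_mask


# ---------------------------------------------------------------------------


class TestCombinedZ:
    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 20, 10)
        values = m.to_numpy()
        idx = np.arange(5)
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, ddof=1, keepdims=True
        )
        expected = z[idx].sum(axis=0) / np.sqrt(5)
        assert np.allclose(combined_z_scores(values, idx), expected, atol=1e-12)

    def test_single_feature_equals_its_z(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(4, 6))
        z0 = (values[2] - values[2].mean()) / values[2].std(ddof=1)
        assert np.allclose(combined_z_scores(values, np.array([2])), z0, atol=1e-12)

    def test_all_constant_rows_missing_with_warning(self):
        values = np.ones((3, 4))
        with pytest.warns(UserWarning, match="constant"):
            out = combined_z_scores(values, np.array([0, 1]))
        assert np.isnan(out).all()


class TestPCA1:
    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            sub = rng.normal(size=(rng.integers(2, 12), rng.integers(2, 10)))
            assert np.allclose(pca1_scores(sub), pca1_oracle(sub), atol=1e-8)

    def test_rank_one_submatrix_recovers_pattern(self):
        rng = np.random.default_rng(14)
        p = rng.normal(size=6)
        c = rng.normal(size=4)
        sub = np.outer(c, p)
        scores = pca1_scores(sub)
        r = np.corrcoef(scores, p)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_submatrix_gives_zeros(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.all(pca1_scores(np.ones((3, 5))) == 0)


class TestPLAGE:
    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            sub = rng.normal(size=(rng.integers(2, 9), rng.integers(3, 8)))
            assert np.allclose(plage_scores(sub), plage_oracle(sub), atol=1e-8)

    def test_unit_norm(self):
        rng = np.random.default_rng(16)
        s = plage_scores(rng.normal(size=(8, 5)))
        assert np.linalg.norm(s) == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_row_matches_single_row(self):
        rng = np.random.default_rng(17)
        row = rng.normal(size=6)
        one = plage_scores(row[None, :].repeat(2, axis=0))
        z = (row - row.mean()) / row.std(ddof=1)
        expected = orient(z / np.linalg.norm(z), z)
        assert np.allclose(np.abs(one), np.abs(expected), atol=1e-10)


class TestSsgsea:
    def test_four_feature_hand_example(self):
        # single sample, values g1..g4 = 3,1,2,4, signature {g1}:
        # walk order g4,g1,g3,g2; ES = -1/3 + 2/3 + 1/3 + 0 = 2/3 for any alpha
        m = pd.DataFrame([[3.0], [1.0], [2.0], [4.0]],
                         index=["g1", "g2", "g3", "g4"], columns=["s1"])
        s, _ = score_signature(m, Signature("h", ("g1",)), "ssgsea")
        assert s.iloc[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(15):
            m, sig, in_mask = make_inputs(rng, int(rng.integers(4, 11)), int(rng.integers(1, 7)), 2)
            got = ssgsea_scores(m.to_numpy(), in_mask, feature_id_rank(m.index), alpha=0.25)
            exp = ssgsea_oracle(m.to_numpy(), list(m.index), set(sig.features), 0.25)
            assert np.allclose(got, exp, atol=1e-10)

    def test_alpha_zero_reduces_to_counts(self):
        rng = np.random.default_rng(19)
        m, sig, in_mask = make_inputs(rng, 8, 3, 3)
        got = ssgsea_scores(m.to_numpy(), in_mask, feature_id_rank(m.index), alpha=0.0)
        exp = ssgsea_oracle(m.to_numpy(), list(m.index), set(sig.features), 0.0)
        assert np.allclose(got, exp, atol=1e-12)

    def test_higher_signature_rank_scores_higher(self):
        m = pd.DataFrame(
            {"a": [5.0, 1.0, 2.0], "b": [1.0, 5.0, 2.0]}, index=["g1", "g2", "g3"]
        )
        s, _ = score_signature(m, Signature("t", ("g1",)), "ssgsea")
        assert s["a"] > s["b"]

    def test_raising_signature_values_increases_score(self):
        rng = np.random.default_rng(20)
        m, sig, in_mask = make_inputs(rng, 10, 4, 3)
        base = ssgsea_scores(m.to_numpy(), in_mask, feature_id_rank(m.index))
        boosted = m.to_numpy().copy()
        boosted[in_mask, 0] = boosted.max() + np.arange(1, in_mask.sum() + 1)
        up = ssgsea_scores(boosted, in_mask, feature_id_rank(m.index))
        assert up[0] > base[0]

    def test_signature_covering_matrix_rejected(self):
        rng = np.random.default_rng(21)
        m, _, _ = make_inputs(rng, 5, 3, 2)
        with pytest.raises(ValueError, match="every matrix feature"):
            ssgsea_scores(m.to_numpy(), np.ones(5, bool), feature_id_rank(m.index))


class TestGsva:
    def test_matches_staged_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            m, sig, in_mask = make_inputs(rng, int(rng.integers(5, 11)), int(rng.integers(3, 7)), 2)
            got = gsva_scores(m.to_numpy(), in_mask, feature_id_rank(m.index))
            exp = gsva_oracle(m.to_numpy(), list(m.index), set(sig.features))
            assert np.allclose(got, exp, atol=1e-10)

    def test_duplicated_sample_columns_score_equally(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=(6, 3))
        dup = np.column_stack([values, values[:, 1]])
        in_mask = np.array([True, True, False, False, False, False])
        idr = np.arange(6)
        s = gsva_scores(dup, in_mask, idr)
        assert s[1] == pytest.approx(s[3], abs=1e-12)

    def test_permuting_samples_permutes_scores(self):
        rng = np.random.default_rng(24)
        values = rng.normal(size=(7, 5))
        in_mask = np.array([1, 0, 1, 0, 0, 1, 0], bool)
        idr = np.arange(7)
        perm = rng.permutation(5)
        assert np.allclose(
            gsva_scores(values[:, perm], in_mask, idr),
            gsva_scores(values, in_mask, idr)[perm],
            atol=1e-12,
        )

    def test_constant_feature_warns(self):
        rng = np.random.default_rng(25)
        values = rng.normal(size=(5, 4))
        values[3] = 2.0
        in_mask = np.array([1, 1, 0, 0, 0], bool)
        with pytest.warns(UserWarning, match="constant feature"):
            gsva_scores(values, in_mask, np.arange(5))

    def test_needs_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            gsva_scores(np.ones((4, 2)), np.array([1, 0, 0, 0], bool), np.arange(4))


class TestFeatureOrderInvariance:
    @pytest.mark.parametrize("scorer_id", ["pca1", "plage"])
    def test_signature_order_irrelevant(self, scorer_id, small_matrix):
        rng = np.random.default_rng(26)
        feats = ("g1", "g3", "g5")
        s1, _ = score_signature(small_matrix, Signature("a", feats), scorer_id)
        s2, _ = score_signature(
            small_matrix, Signature("b", tuple(rng.permutation(feats))), scorer_id
        )
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)
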