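"""Microbiome resemblance statistics against hand oracles, scikit-bio and
exhaustive enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbtsig import (
    DataError,
    berger_parker,
    bray_curtis,
    paired_alpha_test,
    paired_genus_tests,
    pcoa,
    permanova,
    relative_abundance,
)

from oracles import (
    bray_curtis_oracle,
    permanova_exhaustive_oracle,
    wilcoxon_signflip_oracle,
)


def _table(mat, prefix="S"):
    mat = np.asarray(mat)
    return pd.DataFrame(
        mat,
        index=[f"g{i:02d}" for i in range(mat.shape[0])],
        columns=[f"{prefix}{j}" for j in range(mat.shape[1])],
    )


def test_relative_abundance_examples():
    rel = relative_abundance(_table([[2], [1], [1]]))
    np.testing.assert_allclose(rel.to_numpy().ravel(), [0.5, 0.25, 0.25])
    assert relative_abundance(_table([[7]])).iloc[0, 0] == 1.0
    with pytest.raises(DataError, match="S1"):
        relative_abundance(_table([[1, 0], [2, 0]]))


def test_relative_abundance_columns_sum_to_one(rng):
    rel = relative_abundance(_table(rng.integers(0, 50, size=(12, 6)) + 1))
    np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)


def test_bray_curtis_bounds_and_hand_value():
    identical = relative_abundance(_table([[3, 3], [2, 2], [5, 5]]))
    np.testing.assert_allclose(bray_curtis(identical).to_numpy(),
                               [[0, 0], [0, 0]], atol=1e-12)
    disjoint = relative_abundance(_table([[5, 0], [0, 7]]))
    assert bray_curtis(disjoint).iloc[0, 1] == pytest.approx(1.0)
    # raw counts (2,1,0) vs (0,1,3): BC = 1 - 2*1/7 = 5/7
    counts = _table([[2, 0], [1, 1], [0, 3]]).astype(float)
    assert bray_curtis(counts).iloc[0, 1] == pytest.approx(5 / 7)
    # the same pair as proportions: min-sum 1/4, so BC = 3/4
    assert bray_curtis(relative_abundance(counts)).iloc[0, 1] == pytest.approx(0.75)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_bray_curtis_is_a_bounded_semimetric(seed):
    rng = np.random.default_rng(seed)
    rel = relative_abundance(_table(rng.integers(0, 30, size=(8, 5)) + 1))
    d = bray_curtis(rel).to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
    for i in range(5):
        for j in range(i + 1, 5):
            assert d[i, j] == pytest.approx(
                bray_curtis_oracle(rel.iloc[:, i], rel.iloc[:, j]), abs=1e-12
            )


def test_pcoa_two_samples_forced_geometry():
    d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]], index=["a", "b"],
                     columns=["a", "b"])
    coords, eig, prop = pcoa(d, n_axes=1)
    np.testing.assert_allclose(np.abs(coords["PC1"]), 0.4, atol=1e-10)
    assert prop[0] == pytest.approx(1.0)


def test_pcoa_recovers_euclidean_configuration(rng):
    from scipy.spatial import procrustes
    from scipy.spatial.distance import pdist, squareform

    pts = rng.normal(size=(7, 2))
    d = pd.DataFrame(squareform(pdist(pts)))
    coords, eig, prop = pcoa(d, n_axes=2)
    _, _, disparity = procrustes(pts, coords.to_numpy())
    assert disparity < 1e-8


def test_pcoa_equidistant_points_have_equal_eigenvalues():
    n = 4
    d = pd.DataFrame(np.ones((n, n)) - np.eye(n))
    coords, eig, prop = pcoa(d, n_axes=3)
    np.testing.assert_allclose(eig, eig[0], rtol=1e-10)


def test_pcoa_truncates_to_positive_eigenvalues():
    d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]])
    coords, eig, prop = pcoa(d, n_axes=5)
    assert coords.shape[1] == 1


def test_permanova_matches_exhaustive_enumeration(rng):
    rel = relative_abundance(_table(rng.integers(1, 40, size=(10, 6))))
    d = bray_curtis(rel)
    labels = ["A", "A", "A", "B", "B", "B"]
    res = permanova(d, labels, n_perm=999, seed=0)
    p_oracle, f_oracle = permanova_exhaustive_oracle(d.to_numpy().tolist(),
                                                     labels)
    assert res.exhaustive
    assert res.n_permutations == 20
    assert res.pseudo_f == pytest.approx(f_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_permanova_exhaustive_p_invariant_to_relabeling(rng):
    rel = relative_abundance(_table(rng.integers(1, 40, size=(10, 6))))
    d = bray_curtis(rel)
    a = permanova(d, ["A", "A", "A", "B", "B", "B"], n_perm=999, seed=0)
    # swap which group is called what and shuffle within groups
    b = permanova(d, ["B", "B", "B", "A", "A", "A"], n_perm=999, seed=0)
    assert a.p_value == pytest.approx(b.p_value)
    assert a.pseudo_f == pytest.approx(b.pseudo_f)


def test_permanova_agrees_with_skbio(rng):
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    rel = relative_abundance(_table(rng.integers(1, 60, size=(15, 14))))
    d = bray_curtis(rel)
    labels = ["A"] * 7 + ["B"] * 7
    ours = permanova(d, labels, n_perm=999, seed=1)
    theirs = skbio_permanova(
        DistanceMatrix(d.to_numpy(), ids=list(d.columns)),
        grouping=labels, permutations=999,
    )
    assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)
    # both are seeded Monte-Carlo estimates of the same p
    assert abs(ours.p_value - theirs["p-value"]) < 0.1


def test_permanova_separated_groups_hit_the_addone_floor(rng):
    """Strongly separated groups: no permutation reaches the observed F, so
    p = 1/(n_perm+1) with the add-one rule."""
    block = np.zeros((10, 14), dtype=int)
    block[:5, :7] = rng.integers(50, 100, size=(5, 7))
    block[5:, 7:] = rng.integers(50, 100, size=(5, 7))
    block += 1
    d = bray_curtis(relative_abundance(_table(block)))
    res = permanova(d, ["A"] * 7 + ["B"] * 7, n_perm=999, seed=0)
    assert not res.exhaustive
    assert res.p_value == pytest.approx(1 / 1000)


def test_permanova_rejects_degenerate_inputs():
    d = pd.DataFrame(np.zeros((4, 4)))
    with pytest.raises(DataError, match="degenerate"):
        permanova(d, ["A", "A", "B", "B"], seed=0)
    d2 = pd.DataFrame(np.ones((3, 3)) - np.eye(3))
    with pytest.raises(DataError):
        permanova(d2, ["A", "A", "B"], seed=0)


def test_berger_parker_examples_and_scale_invariance(rng):
    t = _table(np.array([[10, 5, 8], [0, 5, 1], [0, 5, 1]]))
    bp = berger_parker(t)
    np.testing.assert_allclose(bp["berger_parker"], [1.0, 1 / 3, 0.8])
    np.testing.assert_allclose(bp["berger_parker_reciprocal"], [1.0, 3.0, 1.25])
    scaled = berger_parker(t * 17)
    np.testing.assert_allclose(bp["berger_parker"], scaled["berger_parker"])


def _pairing(n, prefix="P"):
    return pd.DataFrame({
        "sample_id": [f"{prefix}{i}_T" for i in range(n)]
                     + [f"{prefix}{i}_N" for i in range(n)],
        "patient_id": [f"{prefix}{i}" for i in range(n)] * 2,
        "tissue": ["tumor"] * n + ["NBT"] * n,
    })


def test_identical_paired_profiles_are_all_null():
    n = 6
    mat = np.tile(np.arange(1, 9)[:, None], (1, n))
    rel = relative_abundance(
        pd.DataFrame(
            np.hstack([mat, mat]),
            index=[f"g{i}" for i in range(8)],
            columns=[f"P{i}_T" for i in range(n)] + [f"P{i}_N" for i in range(n)],
        )
    )
    res = paired_genus_tests(rel, _pairing(n))
    assert (res["p_value"] == 1.0).all()
    assert res["all_zero"].all()


def test_wilcoxon_matches_signflip_enumeration(rng):
    """Random paired data, n = 6 pairs: exact p equals the enumeration over
    all 2^6 sign assignments."""
    n = 6
    for _ in range(5):
        t = rng.random((4, n)) + 0.1
        nb = rng.random((4, n)) + 0.1
        rel = pd.DataFrame(
            np.hstack([t / t.sum(0), nb / nb.sum(0)]),
            index=[f"g{i}" for i in range(4)],
            columns=[f"P{i}_T" for i in range(n)] + [f"P{i}_N" for i in range(n)],
        )
        res = paired_genus_tests(rel, _pairing(n))
        for g in rel.index:
            diffs = (t / t.sum(0))[list(rel.index).index(g)] - \
                    (nb / nb.sum(0))[list(rel.index).index(g)]
            _, p_exact = wilcoxon_signflip_oracle(diffs)
            assert res.loc[g, "p_value"] == pytest.approx(p_exact, abs=1e-10)


def test_systematic_shift_reaches_the_exact_floor():
    """One genus higher in every tumor: the smallest exact two-sided p for
    n pairs is 2/2^n."""
    n = 8
    base = np.tile(np.array([10.0, 20, 30, 40])[:, None], (1, n))
    t = base.copy()
    t[0] += np.arange(1, n + 1)          # strictly higher in all tumors
    rel_cols = np.hstack([t / t.sum(0), base / base.sum(0)])
    rel = pd.DataFrame(
        rel_cols,
        index=[f"g{i}" for i in range(4)],
        columns=[f"P{i}_T" for i in range(n)] + [f"P{i}_N" for i in range(n)],
    )
    res = paired_genus_tests(rel, _pairing(n))
    assert res.loc["g0", "p_value"] == pytest.approx(2 / 2**n)


def test_paired_alpha_test_per_group(rng):
    n = 12
    t = rng.integers(10, 100, size=(6, n))
    nb = t + 0  # identical -> p = 1
    table = pd.DataFrame(
        np.hstack([t, nb]),
        index=[f"g{i}" for i in range(6)],
        columns=[f"P{i}_T" for i in range(n)] + [f"P{i}_N" for i in range(n)],
    )
    alpha = berger_parker(table)["berger_parker"]
    res = paired_alpha_test(alpha, _pairing(n))
    assert res.loc["all", "p_value"] == 1.0

    groups = pd.Series(
        ["TSM"] * (n // 2) + ["HM"] * (n // 2),
        index=[f"P{i}" for i in range(n)],
    )
    res2 = paired_alpha_test(alpha, _pairing(n), groups)
    assert set(res2.index) == {"TSM", "HM"}


def test_incomplete_pairing_is_rejected(rng):
    pairing = _pairing(4).drop(index=[0])  # drop one tumor sample
    rel = relative_abundance(_table(rng.integers(1, 20, size=(5, 8))))
    rel.columns = [f"P{i}_T" for i in range(4)] + [f"P{i}_N" for i in range(4)]
    with pytest.raises(DataError, match="incomplete"):
        paired_genus_tests(rel, pairing)
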