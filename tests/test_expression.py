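"""Normalization arithmetic, TMM factors against an external reference
implementation, clustering against a brute-force linkage oracle, and NB
differential expression behavior."""

import numpy as np
import pandas as pd
import pytest

from occc_molpro.expression import (
    ExpressionError,
    ExpressionMatrix,
    cluster_samples,
    nb_two_group_test,
    reference_normalize,
    rpkm,
    tmm_factors,
    tmm_log_cpm_z,
    zscore_rows,
)


def small_matrix(counts, lengths=None, samples=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = samples or [f"s{i}" for i in range(counts.shape[1])]
    lengths = pd.Series(lengths or [1000] * counts.shape[0], index=counts.index)
    return ExpressionMatrix(counts=counts, gene_lengths=lengths)


def test_rpkm_closed_form():
    """count 100, length 1 kb, 1e6 mapped reads -> RPKM 100."""
    m = small_matrix([[100], [999_900]], lengths=[1000, 2000])
    m.library_sizes = pd.Series([1e6], index=m.samples)
    out = rpkm(m)
    assert out.iloc[0, 0] == pytest.approx(100.0)


def test_rpkm_scale_invariance_and_zero():
    m = small_matrix([[100, 200], [300, 600], [0, 0]])
    out = rpkm(m)
    doubled = small_matrix([[200, 400], [600, 1200], [0, 0]])
    out2 = rpkm(doubled)
    assert np.allclose(out.values, out2.values)
    assert (out.iloc[2] == 0).all()


def test_rpkm_zero_total_names_sample():
    m = small_matrix([[0], [0]])
    with pytest.raises(ExpressionError, match="s0"):
        rpkm(m)


def test_reference_normalize_geometric_mean():
    """References (1, 10, 100) give divisor 10; equal references divide by
    their common value."""
    df = pd.DataFrame(
        {"s0": [1.0, 10.0, 100.0, 50.0], "s1": [10.0, 10.0, 10.0, 30.0]},
        index=["VCP", "SF3B1", "ATP5F1B", "other"],
    )
    out = reference_normalize(df)
    assert out.loc["other", "s0"] == pytest.approx(5.0)
    assert out.loc["other", "s1"] == pytest.approx(3.0)


def test_reference_normalize_ratio_invariance():
    """Scaling one sample's whole column leaves its normalized profile unchanged."""
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        rng.uniform(1, 100, size=(10, 3)),
        index=["VCP", "SF3B1", "ATP5F1B"] + [f"g{i}" for i in range(7)],
        columns=["a", "b", "c"],
    )
    out1 = reference_normalize(df)
    df2 = df.copy()
    df2["b"] *= 7.3
    out2 = reference_normalize(df2)
    assert np.allclose(out1["b"], out2["b"])


def test_reference_normalize_zero_reference_excludes_sample():
    df = pd.DataFrame(
        {"ok": [1.0, 2.0, 4.0], "bad": [0.0, 2.0, 4.0]},
        index=["VCP", "SF3B1", "ATP5F1B"],
    )
    out = reference_normalize(df)
    assert list(out.columns) == ["ok"]


# TMM factors for the frozen fixture below were computed once with
# edgeR::calcNormFactors (method="TMM") and serve as the independent oracle.
_EDGER_FACTORS = {"A": 1.152247, "B": 1.158573, "C": 1.141839, "D": 1.110010, "E": 0.591017}


def _tmm_fixture():
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.negative_binomial(20, 0.02, size=(60, 5)),
        index=[f"g{i}" for i in range(60)], columns=list("ABCDE"),
    )
    counts["C"] = (counts["C"] * 3).astype(int)      # pure library-size scaling
    counts.iloc[:10, 4] = counts.iloc[:10, 4] * 8    # composition bias in E
    return counts


def test_tmm_factors_match_external_reference():
    got = tmm_factors(_tmm_fixture())
    for s, expected in _EDGER_FACTORS.items():
        assert got[s] == pytest.approx(expected, abs=1e-5)


def test_tmm_identical_samples_and_pure_scaling():
    """Identical samples get factor 1; a pure 2x library-size difference is
    absorbed by library size, leaving both factors at 1."""
    rng = np.random.default_rng(11)
    base = rng.negative_binomial(10, 0.05, size=200)
    counts = pd.DataFrame({"a": base, "b": base})
    f = tmm_factors(counts)
    assert np.allclose(f, 1.0)
    counts2 = pd.DataFrame({"a": base, "b": base * 2})
    f2 = tmm_factors(counts2)
    assert np.allclose(f2, 1.0, atol=1e-9)


def test_zscore_rows_mean0_sd1_and_idempotent():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(5, 2, size=(20, 30)))
    df.iloc[5] = 4.0  # constant row
    z = zscore_rows(df)
    nonconst = z.drop(index=5)
    assert np.allclose(nonconst.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(nonconst.std(axis=1, ddof=0), 1, atol=1e-12)
    assert (z.loc[5] == 0).all()
    assert np.allclose(zscore_rows(nonconst).values, nonconst.values, atol=1e-12)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def brute_force_complete_linkage(X, k):
    """Naive O(n^3) agglomerative complete-linkage clustering, Manhattan
    distance; returns the partition at k clusters as a set of frozensets."""
    n = X.shape[0]
    clusters = [{i} for i in range(n)]
    d = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)

    def linkage_dist(a, b):
        return max(d[i, j] for i in a for j in b)

    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = linkage_dist(clusters[i], clusters[j])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


@pytest.mark.parametrize("k", [2, 3])
def test_cluster_agrees_with_brute_force(k):
    rng = np.random.default_rng(17)
    X = rng.normal(size=(12, 6))
    X[:4] += 4.0  # separated block so partitions are unambiguous
    df = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(12)])
    res = cluster_samples(df, k=k)
    got = {
        frozenset(int(s[1:]) for s in res.labels[res.labels == c].index)
        for c in res.labels.unique()
    }
    assert got == brute_force_complete_linkage(X, k)


def test_cluster_order_invariance(default_bundle):
    """Permuting samples and genes leaves the partition unchanged."""
    z = tmm_log_cpm_z(default_bundle.expression)
    rng = np.random.default_rng(1)
    shuffled = z.iloc[rng.permutation(z.shape[0]), rng.permutation(z.shape[1])]
    a = cluster_samples(z, k=2)
    b = cluster_samples(shuffled, k=2)
    assert set(a.minority_samples) == set(b.minority_samples)


def test_duplicate_profiles_cluster_together():
    rng = np.random.default_rng(23)
    base = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
    base["e"] = base["a"]
    base[list("abcde")] += 0.0
    base["f"] = base["b"] + 10  # far outlier pair partner
    res = cluster_samples(base, k=2)
    assert res.labels["a"] == res.labels["e"]


def test_cluster_too_few_samples_raises():
    df = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(ExpressionError):
        cluster_samples(df, k=2)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def test_nb_test_recovers_planted_markers(default_bundle):
    """The planted minority-cluster markers come out with the right fold-change
    direction and small adjusted p at n = 105."""
    labels = default_bundle.truth["expression_clusters"]["cluster"]
    res = nb_two_group_test(default_bundle.expression, labels)
    up = res.table.loc[list(default_bundle.spec.expression.up_genes)]
    down = res.table.loc[list(default_bundle.spec.expression.down_genes)]
    assert (up["fold_change"] >= 2.0).all()
    assert (down["fold_change"] <= 0.5).all()
    assert (up["padj"] < 1e-5).all()
    assert (down["padj"] < 1e-5).all()
    assert (res.table["padj"] >= res.table["pvalue"].fillna(0)).all()


def test_nb_test_constant_gene_is_null():
    """A gene with identical counts everywhere: fold change 1, p near 1."""
    rng = np.random.default_rng(9)
    counts = pd.DataFrame(
        rng.negative_binomial(50, 0.1, size=(30, 40)),
        columns=[f"s{i}" for i in range(40)],
    )
    counts.index = [f"g{i}" for i in range(30)]
    counts.loc["g0"] = 500
    counts.loc["g1"] = 0  # all-zero gene excluded
    labels = pd.Series([1] * 20 + [2] * 20, index=counts.columns)
    m = ExpressionMatrix(counts=counts, gene_lengths=pd.Series(1000, index=counts.index))
    res = nb_two_group_test(m, labels)
    assert "g1" in res.excluded_genes
    assert res.table.loc["g0", "fold_change"] == pytest.approx(1.0, abs=0.02)
    assert res.table.loc["g0", "pvalue"] > 0.3


def test_nb_test_type_one_error_near_nominal():
    """Label permutation on a homogeneous cohort: the raw p-value distribution
    is approximately uniform (fraction below 0.05 close to nominal)."""
    rng = np.random.default_rng(31)
    counts = pd.DataFrame(
        rng.negative_binomial(8, 8 / (8 + 200), size=(150, 60)),
        columns=[f"s{i}" for i in range(60)],
    )
    counts.index = [f"g{i}" for i in range(150)]
    labels = pd.Series(rng.permutation([1] * 30 + [2] * 30), index=counts.columns)
    m = ExpressionMatrix(counts=counts, gene_lengths=pd.Series(1000, index=counts.index))
    res = nb_two_group_test(m, labels)
    frac = (res.table["pvalue"] < 0.05).mean()
    assert frac < 0.12  # nominal 0.05 with simulation slack


def test_planted_fold_change_realized(default_bundle):
    """Generator contract: a planted 2-fold shift realizes a group-mean ratio
    within 10% of 2 at n = 105 (library-size adjusted)."""
    from occc_molpro.synthetic import CohortSpec, ExpressionSpec, generate_expression

    spec = CohortSpec(expression=ExpressionSpec(fold_up=2.0, fold_down=0.5))
    matrix, labels = generate_expression(spec, np.random.default_rng(12))
    # undo library-size factors by CPM so the planted ratio is visible
    cpm = matrix.counts.div(matrix.counts.sum(axis=0), axis=1) * 1e6
    g = "AKT3"
    ratio = cpm.loc[g, labels == 2].mean() / cpm.loc[g, labels == 1].mean()
    assert ratio == pytest.approx(2.0, rel=0.10)
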