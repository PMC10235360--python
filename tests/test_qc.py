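"""CPM normalization, correlation, replicate fits, clustering and PCA."""

import numpy as np
import pandas as pd
import pytest

from phdsq import datasets
from phdsq.qc import (cluster_samples, cpm, pca, pearson_matrix,
                      redundant_probe_concordance, redundant_probe_pooled_r2,
                      replicate_fit)


# ---------------------------------------------------------------------------
# CPM


def test_cpm_direct_scaling():
    df = pd.DataFrame({"s1": [10, 90]}, index=["g1", "g2"])
    out = cpm(df)
    assert out["s1"].tolist() == [1e5, 9e5]


def test_cpm_single_gene_column():
    df = pd.DataFrame({"s1": [7]}, index=["g1"])
    assert cpm(df).iloc[0, 0] == 1e6


def test_cpm_toy_matrix_hand_oracle():
    df = pd.DataFrame({"s1": [1, 2, 7], "s2": [0, 5, 5]}, index=list("abc"))
    out = cpm(df)
    # hand-scaled: s1 total 10, s2 total 10
    expected = pd.DataFrame({"s1": [1e5, 2e5, 7e5], "s2": [0.0, 5e5, 5e5]},
                            index=list("abc"))
    pd.testing.assert_frame_equal(out, expected)


def test_cpm_zero_column_warns_and_stays_zero():
    df = pd.DataFrame({"s1": [1, 1], "s2": [0, 0]}, index=["a", "b"])
    with pytest.warns(UserWarning, match="all-zero"):
        out = cpm(df)
    assert (out["s2"] == 0).all()
    assert out["s1"].sum() == 1e6


def test_cpm_columns_sum_to_one_million(small_screen):
    sums = small_screen.gene_cpm.sum(axis=0)
    assert np.allclose(sums, 1e6)


# ---------------------------------------------------------------------------
# Pearson


def test_pearson_self_and_scale_invariance():
    df = pd.DataFrame({"a": [1.0, 5, 9, 2], "b": [2.0, 10, 18, 4]}, index=list("wxyz"))
    m = pearson_matrix(df, log_transform=False)
    assert m.loc["a", "a"] == 1.0
    assert m.loc["a", "b"] == pytest.approx(1.0)  # b = 2a
    assert m.equals(m.T)


def test_pearson_textbook_formula_oracle():
    x = np.array([3.0, 1.0, 4.0, 1.5])
    y = np.array([2.0, 0.5, 5.0, 1.0])
    df = pd.DataFrame({"a": x, "b": y})
    r = pearson_matrix(df, log_transform=False).loc["a", "b"]
    # textbook definition, written out
    oracle = (((x - x.mean()) * (y - y.mean())).sum()
              / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    assert r == pytest.approx(oracle, abs=1e-12)


def test_pearson_rescaling_invariance(small_screen):
    lin = small_screen.gene_cpm
    scaled = lin * pd.Series(np.linspace(0.5, 2.0, lin.shape[1]), index=lin.columns)
    a = pearson_matrix(lin, log_transform=False)
    b = pearson_matrix(scaled, log_transform=False)
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_pearson_zero_variance_reported_missing():
    df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
    with pytest.warns(UserWarning, match="zero-variance"):
        m = pearson_matrix(df, log_transform=False)
    assert np.isnan(m.loc["a", "b"])
    assert m.loc["b", "b"] == 1.0


def test_pearson_requires_two_samples():
    with pytest.raises(ValueError):
        pearson_matrix(pd.DataFrame({"a": [1.0, 2]}))


# ---------------------------------------------------------------------------
# replicate fit


def test_replicate_fit_identity_and_doubling():
    df = pd.DataFrame({"a": [1.0, 5, 20, 80], "b": [1.0, 5, 20, 80],
                       "c": [2.0, 10, 40, 160]}, index=list("wxyz"))
    fit = replicate_fit(df, "a", "b", log_transform=False)
    assert (fit.slope, fit.intercept, fit.r_squared) == pytest.approx((1, 0, 1))
    fit2 = replicate_fit(df, "a", "c", log_transform=False)
    assert fit2.slope == pytest.approx(2.0)
    assert fit2.r_squared == pytest.approx(1.0)


def test_replicate_fit_needs_three_genes():
    df = pd.DataFrame({"a": [1.0, 2], "b": [1.0, 2]})
    with pytest.raises(ValueError):
        replicate_fit(df, "a", "b")


@pytest.fixture(scope="module")
def deep_screen(panel, tmp_path_factory):
    """A few wells sequenced at the platform's working depth (1e4 reads/well):
    1 KF + 2 AD replicates and four compounds spanning the effect axis."""
    import phdsq
    from phdsq.barcodes import make_barcode_map
    from phdsq.layout import default_layout
    from phdsq.simulate import (SimConfig, make_screen_profiles, sample_sheet,
                                simulate_fastq)
    from test_simulate import _controls

    tmp = tmp_path_factory.mktemp("deep")
    rng = np.random.default_rng(2024)
    kf, ad = _controls(panel, rng)
    effects = {f"C{i}": e for i, e in enumerate([0.2, 0.4, 0.6, 0.8])}
    profiles = make_screen_profiles(panel, make_barcode_map(1), kf, ad, 1, 2,
                                    effects, noise_cv=0.1, rng=rng)
    bm = make_barcode_map(1, samples=sample_sheet(profiles))
    cfg = SimConfig(rng_seed=2024, reads_per_well=10_000)
    r1, r2 = tmp / "r1.fastq", tmp / "r2.fastq"
    simulate_fastq(profiles, panel, default_layout(), bm, cfg, r1, r2)
    cm = phdsq.count_reads(r1, r2, panel, bm, default_layout())
    return cpm(cm), cpm(phdsq.aggregate_to_genes(cm, panel))


def test_replicate_consistency_on_simulated_controls(deep_screen):
    """Biological replicates of the same control profile land on the identity
    line: R^2 >= 0.9 and slope near 1."""
    _, gene_cpm = deep_screen
    fit = replicate_fit(gene_cpm, "AD_1", "AD_2")
    assert fit.r_squared >= 0.9
    assert 0.9 <= fit.slope <= 1.1


# ---------------------------------------------------------------------------
# redundant probes


def test_identical_probes_fully_concordant(panel):
    two_probe = [g for g, ps in panel.gene_to_probes.items() if len(ps) == 2]
    probes = [pid for g in two_probe for pid in panel.gene_to_probes[g]]
    rng = np.random.default_rng(3)
    base = pd.DataFrame(rng.uniform(10, 1000, size=(len(two_probe), 5)),
                        index=two_probe, columns=[f"s{i}" for i in range(5)])
    cpm_df = pd.DataFrame(0.0, index=panel.probe_ids, columns=base.columns)
    for g in two_probe:
        p1, p2 = panel.gene_to_probes[g]
        cpm_df.loc[p1] = base.loc[g]
        cpm_df.loc[p2] = base.loc[g] * 0.5  # proportional probes still concordant
    with pytest.warns(UserWarning, match="skipped"):
        conc = redundant_probe_concordance(cpm_df, panel, log_transform=False)
    assert set(conc.index) == set(two_probe)
    assert np.allclose(conc.to_numpy(), 1.0)


def test_redundant_concordance_on_simulated_screen(deep_screen, panel):
    """Probes of one gene draw from the same transcript pool, so at working
    depth signature genes agree across samples and the pooled panel-wide
    probe-1 vs probe-2 fit is tight."""
    probe_cpm, _ = deep_screen
    with pytest.warns(UserWarning, match="skipped"):
        conc = redundant_probe_concordance(probe_cpm, panel)
    signature = [g for g in conc.index if g not in datasets.HOUSEKEEPING_GENES]
    assert (conc[signature] >= 0.9).all()
    pooled = redundant_probe_pooled_r2(probe_cpm, panel)
    assert pooled >= 0.9


# ---------------------------------------------------------------------------
# clustering


def test_identical_pair_merges_first():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4],
                       "c": [4.0, 3, 2, 1]}, index=list("wxyz"))
    res = cluster_samples(df, log_transform=False)
    # the first linkage row joins the two identical samples (leaves 0 and 1)
    assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}
    assert res.labels["a"] == res.labels["b"] != res.labels["c"]


def test_single_sample_trivial_tree():
    df = pd.DataFrame({"a": [1.0, 2]})
    res = cluster_samples(df)
    assert res.leaf_order == ["a"]
    assert res.labels.tolist() == [1]


def test_controls_separate_into_top_clusters(small_screen):
    """KF and AD control replicates must occupy opposite top-level clusters."""
    controls = [s for s, r in small_screen.roles.items() if r != "compound"]
    res = cluster_samples(small_screen.gene_cpm[controls])
    labels = res.labels
    kf = {labels[s] for s in controls if s.startswith("KF")}
    ad = {labels[s] for s in controls if s.startswith("AD")}
    assert len(kf) == 1 and len(ad) == 1 and kf != ad


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_samples_zero_variance():
    df = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]})
    res = pca(df, log_transform=False, n_components=2)
    assert np.allclose(res.scores.to_numpy(), 0.0)


def test_pca_two_samples_pc1_captures_everything():
    df = pd.DataFrame({"a": [1.0, 5, 2], "b": [3.0, 1, 9]})
    res = pca(df, log_transform=False, n_components=1)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_components_capped():
    df = pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]})
    with pytest.raises(ValueError):
        pca(df, n_components=5)


def test_pca_sign_convention_deterministic(small_screen):
    a = pca(small_screen.gene_cpm)
    b = pca(small_screen.gene_cpm)
    assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())
    for c in a.loadings.columns:
        top = a.loadings[c].abs().idxmax()
        assert a.loadings.loc[top, c] > 0


def test_pc1_loadings_expose_signature_genes(small_screen):
    """The screen's planted KF->AD axis must dominate PC1: the top-loading
    genes are signature (fibrosis/adipocyte) genes, not housekeeping."""
    res = pca(small_screen.gene_cpm)
    top5 = res.loadings["PC1"].abs().sort_values(ascending=False).head(5).index
    assert not set(top5) & set(datasets.HOUSEKEEPING_GENES)
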