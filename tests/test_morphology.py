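import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spinedef.morphology import (
    TraitValidationError,
    cluster_syndromes,
    correlation_ratio,
    encode_and_scale,
    ordination,
    read_trait_table,
)
from spinedef.synth import generate_trait_table


def two_species(d1, d2):
    base = dict(
        main_stem_habit="self-supporting", spine_length=2.0,
        spine_shape="straight", branching="unbranched",
        orientation="homogeneous", arrangement="random",
        emergence_timing="late", pruning="maintained", renewal="renewal",
        vertical_distribution="extended", spine_type="cork",
    )
    return pd.DataFrame([
        dict(species_id="a", spine_density=d1, **base),
        dict(species_id="b", spine_density=d2, **base),
    ])


def test_log_minmax_scaling():
    d = 0.1
    m = encode_and_scale(two_species(d, d * np.e))
    col = m.data["spine_density"]
    assert col.loc["a"] == pytest.approx(0.0)
    assert col.loc["b"] == pytest.approx(1.0)
    # constant trait -> all-zero column (degenerate range rule)
    assert (m.data["spine_length"] == 0.0).all()


def test_one_hot_shape_and_bounds():
    t = generate_trait_table(4, seed=2, noise=0.1)
    m = encode_and_scale(t)
    vals = m.values
    assert vals.min() >= 0.0 and vals.max() <= 1.0
    assert not np.isnan(vals).any()
    curved = t.set_index("species_id").spine_shape == "curved"
    got = m.data["spine_shape[curved]"].astype(bool)
    assert (got == curved.reindex(got.index)).all()
    # the three indicator columns partition the species
    onehot = m.data[[f"spine_shape[{s}]" for s in
                     ("curved", "straight", "straightened")]]
    np.testing.assert_allclose(onehot.sum(axis=1), 1.0)
    # spine_type is metadata: it never appears in the encoded matrix
    assert not any("spine_type" in c for c in m.data.columns)


def test_encode_validation():
    bad = two_species(0.0, 1.0)  # non-positive density
    with pytest.raises(TraitValidationError):
        encode_and_scale(bad)
    bad2 = two_species(0.1, 0.2)
    bad2.loc[0, "spine_shape"] = "wavy"
    with pytest.raises(TraitValidationError):
        encode_and_scale(bad2)


def test_clustering_recovers_clean_syndromes():
    t = generate_trait_table(5, seed=1, noise=0.0)
    m = encode_and_scale(t)
    assign, Z = cluster_syndromes(m, 4)
    ari = adjusted_rand_score(t["syndrome"], assign.to_numpy())
    assert ari == pytest.approx(1.0)
    assert Z.shape == (len(t) - 1, 4)


def test_clustering_invariances():
    t = generate_trait_table(5, seed=3, noise=0.0)
    m = encode_and_scale(t)
    assign, _ = cluster_syndromes(m, 4)
    # permuting species order gives the identical partition
    perm = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
    assign_p, _ = cluster_syndromes(encode_and_scale(perm), 4)
    ari = adjusted_rand_score(assign.reindex(assign_p.index), assign_p)
    assert ari == pytest.approx(1.0)
    # duplicated species land in the same cluster
    dup = pd.concat([t, t.iloc[[0]]], ignore_index=True)
    assign_d, _ = cluster_syndromes(encode_and_scale(dup), 4)
    assert assign_d.iloc[0] == assign_d.iloc[-1]


def test_too_many_clusters_rejected():
    t = generate_trait_table(1, seed=4, noise=0.0)
    with pytest.raises(ValueError):
        cluster_syndromes(encode_and_scale(t), 5)


def test_correlation_ratio_limits_and_oracle():
    t = generate_trait_table(5, seed=5, noise=0.0)
    m = encode_and_scale(t)
    assign, _ = cluster_syndromes(m, 4)
    eta = correlation_ratio(m, assign)
    assert ((eta >= 0) & (eta <= 1 + 1e-12)).all()
    # trait constant within clusters but varying between -> eta^2 = 1
    assert eta["main_stem_habit"] == pytest.approx(1.0)
    # trait identical everywhere -> 0 by the zero-variance rule
    t2 = t.copy()
    t2["branching"] = "branched"
    m2 = encode_and_scale(t2)
    assert correlation_ratio(m2, assign)["branching"] == 0.0

    # random column vs direct ANOVA sums of squares
    rng = np.random.default_rng(6)
    col = rng.uniform(size=20)
    groups = rng.integers(0, 4, size=20)
    from spinedef.morphology import TraitMatrix

    tm = TraitMatrix(
        data=pd.DataFrame({"spine_density": col},
                          index=[f"s{i}" for i in range(20)]),
        encoding={"spine_density": ("spine_density",)},
    )
    assign_r = pd.Series(groups, index=tm.data.index)
    got = correlation_ratio(tm, assign_r)["spine_density"]
    grand = col.mean()
    ss_tot = ((col - grand) ** 2).sum()
    ss_between = sum(
        (groups == g).sum() * (col[groups == g].mean() - grand) ** 2
        for g in np.unique(groups)
    )
    assert got == pytest.approx(ss_between / ss_tot, abs=1e-12)


def test_ordination_axes():
    # collinear points -> a single axis carries 100%
    from spinedef.morphology import TraitMatrix

    line = TraitMatrix(
        data=pd.DataFrame(
            {"a": [0.0, 0.25, 0.5, 1.0], "b": [0.0, 0.125, 0.25, 0.5]},
            index=list("wxyz"),
        ),
        encoding={"a": ("a",), "b": ("b",)},
    )
    coords, pct = ordination(line)
    assert pct[0] == pytest.approx(100.0)

    # isotropic 2-d cloud: both axes near 50%, matching covariance eigenvalues
    rng = np.random.default_rng(7)
    X = rng.normal(size=(2000, 2))
    tm = TraitMatrix(
        data=pd.DataFrame(X, columns=["a", "b"],
                          index=[f"s{i}" for i in range(2000)]),
        encoding={"a": ("a",), "b": ("b",)},
    )
    coords, pct = ordination(tm)
    ev = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
    np.testing.assert_allclose(pct, 100 * ev / ev.sum(), rtol=1e-8)
    assert abs(pct[0] - 50.0) < 5.0
    assert all(np.diff(pct) <= 1e-9)


def test_ordination_degenerate_inputs():
    from spinedef.morphology import TraitMatrix

    flat = TraitMatrix(
        data=pd.DataFrame({"a": [0.3, 0.3, 0.3]}, index=list("abc")),
        encoding={"a": ("a",)},
    )
    with pytest.raises(ValueError):
        ordination(flat)
    two = TraitMatrix(
        data=pd.DataFrame({"a": [0.0, 1.0]}, index=list("ab")),
        encoding={"a": ("a",)},
    )
    with pytest.raises(ValueError):
        ordination(two)


def test_trait_csv_roundtrip(tmp_path):
    t = generate_trait_table(3, seed=8)
    p = tmp_path / "traits.csv"
    t.to_csv(p, index=False)
    back = read_trait_table(p)
    assert len(back) == len(t)
    p.write_text("species_id\nonly\n")
    with pytest.raises(TraitValidationError):
        read_trait_table(p)
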