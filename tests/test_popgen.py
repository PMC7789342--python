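import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ssrkit import popgen, simdata

from conftest import random_genotype_matrix


def _matrix(column, name="L"):
    return pd.DataFrame({name: column}, index=[f"i{k}" for k in range(len(column))])


# ---------------------------------------------------------------------------
# locus statistics


def test_locus_stats_high_het_marker():
    m = _matrix(["A/B"] * 26 + ["A/A"])
    s = popgen.locus_stats(m, "L")
    assert round(s.ho, 3) == 0.963
    assert round(s.pic, 3) == 0.375
    assert s.na == 2


def test_locus_stats_low_het_marker():
    m = _matrix(["A/A"] * 25 + ["A/B"] * 2)
    s = popgen.locus_stats(m, "L")
    assert round(s.ho, 3) == 0.074
    assert round(s.pic, 3) == 0.069


def test_locus_stats_balanced_biallelic():
    m = _matrix(["A/A", "B/B", "A/B", "A/B"])
    s = popgen.locus_stats(m, "L")
    assert s.ne == pytest.approx(2.0)
    assert s.he == pytest.approx(0.5)
    assert s.shannon == pytest.approx(math.log(2))


def test_locus_stats_missing_excluded():
    # Ho like 0.087 ~ 2/23 arises from pairwise deletion
    m = _matrix(["A/B"] * 2 + ["A/A"] * 21 + [popgen.MISSING] * 4)
    s = popgen.locus_stats(m, "L")
    assert s.n == 23
    assert round(s.ho, 3) == 0.087


def test_monomorphic_locus_invariants():
    s = popgen.locus_stats(_matrix(["A/A"] * 10), "L")
    assert s.na == 1 and s.ne == pytest.approx(1.0)
    assert s.shannon == s.he == s.pic == 0.0


def test_all_missing_locus_flagged():
    m = pd.DataFrame({"L1": ["A/A", "A/B"], "L2": [popgen.MISSING] * 2},
                     index=["x", "y"])
    with pytest.raises(ValueError):
        popgen.locus_stats(m, "L2")
    table = popgen.diversity_table(m)
    assert table.attrs["skipped"] == ["L2"]
    assert list(table["locus"]) == ["L1"]


@given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=6))
@settings(max_examples=200, deadline=None)
def test_pic_at_most_he(weights):
    p = np.array(weights) / sum(weights)
    he = 1 - float(np.sum(p**2))
    assert popgen._pic_from_freqs(p) <= he + 1e-12


def test_unbiased_he_flag():
    m = _matrix(["A/A", "B/B", "A/B", "A/B"])
    plain = popgen.locus_stats(m, "L").he
    corrected = popgen.locus_stats(m, "L", unbiased=True).he
    assert corrected == pytest.approx(plain * 8 / 7)


def test_marker_table_summary():
    table = pd.DataFrame({
        "locus": [f"M{i}" for i in range(3)],
        "Na": [3, 5, 2],
        "PIC": [0.5, 0.4, 0.3],
        "Ho": [0.1, 0.2, 0.9],
    })
    out = popgen.marker_table_summary(table)
    assert out.loc["Total", "Na"] == 10
    assert out.loc["Minimum", "PIC"] == 0.3
    assert out.loc["Maximum", "Ho"] == 0.9
    assert out.loc["Mean", "PIC"] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# group diversity


def test_group_diversity_mean_row_unweighted():
    # 10 loci; groups polymorphic at 9 / 6 / 10 of them -> PP 90 / 60 / 100
    loci = [f"L{i}" for i in range(10)]
    rows, groups = {}, {}

    def add_group(name, size, n_poly):
        for k in range(size):
            acc = f"{name}{k}"
            rows[acc] = ["A/B" if (i < n_poly and k == 0) else "A/A" for i in range(10)]
            groups[acc] = name

    add_group("MGL", 3, 9)
    add_group("SI", 3, 6)
    add_group("QTP", 3, 10)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    table = popgen.group_diversity(matrix, pd.Series(groups))
    assert list(table.loc[["MGL", "SI", "QTP"], "PP"]) == [90.0, 60.0, 100.0]
    assert round(table.loc["Mean", "PP"], 2) == 83.33


def test_group_diversity_monomorphic_group():
    matrix = pd.DataFrame({"L1": ["A/A"] * 4, "L2": ["C/C"] * 4},
                          index=[f"a{i}" for i in range(4)])
    groups = pd.Series(["G1"] * 4, index=matrix.index)
    table = popgen.group_diversity(matrix, groups)
    assert table.loc["G1", "PP"] == 0.0


def test_group_diversity_matches_direct_recomputation(population_panel):
    matrix, groups, _ = population_panel
    table = popgen.group_diversity(matrix, groups)
    for g in ("MGL", "SI", "QTP"):
        sub = matrix.loc[groups[groups == g].index]
        per = popgen.diversity_table(sub)
        assert table.loc[g, "He"] == pytest.approx(per["He"].mean())
        assert table.loc[g, "Na"] == pytest.approx(per["Na"].mean())
        assert table.loc[g, "N"] == len(sub)


# ---------------------------------------------------------------------------
# dominant statistics


def test_dominant_half_frequency_band():
    bands = pd.DataFrame({"b1": [1, 1, 0, 0]})
    s = popgen.dominant_stats(bands)
    assert s.pic == pytest.approx(0.5)
    assert s.bi == pytest.approx(1.0)
    assert s.rp == pytest.approx(1.0)


def test_dominant_monomorphic_contributes_zero():
    bands = pd.DataFrame({"b1": [1, 1, 0, 0], "b2": [1, 1, 1, 1]})
    s = popgen.dominant_stats(bands)
    assert s.polymorphic_bands == 1
    assert s.pic == pytest.approx(0.25)  # (0.5 + 0) / 2
    assert s.mi == pytest.approx(0.25)


def test_dominant_random_oracle(rng):
    bands = pd.DataFrame(rng.integers(0, 2, size=(12, 10)),
                         columns=[f"b{i}" for i in range(10)])
    s = popgen.dominant_stats(bands)
    f = bands.to_numpy().mean(axis=0)
    pic = np.mean(2 * f * (1 - f))
    ib = 1 - 2 * np.abs(0.5 - f)
    poly = int(((f > 0) & (f < 1)).sum())
    assert s.pic == pytest.approx(pic)
    assert s.bi == pytest.approx(ib.mean())
    assert s.rp == pytest.approx(ib.sum())
    assert s.mi == pytest.approx(pic * poly)
    assert s.polymorphism_pct == pytest.approx(100 * poly / 10)


def test_dominant_rejects_non_binary():
    with pytest.raises(ValueError):
        popgen.dominant_stats(pd.DataFrame({"b": [0, 2]}))


# ---------------------------------------------------------------------------
# distances


def test_nei_identical_accessions_zero():
    m = pd.DataFrame({"L1": ["A/B", "A/B"], "L2": ["C/C", "C/C"]}, index=["x", "y"])
    d = popgen.nei_distance(m)
    assert d.loc["x", "y"] == pytest.approx(0.0)


def test_nei_hand_example():
    # acc1: AA, AB ; acc2: AB, BB -> I = (1/2)/sqrt(3/4 * 3/4) = 2/3
    m = pd.DataFrame({"L1": ["A/A", "A/B"], "L2": ["A/B", "B/B"]}, index=["u", "v"])
    d = popgen.nei_distance(m)
    assert d.loc["u", "v"] == pytest.approx(math.log(1.5))


def test_nei_properties(rng):
    m = random_genotype_matrix(rng, n=8, loci=5)
    d = popgen.nei_distance(m).to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert (d >= 0).all()


def test_dice_distance_for_bands():
    bands = pd.DataFrame({"b1": [1, 1], "b2": [1, 0], "b3": [0, 1]}, index=["x", "y"])
    d = popgen.nei_distance(bands)
    assert d.loc["x", "y"] == pytest.approx(1 - 2 * 1 / 4)


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_three_point():
    d = pd.DataFrame(
        [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC"),
        dtype=float,
    )
    tree = popgen.upgma(d)
    assert tree.newick() == "((A:1,B:1):1,C:2);"
    assert tree.height == 2.0  # max distance / 2


def _leaf_depths(node, acc=0.0, out=None):
    out = {} if out is None else out
    if node.is_leaf:
        out[node.name] = acc
    for c in node.children:
        _leaf_depths(c, acc + (node.height - c.height), out)
    return out


def test_upgma_ultrametric(rng):
    m = random_genotype_matrix(rng, n=10, loci=8)
    tree = popgen.upgma(popgen.nei_distance(m))
    depths = _leaf_depths(tree)
    assert len(depths) == 10
    vals = np.array(list(depths.values()))
    assert np.allclose(vals, vals[0])


def test_upgma_newick_roundtrip(rng):
    dendropy = pytest.importorskip("dendropy")
    m = random_genotype_matrix(rng, n=7, loci=6)
    tree = popgen.upgma(popgen.nei_distance(m))
    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert {t.label for t in parsed.taxon_namespace} == set(m.index)


def test_upgma_bootstrap_supports(population_panel):
    matrix, groups, _ = population_panel
    tree = popgen.upgma_with_bootstrap(matrix, replicates=30, seed=0)
    supports = [n.support for n in _iter_internal(tree)]
    assert supports and all(0.0 <= s <= 100.0 for s in supports)
    # deep structure at Fst 0.25 should be strongly supported somewhere
    assert max(supports) > 50.0


def _iter_internal(node):
    if not node.is_leaf:
        yield node
        for c in node.children:
            yield from _iter_internal(c)


def test_upgma_rejects_asymmetric():
    d = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"], dtype=float)
    with pytest.raises(ValueError):
        popgen.upgma(d)


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_collinear_points():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    d = pd.DataFrame(np.abs(x[:, None] - x[None, :]), index=list("abcd"), columns=list("abcd"))
    res = popgen.pcoa(d)
    pos = res.eigenvalues[res.eigenvalues > 1e-10]
    assert pos[0] / pos.sum() == pytest.approx(1.0, abs=1e-9)


def test_pcoa_euclidean_reconstruction(rng):
    pts = rng.normal(size=(6, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    labels = [f"p{i}" for i in range(6)]
    res = popgen.pcoa(pd.DataFrame(d, index=labels, columns=labels))
    coords = res.coordinates.to_numpy()
    d2 = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    assert np.allclose(d, d2, atol=1e-8)


def test_pcoa_trace_identity(rng):
    m = random_genotype_matrix(rng, n=9, loci=6)
    d = popgen.nei_distance(m)
    res = popgen.pcoa(d)
    D = d.to_numpy()
    n = len(D)
    expected = (D**2)[np.triu_indices(n, 1)].sum() / n
    assert res.eigenvalues.sum() == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# AMOVA


def test_amova_published_single_locus_row():
    res = popgen.amova_from_ss([8, 6, 13], 74.960, 78.003)
    assert res.df_among == 2 and res.df_within == 24
    assert res.n0 == pytest.approx(8.5185, abs=1e-4)
    assert round(res.pmv_among, 2) == 55.28
    assert round(res.fst, 3) == 0.553


def test_amova_published_multi_locus_row():
    res = popgen.amova_from_ss([8, 6, 13], 292.330, 281.744)
    assert round(res.pmv_among, 2) == 57.34
    assert round(res.fst, 3) == 0.573


def test_amova_pmv_sums_to_100():
    res = popgen.amova_from_ss([8, 6, 13], 74.960, 78.003)
    assert res.pmv_among + res.pmv_within == pytest.approx(100.0)


def test_negative_component_truncated():
    with pytest.warns(UserWarning):
        res = popgen.amova_from_ss([5, 5], 0.1, 100.0)
    assert res.sigma2_among == 0.0 and res.fst == 0.0


def brute_force_amova(matrix, groups):
    """ANOVA on allele-count vectors: distances are Euclidean in c/sqrt(2)."""
    prof, _ = popgen._codominant_profile(matrix)
    V = 2.0 * prof / math.sqrt(2.0)
    lab = groups.loc[matrix.index].to_numpy()
    grand = V.mean(axis=0)
    ss_within = ss_among = 0.0
    for g in np.unique(lab):
        sub = V[lab == g]
        centroid = sub.mean(axis=0)
        ss_within += ((sub - centroid) ** 2).sum()
        ss_among += len(sub) * ((centroid - grand) ** 2).sum()
    return ss_among, ss_within


def test_amova_equals_vector_anova_oracle(rng):
    for trial in range(5):
        m = random_genotype_matrix(rng, n=12, loci=4)
        groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=m.index)
        res = popgen.amova(m, groups, permutations=0)
        ssa, ssw = brute_force_amova(m, groups)
        assert res.ss_among == pytest.approx(ssa, rel=1e-9)
        assert res.ss_within == pytest.approx(ssw, rel=1e-9)


def test_amova_group_of_one_rejected(rng):
    m = random_genotype_matrix(rng, n=5, loci=3)
    groups = pd.Series(["A"] * 4 + ["B"], index=m.index)
    with pytest.raises(ValueError):
        popgen.amova(m, groups)


def test_amova_random_labels_near_zero(rng):
    spec = simdata.PopSimSpec(group_sizes=(9, 9, 9), n_loci=200, target_fst=0.0, seed=31)
    m, groups, _ = simdata.simulate_population(spec)
    res = popgen.amova(m, groups, permutations=199, seed=5)
    assert res.fst < 0.05
    assert res.p_value > 0.05


def test_amova_dominant_route(population_panel):
    matrix, groups, _ = population_panel
    bands = simdata.simulate_bands(matrix, seed=3)
    res = popgen.amova(bands, groups, permutations=99, seed=1)
    assert 0.0 <= res.fst <= 1.0
    assert res.p_value < 0.05  # real structure present


# ---------------------------------------------------------------------------
# gene flow and Mann-Whitney


@pytest.mark.parametrize("fst,nm", [(0.25, 0.75), (0.5, 0.25), (0.9, 1 / 36)])
def test_gene_flow(fst, nm):
    assert popgen.gene_flow(fst) == pytest.approx(nm)


def test_gene_flow_limit():
    assert popgen.gene_flow(0.999) == pytest.approx(0.001 / (4 * 0.999))
    with pytest.raises(ValueError):
        popgen.gene_flow(1.0)
    with pytest.raises(ValueError):
        popgen.gene_flow(0.0)


def test_mann_whitney_complete_separation():
    u, p = popgen.mann_whitney([1, 2, 3], [10, 20, 30])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 extreme arrangements of C(6,3)=20


def test_mann_whitney_matches_scipy_exact():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        _, p = popgen.mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def test_mann_whitney_identical_samples():
    _, p = popgen.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_mann_whitney_large_sample_asymptotic():
    rng = np.random.default_rng(4)
    a = rng.normal(size=30)
    b = rng.normal(loc=2.0, size=30)
    _, p = popgen.mann_whitney(a, b)
    assert p < 0.001


def test_mann_whitney_empty_rejected():
    with pytest.raises(ValueError):
        popgen.mann_whitney([], [1.0])
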