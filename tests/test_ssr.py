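"""Marker statistics, Jaccard distances and UPGMA against printed values
and independent implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from diallelkit import datasets, ssr
from diallelkit._utils import round_half_up
from diallelkit.ssr import (
    DistanceMatrix,
    MarkerPanel,
    cophenetic_matrix,
    depth1_leafsets,
    dice_distance_matrix,
    gene_diversity,
    is_ultrametric,
    jaccard_distance_matrix,
    locus_summaries,
    panel_summary,
    pic,
    summarize_distances,
    to_newick,
    upgma,
)


# ---------------------------------------------------------------------------
# diversity statistics


@pytest.mark.parametrize(
    "freqs, gd2, pic2",
    [
        ((5 / 8, 3 / 8), 0.47, 0.36),   # biallelic, major 5/8
        ((7 / 8, 1 / 8), 0.22, 0.19),   # biallelic, major 7/8
        ((4 / 8, 4 / 8), 0.50, 0.38),   # even biallelic
        ((6 / 8, 2 / 8), 0.38, 0.30),
        ((4 / 8, 3 / 8, 1 / 8), 0.59, 0.51),
        ((0.25, 0.25, 0.125, 0.125, 0.125, 0.125), 0.81, 0.79),
        ((1.0,), 0.0, 0.0),
    ],
)
def test_diversity_matches_published_rows(freqs, gd2, pic2):
    assert round_half_up(gene_diversity(freqs)) == pytest.approx(gd2)
    assert round_half_up(pic(freqs)) == pytest.approx(pic2)


def test_frequency_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        gene_diversity([0.5, 0.4])
    with pytest.raises(ValueError, match="non-negative"):
        pic([1.5, -0.5])


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
def test_pic_bounded_by_gene_diversity(weights):
    p = np.array(weights) / np.sum(weights)
    gd, pv = gene_diversity(p), pic(p)
    assert pv <= gd + 1e-12
    assert 0.0 <= pv and gd < 1.0
    if len(p) >= 2 and np.min(p) > 0:
        assert pv < gd


def test_gene_diversity_maximal_at_uniform():
    for k in (2, 3, 6):
        uniform = gene_diversity(np.full(k, 1 / k))
        assert uniform == pytest.approx(1 - 1 / k)
        rng = np.random.default_rng(k)
        w = rng.dirichlet(np.ones(k))
        assert gene_diversity(w) <= uniform + 1e-12


def test_locus_summaries_reference_panel():
    """A panel realizing the published allele counts reproduces the
    published per-locus table and the 2.7 mean alleles/locus."""
    lines = datasets.REFERENCE_LINES
    alleles = {}
    for locus, counts in datasets.REFERENCE_LOCUS_ALLELE_COUNTS.items():
        calls = [f"a{k+1}" for k, c in enumerate(counts) for _ in range(c)]
        for line, call in zip(lines, calls):
            alleles[(line, locus)] = call
    panel = MarkerPanel(lines=lines, loci=tuple(datasets.REFERENCE_LOCUS_ALLELE_COUNTS), alleles=alleles)
    summ = panel_summary(panel)
    mean_row = summ[summ["locus"] == "Mean"].iloc[0]
    assert mean_row["n_alleles"] == pytest.approx(2.7)
    # the published column mean (0.50) does not reconstruct from the
    # published per-locus rows, which themselves average 0.4875
    assert round_half_up(mean_row["gene_diversity"]) == pytest.approx(0.49)
    assert round_half_up(mean_row["pic"]) == pytest.approx(0.41)
    assert round_half_up(mean_row["major_allele_freq"]) == pytest.approx(0.59)
    row = summ[summ["locus"] == "phi96100"].iloc[0]
    assert row["n_alleles"] == 2
    assert row["major_allele_freq"] == pytest.approx(0.875)
    assert round_half_up(row["gene_diversity"]) == pytest.approx(0.22)
    assert round_half_up(row["pic"]) == pytest.approx(0.19)


def test_monomorphic_locus():
    lines = ("A", "B", "C")
    panel = MarkerPanel(lines, ("m1",), {(l, "m1"): "a1" for l in lines})
    (summ,) = locus_summaries(panel)
    assert summ.n_alleles == 1
    assert summ.gene_diversity == 0.0 and summ.pic == 0.0


# ---------------------------------------------------------------------------
# distances


def test_jaccard_hand_counts():
    x = pd.DataFrame([[1, 1, 0, 1], [1, 0, 1, 1]], index=["a", "b"])
    d = jaccard_distance_matrix(x)
    assert d.between("a", "b") == pytest.approx(0.5)  # a=2, b=1, c=1


def test_jaccard_identity_and_disjoint():
    x = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]], index=["a", "b", "c"])
    d = jaccard_distance_matrix(x)
    assert d.between("a", "b") == 0.0
    assert d.between("a", "c") == 1.0


def test_jaccard_ignores_joint_absences():
    x = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
    padded = pd.concat([x, pd.DataFrame(0, index=x.index, columns=["z1", "z2"])], axis=1)
    assert jaccard_distance_matrix(x).between("a", "b") == pytest.approx(
        jaccard_distance_matrix(padded).between("a", "b")
    )


def test_jaccard_all_zero_pair_rejected():
    x = pd.DataFrame([[0, 0], [1, 1]], index=["a", "b"])
    with pytest.raises(ValueError, match="no scored band"):
        jaccard_distance_matrix(x)


def test_dice_le_jaccard():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.integers(0, 2, (6, 20)))
    x.iloc[:, 0] = 1  # avoid empty rows
    dj = jaccard_distance_matrix(x).values
    dd = dice_distance_matrix(x).values
    assert (dd <= dj + 1e-12).all()


def test_summarize_distances_reference_matrix():
    d = datasets.reference_distance_matrix()
    s = summarize_distances(d)
    assert s.min == pytest.approx(0.31)
    assert s.argmin_pairs == [("L1", "L4")]
    assert s.max == pytest.approx(0.78)
    assert set(s.argmax_pairs) == {("L1", "L8"), ("L2", "L5"), ("L2", "L6"), ("L2", "L8")}
    assert round_half_up(s.mean) == pytest.approx(0.62)  # unrounded mean 0.6164


def test_summarize_distances_enumeration_oracle():
    rng = np.random.default_rng(3)
    n = 6
    v = rng.uniform(0.05, 0.95, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    d = DistanceMatrix(tuple("ABCDEF"), v)
    s = summarize_distances(d)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [v[i, j] for i, j in pairs]
    assert s.min == pytest.approx(min(vals))
    assert s.max == pytest.approx(max(vals))
    assert s.mean == pytest.approx(np.mean(vals))


def test_constant_matrix_summary():
    v = np.full((3, 3), 0.5)
    np.fill_diagonal(v, 0.0)
    s = summarize_distances(DistanceMatrix(("a", "b", "c"), v))
    assert s.min == s.max == s.mean == 0.5


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_two_leaves():
    d = DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
    tree = upgma(d)
    assert tree.height == pytest.approx(0.2)
    assert to_newick(tree) == "(A:0.2,B:0.2);"
    assert cophenetic_matrix(tree).between("A", "B") == pytest.approx(0.4)


def test_upgma_three_leaf_hand_execution():
    """d(AB)=0.2, d(AC)=0.6, d(BC)=0.8: merge (A,B) at 0.1 then C at 0.35."""
    v = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]])
    tree = upgma(DistanceMatrix(("A", "B", "C"), v))
    assert tree.height == pytest.approx(0.35)
    inner = [c for c in tree.children if not c.is_leaf][0]
    assert inner.height == pytest.approx(0.1)
    assert sorted(inner.leaves()) == ["A", "B"]


def test_upgma_reference_matrix_two_origin_clusters():
    """The published distance matrix splits local (L1-L4) from exotic
    (L5-L8) lines at the root."""
    tree = upgma(datasets.reference_distance_matrix())
    assert set(depth1_leafsets(tree)) == {
        frozenset({"L1", "L2", "L3", "L4"}),
        frozenset({"L5", "L6", "L7", "L8"}),
    }
    assert is_ultrametric(tree)


@pytest.mark.parametrize("n,seed", [(5, 1), (8, 2), (10, 3)])
def test_upgma_matches_scipy_average_linkage(n, seed):
    """Cophenetic distances agree with scipy's average-linkage UPGMA on
    random tie-free matrices."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.1, 0.9, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    labels = tuple(f"T{i:02d}" for i in range(n))
    tree = upgma(DistanceMatrix(labels, v))
    z = average(squareform(v))
    ref = squareform(cophenet(z))
    got = cophenetic_matrix(tree)
    order = [got.labels.index(lab) for lab in labels]
    np.testing.assert_allclose(got.values[np.ix_(order, order)], ref, atol=1e-10)
    assert is_ultrametric(tree)


def test_upgma_tie_break_deterministic():
    v = np.full((4, 4), 0.6)
    np.fill_diagonal(v, 0.0)
    t1 = upgma(DistanceMatrix(("d", "c", "b", "a"), v))
    t2 = upgma(DistanceMatrix(("a", "b", "c", "d"), v))
    assert to_newick(t1) == to_newick(t2)


def test_newick_round_trip_dendropy():
    dendropy = pytest.importorskip("dendropy")
    tree = upgma(datasets.reference_distance_matrix())
    text = to_newick(tree)
    parsed = dendropy.Tree.get(data=text, schema="newick")
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    mine = cophenetic_matrix(tree)
    for i, a in enumerate(mine.labels):
        for b in mine.labels[i + 1:]:
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(mine.between(a, b), abs=1e-9)


# ---------------------------------------------------------------------------
# panel I/O


def test_band_csv_round_trip(tmp_path):
    from diallelkit.simulate import make_marker_config, simulate_marker_panel

    panel = simulate_marker_panel(make_marker_config(seed=3))
    path = tmp_path / "bands.csv"
    panel.to_band_csv(path)
    back = MarkerPanel.from_band_csv(path)
    assert back.lines == panel.lines
    assert set(back.loci) == set(panel.loci)
    assert back.alleles == panel.alleles
    assert MarkerPanel.from_json(panel.to_json()).alleles == panel.alleles
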