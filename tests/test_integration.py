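"""Boundary-gene classification, feature tests, correlations, windows, GC."""
import numpy as np
import pandas as pd
import pytest

import bact3c as b3c
from bact3c.domains import BoundarySet
from bact3c.genome import ValidationError
from bact3c.integration import bin_expression_track, boundary_gc_summary


def _genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "replicon", "start_bp", "end_bp", "strand"])
    return df


@pytest.fixture(scope="module")
def layout40():
    return b3c.RepliconLayout.single("r", 200_000, circular=True)


@pytest.fixture(scope="module")
def bins40(layout40):
    return b3c.bin_genome(layout40, 5_000)


def test_classify_genes_boundary_vs_interior(bins40):
    bset = BoundarySet("r", True, 40, [(10, 11)])
    genes = _genes(
        [
            ("inside", "r", 52_000, 53_000, "+"),   # inside the boundary interval
            ("flank", "r", 45_100, 45_200, "+"),    # within flank 1 (bin 9)
            ("abut", "r", 65_000, 66_000, "+"),     # first bp past extended end (bin 13)
            ("far", "r", 150_000, 151_000, "+"),
        ]
    )
    lab = b3c.classify_genes_by_boundary(genes, bset, bins40, flank_bins=1)
    assert lab.tolist() == ["boundary", "boundary", "interior", "interior"]


def test_classify_wraps_on_circular_replicon(bins40):
    bset = BoundarySet("r", True, 40, [(0, 0)])
    genes = _genes([("wrap", "r", 197_000, 198_000, "+")])  # last bin = flank of bin 0
    lab = b3c.classify_genes_by_boundary(genes, bset, bins40, flank_bins=1)
    assert lab.tolist() == ["boundary"]


def test_boundary_feature_test_directions_and_errors(bins40, rng):
    n = 60
    starts = np.arange(n) * 3_000
    genes = _genes([(f"g{i}", "r", s, s + 2_000, "+") for i, s in enumerate(starts)])
    genes["expression"] = rng.lognormal(4, 1, size=n)
    labels = pd.Series(["boundary"] * 10 + ["interior"] * 50)
    res = b3c.boundary_feature_test(labels, genes, "expression")
    assert res.alternative == "greater" and 0 <= res.p <= 1
    genes["gc"] = rng.uniform(0.4, 0.8, size=n)
    assert b3c.boundary_feature_test(labels, genes, "gc").alternative == "less"
    genes["expression"] = 1.0
    with pytest.raises(ValidationError, match="variation"):
        b3c.boundary_feature_test(labels, genes, "expression")
    with pytest.raises(ValidationError, match=">= 5"):
        b3c.boundary_feature_test(pd.Series(["boundary"] * 2 + ["interior"] * 58),
                                  genes.assign(expression=rng.lognormal(4, 1, n)),
                                  "expression")


def test_planted_boundary_expression_shift_detected():
    t = b3c.TruthSpec.chr1_like(seed=0)
    bins = b3c.bin_genome(t.layout, 5_000)
    bset = BoundarySet("Chr1", True, 530, [(int(x), int(x)) for x in t.boundaries["Chr1"]])
    genes, _, truth = b3c.simulate_expression_degs(
        t, "Chr1", boundary_expression_multiplier=2.0, boundary_flank_bins=3, seed=1)
    labels = b3c.classify_genes_by_boundary(genes, bset, bins, flank_bins=3)
    # generator truth and classifier agree on who is a boundary gene
    assert set(genes.loc[labels == "boundary", "gene_id"]) == set(truth.boundary_gene_ids)
    res = b3c.boundary_feature_test(labels, genes, "expression")
    assert res.p < 0.01


def test_expression_track_is_overlap_weighted(bins40):
    genes = _genes([("a", "r", 0, 5_000, "+"), ("b", "r", 5_000, 7_500, "+"),
                    ("c", "r", 7_500, 10_000, "+")])
    genes["expression"] = [2.0, 4.0, 8.0]
    track = bin_expression_track(genes, bins40, "r")
    assert track[0] == pytest.approx(2.0)
    assert track[1] == pytest.approx(6.0)  # equal halves of 4 and 8
    assert np.isnan(track[5])


def test_diagonal_correlation_perfect_and_permuted(chr1_norm, rng):
    diag = np.diag(chr1_norm.matrix)
    n = 300
    gbin = np.sort(rng.choice(530, n, replace=False))
    starts = gbin * 5_000 + 1_000  # one gene per bin, wholly inside it
    genes = _genes([(f"g{i}", "Chr1", s, s + 2_000, "+") for i, s in enumerate(starts)])
    genes["expression"] = diag[gbin]  # exactly proportional to the diagonal
    res = b3c.diagonal_expression_correlation(chr1_norm, genes, "Chr1")
    assert res.r == pytest.approx(1.0, abs=1e-9)
    genes["expression"] = rng.permutation(genes["expression"].to_numpy())
    res2 = b3c.diagonal_expression_correlation(chr1_norm, genes, "Chr1")
    assert abs(res2.r) < 0.2
    genes["expression"] = 3.0
    with pytest.raises(ValidationError, match="constant"):
        b3c.diagonal_expression_correlation(chr1_norm, genes, "Chr1")


def test_sliding_window_counts_and_arithmetic(layout40):
    genes = _genes([(f"g{i}", "r", i * 4_000, i * 4_000 + 1_000, "+") for i in range(50)])
    degs = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(5)],
            "log2_fold_change": 2.0,
            "adjusted_p": 0.001,
            "direction": "up",
        }
    )
    res = b3c.sliding_window_enrichment(degs, genes, layout40, "r", n_perm=99, seed=0)
    # circular replicon: one window per step
    assert len(res) == 200_000 // 5_000
    # every DEG midpoint lies in exactly window_bp/step_bp windows
    assert res["deg_count"].sum() == 5 * (100_000 // 5_000)
    assert ((res["q"] >= res["p"] - 1e-12)).all()


def test_sliding_window_concentrated_degs_rank_first(layout40):
    rng = np.random.default_rng(3)
    starts = np.sort(rng.choice(199_000, 80, replace=False))
    genes = _genes([(f"g{i}", "r", s, s + 800, "+") for i, s in enumerate(starts)])
    in_window = [f"g{i}" for i, s in enumerate(starts) if 50_000 <= s < 70_000][:6]
    degs = pd.DataFrame({"gene_id": in_window, "log2_fold_change": 2.0,
                         "adjusted_p": 0.001, "direction": "up"})
    res = b3c.sliding_window_enrichment(degs, genes, layout40, "r", window_bp=20_000,
                                        n_perm=999, seed=1)
    best = res.loc[res["p"].idxmin()]
    assert best["p"] <= 1.0 / (999 + 1) + 1e-12
    assert best["deg_count"] >= 4  # the concentrated region tops the ranking


def test_sliding_window_requires_degs(layout40):
    genes = _genes([("g0", "r", 0, 1_000, "+")])
    degs = pd.DataFrame({"gene_id": ["g0"], "log2_fold_change": [-2.0],
                         "adjusted_p": [0.001], "direction": ["down"]})
    with pytest.raises(ValidationError, match="no up-regulated"):
        b3c.sliding_window_enrichment(degs, genes, layout40, "r", n_perm=9, seed=0)


def test_gc_profile_values_and_errors(bins40):
    layout = b3c.RepliconLayout.single("s", 10_000)
    bins = b3c.bin_genome(layout, 5_000)
    seq = "ATGC" * 2_500
    prof = b3c.gc_profile(seq, bins, "s")
    assert np.allclose(prof, 0.5)
    seq2 = "AT" * 2_500 + "GC" * 2_500
    prof2 = b3c.gc_profile(seq2, bins, "s")
    assert prof2[0] == 0.0 and prof2[1] == 1.0
    with pytest.raises(ValidationError, match="length"):
        b3c.gc_profile("ATGC", bins, "s")


def test_gc_profile_weighted_mean_matches_whole_sequence(rng):
    layout = b3c.RepliconLayout.single("s", 12_000)
    bins = b3c.bin_genome(layout, 5_000)
    seq = "".join(rng.choice(list("ACGTN"), size=12_000))
    prof = b3c.gc_profile(seq, bins, "s")
    widths = (bins.ends() - bins.starts()).astype(float)
    # weights must be unambiguous-base counts per bin, not raw widths
    counts = np.array([sum(c in "ACGT" for c in seq[a:b])
                       for a, b in zip(bins.starts(), bins.ends())])
    pooled = (prof * counts).sum() / counts.sum()
    whole = sum(c in "GC" for c in seq) / sum(c in "ACGT" for c in seq)
    assert pooled == pytest.approx(whole)
    assert ((prof >= 0) & (prof <= 1)).all()


def test_boundary_gc_summary_fraction():
    gcs = np.array([0.6, 0.6, 0.3, 0.6, 0.7, 0.2, 0.6, 0.6])
    bset = BoundarySet("r", True, 8, [(2, 2), (5, 5), (4, 4)])
    out = boundary_gc_summary(gcs, bset)
    assert out["n_below"] == 2
    assert out["fraction_below"] == pytest.approx(2 / 3)
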