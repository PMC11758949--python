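"""Distance decay, expected model, and significant-contact calling."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bact3c as b3c
from bact3c.genome import ValidationError

from conftest import make_raw


def _bins(n, circular=True, name="r"):
    return b3c.bin_genome(b3c.RepliconLayout.single(name, n * 5_000, circular), 5_000)


@pytest.mark.parametrize(
    "i,j,L,expected",
    [
        (0, 1_500_000, 2_649_000, 1_149_000),
        (123, 123, 1_000, 0),
        (0, 500, 1_000, 500),
        (10, 990, 1_000, 20),
    ],
)
def test_circular_distance_examples(i, j, L, expected):
    assert b3c.circular_distance(i, j, L) == expected
    assert b3c.circular_distance(j, i, L) == expected  # symmetric
    assert b3c.circular_distance(i, j, L) <= L / 2


def test_circular_distance_rejects_out_of_range():
    with pytest.raises(ValidationError):
        b3c.circular_distance(0, 1_000, 1_000)


def test_ps_curve_flat_for_translation_invariant_map():
    n = 50
    m = np.ones((n, n), dtype=int) * 3
    np.fill_diagonal(m, 0)
    curve = b3c.ps_curve(make_raw(m, _bins(n)), "r")
    assert np.allclose(curve.table["mean"], 3.0)


def test_ps_curve_max_stratum_is_half_circumference(chr1_map):
    curve = b3c.ps_curve(chr1_map, "Chr1")
    assert curve.table["distance_bp"].max() == 530 // 2 * 5_000  # 1,325,000 ~ L/2


def test_ps_slope_recovers_planted_exponent():
    t = b3c.TruthSpec.chr1_like(seed=3, alpha=1.0, contrast=1.0, arm_strength=0.0,
                                bias_sigma=0.0)
    cm, _ = b3c.simulate_map(t)
    slope = b3c.ps_curve(cm, "Chr1").slope(min_dist_bp=5_000, max_dist_bp=500_000)
    assert slope == pytest.approx(-1.0, abs=0.1)


def test_expected_model_constant_input():
    n = 30
    m = np.full((n, n), 7, dtype=int)
    np.fill_diagonal(m, 0)
    exp = b3c.expected_model(make_raw(m, _bins(n)), "r")
    assert np.allclose(exp.expected, 7.0)


def test_expected_model_is_non_increasing_under_noise(rng):
    n = 80
    idx = np.arange(n)
    diff = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(diff, n - diff)
    mu = np.where(d == 0, 0.0, 200.0 / np.maximum(d, 1))
    counts = rng.poisson(mu)
    counts = np.triu(counts) + np.triu(counts, 1).T
    exp = b3c.expected_model(make_raw(counts, _bins(n)), "r")
    assert (np.diff(exp.expected) <= 1e-9).all()
    assert (exp.expected > 0).all()


def test_expected_model_rejects_all_zero():
    n = 10
    with pytest.raises(ValidationError, match="all-zero"):
        b3c.expected_model(make_raw(np.zeros((n, n)), _bins(n)), "r")


def test_low_count_pairs_never_reported():
    # strong relative enrichment at count 2 must still be filtered out
    n = 40
    rng = np.random.default_rng(0)
    m = rng.poisson(0.05, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    m[3, 20] = m[20, 3] = 2  # enriched but at the count floor
    sig = b3c.call_significant(make_raw(m, _bins(n)), "r")
    assert not ((sig["bin_i"] == 3) & (sig["bin_j"] == 20)).any()
    assert (sig["count"] > 2).all() if len(sig) else True


def test_planted_tenfold_pair_detected(chr1_map):
    exp = b3c.expected_model(chr1_map, "Chr1")
    d = int(np.argmin(np.abs(exp.expected - 5.0))) + 1
    i, j = 100, 100 + d
    m = chr1_map.matrix.copy()
    m[i, j] = m[j, i] = round(10 * exp.expected[d - 1])
    cm = b3c.ContactMatrix(m, chr1_map.bins, state="raw")
    sig = b3c.call_significant(cm, "Chr1")
    hit = sig[(sig["bin_i"] == i) & (sig["bin_j"] == j)]
    assert len(hit) == 1
    assert hit["q"].iloc[0] < 0.05


def test_poisson_significance_q_dominates_p(rng):
    mu = np.exp(rng.normal(np.log(50), 0.5, size=500))
    obs = rng.poisson(mu)
    p, q, keep = b3c.poisson_significance(obs, mu)
    assert (q >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(np.minimum.accumulate(q[order][::-1])[::-1]) >= -1e-15).all()


def test_null_calibration_small():
    """Strict-tail p-values are near-uniform; BH keeps the null clean."""
    rng = np.random.default_rng(7)
    frac = []
    survivors = 0
    for _ in range(20):
        mu = np.exp(rng.normal(np.log(120), 0.5, size=1000))
        obs = rng.poisson(mu)
        p, q, keep = b3c.poisson_significance(obs, mu)
        frac.append((p < 0.05).mean())
        survivors += int(keep.sum() > 0)
    assert 0.03 < np.mean(frac) < 0.07
    assert survivors <= 2


def test_classify_distances_proportions():
    sig = pd.DataFrame({"distance_bp": [10_000, 20_000, 100_000, 600_000]})
    out = b3c.classify_distances(sig)
    assert out["proportion"].sum() == pytest.approx(1.0)
    assert out["proportion"].tolist() == [0.75, 0.25]
    with pytest.raises(ValidationError):
        b3c.classify_distances(sig.iloc[:0])


def test_uv_like_condition_shifts_significant_contacts_to_long_range():
    wt, _ = b3c.simulate_map(b3c.TruthSpec.chr1_like(seed=21))
    uv, _ = b3c.simulate_map(b3c.TruthSpec.chr1_like(seed=21, condition="uv"))
    longf = {}
    for name, cm in (("wt", wt), ("uv", uv)):
        sig = b3c.call_significant(cm, "Chr1")
        out = b3c.classify_distances(sig)
        longf[name] = out["proportion"].iloc[-1]
    assert longf["uv"] > longf["wt"]


def test_stratified_ps_quantile_split_and_anchor_curves(chr1_norm, chr1_truth):
    rng = np.random.default_rng(2)
    n = 100
    starts = np.sort(rng.choice(2_600_000, n, replace=False))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "replicon": "Chr1",
            "start_bp": starts,
            "end_bp": starts + 2_000,
            "strand": "+",
            "expression": rng.lognormal(4, 1, size=n),
        }
    )
    curves = b3c.stratified_ps(chr1_norm, genes, "Chr1")
    assert set(curves) == {"low", "moderate", "high"}
    for c in curves.values():
        assert (c.table["n_pairs"] > 0).all()
    # 10%/10% split on 100 genes -> 10 high and 10 low gene labels
    expr = genes["expression"].to_numpy()
    assert (expr >= np.quantile(expr, 0.9)).sum() == 10


def test_stratified_ps_single_class_when_equal_expression(chr1_norm):
    genes = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "replicon": "Chr1",
            "start_bp": [0, 100_000, 200_000],
            "end_bp": [2_000, 102_000, 202_000],
            "strand": "+",
            "expression": [5.0, 5.0, 5.0],
        }
    )
    with pytest.warns(UserWarning):
        curves = b3c.stratified_ps(chr1_norm, genes, "Chr1")
    assert "high" in curves  # equal values land at both thresholds; top class wins
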