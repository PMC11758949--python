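"""3D embedding, gyration radius, compactness metrics, PPI proximity."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import bact3c as b3c
from bact3c.genome import ValidationError
from bact3c.structure import StructureModel

from conftest import make_norm


def _model(coords, bin_size=5_000, circular=True):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    pos = (np.arange(n) + 0.5) * bin_size
    return StructureModel(coords, np.full(n, "r"), pos, {"r": n * bin_size},
                          {"r": circular}, provenance="simulated",
                          bin_index=np.arange(n))


def test_radius_of_gyration_closed_form():
    m = _model([(0.5, 0.5, 0), (0.5, -0.5, 0), (-0.5, 0.5, 0), (-0.5, -0.5, 0)])
    assert b3c.radius_of_gyration(m) == pytest.approx(np.sqrt(0.5))
    single = StructureModel(np.zeros((1, 3)), np.array(["r"]), np.array([2500.0]),
                            {"r": 5000}, {"r": True})
    assert b3c.radius_of_gyration(single) == 0.0


def test_rg_scales_homogeneously(rng):
    coords = rng.normal(size=(50, 3))
    m = _model(coords)
    mk = _model(coords * 3.5)
    assert b3c.radius_of_gyration(mk) == pytest.approx(3.5 * b3c.radius_of_gyration(m))


def test_metrics_invariant_under_rigid_motion(rng):
    coords = rng.normal(size=(60, 3))
    R = Rotation.random(random_state=1).as_matrix()
    moved = coords @ R.T + np.array([3.0, -2.0, 7.0])
    a, b = _model(coords), _model(moved)
    assert abs(b3c.radius_of_gyration(a) - b3c.radius_of_gyration(b)) <= 1e-9
    ca, cb = b3c.compactness(a), b3c.compactness(b)
    assert abs(ca.gc - cb.gc) <= 1e-9
    assert np.allclose(ca.lc["lc"], cb.lc["lc"], atol=1e-9)
    assert np.allclose(a.pairwise_distances(), b.pairwise_distances(), atol=1e-9)


def test_gc_is_scale_free_and_lc_limits_to_gc(rng):
    coords = rng.normal(size=(40, 3))
    a = _model(coords)
    scaled = _model(coords * 12.0)
    ca, cs = b3c.compactness(a), b3c.compactness(scaled)
    assert ca.gc == pytest.approx(cs.gc)
    whole = b3c.compactness(a, local_scales_bp=(40 * 5_000,))
    assert whole.lc["lc"].iloc[0] == pytest.approx(ca.gc)


def test_collapsing_a_domain_raises_local_compactness():
    ring = b3c.simulate_structure("circle", 100, seed=0)
    coords = ring.coords.copy()
    block = slice(10, 30)
    coords[block] = coords[block].mean(axis=0) + 0.01 * (coords[block] - coords[block].mean(axis=0))
    collapsed = _model(coords)
    base = _model(ring.coords)
    scale = 20 * 5_000  # the collapsed domain's genomic size
    lc_base = b3c.compactness(base, (scale,)).lc["lc"].iloc[0]
    lc_coll = b3c.compactness(collapsed, (scale,)).lc["lc"].iloc[0]
    assert lc_coll > lc_base
    assert b3c.compactness(collapsed).gc > b3c.compactness(base).gc


def test_compactness_rejects_coincident_points():
    coords = np.zeros((5, 3))
    coords[1:] = np.eye(3)[None, 0] * np.arange(1, 5)[:, None]
    coords[2] = coords[1]
    with pytest.raises(ValidationError, match="[Cc]oincident"):
        b3c.compactness(_model(coords))


@pytest.mark.parametrize("shape", ["circle", "boat"])
def test_embedding_round_trip_recovers_shape(shape):
    s = b3c.simulate_structure(shape, 150)
    cm = b3c.structure_to_contacts(s, alpha=1.0, noiseless=True)
    emb = b3c.embed_structure(cm, alpha=1.0)
    assert b3c.procrustes_rmsd_ratio(s.coords, emb.coords) <= 0.15


def test_embedding_rejects_degenerate_and_disconnected():
    bins2 = b3c.bin_genome(b3c.RepliconLayout.single("r", 10_000), 5_000)
    tiny = make_norm([[0, 1.0], [1.0, 0]], bins2, valid=np.ones(2, bool))
    with pytest.raises(ValidationError, match="at least 4"):
        b3c.embed_structure(tiny)
    bins6 = b3c.bin_genome(b3c.RepliconLayout.single("r", 30_000), 5_000)
    m = np.zeros((6, 6))
    m[0, 1] = m[1, 0] = m[1, 2] = m[2, 1] = m[0, 2] = m[2, 0] = 1.0
    m[3, 4] = m[4, 3] = m[4, 5] = m[5, 4] = m[3, 5] = m[5, 3] = 1.0
    with pytest.raises(ValidationError, match="disconnected"):
        b3c.embed_structure(make_norm(m, bins6, valid=np.ones(6, bool)))


def test_structure_table_round_trip(tmp_path):
    s = b3c.simulate_structure("random_walk", 30, seed=5)
    p = tmp_path / "coords.tsv"
    s.to_table(p)
    from bact3c.structure import read_structure_table

    back = read_structure_table(p, "sim", 30 * 5_000, 5_000)
    assert np.allclose(back.coords, s.coords, atol=1e-6)
    pdb = tmp_path / "model.pdb"
    s.to_pdb(pdb)
    assert pdb.read_text().startswith("ATOM")


def _genes_per_bin(n):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "replicon": "sim",
            "start_bp": np.arange(n) * 5_000 + 1_000,
            "end_bp": np.arange(n) * 5_000 + 3_000,
            "strand": "+",
        }
    )


def test_ppi_test_nearest_neighbors_highly_significant():
    s = b3c.simulate_structure("circle", 200)
    genes = _genes_per_bin(200)
    bins = b3c.bin_genome(b3c.RepliconLayout.single("sim", 200 * 5_000), 5_000)
    pairs = [(f"g{i}", f"g{(i + 1) % 200}") for i in range(200)]
    res = b3c.ppi_distance_test(s, pairs, genes, bins)
    assert res.p < 1e-6
    assert res.median_ppi < res.median_all


def test_ppi_test_errors():
    s = b3c.simulate_structure("circle", 50)
    genes = _genes_per_bin(50)
    bins = b3c.bin_genome(b3c.RepliconLayout.single("sim", 50 * 5_000), 5_000)
    with pytest.raises(ValidationError, match="unknown gene ids"):
        b3c.ppi_distance_test(s, [("g0", "nope")], genes, bins)
    # a pair mapping into one bin is dropped; nothing left -> error
    genes2 = genes.copy()
    genes2.loc[1, ["start_bp", "end_bp"]] = [1_200, 3_200]  # same bin as g0
    with pytest.raises(ValidationError, match="no usable"):
        b3c.ppi_distance_test(s, [("g0", "g1")], genes2, bins)


def test_paired_rg_comparison_detects_planted_compaction():
    """Mutant-like maps (short-range depleted) embed to smaller Rg than wild type."""
    rgs = {"wt": [], "mutant": []}
    for cond in rgs:
        for seed in range(3):
            t = b3c.TruthSpec.chr1_like(seed=40 + seed, condition=cond)
            cm, _ = b3c.simulate_map(t)
            nm = b3c.scn_normalize(cm).matrix
            rgs[cond].append(b3c.radius_of_gyration(b3c.embed_structure(nm)))
    assert max(rgs["mutant"]) < min(rgs["wt"])
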