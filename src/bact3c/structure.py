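"""3D coordinate models: contact-map embedding and compactness metrics.

The embedding converts normalized contact values into target distances
d_ij = c_ij^(-1/alpha), completes missing distances by shortest paths over
the contact graph, and places one point per bin with classical
multidimensional scaling (three dimensions).  The result is an *average
structure*: with a polyploid genome, intra- and inter-copy contacts are
indistinguishable, so the model summarises the population rather than any
single molecule.

Compactness metrics:

    Rg          root-mean-square distance of points from their centroid
    GC          mean over all bin pairs of 1 / (d_ij / Rg)   (scale-free)
    LC(scale)   the same mean restricted to pairs with genomic
                separation <= scale
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .genome import BinTable, ValidationError
from .matrix import ContactMatrix
from .significance import circular_distance


@dataclass
class StructureModel:
    """One 3D coordinate per bin (arbitrary units)."""

    coords: np.ndarray  # (n, 3)
    replicon_ids: np.ndarray  # (n,) str
    positions_bp: np.ndarray  # (n,) midpoint of each bin on its replicon
    replicon_lengths: dict
    circular: dict
    provenance: str = "embedded"
    bin_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))

    def genomic_separation(self) -> np.ndarray:
        """(n, n) separation in bp; NaN between different replicons."""
        n = self.n_points
        out = np.full((n, n), np.nan)
        for rep in np.unique(self.replicon_ids):
            sel = np.flatnonzero(self.replicon_ids == rep)
            p = self.positions_bp[sel]
            d = np.abs(p[:, None] - p[None, :])
            if self.circular.get(rep, True):
                L = self.replicon_lengths[rep]
                d = np.minimum(d, L - d)
            out[np.ix_(sel, sel)] = d
        return out

    def to_table(self, path) -> None:
        pd.DataFrame(
            {
                "bin": np.arange(self.n_points) if self.bin_index is None else self.bin_index,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        ).to_csv(path, sep="\t", index=False)

    def to_pdb(self, path) -> None:
        """One pseudo-atom per bin, one chain per replicon."""
        chains = {rep: chr(ord("A") + k % 26)
                  for k, rep in enumerate(dict.fromkeys(self.replicon_ids))}
        scale = 10.0 / max(1e-9, radius_of_gyration(self))
        with open(path, "w") as fh:
            for i in range(self.n_points):
                x, y, z = self.coords[i] * scale
                fh.write(
                    f"ATOM  {i + 1:5d}  CA  BIN {chains[self.replicon_ids[i]]}"
                    f"{(i % 9999) + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
            fh.write("END\n")


def read_structure_table(path, replicon: str, length_bp: int, bin_size_bp: int,
                         circular: bool = True) -> StructureModel:
    df = pd.read_csv(path, sep="\t")
    coords = df[["x", "y", "z"]].to_numpy()
    pos = (df["bin"].to_numpy() + 0.5) * bin_size_bp
    return StructureModel(coords, np.full(len(df), replicon), pos,
                          {replicon: length_bp}, {replicon: circular},
                          provenance="imported", bin_index=df["bin"].to_numpy())


class ContactMDS(BaseEstimator):
    """Classical-MDS embedding of a normalized contact matrix.

    Parameters
    ----------
    alpha : float
        Contact-to-distance exponent: d_ij = c_ij^(-1/alpha).

    Attributes
    ----------
    embedding_ : (n_valid, 3) coordinates, centroid-centered.
    eigenvalues_ : top eigenvalues of the double-centered Gram matrix.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X: ContactMatrix, y=None):
        if X.state != "normalized":
            raise ValidationError("embedding expects a normalized matrix")
        valid = np.flatnonzero(X.valid)
        if valid.size < 4:
            raise ValidationError("need at least 4 valid bins for a 3D embedding")
        C = X.matrix[np.ix_(valid, valid)]
        with np.errstate(divide="ignore"):
            D = np.where(C > 0, C ** (-1.0 / self.alpha), 0.0)
        np.fill_diagonal(D, 0.0)
        graph = csr_matrix(np.where(C > 0, D, 0.0))
        ncomp, labels = connected_components(graph, directed=False)
        if ncomp > 1:
            sizes = np.bincount(labels)
            raise ValidationError(
                f"contact graph is disconnected ({ncomp} components, sizes {sizes.tolist()})"
            )
        full = shortest_path(graph, method="D", directed=False)
        coords, evals = _classical_mds(full, k=3)
        self.embedding_ = coords - coords.mean(axis=0)
        self.eigenvalues_ = evals
        self.valid_index_ = valid
        return self

    def fit_transform(self, X: ContactMatrix, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def _classical_mds(D: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    n = D.shape[0]
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    return coords, evals[order]


def embed_structure(m: ContactMatrix, alpha: float = 1.0) -> StructureModel:
    """Embed a normalized contact map into 3D (classical MDS)."""
    est = ContactMDS(alpha=alpha)
    est.fit(m)
    valid = est.valid_index_
    bins = m.bins
    reps = bins.replicon_of()[valid]
    pos = (bins.df["start_bp"].to_numpy()[valid] + bins.df["end_bp"].to_numpy()[valid]) / 2.0
    lengths = {r.name: r.length_bp for r in bins.layout}
    circ = {r.name: r.circular for r in bins.layout}
    return StructureModel(est.embedding_, reps, pos, lengths, circ,
                          provenance="embedded", bin_index=valid)


def radius_of_gyration(s: StructureModel) -> float:
    """Root-mean-square distance of points from the centroid."""
    c = s.coords - s.coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


@dataclass
class Compactness:
    gc: float
    lc: pd.DataFrame  # columns: scale_bp, lc


def compactness(s: StructureModel, local_scales_bp=(25_000, 50_000, 100_000, 250_000,
                                                    500_000)) -> Compactness:
    """Global and local compactness from mean inverse Rg-scaled distances."""
    if s.n_points < 2:
        raise ValidationError("need at least 2 points")
    D = s.pairwise_distances()
    iu = np.triu_indices(s.n_points, k=1)
    d = D[iu]
    if (d == 0).any():
        bad = np.argwhere((D + np.eye(s.n_points)) == 0)
        raise ValidationError(f"coincident points at bin pairs {bad[:5].tolist()}")
    rg = radius_of_gyration(s)
    inv = rg / d
    gc = float(inv.mean())
    sep = s.genomic_separation()[iu]
    rows = []
    for scale in local_scales_bp:
        sel = np.isfinite(sep) & (sep <= scale) & (sep > 0)
        if sel.any():
            rows.append((scale, float(inv[sel].mean())))
    return Compactness(gc, pd.DataFrame(rows, columns=["scale_bp", "lc"]))


def procrustes_rmsd_ratio(X: np.ndarray, Y: np.ndarray) -> float:
    """Shape discrepancy RMSD / Rg after optimal similarity alignment.

    With both configurations standardized by scipy's procrustes, the ratio
    equals sqrt(disparity).
    """
    _, _, disparity = procrustes(X, Y)
    return float(np.sqrt(disparity))


@dataclass
class PPITestResult:
    median_ppi: float
    median_all: float
    p: float
    n_pairs_used: int
    n_dropped_same_bin: int


def ppi_distance_test(
    s: StructureModel,
    ppi_pairs,
    genes: pd.DataFrame,
    bins: BinTable,
) -> PPITestResult:
    """Are PPI-linked loci spatially closer than background bin pairs?

    Each gene maps to the bin containing its midpoint; pairs collapsing to
    one bin are dropped.  One-sided Mann-Whitney test of PPI-pair spatial
    distances against all distinct valid bin-pair distances.
    """
    gene_bin = {}
    for _, g in genes.iterrows():
        mid = (g["start_bp"] + g["end_bp"]) / 2.0
        gene_bin[g["gene_id"]] = bins.bin_at(g["replicon"], mid)
    unknown = sorted({g for pair in ppi_pairs for g in pair} - set(gene_bin))
    if unknown:
        raise ValidationError(f"unknown gene ids in PPI list: {unknown[:5]}")
    if s.bin_index is None:
        raise ValidationError("structure model carries no bin indices")
    bin_to_point = {int(b): k for k, b in enumerate(s.bin_index)}
    D = s.pairwise_distances()
    dropped = 0
    dists = []
    for ga, gb in ppi_pairs:
        ba, bb = gene_bin[ga], gene_bin[gb]
        if ba == bb:
            dropped += 1
            continue
        if ba in bin_to_point and bb in bin_to_point:
            dists.append(D[bin_to_point[ba], bin_to_point[bb]])
    if not dists:
        raise ValidationError("no usable PPI pairs after bin mapping")
    iu = np.triu_indices(s.n_points, k=1)
    background = D[iu]
    ppi_d = np.asarray(dists)
    stat = stats.mannwhitneyu(ppi_d, background, alternative="less")
    return PPITestResult(float(np.median(ppi_d)), float(np.median(background)),
                         float(stat.pvalue), len(dists), dropped)
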