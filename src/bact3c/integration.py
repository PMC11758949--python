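"""Joint structure-transcription analyses.

Operations linking CID boundaries and contact maps to gene annotation:
boundary/interior gene classification and feature tests, the correlation
between per-bin transcription and the contact-map diagonal, sliding-window
enrichment of differentially expressed genes with a permutation null, and
per-bin G+C profiles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .domains import BoundarySet
from .genome import BinTable, RepliconLayout, ValidationError
from .significance import circular_distance


def classify_genes_by_boundary(
    genes: pd.DataFrame,
    boundaries: BoundarySet,
    bins: BinTable,
    flank_bins: int = 1,
) -> pd.Series:
    """Label each gene 'boundary' or 'interior'.

    Boundary genes overlap any boundary interval extended by ``flank_bins``
    on both sides (bp intervals, half-open; wrapping on circular replicons).
    Genes on other replicons are interior.
    """
    bs = bins.bin_size_bp
    rep = bins.layout[boundaries.replicon]
    n = boundaries.n_bins
    covered = np.zeros(n, dtype=bool)
    for a, b in boundaries.intervals:
        if b < a:
            b += n
        for k in range(a - flank_bins, b + flank_bins + 1):
            covered[k % n if rep.circular else min(max(k, 0), n - 1)] = True
    labels = []
    for _, g in genes.iterrows():
        if g["replicon"] != boundaries.replicon:
            labels.append("interior")
            continue
        first = int(g["start_bp"] // bs)
        last = min(int((g["end_bp"] - 1) // bs), n - 1)
        hit = any(covered[k] for k in range(first, last + 1))
        labels.append("boundary" if hit else "interior")
    return pd.Series(labels, index=genes.index, name="boundary_class")


@dataclass
class FeatureTestResult:
    feature: str
    median_boundary: float
    median_interior: float
    p: float
    alternative: str
    n_boundary: int
    n_interior: int


FEATURE_ALTERNATIVES = {"expression": "greater", "length_bp": "greater", "gc": "less"}


def boundary_feature_test(
    labels: pd.Series,
    genes: pd.DataFrame,
    feature: str = "expression",
    min_group: int = 5,
) -> FeatureTestResult:
    """One-sided Mann-Whitney test of a gene feature, boundary vs interior.

    Expression and gene length are tested for being *larger* at boundaries;
    G+C content for being *smaller* (boundaries are AT-richer).
    """
    if feature == "length_bp":
        values = (genes["end_bp"] - genes["start_bp"]).to_numpy(dtype=float)
    elif feature in genes.columns:
        values = genes[feature].to_numpy(dtype=float)
    else:
        raise ValidationError(f"gene table lacks feature {feature!r}")
    alt = FEATURE_ALTERNATIVES.get(feature, "greater")
    vb = values[(labels == "boundary").to_numpy()]
    vi = values[(labels == "interior").to_numpy()]
    if vb.size < min_group or vi.size < min_group:
        raise ValidationError(
            f"need >= {min_group} genes per group (boundary {vb.size}, interior {vi.size})"
        )
    if np.ptp(values) == 0:
        raise ValidationError(f"feature {feature!r} has no variation")
    res = stats.mannwhitneyu(vb, vi, alternative=alt)
    return FeatureTestResult(feature, float(np.median(vb)), float(np.median(vi)),
                             float(res.pvalue), alt, vb.size, vi.size)


def bin_expression_track(genes: pd.DataFrame, bins: BinTable, replicon: str,
                         expression_col: str = "expression") -> np.ndarray:
    """Per-bin transcription signal: overlap-length-weighted mean expression."""
    s = bins.replicon_slice(replicon)
    n = s.stop - s.start
    bs = bins.bin_size_bp
    wsum = np.zeros(n)
    esum = np.zeros(n)
    sub = genes[genes["replicon"] == replicon]
    for _, g in sub.iterrows():
        e = float(g[expression_col])
        first = int(g["start_bp"] // bs)
        last = min(int((g["end_bp"] - 1) // bs), n - 1)
        for b in range(first, last + 1):
            lo = max(g["start_bp"], b * bs)
            hi = min(g["end_bp"], (b + 1) * bs)
            w = hi - lo
            wsum[b] += w
            esum[b] += w * e
    with np.errstate(invalid="ignore"):
        track = np.where(wsum > 0, esum / np.maximum(wsum, 1e-12), np.nan)
    return track


@dataclass
class CorrelationResult:
    r: float
    p: float
    n_bins: int


def diagonal_expression_correlation(
    m,
    genes: pd.DataFrame,
    replicon: str,
    expression_col: str = "expression",
) -> CorrelationResult:
    """Pearson correlation of per-bin transcription with the map diagonal."""
    C, s = m.cis(replicon)
    track = bin_expression_track(genes, m.bins, replicon, expression_col)
    diag = np.diag(C).copy()
    ok = m.valid[s] & np.isfinite(track)
    x, y = track[ok], diag[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("undefined correlation: constant track")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))


def sliding_window_enrichment(
    degs: pd.DataFrame,
    genes: pd.DataFrame,
    layout: RepliconLayout,
    replicon: str | None = None,
    window_bp: int = 100_000,
    step_bp: int = 5_000,
    n_perm: int = 2000,
    seed: int = 0,
    direction: str = "up",
    boundaries: BoundarySet | None = None,
    bin_size_bp: int = 5_000,
) -> pd.DataFrame:
    """Sliding-window DEG counts with a label-permutation null.

    Windows advance by ``step_bp`` (wrapping on circular replicons); a gene
    belongs to a window if its midpoint falls inside.  The null reassigns
    the DEG labels uniformly over all annotated genes on the replicon,
    preserving gene density; empirical p-values are BH-corrected across
    windows.
    """
    if replicon is None:
        replicon = layout.names[0]
    rep = layout[replicon]
    sub = genes[genes["replicon"] == replicon].reset_index(drop=True)
    deg_ids = set(degs.loc[degs["direction"] == direction, "gene_id"])
    is_deg = sub["gene_id"].isin(deg_ids).to_numpy()
    n_deg = int(is_deg.sum())
    if n_deg == 0:
        raise ValidationError(f"no {direction}-regulated DEGs on {replicon}")
    mid = ((sub["start_bp"] + sub["end_bp"]) / 2.0).to_numpy()
    L = rep.length_bp
    if rep.circular:
        starts = np.arange(0, L, step_bp)
    else:
        starts = np.arange(0, max(L - window_bp, 0) + 1, step_bp)
    n_win = starts.size
    # window membership of each gene midpoint
    members: list[np.ndarray] = []
    k_per = window_bp // step_bp
    for p in mid:
        first = int(np.floor((p - window_bp) / step_bp)) + 1
        ks = np.arange(first, int(p // step_bp) + 1)
        if rep.circular:
            ks = ks % n_win
        else:
            ks = ks[(ks >= 0) & (ks < n_win)]
        members.append(ks)
    obs = np.zeros(n_win, dtype=int)
    for g in np.flatnonzero(is_deg):
        obs[members[g]] += 1
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_win, dtype=int)
    G = len(sub)
    for _ in range(n_perm):
        pick = rng.choice(G, size=n_deg, replace=False)
        cnt = np.zeros(n_win, dtype=int)
        for g in pick:
            cnt[members[g]] += 1
        exceed += cnt >= obs
    p_emp = (1.0 + exceed) / (n_perm + 1.0)
    _, q, _, _ = multipletests(p_emp, method="fdr_bh")
    centers = (starts + window_bp / 2.0) % L if rep.circular else starts + window_bp / 2.0
    if boundaries is not None and len(boundaries):
        bmid_bp = (boundaries.midpoints + 0.5) * bin_size_bp
        if rep.circular:
            dist = np.min(
                np.minimum(np.abs(centers[:, None] - bmid_bp[None, :]),
                           L - np.abs(centers[:, None] - bmid_bp[None, :])), axis=1)
        else:
            dist = np.min(np.abs(centers[:, None] - bmid_bp[None, :]), axis=1)
    else:
        dist = np.full(n_win, np.nan)
    return pd.DataFrame(
        {
            "window_start_bp": starts,
            "window_end_bp": starts + window_bp,
            "deg_count": obs,
            "p": p_emp,
            "q": q,
            "dist_to_boundary_bp": dist,
        }
    )


def gc_profile(sequence, bins: BinTable, replicon: str) -> np.ndarray:
    """Per-bin G+C fraction; ambiguity codes excluded from the denominator."""
    seq = str(sequence).upper()
    rep = bins.layout[replicon]
    if len(seq) != rep.length_bp:
        raise ValidationError(
            f"sequence length {len(seq)} does not match {replicon} length {rep.length_bp}"
        )
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_at = (arr == ord("A")) | (arr == ord("T"))
    s = bins.replicon_slice(replicon)
    n = s.stop - s.start
    bs = bins.bin_size_bp
    out = np.full(n, np.nan)
    for b in range(n):
        lo, hi = b * bs, min((b + 1) * bs, rep.length_bp)
        denom = is_gc[lo:hi].sum() + is_at[lo:hi].sum()
        if denom > 0:
            out[b] = is_gc[lo:hi].sum() / denom
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def boundary_gc_summary(gc_per_bin: np.ndarray, boundaries: BoundarySet) -> dict:
    """Mean boundary-interval GC vs replicon mean; fraction of boundaries below it."""
    genome_mean = float(np.nanmean(gc_per_bin))
    n = boundaries.n_bins
    below = 0
    means = []
    for a, b in boundaries.intervals:
        if b < a:
            b += n
        idx = [k % n for k in range(a, b + 1)]
        mb = float(np.nanmean(gc_per_bin[idx]))
        means.append(mb)
        below += mb < genome_mean
    frac = below / len(means) if means else float("nan")
    return {"genome_mean_gc": genome_mean, "boundary_means": means,
            "n_below": below, "fraction_below": frac}
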