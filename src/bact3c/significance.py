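"""Distance decay, expected-count model, and significant-contact calling.

Contact frequency between cis loci decays with genomic separation roughly
as a power law P(s) ~ s^(-alpha).  Significant contacts are bin pairs whose
raw count exceeds the distance-expected count: the expected value per
distance stratum is the isotonic (non-increasing) fit to the empirical
stratum means, the per-pair p-value is the upper Poisson tail
P(X >= obs | mu = expected(d)), and Benjamini-Hochberg q-values are
computed over all tested pairs.  Pairs with p < alpha, q < alpha and count
> min_count are reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .genome import BinTable, ValidationError
from .matrix import ContactMatrix


def circular_distance(pos_i, pos_j, length_bp: float):
    """Shorter-arc separation between positions on a circular replicon."""
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    if np.any(pos_i < 0) or np.any(pos_i >= length_bp) or np.any(pos_j < 0) or np.any(
        pos_j >= length_bp
    ):
        raise ValidationError(f"positions must lie in [0, {length_bp})")
    d = np.abs(pos_i - pos_j)
    out = np.minimum(d, length_bp - d)
    return float(out) if out.ndim == 0 else out


def _pair_distances_bins(n: int, circular: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle (i, j, distance_in_bins) for one replicon's cis matrix."""
    iu = np.triu_indices(n, k=1)
    d = iu[1] - iu[0]
    if circular:
        d = np.minimum(d, n - d)
    return iu[0], iu[1], d


@dataclass
class PsCurve:
    """Mean contact value per genomic-distance stratum."""

    table: pd.DataFrame  # columns: distance_bp, mean, n_pairs
    replicon: str
    label: str = ""

    def slope(self, min_dist_bp: float | None = None, max_dist_bp: float | None = None) -> float:
        """Log-log slope of the decay (the fitted exponent is -slope)."""
        t = self.table
        sel = t["mean"] > 0
        if min_dist_bp is not None:
            sel &= t["distance_bp"] >= min_dist_bp
        if max_dist_bp is not None:
            sel &= t["distance_bp"] <= max_dist_bp
        t = t[sel]
        if len(t) < 3:
            raise ValidationError("too few strata to fit a decay slope")
        res = stats.linregress(np.log(t["distance_bp"]), np.log(t["mean"]))
        return float(res.slope)


def ps_curve(
    m: ContactMatrix,
    replicon: str,
    log_binning: bool = False,
    n_log_bins: int = 30,
    label: str = "",
) -> PsCurve:
    """P(s): mean contact value per distance stratum on one replicon.

    Distances are shorter-arc separations on circular replicons; the main
    diagonal (s = 0) is excluded.  Empty strata are absent, not zero.
    """
    C, s = m.cis(replicon)
    rep = m.bins.layout[replicon]
    n = C.shape[0]
    bs = m.bins.bin_size_bp
    valid = m.valid[s]
    ii, jj, d = _pair_distances_bins(n, rep.circular)
    keep = valid[ii] & valid[jj]
    vals = C[ii, jj][keep]
    dist_bp = d[keep] * bs
    if log_binning:
        lo, hi = np.log10(bs), np.log10(dist_bp.max())
        edges = np.logspace(lo, hi, n_log_bins + 1)
        idx = np.clip(np.digitize(dist_bp, edges) - 1, 0, n_log_bins - 1)
        rows = []
        for k in range(n_log_bins):
            sel = idx == k
            if sel.any():
                rows.append((float(np.exp(np.mean(np.log(dist_bp[sel])))),
                             float(vals[sel].mean()), int(sel.sum())))
        table = pd.DataFrame(rows, columns=["distance_bp", "mean", "n_pairs"])
    else:
        df = pd.DataFrame({"distance_bp": dist_bp, "v": vals})
        g = df.groupby("distance_bp")["v"].agg(["mean", "size"]).reset_index()
        table = g.rename(columns={"size": "n_pairs"})[["distance_bp", "mean", "n_pairs"]]
    return PsCurve(table, replicon, label)


@dataclass
class ExpectedDecay:
    """Expected mean count per distance stratum (bins), isotonically smoothed."""

    distance_bp: np.ndarray
    expected: np.ndarray
    bin_size_bp: int

    def lookup(self, dist_bp) -> np.ndarray:
        d = np.asarray(dist_bp, dtype=float)
        idx = np.rint(d / self.bin_size_bp).astype(int) - 1
        out = np.full(d.shape, np.nan)
        ok = (idx >= 0) & (idx < self.expected.size)
        out[ok] = self.expected[idx[ok]]
        return out


def expected_model(raw: ContactMatrix, replicon: str) -> ExpectedDecay:
    """Distance-decay expected counts from the raw cis map.

    Empirical per-distance stratum means are smoothed by isotonic
    (non-increasing in distance) regression and floored at the smallest
    positive stratum mean so every stratum has a strictly positive
    expectation.
    """
    if raw.state != "raw":
        raise ValidationError("expected_model works on raw counts")
    C, s = raw.cis(replicon)
    rep = raw.bins.layout[replicon]
    n = C.shape[0]
    bs = raw.bins.bin_size_bp
    valid = raw.valid[s]
    if C[np.ix_(valid, valid)].sum() == 0:
        raise ValidationError("all-zero matrix: expected model undefined")
    ii, jj, d = _pair_distances_bins(n, rep.circular)
    keep = valid[ii] & valid[jj]
    vals = C[ii, jj][keep]
    dbin = d[keep]
    dmax = int(dbin.max())
    means = np.full(dmax, np.nan)
    counts = np.bincount(dbin, minlength=dmax + 1)[1:]
    sums = np.bincount(dbin, weights=vals, minlength=dmax + 1)[1:]
    present = counts > 0
    means[present] = sums[present] / counts[present]
    x = np.flatnonzero(present) + 1
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fitted = iso.fit_transform(x.astype(float), means[present])
    smooth = np.full(dmax, np.nan)
    smooth[present] = fitted
    pos = fitted[fitted > 0]
    floor = pos.min() if pos.size else np.nan
    smooth[present] = np.maximum(smooth[present], floor)
    return ExpectedDecay(np.arange(1, dmax + 1) * bs, smooth, bs)


def poisson_significance(obs, mu, alpha: float = 0.05, min_count: int = 2):
    """Upper-tail Poisson p-values, BH q-values and the keep filter.

    p = P(X >= obs | mu); pairs are kept when p < alpha, q < alpha and
    obs > min_count.
    """
    obs = np.asarray(obs)
    mu = np.asarray(mu, dtype=float)
    p = stats.poisson.sf(obs - 1, mu)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    keep = (p < alpha) & (q < alpha) & (obs > min_count)
    return p, q, keep


class SignificantContactCaller(BaseEstimator):
    """Distance-decay-based significant cis contact detection.

    Attributes (after fit): ``results_`` (kept pairs), ``n_tested_``,
    ``n_skipped_``, ``expected_``.
    """

    def __init__(self, alpha: float = 0.05, min_count: int = 2):
        self.alpha = alpha
        self.min_count = min_count

    def fit(self, X: ContactMatrix, y=None, replicon: str | None = None,
            expected: ExpectedDecay | None = None):
        if replicon is None:
            replicon = X.bins.layout.names[0]
        if X.state != "raw":
            raise ValidationError("significance is computed on raw counts")
        if expected is None:
            expected = expected_model(X, replicon)
        C, s = X.cis(replicon)
        rep = X.bins.layout[replicon]
        n = C.shape[0]
        bs = X.bins.bin_size_bp
        valid = X.valid[s]
        ii, jj, d = _pair_distances_bins(n, rep.circular)
        keep = valid[ii] & valid[jj]
        ii, jj, d = ii[keep], jj[keep], d[keep]
        obs = C[ii, jj]
        mu = expected.lookup(d * bs)
        tested = np.isfinite(mu) & (mu > 0)
        self.n_skipped_ = int((~tested).sum())
        ii, jj, d, obs, mu = ii[tested], jj[tested], d[tested], obs[tested], mu[tested]
        p, q, keep2 = poisson_significance(obs, mu, self.alpha, self.min_count)
        self.results_ = pd.DataFrame(
            {
                "bin_i": ii[keep2] + s.start,
                "bin_j": jj[keep2] + s.start,
                "count": obs[keep2].astype(int),
                "expected": mu[keep2],
                "p": p[keep2],
                "q": q[keep2],
                "distance_bp": d[keep2] * bs,
            }
        ).reset_index(drop=True)
        self.n_tested_ = int(p.size)
        self.p_values_ = p
        self.q_values_ = q
        self.expected_ = expected
        return self


def call_significant(
    raw: ContactMatrix,
    replicon: str | None = None,
    expected: ExpectedDecay | None = None,
    alpha: float = 0.05,
    min_count: int = 2,
) -> pd.DataFrame:
    """Significant cis contacts (p < alpha, BH q < alpha, count > min_count)."""
    est = SignificantContactCaller(alpha=alpha, min_count=min_count)
    est.fit(raw, replicon=replicon, expected=expected)
    return est.results_


def classify_distances(sig: pd.DataFrame, band_edges=(450_000,)) -> pd.DataFrame:
    """Proportion of significant pairs per distance band (proportions sum to 1)."""
    if len(sig) == 0:
        raise ValidationError("no significant interactions to classify")
    edges = [0.0, *sorted(band_edges), np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{_fmt_bp(lo)}-{_fmt_bp(hi)}" if np.isfinite(hi) else f">{_fmt_bp(lo)}")
    idx = np.clip(np.digitize(sig["distance_bp"], edges[1:-1]), 0, len(labels) - 1)
    counts = np.bincount(idx, minlength=len(labels))
    return pd.DataFrame({"band": labels, "n": counts, "proportion": counts / counts.sum()})


def _fmt_bp(x: float) -> str:
    return f"{int(x / 1000)}kb" if np.isfinite(x) else "inf"


def stratified_ps(
    m: ContactMatrix,
    genes: pd.DataFrame,
    replicon: str,
    expression_col: str = "expression",
    quantile: float = 0.10,
    log_binning: bool = True,
) -> dict[str, PsCurve]:
    """P(s) per expression class of the anchor bin.

    Genes in the top ``quantile`` of expression are "high", the bottom
    ``quantile`` "low", the rest "moderate".  A bin takes the maximal class
    (high > moderate > low) of the genes it overlaps; curves average pairs
    whose anchor bin carries the class.
    """
    if expression_col not in genes.columns:
        raise ValidationError(f"gene table lacks {expression_col!r}")
    sub = genes[genes["replicon"] == replicon]
    expr = genes[expression_col].to_numpy(dtype=float)
    hi_thr = np.quantile(expr, 1 - quantile)
    lo_thr = np.quantile(expr, quantile)
    C, s = m.cis(replicon)
    rep = m.bins.layout[replicon]
    n = C.shape[0]
    bs = m.bins.bin_size_bp
    rank = np.full(n, -1)  # -1 no gene, 0 low, 1 moderate, 2 high
    for _, g in sub.iterrows():
        e = float(g[expression_col])
        cls = 2 if e >= hi_thr else (0 if e <= lo_thr else 1)
        first = int(g["start_bp"] // bs)
        last = min(int((g["end_bp"] - 1) // bs), n - 1)
        for b in range(first, last + 1):
            rank[b] = max(rank[b], cls)
    valid = m.valid[s]
    ii, jj, d = _pair_distances_bins(n, rep.circular)
    keep = valid[ii] & valid[jj]
    ii, jj, d = ii[keep], jj[keep], d[keep]
    vals = C[ii, jj]
    curves: dict[str, PsCurve] = {}
    names = {0: "low", 1: "moderate", 2: "high"}
    for cls, name in names.items():
        anchor = (rank[ii] == cls) | (rank[jj] == cls)
        if not anchor.any():
            import warnings

            warnings.warn(f"no bins in expression class {name!r}", stacklevel=2)
            continue
        df = pd.DataFrame({"distance_bp": d[anchor] * bs, "v": vals[anchor]})
        if log_binning:
            lo, hi = np.log10(bs), np.log10(df["distance_bp"].max())
            edges = np.logspace(lo, hi, 21)
            gidx = np.clip(np.digitize(df["distance_bp"], edges) - 1, 0, 19)
            rows = []
            for k in range(20):
                sel = gidx == k
                if sel.any():
                    rows.append((float(np.exp(np.mean(np.log(df["distance_bp"][sel])))),
                                 float(df["v"][sel].mean()), int(sel.sum())))
            table = pd.DataFrame(rows, columns=["distance_bp", "mean", "n_pairs"])
        else:
            g = df.groupby("distance_bp")["v"].agg(["mean", "size"]).reset_index()
            table = g.rename(columns={"size": "n_pairs"})[["distance_bp", "mean", "n_pairs"]]
        curves[name] = PsCurve(table, replicon, label=name)
    return curves
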