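"""Derived map views: per-bin scalograms and condition-ratio maps.

A scalogram summarises local compaction: for each bin it records how far
into the flanking chromatin one must integrate before a given fraction of
that bin's cis contacts is accumulated.  Compact loci reach high fractions
within narrow flanks.  A ratio map compares two normalized maps bin-by-bin
as a function of genomic distance (log2 condition / reference).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ValidationError
from .matrix import ContactMatrix

SCALOGRAM_LEVELS = (0.15, 0.30, 0.45, 0.60, 0.75, 1.00)


@dataclass
class Scalogram:
    """Half-widths (bp) at which each bin reaches the cumulative-contact levels."""

    halfwidths_bp: np.ndarray  # (n_bins, n_levels)
    levels: tuple[float, ...]
    replicon: str
    bin_slice: slice
    max_halfwidth_bp: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"hw_{int(100 * f)}pct_bp" for f in self.levels]
        df = pd.DataFrame(self.halfwidths_bp, columns=cols)
        df.insert(0, "bin_index", np.arange(self.bin_slice.start, self.bin_slice.stop))
        return df


def scalogram(
    m: ContactMatrix,
    replicon: str,
    max_halfwidth_bp: int = 500_000,
    levels: tuple[float, ...] = SCALOGRAM_LEVELS,
) -> Scalogram:
    """Cumulative-contact half-widths per bin on one replicon's cis map."""
    if m.state != "normalized":
        raise ValidationError("scalogram expects a normalized matrix")
    C, s = m.cis(replicon)
    rep = m.bins.layout[replicon]
    n = C.shape[0]
    bs = m.bins.bin_size_bp
    max_w = max_halfwidth_bp // bs
    if rep.circular and max_w > n // 2:
        warnings.warn(
            f"max_halfwidth {max_halfwidth_bp} exceeds half of circular replicon "
            f"{replicon}; clipping", stacklevel=2,
        )
        max_w = n // 2
    max_w = min(max_w, n - 1)
    idx = np.arange(n)
    cum = np.empty((n, max_w + 1))
    cum[:, 0] = np.diag(C)
    for w in range(1, max_w + 1):
        if rep.circular:
            up = C[idx, (idx - w) % n]
            dn = C[idx, (idx + w) % n]
        else:
            up = np.where(idx - w >= 0, C[idx, np.clip(idx - w, 0, n - 1)], 0.0)
            dn = np.where(idx + w < n, C[idx, np.clip(idx + w, 0, n - 1)], 0.0)
        cum[:, w] = cum[:, w - 1] + up + dn
    total = cum[:, -1]
    hw = np.zeros((n, len(levels)))
    for li, f in enumerate(levels):
        target = f * total - 1e-12 * np.maximum(total, 1.0)
        reached = cum >= target[:, None]
        hw[:, li] = np.argmax(reached, axis=1) * bs
    hw[total <= 0] = np.nan
    hw[~m.valid[s]] = np.nan
    return Scalogram(hw, tuple(levels), replicon, s, max_w * bs)


@dataclass
class RatioMap:
    """log2 ratios between two maps over (bin, genomic distance)."""

    values: np.ndarray  # (n_bins, n_dist) with NaN where masked
    distances_bp: np.ndarray
    replicon: str
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{int(d)}" for d in self.distances_bp])
        df.insert(0, "bin", np.arange(self.values.shape[0]))
        return df


def ratio_map(
    a: ContactMatrix,
    b: ContactMatrix,
    replicon: str,
    max_dist_bp: int = 500_000,
    pseudocount: float | None = None,
) -> RatioMap:
    """Per-bin log2(a/b) as a function of genomic distance, directions averaged."""
    if a.state != "normalized" or b.state != "normalized":
        raise ValidationError("ratio_map expects normalized matrices")
    if len(a.bins) != len(b.bins):
        raise ValidationError("matrices are on different bin tables")
    A, s = a.cis(replicon)
    B, _ = b.cis(replicon)
    rep = a.bins.layout[replicon]
    bs = a.bins.bin_size_bp
    n = A.shape[0]
    valid = a.valid[s] & b.valid[s]
    if not np.array_equal(a.valid[s], b.valid[s]):
        warnings.warn("masks differ between conditions; using intersection", stacklevel=2)
    if pseudocount is None:
        pooled = np.concatenate([A[A > 0].ravel(), B[B > 0].ravel()])
        pseudocount = float(np.quantile(pooled, 0.05)) if pooled.size else 1e-9
    max_k = min(max_dist_bp // bs, n // 2 if rep.circular else n - 1)
    idx = np.arange(n)
    out = np.full((n, max_k), np.nan)
    for k in range(1, max_k + 1):
        if rep.circular:
            ja, jb = (idx + k) % n, (idx - k) % n
            ok = valid & valid[ja] & valid[jb]
            ra = np.log2((A[idx, ja] + pseudocount) / (B[idx, ja] + pseudocount))
            rb = np.log2((A[idx, jb] + pseudocount) / (B[idx, jb] + pseudocount))
            val = (ra + rb) / 2.0
        else:
            terms = []
            for j in (idx + k, idx - k):
                inside = (j >= 0) & (j < n)
                jj = np.clip(j, 0, n - 1)
                term = np.log2((A[idx, jj] + pseudocount) / (B[idx, jj] + pseudocount))
                term[~inside | ~valid[jj]] = np.nan
                terms.append(term)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                val = np.nanmean(np.vstack(terms), axis=0)
            ok = valid & ~np.isnan(val)
        out[ok, k - 1] = val[ok]
    distances = np.arange(1, max_k + 1) * bs
    return RatioMap(out, distances, replicon, pseudocount)
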