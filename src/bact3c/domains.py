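"""Directionality index and chromosomal interaction domain (CID) calling.

The directionality index (DI) contrasts, for each bin, the contact sum A
with the window of bins upstream against the sum B with the window
downstream:

    E = (A + B) / 2
    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E),  DI = 0 if A + B = 0

Sustained negative DI (upstream bias) switching to sustained positive DI
(downstream bias) marks a domain boundary; the maximal segments between
successive boundaries are the CIDs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genome import BinTable, ValidationError
from .matrix import ContactMatrix


@dataclass
class DIProfile:
    """Per-bin upstream/downstream sums and DI values for one replicon."""

    replicon: str
    circular: bool
    bin_slice: slice
    A: np.ndarray
    B: np.ndarray
    di: np.ndarray
    scale_bp: int
    valid: np.ndarray

    @property
    def E(self) -> np.ndarray:
        return (self.A + self.B) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.bin_slice.start, self.bin_slice.stop),
                "A_upstream": self.A,
                "B_downstream": self.B,
                "di": self.di,
            }
        )


@dataclass
class BoundarySet:
    """Boundary intervals (local bin coordinates, inclusive) on one replicon."""

    replicon: str
    circular: bool
    n_bins: int
    intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def midpoints(self) -> np.ndarray:
        mids = []
        for a, b in self.intervals:
            if b < a:  # wrap interval on a circular replicon
                b += self.n_bins
            mids.append(((a + b + 1) // 2) % self.n_bins)
        return np.array(sorted(mids), dtype=int)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class CIDSet:
    """Maximal inter-boundary segments, as (start_bin, end_bin_exclusive)."""

    replicon: str
    segments: list[tuple[int, int]]
    bin_size_bp: int
    replicon_length_bp: int

    def sizes_bp(self) -> np.ndarray:
        sizes = []
        for a, b in self.segments:
            nb = b - a if b > a else b - a + self._n_bins()
            sizes.append(nb * self.bin_size_bp)
        total = sum(sizes)
        if sizes and total > self.replicon_length_bp:
            # trailing short bin: clip the segment containing it
            sizes[-1] -= total - self.replicon_length_bp
        return np.array(sizes)

    def _n_bins(self) -> int:
        import math

        return math.ceil(self.replicon_length_bp / self.bin_size_bp)

    def __len__(self) -> int:
        return len(self.segments)


def directionality_index(m: ContactMatrix, replicon: str, scale_bp: int = 100_000) -> DIProfile:
    """DI per bin at the given scale on one replicon's cis matrix.

    Windows wrap on circular replicons and truncate at the ends of linear
    ones; the main diagonal is excluded from both sums.
    """
    bs = m.bins.bin_size_bp
    if scale_bp % bs != 0:
        raise ValidationError(f"scale_bp {scale_bp} must be a multiple of bin size {bs}")
    C, s = m.cis(replicon)
    rep = m.bins.layout[replicon]
    n = C.shape[0]
    w = scale_bp // bs
    if rep.circular and 2 * w >= n:
        raise ValidationError(
            f"scale {scale_bp} bp is not below half of circular replicon {replicon}"
        )
    idx = np.arange(n)
    A = np.zeros(n)
    B = np.zeros(n)
    for k in range(1, w + 1):
        if rep.circular:
            A += C[idx, (idx - k) % n]
            B += C[idx, (idx + k) % n]
        else:
            j = idx - k
            ok = j >= 0
            A[ok] += C[idx[ok], j[ok]]
            j = idx + k
            ok = j < n
            B[ok] += C[idx[ok], j[ok]]
    E = (A + B) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = (A - E) ** 2 / E + (B - E) ** 2 / E
    di = np.sign(B - A) * np.where(E > 0, chi, 0.0)
    di[~np.isfinite(di)] = 0.0
    return DIProfile(replicon, rep.circular, s, A, B, di, scale_bp, m.valid[s])


class DirectionalityCaller(BaseEstimator):
    """DI-based CID boundary caller.

    Parameters
    ----------
    scale_bp : int
        DI window size (upstream and downstream), default 100 kb.
    min_run_bins : int
        Minimum length of the negative run and of the positive run framing
        a boundary.
    min_abs_di : float or None
        Magnitude threshold; if None, the ``di_quantile`` of |DI| over
        valid bins is used.
    di_quantile : float
        Quantile defining the adaptive threshold.

    Attributes
    ----------
    di_ : DIProfile
    boundaries_ : BoundarySet
    cids_ : CIDSet
    threshold_ : float
    """

    def __init__(self, scale_bp: int = 100_000, min_run_bins: int = 3,
                 min_abs_di: float | None = None, di_quantile: float = 0.60):
        self.scale_bp = scale_bp
        self.min_run_bins = min_run_bins
        self.min_abs_di = min_abs_di
        self.di_quantile = di_quantile

    def fit(self, X: ContactMatrix, y=None, replicon: str | None = None):
        if replicon is None:
            replicon = X.bins.layout.names[0]
        di = directionality_index(X, replicon, self.scale_bp)
        self.di_ = di
        self.boundaries_, self.cids_, self.threshold_ = call_boundaries(
            di, X.bins, self.min_run_bins, self.min_abs_di, self.di_quantile,
            return_threshold=True,
        )
        return self


def call_boundaries(
    di: DIProfile,
    bins: BinTable,
    min_run_bins: int = 3,
    min_abs_di: float | None = None,
    di_quantile: float = 0.60,
    return_threshold: bool = False,
):
    """Place boundaries where sustained negative DI flips to sustained positive.

    A boundary requires a run of >= ``min_run_bins`` bins with
    DI <= -threshold followed by a run of >= ``min_run_bins`` bins with
    DI >= +threshold, allowing at most one intervening near-zero bin.  The
    boundary interval spans the transition bins.  On circular replicons the
    scan wraps; CIDs are the segments between successive boundary midpoints.
    """
    n = di.di.size
    if (di.valid.sum()) < 2 * min_run_bins:
        warnings.warn("too few valid bins for boundary calling", stacklevel=2)
        bset = BoundarySet(di.replicon, di.circular, n, [])
        cset = _cids_from_boundaries(bset, bins, di)
        return (bset, cset, np.nan) if return_threshold else (bset, cset)
    if min_abs_di is None:
        thr = float(np.quantile(np.abs(di.di[di.valid]), di_quantile))
    else:
        thr = float(min_abs_di)
    cls = np.zeros(n, dtype=int)
    cls[di.di >= thr] = 1
    cls[di.di <= -thr] = -1

    runs = _run_length_encode(cls, circular=di.circular)
    intervals: list[tuple[int, int]] = []
    nruns = len(runs)
    for ri in range(nruns):
        val, start, length = runs[ri]
        if val != -1 or length < min_run_bins:
            continue
        nxt = (ri + 1) % nruns if di.circular else ri + 1
        if nxt >= nruns and not di.circular:
            continue
        if di.circular and nruns == 1:
            continue
        v2, s2, l2 = runs[nxt]
        gap = 0
        if v2 == 0 and l2 <= 1:
            gap = l2
            nxt2 = (nxt + 1) % nruns if di.circular else nxt + 1
            if not di.circular and nxt2 >= nruns:
                continue
            v2, s2, l2 = runs[nxt2]
        if v2 == 1 and l2 >= min_run_bins:
            last_neg = (start + length - 1) % n
            first_pos = s2 % n
            intervals.append((last_neg, first_pos))
    bset = BoundarySet(di.replicon, di.circular, n, intervals)
    cset = _cids_from_boundaries(bset, bins, di)
    return (bset, cset, thr) if return_threshold else (bset, cset)


def _run_length_encode(cls: np.ndarray, circular: bool) -> list[tuple[int, int, int]]:
    """(value, start, length) runs; on circular tracks the first and last
    runs are merged when equal so the wrap transition is scanned once."""
    runs = []
    n = cls.size
    start = 0
    for i in range(1, n + 1):
        if i == n or cls[i] != cls[start]:
            runs.append((int(cls[start]), start, i - start))
            start = i
    if circular and len(runs) > 1 and runs[0][0] == runs[-1][0]:
        v, s, l = runs.pop()
        v0, s0, l0 = runs[0]
        runs[0] = (v0, s, l + l0)
    return runs


def _cids_from_boundaries(bset: BoundarySet, bins: BinTable, di: DIProfile) -> CIDSet:
    rep = bins.layout[di.replicon]
    mids = bset.midpoints
    n = di.di.size
    segs: list[tuple[int, int]] = []
    if mids.size == 0:
        segs = [(0, n)]
    elif di.circular:
        for i, a in enumerate(mids):
            b = mids[(i + 1) % mids.size]
            segs.append((int(a), int(b)))
    else:
        prev = 0
        for a in mids:
            if a > prev:
                segs.append((prev, int(a)))
            prev = int(a)
        if prev < n:
            segs.append((prev, n))
    return CIDSet(di.replicon, segs, bins.bin_size_bp, rep.length_bp)


@dataclass
class BoundaryComparison:
    conserved: int
    lost: int  # in a but not matched in b
    gained: int  # in b but not matched in a
    matches: list[tuple[int, int]]


def compare_boundaries(a: BoundarySet, b: BoundarySet, tol_bins: int = 2) -> BoundaryComparison:
    """Greedy nearest matching of boundary midpoints within tol_bins."""
    ma, mb = a.midpoints, b.midpoints
    if ma.size == 0 or mb.size == 0:
        return BoundaryComparison(0, int(ma.size), int(mb.size), [])
    n = a.n_bins
    d = np.abs(ma[:, None] - mb[None, :]).astype(float)
    if a.circular:
        d = np.minimum(d, n - d)
    order = np.argsort(d, axis=None)
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for flat in order:
        i, j = divmod(int(flat), mb.size)
        if d[i, j] > tol_bins:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((int(ma[i]), int(mb[j])))
    conserved = len(matches)
    return BoundaryComparison(conserved, int(ma.size) - conserved, int(mb.size) - conserved,
                              matches)


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    n_called: int
    n_truth: int


def boundary_recovery(called: BoundarySet, truth_bins, tol_bins: int = 2) -> RecoveryScore:
    """Precision/recall/F1 of called boundaries against planted truth bins."""
    truth_bins = np.asarray(truth_bins, dtype=int)
    truth = BoundarySet(called.replicon, called.circular, called.n_bins,
                        [(int(t), int(t)) for t in truth_bins])
    cmp = compare_boundaries(called, truth, tol_bins)
    n_called, n_truth = len(called), truth_bins.size
    precision = cmp.conserved / n_called if n_called else (1.0 if n_truth == 0 else 0.0)
    recall = cmp.conserved / n_truth if n_truth else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if n_truth and (precision + recall) > 0 else 0.0)
    return RecoveryScore(precision, recall, f1, n_called, n_truth)
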