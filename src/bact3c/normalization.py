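"""Bin filtering and sequential component normalization (SCN).

SCN removes multiplicative per-bin biases (restriction-site density, GC
content, mappability) by alternately dividing each column and each row of
the contact matrix by its vector norm until the matrix stops changing.  A
separable bias ``M[i,j] = b_i * b_j * K[i,j]`` is removed exactly: the fixed
point depends only on the kernel ``K``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genome import ValidationError
from .matrix import ContactMatrix


def filter_bins(m: ContactMatrix, min_coverage_quantile: float = 0.0) -> np.ndarray:
    """Mask low-coverage bins ahead of normalization.

    Bins with zero total coverage, or coverage below the given quantile of
    the nonzero coverages, are marked invalid.  Returns a boolean mask
    (True = keep).
    """
    if not (0.0 <= min_coverage_quantile < 1.0):
        raise ValidationError(
            f"min_coverage_quantile must be in [0, 1), got {min_coverage_quantile}"
        )
    if m.state != "raw":
        raise ValidationError("filter_bins expects a raw matrix")
    coverage = m.matrix.sum(axis=0)
    keep = coverage > 0
    nonzero = coverage[keep]
    if min_coverage_quantile > 0 and nonzero.size:
        thr = np.quantile(nonzero, min_coverage_quantile)
        keep &= coverage >= thr
    return keep & m.valid


class SCNNormalizer(TransformerMixin, BaseEstimator):
    """Sequential component normalization of a symmetric contact matrix.

    Parameters
    ----------
    norm : {"euclidean", "sum"}
        Vector norm used for the column/row divisions.  Euclidean is the
        original SCN choice; "sum" yields rows summing to one.
    tol : float
        Convergence threshold on the maximum relative entry change between
        iterations.
    max_iter : int
        Iteration cap; non-convergence yields ``converged_ = False`` and a
        warning rather than an error.

    Attributes
    ----------
    n_iter_ : int
    residual_ : float
    converged_ : bool
    mask_ : ndarray of bool, bins actually normalized.
    """

    def __init__(self, norm: str = "euclidean", tol: float = 1e-6, max_iter: int = 2000):
        self.norm = norm
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y=None, mask: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValidationError("SCN expects a square matrix")
        if self.norm not in ("euclidean", "sum"):
            raise ValidationError(f"unknown norm {self.norm!r}")
        self.mask_ = np.asarray(mask, dtype=bool) if mask is not None else X.sum(axis=0) > 0
        if not self.mask_.any():
            raise ValidationError("all bins masked; nothing to normalize")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mask = self.mask_
        W = X[np.ix_(mask, mask)].copy()
        eps = np.finfo(float).tiny
        residual = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            prev = W.copy()
            if self.norm == "euclidean":
                cn = np.sqrt((W**2).sum(axis=0))
            else:
                cn = W.sum(axis=0)
            W = W / np.where(cn > 0, cn, 1.0)[None, :]
            if self.norm == "euclidean":
                rn = np.sqrt((W**2).sum(axis=1))
            else:
                rn = W.sum(axis=1)
            W = W / np.where(rn > 0, rn, 1.0)[:, None]
            residual = float((np.abs(W - prev) / np.maximum(np.abs(prev), eps)).max())
            if residual < self.tol:
                break
        self.n_iter_ = it
        self.residual_ = residual
        self.converged_ = residual < self.tol
        if not self.converged_:
            warnings.warn(
                f"SCN did not converge in {self.max_iter} iterations "
                f"(residual {residual:.3g})", stacklevel=2,
            )
        W = (W + W.T) / 2.0  # alternating row/column steps break exact symmetry
        out = np.zeros_like(X)
        out[np.ix_(mask, mask)] = W
        return out


@dataclass
class NormalizationResult:
    matrix: ContactMatrix
    n_iter: int
    residual: float
    converged: bool
    mask: np.ndarray


def scn_normalize(
    m: ContactMatrix,
    norm: str = "euclidean",
    tol: float = 1e-6,
    max_iter: int = 2000,
    mask: np.ndarray | None = None,
    per_replicon: bool = False,
) -> NormalizationResult:
    """Normalize a raw contact matrix with SCN.

    By default the genome-wide matrix is balanced as a whole; with
    ``per_replicon`` each cis block is balanced independently (trans blocks
    are zeroed).
    """
    if m.state != "raw":
        raise ValidationError("scn_normalize expects a raw matrix")
    base_mask = m.valid if mask is None else (np.asarray(mask, dtype=bool) & m.valid)
    if per_replicon:
        out = np.zeros_like(m.matrix)
        iters, residuals, converged = [], [], True
        for rep in m.bins.layout.names:
            s = m.bins.replicon_slice(rep)
            est = SCNNormalizer(norm=norm, tol=tol, max_iter=max_iter)
            est.fit(m.matrix[s, s], mask=base_mask[s])
            out[s, s] = est.transform(m.matrix[s, s])
            iters.append(est.n_iter_)
            residuals.append(est.residual_)
            converged &= est.converged_
        n_iter, residual = max(iters), max(residuals)
    else:
        est = SCNNormalizer(norm=norm, tol=tol, max_iter=max_iter)
        est.fit(m.matrix, mask=base_mask)
        out = est.transform(m.matrix)
        n_iter, residual, converged = est.n_iter_, est.residual_, est.converged_
    cm = ContactMatrix(out, m.bins, state="normalized", valid=base_mask,
                       note=f"SCN({norm}, tol={tol})")
    return NormalizationResult(cm, n_iter, residual, converged, base_mask)
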