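"""Contact-matrix container and text I/O, replicate correlation and merging."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BinTable, ValidationError

SYMMETRY_ATOL = 1e-8


class ParseError(ValueError):
    pass


@dataclass
class ContactMatrix:
    """Square symmetric matrix of contact values over the bins of a BinTable.

    ``state`` is ``"raw"`` (non-negative integer counts) or ``"normalized"``.
    ``valid`` is a boolean per-bin mask; masked rows/columns carry no
    contacts.
    """

    matrix: np.ndarray
    bins: BinTable
    state: str = "raw"
    valid: np.ndarray | None = None
    note: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {m.shape}")
        if m.shape[0] != len(self.bins):
            raise ValidationError(
                f"matrix size {m.shape[0]} does not match bin table ({len(self.bins)} bins)"
            )
        scale = max(1.0, float(np.abs(m).max(initial=0.0)))
        asym = float(np.abs(m - m.T).max(initial=0.0))
        if asym > SYMMETRY_ATOL * scale:
            raise ValidationError(f"matrix asymmetric beyond tolerance (max |M-M^T| = {asym:g})")
        if (m < 0).any():
            raise ValidationError("contact values must be non-negative")
        if self.state == "raw" and not np.allclose(m, np.rint(m)):
            raise ValidationError("raw state requires integer counts")
        if self.state not in ("raw", "normalized"):
            raise ValidationError(f"unknown state {self.state!r}")
        self.matrix = m
        if self.valid is None:
            self.valid = m.sum(axis=0) > 0
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (m.shape[0],):
                raise ValidationError("valid mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def cis(self, replicon: str) -> tuple[np.ndarray, slice]:
        """Dense cis submatrix of one replicon and its global slice."""
        s = self.bins.replicon_slice(replicon)
        return self.matrix[s, s], s

    def with_matrix(self, m: np.ndarray, state: str | None = None,
                    valid: np.ndarray | None = None, note: str | None = None) -> "ContactMatrix":
        return ContactMatrix(
            m, self.bins,
            state=self.state if state is None else state,
            valid=self.valid if valid is None else valid,
            note=self.note if note is None else note,
        )


# ---------------------------------------------------------------------------
# I/O


def read_contacts(path, fmt: str, bins: BinTable, state: str = "raw") -> ContactMatrix:
    """Read a contact matrix from dense TSV or bin-pair triplet text.

    Triplet input carrying only upper-triangle entries is mirrored; missing
    pairs are zero.
    """
    n = len(bins)
    if fmt == "dense":
        with open(path) as fh:
            first = fh.readline()
        tokens = first.rstrip("\n").split("\t")
        has_header = any(":" in t or t == "" for t in tokens) or not _all_numeric(tokens)
        df = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                         index_col=0 if has_header else None)
        m = df.to_numpy(dtype=float)
        if m.shape != (n, n):
            raise ParseError(f"dense matrix shape {m.shape} does not match {n} bins")
    elif fmt == "triplet":
        m = np.zeros((n, n))
        seen = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"line {lineno}: expected 3 tab-separated fields: {line!r}")
                try:
                    i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from exc
                if not (0 <= i < n and 0 <= j < n):
                    raise ParseError(f"line {lineno}: bin index out of range [0, {n})")
                if c < 0:
                    raise ParseError(f"line {lineno}: negative count {c}")
                key = (min(i, j), max(i, j))
                if key in seen and seen[key] != c:
                    raise ParseError(f"line {lineno}: conflicting duplicate entry for pair {key}")
                seen[key] = c
                m[i, j] = c
                m[j, i] = c
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    if (m < 0).any():
        raise ParseError("negative counts in matrix")
    return ContactMatrix(m, bins, state=state)


def _all_numeric(tokens) -> bool:
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


def write_contacts(cm: ContactMatrix, path, fmt: str = "triplet", header: bool = False) -> None:
    if fmt == "dense":
        if header:
            labels = cm.bins.labels()
            pd.DataFrame(cm.matrix, index=labels, columns=labels).to_csv(path, sep="\t")
        else:
            np.savetxt(path, cm.matrix, delimiter="\t",
                       fmt="%d" if cm.state == "raw" else "%.10g")
    elif fmt == "triplet":
        iu = np.triu_indices(cm.n_bins)
        vals = cm.matrix[iu]
        nz = vals != 0
        with open(path, "w") as fh:
            fh.write("# bin_i\tbin_j\tcount\n")
            fmt_c = "%d" if cm.state == "raw" else "%.10g"
            for i, j, c in zip(iu[0][nz], iu[1][nz], vals[nz]):
                fh.write(f"{i}\t{j}\t{fmt_c % c}\n")
    else:
        raise ValidationError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Replicate handling


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    n_pairs: int


def replicate_correlation(a: ContactMatrix, b: ContactMatrix) -> CorrelationReport:
    """Pearson r over log(count+1) upper-triangle cis entries of jointly valid bins."""
    _check_same_bins(a, b)
    if a.state != "raw" or b.state != "raw":
        raise ValidationError("replicate correlation requires raw matrices")
    valid = a.valid & b.valid
    xs, ys = [], []
    for rep in a.bins.layout.names:
        s = a.bins.replicon_slice(rep)
        v = valid[s]
        sub_a = a.matrix[s, s]
        sub_b = b.matrix[s, s]
        iu = np.triu_indices(s.stop - s.start, k=1)
        keep = v[iu[0]] & v[iu[1]]
        xs.append(sub_a[iu][keep])
        ys.append(sub_b[iu][keep])
    x = np.log1p(np.concatenate(xs))
    y = np.log1p(np.concatenate(ys))
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("undefined correlation: zero-variance input")
    r, _ = stats.pearsonr(x, y)
    return CorrelationReport(float(r), int(x.size))


def merge_replicates(mats: list[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of raw replicate matrices; valid mask intersected."""
    if not mats:
        raise ValidationError("need at least one matrix to merge")
    first = mats[0]
    total = np.zeros_like(first.matrix)
    valid = np.ones(first.n_bins, dtype=bool)
    for m in mats:
        _check_same_bins(first, m)
        if m.state != "raw":
            raise ValidationError("can only merge raw matrices")
        total = total + m.matrix
        valid &= m.valid
    if not valid.any():
        warnings.warn("merged matrix has no jointly valid bins", stacklevel=2)
    return ContactMatrix(total, first.bins, state="raw", valid=valid,
                         note=f"merged {len(mats)} replicates")


def _check_same_bins(a: ContactMatrix, b: ContactMatrix) -> None:
    if len(a.bins) != len(b.bins) or a.bins.bin_size_bp != b.bins.bin_size_bp:
        raise ValidationError("matrices are on different bin tables")
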