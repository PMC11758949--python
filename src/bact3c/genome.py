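"""Genome coordinate model: replicons, fixed-width bins, gene and DEG tables.

A bacterial genome is represented as an ordered collection of replicons
(chromosomes and plasmids), each with a length in bp and a circularity flag.
All downstream contact-map analysis works on a genome-wide, 0-based,
half-open coordinate system in which replicons are concatenated in layout
order and tiled by fixed-width bins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Replicon:
    name: str
    length_bp: int
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValidationError(
                f"replicon {self.name!r}: length_bp must be >= 1, got {self.length_bp}"
            )


@dataclass(frozen=True)
class RepliconLayout:
    """Ordered replicons defining the genome-wide coordinate system."""

    replicons: tuple[Replicon, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.replicons]
        if not names:
            raise ValidationError("layout must contain at least one replicon")
        if len(set(names)) != len(names):
            raise ValidationError(f"replicon names must be unique: {names}")

    def __iter__(self):
        return iter(self.replicons)

    def __getitem__(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.replicons]

    @property
    def total_length_bp(self) -> int:
        return sum(r.length_bp for r in self.replicons)

    @classmethod
    def single(cls, name: str, length_bp: int, circular: bool = True) -> "RepliconLayout":
        return cls((Replicon(name, length_bp, circular),))

    @classmethod
    def deinococcus(cls) -> "RepliconLayout":
        """The four-replicon D. radiodurans genome (Chr1, Chr2, pMP1, pCP1)."""
        return cls(
            (
                Replicon("Chr1", 2_649_000, True),
                Replicon("Chr2", 412_000, True),
                Replicon("pMP1", 177_000, True),
                Replicon("pCP1", 46_000, True),
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "RepliconLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        reps = tuple(
            Replicon(str(r["name"]), int(r["length_bp"]), bool(r.get("circular", True)))
            for r in doc["replicons"]
        )
        return cls(reps)

    def to_yaml(self, path) -> None:
        doc = {
            "replicons": [
                {"name": r.name, "length_bp": r.length_bp, "circular": r.circular}
                for r in self.replicons
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


class BinTable:
    """Fixed-width tiling of a genome layout.

    Bins are 0-based, half-open intervals ``[start, end)`` local to each
    replicon; the global ``bin_index`` runs contiguously across replicons in
    layout order.  All bins have width ``bin_size_bp`` except possibly the
    last bin of each replicon.
    """

    def __init__(self, layout: RepliconLayout, bin_size_bp: int, df: pd.DataFrame):
        self.layout = layout
        self.bin_size_bp = bin_size_bp
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    def replicon_slice(self, name: str) -> slice:
        idx = np.flatnonzero((self.df["replicon"] == name).to_numpy())
        if idx.size == 0:
            raise KeyError(name)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def n_replicon_bins(self, name: str) -> int:
        s = self.replicon_slice(name)
        return s.stop - s.start

    def replicon_of(self) -> np.ndarray:
        return self.df["replicon"].to_numpy()

    def starts(self) -> np.ndarray:
        return self.df["start_bp"].to_numpy()

    def ends(self) -> np.ndarray:
        return self.df["end_bp"].to_numpy()

    def midpoints_bp(self) -> np.ndarray:
        return (self.starts() + self.ends()) / 2.0

    def labels(self) -> list[str]:
        return [
            f"{r}:{s}-{e}"
            for r, s, e in zip(self.df["replicon"], self.df["start_bp"], self.df["end_bp"])
        ]

    def bin_at(self, replicon: str, pos_bp: float) -> int:
        """Global index of the bin containing a local position."""
        rep = self.layout[replicon]
        if not (0 <= pos_bp < rep.length_bp):
            raise ValidationError(
                f"position {pos_bp} outside replicon {replicon} [0, {rep.length_bp})"
            )
        s = self.replicon_slice(replicon)
        local = min(int(pos_bp // self.bin_size_bp), s.stop - s.start - 1)
        return s.start + local

    def cis_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix marking intra-replicon bin pairs."""
        rep = self.df["replicon"].to_numpy()
        return rep[:, None] == rep[None, :]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def bin_genome(layout: RepliconLayout, bin_size_bp: int) -> BinTable:
    """Tile each replicon with ``bin_size_bp`` bins (ceil(length/size) per replicon)."""
    if bin_size_bp < 1:
        raise ValidationError(f"bin_size_bp must be >= 1, got {bin_size_bp}")
    rows = []
    gi = 0
    for rep in layout:
        n = math.ceil(rep.length_bp / bin_size_bp)
        for k in range(n):
            start = k * bin_size_bp
            end = min((k + 1) * bin_size_bp, rep.length_bp)
            rows.append((gi, rep.name, start, end))
            gi += 1
    df = pd.DataFrame(rows, columns=["bin_index", "replicon", "start_bp", "end_bp"])
    return BinTable(layout, bin_size_bp, df)


# ---------------------------------------------------------------------------
# Gene / DEG tables


GENE_COLUMNS = ["gene_id", "replicon", "start_bp", "end_bp", "strand"]


def validate_genes(genes: pd.DataFrame, layout: RepliconLayout | None = None) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene table missing columns: {missing}")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if (genes["start_bp"] >= genes["end_bp"]).any():
        raise ValidationError("gene start_bp must be < end_bp")
    if layout is not None:
        for name, sub in genes.groupby("replicon"):
            length = layout[name].length_bp
            if (sub["end_bp"] > length).any():
                raise ValidationError(f"gene coordinates exceed {name} length {length}")
    return genes


def read_genes(path, layout: RepliconLayout | None = None) -> pd.DataFrame:
    """Read a gene table from GFF3 or headered tabular text.

    GFF3 coordinates (1-based, closed) are converted to 0-based half-open.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (first.count("\t") == 8 and not first.startswith("gene_id")):
        names = [
            "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
        ]
        raw = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
        raw = raw[raw["type"].isin(["gene", "CDS"])]
        gid = raw["attributes"].str.extract(r"(?:ID|locus_tag)=([^;]+)")[0]
        genes = pd.DataFrame(
            {
                "gene_id": gid,
                "replicon": raw["seqid"],
                "start_bp": raw["start"].astype(int) - 1,
                "end_bp": raw["end"].astype(int),
                "strand": raw["strand"],
            }
        ).reset_index(drop=True)
    else:
        genes = pd.read_csv(path, sep="\t")
    return validate_genes(genes, layout)


def validate_degs(degs: pd.DataFrame) -> pd.DataFrame:
    for c in ("gene_id", "log2_fold_change", "adjusted_p", "direction"):
        if c not in degs.columns:
            raise ValidationError(f"DEG table missing column {c!r}")
    if ((degs["adjusted_p"] < 0) | (degs["adjusted_p"] > 1)).any():
        raise ValidationError("adjusted_p must lie in [0, 1]")
    sign_ok = np.where(degs["direction"] == "up", degs["log2_fold_change"] > 0,
                       degs["log2_fold_change"] < 0)
    if not sign_ok.all():
        bad = degs.loc[~sign_ok, "gene_id"].tolist()
        raise ValidationError(f"direction inconsistent with log2_fold_change sign: {bad[:5]}")
    return degs


def read_degs(path) -> pd.DataFrame:
    return validate_degs(pd.read_csv(path, sep="\t"))
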