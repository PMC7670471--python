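"""Contact-matrix I/O and the shared genome/bin coordinate system.

A whole-genome Hi-C contact map is stored as the upper triangle of a
symmetric sparse matrix over a global bin index.  The :class:`GenomeIndex`
maps between global bins, per-chromosome local bins and genomic base-pair
coordinates; every other module works in this frame.

Supported on-disk formats:

* single-resolution ``.cool`` (HDF5 with ``chroms``/``bins``/``pixels``
  tables, COO upper triangle) — read and write;
* plain-text sparse triplets (``bin1  bin2  count``) plus a two-column
  chromosome-sizes table;
* BED-like 2-D pair TSV for detections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeIndex",
    "ContactMatrix",
    "Coordinate2D",
    "read_cool",
    "write_cool",
    "read_sparse_text",
    "read_chromsizes",
    "write_detections",
    "read_detections",
]

DETECTION_COLUMNS = [
    "chrom1", "start1", "end1",
    "chrom2", "start2", "end2",
    "bin1", "bin2", "score",
]


@dataclass(frozen=True)
class GenomeIndex:
    """Bin coordinate system: chromosome names, lengths and a fixed bin size.

    Bins are 0-based; chromosome ``c`` occupies global bins
    ``[offset[c], offset[c] + n_bins(c))`` where ``n_bins = ceil(length / bin_size)``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths_bp: tuple[int, ...]
    bin_size_bp: int

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths_bp):
            raise ValueError("chrom_names and chrom_lengths_bp differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        if any(l <= 0 for l in self.chrom_lengths_bp):
            raise ValueError("chromosome lengths must be positive")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def chrom_n_bins(self) -> np.ndarray:
        return -(-np.asarray(self.chrom_lengths_bp, dtype=np.int64) // self.bin_size_bp)

    @property
    def chrom_bin_offsets(self) -> np.ndarray:
        """Cumulative bin offsets, length n_chroms + 1; offsets[-1] == n_bins."""
        return np.concatenate([[0], np.cumsum(self.chrom_n_bins)])

    @property
    def n_bins(self) -> int:
        return int(self.chrom_bin_offsets[-1])

    def chrom_id(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def extent(self, name: str) -> tuple[int, int]:
        """Global-bin half-open range [lo, hi) of a chromosome."""
        cid = self.chrom_id(name)
        off = self.chrom_bin_offsets
        return int(off[cid]), int(off[cid + 1])

    def to_local(self, global_bin: int | np.ndarray):
        """Map global bin -> (chrom id, local bin)."""
        off = self.chrom_bin_offsets
        b = np.asarray(global_bin)
        if np.any(b < 0) or np.any(b >= self.n_bins):
            raise IndexError("global bin out of range")
        cid = np.searchsorted(off, b, side="right") - 1
        return cid, b - off[cid]

    def to_global(self, chrom: str | int, local_bin: int | np.ndarray) -> np.ndarray:
        cid = chrom if isinstance(chrom, (int, np.integer)) else self.chrom_id(chrom)
        nb = self.chrom_n_bins[cid]
        lb = np.asarray(local_bin)
        if np.any(lb < 0) or np.any(lb >= nb):
            raise IndexError("local bin out of range")
        return self.chrom_bin_offsets[cid] + lb

    def bin_interval_bp(self, global_bin: int) -> tuple[str, int, int]:
        """Genomic half-open interval (chrom, start, end) of a global bin."""
        cid, lb = self.to_local(int(global_bin))
        start = int(lb) * self.bin_size_bp
        end = min(start + self.bin_size_bp, int(self.chrom_lengths_bp[int(cid)]))
        return self.chrom_names[int(cid)], start, end

    def bin_of(self, chrom: str, pos_bp: int) -> int:
        """Global bin containing a genomic position."""
        cid = self.chrom_id(chrom)
        if not 0 <= pos_bp < self.chrom_lengths_bp[cid] + self.bin_size_bp:
            if pos_bp < 0 or pos_bp >= self.chrom_lengths_bp[cid]:
                raise IndexError(f"position {pos_bp} outside {chrom}")
        lb = min(pos_bp // self.bin_size_bp, int(self.chrom_n_bins[cid]) - 1)
        return int(self.chrom_bin_offsets[cid] + lb)

    def bins_table(self) -> pd.DataFrame:
        """cool-style bin table (chrom, start, end), one row per global bin."""
        rows = []
        for cid, name in enumerate(self.chrom_names):
            n = int(self.chrom_n_bins[cid])
            starts = np.arange(n, dtype=np.int64) * self.bin_size_bp
            ends = np.minimum(starts + self.bin_size_bp, self.chrom_lengths_bp[cid])
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class ContactMatrix:
    """Genome-wide symmetric contact map, upper triangle stored sparsely.

    ``matrix`` is an n_bins x n_bins CSR holding only pixels with
    ``row <= col``; symmetric queries go through :meth:`block`.
    ``valid_bins`` marks bins that are covered well enough to be trusted
    ("white lines" on the map are invalid bins).
    """

    index: GenomeIndex
    matrix: sp.csr_matrix
    valid_bins: np.ndarray | None = None
    is_balanced: bool = False
    is_detrended: bool = False
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.index.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape disagrees with genome index")
        coo = self.matrix.tocoo()
        if np.any(coo.row > coo.col):
            raise ValueError("only the upper triangle may hold pixels")
        if not self.is_detrended:
            if coo.data.size and (not np.all(np.isfinite(coo.data)) or np.any(coo.data < 0)):
                raise ValueError("contact values must be finite and non-negative")
        if self.valid_bins is None:
            self.valid_bins = np.ones(n, dtype=bool)
        else:
            self.valid_bins = np.asarray(self.valid_bins, dtype=bool)
            if self.valid_bins.shape != (n,):
                raise ValueError("valid_bins has wrong length")
        self.matrix = self.matrix.tocsr()

    @property
    def n_bins(self) -> int:
        return self.index.n_bins

    @property
    def sum(self) -> float:
        return float(self.matrix.sum())

    def copy_with(self, **kw) -> "ContactMatrix":
        return replace(self, **kw)

    def block(self, chrom1: str, chrom2: str | None = None, dense: bool = False):
        """Sub-matrix of a chromosome pair with symmetric semantics.

        For an intra block the full symmetric square is returned (the stored
        upper triangle is mirrored).  For a trans pair the block is oriented
        (rows = chrom1, cols = chrom2) regardless of storage order.
        """
        chrom2 = chrom1 if chrom2 is None else chrom2
        lo1, hi1 = self.index.extent(chrom1)
        lo2, hi2 = self.index.extent(chrom2)
        if chrom1 == chrom2:
            b = self.matrix[lo1:hi1, lo1:hi1]
            upper = sp.triu(b, k=1)
            out = b + upper.T
        elif lo1 < lo2:
            out = self.matrix[lo1:hi1, lo2:hi2]
        else:
            out = self.matrix[lo2:hi2, lo1:hi1].T
        out = out.tocsr()
        return out.toarray() if dense else out

    def block_valid(self, chrom: str) -> np.ndarray:
        lo, hi = self.index.extent(chrom)
        return self.valid_bins[lo:hi]

    def query(self, i: int, j: int) -> float:
        """Symmetric pixel lookup by global bins."""
        if i > j:
            i, j = j, i
        return float(self.matrix[i, j])

    def mask_invalid(self) -> "ContactMatrix":
        """Drop all pixels on invalid-bin rows/columns (in place on a copy)."""
        coo = self.matrix.tocoo()
        keep = self.valid_bins[coo.row] & self.valid_bins[coo.col]
        m = sp.coo_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
        ).tocsr()
        return self.copy_with(matrix=m)


@dataclass(frozen=True)
class Coordinate2D:
    """A 2-D genomic coordinate pair (half-open intervals, BED convention)."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError("intervals must satisfy start < end")

    def bins(self, index: GenomeIndex) -> tuple[int, int]:
        """Global bin pair (i <= j) of the interval midpoints."""
        i = index.bin_of(self.chrom1, (self.start1 + self.end1) // 2)
        j = index.bin_of(self.chrom2, (self.start2 + self.end2) // 2)
        return (i, j) if i <= j else (j, i)

    @staticmethod
    def from_bins(index: GenomeIndex, bin1: int, bin2: int,
                  score: float | None = None) -> "Coordinate2D":
        c1, s1, e1 = index.bin_interval_bp(bin1)
        c2, s2, e2 = index.bin_interval_bp(bin2)
        return Coordinate2D(c1, s1, e1, c2, s2, e2, score)


# ---------------------------------------------------------------------------
# cool format (single resolution) on h5py

def write_cool(m: ContactMatrix, path: str | Path) -> None:
    """Write a single-resolution cool container (chroms/bins/pixels tables)."""
    idx = m.index
    bins = idx.bins_table()
    coo = sp.triu(m.matrix).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::Cooler"
        h5.attrs["bin-size"] = idx.bin_size_bp
        h5.attrs["bin-type"] = "fixed"
        h5.attrs["nbins"] = idx.n_bins
        h5.attrs["nchroms"] = idx.n_chroms
        h5.attrs["nnz"] = coo.nnz
        g = h5.create_group("chroms")
        g.create_dataset("name", data=np.array(idx.chrom_names, dtype="S64"))
        g.create_dataset("length", data=np.asarray(idx.chrom_lengths_bp, dtype=np.int64))
        g = h5.create_group("bins")
        cid = np.searchsorted(idx.chrom_bin_offsets, np.arange(idx.n_bins), side="right") - 1
        g.create_dataset("chrom", data=cid.astype(np.int32))
        g.create_dataset("start", data=bins["start"].to_numpy(np.int64))
        g.create_dataset("end", data=bins["end"].to_numpy(np.int64))
        if m.bias is not None:
            g.create_dataset("weight", data=np.asarray(m.bias, dtype=np.float64))
        g = h5.create_group("pixels")
        g.create_dataset("bin1_id", data=coo.row[order].astype(np.int64))
        g.create_dataset("bin2_id", data=coo.col[order].astype(np.int64))
        g.create_dataset("count", data=coo.data[order])
        g = h5.create_group("indexes")
        g.create_dataset(
            "bin1_offset",
            data=np.searchsorted(coo.row[order], np.arange(idx.n_bins + 1)).astype(np.int64),
        )


def read_cool(path: str | Path) -> ContactMatrix:
    """Read a single-resolution cool file into a :class:`ContactMatrix`.

    The bin table must have one uniform bin size (the last bin of each
    chromosome may be shorter).  Multi-resolution ``.mcool`` pyramids are
    rejected; open one resolution with an external tool first.
    """
    with h5py.File(path, "r") as h5:
        if "bins" not in h5 or "pixels" not in h5:
            if any(k in h5 for k in ("resolutions", "0")):
                raise ValueError(
                    "multi-resolution container; supply a single-resolution cool file"
                )
            raise ValueError("malformed cool container: missing bins/pixels tables")
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in h5["chroms/name"][:]]
        lengths = h5["chroms/length"][:].astype(int)
        starts = h5["bins/start"][:].astype(np.int64)
        ends = h5["bins/end"][:].astype(np.int64)
        widths = ends - starts
        # every bin but possibly the chromosome-terminal ones must share a size
        bin_size = int(widths.max()) if widths.size else 0
        chrom_ids = h5["bins/chrom"][:]
        if chrom_ids.dtype.kind in "SU":  # some writers store names, not ids
            name_to_id = {n: i for i, n in enumerate(names)}
            chrom_ids = np.array(
                [name_to_id[c.decode() if isinstance(c, bytes) else str(c)]
                 for c in chrom_ids]
            )
        last_bin = np.r_[chrom_ids[1:] != chrom_ids[:-1], True] if widths.size else []
        if widths.size and np.any(widths[~np.asarray(last_bin)] != bin_size):
            raise ValueError("heterogeneous bin sizes; a fixed-bin cool file is required")
        idx = GenomeIndex(tuple(names), tuple(int(l) for l in lengths), bin_size)
        if idx.n_bins != len(starts):
            raise ValueError("bin table inconsistent with chromosome lengths")
        r = h5["pixels/bin1_id"][:].astype(np.int64)
        c = h5["pixels/bin2_id"][:].astype(np.int64)
        v = h5["pixels/count"][:].astype(np.float64)
    lo = np.minimum(r, c)
    hi = np.maximum(r, c)
    mat = sp.coo_matrix((v, (lo, hi)), shape=(idx.n_bins, idx.n_bins)).tocsr()
    mat.sum_duplicates()
    return ContactMatrix(index=idx, matrix=mat)


# ---------------------------------------------------------------------------
# plain-text formats

def read_chromsizes(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["chrom", "length"])
    if (df["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    return df


def read_sparse_text(pixels_path: str | Path, chroms_path: str | Path,
                     bin_size_bp: int) -> ContactMatrix:
    """Read triplets ``bin1 <TAB> bin2 <TAB> count`` plus a chrom-sizes table.

    Bin indices are global; duplicate (i, j) rows are summed.
    """
    chroms = read_chromsizes(chroms_path)
    idx = GenomeIndex(tuple(chroms["chrom"].astype(str)),
                      tuple(int(l) for l in chroms["length"]), bin_size_bp)
    df = pd.read_csv(pixels_path, sep=r"\s+", header=None, comment="#",
                     names=["bin1", "bin2", "count"])
    if len(df) == 0:
        mat = sp.csr_matrix((idx.n_bins, idx.n_bins))
        return ContactMatrix(index=idx, matrix=mat)
    b1 = df["bin1"].to_numpy(np.int64)
    b2 = df["bin2"].to_numpy(np.int64)
    v = df["count"].to_numpy(np.float64)
    if np.any(v < 0):
        raise ValueError("negative contact count")
    if np.any((b1 < 0) | (b2 < 0) | (b1 >= idx.n_bins) | (b2 >= idx.n_bins)):
        raise ValueError("bin index out of range for the given chromosomes")
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    mat = sp.coo_matrix((v, (lo, hi)), shape=(idx.n_bins, idx.n_bins)).tocsr()
    mat.sum_duplicates()
    return ContactMatrix(index=idx, matrix=mat)


# ---------------------------------------------------------------------------
# detection tables

def write_detections(detections: Sequence, path: str | Path,
                     index: GenomeIndex | None = None) -> None:
    """Write detections as a BED-like 2-D pair TSV, deterministically ordered.

    Accepts :class:`Coordinate2D` rows (``index`` required to emit bin ids)
    or objects with ``coord``/``bin1``/``bin2``/``score`` attributes (the
    detect module's Detection).
    """
    rows = []
    for d in detections:
        if isinstance(d, Coordinate2D):
            if index is None:
                raise ValueError("index required to derive bin ids from coordinates")
            b1, b2 = d.bins(index)
            coord, score = d, d.score
        else:
            coord, b1, b2, score = d.coord, d.bin1, d.bin2, d.score
        rows.append((coord.chrom1, coord.start1, coord.end1,
                     coord.chrom2, coord.start2, coord.end2,
                     int(b1), int(b2),
                     float("nan") if score is None else float(score)))
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    df = df.sort_values(["chrom1", "bin1", "bin2"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_detections(path: str | Path) -> list[Coordinate2D]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        score = None if pd.isna(r["score"]) else float(r["score"])
        out.append(Coordinate2D(str(r["chrom1"]), int(r["start1"]), int(r["end1"]),
                                str(r["chrom2"]), int(r["start2"]), int(r["end2"]),
                                score))
    return out
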