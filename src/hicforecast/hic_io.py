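"""Hi-C input/output: valid read pairs, binned contact matrices, rescaling.

Supports the preprocessing route used for spatiotemporal Hi-C series:
parse HiC-Pro style ``allValidPairs`` text, keep long-range (> 20 kb)
intra-chromosomal pairs, optionally downsample to a common depth, bin into
a per-chromosome symmetric contact matrix at a fixed resolution (40 kb by
default), and rescale counts into [0, 1] with a per-dataset cap (maxHiC).
Matrices round-trip through two plain-text formats: dense rows and an
upper-triangle COO triplet listing.

Coordinates: pair files carry 1-based bp positions; matrices use 0-based,
half-open bins (bin k covers [k*res, (k+1)*res), bin = floor((pos-1)/res)).
No ICE/KR balancing is applied anywhere: the method operates on raw
downsampled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ValidPair",
    "ContactMatrix",
    "SpatioTemporalStack",
    "RescaleParams",
    "PairDialect",
    "read_valid_pairs",
    "filter_long_range_intra",
    "downsample_pairs",
    "bin_pairs",
    "choose_max_hic",
    "rescale",
    "write_matrix",
    "read_matrix",
    "read_cool",
]


@dataclass(frozen=True)
class ValidPair:
    """One mapped Hi-C read pair (1-based bp coordinates)."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int

    def __post_init__(self):
        if not self.chrom_a or not self.chrom_b:
            raise ValueError("chromosome names must be nonempty")
        if self.pos_a <= 0 or self.pos_b <= 0:
            raise ValueError("positions must be positive")

    @property
    def distance(self) -> int:
        """Genomic separation in bp; only meaningful intra-chromosomally."""
        return abs(self.pos_a - self.pos_b)

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b


class ContactMatrix:
    """A single chromosome's symmetric binned contact map.

    values[i, j] counts (or rescaled intensities of) contacts between bins
    i and j; symmetry and nonnegativity are enforced at construction.
    """

    def __init__(self, chrom: str, resolution: int, values):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"contact matrix must be square, got {values.shape}")
        if not np.allclose(values, values.T, rtol=0, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if (values < 0).any():
            raise ValueError("contact matrix entries must be nonnegative")
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.chrom = chrom
        self.resolution = int(resolution)
        self.values = values

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def __eq__(self, other):
        return (
            isinstance(other, ContactMatrix)
            and self.chrom == other.chrom
            and self.resolution == other.resolution
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self):
        return (
            f"ContactMatrix({self.chrom}, res={self.resolution}, "
            f"n_bins={self.n_bins}, total={self.values.sum():g})"
        )


class SpatioTemporalStack:
    """An ordered series of contact matrices on one shared bin grid."""

    def __init__(self, matrices: Sequence[ContactMatrix]):
        matrices = list(matrices)
        if not matrices:
            raise ValueError("stack needs at least one matrix")
        first = matrices[0]
        for m in matrices[1:]:
            if m.n_bins != first.n_bins or m.resolution != first.resolution:
                raise ValueError("all matrices in a stack must share the bin grid")
            if m.chrom != first.chrom:
                raise ValueError("all matrices in a stack must be on one chromosome")
        self.matrices = matrices

    @property
    def chrom(self) -> str:
        return self.matrices[0].chrom

    @property
    def resolution(self) -> int:
        return self.matrices[0].resolution

    @property
    def n_bins(self) -> int:
        return self.matrices[0].n_bins

    @property
    def n_steps(self) -> int:
        return len(self.matrices)

    def __len__(self):
        return len(self.matrices)

    def __getitem__(self, i) -> ContactMatrix:
        return self.matrices[i]

    def __iter__(self) -> Iterator[ContactMatrix]:
        return iter(self.matrices)

    def as_array(self) -> np.ndarray:
        """(T, n_bins, n_bins) array view of the series."""
        return np.stack([m.values for m in self.matrices])


@dataclass(frozen=True)
class RescaleParams:
    """Dataset-level cap used to map raw counts into [0, 1]."""

    max_hic: float

    def __post_init__(self):
        if self.max_hic <= 0:
            raise ValueError("max_hic must be positive")


@dataclass(frozen=True)
class PairDialect:
    """0-based column indices of the chrom/pos fields in a pair file.

    Default matches HiC-Pro allValidPairs:
    read_id  chrom_a  pos_a  strand_a  chrom_b  pos_b  strand_b  ...
    """

    chrom_a: int = 1
    pos_a: int = 2
    chrom_b: int = 4
    pos_b: int = 5


class PairFormatError(ValueError):
    """A malformed line in a valid-pairs file (reported with its number)."""


def read_valid_pairs(path, dialect: PairDialect = PairDialect()) -> Iterator[ValidPair]:
    """Stream ValidPair records from a whitespace-separated text file."""
    needed = max(dialect.chrom_a, dialect.pos_a, dialect.chrom_b, dialect.pos_b) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < needed:
                raise PairFormatError(
                    f"{path}:{lineno}: expected at least {needed} columns, got {len(fields)}"
                )
            try:
                pos_a = int(fields[dialect.pos_a])
                pos_b = int(fields[dialect.pos_b])
            except ValueError as exc:
                raise PairFormatError(f"{path}:{lineno}: non-numeric position") from exc
            yield ValidPair(fields[dialect.chrom_a], pos_a, fields[dialect.chrom_b], pos_b)


def filter_long_range_intra(
    pairs: Iterable[ValidPair], min_distance: int = 20000
) -> Iterator[ValidPair]:
    """Keep intra-chromosomal pairs separated by strictly more than min_distance bp."""
    for p in pairs:
        if p.is_intra and p.distance > min_distance:
            yield p


def downsample_pairs(pairs: Sequence[ValidPair], target: int, seed: int) -> list:
    """Uniform random subset of exactly ``target`` pairs, without replacement."""
    pairs = list(pairs)
    if target > len(pairs):
        raise ValueError(f"cannot downsample {len(pairs)} pairs to {target}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=target, replace=False)
    return [pairs[i] for i in idx]


def bin_pairs(
    pairs: Iterable[ValidPair], chrom: str, chrom_length: int, resolution: int = 40000
) -> ContactMatrix:
    """Aggregate pairs of one chromosome into a symmetric contact matrix.

    Each pair increments the symmetric cell pair once (the diagonal cell
    once when both mates fall in the same bin).  Pairs on other
    chromosomes are ignored; positions beyond chrom_length are skipped
    with a warning.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n_bins = ceil(chrom_length / resolution)
    counts = np.zeros((n_bins, n_bins))
    skipped = 0
    for p in pairs:
        if p.chrom_a != chrom or p.chrom_b != chrom:
            continue
        if p.pos_a > chrom_length or p.pos_b > chrom_length:
            skipped += 1
            continue
        ba = (p.pos_a - 1) // resolution
        bb = (p.pos_b - 1) // resolution
        counts[ba, bb] += 1
        if ba != bb:
            counts[bb, ba] += 1
    if skipped:
        warnings.warn(
            f"{chrom}: skipped {skipped} pairs with positions beyond {chrom_length} bp",
            stacklevel=2,
        )
    return ContactMatrix(chrom=chrom, resolution=resolution, values=counts)


def choose_max_hic(matrices: Iterable[ContactMatrix], quantile: float = 99.9) -> RescaleParams:
    """Depth-adaptive cap: a high percentile of nonzero entries pooled over matrices.

    The cap depends on the dataset's sequencing depth and matrix sizes
    through the pooled count distribution; with the default 99.9th
    percentile at most ~0.1% of nonzero entries are clipped.
    """
    pooled = np.concatenate([m.values[m.values > 0].ravel() for m in matrices])
    if pooled.size == 0:
        raise ValueError("cannot choose max_hic: all matrices are empty")
    return RescaleParams(max_hic=float(np.percentile(pooled, quantile)))


def rescale(matrix: ContactMatrix, params: RescaleParams) -> ContactMatrix:
    """Clip at max_hic and divide, mapping entries into [0, 1]."""
    values = np.minimum(matrix.values, params.max_hic) / params.max_hic
    return ContactMatrix(chrom=matrix.chrom, resolution=matrix.resolution, values=values)


class MatrixFormatError(ValueError):
    """Malformed or inconsistent matrix file."""


_HEADER = "# hicforecast chrom={chrom} resolution={res} n_bins={n} format={fmt}"


def write_matrix(matrix: ContactMatrix, path, format: str = "coo") -> None:
    """Write a matrix as 'coo' (upper-triangle triplets) or 'dense' text."""
    if format not in ("coo", "dense"):
        raise ValueError(f"unknown matrix format {format!r}")
    header = _HEADER.format(
        chrom=matrix.chrom, res=matrix.resolution, n=matrix.n_bins, fmt=format
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        if format == "dense":
            np.savetxt(fh, matrix.values, fmt="%.17g")
        else:
            i, j = np.nonzero(np.triu(matrix.values))
            for a, b in zip(i, j):
                fh.write(f"{a} {b} {matrix.values[a, b]:.17g}\n")


def _parse_header(line, path):
    try:
        fields = dict(tok.split("=", 1) for tok in line.lstrip("#").split() if "=" in tok)
        return fields["chrom"], int(fields["resolution"]), int(fields["n_bins"]), fields["format"]
    except (KeyError, ValueError) as exc:
        raise MatrixFormatError(f"{path}: bad or missing header line") from exc


def read_matrix(path) -> ContactMatrix:
    """Read a matrix written by :func:`write_matrix` (format auto-detected)."""
    with open(path) as fh:
        chrom, res, n_bins, fmt = _parse_header(fh.readline(), path)
        if fmt == "dense":
            values = np.loadtxt(fh, ndmin=2)
            if values.shape != (n_bins, n_bins):
                raise MatrixFormatError(
                    f"{path}: dense block is {values.shape}, header says {n_bins}x{n_bins}"
                )
            if not np.allclose(values, values.T, rtol=0, atol=1e-9):
                raise MatrixFormatError(f"{path}: dense matrix is not symmetric")
        elif fmt == "coo":
            values = np.zeros((n_bins, n_bins))
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                try:
                    a_s, b_s, v_s = line.split()
                    a, b, v = int(a_s), int(b_s), float(v_s)
                except ValueError as exc:
                    raise MatrixFormatError(f"{path}:{lineno}: bad triplet line") from exc
                if not (0 <= a <= b < n_bins):
                    raise MatrixFormatError(
                        f"{path}:{lineno}: bin pair ({a},{b}) outside upper triangle of {n_bins}"
                    )
                values[a, b] = v
                values[b, a] = v
        else:
            raise MatrixFormatError(f"{path}: unknown format {fmt!r}")
    return ContactMatrix(chrom=chrom, resolution=res, values=values)


def read_cool(path, chrom: str) -> ContactMatrix:
    """Read one chromosome from a single-resolution .cool file (needs h5py)."""
    try:
        import h5py
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("reading .cool files requires the optional h5py dependency") from exc
    with h5py.File(path, "r") as f:
        chroms = [c.decode() if isinstance(c, bytes) else c for c in f["chroms/name"][:]]
        if chrom not in chroms:
            raise KeyError(f"{chrom} not in {path} (has {chroms})")
        cid = chroms.index(chrom)
        bin_chrom = f["bins/chrom"][:]
        sel = np.nonzero(bin_chrom == cid)[0]
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        res = int(f.attrs["bin-size"])
        n = hi - lo
        values = np.zeros((n, n))
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
        mask = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        i, j, v = b1[mask] - lo, b2[mask] - lo, cnt[mask]
        values[i, j] = v
        values[j, i] = v
    return ContactMatrix(chrom=chrom, resolution=res, values=values)
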