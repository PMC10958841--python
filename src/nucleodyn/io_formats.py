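"""Readers and writers for the plain-text formats the pipeline consumes.

Genomic intervals travel as BED (0-based, half-open); contact matrices as
sparse coordinate text ("chromA binA chromB binB count") or, for toy inputs,
dense square tables; SMLM localization tables as delimited files with
ThunderSTORM-style headers; image stacks and cubes as TIFF or NPY rasters
with a JSON sidecar carrying the pixel size and third-axis grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A malformed record in an input file, reported with its line number."""


# --------------------------------------------------------------------------
# genomic intervals (BED)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, one_based: bool = False) -> list[GenomicInterval]:
    """Read BED3+ intervals, skipping track/browser/comment lines.

    Set ``one_based=True`` for tables using 1-based inclusive starts (e.g.
    gene tables exported from R); starts are shifted to the internal 0-based
    half-open convention at this boundary.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(repr(iv.score) if iv.score is not None else ".")
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` text."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom length'")
            sizes[fields[0]] = int(fields[1])
    return sizes


# --------------------------------------------------------------------------
# contact matrices
# --------------------------------------------------------------------------

@dataclass
class ContactMatrixFile:
    """Binned contact counts in upper-triangular COO form.

    For cis matrices ``chrom_a == chrom_b`` and every stored pair satisfies
    ``bin_i <= bin_j``. Counts may be non-integer: matrices arrive already
    balanced (e.g. KR) upstream.
    """

    chrom_a: str
    chrom_b: str
    resolution: int
    bin_i: np.ndarray
    bin_j: np.ndarray
    count: np.ndarray
    n_bins_a: int | None = None
    n_bins_b: int | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.bin_i = np.asarray(self.bin_i, dtype=np.int64)
        self.bin_j = np.asarray(self.bin_j, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=float)
        if np.any(self.count < 0):
            raise ValueError("contact counts must be non-negative")
        if self.is_cis and np.any(self.bin_i > self.bin_j):
            raise ValueError("cis storage must be upper-triangular (i <= j)")

    @property
    def is_cis(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def n_bins(self) -> int:
        if self.n_bins_a is not None:
            return self.n_bins_a
        if len(self.bin_i) == 0:
            return 0
        hi = int(self.bin_i.max())
        if len(self.bin_j):
            hi = max(hi, int(self.bin_j.max()))
        return hi + 1

    def to_dense(self) -> np.ndarray:
        """Dense matrix; cis matrices are symmetrized."""
        na = self.n_bins_a or self.n_bins
        nb = self.n_bins_b or (self.n_bins if self.is_cis else 0)
        if nb == 0 and len(self.bin_j):
            nb = int(self.bin_j.max()) + 1
        dense = np.zeros((na, nb))
        np.add.at(dense, (self.bin_i, self.bin_j), self.count)
        if self.is_cis:
            off = self.bin_i != self.bin_j
            np.add.at(dense, (self.bin_j[off], self.bin_i[off]), self.count[off])
        return dense

    @property
    def total(self) -> float:
        return float(self.count.sum())


def _dedupe_upper(bin_i, bin_j, count, mirrored: bool):
    """Fold entries to i <= j. A mirrored dialect stores both (i,j) and
    (j,i); keep one copy. An unmirrored dialect may carry genuine duplicate
    records; those are summed."""
    bin_i = np.asarray(bin_i, dtype=np.int64)
    bin_j = np.asarray(bin_j, dtype=np.int64)
    count = np.asarray(count, dtype=float)
    lo = np.minimum(bin_i, bin_j)
    hi = np.maximum(bin_i, bin_j)
    key = lo * (max(hi.max(initial=0), lo.max(initial=0)) + 1) + hi
    order = np.argsort(key, kind="stable")
    key, lo, hi, count = key[order], lo[order], hi[order], count[order]
    uniq, start = np.unique(key, return_index=True)
    if mirrored:
        # one representative per unordered pair
        return lo[start], hi[start], count[start]
    sums = np.add.reduceat(count, start) if len(count) else count
    return lo[start], hi[start], sums


def read_contact_matrix(
    path: str | Path,
    resolution: int,
    dialect: str = "upper",
    chrom_sizes: dict[str, int] | None = None,
) -> ContactMatrixFile:
    """Read sparse COO contact text, or a dense square table for toy inputs.

    COO records are ``chromA binA chromB binB count`` (tab/space/comma
    separated). ``dialect`` declares whether cis input stores both halves of
    each symmetric pair (``"mirrored"``) or only i <= j (``"upper"``,
    default). Dense tables (auto-detected by column count and absence of
    chromosome names) are taken as a single-chromosome cis matrix.
    """
    if dialect not in ("upper", "mirrored"):
        raise ValueError(f"unknown COO dialect {dialect!r}")
    rows: list[tuple[str, int, str, int, float]] = []
    dense_rows: list[list[float]] = []
    dense = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip().replace(",", "\t")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if dense is None:
                dense = len(fields) != 5 or _is_number(fields[0])
            if dense:
                try:
                    dense_rows.append([float(v) for v in fields])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric dense entry") from exc
            else:
                if len(fields) != 5:
                    raise ParseError(f"{path}:{lineno}: expected 5 COO fields")
                try:
                    rows.append((fields[0], int(fields[1]), fields[2],
                                 int(fields[3]), float(fields[4])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed COO record") from exc
                if rows[-1][4] < 0:
                    raise ParseError(f"{path}:{lineno}: negative count")
    if dense:
        mat = np.asarray(dense_rows, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ParseError(f"{path}: dense table must be square")
        iu, ju = np.triu_indices(mat.shape[0])
        keep = mat[iu, ju] != 0
        return ContactMatrixFile("chr?", "chr?", resolution,
                                 iu[keep], ju[keep], mat[iu, ju][keep],
                                 n_bins_a=mat.shape[0], n_bins_b=mat.shape[1])
    if not rows:
        raise ParseError(f"{path}: empty contact file")
    chroms = {(r[0], r[2]) for r in rows}
    if len(chroms) != 1:
        raise ParseError(f"{path}: multiple chromosome pairs in one file")
    ca, cb = chroms.pop()
    bi = np.array([r[1] for r in rows])
    bj = np.array([r[3] for r in rows])
    ct = np.array([r[4] for r in rows])
    na = nb = None
    if chrom_sizes is not None:
        for c, b in ((ca, bi), (cb, bj)):
            if c not in chrom_sizes:
                raise ParseError(f"{path}: unknown chromosome {c!r}")
            n = -(-chrom_sizes[c] // resolution)
            if b.max(initial=0) >= n:
                raise ParseError(f"{path}: bin index beyond {c} extent ({n} bins)")
        na = -(-chrom_sizes[ca] // resolution)
        nb = -(-chrom_sizes[cb] // resolution)
    if ca == cb:
        bi, bj, ct = _dedupe_upper(bi, bj, ct, mirrored=(dialect == "mirrored"))
    return ContactMatrixFile(ca, cb, resolution, bi, bj, ct,
                             n_bins_a=na, n_bins_b=nb)


def write_contact_matrix(matrix: ContactMatrixFile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, j, c in zip(matrix.bin_i, matrix.bin_j, matrix.count):
            fh.write(f"{matrix.chrom_a}\t{i}\t{matrix.chrom_b}\t{j}\t{c:g}\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


# --------------------------------------------------------------------------
# SMLM localization tables
# --------------------------------------------------------------------------

_X_HEADERS = ("x [nm]", "x[nm]", "x_nm", "x")
_Y_HEADERS = ("y [nm]", "y[nm]", "y_nm", "y")


@dataclass
class LocalizationTable:
    """Single-molecule localization events with coordinates in nm."""

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray | None = None
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if len(self.x) and (not np.all(np.isfinite(self.x))
                            or not np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if len(self.x) and (self.x.min() < 0 or self.y.min() < 0):
            raise ValueError("coordinates must be non-negative")

    def __len__(self) -> int:
        return len(self.x)


def read_localizations(path: str | Path) -> LocalizationTable:
    """Read a delimited localization table with headered x/y columns in nm."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    xcol = next((cols[h] for h in _X_HEADERS if h in cols), None)
    ycol = next((cols[h] for h in _Y_HEADERS if h in cols), None)
    if xcol is None or ycol is None:
        raise ParseError(
            f"{path}: missing x/y columns; accepted headers: "
            f"x: {_X_HEADERS}, y: {_Y_HEADERS}"
        )
    frame = df[cols["frame"]].to_numpy() if "frame" in cols else None
    inten = df[cols["intensity"]].to_numpy() if "intensity" in cols else None
    return LocalizationTable(df[xcol].to_numpy(float), df[ycol].to_numpy(float),
                             frame=frame, intensity=inten)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    data = {"x [nm]": table.x, "y [nm]": table.y}
    if table.frame is not None:
        data["frame"] = table.frame
    if table.intensity is not None:
        data["intensity"] = table.intensity
    pd.DataFrame(data).to_csv(path, index=False)


# --------------------------------------------------------------------------
# image stacks / cubes
# --------------------------------------------------------------------------

_AXIS_NAMES = ("wavelength", "time", "z")


@dataclass
class ImageStack:
    """A 2D raster or a 3D cube with a named third axis.

    3D data are laid out ``(axis, row, col)``. ``axis_values`` carries the
    wavelength grid in nm, the frame times in s, or the z positions in nm.
    """

    data: np.ndarray
    pixel_size_nm: float
    axis: str | None = None
    axis_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.data.ndim == 3:
            if self.axis not in _AXIS_NAMES:
                raise ValueError(f"3D stack needs axis in {_AXIS_NAMES}")
            if self.axis_values is None:
                raise ValueError("3D stack needs axis_values metadata")
            self.axis_values = np.asarray(self.axis_values, dtype=float)
            if len(self.axis_values) != self.data.shape[0]:
                raise ValueError("axis_values length must match data extent")
        elif self.data.ndim != 2:
            raise ValueError("data must be 2D or 3D")


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write NPY (``.npy``) or TIFF (``.tif``) plus a ``.json`` sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, stack.data)
    else:
        import tifffile

        tifffile.imwrite(path, stack.data.astype(np.float32))
    meta = {"pixel_size_nm": stack.pixel_size_nm, "axis": stack.axis}
    if stack.axis_values is not None:
        meta["axis_values"] = list(map(float, stack.axis_values))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_image_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        import tifffile

        data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    av = meta.get("axis_values")
    return ImageStack(data, meta["pixel_size_nm"], meta.get("axis"),
                      np.asarray(av) if av is not None else None)


# --------------------------------------------------------------------------
# shared interval helpers (sorted-array primitives used by several modules)
# --------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome; sorted output."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def overlap_bp(query: GenomicInterval, targets: Sequence[GenomicInterval]) -> int:
    """Total bp of ``query`` covered by (assumed merged) same-chrom targets."""
    total = 0
    for t in targets:
        if t.chrom != query.chrom:
            continue
        total += max(0, min(query.end, t.end) - max(query.start, t.start))
    return total
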