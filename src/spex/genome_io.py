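"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are 0-based, half-open. GTF input (1-based, closed)
is converted on read and never stored in its native convention.

Contact matrices follow the cooler schema: an HDF5 container with ``chroms``
(name, length), ``bins`` (chrom, start, end, optional ``weight``) and a
sparse upper-triangular ``pixels`` table (bin1_id, bin2_id, count).
Multi-resolution ``.mcool`` files keep one such group per resolution under
``/resolutions/<r>``. A 7-column whitespace-separated pixel list
(chrom1 start1 end1 chrom2 start2 end2 count) is accepted as a text dialect.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Gene",
    "ContactMatrix",
    "ExpressionTable",
    "load_genes",
    "load_contacts",
    "load_expression",
    "write_pixel_list",
    "write_cool",
    "cache_tensor",
    "load_cached_tensor",
]


@dataclass(frozen=True)
class Gene:
    """A gene anchored at its transcription start site.

    ``tss`` is a 0-based genomic coordinate; for a minus-strand BED record it
    is the last base of the half-open interval (end − 1).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")


class ContactMatrix:
    """Binned symmetric intra-chromosomal contact store at fixed resolution.

    Pixels are stored per chromosome as ``{(i, j): count}`` with ``i <= j``
    and bin indices local to the chromosome. ``count(chrom, i, j)`` is
    symmetric by construction. ``balanced`` records whether the stored counts
    were multiplied by the per-bin normalisation weights.
    """

    def __init__(self, resolution: int, chrom_sizes: dict[str, int], balanced: bool = False):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = int(resolution)
        self.chrom_sizes = dict(chrom_sizes)
        self.balanced = balanced
        self._pixels: dict[str, dict[tuple[int, int], float]] = {c: {} for c in chrom_sizes}

    def add_pixel(self, chrom: str, bin_i: int, bin_j: int, count: float) -> None:
        if not np.isfinite(count) or count < 0:
            raise ValueError(f"invalid count {count} at ({chrom}, {bin_i}, {bin_j})")
        if chrom not in self._pixels:
            self._pixels[chrom] = {}
            self.chrom_sizes.setdefault(chrom, 0)
        i, j = (bin_i, bin_j) if bin_i <= bin_j else (bin_j, bin_i)
        self._pixels[chrom][(i, j)] = self._pixels[chrom].get((i, j), 0.0) + float(count)

    def count(self, chrom: str, bin_i: int, bin_j: int) -> float:
        i, j = (bin_i, bin_j) if bin_i <= bin_j else (bin_j, bin_i)
        return self._pixels.get(chrom, {}).get((i, j), 0.0)

    def pixels(self, chrom: str):
        """Iterate (bin_i, bin_j, count) with bin_i <= bin_j for one chromosome."""
        if chrom not in self._pixels:
            raise KeyError(f"chromosome {chrom!r} not in contact matrix "
                           f"(available: {sorted(self._pixels)})")
        for (i, j), c in sorted(self._pixels[chrom].items()):
            yield i, j, c

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._pixels

    def bin_of(self, pos: int) -> int:
        return pos // self.resolution

    def bin_interval(self, chrom: str, bin_idx: int) -> tuple[int, int]:
        """Genomic interval of a bin, truncated at the chromosome end."""
        start = bin_idx * self.resolution
        end = start + self.resolution
        size = self.chrom_sizes.get(chrom)
        if size:
            end = min(end, size)
        return start, end

    def n_pixels(self) -> int:
        return sum(len(p) for p in self._pixels.values())


@dataclass
class ExpressionTable:
    """gene_id → expression on a linear, non-negative scale (RPKM-like)."""

    entries: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> float:
        return self.entries[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# gene annotations


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def load_genes(path: str, format: str | None = None) -> list[Gene]:
    """Load genes from BED6 or GTF, in file order.

    For GTF (1-based closed), the TSS of a ``+`` feature is ``start − 1`` and
    of a ``−`` feature is ``end − 1``, both 0-based. Records with an unknown
    strand are skipped with a warning; malformed lines raise with the line
    number. ``format`` defaults from the file extension.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".bed": "bed6", ".gtf": "gtf"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path!r}; pass format=")
    if format not in ("bed6", "gtf"):
        raise ValueError(f"unknown annotation format {format!r}")

    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "bed6":
                    if len(fields) < 6:
                        raise ValueError("expected 6 tab-separated fields")
                    chrom, start, end, name, _score, strand = fields[:6]
                    start_i, end_i = int(start), int(end)
                    if end_i <= start_i:
                        raise ValueError("end <= start")
                    if strand not in ("+", "-"):
                        import warnings

                        warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}, record skipped")
                        continue
                    tss = start_i if strand == "+" else end_i - 1
                    gene_id = name
                else:  # gtf
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated fields")
                    chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                    if feature not in ("gene", "transcript"):
                        continue
                    if strand not in ("+", "-"):
                        import warnings

                        warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}, record skipped")
                        continue
                    start_i, end_i = int(start), int(end)
                    tss = start_i - 1 if strand == "+" else end_i - 1
                    parsed = _parse_gtf_attributes(attrs)
                    gene_id = parsed.get("transcript_id") or parsed.get("gene_id")
                    if gene_id is None:
                        raise ValueError("no gene_id/transcript_id attribute")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from None
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(Gene(gene_id, chrom, tss, strand))
    return genes


# ---------------------------------------------------------------------------
# contact matrices


def load_contacts(
    path: str,
    resolution: int,
    chrom_sizes: dict[str, int] | None = None,
    raw_counts: bool = False,
) -> ContactMatrix:
    """Load a contact matrix from a cooler-schema file or a text pixel list.

    For multi-resolution files the requested ``resolution`` selects the
    ``/resolutions/<r>`` group; a missing resolution raises with the available
    ones listed. When the bins table carries a ``weight`` column, stored
    counts are balanced (raw × w_i × w_j; bins with NaN weight dropped) and
    the ``balanced`` flag is set — unless ``raw_counts`` forces raw values.
    Inter-chromosomal pixels are ignored: ChIA-PET loops are intra-chromosomal
    and the spatial selection never queries across chromosomes.
    """
    if _is_hdf5(path):
        return _load_cooler(path, resolution, raw_counts)
    return _load_pixel_list(path, resolution, chrom_sizes)


def _is_hdf5(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(8) == b"\x89HDF\r\n\x1a\n"


def _load_cooler(path: str, resolution: int, raw_counts: bool) -> ContactMatrix:
    with h5py.File(path, "r") as f:
        if "resolutions" in f:
            key = str(int(resolution))
            if key not in f["resolutions"]:
                avail = sorted(int(k) for k in f["resolutions"])
                raise ValueError(
                    f"resolution {resolution} not in {path!r}; available: {avail}"
                )
            grp = f["resolutions"][key]
        elif "bins" in f and "pixels" in f:
            grp = f
        else:
            raise ValueError(f"{path!r} does not follow the cooler schema")

        chrom_names = [c.decode() if isinstance(c, bytes) else str(c) for c in grp["chroms/name"][:]]
        chrom_lengths = grp["chroms/length"][:].astype(int)
        chrom_sizes = dict(zip(chrom_names, chrom_lengths))

        bin_chrom = grp["bins/chrom"][:]
        bin_start = grp["bins/start"][:].astype(int)
        bin_end = grp["bins/end"][:].astype(int)
        # infer/verify resolution from the bins table
        widths = bin_end - bin_start
        res = int(np.max(widths)) if len(widths) else resolution
        if res != resolution:
            raise ValueError(
                f"{path!r} stores resolution {res}, not the requested {resolution}"
            )

        weights = None
        if not raw_counts and "weight" in grp["bins"]:
            weights = grp["bins/weight"][:].astype(float)

        cm = ContactMatrix(resolution, chrom_sizes, balanced=weights is not None)

        bin1 = grp["pixels/bin1_id"][:].astype(int)
        bin2 = grp["pixels/bin2_id"][:].astype(int)
        count = grp["pixels/count"][:].astype(float)

    # bins/chrom may be an int enum (cooler convention) or byte strings
    if bin_chrom.dtype.kind in "iu":
        chrom_of_bin = np.asarray(chrom_names, dtype=object)[bin_chrom]
    else:
        chrom_of_bin = np.array(
            [c.decode() if isinstance(c, bytes) else str(c) for c in bin_chrom], dtype=object
        )

    local_idx = bin_start // resolution
    for b1, b2, c in zip(bin1, bin2, count):
        if chrom_of_bin[b1] != chrom_of_bin[b2]:
            continue
        if weights is not None:
            w = weights[b1] * weights[b2]
            if not np.isfinite(w):
                continue
            c = c * w
        cm.add_pixel(chrom_of_bin[b1], int(local_idx[b1]), int(local_idx[b2]), float(c))
    return cm


def _load_pixel_list(
    path: str, resolution: int, chrom_sizes: dict[str, int] | None
) -> ContactMatrix:
    sizes: dict[str, int] = dict(chrom_sizes or {})
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            c1, s1, e1, c2, s2, e2, cnt = fields
            try:
                s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
                cnt = float(cnt)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparsable coordinates/count") from None
            if cnt < 0:
                raise ValueError(f"{path}:{lineno}: negative count {cnt}")
            rows.append((c1, s1, e1, c2, s2, e2, cnt))
            for c, e in ((c1, e1), (c2, e2)):
                sizes[c] = max(sizes.get(c, 0), e)
    cm = ContactMatrix(resolution, sizes)
    for c1, s1, _e1, c2, s2, _e2, cnt in rows:
        if c1 != c2:
            continue
        cm.add_pixel(c1, s1 // resolution, s2 // resolution, cnt)
    return cm


def write_pixel_list(cm: ContactMatrix, path: str) -> None:
    """Write the matrix as the 7-column text pixel list (upper triangle)."""
    res = cm.resolution
    with open(path, "w") as fh:
        for chrom in sorted(cm.chrom_sizes):
            if not cm.has_chrom(chrom):
                continue
            for i, j, c in cm.pixels(chrom):
                s1, e1 = cm.bin_interval(chrom, i)
                s2, e2 = cm.bin_interval(chrom, j)
                fh.write(f"{chrom}\t{s1}\t{e1}\t{chrom}\t{s2}\t{e2}\t{c:.8g}\n")


def write_cool(
    cm: ContactMatrix,
    path: str,
    weights: dict[str, np.ndarray] | None = None,
    mcool: bool = False,
) -> None:
    """Write a single-resolution cooler-schema HDF5 file.

    ``weights`` optionally supplies per-chromosome balancing weight vectors
    (one value per bin) to store in the bins table; counts are stored raw, as
    the cooler schema prescribes. With ``mcool`` the tables go under
    ``/resolutions/<resolution>``.
    """
    res = cm.resolution
    chroms = sorted(cm.chrom_sizes)
    n_bins_per = {c: -(-cm.chrom_sizes[c] // res) for c in chroms}
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += n_bins_per[c]
    total_bins = off

    bchrom = np.empty(total_bins, dtype=np.int32)
    bstart = np.empty(total_bins, dtype=np.int64)
    bend = np.empty(total_bins, dtype=np.int64)
    wcol = np.full(total_bins, np.nan) if weights is not None else None
    for ci, c in enumerate(chroms):
        n = n_bins_per[c]
        sl = slice(offsets[c], offsets[c] + n)
        bchrom[sl] = ci
        starts = np.arange(n, dtype=np.int64) * res
        bstart[sl] = starts
        bend[sl] = np.minimum(starts + res, cm.chrom_sizes[c])
        if wcol is not None and c in weights:
            w = np.asarray(weights[c], dtype=float)
            if len(w) != n:
                raise ValueError(f"weights for {c} have length {len(w)}, expected {n}")
            wcol[sl] = w

    p1, p2, pc = [], [], []
    for c in chroms:
        for i, j, cnt in cm.pixels(c):
            p1.append(offsets[c] + i)
            p2.append(offsets[c] + j)
            pc.append(cnt)
    order = np.lexsort((np.asarray(p2), np.asarray(p1))) if p1 else np.array([], dtype=int)

    with h5py.File(path, "w") as f:
        grp = f.create_group(f"resolutions/{res}") if mcool else f
        grp.create_dataset("chroms/name", data=np.array([c.encode() for c in chroms]))
        grp.create_dataset("chroms/length", data=np.array([cm.chrom_sizes[c] for c in chroms]))
        grp.create_dataset("bins/chrom", data=bchrom)
        grp.create_dataset("bins/start", data=bstart)
        grp.create_dataset("bins/end", data=bend)
        if wcol is not None:
            grp.create_dataset("bins/weight", data=wcol)
        grp.create_dataset("pixels/bin1_id", data=np.asarray(p1, dtype=np.int64)[order])
        grp.create_dataset("pixels/bin2_id", data=np.asarray(p2, dtype=np.int64)[order])
        grp.create_dataset("pixels/count", data=np.asarray(pc, dtype=float)[order])
        grp.attrs["bin-size"] = res


# ---------------------------------------------------------------------------
# expression


def load_expression(path: str) -> ExpressionTable:
    """Read a two-column gene_id/value TSV; a ``gene_id``-style header row is allowed."""
    entries: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gid, val = fields[0], fields[1]
            if lineno == 1 and gid.lower() in ("gene_id", "gene", "id"):
                continue
            try:
                value = float(val)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparsable value {val!r}") from None
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative expression {value}")
            if gid in entries:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            entries[gid] = value
    return ExpressionTable(entries)


def write_expression(table: ExpressionTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for gid, val in table.entries.items():
            fh.write(f"{gid}\t{val:.8g}\n")


# ---------------------------------------------------------------------------
# tensor cache: flat binary float64 row-major + JSON sidecar


def cache_tensor(gene_id: str, tensor: np.ndarray, path: str, build_params: dict | None = None) -> None:
    """Save a tensor as raw row-major float64 with a JSON metadata sidecar.

    The sidecar records F (rows), the column count (10 baseline / 11 spatial),
    the flattening order and any build parameters, so a later load can verify
    shape instead of trusting the file name.
    """
    arr = np.ascontiguousarray(tensor, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("tensor must be 2-D (F × C)")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{gene_id}: tensor contains non-finite values")
    arr.tofile(path)
    meta = {
        "gene_id": gene_id,
        "F": int(arr.shape[0]),
        "columns": int(arr.shape[1]),
        "spatial": bool(arr.shape[1] == 11),
        "dtype": "float64",
        "order": "row-major (feature-major)",
        "build_params": build_params or {},
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_cached_tensor(path: str) -> tuple[str, np.ndarray, dict]:
    """Load a cached tensor; raises if the sidecar shape disagrees with the file."""
    with open(path + ".json") as fh:
        meta = json.load(fh)
    arr = np.fromfile(path, dtype=np.float64)
    expected = meta["F"] * meta["columns"]
    if arr.size != expected:
        raise ValueError(
            f"{path}: file holds {arr.size} values but sidecar declares "
            f"{meta['F']}×{meta['columns']}={expected}"
        )
    return meta["gene_id"], arr.reshape(meta["F"], meta["columns"]), meta
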