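"""Hi-C contact pairs and low-input library QC statistics.

Contacts are stored canonically (upper triangle under lexicographic
(reference name, position) order) in a pandas frame, which makes exact
deduplication and window counting vectorized. The depth track is a
run-length-encoded per-base coverage profile read from BEDGRAPH produced
with ``bedtools genomecov -bga`` (explicit zero-depth runs).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterator, Mapping, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "ContactPair",
    "ContactSet",
    "DepthTrack",
    "LibraryStats",
    "PairsParseError",
    "read_pairs",
    "write_pairs",
    "deduplicate",
    "bin_contacts",
    "read_bedgraph",
    "depth_stats",
    "predicted_coverage",
]

_COLUMNS = ["ref1", "pos1", "strand1", "ref2", "pos2", "strand2"]


class PairsParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"pairs line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class ContactPair:
    ref1: str
    pos1: int
    strand1: str
    ref2: str
    pos2: int
    strand2: str


@dataclass
class LibraryStats:
    """Summary statistics of a sequencing library.

    Deduplication fills the pair-count fields; depth_stats fills the depth
    fields. duplication_rate = 1 - n_unique/n_pairs; dispersion = var/mean
    (1 in expectation for Poisson-uniform sampling).
    """

    n_pairs: int | None = None
    n_unique: int | None = None
    duplication_rate: float | None = None
    depth_mean: float | None = None
    depth_variance: float | None = None
    dispersion_index: float | None = None


class ContactSet:
    """Deduplicatable collection of mapped contact-pair endpoints."""

    def __init__(self, df: pd.DataFrame, references: Mapping[str, int]):
        self.references = dict(references)
        self.df = _canonicalize(df.reset_index(drop=True))
        self._validate()

    @classmethod
    def from_records(cls, records, references: Mapping[str, int]) -> "ContactSet":
        df = pd.DataFrame(list(records), columns=_COLUMNS)
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=(int if c in ("pos1", "pos2") else str))
                               for c in _COLUMNS})
        return cls(df, references)

    def _validate(self) -> None:
        for side in ("1", "2"):
            refs = self.df[f"ref{side}"]
            unknown = set(refs.unique()) - set(self.references)
            if unknown:
                raise ValueError(f"unknown references in contacts: {sorted(unknown)}")
            if len(self.df):
                lens = refs.map(self.references).to_numpy()
                pos = self.df[f"pos{side}"].to_numpy()
                if (pos < 0).any() or (pos >= lens).any():
                    raise ValueError("contact position outside reference bounds")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[ContactPair]:
        for row in self.df.itertuples(index=False):
            yield ContactPair(*row)


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Swap endpoints (with their strands) so (ref1,pos1) <= (ref2,pos2)."""
    if df.empty:
        return df
    r1, r2 = df["ref1"].to_numpy(), df["ref2"].to_numpy()
    p1, p2 = df["pos1"].to_numpy(), df["pos2"].to_numpy()
    swap = (r1 > r2) | ((r1 == r2) & (p1 > p2))
    if swap.any():
        df = df.copy()
        for a, b in (("ref1", "ref2"), ("pos1", "pos2"), ("strand1", "strand2")):
            va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
            df.loc[swap, a] = vb[swap]
            df.loc[swap, b] = va[swap]
    return df


def read_pairs(source: TextIO | str, references: Mapping[str, int]) -> ContactSet:
    """Read 4DN ``.pairs`` text (7+ columns, 1-based positions) or headerless
    6-column TSV (``ref1 pos1 ref2 pos2 strand1 strand2``, 0-based).

    Header lines start with ``#``. Malformed records raise
    :class:`PairsParseError` with the line number.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    records = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 7:
            _, c1, p1, c2, p2, s1, s2 = cols[:7]
            offset = 1
        elif len(cols) == 6:
            c1, p1, c2, p2, s1, s2 = cols
            offset = 0
        else:
            raise PairsParseError(f"expected 6 or >=7 columns, got {len(cols)}", lineno)
        try:
            pos1, pos2 = int(p1) - offset, int(p2) - offset
        except ValueError:
            raise PairsParseError("non-numeric position", lineno)
        for ref, pos in ((c1, pos1), (c2, pos2)):
            if ref not in references:
                raise PairsParseError(f"unknown reference {ref!r}", lineno)
            if not 0 <= pos < references[ref]:
                raise PairsParseError(
                    f"position {pos} outside {ref} (length {references[ref]})", lineno
                )
        if s1 not in "+-" or s2 not in "+-":
            raise PairsParseError("strand must be + or -", lineno)
        records.append((c1, pos1, s1, c2, pos2, s2))
    return ContactSet.from_records(records, references)


def write_pairs(contacts: ContactSet, stream: TextIO) -> None:
    """Write the 4DN ``.pairs`` text dialect (1-based positions)."""
    stream.write("## pairs format v1.0\n")
    for name, length in contacts.references.items():
        stream.write(f"#chromsize: {name} {length}\n")
    stream.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
    for i, row in enumerate(contacts.df.itertuples(index=False)):
        stream.write(
            f"r{i}\t{row.ref1}\t{row.pos1 + 1}\t{row.ref2}\t{row.pos2 + 1}"
            f"\t{row.strand1}\t{row.strand2}\n"
        )


def deduplicate(contacts: ContactSet) -> tuple[ContactSet, LibraryStats]:
    """Collapse exact positional duplicates (both endpoints and strands).

    Returns the unique set and stats with duplication_rate = removed/total
    (0 for an empty set).
    """
    n = len(contacts)
    unique = contacts.df.drop_duplicates(subset=_COLUMNS, ignore_index=True)
    n_unique = len(unique)
    rate = 0.0 if n == 0 else 1.0 - n_unique / n
    stats = LibraryStats(n_pairs=n, n_unique=n_unique, duplication_rate=rate)
    out = ContactSet(unique, contacts.references)
    return out, stats


def bin_contacts(
    contacts: ContactSet, binsize: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Aggregate contacts into a symmetric count matrix over fixed-size bins.

    Bins are concatenated across references in the order of the reference
    map. Each pair increments (i,j) and (j,i) off-diagonal and the diagonal
    once, so off-diagonal total / 2 + diagonal total = number of pairs.
    Returns (matrix, bin table with columns ref/start/end).
    """
    if binsize < 1:
        raise ValueError("binsize must be >= 1")
    offsets: dict[str, int] = {}
    bins = []
    total = 0
    for name, length in contacts.references.items():
        offsets[name] = total
        n_bins = -(-length // binsize)
        for b in range(n_bins):
            bins.append((name, b * binsize, min((b + 1) * binsize, length)))
        total += n_bins
    mat = np.zeros((total, total), dtype=np.int64)
    if len(contacts):
        df = contacts.df
        i = (df["ref1"].map(offsets).to_numpy() + df["pos1"].to_numpy() // binsize)
        j = (df["ref2"].map(offsets).to_numpy() + df["pos2"].to_numpy() // binsize)
        np.add.at(mat, (i, j), 1)
        off = mat - np.diag(np.diag(mat))
        mat = mat + off.T
    return mat, pd.DataFrame(bins, columns=["ref", "start", "end"])


# ---------------------------------------------------------------------------
# Depth track


class DepthTrack:
    """Run-length-encoded per-base depth covering each reference exactly once."""

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # runs: ref -> (starts, ends, depths), tiling [0, ref length) in order
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if not runs:
            raise ValueError("a depth track needs at least one reference")
        for ref, (starts, ends, depths) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            depths = np.asarray(depths, dtype=np.int64)
            if len(starts) == 0:
                raise ValueError(f"empty run list for {ref}")
            if starts[0] != 0 or (ends[:-1] != starts[1:]).any() or (ends <= starts).any():
                raise ValueError(f"runs for {ref} do not tile the reference")
            if (depths < 0).any():
                raise ValueError("negative depth")
            self._runs[ref] = (starts, ends, depths)
            lens = ends - starts
            # prefix sums of depth*bases and covered (depth>=1) bases
            self._cum[ref] = (
                np.concatenate(([0], np.cumsum(depths * lens))),
                np.concatenate(([0], np.cumsum((depths >= 1) * lens))),
            )

    @classmethod
    def from_runs(cls, runs) -> "DepthTrack":
        """Build from an iterable of (ref, start, end, depth) rows."""
        per: dict[str, list[tuple[int, int, int]]] = {}
        for ref, start, end, depth in runs:
            per.setdefault(ref, []).append((int(start), int(end), int(depth)))
        packed = {}
        for ref, rows in per.items():
            rows.sort()
            arr = np.asarray(rows, dtype=np.int64)
            packed[ref] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(packed)

    @property
    def references(self) -> dict[str, int]:
        return {ref: int(ends[-1]) for ref, (_, ends, _) in self._runs.items()}

    def runs(self, ref: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs[ref]

    def total_bases(self) -> int:
        return sum(self.references.values())

    def _partial(self, ref: str, pos: int, which: int) -> float:
        """Prefix aggregate over [0, pos): which=0 depth sum, 1 covered bases."""
        starts, ends, depths = self._runs[ref]
        cum = self._cum[ref][which]
        i = int(np.searchsorted(ends, pos, side="right"))
        if i >= len(starts):
            return float(cum[-1])
        full = float(cum[i])
        if pos > starts[i]:
            extra = pos - starts[i]
            unit = depths[i] if which == 0 else int(depths[i] >= 1)
            full += float(unit) * extra
        return full

    def interval_depth_sum(self, ref: str, start: int, end: int) -> float:
        return self._partial(ref, end, 0) - self._partial(ref, start, 0)

    def interval_covered(self, ref: str, start: int, end: int) -> int:
        return int(self._partial(ref, end, 1) - self._partial(ref, start, 1))


def read_bedgraph(source: TextIO | str) -> DepthTrack:
    """Read a ``bedtools genomecov -bga`` BEDGRAPH (zero runs explicit).

    Intervals must tile every reference from 0 without holes or overlaps.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    rows = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ValueError(f"bedgraph line {lineno}: expected 4 columns")
        try:
            rows.append((cols[0], int(cols[1]), int(cols[2]), int(cols[3])))
        except ValueError:
            raise ValueError(f"bedgraph line {lineno}: non-integer coordinates/depth")
    return DepthTrack.from_runs(rows)


def write_bedgraph(track: DepthTrack, stream: TextIO) -> None:
    for ref in track.references:
        starts, ends, depths = track.runs(ref)
        for s, e, d in zip(starts, ends, depths):
            stream.write(f"{ref}\t{s}\t{e}\t{d}\n")


def depth_stats(track: DepthTrack) -> LibraryStats:
    """Base-weighted mean, population variance, and dispersion index of depth."""
    total = 0
    sum_d = 0.0
    sum_d2 = 0.0
    for ref in track.references:
        starts, ends, depths = track.runs(ref)
        lens = (ends - starts).astype(float)
        d = depths.astype(float)
        total += int(lens.sum())
        sum_d += float((d * lens).sum())
        sum_d2 += float((d * d * lens).sum())
    if total == 0:
        raise ValueError("zero-length depth track")
    mean = sum_d / total
    var = sum_d2 / total - mean * mean
    disp = var / mean if mean > 0 else float("nan")
    return LibraryStats(depth_mean=mean, depth_variance=var, dispersion_index=disp)


def predicted_coverage(
    n_reads: int, read_length: float, genome_size: float, paired: bool = False
) -> float:
    """Expected fold coverage: reads x read length (x2 if paired) / genome size.

    Returned unrounded; display layers round to an integer fold.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if n_reads < 0 or read_length < 0:
        raise ValueError("read counts and lengths must be non-negative")
    return n_reads * read_length * (2 if paired else 1) / genome_size
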