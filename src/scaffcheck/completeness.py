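"""Assembly completeness by annotation class.

Given a per-base depth track derived from aligning an assembly to an
annotated reference (e.g. minimap2 + ``bedtools genomecov -bga``) and the
reference's GFF3 annotation, score each annotated span base by base and
report, per feature type, the percent of elements with at least a threshold
fraction of their sequence captured (depth >= 1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .pairs import DepthTrack

__all__ = [
    "Feature",
    "FeatureCoverage",
    "Gff3ParseError",
    "read_gff3",
    "write_gff3",
    "feature_coverage",
    "completeness_report",
    "coverage_bimodality",
]


class Gff3ParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"GFF3 line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Feature:
    """An annotated span: 0-based half-open interval with a type label."""

    ref: str
    start: int
    end: int
    strand: str
    type: str
    identifier: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature interval [{self.start},{self.end})")
        if not self.type:
            raise ValueError("feature type label must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureCoverage:
    feature: Feature
    covered_fraction: float  # fraction of bases with depth >= 1
    mean_depth: float


def read_gff3(source: TextIO | str) -> list[Feature]:
    """Parse GFF3 (1-based inclusive, converted on read).

    Type comes from column 3; the ``ID`` attribute (fallback: positional
    index) is the identifier. Comment/directive lines are skipped; an
    embedded ``##FASTA`` section ends parsing.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    features: list[Feature] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if line.startswith("##FASTA"):
            break
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise Gff3ParseError(f"expected 9 columns, got {len(cols)}", lineno)
        ref, _, ftype, start_s, end_s, _, strand, _, attrs = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise Gff3ParseError("non-integer coordinates", lineno)
        if start < 1 or end < start:
            raise Gff3ParseError(f"bad coordinates {start}-{end}", lineno)
        ident = f"feature{len(features) + 1}"
        for kv in attrs.split(";"):
            if kv.startswith("ID="):
                ident = kv[3:]
                break
        try:
            features.append(Feature(ref, start - 1, end, strand, ftype, ident))
        except ValueError as exc:
            raise Gff3ParseError(str(exc), lineno)
    return features


def write_gff3(features: Iterable[Feature], stream: TextIO, source: str = "scaffcheck") -> None:
    stream.write("##gff-version 3\n")
    for f in features:
        stream.write(
            f"{f.ref}\t{source}\t{f.type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
            f"ID={f.identifier}\n"
        )


def feature_coverage(track: DepthTrack, features: Iterable[Feature]) -> list[FeatureCoverage]:
    """Per-feature covered fraction (depth >= 1) and mean depth, base by base."""
    refs = track.references
    out = []
    for f in features:
        if f.ref not in refs:
            raise ValueError(f"feature {f.identifier} on reference {f.ref!r} absent from track")
        if f.end > refs[f.ref]:
            raise ValueError(f"feature {f.identifier} extends beyond {f.ref}")
        covered = track.interval_covered(f.ref, f.start, f.end)
        depth_sum = track.interval_depth_sum(f.ref, f.start, f.end)
        out.append(FeatureCoverage(f, covered / f.length, depth_sum / f.length))
    return out


def completeness_report(
    coverages: Iterable[FeatureCoverage], tau: float = 0.90
) -> pd.DataFrame:
    """Per-type completeness table.

    Columns: type, n, pct_captured_ge_tau (percent of elements with
    covered_fraction >= tau), mean_mean_depth, median_mean_depth. Empty
    input yields an empty frame.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    rows = [
        (c.feature.type, c.covered_fraction, c.mean_depth) for c in coverages
    ]
    cols = ["type", "n", "pct_captured_ge_tau", "mean_mean_depth", "median_mean_depth"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=["type", "covered_fraction", "mean_depth"])
    grouped = df.groupby("type", sort=True)
    out = pd.DataFrame(
        {
            "type": list(grouped.groups),
            "n": grouped.size().to_numpy(),
            "pct_captured_ge_tau": grouped["covered_fraction"]
            .apply(lambda s: 100.0 * float((s >= tau).mean()))
            .to_numpy(),
            "mean_mean_depth": grouped["mean_depth"].mean().to_numpy(),
            "median_mean_depth": grouped["mean_depth"].median().to_numpy(),
        }
    )
    out.attrs["tau"] = tau
    return out


def coverage_bimodality(
    coverages: Iterable[FeatureCoverage],
) -> tuple[np.ndarray, float]:
    """10-bin histogram of covered fractions plus the fraction of elements at
    the extremes (covered_fraction <= 0.1 or >= 0.9).

    Real assembly-capture distributions are typically bimodal: elements are
    either captured by a single assembled contig or missing entirely.
    """
    fracs = np.array([c.covered_fraction for c in coverages], dtype=float)
    if fracs.size == 0:
        raise ValueError("no coverages supplied")
    hist, _ = np.histogram(fracs, bins=np.linspace(0.0, 1.0, 11))
    extreme = float(np.mean((fracs <= 0.1) | (fracs >= 0.9)))
    return hist, extreme
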