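"""Diploid phasing evaluation for an F1 individual with known parents.

An F1 hybrid of two sequenced strains is heterozygous exactly where its
parents differ, so every heterozygous site can be polarized: one allele
assigned to parent A, the other to parent B. Against that truth, a phased
block's haplotype assignments are scored under the standard switch/mismatch
decomposition: a mismatch (flip) is a single variant phased incorrectly in
an otherwise correct neighborhood; a switch is a change-point after which at
least two consecutive variants are phased incorrectly relative to the
preceding sites. Each block is evaluated under the better of its two global
orientations, since block orientation is arbitrary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np

__all__ = [
    "HetSite",
    "TruthPhase",
    "PhasedSite",
    "PhasedBlock",
    "PhaseErrorReport",
    "depth_filter",
    "polarize_from_truth",
    "polarize_paf",
    "evaluate_phase",
    "block_stats",
    "join_switch_fraction",
    "read_phased_vcf",
    "read_paf",
]


@dataclass(frozen=True)
class HetSite:
    ref: str
    pos: int
    alleles: tuple[str, str]
    depth: int = 0
    variant_class: str = "SNP"  # or "indel"

    def __post_init__(self) -> None:
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"het site {self.ref}:{self.pos} alleles not distinct")
        if self.depth < 0:
            raise ValueError("negative depth")


class TruthPhase:
    """Per-site parental allele assignment: (ref, pos) -> (alleleA, alleleB)."""

    def __init__(self, assignments: Mapping[tuple[str, int], tuple[str, str]]):
        self._map = dict(assignments)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, key) -> bool:
        return key in self._map

    def get(self, ref: str, pos: int) -> tuple[str, str] | None:
        return self._map.get((ref, pos))

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, source: TextIO | str) -> "TruthPhase":
        """Columns: ref, pos (0-based), alleleA, alleleB."""
        if isinstance(source, str):
            source = io.StringIO(source)
        out = {}
        for raw in source:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ref, pos, a, b = line.split("\t")[:4]
            out[(ref, int(pos))] = (a, b)
        return cls(out)

    def to_tsv(self, stream: TextIO) -> None:
        for (ref, pos), (a, b) in sorted(self._map.items()):
            stream.write(f"{ref}\t{pos}\t{a}\t{b}\n")


@dataclass(frozen=True)
class PhasedSite:
    ref: str
    pos: int
    hap0: str  # allele assigned to haplotype 0
    hap1: str


@dataclass
class PhasedBlock:
    """A phase set: sites whose assignments are internally consistent."""

    block_id: str
    sites: list[PhasedSite]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a phased block needs at least one site")
        if any(b.pos < a.pos for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError(f"block {self.block_id} sites not position-sorted")

    @property
    def span(self) -> int:
        return self.sites[-1].pos - self.sites[0].pos


@dataclass
class PhaseErrorReport:
    n_sites: int
    n_switch: int
    n_mismatch: int
    n_blocks: int
    n_excluded: int  # sites lacking a usable truth label
    mean_block_len: float
    mean_block_span: float
    largest_block_fraction: float

    @property
    def switch_rate(self) -> float:
        return self.n_switch / self.n_sites if self.n_sites else 0.0

    @property
    def mismatch_rate(self) -> float:
        return self.n_mismatch / self.n_sites if self.n_sites else 0.0

    @property
    def combined_rate(self) -> float:
        return (self.n_switch + self.n_mismatch) / self.n_sites if self.n_sites else 0.0


def depth_filter(sites: Iterable[HetSite]) -> list[HetSite]:
    """Drop sites in the bottom or top decile of observed sequencing depth.

    Percentiles use linear interpolation; sites strictly below P10 or
    strictly above P90 are excluded. Degenerate (all-equal) depth
    distributions retain everything.
    """
    sites = list(sites)
    if not sites:
        return []
    depths = np.array([s.depth for s in sites], dtype=float)
    lo, hi = np.percentile(depths, [10.0, 90.0])
    return [s for s, d in zip(sites, depths) if lo <= d <= hi]


def polarize_from_truth(
    sites: Iterable[HetSite], truth: TruthPhase
) -> tuple[TruthPhase, dict]:
    """Synthetic-path polarization from a known truth table.

    Sites absent from the table are left unpolarized; sites whose alleles do
    not match the table are flagged inconsistent. Returns the polarized
    subset plus a diagnostics tally.
    """
    out = {}
    diag = {"polarized": 0, "unpolarized": 0, "inconsistent": 0}
    for s in sites:
        truth_alleles = truth.get(s.ref, s.pos)
        if truth_alleles is None:
            diag["unpolarized"] += 1
            continue
        if set(truth_alleles) != set(s.alleles):
            diag["inconsistent"] += 1
            continue
        out[(s.ref, s.pos)] = truth_alleles
        diag["polarized"] += 1
    return TruthPhase(out), diag


# ---------------------------------------------------------------------------
# PAF-based polarization


@dataclass(frozen=True)
class PafAlignment:
    query: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target: str
    target_len: int
    target_start: int
    target_end: int
    cs: str | None


def read_paf(source: TextIO | str) -> list[PafAlignment]:
    """Minimal PAF reader retaining the cs tag (required for polarization)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    out = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(f"PAF line {lineno}: expected >=12 columns")
        cs = None
        for tag in cols[12:]:
            if tag.startswith("cs:Z:"):
                cs = tag[5:]
        out.append(
            PafAlignment(
                cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4],
                cols[5], int(cols[6]), int(cols[7]), int(cols[8]), cs,
            )
        )
    return out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _walk_cs(aln: PafAlignment) -> dict[int, str]:
    """Target position -> aligned parent (query) base, from the cs tag.

    Positions deleted from the query map to '', insertions are skipped.
    Identity runs map to the target's own base, recorded as '=' (the VCF REF
    allele stands in for the assembly base at that position).
    """
    if aln.cs is None:
        raise ValueError(f"alignment {aln.query}->{aln.target} lacks a cs tag")
    bases: dict[int, str] = {}
    t = aln.target_start
    i = 0
    cs = aln.cs
    n = len(cs)
    while i < n:
        op = cs[i]
        i += 1
        j = i
        while j < n and cs[j] not in ":*+-=~":
            j += 1
        val = cs[i:j]
        i = j
        if op == ":":
            for k in range(int(val)):
                bases[t + k] = "="
            t += int(val)
        elif op == "=":
            for k, ch in enumerate(val):
                bases[t + k] = "="
            t += len(val)
        elif op == "*":
            # substitution: val = target base + query base
            bases[t] = val[1].upper()
            t += 1
        elif op == "-":
            for k in range(len(val)):
                bases[t + k] = ""
            t += len(val)
        elif op == "+":
            pass  # insertion in the parent; consumes no target
        else:
            raise ValueError(f"unsupported cs op {op!r}")
    return bases


def polarize_paf(
    sites: Iterable[HetSite], alignments: Iterable[PafAlignment]
) -> tuple[TruthPhase, dict]:
    """Polarize SNP sites from a parent-to-assembly PAF with cs tags.

    The assembly is the PAF *target*. For each site covered by exactly one
    alignment, the parent base at the site position decides which allele is
    parent A ('=' means the parent carries the assembly base, i.e. the REF
    allele). Sites in unaligned or multiply-aligned regions stay
    unpolarized; sites where neither allele matches are tallied
    inconsistent and excluded.
    """
    alignments = list(alignments)
    per_target: dict[str, list[PafAlignment]] = {}
    for a in alignments:
        per_target.setdefault(a.target, []).append(a)
    base_maps = {id(a): None for a in alignments}

    diag = {"polarized": 0, "unpolarized": 0, "inconsistent": 0, "indel_skipped": 0}
    out = {}
    for s in sites:
        if s.variant_class != "SNP":
            diag["indel_skipped"] += 1
            continue
        covering = [
            a for a in per_target.get(s.ref, [])
            if a.target_start <= s.pos < a.target_end
        ]
        if len(covering) != 1:
            diag["unpolarized"] += 1
            continue
        aln = covering[0]
        if base_maps[id(aln)] is None:
            base_maps[id(aln)] = _walk_cs(aln)
        parent_base = base_maps[id(aln)].get(s.pos)
        ref_allele, alt_allele = s.alleles
        if parent_base == "=":
            parent_base = ref_allele.upper()
        if parent_base == ref_allele.upper():
            out[(s.ref, s.pos)] = (ref_allele, alt_allele)
            diag["polarized"] += 1
        elif parent_base == alt_allele.upper():
            out[(s.ref, s.pos)] = (alt_allele, ref_allele)
            diag["polarized"] += 1
        else:
            diag["inconsistent"] += 1
    return TruthPhase(out), diag


# ---------------------------------------------------------------------------
# Error evaluation


def _run_errors(disagree: np.ndarray) -> tuple[int, int]:
    """Switch/mismatch counts for one orientation of one block.

    Maximal runs of disagreement: an isolated single-site run (flanked by
    agreement or a block edge) is one mismatch; a run of >=2 contributes one
    switch per boundary with an agreeing neighbor (so an interior run counts
    two change-points, an edge-touching run one).
    """
    n = disagree.size
    if n == 0 or not disagree.any():
        return 0, 0
    d = disagree.astype(np.int8)
    boundaries = np.flatnonzero(np.diff(d))  # index i where d[i] != d[i+1]
    starts = [0] if d[0] else []
    starts += [int(i) + 1 for i in boundaries if d[i + 1] == 1]
    ends = [int(i) for i in boundaries if d[i] == 1]
    if d[-1]:
        ends.append(n - 1)
    switch = mismatch = 0
    for a, b in zip(starts, ends):
        if b == a:
            mismatch += 1
        else:
            switch += int(a > 0) + int(b < n - 1)
    return switch, mismatch


def _block_disagreement(block: PhasedBlock, truth: TruthPhase) -> tuple[np.ndarray, int]:
    """0/1 disagreement vector of truth-labeled sites vs haplotype 0 being
    parent A, plus the count of excluded (unlabeled/inconsistent) sites."""
    d = []
    excluded = 0
    for s in block.sites:
        t = truth.get(s.ref, s.pos)
        if t is None or {s.hap0, s.hap1} != set(t):
            excluded += 1
            continue
        d.append(0 if s.hap0 == t[0] else 1)
    return np.array(d, dtype=np.int8), excluded


def _best_orientation_errors(d: np.ndarray) -> tuple[int, int]:
    """Errors under the better global block orientation.

    Ties go to the orientation agreeing at the first site (standard for
    phasing evaluation, where block orientation is arbitrary)."""
    s0, m0 = _run_errors(d)
    s1, m1 = _run_errors(1 - d)
    if s0 + m0 < s1 + m1:
        return s0, m0
    if s1 + m1 < s0 + m0:
        return s1, m1
    return (s0, m0) if d.size and d[0] == 0 else (s1, m1)


def evaluate_phase(blocks: Iterable[PhasedBlock], truth: TruthPhase) -> PhaseErrorReport:
    """Score phased blocks against truth haplotypes.

    Rates divide by the total number of truth-labeled phased sites; blocks
    with fewer than two labeled sites contribute sites but no errors.
    """
    n_sites = n_switch = n_mismatch = n_excluded = 0
    labeled_per_block = []
    spans = []
    for block in blocks:
        d, excluded = _block_disagreement(block, truth)
        n_excluded += excluded
        n_sites += d.size
        labeled_per_block.append(d.size)
        spans.append(block.span)
        if d.size >= 2:
            s, m = _best_orientation_errors(d)
            n_switch += s
            n_mismatch += m
    n_blocks = len(labeled_per_block)
    if n_blocks == 0:
        raise ValueError("no blocks supplied")
    largest = max(labeled_per_block) / n_sites if n_sites else 0.0
    return PhaseErrorReport(
        n_sites=n_sites,
        n_switch=n_switch,
        n_mismatch=n_mismatch,
        n_blocks=n_blocks,
        n_excluded=n_excluded,
        mean_block_len=n_sites / n_blocks,
        mean_block_span=float(np.mean(spans)),
        largest_block_fraction=largest,
    )


def block_stats(blocks: Iterable[PhasedBlock]) -> dict[str, float]:
    """Block-structure summary: mean variants/block, mean span in bases, and
    the fraction of phased sites in the largest block."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks supplied")
    lens = np.array([len(b.sites) for b in blocks], dtype=float)
    spans = np.array([b.span for b in blocks], dtype=float)
    return {
        "n_blocks": len(blocks),
        "mean_block_len": float(lens.mean()),
        "mean_block_span": float(spans.mean()),
        "largest_block_fraction": float(lens.max() / lens.sum()),
    }


def join_switch_fraction(rate_increase: float, mean_block_len: float) -> float:
    """Fraction of short-read blocks whose joining introduces a switch error.

    Each pre-existing block contributes about one new junction when a
    long-range data type stitches blocks together, i.e. roughly 1/mean
    block length junctions per site, so the per-site switch-rate increase
    times the mean block length estimates the per-junction switch
    probability.
    """
    if rate_increase < 0:
        raise ValueError("rate must be >= 0")
    if mean_block_len < 1:
        raise ValueError("mean block length must be >= 1")
    return rate_increase * mean_block_len


# ---------------------------------------------------------------------------
# Phased VCF input


def read_phased_vcf(path: str) -> tuple[list[PhasedBlock], list[HetSite]]:
    """Read phased blocks from a VCF (first sample; ``|``-separated GT,
    blocks defined by the PS tag, unphased records ignored).

    Returns (blocks, heterozygous sites with depths) for downstream
    filtering and evaluation.
    """
    import pysam

    sites: list[HetSite] = []
    grouped: dict[tuple[str, str], list[PhasedSite]] = {}
    with pysam.VariantFile(path) as vcf:
        sample = vcf.header.samples[0]
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                continue
            alleles = rec.alleles
            a0, a1 = alleles[gt[0]], alleles[gt[1]]
            if a0 == a1:
                continue
            vclass = "SNP" if len(a0) == len(a1) == 1 else "indel"
            depth = call.get("DP") or rec.info.get("DP") or 0
            sites.append(HetSite(rec.chrom, rec.pos - 1, (a0, a1), int(depth), vclass))
            if not call.phased:
                continue
            ps = call.get("PS")
            block_key = (rec.chrom, str(ps) if ps is not None else "default")
            grouped.setdefault(block_key, []).append(
                PhasedSite(rec.chrom, rec.pos - 1, a0, a1)
            )
    blocks = [
        PhasedBlock(f"{chrom}:{ps}", sorted(ss, key=lambda s: s.pos))
        for (chrom, ps), ss in sorted(grouped.items())
    ]
    return blocks, sites
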