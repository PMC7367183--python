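"""Hi-C misjoin detection via insulation scores and an empirical false-join null.

The insulation score at a focal scaffold point is the raw number of contact
pairs with one end in the window immediately left of the point and the other
in the window immediately right (window W each side, truncated at scaffold
ends). A junction whose score is indistinguishable from the score of an
artificial false-join -- a virtual junction between the ends of two contigs
known not to share a scaffold -- has no Hi-C support and is flagged for
breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import Breakpoint, ScaffoldLayout
from .pairs import ContactSet

__all__ = [
    "MisjoinParams",
    "InsulationResult",
    "spanning_count",
    "junction_positions",
    "scan_joins",
    "false_join_null",
    "call_misjoins",
]


@dataclass
class MisjoinParams:
    """Tunables for the misjoin scan.

    window: flanking window W in bases on each side of a test point.
    n_null: number of artificial false-joins sampled for the null.
    flag_quantile: junctions scoring at or below this empirical null quantile
        are flagged.
    seed: RNG seed for the null sampling.
    stride: optional fixed stride for a genome-wide scan in addition to
        junction points.
    """

    window: int = 1_000_000
    n_null: int = 1_000
    flag_quantile: float = 0.95
    seed: int = 0
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if not 0.0 < self.flag_quantile < 1.0:
            raise ValueError("flag_quantile must be in (0,1)")


@dataclass
class InsulationResult:
    scaffold: str
    position: int
    score: int
    is_junction: bool = True
    truncated: bool = False  # a window hit a scaffold end
    null_quantile: float | None = None  # empirical CDF of the null at score
    flagged: bool = False


def spanning_count(contacts: ContactSet, scaffold: str, position: int, window: int) -> int:
    """Pairs with one end in [position-W, position) and the other in
    [position, position+W), truncated at scaffold ends."""
    if scaffold not in contacts.references:
        raise ValueError(f"scaffold {scaffold!r} absent from contact references")
    lo = max(0, position - window)
    hi = min(contacts.references[scaffold], position + window)
    c1, c2, p1, p2, code = _ref_codes(contacts)
    k = code[scaffold]
    same = (c1 == k) & (c2 == k)
    # canonical order guarantees pos1 <= pos2 for same-reference pairs
    return int(np.count_nonzero(same & (p1 >= lo) & (p1 < position)
                                & (p2 >= position) & (p2 < hi)))


def _ref_codes(contacts: ContactSet):
    """Integer-coded endpoint arrays, cached on the contact set."""
    cached = getattr(contacts, "_ref_code_cache", None)
    if cached is not None and cached[5] is contacts.df:
        return cached[:5]
    code = {name: i for i, name in enumerate(contacts.references)}
    df = contacts.df
    c1 = df["ref1"].map(code).to_numpy(dtype=np.int64)
    c2 = df["ref2"].map(code).to_numpy(dtype=np.int64)
    p1 = df["pos1"].to_numpy(dtype=np.int64)
    p2 = df["pos2"].to_numpy(dtype=np.int64)
    contacts._ref_code_cache = (c1, c2, p1, p2, code, df)
    return c1, c2, p1, p2, code


def junction_positions(layout: ScaffoldLayout) -> list[tuple[str, int, bool]]:
    """(scaffold, position, truncated) for every contig-contig junction.

    The junction position is the scaffold coordinate where the left contig
    span ends (gaps between spans belong to the junction). truncated is set
    when a 1-base window would not fit -- callers with larger windows get the
    per-result truncation flag from scan_joins instead.
    """
    out = []
    for scaf in layout.scaffolds:
        span_ends = [off + sp.length for off, sp in scaf.spans()]
        for end in span_ends[:-1]:
            out.append((scaf.name, end, False))
    return out


def scan_joins(
    contacts: ContactSet, layout: ScaffoldLayout, params: MisjoinParams
) -> list[InsulationResult]:
    """Insulation score at every contig-contig junction (and, when
    params.stride is set, at fixed-stride points genome-wide)."""
    ref_lengths = layout.reference_lengths()
    missing = set(ref_lengths) - set(contacts.references)
    if missing:
        raise ValueError(f"layout scaffolds absent from contacts: {sorted(missing)}")
    points: list[tuple[str, int, bool]] = [
        (s, p, True) for s, p, _ in junction_positions(layout)
    ]
    if params.stride is not None:
        for name, length in ref_lengths.items():
            for pos in range(params.stride, length, params.stride):
                points.append((name, pos, False))
    results = []
    for scaffold, pos, is_junction in points:
        length = ref_lengths[scaffold]
        results.append(
            InsulationResult(
                scaffold=scaffold,
                position=pos,
                score=spanning_count(contacts, scaffold, pos, params.window),
                is_junction=is_junction,
                truncated=(pos - params.window < 0) or (pos + params.window > length),
            )
        )
    return results


def _contig_placements(layout: ScaffoldLayout) -> dict[str, tuple[str, int, int]]:
    """Contig -> (scaffold, scaffold start, scaffold end) for single-span contigs."""
    placements: dict[str, tuple[str, int, int]] = {}
    seen_twice: set[str] = set()
    for scaf in layout.scaffolds:
        for off, sp in scaf.spans():
            if sp.contig in placements:
                seen_twice.add(sp.contig)
            placements[sp.contig] = (scaf.name, off, off + sp.length)
    for name in seen_twice:
        placements.pop(name, None)
    return placements


def false_join_null(
    contacts: ContactSet, layout: ScaffoldLayout, params: MisjoinParams
) -> np.ndarray:
    """Null insulation scores of artificial false-joins.

    Each draw picks a random ordered pair of distinct unlinked contigs
    (different scaffolds) and scores the virtual junction formed by gluing
    the right end of the first to the left end of the second: contacts with
    one end within W of the first contig's right end and the other within W
    of the second contig's left end (necessarily inter-contig). Orientation
    of the glued contigs is irrelevant to this counted set.
    """
    placements = _contig_placements(layout)
    contigs = sorted(placements)
    scaf_of = {c: placements[c][0] for c in contigs}
    ordered_pairs = [
        (a, b) for a in contigs for b in contigs if a != b and scaf_of[a] != scaf_of[b]
    ]
    if not ordered_pairs:
        raise ValueError("need at least 2 unlinked contigs for the false-join null")

    rng = np.random.default_rng(params.seed)
    draw = rng.integers(len(ordered_pairs), size=params.n_null)

    r1, r2, p1, p2, code = _ref_codes(contacts)
    W = params.window

    cache: dict[int, int] = {}

    def geometry_score(idx: int) -> int:
        if idx in cache:
            return cache[idx]
        a, b = ordered_pairs[idx]
        sa, a0, a1 = placements[a]
        sb, b0, b1 = placements[b]
        ka, kb = code[sa], code[sb]
        ax_lo, ax_hi = max(a0, a1 - W), a1          # right-end window of A
        bx_lo, bx_hi = b0, min(b1, b0 + W)          # left-end window of B
        m = (
            ((r1 == ka) & (p1 >= ax_lo) & (p1 < ax_hi)
             & (r2 == kb) & (p2 >= bx_lo) & (p2 < bx_hi))
            | ((r1 == kb) & (p1 >= bx_lo) & (p1 < bx_hi)
               & (r2 == ka) & (p2 >= ax_lo) & (p2 < ax_hi))
        )
        score = int(np.count_nonzero(m))
        cache[idx] = score
        return score

    return np.array([geometry_score(int(i)) for i in draw], dtype=np.int64)


def call_misjoins(
    results: list[InsulationResult], null_scores: np.ndarray, params: MisjoinParams
) -> list[Breakpoint]:
    """Flag junctions whose score is <= the q-quantile of the null sample.

    Annotates each result in place (null_quantile, flagged) and returns the
    flagged junctions as breakpoints sorted by ascending score.
    """
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("empty null sample")
    threshold = float(np.quantile(null_scores, params.flag_quantile))
    flagged = []
    for res in results:
        res.null_quantile = float(np.mean(null_scores <= res.score))
        res.flagged = res.is_junction and res.score <= threshold
        if res.flagged:
            flagged.append(res)
    flagged.sort(key=lambda r: r.score)
    return [Breakpoint(r.scaffold, r.position) for r in flagged]
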