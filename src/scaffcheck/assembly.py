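"""Assembly layout model: scaffolds as ordered, oriented contig spans and gaps.

The layout is the coordinate backbone shared by the other modules. It follows
AGP semantics (a scaffold is an ordered list of contig spans and gaps) but all
internal coordinates are 0-based half-open; AGP's 1-based inclusive convention
is converted only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, TextIO, Union

__all__ = [
    "AgpParseError",
    "LayoutError",
    "Contig",
    "ContigSpan",
    "Gap",
    "Scaffold",
    "ScaffoldLayout",
    "Breakpoint",
    "ContigPosition",
    "GapPosition",
    "parse_agp",
    "write_agp",
    "lift_scaffold_to_contig",
    "contig_to_scaffold",
    "apply_breaks",
]


class AgpParseError(ValueError):
    """Malformed AGP input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"AGP line {line}: {message}")
        self.line = line


class LayoutError(ValueError):
    """A layout invariant was violated."""


# AGP v2.1 component type codes. Anything sequence-like is a contig span.
_SPAN_TYPES = frozenset("WDFOAP")
_GAP_TYPES = frozenset("NU")


@dataclass(frozen=True)
class Contig:
    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise LayoutError(f"contig {self.name!r} has non-positive length")


@dataclass(frozen=True)
class ContigSpan:
    """An oriented interval of a contig placed in a scaffold."""

    contig: str
    start: int  # 0-based, on the contig
    end: int    # half-open
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise LayoutError(f"bad span interval [{self.start},{self.end}) on {self.contig}")
        if self.orientation not in ("+", "-"):
            raise LayoutError(f"orientation must be + or -, got {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gap:
    length: int
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "paired-ends"
    component_code: str = "N"  # N = known size, U = unknown (100 by convention)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise LayoutError("gap length must be positive")


Component = Union[ContigSpan, Gap]


@dataclass
class Scaffold:
    name: str
    components: list[Component] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(c.length for c in self.components)

    def spans(self) -> Iterator[tuple[int, ContigSpan]]:
        """Yield (scaffold offset, span) for every contig span."""
        offset = 0
        for c in self.components:
            if isinstance(c, ContigSpan):
                yield offset, c
            offset += c.length


@dataclass
class ScaffoldLayout:
    """Ordered scaffolds plus the registry of contigs they are built from."""

    scaffolds: list[Scaffold]
    contigs: dict[str, Contig] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            self.contigs = _infer_contigs(self.scaffolds)
        self.validate()

    def validate(self) -> None:
        names = [s.name for s in self.scaffolds]
        if len(names) != len(set(names)):
            raise LayoutError("duplicate scaffold names")
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for scaf in self.scaffolds:
            prev_gap = False
            for comp in scaf.components:
                if isinstance(comp, Gap):
                    if prev_gap:
                        raise LayoutError(f"adjacent gaps in scaffold {scaf.name}")
                    prev_gap = True
                else:
                    prev_gap = False
                    ctg = self.contigs.get(comp.contig)
                    if ctg is None:
                        raise LayoutError(f"span references unknown contig {comp.contig!r}")
                    if comp.end > ctg.length:
                        raise LayoutError(
                            f"span [{comp.start},{comp.end}) exceeds contig "
                            f"{ctg.name} length {ctg.length}"
                        )
                    per_contig.setdefault(comp.contig, []).append((comp.start, comp.end))
        for name, ivals in per_contig.items():
            ivals.sort()
            for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise LayoutError(f"overlapping spans of contig {name}")

    def scaffold(self, name: str) -> Scaffold:
        for s in self.scaffolds:
            if s.name == name:
                return s
        raise KeyError(name)

    def reference_lengths(self) -> dict[str, int]:
        """Scaffold name -> length map, the reference map for contact sets."""
        return {s.name: s.length for s in self.scaffolds}

    def contig_scaffold(self) -> dict[str, str]:
        """Contig name -> name of the scaffold holding it (first occurrence)."""
        out: dict[str, str] = {}
        for s in self.scaffolds:
            for _, span in s.spans():
                out.setdefault(span.contig, s.name)
        return out

    def total_span_bases(self) -> int:
        """Total non-gap bases placed in scaffolds (conserved by apply_breaks)."""
        return sum(sp.length for s in self.scaffolds for _, sp in s.spans())


def _infer_contigs(scaffolds: Iterable[Scaffold]) -> dict[str, Contig]:
    lengths: dict[str, int] = {}
    for s in scaffolds:
        for _, span in s.spans():
            lengths[span.contig] = max(lengths.get(span.contig, 0), span.end)
    return {n: Contig(n, ln) for n, ln in lengths.items()}


@dataclass(frozen=True)
class Breakpoint:
    """Scaffold coordinate of a cut: 0-based offset of the first base of the
    right-hand product. Must lie strictly inside the scaffold."""

    scaffold: str
    position: int


@dataclass(frozen=True)
class ContigPosition:
    contig: str
    position: int
    orientation: str


@dataclass(frozen=True)
class GapPosition:
    scaffold: str
    position: int


# ---------------------------------------------------------------------------
# AGP I/O


def parse_agp(source: TextIO | str) -> ScaffoldLayout:
    """Parse AGP v2.1 text into a :class:`ScaffoldLayout`.

    Records must be sorted by object then part number; coordinates are
    validated (consecutive parts, matching span lengths) and converted to
    0-based half-open. Raises :class:`AgpParseError` naming the line number.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()

    scaffolds: list[Scaffold] = []
    current: Scaffold | None = None
    expect_part = 1
    expect_beg = 1

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AgpParseError(f"expected 9 tab-separated columns, got {len(cols)}", lineno)
        obj, beg_s, end_s, part_s, ctype = cols[0], cols[1], cols[2], cols[3], cols[4]
        try:
            beg, end, part = int(beg_s), int(end_s), int(part_s)
        except ValueError:
            raise AgpParseError("non-integer object coordinates or part number", lineno)
        if beg < 1 or end < beg:
            raise AgpParseError(f"bad object interval {beg}-{end}", lineno)

        if current is None or obj != current.name:
            if current is not None and any(s.name == obj for s in scaffolds):
                raise AgpParseError(f"object {obj!r} records are not contiguous", lineno)
            current = Scaffold(obj)
            scaffolds.append(current)
            expect_part = 1
            expect_beg = 1
        if part != expect_part:
            raise AgpParseError(f"part_number {part}, expected {expect_part}", lineno)
        if beg != expect_beg:
            raise AgpParseError(f"object_beg {beg}, expected {expect_beg}", lineno)
        span_len = end - beg + 1

        if ctype in _SPAN_TYPES:
            comp_id, cb_s, ce_s, orient = cols[5], cols[6], cols[7], cols[8]
            try:
                cb, ce = int(cb_s), int(ce_s)
            except ValueError:
                raise AgpParseError("non-integer component coordinates", lineno)
            if cb < 1 or ce < cb:
                raise AgpParseError(f"bad component interval {cb}-{ce}", lineno)
            if ce - cb + 1 != span_len:
                raise AgpParseError(
                    f"component length {ce - cb + 1} != object span {span_len}", lineno
                )
            if orient not in ("+", "-"):
                raise AgpParseError(f"unsupported orientation {orient!r}", lineno)
            try:
                current.components.append(ContigSpan(comp_id, cb - 1, ce, orient))
            except LayoutError as exc:
                raise AgpParseError(str(exc), lineno)
        elif ctype in _GAP_TYPES:
            gap_len_s, gap_type, linkage, evidence = cols[5], cols[6], cols[7], cols[8]
            try:
                gap_len = int(gap_len_s)
            except ValueError:
                raise AgpParseError("non-integer gap length", lineno)
            if gap_len != span_len:
                raise AgpParseError(f"gap length {gap_len} != object span {span_len}", lineno)
            current.components.append(
                Gap(gap_len, gap_type=gap_type, linkage=linkage, evidence=evidence,
                    component_code=ctype)
            )
        else:
            raise AgpParseError(f"unknown component type {ctype!r}", lineno)

        expect_part += 1
        expect_beg = end + 1

    try:
        return ScaffoldLayout(scaffolds)
    except LayoutError as exc:
        raise AgpParseError(str(exc), len(lines))


def write_agp(layout: ScaffoldLayout) -> str:
    """Serialize a layout to AGP v2.1 text (1-based inclusive, parts from 1)."""
    out: list[str] = []
    for scaf in layout.scaffolds:
        offset = 0
        for part, comp in enumerate(scaf.components, start=1):
            beg, end = offset + 1, offset + comp.length
            if isinstance(comp, ContigSpan):
                out.append(
                    "\t".join(
                        (scaf.name, str(beg), str(end), str(part), "W", comp.contig,
                         str(comp.start + 1), str(comp.end), comp.orientation)
                    )
                )
            else:
                out.append(
                    "\t".join(
                        (scaf.name, str(beg), str(end), str(part), comp.component_code,
                         str(comp.length), comp.gap_type, comp.linkage, comp.evidence)
                    )
                )
            offset = end
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# Coordinate lifting


def lift_scaffold_to_contig(
    layout: ScaffoldLayout, scaffold: str, position: int
) -> ContigPosition | GapPosition:
    """Map a scaffold coordinate to its (contig, position, orientation).

    Positions falling in gaps return a :class:`GapPosition` rather than
    failing silently. For a '-' span, offset k within the span maps to contig
    coordinate span.end - 1 - k.
    """
    scaf = layout.scaffold(scaffold)
    if not 0 <= position < scaf.length:
        raise LayoutError(f"position {position} outside scaffold {scaffold}")
    offset = 0
    for comp in scaf.components:
        if position < offset + comp.length:
            k = position - offset
            if isinstance(comp, Gap):
                return GapPosition(scaffold, position)
            if comp.orientation == "+":
                return ContigPosition(comp.contig, comp.start + k, "+")
            return ContigPosition(comp.contig, comp.end - 1 - k, "-")
        offset += comp.length
    raise AssertionError("unreachable")


def contig_to_scaffold(layout: ScaffoldLayout, contig: str, position: int) -> tuple[str, int]:
    """Inverse of :func:`lift_scaffold_to_contig` for placed contig bases."""
    for scaf in layout.scaffolds:
        for offset, span in scaf.spans():
            if span.contig == contig and span.start <= position < span.end:
                if span.orientation == "+":
                    return scaf.name, offset + (position - span.start)
                return scaf.name, offset + (span.end - 1 - position)
    raise LayoutError(f"contig {contig}:{position} not placed in layout")


# ---------------------------------------------------------------------------
# Breaking


def apply_breaks(layout: ScaffoldLayout, breakpoints: Iterable[Breakpoint]) -> ScaffoldLayout:
    """Split scaffolds at the given breakpoints.

    A break inside a contig span splits the span and logically splits the
    contig into deterministically named parts (``name.1``, ``name.2``, ... in
    ascending contig coordinate). A break inside (or at the edge of) a gap
    removes the gap, severing the unsupported join. Non-gap bases are
    conserved. An empty break list returns an equivalent layout.
    """
    by_scaffold: dict[str, list[int]] = {}
    for bp in breakpoints:
        scaf = layout.scaffold(bp.scaffold)
        if not 0 < bp.position < scaf.length:
            raise LayoutError(
                f"breakpoint {bp.position} on {bp.scaffold} must be strictly inside "
                f"(0, {scaf.length})"
            )
        pos_list = by_scaffold.setdefault(bp.scaffold, [])
        if bp.position not in pos_list:
            pos_list.append(bp.position)

    # Collect contig cut coordinates from breaks landing strictly inside spans.
    contig_cuts: dict[str, set[int]] = {}
    for sname, positions in by_scaffold.items():
        scaf = layout.scaffold(sname)
        for pos in positions:
            offset = 0
            for comp in scaf.components:
                if offset < pos < offset + comp.length and isinstance(comp, ContigSpan):
                    k = pos - offset
                    cut = comp.start + k if comp.orientation == "+" else comp.end - k
                    contig_cuts.setdefault(comp.contig, set()).add(cut)
                offset += comp.length

    # Partition each cut contig into named parts.
    part_map: dict[str, list[tuple[int, int, str]]] = {}
    new_contigs: dict[str, Contig] = {}
    for name, ctg in layout.contigs.items():
        cuts = sorted(contig_cuts.get(name, ()))
        if not cuts:
            new_contigs[name] = ctg
            continue
        bounds = [0, *cuts, ctg.length]
        parts = []
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            pname = f"{name}.{i}"
            parts.append((a, b, pname))
            new_contigs[pname] = Contig(pname, b - a)
        part_map[name] = parts

    def remap(span: ContigSpan) -> ContigSpan:
        parts = part_map.get(span.contig)
        if parts is None:
            return span
        for a, b, pname in parts:
            if a <= span.start and span.end <= b:
                return ContigSpan(pname, span.start - a, span.end - a, span.orientation)
        raise LayoutError(f"span of {span.contig} straddles a contig cut")

    out: list[Scaffold] = []
    for scaf in layout.scaffolds:
        cuts = sorted(by_scaffold.get(scaf.name, ()))
        if not cuts:
            out.append(Scaffold(scaf.name, [remap(c) if isinstance(c, ContigSpan) else c
                                            for c in scaf.components]))
            continue
        segments: list[list[Component]] = [[]]
        offset = 0
        cut_iter = iter(cuts + [scaf.length])
        next_cut = next(cut_iter)
        for comp in scaf.components:
            start, end = offset, offset + comp.length
            piece_start = start
            while next_cut < end:
                if next_cut > piece_start:
                    segments[-1].append(_slice_component(comp, piece_start - start,
                                                         next_cut - start))
                segments.append([])
                piece_start = next_cut
                next_cut = next(cut_iter)
            if end > piece_start:
                segments[-1].append(_slice_component(comp, piece_start - start, end - start))
            offset = end
        products = []
        for i, seg in enumerate(segments, start=1):
            while seg and isinstance(seg[0], Gap):
                seg.pop(0)
            while seg and isinstance(seg[-1], Gap):
                seg.pop()
            if not seg:
                raise LayoutError(
                    f"breaks on {scaf.name} would produce an empty scaffold piece"
                )
            products.append(
                Scaffold(f"{scaf.name}.{i}", [remap(c) if isinstance(c, ContigSpan) else c
                                              for c in seg])
            )
        out.extend(products)

    return ScaffoldLayout(out, {n: c for n, c in new_contigs.items()
                                if any(sp.contig == n for s in out for _, sp in s.spans())})


def _slice_component(comp: Component, a: int, b: int) -> Component:
    """Component restricted to local offsets [a, b)."""
    if a == 0 and b == comp.length:
        return comp
    if isinstance(comp, Gap):
        return replace(comp, length=b - a)
    if comp.orientation == "+":
        return ContigSpan(comp.contig, comp.start + a, comp.start + b, "+")
    return ContigSpan(comp.contig, comp.end - b, comp.end - a, "-")
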