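"""Seeded generators for every input the QC modules consume, with ground truth.

The generators emulate the data regime of a low-input single-individual
hybrid assembly project: an F1 heterozygote mosaic of two known parental
genomes, proximity-ligation contacts with power-law distance decay plus a
uniform trans background and planted misjoins, PCR duplicates at a set
rate, overdispersed (negative binomial) sequencing depth, and phased blocks
with planted per-adjacency switch and per-site mismatch events. All
randomness flows through one numpy Generator per call, so outputs are
byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assembly import Contig, ContigSpan, Scaffold, ScaffoldLayout, Breakpoint
from .completeness import Feature
from .pairs import ContactSet, DepthTrack, _COLUMNS
from .phasing import PhasedBlock, PhasedSite, TruthPhase

__all__ = [
    "derive_seed",
    "SimConfig",
    "TruthBundle",
    "simulate_f1",
    "simulate_contacts",
    "plant_misjoin",
    "simulate_depth",
    "simulate_phased_blocks",
    "simulate_annotation",
    "misjoin_benchmark",
    "phasing_benchmark",
    "write_fasta",
    "write_phased_vcf",
]


def derive_seed(base: int, stream: int) -> int:
    """Independent sub-seed (< 2^31) for generator stream ``stream`` of a run
    seeded with ``base``, via numpy's SeedSequence spawning."""
    return int(np.random.SeedSequence([base, stream]).generate_state(1)[0] % (2 ** 31))


@dataclass
class SimConfig:
    """Study conditions for the generators.

    Defaults follow the regime of a single outbred fly sequenced with
    low-input protocols: per-base heterozygosity theta of an
    inter-strain cross (~0.5%), contact distance decay exponent alpha=1
    with a 1 kb minimum separation, a 1% trans-contact background, a 12%
    PCR duplication rate, negative-binomial depth with mean 39.7 and
    variance 1038 (the long-read library's moments), and short-read-scale
    phase blocks of 14 variants with a 0.00147/site error budget.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_contigs: int = 2
    theta: float = 0.005
    n_contacts: int = 100_000
    alpha: float = 1.0
    min_separation: int = 1_000
    trans_rate: float = 0.01
    dup_rate: float = 0.12
    depth_mean: float = 39.7
    depth_var: float = 1038.0
    block_length: int = 14
    switch_rate: float = 0.0
    mismatch_rate: float = 0.00147

    def __post_init__(self) -> None:
        for name in ("theta", "trans_rate", "dup_rate", "switch_rate", "mismatch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.depth_var < self.depth_mean:
            raise ValueError("depth variance must be >= mean (Poisson limit)")


@dataclass
class TruthBundle:
    """Ground truth accompanying generated data."""

    het_truth: TruthPhase | None = None
    misjoin_breakpoints: list[Breakpoint] = field(default_factory=list)
    duplicate_flags: np.ndarray | None = None
    switch_adjacencies: list[tuple[str, int]] = field(default_factory=list)
    mismatch_sites: list[tuple[str, int]] = field(default_factory=list)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_f1(config: SimConfig) -> tuple[str, str, TruthPhase]:
    """Two parental haploid sequences differing by Bernoulli(theta) SNPs.

    Returns (parentA, parentB, truth table of every difference). Parent B is
    parent A with substitutions; coordinates are shared, so the truth table
    is exact by construction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    a = _BASES[rng.integers(4, size=n)]
    b = a.copy()
    het = np.flatnonzero(rng.random(n) < config.theta)
    # substitute with one of the three other bases, uniformly
    shift = rng.integers(1, 4, size=het.size).astype(np.uint8)
    idx_a = np.searchsorted(_BASES, a[het])
    b[het] = _BASES[(idx_a + shift) % 4]
    seq_a = a.tobytes().decode()
    seq_b = b.tobytes().decode()
    truth = TruthPhase(
        {("ref", int(p)): (seq_a[p], seq_b[p]) for p in het}
    )
    return seq_a, seq_b, truth


def _sample_decay_separation(rng, n, smin, smax, alpha):
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return (smin * (smax / smin) ** u).astype(np.int64)
    a1 = 1.0 - alpha
    return ((smin ** a1 + u * (smax ** a1 - smin ** a1)) ** (1.0 / a1)).astype(np.int64)


def simulate_contacts(
    ref_lengths: dict[str, int],
    config: SimConfig,
    n_pairs: int | None = None,
) -> tuple[ContactSet, TruthBundle]:
    """Distance-decay cis contacts, per-reference-pair uniform trans
    background, and planted exact duplicates.

    Cis pairs are allocated to references proportionally to length; the
    left end is uniform and the separation follows the truncated power law
    ``s^-alpha`` on [min_separation, reference length). Trans pairs pick an
    ordered pair of distinct references uniformly, endpoints uniform within
    each. A fraction ``dup_rate`` of the final records are exact re-emissions
    of earlier records.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_contacts if n_pairs is None else n_pairs
    names = list(ref_lengths)
    lengths = np.array([ref_lengths[r] for r in names], dtype=np.int64)

    n_dup = int(round(n * config.dup_rate))
    n_real = n - n_dup
    n_trans = int(round(n_real * config.trans_rate)) if len(names) > 1 else 0
    n_cis = n_real - n_trans

    # cis
    probs = lengths / lengths.sum()
    cis_ref = rng.choice(len(names), size=n_cis, p=probs)
    smax = lengths[cis_ref]
    smin = min(config.min_separation, int(lengths.min()) - 1)
    sep = _sample_decay_separation(rng, n_cis, smin, smax, config.alpha)
    sep = np.minimum(sep, smax - 1)
    left = (rng.random(n_cis) * (smax - sep)).astype(np.int64)
    cis = pd.DataFrame(
        {
            "ref1": np.array(names, dtype=object)[cis_ref],
            "pos1": left,
            "strand1": np.where(rng.random(n_cis) < 0.5, "+", "-"),
            "ref2": np.array(names, dtype=object)[cis_ref],
            "pos2": left + sep,
            "strand2": np.where(rng.random(n_cis) < 0.5, "+", "-"),
        }
    )

    # trans: ordered pair of distinct references, uniform per pair
    frames = [cis]
    if n_trans:
        i = rng.integers(len(names), size=n_trans)
        j = rng.integers(len(names) - 1, size=n_trans)
        j = np.where(j >= i, j + 1, j)
        frames.append(
            pd.DataFrame(
                {
                    "ref1": np.array(names, dtype=object)[i],
                    "pos1": (rng.random(n_trans) * lengths[i]).astype(np.int64),
                    "strand1": np.where(rng.random(n_trans) < 0.5, "+", "-"),
                    "ref2": np.array(names, dtype=object)[j],
                    "pos2": (rng.random(n_trans) * lengths[j]).astype(np.int64),
                    "strand2": np.where(rng.random(n_trans) < 0.5, "+", "-"),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)

    dup_flags = np.zeros(n, dtype=bool)
    if n_dup:
        src = rng.integers(n_real, size=n_dup)
        df = pd.concat([df, df.iloc[src]], ignore_index=True)
        dup_flags[n_real:] = True

    contacts = ContactSet(df[_COLUMNS], ref_lengths)
    return contacts, TruthBundle(duplicate_flags=dup_flags)


def plant_misjoin(
    layout: ScaffoldLayout, rng_or_seed=0
) -> tuple[ScaffoldLayout, TruthBundle]:
    """Concatenate two randomly chosen unlinked contigs into one scaffold.

    The junction position (length of the first contig's placed span) is
    recorded as the planted misjoin; base content is conserved.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    singles = [
        s for s in layout.scaffolds
        if len(s.components) == 1 and isinstance(s.components[0], ContigSpan)
    ]
    if len(singles) < 2:
        raise ValueError("need at least two single-contig scaffolds to plant a misjoin")
    idx = rng.choice(len(singles), size=2, replace=False)
    first, second = singles[int(idx[0])], singles[int(idx[1])]
    joined_name = f"{first.name}_{second.name}_misjoin"
    joined = Scaffold(joined_name, [first.components[0], second.components[0]])
    others = [s for s in layout.scaffolds if s.name not in (first.name, second.name)]
    new_layout = ScaffoldLayout([joined, *others], dict(layout.contigs))
    junction = Breakpoint(joined_name, first.components[0].length)
    return new_layout, TruthBundle(misjoin_breakpoints=[junction])


def simulate_depth(
    ref_lengths: dict[str, int], config: SimConfig
) -> tuple[DepthTrack, TruthBundle]:
    """Per-base i.i.d. depths with moments (mean, var): negative binomial
    when var > mean, Poisson when var == mean. Run-length encoded."""
    if min(ref_lengths.values(), default=0) <= 0:
        raise ValueError("all reference lengths must be positive")
    if config.depth_mean <= 0:
        raise ValueError("depth mean must be > 0")
    rng = np.random.default_rng(config.seed)
    mu, v = config.depth_mean, config.depth_var
    runs = {}
    for ref, length in ref_lengths.items():
        if v == mu:
            d = rng.poisson(mu, size=length)
        else:
            p = mu / v
            r = mu * mu / (v - mu)
            d = rng.negative_binomial(r, p, size=length)
        change = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [length]))
        runs[ref] = (starts, ends, d[starts])
    return DepthTrack(runs), TruthBundle()


def simulate_phased_blocks(
    truth: TruthPhase, config: SimConfig
) -> tuple[list[PhasedBlock], TruthBundle]:
    """Partition truth sites into fixed-length blocks and plant errors.

    Within each block, assignments start from truth (haplotype 0 = parent
    A); each adjacency independently toggles the running orientation with
    probability switch_rate and each site independently flips with
    probability mismatch_rate. Every planted event is recorded.
    """
    rng = np.random.default_rng(config.seed)
    entries = sorted(truth.items())
    if not entries:
        raise ValueError("empty truth table")
    bundle = TruthBundle(het_truth=truth)
    blocks: list[PhasedBlock] = []
    L = config.block_length
    for b0 in range(0, len(entries), L):
        chunk = entries[b0:b0 + L]
        m = len(chunk)
        toggles = rng.random(m - 1) < config.switch_rate if m > 1 else np.zeros(0, bool)
        orientation = np.concatenate(([0], np.cumsum(toggles.astype(np.int8)) % 2))
        flips = rng.random(m) < config.mismatch_rate
        hap = orientation ^ flips.astype(np.int8)  # 0: hap0=alleleA
        sites = []
        block_id = f"ps{b0 // L}"
        for k, ((ref, pos), (a, b)) in enumerate(chunk):
            h0, h1 = (a, b) if hap[k] == 0 else (b, a)
            sites.append(PhasedSite(ref, pos, h0, h1))
            if flips[k]:
                bundle.mismatch_sites.append((ref, pos))
            if k and toggles[k - 1]:
                bundle.switch_adjacencies.append((ref, pos))
        blocks.append(PhasedBlock(block_id, sites))
    return blocks, bundle


def simulate_annotation(
    ref_lengths: dict[str, int],
    config: SimConfig,
    n_features: int = 100,
    types: tuple[str, ...] = ("CDS", "exon", "tRNA"),
    feature_length: tuple[int, int] = (200, 2_000),
) -> list[Feature]:
    """Non-overlapping features of the given types placed uniformly."""
    rng = np.random.default_rng(config.seed)
    names = list(ref_lengths)
    features: list[Feature] = []
    occupied: dict[str, list[tuple[int, int]]] = {r: [] for r in names}
    attempts = 0
    while len(features) < n_features and attempts < n_features * 50:
        attempts += 1
        ref = names[int(rng.integers(len(names)))]
        length = int(rng.integers(feature_length[0], feature_length[1] + 1))
        if length >= ref_lengths[ref]:
            continue
        start = int(rng.integers(ref_lengths[ref] - length))
        end = start + length
        if any(s < end and start < e for s, e in occupied[ref]):
            continue
        occupied[ref].append((start, end))
        ftype = types[int(rng.integers(len(types)))]
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(Feature(ref, start, end, strand, ftype, f"f{len(features) + 1}"))
    return sorted(features, key=lambda f: (f.ref, f.start))


# ---------------------------------------------------------------------------
# Composite benchmarks


@dataclass
class MisjoinBenchmark:
    layout: ScaffoldLayout
    contacts: ContactSet
    planted_junction: Breakpoint
    control_junction: Breakpoint


def misjoin_benchmark(
    seed: int,
    contig_length: int = 3_000_000,
    pairs_per_contig: int = 200_000,
    trans_rate: float = 0.01,
    filler_length: int = 1_000_000,
    alpha: float = 1.0,
) -> MisjoinBenchmark:
    """Planted-misjoin benchmark with a true-junction control.

    True sequences: two unlinked contigs A and B (contig_length each), one
    contiguous control sequence C of twice that length, and two short
    unlinked filler contigs that anchor the false-join null. Contacts are
    simulated on the true sequences (cis decay within each, uniform trans
    between pairs) and lifted onto an assembly layout in which A and B are
    wrongly concatenated into one scaffold and C is correctly represented as
    two adjacent contigs in another.
    """
    true_lengths = {
        "tA": contig_length,
        "tB": contig_length,
        "tC": 2 * contig_length,
        "tD": filler_length,
        "tE": filler_length,
    }
    density = pairs_per_contig / contig_length
    n_cis = int(round(sum(true_lengths.values()) * density))
    cfg = SimConfig(
        seed=seed, alpha=alpha, trans_rate=trans_rate, dup_rate=0.0,
        min_separation=1_000,
    )
    contacts, _ = simulate_contacts(true_lengths, cfg, n_pairs=n_cis)

    # assembly layout: A+B misjoined; C as two adjacent contigs (true join)
    L = contig_length
    layout = ScaffoldLayout(
        [
            Scaffold("scaffold_mis", [ContigSpan("ctgA", 0, L, "+"),
                                      ContigSpan("ctgB", 0, L, "+")]),
            Scaffold("scaffold_ctrl", [ContigSpan("ctgC1", 0, L, "+"),
                                       ContigSpan("ctgC2", 0, L, "+")]),
            Scaffold("scaffold_d", [ContigSpan("ctgD", 0, filler_length, "+")]),
            Scaffold("scaffold_e", [ContigSpan("ctgE", 0, filler_length, "+")]),
        ],
        {
            "ctgA": Contig("ctgA", L), "ctgB": Contig("ctgB", L),
            "ctgC1": Contig("ctgC1", L), "ctgC2": Contig("ctgC2", L),
            "ctgD": Contig("ctgD", filler_length),
            "ctgE": Contig("ctgE", filler_length),
        },
    )
    placement = {  # true ref -> (scaffold, offset)
        "tA": ("scaffold_mis", 0),
        "tB": ("scaffold_mis", L),
        "tC": ("scaffold_ctrl", 0),
        "tD": ("scaffold_d", 0),
        "tE": ("scaffold_e", 0),
    }
    df = contacts.df.copy()
    scaf_map = {r: p[0] for r, p in placement.items()}
    off_map = {r: p[1] for r, p in placement.items()}
    for side in ("1", "2"):
        refs = df[f"ref{side}"]
        df[f"pos{side}"] = df[f"pos{side}"] + refs.map(off_map)
        df[f"ref{side}"] = refs.map(scaf_map)
    lifted = ContactSet(df, layout.reference_lengths())
    return MisjoinBenchmark(
        layout=layout,
        contacts=lifted,
        planted_junction=Breakpoint("scaffold_mis", L),
        control_junction=Breakpoint("scaffold_ctrl", L),
    )


def phasing_benchmark(
    n_sites: int,
    block_length: int,
    switch_rate: float,
    mismatch_rate: float,
    seed: int,
    spacing: int = 150,
) -> tuple[list[PhasedBlock], TruthPhase, TruthBundle]:
    """Phased blocks over n_sites synthetic het sites with planted errors."""
    rng = np.random.default_rng(seed)
    gaps = rng.integers(1, 2 * spacing, size=n_sites)
    positions = np.cumsum(gaps)
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    idx_a = rng.integers(4, size=n_sites)
    idx_b = (idx_a + rng.integers(1, 4, size=n_sites)) % 4  # always != idx_a
    truth = TruthPhase(
        {
            ("chr1", int(p)): (bases[ia], bases[ib])
            for p, ia, ib in zip(positions, idx_a, idx_b)
        }
    )
    cfg = SimConfig(
        seed=seed + 1, block_length=block_length,
        switch_rate=switch_rate, mismatch_rate=mismatch_rate,
    )
    blocks, bundle = simulate_phased_blocks(truth, cfg)
    return blocks, truth, bundle


# ---------------------------------------------------------------------------
# Writers


def write_fasta(sequences: dict[str, str], stream, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, stream, "fasta")


def write_phased_vcf(blocks: list[PhasedBlock], truth: TruthPhase, stream,
                     depths: dict[tuple[str, int], int] | None = None) -> None:
    """Emit phased blocks as a minimal diploid VCF (GT with ``|``, PS tags).

    REF/ALT are the truth table's alleleA/alleleB; GT encodes which
    haplotype carries which.
    """
    refs = sorted({s.ref for b in blocks for s in b.sites})
    maxpos = {r: 0 for r in refs}
    for b in blocks:
        for s in b.sites:
            maxpos[s.ref] = max(maxpos[s.ref], s.pos + 1)
    stream.write("##fileformat=VCFv4.2\n")
    for r in refs:
        stream.write(f"##contig=<ID={r},length={maxpos[r] + 1}>\n")
    stream.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    stream.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
    stream.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
    rows = []
    for bi, b in enumerate(blocks):
        ps = b.sites[0].pos + 1
        for s in b.sites:
            t = truth.get(s.ref, s.pos)
            ref_allele, alt_allele = (t if t is not None else (s.hap0, s.hap1))
            gt0 = 0 if s.hap0 == ref_allele else 1
            dp = (depths or {}).get((s.ref, s.pos), 30)
            rows.append(
                (s.ref, s.pos,
                 f"{s.ref}\t{s.pos + 1}\t.\t{ref_allele}\t{alt_allele}\t.\tPASS\t.\t"
                 f"GT:PS:DP\t{gt0}|{1 - gt0}:{ps}:{dp}\n")
            )
    for _, _, line in sorted(rows, key=lambda r: (r[0], r[1])):
        stream.write(line)
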