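import numpy as np
import pytest

from scaffcheck.assembly import Contig, ContigSpan, Gap, Scaffold, ScaffoldLayout
from scaffcheck.pairs import ContactSet, DepthTrack


@pytest.fixture
def gapped_layout() -> ScaffoldLayout:
    """One scaffold: 1000 bp contig + 100 bp gap + 500 bp contig."""
    return ScaffoldLayout(
        [
            Scaffold(
                "s1",
                [ContigSpan("c1", 0, 1000, "+"), Gap(100), ContigSpan("c2", 0, 500, "+")],
            )
        ]
    )


@pytest.fixture
def mixed_layout() -> ScaffoldLayout:
    """Two scaffolds mixing orientations and a partial span; <=10 kb."""
    return ScaffoldLayout(
        [
            Scaffold(
                "sA",
                [
                    ContigSpan("x", 0, 700, "+"),
                    Gap(50),
                    ContigSpan("y", 100, 400, "-"),
                ],
            ),
            Scaffold("sB", [ContigSpan("z", 0, 1200, "-")]),
        ],
        {"x": Contig("x", 700), "y": Contig("y", 500), "z": Contig("z", 1200)},
    )


@pytest.fixture
def two_ref_contacts() -> ContactSet:
    refs = {"chrA": 1000, "chrB": 800}
    records = [
        ("chrA", 10, "+", "chrA", 500, "-"),
        ("chrA", 10, "+", "chrB", 5, "+"),
        ("chrB", 100, "-", "chrB", 700, "+"),
    ]
    return ContactSet.from_records(records, refs)


@pytest.fixture
def flat_track() -> DepthTrack:
    return DepthTrack.from_runs([("r", 0, 1000, 5)])
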