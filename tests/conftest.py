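import numpy as np
import pytest

from poolscreen import (
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    SampleInfo,
)


@pytest.fixture
def tiny_library() -> GuideLibrary:
    """Three genes x two sets plus two safe harbors, fixed hand-written spacers."""
    # fixed arbitrary 20-mers; none is the reverse complement of another
    rows = [
        ("TP53_SET1", "TP53", "ATCATGTAAAGATAACTGTC", "SET1", False),
        ("TP53_SET2", "TP53", "ACGTTTTACGGATGAGGAAA", "SET2", False),
        ("BRCA1_SET1", "BRCA1", "TTGTTTCAACACAATGGAAT", "SET1", False),
        ("BRCA1_SET2", "BRCA1", "AACCCCAGCCCAGGGCAAGG", "SET2", False),
        ("EGFR_SET1", "EGFR", "CAGCACTCCGTAAGCGACGG", "SET1", False),
        ("EGFR_SET2", "EGFR", "AGCAGTCCACCCATTTATTG", "SET2", False),
        ("SH0001", "SAFE_HARBOR", "GCACGCGGTCTCCCTTCCGA", "CONTROL", True),
        ("SH0002", "SAFE_HARBOR", "TGACACCAACGGCTCCGCCC", "CONTROL", True),
    ]
    return GuideLibrary(
        [GuideRecord(g, gene, sp, s, sh) for g, gene, sp, s, sh in rows]
    )


@pytest.fixture
def samples_3v2() -> list[SampleInfo]:
    return [
        SampleInfo("d0_r1", "baseline", "Day0", 1),
        SampleInfo("d0_r2", "baseline", "Day0", 2),
        SampleInfo("d0_r3", "baseline", "Day0", 3),
        SampleInfo("d20_r1", "selected", "Day20", 1),
        SampleInfo("d20_r2", "selected", "Day20", 2),
    ]


def make_matrix(library: GuideLibrary, samples, counts) -> CountMatrix:
    return CountMatrix(
        guide_ids=library.guide_ids,
        samples=list(samples),
        counts=np.asarray(counts),
    )
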