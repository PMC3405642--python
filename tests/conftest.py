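import pytest

import mitomatch as mm

# The four worked screening examples: (sample, {locus: allele},
# (class label, haplogroup, matched, total)).
WORKED_EXAMPLES = {
    "ad_person": (
        dict(zip([709, 4833, 5108, 5601, 7600, 9377, 9575, 13563, 14569,
                  16362, 16519], "AGCTAGAGACC")),
        ("AD patients", "G2a", 11, 13),
    ),
    "pd_person": (
        dict(zip([204, 709, 1598, 8584, 9950, 12358, 12361, 15223, 15927,
                  16140], "CAAACGGTAC")),
        ("PD patients", "B5b", 10, 12),
    ),
    "t2d_person": (
        dict(zip([194, 1382, 3010, 4883, 5178, 8020, 8414, 8964, 9824,
                  14668, 16519], "TCATAATTATC")),
        ("T2D patients", "D4b2b", 11, 13),
    ),
    "cent_person": (
        dict(zip([199, 1382, 3010, 4883, 5178, 8020, 8414, 8964, 9824,
                  10104, 14668, 16362, 16519], "CCATAATTATTCC")),
        ("Centenarians", "D4b2a", 13, 15),
    ),
}


@pytest.fixture(scope="session")
def tables():
    return mm.load_packaged_tables()


@pytest.fixture(scope="session")
def reference():
    return mm.synthetic_rcrs()


@pytest.fixture
def worked_variant_sets():
    return {
        name: mm.VariantSet(name, calls)
        for name, (calls, _) in WORKED_EXAMPLES.items()
    }
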