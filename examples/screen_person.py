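"""Screen one person's mtDNA mutations against the packaged haplogroup tables.

Builds the documented type-2-diabetes worked example — eleven mutations at
known rCRS loci — and prints every (class, haplogroup) whose match ratio
exceeds the 0.8 decision threshold.  A flagged row means the person carries
most of that haplogroup's defining mutations, i.e. their mtDNA resembles the
profile observed in that study class.
"""

from mitomatch import VariantSet, diagnose, load_packaged_tables

person = VariantSet(
    "example_person",
    dict(zip(
        [194, 1382, 3010, 4883, 5178, 8020, 8414, 8964, 9824, 14668, 16519],
        "TCATAATTATC",
    )),
)

report = diagnose(person, load_packaged_tables())

print(f"sample: {report.sample_id}")
print("class\thaplogroup\tmatched/total\tratio\tflagged")
for entry in report.entries[:6]:
    print(
        f"{entry.class_label}\t{entry.haplogroup_name}\t"
        f"{entry.match.matched}/{entry.match.total}\t"
        f"{entry.rendered_ratio()}\t{'*' if entry.flagged else ''}"
    )
print()
for entry in report.flagged:
    print(
        f"flagged: {entry.haplogroup_name} ({entry.class_label}) — carries "
        f"{entry.match.matched} of {entry.match.total} defining mutations; "
        f"missing loci {list(entry.match.missing_loci)}"
    )
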