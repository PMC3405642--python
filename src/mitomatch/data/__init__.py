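"""Packaged haplogroup defining-SNP reference tables.

Eight study classes are shipped, one TSV per class: Alzheimer's disease (AD)
patients, Parkinson's disease (PD) patients, type 2 diabetes (T2D) patients,
T2D patients with angiopathy, centenarians, semi-supercentenarians, and
healthy non-obese / obese young males.  Each table lists, per haplogroup,
the defining mtDNA mutations (rCRS locus, normal allele, mutant allele).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..profiles import ProfileTable, load_profile_table

#: class label -> packaged TSV file name
PACKAGED_FILES: dict[str, str] = {
    "AD patients": "ad.tsv",
    "PD patients": "pd.tsv",
    "T2D patients": "t2d.tsv",
    "T2D patients with angiopathy": "t2d_angiopathy.tsv",
    "Centenarians": "centenarian.tsv",
    "Semi-supercentenarians": "semi_supercentenarian.tsv",
    "Non-obese young males": "nonobese_young_male.tsv",
    "Obese young males": "obese_young_male.tsv",
}


def packaged_table_path(class_label: str) -> Path:
    """Filesystem path of the packaged TSV for one study class."""
    fname = PACKAGED_FILES[class_label]
    return Path(resources.files(__package__) / fname)


def load_packaged_table(class_label: str) -> ProfileTable:
    return load_profile_table(packaged_table_path(class_label))


def load_packaged_tables() -> dict[str, ProfileTable]:
    """All eight packaged profile tables, keyed by class label."""
    return {label: load_packaged_table(label) for label in PACKAGED_FILES}
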