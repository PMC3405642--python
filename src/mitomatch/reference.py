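"""Reference-sequence helpers.

All coordinates in this package are 1-based rCRS positions over the
16,569-bp human mitochondrial genome.  Profile matching never needs the
reference sequence itself; it is used only to sanity-check profile tables
and to express individuals as variant sets relative to the reference.

Because the package must work without external downloads, ``synthetic_rcrs``
builds a SYNTHETIC stand-in of the reference: correct length, and at every
locus named by the packaged profile tables the table's normal allele; all
other positions are filled deterministically from a seeded generator.  It is
suitable for simulations and internal consistency checks, not for analysing
real genomes — supply the true rCRS via ``read_fasta`` for that.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .profiles import RCRS_LENGTH

_BASES = np.array(list("ACGT"))


def read_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file as an upper-case string."""
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValidationError(f"{path}: no FASTA records")
    return str(record.seq).upper()


def write_fasta(sequence: str, path: str | Path, name: str = "chrM") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def synthetic_rcrs(seed: int = 2012) -> str:
    """Deterministic synthetic mitochondrial reference (see module docstring).

    Normal alleles from every packaged profile table are planted at their
    loci, so ``validate_against_reference`` reports no mismatches for the
    packaged tables; remaining bases are arbitrary but fixed per seed.
    """
    from .data import load_packaged_tables  # deferred: data imports profiles

    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=RCRS_LENGTH)]
    for table in load_packaged_tables().values():
        for profile in table:
            for entry in profile:
                seq[entry.locus - 1] = entry.normal_allele
    return "".join(seq)
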