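"""Per-individual mtDNA variant sets.

A :class:`VariantSet` is the collection of single-nucleotide mutations one
person carries relative to the rCRS: for each mutated locus, the observed
(non-reference-style) nucleotide.  The model is a haploid consensus — one
allele per locus, no heteroplasmy, no indels.  Variants at loci absent from
every haplogroup profile are retained; they simply never match anything.

Readers are provided for a simple TSV (``sample  locus  allele``) and for a
minimal single-contig SNV-only VCF subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError
from .profiles import NUCLEOTIDES, RCRS_LENGTH

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSet:
    """One person's mtDNA mutations: locus -> observed allele (1-based rCRS)."""

    sample_id: str
    variants: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, allele in self.variants.items():
            if not 1 <= locus <= RCRS_LENGTH:
                raise ValidationError(
                    f"sample {self.sample_id}: locus {locus} outside 1..{RCRS_LENGTH}"
                )
            if allele not in NUCLEOTIDES:
                raise ValidationError(
                    f"sample {self.sample_id}: allele {allele!r} at {locus} "
                    "not one of A,C,G,T"
                )
        object.__setattr__(self, "variants", dict(self.variants))

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, item: object) -> bool:
        """Membership of a (locus, allele) pair or of a bare locus."""
        if isinstance(item, tuple):
            locus, allele = item
            return self.variants.get(locus) == allele
        return item in self.variants

    def allele_at(self, locus: int) -> str | None:
        return self.variants.get(locus)

    @property
    def loci(self) -> tuple[int, ...]:
        return tuple(sorted(self.variants))

    def as_pairs(self) -> set[tuple[int, str]]:
        return set(self.variants.items())


def _add_call(
    per_sample: dict[str, dict[int, str]], sample: str, locus: int, allele: str, where: str
) -> None:
    calls = per_sample.setdefault(sample, {})
    if locus in calls and calls[locus] != allele:
        raise ValidationError(
            f"{where}: sample {sample!r} has conflicting alleles "
            f"{calls[locus]}/{allele} at locus {locus}"
        )
    calls[locus] = allele


def read_variants_tsv(path: str | Path) -> list[VariantSet]:
    """Read variant sets from a ``sample  locus  allele`` TSV.

    One :class:`VariantSet` per distinct sample, in order of first
    appearance.  Duplicate (sample, locus) rows must agree on the allele.
    """
    import csv

    path = Path(path)
    per_sample: dict[str, dict[int, str]] = {}
    header_seen = False
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or not any(f.strip() for f in raw):
                continue
            if raw[0].lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in raw]
            if not header_seen:
                if [f.lower() for f in fields[:3]] != ["sample", "locus", "allele"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected header 'sample locus allele'"
                    )
                header_seen = True
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            sample, locus_s, allele = fields[0], fields[1], fields[2]
            try:
                locus = int(locus_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: locus {locus_s!r} is not an integer")
            if allele not in NUCLEOTIDES:
                raise ValidationError(
                    f"{path}:{lineno}: allele {allele!r} not one of A,C,G,T"
                )
            _add_call(per_sample, sample, locus, allele, f"{path}:{lineno}")
    if not header_seen:
        raise ParseError(f"{path}: empty file (no header row)")
    return [VariantSet(sample, calls) for sample, calls in per_sample.items()]


def write_variants_tsv(variant_sets: Iterable[VariantSet], path: str | Path) -> None:
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "locus", "allele"])
        for vs in variant_sets:
            for locus in vs.loci:
                writer.writerow([vs.sample_id, locus, vs.variants[locus]])


def read_variants_vcf(
    path: str | Path, *, return_skipped: bool = False
) -> list[VariantSet] | tuple[list[VariantSet], int]:
    """Read variant sets from a minimal mitochondrial VCF.

    SNV records only; indels, non-ACGT alleles and records whose FILTER is
    neither PASS nor '.' are skipped and counted.  Multiallelic records are
    expanded per ALT.  A sample carries an ALT allele when any GT allele
    index points at it (haploid or diploid GT both accepted).

    With ``return_skipped=True`` returns ``(variant_sets, n_skipped)``;
    the skip count is always logged.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError(f"{path}: VCF has no sample columns")

    per_sample: dict[str, dict[int, str]] = {s: {} for s in samples}
    skipped = 0
    for record in vcf:
        if record.FILTER is not None:  # cyvcf2: None means PASS or '.'
            skipped += 1
            continue
        ref = record.REF.upper()
        alts = [a.upper() for a in (record.ALT or [])]
        if len(ref) != 1 or ref not in NUCLEOTIDES or not alts:
            skipped += 1
            continue
        usable = {
            i + 1: alt
            for i, alt in enumerate(alts)
            if len(alt) == 1 and alt in NUCLEOTIDES
        }
        if not usable:
            skipped += 1
            continue
        for sample, genotype in zip(samples, record.genotypes):
            allele_indices = [g for g in genotype[:-1] if isinstance(g, int) and g > 0]
            for idx in allele_indices:
                if idx in usable:
                    _add_call(
                        per_sample, sample, record.POS, usable[idx],
                        f"{path} POS {record.POS}",
                    )
                    break
    vcf.close()
    if skipped:
        logger.info("%s: skipped %d non-SNV/filtered record(s)", path, skipped)
    sets = [VariantSet(s, calls) for s, calls in per_sample.items()]
    if return_skipped:
        return sets, skipped
    return sets


def variants_from_sequence(
    seq: str, reference: str, sample_id: str = "sample"
) -> VariantSet:
    """Variant set of a full-length sequence relative to a reference.

    Positions are 1-based; every position where the two sequences differ
    becomes a variant carrying the observed base.
    """
    if len(seq) != len(reference):
        raise ValidationError(
            f"sequence length {len(seq)} != reference length {len(reference)}"
        )
    seq = seq.upper()
    reference = reference.upper()
    calls = {
        i + 1: s for i, (s, r) in enumerate(zip(seq, reference)) if s != r
    }
    return VariantSet(sample_id, calls)
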