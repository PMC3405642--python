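"""Position summaries and haplogroup association for a selected subset.

Once the modified cluster (the top-scoring individuals) is in hand, two
questions follow.  First, *which loci vary* within the subset: each varying
locus is summarised in the field's ``locus N>M (Y/X)`` notation, where N is
the normal (reference) nucleotide, M the mutant nucleotide, Y the number of
subset members carrying M and X the number carrying N — ``16362 T>C (9/6)``
reads "at 16362, nine members carry the C mutation and six the normal T".
Second, *which haplogroups* the subset resembles: each member is assigned to
the best-matching profile of a class table (highest matched/size fraction),
and the report gives the percentage of the subset assigned to each
haplogroup.

The assignment here is a flat best-match over profile tables, not a
phylogenetic placement; macrohaplogroup paths are display labels only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .diagnosis import DiagnosisConfig, compute_match_ratio
from .errors import ValidationError
from .profiles import ProfileTable
from .variants import VariantSet

#: marker returned when a variant set matches nothing at all
NO_ASSIGNMENT = None


@dataclass(frozen=True)
class PositionSummary:
    """Allele tally at one varying locus of a subset."""

    locus: int
    normal_allele: str
    mutant_allele: str
    mutant_count: int   # Y
    normal_count: int   # X
    other_count: int = 0  # carriers of a third allele; outside Y and X

    def __post_init__(self) -> None:
        if self.mutant_count < 0 or self.normal_count < 0 or self.other_count < 0:
            raise ValidationError("counts must be nonnegative")

    def rendered(self) -> str:
        return (
            f"{self.locus} {self.normal_allele}>{self.mutant_allele} "
            f"({self.mutant_count}/{self.normal_count})"
        )


def summarize_positions(
    subset: Sequence[VariantSet], reference: str
) -> list[PositionSummary]:
    """Tally alleles at every locus where at least one member is mutated.

    Members without a variant at a locus count as carrying the reference
    base (variant sets are relative to the reference).  When more than one
    mutant allele occurs at a locus, one summary is emitted per mutant
    allele; carriers of the *other* mutant alleles fall into
    ``other_count``, keeping the (Y/X) semantics exact.
    """
    if not subset:
        raise ValidationError("subset is empty")
    loci: set[int] = set()
    for vs in subset:
        loci.update(vs.variants)
    out: list[PositionSummary] = []
    n = len(subset)
    for locus in sorted(loci):
        normal = reference[locus - 1].upper()
        carriers: dict[str, int] = {}
        for vs in subset:
            allele = vs.allele_at(locus)
            if allele is not None and allele != normal:
                carriers[allele] = carriers.get(allele, 0) + 1
        if not carriers:
            continue
        n_mutated = sum(carriers.values())
        normal_count = n - n_mutated
        for allele in sorted(carriers):
            out.append(
                PositionSummary(
                    locus, normal, allele,
                    mutant_count=carriers[allele],
                    normal_count=normal_count,
                    other_count=n_mutated - carriers[allele],
                )
            )
    return out


def variantsets_from_matrix(matrix, reference: str) -> list[VariantSet]:
    """View genotype-matrix rows as variant sets relative to the reference.

    Missing codes are treated as reference calls (the matrix has no
    explicit no-call concept once decoded)."""
    from .rbf import decode_genotypes

    letters = decode_genotypes(matrix)
    sets = []
    for sample_id, row in letters.iterrows():
        calls = {
            int(locus): str(base)
            for locus, base in row.items()
            if str(base) in "ACGT" and str(base) != reference[int(locus) - 1].upper()
        }
        sets.append(VariantSet(str(sample_id), calls))
    return sets


def assign_haplogroup(
    v: VariantSet, table: ProfileTable, config: DiagnosisConfig | None = None
) -> tuple[str | None, Fraction]:
    """Best-matching haplogroup of one table and its match fraction.

    Ties prefer the larger profile, then lexicographic name order.  An empty
    variant set (or a zero match everywhere) yields ``(None, 0)``.
    """
    if len(table) == 0:
        raise ValidationError("profile table has no profiles")
    best: tuple[Fraction, int, str] | None = None
    for profile in table:
        ratio = compute_match_ratio(v, profile, config).ratio
        name, size = profile.haplogroup_name, profile.size
        if (
            best is None
            or ratio > best[0]
            or (ratio == best[0] and size > best[1])
            or (ratio == best[0] and size == best[1] and name < best[2])
        ):
            best = (ratio, size, name)
    assert best is not None
    if best[0] == 0:
        return NO_ASSIGNMENT, Fraction(0)
    return best[2], best[0]


def _round_percent(fraction: Fraction) -> int:
    """Whole-percent rounding, half away from zero (8/15 -> 53, 3/15 -> 20)."""
    d = Decimal(fraction.numerator * 100) / Decimal(fraction.denominator)
    return int(d.quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssociationEntry:
    haplogroup_name: str
    n_assigned: int
    percent: int


@dataclass(frozen=True)
class AssociationReport:
    """Haplogroup composition of a subset, descending percentage."""

    class_label: str
    subset_size: int
    entries: tuple[AssociationEntry, ...]
    n_unassigned: int

    def __post_init__(self) -> None:
        if sum(e.n_assigned for e in self.entries) + self.n_unassigned != self.subset_size:
            raise ValidationError("assigned + unassigned must equal subset size")

    def percent_of(self, haplogroup_name: str) -> int:
        for e in self.entries:
            if e.haplogroup_name == haplogroup_name:
                return e.percent
        return 0

    @property
    def modal_haplogroup(self) -> str | None:
        return self.entries[0].haplogroup_name if self.entries else None


def associate_subset(
    subset: Sequence[VariantSet],
    table: ProfileTable,
    min_fraction: float = 0.5,
    config: DiagnosisConfig | None = None,
) -> AssociationReport:
    """Assign each subset member to its best haplogroup (if the match
    fraction reaches ``min_fraction``) and report percentages of the subset.

    Percentages are rounded to whole percent; members below the cutoff are
    counted as unassigned.
    """
    if not subset:
        raise ValidationError("subset is empty")
    cutoff = Fraction(str(min_fraction))
    counts: dict[str, int] = {}
    unassigned = 0
    for vs in subset:
        name, fraction = assign_haplogroup(vs, table, config)
        if name is not None and fraction >= cutoff:
            counts[name] = counts.get(name, 0) + 1
        else:
            unassigned += 1
    n = len(subset)
    entries = tuple(
        AssociationEntry(name, k, _round_percent(Fraction(k, n)))
        for name, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return AssociationReport(table.class_label, n, entries, unassigned)


def write_association_tsv(
    report: AssociationReport, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """TSV with columns haplogroup, percent, n_assigned, subset_size."""
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("haplogroup\tpercent\tn_assigned\tsubset_size\n")
        for e in report.entries:
            fh.write(
                f"{e.haplogroup_name}\t{e.percent}\t{e.n_assigned}\t{report.subset_size}\n"
            )
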