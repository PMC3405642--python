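"""Match-ratio screening of a person's mtDNA mutations against haplogroup
profiles.

The statistic is deliberately simple: for a haplogroup with k defining
mutations, the ratio is (number of those mutations the person carries) / k,
kept as an exact rational.  A ratio strictly greater than the decision
threshold (default 0.8) flags the person as resembling the haplogroup's
study class — e.g. carrying 11 of the 13 G2a-defining mutations gives
11/13 ~ 0.846 and a flag against the Alzheimer's-patient table.  Mutations
outside the profile never affect the ratio, and the denominator counts every
profile entry, including two entries at one locus with different alleles.

This is an initial screen, not a calibrated clinical probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .profiles import HaplogroupProfile, ProfileEntry, ProfileTable
from .variants import VariantSet


@dataclass(frozen=True)
class DiagnosisConfig:
    """Decision threshold (strict) and allele-matching strictness.

    With ``require_allele_match`` (the default) a profile entry counts as
    matched only when the person's allele at the locus equals the entry's
    mutant allele; otherwise any non-reference call at the locus counts.
    """

    threshold: float = 0.8
    require_allele_match: bool = True

    def __post_init__(self) -> None:
        if not 0 < float(self.threshold) < 1:
            raise ValidationError("threshold must be in (0, 1)")

    @property
    def threshold_fraction(self) -> Fraction:
        # via str() so 0.8 means the decimal 8/10, not the nearest binary float
        return Fraction(str(self.threshold))


def render_ratio(ratio: Fraction, decimals: int = 3) -> str:
    """Exact rational rendered at fixed decimals, round-half-away-from-zero
    (11/13 -> '0.846', 13/15 -> '0.867', 10/12 -> '0.833')."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(ratio.numerator) / Decimal(ratio.denominator)
    return str(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one person against one profile."""

    matched: int
    total: int
    matched_entries: tuple[ProfileEntry, ...]
    missing_entries: tuple[ProfileEntry, ...]

    @property
    def ratio(self) -> Fraction:
        return Fraction(self.matched, self.total)

    @property
    def matched_loci(self) -> tuple[int, ...]:
        return tuple(e.locus for e in self.matched_entries)

    @property
    def missing_loci(self) -> tuple[int, ...]:
        return tuple(e.locus for e in self.missing_entries)


def compute_match_ratio(
    v: VariantSet, profile: HaplogroupProfile, config: DiagnosisConfig | None = None
) -> MatchResult:
    """Count profile entries present in the variant set.

    Returns matched count, profile size and the exact ratio (plus the
    matched/missing entries for reporting).  The person's mutations outside
    the profile are ignored.
    """
    config = config or DiagnosisConfig()
    matched: list[ProfileEntry] = []
    missing: list[ProfileEntry] = []
    for entry in profile:
        allele = v.allele_at(entry.locus)
        if allele is None:
            hit = False
        elif config.require_allele_match:
            hit = allele == entry.mutant_allele
        else:
            hit = allele != entry.normal_allele
        (matched if hit else missing).append(entry)
    return MatchResult(len(matched), profile.size, tuple(matched), tuple(missing))


@dataclass(frozen=True)
class DiagnosisEntry:
    """One (study class, haplogroup) row of a person's report."""

    class_label: str
    haplogroup_name: str
    match: MatchResult
    flagged: bool

    @property
    def ratio(self) -> Fraction:
        return self.match.ratio

    def rendered_ratio(self, decimals: int = 3) -> str:
        return render_ratio(self.ratio, decimals)


@dataclass(frozen=True)
class DiagnosisReport:
    sample_id: str
    entries: tuple[DiagnosisEntry, ...] = field(default=())  # descending ratio

    @property
    def flagged(self) -> tuple[DiagnosisEntry, ...]:
        return tuple(e for e in self.entries if e.flagged)

    @property
    def best(self) -> "DiagnosisEntry | None":
        return self.entries[0] if self.entries else None

    def entry_for(self, class_label: str, haplogroup_name: str) -> DiagnosisEntry:
        for e in self.entries:
            if e.class_label == class_label and e.haplogroup_name == haplogroup_name:
                return e
        raise KeyError((class_label, haplogroup_name))


def diagnose(
    v: VariantSet,
    tables: Iterable[ProfileTable] | Mapping[str, ProfileTable],
    config: DiagnosisConfig | None = None,
) -> DiagnosisReport:
    """Match one person against every haplogroup of every table.

    Entries are sorted by descending ratio (ties: class label then
    haplogroup name); flagged entries have ratio strictly greater than the
    threshold, compared in exact rational arithmetic.
    """
    config = config or DiagnosisConfig()
    if isinstance(tables, Mapping):
        tables = tables.values()
    tables = list(tables)
    if not tables:
        raise ValidationError("no profile tables given")
    cutoff = config.threshold_fraction
    entries: list[DiagnosisEntry] = []
    for table in tables:
        for profile in table:
            match = compute_match_ratio(v, profile, config)
            entries.append(
                DiagnosisEntry(
                    table.class_label,
                    profile.haplogroup_name,
                    match,
                    match.ratio > cutoff,
                )
            )
    entries.sort(key=lambda e: (-e.ratio, e.class_label, e.haplogroup_name))
    return DiagnosisReport(v.sample_id, tuple(entries))


def diagnose_batch(
    variant_sets: Sequence[VariantSet],
    tables: Iterable[ProfileTable] | Mapping[str, ProfileTable],
    config: DiagnosisConfig | None = None,
) -> list[DiagnosisReport]:
    """Independent per-sample reports, input order preserved."""
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    else:
        tables = list(tables)
    reports = []
    for v in variant_sets:
        try:
            reports.append(diagnose(v, tables, config))
        except Exception as exc:
            raise type(exc)(f"sample {v.sample_id!r}: {exc}") from exc
    return reports


def write_diagnosis_tsv(
    reports: Sequence[DiagnosisReport], path: str | Path,
    decimals: int = 3, header_lines: Sequence[str] = (),
) -> None:
    """Report TSV: sample, class, haplogroup, matched, total, ratio,
    flagged, missing_loci."""
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample\tclass\thaplogroup\tmatched\ttotal\tratio\tflagged\tmissing_loci\n")
        for report in reports:
            for e in report.entries:
                missing = ",".join(str(l) for l in e.match.missing_loci)
                fh.write(
                    f"{report.sample_id}\t{e.class_label}\t{e.haplogroup_name}\t"
                    f"{e.match.matched}\t{e.match.total}\t"
                    f"{e.rendered_ratio(decimals)}\t{str(e.flagged).lower()}\t{missing}\n"
                )


def reports_to_json(reports: Sequence[DiagnosisReport], decimals: int = 3) -> list[dict]:
    return [
        {
            "sample": r.sample_id,
            "entries": [
                {
                    "class": e.class_label,
                    "haplogroup": e.haplogroup_name,
                    "matched": e.match.matched,
                    "total": e.match.total,
                    "ratio": e.rendered_ratio(decimals),
                    "flagged": e.flagged,
                    "missing_loci": list(e.match.missing_loci),
                }
                for e in r.entries
            ],
        }
        for r in reports
    ]
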