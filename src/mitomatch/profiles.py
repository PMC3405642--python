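"""Haplogroup defining-SNP profile tables.

A *profile* is the set of mtDNA mutations that characterises one haplogroup
within one study class (e.g. the G2a profile observed among Alzheimer's
disease patients).  Each entry is a (locus, normal allele, mutant allele)
triple in 1-based rCRS coordinates.  Profiles are flat sets — no phylogenetic
hierarchy is modelled — and a locus may legitimately appear twice in one
profile with different mutant alleles; both entries count toward the profile
size, which is the denominator of the match-ratio diagnostic.

On disk a profile table is a TSV with columns ``locus  normal  mutant
haplogroup``, a header row, ``#`` comment lines, and the study class recorded
in a ``# class: <label>`` metadata line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError, ValidationError

RCRS_LENGTH = 16569
NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class ProfileEntry:
    """One defining mutation: rCRS locus, normal (reference) allele, mutant allele."""

    locus: int
    normal_allele: str
    mutant_allele: str

    def __post_init__(self) -> None:
        if not 1 <= self.locus <= RCRS_LENGTH:
            raise ValidationError(
                f"locus {self.locus} outside rCRS range 1..{RCRS_LENGTH}"
            )
        for name in ("normal_allele", "mutant_allele"):
            allele = getattr(self, name)
            if allele not in NUCLEOTIDES:
                raise ValidationError(f"{name} {allele!r} not one of A,C,G,T")
        if self.normal_allele == self.mutant_allele:
            raise ValidationError(
                f"locus {self.locus}: normal and mutant allele both {self.normal_allele}"
            )


@dataclass(frozen=True)
class HaplogroupProfile:
    """Defining-SNP set of one haplogroup for one study class."""

    haplogroup_name: str
    class_label: str
    entries: tuple[ProfileEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(
                f"profile {self.haplogroup_name!r} has no entries"
            )
        pairs = [(e.locus, e.mutant_allele) for e in self.entries]
        if len(pairs) != len(set(pairs)):
            raise ValidationError(
                f"profile {self.haplogroup_name!r} repeats a (locus, mutant) pair"
            )

    @property
    def size(self) -> int:
        """Number of defining mutations (the match-ratio denominator)."""
        return len(self.entries)

    @property
    def loci(self) -> tuple[int, ...]:
        return tuple(e.locus for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ProfileEntry]:
        return iter(self.entries)


@dataclass(frozen=True)
class ProfileTable:
    """All haplogroup profiles of one study class."""

    class_label: str
    profiles: tuple[HaplogroupProfile, ...] = field(default=())

    def __post_init__(self) -> None:
        names = [p.haplogroup_name for p in self.profiles]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"duplicate haplogroup names in table {self.class_label!r}"
            )
        for p in self.profiles:
            if p.class_label != self.class_label:
                raise ValidationError(
                    f"profile {p.haplogroup_name!r} carries class "
                    f"{p.class_label!r}, table is {self.class_label!r}"
                )

    def __iter__(self) -> Iterator[HaplogroupProfile]:
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def haplogroup_names(self) -> tuple[str, ...]:
        return tuple(p.haplogroup_name for p in self.profiles)

    def get(self, haplogroup_name: str) -> HaplogroupProfile:
        for p in self.profiles:
            if p.haplogroup_name == haplogroup_name:
                return p
        raise KeyError(haplogroup_name)

    def __getitem__(self, haplogroup_name: str) -> HaplogroupProfile:
        return self.get(haplogroup_name)


_COLUMNS = ("locus", "normal", "mutant", "haplogroup")


def load_profile_table(path: str | Path, class_label: str | None = None) -> ProfileTable:
    """Read a profile table TSV.

    The class label is taken from a ``# class: <label>`` comment line unless
    given explicitly.  Haplogroup order and entry order follow the file.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    file_class: str | None = None
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or not any(f.strip() for f in raw):
                continue
            if raw[0].lstrip().startswith("#"):
                text = "\t".join(raw).lstrip("# ").strip()
                if text.lower().startswith("class:"):
                    file_class = text.split(":", 1)[1].strip()
                continue
            if header is None:
                header = [f.strip() for f in raw]
                if tuple(header) != _COLUMNS:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {_COLUMNS}, got {tuple(header)}"
                    )
                continue
            rows.append((lineno, [f.strip() for f in raw]))
    if header is None:
        raise ParseError(f"{path}: empty file (no header row)")
    label = class_label if class_label is not None else file_class
    if label is None:
        raise ParseError(f"{path}: no '# class:' line and no class_label given")

    by_haplogroup: dict[str, list[ProfileEntry]] = {}
    seen: set[tuple[str, int, str]] = set()
    for lineno, fields in rows:
        if len(fields) != len(_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} columns, got {len(fields)}"
            )
        locus_s, normal, mutant, hap = fields
        try:
            locus = int(locus_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: locus {locus_s!r} is not an integer")
        try:
            entry = ProfileEntry(locus, normal, mutant)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        key = (hap, locus, mutant)
        if key in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate entry {hap} {locus} {mutant}"
            )
        seen.add(key)
        by_haplogroup.setdefault(hap, []).append(entry)

    profiles = tuple(
        HaplogroupProfile(name, label, tuple(entries))
        for name, entries in by_haplogroup.items()
    )
    return ProfileTable(class_label=label, profiles=profiles)


def write_profile_table(table: ProfileTable, path: str | Path) -> None:
    """Write a profile table TSV; ``load_profile_table`` round-trips it exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        fh.write(f"# class: {table.class_label}\n")
        writer.writerow(_COLUMNS)
        for profile in table:
            for e in profile:
                writer.writerow(
                    [e.locus, e.normal_allele, e.mutant_allele, profile.haplogroup_name]
                )


@dataclass(frozen=True)
class ReferenceMismatch:
    """A profile entry whose normal allele disagrees with the reference base."""

    haplogroup_name: str
    locus: int
    normal_allele: str
    reference_base: str


def validate_against_reference(
    table: ProfileTable, reference: str
) -> list[ReferenceMismatch]:
    """Check every entry's normal allele against the reference sequence.

    Returns the mismatching entries; an empty list means the table is
    consistent with the reference.
    """
    if len(reference) != RCRS_LENGTH:
        raise ValidationError(
            f"reference length {len(reference)} != {RCRS_LENGTH}"
        )
    mismatches = []
    for profile in table:
        for e in profile:
            base = reference[e.locus - 1].upper()
            if base != e.normal_allele:
                mismatches.append(
                    ReferenceMismatch(
                        profile.haplogroup_name, e.locus, e.normal_allele, base
                    )
                )
    return mismatches


def merge_tables(tables: Iterable[ProfileTable]) -> dict[str, ProfileTable]:
    """Index tables by class label, rejecting duplicates."""
    out: dict[str, ProfileTable] = {}
    for t in tables:
        if t.class_label in out:
            raise ValidationError(f"duplicate class label {t.class_label!r}")
        out[t.class_label] = t
    return out
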