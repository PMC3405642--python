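"""Synthetic mtDNA cohorts with planted haplogroup-class structure.

The generator emulates the study design the classifier was built for:
case-control style cohorts of ~96 individuals per class (112 for the
semi-supercentenarian analogue), where a stated share of each class carries
one haplogroup's defining mutations.  A carrier inherits each profile entry
independently with probability ``carrier_completeness`` (default 0.9 —
real carriers usually miss a defining mutation or two) and additionally
acquires ``Poisson(noise_rate)`` private mutations (default 3) at loci
outside its own profile, each with a random non-reference allele.
Individuals not covered by the haplogroup mixture are background: noise
mutations only.

Everything is a pure function of (spec, seed).  No mutation-rate model, no
phylogeny, no heteroplasmy, no sequencing error — the generator provides
separable planted structure, not population realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .association import associate_subset
from .errors import ValidationError
from .profiles import HaplogroupProfile, ProfileTable, RCRS_LENGTH
from .rbf import GenotypeMatrix, TrainConfig, encode_genotypes, train_rbf
from .selection import scores_for_matrix, select_modified_cluster
from .variants import VariantSet

_BASES = "ACGT"


@dataclass(frozen=True)
class ClassSpec:
    """One simulated class: label, size, and its haplogroup mixture.

    ``mixture`` maps haplogroup name -> proportion of the class sourced from
    that profile; proportions must sum to <= 1, the remainder being
    background individuals."""

    class_label: str
    n_individuals: int
    mixture: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        total = sum(p for _, p in self.mixture)
        if total > 1.0 + 1e-9:
            raise ValidationError(
                f"class {self.class_label!r}: mixture proportions sum to {total} > 1"
            )
        if any(p < 0 for _, p in self.mixture):
            raise ValidationError("mixture proportions must be nonnegative")


@dataclass(frozen=True)
class SimSpec:
    """Full cohort recipe; defaults mirror the study conditions."""

    classes: tuple[ClassSpec, ...]
    carrier_completeness: float = 0.9
    noise_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValidationError("at least one class required")
        if not 0.0 <= self.carrier_completeness <= 1.0:
            raise ValidationError("carrier_completeness must be in [0, 1]")
        if self.noise_rate < 0:
            raise ValidationError("noise_rate must be nonnegative")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimSpec":
        classes = tuple(
            ClassSpec(
                c["class_label"],
                int(c["n_individuals"]),
                tuple((str(h), float(p)) for h, p in c.get("mixture", [])),
            )
            for c in payload["classes"]
        )
        return cls(
            classes=classes,
            carrier_completeness=float(payload.get("carrier_completeness", 0.9)),
            noise_rate=float(payload.get("noise_rate", 3.0)),
            seed=int(payload.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "classes": [
                {
                    "class_label": c.class_label,
                    "n_individuals": c.n_individuals,
                    "mixture": [[h, p] for h, p in c.mixture],
                }
                for c in self.classes
            ],
            "carrier_completeness": self.carrier_completeness,
            "noise_rate": self.noise_rate,
            "seed": self.seed,
        }
        with Path(path).open("w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class SimResult:
    genotypes: GenotypeMatrix
    variant_sets: tuple[VariantSet, ...]
    #: sample id -> source haplogroup name (None for background individuals)
    truth: dict[str, str | None] = field(default_factory=dict)


def _profile_index(tables: Mapping[str, ProfileTable] | Sequence[ProfileTable]):
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    index: dict[str, HaplogroupProfile] = {}
    all_loci: set[int] = set()
    for table in tables:
        for profile in table:
            # class-qualified name wins only if the bare name collides
            key = profile.haplogroup_name
            if key in index and index[key] is not profile:
                key = f"{profile.class_label}/{profile.haplogroup_name}"
            index[key] = profile
            all_loci.update(profile.loci)
    return index, all_loci


def _mixture_counts(class_spec: ClassSpec) -> list[tuple[str | None, int]]:
    """Deterministic largest-remainder allocation of class members.

    Carrier counts are the mixture proportions times the class size, floored
    and topped up in order of largest fractional remainder so that the total
    carrier count is the rounded carrier mass; the rest are background."""
    n = class_spec.n_individuals
    names = [h for h, _ in class_spec.mixture]
    exact = [p * n for _, p in class_spec.mixture]
    base = [int(math.floor(x)) for x in exact]
    target = int(round(sum(exact)))
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[: max(0, target - sum(base))]:
        base[i] += 1
    out: list[tuple[str | None, int]] = [
        (names[i], base[i]) for i in range(len(names)) if base[i] > 0
    ]
    background = n - sum(base)
    if background:
        out.append((None, background))
    return out


def simulate_cohort(
    spec: SimSpec,
    tables: Mapping[str, ProfileTable] | Sequence[ProfileTable],
    reference: str,
) -> SimResult:
    """Generate a labelled cohort (see module docstring for the model).

    Noise loci are drawn uniformly from positions outside the individual's
    own source profile; the genotype matrix covers the union of all profile
    loci plus every noise locus actually used.
    """
    if len(reference) != RCRS_LENGTH:
        raise ValidationError(f"reference length {len(reference)} != {RCRS_LENGTH}")
    index, profile_loci = _profile_index(tables)
    for class_spec in spec.classes:
        for name, _ in class_spec.mixture:
            if name not in index:
                raise ValidationError(f"unknown profile name {name!r}")

    rng = np.random.default_rng(spec.seed)
    variant_sets: list[VariantSet] = []
    labels: list[str] = []
    truth: dict[str, str | None] = {}
    counter = 0
    for class_spec in spec.classes:
        for hap_name, count in _mixture_counts(class_spec):
            profile = index[hap_name] if hap_name is not None else None
            for _ in range(count):
                counter += 1
                sample_id = f"S{counter:04d}"
                calls: dict[int, str] = {}
                own_loci: set[int] = set()
                if profile is not None:
                    own_loci = set(profile.loci)
                    keep = rng.random(profile.size) < spec.carrier_completeness
                    for entry, kept in zip(profile, keep):
                        if not kept:
                            continue
                        if entry.locus in calls:
                            # two mutant alleles at one locus: keep one at random
                            if rng.random() < 0.5:
                                calls[entry.locus] = entry.mutant_allele
                        else:
                            calls[entry.locus] = entry.mutant_allele
                n_noise = int(rng.poisson(spec.noise_rate))
                placed = 0
                while placed < n_noise:
                    locus = int(rng.integers(1, RCRS_LENGTH + 1))
                    if locus in own_loci or locus in calls:
                        continue
                    ref_base = reference[locus - 1].upper()
                    choices = [b for b in _BASES if b != ref_base]
                    calls[locus] = choices[int(rng.integers(0, 3))]
                    placed += 1
                variant_sets.append(VariantSet(sample_id, calls))
                labels.append(class_spec.class_label)
                truth[sample_id] = hap_name

    used_loci = sorted(
        profile_loci.union(*[set(vs.variants) for vs in variant_sets])
        if variant_sets
        else profile_loci
    )
    rows = []
    for vs in variant_sets:
        rows.append(
            [vs.variants.get(locus, reference[locus - 1].upper()) for locus in used_loci]
        )
    raw = pd.DataFrame(rows, index=[vs.sample_id for vs in variant_sets],
                       columns=used_loci)
    matrix = encode_genotypes(raw, labels)
    return SimResult(matrix, tuple(variant_sets), truth)


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one end-to-end plant-and-recover run."""

    planted_haplogroup: str
    recovered_haplogroup: str | None
    recovered: bool
    association: object  # AssociationReport of the selected subset
    selected_ids: tuple[str, ...]


def pipeline_recovery_check(
    spec: SimSpec,
    tables: Mapping[str, ProfileTable] | Sequence[ProfileTable],
    reference: str,
    positive_class: str,
    planted_haplogroup: str,
    association_table: ProfileTable,
    top_n: int = 15,
    train_config: TrainConfig | None = None,
) -> RecoveryResult:
    """Run simulate -> train -> select top-N -> associate, and check that the
    planted dominant haplogroup comes back as the modal assignment.

    Scores every individual in the cohort (training and validation alike),
    exactly as the cluster-report stage does.
    """
    train_config = train_config or TrainConfig(seed=spec.seed)
    sim = simulate_cohort(spec, tables, reference)
    model, _ = train_rbf(sim.genotypes, positive_class, train_config)
    # rank on raw scores: clipping would collapse near-1 scores into ties
    scores = scores_for_matrix(model, sim.genotypes, raw=True)
    selection = select_modified_cluster(scores, top_n=top_n)
    by_id = {vs.sample_id: vs for vs in sim.variant_sets}
    subset = [by_id[sid] for sid in selection.sample_ids]
    report = associate_subset(subset, association_table)
    recovered = report.modal_haplogroup
    return RecoveryResult(
        planted_haplogroup=planted_haplogroup,
        recovered_haplogroup=recovered,
        recovered=recovered == planted_haplogroup,
        association=report,
        selected_ids=selection.sample_ids,
    )
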