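"""Cluster reports and modified-cluster selection.

After the network is fitted, every individual gets a predicted probability
of belonging to the target class.  Two views are built on top of these
scores: a cluster report (individuals grouped by their nearest basis-function
center, each cluster summarised by its mean predicted probability as a
percentage) and the *modified cluster* — the subset of individuals with the
highest predicted probabilities, chosen either as a fixed count (top-N,
the study default being the top 15) or by a strict probability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .rbf import GenotypeMatrix, RBFModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    member_ids: tuple[str, ...]
    mean_probability_pct: float

    @property
    def n_persons(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class ClusterReport:
    """Partition of the scored cohort, clusters in descending mean probability."""

    clusters: tuple[Cluster, ...]
    class_label: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not 0.0 <= c.mean_probability_pct <= 100.0:
                raise ValidationError("cluster mean probability outside [0, 100]")
            overlap = seen.intersection(c.member_ids)
            if overlap:
                raise ValidationError(f"samples in two clusters: {sorted(overlap)[:3]}")
            seen.update(c.member_ids)
        probs = [c.mean_probability_pct for c in self.clusters]
        if probs != sorted(probs, reverse=True):
            raise ValidationError("clusters must be in descending mean probability")

    @property
    def n_total(self) -> int:
        return sum(c.n_persons for c in self.clusters)

    def member_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out.update(c.member_ids)
        return out


def form_clusters(model: RBFModel, data: GenotypeMatrix) -> ClusterReport:
    """Assign each sample to its nearest center and report per-cluster mean
    predicted probabilities (%).  Empty clusters are dropped; cluster ids are
    renumbered 1.. in descending mean probability."""
    if data.loci != model.loci:
        raise ValidationError("genotype matrix loci do not match the model")
    X = data.rows()
    assignment = model.nearest_center(X)
    proba = model.predict_proba(X)
    groups: list[tuple[float, tuple[str, ...]]] = []
    for center in range(model.m):
        mask = assignment == center
        if not mask.any():
            continue
        members = tuple(
            sid for sid, hit in zip(data.sample_ids, mask) if hit
        )
        groups.append((float(proba[mask].mean()) * 100.0, members))
    groups.sort(key=lambda g: (-g[0], g[1]))
    clusters = tuple(
        Cluster(i + 1, members, pct) for i, (pct, members) in enumerate(groups)
    )
    return ClusterReport(clusters, model.positive_class)


def write_cluster_tsv(report: ClusterReport, path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    """TSV with columns classification_id, n_persons,
    predicted_probability_pct, member_ids."""
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("classification_id\tn_persons\tpredicted_probability_pct\tmember_ids\n")
        for c in report.clusters:
            fh.write(
                f"{c.cluster_id}\t{c.n_persons}\t{c.mean_probability_pct:.1f}\t"
                + ",".join(c.member_ids) + "\n"
            )


@dataclass(frozen=True)
class SelectionResult:
    """The modified cluster: selected samples with their scores."""

    selected: tuple[tuple[str, float], ...]  # (sample_id, score), best first
    rule: str

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.selected)

    def __len__(self) -> int:
        return len(self.selected)


def select_modified_cluster(
    scores: Mapping[str, float],
    top_n: int | None = None,
    threshold: float | None = None,
) -> SelectionResult:
    """Pick the modified cluster from per-sample probabilities.

    Exactly one of ``top_n`` / ``threshold`` must be given.  Top-N keeps the
    N highest scores (ties broken by ascending sample id); a threshold keeps
    scores strictly greater than the value.
    """
    if (top_n is None) == (threshold is None):
        raise ValidationError("give exactly one of top_n or threshold")
    if not scores:
        raise ValidationError("scores are empty")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        if top_n <= 0:
            raise ValidationError("top_n must be >= 1")
        if top_n > len(ranked):
            logger.warning(
                "requested top %d of %d samples; selecting all", top_n, len(ranked)
            )
        chosen = ranked[:top_n]
        rule = f"top-{top_n}"
    else:
        if not 0.0 <= threshold <= 1.0:
            raise ValidationError("threshold must be in [0, 1]")
        chosen = [(sid, s) for sid, s in ranked if s > threshold]
        rule = f"threshold>{threshold}"
    return SelectionResult(tuple((sid, float(s)) for sid, s in chosen), rule)


def scores_for_matrix(
    model: RBFModel, data: GenotypeMatrix, raw: bool = False
) -> dict[str, float]:
    """Per-sample scores keyed by sample id.

    By default clipped probabilities in [0, 1]; with ``raw=True`` the
    unclipped weighted sums, which preserve the ordering that clipping
    collapses into ties near 0 and 1 — use raw scores for ranking, clipped
    ones for reporting."""
    if data.loci != model.loci:
        raise ValidationError("genotype matrix loci do not match the model")
    f = model.decision_function(data.rows())
    if not raw:
        f = np.clip(f, 0.0, 1.0)
    return {sid: float(p) for sid, p in zip(data.sample_ids, f)}
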