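"""Ortholog typing at >=90% PID, novelty binning, distribution tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from panelforge.amplicon_pipeline.classify import compute_pid
from panelforge.seqio import SequenceRecord, ValidationError

__all__ = [
    "DistributionMatrix",
    "RdhaType",
    "cluster_types",
    "distribution_matrix",
    "novelty_bins",
]

CLUSTER_MIN_COVERAGE = 0.9

NOVELTY_IDENTICAL = "identical"
NOVELTY_HIGH = "high_90_99"
NOVELTY_NOVEL = "novel_30_89"
NOVELTY_UNASSIGNED = "unassigned"


@dataclass
class RdhaType:
    """A >=90%-PID protein cluster with an optional novelty category."""

    type_id: int
    centroid_id: str
    members: list[tuple[str, str]]  # (sequence id, sample/genome label)
    novelty: str | None = None

    def member_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def labels(self) -> set[str]:
        return {m[1] for m in self.members}


def _pid_ok(a: SequenceRecord, b: SequenceRecord, threshold: float) -> bool:
    pid, cov = compute_pid(a, b)
    return pid >= threshold and cov > CLUSTER_MIN_COVERAGE


def cluster_types(
    proteins: list[tuple[SequenceRecord, str]],
    threshold: float = 90.0,
) -> list[RdhaType]:
    """Greedy centroid clustering with a post-hoc all-pairs guarantee.

    Sequences (paired with their sample/genome label) are visited longest
    first (ties by id); each joins the first centroid it matches at
    >= threshold PID with > 0.9 coverage, else founds a new type. Types
    whose members fail the all-pairs PID check are split
    deterministically in join order.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValidationError("threshold outside (0, 100]")
    order = sorted(proteins, key=lambda p: (-len(p[0]), p[0].id))
    clusters: list[list[tuple[SequenceRecord, str]]] = []
    for rec, label in order:
        for members in clusters:
            centroid = members[0][0]
            if _pid_ok(rec, centroid, threshold):
                members.append((rec, label))
                break
        else:
            clusters.append([(rec, label)])

    # all-pairs verification; evict members breaking the guarantee and
    # re-cluster the evicted set with the same complete-linkage rule
    verified: list[list[tuple[SequenceRecord, str]]] = []
    for members in clusters:
        kept: list[tuple[SequenceRecord, str]] = []
        evicted: list[tuple[SequenceRecord, str]] = []
        for rec, label in members:
            if all(
                compute_pid(rec, other)[0] >= threshold for other, _ in kept
            ):
                kept.append((rec, label))
            else:
                evicted.append((rec, label))
        verified.append(kept)
        while evicted:
            seed_rec, seed_label = evicted.pop(0)
            group = [(seed_rec, seed_label)]
            rest = []
            for rec, label in evicted:
                if all(
                    compute_pid(rec, other)[0] >= threshold
                    and _pid_ok(rec, other, threshold)
                    for other, _ in group
                ):
                    group.append((rec, label))
                else:
                    rest.append((rec, label))
            verified.append(group)
            evicted = rest

    types = []
    for tid, members in enumerate(verified, start=1):
        types.append(
            RdhaType(
                type_id=tid,
                centroid_id=members[0][0].id,
                members=[(rec.id, label) for rec, label in members],
            )
        )
    # soundness assertion: every emitted type passes the all-pairs check
    by_id = {rec.id: rec for rec, _ in proteins}
    for t in types:
        ids = t.member_ids()
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                pid, _ = compute_pid(by_id[a], by_id[b])
                assert pid >= threshold, (t.type_id, a, b, pid)
    return types


def novelty_bins(max_pid_to_db: list[float]) -> dict:
    """Histogram of best-database identities into the four novelty bins.

    identical (=100), high (>=90, <100), novel (>=30, <90),
    unassigned (<30); returns counts and fractions.
    """
    counts = {
        NOVELTY_IDENTICAL: 0,
        NOVELTY_HIGH: 0,
        NOVELTY_NOVEL: 0,
        NOVELTY_UNASSIGNED: 0,
    }
    for pid in max_pid_to_db:
        if not 0.0 <= pid <= 100.0:
            raise ValidationError(f"pid {pid} outside [0, 100]")
        if pid == 100.0:
            counts[NOVELTY_IDENTICAL] += 1
        elif pid >= 90.0:
            counts[NOVELTY_HIGH] += 1
        elif pid >= 30.0:
            counts[NOVELTY_NOVEL] += 1
        else:
            counts[NOVELTY_UNASSIGNED] += 1
    n = len(max_pid_to_db)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions, "total": n}


@dataclass
class DistributionMatrix:
    """Ordered presence/absence of types across samples and genomes."""

    table: pd.DataFrame  # bool; rows: type ids, columns: labels
    study_samples: list[str]
    reference_genomes: list[str]
    summary: dict[int, int] = field(default_factory=dict)
    unique_types: list[int] = field(default_factory=list)


def distribution_matrix(
    types: list[RdhaType],
    study_samples: list[str],
    reference_genomes: list[str],
    max_db_pid: dict[int, float] | None = None,
) -> DistributionMatrix:
    """Presence/absence matrix ordered by study-sample spread.

    Rows sort by (number of study samples containing the type,
    descending; total labels, descending; type_id). The summary counts
    types present in >= k study samples; "unique" types occur in a
    single study sample with no reference member and (when given) a best
    database identity < 90.
    """
    known = set(study_samples) | set(reference_genomes)
    for t in types:
        unlabeled = [m for m in t.members if m[1] not in known]
        if unlabeled:
            raise ValidationError(
                f"type {t.type_id}: member label(s) not declared: "
                f"{sorted({m[1] for m in unlabeled})}"
            )
    columns = list(study_samples) + list(reference_genomes)
    data = {}
    for t in types:
        labels = t.labels()
        data[t.type_id] = [c in labels for c in columns]
    table = pd.DataFrame.from_dict(
        data, orient="index", columns=columns
    ).astype(bool)

    def keys(tid: int) -> tuple:
        row = table.loc[tid]
        n_study = int(row[study_samples].sum())
        return (-n_study, -int(row.sum()), tid)

    table = table.loc[sorted(table.index, key=keys)]

    n_study_per_type = table[study_samples].sum(axis=1)
    summary = {
        k: int((n_study_per_type >= k).sum())
        for k in range(1, len(study_samples) + 1)
    }
    unique = []
    for t in types:
        row = table.loc[t.type_id]
        in_ref = bool(row[reference_genomes].sum()) if reference_genomes else False
        if int(row[study_samples].sum()) == 1 and not in_ref:
            if max_db_pid is None or max_db_pid.get(t.type_id, 0.0) < 90.0:
                unique.append(t.type_id)
    return DistributionMatrix(
        table=table,
        study_samples=list(study_samples),
        reference_genomes=list(reference_genomes),
        summary=summary,
        unique_types=sorted(unique),
    )
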