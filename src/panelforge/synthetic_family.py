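"""Seeded generators for gene families, sample mixtures, reads, and chimeras.

Everything the toolkit consumes can be simulated here with controlled
divergence and conserved primer-able blocks, so all modules are testable
without downloads. All randomness flows from a single integer seed.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from panelforge.seqio import (
    Alignment,
    PhyloTree,
    SequenceRecord,
    ValidationError,
)

__all__ = [
    "FamilySpec",
    "SampleSpec",
    "fragment_reads",
    "make_samples",
    "simulate_family",
]

KAPPA = 2.0  # transition/transversion rate ratio of the two-parameter model

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_BASES = np.array(list("ACGT"))


@dataclass
class FamilySpec:
    """Shape of a simulated gene family."""

    n_taxa: int = 12
    tree_shape: str = "birth_death"  # or random_coalescent
    mean_divergence: float = 0.2  # expected pairwise substitutions/site
    conserved_blocks: tuple[tuple[int, int, float], ...] = ()
    gene_length: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_shape not in ("birth_death", "random_coalescent"):
            raise ValidationError(f"unknown tree shape {self.tree_shape!r}")
        last_end = 0
        for pos, length, mult in sorted(self.conserved_blocks):
            if pos < last_end:
                raise ValidationError("conserved blocks overlap")
            if pos + length > self.gene_length:
                raise ValidationError("conserved block outside gene")
            if not 0.0 <= mult <= 1.0:
                raise ValidationError("rate multiplier outside [0, 1]")
            last_end = pos + length


@dataclass
class SampleSpec:
    """Composition of simulated per-sample sequence sets."""

    n_samples: int = 6
    inclusion_probability: float = 0.8
    background_count: int = 3
    chimera_count: int = 1
    read_length: int = 102
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inclusion_probability <= 1.0:
            raise ValidationError("inclusion probability outside [0, 1]")
        if min(self.n_samples, self.background_count, self.chimera_count) < 0:
            raise ValidationError("counts must be >= 0")


def _site_rates(spec: FamilySpec) -> np.ndarray:
    rates = np.ones(spec.gene_length)
    for pos, length, mult in spec.conserved_blocks:
        rates[pos : pos + length] = mult
    return rates


def _evolve(parent: np.ndarray, t: float, rates: np.ndarray, rng) -> np.ndarray:
    """One branch of two-parameter (K2P) evolution, per-site rates."""
    d = t * rates
    kt = KAPPA + 2.0
    alpha_t = d * KAPPA / kt
    beta_t = d / kt
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    p_tv = 0.25 - 0.25 * np.exp(-4.0 * beta_t)  # per transversion partner
    u = rng.random(parent.shape[0])
    child = parent.copy()
    ts_mask = u < p_ts
    tv1_mask = (~ts_mask) & (u < p_ts + p_tv)
    tv2_mask = (~ts_mask) & (~tv1_mask) & (u < p_ts + 2 * p_tv)
    for i in np.nonzero(ts_mask)[0]:
        child[i] = _TRANSITION[parent[i]]
    for i in np.nonzero(tv1_mask)[0]:
        child[i] = _TRANSVERSIONS[parent[i]][0]
    for i in np.nonzero(tv2_mask)[0]:
        child[i] = _TRANSVERSIONS[parent[i]][1]
    return child


def simulate_family(
    spec: FamilySpec,
) -> tuple[Alignment, PhyloTree, dict[str, str]]:
    """Simulate a tree and sequences evolved along it.

    Sequences evolve under a two-parameter substitution model with
    per-site rates scaled down inside conserved blocks. Because the
    model is substitution-only, the true alignment equals the ungapped
    sequences. Deterministic under ``spec.seed``.
    """
    if spec.n_taxa < 3:
        raise ValidationError("n_taxa must be >= 3")
    pyrng = random.Random(spec.seed)
    rng = np.random.default_rng(spec.seed)

    if spec.tree_shape == "birth_death":
        dtree = treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=spec.n_taxa,
            rng=pyrng,
        )
    else:
        import dendropy

        tn = dendropy.TaxonNamespace(
            [f"T{i + 1:02d}" for i in range(spec.n_taxa)]
        )
        dtree = treesim.pure_kingman_tree(
            taxon_namespace=tn, pop_size=1.0, rng=pyrng
        )

    # deterministic leaf labels in tree order
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i:02d}"

    # scale so the mean root-to-tip depth is mean_divergence / 2,
    # giving pairwise divergences on the order of mean_divergence
    depths = []
    for leaf in dtree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    mean_depth = float(np.mean(depths))
    scale = (
        (spec.mean_divergence / 2.0) / mean_depth if mean_depth > 0 else 0.0
    )
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale

    rates = _site_rates(spec)
    root_seq = _BASES[rng.integers(0, 4, size=spec.gene_length)]
    seqs: dict = {id(dtree.seed_node): root_seq}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        parent = seqs[id(node.parent_node)]
        seqs[id(node)] = _evolve(parent, node.edge.length or 0.0, rates, rng)

    rows = []
    ungapped = {}
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label
        seq = "".join(seqs[id(leaf)])
        rows.append(SequenceRecord(id=label, residues=seq, allow_gap=True))
        ungapped[label] = seq
    return Alignment(rows=rows), PhyloTree(dtree), ungapped


def _shuffled_decoy(source: str, rng: random.Random) -> str:
    letters = list(source)
    rng.shuffle(letters)
    return "".join(letters)


def make_samples(
    members: dict[str, str],
    spec: SampleSpec,
    groups: dict[str, str] | None = None,
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Per-sample FASTA sets (members + decoys + chimeras) with a truth table.

    Background decoys are composition-preserving shuffles of family
    members; chimeras splice the 5' half of one member onto the 3' half
    of another at the donors' midpoints, with the breakpoint recorded.
    """
    if spec.chimera_count > 0 and len(members) < 2:
        raise ValidationError("chimeras require >= 2 family members")
    groups = groups or {}
    rng = random.Random(spec.seed)
    member_ids = sorted(members)
    samples: dict[str, list[SequenceRecord]] = {}
    truth_rows = []
    for s in range(1, spec.n_samples + 1):
        name = f"S{s}"
        records = []
        for mid in member_ids:
            if rng.random() < spec.inclusion_probability:
                sid = f"{name}_{mid}"
                records.append(SequenceRecord(id=sid, residues=members[mid]))
                truth_rows.append(
                    dict(sample=name, seq_id=sid, origin="member",
                         source=mid, group=groups.get(mid, ""), breakpoint=-1)
                )
        for b in range(1, spec.background_count + 1):
            donor = rng.choice(member_ids)
            sid = f"{name}_bg{b}"
            records.append(
                SequenceRecord(id=sid, residues=_shuffled_decoy(members[donor], rng))
            )
            truth_rows.append(
                dict(sample=name, seq_id=sid, origin="background",
                     source=donor, group="", breakpoint=-1)
            )
        for c in range(1, spec.chimera_count + 1):
            d5, d3 = rng.sample(member_ids, 2)
            half5 = members[d5][: len(members[d5]) // 2]
            half3 = members[d3][len(members[d3]) // 2 :]
            sid = f"{name}_chimera{c}"
            records.append(SequenceRecord(id=sid, residues=half5 + half3))
            truth_rows.append(
                dict(sample=name, seq_id=sid, origin="chimera",
                     source=f"{d5}+{d3}",
                     group=f"{groups.get(d5, '')}+{groups.get(d3, '')}",
                     breakpoint=len(half5))
            )
        samples[name] = records
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "seq_id", "origin", "source", "group", "breakpoint"],
    )
    return samples, truth


def fragment_reads(
    sequences: list[SequenceRecord],
    read_len: int,
    head_pad: int,
    tail_pad: int,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Fixed-length reads tiled over each sequence with synthetic pads.

    Each read is ``head_pad`` random bases + a core substring + ``tail_pad``
    random bases, so trimming with a matching spec reconstructs exact
    substrings of the source. Sequences shorter than the core are skipped
    with a warning.
    """
    core = read_len - head_pad - tail_pad
    if core <= 0:
        raise ValidationError("read_len must exceed head_pad + tail_pad")
    rng = random.Random(seed)
    reads = []
    for rec in sequences:
        if len(rec) < core:
            warnings.warn(
                f"{rec.id}: shorter than read core ({core}); skipped",
                stacklevel=2,
            )
            continue
        starts = list(range(0, len(rec) - core + 1, core))
        for i, start in enumerate(starts, start=1):
            pad5 = "".join(rng.choice("ACGT") for _ in range(head_pad))
            pad3 = "".join(rng.choice("ACGT") for _ in range(tail_pad))
            reads.append(
                SequenceRecord(
                    id=f"{rec.id}_r{i}",
                    residues=pad5 + rec.residues[start : start + core] + pad3,
                    description=f"source={rec.id} start={start}",
                )
            )
    return reads
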