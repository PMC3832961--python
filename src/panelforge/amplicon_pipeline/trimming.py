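"""Read trimming/filtering and contig length gates."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from panelforge.seqio import SequenceRecord, ValidationError

__all__ = ["TrimSpec", "length_gates", "trim_and_filter"]

ENTROPY_WINDOW = 32
ADAPTER_SEED = 12
ADAPTER_MIN_IDENTITY = 0.9


@dataclass
class TrimSpec:
    """Fixed trim amounts plus adapter/complexity filters."""

    head_trim: int = 0
    tail_trim: int = 0
    min_len: int = 30
    min_entropy: float = 0.0  # bits per base over a sliding window
    adapter_seqs: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if min(self.head_trim, self.tail_trim, self.min_len) < 0:
            raise ValidationError("trim amounts must be >= 0")
        if not 0.0 <= self.min_entropy <= 2.0:
            raise ValidationError("min_entropy must be in [0, 2]")
        self.adapter_seqs = tuple(a.upper() for a in self.adapter_seqs)


def _shannon_entropy(seq: str) -> float:
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def _min_window_entropy(seq: str, window: int = ENTROPY_WINDOW) -> float:
    if len(seq) <= window:
        return _shannon_entropy(seq)
    return min(
        _shannon_entropy(seq[i : i + window])
        for i in range(len(seq) - window + 1)
    )


def _matches_adapter(seq: str, adapter: str) -> bool:
    if len(adapter) < ADAPTER_SEED:
        return adapter in seq
    seed = adapter[:ADAPTER_SEED]
    pos = seq.find(seed)
    while pos != -1:
        overlap = min(len(adapter), len(seq) - pos)
        matches = sum(
            1 for i in range(overlap) if seq[pos + i] == adapter[i]
        )
        if overlap and matches / overlap >= ADAPTER_MIN_IDENTITY:
            return True
        pos = seq.find(seed, pos + 1)
    return False


def trim_and_filter(
    reads: list[SequenceRecord], spec: TrimSpec
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Trim fixed head/tail amounts and drop short/adapter/low-complexity reads.

    Returns the surviving reads (qualities trimmed alongside) and a count
    of removals per reason. Raises when no read is long enough to trim.
    """
    min_total = spec.head_trim + spec.tail_trim + spec.min_len
    if reads and all(len(r) < spec.head_trim + spec.tail_trim for r in reads):
        raise ValidationError("no reads survive: head+tail exceeds every read length")
    stats = {"input": len(reads), "too_short": 0, "adapter": 0,
             "low_complexity": 0, "kept": 0}
    kept: list[SequenceRecord] = []
    for read in reads:
        if len(read) < min_total:
            stats["too_short"] += 1
            continue
        end = len(read) - spec.tail_trim
        residues = read.residues[spec.head_trim : end]
        quals = (
            read.qualities[spec.head_trim : end]
            if read.qualities is not None
            else None
        )
        if any(_matches_adapter(residues, a) for a in spec.adapter_seqs):
            stats["adapter"] += 1
            continue
        if spec.min_entropy > 0 and _min_window_entropy(residues) < spec.min_entropy:
            stats["low_complexity"] += 1
            continue
        kept.append(
            SequenceRecord(
                id=read.id,
                residues=residues,
                alphabet=read.alphabet,
                description=read.description,
                qualities=quals,
            )
        )
        stats["kept"] += 1
    return kept, stats


def length_gates(
    contigs: list[SequenceRecord],
    reporting_cutoff: int = 250,
    external_cutoff: int = 500,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Strictly-greater length gates: the reporting set (>250 bp) and its
    external-search subset (>500 bp)."""
    reporting = [c for c in contigs if len(c) > reporting_cutoff]
    external = [c for c in reporting if len(c) > external_cutoff]
    return reporting, external
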