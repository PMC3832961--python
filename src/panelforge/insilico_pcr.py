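"""In-silico PCR: binding-site search and amplicon prediction.

Primer-vs-target comparison is IUPAC-vs-IUPAC by expansion-set
intersection, so degenerate target bases (e.g. ``N`` in contigs) match
permissively. Perfect-match mode is ``max_mm=0``; tolerant mode defaults
to 2 mismatches with a mismatch-free 3-bp 3' clamp. All overlapping and
nested products are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from panelforge.seqio import (
    IUPAC_SETS,
    PanelTable,
    SequenceRecord,
    ValidationError,
    reverse_complement,
)

__all__ = [
    "Amplicon",
    "BindingSite",
    "amplify",
    "amplify_seqs",
    "find_binding_sites",
    "iupac_match",
    "screen_panel",
]

DEFAULT_MAX_MM = 2
DEFAULT_CLAMP = 3
DEFAULT_MAX_LEN = 4000

_MATCH: dict[tuple[str, str], bool] = {
    (a, b): bool(IUPAC_SETS[a] & IUPAC_SETS[b])
    for a in IUPAC_SETS
    for b in IUPAC_SETS
}


def iupac_match(primer_char: str, target_char: str) -> bool:
    """True iff the two IUPAC codes' expansion sets intersect."""
    try:
        return _MATCH[(primer_char, target_char)]
    except KeyError:
        bad = primer_char if primer_char not in IUPAC_SETS else target_char
        raise ValidationError(f"invalid IUPAC code {bad!r}") from None


@dataclass(frozen=True)
class BindingSite:
    """A primer binding location on the plus strand of a target."""

    target_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    three_prime_mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not (self.mismatches >= self.three_prime_mismatches >= 0):
            raise ValidationError("mismatch counts inconsistent")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, outer coordinates including primer sites."""

    target_id: str
    start: int
    end: int
    length: int
    fwd_site: BindingSite
    rev_site: BindingSite
    group_id: str = ""

    def __post_init__(self) -> None:
        if self.length != self.end - self.start:
            raise ValidationError("length != end - start")
        if self.fwd_site.strand == self.rev_site.strand:
            raise ValidationError("amplicon primer sites must be on opposite strands")


def _count_mm(primer: str, window: str, clamp_len: int) -> tuple[int, int]:
    """(total, 3'-clamp) mismatches of primer 5'->3' against its window."""
    n = len(primer)
    total = clamp = 0
    for i in range(n):
        if not _MATCH.get((primer[i], window[i]), False):
            total += 1
            if i >= n - clamp_len:
                clamp += 1
    return total, clamp


def find_binding_sites(
    primer: str,
    target: SequenceRecord,
    max_mm: int = 0,
    clamp_len: int = DEFAULT_CLAMP,
) -> list[BindingSite]:
    """All positions on both strands with <= max_mm mismatches and a clean 3' clamp.

    On the plus strand the primer reads 5'->3' left to right; on the minus
    strand its reverse complement is matched, so the primer's 3' end sits at
    the left (``start``) edge of the site. Sites are sorted by
    (start, strand).
    """
    if target.alphabet != "dna":
        raise ValidationError("targets must be DNA")
    if max_mm < 0 or clamp_len < 0:
        raise ValidationError("max_mm and clamp_len must be >= 0")
    primer = primer.upper()
    for ch in primer:
        if ch not in IUPAC_SETS:
            raise ValidationError(f"invalid IUPAC code {ch!r} in primer")
    seq = target.residues
    n, m = len(seq), len(primer)
    sites = []
    if m > n:
        return sites
    rc = reverse_complement(primer)
    for start in range(n - m + 1):
        window = seq[start : start + m]
        total, clamp = _count_mm(primer, window, clamp_len)
        if total <= max_mm and clamp == 0:
            sites.append(
                BindingSite(target.id, start, start + m, "+", total, clamp)
            )
        # minus strand: primer rc aligned left-to-right; primer 3' end is
        # at the window's left edge, so the clamp covers the first bases
        total_rc = clamp_rc = 0
        for i in range(m):
            if not _MATCH.get((rc[i], window[i]), False):
                total_rc += 1
                if i < clamp_len:
                    clamp_rc += 1
        if total_rc <= max_mm and clamp_rc == 0:
            sites.append(
                BindingSite(target.id, start, start + m, "-", total_rc, clamp_rc)
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify_seqs(
    fwd: str,
    rev: str,
    target: SequenceRecord,
    max_mm: int = 0,
    clamp_len: int = DEFAULT_CLAMP,
    max_len: int = DEFAULT_MAX_LEN,
    group_id: str = "",
) -> list[Amplicon]:
    """Predict products of a primer pair (given as IUPAC strings) on a target.

    Both orientations of the pair relative to the deposited strand are
    considered: (forward on +, reverse on -) and (reverse on +, forward
    on -). A product requires the minus-strand site to start at or after
    the plus-strand site's start and span <= max_len overall.
    """
    fwd_sites = find_binding_sites(fwd, target, max_mm, clamp_len)
    rev_sites = find_binding_sites(rev, target, max_mm, clamp_len)
    amps = []
    for plus_pool, minus_pool in (
        ([s for s in fwd_sites if s.strand == "+"],
         [s for s in rev_sites if s.strand == "-"]),
        ([s for s in rev_sites if s.strand == "+"],
         [s for s in fwd_sites if s.strand == "-"]),
    ):
        for p in plus_pool:
            for q in minus_pool:
                if q.start < p.start:
                    continue
                length = q.end - p.start
                if length > max_len:
                    continue
                amps.append(
                    Amplicon(
                        target_id=target.id,
                        start=p.start,
                        end=q.end,
                        length=length,
                        fwd_site=p,
                        rev_site=q,
                        group_id=group_id,
                    )
                )
    amps.sort(key=lambda a: (a.start, a.length, a.rev_site.strand))
    return amps


def amplify(
    pair,
    target: SequenceRecord,
    max_mm: int = 0,
    clamp_len: int = DEFAULT_CLAMP,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Amplicon]:
    """Predict products of a :class:`~panelforge.primer_engine.PrimerPair`."""
    return amplify_seqs(
        pair.forward.iupac_seq,
        pair.reverse.iupac_seq,
        target,
        max_mm=max_mm,
        clamp_len=clamp_len,
        max_len=max_len,
        group_id=pair.group_id,
    )


def screen_panel(
    panel: PanelTable,
    targets: list[SequenceRecord],
    mode: str = "perfect",
    max_mm: int = DEFAULT_MAX_MM,
    clamp_len: int = DEFAULT_CLAMP,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[pd.DataFrame, pd.Series]:
    """Amplicon-count matrix (groups x targets) plus per-target summary.

    The summary counts, per target, how many of the panel's primer sets
    yield at least one product ("n positive of N primer sets").
    """
    if len(panel) == 0:
        raise ValidationError("empty panel")
    if mode not in ("perfect", "tolerant"):
        raise ValidationError(f"unknown mode {mode!r}")
    mm = 0 if mode == "perfect" else max_mm
    clamp = 0 if mode == "perfect" else clamp_len
    groups = [r.group_id for r in panel]
    counts = pd.DataFrame(
        0, index=groups, columns=[t.id for t in targets], dtype=int
    )
    for row in panel:
        for t in targets:
            amps = amplify_seqs(
                row.fwd_seq, row.rev_seq, t,
                max_mm=mm, clamp_len=clamp, max_len=max_len,
                group_id=row.group_id,
            )
            counts.loc[row.group_id, t.id] = len(amps)
    positive = (counts > 0).sum(axis=0)
    summary = positive.map(lambda k: f"{k} positive of {len(panel)} primer sets")
    return counts, summary
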