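"""Translation, pairwise identity, best-hit classification, chimera screen.

BLAST is replaced by in-repo global affine-gap alignment with free end
gaps (protein: BLOSUM62 -11/-1; nucleotide: +2/-3, -5/-2), so results
are deterministic and self-contained. Percent identity is computed over
mutually aligned (both non-gap) columns; coverage is the fraction of the
query spanned by the aligned region.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from panelforge.seqio import SequenceRecord, ValidationError

__all__ = [
    "ClassifiedHit",
    "chimera_screen",
    "classify",
    "compute_pid",
    "compute_pid_nt",
    "translate_longest_orf",
]

MIN_ORF_CODONS = 30
NONSPECIFIC_MIN_PID = 25.0
NONSPECIFIC_MIN_COVERAGE = 0.5
TRANSLATION_TABLE = 11  # bacterial

# residues without a BLOSUM62 row, mapped to their closest standard code
_AA_FALLBACK = str.maketrans({"J": "L", "U": "C", "O": "K"})


def _free_end_gaps(aligner: PairwiseAligner) -> None:
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # biopython < 1.86 attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    _free_end_gaps(aligner)
    return aligner


def _nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    _free_end_gaps(aligner)
    return aligner


_PROT = _protein_aligner()
_NUC = _nucleotide_aligner()


def translate_longest_orf(contig: SequenceRecord) -> SequenceRecord | None:
    """Longest ORF over all six frames, bacterial code, edge-tolerant.

    A start codon is not required at the contig edge; stop codons
    terminate ORFs. Ties break by frame order +1, +2, +3, -1, -2, -3.
    Returns ``None`` when no ORF reaches 30 codons.
    """
    if contig.alphabet != "dna":
        raise ValidationError("translate_longest_orf requires a DNA contig")
    seq = Seq(contig.residues)
    frames = [("+1", seq), ("+2", seq[1:]), ("+3", seq[2:])]
    rc = seq.reverse_complement()
    frames += [("-1", rc), ("-2", rc[1:]), ("-3", rc[2:])]
    best_prot, best_frame = "", None
    for frame, fseq in frames:
        trimmed = fseq[: len(fseq) - len(fseq) % 3]
        if len(trimmed) < 3:
            continue
        translated = str(trimmed.translate(table=TRANSLATION_TABLE))
        for segment in translated.split("*"):
            if len(segment) > len(best_prot):
                best_prot, best_frame = segment, frame
    if len(best_prot) < MIN_ORF_CODONS:
        return None
    return SequenceRecord(
        id=contig.id,
        residues=best_prot,
        alphabet="protein",
        description=f"frame={best_frame}",
    )


def _pid_from_alignment(alignment, qlen: int) -> tuple[float, float]:
    qblocks, rblocks = alignment.aligned
    identities = 0
    aligned_cols = 0
    qseq, rseq = alignment.target, alignment.query
    for (qs, qe), (rs, re) in zip(qblocks, rblocks):
        aligned_cols += qe - qs
        for i in range(qe - qs):
            if qseq[qs + i] == rseq[rs + i]:
                identities += 1
    if aligned_cols == 0:
        return 0.0, 0.0
    span = int(qblocks[-1][1] - qblocks[0][0])
    return float(100.0 * identities / aligned_cols), float(span / qlen)


def compute_pid(query: SequenceRecord, ref: SequenceRecord) -> tuple[float, float]:
    """(percent identity, query coverage) from a global protein alignment."""
    if not query.residues or not ref.residues:
        raise ValidationError("empty sequence")
    if query.alphabet != "protein" or ref.alphabet != "protein":
        raise ValidationError("compute_pid requires protein sequences")
    q = query.residues.translate(_AA_FALLBACK)
    r = ref.residues.translate(_AA_FALLBACK)
    alignment = _PROT.align(q, r)[0]
    return _pid_from_alignment(alignment, len(q))


def compute_pid_nt(query: SequenceRecord, ref: SequenceRecord) -> tuple[float, float]:
    """Nucleotide-mode counterpart of :func:`compute_pid`."""
    if not query.residues or not ref.residues:
        raise ValidationError("empty sequence")
    alignment = _NUC.align(query.residues, ref.residues)[0]
    return _pid_from_alignment(alignment, len(query.residues))


@dataclass
class ClassifiedHit:
    """Best-reference assignment for one query."""

    query_id: str
    sample_label: str
    best_ref_id: str
    group_id: str
    pid: float
    query_coverage: float
    score: float
    passed_length_gate: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.pid <= 100.0:
            raise ValidationError("pid outside [0, 100]")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValidationError("coverage outside [0, 1]")


def _best_hit(query: SequenceRecord, references, aligner, pid_fn):
    scored = []
    for ref in references:
        if query.alphabet == "protein":
            score = aligner.score(
                query.residues.translate(_AA_FALLBACK),
                ref.residues.translate(_AA_FALLBACK),
            )
        else:
            score = aligner.score(query.residues, ref.residues)
        scored.append((score, ref))
    # deterministic under reference permutation: score, then pid, then id
    top_score = max(s for s, _ in scored)
    contenders = [ref for s, ref in scored if s == top_score]
    best, best_pid, best_cov = None, -1.0, 0.0
    for ref in sorted(contenders, key=lambda r: r.id):
        pid, cov = pid_fn(query, ref)
        if pid > best_pid:
            best, best_pid, best_cov = ref, pid, cov
    return best, best_pid, best_cov, top_score


def classify(
    queries: list[SequenceRecord],
    reference_db: list[SequenceRecord],
    group_map: dict[str, str],
    min_protein_len: int = 200,
    sample_label: str = "",
) -> list[ClassifiedHit]:
    """Assign each query to the primer group of its best-scoring reference.

    Queries whose best hit has pid < 25% or coverage < 0.5 are labeled
    ``non-specific``. Protein queries of <= ``min_protein_len`` residues
    get ``passed_length_gate=False`` (strict inequality).
    """
    if not reference_db:
        raise ValidationError("empty reference database")
    missing = [r.id for r in reference_db if r.id not in group_map]
    if missing:
        raise ValidationError(f"references without group labels: {missing}")
    is_protein = reference_db[0].alphabet == "protein"
    aligner = _PROT if is_protein else _NUC
    pid_fn = compute_pid if is_protein else compute_pid_nt
    hits = []
    for query in queries:
        best, pid, cov, score = _best_hit(query, reference_db, aligner, pid_fn)
        if pid < NONSPECIFIC_MIN_PID or cov < NONSPECIFIC_MIN_COVERAGE:
            group = "non-specific"
        else:
            group = group_map[best.id]
        hits.append(
            ClassifiedHit(
                query_id=query.id,
                sample_label=sample_label,
                best_ref_id=best.id,
                group_id=group,
                pid=pid,
                query_coverage=cov,
                score=score,
                passed_length_gate=len(query) > min_protein_len,
            )
        )
    return hits


def chimera_screen(
    query: SequenceRecord,
    reference_db: list[SequenceRecord],
    group_map: dict[str, str],
    min_half_pid: float = 80.0,
) -> dict:
    """Midpoint-split chimera verdict against a nucleotide reference set.

    Flags ``chimeric`` iff both halves hit a reference at >= min_half_pid
    and the halves' best references belong to different groups. Halves
    without a qualifying hit are insufficient evidence (``ok``). Queries
    under 400 nt are ``untestable``.
    """
    if query.alphabet != "dna":
        raise ValidationError("chimera_screen requires a DNA query")
    if len(query) < 400:
        return {"query_id": query.id, "verdict": "untestable"}
    mid = len(query) // 2
    halves = [
        SequenceRecord(id=f"{query.id}/5p", residues=query.residues[:mid]),
        SequenceRecord(id=f"{query.id}/3p", residues=query.residues[mid:]),
    ]
    results = []
    for half in halves:
        best, pid, _cov, _score = _best_hit(
            half, reference_db, _NUC, compute_pid_nt
        )
        results.append((best, pid))
    detail = {
        "query_id": query.id,
        "half_refs": [b.id for b, _ in results],
        "half_groups": [group_map.get(b.id) for b, _ in results],
        "half_pids": [round(p, 2) for _, p in results],
    }
    both_hit = all(p >= min_half_pid for _, p in results)
    groups = {group_map[b.id] for b, p in results if p >= min_half_pid}
    detail["verdict"] = (
        "chimeric" if both_hit and len(groups) > 1 else "ok"
    )
    return detail
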