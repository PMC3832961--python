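"""Degenerate consensus primers per group, screened against design constraints.

A candidate primer window must be gap-free in every group member, its
IUPAC consensus (which matches every member by construction) must stay
under the degeneracy cap, its Tm range (min/max over expansions) must sit
inside the annealing window, its worst hairpin must stay under the cap,
and the worst dimer of an emitted pair may be at most one third of the
weaker primer's full-duplex dG.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from panelforge.seqio import (
    IUPAC_SETS,
    SET_TO_IUPAC,
    Alignment,
    PanelRow,
    PanelTable,
    SequenceRecord,
    ValidationError,
    reverse_complement,
)
from panelforge.primer_engine.thermo import (
    NO_STEM,
    ThermoParams,
    duplex_dg,
    duplex_full_dg,
    hairpin_tm,
    tm_nn,
)

__all__ = [
    "DegeneratePrimer",
    "DesignResult",
    "PrimerConstraints",
    "PrimerPair",
    "degeneracy",
    "design_pair",
    "enumerate_expansions",
    "iupac_consensus",
    "tm_range_degenerate",
    "validate_panel",
]


def iupac_consensus(columns: list[set[str]] | list[frozenset[str]]) -> str:
    """IUPAC string whose per-position expansion equals each column set."""
    out = []
    for i, col in enumerate(columns):
        if not col:
            raise ValidationError(f"column {i}: empty residue set")
        if "-" in col:
            raise ValidationError(f"column {i}: gap in residue set")
        key = frozenset(col)
        if not key <= frozenset("ACGT"):
            raise ValidationError(f"column {i}: residues outside ACGT: {sorted(col)}")
        out.append(SET_TO_IUPAC[key])
    return "".join(out)


def degeneracy(iupac_seq: str) -> int:
    """Product of per-position IUPAC expansion-set sizes."""
    if not iupac_seq:
        raise ValidationError("empty IUPAC sequence")
    d = 1
    for ch in iupac_seq.upper():
        try:
            d *= len(IUPAC_SETS[ch])
        except KeyError:
            raise ValidationError(f"invalid IUPAC code {ch!r}") from None
    return d


def enumerate_expansions(
    iupac_seq: str, cap: int = 512, seed: int = 0
) -> list[str]:
    """Plain-DNA expansions of a degenerate oligo.

    All expansions in lexicographic order when degeneracy <= cap;
    otherwise a seeded sample of ``cap`` distinct expansions that always
    includes the lexicographically first and last.
    """
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    seq = iupac_seq.upper()
    deg = degeneracy(seq)
    choice_sets = [sorted(IUPAC_SETS[ch]) for ch in seq]
    if deg <= cap:
        return ["".join(p) for p in itertools.product(*choice_sets)]
    first = "".join(c[0] for c in choice_sets)
    last = "".join(c[-1] for c in choice_sets)
    rng = random.Random(seed)
    picked = {first, last}
    while len(picked) < min(cap, deg):
        picked.add("".join(rng.choice(c) for c in choice_sets))
    return sorted(picked)


def tm_range_degenerate(
    iupac_seq: str,
    params: ThermoParams = ThermoParams(),
    cap: int = 512,
    seed: int = 0,
) -> tuple[float, float]:
    """(min, max) nearest-neighbor Tm over expansions; exact under the cap."""
    tms = [tm_nn(s, params) for s in enumerate_expansions(iupac_seq, cap, seed)]
    return min(tms), max(tms)


@dataclass
class DegeneratePrimer:
    """IUPAC-coded oligo with degeneracy and thermodynamic summary."""

    iupac_seq: str
    orientation: str  # forward | reverse
    degeneracy: int
    tm_min: float
    tm_max: float
    hairpin_tm: float
    dg_full_duplex: float
    dg_worst_dimer: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if self.degeneracy != degeneracy(self.iupac_seq):
            raise ValidationError("degeneracy inconsistent with sequence")
        if self.tm_min > self.tm_max:
            raise ValidationError("tm_min > tm_max")

    def __len__(self) -> int:
        return len(self.iupac_seq)


@dataclass
class PrimerPair:
    """Oriented primer pair anchored on master-alignment columns."""

    group_id: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    fwd_start: int
    rev_end: int
    expected_len: int
    dg_worst_dimer: float = 0.0

    def __post_init__(self) -> None:
        if self.expected_len != self.rev_end - self.fwd_start:
            raise ValidationError("expected_len != rev_end - fwd_start")

    def combined_degeneracy(self) -> int:
        return self.forward.degeneracy * self.reverse.degeneracy

    def as_panel_row(self) -> PanelRow:
        return PanelRow(
            group_id=self.group_id,
            fwd_seq=self.forward.iupac_seq,
            rev_seq=self.reverse.iupac_seq,
            tm_min_c=round(min(self.forward.tm_min, self.reverse.tm_min), 2),
            tm_max_c=round(max(self.forward.tm_max, self.reverse.tm_max), 2),
            expected_len_bp=self.expected_len,
        )


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraint knobs; defaults follow the toolkit's conventions."""

    tm_lo: float = 40.0
    tm_hi: float = 65.0
    hairpin_max: float = 25.0
    dimer_ratio: float = 1.0 / 3.0
    min_len: int = 18
    max_len: int = 28
    degeneracy_cap: int = 512
    min_amplicon: int = 300
    max_amplicon: int = 1700
    thermo_sample_cap: int = 64
    max_pairs: int = 20


@dataclass
class DesignResult:
    """Ranked pairs plus per-constraint window-rejection diagnostics."""

    pairs: list[PrimerPair] = field(default_factory=list)
    diagnostics: dict[str, int] = field(default_factory=dict)


@dataclass
class _Candidate:
    start: int  # alignment column of window start
    end: int
    iupac: str  # oriented 5'->3' primer sequence
    deg: int
    tm_min: float
    tm_max: float
    hairpin: float
    dg_full: float


def _column_sets(aln: Alignment) -> list[set[str]]:
    cols = []
    for i in range(aln.n_columns):
        cols.append(set(aln.column(i)))
    return cols


def _evaluate_window(
    consensus: str,
    orientation: str,
    params: ThermoParams,
    cons: PrimerConstraints,
    seed: int,
) -> _Candidate | str:
    """Thermo summary of one oriented window; staged so the cheap Tm
    screen runs before the O(n^3) hairpin scan. Returns the rejecting
    constraint name instead of a candidate when the window fails."""
    oriented = consensus if orientation == "forward" else reverse_complement(consensus)
    expansions = enumerate_expansions(oriented, cons.thermo_sample_cap, seed)
    tms = [tm_nn(s, params) for s in expansions]
    tm_min, tm_max = min(tms), max(tms)
    if tm_min < cons.tm_lo or tm_max > cons.tm_hi:
        return "tm"
    hairpin_sample = expansions if len(expansions) <= 16 else (
        enumerate_expansions(oriented, 16, seed)
    )
    hp = max(hairpin_tm(s, params) for s in hairpin_sample)
    if hp > cons.hairpin_max:
        return "hairpin"
    # weakest (least negative) full duplex is the conservative "total dG"
    dg_full = max(duplex_full_dg(s, params) for s in expansions)
    return _Candidate(
        -1, -1, oriented, degeneracy(oriented), tm_min, tm_max, hp, dg_full
    )


def _worst_dimer(
    a: str, b: str, params: ThermoParams, cap: int, seed: int
) -> float:
    """Most negative cross/self dimer dG over sampled expansion pairs."""
    ea = enumerate_expansions(a, cap, seed)
    eb = enumerate_expansions(b, cap, seed)
    worst = 0.0
    for x in ea:
        for y in eb:
            worst = min(worst, duplex_dg(x, y, params))
    return worst


def design_pair(
    group_aln: Alignment,
    constraints: PrimerConstraints = PrimerConstraints(),
    params: ThermoParams = ThermoParams(),
    group_id: str = "1",
    seed: int = 0,
) -> DesignResult:
    """Design ranked degenerate primer pairs for one group alignment.

    Every emitted pair satisfies the annealing window, hairpin cap, and
    one-third dimer rule; see module docstring. Ranking: lower combined
    degeneracy, then wider Tm headroom, then longer amplicon, then
    leftmost forward anchor.
    """
    cons = constraints
    diagnostics = {
        "windows_total": 0,
        "rejected_gap": 0,
        "rejected_degeneracy": 0,
        "rejected_tm": 0,
        "rejected_hairpin": 0,
        "pairs_rejected_amplicon": 0,
        "pairs_rejected_dimer": 0,
    }
    cols = _column_sets(group_aln)
    ncol = len(cols)
    gap_col = ["-" in c for c in cols]

    # dimer-sampling cap kept small: cost is quadratic in expansions
    dimer_cap = min(8, cons.thermo_sample_cap)

    candidates: dict[str, list[_Candidate]] = {"forward": [], "reverse": []}
    for length in range(cons.min_len, cons.max_len + 1):
        for start in range(0, ncol - length + 1):
            end = start + length
            diagnostics["windows_total"] += 1
            if any(gap_col[start:end]):
                diagnostics["rejected_gap"] += 1
                continue
            try:
                consensus = iupac_consensus(cols[start:end])
            except ValidationError:
                diagnostics["rejected_gap"] += 1
                continue
            if degeneracy(consensus) > cons.degeneracy_cap:
                diagnostics["rejected_degeneracy"] += 1
                continue
            for orientation in ("forward", "reverse"):
                got = _evaluate_window(consensus, orientation, params, cons, seed)
                if isinstance(got, str):
                    diagnostics[f"rejected_{got}"] += 1
                    continue
                got.start, got.end = start, end
                candidates[orientation].append(got)

    # keep the least degenerate candidates to bound the pairing cost;
    # forwards prefer leftmost anchors, reverses rightmost, so the two
    # retained sets can still bracket a long amplicon
    candidates["forward"].sort(key=lambda c: (c.deg, c.start))
    candidates["reverse"].sort(key=lambda c: (c.deg, -c.start))
    for key in candidates:
        candidates[key] = candidates[key][:80]

    def headroom(*cands: _Candidate) -> float:
        return min(
            min(c.tm_min - cons.tm_lo, cons.tm_hi - c.tm_max) for c in cands
        )

    raw_pairs = []
    for f in candidates["forward"]:
        for r in candidates["reverse"]:
            if r.start < f.end:
                continue
            amp_len = r.end - f.start
            if not (cons.min_amplicon <= amp_len <= cons.max_amplicon):
                diagnostics["pairs_rejected_amplicon"] += 1
                continue
            raw_pairs.append((f, r, amp_len))

    raw_pairs.sort(
        key=lambda t: (
            t[0].deg * t[1].deg,
            -headroom(t[0], t[1]),
            -t[2],
            t[0].start,
        )
    )

    pairs: list[PrimerPair] = []
    for f, r, amp_len in raw_pairs:
        if len(pairs) >= cons.max_pairs:
            break
        worst = min(
            _worst_dimer(f.iupac, r.iupac, params, dimer_cap, seed),
            _worst_dimer(f.iupac, f.iupac, params, dimer_cap, seed),
            _worst_dimer(r.iupac, r.iupac, params, dimer_cap, seed),
        )
        limit = cons.dimer_ratio * min(abs(f.dg_full), abs(r.dg_full))
        if abs(worst) > limit:
            diagnostics["pairs_rejected_dimer"] += 1
            continue
        fwd = DegeneratePrimer(
            iupac_seq=f.iupac, orientation="forward", degeneracy=f.deg,
            tm_min=f.tm_min, tm_max=f.tm_max, hairpin_tm=f.hairpin,
            dg_full_duplex=f.dg_full, dg_worst_dimer=worst,
        )
        rev = DegeneratePrimer(
            iupac_seq=r.iupac, orientation="reverse", degeneracy=r.deg,
            tm_min=r.tm_min, tm_max=r.tm_max, hairpin_tm=r.hairpin,
            dg_full_duplex=r.dg_full, dg_worst_dimer=worst,
        )
        pairs.append(
            PrimerPair(
                group_id=group_id, forward=fwd, reverse=rev,
                fwd_start=f.start, rev_end=r.end,
                expected_len=amp_len, dg_worst_dimer=worst,
            )
        )

    # constraint assertions on everything emitted
    for p in pairs:
        for prm in (p.forward, p.reverse):
            assert prm.tm_min >= cons.tm_lo and prm.tm_max <= cons.tm_hi
            assert prm.hairpin_tm is NO_STEM or prm.hairpin_tm <= cons.hairpin_max
        assert abs(p.dg_worst_dimer) <= cons.dimer_ratio * min(
            abs(p.forward.dg_full_duplex), abs(p.reverse.dg_full_duplex)
        ) + 1e-9
    return DesignResult(pairs=pairs, diagnostics=diagnostics)


def validate_panel(
    panel: PanelTable,
    design_set: dict[str, list[SequenceRecord]],
    max_len: int = 4000,
) -> dict[str, dict]:
    """Per-group perfect-match coverage of a panel on its own design set.

    ``design_set`` maps group_id -> the group's (ungapped) member
    sequences. Returns per-group fraction amplified and the ids missed.
    """
    from panelforge.insilico_pcr import amplify_seqs

    if not design_set:
        raise ValidationError("empty design set")
    unknown = [g for g in design_set if g not in {r.group_id for r in panel}]
    if unknown:
        raise ValidationError(f"unknown group label(s): {unknown}")
    report: dict[str, dict] = {}
    for gid, members in design_set.items():
        row = panel.row(gid)
        missed = []
        for rec in members:
            amps = amplify_seqs(
                row.fwd_seq, row.rev_seq, rec, max_mm=0, clamp_len=0,
                max_len=max_len,
            )
            if not amps:
                missed.append(rec.id)
        n = len(members)
        report[gid] = {
            "n_members": n,
            "n_amplified": n - len(missed),
            "coverage": (n - len(missed)) / n if n else 0.0,
            "missed": missed,
        }
    return report
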