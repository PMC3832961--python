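"""Nearest-neighbor thermodynamics for oligonucleotides.

Uses the unified NN parameter set (Allawi & SantaLucia 1997, as tabulated
in SantaLucia 1998) with the entropic monovalent-salt correction
``dS += 0.368 * (N-1) * ln[Na+]`` and divalent ions folded into an
effective monovalent concentration ``Na_eq = Na + 120 * sqrt(Mg)`` (mM).
Duplex Tm uses ``CT/4`` for non-self-complementary oligos. Free energies
are reported at the configured temperature (default 37 degC) via
``dG = dH - T * dS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from panelforge.seqio import ValidationError, reverse_complement

__all__ = [
    "NO_STEM",
    "ThermoParams",
    "duplex_dg",
    "hairpin_tm",
    "stack_dg",
    "tm_nn",
]

R_GAS = 1.987  # cal / (K mol)

#: Unified NN stacks: top-strand dinucleotide -> (dH kcal/mol, dS cal/K/mol).
#: Only 10 unique stacks; the complementary-strand reading maps onto them.
NN_STACKS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

#: Terminal base-pair initiation terms (per A/T or G/C end).
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)
#: Symmetry correction for self-complementary duplexes.
SYM = (0.0, -1.4)

#: Sentinel Tm for "no hairpin stem exists".
NO_STEM = float("-inf")

#: Entropic penalty for closing a hairpin loop, cal/(K mol). Corresponds
#: to ~ +3.5 kcal/mol at 37 degC, a typical small-loop closure cost.
HAIRPIN_LOOP_DS = -11.3


@dataclass(frozen=True)
class ThermoParams:
    """Buffer and oligo parameters for all thermodynamic calculations."""

    monovalent_salt_mm: float = 50.0
    divalent_salt_mm: float = 1.5
    primer_conc_um: float = 0.5
    dg_temperature_c: float = 37.0
    nn_parameter_set: str = "unified-santalucia-1998"

    def __post_init__(self) -> None:
        if self.monovalent_salt_mm < 0 or self.divalent_salt_mm < 0:
            raise ValidationError("salt concentrations must be >= 0")
        if self.primer_conc_um <= 0:
            raise ValidationError("primer concentration must be > 0")

    @property
    def na_equivalent_mm(self) -> float:
        return self.monovalent_salt_mm + 120.0 * math.sqrt(self.divalent_salt_mm)


def _stack_params(dinuc: str) -> tuple[float, float]:
    try:
        return NN_STACKS[dinuc]
    except KeyError:
        return NN_STACKS[reverse_complement(dinuc)]


def _check_plain(seq: str, caller: str) -> str:
    seq = seq.upper()
    bad = [ch for ch in seq if ch not in "ACGT"]
    if bad:
        raise ValidationError(
            f"{caller}: ambiguity code {bad[0]!r} not allowed; "
            "expand the degenerate sequence first"
        )
    return seq


def _duplex_dh_ds(seq: str) -> tuple[float, float]:
    """dH/dS of the perfect full-length duplex of ``seq``, incl. initiation."""
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = _stack_params(seq[i : i + 2])
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = INIT_AT if end in "AT" else INIT_GC
        dh += h
        ds += s
    return dh, ds


def tm_nn(seq: str, params: ThermoParams = ThermoParams()) -> float:
    """Nearest-neighbor melting temperature (degC) of a plain-DNA oligo."""
    seq = _check_plain(seq, "tm_nn")
    if len(seq) < 6:
        raise ValidationError("tm_nn requires length >= 6")
    dh, ds = _duplex_dh_ds(seq)
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        dh += SYM[0]
        ds += SYM[1]
    ds += 0.368 * (len(seq) - 1) * math.log(params.na_equivalent_mm * 1e-3)
    ct = params.primer_conc_um * 1e-6
    k = ct if selfcomp else ct / 4.0
    return 1000.0 * dh / (ds + R_GAS * math.log(k)) - 273.15


def stack_dg(dinuc: str, params: ThermoParams = ThermoParams()) -> float:
    """dG (kcal/mol) of one NN stack at the configured temperature."""
    dh, ds = _stack_params(dinuc)
    t = params.dg_temperature_c + 273.15
    return dh - t * ds / 1000.0


def duplex_full_dg(seq: str, params: ThermoParams = ThermoParams()) -> float:
    """dG of the perfect full-length self duplex (stacks only, no initiation).

    This is the "total dG" that the one-third dimer rule is measured
    against; consistent with :func:`duplex_dg`, which also sums stacks.
    """
    seq = _check_plain(seq, "duplex_full_dg")
    return sum(stack_dg(seq[i : i + 2], params) for i in range(len(seq) - 1))


def duplex_dg(
    seq1: str, seq2: str, params: ThermoParams = ThermoParams()
) -> float:
    """Most stable dG over all ungapped antiparallel offsets of seq1 vs seq2.

    NN stack terms are summed over contiguous complementary stretches of
    >= 2 bp; returns 0.0 when no such stretch exists at any offset.
    """
    seq1 = _check_plain(seq1, "duplex_dg")
    seq2 = _check_plain(seq2, "duplex_dg")
    # antiparallel register: seq1 5'->3' against seq2 3'->5'
    s2r = seq2[::-1]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    best = 0.0
    n1, n2 = len(seq1), len(s2r)
    for offset in range(-(n2 - 1), n1):
        dg = 0.0
        run_start = None
        lo = max(0, offset)
        hi = min(n1, offset + n2)
        for i in range(lo, hi + 1):
            paired = i < hi and seq1[i] == comp[s2r[i - offset]]
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                if i - run_start >= 2:
                    dg += sum(
                        stack_dg(seq1[j : j + 2], params)
                        for j in range(run_start, i - 1)
                    )
                run_start = None
        best = min(best, dg)
    return best


def hairpin_tm(seq: str, params: ThermoParams = ThermoParams()) -> float:
    """Tm (degC) of the most stable intramolecular hairpin stem.

    Scans all stems of >= 3 bp with loops of >= 3 nt; the stem
    contributes NN stack dH/dS and the loop a fixed entropy penalty
    (unimolecular, so no concentration term). Returns :data:`NO_STEM`
    when no qualifying stem exists.
    """
    seq = _check_plain(seq, "hairpin_tm")
    if len(seq) < 8:
        raise ValidationError("hairpin_tm requires length >= 8")
    ds_salt_per_stack = 0.368 * math.log(params.na_equivalent_mm * 1e-3)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    best = NO_STEM
    # all stems: 5' arm starts at i, 3' arm ends at j (pairing with i),
    # stem length k, loop = j - i - 2k + 1 >= 3
    for i in range(n):
        for j in range(i + 7, n):
            for k in range(3, (j - i - 2) // 2 + 1):
                if any(seq[i + m] != comp[seq[j - m]] for m in range(k)):
                    break  # longer stems at (i, j) pair the same bases
                dh = ds = 0.0
                for m in range(k - 1):
                    h, s = _stack_params(seq[i + m : i + m + 2])
                    dh += h
                    ds += s
                ds += HAIRPIN_LOOP_DS + (k - 1) * ds_salt_per_stack
                if ds < 0 and dh < 0:
                    best = max(best, 1000.0 * dh / ds - 273.15)
    return best
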