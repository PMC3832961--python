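import itertools
import random

import pytest

from panelforge.insilico_pcr import amplify_seqs
from panelforge.primer_engine import (
    DegeneratePrimer,
    PrimerConstraints,
    ThermoParams,
    degeneracy,
    design_pair,
    enumerate_expansions,
    iupac_consensus,
    tm_nn,
    tm_range_degenerate,
    validate_panel,
)
from panelforge.seqio import (
    IUPAC_SETS,
    Alignment,
    PanelTable,
    SequenceRecord,
    ValidationError,
    reverse_complement,
)

from conftest import mutate_dna, random_dna


def aln_from(rows: dict[str, str]) -> Alignment:
    return Alignment(
        rows=[
            SequenceRecord(id=k, residues=v, allow_gap=True)
            for k, v in rows.items()
        ]
    )


class TestConsensus:
    def test_mixed_sets(self):
        assert iupac_consensus([{"A"}, {"A", "G"}, {"C", "G", "T"}]) == "ARB"

    def test_singletons_literal(self):
        assert iupac_consensus([{"A"}, {"C"}, {"G"}, {"T"}]) == "ACGT"

    def test_full_set_is_n(self):
        assert iupac_consensus([{"A", "C", "G", "T"}]) == "N"

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            iupac_consensus([set()])

    def test_gap_rejected(self):
        with pytest.raises(ValidationError, match="gap"):
            iupac_consensus([{"A", "-"}])

    def test_consensus_matches_every_member(self):
        columns = [{"A", "G"}, {"C"}, {"C", "T"}]
        consensus = iupac_consensus(columns)
        for combo in itertools.product(*[sorted(c) for c in columns]):
            for ch, code in zip(combo, consensus):
                assert ch in IUPAC_SETS[code]


class TestDegeneracy:
    def test_plain(self):
        assert degeneracy("ACGT") == 1

    def test_ryn(self):
        assert degeneracy("RYN") == 16

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            degeneracy("")

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_enumeration_count(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGTRYSWKM") for _ in range(6))
        assert degeneracy(seq) == len(enumerate_expansions(seq, cap=10_000))


class TestEnumerateExpansions:
    def test_simple(self):
        assert enumerate_expansions("AR") == ["AA", "AG"]

    def test_n_full(self):
        assert enumerate_expansions("N", cap=4) == ["A", "C", "G", "T"]

    def test_capped_sampling_deterministic(self):
        seq = "N" * 5  # degeneracy 1024
        sample1 = enumerate_expansions(seq, cap=64, seed=42)
        sample2 = enumerate_expansions(seq, cap=64, seed=42)
        assert sample1 == sample2
        assert len(set(sample1)) == 64
        assert "A" * 5 in sample1 and "T" * 5 in sample1

    def test_different_seed_different_sample(self):
        seq = "N" * 6
        assert enumerate_expansions(seq, 32, seed=1) != enumerate_expansions(
            seq, 32, seed=2
        )


class TestTmRange:
    def test_degeneracy_one_collapses(self):
        lo, hi = tm_range_degenerate("GACGTCCAGTGCAGCTAGCA")
        assert lo == hi

    def test_r_spans_both_variants(self):
        seq = "GACGTCCAGTGCAGCTAGCR"
        lo, hi = tm_range_degenerate(seq)
        tm_a = tm_nn(seq[:-1] + "A")
        tm_g = tm_nn(seq[:-1] + "G")
        assert lo == pytest.approx(min(tm_a, tm_g))
        assert hi == pytest.approx(max(tm_a, tm_g))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_bruteforce_under_cap(self, seed):
        rng = random.Random(seed)
        seq = random_dna(rng, 16) + "".join(rng.choice("RYSW") for _ in range(4))
        lo, hi = tm_range_degenerate(seq, cap=64)
        tms = [tm_nn(s) for s in enumerate_expansions(seq, cap=10_000)]
        assert lo == pytest.approx(min(tms))
        assert hi == pytest.approx(max(tms))

    def test_expansion_tms_within_range(self):
        seq = "GACGTCCAGTGCAGCTRGCW"
        lo, hi = tm_range_degenerate(seq)
        for s in enumerate_expansions(seq, cap=16):
            assert lo - 1e-9 <= tm_nn(s) <= hi + 1e-9


def conserved_group_alignment(n_rows=4, length=620, seed=5) -> Alignment:
    """Fully conserved alignment: consensus primers are degeneracy-1."""
    rng = random.Random(seed)
    seq = random_dna(rng, length)
    return aln_from({f"M{i}": seq for i in range(1, n_rows + 1)})


class TestDesignPair:
    def test_conserved_alignment_yields_degeneracy_one_pair(self):
        aln = conserved_group_alignment()
        result = design_pair(aln, PrimerConstraints(min_amplicon=300, max_amplicon=620))
        assert result.pairs, result.diagnostics
        top = result.pairs[0]
        assert top.combined_degeneracy() == 1
        # both primers match every member exactly
        for row in aln.rows:
            rec = SequenceRecord(id=row.id, residues=row.ungapped)
            assert amplify_seqs(
                top.forward.iupac_seq, top.reverse.iupac_seq, rec,
                max_mm=0, clamp_len=0,
            )

    def test_emitted_pairs_satisfy_all_constraints(self):
        cons = PrimerConstraints(min_amplicon=300, max_amplicon=620)
        result = design_pair(conserved_group_alignment(seed=9), cons)
        for pair in result.pairs:
            for primer in (pair.forward, pair.reverse):
                assert primer.tm_min >= cons.tm_lo
                assert primer.tm_max <= cons.tm_hi
                assert primer.hairpin_tm <= cons.hairpin_max
            limit = cons.dimer_ratio * min(
                abs(pair.forward.dg_full_duplex),
                abs(pair.reverse.dg_full_duplex),
            )
            assert abs(pair.dg_worst_dimer) <= limit + 1e-9

    def test_hyperdegenerate_alignment_rejected_with_diagnostics(self):
        # every column takes all four bases -> every window exceeds the cap
        rows = {}
        length = 400
        for i, base in enumerate(["A", "C", "G", "T"]):
            rng = random.Random(i)
            rows[f"M{i}"] = "".join(
                "ACGT"[(j + i) % 4] for j in range(length)
            )
        result = design_pair(aln_from(rows), PrimerConstraints())
        assert result.pairs == []
        assert result.diagnostics["rejected_degeneracy"] > 0

    def test_gapped_windows_ineligible(self):
        rng = random.Random(1)
        seq = random_dna(rng, 60)
        rows = {"A": seq, "B": seq[:30] + "-" * 5 + seq[35:]}
        result = design_pair(aln_from(rows), PrimerConstraints(min_amplicon=10, max_amplicon=60))
        assert result.diagnostics["rejected_gap"] > 0

    def test_reverse_primer_is_revcomp_of_window_consensus(self):
        aln = conserved_group_alignment(seed=11)
        result = design_pair(aln, PrimerConstraints(min_amplicon=300, max_amplicon=620))
        top = result.pairs[0]
        window = aln.rows[0].residues[
            top.rev_end - len(top.reverse.iupac_seq) : top.rev_end
        ]
        assert top.reverse.iupac_seq == reverse_complement(window)

    def test_expected_len_invariant(self):
        result = design_pair(
            conserved_group_alignment(seed=13),
            PrimerConstraints(min_amplicon=300, max_amplicon=620),
        )
        for pair in result.pairs:
            assert pair.expected_len == pair.rev_end - pair.fwd_start

    def test_deterministic_under_seed(self):
        aln = conserved_group_alignment(seed=17)
        cons = PrimerConstraints(min_amplicon=300, max_amplicon=620)
        r1 = design_pair(aln, cons, seed=7)
        r2 = design_pair(aln, cons, seed=7)
        assert [p.as_panel_row() for p in r1.pairs] == [
            p.as_panel_row() for p in r2.pairs
        ]


class TestValidatePanel:
    def _panel_and_members(self, seed=21):
        aln = conserved_group_alignment(seed=seed)
        result = design_pair(
            aln, PrimerConstraints(min_amplicon=300, max_amplicon=620),
            group_id="1",
        )
        panel = PanelTable(rows=[result.pairs[0].as_panel_row()])
        members = [
            SequenceRecord(id=r.id, residues=r.ungapped) for r in aln.rows
        ]
        return panel, members

    def test_own_group_full_coverage(self):
        panel, members = self._panel_and_members()
        report = validate_panel(panel, {"1": members})
        assert report["1"]["coverage"] == 1.0
        assert report["1"]["missed"] == []

    def test_three_prime_mutation_flagged(self):
        panel, members = self._panel_and_members()
        row = panel.row("1")
        fwd = row.fwd_seq
        seq = members[0].residues
        pos = seq.index(fwd) + len(fwd) - 1  # 3' terminal base of fwd site
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
        members[0] = SequenceRecord(id=members[0].id, residues=mutated)
        report = validate_panel(panel, {"1": members})
        assert members[0].id in report["1"]["missed"]

    def test_empty_design_set_rejected(self):
        panel, _ = self._panel_and_members()
        with pytest.raises(ValidationError, match="empty"):
            validate_panel(panel, {})

    def test_unknown_group_rejected(self):
        panel, members = self._panel_and_members()
        with pytest.raises(ValidationError, match="unknown group"):
            validate_panel(panel, {"99": members})


class TestDegeneratePrimerInvariants:
    def test_degeneracy_must_match_sequence(self):
        with pytest.raises(ValidationError):
            DegeneratePrimer(
                iupac_seq="ACGR", orientation="forward", degeneracy=3,
                tm_min=50, tm_max=55, hairpin_tm=0, dg_full_duplex=-10,
            )

    def test_orientation_checked(self):
        with pytest.raises(ValidationError):
            DegeneratePrimer(
                iupac_seq="ACGT", orientation="sideways", degeneracy=1,
                tm_min=50, tm_max=55, hairpin_tm=0, dg_full_duplex=-10,
            )
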