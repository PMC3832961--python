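import random

import pytest

from panelforge.seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(n))


def mutate_protein(seq: str, n_subs: int, rng: random.Random) -> str:
    chars = list(seq)
    for pos in rng.sample(range(len(chars)), n_subs):
        chars[pos] = rng.choice([a for a in AA20 if a != chars[pos]])
    return "".join(chars)


def mutate_dna(seq: str, n_subs: int, rng: random.Random) -> str:
    chars = list(seq)
    for pos in rng.sample(range(len(chars)), n_subs):
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(0)


@pytest.fixture
def dna_record(rng) -> SequenceRecord:
    return SequenceRecord(id="seq1", residues=random_dna(rng, 120))
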