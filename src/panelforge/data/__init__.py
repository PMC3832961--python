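"""Registry for the vendored worked-example GenBank records.

See README.txt in this directory for provenance and how to populate the
FASTA files when they are absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

_DATA_DIR = Path(__file__).parent


@dataclass(frozen=True)
class HomologCase:
    """One deposited-amplicon vs characterized-protein worked example."""

    target_id: str
    amplicon_accession: str
    reference_accession: str
    reference_name: str

    @property
    def amplicon_path(self) -> Path:
        return _DATA_DIR / f"{self.amplicon_accession}.fasta"

    @property
    def reference_path(self) -> Path:
        return _DATA_DIR / f"{self.reference_accession}.fasta"

    def available(self) -> bool:
        return self.amplicon_path.exists() and self.reference_path.exists()


HOMOLOG_CASES: tuple[HomologCase, ...] = (
    HomologCase("t1", "KF138765", "AAQ94119", "VcrA (D. mccartyi VS)"),
    HomologCase("t2", "KF138603", "AAT64888", "BvcA (D. mccartyi BAV1)"),
    HomologCase("t3", "KF138991", "AAF73916", "TceA (D. mccartyi 195)"),
)
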