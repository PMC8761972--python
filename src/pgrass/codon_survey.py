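"""Gene-specific codon frequency survey over CDS datasets.

Answers the question behind orientation screening's general applicability:
what fraction of genes in an organism's coding sequences contain at least
one in-frame TCA, TTA or CTA codon (and so can be screened by premature
antisense termination)?  Matching is strictly frame-aware — a target
trinucleotide occurring out of frame never counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from pgrass.olivar import enumerate_target_codons
from pgrass.seqcore import NucSeq, codons, read_fasta


class EmptyDatasetError(ValueError):
    """No frame-valid coding sequences to analyse."""


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence of a dataset; ``frame_valid`` gates analysis.

    A record is frame-valid when its length is a multiple of 3 and no
    scanned codon position contains an ambiguous base.
    """

    id: str
    seq: NucSeq

    @property
    def frame_valid(self) -> bool:
        return len(self.seq) % 3 == 0 and "N" not in self.seq.bases


@dataclass(frozen=True)
class SurveyResult:
    """Per-dataset fraction of genes carrying at least one target codon."""

    n_genes: int
    n_with_target: int
    per_codon: dict[str, float] = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def fraction(self) -> float:
        return self.n_with_target / self.n_genes

    def to_frame(self, dataset: str = "dataset") -> pd.DataFrame:
        row = {
            "dataset": dataset,
            "n_genes": self.n_genes,
            "n_with_target": self.n_with_target,
            "fraction": self.fraction,
            "n_skipped": self.n_skipped,
        }
        row.update({f"frac_{c}": f for c, f in sorted(self.per_codon.items())})
        return pd.DataFrame([row])


def survey_cds(
    records: list[CdsRecord],
    target_codons: frozenset[str] | set[str] | None = None,
) -> SurveyResult:
    """Fraction of genes containing >=1 in-frame target codon.

    A gene counts iff one of its in-frame codons (positions 0, 3, 6, ...) is
    in ``target_codons``; the terminal stop codon, if present, is scanned
    like any other codon (it can never match the default target set).
    Frame-invalid records are skipped and tallied in ``n_skipped``.
    """
    if target_codons is None:
        target_codons = enumerate_target_codons()
    target_codons = frozenset(target_codons)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in CDS dataset")
    valid = [r for r in records if r.frame_valid]
    if not valid:
        raise EmptyDatasetError("no frame-valid coding sequences in dataset")
    n_with = 0
    per_codon_hits = {c: 0 for c in target_codons}
    for r in valid:
        gene_codons = set(codons(r.seq.bases))
        present = gene_codons & target_codons
        if present:
            n_with += 1
        for c in present:
            per_codon_hits[c] += 1
    return SurveyResult(
        n_genes=len(valid),
        n_with_target=n_with,
        per_codon={c: k / len(valid) for c, k in per_codon_hits.items()},
        n_skipped=len(records) - len(valid),
    )


def load_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a multi-FASTA CDS dataset (pre-extracted coding sequences)."""
    return [CdsRecord(s.id, s) for s in read_fasta(path)]


def write_survey_tsv(result: SurveyResult, path: str | Path, dataset: str = "dataset") -> None:
    result.to_frame(dataset).to_csv(path, sep="\t", index=False)
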