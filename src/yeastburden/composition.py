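"""Proteome amino-acid usage relative to codon-table expectation.

The null model: if residues were drawn uniformly at random from the 61 sense
codons of the standard nuclear code, each amino acid would occur with
probability n_codons(aa) / 61 (e.g. cysteine: 2/61).  Relative usage is the
observed residue frequency in a proteome (or a subset such as highly
expressed proteins) divided by that expectation; values below 1 indicate
depletion.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AAS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Default copies-per-cell cutoff defining "highly expressed" proteins.
HIGH_EXPRESSION_THRESHOLD: float = 100_000.0

N_SENSE_CODONS: int = 61


def _codon_counts() -> dict[str, int]:
    table = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
    counts = Counter(table.forward_table.values())
    assert sum(counts.values()) == N_SENSE_CODONS
    return {aa: counts[aa] for aa in STANDARD_AAS}


#: Number of sense codons encoding each standard amino acid.
CODON_COUNTS: dict[str, int] = _codon_counts()


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, amino-acid sequence, optional abundance.

    ``abundance`` is copies per cell (or any nonnegative expression proxy);
    ``None`` means unknown.
    """

    id: str
    sequence: str
    abundance: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence.rstrip("*")) < 1:
            raise ValueError(f"{self.id}: empty sequence after stripping terminal stop")
        if self.abundance is not None and self.abundance < 0:
            raise ValueError(f"{self.id}: abundance must be nonnegative")


@dataclass
class UsageProfile:
    """Per-amino-acid usage table for one proteome subset.

    ``table`` is indexed by one-letter code with columns ``observed_count``,
    ``observed_frequency``, ``expected_probability`` and ``relative_usage``.
    """

    table: pd.DataFrame
    total_residues: int
    subset_label: str
    excluded_letters: int = 0

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="amino_acid")


def expected_aa_probability(amino_acid: str) -> float:
    """Probability of ``amino_acid`` under uniform draws from the 61 sense codons."""
    try:
        return CODON_COUNTS[amino_acid] / N_SENSE_CODONS
    except KeyError:
        raise ValueError(f"unknown amino acid code: {amino_acid!r}") from None


def count_amino_acids(sequence: str) -> tuple[dict[str, int], int]:
    """Count standard residues in one sequence.

    A terminal ``*`` (stop marker) is stripped first.  Nonstandard letters
    (X, U, B, Z, internal ``*``, ...) are excluded from the counts and
    returned as a separate total.

    Returns
    -------
    counts, n_excluded
        ``counts`` maps every one of the 20 standard letters to an integer.
    """
    seq = sequence.rstrip("*").upper()
    if not seq:
        raise ValueError("empty sequence")
    raw = Counter(seq)
    counts = {aa: raw.get(aa, 0) for aa in STANDARD_AAS}
    n_excluded = len(seq) - sum(counts.values())
    return counts, n_excluded


def select_high_expression(
    records: Iterable[ProteinRecord],
    threshold: float = HIGH_EXPRESSION_THRESHOLD,
) -> list[ProteinRecord]:
    """Proteins with abundance strictly greater than ``threshold``.

    Records lacking an abundance are excluded; the count of such records is
    logged so the exclusion is visible.
    """
    records = list(records)
    missing = sum(1 for r in records if r.abundance is None)
    if missing:
        logger.warning("%d records lack abundance and were excluded", missing)
    return [r for r in records if r.abundance is not None and r.abundance > threshold]


def relative_usage(
    records: Sequence[ProteinRecord],
    subset_label: str = "proteome",
) -> UsageProfile:
    """Pooled amino-acid usage of ``records`` relative to codon expectation.

    Residue counts are pooled across all sequences (equivalent to counting in
    the concatenated proteome); each amino acid's observed frequency is then
    divided by its codon-table expected probability.
    """
    if len(records) == 0:
        raise ValueError("need at least one protein record")
    pooled = Counter()
    excluded = 0
    for rec in records:
        counts, n_exc = count_amino_acids(rec.sequence)
        pooled.update(counts)
        excluded += n_exc
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("no standard residues in input")
    rows = {}
    for aa in STANDARD_AAS:
        obs_freq = pooled[aa] / total
        exp_p = expected_aa_probability(aa)
        rows[aa] = {
            "observed_count": pooled[aa],
            "observed_frequency": obs_freq,
            "expected_probability": exp_p,
            "relative_usage": obs_freq / exp_p,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["observed_count"] = table["observed_count"].astype(int)
    return UsageProfile(
        table=table,
        total_residues=total,
        subset_label=subset_label,
        excluded_letters=excluded,
    )


def aa_counts_table(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Per-protein counts of the 20 standard residues (rows = protein ids)."""
    data = {}
    for rec in records:
        counts, _ = count_amino_acids(rec.sequence)
        data[rec.id] = counts
    return pd.DataFrame.from_dict(data, orient="index", columns=list(STANDARD_AAS)).fillna(0).astype(int)


def join_abundance(
    records: Sequence[ProteinRecord],
    abundance: Mapping[str, float],
) -> list[ProteinRecord]:
    """Attach abundances (gene id -> copies per cell) to protein records."""
    return [
        ProteinRecord(r.id, r.sequence, abundance.get(r.id, r.abundance))
        for r in records
    ]
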