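"""In silico tryptic digestion and the weighted peptide-completeness metric.

Trypsin cleaves C-terminal to lysine (K) and arginine (R); by the standard
rule, cleavage is suppressed when the next residue is proline. The number of
distinct tryptic peptides a species contributes to a database is a proxy for
how completely its proteome is represented; weighting the log-transformed
per-species peptide counts by 16S relative abundance gives a single
database-completeness score per sample:

    W = sum_i ln(1 + G_i) * A_i

where G_i is the number of unique tryptic peptides longer than five residues
available for species i and A_i its relative abundance in the sample.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .dbforge import AbundanceProfile, ProteinRecord, ValidationError

_VALID_SEQ = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion settings.

    max_missed_cleavages: internal cleavage sites allowed per peptide.
    min_length: shortest peptide emitted, in residues.
    suppress_cleavage_before_proline: skip K/R sites followed by P.
    """

    max_missed_cleavages: int = 0
    min_length: int = 1
    suppress_cleavage_before_proline: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")
        if self.max_missed_cleavages < 0:
            raise ValidationError("max_missed_cleavages must be >= 0")


#: Digest used for the completeness metric: fully tryptic, no missed
#: cleavages, peptides longer than five residues.
METRIC_DIGEST = DigestParams(max_missed_cleavages=0, min_length=6)


def cleavage_sites(sequence: str, suppress_proline: bool = True) -> list[int]:
    """Positions after which trypsin cleaves (0 < pos < len)."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and not (suppress_proline and sequence[i] == "P"):
            sites.append(i)
    return sites


def digest_protein(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Tryptic peptides of one protein, ordered by start position then span.

    With zero missed cleavages and ``min_length`` 1 the emitted peptides
    concatenate back to the input sequence.
    """
    if not sequence or not _VALID_SEQ.match(sequence):
        bad = sorted(set(sequence) - set("ACDEFGHIKLMNPQRSTVWY")) or ["<empty>"]
        raise ValidationError(f"invalid amino-acid characters {bad}")
    bounds = [0] + cleavage_sites(sequence, params.suppress_cleavage_before_proline) + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + params.max_missed_cleavages, len(bounds))):
            pep = sequence[bounds[i] : bounds[j]]
            if len(pep) >= params.min_length:
                peptides.append(pep)
    return peptides


def unique_tryptic_peptides(
    records: Iterable[ProteinRecord],
    params: DigestParams = METRIC_DIGEST,
) -> dict[str, int]:
    """Distinct tryptic peptide count per species, duplicates counted once."""
    per_species: dict[str, set[str]] = {}
    for rec in records:
        bag = per_species.setdefault(rec.species, set())
        bag.update(digest_protein(rec.sequence, params))
    return {species: len(peps) for species, peps in per_species.items()}


@dataclass
class WeightedPeptideScore:
    """Per-sample weighted tryptic-peptide completeness W."""

    sample_id: str
    per_species: list[tuple[str, int, float]] = field(default_factory=list)
    # each entry: (species, G_i, A_i)
    value: float = 0.0

    @property
    def n(self) -> int:
        return len(self.per_species)


def weighted_tryptic_metric(
    profile: AbundanceProfile,
    counts: Mapping[str, int],
) -> WeightedPeptideScore:
    """W = sum ln(1+G_i)*A_i over the species in the profile.

    Species absent from ``counts`` contribute G_i = 0 (no public peptides),
    mirroring taxa with no sequenced genome.
    """
    rows: list[tuple[str, int, float]] = []
    total = 0.0
    for species, _genus, ab in profile.entries:
        if ab < 0:
            raise ValidationError(f"negative abundance for {species!r}")
        g = int(counts.get(species, 0))
        if g < 0:
            raise ValidationError(f"negative peptide count for {species!r}")
        rows.append((species, g, ab))
        total += math.log1p(g) * ab
    return WeightedPeptideScore(sample_id=profile.sample_id, per_species=rows, value=total)
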