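"""PSM classification, filtering, peptide validity, and protein inference.

Implements the hierarchical spectrum classification used for metaproteomic
bookkeeping (decoy > contaminant > human > fungal > trichomonas > bacterial),
the strict q < 0.01 significance filter, the two peptide-validity rules
(spectral probability < 1e-15, or two unique peptides on one protein), greedy
unique-protein counting with peptide-pool removal, taxonomic assignment over
all matched proteins, and the replicate-overlap partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dbforge import ProteinDatabase, ProteinRecord, ValidationError
from .searchlite import DECOY_PREFIX

#: classification precedence, highest first
LABELS = ("decoy", "contaminant", "human", "fungal", "trichomonas", "bacterial")

_CATEGORY_TO_LABEL = {
    "decoy": "decoy",
    "contaminant": "contaminant",
    "host": "human",
    "fungal": "fungal",
    "parasite": "trichomonas",
    "bacterial": "bacterial",
    "translated_ORF": "bacterial",
}

PROBABILITY_RULE_THRESHOLD = 1e-15
Q_THRESHOLD = 0.01


def _label_for(protein_ids: Iterable[str], categories: Mapping[str, str]) -> str:
    seen = set()
    for pid in protein_ids:
        if pid.startswith(DECOY_PREFIX):
            return "decoy"
        cat = categories.get(pid)
        if cat is None:
            raise ValidationError(f"protein id {pid!r} not resolvable to a category")
        seen.add(_CATEGORY_TO_LABEL[cat])
    for label in LABELS:
        if label in seen:
            return label
    return "bacterial"


def classify_psms(psms: pd.DataFrame, categories: Mapping[str, str] | ProteinDatabase) -> pd.DataFrame:
    """Assign one hierarchical label per PSM (a total function).

    Any decoy match makes the PSM a decoy; any contaminant match a
    contaminant; any host match human; then fungal, then trichomonas, and
    bacterial only when nothing but bacterial (or unresolved-ORF) proteins
    matched.
    """
    if isinstance(categories, ProteinDatabase):
        categories = categories.category_index()
    out = psms.copy()
    out["classification"] = [
        _label_for(ids.split(";"), categories) for ids in out["protein_ids"]
    ]
    return out


def classification_counts(psms: pd.DataFrame) -> dict[str, int]:
    counts = psms["classification"].value_counts().to_dict()
    return {label: int(counts.get(label, 0)) for label in LABELS}


def filter_significant(psms: pd.DataFrame, q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Strict q < threshold; decoy and contaminant PSMs are then discarded
    (they are counted by :func:`classification_counts` beforehand for audit).
    """
    sig = psms[psms["q_value"] < q_threshold]
    return sig[~sig["classification"].isin(["decoy", "contaminant"])]


# ---------------------------------------------------------------------------
# Peptide validity
# ---------------------------------------------------------------------------

def valid_peptides(significant_psms: pd.DataFrame) -> pd.DataFrame:
    """Peptides retained for further analysis, with their qualifying rule.

    A peptide qualifies if (i) any supporting PSM has spectral probability
    below 1e-15 (``probability`` rule), or (ii) some protein it matches has
    at least two distinct significant peptides (``two_peptide`` rule).

    Returns one row per peptide: ``peptide``, ``rule``, ``n_psms``,
    ``min_spectral_probability``, ``protein_ids`` (union over supporting
    PSMs), ``classification``.
    """
    if significant_psms.empty:
        return pd.DataFrame(
            columns=["peptide", "rule", "n_psms", "min_spectral_probability",
                     "protein_ids", "classification"]
        )
    per_pep: dict[str, dict] = {}
    protein_peptides: dict[str, set[str]] = {}
    for row in significant_psms.itertuples():
        info = per_pep.setdefault(
            row.peptide,
            {"n": 0, "minp": 1.0, "proteins": set(), "classification": row.classification},
        )
        info["n"] += 1
        info["minp"] = min(info["minp"], row.spectral_probability)
        ids = row.protein_ids.split(";")
        info["proteins"].update(ids)
        for pid in ids:
            protein_peptides.setdefault(pid, set()).add(row.peptide)
    rows = []
    for pep in sorted(per_pep):
        info = per_pep[pep]
        if info["minp"] < PROBABILITY_RULE_THRESHOLD:
            rule = "probability"
        elif any(len(protein_peptides[pid]) >= 2 for pid in info["proteins"]):
            rule = "two_peptide"
        else:
            continue
        rows.append(
            (
                pep,
                rule,
                info["n"],
                info["minp"],
                ";".join(sorted(info["proteins"])),
                info["classification"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=["peptide", "rule", "n_psms", "min_spectral_probability",
                 "protein_ids", "classification"],
    )


# ---------------------------------------------------------------------------
# Greedy unique-protein counting
# ---------------------------------------------------------------------------

@dataclass
class ProteinCount:
    """Result of greedy unique-protein counting."""

    counted: dict[str, list[str]] = field(default_factory=dict)
    # category label ("human"/"bacterial"/...) -> counted representative ids

    def totals(self) -> dict[str, int]:
        return {cat: len(ids) for cat, ids in self.counted.items()}


def count_unique_proteins(
    peptides: pd.DataFrame,
    db: ProteinDatabase | Sequence[ProteinRecord],
) -> ProteinCount:
    """Greedy protein counting over the valid-peptide pool.

    Proteins with identical sequences are collapsed to one representative
    (smallest record id). Proteins are visited in a deterministic order —
    descending number of distinct supporting peptides, ties by ascending
    record id — and counted if, against the CURRENT peptide pool, (i) more
    than one non-identical matching peptide exists, (ii) some matching
    peptide was observed more than once, or (iii) some matching peptide has
    spectral probability < 1e-15. A counted protein's peptides leave the
    pool, so shared peptides support at most one counted protein.
    """
    records = db.records if isinstance(db, ProteinDatabase) else list(db)
    by_id = {r.record_id: r for r in records}
    # collapse identical sequences to one representative id
    rep_of: dict[str, str] = {}
    seq_rep: dict[str, str] = {}
    for rec in sorted(records, key=lambda r: r.record_id):
        rep = seq_rep.setdefault(rec.sequence, rec.record_id)
        rep_of[rec.record_id] = rep

    pep_info: dict[str, tuple[int, float]] = {}
    protein_peps: dict[str, set[str]] = {}
    for row in peptides.itertuples():
        pep_info[row.peptide] = (int(row.n_psms), float(row.min_spectral_probability))
        for pid in row.protein_ids.split(";"):
            if pid.startswith(DECOY_PREFIX) or pid not in rep_of:
                continue
            protein_peps.setdefault(rep_of[pid], set()).add(row.peptide)

    order = sorted(protein_peps, key=lambda pid: (-len(protein_peps[pid]), pid))
    pool = set(pep_info)
    result = ProteinCount()
    for pid in order:
        current = protein_peps[pid] & pool
        if not current:
            continue
        qualifies = (
            len(current) > 1
            or any(pep_info[p][0] > 1 for p in current)
            or any(pep_info[p][1] < PROBABILITY_RULE_THRESHOLD for p in current)
        )
        if not qualifies:
            continue
        label = _CATEGORY_TO_LABEL.get(by_id[pid].category, "bacterial")
        result.counted.setdefault(label, []).append(pid)
        pool -= current
    return result


# ---------------------------------------------------------------------------
# Taxonomic assignment
# ---------------------------------------------------------------------------

def assign_taxa(
    psms: pd.DataFrame, db: ProteinDatabase | Mapping[str, ProteinRecord]
) -> pd.DataFrame:
    """Species/genus sets over all matched proteins, with exclusivity flags.

    Exclusive means every matched protein agrees on a single species (or
    genus); unresolved ORFs propagate the literal taxon ``Unknown``.
    """
    by_id = db.by_id() if isinstance(db, ProteinDatabase) else dict(db)
    species_sets, genus_sets, sp_exc, ge_exc = [], [], [], []
    for ids in psms["protein_ids"]:
        species, genera = set(), set()
        for pid in ids.split(";"):
            if pid.startswith(DECOY_PREFIX):
                continue
            rec = by_id.get(pid)
            if rec is None:
                raise ValidationError(f"protein id {pid!r} not in database")
            species.add(rec.species or "Unknown")
            genera.add(rec.genus or "Unknown")
        species_sets.append(";".join(sorted(species)))
        genus_sets.append(";".join(sorted(genera)))
        sp_exc.append(len(species) == 1)
        ge_exc.append(len(genera) == 1)
    out = psms.copy()
    out["species_set"] = species_sets
    out["genus_set"] = genus_sets
    out["species_exclusive"] = sp_exc
    out["genus_exclusive"] = ge_exc
    return out


# ---------------------------------------------------------------------------
# Replicate overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapPartition:
    first_only: int
    second_only: int
    both: int

    @property
    def union(self) -> int:
        return self.first_only + self.second_only + self.both

    def percentages(self) -> tuple[float, float, float]:
        """(first_only%, second_only%, both%), one-decimal rounding."""
        u = self.union
        return (
            round(100.0 * self.first_only / u, 1),
            round(100.0 * self.second_only / u, 1),
            round(100.0 * self.both / u, 1),
        )


def replicate_overlap(peptides_rep1: Iterable[str], peptides_rep2: Iterable[str]) -> OverlapPartition:
    """Partition the peptide union into first-only / second-only / both."""
    s1, s2 = set(peptides_rep1), set(peptides_rep2)
    if not s1 and not s2:
        raise ValidationError("both replicate peptide sets are empty; partition undefined")
    return OverlapPartition(
        first_only=len(s1 - s2),
        second_only=len(s2 - s1),
        both=len(s1 & s2),
    )
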