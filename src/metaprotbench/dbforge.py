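"""Protein records, abundance profiles, and database-construction strategies.

Metaproteomic search results depend heavily on the protein database searched.
This module builds the competing database strategies evaluated by the
benchmark: a Global database (everything public), per-sample 16S-matched
databases (taxa above an abundance cutoff), a pooled variant, reference-strain
variants, shotgun (translated-ORF) databases, and hybrid databases that merge
public and shotgun sequences with exact-sequence deduplication.

FASTA header dialect (pipe-delimited, no pipes inside fields)::

    >{record_id}|{category}|{genus}|{species}|{strain}
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("metaprotbench")

# 20 standard residues; sequences are validated against this alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_SEQ = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

CATEGORIES = frozenset(
    {"host", "bacterial", "fungal", "parasite", "contaminant", "translated_ORF", "decoy"}
)
SOURCES = frozenset({"public", "shotgun", "core"})

#: Strategy names for the seven database types plus "custom" for augmented sets.
STRATEGIES = (
    "global",
    "pooled_16s",
    "sample_matched_16s",
    "reference_16s",
    "shotgun_pooled",
    "shotgun_sample_matched",
    "hybrid_sample_matched",
    "custom",
)

#: The five strategies compared head-to-head by relative identification rate.
COMPARED_STRATEGIES = (
    "pooled_16s",
    "sample_matched_16s",
    "shotgun_pooled",
    "shotgun_sample_matched",
    "hybrid_sample_matched",
)

#: Extra organisms folded into the pooled public database by default when real
#: sequence data is supplied (common vaginal fungi, the T. vaginalis parasite,
#: and two bacterial STI pathogens).
POOLED_EXTRA_TAXA = (
    ("Trichomonas vaginalis", "parasite"),
    ("Chlamydia trachomatis", "bacterial"),
    ("Neisseria gonorrhoeae", "bacterial"),
    ("Alternaria alternata", "fungal"),
    ("Candida albicans", "fungal"),
    ("Candida glabrata", "fungal"),
    ("Candida tropicalis", "fungal"),
    ("Pichia kudriavzevii", "fungal"),
    ("Saccharomyces cerevisiae", "fungal"),
)

# Mnemonics of the 16 laboratory contaminants (porcine/bovine trypsins,
# chymotrypsinogens, serum albumins, and human keratins) carried in every
# database. Pipes in accession-style ids are dropped because the FASTA header
# dialect is pipe-delimited.
CONTAMINANT_IDS = (
    "TRYP_PIG",
    "Trypa1",
    "Trypa2",
    "Trypa3",
    "Trypa4",
    "Trypa5",
    "Trypa6",
    "TRYP_BOVIN",
    "CTRA_BOVIN",
    "CTRB_BOVIN",
    "ALBU_HUMAN",
    "ALBU_BOVIN",
    "K2C1_HUMAN",
    "K22E_HUMAN",
    "K1C9_HUMAN",
    "K1C10_HUMAN",
)

_CONTAMINANT_SPECIES = {
    "TRYP_PIG": ("Sus scrofa", "Sus"),
    "TRYP_BOVIN": ("Bos taurus", "Bos"),
    "CTRA_BOVIN": ("Bos taurus", "Bos"),
    "CTRB_BOVIN": ("Bos taurus", "Bos"),
    "ALBU_BOVIN": ("Bos taurus", "Bos"),
    "ALBU_HUMAN": ("Homo sapiens", "Homo"),
    "K2C1_HUMAN": ("Homo sapiens", "Homo"),
    "K22E_HUMAN": ("Homo sapiens", "Homo"),
    "K1C9_HUMAN": ("Homo sapiens", "Homo"),
    "K1C10_HUMAN": ("Homo sapiens", "Homo"),
}


class ValidationError(ValueError):
    """Raised for malformed records, sequences, or configuration."""


@dataclass
class ProteinRecord:
    """One protein sequence with taxonomy and provenance labels."""

    record_id: str
    sequence: str
    species: str = ""
    strain: str = ""
    genus: str = ""
    category: str = "bacterial"
    source: str = "public"

    def header(self) -> str:
        return f"{self.record_id}|{self.category}|{self.genus}|{self.species}|{self.strain}"


@dataclass
class AbundanceProfile:
    """Per-sample taxon relative abundances (the 16S view of one sample)."""

    sample_id: str
    entries: list[tuple[str, str, float]] = field(default_factory=list)
    # each entry: (species, genus, relative_abundance)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        total = 0.0
        for species, _genus, ab in self.entries:
            if ab < 0:
                raise ValidationError(f"negative abundance for {species!r}")
            if species in seen:
                raise ValidationError(f"duplicate species {species!r} in profile")
            seen.add(species)
            total += ab
        if total > 1 + 1e-6:
            raise ValidationError(f"abundances sum to {total}, above 1")

    def species_abundance(self) -> dict[str, float]:
        return {sp: ab for sp, _g, ab in self.entries}

    def genus_abundance(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for _sp, genus, ab in self.entries:
            out[genus] = out.get(genus, 0.0) + ab
        return out


@dataclass
class ProteinDatabase:
    """A named, deduplicated collection of records built by one strategy."""

    name: str
    strategy: str
    records: list[ProteinRecord] = field(default_factory=list)
    sample_id: str = ""
    #: sequence-collapse aliases: kept record_id -> ids merged into it
    aliases: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate record ids in database {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, ProteinRecord]:
        return {r.record_id: r for r in self.records}

    def category_index(self) -> dict[str, str]:
        return {r.record_id: r.category for r in self.records}


# ---------------------------------------------------------------------------
# FASTA I/O (canonical pipe-delimited dialect)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.header()}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path, source: str = "public") -> list[ProteinRecord]:
    """Read records written in the canonical header dialect.

    Uses Biopython's FASTA parser; headers without the full pipe layout get
    empty taxonomy fields and must pass through :func:`normalize_records`
    before database construction.
    """
    from Bio import SeqIO

    out: list[ProteinRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        fields = seqrec.description.split("|")
        fields += [""] * (5 - len(fields))
        rid, category, genus, species, strain = fields[:5]
        if category not in CATEGORIES:
            category = "bacterial" if category == "" else category
        out.append(
            ProteinRecord(
                record_id=rid,
                sequence=str(seqrec.seq),
                species=species,
                strain=strain,
                genus=genus,
                category=category if category in CATEGORIES else "bacterial",
                source=source,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_records(raw: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Normalize raw records into the canonical dialect.

    Strips whitespace and stop characters (``*``) from sequences, uppercases,
    validates the amino-acid alphabet, and deterministically disambiguates
    duplicate ids by suffixing ``_1``, ``_2``, ... in input order. Public
    records must carry a species label. Idempotent.
    """
    out: list[ProteinRecord] = []
    used: set[str] = set()
    for rec in raw:
        seq = re.sub(r"\s+", "", rec.sequence).upper().rstrip("*").replace("*", "")
        if not seq or not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set(AMINO_ACIDS)) if seq else ["<empty>"]
            raise ValidationError(
                f"record {rec.record_id!r}: invalid sequence characters {bad}"
            )
        if rec.source == "public" and rec.category in {"bacterial", "fungal", "parasite"} and not rec.species:
            raise ValidationError(f"public record {rec.record_id!r} lacks taxonomy")
        rid = rec.record_id.strip().replace("|", "_")
        if rid in used:
            n = 1
            while f"{rid}_{n}" in used:
                n += 1
            rid = f"{rid}_{n}"
        used.add(rid)
        out.append(replace(rec, record_id=rid, sequence=seq))
    return out


# ---------------------------------------------------------------------------
# Core host + contaminant set
# ---------------------------------------------------------------------------

def _synthetic_contaminant_sequences() -> list[str]:
    # Deterministic synthetic placeholder sequences standing in for the real
    # contaminant proteins; fixed internal seed so every database ever built
    # shares byte-identical core sequences.
    rng = np.random.default_rng(787878)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    probs = np.full(20, 0.88 / 18)
    probs[AMINO_ACIDS.index("K")] = 0.06
    probs[AMINO_ACIDS.index("R")] = 0.06
    seqs = []
    for _ in CONTAMINANT_IDS:
        length = int(rng.integers(110, 180))
        seqs.append("".join(rng.choice(alphabet, size=length, p=probs)))
    return seqs


_CONTAMINANT_CACHE: list[ProteinRecord] | None = None


def contaminant_records(sequences: Sequence[str] | None = None) -> list[ProteinRecord]:
    """The 16 contaminant records carried in every database.

    Real sequences may be supplied (in :data:`CONTAMINANT_IDS` order);
    otherwise deterministic synthetic placeholders are used.
    """
    global _CONTAMINANT_CACHE
    if sequences is None:
        if _CONTAMINANT_CACHE is None:
            _CONTAMINANT_CACHE = [
                ProteinRecord(
                    record_id=cid,
                    sequence=seq,
                    species=_CONTAMINANT_SPECIES.get(cid, ("", ""))[0],
                    genus=_CONTAMINANT_SPECIES.get(cid, ("", ""))[1],
                    category="contaminant",
                    source="core",
                )
                for cid, seq in zip(CONTAMINANT_IDS, _synthetic_contaminant_sequences())
            ]
        return list(_CONTAMINANT_CACHE)
    if len(sequences) != len(CONTAMINANT_IDS):
        raise ValidationError(
            f"contaminant set must have {len(CONTAMINANT_IDS)} sequences, got {len(sequences)}"
        )
    return [
        ProteinRecord(
            record_id=cid,
            sequence=seq,
            species=_CONTAMINANT_SPECIES.get(cid, ("", ""))[0],
            genus=_CONTAMINANT_SPECIES.get(cid, ("", ""))[1],
            category="contaminant",
            source="core",
        )
        for cid, seq in zip(CONTAMINANT_IDS, sequences)
    ]


def core_set(
    host_records: Iterable[ProteinRecord] = (),
    contaminant_sequences: Sequence[str] | None = None,
) -> list[ProteinRecord]:
    """Host proteins plus the 16-entry contaminant set.

    Every database built by any strategy includes this core. Host records are
    relabelled category ``host`` / source ``core``.
    """
    host = [
        replace(r, category="host", source="core") for r in host_records
    ]
    contams = contaminant_records(contaminant_sequences)
    if len(contams) != 16:
        raise ValidationError("internal error: contaminant core set must have 16 records")
    return host + contams


# ---------------------------------------------------------------------------
# Database builders
# ---------------------------------------------------------------------------

def _assemble(
    name: str,
    strategy: str,
    core: list[ProteinRecord],
    extra: Iterable[ProteinRecord],
    sample_id: str = "",
) -> ProteinDatabase:
    records = list(core)
    seen = {r.record_id for r in records}
    for rec in extra:
        if rec.record_id in seen:
            continue
        seen.add(rec.record_id)
        records.append(rec)
    return ProteinDatabase(name=name, strategy=strategy, records=records, sample_id=sample_id)


def build_sample_matched_16s(
    profile: AbundanceProfile,
    repository: Sequence[ProteinRecord],
    core: list[ProteinRecord],
    cutoff: float = 0.001,
    exclusion_list: Iterable[str] = (),
) -> ProteinDatabase:
    """Public records of every species above the abundance cutoff (strict >).

    Species on the exclusion list, or with zero public records (the
    uncultivated-taxon case), are skipped with a warning rather than an error.
    """
    if not 0 < cutoff < 1:
        raise ValidationError(f"cutoff must be in (0,1), got {cutoff}")
    excluded = set(exclusion_list)
    by_species: dict[str, list[ProteinRecord]] = {}
    for rec in repository:
        by_species.setdefault(rec.species, []).append(rec)
    picked: list[ProteinRecord] = []
    for species, _genus, ab in profile.entries:
        if ab <= cutoff or species in excluded:
            continue
        recs = by_species.get(species)
        if not recs:
            logger.warning(
                "sample %s: species %r above cutoff but has no public records; skipped",
                profile.sample_id, species,
            )
            continue
        picked.extend(recs)
    return _assemble(
        f"16S_Sample-Matched_{profile.sample_id}",
        "sample_matched_16s",
        core,
        picked,
        sample_id=profile.sample_id,
    )


def build_pooled_16s(
    profiles: Sequence[AbundanceProfile],
    repository: Sequence[ProteinRecord],
    core: list[ProteinRecord],
    cutoff: float = 0.001,
    extra_records: Iterable[ProteinRecord] = (),
    exclusion_list: Iterable[str] = (),
) -> ProteinDatabase:
    """Union of all per-sample matched bacterial sets plus extra taxa."""
    if not profiles:
        raise ValidationError("pooled database needs at least one profile")
    pooled: dict[str, ProteinRecord] = {}
    for profile in profiles:
        sm = build_sample_matched_16s(profile, repository, [], cutoff, exclusion_list)
        for rec in sm.records:
            pooled.setdefault(rec.record_id, rec)
    for rec in extra_records:
        pooled.setdefault(rec.record_id, rec)
    return _assemble("16S_Pooled", "pooled_16s", core, pooled.values())


def build_reference_16s(
    profile: AbundanceProfile,
    repository: Sequence[ProteinRecord],
    core: list[ProteinRecord],
    reference_strain_map: Mapping[str, str] | None = None,
    cutoff: float = 0.001,
    exclusion_list: Iterable[str] = (),
) -> ProteinDatabase:
    """Sample-matched database restricted to one reference strain per species.

    Species missing from the map default to their only available strain; the
    sentinel ``"A"`` in a map explicitly marks that single-genome case. A
    mapped strain absent from the repository is an error.
    """
    ref_map = dict(reference_strain_map or {})
    sm = build_sample_matched_16s(profile, repository, [], cutoff, exclusion_list)
    strains_by_species: dict[str, set[str]] = {}
    for rec in sm.records:
        strains_by_species.setdefault(rec.species, set()).add(rec.strain)
    chosen: dict[str, str] = {}
    for species, strains in strains_by_species.items():
        ref = ref_map.get(species)
        if ref is None or ref == "A":
            # no mapping (or the single-genome sentinel "A"): deterministic
            # fallback to the first strain in sorted order
            chosen[species] = next(iter(sorted(strains)))
        else:
            if ref not in strains:
                raise ValidationError(
                    f"reference strain {ref!r} for {species!r} absent from repository"
                )
            chosen[species] = ref
    picked = [r for r in sm.records if r.strain == chosen.get(r.species)]
    return _assemble(
        f"16S_Reference_{profile.sample_id}",
        "reference_16s",
        core,
        picked,
        sample_id=profile.sample_id,
    )


def build_shotgun(
    catalogs: Mapping[str, Sequence[ProteinRecord]],
    core: list[ProteinRecord],
    pooled: bool,
    sample_id: str = "",
) -> ProteinDatabase:
    """Translated-ORF database for one sample, or pooled across all samples."""
    if not catalogs:
        raise ValidationError("no shotgun catalogs supplied")
    if pooled:
        recs: list[ProteinRecord] = []
        for sid in sorted(catalogs):
            recs.extend(catalogs[sid])
        return _assemble("Shotgun_Pooled", "shotgun_pooled", core, recs)
    if sample_id not in catalogs:
        raise ValidationError(f"no catalog for sample {sample_id!r}")
    return _assemble(
        f"Shotgun_Sample-Matched_{sample_id}",
        "shotgun_sample_matched",
        core,
        catalogs[sample_id],
        sample_id=sample_id,
    )


def build_hybrid(sm_16s: ProteinDatabase, sm_shotgun: ProteinDatabase) -> ProteinDatabase:
    """Sequence-level union of a sample's 16S-matched and shotgun databases.

    Identical amino-acid sequences collapse to a single record; the public
    (16S) record's identity and taxonomy win, and the shotgun record's id is
    recorded as an alias on the kept record.
    """
    if sm_16s.sample_id != sm_shotgun.sample_id:
        raise ValidationError(
            f"sample mismatch: {sm_16s.sample_id!r} vs {sm_shotgun.sample_id!r}"
        )
    kept: list[ProteinRecord] = []
    by_seq: dict[str, str] = {}
    aliases: dict[str, list[str]] = {}
    for rec in list(sm_16s.records) + list(sm_shotgun.records):
        owner = by_seq.get(rec.sequence)
        if owner is None:
            by_seq[rec.sequence] = rec.record_id
            kept.append(rec)
        elif owner != rec.record_id:
            aliases.setdefault(owner, []).append(rec.record_id)
    return ProteinDatabase(
        name=f"Hybrid_Sample-Matched_{sm_16s.sample_id}",
        strategy="hybrid_sample_matched",
        records=kept,
        sample_id=sm_16s.sample_id,
        aliases=aliases,
    )


def build_global(
    repository_all_taxa: Sequence[ProteinRecord],
    core: list[ProteinRecord],
) -> ProteinDatabase:
    """Everything public regardless of sample profiles, plus the core set."""
    return _assemble("Global", "global", core, repository_all_taxa)


def build_augmented(
    baseline: ProteinDatabase,
    pool: Mapping[str, Sequence[ProteinRecord]],
    k: int,
    seed: int,
) -> ProteinDatabase:
    """Baseline plus ``k`` genomes sampled from the pool without replacement."""
    genome_ids = sorted(pool)
    if k > len(genome_ids):
        raise ValidationError(f"k={k} exceeds pool size {len(genome_ids)}")
    rng = np.random.default_rng(seed)
    chosen = [genome_ids[i] for i in sorted(rng.choice(len(genome_ids), size=k, replace=False))]
    extra: list[ProteinRecord] = []
    for gid in chosen:
        extra.extend(pool[gid])
    db = _assemble(
        f"{baseline.name}+{k}genomes", "custom", list(baseline.records), extra,
        sample_id=baseline.sample_id,
    )
    return db


def database_stats(db: ProteinDatabase) -> dict:
    """Exact record counts, total and by category/source."""
    by_category: dict[str, int] = {}
    by_source: dict[str, int] = {}
    for rec in db.records:
        by_category[rec.category] = by_category.get(rec.category, 0) + 1
        by_source[rec.source] = by_source.get(rec.source, 0) + 1
    return {
        "name": db.name,
        "strategy": db.strategy,
        "total": len(db.records),
        "by_category": by_category,
        "by_source": by_source,
    }
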