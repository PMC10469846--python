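"""Synthetic metaproteomic study generator.

Emulates the statistical structure of a low-diversity (vaginal-like)
microbiome metaproteomics study so the whole database-benchmarking pipeline
runs without downloads: a public proteome repository with uneven strain
coverage and zero-genome ("uncultivated") taxa, per-sample Dirichlet
abundance profiles, shotgun ORF catalogs that partially sample the expressed
proteome and carry taxonomically unresolved entries, host and contaminant
protein sets, and two-replicate tandem-MS spectra with per-spectrum ground
truth for FDR verification.

All generators are pure functions of (config, seed): the same configuration
reproduces byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dbforge import (
    AMINO_ACIDS,
    AbundanceProfile,
    ProteinRecord,
    ValidationError,
    contaminant_records,
    write_fasta,
)
from .proteolysis import DigestParams, digest_protein
from .searchlite import ISOTOPE_SPACING, Spectrum, fragment_mz, peptide_mass

_ALPHABET = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
# uniform composition with K/R boosted to 6% so tryptic peptides always exist
_AA_PROBS = np.full(20, 0.88 / 18)
_AA_PROBS[AMINO_ACIDS.index("K")] = 0.06
_AA_PROBS[AMINO_ACIDS.index("R")] = 0.06

#: digest used to draw true source peptides for spectra
_SPECTRUM_DIGEST = DigestParams(max_missed_cleavages=0, min_length=7)
_MAX_TRUE_PEPTIDE = 25


@dataclass(frozen=True)
class CommunityConfig:
    """Study-level generator settings.

    Defaults emulate a low-diversity vaginal-like community: a handful of
    species with highly skewed abundances (Dirichlet concentration well below
    1), a quarter of species without public genomes, shotgun catalogs that
    capture most but not all of the expressed proteome, and ~52% of source
    peptides shared between the two injection replicates.
    """

    n_species: int = 14
    n_samples: int = 5
    strains_per_species: tuple[int, int] = (1, 3)
    proteins_per_strain: tuple[int, int] = (20, 35)
    protein_length: tuple[int, int] = (60, 140)
    abundance_concentration: float = 0.15
    fraction_uncultivated: float = 0.25
    strain_shared_fraction: float = 0.5
    shotgun_capture_fraction: float = 0.85
    shotgun_unresolved_fraction: float = 0.15
    replicate_shared_fraction: float = 0.52
    n_spectra: int = 600
    host_protein_count: int = 25
    host_weight: float = 0.30
    contaminant_weight: float = 0.04
    #: fraction of spectra with no peptide source at all (unfragmented
    #: precursors, modified peptides, chemical noise); these can only draw
    #: random matches and are what makes database bloat costly
    junk_spectrum_fraction: float = 0.25
    dropped_peak_rate: float = 0.62
    #: per-spectrum quality varies: the drop rate is drawn uniformly in
    #: rate +/- spread (clipped to [0.02, 0.9]), giving a smooth continuum
    #: of spectrum qualities around the significance threshold
    dropped_peak_spread: float = 0.28
    spurious_peak_rate: float = 0.30
    #: when > 0, rescale each profile so uncultivated species jointly hold
    #: this much abundance mass (emulates a dominant unsequenced taxon)
    min_uncultivated_mass: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_uncultivated",
            "strain_shared_fraction",
            "shotgun_capture_fraction",
            "shotgun_unresolved_fraction",
            "replicate_shared_fraction",
            "junk_spectrum_fraction",
            "dropped_peak_rate",
            "dropped_peak_spread",
            "spurious_peak_rate",
            "min_uncultivated_mass",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        for name in ("strains_per_species", "proteins_per_strain", "protein_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValidationError(f"{name} must be a nonempty positive range")
        if self.n_species < 1 or self.n_samples < 1 or self.n_spectra < 1:
            raise ValidationError("n_species, n_samples and n_spectra must be >= 1")
        if self.host_protein_count < 0:
            raise ValidationError("host_protein_count must be >= 0")
        if self.abundance_concentration <= 0:
            raise ValidationError("abundance_concentration must be > 0")
        if self.host_weight + self.contaminant_weight >= 1:
            raise ValidationError("host_weight + contaminant_weight must be < 1")


def _rng(config_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config_seed & 0x7FFFFFFF, *tags])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length, p=_AA_PROBS))


def _variant(rng: np.random.Generator, seq: str, rate: float = 0.08) -> str:
    chars = np.array(list(seq))
    mask = rng.random(len(seq)) < rate
    if mask.any():
        chars[mask] = rng.choice(_ALPHABET, size=int(mask.sum()), p=_AA_PROBS)
    return "".join(chars)


# ---------------------------------------------------------------------------
# Species universe and public repository
# ---------------------------------------------------------------------------

@dataclass
class SpeciesInfo:
    species: str
    genus: str
    cultivated: bool
    #: strain name -> list of records carrying the strain's true proteome
    strains: dict[str, list[ProteinRecord]]

    def expressed_records(self) -> list[ProteinRecord]:
        """Distinct-sequence union over strains (the species' true proteome)."""
        seen: dict[str, ProteinRecord] = {}
        for strain in sorted(self.strains):
            for rec in self.strains[strain]:
                seen.setdefault(rec.sequence, rec)
        return list(seen.values())


def build_universe(config: CommunityConfig) -> list[SpeciesInfo]:
    """The true species universe: every species' strains and proteomes.

    Uncultivated species still have true proteomes — they are simply absent
    from the public repository.
    """
    rng = _rng(config.seed, 1)
    n_uncult = int(round(config.fraction_uncultivated * config.n_species))
    uncult = set(rng.choice(config.n_species, size=n_uncult, replace=False).tolist())
    universe: list[SpeciesInfo] = []
    for i in range(config.n_species):
        species = f"Species_{i + 1:02d}"
        genus = f"Genus_{i + 1:02d}"
        cultivated = i not in uncult
        n_strains = int(rng.integers(config.strains_per_species[0], config.strains_per_species[1] + 1))
        n_prot = int(rng.integers(config.proteins_per_strain[0], config.proteins_per_strain[1] + 1))
        base = [
            _random_sequence(rng, int(rng.integers(config.protein_length[0], config.protein_length[1] + 1)))
            for _ in range(n_prot)
        ]
        prefix = "P" if cultivated else "U"
        strains: dict[str, list[ProteinRecord]] = {}
        for j in range(n_strains):
            strain = f"st{j + 1}"
            recs = []
            for k, base_seq in enumerate(base):
                if j == 0 or rng.random() < config.strain_shared_fraction:
                    seq = base_seq
                else:
                    seq = _variant(rng, base_seq)
                recs.append(
                    ProteinRecord(
                        record_id=f"{prefix}{i + 1:02d}_{strain}_{k + 1:03d}",
                        sequence=seq,
                        species=species,
                        strain=strain,
                        genus=genus,
                        category="bacterial",
                        source="public",
                    )
                )
            strains[strain] = recs
        universe.append(SpeciesInfo(species, genus, cultivated, strains))
    return universe


def generate_repository(config: CommunityConfig) -> list[ProteinRecord]:
    """The public repository: every strain record of every cultivated species."""
    records: list[ProteinRecord] = []
    for info in build_universe(config):
        if not info.cultivated:
            continue
        for strain in sorted(info.strains):
            records.extend(info.strains[strain])
    return records


def generate_host(config: CommunityConfig) -> list[ProteinRecord]:
    """Synthetic host (human-like) protein set."""
    rng = _rng(config.seed, 2)
    return [
        ProteinRecord(
            record_id=f"HUMAN_{n + 1:04d}",
            sequence=_random_sequence(
                rng, int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
            ),
            species="Homo sapiens",
            genus="Homo",
            category="host",
            source="core",
        )
        for n in range(config.host_protein_count)
    ]


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

@dataclass
class Community:
    """One sample: its abundance profile and expressed proteome."""

    sample_id: str
    sample_index: int
    profile: AbundanceProfile
    #: (record, sampling weight) for every expressed bacterial protein
    expressed: list[tuple[ProteinRecord, float]]
    uncultivated_species: set[str] = field(default_factory=set)


def generate_community(
    config: CommunityConfig,
    repository: Sequence[ProteinRecord] | None = None,
    sample_index: int = 0,
) -> Community:
    """Draw one sample's abundance profile and expressed proteome.

    Abundances come from a symmetric Dirichlet on the species simplex; small
    concentration values produce the dominated (Lactobacillus-like) regime,
    values near 1 the diverse (BV-like) regime. Each sample carries one
    resident strain per species (subjects host different strains of the same
    species), so the expressed proteome is that strain's distinct sequences —
    including uncultivated species, whose proteins exist in the community but
    not in the repository. ``repository`` is accepted for interface symmetry;
    the universe is regenerated deterministically from the config.
    """
    universe = build_universe(config)
    if not universe:
        raise ValidationError("empty species universe")
    rng = _rng(config.seed, 10, sample_index)
    ab = rng.dirichlet(np.full(config.n_species, config.abundance_concentration))
    uncult_mask = np.array([not info.cultivated for info in universe])
    if config.min_uncultivated_mass > 0 and uncult_mask.any() and not uncult_mask.all():
        t = config.min_uncultivated_mass
        u_sum = ab[uncult_mask].sum()
        c_sum = ab[~uncult_mask].sum()
        if u_sum == 0:
            ab[uncult_mask] = t / uncult_mask.sum()
        else:
            ab[uncult_mask] *= t / u_sum
        ab[~uncult_mask] *= (1 - t) / c_sum
    ab = ab / ab.sum()
    sample_id = f"S{sample_index + 1:02d}"
    entries = [(info.species, info.genus, float(a)) for info, a in zip(universe, ab)]
    profile = AbundanceProfile(sample_id=sample_id, entries=entries)
    expressed: list[tuple[ProteinRecord, float]] = []
    for info, a in zip(universe, ab):
        strains = sorted(info.strains)
        resident = strains[int(rng.integers(len(strains)))]
        seen: dict[str, ProteinRecord] = {}
        for rec in info.strains[resident]:
            seen.setdefault(rec.sequence, rec)
        recs = list(seen.values())
        if not recs:
            continue
        w = float(a) / len(recs)
        expressed.extend((rec, w) for rec in recs)
    return Community(
        sample_id=sample_id,
        sample_index=sample_index,
        profile=profile,
        expressed=expressed,
        uncultivated_species={info.species for info in universe if not info.cultivated},
    )


def _assemblability(sequence: str) -> float:
    """Deterministic uniform [0,1) score of how readily a protein's gene
    assembles from shotgun reads (a stable property of the sequence)."""
    import zlib

    return zlib.crc32(sequence.encode()) / 2**32


#: metagenomic assembly saturates: above this relative abundance a species is
#: captured at the full configured rate, below it capture decays
#: exponentially with the depth deficit
_CAPTURE_SATURATION_ABUNDANCE = 0.02


def generate_shotgun_catalog(
    community: Community, config: CommunityConfig
) -> list[ProteinRecord]:
    """Translated-ORF catalog of one sample.

    A protein is captured when its intrinsic "assemblability" — a uniform
    [0,1) value derived deterministically from its sequence — falls below
    ``shotgun_capture_fraction ** (1 / min(1, a / 0.02))``: assembly
    saturates above 2% relative abundance and falls off steeply below it,
    while a capture fraction of 1 always captures everything. A uniform
    profile therefore reduces to marginal per-protein capture with the plain
    capture fraction. Because
    assemblability is a property of the protein and not of the sample, the
    same hard-to-assemble proteins are missed in every sample, as with real
    metagenomic assembly. A configurable fraction of captured ORFs cannot be
    taxonomically resolved and is labelled ``Unknown``.
    """
    rng = _rng(config.seed, 20, community.sample_index)
    ab = community.profile.species_abundance()
    catalog: list[ProteinRecord] = []
    n = 0
    for rec, _w in community.expressed:
        a = ab.get(rec.species, 0.0)
        depth = min(1.0, a / _CAPTURE_SATURATION_ABUNDANCE)
        if depth == 0.0:
            continue
        p = config.shotgun_capture_fraction ** (1.0 / depth)
        if _assemblability(rec.sequence) >= p:
            continue
        n += 1
        unresolved = rng.random() < config.shotgun_unresolved_fraction
        catalog.append(
            ProteinRecord(
                record_id=f"ORF_{community.sample_id}_{n:05d}",
                sequence=rec.sequence,
                species="Unknown" if unresolved else rec.species,
                strain="",
                genus="Unknown" if unresolved else rec.genus,
                category="translated_ORF",
                source="shotgun",
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectraResult:
    replicate1: list[Spectrum]
    replicate2: list[Spectrum]
    truth: pd.DataFrame  # CommunityGroundTruth: one row per spectrum


TRUTH_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "replicate",
    "peptide",
    "protein_id",
    "taxon",
    "category",
    "in_repository",
]


def simulate_spectra(
    community: Community,
    host_records: Sequence[ProteinRecord],
    contaminant_set: Sequence[ProteinRecord] | None,
    config: CommunityConfig,
) -> SpectraResult:
    """Two-replicate spectrum sets with per-spectrum ground truth.

    Source peptides are fully tryptic peptides (7-25 residues) of expressed,
    host and contaminant proteins, sampled proportionally to protein weight;
    a configured fraction of distinct source peptides occurs in both
    replicates, the remainder split between them. Each spectrum carries the
    peptide's neutral monoisotopic mass (with occasional isotope-selection
    error and small gaussian jitter) and its singly charged b/y fragment
    ladder with dropped-peak and spurious-peak noise.
    """
    if contaminant_set is None:
        contaminant_set = contaminant_records()
    rng = _rng(config.seed, 30, community.sample_index)

    pool: list[tuple[ProteinRecord, float, str, bool]] = []
    bact_total = sum(w for _r, w in community.expressed)
    bact_share = 1.0 - config.host_weight - config.contaminant_weight
    for rec, w in community.expressed:
        in_repo = rec.record_id.startswith("P")
        pool.append((rec, bact_share * w / bact_total if bact_total else 0.0, rec.species, in_repo))
    for rec in host_records:
        pool.append((rec, config.host_weight / max(len(host_records), 1), "Host", True))
    for rec in contaminant_set:
        pool.append((rec, config.contaminant_weight / max(len(contaminant_set), 1), "Contaminant", True))

    digests: list[list[str]] = []
    weights = []
    kept_pool = []
    for rec, w, taxon, in_repo in pool:
        peps = [
            p
            for p in digest_protein(rec.sequence, _SPECTRUM_DIGEST)
            if len(p) <= _MAX_TRUE_PEPTIDE
        ]
        if peps and w > 0:
            digests.append(peps)
            weights.append(w)
            kept_pool.append((rec, taxon, in_repo))
    if not digests:
        raise ValidationError("no tryptic peptide of the minimum length in the proteome")
    weights = np.asarray(weights)
    weights = weights / weights.sum()

    n_junk = int(round(config.junk_spectrum_fraction * config.n_spectra))
    n_peptide_spectra = max(1, config.n_spectra - n_junk)

    s = config.replicate_shared_fraction
    m_target = max(1, int(round(n_peptide_spectra / (1.0 + s))))
    chosen: dict[str, tuple[int, str]] = {}  # peptide -> (pool idx, share label)
    attempts = 0
    while len(chosen) < m_target and attempts < 60 * m_target:
        attempts += 1
        pi = int(rng.choice(len(digests), p=weights))
        pep = digests[pi][int(rng.integers(len(digests[pi])))]
        if pep in chosen:
            continue
        r = rng.random()
        label = "both" if r < s else ("r1" if r < s + (1 - s) / 2 else "r2")
        chosen[pep] = (pi, label)

    order = list(chosen.items())
    events: list[tuple[str, int, int]] = []  # (peptide, pool idx, replicate)
    while True:
        mandatory = sum(2 if lab == "both" else 1 for _p, (_i, lab) in order)
        if mandatory <= n_peptide_spectra or len(order) <= 1:
            break
        order.pop()
    for pep, (pi, lab) in order:
        reps = (1, 2) if lab == "both" else ((1,) if lab == "r1" else (2,))
        for rep in reps:
            events.append((pep, pi, rep))
    n_extra = n_peptide_spectra - len(events)
    if n_extra > 0 and order:
        idx = rng.integers(len(order), size=n_extra)
        for ix in idx:
            pep, (pi, lab) = order[int(ix)]
            if lab == "both":
                rep = int(rng.integers(1, 3))
            else:
                rep = 1 if lab == "r1" else 2
            events.append((pep, pi, rep))

    rep_specs: dict[int, list[Spectrum]] = {1: [], 2: []}
    truth_rows = []
    for n, (pep, pi, rep) in enumerate(events):
        rec, taxon, in_repo = kept_pool[pi]
        theo = fragment_mz(pep)
        drop = config.dropped_peak_rate
        if drop > 0 and config.dropped_peak_spread > 0:
            drop = float(
                np.clip(
                    rng.uniform(drop - config.dropped_peak_spread, drop + config.dropped_peak_spread),
                    0.02,
                    0.9,
                )
            )
        keep = rng.random(theo.size) >= drop
        if not keep.any():
            keep[int(rng.integers(theo.size))] = True
        frags = theo[keep]
        n_spurious = int(rng.binomial(theo.size, config.spurious_peak_rate))
        if n_spurious:
            lo, hi = 150.0, max(800.0, peptide_mass(pep))
            frags = np.concatenate([frags, rng.uniform(lo, hi, size=n_spurious)])
        iso = int(rng.choice([-1, 0, 1, 2], p=[0.04, 0.85, 0.07, 0.04]))
        precursor = peptide_mass(pep) + iso * ISOTOPE_SPACING + rng.normal(0.0, 0.015)
        sid = f"{community.sample_id}_sp{n + 1:05d}"
        rep_specs[rep].append(
            Spectrum(
                spectrum_id=sid,
                sample_id=community.sample_id,
                replicate=rep,
                precursor_mass=float(precursor),
                fragment_masses=np.sort(frags),
            )
        )
        truth_rows.append(
            (
                sid,
                community.sample_id,
                rep,
                pep,
                rec.record_id,
                taxon,
                rec.category if taxon not in ("Host", "Contaminant") else
                ("host" if taxon == "Host" else "contaminant"),
                bool(in_repo),
            )
        )
    # sourceless noise spectra (truth taxon "Noise"): random precursor and
    # uniformly scattered peaks; any match they draw is by definition false
    for k in range(n_junk):
        rep = 1 if rng.random() < 0.5 else 2
        precursor = float(rng.uniform(800.0, 2400.0))
        n_peaks = int(rng.integers(15, 40))
        frags = rng.uniform(150.0, precursor * 0.95, size=n_peaks)
        sid = f"{community.sample_id}_noise{k + 1:05d}"
        rep_specs[rep].append(
            Spectrum(
                spectrum_id=sid,
                sample_id=community.sample_id,
                replicate=rep,
                precursor_mass=precursor,
                fragment_masses=np.sort(frags),
            )
        )
        truth_rows.append((sid, community.sample_id, rep, "", "", "Noise", "noise", False))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SpectraResult(rep_specs[1], rep_specs[2], truth)


# ---------------------------------------------------------------------------
# Whole-study convenience and genome pools
# ---------------------------------------------------------------------------

@dataclass
class SampleData:
    sample_id: str
    community: Community
    catalog: list[ProteinRecord]
    spectra: SpectraResult


@dataclass
class Study:
    config: CommunityConfig
    repository: list[ProteinRecord]
    host: list[ProteinRecord]
    contaminants: list[ProteinRecord]
    samples: list[SampleData]

    def catalogs(self) -> dict[str, list[ProteinRecord]]:
        return {s.sample_id: s.catalog for s in self.samples}

    def profiles(self) -> list[AbundanceProfile]:
        return [s.community.profile for s in self.samples]

    def all_spectra(self, sample_id: str) -> list[Spectrum]:
        for s in self.samples:
            if s.sample_id == sample_id:
                return list(s.spectra.replicate1) + list(s.spectra.replicate2)
        raise KeyError(sample_id)


def generate_study(
    config: CommunityConfig,
    uncultivated_tilts: Sequence[float] | None = None,
) -> Study:
    """Generate a full multi-sample study from one config.

    ``uncultivated_tilts`` optionally overrides ``min_uncultivated_mass``
    per sample (used to grade public-repository coverage across samples).
    """
    repository = generate_repository(config)
    host = generate_host(config)
    contams = contaminant_records()
    samples = []
    for i in range(config.n_samples):
        cfg_i = config
        if uncultivated_tilts is not None:
            cfg_i = replace(config, min_uncultivated_mass=float(uncultivated_tilts[i]))
        community = generate_community(cfg_i, repository, sample_index=i)
        catalog = generate_shotgun_catalog(community, cfg_i)
        spectra = simulate_spectra(community, host, contams, cfg_i)
        samples.append(SampleData(community.sample_id, community, catalog, spectra))
    return Study(config, repository, host, contams, samples)


def generate_genome_pool(
    kind: str,
    n_genomes: int,
    seed: int,
    proteins_per_genome: tuple[int, int] = (10, 16),
    protein_length: tuple[int, int] = (60, 120),
    strain_shared_fraction: float = 0.85,
) -> dict[str, list[ProteinRecord]]:
    """Genome pools for database-augmentation experiments.

    ``kind='species'`` yields genomes of unrelated novel species (every
    protein distinct); ``kind='strain'`` yields strains of one donor species
    sharing most of a common base proteome, so the pool is highly redundant
    at the sequence level.
    """
    if kind not in ("strain", "species"):
        raise ValidationError(f"pool kind must be 'strain' or 'species', got {kind!r}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 40, 0 if kind == "strain" else 1])
    pool: dict[str, list[ProteinRecord]] = {}
    base = [
        _random_sequence(rng, int(rng.integers(protein_length[0], protein_length[1] + 1)))
        for _ in range(proteins_per_genome[1])
    ]
    for g in range(n_genomes):
        recs = []
        n_prot = int(rng.integers(proteins_per_genome[0], proteins_per_genome[1] + 1))
        if kind == "species":
            species, genus, strain = f"PoolSp_{g + 1:03d}", f"PoolGen_{g + 1:03d}", "st1"
            seqs = [
                _random_sequence(rng, int(rng.integers(protein_length[0], protein_length[1] + 1)))
                for _ in range(n_prot)
            ]
        else:
            species, genus, strain = "PoolDonor", "PoolDonorGenus", f"st{g + 1}"
            seqs = []
            for k in range(n_prot):
                base_seq = base[k % len(base)]
                if rng.random() < strain_shared_fraction:
                    seqs.append(base_seq)
                else:
                    seqs.append(_variant(rng, base_seq))
        gid = f"{kind}_genome_{g + 1:03d}"
        for k, seq in enumerate(seqs):
            recs.append(
                ProteinRecord(
                    record_id=f"{gid}_{k + 1:03d}",
                    sequence=seq,
                    species=species,
                    strain=strain,
                    genus=genus,
                    category="bacterial",
                    source="public",
                )
            )
        pool[gid] = recs
    return pool


# ---------------------------------------------------------------------------
# Fixture I/O (plain-text round trips)
# ---------------------------------------------------------------------------

def write_abundance_tsv(profiles: Sequence[AbundanceProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for species, genus, ab in prof.entries:
            rows.append((prof.sample_id, species, species, genus, repr(ab)))
    df = pd.DataFrame(rows, columns=["sample_id", "taxon", "species", "genus", "relative_abundance"])
    df.to_csv(path, sep="\t", index=False)


def read_abundance_tsv(path: str | Path) -> list[AbundanceProfile]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        entries = [
            (row.species, row.genus, float(row.relative_abundance)) for row in grp.itertuples()
        ]
        out.append(AbundanceProfile(sample_id=str(sid), entries=entries))
    return out


def write_spectra_tsv(spectra: Sequence[Spectrum], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("spectrum_id\tsample_id\treplicate\tprecursor_mass\tfragment_masses\n")
        for s in spectra:
            frags = ";".join(repr(float(x)) for x in s.fragment_masses)
            fh.write(f"{s.spectrum_id}\t{s.sample_id}\t{s.replicate}\t{s.precursor_mass!r}\t{frags}\n")


def read_spectra_tsv(path: str | Path) -> list[Spectrum]:
    out = []
    with Path(path).open() as fh:
        header = fh.readline()
        assert header.startswith("spectrum_id")
        for line in fh:
            sid, sample_id, rep, prec, frags = line.rstrip("\n").split("\t")
            out.append(
                Spectrum(
                    spectrum_id=sid,
                    sample_id=sample_id,
                    replicate=int(rep),
                    precursor_mass=float(prec),
                    fragment_masses=np.array([float(x) for x in frags.split(";")]),
                )
            )
    return out


def write_fixture(study: Study, outdir: str | Path) -> None:
    """Write every study artifact as plain text (FASTA/TSV round-trippable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.repository, outdir / "repository.fasta")
    write_fasta(study.host, outdir / "host.fasta")
    write_fasta(study.contaminants, outdir / "contaminants.fasta")
    write_abundance_tsv(study.profiles(), outdir / "abundance.tsv")
    all_spectra: list[Spectrum] = []
    truths = []
    for s in study.samples:
        write_fasta(s.catalog, outdir / f"catalog_{s.sample_id}.fasta")
        all_spectra.extend(s.spectra.replicate1)
        all_spectra.extend(s.spectra.replicate2)
        truths.append(s.spectra.truth)
    write_spectra_tsv(all_spectra, outdir / "spectra.tsv")
    pd.concat(truths, ignore_index=True).to_csv(outdir / "truth.tsv", sep="\t", index=False)
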