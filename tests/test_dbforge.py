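"""Database construction strategies, normalization, and the core set."""

import numpy as np
import pytest

from metaprotbench import dbforge, synthio
from metaprotbench.dbforge import (
    AbundanceProfile,
    ProteinDatabase,
    ValidationError,
    build_augmented,
    build_global,
    build_hybrid,
    build_pooled_16s,
    build_reference_16s,
    build_sample_matched_16s,
    build_shotgun,
    core_set,
    database_stats,
    normalize_records,
    read_fasta,
    write_fasta,
)

from conftest import make_record


# ---------------------------------------------------------------- normalize

def test_normalize_strips_stops_and_whitespace_and_uppercases():
    rec = make_record("r1", "mkll r*")
    out = normalize_records([rec])
    assert out[0].sequence == "MKLLR"


def test_normalize_disambiguates_duplicate_ids_deterministically():
    recs = [make_record("x", "MKR"), make_record("x", "MLR"), make_record("x", "MIR")]
    out = normalize_records(recs)
    assert [r.record_id for r in out] == ["x", "x_1", "x_2"]


def test_normalize_is_idempotent():
    recs = [make_record("x", "mk*"), make_record("x", "MLR")]
    once = normalize_records(recs)
    twice = normalize_records(once)
    assert once == twice


def test_normalize_errors():
    with pytest.raises(ValidationError):
        normalize_records([make_record("r", "MKZ9")])
    with pytest.raises(ValidationError):
        normalize_records([make_record("r", "MKR", species="")])


# ----------------------------------------------------------------- core set

def test_core_set_has_exactly_16_contaminants():
    core = core_set()
    contams = [r for r in core if r.category == "contaminant"]
    assert len(contams) == 16
    assert {c.record_id for c in contams} == set(dbforge.CONTAMINANT_IDS)


def test_core_set_includes_host_records_with_core_labels():
    host = [make_record("H1", "MKLLR", species="Homo sapiens", category="host")]
    core = core_set(host)
    assert core[0].category == "host" and core[0].source == "core"
    assert len(core) == 17


def test_core_set_rejects_wrong_contaminant_count():
    with pytest.raises(ValidationError):
        core_set(contaminant_sequences=["MKR"] * 15)


# -------------------------------------------------------- sample-matched 16S

@pytest.fixture
def repo():
    return [
        make_record("A1", "MKAAAAAR", species="A", genus="GA", strain="s1"),
        make_record("A2", "MKCCCCCR", species="A", genus="GA", strain="s2"),
        make_record("B1", "MKDDDDDR", species="B", genus="GB", strain="s1"),
    ]


def test_sample_matched_threshold_is_strict(repo):
    profile = AbundanceProfile("s1", [("A", "GA", 0.5), ("B", "GB", 0.0005)])
    db = build_sample_matched_16s(profile, repo, [], cutoff=0.001)
    assert {r.record_id for r in db.records} == {"A1", "A2"}
    # boundary: exactly at the cutoff is excluded
    profile2 = AbundanceProfile("s1", [("A", "GA", 0.001)])
    db2 = build_sample_matched_16s(profile2, repo, [], cutoff=0.001)
    assert len(db2.records) == 0


def test_sample_matched_skips_genomeless_species_with_warning(repo, caplog):
    profile = AbundanceProfile("s1", [("A", "GA", 0.5), ("NoGenome", "GX", 0.4)])
    with caplog.at_level("WARNING", logger="metaprotbench"):
        db = build_sample_matched_16s(profile, repo, [], cutoff=0.001)
    assert {r.record_id for r in db.records} == {"A1", "A2"}
    assert any("NoGenome" in m for m in caplog.messages)


def test_every_strategy_database_contains_the_core_set(tiny_study, tiny_core):
    from metaprotbench import benchmetrics

    dbs = benchmetrics.build_strategy_databases(
        tiny_study, "S01",
        strategies=("sample_matched_16s", "pooled_16s", "reference_16s",
                    "shotgun_sample_matched", "shotgun_pooled",
                    "hybrid_sample_matched", "global"),
    )
    core_ids = {r.record_id for r in tiny_core}
    for name, db in dbs.items():
        ids = {r.record_id for r in db.records}
        assert core_ids <= ids, name


# ----------------------------------------------------------------- pooled 16S

def test_pooled_equals_single_sample_plus_extras(repo):
    profile = AbundanceProfile("s1", [("A", "GA", 0.5)])
    extra = [make_record("TV1", "MKEEEEER", species="Tvag", genus="T", category="parasite")]
    pooled = build_pooled_16s([profile], repo, [], extra_records=extra)
    sm = build_sample_matched_16s(profile, repo, [])
    assert {r.record_id for r in pooled.records} == {r.record_id for r in sm.records} | {"TV1"}


def test_pooled_union_of_disjoint_samples_is_the_sum(repo):
    p1 = AbundanceProfile("s1", [("A", "GA", 0.5)])
    p2 = AbundanceProfile("s2", [("B", "GB", 0.5)])
    pooled = build_pooled_16s([p1, p2], repo, [])
    n1 = len(build_sample_matched_16s(p1, repo, []).records)
    n2 = len(build_sample_matched_16s(p2, repo, []).records)
    assert len(pooled.records) == n1 + n2
    assert len(pooled.records) >= max(n1, n2)


# -------------------------------------------------------------- reference 16S

def test_reference_restricts_to_mapped_strain(repo):
    profile = AbundanceProfile("s1", [("A", "GA", 0.5), ("B", "GB", 0.3)])
    db = build_reference_16s(profile, repo, [], reference_strain_map={"A": "s2"})
    assert {r.record_id for r in db.records} == {"A2", "B1"}  # B defaults to its one strain
    sm = build_sample_matched_16s(profile, repo, [])
    assert len(db.records) <= len(sm.records)


def test_reference_single_genome_sentinel_and_missing_strain_error(repo):
    profile = AbundanceProfile("s1", [("B", "GB", 0.5)])
    db = build_reference_16s(profile, repo, [], reference_strain_map={"B": "A"})
    assert {r.record_id for r in db.records} == {"B1"}
    with pytest.raises(ValidationError):
        build_reference_16s(profile, repo, [], reference_strain_map={"B": "s9"})


# -------------------------------------------------------------------- shotgun

def test_shotgun_pooled_and_sample_matched():
    cat = {
        "s1": [make_record("O1", "MKAAAAAR", species="Unknown", category="translated_ORF",
                           source="shotgun")],
        "s2": [make_record("O2", "MKCCCCCR", species="A", category="translated_ORF",
                           source="shotgun")],
    }
    sm = build_shotgun(cat, [], pooled=False, sample_id="s1")
    pooled = build_shotgun(cat, [], pooled=True)
    assert {r.record_id for r in sm.records} == {"O1"}
    assert {r.record_id for r in pooled.records} == {"O1", "O2"}
    assert all(r.category in ("translated_ORF",) for r in pooled.records)
    assert len(pooled.records) >= len(sm.records)
    with pytest.raises(ValidationError):
        build_shotgun({}, [], pooled=True)


# --------------------------------------------------------------------- hybrid

def _hybrid_pair():
    a = ProteinDatabase("sm16", "sample_matched_16s", [
        make_record("P1", "MKAAAAAR", species="A"),
        make_record("P2", "MKCCCCCR", species="A"),
    ], sample_id="s1")
    b = ProteinDatabase("smshot", "shotgun_sample_matched", [
        make_record("O1", "MKAAAAAR", species="Unknown", category="translated_ORF",
                    source="shotgun"),
        make_record("O2", "MKEEEEER", species="Unknown", category="translated_ORF",
                    source="shotgun"),
    ], sample_id="s1")
    return a, b


def test_hybrid_collapses_identical_sequences_keeping_public_identity():
    a, b = _hybrid_pair()
    hyb = build_hybrid(a, b)
    ids = {r.record_id for r in hyb.records}
    assert ids == {"P1", "P2", "O2"}
    assert hyb.aliases == {"P1": ["O1"]}
    seqs = [r.sequence for r in hyb.records]
    assert len(seqs) == len(set(seqs))  # no duplicate sequences
    assert max(len(a.records), len(b.records)) <= len(hyb.records) <= len(a.records) + len(b.records)


def test_hybrid_disjoint_sets_sum_and_identity_on_empty():
    a, b = _hybrid_pair()
    b_disjoint = ProteinDatabase("smshot", "shotgun_sample_matched",
                                 [r for r in b.records if r.record_id == "O2"],
                                 sample_id="s1")
    assert len(build_hybrid(a, b_disjoint).records) == 3
    empty = ProteinDatabase("smshot", "shotgun_sample_matched", [], sample_id="s1")
    assert [r.record_id for r in build_hybrid(a, empty).records] == ["P1", "P2"]


def test_hybrid_is_idempotent_and_checks_sample_ids():
    a, b = _hybrid_pair()
    h1 = build_hybrid(a, b)
    h2 = build_hybrid(h1, b)
    assert [r.record_id for r in h1.records] == [r.record_id for r in h2.records]
    b_bad = ProteinDatabase("x", "shotgun_sample_matched", [], sample_id="other")
    with pytest.raises(ValidationError):
        build_hybrid(a, b_bad)


# --------------------------------------------------------------------- global

def test_global_is_a_superset_and_handles_empty_repository(repo):
    core = core_set()
    g = build_global(repo, core)
    assert len(g.records) == len(repo) + len(core)
    profile = AbundanceProfile("s1", [("A", "GA", 0.5)])
    sm = build_sample_matched_16s(profile, repo, core)
    assert {r.record_id for r in sm.records} <= {r.record_id for r in g.records}
    assert len(build_global([], core).records) == len(core)


# ------------------------------------------------------------------ augmented

def test_augmented_sampling_is_seeded_and_bounded():
    base = ProteinDatabase("base", "custom", [make_record("P1", "MKAAAAAR")])
    pool = synthio.generate_genome_pool("species", 10, seed=3)
    assert build_augmented(base, pool, 0, seed=1).records == base.records
    d1 = build_augmented(base, pool, 4, seed=9)
    d2 = build_augmented(base, pool, 4, seed=9)
    assert [r.record_id for r in d1.records] == [r.record_id for r in d2.records]
    with pytest.raises(ValidationError):
        build_augmented(base, pool, 11, seed=1)


def test_strain_pool_adds_fewer_distinct_sequences_than_species_pool():
    base = ProteinDatabase("base", "custom", [make_record("P1", "MKAAAAAR")])
    strain_pool = synthio.generate_genome_pool("strain", 30, seed=3)
    species_pool = synthio.generate_genome_pool("species", 30, seed=3)
    n_strain = len({r.sequence for r in build_augmented(base, strain_pool, 30, 1).records})
    n_species = len({r.sequence for r in build_augmented(base, species_pool, 30, 1).records})
    assert n_strain < n_species


# ---------------------------------------------------------------------- stats

def test_database_stats_counts_are_conserved(tiny_study, tiny_core):
    db = build_global(tiny_study.repository, tiny_core)
    stats = database_stats(db)
    assert stats["total"] == len(db.records)
    assert sum(stats["by_category"].values()) == stats["total"]
    assert sum(stats["by_source"].values()) == stats["total"]
    empty = database_stats(ProteinDatabase("e", "custom", []))
    assert empty["total"] == 0 and empty["by_category"] == {}


# ----------------------------------------------------------------- FASTA I/O

def test_fasta_round_trip_preserves_records_and_taxonomy(tmp_path, tiny_study):
    path = tmp_path / "repo.fasta"
    write_fasta(tiny_study.repository, path)
    back = read_fasta(path)
    assert back == tiny_study.repository
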