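"""Search engine: decoys, scoring, q-values, two-step search, and imports."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metaprotbench import searchlite as sl
from metaprotbench.dbforge import ProteinDatabase, ValidationError
from metaprotbench.searchlite import (
    DECOY_PREFIX,
    SearchParams,
    Spectrum,
    build_decoys,
    compute_qvalues,
    condense_results,
    fragment_mz,
    match_count,
    merge_replicates,
    peptide_mass,
    read_msgf_tsv,
    read_psm_tsv,
    score_match,
    search,
    spectral_probability,
    strip_flanks,
    two_step_search,
    write_psm_tsv,
)

from conftest import make_record


def make_psms(rows):
    """rows: (spectrum_id, raw, sp, is_decoy)"""
    return pd.DataFrame(
        [
            (sid, "s", 1, "PEPTIDEK", "P1", dec, raw, sp, np.nan, "")
            for sid, raw, sp, dec in rows
        ],
        columns=sl.PSM_COLUMNS,
    )


# ------------------------------------------------------------------- decoys

def test_decoys_reverse_sequences_one_per_target():
    targets = [make_record("P1", "MKR"), make_record("P2", "ABA".replace("B", "C"))]
    decoys = build_decoys(targets)
    assert len(decoys) == len(targets)
    assert decoys[0].record_id == "XXX_P1" and decoys[0].sequence == "RKM"
    assert all(d.category == "decoy" for d in decoys)
    palindrome = make_record("P3", "MKM")
    d = build_decoys([palindrome])[0]
    assert d.sequence == palindrome.sequence and d.record_id.startswith(DECOY_PREFIX)


# ------------------------------------------------------------------ scoring

def _bruteforce_max_matching(theo, obs, tol):
    """Exact maximum one-to-one matching by exhaustive recursion."""
    theo, obs = list(theo), list(obs)

    def rec(i, used):
        if i == len(theo):
            return 0
        best = rec(i + 1, used)
        for j in range(len(obs)):
            if j not in used and abs(theo[i] - obs[j]) <= tol:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


def test_match_count_equals_bruteforce_on_random_toys():
    rng = np.random.default_rng(0)
    for _ in range(100):
        theo = np.sort(rng.uniform(0, 30, size=rng.integers(1, 6)))
        obs = np.sort(rng.uniform(0, 30, size=rng.integers(1, 6)))
        tol = float(rng.uniform(0.2, 3.0))
        assert match_count(theo, obs, tol) == _bruteforce_max_matching(theo, obs, tol)


def test_hand_computed_four_peak_toy():
    theo = np.array([10.0, 20.0, 30.0, 40.0])
    obs = np.array([10.2, 19.9, 30.6, 55.0])
    assert match_count(theo, obs, 0.5) == 2
    assert _bruteforce_max_matching(theo, obs, 0.5) == 2


def test_noise_free_spectrum_scores_all_by_ions():
    pep = "ELVISLIVESK"
    spec = Spectrum("s1", "s", 1, peptide_mass(pep), fragment_mz(pep))
    raw, sp = score_match(spec, pep)
    assert raw == 2 * (len(pep) - 1)
    assert sp < 1e-10


def test_zero_overlap_gives_probability_one():
    spec = Spectrum("s1", "s", 1, 1000.0, np.array([5000.0, 6000.0]))
    raw, sp = score_match(spec, "AAAAAAK")
    assert raw == 0 and sp == 1.0


def test_spectral_probability_decreases_with_score():
    params = SearchParams()
    probs = [spectral_probability(k, 30, 30, params) for k in range(1, 12)]
    assert all(a > b for a, b in zip(probs, probs[1:]))


# ----------------------------------------------------------------- q-values

def _bruteforce_qvalues(df):
    order = df.sort_values(
        ["raw_score", "spectral_probability", "spectrum_id"],
        ascending=[False, True, True], kind="mergesort",
    )
    decoys = order["is_decoy"].tolist()
    fdrs = []
    for r in range(1, len(order) + 1):
        d = sum(decoys[:r])
        t = r - d
        fdrs.append(min(d / max(t, 1), 1.0))
    qs = [min(fdrs[r:]) for r in range(len(fdrs))]
    return pd.Series(qs, index=order.index).reindex(df.index)


def test_qvalue_worked_example():
    df = make_psms([("a", 10, 0.1, False), ("b", 9, 0.1, False),
                    ("c", 8, 0.1, True), ("d", 7, 0.1, False)])
    q = compute_qvalues(df)["q_value"]
    assert q.tolist() == pytest.approx([0.0, 0.0, 1 / 3, 1 / 3])


def test_qvalue_boundaries():
    all_targets = make_psms([(f"s{i}", 10 - i, 0.1, False) for i in range(5)])
    assert (compute_qvalues(all_targets)["q_value"] == 0).all()
    decoys_on_top = make_psms(
        [(f"d{i}", 20 + i, 0.1, True) for i in range(3)]
        + [(f"t{i}", 5 - i, 0.1, False) for i in range(3)]
    )
    q = compute_qvalues(decoys_on_top)
    assert (q[~q["is_decoy"]]["q_value"] == 1.0).all()


def test_qvalues_match_bruteforce_on_randomized_tables():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(1, 40))
        df = make_psms([
            (f"s{i}", int(rng.integers(0, 12)), float(rng.uniform(1e-20, 1)),
             bool(rng.random() < 0.4))
            for i in range(n)
        ])
        got = compute_qvalues(df)["q_value"]
        want = _bruteforce_qvalues(df)
        assert np.allclose(got, want)


def test_qvalues_are_monotone_in_score_rank():
    rng = np.random.default_rng(1)
    df = make_psms([
        (f"s{i}", int(rng.integers(0, 15)), float(rng.uniform()), bool(rng.random() < 0.3))
        for i in range(200)
    ])
    out = compute_qvalues(df).sort_values(
        ["raw_score", "spectral_probability", "spectrum_id"],
        ascending=[False, True, True])
    assert (np.diff(out["q_value"]) >= -1e-12).all()


# --------------------------------------------------------------- condensation

def test_condense_keeps_best_per_spectrum_and_matches_bruteforce():
    c1 = make_psms([("a", 12, 0.5, False), ("b", 3, 0.5, False)])
    c2 = make_psms([("a", 9, 0.5, False), ("b", 7, 0.5, True)])
    out = condense_results([c1, c2])
    assert out.set_index("spectrum_id")["raw_score"].to_dict() == {"a": 12, "b": 7}

    rng = np.random.default_rng(5)
    for _ in range(100):
        chunks = []
        spectra = [f"s{i}" for i in range(int(rng.integers(1, 8)))]
        for _c in range(int(rng.integers(1, 4))):
            chunks.append(make_psms([
                (sid, int(rng.integers(0, 10)), float(rng.uniform()), False)
                for sid in spectra if rng.random() < 0.8
            ]))
        nonempty = [c for c in chunks if not c.empty]
        if not nonempty:
            continue
        merged = pd.concat(nonempty, ignore_index=True)
        out = condense_results(chunks)
        brute = merged.groupby("spectrum_id")["raw_score"].max()
        assert out.set_index("spectrum_id")["raw_score"].to_dict() == brute.to_dict()
        assert out["spectrum_id"].is_unique


def test_condense_single_chunk_is_identity_with_recomputed_q():
    c1 = compute_qvalues(make_psms([("a", 12, 0.5, False), ("b", 3, 0.5, True)]))
    out = condense_results([c1]).sort_values("spectrum_id").reset_index(drop=True)
    want = c1.sort_values("spectrum_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(out, want)


# -------------------------------------------------------------------- search

def _toy_db():
    return ProteinDatabase("toy", "custom", [
        make_record("P1", "MAAAELVISLIVESKRDDDDK", species="A"),
        make_record("P2", "MCCCCELVISLIVESKW", species="B"),
        make_record("P3", "MWWWWWWWWYYYYYYYK", species="C"),
    ])


def test_search_recovers_noise_free_peptide_with_all_source_proteins():
    pep = "ELVISLIVESK"
    spec = Spectrum("s1", "s", 1, peptide_mass(pep), fragment_mz(pep))
    psms = search([spec], _toy_db())
    assert len(psms) == 1
    row = psms.iloc[0]
    assert row.peptide == pep
    ids = row.protein_ids.split(";")
    assert "P1" in ids and "P2" in ids  # shared peptide: both proteins listed
    assert not row.is_decoy


def test_search_omits_spectra_without_candidates_and_rejects_empty_db():
    spec = Spectrum("s1", "s", 1, 50.0, np.array([10.0]))
    assert search([spec], _toy_db()).empty
    with pytest.raises(ValidationError):
        search([spec], ProteinDatabase("e", "custom", []))


def test_search_is_deterministic():
    rng = np.random.default_rng(8)
    pep = "ELVISLIVESK"
    frags = fragment_mz(pep)[::2]
    spec = Spectrum("s1", "s", 1, peptide_mass(pep), frags)
    a = search([spec], _toy_db())
    b = search([spec], _toy_db())
    pd.testing.assert_frame_equal(a, b)


# ------------------------------------------------------------------ two-step

def test_two_step_fixed_point_when_every_protein_matched():
    pep1, pep2, pep3 = "ELVISLIVESK", "WWWWWWWWYYYYYYYK", "DDDDK"
    db = _toy_db()
    spectra = [
        Spectrum("s1", "s", 1, peptide_mass(pep1), fragment_mz(pep1)),
        Spectrum("s2", "s", 1, peptide_mass(pep2), fragment_mz(pep2)),
    ]
    psms, subset = two_step_search(spectra, db)
    matched_ids = set()
    for ids in psms["protein_ids"]:
        matched_ids.update(i for i in ids.split(";") if not i.startswith(DECOY_PREFIX))
    assert {r.record_id for r in subset.records} == matched_ids
    # P3 unmatched only if absent from results; all its peptides were searched
    one_step = search(spectra, subset)
    pd.testing.assert_frame_equal(
        psms.reset_index(drop=True), one_step.reset_index(drop=True))


def test_two_step_never_keeps_unmatched_proteins(tiny_study, tiny_core):
    from metaprotbench import dbforge

    s = tiny_study.samples[0]
    db = dbforge.build_sample_matched_16s(
        s.community.profile, tiny_study.repository, tiny_core)
    spectra = tiny_study.all_spectra(s.sample_id)
    psms, subset = two_step_search(spectra, db)
    matched = set()
    step1 = search(spectra, db)
    for ids in step1["protein_ids"]:
        matched.update(i for i in ids.split(";") if not i.startswith(DECOY_PREFIX))
    for rec in subset.records:
        assert rec.record_id in matched or rec.source == "core"
    # FDR shrinkage: the subset search accepts at least as many PSMs
    assert len(sl.significant(psms)) >= len(sl.significant(step1))


# ------------------------------------------------------------------- merging

def test_merge_replicates_concatenates_and_recomputes_q():
    r1 = compute_qvalues(make_psms([("a", 10, 0.5, False)]))
    r2 = compute_qvalues(make_psms([("b", 2, 0.5, True), ("c", 8, 0.4, False)]))
    merged = merge_replicates(r1, r2)
    assert len(merged) == 3
    empty = r2.iloc[0:0]
    only = merge_replicates(r1, empty)
    assert len(only) == 1
    r2_bad = r2.copy()
    r2_bad["sample_id"] = "other"
    with pytest.raises(ValidationError):
        merge_replicates(r1, r2_bad)


# ----------------------------------------------------------------- TSV paths

def test_internal_psm_tsv_round_trip(tmp_path):
    df = compute_qvalues(make_psms([("a", 10, 1e-17, False), ("b", 2, 0.5, True)]))
    df.loc[0, "classification"] = "bacterial"
    path = tmp_path / "psms.tsv"
    write_psm_tsv(df, path)
    back = read_psm_tsv(path)
    pd.testing.assert_frame_equal(back, df.reset_index(drop=True))


def test_msgf_import_maps_columns_and_flags_decoys(tmp_path):
    path = tmp_path / "msgf.tsv"
    path.write_text(
        "#SpecFile\tSpecID\tScanNum\tPeptide\tProtein\tSpecEValue\tQValue\n"
        "run1.mzML\tspec_1\t10\tK.AAAAAR.L\tP1;XXX_P2\t1e-12\t0.001\n"
        "run1.mzML\tspec_2\t11\tR.CCCCCK.A\tP3\t1e-3\t0.2\n"
    )
    psms = read_msgf_tsv(path)
    assert psms.loc[0, "peptide"] == "AAAAAR"
    assert bool(psms.loc[0, "is_decoy"]) is True
    assert bool(psms.loc[1, "is_decoy"]) is False
    assert psms.loc[0, "sample_id"] == "run1"

    bad = tmp_path / "bad.tsv"
    bad.write_text("#SpecFile\tSpecID\tScanNum\tPeptide\tSpecEValue\tQValue\n")
    with pytest.raises(ValidationError, match="Protein"):
        read_msgf_tsv(bad)


def test_strip_flanks():
    assert strip_flanks("K.PEPTIDER.A") == "PEPTIDER"
    assert strip_flanks("-.MKKR.A") == "MKKR"
    assert strip_flanks("PEPTIDER") == "PEPTIDER"
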