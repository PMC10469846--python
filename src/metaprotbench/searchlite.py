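"""A lightweight deterministic target-decoy peptide-spectrum search engine.

Stands in for a production search tool (MS-GF+-like) at desk scale: it digests
the database semi-tryptically, matches spectra by precursor mass with an
isotope-error window, scores candidates by matched b/y fragment counts,
converts scores to a Poisson-null spectral probability (the SpecEValue
analog), and estimates FDR/q-values from a concatenated reversed-decoy
search. The statistics of target-decoy competition — not fragmentation
chemistry — are what matter for database benchmarking, so fragments are
singly charged monoisotopic b/y ions only.

Also provides the two-step search (initial search, subset database of every
matched protein, fresh search with fresh decoys), multi-chunk result
condensation, replicate merging, and an MS-GF+ TSV import path.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from scipy import special as _special

from .dbforge import ProteinDatabase, ProteinRecord, ValidationError
from .proteolysis import cleavage_sites

logger = logging.getLogger("metaprotbench")

PROTON = 1.00727646688
WATER = _ptmass.calculate_mass(formula="H2O")
#: averaged C13-C12 spacing used for the isotope-error window
ISOTOPE_SPACING = 1.00335483

DECOY_PREFIX = "XXX_"

# monoisotopic residue masses indexed by ASCII code
_RESIDUE_MASS = np.zeros(128)
for _aa, _m in _ptmass.std_aa_mass.items():
    if len(_aa) == 1 and _aa.isupper():
        _RESIDUE_MASS[ord(_aa)] = _m


@dataclass(frozen=True)
class SearchParams:
    """Search engine settings (tolerances in Da, lengths in residues)."""

    precursor_tolerance: float = 0.05
    fragment_tolerance: float = 0.5
    min_peptide_length: int = 6
    max_peptide_length: int = 30
    max_missed_cleavages: int = 2
    isotope_error_range: tuple[int, int] = (-1, 2)
    #: effective m/z span of the Poisson null for spectral probabilities
    null_mass_range: float = 2000.0


@dataclass
class Spectrum:
    """One synthetic tandem mass spectrum."""

    spectrum_id: str
    sample_id: str
    replicate: int
    precursor_mass: float
    fragment_masses: np.ndarray

    def __post_init__(self) -> None:
        self.fragment_masses = np.asarray(self.fragment_masses, dtype=float)
        if self.fragment_masses.size == 0:
            raise ValidationError(f"spectrum {self.spectrum_id}: no fragment masses")


PSM_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "replicate",
    "peptide",
    "protein_ids",
    "is_decoy",
    "raw_score",
    "spectral_probability",
    "q_value",
    "classification",
]


def peptide_mass(peptide: str) -> float:
    """Neutral monoisotopic peptide mass."""
    res = _RESIDUE_MASS[np.frombuffer(peptide.encode(), dtype=np.uint8)]
    return float(res.sum() + WATER)


def fragment_mz(peptide: str) -> np.ndarray:
    """Sorted singly charged b/y fragment m/z values of a peptide."""
    res = _RESIDUE_MASS[np.frombuffer(peptide.encode(), dtype=np.uint8)]
    prefix = np.cumsum(res)
    b = prefix[:-1] + PROTON
    y = prefix[-1] - prefix[:-1] + WATER + PROTON
    out = np.concatenate([b, y])
    out.sort()
    return out


def build_decoys(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, id prefixed ``XXX_``."""
    return [
        ProteinRecord(
            record_id=DECOY_PREFIX + rec.record_id,
            sequence=rec.sequence[::-1],
            species=rec.species,
            strain=rec.strain,
            genus=rec.genus,
            category="decoy",
            source=rec.source,
        )
        for rec in records
    ]


def match_count(theoretical: np.ndarray, observed: np.ndarray, tolerance: float) -> int:
    """Maximum one-to-one matching between sorted mass lists within tolerance.

    Two-pointer greedy sweep; on sorted inputs with a fixed window this
    attains the maximum bipartite matching.
    """
    t = theoretical.tolist()
    o = observed.tolist()
    i = j = matched = 0
    nt, no = len(t), len(o)
    while i < nt and j < no:
        d = t[i] - o[j]
        if d > tolerance:
            j += 1
        elif d < -tolerance:
            i += 1
        else:
            matched += 1
            i += 1
            j += 1
    return matched


def spectral_probability(
    raw_score: int, n_observed: int, n_theoretical: int, params: SearchParams
) -> float:
    """Survival probability of >= raw_score matches under a Poisson null.

    The null rate is the expected number of random peak coincidences:
    ``n_observed * 2*tol * n_theoretical / null_mass_range``.
    """
    if raw_score <= 0:
        return 1.0
    lam = (
        n_observed
        * 2.0
        * params.fragment_tolerance
        * n_theoretical
        / params.null_mass_range
    )
    # P(X >= k) for X ~ Poisson(lam); pdtrc(k-1, lam) avoids the frozen
    # scipy.stats distribution overhead on this hot path
    p = float(_special.pdtrc(raw_score - 1, lam))
    return min(max(p, 5e-324), 1.0)


def score_match(
    spectrum: Spectrum, peptide: str, params: SearchParams = SearchParams()
) -> tuple[int, float]:
    """Raw matched-fragment count and spectral probability for one peptide."""
    obs = np.sort(spectrum.fragment_masses)
    theo = fragment_mz(peptide)
    raw = match_count(theo, obs, params.fragment_tolerance)
    return raw, spectral_probability(raw, obs.size, theo.size, params)


# ---------------------------------------------------------------------------
# Peptide index: semi-tryptic spans over all database records
# ---------------------------------------------------------------------------

class PeptideIndex:
    """Mass-sorted index of semi-tryptic peptide spans of a record set.

    Peptides are represented as (record, start, end) spans rather than
    materialized strings; at least one terminus of every span is a tryptic
    cleavage point or protein terminus, and at most ``max_missed_cleavages``
    cleavage sites fall strictly inside the span.
    """

    def __init__(self, records: Sequence[ProteinRecord], params: SearchParams):
        self.records = list(records)
        self.params = params
        rec_parts: list[np.ndarray] = []
        start_parts: list[np.ndarray] = []
        end_parts: list[np.ndarray] = []
        mass_parts: list[np.ndarray] = []
        minl, maxl = params.min_peptide_length, params.max_peptide_length
        mc = params.max_missed_cleavages
        for ridx, rec in enumerate(self.records):
            seq = rec.sequence
            L = len(seq)
            if L < minl:
                continue
            sites = cleavage_sites(seq)
            B = np.array([0] + sites + [L], dtype=np.int64)
            nb = B.size
            is_bound = np.zeros(L + 1, dtype=bool)
            is_bound[B] = True
            res = _RESIDUE_MASS[np.frombuffer(seq.encode(), dtype=np.uint8)]
            cs = np.concatenate([[0.0], np.cumsum(res)])
            starts: list[np.ndarray] = []
            ends: list[np.ndarray] = []
            # fully tryptic spans (both termini at boundaries)
            for i in range(nb - 1):
                for j in range(i + 1, min(i + 2 + mc, nb)):
                    if minl <= B[j] - B[i] <= maxl:
                        starts.append(np.array([B[i]]))
                        ends.append(np.array([B[j]]))
            # semi-tryptic: tryptic N terminus, ragged C terminus
            for i in range(nb - 1):
                s = int(B[i])
                cap_idx = i + 1 + mc
                e_cap = int(B[cap_idx]) if cap_idx < nb else L
                e_arr = np.arange(s + minl, min(s + maxl, e_cap) + 1)
                e_arr = e_arr[~is_bound[e_arr]]
                if e_arr.size:
                    starts.append(np.full(e_arr.size, s))
                    ends.append(e_arr)
            # semi-tryptic: ragged N terminus, tryptic C terminus
            for j in range(1, nb):
                e = int(B[j])
                cap_idx = j - 1 - mc
                s_floor = int(B[cap_idx]) if cap_idx >= 0 else 0
                s_arr = np.arange(max(e - maxl, s_floor), e - minl + 1)
                s_arr = s_arr[~is_bound[s_arr]]
                if s_arr.size:
                    starts.append(s_arr)
                    ends.append(np.full(s_arr.size, e))
            if not starts:
                continue
            s_all = np.concatenate(starts)
            e_all = np.concatenate(ends)
            rec_parts.append(np.full(s_all.size, ridx, dtype=np.int32))
            start_parts.append(s_all.astype(np.int32))
            end_parts.append(e_all.astype(np.int32))
            mass_parts.append(cs[e_all] - cs[s_all] + WATER)
        if mass_parts:
            masses = np.concatenate(mass_parts)
            order = np.argsort(masses, kind="stable")
            self.mass = masses[order]
            self.rec_idx = np.concatenate(rec_parts)[order]
            self.start = np.concatenate(start_parts)[order]
            self.end = np.concatenate(end_parts)[order]
        else:
            self.mass = np.empty(0)
            self.rec_idx = np.empty(0, dtype=np.int32)
            self.start = np.empty(0, dtype=np.int32)
            self.end = np.empty(0, dtype=np.int32)

    def __len__(self) -> int:
        return self.mass.size

    def candidates(self, precursor_mass: float) -> np.ndarray:
        """Index positions whose mass fits the precursor within tolerance,
        allowing the configured isotope error range."""
        p = self.params
        lo_iso, hi_iso = p.isotope_error_range
        hits = []
        for iso in range(lo_iso, hi_iso + 1):
            m = precursor_mass - iso * ISOTOPE_SPACING
            lo = np.searchsorted(self.mass, m - p.precursor_tolerance, side="left")
            hi = np.searchsorted(self.mass, m + p.precursor_tolerance, side="right")
            if hi > lo:
                hits.append(np.arange(lo, hi))
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))

    def peptide_at(self, i: int) -> str:
        return self.records[self.rec_idx[i]].sequence[self.start[i] : self.end[i]]


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def build_index(db: ProteinDatabase, params: SearchParams = SearchParams()) -> PeptideIndex:
    """Peptide index over the database targets plus their fresh decoys."""
    if not db.records:
        raise ValidationError("cannot search an empty database")
    return PeptideIndex(list(db.records) + build_decoys(db.records), params)


def search(
    spectra: Sequence[Spectrum],
    db: ProteinDatabase,
    params: SearchParams = SearchParams(),
    index: PeptideIndex | None = None,
) -> pd.DataFrame:
    """Best-scoring peptide per spectrum against targets plus fresh decoys.

    Each spectrum's best candidate is retained with every database protein
    (target or decoy) containing that peptide among the mass-window
    candidates. Spectra with an empty candidate set are omitted. Ties break
    deterministically: higher raw score, then lower spectral probability,
    then lexicographically smallest peptide. q-values are computed on the
    returned table. A prebuilt ``index`` (from :func:`build_index` on the
    same database and params) may be supplied to amortize repeated searches.
    """
    if index is None:
        index = build_index(db, params)
    all_records = index.records
    rows = []
    for spec in spectra:
        cand = index.candidates(spec.precursor_mass)
        if cand.size == 0:
            continue
        by_pep: dict[str, list[int]] = {}
        for i in cand.tolist():
            by_pep.setdefault(index.peptide_at(i), []).append(i)
        obs = np.sort(spec.fragment_masses)
        # raw scores for every unique candidate; spectral probabilities only
        # for the top raw-score group (probability is monotone in raw score
        # at fixed peptide length, so it only breaks ties)
        scored: list[tuple[int, str, np.ndarray]] = []
        best_raw = -1
        for pep in by_pep:
            theo = fragment_mz(pep)
            raw = match_count(theo, obs, params.fragment_tolerance)
            if raw > best_raw:
                best_raw = raw
            scored.append((raw, pep, theo))
        best: tuple[int, float, str] | None = None
        for raw, pep, theo in scored:
            if raw != best_raw:
                continue
            sp = spectral_probability(raw, obs.size, theo.size, params)
            if best is None or (sp, pep) < (best[1], best[2]):
                best = (raw, sp, pep)
        assert best is not None
        raw, sp, pep = best
        ids = sorted({all_records[index.rec_idx[i]].record_id for i in by_pep[pep]})
        rows.append(
            (
                spec.spectrum_id,
                spec.sample_id,
                spec.replicate,
                pep,
                ";".join(ids),
                any(i.startswith(DECOY_PREFIX) for i in ids),
                raw,
                sp,
                np.nan,
                "",
            )
        )
    df = pd.DataFrame(rows, columns=PSM_COLUMNS)
    return compute_qvalues(df)


def compute_qvalues(psms: pd.DataFrame) -> pd.DataFrame:
    """Target-decoy FDR and monotonized q-values.

    PSMs are ranked by decreasing raw score (ties: increasing spectral
    probability, then spectrum id); at each rank FDR = decoys-at-or-above /
    max(1, targets-at-or-above), and the q-value is the minimum FDR at any
    rank at or below. Decoy PSMs keep their q-values for audit.
    """
    if psms.empty:
        out = psms.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    df = psms.sort_values(
        ["raw_score", "spectral_probability", "spectrum_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    decoy = df["is_decoy"].to_numpy(dtype=bool)
    n_decoy = np.cumsum(decoy)
    n_target = np.cumsum(~decoy)
    fdr = np.minimum(n_decoy / np.maximum(n_target, 1), 1.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    df = df.copy()
    df["q_value"] = q
    return df.loc[psms.index]


def significant(psms: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Target PSMs below the q-value threshold (strict inequality)."""
    return psms[(psms["q_value"] < q_threshold) & (~psms["is_decoy"])]


def two_step_search(
    spectra: Sequence[Spectrum],
    db: ProteinDatabase,
    params: SearchParams = SearchParams(),
    step1_index: PeptideIndex | None = None,
) -> tuple[pd.DataFrame, ProteinDatabase]:
    """The two-step search strategy.

    Step 1 searches the full database and records every matched target
    protein regardless of statistical significance. A subset database of
    those proteins plus the core set is then searched afresh (with fresh
    decoys built from the subset); the second-pass table is returned along
    with the subset database.
    """
    step1 = search(spectra, db, params, index=step1_index)
    matched: set[str] = set()
    for ids in step1["protein_ids"]:
        for pid in ids.split(";"):
            if not pid.startswith(DECOY_PREFIX):
                matched.add(pid)
    if not matched:
        logger.warning("two-step search: step 1 matched no target proteins")
        empty = pd.DataFrame(columns=PSM_COLUMNS)
        return empty, ProteinDatabase(name=db.name + "_subset", strategy=db.strategy,
                                      records=[], sample_id=db.sample_id)
    subset_records = [
        r for r in db.records if r.record_id in matched or r.source == "core"
    ]
    subset_db = ProteinDatabase(
        name=db.name + "_subset",
        strategy=db.strategy,
        records=subset_records,
        sample_id=db.sample_id,
    )
    step2 = search(spectra, subset_db, params)
    return step2, subset_db


def pooled_two_step_search(
    spectra_by_sample: dict[str, Sequence[Spectrum]],
    db: ProteinDatabase,
    params: SearchParams = SearchParams(),
    step1_index: PeptideIndex | None = None,
) -> tuple[dict[str, pd.DataFrame], ProteinDatabase]:
    """Two-step search of a pooled database shared by many samples.

    As in the study-scale workflow for pooled databases, the subset database
    is built from the union of proteins hit in the initial searches of
    every sample, then each sample is re-searched against that one subset.
    """
    if step1_index is None:
        step1_index = build_index(db, params)
    matched: set[str] = set()
    for sample_id in sorted(spectra_by_sample):
        step1 = search(spectra_by_sample[sample_id], db, params, index=step1_index)
        for ids in step1["protein_ids"]:
            for pid in ids.split(";"):
                if not pid.startswith(DECOY_PREFIX):
                    matched.add(pid)
    subset_records = [
        r for r in db.records if r.record_id in matched or r.source == "core"
    ]
    subset_db = ProteinDatabase(
        name=db.name + "_subset", strategy=db.strategy,
        records=subset_records, sample_id=db.sample_id,
    )
    subset_index = build_index(subset_db, params)
    out = {
        sample_id: search(spectra_by_sample[sample_id], subset_db, params, index=subset_index)
        for sample_id in sorted(spectra_by_sample)
    }
    return out, subset_db


def condense_results(chunks: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-chunk searches of the same spectra, keeping the single
    best-scoring PSM per spectrum; q-values are recomputed on the result."""
    frames = [c for c in chunks if not c.empty]
    if not frames:
        return compute_qvalues(pd.DataFrame(columns=PSM_COLUMNS))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(
        ["raw_score", "spectral_probability", "peptide", "protein_ids"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    df = df.drop_duplicates("spectrum_id", keep="first").reset_index(drop=True)
    return compute_qvalues(df)


def merge_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Concatenate the two replicate searches of one sample; q-values are
    recomputed on the union."""
    for df in (rep1, rep2):
        if df.empty:
            continue
        samples = set(df["sample_id"].unique())
        if len(samples) > 1:
            raise ValidationError(f"replicate table spans samples {sorted(samples)}")
    s1 = set(rep1["sample_id"].unique()) if not rep1.empty else set()
    s2 = set(rep2["sample_id"].unique()) if not rep2.empty else set()
    if s1 and s2 and s1 != s2:
        raise ValidationError(f"sample mismatch between replicates: {s1} vs {s2}")
    merged = pd.concat([rep1, rep2], ignore_index=True)
    return compute_qvalues(merged)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_psm_tsv(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psm_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"classification": str}, keep_default_na=False,
                     na_values=[""])
    df["classification"] = df["classification"].fillna("")
    for col, dtype in [("replicate", int), ("is_decoy", bool), ("raw_score", int)]:
        if col in df:
            df[col] = df[col].astype(dtype)
    return df


_FLANK = re.compile(r"^(?:[A-Z*]|-)\.(.+)\.(?:[A-Z*]|-)$")

_MSGF_REQUIRED = ["#SpecFile", "SpecID", "ScanNum", "Peptide", "Protein", "SpecEValue", "QValue"]


def strip_flanks(peptide: str) -> str:
    """``K.PEPTIDER.A`` -> ``PEPTIDER``; bare sequences pass through."""
    m = _FLANK.match(peptide)
    return m.group(1) if m else peptide


def read_msgf_tsv(path: str | Path) -> pd.DataFrame:
    """Import an MS-GF+ TSV result file as a PSM table.

    Decoy status is detected from the ``XXX_`` protein-id prefix; flanking
    residue annotations on peptides are stripped. The MSGFScore column is
    used as the raw score when present.
    """
    df = pd.read_csv(path, sep="\t")
    for col in _MSGF_REQUIRED:
        if col not in df.columns:
            raise ValidationError(f"MS-GF+ TSV missing mandatory column {col!r}")
    proteins = df["Protein"].astype(str).str.split(";")
    out = pd.DataFrame(
        {
            "spectrum_id": df["SpecID"].astype(str),
            "sample_id": [Path(str(f)).stem for f in df["#SpecFile"]],
            "replicate": 1,
            "peptide": [strip_flanks(p) for p in df["Peptide"].astype(str)],
            "protein_ids": [";".join(ps) for ps in proteins],
            "is_decoy": [any(p.startswith(DECOY_PREFIX) for p in ps) for ps in proteins],
            "raw_score": df["MSGFScore"] if "MSGFScore" in df.columns else np.nan,
            "spectral_probability": df["SpecEValue"].astype(float),
            "q_value": df["QValue"].astype(float),
            "classification": "",
        }
    )
    return out
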