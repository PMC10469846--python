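"""Database-comparison metrics, statistical tests, and experiment harnesses.

Consumes classified PSM tables and produces the benchmark's headline
quantities: per-sample significant PSM counts by database strategy, relative
identification rates (normalized so the five compared strategies average to
1 per sample), pairwise Wilcoxon signed-rank comparisons, presumptive
false-positive rates against the 16S profile, spectral-count functional
differential abundance, the weighted-peptide-completeness correlation, the
strains-versus-species augmentation experiment, hybrid dominance share, and
exclusive-spectra overlaps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import dbforge, proteolysis, psmclass, searchlite, synthio
from .dbforge import COMPARED_STRATEGIES, ProteinDatabase, ValidationError

PSM_TYPES = ("human", "bacterial")


# ---------------------------------------------------------------------------
# Relative identification rate and pairwise tests
# ---------------------------------------------------------------------------

def relative_identification_rate(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample significant-PSM counts normalized by the five-strategy mean.

    ``counts`` columns: sample_id, strategy, psm_type, count. Exactly the
    five compared strategies must be present for each (sample, psm_type);
    the mean of the returned rates is 1 per (sample, psm_type) by
    construction. A zero mean is an error.
    """
    rows = []
    for (sample, ptype), grp in counts.groupby(["sample_id", "psm_type"], sort=True):
        present = set(grp["strategy"])
        missing = set(COMPARED_STRATEGIES) - present
        if missing:
            raise ValidationError(
                f"sample {sample}/{ptype}: missing strategies {sorted(missing)}"
            )
        grp = grp[grp["strategy"].isin(COMPARED_STRATEGIES)]
        mean = grp["count"].mean()
        if mean == 0:
            raise ValidationError(f"sample {sample}/{ptype}: zero mean significant PSMs")
        for row in grp.itertuples():
            rows.append((sample, row.strategy, ptype, row.count / mean))
    return pd.DataFrame(rows, columns=["sample_id", "strategy", "psm_type", "rate"])


def pairwise_db_comparison(
    counts: pd.DataFrame, p_threshold: float = 0.01
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank tests on paired per-sample counts.

    One row per (psm_type, strategy pair): p-value, significance at the
    threshold, and the direction (which strategy identified more PSMs).
    The exact null distribution is used for n <= 25 without ties (scipy's
    default policy); all-zero differences are reported non-significant with
    a note.
    """
    rows = []
    for ptype in sorted(counts["psm_type"].unique()):
        sub = counts[counts["psm_type"] == ptype]
        wide = sub.pivot_table(index="sample_id", columns="strategy", values="count")
        strategies = sorted(wide.columns)
        for a, b in itertools.combinations(strategies, 2):
            paired = wide[[a, b]].dropna()
            if len(paired) < 6:
                raise ValidationError(f"need >= 6 paired samples, have {len(paired)}")
            diff = paired[a] - paired[b]
            note = ""
            if (diff == 0).all():
                p = 1.0
                note = "all differences zero"
            else:
                p = float(stats.wilcoxon(paired[a], paired[b]).pvalue)
            direction = "none"
            if p < p_threshold:
                direction = a if diff.sum() > 0 else b
            rows.append((ptype, a, b, p, p < p_threshold, direction, note))
    return pd.DataFrame(
        rows,
        columns=["psm_type", "strategy_a", "strategy_b", "p_value", "significant",
                 "winner", "note"],
    )


def hybrid_dominance_share(
    counts_16s: Mapping[str, int], counts_hybrid: Mapping[str, int]
) -> int:
    """Percent of samples where the hybrid database matched or beat the
    16S sample-matched database on bacterial PSMs (integer percent)."""
    samples = sorted(counts_16s)
    if set(samples) != set(counts_hybrid):
        raise ValidationError("sample sets differ between the two count maps")
    wins = sum(1 for s in samples if counts_hybrid[s] >= counts_16s[s])
    return int(round(100.0 * wins / len(samples)))


# ---------------------------------------------------------------------------
# Presumptive false positives
# ---------------------------------------------------------------------------

def presumptive_false_positive_rate(
    classified_bacterial: pd.DataFrame,
    profile: dbforge.AbundanceProfile,
    cutoff: float = 0.001,
) -> float | None:
    """Percent of significant bacterial PSMs that exclusively match genera
    below the abundance cutoff — likely false positives.

    Requires the ``genus_set`` column from :func:`psmclass.assign_taxa`.
    PSMs matching any unresolved (``Unknown``) ORF are not counted as
    presumptive false positives, since their abundance cannot be judged.
    Returns ``None`` when the sample has no bacterial PSMs.
    """
    if classified_bacterial.empty:
        return None
    genus_ab = profile.genus_abundance()
    n_fp = 0
    for genera in classified_bacterial["genus_set"]:
        gset = genera.split(";")
        if "Unknown" in gset:
            continue
        if all(genus_ab.get(g, 0.0) < cutoff for g in gset):
            n_fp += 1
    return 100.0 * n_fp / len(classified_bacterial)


# ---------------------------------------------------------------------------
# Functional differential abundance
# ---------------------------------------------------------------------------

def functional_differential_abundance(
    classified_psms: pd.DataFrame,
    annotation_map: Mapping[str, Sequence[str]] | pd.DataFrame,
    groups: Mapping[str, str],
    category: str = "bacterial",
    p_threshold: float = 0.01,
    correction: str | None = None,
) -> pd.DataFrame:
    """Spectral-count differential abundance of functional terms.

    Per PSM only the first matched protein is annotated; per term and sample
    the spectral count is divided by the sample's total PSMs of the category,
    log2-transformed (zeros get half the smallest nonzero relative abundance
    as a pseudocount), and compared between the two groups by Mann-Whitney U.
    Terms absent everywhere are excluded. Significance is a raw per-term
    P < threshold by default; ``correction="bh"`` applies Benjamini-Hochberg
    adjustment first. Returns per-term statistics sorted by term id.
    """
    if isinstance(annotation_map, pd.DataFrame):
        amap: dict[str, list[str]] = {}
        for row in annotation_map.itertuples():
            amap.setdefault(str(row.protein_id), []).append(str(row.term_id))
    else:
        amap = {k: list(v) for k, v in annotation_map.items()}
    if not amap:
        raise ValidationError("empty annotation map")
    sub = classified_psms[classified_psms["classification"] == category]
    samples = sorted(groups)
    totals = sub.groupby("sample_id").size().to_dict()
    counts: dict[str, dict[str, int]] = {}
    for row in sub.itertuples():
        first_protein = row.protein_ids.split(";")[0]
        for term in amap.get(first_protein, ()):
            per = counts.setdefault(term, {})
            per[row.sample_id] = per.get(row.sample_id, 0) + 1
    rows = []
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValidationError(f"need exactly two groups, got {group_names}")
    for term in sorted(counts):
        rel = np.array(
            [counts[term].get(s, 0) / totals.get(s, np.nan) for s in samples], dtype=float
        )
        rel = np.nan_to_num(rel, nan=0.0)
        if rel.sum() == 0:
            continue
        nonzero = rel[rel > 0]
        eps = nonzero.min() / 2.0
        logged = np.log2(rel + eps)
        ga = logged[[groups[s] == group_names[0] for s in samples]]
        gb = logged[[groups[s] == group_names[1] for s in samples]]
        if np.all(ga[:, None] == gb[None, :]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
        rows.append((term, p))
    out = pd.DataFrame(rows, columns=["term_id", "p_value"])
    if correction == "bh" and not out.empty:
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
        out["significant"] = out["p_adjusted"] < p_threshold
    elif correction is None:
        out["significant"] = out["p_value"] < p_threshold
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return out


# ---------------------------------------------------------------------------
# Weighted-metric correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    table: pd.DataFrame  # sample_id, weighted_metric, ratio


def weighted_metric_correlation(
    scores: Mapping[str, float],
    counts_16s: Mapping[str, int],
    counts_hybrid: Mapping[str, int],
) -> CorrelationResult:
    """Spearman correlation between database completeness W and the
    16S-matched / hybrid bacterial-PSM ratio.

    Samples with zero hybrid PSMs are dropped with a warning; at least five
    usable samples are required.
    """
    rows = []
    for sample in sorted(scores):
        hyb = counts_hybrid.get(sample, 0)
        if hyb == 0:
            dbforge.logger.warning("sample %s: zero hybrid PSMs; dropped", sample)
            continue
        rows.append((sample, scores[sample], counts_16s.get(sample, 0) / hyb))
    table = pd.DataFrame(rows, columns=["sample_id", "weighted_metric", "ratio"])
    if len(table) < 5:
        raise ValidationError(f"need >= 5 samples for correlation, have {len(table)}")
    rho, p = stats.spearmanr(table["weighted_metric"], table["ratio"])
    return CorrelationResult(rho=float(rho), p_value=float(p), table=table)


# ---------------------------------------------------------------------------
# Exclusive-spectra overlap
# ---------------------------------------------------------------------------

@dataclass
class ExclusiveOverlap:
    only_a_pct: float
    only_b_pct: float
    both_pct: float
    #: of A-only spectra, fraction where B assigned the same peptide but
    #: above the q threshold (the database-size diagnostic)
    same_peptide_insignificant_fraction: float | None


def exclusive_spectra_overlap(
    psms_a: pd.DataFrame,
    psms_b: pd.DataFrame,
    q_threshold: float = 0.01,
) -> ExclusiveOverlap:
    """Partition the union of significantly identified spectra of two
    searches, plus the same-peptide-but-insignificant diagnostic for A-only
    spectra."""
    sig_a = set(searchlite.significant(psms_a, q_threshold)["spectrum_id"])
    sig_b = set(searchlite.significant(psms_b, q_threshold)["spectrum_id"])
    union = sig_a | sig_b
    if not union:
        return ExclusiveOverlap(0.0, 0.0, 0.0, None)
    only_a = sig_a - sig_b
    only_b = sig_b - sig_a
    pep_a = psms_a.set_index("spectrum_id")["peptide"].to_dict()
    pep_b = psms_b.set_index("spectrum_id")["peptide"].to_dict()
    same = sum(
        1 for sid in only_a if sid in pep_b and pep_b[sid] == pep_a.get(sid)
    )
    frac = same / len(only_a) if only_a else None
    return ExclusiveOverlap(
        only_a_pct=100.0 * len(only_a) / len(union),
        only_b_pct=100.0 * len(only_b) / len(union),
        both_pct=100.0 * len(sig_a & sig_b) / len(union),
        same_peptide_insignificant_fraction=frac,
    )


# ---------------------------------------------------------------------------
# Pipeline harness: strategies -> searches -> classified counts
# ---------------------------------------------------------------------------

def build_strategy_databases(
    study: synthio.Study,
    sample_id: str,
    strategies: Sequence[str] = COMPARED_STRATEGIES,
    cutoff: float = 0.001,
) -> dict[str, ProteinDatabase]:
    """Build the requested database strategies for one sample of a study."""
    core = dbforge.core_set(study.host)
    profiles = study.profiles()
    profile = next(p for p in profiles if p.sample_id == sample_id)
    catalogs = study.catalogs()
    out: dict[str, ProteinDatabase] = {}
    need = set(strategies)
    sm16 = dbforge.build_sample_matched_16s(profile, study.repository, core, cutoff)
    smshot = dbforge.build_shotgun(catalogs, core, pooled=False, sample_id=sample_id)
    if "sample_matched_16s" in need:
        out["sample_matched_16s"] = sm16
    if "pooled_16s" in need:
        out["pooled_16s"] = dbforge.build_pooled_16s(profiles, study.repository, core, cutoff)
    if "reference_16s" in need:
        out["reference_16s"] = dbforge.build_reference_16s(profile, study.repository, core, cutoff=cutoff)
    if "shotgun_sample_matched" in need:
        out["shotgun_sample_matched"] = smshot
    if "shotgun_pooled" in need:
        out["shotgun_pooled"] = dbforge.build_shotgun(catalogs, core, pooled=True)
    if "hybrid_sample_matched" in need:
        out["hybrid_sample_matched"] = dbforge.build_hybrid(sm16, smshot)
    if "global" in need:
        out["global"] = dbforge.build_global(study.repository, core)
    return out


def search_and_classify(
    spectra: Sequence[searchlite.Spectrum],
    db: ProteinDatabase,
    params: searchlite.SearchParams = searchlite.SearchParams(),
    two_step: bool = True,
    index: searchlite.PeptideIndex | None = None,
) -> pd.DataFrame:
    """Run the (optionally two-step) search and classify the resulting PSMs."""
    if two_step:
        psms, subset_db = searchlite.two_step_search(spectra, db, params, step1_index=index)
        cat_db = subset_db
    else:
        psms = searchlite.search(spectra, db, params, index=index)
        cat_db = db
    if psms.empty:
        return psms
    return psmclass.classify_psms(psms, cat_db)


def significant_counts(classified: pd.DataFrame, q_threshold: float = 0.01) -> dict[str, int]:
    """Significant PSM counts per classification label."""
    if classified.empty:
        return {label: 0 for label in psmclass.LABELS}
    sig = classified[(classified["q_value"] < q_threshold) & (~classified["is_decoy"])]
    return psmclass.classification_counts(sig)


def evaluate_study(
    study: synthio.Study,
    strategies: Sequence[str] = COMPARED_STRATEGIES,
    params: searchlite.SearchParams = searchlite.SearchParams(),
    two_step: bool = True,
    keep_psms: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Search every sample against every strategy database.

    Returns the long-format counts table (sample_id, strategy, psm_type,
    count) for human and bacterial PSMs, and — when ``keep_psms`` — the
    classified PSM table per (sample, strategy).
    """
    rows = []
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    pooled_strategies = [s for s in ("pooled_16s", "shotgun_pooled", "global") if s in strategies]
    sample_strategies = [s for s in strategies if s not in pooled_strategies]
    spectra_by_sample = {s.sample_id: study.all_spectra(s.sample_id) for s in study.samples}

    # pooled databases are shared by all samples: search them study-wide, with
    # one subset database built from step-1 hits across every sample
    if pooled_strategies:
        shared_dbs = build_strategy_databases(
            study, study.samples[0].sample_id, pooled_strategies
        )
        for strategy in pooled_strategies:
            db = shared_dbs[strategy]
            if two_step:
                per_sample, subset_db = searchlite.pooled_two_step_search(
                    spectra_by_sample, db, params
                )
                cat_db = subset_db
            else:
                index = searchlite.build_index(db, params)
                per_sample = {
                    sid: searchlite.search(spectra_by_sample[sid], db, params, index=index)
                    for sid in sorted(spectra_by_sample)
                }
                cat_db = db
            for sid, psms in per_sample.items():
                classified = psmclass.classify_psms(psms, cat_db) if not psms.empty else psms
                counts = significant_counts(classified)
                for ptype in PSM_TYPES:
                    rows.append((sid, strategy, ptype, counts.get(ptype, 0)))
                if keep_psms:
                    tables[(sid, strategy)] = classified

    for sample in study.samples:
        if not sample_strategies:
            break
        spectra = spectra_by_sample[sample.sample_id]
        dbs = build_strategy_databases(study, sample.sample_id, sample_strategies)
        for strategy in sample_strategies:
            classified = search_and_classify(spectra, dbs[strategy], params, two_step)
            counts = significant_counts(classified)
            for ptype in PSM_TYPES:
                rows.append((sample.sample_id, strategy, ptype, counts.get(ptype, 0)))
            if keep_psms:
                tables[(sample.sample_id, strategy)] = classified
    counts_df = pd.DataFrame(rows, columns=["sample_id", "strategy", "psm_type", "count"])
    return counts_df, tables


def weighted_metric_by_sample(study: synthio.Study) -> dict[str, float]:
    """Per-sample completeness W from the public repository's peptide counts."""
    counts = proteolysis.unique_tryptic_peptides(study.repository)
    return {
        p.sample_id: proteolysis.weighted_tryptic_metric(p, counts).value
        for p in study.profiles()
    }


# ---------------------------------------------------------------------------
# Strains-versus-species augmentation experiment
# ---------------------------------------------------------------------------

def strains_vs_species_experiment(
    baseline: ProteinDatabase,
    strain_pool: Mapping[str, Sequence[dbforge.ProteinRecord]],
    species_pool: Mapping[str, Sequence[dbforge.ProteinRecord]],
    sizes: Sequence[int],
    spectra: Sequence[searchlite.Spectrum],
    params: searchlite.SearchParams = searchlite.SearchParams(),
    replicates: int = 3,
    seed: int = 0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Fold-change in significant PSMs when augmenting a database with
    random genomes from a redundant strain pool versus a diverse species
    pool (one-step searches).

    Returns one row per (pool, size, replicate) with the augmented database's
    distinct-sequence size and the fold-change in q-significant PSMs relative
    to the baseline search.
    """
    for name, pool in (("strain", strain_pool), ("species", species_pool)):
        if len(pool) < max(sizes):
            raise ValidationError(f"{name} pool has {len(pool)} genomes; need {max(sizes)}")
    base_psms = searchlite.search(spectra, baseline, params)
    base_sig = len(searchlite.significant(base_psms, q_threshold))
    if base_sig == 0:
        raise ValidationError("baseline search found no significant PSMs")
    rows = [("baseline", 0, 0, len({r.sequence for r in baseline.records}),
             float(base_sig), 1.0)]
    for pool_name, pool in (("strain", strain_pool), ("species", species_pool)):
        for size in sizes:
            for rep in range(replicates):
                rep_seed = (seed * 10007 + size * 101 + rep
                            + (0 if pool_name == "strain" else 50021)) % (2**31)
                db = dbforge.build_augmented(baseline, pool, size, rep_seed)
                psms = searchlite.search(spectra, db, params)
                sig = len(searchlite.significant(psms, q_threshold))
                rows.append(
                    (
                        pool_name,
                        size,
                        rep,
                        len({r.sequence for r in db.records}),
                        float(sig),
                        sig / base_sig,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["pool", "size", "replicate", "distinct_sequences",
                 "significant_psms", "fold_change"],
    )


def fold_change_summary(experiment: pd.DataFrame) -> pd.DataFrame:
    """Mean fold-change and standard error per (pool, size) cell."""
    grp = experiment[experiment["pool"] != "baseline"].groupby(["pool", "size"])
    out = grp["fold_change"].agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_fold_change", "sem": "stderr"})


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def report(metrics: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write every metric table as a TSV; deterministic byte-identical output."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(metrics):
        path = outdir / f"{name}.tsv"
        metrics[name].to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
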