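# Methods

This note describes the models behind `metaprotbench`: what the synthetic
study generator emulates and deliberately omits, how the search engine and
its statistics work, the rules used for classification and protein
inference, and the numerical and design choices a maintainer would want
spelled out.

## The synthetic study

A *study* is a species universe plus a set of samples drawn from it. The
generator is a pure function of its `CommunityConfig` (all randomness flows
from `seed` through tagged child generators), so every artifact — FASTA
repositories, abundance TSVs, spectra, ground truth — is byte-reproducible.

**Species universe.** `n_species` (default 14) species, each with 1–3
strains. A strain shares a configurable fraction (default 0.5) of its
proteins identically with the species' base proteome; the rest are variants
with ~8% substituted residues. A `fraction_uncultivated` of species
(default 0.25) has no public genome: their proteins exist in communities but
never in the repository — the situation of prominent but unsequenced taxa in
real host-associated communities. Protein sequences are uniform over the 20
residues with lysine and arginine boosted to 6% each so tryptic peptides
always exist.

**Communities.** Per-sample abundances come from a symmetric Dirichlet with
concentration 0.15: strongly dominated profiles typical of low-diversity
communities, with which species dominate varying by sample. Each sample
hosts one *resident strain* per species, and the expressed proteome is that
strain's distinct sequences. This per-subject strain incidence matters: it
is why pooling shotgun catalogs across samples adds mostly non-matching
variant sequences (decoy diversity, i.e. cost) rather than coverage. The
benchmark fixtures additionally force the uncultivated species to hold 40%
of the community (`min_uncultivated_mass=0.4`), the regime where hybrid
databases have something to win.

**Shotgun catalogs.** A protein enters its sample's translated-ORF catalog
when its *assemblability* — a uniform [0,1) score derived deterministically
from the sequence (CRC32) — falls below `capture ** (1/depth)` with
`depth = min(1, abundance/0.02)`. Assembly therefore saturates above 2%
relative abundance, decays sharply below it, is a property of the protein
rather than a per-sample coin flip (the same hard-to-assemble genes are
missed everywhere), and captures everything when `capture = 1`. A fraction
of captured ORFs (default 0.15) is labelled taxon `Unknown`, emulating
unresolved assembly bins.

**Spectra.** True peptides are fully tryptic (7–25 residues) from expressed,
host, and contaminant proteins, sampled in proportion to species abundance
(host 30%, contaminants 4% of sampling mass by default). A configured
fraction of distinct peptides (default 0.52) occurs in both injection
replicates, the rest split between them. Each spectrum carries the neutral
monoisotopic precursor mass — with occasional isotope-selection error and
0.015 Da gaussian jitter — and the singly charged b/y ladder with per-peak
dropout and spurious uniform peaks. Two deliberate realism features drive
the benchmark's statistics:

* *Quality continuum*: the dropout rate is drawn per spectrum, uniform in
  0.62 ± 0.28, so identification scores form a continuum through the
  significance threshold instead of a well-separated blob.
* *Junk spectra*: 25% of spectra have no peptide source at all (noise,
  modified or unfragmented species). They can only draw random matches, and
  they are what makes a bloated database expensive — their best random hit
  grows with database diversity and inflates the decoy count at the
  threshold.

What the generator does **not** model: fragmentation physics and intensity
patterns, charge states beyond 1+, retention time, modified residues,
protein-level abundance distributions within a species, chimeric spectra.
Passing benchmarks therefore demonstrate the statistical behavior of
database choice under target-decoy FDR control — not instrument-level
realism.

## The search engine

`searchlite` is a deliberately small, fully deterministic stand-in for a
production search tool; what matters for the benchmark is that its scoring
and its target-decoy statistics behave like the real thing.

* **Index.** Semi-tryptic peptide spans (≥1 tryptic terminus or protein
  terminus, ≤2 internal missed cleavages, 6–30 residues) of all targets plus
  reversed decoys, stored as (record, start, end) triples with a mass-sorted
  array — peptides are never materialized until scoring.
* **Candidates.** Precursor window ±0.05 Da, isotope error −1..+2 at
  1.00335 Da spacing.
* **Score.** Raw score = maximum one-to-one matching between theoretical
  b/y masses and observed peaks within ±0.5 Da (two-pointer greedy on sorted
  lists, provably maximal for a fixed window). Spectral probability =
  Poisson survival P(X ≥ raw) with rate
  `n_peaks · 2·tol · n_fragments / 2000 Da` — the SpecEValue analog; smaller
  is better. Ties break by spectral probability, then lexicographic peptide.
* **q-values.** PSMs ranked by raw score (ties by spectral probability,
  then spectrum id); FDR = cumulative decoys over max(1, targets);
  q = reverse running minimum, capped at 1. Decoys keep their q-values for
  audit.
* **Two-step search.** Step 1 records every matched target protein
  regardless of significance; the subset database (matched proteins + core)
  is searched afresh with fresh decoys. For pooled databases the subset is
  the union of step-1 hits across all samples — pooled databases are shared
  artifacts, and their second pass keeps the size handicap that motivates
  sample matching.
* **Determinism.** No randomness anywhere in the engine; decoys are
  reversals, not shuffles.

## Classification and inference rules

Spectra are classified hierarchically: any decoy match → `decoy`; else any
contaminant → `contaminant`; else any host → `human`; else fungal;
else parasite (`trichomonas`); else `bacterial` (unresolved ORFs count as
bacterial). Significance is strict q < 0.01. A peptide is *valid* if a
supporting PSM has spectral probability < 1e-15, or some matched protein
has ≥ 2 distinct significant peptides ("two" read as a minimum evidence
bar, not exactly two). Unique proteins are counted greedily over
sequence-collapsed proteins, visited by descending distinct-peptide support
(ties by id): a protein is counted if, against the current pool, it has >1
distinct peptide, a peptide observed more than once, or a peptide below
1e-15; its peptides then leave the pool, so shared evidence supports at
most one protein. Peptide validity can be evaluated per sample (for
per-sample metrics) or jointly across samples (for unique-protein totals);
both are plain function arguments.

## Benchmark metrics

Relative identification rates divide each sample's significant PSM count by
the mean over the five compared strategies (so rates average to 1 per
sample). Pairwise strategy comparisons use two-sided Wilcoxon signed-rank
tests on paired per-sample counts (exact null for small n via scipy);
functional differential abundance uses Mann-Whitney U on log2 spectral-count
fractions with a half-minimum pseudocount for zeros and a raw P < 0.01
cutoff (a Benjamini-Hochberg switch exists but is off, matching the plain
per-term threshold); completeness correlation uses Spearman's rank
correlation between W = Σ ln(1+G_i)·A_i and the 16S-matched/hybrid
bacterial-PSM ratio. Presumptive false positives are significant bacterial
PSMs whose entire genus set sits below 0.1% abundance; PSMs touching an
`Unknown` ORF are not counted, since their abundance cannot be judged.

## Numerical and design choices

* Proline suppression is on by default in tryptic digestion (standard
  trypsin rule). The completeness metric uses fully tryptic, 0 missed
  cleavages, length > 5; search candidate generation independently allows
  ≤2 missed cleavages and semi-tryptic termini.
* The >0.1% abundance cutoff and the q < 0.01 filter are strict
  inequalities; boundary values are excluded.
* Sequence deduplication (hybrid building, protein counting) uses exact
  string equality — no isoleucine/leucine folding.
* Species with abundance above the cutoff but no public genome are skipped
  with a warning, not an error.
* The 16 contaminant entries carry deterministic synthetic placeholder
  sequences (fixed internal seed) unless real sequences are supplied; their
  identifiers use the pipe-free mnemonic form because the FASTA header
  dialect is pipe-delimited.
* Problem sizes used by the test suite and the acceptance script — 5-sample
  studies of 400 spectra for strategy rankings, single-sample 2,000-spectrum
  fixtures for FDR control, 100-genome pools at sizes 50/100 with 3
  replicate databases for the augmentation experiment, 6-sample
  coverage-gradient studies of 300 spectra for the correlation — were chosen
  as the smallest designs at which the compared effects are statistically
  resolvable over seeds.

## Known limitations

* The scorer's Poisson null is approximate; its spectral probabilities are
  calibrated in rank, not in absolute value, and the 1e-15 validity
  threshold selects roughly the same "very confident" stratum it does for
  real search engines rather than an identical population.
* Strain variation is substitution-only; no gene gain/loss, rearrangement,
  or fragmentary ORFs, so hybrid databases gain slightly cleaner coverage
  than real translated assemblies would provide.
* With a single resident strain per species and sample, within-sample strain
  mixtures are not represented.
* Search runtime is O(candidates) per spectrum in pure Python/numpy;
  adequate for study sizes here (hundreds of proteins, thousands of
  spectra), not for proteome-scale databases.
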