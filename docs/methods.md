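# Methods

## Quantitative model

The unit of quantitation is the peptide. For peptide *p* in replicate
*r*, the peak area A(p, r) is the sum of its monitored transition
areas. Normalization divides each peptide by its own mean over all
observed replicates of both samples:

    x̃(p, r) = A(p, r) / mean_r' A(p, r')

so every peptide contributes on the same scale regardless of
ionization efficiency, and a peptide's normalized sample means satisfy

    mean_GW x̃ = 2ρ/(1+ρ),   mean_MW x̃ = 2/(1+ρ),   ρ = true GW:MW ratio

when the peptide is observed in all replicates. Group (family) and
epitope-category abundances are sums of normalized values over member
peptides per replicate; ratios are ratios of the per-sample means of
those sums. A useful identity follows: any summed ratio over a peptide
set S equals (|S| − W)/W with W = Σ_{p∈S} 1/(1+ρ_p). The net canonical
gluten content sums the five gliadin/glutenin families only (α-, γ-,
ω-gliadin, LMW-GS, HMW-GS); ALP and ATI are reported alongside but are
not canonical gluten.

Differential testing uses a two-sided Welch (unequal-variance) t-test
on log2-transformed normalized values — the log stabilizes
multiplicative technical noise; a raw-scale option remains in the
configuration. Zero within-group variance yields p = NaN with a
`degenerate-variance` flag rather than a fabricated p-value; peptides
observed in only one sample are flagged `one-sided presence` and kept
out of the volcano. No multiple-testing correction gates significance
(the volcano convention is raw p < 0.01 with |log2FC| ≥ 1); BH
q-values are emitted for transparency. Missing cells are excluded
pairwise; nothing is imputed.

## Digestion and mapping

Trypsin cleaves C-terminal to K/R and chymotrypsin C-terminal to
F/W/Y/L, both suppressed before proline; the rule sets are data, not
code, and can be replaced via `DigestionRules`. Candidate enumeration
is fully specific with 0 missed cleavages by default (configurable up
to 2 when matching observed peptides). Candidates are restricted to
6–30 residues, deduplicated preserving first occurrence, and peptides
containing X are dropped because neither mass nor exact matching is
defined for them. Peptide-to-protein mapping is exact substring
search; overlapping occurrences in one protein count once toward the
parent set but every position is recorded, and orphans are flagged,
never silently dropped.

## Assay design

Monoisotopic residue masses come from the standard table (pyteomics);
water 18.010565 Da, proton 1.007276 Da; carbamidomethyl-C
(+57.02146 Da) is a fixed modification because cysteines are alkylated
during sample preparation. Transition QC: a precursor is accepted when
at least `min_transitions` (3) transitions pass intensity > 1,000 cps
(strict), S/N > 5 (strict) and co-elution within `rt_tolerance`
(0.2 min — the co-elution wording in targeted workflows carries no
number, so this default is ours) of the precursor's median observed
RT; the `keep_top` (3) most intense passing transitions are retained,
ties broken by ascending fragment m/z for determinism. Scheduling
packs assays into transition lists by first-fit over ascending RT so
that overlapping 60 s windows never exceed `max_concurrent` =
floor(cycle_time / min_dwell) (0.3 s / 5 ms → 60 by default; both
configurable); a sweep-line validator independently rechecks every
emitted list. Monitored precursor charges default to {2, 3}.

## Grouping

Family assignment uses header-keyword regexes plus sequence motifs as
proxies for the diagnostic Pfam domains (gliadin PF13016, HMW-glutenin
repeat PF03157, cereal trypsin/α-amylase inhibitor PF00234); an
explicit id→family override table reproduces manual curation, and the
synthetic scenario always ships one. A protein firing rules from two
or more families is `mixed`. A peptide inherits its parents' family
when unanimous; parents spanning families — or parents that are
themselves `mixed` — give the peptide label `multiple`, which is
quantified but never attributed to a family.

## Enrichment

Term overrepresentation is the upper-tail hypergeometric probability
P(X ≥ k) with BH adjustment across terms, one-sided by design. Two
selection modes exist because both are defensible entry points:
proteins detected in exactly one sample, or proteins past a fold-change
cutoff (≥ 2-fold by default, boundary inclusive). The background
defaults to all proteins detected in either sample. No GO-graph
propagation is performed; annotations are taken as given. Results are
not expected to reproduce any specific web-service output numerically —
multi-source corrections used by such services differ from BH.

## Synthetic data generator

The generator emulates a two-sample (GW vs MW), four-technical-
replicate targeted experiment on Q/P-rich prolamin-like sequences:

- **Proteins** are concatenations of fully tryptic units (each unit
  ends in K/R, never starts with P, no internal cleavage site), so the
  tryptic digest recovers the designed units exactly. Background
  proteins contribute two tryptic units and, where a unique 6–30
  residue product exists, one chymotryptic product to the monitored
  set.
- **Epitope-bearing peptides** each live in a dedicated carrier
  protein so each one's GW:MW ratio is independently assignable. They
  are synthesized from epitope cores plus random tryptic-clean flanks,
  rejection-sampled so that each peptide maps uniquely and contains no
  epitope of a category it was not designed for.
- **Abundances**: protein MW abundance is log-normal around 10⁶ area
  units (σ = 0.5); each peptide gets a log-normal response factor
  (σ = 0.3) shared between samples so protein ratios carry through;
  replicate areas multiply a log-normal noise factor with coefficient
  of variation `peptide_cv` = 0.15 (technical-replicate noise only —
  the design uses technical replicates, so no biological layer is
  simulated); transition areas split each peptide area 0.5/0.3/0.2.
  At cv = 0 areas equal true means exactly. All randomness derives
  from one seed; regeneration is byte-identical.

### The packaged scenario

The packaged scenario plants the aggregate outcomes this analysis is
designed to detect: net canonical gluten at 67% (GW/MW), coeliac
HLA-DQ epitope peptides at 67%, BA at 180%, WA at 379%, WDEIA at
17.7%, combined allergy total at 153.5%, HMW-GS and ATI up, LMW-GS,
α-, γ-gliadin and ALP down, ω-gliadin flat. Category composition: six
CD 9-mer cores over 25 peptides, 12 BA peptides, 10 WA peptides, one
WDEIA peptide (the ω-5 gliadin epitope QILQQQLIPC inside
QQQQQQQQILQQILQQQLIPCR, kept verbatim).

Planting is exact, not sampled-and-hoped: using the identity
ratio = (n − W)/W above, the per-protein true ratios are solved in
closed form from the realized monitored-peptide counts — single-
category members take their category's ratio directly; the combined
allergy total pins the summed weight of the BA∩WA-shared peptides
(seven of the ten WA peptides also carry a BA epitope; with disjoint
categories the combined total would already be fixed by the counts,
so exact planting *requires* shared peptides); the ω-gliadin
background absorbs its family's flat-ratio constraint around the
low WDEIA peptide; and the LMW-GS baseline absorbs the net-gluten
constraint. The truth manifest stores per-protein and per-peptide
truths and the recomputed aggregates; generation asserts they hit the
targets to 1e-9. A feasibility note: at the mean-normalized estimand,
planting all four allergy aggregates exactly is impossible for
arbitrarily large WA categories — the chosen 12/10/7 composition is
the largest that keeps every solved peptide ratio in a plausible
range (0.18–6.7).

### What passing tests do and do not show

The generator produces complete observations (no missing cells), no
retention-time drift, no interference, and noise that is independent
across peptides and replicates. Recovery of the planted ratios
therefore validates the estimator and the pipeline plumbing, not
robustness to chromatographic pathologies or missingness; the
missing-data paths are exercised by dedicated unit tests instead.
Single- and few-peptide categories inherit real sampling variance: at
cv 0.15 and n = 4 the WDEIA (one-peptide) ratio has a standard
deviation near 1.9 percentage points, so individual runs scatter
around 17.7% accordingly.

## Problem sizes and numerical choices

The packaged scenario uses 66 proteins and ~115 monitored peptides ×
8 replicates × 3 transitions (~2,800 rows), chosen so a full run takes
seconds; all statistics are closed-form or scipy-backed, with no
iterative fitting. Determinism: seeds feed `numpy.random.default_rng`
via `SeedSequence.spawn`; top-k and scheduling ties break on stable
keys; report bodies are reproducible byte-for-byte for identical
inputs and seed.
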