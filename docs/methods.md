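# Methods

`pepmine` re-implements, as a tested library plus analysis drivers, an
in-silico procedure for mining anticancer-peptide (ACP) candidates from
metagenomic reads and optimising a selected candidate by constrained serial
mutation, together with the assay formulas and dose-response fit used to
characterise the peptide. This note records the models, the defaults and
why, the numerical choices, and what the synthetic data do and do not show.

## The screen

**Read QC** (`read_qc`). Reads are end-trimmed at Phred < 15 on both ends,
then truncated at the first sliding window (15 bases) whose mean quality
falls below 15. Trimmed reads are dropped when shorter than 60 bp, when
their sequence entropy is below 50 on a 0–100 scale, when ambiguous bases
exceed 5% of the length, or when the mean quality is below 15. Entropy is
the Shannon entropy of overlapping trinucleotide counts normalised by the
maximum attainable for the read length and scaled ×100 (the PRINSEQ
convention); it is computed post-trimming. Finally, near-identical
pyrosequencing replicates are removed by greedy longest-first clustering:
a read joins a cluster when its ungapped prefix identity to an equal-or-
longer representative is ≥ 98% (matching columns / read length). Ungapped
prefix identity suffices because 454-style replicate artifacts are prefix
copies; this is not a general-purpose clusterer.

**Window enumeration** (`translate_scan`). Each surviving read is translated
in all six frames with the standard genetic code (stops emit `*`, codons
containing `N` emit `X`, trailing partial codons are dropped) and every
substring of 5–50 residues that contains no `*`/`X` becomes a candidate
window, step 1 (exhaustive). Coordinates are 1-based inclusive on the
forward strand with strand implied by the frame sign, and every emitted
window satisfies a re-translation round-trip.

**Features and selection** (`composition_features`). Peptides are encoded
as 420 features: 20 amino-acid frequencies plus 400 overlapping-dipeptide
frequencies (each block sums to 1). Class-contrast features are chosen by a
per-feature Welch t-test (unequal variances — composition variances differ
between classes) with Bonferroni correction at a fixed denominator of 420,
selected at adjusted p < 0.05. The denominator stays 420 even when features
are constant, for reproducibility. The conformity score of a peptide is the
negative SE-standardised L1 distance to the ACP class mean over selected
features (0 is maximal); the associated pre-filter requires *all* selected
features within k·SE of the mean (k = 1 by default, configurable). With 225
training peptides the SE of the mean is ~15× smaller than single-peptide
sampling noise, so this filter rejects essentially every peptide, including
the training ACPs themselves; the pipeline therefore reports the conformity
score for every candidate but leaves the hard pre-filter off by default.

**Classifier** (`acp_classifier`). A linear soft-margin SVM (C = 1) on the
composition features, standardised with training statistics (zero-variance
features dropped); two configurations mirror the screening design — model 1:
ACP vs random peptides; model 2: ACP vs antimicrobial peptides without
anticancer activity. The decision value is the reported ACP/non-ACP score;
threshold 0, ties labelled ACP (the study's scores span 0: −0.98 → 0.28).
A linear kernel fits because composition features are low-dimensional and
near-linearly separable at these effect sizes; no probability calibration —
raw signed decision values are reported.

**Pipeline** (`candidate_pipeline`). QC → scan → score → filter (net charge
> 0 and length ≤ 50; cationicity is the first retention rule because ACPs
target anionic membranes) → collapse identical peptides (keeping all source
coordinates) → optional profile-HMM annotation (advisory only — the study
used the homeodomain hit to *choose* a candidate, not to exclude others) →
rank. Ranking is lexicographic and total: model-2 score desc, net charge
desc, length asc, window id asc. Window scoring is exact but vectorised:
both SVM decision values and window charge are linear in per-position (and
per-adjacent-pair) contributions, so each clean translation segment is
scored with cumulative sums; retained records are re-checked post hoc with
the scalar code paths (top of table plus a stride sample; full equivalence
is unit-tested). The manifest records input digest, seed, and stage counts;
re-running with identical inputs reproduces the table exactly.

## Profile HMMs

`profile_hmm` is self-contained: a HMMER3/f text reader/writer, a profile
builder from a toy alignment, and local Viterbi alignment. The model is a
plan7-style core (M match states, per-node inserts, silent deletes, seven
transition probabilities per node). Alignment is local in both query and
model: free entry at any match state, free exit after any match state,
residues outside the alignment emitted by the background; the score is the
log-odds versus the background in bits. The Viterbi DP is verified exactly
(log space) against exhaustive path enumeration on all small instances.
Reporting threshold 0 bits by default. Forward scores and E-values are out
of scope — the downstream use is presence/absence plus the hit envelope.

Numerical notes: emission/transition rows are validated to sum to 1 after
exponentiation with tolerance 1e-4, accommodating the 5-decimal precision
of real HMMER3 files; our writer emits 10 decimals so a read→write→read
round trip agrees within 1e-9. The background distribution is taken from
the file's `COMPO` line when present, else uniform. Profiles built from
alignments use Laplace-smoothed column counts (columns ≤ 50% gaps become
match states), uniform insert emissions and fixed default transitions
(M→M/M→I/M→D = 0.9/0.05/0.05; I and D splits 0.5/0.5).

## Serial mutation optimisation

`optimizer` formalises "serial modifications outside the HMM alignment
region" as greedy best-improvement hill climbing: each round evaluates the
scorer on every single-residue substitution at every unprotected position
and accepts the best strictly-improving one (ties: lowest position, then
alphabetical residue; strict improvement guarantees termination without a
tabu list). It halts at the stop threshold, when no move improves, or at
the mutation cap (default: number of unprotected positions). The protected
interval — the HMM hit envelope, residues 1–31 on the 37-mer — is never
touched. Charge preservation is available but off by default (the reported
modification happens to preserve charge +4, but it is never stated as a
constraint). The substitution alphabet defaults to all 20 residues. On the
printed 37-mer with a scorer rewarding cysteines at positions 32/33/36,
the greedy search recovers exactly {p.V32C, p.M33C, p.S36C}.

## Physicochemical properties

Net charge = (#K + #R) − (#D + #E), histidine 0 (this rule reproduces the
reported charge +4 on both printed sequences; pH-dependent pKa models are
out of scope). Molecular weight = standard average residue masses + one
water (18.0153 Da; monoisotopic selectable); agrees with Biopython's
ProtParam within rounding of the mass tables. The three scale means use the
conventional table for each property name: Eisenberg consensus
(hydrophobicity), Kyte–Doolittle (hydropathicity/GRAVY), Hopp–Woods
(hydrophilicity); tables ship as versioned JSON data files.

## Assay statistics

Five closed-form calculators implemented exactly as printed: hemocytometer
density (count × DF / chambers × 10,000), doubling time (T·ln2 / ln(Xe/Xb)),
wound closure ((wc0 − wcx)/wc0 × 100, negative = gap widening), hemolysis
((Amax − At)/(Amax − Amin) × 100 with Amax = untreated — the labelling is
inverted relative to common practice; `labels="conventional"` swaps roles),
and CFU/ml (colonies × DF / plated volume).

Dose-response: viability (untreated = 100) is fitted jointly over replicate
wells on log10 dose. The *relative* IC50 and Hill coefficient come from the
plateau-constrained model y = 100/(1 + (x/IC50)^h); the *absolute* IC50 is
where an unconstrained four-parameter logistic crosses y = 50 (flagged
undefined when the fitted curve never brackets 50). The two coincide when
the free plateaus come out at 100/0. Fitting uses `scipy.optimize.curve_fit`
with a seeded multi-start (quantile + jittered initialisations), so the fit
is deterministic given data and seed; parameter standard errors come from
the covariance (delta method for the log-parametrised IC50); R² is
1 − SS_res/SS_tot of the constrained fit. Replicates are fitted jointly,
not averaged, to preserve the error structure.

## Synthetic data: what it emulates, and what passing tests show

`synthetic_data` generates every input. Training classes draw a per-peptide
frequency vector from a Dirichlet centred on the class target (concentration
50, a deliberate middle ground — real ACP composition varies widely) and
then sample residues i.i.d., lengths uniform on 5–50. The ACP target raises
K/L/A/I by +0.05 and lowers D/E by 0.03 versus uniform (cationic,
hydrophobic); the AMP-negative target is cationic but not hydrophobic
(K/R +0.05, G +0.03, D/E −0.03); the random class is uniform.

The metagenome is background reads of i.i.d. uniform nucleotides (the
pipeline needs compositional contrast, not realistic genomes), length
N(110, 10); planted peptides (lengths 20–30 by default, so a plant plus
frame offset fits a typical read) are drawn from the ACP profile
*conditioned on positive net charge* — cationicity defines the class the
screen is built to recover — reverse-translated with uniform synonymous
codons, and embedded at recorded frames/coordinates on either strand.
Per-base Phred means are flat (35) with a linear decay (−10) over the last
10 bases of each end, exercising the end-trimming rules. The default
substitution error rate is 0: the generator emulates a post-QC clean
library, and error injection is an explicit robustness knob. Everything is
bit-reproducible under the config seed.

What passing tests show: the machinery is exact (oracle equivalences,
coordinate round-trips, planted-truth recovery at zero error) and the
statistical components behave as designed (selection power, null error
control, IC50 recovery). What they do not show: performance on real reads
(indel-dominated 454 errors, genomic repeat structure, real ACP training
sets) or that ranking alone isolates true positives — a measured limitation:
at this class effect size a single short peptide's composition carries too
little information for planted ACPs to out-rank the extreme tail of ~10⁶
random windows, so the screen guarantees *recall* (plants always appear in
the candidate table) while final selection, as in the original study,
requires further evidence such as the HMM domain annotation.

## Problem sizes used

Defaults keep every stage at desk scale: 1,000 reads per simulated
metagenome (~1.6M windows, ~17 s per full screen), 225 peptides per
training class, 20-seed batteries for power checks, 100 simulations for
IC50 recovery, and exhaustive oracle batteries over reduced alphabets
(profiles M ≤ 4, peptides ≤ 6 residues).
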