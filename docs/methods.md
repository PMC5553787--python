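# Methods

## Extraction model

PCI/CAG reports are treated as sequences of *vessel sections*. A line is a
section header when it contains a colon and the pre-colon text is non-empty
and at most 40 characters; only the first colon on a line delimits the
header. The 40-character cap keeps prose sentences that happen to contain a
colon from being mistaken for headers — real headers are single terms, not
sentences. A section's body runs from the colon to the start of the next
header line, so multi-line bodies are allowed, and text before the first
header is ignored. Offsets are 0-based half-open character positions so
every extracted value can be displayed in context during adjudication.

Matching is exact-form against the lexicon after normalization
(edge-punctuation strip, whitespace collapse, case-fold). There is no
fuzzy/edit-distance matching: an unknown spelling is handled by registering
it as a variant, which keeps the matcher's behaviour fully auditable. The
dimension pattern accepts `<number>/<number>` followed by `mm` with an
optional space, where numbers may carry one decimal; `mm` must not be
followed by a word character, which rejects `mmHg`.

Stent names and dimension tuples are paired by proximity: names are walked
in textual order and each takes the nearest unused dimension starting after
it, falling back to the nearest unused one before it. This is the minimal
assumption for bodies that list several `name d/l mm` entries in sequence,
and it is exercised directly by the generator (multi-stent sections, balloon
dimension strings trailing the stent lines). A name without a pairable
dimension — or a dimension without a name — produces no record, only a
logged warning: a stent is asserted only when name, diameter and length are
all present. Duplicate identical records in one section are kept (two
same-size stents in one vessel is clinically real). Non-compliant balloon
use is a per-section flag: a word-bounded `HP` token (so `CHPX` does not
match) or any registered balloon brand.

## Validation model

The unit of comparison is the report's *pair set* — its distinct (vessel
category, stent label) assertions. True negatives need a closed universe;
we use, per report, the full cross product of the 4 vessel categories with
the stent labels under comparison (4 class labels by default, brand families
optionally). This minimal closed universe makes specificity and NPV
near-but-not-trivially 1 and makes kappa computable. Kappa is computed over
the pooled (report x slot) binary ratings with the standard two-rater
chance correction; when both raters are constant (p_e = 1) it is flagged
undefined rather than forced.

The three-extractor merge requires unanimity: a pair asserted by one or two
extractors is *disputed* and exported to an adjudication CSV (report,
vessel, label, verdict in {present, absent}, adjudicator, note); the final
collection is the unanimous pairs plus the adjudicated-present ones.
Majority voting is deliberately not used — any mismatch is a prompt for
manual review, which is what makes the merged table trustworthy.

## Warehouse model

The analysis row is the vessel episode: (patient, vessel category, index
date). The index procedure is the first stent-implanting PCI recorded for
that patient-vessel; later stent-bearing reports on the same vessel count as
revascularization evidence, not as new episodes. TVR is a repeat PCI on the
same vessel category within 730 days (2 years at 365 days/year); otherwise
the episode is censored at the earlier of last contact (the latest date seen
anywhere in the patient's tables) and the window. A repeat dated before the
index raises a data-integrity error. Matching is at vessel-category level
(a D1 repeat counts against an LAD index) because the warehouse stores
categories.

Hypertension is ICD-10 I10 on/before the index or any antihypertensive
started on/before it. Diabetes uses a deliberately simplified, swappable
phenotype: a diabetes code (E11) or any antidiabetic prescription — a full
EHR phenotyping algorithm is out of scope. DAPT duration is the count of
post-index days on which aspirin-class and P2Y12-class prescription
intervals overlap (intervals merged per class first); the model covariate
is the >= 365-day flag. Drug-class membership is a configuration file, not
code.

Mixed-category exclusions are comparison-specific: a vessel carrying both
polymer types is excluded from the polymer contrast but is a valid
second-generation episode in the generation contrast; a vessel with two
durable-polymer brands is retained in the polymer contrast but excluded
from the brand-wise contrast. Warehouse assembly is deterministic and
byte-idempotent (fixed column order and float formatting), with a
provenance JSON (row counts, orphan count, input hash) alongside.

## Survival model

All three contrasts use Kaplan-Meier + log-rank and a Cox
proportional-hazards model with the standard covariate set: age, sex,
hypertension, diabetes, total stent length, average stent diameter,
non-compliant balloon use, target vessel indicators (LAD reference), number
of stents, radial approach, emergent PCI, DAPT > 12 months. Estimation is
delegated to lifelines with Efron tie handling (day-resolution times are
heavily tied) and Wald CIs/p-values; p < 0.05 is called significant and no
multiple-testing correction is applied anywhere, as a deliberate
reproduction of the single-institution surveillance design this package
supports. The brand-wise contrast fits one model per brand family with at
least 100 second-generation episodes, the brand indicator against all other
second-generation episodes. Constant adjustment covariates are dropped with
a note; a constant *contrast* indicator is an error. An optional
cluster-robust variance by patient is available because patients contribute
multiple vessels; it is off by default so the vessel-level fit is the
primary analysis. Only the DAPT > 12 months flag (not the continuous
duration) enters the model, matching the covariate set above.

## Synthetic data

The generator defines the study conditions under which the pipeline is
tested. Defaults, chosen once to echo a realistic tertiary-centre PCI
cohort: ~1.5 treated vessels per patient (60/30/10% for 1/2/3); vessel mix
LAD 45%, RCA 25%, LCx 22%, LM 8%; stents per vessel 80/15/5% for 1/2/3;
class mix 5% BMS, 20% first-generation DES, 55% durable-polymer and 20%
biodegradable-polymer second generation (Endeavor 7% within the
durable-polymer family mix); diameters ~N(3.0, 0.4) mm on a 0.25-mm grid,
per-stent lengths ~N(24, 8) mm, so a ~1.25-stent vessel totals ~28 mm; 52%
balloon use, 19% radial access, 15% emergent; age ~N(63, 11.8), 71% male,
46% hypertension, 20% diabetes, DAPT ~N(572, 445) days truncated at the
censoring time (observed DAPT cannot exceed observation).

Events follow an exponential proportional-hazards model,
`lambda = lambda0 * exp(x'beta)` with `lambda0 = 6e-5`/day for the
reference profile (a first-generation DES episode without risk factors),
which yields a 2-year TVR fraction around 5%. The generating log-hazard
ratios default to clinically established magnitudes: second- vs
first-generation HR 0.423, biodegradable- vs durable-polymer 0.568,
hypertension 3.469, diabetes 2.100, DAPT > 12 months 0.389, emergent PCI
3.270, age 0.978/year; BMS gets HR 1.8 vs first-generation DES as a
realistic elevated restenosis risk. Administrative censoring is uniform on
a configurable (low, high) day range, fixed at 730/730 by default. Mixed
class (2%) and mixed brand (10% given an additional stent) vessels are
generated so the exclusion logic has real work to do.

Rendered reports contain exactly the structure the parser assumes — vessel
headers, `name d/l mm` stent lines, balloon tokens — plus controllable
noise: registered lexicon variants (rate 0.3), unregistered typos (0 by
default; corruptions are verified not to resolve in the lexicon), and
mixed-language decoy filler (rate 0.2), including decoy headers like
`Conclusion:`. Decoy bodies never contain a colon or a dimension-shaped
string, so decoys can hide nothing and invent nothing; with typo noise the
parser can only *lose* true pairs (precision stays 1 while recall falls),
and in the variants-only limit extraction round-trips the gold exactly.
Inter-extractor disagreement is simulated as a per-description miss by one
of three extractor variants (rate 0.039), the characteristic failure mode
of an over-narrow pattern, so the disputed fraction of the unanimity merge
tracks the configured rate.

What the generator does not emulate: narrative prose, negation ("stent not
deployed"), stenosis grades/TIMI flow, OCR-style character noise with
registered look-alikes, between-hospital attrition, and non-proportional
hazards. Passing tests therefore demonstrate that the pipeline is correct
for the structural report format and that the statistical stages recover
known effects — not that real-corpus sensitivity would reach any particular
value; on real data the lexicon-revision loop (variant registration driven
by the consensus/adjudication queue) is what carries sensitivity.

## Numerical and testing choices

Problem sizes in the default test run are chosen for desk-scale execution:
200-report corpora for round-trip checks, 800-1,500 patients where
distributional fidelity is asserted, 50 replicates of 3,000 episodes for
Cox parameter recovery (mean fitted HR within 3 Monte-Carlo SEs of truth),
and 1,000 null replicates for the log-rank type-I-error band [0.03, 0.07].
Seeds are fixed in tests and derived from `--seed` via `SeedSequence` in
the acceptance script; fits themselves are deterministic. Hand oracles are
frozen from closed-form product-limit and observed-minus-expected
computations on <= 6-row examples; Cohen's kappa is cross-checked against
scikit-learn's implementation on random ratings.

Known limitations: exact-form matching misses unregistered spellings by
design; the Endeavor family is classified second-generation durable-polymer
(a config switch reclassifies it first-generation, as some registries do);
the TVR window and DAPT threshold use calendar-day conventions (730/365);
and the per-slot pooled construction of kappa is one consistent reading of
pair-list agreement — per-report averaging would weight reports differently.
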