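# Methods

## Data model and ingest

A specimen is a map from canonical amino-acid code
({Glx, Asx, Ala, Ile, Leu, Pro, Val, Gly, Phe, Thr, Met}) to δ¹⁵N (‰ vs.
atmospheric N₂), with optional replicate SDs. Acid hydrolysis folds Gln
into Glu and Asn into Asp, so `Glu`/`Gln` and `Asp`/`Asn` are normalised to
the measured pools `Glx`/`Asx` on ingest; two rows that collide after
aliasing are a duplicate-row error, not a silent overwrite. δ¹⁵N values
outside [−30, +60] ‰ are rejected as implausible for animal tissue.

The canonical file layout is a tidy long table
(`specimen_id, species, tissue, aa, d15n[, sd, n_reps]`), which makes
replicate handling unambiguous; a wide reader is a convenience that melts
to the same layout (and cannot carry replicate SDs). Comma is the default
delimiter, tab is auto-detected. Values are written back at full precision
(`%.15g`), so read → write → read round-trips to 15 significant digits;
rounding happens only in report tables.

Amino-acid classification defaults to seven trophic amino acids
(Glx, Asx, Ala, Ile, Leu, Pro, Val), Phe as the sole source amino acid,
and Gly excluded (it is no longer considered a reliable source amino acid).
Exclusion overrides membership: an excluded amino acid never enters a mean
even if a custom classification lists it as trophic. The multi-amino-acid
equation requires the full set in strict mode (the default); permissive
mode averages whatever subset is present and flags the estimate
`permissive_aa_set`, since a changed averaging set silently changes the
number.

## Trophic-position equations

All four frameworks are ratios of a numerator that is linear in the
measured δ¹⁵N values and the β/TDF parameters to a single denominator TDF
(the `frameworks` module table). Design points:

* Internal arithmetic is full precision; report rounding is half-up, 1
  decimal for TP, 2 for ‰ summaries — matching how the reference tables
  were rounded and avoiding cumulative rounding error. (Python's built-in
  `round` is banker's rounding and reproduces some published cells
  incorrectly.)
* TP < 1 (below primary producers) is physically dubious but reported
  as-is with a `below_one` flag, never clamped — published tables print
  sub-2 values without censoring, and clamping would hide exactly the
  compressed-TDF signal the comparison is about.
* The four parameter sets ship as immutable registry defaults; overrides
  are made with `dataclasses.replace` and recorded in CLI output metadata.
* Equation 2 deliberately reuses β = 3.4 ‰ and TDF = 7.6 ‰; no
  multi-amino-acid-specific β is introduced.
* Group summaries use the sample SD (n−1 denominator); single-member
  groups report SD as missing rather than zero.

The stomach-content comparison value is TP_SC = 1 + Σᵢ pᵢ·TPᵢ over prey
items with proportions summing to 1 (tolerance 1e−9) and prey TPs ≥ 1.

## Uncertainty propagation

First-order Taylor propagation with all inputs independent (no published
covariance structure exists for β and the TDFs). Writing λ for the
denominator TDF and N for the numerator, each additive numerator term
contributes ±1/λ and the denominator contributes −N/λ², giving

Var(TP) = (σ_Δ² + σ_β² [+ σ_extra²]) / λ² + (N σ_λ / λ²)²

where σ_extra is the seal TDF (equation 3) or the plankton TDF (equation
4, whose denominator is the penguin TDF). When only Δ = Glx − Phe is known,
σ_Δ² = σ_Glx² + σ_Phe²; absent replicate SDs fall back to a per-amino-acid
tissue default of 0.5 ‰ (configurable; analytical precision from replicate
GC-IRMS runs is below 1 ‰) and the estimate is flagged
`missing_sd_defaulted`. For the multi-amino-acid equation the SD of a mean
of k independent measurements is √(Σσᵢ²)/k.

A Monte-Carlo propagator with Gaussian marginals is the validation oracle,
never the production path. Denominator draws ≤ 0 are rejected and redrawn
(logged; warned above 1% — at the default 7.6 ± 1.2 ‰ the rate is ~10⁻¹⁰).
For σ on numerator terms only, the map is linear and first order is exact,
so the two agree to Monte-Carlo error; with the default denominator
uncertainty (cv ≈ 0.16) the ratio-distribution correction the first-order
result ignores is O(cv²) ≈ 2.5%, and the tests bound the disagreement at
10% with 10⁶ draws. Second-order terms and full distribution propagation
are out of scope.

## Forward simulator

The simulator walks a food chain forward: each amino acid starts at a
producer value (the scenario's `baseline_phe` plus a per-amino-acid
offset, with the Glx offset equal to β_true) and gains its per-transfer
enrichment at every trophic step, plus Gaussian measurement noise. Default
per-step enrichments are Glx +8.0 ‰ and Phe +0.4 ‰ — difference exactly
7.6 ‰ — so the simulator is the exact forward model the single-TDF
equation inverts, and noiseless simulation at TP t must invert to t to
machine precision (tested). Fractional TPs scale the final transfer's
enrichments linearly, because the estimating equations treat TP as
continuous output, so the forward model must too.

Per-step enrichments for the other amino acids (Asx 6.5, Ala 7.5, Ile 6.0,
Leu 6.5, Pro 8.0, Val 7.5, Gly 4.0 ‰/step) and the producer offsets are
phenomenological placeholders consistent with the observed ordering
(Pro/Val high, Asx low); they do not enter Δ-based estimation and are
overridable per scenario. There is no mechanistic amino-acid metabolism
model — enrichments are constants per step.

Defaults emulate the study conditions: measurement noise 0.5 ‰ per amino
acid (sub-per-mil analytical precision), consumers in the TP 2–5 range,
cohort sizes of tens of specimens. What the simulator does **not** emulate:
baseline spatial/temporal variation within a cohort, tissue-specific
fractionation, diet-quality-driven TDF variation, or correlated
measurement error across amino acids. Passing recovery tests therefore
demonstrates estimator/propagation self-consistency under the assumed
fractionation model, not field accuracy of any TDF choice.

The compressed-Phe scenario raises the Phe enrichment on transfers beyond
the second, shrinking the realized per-step Glx−Phe difference at upper
trophic levels — the forward model of the hypothesis that trophic ¹⁵N
enrichment of Phe is not negligible in high-TP consumers. No quantitative
per-step Phe enrichment is established for cetaceans (reported ranges in
other taxa are ~1–3 ‰), so it is a free parameter rather than a default.

## Study fixture

Per-individual measurements were published only as δ¹⁵N_Glx-Phe, so
`make_study_fixture` reconstructs profiles by anchoring each specimen's
Phe at its species × tissue group mean and setting Glx = Phe + Δ
(documented as synthetic in the docstring). Δ-based estimation is
translation-invariant, so TPs computed from these profiles are exactly
those implied by the published differences; the multi-amino-acid equation
correctly reports them as missing analytes. One published inconsistency is
preserved as printed: the bowhead-skin group mean Δ is quoted as 13.50 ‰
while its ten individual values average 13.59 ‰ — recomputed summaries
follow the individual values.

## Problem sizes and determinism

Monte-Carlo oracle checks use 10⁶ draws (seconds); parameter-recovery
checks use 200 simulated specimens per true TP, which puts the standard
error of the mean recovered TP near 0.007 TP units. Every stochastic
component takes an explicit integer seed (`numpy.random.default_rng`);
identical scenario + seed reproduces bit-identical profiles, and the CLI
records seeds, parameters and a config hash in every output header so a
run is reproducible from its own artifacts.

## Known limitations

* Single-tissue, single-consumer chain: no mixing of diets in the forward
  model (diet mixtures appear only in TP_SC).
* Independence assumptions everywhere; real replicate errors and β/TDF
  estimates may covary.
* The propagated SDs for the study fixture depend on an assumed tissue
  measurement SD (the per-specimen replicate SDs were not published);
  the tests bracket the published ±0.2–0.6 band across the plausible
  0–0.9 ‰ range rather than matching each printed value.
* No threonine-based estimation and no TP-dependent continuous TDF
  regression models.
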