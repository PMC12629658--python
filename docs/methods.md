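# Methods

## Isotope arithmetic

All conversions run through the isotope ratio R = ¹³C/¹²C. Delta notation
is δ¹³C = (R/R_std − 1)·1000 (‰ vs VPDB) and atom percent is
AP = 100·R/(1+R); both maps are strictly monotone and inverted in closed
form, so δ ↔ R ↔ AP round-trip to machine precision. Deltas are carried in
‰ as-is (never pre-divided by 1000) and atom percent on the 0–100 scale.

**VPDB constant.** Two values of the VPDB ¹³C/¹²C ratio circulate in the
compound-specific literature: 0.0112372 (the value attached to the
atom-percent equations in the tracer-accounting lineage this package
follows) and 0.0111802 (common in CSIA methods sections). The default is
0.0112372; `IsotopeConstants(r_standard=...)` selects the other. The two
differ by ~0.5% relative, and since conversion efficiency is a ratio of
atom-percent *excesses*, the choice has a sub-rounding effect on CE.

**Atom percent excess.** APE = AP_labelled − AP_control. Negative APE
(a product pool in a dosed bird measured *less* enriched than the control)
is instrument noise at natural-abundance scale; it is retained by default
with a warning, because silently clamping would bias CE upward. A
`negative_ape="floor"` policy clamps to zero for users who prefer
non-negative pools (the CE normalization Σ = 100 then still holds).

**Methylation correction.** GC-IRMS measures the methyl ester, whose n+1
carbons mix the n acid carbons with one methanol carbon:
δ_FAME = (n·δ_FA + δ_MeOH)/(n+1). The correction inverts this. δ_MeOH is
reagent-batch-specific and has no defensible universal value, so it is a
required configuration input (the synthetic generator uses −40‰, a typical
petrochemical methanol). The correction magnitude decays as 1/n, so for
18–22-carbon PUFA it shifts per-bird total CE by well under one percentage
point — corrected and uncorrected analyses are both supported and give
materially identical conversion efficiencies.

## Pathway accounting

The omega-3 chain is ordered (ALA, EPA, DPA, DHA) and the omega-6 chain
(LA, DGLA, ARA); the precursor is always the first member. Each dosed bird
is accounted along the single pathway its treatment traces. Per fatty acid,
total_label = %FAME × APE, and CE_i = total_label_i / Σ_pathway × 100.
Properties relied on throughout:

- **Normalization**: CE over all members (precursor included) sums to 100
  whenever all pools are non-negative.
- **Scale invariance**: CE is unchanged by rescaling all %FAME in a
  pathway — compositional shares work as well as concentrations, which is
  why body metrics and liver mass never enter the calculation.
- **Control invariance**: a common additive shift of control and labelled
  atom percents cancels.

A bird whose pathway label sum is not positive (e.g. indistinguishable
from the control) has no defined CE and is excluded with a log record.
Missing non-precursor measurements contribute zero label with a warning;
a missing precursor or a missing control baseline is a hard error.
Enrichment outside the dosed pathway (cross-pathway leakage) never enters
the CE denominator. The control reference is normally a single bird per
species, the usual design for these experiments; several controls are
averaged per fatty acid if provided.

## Statistical layer

Total CE is modelled as `total_ce ~ species + pathway` by OLS with
treatment coding against the alphabetically first level, so the reported
contrasts are omega-6 vs omega-3 and second species vs first. Model
selection between the additive and interaction models uses

    AICc = n·ln(2π) + n·ln(RSS/n) + n + 2k + 2k(k+1)/(n−k−1),

with k = p + 1 counting the residual variance — the convention of R's
MuMIn. AICc conventions are not standardized across software; this one is
adopted because it is the one consistent with published small-sample
AICc values in this literature, and it is validated in the tests against
the reconstructed 2×2 design (both model AICc values reproduce to < 0.05).

Because the design is balanced, the OLS fit is a function of cell means
and within-cell sums of squares only. `lm_from_cell_summaries` therefore
constructs *any* raw realization of four printed (mean, SD, n) summaries —
the implementation uses a standardized grid rescaled to the exact mean and
n−1 SD — and fits it; an oracle test confirms equality with `fit_lm` on
independent realizations to 1e-8 on every statistic.

The corrected-vs-uncorrected comparison is a classical paired t-test on
per-bird total CE (df = n_birds − 1), delegated to scipy; degenerate
zero-variance differences return t = 0 (identical vectors) or ±∞ with a
warning.

## Synthetic experiments

The generator emulates the study design end to end: per species one
control bird plus `n_per_group = 3` birds per labelled precursor, all
pathway fatty acids of both chains measured per bird. Isotope mass balance
drives the signal: the absorbed label carbon — `tracer_fraction_scale`
(default 0.01, subsuming dose size and absorption) times the dosed
pathway's total pool — is split across pathway members by the allocation
fractions (the ground-truth CE; defaults are the per-step efficiencies a
two-species swallow/martin study reports, e.g. most omega-3 label in DHA).
Pool sizes are proportional to %FAME (default compositions shaped like
passerine liver profiles, DHA and LA the largest PUFA pools). The tracer
fraction of pool *i* is φ_i = a_i·M/w_i, and its atom percent is the
two-member mix (1−φ_i)·AP_base + φ_i·AP_tracer with AP_tracer = 98
(uniformly labelled precursor oil). Values are converted back to δ and
Gaussian noise is applied on the instrument scales: σ_δ = 0.5‰ (a
documented guess for enriched GC-IRMS peaks) and σ_%FAME = 0.3 points.
Baseline δ¹³C defaults to −30‰, a typical C3 food-web value.

**Exact-recovery identity.** With zero noise and a common baseline,
total_label_i = w_i·φ_i·(AP_tracer − AP_base) ∝ a_i, so the pipeline
returns the allocation fractions exactly; this is the generator's central
validation contract and holds to ~1e-14 in the tests. With per-fatty-acid
baselines the identity is approximate (the per-pool enrichment span
AP_tracer − AP_base_i varies in the fifth significant digit), which is why
the default baseline is common.

**What the generator does not emulate**: pharmacokinetics of the 48-h
window (a single endpoint is drawn), biological between-bird variance in
allocation (noise is purely instrumental by default), cross-pathway
leakage, chromatographic artifacts, or realistic correlation between δ
and %FAME errors. Passing recovery tests therefore demonstrates the
correctness of the accounting chain, not the field accuracy of CE
estimates on real birds.

**Monte-Carlo checks** replicate at the experiment level, not the bird
level: the single control bird's measurement error is shared by every
dosed bird in its group, so across-bird standard errors understate the
uncertainty of a group mean. Unbiasedness is asserted over 40 replicate
experiments; noise-monotonicity of the recovery RMSE over 20 seeds per
noise level. Test problem sizes (≤ 50 birds per group, ≤ 40 replicates)
keep the full suite in the tens of seconds while leaving Monte-Carlo
standard errors well below the asserted effects.

## Data interchange

Long-format UTF-8 CSV, one row per (bird, fatty acid) with columns
bird_id, species, treatment, fatty_acid, delta13c, pct_fame. Validation
rejects duplicate (bird, FA) keys, out-of-range values and per-bird %FAME
sums above 100 (+0.5 rounding slack), naming the offending line. Unknown
species warn but process, so the pipeline applies beyond the two species
it ships configured for; a config-supplied column mapping adapts
spreadsheet exports. Every run logs R_standard, the correction flag and
the negative-APE policy for provenance.

## Known limitations

- Conversion efficiencies are *apparent*: label in a product reflects net
  accumulation at one endpoint, not flux, and turnover or re-export of
  labelled products is invisible to the accounting.
- The summary-based LM reconstruction requires a balanced full 2×2 design;
  unbalanced data must be fit from raw records.
- The AICc convention is inferred, not derivable from first principles;
  fits compared across software should check conventions first.
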