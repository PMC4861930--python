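# Methods

## Model and assumptions

The quantification model is a three-level Gaussian hierarchy on log2
reporter-ion ratios.

**Spectrum level.** For one comparison, the channels of the test and
reference cohorts are collapsed by *summing* intensities (`I_A`, `I_B`)
before the ratio `x_s = log2(I_A/I_B)`. Summing (rather than averaging log
ratios per channel) keeps the counting-noise model coherent: the modelled
variance is

    v_s = k · (1/I_A + 1/I_B),

a Poisson-like law in which low-intensity spectra are noisier. `k` (in
intensity units) absorbs detector gain and is estimated from the data.
Spectra with a zero total on either side are dropped and counted — no
pseudocounts, which would bias low-intensity ratios.

**Peptide and protein levels.** Spectra are combined into peptides by
inverse-variance weighting (`w_s = 1/v_s`); peptides into proteins with
weights `w_p = 1/(1/Σw_s + σP²)`, where σP² is the variance of peptide
ratios about their protein; proteins scatter about the grand mean with
additional variance σQ². The standardization weight is
`Wq = 1/(1/Σw_p + σQ²)` and the final score `Zq = (x_q − x̄)·√Wq`, with
`x̄` the Wq-weighted grand mean of non-excluded proteins. By construction
`Σ Wq·(x_q − x̄) = 0` over included proteins, and under the null
`Zq ~ N(0,1)`.

Assumptions: independent Gaussian noise at each level after the log2
transform; one protein per PSM (protein inference and shared-peptide
handling are upstream); no co-isolation ratio-compression or isotope
impurity correction (out of scope).

## Estimation

**Spectrum scale k.** Within-peptide residuals carry only spectrum noise.
With weights ∝ 1/u (u = 1/I_A + 1/I_B), the residual of spectrum s about
its peptide mean has variance `k·u_s·(1−h_s)`, where `h_s` is the
spectrum's leverage in the weighted mean. We match the median absolute
standardized residual to the standard-normal MAD (0.6745):

    k̂ = ( median |x_s − x_p| / √(u_s (1−h_s)) / 0.6745 )²

over peptides with ≥ 2 spectra (≥ 50 such spectra required; tiny datasets
can pin `k` explicitly). The exact leverage factor is used instead of the
equal-weight approximation m/(m−1) because within-peptide weights are
typically unequal (intensities are roughly lognormal); with the
approximation, k̂ is biased ~10–15% low at realistic intensity spreads.
The median makes the calibration robust to outlier spectra.

**Variance components.** σP² and σQ² solve the method-of-moments equation

    Σ_i (x_i − parent_i)² / (1/W_i + σ²) = N_eff,

whose left side is strictly decreasing in σ², by bracketed Brent root
search (clipped to 0 when no positive root exists; xtol 1e-14). N_eff is
the df-corrected pair count: children − parents for the peptide layer
(singleton children contribute zero residual and zero df, consistently)
and N − 1 for the protein layer about the grand mean. Moment matching was
chosen over maximum likelihood because it is deterministic, fast, and
directly enforces the calibration contract (unit-variance standardized
residuals — it is the same sum that defines Σ Zq²).

**Orchestration.** `run_wspp` composes: ratios → k̂ → peptides → σ̂P²
(parents from σP²=0 protein means) → proteins → σ̂Q² → one outer
re-estimation pass (σ̂P² and σ̂Q² re-derived from the improved protein
means and weights) → standardize. One pass is empirically sufficient for
the calibration invariants (null SD(Zq) = 1.000 ± 0.01) and keeps runtime
bounded and deterministic. All reductions operate on canonically sorted
records (by spectrum id / accession), so results are exactly invariant to
input row order.

**Exclusion lists.** Contaminant accessions (plasma proteins, epidermal
cytokeratins in the motivating tissue context) are excluded *after*
quantification but *before* grand-mean and σQ² estimation and all
downstream analysis; they still receive a Zq for transparency. Including
them demonstrably breaks the normality of the Zq distribution (tested:
the KS goodness-of-fit rejects without exclusion and passes with it).

## Category statistics

**Enrichment** of a DAP set uses the plain hypergeometric upper tail
against the quantified, non-excluded background (not a genome background,
and not the EASE-modified score some annotation servers use — the exact
tail is reproducible and testable by enumeration). Categories with fewer
than `min_category_size` (default 5) background members are skipped.

**Regulation (threshold-free).** `Zc = Σ_{q∈C} Zq / √n_C` over quantified
members, standard normal under the null if members are independent.
Two-sided normal p-values, BH adjustment across all tested categories,
regulated iff q ≤ fdr (default 0.05). The sum is unweighted in Wq: the
statistic tests the members as a set of standardized observations; a
Wq-weighted variant would re-mix measurement precision into the category
level and was not adopted. Proteins belonging to several categories count
in each; the dependence this induces between category tests is handled at
the reporting level by redundancy clustering, not by disjointification.

Known operating characteristics at the default synthetic conditions
(σQ = 0.25, 2000 proteins, 330 categories of which 30 planted, shift
0.8·σQ, 20 members): empirical FDR ≈ 2–4.5% at the 5% operating point;
per-category power ≈ 0.5–0.6. Power is bounded by two structural effects:
the planted proteins themselves inflate σ̂Q (deflating every Zq), and the
BH threshold at ~9% true categories sits near |Zc| ≈ 3. Substantially
higher power at this effect size would require either larger categories,
larger shifts, or a corpus dominated by true categories.

**Cumulative curves.** For chosen categories the member Zq ECDF is
exported together with the theoretical N(0,1) CDF and the whole-proteome
ECDF; a coherent shift appears as a horizontal translation. The core
produces plot-ready tables only, no graphics.

## Redundancy clustering

Similarity between categories is the Jaccard index of their member sets
intersected with the quantified proteome; clustering is average linkage on
distance 1 − J with a configurable cut (default 0.75). Metric, linkage and
cut are explicit configuration, not inferences about any external
pipeline. Category ids are sorted before linkage so merge order — and the
partition — is deterministic and independent of input order, including on
tied distances. The representative of a cluster is the member with the
largest |Zc|, falling back to the largest category, then to the
lexicographically smallest id.

## Synthetic data generator

`wsppq.simulate.generate` emulates an 8-channel experiment with 4 cohorts
× 2 channels (the channel-to-pool layout is configurable; two channels per
cohort is the default because replicate labelling of pools is the common
8-plex design). Per comparison the generator realizes exactly the variance
structure the estimator assumes:

* protein and peptide deviations are drawn per cohort with variance σ²/2,
  so every pairwise cohort contrast has variance σP² resp. σQ²;
* each spectrum draws a lognormal base intensity (log2 location 18, scale
  1.5 — summed cohort intensities ~6·10⁴, putting spectrum-level noise SD
  near 0.1 log2 units at k = 400), splits it across channels, and
  perturbs each channel in log2 space with variance k/I_channel. By the
  delta method the cohort log2 ratio then has variance k·(1/I_A + 1/I_B)
  for any channel balance, and one noise draw per channel keeps the three
  comparisons coherent on shared channels;
* peptide counts per protein are 1 + Poisson(mean−1) (default mean 3),
  spectra per peptide likewise (default mean 2);
* planted DAP shifts and planted category shifts are additive in log2,
  never overlap on the same protein, and planted category directions are
  randomized ± so the planted mass does not displace the grand mean;
* contaminants receive a large common offset (+2 log2 by default) and
  appear on the generated exclusion list.

Defaults k = 400, σP = 0.15, σQ = 0.25 are the reference noise conditions
used throughout the tests; they correspond to a well-behaved 8-plex run
(protein-level biological spread ~19% per cohort, peptide-level ~11%).

What the generator does **not** emulate: missing channels, co-isolation
interference (ratio compression), isotope-impurity bleed-through,
identification errors, shared peptides, or intensity-dependent effect
sizes. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under its own model, not that the model captures
every artifact of real LC-MS data.

## Numerical and degenerate-case choices

* All group reductions run over canonically sorted keys: byte-identical
  reports across reruns and input permutations.
* Root searches: Brent with xtol 1e-14 on a doubling bracket; σ̂² = 0 when
  the moment equation has no positive root.
* Degenerate inputs raise typed errors rather than guessing: identical
  duplicate spectra (k unidentifiable), all proteins excluded, < 30 pairs
  for a variance component, empty comparisons. Tiny fixtures can pin
  k/σP²/σQ² explicitly through `run_wspp` keyword overrides.
* DAP threshold comparison is inclusive (|Zq| ≥ 2).
* Report floats carry 6 significant digits; row order is descending |Zq|
  with lexicographic tie-break.

## Problem sizes in the test suite

Simulation-backed tests use 2000-protein proteomes (≈12,000 spectra) with
10–50 seeds per property, and one 10,000-protein null for tail
calibration; these sizes give standard errors comfortably below the
asserted tolerances while keeping the suite quick to run.
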