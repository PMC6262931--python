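# Methods

## Scope and model structure

`copelink` computes a steady-state, annually integrated carbon and
nitrogen budget for the global metazoan-copepod trophic link in the top
100 m of the ocean, plus the clone-library diet analysis that motivates
it. There is no time stepping, no spatial resolution beyond the
coastal/oceanic split, and no carbonate chemistry or microbial loop:
the budget is a single-box mass-balance ledger per realm scenario.

## Composition profiles

Database records are filtered to depth ≤ 100 m (inclusive — "above
100 m" is read as the 0–100 m layer), mesh size in [100, 116] µm
(inclusive at both ends, matching the printed range), and stages
{adult, copepodite}. Order shares are **abundance-weighted** by
default, since plankton databases report densities; a
record-count-weighted mode is exposed (`weighting="record_count"`)
because the original database reduction does not state which
convention was used. Poecilostomatoids are merged into cyclopoids
(they are carnivores historically placed in that order); harpacticoids
are reported but **not** redistributed, so group shares need not sum
to 1 — this matches the published group stocks, which sum to less than
the adult total.

## Standing stocks

`B_adult = z0 (1 + c) f_cop f_adult` with defaults z0 = 0.31 GtC,
c = 1/3 (200-µm-net undersampling correction), f_cop = 0.8,
f_adult = 0.6, giving 0.1984 GtC. Stocks are carried unrounded through
the pipeline; rounding happens only at the reporting edge.

Two reporting conventions are exposed because the published chain is
internally inconsistent for the oceanic realm: the printed oceanic
cyclopoid stock (0.013 GtC) reflects the merged share (6.3%), while
the printed oceanic annual ingestion (1.79 GtC/yr) back-solves to the
strict share (5.9%). `paper_replication` mode therefore uses strict
oceanic shares and coastal stocks rounded to 2 significant figures
(the printed 2.80 GtC/yr is reproducible only from the rounded 0.12 /
0.078); `best_practice` mode carries unrounded, merged values. The two
modes differ by at most ~1% per scenario. A related rounding quirk:
0.1984 × 6.3% = 0.0124992, which rounds to 0.012 at 2 s.f.; the
published 0.013 follows from rounding through the intermediate 0.0125.

## WSIR estimation

The meta-analysis source table is not bundled (external copyrighted
dataset); the published point estimates are the canonical defaults and
the estimator is validated on synthetic data. How "mean weight … as a
proxy" was originally operationalised is unstated, so both estimators
are exposed:

* `allometric` (default): OLS fit of log10(ingestion) on log10(mass),
  evaluated at the subset's arithmetic mean mass (geometric available
  via `mass_average="geometric"`), divided by that mass. Requires ≥ 3
  records.
* `ratio_mean`: arithmetic mean of per-record ingestion/mass.

They coincide exactly for a unit exponent without noise. The diet
column is carried but not stratified by default (the original pooling
across diets per setting is unstated).

## Annual ingestion

`I = (B_cal · w_cal + B_cyc · w_cyc) · 365`; days fixed at 365 (no
leap handling). Linearity in both stock and rate, and lab ≥ field
monotonicity given lab rates ≥ field rates, are asserted as
properties.

## Flux budget

Copepod carbon closes exactly with the consistent rate triple
AE = 0.7, GGE = 0.3, ingestion = 2.5 × respiration (growth = 0.75 ×
respiration is implied): growth 0.3 I + respiration 0.4 I + egestion
0.3 I = I. An inconsistent triple issues a warning and breaks closure
transparently rather than silently renormalising.

Nitrogen: N_s = I_s / C:N_s per source; NH₄⁺ = 20% and debris/pellets
= 40% of total ingested N; growth N = growth C / 6.86. The N ledger
does **not** force closure — the published fractions plus growth need
not sum to ingested N, so a residual line is reported.

Headline metrics for a link ingestion I_met:

* `pct_of_PP` = 100 · I_met / PP with PP = 45 GtC/yr. The cited
  source figure is a phytoplankton standing stock, but the published
  percentages back-solve to a 45 GtC/yr flux denominator, so it is
  treated as annual PP and flagged in reports.
* `pct_increment_over_unicellular` = 100 · I_met / (8.67 + 2.82).
* `pct_PP_indirect` = 100 · (I_met / (AE·GGE)) / PP: metazoan prey are
  assumed to be single-trophic-level grazers with gross efficiency
  AE·GGE = 0.21, the only convention that reproduces the published
  18.9–29.7% range.

The published "17 to 20.7" regenerated-nutrient figure has unstated
units and baseline; only its ratio is well defined here. Under the
60%-regenerated-N convention the regenerated fraction cancels, so
`nitrogen_regeneration_ratio` returns the ratio of ingested N with and
without the link (1.217 at the high end, matching 20.7/17 within
0.1%).

Export fractions (HTL 8%, remineralization 8%, DOM 3–5% as an interval,
never a point) are applied to copepod production (growth) by default;
the base is a named config choice (`export_base`) because the ecosystem
model they come from does not fully specify it. Sinking is 3% of
egestion. All link-dependent fluxes are intervals [f(low), f(high)];
interval ordering, non-negativity and monotonicity in I_met are tested
properties.

## Gut-content analysis

Pairwise divergence uses end-to-end global alignment (match 1,
mismatch −1, linear gap −2) with divergence = (mismatches + gap
columns) / alignment length; on equal-length indel-free pairs this is
the Hamming fraction. Clustering is greedy centroid in input order
(FASTA order, recorded): a clone joins the first OTU whose *founding*
sequence is < 1% divergent, else founds a new OTU. This guarantees the
within-threshold bound to the representative and is the common
convention for small clone libraries; single linkage is available via
`linkage="single"` but can chain clusters beyond the threshold
diameter. No taxonomic identification, multiple alignment, tree
inference or chimera detection is attempted.

The richness t test defaults to Student equal-variance two-sided
(Welch via `equal_var=False`); the variant is reported alongside the
p-value. Zero-variance groups use the degenerate convention p = 1 for
equal means, p = 0 otherwise. The packaged incidence fixture yields
per-copepod richness 1.86 ± 0.69 under downwelling and 2.0 ± 1.15
under upwelling as parsed; published prose swaps the two condition
labels, so the module reports computed values per condition without
asserting any labelling.

## Synthetic data

The generators define the test conditions; they are deliberately
simple:

* **Abundance**: non-decoy records are drawn inside the filter window
  with orders at the planted fractions and lognormal abundance
  weights; 20% decoys each violate exactly one filter (depth, mesh or
  stage) and are flagged in a `decoy` column for oracle checks.
  Composition recovery is within ±0.01 at n = 10⁵.
* **Ingestion**: masses log-uniform over the range; log10 ingestion =
  planted allometry + Normal(0, σ) noise. Allometric recovery is
  within ±10% at n = 500, σ = 0.1.
* **Clones**: alphabet {A,C,G,T}, substitutions only — divergence is
  Hamming/length, with indel handling delegated to the aligner. OTU
  references differ on disjoint substituted site blocks (pairwise
  divergence ≥ the between-OTU floor by construction); clone variation
  is confined to a shared site pool of size ⌊within·L⌋ disjoint from
  all distinguishing blocks, so any two same-OTU clones diverge by at
  most the within-OTU bound. This makes exact recovery provable for
  any within < threshold, not merely likely. No chimeras, PCR bias or
  quality scores are simulated.

Passing recovery tests therefore shows the estimators are correct
under clean mixtures and clean substitution noise; they do not probe
taxonomic misassignment, database heterogeneity, indel-rich markers or
amplification artefacts in real data.

Each spec carries one integer seed feeding a dedicated
`numpy.random.Generator`; no global random state is used and identical
spec + seed is byte-reproducible.

## Numerical choices

Proportions are validated to 1e-12; stock partitions tolerate 1e-12
slack on the ≤-adult-total invariant; interval bounds tolerate 1e-12
inversion slack. Significant-figure rounding uses round-half-even via
Python's `round`. Problem sizes in the test suite (10⁵ abundance
records, 500 ingestion records × 10 seeds, 20 clone libraries of ≤ 60
clones, 1,000 budget parameterizations) were chosen so the stated
recovery tolerances are comfortably powered while the full suite runs
in seconds.

## Known limitations

* The estimation chain propagates no uncertainty beyond the
  field/laboratory and realm scenario structure; parameters are point
  values (DOM is the only native interval).
* Realm profiles are static inputs; the package does not re-derive
  them from the public databases.
* The WSIR defaults stand in for the external meta-analysis table;
  estimating WSIR from user-supplied records reproduces the defaults
  only insofar as the records resemble that dataset.
* Greedy-centroid OTU assignment is input-order dependent by design;
  reordering a library can change cluster identities at borderline
  divergences.
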