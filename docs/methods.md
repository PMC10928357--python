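# Methods

## Scope and model

The package chains four stages. (1) **Isotope correction**: measured bulk
δ²H_tot is decomposed as δ²H_tot = f_ex·δ²H_ex + (1 − f_ex)·δ²H_n and
inverted for the non-exchangeable δ²H_n. f_ex per material class comes
from two-water comparative equilibration, f_ex = Δδ²H_material /
Δδ²H_water; shipped defaults are muscle 0.0279, chitin 0.0180, algae
0.0210, and δ²H_ex defaults to the equilibration water (−54.42 ‰) — the
decomposition leaves δ²H_ex operationally open, so it is an explicit,
configurable scalar rather than a hidden constant. An optional linear map
onto in-house standards (least squares; exact interpolation with two
standards) runs before the f_ex inversion; with the correction order
unstated in common lab practice, normalize-then-correct was chosen and is
the only order implemented. (2) **Mixing**: water compounding ω_compound =
1 − (1 − ω)^(TL−1); consumer endmembers δ²H_C^100% = ω_c·δ²H_water +
(1 − ω_c)·δ²H_source; terrestrial index as the linear two-endmember
solution. (3) **Community metrics**: CPUE/BPUE per 1000 m, benthic
density per m², Fulton's K (L in cm), pooled ≤ 0.1 % rare-species filter.
(4) **Statistics**: Bray–Curtis, ANOSIM, and a two-sample rank test.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| ω | 0.28 | fraction/step | literature range 0.17–0.30; sensitivity scan provided |
| consumer TL | 2.5 | – | omnivorous cyprinids/percids; overridable per species |
| insect-source TL | 2 | – | terrestrial insects treated as primary consumers |
| δ²H_water | −55.06 | ‰ V-SMOW | regional river-water mean |
| δ²H_ex | −54.42 | ‰ V-SMOW | sample equilibration water |
| replicate-SD gate | 1.1 | ‰ | samples flagged (never dropped) above it |
| rare-species threshold | 0.001 | fraction | pooled over all sites, not per site |
| Ekman grab area | 0.0225 | m² | standard small Ekman; not always reported, so configurable |

## Design choices where the design was open

- **Insect-source water correction.** "Correcting" a measured terrestrial
  insect value for dietary water is ambiguous between applying and
  inverting the water mixture. The default **inverts** (removes the
  insects' own water contribution at TL 2), so the endmember equation then
  re-adds water at the consumer's TL; `source_correction="apply"` gives
  the alternative. Inversion is the self-consistent choice: with it, a
  consumer eating only insects sits exactly at the terrestrial endmember.
- **Endmembers are section-specific** (upstream/downstream sources are
  kept apart); a pooled mode exists for designs without section replication
  of sources.
- **Indices outside [0, 1] are kept raw and flagged** (`clipped`), with a
  truncated companion value; silent truncation would bias group means near
  the endpoints.
- **Rank-test reporting.** The default mode reports the two-group
  Kruskal–Wallis H (tie-corrected, no continuity correction) with p from
  χ²(1); for two groups H = z², which is the scale many field studies
  label "Z" (a fully separated 3-vs-3 comparison gives H = 3.86,
  p = .0495). z-scale and exact-enumeration modes (n ≤ 12) are available;
  both the statistic scale and the exact option are surfaced because the
  "Z" label is ambiguous in the literature.
- **ANOSIM** R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2, on mid-ranked
  dissimilarities. Label arrangements are enumerated completely when their
  number is ≤ 20 000 (covers the 6-site two-section design, 20
  arrangements, and small multi-group designs via a multiset-permutation
  generator); otherwise Monte-Carlo with the observed labeling counted in
  numerator and denominator, so p ≥ 1/(n_perm + 1). Community matrices
  enter raw (no standardization or transformation).
- **Gut counts are species presences**, never read proportions —
  metabarcoding read depth is not quantitative. The aquatic/terrestrial
  classification is data (a user-supplied habitat map), not logic. Fish
  with zero confirmed detections are kept with counts (0, 0) and flagged.

## The synthetic-data generator

The generator emulates a two-section river study with known ground truth:

- **Isotopes.** Seston and insect samples are Gaussian around section
  means (−150 ‰ seston, −90 ‰ insects on the measured scale, SD equal to
  the consumer noise); true endmembers are built from the section means,
  and each fish's δ²H_n is the exact mixture at its group's true
  terrestrial fraction (defaults 0.41/0.68/0.64 upstream and
  0.19/0.13/0.10 downstream for roach/perch/bleak) plus N(0, 3 ‰) noise —
  a single noise term lumping measurement error and individual ecological
  variation, applied on the δ²H scale (the simplest identifiable model).
  Bulk δ²H_tot values are re-composed with the material f_ex so the
  correction stage has real work. Source sample sizes follow the field
  design: 3 seston and 6 insects per section, 30 fish per species ×
  section.
- **Counts.** Site-level expected CPUE and benthic density are gamma
  around the section means with shape k = (mean/SD)² taken from the
  field site-level summaries (CPUE 60 ± 35 vs 158 ± 49 → k ≈ 2.9/10.4;
  benthos 982 ± 1100 vs 5945 ± 2106 → k ≈ 0.8/8.0); observed counts are
  Poisson around the site expectation (marginally negative binomial —
  the printed SDs are strongly overdispersed). Fished lengths are uniform
  in 300–640 m; three grab replicates per site.
- **Gut tables.** Per-fish terrestrial/aquatic species counts are Poisson;
  each detection is duplicated into two technical replicates with an
  independent dropout probability (default 0.2) so the consistency filter
  is exercised. Configured rates are the expected *confirmed* counts; the
  latent ingestion rate is inflated by 1/(1 − dropout)².

Determinism: one global seed; each generator derives an independent child
stream via a stable string-hashed `SeedSequence`, so e.g. the catch table
is identical across configs that differ only in isotope noise.

What the generator does **not** emulate: spatial autocorrelation among
sites, seasonal variation, species-specific endmember differences,
correlated measurement errors within runs, taxonomic mis-assignment in
metabarcoding, and length–weight allometry (biomass per fish is uniform).
Passing tests therefore demonstrate that the estimation chain inverts its
own forward model under realistic noise and effect sizes — not that field
data meet those assumptions.

## Numerical notes and known limitations

- Forward/inverse identities (δ²H_tot round trip, index recovery) hold to
  ≤ 1e−9 and are tested at that tolerance.
- The plug-in terrestrial index is a ratio estimator: with endmembers
  re-estimated from 3–6 source samples per section its group means carry a
  second-order bias of order (source-noise/endmember-separation)² —
  about ±0.002 at the default conditions, negligible against the
  study-level standard error (≈ 0.04) but visible in very large
  Monte-Carlo averages.
- f_ex estimates outside [−0.01, 1.01] raise a data-quality error; values
  within numerical tolerance of [0, 1] are clamped.
- Degenerate inputs fail loudly: equal equilibration waters, coincident
  endmembers, f_ex = 1, zero effort/area, all-zero abundance pairs in
  Bray–Curtis, groups of size < 2 in ANOSIM.
- Exact rank-test enumeration is limited to n₁+n₂ ≤ 12 (C(12,6) = 924
  allocations); larger samples use the chi-square/z approximations.
- Problem sizes in tests and the acceptance script (100–200 replicate
  studies for recovery/power; 500 null datasets × 999 permutations for
  ANOSIM calibration; 40 replicate studies for count moments) were chosen
  to keep Monte-Carlo error well below the tolerances being checked while
  the full suite runs in well under a minute.
- No Bayesian mixing, no carbon/nitrogen isotopes, no lipid correction,
  no depletion estimators, no multiple-testing correction across
  responses: out of scope by design.
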