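# terrsub

Terrestrial-insect subsidy of river fish diets from hydrogen stable
isotopes, with the surrounding community metrics and nonparametric
statistics needed to compare two river sections (e.g. an iron-impacted
reach upstream of a dam against a remediated reach downstream).

The package is aimed at stream and food-web ecologists who have δ²H
measurements of fish muscle, seston and terrestrial insects, plus
electrofishing, benthic-grab and gut-content metabarcoding tables, and who
want a reproducible, testable path from raw measurements to a per-fish
**terrestrial index** (allochthony) and section-level comparisons.

## The model

Tissue δ²H is first corrected for exchangeable hydrogen. With the
material-specific exchangeable fraction f_ex (estimated by two-water
comparative equilibration) and δ²H_ex the composition of the exchangeable
pool,

    δ²H_tot = f_ex · δ²H_ex + (1 − f_ex) · δ²H_n

is inverted for the non-exchangeable value δ²H_n. A consumer's
non-exchangeable hydrogen also carries a contribution from environmental
water that compounds over trophic steps,

    ω_compound = 1 − (1 − ω)^(TL − 1),

so a consumer feeding 100 % on a resource pool with δ²H_source is modeled
as

    δ²H_C^100% = ω_compound · δ²H_water + (1 − ω_compound) · δ²H_source.

Building this endmember once for the aquatic pool (section-mean seston)
and once for the terrestrial pool (section-mean flying insects, themselves
corrected for their own water contribution at TL 2), the terrestrial index
of a measured fish is the linear two-endmember mixing solution

    T = (δ²H_C − δ²H_C^100%aquatic) / (δ²H_C^100%terrestrial − δ²H_C^100%aquatic),

ranging from 0 (fully aquatic) to 1 (fully terrestrial). Defaults: ω =
0.28, consumer TL = 2.5, insect TL = 2, river-water δ²H = −55.06 ‰; all
overridable, with a sensitivity scan over ω × TL built in.

Around the index the package provides CPUE/BPUE (individuals or g per
1000 m of electrofished bank), benthic density (individuals m⁻²), Fulton's
condition factor K = 100·W/L³, a pooled ≤ 0.1 % rare-species filter, gut
metabarcoding incidence processing (two-replicate consistency filter,
exclusions, aquatic/terrestrial presence counts), and self-implemented
Bray–Curtis + ANOSIM and Mann–Whitney-type rank tests in the chi-square
reporting convention common in field papers.

## Worked example

The repository is organised as an analysis project: numbered drivers under
`analysis/` run the pipeline over a seeded synthetic study whose
generating conditions mirror the field setting (three sites per section,
30 fish per species × section, known true terrestrial fractions).

```
python analysis/01_simulate.py
python analysis/02_correct_isotopes.py
python analysis/03_terrestrial_index.py
```

prints, among other things:

```
terrestrial index, mean +/- SD per species x section:
  bleak  downstream 0.09 +/- 0.10 (n=30)
  bleak  upstream   0.63 +/- 0.09 (n=30)
  perch  downstream 0.17 +/- 0.13 (n=30)
  perch  upstream   0.65 +/- 0.11 (n=30)
  roach  downstream 0.20 +/- 0.11 (n=30)
  roach  upstream   0.42 +/- 0.14 (n=30)
```

i.e. the pipeline recovers the configured group means (0.64/0.68/0.41
upstream, 0.10/0.13/0.19 downstream) from noisy forward-generated data:
upstream fish derive roughly half their non-exchangeable hydrogen from
terrestrial insects, downstream fish little. Continuing,

```
python analysis/04_community_metrics.py
python analysis/05_diet_counts.py
python analysis/06_compare_sections.py
python analysis/07_sensitivity.py
```

computes section community metrics, per-fish gut incidence counts, the
upstream/downstream test table (rank tests report the two-group
Kruskal–Wallis statistic, e.g. `stat 3.857, p 0.0495` for a fully
separated 3-vs-3 site comparison; ANOSIM enumerates all 20 label
arrangements at n = 6 sites) and an ω × TL sensitivity scan confirming
the section contrast keeps its sign across ω ∈ [0.17, 0.30].

The same stages are available as a console script for real data
(`terrsub simulate|correct|index|community|diet|compare|all`); input CSV
schemas are documented in the module docstrings.

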