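# isoniche

Bayesian stable-isotope niche analysis for reef fish communities.

`isoniche` quantifies how the trophic niches of a mesopredator community
(here: *Sebastes* rockfish on temperate rocky reefs) differ between
marine protected areas (MPAs) and adjacent fished areas, from per-fish
δ¹³C and δ¹⁵N values. It is written for ecologists who have a nested
field design — replicate sites inside protected and fished areas — and
want posterior evidence for niche expansion rather than point estimates.

## What it computes

- **Species niche widths** as Bayesian standard ellipse areas. Each
  species × area group's (δ¹³C, δ¹⁵N) sample is modelled as bivariate
  normal; exact conjugate normal–inverse-Wishart draws of (μ, Σ) give a
  posterior for SEA = π√(det Σ) and its small-sample-corrected version
  SEAc = SEA·(n−1)/(n−2).
- **Community-wide metrics** per area, evaluated on every posterior draw
  of the species mean vectors: total hull area (TA), nitrogen range
  (NR), carbon range (CR) and mean distance to centroid (CD).
- **Exceedance probabilities** between groups,
  P(a>b) = Σ 1[Xₐ > X_b]/n × 100, the posterior percentage by which one
  area's (or species') niche metric exceeds another's.
- **Diet summaries** from stomach contents: %N, %M, %FO, the index of
  relative importance IRI = (%N+%M)·%FO, and rarefied prey richness.
- **AICc model selection** for δ¹⁵N ~ length × protection status with a
  site random intercept (own exact profiled-likelihood fitter), Akaike
  weights, ΔAICc < 4 model averaging and relative variable importance.
- **A synthetic-data generator** that emulates the full nested design
  (3 areas × 3 sites, 5 species, ~90 fish) under three competing
  hypotheses — carbon expansion, nitrogen expansion, no change — with a
  machine-readable truth manifest for parameter-recovery testing.

See `docs/methods.md` for the models, priors, defaults and limitations.

## Worked example

Generate a synthetic study in which the protected area's community
nitrogen range is 2 ‰ wider (the "nitrogen expansion" hypothesis), then
run the full pipeline:

```python
import isoniche as iso

spec = iso.ScenarioSpec.from_hypothesis("H2", seed=1)
records, manifest = iso.generate_isotope_dataset(spec)
report = iso.run_full_analysis(records, iso.RunConfig(seed=1, n_draws=10_000))
print(report.protected_over_fished()[
    ["metric", "group_a", "group_b", "p_exceed_percent"]].to_string(index=False))
```

```
metric group_a      group_b  p_exceed_percent
    TA     MPA Fished North             83.56
    TA     MPA Fished South             74.22
    NR     MPA Fished North             99.94
    NR     MPA Fished South            100.00
    CR     MPA Fished North             29.39
    CR     MPA Fished South             61.86
    CD     MPA Fished North             99.10
    CD     MPA Fished South             99.48
```

The generated nitrogen-range expansion is detected almost surely
(NR rows ≈ 100%), drags total niche area with it (TA 74–84%), and does
not masquerade as a carbon-range effect (CR ≈ 29–62%, i.e. no clear
direction). Each percentage is the share of 10⁴ paired posterior draws
in which the MPA's metric exceeds the fished area's.

The same run ranks the δ¹⁵N candidate models (ML fits with a site
random intercept; at this effect size the protection main effect, not
the interaction, carries most of the weight):

```
Model                                      K    Log(L)     AICc   dAICc     Wi
Status                                     4   -141.62    291.7    0.00   0.40
Length + Status                            5   -140.81    292.3    0.61   0.29
Length + Status + Length*Status            6   -140.55    294.1    2.39   0.12
Intercept                                  3   -143.93    294.1    2.43   0.12
Length                                     4   -143.32    295.1    3.40   0.07
```

Per-species posteriors are summarised the same way, e.g. quillback
rockfish inside the MPA (n = 6): median SEAc 1.73 ‰², 95% interval
[0.93, 3.87] ‰².

The command line mirrors the library:

```sh
isoniche simulate --scenario H2 --seed 7 --out synthetic/
isoniche fit-niche --isotopes synthetic/isotopes.csv --out draws.csv
isoniche model-select --isotopes synthetic/isotopes.csv
isoniche run --config analysis.yaml    # full pipeline from a config file
```

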