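# mpafit

Growth-curve analysis of long-term fish-monitoring series from marine
protected areas (MPAs).

`mpafit` implements a complete, reproducible pipeline for the question
*"has a protected fish community recovered, and to what level?"*:

1. **Survey ingestion** — underwater visual census (UVC) sightings on
   belt transects, with nine-class abundance coding, 2-cm/5-cm length
   classes and a packaged 62-species Mediterranean reef-fish trait
   table (trophic group, pelagic flag, length-weight coefficients).
2. **Biomass & density estimation** — class-midpoint decoding, W = a·L^b
   length-weight conversion, per-transect density (individuals · 250 m⁻²)
   and biomass (g · 250 m⁻²) for configurable descriptors: total
   community, total without pelagics, each trophic group, and reduced
   group variants.
3. **Yearly series** — global yearly mean ± SE per descriptor and
   variable, with t = years since protection began.
4. **Growth-model fitting** — seven population-growth families (linear,
   exponential, von Bertalanffy, logistic, asymptotic, Gompertz,
   Ricker) fitted by seeded multi-start nonlinear least squares.
5. **Model selection** — AICc (small-sample form), ΔAICc ≤ 2
   equivalence, greatest-R² tie-break.
6. **Carrying capacity** — asymptote K of the selected saturating model
   with time-to-95% recovery, Ricker peaks, and the projection of an
   early exponential trend to the study horizon.
7. **Period analysis** — the pipeline runs per enforcement period
   (whole span, well-enforced early years, post-restoration years) and
   per area (protected / control), producing a deterministic JSON
   bundle and a capacity table.
8. **Synthetic data** — seeded generators for descriptor series and for
   full surveys with known ground truth, so the whole pipeline is
   testable end to end by parameter recovery.

The fitting and selection estimators follow scikit-learn conventions
(`fit`/`predict`, `get_params`, trailing-underscore fitted attributes)
and compose with sklearn tooling; module-level functions wrap them for
scripting. See `docs/methods.md` for models, assumptions and numerical
choices.

## Worked example

Simulate a 19-year survey in which piscivore density follows a logistic
recovery toward K = 40 individuals per 250 m², then recover the
trajectory with the full pipeline:

```python
from mpafit import (
    AnalysisConfig, CommunitySimConfig, GrowthModelSpec,
    capacity_table, run_analysis, simulate_survey,
)

truth = GrowthModelSpec("logistic", {"K": 40, "N0": 4, "r": 0.5})
dataset = simulate_survey(
    CommunitySimConfig(group_trajectories={"PISC": truth}, seed=1)
)
print(f"{len(dataset.records)} sightings on "
      f"{len(dataset.transect_index())} transects")

bundle = run_analysis(
    dataset,
    AnalysisConfig(descriptors=("PISC",), variables=("density",), seed=1),
)
cell = bundle.get("PISC", "density", "whole")
sel = cell.selection
print("selected:", sel.selected.family, f"(rule: {sel.selection_rule_applied})")
print("params:", {k: round(v, 3) for k, v in sel.selected.spec.params.items()})
print(f"capacity: {cell.capacity.value:.2f} ind/250m2 "
      f"(t95 = {cell.capacity.time_to_95pct:.1f} y)")
print()
print(capacity_table(bundle).to_string(index=False))
```

Output:

```text
2563 sightings on 171 transects
selected: logistic (rule: lowest_aicc)
params: {'K': 39.195, 'N0': 3.554, 'r': 0.56}
capacity: 39.19 ind/250m2 (t95 = 9.4 y)

variable descriptor  capacity_whole_period capacity_method capacity_exponential_projection  time_to_95pct selected_family
 density       PISC              39.194815       asymptote                            None       9.373383        logistic
```

The pipeline recovers the generating model family (logistic), its
carrying capacity (39.19 vs the true 40) and a ~9-year time to 95% of
capacity — all from abundance-class-coded, noisy transect records.

## Command line

The same pipeline is scriptable via the `mpafit` CLI:

```console
$ mpafit simulate --group "PISC:logistic:K=40,N0=4,r=0.5" --seed 1 \
      --out sightings.csv --truth-out truth.json
wrote sightings.csv (2563 records)
$ mpafit fit --sightings sightings.csv --descriptor PISC \
      --variable density --seed 1 --out bundle.json
wrote bundle.json (3 cells)
$ mpafit capacity-table --sightings sightings.csv --seed 1 --out table.csv
wrote table.csv
$ head -3 sightings.csv
year,site,transect,species,abundance_class,exact_count,size_class_cm,size_class_width_cm
1996,S01,T1,Dentex dentex,1,,12.0,2.0
1996,S01,T1,Epinephelus costae,1,,14.0,2.0
```

`mpafit fit` accepts real survey CSVs (column names remappable), a
custom trait table, a length-weight table, and a YAML config for
descriptors, periods, abundance-class scheme and fitting options.
`mpafit report` flattens a bundle JSON into a tidy per-cell CSV. An
optional `--lapse start:end:factor` flag simulates an enforcement lapse
(reduced surveillance, increased poaching) that depresses expected
abundances within a year range.

## Repository layout

```
src/mpafit/
  survey.py     UVC records, trait tables, I/O, composition summary
  biomass.py    abundance classes, length-weight, transect measures
  series.py     yearly mean ± SE descriptor series
  models.py     the seven growth families, asymptotes, start values
  fitting.py    multi-start NLS, AICc, selection (sklearn estimators)
  capacity.py   carrying capacity, time-to-fraction, projections
  periods.py    per-period orchestration, bundles, capacity table
  simulate.py   seeded synthetic series and survey generators
  cli.py        `mpafit` command-line interface
  data/         packaged 62-species trait table
docs/methods.md statistical and numerical documentation
scripts/acceptance.py  headline parameter-recovery target
tests/          pytest suite (tests/test_acceptance.py holds the
                acceptance criteria)
```
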