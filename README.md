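# drtriage

Red–green–yellow referral triage for diabetic retinopathy (DR) screening from
single-field 45° posterior-pole fundus photographs, plus the reader-study
statistics used to validate such a triage rule against a gold-standard grader.

The package has five parts:

- **`drtriage.grading`** — the domain vocabulary: the nine-lesion taxonomy,
  ordered referral categories (1-year < 6-month < immediate), the five-level
  severity scale, Snellen visual acuity, and the validated per-eye grading
  form (`EyeGradingForm`, with JSON round-tripping).
- **`drtriage.geometry`** — partitions an image into four anatomical
  quadrants (two crossing lines through the disc center, axes defined by the
  disc–fovea landmarks) and three concentric macular zones at 1 and 2 disc
  diameters from the fovea; aggregates point lesion annotations into a form.
- **`drtriage.triage`** — the decision matrix mapping a form to marked color
  boxes with an audit trail, a severity level, and the final referral. Acuity
  worse than 20/40 escalates a yellow eye to immediate referral; two eyes
  combine by taking the worse referral. The matrix is declarative and can be
  swapped via a JSON config (`--matrix`).
- **`drtriage.stats`** — one-vs-rest confusion tables, Cohen's kappa ± SE
  with agreement bands, sensitivity/specificity with Wilson (or Wald) 95%
  CIs, a single-operating-point binary AUC with a Hanley–McNeil CI, subgroup
  stratification, an AUC-difference z-test, and a noncentral-chi-square
  sample-size calculation. A fixture of published one-vs-rest confusion
  counts (4780 responses) is packaged as CSV.
- **`drtriage.simulate`** — synthetic multi-reader studies (per-reader 3×3
  confusion matrices, missing-response rate, seeded) and fundus annotation
  sets constructed so their expected referral is known by construction.

## CLI

The console script `drtriage` (equivalently `python -m drtriage.cli`) has
four subcommands:

```sh
# triage a grading form (one eye, or {"eyes": [od, os]}) to a referral
drtriage triage form.json [--matrix alternate_matrix.json]

# per-lesion quadrant / macular-zone table from an annotation file
drtriage zones annotations.json [--out zones.csv]

# agreement + diagnostics report from study CSVs or the packaged fixture
drtriage evaluate --gold gold.csv --responses responses.csv --readers readers.csv \
    [--by group|prior_grading|image-block=25] [--ci wilson|wald]
drtriage evaluate --fixture pilot

# simulate a reader study (writes gold/responses/readers CSVs + manifest)
drtriage simulate --readers 99 --images 50 --seed 7 --missing-rate 0.034 \
    --confusion identity --out-dir study/
```

Exit codes: 0 success, 2 validation/input error (JSON diagnostics on
stderr), 64 usage error.

CSV conventions: UTF-8, comma-separated, header row, `NA` for a missing
response; referral tokens are `green` / `yellow` / `red` (case-insensitive).

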