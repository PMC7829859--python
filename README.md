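# hcsquant

Quantification of high-content fluorescence plate screens of innate-immune
activation in adherent cells (primary and immortalized fibroblasts). The
package implements the two standard single-cell readouts of such screens,
the plate-level statistics used to compare donors, and a synthetic-image
simulator with exact ground truth for validating the whole chain.

## The readouts

**NF-κB nuclear translocation.** On stimulation of a pattern-recognition
pathway (LPS/TLR4, poly I:C/TLR3, TNF-α), the transcription factor NF-κB
(p65) moves from the cytoplasm into the nucleus. For every cell the pipeline
segments the nucleus from the DNA counterstain (Hoechst), derives a
perinuclear cytoplasm ring, and computes

    r = mean signal intensity per pixel in the nucleus mask
        ─────────────────────────────────────────────────────
        mean signal intensity per pixel in the cytoplasm mask

A cell with `r > 1.2` is classified **activated**, with `r < 1.0`
**non-activated** (both strict), and otherwise **intermediate**. A well is
summarised as the percent of activated cells in its entire measured
population, aggregated over all acquired fields (47 per well by default).

**GFP-reporter infection.** For a nuclear-localised viral reporter (e.g. an
HSV-1 VP26-GFP capsid fusion), only GFP inside nucleus masks is read; the
percent infected is the number of GFP-positive nuclei over the total
Hoechst-counted population of the well.

**Plate statistics.** Triplicate wells are aggregated to donor-level
mean ± sd, dose–response tables are assembled per donor, donors are split
into low/high responder groups (fixed cutoff or variance-minimising split),
groups are compared with a two-sided Mann–Whitney U test (exact enumeration
for combined n ≤ 12) at α = 0.05, and repeat experiments are compared with a
chi-square test on activated/non-activated counts.

## Worked example

Simulate a two-well plate in which 50% of cells draw their true
nucleus:cytoplasm ratio from the activated component, then score it:

```python
from dataclasses import replace
from hcsquant import SimParams, SegmentationParams, ScoringParams
from hcsquant.validation import score_simulated_well

sim = replace(SimParams(), activated_fraction=0.5, seed=1)
row, truth = score_simulated_well(sim, "B02", n_fields=8)
print(row)
```

prints (machine-exact values depend only on the seed):

```
well                            B02
n_cells_measured               1004
percent_activated         51.195219
true_percent_activated    51.195219
n_cells_true                   1004
```

All 1,004 simulated cells were measurable across the 8 fields, and with the
default well-separated ratio mixture every cell is classified correctly in
this draw, so the measured 51.2% activated coincides with the realized
ground truth (the nominal mixture parameter was 50%; the difference is
binomial sampling). The same pipeline is available from the shell:

```sh
hcsquant run --config config.yaml --outdir out/ --seed 1
```

which writes per-channel TIFFs, a per-cell measurement CSV, per-well percent
summaries and a JSON statistics report (donor means, responder groups,
Mann–Whitney results), all stamped with the config hash.

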