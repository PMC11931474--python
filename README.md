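# syncoloc

Single-synapse colocalization and nearest-neighbor spatial-interaction
analysis for multi-channel punctate immunofluorescence.

## The problem

Glutamatergic synapses appear in super-resolution immunofluorescence as
pairs of diffraction-limited puncta: a presynaptic scaffold marker (e.g.
bassoon) juxtaposed to a postsynaptic one (e.g. homer, PSD-95, SAP102),
~200 nm apart. Questions like *"what fraction of synapses carry this NMDA
receptor subunit, and does it differ between corticothalamic
(VGLUT1-positive) and ascending sensory (VGLUT2-positive) inputs?"* reduce
to three computational steps, all implemented here:

1. **Puncta detection** — ImageJ-style prominence-based maxima (noise
   tolerance = minimum peak-minus-saddle height), marker-seeded watershed
   segmentation, and calibrated size filtering, after a 2-pixel median
   filter.
2. **Synapse pairing and receptor assignment** — a synapse is an
   overlapping pre/post punctum pair (≥ 1 shared pixel, distance measured
   between intensity maxima); synapses are gated by VGLUT overlap of the
   presynaptic punctum; receptor puncta are classified postsynaptic /
   presynaptic by overlap, ties resolved by the shorter maxima distance.
3. **Spatial interaction analysis** — object-based nearest-neighbor (NN)
   statistics under a Gibbs model with a Hernquist pairwise potential

       q(d) = p(d) · exp(−φ(d)) / Z,   φ(d; ε, σ) = −ε · σ / (d + σ),

   where q(d) is the reference channel's NN-distance density toward the
   target channel and p(d) the same density from random field positions
   (the independence baseline). The fitted ε is the *interaction
   strength* (0 = independent, > 0 attraction); significance comes from a
   Monte Carlo randomization test (default 1000 runs, α = 0.05) against
   uniformly redrawn reference coordinates.

Because raw tissue images for this kind of study are rarely deposited, the
package includes a first-class **synthetic-data module**: ground-truthed
fields of paired puncta with configurable densities, pairing offsets,
receptor attachment probabilities and VGLUT terminal geometry, rendered
through a Gaussian-PSF forward model — plus exact Gibbs point-pattern
sampling for validating the interaction fitter. Every pipeline stage is
tested against these ground truths and independent brute-force oracles.

## Worked example

```python
from syncoloc import SynthConfig, AnalysisConfig, run_fov_analysis
from syncoloc.pipeline import default_detection_params
from syncoloc.synthetic import generate_synapse_field, render_field

cfg = SynthConfig(seed=7)                    # 13.8 um FOV, 27 nm pixels
gt = generate_synapse_field(cfg)             # ground-truthed point field
images = render_field(gt)                    # 5 channels: pre, post,
                                             # receptor, vglut1, vglut2
analysis = AnalysisConfig(
    detection={ch: default_detection_params(cfg, ch)
               for ch in ("pre", "post", "receptor")},
    vglut_thresholds={"vglut1": 350.0, "vglut2": 350.0},
    run_interaction=True, interaction_run_mc=True,
    interaction_n_runs=199, seed=7)
result = run_fov_analysis(images, analysis, fov_id="demo")
```

Output (printed from `result.metrics`, `result.histograms`,
`result.fits`):

```
synapse pairs: 47
% presynaptic puncta synaptic: 47.4 (46/97)
% postsynaptic puncta synaptic: 42.5
% synapses VGLUT1 / VGLUT2: 29.8 / 4.3
% synapses with postsynaptic receptor: 44.7
% receptor puncta postsynaptic: 10.1
pre/post maxima distance: median 181 nm (IQR 29)
interaction strength (pre->post): 5.65 (sigma 487 nm), p = 0.0050, reject = True
```

Reading this: 47 of 97 detected presynaptic puncta overlapped a
postsynaptic punctum (the generator paired 42% of them; random overlap
adds the rest); paired maxima sit a median 181 nm apart (the generator
draws true offsets at median 193 nm, and maxima localization is
pixel-quantized); 44.7% of synapses carry a postsynaptic receptor punctum
(51% were attached in truth, minus single-plane detection losses); and the
pre→post interaction strength is large and highly significant — as it
should be on a field where nearly half the reference puncta have a partner
at a fixed sub-resolution offset. Rotating one channel 90° (
`AnalysisConfig(rotate_control="post", ...)`) destroys the pairing and the
test stops rejecting.

Every metric is a `Metric(value, numerator, denominator)`; undefined
ratios (zero denominator) are `None`, never silently 0.

## Command line

```
syncoloc simulate --config sim.yaml --seed 3 --out fov1/      # TIFFs + truth CSVs
syncoloc detect fov1/pre.tif --config analysis.yaml --channel pre --out puncta.csv
syncoloc pair fov1/pre.tif fov1/post.tif --config analysis.yaml --out synapses.csv
syncoloc interact ref.csv target.csv --fov-nm 13824 13824 --out fit.json
syncoloc run --config sim.yaml --seed 5 --out results/          # end-to-end demo
syncoloc aggregate per_fov.csv --out per_mouse.csv              # 3 FOVs -> 1 mouse
syncoloc compare groupA.csv groupB.csv                          # Welch's t-test
```

Exit code 2 flags validation errors (bad config values, missing channels).

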