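# micasa

Multitaper circularly averaged spectral analysis of two-channel
fluorescence tissue images.

Many tools quantify *which* cell types a tissue contains; far fewer
quantify *how they are arranged*. `micasa` measures tissue organization
from two-marker fluorescence images of whole sections (e.g. cortical and
medullary markers of the thymus, or any pair of stains): how strongly
each cell population is structured at every spatial scale, how the two
populations are organized relative to each other, and — critically — how
*consistent* that organization is between replicate sections. The result
is a set of six curves with confidence intervals that turn "it looks
disorganized" into a statistically testable statement, including the
*variance phenotype*: conditions whose mean organization is unchanged
but whose organization has become more variable.

## Method

For a condition of $N$ section images (two marker channels each, pixel
size in µm), each mean-subtracted channel is multiplied by $M$
orthonormal 2D Slepian tapers (outer products of discrete prolate
spheroidal sequences, ranked by concentration; $M = 7$ by default) and
Fourier transformed, giving $NM$ tapered coefficient grids
$J^{(i,m)}(\mathbf{k})$ per channel. From these:

- **log-spectra** $\log |J^{(i,m)}(\mathbf{k})|^2$ per channel — structure of
  one cell population at each spatial frequency;
- **atanh-coherence**
  $\mathrm{atanh}\, C(\mathbf{k})$, with
  $C = |\sum_{i,m} J_a \bar J_b| \,/\, (\sum |J_a|^2 \sum |J_b|^2)^{1/2}$
  pooled over all $NM$ estimates — frequency-resolved association of the
  two populations (a single tapered estimate has $C \equiv 1$, which is
  why multitaper pooling is essential).

Each 2D field is circularly averaged into a function of radial frequency
$f = |\mathbf{k}|$ on a log-spaced grid in cycles/µm; a spectral feature at
$f$ corresponds to cellular structure at the length scale $1/f$ µm.
Delete-one jackknife t-intervals (images as the resampling unit by
default) give confidence bands for the three primary curves, and
chi-square intervals on the across-replicate sample variance give the
three variance curves. Two conditions differ, with at least the
configured confidence, wherever their bands are disjoint — statistics by
eye, or programmatically via `compare_conditions`.

A seeded synthetic-image module (white noise, jittered cell lattices,
anticorrelated compartment patterns) generates ground-truth conditions so
the whole pipeline is testable without tissue data, and a region module
partitions a section into medulla / cortico-medullary junction /
subcapsular / cortex bands and counts marker-positive objects per region.

## Worked example

Compare two synthetic conditions whose compartments differ only in scale
(200 vs 320 µm) — a stand-in for a mutant with enlarged medullary islets:

```python
from micasa import (GeneratorSpec, make_condition, micasa_analyze,
                    compare_conditions)

spec = lambda scale: GeneratorSpec(
    pattern="compartments", shape=(512, 512), pixel_size_um=2.0,
    pattern_params={"compartment_scale_um": scale, "fill_fraction": 0.5,
                    "replicate_variability": 0.0},
)
control = make_condition(9, spec(200.0), base_seed=1, label="control")
mutant  = make_condition(9, spec(320.0), base_seed=2, label="mutant")

result_c = micasa_analyze(control)
result_m = micasa_analyze(mutant)
print(f"N={result_c.N}, M={result_c.M}, NM={result_c.NM}")
print(compare_conditions(result_c, result_m).to_text())
```

prints

```
N=9, M=7, NM=63
Comparison: control vs mutant (CI level 0.99)
  log_spectrum_a:
    337.8-308.0 um (0.0029604-0.003247 cycles/um): control higher
    256.0-58.4 um (0.0039062-0.017138 cycles/um): control higher
  log_spectrum_b:
    337.8-280.8 um (0.0029604-0.0035614 cycles/um): control higher
    256.0-161.3 um (0.0039062-0.0062008 cycles/um): control higher
    147.0-64.0 um (0.0068012-0.015625 cycles/um): control higher
  atanh_coherence:
    194.0-134.1 um (0.0051543-0.0074597 cycles/um): mutant higher
    25.4-23.2 um (0.039373-0.043185 cycles/um): control higher
  var_log_spectrum_a:
    77.0-70.2 um (0.012988-0.014246 cycles/um): mutant higher
  var_log_spectrum_b: no significant bands
  var_atanh_coherence: no significant bands
```

Both channels lose spectral power across the ~60–340 µm band in the
"mutant" (its compartments are larger, so less structure at the control's
scales), and the coherence band at 134–194 µm flags the changed
between-channel organization near the compartment scale — the two
conditions are statistically distinguishable exactly where the generator
made them differ.

The same analysis runs from the shell on directories of TIFF/PNG images:

```bash
micasa simulate --pattern compartments --param compartment_scale_um=200 \
    --shape 512 512 --n-images 9 --seed 1 --out data/control
micasa analyze --dir data/control --mode paired --pixel-size 2.0 --out out/control
micasa compare out/control out/mutant --out report/
```

`micasa analyze` writes one CSV per output curve (frequency, length
scale, estimate, CI bounds), a JSON run manifest and a confidence-band
plot on a log-frequency axis labelled in µm.

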