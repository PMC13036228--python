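# afterimage

A spiking neural-network model of contour-induced color afterimages and
perceptual filling-in, for researchers in visual neuroscience and
neuromorphic engineering.

After staring at a colored figure, an achromatic outline presented in
its place can summon an illusory color — complementary to the inducer
when the outline falls just outside it, the *same* hue when it falls
inside, spreading even into regions never exposed to color.  This
package models that family of percepts with one biologically motivated
mechanism, implemented end to end as a spiking network built on a
minimal Neural Engineering Framework (NEF) substrate:

* single-opponent coding: `(SO_RG, SO_BY, Lum)ᵀ = M (R, G, B)ᵀ`
* double-opponent edge detection: `DO(ch) = SO(ch) ∗ (k_ch L)` with the
  discrete Laplacian `L`
* high-pass synaptic adaptation: `DO_ada = DO ∗ HPF`, τ = 1 s — a
  sustained edge fades and rebounds sign-reversed at offset
* contour-gated amplification:
  `C = max(|DO_Lum| − β·M_SO ∗ 1₃ₓ₃, 0)`,
  `E = sign(DO_ada)·(|DO_ada| + αC)` with α = 10, β = 100
* diffusion filling-in on the retinotopic map:
  `∂I/∂t = c_r ΔI + c_i E`, compiled onto a recurrent spiking
  connection (`c_r` = 2, `c_i` = 0.25, τ_r = 0.01 s)
* percept readout: anchored affine rescaling, inverse opponent
  transform, CIELAB hue/chroma analysis of region means.

Veridical color and every afterimage variant (negative, positive,
constructive, destructive, star-shaped, open-contour) emerge from this
single pipeline; the model's percepts evolve in time, driven only by
the stimulus sequence.  See `docs/methods.md` for the full account.

## Worked example

```python
from afterimage.runner import ExperimentConfig, NetworkConfig, run_experiment
from afterimage.stimuli import StimulusSpec

config = ExperimentConfig(
    StimulusSpec("contour", "I", "green", image_size=24),  # outer test contour
    NetworkConfig(mode="rate"),
)
result = run_experiment(config)
cls = result.classifications[0]
print(f"{cls.label}: hue {cls.hue_deg:.1f} deg, chroma {cls.chroma:.1f}")
```

prints

```
negative: hue 307.4 deg, chroma 17.0
```

— after one second of adaptation to a green square contour
(CIELAB hue 120°), the gray region enclosed by the achromatic test
contour is predicted to appear at hue 307°, i.e. in the pink
direction complementary to the inducer, with clearly visible chroma.
Swapping configuration `"I"` for `"II"` (test contour inside the
adapting contour) yields `positive: hue 130.2 deg, chroma 10.0` — the
same green hue as the inducer.

The same entry point runs star, spiral and alternating-contour
experiments; `result.percept.frames` holds the predicted percept
images, `result.metrics` the CIELAB trajectories per region.

A command-line interface wraps the library:

```
afterimage run --preset contour-I-green --mode rate --out out/
afterimage stimgen --family star --config star_plain --size 50 --out stim/
afterimage check-table1
afterimage battery --mode rate --out battery.csv
```

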