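# mpalesion

Lesion recognition in multispectral photoacoustic (PA) image stacks.

Multispectral PA imaging excites tissue with pulsed light at many wavelengths
and records the resulting ultrasound, yielding one 2-D image per wavelength —
an H × W × Λ stack in which every pixel carries an absorption spectrum.
`mpalesion` implements a complete desk-scale recognition pipeline for such
stacks:

1. **Bilateral denoising** — the classical edge-preserving filter
   `out(p) = Σ_q w(p,q) I(q) / Σ_q w(p,q)` with
   `w = exp(−‖p−q‖²/2σ_s²) · exp(−(I(p)−I(q))²/2σ_r²)`, applied per
   wavelength, plus corner-aligned bilinear resizing that normalises stacks of
   non-uniform acquisition extent to a common grid.
2. **Lesion segmentation** — a lightweight encoder–decoder network:
   downsampling blocks (3×3 stride-2 convolution ‖ 2×2 max-pool,
   channel-concatenated), split-shuffle residual units with factorized
   dilated 3×1/1×3 convolutions, and an attention-pyramid decoder fusing
   3/5/7-kernel stride-2 convolutions into a spatial gate on a 1×1-projected
   encoder map, with a global-average-pooling branch.
3. **Hybrid swarm/colony wavelength selection** — a particle swarm
   (`F' = δF + l₁r₁(O−C) + l₂r₂(P_gbest−C)`, clamped at ±V_max) and an ant
   colony (`P_j ∝ μ_j^α φ_j^β` with evaporation-plus-elitist-deposit
   pheromone updates) run side by side on a cross-validated nearest-centroid
   wrapper fitness; each iteration their champions are recombined into
   **FinalBest**, choosing the colony's best with probability
   `f_best / (f_best + f_gbest)`, and FinalBest is fed back to both
   populations.
4. **Recurrent classification** — each specimen becomes a sequence with one
   time step per selected wavelength (features: masked mean and SD of that
   wavelength's image); an Elman network trained by backpropagation through
   time with learning rate `lr(t) = 0.01·e^(−0.1 t)` assigns cancer/normal
   labels.
5. **Evaluation** — stratified 70:30 splitting, per-class
   precision/recall/F-measure, ROC-AUC, and serialisable reports.

Because no public multispectral PA lesion dataset is available, the package
ships a first-class synthetic phantom generator (elliptical lesions whose
mean absorption spectrum differs between classes, multiplicative speckle and
additive Gaussian noise) and an abstract feature-selection benchmark with
known informative support, so every stage is testable end to end.

Intended users: researchers prototyping spectral feature-selection and
classification methods for multispectral imaging who need a reproducible,
fully seeded reference pipeline.

## Worked example

```python
from mpalesion.pipeline import PipelineConfig, SegmenterSettings, run_pipeline
from mpalesion.synthetic_data import PhantomConfig
from mpalesion.preprocess import BilateralParams
from mpalesion.psaco import PsacoConfig
from mpalesion.classifier import RnnConfig

config = PipelineConfig(
    n_specimens=40, effect_size=3.0, seed=1,
    phantom=PhantomConfig(32, 32, 32, lesion_radius_range=(4, 9)),
    height_range=(20, 32),                    # non-uniform acquisition extent
    bilateral=BilateralParams(1.0, 0.1),
    segmenter=SegmenterSettings(n_steps=150, lr=0.5),
    psaco=PsacoConfig(k=6, n_particles=15, n_iterations=15),
    rnn=RnnConfig(epochs=150),
)
report, outdir = run_pipeline(config, "run1")
print(report.to_frame().to_string(index=False))
print(f"accuracy {report.accuracy:.1f}%  AUC {report.auc:.3f}")
```

prints (exact numbers for this config and seed):

```
       class  precision_pct  recall_pct  f_measure_pct  support
      cancer          100.0       100.0          100.0        6
      normal          100.0       100.0          100.0        6
   macro avg          100.0       100.0          100.0       12
weighted avg          100.0       100.0          100.0       12
accuracy 100.0%  AUC 1.000
```

i.e. on well-separated phantoms (class spectra differ by 3 noise SDs at the
discriminative wavelengths) the pipeline recovers the class signal perfectly
on the 12 held-out specimens; with `effect_size=0` (identical class spectra)
the same pipeline stays at chance, as it must.

The same flow is available from the shell:

```sh
mpalesion generate --n 16 --out data/
mpalesion preprocess --sigma-spatial 2 --sigma-range 0.1 --target-size 64x64 in.tiff out.tiff
mpalesion select-features --features features.csv --k 5 --out sel/
mpalesion run-all --config pipeline.yaml --seed 1 --out run/
```

## Layout

- `src/mpalesion/synthetic_data.py` — phantom and benchmark generators, disk formats
- `src/mpalesion/preprocess.py` — bilateral filter, bilinear resize
- `src/mpalesion/segmentation.py`, `src/mpalesion/nn.py` — segmenter + autodiff
- `src/mpalesion/psaco.py` — hybrid swarm/colony feature selection
- `src/mpalesion/classifier.py` — Elman RNN with BPTT
- `src/mpalesion/evaluation.py` — splits, metrics, reports
- `src/mpalesion/pipeline.py`, `src/mpalesion/cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
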