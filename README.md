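# betadyn

Nonlinear dynamics of beta-band (13–30 Hz) MEG and EMG during steady
isometric contraction.

Sensorimotor beta activity appears as transient bursts of a few cycles
rather than a sustained oscillation — behaviour typical of complex,
possibly nonlinear systems. `betadyn` implements the full analysis chain
needed to ask whether cortical (MEG) and muscular (EMG) beta signals carry
structured nonlinear dynamics, how stable those dynamics are over time, and
whether they are shared across the two modalities:

1. **Preprocessing** — zero-phase FFT-based raised-cosine band-pass
   (13–30 Hz), segmentation into 10 s windows.
2. **Phase-space reconstruction** — delay `τ` from the first minimum of the
   average mutual information, dimension `m` from false nearest neighbours
   (Kennel criteria), delay embedding.
3. **Per-window nonlinear features**
   - largest Lyapunov exponent `λ₁` (Rosenstein nearest-neighbour
     divergence; units 1/s),
   - Higuchi fractal dimension `FD ∈ [1, 2]`,
   - Grassberger–Procaccia correlation dimension `ν` from the scaling of
     the correlation sum `C(r) ∝ r^ν`.
4. **Envelope analysis** — Hilbert amplitude envelope, normalized by its
   0.1 Hz low-passed version; burstiness as the coefficient of variation
   `CV = SD/mean` of the normalized envelope; cross-modal similarity as the
   Pearson correlation of normalized envelopes.
5. **Surrogate validation** — phase-randomized surrogates (amplitude
   spectrum preserved exactly, phases iid uniform) pushed through the
   identical pipeline; per record the original feature is compared with the
   mean over surrogate realizations.
6. **Group statistics** — paired and one-sample t-tests, Cohen's d, exact
   noncentral-t post hoc power, across-subject Pearson correlations, and
   per-subject window-stability summaries.

Because the recordings such analyses target are rarely public, the package
ships a first-class synthetic-data module: canonical systems with known
invariants (Lorenz, Rössler, fractional Brownian motion, linear AR
processes) for validating each estimator against independent oracles, and
paired pseudo-MEG/EMG generators with planted burstiness and a controllable
shared envelope component for end-to-end cohort runs.

Feature estimators follow scikit-learn conventions
(`fit` + trailing-underscore attributes, `get_params`/`set_params`), e.g.
`DelayEmbedding`, `RosensteinLyapunov`, `HiguchiFractalDimension`,
`GrassbergerProcaccia`, `EnvelopeBurstiness`; module-level functions wrap
them for one-shot use.

## Worked example

Simulate a small cohort and run the full study flow:

```sh
betadyn simulate --out demo --n-subjects 3 --seed 21 --duration 60
betadyn run-all --manifest demo/manifest.csv --out demo_out --seed 7
```

or from Python:

```python
from betadyn import RunConfig, make_demo_cohort, run_study

manifest = make_demo_cohort("demo", n_subjects=3, seed=21, duration=60.0)
result = run_study(manifest, RunConfig(master_seed=7, n_surrogates=2), "demo_out")
print(result["stats"]["meg_vs_emg"]["LE"])
```

which prints (values recomputed deterministically from the seed):

```
{'comparison': 'LE MEG vs EMG', 't': 0.6434345118946504, 'df': 2,
 'p': 0.5858716123315799, 'd': 0.3714870886482718,
 'power': 0.0689815485827543, 'n': 3,
 'meg_mean': 17.958640812384843, 'meg_sd': 3.3159532506651774,
 'emg_mean': 17.0229452867274, 'emg_sd': 3.07293913382437}
```

i.e. on this tiny demo cohort the per-subject mean Lyapunov exponents of the
two modalities (≈17–18 1/s on 1 kHz beta-band data) do not differ reliably
(`p = 0.59`), and the post hoc power for the observed effect size is low —
exactly the kind of readout the statistics layer produces for each feature.
`demo_out/` additionally contains the tidy per-window feature table
(`features.tsv`), burstiness and envelope-correlation tables, the
original-vs-surrogate table, and `stats.json` with every group test.

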