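# hrfdeconv

Hemodynamic response estimation and neural-activity deconvolution for
functional near-infrared spectroscopy (fNIRS), with a searchable, shareable
spatial store of HRF estimates.

## The problem

An fNIRS channel records slow hemoglobin concentration changes (HbO/HbR) that
are a *blurred* readout of neural events: the observed signal is the latent
neural activity convolved with a hemodynamic response function (HRF) that
peaks seconds after the triggering event. Most pipelines assume one canonical
adult HRF for everyone, which is a poor fit for young children and other
populations whose responses are delayed or blunted. `hrfdeconv` instead
*estimates* the HRF per channel from event-related recordings, pools it
across a subject cohort, and then inverts the convolution a second time to
replace hemoglobin with an estimate of the underlying neural activity.

## The model

Writing convolution as a Toeplitz design matrix **H** whose columns are
shifted copies of a known driver, both inversions solve the Tikhonov
(ridge) regularized least-squares problem

```
x̂ = (HᵀH + λLᵀL)⁻¹ Hᵀ y
```

* **HRF estimation** — the driver is the event impulse train, `x` is the HRF
  kernel. The signal is z-scored, the kernel window is expanded by 25% per
  side before the solve and trimmed after (suppressing the classic Toeplitz
  edge artifact), and an implicit intercept absorbs the baseline offset.
  Per-subject kernels are pooled with a per-sample trimmed mean (10% per
  tail) and their spread is retained.
* **Activity estimation** — the driver is a peak-scaled HRF
  (`max |h| = 1`, with ε = 1e-7 in the denominator), **H** is the full
  n × n convolution matrix, and `x` is the neural activity over the whole
  scan in arbitrary units.

λ defaults to 1.0 (identity **L**); channels whose regularized normal matrix
is ill-conditioned, or whose solve exceeds a time limit, are dropped rather
than returned as noise.

Estimates live in an `HRStore`: a k-d tree over 3-D optode coordinates
(nearest-neighbour search within a 1 mm default radius, spherical ROI
search), crossed with a SHA3-256 / quadratic-probing hash table over
experimental context ("task-flanker", age ranges binned centre-out, …) so a
context-filtered sub-tree can be pulled out at a 95% weighted-similarity
threshold. A canonical double-gamma HRF pinned at (359, 359, 359) is the
universal fallback. Stores serialize to a deterministic JSON format keyed by
`doi|channel` and merge across montages.

## Worked example

```python
import hrfdeconv as hd
from scipy.stats import pearsonr

# a simulated cohort: 5 subjects, 30 s HRF at 10 Hz, 20 events (ISI >= 25 s),
# cardiac/respiratory/Mayer noise scaled to a PSD-band SNR of 5
spec = hd.SimulationSpec(n_subjects=5, seed=1)
model, truth = hd.HRFDeconvolution.from_simulation(spec)
res = model.fit()
print(res.summary())
print("recovery r:", round(pearsonr(res.params, truth.kernel)[0], 3))
```

```
HRF deconvolution results
=========================================
subjects fit                            5
subjects dropped                        0
kernel duration (s)                  30.0
sampling rate (Hz)                  10.00
trim proportion / tail               0.10
lambda                                  1
peak time (s)                        5.00
peak amplitude (a.u.)              2.1190
mean subject spread (a.u.)         0.1059
=========================================
recovery r: 0.982
```

The pooled kernel peaks at 5.0 s — the double-gamma ground truth peaks at
5.0 s — and correlates with the truth at r = 0.982 despite the worst
acceptable signal quality (SNR 5 is the exclusion boundary). `res.plot()`
shows the subject traces, the trimmed mean and the ±1 SD band;
`res.to_estimate()` yields a peak-scaled kernel ready for
`hd.NeuralActivityModel(recording, hrf).fit()`, whose `summary()` reports the
kurtosis increase that indicates successful temporal de-blurring.

The same workflow is available from the shell:

```bash
hrfdeconv simulate --n-subjects 5 --seed 1 -o sim/
hrfdeconv estimate-hrf sim/sub00*_signals.tsv --montage sim/sub000_montage.tsv \
    --events sim/sub000_events.tsv --events sim/sub001_events.tsv ... \
    --context task=sim -o hrfs.json
hrfdeconv estimate-activity sim/sub000_signals.tsv --montage sim/sub000_montage.tsv \
    --store hrfs.json -o activity
hrfdeconv store search hrfs.json --x 0 --y 0 --z 0 --max-dist 1.0
hrfdeconv qc sim/sub000_signals.tsv --montage sim/sub000_montage.tsv
```

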