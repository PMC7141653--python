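# rhythmkit

Rhythm and periodicity analysis of animal acoustic signals — bat isolation
calls, whale click trains, bird song, drumming — from nothing but the onset
times of their elements.

Researchers in bioacoustics, biomusicology and vocal-learning studies keep
asking the same two questions of a sequence of syllables, calls or clicks:
*is it periodic*, and if so, *what beat frequency describes it best and how
well?* rhythmkit implements five complementary answers behind one interface,
plus the plumbing to compare them, because every single method has a regime
where it misleads.

## Methods

All analyses start from inter-onset intervals (IOIs), the time from one
element's onset to the next, or equivalently from the onset times themselves.

* **IOI statistics** — mean IOI (its reciprocal is the "exact beat
  frequency" in Hz), the coefficient of variation CV = s/x̄ and its
  small-sample unbiased form CV\* = (1 + 1/(4n))·CV. The gap between the
  pooled CV\* and the mean per-sequence CV\* indicates variation between
  sequences (and possibly individuals).
* **nPVI** — the normalized Pairwise Variability Index,
  nPVI = 100/(m−1) · Σ |IOIₖ−IOIₖ₊₁| / ((IOIₖ+IOIₖ₊₁)/2): zero for perfect
  isochrony, large for alternating or random interval patterns.
* **Fourier beat detection** — onsets are rasterized onto a 0/1 grid
  (default dt = 5 ms → a 0–100 Hz analysis band), transformed with the 1/N
  DFT convention, and the largest non-DC magnitude in the band is the best
  beat. For a 0/1 raster the DC amplitude P₀ = X(0) equals the event fraction
  and bounds every other amplitude, giving an internal reference:
  GOF = |P_best|/|P₀| and the length-normalized nGOF = GOF/L (L the number of
  samples by default).
* **Generate-and-test (GAT)** — every candidate frequency on a 2–100 Hz grid
  (0.01 Hz steps) defines an isochronous beat grid anchored at the first
  onset; the RMS deviation of onsets from their nearest beats, expressed as
  a fraction of the cycle (FRMSD = RMSD·f), scores the candidate. Minimizing
  FRMSD finds the slowest beat that coincides with the onsets.
* **Recurrence matrices** — M[i,j] = |IOIᵢ−IOIⱼ| rendered white-to-dark, for
  visual detection of higher-order structure (blocks, alternations, nested
  tempi) that scalar indices hide.

On top of these: UPGMA clustering of per-sequence beats within individuals
(largest-cluster share = how concentrated an individual's tempo is),
synthetic data generators (isochronous, uniform-aperiodic, Gaussian,
jittered combs, and stand-ins emulating published study datasets), and a
decision cascade that recommends which beat method suits a dataset based on
its IOI distribution, nPVI, CV gap and sequence durations.

## Worked example

Generate five noisy-periodic sequences (Gaussian IOIs, mean 0.2 s ⇒ a 5 Hz
beat) and run the full pipeline:

```sh
rhythmkit synth --kind gaussian --mean 0.2 --sd 0.02 --nseq 5 --nel 20 \
    --seed 42 --out calls.csv
rhythmkit run --in calls.csv --out report
```

```
periodic: yes; isochronous: yes
recommended methods: IOI, FFT
report written to report
```

`report/summary.csv` holds the dataset-level IOI statistics:

```
mean_ioi_s  cv_overall  cv_sequence_mean  npvi_mean  n_iois  n_sequences
0.1998      0.0762      0.0772            8.20       95      5
```

A mean IOI of 0.1998 s recovers the generating tempo (1/0.2 s = 5 Hz); the
CV\* of ~0.08 and mean nPVI of 8.2 (< 15) mark the data as strictly
isochronous. `report/beats.csv` gives the per-sequence beats, e.g. for the
first sequence:

```
ioi_beat_hz  fft_beat_hz  fft_gof  fft_ngof   gat_beat_hz  gat_frmsd
5.016        5.007        0.775    1.02e-03   5.05         0.118
```

All three methods agree near 5 Hz; the FFT's best beat carries 77% of the
internal reference amplitude (GOF 0.775), and the GAT deviation is ~12% of a
cycle. `report/recommendation.json` records the full rule trail and every
threshold used, so the verdict is reproducible and comparable across
studies.

The same analyses are callable as a library:

```python
import rhythmkit as rk

seq = rk.gen_jittered_comb(0.1, 0.1, 21, seed=7)   # ~10 Hz comb, ±10% jitter
spec = rk.fft_best_beat(rk.binarize_onsets(seq.onsets))
gat = rk.gat_search(seq.onsets)
print(spec.best_frequency, spec.ngof, gat.best_frequency, gat.best_frmsd)
```

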