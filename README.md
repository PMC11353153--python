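# fluopipe

Co-analysis of two-photon calcium imaging and electrophysiology, with an
emphasis on the frequency domain: from two-channel fluorescence movies and
an aligned field-potential recording to validated, classified cells
(neuron vs astrocyte), ΔF/F₀ traces, complex-Morlet wavelet spectra, and
network-synchrony matrices — as a scriptable library plus a thin CLI, with
batch processing and HTML report generation.

## Who it is for

Labs imaging calcium dynamics in neurons *and* astrocytes at sampling
rates high enough (tens of Hz, frame or line scan) that oscillatory
structure in the physiological bands — delta (0.5–4 Hz), theta (4–8 Hz),
alpha (8–13 Hz), beta (13–30 Hz) — is resolvable, and who record local
field potentials alongside. Most imaging toolchains stop at event
detection; this one decomposes both modalities on a common
time–frequency grid so single-cell calcium oscillations can be related to
network-level electrical activity.

## What it computes

* **ΔF/F₀** = (F − F₀)/F₀ on the background-corrected green (calcium)
  channel, F₀ averaged over a control range; **ΔG/R** =
  (G[t] − G[0])/R[t] as the movement-robust alternative.
* **Cell classification**: ROIs validated by area (> 100 px),
  eccentricity (< 0.85) and contrast (≥ 2× vicinity), then split on the
  red/green intensity ratio (SR-101-bright astrocytes vs neurons), with
  manual override and annotation round-trip.
* **Spectra**: continuous wavelet transform with the analytic Morlet
  wavelet (ω₀ = 6), log-spaced grid, amplitude-calibrated magnitudes, and
  per-band power summaries for every cell and the field potential.
* **Synchrony**: phase-locking values PLV = |⟨e^{i(φₐ−φᵦ)}⟩| per cell pair
  in a chosen band (phases from a zero-phase band-pass + analytic signal),
  and sliding-window cross-correlation with per-window maximum correlation
  and lag.
* **Electrophysiology alignment**: marker-based segment extraction and
  anti-aliased 10× decimation.

A synthetic-data generator plants disk-shaped somata, per-cell
oscillations, red co-labelling and an LFP sharing a slow-envelope network
source with chosen cells, so the entire pipeline is testable against
known ground truth. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

```python
import numpy as np
import fluopipe as fp

# generate a synthetic session: 10 cells, 3 coupled to a 3 Hz network source
session, truth = fp.make_movie(n_cells=10, shape=(128, 128), radius=6.5,
                               duration_s=30.0, fs=68.0, cell_freqs=8.0,
                               coupled=(0, 1, 2), network_freq=3.0, seed=1)
ephys = fp.load_ephys(fp.make_ephys(truth, fs_native=1250.0), session,
                      marker="imaging")

# detect and classify cells
ref_g = fp.make_reference(session, method="average", channel="green")
ref_r = fp.make_reference(session, method="average", channel="red")
rois = fp.extract_rois(fp.threshold_reference(ref_g), min_area=30)
fp.classify_cells(session, rois, ref_g, ref_r)
n_astro = sum(l.value == "astrocyte" for l in rois.labels.values())
print(f"{len(rois)} ROIs detected; {n_astro} astrocytes, "
      f"{len(rois) - n_astro} neurons")

# dF/F0 traces and delta-band wavelet power
traces = fp.compute_dff(fp.compute_F(session, rois), session, rois,
                        background="auto")
spectra = fp.analyze_session(traces, ephys)
delta_e = np.interp(spectra.cell_times, spectra.ephys_times,
                    spectra.ephys_band_power[0])
for j, rid in enumerate(traces.roi_ids[:4]):
    r = float(np.corrcoef(spectra.cell_band_power[j, 0], delta_e)[0, 1])
    print(f"cell {rid}: delta-power correlation with LFP r = {r:+.2f}")

# phase locking in the delta band
plv = fp.plv_matrix(traces, fp.DEFAULT_BANDS[0])
print(f"mean off-diagonal PLV = "
      f"{plv.values[np.triu_indices(len(rois), 1)].mean():.2f}")
```

Output:

```
10 ROIs detected; 3 astrocytes, 7 neurons
cell 1: delta-power correlation with LFP r = +0.12
cell 2: delta-power correlation with LFP r = +0.98
cell 3: delta-power correlation with LFP r = -0.06
cell 4: delta-power correlation with LFP r = +0.99
mean off-diagonal PLV = 0.15
```

All 10 planted cells are recovered and the red/green split matches the
planted labels. Cells 2 and 4 are two of the three coupled to the 3 Hz
network source: their delta-band power tracks the LFP's delta power at
r ≈ 0.98, while uncoupled cells (1, 3) sit near zero. The low mean PLV
reflects that most pairs here oscillate independently.

The same pipeline runs from the shell:

```
fluopipe synth --cells 20 --fs 68 --duration 30 --seed 1 --out fixture/
fluopipe load --image fixture/movie.tif --ephys fixture/ephys.txt \
    --channels 2 --dt 0.0147 --marker imaging --out session.h5
fluopipe rois session.h5 --method average --min-area 30
fluopipe classify session.h5
fluopipe traces session.h5 --background auto
fluopipe report session.h5 --cells --network --out reports/
fluopipe batch ./results/ --apply band_summary
```

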