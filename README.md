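# roipulse

Facial region-of-interest (ROI) evaluation for remote photoplethysmography
(rPPG) heart-rate measurement.

Remote photoplethysmography estimates the cardiac pulse from the subtle
skin-color fluctuations visible in ordinary face video. Which patch of skin
the pixels are averaged over matters a great deal: forehead and cheeks are
the traditional choices, but a systematic comparison requires a fixed,
reproducible region scheme and a common scoring pipeline. `roipulse`
implements that pipeline end to end:

- **28 anatomically named facial ROIs**, each defined as an ordered polygon
  over the 468-point face-mesh keypoint convention (glabella, medial
  forehead, malars, nasal dorsum, ...), with pixel-center even-odd polygon
  rasterization and mean-RGB trace extraction;
- **four classical rPPG conversion algorithms** — CHROM (chrominance
  combination), POS (plane orthogonal to skin), LGI (local group
  invariance) and OMIT (orthogonal matrix image transformation);
- **windowed spectral HR estimation**: zero-phase sixth-order Butterworth
  bandpass over 0.65–4 Hz, then per 6 s sliding window (5 s overlap) the
  Welch power-spectral-density peak on a ≤0.1 BPM frequency grid;
- **evaluation metrics**: MAE of the aligned HR series, windowed Pearson
  correlation against the contact-PPG waveform, masked-spectrum SNR
  (±12 BPM around the reference HR and its first harmonic), the
  min–max-normalized overall score

  OS_k = 1/3 [ (MAE_max − MAE_k)/(MAE_max − MAE_min)
             + (PCC_k − PCC_min)/(PCC_max − PCC_min)
             + (SNR_k − SNR_min)/(SNR_max − SNR_min) ],

  25 s-window acceptance rates (MAE ≤ 10 BPM) and Bland–Altman agreement
  statistics;
- **cross-activity ROI ranking** by the summed overall score, with a
  stacked-bar report;
- **a synthetic-data module** that generates pulse-modulated per-ROI RGB
  traces (graded amplitudes, white noise, illumination drift, motion
  bursts), ground truth sampled at its own rate, and rendered frame
  sequences with matching landmark files — so the whole pipeline is
  testable without any external video dataset.

## Worked example

```python
import numpy as np
from roipulse import (SimulationConfig, simulate_traces, apply_rppg,
                      bandpass, welch_hr, align, mae)
from roipulse.synthetic import StudyUnit
from roipulse.pipeline import evaluate_unit

cfg = SimulationConfig(seed=1)                # 30 s at 30 fps, 72 BPM
traces, cppg, hr = simulate_traces(cfg)       # 28 ROI traces + ground truth

pulse = bandpass(apply_rppg(traces[4], "POS"))  # ROI 4 = glabella
est = welch_hr(pulse)                            # 25 windowed estimates
print(round(mae(align(est, hr)), 2))             # -> 0.24  (BPM)

records = evaluate_unit(StudyUnit("p01", "cognitive", cfg, traces, cppg, hr))
print(records[records.roi_index == 4][["method", "mae", "pcc", "snr"]].round(3))
#    method    mae    pcc     snr
# 3   CHROM  0.308 -0.966   9.551
# 31    POS  0.244  0.977  10.409
# 59    LGI  0.200  0.988  11.249
# 87   OMIT  0.200  0.988  11.255
```

The glabella trace carries the strongest embedded pulse in the default
simulation, so every method recovers HR to a fraction of a BPM (MAE), the
pulse waveform correlates almost perfectly with the contact-PPG reference
(PCC; CHROM's chrominance combination flips polarity, hence the sign), and
about 10 dB of the spectrum sits inside the reference-HR mask (SNR).

Ranking a full synthetic study:

```python
from roipulse import make_study, aggregate_and_rank
from roipulse.pipeline import evaluate_study

study = make_study(seed=3)                    # 6 participants x 2 activities
result = aggregate_and_rank(evaluate_study(study))
print(result.table.head(3)[["rank", "roi_name", "os_sum"]].to_string(index=False))
#  rank              roi_name  os_sum
#     1              glabella   1.833
#     2 left lateral forehead   1.786
#     3       medial forehead   1.781
```

A command line mirrors the two-phase pipeline (raw signal extraction, then
HR estimation) for file-based workflows:

```sh
roipulse simulate --out study --seed 7 --participants 2
roipulse evaluate --study study --out eval
roipulse rank --metrics eval/metrics.csv --out report
```

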