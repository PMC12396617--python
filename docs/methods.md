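# Methods

## Scope and data model

The package analyzes beat-to-beat cardiovascular variability in the rat:
either a pulsatile arterial pressure (PAP) waveform sampled uniformly (the
acquisition convention is 2 kHz) or a pre-extracted beat series of
(systolic-peak time, SAP) pairs. The pulse interval PI<sub>k</sub> =
(t<sub>k+1</sub> − t<sub>k</sub>)·1000 ms is always derived from the beat
times, so `hr_k · pi_k = 60000` holds exactly and a file's redundant `pi_ms`
column can never disagree with its timestamps (mismatches > 1 ms are logged;
times win).

## Beat extraction

Systolic peaks are found with a refractory period of 60000/max_rate ms
(defaults 200–500 bpm, covering the anesthetized-to-stressed rat) and an
*adaptive* prominence threshold: 0.4 × the rolling median pulse amplitude
over 5-s windows. The fraction was chosen well below 1 so that respiratory
and LF amplitude modulation of the pulse never drops beats, and well above
the dicrotic-notch prominence; because the threshold is relative, gain
changes and drift need no absolute mmHg constant. The beat time is the local
maximum sample (earlier sample on ties); SAP is its value. MAP is the true
time-average of the waveform over [t<sub>k</sub>, t<sub>k+1</sub>) — exact
for sampled data, unlike the cuff-era diastolic + PP/3 estimator.

PI is defined systolic-peak-to-peak rather than foot-to-foot so that SAP and
the beat fiducial come from the same point of the pulse.

## Stable-segment selection

Experimenters analyze the quietest ~10-min stretch of a 30-min recording.
To make that choice auditable, each beat is scored by the sum of the
rank-normalized rolling variances (32-beat window) of PI and of SAP — rank
normalization makes ms² and mmHg² commensurate without unit-dependent
weights — and the contiguous window of the requested duration with the
lowest mean score is selected, earliest window on ties. Segment boundaries,
beat counts and scores are logged.

## Time domain

Mean, SD and variance (unbiased, n−1) per series; RMSSD for PI only.
All indices are computed on the selected segment.

## Frequency domain

The unevenly sampled beat series is interpolated with a cubic spline and
evaluated on a uniform 10 Hz grid — above twice the 3.00 Hz HF edge with
margin; linear interpolation was rejected because it measurably attenuates
HF power at rat heart rates, where the HF rhythm is only a factor ~2 below
the beat rate. The PI value of an interval is anchored at the beat opening
it (the cycle length in force at that beat); SAP at its own beat time.

PSD: Welch's method, Hann taper, linear detrend per segment, 512-sample
(51.2 s) segments with 50% overlap — long enough to resolve the 0.20 Hz
lower LF edge with ≥10 cycles per segment while still averaging ~20
segments in 10 min. A series shorter than one segment falls back to a
single full-length periodogram with a logged warning. Density scaling is
such that the integral of the PSD over frequency approximates the variance
of the detrended series (Parseval property test).

Band power is the integral of the piecewise-linear PSD over the continuous
interval [low, high). Treating the PSD as a function rather than binning
grid points has two consequences: band edges need not coincide with grid
frequencies, and adjacent bands tile the axis exactly, so
below-LF + LF + HF equals the total power over [0, 3.00) to machine
precision. The ">0.75 Hz" HF convention is honored by assigning the 0.75 Hz
point to LF; since a single point has zero measure, the integrals are
unaffected. "Total power" is defined over [0, HF-upper); spectral content
between 3.00 Hz and the 5 Hz Nyquist of the resampled series lies outside
the physiological analysis range and is not reported. Power below 0.20 Hz
(VLF) is computed only for the partition check.

Normalized units: LF(nu) = 100·LF/(LF+HF) and complement; LF/HF is the
sympathovagal ratio. With LF+HF = 0 the normalized units are undefined and
reported as null; HF = 0 with LF > 0 yields an infinite-ratio flag.

## Symbolic dynamics

PI values are quantized into 6 equal-width levels over the segment's
observed [min, max] (the convention of the Porta-family symbolic-analysis
lineage; a mean-centered ±k·SD alternative was considered and rejected to
keep the scheme parameter-free). Overlapping 3-symbol windows, stride 1.
With d1 = s2−s1, d2 = s3−s2: 0V iff d1 = d2 = 0; 1V iff exactly one is 0;
2LV iff d1·d2 > 0; 2UV iff d1·d2 < 0. Over all 6³ = 216 patterns the family
sizes are 6/60/40/110 — an exhaustive-enumeration oracle the tests check
against an independent brute-force loop. Family rates are percentages of
the pattern count; 2V = 2LV + 2UV is the reported parasympathetic marker.
A constant segment quantizes to all-zeros and correctly reports 0V = 100%.
Symbolic analysis is applied to PI only.

## Group statistics

Each index is compared between two groups of animals by first screening
*both* groups with Shapiro–Wilk at the same alpha; only if both pass is the
pooled-variance Student's *t*-test used, otherwise Mann–Whitney U (both
two-sided, unpaired — the groups are distinct animals). Requiring both
groups to pass is the conservative reading of dispatch-by-normality when
the per-group rule is not specified. Results are means ± SEM (SD/√n),
significant at P < alpha (default 0.05) with no multiple-testing correction
by default, matching the per-index reporting convention of the field; a
Holm step-down option exists. A simulation test verifies the dispatched
procedure's type-I error stays in [0.03, 0.07] at alpha = 0.05 under a
normal null (n = 10 per group, 2000 replicates).

## Synthetic generator

The generator is an integral-pulse model: PI<sub>k</sub> = mean_pi +
A<sub>LF</sub> sin(2π f<sub>LF</sub> t<sub>k</sub>) +
A<sub>HF</sub> sin(2π f<sub>HF</sub> t<sub>k</sub> + φ) + ε<sub>k</sub>,
with t<sub>k+1</sub> = t<sub>k</sub> + PI<sub>k</sub>/1000 and SAP built
analogously at the beat times. The HF phase φ is drawn from the seed to
avoid phase-locking between the two oscillations; noise is independent
Gaussian per beat; slow 1/f-like SAP drift (a sum of sub-0.05 Hz tones) is
available behind `drift_amp_sap`. Defaults emulate the study population:
mean PI 170 ms (~353 bpm), SAP 130 mmHg Wistar-like (`shr_like()` gives a
180 mmHg hypertensive preset), LF at 0.4 Hz and HF at 1.5 Hz with
amplitudes of a few ms/mmHg and 1–2 units of beat noise — no numeric
variance is published for the study animals (figures only), so noise
defaults were fixed once at levels giving informative recovery tests.

Waveform rendering: each pulse rises over a 30 ms half-sine upstroke from
the previous diastolic level to SAP<sub>k</sub>, then decays exponentially
(time constant PI/3) toward SAP<sub>k</sub> − pulse_pressure. The systolic
peak is snapped to the sample grid and carries exactly SAP<sub>k</sub>, so
ground-truth peak times are recoverable to ±1 sample and the recovery test
is exact rather than tolerance-tuned.

What the generator does *not* emulate: baroreflex closed-loop coupling
between SAP and PI, respiration as a distinct physical signal, ectopic
beats and arrhythmia, movement artifacts, and any pharmacokinetics —
anesthetic scenarios exist only as parameter presets. Passing tests
therefore demonstrate that the *estimators* recover known structure from
realistically sampled, noisy series, not that the physiology of a real rat
is reproduced.

## Numerical and degenerate-input choices

* Artifact correction (off by default): a beat whose two flanking intervals
  both deviate > 30% from the median PI while their sum is normal is a
  displaced fiducial and is moved to its neighbors' midpoint; missed/extra
  detections are logged, not guessed at.
* `run_pipeline` refuses segments shorter than 60 s (too short for a
  512-sample Welch segment at 10 Hz to say anything about the 0.2 Hz edge).
* Constant series: zero variance, RMSSD 0, empty spectrum (null normalized
  units), all-0V symbolic output — every stage degrades to a defined answer.
* Reports serialize with sorted keys and the shortest round-trip float
  representation; identical input and config give byte-identical JSON.
* Analysis sizes in tests and the acceptance script (10-min series for
  recovery claims, 200 s for identity sweeps, 2000 replicates for
  calibration) were chosen so each claim's sampling error is far below its
  asserted tolerance.
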