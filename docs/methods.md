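# Methods

## The suppression model

The algorithm treats each stimulation artifact independently: no assumption
is made about other stimuli on the same channel, because artifact shape
depends on stimulation history, electrode geometry and amplifier state. A
trial is the half-open window `[onset_i, onset_{i+1})` (0-based samples;
the last trial runs to the end of the recording; the pre-first-onset prefix
is never touched). All durations are configured in milliseconds and
converted with `round(ms·1e-3·fs)`, which keeps the method sampling-rate
agnostic.

**Transient gate.** A trial is only modified beyond the default blanking
β₀ if it carries a significant transient. The gate compares 5 ms of signal
immediately before the onset with 5 ms after β₀: no transient when
|mean_post − mean_pre| ≤ 2·std_pre and std_post/std_pre ∈ [0.5, 2]. The
constants are scale-free, deliberately conservative, and exposed in
`LogLiraConfig`. Trials too short to hold the post-window, or with no
pre-onset signal, are treated as containing a transient. The pre-window is
taken from the raw recording; trials whose pre-window overlaps the
previous trial's transient are flagged (`pre_window_overlap`) rather than
handled specially.

**Transient end.** A 5 ms centered moving average (edge-truncated, so no
phase lag biases the landmark) is compared with the median of the samples
beyond the 40 ms settling time; the first sample within ±1 µV of that
median, scanning from the end of the blanking interval, is `n_e`. Trials
shorter than the settling time use the whole-trial median and fall back to
`n_e` = end of trial, as do trials whose moving average never enters the
band.

**Recovery start and dynamic blanking.** Saturation is declared where
|v| ≥ 95 % of the amplifier operating limit, or of the channel-wide
maximum voltage when the limits are unknown (channel-wide, not per trial,
so artifact-free trials cannot misfire; and the fallback is only consulted
on the transient path for the same reason). Saturated stretches are
concatenated: `n_s` follows the last one, never earlier than β₀, and the
saturation scan is bounded by `min(n_e, T)` so a late excursion cannot
blank a whole trial. β is `n_s` expressed in ms; a fully saturated trial is
blanked entirely and flagged.

**Logarithmic grid and interpolation.** Grid times
`t_j = 10^(j/(P−1)·log₁₀T) − 1` for `j = 0…P−1` (`P = 42`, `T = 50 ms` by
default) give `t_0 = 0`, `t_{P−1} = T−1` and spacing that grows with `j` —
dense where artifact dynamics are fast. After conversion to samples,
shifting by β and truncation at `n_e`, duplicate indices (inevitable at
low sampling rates) are merged. Node values are neighborhood means over
ε+1 samples; the width schedule is ε_j = ⌊(n_{j+1} − n_{j−1})/2⌋ capped at
2·(n_{j+1} − n_j) (one-sided at the endpoints, neighborhoods clipped to
[n_s, n_e)): smoothing proportional to the local pitch without swallowing
distant nodes, with the proportionality cap exposed as `epsilon_cap`. The
interpolant is anchored at `n_e` on the raw signal so the residual is
continuous there; with `epsilon_cap = 0` the interpolant reproduces any
piecewise-linear-over-nodes trial exactly (this is a test oracle). The
blanked region is pasted unmodified into the estimate and the estimate is
zero beyond `n_e`, so subtraction touches only `[n_s, n_e)`.

**Bridging.** After subtraction a line is traced from the sample preceding
the onset to the sample following `n_e` (to the last sample when
`n_e` = trial end); the blanked region takes the line's values and the
recovered residual is superimposed on it. This removes the step
discontinuities that would ring through the evaluation bandpass filter.

**Secondary-artifact mitigation.** The interpolation is deterministic, so
its residual in the first ~2 ms after blanking is nearly identical across
trials with similar artifacts, while genuine activity is not time-locked.
The 2 ms windows starting at each trial's own `n_s` are embedded to 2-D
with UMAP (correlation metric — scale-invariant, so raw windows are used
without normalization; 15 neighbors, min_dist 0.1, seeded) and clustered
by density: a Gaussian KDE of the embedding is evaluated on a 64×64 grid,
cells hill-climb to their local density maximum, and two modes merge when
the saddle between them is at least half the smaller peak (ratio
configurable). This realizes the density-based-merging contract — no
preset cluster count, noise-aware — and is robust at the small trial
counts where a minimum-spanning-tree density clusterer prunes everything
to noise. Clusters with fewer than θ = 20 members are discarded; each
retained cluster's mean window is subtracted in place from its member
trials. With fewer than θ usable trials the stage is the identity.
Windows from trials that failed the transient gate are excluded by
default (`include_quiet_trials`): including them would let an
artifact-free channel's noise windows form a retained cluster whose mean
(~noise/√K) would then be subtracted, violating the contract that quiet
channels are modified only inside their blanking windows. Stereotyped
short-latency evoked spikes may be partially attenuated by the cluster
mean; this trade-off is accepted, not corrected.

## Baseline suppressors

Both baselines sit behind the same interface (`clean(recording, stims) →
recording + per-trial blanking metadata`) as logLIRA, so the evaluation
harness runs unchanged; an external command can be plugged in through a
file-based contract. *Dynamic averaging* subtracts, from each trial, the
mean of its `n_neighbors = 10` temporally nearest trials (self included,
ties toward earlier; truncated to the shortest trial involved; global
average fallback when K ≤ n_neighbors), then blanks 1 ms. *Global
polynomial fitting* least-squares fits a polynomial (order 8 over 10 ms by
default, 0.5 ms blank) to each trial's post-blanking span and subtracts it
there. The exact parameterizations used in published comparisons are not
public; these defaults are reasonable choices and fully exposed. They are
approximate baselines for ordering comparisons, not faithful ports.

## Synthetic fixtures

Real ICMS recordings are embargoed, so the package generates its own test
substrate. *Basal activity*: Gaussian noise band-limited to 300–6000 Hz
(rescaled to a 4 µV standard deviation) plus ~1 ms biphasic/triphasic
spike waveforms (three canonical shapes, peak amplitudes uniform in
30–120 µV) at gamma ISIs (shape 2 — avoids the unrealistically short
Poisson intervals that would confound jitter-matched scoring) with a 2 ms
refractory period; the realization is redrawn until the spike count hits
the target mean firing rate within ±0.5 Hz. The signal is stored as
noise + spike-track so the decomposition is bit-exact. *Artifact
templates*: a biphasic fast transient (difference of exponentials,
τ_fast ≈ 0.3 ms, peak ~kV-scale µV) plus a bi-exponential slow decay
(τ_slow ≈ 8 ms) with per-template jitter and random polarity; the slow
component is capped so every template decays below 1 µV before the end of
its 50 ms span; saturating variants clip exactly at the amplifier limits
with an exact plateau. *Onset trains*: log-normal (σ = 0.6) inter-artifact
intervals rescaled so 1/median hits the target mean artifact rate, with a
degenerate constant-interval mode for toy cases. An optional evoked mode
inserts spikes time-locked 1–5 ms after onsets — a scenario the
semisynthetic benchmark itself deliberately does not model, since its
ground-truth spikes must be independent of artifact placement.

What the fixtures do **not** emulate: electrode drift, bursting and
correlated network activity, amplifier nonlinearity short of hard
clipping, movement artifacts, and any statistical coupling between
artifact shape and stimulation history. Passing tests therefore show that
the pipeline's mechanics are correct under controlled conditions, not that
performance numbers transfer to any particular real preparation.

## Benchmark synthesis

Dictionary building extracts all per-stimulus waveforms at the length of
the minimum inter-artifact interval, embeds and density-clusters them with
the same machinery as the secondary stage, discards clusters under 100
members, and takes each survivor's per-sample median smoothed with a
minimum-order FIR lowpass (~2 kHz cutoff, Kaiser design, zero-phase). For
clusters containing saturation, the raw median is kept up to the last
sample where it departs from the smoothed version by more than 2.5× the
median departure, preserving onset and clip edges.

IAI resampling shifts the source intervals rightward (constant shift
placing the median at 1/MAR) to lower the rate, or trims the largest 2 %
per iteration to raise it (minimum kept in place; if a trim step overshoots
the ±0.1 Hz tolerance a small recentring shift follows). A Gaussian KDE
(Silverman bandwidth) of the adjusted intervals is sampled, truncated to
their [min, max] range, until the cumulative sum covers the snippet. At
desk scale (10 s snippets, ~10² intervals) the sample median fluctuates
more than the ±0.1 Hz tolerance, so a drawn sequence that misses is
recentred by a small constant shift (clipped to the support) and the
realized rate is re-verified on the final integer onset train, redrawing
when needed.

Template insertion multiplies each randomly picked template (truncated at
the next onset if it would overlap) by a window with both endpoints
exactly zero: a ~0.2 ms raised-cosine onset ramp — a full symmetric taper
would destroy the fast transient that makes the artifact hard — followed
by the decaying half of a Blackman window raised to a per-insertion
exponent α ∈ [0.5, 2], which modulates decay speed and adds template
variability. The snippet is the windowed-template track plus the basal
signal, so `snippet == track + basal` holds bitwise and the ground-truth
spike train is untouched by construction. A full default grid produces one
snippet per (MFR, MAR) cell — 5 × 10 = 50 per subset.

## Evaluation

Suppressor outputs and the basal ground truth go through the same
zero-phase 4th-order Butterworth bandpass (300–7000 Hz; the upper cutoff
drops to 0.45·fs with a warning when the sampling rate is too low). Spike
detection is SWTTEO: a stationary wavelet transform (sym4, 2 levels), the
Teager energy operator Ψ[n] = y[n]² − y[n−1]y[n+1] applied to the deepest
approximation subband — at these sampling rates the 300–3000 Hz spike
energy concentrates there, while the detail bands carry essentially no
spike/noise contrast — then 1 ms Hamming smoothing, a robust threshold
5·median(|Ψ|)/0.6745, 1 ms dead time, and alignment of each event to the
dominant extremum of the filtered trace within ±0.5 ms. The detector is
deterministic, and each snippet's detection parameters are stored in the
dataset manifest so every suppressor is scored with the settings of its
own ground truth.

The scoring reference spike train is the detector's output on the clean
basal signal (not the inserted spike times), so detector timing bias
cancels between reference and test. Matching is greedy nearest-first
within ±0.2 ms, ties toward the earlier ground-truth event; FP/FN
percentages are normalized by the ground-truth count and deliberately not
capped at 100 %. C₀ counts coincidences within a closed ±Δτ/2 window
(Δτ = 0.4 ms) at sample resolution, normalized by √(NₓN_y) and clipped to
[0, 1]. Per-artifact timing is reported but hardware-dependent. PSTHs use
0.25 ms bins with a 5000-stimulus truncation.

## Problem sizes

The test suite and the acceptance script run everything on synthetic
material generated at run time: 20 kHz sampling for most checks (30 kHz
where a rate is part of the check), snippets of 4–10 s, benchmarks of 6–10
snippets, and boundary sweeps of ~5–10 channel constructions. These sizes
were chosen so the full suite completes in minutes on one core while every
boundary (θ = 20, 100 members, ±0.5/±0.1 Hz tolerances, 0.4 ms window) is
still exercised exactly.

## Known limitations

- Streaming/real-time operation is out of scope: the secondary stage needs
  the whole trial population before it can cluster.
- Multi-channel joint processing is not supported; channels are
  independent.
- The ε schedule's proportionality constant and the transient gate's
  "similar enough" thresholds are heuristics exposed in configuration, not
  fitted quantities.
- With fewer than ~20 stimuli the secondary stage never engages; a few
  hundred trials are needed for reliable cluster means.
- Benchmark performance numbers depend on the synthetic generator's
  declared scales (noise 4 µV, spikes 30–120 µV, artifact peaks in the mV
  range) and are not comparable to numbers obtained on real recordings.
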