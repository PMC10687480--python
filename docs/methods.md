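# Methods

This note documents the model, the synthetic-data generator, the analysis
pipelines and the numerical choices behind `arcsim`, in the order a reader
would meet them.

## Task and trial model

A session is a seeded shuffle of a fixed stimulus multiset. The standard
Simon session has 200 trials (160 congruent, 40 incongruent; the two
variants within each class balanced), the non-conflict control session 100
congruent trials. Stimuli appear for 500 ms with inter-trial intervals
drawn uniformly from 3000–5000 ms; the shuffle is an unconstrained uniform
permutation (no run-length constraints — nothing in the design motivates
any). Trials after the first are labelled by (current, previous)
congruency: C(C), C(I), I(C), I(I); the first trial is excluded from every
conditioned summary. Crossing these with response correctness
(relevant/irrelevant) yields the eight event conditions all physiological
analyses key on.

## Information accounting and free energy

Entropy is Shannon's `H = −Σ p log p`; collapsing the four stimulus types
to two congruency classes saves exactly one bit. Response codes are one-hot
2-vectors; the action rule is the anti-diagonal exchange operator Ψ, an
involution.

Per-trial cost is free energy `F = D_KL(Q‖P(φ|Φ)) − log P(Φ)`: Bayesian
surprise plus Shannon surprise, in nats. The cases:

* congruent — the rapid location-driven response already is the goal
  response; the final state has probability one and `F = 0`;
* incongruent, reversal applied — the inference error cancels and
  `F = −log P(reversed code)`, the Shannon surprise of the rarer code;
* incongruent, reversal not applied — the goal code and the executed code
  are opposite one-hot vectors, so the Bayesian term is their KL divergence.

Degenerate one-hot codes make that divergence infinite, so distributions
are floored at ε = 10⁻⁶ and renormalised before the KL sum; the unadapted
Bayesian term is then ≈ −ln ε ≈ 13.8 nats — finite, and ordered above the
adapted case for every prior. The same Shannon term is used in both the
adapted and unadapted branch (the executed final code is the reversed one
in both accountings); this is the only reading under which adaptation is
cheaper for *every* prior, which is the substance of the model's
cost-saving claim.

The prior over final response codes defaults to the session base rates:
P(reversed) = κ/(1+κ) = 0.2 for κ = 0.25, giving the adapted incongruent
cost −ln 0.2 = 1.609 nats. No numerical prior is dictated by the theory;
the base-rate choice makes the Shannon surprise exactly the surprise of the
class frequency.

The presumed symbol is computed as `q* = p XOR θ`: congruent stimuli copy
the location, incongruent ones mirror it. (A NAND gate cannot express
"copy when congruent"; XOR is the operation the stated reversal rule
implies.)

### What the agent is charged per trial

The simulator books cost as the free energy of the trial *as perceived*:
baseline (0.5 nats, covering congruency detection and response assembly)
plus the Shannon surprise of the reversed code whenever incongruence was
perceived and the rule fired. A missed incongruent trial therefore costs
only the baseline — the agent experienced a seemingly congruent trial and
its error is revealed only behaviourally — while a false alarm on a
congruent trial pays the full reversal surprise for nothing. This is what
makes I(C) errors cheap/reactive and C(I) errors expensive/conflicted, and
it is asserted as such in the tests.

## Congruency perception and threshold mediation

The sensory signal for class θ is Gaussian with mean V_θ and spread σ_θ;
the classifier reports incongruence when the sample meets the threshold
(`v ≥ V_th`; exact ties, a measure-zero event, go to the incongruent
class). Densities are unit-area Gaussians — the sensitivity scores are
ratios of probability masses and require normalised densities. The
sensitivity scores weight the competing tail masses by the prior odds
(1/κ for the incongruence score, κ for the congruence score); the weight
is exposed as an override for sensitivity analyses.

Threshold mediation is `V_th ← ρ·V_th + (−1)^θ·Γ` with retention ρ and step
Γ; under a constant class it converges geometrically (rate ρ) to
±Γ/(1−ρ).

**What drives the update.** By default the update is driven by the
congruency as *resolved by trial end* — semantic processing and outcome
feedback always reveal the true class within the trial — while
classification itself stays purely perceptual. The alternative, feeding
the classifier's own output back into the rule (`update_on="perceived"`),
is implemented and available, but it makes false alarms self-reinforcing:
a false alarm lowers the threshold, which makes the next false alarm more
likely, and the closed loop has an absorbing all-error state at −Γ/(1−ρ).
A drift analysis plus simulation showed that at *any* parameter setting
producing realistic few-percent error rates, a non-negligible fraction of
200-trial sessions collapses into that state — runs of errors that no
behaving cohort shows (errors in this task are idiopathic and unclustered).
Outcome-driven consolidation removes the pathological feedback without
touching the perceptual error mechanism, so it is the default.

**Default parameters.** V0 = 0, V1 = 1, σ0 = 0.22, σ1 = 0.35, ρ = 0.95,
Γ = 0.04, V_th(0) = 0.5. The asymmetric spreads (tight congruent class,
broad incongruent class) reflect that the rare, salient incongruent
stimulus evokes a more variable response, and they shape the error
structure: with the threshold orbiting near 0.5 and drifting up during
congruent runs, misses concentrate on I(C) (~8%), are rarer on I(I) (~5%),
false alarms appear on C(I) (~3%) and are rare on C(C) (~2%). Switch
trials err roughly three times as often as repeat trials — the
congruency-sequence effect the model exists to produce — with every error
class populated, as in the behavioural data the model addresses.

## Behavioural simulator

Each trial: sample the signal, classify, launch the rapid response at the
location side, reverse it iff incongruence was perceived, score relevance
against the symbol, book the cost, update the threshold, log latencies.
APA latency is N(300, 20) ms truncated at zero and independent of
congruency by construction; foot-off is N(500, 50) ms plus a fixed 100 ms
reversal cost whenever Ψ was applied (and never earlier than the APA).
Latency noise is Gaussian because nothing in the design constrains its
shape; the within-subject foot-off spread of 50 ms is a typical
step-initiation variability.

## Synthetic physiology

All generators are pure functions of (trial records, parameters, seed).
Subject-level variability is a lognormal multiplicative amplitude gain
(σ = 0.2, median 1) per subject; the default cohort is 17 subjects.

**EEG (O1, O2, Cz at 256 Hz).** Occipital channels are 1/f-amplitude noise
(10 µV) plus a 11.5 Hz alpha carrier (20 µV) whose envelope is suppressed
multiplicatively by a Gaussian bump after each stimulus: depth
`d = 0.05 + 0.2·cost` (clipped to [0, 0.95]), centred 500 ms post-onset,
300 ms FWHM. Relevant responses get the full dip; incongruent relevant
trials additionally get an early shoulder (0.3·d at 250 ms) so incongruent
traces depart from congruent ones early; irrelevant responses get no dip —
except irrelevant C(C) trials, which get an early-shifted (300 ms) one.
Cz carries Gaussian ERP deflections (P200 at 210 ms, N200 at 290, P300 at
360, N400 at 470, LPC at 640; the centres sit inside the classical
measurement windows and far enough apart that neighbouring tails do not
bias peak measurements); only the P200 depends on congruency by default
(3 µV congruent, 6 µV incongruent).

**EMG (tibialis anterior + gastrocnemius per leg, 1024 Hz).** Each channel
is 20–500 Hz band noise amplitude-modulated by side- and
condition-dependent envelopes: both sides rise from ~120 ms with the burst
on the stimulus-location side; on relevant incongruent trials the
envelopes exchange sides at 200 ms (smooth 30 ms logistic transitions); on
irrelevant C(C) trials the pattern inverts late (600 ms); otherwise no
exchange. Everything decays after foot-off + 300 ms.

**Acceleration (3 axes, 256 Hz).** The horizontal axis carries, per trial,
two opposite-signed Gaussian lobes: the APA peak at the trial's APA time
(amplitude 1) and the foot-off peak at its foot-off time (amplitude 1.5),
with polarity encoding the executed step side; 80/100 ms FWHM so that
after the analysis low-pass the two remain cleanly separated peaks
(overlapping tails would pull each detected peak toward the other in a
congruency-dependent way). Other axes are noise.

What the generator does *not* emulate: volume conduction, eye/muscle
artifacts, electrode drift, non-stationary alpha, inter-trial latency
correlations, or any biophysical forward model. Passing recovery tests
therefore demonstrate that the pipelines measure what they claim on
signals with the assumed statistical structure — not that they are robust
to real-world artifact regimes.

## Analysis pipelines

**Recordings and epochs.** Storage is plain EDF (16-bit, one-second data
records, per-signal rates); the reader/writer covers exactly this subset
and round-trips within one digitisation step, and files are cross-read
with MNE in the tests. Epochs span −500…2000 ms around onsets
(nearest-sample mapping, half-open windows → exactly 2.5·fs samples);
baseline correction subtracts each trial's −500…0 ms mean and is
idempotent. Grand averages are unweighted means of subject means, SEM = SD
of subject means/√n.

**ER-DBA.** Per occipital channel: zero-phase 3rd-order Butterworth
band-pass 10–13 Hz, squared, moving-averaged, then O1/O2 averaged
(power-then-average, matching the index definition). The nominal 32.25 ms
smoothing window is 8.256 samples at 256 Hz; the implementation uses
`round(fs·32.25 ms)` = 8 samples (31.25 ms) and reports that rule here.
Zero-phase filtering is chosen so dip latencies carry no filter delay. Dip
metrics take the minimum of the baseline-corrected mean trace within
0–1000 ms (bracketing the observed nadirs around 450–600 ms); depth is the
magnitude of a negative minimum, else zero. Difference traces subtract
means pointwise and combine SEMs in quadrature.

Fractional dip depths are estimated per subject — each subject's dip
divided by their own pre-onset power — and then averaged; this removes the
between-subject amplitude-gain variance that a grand-power-trace estimate
inherits. Two known small biases remain and are documented rather than
corrected: the pre-onset power includes the noise floor in the band
(≈1–2%), and the 3 Hz-wide band-pass attenuates a 300 ms envelope notch by
≈16% in amplitude — so shallow dips are systematically under-recovered by
roughly their attenuation, ~15% relative, while deep dips land within
5–10%. The square-law (a fractional amplitude dip d appears as a
1−(1−d)² fractional power dip) is what recovery is scored against.

**ERP.** Cz is band-passed 0.05–45 Hz (zero-phase, 3rd order), epoched,
baseline-corrected, grand-averaged. Component amplitude is the
polarity-consistent extremum inside the fixed windows — P200 150–275 ms,
N200 200–350, P300 300–400, N400 250–550, LPC/P600 450–800 — with its
latency; a window-mean option exists. Overlapping windows are measured
independently. Peak rather than mean is the default because latency
statements ("appeared earlier") are peak statements.

**EMG.** Per leg: band-pass 20–500 Hz (upper edge clipped below Nyquist;
designed in second-order sections), 50 ms moving RMS per muscle, power =
(RMS₁² + RMS₂²)/2. Step- and support-side traces are assembled per trial
(which leg is which changes trial to trial), baseline-corrected and
averaged per condition; Δ = step − support measures lateralisation and its
zero crossing marks the redirection of the initial location-driven burst.

**Step timing.** Horizontal acceleration is low-passed at 5 Hz
(zero-phase); within each trial the first two opposite-signed extrema
exceeding a prominence threshold are the APA and the foot-off, and APA
polarity gives the executed step side (replacing video scoring). The
prominence threshold is max(3× the trial's pre-onset SD, 25% of the
trial's peak amplitude): the absolute floor rejects the ~8% ringing side
lobes that zero-phase filtering places around each true extremum, which
would otherwise outrank a true peak whenever the pre-onset noise happens
to be low. Trials without two qualifying extrema are flagged unresolved,
never guessed. Detected latencies are quantised to the sample grid, so
latency contrasts below one sampling period (3.9 ms) are below the
method's resolution.

## Experiment runner and prediction checks

A run simulates each subject's own randomised session (and, by default,
the congruent-only control session), synthesises all modalities, runs all
pipelines, grand-averages, and writes delimited tables stamped with a hash
of the result-determining configuration. Runs are deterministic: all
randomness derives from one seed via spawned seed sequences, and identical
configurations reproduce identical bytes.

The model's five predictions are restated as machine checks: (1) mean cost
higher on incongruent than congruent trials; (2) switch error rates exceed
repeat rates and C(I) errors cost more than I(C) errors; (3) APA latency
congruency-independent (difference within 3 pooled SEs); (4) recovered
P200 larger for incongruent; (5) every relevant condition shows a dip —
trace minimum deeper than five between-subject SEMs — and no irrelevant
condition except C(C) does (conditions carried by a single subject have no
SEM and no assessable evidence). The five-SEM presence rule is a strong
significance cut chosen so that the noisy minimum of a near-empty
condition (a multiple-comparisons maximum over the search window,
typically 2–3 SEM) does not count as a dip; disabling dip generation makes
check (5) fail, which the tests assert as a negative control.

## Problem sizes

The default study is 17 subjects × 200 trials (plus 17 × 100 control
trials), the scale of the cohort the design describes; the behavioural
sequence-effect study uses 20 independently seeded sessions. The test
suite exercises reduced versions (20-trial sessions, 2–5 subjects) for
unit-level properties and the full cohort for recovery criteria; the whole
suite runs in well under a minute of CPU.

## Known limitations

* The ER-DBA index is reproduced as a computation; no claim about what it
  measures neurally is made or testable here.
* Shallow-dip recovery carries the ≈15% band-pass attenuation described
  above; a deconvolution-based estimator could remove it but would assume
  the dip shape it is supposed to measure.
* The perceived-feedback variant of threshold mediation is unstable by
  construction (see above); it is provided for sensitivity analyses, not
  as a default.
* EMG and acceleration envelopes are stylised; their recovery tests
  validate pipeline logic (sign, timing, labels), not biomechanical
  realism.
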