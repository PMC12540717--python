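# Methods

## Signal model and preprocessing

Input signals are multi-channel sEMG sampled at a nominal 2 kHz, stored as
delimited numeric text (comma or whitespace, auto-detected) with a YAML
manifest assigning gesture/subject/session per file. Amplitude units are
opaque; every threshold downstream is configurable in the same units.

Denoising is a two-stage IIR cascade applied per channel, notch first:

* **Notch** at 50 Hz, quality factor Q = 30 (≈ 1.7 Hz −3 dB width).
  Q = 30 is a conventional narrow setting for powerline removal and is
  configurable.
* **Band-pass**: 4th-order Butterworth, 10–500 Hz. "4th order" is read as
  the analog prototype order (the digital filter has 8 poles).

Filtering is causal single-pass by default — matching real-time prosthetic
use, where future samples are unavailable — with a zero-phase two-pass
(`filtfilt`) option for offline work. Both stages are LTI, so the cascade
order is analytically immaterial for the output; it is nevertheless fixed
(notch → band-pass) as the documented contract, and tests measure tone
attenuation on the steady-state portion of the response to sidestep the
causal transient. Stability (all poles strictly inside the unit circle) is
checked at design time.

## Windowing and features

Window length W = round(256 ms · fs / 1000) samples (512 at 2 kHz); step
= W − round(0.25 · W) (384). The trailing remainder shorter than W is
discarded; windows inherit the record's labels. "Overlap 25 %" is read as
25 % of the window (64 ms); a different `overlap_frac` selects the
alternative reading.

The 17 features are listed in `features.py`'s module docstring. Decisions
where common transcriptions of the definitions are ambiguous or
degenerate:

* **WL**: a frequently transcribed waveform-length variant
  ((1/(N−1))Σ|x_p|²) is algebraically identical to VAR; the default is the
  conventional Σ|x_{p+1} − x_p|, with that variant preserved as the
  `as_printed` mode.
* **PKF**: the analogous variant ((1/2)ΣP_k) carries no peak information;
  the default is the frequency at maximum power, `as_printed` available.
* **MDF**: first bin whose cumulative power reaches TP/2, no interpolation
  (deterministic tie convention: ties resolve to the lower frequency).
* **WAMP/MYOP thresholds** default to 0.01 signal units (configurable);
  MYOP tests |x_p| ≥ threshold.
* **FR bands** default to 10–250 Hz over 250–500 Hz, splitting the
  analysis passband at its midpoint. A spectrum with zero high-band power
  raises an error; an all-zero spectrum yields NaN sentinels with a warning.
* **LOG** uses log(|x_p| + ε), ε = 10⁻¹², to avoid −∞ at zero samples.
* **Spectrum**: one-sided periodogram, rectangular taper, mean-detrended,
  scaled so ΣP_k equals the mean square of the detrended window (Parseval).
* **ZC** is the strict sign-product test with no noise threshold, exactly
  as defined.

Columns are channel-major (`MAV_ch1 … MNP_ch1, MAV_ch2 …`); rows ordered
by (record, window start). Feature tables round-trip through CSV
bit-for-bit (floats serialized at shortest-round-trip precision and parsed
with `float_precision="round_trip"`).

## Evaluation

The temporal split takes the first floor(0.7·n) windows of each gesture's
contiguous block for training — per-class rather than global so all six
classes appear on both sides (a global split option exists). Precision,
recall and F1 are support-weighted averages of per-class values; weighted
recall then equals accuracy exactly, an identity the tests assert on every
report. The split-score diagnostic S_c = 2I/(H_split + H_class) uses
base-2 entropies (the normalization makes S_c base-invariant). The paired
t-test is two-sided (`scipy.stats.ttest_rel`) and refuses zero-variance
difference vectors. Cross-session evaluation trains on one session's
windows and evaluates on each other session in full.

The classifier backends are scikit-learn estimators behind a name
registry ("ET" featured; ADB/BAG/DT/GB/KNN/LR/NB/RF/SVM registered);
Extra-Trees internals are deliberately not re-implemented — the
contribution here is the tuning framework, with the split score kept as an
authored diagnostic.

## L-SHADE

The optimizer maximizes a black-box objective over [0, 1]^N; integer
dimensions decode as round(lo + g·(hi − lo)), categoricals as
floor(g · n_levels) (clamped).

Per-trial control parameters: memory index k ~ U{1..H} (H = 6 cells, all
initialized at 0.5); SF ~ Cauchy(M_SF[k], 0.1), resampled while ≤ 0 and
clipped to 1; CR ~ N(M_CR[k], 0.1) clipped to [0, 1]. Mutation is
current-to-pbest/1 with an external archive of replaced parents (the
canonical strategy of this algorithm family), pbest fraction 0.11, archive capacity 1.4 × NP with uniform-random
eviction. Binomial crossover guarantees one inherited mutant coordinate;
out-of-box coordinates are repaired to the midpoint of parent and violated
bound. A trial replaces its parent when not worse; only strict
improvements record (SF, CR, |Δf|) successes. Memory cells update as
M ← c·M + (1 − c)·mean_wl with c = 0.5 and the Δf-weighted Lehmer mean —
the blended update (rather than the overwrite some variants use) is a
deliberate design choice kept exact. An empty success set
leaves the memory and its write index untouched.

Population size follows NP(NF) = round((NP_min − NP_max)/NF_max · NF +
NP_max), eliminating the worst-fitness members after each generation (ties
eliminate the older index first). Budgets can be capped in evaluations
(NF_max, the schedule's clock), in generations, or both; when only a
generation cap is given NF_max defaults to np_init × generations, so the
schedule then underestimates shrinkage — intentional, since a
generation-based cap is the natural reading of an "iterations" budget.

Hyperparameter tuning scores candidates by 3-fold contiguous-block
cross-validation accuracy within the training split (no test leakage); a
`holdout` protocol that scores candidates directly on the held-out 30 %
is available for studies that prefer that setup. A uniform random-search baseline at
the same budget is included for sanity comparisons, and the optimizer
interface (objective over a `HyperparamSpace`) is pluggable for other
metaheuristics.

## Synthetic data

The generator emulates the target acquisition: 6 gestures × 2 channels ×
2 kHz × 40 s, sessions and subjects. Each channel is white Gaussian noise
shaped by the package's own 20–450 Hz Butterworth design (reusing tested
components), multiplied by an envelope
`session_factor · amp(gesture, channel) · (0.6 + 0.8·burst(t)) · exp(drift)`,
plus 0.15 × a 50 Hz sinusoid and a 0.05 white noise floor. Bursts are
periodic (gesture-specific rate 2–5 Hz, duty 0.5). The drift term is an
AR(1) log-amplitude random walk (σ = 0.10, time constant 1 s) that smears
per-window amplitudes and creates class overlap; σ was calibrated once
against the stated target band for baseline accuracy (0.85–0.99) — the
default world gives ≈ 0.94 baseline Extra-Trees accuracy — and is not a
per-test knob. Session jitter is a deterministic multiplicative amplitude
factor in [1 − j, 1 + j] (j = 0.1) derived from a stable hash of
(seed, subject, session), so datasets are byte-reproducible from the seed.

What the generator does **not** model: motor-unit action potentials,
fatigue, electrode shift, inter-subject anatomy, or any nonstationarity
beyond amplitude drift. A green end-to-end test therefore establishes that
the pipeline's mechanics (filtering, windowing, features, split, tuning)
are correct and that tuning does not hurt on learnable data — not that
accuracy levels achievable on real recordings are reproduced.

## Numerical conventions

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical traces,
  reports and datasets.
* Feature-oracle agreement is asserted to 1e-10 relative (time domain) and
  1e-8 (frequency domain); filter linearity to 1e-9 of signal scale.
* Non-finite objective values are treated as worst-possible with a warning
  rather than aborting an optimization run.
* `round` is IEEE banker's rounding throughout (numpy/python default);
  window geometry and the LPSR schedule inherit it.

## Known limitations

* Causal filtering leaves an edge transient inside the first windows of
  each record; zero-phase mode avoids it at the cost of acausality.
* The reduced tuning budgets used in tests (population 20, 20 generations)
  are far below what a full study would spend (hundreds of generations
  over tens of independent runs); at desk scale tuning gains are
  accordingly fractions of a point, not several.
* The t-test helper accepts any paired accuracy vectors; with few subjects
  and near-constant gains the difference variance can legitimately
  degenerate, which raises rather than fabricating a statistic.
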