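# wingbeam

Signal analysis for bistatic optical insect sensors: from a raw
transmitted-light voltage stream to detected beam transits, per-event
wingbeat frequencies and optical extinction cross-sections, mosquito sex
classification, absolute aerial densities, trap-count comparison, and a
monitoring-network precision simulation.

## The problem

A bistatic optical sensor points a near-infrared laser across tens of
metres of open air at a photodetector. Every insect that crosses the
beam scatters, diffracts and absorbs light, producing a transient dip in
the received voltage — a *transit signal* — with the wingbeat
superimposed as a harmonic-rich oscillation. One such instrument can
observe thousands of insects per day, continuously and automatically,
which makes it an attractive complement to physical traps for mosquito
surveillance: traps give species-level taxonomy but only a coarse
count-per-day index, while the optical record resolves abundance at
one-minute resolution.

`wingbeam` implements the full analysis chain for such instruments, and
a synthetic-signal generator with exact ground truth so every stage is
testable without field data.

## The method

**Detection.** The background level V0(t) is tracked by a decimated
rolling median; candidate transits are contiguous runs where the signal
drops below V0 by more than k robust noise SDs. Events shorter than
10 ms are discarded (too few wing cycles), events approaching 1 s are
kept but not treated as insects. An event is an *insect* only if its
envelope-detrended spectrum shows a prominent peak in the 10–900 Hz
wingbeat band — rain droplets and other smooth objects fail this test.
During heavy rain the signal is continuously perturbed and detection is
impossible; that time is flagged invalid and excluded from the
observation time rather than zero-filled.

**Per-event features.** The transmitted voltage touches the body-only
level between wingbeats, so interpolating through the local voltage
maxima recovers the body envelope and the remainder is the wing
component. With Vw and VB the mean of the 10% lowest values of the
wing-contribution and body-envelope signals, and A the beam
cross-section area:

    sigma_w = (V0 − Vw) / V0 × A
    sigma_B = (V0 − VB) / V0 × A
    sigma_w/b = sigma_w / (sigma_w + sigma_B)

The wingbeat frequency f_w is the fundamental of the transit spectrum
(Hann window, 8× zero-padding, parabolic peak interpolation, harmonic
consistency checks to avoid picking the first harmonic).

**Classification.** In (f_w, sigma_w/b) space mosquitoes stand out with
high frequency and low wing-to-body ratio: females ≈ 250–400 Hz, males
≈ 350–700 Hz. Rectangular configurable gates assign each event a
cluster label.

**Aerial density.** Counting transits over-represents fast fliers; the
summed transit time does not:

    rho_a = Σ_i Δt_i / (T · V)        [insects / m³]

with V = π(d/2)²L the probe volume and T the (valid) observation time,
choosable from minutes to weeks.

**Trap comparison and network precision.** Trap catches become counts
per day (catch / days since last collection, averaged over traps); the
density series is averaged over the same collection intervals and the
paired series correlated. Seasonal abundance is modelled as an
exponential cubic exp(β0 + β1·t + β2·t²) on day-of-year t, fitted by
negative-binomial regression for counts and by OLS on log densities; a
paired simulation with the seasonal curve scaled by 1.05 measures how
precisely networks of 1–16 devices resolve a 5% abundance change, and
spread-matching across device counts yields device-equivalence factors.

## Worked example

```python
import numpy as np
import wingbeam as wb

rng = np.random.default_rng(0)
events = []
for i in range(40):
    female = i % 2 == 0
    fw = float(rng.normal(300, 30)) if female else float(rng.normal(524, 65))
    ratio = float(rng.normal(0.27, 0.07)) if female else float(rng.normal(0.19, 0.05))
    body = float(rng.uniform(0.2, 0.4))
    wing = wb.wing_depth_for_ratio(np.clip(ratio, 0.02, 0.9), body, 0.1, fw)
    events.append(wb.TransitParams(1.0 + 1.4 * i, 0.1, fw, body, wing))

scenario = wb.StreamScenario(duration=60.0, noise_sd=0.005,
                             events=tuple(events), seed=7)
segment, truth = wb.simulate_stream(scenario)
features, series, runlog = wb.run_pipeline(segment)

print(f"events detected : {runlog.n_raw_events}")
print(f"labelled insect : {runlog.n_insect}")
print(f"clusters        : {runlog.cluster_counts}")
print(f"aerial density  : {series['all'].density[0]:.3f} insects / m^3")
```

prints

```
events detected : 40
labelled insect : 40
clusters        : {'female_mosquito': 20, 'male_mosquito': 19, 'other_insect': 1}
aerial density  : 0.901 insects / m^3
```

All 40 injected transits are found and labelled insect; 39 of 40 land in
the correct sex gate (one male drawn in the unassigned 400–425 Hz band
between the gates falls back to `other_insect`). The density is the
summed transit time (40 × ~0.1 s) over one minute of observation and the
73-litre probe volume. The per-event table carries `fw_hz`,
`sigma_w_m2`, `sigma_b_m2` and `ratio_wb` per event; on this stream the
female events average 309 Hz with mean ratio 0.29 and the males 531 Hz
with 0.19, matching the generator's field-population settings.

A command-line surface mirrors the library:

```sh
wingbeam simulate --duration 60 --event-rate 0.5 --seed 7 --out stream.txt
wingbeam detect --in stream.txt --out events.csv
wingbeam features --in stream.txt --out features.csv --classify
wingbeam power --model fitted.json --devices 1,2,4,8,16 --reps 10000 --seed 7 --out power.json
```

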