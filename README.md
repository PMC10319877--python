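# pedtraj

Processing and validation of high-resolution pedestrian GPS commute
trajectories: kinematic featurisation, staged cleaning, spatial
k-anonymity geomasking with a quantitative disclosure-risk model, 1 Hz
linear resampling, and the movement statistics used to validate that the
processing preserves the dynamics.

The package targets purposed-based micro-mobility data — trips with a
fixed origin and destination, such as students walking between home and
school — collected at ~1 Hz by phone apps in citizen-science settings.
Such data is noisy (GPS activation spikes, indoor accumulation, gaps),
contaminated (vehicle trips among walkers), and privacy-sensitive (the
home end of a trace reveals where someone lives). `pedtraj` gives
researchers in human mobility, movement ecology and spatial epidemiology
a tested, reproducible version of the whole chain, plus a labelled
synthetic-cohort generator so every stage can be verified without any
collected data.

## The model

For fixes r(t) at irregular timestamps, step quantities use the
time-advanced convention (index *i* spans fixes *i* and *i*+1):

    d(t) = |r(t + Δt) − r(t)|,   v(t) = d(t) / Δt,
    D = Σ d(t),   T = Σ Δt,   v_eff = D / T

with great-circle distances (mean Earth radius 6 371 008.8 m).

**Cleaning** runs in five fixed stages over a cohort:

1. *Non-pedestrian removal* — declared vehicle modes are dropped; trips
   with no declared mode are dropped when v_eff exceeds a walking
   plausibility cap (default 2.5 m/s).
2. *Origin–destination validation* — a valid commute has exactly one
   endpoint within 150 m of the school, ≥ 30 fixes, and a net
   displacement of at least twice that radius (rejects fix clouds
   scattered around the school).
3. *Outlier clean-up* — records implicated in velocity spikes
   (> 10 m/s on both adjacent steps; activation bursts can exceed
   90 m/s) or poor accuracy (> 100 m) are deleted iteratively to a
   fixed point; a terminal indoor dwell cluster collapses to its first
   fix; trips with too high a spike fraction are discarded whole.
4. *Geomasking* — the first (home→school) or last (school→home)
   *t* seconds of movement are stripped, *t* drawn uniformly on the
   integers [20, 50] per trip. With housing density ρ (units/km²) and an
   assumed walking speed v = 1.5 m/s, the masked endpoint is consistent
   with k = ρ·π·(v·t)² housing units, so the disclosure risk — the
   probability of pointing at the right home — is **1/k**.
5. *1 Hz linear interpolation* — a fix at every integer second; original
   fixes preserved, Δt ≡ 1.0 and d ≡ v afterwards.

**Validation statistics** over a cohort: the velocity distribution p(v);
the log-velocity u = ln(v/v_m) with v_m the trip mean; the mean squared
displacement MSD(τ) = E[|r(t+τ) − r(t)|²] ((vτ)² for ballistic motion);
and the autocorrelation C(τ) of u, normalised per trip so C(0) = 1, with
bootstrap confidence intervals over trajectories.

## Worked example

Generate a labelled synthetic cohort (80 participants, 10 schools,
realistic gaps/noise/contaminants), run the full pipeline, and
reconstruct the disclosure-risk table:

```
$ pedtraj simulate --out raw/ --seed 4
wrote 80 raw trajectories + truth ledger to raw/

$ pedtraj process --input raw/ --out run/ --seed 4
processed 59 trajectories (22138 records); interpolated 27990 records; 0 quarantined

$ pedtraj risk
Sarrià             6.105 km²    74729 units    12240.62 /km²  1/k = 0.00462
Ciutat Vella       1.296 km²    55663 units    42949.85 /km²  1/k = 0.00132
Horta-Guinardó     2.898 km²    78367 units    27041.75 /km²  1/k = 0.00209
Sant Andreu        1.906 km²    70056 units    36755.51 /km²  1/k = 0.00154
L'Eixample         3.719 km²   143403 units    38559.56 /km²  1/k = 0.00147
L'Hospitalet       3.010 km²   111363 units    36997.67 /km²  1/k = 0.00153
Sants-Montjuïc     2.516 km²    90449 units    35949.52 /km²  1/k = 0.00157
Sant Martí         2.889 km²   111536 units    38607.13 /km²  1/k = 0.00147
Viladecans         3.811 km²    24221 units     6355.55 /km²  1/k = 0.0089
mean disclosure risk <1/k> = 0.00272
```

The `process` run keeps 59 of 80 trips: vehicle and scatter contaminants
are removed by stages 1–2, spike-dominated trips by stage 3, and the
geomask then strips 20–50 s from the home end of each survivor (the
per-school reduction is written to `run/geomask_reduction.csv`, about
8–12% of records). The risk table says that stripping t = 50 s at
v = 1.5 m/s leaves each masked endpoint ambiguous among k ≈ 110–760
homes depending on district — an average disclosure risk ⟨1/k⟩ of
2.72 × 10⁻³.

The same operations are available as a library; the stages are
scikit-learn style transformers over lists of `Trajectory`:

```python
from pedtraj import (CohortSpec, generate_cohort, NonPedestrianFilter,
                     OutlierRemover, summarize)

trajs, truth = generate_cohort(CohortSpec(rng_seed=4))
kept = NonPedestrianFilter(v_nonped=2.5).fit(trajs).transform(trajs)
cleaner = OutlierRemover().fit(kept)
clean = cleaner.transform(kept)
print(cleaner.report_.n_records_removed, "records removed")
print(round(sum(summarize(t).v_eff for t in clean) / len(clean), 2), "m/s mean v_eff")
```

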