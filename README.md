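# entolidar

Unsupervised insect-diversity analysis for entomological lidar surveys, with
a synthetic survey simulator that makes every stage testable without field
data.

An entomological lidar records the light an insect scatters while crossing a
static near-infrared beam: a short, nonnegative two-channel (co- and
de-polarized) intensity transient with a smooth body-glint envelope and a
periodic wing-glint modulation on top. Species cannot be read off such a
signal directly, but the *modulation power spectrum* — harmonic structure set
by the wingbeat fundamental and the wing's specularity — is a strong
optical fingerprint. This package implements the full analysis chain used to
turn tens of thousands of such transits into vertical- and diel-stratified
richness estimates:

1. **Observation selection** — keep transits with duration > 25 ms and at
   least 80 samples per channel (resolving wingbeats down to 80 Hz, and the
   40 Hz edge of the analysis band).
2. **Features** — 80 modulation powers on log-spaced bins from 40 Hz to the
   1666 Hz Nyquist limit; the wingbeat fundamental by a harmonic-comb search
   on a zero-padded periodogram; the degree of linear polarization
   (Pco − Pde)/(Pco + Pde).
3. **Diversity (NoC)** — pairwise distance between spectral *shapes*
   D(a,b) = √ Σ_f ( log(Pa(f)/ΣPa) − log(Pb(f)/ΣPb) )², hierarchical
   clustering, detrending of the linkage sequence Z(p) (sorted in descending
   order) by Z_comp(p) = ((N−1)/p)^β Z(p) with β the median log-log slope,
   and NoC = #{ Z_comp(p) > median + IQR } — the number of merges that break
   above the scale-free trend, a species-richness proxy. Instrument-noise
   fragments pushed through the identical pipeline bound the spurious count
   (negative control).
4. **Stratification** — events mapped to shrub (< 2.5 m) / canopy
   (2.5–25 m) / open-sky (≥ 25 m) layers via beam geometry and to
   dawn/diurnal/dusk/nocturnal classes; activity per 10-min bin compensated
   by the instrument's operational fraction; ternary composition diagrams;
   independent per-(day, layer) clustering runs.

The synthetic generator emulates the survey conditions: insect classes with
distinct fundamentals and harmonic richness, a scanning schedule cycling
seven elevation angles with repositioning pauses and four daily ~7-min
refuel gaps (≈12% duty cycle), Poisson arrivals modulated by diel activity
profiles, and pure-noise fragments.

## Worked example

```sh
python examples/diversity_estimate.py
```

```
observations: 703 from 5 true classes
NoC = 5   (beta = -0.182, threshold = 5.71)
noise control NoC = 0  (from 300 pure-noise fragments)
```

Five separable synthetic classes yield NoC = 5 distinguishable spectral
groups, while 300 pure-noise fragments through the identical pipeline yield
0 — the negative control confirms the count is not an artifact of the
clustering itself. See also `examples/wing_signals.py` (wingbeat and
polarization features: the three reference wing types at 80, 178 and 208 Hz
are recovered to a fraction of a Hz), `examples/survey_simulation.py` (the
12% duty cycle and the observation funnel) and
`examples/stratification_report.py` (per-layer, per-day diversity tables).

The same pipeline is scriptable from a shell:

```sh
entolidar run-all --seed 7 --out-dir runs/demo
```

writes the signal container (HDF5), events table (TSV), spectra matrix,
cluster results (JSON) and the report directory (activity, ternary and
diversity tables plus figures); reruns with the same seed are byte-identical.

## Limitations

NoC counts *distinguishable spectral groups*, not species. When within-class
wingbeat spread approaches the spacing between classes (the ~25%
within-species variation reported for real insects), class manifolds blend
into a continuum and the statistic deliberately reports fewer groups; it
also saturates for many (≳20) simultaneously present groups. See
`docs/methods.md` for the full analysis.
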