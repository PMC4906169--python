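# golgiring

Quantitative image analysis of Golgi-localized cellulose synthase (CesA)
trafficking, for plant cell-biology groups doing spinning-disc confocal and
immuno-TEM work on cellulose synthase complexes (CSCs).

In *Arabidopsis* hypocotyl cells, Golgi-resident GFP-CesA3 normally appears
as a peripheral **ring**; when CSC assembly is perturbed the signal collapses
into a **solid** sphere. This package implements the full analysis chain used
to quantify that phenotype and the downstream CSC behaviour:

- **Ring/solid morphometry** (`golgiring.profiles`): a transect through each
  Golgi body gives a 1D intensity profile; a peak-finding rule classifies it
  (1 peak → solid, 2 peaks → ring, otherwise rejected). Profiles are fitted
  with a two-Gaussian model

  `I(x) = b + A1·exp(−(x−μ1)²/2σ1²) + A2·exp(−(x−μ2)²/2σ2²)`

  with the separation μ2−μ1 free for rings and fixed to the microscope
  resolution limit (266 nm) for unresolved solids. The object diameter is
  `(μ2−μ1) + FWHM(σ1) + FWHM(σ2)`.
- **FRAP delivery-rate scoring** (`golgiring.frap`): new CSC insertion events
  in a post-bleach plasma-membrane movie are scored by two criteria — an
  empty neighbourhood before appearance and persistent tracking afterwards —
  inside a central subregion, giving a delivery rate in foci·μm⁻²·h⁻¹.
- **Foci tracking and speeds** (`golgiring.tracking`): LoG spot detection,
  greedy nearest-neighbour linking, and kymograph-slope speed estimation in
  nm·min⁻¹ (unbiased under localization noise, unlike mean step length).
- **Co-localization and immuno-gold statistics** (`golgiring.coloc_gold`):
  thresholded Manders M1/M2 coefficients, and the periphery statistic
  `d_rel = |s − L/2| / L` of gold particles projected on the Golgi long axis.
- **Synthetic ground truth** (`golgiring.synth`): seeded generators for
  PSF-blurred ring/solid populations, Poisson-timed insertion movies,
  constant-velocity track sets, two-channel pairs and gold-particle tables,
  with named presets (`wt_golgi`, `stl_golgi`, `wt_frap`, `stl_frap`,
  `wt_speed`, `stl_speed`) carrying the published population parameters.

## Worked example

`examples/01_ring_solid_classification.py` generates 820 synthetic profiles
at the mutant-condition composition (54% solid) and recovers it:

```
objects analysed:        820
classified ring/solid:   373/447 (0 rejected)
percent solid:           54.5% (generative: 54%)
mean object diameter:    1141 nm
median object diameter:  1162 nm
```

`examples/02_frap_delivery_rate.py` scores a simulated 10-min post-bleach
movie at the wild-type delivery rate:

```
movie:            121 frames of 150x150 px
true insertions:  329 over the whole field
scored events:    107 (central subregion only)
delivery rate:    4.92 foci/um^2/h (generative: 4.8)
```

The remaining examples cover speed estimation (slope 251.1 vs stepwise
1094.0 nm/min at 50 nm localization noise — the reason slope is the
default), Manders coefficients on a half-overlapping pair (M1 ≈ M2 ≈ 0.5),
and the gold periphery statistic (uniform median d_rel ≈ 0.24 vs 0.12 for
centrally confined cargo).

A thin CLI mirrors the library for file-based runs:

```sh
golgiring simulate --preset wt_frap --seed 1 --out run/
golgiring frap --movie run/frap_movie.tif --interval 5 --out run/
```

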