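# cmphs-access

Spatial accessibility of **continuous maternal and perinatal health care
services (CMPHS)** for women of reproductive age in low-resource settings.

Maternal and perinatal health outcomes depend not on single interventions
but on a *continuum* of three service packages — antenatal care (ANC),
institutional delivery (ID), and postnatal care (PNC) — and in much of
sub-Saharan Africa the binding constraint on receiving them is plain
geography: how long a woman must walk to the nearest facility that can
actually deliver each package. This package implements a two-step
procedure for quantifying that constraint from a national facility census
(SARA-style readiness indicators), a gridded demand raster, and
administrative population totals. It is aimed at health-systems and
spatial-epidemiology researchers who need a reproducible, testable version
of this analysis for their own settings.

## Method

**Step 1 — facility capability.** Each facility carries one boolean
readiness flag per indicator from a fixed catalog of 25 indicators
(7 ANC, 8 ID, 10 PNC). A facility is *capable* of package
*S* under the default rule when every indicator of *S* is present
(`all`; `any` and `at_least_k` are available as options).

**Step 2 — spatial access.**

1. *Demand.* A gridded density proxy G (≈1 km² cells) is rescaled so each
   administrative region *j* matches its announced count T_j of women of
   reproductive age:

   P_ij = T_j · G_ij / G_j,   with G_j = Σ_i G_ij over region j,

   which conserves regional totals exactly while preserving the
   within-region settlement pattern (dasymetric redistribution).
2. *Travel time.* For every cell and every package, the nearest-neighbor
   method: time = (haversine distance to the nearest capable facility) /
   walking speed, with defaults of 4 km/h and a 2-hour timeliness
   threshold (closed inequality). A planar metric is available for
   projected inputs.
3. *Overlay.* The three timely-access masks combine into 8 multilevel
   access-zone types — type 1 = timely access to all of ANC+ID+PNC,
   types 2–4 = two packages, types 5–7 = one, type 8 = none — with the
   percent of land area and of women of reproductive age in each type.
4. *Regional summary.* Population-weighted median, IQR, maximum, and mean
   travel time per region and nationally, per package.

Because the real census and raster inputs for such studies are typically
not redistributable, the package ships a deterministic synthetic-scenario
generator (regions, clustered density, facility network with realistic
per-indicator readiness prevalences) plus closed-form "known truth"
scenarios used by the test suite.

## Worked example

```bash
cmphs simulate --seed 7 --out data      # synthetic census + raster + totals
cmphs run --config run.yaml             # run.yaml points at data/, out_dir: out
```

`out/zone_shares.csv` from this run:

```
type,description,area_pct,pop_pct
1,"Able to obtain timely CMPHS (ANC, ID, and PNC)",0.0,0.0
2,Able to obtain timely ANC and ID,2.51,6.18
3,Able to obtain timely ANC and PNC,0.8,2.77
4,Able to obtain timely ID and PNC,0.0,0.0
5,Able to obtain timely ANC,17.04,26.86
6,Able to obtain timely ID,2.68,6.5
7,Able to obtain timely PNC,0.92,0.99
8,Not able to obtain timely CMPHS,76.05,56.69
```

Reading: under this scenario's facility readiness rates, 56.69% of women
of reproductive age (76.05% of the land area) cannot reach *any* package
within 2 hours' walk, and nobody has timely access to the full continuum —
ID and PNC capability is rare because the `all` rule requires every one of
the package's 8 (resp. 10) indicators. `out/regional_times.csv` holds the
per-region medians, e.g. nationally the ANC median is 2.82 h (IQR
1.52–4.85 h) while ID is far worse because few facilities pass all eight
ID indicators. The other outputs are the per-indicator coverage and
per-level capability reports, the demand and travel-time grids, the zone
raster, and `manifest.json` (parameters, seed, input checksums) from which
the run is byte-for-byte reproducible.

Every subcommand (`simulate`, `classify`, `redistribute`, `access`,
`overlay`, `summarize`, `run`) is a thin wrapper over the library API
(`cmphs_access.*`), which you can use directly from Python.

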