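# Methods

`oceangap` implements a global marine-biodiversity gap-and-driver analysis
as a tested pipeline: occurrence quality control, equal-area hexagonal and
latitudinal binning by depth zone, bias-corrected richness estimation,
modality testing of latitudinal gradients, and AIC-ranked driver models.
Because the real inputs of such analyses (OBIS/GBIF extracts, climatological
rasters) are tens of millions of records, every stage here is validated on a
synthetic ocean world with exact ground truth instead. This note records the
models, the parameters that matter, and the design choices that were
genuinely open.

## Spatial and bathymetric frames

**Hexagonal grid.** The analysis unit is an icosahedral, aperture-4 discrete
global grid: cell count 10·4^r + 2, with resolution r = 3 giving 642 cells
(630 hexagons + 12 pentagons at the icosahedron vertices) of mean area
4πR²/642 ≈ 7.94×10⁵ km² on a spherical Earth of R = 6371 km — the
"~800,000 km²" cells used for global binning. Construction: each icosahedron
face is mapped to a planar equilateral triangle by an equal-area projection
of the Snyder type, derived by matching cumulative sector areas. For azimuth
a from the face centre (within one of six 60° symmetry sectors), the
spherical area swept up to the face edge has the closed form
E(a) = a + G + H(a) − π with G = 36° (half the face angle at a vertex) and
H(a) = arccos(sin a · sin G · cos g − cos a · cos G), g the centre-to-vertex
angular distance; the planar azimuth is matched so the planar sector sweeps
the same area fraction, and the radial coordinate scales as
√((1−cos z)/(1−cos z_edge)). The forward map is closed-form; the inverse
solves the 1-D equation E(a) = const by bracketed root-finding.

The hexagons are the Voronoi cells of the aperture-4 triangular lattice
*in the equal-area plane*, so cell areas are exact by construction: all
hexagons are identical, pentagons are exactly 5/6 of a hexagon, and areas
sum to exactly 4πR². Cell membership of a point is likewise exact: project
the point into its face's plane and take the nearest lattice point (the
planar hexagon containing it). A consequence worth noting: the cells are
*not* spherical Voronoi cells of their centres, so nearest-centre assignment
would mislabel ~2% of points near edges; the planar rule avoids this. Cell
boundaries are straight in the projection plane and gently curved on the
sphere; exported polygons (GeoJSON) densify each edge at thirds, which keeps
point-in-polygon agreement with the exact rule at ~99.95% (the residual is
chord error of the densified polygon, not assignment error). The grid is
oriented with an icosahedron vertex at the north pole, so both poles fall in
pentagon cells and cell ids are reproducible (sorted north to south).

**Bands and zones.** Latitude is binned into 36 half-open 5° bands (the top
band closed at 90°). Depth zones are shallow [0, 200) m, mesopelagic
[200, 500) m, deep [500, 11000] m; the shared boundary values belong to the
deeper zone (a record at exactly 200 m is mesopelagic). Records without
depth form an "unknown" zone excluded from depth-specific analyses but kept
in pooled ones. Continental shelf is bathymetry 0–≤140 m; continental margin
>140–3500 m; raster cell areas are the exact spherical quadrangle areas
R²·Δλ·(sin φ₂ − sin φ₁). Covariate aggregation reports per cell/band the
ocean, shelf and margin areas, maximum depth, and area-weighted mean
plus min/max of each environmental layer (nodata cells excluded). A cell
with fewer than 50 records is an under-sampled "gap"; gap summaries report
the ocean-area fraction in gap cells per zone.

## Quality control

Raw Darwin-Core-style tables are reduced to accepted marine/brackish animal
records by rules applied in a fixed order — duplicates (key: name,
coordinates, depth, date, dataset; uncertainty metadata deliberately
excluded), absence records, fossils, invalid coordinates (lon 180°
normalised to −180°), on-land points (raster cell of the point is land;
half-open cells with the floor convention), depth exceeding local bathymetry
by strictly more than 50 m (records without depth unaffected), coordinate
uncertainty strictly above 100 km (missing uncertainty kept), and taxon
matching (exact string against a registry; synonyms resolved to accepted
names; non-marine-or-brackish and non-animal taxa dropped). The fixed order
makes removal attribution deterministic: each record is counted under its
first failing rule and `records_in − Σ removals = records_out` holds
exactly. QC is idempotent, and tightening either threshold can only shrink
the surviving set. A lat=lon=0 "doubtful coordinate" rule exists but is off
by default, since beyond that heuristic the notion is not well defined.

## Richness and diversity measures

Per unit (cell or band), zone, and optionally phylum: record count, observed
species S_obs, and four bias-aware estimators.

- **ES50 (Hurlbert rarefaction)**: ES_n = Σ_i [1 − C(N−N_i, n)/C(N, n)],
  the expected species count in a hypergeometric draw of n = 50 of the N
  records; binomial ratios are computed in log-space (gammaln) so large N is
  exact to double precision. ES50 is undefined (null) when N < 50 — such
  units are precisely the under-sampled gaps.
- **Chao2** (incidence-based), always in the bias-corrected form
  S_obs + ((m−1)/m)·q₁(q₁−1)/(2(q₂+1)), which is defined when q₂ = 0; the
  classic q₁²/(2q₂) variant is never used. The incidence sample unit within
  a spatial unit is a distinct (dataset, event date, coordinates rounded to
  0.1°) tuple — a deterministic proxy for a sampling event, which real
  archives do not delimit unambiguously.
- **ACE** with the standard rare/abundant split at ≤10 individuals, sample
  coverage C = 1 − F₁/N_rare, and squared coefficient of variation
  γ² = max((S_rare/C)·Σk(k−1)F_k/(N_rare(N_rare−1)) − 1, 0). When every
  rare species is a singleton (C = 0) the bias-corrected Chao1 of the full
  vector is returned.
- **Inverse Simpson** 1/Σp_i².

Occurrence records stand in for individuals in the abundance-based
estimators. That is the standard practice when occurrence archives are fed
to abundance-based functions, and a known caveat: record counts conflate
abundance with sampling, which is exactly why ES50 is the headline
bias-corrected measure. ES50 and ACE were cross-checked during development
against the vegan reference implementations to printed precision; the test
suite pins those values and additionally checks ES50 against a seeded
Monte-Carlo rarefaction oracle (agreement < 0.02 at 10⁵ draws).

## Gradient profiles and modality tests

Latitudinal (5° bins, 10° Gaussian KDE bandwidth) and bathymetric (10 m
bins, 20 m bandwidth) profiles carry per-bin record counts, S_obs and ES50.
The KDE is the exact Gaussian mixture (no grid renormalisation), so its mass
on a sufficiently wide grid is 1 to <0.1%.

**Anderson–Darling** composite normality uses the estimated-parameter
statistic A*² = A²(1 + 0.75/n + 2.25/n²) with the Stephens
piecewise-exponential p-value approximation (the convention of the usual
normality-test packages; verified against the R reference to 7 digits).

**Hartigan's dip** is computed exactly by the iterative greatest-convex-
minorant / least-concave-majorant algorithm (all arithmetic in ECDF counts;
the candidate modal interval shrinks to the largest GCM–LCM gap until the
accumulated outside misfit dominates). The implementation was validated
against an exhaustive LP oracle — for each candidate mode position the
nearest unimodal CDF is a linear program over band constraints at the data
points — with exact agreement on hundreds of random samples (n = 4–60,
unimodal and multimodal), and reproduces the two-point-mass limit D = 0.25.
The null is Monte-Carlo: p = (1 + #{D_b ≥ D})/(n_boot + 1) with D_b from
U(0,1) samples of the same n (default n_boot = 2000). Null tables depend
only on n and are cached and shared across tests.

Modality is tested on two views, neither privileged: (1) raw per-record axis
values, i.e. the effort-weighted distribution (tables larger than 1000 are
subsampled, seeded, so the Monte-Carlo null stays tractable; power at
n = 1000 is ample for global gradients); (2) the binned ES50 profile,
converted to a pseudo-sample of 2 points per bin (≈72 for latitude,
largest-remainder quotas with within-bin jitter). The small pseudo-sample is
deliberate: a 36-bin profile carries only bin-level information, and a large
pseudo-sample would let the dip test "significantly" reject on within-bin
structure the profile cannot resolve. The reported n makes the resolution
explicit.

## Driver models

**Collinearity screen.** Pairwise Pearson correlations; for any pair with
|r| ≥ 0.95 the lower-priority member is dropped, with priority
temperature > productivity > nitrate > O₂ > everything else. Only the
temperature-over-O₂ preference is scientifically anchored (their
correlation is ≈1 in surface and mesopelagic water, where O₂ solubility is
temperature-controlled); the rest of the order is a convention. Constant
covariates are excluded with a warning.

**Per-band GLMs.** Single-covariate Poisson GLMs (log link) of band species
counts, plus an intercept-only null; covariates are z-scored. Sampling
effort (log record count) competes as its own candidate covariate for the
count response — treating effort as a rival explanation rather than a fixed
offset — and an offset mode is available behind a flag. ES50 responses are
continuous and use a Gaussian family on the same machinery, excluding the
effort covariate (rarefaction already controls effort). Log-likelihoods keep
all constants (ln y!), so AIC is comparable across models. Fitting is
delegated to statsmodels' IRLS; the test suite cross-checks it against
direct numerical maximisation of the handwritten Poisson likelihood.
Suites are ranked by AIC; ΔAIC ≤ 2 defines the inconclusive "best set"
(ties broken by AIC then fewer parameters), and Akaike weights
exp(−Δ_i/2)/Σ exp(−Δ_j/2) are reported and sum to 1.

**Per-cell GAMs.** Written from scratch as penalized regression: each
covariate gets a centred cubic B-spline basis (k = 5, knots at quantiles)
with a second-difference penalty plus a small shrinkage ridge, so λ → ∞
removes the term entirely (the penalized-regression analogue of automatic
term selection); spatial autocorrelation is absorbed by a great-circle
radial basis (Gaussian in arc distance, length scale = median knot spacing)
on 50 farthest-point-sampled knots with a ridge penalty. The family is
negative binomial (log link) for counts — the cell tables contain genuine
zeros — with θ profiled over a log-spaced grid (0.1–100) by maximum
likelihood; smoothing parameters minimise GCV = n·D/(n − edf)² by
coordinate search over a log-spaced grid. Effective degrees of freedom are
tr[(XᵀWX + S)⁻¹XᵀWX], reported per term; AIC uses edf + 1 (for θ).
Predictions carry delta-method 95% intervals from the penalized posterior
covariance, and out-of-range covariate values are flagged as extrapolation.
This is an approximation of an exact-REML thin-plate/spline-on-the-sphere
fit, traded for a dependency-free implementation; acceptance is therefore
parameter recovery on synthetic data (smooth-effect correlation with truth
r ≥ 0.9; pure-noise smooths shrink below 1.5 edf), not coefficient equality
with any external smoother. One structural caveat: a spatial smooth over
(lat, lon) can absorb any latitude-only effect, so latitude-effect recovery
is assessed without the spatial term; the covariate-driver models keep it.

The GAM candidate suite mirrors the GLM suite (null, one single-smooth model
per retained covariate — each with the spatial term — plus an all-terms
model); the published analyses do not enumerate their GAM candidate set, so
this mirroring is an interpretation, stated as such.

## Synthetic world

The generator defines the study conditions; defaults were chosen once to
emulate the statistical structure of real occurrence archives at desk scale.

- **World**: 2.5° rasters; land = top 30% of a smooth random field (a few
  contiguous continents); ocean depth grows away from land into (0, 11000] m
  so shelves (≤140 m) exist; temperature falls with |latitude|
  (r < −0.98); nitrate rises with depth (remineralisation); surface and
  mesopelagic O₂ are exact affine functions of temperature (so the
  collinearity screen must remove them, as in real climatologies) while
  benthic O₂ is independent; productivity, radiation, currents, ice cover
  and a human-influence index round out the covariates, each tagged with a
  realm (surface / mesopelagic / benthic) matched to the depth zone being
  analysed.
- **Species pool**: 300 species in the 7 dominant marine animal phyla with
  skewed weights; depth-zone specialists 60/25/15%; log-normal mean
  abundances (σ = 1), the standard skewed species-abundance stand-in (the
  real archives' abundance structure is not characterised, so this is a
  stand-in, not an inference). Ranges are latitude-band-aligned rectangles
  with Gaussian-tapered abundance: bimodal truth places range centres at
  ±25° (width 10°), the flat configuration tiles the bands exactly so
  per-band true richness is constant; per-band truth is recorded exactly.
- **Sampling**: 20,000 records drawn location-first with probability ∝
  effort × cell area × locally available abundance. Effort is a clustered
  log-normal field times a northern-hemisphere factor (2.0) and an
  equatorial (|lat| ≤ 5°) deficit factor (0.15, emulating the central
  tropics' <2.5% contribution to global archives). The abundance factor
  makes record density track how much there is to record — under a flat
  gradient it is latitude-independent, so record counts remain effort-driven
  by construction; under a bimodal gradient record counts inherit the
  bimodality, as real archives' do. Record depth is the species' zone
  midpoint plus noise truncated to the zone and local bathymetry.
- **Corruptions** mutate disjoint record subsets after sampling, so per-rule
  ground truth is exact: duplicates (2%, appended copies), fossils (1%),
  absences (1%), on-land relocations (1%), depth set to bathymetry + 100 m
  (1%, beyond the 50 m margin), missing depth (7%, matching the ≈7% of real
  records lacking depth), synonym relabelling (5%), inflated coordinate
  uncertainty (1%). The registry carries one accepted row per species,
  20% synonym rows, and a few freshwater/non-animal decoys. One root seed
  feeds independent derived streams per component, so identical
  configurations are byte-identical and adding a corruption type does not
  perturb earlier draws.

What the generator does **not** emulate: real taxonomic composition,
temporal trends, dataset-level metadata beyond an id, coastline-hugging
sampling tracks, or spatially autocorrelated *residual* richness beyond the
range structure. Passing tests therefore demonstrate that the machinery is
correct and calibrated under controlled, favourable conditions — not that
the real-data conclusions are reproduced; the real headline numbers
(~48M records, 184,141 species, 15%/32% gap fractions) require the full
archives and are out of scope.

## Problem sizes and acceptance checks

The acceptance suite runs, per invocation: grid construction (seconds);
ES50 vs Monte-Carlo on 20 random vectors at 10⁵ draws; dip type-I error at
n = 100 over 500 replicates against a shared 2000-sample null, dip power
against a 4σ bimodal mixture at n = 200 (200 replicates), AD calibration
(1000 replicates); Poisson-GLM recovery at n = 36 bands over 200 replicates,
AIC ranking over 100, GAM smooth recovery over 20 seeds at 300 cells; and
the headline contrast over 20 synthetic worlds of 20,000 records each (flat
truth + equatorial deficit: the record-count profile must dip at the
equator while the dip test on the band-ES50 profile keeps unimodality).
These sizes were chosen as the smallest at which the checked rates are
stable; the full default pipeline run (simulate → models) takes well under
five minutes on one CPU.

## Known limitations

- Grid GeoJSON polygons are written in raw lon/lat; cells crossing the
  antimeridian or containing a pole render incorrectly in naive viewers
  (the geometry itself is correct and is what the assignment rule uses).
- The dip-test p-value is Monte-Carlo with a shared-per-n null table;
  p-values are therefore granular at 1/(n_boot + 1).
- The NB GAM's GCV/profile-θ search is a grid, not a continuous optimiser;
  λ and θ are only grid-optimal, and uncertainty bands do not account for
  smoothing-parameter uncertainty.
- Name matching is exact-string; misspellings are resolved only if present
  as registry rows. Live taxonomic services are out of scope.
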