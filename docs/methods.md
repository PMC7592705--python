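# Methods

This note documents the procedure `paloss` implements, the choices made
where the method description leaves the design open, what the synthetic
generator does and does not emulate, and the numerical conventions. It
states no empirical result that the test suite does not itself compute.

## The screening procedure

The unit of analysis is the fine geographic pixel (~0.00025°, the 30 m
analog) of the loss product's grid; all other layers are brought onto that
grid. For each pixel the pipeline decides, in order:

1. **Protection.** A pixel is protected when its center lies inside at
   least one retained PA polygon. Retained means: not fully marine
   (`MARINE = 2` dropped; coastal `MARINE = 1` kept, because its
   terrestrial forest is still analyzed), formally designated
   (`STATUS ∈ {Designated, Inscribed, Established}`; proposed-only records
   dropped), and polygonal (point-only records dropped). Every IUCN
   category is retained, including the three uncategorized labels. Where
   polygons overlap, the pixel is attributed to the most stringent
   category, ordered Ia < Ib < II < III < IV < V < VI < {Not Applicable,
   Not Assigned, Not Reported}; the three uncategorized labels tie and all
   ties break to the lower `WDPAID`. The ordering of the uncategorized
   labels below VI is a design choice — category semantics imply it, but no
   canonical order is published.
2. **Forest.** The pixel is forest when its year-2000 canopy percent is
   ≥ 50 (threshold configurable; the boundary is inclusive, so 50 is forest
   and 49 is not).
3. **Counted loss.** A forest pixel with loss year `y ∈ [2001, 2018]` is
   counted if it is unprotected, or if `y` is strictly greater than the
   winning PA's establishment year (`STATUS_YR`). The strict inequality —
   tallying from the year *after* designation, so loss in the
   establishment year itself is excluded — is the more conservative of the
   two plausible readings of the rule and is applied uniformly. A missing
   `STATUS_YR` (about a tenth of real records) is interpreted as
   establishment before 2001, so every analysis-year loss counts.
   Establishment filtering applies only to loss numerators, never to the
   year-2000 forest-area denominators.
4. **Follow-up class.** Loss in 2001–2004, 2005–2009 and 2010–2014 is
   assigned the land cover of the 2005, 2010 and 2015 epoch respectively at
   that pixel, after (a) containing-cell (nearest-neighbor) resampling of
   the ~300 m epoch raster to the fine grid — exact block replication when
   the grids nest — and (b) reclassification of the 22-class legend to
   seven classes: forest, shrubland, grassland, cropland, mosaic cropland
   (>50% cropland), mosaic vegetation (<50% cropland), other. Loss in
   2015–2018 is counted but labelled *unassigned*: no land-cover epoch
   follows it. Loss recorded at non-forest pixels (canopy below threshold)
   is ignored entirely — it enters no numerator and no denominator.

The shipped legend→class CSV is a reconstruction from the written
description of the consolidation (forest codes 50–90 plus flooded-forest
160/170; shrubland 100–122 plus 180; grassland 130; cropland 10–20; mosaic
cropland 30; mosaic vegetation 40; everything sparse/bare/urban/water/snow
to *other*); the exact published table is not available, so the map is an
editable input validated for totality against every raster it is applied
to. The ISO3→region table behind regional reporting is likewise a shipped,
editable default.

## Areas and reporting

Pixel areas use the spherical zone formula
`A = R² · Δλ · (sin φ_top − sin φ_bottom)` with the authalic Earth radius
`R = 6 371 007.181 m`, exact per grid row on the sphere; a grid tiling the
sphere sums to `4πR²` to rounding error. Areas are carried in hectares in
full precision; percentages (e.g. loss/forest, follow-up shares) are formed
and rounded (default one decimal) only at reporting. Strata with zero
denominator are omitted from percentage tables and logged, never emitted as
NaN. Country-level report tables omit countries with less than 1000 ha
(strictly less) of PA forest; the omission is reporting-only and never
changes regional or global totals. All CSV outputs are sorted by their
stratum keys, so identical configuration and inputs give byte-identical
outputs (recorded, with input checksums and the configuration hash, in
`manifest.json`).

## The synthetic world

The generator emulates the three inputs with exact per-pixel truth:

* **PA layer.** `n_pas` random axis-aligned rectangles (valid geometry by
  construction), each 10–35% of the grid extent per side; with probability
  `p_overlap` a new rectangle is centered inside an existing one,
  guaranteeing overlap. Configured fractions of records are made fully
  marine, proposed-only or point-only (mutually exclusive), and a fraction
  have no establishment year; otherwise establishment years are uniform on
  `establishment_year_range` (default 1990–2015, so establishment masking
  is actually exercised). IUCN categories are uniform over all ten labels;
  countries are drawn from a fixed twelve-country list spanning the
  shipped regions.
* **Canopy.** Per-pixel normal draw (default mean 70%, SD 25%) clipped to
  [0, 100] and rounded — enough mass on both sides of the 50% threshold to
  exercise the forest mask. No spatial correlation.
* **Loss.** Independent annual Bernoulli trials per pixel, 2001–2018, at
  `loss_rate_inside` where any valid polygon covers the pixel and
  `loss_rate_outside` elsewhere; the first success is the loss year. The
  defaults 0.00233 / 0.00720 solve `1−(1−p)^18` for 18-year loss fractions
  of 4.1% and 12.2% — the reported protected and global fractions — so the
  stated world has protection associated with less loss by construction.
* **Land cover.** One static background raster on the coarse grid (cell =
  `coarse_factor` × fine cell, default 12, the 300 m/30 m ratio; coarse
  dimensions round up so any fine size nests). For each epoch, every
  coarse cell containing at least one forest-loss pixel of that epoch's
  period is overwritten with a representative legend code of a class drawn
  from `followup_distribution` — one draw per (cell, epoch). The default
  distribution is the reported global follow-up mix (shrubland 0.47,
  cropland 0.22, mosaic vegetation 0.14, grassland 0.06, other 0.11, with
  the published cropland+mosaic-cropland agriculture bucket carried by
  cropland). By construction the truth class of every loss pixel equals
  the reclassified epoch code at its parent cell, which is what the
  pipeline recomputes.

Because follow-up classes are drawn per coarse cell, lost pixels in one
cell share a draw: empirical shares are a *weighted* mean of i.i.d.
categorical draws, and Monte-Carlo standard errors in recovery tests use
the effective sample size `(Σw)²/Σw²` over per-cell loss-area weights, not
the raw pixel count.

A green test on this world establishes that the pipeline implements the
stated rules exactly (the independent brute-force oracle re-derives every
table by literal per-pixel looping with no shared code), and that the
statistical machinery recovers configured rates and mixes. It does not
establish anything about real-data artifacts the generator omits: spatially
autocorrelated deforestation fronts and fire scars, mixed pixels at PA
boundaries, legend classes absent from the background mix, geolocation
error between products, or the published global magnitudes, which require
the full global datasets.

## Numerical and degenerate-case conventions

* Pixel-center containment uses strict interior containment; a polygon
  exactly aligned with cell edges covers exactly the cells whose centers it
  contains. Invalid (self-intersecting) polygons are repaired when a valid
  polygonal geometry can be extracted, otherwise rejected with the record
  id.
* The oracle-vs-pipeline "identical tables" check compares strata exactly
  and areas to 1e-9 relative: both sides sum the same float64 per-pixel
  areas, in different orders.
* Scenes with no PAs, with zero loss, or with no protected forest are
  legal: tables simply lack the corresponding rows, and zero-denominator
  percentage rows are omitted.
* Rasters: canopy and loss-year uint8 (loss 0 = none, k = year 2000+k),
  legend codes uint8, PA ids int32, follow-up codes uint8 (0 undefined,
  1–7 the classes in fixed order, 8 unassigned).
* All randomness flows from one seed through per-layer substreams
  (`numpy` `SeedSequence.spawn`), so adding a layer does not perturb the
  others and every output is reproducible byte-for-byte.
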