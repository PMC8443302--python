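# vesselquant

Quantification pipeline for microvessel-on-chip assays, with a
synthetic-phantom generator so every estimator is validated by parameter
recovery against known ground truth.

Stages:

| Stage | What it measures |
| --- | --- |
| `synthgen` (`vesselquant.phantoms`, `vesselquant.presets`) | Phantom movies/stacks with known ground truth: dextran leakage across a circular lumen wall, advected FRAP bleach spots, von Mises fiber textures, two-population nuclear z-stacks, projection/lattice images |
| `vesselquant.geometry` | Junction-network segmentation, monolayer continuity (connected components), vessel axis + diameter from projections, lumen-circle localisation |
| `vesselquant.permeability` | Diffusive permeability `P_d = (r / 2 I0) * dI_out/dt` from lumen/exterior intensity traces with an early-time fit window |
| `vesselquant.frap` | Subpixel bleach-spot tracking, interstitial flow velocity, hydraulic permeability `k = v mu L / dP` (heads given in mmH2O) |
| `vesselquant.alignment` | Patch-FFT alignment index `alpha in [0, 1]` relative to the vessel axis (1 = parallel, 0 = isotropic) |
| `vesselquant.extravasation` | 3-D nucleus detection (DoG + distance-transform watershed), monocyte vs endothelial classification, adhered/extravasated scoring and radial migration distances |
| `vesselquant.stats_report` | One-way ANOVA with significance stars, Tukey-fence outlier flagging (flagged, never excluded), per-condition summary tables |

## CLI

Every stage is exposed through one executable:

```bash
# generate a phantom + ground-truth sidecar JSON
vesselquant simulate --preset static-2.5mg --seed 1 -o out/

# diffusive permeability (radius in um, or --auto-circle)
vesselquant permeability out/static-2.5mg_seed1.tif \
    --pixel-size-um 2.0 --step 5.0 --auto-circle -o out/

# geometry: continuity + diameter from a projection
vesselquant geometry out/diam-hi_seed1.tif --pixel-size-um 2.0 -o out/

# FRAP -> Darcy (head in mmH2O, gap L in um, viscosity in Pa s)
vesselquant frap spot.tif --pixel-size-um 1.0 --step 1.0 \
    --head-mmh2o 10 --gap-um 1000 --mu 7e-4 -o out/

# alignment index
vesselquant align out/aligned_seed1.tif --axis-deg 0 -o out/

# extravasation scoring
vesselquant extravasation cells.tif --pixel-size-um 1.5 --z-step-um 2.0 \
    --radius-um 50 --axis-y-um 112 --axis-z-um 105 -o out/

# condition-level statistics from a per-device CSV
vesselquant report measurements.csv -o out/
```

Presets: `static-2.5mg`, `flow-2.5mg`, `flow-6mg` (leakage movies at
P_d = 1.45 / 0.10 / 0.60 um/s), `migration-20um`, `counts-static`,
`counts-flow` (nuclear stacks), `diam-hi`, `diam-lo` (projections),
`aligned`, `random` (fiber fields).

Units: geometry in micrometres, time in seconds, pressure in pascal
internally; the CLI accepts hydrostatic heads in mmH2O
(1 mmH2O = 9.80665 Pa). All estimators are invariant to affine
intensity gain where physically possible.

Configuration is a YAML tree mirroring `vesselquant.config.DEFAULTS`;
unknown keys are rejected. Identical config + seed reproduces output
tables byte for byte.

## Notes on the leakage phantom

The dextran phantom holds the lumen at constant concentration
(reservoir assumption) and diffuses tracer radially outward with
membrane flux `P_d (C_lumen - C_wall)`; the outer boundary is closed at
the inscribed radius of the frame so the frame total counts all leaked
tracer. The slope estimator is exact only while the wall concentration
stays negligible, so the permeability presets use a fast exterior
diffusivity (quasi-well-mixed gel). With slow tracer diffusion
(e.g. 25 um^2/s for 70-kDa dextran in collagen) the wall concentration
builds up within a few frames and any estimator built from the two
intensity totals alone under-reads P_d by tens of percent; see
`vesselquant/permeability.py` for the derivation and caveats.
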