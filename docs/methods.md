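# Methods

`pepperhsi` re-creates a hyperspectral pest-symptom detection analysis for
bell pepper (*Capsicum annuum*) as a fully synthetic, testable pipeline.  The
biological problem: distinguish plants infested with the green peach aphid
*Myzus persicae* (MP) and the western flower thrips *Frankliniella
occidentalis* (FO) from uninfested controls (UC), using paired
visible/near-infrared (VNIR, 404–994 nm, 184 bands) and short-wave infrared
(SWIR, 954–2511 nm, 288 bands) line-scan images.  The discriminating signal
is symptom-dominated: aphid colonies coat leaves with sugary honeydew
(≈ 90.62 ± 9.19 % of leaf area in the regime modelled here), while thrips
leave whitish single-cell feeding spots and dark feces specks
(≈ 9.56 ± 4.15 % of leaf area).

Because no raw image set is available, a synthetic scene generator is a
first-class component: it defines the study conditions under which the
pipeline's behaviour is asserted.

## Spectral model

Camera grids are linear between the printed endpoint wavelengths with the
printed band counts; band indices are 1-based.  (The nominal sensor
resolutions, 3.5 nm VNIR / 7 nm SWIR, are treated as descriptive.  Published
band-to-wavelength pairs for bands 20/120/180 are not consistent with any
linear grid on the printed endpoints; the true instrument grid is unknown,
and the linear convention is adopted explicitly.)

Leaf reflectance is parametric, not radiative-transfer based: a visible
baseline with a green peak (Gaussian, ~550 nm), a logistic red edge
(~715 nm) rising to a NIR plateau (~0.46), Gaussian water-absorption dips at
970/1200/1450/1930 nm, and a logistic decline toward 2500 nm.  Two built-in
constraints — R(760) > R(680) and R(1650) > R(1930) — are validated on every
parameter set.  Symptom perturbations:

* **honeydew** — broadband additive gloss (+0.10) plus absorption features
  near 980/1340/1518/1833 nm (sugar/water overtones);
* **feeding spots** — blend toward a flat bright level (0.38) confined to
  the visible range by a logistic roll-off at 720 nm.  Emptied cells scatter
  where pigments used to absorb; the NIR plateau is scattering-dominated
  already, so spots keep a strong red edge and stay inside vegetation-index
  masks;
* **feces specks** — broadband darkening toward 0.06.

A single `symptom_amplitude` scales all perturbations; 0 makes the three
classes spectrally identical (negative control).  A diagnostic *planted-band*
mode suppresses the broadband perturbations and confines the class signal to
three known channels (aphid-specific, thrips-specific, and a shared symptom
channel perturbed by every symptom type), used to verify that importance
ranking recovers known discriminative wavelengths.  The shared channel is the
single best split for separating UC from both pests, the specific channels
for their pest — so all three carry high gain by construction.

## Scene geometry

Geometry is defined in continuous normalized coordinates and rasterized at
each camera's native resolution, so the two cubes of a scene are
co-registered by construction; spatial dimensions keep the exact 111:25
VNIR:SWIR ratio of the tile sizes (defaults 333×333 VNIR / 75×75 SWIR per
leaf scene, chosen for desk-scale runtimes).  Every scene embeds a flat
white-reference patch and is emitted as raw radiance: reflectance × lamp
spectrum × lateral illumination gradient (±5 % by default) + Gaussian noise
(σ = 0.008 reflectance units), so the calibration stage does real work.

Three tiers:

* **leaf** — one elliptical dissected leaf filling most of the frame;
* **plant** — a stem (woody spectrum, no red edge) plus overlapping leaves
  painted in order, later leaves occluding earlier ones; per-leaf symptom
  coverage is sampled independently;
* **greenhouse** — several plants side by side with per-plant scale jitter,
  axial compression of the scan axis (line-scan speed mismatch, default
  0.9), an additive ambient-light field, optional secondary aphid
  infestation on UC/FO plants (off by default), and per-plant horizontal
  pixel spans returned for scoring.

Symptom placement: thrips symptoms and light honeydew grow as unions of
random disks (spatially clustered damage) until the realized symptomatic
fraction crosses the target sampled from a truncated normal; disk areas stay
under 1 pp of the leaf area so the realized fraction lands within 1 pp of
the target.  Heavy honeydew (> 50 % coverage) uses the inverse: the leaf is
covered entirely and clustered *healthy gaps* are carved out.  This matters
for cross-tier consistency: the per-tile coverage of training tiles then
spans a realistic range rather than collapsing onto the per-leaf mean, which
is what lets a leaf-trained model generalize to plant scenes whose visible
coverage is lower.  Plant scenes additionally apply a mild canopy gradient
(topmost, least-occluded leaves carry up to 15 % fewer symptoms — colonies
establish on older foliage and honeydew accumulates below them), which is
why the visible symptomatic fraction of plants is lower than that of
dissected leaves in expectation.

Insect counts per scene are Poisson with mean proportional to realized
coverage (MP 46.55, FO 1.8 at the nominal coverages), recorded as metadata
for comparison with visual count categories; insect bodies are not rendered.

## Pipeline stages

1. **Calibration** — each pixel spectrum divided by the white patch's
   per-band mean; output clamped to [0, 1.2] (honeydew glint can exceed the
   plate).  The ratio cancels any global illumination scale (asserted to
   1e-10; calibrated cubes are float64 for this reason).
2. **Segmentation** — normalized-difference index (NIR−red)/(NIR+red) at
   780/680 nm on the calibrated VNIR cube, threshold 0.3, connected
   components < 64 px removed, holes filled.  This is an explicit stand-in
   for annotation-trained semantic segmentation, which needs real annotated
   images; external masks can be supplied instead.  Masks are computed at
   VNIR resolution and transferred to SWIR by area-weighted block averaging
   with ties at 0.5 resolving to leaf (favor recall of plant tissue).
3. **Featurization** — complete 111-px (VNIR) / 25-px (SWIR) tiles; the
   feature of tile and band is the mean reflectance over the tile's *leaf*
   pixels only; tiles under 50 % leaf occupancy are dropped; aligned
   VNIR+SWIR tiles concatenate to 472 columns (VNIR block first, ascending
   band order).  Per-tile standard deviations are available behind a flag
   but off by default (no benefit in this regime).  Partial edge tiles are
   dropped.  Tiles inherit the scene's class label (weak labeling).
4. **Classification** — XGBoost gradient-boosted trees, learning rate 0.05,
   depth 10, ~100 trees (the regime's tuned values; a grid search over
   {0.01, 0.05, 0.1} × {4, 6, 10, 12} × {50, 100, 200} by scene-grouped
   cross-validated multiclass log-loss is available, with an
   RMSE-on-one-hot option).  Splits are by scene — 70 % of each class's
   scenes to training — never by tile, to prevent leakage.  Image-level
   prediction averages tile probabilities; argmax ties resolve to UC
   (conservative: do not alarm).
5. **Wavelength selection** — total-gain importance per feature column,
   ties toward the shorter wavelength; ranking computed on the training
   partition only; for each k the model is retrained on the top-k channels
   and evaluated on the untouched test partition (retraining, not feature
   zeroing).
6. **Plant scoring** — per plant (tile assigned by tile-center column) and
   per pest class, the percentage of tiles with that class's probability
   strictly above 0.80; visual monitoring is emulated by the ten ordinal
   insect-count categories (0 = none, 1 = 1–5, …, 9 = > 100); the two are
   compared by Spearman rank correlation (constant inputs flagged,
   correlation defined as 0).

## Evaluation report

The report engine computes per-class precision (= diag/column sum, 0 when
the column is empty), recall (= diag/row sum), F1 (harmonic mean, 0 when
p + r = 0), support, accuracy, macro (unweighted) and weighted
(support-weighted) averages.  Full precision is retained internally;
rendering rounds half-up to two decimals.  With equal supports, macro and
weighted averages coincide.  The engine is cross-checked against
scikit-learn's implementations in the test suite.

## What the generator does and does not show

The generator carries the statistical structure the analysis assumes —
coverage distributions, co-registered dual-camera geometry, spatially
clustered symptoms, tier-to-tier degradation, greenhouse distortions — but
not: radiative-transfer realism, insect bodies, sooty mold succession,
specular BRDF effects, real annotation noise, or the actual spectral shapes
of honeydew and thrips damage (no published spectra exist; the perturbations
are anchored to symptom descriptions and pest-relevant wavelength regions).
Passing tests therefore demonstrate that the *pipeline* is correct and that
the method behaves as expected under the stated assumptions; they do not
certify performance on real greenhouse images, and the published
15-wavelength list for the real data is carried as a reference constant
only.

## Problem sizes and numerical choices

Default experiment sizes: 30 scenes/class for leaf- and plant-tier runs
(split 21/9 per class), giving 27 test images for the three-class leaf
problem; the planted-band diagnostic uses 6 scenes/class over 10 seeds.
These sizes keep a full run at minutes on one CPU while leaving the
assertions statistically meaningful.  All randomness flows from a single
seed: stage seeds are derived as SHA-256 of `"{seed}:{stage}"` (mod 2³¹), so
any stage can be replayed in isolation and reruns are byte-identical.
Degenerate inputs are defined explicitly: empty masks segment to empty;
index denominator 0 → index 0; both-empty mask IoU = 1; a scene whose tiles
are all filtered out becomes an abstention excluded from the report with a
warning; a plant span containing no tile is flagged rather than scored.
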