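# Methods

`mitescan` quantifies the feeding activity of the two-spotted spider mite
(*Tetranychus urticae*, TSSM) on detached rosette leaves from paired
high-resolution scans of the two leaf surfaces.  This note records the
models, conventions and numerical choices the package is built on, what the
synthetic data generator does and does not emulate, and the known
limitations.

## Imaging model and conventions

The input is one RGB TIFF per leaf side per plant.  Leaves are taped to a
square plate in two rows, youngest first (top-left onward), scanned from
the lower (abaxial) surface, then the plate is turned over and scanned
again, so the adaxial exposure is a left–right mirror of the plate taken
through the plastic and adhesive tape (hence blurrier, with mottled tape
texture and air-bubble confounders in the glue).

Physical scale comes from dots-per-inch: `µm/px = 25400 / dpi`.  The
protocol's scanning resolution of 8500 dpi gives ≈ 2.99 µm pixels; the desk
benchmarks in this repository render at 1200 dpi (≈ 21.2 µm/px) so that
whole plates stay small enough to generate and analyse in seconds.  Scale
precedence on read is: explicit argument → TIFF resolution tag → configured
default; the package never guesses.

All pixel coordinates are 0-based, row-major, origin top-left; boxes are
half-open `(r0, c0, r1, c1)`.  Areas convert as `px_count · (µm/px / 1000)²`
mm².  Filename metadata (side, ecotype, replicate, batch, declared leaf
count) is a configurable underscore-token template because the token
semantics of plate-naming dialects vary between labs; the default template
decodes names shaped like `D_A_1_I_2_K1_12`.

## Leaf identification

Leaf/background separation uses the excess-green index `2G − R − B` with an
Otsu threshold, morphological closing (disk, 150 µm) and hole filling —
chlorotic or necrotic patches inside a blade are part of the leaf even when
they are no longer green.  Components whose maximum caliper (Feret)
diameter is under 4 mm are debris: the mounting protocol only uses leaves
of at least 4 mm.  The Feret diameter is used rather than the ellipse-fit
major axis because the blade-plus-petiole outline under-reads on the
inertia axis.

Ordering follows the mounting convention.  Rows are split by 1-D 2-means on
the centroid row coordinate; if the between-row gap is smaller than one
mean leaf height the plate is treated as a single row.  Within rows, leaves
order by centroid column; the top row numbers first; index 0 is the
youngest leaf.

Side pairing mirrors the adaxial masks back (`col → width − 1 − col`) and
matches leaves greedily by mask IOU, one-to-one; pairs under 0.5 IOU are
flagged unpaired rather than forced.  0.5 is the conventional
detection-matching threshold.  A config switch can select a top-bottom
mirror axis for rigs that flip the plate the other way.

## Detection backends

Detection confidences live in [0, 1] and are filtered by user-adjustable
significance levels: eggs within [0.80, 0.95] (default 0.90), black feces
within [0.50, 0.95] (default 0.75) — the defaults are the midpoints of the
legal ranges.  Damage has a fixed threshold, not a user level.  Counts are
non-increasing in the level by construction.

**Eggs** (≈ 100–150 µm bright ellipsoids) are found as difference-of-
Gaussians (DoG) blobs of egg scale in luminance (σ₁ = r/√2, σ₂ = 1.6 σ₁,
r = 62.5 µm), with hysteresis support (low = 0.3 × high; high =
max(5 × MAD noise, 6 DN)).  A candidate survives if its support has an
equivalent diameter of 70–200 µm and circularity `4πA/P² ≥ 0.6` (computed
with the Crofton perimeter and clipped — discretised small blobs can
exceed 1).  Confidence maps the DoG peak linearly from 3 → 0 to 11 → 1 DN
(8-bit).  Three further tissue checks remove non-eggs: the brightest decile
of the support must be bright (mean luminance ≥ 165; chlorotic tissue never
reaches egg-core luminance, because the egg chorion is glossy), coloured
(median chroma ≥ 12; bare tape and glue are neutral) and warm (median
R − B ≥ 15; air bubbles stay neutral even when optical blur tints them with
the surrounding leaf).  On the adaxial side an explicit bubble test also
rejects candidates whose rim outshines their core (bubbles in glue are
rings) or whose support leaves the leaf mask.

**Black feces** (40–250 µm near-black pellets) are found on a darkness map:
local background luminance minus pixel luminance, the background being a
running median over a 0.6 mm window inside the leaf (a true median is robust
both to the pellets themselves and to bright chlorosis or tape at the
petiole notch, which bias morphological background estimators).  Support
pixels must be dark both locally (contrast > 25 DN) and absolutely
(luminance below the leaf median minus 25 DN) — green tissue enclosed by
bright chlorosis is locally dark but is not a pellet.  Components are
refined at half their peak contrast so optical blur does not inflate the
measured area, then gated to 40–250 µm equivalent diameter.  Confidence maps
mean contrast from 20 → 0 to 60 → 1 DN.  White guanine feces are not
quantified.

**Damage** is per-pixel: the chlorosis score is yellowness
`(R + G)/2 − B` plus half the luminance, both as deviations from the leaf's
median colour; healthy tissue scores near zero.  The threshold is fixed at
40 DN — roughly half the typical chlorosis contrast, which balances the
boundary shift introduced by optical blur.  The mask is opened at the
100 µm scale, specks under 0.05 mm² are dropped (egg-sized bright spots are
not feeding lesions), and the result is clipped to the leaf mask.

**Trainable backend.**  The same damage contract is satisfied by a
gradient-boosted per-pixel classifier (scikit-learn
`HistGradientBoostingClassifier`) over multiscale colour features of the
standardized 128×128 patches (raw channels, 1.5 px and 4 px Gaussian
contexts, yellowness).  Off-leaf pixels are filled with the leaf's median
colour before patching; otherwise bright tape dominates per-patch
standardization statistics and the colour classes drift from patch to
patch — this drift is also why a linear pixel classifier is insufficient.
The decision threshold is tuned on the validation split by pixel IOU.  The
model trains in seconds on one CPU and reaches IOU ≥ 0.95 on held-out
synthetic damage; it exists to exercise the patching, split and backend
contracts end-to-end, not to compete with large detection architectures.

The patch machinery follows the conventional preprocessing: non-overlapping
128×128 tiles with reflection-padded remainders, per-patch per-channel
standardization, annotation masks dilated by 5 iterations of a 3×3
structuring element ("five-fold dilation" read as five unit dilations, so a
single pixel grows to an 11×11 square), and a deterministic 80-10-10
train/validation/test split (⌊n·r⌋ sizes, remainder assigned train-first).

## Quantification

Counts and areas accumulate per leaf per side.  Feeding damage overlaps
only partially between the two surfaces, so the per-leaf damage figure is
the area of the union of the two masks after registering the mirrored
adaxial mask onto the abaxial frame — mirror flip, then translation
aligning the leaf centroids, then rotation aligning the mask principal
axes.  Rigid registration suffices for flat taped leaves; non-rigid warping
was considered and rejected as overkill.  Unpaired leaves report their
single side, flagged.

Plant totals are leaf sums; eggs shed off-leaf enter as `additional_eggs`
attached to the plant (they cannot be attributed to a leaf or side).  The
oviposition rate is eggs per female over the whole infestation window
(defaults: 10 females, 72 h); a per-day variant is a config flag.  Manual
corrections (add a missed egg/pellet, remove a false detection) are an
ordered edit list applied to the detection registry; totals are rebuilt
from scratch after every edit and an append-only audit log records each
one.  Corrections cover countable objects only; damage masks are not
hand-edited.

## Validation metrics

Pixel-level agreement is the Jaccard IOU (`|∩|/|∪|`), with two empty masks
defined as perfect agreement (1.0).  Pixel accuracy is emitted alongside
and clearly labelled, since the two are often conflated.  Object-level
"efficiency" is program value / reference value × 100% per item, summarised
by mean and range, with a paired two-sided t-test of program versus
reference; items with a zero reference value are excluded with a warning,
and identical series define p = 1.  Detection-to-truth matching is greedy
one-to-one by centre distance (eggs: within two egg radii).

## Susceptibility statistics

Analyses run on a tidy per-plant trait table (plus a long per-leaf table).
Relative values divide each plant's trait by the mean of the reference
ecotype grown in the same batch — batches measured weeks apart stay
comparable, and the reference's relative values average to 1 per batch by
construction.  Group comparisons are one-way ANOVA followed, when the
global test rejects at α, by Tukey HSD over all pairs; Tukey is the
standard post-hoc companion and controls the family-wise error.  The
compact letter display uses the insert-and-absorb algorithm, which
guarantees two groups share a letter exactly when their pair is not
significant and prunes redundant letters to a minimal cover; the letters
are therefore a lossless encoding of the decision matrix, and the tests
verify this equivalence on every run (with `scipy.stats.tukey_hsd` as an
independent oracle for the decisions themselves).  Dynamic range is the
max/min ratio of ecotype means.  Leaf-position distributions re-index
leaves from the oldest (mounting is youngest-first; positional plots read
oldest-first) and align plants of different leaf counts by position, with
missing positions simply absent.  Side distributions use the adaxial
fraction `ad/(ad+ab)` per plant; plants with zero totals carry no
information about side preference and are excluded with a warning.  Group
summaries report mean ± SE.

## The synthetic generator

The generator is first-class, tested code: it renders paired plate scans
with exact ground truth so every stage is testable without microscope data.

What it emulates: two-row youngest-first layout with ≥ 2 mm clear spacing;
elliptical blades with petioles; a trichome texture densest on the youngest
leaves (line density interpolates from 2 /mm² on the youngest by the
configured gradient, default 0.25, to the oldest); eggs as 100–150 µm
glossy ellipsoids in three age tints (translucent, straw-yellow, orange —
egg age spans 0–3 days) with a configurable adaxial probability (default
1/6, matching the ~1:5 adaxial:abaxial preference of TSSM; ecotypes with
inverted preference are expressed by raising it); black pellets as 100–250 µm
compact connected blobs (the detection gate keeps the full 40–250 µm legal
range; at the 1200 dpi desk scale a 40 µm object would be sub-pixel, so the
generator draws from 100 µm up); chlorotic damage as irregular patches that
share a configurable core between the two sides (default overlap 0.6);
and the adaxial degradations — Gaussian blur (σ 0.6 px), low-frequency tape
mottling, and bright-rimmed air-bubble rings (default 0.5 /cm²) anywhere on
the plate.

Blob areas are exact by construction: damage masks take exactly the top-k
pixels of a shaped random field and pellets grow as connected regions of
exactly k pixels, so ground-truth mm² values are stable to within ~1%
across render resolutions.  Per-leaf truth tables and plant totals are
consistent by construction, and everything is deterministic given the
plant specification's seed (object attributes and rendering draw from separate seeded streams, so
truth-only generation replays the identical object list).

Experiment-level sampling: per-plant symptom totals are negative-binomial
(dispersion 5) spread over leaves in proportion to blade area; damage uses
a two-level gamma model — a plant-level susceptibility factor (CV 15%,
appropriate for inbred accessions in a controlled chamber) times
leaf-level scatter (CV 20%) — because leaves of one plant share that
plant's susceptibility; treating leaves as independent draws would inflate
between-plant variance unrealistically.  The two youngest leaves carry no
eggs or damage (their dense trichome coat keeps females off; feces still
occur).  Oviposition is totalled per plant over 10 females.

What it does not emulate — and hence what passing tests do not show about
real scans: true leaf shapes (lobes, serration, curvature and the local
defocus it causes), specular tape reflections, condensation, mite bodies
or webbing, egg clustering behaviour, colour variation between microscope
set-ups, and stitching artefacts from the ~400 merged camera tiles.  The
trichome model is a stylised stand-in (short bright line segments) for a
structure that is only qualitatively described.  Detector parameters
calibrated on the synthetic appearance (contrast spans, the fixed damage
threshold) would need recalibration on real scans.

## Benchmark and problem sizes

The default detection benchmark generates 10 plants × 10 leaves (100
leaves, both sides) at 1200 dpi with the default symptom load and scores
the full pipeline against truth: egg F1 (centre matching within two egg
radii), total feces and damage area errors, and per-plant egg-count
efficiency.  Typical results: F1 ≈ 0.99, area errors ≤ 2%, efficiency
≈ 99–101%.  Statistical validity checks run 1000 reduced-scale null
simulations (4 groups × 6 plants); parameter recovery uses 2 ecotypes × 6
plants, the replication level of the motivating screen.  These sizes keep
the whole suite and the acceptance script in the minutes range on one CPU.

## Known limitations

* The classical backends are calibrated to reflected-light scans of
  *Arabidopsis*-like material; other hosts (thicker cuticles, different
  chlorosis hues) need the colour parameters revisited.
* Touching or overlapping leaves are out of scope — the mounting protocol
  forbids them and segmentation assumes separation.
* Egg developmental-stage classification and mite counting are out of
  scope (leaves are detached after infestation; no mites are imaged).
* Damage merging assumes rigid geometry; strongly curled leaves would need
  non-rigid registration.
* A declared-versus-found leaf-count mismatch warns rather than fails: the
  declared count is treated as a hint, not a hard constraint.
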