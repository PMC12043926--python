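# Methods

This note documents the models and procedures implemented in `echoseg`,
the assumptions behind them, the parameters that matter, and what the
synthetic phantom does and does not establish about real data.

## The self-supervised pipeline

The pipeline turns unlabelled echocardiogram cine loops into chamber
segmentations and guideline measurements without any human-drawn contour.
Its premise is twofold. First, classical computer vision plus clinical
shape priors can produce *weak* labels — coarse, frame-skipping, sometimes
wrong, but abundant and free. Second, a network trained on noisy labels
passes through an early-learning phase in which it fits the cleanly
labelled structure before it memorizes label noise; stopping at the bend
of the validation-loss curve therefore yields a model *better* than its
own training labels, and its QC-filtered predictions can be recruited as
labels for a further round (self-learning).

### Weak labels

* **Apical two-chamber (A2C).** Gaussian smoothing (σ = 1 mm) → 3-class
  Otsu threshold within the imaging fan, keeping the darkest class (blood
  pools) → morphological opening (2 mm disk) → connected components →
  shape-prior gates: area 5–80 cm², eccentricity ≤ 0.95, solidity ≥ 0.7,
  centroid within the central 60% of the fan width → the admissible pool
  nearest the sector apex is the LV, the one beyond the valve plane the LA
  → convex-hull smoothing. Frames with fewer than two admissible pools are
  rejected; rejection is part of the recipe, not an error.
* **Apical four-chamber (A4C).** The final A2C model, whose features are
  deliberately blind to left/right (below), predicts *two* ventricle and
  *two* atrium components on A4C frames. These are relabelled by centroid
  column given the display orientation (ventricles must also sit apex-ward
  of their atria), and the RV apex is stretched along its long axis by
  iterative directional dilation inside a 25° cone until RV length reaches
  0.9 × LV length (configurable; the clinical correlation is reported
  without a universal number), stopping early at collision with the LV.
* **Short-axis (SAX).** Gradient-based Hough circle detection
  (radius 15–45 mm, one best centre per radius, greedy suppression that
  lets concentric candidates coexist) seeds circle-outline labels; an edge
  detector is trained on those outlines; its predicted edge maps are
  bridged by dilation, the largest *enclosed, simply connected* non-edge
  region (the cavity, not the inter-boundary annulus) is kept and grown
  back to the contour line; those filled masks train the first segmenter;
  after self-learning, epicardial/endocardial labels are synthesized by
  dilating/eroding the predictions (wall 9 mm, endocardial margin 1 mm at
  0.5 mm/px; the margin is dropped on the 2 mm/px desk grid where it would
  round up to a whole pixel) and a second segmenter learns both contours.

### The trainable segmenter

With no deep-learning framework as a dependency, the segmenter is a
convolutional-feature pixel classifier written in NumPy: per-pixel features
are a fixed multiscale filter bank (Gaussian smoothings and gradient
magnitudes at σ ∈ {1, 2, 4} px, a Laplacian of Gaussian), the normalized
depth coordinate, and two sector features computed from the image itself —
an inside-the-fan indicator (convex hull of above-background pixels) and
the normalized distance to the fan boundary. Features are standardized to
the training set's mean/SD. The head is one hidden ReLU layer with
per-chamber sigmoid outputs, trained with Adam on soft Dice loss

    L = 1 − (2 Σ p·t + ε) / (Σ p + Σ t + ε),   ε = 1 pixel,

averaged over channels, with analytically derived gradients. Output biases
are initialized to −3 so every head starts near-empty and the Dice
gradient grows each head out of its own target region; without this the
per-chamber heads can collapse onto one another. Training is bit
reproducible given the seed.

The two sector features are what make the A2C→A4C bootstrap work: they
separate dark blood pools from the dark corners outside the fan without
encoding laterality, so the A2C model marks *both* ventricles on an A4C
frame. The A4C model itself re-enables a signed lateral-coordinate feature
to tell left from right.

Two profiles are used. The *full* profile mirrors the standard
configuration (256 × 256 grid at 0.5 mm/px, Adam 1e−4, batch 32); the
*desk-tiny* profile (64 × 64 grid at 2 mm/px, hidden width 12, Adam 0.03,
batch 8, ≤ 60 epochs) is what the test suite and acceptance script run —
this model is orders of magnitude smaller than a UNet, so its useful
learning rate is correspondingly larger. All stage runtimes are seconds on
one CPU at the tiny profile; suite sizes in the tests (6–20 studies of 16
frames) were chosen so the full pipeline exercises every stage with
meaningful variation across studies.

### Early stopping and self-learning

The validation soft-Dice loss is recorded every epoch on a 20% hold-out
split **by patient** (no study id ever crosses the boundary). The elbow is
found post hoc by standard knee detection: min–max normalize both axes,
smooth with a 3-epoch running median, and take the epoch lying furthest
below the chord joining the endpoints. The median smoother is the identity
on monotone curves, so a clean piecewise-linear corner is recovered
exactly; a moving average would shift it by an epoch. Constant or straight
curves raise a no-elbow error; short smooth descents without a bend fall
back to the minimum-loss epoch. Checkpoints are kept per epoch and the
elbow checkpoint is restored (checkpoint-and-rewind rather than live
stopping — deterministic and reproducible). Self-learning then runs
inference on every frame of every clip, gates each prediction with the QC
rules, and promotes survivors (provenance `qc_passed`) to the next round's
training set; every training entry point asserts that provenance, so no
stage can consume ungated labels. Retraining is from scratch each round.

### Quality control

Shape descriptors per chamber (area = pixels × spacing², eccentricity and
orientation from the second-moment ellipse, solidity = area / convex-hull
area, long-axis length) are gated against per-chamber bounds
(LV 5–80 cm², LA/RA 3–60 cm², RV 4–60 cm², LV-epicardium 8–120 cm²;
eccentricity ≤ 0.95, solidity ≥ 0.7) and relational rules (pairwise
disjointness; ventricle apex-ward of its atrium in apical views; LV/LA
area ratio in [0.3, 6]; secondary fragments ≤ 10% of the main component).
The gate is a pure predicate and returns *every* violated rule. All
thresholds are config (YAML-serializable); the defaults are
physiologically permissive.

## Clinical calculations

Chamber areas per frame are fitted with offset + amplitude·sin(2πft + φ)
by linear least squares at the fixed frequency f = HR/60 (periodogram peak
in 0.5–3 Hz when no heart rate is recorded); a constant trace or vanishing
amplitude raises a fit failure, the signal for manual frame choice. The
video with the best r² is selected; ED is its largest-area frame, ES its
smallest, ties to the earliest frame. Since the raw argmax frame is used,
ED/ES accuracy is limited near the flat sinusoid extremes by the
frame-to-frame area noise: at ~0.7% noise (a clean segmenter) selection is
within ±1 frame of a true phase extremum essentially always, which is the
condition the acceptance suite checks.

Volumes use the method of discs with n = 20 slabs along the chamber's long
axis, defined as the principal axis of the mask's second moments. Slab
diameters are area-average widths (slab area / slab height), which is
robust to rasterization at the slab tips. Biplane volumes slice each view
along its own axis and pair diameters at equal fractions with the longer
length L; the result is symmetric in the two views and reduces exactly to
the single-plane formula for identical masks. One caveat of the
principal-axis rule: for very squat bullet shapes (length < ~1.2 × width)
the second-moment axis flips to the width direction and the solid of
revolution differs; real LV geometry (length ≈ 1.5–2 × diameter) is safely
inside the valid regime. LV mass uses the area–length formula with
myocardial density 1.05 g/cm³, taking epicardial/endocardial areas from
the SAX view at ED and the LV length from an apical view. LA volume uses
discs at the atrial-maximum frame (biplane when both apical views exist),
RA volume single-plane on A4C, RV areas are read at the ventricular ED/ES
frames. Guideline classification indexes volumes, mass and RV areas by BSA
and bins each measure normal/abnormal (LVEF and LV mass additionally
graded); the abnormal interval is closed at the threshold, and the whole
table is replaceable config, not ground truth.

Agreement statistics follow the conventions used throughout: limits of
agreement are exactly ±2·SD of the paired differences (a `z=1.96` flag is
available), Cohen's κ uses marginal-product chance agreement, Dice of two
empty masks is defined as 1 (perfect agreement on an absent structure),
and the bootstrap is a seeded 10,000-iteration percentile interval.

## The phantom and what it shows

The generator emulates: a 90° sector with apex at top-centre; chambers as
ellipses (apical: ventricle + atrium separated by a bright valve-plane
band; A4C: four chambers with a bright septum; SAX: cavity disc inside a
myocardial annulus) with bright wall bands of configurable thickness;
multiplicative unit-mean Rayleigh speckle (strength 0.5 by default, the
level at which the weak-label recipe is visibly degraded but not broken);
angular dropout wedges (12% of the fan on 30% of studies in pipeline
suites — a rib-shadow-like artifact); and cines whose ventricular areas
follow A(t) = A_ed − (A_ed − A_es)(1 − cos 2πft)/2 with
A_es/A_ed = (1 − EF)^(2/3), so the prolate-spheroid volume excursion gives
exactly the target EF; atria contract in counter-phase with a 35% area
excursion. Default chamber sizes (LV ≈ 17 cm² / 54 mL at ED, constrained
by the 128 mm display depth, hence at the small end of adult anatomy) and
per-study ±8% geometry jitter and EF ∈ [0.35, 0.70] define the study
population; in multi-view suites the same study index carries the same
physiology across views so biplane measurements are coherent, while the
speckle realization differs per view.

What passing on phantoms does **not** show: real ultrasound has continuous
tissue texture, anisotropic point-spread, valve and papillary anatomy,
view foreshortening, probe motion and genuinely non-elliptical chambers.
The phantom establishes that every algorithmic link of the chain is
correct against closed forms and that the self-learning loop improves on
its weak starting labels under controlled noise — not that the pipeline
reaches any particular accuracy on clinical images. The deliberately
simple geometry is what makes analytic oracles (areas, spheroid volumes,
exact EF) possible.

## Numerical choices and degenerate inputs

* Probability threshold strictly > 0.5; ties go to background; the largest
  connected component per chamber is kept at inference.
* Resampling: bilinear for images, nearest-neighbour for masks (masks stay
  binary); intensity min–max rescaling happens before zero-padding so a
  constant frame maps to zeros rather than being stretched against its own
  padding.
* Circularly symmetric masks have a degenerate second-moment axis; the
  implementation takes the two orthogonal eigenvectors explicitly, so a
  perfect disc still yields a valid axis pair.
* Hough ties are broken by accumulator score then smaller radius; circles
  poking outside the frame are dropped.
* `make_loss_curve` produces piecewise-linear expectation (rate change at
  the elbow) plus Gaussian noise — the cleanest construction for which the
  curvature-maximum location has a closed form.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integer lists; reruns are bit-identical, which the acceptance
  script verifies end to end.

## Known limitations

* The pixel classifier has no learned spatial context beyond its filter
  bank; on real data it would underperform a UNet, and the desk profile's
  hyperparameters (learning rate 0.03) are tuned to its scale, not to a
  deep network's.
* The edge detector is the same classifier on outline targets; it is a
  functional stand-in for a multi-scale deep edge network at phantom
  complexity only.
* LV mass couples two views (SAX areas, apical length); inconsistent
  per-view segmentation quality propagates into mass more than into any
  single-view measure, and mass shows the widest phantom agreement bands.
* The A4C atrium labels inherit whatever the A2C model believed about
  atria; a poor A2C round degrades all four A4C chambers.
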