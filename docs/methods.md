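# Methods

## Filtering model

Training patches inherit labels from coarse annotations, so a fraction of
them is mislabeled. The filter relies on a single empirical regularity:
gradient training fits the shared structure of a class early, while
mislabeled samples are memorized late and carry above-average loss while it
happens. The loop therefore tracks, for each class, the running sum and
count of the cross-entropy losses of **correctly classified** samples only
(misclassified samples contribute nothing), and a batch counter `k`. The
class average is the plain mean of all recorded losses, accumulated over the
entire run — it is never reset between epochs, so early high-loss history
keeps the threshold conservative. A sample whose loss reaches
`alpha * class_average` triggers the abstain condition (the boundary is
inclusive).

Two repair modes act on triggered samples:

* **discard** — remove the record permanently. By default this additionally
  requires the sample to be *correctly* classified: the model already
  reproduces its (possibly corrupted) label, i.e. has memorized it, yet the
  loss is still high. This is the literal cleaning rule; the
  `require_correct` toggle exposes the broader variant that also removes
  high-loss misclassified samples.
* **flip** — relabel rather than remove. Triggering on correctly classified
  samples would make "set label to the prediction" a no-op, so flip mode
  acts on high-loss *mis*classified samples and sets the label to the
  current prediction. Flipped records stay in training and may flip again
  in a later epoch; discards are never revisited.

Decisions in a batch are evaluated against the tracker state accumulated
from *previous* batches, so a sample's own loss never inflates the
threshold it is judged against. Discards take effect at the next epoch's
shuffle (each sample appears once per epoch); flips take effect
immediately. Filtering is inert during the first `warmup_epochs` epochs
while loss statistics accumulate.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1.0 | threshold multiplier on the class average; smaller = more aggressive. Unitless. `1e9` (or `policy=None`) reproduces plain training bit-for-bit |
| `mode` | `discard` | `discard` or `flip` (discarding performed better in our experiments and in the motivating study) |
| `warmup_epochs` | 2 | epochs of pure statistics accumulation; overfitting on noisy data shows within the first ~5 epochs, so filtering starts before it peaks |
| `require_correct` | mode-dependent | see above |
| `tracker_scope` | `per_class` | each sample is compared against its own class's average; `global` pools all classes |
| `epochs` / `batch_size` / `learning_rate` | 30 / 32 / 1e-3 | standard cross-entropy + Adam training configuration |

## Reference backbone

The filter is architecture-agnostic (`ClassifierContract`); any model with
per-sample cross-entropy `train_step`, probabilistic `predict`, and
penultimate `features` plugs in. The shipped backbone (`SoftmaxNet`) is a
small numpy network designed for deterministic CPU experiments:

* stem: the image is averaged over a 16x16 grid of cells; features are the
  3 per-cell channel means plus a per-cell grayscale standard deviation
  (contrast), 1024 inputs for any patch size divisible by 16;
* conditioning: `calibrate()` (called once on the initial training split)
  centers the features and rescales each principal direction by
  `lambda**-0.5`. This exponent is load-bearing. Raw stem features are so
  ill-conditioned that Adam cannot memorize labels at all — the model
  converges to the class-conditional noise posterior and nothing is ever
  "correct with high loss", starving the filter. Fully whitened features
  (`lambda**-1`) are the opposite failure: clean and corrupted labels are
  interpolated within one epoch and the filter again sees no loss gap.
  Half-power whitening puts clean-structure fitting inside the warm-up and
  noise memorization after it;
* head: one ReLU hidden layer (512 units) and a softmax, trained with Adam.

Everything is seeded; two runs with the same seeds are bit-identical, which
is what makes the "disabled filter == plain baseline" equivalence testable
as exact equality.

## Synthetic data

The generator stands in for stained-tissue patches with textures that are
controllably class-separable: per-class base color, oriented sinusoidal
stripes, dark nuclei-like blobs (Poisson counts, local darkening), and
per-pixel Gaussian jitter. A `difficulty` knob linearly interpolates all
class recipes toward their common mean: 0 is separable by channel means
alone (a nearest-centroid baseline exceeds 95%), 1 collapses all classes to
one recipe (chance level). Patches are distributed over virtual slides
(~200 patches each, never fewer than 10 slides so an 80/10/10 slide-level
split never leaves a split empty), and symmetric label noise is injected
into the train split only: exactly `round(rate * n_train)` records chosen
by seeded permutation, flipped to the opposite class (binary) or uniformly
to one of the other classes. Exact counts rather than Bernoulli draws make
the stated percentages hold exactly and experiments reproducible.

Composite synthetic slides emulate the annotation-noise mechanism itself:
regions are rendered on a white background, and the emitted annotation
polygons are the true region polygons dilated outward by a configurable
radius. Tiling plus area-overlap labeling against the dilated polygons then
mislabels benign tissue near region borders — the noise rate is zero at
zero dilation and grows monotonically with it.

What the generator does **not** emulate: real nuclear/glandular morphology,
stain variability, pyramidal WSI formats, magnification effects, or
instance-dependent (structured) label noise. Passing tests therefore show
that the filtering mechanism works when the memorization/overfitting
premise holds; they do not certify performance on real slides, where class
boundaries are subtler and noise is not symmetric.

## Patch preparation conventions

Coordinates are 0-based, origin top-left, tiles half-open
`[x, x+size) x [y, y+size)`, enumerated row-major. A pixel is background
("white", non-tissue) when all three channels are >= 220/255; a tile is
kept when at most 70% of its pixels are background. A tile takes the class
of the annotation region with maximal area overlap if that overlap reaches
0.5 (ties break to the lowest class index; a center-point mode is available),
otherwise it is benign — benign tissue carries no annotation. Slides are
shuffled with a seed and cut at the cumulative split fractions (floored);
leftover slides go to train. All of these thresholds are configurable; the
overlap rule in particular is a package choice, since no standard exists
for partially overlapping border tiles.

## Evaluation

Accuracy (percent correct), the K x K confusion matrix (rows = truth),
one-vs-rest ROC-AUC via the rank statistic with midranks on ties (equal to
the trapezoidal area under the threshold-sweep curve), micro averaging by
pooling the binarized label/score matrix (for two classes the indicator
binarizes to the single positive column, so binary micro equals the
positive-class AUC), and macro averaging as the unweighted mean over
classes present in the truths. The McNemar test uses the
continuity-corrected chi-square form at 25 or more discordant pairs and the
exact two-sided binomial form below that — the conventional small-sample
rule. t-SNE export delegates to scikit-learn at default parameters with a
fixed seed (perplexity auto-reduced for tiny inputs). All of these are
cross-checked against scikit-learn/statsmodels in the test suite; the
implementations here exist so the package's reported numbers do not depend
on the library being used as its own oracle.

## Problem sizes used in tests and the acceptance script

Experiments run at desk scale, chosen as the smallest sizes at which the
phenomena are stable: 3 classes, 64x64 patches, 500 patches/class
(~1,200 training records) for the noise-robustness comparisons, 10 epochs,
5 seeds per condition; 1,250 patches/class (~3,000 training records) for
the tracker bookkeeping check; 1,024x1,024 synthetic slides with 64-pixel
tiles for the annotation-dilation sweep. A full run of the acceptance
script takes a few minutes on one CPU.

## Known limitations

* The discard condition's reliance on memorization means the filter is only
  as good as the backbone's tendency to overfit; a heavily regularized or
  underparameterized model starves it (see the conditioning discussion
  above).
* With `require_correct` true, noise that is never memorized is never
  removed — recall plateaus (~0.5-0.8 in our runs) even when precision is
  near 1.
* `alpha` is fixed, not learned; the appropriate value depends on the loss
  distribution of the data at hand.
* Symmetric noise is the only injected model; annotation-induced noise from
  the slide generator is spatially structured but still class-symmetric in
  texture.
* The manifest format stores one label per patch; soft or multi-rater
  labels are out of scope.
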