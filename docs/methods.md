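# Methods

`pillid` implements a two-step pill-identification system: a **recognition**
step that reads a pill's characteristics from its reference image, and a
**retrieval** step that ranks every pill in a database by a similarity score
over those characteristics.  This note records the models, the numerical
choices, and what the synthetic study conditions do and do not show.

## Problem setting

A pill's *features* are its shape (11 classes), color (16 classes) and form
(tablet or capsule).  Its *imprint* is the character string engraved on its
surface — uppercase letters, digits, and the single lowercase token "mg" —
with an underscore `_` separating the front and back faces.  Features plus
imprint are the pill's *characteristics*.  Identification is retrieval, not
classification: a query image is scored against every database record, so
newly registered pills need a database row, not a retrained model.  Because
many pills are, e.g., white round tablets, the imprint carries most of the
identifying information; the system is built around reading it accurately.

## Recognition models

All three models are NumPy implementations trained with a small
reverse-mode autodiff core (`pillid._autograd`); each is deterministic given
its config seed.

**Orientation normalization.** The pill silhouette is segmented by
background subtraction; the second-moment principal axis of the foreground
is rotated to horizontal.  A silhouette whose axis ratio is within 5% of 1
is treated as circular and left unrotated (the principal axis is undefined).
Recovered angles are accurate to within 2 degrees on synthetic renders.

**Character detection** is a single-shot grid detector in the YOLO family:
the face image is divided into an 8x8 grid and a shared two-layer perceptron
(a strided convolution in effect) maps each cell's 2x-cell patch to an
objectness logit, a 37-way class distribution and four box coordinates.
Patch features are absolute deviations from the patch median, which makes
them invariant to ink polarity (dark-on-light vs light-on-dark imprints).
Training uses SGD (momentum 0.9) with a linear warm-up over the first 3
epochs, default learning rate 1e-2 and batch size 16.  Inference applies
greedy non-maximum suppression at IoU 0.45, ties broken by lower cell index,
and returns detections sorted by face, then y, then x — a convention only;
downstream code must not rely on this order being semantically correct.
The interface is pluggable: any model exposing the same detect signature
(e.g. a full YOLOv5) can be substituted.

**Feature recognition** is a multitask classifier: a shared backbone maps
the image to a vector p_i of size h (default 128), and three linear heads
w_s (h x 11), w_c (h x 16), w_f (h x 2) produce z_{i,k} = softmax(w_k p_i).
The loss is the weighted sum of the three per-head cross-entropies, all
weights 1 by default.  The backbone here is a residual two-layer perceptron
over a 4x mean-pooled image — sufficient for the synthetic renders and
replaceable by a deep convolutional network (the full-scale system uses
ResNet-32 with learning rate 0.1, weight decay 1e-4, batch 10, 100 epochs;
those settings diverge for this backbone, so desk defaults are learning
rate 0.02, batch 32, 40 epochs, same weight decay).  Optional oversampling
draws each epoch with replacement using inverse-class-frequency weights
multiplied across the three heads; the weight ratio is capped at 100x
because a sample rare in every head would otherwise dominate the epoch.
Capsules carry a single color label — the dominant half of the two-tone
body — in both training data and scoring.

**Imprint correction** turns the detector's noisy, unordered character bag
into the canonical imprint with an attention-based bidirectional GRU
sequence-to-sequence model.  Each detected character t is *coordinate
encoded* as one-hot(t) ++ (x_t, y_t) with image-relative coordinates in
[0,1].  The decoder is trained by teacher forcing to maximize
prod_j p(tgt_j | tgt_<j, src) and decodes greedily (beam search adds
nondeterminism for little gain at this scale).  Detections are pre-sorted by
(face, y-band, x) with y quantized to 1/8 bands so row-internal jitter
cannot scramble a text row; genuine order errors are the model's job, which
is why the coordinates are in the input at all.  `_` is an ordinary token;
decodes with more than one keep the first.  Optionally the (shape, color,
form) labels are embedded, summed, and added to the encoder/decoder initial
states, letting appearance act as context for the imprint (ambiguous
O-vs-0 pills that correlate with color are resolved this way).  Full-scale
defaults follow the reference configuration (embedding 45, hidden 256,
Adam, learning rate 1e-3, batch 50); the desk profile uses embedding 32,
hidden 64, learning rate 2e-3, 40 epochs.

The pipeline trains the corrector on noise-corrupted copies of the *whole*
database inventory (text and ground-truth layouts only, no images): the
corrector is a lexicon-aware spelling model over the retrieval database,
which is available in deployment without new photographs.  The unseen-species
split applies to the visual models (detector, features), whose queries are
images of pills never seen in training.

## Retrieval score

The score of a prediction (shape, color, form, imprint a) against a database
record with imprint b is the sum of five terms, computed in exact rational
arithmetic:

* 1/3 for each exactly matching feature label (hard labels, not
  probabilities);
* normalized edit similarity  2·matches/(|a|+|b|), where matches is the
  number of aligned equal tokens in a minimum-cost Levenshtein script
  chosen, among all minimum-cost scripts, to maximize matches
  (lexicographic DP on (cost, −matches)); equivalently
  (|a|+|b|−d−x)/(|a|+|b|) with d the edit distance and x the substitution
  count of that script;
* overlap similarity  2·|multiset intersection|/(|a|+|b|) over tokens,
  `_` included.

Tokens are "mg", "_", and single characters; two empty imprints have
similarity 1 by convention.  The total lies in [0,3] and equals 3 exactly
iff every characteristic matches.  Candidates are ranked by total
descending, ties broken by pill_id ascending so ranking is deterministic.
Both imprint formulas are reconstructions from printed worked values
(12/12, 10/12, 6/13 for the edit term; 12/12, 10/12, 8/13 for the overlap
term), each isolated behind a single function so an alternative closed form
can be swapped in.  Database imprints are tokenized permissively (symbols
outside the generation vocabulary score as ordinary tokens).

## Synthetic data

The generator emulates a regulatory reference database: one record per pill;
class marginals matching the NLM database (round 46.18%, oval 35.01%,
oblong 15.46%; white 42.27%, yellow 12.68%, pink 8.93%, orange 8.64%,
blue 8.44%, brown 5.76%, green 5.53%; 15% capsules); imprints of 2-8 tokens
per face drawn with digits slightly favored (imprints often encode doses)
and "mg" at 6%; and one composite image per pill, front face left, back face
right.  Shape is sampled conditionally on form — capsules are lozenges, so
their shape is oval/oblong, with the tablet-conditional adjusted to preserve
the configured shape marginals — and sampled rectangles map to square,
matching common fine-tuning practice.  At least 10% of records share their
feature triple with another record while differing in imprint, so retrieval
cannot succeed on appearance alone.  Imprints are unique per database and
test-fitted against the silhouette layout so every generated record renders.

Rendering uses filled polygons/ellipses ("others" is a semicircle) and a
fixed in-code 5x7 bitmap font, so per-character ground-truth boxes come from
glyph metrics, never re-detection.  Detector noise is simulated directly on
the ground truth: symmetric character confusions (O-0, I-1, B-8, S-5, Z-2),
Bernoulli drops, Gaussian coordinate jitter and order scrambling, all
deterministic given the noise seed.

What the generator does **not** emulate: photographic lighting, perspective,
broken pills, logos/symbols, lowercase imprints beyond "mg", consumer-grade
images, or detector error patterns beyond the confusion/drop/jitter model.
Passing tests therefore show that the architecture and scoring behave as
designed under controlled conditions — not that the desk-scale models reach
the accuracy a full-scale system attains on real regulatory databases.

## Study conditions and problem sizes

Fixed once for the test suite: 460 pills at 96 px face resolution, species
split 400/60; detector trained 80 epochs (hidden 160); feature model 40
epochs; corrector trained on 6 corruption draws per pill at the benchmark
noise (confusion 0.3, drop 0.05, jitter 0.01, shuffle on), 40 epochs.
These sizes keep the whole suite within a desktop-CPU budget while leaving
clear margins on the behavioral claims:

* correction strictly improves mean normalized edit similarity over the raw
  detector string, and end-to-end top-1 with correction beats top-1 without
  it under the benchmark noise;
* ablating both imprint terms collapses top-1 to at most the
  feature-duplicate chance level of the database (mean of 1/n over queries,
  n = the number of records sharing the query's feature triple);
* zeroing coordinates at train and test reduces exact-match on shuffled
  inputs — the coordinate-encoding claim made testable;
* feature heads reach >= 95% held-out accuracy and the detector >= 0.9
  recall/precision with mean center error <= 0.02 image widths on
  noise-free renders.

## Numerical choices and degenerate inputs

Float32 training throughout; scoring in `fractions.Fraction` (display-only
float conversion).  Empty detection sets decode to the empty imprint and
retrieval proceeds on features alone, flagged low-confidence.  A blank image
raises on orientation normalization (no foreground) but identification
falls back to the unnormalized half.  Oversampling with a never-observed
class warns and trains on the remaining classes.  Imprints too long for a
silhouette raise an explicit overflow error rather than truncating.

## Known limitations

The detector's character classifier is the accuracy bottleneck
(~95% per-character on held-out renders); localization is essentially exact.
Exact-match correction degrades when characters are dropped, since restoring
an unseen character requires the lexicon to disambiguate.  The corrector
memorizes the database inventory by design; imprints absent from its
training corpus are corrected only up to ordering and pass-through.  The
feature backbone is not a deep CNN and would not transfer to photographic
inputs.
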