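# Methods

## Setting and model

The package analyzes serial, co-registered, multicontrast brain MRI of
focal inflammatory demyelinating white-matter lesions (the marmoset EAE
setting: weekly scans at 150 µm in-plane / 1 mm slice resolution, so one
voxel is 0.15 × 0.15 × 1 mm = 0.0225 µL). All intensity reasoning happens
on proton density-weighted (PDw) images normalized so mean gray-matter
signal is 1; normal-appearing white matter (NAWM) then occupies a
0.65–0.75 band and demyelinated tissue is hyperintense. Auxiliary
contrasts are pre/post-gadolinium T1w pairs (blood–brain-barrier
enhancement marks acute inflammation) and MT-on/MT-off pairs, from which
the magnetization transfer ratio MTR = (M0 − M_SAT)/M0 is derived
voxelwise.

The lesion life cycle assumed by the classifier: a lesion appears abruptly
(hyperintense at its first scan), grows and brightens over a 4–7-week
demyelination phase, and then either stays hyperintense (demyelinated
classes) or decays back into the NAWM band over 4–9 weeks
(remyelination). Enhancement accompanies lesion appearance in ~82% of
lesions and resolves within 1–2 subsequent scans; only lesions still in
their active phase enhance at the terminal scan. Lesions whose peak
volume exceeds 0.5 µL do not remyelinate.

## Pipeline stages and their parameters

**Normalization** divides by the mean over the gray-matter mask; it is
idempotent and scale-invariant, so already-normalized input is unchanged.

**Segmentation** thresholds normalized PDw inside the white-matter mask at
0.80 (chosen between the NAWM band ceiling 0.75 and the lesion peak range
0.85–1.00; configurable), extracts 26-connected components, and removes
components smaller than 4 voxels — the conventional minimum lesion size.
Surviving components are relabeled deterministically by descending size,
ties by centroid. A trained segmentation network would be opaque here; the
claims under test concern the post-segmentation logic, so a transparent
threshold segmenter is used.

**Tracking** identifies components at consecutive timepoints as the same
lesion when they overlap by ≥ 4 voxels in 3D; with several qualifying
predecessors the maximal overlap wins (ties to the smaller label).
Components that fail week-to-week linking are re-attached to an existing
track when they overlap its full-extent ROI by ≥ 4 voxels — this covers
both a lesion that disappeared and reappeared and a transient split at the
threshold (noise can briefly cut a near-isointense lesion in two); the
event is recorded on the track. Otherwise a new track starts. For weeks
before first detection and after disappearance, statistics are measured in
the propagated maximum-extent ROI (the component at the week of maximal
volume), so the pre-lesion baseline and post-recovery plateau are always
defined; these points carry `roi_propagated = True` and volume 0.

**MRI classification** needs ≥ 2 pre-lesion baseline points to estimate a
baseline mean µ_b and SD σ_b. A timepoint is *hyperintense* when its mean
normalized intensity exceeds µ_b + max(0.05, 2 σ_b); the 0.05 floor keeps
the band meaningful when the baseline is nearly noiseless, and the 2 σ
term widens it for noisy baselines (both configurable; the underlying
rater criterion is qualitative, and this operationalization is the
package's). Rules in order: terminal-hyperintense and enhancing → early
active; terminal-hyperintense, not enhancing → chronic demyelinated;
previously hyperintense, terminal-isointense, not enhancing →
remyelinated. Enhancement takes precedence, since it is what separates the
two demyelinated classes. The size rule treats the 0.5 µL boundary as
inclusive ("larger than 0.5 µL" excludes the boundary itself).

**Window estimation** (remyelinated tracks only): demyelination starts at
the first hyperintense timepoint; remyelination starts at the intensity
maximum; the plateau is the first later timepoint that is isointense and
stays isointense. With noiseless weekly data the estimated duration equals
the generator's true duration exactly; at the study noise level the
intensity maximum can drift 1–2 weeks into the flat early part of the
decay, biasing durations slightly short (about −0.5 weeks on average).

**Histology.** Demyelinated area is 100 × (null pixels)/(total pixels)
inside the core ROI — value 0 encodes "unstained", matching threshold-tool
practice. The ROI is a square centered on the lesion core. The literal
"1500 µm²" area reading (a 38.7 µm square) cannot "include even the
biggest lesion", so the default convention is a 1500 µm **side**; a config
switch (`RoiSpec(kind="area")`) restores the literal reading. Cells are
8-connected components of Olig2-positive pixels; a cell ≥ 50% covered by
ASPA-positive pixels is a mature oligodendrocyte, otherwise an OPC (the
overlap fraction is this package's rule). Categories: remyelinated iff
PLP unstained ≤ 6% **and** oligodendrocytes ≥ 12 (above the chronic-class
level — repopulation is required); otherwise early active iff Iba1
positive-pixel density ≥ 0.30 (prominent infiltration), else chronic. A
lesion remyelinated on PLP but > 20% unstained on LFB is classified by PLP
and flagged discordant, preserving the ambiguity rather than resolving it.

**Statistics.** The positive class is remyelination throughout. t-tests
default to Welch (unequal variances; a pooled-variance flag exists), ANOVA
is the standard one-way F, and no multiple-testing correction is applied.
Cohen's κ uses the usual (p_o − p_e)/(1 − p_e) with marginal-product
chance agreement. The point-biserial p uses the t transform with n − 2 df;
for binary outcomes an exact permutation p is available by hypergeometric
enumeration of the group-1 positive count. The evaluation report prints
the table-derived specificity next to any externally stated value and
flags disagreement beyond one percentage point; for the reference cohort
the 2×2 cells give 19/22 = 86.4% while the stated value is 90% — the
binary accuracy 28/31 = 90.3% is the plausible source, and both are
reported.

## The synthetic generator

`synthgen` emulates the study conditions so that every stage can be tested
against exact ground truth: 64 × 64 × 24 grids with a central white-matter
box and surrounding gray matter, 22 weekly timepoints with ≥ 2 lesion-free
baseline scans, per-subject NAWM baseline drawn from 0.65–0.75, lesion
class mix 30/25/45% (early active / chronic / remyelinated), integer
demyelination durations 4–7 weeks and remyelination durations 4–9 weeks,
log-uniform peak volumes 0.02–3.0 µL, additive Gaussian noise of SD 0.01
normalized units, enhancement probability 0.82 at first detection with a
0.2 offset on post-gadolinium T1.

Lesions are axis-aligned ellipsoids with mild per-axis jitter, placed in
white matter with a one-voxel separation margin (so distinct lesions can
never fuse into one 26-connected component); placement failure after
bounded retries raises an error naming the lesion. Intensity is uniform
across the lesion at each week: at the first scan after onset the lesion
is already hyperintense (≥ 0.85 — the sub-week initial rise is unobserved
at weekly sampling, which is also what makes "first detection within one
scan interval of onset" well defined), rises linearly to its peak, and for
remyelinating lesions decays back to baseline as a quartic in time
(slow initial drop, then a rapid return into the isointensity band — a
downward slope followed by a plateau). Two generator constraints exist to
keep the stated study conditions self-consistent: peak intensity is at
least baseline + 0.15 (lesions are unambiguously hyperintense, and the
plateau detector's crossing lands within the ±1-week window-recovery
tolerance), and peak volumes are clamped to at least 5 voxels (0.1125 µL)
so every true lesion survives the 4-voxel minimum filter — otherwise the
generator's own round-trip guarantee (100% recovery at zero noise) would
be violated by construction. Remyelinated lesions are additionally capped
at 0.5 µL after voxelization, matching the size rule.

Terminal histology endpoints are drawn per class. The PLP/LFB unstained
percentages use the reference class-conditional moments (PLP 58 ± 25 /
38 ± 25 / 4.5 ± 1.1% for early/chronic/remyelinated, NAWM 2.6 ± 0.3; LFB
63 ± 26 / 43 ± 26 / 15 ± 25%, NAWM 3.0 ± 0.4). Exact cell-count and Iba1
distributions are not published as numbers, so the generator uses values
chosen once to encode the reported qualitative ordering — oligodendrocytes
8 ± 4 / 5 ± 3 / 25 ± 6 (NAWM 35 ± 5), OPC 15 ± 5 / 4 ± 2 / 6 ± 2 (NAWM
5 ± 2), Iba1 density 0.50 ± 0.10 / 0.15 ± 0.05 / 0.08 ± 0.03 —
oligodendrocyte repopulation in remyelinated lesions, an OPC excess in
young early-active lesions (which also reproduces the negative lesion-age
vs OPC correlation at cohort level), and prominent microglial infiltration
only in active lesions. Stain images are rendered so quantification
recovers the truth: an exact-count center-weighted null-pixel blob for
PLP/LFB, an exact positive-pixel fraction for Iba1, and non-touching
disc cells on a jittered grid for ASPA/Olig2 (counts recover exactly).

What the generator does **not** model — and what passing tests therefore
do not show about real data: registration error, bias fields, motion,
partial-volume effects, irregular lesion shapes, confluent or reappearing
lesions, spatially heterogeneous (e.g. edge-only) remyelination, rater
variability, or any real anatomy. Recovery of the true class at 100% under
these conditions demonstrates the internal consistency of the rules and
the correctness of the implementation, not field performance.

## Numerical and design choices

- Determinism: one integer seed drives everything (per-subject and
  per-lesion streams are spawned from it); identical configuration gives
  bit-identical volumes, tracks and reports. Volumes are float32.
- Degenerate inputs raise informative errors rather than warning-and-
  continuing: empty masks, zero gray-matter mean, mismatched grids, < 2
  baseline points, tracks that are never hyperintense, all-propagated
  tracks, undefined sensitivity/specificity denominators, constant inputs
  to correlations.
- Problem sizes in the default test and acceptance runs (25 × 8 lesions
  for parameter recovery, 4 × 6 for window recovery, 100 histology
  round trips, 1,000 calibration simulations) were chosen as the smallest
  cohorts at which the binomial uncertainty of the checked rates is well
  inside the asserted margins.
- The "4 voxels (0.0225 µL)" convention: 0.0225 µL is the volume of one
  voxel at the reference spacing; the minimum-size filter is defined by
  the voxel count (4 voxels = 0.09 µL).

## Known limitations

- The MTR-based rater categorization arm is not implemented: its criteria
  are not reproducible from the available description. MTR maps are
  computed and the generator encodes a demyelination-dependent MTR drop,
  but classification uses PDw + terminal enhancement only.
- Track/truth matching in the evaluation uses maximal voxel overlap with
  the generator's lesion geometry; it is exact for the generator's
  non-overlapping lesions but would need revisiting for confluent ones.
- The window estimator's argmax-based remyelination onset is slightly
  early-biased under noise (see above); a change-point fit would be more
  robust but less transparent.
- `binarize_and_tabulate` excludes lesions without histology rather than
  imputing; the excluded count is logged.
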