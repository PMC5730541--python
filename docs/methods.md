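# Methods

This note documents the models, conventions and numerical choices behind
`mandasym`, and what the synthetic validation does and does not show.

## Coordinate frame and projections

All geometry lives in a right-handed millimetre frame: +x is the
subject's anatomical left, +y anterior, +z superior. The source material
for this kind of analysis never states a frame, so this one is fixed and
written into every landmark file.

The facial midline is defined in the frontal (posteroanterior) view as
the line through the crista galli perpendicular to the latero-orbitale
segment Lo–Lo′. Clinically this view is a radiograph, i.e. a perspective
projection; the package uses an **orthographic** projection onto the x–z
plane (drop y) instead. This is a deliberate deviation: magnification and
distortion are precisely the artefacts that motivate 3D analysis over 2D
cephalometry, and an orthographic projection makes the midline and the
menton deviation exactly reproducible functions of the 3D landmarks.
Menton deviation is the *perpendicular* signed distance of the projected
menton from the midline (whether clinical practice measures
perpendicular or horizontal distance is ambiguous; perpendicular is used
throughout). Positive deviation means toward +x (subject-left); the
FA/NA classification uses the magnitude, with the 4-mm threshold
inclusive (|d| = 4.0 mm is FA). An exactly-zero deviation assigns the
"deviated side" to the left with a logged warning.

## Condylar base plane and volumetry

The ramal axis runs from F (mandibular foramen) to Cd (condylar apex);
the condylar base plane is perpendicular to it and passes through
Cd_neck. The plane's normal is oriented toward Cd, so "the condyle" is
the positive half-space. Only the axis projection of Cd_neck matters:
displacing it parallel to the plane changes nothing (tested property).

Clipping: triangles are classified by signed distance to the plane;
vertices within 1e-9 mm are snapped onto the plane first, which prevents
sliver triangles in the cap. Mixed triangles are clipped
(Sutherland-Hodgman against the positive half-space) with cut points
cached per mesh edge so adjacent triangles share them exactly. The open
boundary of the kept surface is then assembled into directed loops and
each loop is closed by a fan from its centroid, wound so the cap's
outward normal points along −n. Fan capping is exact for star-shaped
cross-sections, which condylar (and all convex test) cross-sections are;
multiple loops are capped independently (verified on a torus). Zero-area
slivers that remain after snapping are left in place — removing them
would open the surface, and they contribute nothing to the volume.

Volume is the signed-tetrahedron (divergence-theorem) sum; a negative
sum indicates inward winding and is reported as |V| with a logged
warning rather than an error. Non-watertight input (any edge not shared
by exactly two faces, or inconsistent winding) is rejected with the open
edge count — mesh repair is out of scope. The surface-enclosed volume is
computed; internal voids, if a mesh had them, would subtract.

Condylar and inferior ramal height are measured along the Cd–Go_mid
line on either side of its intersection with the *infinite* base plane
(no clamping to the anatomical outline), exactly as the landmark
definitions imply; the intersection must fall inside the Cd–Go_mid
segment or an anatomical-inconsistency error is raised. The gonial angle
is the true 3D angle at Go_mid between the Cd_post and Me directions,
not a projected angle — the projected alternative is under-specified.

## Exact nonparametric tests

With 14 subjects per group, asymptotic p-values are the wrong tool, so
the exact null distributions are used whenever the data permit:

* **Mann-Whitney U**: exact permutation distribution of U (count
  recursion c(u; n, m) = c(u−m; n−1, m) + c(u; n, m−1)) for sample sizes
  up to 20 without ties; otherwise mid-ranks with the tie-corrected
  normal approximation, *without* continuity correction — so two
  identical samples give p = 1 exactly.
* **Wilcoxon signed-rank**: zero differences are dropped (Wilcoxon's
  original rule, logged); exact sign-flip distribution of W⁺ (generating
  polynomial ∏(1 + x^i)) for up to 20 nonzero differences without tied
  magnitudes, tie-corrected normal approximation otherwise. All-zero
  input degenerates to p = 1 with a warning.
* **Spearman**: rho from mid-ranks; exact permutation p for n ≤ 10
  (cached Σd² distribution when tie-free, full enumeration of pairings
  with ties), Student-t approximation above.

Two-sided p-values throughout, computed as 2·min(CDF, survival) capped
at 1 (the exact distributions are symmetric). No multiple-testing
correction is applied by default, matching common practice in this
literature; `holm_adjust` is available as an opt-in helper. The exact
implementations are cross-checked in the test suite against brute-force
enumeration over all labelings / sign patterns / pairings and against
scipy's independent implementations.

Dahlberg's duplicate-measurement error is Se = √(ΣD²/2n); the
reliability report computes it per rater and between raters (on
rater-mean series).

## Table conventions

Bilateral contrasts are **difference = nondeviated − deviated** and
**ratio = deviated ⁄ nondeviated**. The ratio direction makes the
negative correlations between |menton deviation| and the ratios the
natural signature of asymmetry (more deviation → relatively smaller
deviated side → ratio further below 1), and the difference direction
makes FA group means positive. For NA subjects the "deviated side" is
still the side of the (small) deviation. The FA-vs-NA per-side
comparison defaults to matched sides (deviated vs deviated, nondeviated
vs nondeviated); pooling both NA sides is a config option. Significance
stars (\*: p < 0.05, \*\*: p < 0.01) are emitted in a separate column,
never embedded in numbers. A group with fewer than two subjects gets
descriptive columns only.

## Synthetic cohort generator

The generator's defaults are the published group statistics of a
28-patient surgical mandibular-prognathism cohort: per-group, per-side
means/SDs of the six measurements, |menton deviation| 8.9 ± 4.3 mm (FA)
and 1.6 ± 0.8 mm (NA), 14 subjects per group.

**Sampling model.** Only marginal means/SDs and the correlation *signs*
are published, so the joint structure is a modelling choice, kept as
simple as possible:

* five base measurements are sampled per side (ramal height is the sum
  of condylar and inferior ramal height, never sampled — the partition
  is a geometric identity);
* a shared per-measurement size factor couples the two sides
  (`cross_side_corr`, default 0.5);
* a single **asymmetry coupling** a (default 0.65) depresses the
  deviated side's standardised score by a·u, where u is the subject's
  menton-deviation score standardised *within the truncated group band*
  — this induces the negative deviation-ratio correlations and keeps
  the configured side means/SDs the exact marginal moments;
* condylar and inferior ramal height are correlated within side
  (defaults 0.44 FA / −0.17 NA, chosen so the SD of their sum is close
  to the published ramal-height SDs).

Deviation magnitudes are drawn from the group's normal and
rejected/resampled outside the band ([4, ∞) FA, (0, 4) NA), so generated
cohorts classify perfectly at the 4-mm threshold by construction.
Measurement vectors with non-positive entries are likewise resampled
rather than clipped. Because ramal height is derived, its generator mean
is the sum of the partition means, which can differ from the published
(independently rounded) ramal figure by one rounding unit — e.g. 58.7 vs
the printed 58.6 for the FA deviated side.

**Geometric realisation.** Each hemimandible is built constructively in
a canonical left-side frame — ramus vertical from Go_mid, F off the
ramal line so the Cd–F axis is oblique, Cd_neck offset laterally within
the base plane, Me placed at the requested body length and gonial angle
— and the right side is the mirror image (distances and unsigned angles
are mirror-invariant). Both sides are then translated so they share the
menton, which sits at the subject's signed deviation from the x = 0
midline defined by fixed cranial landmarks; deviation is thus realised
as lateral translation of the symphysis, not rotation of the mandible.
Cd_post sits on the posterior ramal border at 0.8 of ramal height.

The condyle is an ellipsoid solid with its polar axis along the ramal
axis, apex exactly at Cd, vertical semi-axis 3/4 of Cd's height above
the base plane (so it dips below the plane like a neck). Its lateral
semi-axes are seeded from the analytic ellipsoidal-cap volume and then
corrected once by the exact ratio of requested to discretised clipped
volume — in-plane scaling about the axis leaves the plane and the clip
combinatorics untouched and scales the clipped volume quadratically, so
the discrete clipped volume equals the request to floating-point
precision, at any mesh resolution (default 24×24 UV sphere).

**Round-trip guarantee.** Measuring the generated geometry reproduces
the drawn measurement vector to 1e-6 mm (linear, angular) and to
floating-point precision for volume; this is what makes
parameter-recovery and cross-table tests meaningful.

**What the generator does not emulate:** a full mandibular surface (only
landmark geometry plus a condylar solid), landmark digitisation error
(added explicitly in the reliability analysis), anatomical covariance
beyond the single coupling parameter, rotational components of
asymmetry, and any imaging artefacts. Passing tests therefore validate
the *measurement and statistics machinery*, not claims about real
patient anatomy.

## Validation fixtures and problem sizes

The cross-table consistency check feeds the table builder a fixture
cohort whose per-side measurements equal the published side means,
realised through the full landmark/mesh pipeline. By linearity of the
mean, the bilateral-difference means must then equal the
nondeviated-minus-deviated side-mean differences; the published
difference table is reproduced to one rounding unit (the published
ramal-height and one condylar-volume cell are internally inconsistent
with their own side means by one to three tenths, which the checks
tolerate explicitly rather than hide).

Simulation problem sizes were chosen to keep the whole validation suite
in the minutes range on one CPU while leaving binomial/SE margins
comfortable: 10,000 replicates for the type-I error of the exact
Mann-Whitney test (SE ≈ 0.002 at the nominal 0.05), 1,000 replicates for
the n = 14 sign-recovery rate, and n = 200 per group (3-SE band) for
parameter recovery. Sphere-based volumetry oracles use icosphere
subdivision 4, where discretisation error is below 0.5 %.

## Known limitations

* The fan cap assumes star-shaped cut cross-sections; highly non-convex
  cross-sections (not reachable with the shipped generator) could
  self-intersect, although the volume sum would often still be correct.
* Non-manifold meshes are rejected, not repaired.
* The exact Spearman permutation p enumerates up to 10! pairings; n = 10
  with ties is the slow worst case (seconds).
* The generator's inter-measurement covariance is a one-parameter
  stand-in for an unknown anatomical covariance structure; only marginal
  moments and correlation signs should be compared against published
  cohorts.
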