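# Methods

## Data model

A traced network is a rooted tree of vessel segments. Each segment is an
ordered polyline (proximal → distal) of centerline points carrying outer
and inner (lumen) diameters in µm. The analysis is planar: traced coronary
collages are horizontal-plane projections of vessels running parallel to
the epicardial surface, so SWC z-coordinates are dropped on import (with a
warning when nonzero). On load, coordinates are translated so the orifice —
the first point of the root segment — sits at (0, 0); the X axis points
orifice → apex and positive Y toward the left ventricle. A child segment
must begin within 5 µm of some vertex of its parent (manual-tracing
tolerance); the nearest such vertex defines the attachment arc position
used for flow distances. Every traced point must keep an outer diameter at
or above the preparation cutoff (default 80 µm), mirroring how far
peripheral tracing is carried.

SWC files store a single radius, taken here as the *outer* radius; the
lumen is derived from a linear wall model w = a + b·d_outer supplied at
import. This import rule is a convention of this package, not a property of
the source data; if the model would close the lumen the inner diameter is
clamped to 5 % of the outer diameter (logged).

## Ring units

Segments are cut independently into 50-µm rings from their proximal end;
ring k spans arc [(k−1)L, kL] and its feature vector is sampled at the
centre arc position (k−½)L. A trailing remainder shorter than L is
discarded (floor rule); remainder handling and centre-sampling versus
span-averaging are free choices here — centre sampling with linear
interpolation between the bracketing traced points is the simplest
consistent estimator and is exact under linear taper. The ring axis angle
is the secant direction over one ring length, folded to [0°, 180°) because
a ring axis is undirected. Flow distance of a ring is the parent-path flow
distance at the attachment plus (k−½)L; it always dominates the direct
(Euclidean) distance by the triangle inequality, with equality on straight
unbranched stems through the origin.

## Bifurcations

Every attachment point with at least two daughters is a bifurcation; the
distal continuation of the parent counts as one daughter, a single child at
a segment tip is a plain continuation (not recorded), and trifurcations are
reduced to the two largest daughters with a warning. Axes are secants over
a 100-µm window (two ring lengths — wide enough to smooth tracing noise,
short against the ~900-µm segment scale) proximal for the mother and distal
for the daughters. The reported angle is 180° − arccos(u_m·u_d): 180° for a
daughter continuing the mother's course, 90° for a perpendicular takeoff.

Murray compliance uses lumen radii: residual(γ) = log₁₀(r_d1^γ + r_d2^γ) −
γ·log₁₀ r_m, zero at exact compliance and invariant under uniform
rescaling. The exponent is estimated by minimizing the sum of squared
residuals over γ ∈ [1, 6] (bounded scalar minimization, tolerance 1e-8).
On noise-free data this recovers the generating exponent to three decimals
for any γ ∈ [2, 4].

**Known limitation — exponent attenuation.** The least-squares-in-γ
estimator treats the mother radius as exogenous. When daughter radii
scatter log-normally around the Murray prediction (the regression reading
of calibre noise), the scatter leaks into the γ-sensitivity of the
objective and attenuates the estimate: at σ = 0.05 and daughter asymmetry
r_small/r_large ∈ [0.4, 1.0] the bias is ≈ −0.14 over 200 bifurcations, so
individual fits land around 2.81–2.94 rather than 3.00. Placing the same
noise on all three radii roughly doubles the attenuation (≈ 2.68).
Very asymmetric bifurcations carry almost no information about γ (the
residual's γ-derivative vanishes as the small daughter vanishes), so
identifiability rests on the near-symmetric branch points.

Group differences in compliance ("deviations not significantly different")
are assessed by ANOVA on |residual| per group — a stand-in, since the
original analyses do not name a test.

## Spectra and χ²

Outer diameters are classified into 13 half-open 50-µm classes centred at
100, 150, …, 700 µm; rings under 75 µm (just below the preparation cutoff)
are dropped with a logged count, and anything ≥ 725 µm pools into the top
class. This binning is chosen so that a two-group comparison occupying all
classes has 12 degrees of freedom, matching how such spectra are reported;
exact bin edges are otherwise unconstrained by the source analyses.
Bidimensional histograms cross the same diameter classes with 1-mm
half-open flow-distance bins up to a 25-mm ceiling; the marginal over
distance reproduces the diameter spectrum of the in-range rings.

Group spectra are pooled over animals before the two-sample χ² homogeneity
test (2 × K table, classes empty in both groups dropped, df = K′ − 1, no
continuity correction). Pooling rings across animals is pseudo-replication
— the test treats every ring as independent — and is documented rather
than corrected, because that is the design being reproduced. Under the
null (two multinomial samples of 700 rings over 13 classes) the empirical
type-I rate at α = 0.05 sits inside [0.035, 0.065] over 2000 replicates.

## Wall morphometry

Per diameter class: ring count, mean wall thickness and SEM (reported
missing below n = 2), plus the overall Pearson correlation of wall with
outer diameter. Group comparisons use a ring-level two-way ANOVA
(group × diameter class with interaction). Type-II sums of squares are
used for unbalanced layouts (ring counts per class differ between groups);
on balanced designs this coincides with the classical decomposition and is
verified against a from-scratch sums-of-squares oracle to 1e-6 relative
error. Classes with an empty cell in any group are excluded (logged).
Tukey HSD pairwise group comparisons run within each retained class; under
the null the family-wise error at α = 0.05 is empirically within
[0.03, 0.07]. The ring-level unit of analysis inherits the
pseudo-replication caveat above.

## Echo formulas

Inputs in cm (linear LV dimensions) and g (body weight): LV mass (g) =
[[(LVEDD + AWTd + PWTd)³ − LVEDD³] × 1.04] × 0.8 + 0.14; mass index =
mass/BW in g/kg; FS = (LVEDD − LVESD)/LVEDD × 100; Teichholz volume
V(D) = 7D³/(2.4 + D) ml; EF from the two Teichholz volumes. The 0.14
additive constant is taken to be in grams. EF ≥ FS for all
0 < LVESD < LVEDD (checked numerically over a grid).

## Synthetic generator

The generator emulates the constraints of a microprepared LAD network
rather than its biophysics: planar recursive growth from the orifice along
+X in 50-µm steps with a Gaussian direction random walk (tortuosity SD 3°
per step), log-normal segment lengths (median 900 µm, σ_log 0.4), linear
per-segment lumen taper, exact Murray splits at segment tips with daughter
asymmetry ratio uniform on [0.4, 1.0], a wall law w = 8 + 0.06·d_outer µm
with Gaussian noise (SD 3 µm) entering through the wall only (lumen radii
stay exactly Murray-compliant unless radius noise is requested in the
direct bifurcation sampler), and an angle law
angle = 180° − 25·(r_m/r_d − 1) ± 10° clamped to (60°, 180°], which
produces the negative angle-versus-ratio correlation seen in real trees.
Branches stop at the 80-µm outer-diameter cutoff or beyond 20 mm of flow
distance. All randomness flows from one seeded NumPy generator; cohort
members get seeds derived deterministically via `SeedSequence.spawn`.

**Calibration.** The free scale parameter is the per-segment taper. Real
traced networks of this preparation hold roughly 700–780 ring units per
heart; with the other defaults above, a taper of 0.15 per segment yields a
mean of ≈ 760 rings per network (range ≈ 600–920 over 20 seeds), inside
the documented 500–1000 band, so 0.15 is the default. (Shallower taper
such as 0.05 produces several thousand rings per tree — far more periphery
than the 80-µm tracing limit admits.)

**Presets.** `MSed` is the male baseline (root outer diameter 550 µm);
`FSed` is thinner-rooted (480 µm) with a lower wall intercept. `MEx`
raises the wall slope by +0.025 on the 200–500-µm calibre window and
inserts extra 400-µm-class side branches within 5 mm of the orifice and
200-µm-class branches at 8–13 mm; `FEx` lowers the large-vessel wall slope
and inserts 200–250-µm side branches at 5–8 mm. These encode the
qualitative group contrasts (training thickens male mid-calibre walls and
shifts the calibre spectrum; in females a new small-calibre population
appears close to the orifice) and are not calibrated to absolute counts.

What passing tests on these trees show: the pipeline's geometry,
conservation and statistical machinery are correct, and imposed group
effects of realistic direction and size are detected. What they do not
show: anything about real tracing noise (segment crossings, collage
stitching errors, diameter-reading bias), non-planarity, or the true
effect sizes in animals.

Because no ring can exceed the root calibre (550 µm), preset-based group
comparisons occupy only the lower ~10 diameter classes and their χ² df is
correspondingly K′ − 1 < 12; the 12-df case arises for fully occupied
spectra, as produced by real pooled data.

## Numerical choices and degenerate inputs

Linear interpolation everywhere along polylines (positions, diameters);
half-open binning with the upper class pooling; direction secants clipped
to the segment with an error on zero-length spans; segments shorter than
one ring length contribute zero rings (logged, not an error); empty
networks refuse to serialize; χ² comparisons with fewer than two occupied
classes return χ² = 0, df = 0, p = 1; Pearson correlations on
zero-variance inputs raise rather than return NaN. Problem sizes in tests
(cohorts of 4–10 networks, 100 generator seeds, 2000-replicate null
simulations) are the package's own choice of desk-scale defaults that keep
the full suite in a few minutes.
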