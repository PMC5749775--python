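# Methods

## Scope and model

The package implements chromosomal DNA sizing by Feulgen image cytometry:
transmitted-light optical density is integrated per chromosome portion and
the flow-cytometric nuclear 2C value is distributed proportionally to
integrated optical density (IOD).  The method rests on two assumptions:

1. **Stoichiometry.** Feulgen-stained chromatin absorbs in proportion to
   local DNA, so pixel OD = log10(I0/I) is a DNA surface density and IOD is
   proportional to DNA mass with one slide-wide constant.
2. **Proportional allocation.** Ratios of IODs equal ratios of DNA
   amounts, so anchoring the complement total to the FCM 2C value yields
   absolute per-portion amounts without absolute densitometric calibration.

Under these assumptions conservation is built in algebraically: arm values
sum exactly to their pair value and pair values to the nuclear 2C (asserted
to 1e-12 relative in the tests), and the allocation is invariant to
rescaling all IODs by a constant.

## Flow-cytometric sizing

The 2C estimate is the ratio estimator `2C_standard × ch_sample /
ch_standard` on the fitted G0/G1 peak means.  Peak fitting proceeds in
three stages: local maxima of a lightly smoothed histogram (Gaussian
σ = 1 channel) above a count threshold seed the fits; each peak is refined
on a ±2.5 σ window against the counts minus the other components
(backfitting); a final joint fit of the full Gaussian mixture on the union
of windows removes the residual bias that windowed fits keep when peaks
overlap.  With two populations 19 channels apart at CVs of 3.2%/3.8% and
10,000 events — the regime of the reference measurements — the estimator is
unbiased (Monte-Carlo bias ≲ 1e-3 pg) and fitted means land within 0.2
channels of truth at 50,000 events.  CVs come from the fitted σ, not raw
moments, so a debris floor does not inflate them; fits with CV > 5% are
flagged rather than rejected (the reference measurements accepted
3.0–4.1%).  Light smoothing for candidate detection matters: the valley
between G0/G1 peaks at these CVs is shallow, and σ ≥ 2 channels of
smoothing erases it in a noticeable fraction of seeded histograms, while
σ = 1 resolves it reliably; a minimum candidate separation (5 channels)
prevents both candidates from landing on one peak.

## Densitometry and calibration

Background I0 is the mode (unit-count bins) of non-object pixels, the
bright Otsu class by default — robust against the dark tail that would bias
a mean.  OD is the Beer–Lambert inverse with negatives clipped to zero and
zero-count pixels capped at the OD of 0.5 counts and flagged in a
saturation mask (12-bit floors occur inside dense knobs; affected
measurements carry flags instead of infinities).

Instrument qualification mirrors standard ICM practice: **linearity** is
the R² of measured mean band OD against the nominal ODs of an 11-step
density filter (synthetic default: ODs 0.1–1.1); **uniformity** is the CV
of per-tile mean intensities on an 8×8 grid of a blank field (tiling
suppresses shot noise so the statistic tracks illumination structure, which
is what a field-uniformity CV is meant to capture); **stability** reports
the first time from which the rolling range of the mean-OD trace (window 3
samples, tolerance 0.03 OD by default) stays within tolerance.  The
bundled warm-up simulator (exponential approach, τ = 5 min, sampled every
2 min) settles at 12 min under the default test settings.

## Synthetic metaphases

Each chromosome is a curved capsule: an arc-length-parameterised axis with
sinusoidally varying heading (bend amplitude 0.25–0.5 rad), constant width
1.1 µm, and Gaussian width dips of 40% depth at constrictions (σ 0.8 µm at
the centromere, σ 0.3 µm at the secondary constriction, which must fit
inside a ~1 µm satellite).  Pixel intensity is
`clip(round(I0·g·10^(−OD) + noise))` in a 16-bit container with 12-bit
range (I0 = 3000 counts, Gaussian read noise σ = 8 counts, optional Poisson
statistics and a linear illumination gradient g).

DNA→OD scaling is a single user-visible constant per slide
(`iod_per_pg` ≈ 26.6 OD·µm²/pg, anchored so chromosome 1 carries its
published IOD of 10.679 at 0.4015 pg).  The renderer distributes each
*arm's* declared DNA over that arm's pixels, weighted by knob blocks
(density multipliers 1.6–2.0 on the long arms of pairs 2–9), so per-arm
integrated OD equals the declared arm DNA times the constant *exactly*.
Knobs therefore raise local density contrast — detectable as bands ≥1.3×
the median linear density — without changing arm totals; this keeps the
ground truth exactly recoverable, which we judged more valuable than
letting knob mass float on top of the declared amounts.

The default karyotype takes its DNA composition from the published per-arm
2C table (pair totals 0.803…0.386 pg, satellite 0.053 pg, complement
6.10 pg).  Chromosome areas scale linearly with pair DNA
(11.8 µm² per pg of pair 2C), which reproduces the four printed area
anchors (chromosomes 1, 8, 9, 10) within ~2% and makes mean OD ≈ 1.12
across the complement, matching the printed OD range; absolute lengths
follow from area at the default width, since only relative lengths are
published.  Arm ratios are free choices within the published classes:
1.15 and 1.30 for the metacentric pairs 1 and 5, 1.65–2.65 for the
submetacentric pairs.  For the satellited pair 6 the ratio is defined on
long/(short + satellite), so the class is identical whether or not the
satellite is counted with the short arm — this keeps classification robust
to an occasional missed secondary constriction.  The satellite's length
(1.0 µm) is sized to its DNA share like every other portion; an oversized
satellite would render at roughly half the body's stain density and sit on
the segmentation threshold.

Placement is rejection sampling: no two chromosomes closer than 3 px, no
canvas contact, bounded attempts with an explicit error naming the
canvas/size conflict.  A separate touching fixture lays the two homologs of
the largest pair tip-to-tip with slightly interpenetrating caps (plus two
isolated small chromosomes as a size reference) to exercise the watershed
splitter.  Identical spec + parameters + seed give bit-identical images.

What the simulator deliberately does **not** model: chromatin texture and
banding, cytoplasmic background and debris, partial-volume edge pixels
(masks are binary, so rendered object borders are sharp), overlapping or
bent-and-twisted chromosomes, and DAPI fluorescence.  Passing recovery
tests therefore demonstrates the correctness of the measurement chain under
the stated imaging model, not segmentation robustness on real slides,
where touching chromosomes, halos and focus gradients dominate the error
budget.

## Segmentation and morphometry

Segmentation is a global Otsu threshold on OD, connected components, and a
distance-transform watershed applied to components larger than 1.6× the
median area.  Watershed markers are the connected regions above 0.6× the
component's maximum distance value: the contact waist between touching
chromosomes falls below that fraction while the 40% constriction dips stay
above it, so merged objects split without fragmenting single chromosomes.

The medial axis is the ridge-weighted geodesic between the two
geodesically farthest pixels of the mask (8-connected pixel graph; edge
cost = Euclidean step × (1 + 4/EDT)).  Unlike a morphological skeleton,
this path spans tip to tip and crosses the narrow neck of a secondary
constriction into the satellite, which a skeleton does not reach.  Width
is twice the distance transform along the (smoothed) path.  Arc length is
measured by projecting raw path steps on the local tangent of a heavily
smoothed copy of the path, with end tangents clamped to the adjacent
interior chord within one cap radius of each tip: lattice zigzag and the
diagonal run a geodesic takes into a square corner then contribute only
their axial advance.  A 10 × 1 µm rectangle measures 10.15 µm; simulated
chromosome lengths recover within 2%.

The centromere is the global width minimum over the central 60% of the
axis (telomeric taper excluded), centred on its plateau, and validated by
requiring the full profile to rise ≥5% above the minimum on both sides —
flat profiles and monotone wedges raise an explicit error.  A secondary
constriction is accepted on the short-arm side only, outside a 1 µm
exclusion zone around the centromere, when its dip depth reaches half the
primary dip's; the segment distal to it is the satellite.  Pixels join the
arm whose side of the centromere their nearest axis point falls on
(locally the perpendicular cut, robust on curved chromosomes); the
partition is disjoint and exhaustive by construction, and per-portion IODs
sum to the chromosome IOD exactly.  S/L labels follow arm length, ties
broken by lower IOD.  Class thresholds (M exactly 1; m < 1.5; sm < 3;
st < 7; t ≥ 7) are a configurable table with the Guerra-revision defaults.

## Karyotyping

Homologs are paired by greedy minimum-distance matching on z-scored
(length, CI, IOD) with unit weights — the DNA amount is what separates
morphologically similar pairs; near-ties are flagged ambiguous.  Numbering
is either by decreasing length or by one-to-one nearest-neighbour
assignment (Hungarian algorithm on normalized length/CI distance) to a
reference table, which preserves conventional maize numbers; disagreements
with pure size order — chromosome 9 vs 8, whose area and DNA order is
inverted — are reported as inversions.  On ten seeded default plates
pairing is 100% correct and reference-map numbering recovers all
conventional numbers.

Cross-study comparison reports percent differences in both directions
explicitly, with the named external study as the denominator, on 1C values
rounded to three decimals of 10⁹ bp — the printed precision at which the
reference percentages (7.67%, 26.00%) are exact.

## Numerical choices and degenerate inputs

- Allocation SDs come from per-metaphase allocations (each metaphase
  allocated against its own complement total), matching the
  between-metaphase semantics of the published ±SD column; SD is undefined
  (None) with fewer than two complete metaphases.
- Reported tables round pg and 10⁹ bp values to three decimals; full
  precision is kept internally.
- A metaphase contributing a homolog count other than two for a pair is
  excluded for that pair with a warning; portions missing from one homolog
  (an undetected satellite) count as zero rather than silently shifting
  mass between portions.
- Empty masks, odd chromosome counts, zero total IOD, negative DNA
  amounts, non-increasing histogram channels and identical linearity
  nominals all raise typed errors (`icmkaryo.errors`).
- Problem sizes in the test suite: recovery properties run on ten
  560×560 px plates (20 chromosomes each) and published-value checks are
  closed-form; the full suite runs in well under a minute of compute per
  plate.

## Known limitations

- The satellite is detected in ~95% of rendered pair-6 homologs; a miss
  folds the satellite's mass into the short arm of that homolog (the
  aggregate satellite estimate is then biased low for that metaphase).
- The watershed splitter handles tip-to-tip and shallow side contacts; it
  is not designed for heavily overlapping chromosome clusters.
- Arm-level recovery accuracy (~1% median on default plates) is dominated
  by centromere localization, not by noise; strongly asymmetric real
  chromosomes with shallow primary constrictions would degrade it.
- The FCM model is a two-component Gaussian mixture with an optional
  uniform debris floor; S/G2 populations, doublets and gating are out of
  scope.
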