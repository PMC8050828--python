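# Methods

## Measurement model

A de-mixed Janus GUV sectioned at its equator is modelled as a circle of
radius R whose membrane carries two contiguous arcs: a liquid-disordered
(Ld) arc enriched in the lipid dye, and a liquid-ordered (Lo) arc. Two
detection channels are carried throughout: channel 0 is the lipid-phase
marker (Ld-bright), channel 1 the construct label. The per-vesicle
statistic is the fractional Lo intensity

    f = I_Lo / (I_Lo + I_Ld),

with I_Lo, I_Ld the background-corrected mean construct-channel intensities
over the two arcs. Assuming fluorescence proportional to construct
concentration, f maps to a partitioning free energy

    dG = -ln(f / (1 - f))        (kBT units, natural log)

and inversely f = 1/(1 + e^dG) — the logistic map. All energies are
dimensionless in kBT; no temperature parameter is exposed. The additive
anchor rule models a multi-anchor construct's free energy as the sum of
per-anchor contributions; the shipped anchor table (sC −0.4, dC −0.8,
sT +1.9, coupled sT+dC measured +1.0 kBT) comes from ternary-mixture
measurements and is overridable per run. Nonadditivity is reported as
measured − predicted, negative meaning stronger Lo preference than the sum
predicts.

Conventions, used everywhere: 0-based pixel coordinates with x = column,
y = row; angles in radians counter-clockwise from +x; default pixel pitch
0.2 µm/px (a 35 px radius is a 7 µm GUV). The pixel pitch and detector
statistics are configuration defaults, not asserted facts about any
specific instrument.

## Synthetic image generator

The generator exists so that every downstream stage can be validated
against programmed ground truth. Per vesicle and channel the pre-optics
signal is a Gaussian radial ring profile, amplitude A(θ) two-level with a
sharp arc boundary:

- lipid channel: Ld arc brighter by `lipid_contrast` (default 3);
- construct channel: Lo:Ld amplitude ratio e^(−dG) (the Boltzmann
  concentration ratio), with the two arc amplitudes normalised to a
  constant sum so overall brightness is comparable across dG.

Rendering then applies, in order: Gaussian PSF blur (σ 2 px), linear
inter-channel cross-talk (row-stochastic leakage matrix, identity by
default; photons are conserved when rows sum to 1), constant background
(100 counts), and shot noise (Poisson on total counts; a Gaussian
alternative is selectable for low-count regimes). The PSF is the only
source of boundary smearing, keeping arc ground truth unambiguous.

Populations draw radii log-normally (median 35 px, shape 0.3, truncated at
15 px), arc fractions uniformly on (0.3, 0.7), arc orientations uniformly,
and per-vesicle free energies normally about the population mean with SD
`dG_jitter_sd` = 0.15 kBT. The jitter models vesicle-to-vesicle
compositional variability — real GUV populations show per-vesicle f
scatter of a few hundredths, which is why partitioning data are presented
as box-scatter distributions; without it the synthetic per-vesicle spread
collapses to the ~10⁻³ photon-noise floor and rank statistics over the
population degenerate. At f ≈ 0.6 the default gives SD(f) ≈ 0.04.
Placement is rejection sampling with non-overlap margins; one master seed
spawns independent per-frame placement and noise streams, so populations
are bit-reproducible.

What the generator does not emulate — and hence what passing tests do not
certify on real data: photobleaching, vesicle deformation and drift,
out-of-focus light from non-equatorial structure, multi-domain
(non-coalesced) vesicles, detector fixed-pattern noise, and chromatic
registration error between channels.

## Detection

Detection runs on the channel sum. The frame is smoothed (σ 2 px); a
robust gate (99.5th percentile at least 6 scaled-MADs above the median)
declares blank frames empty before any circle search. Ring pixels
thresholded at background + 25% of the peak excess vote in a Hough circle
transform over a radius grid (default 18–70 px, step 2); each peak is
refined by three iterations of an intensity-weighted algebraic (Kåsa)
circle fit over a radial band, giving sub-pixel centres (< 1 px error on
noise-free phantoms; radius < 2%).

Quality in [0, 1] is angular sector coverage of the thresholded ring times
a circularity term, 1 − 4·rms_c/R, where rms_c is the intensity-weighted
RMS deviation of per-sector radial centroids from R. Sector centroids are
insensitive to the membrane's radial width (an optics property), so the
score measures deviation from circularity, not ring thickness, and does
not penalise small vesicles. Contours below 0.5 quality are dropped; of
overlapping pairs the lower-quality one is dropped; vesicles whose annulus
comes within one ring width of the border are excluded rather than
partially quantified (partial arcs would bias the arc means).

The sampling annulus width defaults to 3× the intensity-weighted RMS
radial residual of the fit (≈ 3 σ_eff of the blurred membrane profile,
capturing essentially all membrane signal); the angular profile uses 72
bins (5°) so the smallest expected arc (30% of the circumference) spans
over 20 bins. Binning is exact: each annulus pixel belongs to one
half-open bin, and Σ(count × mean) reproduces the total annulus intensity
to machine precision.

## Segmentation

The lipid-channel bin means are split by exact Otsu scan (minimising
intra-class variance over all splits of the 72 values); the brighter class
is Ld. A 3-bin circular majority filter removes isolated flips, then the
largest contiguous cyclic run of each class defines its arc (ties broken
by higher mean contrast against the threshold; conflicting bins are
excluded). Two bins are excluded on each side of each phase boundary
(10° at default binning) because the PSF smears the domain edge; the
width is configuration-exposed and validated only by synthetic recovery.
Arcs shorter than 4 bins after exclusion raise an error rather than pass
silently.

The separation score is (mean_Ld − mean_Lo)/pooled SD over the retained
bins. The de-mixing gate (default 5.0) is applied both to the raw
two-class split — so a noise-only profile is reported as "not phase
separated" rather than as a degenerate arc — and to the final arcs. The
default sits above the ~2.7 truncation score that splitting pure Gaussian
noise at any threshold produces, and far below the scores (tens) of
genuinely de-mixed profiles at usable SNR.

## Quantification

Background is the per-channel median over pixels outside every vesicle
disk dilated by half the ring width plus a margin. Phase means are
pixel-count-weighted over retained bins (equal to the direct per-pixel arc
mean, robust to unequal bin occupancy); negatives after background
subtraction clamp to zero with a flag so f stays in [0, 1]. Vesicles with
no construct signal above background are dropped with a logged reason;
every detected vesicle appears in the decision log exactly once.

Bleed-through is a 2×2 linear mixing matrix estimated from
single-fluorophore controls: the off-diagonal entry is the observed
off-channel over on-channel membrane signal, diagonals normalised to 1.
Correction left-multiplies per-bin channel vectors by the inverse
(condition number capped at 10⁶), and the background vector is passed
through the same inverse before subtraction. FRET between the two
fluorophores is absorbed into this empirical matrix rather than modelled
photophysically: the pipeline's job is to demonstrate that mixing bias
exists and is removable, which the linear model does.

## Population statistics

Free energies are computed per vesicle and then averaged (vesicles at
f ∈ {0, 1} excluded and counted), alongside the f-scale summary — both
views are reported since they answer different questions (typical vesicle
vs population fraction). Two-sample comparisons use the two-sided
Mann–Whitney test: exact enumeration when the smaller sample has ≤ 8
tie-free values, the tie-corrected normal approximation otherwise;
degenerate inputs (all values identical) return p = 1 with a warning. The
radius-independence check is a Spearman rank correlation of f against
radius. Density sweeps summarise mean f per DNA-to-lipid ratio with a
flatness statistic over a stated stationary range; no saturation model is
fitted. No multiple-testing correction is applied — runs with more than
three pairwise comparisons are flagged in the log instead.

## Responsive device

The cargo's anchoring configuration is a three-state machine: State 1
(cargo on the sT module, Ld-localised), State 2 (bridging sT and dC),
State 3 (on dC, Lo-localised), with transitions Fuel1: 1→2,
Antifuel2: 2→3, Fuel2: 3→2, Antifuel1: 2→1 and all other (state, cue)
pairs warnings-level no-ops. DNA strand-displacement mechanics are
abstracted to these labels; hybridisation thermodynamics are out of scope.
Equilibrium f per state comes from the anchor library (State 2 either the
additive sT+dC sum, 1.1 kBT, or the measured coupled value, 1.0 kBT —
selectable, with no claim the dynamic experiment equals the static
construct). Relaxation between equilibria is single-exponential with
user τ (default 5 min, the diffusion-limited equilibration scale);
protocols produce piecewise traces that are continuous at cue times (only
the attractor switches). Incomplete reversibility is modelled, when
enabled, as a single additive offset applied to equilibria entered via
the reverse-path cues (default 0; no mechanism is claimed).

## Problem sizes and numerical choices

Validation suites run the full chain on 192×192 px single-vesicle frames,
20 vesicles per condition for free-energy recovery (recovered population
mean f within ±0.03 of the logistic ground truth across dG from −1.4 to
+1.9 kBT) and 40 for the radius-independence check — sizes chosen so each
population estimate's standard error (~0.008 in f) sits well inside the
recovery tolerance. Determinism: all randomness flows from explicit seeds
through `numpy.random.default_rng` / `SeedSequence.spawn`; identical
config and seed give byte-identical frames and CSVs. Degenerate inputs
raise typed errors (placement failure names the achieved count; clipped
annuli, non-de-mixed profiles, zero-signal vesicles and singular mixing
matrices each have a dedicated exception).

## Known limitations

Only circular contours and exactly two domains are supported; multi-domain
or deformed vesicles are rejected by the quality and contiguity gates, not
quantified. The boundary-exclusion width and de-mixing threshold are
validated against the generator, not against instrument data. Quaternary
lipid mixtures are analysable with the same pipeline but no anchor table
for them is shipped; anchor values there are user-supplied. The
experimental per-population distributions and the reported p-values of the
original study are not reproducible from this package since the raw
micrographs are not public; the pipeline's statistical machinery is
validated on synthetic populations only.
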