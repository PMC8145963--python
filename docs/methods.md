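# Methods

`colipid` implements the computational side of a plate-scale *E. coli*
phospholipidomics screen: profiling the lipidomes and growth of gene
knock-outs (KO) and overexpressors (OV) of the lipid-gene complement, with
and without sub-lethal n-butanol, to find marker lipids and genes that
control membrane adaptation. This note documents the models, the parameters
that matter, and the design decisions where the choice was genuinely open.

## In-silico lipid database

Species-level annotation names a lipid as `CLASS C:D[cK]` — headgroup class,
total acyl carbons, total double bonds, and optionally K cyclopropane rings —
without resolving individual chains or positions. Eleven glycerophospholipid
classes are enumerated: PA, PE, PG, PS, PGP, CDP-DAG, CL, DLCL, aPE, aPG and
PBut (phosphatidylbutanol, the transphosphatidylation product formed by ClsB
acting on n-butanol). Each class is a fixed zero-acyl backbone (e.g.
glycerophosphoethanolamine C5H14NO6P for PE; the bis(glycerophospho)glycerol
core C9H22O13P2 for CL and DLCL; PA backbone + C4H8 for the butyl ester
PBut) plus 2, 3 (headgroup acylated) or 4 (CL) acyl positions. A species
formula is backbone + combined free fatty acids C_C H_(2C−2(D+K)) O_(2n)
minus one water per linkage; a cyclopropane ring costs two hydrogens, exactly
like a double bond. Monoisotopic masses come from `pyteomics`; m/z is the
deprotonated molecule [M−H]⁻ (negative-mode electrospray; singly charged
throughout — doubly charged CL/PGP forms are out of scope).

Cyclopropane rings are strictly isobaric with double bonds, so the database
carries both annotations as distinct entries sharing one m/z, and reporting
collapses them by the odd/even-carbon convention: *E. coli* synthesizes rings
by Cfa methylenation of a double bond (adding one carbon), so odd-total-carbon
species are annotated `cK` and even-carbon species as plain double bonds.
Default per-class carbon ranges (PE/PG 28–40, CL 62–70, aPE/aPG 46–52, PA/PS/
PGP/CDP-DAG 30–34, DLCL 30–33, PBut 31–34; double bonds + rings ≤ 2) give
231 reported species, all inside the 350–1750 Th acquisition window. Because
each carbon value contributes exactly three reported names under this cap,
the census can only move in steps of three; ranges were fixed once to cover
every species named in reported *E. coli* HILIC lipidomes.

The isotope model is carbon-only binomial: the A+k peak has relative
intensity C(n,k)(p/(1−p))^k with p = 0.011 (configurable). Minor isotopes of
H, N, O and P contribute <0.1% at A+2 for these formulas and are neglected.

## Annotation

Retention time identifies the class (HILIC separates by headgroup); exact
mass identifies the species within the class. Class rt windows are package
conventions for a ~5-min gradient, used consistently by the annotator and the
simulator — they are not instrument claims. The m/z tolerance defaults to
0.3 Th (unit-resolution ion trap). Features in overlapping windows resolve to
the nearest window center; several features matching one species are summed;
unmatched features are retained, with features sitting one or two ¹³C
spacings above a database species flagged as isotope peaks.

De-isotoping corrects the only systematic overlap a unit-resolution trap
cannot separate: the A+2 ¹³C₂ peak of a species (at +2.0067 Th) merges with
the monoisotopic peak of the species with one double-bond equivalent fewer
(+2.0156 Th). Species are processed in ascending m/z within each class in a
single pass, so cascaded corrections use already-corrected upstream
intensities; results are clipped at zero and clips logged. A+1 peaks fall at
odd nominal-mass offsets and never coincide with another species.

The noise filter keeps a species whose corrected intensity exceeds a
threshold (default 3× the noise floor, estimated as the median intensity of
unmatched non-isotope features) in at least one sample. Force integration
then re-reads every retained species at its expected (m/z, rt) in samples
where it was not detected — from the raw re-integration table when supplied —
recording 0 when nothing is there, and flags those cells `force_integrated`.
The fallback is 0 rather than an imputed noise draw so downstream statistics
see true sparsity; the provenance flags let users re-impute. Finally each
sample is normalized to percent of total lipid signal (columns sum to 100);
samples with no signal at all (cell-free incubations) are dropped and
reported.

## Acyl properties, Z-scores, correlation structure

Acyl properties summarize a composition as per-chain averages: mean chain
length, unsaturation index, cyclopropane fraction. Averages are
chain-weighted (weight = abundance × chains per molecule: CL counts 4, aPE/aPG
3, diacyl classes 2), which is the physically meaningful membrane average;
mole weighting is available via a flag. The butanol Z-score per species is
(mean_butanol − mean_control)/sd_control, positive meaning more abundant
under butanol; species absent from all control samples have zero control SD
and are reported missing rather than infinite.

Lipid–lipid correlation uses Pearson on percent values by default (CLR
transformation available for compositional-bias-aware analysis), hierarchical
agglomeration with average linkage on distance 1 − r, species sorted by name
first so results are independent of input order; constant species are
excluded and logged. The dendrogram exports as newick via scikit-bio, cluster
membership at any cut via `cluster_labels(k)`.

## Marker selection

A random forest classifies the joint (construct × butanol) label. Sequential
backward elimination removes the least important feature(s) per iteration
(default 1; a fractional `step` removes that fraction of remaining features,
trading resolution for speed), tracking out-of-bag error. The returned panel
is the smallest feature set whose OOB error — after a 3-point rolling-median
smoothing of the trace — is within one standard error of the minimum.
Selection is bit-for-bit reproducible under a fixed seed. The informative
core of the panel is stable across forest seeds; the panel tail beyond the
informative features consists of near-null species admitted by the 1-SE
tolerance and fluctuates, which is intrinsic to OOB-based size selection.
A run is flagged non-informative when the full-feature OOB error is not
clearly below chance (the trace minimum is not used for this judgement — it
is biased downward by selection).

The marker summary reports, per marker, the overall average percent and the
maximum/minimum per-construct mean percent with the constructs attaining
them, plus the summed panel contribution in wild-type samples. Gene tag
counts take the k highest and k lowest constructs per marker (k = 5; a
10-marker panel yields 100 tags) and count gene occurrences — the table
behind a tag cloud.

## Regularized differential testing

Per species, a one-way ANOVA across lipidome groups with Bayesian variance
regularization (Cyber-T style): each group's variance is shrunk toward a
background variance estimated as the sliding-window mean (window 101
species, tie-breaks by name) of variances over that group's mean-abundance
rank, s²_reg = (conf·s²_bg + (n−1)s²)/(conf + n − 2) with conf = 5. The F
denominator pools groups with effective-observation weights (conf + n − 1),
which keeps the pooled within mean square unbiased under the null and makes
conf = 0 coincide exactly with the classical one-way ANOVA. p-values are
BH-adjusted across species; adjusted p < 0.05 flags significance. With
strongly heteroscedastic species (variance growing with abundance) a
101-species window spans a wide abundance range and the test becomes mildly
conservative; on log-scale or variance-homogeneous data it is well
calibrated (null p-values uniform).

## Growth phenotyping

μ_max is the largest least-squares slope of ln(OD600) over a sliding window
(default 13 points = 1 h at 5-min sampling) among windows entirely above the
OD floor (default 0.02, after optional blank subtraction). On logistic
growth this estimate is depressed by curvature by ~3–4% at μ = 1.2 h⁻¹ with
the defaults used here — within the 5% recovery tolerance the tests enforce.
Steady-state OD600 is the median over the longest trailing run of windows
with specific slope below 0.02 h⁻¹; curves that never plateau fall back to
the final window median and are flagged. QC excludes cultures never reaching
OD 0.2 (inclusive boundary). Construct-vs-control classification uses Welch
two-sample tests (robust to unequal variances between triplicate constructs
and larger pooled control groups): KO vs wild type, OV vs empty vector,
separately per butanol condition, two-sided, uncorrected p vs α = 0.05.

## Synthetic study generator

The generator defines the study conditions every recovery test runs under:
68 lipid-related genes (20 essential → OV only, 48 non-essential → OV and
KO; 116 constructs), triplicate cultures, ± butanol, WT and EV controls on
every 96-well plate — 728 lipidomes, matching the ~730-culture scale.

The compositional model: one study-level baseline over the 231 species from
a Dirichlet prior (precision 5000) whose mean follows class weights (PE ≫ PG
> CL > minor classes) × a Gaussian carbon profile × a log-normal spread
(SD 1.0), spanning roughly 20% down to 0.01% — the observed dynamic range of
these lipidomes. Construct effects are multiplicative log-normal factors on
gene-specific target species; ten designated marker species act as hubs
targeted by two genes' effects each (log-SD 0.8) on top of four random
targets per gene (log-SD 0.4), so the hubs carry most between-construct
variance — the ground truth the marker-recovery test checks. Mechanistic
overlays: cfa-KO collapses ring species onto their precursors (retaining
5%), cfa-OV converts 80% of precursors to ring products; fabH expression
shifts chain length and unsaturation (KO longer/more unsaturated, OV
shorter/more saturated); clsA/aas/pldA scale CL and headgroup-acylated
classes; glpD/glpK/glpR act on growth only. Butanol moves 40% of each ring
species back to its precursor (net cyclopropane reduction) and introduces
PBut: 0.05% background in any butanol culture, 3% in the ClsB overexpressor.
Biological replicate noise is log-normal, SD 0.05 — these lipidomes are
highly reproducible between replicate cultures.

The measurement layer emits one monoisotopic feature row per species (m/z
jitter SD 0.01 Th, rt jitter SD 0.03 min) plus A+1/A+2 isotope rows scaled
by the carbon binomial model, per-cell log-normal intensity noise (CV 0.05)
on a per-sample total signal (10⁶ counts, CV 0.1), Poisson decoy features
(rate 0.1 per species row, log-normal around 20 counts), and a detection
limit of 50 counts below which cells are censored (the uncensored table
stands in for raw-data re-integration). Growth curves are logistic on a
5-min grid over 16 h (od0 = 0.02 ≈ a 1:100 dilution; carrying capacity 1.0;
base μ = 1.0 h⁻¹) with 1% multiplicative reading noise; butanol multiplies μ
by 0.5 (the 50% inhibition the screen is built around) and K by 0.85. 42
constructs carry planted μ effects (±15–50%, glpK-OV highest, glpD
manipulations lowest); the growth-failure rate defaults to 0 and is raised
explicitly in QC tests.

What the generator does **not** emulate: chromatographic peak shapes,
ionization suppression and response differences between classes (the reason
percent-of-signal values are not absolute molar fractions), retention drift
across batches, carry-over, plate-position effects, and any real covariance
between growth phenotype and lipidome beyond the planted effects. Passing
recovery tests therefore demonstrates the correctness of the computational
chain under its stated statistical assumptions, not instrument-level
robustness.

## Problem sizes and numerics

The test suite and acceptance script run the full 728-sample study for
annotation, metrics and growth, and scale the forests down to 100 trees with
10%-batch elimination for marker selection (the spec-level default of 500
trees with single-feature elimination is available through the same
interface). The classical-limit check uses 2 × 200 000 samples; the null
calibration 200 homoscedastic species. Ties in importance ranking, species
ordering and window assignment all break by species name, making every
result deterministic under a fixed seed. Degenerate inputs (all-zero
samples, constant species, zero control SD, sub-floor growth curves) are
excluded-and-logged or flagged rather than propagated as NaN/inf.
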