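# Methods

## The model

A tumor section is represented as a marked planar point pattern: cell
centroids `(x, y)` in µm (image convention, y down), a class mark
(cancer / stromal / lymphocyte), and per-cell nuclear area `a` (µm²) and
perimeter `p` (µm). The analysis asks where, within the section, the
*morphological variability* of cancer nuclei is locally elevated.

**Shape factor.** Each nucleus is summarized by the dimensionless
`s = p / (2√(π a))` — inverse circularity. The isoperimetric inequality
makes `s = 1` for a circle and `s > 1` for any other outline, so `s` is
scale-free and grows with irregularity.

**Zones.** The section is partitioned into Voronoi zones seeded by
cancer cells drawn uniformly at random. Seeding by cancer cells
guarantees each zone contains cancer and concentrates zones where cancer
is dense; drawing the *number* of seeds from the tissue area,
`N = max(1, ⌊√(area/area_unit_scale)/3⌋)`, makes zone size track tissue
size rather than cellularity, so fibrotic sections are not
under-resolved. The tissue polygon is the convex hull of the cells by
default (an alpha-shape option exists for ragged sections); Voronoi cells
are clipped to it so every zone is a bounded polygon and polygon
adjacency is well defined. Cells are assigned to the nearest seed by
Euclidean distance; exact ties go to the seed with the smaller cell id,
which is deterministic and independent of seed order. Duplicate seed
coordinates are rejected rather than jittered — reproducibility over
convenience.

**Zonal statistic.** `Y_i` is the sample standard deviation (n−1
denominator, unbiased variance at the small counts typical of zones) of
`s` over the zone's cancer cells. Zones with fewer than
`min_cancer_cells_per_zone = 2` cancer cells carry no SD and are excluded
from the spatial test; they are removed from the weights graph entirely
(no bridging through excluded zones).

**Spatial test.** Two zones are neighbors when their polygons share an
edge or a single point (queen contiguity), giving symmetric binary
weights `w_ij`. The local Moran statistic of zone *i* is the
unnormalized form

    I_i = (Y_i − Ȳ) Σ_j w_ij (Y_j − Ȳ)

with `Ȳ` the global mean of Y over tested zones. (A `neighborhood`
mean mode — `Ȳ_i` the mean over zone i's neighbors — is exposed for
sensitivity analyses; the global mean is the default because the flag is
meant to compare a zone against the slide as a whole as well as its
surroundings. Analytic moments are available for the global mode only;
the neighborhood mode falls back to the permutation route.)

Significance is assessed against the **conditional randomization** null:
hold `Y_i` fixed, permute the remaining values over the remaining zones.
For binary weights the neighbor sum is then a sample of `w_i = Σ_j w_ij`
values drawn without replacement from the `n−1` held-out deviations
`z_k = Y_k − Ȳ`, which gives exact closed forms

    E[I_i]   = −w_i z_i² / (n − 1)
    Var[I_i] = z_i² · w_i · s² · (n − 1 − w_i) / (n − 2)

where `s²` is the population variance of the held-out deviations. The
standardized statistic `z_i = (I_i − E[I_i]) / √Var[I_i]` is referred to
the standard normal, two-sided by default (the high-variability
requirement below, not the tail, enforces directionality; an `upper`
tail is available). The moments are verified in the test suite against
explicit 50,000-permutation enumeration — the module's central
correctness property.

A Monte-Carlo alternative (`method="permutation"`) estimates the same
null by explicit conditional permutation with the Hope add-one
correction, `p = (1 + #{|I*| ≥ |I_obs|}) / (1 + B)`, bounded below by
`1/(1+B)`. With several hundred zones under FDR the discreteness of the
Monte-Carlo p is limiting unless `B` is large, which is why the analytic
route is the default; on smooth (gaussian) zonal fields the two agree
within Monte-Carlo error once the zone count is large, as expected, and
a test pins that agreement.

**Calling zones and slides.** p-values are Benjamini–Hochberg adjusted
across the slide's tested zones. The default flag rule requires `q < α`
(α = 0.05) *and* `Y_i` above the slide mean, so flagged zones are always
high-variability zones — spatial clusters and spatial outliers of high Y
both qualify, low-variability coldspots never do. A slide is *present*
for diversification iff at least one zone is flagged;
`fraction_diversified` is reported over tested zones.

## Microenvironmental context

Zonal composition is the exact class count and fraction per zone. Zones
are ordered **diversified (1) < adjacent (2) < rest (3)**, where adjacent
means unflagged with at least one flagged queen-neighbor (flagged zones
keep group 1). Ordered trends — e.g. lymphocyte abundance rising away
from diversified zones, the spatial signature of local immune depletion —
are tested with the Jonckheere–Terpstra statistic: Mann–Whitney counts
summed over ordered group pairs, ties counted one half, with the
tie-corrected normal approximation or a label-permutation null
(Hope-corrected). `alternative="increasing"` rejects for values rising
along the group order; depletion *toward* diversified zones corresponds
to `increasing` under the 1 < 2 < 3 ordering above.

Zone-level marker correlation (e.g. galectin-3 positivity against
lymphocyte abundance) is Spearman's rank correlation computed only on
zones with tumor fraction in [0.30, 0.70] (bounds inclusive), so the
estimate comes from zones where cancer and microenvironment co-occur.
Marker values enter as the mean per-cell positivity over the zone.

## Cohort statistics

Slide-level calls are crossed with categorical labels in 2×2 tables
(`a` = positive & present, `b` = other & present, `c` = positive &
absent, `d` = other & absent); slides with a missing label are dropped
entirely — the "Unknown" convention. Fisher's exact test reports the
sample odds ratio `ad/bc` and the minimum-likelihood two-sided p (sum of
all fixed-margin tables at most as probable as the observed one), the
convention of the common statistical environments; a brute-force
hypergeometric enumeration oracle checks it in the tests.
Kruskal–Wallis compares continuous per-slide quantities.
Microenvironmental subtypes use the 75%/25% rule — Lymphocyte-high means
lymphocyte abundance at or above the high threshold with stromal
abundance at or below the low one, Stromal-high the mirror image — with
thresholds taken as cohort percentiles by default (the rule was tuned to
cohort composition) or as absolute percentages.

## The synthetic generator

The generator emulates what segmentation and classification of a
whole-slide H&E image produce, at desk scale:

- **Counts and proportions.** Default 20,000 cancer / 3,800 lymphocyte /
  4,300 stromal cells on a 5×5 mm slide — the cohort-average class
  proportions (~71/13.5/15.3%) at about 1/9 of the average per-slide cell
  count, and the same overall cell density.
- **Spatial clustering.** Positions come from a Thomas cluster process
  (Poisson parents, default intensity 2·10⁻⁶ /µm²; gaussian offspring,
  sd 200 µm) conditioned on the exact class counts; `uniform` is
  available. Each stage draws from its own spawned RNG stream, so
  changing one knob (e.g. depletion) leaves all other draws untouched —
  this makes paired simulation designs exact.
- **Morphometry.** Nuclear area is lognormal (median 30 µm², log-sd
  0.35). The shape factor is synthesized as `s = 1 + exp(N(µ, σ))` with
  µ = −1.5, σ = 0.5 (median s ≈ 1.22, SD ≈ 0.14 — typical of H&E
  nuclear segmentations), and the perimeter is back-computed as
  `p = s · 2√(π a)`, so every generated cell has `s > 1` by construction
  and the ground-truth shape factor is exact.
- **Planted zones.** Circles (default three, r = 250 µm) inside which σ
  is multiplied by `variance_multiplier` (default 3): the *spread* of the
  shape factor is inflated, not its mean, because the detection statistic
  is a standard deviation. `lymphocyte_depletion ∈ [0,1]` displaces that
  fraction of in-circle lymphocytes to positions outside all circles —
  displacement rather than deletion keeps class counts exactly equal to
  the config while emulating local immune exclusion.

`area_unit_scale` defaults to 10 µm² per area unit, under which the
desk-scale slide tessellates into ~527 zones of ~38 cancer cells — the
cohort-average zones-per-tumor, with cells-per-zone scaled down in
proportion to the slide's cell count. The unit of the area term in the
seed-count rule is not recoverable from the full-scale analysis (no unit
choice reconciles raw µm² or pixel areas with the reported average zone
count), so the parameter is explicit and the default is calibrated to
reproduce the reported zonal granularity.

**What the generator does not emulate:** segmentation and classification
error, staining artefacts, vessels and clear areas (zones are not masked
for them), anisotropic or non-circular diversification zones, spatial
correlation between nuclear size and position, and marker (IHC) images —
marker values must already be attached to cells. Passing recovery tests
therefore demonstrates the statistical machinery on idealized but
realistically sized and clustered inputs, not robustness to upstream
image-analysis failure modes.

## Standing experiments and their sizes

- **Null calibration** (50 slides, nothing planted): mean flagged-zone
  fraction, expected ≤ α under FDR control. Measured ≈ 0.001 — strongly
  conservative, because under the exchangeable null with ~40-cell zones
  the analytic p is approximately uniform (tested by KS across seeds)
  and BH then controls the slide-wise FDR.
- **Planted-zone recovery** (120 slides, variance ×3): a tessellated
  zone is *true* when ≥ 50% of its cancer cells lie in a planted circle;
  the confusion matrix is pooled across slides because a single slide
  carries only ~10 true zones. Conditional local-Moran inference is
  neighbor-driven — the focal deviation cancels from the standardized
  statistic — so cluster-edge zones with weak neighborhoods are the
  characteristic misses; pooled sensitivity ≈ 0.75 at specificity ≈ 0.99.
- **Depletion trend power** (25 slides × depletion ∈ {0, 0.5, 1}),
  paired by common random numbers: identical slides and flags per level,
  only lymphocyte placement differs. Rejection rates of the pooled
  Jonckheere test rise with the planted depletion; power at zero
  depletion exceeds the nominal level because clustered lymphocyte nests
  violate the exchangeability the trend null assumes — a real feature of
  spatially autocorrelated compositions, worth remembering when applying
  the test to single slides.

These sizes keep the full suite and the acceptance script in the
seconds-to-a-minute range on one CPU while leaving the stochastic
quantities stable to a few percent.

## Numerical and degenerate-input choices

- Polygon contact uses exact GEOS predicates; polygons from one Voronoi
  diagram share vertices exactly, so queen adjacency needs no tolerance.
  Nearest-seed ties use a 10⁻⁹ relative distance band before the
  smaller-id rule.
- `Var[I_i] = 0` (isolated zone, `z_i = 0`, or all held-out values
  equal) makes `z_i` undefined: the zone is excluded with reason
  `degenerate_null` rather than silently given p = 1. Zones with no
  neighbors get `I_i = 0`.
- Fewer than 4 tested zones: the spatial test is skipped and all zones
  are excluded (`too_few_zones`) — the randomization moments need n ≥ 4.
- Recovery ratios with empty denominators are reported as missing
  (`None`), never as 0.
- A zero row or column margin makes Fisher's test degenerate: p = 1 and
  the odds ratio is flagged undefined (NaN); `ad > 0` with `bc = 0`
  reports +inf.
- All-identical values give Kruskal–Wallis H = 0, p = 1, and a
  Jonckheere J of half the between-group pair count with p ≈ 1.

## Known limitations

- The analytic normal reference for `z_i` is approximate when the zonal
  field is heavy-tailed (planted slides make Y so); the far tail is
  mildly anticonservative and the mid-range conservative relative to the
  exact permutation null. The permutation route is exact but its
  resolution under many-zone FDR is bounded by `1/(1+B)`.
- FDR is controlled per slide across zones; no cross-slide multiplicity
  is attempted.
- The flag set is not invariant under monotone transforms of Y when the
  analytic route is used (the permutation route is rank-preserving only
  in its extremeness comparison, not in I itself); this is a documented
  non-property.
- Square-grid tessellation, vessel/clear-area masking, survival
  modeling, and pixel-level IHC scoring are out of scope.
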