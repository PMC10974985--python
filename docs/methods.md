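# Methods

This note documents the models implemented in `schooldust`, the design of
the synthetic survey generator, the numerical choices, and what the test
suite does and does not demonstrate.

## Contamination indices

All indices compare a measured concentration (mg/kg dry dust) against a
per-element geochemical background. The geo-accumulation index uses
Müller's formulation `Igeo = log2(C / (1.5 B))`; the 1.5 factor absorbs
natural background variability. Class boundaries are the standard
unit-wide bins: class 0 for Igeo ≤ 0, class k for k−1 < Igeo ≤ k
(k = 1…5), class 6 above 5. A narrative description sometimes attached to
class 6 ("at least 100-fold enrichment") conflicts with the boundary
arithmetic (Igeo > 5 corresponds to C/B > 48) and is treated as narrative,
not as a cut point.

The contamination factor CF = C/B uses lower-inclusive bins [1, 3),
[3, 6] and (6, ∞); a CF of exactly 6 is graded "considerable" — the
published class prose is silent at the boundary, so the choice is
centralised in `classify_cf` and documented here. The modified degree of
contamination is the arithmetic mean of a site's CFs; the pollution load
index is their geometric mean, computed in log space so long products
cannot overflow or underflow. Both composites use every element present in
the matrix by default; the element set can be restricted via
`site_indices(..., elements=...)` since published studies do not always
state which elements entered the composites. The enrichment factor uses Fe
as the crustal reference element; EF of the reference is identically 1 by
construction, and a zero reference concentration at a site is an error
naming the site rather than a silent NaN.

Zero concentrations are accepted in the data model (no detection-limit
model is implemented); they leave Igeo undefined (NaN, graded class 0) and
make the PLI an error for that site, since a geometric mean with a zero
factor is not meaningful.

## Health-risk model

Non-carcinogenic exposure doses follow the EPA dust model for two
receptors (child, adult) and three pathways (ingestion, inhalation with
the particle-emission factor, dermal contact). The packaged defaults
reproduce the published receptor tables exactly; the non-carcinogenic
averaging time is validated as ED × 365 and recomputed when a config file
overrides the exposure duration. The carcinogenic averaging time and the
volatilization factor are parsed and stored because the parameter table
lists them, but no operation consumes them — the model is deliberately
non-carcinogenic only.

One published formulation prints the ingestion rate inside the inhalation
dose; the engine uses the inhalation rate proper (the two rates are defined
separately in the parameter table, so the printed symbol is read as a
typographical slip). The literal variant remains available through
`use_printed_inhalation_formula` for sensitivity analysis. The dermal slot
sometimes labelled "SL" is identified with the skin-adherence factor AF,
its standard EPA role.

Hazard quotients divide each pathway dose by its reference dose; pathways
without a published dose contribute nothing (Zr: ingestion only), and
elements with no dose at all (Sc, Rb) are excluded from the hazard table
with a logged warning rather than an error, because hazard indices are
routinely reported for partially-covered panels.

## Multivariate tool-chain

Standardisation uses sample (ddof = 1) standard deviations. PCA is
computed by SVD of the column-centred matrix with a deterministic sign
convention (largest-magnitude loading positive). Hierarchical clustering
is Ward/Euclidean via `scipy.cluster.hierarchy`; the test suite checks the
linkage against an exhaustive greedy Ward recomputation on small
instances. k-means uses 10 restarts with a seeded generator. When a
cluster count is not supplied it is chosen by silhouette argmax; the elbow
(WCSS) curve is emitted for inspection but not auto-interpreted, since
elbow reading is a judgement call.

## PMF receptor model

The receptor model minimises the uncertainty-weighted objective
`Q = Σ ((x − (GF)) / u)²` over nonnegative G (site × factor contributions)
and F (factor × element profiles), using Lee–Seung-style multiplicative
updates with weights `1/u²`. Q is monotone non-increasing under these
updates; each fit runs to a relative Q change below 1e-8 or 5000
iterations, from 20 random nonnegative initialisations (one per restart
seed), keeping the lowest-Q run. Uncertainties follow the standard EPA
convention `u = sqrt((f·c)² + (0.5·mdl)²)` with detection limits defaulting
to zero and error fractions set by the instrument accuracy classes: 10 %
for Cr, Cu, Zn, Zr, Sr, Rb and Fe, 20 % for As and Pb; V and Sc carry no
published class and default to the conservative 20 %, overridable in
config.

Factor count is selected over candidates {3, 4, 5} by comparing the best Q
per candidate against `Q_expected = n·m − k(n+m)` (data cells minus fitted
parameters) and choosing the ratio closest to 1, ties to the smaller k;
run-to-run Q dispersion is reported alongside. Rotational ambiguity
exploration (FPEAK-style) and bootstrap error estimation are not
implemented; single solutions should be interpreted with that caveat.

Profile recovery in tests and diagnostics is measured by Hungarian-matched
cosine similarity in fraction-of-element space (each element column scaled
by the planted profiles' column sum) — the scale on which receptor-model
profiles are conventionally read. Raw mg/kg cosines would be dominated by
the most abundant elements (Fe, Zn) and insensitive to errors everywhere
else.

## Synthetic survey generator

The generator exists because school-dust surveys of this kind are not
publicly released; it produces matrices with the statistical properties the
pipeline assumes, plus the planted ground truth needed for recovery tests.

Structure. Five sources, each owning a disjoint set of elements: traffic
wear {Cu, Zn}, road dust {Zr, Rb, V}, construction {Sr, Sc}, combustion
{As, Pb}, brake/rail abrasion {Cr, Fe}. The two traffic-related sources
and the two combustion/abrasion sources are correlated pairs, which makes
the eleven elements fall into exactly three correlation clusters
(traffic/road, construction, combustion/abrasion) — the grouping the
multivariate stage is expected to find. Site log-contributions are built
on an exactly orthonormalised random basis so that the within-pair sample
correlation equals `pair_correlation` (default 0.55) exactly and every
other factor pair is exactly uncorrelated; the cluster geometry therefore
does not drift from seed to seed. An earlier design that included a
constant-contribution crustal-baseline factor was abandoned: a constant
factor creates an exact rotational degeneracy (a constant slice of its
profile can be moved into any other factor without changing G·F), which
caps profile recovery no matter how the solver is run.

Calibration. Each factor's contributions are lognormal in shape with
their log-range pinned to the common min/max ratio of that factor's
elements. Because every element belongs to exactly one factor, the
noiseless matrix maps onto the configured concentration ranges by a pure
per-element scaling: the noiseless data equal G·F exactly and have exact
rank k_true. Published sample ranges anchor As (4.55–69.96 mg/kg) and Cu
(51.28–395.37 mg/kg); the other elements use plausible non-study spans
(min/max ratio 20, except the traffic pair which shares Cu's ratio and the
combustion pair which shares As's) chosen to be consistent with the
contamination classes such surveys report. Elements sharing a factor must
share a min/max ratio; the generator validates this for overridden ranges.

Noise. Multiplicative lognormal noise with coefficient of variation
`noise_cv` (default 0.10) is applied to the calibrated values —
concentrations are positive and right-skewed, so the error model is
multiplicative. A final affine re-pinning restores the exact range anchors
after noise; its per-element offset is a small fraction of the signal and
is part of the effective measurement error that recovery tests tolerate.

PM series. Daily PM2.5/PM10 ratios are drawn from truncated normals
centred at 0.62 (combustion regime), 0.30 (crustal) or 0.46 (mixed), with
PM10 lognormal around 22 µg/m³ — the regimes bracket the published
European urban range of roughly 0.39–0.74.

What the generator does and does not emulate. It reproduces the printed
concentration ranges, a plausible low-rank source structure, the
three-way element grouping, strong within-group correlations (the As–Pb
correlation on generated data is ≈ 0.96–0.99), and the qualitative
health-risk pattern (child hazard indices above 1 for Zr everywhere and
for As and Pb at the most-polluted sites, adult indices far lower). It
does not model spatial structure, seasonality, detection limits, or
inter-element correlations beyond the planted group structure; passing
recovery tests on it shows the pipeline is correct and that the planted
structure is identifiable at realistic noise, not that any particular real
survey would be recovered equally well. Two known departures from the
study narrative: the default Zr span (25–500 mg/kg) makes the adult Zr
hazard index exceed 1 at high-Zr sites, whereas the study reports all
adult values below 1 — Zr levels of roughly 8–72 mg/kg would reproduce
that finding exactly (child HI above 1 at every site, adult below 1), but
compressing the road-dust ranges that far weakens the identifiability of
the planted sources, so the wider default is kept. And the observed PMF
profile-recovery minimum cosine across seeds is typically 0.93–0.98: with
24 samples, 11 elements and 5 factors the weighted factorization fits 175
parameters to 264 noisy cells, and the Q-optimal solution absorbs some
noise into the factors. At the default seed the minimum matched cosine is
0.96.

## Numerical choices

- Geometric means in log space; classification boundaries centralised and
  total over their domains.
- PMF multiplicative updates guard denominators at 1e-12; factors in a
  fitted model are ordered by decreasing mean contribution; restart s of a
  fit seeded with `seed` uses the independent stream `(seed, s)`.
- Ward linkage heights and the brute-force oracle use the scipy height
  convention `sqrt(2 |A||B| / (|A|+|B|)) · ||mean_A − mean_B||`.
- CSV round-trips write 12 significant digits.

## Problem sizes

The default study conditions — 24 sites, 11 elements, 5 factors, 10 %
noise, 20 PMF restarts, factor candidates {3, 4, 5} — are the conditions
every analysis script, test and the acceptance script use; a full
acceptance run completes in a few seconds.
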