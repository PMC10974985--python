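# schooldust

Heavy-metal contamination analysis for settled (school) dust: pollution
indices, EPA-style non-carcinogenic health-risk assessment, multivariate
source identification, and an uncertainty-weighted positive matrix
factorization (PMF) receptor model — with a synthetic-data generator that
emulates a 24-school × 11-element XRF dust survey (elements As, Cu, Zn, Zr,
Sr, Rb, Pb, Cr, V, Fe, Sc), so the full pipeline can be exercised and
validated end-to-end even though such surveys are rarely released publicly.

It is aimed at environmental-health researchers who want a tested, scripted
version of the standard dust-geochemistry workflow rather than a chain of
spreadsheet steps.

## The models

**Contamination indices** grade measured concentrations `C` against a
geochemical background `B`:

- geo-accumulation index `Igeo = log2(C / 1.5 B)` (Müller's classes 0–6),
- contamination factor `CF = C / B` (low < 1, moderate, considerable, very high > 6),
- modified degree of contamination `mCd = mean(CF)` per site,
- pollution load index `PLI = (ΠCF)^(1/n)` per site, geometric mean again
  across sites for a zone,
- enrichment factor `EF = (C/C_Fe)_sample / (C/C_Fe)_background` with Fe as
  the crustal reference.

**Health risk** follows the EPA exposure-dose model for a child and an
adult receptor over three pathways (mg per kg body weight per day):

```
ADD_ing  = C · IngR · EFfreq · ED / (BW · AT) · 1e-6
ADD_inh  = C · InhR · EFfreq · ED / (PEF · BW · AT)
ADD_derm = C · AF · SA · ABS · EFfreq · ED / (BW · AT) · 1e-6
HQ = ADD / RfD          HI = Σ_pathways HQ
```

HI ≥ 1 flags a potential non-carcinogenic risk.  Default receptor constants
and reference doses reproduce the published tables (including Zr having an
ingestion dose only, and no doses at all for Sc and Rb).

**Source identification**: z-scoring, Pearson correlation, PCA (SVD),
Ward/Euclidean hierarchical clustering of sites and of elements, and
k-means with elbow/silhouette model selection.

**PMF receptor model**: decompose the site × element matrix X into
nonnegative source contributions G and profiles F by minimising

```
Q = Σ_ij ((x_ij − (G F)_ij) / u_ij)²
```

where `u_ij` is the per-cell measurement uncertainty (10 % or 20 % of the
concentration by element accuracy class).  The solver uses weighted
multiplicative updates with 20 random restarts; factor count is chosen over
{3, 4, 5} by the Q/Q_expected criterion with `Q_expected = n·m − k(n+m)`.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic survey and write their tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_pollution_indices.py
python analysis/03_health_risk.py
python analysis/04_multivariate.py
python analysis/05_source_apportionment.py
```

`01_simulate.py` generates the survey; the As and Cu columns span exactly
4.55–69.96 and 51.28–395.37 mg/kg (published school-dust ranges used as
calibration anchors).  `02` grades contamination:

```
mean contamination factor by element (top 4):
Zn    12.82
Cu     4.20
Pb     3.45
Sc     2.44
most polluted sites by PLI:
  S22: PLI=4.12 (deteriorated)
  S13: PLI=2.54 (deteriorated)
  S16: PLI=2.15 (deteriorated)
zone PLI: 1.20
```

Zn comes out as the dominant contaminant and a handful of schools carry
most of the pollution load — the zone as a whole sits just above the
baseline (PLI 1.2).  `03` computes hazard indices; with these dust levels
the child receptor is flagged (HI ≥ 1) for Zr at every school and for As
and Pb at the most-polluted ones, while adult HIs stay an order of
magnitude lower — ingestion dominating the dose in every case.  `04`
clusters the standardised elements:

```
element clusters (HCA, k=3):
  cluster 3: As, Pb, Cr, Fe
  cluster 1: Cu, Zn, Zr, Rb, V
  cluster 2: Sr, Sc
HCA matches planted groups: True | k-means matches HCA: True
```

Both clustering methods agree and recover the three planted source groups
(traffic/road, construction, combustion/abrasion).  `05` fits the receptor
model:

```
 k  q_best  q_expected  q_ratio
 3 986.462         159    6.204
 4 321.490         124    2.593
 5  68.073          89    0.765
selected k = 5
recovered vs planted profiles (cosine, fraction-of-element space):
  traffic_wear   <- F4  cosine 0.982
  road_dust      <- F1  cosine 0.977
  construction   <- F5  cosine 0.996
  combustion     <- F3  cosine 0.962
  brake_rail     <- F2  cosine 0.988
```

PMF picks the planted factor count and recovers every planted source
profile at cosine ≥ 0.96.

A `schooldust` command-line tool exposes the same stages
(`simulate | indices | risk | multivariate | pmf | report`) for running the
pipeline on your own concentration CSVs; see `schooldust --help`.

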