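"""Contamination indices for dust geochemistry, with their class schemes.

Implements the classical single-element and composite indices used to grade
metal pollution against a geochemical background:

* geo-accumulation index  Igeo = log2(C / (1.5 B))   (Mueller's 7 classes)
* contamination factor    CF   = C / B
* modified degree of contamination  mCd = mean of a site's CFs
* pollution load index    PLI  = geometric mean of a site's CFs
                          (zone PLI = geometric mean of site PLIs)
* enrichment factor       EF   = (C/C_Fe)_sample / (C/C_Fe)_background

plus the PM2.5/PM10 fine-to-coarse ratio summary used to separate
combustion-dominated from crustal particulate sources.

All index functions return tidy DataFrames with a closed classification
vocabulary; boundary conventions are centralised in the ``classify_*``
helpers so they are stated (and tested) exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    BackgroundTable,
    ConcentrationMatrix,
    PMSeries,
    ValidationError,
    geometric_mean,
)

__all__ = [
    "geo_accumulation_index",
    "contamination_factor",
    "modified_degree_of_contamination",
    "pollution_load_index_site",
    "pollution_load_index_zone",
    "enrichment_factor",
    "pm_ratio_summary",
    "classify_igeo",
    "classify_cf",
    "classify_mcd",
    "classify_pli",
    "classify_ef",
]

IGEO_LABELS = {
    0: "unpolluted",
    1: "unpolluted to moderately polluted",
    2: "moderately polluted",
    3: "moderately to heavily polluted",
    4: "heavily polluted",
    5: "heavily to extremely polluted",
    6: "extremely polluted",
}

CF_LABELS = ("low", "moderate", "considerable", "very high")
MCD_LABELS = (
    "uncontaminated to very low",
    "low",
    "moderate",
    "high",
    "very high",
    "extremely high",
    "ultra-high",
)
PLI_LABELS = ("no pollution", "baseline", "deteriorated")
EF_LABELS = (
    "no enrichment",
    "natural weathering",
    "non-crustal contribution",
    "extremely severe enrichment",
)


def classify_igeo(igeo: float) -> str:
    """Mueller class: Igeo <= 0 -> class 0; (k-1, k] -> class k; > 5 -> class 6."""
    if math.isnan(igeo) or igeo <= 0:
        k = 0
    elif igeo > 5:
        k = 6
    else:
        k = int(math.ceil(igeo))
    return f"class {k}: {IGEO_LABELS[k]}"


def classify_cf(cf: float) -> str:
    # CF exactly 6 falls in "considerable": bins [1,3), [3,6], (6, inf).
    if cf < 1:
        return "low"
    if cf < 3:
        return "moderate"
    if cf <= 6:
        return "considerable"
    return "very high"


def classify_mcd(mcd: float) -> str:
    bounds = (1.5, 2.0, 4.0, 8.0, 16.0, 32.0)
    for label, hi in zip(MCD_LABELS, bounds):
        if mcd <= hi:
            return label
    return MCD_LABELS[-1]


def classify_pli(pli: float) -> str:
    if pli < 1:
        return "no pollution"
    if pli == 1:
        return "baseline"
    return "deteriorated"


def classify_ef(ef: float) -> str:
    if ef < 1:
        return "no enrichment"
    if ef <= 3:
        return "natural weathering"
    if ef <= 50:
        return "non-crustal contribution"
    return "extremely severe enrichment"


def _check_backgrounds(conc: ConcentrationMatrix, background: BackgroundTable) -> None:
    missing = [el for el in conc.element_symbols if el not in background]
    if missing:
        raise ValidationError(f"elements missing from background table: {missing}")


def geo_accumulation_index(
    conc: ConcentrationMatrix, background: BackgroundTable
) -> pd.DataFrame:
    """Per site/element Igeo = log2(Cn / (1.5 Bn)), with Mueller classes.

    The 1.5 factor absorbs natural background variability so that only
    anthropogenic excess scores above class 0.  A zero concentration leaves
    Igeo undefined (NaN) and is graded class 0.
    """
    _check_backgrounds(conc, background)
    rows = []
    for site in conc.site_ids:
        for el in conc.element_symbols:
            c = conc.data.at[site, el]
            if c == 0:
                val = float("nan")
            else:
                val = math.log2(c / (1.5 * background[el]))
            rows.append((site, el, "igeo", val, classify_igeo(val)))
    return pd.DataFrame(rows, columns=["site", "element", "index", "value", "class"])


def contamination_factor(
    conc: ConcentrationMatrix, background: BackgroundTable
) -> pd.DataFrame:
    """Per site/element CF = C_sample / C_background with the 4-class scheme."""
    _check_backgrounds(conc, background)
    rows = []
    for site in conc.site_ids:
        for el in conc.element_symbols:
            cf = conc.data.at[site, el] / background[el]
            rows.append((site, el, "cf", cf, classify_cf(cf)))
    return pd.DataFrame(rows, columns=["site", "element", "index", "value", "class"])


def modified_degree_of_contamination(cf_values) -> tuple[float, str]:
    """mCd = arithmetic mean of one site's contamination factors."""
    arr = np.asarray(list(cf_values), dtype=float)
    if arr.size == 0:
        raise ValidationError("mCd requires at least one contamination factor")
    mcd = float(arr.mean())
    return mcd, classify_mcd(mcd)


def pollution_load_index_site(cf_values) -> tuple[float, str]:
    """Site PLI = geometric mean of the site's CFs (computed in log space)."""
    arr = np.asarray(list(cf_values), dtype=float)
    if arr.size == 0:
        raise ValidationError("PLI requires at least one contamination factor")
    if (arr <= 0).any():
        raise ValidationError(
            "PLI undefined for non-positive contamination factors (geometric mean)"
        )
    pli = geometric_mean(arr)
    return pli, classify_pli(pli)


def pollution_load_index_zone(site_plis) -> tuple[float, str]:
    """Zone PLI = geometric mean of the site PLIs."""
    arr = np.asarray(list(site_plis), dtype=float)
    if arr.size == 0:
        raise ValidationError("zone PLI requires at least one site PLI")
    if (arr <= 0).any():
        raise ValidationError("zone PLI requires strictly positive site PLIs")
    pli = geometric_mean(arr)
    return pli, classify_pli(pli)


def site_indices(
    conc: ConcentrationMatrix,
    background: BackgroundTable,
    elements: list[str] | None = None,
) -> pd.DataFrame:
    """Site-level composite table: mCd and PLI per site plus the zone PLI.

    By default all elements present in the matrix enter the composites; pass
    ``elements`` to restrict the panel.
    """
    use = elements if elements is not None else conc.element_symbols
    unknown = [el for el in use if el not in conc.element_symbols]
    if unknown:
        raise ValidationError(f"elements not in concentration matrix: {unknown}")
    cf = contamination_factor(conc, background)
    cf = cf[cf["element"].isin(use)]
    rows = []
    plis = []
    for site in conc.site_ids:
        cfs = cf.loc[cf["site"] == site, "value"].to_numpy()
        mcd, mcd_class = modified_degree_of_contamination(cfs)
        pli, pli_class = pollution_load_index_site(cfs)
        plis.append(pli)
        rows.append((site, "mcd", mcd, mcd_class))
        rows.append((site, "pli", pli, pli_class))
    zone, zone_class = pollution_load_index_zone(plis)
    rows.append(("ZONE", "pli_zone", zone, zone_class))
    return pd.DataFrame(rows, columns=["site", "index", "value", "class"])


def enrichment_factor(
    conc: ConcentrationMatrix,
    background: BackgroundTable,
    reference_element: str = "Fe",
) -> pd.DataFrame:
    """EF = (Cx/Cref)_sample / (Cx/Cref)_background, Fe as crustal reference.

    The reference element scores EF = 1 at every site by construction.
    """
    _check_backgrounds(conc, background)
    if reference_element not in conc.element_symbols:
        raise ValidationError(
            f"reference element {reference_element!r} not in concentration matrix"
        )
    ref_bg = background[reference_element]
    rows = []
    for site in conc.site_ids:
        ref_c = conc.data.at[site, reference_element]
        if ref_c == 0:
            raise ValidationError(
                f"reference element {reference_element!r} has zero concentration "
                f"at site {site!r}; enrichment factor undefined"
            )
        for el in conc.element_symbols:
            ef = (conc.data.at[site, el] / ref_c) / (background[el] / ref_bg)
            rows.append((site, el, "ef", ef, classify_ef(ef)))
    return pd.DataFrame(rows, columns=["site", "element", "index", "value", "class"])


@dataclass
class PMRatioSummary:
    """Per-timestamp PM2.5/PM10 ratios with combustion-dominance flags."""

    table: pd.DataFrame  # timestamp, pm25, pm10, ratio, combustion_dominated
    mean: float
    min: float
    max: float
    n_undefined: int
    n_inversions: int  # pm25 > pm10 rows (flagged, kept)


def pm_ratio_summary(series: PMSeries, high_threshold: float = 0.5) -> PMRatioSummary:
    """PM2.5/PM10 ratio per timestamp plus mean/min/max.

    Ratios above ``high_threshold`` (strictly) are flagged as
    combustion-dominated.  Timestamps with PM10 = 0 leave the ratio
    undefined and are excluded from the summary statistics; rows with
    PM2.5 > PM10 are physically suspect and flagged but retained.
    """
    ratio = np.full(len(series), np.nan)
    ok = series.pm10 > 0
    ratio[ok] = series.pm25[ok] / series.pm10[ok]
    table = pd.DataFrame(
        {
            "timestamp": series.timestamps,
            "pm25": series.pm25,
            "pm10": series.pm10,
            "ratio": ratio,
            "combustion_dominated": ratio > high_threshold,
            "inversion": series.pm25 > series.pm10,
        }
    )
    defined = ratio[ok]
    if defined.size == 0:
        raise ValidationError("no timestamp has PM10 > 0; ratio summary undefined")
    return PMRatioSummary(
        table=table,
        mean=float(defined.mean()),
        min=float(defined.min()),
        max=float(defined.max()),
        n_undefined=int((~ok).sum()),
        n_inversions=int(table["inversion"].sum()),
    )
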