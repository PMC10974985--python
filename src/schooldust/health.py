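"""Non-carcinogenic health-risk model for metal exposure via dust.

EPA-style average daily doses (ADD, mg per kg body weight per day) over
three pathways, for a child and an adult receptor:

    ingestion:  ADD = C * IngR * EFfreq * ED / (BW * AT) * CFconv
    inhalation: ADD = C * InhR * EFfreq * ED / (PEF * BW * AT)
    dermal:     ADD = C * AF * SA * ABS * EFfreq * ED / (BW * AT) * CFconv

with C the dust concentration (mg/kg) and the receptor constants from
:class:`~schooldust.datamodel.ExposureParameters`.  Each pathway's hazard
quotient is HQ = ADD / RfD, and the hazard index HI sums the HQs over the
pathways with an available reference dose; HI >= 1 marks a potential
non-carcinogenic risk.

Elements without any reference dose (Sc, Rb in the default table) are
excluded from the hazard table with a logged warning; elements with partial
RfD coverage (Zr: ingestion only) contribute only their covered pathways.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    PATHWAYS,
    ConcentrationMatrix,
    ExposureParameters,
    RfDTable,
)

logger = logging.getLogger(__name__)

__all__ = ["average_daily_dose", "hazard_quotient", "hazard_index", "risk_report"]


def average_daily_dose(
    conc: float,
    params: ExposureParameters,
    pathway: str,
    use_printed_inhalation_formula: bool = False,
) -> float:
    """Pathway-specific average daily dose, mg/(kg·day), linear in ``conc``.

    ``use_printed_inhalation_formula`` substitutes the ingestion rate for
    the inhalation rate inside the inhalation dose — a sensitivity variant
    reproducing a formulation in which the two rates are conflated; the
    default uses the inhalation rate proper.
    """
    if conc < 0 or not np.isfinite(conc):
        raise ValueError(f"concentration must be finite and >= 0, got {conc}")
    p = params
    scale = p.exposure_frequency * p.exposure_duration / (
        p.body_weight * p.averaging_time_noncarcinogenic
    )
    if pathway == "ingestion":
        return conc * p.ingestion_rate * scale * p.conversion_factor
    if pathway == "inhalation":
        rate = p.ingestion_rate if use_printed_inhalation_formula else p.inhalation_rate
        return conc * rate * scale / p.particle_emission_factor
    if pathway == "dermal":
        return (
            conc
            * p.skin_adherence
            * p.skin_area
            * p.dermal_absorption
            * scale
            * p.conversion_factor
        )
    raise ValueError(f"unknown pathway {pathway!r}; valid: {PATHWAYS}")


def hazard_quotient(add: float, rfd: float) -> float:
    """HQ = ADD / RfD for one pathway."""
    if rfd <= 0:
        raise ValueError(f"reference dose must be > 0, got {rfd}")
    if add < 0:
        raise ValueError(f"average daily dose must be >= 0, got {add}")
    return add / rfd


def hazard_index(
    conc: ConcentrationMatrix,
    params: ExposureParameters,
    rfd: RfDTable,
    use_printed_inhalation_formula: bool = False,
) -> pd.DataFrame:
    """Per site/element dose, HQ and HI table for one receptor.

    Columns: site, element, receptor, add_<pathway>, hq_<pathway>, hi,
    flag (HI >= 1).  Pathways lacking an RfD contribute a dose but no HQ
    (NaN) and nothing to HI; elements with no RfD at all are skipped with a
    warning.
    """
    skipped = [el for el in conc.element_symbols if not rfd.pathways_for(el)]
    if skipped:
        logger.warning(
            "elements without any reference dose skipped in hazard index: %s", skipped
        )
    rows = []
    for site in conc.site_ids:
        for el in conc.element_symbols:
            if not rfd.pathways_for(el):
                continue
            c = conc.data.at[site, el]
            row: dict[str, object] = {"site": site, "element": el, "receptor": params.receptor}
            hi = 0.0
            for pw in PATHWAYS:
                add = average_daily_dose(
                    c, params, pw, use_printed_inhalation_formula=use_printed_inhalation_formula
                )
                row[f"add_{pw}"] = add
                r = rfd.get(el, pw)
                if r is None:
                    row[f"hq_{pw}"] = np.nan
                else:
                    hq = hazard_quotient(add, r)
                    row[f"hq_{pw}"] = hq
                    hi += hq
            row["hi"] = hi
            row["flag"] = hi >= 1.0
            rows.append(row)
    return pd.DataFrame(rows)


def risk_report(hazard: pd.DataFrame) -> pd.DataFrame:
    """Rank a hazard table by HI (descending) within each receptor.

    Returns the full table re-ordered with flagged (HI >= 1) site/element
    pairs first; the ``flag`` column delimits the at-risk section.
    """
    if hazard.empty:
        raise ValueError("empty hazard table")
    out = hazard.sort_values(
        ["receptor", "flag", "hi"], ascending=[True, False, False]
    ).reset_index(drop=True)
    return out
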