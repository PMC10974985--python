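"""Grade contamination: Igeo, CF, EF per site/element; mCd, PLI per site.

Reads the simulated survey, applies every pollution index against the
world-soil background defaults, and reports which sites and elements come
out most contaminated, plus the PM2.5/PM10 source indication.
"""

from pathlib import Path

import pandas as pd

from schooldust import default_background, read_concentration_csv, PMSeries
from schooldust.indices import (
    contamination_factor,
    enrichment_factor,
    geo_accumulation_index,
    pm_ratio_summary,
    site_indices,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    conc = read_concentration_csv(ROOT / "data" / "concentrations.csv")
    background = default_background()
    out = ROOT / "indices"
    out.mkdir(parents=True, exist_ok=True)

    igeo = geo_accumulation_index(conc, background)
    cf = contamination_factor(conc, background)
    ef = enrichment_factor(conc, background)
    pd.concat([igeo, cf, ef], ignore_index=True).to_csv(out / "element_indices.csv", index=False, float_format="%.6g")
    sites = site_indices(conc, background)
    sites.to_csv(out / "site_indices.csv", index=False)

    mean_cf = cf.groupby("element")["value"].mean().sort_values(ascending=False)
    print("mean contamination factor by element (top 4):")
    print(mean_cf.head(4).round(2).to_string())

    pli = sites[sites["index"] == "pli"].nlargest(3, "value")
    print("\nmost polluted sites by PLI:")
    for _, r in pli.iterrows():
        print(f"  {r['site']}: PLI={r['value']:.2f} ({r['class']})")
    zone = sites.loc[sites["index"] == "pli_zone", "value"].iloc[0]
    print(f"zone PLI: {zone:.2f}")

    severe = ef[ef["class"] == "extremely severe enrichment"]["element"].value_counts()
    if len(severe):
        print("\nelements with extremely severe enrichment (site count):")
        print(severe.to_string())

    pm = pm_ratio_summary(PMSeries.from_csv(ROOT / "data" / "pm_series.csv"))
    frac = pm.table["combustion_dominated"].mean()
    print(
        f"\nPM2.5/PM10: mean {pm.mean:.2f} (range {pm.min:.2f}-{pm.max:.2f}); "
        f"{100 * frac:.0f}% of days combustion-dominated (ratio > 0.5)"
    )


if __name__ == "__main__":
    main()
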