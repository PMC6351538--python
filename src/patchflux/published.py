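"""Site-level summary of the seven-site LAC rainy-season urine campaign.

These are the site x pasture-condition summary numbers of the reference
campaign this package was built around — applied urine-N, peak daily
flux, and cumulative N2O-N emission over the 18-24 day monitoring window
— entered at their printed precision.  They feed the inference layer's
documented side entry point (site-level values, bypassing the chamber
stage) and the worked examples: regional means, the emission-factor
bound at the lowest-N site, and the observed range of cumulative
emissions.

The St. Augustine urine-N value is missing: no laboratory could assay
urine N there, so its emission factor is undefined rather than zero.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # country, site, condition, n_applied_kg_ha, peak, peak_sem, cumulative, cum_sem, letter
    ("Nicaragua", "Esteli", "LVC", 464.0, 129.0, 19.0, 5.82, 0.73, "a"),
    ("Nicaragua", "Esteli", "AVC", 464.0, 60.0, 5.0, 1.85, 0.26, "b"),
    ("Colombia", "Patia", "LVC", 789.0, 92.0, 26.0, 3.85, 0.71, "a"),
    ("Colombia", "Patia", "AVC", 789.0, 27.0, 2.0, 1.41, 0.51, "b"),
    ("Colombia", "Taluma", "LVC", 112.0, 0.2, 0.2, 0.02, 0.01, "a"),
    ("Colombia", "Taluma", "AVC", 112.0, 0.2, 0.1, 0.02, 0.005, "a"),
    ("Brazil", "Rio Grande do Sul", "LVC", 619.0, 45.0, 18.0, 4.59, 1.23, "a"),
    ("Brazil", "Rio Grande do Sul", "AVC", 619.0, 59.0, 26.0, 3.01, 1.88, "a"),
    ("Argentina", "Balcarce", "LVC", 1641.0, 29.0, 10.0, 1.23, 0.57, "a"),
    ("Argentina", "Balcarce", "AVC", 1641.0, 22.0, 2.0, 0.90, 0.14, "a"),
    ("Argentina", "Manfredi", "LVC", 546.0, 4.2, 0.5, 0.21, 0.01, "a"),
    ("Argentina", "Manfredi", "AVC", 546.0, 3.0, 0.5, 0.18, 0.02, "a"),
    ("Trinidad & Tobago", "St. Augustine", "LVC", None, 107.0, 14.0, 7.49, 1.26, "a"),
    ("Trinidad & Tobago", "St. Augustine", "AVC", None, 80.0, 7.0, 6.00, 0.23, "a"),
]


def seven_site_summary() -> pd.DataFrame:
    """Tidy site x condition summary table of the reference campaign.

    Columns: country, site, condition, n_applied_kg_ha (NaN where the
    urine-N assay is missing), peak_flux_mg_m2_d, peak_sem,
    cumulative_kg_ha, cumulative_sem, letter (within-site significance
    letter for the cumulative emission at alpha = 0.05).
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "country", "site", "condition", "n_applied_kg_ha",
            "peak_flux_mg_m2_d", "peak_sem", "cumulative_kg_ha",
            "cumulative_sem", "letter",
        ],
    )
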