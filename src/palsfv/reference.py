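"""Published replicate summary for ex vivo human stratum corneum.

Per-sample o-Ps parameters (tau3, I3) and the derived free-volume metrics
for eleven independent ex vivo human skin samples (donors of both sexes,
aged 35-50; each row is the mean of 15 repeated acquisitions).  These rows
serve as default ground truths for the simulator, as regression anchors for
the Tao-Eldrup chain, and as the canonical worked example for the replicate
summary.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_SAMPLES", "reference_table"]

#: (sample_id, tau3 [ns], I3 [%], R [nm], Vf [nm^3], fv [a.u.]) as printed.
REFERENCE_SAMPLES: tuple[tuple[str, float, float, float, float, float], ...] = (
    ("I",    1.86,  8.96, 0.272, 0.084, 0.00135),
    ("II",   1.80,  9.66, 0.265, 0.078, 0.00136),
    ("III",  1.82,  9.65, 0.268, 0.080, 0.00139),
    ("IV",   1.84, 10.18, 0.269, 0.082, 0.00150),
    ("V",    1.77,  7.86, 0.263, 0.076, 0.00108),
    ("VI",   1.86,  8.52, 0.272, 0.084, 0.00129),
    ("VII",  1.80,  7.79, 0.265, 0.078, 0.00109),
    ("VIII", 1.87,  9.68, 0.273, 0.085, 0.00148),
    ("IX",   1.81,  9.62, 0.267, 0.080, 0.00139),
    ("X",    1.92,  9.89, 0.277, 0.089, 0.00158),
    ("XI",   1.80,  7.29, 0.266, 0.079, 0.00104),
)


def reference_table() -> pd.DataFrame:
    """The reference rows as a DataFrame with columns
    sample_id, tau3_ns, i3_percent, r_nm, vf_nm3, fv."""
    return pd.DataFrame(
        REFERENCE_SAMPLES,
        columns=["sample_id", "tau3_ns", "i3_percent", "r_nm", "vf_nm3", "fv"],
    )
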