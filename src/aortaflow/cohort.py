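"""Synthetic subject cohorts for exercising the statistical battery.

Real patient-level data are not available, so cohorts are drawn from
normal distributions whose group means, spreads and sample sizes mirror a
typical adolescent connective-tissue-disorder follow-up study: 19 patients
scanned twice (baseline t1, follow-up t2) against 10 healthy volunteers.
The key programmed contrast is the proximal inner descending-aorta
systolic WSS (patients 0.60 ± 0.18 N/m² at t1, 0.55 ± 0.16 at t2,
volunteers 0.78 ± 0.15) and a negative association between that WSS and
the descending-aorta diameter Z-score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import compute_bsa

__all__ = ["synthetic_cohort", "COHORT_CONDITIONS"]

#: Programmed group conditions (mean, sd) by variable and group.
COHORT_CONDITIONS = {
    "wss_prox_inner_dao": {"t1": (0.60, 0.18), "t2": (0.55, 0.16),
                           "volunteer": (0.78, 0.15)},
    "vel_aao": {"t1": (1.50, 0.19), "t2": (1.38, 0.19),
                "volunteer": (1.45, 0.16)},
    "zscore_dao": {"t1": (3.15, 1.66), "t2": (3.71, 1.90),
                   "volunteer": (0.0, 1.0)},
    "height_cm": {"t1": (172.0, 21.9), "t2": (181.1, 17.2),
                  "volunteer": (175.0, 9.0)},
    "weight_kg": {"t1": (54.0, 17.2), "t2": (64.4, 16.5),
                  "volunteer": (70.0, 10.0)},
}

#: Correlation between WSS in the proximal inner DAo and the DAo Z-score.
WSS_ZSCORE_RHO = -0.60


def synthetic_cohort(seed: int = 0, n_patients: int = 19,
                     n_volunteers: int = 10) -> pd.DataFrame:
    """Draw one synthetic cohort table.

    Returns a long-format frame with one row per subject and timepoint
    (patients appear at ``t1`` and ``t2``, volunteers once) and columns for
    the programmed hemodynamic and morphometric variables plus BSA.
    WSS and Z-score are drawn jointly with correlation −0.60 within each
    patient timepoint.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def bivariate(mu_w, sd_w, mu_z, sd_z, rho, n):
        cov = [[sd_w ** 2, rho * sd_w * sd_z],
               [rho * sd_w * sd_z, sd_z ** 2]]
        return rng.multivariate_normal([mu_w, mu_z], cov, size=n)

    for tp, n in (("t1", n_patients), ("t2", n_patients),
                  ("volunteer", n_volunteers)):
        c = {k: v[tp] for k, v in COHORT_CONDITIONS.items()}
        wz = bivariate(*c["wss_prox_inner_dao"], *c["zscore_dao"],
                       WSS_ZSCORE_RHO, n)
        ids = [f"P{i:02d}" if tp != "volunteer" else f"V{i:02d}"
               for i in range(n)]
        for i in range(n):
            h = rng.normal(*c["height_cm"])
            w = max(rng.normal(*c["weight_kg"]), 20.0)
            rows.append({
                "id": ids[i], "timepoint": tp,
                "height_cm": h, "weight_kg": w,
                "bsa_m2": compute_bsa(max(h, 100.0), w),
                "wss_prox_inner_dao": max(wz[i, 0], 0.05),
                "zscore_dao": wz[i, 1],
                "vel_aao": max(rng.normal(*c["vel_aao"]), 0.2),
            })
    return pd.DataFrame(rows)
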