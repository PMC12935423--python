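"""Published reference tables of the slowness study, as in-memory fixtures.

The study's raw recordings were never deposited; its printed cohort tables
are the only real-data surface available. They are transcribed here verbatim
so that every number derivable from them (group extrema, ON/OFF change
classification, pooled rank correlations) can be recomputed.

* Table 1 — participant characteristics: ages for both groups, MDS-UPDRS
  Part III totals and Hoehn & Yahr stage for the Parkinson group in the ON
  and OFF medication states.
* Table 2 — slowness evaluation: per-participant average response time (RT,
  s) and angular velocity (AV, deg/s) for the control group (CG) and the
  Parkinson group (EG) in ON and OFF states, plus a per-state bradykinesia
  score. Note: that score column is printed under the heading "MDS-UPDRS"
  but spans 2–12; it is exposed here as ``brad_score`` on the reading that
  it is the bradykinesia item sum (items 3.4a–3.6b).
* Table 3 — Spearman correlations of RT and AV against each bradykinesia
  item and their sum (BRADINDEX).
"""

from __future__ import annotations

import pandas as pd

from .io import summaries_to_frame
from .types import ParticipantSummary

# (id, cg_age, eg_age, updrs_on, hy_on, updrs_off, hy_off)
_TABLE1 = [
    (1, 82, 57, 25, 3, 61, 2),
    (2, 64, 80, 25, 2, 49, 2),
    (3, 80, 64, 26, 2, 58, 2),
    (4, 66, 77, 31, 2, 44, 2),
    (5, 51, 59, 24, 3, 47, 2),
    (6, 56, 64, 39, 2, 48, 2),
    (7, 77, 70, 20, 2, 41, 2),
    (8, 62, 73, 42, 3, 45, 3),
    (9, 60, 60, 12, 2, 29, 1),
    (10, 80, 66, 16, 1, 29, 1),
    (11, 69, 69, 37, 3, 70, 2),
    (12, 59, 60, 31, 2, 54, 2),
    (13, 62, 50, 35, 3, 59, 3),
    (14, 55, 68, 38, 2, 52, 2),
    (15, 71, 77, 11, 1, 38, 1),
]

# (id, cg_rt, cg_av, brad_on, rt_on, av_on, brad_off, rt_off, av_off)
_TABLE2 = [
    (1, 1.13, 308.38, 3, 1.66, 305.35, 5, 3.30, 139.49),
    (2, 1.30, 347.34, 6, 3.73, 139.20, 9, 2.53, 177.71),
    (3, 3.27, 287.36, 8, 2.08, 248.31, 8, 1.63, 182.14),
    (4, 2.00, 400.60, 6, 1.84, 351.83, 9, 1.43, 394.17),
    (5, 1.59, 460.94, 2, 1.98, 398.71, 3, 2.60, 306.59),
    (6, 1.57, 520.40, 6, 1.94, 245.04, 9, 2.42, 182.70),
    (7, 2.50, 391.27, 4, 1.14, 234.44, 8, 2.20, 238.86),
    (8, 1.95, 401.34, 3, 2.15, 234.16, 6, 1.99, 301.79),
    (9, 1.49, 621.23, 3, 1.42, 473.47, 5, 1.93, 352.31),
    (10, 1.33, 506.88, 2, 1.22, 272.14, 4, 1.45, 316.26),
    (11, 1.70, 466.61, 6, 1.26, 492.09, 9, 1.84, 327.66),
    (12, 1.49, 555.35, 6, 2.94, 167.36, 12, 3.70, 135.72),
    (13, 1.60, 565.49, 6, 1.90, 152.37, 9, 1.41, 170.01),
    (14, 1.49, 518.94, 5, 1.90, 260.84, 9, 2.04, 252.35),
    (15, 1.48, 383.09, 3, 1.98, 374.44, 7, 3.51, 278.41),
]

# (item, rho_rt, rho_av)
_TABLE3 = [
    ("3.4a", 0.058, -0.656),
    ("3.4b", 0.217, -0.617),
    ("3.5a", 0.114, -0.687),
    ("3.5b", 0.216, -0.625),
    ("3.6a", 0.118, -0.725),
    ("3.6b", 0.215, -0.665),
    ("BRADINDEX", 0.147, -0.698),
]


def fixture_table1() -> pd.DataFrame:
    """Participant characteristics: one row per participant and state.

    30 participant rows in long format: 15 CG rows (age only, state NA) and
    15 EG participants with two state rows each (ON and OFF) carrying the
    clinical scores.
    """
    rows = []
    for pid, cg_age, eg_age, u_on, hy_on, u_off, hy_off in _TABLE1:
        rows.append(ParticipantSummary(
            participant_id=f"CG{pid:02d}", cohort="CG", state="NA",
            age_years=cg_age))
        rows.append(ParticipantSummary(
            participant_id=f"EG{pid:02d}", cohort="EG", state="ON",
            age_years=eg_age, updrs3_total=u_on, hy_stage=hy_on))
        rows.append(ParticipantSummary(
            participant_id=f"EG{pid:02d}", cohort="EG", state="OFF",
            age_years=eg_age, updrs3_total=u_off, hy_stage=hy_off))
    return summaries_to_frame(rows)


def fixture_table2() -> pd.DataFrame:
    """Slowness results: 15 CG rows, 15 EG-ON rows, 15 EG-OFF rows."""
    rows = []
    for pid, cg_rt, cg_av, b_on, rt_on, av_on, b_off, rt_off, av_off in _TABLE2:
        rows.append(ParticipantSummary(
            participant_id=f"CG{pid:02d}", cohort="CG", state="NA",
            rt_s=cg_rt, av_dps=cg_av))
        rows.append(ParticipantSummary(
            participant_id=f"EG{pid:02d}", cohort="EG", state="ON",
            rt_s=rt_on, av_dps=av_on, brad_score=b_on))
        rows.append(ParticipantSummary(
            participant_id=f"EG{pid:02d}", cohort="EG", state="OFF",
            rt_s=rt_off, av_dps=av_off, brad_score=b_off))
    return summaries_to_frame(rows)


def fixture_table3() -> pd.DataFrame:
    """Published Spearman correlations (item, rho_rt, rho_av)."""
    return pd.DataFrame(_TABLE3, columns=["item", "rho_rt", "rho_av"])
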