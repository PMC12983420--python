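"""Published reference cohort statistics used to calibrate the simulator.

Group-level displacement-vector statistics (magnitude in mm, direction in
degrees) for a 21-subject transperineal-ultrasound cohort: 10 continent
controls and 11 women with stress urinary incontinence (SUI), three urethral
segments, three maneuvers.  CV is the coefficient of variation as printed in
the source report, ``round(100 * SD / |mean|)`` up to the report's own
upstream rounding.

These numbers serve two purposes: (i) default effect sizes for the synthetic
cohort generator, so simulated group contrasts have realistic magnitude, and
(ii) reference values for the CV / SEM arithmetic checks.
"""

from __future__ import annotations

import pandas as pd

N_CONTROL = 10
N_SUI = 11

MANEUVERS = ("cough", "valsalva", "pmc")
SEGMENTS = ("proximal", "mid", "distal")
GROUPS = ("control", "sui")

# (maneuver, roi, group) -> (mean, sd, range, cv_printed)
MAGNITUDE_MM = {
    ("cough", "proximal", "control"): (4.88, 1.64, 5.56, 34),
    ("cough", "proximal", "sui"): (6.59, 1.61, 4.89, 24),
    ("cough", "mid", "control"): (4.13, 1.52, 4.37, 37),
    ("cough", "mid", "sui"): (3.88, 1.22, 4.12, 31),
    ("cough", "distal", "control"): (3.98, 1.42, 3.95, 36),
    ("cough", "distal", "sui"): (3.65, 1.32, 4.33, 36),
    ("valsalva", "proximal", "control"): (5.98, 2.01, 5.64, 34),
    ("valsalva", "proximal", "sui"): (10.64, 3.69, 10.91, 35),
    ("valsalva", "mid", "control"): (4.97, 2.06, 5.62, 41),
    ("valsalva", "mid", "sui"): (6.50, 1.99, 6.52, 31),
    ("valsalva", "distal", "control"): (4.94, 2.06, 5.95, 42),
    ("valsalva", "distal", "sui"): (3.77, 1.38, 4.63, 37),
    ("pmc", "proximal", "control"): (4.46, 4.01, 11.95, 90),
    ("pmc", "proximal", "sui"): (3.43, 2.58, 9.39, 75),
    ("pmc", "mid", "control"): (2.81, 2.82, 9.19, 101),
    ("pmc", "mid", "sui"): (1.93, 1.22, 3.38, 64),
    ("pmc", "distal", "control"): (2.29, 1.32, 3.62, 58),
    ("pmc", "distal", "sui"): (1.72, 1.35, 3.77, 79),
}

DIRECTION_DEG = {
    ("cough", "proximal", "control"): (-79.55, 18.39, 43.38, 23),
    ("cough", "proximal", "sui"): (-83.65, 10.34, 28.88, 12),
    ("cough", "mid", "control"): (-90.14, 8.55, 23.81, 9),
    ("cough", "mid", "sui"): (-95.26, 25.55, 87.78, 27),
    ("cough", "distal", "control"): (-117.56, 17.49, 49.94, 15),
    ("cough", "distal", "sui"): (-128.03, 22.75, 72.73, 18),
    ("valsalva", "proximal", "control"): (-67.08, 18.56, 60.64, 28),
    ("valsalva", "proximal", "sui"): (-75.16, 24.52, 61.48, 33),
    ("valsalva", "mid", "control"): (-92.64, 16.79, 50.94, 18),
    ("valsalva", "mid", "sui"): (-79.73, 32.86, 87.93, 41),
    ("valsalva", "distal", "control"): (-121.68, 30.73, 97.41, 25),
    ("valsalva", "distal", "sui"): (-128.79, 26.19, 89.40, 20),
    ("pmc", "proximal", "control"): (134.06, 25.17, 64.58, 19),
    ("pmc", "proximal", "sui"): (131.66, 7.66, 22.04, 6),
    ("pmc", "mid", "control"): (145.42, 10.69, 29.77, 7),
    ("pmc", "mid", "sui"): (115.97, 16.90, 52.99, 15),
    ("pmc", "distal", "control"): (61.67, 43.04, 113.79, 70),
    ("pmc", "distal", "sui"): (85.45, 49.28, 161.15, 58),
}


def magnitude_table() -> pd.DataFrame:
    """Reference magnitude statistics as a tidy DataFrame."""
    rows = [
        {"maneuver": m, "roi": r, "group": g,
         "mean_mm": v[0], "sd_mm": v[1], "range_mm": v[2], "cv_printed": v[3]}
        for (m, r, g), v in MAGNITUDE_MM.items()
    ]
    return pd.DataFrame(rows)


def direction_table() -> pd.DataFrame:
    """Reference direction statistics as a tidy DataFrame."""
    rows = [
        {"maneuver": m, "roi": r, "group": g,
         "mean_deg": v[0], "sd_deg": v[1], "range_deg": v[2], "cv_printed": v[3]}
        for (m, r, g), v in DIRECTION_DEG.items()
    ]
    return pd.DataFrame(rows)
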