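"""Self-validation experiments: calibrated power cohorts and null simulations.

These helpers define the package's standard validation problems so that the
test suite and the reproduction script run the exact same experiments:

* :func:`reference_valsalva_spec` — a synthetic cohort (10 controls, 11 SUI)
  whose proximal-urethra Valsalva displacement distributions are calibrated
  to the reference cohort statistics (control 5.98 +/- 2.01 mm vs. SUI
  10.64 +/- 3.69 mm), or a null variant where both groups share the control
  distribution.  A shortened Valsalva waveform (1.8 s ramp-hold-release) is
  used so a whole cohort tracks in about a minute; the waveform shape and
  30 Hz sampling are unchanged.
* :func:`proximal_group_contrast` — the pooled-variance control-vs-SUI
  t-test on proximal displacement magnitude with the standard per-ROI
  Bonferroni family of five.
* :func:`type1_error_rate` — the group-effect rejection rate of the mixed
  ANOVA over simulated null cohorts (random subject intercepts, no group
  effect), which should sit near the nominal alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort_stats as cs
from . import reference_cohort as ref
from .synthetic_cine import CohortSpec

#: Shortened Valsalva used for cohort-scale validation runs (same shape:
#: smoothstep ramp, plateau >= 25 % of duration, release).
SHORT_VALSALVA = {"valsalva": dict(duration_s=1.8, onset_s=0.1, rise_s=0.7,
                                   hold_s=0.5, rebound_s=0.5)}

#: Size of the per-ROI pairwise-contrast family (3 between-group + 2
#: within-group comparisons) used for Bonferroni adjustment.
CONTRAST_FAMILY_SIZE = 5


def reference_valsalva_spec(seed: int, null: bool = False) -> CohortSpec:
    """Cohort spec at the reference proximal-Valsalva effect size.

    With ``null=True`` both groups draw from the control distribution, so
    any detected group difference is a false positive.
    """
    params = {}
    for group in ("control", "sui"):
        source = "control" if null else group
        for roi in ref.SEGMENTS:
            mu, sd, _range, _cv = ref.MAGNITUDE_MM[("valsalva", roi, source)]
            phi = ref.DIRECTION_DEG[("valsalva", roi, source)][0]
            params[(group, "valsalva", roi)] = (mu, sd, phi)
    return CohortSpec(n_control=ref.N_CONTROL, n_sui=ref.N_SUI, seed=seed,
                      maneuvers=("valsalva",), amplitude_params=params,
                      template_overrides=SHORT_VALSALVA)


def proximal_group_contrast(table: pd.DataFrame) -> dict:
    """Control-vs-SUI pooled t-test on proximal |d| with Bonferroni family 5.

    Returns group means/SDs, raw and adjusted p, and the significance call
    at alpha = 0.05.
    """
    sub = table[(table["metric"] == "dmag_mm") & (table["roi"] == "proximal")]
    x = sub[sub["group"] == "control"]["value"].to_numpy(float)
    y = sub[sub["group"] == "sui"]["value"].to_numpy(float)
    t, p_raw = stats.ttest_ind(x, y, equal_var=True)
    p_adj = min(1.0, CONTRAST_FAMILY_SIZE * float(p_raw))
    return {
        "control_mean_mm": float(x.mean()),
        "control_sd_mm": float(x.std(ddof=1)),
        "sui_mean_mm": float(y.mean()),
        "sui_sd_mm": float(y.std(ddof=1)),
        "t": float(t),
        "p_raw": float(p_raw),
        "p_bonferroni": p_adj,
        "significant": bool(p_adj < 0.05),
    }


def type1_error_rate(n_reps: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> float:
    """Group-effect rejection rate of the mixed ANOVA on null cohorts.

    Each replicate simulates 10 + 11 subjects x 3 maneuvers with per-subject
    random intercepts and no group effect; the rate should be close to
    ``alpha`` (the test is exact under these assumptions).
    """
    rng = np.random.default_rng(seed)
    subjects = [f"s{i:02d}" for i in range(ref.N_CONTROL + ref.N_SUI)]
    groups = ["control"] * ref.N_CONTROL + ["sui"] * ref.N_SUI
    base = pd.DataFrame({
        "subject": np.repeat(subjects, 3),
        "group": np.repeat(groups, 3),
        "maneuver": np.tile(["cough", "valsalva", "pmc"], len(subjects)),
        "roi": "proximal",
        "metric": "dmag_mm",
        "value": 0.0,
    })
    maneuver_means = np.array([5.0, 7.0, 3.0])
    rejections = 0
    for _ in range(n_reps):
        intercept = rng.normal(0.0, 1.5, len(subjects))
        values = (maneuver_means[None, :] + intercept[:, None]
                  + rng.normal(0.0, 1.0, (len(subjects), 3)))
        base["value"] = values.ravel()
        out = cs.rm_anova_2x3(base, "proximal", "dmag_mm")
        p = float(out.loc[out["effect"] == "group", "p"].iloc[0])
        rejections += p < alpha
    return rejections / n_reps
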