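"""Printed reference values from the source validation study.

These constants are the study's published summary statistics: group
demographics (resting metabolic rate, resting heart rate, body mass),
the treadmill task battery, per-group-per-task means and SDs of criterion
PAEE, accelerometer counts (PAC), heart rate, RER and PCI, the published
population-specific prediction equations, and the agreement statistics the
study reports. They serve two roles:

* as the population parameters the synthetic cohort generator emulates, and
* as embedded inputs for the worked-example checks (arithmetic that can be
  reproduced from the printed tables alone).

All energy rates are kcal·min⁻¹, PAC in counts·min⁻¹, HR in bpm, RMR in
kcal·day⁻¹, velocities in m·s⁻¹.
"""

from __future__ import annotations

from types import MappingProxyType

GROUPS = ("unilateral", "bilateral", "control")

#: Walking task names in protocol order (5 flat speeds, then 3% and 5%
#: gradients at 0.89 m·s⁻¹). "rest" is the seated RMR measurement.
TASK_ORDER = (
    "rest",
    "tm_0.48",
    "tm_0.67",
    "tm_0.89",
    "tm_1.12",
    "tm_1.34",
    "tm_0.89_g3",
    "tm_0.89_g5",
)
WALKING_TASKS = TASK_ORDER[1:]

#: (velocity m·s⁻¹, gradient %) per task.
TASK_KINEMATICS = MappingProxyType(
    {
        "rest": (0.0, 0.0),
        "tm_0.48": (0.48, 0.0),
        "tm_0.67": (0.67, 0.0),
        "tm_0.89": (0.89, 0.0),
        "tm_1.12": (1.12, 0.0),
        "tm_1.34": (1.34, 0.0),
        "tm_0.89_g3": (0.89, 3.0),
        "tm_0.89_g5": (0.89, 5.0),
    }
)

#: Group demographics: sample size, RMR (kcal·day⁻¹), resting HR during the
#: RMR measurement (bpm), sleeping HR (bpm), body mass (kg); mean and SD.
GROUP_DEMOGRAPHICS = MappingProxyType(
    {
        "unilateral": {
            "n": 9,
            "rmr_mean": 1776.0,
            "rmr_sd": 269.0,
            "rest_hr_mean": 66.0,
            "rest_hr_sd": 11.0,
            "sleep_hr_mean": 63.0,
            "sleep_hr_sd": 9.0,
            "body_mass_mean": 81.0,
            "body_mass_sd": 11.0,
        },
        "bilateral": {
            "n": 10,
            "rmr_mean": 1596.0,
            "rmr_sd": 178.0,
            "rest_hr_mean": 67.0,
            "rest_hr_sd": 10.0,
            "sleep_hr_mean": 57.0,
            "sleep_hr_sd": 7.0,
            "body_mass_mean": 82.0,
            "body_mass_sd": 19.0,
        },
        "control": {
            "n": 9,
            "rmr_mean": 1846.0,
            "rmr_sd": 191.0,
            "rest_hr_mean": 54.0,
            "rest_hr_sd": 4.0,
            "sleep_hr_mean": 48.0,
            "sleep_hr_sd": 3.0,
            "body_mass_mean": 80.0,
            "body_mass_sd": 7.0,
        },
    }
)

# Per group-per task: criterion PAEE, PAC, HR (mean, sd), calculated METs,
# RER, PCI (mean, sd; None at rest) and number of completers.
# Keys: (group, task).
_T = {
    # group, task: paee, paee_sd, pac, pac_sd, hr, hr_sd, mets, rer, pci, pci_sd, n
    ("unilateral", "rest"): (0.00, 0.00, 0, 0, 66, 11, 1.0, 0.74, None, None, 9),
    ("unilateral", "tm_0.48"): (2.40, 0.71, 2643, 866, 96, 17, 3.1, 0.76, 1.01, 0.28, 9),
    ("unilateral", "tm_0.67"): (3.00, 0.95, 2939, 908, 101, 18, 3.6, 0.79, 0.85, 0.24, 9),
    ("unilateral", "tm_0.89"): (3.61, 1.12, 3353, 892, 106, 21, 4.1, 0.81, 0.74, 0.26, 9),
    ("unilateral", "tm_1.12"): (4.39, 1.42, 4107, 707, 112, 24, 4.7, 0.83, 0.67, 0.26, 9),
    ("unilateral", "tm_1.34"): (5.89, 1.70, 4977, 581, 126, 36, 5.7, 0.86, 0.73, 0.33, 6),
    ("unilateral", "tm_0.89_g3"): (4.17, 1.06, 3642, 981, 111, 21, 4.5, 0.82, 0.84, 0.26, 9),
    ("unilateral", "tm_0.89_g5"): (4.82, 1.24, 4020, 1005, 119, 23, 5.0, 0.84, 0.99, 0.29, 9),
    ("bilateral", "rest"): (0.00, 0.00, 0, 0, 67, 10, 1.0, 0.75, None, None, 10),
    ("bilateral", "tm_0.48"): (3.72, 1.37, 4800, 1410, 108, 13, 4.4, 0.78, 1.45, 0.32, 10),
    ("bilateral", "tm_0.67"): (4.59, 1.54, 5264, 1603, 121, 15, 5.1, 0.81, 1.35, 0.29, 10),
    ("bilateral", "tm_0.89"): (5.46, 1.74, 5600, 1502, 133, 18, 5.8, 0.84, 1.25, 0.32, 10),
    ("bilateral", "tm_1.12"): (5.54, 2.85, 6123, 2823, 139, 31, 5.3, 0.91, 1.22, 0.43, 3),
    ("bilateral", "tm_1.34"): (5.23, 2.76, 5235, 1212, 142, 41, 5.7, 0.86, 1.03, 0.36, 2),
    ("bilateral", "tm_0.89_g3"): (5.93, 2.29, 5973, 1592, 138, 19, 6.1, 0.87, 1.36, 0.40, 8),
    ("bilateral", "tm_0.89_g5"): (5.77, 1.85, 5806, 2231, 146, 30, 5.7, 0.93, 1.37, 0.56, 4),
    ("control", "rest"): (0.00, 0.00, 0, 0, 54, 4, 1.0, 0.75, None, None, 9),
    ("control", "tm_0.48"): (1.43, 0.31, 1299, 411, 72, 7, 2.2, 0.78, 0.61, 0.15, 9),
    ("control", "tm_0.67"): (1.81, 0.32, 1811, 368, 74, 6, 2.5, 0.82, 0.50, 0.09, 9),
    ("control", "tm_0.89"): (2.32, 0.40, 2430, 459, 78, 4, 2.9, 0.82, 0.45, 0.05, 9),
    ("control", "tm_1.12"): (2.80, 0.43, 3325, 480, 82, 5, 3.3, 0.82, 0.41, 0.04, 9),
    ("control", "tm_1.34"): (3.40, 0.34, 4144, 457, 85, 5, 3.7, 0.83, 0.38, 0.04, 9),
    ("control", "tm_0.89_g3"): (2.88, 0.38, 2551, 385, 83, 5, 3.3, 0.84, 0.54, 0.06, 9),
    ("control", "tm_0.89_g5"): (3.45, 0.43, 2720, 311, 87, 4, 3.8, 0.83, 0.61, 0.06, 9),
}

_FIELDS = (
    "paee_mean",
    "paee_sd",
    "pac_mean",
    "pac_sd",
    "hr_mean",
    "hr_sd",
    "mets_mean",
    "rer",
    "pci_mean",
    "pci_sd",
    "n_completed",
)

#: (group, task) -> dict of published group-task summary statistics.
GROUP_TASK_SUMMARY = MappingProxyType(
    {key: dict(zip(_FIELDS, vals)) for key, vals in _T.items()}
)

#: Published population-specific prediction equations
#: PAEE = beta_pac·PAC + beta_hr·HR + intercept.
PRINTED_COEFFICIENTS = MappingProxyType(
    {
        "unilateral": {"beta_pac": 0.000453, "beta_hr": 0.045487, "intercept": -2.713284},
        "bilateral": {"beta_pac": 0.000658, "beta_hr": 0.025308, "intercept": -1.795157},
        "control": {"beta_pac": 0.000550, "beta_hr": 0.036472, "intercept": -1.797866},
    }
)

#: Published agreement of the fitted PAC+HR model against criterion PAEE
#: (r, R², SEE and half-width of the 95% limits of agreement, by group),
#: plus the study's reported leave-one-participant-out mean absolute
#: percentage errors. Used to parameterise the synthetic cohort (residual
#: SD) and as upper bounds in worked-example checks.
PUBLISHED_AGREEMENT = MappingProxyType(
    {
        "unilateral": {"r": 0.92, "r_squared": 0.85, "see": 0.78, "loa_half_width": 1.50,
                       "loocv_mape_pct": 18.0},
        "bilateral": {"r": 0.93, "r_squared": 0.87, "see": 0.96, "loa_half_width": 1.84,
                      "loocv_mape_pct": 15.0},
        "control": {"r": 0.91, "r_squared": 0.83, "see": 0.48, "loa_half_width": 0.93,
                    "loocv_mape_pct": 15.0},
    }
)

#: A-priori power-analysis inputs the study states (paired comparison of
#: absolute errors between two prediction methods).
POWER_INPUTS = MappingProxyType({"d": 1.0, "alpha": 0.05, "power": 0.8, "n_required": 8})

#: Published between-group heart-rate ratio bands across the walking tasks
#: analysed (bilateral comparisons restricted to 0.48–0.89 m·s⁻¹ and the 3%
#: gradient because of dropout at the higher speeds).
HR_RATIO_BANDS = MappingProxyType(
    {
        ("unilateral", "control"): (1.3, 1.5),
        ("bilateral", "control"): (1.5, 1.7),
        ("bilateral", "unilateral"): (1.1, 1.3),
    }
)
RESTRICTED_SPEED_TASKS = ("tm_0.48", "tm_0.67", "tm_0.89", "tm_0.89_g3")


def completion_probability(group: str, task: str) -> float:
    """Empirical completion probability for a group-task cell (n completed / n)."""
    n_group = GROUP_DEMOGRAPHICS[group]["n"]
    return GROUP_TASK_SUMMARY[(group, task)]["n_completed"] / n_group
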