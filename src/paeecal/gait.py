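"""Gait economy metrics: physiological cost index and between-group HR ratios.

The physiological cost index (PCI) expresses the heart-rate cost of walking
per metre travelled,

    PCI (beats·m⁻¹) = (mean working HR − mean resting HR) / velocity (m·min⁻¹),

here evaluated at pre-set treadmill velocities rather than self-selected
walking speed. Between-group heart-rate ratios compare the chronotropic
response of two groups over a common task set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class GroupTaskMeans:
    """Group-level mean heart rates for one task."""

    group: str
    task: str
    mean_hr: float
    mean_rest_hr: float
    velocity: float


def pci(hr_work, hr_rest, velocity):
    """Physiological cost index in beats per metre.

    ``velocity`` is in m·s⁻¹ and is converted to m·min⁻¹ internally. Accepts
    scalars or arrays. Undefined at rest (velocity must be positive); a
    negative PCI (working HR below resting HR) is returned with a warning.
    """
    velocity = np.asarray(velocity, dtype=float)
    if np.any(velocity <= 0):
        raise ValueError("PCI undefined: velocity must be positive")
    out = (np.asarray(hr_work, float) - np.asarray(hr_rest, float)) / (velocity * 60.0)
    if np.any(out < 0):
        warnings.warn("negative PCI: working HR below resting HR", stacklevel=2)
    return float(out) if out.ndim == 0 else out


def between_group_hr_ratio(
    a: Iterable[GroupTaskMeans],
    b: Iterable[GroupTaskMeans],
    tasks: Sequence[str] | None = None,
) -> tuple[dict[str, float], tuple[float, float]]:
    """Per-task heart-rate ratios a/b and their (min, max).

    Both groups must provide every requested task; the ratio is scale
    invariant (multiplying all HRs by a constant leaves it unchanged).
    """
    hr_a = {m.task: m.mean_hr for m in a}
    hr_b = {m.task: m.mean_hr for m in b}
    if tasks is None:
        tasks = [t for t in hr_a if t in hr_b]
        if set(hr_a) != set(hr_b):
            raise KeyError(
                f"task sets differ: {sorted(set(hr_a) ^ set(hr_b))}"
            )
    missing = [t for t in tasks if t not in hr_a or t not in hr_b]
    if missing:
        raise KeyError(f"tasks missing from one group: {missing}")
    ratios = {t: hr_a[t] / hr_b[t] for t in tasks}
    values = list(ratios.values())
    return ratios, (min(values), max(values))
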