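"""Synthetic cohort and sensor-stream generator.

Emulates a three-group treadmill calibration study — unilateral amputee
(n=9), bilateral amputee (n=10) and non-injured control (n=9) — completing a
battery of rest plus seven 5-minute walking stages (five speeds 0.48–1.34
m·s⁻¹ and 3%/5% gradients at 0.89 m·s⁻¹). For every participant-task the
generator emits 30-s epoch streams of accelerometer counts (PAC) and heart
rate, and a parallel gas-exchange stream (V̇O₂, V̇CO₂) whose Weir energy
expenditure reproduces the intended steady-state value exactly in noiseless
mode.

Generative model, per participant-task:

1. a participant economy factor (lognormal, mean 1) scales the activity
   response: less economical gait costs more movement and a larger HR rise;
2. steady-state PAC and HR are drawn around the group-task target means;
3. steady-state criterion PAEE is the group TrueModel evaluated at
   (PAC, HR) plus Gaussian residual noise — the same direction of causality
   the downstream regression assumes, so coefficient recovery is unbiased;
4. TEE = PAEE + RMR/1440 is inverted through the Weir equation at the
   group-task RER to yield the gas channels;
5. the first 3 minutes follow an exponential approach (τ = 45 s) to steady
   state; from 3 minutes on the signals are stationary, so the final-2-min
   window used downstream sits entirely on the plateau.

Dropout at the higher speeds (pronounced in the bilateral group) is drawn
per participant-task from the empirical completion probabilities, with an
optional monotone mode where failing one speed fails all faster stages.

Everything is a pure function of (configuration, seed): per-participant and
per-task substreams are derived deterministically from the master seed and
the participant/task identifiers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .calorimetry import MIN_PER_DAY, invert_weir

#: Exponential time constant of the on-transient, seconds.
STEADY_STATE_TAU_S = 45.0
#: Time after which signals are treated as stationary, seconds.
STEADY_STATE_ONSET_S = 180.0
EPOCH_S = 30.0

PARTICIPANT_COLUMNS = ("id", "group", "rmr_kcal_day", "rest_hr_bpm", "body_mass_kg")
EPOCH_COLUMNS = ("id", "task", "t_s", "pac_counts_min", "hr_bpm")
GAS_COLUMNS = ("id", "task", "t_s", "vo2_l_min", "vco2_l_min")


@dataclass(frozen=True)
class GroupSpec:
    """Population parameters of one study group."""

    label: str
    n: int
    rmr_mean: float
    rmr_sd: float
    rest_hr_mean: float
    rest_hr_sd: float
    body_mass_mean: float
    body_mass_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group '{self.label}': n must be >= 1, got {self.n}")
        for name in ("rmr_sd", "rest_hr_sd", "body_mass_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"group '{self.label}': {name} must be >= 0")
        if not self.rmr_mean > 0:
            raise ValueError(f"group '{self.label}': rmr_mean must be positive")
        if not 30 < self.rest_hr_mean < 120:
            raise ValueError(f"group '{self.label}': rest_hr_mean must be in (30, 120)")


@dataclass(frozen=True)
class TaskSpec:
    """One protocol stage: treadmill velocity, gradient and duration."""

    name: str
    velocity: float
    gradient: float = 0.0
    duration_min: float = 5.0
    completion_prob: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise ValueError(f"task '{self.name}': velocity must be >= 0")
        if not self.duration_min > 0:
            raise ValueError(f"task '{self.name}': duration must be positive")
        for g, p in self.completion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"task '{self.name}': completion_prob[{g!r}] must be in [0, 1]"
                )

    def prob(self, group: str) -> float:
        return self.completion_prob.get(group, 1.0)


@dataclass(frozen=True)
class TrueModel:
    """The linear PAC+HR → PAEE relationship a group's data are drawn from."""

    group: str
    beta_pac: float
    beta_hr: float
    intercept: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def paee(self, pac: float, hr: float) -> float:
        return self.intercept + self.beta_pac * pac + self.beta_hr * hr


@dataclass(frozen=True)
class TaskTarget:
    """Group-task steady-state targets the draws are centred on."""

    pac_mean: float
    hr_mean: float
    paee_mean: float
    rer: float
    rest_hr_mean: float


@dataclass(frozen=True)
class ParticipantProfile:
    """One simulated subject."""

    id: str
    group: str
    rmr: float
    rest_hr: float
    body_mass: float
    economy_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.rmr > 0:
            raise ValueError("rmr must be positive")
        if not self.economy_factor > 0:
            raise ValueError("economy_factor must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    """Scatter magnitudes around the group-task targets.

    ``economy_sd`` is the lognormal sigma of the between-subject economy
    factor; ``pac_cv``/``hr_sd`` scatter the per-task steady states between
    subjects; ``epoch_*`` add within-task epoch-to-epoch measurement noise.
    """

    economy_sd: float = 0.15
    pac_cv: float = 0.10
    hr_sd: float = 5.0
    epoch_pac_cv: float = 0.05
    epoch_hr_sd: float = 1.5
    epoch_gas_cv: float = 0.02

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """Fully deterministic configuration (noiseless mode)."""
        return cls(economy_sd=0.0, pac_cv=0.0, hr_sd=0.0,
                   epoch_pac_cv=0.0, epoch_hr_sd=0.0, epoch_gas_cv=0.0)


@dataclass(frozen=True)
class SyntheticDataset:
    """The generated study: cohort, completion table and streams."""

    cohort: tuple[ParticipantProfile, ...]
    completion: pd.DataFrame
    participants: pd.DataFrame
    epochs: pd.DataFrame
    gas: pd.DataFrame


# ---------------------------------------------------------------------------
# defaults: the published study conditions


def default_group_specs() -> list[GroupSpec]:
    out = []
    for g in reference.GROUPS:
        d = reference.GROUP_DEMOGRAPHICS[g]
        out.append(
            GroupSpec(
                label=g, n=d["n"], rmr_mean=d["rmr_mean"], rmr_sd=d["rmr_sd"],
                rest_hr_mean=d["rest_hr_mean"], rest_hr_sd=d["rest_hr_sd"],
                body_mass_mean=d["body_mass_mean"], body_mass_sd=d["body_mass_sd"],
            )
        )
    return out


def default_tasks() -> list[TaskSpec]:
    out = []
    for t in reference.TASK_ORDER:
        v, grad = reference.TASK_KINEMATICS[t]
        probs = {g: reference.completion_probability(g, t) for g in reference.GROUPS}
        out.append(TaskSpec(name=t, velocity=v, gradient=grad, completion_prob=probs))
    return out


def default_true_models() -> dict[str, TrueModel]:
    """Published equations as generative truths, residual SD from published SEE."""
    out = {}
    for g in reference.GROUPS:
        c = reference.PRINTED_COEFFICIENTS[g]
        out[g] = TrueModel(
            group=g, beta_pac=c["beta_pac"], beta_hr=c["beta_hr"],
            intercept=c["intercept"],
            residual_sd=reference.PUBLISHED_AGREEMENT[g]["see"],
        )
    return out


def default_targets() -> dict[tuple[str, str], TaskTarget]:
    out = {}
    for (g, t), row in reference.GROUP_TASK_SUMMARY.items():
        out[(g, t)] = TaskTarget(
            pac_mean=float(row["pac_mean"]), hr_mean=float(row["hr_mean"]),
            paee_mean=float(row["paee_mean"]), rer=float(row["rer"]),
            rest_hr_mean=float(reference.GROUP_DEMOGRAPHICS[g]["rest_hr_mean"]),
        )
    return out


# ---------------------------------------------------------------------------
# deterministic substreams


def _substream(seed: int, *labels: str, salt: int = 0) -> np.random.Generator:
    """Generator derived deterministically from (seed, labels, salt)."""
    keys = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([seed % 2**32, salt, *keys]))


# ---------------------------------------------------------------------------
# operations


def generate_cohort(
    specs: Sequence[GroupSpec],
    seed: int,
    economy_sd: float = 0.15,
) -> list[ParticipantProfile]:
    """Draw participant profiles for each group.

    RMR, resting HR and body mass are Gaussian around the group means
    (degenerate at the means when SDs are zero); the economy factor is
    lognormal with mean exactly 1 and sigma ``economy_sd``. Identical seeds
    give identical cohorts.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    profiles: list[ParticipantProfile] = []
    for spec in specs:
        rng = _substream(seed, spec.label, salt=1)
        for i in range(spec.n):
            rmr = max(spec.rmr_mean + spec.rmr_sd * rng.standard_normal(), 300.0)
            rest_hr = float(
                np.clip(spec.rest_hr_mean + spec.rest_hr_sd * rng.standard_normal(),
                        31.0, 119.0)
            )
            mass = max(spec.body_mass_mean + spec.body_mass_sd * rng.standard_normal(),
                       30.0)
            if economy_sd > 0:
                ef = float(np.exp(rng.normal(-economy_sd**2 / 2.0, economy_sd)))
            else:
                ef = 1.0
            profiles.append(
                ParticipantProfile(
                    id=f"{spec.label[:3]}{i + 1:02d}", group=spec.label,
                    rmr=float(rmr), rest_hr=rest_hr, body_mass=float(mass),
                    economy_factor=ef,
                )
            )
    return profiles


def draw_steady_state(
    p: ParticipantProfile,
    task: TaskSpec,
    tm: TrueModel,
    target: TaskTarget,
    rng: np.random.Generator,
    noise: NoiseConfig,
) -> dict[str, float]:
    """Steady-state (PAC, HR, criterion PAEE, TEE, RER) for one stage.

    At rest PAC is 0, HR is the participant's resting HR and PAEE is 0 by
    definition (TEE equals RMR). For walking stages the economy factor
    scales both the movement output and the HR rise above rest, and the
    criterion is the TrueModel evaluated at the drawn sensors plus residual
    noise.
    """
    rmr_min = p.rmr / MIN_PER_DAY
    if task.velocity == 0:
        return {"pac": 0.0, "hr": p.rest_hr, "paee": 0.0,
                "tee": rmr_min, "rer": target.rer}
    pac = target.pac_mean * p.economy_factor
    if noise.pac_cv > 0:
        pac += rng.normal(0.0, noise.pac_cv * target.pac_mean)
    pac = max(pac, 0.0)
    hr = p.rest_hr + (target.hr_mean - target.rest_hr_mean) * p.economy_factor
    if noise.hr_sd > 0:
        hr += rng.normal(0.0, noise.hr_sd)
    hr = max(hr, p.rest_hr * 0.5 + 20.0)
    paee = tm.paee(pac, hr)
    if tm.residual_sd > 0:
        paee += rng.normal(0.0, tm.residual_sd)
    tee = max(paee + rmr_min, 0.0)
    return {"pac": pac, "hr": hr, "paee": paee, "tee": tee, "rer": target.rer}


def _onset_fraction(t_s: np.ndarray) -> np.ndarray:
    f = 1.0 - np.exp(-t_s / STEADY_STATE_TAU_S)
    return np.where(t_s >= STEADY_STATE_ONSET_S, 1.0, f)


def simulate_activity(
    p: ParticipantProfile,
    task: TaskSpec,
    tm: TrueModel,
    target: TaskTarget,
    seed: int,
    noise: NoiseConfig | None = None,
    completed: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one participant-task stage.

    Returns ``(gas, epochs)`` DataFrames at 30-s epochs with timestamps at
    epoch starts (t = 0, 30, …). A non-completed stage yields empty frames
    with the correct columns (the empty-stream dropout marker). The
    substream is a pure function of (seed, participant id, task name).
    """
    if task.duration_min < 3:
        raise ValueError("task duration must be >= 3 min for a steady state")
    noise = noise or NoiseConfig()
    gas_cols, epoch_cols = list(GAS_COLUMNS[2:]), list(EPOCH_COLUMNS[2:])
    if not completed:
        empty = {"t_s": pd.Series(dtype=float)}
        gas = pd.DataFrame({**empty, **{c: pd.Series(dtype=float) for c in gas_cols[1:]}})
        ep = pd.DataFrame({**empty, **{c: pd.Series(dtype=float) for c in epoch_cols[1:]}})
        return gas, ep

    rng = _substream(seed, p.id, task.name, salt=2)
    ss = draw_steady_state(p, task, tm, target, rng, noise)
    t = np.arange(0.0, task.duration_min * 60.0, EPOCH_S)
    f = _onset_fraction(t)
    rmr_min = p.rmr / MIN_PER_DAY

    hr_t = p.rest_hr + (ss["hr"] - p.rest_hr) * f
    if noise.epoch_hr_sd > 0:
        hr_t = hr_t + rng.normal(0.0, noise.epoch_hr_sd, size=t.shape)
    pac_t = ss["pac"] * f
    if noise.epoch_pac_cv > 0 and ss["pac"] > 0:
        pac_t = np.maximum(
            pac_t + rng.normal(0.0, noise.epoch_pac_cv * ss["pac"], size=t.shape), 0.0
        )
    tee_t = rmr_min + (ss["tee"] - rmr_min) * f
    vo2, vco2 = np.empty_like(t), np.empty_like(t)
    for i, tee in enumerate(tee_t):
        vo2[i], vco2[i] = invert_weir(tee, ss["rer"])
    if noise.epoch_gas_cv > 0:
        # shared multiplicative noise keeps RER constant within the stage
        factor = np.maximum(rng.normal(1.0, noise.epoch_gas_cv, size=t.shape), 0.0)
        vo2, vco2 = vo2 * factor, vco2 * factor

    gas = pd.DataFrame({"t_s": t, "vo2_l_min": vo2, "vco2_l_min": vco2})
    epochs = pd.DataFrame({"t_s": t, "pac_counts_min": pac_t, "hr_bpm": hr_t})
    return gas, epochs


def apply_dropout(
    cohort: Sequence[ParticipantProfile],
    tasks: Sequence[TaskSpec],
    seed: int,
    monotone: bool = False,
) -> pd.DataFrame:
    """Participant × task completion table (True = completed).

    Independent Bernoulli draws from each task's per-group completion
    probability; with ``monotone=True`` a failure at one walking stage fails
    every later walking stage in protocol order.
    """
    table = {}
    for p in cohort:
        rng = _substream(seed, p.id, salt=3)
        row, failed = {}, False
        for task in tasks:
            if task.velocity == 0:
                row[task.name] = True
                continue
            ok = bool(rng.random() < task.prob(p.group))
            if monotone:
                failed = failed or not ok
                ok = not failed
            row[task.name] = ok
        table[p.id] = row
    out = pd.DataFrame.from_dict(table, orient="index")
    out.index.name = "id"
    return out


def generate_dataset(
    seed: int = 0,
    group_specs: Sequence[GroupSpec] | None = None,
    tasks: Sequence[TaskSpec] | None = None,
    true_models: Mapping[str, TrueModel] | None = None,
    targets: Mapping[tuple[str, str], TaskTarget] | None = None,
    noise: NoiseConfig | None = None,
    monotone_dropout: bool = False,
) -> SyntheticDataset:
    """Generate the full study: cohort, dropout, and all streams.

    All defaults reproduce the published study conditions (group sizes
    9/10/9, the 8-stage battery, Table-level targets and completion rates).
    """
    group_specs = list(group_specs) if group_specs is not None else default_group_specs()
    tasks = list(tasks) if tasks is not None else default_tasks()
    true_models = dict(true_models) if true_models is not None else default_true_models()
    targets = dict(targets) if targets is not None else default_targets()
    noise = noise or NoiseConfig()

    cohort = generate_cohort(group_specs, seed, economy_sd=noise.economy_sd)
    completion = apply_dropout(cohort, tasks, seed, monotone=monotone_dropout)

    part_rows, epoch_frames, gas_frames = [], [], []
    for p in cohort:
        part_rows.append(
            {"id": p.id, "group": p.group, "rmr_kcal_day": p.rmr,
             "rest_hr_bpm": p.rest_hr, "body_mass_kg": p.body_mass}
        )
        for task in tasks:
            if (p.group, task.name) not in targets:
                raise KeyError(f"no target defined for {(p.group, task.name)}")
            gas, epochs = simulate_activity(
                p, task, true_models[p.group], targets[(p.group, task.name)],
                seed, noise=noise, completed=bool(completion.loc[p.id, task.name]),
            )
            if gas.empty:
                continue
            for df, sink in ((gas, gas_frames), (epochs, epoch_frames)):
                df = df.copy()
                df.insert(0, "task", task.name)
                df.insert(0, "id", p.id)
                sink.append(df)

    participants = pd.DataFrame(part_rows, columns=list(PARTICIPANT_COLUMNS))
    epochs = pd.concat(epoch_frames, ignore_index=True) if epoch_frames else \
        pd.DataFrame(columns=list(EPOCH_COLUMNS))
    gas = pd.concat(gas_frames, ignore_index=True) if gas_frames else \
        pd.DataFrame(columns=list(GAS_COLUMNS))
    return SyntheticDataset(
        cohort=tuple(cohort), completion=completion,
        participants=participants, epochs=epochs, gas=gas,
    )


def write_dataset(dataset: SyntheticDataset, path) -> dict[str, str]:
    """Write participants/epochs/gas CSVs (and the completion table) to ``path``.

    Floats are written at full precision, so read-back reproduces values
    bit-identically.
    """
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "participants": path / "participants.csv",
        "epochs": path / "epochs.csv",
        "gas": path / "gas.csv",
        "completion": path / "completion.csv",
    }
    dataset.participants.to_csv(files["participants"], index=False)
    dataset.epochs.to_csv(files["epochs"], index=False)
    dataset.gas.to_csv(files["gas"], index=False)
    dataset.completion.to_csv(files["completion"])
    return {k: str(v) for k, v in files.items()}


def read_dataset(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back (participants, epochs, gas) written by :func:`write_dataset`."""
    from pathlib import Path

    path = Path(path)
    participants = pd.read_csv(path / "participants.csv")
    epochs = pd.read_csv(path / "epochs.csv")
    gas = pd.read_csv(path / "gas.csv")
    for df, cols in ((participants, PARTICIPANT_COLUMNS), (epochs, EPOCH_COLUMNS),
                     (gas, GAS_COLUMNS)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"dataset file missing columns: {missing}")
    return participants, epochs, gas


def noiseless_dataset(seed: int = 0, **kwargs) -> SyntheticDataset:
    """Convenience: the default study with every noise source disabled.

    Both the sensor scatter and the TrueModel residual SD are zeroed, so
    every walking record lies exactly on the generating plane and the
    downstream fit recovers the coefficients to machine precision.
    """
    if "true_models" not in kwargs:
        kwargs["true_models"] = {
            g: _dc_replace(tm, residual_sd=0.0)
            for g, tm in default_true_models().items()
        }
    return generate_dataset(seed=seed, noise=NoiseConfig.zero(), **kwargs)
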