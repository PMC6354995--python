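"""End-to-end orchestration: simulate → summarize → calibrate → validate.

The pipeline reproduces the structure of a wearable-device calibration
study: generate (or load) epoch-level sensor and gas-exchange data, reduce
each participant-task stage to a steady-state summary, fit population
specific PAC+HR prediction equations, cross-validate them
leave-one-participant-out, and tabulate agreement against the calorimetry
criterion for several comparator methods:

* ``fitted``   — per-group PAC+HR OLS model, predictions out-of-sample
  (leave-one-participant-out);
* ``printed``  — the published population equations applied as-is;
* ``hr_only``  — HR-only linear comparator, also out-of-sample;
* ``external`` — any externally supplied prediction column merged by
  (id, task), standing in for a proprietary multi-sensor device.

Calibration and agreement use the walking stages only; the rest stage has
criterion PAEE = 0 by construction and is reported in the summaries.

Every run is a pure function of (config, seed); the report bundle is
written with full float precision so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference, synthetic
from .agreement import agreement_report, error_stats
from .calibration import (
    PRINTED_MODELS,
    PredictionModel,
    fit_paee_model,
    loocv_predict,
    predict_paee,
)
from .calorimetry import RestingProfile, summarize_task
from .gait import GroupTaskMeans, between_group_hr_ratio

__version__ = "0.1.0"

KNOWN_METHODS = ("fitted", "printed", "hr_only", "external")


class ConfigError(ValueError):
    """Run configuration is invalid; message lists the offending keys."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulate/validate run."""

    seed: int = 0
    groups: tuple[synthetic.GroupSpec, ...] = field(
        default_factory=lambda: tuple(synthetic.default_group_specs())
    )
    noise: synthetic.NoiseConfig = field(default_factory=synthetic.NoiseConfig)
    models: tuple[str, ...] = ("fitted", "printed", "hr_only")
    monotone_dropout: bool = False
    clamp_zero: bool = False
    noiseless: bool = False

    def __post_init__(self) -> None:
        bad = [m for m in self.models if m not in KNOWN_METHODS]
        if bad:
            raise ConfigError(f"unknown methods: {bad}; known: {list(KNOWN_METHODS)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        d["noise"] = dataclasses.asdict(self.noise)
        d["models"] = list(self.models)
        return d


_TOP_KEYS = {"seed", "groups", "noise", "models", "monotone_dropout",
             "clamp_zero", "noiseless"}


def config_from_dict(raw: Mapping) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed key-value document.

    ``groups`` may override any :class:`~paeecal.synthetic.GroupSpec` field
    per group label; unknown keys anywhere raise :class:`ConfigError`
    naming them.
    """
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "groups" in raw:
        bad = sorted(set(raw["groups"]) - set(reference.GROUPS))
        if bad:
            raise ConfigError(f"unknown group labels: {bad}")
        specs = []
        for spec in synthetic.default_group_specs():
            over = dict(raw["groups"].get(spec.label, {}))
            bad_fields = sorted(
                set(over) - {f.name for f in dataclasses.fields(synthetic.GroupSpec)}
            )
            if bad_fields:
                raise ConfigError(
                    f"unknown fields for group '{spec.label}': {bad_fields}"
                )
            specs.append(dataclasses.replace(spec, **over))
        kwargs["groups"] = tuple(specs)
    if "noise" in raw:
        noise_fields = {f.name for f in dataclasses.fields(synthetic.NoiseConfig)}
        bad = sorted(set(raw["noise"]) - noise_fields)
        if bad:
            raise ConfigError(f"unknown noise keys: {bad}")
        kwargs["noise"] = synthetic.NoiseConfig(**raw["noise"])
    if "models" in raw:
        kwargs["models"] = tuple(raw["models"])
    for key in ("monotone_dropout", "clamp_zero", "noiseless"):
        if key in raw:
            kwargs[key] = bool(raw[key])
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config document must be a key-value mapping")
    return config_from_dict(raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _generate(config: RunConfig) -> synthetic.SyntheticDataset:
    if config.noiseless:
        return synthetic.noiseless_dataset(
            seed=config.seed, group_specs=config.groups,
            monotone_dropout=config.monotone_dropout,
        )
    return synthetic.generate_dataset(
        seed=config.seed, group_specs=config.groups, noise=config.noise,
        monotone_dropout=config.monotone_dropout,
    )


def run_simulate(config: RunConfig, out_dir) -> dict[str, str]:
    """Generate the synthetic study and write the dataset plus a manifest."""
    dataset = _generate(config)
    files = synthetic.write_dataset(dataset, out_dir)
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "version": __version__,
        "n_participants": int(len(dataset.participants)),
        "n_epoch_records": int(len(dataset.epochs)),
        "n_gas_records": int(len(dataset.gas)),
    }
    manifest_path = Path(out_dir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    files["manifest"] = str(manifest_path)
    return files


# ---------------------------------------------------------------------------
# summaries


def summarize_dataset(
    participants: pd.DataFrame,
    epochs: pd.DataFrame,
    gas: pd.DataFrame,
    task_kinematics: Mapping[str, tuple[float, float]] | None = None,
    duration_min: float = 5.0,
) -> pd.DataFrame:
    """Steady-state per-participant-per-task summaries.

    Returns one row per completed stage with columns id, group, task, tee,
    paee, mets, rer, mean_hr, mean_pac, pci, n_epochs.
    """
    kin = dict(task_kinematics) if task_kinematics is not None \
        else dict(reference.TASK_KINEMATICS)
    meta = participants.set_index("id")
    rows = []
    for (pid, task), ep in epochs.groupby(["id", "task"], sort=False):
        if task not in kin:
            raise KeyError(f"unknown task '{task}': no kinematics defined")
        g = gas[(gas["id"] == pid) & (gas["task"] == task)]
        resting = RestingProfile(
            rmr=float(meta.loc[pid, "rmr_kcal_day"]),
            rest_hr=float(meta.loc[pid, "rest_hr_bpm"]),
        )
        s = summarize_task(
            g, ep, resting, task, duration_min=duration_min, velocity=kin[task][0]
        )
        rows.append(
            {"id": pid, "group": meta.loc[pid, "group"], "task": task,
             "tee": s.tee, "paee": s.paee, "mets": s.mets, "rer": s.rer,
             "mean_hr": s.mean_hr, "mean_pac": s.mean_pac,
             "pci": np.nan if s.pci is None else s.pci,
             "n_epochs": s.n_epochs_averaged}
        )
    order = {t: i for i, t in enumerate(kin)}
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["group", "id", "task"], key=lambda c: c.map(order).fillna(c) if c.name == "task" else c,
    ).reset_index(drop=True)


def group_task_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Group × task mean ± SD table of the summary quantities."""
    agg = summaries.groupby(["group", "task"], sort=False).agg(
        n=("id", "size"),
        paee_mean=("paee", "mean"), paee_sd=("paee", "std"),
        pac_mean=("mean_pac", "mean"), pac_sd=("mean_pac", "std"),
        hr_mean=("mean_hr", "mean"), hr_sd=("mean_hr", "std"),
        mets_mean=("mets", "mean"), rer_mean=("rer", "mean"),
        pci_mean=("pci", "mean"), pci_sd=("pci", "std"),
    )
    return agg.reset_index()


def gait_metrics_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-group-task PCI (mean of individual ratios and ratio of means) and
    the HR ratio against the control group."""
    walking = summaries[summaries["pci"].notna()]
    rows = []
    grouped = walking.groupby(["group", "task"], sort=False)
    control_hr = {
        task: g["mean_hr"].mean()
        for (grp, task), g in grouped if grp == "control"
    }
    rest_hr = summaries[summaries["task"] == "rest"].groupby("group")["mean_hr"].mean()
    for (grp, task), g in grouped:
        velocity = reference.TASK_KINEMATICS.get(task, (np.nan, np.nan))[0]
        ratio_of_means = (
            (g["mean_hr"].mean() - rest_hr.get(grp, np.nan)) / (velocity * 60.0)
            if velocity and velocity > 0 else np.nan
        )
        rows.append(
            {"group": grp, "task": task,
             "pci_mean": g["pci"].mean(), "pci_sd": g["pci"].std(),
             "pci_ratio_of_means": ratio_of_means,
             "hr_ratio_vs_control": g["mean_hr"].mean() / control_hr[task]
             if task in control_hr else np.nan}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation


def _walking_records(summaries: pd.DataFrame) -> pd.DataFrame:
    rec = summaries[summaries["task"] != "rest"].rename(
        columns={"id": "participant", "mean_pac": "pac", "mean_hr": "hr",
                 "paee": "criterion_paee"}
    )
    return rec[["participant", "group", "task", "pac", "hr", "criterion_paee"]]


def run_validate(
    participants: pd.DataFrame,
    epochs: pd.DataFrame,
    gas: pd.DataFrame,
    config: RunConfig | None = None,
    external_predictions: pd.DataFrame | None = None,
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Full validation: summaries, calibration, cross-validation, agreement.

    ``external_predictions`` (columns id, task, predicted_paee) injects a
    fourth comparator. Returns the report bundle as DataFrames keyed
    ``summaries, group_task, gait_metrics, models, predictions, agreement,
    errors`` and writes them as CSVs when ``out_dir`` is given.
    """
    config = config or RunConfig()
    for df, need in ((participants, synthetic.PARTICIPANT_COLUMNS),
                     (epochs, synthetic.EPOCH_COLUMNS),
                     (gas, synthetic.GAS_COLUMNS)):
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")

    summaries = summarize_dataset(participants, epochs, gas)
    records = _walking_records(summaries)

    methods = list(config.models)
    if external_predictions is not None and "external" not in methods:
        methods.append("external")
    if "external" in methods and external_predictions is None:
        raise ValueError("'external' method requested but no predictions supplied")

    model_rows, pred_frames = [], []
    for grp, g_rec in records.groupby("group", sort=False):
        for method in methods:
            if method == "fitted":
                model = fit_paee_model(g_rec)
                cv = loocv_predict(g_rec, clamp_zero=config.clamp_zero)
            elif method == "hr_only":
                model = fit_paee_model(g_rec, use_pac=False)
                cv = loocv_predict(g_rec, use_pac=False, clamp_zero=config.clamp_zero)
            elif method == "printed":
                model = PRINTED_MODELS[grp]
                cv = g_rec.copy()
                cv["predicted_paee"] = predict_paee(
                    model, cv["pac"], cv["hr"], clamp_zero=config.clamp_zero
                )
                cv["fold"] = -1
            elif method == "external":
                model = None
                ext = external_predictions.rename(columns={"id": "participant"})
                need = {"participant", "task", "predicted_paee"}
                if not need <= set(ext.columns):
                    raise ValueError(
                        f"external predictions missing columns: {sorted(need - set(ext.columns))}"
                    )
                cv = g_rec.merge(
                    ext[["participant", "task", "predicted_paee"]],
                    on=["participant", "task"], how="left",
                )
                cv["fold"] = -1
            if model is not None:
                model_rows.append(
                    {"group": grp, "method": method, "beta_pac": model.beta_pac,
                     "beta_hr": model.beta_hr, "intercept": model.intercept,
                     "r": model.r, "r_squared": model.r_squared, "see": model.see,
                     "n": model.n}
                )
            cv = cv.copy()
            cv.insert(0, "method", method)
            pred_frames.append(cv)

    predictions = pd.concat(pred_frames, ignore_index=True)
    ok = predictions["predicted_paee"].notna()

    agree_rows, err_frames = [], []
    for (grp, method), g in predictions[ok].groupby(["group", "method"], sort=False):
        n_params = {"fitted": 3, "printed": 3, "hr_only": 2, "external": 1}[method]
        rep = agreement_report(
            g["criterion_paee"], g["predicted_paee"], n_params=n_params
        )
        agree_rows.append({"group": grp, "method": method, **dataclasses.asdict(rep)})
        err = error_stats(g)
        err.insert(0, "method", method)
        err.insert(0, "group", grp)
        err_frames.append(err)

    bundle = {
        "summaries": summaries,
        "group_task": group_task_table(summaries),
        "gait_metrics": gait_metrics_table(summaries),
        "models": pd.DataFrame(model_rows),
        "predictions": predictions,
        "agreement": pd.DataFrame(agree_rows),
        "errors": pd.concat(err_frames, ignore_index=True),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(
                {"seed": config.seed, "config_hash": config_hash(config),
                 "version": __version__,
                 "counts": {k: int(len(v)) for k, v in bundle.items()}},
                sort_keys=True, indent=1,
            ) + "\n"
        )
    return bundle


def run_pipeline(config: RunConfig | None = None, out_dir=None) -> dict[str, pd.DataFrame]:
    """Simulate the default study and validate it in one call."""
    config = config or RunConfig()
    ds = _generate(config)
    return run_validate(ds.participants, ds.epochs, ds.gas, config=config,
                        out_dir=out_dir)


# ---------------------------------------------------------------------------
# worked examples: arithmetic reproducible from the published tables alone


def run_worked_examples() -> list[dict]:
    """Recompute every published-table check and report pass/fail.

    Each check derives a quantity from the published group-level constants
    through the package's own functions and compares it with the printed
    value at a stated tolerance. Returns a list of dicts with keys
    ``id, description, value, expected, cmp, tol, passed``.
    """
    from .agreement import PowerSpec, power_sample_size
    from .gait import pci

    checks: list[dict] = []

    def add(check_id, description, value, expected, tol=None, cmp="rel"):
        if cmp == "rel":
            passed = abs(value - expected) <= tol * abs(expected)
        elif cmp == "le":
            passed = value <= expected
        elif cmp == "ge":
            passed = value >= expected
        elif cmp == "between":
            passed = expected[0] <= value[0] and value[1] <= expected[1]
        elif cmp == "eq":
            passed = value == expected
        else:
            raise ValueError(f"unknown cmp '{cmp}'")
        checks.append(
            {"id": check_id, "description": description, "value": value,
             "expected": expected, "cmp": cmp, "tol": tol, "passed": bool(passed)}
        )

    # published equations applied to the published group-task means
    for grp in reference.GROUPS:
        model = PRINTED_MODELS[grp]
        abs_pct = []
        for task in reference.WALKING_TASKS:
            row = reference.GROUP_TASK_SUMMARY[(grp, task)]
            pred = predict_paee(model, row["pac_mean"], row["hr_mean"])
            abs_pct.append(abs(pred - row["paee_mean"]) / row["paee_mean"] * 100)
        add(
            f"printed_eq_mape_{grp}",
            f"{grp}: MAPE of published equation on published walking means "
            "is below the published out-of-sample percent error",
            float(np.mean(abs_pct)),
            reference.PUBLISHED_AGREEMENT[grp]["loocv_mape_pct"],
            cmp="le",
        )
    row = reference.GROUP_TASK_SUMMARY[("unilateral", "tm_0.89")]
    add(
        "printed_eq_unilateral_0.89",
        "unilateral equation at the 0.89 m/s group means reproduces the "
        "printed criterion PAEE",
        predict_paee(PRINTED_MODELS["unilateral"], row["pac_mean"], row["hr_mean"]),
        row["paee_mean"], tol=0.01,
    )
    row = reference.GROUP_TASK_SUMMARY[("bilateral", "tm_1.34")]
    add(
        "printed_eq_bilateral_1.34",
        "bilateral equation at the 1.34 m/s group means reproduces the "
        "printed criterion PAEE",
        predict_paee(PRINTED_MODELS["bilateral"], row["pac_mean"], row["hr_mean"]),
        row["paee_mean"], tol=0.01,
    )

    # PCI from group-mean HRs (ratio of means vs the printed mean of ratios:
    # a few percent of discrepancy is structural, larger where dropout
    # changes the completer subset between the rest row and the task row)
    for grp, task, tol in (("unilateral", "tm_0.89", 0.02), ("control", "tm_1.34", 0.02)):
        row = reference.GROUP_TASK_SUMMARY[(grp, task)]
        rest = reference.GROUP_TASK_SUMMARY[(grp, "rest")]
        add(
            f"pci_{grp}_{task}",
            f"{grp} PCI at {task} from printed mean HRs matches the printed value",
            pci(row["hr_mean"], rest["hr_mean"], reference.TASK_KINEMATICS[task][0]),
            row["pci_mean"], tol=tol,
        )
    full = [
        (g, t) for (g, t), row in reference.GROUP_TASK_SUMMARY.items()
        if row["pci_mean"] is not None
        and row["n_completed"] == reference.GROUP_DEMOGRAPHICS[g]["n"]
    ]
    dev = max(
        abs(
            pci(
                reference.GROUP_TASK_SUMMARY[(g, t)]["hr_mean"],
                reference.GROUP_TASK_SUMMARY[(g, "rest")]["hr_mean"],
                reference.TASK_KINEMATICS[t][0],
            )
            - reference.GROUP_TASK_SUMMARY[(g, t)]["pci_mean"]
        )
        / reference.GROUP_TASK_SUMMARY[(g, t)]["pci_mean"]
        for g, t in full
    )
    add(
        "pci_full_completion_max_dev",
        "max relative deviation of PCI-from-means vs printed PCI over "
        "full-completion cells stays within the mean-of-ratios discrepancy",
        float(dev), 0.04, cmp="le",
    )

    # METs referenced to per-minute RMR
    from .calorimetry import compute_mets, rmr_per_min

    for grp in reference.GROUPS:
        resting = RestingProfile(
            rmr=reference.GROUP_DEMOGRAPHICS[grp]["rmr_mean"],
            rest_hr=reference.GROUP_DEMOGRAPHICS[grp]["rest_hr_mean"],
        )
        add(
            f"mets_rest_{grp}",
            f"{grp}: METs at rest is exactly 1.0",
            compute_mets(rmr_per_min(resting.rmr), resting), 1.0, cmp="eq",
        )
    resting = RestingProfile(rmr=reference.GROUP_DEMOGRAPHICS["bilateral"]["rmr_mean"],
                             rest_hr=67.0)
    row = reference.GROUP_TASK_SUMMARY[("bilateral", "tm_0.48")]
    add(
        "mets_bilateral_0.48",
        "bilateral 0.48 m/s METs from printed PAEE and RMR matches the "
        "printed value",
        compute_mets(row["paee_mean"] + rmr_per_min(resting.rmr), resting),
        row["mets_mean"], tol=0.01,
    )

    # between-group HR ratio bands
    def _means(grp, tasks):
        return [
            GroupTaskMeans(
                group=grp, task=t,
                mean_hr=reference.GROUP_TASK_SUMMARY[(grp, t)]["hr_mean"],
                mean_rest_hr=reference.GROUP_TASK_SUMMARY[(grp, "rest")]["hr_mean"],
                velocity=reference.TASK_KINEMATICS[t][0],
            )
            for t in tasks
        ]

    band_tasks = {
        ("unilateral", "control"): reference.WALKING_TASKS,
        ("bilateral", "control"): reference.RESTRICTED_SPEED_TASKS,
        ("bilateral", "unilateral"): reference.RESTRICTED_SPEED_TASKS,
    }
    for (a, b), band in reference.HR_RATIO_BANDS.items():
        tasks = band_tasks[(a, b)]
        _, (lo, hi) = between_group_hr_ratio(_means(a, tasks), _means(b, tasks), tasks)
        if (a, b) == ("bilateral", "control"):
            add(f"hr_ratio_min_{a}_vs_{b}",
                f"{a}/{b} HR ratios at the restricted speeds are >= {band[0]}",
                lo, band[0], cmp="ge")
        elif (a, b) == ("bilateral", "unilateral"):
            add(f"hr_ratio_max_{a}_vs_{b}",
                f"{a}/{b} HR ratios at the restricted speeds are <= {band[1]}",
                hi, band[1], cmp="le")
        else:
            add(f"hr_ratio_band_{a}_vs_{b}",
                f"{a}/{b} HR ratios across walking tasks lie in "
                f"[{band[0]}, {band[1]}]",
                (lo, hi), band, cmp="between")

    # a-priori power computation
    p = reference.POWER_INPUTS
    add(
        "power_sample_size",
        "paired power computation (d=1.0, alpha=0.05, power=0.8) gives the "
        "published minimum sample size",
        power_sample_size(PowerSpec(d=p["d"], alpha=p["alpha"], power=p["power"])),
        p["n_required"], cmp="eq",
    )
    return checks
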