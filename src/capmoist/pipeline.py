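"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: simulate the factorial
campaign, split it 3:1 into training and prediction sets, fit the six model
variants (BP, SSA-BP, Logistic-SSA-BP, ELM, SSA-ELM, Logistic-SSA-ELM) on a
shared split with a shared model seed, and evaluate each with the
R/RMSE/RPD triplet on both sets.  ``write_report`` emits the dataset-summary
and model-comparison tables as CSV (4-decimal display plus a full-precision
sidecar), per-variant convergence traces, and a provenance block (config
hash, seeds, library versions).

Empty-cell records (duty cycle 0) are air baselines with no grain between
the plates; they calibrate the reference channel but carry no moisture
signal, so by default they are excluded from the model-fitting stage (the
campaign and its split keep all 720 records).  Set
``include_empty_cell=True`` to regress on them anyway.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import DatasetSummary, ModelReport, report_frame, summarize_dataset, summary_frame
from .regressors import BPRegressor, ELMRegressor, SSATunedRegressor
from .synthetic import CAMPAIGN_COLUMNS, CampaignDesign, NoiseModel, generate_campaign, split_train_test

__all__ = [
    "FEATURE_COLUMNS",
    "TARGET_COLUMN",
    "MODEL_VARIANTS",
    "ExperimentConfig",
    "ExperimentResult",
    "PipelineError",
    "build_variants",
    "run_experiment",
    "write_report",
    "read_measurements",
    "write_measurements",
]

FEATURE_COLUMNS = ("temperature_C", "duty_cycle", "capacitance_pF")
TARGET_COLUMN = "moisture_percent"

MODEL_VARIANTS = ("BP", "SSA-BP", "Logistic-SSA-BP", "ELM", "SSA-ELM", "Logistic-SSA-ELM")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    design: CampaignDesign = field(default_factory=CampaignDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    elm_hidden_units: int = 100
    bp_hidden_units: int = 5
    bp_learning_rate: float = 0.01
    bp_max_epochs: int = 10000
    bp_target_error: float = 0.01
    ssa_pop_size: int = 20
    ssa_max_iters: int = 20
    campaign_seed: int = 0
    split_seed: int = 1
    model_seed: int = 2
    include_empty_cell: bool = False

    @classmethod
    def from_global_seed(cls, seed: int, **overrides) -> "ExperimentConfig":
        """Fan one global seed out into independent stage seeds."""
        c, s, m = (int(x) for x in np.random.SeedSequence(seed).generate_state(3) % 2**31)
        return cls(campaign_seed=c, split_seed=s, model_seed=m, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["moisture_levels_percent"] = list(d["design"]["moisture_levels_percent"])
        d["design"]["temperatures_C"] = list(d["design"]["temperatures_C"])
        d["design"]["duty_cycles"] = list(d["design"]["duty_cycles"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            for key in ("moisture_levels_percent", "temperatures_C", "duty_cycles"):
                if key in dd:
                    dd[key] = tuple(dd[key])
            d["design"] = CampaignDesign(**dd)
        if "noise" in d:
            d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """SHA-256 of the canonical JSON rendering."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class ExperimentResult:
    train_summary: DatasetSummary
    test_summary: DatasetSummary
    reports: list
    traces: dict
    provenance: dict


def build_variants(config: ExperimentConfig) -> dict:
    """Fresh estimator instances for the six model variants (shared seed)."""
    ms = config.model_seed

    def elm():
        return ELMRegressor(hidden_units=config.elm_hidden_units, random_state=ms)

    def bp():
        return BPRegressor(
            hidden_units=config.bp_hidden_units,
            learning_rate=config.bp_learning_rate,
            max_epochs=config.bp_max_epochs,
            target_error=config.bp_target_error,
            random_state=ms,
        )

    def tuned(base, mode):
        return SSATunedRegressor(
            estimator=base,
            pop_size=config.ssa_pop_size,
            max_iters=config.ssa_max_iters,
            init_mode=mode,
            random_state=ms,
        )

    return {
        "BP": bp(),
        "SSA-BP": tuned(bp(), "uniform"),
        "Logistic-SSA-BP": tuned(bp(), "logistic"),
        "ELM": elm(),
        "SSA-ELM": tuned(elm(), "uniform"),
        "Logistic-SSA-ELM": tuned(elm(), "logistic"),
    }


def _model_frame(records: pd.DataFrame, include_empty_cell: bool) -> pd.DataFrame:
    if include_empty_cell:
        return records
    return records[records["duty_cycle"] > 0]


def run_experiment(config: ExperimentConfig = ExperimentConfig()) -> ExperimentResult:
    """Simulate, split, fit all six variants, and evaluate.

    Fully deterministic given the three stage seeds; all variants share one
    split and one model seed so their comparison is paired.
    """
    try:
        records = generate_campaign(config.design, config.noise, seed=config.campaign_seed)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"[simulate] {exc}") from exc
    try:
        train, test = split_train_test(records, seed=config.split_seed)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"[split] {exc}") from exc

    train_summary = summarize_dataset(train[TARGET_COLUMN])
    test_summary = summarize_dataset(test[TARGET_COLUMN])

    train_m = _model_frame(train, config.include_empty_cell)
    test_m = _model_frame(test, config.include_empty_cell)
    x_train = train_m[list(FEATURE_COLUMNS)].to_numpy()
    y_train = train_m[TARGET_COLUMN].to_numpy()
    x_test = test_m[list(FEATURE_COLUMNS)].to_numpy()
    y_test = test_m[TARGET_COLUMN].to_numpy()

    reports, traces = [], {}
    for name, est in build_variants(config).items():
        try:
            est.fit(x_train, y_train)
            report = ModelReport.from_predictions(
                name, y_train, est.predict(x_train), y_test, est.predict(x_test)
            )
        except Exception as exc:
            raise PipelineError(f"[fit:{name}] {exc}") from exc
        reports.append(report)
        if hasattr(est, "history_"):
            traces[name] = np.asarray(est.history_)

    provenance = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seeds": {
            "campaign_seed": config.campaign_seed,
            "split_seed": config.split_seed,
            "model_seed": config.model_seed,
        },
        "n_records": int(len(records)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "n_train_model": int(len(train_m)),
        "n_test_model": int(len(test_m)),
        "versions": {
            "capmoist": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return ExperimentResult(
        train_summary=train_summary,
        test_summary=test_summary,
        reports=reports,
        traces=traces,
        provenance=provenance,
    )


def write_report(result: ExperimentResult, outdir) -> Path:
    """Write the summary tables, traces and provenance under ``outdir``.

    ``table2.csv`` rounds metrics to 4 decimals for display;
    ``table2_full.csv`` keeps full precision.  On failure, files created by
    this call are removed so no partial report is left behind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        t1 = summary_frame(result.train_summary, result.test_summary)
        path = outdir / "table1.csv"
        t1.to_csv(path, index=False, float_format="%.4f")
        written.append(path)

        t2 = report_frame(result.reports)
        path = outdir / "table2.csv"
        t2.to_csv(path, index=False, float_format="%.4f")
        written.append(path)
        path = outdir / "table2_full.csv"
        t2.to_csv(path, index=False, float_format="%.17g")
        written.append(path)

        traces_dir = outdir / "traces"
        traces_dir.mkdir(exist_ok=True)
        for name, hist in result.traces.items():
            frame = pd.DataFrame(
                {"iteration": np.arange(1, len(hist) + 1), "best_fitness": hist}
            )
            path = traces_dir / f"{name.replace(' ', '_')}.csv"
            frame.to_csv(path, index=False, float_format="%.17g")
            written.append(path)

        path = outdir / "provenance.json"
        path.write_text(json.dumps(result.provenance, indent=2, sort_keys=True))
        written.append(path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"[report] {exc}") from exc
    return outdir


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV, validating schema and numeric parsability."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file, expected columns {CAMPAIGN_COLUMNS}") from exc
    missing = [c for c in CAMPAIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    numeric = ["moisture_percent", "temperature_C", "duty_cycle", "capacitance_pF"]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        frame[col] = coerced
    return frame


def write_measurements(frame: pd.DataFrame, path) -> None:
    """Write a measurement table; numerics round-trip at 12 significant digits."""
    frame.to_csv(path, index=False, float_format="%.12g")
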