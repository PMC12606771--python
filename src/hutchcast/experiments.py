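"""Training loop, evaluation metrics, and the experiment harnesses.

Covers the full protocol around the forecaster: Adam/MSE training with
best-validation-epoch selection, per-target MAE/RMSE/R2 on the physical
scale, the input/output-length sweep, the module ablation study, and the
cross-region pretrain/fine-tune transfer protocol, all reproducible from
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .model import ModelConfig, PatchCrossFormer, SMOKE_PROFILE
from .preprocessing import (
    ENV_CHANNELS,
    CleanSeriesTable,
    NormalizationState,
    WindowBatch,
    chronological_split,
    denormalize_array,
    fit_normalizer,
    make_windows,
    normalize,
)

# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def mae(y_pred, y_true) -> float:
    """Mean absolute error."""
    y_pred, y_true = _check_pair(y_pred, y_true)
    return float(np.abs(y_pred - y_true).mean())


def rmse(y_pred, y_true) -> float:
    """Root mean squared error."""
    y_pred, y_true = _check_pair(y_pred, y_true)
    return float(np.sqrt(((y_pred - y_true) ** 2).mean()))


def _check_pair(y_pred, y_true):
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if y_pred.size == 0:
        raise ValueError("empty input")
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/observation length mismatch")
    return y_pred, y_true


def r_squared(y_pred, y_true, form: str = "standard") -> float:
    """Coefficient of determination.

    form='standard': 1 - SSE/SST (can be negative; the default reporting
    form). form='printed': explained-variance ratio
    sum((y_pred - ybar)^2) / sum((y_true - ybar)^2), which can exceed 1.
    """
    y_pred, y_true = _check_pair(y_pred, y_true)
    if y_pred.size < 2:
        raise ValueError("R^2 needs at least 2 observations")
    ybar = y_true.mean()
    sst = ((y_true - ybar) ** 2).sum()
    if sst == 0:
        raise ValueError("R^2 undefined for constant observations")
    if form == "printed":
        return float(((y_pred - ybar) ** 2).sum() / sst)
    if form == "standard":
        return float(1.0 - ((y_true - y_pred) ** 2).sum() / sst)
    raise ValueError("form must be 'standard' or 'printed'")


def improvement_pct(baseline: float, proposed: float, form: str = "decrease") -> float:
    """Percentage change between a baseline and a proposed value.

    form='decrease': 100*(baseline - proposed)/baseline, one decimal —
    the improvement-over-baseline convention. form='increase':
    100*(proposed - baseline)/baseline, nearest integer — the
    degradation-over-full-model convention used for ablations.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if form == "decrease":
        pct = 100.0 * (baseline - proposed) / baseline
        return float(Decimal(repr(pct)).quantize(Decimal("0.1"), ROUND_HALF_UP))
    if form == "increase":
        pct = 100.0 * (proposed - baseline) / baseline
        return float(Decimal(repr(pct)).quantize(Decimal("1"), ROUND_HALF_UP))
    raise ValueError("form must be 'decrease' or 'increase'")


@dataclass
class MetricsReport:
    """Per-target MAE/RMSE/R2 on the original physical scales."""

    per_target: dict[str, dict[str, float]]
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": t, **m} for t, m in self.per_target.items()
        ]
        return pd.DataFrame(rows)

    def __getitem__(self, target: str) -> dict[str, float]:
        return self.per_target[target]


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainResult:
    model: object
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int


def _mse_loss(model, inputs: np.ndarray, targets: np.ndarray,
              n_env: int) -> Tensor:
    """Sum over targets of per-target MSE, on the normalized scale."""
    pred = model.forward_tensor(inputs[:, :, :n_env], inputs[:, :, n_env:])
    err = pred - Tensor(targets)
    return (err * err).mean(axis=(0, 1)).sum()


def _eval_loss(model, windows: WindowBatch, n_env: int, batch_size: int) -> float:
    total, count = 0.0, 0
    for i in range(0, len(windows), batch_size):
        x = windows.inputs[i:i + batch_size]
        y = windows.targets[i:i + batch_size]
        pred = model.predict_windows(x, batch_size=batch_size)
        total += ((pred - y) ** 2).mean(axis=(1, 2)).sum()
        count += len(x)
    return total / count


def train_model(model, train_windows: WindowBatch, val_windows: WindowBatch,
                config: TrainConfig) -> TrainResult:
    """Adam/MSE training with per-epoch logging and best-validation-epoch
    weight selection. Fully deterministic given the seed."""
    if len(train_windows) == 0 or len(val_windows) == 0:
        raise ValueError("training and validation window sets must be non-empty")
    n_env = model.config.n_env
    if config.epochs == 0:
        return TrainResult(model, [], [], -1)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best_val, best_state, best_epoch = np.inf, model.state_dict(), -1
    train_trace, val_trace = [], []
    n = len(train_windows)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            loss = _mse_loss(model, train_windows.inputs[idx],
                             train_windows.targets[idx], n_env)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        train_trace.append(epoch_loss / seen)
        vl = _eval_loss(model, val_windows, n_env, config.batch_size)
        val_trace.append(vl)
        if vl < best_val:
            best_val, best_state, best_epoch = vl, model.state_dict(), epoch
    model.load_state_dict(best_state)
    return TrainResult(model, train_trace, val_trace, best_epoch)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


def _guard_physical_scale(y_true_phys: np.ndarray) -> None:
    # (n, H, 3) on physical scales: CO2 is hundreds of ppm, RH tens of %.
    if np.nanmax(np.abs(y_true_phys)) <= 1.5:
        raise ValueError(
            "targets look normalized (all within [-1.5, 1.5]); metrics must be "
            "computed on the denormalized physical scale"
        )


def evaluate(model, test_windows: WindowBatch,
             norm_state: NormalizationState,
             r2_form: str = "standard") -> MetricsReport:
    """Per-target MAE/RMSE/R2 after inverting the min-max scaling."""
    if not set(ENV_CHANNELS).issubset(norm_state.channels):
        raise ValueError(
            f"normalization state lacks target channels {ENV_CHANNELS}; "
            f"has {norm_state.channels}"
        )
    pred_n = model.predict_windows(test_windows.inputs)
    pred = denormalize_array(pred_n, norm_state, ENV_CHANNELS)
    truth = denormalize_array(test_windows.targets, norm_state, ENV_CHANNELS)
    _guard_physical_scale(truth)
    per_target = {}
    for i, name in enumerate(ENV_CHANNELS):
        per_target[name] = {
            "MAE": mae(pred[:, :, i], truth[:, :, i]),
            "RMSE": rmse(pred[:, :, i], truth[:, :, i]),
            "R2": r_squared(pred[:, :, i], truth[:, :, i], form=r2_form),
        }
    return MetricsReport(per_target=per_target, n=len(test_windows))


class PersistencePredictor:
    """Repeats the last observed value of each target across the horizon —
    the standard naive reference forecaster."""

    def __init__(self, config: ModelConfig):
        self.config = config

    def predict_windows(self, inputs: np.ndarray, batch_size: int = 256) -> np.ndarray:
        last = inputs[:, -1, :self.config.n_env]
        return np.repeat(last[:, None, :], self.config.H, axis=1)


# --------------------------------------------------------------------------
# dataset preparation shared by the harnesses
# --------------------------------------------------------------------------


@dataclass
class PreparedData:
    train: WindowBatch
    val: WindowBatch
    test: WindowBatch
    norm_state: NormalizationState


def prepare_windows(dataset: CleanSeriesTable, N: int, H: int,
                    ratios=(6, 1, 3)) -> PreparedData:
    """Chronological 6:1:3 split, training-set normalizer, stride-1 windows."""
    train_t, val_t, test_t = chronological_split(dataset, ratios)
    state = fit_normalizer(train_t)
    return PreparedData(
        train=make_windows(normalize(train_t, state), N, H),
        val=make_windows(normalize(val_t, state), N, H),
        test=make_windows(normalize(test_t, state), N, H),
        norm_state=state,
    )


def _report_rows(report: MetricsReport, **extra) -> list[dict]:
    return [
        {**extra, "target": t, **m} for t, m in report.per_target.items()
    ]


# --------------------------------------------------------------------------
# harness 1: input/output length sweep
# --------------------------------------------------------------------------

N_VALUES = (6, 12, 24, 48, 72, 96, 144)
H_VALUES = (6, 12, 24)


def length_sweep(dataset: CleanSeriesTable,
                 N_values=N_VALUES, H_values=H_VALUES,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None) -> pd.DataFrame:
    """Train and evaluate one model per (N, H) pair.

    Returns a tidy table with one row per (N, H, target); cells that cannot
    be run (no segment long enough) are recorded with a `skipped` reason
    instead of aborting the grid.
    """
    base = model_config or ModelConfig()
    tcfg = train_config or TrainConfig()
    rows = []
    for N in N_values:
        for H in H_values:
            try:
                cfg = replace(base, N=N, H=H)
                data = prepare_windows(dataset, N, H)
                model = PatchCrossFormer(cfg)
                train_model(model, data.train, data.val, tcfg)
                report = evaluate(model, data.test, data.norm_state)
                rows.extend(_report_rows(report, N=N, H=H, skipped=""))
            except ValueError as exc:
                rows.extend(
                    {"N": N, "H": H, "target": t, "MAE": np.nan, "RMSE": np.nan,
                     "R2": np.nan, "skipped": str(exc)}
                    for t in ENV_CHANNELS
                )
    return pd.DataFrame(rows, columns=["N", "H", "target", "MAE", "RMSE", "R2", "skipped"])


# --------------------------------------------------------------------------
# harness 2: ablation study
# --------------------------------------------------------------------------

ABLATION_VARIANTS = (
    ("full", {}),
    ("no_patch_encoding", {"use_patch_encoding": False}),
    ("no_aggregator", {"use_aggregator": False}),
    ("no_cross_attention", {"use_cross_attention": False}),
)


def ablation_study(dataset: CleanSeriesTable,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None) -> pd.DataFrame:
    """Train the full model and each single-module-ablated variant under
    identical seeds and data; tidy table of 4 configurations x 3 targets."""
    base = model_config or ModelConfig()
    tcfg = train_config or TrainConfig()
    data = prepare_windows(dataset, base.N, base.H)
    rows = []
    for name, flags in ABLATION_VARIANTS:
        cfg = replace(base, **flags)
        model = PatchCrossFormer(cfg)
        train_model(model, data.train, data.val, tcfg)
        report = evaluate(model, data.test, data.norm_state)
        rows.extend(_report_rows(report, variant=name, n_params=model.num_params()))
    return pd.DataFrame(
        rows, columns=["variant", "n_params", "target", "MAE", "RMSE", "R2"]
    )


# --------------------------------------------------------------------------
# harness 3: cross-region transfer protocol
# --------------------------------------------------------------------------


@dataclass
class TransferPlan:
    """Pretrain/fine-tune protocol: nested chronological prefixes of the
    target training partition, fixed validation and test partitions."""

    pretrain_sources: list[str] = field(default_factory=lambda: ["gansu", "henan"])
    subset_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)

    def __post_init__(self):
        fr = self.subset_fractions
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("subset fractions must be strictly increasing")


def transfer_protocol(source_sets: dict[str, CleanSeriesTable],
                      target_set: CleanSeriesTable,
                      plan: TransferPlan | None = None,
                      model_config: ModelConfig | None = None,
                      train_config: TrainConfig | None = None,
                      finetune_epochs: int | None = None) -> pd.DataFrame:
    """Zero-shot and fine-tuned evaluation of pretrained initializations.

    Initializations: random, one per pretrain source, and the combined
    sources. Each is evaluated zero-shot on the target test set, then
    fine-tuned (all weights updated) on every nested subset fraction of the
    target training windows and re-evaluated. Rows:
    (init, subset_fraction, target, MAE, RMSE, R2); subset_fraction 0 marks
    the zero-shot row.
    """
    plan = plan or TransferPlan()
    base = model_config or ModelConfig()
    tcfg = train_config or TrainConfig()
    ft_cfg = replace(tcfg, epochs=finetune_epochs if finetune_epochs is not None
                     else tcfg.epochs)
    missing = [s for s in plan.pretrain_sources if s not in source_sets]
    if missing:
        raise ValueError(f"pretrain sources not supplied: {missing}")

    target_data = prepare_windows(target_set, base.N, base.H)

    def pretrain(tables: list[CleanSeriesTable]) -> dict[str, np.ndarray]:
        batches = []
        for tab in tables:
            d = prepare_windows(tab, base.N, base.H)
            batches.append((d.train, d.val))
        train = WindowBatch(
            np.concatenate([b[0].inputs for b in batches]),
            np.concatenate([b[0].targets for b in batches]),
            np.concatenate([b[0].start_rows for b in batches]),
            base.N, base.H,
        )
        val = WindowBatch(
            np.concatenate([b[1].inputs for b in batches]),
            np.concatenate([b[1].targets for b in batches]),
            np.concatenate([b[1].start_rows for b in batches]),
            base.N, base.H,
        )
        model = PatchCrossFormer(base)
        train_model(model, train, val, tcfg)
        return model.state_dict()

    inits: dict[str, dict[str, np.ndarray] | None] = {"random": None}
    for src in plan.pretrain_sources:
        inits[src] = pretrain([source_sets[src]])
    combined_name = "+".join(plan.pretrain_sources)
    inits[combined_name] = pretrain(
        [source_sets[s] for s in plan.pretrain_sources]
    )

    rows = []
    n_train = len(target_data.train)
    for init_name, state in inits.items():
        model = PatchCrossFormer(base)
        if state is not None:
            model.load_state_dict(state)
        report = evaluate(model, target_data.test, target_data.norm_state)
        rows.extend(_report_rows(report, init=init_name, subset_fraction=0.0))
        for frac in plan.subset_fractions:
            sub = target_data.train.subset(slice(0, max(1, int(frac * n_train))))
            model = PatchCrossFormer(base)
            if state is not None:
                model.load_state_dict(state)
            train_model(model, sub, target_data.val, ft_cfg)
            report = evaluate(model, target_data.test, target_data.norm_state)
            rows.extend(_report_rows(report, init=init_name, subset_fraction=frac))
    return pd.DataFrame(
        rows, columns=["init", "subset_fraction", "target", "MAE", "RMSE", "R2"]
    )


def plot_transfer_curves(results: pd.DataFrame, metric: str = "RMSE"):
    """Per-target fine-tuning curves (metric vs subset fraction, one line
    per initialization). Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = list(dict.fromkeys(results["target"]))
    fig, axes = plt.subplots(1, len(targets), figsize=(4 * len(targets), 3.2),
                             squeeze=False)
    for ax, tgt in zip(axes[0], targets):
        sub = results[results["target"] == tgt]
        for init, grp in sub.groupby("init"):
            grp = grp.sort_values("subset_fraction")
            ax.plot(grp["subset_fraction"], grp[metric], marker="o", label=init)
        ax.set_title(tgt)
        ax.set_xlabel("target training fraction")
        ax.set_ylabel(metric)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    return fig
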