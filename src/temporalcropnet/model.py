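"""TemporalCropNet: hybrid stacked LSTM-GRU forecaster of plant growth.

The model consumes per-plant sequences of (height, crown area) at the
first ``input_len`` growth stages and predicts both parameters at the next
stage.  Usage follows the fit/results idiom::

    model = TemporalCropNet(train_series, hidden_units=50)
    res = model.fit(epochs=400, batch_size=50, seed=0, val_series=val)
    pred = res.predict_next(series)        # a PlantRecord for the next stage
    report = res.evaluate(test_series, "height")
    print(res.summary())

Training minimizes mean squared error on min-max scaled features with
adaptive-moment (Adam) mini-batch gradient descent; the scaler is fitted on
the training split only, and the parameters with the best validation loss
are the ones returned.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .crowns import GrowthSeries, PlantRecord
from .metrics import EvalReport, evaluation_report

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalCropNet",
    "TemporalCropNetResults",
    "split_dataset",
    "cross_validate",
]

_FEATURES = ("height", "crown_area")
_CHECKPOINT_SCHEMA = 1


def _series_to_arrays(
    series: list[GrowthSeries], input_len: int, require_target: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack series into X (N, input_len, 2) and next-stage targets Y (N, 2)."""
    need = input_len + 1 if require_target else input_len
    X, Y = [], []
    for s in series:
        if len(s) < need:
            raise ValueError(
                f"plant {s.plant_id}: series of length {len(s)} < required {need}"
            )
        vals = s.values(_FEATURES)
        X.append(vals[:input_len])
        if require_target:
            Y.append(vals[input_len])
    return np.array(X), (np.array(Y) if require_target else None)


def _fit_scaler(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature min-max over all stage values of the training split."""
    flat = values.reshape(-1, values.shape[-1])
    mins = flat.min(axis=0)
    maxs = flat.max(axis=0)
    span = maxs - mins
    maxs = np.where(span <= 0, mins + 1.0, maxs)  # degenerate feature guard
    return mins, maxs


def _scale(v: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mins, maxs = scaler
    return (v - mins) / (maxs - mins)


def _unscale(v: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mins, maxs = scaler
    return v * (maxs - mins) + mins


class TemporalCropNet:
    """Hybrid stacked LSTM-GRU model over per-plant growth series.

    Parameters
    ----------
    series : list of GrowthSeries
        Training data; each series needs ``input_len + 1`` stages (the last
        one is the prediction target).
    input_len : int
        Number of growth stages consumed per prediction (default 3:
        three observed dates forecasting the fourth).
    hidden_units, lstm_layers, gru_layers : int
        Stack geometry.  Setting one of the layer counts to 0 yields a
        single-branch ablation (used for baseline comparisons).
    branches : {"both", "lstm", "gru"}
        Convenience switch for the ablations.
    """

    def __init__(
        self,
        series: list[GrowthSeries],
        input_len: int = 3,
        hidden_units: int = 50,
        lstm_layers: int = 2,
        gru_layers: int = 2,
        branches: str = "both",
        activation: str = "relu",
    ):
        if branches == "lstm":
            gru_layers = 0
        elif branches == "gru":
            lstm_layers = 0
        elif branches != "both":
            raise ValueError("branches must be 'both', 'lstm' or 'gru'")
        self.series = list(series)
        self.input_len = int(input_len)
        self.hidden_units = int(hidden_units)
        self.lstm_layers = int(lstm_layers)
        self.gru_layers = int(gru_layers)
        self.activation = activation
        # validates lengths eagerly
        self._X_raw, self._Y_raw = _series_to_arrays(self.series, self.input_len, True)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "TemporalCropNet":
        """Build from a PlantRecord-schema table (see crowns module)."""
        from .crowns import records_from_dataframe

        return cls(records_from_dataframe(df), **kwargs)

    def fit(
        self,
        epochs: int = 400,
        batch_size: int = 50,
        learning_rate: float = 1e-3,
        seed: int = 0,
        val_series: list[GrowthSeries] | None = None,
        verbose: bool = False,
    ) -> "TemporalCropNetResults":
        """Train with MSE loss and Adam; returns the best-validation results."""
        model = nn.init_hybrid(
            input_dim=len(_FEATURES),
            output_dim=len(_FEATURES),
            hidden_units=self.hidden_units,
            lstm_layers=self.lstm_layers,
            gru_layers=self.gru_layers,
            activation=self.activation,
            seed=seed,
        )
        scaler = _fit_scaler(np.concatenate([self._X_raw.reshape(-1, 2), self._Y_raw]))
        model.scaler = scaler
        X = _scale(self._X_raw, scaler)
        Y = _scale(self._Y_raw, scaler)
        Xv = Yv = None
        if val_series is not None:
            Xv_raw, Yv_raw = _series_to_arrays(val_series, self.input_len, True)
            Xv, Yv = _scale(Xv_raw, scaler), _scale(Yv_raw, scaler)

        rng = np.random.default_rng(seed)
        opt = nn.AdamOptimizer(model, learning_rate)
        n = len(X)
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_params = None
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], Y[idx]
                cache = nn._hybrid_forward_cached(xb, model)
                out = cache[0]
                err = out - yb
                loss = float((err**2).mean())
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}; "
                        "lower the learning rate"
                    )
                epoch_loss += loss * len(idx)
                dout = 2.0 * err / err.size
                grads = nn.hybrid_backward(xb, dout, model, cache)
                opt.step(grads)
            history["train_loss"].append(epoch_loss / n)
            if Xv is not None:
                vout = nn.hybrid_forward(Xv, model)
                vloss = float(((vout - Yv) ** 2).mean())
                history["val_loss"].append(vloss)
                if vloss < best_val:
                    best_val = vloss
                    best_params = _copy_params(model)
            if verbose and (epoch + 1) % 50 == 0:
                logger.info(
                    "epoch %d: train %.3g%s",
                    epoch + 1,
                    history["train_loss"][-1],
                    f", val {history['val_loss'][-1]:.3g}" if Xv is not None else "",
                )
        if best_params is not None:
            _restore_params(model, best_params)
        return TemporalCropNetResults(self, model, history)


@dataclass
class TemporalCropNetResults:
    """Fitted parameters, training history and prediction interface."""

    model_spec: TemporalCropNet
    params: nn.HybridModel
    history: dict[str, list[float]] = field(default_factory=dict)

    # -- prediction --------------------------------------------------------

    def predict(self, series: list[GrowthSeries]) -> np.ndarray:
        """Next-stage (height, crown_area) in physical units, one row per series."""
        X_raw, _ = _series_to_arrays(series, self.model_spec.input_len, False)
        X = _scale(X_raw, self.params.scaler)
        out = nn.hybrid_forward(X, self.params)
        return _unscale(np.atleast_2d(out), self.params.scaler)

    def predict_next(self, series: GrowthSeries) -> PlantRecord:
        """Forecast the record for the growth stage after the series' last."""
        if len(series) < self.model_spec.input_len:
            raise ValueError(
                f"series length {len(series)} < model input length "
                f"{self.model_spec.input_len}"
            )
        pred = self.predict([series])[0]
        height, area = float(pred[0]), float(pred[1])
        floor = 1e-6
        if height <= 0 or area <= 0:
            logger.warning(
                "plant %d: non-positive forecast clamped to %.1e", series.plant_id, floor
            )
        return PlantRecord(
            plant_id=series.plant_id,
            date_index=series.records[self.model_spec.input_len - 1].date_index + 1,
            height=max(height, floor),
            crown_area=max(area, floor),
            centroid=series.records[-1].centroid,
        )

    def evaluate(self, series: list[GrowthSeries], parameter: str = "height") -> EvalReport:
        """SMAPE / log-deviation report of next-stage forecasts vs observed."""
        preds, truth = [], []
        for s in series:
            truth.append(s.records[self.model_spec.input_len])
            preds.append(
                self.predict_next(GrowthSeries(s.plant_id, s.records[: self.model_spec.input_len]))
            )
        return evaluation_report(preds, truth, parameter)

    # -- presentation ------------------------------------------------------

    def summary(self, test_series: list[GrowthSeries] | None = None) -> str:
        spec = self.model_spec
        buf = io.StringIO()
        w = buf.write
        w("TemporalCropNet results\n")
        w("=" * 58 + "\n")
        rows = [
            ("Input stages", spec.input_len),
            ("Predicted parameters", ", ".join(_FEATURES)),
            ("LSTM layers", spec.lstm_layers),
            ("GRU layers", spec.gru_layers),
            ("Hidden units", spec.hidden_units),
            ("Training series", len(spec.series)),
            ("Epochs run", len(self.history.get("train_loss", []))),
        ]
        if self.history.get("train_loss"):
            rows.append(("Final train MSE (scaled)", f"{self.history['train_loss'][-1]:.4g}"))
        if self.history.get("val_loss"):
            rows.append(("Best val MSE (scaled)", f"{min(self.history['val_loss']):.4g}"))
        for k, v in rows:
            w(f"{k:<32}{v}\n")
        if test_series:
            w("-" * 58 + "\n")
            for parameter in _FEATURES:
                rep = self.evaluate(test_series, parameter)
                w(
                    f"{parameter:<14} SMAPE {rep.smape_percent:6.2f} %   "
                    f"L_d sum {rep.ld_sum:+8.4f}   "
                    f"(n={rep.n_pairs}, over={rep.over_count}, under={rep.under_count})\n"
                )
        return buf.getvalue()

    def plot_history(self, ax=None):
        """Training/validation loss curves (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["train_loss"], label="train")
        if self.history.get("val_loss"):
            ax.plot(self.history["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (scaled)")
        ax.set_yscale("log")
        ax.legend()
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: parameter arrays + config + scaler."""
        spec = self.model_spec
        config = {
            "schema": _CHECKPOINT_SCHEMA,
            "input_len": spec.input_len,
            "hidden_units": spec.hidden_units,
            "lstm_layers": spec.lstm_layers,
            "gru_layers": spec.gru_layers,
            "activation": spec.activation,
        }
        arrays = {key.replace(".", "__"): arr for key, arr in nn.iter_params(self.params)}
        arrays["scaler_min"], arrays["scaler_max"] = self.params.scaler
        np.savez(path, config=json.dumps(config), history=json.dumps(self.history), **arrays)

    @classmethod
    def load(cls, path) -> "TemporalCropNetResults":
        with np.load(path, allow_pickle=False) as data:
            config = json.loads(str(data["config"]))
            if config.get("schema") != _CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {config.get('schema')}")
            history = json.loads(str(data["history"]))
            model = nn.init_hybrid(
                input_dim=len(_FEATURES),
                output_dim=len(_FEATURES),
                hidden_units=config["hidden_units"],
                lstm_layers=config["lstm_layers"],
                gru_layers=config["gru_layers"],
                activation=config["activation"],
                seed=0,
            )
            for key, arr in nn.iter_params(model):
                arr[...] = data[key.replace(".", "__")]
            model.scaler = (data["scaler_min"], data["scaler_max"])
        spec = TemporalCropNet.__new__(TemporalCropNet)
        spec.series = []
        spec.input_len = config["input_len"]
        spec.hidden_units = config["hidden_units"]
        spec.lstm_layers = config["lstm_layers"]
        spec.gru_layers = config["gru_layers"]
        spec.activation = config["activation"]
        return cls(spec, model, history)


def _copy_params(model: nn.HybridModel) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in nn.iter_params(model)}


def _restore_params(model: nn.HybridModel, saved: dict[str, np.ndarray]) -> None:
    for k, v in nn.iter_params(model):
        v[...] = saved[k]


# ---------------------------------------------------------------------------
# Dataset utilities


def split_dataset(
    series: list[GrowthSeries],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[GrowthSeries], list[GrowthSeries], list[GrowthSeries]]:
    """Plant-level train/validation/test split (largest-remainder rounding).

    A plant's whole series lands in exactly one split; membership is
    deterministic under the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(series)
    if n < 5:
        raise ValueError("need at least 5 series for a meaningful split")
    exact = np.array(fractions) * n
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    for _ in range(n - sizes.sum()):
        i = int(np.argmax(remainder))
        sizes[i] += 1
        remainder[i] = -1
    order = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    pick = lambda idx: [series[i] for i in idx]
    return pick(order[:a]), pick(order[a:b]), pick(order[b:])


def cross_validate(
    series: list[GrowthSeries],
    cv_folds: int = 5,
    input_len: int = 3,
    seed: int = 0,
    model_kwargs: dict | None = None,
    **fit_kwargs,
) -> dict:
    """Plant-level k-fold cross-validation of the hybrid forecaster.

    Each fold trains on the other k-1 folds and reports held-out SMAPE and
    log deviation for both parameters.  Returns per-fold reports plus the
    mean and standard deviation of SMAPE across folds.
    """
    n = len(series)
    if n < cv_folds:
        raise ValueError("fewer series than folds")
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, cv_folds)
    model_kwargs = model_kwargs or {}
    fold_reports = []
    for k, hold in enumerate(folds):
        hold_set = set(hold.tolist())
        train = [series[i] for i in order if i not in hold_set]
        test = [series[i] for i in hold]
        res = TemporalCropNet(train, input_len=input_len, **model_kwargs).fit(
            seed=seed + k, **fit_kwargs
        )
        reports = {p: res.evaluate(test, p) for p in _FEATURES}
        fold_reports.append(reports)
    summary = {}
    for p in _FEATURES:
        vals = np.array([fr[p].smape_percent for fr in fold_reports])
        summary[p] = {"smape_mean": float(vals.mean()), "smape_sd": float(vals.std(ddof=1))}
    return {"folds": fold_reports, "summary": summary}
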