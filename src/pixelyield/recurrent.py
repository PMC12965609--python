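"""Two-branch recurrent yield downscaler with static-input fusion.

The network ingests three inputs per sample: a band sequence (T1 time
steps x F1 spectral/backscatter features), a weather sequence (T2 x F2)
and a static vector (F3).  Each sequence runs through its own recurrent
cell (LSTM or GRU, 32 units) followed by a 16-unit ReLU dense layer; the
two 16-wide branch summaries and the static input are concatenated
(16 + 16 + F3 wide) and passed through a 128-64-32 ReLU head with
dropout, ending in a single Softplus output so predicted yields are
strictly non-negative.

The GRU uses the double-bias ("reset-after") formulation, with separate
input and recurrent bias vectors; with 32 units and the default input
widths this puts the trainable parameter totals at exactly 25,889 (LSTM)
and 23,553 (GRU).

Everything — forward pass, backpropagation through time, Adam, early
stopping — is implemented on numpy arrays, which keeps training fully
deterministic under a seed and makes the model dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SampleSet
from .raster import RasterStack
from .regions import VillageMap, zonal_aggregate

__all__ = [
    "RecurrentSpec",
    "TrainConfig",
    "FeatureCube",
    "RecurrentDownscaler",
    "build_recurrent_model",
    "count_trainable_parameters",
    "train_model",
    "predict_pixel_yield",
    "aggregate_to_admin",
]


@dataclass(frozen=True)
class RecurrentSpec:
    """Architecture hyperparameters (defaults follow the reference setup)."""

    cell: str = "LSTM"            # "LSTM" or "GRU"
    t1: int = 3                   # band time steps
    f1: int = 7                   # band features per step
    t2: int = 5                   # weather time steps
    f2: int = 6                   # weather features per step
    f3: int = 1                   # static input width
    rnn_units: int = 32
    branch_dense: int = 16
    head: tuple[int, ...] = (128, 64, 32)
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.cell not in ("LSTM", "GRU"):
            raise ValueError("cell must be 'LSTM' or 'GRU'")
        if min(self.t1, self.f1, self.t2, self.f2, self.f3, self.rnn_units) < 1:
            raise ValueError("all dimensions must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def merged_width(self) -> int:
        return 2 * self.branch_dense + self.f3


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam on MSE, MAE monitored, early stopping."""

    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 25            # epochs without val improvement; <=0 disables
    batch_size: int = 32
    monitor: str = "val_loss"     # "val_loss" (MSE) or "val_mae"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.monitor not in ("val_loss", "val_mae"):
            raise ValueError("monitor must be 'val_loss' or 'val_mae'")


def count_trainable_parameters(spec: RecurrentSpec) -> int:
    """Closed-form trainable parameter total of the architecture.

    Per cell with input width d and h units: LSTM 4*(d*h + h*h + h);
    GRU (double-bias) 3*(d*h + h*h + 2*h).  A dense layer in -> out has
    (in + 1) * out parameters.  Dropout and activations add none.
    """
    h = spec.rnn_units
    if spec.cell == "LSTM":
        cell = lambda d: 4 * (d * h + h * h + h)
    else:
        cell = lambda d: 3 * (d * h + h * h + 2 * h)
    dense = lambda i, o: (i + 1) * o
    total = cell(spec.f1) + dense(h, spec.branch_dense)
    total += cell(spec.f2) + dense(h, spec.branch_dense)
    width = spec.merged_width
    for w in spec.head:
        total += dense(width, w)
        width = w
    total += dense(width, 1)
    return total


# ---------------------------------------------------------------------------
# numerics


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:n, :m] if q.shape == (n, m) else q.T[:n, :m]


class _LSTMCell:
    """LSTM over a full sequence; gate order i, f, g, o."""

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        self.d, self.h = d, h
        self.Wx = _glorot(rng, d, 4 * h)
        self.Wh = _orthogonal(rng, h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # forget-gate bias

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray):
        n, T, _ = x.shape
        h = self.h
        hs = np.zeros((n, h))
        cs = np.zeros((n, h))
        cache = []
        for t in range(T):
            z = x[:, t] @ self.Wx + hs @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_new = f * cs + i * g
            tc = np.tanh(c_new)
            cache.append((x[:, t], hs, cs, i, f, g, o, tc))
            hs, cs = o * tc, c_new
        return hs, cache

    def backward(self, dh_last: np.ndarray, cache):
        h = self.h
        g_Wx = np.zeros_like(self.Wx)
        g_Wh = np.zeros_like(self.Wh)
        g_b = np.zeros_like(self.b)
        dh = dh_last
        dc = np.zeros_like(dh_last)
        dx_seq = []
        for t in reversed(range(len(cache))):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            g_Wx += x_t.T @ dz
            g_Wh += h_prev.T @ dz
            g_b += dz.sum(axis=0)
            dx_seq.append(dz @ self.Wx.T)
            dh = dz @ self.Wh.T
            dc = dc * f
        dx = np.stack(dx_seq[::-1], axis=1)
        return dx, {"Wx": g_Wx, "Wh": g_Wh, "b": g_b}


class _GRUCell:
    """Reset-after GRU with separate input/recurrent biases; gate order z, r, h."""

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        self.d, self.h = d, h
        self.Wx = _glorot(rng, d, 3 * h)
        self.Wh = _orthogonal(rng, h, 3 * h)
        self.bx = np.zeros(3 * h)
        self.bh = np.zeros(3 * h)

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "bx": self.bx, "bh": self.bh}

    def forward(self, x: np.ndarray):
        n, T, _ = x.shape
        h = self.h
        hs = np.zeros((n, h))
        cache = []
        for t in range(T):
            ax = x[:, t] @ self.Wx + self.bx
            ah = hs @ self.Wh + self.bh
            z = _sigmoid(ax[:, :h] + ah[:, :h])
            r = _sigmoid(ax[:, h:2 * h] + ah[:, h:2 * h])
            hh = ah[:, 2 * h:]
            cand = np.tanh(ax[:, 2 * h:] + r * hh)
            h_new = z * hs + (1 - z) * cand
            cache.append((x[:, t], hs, z, r, hh, cand))
            hs = h_new
        return hs, cache

    def backward(self, dh_last: np.ndarray, cache):
        h = self.h
        g_Wx = np.zeros_like(self.Wx)
        g_Wh = np.zeros_like(self.Wh)
        g_bx = np.zeros_like(self.bx)
        g_bh = np.zeros_like(self.bh)
        dh = dh_last
        dx_seq = []
        for t in reversed(range(len(cache))):
            x_t, h_prev, z, r, hh, cand = cache[t]
            dz = dh * (h_prev - cand)
            dcand = dh * (1 - z)
            dh_prev = dh * z
            da_cand = dcand * (1 - cand ** 2)   # pre-tanh
            dr = da_cand * hh
            dhh = da_cand * r
            da_z = dz * z * (1 - z)
            da_r = dr * r * (1 - r)
            dax = np.concatenate([da_z, da_r, da_cand], axis=1)
            dah = np.concatenate([da_z, da_r, dhh], axis=1)
            g_Wx += x_t.T @ dax
            g_bx += dax.sum(axis=0)
            g_Wh += h_prev.T @ dah
            g_bh += dah.sum(axis=0)
            dx_seq.append(dax @ self.Wx.T)
            dh = dh_prev + dah @ self.Wh.T
        dx = np.stack(dx_seq[::-1], axis=1)
        return dx, {"Wx": g_Wx, "Wh": g_Wh, "bx": g_bx, "bh": g_bh}


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu: bool):
        self.W = _glorot(rng, d_in, d_out)
        self.b = np.zeros(d_out)
        self.relu = relu

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray):
        a = x @ self.W + self.b
        out = np.maximum(a, 0.0) if self.relu else a
        return out, (x, a)

    def backward(self, dout: np.ndarray, cache):
        x, a = cache
        da = dout * (a > 0) if self.relu else dout
        return da @ self.W.T, {"W": x.T @ da, "b": da.sum(axis=0)}


@dataclass
class FeatureCube:
    """Per-pixel model input: grouped feature arrays plus grid georeference."""

    bands: np.ndarray    # (n_pixels, T1, F1)
    weather: np.ndarray  # (n_pixels, T2, F2)
    static: np.ndarray   # (n_pixels, F3)
    shape: tuple[int, int] | None = None
    resolution: float | None = None
    origin: tuple[float, float] | None = None

    @classmethod
    def from_stack(cls, stack: RasterStack, static: np.ndarray | None = None) -> "FeatureCube":
        """Flatten a covariate stack into model inputs.

        Optical and radar layers together form the band sequence (feature
        order: optical first, radar second, as stacked).  ``static``
        defaults to a crop-indicator column of ones.
        """
        rows, cols = stack.shape
        opt = stack.time_series("optical")
        rad = stack.time_series("radar")
        bands = np.concatenate([opt, rad], axis=3).reshape(rows * cols, opt.shape[2], -1)
        weather = stack.time_series("weather").reshape(rows * cols, -1, len(
            {li.feature for li in stack.layers if li.source == "weather"}
        ))
        if static is None:
            static = np.ones((rows * cols, 1))
        return cls(bands, weather, np.asarray(static, float).reshape(rows * cols, -1),
                   (rows, cols), stack.resolution, stack.origin)


class RecurrentDownscaler:
    """The assembled network with explicit forward/backward passes."""

    def __init__(self, spec: RecurrentSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        Cell = _LSTMCell if spec.cell == "LSTM" else _GRUCell
        self.bands_cell = Cell(spec.f1, spec.rnn_units, rng)
        self.bands_dense = _Dense(spec.rnn_units, spec.branch_dense, rng, relu=True)
        self.weather_cell = Cell(spec.f2, spec.rnn_units, rng)
        self.weather_dense = _Dense(spec.rnn_units, spec.branch_dense, rng, relu=True)
        self.head = []
        width = spec.merged_width
        for w in spec.head:
            self.head.append(_Dense(width, w, rng, relu=True))
            width = w
        self.out = _Dense(width, 1, rng, relu=False)
        self.norm: dict[str, np.ndarray] | None = None  # z-score stats from training

    # -- parameter bookkeeping ----------------------------------------

    def _modules(self):
        mods = {
            "bands_cell": self.bands_cell,
            "bands_dense": self.bands_dense,
            "weather_cell": self.weather_cell,
            "weather_dense": self.weather_dense,
            "out": self.out,
        }
        for i, layer in enumerate(self.head):
            mods[f"head{i}"] = layer
        return mods

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{mname}.{pname}": arr
            for mname, mod in self._modules().items()
            for pname, arr in mod.params().items()
        }

    def n_parameters(self) -> int:
        return sum(arr.size for arr in self.parameters().values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in weights.items():
            params[k][...] = v

    # -- passes --------------------------------------------------------

    def forward(
        self,
        bands: np.ndarray,
        weather: np.ndarray,
        static: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        hb, cache_b = self.bands_cell.forward(bands)
        fb, cache_bd = self.bands_dense.forward(hb)
        hw, cache_w = self.weather_cell.forward(weather)
        fw, cache_wd = self.weather_dense.forward(hw)
        x = np.concatenate([fb, fw, static], axis=1)
        caches_h, drop_masks = [], []
        p = self.spec.dropout
        for layer in self.head:
            x, c = layer.forward(x)
            caches_h.append(c)
            if training and p > 0:
                mask = (dropout_rng.random(x.shape) >= p) / (1.0 - p)
                x = x * mask
                drop_masks.append(mask)
            else:
                drop_masks.append(None)
        a, cache_o = self.out.forward(x)
        a = a[:, 0]
        yhat = np.logaddexp(0.0, a)  # softplus
        cache = (cache_b, cache_bd, cache_w, cache_wd, caches_h, drop_masks, cache_o, a)
        return yhat, cache

    def predict(self, bands, weather, static, batch: int = 8192) -> np.ndarray:
        """Standardize with the stored training statistics and run forward."""
        if self.norm is not None:
            bands, weather, static = _apply_norm(self.norm, bands, weather, static)
        out = np.empty(len(bands))
        for s in range(0, len(bands), batch):
            sl = slice(s, s + batch)
            out[sl] = self.forward(bands[sl], weather[sl], static[sl])[0]
        return out

    def backward(self, dyhat: np.ndarray, cache):
        cache_b, cache_bd, cache_w, cache_wd, caches_h, drop_masks, cache_o, a = cache
        da = (dyhat * _sigmoid(a))[:, None]
        dx, g_out = self.out.backward(da, cache_o)
        grads = {f"out.{k}": v for k, v in g_out.items()}
        for i in reversed(range(len(self.head))):
            if drop_masks[i] is not None:
                dx = dx * drop_masks[i]
            dx, g = self.head[i].backward(dx, caches_h[i])
            grads.update({f"head{i}.{k}": v for k, v in g.items()})
        nb = self.spec.branch_dense
        dfb, dfw = dx[:, :nb], dx[:, nb:2 * nb]
        dhb, g = self.bands_dense.backward(dfb, cache_bd)
        grads.update({f"bands_dense.{k}": v for k, v in g.items()})
        _, g = self.bands_cell.backward(dhb, cache_b)
        grads.update({f"bands_cell.{k}": v for k, v in g.items()})
        dhw, g = self.weather_dense.backward(dfw, cache_wd)
        grads.update({f"weather_dense.{k}": v for k, v in g.items()})
        _, g = self.weather_cell.backward(dhw, cache_w)
        grads.update({f"weather_cell.{k}": v for k, v in g.items()})
        return grads


def build_recurrent_model(spec: RecurrentSpec, seed: int = 0) -> RecurrentDownscaler:
    """Instantiate the network; its weight count matches the closed form."""
    model = RecurrentDownscaler(spec, seed)
    assert model.n_parameters() == count_trainable_parameters(spec)
    return model


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _norm_stats(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    flat = arr.reshape(len(arr), -1)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    return mean.reshape(arr.shape[1:]), sd.reshape(arr.shape[1:])


def _apply_norm(norm, bands, weather, static):
    return (
        (bands - norm["bands_mean"]) / norm["bands_sd"],
        (weather - norm["weather_mean"]) / norm["weather_sd"],
        (static - norm["static_mean"]) / norm["static_sd"],
    )


def train_model(
    model: RecurrentDownscaler,
    train: SampleSet,
    val: SampleSet,
    config: TrainConfig = TrainConfig(),
) -> tuple[RecurrentDownscaler, pd.DataFrame]:
    """Fit the downscaler with Adam on MSE, monitoring MAE.

    Inputs are z-scored per feature with training-split statistics (the
    statistics are stored on the model and re-applied at prediction
    time); the output bias is initialized so the Softplus output starts
    at the training-mean yield.  Early stopping watches the configured
    monitor with the given patience and restores the best weights.

    Returns the trained model and a per-epoch history frame with columns
    ``loss, mae, val_loss, val_mae``.
    """
    if set(train.village_id) & set(val.village_id):
        raise ValueError("train and validation samples overlap")
    rng = np.random.default_rng(config.seed)
    norm = {}
    norm["bands_mean"], norm["bands_sd"] = _norm_stats(train.bands)
    norm["weather_mean"], norm["weather_sd"] = _norm_stats(train.weather)
    norm["static_mean"], norm["static_sd"] = _norm_stats(train.static)
    model.norm = norm
    Xb, Xw, Xs = _apply_norm(norm, train.bands, train.weather, train.static)
    Vb, Vw, Vs = _apply_norm(norm, val.bands, val.weather, val.static)
    y, yv = train.y, val.y

    # start the Softplus output at the mean training yield
    mean_y = max(float(y.mean()), 1e-6)
    model.out.b[0] = mean_y + np.log1p(-np.exp(-mean_y))  # inverse softplus

    opt = _Adam(model.parameters(), config.learning_rate)
    best_metric = np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    history = []
    n = len(y)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for s in range(0, n, config.batch_size):
            ii = order[s:s + config.batch_size]
            yhat, cache = model.forward(Xb[ii], Xw[ii], Xs[ii], training=True, dropout_rng=rng)
            err = yhat - y[ii]
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            grads = model.backward(2.0 * err / len(ii), cache)
            opt.step(grads)
        pt = model.forward(Xb, Xw, Xs)[0]
        pv = model.forward(Vb, Vw, Vs)[0]
        rec = {
            "loss": float(np.mean((pt - y) ** 2)),
            "mae": float(np.mean(np.abs(pt - y))),
            "val_loss": float(np.mean((pv - yv) ** 2)),
            "val_mae": float(np.mean(np.abs(pv - yv))),
        }
        history.append(rec)
        metric = rec[config.monitor]
        if metric < best_metric - 1e-12:
            best_metric = metric
            best_weights = model.get_weights()
            best_epoch = epoch
        elif config.patience > 0 and epoch - best_epoch >= config.patience:
            break
    model.set_weights(best_weights)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    hist.attrs["stopped_epoch"] = len(history) - 1
    return model, hist


def predict_pixel_yield(
    model: RecurrentDownscaler,
    cube: FeatureCube,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pixel-level yield raster from per-pixel features.

    Applies the training standardization stored on the model; pixels
    outside ``mask`` (or with missing features) are nodata.  The Softplus
    head guarantees non-negative yields everywhere else.
    """
    if cube.shape is None:
        raise ValueError("feature cube lacks grid shape")
    rows, cols = cube.shape
    spec = model.spec
    if cube.bands.shape[1:] != (spec.t1, spec.f1) or cube.weather.shape[1:] != (spec.t2, spec.f2):
        raise ValueError("feature cube layout does not match the model spec")
    flat_ok = ~(
        np.isnan(cube.bands.reshape(len(cube.bands), -1)).any(axis=1)
        | np.isnan(cube.weather.reshape(len(cube.weather), -1)).any(axis=1)
        | np.isnan(cube.static).any(axis=1)
    )
    if mask is not None:
        flat_ok &= np.asarray(mask, bool).ravel()
    out = np.full(rows * cols, np.nan)
    if flat_ok.any():
        out[flat_ok] = model.predict(
            cube.bands[flat_ok], cube.weather[flat_ok], cube.static[flat_ok]
        )
    return out.reshape(rows, cols)


def aggregate_to_admin(
    raster: np.ndarray,
    villages: VillageMap,
    resolution: float,
    origin: tuple[float, float],
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Masked zonal means of a prediction raster per administrative unit."""
    return zonal_aggregate(raster, villages, mask, resolution=resolution, origin=origin)
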