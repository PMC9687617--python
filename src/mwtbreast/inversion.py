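"""End-to-end fully-connected inverter: scattered field -> dielectric maps.

A multilayer perceptron maps the vectorized scattering matrix (2 M reals)
directly to the vectorized eps'/sigma maps (2 N reals) — a direct inversion
scheme with no intermediate imaging step.  The reference architecture is
three hidden layers of 2000 rectifier units plus a linear regression output
layer, trained with Adam on a mean-squared-error loss (initial learning
rate 5e-5, 30 epochs, mini-batches of 64 at full scale).

The network, loss and optimizer are implemented in NumPy: the stack is
small enough that a hand-rolled, fully seeded implementation keeps training
bit-reproducible and dependency-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import (Dataset, NormStats, compute_normalization,
                      devectorize_output, vectorize_input)
from .em_forward import ScatteringMatrix

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "MLP",
    "TrainedInverter",
    "build_network",
    "parameter_count",
    "train",
    "invert",
    "architecture_sweep",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("relu", "tanh", "identity")


@dataclass(frozen=True)
class NetworkSpec:
    """Hidden-stack layout; the linear regression output layer is implied."""

    n_hidden_layers: int = 3
    nodes_per_layer: int = 2000
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1 or self.nodes_per_layer < 1:
            raise ValueError("need >= 1 hidden layer and >= 1 node")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")


@dataclass(frozen=True)
class TrainConfig:
    """Adam / MSE training schedule (full-scale defaults)."""

    learning_rate: float = 5e-5
    epochs: int = 30
    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning rate, epochs, batch size must be > 0")


class MLP:
    """Plain fully-connected stack with seeded Glorot-uniform init."""

    def __init__(self, sizes: list[int], activation: str, seed: int):
        self.sizes = list(sizes)
        self.activation = activation
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound,
                                            size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "tanh":
            return np.tanh(z)
        return z

    def _act_grad(self, z: np.ndarray, a: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return (z > 0).astype(z.dtype)
        if self.activation == "tanh":
            return 1.0 - a ** 2
        return np.ones_like(z)

    def forward(self, x: np.ndarray, cache: bool = False):
        """Batch forward pass; returns output (and caches for backward)."""
        a = x
        zs, acts = [], [a]
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if i == n_layers - 1 else self._act(z)  # linear output
            if cache:
                zs.append(z)
                acts.append(a)
        return (a, zs, acts) if cache else a

    def backward(self, zs, acts, grad_out):
        """MSE-style output gradient -> per-parameter gradients."""
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = grad_out
        for i in range(len(self.weights) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) \
                    * self._act_grad(zs[i - 1], acts[i])
        return gW, gb

    def parameters(self):
        return self.weights + self.biases

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [p.copy() for p in params[:k]]
        self.biases = [p.copy() for p in params[k:]]


def build_network(spec: NetworkSpec, input_size: int, output_size: int,
                  seed: int = 0) -> MLP:
    """Untrained MLP: input -> hidden stack -> linear regression layer."""
    if input_size < 1 or output_size < 1:
        raise ValueError("sizes must be positive")
    sizes = [input_size] + [spec.nodes_per_layer] * spec.n_hidden_layers \
        + [output_size]
    return MLP(sizes, spec.activation, seed)


def parameter_count(spec: NetworkSpec, input_size: int,
                    output_size: int) -> int:
    """Closed-form trainable-parameter count of :func:`build_network`."""
    sizes = [input_size] + [spec.nodes_per_layer] * spec.n_hidden_layers \
        + [output_size]
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


@dataclass
class TrainedInverter:
    """Learned network plus everything needed to apply it."""

    spec: NetworkSpec
    model: MLP
    norm: NormStats
    history: dict                      # per-epoch train/val loss
    best_epoch: int
    grid_n: int

    def predict(self, x_raw: np.ndarray) -> np.ndarray:
        """Raw input vectors -> denormalized output vectors."""
        x = self.norm.normalize_inputs(np.atleast_2d(
            np.asarray(x_raw, dtype=float)))
        y = self.model.forward(x)
        return self.norm.denormalize_targets(y)


class TrainingDiverged(RuntimeError):
    pass


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(network: MLP, ds: Dataset, cfg: TrainConfig,
          norm: NormStats | None = None,
          select_best_epoch: bool = True,
          verbose: bool = False) -> TrainedInverter:
    """Seeded Adam/MSE training with per-epoch train/val history.

    Normalization statistics are fitted on the training split only (unless
    supplied).  The reference protocol trains a fixed number of epochs; in
    addition the parameters of the best validation epoch are checkpointed
    and restored by default.
    """
    Xtr_raw = ds.inputs[ds.train_idx].astype(float)
    Ytr_raw = ds.targets[ds.train_idx].astype(float)
    if norm is None:
        norm = compute_normalization(Xtr_raw, Ytr_raw)
    Xtr = norm.normalize_inputs(Xtr_raw)
    Ytr = norm.normalize_targets(Ytr_raw)
    Xva = norm.normalize_inputs(ds.inputs[ds.val_idx].astype(float))
    Yva = norm.normalize_targets(ds.targets[ds.val_idx].astype(float))

    rng = np.random.default_rng(cfg.seed)
    params = network.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None, -1)

    n_tr = len(Xtr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        losses = []
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            out, zs, acts = network.forward(xb, cache=True)
            loss = _mse(out, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}, "
                    f"step {start // cfg.batch_size}")
            losses.append(loss)
            grad_out = 2.0 * (out - yb) / out.size
            gW, gb = network.backward(zs, acts, grad_out)
            t += 1
            params = network.parameters()
            for p, g, mi, vi in zip(params, gW + gb, m, v):
                mi *= cfg.beta1
                mi += (1 - cfg.beta1) * g
                vi *= cfg.beta2
                vi += (1 - cfg.beta2) * g * g
                mhat = mi / (1 - cfg.beta1 ** t)
                vhat = vi / (1 - cfg.beta2 ** t)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat)
                                                 + cfg.adam_eps)
        val_loss = _mse(network.forward(Xva), Yva) if len(Xva) else np.nan
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if len(Xva) and val_loss < best[0]:
            best = (val_loss, network.copy_parameters(), epoch)
        if verbose:
            print(f"  epoch {epoch + 1}/{cfg.epochs}: "
                  f"train {history['train_loss'][-1]:.4e}, "
                  f"val {val_loss:.4e}")

    best_epoch = best[2] if best[1] is not None else cfg.epochs - 1
    if select_best_epoch and best[1] is not None:
        network.set_parameters(best[1])
    grid_n = int(round(np.sqrt(ds.targets.shape[1] // 2)))
    return TrainedInverter(spec=NetworkSpec(
        n_hidden_layers=len(network.sizes) - 2,
        nodes_per_layer=network.sizes[1],
        activation=network.activation),
        model=network, norm=norm, history=history,
        best_epoch=best_epoch, grid_n=grid_n)


def invert(model: TrainedInverter, s: ScatteringMatrix | np.ndarray,
           ) -> tuple[np.ndarray, np.ndarray]:
    """Scattering matrix -> (eps' map, sigma map); pure function of inputs."""
    x = vectorize_input(s)
    if x.size != model.model.sizes[0]:
        raise ValueError(
            f"input size {x.size} does not match network "
            f"input {model.model.sizes[0]}")
    y = model.predict(x)[0]
    return devectorize_output(y)


def architecture_sweep(ds: Dataset, node_list=None, layer_list=None,
                       base_spec: NetworkSpec = NetworkSpec(),
                       train_cfg: TrainConfig = TrainConfig(),
                       verbose: bool = False) -> list[dict]:
    """Train one model per architecture on identical data/seed and score it.

    Exactly one of ``node_list`` / ``layer_list`` is varied.  Each record
    carries the spec, held-out test MSE/NRMSE and the radial power spectrum
    S(nu) of the reconstructed complex-permittivity maps.
    """
    from dataclasses import replace as _replace

    from .metrics import mean_power_spectrum, radial_spectrum
    from .config import MeasurementConfig, complex_permittivity

    if (node_list is None) == (layer_list is None):
        raise ValueError("specify exactly one of node_list / layer_list")
    specs = []
    if node_list is not None:
        specs = [(_replace(base_spec, nodes_per_layer=int(k)), f"{k} nodes")
                 for k in node_list]
    else:
        specs = [(_replace(base_spec, n_hidden_layers=int(k)), f"{k} layers")
                 for k in layer_list]

    omega = MeasurementConfig().omega
    Xte = ds.inputs[ds.test_idx].astype(float)
    Yte = ds.targets[ds.test_idx].astype(float)
    records = []
    for spec, name in specs:
        net = build_network(spec, ds.inputs.shape[1], ds.targets.shape[1],
                            seed=train_cfg.seed)
        model = train(net, ds, train_cfg)
        pred = model.predict(Xte)
        mse = _mse(pred, Yte)
        nrmse = float(np.linalg.norm(pred - Yte) / np.linalg.norm(Yte))
        maps = []
        for row in pred:
            eps, sig = devectorize_output(row)
            maps.append(complex_permittivity(eps, sig, omega))
        spectrum = radial_spectrum(mean_power_spectrum(maps))
        records.append({"name": name, "spec": spec, "test_mse": mse,
                        "test_nrmse": nrmse, "radial_spectrum": spectrum,
                        "model": model})
        if verbose:
            print(f"  {name}: test MSE {mse:.4e}, NRMSE {nrmse:.4f}")
    return records


def save_model(model: TrainedInverter, path: str) -> None:
    """Weights to ``<path>.npz``, spec/normalization/history to JSON."""
    arrays = {f"W{i}": w for i, w in enumerate(model.model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.model.biases)})
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    sidecar = {
        "spec": asdict(model.spec),
        "sizes": model.model.sizes,
        "norm": model.norm.to_dict(),
        "history": model.history,
        "best_epoch": model.best_epoch,
        "grid_n": model.grid_n,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as f:
        json.dump(sidecar, f)


def load_model(path: str) -> TrainedInverter:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as f:
        sidecar = json.load(f)
    spec = NetworkSpec(**sidecar["spec"])
    net = MLP(sidecar["sizes"], spec.activation, seed=0)
    data = np.load(base + ".npz")
    net.weights = [data[f"W{i}"] for i in range(len(net.weights))]
    net.biases = [data[f"b{i}"] for i in range(len(net.biases))]
    return TrainedInverter(
        spec=spec, model=net, norm=NormStats.from_dict(sidecar["norm"]),
        history=sidecar["history"], best_epoch=sidecar["best_epoch"],
        grid_n=sidecar["grid_n"])
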