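"""Database construction for network training.

Each sample pairs the vectorized scattering matrix of one phantom (input)
with its vectorized dielectric maps (target):

* input ``x_in``: 2 M reals, M = n_antennas^2 — real parts of S in row-major
  (view, receiver) order, then imaginary parts;
* target ``x_out``: 2 N reals, N = n^2 — the eps' map row-major, then the
  sigma map.

Datasets are stored in HDF5 (``/inputs``, ``/targets``, ``/class``,
``/splits/{train,val,test}``, full config manifest in attributes) and split
85/10/5 by a seeded shuffle stratified by breast class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .config import ImagingGrid, MeasurementConfig
from .em_forward import (ConvergenceError, ScatteringMatrix, add_awgn,
                         assemble_scattering_matrix)
from .phantoms import BreastPhantom, GeneratorConfig, generate_phantom, \
    phantom_contrast

__all__ = [
    "DatasetSpec",
    "Dataset",
    "NormStats",
    "vectorize_input",
    "devectorize_input",
    "vectorize_output",
    "devectorize_output",
    "split_counts",
    "stratified_split",
    "build_dataset",
    "load_dataset",
    "compute_normalization",
]

CLASSES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class DatasetSpec:
    """Size, noise and seeding of a phantom/scattering database.

    The published protocol uses 30,000 phantoms per class (120,000 total) on
    the 108-pixel grid; the desk default keeps the same structure at a size
    a single CPU handles in minutes.
    """

    n_per_class: int = 500
    split_fractions: tuple[float, float, float] = (0.85, 0.10, 0.05)
    snr_db: float = 30.0
    master_seed: int = 0
    store_noiseless: bool = True
    solver_tol: float = 1e-6
    grid: ImagingGrid = field(default_factory=ImagingGrid)
    config: MeasurementConfig = field(default_factory=MeasurementConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-12:
            raise ValueError("split fractions must sum to 1")
        if self.n_per_class < 20:
            raise ValueError("need >= 20 samples per class so every split "
                             "is nonempty")

    @property
    def n_total(self) -> int:
        return self.n_per_class * len(CLASSES)


def vectorize_input(s: ScatteringMatrix | np.ndarray) -> np.ndarray:
    """Scattering matrix -> real vector [Re(S) row-major, Im(S) row-major]."""
    S = s.values if isinstance(s, ScatteringMatrix) else np.asarray(s)
    return np.concatenate([S.real.ravel(), S.imag.ravel()])


def devectorize_input(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_input`; returns the complex matrix."""
    m2 = x.size // 2
    n = int(round(np.sqrt(m2)))
    if 2 * n * n != x.size:
        raise ValueError("input vector length is not 2 * n_antennas^2")
    return (x[:m2] + 1j * x[m2:]).reshape(n, n)


def vectorize_output(phantom: BreastPhantom | tuple[np.ndarray, np.ndarray],
                     ) -> np.ndarray:
    """Dielectric maps -> real vector [eps' row-major, sigma row-major]."""
    if isinstance(phantom, BreastPhantom):
        eps, sigma = phantom.eps_map, phantom.sigma_map
    else:
        eps, sigma = phantom
    return np.concatenate([np.asarray(eps).ravel(),
                           np.asarray(sigma).ravel()])


def devectorize_output(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`vectorize_output`; returns (eps' map, sigma map)."""
    half = x.size // 2
    n = int(round(np.sqrt(half)))
    if 2 * n * n != x.size:
        raise ValueError("output vector length is not 2 * n^2")
    return x[:half].reshape(n, n), x[half:].reshape(n, n)


def split_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer split sizes by largest remainder; sums exactly to n."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def stratified_split(class_labels: np.ndarray,
                     fractions: tuple[float, float, float],
                     rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded class-stratified shuffle into train/val/test index arrays."""
    parts: list[list[np.ndarray]] = [[], [], []]
    for c in np.unique(class_labels):
        idx = np.flatnonzero(class_labels == c)
        rng.shuffle(idx)
        sizes = split_counts(len(idx), fractions)
        ofs = 0
        for k, sz in enumerate(sizes):
            parts[k].append(idx[ofs:ofs + sz])
            ofs += sz
    return tuple(np.sort(np.concatenate(p)) for p in parts)


@dataclass
class Dataset:
    """In-memory database: float32 matrices plus split index arrays."""

    inputs: np.ndarray              # (n_samples, 2 M)
    targets: np.ndarray             # (n_samples, 2 N)
    class_labels: np.ndarray        # int8 index into CLASSES
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    inputs_noiseless: np.ndarray | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]


def _manifest(spec: DatasetSpec) -> dict:
    man = asdict(spec)
    man["grid"] = {"side": spec.grid.side, "n": spec.grid.n}
    man["config"] = {
        "n_antennas": spec.config.n_antennas,
        "radius": spec.config.radius,
        "frequency": spec.config.frequency,
        "eps_b": [spec.config.background_rel_permittivity.real,
                  spec.config.background_rel_permittivity.imag],
        "source_amplitude": [complex(spec.config.source_amplitude).real,
                             complex(spec.config.source_amplitude).imag],
    }
    gen = asdict(spec.generator)
    gen["tissue_stats"] = {str(k): v for k, v in gen["tissue_stats"].items()}
    man["generator"] = gen
    # canonical JSON form so stored and in-memory manifests compare equal
    return json.loads(json.dumps(man))


def build_dataset(spec: DatasetSpec, out_path: str | None = None,
                  progress: bool = False) -> Dataset:
    """Generate phantoms, run the forward solver, add noise, split, store.

    Per-sample seeds derive from the master seed, so an identical spec
    reproduces the database bit for bit.  A sample whose forward solve does
    not converge is resampled with the next derived seed; more than 1%
    failures aborts.
    """
    rng = np.random.default_rng(spec.master_seed)
    seed_stream = iter(rng.integers(0, 2 ** 31 - 1,
                                    size=8 * spec.n_total).tolist())
    n_in = 2 * spec.config.n_antennas ** 2
    n_out = 2 * spec.grid.n_pixels
    inputs = np.empty((spec.n_total, n_in), dtype=np.float32)
    noiseless = np.empty_like(inputs) if spec.store_noiseless else None
    targets = np.empty((spec.n_total, n_out), dtype=np.float32)
    labels = np.empty(spec.n_total, dtype=np.int8)

    failures = 0
    i = 0
    for ci, cls in enumerate(CLASSES):
        for _ in range(spec.n_per_class):
            while True:
                seed = next(seed_stream)
                phantom = generate_phantom(spec.generator, cls, spec.grid,
                                           seed, spec.config)
                chi = phantom_contrast(phantom, spec.config)
                try:
                    s = assemble_scattering_matrix(
                        chi, spec.config, spec.grid, tol=spec.solver_tol)
                except ConvergenceError:
                    failures += 1
                    if failures > max(1, spec.n_total // 100):
                        raise
                    continue
                break
            if noiseless is not None:
                noiseless[i] = vectorize_input(s)
            noisy = add_awgn(s, spec.snr_db, seed=next(seed_stream))
            inputs[i] = vectorize_input(noisy)
            targets[i] = vectorize_output(phantom)
            labels[i] = ci
            i += 1
            if progress and i % 50 == 0:
                print(f"  built {i}/{spec.n_total} samples")

    split_rng = np.random.default_rng(
        np.random.default_rng(spec.master_seed + 1).integers(2 ** 31 - 1))
    tr, va, te = stratified_split(labels, spec.split_fractions, split_rng)
    ds = Dataset(inputs=inputs, targets=targets, class_labels=labels,
                 train_idx=tr, val_idx=va, test_idx=te,
                 inputs_noiseless=noiseless, manifest=_manifest(spec))
    if out_path is not None:
        save_dataset(ds, out_path)
    return ds


def save_dataset(ds: Dataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ds.inputs)
        f.create_dataset("targets", data=ds.targets)
        f.create_dataset("class", data=ds.class_labels)
        if ds.inputs_noiseless is not None:
            f.create_dataset("inputs_noiseless", data=ds.inputs_noiseless)
        g = f.create_group("splits")
        g.create_dataset("train", data=ds.train_idx.astype(np.int64))
        g.create_dataset("val", data=ds.val_idx.astype(np.int64))
        g.create_dataset("test", data=ds.test_idx.astype(np.int64))
        f.attrs["manifest"] = json.dumps(ds.manifest)


def load_dataset(path: str) -> Dataset:
    with h5py.File(path, "r") as f:
        return Dataset(
            inputs=f["inputs"][()],
            targets=f["targets"][()],
            class_labels=f["class"][()],
            train_idx=f["splits/train"][()],
            val_idx=f["splits/val"][()],
            test_idx=f["splits/test"][()],
            inputs_noiseless=(f["inputs_noiseless"][()]
                              if "inputs_noiseless" in f else None),
            manifest=json.loads(f.attrs.get("manifest", "{}")),
        )


@dataclass
class NormStats:
    """Feature scaling fitted on the training split only.

    Inputs are standardized per feature; each target block (eps' pixels,
    sigma pixels) is standardized by its global mean/std so the two
    channels contribute comparably to the MSE loss.
    """

    in_mean: np.ndarray
    in_std: np.ndarray
    out_block_mean: np.ndarray   # (2,)
    out_block_std: np.ndarray    # (2,)

    def normalize_inputs(self, x: np.ndarray) -> np.ndarray:
        return (x - self.in_mean) / self.in_std

    def normalize_targets(self, y: np.ndarray) -> np.ndarray:
        half = y.shape[-1] // 2
        out = np.empty_like(y, dtype=float)
        out[..., :half] = (y[..., :half] - self.out_block_mean[0]) \
            / self.out_block_std[0]
        out[..., half:] = (y[..., half:] - self.out_block_mean[1]) \
            / self.out_block_std[1]
        return out

    def denormalize_targets(self, y: np.ndarray) -> np.ndarray:
        half = y.shape[-1] // 2
        out = np.empty_like(y, dtype=float)
        out[..., :half] = y[..., :half] * self.out_block_std[0] \
            + self.out_block_mean[0]
        out[..., half:] = y[..., half:] * self.out_block_std[1] \
            + self.out_block_mean[1]
        return out

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


def compute_normalization(train_inputs: np.ndarray,
                          train_targets: np.ndarray,
                          eps: float = 1e-12) -> NormStats:
    """Fit :class:`NormStats` on training data (zero-variance std clamped)."""
    if len(train_inputs) == 0:
        raise ValueError("empty training set")
    in_mean = train_inputs.mean(axis=0)
    in_std = np.maximum(train_inputs.std(axis=0), eps)
    half = train_targets.shape[1] // 2
    blocks = [train_targets[:, :half], train_targets[:, half:]]
    return NormStats(
        in_mean=in_mean, in_std=in_std,
        out_block_mean=np.array([b.mean() for b in blocks]),
        out_block_std=np.array([max(float(b.std()), eps) for b in blocks]),
    )
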