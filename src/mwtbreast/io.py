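"""HDF5 / plain-text serialization of scattering matrices and phantoms."""

from __future__ import annotations

import h5py
import numpy as np

from .config import MeasurementConfig
from .em_forward import ScatteringMatrix
from .phantoms import BreastPhantom, Geometry

__all__ = [
    "save_scattering_matrix",
    "load_scattering_matrix",
    "scattering_matrix_to_csv",
    "save_phantom",
    "load_phantom",
]


def save_scattering_matrix(s: ScatteringMatrix, path: str,
                           config: MeasurementConfig) -> None:
    """Real/imag datasets plus measurement attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=s.values.real)
        f.create_dataset("imag", data=s.values.imag)
        f.attrs.update({
            "frequency": config.frequency,
            "radius": config.radius,
            "n_antennas": config.n_antennas,
            "eps_b_real": complex(config.background_rel_permittivity).real,
            "eps_b_imag": complex(config.background_rel_permittivity).imag,
            "snr_db": s.snr_db,
            "seed": -1 if s.noise_seed is None else s.noise_seed,
        })


def load_scattering_matrix(path: str) -> tuple[ScatteringMatrix, dict]:
    with h5py.File(path, "r") as f:
        values = f["real"][()] + 1j * f["imag"][()]
        attrs = dict(f.attrs)
    seed = int(attrs.get("seed", -1))
    s = ScatteringMatrix(values=values,
                         snr_db=float(attrs.get("snr_db", np.inf)),
                         noise_seed=None if seed < 0 else seed)
    return s, attrs


def scattering_matrix_to_csv(s: ScatteringMatrix, path: str) -> None:
    """Interoperability export: [Re(S) | Im(S)] side by side, one row per
    transmitting view."""
    np.savetxt(path, np.hstack([s.values.real, s.values.imag]),
               delimiter=",")


def save_phantom(phantom: BreastPhantom, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("tissue_map", data=phantom.tissue_map.astype("i1"))
        f.create_dataset("eps_map", data=phantom.eps_map.astype("f4"))
        f.create_dataset("sigma_map", data=phantom.sigma_map.astype("f4"))
        g = phantom.geometry
        f.attrs.update({
            "axis_a": g.axis_a, "axis_b": g.axis_b,
            "center_x": g.center[0], "center_y": g.center[1],
            "orientation": g.orientation,
            "skin_thickness": g.skin_thickness,
            "breast_class": phantom.breast_class,
            "seed": phantom.seed,
        })


def load_phantom(path: str) -> BreastPhantom:
    with h5py.File(path, "r") as f:
        a = dict(f.attrs)
        return BreastPhantom(
            tissue_map=f["tissue_map"][()],
            eps_map=f["eps_map"][()].astype(float),
            sigma_map=f["sigma_map"][()].astype(float),
            geometry=Geometry(
                axis_a=float(a["axis_a"]), axis_b=float(a["axis_b"]),
                center=(float(a["center_x"]), float(a["center_y"])),
                orientation=float(a["orientation"]),
                skin_thickness=float(a["skin_thickness"])),
            breast_class=str(a["breast_class"]),
            seed=int(a["seed"]),
        )
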