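"""CSV/YAML I/O for VTVH datasets, spectra and run configurations.

File conventions: VTVH tables carry columns wavelength_nm, B_T, T_K,
intensity and optionally sigma; spectra carry energy_cm1, intensity.
Energies are cm^-1 everywhere; wavelength <-> energy conversion is
E = 1e7 / lambda.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import Spectrum
from .fitting import VTVHDataset

__all__ = [
    "read_vtvh",
    "write_vtvh",
    "read_spectrum",
    "write_spectrum",
    "RunConfig",
]

logger = logging.getLogger("vtvhmcd")

_VTVH_COLUMNS = ["wavelength_nm", "B_T", "T_K", "intensity"]
_FLOAT_FMT = "%.10g"


def read_vtvh(path: str | Path) -> list[VTVHDataset]:
    """Read a VTVH CSV into one dataset per wavelength.

    Rows with non-positive temperature are rejected with their row numbers;
    when the sigma column is absent unit weights are recorded (sigma=None).
    """
    df = pd.read_csv(path)
    missing = [c for c in _VTVH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing VTVH columns: {missing}")
    for col in _VTVH_COLUMNS + (["sigma"] if "sigma" in df.columns else []):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")
    bad = df.index[df["T_K"] <= 0].tolist()
    if bad:
        rows = [i + 2 for i in bad]  # 1-based, plus header line
        raise ValueError(f"non-positive temperature in rows {rows}")
    has_sigma = "sigma" in df.columns
    has_tag = "site_tag" in df.columns
    datasets = []
    for wl, group in df.groupby("wavelength_nm", sort=True):
        datasets.append(
            VTVHDataset(
                wavelength_nm=float(wl),
                B=group["B_T"].to_numpy(),
                T=group["T_K"].to_numpy(),
                intensity=group["intensity"].to_numpy(),
                sigma=group["sigma"].to_numpy() if has_sigma else None,
                site_tag=str(group["site_tag"].iloc[0]) if has_tag else "total",
            )
        )
    return datasets


def write_vtvh(datasets: list[VTVHDataset], path: str | Path) -> None:
    """Write datasets to CSV (plus a JSON truth sidecar when present)."""
    frames = []
    any_sigma = any(ds.sigma is not None for ds in datasets)
    for ds in datasets:
        frame = pd.DataFrame(
            {
                "wavelength_nm": np.full(ds.n_points, ds.wavelength_nm),
                "B_T": ds.B,
                "T_K": ds.T,
                "intensity": ds.intensity,
            }
        )
        if any_sigma:
            frame["sigma"] = ds.sigma if ds.sigma is not None else np.ones(ds.n_points)
        frame["site_tag"] = ds.site_tag
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)
    truths = {str(ds.wavelength_nm): ds.truth for ds in datasets if ds.truth is not None}
    if truths:
        sidecar = Path(path).with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truths, indent=1, sort_keys=True))


def read_spectrum(path: str | Path, kind: str = "abs") -> Spectrum:
    """Read an energy/intensity CSV; sorts (with a warning) if unsorted."""
    df = pd.read_csv(path)
    for col in ("energy_cm1", "intensity"):
        if col not in df.columns:
            raise ValueError(f"missing spectrum column {col!r}")
    if len(df) == 0:
        raise ValueError("empty spectrum file")
    energies = df["energy_cm1"].to_numpy(dtype=float)
    if len(np.unique(energies)) != len(energies):
        raise ValueError("duplicate energies in spectrum")
    if np.any(np.diff(energies) < 0):
        logger.warning("spectrum %s is not sorted by energy; sorting", path)
        df = df.sort_values("energy_cm1")
        energies = df["energy_cm1"].to_numpy(dtype=float)
    return Spectrum(energies=energies, intensities=df["intensity"].to_numpy(dtype=float), kind=kind)


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"energy_cm1": spec.energies, "intensity": spec.intensities}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


_TASKS = ("simulate-vtvh", "fit-vtvh", "deconvolve", "predict-sign", "make-synthetic")


@dataclass
class RunConfig:
    """A complete, serializable description of one pipeline run."""

    task: str
    seed: int = 0
    out_dir: str = "."
    system: dict | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {_TASKS}")

    def to_dict(self) -> dict:
        d = {"task": self.task, "seed": self.seed, "out_dir": self.out_dir, "options": self.options}
        if self.system is not None:
            d["system"] = self.system
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"task", "seed", "out_dir", "system", "options"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            task=d["task"],
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", ".")),
            system=d.get("system"),
            options=dict(d.get("options", {})),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))
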