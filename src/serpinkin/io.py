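"""Readers and writers for the file formats the pipeline touches.

Canonical tabular input is long (tidy) CSV with columns ``sample``,
``condition``, ``x``, ``y``; the unit of the condition column (ramp rate in
degC/min for melt data, hold temperature in degC for kinetic data) is declared
once per file on a leading ``# condition_unit: <unit>`` comment line, or
passed explicitly.  Coordinate input is PDB only, read through gemmi.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd
import yaml

from .bfactor import ResidueBMap
from .errors import (
    ConfigError,
    EmptyStructureError,
    FormatError,
    UnitError,
)

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("sample", "condition", "x", "y")

#: condition units accepted per trace schema
SCHEMA_UNITS = {"melt": "C_per_min", "kinetic": "C"}


@dataclass
class TraceTable:
    """Grouped, x-sorted fluorescence traces in long format.

    ``data`` holds columns sample (str), condition (float), x (float),
    y (float); within each (sample, condition) group x is strictly
    increasing.  ``condition_unit`` is the declared unit of the condition
    column ("C_per_min" or "C").
    """

    data: pd.DataFrame
    condition_unit: str

    def groups(self) -> Iterator[tuple[tuple[str, float], pd.DataFrame]]:
        for key, sub in self.data.groupby(["sample", "condition"], sort=True):
            yield key, sub

    def trace(self, sample: str, condition: float) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[
            (self.data["sample"] == sample) & (self.data["condition"] == condition)
        ]
        if sub.empty:
            raise KeyError(f"no trace for sample={sample!r} condition={condition}")
        return sub["x"].to_numpy(), sub["y"].to_numpy()

    @property
    def n_groups(self) -> int:
        return self.data.groupby(["sample", "condition"]).ngroups


def _parse_unit_comments(path: Path) -> list[str]:
    units = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("condition_unit"):
                units.append(stripped.split(":", 1)[1].strip())
    return units


def read_trace_table(
    path,
    schema: str,
    condition_unit: str | None = None,
    min_points: int = 8,
) -> TraceTable:
    """Read a long-format trace CSV into a grouped, sorted :class:`TraceTable`.

    Duplicate x within a group are collapsed by mean; groups with fewer than
    ``min_points`` points (after collapsing) are rejected by name.
    """
    if schema not in SCHEMA_UNITS:
        raise ValueError(f"schema must be one of {sorted(SCHEMA_UNITS)}, got {schema!r}")
    path = Path(path)
    units = _parse_unit_comments(path)
    if len(set(units)) > 1:
        raise UnitError(f"mixed condition units declared in {path.name}: {sorted(set(units))}")
    if units:
        file_unit = units[0]
        if condition_unit is not None and condition_unit != file_unit:
            raise UnitError(
                f"condition unit {file_unit!r} in file contradicts {condition_unit!r}"
            )
        condition_unit = file_unit
    if condition_unit is None:
        raise UnitError(
            f"{path.name}: no condition-unit metadata row and none supplied"
        )

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    df = df[list(TRACE_COLUMNS)].copy()
    df["sample"] = df["sample"].astype(str)
    for col in ("condition", "x", "y"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df["x"].isna().any():
        raise FormatError(f"{path.name}: NaN in x column")

    # collapse duplicate x by mean, then sort within group
    df = (
        df.groupby(["sample", "condition", "x"], as_index=False, sort=True)["y"]
        .mean()
    )
    sizes = df.groupby(["sample", "condition"]).size()
    small = sizes[sizes < min_points]
    if not small.empty:
        names = ", ".join(f"{s}@{c}" for s, c in small.index)
        raise FormatError(
            f"{path.name}: group(s) with fewer than {min_points} points: {names}"
        )
    return TraceTable(data=df.reset_index(drop=True), condition_unit=condition_unit)


def write_trace_table(table: TraceTable, path) -> None:
    """Write a TraceTable to CSV at full float precision (round-trip exact)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# condition_unit: {table.condition_unit}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for row in table.data.itertuples(index=False):
            fh.write(f"{row.sample},{row.condition!r},{row.x!r},{row.y!r}\n")


@dataclass
class SpectrumRecord:
    """An emission spectrum: wavelength (nm, strictly increasing) vs intensity."""

    wavelength: np.ndarray
    intensity: np.ndarray
    n_clipped: int = 0  # negative intensities clipped to zero on load

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.size < 3:
            raise FormatError(f"spectrum needs >= 3 points, got {self.wavelength.size}")
        if np.ptp(self.wavelength) <= 0 or np.any(np.diff(self.wavelength) <= 0):
            raise FormatError("wavelengths must be strictly increasing with positive span")
        if np.any(self.intensity < 0):
            raise FormatError("negative intensity in SpectrumRecord")


def read_spectrum(path) -> SpectrumRecord:
    """Read a two-column (wavelength, intensity) CSV; sort by wavelength and
    clip negative intensities to zero (counted, logged)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: expected two columns (wavelength, intensity)")
    wl = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy()
    inten = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    if wl.size < 3:
        raise FormatError(f"{path.name}: spectrum needs >= 3 points, got {wl.size}")
    order = np.argsort(wl, kind="stable")
    wl, inten = wl[order], inten[order]
    n_clipped = int((inten < 0).sum())
    if n_clipped:
        logger.warning("%s: clipped %d negative intensities to 0", path.name, n_clipped)
        inten = np.clip(inten, 0.0, None)
    return SpectrumRecord(wl, inten, n_clipped=n_clipped)


def read_structure_b(path, selection: str = "all_heavy") -> ResidueBMap:
    """Per-residue mean B-factor from a PDB file.

    Uses the first model only; waters and hetero groups are excluded; among
    alternate conformers of an atom, only the highest-occupancy one
    contributes.  ``selection`` is ``all_heavy`` (non-hydrogen atoms) or
    ``calpha``.
    """
    if selection not in ("all_heavy", "calpha"):
        raise ValueError(f"selection must be 'all_heavy' or 'calpha', got {selection!r}")
    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path.name}: cannot parse PDB: {exc}") from exc
    if len(structure) == 0:
        raise EmptyStructureError(f"{path.name}: no models")
    model = structure[0]
    values: dict[tuple, float] = {}
    for chain in model:
        for residue in chain:
            if residue.is_water() or residue.het_flag != "A":
                continue
            # pick highest-occupancy conformer per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                if selection == "calpha" and atom.name != "CA":
                    continue
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            if not by_name:
                continue
            key = (chain.name, residue.seqid.num, residue.seqid.icode.strip() or "")
            values[key] = float(np.mean([a.b_iso for a in by_name.values()]))
    if not values:
        raise EmptyStructureError(f"{path.name}: no protein atoms found")
    return ResidueBMap(values=dict(sorted(values.items())), lineage="raw",
                       sources=(path.stem,))


_CONFIG_FIELDS = {
    "fit_window": None,        # (lo_C, hi_C) or None for auto
    "tref_c": 54.8,            # reference temperature for half-time comparison
    "normalization": "znorm",  # b-factor scheme: znorm | minmax | mean_relative
    "seed": None,
    "out_dir": ".",
}


@dataclass
class RunConfig:
    """Validated run settings; unknown keys are rejected at load time."""

    fit_window: tuple[float, float] | None = None
    tref_c: float = 54.8
    normalization: str = "znorm"
    seed: int | None = None
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.fit_window is not None:
            cfg.fit_window = tuple(float(v) for v in cfg.fit_window)  # type: ignore[assignment]
        cfg.out_dir = str(Path(cfg.out_dir).resolve())
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_ramp_tm() -> pd.DataFrame:
    """Packaged (variant, ramp rate, Tm) table for the two AAT variants.

    Columns: variant, v_C_per_min, tm_C, tm_se_C.  Observed DSF thermal
    midpoints at ramp rates 0.5, 1, 2 and 4 degC/min.
    """
    from importlib.resources import files

    with (files("serpinkin") / "data" / "ramp_tm.csv").open() as fh:
        return pd.read_csv(fh)
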