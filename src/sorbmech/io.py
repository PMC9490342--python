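"""File round-trips: extended XYZ configurations, CSV tables, JSON
summaries, YAML run configs, and the packaged reference tables.

Configurations are written as extended XYZ (species column, per-frame
``Lattice=...`` box in the comment line) with the bonded topology in a
JSON sidecar.  Tables carry unit-annotated column names; loaders check
them and fail naming the offending column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sorption import GABParams, SorptionIsotherm
from .system import SystemConfiguration

__all__ = [
    "write_extxyz",
    "read_extxyz",
    "write_topology",
    "read_topology",
    "load_table1",
    "load_table2",
    "table1_isotherm",
    "write_isotherm",
    "read_isotherm",
    "write_curve",
    "read_curve",
    "write_gab_params",
    "read_gab_params",
    "RunConfig",
    "config_hash",
]

_FLOAT_FMT = "%.10f"  # lossless round trip to the stated 1e-8 precision


# ----------------------------------------------------------------------
# extended XYZ
# ----------------------------------------------------------------------
def write_extxyz(path, configs) -> None:
    """Write one or more configurations as extended-XYZ frames."""
    if isinstance(configs, SystemConfiguration):
        configs = [configs]
    with open(path, "w") as fh:
        for conf in configs:
            lat = (
                f"{conf.box[0]:.10f} 0.0 0.0 "
                f"0.0 {conf.box[1]:.10f} 0.0 "
                f"0.0 0.0 {conf.box[2]:.10f}"
            )
            pbc = " ".join("T" if p else "F" for p in conf.periodic)
            fh.write(f"{conf.n_particles}\n")
            fh.write(
                f'Lattice="{lat}" Properties=species:S:1:pos:R:3 pbc="{pbc}"\n'
            )
            for sp, (x, y, z) in zip(conf.species, conf.positions):
                fh.write(f"{sp} {x:.10f} {y:.10f} {z:.10f}\n")


def read_extxyz(path) -> list[SystemConfiguration]:
    """Read extended-XYZ frames; malformed frames fail with a line number."""
    frames: list[SystemConfiguration] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i + 1}: expected particle count, got "
                f"{lines[i].strip()!r}"
            ) from exc
        if i + 1 >= len(lines):
            raise ValueError(f"{path}:{i + 1}: missing comment line")
        comment = lines[i + 1]
        if "Lattice=" not in comment:
            raise ValueError(
                f"{path}:{i + 2}: frame comment lacks the Lattice box entry"
            )
        lat_str = comment.split('Lattice="', 1)[1].split('"', 1)[0]
        lat = np.array([float(v) for v in lat_str.split()]).reshape(3, 3)
        box = np.diag(lat)
        periodic = np.ones(3, dtype=bool)
        if 'pbc="' in comment:
            pbc_str = comment.split('pbc="', 1)[1].split('"', 1)[0]
            periodic = np.array([t == "T" for t in pbc_str.split()])
        species, pos = [], []
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ValueError(f"{path}:{ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{ln + 1}: expected 'species x y z', got "
                    f"{lines[ln].strip()!r}"
                )
            species.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
        frames.append(
            SystemConfiguration(
                positions=np.array(pos).reshape(-1, 3),
                species=np.array(species, dtype=object),
                bonds=np.empty((0, 2), dtype=np.intp),
                crosslinks=np.empty((0, 2), dtype=np.intp),
                box=box,
                periodic=periodic,
            )
        )
        i += 2 + n
    return frames


def write_topology(path, config: SystemConfiguration) -> None:
    """JSON sidecar with bonds, cross-links and cys site indices."""
    payload = {
        "bonds": config.bonds.tolist(),
        "crosslinks": config.crosslinks.tolist(),
        "cys_indices": config.metadata.get("cys_indices", []),
    }
    Path(path).write_text(json.dumps(payload))


def read_topology(path, config: SystemConfiguration) -> SystemConfiguration:
    """Attach a topology sidecar to a configuration read from XYZ."""
    payload = json.loads(Path(path).read_text())
    config.bonds = np.array(payload["bonds"], dtype=np.intp).reshape(-1, 2)
    config.crosslinks = np.array(
        payload["crosslinks"], dtype=np.intp
    ).reshape(-1, 2)
    config.metadata["cys_indices"] = payload.get("cys_indices", [])
    config.validate()
    return config


# ----------------------------------------------------------------------
# packaged reference tables
# ----------------------------------------------------------------------
_T1_COLS = [
    "rh_percent",
    "solubility_g_per_100g_keratin",
    "number_density_per_nm3",
    "water_per_residue",
    "vol_percent_water",
]
_T2_COLS = [
    "rh_percent",
    "youngs_modulus_gpa",
    "yield_stress_mpa",
    "yield_strain",
    "failure_stress_mpa",
    "failure_strain",
    "poisson_ratio",
]


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    for col in expected:
        if col not in df.columns:
            raise ValueError(
                f"{what}: missing or unit-mismatched column {col!r} "
                f"(found {list(df.columns)})"
            )


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("sorbmech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1(path=None) -> pd.DataFrame:
    """RH vs solubility/number-density/per-residue/volume-percent table."""
    df = pd.read_csv(path) if path is not None else _packaged("table1.csv")
    _check_columns(df, _T1_COLS, "sorption table")
    return df


def load_table2(path=None) -> pd.DataFrame:
    """RH vs mechanical-properties table."""
    df = pd.read_csv(path) if path is not None else _packaged("table2.csv")
    _check_columns(df, _T2_COLS, "mechanics table")
    return df


def table1_isotherm(path=None) -> SorptionIsotherm:
    """The packaged sorption table as an isotherm (activities 0-1)."""
    df = load_table1(path)
    return SorptionIsotherm(
        activity=df["rh_percent"].to_numpy() / 100.0,
        content=df["solubility_g_per_100g_keratin"].to_numpy(),
    )


# ----------------------------------------------------------------------
# isotherms / curves / fits
# ----------------------------------------------------------------------
_ISO_COLS = ["activity", "content_g_per_100g", "error_g_per_100g"]


def write_isotherm(path, iso: SorptionIsotherm) -> None:
    pd.DataFrame(
        {
            "activity": iso.activity,
            "content_g_per_100g": iso.content,
            "error_g_per_100g": iso.error,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_isotherm(path) -> SorptionIsotherm:
    df = pd.read_csv(path)
    _check_columns(df, _ISO_COLS, "isotherm file")
    return SorptionIsotherm(
        activity=df["activity"].to_numpy(),
        content=df["content_g_per_100g"].to_numpy(),
        error=df["error_g_per_100g"].to_numpy(),
    )


_CURVE_COLS = ["strain", "stress", "l_perp"]


def write_curve(path, curve) -> None:
    lp = curve.l_perp if curve.l_perp is not None else np.full_like(
        curve.strain, np.nan
    )
    pd.DataFrame(
        {"strain": curve.strain, "stress": curve.stress, "l_perp": lp}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curve(path):
    from .mechanics import StressStrainCurve

    df = pd.read_csv(path)
    _check_columns(df, _CURVE_COLS, "stress-strain file")
    lp = df["l_perp"].to_numpy()
    return StressStrainCurve(
        strain=df["strain"].to_numpy(),
        stress=df["stress"].to_numpy(),
        l_perp=None if np.all(np.isnan(lp)) else lp,
    )


def write_gab_params(path, params: GABParams) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "cm_g_per_100g": params.cm,
                "k": params.k,
                "b": params.b,
                "dh_kj_mol": params.dh,
                "diagnostics": params.diagnostics,
            },
            indent=2,
        )
    )


def read_gab_params(path) -> GABParams:
    d = json.loads(Path(path).read_text())
    return GABParams(
        cm=d["cm_g_per_100g"], k=d["k"], b=d["b"], dh=d.get("dh_kj_mol"),
        diagnostics=d.get("diagnostics", {}),
    )


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------
_RUNCONFIG_KEYS = {"stage", "paths", "physical", "numerics", "units"}


@dataclass
class RunConfig:
    """One pipeline stage's configuration.

    Blocks: ``paths`` (inputs/outputs), ``physical`` (T, P, mu targets,
    RH list), ``numerics`` (dt, steps, seeds, cutoffs, grid spacings)
    and ``units`` (reduced-to-physical conversion constants).  Every
    stochastic stage must carry an explicit seed in ``numerics``.
    """

    stage: str
    paths: dict = field(default_factory=dict)
    physical: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stage" not in raw:
            raise ValueError("config lacks the 'stage' key")
        cfg = cls(**raw)
        if "seed" not in cfg.numerics:
            raise ValueError("numerics block must carry an explicit seed")
        return cfg

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "paths": self.paths,
            "physical": self.physical,
            "numerics": self.numerics,
            "units": self.units,
        }


def config_hash(obj) -> str:
    """Stable short hash of a config mapping (for output provenance)."""
    if isinstance(obj, RunConfig):
        obj = obj.to_dict()
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
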