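"""Flat key-value run configuration ([system]/[forcefield]/[shear]/[output]).

A config file fully determines a run; together with the seed it is the
reproducibility unit.  The bundled ``published_defaults`` profile is the
published full-scale parameterization (cubic box 30 rc, density 3, chains
3-head + variable tails, the standard repulsion matrix).
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .builder import SystemSpec
from .forcefield import (
    SPECIES_INDEX,
    ForceFieldParams,
    InteractionMatrix,
    default_forcefield,
    lipid_type_I,
    lipid_type_II,
    validate,
)
from .shear import ShearProtocol


class ConfigError(ValueError):
    """Invalid or missing configuration field; the message names the field."""


@dataclass(frozen=True)
class OutputOptions:
    steps: int = 10000
    sample_every: int = 100
    frame_every: int = 1000
    trajectory_format: str = "xyz"  # or "lammps"
    directory: str = "runs"


@dataclass(frozen=True)
class RunConfig:
    system: SystemSpec
    forcefield: ForceFieldParams
    shear: ShearProtocol | None
    output: OutputOptions

    def digest(self) -> str:
        """Stable short hash of the resolved configuration."""
        payload = json.dumps(
            {
                "system": {
                    "box": self.system.box_length,
                    "density": self.system.density,
                    "n_lipids": self.system.n_lipids,
                    "lipid_I": (self.system.lipid_I.n_head, self.system.lipid_I.n_tail),
                    "lipid_II": (self.system.lipid_II.n_head, self.system.lipid_II.n_tail),
                    "split": self.system.split,
                    "seed": self.system.seed,
                },
                "ff": {
                    "gamma": self.forcefield.gamma,
                    "sigma": self.forcefield.sigma,
                    "dt": self.forcefield.dt,
                    "a": self.forcefield.aij.a.tolist(),
                },
                "shear": None if self.shear is None else self.shear.swap_every,
                "steps": self.output.steps,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


PUBLISHED_DEFAULTS = """\
[system]
box_length = 30
density = 3
n_lipids = 2400
nh1 = 3
nt1 = 2
nh2 = 3
nt2 = 4
split = 0.5
seed = 0

[forcefield]
profile = published_defaults

[shear]
preset = none

[output]
steps = 300000
sample_every = 100
frame_every = 10000
format = xyz
directory = runs
"""


def _get(section, key, cast, where, default=None, required=False):
    if key not in section:
        if required:
            raise ConfigError(f"missing required field {where}.{key}")
        return default
    try:
        return cast(section[key])
    except ValueError as exc:
        raise ConfigError(f"bad value for {where}.{key}: {section[key]!r}") from exc


def parse_config(text: str) -> RunConfig:
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    parser.read_string(text)
    if "system" not in parser:
        raise ConfigError("missing [system] section")
    sysec = parser["system"]
    seed = _get(sysec, "seed", int, "system", required=True)
    spec = SystemSpec(
        box_length=_get(sysec, "box_length", float, "system", 30.0),
        density=_get(sysec, "density", float, "system", 3.0),
        n_lipids=_get(sysec, "n_lipids", int, "system", 0),
        lipid_I=lipid_type_I(
            n_tail=_get(sysec, "nt1", int, "system", 2),
            n_head=_get(sysec, "nh1", int, "system", 3),
        ),
        lipid_II=lipid_type_II(
            n_tail=_get(sysec, "nt2", int, "system", 4),
            n_head=_get(sysec, "nh2", int, "system", 3),
        ),
        split=_get(sysec, "split", float, "system", 0.5),
        seed=seed,
    )

    ff = default_forcefield()
    if "forcefield" in parser:
        ffsec = parser["forcefield"]
        overrides = {}
        for key in ("gamma", "sigma", "kBT", "rc", "ks", "rs", "ktheta", "theta0", "dt"):
            if key in ffsec:
                overrides[key] = _get(ffsec, key, float, "forcefield")
        a = ff.aij.a.copy()
        for key in ffsec:
            if key.startswith("a_"):
                _, s1, s2 = key.split("_")
                i, j = SPECIES_INDEX[s1.upper()], SPECIES_INDEX[s2.upper()]
                a[i, j] = a[j, i] = float(ffsec[key])
                overrides["aij"] = InteractionMatrix(a)
        if overrides:
            ff = ff.replace(**overrides)
    problems = validate(ff)
    if problems:
        raise ConfigError("forcefield invalid: " + "; ".join(problems))

    shear = None
    if "shear" in parser:
        shsec = parser["shear"]
        preset = _get(shsec, "preset", str, "shear", "none").strip().lower()
        n_slabs = _get(shsec, "n_slabs", int, "shear", 20)
        geometry = _get(shsec, "geometry", str, "shear", "edges")
        if preset in ("weak", "strong"):
            shear = ShearProtocol(
                swap_every=6 if preset == "weak" else 1, n_slabs=n_slabs, geometry=geometry
            )
        elif preset in ("none", "zero"):
            if "swap_every" in shsec:
                shear = ShearProtocol(
                    swap_every=_get(shsec, "swap_every", int, "shear"),
                    n_slabs=n_slabs,
                    geometry=geometry,
                )
        else:
            raise ConfigError(f"unknown shear.preset {preset!r}")

    out = OutputOptions()
    if "output" in parser:
        osec = parser["output"]
        fmt = _get(osec, "format", str, "output", "xyz").strip().lower()
        if fmt not in ("xyz", "lammps"):
            raise ConfigError(f"unknown output.format {fmt!r}")
        out = OutputOptions(
            steps=_get(osec, "steps", int, "output", 10000),
            sample_every=_get(osec, "sample_every", int, "output", 100),
            frame_every=_get(osec, "frame_every", int, "output", 1000),
            trajectory_format=fmt,
            directory=_get(osec, "directory", str, "output", "runs"),
        )
    return RunConfig(spec, ff, shear, out)


def load_config(path: str | Path) -> RunConfig:
    return parse_config(Path(path).read_text())
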