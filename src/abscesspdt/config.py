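"""Sweep configuration files and run manifests.

A sweep config (YAML or JSON) lists phantom specs and/or mask paths, the
explicit optical-coefficient value lists (or the equivalent MB / Intralipid
concentration lists, converted through the optics module), dose-target
overrides, photon count, and a master seed.  Value lists are explicit —
never range strings — so the enumerated grid is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .geometry import PhantomSpec
from .optics import intralipid_to_mus, mb_to_mua
from .planner import CASE2_MODES, DoseTargets
from .provenance import config_hash

__all__ = ["SweepConfig", "RunManifest", "load_config"]

MIN_PLANNING_PHOTONS = 1000


@dataclass
class SweepConfig:
    """Parsed sweep configuration (coefficients in cm^-1, cm, mW)."""

    phantoms: list[PhantomSpec] = field(default_factory=list)
    mask_paths: list[str] = field(default_factory=list)
    mua_wall: list[float] = field(default_factory=lambda: [0.2])
    mus_cavity: list[float] = field(default_factory=lambda: [0.0])
    mua_cavity: list[float] = field(default_factory=lambda: [0.0])
    targets: DoseTargets = field(default_factory=DoseTargets)
    n_photons: int = 100_000
    seed: int = 0
    modes: tuple[str, ...] = CASE2_MODES
    cases: tuple[int, ...] = (1,)
    save_maps: bool = False

    def __post_init__(self) -> None:
        if not self.phantoms and not self.mask_paths:
            raise ValueError("config must list at least one phantom spec or mask path")
        for name in ("mua_wall", "mus_cavity", "mua_cavity"):
            if not getattr(self, name):
                raise ValueError(f"value list {name} must be non-empty")
        for p in self.mask_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"mask path not found: {p}")
        for m in self.modes:
            if m not in CASE2_MODES:
                raise ValueError(f"unknown planning mode {m!r}")
        if any(c not in (1, 2) for c in self.cases):
            raise ValueError("cases must be a subset of {1, 2}")
        if self.n_photons < MIN_PLANNING_PHOTONS:
            import warnings

            warnings.warn(
                f"n_photons={self.n_photons} is below {MIN_PLANNING_PHOTONS}; "
                "planning quantiles will be noisy"
            )

    def to_dict(self) -> dict:
        d = {
            "phantoms": [p.to_dict() for p in self.phantoms],
            "mask_paths": list(self.mask_paths),
            "mua_wall": list(self.mua_wall),
            "mus_cavity": list(self.mus_cavity),
            "mua_cavity": list(self.mua_cavity),
            "targets": asdict(self.targets),
            "n_photons": self.n_photons,
            "seed": self.seed,
            "modes": list(self.modes),
            "cases": list(self.cases),
            "save_maps": self.save_maps,
        }
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def load_config(path) -> SweepConfig:
    """Read a YAML/JSON sweep config.

    Concentration lists ``mb_cavity_um`` and ``intralipid_pct`` are accepted
    in place of (or in addition to) the coefficient lists and converted
    through the 665-nm chromophore maps.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")

    kwargs: dict = {}
    if "phantoms" in raw:
        kwargs["phantoms"] = [PhantomSpec.from_dict(d) for d in raw["phantoms"]]
    if "mask_paths" in raw:
        kwargs["mask_paths"] = [str(p) for p in raw["mask_paths"]]
    if "intralipid_pct" in raw:
        kwargs["mus_cavity"] = [float(intralipid_to_mus(c)) for c in raw["intralipid_pct"]]
    if "mus_cavity" in raw:
        kwargs["mus_cavity"] = [float(v) for v in raw["mus_cavity"]]
    if "mb_cavity_um" in raw:
        kwargs["mua_cavity"] = [float(mb_to_mua(c)) for c in raw["mb_cavity_um"]]
    if "mua_cavity" in raw:
        kwargs["mua_cavity"] = [float(v) for v in raw["mua_cavity"]]
    if "mua_wall" in raw:
        kwargs["mua_wall"] = [float(v) for v in raw["mua_wall"]]
    if "targets" in raw:
        kwargs["targets"] = DoseTargets(**raw["targets"])
    for key in ("n_photons", "seed", "save_maps"):
        if key in raw:
            kwargs[key] = raw[key]
    if "modes" in raw:
        kwargs["modes"] = tuple(raw["modes"])
    if "cases" in raw:
        kwargs["cases"] = tuple(int(c) for c in raw["cases"])
    return SweepConfig(**kwargs)


@dataclass
class RunManifest:
    """Provenance record for a sweep run, written as JSON next to the outputs."""

    config_hash: str
    master_seed: int
    version: str
    tasks: dict = field(default_factory=dict)  # task key -> {seed, status, outputs}

    def record(self, key: str, seed: int, status: str, outputs: list[str]) -> None:
        self.tasks[key] = {"seed": seed, "status": status, "outputs": outputs}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "master_seed": self.master_seed,
                    "version": self.version,
                    "tasks": self.tasks,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config_hash"], d["master_seed"], d["version"], d["tasks"])
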