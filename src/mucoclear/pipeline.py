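"""End-to-end scenario orchestration: domain -> flow -> spray -> deposition
-> clearance -> absorption, with reproducible seeding and a file manifest.

A scenario is fully described by a :class:`ScenarioConfig`; running it twice
with the same seed produces byte-identical outputs.  A single global seed is
expanded into per-stage child seeds so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mucoclear
from mucoclear import absorption as absorption_mod
from mucoclear import clearance as clearance_mod
from mucoclear import deposition as deposition_mod
from mucoclear import domain as domain_mod
from mucoclear import mucus_flow as flow_mod
from mucoclear import spray as spray_mod
from mucoclear.absorption import DiffusionConstants, GelLayer, SoluteSpec
from mucoclear.domain import DomainConfig
from mucoclear.mucus_flow import MucusProperties
from mucoclear.spray import SprayConfig

__all__ = ["ScenarioConfig", "run_scenario", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class ScenarioConfig:
    """All module configurations plus the global seed and horizon policy."""

    domain: DomainConfig = field(default_factory=DomainConfig)
    mucus: MucusProperties = field(default_factory=MucusProperties)
    spray: SprayConfig = field(default_factory=SprayConfig)
    gel: GelLayer = field(default_factory=GelLayer)
    constants: DiffusionConstants = field(default_factory=DiffusionConstants)
    solute: SoluteSpec = field(default_factory=lambda: SoluteSpec(radius_nm=50.0))
    seed: int = 0
    ostium_source_fraction: float = 0.6
    swirl_enabled: bool = True
    swirl_peak_mm_min: float = 2.5
    dt_s: float = 2.0
    horizon_s: float = 14400.0  # absorption runs: until cleared, capped at 4 h
    snapshot_times_s: tuple[float, ...] = (0.0, 60.0, 300.0, 600.0, 900.0, 1800.0)
    sweep_radii_nm: tuple[float, ...] = tuple(float(r) for r in range(1, 111))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        sub = {
            "domain": DomainConfig,
            "mucus": MucusProperties,
            "spray": SprayConfig,
            "gel": GelLayer,
            "constants": DiffusionConstants,
            "solute": SoluteSpec,
        }
        for key, val in raw.items():
            if key in sub:
                if key == "domain" and "areas_cm2" in val:
                    val = dict(val)
                    val["areas_cm2"] = {
                        k: tuple(v) for k, v in val["areas_cm2"].items()
                    }
                kwargs[key] = sub[key](**val)
            elif key in ("snapshot_times_s", "sweep_radii_nm"):
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return enc(dataclasses.asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def child_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_scenario(config: ScenarioConfig, outdir: str | Path) -> dict:
    """Run the full pipeline and write all outputs plus a JSON manifest.

    Returns the manifest dict.  Any stage failure raises ``PipelineError``
    naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    domain = stage("domain", lambda: domain_mod.build_synthetic_domain(config.domain))
    outputs["domain"] = outdir / "domain.csv"
    domain_mod.write_domain_csv(domain, outputs["domain"])
    domain_mod.region_area_table(domain).to_csv(outdir / "region_table.csv", index=False)
    outputs["region_table"] = outdir / "region_table.csv"

    def solve():
        layout = flow_mod.default_source_layout(domain, config.ostium_source_fraction)
        swirl = (
            flow_mod.default_swirl(domain, config.swirl_peak_mm_min)
            if config.swirl_enabled
            else None
        )
        return flow_mod.solve_mucus_field(domain, config.mucus, layout, swirl=swirl)

    fld = stage("flow", solve)
    outputs["field"] = outdir / "field.csv"
    flow_mod.write_field_csv(fld, outputs["field"])

    population = stage("spray", lambda: spray_mod.build_droplet_population(config.spray))
    outputs["population"] = outdir / "population.csv"
    spray_mod.write_population_csv(population, outputs["population"])

    deposited = stage(
        "deposition",
        lambda: deposition_mod.generate_deposition(
            population, domain, seed=config.child_seed("deposition")
        ),
    )
    outputs["deposition"] = outdir / "deposition.csv"
    deposition_mod.write_deposition_csv(deposited, outputs["deposition"])
    split = deposition_mod.group_mass_fractions(deposited, domain)
    (outdir / "deposition_split.json").write_text(
        json.dumps({k: round(v, 4) for k, v in split.items()}, indent=2)
    )
    outputs["deposition_split"] = outdir / "deposition_split.json"

    clearance = stage(
        "clearance",
        lambda: clearance_mod.advect_particles(
            deposited.x_mm,
            deposited.y_mm,
            fld,
            dt_s=config.dt_s,
            horizon_s=config.horizon_s,
            snapshot_times_s=config.snapshot_times_s,
        ),
    )
    outputs["passages"] = outdir / "passages.csv"
    clearance_mod.write_passage_csv(clearance, outputs["passages"])

    def absorb():
        if len(deposited) == 0:
            return pd.DataFrame(
                columns=["r_s_nm", "d_g_m2_s", "total_pct", "lost_vestibule_pct",
                         "cleared_unabsorbed_pct", "residual_pct"]
            )
        return absorption_mod.absorption_radius_sweep(
            clearance,
            deposited.mass_kg,
            config.sweep_radii_nm,
            gel=config.gel,
            constants=config.constants,
            regions=domain.regions,
            alpha=config.solute.mass_fraction,
        )

    sweep = stage("absorption", absorb)
    outputs["sweep"] = outdir / "sweep.csv"
    sweep.to_csv(outputs["sweep"], index=False)
    if len(sweep):
        row = sweep.iloc[(sweep["r_s_nm"] - config.solute.radius_nm).abs().argmin()]
        summary = {
            "solute_radius_nm": float(row["r_s_nm"]),
            "total_absorbed_pct": float(row["total_pct"]),
            "lost_vestibule_pct": float(row["lost_vestibule_pct"]),
            "cleared_unabsorbed_pct": float(row["cleared_unabsorbed_pct"]),
            "residual_pct": float(row["residual_pct"]),
        }
    else:
        summary = {"solute_radius_nm": config.solute.radius_nm, "total_absorbed_pct": 0.0}
    (outdir / "absorption_summary.json").write_text(json.dumps(summary, indent=2))
    outputs["absorption_summary"] = outdir / "absorption_summary.json"

    manifest = {
        "package": "mucoclear",
        "version": mucoclear.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            name: {"path": p.name, "sha256": _sha256(p)} for name, p in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
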