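"""Study-replication driver: sweeps over (Wi, P), manifests, aggregation.

The production study maps friction over Wi in [1e-4, 1] and P in
{0.14, 0.21, 0.28} in a 60^3 box; the default desk profile runs the same
protocol at reduced scale (see docs/methods.md for the sizes and what they
do and do not resolve).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ShearCellConfig
from .characterize import MaterialProps
from .io import RunManifest, read_lammps_data
from .shear import Fn_from_P, V_from_Wi, run_shear

__all__ = ["SweepSpec", "run_sweep", "read_geometry"]


@dataclass
class SweepSpec:
    """Grid of a friction sweep.

    ``scale`` is the box edge relative to the production edge of 60; the
    desk default 1/3 gives a 20^3 cell.
    """

    Wi_grid: tuple = (1e-3, 1e-1, 1.0)
    P_grid: tuple = (0.14, 0.28)
    replicates: int = 1
    scale: float = 1.0 / 3.0
    equilibration_steps: int = 15_000
    production_steps: int = 25_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.Wi_grid or not self.P_grid:
            raise ValueError("empty sweep grid")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def box_edge(self) -> float:
        return 60.0 * self.scale


def run_sweep(spec: SweepSpec, base: ShearCellConfig | None = None,
              props: MaterialProps | None = None,
              out_dir: str | Path | None = None):
    """One run per (Wi, P, replicate) with independent seeds.

    Returns ``(records, table, manifests)``; failures are flagged in the
    table, never silently dropped.  Deterministic for a given spec seed.
    """
    props = props or MaterialProps.reference()
    base = base or ShearCellConfig()
    L = spec.box_edge
    rows = []
    records = []
    manifests = []
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s) for s in ss.generate_state(
        len(spec.Wi_grid) * len(spec.P_grid) * spec.replicates) >> 1]
    k = 0
    for P in spec.P_grid:
        for Wi in spec.Wi_grid:
            for rep in range(spec.replicates):
                seed = seeds[k]
                k += 1
                net = dataclasses.replace(base.network, box=(L, L, L),
                                          seed=seed)
                cfg = dataclasses.replace(
                    base, network=net, P=P, Wi=Wi, seed=seed,
                    equilibration_steps=spec.equilibration_steps,
                    production_steps=spec.production_steps,
                    walls=dataclasses.replace(
                        base.walls,
                        V=V_from_Wi(Wi, props, base.dpd.kBT),
                        F_n=Fn_from_P(P, props, L * L)))
                status = "ok"
                try:
                    rec, acc, gamma = run_shear(cfg, props)
                except Exception as exc:   # flagged, not dropped
                    status = f"failed: {exc}"
                    rec, gamma = None, np.nan
                man = RunManifest(config=cfg.to_dict(), seed=seed,
                                  start_step=0,
                                  end_step=spec.equilibration_steps
                                  + spec.production_steps,
                                  material_props=dataclasses.asdict(props))
                manifests.append(man)
                if rec is not None:
                    records.append(rec)
                rows.append({
                    "P": P, "Wi": Wi, "replicate": rep, "seed": seed,
                    "mu": rec.mu if rec else np.nan,
                    "mu_err": rec.mu_err if rec else np.nan,
                    "gamma": gamma,
                    "wall_h": float(np.mean(rec.wall_h)) if rec else np.nan,
                    "status": status,
                    "manifest": man.input_hash,
                })
                if out_dir is not None:
                    d = Path(out_dir)
                    d.mkdir(parents=True, exist_ok=True)
                    man.to_json(d / f"manifest_{man.input_hash}.json")
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "sweep.csv", index=False)
    return records, table, manifests


def read_geometry(path: str | Path, dialect: str = "lammps"):
    """Ingest an externally deposited bead-spring network."""
    if dialect != "lammps":
        raise ValueError(f"unsupported dialect {dialect!r}")
    return read_lammps_data(path)
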