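"""Parameter sweeps over the (kD1, CAT0) phenotype plane.

A sweep integrates the model at every grid point for one or more treatment
regimes and tabulates the full measure set, producing the susceptibility
surfaces from which the selectivity and synergy summaries are read:

* ``selectivity_ratio`` — c1_max at the most susceptible corner (max kD1,
  min CAT0; cancer-like) over the most resistant corner (min kD1, max CAT0;
  normal-like);
* ``synergy_ratio`` — per-grid-point fold change of a measure between a
  with-nitrite and a without-nitrite surface;
* ``kd1_dependence_profile`` — per-CAT0 relative spread of a measure across
  the kD1 axis, which localises the regime shift in catalase concentration
  without hard-coding it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import MEASURE_COLUMNS, compute_all, default_baseline
from .model_core import (
    CellPhenotype,
    InvalidParameterError,
    ModelConstants,
    TreatmentScenario,
)
from .simulator import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    SWEEP_TIME_GRID,
    IntegrationError,
    TimeGrid,
    simulate,
)

__all__ = [
    "GridSpec",
    "SurfaceTable",
    "run_sweep",
    "selectivity_ratio",
    "synergy_ratio",
    "kd1_dependence_profile",
]

_KEY_COLS = ("kD1", "CAT0", "regime")


@dataclass(frozen=True)
class GridSpec:
    """Rectangular sweep grid over kD1 (s-1) and CAT0 (M).

    Defaults cover 100-2000 s-1 and 1e-8 to 1e-5 M with 100 linearly spaced
    points per axis; log spacing is available per axis.
    """

    kd1_min: float = 100.0
    kd1_max: float = 2000.0
    cat0_min: float = 1e-8
    cat0_max: float = 1e-5
    n_kd1: int = 100
    n_cat0: int = 100
    kd1_spacing: str = "linear"
    cat0_spacing: str = "linear"

    def __post_init__(self) -> None:
        if not (0 < self.kd1_min <= self.kd1_max):
            raise InvalidParameterError("need 0 < kd1_min <= kd1_max")
        if not (0 < self.cat0_min <= self.cat0_max):
            raise InvalidParameterError("need 0 < cat0_min <= cat0_max")
        if self.n_kd1 < 1 or self.n_cat0 < 1:
            raise InvalidParameterError("axis step counts must be >= 1")
        for s in (self.kd1_spacing, self.cat0_spacing):
            if s not in ("linear", "log"):
                raise InvalidParameterError(f"spacing must be 'linear' or 'log', got {s!r}")

    @staticmethod
    def _axis(lo: float, hi: float, n: int, spacing: str) -> np.ndarray:
        if n == 1:
            return np.array([lo])
        if spacing == "log":
            return np.geomspace(lo, hi, n)
        return np.linspace(lo, hi, n)

    @property
    def kd1_values(self) -> np.ndarray:
        return self._axis(self.kd1_min, self.kd1_max, self.n_kd1, self.kd1_spacing)

    @property
    def cat0_values(self) -> np.ndarray:
        return self._axis(self.cat0_min, self.cat0_max, self.n_cat0, self.cat0_spacing)

    def to_dict(self) -> dict:
        return {
            "kd1_min": self.kd1_min, "kd1_max": self.kd1_max,
            "cat0_min": self.cat0_min, "cat0_max": self.cat0_max,
            "n_kd1": self.n_kd1, "n_cat0": self.n_cat0,
            "kd1_spacing": self.kd1_spacing, "cat0_spacing": self.cat0_spacing,
        }


@dataclass
class SurfaceTable:
    """Long-format measure table over (kD1, CAT0, regime) plus provenance."""

    data: pd.DataFrame
    grid: GridSpec
    manifest: dict = field(default_factory=dict)

    def select(self, regime: str) -> pd.DataFrame:
        sub = self.data[self.data["regime"] == regime]
        if sub.empty:
            raise InvalidParameterError(f"no records for regime {regime!r}")
        return sub

    def at_point(self, kd1: float, cat0: float, regime: str) -> pd.Series:
        sub = self.select(regime)
        hit = sub[np.isclose(sub["kD1"], kd1) & np.isclose(sub["CAT0"], cat0, rtol=1e-9)]
        if hit.empty:
            raise InvalidParameterError(
                f"no record at kD1={kd1:g}, CAT0={cat0:g}, regime={regime!r}"
            )
        return hit.iloc[0]

    def pivot(self, measure: str, regime: str) -> pd.DataFrame:
        """Wide matrix of one measure (rows: CAT0, columns: kD1)."""
        return self.select(regime).pivot(index="CAT0", columns="kD1", values=measure)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, grid: GridSpec | None = None, manifest: dict | None = None):
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"),
                   grid=grid, manifest=manifest or {})


def _record(
    kd1, cat0, scenario, constants, time_grid, rtol, atol, baseline,
    tau_tolerance, tau_convention,
) -> dict:
    rec = {"kD1": float(kd1), "CAT0": float(cat0), "regime": scenario.regime_label}
    try:
        traj = simulate(
            CellPhenotype(kD1=float(kd1), CAT0=float(cat0)), scenario,
            constants, time_grid, rtol=rtol, atol=atol,
        )
        ms = compute_all(traj, baseline=baseline,
                         tau_tolerance=tau_tolerance, tau_convention=tau_convention)
        rec.update(ms.to_dict())
        rec["status"] = "ok"
    except IntegrationError as exc:  # failed points are flagged, never dropped
        rec.update({k: np.nan for k in MEASURE_COLUMNS})
        rec["status"] = f"failed: {exc}"
    return rec


def run_sweep(
    grid: GridSpec,
    scenarios: list[TreatmentScenario],
    constants: ModelConstants | None = None,
    time_grid: TimeGrid | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    baseline: float | None = None,
    tau_tolerance: float = 0.10,
    tau_convention: str = "increase",
    resume_path=None,
    progress: bool = False,
) -> SurfaceTable:
    """Measure surfaces for every (grid point x scenario).

    The intracellular steady state is re-initialised per CAT0 via the model's
    initialisation, so each grid point is an independent deterministic run;
    iteration order is fixed (CAT0 outer, kD1 inner, scenarios innermost) and
    results are order-independent.  When ``resume_path`` points at a TSV from
    an interrupted sweep, finished records are loaded and skipped, and each
    new record is appended and flushed immediately.
    """
    if not scenarios:
        raise InvalidParameterError("need at least one scenario")
    if constants is None:
        constants = ModelConstants()
    if time_grid is None:
        time_grid = SWEEP_TIME_GRID
    if baseline is None:
        baseline = default_baseline(constants)

    done: set[tuple] = set()
    rows: list[dict] = []
    if resume_path is not None and os.path.exists(resume_path):
        prior = pd.read_csv(resume_path, sep="\t", float_precision="round_trip")
        rows = prior.to_dict("records")
        done = {(round(r["kD1"], 9), float(r["CAT0"]), r["regime"]) for r in rows}

    tasks = [
        (kd1, cat0, sc)
        for cat0 in grid.cat0_values
        for kd1 in grid.kd1_values
        for sc in scenarios
    ]
    iterator = tasks
    if progress:
        from tqdm import tqdm
        iterator = tqdm(tasks, desc="sweep", unit="run")

    out_fh = None
    all_cols = list(_KEY_COLS) + list(MEASURE_COLUMNS) + ["status"]
    if resume_path is not None:
        new_file = not os.path.exists(resume_path)
        out_fh = open(resume_path, "a")
        if new_file:
            out_fh.write("\t".join(all_cols) + "\n")
            out_fh.flush()
    try:
        for kd1, cat0, sc in iterator:
            key = (round(float(kd1), 9), float(cat0), sc.regime_label)
            if key in done:
                continue
            rec = _record(kd1, cat0, sc, constants, time_grid, rtol, atol,
                          baseline, tau_tolerance, tau_convention)
            rows.append(rec)
            if out_fh is not None:
                out_fh.write("\t".join(
                    _fmt(rec.get(c)) for c in all_cols) + "\n")
                out_fh.flush()
    finally:
        if out_fh is not None:
            out_fh.close()

    df = pd.DataFrame(rows, columns=all_cols)
    n_failed = int((df["status"] != "ok").sum())
    if len(df) and n_failed == len(df):
        raise IntegrationError("every grid point failed to integrate")
    manifest = {
        "grid": grid.to_dict(),
        "scenarios": [sc.regime_label for sc in scenarios],
        "constants": constants.to_dict(),
        "time_grid": {k: getattr(time_grid, k)
                      for k in ("t1", "t2", "tf", "dt1", "dt2", "dt3")},
        "rtol": rtol, "atol": atol, "baseline": baseline,
        "tau_tolerance": tau_tolerance, "tau_convention": tau_convention,
        "n_records": len(df), "n_failed": n_failed,
    }
    return SurfaceTable(data=df, grid=grid, manifest=manifest)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return "nan" if np.isnan(v) else f"{v:.17g}"
    return str(v)


def selectivity_ratio(surface: SurfaceTable, regime: str) -> float:
    """c1_max fold between the most susceptible and most resistant corners.

    Susceptible (cancer-like) corner: (kd1_max, cat0_min); resistant
    (normal-like) corner: (kd1_min, cat0_max).
    """
    g = surface.grid
    if g is None:
        raise InvalidParameterError("surface lacks its GridSpec")
    top = surface.at_point(g.kd1_max, g.cat0_min, regime)
    bot = surface.at_point(g.kd1_min, g.cat0_max, regime)
    if top["status"] != "ok" or bot["status"] != "ok":
        raise InvalidParameterError("corner grid point failed to integrate")
    return float(top["c1_max"] / bot["c1_max"])


def synergy_ratio(
    surface_with: SurfaceTable,
    surface_without: SurfaceTable,
    measure: str = "c4_max",
) -> tuple[pd.DataFrame, dict]:
    """Per-point fold change (with-nitrite / without-nitrite) of a measure.

    Returns the merged per-point table with a ``ratio`` column and a summary
    dict (median, min, max).  Grids must be identical.
    """
    gw, go = surface_with.grid, surface_without.grid
    if gw is None or go is None or gw != go:
        raise InvalidParameterError("surfaces must share an identical GridSpec")
    left = surface_with.data[surface_with.data["status"] == "ok"]
    right = surface_without.data[surface_without.data["status"] == "ok"]
    merged = left.merge(
        right, on=["kD1", "CAT0"], suffixes=("_with", "_without"),
    )
    if merged.empty:
        raise InvalidParameterError("no shared (kD1, CAT0) points between surfaces")
    merged = merged[["kD1", "CAT0", f"{measure}_with", f"{measure}_without"]].copy()
    merged["ratio"] = merged[f"{measure}_with"] / merged[f"{measure}_without"]
    summary = {
        "median": float(merged["ratio"].median()),
        "min": float(merged["ratio"].min()),
        "max": float(merged["ratio"].max()),
    }
    return merged, summary


def kd1_dependence_profile(
    surface: SurfaceTable, measure: str = "c1_max", regime: str | None = None,
) -> pd.Series:
    """Relative spread (max - min)/min of a measure across kD1, per CAT0.

    A flat profile at low CAT0 turning into a large spread at high CAT0 is
    the signature of the shift from production-dominated to
    diffusion-dominated intracellular H2O2 build-up.
    """
    df = surface.data if regime is None else surface.select(regime)
    df = df[df["status"] == "ok"]
    spreads = {}
    for cat0, sub in df.groupby("CAT0"):
        if sub["kD1"].nunique() < 2:
            raise InvalidParameterError(
                f"need >= 2 kD1 values per CAT0 (CAT0={cat0:g})"
            )
        lo, hi = sub[measure].min(), sub[measure].max()
        if lo <= 0:
            raise InvalidParameterError(
                f"relative spread undefined for non-positive minimum at CAT0={cat0:g}"
            )
        spreads[float(cat0)] = (hi - lo) / lo
    return pd.Series(spreads, name=f"{measure}_kd1_spread").sort_index()
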