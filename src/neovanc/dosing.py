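"""AUC-guided vancomycin dose derivation and the Monte-Carlo dose table.

At steady state the daily AUC of an intravenous drug is daily dose / CL,
so the dose meeting the efficacy target AUC24/MIC >= 400 is

    daily dose (mg) = 400 * MIC * CL.

The initial-dose table simulates virtual neonates per (Scr, DFI,
diuretic) cell — weight uniform on 1-5 kg, eta_CL ~ N(0, omega^2) —
computes each patient's required per-kg daily dose 400*CL/WT and reports
the cell median rounded half-up to an integer mg/kg/day.  One common set
of random draws is shared by all cells (common random numbers), which
removes Monte-Carlo noise from the between-cell contrasts and makes the
monotone structure of the table exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    DomainError,
    ModelSpec,
    ParameterSet,
    ValidationError,
    auc24_at_steady_state,
    typical_params,
)

__all__ = [
    "DoseTable",
    "daily_dose_for_target",
    "dose_table",
    "check_dose_table_monotonicity",
    "SCR_LEVELS",
    "DFI_LEVELS",
]

SCR_LEVELS = (10.0, 30.0, 50.0, 70.0, 90.0)     # umol/L
DFI_LEVELS = (100.0, 250.0, 400.0, 550.0, 700.0)  # mL/day


def daily_dose_for_target(CL: float, mic: float = 1.0,
                          target_ratio: float = 400.0) -> float:
    """Daily dose (mg) achieving AUC24/MIC = ``target_ratio`` at clearance CL."""
    if not CL > 0:
        raise DomainError("CL must be > 0")
    if not mic > 0:
        raise DomainError("MIC must be > 0")
    return target_ratio * mic * CL


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DoseTable:
    """Recommended initial doses (mg/kg/day) on the Scr x DFI x diuretic grid."""

    table: pd.DataFrame      # columns: SCR, DFI, dose_DA, dose_non_DA
    mic: float
    target_ratio: float
    n_sim: int
    seed: int

    def cell(self, scr: float, dfi: float, da: int) -> int:
        row = self.table[(self.table.SCR == scr) & (self.table.DFI == dfi)]
        if row.empty:
            raise ValidationError(f"no cell for Scr={scr}, DFI={dfi}")
        return int(row["dose_DA" if da else "dose_non_DA"].iloc[0])

    def to_csv(self, path) -> None:
        out = self.table.rename(columns={
            "SCR": "Scr (umol/L)", "DFI": "DFI (mL)",
            "dose_DA": "Dose DA (mg/kg/day)", "dose_non_DA": "Dose non-DA (mg/kg/day)",
        })
        out.to_csv(path, index=False)


def dose_table(params: ParameterSet, spec: ModelSpec,
               scr_levels: Sequence[float] = SCR_LEVELS,
               dfi_levels: Sequence[float] = DFI_LEVELS,
               weight_range: tuple[float, float] = (1.0, 5.0),
               n_sim: int = 5000, mic: float = 1.0,
               target_ratio: float = 400.0, seed: int = 0) -> DoseTable:
    """Monte-Carlo initial-dose table for the AUC24/MIC target.

    Residual (assay) error plays no role: steady-state AUC depends on CL
    only.  Inter-individual variability on CL is included.
    """
    if not scr_levels or not dfi_levels:
        raise ValidationError("covariate grids must be nonempty")
    if n_sim < 100:
        raise ValidationError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    wt = rng.uniform(weight_range[0], weight_range[1], size=n_sim)
    omega_sd = math.sqrt(max(params.omega.get("CL", 0.0), 0.0))
    eta = rng.normal(0.0, omega_sd, size=n_sim) if omega_sd > 0 else np.zeros(n_sim)
    rows = []
    for scr in scr_levels:
        for dfi in dfi_levels:
            doses = {}
            for da in (1, 0):
                cov = {"WT": wt, "SCR": np.full(n_sim, scr),
                       "DFI": np.full(n_sim, dfi), "DA": np.full(n_sim, float(da))}
                cl = typical_params(params.theta, cov, spec).CL * np.exp(eta)
                per_kg = target_ratio * mic * cl / wt
                doses[da] = _round_half_up(float(np.median(per_kg)))
            rows.append({"SCR": scr, "DFI": dfi,
                         "dose_DA": doses[1], "dose_non_DA": doses[0]})
    return DoseTable(table=pd.DataFrame(rows), mic=mic,
                     target_ratio=target_ratio, n_sim=n_sim, seed=seed)


def check_dose_table_monotonicity(dt: DoseTable) -> None:
    """Assert the clinical-structure invariants of the dose grid:
    doses fall with Scr, rise with DFI, and the diuretic column never
    exceeds the non-diuretic column.  Raises ``ValidationError`` on
    violation."""
    t = dt.table.sort_values(["SCR", "DFI"]).reset_index(drop=True)
    if (t[["dose_DA", "dose_non_DA"]] <= 0).any().any():
        raise ValidationError("non-positive dose in table")
    for col in ("dose_DA", "dose_non_DA"):
        for scr, grp in t.groupby("SCR"):
            if not grp.sort_values("DFI")[col].is_monotonic_increasing:
                raise ValidationError(f"{col} not non-decreasing in DFI at Scr={scr}")
        for dfi, grp in t.groupby("DFI"):
            vals = grp.sort_values("SCR")[col].to_numpy()
            if np.any(np.diff(vals) > 0):
                raise ValidationError(f"{col} not non-increasing in Scr at DFI={dfi}")
    if np.any(t["dose_DA"].to_numpy() > t["dose_non_DA"].to_numpy()):
        raise ValidationError("diuretic dose exceeds non-diuretic dose in a cell")
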