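"""Growth and methanogenesis kinetics for chemostat and batch-bottle cultures.

Estimators
----------
* specific growth rate k (1/h): OLS slope of ln(cell count) on time;
* chemostat CH4 production rate and cell-specific rate q: headspace export
  plus dissolved export, normalized by total cells in the vessel;
* chemostat cell yield Y = D*X*V / production rate (cells per mol CH4);
* batch cell yield Y: OLS slope of cells per bottle on product per bottle;
* batch cell-specific rate q = k / (ln 2 * Y), the doubling-time form used
  for methanogen CH4 and for heterotroph acetate/formate/H2 rates alike.

Units contract: vessel totals in mol, concentrations in mol/l, cell
concentrations in cells/ml, rates surfaced in fmol/cell/h (1e-15 mol) and
yields in cells/mol.  At chemostat steady state the identity Y * q = D holds
exactly (q in mol/cell/h), because both sides express the same balance of
cell production against CH4 production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

LN2 = math.log(2.0)

#: fmol per mol.
FMOL_PER_MOL = 1e15

__all__ = [
    "LN2",
    "CellCountSeries",
    "GrowthFit",
    "ChemostatState",
    "BatchBottleSeries",
    "YieldFit",
    "RateResult",
    "fit_growth_rate",
    "chemostat_production_rate",
    "chemostat_yield",
    "batch_yield",
    "batch_cell_specific_rate",
    "metabolite_cell_specific_rate",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _as_1d(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class CellCountSeries:
    """Timestamped cell concentrations for one organism in one vessel."""

    time_h: np.ndarray
    count_per_ml: np.ndarray
    organism_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = _as_1d("time_h", self.time_h)
        self.count_per_ml = _as_1d("count_per_ml", self.count_per_ml)
        if self.time_h.size != self.count_per_ml.size:
            raise ValueError("time and count arrays must have equal length")
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.count_per_ml <= 0):
            raise ValueError("all cell counts must be positive")

    def __len__(self) -> int:
        return self.time_h.size


@dataclass(frozen=True)
class GrowthFit:
    """Log-linear growth fit: ln(count) = ln_intercept + k * t."""

    k_per_h: float
    ln_intercept: float
    stderr_k_per_h: float
    r_squared: float
    window: Tuple[int, int]


@dataclass(frozen=True)
class ChemostatState:
    """Steady-state operating point of a sparged chemostat.

    ``headspace_ch4_mol_per_l`` is the CH4 concentration of the exiting gas
    stream; ``dissolved_ch4_mol_per_l`` that of the exiting medium.
    """

    dilution_rate_per_h: float
    cell_conc_per_ml: float
    liquid_volume_l: float
    gas_outflow_l_per_h: float
    headspace_ch4_mol_per_l: float
    dissolved_ch4_mol_per_l: float

    def __post_init__(self) -> None:
        for name in (
            "dilution_rate_per_h",
            "cell_conc_per_ml",
            "liquid_volume_l",
            "gas_outflow_l_per_h",
            "headspace_ch4_mol_per_l",
            "dissolved_ch4_mol_per_l",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.liquid_volume_l <= 0:
            raise ValueError("liquid volume must be positive")

    @property
    def total_cells(self) -> float:
        """Total cells in the vessel (cells/ml * 1000 ml/l * liters)."""
        return self.cell_conc_per_ml * 1e3 * self.liquid_volume_l


@dataclass
class BatchBottleSeries:
    """Joint time series of cells and cumulative amounts in one sealed bottle.

    All amounts are mol per bottle; cell columns are total cells per bottle.
    Optional columns may be None when not measured.
    """

    time_h: np.ndarray
    methanogen_cells_total: Optional[np.ndarray] = None
    heterotroph_cells_total: Optional[np.ndarray] = None
    ch4_mol_total: Optional[np.ndarray] = None
    h2_mol_total: Optional[np.ndarray] = None
    acetate_mol_total: Optional[np.ndarray] = None
    formate_mol_total: Optional[np.ndarray] = None
    h2_transferred_mol: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    _AMOUNT_COLUMNS = (
        "ch4_mol_total",
        "h2_mol_total",
        "acetate_mol_total",
        "formate_mol_total",
        "h2_transferred_mol",
    )

    def __post_init__(self) -> None:
        self.time_h = _as_1d("time_h", self.time_h)
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time grid must be strictly increasing")
        n = self.time_h.size
        for name in ("methanogen_cells_total", "heterotroph_cells_total") + self._AMOUNT_COLUMNS:
            col = getattr(self, name)
            if col is None:
                continue
            col = _as_1d(name, col)
            if col.size != n:
                raise ValueError(f"{name} must match the time grid length")
            if np.any(col < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, col)

    def __len__(self) -> int:
        return self.time_h.size


@dataclass(frozen=True)
class YieldFit:
    """Cell yield (cells per mol of product) from a linear regression."""

    yield_cells_per_mol: float
    intercept_cells: float
    stderr_yield: float
    r_squared: float


@dataclass(frozen=True)
class RateResult:
    """Vessel-total production rate and the cell-specific rate q."""

    production_rate_mol_per_h: float
    q_fmol_per_cell_h: float

    @property
    def q_mol_per_cell_h(self) -> float:
        return self.q_fmol_per_cell_h / FMOL_PER_MOL


# ---------------------------------------------------------------------------
# growth-rate fitting
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    """Slope, intercept, slope stderr and r^2, robust to zero-variance y."""
    res = stats.linregress(x, y)
    r2 = res.rvalue**2 if np.isfinite(res.rvalue) else 0.0
    stderr = res.stderr if np.isfinite(res.stderr) else 0.0
    return float(res.slope), float(res.intercept), float(stderr), float(r2)


def fit_growth_rate(
    series: CellCountSeries, window: Optional[Tuple[int, int]] = None
) -> GrowthFit:
    """Specific growth rate from an OLS fit of ln(count) against time.

    ``window`` is an optional (start, stop) index range selecting the
    exponential portion of the curve; the default uses all points.  At least
    three points are required and every count must be positive (the log
    transform rejects rather than drops bad points).
    """
    start, stop = window if window is not None else (0, len(series))
    t = series.time_h[start:stop]
    x = series.count_per_ml[start:stop]
    if t.size < 3:
        raise ValueError(f"growth fit needs >= 3 points (window has {t.size})")
    slope, intercept, stderr, r2 = _ols(t, np.log(x))
    return GrowthFit(
        k_per_h=slope,
        ln_intercept=intercept,
        stderr_k_per_h=stderr,
        r_squared=r2,
        window=(start, stop),
    )


# ---------------------------------------------------------------------------
# chemostat rates and yields
# ---------------------------------------------------------------------------

def chemostat_production_rate(state: ChemostatState) -> RateResult:
    """Vessel CH4 production rate and cell-specific rate q at steady state.

    rate = [CH4]_gas * gas outflow + [CH4]_medium * (D * V)   [mol/h]
    q    = rate / total cells                                  [mol/cell/h]
    """
    rate = (
        state.headspace_ch4_mol_per_l * state.gas_outflow_l_per_h
        + state.dissolved_ch4_mol_per_l
        * state.dilution_rate_per_h
        * state.liquid_volume_l
    )
    if state.total_cells <= 0:
        raise ValueError("cell concentration must be positive to compute q")
    q_mol = rate / state.total_cells
    return RateResult(
        production_rate_mol_per_h=rate, q_fmol_per_cell_h=q_mol * FMOL_PER_MOL
    )


def chemostat_yield(state: ChemostatState, rate: Optional[RateResult] = None) -> YieldFit:
    """Cell yield Y = cell production rate / CH4 production rate.

    At steady state the cell production rate is D * X * V, so
    Y = D * total cells / rate (cells per mol CH4).  This is a point
    computation, not a regression: the fit diagnostics are degenerate
    (stderr 0, r^2 1).
    """
    if state.dilution_rate_per_h <= 0:
        raise ValueError("dilution rate must be positive for a yield")
    if rate is None:
        rate = chemostat_production_rate(state)
    if rate.production_rate_mol_per_h <= 0:
        raise ValueError("CH4 production rate must be positive for a yield")
    y = state.dilution_rate_per_h * state.total_cells / rate.production_rate_mol_per_h
    return YieldFit(yield_cells_per_mol=y, intercept_cells=0.0, stderr_yield=0.0, r_squared=1.0)


# ---------------------------------------------------------------------------
# batch yields and cell-specific rates
# ---------------------------------------------------------------------------

_PRODUCT_COLUMNS = {
    "CH4": "ch4_mol_total",
    "H2": "h2_mol_total",
    "acetate": "acetate_mol_total",
    "formate": "formate_mol_total",
}

#: cells regressed against each product: CH4 belongs to the methanogen,
#: fermentation products to the heterotroph.
_DEFAULT_ORGANISM = {
    "CH4": "methanogen",
    "H2": "heterotroph",
    "acetate": "heterotroph",
    "formate": "heterotroph",
}


def batch_yield(
    series: BatchBottleSeries,
    product: str = "CH4",
    organism: Optional[str] = None,
    through_origin: bool = False,
) -> YieldFit:
    """Cell yield from the slope of cells per bottle against product per bottle.

    The intercept is kept free by default (bottles start with a nonzero
    inoculum); ``through_origin`` forces a slope-only fit.  ``organism``
    defaults to the producer of the product: the methanogen for CH4, the
    heterotroph for acetate, formate and H2.
    """
    if product not in _PRODUCT_COLUMNS:
        raise ValueError(f"unknown product {product!r}; expected one of {sorted(_PRODUCT_COLUMNS)}")
    organism = organism or _DEFAULT_ORGANISM[product]
    cells = getattr(series, f"{organism}_cells_total", None)
    if cells is None:
        raise ValueError(f"series has no {organism} cell counts")
    amounts = getattr(series, _PRODUCT_COLUMNS[product])
    if amounts is None:
        raise ValueError(f"series has no {product} column")
    if len(series) < 3:
        raise ValueError("yield fit needs >= 3 paired points")
    if np.all(amounts == 0):
        raise ValueError(f"all-zero {product} column: no production to regress on")
    if through_origin:
        slope = float(np.dot(amounts, cells) / np.dot(amounts, amounts))
        resid = cells - slope * amounts
        ss_tot = float(np.dot(cells, cells))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
        dof = len(series) - 1
        stderr = (
            math.sqrt(float(np.dot(resid, resid)) / dof / float(np.dot(amounts, amounts)))
            if dof > 0
            else 0.0
        )
        return YieldFit(slope, 0.0, stderr, r2)
    slope, intercept, stderr, r2 = _ols(amounts, cells)
    return YieldFit(slope, intercept, stderr, r2)


def _q_from_k_and_yield(k_per_h: float, y: "YieldFit | float") -> RateResult:
    y_val = y.yield_cells_per_mol if isinstance(y, YieldFit) else float(y)
    if y_val <= 0:
        raise ValueError(f"yield must be positive (got {y_val})")
    q_mol = k_per_h / (LN2 * y_val)
    return RateResult(
        production_rate_mol_per_h=float("nan"),
        q_fmol_per_cell_h=q_mol * FMOL_PER_MOL,
    )


def batch_cell_specific_rate(k_per_h: float, y: "YieldFit | float") -> RateResult:
    """Cell-specific CH4 production rate in batch: q = k / (ln 2 * Y).

    During one doubling time (ln 2 / k) the population produces one cell per
    1/Y mol of product per existing cell, giving the per-cell, per-hour rate
    k / (ln 2 * Y).  The vessel-total rate is not defined from (k, Y) alone
    and is reported as NaN.
    """
    return _q_from_k_and_yield(k_per_h, y)


def metabolite_cell_specific_rate(k_per_h: float, y_metabolite: "YieldFit | float") -> RateResult:
    """Cell-specific acetate/formate/H2 production rate, same form as CH4."""
    return _q_from_k_and_yield(k_per_h, y_metabolite)
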