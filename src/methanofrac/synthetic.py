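"""Synthetic data generators with the statistical structure the estimators assume.

Each generator builds a noise-free truth from its parameters and then applies
measurement noise:

* cell counts get independent multiplicative lognormal noise (counts are
  positive and microscopy error scales with the count), CV 0.05 by default;
* delta13C values get independent additive Gaussian noise, SD 0.3 permil
  (typical replicate-injection scatter of IRMS measurements);
* with all noise set to zero, every generator composed with its estimator is
  an exact identity, which is the backbone of the test suite.

All draws flow from one ``numpy`` generator seeded per call from the
``SimConfig`` seed, so identical configurations give bit-identical output;
the seed and parameters are recorded in each output's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import (
    LN2,
    BatchBottleSeries,
    CellCountSeries,
    ChemostatState,
)
from .isotopes import rayleigh_closed_form

__all__ = [
    "SimConfig",
    "gen_batch_growth",
    "gen_chemostat_run",
    "gen_coculture",
    "gen_isotope_drawdown",
]


@dataclass(frozen=True)
class SimConfig:
    """Shared knobs of the synthetic study.

    ``noise_cv_counts`` is the coefficient of variation of multiplicative
    count noise; ``sigma_delta_permil`` the SD of additive isotope noise.
    ``time_grid_h`` is the sampling schedule used by the time-series
    generators.
    """

    seed: int
    noise_cv_counts: float = 0.05
    sigma_delta_permil: float = 0.3
    time_grid_h: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 4.0, 9)
    )

    def __post_init__(self) -> None:
        if self.noise_cv_counts < 0:
            raise ValueError("count-noise CV must be non-negative")
        if self.sigma_delta_permil < 0:
            raise ValueError("isotope-noise SD must be non-negative")
        grid = np.asarray(self.time_grid_h, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("time grid must be a 1-d sequence of >= 2 times")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time_grid_h", grid)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def metadata(self, **params) -> dict:
        meta = {"seed": self.seed, "noise_cv_counts": self.noise_cv_counts,
                "sigma_delta_permil": self.sigma_delta_permil}
        meta.update(params)
        return meta


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


# ---------------------------------------------------------------------------
# batch monoculture growth
# ---------------------------------------------------------------------------

def gen_batch_growth(
    k_per_h: float,
    x0_per_ml: float,
    config: SimConfig,
    organism_label: str = "methanogen",
) -> CellCountSeries:
    """Exponential growth curve x0 * exp(k t) with multiplicative count noise."""
    if not np.isfinite(k_per_h):
        raise ValueError("growth rate k must be finite")
    if x0_per_ml <= 0:
        raise ValueError("initial cell concentration must be positive")
    t = config.time_grid_h
    truth = x0_per_ml * np.exp(k_per_h * t)
    counts = truth * _lognormal_factors(config.rng(), config.noise_cv_counts, t.size)
    return CellCountSeries(
        time_h=t,
        count_per_ml=counts,
        organism_label=organism_label,
        meta=config.metadata(k_per_h=k_per_h, x0_per_ml=x0_per_ml),
    )


# ---------------------------------------------------------------------------
# chemostat steady state
# ---------------------------------------------------------------------------

def gen_chemostat_run(
    d_per_h: float,
    x_per_ml: float,
    q_true_mol_per_cell_h: float,
    gas_flow_l_per_h: float,
    volume_l: float,
    config: SimConfig,
    dissolved_fraction: float = 0.002,
) -> ChemostatState:
    """Steady-state chemostat observation consistent with a true per-cell rate.

    The vessel-total CH4 production rate q_true * total cells is split between
    the exiting gas stream and the exiting medium (``dissolved_fraction`` of
    the total leaves dissolved, emulating the small Henry's-law solubility of
    CH4 at 82 degC), then each measured concentration and the cell count get
    independent multiplicative noise.  With zero noise, the chemostat
    estimators recover q_true and Y = D / q_true exactly.
    """
    if min(d_per_h, x_per_ml, q_true_mol_per_cell_h, gas_flow_l_per_h, volume_l) <= 0:
        raise ValueError("all chemostat parameters must be positive")
    if not (0 <= dissolved_fraction < 1):
        raise ValueError("dissolved fraction must lie in [0, 1)")
    total_cells = x_per_ml * 1e3 * volume_l
    rate = q_true_mol_per_cell_h * total_cells
    headspace_conc = (1.0 - dissolved_fraction) * rate / gas_flow_l_per_h
    dissolved_conc = dissolved_fraction * rate / (d_per_h * volume_l)
    noise = _lognormal_factors(config.rng(), config.noise_cv_counts, 3)
    return ChemostatState(
        dilution_rate_per_h=d_per_h,
        cell_conc_per_ml=x_per_ml * noise[0],
        liquid_volume_l=volume_l,
        gas_outflow_l_per_h=gas_flow_l_per_h,
        headspace_ch4_mol_per_l=headspace_conc * noise[1],
        dissolved_ch4_mol_per_l=dissolved_conc * noise[2],
    )


# ---------------------------------------------------------------------------
# coculture with interspecies H2 transfer
# ---------------------------------------------------------------------------

def gen_coculture(
    k_het_per_h: float,
    h2_per_cell_mol_h: float,
    y_ch4_cells_per_mol: float,
    config: SimConfig,
    acetate_per_cell_mol_h: float = 1.0e-12,
    het_x0_total: float = 1.5e9,
    meth_x0_total: float = 1.5e9,
) -> BatchBottleSeries:
    """Sealed-bottle coculture: fermentative H2 feeds hydrogenotrophic CH4.

    The heterotroph grows exponentially and produces H2 and acetate in
    proportion to its cell increase (rate parameters use the same
    per-doubling convention as q = k/(ln 2 * Y), so estimator round trips are
    exact).  Transfer is quasi-steady: the methanogen consumes all H2
    instantaneously at the 4 H2 : 1 CH4 stoichiometry of CO2 reduction, so
    the free H2 pool stays at zero, and methanogen cells accrue at
    ``y_ch4_cells_per_mol`` per mol CH4.  ``h2_transferred_mol`` records the
    cumulative H2 routed to the methanogen (4x the CH4 column).
    """
    if min(k_het_per_h, y_ch4_cells_per_mol, het_x0_total, meth_x0_total) <= 0:
        raise ValueError("rates, yields and inocula must be positive")
    if h2_per_cell_mol_h < 0 or acetate_per_cell_mol_h < 0:
        raise ValueError("per-cell production rates must be non-negative")
    t = config.time_grid_h
    n_het = het_x0_total * np.exp(k_het_per_h * t)
    delta_n = n_het - het_x0_total
    # per-doubling convention: mol = q * (ln2/k) * (cell increase)
    h2_produced = h2_per_cell_mol_h * (LN2 / k_het_per_h) * delta_n
    acetate = acetate_per_cell_mol_h * (LN2 / k_het_per_h) * delta_n
    ch4 = h2_produced / 4.0
    n_meth = meth_x0_total + y_ch4_cells_per_mol * ch4

    rng = config.rng()
    cv = config.noise_cv_counts
    n = t.size
    series = BatchBottleSeries(
        time_h=t,
        methanogen_cells_total=n_meth * _lognormal_factors(rng, cv, n),
        heterotroph_cells_total=n_het * _lognormal_factors(rng, cv, n),
        ch4_mol_total=ch4 * _lognormal_factors(rng, cv, n),
        h2_mol_total=np.zeros(n),
        acetate_mol_total=acetate * _lognormal_factors(rng, cv, n),
        formate_mol_total=np.zeros(n),
        h2_transferred_mol=h2_produced,
        meta=config.metadata(
            k_het_per_h=k_het_per_h,
            h2_per_cell_mol_h=h2_per_cell_mol_h,
            y_ch4_cells_per_mol=y_ch4_cells_per_mol,
            acetate_per_cell_mol_h=acetate_per_cell_mol_h,
            het_x0_total=het_x0_total,
            meth_x0_total=meth_x0_total,
        ),
    )
    return series


# ---------------------------------------------------------------------------
# closed-system isotope drawdown
# ---------------------------------------------------------------------------

def gen_isotope_drawdown(
    delta0_permil: float,
    epsilon_permil: float,
    f_final: float,
    n_obs: int,
    config: SimConfig,
) -> pd.DataFrame:
    """Observed Rayleigh drawdown: (f, residual delta, cumulative-product delta).

    Noise-free values follow the closed-form Rayleigh solution on a log-spaced
    grid of f from 1 down to ``f_final``; Gaussian noise with
    ``sigma_delta_permil`` is added independently to every delta.  The
    cumulative product is undefined (NaN) at f = 1.
    """
    if not (0.0 < f_final <= 1.0):
        raise ValueError("f_final must lie in (0, 1]")
    if epsilon_permil < 0:
        raise ValueError("epsilon must be non-negative")
    if n_obs < 1:
        raise ValueError("need at least one observation")
    if f_final == 1.0:
        f = np.ones(n_obs)
    else:
        f = np.exp(np.linspace(0.0, np.log(f_final), n_obs))
        f[0] = 1.0
    residual, product = rayleigh_closed_form(delta0_permil, epsilon_permil, f)
    residual = np.atleast_1d(residual).astype(float)
    product = np.atleast_1d(product).astype(float)
    sigma = config.sigma_delta_permil
    if sigma > 0:
        rng = config.rng()
        residual = residual + rng.normal(0.0, sigma, size=n_obs)
        noisy_product = product + rng.normal(0.0, sigma, size=n_obs)
        product = np.where(np.isnan(product), np.nan, noisy_product)
    df = pd.DataFrame(
        {
            "f": f,
            "delta_residual_permil": residual,
            "delta_product_cum_permil": product,
        }
    )
    df.attrs["meta"] = config.metadata(
        delta0_permil=delta0_permil, epsilon_permil=epsilon_permil, f_final=f_final
    )
    return df
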