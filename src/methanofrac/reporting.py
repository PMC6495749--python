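"""TSV schemas, condition-level summaries, and the reproducible pipeline.

The analysis reads and writes plain tab-separated tables with a fixed header
vocabulary:

* cell counts:    time_h, count_per_ml, organism
* batch bottles:  time_h, methanogen_cells_total, heterotroph_cells_total,
                  ch4_mol, h2_mol, acetate_mol, formate_mol
* chemostats:     one row per replicate with the six ChemostatState fields
* isotopes:       condition, analyte (CO2|DIC|CH4), timepoint (To|Tf),
                  delta_permil, sigma_permil

``simulate`` turns a plain-text config into a full synthetic study on disk
(every table gets a key=value metadata sidecar recording seed and
parameters); ``run_condition`` reads measurement tables and emits a
condition-level summary table plus a run log.  Reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import math
from configparser import ConfigParser
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .isotopes import alpha_epsilon, rayleigh_invert
from .kinetics import (
    BatchBottleSeries,
    CellCountSeries,
    ChemostatState,
    batch_cell_specific_rate,
    batch_yield,
    chemostat_production_rate,
    chemostat_yield,
    fit_growth_rate,
)
from .synthetic import SimConfig, gen_batch_growth, gen_chemostat_run, gen_coculture, gen_isotope_drawdown

__all__ = [
    "ConditionSummary",
    "read_cell_counts",
    "write_cell_counts",
    "read_batch_series",
    "write_batch_series",
    "read_chemostat_states",
    "write_chemostat_states",
    "read_isotope_table",
    "write_isotope_table",
    "packaged_isotope_table",
    "write_metadata_sidecar",
    "read_metadata_sidecar",
    "condition_isotopes",
    "epsilon_for_condition",
    "summarize_chemostat",
    "summarize_batch",
    "run_condition",
    "simulate",
    "default_simulation_config",
    "write_summary_table",
]

_TSV_KW = dict(sep="\t", index=False, float_format="%.12g", lineterminator="\n")

_BATCH_COLUMNS = {
    "methanogen_cells_total": "methanogen_cells_total",
    "heterotroph_cells_total": "heterotroph_cells_total",
    "ch4_mol": "ch4_mol_total",
    "h2_mol": "h2_mol_total",
    "acetate_mol": "acetate_mol_total",
    "formate_mol": "formate_mol_total",
}

_CHEMOSTAT_COLUMNS = [
    "dilution_rate_per_h",
    "cell_conc_per_ml",
    "liquid_volume_l",
    "gas_outflow_l_per_h",
    "headspace_ch4_mol_per_l",
    "dissolved_ch4_mol_per_l",
]


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def write_cell_counts(series: CellCountSeries, path) -> None:
    pd.DataFrame(
        {
            "time_h": series.time_h,
            "count_per_ml": series.count_per_ml,
            "organism": series.organism_label,
        }
    ).to_csv(path, **_TSV_KW)


def read_cell_counts(path) -> CellCountSeries:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_h", "count_per_ml"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    label = str(df["organism"].iloc[0]) if "organism" in df.columns and len(df) else ""
    return CellCountSeries(
        time_h=df["time_h"].to_numpy(),
        count_per_ml=df["count_per_ml"].to_numpy(),
        organism_label=label,
    )


def write_batch_series(series: BatchBottleSeries, path) -> None:
    data = {"time_h": series.time_h}
    for col, attr in _BATCH_COLUMNS.items():
        values = getattr(series, attr)
        if values is not None:
            data[col] = values
    pd.DataFrame(data).to_csv(path, **_TSV_KW)


def read_batch_series(path) -> BatchBottleSeries:
    df = pd.read_csv(path, sep="\t")
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_h'")
    kwargs = {}
    for col, attr in _BATCH_COLUMNS.items():
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy()
    return BatchBottleSeries(time_h=df["time_h"].to_numpy(), **kwargs)


def write_chemostat_states(states: Sequence[ChemostatState], path) -> None:
    rows = [{c: getattr(s, c) for c in _CHEMOSTAT_COLUMNS} for s in states]
    pd.DataFrame(rows, columns=_CHEMOSTAT_COLUMNS).to_csv(path, **_TSV_KW)


def read_chemostat_states(path) -> List[ChemostatState]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CHEMOSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        ChemostatState(**{c: float(row[c]) for c in _CHEMOSTAT_COLUMNS})
        for _, row in df.iterrows()
    ]


def write_isotope_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, **_TSV_KW)


def read_isotope_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "analyte", "timepoint", "delta_permil"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def packaged_isotope_table() -> pd.DataFrame:
    """The published condition-level delta13C table shipped with the package.

    One row per (condition, analyte, timepoint): chemostat runs R1-R6 at high
    and low H2, monoculture serum bottles B1-B2, and coculture bottles B3-B6
    on formate or maltose.  For B1/B2 both the measured DIC pool and the
    Mook-converted CO2(aq) values at 82 degC are included.
    """
    ref = resources.files("methanofrac").joinpath("data/isotope_conditions.tsv")
    with resources.as_file(ref) as path:
        return read_isotope_table(path)


def write_metadata_sidecar(path, meta: Dict) -> None:
    lines = [f"{k}={meta[k]}" for k in sorted(meta)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata_sidecar(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, value = line.partition("=")
            out[key] = value
    return out


# ---------------------------------------------------------------------------
# condition summaries
# ---------------------------------------------------------------------------

@dataclass
class ConditionSummary:
    """Condition-level estimates, mean +/- standard error across replicates."""

    condition_label: str
    replicate_count: int
    k_per_h: Optional[float] = None
    k_se: Optional[float] = None
    q_fmol_per_cell_h: Optional[float] = None
    q_se: Optional[float] = None
    yield_cells_per_mol: Optional[float] = None
    yield_se: Optional[float] = None
    delta_co2_to_permil: Optional[float] = None
    delta_co2_tf_permil: Optional[float] = None
    delta_ch4_tf_permil: Optional[float] = None
    epsilon_permil: Optional[float] = None


def _mean_se(values: Sequence[float]) -> Tuple[float, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


def condition_isotopes(df: pd.DataFrame, condition: str) -> Dict[str, Optional[float]]:
    """Mean delta13C values for one condition, keyed by analyte/timepoint.

    CO2(aq) rows are preferred over raw DIC rows when both are present.
    """
    sub = df[df["condition"] == condition]

    def pick(timepoint: str, analytes: Sequence[str]) -> Optional[float]:
        for analyte in analytes:
            rows = sub[(sub["analyte"] == analyte) & (sub["timepoint"] == timepoint)]
            if len(rows):
                return float(rows["delta_permil"].mean())
        return None

    return {
        "delta_co2_to": pick("To", ("CO2", "DIC")),
        "delta_co2_tf": pick("Tf", ("CO2", "DIC")),
        "delta_ch4_tf": pick("Tf", ("CH4",)),
    }


def epsilon_for_condition(
    df: pd.DataFrame, condition: str, mode: str = "direct"
) -> Optional[float]:
    """epsilon_CO2-CH4 (permil) for one condition of the isotope table.

    ``mode='direct'`` applies the alpha/epsilon definition to the final
    deltas (appropriate when the CO2 reservoir is effectively unlimited, as
    in a sparged chemostat or an H2-fed coculture with excess CO2).
    ``mode='rayleigh'`` treats the bottle as a closed reservoir and inverts
    the Rayleigh model from the initial CO2, final residual CO2 and final
    accumulated CH4 (appropriate for the extensively drawn-down monoculture
    bottles).
    """
    vals = condition_isotopes(df, condition)
    if vals["delta_co2_tf"] is None or vals["delta_ch4_tf"] is None:
        return None
    if mode == "direct":
        return alpha_epsilon(vals["delta_co2_tf"], vals["delta_ch4_tf"]).epsilon_permil
    if mode == "rayleigh":
        if vals["delta_co2_to"] is None:
            raise ValueError(f"{condition}: Rayleigh inversion needs an initial CO2 delta")
        eps, _ = rayleigh_invert(
            vals["delta_co2_to"], vals["delta_co2_tf"], vals["delta_ch4_tf"]
        )
        return eps
    raise ValueError(f"unknown isotope mode {mode!r}; expected 'direct' or 'rayleigh'")


def summarize_chemostat(states: Sequence[ChemostatState], label: str) -> ConditionSummary:
    """Per-replicate q and Y, aggregated as mean +/- SE.

    At steady state the specific growth rate equals the dilution rate, so k
    is reported as the mean D across replicates.
    """
    if not states:
        raise ValueError("need at least one chemostat replicate")
    qs, ys, ks = [], [], []
    for state in states:
        rate = chemostat_production_rate(state)
        qs.append(rate.q_fmol_per_cell_h)
        ys.append(chemostat_yield(state, rate).yield_cells_per_mol)
        ks.append(state.dilution_rate_per_h)
    k, k_se = _mean_se(ks)
    q, q_se = _mean_se(qs)
    y, y_se = _mean_se(ys)
    return ConditionSummary(
        condition_label=label,
        replicate_count=len(states),
        k_per_h=k,
        k_se=k_se,
        q_fmol_per_cell_h=q,
        q_se=q_se,
        yield_cells_per_mol=y,
        yield_se=y_se,
    )


def summarize_batch(
    series_list: Sequence[BatchBottleSeries],
    label: str,
    product: str = "CH4",
    growth_organism: str = "methanogen",
    window: Optional[Tuple[int, int]] = None,
) -> ConditionSummary:
    """Per-replicate (k, Y, q) from batch bottles, aggregated as mean +/- SE.

    k comes from a log-linear fit to the ``growth_organism`` counts, Y from
    the cells-vs-product regression, and q = k / (ln 2 * Y) — computed per
    replicate first, then averaged, which is how replicate means of derived
    quantities must be formed (the mean of per-replicate q generally differs
    from the formula applied to mean k and mean Y).
    """
    if not series_list:
        raise ValueError("need at least one bottle replicate")
    ks, ys, qs = [], [], []
    for series in series_list:
        cells = getattr(series, f"{growth_organism}_cells_total")
        if cells is None:
            raise ValueError(f"series has no {growth_organism} cell counts")
        counts = CellCountSeries(
            time_h=series.time_h, count_per_ml=cells, organism_label=growth_organism
        )
        k = fit_growth_rate(counts, window=window).k_per_h
        y = batch_yield(series, product=product)
        q = batch_cell_specific_rate(k, y).q_fmol_per_cell_h
        ks.append(k)
        ys.append(y.yield_cells_per_mol)
        qs.append(q)
    k, k_se = _mean_se(ks)
    q, q_se = _mean_se(qs)
    y_mean, y_se = _mean_se(ys)
    return ConditionSummary(
        condition_label=label,
        replicate_count=len(series_list),
        k_per_h=k,
        k_se=k_se,
        q_fmol_per_cell_h=q,
        q_se=q_se,
        yield_cells_per_mol=y_mean,
        yield_se=y_se,
    )


def write_summary_table(summaries: Sequence[ConditionSummary], path) -> None:
    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": s.condition_label,
                "replicates": s.replicate_count,
                "k_per_h": s.k_per_h,
                "k_se": s.k_se,
                "q_fmol_per_cell_h": s.q_fmol_per_cell_h,
                "q_se": s.q_se,
                "yield_cells_per_mol": s.yield_cells_per_mol,
                "yield_se": s.yield_se,
                "delta_co2_to_permil": s.delta_co2_to_permil,
                "delta_co2_tf_permil": s.delta_co2_tf_permil,
                "delta_ch4_tf_permil": s.delta_ch4_tf_permil,
                "epsilon_permil": s.epsilon_permil,
            }
        )
    pd.DataFrame(rows).to_csv(path, **_TSV_KW)


# ---------------------------------------------------------------------------
# pipeline: run_condition
# ---------------------------------------------------------------------------

def _read_config(config_path) -> ConfigParser:
    parser = ConfigParser()
    read = parser.read(config_path)
    if not read:
        raise FileNotFoundError(f"config file not found: {config_path}")
    return parser


def _resolve(base: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else base / p


def run_condition(config_path, out_dir=None) -> List[ConditionSummary]:
    """Run the estimator chain for every condition in a plain-text config.

    Each ``[condition:<label>]`` section names its vessel type
    (chemostat | bottle | coculture), the input tables (paths relative to the
    config file) and analysis options; replicates are aggregated as mean +/-
    SE.  When ``out_dir`` is given, a summary TSV and a run log (package
    version, config hash, per-condition options) are written; reruns with the
    same config are byte-identical.
    """
    config_path = Path(config_path)
    parser = _read_config(config_path)
    base = config_path.parent
    summaries: List[ConditionSummary] = []
    log_lines = [
        f"methanofrac_version={__version__}",
        f"config_sha256={hashlib.sha256(config_path.read_bytes()).hexdigest()}",
    ]
    for section in parser.sections():
        if not section.startswith("condition:"):
            continue
        label = section.split(":", 1)[1]
        opts = parser[section]
        vessel = opts.get("vessel", "").strip()
        if vessel == "chemostat":
            states = read_chemostat_states(_resolve(base, opts["chemostat_table"]))
            summary = summarize_chemostat(states, label)
        elif vessel in ("bottle", "coculture"):
            tables = [t.strip() for t in opts["tables"].split(",") if t.strip()]
            series_list = [read_batch_series(_resolve(base, t)) for t in tables]
            summary = summarize_batch(
                series_list,
                label,
                product=opts.get("product", "CH4"),
                growth_organism=opts.get(
                    "growth_organism",
                    "heterotroph" if vessel == "coculture" else "methanogen",
                ),
            )
        else:
            raise ValueError(
                f"[{section}] has unknown vessel {vessel!r}; "
                "expected chemostat, bottle or coculture"
            )
        if opts.get("isotope_table"):
            iso = read_isotope_table(_resolve(base, opts["isotope_table"]))
            iso_condition = opts.get("isotope_condition", label)
            mode = opts.get("isotope_mode", "direct")
            vals = condition_isotopes(iso, iso_condition)
            summary.delta_co2_to_permil = vals["delta_co2_to"]
            summary.delta_co2_tf_permil = vals["delta_co2_tf"]
            summary.delta_ch4_tf_permil = vals["delta_ch4_tf"]
            summary.epsilon_permil = epsilon_for_condition(iso, iso_condition, mode)
        summaries.append(summary)
        log_lines.append(f"condition={label} vessel={vessel} options={dict(opts)}")
    if not summaries:
        raise ValueError(f"{config_path}: no [condition:<label>] sections found")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary_table(summaries, out / "summary.tsv")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summaries


# ---------------------------------------------------------------------------
# pipeline: simulate
# ---------------------------------------------------------------------------

def default_simulation_config() -> ConfigParser:
    """The default synthetic study: two chemostat H2 levels (3 replicates
    each) and two coculture substrates, sized like the experiments they
    emulate (1.5-l vessel, dilution rates set by 3 volume turnovers in ~5 h
    and ~14 h, per-cell rates at the reported condition means)."""
    parser = ConfigParser()
    parser["simulate"] = {
        "seed": "1",
        "noise_cv_counts": "0.05",
        "sigma_delta_permil": "0.3",
    }
    parser["chemostat:high_H2"] = {
        "replicates": "3",
        "dilution_rate_per_h": "0.6",
        "cell_conc_per_ml": "1e7",
        "q_fmol_per_cell_h": "496",
        "gas_flow_l_per_h": "9.15",
        "liquid_volume_l": "1.5",
    }
    parser["chemostat:low_H2"] = {
        "replicates": "3",
        "dilution_rate_per_h": "0.21",
        "cell_conc_per_ml": "1e7",
        "q_fmol_per_cell_h": "139",
        "gas_flow_l_per_h": "9.18",
        "liquid_volume_l": "1.5",
    }
    parser["coculture:maltose"] = {
        "replicates": "3",
        "k_het_per_h": "0.16",
        "h2_per_cell_fmol_h": "85",
        "y_ch4_cells_per_mol": "9.1e12",
        "acetate_per_cell_fmol_h": "1050",
        "t_max_h": "12",
        "n_points": "9",
    }
    parser["coculture:formate"] = {
        "replicates": "4",
        "k_het_per_h": "0.16",
        "h2_per_cell_fmol_h": "130.9",
        "y_ch4_cells_per_mol": "13.5e12",
        "acetate_per_cell_fmol_h": "0",
        "t_max_h": "12",
        "n_points": "9",
    }
    parser["growth:high_H2_batch"] = {
        "k_per_h": "1.04",
        "x0_per_ml": "1e6",
        "t_max_h": "4",
        "n_points": "9",
    }
    parser["isotope:bottle_drawdown"] = {
        "delta0_permil": "-26.1",
        "epsilon_permil": "22.1",
        "f_final": "0.12",
        "n_obs": "8",
    }
    return parser


def _child_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % 2**31)


def simulate(
    config_path=None,
    out_dir=".",
    seed: Optional[int] = None,
) -> Dict[str, List[str]]:
    """Generate the synthetic study described by a config (or the default one).

    Writes, under ``out_dir``: one TSV per generated table, a key=value
    metadata sidecar per table recording the seed and parameters, and an
    ``analysis.ini`` consumable by :func:`run_condition`.  ``seed`` overrides
    the config's base seed.  Returns a manifest mapping condition labels to
    the files written.
    """
    parser = _read_config(config_path) if config_path is not None else default_simulation_config()
    sim_opts = parser["simulate"] if parser.has_section("simulate") else {}
    base_seed = seed if seed is not None else int(sim_opts.get("seed", "1"))
    cv = float(sim_opts.get("noise_cv_counts", "0.05"))
    sigma = float(sim_opts.get("sigma_delta_permil", "0.3"))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: Dict[str, List[str]] = {}
    analysis = ConfigParser()
    index = 0

    def cfg(time_grid=None) -> SimConfig:
        nonlocal index
        child = _child_seed(base_seed, index)
        index += 1
        kwargs = dict(seed=child, noise_cv_counts=cv, sigma_delta_permil=sigma)
        if time_grid is not None:
            kwargs["time_grid_h"] = time_grid
        return SimConfig(**kwargs)

    for section in parser.sections():
        kind, _, label = section.partition(":")
        opts = parser[section]
        files: List[str] = []
        if kind == "chemostat":
            states = []
            seeds = []
            for _ in range(int(opts.get("replicates", "3"))):
                config = cfg()
                seeds.append(config.seed)
                states.append(
                    gen_chemostat_run(
                        d_per_h=float(opts["dilution_rate_per_h"]),
                        x_per_ml=float(opts["cell_conc_per_ml"]),
                        q_true_mol_per_cell_h=float(opts["q_fmol_per_cell_h"]) * 1e-15,
                        gas_flow_l_per_h=float(opts["gas_flow_l_per_h"]),
                        volume_l=float(opts["liquid_volume_l"]),
                        config=config,
                    )
                )
            table = f"{label}_chemostat.tsv"
            write_chemostat_states(states, out / table)
            write_metadata_sidecar(
                out / f"{table}.meta.txt",
                {"base_seed": base_seed, "replicate_seeds": seeds, **dict(opts)},
            )
            files.append(table)
            analysis[f"condition:{label}"] = {
                "vessel": "chemostat",
                "chemostat_table": table,
            }
        elif kind == "coculture":
            grid = np.linspace(
                0.0, float(opts.get("t_max_h", "12")), int(opts.get("n_points", "9"))
            )
            tables = []
            for rep in range(int(opts.get("replicates", "3"))):
                config = cfg(time_grid=grid)
                series = gen_coculture(
                    k_het_per_h=float(opts["k_het_per_h"]),
                    h2_per_cell_mol_h=float(opts["h2_per_cell_fmol_h"]) * 1e-15,
                    y_ch4_cells_per_mol=float(opts["y_ch4_cells_per_mol"]),
                    acetate_per_cell_mol_h=float(opts.get("acetate_per_cell_fmol_h", "0"))
                    * 1e-15,
                    config=config,
                )
                table = f"{label}_rep{rep + 1}.tsv"
                write_batch_series(series, out / table)
                write_metadata_sidecar(out / f"{table}.meta.txt", series.meta)
                tables.append(table)
            files.extend(tables)
            analysis[f"condition:{label}"] = {
                "vessel": "coculture",
                "tables": ",".join(tables),
                "growth_organism": "heterotroph",
                "product": "CH4",
            }
        elif kind == "growth":
            grid = np.linspace(
                0.0, float(opts.get("t_max_h", "4")), int(opts.get("n_points", "9"))
            )
            config = cfg(time_grid=grid)
            series = gen_batch_growth(
                k_per_h=float(opts["k_per_h"]),
                x0_per_ml=float(opts["x0_per_ml"]),
                config=config,
            )
            table = f"{label}_counts.tsv"
            write_cell_counts(series, out / table)
            write_metadata_sidecar(out / f"{table}.meta.txt", series.meta)
            files.append(table)
        elif kind == "isotope":
            config = cfg()
            df = gen_isotope_drawdown(
                delta0_permil=float(opts["delta0_permil"]),
                epsilon_permil=float(opts["epsilon_permil"]),
                f_final=float(opts["f_final"]),
                n_obs=int(opts.get("n_obs", "8")),
                config=config,
            )
            table = f"{label}_drawdown.tsv"
            df.to_csv(out / table, **_TSV_KW)
            write_metadata_sidecar(out / f"{table}.meta.txt", df.attrs["meta"])
            files.append(table)
        elif kind == "simulate":
            continue
        else:
            raise ValueError(f"unknown simulate section kind {kind!r}")
        manifest[label] = files

    if any(s.startswith("condition:") for s in analysis.sections()):
        with open(out / "analysis.ini", "w") as fh:
            analysis.write(fh)
    write_metadata_sidecar(
        out / "simulate.meta.txt",
        {"base_seed": base_seed, "noise_cv_counts": cv, "sigma_delta_permil": sigma,
         "methanofrac_version": __version__},
    )
    return manifest
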