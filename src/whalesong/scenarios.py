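"""Canned scenario configurations and batch experiment drivers.

The named scenarios mirror the study designs:

``SH``
    the 11 Southern Hemisphere populations on a west-to-east ring with
    the shipped (placeholder) demography table — the configuration the
    learning parameters are fitted against;
``SH_rerun``
    the same configuration rerun at parameters drawn from a posterior
    (stochastic replicate batches);
``SH_equal``
    all 11 populations forced to identical demography
    (N_min=100, N_2015=1000, N_K=5000) to test whether population-size
    differences set the direction of revolutions;
``SH_bottleneck``
    empirical N_min kept, N_2015 and N_K equalised at 1000/5000;
``SH_future``
    the SH configuration run for 500 years, trajectories saturating at
    carrying capacity;
``NH``
    the six Northern Hemisphere populations as two disconnected
    within-ocean cliques (Atlantic: CB, CV; Pacific: WP, HI, MX, CA),
    run at the Southern-Hemisphere-estimated learning parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import PopulationDemography
from .model_core import LearningParams
from .simulator import SimulationConfig, Topology, run_simulation
from .summary_stats import diagnostics

#: Published posterior medians of the six learning parameters (SH fit).
POSTERIOR_MEDIANS = LearningParams(
    N_t=5.11, P_n=0.001, mu=1.6e-7, L_sm=54.59, P_d=6.42, P_i=3.69
)

SH_RING_ORDER = ("BR", "GA", "MZ", "MD", "WA", "EA", "NC", "TO", "CrI", "FP", "CO")
SCENARIO_NAMES = ("SH", "SH_rerun", "SH_equal", "SH_bottleneck", "SH_future", "NH")


def _load_yaml(name: str) -> dict:
    with resources.files("whalesong.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def sh_demography_table(path: str | Path | None = None) -> dict:
    data = _load_yaml("sh_demography.yaml") if path is None else yaml.safe_load(
        Path(path).read_text()
    )
    return data["populations"]


def nh_demography() -> tuple[Topology, dict]:
    data = _load_yaml("nh_demography.yaml")
    topo = Topology.cliques([data["oceans"]["pacific"], data["oceans"]["atlantic"]])
    return topo, data["populations"]


def _demog_tuple(topology: Topology, table: dict, calibration_years: int = 50):
    out = []
    for label in topology.populations:
        row = table[label]
        out.append(
            PopulationDemography(
                label,
                float(row["N_min"]),
                float(row["N_2015"]),
                float(row["N_K"]),
                calibration_years,
            )
        )
    return tuple(out)


@dataclass
class ScenarioSpec:
    name: str
    topology: Topology
    demography: tuple
    years: int = 50
    param_source: str = "fixed"  # "fixed" | "prior" | "posterior"
    params: LearningParams = POSTERIOR_MEDIANS
    posterior_file: str | None = None
    sample_size: int = 20


def build_scenario(name: str, overrides: dict | None = None) -> ScenarioSpec:
    """Build a named scenario; ``overrides`` may rescale it.

    Recognised override keys: ``years``, ``sample_size``, ``params``
    (a :class:`LearningParams`), ``param_source``, ``posterior_file``,
    ``demography`` (label -> {N_min, N_2015, N_K}) and ``equal_sizes``
    (a (N_min, N_2015, N_K) triple applied to every population).
    """
    overrides = dict(overrides or {})
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    years = 500 if name == "SH_future" else 50
    if name == "NH":
        topology, table = nh_demography()
    else:
        topology = Topology.ring(SH_RING_ORDER)
        table = sh_demography_table()
    if name == "SH_equal":
        table = {k: {"N_min": 100, "N_2015": 1000, "N_K": 5000} for k in table}
    elif name == "SH_bottleneck":
        table = {
            k: {"N_min": v["N_min"], "N_2015": 1000, "N_K": 5000}
            for k, v in table.items()
        }
    if "demography" in overrides:
        table = overrides.pop("demography")
    if "equal_sizes" in overrides:
        n_min, n_2015, n_k = overrides.pop("equal_sizes")
        table = {k: {"N_min": n_min, "N_2015": n_2015, "N_K": n_k} for k in table}
    years = overrides.pop("years", years)
    param_source = overrides.pop(
        "param_source", "posterior" if name in ("SH_rerun",) else "fixed"
    )
    spec = ScenarioSpec(
        name=name,
        topology=topology,
        demography=_demog_tuple(topology, table),
        years=years,
        param_source=param_source,
        params=overrides.pop("params", POSTERIOR_MEDIANS),
        posterior_file=overrides.pop("posterior_file", None),
        sample_size=overrides.pop("sample_size", 20),
    )
    if overrides:
        raise ValueError(f"unknown overrides: {sorted(overrides)}")
    return spec


def make_config(
    spec: ScenarioSpec,
    seed: int,
    params: LearningParams | None = None,
    sampling_plan: dict | None = None,
) -> SimulationConfig:
    return SimulationConfig(
        topology=spec.topology,
        demography=spec.demography,
        params=params or spec.params,
        years=spec.years,
        seed=seed,
        sample_size=spec.sample_size,
        sampling_plan=sampling_plan,
    )


def _param_stream(spec: ScenarioSpec, n_runs: int, seed: int):
    """One LearningParams per run, according to the scenario's source."""
    if spec.param_source == "fixed":
        return [spec.params] * n_runs
    rng = np.random.default_rng((seed, 11))
    if spec.param_source == "prior":
        from .abc_pmc import PriorSpec, sample_prior

        prior = PriorSpec()
        return [
            prior.params_from_theta(sample_prior(prior, rng)) for _ in range(n_runs)
        ]
    if spec.param_source == "posterior":
        if spec.posterior_file is None:
            return [spec.params] * n_runs  # medians stand in for a posterior file
        df = pd.read_csv(spec.posterior_file)
        w = df["weight"].to_numpy() if "weight" in df else None
        if w is not None:
            w = w / w.sum()
        idx = rng.choice(len(df), size=n_runs, replace=True, p=w)
        return [
            LearningParams(
                *[float(df.iloc[i][k]) for k in
                  ("N_t", "P_n", "mu", "L_sm", "P_d", "P_i")]
            )
            for i in idx
        ]
    raise ValueError(f"unknown parameter source {spec.param_source!r}")


def run_batch(
    spec: ScenarioSpec,
    n_runs: int,
    seed: int = 0,
    last_years: int = 11,
    progress: bool = False,
) -> pd.DataFrame:
    """Run ``n_runs`` independent seeded simulations; one diagnostics row each."""
    params_per_run = _param_stream(spec, n_runs, seed)
    rows = []
    for i, params in enumerate(params_per_run):
        run_seed = int(np.random.default_rng((seed, 13, i)).integers(2**31))
        config = make_config(spec, seed=run_seed, params=params)
        record = run_simulation(config)
        d = diagnostics(record, last_years=last_years)
        rows.append(
            {
                "run": i,
                "seed": run_seed,
                "N_t": params.N_t,
                "P_n": params.P_n,
                "mu": params.mu,
                "L_sm": params.L_sm,
                "P_d": params.P_d,
                "P_i": params.P_i,
                "TS_FC": d.ts_fc,
                "TS_FP": d.ts_fp,
                "TS_WP": d.ts_wp,
                "TS_EP": d.ts_ep,
                "Diff": d.diff,
                "Max": d.max_ts,
                "turnover": d.turnover,
                "label": d.label,
            }
        )
        if progress and (i + 1) % 10 == 0:
            print(f"  {spec.name}: {i + 1}/{n_runs} runs", flush=True)
    return pd.DataFrame(rows)


def revolution_counts(batch: pd.DataFrame) -> dict:
    """Revolution tallies and the east-to-west proportion among labelled runs.

    An eastward label (Diff >= 0.2) is a west-to-east wave; a westward
    label (Diff <= -0.2) is an east-to-west wave.
    """
    eastward = int((batch["label"] == "eastward").sum())
    westward = int((batch["label"] == "westward").sum())
    labelled = eastward + westward
    return {
        "n_runs": len(batch),
        "eastward": eastward,
        "westward": westward,
        "labelled": labelled,
        "prop_east_to_west": westward / labelled if labelled else float("nan"),
    }
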