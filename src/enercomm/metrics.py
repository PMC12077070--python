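"""Response metrics and replicate sweeps.

Population-level disturbance metrics follow the usual
resistance/recovery decomposition: the pre-drought *baseline* is the mean
population over a window (default 30 days) before the drought starts;
*recovery time* is the number of days after the drought ends until the
population first regains that baseline (``None`` if censored at the end
of the series); *resistance* is the minimum population during or after
the drought relative to baseline.  Community summaries compare species
richness and per-species abundances between a reference day and an
evaluation day (typically one year after the drought).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import SimResult, run_simulation
from .scenarios import ScenarioConfig, replicate_seed

__all__ = ["recovery_time", "resistance", "community_summary",
           "sweep", "SweepResult"]


def recovery_time(pop_series, drought_end_day: int, baseline_window: int = 30,
                  drought_start_day: int | None = None) -> int | None:
    """Days after drought end until the population regains its baseline.

    The baseline is the mean population over ``baseline_window`` days
    before ``drought_start_day`` (before the drought end if no start is
    given).  Returns 0 if the population never fell below baseline, or
    ``None`` (censored) if it never recovers within the series.
    """
    if baseline_window < 1:
        raise ValueError("baseline_window must be >= 1")
    pop = np.asarray(pop_series, dtype=float)
    if drought_end_day >= len(pop):
        raise ValueError("series does not cover drought_end_day")
    ref = drought_start_day if drought_start_day is not None else drought_end_day
    baseline = pop[max(0, ref - baseline_window):ref].mean()
    after = pop[drought_end_day:]
    hits = np.flatnonzero(after >= baseline)
    return int(hits[0]) if hits.size else None


def resistance(pop_series, drought_span: tuple[int, int], baseline: float) -> float:
    """Minimum population during/after the drought relative to baseline.

    ``drought_span`` is (start, end) in days; the minimum is taken from
    the drought start to the end of the series and floored at 0 (a value
    slightly above 1 is possible for populations that never decline).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    pop = np.asarray(pop_series, dtype=float)
    start, _ = drought_span
    return float(max(0.0, pop[start:].min() / baseline))


def community_summary(result_or_pop, reference_day: int, eval_day: int) -> dict:
    """Richness and abundance ratios between two days of one run.

    Accepts a :class:`~enercomm.engine.SimResult` or a (days, S)
    population matrix.  Richness counts species with at least one living
    individual; abundance ratios are per-species eval/reference counts
    (``inf`` for species absent at reference but present at eval never
    occurs in a closed community, so absent-at-reference species report
    ``nan``).
    """
    pop = (result_or_pop.population if isinstance(result_or_pop, SimResult)
           else np.asarray(result_or_pop))
    days = pop.shape[0]
    if not (0 <= reference_day < days and 0 <= eval_day < days):
        raise ValueError("days outside the series")
    ref = pop[reference_day].astype(float)
    ev = pop[eval_day].astype(float)
    ref_rich = int((ref > 0).sum())
    if ref_rich == 0:
        raise ValueError("reference-day richness is zero")
    ratios = np.divide(ev, ref, out=np.full_like(ref, np.nan), where=ref > 0)
    return {
        "richness_ratio": int((ev > 0).sum()) / ref_rich,
        "abundance_ratios": ratios,
        "reference_richness": ref_rich,
        "eval_richness": int((ev > 0).sum()),
    }


@dataclass
class SweepResult:
    runs: list[SimResult]
    table: pd.DataFrame        # one row per run
    aggregate: pd.DataFrame    # replicate means/dispersion per scenario


def _run_row(res: SimResult) -> dict:
    cfg = res.config
    row = {
        "scenario_id": cfg.scenario_id or "scenario",
        "seed": cfg.seed,
        "fragmentation": cfg.fragmentation,
        "behaviour": cfg.behaviour,
        "magnitude": cfg.events[0].magnitude if cfg.events else 0.0,
        "length": cfg.events[0].length_days if cfg.events else 0,
        "final_richness": res.richness(),
        "total_population": int(res.population[-1].sum()),
    }
    return row


def sweep(configs: list[ScenarioConfig], replicates: int | None = None,
          workers: int = 1, audit: bool = False,
          keep_results: bool = True) -> SweepResult:
    """Run many scenarios (optionally replicated) and aggregate over replicates.

    With ``replicates`` given, each config is expanded into that many runs
    with seeds derived from its ``scenario_id`` and the replicate index.
    Duplicate (scenario_id, seed) pairs are rejected.  Results are
    independent of worker count and execution order: every run's outcome
    is fixed by its own seed, and aggregation is order-insensitive.
    """
    if not configs:
        raise ValueError("need at least one config")
    expanded: list[ScenarioConfig] = []
    for cfg in configs:
        if replicates:
            sid = cfg.scenario_id or "scenario"
            expanded.extend(replace(cfg, seed=replicate_seed(sid, r))
                            for r in range(1, replicates + 1))
        else:
            expanded.append(cfg)
    keys = [(c.scenario_id, c.seed) for c in expanded]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (scenario_id, seed) pairs in sweep")
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(run_simulation)(c, audit) for c in expanded)
    else:
        results = [run_simulation(c, audit) for c in expanded]
    table = pd.DataFrame([_run_row(r) for r in results])
    aggregate = (table
                 .groupby("scenario_id")
                 .agg(n_runs=("seed", "size"),
                      mean_richness=("final_richness", "mean"),
                      sd_richness=("final_richness", "std"),
                      mean_population=("total_population", "mean"))
                 .reset_index())
    return SweepResult(runs=results if keep_results else [],
                       table=table, aggregate=aggregate)
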