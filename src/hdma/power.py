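"""Monte-Carlo power / type-I-error study harness.

Runs generate -> test -> per-mediator rejection over seeded replications for
a grid of (n, k, rho, c_prime) scenarios and both testing methods, and
aggregates per-mediator rejection rates.  Under the default coefficient
design mediators 1-4 carry true indirect effects (their rates are power)
while mediators 5-8 and the remaining k-8 are nulls (their rates are type-I
error); the mean rate over the k-8 trailing nulls is reported as
``m_other``.

Seeds are derived deterministically from (seed_base, cell, replication), so
results are independent of worker count and execution order, and both
methods see identical datasets within a cell (paired comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .hima import hima_test
from .mediation import TestConfig, hdma_test
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PowerTable", "replication_seed", "run_replication", "run_power_study"]

_METHODS = {"hdma": hdma_test, "hima": hima_test}


@dataclass(frozen=True)
class PowerTable:
    """Aggregated rejection rates for one (scenario, method) cell."""

    n: int
    k: int
    rho: float
    c_prime: float
    method: str
    rates: np.ndarray  # per-mediator rejection rate, length k
    m_other: float  # mean rate over mediators 9..k
    reps: int
    failures: int
    seed_base: int

    @property
    def mc_se(self) -> np.ndarray:
        """Per-mediator Monte-Carlo standard error sqrt(r(1-r)/reps)."""
        return np.sqrt(self.rates * (1.0 - self.rates) / max(self.reps, 1))

    def leading(self, m: int = 8) -> dict:
        return {f"M{i + 1}": float(self.rates[i]) for i in range(min(m, self.k))}


def replication_seed(seed_base: int, cell_index: int, rep: int) -> int:
    """Deterministic per-replication seed, shared by both methods."""
    ss = np.random.SeedSequence([int(seed_base), int(cell_index), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_replication(config: SimulationConfig, method: str = "hdma",
                    seed: int | None = None,
                    test_config: TestConfig | None = None) -> np.ndarray:
    """One generate -> test pass; returns the length-k 0/1 rejection vector.

    Mediators not retained by the screening step count as non-rejections.
    """
    if seed is not None:
        config = config.with_seed(seed)
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {set(_METHODS)}")
    data = simulate_dataset(config)
    result = _METHODS[method](
        data.X, data.M, data.Y, family=config.family, config=test_config
    )
    rejected = np.zeros(config.k, dtype=int)
    rejected[result.significant] = 1
    return rejected


def _run_cell(cell_index, scenario: SimulationConfig, methods, reps, seed_base,
              test_config, n_jobs):
    seeds = [replication_seed(seed_base, cell_index, r) for r in range(reps)]

    def one(seed):
        out = {}
        data = simulate_dataset(scenario.with_seed(seed))
        for method in methods:
            try:
                res = _METHODS[method](
                    data.X, data.M, data.Y,
                    family=scenario.family, config=test_config,
                )
                rej = np.zeros(scenario.k, dtype=int)
                rej[res.significant] = 1
                out[method] = rej
            except Exception as err:
                logger.warning("replication seed=%d method=%s failed: %s",
                               seed, method, err)
                out[method] = None
        return out

    if n_jobs == 1:
        results = [one(s) for s in seeds]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in seeds)

    tables = []
    for method in methods:
        rej = [r[method] for r in results if r[method] is not None]
        failures = reps - len(rej)
        if failures > 0.02 * reps:
            logger.warning(
                "cell %s method %s: %d/%d replications failed",
                cell_index, method, failures, reps,
            )
        stack = np.vstack(rej) if rej else np.zeros((0, scenario.k), dtype=int)
        rates = stack.mean(axis=0) if len(stack) else np.full(scenario.k, np.nan)
        m_other = float(rates[8:].mean()) if scenario.k > 8 else float("nan")
        tables.append(
            PowerTable(
                n=scenario.n, k=scenario.k, rho=scenario.rho,
                c_prime=scenario.c_prime, method=method,
                rates=rates, m_other=m_other, reps=len(stack),
                failures=failures, seed_base=seed_base,
            )
        )
    return tables


def run_power_study(grid, reps=200, methods=("hdma", "hima"), seed_base=0,
                    n_workers=1, test_config: TestConfig | None = None,
                    family="binary") -> list[PowerTable]:
    """Run the replication study over a scenario grid.

    ``grid`` is an iterable of dicts with keys among {n, k, rho, c_prime}
    (or ready-made SimulationConfig objects).  Replication seeds derive from
    ``seed_base`` and the cell position only, so the output is invariant to
    ``n_workers``; both methods are evaluated on identical datasets.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(methods) - set(_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {unknown}")
    tables = []
    for ci, cell in enumerate(grid):
        if isinstance(cell, SimulationConfig):
            scenario = cell
        else:
            scenario = SimulationConfig(family=family, **cell)
        tables.extend(
            _run_cell(ci, scenario, list(methods), reps, seed_base,
                      test_config, n_workers)
        )
    return tables


def tables_to_long(tables: list[PowerTable]) -> pd.DataFrame:
    """Long-format frame: one row per (cell, method, mediator 1-8 or other)."""
    rows = []
    for t in tables:
        for i in range(min(8, t.k)):
            rows.append(
                dict(n=t.n, k=t.k, rho=t.rho, c_prime=t.c_prime, method=t.method,
                     mediator=f"M{i + 1}", rate=t.rates[i],
                     mc_se=t.mc_se[i], reps=t.reps)
            )
        rows.append(
            dict(n=t.n, k=t.k, rho=t.rho, c_prime=t.c_prime, method=t.method,
                 mediator="M_other", rate=t.m_other,
                 mc_se=float(np.sqrt(max(t.m_other * (1 - t.m_other), 0) / max(t.reps, 1))),
                 reps=t.reps)
        )
    return pd.DataFrame(rows)


def tables_to_wide(tables: list[PowerTable]) -> pd.DataFrame:
    """Wide frame shaped like the usual power/type-I summary table."""
    rows = []
    for t in tables:
        row = dict(n=t.n, k=t.k, rho=t.rho, c_prime=t.c_prime,
                   method=t.method.upper(), reps=t.reps)
        row.update(t.leading(8))
        row["M_other"] = t.m_other
        rows.append(row)
    return pd.DataFrame(rows)
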