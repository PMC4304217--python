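"""Simulation-study orchestration: repeated simulate -> test -> evaluate runs.

Each cell of the study is a (method, sample size) pair; ``n_reps``
datasets are simulated per sample size and every requested method is run
on the same datasets, so methods are compared on identical inputs.
Per-repetition seeds are a pure function of (base_seed, sample size,
repetition index), so any single cell reproduces exactly in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import run_noiseq_like, run_shgt
from .core import LFCseqConfig, run_lfcseq
from .evaluate import evaluate_result
from .simulate import SimulationParams, simulate_sim1, simulate_sim2

__all__ = ["BenchConfig", "rep_seed", "run_bench"]

_METHODS = {
    "lfcseq": run_lfcseq,
    "noiseq-like": run_noiseq_like,
    "shgt": run_shgt,
}


@dataclass
class BenchConfig:
    methods: tuple = ("lfcseq", "noiseq-like")
    sample_sizes: tuple = ((2, 2), (5, 5), (8, 8))
    n_reps: int = 20
    base_seed: int = 1
    sim_design: str = "sim1"            # "sim1" | "sim2"
    sim_params: SimulationParams = field(default_factory=SimulationParams)
    param_table: pd.DataFrame | None = None
    test_config: LFCseqConfig = field(default_factory=LFCseqConfig)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.sim_design not in ("sim1", "sim2"):
            raise ValueError("sim_design must be 'sim1' or 'sim2'")
        if self.sim_design == "sim2" and self.param_table is None:
            raise ValueError("sim2 needs a parameter table")


def rep_seed(base_seed: int, n_a: int, n_b: int, rep: int) -> int:
    """Deterministic per-repetition seed, below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(n_a), int(n_b), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_bench(c: BenchConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the study; returns (summary, per_rep) tables.

    ``per_rep`` has one row per method x sample size x repetition with
    AUC, precision, sensitivity and F-score; ``summary`` aggregates mean
    and sd of AUC plus mean PRE/SEN/FS (NaN-aware) per cell.
    """
    records = []
    for n_a, n_b in c.sample_sizes:
        for rep in range(c.n_reps):
            seed = rep_seed(c.base_seed, n_a, n_b, rep)
            sp = replace(c.sim_params, n_A=n_a, n_B=n_b, seed=seed)
            if c.sim_design == "sim1":
                ds = simulate_sim1(sp)
            else:
                ds = simulate_sim2(c.param_table, sp)
            tc = replace(c.test_config, seed=seed)
            for method in c.methods:
                res = _METHODS[method](ds.counts, ds.design, tc)
                rep_eval = evaluate_result(res, ds.truth)
                records.append(
                    {
                        "method": method,
                        "n_A": n_a,
                        "n_B": n_b,
                        "rep": rep,
                        "seed": seed,
                        "auc": rep_eval.auc,
                        "pre": rep_eval.pre,
                        "sen": rep_eval.sen,
                        "fs": rep_eval.fs,
                    }
                )
    per_rep = pd.DataFrame.from_records(records)
    summary = (
        per_rep.groupby(["method", "n_A", "n_B"], sort=False)
        .agg(
            mean_auc=("auc", "mean"),
            sd_auc=("auc", "std"),
            mean_pre=("pre", "mean"),
            mean_sen=("sen", "mean"),
            mean_fs=("fs", "mean"),
            n_reps=("rep", "count"),
        )
        .reset_index()
    )
    return summary, per_rep
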