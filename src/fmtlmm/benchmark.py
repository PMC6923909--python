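"""Power / false-positive benchmark harness over replicate grids.

For every grid cell (n_s, n_r) and run, a dataset is simulated with a
counter-derived child seed, fitted once, and every requested method is scored
against the ground truth: power = (rejected true-DE genes)/n_de and fp = number
of rejected null genes.  Aggregates report the mean and Monte-Carlo standard
error over runs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .comparators import dream_like_test, limma_like_test
from .inference import moderated_t_test
from .model_fit import fit_balanced_anova
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["METHODS", "power_and_fp", "run_single", "run_benchmark"]

METHODS = ("FMT-VC", "FMT-Sat", "OT-VC", "OT-Sat", "Limma-like", "Dream-like")

_CANON = {m.lower(): m for m in METHODS}


def canonical_method(name: str) -> str:
    key = name.lower().replace("_", "-")
    if key not in _CANON:
        raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
    return _CANON[key]


def power_and_fp(results: pd.DataFrame, truth: pd.DataFrame) -> tuple:
    """Score one method's results table against ground-truth DE flags.

    ``truth`` needs columns gene_id and is_de; the tables are aligned by
    gene_id and must cover identical gene sets.
    """
    merged = results.merge(truth[["gene_id", "is_de"]], on="gene_id", how="inner",
                           validate="one_to_one")
    if len(merged) != len(results) or len(merged) != len(truth):
        raise ValueError("results and truth gene_ids are misaligned")
    n_de = int(merged["is_de"].sum())
    rej = merged["rejected"].to_numpy(dtype=bool)
    is_de = merged["is_de"].to_numpy(dtype=bool)
    power = float((rej & is_de).sum() / n_de) if n_de else 0.0
    fp = int((rej & ~is_de).sum())
    return power, fp


def derive_seed(master_seed: int, n_s: int, n_r: int, run: int) -> int:
    """Counter-based per-run seed: reproducible for any grid cell in isolation."""
    ss = np.random.SeedSequence([int(master_seed), int(n_s), int(n_r), int(run)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_single(methods: Sequence[str], config: SimulationConfig, k: float = 5.0,
               span: float = 0.4) -> dict:
    """Simulate one dataset and score every method on it.

    Returns {method: (power, fp)}.  The per-gene fits and the FMT shrinkage are
    computed once and shared between methods that use them.
    """
    methods = [canonical_method(m) for m in methods]
    ds = simulate_dataset(config)
    truth = ds.truth_frame()
    fits = fit_balanced_anova(ds.Y, ds.design, gene_ids=ds.gene_ids)

    fmt_hyper = {}
    out = {}
    for m in methods:
        if m in ("FMT-VC", "FMT-Sat"):
            if not fmt_hyper:
                from .ebayes import estimate_hyperparameters

                fmt_hyper["e"] = estimate_hyperparameters(fits.s2_e, fits.d_e,
                                                          fits.alpha_hat, span=span)
                fmt_hyper["r"] = estimate_hyperparameters(fits.s2_r, fits.d_r,
                                                          fits.alpha_hat, span=span)
            res = moderated_t_test(fits, method=m, k=k, span=span,
                                   hyper_e=fmt_hyper["e"], hyper_r=fmt_hyper["r"])
        elif m in ("OT-VC", "OT-Sat"):
            res = moderated_t_test(fits, method=m, k=k)
        elif m == "Limma-like":
            res = limma_like_test(ds.Y, ds.design, k=k, gene_ids=ds.gene_ids)
        else:
            res = dream_like_test(fits=fits, k=k)
        out[m] = power_and_fp(res, truth)
    return out


def run_benchmark(ns_list: Iterable[int], nr_list: Iterable[int],
                  methods: Sequence[str] = METHODS, runs: int = 100, k: float = 5.0,
                  seed: int = 0, n_genes: int = 12000, n_de: int = 500,
                  span: float = 0.4, block_size=None, rho: float = 0.5) -> pd.DataFrame:
    """Run the full grid and aggregate.

    Output columns: method, n_s, n_r, runs, mean_power, se_power, mean_fp, se_fp.
    Deterministic under the master seed; failed runs are logged, excluded from
    the aggregates and counted in the `runs` column actually used.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    methods = [canonical_method(m) for m in methods]
    rows = []
    for n_s in ns_list:
        for n_r in nr_list:
            per_method: dict = {m: {"power": [], "fp": []} for m in methods}
            for run in range(runs):
                cfg = SimulationConfig(
                    n_genes=n_genes, n_de=n_de, n_s=n_s, n_r=n_r,
                    seed=derive_seed(seed, n_s, n_r, run),
                    block_size=block_size, rho=rho,
                )
                try:
                    scores = run_single(methods, cfg, k=k, span=span)
                except Exception:  # noqa: BLE001 - a failed run must not kill the grid
                    logger.warning("run %d failed at n_s=%d n_r=%d; excluded",
                                   run, n_s, n_r, exc_info=True)
                    continue
                for m, (power, fp) in scores.items():
                    per_method[m]["power"].append(power)
                    per_method[m]["fp"].append(fp)
            for m in methods:
                pw = np.asarray(per_method[m]["power"], dtype=float)
                fp = np.asarray(per_method[m]["fp"], dtype=float)
                n_ok = len(pw)
                if n_ok < runs:
                    logger.warning("n_s=%d n_r=%d method=%s: only %d/%d runs usable",
                                   n_s, n_r, m, n_ok, runs)
                rows.append(
                    {
                        "method": m,
                        "n_s": n_s,
                        "n_r": n_r,
                        "runs": n_ok,
                        "mean_power": pw.mean() if n_ok else np.nan,
                        "se_power": pw.std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else np.nan,
                        "mean_fp": fp.mean() if n_ok else np.nan,
                        "se_fp": fp.std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
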