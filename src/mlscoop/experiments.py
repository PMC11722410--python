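"""Scripted computational experiments: survival maps, competition heatmaps,
and the extinction-through-sociality scenario.

Every sweep cell is an independent job with a seed derived deterministically
from (root seed, cell index); re-running with the same configuration is
bit-exact.  Results are plain long-format DataFrames (written as CSV by the
CLI together with a JSON manifest); analytic overlay curves come from
:mod:`mlscoop.analytics` and never from the simulation output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from . import analytics
from .simulator import (
    SimConfig,
    composition_statistic,
    run_replicates,
    s_statistic,
    theta_mean,
)

__all__ = [
    "cell_seed",
    "sweep_theta",
    "sweep_S",
    "sweep_KNg",
    "scenario_extinction_by_sociality",
    "predicted_regime",
    "observed_regime",
    "write_outputs",
]


def cell_seed(root_seed: int, *cell_index: int) -> int:
    """Deterministic per-cell seed below 2^31."""
    ss = np.random.SeedSequence(root_seed, spawn_key=tuple(cell_index))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def sweep_theta(
    mu_grid: Iterable[float],
    K_grid: Iterable[int],
    *,
    Ng: int,
    Kg: int,
    b: float = 1.0,
    M: int = 50,
    T: int = 1000,
    seed: int = 0,
    engine: str = "numba",
) -> pd.DataFrame:
    """Survival map: mean extinction indicator <Theta> over a (mu, K) grid in
    the neutral case (single-type groups, no social trait).

    Adds the analytic threshold overlays per K: ``mu_star_highdelta`` from the
    closed-form proliferation relation and ``mu_star_numeric`` from the exact
    psi-average root (NaN where out of regime).
    """
    rows = []
    for i, K in enumerate(K_grid):
        try:
            mu_hd = analytics.neutral_threshold(int(K), b, Ng=Ng)
        except ValueError:
            mu_hd = np.nan
        try:
            mu_num = analytics.solve_threshold_numeric(int(K), Ng, b)
            mu_num = mu_num if mu_num <= 1.0 else np.nan
        except ValueError:
            mu_num = np.nan
        for j, mu in enumerate(mu_grid):
            cfg = SimConfig.create(
                K=int(K), b=b, mu=float(mu), a=0.0, Kg=Kg, mode="neutral",
                T=T, M=M, seed=cell_seed(seed, i, j),
                init_mode="neutral_uniform", Ng=Ng,
                record_every=0, engine=engine,
            )
            trajs = run_replicates(cfg)
            rows.append(
                dict(mu=float(mu), K=int(K), theta=theta_mean(trajs),
                     n_replicates=M, mu_star_highdelta=mu_hd,
                     mu_star_numeric=mu_num)
            )
    return pd.DataFrame(rows)


def sweep_S(
    a_grid: Iterable[float],
    b_grid: Iterable[float],
    *,
    mu: float,
    K: int,
    Ng: int,
    NgA: int,
    Kg: int,
    mode: str = "relative",
    init: Literal["homogeneous_mix", "heterogeneous"] = "homogeneous_mix",
    M: int = 50,
    T: int = 3000,
    seed: int = 0,
    engine: str = "numba",
) -> pd.DataFrame:
    """Competition heatmap over (a, b): mean of the all-A-group excess S for
    homogeneous initialisation, or of the individual-composition excess for
    heterogeneous initialisation, at sampling time T (extinct runs count 0)."""
    stat = s_statistic if init == "homogeneous_mix" else composition_statistic
    rows = []
    for i, a in enumerate(a_grid):
        for j, b in enumerate(b_grid):
            kwargs = dict(init_mode=init)
            if init == "homogeneous_mix":
                kwargs.update(NgA=NgA, NgB=Ng - NgA)
            else:
                kwargs.update(Ng=Ng)
            cfg = SimConfig.create(
                K=K, b=float(b), mu=mu, a=float(a), Kg=Kg, mode=mode,
                T=T, M=M, seed=cell_seed(seed, i, j),
                record_every=0, engine=engine, **kwargs,
            )
            trajs = run_replicates(cfg)
            svals = [stat(t.final) for t in trajs]
            rows.append(
                dict(a=float(a), b=float(b), mean_S=float(np.mean(svals)),
                     theta=theta_mean(trajs), n_replicates=M)
            )
    return pd.DataFrame(rows)


def sweep_KNg(
    K_grid: Iterable[int],
    Ng_grid: Iterable[int],
    *,
    mu: float,
    a: float,
    b: float,
    Kg: int,
    mode: str = "relative",
    M: int = 50,
    T: int = 5000,
    seed: int = 0,
    engine: str = "numba",
) -> pd.DataFrame:
    """Competition outcome over (K, Ng) with NgA = floor(Ng/2), plus the
    numeric and high-survival threshold group numbers for each K."""
    rows = []
    for i, K in enumerate(K_grid):
        K = int(K)
        H = analytics.harmonic(K - 1)
        # high-survival thresholds: Ng solving psi_A = 1/2 (b = 1) and
        # psi_B = 1/2 at NgA = Ng/2
        C = 2.0 * mu * H * K**2
        if mode == "relative":
            ng_A_hd = C * (1.0 - a) / ((K - 1) * (1.0 - a / 2.0))
            ng_B_hd = C / ((K - 1) * b * (1.0 - a / 2.0))
        else:
            ng_A_hd = C * (1.0 - a) / (K - 1)
            ng_B_hd = C / ((K - 1) * b)
        try:
            ng_A_num = analytics.psi_half_ng(mode, mu, K, 1.0, "A", a)
        except ValueError:
            ng_A_num = np.nan
        try:
            ng_B_num = analytics.psi_half_ng(mode, mu, K, b, "B", a)
        except ValueError:
            ng_B_num = np.nan
        for j, Ng in enumerate(Ng_grid):
            Ng = int(Ng)
            NgA = Ng // 2
            cfg = SimConfig.create(
                K=K, b=b, mu=mu, a=a, Kg=Kg, mode=mode,
                T=T, M=M, seed=cell_seed(seed, i, j),
                init_mode="homogeneous_mix", NgA=NgA, NgB=Ng - NgA,
                record_every=0, engine=engine,
            )
            trajs = run_replicates(cfg)
            svals = [s_statistic(t.final) for t in trajs]
            rows.append(
                dict(K=K, Ng=Ng, NgA=NgA, mean_S=float(np.mean(svals)),
                     theta=theta_mean(trajs), n_replicates=M,
                     ng_star_A_numeric=ng_A_num, ng_star_B_numeric=ng_B_num,
                     ng_star_A_highdelta=ng_A_hd, ng_star_B_highdelta=ng_B_hd)
            )
    return pd.DataFrame(rows)


def predicted_regime(
    a: float, b: float, *, mu: float, K: int, Ng: float, NgA: float, mode: str
) -> str:
    """Analytic regime from the initial-composition proliferation
    probabilities: social when both types can proliferate, asocial when only
    the asocial type can, extinct otherwise (including the
    cooperators-homogenize-then-die case)."""
    dA, dB = analytics.survival_probs(mode, Ng, NgA, mu, a)
    psiA = analytics.psi_avg(analytics.SurvivalContext(dA, K, 1.0))
    psiB = analytics.psi_avg(analytics.SurvivalContext(dB, K, b))
    if psiA > 0.5 and psiB > 0.5:
        return "social"
    if psiB > 0.5:
        return "asocial"
    return "extinct"


def observed_regime(theta: float, mean_S: float) -> str:
    """Empirical regime of one sweep cell: extinct when most replicates died,
    otherwise the sign of the mean outcome statistic decides."""
    if theta < 0.5:
        return "extinct"
    return "social" if mean_S > 0 else "asocial"


def scenario_extinction_by_sociality(
    *,
    mu: float = 0.5,
    a: float = 0.75,
    b: float = 4.0,
    K: int = 20,
    Ng: int = 30,
    Kg: int = 45,
    M: int = 50,
    T: int = 5000,
    seed: int = 0,
    record_every: int = 10,
    engine: str = "numba",
    warn=print,
) -> dict:
    """Resource-limited scenario: the carrying capacity supports an asocial
    but not a social homogeneous population, so cooperator success drags the
    whole population to extinction.

    Runs three initialisations (all-B only, even homogeneous mix,
    heterogeneous) and returns their trajectories plus summary statistics.
    The precondition psiB(Kg) > 1/2 > psiA(Kg) is checked with the analytic
    module; a violation for user-supplied parameters is reported via ``warn``
    but the scenario still runs.
    """
    delta_at_kg = 1.0 - mu / Kg
    psiA = analytics.psi_avg(analytics.SurvivalContext(delta_at_kg, K, 1.0))
    psiB = analytics.psi_avg(analytics.SurvivalContext(delta_at_kg, K, b))
    precondition = psiB > 0.5 > psiA
    if not precondition:
        warn(
            f"precondition violated: psiB={psiB:.3f}, psiA={psiA:.3f} "
            "(expected psiB > 1/2 > psiA at carrying capacity)"
        )

    def _run(init_mode, **kw):
        cfg = SimConfig.create(
            K=K, b=b, mu=mu, a=a, Kg=Kg, mode="relative",
            T=T, M=M, seed=cell_seed(seed, hash(init_mode) & 0xFFFF),
            init_mode=init_mode, record_every=record_every, engine=engine, **kw,
        )
        return run_replicates(cfg)

    half = Ng // 2
    runs = {
        "all_B": _run("homogeneous_mix", NgA=0, NgB=Ng),
        "mixed": _run("homogeneous_mix", NgA=half, NgB=Ng - half),
        "heterogeneous": _run("heterogeneous", Ng=Ng),
    }
    summary = {
        name: dict(
            extinction_fraction=float(np.mean([not t.surviving for t in trajs])),
            mean_final_ng=float(np.mean([t.final.ng for t in trajs])),
        )
        for name, trajs in runs.items()
    }
    return dict(
        runs=runs,
        summary=summary,
        precondition_ok=bool(precondition),
        psiA_at_Kg=float(psiA),
        psiB_at_Kg=float(psiB),
    )


def mean_b_fraction(trajs) -> pd.DataFrame:
    """Mean asocial individual fraction over time across replicates (extinct
    replicates drop out of the average once empty)."""
    frames = []
    for t in trajs:
        df = t.to_dataframe()
        tot = df["sum_nA"] + df["sum_nB"]
        df = df[tot > 0].copy()
        df["b_fraction"] = df["sum_nB"] / (df["sum_nA"] + df["sum_nB"])
        frames.append(df[["t", "b_fraction"]])
    allf = pd.concat(frames)
    return allf.groupby("t", as_index=False)["b_fraction"].mean()


def write_outputs(
    df: pd.DataFrame,
    outdir: str | Path,
    name: str,
    manifest: Optional[dict] = None,
) -> Path:
    """Write a sweep result as CSV plus a JSON manifest sufficient for
    bit-exact re-execution."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{name}.csv"
    df.to_csv(csv_path, index=False)
    if manifest is not None:
        manifest = {k: _jsonable(v) for k, v in manifest.items()}
        (outdir / f"{name}.manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return csv_path


def _jsonable(v):
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return dataclasses.asdict(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
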