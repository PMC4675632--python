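"""Preset simulation experiments.

Five bundled experiments probe the model, each pairing a shipped task
preset with the single shared agent configuration:

1. ``sim1`` — goal-directed learning alone (Pavlovian side observes but
   cannot act): action values converge to the expected value of each
   action, Pavlovian values to the realized shock rate per cue.
2. ``sim2`` — full competition: a cue whose best action still usually
   shocks falls into a vicious circle and ends under Pavlovian control.
3. ``sim3`` — specific controllability: equal best-case shock probability,
   but only one cue offers an action better than the others.
4. ``sim4`` — generalised controllability / learned helplessness: short
   vs long uncontrollable pre-training, then a novel controllable context,
   with the two agents yoked to identical test-block random streams.
5. ``sim5`` — threat distance: the signalled cue-to-shock delay (3 s vs
   30 s) shifts control toward the goal-directed system when the threat
   is far.

Every summary statistic here is a pure function of the raw per-trial
records, so results can be re-derived from the trace CSVs alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .agent import AgentConfig, records_to_frame, run_task
from .arbitration import ArbitrationParams
from .environment import Block, TaskSpec

__all__ = [
    "PRESETS",
    "load_task",
    "default_config",
    "ExperimentResult",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "run_sim4",
    "run_sim5",
    "run_experiment",
    "final_window_mean",
    "window_mean",
    "sign_test",
    "moving_average",
]

PRESETS = ("sim1", "sim2", "sim3", "sim4", "sim5", "sim5_textvariant")


def load_task(name: str, n_trials: int | None = None) -> TaskSpec:
    """Load a shipped task preset, optionally overriding the trial count.

    For single-block (randomised-cue) tasks ``n_trials`` replaces the block
    length; for the two-block helplessness task it is not applicable (use
    :func:`run_sim4`'s block-length arguments instead).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
    ref = resources.files("aversim.presets").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as path:
        spec = TaskSpec.from_yaml(path)
    if n_trials is not None:
        if len(spec.blocks) != 1:
            raise ValueError("n_trials override only applies to single-block tasks")
        b = spec.blocks[0]
        spec = spec.with_blocks([Block(b.cue, int(n_trials), b.novel_context)])
    return spec


def default_config(gd_only: bool = False, **overrides) -> AgentConfig:
    """The single shared agent configuration used by all experiments.

    Only the manipulated variables ever differ between simulations
    (``gd_only`` for sim 1, block lengths for sim 4, the delay channel for
    sim 5); everything else is held fixed.
    """
    arb = overrides.pop("arbitration", ArbitrationParams(gd_only=gd_only))
    return AgentConfig(arbitration=arb, **overrides)


@dataclass
class ExperimentResult:
    """Raw trace plus per-seed summary of one experiment."""

    name: str
    records: pd.DataFrame  # one row per (seed, trial)
    summary: pd.DataFrame  # one row per seed (or seed pair)
    config: AgentConfig

    def seed_mean(self) -> pd.Series:
        return self.summary.mean(numeric_only=True)


def _seeds(base_seed: int, n_seeds: int) -> list[int]:
    """Independent per-run seeds derived from one base seed (kept < 2^31)."""
    state = np.random.SeedSequence(base_seed).generate_state(n_seeds)
    return [int(s) % 2**31 for s in state]


def _run_many(
    spec: TaskSpec, config: AgentConfig, seeds: list[int], preserve_gc: bool = True
) -> pd.DataFrame:
    frames = []
    for s in seeds:
        _, records = run_task(spec, config, seed=s, preserve_gc=preserve_gc)
        df = records_to_frame(records)
        df.insert(0, "seed", s)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def window_mean(
    df: pd.DataFrame, col: str, lo: float, hi: float, cue: str | None = None
) -> float:
    """Mean of a column over the [lo, hi) fraction of the trial range,
    optionally restricted to one cue's trials."""
    n = df["trial_index"].max() + 1
    sel = (df["trial_index"] >= lo * n) & (df["trial_index"] < hi * n)
    if cue is not None:
        sel &= df["cue"] == cue
    return float(df.loc[sel, col].mean())


def final_window_mean(
    df: pd.DataFrame, col: str, cue: str | None = None, frac: float = 0.2
) -> float:
    """Mean of a column over the final ``frac`` of trials (the asymptote)."""
    return window_mean(df, col, 1.0 - frac, 1.0 + 1e-9, cue=cue)


def sign_test(diffs, alternative: str = "greater") -> float:
    """One-sided sign test p-value that the paired differences are positive."""
    diffs = np.asarray(list(diffs), dtype=float)
    n_pos = int((diffs > 0).sum())
    n = int((diffs != 0).sum())
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_pos, n, 0.5, alternative=alternative).pvalue)


def moving_average(x, window: int = 25) -> np.ndarray:
    """Trailing moving average used for plotting trajectories."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    c = np.cumsum(np.insert(x, 0, 0.0))
    for i in range(len(x)):
        j = max(0, i - window + 1)
        out[i] = (c[i + 1] - c[j]) / (i + 1 - j)
    return out


# ---------------------------------------------------------------------
# the five experiments
# ---------------------------------------------------------------------


def run_sim1(
    n_seeds: int = 20,
    n_trials: int = 1000,
    base_seed: int = 0,
    config: AgentConfig | None = None,
) -> ExperimentResult:
    """Goal-directed control alone (gd_only mode).

    Summary per seed: asymptotic action values of the best action under
    each cue and asymptotic Pavlovian values per cue.
    """
    spec = load_task("sim1", n_trials=n_trials)
    config = config or default_config(gd_only=True)
    records = _run_many(spec, config, _seeds(base_seed, n_seeds))
    rows = []
    for seed, df in records.groupby("seed"):
        rows.append(
            {
                "seed": seed,
                "q_lever_press_red": final_window_mean(df, "q_lever_press", "red"),
                "q_chain_pull_black": final_window_mean(df, "q_chain_pull", "black"),
                "pv_red": final_window_mean(df, "pv_post", "red"),
                "pv_black": final_window_mean(df, "pv_post", "black"),
            }
        )
    return ExperimentResult("sim1", records, pd.DataFrame(rows), config)


def run_sim2(
    n_seeds: int = 20,
    n_trials: int = 1000,
    base_seed: int = 0,
    config: AgentConfig | None = None,
) -> ExperimentResult:
    """Full goal-directed / Pavlovian competition.

    Summary per seed: first- and last-quintile mean probability of
    goal-directed control per cue.
    """
    spec = load_task("sim2", n_trials=n_trials)
    config = config or default_config()
    records = _run_many(spec, config, _seeds(base_seed, n_seeds))
    rows = []
    for seed, df in records.groupby("seed"):
        rows.append(
            {
                "seed": seed,
                "p_gd_red_first": window_mean(df, "p_goal_directed", 0.0, 0.2, "red"),
                "p_gd_red_final": final_window_mean(df, "p_goal_directed", "red"),
                "p_gd_black_first": window_mean(df, "p_goal_directed", 0.0, 0.2, "black"),
                "p_gd_black_final": final_window_mean(df, "p_goal_directed", "black"),
                "pv_black_final": final_window_mean(df, "pv_post", "black"),
            }
        )
    return ExperimentResult("sim2", records, pd.DataFrame(rows), config)


def run_sim3(
    n_seeds: int = 20,
    n_trials: int = 1000,
    base_seed: int = 0,
    config: AgentConfig | None = None,
) -> ExperimentResult:
    """Specific-controllability contrast at matched shock probability.

    Summary per seed: asymptotic SC and probability of goal-directed
    control per cue.
    """
    spec = load_task("sim3", n_trials=n_trials)
    config = config or default_config()
    records = _run_many(spec, config, _seeds(base_seed, n_seeds))
    rows = []
    for seed, df in records.groupby("seed"):
        rows.append(
            {
                "seed": seed,
                "sc_red": final_window_mean(df, "sc", "red"),
                "sc_black": final_window_mean(df, "sc", "black"),
                "p_gd_red": final_window_mean(df, "p_goal_directed", "red"),
                "p_gd_black": final_window_mean(df, "p_goal_directed", "black"),
            }
        )
    return ExperimentResult("sim3", records, pd.DataFrame(rows), config)


def _sim4_spec(n_block1: int, n_block2: int) -> TaskSpec:
    spec = load_task("sim4")
    return spec.with_blocks(
        [
            Block("red", n_block1),
            Block("black", n_block2, novel_context=True),
        ]
    )


def run_sim4(
    n_seeds: int = 20,
    n_block1_short: int = 500,
    n_block1_long: int = 7000,
    n_block2: int = 500,
    base_seed: int = 0,
    config: AgentConfig | None = None,
    preserve_gc: bool = True,
) -> ExperimentResult:
    """Learned helplessness: short vs long uncontrollable pre-training.

    For every seed the two agents share identical random substreams on the
    novel test block (yoked design), so generalised controllability is the
    only quantity crossing the context boundary that differs between them.
    With ``preserve_gc=False`` even that is reset, and the two test-block
    trajectories become bit-identical.

    Summary per seed pair: GC at the end of block 1 and mean probability
    of goal-directed control over block 2, for each agent.
    """
    config = config or default_config()
    seeds = _seeds(base_seed, n_seeds)
    frames, rows = [], []
    specs = {
        "short": _sim4_spec(n_block1_short, n_block2),
        "long": _sim4_spec(n_block1_long, n_block2),
    }
    for s in seeds:
        per_agent = {}
        for label, spec in specs.items():
            _, records = run_task(spec, config, seed=s, preserve_gc=preserve_gc)
            df = records_to_frame(records)
            df.insert(0, "seed", s)
            df.insert(1, "agent", label)
            frames.append(df)
            per_agent[label] = df
        row = {"seed": s}
        for label, df in per_agent.items():
            b1 = df[df["block"] == 0]
            b2 = df[df["block"] == 1]
            row[f"gc_end_block1_{label}"] = float(b1["gc_post"].iloc[-1])
            row[f"p_gd_block2_{label}"] = float(b2["p_goal_directed"].mean())
        rows.append(row)
    return ExperimentResult(
        "sim4", pd.concat(frames, ignore_index=True), pd.DataFrame(rows), config
    )


def run_sim5(
    n_seeds: int = 20,
    n_trials: int = 1000,
    base_seed: int = 0,
    config: AgentConfig | None = None,
    variant: str = "sim5",
) -> ExperimentResult:
    """Threat-distance manipulation (3 s vs 30 s signalled delay).

    Summary per seed: mean probability of goal-directed control per
    (cue, delay) cell, over the whole run (delays are randomised i.i.d.,
    so the two delay conditions sample identical learning histories).
    """
    spec = load_task(variant, n_trials=n_trials)
    config = config or default_config()
    records = _run_many(spec, config, _seeds(base_seed, n_seeds))
    short_d, long_d = min(spec.delay_levels), max(spec.delay_levels)
    rows = []
    for seed, df in records.groupby("seed"):
        row = {"seed": seed}
        for cue in spec.cues:
            for label, d in (("short", short_d), ("long", long_d)):
                sel = (df["cue"] == cue) & (df["delay_s"] == d)
                row[f"p_gd_{cue}_{label}"] = float(
                    df.loc[sel, "p_goal_directed"].mean()
                )
        rows.append(row)
    return ExperimentResult(variant, records, pd.DataFrame(rows), config)


_RUNNERS = {
    "sim1": run_sim1,
    "sim2": run_sim2,
    "sim3": run_sim3,
    "sim4": run_sim4,
    "sim5": run_sim5,
}


def run_experiment(name: str, **kwargs) -> ExperimentResult:
    """Dispatch to one of the five preset experiment runners by name."""
    if name == "sim5_textvariant":
        return run_sim5(variant="sim5_textvariant", **kwargs)
    if name not in _RUNNERS:
        raise ValueError(f"unknown experiment {name!r}")
    return _RUNNERS[name](**kwargs)
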