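"""Multi-run study workflows: bias comparison, diffuser comparison, ablations.

These are thin orchestration loops over the simulator and the evaluation
harness; each resamples the dataset from a derived master seed per
repetition so that repetition-to-repetition variation reflects the whole
pipeline, not just the classifier.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import pandas as pd

from . import evaluation as evl
from . import simulate as sim


def bias_comparison(
    cfg: sim.SimulationConfig,
    n_reps: int,
    fc: evl.FeatureConfig = evl.FeatureConfig(),
    tie_seed: int = 0,
    train_fraction: float = 5 / 6,
) -> pd.DataFrame:
    """Single-session vs intertwined accuracy over seeded repetitions.

    Each repetition regenerates the dataset at ``master_seed + rep``, then
    measures (a) the single-session protocol averaged over all sessions and
    (b) the leave-one-session-out intertwined protocol.  With
    class-correlated drift enabled the single-session figure is expected to
    be optimistically inflated relative to the intertwined one.
    """
    rows = []
    for rep in range(n_reps):
        ds = sim.simulate_session_dataset(replace(cfg, master_seed=cfg.master_seed + rep))
        single, _ = evl.single_session_accuracy(
            ds, fc, train_fraction=train_fraction, tie_seed=tie_seed, seed=cfg.master_seed + rep
        )
        inter, _ = evl.leave_one_session_out(ds, fc, tie_seed=tie_seed)
        rows.append(
            {
                "rep": rep,
                "single_session_accuracy": single,
                "intertwined_accuracy": inter,
                "gap": single - inter,
            }
        )
    return pd.DataFrame(rows)


def diffuser_comparison(
    cfg: sim.SimulationConfig,
    diffusers: Mapping[str, sim.DiffuserConfig | None],
    n_repeats: int = 5,
    fc: evl.FeatureConfig = evl.FeatureConfig(),
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Mean intertwined accuracy per diffuser condition over seeded repeats.

    Mirrors the grit-comparison table: the same pipeline is run once per
    condition and repeat, with the dataset seed and the diffuser plate seed
    varied per repeat, and the per-condition mean reported.
    """
    rows = []
    for name, diffuser in diffusers.items():
        for rep in range(n_repeats):
            d = diffuser
            if d is not None:
                d = replace(d, seed=d.seed + rep)
            run_cfg = replace(
                cfg, diffuser=d if d is not None else sim.DiffuserConfig(), master_seed=cfg.master_seed + rep
            )
            ds = sim.simulate_session_dataset(run_cfg)
            acc, _ = evl.leave_one_session_out(ds, fc, tie_seed=tie_seed)
            rows.append({"condition": name, "repeat": rep, "accuracy": acc})
    table = pd.DataFrame(rows)
    means = (
        table.groupby("condition", sort=False)["accuracy"].mean().rename("mean_accuracy")
    )
    return table.merge(means, on="condition")


def grit_diffusers(
    grits: Sequence[int | None], envelope_scale: float = 1.0, seed: int = 0
) -> dict[str, sim.DiffuserConfig | None]:
    """Build the standard named diffuser set for a grit list (None = no plate)."""
    out: dict[str, sim.DiffuserConfig | None] = {}
    for grit in grits:
        name = "none" if grit is None else f"grit{grit}"
        out[name] = (
            None
            if grit is None
            else sim.DiffuserConfig(grit=grit, envelope_scale=envelope_scale, seed=seed)
        )
    return out
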