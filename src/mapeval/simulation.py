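"""Synthetic perturbation/control profiles and the four-method benchmark.

Each simulated condition draws control profiles with every feature from a
baseline distribution (standard normal by default) and perturbation
replicates with a fixed fraction of features from a location-shifted
distribution (N(1, 1) by default; a Cauchy family probes heavy tails).
Recall of a method under a condition is the fraction of simulated
perturbations it calls significantly different from the controls at raw
p < alpha (for k-means: exact cluster separation), without multiple-testing
adjustment.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import kmeans_separation, mmd_test, mp_value
from .matching import ProfileTable
from .significance import SignificanceConfig
from .tasks import phenotypic_activity

logger = logging.getLogger("mapeval")

__all__ = [
    "SimulationConfig",
    "BenchmarkRecord",
    "simulate_condition",
    "run_benchmark",
    "reduced_grid",
    "plot_recall",
    "CONTROL_LABEL",
]

CONTROL_LABEL = "control"

# Full benchmark design: binary-exponential fraction scale, figure-style
# control counts (an alternative 8/16/32 control design is sometimes quoted;
# pass n_controls explicitly to use it).
FEATURE_SIZES = (100, 200, 500, 1000, 2500, 5000)
FRACTIONS = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64)
REPLICATES = (2, 3, 4)
CONTROLS = (12, 24, 36)


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid.

    ``frac_perturbed`` of the ``n_features`` features (rounded to the
    nearest integer, at least 1 when the fraction is positive) are drawn
    from the shifted distribution in perturbation replicates; everything
    else, and all control features, comes from the control distribution.
    ``frac_perturbed = 0`` is the explicit null condition used for type-I
    calibration. The perturbed feature indices are the first ones — AP and
    the baselines are invariant to feature permutation, so which indices
    shift carries no information.
    """

    n_features: int = 100
    frac_perturbed: float = 0.64
    n_replicates: int = 4
    n_controls: int = 36
    n_perturbations: int = 100
    family: str = "normal"
    control_loc: float = 0.0
    control_scale: float = 1.0
    shift_loc: float = 1.0
    shift_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_replicates < 2 or self.n_controls < 1:
            raise ValueError("counts must be positive (and >= 2 replicates)")
        if self.n_perturbations < 1:
            raise ValueError("need at least one perturbation")
        if not 0 <= self.frac_perturbed <= 1:
            raise ValueError("frac_perturbed must lie in [0, 1]")
        if self.family not in ("normal", "cauchy"):
            raise ValueError("family must be 'normal' or 'cauchy'")
        if self.frac_perturbed > 0 and self.n_perturbed_features == 0:
            raise ValueError(
                "frac_perturbed rounds to zero perturbed features; "
                "increase it or use frac_perturbed=0 for the null condition"
            )

    @property
    def n_perturbed_features(self) -> int:
        return int(round(self.frac_perturbed * self.n_features))

    @property
    def key(self) -> str:
        return (
            f"{self.family}_f{self.n_features}_p{self.frac_perturbed:g}"
            f"_r{self.n_replicates}_c{self.n_controls}"
        )


@dataclass
class BenchmarkRecord:
    config_key: str
    method: str
    recall: float
    n_perturbations: int
    seed: int | None = None
    config: SimulationConfig | None = None


def _draw(rng, family, loc, scale, size):
    if family == "normal":
        return rng.normal(loc, scale, size)
    return loc + scale * rng.standard_cauchy(size)


def simulate_condition(config: SimulationConfig) -> ProfileTable:
    """Generate one condition's profile table.

    Rows: ``n_controls`` controls followed by ``n_perturbations`` blocks of
    ``n_replicates`` rows. Metadata columns: ``perturbation`` (controls
    labeled ``"control"``) and ``replicate``.
    """
    rng = np.random.default_rng(config.seed)
    d = config.n_features
    k = config.n_perturbed_features
    fam = config.family

    controls = _draw(
        rng, fam, config.control_loc, config.control_scale, (config.n_controls, d)
    )
    n_rep_rows = config.n_perturbations * config.n_replicates
    reps = _draw(rng, fam, config.control_loc, config.control_scale, (n_rep_rows, d))
    if k > 0:
        reps[:, :k] = _draw(
            rng, fam, config.shift_loc, config.shift_scale, (n_rep_rows, k)
        )

    ids = [f"c{j}" for j in range(config.n_controls)]
    pert, repl = [CONTROL_LABEL] * config.n_controls, list(range(config.n_controls))
    for i in range(config.n_perturbations):
        for r in range(config.n_replicates):
            ids.append(f"p{i:03d}_r{r}")
            pert.append(f"p{i:03d}")
            repl.append(r)
    meta = pd.DataFrame(
        {"perturbation": pert, "replicate": repl},
        index=pd.Index(ids, name="profile"),
    )
    return ProfileTable(meta, np.vstack([controls, reps]))


def _method_seed(base: int | None, *parts: int) -> int:
    ss = np.random.SeedSequence(0 if base is None else base, spawn_key=tuple(parts))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def score_condition(
    table: ProfileTable,
    methods=("map", "mp_value", "mmd", "kmeans"),
    alpha: float = 0.05,
    n_permutations: int = 2000,
    metric: str = "cosine",
    seed: int | None = None,
) -> dict:
    """Recall of each method on one simulated condition's table.

    A method failure on a single perturbation counts as not retrieved and
    is logged, never raised.
    """
    meta = table.meta
    is_ctrl = (meta["perturbation"] == CONTROL_LABEL).to_numpy()
    ctrl_X = table.X[is_ctrl]
    pert_names = meta.loc[~is_ctrl, "perturbation"].unique()
    recalls: dict = {}

    if "map" in methods:
        cfg = SignificanceConfig(
            null_size=n_permutations, seed=_method_seed(seed, 0), raw=True, alpha=alpha
        )
        results = phenotypic_activity(
            table, "perturbation", CONTROL_LABEL, metric=metric, config=cfg,
            adjust=False,
        )
        recalls["map"] = float(np.mean([r.p_value < alpha for r in results]))

    per_pert = {m: [] for m in methods if m != "map"}
    if per_pert:
        for i, pert in enumerate(pert_names):
            grp = table.X[(meta["perturbation"] == pert).to_numpy()]
            for m in per_pert:
                try:
                    if m == "mp_value":
                        res = mp_value(
                            grp, ctrl_X, n_permutations, _method_seed(seed, 1, i)
                        )
                        hit = res.p_value < alpha
                    elif m == "mmd":
                        res = mmd_test(
                            grp, ctrl_X, n_permutations, _method_seed(seed, 2, i)
                        )
                        hit = res.p_value < alpha
                    elif m == "kmeans":
                        res = kmeans_separation(grp, ctrl_X, seed=_method_seed(seed, 3, i))
                        hit = res.success
                    else:
                        raise ValueError(f"unknown method {m!r}")
                except ValueError as exc:
                    logger.warning("%s failed on %s: %s", m, pert, exc)
                    hit = False
                per_pert[m].append(bool(hit))
        for m, hits in per_pert.items():
            recalls[m] = float(np.mean(hits))
    return recalls


def run_benchmark(
    grid,
    methods=("map", "mp_value", "mmd", "kmeans"),
    alpha: float = 0.05,
    seeds=(0, 1, 2),
    n_permutations: int = 2000,
    metric: str = "cosine",
) -> pd.DataFrame:
    """Recall of each method over a grid of simulated conditions.

    Returns a tidy table with one row per (condition, seed, method); the
    ``recall`` column is the fraction of that condition's perturbations
    the method retrieved at raw p < alpha (or separated, for k-means).
    """
    records = []
    for config in grid:
        for run, seed in enumerate(seeds):
            cond_seed = _method_seed(seed, zlib.crc32(config.key.encode()) & 0xFFFF)
            table = simulate_condition(replace(config, seed=cond_seed))
            recalls = score_condition(
                table, methods, alpha, n_permutations, metric, seed=cond_seed
            )
            for method, recall in recalls.items():
                records.append(
                    {
                        "config_key": config.key,
                        "family": config.family,
                        "n_features": config.n_features,
                        "frac_perturbed": config.frac_perturbed,
                        "n_replicates": config.n_replicates,
                        "n_controls": config.n_controls,
                        "seed": seed,
                        "method": method,
                        "recall": recall,
                        "n_perturbations": config.n_perturbations,
                    }
                )
    return pd.DataFrame.from_records(records)


def reduced_grid(
    feature_sizes=(100, 1000),
    fractions=FRACTIONS,
    n_replicates=4,
    n_controls=36,
    **kwargs,
) -> list[SimulationConfig]:
    """Desk-scale benchmark grid (full grids are cluster-scale)."""
    return [
        SimulationConfig(
            n_features=d,
            frac_perturbed=f,
            n_replicates=n_replicates,
            n_controls=n_controls,
            **kwargs,
        )
        for d in feature_sizes
        for f in fractions
    ]


def plot_recall(df: pd.DataFrame, path: str) -> None:
    """Recall-vs-fraction-perturbed panels, one per (features, controls)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = sorted(df["n_features"].unique())
    ctrls = sorted(df["n_controls"].unique())
    fig, axes = plt.subplots(
        len(feats), len(ctrls), figsize=(3.2 * len(ctrls), 2.6 * len(feats)),
        squeeze=False, sharey=True,
    )
    for i, d in enumerate(feats):
        for j, c in enumerate(ctrls):
            ax = axes[i][j]
            sub = df[(df["n_features"] == d) & (df["n_controls"] == c)]
            for method, g in sub.groupby("method"):
                mean = g.groupby("frac_perturbed")["recall"].mean()
                ax.plot(mean.index, mean.values, marker="o", label=method)
            ax.set_xscale("log", base=2)
            ax.set_title(f"{d} features, {c} controls", fontsize=9)
            if i == len(feats) - 1:
                ax.set_xlabel("fraction perturbed")
            if j == 0:
                ax.set_ylabel("recall")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
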