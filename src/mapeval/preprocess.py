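"""Profile normalization, feature selection, and table I/O.

Two normalization schemes are provided: plain standardization (subtract
the mean, divide by the standard deviation, over the whole dataset or per
plate) and the robust per-plate variant that substitutes median and median
absolute deviation ("MAD robustize"). Feature selection removes
blocklisted, missing-valued, low-variance, redundant (highly correlated)
and outlier-carrying features, in that order.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matching import ProfileTable

logger = logging.getLogger("mapeval")

__all__ = [
    "PreprocessConfig",
    "standardize",
    "mad_robustize",
    "feature_select",
    "read_profiles",
    "write_profiles",
    "write_results",
]

# Normal-consistency constant: MAD * 1.4826 estimates the standard
# deviation of Gaussian data, making the two normalizations comparable.
MAD_CONSISTENCY = 1.4826


@dataclass
class PreprocessConfig:
    """Normalization + feature-selection settings.

    variance_floor: drop features with variance below it (after
    normalization). correlation_ceiling: of each feature pair correlated
    above it, drop the later column. outlier_bound: drop features with any
    |value| beyond it. blocklist: fnmatch-style feature-name patterns.
    mad_epsilon: when set, zero-MAD features are kept and the denominator
    becomes c*MAD + epsilon; by default they are dropped (a zero-MAD
    feature carries no within-plate signal).
    """

    method: str = "mad_robustize"
    scope: str = "per_plate"
    plate_col: str | None = "plate"
    variance_floor: float = 1e-8
    correlation_ceiling: float = 0.95
    outlier_bound: float = 500.0
    blocklist: tuple[str, ...] = ()
    mad_epsilon: float | None = None
    mad_c: float = MAD_CONSISTENCY

    def __post_init__(self) -> None:
        if self.method not in ("standardize", "mad_robustize"):
            raise ValueError("method must be standardize or mad_robustize")
        if self.scope not in ("global", "per_plate"):
            raise ValueError("scope must be global or per_plate")
        if self.scope == "per_plate" and not self.plate_col:
            raise ValueError("per_plate scope requires plate_col")
        for name in ("variance_floor", "correlation_ceiling", "outlier_bound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _blocks(profiles: ProfileTable, scope: str, plate_col: str | None):
    if scope == "global":
        yield "all", np.arange(profiles.n_profiles)
    else:
        if plate_col not in profiles.meta.columns:
            raise ValueError(f"plate column {plate_col!r} not in metadata")
        for plate, idx in profiles.meta.groupby(plate_col, observed=True).indices.items():
            yield plate, np.asarray(idx)


def standardize(
    profiles: ProfileTable, scope: str = "global", plate_col: str | None = None
) -> ProfileTable:
    """Center and scale each feature to mean 0, sd 1 per scope block.

    The population standard deviation (denominator n) is used. Features
    constant within any block are dropped with a warning.
    """
    X = profiles.X.copy()
    if np.isnan(X).all(axis=0).any():
        raise ValueError("all-NaN feature column")
    dead = np.zeros(profiles.n_features, dtype=bool)
    for block, idx in _blocks(profiles, scope, plate_col):
        if len(idx) < 2:
            raise ValueError(f"scope block {block!r} has fewer than 2 rows")
        sd = X[idx].std(axis=0, ddof=0)
        zero = sd == 0
        dead |= zero
        sd = np.where(zero, 1.0, sd)
        X[idx] = (X[idx] - X[idx].mean(axis=0)) / sd
    return _drop_dead(profiles, X, dead, "constant within a block")


def mad_robustize(
    profiles: ProfileTable,
    plate_col: str,
    c: float = MAD_CONSISTENCY,
    epsilon: float | None = None,
) -> ProfileTable:
    """Per-plate robust normalization: (x - median) / (c * MAD).

    After the transform every feature has per-plate median 0. Features with
    zero MAD on some plate are dropped with a warning unless ``epsilon`` is
    given, in which case the denominator becomes c*MAD + epsilon and all
    values stay finite.
    """
    X = profiles.X.copy()
    dead = np.zeros(profiles.n_features, dtype=bool)
    for plate, idx in _blocks(profiles, "per_plate", plate_col):
        if len(idx) < 2:
            raise ValueError(f"plate {plate!r} has a single row")
        med = np.median(X[idx], axis=0)
        mad = np.median(np.abs(X[idx] - med), axis=0)
        if epsilon is None:
            zero = mad == 0
            dead |= zero
            denom = np.where(zero, 1.0, c * mad)
        else:
            denom = c * mad + epsilon
        X[idx] = (X[idx] - med) / denom
    return _drop_dead(profiles, X, dead, "zero MAD on a plate")


def _drop_dead(profiles, X, dead, reason):
    if dead.any():
        names = [profiles.feature_names[j] for j in np.flatnonzero(dead)]
        logger.warning("dropping %d feature(s) (%s): %s", len(names), reason, names[:10])
        keep = ~dead
        X = X[:, keep]
        names = [n for n, k in zip(profiles.feature_names, keep) if k]
        return ProfileTable(profiles.meta, X, names)
    return ProfileTable(profiles.meta, X, list(profiles.feature_names))


def feature_select(
    profiles: ProfileTable, config: PreprocessConfig | None = None
) -> tuple[ProfileTable, pd.DataFrame]:
    """Drop uninformative or problematic features, in a fixed order.

    Order: blocklisted names; features with missing values; variance below
    the floor; of each pair with |correlation| above the ceiling, the later
    column; features with any value beyond the outlier bound. Returns the
    reduced table plus a report of dropped features and reasons.
    """
    cfg = config or PreprocessConfig()
    names = list(profiles.feature_names)
    X = profiles.X
    dropped: list[tuple[str, str]] = []
    keep = np.ones(len(names), dtype=bool)

    for j, name in enumerate(names):
        if any(fnmatch.fnmatch(name, pat) for pat in cfg.blocklist):
            keep[j] = False
            dropped.append((name, "blocklist"))
    nan_cols = np.isnan(X).any(axis=0)
    for j in np.flatnonzero(nan_cols & keep):
        keep[j] = False
        dropped.append((names[j], "missing values"))
    with np.errstate(invalid="ignore"):
        variance = np.nanvar(X, axis=0)
    for j in np.flatnonzero((variance < cfg.variance_floor) & keep):
        keep[j] = False
        dropped.append((names[j], "low variance"))

    live = np.flatnonzero(keep)
    if len(live) > 1:
        corr = np.corrcoef(X[:, live], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        for a in range(len(live)):
            if not keep[live[a]]:
                continue
            for b in range(a + 1, len(live)):
                if keep[live[b]] and abs(corr[a, b]) > cfg.correlation_ceiling:
                    keep[live[b]] = False
                    dropped.append((names[live[b]], "correlated"))
    for j in np.flatnonzero(keep):
        if np.abs(X[:, j]).max() > cfg.outlier_bound:
            keep[j] = False
            dropped.append((names[j], "outlier"))

    if not keep.any():
        raise ValueError("feature selection dropped every feature")
    report = pd.DataFrame(dropped, columns=["feature", "reason"])
    if len(report):
        logger.info("feature_select dropped %d feature(s)", len(report))
    out = ProfileTable(
        profiles.meta,
        X[:, keep],
        [n for n, k in zip(names, keep) if k],
    )
    return out, report


def read_profiles(
    path: str, format: str | None = None, prefix: str = "Metadata_", id_col: str | None = None
) -> ProfileTable:
    """Read a profile table from CSV or Parquet.

    Columns starting with ``prefix`` are metadata, the rest features.
    ``id_col`` (a metadata column name, without prefix) becomes the profile
    id; otherwise the row number is used.
    """
    fmt = format or ("parquet" if str(path).endswith(".parquet") else "csv")
    df = pd.read_parquet(path) if fmt == "parquet" else pd.read_csv(path)
    table = ProfileTable.from_dataframe(df, prefix=prefix)
    if id_col is not None:
        if id_col not in table.meta.columns:
            raise ValueError(f"id column {id_col!r} not found in metadata")
        table = ProfileTable(
            table.meta.set_index(id_col, drop=False).rename_axis("profile"),
            table.X,
            table.feature_names,
        )
    bad = [
        c for c in table.feature_names
        if not np.issubdtype(df[c].dtype, np.number)
    ]
    if bad:
        raise ValueError(f"non-numeric feature columns: {bad[:5]}")
    return table


def write_profiles(
    table: ProfileTable, path: str, format: str | None = None, prefix: str = "Metadata_"
) -> None:
    fmt = format or ("parquet" if str(path).endswith(".parquet") else "csv")
    df = table.to_dataframe(prefix=prefix)
    if fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def write_results(df: pd.DataFrame, path: str) -> None:
    """Write a tidy result table (CSV or Parquet by extension)."""
    if str(path).endswith(".parquet"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
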