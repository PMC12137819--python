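"""Metadata-driven pair matching for profile retrieval.

A retrieval task is defined by a block design: for every query profile,
which other profiles count as *correct* matches (positives) and which as
*incorrect* matches (negatives). Both sets are expressed through metadata
predicates — lists of columns whose values must agree (``sameby``) or
disagree (``diffby``) between the query and the candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mapeval")

__all__ = [
    "ProfileTable",
    "MatchSpec",
    "PairIndex",
    "MatchSpecError",
    "EmptyResultError",
    "build_pairs",
]


class MatchSpecError(ValueError):
    """A MatchSpec references unknown columns or is internally inconsistent."""


class EmptyResultError(RuntimeError):
    """Every query was excluded; nothing can be scored."""


@dataclass
class ProfileTable:
    """A profile dataset: categorical metadata plus an aligned feature matrix.

    Parameters
    ----------
    meta
        One row per profile. Index values are the profile ids and must be
        unique. Columns are categorical annotations (perturbation id, plate,
        well, labels ...).
    X
        Float matrix, one row per profile, one column per feature. Row ``i``
        of ``X`` describes row ``i`` of ``meta``.
    feature_names
        Optional column names for ``X``; generated as ``f0..f{d-1}`` if absent.
    """

    meta: pd.DataFrame
    X: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError(
                f"meta has {len(self.meta)} rows but X has {self.X.shape[0]}"
            )
        if not self.meta.index.is_unique:
            raise ValueError("profile ids (meta index) must be unique")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")

    @property
    def n_profiles(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def ids(self) -> np.ndarray:
        return self.meta.index.to_numpy()

    def subset(self, mask) -> "ProfileTable":
        """Row subset by boolean mask or positional indices."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ProfileTable(self.meta.iloc[idx], self.X[idx], list(self.feature_names))

    def to_dataframe(self, prefix: str = "Metadata_") -> pd.DataFrame:
        meta = self.meta.rename(columns=lambda c: f"{prefix}{c}")
        feats = pd.DataFrame(self.X, columns=self.feature_names, index=self.meta.index)
        return pd.concat([meta, feats], axis=1)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, prefix: str = "Metadata_"
    ) -> "ProfileTable":
        meta_cols = [c for c in df.columns if c.startswith(prefix)]
        feat_cols = [c for c in df.columns if not c.startswith(prefix)]
        if not feat_cols:
            raise ValueError("no feature columns found")
        meta = df[meta_cols].rename(columns=lambda c: c[len(prefix):])
        X = df[feat_cols].to_numpy(dtype=np.float64)
        return cls(meta, X, feat_cols)


@dataclass(frozen=True)
class MatchSpec:
    """Block design: which metadata columns define positives and negatives.

    A candidate ``j`` is a *positive* of query ``i`` when the two rows agree
    on every ``pos_sameby`` column and differ on every ``pos_diffby`` column;
    *negatives* are defined likewise by ``neg_sameby`` / ``neg_diffby``.
    """

    pos_sameby: tuple[str, ...] = ()
    pos_diffby: tuple[str, ...] = ()
    neg_sameby: tuple[str, ...] = ()
    neg_diffby: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos_sameby", tuple(self.pos_sameby))
        object.__setattr__(self, "pos_diffby", tuple(self.pos_diffby))
        object.__setattr__(self, "neg_sameby", tuple(self.neg_sameby))
        object.__setattr__(self, "neg_diffby", tuple(self.neg_diffby))
        if set(self.pos_sameby) & set(self.pos_diffby):
            raise MatchSpecError("pos_sameby and pos_diffby overlap")
        if set(self.neg_sameby) & set(self.neg_diffby):
            raise MatchSpecError("neg_sameby and neg_diffby overlap")

    @property
    def columns(self) -> set[str]:
        return (
            set(self.pos_sameby)
            | set(self.pos_diffby)
            | set(self.neg_sameby)
            | set(self.neg_diffby)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "MatchSpec":
        return cls(
            pos_sameby=tuple(d.get("pos_sameby", ())),
            pos_diffby=tuple(d.get("pos_diffby", ())),
            neg_sameby=tuple(d.get("neg_sameby", ())),
            neg_diffby=tuple(d.get("neg_diffby", ())),
        )


@dataclass
class PairIndex:
    """Per-query positive and negative candidate sets (profile ids).

    ``excluded`` maps query ids that could not be scored to a reason
    ("no positives" / "no negatives" / "NaN metadata").
    """

    positives: dict = field(default_factory=dict)
    negatives: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)

    @property
    def query_ids(self) -> list:
        return list(self.positives)

    def __len__(self) -> int:
        return len(self.positives)


def _match_matrix(
    meta: pd.DataFrame, sameby: tuple[str, ...], diffby: tuple[str, ...]
) -> np.ndarray:
    """Boolean n x n matrix: entry (i, j) true iff j satisfies the predicate
    for query i. NaN metadata never matches under sameby and never *differs*
    under diffby, so rows with NaN in any referenced column drop out.
    """
    n = len(meta)
    ok = np.ones((n, n), dtype=bool)
    for col in sameby:
        v = meta[col].to_numpy()
        valid = ~pd.isna(v)
        eq = (v[:, None] == v[None, :]) & valid[:, None] & valid[None, :]
        ok &= eq
    for col in diffby:
        v = meta[col].to_numpy()
        valid = ~pd.isna(v)
        ne = (v[:, None] != v[None, :]) & valid[:, None] & valid[None, :]
        ok &= ne
    np.fill_diagonal(ok, False)
    return ok


def build_pairs(
    profiles: ProfileTable,
    spec: MatchSpec,
    query_ids=None,
) -> PairIndex:
    """Materialize positive/negative candidate sets for every query.

    Parameters
    ----------
    profiles
        The profile dataset.
    spec
        The block design. Candidates matching neither predicate are simply
        absent from the rank list (they are not forced into negatives).
    query_ids
        Optional subset of profile ids to use as queries (e.g. perturbation
        replicates only, when controls should never be queries). Defaults to
        all profiles.

    Returns
    -------
    PairIndex
        Queries with at least one positive and one negative; all others are
        recorded in ``excluded`` with a reason.

    Raises
    ------
    MatchSpecError
        If the spec names a column absent from ``profiles.meta``.
    EmptyResultError
        If every query ends up excluded.
    """
    if profiles.n_profiles == 0:
        raise EmptyResultError("profile table is empty")
    missing = spec.columns - set(profiles.meta.columns)
    if missing:
        raise MatchSpecError(f"unknown metadata columns: {sorted(missing)}")

    meta = profiles.meta
    ids = profiles.ids
    pos_ok = _match_matrix(meta, spec.pos_sameby, spec.pos_diffby)
    neg_ok = _match_matrix(meta, spec.neg_sameby, spec.neg_diffby)
    # a candidate can satisfy both predicates under odd specs; positives win
    neg_ok &= ~pos_ok

    if query_ids is None:
        query_pos = np.arange(len(ids))
    else:
        lookup = {pid: i for i, pid in enumerate(ids)}
        query_pos = np.array([lookup[q] for q in query_ids], dtype=int)

    index = PairIndex()
    for i in query_pos:
        qid = ids[i]
        pos = ids[pos_ok[i]]
        neg = ids[neg_ok[i]]
        if len(pos) == 0:
            index.excluded[qid] = "no positives"
        elif len(neg) == 0:
            index.excluded[qid] = "no negatives"
        else:
            index.positives[qid] = set(pos)
            index.negatives[qid] = set(neg)
    if index.excluded:
        logger.info(
            "build_pairs: excluded %d of %d queries (%s)",
            len(index.excluded),
            len(query_pos),
            ", ".join(sorted(set(index.excluded.values()))),
        )
    if not index.positives:
        raise EmptyResultError("all queries excluded: no scorable pairs")
    return index
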