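"""Retrieval tasks: phenotypic activity, consistency, distinctiveness.

*Phenotypic activity* asks whether a perturbation's replicates can be
retrieved against negative controls — i.e. whether the perturbation has a
detectable phenotype at all. *Phenotypic consistency* asks whether
perturbations sharing a biological annotation (MoA, target gene, complex)
retrieve one another against differently annotated perturbations, on
median-aggregated consensus profiles. *Phenotypic distinctiveness* asks
whether a perturbation's replicates stand apart from all other
perturbations. All three reduce to the same machinery: a block design
(matching), ranked binary relevance lists (metrics) and a permutation null
(significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matching import (
    EmptyResultError,
    MatchSpec,
    PairIndex,
    ProfileTable,
    build_pairs,
)
from .metrics import APResult, MAPResult, average_precision, distance_to, rank_relevance
from .significance import NullCache, SignificanceConfig, bh_fdr, percent_retrieved

logger = logging.getLogger("mapeval")

__all__ = [
    "ConsensusProfile",
    "MultiLabelAPMatrix",
    "phenotypic_activity",
    "consensus",
    "phenotypic_consistency",
    "phenotypic_distinctiveness",
    "multilabel_ap",
    "results_to_frame",
]


@dataclass
class ConsensusProfile:
    """Per-perturbation aggregate: feature-wise median over replicates."""

    perturbation: object
    features: np.ndarray
    n_replicates: int


@dataclass
class MultiLabelAPMatrix:
    """Sparse P x T matrix of AP values for (perturbation, label) pairs.

    An entry exists iff the perturbation carries the label. Row means give
    per-perturbation scores, column means per-label mAPs.
    """

    entries: dict = field(default_factory=dict)  # (pert, label) -> ap
    perturbations: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def per_label_map(self) -> dict:
        out: dict = {}
        for (p, t), ap in self.entries.items():
            out.setdefault(t, []).append(ap)
        return {t: float(np.mean(v)) for t, v in out.items()}

    def per_perturbation_map(self) -> dict:
        out: dict = {}
        for (p, t), ap in self.entries.items():
            out.setdefault(p, []).append(ap)
        return {p: float(np.mean(v)) for p, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"perturbation": p, "label": t, "ap": ap}
            for (p, t), ap in self.entries.items()
        ]
        return pd.DataFrame(rows)


def _score_queries(
    profiles: ProfileTable, pairs: PairIndex, metric: str
) -> dict:
    """AP per query id given its positive/negative candidate sets."""
    row_of = {pid: i for i, pid in enumerate(profiles.ids)}
    results = {}
    for qid in pairs.query_ids:
        pos = sorted(pairs.positives[qid], key=lambda x: row_of[x])
        neg = sorted(pairs.negatives[qid], key=lambda x: row_of[x])
        cand_idx = np.array([row_of[c] for c in pos + neg])
        is_pos = np.zeros(len(cand_idx), dtype=bool)
        is_pos[: len(pos)] = True
        d = distance_to(profiles.X[row_of[qid]], profiles.X[cand_idx], metric)
        rl = rank_relevance(d, is_pos)
        results[qid] = APResult(qid, average_precision(rl), rl.n_pos, rl.n_total)
    return results


def _finalize_groups(
    grouped: dict,
    cfg: SignificanceConfig,
    cache: NullCache | None = None,
    adjust: bool = True,
) -> list[MAPResult]:
    """Turn {group: [APResult, ...]} into MAPResults with p, q, retrieved."""
    if cache is None:
        cache = cfg.make_cache()
    results = []
    for group, members in grouped.items():
        observed = float(np.mean([m.ap for m in members]))
        configs = [(m.n_pos, m.n_total) for m in members]
        null_maps = cache.group_null(configs)
        from .significance import ap_p_value

        p = ap_p_value(observed, null_maps, raw=cfg.raw)
        for m in members:
            m.p_value = ap_p_value(m.ap, cache.get(m.n_pos, m.n_total), raw=cfg.raw)
        results.append(MAPResult(group, observed, members, p_value=p))
    if adjust:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.retrieved = bool(qv < cfg.alpha)
    else:
        for r in results:
            r.q_value = r.p_value
            r.retrieved = bool(r.p_value < cfg.alpha)
    return results


def phenotypic_activity(
    profiles: ProfileTable,
    pert_col: str,
    control_value,
    pos_extra_sameby: tuple = (),
    pos_extra_diffby: tuple = (),
    neg_extra_sameby: tuple = (),
    neg_extra_diffby: tuple = (),
    metric: str = "cosine",
    config: SignificanceConfig | None = None,
    adjust: bool = True,
) -> list[MAPResult]:
    """Replicate retrievability of each perturbation against controls.

    Each replicate of a perturbation is used in turn as a query; the
    remaining M-1 replicates are the correct matches and the N control
    profiles the incorrect ones. Extra sameby/diffby constraints implement
    restricted block designs (same well position, different plate, ...).
    Perturbations with fewer than two replicates cannot be scored and are
    skipped with a log message. Set ``adjust=False`` to flag retrieval on
    raw (unadjusted) p-values instead of Benjamini-Hochberg q-values.
    """
    cfg = config or SignificanceConfig()
    is_control = (profiles.meta[pert_col] == control_value).to_numpy()
    if not is_control.any():
        raise ValueError(f"no control profiles with {pert_col} == {control_value!r}")
    control_idx = np.flatnonzero(is_control)

    spec = MatchSpec(
        pos_sameby=(pert_col, *pos_extra_sameby),
        pos_diffby=tuple(pos_extra_diffby),
        neg_sameby=tuple(neg_extra_sameby),
        neg_diffby=(pert_col, *neg_extra_diffby),
    )
    cache = cfg.make_cache()
    grouped: dict = {}
    perts = profiles.meta.loc[~is_control, pert_col]
    for pert, rows in perts.groupby(perts, observed=True, sort=False).groups.items():
        rep_idx = np.array([profiles.meta.index.get_loc(r) for r in rows])
        if len(rep_idx) < 2:
            logger.info("activity: skipping %r (single replicate)", pert)
            continue
        sub = profiles.subset(np.concatenate([rep_idx, control_idx]))
        try:
            pairs = build_pairs(sub, spec, query_ids=sub.ids[: len(rep_idx)])
        except EmptyResultError:
            logger.info("activity: skipping %r (no scorable queries)", pert)
            continue
        aps = _score_queries(sub, pairs, metric)
        grouped[pert] = list(aps.values())
    if not grouped:
        raise EmptyResultError("no perturbation could be scored")
    return _finalize_groups(grouped, cfg, cache, adjust=adjust)


def consensus(profiles: ProfileTable, by: str) -> ProfileTable:
    """Aggregate replicates into one consensus profile per group.

    Features become the column-wise median over replicates. Metadata
    columns constant within every group are retained; varying ones are
    dropped. A ``n_replicates`` column records group sizes.
    """
    groups = profiles.meta.groupby(by, sort=True, observed=True)
    keys, medians, sizes = [], [], []
    for key, idx in groups.indices.items():
        keys.append(key)
        medians.append(np.median(profiles.X[idx], axis=0))
        sizes.append(len(idx))
    keep_cols = []
    for col in profiles.meta.columns:
        if col == by:
            continue
        if groups[col].nunique(dropna=False).le(1).all():
            keep_cols.append(col)
    meta = pd.DataFrame({by: keys}, index=pd.Index(keys, name="profile"))
    for col in keep_cols:
        meta[col] = groups[col].first().reindex(keys).to_numpy()
    meta["n_replicates"] = sizes
    return ProfileTable(meta, np.vstack(medians), list(profiles.feature_names))


def phenotypic_consistency(
    consensus_profiles: ProfileTable,
    label_col: str,
    gate: set | None = None,
    metric: str = "cosine",
    config: SignificanceConfig | None = None,
    adjust: bool = True,
) -> list[MAPResult]:
    """Retrievability of same-label consensus profiles against other labels.

    ``gate`` optionally restricts scoring to phenotypically active
    perturbations (profile ids that passed the activity threshold); apply it
    before interpreting consistency, so that similarity among inactive
    profiles does not masquerade as biological signal.
    """
    cfg = config or SignificanceConfig()
    table = consensus_profiles
    if gate is not None:
        keep = np.array([pid in gate for pid in table.ids])
        if not keep.any():
            raise EmptyResultError("activity gate removed every profile")
        table = table.subset(keep)
    if table.meta[label_col].nunique(dropna=True) < 2:
        raise ValueError("phenotypic consistency needs at least 2 labels")
    spec = MatchSpec(pos_sameby=(label_col,), neg_diffby=(label_col,))
    pairs = build_pairs(table, spec)
    aps = _score_queries(table, pairs, metric)
    grouped: dict = {}
    labels = table.meta[label_col]
    for qid, ap in aps.items():
        grouped.setdefault(labels.loc[qid], []).append(ap)
    return _finalize_groups(grouped, cfg, adjust=adjust)


def phenotypic_distinctiveness(
    profiles: ProfileTable,
    pert_col: str,
    control_value=None,
    metric: str = "cosine",
    config: SignificanceConfig | None = None,
    adjust: bool = True,
) -> list[MAPResult]:
    """Replicate retrievability of each perturbation against all others.

    Controls (rows whose ``pert_col`` equals ``control_value``) are removed
    before scoring; negatives are every other perturbation's replicates.
    """
    cfg = config or SignificanceConfig()
    table = profiles
    if control_value is not None:
        table = table.subset((table.meta[pert_col] != control_value).to_numpy())
    if table.meta[pert_col].nunique(dropna=True) < 2:
        raise ValueError("phenotypic distinctiveness needs at least 2 perturbations")
    spec = MatchSpec(pos_sameby=(pert_col,), neg_diffby=(pert_col,))
    pairs = build_pairs(table, spec)
    aps = _score_queries(table, pairs, metric)
    grouped: dict = {}
    perts = table.meta[pert_col]
    for qid, ap in aps.items():
        grouped.setdefault(perts.loc[qid], []).append(ap)
    return _finalize_groups(grouped, cfg, adjust=adjust)


def multilabel_ap(
    consensus_profiles: ProfileTable,
    label_map: dict,
    metric: str = "cosine",
    config: SignificanceConfig | None = None,
    drop_confounders: bool = False,
    adjust: bool = True,
):
    """AP per (perturbation, label) pair when perturbations carry many labels.

    For a label t and a perturbation p annotated with it, the query is p's
    consensus profile, positives are the other perturbations annotated with
    t, and negatives are all remaining profiles — by default regardless of
    any other labels they share with the query (``drop_confounders=True``
    removes such shared-other-label profiles from the negatives). Labels
    with a single annotated perturbation are excluded with a log message.

    Returns the sparse AP matrix together with per-label MAPResults.
    """
    cfg = config or SignificanceConfig()
    table = consensus_profiles
    row_of = {pid: i for i, pid in enumerate(table.ids)}
    unknown = set(label_map) - set(row_of)
    if unknown:
        raise ValueError(f"label_map names unknown profiles: {sorted(unknown)[:5]}")
    members_of: dict = {}
    for pid, labels in label_map.items():
        for t in labels:
            members_of.setdefault(t, set()).add(pid)

    matrix = MultiLabelAPMatrix(
        perturbations=list(label_map), labels=sorted(members_of, key=str)
    )
    cache = cfg.make_cache()
    grouped: dict = {}
    for t in matrix.labels:
        members = members_of[t]
        if len(members) < 2:
            logger.info("multilabel: skipping label %r (single member)", t)
            continue
        for p in sorted(members, key=lambda x: row_of[x]):
            pos = [m for m in sorted(members, key=lambda x: row_of[x]) if m != p]
            neg = [
                pid
                for pid in table.ids
                if pid not in members and pid != p
                and not (
                    drop_confounders
                    and set(label_map.get(pid, ())) & set(label_map.get(p, ())) - {t}
                )
            ]
            if not neg:
                logger.info("multilabel: label %r has no negatives", t)
                continue
            cand_idx = np.array([row_of[c] for c in pos + neg])
            is_pos = np.zeros(len(cand_idx), dtype=bool)
            is_pos[: len(pos)] = True
            d = distance_to(table.X[row_of[p]], table.X[cand_idx], metric)
            rl = rank_relevance(d, is_pos)
            ap = average_precision(rl)
            matrix.entries[(p, t)] = ap
            grouped.setdefault(t, []).append(APResult(p, ap, rl.n_pos, rl.n_total))
    if not matrix.entries:
        raise EmptyResultError("no (perturbation, label) pair could be scored")
    label_results = _finalize_groups(grouped, cfg, cache, adjust=adjust)
    return matrix, label_results


def results_to_frame(results: list[MAPResult]) -> pd.DataFrame:
    """Tidy one-row-per-group table of mAP results."""
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group,
                "map": r.map,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "retrieved": r.retrieved,
                "n_queries": len(r.members),
                "n_pos": r.members[0].n_pos if r.members else None,
                "n_total": r.members[0].n_total if r.members else None,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["percent_retrieved"] = percent_retrieved(
        [r.q_value for r in results]
    ) if results else float("nan")
    return df
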