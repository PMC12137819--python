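"""Permutation nulls and significance for AP / mAP scores.

Under the null hypothesis that query and reference profiles come from one
distribution, every ordering of the binary rank list is equally likely, so
the null AP distribution depends only on (n_pos, n_total) and has exactly
C(n_total, n_pos) support points. Small configurations are enumerated
exhaustively; larger ones are approximated by uniformly random relevance
lists. Shuffling the rank list directly is equivalent to reshuffling the
profile labels and never requires re-computing distances, which makes the
null cacheable by its two parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from .metrics import ap_from_hit_positions

__all__ = [
    "NullDistribution",
    "SignificanceConfig",
    "NullCache",
    "null_ap_distribution",
    "ap_p_value",
    "map_p_value",
    "bh_fdr",
    "percent_retrieved",
]

DEFAULT_SIZE = 10_000
DEFAULT_EXACT_THRESHOLD = 10_000


@dataclass
class SignificanceConfig:
    """Knobs for permutation testing.

    null_size: Monte-Carlo draws when enumeration is infeasible and draws
    used for group (mAP) nulls. exact_threshold: enumerate exhaustively when
    C(n_total, n_pos) does not exceed it. raw: report the unsmoothed
    fraction of the null >= observed instead of the +1-smoothed estimate.
    """

    null_size: int = DEFAULT_SIZE
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD
    seed: int | None = None
    raw: bool = False
    alpha: float = 0.05
    coupling: str = "coupled"

    def make_cache(self) -> "NullCache":
        return NullCache(
            self.null_size, self.exact_threshold, self.seed, self.coupling
        )


@dataclass
class NullDistribution:
    n_pos: int
    n_total: int
    samples: np.ndarray
    exact: bool
    seed: int | None = None


def null_ap_distribution(
    n_pos: int,
    n_total: int,
    size: int = DEFAULT_SIZE,
    seed: int | None = None,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> NullDistribution:
    """Null AP distribution for a list with ``n_pos`` ones in ``n_total`` ranks.

    When the number of placements C(n_total, n_pos) is at most
    ``exact_threshold`` all placements are enumerated (exact=True, each with
    equal probability mass); otherwise ``size`` random lists are drawn.
    """
    if not 1 <= n_pos < n_total:
        raise ValueError(f"need 1 <= n_pos < n_total, got ({n_pos}, {n_total})")
    n_lists = comb(n_total, n_pos, exact=True)
    if n_lists <= exact_threshold:
        positions = np.array(
            list(itertools.combinations(range(1, n_total + 1), n_pos)),
            dtype=np.float64,
        )
        samples = ap_from_hit_positions(positions)
        return NullDistribution(n_pos, n_total, samples, exact=True, seed=seed)
    rng = np.random.default_rng(seed)
    samples = _random_ap_draws(rng, n_pos, n_total, size)
    return NullDistribution(n_pos, n_total, samples, exact=False, seed=seed)


def _random_ap_draws(
    rng: np.random.Generator, n_pos: int, n_total: int, size: int
) -> np.ndarray:
    """AP of ``size`` uniformly random binary lists with the given counts."""
    out = np.empty(size)
    chunk = max(1, int(2e6 // max(n_total, 1)))
    for start in range(0, size, chunk):
        stop = min(start + chunk, size)
        keys = rng.random((stop - start, n_total))
        pos = np.argpartition(keys, n_pos - 1, axis=1)[:, :n_pos]
        pos.sort(axis=1)
        out[start:stop] = ap_from_hit_positions(pos + 1.0)
    return out


class NullCache:
    """Cache of null distributions keyed by (n_pos, n_total, size, seed).

    Group (mAP) nulls are resampled from these per-configuration nulls with
    independent per-member streams. The cache can be persisted to a simple
    columnar file for large runs.
    """

    def __init__(
        self,
        size: int = DEFAULT_SIZE,
        exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
        seed: int | None = None,
        coupling: str = "coupled",
    ) -> None:
        if coupling not in ("coupled", "independent"):
            raise ValueError("coupling must be 'coupled' or 'independent'")
        self.size = size
        self.exact_threshold = exact_threshold
        self.seed = seed
        self.coupling = coupling
        self._nulls: dict[tuple[int, int], NullDistribution] = {}
        self._vectors: dict[tuple[int, int], np.ndarray] = {}
        self._group_nulls: dict[tuple, np.ndarray] = {}

    def get(self, n_pos: int, n_total: int) -> NullDistribution:
        key = (n_pos, n_total)
        if key not in self._nulls:
            child = None
            if self.seed is not None:
                child = np.random.SeedSequence(
                    self.seed, spawn_key=(n_pos, n_total)
                ).generate_state(1)[0]
            self._nulls[key] = null_ap_distribution(
                n_pos, n_total, self.size, child, self.exact_threshold
            )
        return self._nulls[key]

    def _sample_vector(self, n_pos: int, n_total: int) -> np.ndarray:
        """Fixed-length (``size``) null AP sample vector for one configuration.

        Exhaustively enumerated nulls are resampled to ``size`` draws with a
        configuration-derived seed so that every member with the same
        (n_pos, n_total) sees the identical vector.
        """
        key = (n_pos, n_total)
        if key not in self._vectors:
            null = self.get(n_pos, n_total)
            if len(null.samples) == self.size:
                self._vectors[key] = null.samples
            else:
                ss = np.random.SeedSequence(
                    0 if self.seed is None else self.seed,
                    spawn_key=(1, n_pos, n_total),
                )
                rng = np.random.default_rng(ss)
                idx = rng.integers(len(null.samples), size=self.size)
                self._vectors[key] = null.samples[idx]
        return self._vectors[key]

    def group_null(self, configs: list[tuple[int, int]]) -> np.ndarray:
        """Null mAP samples for a group of relevance-list configurations.

        In the default ``coupled`` mode, draw k of the group null is the
        mean over members of draw k of each member's null sample vector;
        members with identical (n_pos, n_total) share the same vector, so
        one joint reshuffle drives all of them. This mirrors how the null
        behaves when every member's rank list is permuted by the same
        random outcome and keeps the test conservative for groups whose
        member APs are positively correlated. ``independent`` mode instead
        averages independently resampled per-member draws, which assumes
        uncorrelated member lists.

        A single-member group uses the member's own (possibly exact) null
        directly, so its p-value coincides with the plain AP p-value.
        """
        if not configs:
            raise ValueError("empty group")
        if len(configs) == 1:
            return self.get(*configs[0]).samples
        key = (self.coupling, tuple(sorted(configs)))
        if key not in self._group_nulls:
            total = np.zeros(self.size)
            if self.coupling == "coupled":
                for n_pos, n_total in configs:
                    total += self._sample_vector(n_pos, n_total)
            else:
                ss = np.random.SeedSequence(
                    0 if self.seed is None else self.seed,
                    spawn_key=(2, hash(tuple(sorted(configs))) & 0x7FFFFFFF),
                )
                for member_ss, (n_pos, n_total) in zip(
                    ss.spawn(len(configs)), configs
                ):
                    rng = np.random.default_rng(member_ss)
                    null = self.get(n_pos, n_total)
                    idx = rng.integers(len(null.samples), size=self.size)
                    total += null.samples[idx]
            self._group_nulls[key] = total / len(configs)
        return self._group_nulls[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (n_pos, n_total), null in self._nulls.items():
            rows.append(
                pd.DataFrame(
                    {
                        "n_pos": n_pos,
                        "n_total": n_total,
                        "size": self.size,
                        "seed": -1 if self.seed is None else self.seed,
                        "exact": null.exact,
                        "ap": null.samples,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def load(self, path: str) -> None:
        df = pd.read_csv(path)
        for (n_pos, n_total), grp in df.groupby(["n_pos", "n_total"]):
            self._nulls[(int(n_pos), int(n_total))] = NullDistribution(
                int(n_pos),
                int(n_total),
                grp["ap"].to_numpy(),
                bool(grp["exact"].iloc[0]),
                self.seed,
            )


def ap_p_value(observed: float, null: NullDistribution | np.ndarray, raw: bool = False) -> float:
    """Permutation p-value: fraction of the null at or above the observed AP.

    The default adds the +1 smoothing of standard permutation practice (the
    observed statistic counts as one permutation), so p >= 1/(n+1) and p is
    never zero; ``raw=True`` returns the literal unsmoothed fraction.
    """
    samples = null.samples if isinstance(null, NullDistribution) else np.asarray(null)
    if len(samples) == 0:
        raise ValueError("empty null distribution")
    n_ge = int((samples >= observed - 1e-12).sum())
    if raw:
        return n_ge / len(samples)
    return (1 + n_ge) / (1 + len(samples))


def map_p_value(
    configs: list[tuple[int, int]],
    observed_map: float,
    size: int = DEFAULT_SIZE,
    seed: int | None = None,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    raw: bool = False,
    coupling: str = "coupled",
    cache: NullCache | None = None,
) -> float:
    """Permutation p-value for a group mAP.

    ``configs`` lists each member's (n_pos, n_total). Draw k of the null
    mAP averages draw k of each member's null AP samples (see
    ``NullCache.group_null`` for the coupled vs independent draw modes);
    mixed-size groups are handled naturally.
    """
    if cache is None:
        cache = NullCache(size, exact_threshold, seed, coupling)
    null_maps = cache.group_null(list(configs))
    return ap_p_value(observed_map, null_maps, raw=raw)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_retrieved(q_values, alpha: float = 0.05) -> float:
    """Percentage of scores whose (corrected) p-value is below ``alpha``."""
    q = np.asarray(q_values, dtype=np.float64)
    if q.size == 0:
        raise ValueError("empty q-value list")
    return float(100.0 * np.mean(q < alpha))
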