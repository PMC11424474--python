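"""Nearest-neighbour spine-pair statistics and the permutation clustering test.

Neighbouring spines that change size in the same direction amount to spatially
clustered plasticity.  The statistic implemented here works on persistent
spines (those with a defined window-averaged change ``delta_bar``):

1. classify each spine as increasing (``delta_bar > tau``), decreasing
   (``delta_bar < -tau``) or stable, with the threshold ``tau`` set to one
   standard deviation of baseline-session change scores in control animals
   (default 0.14);
2. for every spine find its closest neighbour along the dendritic path, keep
   each unordered pair once, and drop pairs closer than ``d_min`` (overlapping
   ROIs) or farther than ``d_max`` (default 1.0 and 3.5 um, boundaries
   inclusive);
3. compute the fraction of retained pairs in which both spines increased,
   both decreased, both changed in the same direction, or the two changed in
   opposite directions (pairs containing a stable spine count toward none of
   the four);
4. compare the observed pooled fractions against a null built by shuffling
   the ``delta_bar`` values uniformly over the spine positions within each
   dendrite, pair geometry untouched; the Monte Carlo p-value is the tail
   proportion of shuffled fractions at or beyond the observed value.

Fractions are reported both pooled over all pairs (the Monte Carlo test
operates on these) and per dendrite (for group comparisons).  Because the
pair geometry is fixed across shuffles, the engine works on integer pair
counts with a common denominator, so tail comparisons are exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "SpinePair",
    "PairStatistics",
    "MonteCarloResult",
    "METRICS",
    "classify_spine",
    "classify_codes",
    "derive_threshold",
    "nearest_neighbor_pairs",
    "pair_metric_counts",
    "pair_fractions",
    "pair_statistics",
    "shuffle_deltas",
    "monte_carlo_test",
]

#: The four directional pair metrics, in reporting order.
METRICS = (
    "both_increased",
    "both_decreased",
    "same_direction",
    "opposite_direction",
)

_INC, _STABLE, _DEC = 1, 0, -1
_CLASS_NAMES = {_INC: "increasing", _STABLE: "stable", _DEC: "decreasing"}


@dataclass
class ClusteringConfig:
    """Parameters of the clustering analysis.

    ``tau`` is the stable-band half-width in normalized-change units;
    ``d_min``/``d_max`` the inclusive pair-distance window in um; ``n_pools``
    the number of within-dendrite shuffles.  ``tail`` selects the Monte Carlo
    tail: "upper" (shuffled >= observed), "lower", or "auto" (the side toward
    which the observation deviates from the shuffled median, reported per
    metric).  ``include_observed`` switches to the add-one convention
    ``(k + 1) / (n_pools + 1)``.
    """

    tau: float = 0.14
    d_min: float = 1.0
    d_max: float = 3.5
    n_pools: int = 10_000
    window: tuple[int, ...] | None = None
    seed: int = 0
    tail: str = "auto"
    include_observed: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.d_min < self.d_max:
            raise ValueError("need 0 <= d_min < d_max")
        if self.n_pools < 1:
            raise ValueError("n_pools must be >= 1")
        if self.tail not in ("auto", "upper", "lower"):
            raise ValueError("tail must be 'auto', 'upper' or 'lower'")
        if self.n_pools < 100:
            warnings.warn(
                f"n_pools={self.n_pools} gives a p-value resolution of "
                f"{1 / self.n_pools:.2g}; results will be coarse",
                stacklevel=2,
            )


def classify_spine(delta_bar: float, tau: float = 0.14) -> str:
    """Classify one spine: increasing, decreasing or stable.

    The boundary ``|delta_bar| == tau`` classifies as stable.
    """
    if np.isnan(delta_bar):
        raise ValueError("delta_bar undefined (non-persistent spine)")
    if delta_bar > tau:
        return "increasing"
    if delta_bar < -tau:
        return "decreasing"
    return "stable"


def classify_codes(delta_bar, tau: float = 0.14) -> np.ndarray:
    """Vectorized classification to integer codes (+1 / 0 / -1)."""
    delta_bar = np.asarray(delta_bar, dtype=float)
    if np.any(np.isnan(delta_bar)):
        raise ValueError("delta_bar contains undefined values")
    codes = np.zeros(delta_bar.shape, dtype=np.int8)
    codes[delta_bar > tau] = _INC
    codes[delta_bar < -tau] = _DEC
    return codes


def derive_threshold(baseline_deltas, default: float = 0.14) -> float:
    """Stable-band half-width from control baseline variability.

    Returns the sample standard deviation (n-1 denominator) of
    baseline-session change scores.  With fewer than two values, or a
    degenerate zero spread, falls back to ``default`` with a warning.
    """
    values = np.asarray(baseline_deltas, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        warnings.warn(
            f"fewer than two baseline change values; using default tau="
            f"{default}",
            stacklevel=2,
        )
        return default
    tau = float(np.std(values, ddof=1))
    if tau == 0:
        warnings.warn(
            f"baseline change values have zero spread; using default tau="
            f"{default}",
            stacklevel=2,
        )
        return default
    return tau


@dataclass(frozen=True)
class SpinePair:
    """An unordered nearest-neighbour pair (indices into the input arrays)."""

    a: int
    b: int
    distance: float


def nearest_neighbor_pairs(
    positions, d_min: float = 1.0, d_max: float = 3.5
) -> list[SpinePair]:
    """Deduplicated nearest-neighbour pairs within the distance window.

    For every spine the closest other spine along the path is found (an
    equidistant tie breaks toward the smaller position); each unordered pair
    is kept once, and pairs with distance below ``d_min`` or above ``d_max``
    are removed (boundary distances retained).  Fewer than two spines yield
    an empty list.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.size
    if n < 2:
        return []
    order = np.argsort(positions, kind="stable")
    sorted_pos = positions[order]
    seen: set[tuple[int, int]] = set()
    pairs: list[SpinePair] = []
    for k in range(n):
        d_prev = sorted_pos[k] - sorted_pos[k - 1] if k > 0 else np.inf
        d_next = sorted_pos[k + 1] - sorted_pos[k] if k < n - 1 else np.inf
        neighbor = k - 1 if d_prev <= d_next else k + 1
        dist = min(d_prev, d_next)
        i, j = order[k], order[neighbor]
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        if d_min <= dist <= d_max:
            pairs.append(SpinePair(a=key[0], b=key[1], distance=float(dist)))
    return pairs


def pair_metric_counts(pairs, codes) -> dict[str, int]:
    """Counts of the four directional metrics over a pair list."""
    codes = np.asarray(codes)
    counts = dict.fromkeys(METRICS, 0)
    for pair in pairs:
        ca, cb = codes[pair.a], codes[pair.b]
        if ca == _INC and cb == _INC:
            counts["both_increased"] += 1
        elif ca == _DEC and cb == _DEC:
            counts["both_decreased"] += 1
        elif ca * cb == -1:
            counts["opposite_direction"] += 1
    counts["same_direction"] = (
        counts["both_increased"] + counts["both_decreased"]
    )
    return counts


def pair_fractions(pairs, codes) -> dict[str, float]:
    """Percentages of retained pairs per directional metric.

    Pairs containing a stable spine fall in no directional category, so
    same-direction plus opposite-direction percentages need not reach 100.
    """
    if not pairs:
        raise ValueError("no retained pairs")
    counts = pair_metric_counts(pairs, codes)
    return {m: 100.0 * counts[m] / len(pairs) for m in METRICS}


@dataclass
class PairStatistics:
    """Pair geometry and fractions for a classified dataset.

    ``pairs``: one row per retained pair; ``per_dendrite``: percentages per
    dendrite (dendrites with no retained pair omitted from the denominators);
    ``pooled``: percentages over all pairs; ``n_pairs``: pooled pair count.
    """

    pairs: pd.DataFrame
    per_dendrite: pd.DataFrame
    pooled: dict[str, float]
    n_pairs: int


def _dendrite_arrays(spines_df: pd.DataFrame, tau: float):
    """Per-dendrite persistent-spine arrays: positions, deltas, class codes."""
    persistent = spines_df[spines_df["persistent"]]
    out = []
    for dend_id, group in persistent.groupby("dendrite_id", sort=True):
        positions = group["position_um"].to_numpy(dtype=float)
        deltas = group["delta_bar"].to_numpy(dtype=float)
        codes = classify_codes(deltas, tau)
        spine_ids = group["spine_id"].to_numpy()
        out.append((dend_id, positions, deltas, codes, spine_ids))
    return out


def pair_statistics(
    spines_df: pd.DataFrame, config: ClusteringConfig | None = None
) -> PairStatistics:
    """Nearest-neighbour pair table and fractions for a per-spine summary.

    ``spines_df`` is the ``spines`` table of a
    :class:`~spinisi.spines.SizeChangeTable` (columns dendrite_id, spine_id,
    position_um, delta_bar, persistent).  Only persistent spines enter the
    pairing.
    """
    if config is None:
        config = ClusteringConfig()
    pair_rows = []
    per_dendrite_rows = []
    pooled_counts = dict.fromkeys(METRICS, 0)
    total_pairs = 0
    for dend_id, positions, deltas, codes, spine_ids in _dendrite_arrays(
        spines_df, config.tau
    ):
        pairs = nearest_neighbor_pairs(positions, config.d_min, config.d_max)
        if not pairs:
            logger.info(
                "dendrite %s: no retained pairs; omitted from fractions",
                dend_id,
            )
            continue
        for pair in pairs:
            pair_rows.append(
                {
                    "dendrite_id": dend_id,
                    "spine_a": spine_ids[pair.a],
                    "spine_b": spine_ids[pair.b],
                    "distance_um": pair.distance,
                    "class_a": _CLASS_NAMES[int(codes[pair.a])],
                    "class_b": _CLASS_NAMES[int(codes[pair.b])],
                }
            )
        counts = pair_metric_counts(pairs, codes)
        for m in METRICS:
            pooled_counts[m] += counts[m]
        total_pairs += len(pairs)
        row = {"dendrite_id": dend_id, "n_pairs": len(pairs)}
        row.update(
            {f"pct_{m}": 100.0 * counts[m] / len(pairs) for m in METRICS}
        )
        per_dendrite_rows.append(row)
    pooled = {
        m: (100.0 * pooled_counts[m] / total_pairs if total_pairs else np.nan)
        for m in METRICS
    }
    return PairStatistics(
        pairs=pd.DataFrame(
            pair_rows,
            columns=[
                "dendrite_id", "spine_a", "spine_b", "distance_um",
                "class_a", "class_b",
            ],
        ),
        per_dendrite=pd.DataFrame(
            per_dendrite_rows,
            columns=["dendrite_id", "n_pairs"]
            + [f"pct_{m}" for m in METRICS],
        ),
        pooled=pooled,
        n_pairs=total_pairs,
    )


def shuffle_deltas(spines_df: pd.DataFrame, rng) -> pd.DataFrame:
    """One within-dendrite shuffle of the persistent delta_bar values.

    Within each dendrite independently, the multiset of ``delta_bar`` values
    of persistent spines is permuted uniformly over that dendrite's spine
    positions; positions, presence and pair geometry are untouched.
    """
    out = spines_df.copy()
    for dend_id, group in out[out["persistent"]].groupby(
        "dendrite_id", sort=True
    ):
        perm = rng.permutation(len(group))
        out.loc[group.index, "delta_bar"] = (
            group["delta_bar"].to_numpy()[perm]
        )
    return out


@dataclass
class MonteCarloResult:
    """Observed pooled fractions, shuffle distributions and tail p-values."""

    observed: dict[str, float]
    observed_counts: dict[str, int]
    shuffled: dict[str, np.ndarray]
    p_values: dict[str, float]
    tails: dict[str, str]
    n_pairs: int
    n_pools: int
    n_dendrites: int

    def summary(self) -> pd.DataFrame:
        """One row per metric: observed %, shuffled mean %, p, tail side."""
        rows = [
            {
                "metric": m,
                "observed_pct": self.observed[m],
                "shuffled_mean_pct": float(np.mean(self.shuffled[m])),
                "p_value": self.p_values[m],
                "tail": self.tails[m],
            }
            for m in METRICS
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            m: {
                "observed": self.observed[m],
                "p": self.p_values[m],
                "tail": self.tails[m],
            }
            for m in METRICS
        }


def _shuffled_metric_counts(codes, pairs, n_pools, rng) -> np.ndarray:
    """(n_pools, 4) metric counts for uniform permutations of one dendrite."""
    n = codes.size
    perms = np.argsort(rng.random((n_pools, n)), axis=1)
    permuted = codes[perms]
    a_idx = np.fromiter((p.a for p in pairs), dtype=int)
    b_idx = np.fromiter((p.b for p in pairs), dtype=int)
    a = permuted[:, a_idx]
    b = permuted[:, b_idx]
    both_inc = np.sum((a == _INC) & (b == _INC), axis=1)
    both_dec = np.sum((a == _DEC) & (b == _DEC), axis=1)
    opposite = np.sum(a.astype(np.int16) * b.astype(np.int16) == -1, axis=1)
    return np.stack(
        [both_inc, both_dec, both_inc + both_dec, opposite], axis=1
    )


def _tail_p(observed, shuffled, tail, include_observed):
    """Tail proportion at or beyond the observed count (exact integer ties)."""
    n = shuffled.size
    median = float(np.median(shuffled))
    if tail == "auto":
        side = "upper" if observed >= median else "lower"
    else:
        side = tail
    if side == "upper":
        k = int(np.sum(shuffled >= observed))
    else:
        k = int(np.sum(shuffled <= observed))
    if include_observed:
        return (k + 1) / (n + 1), side
    return k / n, side


def monte_carlo_test(
    spines_df: pd.DataFrame,
    config: ClusteringConfig | None = None,
    rng=None,
) -> MonteCarloResult:
    """Within-dendrite shuffle test of spatial clustering.

    For each of the four pair metrics, the observed pooled fraction is
    compared against ``n_pools`` re-computations in which the persistent
    ``delta_bar`` values are permuted uniformly over spine positions within
    each dendrite.  The p-value is the proportion of shuffled values at or
    beyond the observed one on the configured tail (ties counted).
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    if config is None:
        config = ClusteringConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    observed_counts = np.zeros(4, dtype=np.int64)
    shuffled_counts = np.zeros((config.n_pools, 4), dtype=np.int64)
    total_pairs = 0
    n_dendrites = 0
    for dend_id, positions, deltas, codes, _ids in _dendrite_arrays(
        spines_df, config.tau
    ):
        pairs = nearest_neighbor_pairs(positions, config.d_min, config.d_max)
        if not pairs:
            continue
        n_dendrites += 1
        total_pairs += len(pairs)
        counts = pair_metric_counts(pairs, codes)
        observed_counts += np.array([counts[m] for m in METRICS])
        shuffled_counts += _shuffled_metric_counts(
            codes, pairs, config.n_pools, rng
        )
    if total_pairs == 0:
        raise ValueError("no retained pairs in any dendrite")
    observed = {
        m: 100.0 * observed_counts[i] / total_pairs
        for i, m in enumerate(METRICS)
    }
    shuffled = {
        m: 100.0 * shuffled_counts[:, i] / total_pairs
        for i, m in enumerate(METRICS)
    }
    p_values = {}
    tails = {}
    for i, m in enumerate(METRICS):
        p, side = _tail_p(
            int(observed_counts[i]),
            shuffled_counts[:, i],
            config.tail,
            config.include_observed,
        )
        p_values[m] = p
        tails[m] = side
    return MonteCarloResult(
        observed=observed,
        observed_counts={
            m: int(observed_counts[i]) for i, m in enumerate(METRICS)
        },
        shuffled=shuffled,
        p_values=p_values,
        tails=tails,
        n_pairs=total_pairs,
        n_pools=config.n_pools,
        n_dendrites=n_dendrites,
    )
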