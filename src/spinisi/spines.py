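"""Containers and per-spine metrics for longitudinal dendritic-spine imaging.

Dendritic spines are imaged repeatedly over days; the fluorescence intensity of
a spine head is used as a proxy for synaptic strength.  To compare intensities
across imaging sessions, each spine measurement is normalized to the adjacent
dendritic shaft after background subtraction (``raw_spine_size``).  Size
changes relative to a baseline window are expressed with a bounded score

    delta = (v_d - v_base) / (v_d + v_base)

which lies in [-1, +1] for non-negative sizes: -1 is complete loss of signal,
+1 an appearance from nothing, and 0 no change.  Structural remodelling is
summarized per dendritic segment as addition and elimination rates (counts on
a session divided by the spine count of the previous session) and their sum,
the turnover ratio.

The containers here (:class:`SpineDataset` / :class:`DendriteSegment` /
:class:`SpineTrajectory`) are the unit of every downstream analysis.  A
dataset is a list of dendritic segments, each carrying spine trajectories with
per-session presence flags and intensity triplets (spine ROI, adjacent-shaft
ROI, background ROI), aligned to a shared, strictly increasing schedule of
integer day labels.  Day labels are relative to the manipulation: day 0 is the
last pre-manipulation session, and the baseline sessions form a prefix of the
schedule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateIntensityError",
    "SpineTrajectory",
    "DendriteSegment",
    "SpineDataset",
    "SizeChangeTable",
    "raw_spine_size",
    "normalized_change",
    "baseline_size",
    "size_change_table",
    "turnover_rates",
    "turnover_table",
    "spine_density",
    "density_table",
    "paired_session_average",
]


class DegenerateIntensityError(ValueError):
    """Shaft intensity at or below background: the size denominator vanishes."""


def raw_spine_size(spine_intensity, shaft_intensity, background_intensity):
    """Background-subtracted, shaft-normalized spine size.

    Parameters may be scalars or arrays.  Returns
    ``(spine - background) / (shaft - background)``, clipped below at 0 when
    the spine ROI is dimmer than the background (sizes are non-negative by
    definition, and the bounds of the change score depend on that).

    Raises
    ------
    DegenerateIntensityError
        If any shaft intensity is at or below its background intensity.
    """
    spine = np.asarray(spine_intensity, dtype=float)
    shaft = np.asarray(shaft_intensity, dtype=float)
    background = np.asarray(background_intensity, dtype=float)
    denom = shaft - background
    if np.any(denom <= 0):
        raise DegenerateIntensityError(
            "shaft intensity must exceed background intensity "
            f"(shaft={shaft!r}, background={background!r})"
        )
    size = np.maximum((spine - background) / denom, 0.0)
    if np.ndim(size) == 0:
        return float(size)
    return size


def normalized_change(v_d, v_base):
    """Bounded size-change score ``(v_d - v_base) / (v_d + v_base)``.

    Both arguments must be non-negative and not simultaneously zero; the score
    is then confined to [-1, +1], reaching -1 only at ``v_d = 0`` and +1 only
    at ``v_base = 0``.
    """
    v_d = np.asarray(v_d, dtype=float)
    v_base = np.asarray(v_base, dtype=float)
    if np.any(v_d < 0) or np.any(v_base < 0):
        raise ValueError("sizes must be non-negative")
    total = v_d + v_base
    if np.any(total == 0):
        raise ValueError(
            "normalized change undefined when both sizes are zero"
        )
    delta = (v_d - v_base) / total
    if np.ndim(delta) == 0:
        return float(delta)
    return delta


def baseline_size(sizes, baseline_mask):
    """Mean raw size over the baseline sessions in which the spine is present.

    ``sizes`` is a per-session array with NaN where the spine is absent;
    ``baseline_mask`` is a boolean array marking the baseline sessions.
    Returns NaN if the spine is absent from every baseline session (such
    spines are flagged non-persistent and excluded from size analyses).
    """
    sizes = np.asarray(sizes, dtype=float)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    vals = sizes[baseline_mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


@dataclass
class SpineTrajectory:
    """One spine tracked across all imaging sessions of a dendrite.

    All per-session arrays are aligned to ``SpineDataset.sessions``.
    Intensity entries are meaningful only where ``present`` is True (NaN
    elsewhere).  ``true_size`` / ``true_change`` carry generator ground truth
    for synthetic data and are NaN for real annotations.
    """

    id: int
    position: float
    present: np.ndarray
    spine_intensity: np.ndarray
    shaft_intensity: np.ndarray
    background_intensity: np.ndarray
    true_size: np.ndarray | None = None
    true_change: float = float("nan")

    def raw_sizes(self) -> np.ndarray:
        """Shaft-normalized size per session (NaN where absent)."""
        out = np.full(self.present.shape, np.nan)
        idx = np.flatnonzero(self.present)
        if idx.size:
            try:
                out[idx] = raw_spine_size(
                    self.spine_intensity[idx],
                    self.shaft_intensity[idx],
                    self.background_intensity[idx],
                )
            except DegenerateIntensityError as err:
                raise DegenerateIntensityError(
                    f"spine {self.id}: {err}"
                ) from None
        return out


@dataclass
class DendriteSegment:
    """A traced dendritic segment with its spines.

    Positions are distances in μm along the traced path (not 3-D Euclidean
    distances); pairing and density are defined along the segment.
    """

    id: int
    length: float
    spines: list[SpineTrajectory] = field(default_factory=list)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"dendrite {self.id}: length must be positive")
        for spine in self.spines:
            if not 0 <= spine.position <= self.length:
                raise ValueError(
                    f"dendrite {self.id}, spine {spine.id}: position "
                    f"{spine.position} outside [0, {self.length}]"
                )

    def presence_matrix(self) -> np.ndarray:
        """Boolean (n_spines, n_sessions) presence matrix."""
        if not self.spines:
            return np.zeros((0, 0), dtype=bool)
        return np.vstack([s.present for s in self.spines])


@dataclass
class SpineDataset:
    """Dendrites plus the shared session schedule.

    ``sessions`` are strictly increasing integer day labels;
    ``baseline_sessions`` is a non-empty prefix of ``sessions``.
    """

    dendrites: list[DendriteSegment]
    sessions: tuple[int, ...]
    baseline_sessions: tuple[int, ...]

    def __post_init__(self):
        self.sessions = tuple(int(s) for s in self.sessions)
        self.baseline_sessions = tuple(int(s) for s in self.baseline_sessions)
        if len(self.sessions) < 2:
            raise ValueError("need at least two sessions")
        if any(b >= a for a, b in zip(self.sessions[1:], self.sessions)):
            raise ValueError("session labels must be strictly increasing")
        if not self.baseline_sessions:
            raise ValueError("need at least one baseline session")
        if self.sessions[: len(self.baseline_sessions)] != self.baseline_sessions:
            raise ValueError("baseline sessions must be a prefix of sessions")
        n = len(self.sessions)
        for dend in self.dendrites:
            for spine in dend.spines:
                if len(spine.present) != n:
                    raise ValueError(
                        f"dendrite {dend.id}, spine {spine.id}: per-session "
                        f"arrays must have length {n}"
                    )

    @property
    def post_sessions(self) -> tuple[int, ...]:
        return self.sessions[len(self.baseline_sessions):]

    @property
    def n_spines(self) -> int:
        return sum(len(d.spines) for d in self.dendrites)

    def baseline_mask(self) -> np.ndarray:
        return np.array(
            [s in self.baseline_sessions for s in self.sessions], dtype=bool
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: one row per spine × session (the CSV interchange schema)."""
        rows = []
        for dend in self.dendrites:
            for spine in dend.spines:
                for k, day in enumerate(self.sessions):
                    rows.append(
                        {
                            "dendrite_id": dend.id,
                            "spine_id": spine.id,
                            "position_um": spine.position,
                            "day": day,
                            "present": int(spine.present[k]),
                            "spine_intensity": spine.spine_intensity[k],
                            "shaft_intensity": spine.shaft_intensity[k],
                            "background_intensity": spine.background_intensity[k],
                            "true_size": (
                                spine.true_size[k]
                                if spine.true_size is not None
                                else np.nan
                            ),
                            "true_change": spine.true_change,
                            "dendrite_length_um": dend.length,
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        baseline_sessions,
        allow_readdition: bool = False,
    ) -> "SpineDataset":
        """Rebuild a dataset from the long interchange table.

        Missing spine × session rows are treated as absences.  A presence gap
        (present, absent, then present again) is rejected unless
        ``allow_readdition`` is set: with re-addition disabled an eliminated
        spine must stay absent.
        """
        required = {
            "dendrite_id", "spine_id", "position_um", "day", "present",
            "spine_intensity", "shaft_intensity", "background_intensity",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        days = df["day"]
        if not np.all(days == days.astype(int)):
            bad = df.index[days != days.astype(int)][0]
            raise ValueError(
                f"column 'day' must be integer (row {bad}: {days.loc[bad]!r})"
            )
        sessions = tuple(sorted(int(d) for d in days.unique()))
        has_truth = "true_size" in df.columns
        day_index = {d: k for k, d in enumerate(sessions)}
        n = len(sessions)
        dendrites = []
        for dend_id, dgroup in df.groupby("dendrite_id", sort=True):
            if "dendrite_length_um" in dgroup.columns and dgroup[
                "dendrite_length_um"
            ].notna().any():
                length = float(dgroup["dendrite_length_um"].dropna().iloc[0])
            else:
                length = float(dgroup["position_um"].max())
                warnings.warn(
                    f"dendrite {dend_id}: no dendrite_length_um column; "
                    "using max spine position as segment length",
                    stacklevel=2,
                )
            spines = []
            for spine_id, sgroup in dgroup.groupby("spine_id", sort=True):
                positions = sgroup["position_um"].unique()
                if len(positions) != 1:
                    raise ValueError(
                        f"dendrite {dend_id}, spine {spine_id}: inconsistent "
                        f"positions {positions}"
                    )
                present = np.zeros(n, dtype=bool)
                arrays = {
                    name: np.full(n, np.nan)
                    for name in (
                        "spine_intensity",
                        "shaft_intensity",
                        "background_intensity",
                        "true_size",
                    )
                }
                for _, row in sgroup.iterrows():
                    k = day_index[int(row["day"])]
                    is_present = bool(row["present"])
                    present[k] = is_present
                    if is_present:
                        for name in (
                            "spine_intensity",
                            "shaft_intensity",
                            "background_intensity",
                        ):
                            if np.isnan(row[name]):
                                raise ValueError(
                                    f"dendrite {dend_id}, spine {spine_id}, "
                                    f"day {int(row['day'])}: present spine "
                                    f"with undefined {name}"
                                )
                            arrays[name][k] = row[name]
                        if has_truth and not np.isnan(row.get("true_size", np.nan)):
                            arrays["true_size"][k] = row["true_size"]
                if not allow_readdition:
                    idx = np.flatnonzero(present)
                    if idx.size and np.any(~present[idx[0]: idx[-1] + 1]):
                        raise ValueError(
                            f"dendrite {dend_id}, spine {spine_id}: presence "
                            "gap (absent between present sessions); pass "
                            "allow_readdition=True to accept"
                        )
                true_change = float("nan")
                if "true_change" in sgroup.columns:
                    tc = sgroup["true_change"].dropna()
                    if not tc.empty:
                        true_change = float(tc.iloc[0])
                spines.append(
                    SpineTrajectory(
                        id=int(spine_id),
                        position=float(positions[0]),
                        present=present,
                        spine_intensity=arrays["spine_intensity"],
                        shaft_intensity=arrays["shaft_intensity"],
                        background_intensity=arrays["background_intensity"],
                        true_size=arrays["true_size"] if has_truth else None,
                        true_change=true_change,
                    )
                )
            dendrites.append(
                DendriteSegment(id=int(dend_id), length=length, spines=spines)
            )
        return cls(
            dendrites=dendrites,
            sessions=sessions,
            baseline_sessions=tuple(int(b) for b in baseline_sessions),
        )


@dataclass
class SizeChangeTable:
    """Per-spine size-change results.

    ``changes``: long table (dendrite_id, spine_id, day, size, delta) with the
    bounded change score per session, including baseline sessions referenced
    to the baseline mean (used to derive the classification threshold from
    control variability).

    ``spines``: one row per spine with its baseline size, the window-averaged
    change ``delta_bar`` and a ``persistent`` flag.  Following the persistence
    rule, a spine absent at any baseline or window session has no defined
    ``delta_bar`` and is excluded from size-change and clustering analyses
    (it still counts in turnover metrics).
    """

    changes: pd.DataFrame
    spines: pd.DataFrame
    window: tuple[int, ...]
    excluded: pd.DataFrame


def size_change_table(dataset: SpineDataset, window=None) -> SizeChangeTable:
    """Compute per-session change scores and window-averaged changes.

    ``window`` defaults to all post-baseline sessions (days 1-4 under the
    default schedule).  The window average is taken over per-session change
    scores, not over paired-session presentation averages.
    """
    if window is None:
        window = dataset.post_sessions
    window = tuple(int(w) for w in window)
    unknown = set(window) - set(dataset.sessions)
    if unknown:
        raise ValueError(f"window days not in schedule: {sorted(unknown)}")
    baseline_mask = dataset.baseline_mask()
    window_mask = np.array([s in window for s in dataset.sessions], dtype=bool)
    change_rows = []
    spine_rows = []
    excluded_rows = []
    for dend in dataset.dendrites:
        for spine in dend.spines:
            sizes = spine.raw_sizes()
            v_base = baseline_size(sizes, baseline_mask)
            deltas = np.full(sizes.shape, np.nan)
            if not np.isnan(v_base):
                for k in np.flatnonzero(~np.isnan(sizes)):
                    if sizes[k] + v_base == 0:
                        logger.info(
                            "dendrite %s spine %s day %s: both sizes zero; "
                            "change undefined, session excluded",
                            dend.id, spine.id, dataset.sessions[k],
                        )
                        continue
                    deltas[k] = normalized_change(sizes[k], v_base)
            for k, day in enumerate(dataset.sessions):
                change_rows.append(
                    (dend.id, spine.id, day, sizes[k], deltas[k])
                )
            required = baseline_mask | window_mask
            persistent = bool(np.all(spine.present[required]))
            reason = None
            if np.isnan(v_base):
                reason = "absent at all baseline sessions"
            elif not persistent:
                reason = "absent at a baseline or window session"
            elif np.any(np.isnan(deltas[window_mask])):
                persistent = False
                reason = "undefined change in window (both sizes zero)"
            if reason is not None:
                persistent = False
                excluded_rows.append(
                    {
                        "dendrite_id": dend.id,
                        "spine_id": spine.id,
                        "reason": reason,
                    }
                )
            delta_bar = (
                float(np.mean(deltas[window_mask])) if persistent else np.nan
            )
            spine_rows.append(
                {
                    "dendrite_id": dend.id,
                    "spine_id": spine.id,
                    "position_um": spine.position,
                    "baseline_size": v_base,
                    "delta_bar": delta_bar,
                    "persistent": persistent,
                    "true_change": spine.true_change,
                }
            )
    changes = pd.DataFrame(
        change_rows,
        columns=["dendrite_id", "spine_id", "day", "size", "delta"],
    )
    spines = pd.DataFrame(spine_rows)
    excluded = pd.DataFrame(
        excluded_rows, columns=["dendrite_id", "spine_id", "reason"]
    )
    if len(excluded):
        logger.info(
            "%d spines excluded from size analyses (%s)",
            len(excluded),
            "; ".join(
                f"{reason}: {n}"
                for reason, n in excluded["reason"].value_counts().items()
            ),
        )
    return SizeChangeTable(
        changes=changes, spines=spines, window=window, excluded=excluded
    )


def turnover_rates(n_prev: int, n_added: int, n_eliminated: int):
    """Addition/elimination rates and turnover for one dendrite-session.

    Rates are counts divided by the spine count of the previous session; the
    turnover ratio is their sum (stored as that exact sum).
    """
    if n_prev <= 0:
        raise ValueError("rates undefined with no spines at previous session")
    addition_rate = n_added / n_prev
    elimination_rate = n_eliminated / n_prev
    return addition_rate, elimination_rate, addition_rate + elimination_rate


def turnover_table(dataset: SpineDataset) -> pd.DataFrame:
    """Per-dendrite, per-session addition/elimination/turnover rates.

    A spine is newly added on a session if present then but not on the
    previous session, and eliminated if present previously but absent now.
    Dendrite-sessions with no spines on the previous session are skipped with
    a log message (the rates are undefined).
    """
    rows = []
    for dend in dataset.dendrites:
        presence = dend.presence_matrix()
        for k in range(1, len(dataset.sessions)):
            if presence.size == 0:
                n_prev = 0
            else:
                n_prev = int(presence[:, k - 1].sum())
            if n_prev == 0:
                logger.info(
                    "dendrite %s day %s: no spines at previous session; "
                    "rates undefined, skipped",
                    dend.id, dataset.sessions[k],
                )
                continue
            n_added = int(np.sum(presence[:, k] & ~presence[:, k - 1]))
            n_elim = int(np.sum(~presence[:, k] & presence[:, k - 1]))
            add_rate, elim_rate, turnover = turnover_rates(
                n_prev, n_added, n_elim
            )
            rows.append(
                {
                    "dendrite_id": dend.id,
                    "day": dataset.sessions[k],
                    "n_prev": n_prev,
                    "n_added": n_added,
                    "n_eliminated": n_elim,
                    "addition_rate": add_rate,
                    "elimination_rate": elim_rate,
                    "turnover": turnover,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dendrite_id", "day", "n_prev", "n_added", "n_eliminated",
            "addition_rate", "elimination_rate", "turnover",
        ],
    )


def spine_density(dendrite: DendriteSegment, session_index: int) -> float:
    """Spines present at a session divided by segment length (per μm)."""
    if not dendrite.spines:
        return 0.0
    n = int(sum(s.present[session_index] for s in dendrite.spines))
    return n / dendrite.length


def density_table(dataset: SpineDataset) -> pd.DataFrame:
    """Per-dendrite spine density at every session."""
    rows = [
        {
            "dendrite_id": dend.id,
            "day": day,
            "n_present": int(
                sum(s.present[k] for s in dend.spines)
            ),
            "density": spine_density(dend, k),
        }
        for dend in dataset.dendrites
        for k, day in enumerate(dataset.sessions)
    ]
    return pd.DataFrame(
        rows, columns=["dendrite_id", "day", "n_present", "density"]
    )


def paired_session_average(
    series: pd.Series, leftover: str = "drop"
) -> pd.Series:
    """Average adjacent imaging sessions for presentation.

    Values keyed by day are averaged pairwise in schedule order (-3 with -2,
    -1 with 0, 1 with 2, ...), labelled "a/b".  An odd leftover session is
    dropped with a warning by default, or kept as a singleton with
    ``leftover="keep"``.
    """
    if leftover not in ("drop", "keep"):
        raise ValueError("leftover must be 'drop' or 'keep'")
    series = series.sort_index()
    days = list(series.index)
    out = {}
    for i in range(0, len(days) - 1, 2):
        a, b = days[i], days[i + 1]
        out[f"{a}/{b}"] = (series[a] + series[b]) / 2
    if len(days) % 2:
        if leftover == "keep":
            out[str(days[-1])] = series[days[-1]]
        else:
            warnings.warn(
                f"odd leftover session {days[-1]} dropped from pairing",
                stacklevel=2,
            )
    return pd.Series(out)
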