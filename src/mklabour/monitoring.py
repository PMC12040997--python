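"""Peer-based online monitoring: the dynamic core of the paradigm.

For a monitored subject at each follow-up, the engine (1) projects the
updated state into the learned embedding, (2) retrieves *peers* — historical
training subjects whose interpolated embedded position at the same time
since admission lies within a hypersphere around the subject, (3) estimates
a personalised "ideal" trajectory as the mean +/- dispersion of the peers
with uncomplicated outcomes and measures the subject's z-score deviation
from the reference estimated at the *previous* follow-up, and (4) estimates
the chance of a future event as the proportion of peers who would yet
experience it.  Per-subject summaries are the maxima over follow-ups of
pi(t), pi(t)*z(t) and pi(t)*z(t)*t  (the scores v_pi, v_pi_z, v_pi_z_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CS_EVENT
from .embedding import EmbeddedPoint, MKLEmbeddingResults, Trajectory
from .exceptions import ValidationError
from .pipeline import EncodedCohort, SubjectState

NO_REFERENCE = "no_reference"
REFERENCE_EXPIRED = "reference_expired"
INFINITE_Z = "infinite_z"
UNDEFINED_CHANCE = "undefined_chance"
EMPTY_DISTRIBUTION = "empty_distribution"


class TrajectoryIndex:
    """Training-cohort trajectories, vectorised for position-at-time queries.

    A training subject's embedded position at an arbitrary time t is the
    linear interpolation between the surrounding follow-ups; past the last
    follow-up (but before delivery) the last position is held.  Subjects
    already delivered at t (or with no follow-up yet) are invalid at t.
    """

    def __init__(self, trajectories, outcomes: pd.DataFrame, events_table: pd.DataFrame):
        if not trajectories:
            raise ValidationError("cannot build a trajectory index from an empty training set")
        self.subject_ids = [tr.subject_id for tr in trajectories]
        self.n = len(trajectories)
        self.n_dims = trajectories[0].coords.shape[1]
        L = max(len(tr) for tr in trajectories)
        self._times = np.full((self.n, L), np.inf)
        self._coords = np.zeros((self.n, L, self.n_dims))
        self._n_obs = np.zeros(self.n, dtype=int)
        for i, tr in enumerate(trajectories):
            k = len(tr)
            self._times[i, :k] = tr.times
            self._coords[i, :k] = tr.coords
            self._n_obs[i] = k
        out = outcomes.loc[self.subject_ids]
        self.delivery = out["delivery_time"].to_numpy(dtype=float)
        self.uncomplicated = (
            (out["outcome_label"] == "uncomplicated") & (~out["cs_flag"].astype(bool))
        ).to_numpy()
        ev = events_table.groupby(["subject_id", "event"])["t_event"].min()
        self._event_times: dict[str, np.ndarray] = {}
        for event in events_table["event"].unique():
            col = np.full(self.n, np.nan)
            for i, sid in enumerate(self.subject_ids):
                key = (sid, event)
                if key in ev.index:
                    col[i] = ev.loc[key]
            self._event_times[event] = col
        # default peer radius: 10% of the dimension-wise IQR norm of the
        # admission-time training embedding
        adm = self._coords[np.arange(self.n), 0]
        iqr = np.subtract(*np.percentile(adm, [75, 25], axis=0))
        self.default_radius = max(0.1 * float(np.linalg.norm(iqr)), 1e-9)

    @classmethod
    def from_cohort(
        cls, results: MKLEmbeddingResults, cohort: EncodedCohort, subject_ids=None
    ) -> "TrajectoryIndex":
        ids = list(subject_ids) if subject_ids is not None else cohort.subject_ids
        # project all follow-ups of all subjects in one kernel evaluation
        blocks, times_list = [], []
        for sid in ids:
            times, mat = cohort.state_matrix(sid)
            times_list.append(times)
            blocks.append(mat)
        coords = results.project(np.vstack(blocks))
        trajectories, k0 = [], 0
        for sid, times in zip(ids, times_list):
            k1 = k0 + times.size
            trajectories.append(Trajectory(sid, times, coords[k0:k1]))
            k0 = k1
        return cls(trajectories, cohort.outcomes, cohort.events)

    def event_times(self, event: str) -> np.ndarray:
        return self._event_times.get(event, np.full(self.n, np.nan))

    def positions_at(self, t: float):
        """(positions (n x d), valid mask) for all training subjects at time t."""
        j = (self._times <= t).sum(axis=1)
        valid = (j >= 1) & (t <= self.delivery) & (t >= 0)
        rows = np.arange(self.n)
        jm1 = np.clip(j - 1, 0, self._times.shape[1] - 1)
        jj = np.clip(j, 0, self._times.shape[1] - 1)
        hold = j >= self._n_obs
        t0 = self._times[rows, jm1]
        t1 = self._times[rows, jj]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(hold | (t1 <= t0) | ~np.isfinite(t1), 0.0, (t - t0) / (t1 - t0))
        c0 = self._coords[rows, jm1]
        c1 = self._coords[rows, jj]
        pos = c0 + frac[:, None] * (c1 - c0)
        pos[~valid] = np.nan
        return pos, valid


@dataclass
class PeerSet:
    """Training subjects within a hypersphere around the query at time t."""

    subject_id: str
    t: float
    peer_indices: np.ndarray
    peer_ids: list
    distances: np.ndarray
    radius: float
    expanded: bool = False

    def __len__(self):
        return len(self.peer_indices)


def find_peers(
    index: TrajectoryIndex,
    query: np.ndarray | EmbeddedPoint,
    t: float | None = None,
    radius: float | None = None,
    min_peers: int = 30,
    expansion: float = 1.5,
    exclude_id: str | None = None,
    subject_id: str = "?",
) -> PeerSet:
    """All training subjects whose interpolated position at t is within radius.

    If fewer than ``min_peers`` fall inside, the radius expands geometrically
    (factor ``expansion``) until satisfied or every valid subject is
    included; the expansion flag is set in that case.
    """
    if isinstance(query, EmbeddedPoint):
        subject_id, t, query = query.subject_id, query.t, query.coordinates
    if t is None:
        raise ValidationError("query time t is required")
    query = np.asarray(query, dtype=float)
    if radius is None:
        radius = index.default_radius
    pos, valid = index.positions_at(t)
    if exclude_id is not None and exclude_id in index.subject_ids:
        valid = valid.copy()
        valid[index.subject_ids.index(exclude_id)] = False
    dist = np.full(index.n, np.inf)
    dist[valid] = np.linalg.norm(pos[valid] - query, axis=1)
    n_valid = int(valid.sum())
    expanded = False
    r = max(float(radius), 1e-12)
    while True:
        inside = dist <= r
        if inside.sum() >= min(min_peers, n_valid) or n_valid == 0:
            break
        r *= expansion
        expanded = True
    idx = np.where(inside)[0]
    order = np.argsort(dist[idx], kind="stable")
    idx = idx[order]
    return PeerSet(
        subject_id=subject_id, t=float(t), peer_indices=idx,
        peer_ids=[index.subject_ids[i] for i in idx],
        distances=dist[idx], radius=r, expanded=expanded,
    )


@dataclass
class IdealTrajectory:
    """Peer-derived expected curve: mean, dispersion and support over time.

    The curve is estimated from uncomplicated-outcome peers only, on a
    regular time grid, and *cropped* at the first time where the number of
    contributing peers drops below half its initial value (slower labours
    would otherwise dominate the tail).
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    sd: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    support: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    crop_time: float = np.inf
    flag: str | None = None

    @property
    def available(self) -> bool:
        return self.flag is None and self.times.size > 0

    def at(self, t: float):
        """Interpolated (mean, sd) at t, or (None, None, flag)."""
        if not self.available:
            return None, None, NO_REFERENCE
        if t >= self.crop_time or t < self.times[0] or t > self.times[-1]:
            return None, None, REFERENCE_EXPIRED
        e = np.array([np.interp(t, self.times, self.mean[:, p]) for p in range(self.mean.shape[1])])
        s = np.array([np.interp(t, self.times, self.sd[:, p]) for p in range(self.sd.shape[1])])
        return e, s, None

    def plot(self, dim: int = 0, ax=None):
        """Mean +/- sd band along one dimension, with the support count below."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(2, 1, sharex=True, height_ratios=[3, 1])
            ax, ax_support = axes
        else:
            ax_support = None
        m, s = self.mean[:, dim], self.sd[:, dim]
        ax.plot(self.times, m, color="tab:blue", label=f"expected dim {dim + 1}")
        ax.fill_between(self.times, m - s, m + s, color="tab:pink", alpha=0.5, label="+/- sd")
        ax.set_ylabel(f"dimension {dim + 1}")
        ax.legend()
        if ax_support is not None:
            ax_support.step(self.times, self.support, where="post", color="k")
            ax_support.set_ylabel("|C(t)|")
            ax_support.set_xlabel("hours since admission")
        return ax


def estimate_ideal_trajectory(
    index: TrajectoryIndex,
    peers: PeerSet,
    grid_step: float = 0.5,
    support_floor: int = 10,
) -> IdealTrajectory:
    """Mean/dispersion curve of uncomplicated peers from the query time on.

    Dispersion is the population standard deviation per dimension.  If fewer
    than ``support_floor`` uncomplicated peers are available at the start,
    the result is flagged ``no_reference`` rather than raising.
    """
    ref_idx = peers.peer_indices[index.uncomplicated[peers.peer_indices]]
    if ref_idx.size < support_floor:
        return IdealTrajectory(flag=NO_REFERENCE)
    t_end = float(np.max(index.delivery[ref_idx]))
    times = peers.t + grid_step * np.arange(int(np.floor((t_end - peers.t) / grid_step)) + 1)
    means, sds, supports = [], [], []
    for t in times:
        pos, valid = index.positions_at(float(t))
        sub = ref_idx[valid[ref_idx]]
        supports.append(sub.size)
        if sub.size:
            means.append(pos[sub].mean(axis=0))
            sds.append(pos[sub].std(axis=0, ddof=0))
        else:
            means.append(np.full(index.n_dims, np.nan))
            sds.append(np.full(index.n_dims, np.nan))
    support = np.asarray(supports)
    if support[0] < support_floor:
        return IdealTrajectory(flag=NO_REFERENCE)
    below = np.where(support < support[0] / 2.0)[0]
    crop_time = float(times[below[0]]) if below.size else np.inf
    keep = (support >= support_floor) & (times < crop_time)
    # keep the contiguous prefix of valid grid points
    cut = int(np.argmin(keep)) if not keep.all() else keep.size
    return IdealTrajectory(
        times=times[:cut], mean=np.asarray(means)[:cut], sd=np.asarray(sds)[:cut],
        support=support[:cut], crop_time=crop_time,
    )


@dataclass
class ZScore:
    value: float
    flag: str | None = None

    @property
    def valid(self) -> bool:
        return self.flag is None and np.isfinite(self.value)


def deviation_z(query: np.ndarray, t: float, ideal: IdealTrajectory) -> ZScore:
    """Deviation from the expected position, in peer standard deviations.

    Per dimension ``z_d = |y_d - E_d(t)| / sigma_d(t)``, aggregated as the
    Euclidean norm divided by sqrt(n_dims) — dimensionless, and equal to the
    textbook z-score in one dimension.  Zero dispersion with a nonzero
    offset yields an infinite, flagged z.
    """
    query = np.asarray(query, dtype=float)
    e, s, flag = ideal.at(t)
    if flag is not None:
        return ZScore(np.nan, flag)
    offset = np.abs(query - e)
    with np.errstate(divide="ignore", invalid="ignore"):
        zd = np.where(offset == 0.0, 0.0, offset / s)
    if np.any(np.isinf(zd)) or np.any(np.isnan(zd)):
        return ZScore(np.inf, INFINITE_Z)
    return ZScore(float(np.linalg.norm(zd) / np.sqrt(zd.size)))


@dataclass
class ChanceEstimate:
    value: float
    flag: str | None = None

    @property
    def valid(self) -> bool:
        return self.flag is None and np.isfinite(self.value)


def event_chance(index: TrajectoryIndex, peers: PeerSet, event: str, t: float) -> ChanceEstimate:
    """Proportion of peers who would *yet* experience the event after t.

    Peers whose event already occurred at or before t count in the
    denominator only; peers who never experience it likewise.
    """
    if len(peers) == 0:
        return ChanceEstimate(np.nan, UNDEFINED_CHANCE)
    times = index.event_times(event)[peers.peer_indices]
    future = np.sum(np.nan_to_num(times, nan=-np.inf) > t)
    return ChanceEstimate(float(future) / len(peers))


@dataclass
class EventTimeDistribution:
    """Empirical distribution of event timings among peers."""

    times: np.ndarray  # sorted occurrence times
    n_peers: int
    flag: str | None = None

    @property
    def cdf(self):
        """(support, cumulative fraction) step function over occurrence times."""
        k = self.times.size
        return self.times, np.arange(1, k + 1) / k

    def cdf_at(self, t: float) -> float:
        return float(np.searchsorted(self.times, t, side="right")) / self.times.size

    def median(self) -> float:
        return float(np.median(self.times))

    def chance_by_time(self, t: float) -> float:
        """Chance the event still lies ahead at time t (scaled to all peers)."""
        later = np.sum(self.times > t)
        return float(later) / self.n_peers


def event_time_distribution(index: TrajectoryIndex, peers: PeerSet, event: str) -> EventTimeDistribution:
    times = index.event_times(event)[peers.peer_indices]
    times = np.sort(times[np.isfinite(times)])
    if times.size == 0:
        return EventTimeDistribution(times=times, n_peers=len(peers), flag=EMPTY_DISTRIBUTION)
    return EventTimeDistribution(times=times, n_peers=len(peers))


@dataclass
class RiskSeries:
    """Per-follow-up chance and deviation plus the composite summary scores."""

    subject_id: str
    times: np.ndarray
    pi: np.ndarray  # NaN where flagged
    z: np.ndarray  # NaN where flagged (inf sentinel excluded from maxima)
    pi_flags: list
    z_flags: list
    n_peers: np.ndarray
    vpi: float = np.nan
    vpiz: float = np.nan
    vpizt: float = np.nan

    @property
    def all_flagged(self) -> bool:
        return not (np.isfinite(self.vpi) or np.isfinite(self.vpiz) or np.isfinite(self.vpizt))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id, "t": self.times, "pi": self.pi, "z": self.z,
                "n_peers": self.n_peers, "pi_flag": self.pi_flags, "z_flag": self.z_flags,
            }
        )


def summarise_scores(times, pi, z, pi_flags, z_flags):
    """Maxima over follow-ups, skipping flagged entries."""
    vpi = vpiz = vpizt = np.nan
    for k in range(len(times)):
        if pi_flags[k] is None and np.isfinite(pi[k]):
            vpi = pi[k] if np.isnan(vpi) else max(vpi, pi[k])
            if z_flags[k] is None and np.isfinite(z[k]):
                vpiz = pi[k] * z[k] if np.isnan(vpiz) else max(vpiz, pi[k] * z[k])
                prod_t = pi[k] * z[k] * times[k]
                vpizt = prod_t if np.isnan(vpizt) else max(vpizt, prod_t)
    return vpi, vpiz, vpizt


class MonitoringSession:
    """Stateful façade: embedding results + training trajectory index.

    Parameters follow the peer-retrieval and reference-estimation defaults:
    radius 10% of the admission embedding IQR norm (expansion x1.5 until 30
    peers), 30-minute reference grid, support floor of 10 uncomplicated
    peers.
    """

    def __init__(
        self,
        results: MKLEmbeddingResults,
        index: TrajectoryIndex,
        radius: float | None = None,
        min_peers: int = 30,
        expansion: float = 1.5,
        grid_step: float = 0.5,
        support_floor: int = 10,
    ):
        self.results = results
        self.index = index
        self.radius = radius
        self.min_peers = min_peers
        self.expansion = expansion
        self.grid_step = grid_step
        self.support_floor = support_floor
        self.log_rows: list[dict] = []

    def score_subject(
        self, states: list[SubjectState], event: str = CS_EVENT, exclude_self: bool = False
    ) -> RiskSeries:
        """Run the per-follow-up monitoring loop for one subject.

        The deviation at follow-up k is measured against the reference
        trajectory estimated from the peers of follow-up k-1 (the subject's
        new position is compared to what was *expected* for them); the first
        follow-up therefore has no deviation.  Flagged entries are excluded
        from the score maxima.
        """
        if not states:
            raise ValidationError("cannot score a subject without follow-ups")
        exclude_id = states[0].subject_id if exclude_self else None
        times, pis, zs, pi_flags, z_flags, n_peers = [], [], [], [], [], []
        reference: IdealTrajectory | None = None
        all_coords = self.results.project(np.vstack([s.values for s in states]))
        for k, state in enumerate(states):
            point = EmbeddedPoint(state.subject_id, state.t, all_coords[k])
            peers = find_peers(
                self.index, point, radius=self.radius, min_peers=self.min_peers,
                expansion=self.expansion, exclude_id=exclude_id,
            )
            chance = event_chance(self.index, peers, event, state.t)
            if reference is None:
                zres = ZScore(np.nan, NO_REFERENCE)
            else:
                zres = deviation_z(point.coordinates, state.t, reference)
            times.append(state.t)
            pis.append(chance.value)
            zs.append(zres.value)
            pi_flags.append(chance.flag)
            z_flags.append(zres.flag)
            n_peers.append(len(peers))
            self.log_rows.append(
                {
                    "subject_id": state.subject_id, "t": state.t,
                    **{f"dim{p + 1}": point.coordinates[p] for p in range(point.coordinates.size)},
                    "n_peers": len(peers), "pi": chance.value, "z": zres.value,
                }
            )
            reference = estimate_ideal_trajectory(
                self.index, peers, grid_step=self.grid_step, support_floor=self.support_floor
            )
        times = np.asarray(times)
        pis, zs = np.asarray(pis), np.asarray(zs)
        vpi, vpiz, vpizt = summarise_scores(times, pis, zs, pi_flags, z_flags)
        return RiskSeries(
            subject_id=states[0].subject_id, times=times, pi=pis, z=zs,
            pi_flags=pi_flags, z_flags=z_flags, n_peers=np.asarray(n_peers),
            vpi=vpi, vpiz=vpiz, vpizt=vpizt,
        )

    def score_cohort(
        self, cohort: EncodedCohort, subject_ids=None, event: str = CS_EVENT,
        exclude_self: bool = False,
    ) -> pd.DataFrame:
        """Score many subjects; one row per subject with v_pi, v_pi_z, v_pi_z_t."""
        ids = list(subject_ids) if subject_ids is not None else cohort.subject_ids
        rows = []
        for sid in ids:
            series = self.score_subject(
                cohort.subject_states(sid), event=event, exclude_self=exclude_self
            )
            rows.append(
                {"subject_id": sid, "vpi": series.vpi, "vpiz": series.vpiz, "vpizt": series.vpizt}
            )
        return pd.DataFrame(rows).set_index("subject_id")

    def session_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_rows)
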