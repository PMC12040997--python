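"""Synthetic labour-cohort simulator.

Generates cohorts that structurally resemble a multi-site intrapartum study:
a static (admission-time) profile per woman, irregularly timed follow-up
assessments of dynamic features, and an events table with interventions,
outcomes and delivery timings.  Every subject carries its latent labour-speed
parameter as ground truth, so downstream components (embedding, peer
monitoring, risk scoring) can be tested against known structure.

The generative model, in brief:

* Two latent factors per subject: ``z1`` (labour-progress propensity) and
  ``z2`` (a site/practice factor).  Static continuous features load on both
  factors plus noise; a two-level ``site`` categorical follows the sign of
  ``z2`` (with flips), and shifts intervention propensity.
* Cervical dilatation follows a logistic growth curve from the admission
  value towards 10 cm, with per-subject rate ``r = exp(mu + a*z1 + noise)``.
  Vaginal delivery occurs when dilatation reaches 9.5 cm.
* A fraction of labours *arrest*: at a random mid-labour time progress
  nearly stops (obstructed/dysfunctional labour) — the deviation pattern
  trajectory monitoring is designed to detect.  Most arrested labours end
  in caesarean section after a prolonged stall (hours of alarming data,
  as on a partograph crossing its action line); the rest resolve after a
  shorter stall and resume at a near-normal rate.
* Caesarean hazard is logistic in the *progress deficit* (standardised
  negative log-rate) and in the arrest indicator.  The intercept is solved
  numerically so that the marginal caesarean rate equals the configured
  ``cs_base_rate`` exactly in expectation, independent of the slopes.
* Follow-ups happen at admission (t = 0) and then at jittered intervals
  until delivery; dynamic cells are masked missing completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import ConfigurationError, ValidationError

DILATATION = "dilatation"
DELIVERY_EVENT = "delivery"
CS_EVENT = "caesarean_section"
AUGMENTATION_EVENT = "augmentation"
OUTCOME_PREFIX = "outcome_"

_FULL_DILATATION = 10.0
_DELIVERY_DILATATION = 9.5


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults emulate the structure of a large multi-site intrapartum cohort:
    33 static features (20 continuous + 13 categorical) and 19 dynamic
    features, a caesarean incidence near 12.9%, and nonstandardised
    follow-up intervals averaging 1 h.
    """

    n_subjects: int = 500
    n_static_cont: int = 20
    n_static_cat: int = 13
    static_cat_levels: Sequence[int] = ()  # per-feature; default 2 for site, 3 else
    n_dynamic: int = 19
    followup_interval_mean: float = 1.0  # hours
    followup_interval_jitter: float = 0.5  # hours (sd)
    latent_rate_log_mean: float = float(np.log(0.55))  # log(cm-growth rate /h)
    latent_rate_log_sd: float = 0.25
    latent_factor_loading: float = 0.7  # share of log-rate variance from z1
    admission_dilatation_mean: float = 4.0  # cm
    admission_dilatation_sd: float = 1.8  # cm
    cs_base_rate: float = 817.0 / 6349.0
    cs_slowness_coefficient: float = 1.0  # log-odds per SD of progress deficit
    arrest_rate: float = 0.12  # fraction of labours with mid-course arrest
    cs_arrest_coefficient: float = 4.0  # extra CS log-odds for arrested labours
    adverse_outcome_rate: float = 0.10
    adverse_slowness_coefficient: float = 0.6
    missingness_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_static_cont", "n_static_cat", "n_dynamic"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(name, f"must be a nonnegative integer, got {v!r}")
        for name in ("cs_base_rate", "adverse_outcome_rate", "missingness_rate", "arrest_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, f"must lie in [0, 1], got {v!r}")
        if self.followup_interval_mean <= 0:
            raise ConfigurationError(
                "followup_interval_mean", f"must be > 0, got {self.followup_interval_mean!r}"
            )
        if self.followup_interval_jitter < 0:
            raise ConfigurationError(
                "followup_interval_jitter", f"must be >= 0, got {self.followup_interval_jitter!r}"
            )
        if self.n_dynamic < 1:
            raise ConfigurationError("n_dynamic", "at least one dynamic feature (dilatation) is required")
        if self.static_cat_levels and len(self.static_cat_levels) != self.n_static_cat:
            raise ConfigurationError(
                "static_cat_levels",
                f"length {len(self.static_cat_levels)} != n_static_cat {self.n_static_cat}",
            )

    @property
    def cat_levels(self) -> tuple:
        if self.static_cat_levels:
            return tuple(int(v) for v in self.static_cat_levels)
        # first categorical is the two-level site; the rest default to 3 levels
        return tuple(2 if i == 0 else 3 for i in range(self.n_static_cat))

    @property
    def static_cont_names(self) -> tuple:
        return tuple(f"sc{i:02d}" for i in range(self.n_static_cont))

    @property
    def static_cat_names(self) -> tuple:
        names = []
        for i in range(self.n_static_cat):
            names.append("site" if i == 0 else f"cat{i:02d}")
        return tuple(names)

    @property
    def dynamic_names(self) -> tuple:
        names = [DILATATION]
        for i in range(1, self.n_dynamic):
            names.append(f"dy{i:02d}")
        return tuple(names)


@dataclass
class LabourRecord:
    """One subject: static profile, ordered follow-ups, events and outcomes."""

    subject_id: str
    static: dict
    followup_times: np.ndarray  # hours since admission, strictly increasing, [0] == 0
    dynamics: np.ndarray  # (n_followups, n_dynamic) float, NaN = missing
    dynamic_names: tuple
    events: list  # (event_name, t_event hours)
    outcome_label: str  # "uncomplicated" | "adverse"
    cs_flag: bool
    delivery_time: float  # hours
    latent_rate: float | None = None  # ground-truth labour-speed (cm logistic rate /h)
    latent_deficit: float | None = None  # standardised progress deficit (ground truth)
    latent_admission_dilatation: float | None = None  # noise-free stage at t = 0 (cm)
    latent_arrest_time: float | None = None  # onset of arrest (NaN if none)

    def __post_init__(self):
        t = np.asarray(self.followup_times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] != 0.0):
            raise ValidationError(
                f"subject {self.subject_id}: follow-up times must start at 0 and strictly increase"
            )


def _dilatation_curve(d0: np.ndarray, rate: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Logistic growth from admission dilatation towards 10 cm."""
    e = np.exp(rate * t)
    return _FULL_DILATATION * d0 * e / (_FULL_DILATATION + d0 * (e - 1.0))


def _delivery_time(d0: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Time at which the logistic curve reaches the delivery threshold."""
    target = _DELIVERY_DILATATION
    ratio = target * (_FULL_DILATATION - d0) / (d0 * (_FULL_DILATATION - target))
    return np.log(ratio) / rate


def _calibrated_intercept(target_rate: float, linear_term: np.ndarray) -> float:
    """Intercept a such that mean(expit(a + linear_term)) == target_rate.

    A plain logit(target) intercept is biased whenever the linear term has
    spread (Jensen); solving for the intercept makes the marginal rate match
    the configured one by construction.
    """
    if target_rate <= 0.0:
        return -np.inf
    if target_rate >= 1.0:
        return np.inf
    if np.allclose(linear_term, 0.0):
        return float(logit(target_rate))

    def gap(a):
        return float(np.mean(expit(a + linear_term))) - target_rate

    return float(brentq(gap, -40.0, 40.0, xtol=1e-12))


def simulate_cohort(config: SimConfig) -> list[LabourRecord]:
    """Simulate a labour cohort; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if n == 0:
        return []

    z1 = rng.standard_normal(n)  # progress propensity
    z2 = rng.standard_normal(n)  # site / practice factor

    # Per-subject labour speed (logistic dilatation rate, cm-scale, per hour).
    lam = config.latent_factor_loading
    log_rate = (
        config.latent_rate_log_mean
        + config.latent_rate_log_sd * (np.sqrt(lam) * z1 + np.sqrt(1.0 - lam) * rng.standard_normal(n))
    )
    rate = np.exp(log_rate)
    # Standardised progress deficit: positive = slower than typical.
    deficit = -(log_rate - config.latent_rate_log_mean) / config.latent_rate_log_sd

    d0 = np.clip(
        rng.normal(config.admission_dilatation_mean, config.admission_dilatation_sd, n), 1.0, 8.5
    )
    t_natural = _delivery_time(d0, rate)

    # Mid-labour arrest: progress nearly stops at a random time.
    arrest = rng.random(n) < config.arrest_rate
    t_arrest = rng.uniform(0.15, 0.60, n) * t_natural
    d_arrest = _dilatation_curve(d0, rate, t_arrest)
    stall_rate = rate * rng.uniform(0.05, 0.20, n)

    # Caesarean: logistic hazard in progress deficit and arrest, intercept
    # calibrated so the marginal rate equals cs_base_rate.
    cs_lin = config.cs_slowness_coefficient * deficit + config.cs_arrest_coefficient * arrest
    cs_alpha = _calibrated_intercept(config.cs_base_rate, cs_lin)
    p_cs = expit(cs_alpha + cs_lin) if np.isfinite(cs_alpha) else np.full(n, float(cs_alpha > 0))
    cs_flag = rng.random(n) < p_cs

    # Arrested + caesarean: section after a prolonged stall.  Arrested but
    # resolving: stall ends after a shorter window, progress resumes near
    # the original rate.  Non-arrested caesareans occur mid-labour.
    stall_dur = np.where(cs_flag, rng.uniform(3.0, 8.0, n), rng.uniform(2.0, 5.0, n))
    resume_rate = rate * rng.uniform(0.6, 1.0, n)
    d_resume = _dilatation_curve(d_arrest, stall_rate, stall_dur)
    t_resolve = t_arrest + stall_dur + _delivery_time(d_resume, resume_rate)
    delivery_nat = np.where(arrest, t_resolve, t_natural)

    t_cs = np.where(arrest, t_arrest + stall_dur, rng.uniform(0.35, 0.90, n) * t_natural)
    t_cs = np.maximum(t_cs, 0.25)
    delivery = np.where(cs_flag, t_cs, delivery_nat)

    adv_lin = config.adverse_slowness_coefficient * deficit + 1.5 * arrest
    adv_alpha = _calibrated_intercept(config.adverse_outcome_rate, adv_lin)
    p_adv = expit(adv_alpha + adv_lin) if np.isfinite(adv_alpha) else np.full(n, float(adv_alpha > 0))
    adverse = rng.random(n) < p_adv

    # Static continuous features: factor loadings on (z1, z2) plus noise.
    p_cont = config.n_static_cont
    load1 = rng.uniform(-0.6, 0.6, p_cont)
    load2 = rng.uniform(-0.6, 0.6, p_cont)
    if p_cont:
        load1[0] = 0.9  # the first static feature is a strong progress marker
        load2[0] = 0.0
    noise_sd = np.sqrt(np.clip(1.0 - load1**2 - load2**2, 0.05, None))
    static_cont = (
        np.outer(z1, load1) + np.outer(z2, load2) + rng.standard_normal((n, p_cont)) * noise_sd
    )

    # Categorical features: site follows sign(z2) with 15% flips, others are
    # multinomial draws with a mild z2 tilt.
    levels = config.cat_levels
    static_cat = np.zeros((n, config.n_static_cat), dtype=int)
    for j, n_lev in enumerate(levels):
        if j == 0:
            flips = rng.random(n) < 0.15
            static_cat[:, 0] = ((z2 > 0) ^ flips).astype(int) % n_lev
        else:
            tilt = np.clip(0.15 * z2, -0.3, 0.3)
            u = rng.random(n) + tilt
            static_cat[:, j] = np.clip((u * n_lev).astype(int), 0, n_lev - 1)

    site = static_cat[:, 0] if config.n_static_cat else np.zeros(n, dtype=int)

    # Augmentation propensity shifts with site (practice bias) and slowness.
    p_aug = expit(-1.2 + 0.9 * site + 0.4 * deficit)
    aug_flag = rng.random(n) < p_aug
    t_aug = rng.uniform(0.2, 0.8, n) * delivery

    # Dynamic feature model: feature 0 is dilatation; the majority of the
    # dynamic features track the current dilatation (progress-linked
    # vitals such as contraction duration/spacing and fetal station), the
    # rest are noisy subject-level signals.
    p_dyn = config.n_dynamic
    dyn_link = rng.uniform(0.6, 1.0, p_dyn)  # coupling to progress
    dyn_link[0] = 1.0
    n_linked = max(1, (2 * p_dyn) // 3)
    dyn_link[n_linked:] = 0.0

    records: list[LabourRecord] = []
    cat_labels = [tuple(f"L{k}" for k in range(n_lev)) for n_lev in levels]
    width = max(4, len(str(n)))
    for i in range(n):
        times = [0.0]
        while True:
            step = rng.normal(config.followup_interval_mean, config.followup_interval_jitter)
            step = max(0.25, step)
            t_next = times[-1] + step
            if t_next >= delivery[i]:
                break
            times.append(t_next)
        t_arr = np.asarray(times)

        if arrest[i]:
            t_res = t_arrest[i] + stall_dur[i]
            dil = np.where(
                t_arr < t_arrest[i],
                _dilatation_curve(d0[i], rate[i], t_arr),
                np.where(
                    t_arr < t_res,
                    _dilatation_curve(d_arrest[i], stall_rate[i], t_arr - t_arrest[i]),
                    _dilatation_curve(d_resume[i], resume_rate[i], t_arr - t_res),
                ),
            )
        else:
            dil = _dilatation_curve(d0[i], rate[i], t_arr)
        dyn = np.empty((t_arr.size, p_dyn))
        dyn[:, 0] = dil
        for j in range(1, p_dyn):
            if dyn_link[j] > 0:
                dyn[:, j] = dyn_link[j] * dil + 0.3 * z1[i] + rng.standard_normal(t_arr.size) * 0.35
            else:
                dyn[:, j] = 0.5 * z1[i] + 0.3 * z2[i] + rng.standard_normal(t_arr.size) * 0.8

        if config.missingness_rate > 0:
            mask = rng.random(dyn.shape) < config.missingness_rate
            dyn[mask] = np.nan

        events = [(DELIVERY_EVENT, float(delivery[i]))]
        if cs_flag[i]:
            events.append((CS_EVENT, float(t_cs[i])))
        if aug_flag[i]:
            events.append((AUGMENTATION_EVENT, float(t_aug[i])))

        static = {}
        for name, val in zip(config.static_cont_names, static_cont[i]):
            static[name] = float(val)
        for j, name in enumerate(config.static_cat_names):
            static[name] = cat_labels[j][static_cat[i, j]]

        records.append(
            LabourRecord(
                subject_id=f"S{i:0{width}d}",
                static=static,
                followup_times=t_arr,
                dynamics=dyn,
                dynamic_names=config.dynamic_names,
                events=events,
                outcome_label="adverse" if adverse[i] else "uncomplicated",
                cs_flag=bool(cs_flag[i]),
                delivery_time=float(delivery[i]),
                latent_rate=float(rate[i]),
                latent_deficit=float(deficit[i]),
                latent_admission_dilatation=float(d0[i]),
                latent_arrest_time=float(t_arrest[i]) if arrest[i] else None,
            )
        )
    return records


def cohort_to_tables(records: Sequence[LabourRecord]):
    """Flatten records into the three interchange tables.

    Returns ``(static_table, followup_table, events_table)``.  Outcome label,
    caesarean flag and delivery time are encoded as event rows
    (``outcome_<label>`` at delivery time; ``caesarean_section``;
    ``delivery``), so the three tables round-trip losslessly through
    :func:`mklabour.io.read_cohort`.
    """
    if not records:
        raise ValidationError("cannot tabulate an empty cohort")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject_id values in cohort")

    static_rows = []
    for r in records:
        row = {"subject_id": r.subject_id}
        row.update(r.static)
        static_rows.append(row)
    static_table = pd.DataFrame(static_rows)

    fu_frames = []
    for r in records:
        df = pd.DataFrame(r.dynamics, columns=list(r.dynamic_names))
        df.insert(0, "t", r.followup_times)
        df.insert(0, "subject_id", r.subject_id)
        fu_frames.append(df)
    followup_table = pd.concat(fu_frames, ignore_index=True)

    ev_rows = []
    for r in records:
        for name, t in sorted(r.events, key=lambda e: (e[1], e[0])):
            ev_rows.append({"subject_id": r.subject_id, "event": name, "t_event": t})
        ev_rows.append(
            {
                "subject_id": r.subject_id,
                "event": OUTCOME_PREFIX + r.outcome_label,
                "t_event": r.delivery_time,
            }
        )
    events_table = pd.DataFrame(ev_rows, columns=["subject_id", "event", "t_event"])
    return static_table, followup_table, events_table


def records_from_tables(static_table, followup_table, events_table) -> list[LabourRecord]:
    """Inverse of :func:`cohort_to_tables` (latent ground truth is not recoverable)."""
    dynamic_names = tuple(c for c in followup_table.columns if c not in ("subject_id", "t"))
    static_cols = [c for c in static_table.columns if c != "subject_id"]
    fu_groups = dict(tuple(followup_table.groupby("subject_id", sort=False)))
    ev_groups = dict(tuple(events_table.groupby("subject_id", sort=False)))
    records = []
    for _, srow in static_table.iterrows():
        sid = srow["subject_id"]
        fu = fu_groups.get(sid)
        if fu is None:
            raise ValidationError(f"subject {sid} has no follow-up rows")
        fu = fu.sort_values("t")
        ev = ev_groups.get(sid)
        events, outcome, cs, delivery = [], "uncomplicated", False, np.nan
        if ev is not None:
            for _, erow in ev.iterrows():
                name = erow["event"]
                if name.startswith(OUTCOME_PREFIX):
                    outcome = name[len(OUTCOME_PREFIX):]
                else:
                    events.append((name, float(erow["t_event"])))
                    if name == CS_EVENT:
                        cs = True
                    if name == DELIVERY_EVENT:
                        delivery = float(erow["t_event"])
        records.append(
            LabourRecord(
                subject_id=sid,
                static={c: srow[c] for c in static_cols},
                followup_times=fu["t"].to_numpy(dtype=float),
                dynamics=fu[list(dynamic_names)].to_numpy(dtype=float),
                dynamic_names=dynamic_names,
                events=events,
                outcome_label=outcome,
                cs_flag=cs,
                delivery_time=delivery,
            )
        )
    return records
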