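"""Feature pipeline: schema, encoding, imputation, propagation, exclusions.

Turns the three raw cohort tables into model-ready matrices while keeping a
strict train/test separation: all statistics used for standardisation and
admission-time imputation come from the training subjects only.  Missing
follow-up values are handled by last-observation-carried-forward (LOCF)
propagation; subjects with residual missingness or time inconsistencies are
excluded with a per-reason report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CS_EVENT, DELIVERY_EVENT, DILATATION, OUTCOME_PREFIX, SimConfig
from .exceptions import ValidationError

STATIC, DYNAMIC = "static", "dynamic"
CONTINUOUS, ORDINAL, CATEGORICAL = "continuous", "ordinal", "categorical"


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    role: str  # static | dynamic
    kind: str  # continuous | ordinal | categorical
    categories: tuple = ()
    lower: float | None = None
    upper: float | None = None
    standardise: bool = True

    def __post_init__(self):
        if self.role not in (STATIC, DYNAMIC):
            raise ValidationError(f"feature {self.name}: unknown role {self.role!r}")
        if self.kind not in (CONTINUOUS, ORDINAL, CATEGORICAL):
            raise ValidationError(f"feature {self.name}: unknown kind {self.kind!r}")

    @property
    def numeric(self) -> bool:
        return self.kind in (CONTINUOUS, ORDINAL)


class FeatureSchema:
    """Ordered collection of feature specifications with unique names."""

    def __init__(self, specs: Sequence[FeatureSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValidationError("feature names must be unique")
        self.specs = tuple(specs)
        self._by_name = {s.name: s for s in specs}

    def __iter__(self):
        return iter(self.specs)

    def __len__(self):
        return len(self.specs)

    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def names(self, role: str | None = None) -> list[str]:
        return [s.name for s in self.specs if role is None or s.role == role]

    @property
    def static_names(self) -> list[str]:
        return self.names(STATIC)

    @property
    def dynamic_names(self) -> list[str]:
        return self.names(DYNAMIC)

    @property
    def feature_names(self) -> list[str]:
        """Model feature order: static block then dynamic block."""
        return self.static_names + self.dynamic_names

    def to_dicts(self) -> list[dict]:
        out = []
        for s in self.specs:
            d = {"name": s.name, "role": s.role, "kind": s.kind, "standardise": s.standardise}
            if s.categories:
                d["categories"] = list(s.categories)
            if s.lower is not None:
                d["lower"] = float(s.lower)
            if s.upper is not None:
                d["upper"] = float(s.upper)
            out.append(d)
        return out

    @classmethod
    def from_dicts(cls, dicts: Iterable[dict]) -> "FeatureSchema":
        specs = []
        for d in dicts:
            specs.append(
                FeatureSpec(
                    name=d["name"],
                    role=d["role"],
                    kind=d["kind"],
                    categories=tuple(d.get("categories", ())),
                    lower=d.get("lower"),
                    upper=d.get("upper"),
                    standardise=bool(d.get("standardise", True)),
                )
            )
        return cls(specs)


def schema_for_config(config: SimConfig) -> FeatureSchema:
    """The schema matching the synthetic generator's column layout."""
    specs = []
    for name in config.static_cont_names:
        specs.append(FeatureSpec(name, STATIC, CONTINUOUS))
    for name, n_lev in zip(config.static_cat_names, config.cat_levels):
        specs.append(
            FeatureSpec(name, STATIC, CATEGORICAL, categories=tuple(f"L{k}" for k in range(n_lev)))
        )
    for name in config.dynamic_names:
        lo, hi = (0.0, 10.0) if name == DILATATION else (None, None)
        specs.append(FeatureSpec(name, DYNAMIC, CONTINUOUS, lower=lo, upper=hi))
    return FeatureSchema(specs)


@dataclass
class SubjectState:
    """One subject's complete feature state at a follow-up time.

    ``observed`` marks entries actually measured at this follow-up;
    ``missing`` marks entries that remained unresolved after propagation
    (no prior observation and no admission imputation).
    """

    subject_id: str
    t: float
    values: np.ndarray
    observed: np.ndarray  # bool, same length as values
    missing: np.ndarray  # bool, same length as values

    def __post_init__(self):
        if not (len(self.values) == len(self.observed) == len(self.missing)):
            raise ValidationError("provenance masks must match the value vector length")


def locf(values: np.ndarray) -> np.ndarray:
    """Column-wise last-observation-carried-forward over a (time x feature) array."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("locf expects a 2-D (time x feature) array")
    out = values.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        mask = np.isnan(col)
        if not mask.any():
            continue
        idx = np.where(~mask, np.arange(col.size), -1)
        np.maximum.accumulate(idx, out=idx)
        filled = np.where(idx >= 0, col[np.maximum(idx, 0)], np.nan)
        out[:, j] = filled
    return out


def propagate_followups(
    subject_id: str, times: np.ndarray, values: np.ndarray, feature_names: Sequence[str] | None = None
) -> list[SubjectState]:
    """LOCF propagation of a subject's dynamic follow-up matrix.

    Each missing entry is replaced by the most recent observed value of that
    feature; entries with no prior observation stay NaN and are flagged
    ``missing``.  Idempotent: propagating an already-propagated matrix is the
    identity.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValidationError(f"subject {subject_id}: follow-up times must be strictly increasing")
    observed = ~np.isnan(values)
    filled = locf(values)
    states = []
    for k in range(times.size):
        states.append(
            SubjectState(
                subject_id=subject_id,
                t=float(times[k]),
                values=filled[k],
                observed=observed[k],
                missing=np.isnan(filled[k]),
            )
        )
    return states


class CohortEncoder:
    """Schema-driven encoder with leakage-safe statistics.

    ``fit`` learns category maps, standardisation moments and admission-time
    imputation values from the training subjects only; ``transform`` applies
    them to any table set.  Out-of-range or unmappable cells are reported
    row-by-row, never silently dropped.
    """

    def __init__(self, schema: FeatureSchema, impute_admission: bool = True):
        self.schema = schema
        self.impute_admission = impute_admission
        self.category_maps: dict[str, dict] = {}
        self.moments: dict[str, tuple[float, float]] = {}
        self.impute_values: dict[str, float] = {}
        self.zero_variance: list[str] = []
        self.fitted = False

    def fit(self, static_table: pd.DataFrame, followup_table: pd.DataFrame) -> "CohortEncoder":
        for spec in self.schema:
            table = static_table if spec.role == STATIC else followup_table
            if spec.name not in table.columns:
                raise ValidationError(f"column '{spec.name}' missing from {spec.role} table")
            col = table[spec.name]
            if spec.kind == CATEGORICAL:
                cats = spec.categories or tuple(pd.unique(col.dropna()))
                self.category_maps[spec.name] = {c: i for i, c in enumerate(cats)}
                codes = col.map(self.category_maps[spec.name])
                mode = codes.mode()
                self.impute_values[spec.name] = float(mode.iloc[0]) if len(mode) else np.nan
            else:
                vals = pd.to_numeric(col, errors="coerce")
                mean = float(vals.mean())
                sd = float(vals.std(ddof=0))
                if not np.isfinite(sd) or sd == 0.0:
                    self.zero_variance.append(spec.name)
                    sd = 1.0
                self.moments[spec.name] = (mean, sd) if spec.standardise else (0.0, 1.0)
                if spec.role == STATIC:
                    self.impute_values[spec.name] = float(vals.median())
                else:
                    adm = vals[followup_table["t"] == 0.0]
                    self.impute_values[spec.name] = float(adm.median())
        self.fitted = True
        return self

    def _encode_column(self, spec: FeatureSpec, col: pd.Series, report: list, table_name: str):
        if spec.kind == CATEGORICAL:
            mapped = col.map(self.category_maps[spec.name])
            bad = col.notna() & mapped.isna()
            for idx in col.index[bad]:
                report.append(
                    {"table": table_name, "row": int(idx), "column": spec.name,
                     "value": col.loc[idx], "issue": "unknown category"}
                )
            return mapped.astype(float)
        vals = pd.to_numeric(col, errors="coerce")
        coerce_bad = col.notna() & vals.isna()
        for idx in col.index[coerce_bad]:
            report.append(
                {"table": table_name, "row": int(idx), "column": spec.name,
                 "value": col.loc[idx], "issue": "not numeric"}
            )
        if spec.lower is not None or spec.upper is not None:
            lo = -np.inf if spec.lower is None else spec.lower
            hi = np.inf if spec.upper is None else spec.upper
            oob = vals.notna() & ((vals < lo) | (vals > hi))
            for idx in vals.index[oob]:
                report.append(
                    {"table": table_name, "row": int(idx), "column": spec.name,
                     "value": float(vals.loc[idx]), "issue": "out of range"}
                )
        mean, sd = self.moments[spec.name]
        return (vals - mean) / sd

    def transform(self, static_table, followup_table, events_table) -> "EncodedCohort":
        if not self.fitted:
            raise ValidationError("encoder must be fitted before transform")
        report: list[dict] = []
        for name in self.zero_variance:
            report.append({"table": "train", "row": -1, "column": name,
                           "value": None, "issue": "zero variance"})

        static = pd.DataFrame({"subject_id": static_table["subject_id"]})
        for name in self.schema.static_names:
            static[name] = self._encode_column(self.schema[name], static_table[name], report, "static")
        static = static.set_index("subject_id")
        if self.impute_admission:
            for name in self.schema.static_names:
                spec = self.schema[name]
                fill = self.impute_values[name]
                if spec.kind == CATEGORICAL:
                    static[name] = static[name].fillna(fill)
                else:
                    mean, sd = self.moments[name]
                    static[name] = static[name].fillna((fill - mean) / sd)

        fu = pd.DataFrame(
            {"subject_id": followup_table["subject_id"], "t": followup_table["t"].astype(float)}
        )
        for name in self.schema.dynamic_names:
            fu[name] = self._encode_column(self.schema[name], followup_table[name], report, "followup")
        if self.impute_admission:
            adm = fu["t"] == 0.0
            for name in self.schema.dynamic_names:
                mean, sd = self.moments[name]
                fill = (self.impute_values[name] - mean) / sd
                fu.loc[adm, name] = fu.loc[adm, name].fillna(fill)

        outcomes = _outcomes_from_events(events_table)
        return EncodedCohort(
            schema=self.schema,
            encoder=self,
            static=static,
            followups=fu,
            events=events_table.copy(),
            outcomes=outcomes,
            report=pd.DataFrame(report, columns=["table", "row", "column", "value", "issue"]),
        )


def _outcomes_from_events(events_table: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for sid, grp in events_table.groupby("subject_id", sort=False):
        outcome, cs, delivery = "uncomplicated", False, np.nan
        for _, r in grp.iterrows():
            name = r["event"]
            if name.startswith(OUTCOME_PREFIX):
                outcome = name[len(OUTCOME_PREFIX):]
            elif name == CS_EVENT:
                cs = True
            elif name == DELIVERY_EVENT:
                delivery = float(r["t_event"])
        rows[sid] = {"outcome_label": outcome, "cs_flag": cs, "delivery_time": delivery}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def validate_and_encode(
    tables, schema: FeatureSchema, train_ids: Sequence[str] | None = None,
    impute_admission: bool = True,
) -> "EncodedCohort":
    """Fit an encoder on the training subjects and encode the full table set.

    ``train_ids`` defaults to all subjects (fit-on-everything is only
    appropriate for exploratory use; pass the training partition for any
    train/test evaluation).
    """
    static_table, followup_table, events_table = tables
    if train_ids is None:
        st, ft = static_table, followup_table
    else:
        train_ids = set(train_ids)
        st = static_table[static_table["subject_id"].isin(train_ids)]
        ft = followup_table[followup_table["subject_id"].isin(train_ids)]
    enc = CohortEncoder(schema, impute_admission=impute_admission).fit(st, ft)
    return enc.transform(static_table, followup_table, events_table)


class EncodedCohort:
    """Encoded tables plus per-subject state assembly.

    Feature order everywhere is the schema's: static block then dynamic
    block.  ``propagate()`` applies LOCF to the follow-up table in place
    (idempotent) and must run before state matrices are requested.
    """

    def __init__(self, schema, encoder, static, followups, events, outcomes, report):
        self.schema = schema
        self.encoder = encoder
        self.static = static
        self.followups = followups
        self.events = events
        self.outcomes = outcomes
        self.report = report
        self.propagated = False
        self._fu_groups: dict | None = None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.static.index)

    @property
    def feature_names(self) -> list[str]:
        return self.schema.feature_names

    def propagate(self) -> "EncodedCohort":
        if self.propagated:
            return self
        dyn = self.schema.dynamic_names
        filled = []
        for sid, grp in self.followups.groupby("subject_id", sort=False):
            grp = grp.sort_values("t")
            vals = locf(grp[dyn].to_numpy(dtype=float))
            out = grp.copy()
            out[dyn] = vals
            filled.append(out)
        self.followups = pd.concat(filled, ignore_index=True)
        self.propagated = True
        self._fu_groups = None
        return self

    def _groups(self) -> dict:
        if self._fu_groups is None:
            self._fu_groups = {
                sid: grp.sort_values("t") for sid, grp in self.followups.groupby("subject_id", sort=False)
            }
        return self._fu_groups

    def subject_states(self, subject_id: str) -> list[SubjectState]:
        """Complete (static + propagated dynamic) state vectors per follow-up."""
        grp = self._groups()[subject_id]
        dyn_raw = grp[self.schema.dynamic_names].to_numpy(dtype=float)
        states = propagate_followups(
            subject_id, grp["t"].to_numpy(dtype=float), dyn_raw, self.schema.dynamic_names
        )
        svec = self.static.loc[subject_id, self.schema.static_names].to_numpy(dtype=float)
        full_states = []
        for st in states:
            values = np.concatenate([svec, st.values])
            observed = np.concatenate([np.full(svec.size, st.t == 0.0), st.observed])
            missing = np.concatenate([np.isnan(svec), st.missing])
            full_states.append(SubjectState(subject_id, st.t, values, observed, missing))
        return full_states

    def admission_matrix(self, subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Admission-time (t = 0) state matrix, one row per subject."""
        if not self.propagated:
            self.propagate()
        ids = list(subject_ids) if subject_ids is not None else self.subject_ids
        groups = self._groups()
        dyn = self.schema.dynamic_names
        rows = np.empty((len(ids), len(dyn)))
        for i, sid in enumerate(ids):
            grp = groups[sid]
            rows[i] = grp[dyn].to_numpy(dtype=float)[0]
        out = self.static.loc[ids, self.schema.static_names].copy()
        for j, name in enumerate(dyn):
            out[name] = rows[:, j]
        return out

    def state_matrix(self, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, states) for one subject; states is (n_followups, n_features)."""
        states = self.subject_states(subject_id)
        times = np.array([s.t for s in states])
        mat = np.vstack([s.values for s in states]) if states else np.empty((0, len(self.feature_names)))
        return times, mat

    def subset(self, subject_ids: Sequence[str]) -> "EncodedCohort":
        ids = list(subject_ids)
        idset = set(ids)
        sub = EncodedCohort(
            schema=self.schema,
            encoder=self.encoder,
            static=self.static.loc[ids],
            followups=self.followups[self.followups["subject_id"].isin(idset)].reset_index(drop=True),
            events=self.events[self.events["subject_id"].isin(idset)].reset_index(drop=True),
            outcomes=self.outcomes.loc[[i for i in ids if i in self.outcomes.index]],
            report=self.report,
        )
        sub.propagated = self.propagated
        return sub


def apply_exclusions(cohort: EncodedCohort):
    """Drop subjects with residual missingness or time inconsistencies.

    Returns ``(retained_cohort, report)`` where the report has one row per
    excluded subject with the exclusion reason; aggregate counts are in
    ``report.attrs['counts']``.
    """
    if not cohort.propagated:
        cohort.propagate()
    reasons: list[dict] = []
    keep = []
    groups = cohort._groups()
    dyn = cohort.schema.dynamic_names
    delivery = cohort.outcomes["delivery_time"] if "delivery_time" in cohort.outcomes else None
    ev_groups = dict(tuple(cohort.events.groupby("subject_id", sort=False)))
    for sid in cohort.subject_ids:
        grp = groups.get(sid)
        if grp is None or len(grp) == 0:
            reasons.append({"subject_id": sid, "reason": "no followups"})
            continue
        times = grp["t"].to_numpy(dtype=float)
        bad_time = times[0] < 0 or np.any(np.diff(times) <= 0)
        if not bad_time and delivery is not None and sid in delivery.index:
            d = delivery.loc[sid]
            ev = ev_groups.get(sid)
            if np.isfinite(d):
                if np.any(times >= d):
                    bad_time = True
                if ev is not None and np.any(ev["t_event"].to_numpy(dtype=float) > d + 1e-9):
                    bad_time = True
        if bad_time:
            reasons.append({"subject_id": sid, "reason": "time inconsistency"})
            continue
        static_missing = np.isnan(
            cohort.static.loc[sid, cohort.schema.static_names].to_numpy(dtype=float)
        ).any()
        dyn_missing = np.isnan(grp[dyn].to_numpy(dtype=float)).any()
        if static_missing or dyn_missing:
            reasons.append({"subject_id": sid, "reason": "residual missing"})
            continue
        keep.append(sid)
    report = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    report.attrs["counts"] = report["reason"].value_counts().to_dict() if len(report) else {}
    return cohort.subset(keep), report


def split_train_test(subject_ids: Sequence[str], fraction: float, seed: int):
    """Disjoint, exhaustive, seed-reproducible split; train size is floored."""
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must lie in (0, 1), got {fraction}")
    ids = list(subject_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * fraction))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test
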