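"""Synthetic tumor-board cohorts, consistency screening, summaries and CSV I/O.

The reference cohort behind the packaged model (97 laryngeal-cancer
tumor-board cases, 5 excluded for inconsistent records, 92 analyzed) is
not publicly deposited; this module generates synthetic stand-ins that
reproduce its published marginal statistics.  Demographics (gender, age
group) and staging (T, N, M, chemotherapy tolerance) are drawn
independently from configurable categorical marginals — the published
tables give marginals only, so no inter-variable correlation is
emulated.  Treatment truth labels are assigned either by sampling each
treatment node's CPT given the case's staging (``sample`` mode, the
model's own uncertainty) or by taking the model's argmax recommendation
and flipping it with probability ``epsilon`` (``argmax_noise`` mode, a
calibration device: prediction accuracy is then ``1 - epsilon`` in
expectation).  Missing values and inconsistent records can be injected
at configurable rates to emulate real health-record noise; a screening
step excludes inconsistent records with machine-readable reasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_core import Network, map_state, posterior
from .guideline_model import (
    M_STATES,
    N_STATES,
    T_PRIOR_COUNTS,
    T_STATES,
    TOLERANCE_STATES,
    TREATMENT_STATES,
    TREATMENTS,
)

logger = logging.getLogger("larynxbn")

GENDER_STATES = ("male", "female")
AGE_GROUPS = ("51-60", "61-70", "71-80", "81-90", "unknown")
OBSERVABLE_FIELDS = ("T", "N", "M", "chemo_tolerance")
STAGING_FIELDS = ("T", "N", "M")
CSV_COLUMNS = ("case_id", "gender", "age_group") + OBSERVABLE_FIELDS + TREATMENTS

MISSING = None  # in-memory marker; empty cell on disk


def _norm(d: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(d.values()))
    if total <= 0:
        raise ValueError("marginal has zero mass")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"marginal not normalized (sums to {total!r})")
    return {k: float(v) for k, v in d.items()}


def _empirical(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


#: Published patient-level marginals (counts out of 97).
GENDER_COUNTS = {"male": 83, "female": 14}
AGE_COUNTS = {"51-60": 30, "61-70": 32, "71-80": 21, "81-90": 12, "unknown": 2}

#: N / M / tolerance marginals are not published; these defaults are the
#: package's own clinically-plausible choice (documented, configurable):
#: node-negative disease dominates, distant metastasis is uncommon, and
#: most patients tolerate chemotherapy.
DEFAULT_N_MARGINAL = {
    "NX": 0.03, "N0": 0.50, "N1": 0.10, "N2a": 0.07,
    "N2b": 0.12, "N2c": 0.12, "N3a": 0.03, "N3b": 0.03,
}
DEFAULT_M_MARGINAL = {"MX": 0.05, "M0": 0.85, "M1": 0.10}
DEFAULT_TOLERANCE_MARGINAL = {"tolerant": 0.85, "intolerant": 0.15}


@dataclass
class PatientRecord:
    """One tumor-board case: demographics, staging, treatment truth labels."""

    case_id: str
    gender: str | None = None
    age_group: str | None = None
    T: str | None = None
    N: str | None = None
    M: str | None = None
    chemo_tolerance: str | None = None
    treatments: dict[str, str | None] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def staging_evidence(self) -> dict[str, str]:
        """Non-missing observable values, ready to use as network evidence."""
        out = {}
        for f in OBSERVABLE_FIELDS:
            v = getattr(self, f)
            if v is not None:
                out[f] = v
        return out


@dataclass
class CohortConfig:
    """Generation settings; the defaults emulate the reference cohort.

    ``n`` = 97 collected cases with an inconsistency-injection rate of
    5/97 reproduces, in expectation, the published 97 -> 92 screening
    step.  ``epsilon`` applies only in ``argmax_noise`` mode (in
    ``sample`` mode it is ignored with a warning).
    """

    n: int = 97
    gender_marginal: dict[str, float] = field(
        default_factory=lambda: _empirical(GENDER_COUNTS)
    )
    age_marginal: dict[str, float] = field(
        default_factory=lambda: _empirical(AGE_COUNTS)
    )
    t_marginal: dict[str, float] = field(
        default_factory=lambda: _empirical(T_PRIOR_COUNTS)
    )
    n_marginal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_N_MARGINAL))
    m_marginal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_M_MARGINAL))
    tolerance_marginal: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOLERANCE_MARGINAL)
    )
    treatment_mode: str = "sample"  # or "argmax_noise"
    epsilon: float = 0.1
    missingness_rate: float = 0.0
    inconsistency_rate: float = 5 / 97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment_mode not in ("sample", "argmax_noise"):
            raise ValueError(f"unknown treatment mode {self.treatment_mode!r}")
        for rate in (self.epsilon, self.missingness_rate, self.inconsistency_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0,1]")


def _sample_categorical(
    marginal: Mapping[str, float], valid: Sequence[str], n: int, rng: np.random.Generator
) -> np.ndarray:
    marginal = _norm(marginal)
    unknown = set(marginal) - set(valid)
    if unknown:
        raise ValueError(f"marginal references unknown categories {sorted(unknown)}")
    cats = [c for c in valid if c in marginal]
    p = np.array([marginal[c] for c in cats])
    return np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n, p=p)]


def generate_cohort(config: CohortConfig, model: Network) -> list[PatientRecord]:
    """Draw a synthetic cohort; fully reproducible from ``config.seed``.

    Order of operations: staging/demographics from the marginals,
    treatment labels per mode, then missingness, then inconsistency
    injection — so injected corruption is never 'repaired' later.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    gender = _sample_categorical(config.gender_marginal, GENDER_STATES, n, rng)
    age = _sample_categorical(config.age_marginal, AGE_GROUPS, n, rng)
    t = _sample_categorical(config.t_marginal, T_STATES, n, rng)
    nn = _sample_categorical(config.n_marginal, N_STATES, n, rng)
    m = _sample_categorical(config.m_marginal, M_STATES, n, rng)
    tol = _sample_categorical(config.tolerance_marginal, TOLERANCE_STATES, n, rng)

    # Treatment assignment. Both modes condition on the full staging of the
    # case; distinct staging combinations are cached (<= 480 of them).
    treatment_cols: dict[str, np.ndarray] = {
        tr: np.empty(n, dtype=object) for tr in TREATMENTS
    }
    if config.treatment_mode == "sample" and config.epsilon != 0.1:
        logger.warning("epsilon=%s is ignored in 'sample' treatment mode", config.epsilon)

    cache: dict[tuple, dict[str, object]] = {}
    for i in range(n):
        key = (t[i], nn[i], m[i], tol[i])
        if key not in cache:
            ev = dict(zip(OBSERVABLE_FIELDS, key))
            entry: dict[str, object] = {}
            for tr in TREATMENTS:
                dist = posterior(model, ev, tr)
                entry[tr] = (dist, map_state(dist, TREATMENT_STATES))
            cache[key] = entry
        for tr in TREATMENTS:
            dist, argmax = cache[key][tr]
            if config.treatment_mode == "sample":
                treatment_cols[tr][i] = (
                    "true" if rng.random() < dist["true"] else "false"
                )
            else:
                label = argmax
                if config.epsilon > 0 and rng.random() < config.epsilon:
                    label = "true" if label == "false" else "false"
                treatment_cols[tr][i] = label

    records = [
        PatientRecord(
            case_id=f"case-{i + 1:04d}",
            gender=gender[i],
            age_group=age[i],
            T=t[i],
            N=nn[i],
            M=m[i],
            chemo_tolerance=tol[i],
            treatments={tr: treatment_cols[tr][i] for tr in TREATMENTS},
        )
        for i in range(n)
    ]

    if config.missingness_rate > 0:
        for rec in records:
            for f in OBSERVABLE_FIELDS:
                if rng.random() < config.missingness_rate:
                    setattr(rec, f, None)

    if config.inconsistency_rate > 0:
        for rec in records:
            if rng.random() < config.inconsistency_rate:
                if rng.random() < 0.5:
                    # prerequisite violation: systemic therapy despite intolerance
                    rec.chemo_tolerance = "intolerant"
                    rec.treatments["chemotherapy"] = "true"
                else:
                    rec.T = rec.N = rec.M = None  # staging wiped entirely

    return records


# ---------------------------------------------------------------------------
# Consistency screening
# ---------------------------------------------------------------------------

REASON_INVALID_LABEL = "invalid_label"
REASON_PREREQUISITE = "prerequisite_violation"
REASON_NO_STAGING = "all_staging_missing"


@dataclass
class Exclusion:
    record: PatientRecord
    reason: str
    detail: str


@dataclass
class ScreenResult:
    kept: list[PatientRecord]
    excluded: list[Exclusion]


def _valid_states(model: Network | None) -> dict[str, tuple[str, ...]]:
    if model is not None:
        fields = {
            v.name: v.states for v in model.variables if v.name in OBSERVABLE_FIELDS
        }
        treatments = {
            v.name: v.states for v in model.variables if v.role == "target"
        }
        return {**fields, **treatments}
    out = dict(
        zip(OBSERVABLE_FIELDS, (T_STATES, N_STATES, M_STATES, TOLERANCE_STATES))
    )
    out.update({tr: TREATMENT_STATES for tr in TREATMENTS})
    return out


def screen_cohort(
    records: Iterable[PatientRecord], model: Network | None = None
) -> ScreenResult:
    """Apply the consistency screen; every exclusion carries a reason.

    Rules (a documented reconstruction — the original exclusion criteria
    are unpublished, only the 97 -> 92 count is): (i) any invalid state
    label; (ii) chemotherapy or radiochemotherapy recorded as performed
    despite chemotherapy intolerance; (iii) T, N and M all missing.
    Screening is idempotent: re-screening kept records excludes nothing.
    """
    valid = _valid_states(model)
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        problem: Exclusion | None = None
        for name, states in valid.items():
            value = (
                rec.treatments.get(name) if name in TREATMENTS else getattr(rec, name)
            )
            if value is not None and value not in states:
                problem = Exclusion(
                    rec, REASON_INVALID_LABEL, f"{name}={value!r} is not a valid state"
                )
                break
        if problem is None and rec.chemo_tolerance == "intolerant":
            for tr in ("chemotherapy", "radiochemotherapy"):
                if rec.treatments.get(tr) == "true":
                    problem = Exclusion(
                        rec,
                        REASON_PREREQUISITE,
                        f"{tr}=true despite chemo_tolerance=intolerant",
                    )
                    break
        if problem is None and all(getattr(rec, f) is None for f in STAGING_FIELDS):
            problem = Exclusion(rec, REASON_NO_STAGING, "T, N and M all missing")
        if problem is None:
            kept.append(rec)
        else:
            excluded.append(problem)
            rec.flags = rec.flags + (problem.reason,)
    return ScreenResult(kept=kept, excluded=excluded)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Per-category absolute counts and relative frequencies (3 decimals)."""

    name: str
    rows: list[tuple[str, int, float]]
    denominator: int

    @property
    def total(self) -> int:
        return sum(count for _, count, _ in self.rows)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["category", "absolute_frequency", "relative_frequency"]
        )


def _freq_table(
    name: str,
    values: list[str | None],
    categories: Sequence[str],
    denominator: int,
) -> FrequencyTable:
    rows = []
    counted = 0
    for cat in categories:
        c = sum(1 for v in values if v == cat)
        counted += c
        rows.append((cat, c, round(c / denominator, 3) if denominator else 0.0))
    n_missing = len(values) - counted
    if n_missing:
        rows.append(
            ("missing", n_missing, round(n_missing / denominator, 3) if denominator else 0.0)
        )
    return FrequencyTable(name=name, rows=rows, denominator=denominator)


def summarize_cohort(
    records: Sequence[PatientRecord], denominator: int | None = None
) -> dict[str, FrequencyTable]:
    """Frequency tables for demographics, T stage and performed treatments.

    ``denominator`` defaults to the cohort size; pass the pre-exclusion
    size (e.g. 97 when summarizing the 92 kept cases) to mirror the
    published convention of reporting fractions against the full
    collection.
    """
    if not records:
        return {}
    denom = len(records) if denominator is None else denominator
    no_surgery = [r for r in records if r.treatments.get("larynx_surgery") == "false"]
    tables = {
        "gender": _freq_table(
            "gender", [r.gender for r in records], GENDER_STATES, denom
        ),
        "age_group": _freq_table(
            "age_group", [r.age_group for r in records], AGE_GROUPS, denom
        ),
        "t_state_total": _freq_table(
            "t_state_total", [r.T for r in records], T_STATES, denom
        ),
        "t_state_without_surgery": _freq_table(
            "t_state_without_surgery", [r.T for r in no_surgery], T_STATES, denom
        ),
        "treatments_performed": FrequencyTable(
            name="treatments_performed",
            rows=[
                (
                    tr,
                    sum(1 for r in records if r.treatments.get(tr) == "true"),
                    round(
                        sum(1 for r in records if r.treatments.get(tr) == "true") / denom,
                        3,
                    ),
                )
                for tr in TREATMENTS
            ],
            denominator=denom,
        ),
    }
    return tables


# ---------------------------------------------------------------------------
# CSV case files
# ---------------------------------------------------------------------------


def write_cases(records: Sequence[PatientRecord], path) -> None:
    """Write a case file: one row per case, empty cell = missing value."""
    extra_cols = sorted({k for r in records for k in r.extra})
    rows = []
    for r in records:
        row = {
            "case_id": r.case_id,
            "gender": r.gender,
            "age_group": r.age_group,
            **{f: getattr(r, f) for f in OBSERVABLE_FIELDS},
            **{tr: r.treatments.get(tr) for tr in TREATMENTS},
            **{c: r.extra.get(c) for c in extra_cols},
        }
        rows.append({k: ("" if v is None else v) for k, v in row.items()})
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS) + extra_cols)
    frame.to_csv(path, index=False)


def read_cases(path) -> list[PatientRecord]:
    """Read a case file; unknown columns are preserved in ``extra`` and flagged."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "case_id" not in frame.columns:
        raise ValueError(f"{path}: case file needs a 'case_id' column")
    unknown = [c for c in frame.columns if c not in CSV_COLUMNS]
    if unknown:
        logger.warning("%s: unknown columns preserved but unused: %s", path, unknown)

    def cell(row, col):
        if col not in frame.columns:
            return None
        v = row[col]
        return None if v == "" else v

    records = []
    for _, row in frame.iterrows():
        records.append(
            PatientRecord(
                case_id=row["case_id"],
                gender=cell(row, "gender"),
                age_group=cell(row, "age_group"),
                T=cell(row, "T"),
                N=cell(row, "N"),
                M=cell(row, "M"),
                chemo_tolerance=cell(row, "chemo_tolerance"),
                treatments={tr: cell(row, tr) for tr in TREATMENTS},
                extra={
                    c: row[c] for c in unknown if row[c] != ""
                },
                flags=("unknown_columns",) if unknown else (),
            )
        )
    return records


def cases_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Network-variable view of a cohort (one column per model variable)."""
    data = {
        **{f: [getattr(r, f) for r in records] for f in OBSERVABLE_FIELDS},
        **{tr: [r.treatments.get(tr) for r in records] for tr in TREATMENTS},
    }
    return pd.DataFrame(data)
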