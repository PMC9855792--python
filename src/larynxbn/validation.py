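"""Model validation: target prediction, accuracy/F1/ROC/PR, learning and CV.

The validation procedure mirrors how a clinical decision network is
scored against tumor-board records: for every case the observable
evidence (the non-missing staging values; missing entries are simply
marginalized by exact inference) is entered, the posterior of each
binary treatment node is computed, the MAP state (argmax; for binary
nodes equivalent to a 0.5 threshold, ties resolving to the negative
recommendation) is compared to the recorded therapy, and accuracy, F1,
ROC/AUC and precision-recall/AP statistics are aggregated per treatment
and overall.  Classes without a single true member yield an explicit
"undefined" marker instead of a number, the same convention under which
curves for never-performed therapies are omitted from reports.

Parameter learning estimates CPTs for a fixed structure by
Dirichlet-uniform posterior-mean counting (observed count plus a
uniform pseudo-count per cell, normalized); rows with missing values
are handled by expectation-maximization from a uniform start.  K-fold
cross-validation combines learning and prediction to quantify how much
a data-trained model loses against the expert-elicited one on small
cohorts.

ROC, PR and F1 numbers are computed through scikit-learn; the test
suite checks them against independent pair-counting and
confusion-matrix oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .bn_core import CPT, Network, map_state, posterior
from .cohort import PatientRecord, cases_to_frame

logger = logging.getLogger("larynxbn")

POSITIVE, NEGATIVE = "true", "false"


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictionRecord:
    """Posterior, MAP prediction and recorded truth for one (case, target)."""

    case_id: str
    target: str
    p_true: float
    predicted: str
    truth: str | None
    complete_evidence: bool


@dataclass
class PredictionSet:
    """Prediction records plus cases flagged (not silently dropped) as invalid."""

    records: list[PredictionRecord]
    flagged: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_target(self, target: str) -> list[PredictionRecord]:
        return [r for r in self.records if r.target == target]


def predict_targets(
    net: Network,
    cohort: Sequence[PatientRecord],
    targets: Sequence[str] | None = None,
) -> PredictionSet:
    """Infer every target for every case against its recorded therapy.

    Evidence per case is the set of non-missing observable values; a
    case carrying an invalid state label is flagged with the offending
    value and produces no records.  Treatment nodes are never used as
    evidence for one another: each target is inferred from observables
    only.
    """
    if targets is None:
        targets = [v.name for v in net.variables if v.role == "target"]
    else:
        for t in targets:
            if net.variable(t).role != "target":
                raise ValueError(f"{t!r} is not a target variable")
    observables = {v.name: v for v in net.variables if v.role == "observable"}

    records: list[PredictionRecord] = []
    flagged: list[tuple[str, str]] = []
    cache: dict[tuple, dict[str, float]] = {}
    for rec in cohort:
        evidence = {}
        bad = None
        for name, var in observables.items():
            value = getattr(rec, name, None)
            if value is None:
                continue
            if value not in var.states:
                bad = f"{name}={value!r} is not a valid state"
                break
            evidence[name] = value
        if bad is not None:
            flagged.append((rec.case_id, bad))
            continue
        complete = len(evidence) == len(observables)
        key_base = tuple(sorted(evidence.items()))
        for target in targets:
            key = key_base + (target,)
            if key not in cache:
                cache[key] = posterior(net, evidence, target)
            dist = cache[key]
            predicted = map_state(dist, net.variable(target).states)
            truth = rec.treatments.get(target)
            if truth is not None and truth not in net.variable(target).states:
                flagged.append((rec.case_id, f"{target}={truth!r} is not a valid state"))
                truth = None
            records.append(
                PredictionRecord(
                    case_id=rec.case_id,
                    target=target,
                    p_true=dist.get(POSITIVE, 0.0),
                    predicted=predicted,
                    truth=truth,
                    complete_evidence=complete,
                )
            )
    return PredictionSet(records=records, flagged=flagged)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------


@dataclass
class AccuracyReport:
    per_target: dict[str, tuple[int, int, float]]  # correct, total, fraction
    overall_correct: int
    overall_total: int
    n_missing_truth: int

    @property
    def overall(self) -> float:
        return self.overall_correct / self.overall_total if self.overall_total else 0.0


def accuracy(preds: PredictionSet | Iterable[PredictionRecord]) -> AccuracyReport:
    """Fraction of correct MAP recommendations, per target and overall.

    Records without a recorded truth label are counted separately and
    excluded from the fractions; the overall counts always equal the
    sums of the per-target counts.
    """
    records = list(preds)
    per: dict[str, list[int]] = {}
    n_missing = 0
    for r in records:
        if r.truth is None:
            n_missing += 1
            continue
        c = per.setdefault(r.target, [0, 0])
        c[1] += 1
        c[0] += int(r.predicted == r.truth)
    per_target = {
        t: (c[0], c[1], c[0] / c[1]) for t, c in per.items()
    }
    total_correct = sum(c for c, _, _ in per_target.values())
    total = sum(n for _, n, _ in per_target.values())
    return AccuracyReport(
        per_target=per_target,
        overall_correct=total_correct,
        overall_total=total,
        n_missing_truth=n_missing,
    )


# ---------------------------------------------------------------------------
# F1
# ---------------------------------------------------------------------------


@dataclass
class F1Report:
    f1_positive: float
    f1_negative: float
    weighted: float
    n_positive: int
    n_negative: int


def f1_scores(
    preds: PredictionSet | Iterable[PredictionRecord], target: str
) -> F1Report:
    """Per-class F1 for a binary target plus the frequency-weighted average.

    Each class is scored in turn as the positive one.  A class with no
    true and no predicted members has undefined F1 and is reported as 0
    (and then carries weight 0 in the weighted average).
    """
    rows = [r for r in preds if r.target == target and r.truth is not None]
    if not rows:
        return F1Report(0.0, 0.0, 0.0, 0, 0)
    y_true = [r.truth for r in rows]
    y_pred = [r.predicted for r in rows]
    f1_pos = float(
        skm.f1_score(y_true, y_pred, pos_label=POSITIVE, zero_division=0)
    )
    f1_neg = float(
        skm.f1_score(y_true, y_pred, pos_label=NEGATIVE, zero_division=0)
    )
    n_pos = sum(1 for t in y_true if t == POSITIVE)
    n_neg = len(y_true) - n_pos
    weighted = (n_pos * f1_pos + n_neg * f1_neg) / len(y_true)
    return F1Report(f1_pos, f1_neg, weighted, n_pos, n_neg)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    target: str
    defined: bool
    reason: str = ""
    fpr: np.ndarray | None = None
    tpr: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    auc: float | None = None


def roc_curve(
    preds: PredictionSet | Iterable[PredictionRecord], target: str
) -> RocResult:
    """ROC points and trapezoidal AUC for one target's posterior scores.

    With single-class truth the curve is undefined and an explicit
    marker is returned instead of a number (mirroring the convention of
    omitting curves for therapies with no positive cases).
    """
    rows = [r for r in preds if r.target == target and r.truth is not None]
    y = np.array([1 if r.truth == POSITIVE else 0 for r in rows])
    scores = np.array([r.p_true for r in rows])
    if len(rows) == 0 or y.min(initial=1) == y.max(initial=0):
        return RocResult(
            target=target,
            defined=False,
            reason="single-class truth: no positives and/or no negatives",
        )
    fpr, tpr, thr = skm.roc_curve(y, scores)
    return RocResult(
        target=target,
        defined=True,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=float(skm.auc(fpr, tpr)),
    )


# ---------------------------------------------------------------------------
# Precision-recall
# ---------------------------------------------------------------------------


@dataclass
class PRClassCurve:
    positive_class: str
    defined: bool
    reason: str = ""
    precision: np.ndarray | None = None
    recall: np.ndarray | None = None
    ap: float | None = None


@dataclass
class PRResult:
    target: str
    per_class: dict[str, PRClassCurve]
    micro_ap: float | None
    micro_defined: bool


def pr_curve(
    preds: PredictionSet | Iterable[PredictionRecord], target: str
) -> PRResult:
    """Precision-recall staircases per class orientation plus micro-average.

    Each binary class is scored in turn as positive (score ``p_true``
    for the positive orientation, ``1 - p_true`` for the negative one).
    AP is the area under the step-interpolated curve.  The micro average
    pools the (score, label) pairs of both orientations; orientations
    without true members are omitted with a marker.
    """
    rows = [r for r in preds if r.target == target and r.truth is not None]
    per_class: dict[str, PRClassCurve] = {}
    pooled_y: list[int] = []
    pooled_s: list[float] = []
    for cls in (POSITIVE, NEGATIVE):
        y = np.array([1 if r.truth == cls else 0 for r in rows])
        s = np.array([r.p_true if cls == POSITIVE else 1.0 - r.p_true for r in rows])
        if len(rows) == 0 or y.sum() == 0:
            per_class[cls] = PRClassCurve(
                positive_class=cls,
                defined=False,
                reason="no true members of this class",
            )
            continue
        prec, rec, _ = skm.precision_recall_curve(y, s)
        per_class[cls] = PRClassCurve(
            positive_class=cls,
            defined=True,
            precision=prec,
            recall=rec,
            ap=float(skm.average_precision_score(y, s)),
        )
        pooled_y.extend(y.tolist())
        pooled_s.extend(s.tolist())
    micro_defined = all(c.defined for c in per_class.values())
    micro_ap = (
        float(skm.average_precision_score(np.array(pooled_y), np.array(pooled_s)))
        if micro_defined
        else None
    )
    return PRResult(
        target=target,
        per_class=per_class,
        micro_ap=micro_ap,
        micro_defined=micro_defined,
    )


# ---------------------------------------------------------------------------
# Parameter learning
# ---------------------------------------------------------------------------


@dataclass
class LearnedParameters:
    network: Network
    prior_strength: float
    n_rows: int
    n_incomplete_rows: int
    em_iterations: int
    undefined_columns: list[str] = field(default_factory=list)


def _as_frame(structure: Network, data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        frame = data.copy()
    else:
        frame = cases_to_frame(list(data))
    names = [v.name for v in structure.variables]
    missing_cols = [n for n in names if n not in frame.columns]
    if missing_cols:
        raise ValueError(f"data lacks columns for variables: {missing_cols}")
    return frame[names]


def fit_parameters(
    structure: Network,
    data,
    prior_strength: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> LearnedParameters:
    """Estimate CPTs for a fixed structure from (possibly incomplete) cases.

    Complete rows contribute exact counts; the estimate per CPT column
    is the Dirichlet posterior mean ``(count + a) / (total + a*k)`` with
    uniform pseudo-count ``a = prior_strength`` per cell.  Rows with any
    missing value are handled by EM from a uniform start: expected
    family counts are computed per unique incomplete row by enumerating
    its completions under the current parameters, until the largest CPT
    change drops below ``tol`` or ``max_iter`` is reached.  Columns with
    no observations and ``prior_strength == 0`` are reported as
    undefined (and left uniform).
    """
    if prior_strength < 0:
        raise ValueError("prior_strength must be >= 0")
    frame = _as_frame(structure, data)
    n_rows = len(frame)

    variables = list(structure.variables)
    state_index = {
        v.name: {s: i for i, s in enumerate(v.states)} for v in variables
    }
    codes = np.empty((n_rows, len(variables)), dtype=int)
    for j, v in enumerate(variables):
        col = frame[v.name]
        idx = np.full(n_rows, -1, dtype=int)
        for i, val in enumerate(col):
            if val is None or (isinstance(val, float) and np.isnan(val)) or val is pd.NA:
                continue
            try:
                idx[i] = state_index[v.name][val]
            except KeyError:
                raise ValueError(
                    f"row {i}: {val!r} is not a state of {v.name!r}"
                ) from None
        codes[:, j] = idx

    col_of = {v.name: j for j, v in enumerate(variables)}
    import itertools as _it

    families = {}
    for v in variables:
        cpt = structure.cpts[v.name]
        parent_states = [structure.variable(p).states for p in cpt.parents]
        combos = list(_it.product(*parent_states))
        families[v.name] = {
            "parents": cpt.parents,
            "combos": combos,
            "combo_rank": {c: i for i, c in enumerate(combos)},
            "k": len(v.states),
            "dims": [len(s) for s in parent_states],
        }

    complete_mask = (codes >= 0).all(axis=1)
    base_counts = {
        name: np.zeros((len(f["combos"]), f["k"])) for name, f in families.items()
    }
    comp = codes[complete_mask]
    for name, f in families.items():
        flat = np.zeros(len(comp), dtype=int)
        for pname, d in zip(f["parents"], f["dims"]):
            flat = flat * d + comp[:, col_of[pname]]
        child = comp[:, col_of[name]]
        np.add.at(base_counts[name], (flat, child), 1.0)

    incomplete = codes[~complete_mask]
    n_incomplete = len(incomplete)

    def normalize(counts: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        theta = {}
        for name, f in families.items():
            c = counts[name] + prior_strength
            totals = c.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                th = np.where(totals > 0, c / totals, 1.0 / f["k"])
            theta[name] = th
        return theta

    def theta_to_cpts(theta: dict[str, np.ndarray]) -> list[CPT]:
        cpts = []
        for v in variables:
            f = families[v.name]
            table = {
                combo: tuple(theta[v.name][i]) for i, combo in enumerate(f["combos"])
            }
            cpts.append(CPT(child=v.name, parents=f["parents"], table=table))
        return cpts

    em_iterations = 0
    if n_incomplete == 0:
        theta = normalize(base_counts)
    else:
        # EM from a uniform start; unique incomplete row patterns are grouped.
        uniq, inverse = np.unique(incomplete, axis=0, return_inverse=True)
        weights = np.bincount(inverse, minlength=len(uniq)).astype(float)
        theta = {
            name: np.full((len(f["combos"]), f["k"]), 1.0 / f["k"])
            for name, f in families.items()
        }
        names = [v.name for v in variables]
        states = {v.name: v.states for v in variables}
        for em_iterations in range(1, max_iter + 1):
            counts = {name: c.copy() for name, c in base_counts.items()}
            net_now = structure.copy_with_cpts(theta_to_cpts(theta))
            for row, w in zip(uniq, weights):
                free = [j for j in range(len(names)) if row[j] < 0]
                options = [
                    range(len(states[names[j]])) if row[j] < 0 else (row[j],)
                    for j in range(len(names))
                ]
                completions = list(_it.product(*options))
                probs = np.array(
                    [
                        net_now.joint_probability(
                            {names[j]: states[names[j]][c[j]] for j in range(len(names))}
                        )
                        for c in completions
                    ]
                )
                z = probs.sum()
                if z <= 0:
                    continue  # impossible row under current parameters
                probs /= z
                for c, p in zip(completions, probs):
                    if p == 0.0:
                        continue
                    for name, f in families.items():
                        flat = 0
                        for pname, d in zip(f["parents"], f["dims"]):
                            flat = flat * d + c[col_of[pname]]
                        counts[name][flat, c[col_of[name]]] += w * p
            new_theta = normalize(counts)
            delta = max(
                float(np.abs(new_theta[name] - theta[name]).max())
                for name in families
            )
            theta = new_theta
            if delta < tol:
                break

    undefined = []
    if prior_strength == 0:
        for name, f in families.items():
            totals = base_counts[name].sum(axis=1)
            for i, tot in enumerate(totals):
                if tot == 0 and n_incomplete == 0:
                    undefined.append(f"{name} | {f['combos'][i]}")

    learned = structure.copy_with_cpts(theta_to_cpts(theta))
    return LearnedParameters(
        network=learned,
        prior_strength=prior_strength,
        n_rows=n_rows,
        n_incomplete_rows=n_incomplete,
        em_iterations=em_iterations,
        undefined_columns=undefined,
    )


def cpt_recovery_error(
    truth: Network, learned: Network, observed_counts: Mapping[str, np.ndarray] | None = None
) -> float:
    """Max absolute difference between two networks' CPT entries.

    If ``observed_counts`` maps variable names to per-combo observation
    totals, combos with zero observations are skipped.
    """
    import itertools as _it

    worst = 0.0
    for v in truth.variables:
        cpt_t = truth.cpts[v.name]
        cpt_l = learned.cpts[v.name]
        parent_states = [truth.variable(p).states for p in cpt_t.parents]
        for i, combo in enumerate(_it.product(*parent_states)):
            if observed_counts is not None:
                if observed_counts[v.name][i] == 0:
                    continue
            a = np.asarray(cpt_t.table[combo])
            b = np.asarray(cpt_l.table[combo])
            worst = max(worst, float(np.abs(a - b).max()))
    return worst


def cpt_recovery_weighted_error(
    truth: Network, learned: Network, observed_counts: Mapping[str, np.ndarray]
) -> float:
    """Observation-count-weighted mean of per-column max CPT errors.

    Unlike the raw maximum over observed cells — which is dominated by
    parent combinations seen only a handful of times and therefore does
    not shrink with sample size — this weighted mean is an estimate of
    the CPT error at a randomly drawn case and decreases as the data
    grow.
    """
    import itertools as _it

    num = 0.0
    den = 0.0
    for v in truth.variables:
        cpt_t = truth.cpts[v.name]
        cpt_l = learned.cpts[v.name]
        parent_states = [truth.variable(p).states for p in cpt_t.parents]
        for i, combo in enumerate(_it.product(*parent_states)):
            c = float(observed_counts[v.name][i])
            if c == 0:
                continue
            a = np.asarray(cpt_t.table[combo])
            b = np.asarray(cpt_l.table[combo])
            num += c * float(np.abs(a - b).max())
            den += c
    return num / den if den else 0.0


def observation_counts(structure: Network, data) -> dict[str, np.ndarray]:
    """Per-CPT parent-combination observation totals in a complete dataset."""
    import itertools as _it

    frame = _as_frame(structure, data)
    out = {}
    for v in structure.variables:
        cpt = structure.cpts[v.name]
        parent_states = [structure.variable(p).states for p in cpt.parents]
        combos = list(_it.product(*parent_states))
        rank = {c: i for i, c in enumerate(combos)}
        totals = np.zeros(len(combos))
        cols = [frame[p] for p in cpt.parents]
        for combo_vals in zip(*cols) if cpt.parents else [()] * len(frame):
            totals[rank[tuple(combo_vals)]] += 1
        out[v.name] = totals
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    fold_accuracies: list[float]
    fold_sizes: list[int]
    mean_accuracy: float
    k: int
    seed: int


def kfold_cv(
    structure: Network,
    records: Sequence[PatientRecord],
    k: int = 10,
    seed: int = 0,
    prior_strength: float = 1.0,
    targets: Sequence[str] | None = None,
) -> CVResult:
    """Seeded k-fold cross-validation of data-trained parameters.

    Cases are shuffled once with the seed and split into ``k`` near-equal
    folds (remainders spread over the first folds, no stratification).
    Each fold is scored by fitting parameters on the other ``k - 1``
    folds (uniform initialization via the pseudo-count prior) and
    predicting the held-out cases.
    """
    n = len(records)
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    accs: list[float] = []
    sizes: list[int] = []
    for fold in folds:
        test_idx = set(int(i) for i in fold)
        train = [records[i] for i in range(n) if i not in test_idx]
        test = [records[i] for i in sorted(test_idx)]
        learned = fit_parameters(structure, train, prior_strength=prior_strength)
        preds = predict_targets(learned.network, test, targets)
        rep = accuracy(preds)
        accs.append(rep.overall)
        sizes.append(len(test))
    return CVResult(
        fold_accuracies=accs,
        fold_sizes=sizes,
        mean_accuracy=float(np.mean(accs)),
        k=k,
        seed=seed,
    )
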