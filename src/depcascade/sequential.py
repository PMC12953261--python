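"""Stacked models, the sequential propagation-threshold cascade, and the
traffic-light certainty stratification.

The sequential model decides each case at the first step whose prediction
certainty ``max(p, 1-p)`` reaches that step's propagation threshold tau;
otherwise the case is propagated to the next (richer-modality) step, and the
final step always decides.  Thresholds are tuned on inner cross-validation to
maximize mean balanced accuracy, with ties broken by the smaller propagated
fraction (fewer per-case examinations) and then by the smaller tau.

Certainty is banded as low (50-66%), medium (67-82%) and high (83-100%);
non-low certainty renders a red (predicted depressed) or green (predicted
not depressed) light, low certainty renders yellow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import models as _models
from .cohort import CohortTable
from .evaluation import CVReport, FoldPlan, balanced_weights, metric_triple
from .exceptions import LeakageError

BAND_EDGES = (0.50, 0.67, 0.83)
COLOURS = ("green", "yellow", "red")
LEVELS = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# certainty bands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CertaintyBand:
    probability: float
    certainty: float
    level: str   # low / medium / high
    colour: str  # yellow / red / green


def assign_band(p: float) -> CertaintyBand:
    """Band a depression probability; 0.67 and 0.83 are inclusive upward."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    certainty = max(p, 1.0 - p)
    if certainty < BAND_EDGES[1]:
        level = "low"
    elif certainty < BAND_EDGES[2]:
        level = "medium"
    else:
        level = "high"
    if level == "low":
        colour = "yellow"
    else:
        colour = "red" if p > 0.5 else "green"
    return CertaintyBand(probability=p, certainty=certainty, level=level, colour=colour)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------


@dataclass
class OOFMatrix:
    """Out-of-fold member probabilities (cases x members) with provenance."""

    member_names: list[str]
    probabilities: np.ndarray
    out_of_fold: bool = True


@dataclass(frozen=True)
class StackSpec:
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a stack needs at least two member models")


@dataclass
class StackedModel:
    spec: StackSpec
    meta: LogisticRegression = field(repr=False, default=None)

    def predict_proba(self, member_probs: np.ndarray) -> np.ndarray:
        return self.meta.predict_proba(np.asarray(member_probs))[:, 1]


def train_stacker(spec: StackSpec, member_oof_probs: OOFMatrix, labels: np.ndarray,
                  seed: int = 0) -> StackedModel:
    """Logistic meta-learner on out-of-fold member probabilities.

    Member probabilities must be out-of-fold (no member was fitted on the
    case it scores); in-fold provenance raises a leakage error.
    """
    if not member_oof_probs.out_of_fold:
        raise LeakageError("member probabilities are in-fold; stacking would leak")
    if list(member_oof_probs.member_names) != list(spec.members):
        raise ValueError("member probability columns do not match the stack spec")
    y = np.asarray(labels)
    meta = LogisticRegression(random_state=seed)
    meta.fit(member_oof_probs.probabilities, y, sample_weight=balanced_weights(y))
    return StackedModel(spec=spec, meta=meta)


def member_oof_probabilities(
    member_specs: Sequence[_models.ModalityModelSpec],
    train: CohortTable,
    inner_folds: int = 5,
    seed: int = 0,
) -> OOFMatrix:
    """Inner-CV out-of-fold probabilities for each member model."""
    y = train.labels
    probs = np.full((train.n, len(member_specs)), np.nan)
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for tr, te in cv.split(np.zeros(train.n), y):
        sub = CohortTable(df=train.df.iloc[tr].reset_index(drop=True),
                          dictionary=train.dictionary, item_scales=train.item_scales)
        held = CohortTable(df=train.df.iloc[te].reset_index(drop=True),
                           dictionary=train.dictionary, item_scales=train.item_scales)
        for j, spec in enumerate(member_specs):
            model = _models.train_base_model(spec, sub, seed=seed + 13 * j)
            probs[te, j] = _models.predict_proba(model, held).probabilities
    return OOFMatrix(member_names=[s.name for s in member_specs],
                     probabilities=probs, out_of_fold=True)


# ---------------------------------------------------------------------------
# sequential policy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequentialPolicy:
    """Ordered steps with per-step propagation thresholds; the final step has
    no threshold and always decides."""

    step_names: tuple[str, ...]
    taus: tuple[float, ...]          # one per non-final step
    band_edges: tuple[float, float, float] = BAND_EDGES

    def __post_init__(self) -> None:
        if len(self.step_names) < 2:
            raise ValueError("a sequential policy needs at least two steps")
        if len(self.taus) != len(self.step_names) - 1:
            raise ValueError("need exactly one threshold per non-final step")
        for t in self.taus:
            if not 0.5 <= t <= 1.0:
                raise ValueError(f"propagation threshold {t} outside [0.5, 1]")


@dataclass
class RoutingResult:
    step_index: np.ndarray          # deciding step per case (0-based)
    probabilities: np.ndarray       # probability at the deciding step
    bands: list[CertaintyBand]
    propagated_fraction: list[float]  # fraction propagated beyond step s

    @property
    def labels(self) -> np.ndarray:
        return (self.probabilities > 0.5).astype(int)


def route_from_probabilities(step_probs: Sequence[np.ndarray],
                             taus: Sequence[float]) -> RoutingResult:
    """Core routing rule on precomputed per-step probabilities."""
    step_probs = [np.asarray(p, dtype=float) for p in step_probs]
    n_steps = len(step_probs)
    if len(taus) != n_steps - 1:
        raise ValueError("need one threshold per non-final step")
    for t in taus:
        if not 0.5 <= t <= 1.0:
            raise ValueError(f"propagation threshold {t} outside [0.5, 1]")
    n = len(step_probs[0])
    decided = np.zeros(n, dtype=bool)
    step_index = np.full(n, n_steps - 1, dtype=int)
    final_p = step_probs[-1].copy()
    propagated = []
    for s, tau in enumerate(taus):
        p = step_probs[s]
        certainty = np.maximum(p, 1.0 - p)
        decide_here = ~decided & (certainty >= tau)
        step_index[decide_here] = s
        final_p[decide_here] = p[decide_here]
        decided |= decide_here
        propagated.append(float((~decided).mean()))
    bands = [assign_band(float(p)) for p in final_p]
    return RoutingResult(step_index=step_index, probabilities=final_p,
                         bands=bands, propagated_fraction=propagated)


def route_cases(policy: SequentialPolicy, cases: CohortTable,
                step_models: Sequence[_models.TrainedModel]) -> RoutingResult:
    """Route raw cases through trained step models under a policy."""
    if len(step_models) != len(policy.step_names):
        raise ValueError("one trained model per policy step is required")
    step_probs = [_models.predict_proba(m, cases).probabilities for m in step_models]
    return route_from_probabilities(step_probs, policy.taus)


DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.50, 1.0001, 0.05), 2))


def optimize_policy(
    step_specs: Sequence[_models.ModalityModelSpec],
    train: CohortTable,
    inner_fold_ids: np.ndarray,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    seed: int = 0,
    step_names: Sequence[str] | None = None,
) -> SequentialPolicy:
    """Tune propagation thresholds on inner cross-validation.

    Every step model is trained on each inner-training split and scored on
    the inner-validation split; the tau vector maximizing mean routed
    balanced accuracy wins, ties going to the smallest propagated fraction
    and then the smallest tau.
    """
    if len(step_specs) < 2:
        raise ValueError("need at least two steps")
    grid = sorted(set(float(t) for t in tau_grid))
    if not grid:
        raise ValueError("empty tau grid")
    for t in grid:
        if not 0.5 <= t <= 1.0:
            raise ValueError(f"grid threshold {t} outside [0.5, 1]")
    y = train.labels
    inner_fold_ids = np.asarray(inner_fold_ids)
    folds = sorted(set(inner_fold_ids.tolist()))
    fold_probs: list[tuple[np.ndarray, list[np.ndarray]]] = []
    for j in folds:
        tr = np.where(inner_fold_ids != j)[0]
        te = np.where(inner_fold_ids == j)[0]
        sub = CohortTable(df=train.df.iloc[tr].reset_index(drop=True),
                          dictionary=train.dictionary, item_scales=train.item_scales)
        held = CohortTable(df=train.df.iloc[te].reset_index(drop=True),
                           dictionary=train.dictionary, item_scales=train.item_scales)
        probs = []
        for s, spec in enumerate(step_specs):
            m = _models.train_base_model(spec, sub, seed=seed + 7 * s)
            probs.append(_models.predict_proba(m, held).probabilities)
        fold_probs.append((y[te], probs))

    best = None
    for taus in itertools.product(grid, repeat=len(step_specs) - 1):
        bacs, props = [], []
        for y_te, probs in fold_probs:
            routing = route_from_probabilities(probs, taus)
            if len(np.unique(y_te)) < 2:
                continue
            bacs.append(metric_triple(y_te, routing.labels).balanced_accuracy)
            props.append(float(np.mean(routing.propagated_fraction)))
        key = (-np.mean(bacs), np.mean(props), taus)
        if best is None or key < best[0]:
            best = (key, taus)
    names = tuple(step_names) if step_names else tuple(s.name for s in step_specs)
    return SequentialPolicy(step_names=names, taus=best[1])


# ---------------------------------------------------------------------------
# traffic-light report
# ---------------------------------------------------------------------------


def format_percentage(correct: int, total: int) -> float | None:
    """One-decimal correct/total percentage; undefined (None) for empty cells."""
    if total == 0:
        return None
    return round(100.0 * correct / total, 1)


def format_count_cell(correct: int, total: int) -> str:
    pct = format_percentage(correct, total)
    return f"{correct}/{total} (-)" if pct is None else f"{correct}/{total} ({pct}%)"


@dataclass
class TrafficLightReport:
    """Correct / total counts and one-decimal percentages per traffic-light
    colour and true class (class 1 = depression, 0 = healthy control)."""

    cells: dict[tuple[str, int], dict]

    def percentage(self, colour: str, true_class: int) -> float | None:
        c = self.cells[(colour, true_class)]
        return format_percentage(c["correct"], c["total"])

    def to_json_dict(self) -> dict:
        return {
            f"{colour}/{'depressed' if cls else 'control'}": {
                **self.cells[(colour, cls)],
                "percentage": self.percentage(colour, cls),
            }
            for (colour, cls) in self.cells
        }


def traffic_light_report(routing: RoutingResult, y_true: np.ndarray) -> TrafficLightReport:
    """Count correct classifications per colour x true class."""
    y_true = np.asarray(y_true, dtype=int)
    if len(y_true) != len(routing.probabilities):
        raise ValueError("routing and labels have different lengths")
    pred = routing.labels
    colours = np.array([b.colour for b in routing.bands])
    cells = {}
    for colour in COLOURS:
        for cls in (0, 1):
            sel = (colours == colour) & (y_true == cls)
            cells[(colour, cls)] = {
                "correct": int((pred[sel] == y_true[sel]).sum()),
                "total": int(sel.sum()),
            }
    return TrafficLightReport(cells=cells)


def render_traffic_table(reports: dict[str, TrafficLightReport]) -> str:
    """Markdown table in the published layout: per-class totals, the
    high-certainty red (depressed) and green (control) cells, and the yellow
    cells, one row per model."""
    lines = [
        "| Model | Depression total | HC total | Red (Depression) | Green (HC) "
        "| Yellow (Depression) | Yellow (HC) |",
        "|---|---|---|---|---|---|---|",
    ]
    for name, rep in reports.items():
        def cell(colour, cls):
            c = rep.cells[(colour, cls)]
            return format_count_cell(c["correct"], c["total"])
        dep_total = {"correct": sum(rep.cells[(c, 1)]["correct"] for c in COLOURS),
                     "total": sum(rep.cells[(c, 1)]["total"] for c in COLOURS)}
        hc_total = {"correct": sum(rep.cells[(c, 0)]["correct"] for c in COLOURS),
                    "total": sum(rep.cells[(c, 0)]["total"] for c in COLOURS)}
        lines.append(
            f"| {name} | {format_count_cell(**dep_total)} | {format_count_cell(**hc_total)} "
            f"| {cell('red', 1)} | {cell('green', 0)} "
            f"| {cell('yellow', 1)} | {cell('yellow', 0)} |"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# nested evaluation of the two-step clinical cascade
# ---------------------------------------------------------------------------


def clinical5_spec(clinical15_model: _models.TrainedModel) -> _models.ModalityModelSpec:
    """First-step model: the five most important items of a trained
    15-item model."""
    items = _models.top_k_features(clinical15_model, 5)
    return _models.ModalityModelSpec(
        name="Clinical 5", modalities=clinical15_model.spec.modalities,
        features=tuple(items), feature_count=5, pipeline="P1",
    )


def evaluate_sequential_nested(
    cohort: CohortTable,
    plan: FoldPlan,
    clinical15: _models.ModalityModelSpec,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    seed: int | None = None,
) -> tuple[CVReport, RoutingResult, TrafficLightReport, list[SequentialPolicy]]:
    """Nested-CV evaluation of the Clinical 5 -> Clinical 15 cascade.

    Per outer fold: the 15-item model is trained on the outer-training split,
    its top-5 items define the first step, the propagation threshold is tuned
    on the fold's inner splits, and the outer-test split is routed once.
    Routing results are pooled over outer folds for the traffic-light report.
    """
    seed = plan.seed if seed is None else seed
    y = cohort.labels
    n = cohort.n
    fold_metrics = []
    pooled_step = np.zeros(n, dtype=int)
    pooled_p = np.zeros(n, dtype=float)
    policies = []
    prop_fracs = []
    for k in range(plan.n_outer):
        tr_idx, te_idx = plan.outer_split(k)
        train_tab = CohortTable(df=cohort.df.iloc[tr_idx].reset_index(drop=True),
                                dictionary=cohort.dictionary, item_scales=cohort.item_scales)
        test_tab = CohortTable(df=cohort.df.iloc[te_idx].reset_index(drop=True),
                               dictionary=cohort.dictionary, item_scales=cohort.item_scales)
        fold_seed = seed + 1000 * k
        m15 = _models.train_base_model(clinical15, train_tab, seed=fold_seed)
        spec5 = clinical5_spec(m15)
        policy = optimize_policy([spec5, clinical15], train_tab, plan.inner[k],
                                 tau_grid=tau_grid, seed=fold_seed)
        m5 = _models.train_base_model(spec5, train_tab, seed=fold_seed)
        routing = route_cases(policy, test_tab, [m5, m15])
        fold_metrics.append(metric_triple(y[te_idx], routing.labels))
        pooled_step[te_idx] = routing.step_index
        pooled_p[te_idx] = routing.probabilities
        policies.append(policy)
        prop_fracs.append(routing.propagated_fraction[0])
    pooled = RoutingResult(
        step_index=pooled_step, probabilities=pooled_p,
        bands=[assign_band(float(p)) for p in pooled_p],
        propagated_fraction=[float(np.mean(prop_fracs))],
    )
    report = CVReport(model_name="Clinical 15 (sequential)", seed=seed,
                      fold_metrics=fold_metrics)
    return report, pooled, traffic_light_report(pooled, y), policies
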