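"""Synthetic primary-care cohort generator.

The real study cohort (581 outpatients, 90 of them with a structured-interview
depression diagnosis) is not publicly deposited, so every downstream stage of
this package is exercised on synthetic cohorts that reproduce the published
marginal structure: group-wise means/SDs and categorical rates for every
feature, four latent biomarker subtypes within the depressed group with their
own profiles, questionnaire totals that decompose into in-range item scores,
an exchangeable within-modality correlation, physiological clipping bounds,
and missing-completely-at-random cells.

Continuous features are drawn blockwise (one block per modality) from a
multivariate normal with exchangeable correlation, then clipped to the
plausibility bounds declared in the data dictionary; ordinal features are
additionally rounded.  Questionnaire totals are drawn first and item scores
are then allocated by a seeded uniform random partition that sums exactly to
the total.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError

ID_COLUMN = "participant_id"
LABEL_COLUMN = "diagnosis"
SUBTYPE_COLUMN = "subtype"

MODALITIES = (
    "self_report_item",
    "self_report_total",
    "lab",
    "physiological",
    "anthropometric",
    "biographic",
)

#: Subtype labels in fixture order; default weights follow the published
#: cluster sizes 26/27/9/28 (Adaptive / LateDepression / ImmunoMetabolic /
#: OverweightNonInflammatory).
SUBTYPE_LABELS = (
    "Adaptive",
    "LateDepression",
    "ImmunoMetabolic",
    "OverweightNonInflammatory",
)

_DEFAULT_FIXTURE = importlib.resources.files("depcascade.data") / "profiles.yaml"


# ---------------------------------------------------------------------------
# profile containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupProfile:
    """Marginal parameters of one diagnostic group."""

    group_label: str
    continuous_params: Mapping[str, tuple[float, float]]
    categorical_params: Mapping[str, Mapping[str, float]]
    n_default: int

    def __post_init__(self) -> None:
        if self.n_default <= 0:
            raise ValidationError(f"{self.group_label}: n_default must be positive")
        _check_params(self.group_label, self.continuous_params, self.categorical_params)


@dataclass(frozen=True)
class SubtypeProfile:
    """Biomarker parameters of one latent depressed subtype."""

    subtype_label: str
    continuous_params: Mapping[str, tuple[float, float]]
    categorical_params: Mapping[str, Mapping[str, float]]
    mixing_weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mixing_weight <= 1.0:
            raise ValidationError(
                f"{self.subtype_label}: mixing weight {self.mixing_weight} not in (0, 1]"
            )
        _check_params(self.subtype_label, self.continuous_params, self.categorical_params)


def _check_params(owner, continuous, categorical) -> None:
    for feat, (mean, sd) in continuous.items():
        if sd < 0:
            raise ValidationError(f"{owner}/{feat}: negative sd {sd}")
        if not np.isfinite(mean) or not np.isfinite(sd):
            raise ValidationError(f"{owner}/{feat}: non-finite parameter")
    for feat, probs in categorical.items():
        total = float(sum(probs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{owner}/{feat}: category probabilities sum to {total}, not 1"
            )
        if any(p < 0 for p in probs.values()):
            raise ValidationError(f"{owner}/{feat}: negative category probability")


@dataclass(frozen=True)
class GeneratorSpec:
    """Sampling configuration for one synthetic cohort."""

    n_total: int = 581
    n_depressed: int = 90
    within_block_correlation: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0
    item_scales: Mapping[str, tuple[int, int, int]] | None = None
    #: optional override of the subtype mixing weights, e.g. to force every
    #: depressed participant into one subtype: {"ImmunoMetabolic": 1.0}
    subtype_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_depressed <= self.n_total:
            raise ValueError(
                f"n_depressed={self.n_depressed} must lie in [0, n_total={self.n_total}]"
            )
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError("within_block_correlation must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.subtype_weights is not None:
            unknown = set(self.subtype_weights) - set(SUBTYPE_LABELS)
            if unknown:
                raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
            if abs(sum(self.subtype_weights.values()) - 1.0) > 1e-9:
                raise ValueError("subtype_weights must sum to 1")


@dataclass
class CohortTable:
    """Participants x typed features, plus the data dictionary.

    ``df`` holds one row per participant: participant id, 0/1 diagnosis,
    nullable latent subtype, and feature columns whose modality / value type /
    units / bounds are described by ``dictionary``.
    """

    df: pd.DataFrame
    dictionary: dict[str, dict]
    item_scales: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df[LABEL_COLUMN].to_numpy(dtype=int)

    def feature_columns(self, modalities: Sequence[str] | None = None) -> list[str]:
        if modalities is None:
            return list(self.dictionary)
        bad = set(modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        return [c for c, m in self.dictionary.items() if m["modality"] in modalities]

    def write(self, csv_path: str | Path, dict_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        self.df.to_csv(csv_path, index=False, na_rep="")
        if dict_path is None:
            dict_path = csv_path.with_suffix(".dictionary.json")
        payload = {"columns": self.dictionary, "item_scales": {
            k: list(v) for k, v in self.item_scales.items()}}
        Path(dict_path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, csv_path: str | Path, dict_path: str | Path | None = None) -> "CohortTable":
        csv_path = Path(csv_path)
        if dict_path is None:
            dict_path = csv_path.with_suffix(".dictionary.json")
        payload = json.loads(Path(dict_path).read_text())
        dictionary = payload["columns"]
        item_scales = {k: tuple(v) for k, v in payload.get("item_scales", {}).items()}
        df = pd.read_csv(csv_path, na_values=[""], keep_default_na=True)
        expected = [ID_COLUMN, LABEL_COLUMN, SUBTYPE_COLUMN, *dictionary]
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            raise SchemaError(f"CSV columns not in data dictionary: {unknown}")
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise SchemaError(f"CSV is missing declared columns: {missing}")
        for col, meta in dictionary.items():
            if meta["vtype"] == "categorical":
                df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
            else:
                df[col] = df[col].astype(float)
        return cls(df=df[expected], dictionary=dictionary, item_scales=item_scales)


# ---------------------------------------------------------------------------
# fixture loading
# ---------------------------------------------------------------------------


def load_feature_metadata(fixture_path: str | Path | None = None) -> dict[str, dict]:
    """The data dictionary of generated columns (modality, vtype, units, bounds)."""
    raw = _read_fixture(fixture_path)
    return dict(raw["features"])


def load_item_scales(fixture_path: str | Path | None = None) -> dict[str, tuple[int, int, int]]:
    raw = _read_fixture(fixture_path)
    scales = {}
    for name, s in raw["item_scales"].items():
        if s["min_item"] > s["max_item"]:
            raise ValidationError(f"item scale {name}: min_item > max_item")
        scales[name] = (int(s["items"]), int(s["min_item"]), int(s["max_item"]))
    return scales


def load_profiles(
    fixture_path: str | Path | None = None,
) -> tuple[dict[str, GroupProfile], dict[str, SubtypeProfile]]:
    """Load and validate the calibration fixture.

    Returns the (non_depressed, depressed) group profiles and the four
    depressed-subtype profiles.  Any feature referenced by a profile must be
    declared in the fixture's data dictionary; validation failures name the
    offending entry.
    """
    raw = _read_fixture(fixture_path)
    for key in ("features", "group_profiles", "subtype_profiles"):
        if key not in raw:
            raise SchemaError(f"fixture is missing section '{key}'")
    known = set(raw["features"])

    groups: dict[str, GroupProfile] = {}
    for label, spec in raw["group_profiles"].items():
        if label not in ("depressed", "non_depressed"):
            raise SchemaError(f"unknown group label '{label}'")
        _reject_unknown(label, spec, known)
        groups[label] = GroupProfile(
            group_label=label,
            continuous_params={k: (float(m), float(s)) for k, (m, s) in spec["continuous"].items()},
            categorical_params={k: {str(c): float(p) for c, p in v.items()}
                                for k, v in spec["categorical"].items()},
            n_default=int(spec["n_default"]),
        )
    if set(groups) != {"depressed", "non_depressed"}:
        raise SchemaError("fixture must define exactly the depressed and non_depressed groups")

    subtypes: dict[str, SubtypeProfile] = {}
    for label, spec in raw["subtype_profiles"].items():
        if label not in SUBTYPE_LABELS:
            raise SchemaError(f"unknown subtype label '{label}'")
        _reject_unknown(label, spec, known)
        subtypes[label] = SubtypeProfile(
            subtype_label=label,
            continuous_params={k: (float(m), float(s)) for k, (m, s) in spec["continuous"].items()},
            categorical_params={k: {str(c): float(p) for c, p in v.items()}
                                for k, v in spec.get("categorical", {}).items()},
            mixing_weight=float(spec["mixing_weight"]),
        )
    if set(subtypes) != set(SUBTYPE_LABELS):
        raise SchemaError("fixture must define exactly the four depressed subtypes")
    wsum = sum(p.mixing_weight for p in subtypes.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ValidationError(f"subtype mixing weights sum to {wsum}, not 1")
    return groups, subtypes


def _read_fixture(fixture_path):
    if fixture_path is None:
        text = _DEFAULT_FIXTURE.read_text()
    else:
        path = Path(fixture_path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed handcrafted file
        raise SchemaError(f"fixture does not parse as YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("fixture root must be a mapping")
    return raw


def _reject_unknown(owner, spec, known) -> None:
    for section in ("continuous", "categorical"):
        for feat in spec.get(section, {}) or {}:
            if feat not in known:
                raise SchemaError(f"{owner}: unknown feature '{feat}'")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    from scipy import stats as _st
    a, b = (lo - mu) / sd, (hi - mu) / sd
    Fa, Fb = _st.norm.cdf(a), _st.norm.cdf(b)
    fa, fb = _st.norm.pdf(a), _st.norm.pdf(b)
    return lo * Fa + hi * (1.0 - Fb) + mu * (Fb - Fa) - sd * (fb - fa)


_MU_CACHE: dict[tuple[float, float, float, float], float] = {}


def _latent_mu(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent Gaussian mean whose clipped-to-[lo, hi] expectation equals the
    printed mean, so plausibility clipping does not bias the calibration.
    Monotone in mu; solved by bracketing."""
    if sd == 0 or not (np.isfinite(lo) or np.isfinite(hi)):
        return target_mean
    if not lo < target_mean < hi:
        return target_mean
    key = (target_mean, sd, lo, hi)
    if key not in _MU_CACHE:
        from scipy.optimize import brentq
        f = lambda mu: _clipped_normal_mean(mu, sd, lo, hi) - target_mean  # noqa: E731
        if abs(f(target_mean)) < 1e-12:
            _MU_CACHE[key] = target_mean
        else:
            _MU_CACHE[key] = float(brentq(f, target_mean - 10 * sd, target_mean + 10 * sd,
                                          xtol=1e-10))
    return _MU_CACHE[key]


def allocate_item_scores(
    total: float,
    scale: tuple[int, int, int],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Partition a questionnaire total into integer item scores.

    The total is rounded and clipped into the representable range, then the
    surplus over the per-item minimum is split uniformly at random over the
    items subject to the per-item maximum (a multivariate-hypergeometric
    draw, i.e. a uniform random bounded composition).  Items always sum
    exactly to the clipped, rounded total.
    """
    n_items, lo, hi = (int(v) for v in scale)
    if lo > hi:
        raise ValueError(f"impossible item scale: min_item {lo} > max_item {hi}")
    if n_items <= 0:
        raise ValueError("item_count must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    total = int(np.clip(np.rint(total), n_items * lo, n_items * hi))
    surplus = total - n_items * lo
    cap = hi - lo
    if cap == 0:
        return np.full(n_items, lo)
    items = lo + rng.multivariate_hypergeometric([cap] * n_items, surplus)
    return items.astype(int)


def sample_cohort(
    spec: GeneratorSpec,
    profiles: tuple[dict[str, GroupProfile], dict[str, SubtypeProfile]] | None = None,
    fixture_path: str | Path | None = None,
) -> CohortTable:
    """Draw one cohort table under ``spec``.

    Exactly ``spec.n_depressed`` rows carry diagnosis 1 (deterministic
    stratification).  Depressed rows get a latent subtype by largest-remainder
    apportionment of the mixing weights; subtype biomarker parameters override
    the group-level ones for those rows.  Identical specs give identical
    tables.
    """
    if profiles is None:
        profiles = load_profiles(fixture_path)
    groups, subtypes = profiles
    features = load_feature_metadata(fixture_path)
    scales = dict(load_item_scales(fixture_path))
    if spec.item_scales is not None:
        scales.update({k: tuple(v) for k, v in spec.item_scales.items()})

    rng = np.random.default_rng(spec.seed)
    n, n_dep = spec.n_total, spec.n_depressed

    # deterministic stratification, then a seeded shuffle of row order
    labels = np.zeros(n, dtype=int)
    labels[:n_dep] = 1
    order = rng.permutation(n)
    labels = labels[order]

    # subtype apportionment among depressed rows
    weights = {lab: subtypes[lab].mixing_weight for lab in SUBTYPE_LABELS}
    if spec.subtype_weights is not None:
        weights = {lab: spec.subtype_weights.get(lab, 0.0) for lab in SUBTYPE_LABELS}
    counts = _largest_remainder(weights, n_dep)
    subtype_pool = np.concatenate(
        [np.full(c, i) for i, lab in enumerate(SUBTYPE_LABELS) for c in [counts[lab]]]
    ) if n_dep else np.empty(0, dtype=int)
    subtype_pool = rng.permutation(subtype_pool)
    subtype_idx = np.full(n, -1, dtype=int)
    subtype_idx[labels == 1] = subtype_pool

    dep, nondep = groups["depressed"], groups["non_depressed"]

    data: dict[str, np.ndarray | pd.Series] = {}
    # continuous features, blockwise with exchangeable correlation
    cont_feats = [f for f, m in features.items() if m["vtype"] in ("continuous", "ordinal")]
    blocks: dict[str, list[str]] = {}
    for f in cont_feats:
        blocks.setdefault(features[f]["modality"], []).append(f)
    rho = spec.within_block_correlation
    for modality in sorted(blocks):
        feats = blocks[modality]
        shared = rng.standard_normal(n)
        eps = rng.standard_normal((n, len(feats)))
        z = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * eps
        for j, f in enumerate(feats):
            lo, hi = features[f].get("bounds", (-np.inf, np.inf))
            mu = np.empty(n)
            sd = np.empty(n)
            m0, s0 = nondep.continuous_params[f]
            m1, s1 = dep.continuous_params[f]
            mu[labels == 0], sd[labels == 0] = _latent_mu(m0, s0, lo, hi), s0
            mu[labels == 1], sd[labels == 1] = _latent_mu(m1, s1, lo, hi), s1
            for i, lab in enumerate(SUBTYPE_LABELS):
                if f in subtypes[lab].continuous_params:
                    ms, ss = subtypes[lab].continuous_params[f]
                    sel = subtype_idx == i
                    mu[sel], sd[sel] = _latent_mu(ms, ss, lo, hi), ss
            x = mu + sd * z[:, j]
            x = np.clip(x, lo, hi)
            if features[f]["vtype"] == "ordinal":
                x = np.rint(x)
            data[f] = x

    # categorical features (independent draws from group marginals)
    cat_feats = [f for f, m in features.items() if m["vtype"] in ("binary", "categorical")]
    for f in cat_feats:
        out = np.empty(n, dtype=object)
        for glabel, profile in (("non_depressed", nondep), ("depressed", dep)):
            probs = profile.categorical_params[f]
            cats = list(probs)
            p = np.array([probs[c] for c in cats], dtype=float)
            sel = labels == (1 if glabel == "depressed" else 0)
            draws = rng.choice(len(cats), size=int(sel.sum()), p=p)
            out[sel] = np.array(cats, dtype=object)[draws]
        if features[f]["vtype"] == "binary":
            data[f] = out.astype(float)
        else:
            data[f] = out

    # item scores allocated from totals
    dictionary = {f: dict(meta) for f, meta in features.items()}
    for total_col, meta in features.items():
        qname = meta.get("scale")
        if not qname:
            continue
        n_items, lo, hi = scales[qname]
        item_cols = [f"{qname}_i{k}" for k in range(1, n_items + 1)]
        mat = np.empty((n, n_items), dtype=float)
        totals = data[total_col]
        for r in range(n):
            mat[r] = allocate_item_scores(totals[r], (n_items, lo, hi), rng)
        # keep the stored total consistent with the (clipped) item sum
        data[total_col] = mat.sum(axis=1)
        for k, col in enumerate(item_cols):
            data[col] = mat[:, k]
            dictionary[col] = {
                "modality": "self_report_item",
                "vtype": "ordinal",
                "units": "points",
                "bounds": [lo, hi],
                "scale": qname,
            }

    subtype_col = np.where(
        subtype_idx >= 0, np.array(SUBTYPE_LABELS, dtype=object)[np.clip(subtype_idx, 0, None)], None
    )
    df = pd.DataFrame(
        {
            ID_COLUMN: [f"P{i:05d}" for i in range(1, n + 1)],
            LABEL_COLUMN: labels,
            SUBTYPE_COLUMN: subtype_col,
            **data,
        }
    )[[ID_COLUMN, LABEL_COLUMN, SUBTYPE_COLUMN, *dictionary]]
    table = CohortTable(df=df, dictionary=dictionary, item_scales=scales)
    if spec.missing_rate > 0:
        table = inject_missingness(table, spec.missing_rate, seed=int(rng.integers(2**31)))
    return table


def inject_missingness(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """Mask feature cells missing-completely-at-random at the given rate.

    Id, diagnosis and latent-subtype columns are never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    df = table.df.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        cols = list(table.dictionary)
        mask = rng.random((len(df), len(cols))) < rate
        for j, col in enumerate(cols):
            sub = df[col].to_numpy(copy=True)
            if df[col].dtype == object:
                sub = sub.astype(object)
                sub[mask[:, j]] = np.nan
            else:
                sub = sub.astype(float)
                sub[mask[:, j]] = np.nan
            df[col] = sub
    return CohortTable(df=df, dictionary=dict(table.dictionary), item_scales=dict(table.item_scales))


def _largest_remainder(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion n units to keys proportionally, deterministically."""
    quotas = {k: w * n for k, w in weights.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(weights, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts
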