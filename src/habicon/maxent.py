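"""Presence-background maximum-entropy species distribution model.

The model is a Gibbs distribution over background cells,
``q(x) ∝ exp(λ·f(x))``, fitted by maximizing the L1-regularized gain

    G(λ) = mean_presence[λ·f(x)] − ln Z(λ) − Σ_j β_j |λ_j|,

with ``Z = mean_background exp(λ·f)``, by cyclic coordinate descent: each
pass performs a one-dimensional exact line search per feature and accepts
only gain-improving steps, stopping when a full cycle improves the gain by
less than the convergence tolerance.

Features are built from background-scaled variables (min/max to [0, 1]):
linear, quadratic, pairwise products, forward/reverse hinges at evenly
spaced background quantiles, and per-category indicators for categorical
variables. Regularization per feature follows the conventional
sample-size-interpolated base penalties scaled by the feature's presence
standard deviation over sqrt(sample size).

The logistic output calibrates the raw distribution so an uninformative
model scores 0.5 everywhere: ``logistic = e^H q / (1 + e^H q)`` with ``H``
the entropy of ``q`` over the background.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import EnvStack, GridLayer
from .occurrences import OccurrenceSet

__all__ = [
    "MaxEntConfig",
    "MaxEntModel",
    "VariableReport",
    "pearson_screen",
    "fit",
    "predict",
    "evaluate_replicates",
    "percent_contribution",
    "jackknife",
    "response_curve",
]


class MaxEntError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_ALL_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "categorical")

# Base L1 penalties interpolated on presence sample size (standard defaults
# of the reference implementation).
_BETA_TABLES = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 1.6, 0.9, 0.55, 0.05]),
    "hinge": ([0], [0.5]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
}


@dataclass
class MaxEntConfig:
    """Fitting configuration; defaults follow common MaxEnt practice."""

    feature_classes: Optional[Tuple[str, ...]] = None  # None = auto by stack
    n_background: int = 10000
    reg_multiplier: float = 1.0
    convergence_tol: float = 1e-5
    max_iterations: int = 500
    test_fraction: float = 0.25
    n_replicates: int = 10
    n_hinge_knots: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise MaxEntError("convergence_tol must be positive")
        if not (0 < self.test_fraction < 1):
            raise MaxEntError("test_fraction must lie in (0, 1)")
        if self.n_replicates < 1:
            raise MaxEntError("n_replicates must be >= 1")
        if self.reg_multiplier < 0:
            raise MaxEntError("reg_multiplier must be non-negative")
        if self.feature_classes is not None:
            bad = set(self.feature_classes) - set(_ALL_FEATURE_CLASSES)
            if bad:
                raise MaxEntError(f"unknown feature classes: {sorted(bad)}")
            self.feature_classes = tuple(self.feature_classes)

    def resolve_feature_classes(self, stack: EnvStack) -> Tuple[str, ...]:
        if self.feature_classes is not None:
            return self.feature_classes
        classes = ["linear", "quadratic", "hinge"]
        if len(stack.continuous_names()) >= 2:
            classes.append("product")
        if stack.categorical_names():
            classes.append("categorical")
        return tuple(classes)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One model feature derived from source variable(s).

    ``kind`` is one of linear/quadratic/product/hinge_fwd/hinge_rev/
    indicator. ``variables`` holds one name (two for products). ``param``
    is the hinge knot (scaled units) or the category code.
    """

    kind: str
    variables: Tuple[str, ...]
    param: float = 0.0

    @property
    def source_variable(self) -> str:
        # products credit their first variable; used by contribution tallies
        return self.variables[0]

    def evaluate(self, scaled: Dict[str, np.ndarray]) -> np.ndarray:
        if self.kind == "linear":
            return scaled[self.variables[0]]
        if self.kind == "quadratic":
            return scaled[self.variables[0]] ** 2
        if self.kind == "product":
            return scaled[self.variables[0]] * scaled[self.variables[1]]
        if self.kind == "hinge_fwd":
            v = scaled[self.variables[0]]
            knot = self.param
            span = max(1.0 - knot, 1e-12)
            return np.clip((v - knot) / span, 0.0, None)
        if self.kind == "hinge_rev":
            v = scaled[self.variables[0]]
            knot = self.param
            span = max(knot, 1e-12)
            return np.clip((knot - v) / span, 0.0, None)
        if self.kind == "indicator":
            return (scaled[self.variables[0]] == self.param).astype(float)
        raise MaxEntError(f"unknown feature kind {self.kind!r}")

    @property
    def beta_class(self) -> str:
        return {
            "linear": "linear",
            "quadratic": "quadratic",
            "product": "product",
            "hinge_fwd": "hinge",
            "hinge_rev": "hinge",
            "indicator": "categorical",
        }[self.kind]


def _build_features(
    stack: EnvStack,
    classes: Sequence[str],
    scaled_bg: Dict[str, np.ndarray],
    n_hinge_knots: int,
) -> List[Feature]:
    continuous = stack.continuous_names()
    categorical = stack.categorical_names()
    feats: List[Feature] = []
    if "linear" in classes:
        feats += [Feature("linear", (v,)) for v in continuous]
    if "quadratic" in classes:
        feats += [Feature("quadratic", (v,)) for v in continuous]
    if "product" in classes:
        for i, a in enumerate(continuous):
            for b in continuous[i + 1 :]:
                feats.append(Feature("product", (a, b)))
    if "hinge" in classes and n_hinge_knots > 0:
        qs = np.linspace(0, 1, n_hinge_knots + 2)[1:-1]
        for v in continuous:
            knots = np.unique(np.quantile(scaled_bg[v], qs))
            for k in knots:
                if 0.0 < k < 1.0:
                    feats.append(Feature("hinge_fwd", (v,), float(k)))
                    feats.append(Feature("hinge_rev", (v,), float(k)))
    if "categorical" in classes:
        for v in categorical:
            for code in np.unique(scaled_bg[v]):
                feats.append(Feature("indicator", (v,), float(code)))
    return feats


def _beta_base(beta_class: str, n_presence: int) -> float:
    xs, ys = _BETA_TABLES[beta_class]
    return float(np.interp(n_presence, xs, ys))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class MaxEntModel:
    """Fitted maximum-entropy model.

    ``partition_Z`` is the background mean of ``exp(λ·f)``; ``entropy_H``
    the entropy of the raw distribution over the fitting background;
    ``gain_path`` records each accepted coordinate step as
    ``(feature_index, gain_delta)``.
    """

    features: List[Feature]
    coefficients: np.ndarray
    scaling: Dict[str, Tuple[float, float]]  # var -> (min, max) over background
    variable_kinds: Dict[str, str]
    partition_Z: float
    entropy_H: float
    n_background: int
    gain: float
    gain_path: List[Tuple[int, float]] = field(default_factory=list)
    contribution_tally: Dict[str, float] = field(default_factory=dict)
    converged: bool = False
    n_iterations: int = 0

    # -- evaluation -------------------------------------------------------
    def _scale_values(self, raw: Dict[str, np.ndarray], clamp: bool = True) -> Dict[str, np.ndarray]:
        scaled: Dict[str, np.ndarray] = {}
        for name, vals in raw.items():
            if self.variable_kinds.get(name) == "categorical":
                scaled[name] = np.asarray(vals, dtype=float)
                continue
            lo, hi = self.scaling[name]
            v = np.asarray(vals, dtype=float)
            if clamp:
                v = np.clip(v, lo, hi)
            span = hi - lo
            scaled[name] = (v - lo) / span if span > 0 else np.zeros_like(v)
        return scaled

    def linear_score(self, raw_values: Dict[str, np.ndarray]) -> np.ndarray:
        """λ·f(x) with out-of-range clamping before feature evaluation."""
        scaled = self._scale_values(raw_values)
        eta = np.zeros(next(iter(scaled.values())).shape, dtype=float)
        for lam, feat in zip(self.coefficients, self.features):
            if lam != 0.0:
                eta = eta + lam * feat.evaluate(scaled)
        return eta

    def raw_density(self, raw_values: Dict[str, np.ndarray]) -> np.ndarray:
        """q(x) = exp(η)/(N·Z); sums to 1 over the fitting background."""
        eta = self.linear_score(raw_values)
        return np.exp(eta) / (self.n_background * self.partition_Z)

    def logistic(self, raw_values: Dict[str, np.ndarray]) -> np.ndarray:
        q = self.raw_density(raw_values)
        s = np.exp(self.entropy_H) * q
        return s / (1.0 + s)

    @property
    def source_variables(self) -> List[str]:
        seen: List[str] = []
        for f in self.features:
            for v in f.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "features": [
                {"kind": f.kind, "variables": list(f.variables), "param": f.param}
                for f in self.features
            ],
            "coefficients": self.coefficients.tolist(),
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "variable_kinds": self.variable_kinds,
            "partition_Z": self.partition_Z,
            "entropy_H": self.entropy_H,
            "n_background": self.n_background,
            "gain": self.gain,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "contribution_tally": self.contribution_tally,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "MaxEntModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            features=[
                Feature(f["kind"], tuple(f["variables"]), f["param"])
                for f in p["features"]
            ],
            coefficients=np.asarray(p["coefficients"], dtype=float),
            scaling={k: (v[0], v[1]) for k, v in p["scaling"].items()},
            variable_kinds=p["variable_kinds"],
            partition_Z=p["partition_Z"],
            entropy_H=p["entropy_H"],
            n_background=p["n_background"],
            gain=p["gain"],
            converged=p["converged"],
            n_iterations=p["n_iterations"],
            contribution_tally=p.get("contribution_tally", {}),
        )


@dataclass
class VariableReport:
    pearson_matrix: "np.ndarray"
    variable_names: List[str]
    selected: List[str]
    contributions_pct: Dict[str, float]
    dropped: List[Tuple[str, str, float]] = field(default_factory=list)  # (dropped, vs, r)
    excluded_constant: List[str] = field(default_factory=list)
    jackknife: Optional[Dict[str, Tuple[float, float, float]]] = None


# ---------------------------------------------------------------------------
# Variable screening
# ---------------------------------------------------------------------------

def pearson_screen(
    stack: EnvStack,
    contributions: Optional[Dict[str, float]] = None,
    threshold: float = 0.8,
) -> VariableReport:
    """Drop the lower-contribution member of every |r| >= threshold pair.

    Pairs are resolved in descending |r| order; pairs whose member is
    already dropped are skipped. Pearson r is computed over all
    joint-valid cells. Categorical layers bypass screening and are always
    retained. Constant (zero-variance) layers are excluded with a warning.
    """
    continuous = stack.continuous_names()
    if len(continuous) < 2:
        raise MaxEntError("pearson_screen needs at least two continuous variables")
    mask = stack.joint_valid_mask()
    if not mask.any():
        raise MaxEntError("no joint-valid cells")
    data = {v: stack[v].values[mask] for v in continuous}
    if contributions is None:
        contributions = {v: 1.0 for v in continuous}
    constant = [v for v in continuous if np.std(data[v]) == 0]
    for v in constant:
        warnings.warn(f"variable {v!r} is constant over valid cells; excluded")
    names = [v for v in continuous if v not in constant]
    mat = np.corrcoef(np.array([data[v] for v in names]))
    mat = np.atleast_2d(mat)

    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((abs(mat[i, j]), i, j))
    pairs.sort(key=lambda t: -t[0])
    dropped: Dict[str, Tuple[str, float]] = {}
    for r, i, j in pairs:
        if r < threshold:
            break
        a, b = names[i], names[j]
        if a in dropped or b in dropped:
            continue
        ca = contributions.get(a, 0.0)
        cb = contributions.get(b, 0.0)
        loser, keeper = (a, b) if ca < cb else (b, a)
        dropped[loser] = (keeper, r)
    selected = [v for v in names if v not in dropped]
    selected += stack.categorical_names()
    return VariableReport(
        pearson_matrix=mat,
        variable_names=names,
        selected=selected,
        contributions_pct=dict(contributions),
        dropped=[(lo, vs, r) for lo, (vs, r) in dropped.items()],
        excluded_constant=constant,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _extract_cells(stack: EnvStack, rows: np.ndarray, cols: np.ndarray) -> Dict[str, np.ndarray]:
    return {name: stack[name].values[rows, cols] for name in stack.names}


def _presence_cells(presences: OccurrenceSet, stack: EnvStack) -> Tuple[np.ndarray, np.ndarray]:
    template = stack.template
    mask = stack.joint_valid_mask()
    rows, cols, bad = [], [], []
    for x, y, _tag in presences:
        r, c = template.index_of(x, y)
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            bad.append((x, y))
        else:
            rows.append(r)
            cols.append(c)
    if bad:
        raise MaxEntError(f"presences outside the valid study mask: {bad[:5]}"
                          + (" ..." if len(bad) > 5 else ""))
    return np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)


def _sample_background(
    stack: EnvStack, n_background: int, seed: int,
    presence_rc: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    mask = stack.joint_valid_mask()
    valid_rows, valid_cols = np.nonzero(mask)
    n_valid = valid_rows.size
    rng = np.random.default_rng(seed)
    if n_background >= n_valid:
        idx = np.arange(n_valid)
    else:
        idx = rng.choice(n_valid, size=n_background, replace=False)
    rows, cols = valid_rows[idx], valid_cols[idx]
    if presence_rc is not None:
        # presence cells join the background ("samples added to background")
        flat = set(zip(rows.tolist(), cols.tolist()))
        extra = [(r, c) for r, c in zip(*presence_rc) if (r, c) not in flat]
        if extra:
            er, ec = zip(*extra)
            rows = np.concatenate([rows, np.asarray(er)])
            cols = np.concatenate([cols, np.asarray(ec)])
    return rows, cols


def fit(presences: OccurrenceSet, stack: EnvStack, config: MaxEntConfig) -> MaxEntModel:
    """Fit by cyclic coordinate descent on the regularized gain."""
    if len(presences) < 2:
        raise MaxEntError("need at least two presence points")
    pres_rc = _presence_cells(presences, stack)
    bg_rc = _sample_background(stack, config.n_background, config.seed, pres_rc)
    return _fit_cells(pres_rc, bg_rc, stack, config)


def _fit_cells(
    pres_rc: Tuple[np.ndarray, np.ndarray],
    bg_rc: Tuple[np.ndarray, np.ndarray],
    stack: EnvStack,
    config: MaxEntConfig,
) -> MaxEntModel:
    raw_bg = _extract_cells(stack, *bg_rc)
    raw_pres = _extract_cells(stack, *pres_rc)
    m = pres_rc[0].size
    N = bg_rc[0].size

    kinds = {name: stack[name].kind for name in stack.names}
    scaling: Dict[str, Tuple[float, float]] = {}
    scaled_bg: Dict[str, np.ndarray] = {}
    scaled_pres: Dict[str, np.ndarray] = {}
    for name in stack.names:
        if kinds[name] == "categorical":
            scaling[name] = (0.0, 1.0)
            scaled_bg[name] = raw_bg[name].astype(float)
            scaled_pres[name] = raw_pres[name].astype(float)
        else:
            lo = float(np.min(raw_bg[name]))
            hi = float(np.max(raw_bg[name]))
            scaling[name] = (lo, hi)
            span = hi - lo
            if span > 0:
                scaled_bg[name] = (raw_bg[name] - lo) / span
                scaled_pres[name] = (np.clip(raw_pres[name], lo, hi) - lo) / span
            else:
                scaled_bg[name] = np.zeros(N)
                scaled_pres[name] = np.zeros(m)

    classes = config.resolve_feature_classes(stack)
    features = _build_features(stack, classes, scaled_bg, config.n_hinge_knots)
    if not features:
        raise MaxEntError("no features could be built from the stack")

    F_bg = np.column_stack([f.evaluate(scaled_bg) for f in features])
    F_pres = np.column_stack([f.evaluate(scaled_pres) for f in features])
    sd_bg = F_bg.std(axis=0)
    if not np.any(sd_bg > 0):
        raise MaxEntError("all features are constant over the background")

    # per-feature L1 penalties
    betas = np.empty(len(features))
    for j, feat in enumerate(features):
        base = _beta_base(feat.beta_class, m)
        s = max(float(F_pres[:, j].std()), 0.05)
        betas[j] = config.reg_multiplier * base * s / np.sqrt(m)

    pres_mean = F_pres.mean(axis=0)
    lam = np.zeros(len(features))
    eta_bg = np.zeros(N)

    def log_Z(eta: np.ndarray) -> float:
        return float(logsumexp(eta) - np.log(N))

    def gain_value(lam_vec: np.ndarray, eta: np.ndarray) -> float:
        return float(lam_vec @ pres_mean - log_Z(eta) - betas @ np.abs(lam_vec))

    gain = gain_value(lam, eta_bg)
    gain_path: List[Tuple[int, float]] = []
    active = np.nonzero(sd_bg > 0)[0]
    converged = False
    n_cycles = 0
    penalty = float(betas @ np.abs(lam))
    logZ_cur = log_Z(eta_bg)
    for cycle in range(config.max_iterations):
        cycle_start_gain = gain
        for j in active:
            fj_bg = F_bg[:, j]
            # softmax expectations under the current model
            w = np.exp(eta_bg - (logZ_cur + np.log(N)))
            mu = float(w @ fj_bg)
            var = float(w @ (fj_bg * fj_bg)) - mu * mu
            if var <= 1e-12:
                continue
            # Newton target with L1 soft-threshold, then backtrack on gain
            z = lam[j] + (pres_mean[j] - mu) / var
            t_new = math.copysign(max(abs(z) - betas[j] / var, 0.0), z)
            delta = np.clip(t_new - lam[j], -4.0, 4.0)
            if delta == 0.0:
                continue
            accepted = False
            for _ in range(8):
                cand = lam[j] + delta
                if abs(cand) < 1e-12:
                    cand = 0.0
                new_eta = eta_bg + (cand - lam[j]) * fj_bg
                new_logZ = log_Z(new_eta)
                new_penalty = penalty + betas[j] * (abs(cand) - abs(lam[j]))
                new_gain = (gain + (cand - lam[j]) * pres_mean[j]
                            - (new_logZ - logZ_cur) - (new_penalty - penalty))
                if new_gain > gain:
                    gain_path.append((int(j), new_gain - gain))
                    lam[j] = cand
                    eta_bg = new_eta
                    logZ_cur = new_logZ
                    penalty = new_penalty
                    gain = new_gain
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-14:
                    break
            del accepted
        n_cycles = cycle + 1
        if gain - cycle_start_gain < config.convergence_tol:
            converged = True
            break

    logZ = log_Z(eta_bg)
    log_q = eta_bg - logZ - np.log(N)
    q = np.exp(log_q)
    H = float(-(q * log_q).sum())

    tally: Dict[str, float] = {}
    for j, delta in gain_path:
        var = features[j].source_variable
        tally[var] = tally.get(var, 0.0) + delta

    return MaxEntModel(
        features=features,
        coefficients=lam,
        scaling=scaling,
        variable_kinds=kinds,
        partition_Z=float(np.exp(logZ)),
        entropy_H=H,
        n_background=N,
        gain=gain,
        gain_path=gain_path,
        contribution_tally=tally,
        converged=converged,
        n_iterations=n_cycles,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(model: MaxEntModel, stack: EnvStack, output: str = "logistic") -> GridLayer:
    """Predict over all joint-valid cells of the stack.

    ``raw`` is the Gibbs density normalized over the fitting background;
    ``logistic`` the 0.5-calibrated transform. Out-of-training-range
    values are clamped to the training min/max before feature evaluation.
    """
    missing = [v for v in model.source_variables if v not in stack]
    if missing:
        raise MaxEntError(f"stack is missing model variable(s): {missing}")
    mask = stack.joint_valid_mask()
    rows, cols = np.nonzero(mask)
    raw_values = {v: stack[v].values[rows, cols] for v in model.source_variables}
    if output == "raw":
        scores = model.raw_density(raw_values)
    elif output == "logistic":
        scores = model.logistic(raw_values)
    else:
        raise MaxEntError(f"unknown output {output!r}")
    template = stack.template
    out = np.zeros(template.shape, dtype=float)
    out[rows, cols] = scores
    return GridLayer(out, template.cellsize, template.origin, ~mask,
                     template.crs_tag, "continuous")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auc_score(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outranks random background cell)."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise MaxEntError("AUC needs non-empty presence and background scores")
    ranks = rankdata(np.concatenate([pres, bg]))
    u = ranks[: pres.size].sum() - pres.size * (pres.size + 1) / 2
    return float(u / (pres.size * bg.size))


def evaluate_replicates(
    presences: OccurrenceSet, stack: EnvStack, config: MaxEntConfig
) -> Tuple[float, float, List[dict]]:
    """Seeded random train/test splits; per-replicate fit and test AUC."""
    n = len(presences)
    n_test = int(round(n * config.test_fraction))
    if n_test < 1 or n - n_test < 2:
        raise MaxEntError(
            f"cannot split {n} presences with test fraction {config.test_fraction}"
        )
    mask = stack.joint_valid_mask()
    rng = np.random.default_rng(config.seed)
    per_rep: List[dict] = []
    template = stack.template
    for rep in range(config.n_replicates):
        order = rng.permutation(n)
        test_idx = order[:n_test]
        train_idx = order[n_test:]
        train = OccurrenceSet([presences.points[i] for i in train_idx], presences.crs_tag)
        test = OccurrenceSet([presences.points[i] for i in test_idx], presences.crs_tag)
        rep_config = MaxEntConfig(
            feature_classes=config.feature_classes,
            n_background=config.n_background,
            reg_multiplier=config.reg_multiplier,
            convergence_tol=config.convergence_tol,
            max_iterations=config.max_iterations,
            test_fraction=config.test_fraction,
            n_replicates=1,
            n_hinge_knots=config.n_hinge_knots,
            seed=config.seed + rep + 1,
        )
        model = fit(train, stack, rep_config)
        rows, cols = np.nonzero(mask)
        bg_scores = model.logistic({v: stack[v].values[rows, cols]
                                    for v in model.source_variables})
        t_rc = _presence_cells(test, stack)
        test_scores = model.logistic({v: stack[v].values[t_rc]
                                      for v in model.source_variables})
        auc = auc_score(test_scores, bg_scores)
        per_rep.append({"replicate": rep, "auc": auc, "gain": model.gain,
                        "converged": model.converged})
    aucs = np.array([r["auc"] for r in per_rep])
    return float(aucs.mean()), float(aucs.std(ddof=0)), per_rep


def percent_contribution(model: MaxEntModel) -> Dict[str, float]:
    """Training-path gain attribution, normalized to sum to 100."""
    tally = {v: max(t, 0.0) for v, t in model.contribution_tally.items()}
    for v in model.source_variables:
        tally.setdefault(v, 0.0)
    total = sum(tally.values())
    if total <= 0:
        n = len(tally)
        return {v: 100.0 / n for v in tally}
    return {v: 100.0 * t / total for v, t in tally.items()}


def jackknife(
    presences: OccurrenceSet, stack: EnvStack, config: MaxEntConfig
) -> Dict[str, Tuple[float, float, float]]:
    """Per variable: (gain_with_only, gain_without, auc_with_only).

    Gains are training gains; AUC is the training AUC of the
    single-variable model. With a one-variable stack, ``gain_without`` is
    the null-model gain, 0.
    """
    mask = stack.joint_valid_mask()
    rows, cols = np.nonzero(mask)
    out: Dict[str, Tuple[float, float, float]] = {}
    for var in stack.names:
        only = stack.subset([var])
        model_only = fit(presences, only, config)
        p_rc = _presence_cells(presences, only)
        pres_scores = model_only.logistic({var: only[var].values[p_rc]})
        bg_scores = model_only.logistic({var: only[var].values[rows, cols]})
        auc_only = auc_score(pres_scores, bg_scores)
        rest = [v for v in stack.names if v != var]
        if rest:
            model_without = fit(presences, stack.subset(rest), config)
            gain_without = model_without.gain
        else:
            gain_without = 0.0
        out[var] = (model_only.gain, gain_without, auc_only)
    return out


def response_curve(
    model: MaxEntModel, stack: EnvStack, variable: str, n_points: int = 100
) -> List[Tuple[float, float]]:
    """Marginal response: sweep one variable, others at background
    mean (continuous) or mode (categorical)."""
    if variable not in model.source_variables:
        raise MaxEntError(f"variable {variable!r} is not in the model")
    mask = stack.joint_valid_mask()
    rows, cols = np.nonzero(mask)
    consts: Dict[str, float] = {}
    for v in model.source_variables:
        vals = stack[v].values[rows, cols]
        if model.variable_kinds.get(v) == "categorical":
            codes, counts = np.unique(vals, return_counts=True)
            consts[v] = float(codes[np.argmax(counts)])
        else:
            consts[v] = float(vals.mean())
    if model.variable_kinds.get(variable) == "categorical":
        sweep = np.unique(stack[variable].values[rows, cols]).astype(float)
    else:
        vals = stack[variable].values[rows, cols]
        sweep = np.linspace(float(vals.min()), float(vals.max()), n_points)
    raw_values = {v: np.full(sweep.shape, consts[v]) for v in model.source_variables}
    raw_values[variable] = sweep
    logit = model.logistic(raw_values)
    return [(float(x), float(s)) for x, s in zip(sweep, logit)]
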