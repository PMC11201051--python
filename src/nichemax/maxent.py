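"""Maximum-entropy niche model over background cells.

The model is the Gibbs density ``q(x) = exp(Σ_j λ_j f_j(x)) / Z`` defined
over a finite set of background cells, fitted so that expected feature
values under ``q`` match the presence-sample feature means as closely as
the L1 penalty allows.  The maximised objective is the regularised
training gain

    G(λ) = mean_presence[λ·f] − log Z + log N_bg − Σ_j β_j |λ_j|,

which is 0 for the uniform model and concave in λ.  Optimisation is
cyclic coordinate descent with an exact 1-D line search per coordinate,
so each accepted step increases G and can be credited to the stepped
feature's variable (the bookkeeping behind percent contribution).

Per-feature penalties follow
``β_j = reg_multiplier · β_class(j) · sd_background(f_j) / sqrt(m)``
with m the presence count; at the optimum every free coordinate
satisfies the KKT box condition ``|E_q[f_j] − mean_presence[f_j]| ≤ β_j``,
tight for active features.

Suitability is reported on the logistic scale
``p = e^H q / (1 + e^H q)`` where H is the entropy of the fitted raw
distribution, a monotone transform calibrated so a typical presence
scores about 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grid_io import EnvGrid, GridStack, extract_values
from .occurrence import OccurrenceSet

FEATURE_KINDS = ("linear", "quadratic", "product",
                 "forward_hinge", "reverse_hinge", "threshold")

DEFAULT_FEATURE_CLASSES = frozenset(
    {"linear", "quadratic", "product", "forward_hinge", "reverse_hinge"})

#: class-level L1 penalty scales (multiplied by reg_multiplier and the
#: per-feature background s.d. / sqrt(presences))
BETA_CLASS = {"linear": 0.05, "quadratic": 0.05, "product": 0.05,
              "forward_hinge": 0.5, "reverse_hinge": 0.5, "threshold": 1.0}

_LAMBDA_CAP = 200.0  # |λ| bound; features live in [0,1] so exp stays finite


class DegenerateModelError(ValueError):
    """Model carries no information (zero gain / constant features)."""


@dataclass(frozen=True)
class FeatureDef:
    """One feature of the Gibbs model.

    ``variables`` holds one name (two for products); ``knot`` is the
    hinge/threshold location in the variable's scaled [0,1] range.
    """

    kind: str
    variables: tuple[str, ...]
    knot: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        n_expected = 2 if self.kind == "product" else 1
        if len(self.variables) != n_expected:
            raise ValueError(f"{self.kind} feature needs {n_expected} variable(s)")
        if self.kind == "product" and self.variables[0] == self.variables[1]:
            raise ValueError("product feature needs two distinct variables")
        if self.knot is not None and not (0.0 <= self.knot <= 1.0):
            raise ValueError("knot must lie in [0, 1]")

    @property
    def label(self) -> str:
        k = "" if self.knot is None else f"@{self.knot:.4g}"
        return f"{self.kind}({','.join(self.variables)}){k}"


@dataclass(frozen=True)
class TrainConfig:
    """Fitting configuration; defaults mirror common practice for the method."""

    reg_multiplier: float = 1.0
    background_size: int = 10000
    max_iterations: int = 500
    tolerance: float = 1e-5
    hinge_knots: int = 10
    seed: int = 0
    feature_classes: frozenset = DEFAULT_FEATURE_CLASSES

    def __post_init__(self) -> None:
        if self.background_size < 1 or self.max_iterations < 1 or self.hinge_knots < 1:
            raise ValueError("counts must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.reg_multiplier < 0:
            raise ValueError("reg_multiplier must be non-negative")
        unknown = set(self.feature_classes) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature classes {unknown}")


# ---------------------------------------------------------------------------
# feature space


@dataclass
class FeatureSpace:
    """Variable scaling plus the feature expansion derived from background.

    Variables are mapped to [0,1] with the background min/max; hinge
    knots sit at equal background quantiles (forward hinges at levels
    i/k for i = 0..k−1, reverse at i/k for i = 1..k, so the default
    k = 10 places knots at deciles while excluding each direction's
    degenerate endpoint).
    """

    variables: list[str]
    scaling: dict[str, tuple[float, float]]
    features: list[FeatureDef]

    def scale(self, table: pd.DataFrame, clamp: bool = True) -> dict[str, np.ndarray]:
        scaled = {}
        for v in self.variables:
            if v not in table.columns:
                raise KeyError(f"variable '{v}' missing from input table")
            lo, hi = self.scaling[v]
            x = table[v].to_numpy(dtype=float)
            if clamp:
                x = np.clip(x, lo, hi)
            z = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
            scaled[v] = z
        return scaled

    def evaluate(self, table: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """Feature matrix (rows × features) for raw variable values."""
        z = self.scale(table, clamp=clamp)
        cols = np.empty((len(table), len(self.features)))
        for j, f in enumerate(self.features):
            cols[:, j] = _feature_column(f, z)
        return cols


def _feature_column(f: FeatureDef, z: dict[str, np.ndarray]) -> np.ndarray:
    if f.kind == "linear":
        return z[f.variables[0]]
    if f.kind == "quadratic":
        return z[f.variables[0]] ** 2
    if f.kind == "product":
        return z[f.variables[0]] * z[f.variables[1]]
    x = z[f.variables[0]]
    k = f.knot
    if f.kind == "forward_hinge":
        return np.maximum(0.0, (x - k) / (1.0 - k))
    if f.kind == "reverse_hinge":
        return np.maximum(0.0, (k - x) / k)
    return (x >= k).astype(float)  # threshold


def _hinge_knots(zbg: np.ndarray, n: int, kind: str) -> np.ndarray:
    if kind == "forward_hinge":
        levels = np.arange(0, n) / n          # 0, 1/n, ..., (n-1)/n
    else:
        levels = np.arange(1, n + 1) / n      # 1/n, ..., 1
    knots = np.quantile(zbg, levels)
    if kind == "forward_hinge":
        knots = knots[knots < 1.0]
    else:
        knots = knots[knots > 0.0]
    return np.unique(np.round(knots, 12))


def build_feature_space(background: pd.DataFrame, variables: Sequence[str],
                        config: TrainConfig) -> FeatureSpace:
    """Derive scaling and feature definitions from background values.

    A variable constant on background keeps only its linear feature
    (its weight is irrelevant but the schema stays uniform).
    """
    scaling: dict[str, tuple[float, float]] = {}
    for v in variables:
        col = background[v].to_numpy(dtype=float)
        scaling[v] = (float(np.min(col)), float(np.max(col)))
    classes = config.feature_classes
    feats: list[FeatureDef] = []
    for v in variables:
        lo, hi = scaling[v]
        constant = hi == lo
        if "linear" in classes or constant:
            feats.append(FeatureDef("linear", (v,)))
        if constant:
            continue
        if "quadratic" in classes:
            feats.append(FeatureDef("quadratic", (v,)))
        zbg = (background[v].to_numpy(dtype=float) - lo) / (hi - lo)
        for kind in ("forward_hinge", "reverse_hinge"):
            if kind in classes:
                for k in _hinge_knots(zbg, config.hinge_knots, kind):
                    feats.append(FeatureDef(kind, (v,), float(k)))
        if "threshold" in classes:
            for k in _hinge_knots(zbg, config.hinge_knots, "reverse_hinge"):
                if 0.0 < k < 1.0:
                    feats.append(FeatureDef("threshold", (v,), float(k)))
    if "product" in classes:
        for i, a in enumerate(variables):
            for b in variables[i + 1:]:
                if scaling[a][0] != scaling[a][1] and scaling[b][0] != scaling[b][1]:
                    feats.append(FeatureDef("product", (a, b)))
    return FeatureSpace(list(variables), scaling, feats)


def build_features(stack: GridStack, presence: pd.DataFrame, config: TrainConfig
                   ) -> tuple[FeatureSpace, np.ndarray, np.ndarray, pd.DataFrame]:
    """Sample background and expand features for presences and background.

    Background cells are drawn uniformly without replacement from the
    stack mask with ``config.seed`` (all cells when the mask is small).
    Returns ``(space, F_presence, F_background, background_table)``.
    """
    background = sample_background(stack, config)
    space = build_feature_space(background, stack.names, config)
    return (space, space.evaluate(presence), space.evaluate(background), background)


def sample_background(stack: GridStack, config: TrainConfig) -> pd.DataFrame:
    table = stack.to_table()
    if len(table) > config.background_size:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(len(table), size=config.background_size, replace=False)
        table = table.iloc[np.sort(idx)].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MaxentModel:
    """Fitted weights plus everything needed to predict and project."""

    space: FeatureSpace
    lambdas: np.ndarray
    betas: np.ndarray
    log_partition: float
    entropy_H: float
    gain: float
    gain_trace: list[tuple[int, float]]
    converged: bool
    kkt_violation: float
    n_background: int
    n_presence: int
    variable_credit: dict[str, float]

    @property
    def features(self) -> list[FeatureDef]:
        return self.space.features

    @property
    def variables(self) -> list[str]:
        return self.space.variables

    # -- prediction -------------------------------------------------------
    def predict_raw(self, F: np.ndarray) -> np.ndarray:
        """Raw Gibbs density at feature rows (sums to 1 over training bg)."""
        F = np.asarray(F, dtype=float)
        if F.ndim != 2 or F.shape[1] != len(self.lambdas):
            raise ValueError("feature matrix does not match the model schema")
        return np.exp(F @ self.lambdas - self.log_partition)

    def predict_logistic(self, F: np.ndarray) -> np.ndarray:
        """Logistic suitability p = e^H·q / (1 + e^H·q) ∈ (0, 1)."""
        logit = self.entropy_H + np.asarray(F, dtype=float) @ self.lambdas \
            - self.log_partition
        return 1.0 / (1.0 + np.exp(-logit))

    def score_table(self, table: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        return self.predict_logistic(self.space.evaluate(table, clamp=clamp))

    def project(self, stack: GridStack, clamp: bool = True) -> EnvGrid:
        """Logistic suitability raster over another (or the training) stack.

        Values beyond the training range are clamped to it by default;
        nodata cells stay nodata.
        """
        missing = [v for v in self.variables if v not in stack.layers]
        if missing:
            raise KeyError(f"projection stack lacks variables {missing}")
        table = stack.subset(self.variables).to_table()
        p = self.score_table(table, clamp=clamp)
        header = stack.header
        out = np.full((header.nrows, header.ncols), np.nan)
        out[table["row"].to_numpy(), table["col"].to_numpy()] = p
        return EnvGrid(header, "suitability", out)

    # -- interpretation ---------------------------------------------------
    def percent_contribution(self) -> pd.Series:
        """Share of accumulated training gain credited to each variable.

        Product-feature steps are split 50/50 between the two variables.
        Sums to 100; all-zero (degenerate) models are flagged via
        ``.attrs['degenerate']``.
        """
        credit = pd.Series({v: self.variable_credit.get(v, 0.0)
                            for v in self.variables}).clip(lower=0.0)
        total = credit.sum()
        if total <= 0:
            out = credit * 0.0
            out.attrs["degenerate"] = True
            return out
        out = 100.0 * credit / total
        out.attrs["degenerate"] = False
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variables": self.variables,
            "scaling": {v: list(self.space.scaling[v]) for v in self.variables},
            "features": [{"kind": f.kind, "variables": list(f.variables),
                          "knot": f.knot} for f in self.features],
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "log_partition": self.log_partition,
            "entropy_H": self.entropy_H,
            "gain": self.gain,
            "converged": self.converged,
            "kkt_violation": self.kkt_violation,
            "n_background": self.n_background,
            "n_presence": self.n_presence,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        space = FeatureSpace(
            variables=list(d["variables"]),
            scaling={v: tuple(s) for v, s in d["scaling"].items()},
            features=[FeatureDef(f["kind"], tuple(f["variables"]), f["knot"])
                      for f in d["features"]])
        return cls(space=space, lambdas=np.asarray(d["lambdas"], dtype=float),
                   betas=np.asarray(d["betas"], dtype=float),
                   log_partition=d["log_partition"], entropy_H=d["entropy_H"],
                   gain=d["gain"], gain_trace=[], converged=d["converged"],
                   kkt_violation=d["kkt_violation"],
                   n_background=d["n_background"], n_presence=d["n_presence"],
                   variable_credit={})


def compute_betas(F_bg: np.ndarray, features: Sequence[FeatureDef],
                  n_presence: int, reg_multiplier: float) -> np.ndarray:
    sd = F_bg.std(axis=0)
    cls = np.array([BETA_CLASS[f.kind] for f in features])
    return reg_multiplier * cls * sd / math.sqrt(max(n_presence, 1))


def _coordinate_optimum(base_eta: np.ndarray, f: np.ndarray, fbar: float,
                        beta: float) -> float:
    """Exact 1-D maximiser of the penalised coordinate objective.

    ``base_eta`` is the background linear predictor with this feature's
    term removed.  The smooth part's derivative g(t) = fbar − E_q[f] is
    strictly decreasing (g' = −Var_q[f]), so the optimum is 0 when
    |g(0)| ≤ β and otherwise the unique root of g(t) = ±β on the
    matching side, found by Newton iterations safeguarded by bisection.
    """
    def g_var(t: float) -> tuple[float, float]:
        z = base_eta + t * f
        z = z - z.max()
        w = np.exp(z)
        s = float(w.sum())
        ef = float(w @ f) / s
        ef2 = float(w @ (f * f)) / s
        return fbar - ef, max(ef2 - ef * ef, 1e-12)

    g0, var0 = g_var(0.0)
    if abs(g0) <= beta:
        return 0.0
    sign = 1.0 if g0 > beta else -1.0
    target = sign * beta
    lo, hi = 0.0, None  # h(lo) has sign `sign`; hi (if set) the opposite
    t = g0 - target  # first Newton step from 0 with unit-capped curvature
    t /= var0
    t = float(np.clip(t, -_LAMBDA_CAP, _LAMBDA_CAP))
    for _ in range(60):
        h, var = g_var(t)
        h -= target
        if abs(h) < 1e-12:
            return t
        if sign * h > 0:
            lo = t
        else:
            hi = t
        t_new = t + h / var
        if hi is not None:
            a, b = (lo, hi) if lo < hi else (hi, lo)
            if not a < t_new < b:
                t_new = 0.5 * (lo + hi)
        elif abs(t_new) >= _LAMBDA_CAP:
            h_cap, _ = g_var(sign * _LAMBDA_CAP)
            if sign * (h_cap - target) > 0:
                return sign * _LAMBDA_CAP  # unbounded direction, capped
            hi = sign * _LAMBDA_CAP
            t_new = 0.5 * (lo + hi)
        if abs(t_new - t) < 1e-14:
            return t_new
        t = t_new
    return t


def fit_maxent(F_pres: np.ndarray, F_bg: np.ndarray, space: FeatureSpace,
               config: TrainConfig) -> MaxentModel:
    """Fit the L1-penalised Gibbs model by cyclic coordinate descent.

    Each sweep visits features in construction order, skipping
    coordinates already satisfying their KKT condition at the
    sweep-start gradient, and solves the rest exactly; sweeps repeat
    until the gain stops improving (relative change below
    ``config.tolerance``) or ``max_iterations`` sweeps elapse (the model
    is then returned with ``converged=False`` rather than raising).
    """
    F_pres = np.asarray(F_pres, dtype=float)
    F_bg = np.asarray(F_bg, dtype=float)
    if F_pres.shape[0] < 2:
        raise ValueError("need at least 2 presences")
    if not (np.isfinite(F_pres).all() and np.isfinite(F_bg).all()):
        raise ValueError("non-finite feature values")
    n_bg, J = F_bg.shape
    m = F_pres.shape[0]
    fbar = F_pres.mean(axis=0)
    betas = compute_betas(F_bg, space.features, m, config.reg_multiplier)
    frozen = F_bg.std(axis=0) == 0.0
    logN = math.log(n_bg)

    lam = np.zeros(J)
    eta = np.zeros(n_bg)
    lse = math.log(n_bg)

    def gain_at(lse_val: float) -> float:
        return float(fbar @ lam) - lse_val + logN - float(betas @ np.abs(lam))

    def kkt_violation_of(g_all: np.ndarray) -> float:
        # free coordinates: |g| may not exceed beta; active ones must sit
        # at their subgradient equality g = sign(lambda)*beta
        viol = np.where(lam == 0.0, np.abs(g_all) - betas,
                        np.abs(g_all - np.copysign(betas, lam)))
        viol[frozen] = 0.0
        return float(max(viol.max(initial=0.0), 0.0))

    gain = 0.0
    prev_gain = 0.0
    trace: list[tuple[int, float]] = []
    credit: dict[str, float] = {}
    converged = False
    for sweep in range(config.max_iterations):
        eta = F_bg @ lam  # refresh against incremental drift
        lse = float(logsumexp(eta))
        w = np.exp(eta - lse)
        g_all = fbar - F_bg.T @ w
        gain_before = gain_at(lse)
        if sweep > 0 and (gain_before - prev_gain
                          <= config.tolerance * max(1.0, abs(gain_before))) \
                and kkt_violation_of(g_all) <= config.tolerance:
            gain = gain_before
            converged = True
            break
        prev_gain = gain_before
        for j in range(J):
            if frozen[j]:
                continue
            if lam[j] == 0.0 and abs(g_all[j]) <= betas[j]:
                continue  # KKT-satisfied at sweep start; revisited next sweep
            if lam[j] != 0.0 and abs(
                    g_all[j] - math.copysign(betas[j], lam[j])
            ) <= 0.1 * config.tolerance:
                continue  # active coordinate already at its KKT equality
            f = F_bg[:, j]
            base = eta - lam[j] * f
            new = _coordinate_optimum(base, f, fbar[j], betas[j])
            if new == lam[j]:
                continue
            eta_new = base + new * f
            lse_new = float(logsumexp(eta_new))
            delta = (fbar[j] * (new - lam[j]) - (lse_new - lse)
                     - betas[j] * (abs(new) - abs(lam[j])))
            if delta < -1e-12:  # numerical guard: never descend
                continue
            lam[j] = new
            eta, lse = eta_new, lse_new
            if delta > 0:
                fvars = space.features[j].variables
                for v in fvars:
                    credit[v] = credit.get(v, 0.0) + delta / len(fvars)
                trace.append((j, gain_at(lse)))
        gain = gain_at(lse)

    eta = F_bg @ lam
    logZ = float(logsumexp(eta))
    w = np.exp(eta - logZ)
    entropy = float(-np.sum(w * np.log(np.maximum(w, 1e-300))))
    kkt = float(np.max(np.abs(fbar - F_bg.T @ w) - betas)) if J else 0.0
    return MaxentModel(space=space, lambdas=lam, betas=betas,
                       log_partition=logZ, entropy_H=entropy, gain=gain,
                       gain_trace=trace, converged=converged,
                       kkt_violation=max(kkt, 0.0), n_background=n_bg,
                       n_presence=m, variable_credit=credit)


# ---------------------------------------------------------------------------
# stack-level convenience


@dataclass
class TrainingData:
    """Raw tables and feature matrices behind a fitted model."""

    presence: pd.DataFrame
    background: pd.DataFrame
    space: FeatureSpace
    F_pres: np.ndarray
    F_bg: np.ndarray


def prepare_training(stack: GridStack, occ: OccurrenceSet, config: TrainConfig,
                     variables: Sequence[str] | None = None
                     ) -> TrainingData:
    sub = stack if variables is None else stack.subset(variables)
    presence, rejections = extract_values(sub, occ)
    if len(presence) < 2:
        raise ValueError(
            f"only {len(presence)} presences fall on valid cells "
            f"({len(rejections)} rejected)")
    background = sample_background(sub, config)
    space = build_feature_space(background, sub.names, config)
    return TrainingData(presence, background, space,
                        space.evaluate(presence), space.evaluate(background))


def fit(stack: GridStack, occ: OccurrenceSet, config: TrainConfig,
        variables: Sequence[str] | None = None
        ) -> tuple[MaxentModel, TrainingData]:
    """Extract presences, sample background, expand features, and fit."""
    data = prepare_training(stack, occ, config, variables)
    model = fit_maxent(data.F_pres, data.F_bg, data.space, config)
    return model, data


# ---------------------------------------------------------------------------
# interpretation


def permutation_importance(model: MaxentModel, data: TrainingData,
                           seed: int = 0) -> pd.Series:
    """Training-AUC drop when one variable is shuffled, rescaled to 100.

    Each variable's values are permuted jointly across presence and
    background rows, features rebuilt, and the drop in the training
    presence-vs-background AUC recorded (floored at 0); drops are
    normalised to sum to 100.
    """
    from .evaluation import auc  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    n_p = len(data.presence)
    base_auc = auc(model.predict_logistic(model.space.evaluate(data.presence)),
                   model.predict_logistic(model.space.evaluate(data.background)))
    cols = model.variables
    joint = pd.concat([data.presence[cols], data.background[cols]],
                      ignore_index=True)
    drops = {}
    for v in cols:
        perm = joint.copy()
        perm[v] = rng.permutation(perm[v].to_numpy())
        F = model.space.evaluate(perm)
        scores = model.predict_logistic(F)
        drops[v] = max(0.0, base_auc - auc(scores[:n_p], scores[n_p:]))
    s = pd.Series(drops)
    total = s.sum()
    if total <= 0:
        return s * 0.0
    return 100.0 * s / total


@dataclass
class JackknifeResult:
    """Regularised training gains with each variable isolated or removed."""

    gain_full: float
    with_only: pd.Series
    without: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gain_with_only": self.with_only,
                           "gain_without": self.without})
        df.attrs["gain_full"] = self.gain_full
        return df


def jackknife_gains(stack: GridStack, occ: OccurrenceSet,
                    config: TrainConfig) -> JackknifeResult:
    """Gain with each variable alone and with it left out (same seed)."""
    names = stack.names
    if len(names) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full, _ = fit(stack, occ, config)
    with_only, without = {}, {}
    for v in names:
        try:
            m_only, _ = fit(stack, occ, config, variables=[v])
            with_only[v] = max(m_only.gain, 0.0)
        except Exception as exc:
            raise RuntimeError(f"jackknife with-only fit failed for '{v}'") from exc
        rest = [n for n in names if n != v]
        try:
            m_wo, _ = fit(stack, occ, config, variables=rest)
            without[v] = max(m_wo.gain, 0.0)
        except Exception as exc:
            raise RuntimeError(f"jackknife without fit failed for '{v}'") from exc
    return JackknifeResult(gain_full=max(full.gain, 0.0),
                           with_only=pd.Series(with_only),
                           without=pd.Series(without))


@dataclass
class ResponseCurve:
    """Single-variable model response sampled over the background range."""

    variable: str
    values: np.ndarray       # raw units
    probability: np.ndarray  # logistic suitability

    def optimal_range(self, threshold: float = 0.5
                      ) -> list[tuple[float, float]]:
        return optimal_range(self, threshold)


def response_curve(variable: str, stack: GridStack, occ: OccurrenceSet,
                   config: TrainConfig, n_points: int = 101) -> ResponseCurve:
    """Fit a single-factor model and sample its logistic response.

    The curve spans the background min/max of the variable in raw units
    with at least 100 evenly spaced samples.
    """
    n_points = max(n_points, 100)
    model, data = fit(stack, occ, config, variables=[variable])
    lo, hi = model.space.scaling[variable]
    if hi == lo:
        raise DegenerateModelError(f"variable '{variable}' constant on background")
    xs = np.linspace(lo, hi, n_points)
    p = model.score_table(pd.DataFrame({variable: xs}))
    return ResponseCurve(variable, xs, p)


def optimal_range(curve: ResponseCurve, threshold: float = 0.5
                  ) -> list[tuple[float, float]]:
    """Maximal raw-unit intervals where the response exceeds threshold.

    Interval endpoints between samples are linearly interpolated; a
    curve that never exceeds the threshold yields an empty list.
    """
    x, p = curve.values, curve.probability
    above = p > threshold
    ranges: list[tuple[float, float]] = []
    i = 0
    n = len(x)
    while i < n:
        if not above[i]:
            i += 1
            continue
        # left endpoint
        if i == 0:
            left = x[0]
        else:
            t = (threshold - p[i - 1]) / (p[i] - p[i - 1])
            left = x[i - 1] + t * (x[i] - x[i - 1])
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if j == n - 1:
            right = x[n - 1]
        else:
            t = (p[j] - threshold) / (p[j] - p[j + 1])
            right = x[j] + t * (x[j + 1] - x[j])
        ranges.append((float(left), float(right)))
        i = j + 1
    return ranges
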