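"""Presence-background maximum-entropy suitability model.

The model is the Gibbs distribution q(x) ~ exp(sum_j lambda_j f_j(x)) over
the background cells that maximizes the L1-penalized log-likelihood of the
presence sample:

    max_lambda  (1/m) sum_i eta(x_i)  -  log Z_bg  -  sum_j beta_j |lambda_j|

with eta = sum_j lambda_j f_j, Z_bg the partition sum over background
points, and per-feature penalties beta_j = beta * s_j / sqrt(m) (s_j the
presence-sample standard deviation of feature j, floored at 5% of the
feature's range).  Features are the classic linear / quadratic / hinge
transforms of min-max standardized variables, all mapping into [0, 1].
The "logistic" output p = e^H q / (1 + e^H q) uses the entropy H of the
fitted distribution over the training background as the prevalence
constant, so a completely uninformative model scores 0.5 everywhere.

The objective is concave; it is solved by the bound-constrained split
lambda = lambda+ - lambda- with L-BFGS-B, then polished with proximal
(soft-thresholding) gradient steps until the subgradient optimality
condition holds to ``tol``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import rankdata

from .grids import ClimateStack, Grid
from .occurrences import BackgroundSet, OccurrenceSet

__all__ = [
    "FeatureSet",
    "MaxentModel",
    "EvalReport",
    "FitError",
    "ProjectionError",
    "build_features",
    "fit_maxent",
    "predict_logistic",
    "evaluate_auc",
    "replicate_runs",
]

DEFAULT_CLASSES = ("linear", "quadratic", "hinge")
DEFAULT_HINGE_KNOTS = 16


class FitError(RuntimeError):
    """Optimizer failed to reach the requested gradient tolerance."""


class ProjectionError(KeyError):
    """Projection stack does not supply every model variable."""


@dataclass
class FeatureSet:
    """Feature definitions: classes, per-variable bounds and knot grid."""

    var_names: list[str]
    classes: tuple[str, ...]
    n_hinge_knots: int
    bounds: dict[str, tuple[float, float]]
    feature_index: list[tuple[str, str, float | None]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(DEFAULT_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        if not self.feature_index:
            self.feature_index = self._build_index()

    def _build_index(self) -> list[tuple[str, str, float | None]]:
        index: list[tuple[str, str, float | None]] = []
        for name in self.var_names:
            lo, hi = self.bounds[name]
            if hi <= lo:
                continue  # constant variable: no usable features
            if "linear" in self.classes:
                index.append(("linear", name, None))
            if "quadratic" in self.classes:
                index.append(("quadratic", name, None))
            if "hinge" in self.classes:
                span = hi - lo
                for i in range(self.n_hinge_knots):
                    index.append(("hinge", name, lo + span * i / self.n_hinge_knots))
        return index

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    def transform(self, values: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Design matrix for a (n, n_variables) matrix of raw values."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(self.var_names):
            raise ValueError("values must be (n, n_variables)")
        cols = {n: values[:, i] for i, n in enumerate(self.var_names)}
        if clamp:
            cols = {
                n: np.clip(v, self.bounds[n][0], self.bounds[n][1])
                for n, v in cols.items()
            }
        out = np.empty((values.shape[0], self.n_features))
        for j, (cls, name, knot) in enumerate(self.feature_index):
            lo, hi = self.bounds[name]
            v = cols[name]
            if cls == "linear":
                out[:, j] = (v - lo) / (hi - lo)
            elif cls == "quadratic":
                out[:, j] = ((v - lo) / (hi - lo)) ** 2
            else:  # hinge
                out[:, j] = np.maximum(0.0, (v - knot) / (hi - knot))
        return out


def build_features(
    values: np.ndarray,
    var_names: list[str],
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_hinge_knots: int = DEFAULT_HINGE_KNOTS,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[FeatureSet, np.ndarray]:
    """Derive bounds from the data (unless given) and build the design matrix."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(var_names):
        raise ValueError("values must be (n, n_variables)")
    if bounds is None:
        bounds = {
            n: (float(values[:, i].min()), float(values[:, i].max()))
            for i, n in enumerate(var_names)
        }
    dropped = [n for n in var_names if bounds[n][1] <= bounds[n][0]]
    if dropped:
        warnings.warn(f"constant variable(s) {dropped}: features dropped", stacklevel=2)
    fs = FeatureSet(list(var_names), tuple(classes), n_hinge_knots, dict(bounds), dropped=dropped)
    return fs, fs.transform(values)


@dataclass
class MaxentModel:
    """Fitted maximum-entropy model (coefficients + normalizers)."""

    features: FeatureSet
    lambdas: np.ndarray
    beta: float
    beta_j: np.ndarray
    log_z: float
    entropy: float
    n_presence: int
    n_background: int
    gain: float
    objective_history: list[float] = field(default_factory=list)

    def eta(self, design: np.ndarray) -> np.ndarray:
        return design @ self.lambdas

    def raw(self, design: np.ndarray) -> np.ndarray:
        """Gibbs probability relative to the training background."""
        return np.exp(self.eta(design) - self.log_z)

    def logistic(self, design: np.ndarray) -> np.ndarray:
        return expit(self.entropy + self.eta(design) - self.log_z)

    def predict_values(self, values: np.ndarray, clamp: bool = True) -> np.ndarray:
        return self.logistic(self.features.transform(values, clamp=clamp))

    # -- text serialization (a JSON "lambdas file") --------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "var_names": self.features.var_names,
                "classes": list(self.features.classes),
                "n_hinge_knots": self.features.n_hinge_knots,
                "bounds": {k: list(v) for k, v in self.features.bounds.items()},
                "feature_index": [
                    [cls, name, knot] for cls, name, knot in self.features.feature_index
                ],
                "lambdas": self.lambdas.tolist(),
                "beta": self.beta,
                "beta_j": self.beta_j.tolist(),
                "log_z": self.log_z,
                "entropy": self.entropy,
                "n_presence": self.n_presence,
                "n_background": self.n_background,
                "gain": self.gain,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        fs = FeatureSet(
            d["var_names"],
            tuple(d["classes"]),
            d["n_hinge_knots"],
            {k: tuple(v) for k, v in d["bounds"].items()},
            feature_index=[(c, n, k) for c, n, k in d["feature_index"]],
        )
        return cls(
            features=fs,
            lambdas=np.asarray(d["lambdas"], dtype=float),
            beta=d["beta"],
            beta_j=np.asarray(d["beta_j"], dtype=float),
            log_z=d["log_z"],
            entropy=d["entropy"],
            n_presence=d["n_presence"],
            n_background=d["n_background"],
            gain=d["gain"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        return cls.from_json(Path(path).read_text())


def _objective_parts(lam, pres_f, bg_f):
    """(penalty-free objective value, smooth gradient) at lambda."""
    eta_bg = bg_f @ lam
    log_z = logsumexp(eta_bg)
    q = np.exp(eta_bg - log_z)
    value = float(pres_f.mean(axis=0) @ lam - log_z)
    grad = pres_f.mean(axis=0) - q @ bg_f
    return value, grad, log_z, q


def _l1_quadratic_cd(
    lam_w: np.ndarray,
    grad_w: np.ndarray,
    hess: np.ndarray,
    beta_w: np.ndarray,
    sweeps: int = 1000,
    tol: float = 1e-13,
) -> np.ndarray:
    """Coordinate descent on the local L1-penalized quadratic model.

    Maximizes grad_w^T d - 0.5 d^T H d - sum beta_w |lam_w + d| over the
    step d; returns d.
    """
    z = lam_w.copy()
    hd = np.zeros_like(z)  # H @ (z - lam_w)
    diag = np.diag(hess)
    for _ in range(sweeps):
        delta_max = 0.0
        for j in range(len(z)):
            a = diag[j]
            if a <= 0:
                continue
            # unpenalized 1-D minimizer of the quadratic in z_j
            u = z[j] + (grad_w[j] - hd[j]) / a
            new = np.sign(u) * max(abs(u) - beta_w[j] / a, 0.0)
            step = new - z[j]
            if step != 0.0:
                hd += hess[:, j] * step
                z[j] = new
                delta_max = max(delta_max, abs(step))
        if delta_max <= tol:
            break
    return z - lam_w


def _kkt_violation(grad: np.ndarray, lam: np.ndarray, beta_j: np.ndarray) -> float:
    v = np.where(
        lam == 0.0,
        np.maximum(0.0, np.abs(grad) - beta_j),
        np.abs(grad - beta_j * np.sign(lam)),
    )
    return float(v.max()) if v.size else 0.0


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10000,
    feature_set: FeatureSet | None = None,
) -> MaxentModel:
    """Maximize the L1-penalized presence log-likelihood over the background.

    Raises :class:`FitError` if the subgradient optimality condition is not
    met within ``max_iter`` total iterations.
    """
    pres_f = np.asarray(presence_features, dtype=float)
    bg_f = np.asarray(background_features, dtype=float)
    m, p = pres_f.shape
    if m < 2:
        raise ValueError("need at least 2 presence records")
    if bg_f.shape[0] < 10 * m:
        warnings.warn(
            f"background ({bg_f.shape[0]}) smaller than 10x presences ({m})",
            stacklevel=2,
        )
    # per-feature penalty: presence-sample sd / sqrt(m), floored at 5% of range
    s = pres_f.std(axis=0)
    both = np.vstack([pres_f, bg_f])
    rng_j = both.max(axis=0) - both.min(axis=0)
    s = np.maximum(s, 0.05 * rng_j)
    beta_j = beta * s / np.sqrt(m)

    history: list[float] = []

    def full_objective(lam: np.ndarray) -> float:
        value, *_ = _objective_parts(lam, pres_f, bg_f)
        return value - float(beta_j @ np.abs(lam))

    history.append(full_objective(np.zeros(p)))

    # Stage 1: smooth bound-constrained reformulation lambda = u - v, u,v >= 0
    def neg_obj(uv: np.ndarray):
        lam = uv[:p] - uv[p:]
        value, grad, *_ = _objective_parts(lam, pres_f, bg_f)
        f = -(value) + float(beta_j @ (uv[:p] + uv[p:]))
        g = np.concatenate([-grad + beta_j, grad + beta_j])
        return f, g

    res = minimize(
        neg_obj,
        np.zeros(2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        options={"maxiter": max_iter, "maxfun": 3 * max_iter, "maxcor": 30,
                 "ftol": 1e-18, "gtol": tol * 0.1},
    )
    lam = res.x[:p] - res.x[p:]
    best_obj = full_objective(lam)
    if best_obj < history[-1]:  # never accept a step below the uniform model
        lam = np.zeros(p)
        best_obj = history[-1]
    history.append(best_obj)

    # Stage 2: proximal-Newton polish to the subgradient tolerance.  Each
    # outer step builds the exact Hessian of logZ on a working set (active
    # coefficients plus worst violators), solves the resulting L1 quadratic
    # subproblem by coordinate descent, and line-searches the full objective
    # so the accepted history stays monotone.
    for _outer in range(100):
        value, grad, log_z, q = _objective_parts(lam, pres_f, bg_f)
        viol = np.where(
            lam == 0.0,
            np.maximum(0.0, np.abs(grad) - beta_j),
            np.abs(grad - beta_j * np.sign(lam)),
        )
        if (viol.max() if viol.size else 0.0) <= tol:
            break
        work = np.flatnonzero((lam != 0.0) | (viol > tol / 10))
        if work.size > 300:
            work = work[np.argsort(viol[work])[::-1][:300]]
        bw = bg_f[:, work]
        qb = q @ bw
        hess = bw.T @ (bw * q[:, None]) - np.outer(qb, qb)
        hess[np.diag_indices_from(hess)] += 1e-10
        d = _l1_quadratic_cd(lam[work], grad[work], hess, beta_j[work])
        if not np.any(d):
            break
        slack = 1e-11 * (1.0 + abs(best_obj))
        alpha = 1.0
        for _bt in range(60):
            cand = lam.copy()
            cand[work] = lam[work] + alpha * d
            cand_obj = full_objective(cand)
            if cand_obj >= best_obj - slack:
                lam = cand
                best_obj = max(best_obj, cand_obj)
                history.append(best_obj)
                break
            alpha *= 0.5
        else:
            break
    value, grad, log_z, q = _objective_parts(lam, pres_f, bg_f)
    if _kkt_violation(grad, lam, beta_j) > tol:
        raise FitError(
            f"no convergence to tol={tol} in {max_iter} iterations "
            f"(last objective {best_obj:.10g})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-(q * np.where(q > 0, np.log(q), 0.0)).sum())
    gain = best_obj - history[0]  # improvement over the uniform model
    if feature_set is None:
        feature_set = FeatureSet(
            [f"f{i}" for i in range(p)],
            ("linear",),
            0,
            {f"f{i}": (0.0, 1.0) for i in range(p)},
            feature_index=[("linear", f"f{i}", None) for i in range(p)],
        )
    return MaxentModel(
        features=feature_set,
        lambdas=lam,
        beta=beta,
        beta_j=beta_j,
        log_z=float(log_z),
        entropy=entropy,
        n_presence=m,
        n_background=bg_f.shape[0],
        gain=float(gain),
        objective_history=history,
    )


def predict_logistic(model: MaxentModel, stack: ClimateStack, clamp: bool = True) -> Grid:
    """Project the model onto a climate stack as a logistic-output grid.

    With ``clamp`` on (the default, and the right choice when transferring
    to other periods), variable values are truncated to the training bounds
    before feature evaluation.
    """
    missing = [n for n in model.features.var_names if n not in stack.variables]
    if missing:
        raise ProjectionError(f"stack {stack.period_label!r} lacks variable(s) {missing}")
    mask = stack.mask
    values = stack.values_matrix(model.features.var_names)
    p = model.predict_values(values, clamp=clamp)
    out = np.full(mask.shape, np.nan)
    out[~mask] = p
    return stack.template.like(out, mask.copy())


def evaluate_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based AUC: P(presence outranks background), ties counted 1/2."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


@dataclass
class EvalReport:
    """Replicate train/test AUC summary."""

    replicates: pd.DataFrame  # columns: replicate, n_train, n_test, train_auc, test_auc
    mean_train_auc: float
    mean_test_auc: float
    n_replicates: int
    train_fraction: float
    seed: int

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.replicates.to_csv(path, index=False)


def replicate_runs(
    occ: OccurrenceSet,
    background: BackgroundSet,
    stack: ClimateStack,
    k: int = 10,
    train_fraction: float = 0.75,
    beta: float = 1.0,
    seed: int = 0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_hinge_knots: int = DEFAULT_HINGE_KNOTS,
) -> tuple[EvalReport, MaxentModel]:
    """k random 75/25-style presence splits + a final all-presence refit.

    The test partition gets floor((1 - train_fraction) * m) records and the
    remainder trains.  AUC is reported per replicate (train and test,
    presences against the shared background).  The returned model, used for
    mapping, is refit on all presences.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    m = len(occ)
    names = stack.names
    pres_vals = stack.values_at(occ.xy[:, 0], occ.xy[:, 1], names)
    bg_vals = stack.values_at(background.xy[:, 0], background.xy[:, 1], names)
    n_test = int(np.floor((1 - train_fraction) * m))
    n_train = m - n_test
    if n_train < 2:
        raise ValueError(f"training split of {n_train} presences is too small")
    rows = []
    for r in range(k):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        perm = rng.permutation(m)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        fs, bg_design = build_features(
            bg_vals, names, classes, n_hinge_knots,
            bounds=_joint_bounds(pres_vals[train_idx], bg_vals, names),
        )
        model = fit_maxent(
            fs.transform(pres_vals[train_idx]), bg_design, beta=beta, feature_set=fs
        )
        bg_scores = model.eta(bg_design)
        train_auc = evaluate_auc(model.eta(fs.transform(pres_vals[train_idx])), bg_scores)
        test_auc = (
            evaluate_auc(model.eta(fs.transform(pres_vals[test_idx], clamp=True)), bg_scores)
            if n_test
            else np.nan
        )
        rows.append(
            {"replicate": r, "n_train": n_train, "n_test": n_test,
             "train_auc": train_auc, "test_auc": test_auc}
        )
    df = pd.DataFrame(rows)
    fs, bg_design = build_features(
        bg_vals, names, classes, n_hinge_knots,
        bounds=_joint_bounds(pres_vals, bg_vals, names),
    )
    final = fit_maxent(fs.transform(pres_vals), bg_design, beta=beta, feature_set=fs)
    report = EvalReport(
        replicates=df,
        mean_train_auc=float(df["train_auc"].mean()),
        mean_test_auc=float(df["test_auc"].mean()),
        n_replicates=k,
        train_fraction=train_fraction,
        seed=seed,
    )
    return report, final


def _joint_bounds(pres_vals: np.ndarray, bg_vals: np.ndarray, names: list[str]):
    both = np.vstack([pres_vals, bg_vals])
    return {n: (float(both[:, i].min()), float(both[:, i].max())) for i, n in enumerate(names)}
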