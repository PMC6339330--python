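"""Automatic filter-parameter selection.

Two ingredients: a brute-force grid search for the PSNR-optimal filter
parameters (the training target and the reference optimum), and a two-stage
feed-forward network system — stage 1 classifies the noise level into
{low, median, high}, stage 2 holds one per-class regressor that predicts the
continuous filter parameters.  Both stages are single-hidden-layer networks
with hyperbolic-tangent hidden units and linear outputs, trained by
Levenberg-Marquardt damped Gauss-Newton on sum-of-squared error with early
stopping on a held-out split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .collateral_filter import FilterParams, _filter_core, _prepare, blend_image
from .image import Image2D
from .quality_metrics import psnr, relative_error

__all__ = [
    "ParameterGrid",
    "TrainingSample",
    "TwoStageModel",
    "AutomationReport",
    "TinyNetwork",
    "lm_minimize",
    "brute_force_optimize",
    "build_training_samples",
    "train_two_stage",
    "predict_parameters",
    "evaluate_automation",
    "DEFAULT_FEATURES",
]

CLASS_NAMES = ("low", "median", "high")

#: Working feature subset used by default for automation.
DEFAULT_FEATURES = ("RLN_0", "RP_135", "RP_90", "AJA", "kurtosis")

PARAM_NAMES = ("sigma_s", "sigma_r", "sigma_m", "beta")


@dataclass
class ParameterGrid:
    """Axes of the brute-force search; the window radius stays fixed."""

    sigma_s: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    sigma_r: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)  # x MAX_I
    sigma_m: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)  # x MAX_I
    beta: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    radius: int = 1

    def points(self, max_intensity: float = 1.0):
        """Yield every grid point as a FilterParams, in axis-major order."""
        for ss, sr, sm, b in product(self.sigma_s, self.sigma_r, self.sigma_m, self.beta):
            yield FilterParams(radius=self.radius, sigma_s=ss,
                               sigma_r=sr * max_intensity, sigma_m=sm * max_intensity,
                               beta=b, beta_mode="scalar")

    def bounds(self, max_intensity: float = 1.0) -> dict[str, tuple[float, float]]:
        """Axis-aligned hull used to clip network predictions."""
        return {
            "sigma_s": (min(self.sigma_s), max(self.sigma_s)),
            "sigma_r": (min(self.sigma_r) * max_intensity, max(self.sigma_r) * max_intensity),
            "sigma_m": (min(self.sigma_m) * max_intensity, max(self.sigma_m) * max_intensity),
            "beta": (min(self.beta), max(self.beta)),
        }


def brute_force_optimize(noisy: Image2D, clean: Image2D,
                         grid: ParameterGrid | None = None) -> tuple[FilterParams, float]:
    """Filter with every grid point and return the PSNR-argmax parameters.

    Ties are broken by first occurrence in grid order.  The median image,
    agreement map and entropy map depend only on the image and radius, so
    they are computed once and shared across the grid.
    """
    if grid is None:
        grid = ParameterGrid()
    if noisy.shape != clean.shape:
        raise ValueError("noisy and clean images must share shape")
    points = list(grid.points(noisy.max_intensity))
    if not points:
        raise ValueError("grid is empty")
    med, p, entropy = _prepare(noisy, points[0])
    best_params, best_psnr = None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # inf PSNR is a valid optimum
        for params in points:
            blend = blend_image(noisy, med, params, p_map=p)
            restored = noisy.like(_filter_core(noisy, med, entropy, blend, params))
            score = psnr(clean, restored)
            if score > best_psnr:
                best_params, best_psnr = params, score
    return best_params, float(best_psnr)


# ------------------------------------------------------------------ networks

def lm_minimize(residual_jacobian, theta0: np.ndarray, max_iter: int = 200,
                lam0: float = 1e-3, grad_tol: float = 1e-8,
                on_accept=None) -> tuple[np.ndarray, list[float]]:
    """Levenberg-Marquardt damped Gauss-Newton on a sum-of-squares objective.

    ``residual_jacobian(theta)`` returns ``(residuals, jacobian)``.  The
    damping factor starts at ``lam0``, is divided by 10 after an accepted
    step and multiplied by 10 after a rejected one; iteration stops at
    ``max_iter``, when the gradient infinity-norm drops below ``grad_tol``,
    when no step can be accepted, or when ``on_accept(theta, sse)`` returns
    False (the early-stopping hook).
    """
    theta = np.asarray(theta0, dtype=np.float64).copy()
    resid, jac = residual_jacobian(theta)
    sse = float(resid @ resid)
    lam = lam0
    history: list[float] = []
    for _ in range(max_iter):
        grad = jac.T @ resid
        if np.max(np.abs(grad)) < grad_tol:
            break
        jtj = jac.T @ jac
        accepted = False
        for _ in range(30):
            try:
                step = np.linalg.solve(jtj + lam * np.eye(len(theta)), grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = theta - step
            trial_resid, trial_jac = residual_jacobian(trial)
            trial_sse = float(trial_resid @ trial_resid)
            if trial_sse < sse:
                theta, sse = trial, trial_sse
                resid, jac = trial_resid, trial_jac
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        history.append(sse)
        if on_accept is not None and on_accept(theta, sse) is False:
            break
    return theta, history


class TinyNetwork:
    """Single-hidden-layer tanh network with linear outputs, trained by LM."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_hidden, n_in))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=(n_out, n_hidden))
        self.b2 = np.zeros(n_out)

    # -- parameter vector packing -------------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    def set_params(self, theta: np.ndarray) -> None:
        h, d = self.w1.shape
        o = self.w2.shape[0]
        idx = 0
        self.w1 = theta[idx : idx + h * d].reshape(h, d); idx += h * d
        self.b1 = theta[idx : idx + h].copy(); idx += h
        self.w2 = theta[idx : idx + o * h].reshape(o, h); idx += o * h
        self.b2 = theta[idx : idx + o].copy()

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.tanh(x @ self.w1.T + self.b1)
        return a @ self.w2.T + self.b2

    def _jacobian(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Residual Jacobian d(y_pred)/d(theta), stacked sample-major.

        Returns (predictions, J) with J of shape (n*o, P).
        """
        n, d = x.shape
        h = self.w1.shape[0]
        o = self.w2.shape[0]
        a = np.tanh(x @ self.w1.T + self.b1)       # (n, h)
        y = a @ self.w2.T + self.b2                 # (n, o)
        da = 1.0 - a**2                             # (n, h)
        p_total = h * d + h + o * h + o
        jac = np.zeros((n, o, p_total))
        # dy_k/dW1_{ji} = w2[k, j] * da[:, j] * x[:, i]
        g = self.w2[None, :, :] * da[:, None, :]    # (n, o, h)
        jac[:, :, : h * d] = (g[:, :, :, None] * x[:, None, None, :]).reshape(n, o, h * d)
        jac[:, :, h * d : h * d + h] = g
        idx = h * d + h
        jac[:, :, idx : idx + o * h] = np.einsum(
            "nh,ko->nkoh", a, np.eye(o)
        ).reshape(n, o, o * h)
        idx += o * h
        jac[:, :, idx :] = np.eye(o)[None, :, :]
        return y, jac.reshape(n * o, p_total)

    def fit_lm(self, x: np.ndarray, y: np.ndarray,
               x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
               max_iter: int = 200, lam0: float = 1e-3, grad_tol: float = 1e-8,
               patience: int = 25) -> dict:
        """Levenberg-Marquardt on SSE with multiplicative damping control.

        Delegates to :func:`lm_minimize`; when a validation set is given the
        weights with the lowest validation SSE are restored at the end
        (early stopping with the given patience).
        """
        state = {"best_val": np.inf, "best_theta": None, "stall": 0}

        def residual_jacobian(theta):
            self.set_params(theta)
            pred, jac = self._jacobian(x)
            return (pred - y).ravel(), jac

        def on_accept(theta, sse):
            if x_val is None or not len(x_val):
                return True
            self.set_params(theta)
            val_sse = float(np.sum((self.forward(x_val) - y_val) ** 2))
            if val_sse < state["best_val"] - 1e-12:
                state["best_val"] = val_sse
                state["best_theta"] = theta.copy()
                state["stall"] = 0
            else:
                state["stall"] += 1
                if state["stall"] >= patience:
                    return False
            return True

        theta, history = lm_minimize(residual_jacobian, self.get_params(),
                                     max_iter=max_iter, lam0=lam0, grad_tol=grad_tol,
                                     on_accept=on_accept)
        if state["best_theta"] is not None:
            theta = state["best_theta"]
        self.set_params(theta)
        sse = float(np.sum((self.forward(x) - y) ** 2))
        return {"sse": sse, "iterations": len(history), "history": history}

    def to_dict(self) -> dict:
        return {"w1": self.w1.tolist(), "b1": self.b1.tolist(),
                "w2": self.w2.tolist(), "b2": self.b2.tolist()}

    @classmethod
    def from_dict(cls, data: dict) -> "TinyNetwork":
        net = cls.__new__(cls)
        net.w1 = np.asarray(data["w1"], dtype=np.float64)
        net.b1 = np.asarray(data["b1"], dtype=np.float64)
        net.w2 = np.asarray(data["w2"], dtype=np.float64)
        net.b2 = np.asarray(data["b2"], dtype=np.float64)
        return net


# ------------------------------------------------------------------- samples

@dataclass
class TrainingSample:
    """Selected features, noise class and brute-force optimum for one image."""

    features: dict[str, float]
    noise_class: str
    optimal_params: FilterParams
    psnr_t: float
    anatomy_id: int = 0


@dataclass
class AutomationReport:
    """Predicted vs brute-force restoration scores for one image."""

    psnr_a: float
    psnr_t: float
    epsilon_r: float
    predicted_params: FilterParams
    optimal_params: FilterParams
    noise_class: str


@dataclass
class TwoStageModel:
    """Stage-1 noise-class classifier plus per-class parameter regressors."""

    feature_names: list[str]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    stage1: TinyNetwork
    stage2: dict[str, TinyNetwork]
    target_mean: dict[str, np.ndarray]
    target_scale: dict[str, np.ndarray]
    bounds: dict[str, tuple[float, float]]
    radius: int = 1
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "stage1": self.stage1.to_dict(),
            "stage2": {k: v.to_dict() for k, v in self.stage2.items()},
            "target_mean": {k: v.tolist() for k, v in self.target_mean.items()},
            "target_scale": {k: v.tolist() for k, v in self.target_scale.items()},
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "radius": self.radius,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TwoStageModel":
        return cls(
            feature_names=list(data["feature_names"]),
            feature_mean=np.asarray(data["feature_mean"], dtype=np.float64),
            feature_scale=np.asarray(data["feature_scale"], dtype=np.float64),
            stage1=TinyNetwork.from_dict(data["stage1"]),
            stage2={k: TinyNetwork.from_dict(v) for k, v in data["stage2"].items()},
            target_mean={k: np.asarray(v, dtype=np.float64) for k, v in data["target_mean"].items()},
            target_scale={k: np.asarray(v, dtype=np.float64) for k, v in data["target_scale"].items()},
            bounds={k: (float(v[0]), float(v[1])) for k, v in data["bounds"].items()},
            radius=int(data.get("radius", 1)),
            metadata=data.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TwoStageModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # convenience -----------------------------------------------------------
    def _vectorize(self, features: dict[str, float]) -> np.ndarray:
        missing = [n for n in self.feature_names if n not in features]
        if missing:
            raise KeyError(f"missing feature(s): {missing}")
        x = np.array([features[n] for n in self.feature_names], dtype=np.float64)
        return (x - self.feature_mean) / self.feature_scale


def build_training_samples(pairs, labels, grid: ParameterGrid | None = None,
                           feature_subset: Sequence[str] = DEFAULT_FEATURES):
    """Brute-force each phantom pair and extract its working features."""
    from .texture_features import feature_bank

    grid = grid or ParameterGrid()
    samples = []
    for pair, (_, row) in zip(pairs, labels.iterrows()):
        params, score = brute_force_optimize(pair.noisy, pair.clean, grid)
        feats = feature_bank(pair.noisy, subset=list(feature_subset))
        samples.append(TrainingSample(
            features=feats, noise_class=row["noise_class"],
            optimal_params=params, psnr_t=score,
            anatomy_id=int(row["anatomy_id"]),
        ))
    return samples


def _targets(sample: TrainingSample) -> np.ndarray:
    p = sample.optimal_params
    return np.array([p.sigma_s, p.sigma_r, p.sigma_m, p.beta], dtype=np.float64)


def train_two_stage(samples: Sequence[TrainingSample], grid: ParameterGrid | None = None,
                    n_hidden: int = 10, seed: int = 0, max_iter: int = 200,
                    min_per_class: int = 30, val_fraction: float = 0.25,
                    max_intensity: float = 1.0) -> TwoStageModel:
    """Train stage-1 classifier and per-class stage-2 regressors.

    Features are z-normalized with training statistics; regression targets
    are z-normalized per class.  Every source of randomness derives from
    ``seed``.
    """
    grid = grid or ParameterGrid()
    counts = {c: sum(s.noise_class == c for s in samples) for c in CLASS_NAMES}
    for cls, cnt in counts.items():
        if cnt < min_per_class:
            raise ValueError(
                f"noise class {cls!r} has only {cnt} samples (< {min_per_class})"
            )

    feature_names = sorted(samples[0].features)
    x = np.array([[s.features[n] for n in feature_names] for s in samples])
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xz = (x - mean) / scale
    y_cls = np.array([CLASS_NAMES.index(s.noise_class) for s in samples])
    onehot = -np.ones((len(samples), len(CLASS_NAMES)))
    onehot[np.arange(len(samples)), y_cls] = 1.0

    rng = np.random.default_rng(seed)

    def split(n_items: int, r: np.random.Generator):
        order = r.permutation(n_items)
        n_val = max(1, int(round(val_fraction * n_items)))
        return order[n_val:], order[:n_val]

    tr, va = split(len(samples), rng)
    stage1 = TinyNetwork(len(feature_names), n_hidden, len(CLASS_NAMES), rng)
    s1_fit = stage1.fit_lm(xz[tr], onehot[tr], xz[va], onehot[va], max_iter=max_iter)

    stage2: dict[str, TinyNetwork] = {}
    t_mean: dict[str, np.ndarray] = {}
    t_scale: dict[str, np.ndarray] = {}
    curves = {"stage1": s1_fit["history"]}
    for ci, cls in enumerate(CLASS_NAMES):
        idx = np.flatnonzero(y_cls == ci)
        targets = np.array([_targets(samples[i]) for i in idx])
        tm = targets.mean(axis=0)
        ts = targets.std(axis=0)
        ts[ts == 0] = 1.0
        tz = (targets - tm) / ts
        tr_c, va_c = split(len(idx), rng)
        net = TinyNetwork(len(feature_names), n_hidden, len(PARAM_NAMES), rng)
        fit = net.fit_lm(xz[idx][tr_c], tz[tr_c], xz[idx][va_c], tz[va_c],
                         max_iter=max_iter)
        stage2[cls] = net
        t_mean[cls] = tm
        t_scale[cls] = ts
        curves[f"stage2_{cls}"] = fit["history"]

    return TwoStageModel(
        feature_names=feature_names, feature_mean=mean, feature_scale=scale,
        stage1=stage1, stage2=stage2, target_mean=t_mean, target_scale=t_scale,
        bounds=grid.bounds(max_intensity), radius=grid.radius,
        metadata={"seed": seed, "n_hidden": n_hidden, "n_samples": len(samples),
                  "class_counts": counts, "training_curves": curves},
    )


def predict_parameters(model: TwoStageModel, features: dict[str, float]) -> tuple[str, FilterParams]:
    """Stage-1 class, then that class's stage-2 regressor, clipped to the grid hull."""
    xz = model._vectorize(features)[None, :]
    cls = CLASS_NAMES[int(np.argmax(model.stage1.forward(xz)[0]))]
    raw = model.stage2[cls].forward(xz)[0] * model.target_scale[cls] + model.target_mean[cls]
    clipped = {}
    for name, value in zip(PARAM_NAMES, raw):
        lo, hi = model.bounds[name]
        clipped[name] = float(np.clip(value, lo, hi))
    params = FilterParams(radius=model.radius, beta_mode="scalar", **clipped)
    params.validate()
    return cls, params


def evaluate_automation(model: TwoStageModel, noisy: Image2D, clean: Image2D,
                        grid: ParameterGrid | None = None,
                        features: dict[str, float] | None = None) -> AutomationReport:
    """Compare the predicted parameters against the brute-force grid optimum."""
    from .collateral_filter import filter_tiled
    from .texture_features import feature_bank

    grid = grid or ParameterGrid()
    if features is None:
        features = feature_bank(noisy, subset=list(model.feature_names))
    cls, predicted = predict_parameters(model, features)
    restored = filter_tiled(noisy, predicted)
    psnr_a = psnr(clean, restored)
    optimal, psnr_t = brute_force_optimize(noisy, clean, grid)
    return AutomationReport(
        psnr_a=float(psnr_a), psnr_t=float(psnr_t),
        epsilon_r=relative_error(psnr_t, psnr_a),
        predicted_params=predicted, optimal_params=optimal, noise_class=cls,
    )
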