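"""Three-component Gaussian mixture clustering of normalized (ADC, SUV) voxels.

The mixture is fitted by expectation-maximization written out in full:
responsibilities via log-sum-exp in the E-step, weighted moment updates in
the M-step, a covariance eigenvalue floor against degenerate components, and
the best of several seeded restarts kept.  For 1D fits the pairwise
intersection abscissae of adjacent weighted component densities serve as
demarcation thresholds that segment the axis into subregions; in 2D voxels
are assigned to the maximum-responsibility component.

Fitted components are relabeled to the semantic names ``vital`` /
``equivocal`` / ``low_vital`` from their normalized means, so downstream
reporting is invariant to the arbitrary component order EM converges to.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .stats import pearson
from .voxels import VoxelTable

logger = logging.getLogger(__name__)

CLUSTER_NAMES = ("vital", "equivocal", "low_vital")

_COV_FLOOR = 1e-6
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GaussianComponent:
    """One weighted Gaussian: weight in (0, 1], mean vector, covariance matrix."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, dtype=float)))
        object.__setattr__(self, "cov", np.atleast_2d(np.asarray(self.cov, dtype=float)))
        if not 0 < self.weight <= 1:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean dimension")
        eigvals = np.linalg.eigvalsh(self.cov)
        if eigvals.min() <= 0:
            raise ValueError("covariance must be positive-definite")

    @property
    def ndim(self) -> int:
        return self.mean.size

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Weighted log density log(w * N(x; mean, cov)) at rows of ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = self.ndim
        chol = np.linalg.cholesky(self.cov)
        diff = x - self.mean
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return np.log(self.weight) - 0.5 * (d * _LOG2PI + logdet + maha)


@dataclass
class MixtureModel:
    """Fitted mixture: exactly k components plus diagnostics and thresholds."""

    components: list[GaussianComponent]
    ndim: int
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    demarcation: list[float] | None = None  # 1D only

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"component weights must sum to 1, got {total}")
        if any(c.ndim != self.ndim for c in self.components):
            raise ValueError("component dimensionality mismatch")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def final_log_likelihood(self) -> float:
        return self.log_likelihoods[-1] if self.log_likelihoods else float("nan")

    def log_responsibilities(self, x: np.ndarray) -> np.ndarray:
        lw = np.column_stack([c.log_density(x) for c in self.components])
        return lw - logsumexp(lw, axis=1, keepdims=True)

    def total_log_likelihood(self, x: np.ndarray) -> float:
        lw = np.column_stack([c.log_density(x) for c in self.components])
        return float(logsumexp(lw, axis=1).sum())

    def to_json(self, path=None) -> str:
        payload = {
            "ndim": self.ndim,
            "components": [
                {"weight": c.weight, "mean": c.mean.tolist(), "cov": c.cov.tolist()}
                for c in self.components
            ],
            "demarcation": self.demarcation,
            "diagnostics": {
                "final_log_likelihood": self.final_log_likelihood,
                "n_iter": self.n_iter,
                "converged": self.converged,
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _floor_cov(cov: np.ndarray, floor: float = _COV_FLOOR) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++ center selection (distance-weighted sampling)."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            np.stack([np.sum((x - c) ** 2, axis=1) for c in centers]), axis=0
        )
        total = d2.sum()
        if total <= 0:  # all points coincide with a center
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.stack(centers)


def _init_params(x: np.ndarray, k: int, rng: np.random.Generator):
    """k-means++ seeding followed by one hard-assignment moment step."""
    n, d = x.shape
    centers = _kmeanspp_centers(x, k, rng)
    dist = np.stack([np.sum((x - c) ** 2, axis=1) for c in centers])
    assign = np.argmin(dist, axis=0)
    weights = np.empty(k)
    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    global_cov = _floor_cov(np.atleast_2d(np.cov(x.T)) if n > 1 else np.eye(d))
    for j in range(k):
        pts = x[assign == j]
        weights[j] = max(len(pts), 1) / n
        if len(pts) == 0:
            means[j] = centers[j]
            covs[j] = global_cov
        else:
            means[j] = pts.mean(axis=0)
            covs[j] = _floor_cov(np.cov(pts.T, bias=True).reshape(d, d)) if len(pts) > 1 else global_cov
    weights /= weights.sum()
    return weights, means, covs


def _em_single(x, k, rng, tol, max_iter, cov_floor):
    n, d = x.shape
    weights, means, covs = _init_params(x, k, rng)
    lls: list[float] = []
    converged = False
    for it in range(max_iter):
        comps = [GaussianComponent(weights[j], means[j], covs[j]) for j in range(k)]
        lw = np.column_stack([c.log_density(x) for c in comps])
        norm = logsumexp(lw, axis=1)
        ll = float(norm.sum())
        lls.append(ll)
        if len(lls) > 1:
            prev = lls[-2]
            if abs(ll - prev) < tol * max(abs(prev), 1.0):
                converged = True
                break
        resp = np.exp(lw - norm[:, None])  # (n, k)
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        for j in range(k):
            diff = x - means[j]
            covs[j] = _floor_cov((resp[:, j][:, None] * diff).T @ diff / nk[j], cov_floor)
    comps = [GaussianComponent(weights[j], means[j], covs[j]) for j in range(k)]
    return comps, lls, converged


def fit_gmm(
    data: np.ndarray,
    k: int = 3,
    seed: int | np.random.Generator | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 5,
    cov_floor: float = _COV_FLOOR,
) -> MixtureModel:
    """Fit a k-component Gaussian mixture by EM; best of ``n_init`` restarts.

    ``data`` is (n,) or (n, d) with d in {1, 2}; values must be finite and
    n >= 10 k.  In 1D the returned components are sorted by mean and the
    demarcation thresholds are attached.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("data must be 1D or 2D")
    n, d = x.shape
    if not np.isfinite(x).all():
        raise ValueError("data contains non-finite values")
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} points to fit k={k}, got {n}")
    if np.allclose(x, x[0]):
        raise ValueError("all data points identical; mixture is undefined")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        comps, lls, converged = _em_single(x, k, rng, tol, max_iter, cov_floor)
        if best is None or lls[-1] > best[1][-1]:
            best = (comps, lls, converged)
    comps, lls, converged = best
    if not converged:
        logger.warning("fit_gmm: EM did not converge within %d iterations", max_iter)

    model = MixtureModel(
        components=comps, ndim=d, log_likelihoods=lls, converged=converged,
        n_iter=len(lls),
    )
    if d == 1:
        model.components = sorted(comps, key=lambda c: float(c.mean[0]))
        model.demarcation = demarcation_thresholds(model)
    return model


def gaussian_intersections(c1: GaussianComponent, c2: GaussianComponent) -> list[float]:
    """Abscissae where two weighted 1D Gaussian densities intersect (0-2 roots).

    Setting the weighted log densities equal yields a quadratic in x; its real
    roots are returned sorted ascending.  Identical components are rejected
    (infinitely many intersections).
    """
    if c1.ndim != 1 or c2.ndim != 1:
        raise ValueError("intersections are defined for 1D components only")
    m1, m2 = float(c1.mean[0]), float(c2.mean[0])
    v1, v2 = float(c1.cov[0, 0]), float(c2.cov[0, 0])
    lw1 = np.log(c1.weight) - 0.5 * np.log(v1)
    lw2 = np.log(c2.weight) - 0.5 * np.log(v2)

    a = 0.5 * (1.0 / v2 - 1.0 / v1)
    b = m1 / v1 - m2 / v2
    c = 0.5 * (m2**2 / v2 - m1**2 / v1) + lw1 - lw2

    if abs(a) < 1e-300:  # equal variances: the quadratic degenerates to a line
        if abs(b) < 1e-300:
            raise ValueError("identical components: infinitely many intersections")
        return [-c / b]
    disc = b * b - 4 * a * c
    if disc < 0:
        return []
    sq = float(np.sqrt(disc))
    roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    if abs(roots[0] - roots[1]) < 1e-12:
        return [roots[0]]
    return list(roots)


def demarcation_thresholds(model: MixtureModel) -> list[float]:
    """For each adjacent 1D component pair, the intersection between the means.

    Components must be sorted by mean.  If no intersection lies strictly
    between the two means, the midpoint is used with a logged warning.
    The k-1 thresholds come back strictly increasing.
    """
    if model.ndim != 1:
        raise ValueError("demarcation thresholds are defined for 1D models only")
    comps = model.components
    means = [float(c.mean[0]) for c in comps]
    if means != sorted(means):
        raise ValueError("components must be sorted by mean")
    thresholds = []
    for c1, c2 in zip(comps[:-1], comps[1:]):
        lo, hi = float(c1.mean[0]), float(c2.mean[0])
        between = [r for r in gaussian_intersections(c1, c2) if lo < r < hi]
        if between:
            thresholds.append(between[0])
        else:
            mid = 0.5 * (lo + hi)
            logger.warning(
                "demarcation_thresholds: no intersection in (%g, %g); using midpoint %g",
                lo, hi, mid,
            )
            thresholds.append(mid)
    if any(b <= a for a, b in zip(thresholds[:-1], thresholds[1:])):
        raise RuntimeError("demarcation thresholds are not strictly increasing")
    return thresholds


def _semantic_order(model: MixtureModel, feature: str = "suv") -> dict[int, str]:
    """Map component index -> semantic name from the normalized means.

    2D (columns adc, suv): highest SUV-minus-ADC mean is vital, lowest is
    low_vital.  1D: ordering along the fitted feature axis ("suv": high mean
    is vital; "adc": low mean is vital).
    """
    if model.ndim == 2:
        score = [float(c.mean[1] - c.mean[0]) for c in model.components]
    elif feature == "suv":
        score = [float(c.mean[0]) for c in model.components]
    elif feature == "adc":
        score = [-float(c.mean[0]) for c in model.components]
    else:
        raise ValueError(f"unknown 1D feature {feature!r}")
    order = np.argsort(score)  # ascending: low_vital ... vital
    names = {}
    names[int(order[0])] = "low_vital"
    names[int(order[1])] = "equivocal"
    names[int(order[2])] = "vital"
    return names


def assign_clusters(
    model: MixtureModel,
    table: VoxelTable,
    feature: str = "suv",
) -> tuple[VoxelTable, dict[str, float]]:
    """Assign every voxel to a semantic cluster and report cluster proportions.

    2D models assign by maximum responsibility on (adc_norm, suv_norm); 1D
    models segment the chosen normalized feature by the demarcation
    thresholds.  Requires the table to carry the normalized columns the model
    was fitted on.
    """
    if model.k != 3:
        raise ValueError("semantic cluster naming requires exactly 3 components")
    if model.ndim == 2:
        cols = ["adc_norm", "suv_norm"]
        if any(c not in table.df.columns for c in cols):
            raise ValueError("table lacks normalized columns adc_norm/suv_norm")
        x = table.df[cols].to_numpy(dtype=float)
        comp_idx = np.argmax(model.log_responsibilities(x), axis=1)
    elif model.ndim == 1:
        col = f"{feature}_norm"
        if col not in table.df.columns:
            raise ValueError(f"table lacks normalized column {col!r}")
        v = table.df[col].to_numpy(dtype=float)
        comp_idx = np.searchsorted(np.asarray(model.demarcation), v)
    else:
        raise ValueError(f"unsupported model dimensionality {model.ndim}")

    names = _semantic_order(model, feature)
    labels = np.array([names[int(i)] for i in comp_idx], dtype=object)
    df = table.df.copy()
    df["cluster"] = labels
    n = len(df)
    proportions = {name: float((labels == name).sum()) / n for name in CLUSTER_NAMES}
    return table.with_df(df), proportions


def correlate_within_clusters(table: VoxelTable) -> dict[str, dict]:
    """Pearson R of raw (ADC, SUV) within each assigned cluster.

    Clusters with fewer than 3 voxels or constant values come back with
    ``r`` and ``p`` missing (None) and a warning.
    """
    if "cluster" not in table.df.columns:
        raise ValueError("table has no cluster assignments")
    out = {}
    for name in CLUSTER_NAMES:
        sub = table.df[table.df["cluster"] == name]
        entry = {"n": int(len(sub)), "r": None, "p": None}
        if len(sub) < 3:
            warnings.warn(f"cluster {name!r} has {len(sub)} voxels; R undefined", stacklevel=2)
        else:
            try:
                r, p = pearson(sub["adc"].to_numpy(), sub["suv"].to_numpy())
                entry["r"], entry["p"] = r, p
            except ValueError:
                warnings.warn(f"cluster {name!r} degenerate; R undefined", stacklevel=2)
        out[name] = entry
    return out
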