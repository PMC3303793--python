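"""Gaussian-mixture analysis of photoconverted nuclear intensities.

A long-lived converted label is diluted roughly two-fold per division, so
the per-nucleus intensity histogram is a superposition of Gaussian-like
modes, one per division extent. This module fits K-component mixtures by
EM on the linear intensities, selects K by BIC, optionally constrains the
component means to a geometric-halving ladder mu_k = mu0 * 2**(-d_k), and
maps intensities back to division counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateSampleError(ValueError):
    pass


@dataclass
class MixtureModel:
    """Fitted K-component univariate Gaussian mixture (means sorted descending)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    aic: float
    n: int
    constrained: bool = False
    mu0: float | None = None
    division_indices: np.ndarray | None = None
    sigma_floor: float = 0.0
    history: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.sds) == self.k):
            raise ValueError("weights/means/sds must all have length k")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be > 0")
        if np.any(np.diff(self.means) > 1e-12):
            raise ValueError("means must be sorted descending")

    # -- posteriors ---------------------------------------------------------

    def log_component_densities(self, x: np.ndarray) -> np.ndarray:
        """(n, k) array of log w_k + log N(x | mu_k, sd_k)."""
        x = np.asarray(x, dtype=float)[:, None]
        mu = self.means[None, :]
        sd = self.sds[None, :]
        return (
            np.log(self.weights[None, :])
            - np.log(sd)
            - 0.5 * _LOG_2PI
            - 0.5 * ((x - mu) / sd) ** 2
        )

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        logd = self.log_component_densities(x)
        return np.exp(logd - logsumexp(logd, axis=1, keepdims=True))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "aic": self.aic,
            "n": self.n,
            "constrained": self.constrained,
            "sigma_floor": self.sigma_floor,
        }
        if self.constrained:
            d["mu0"] = self.mu0
            d["division_indices"] = [int(v) for v in self.division_indices]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            k=int(d["k"]),
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            log_likelihood=float(d["log_likelihood"]),
            bic=float(d["bic"]),
            aic=float(d["aic"]),
            n=int(d["n"]),
            constrained=bool(d.get("constrained", False)),
            mu0=d.get("mu0"),
            division_indices=(
                np.array(d["division_indices"]) if d.get("division_indices") is not None else None
            ),
            sigma_floor=float(d.get("sigma_floor", 0.0)),
        )


@dataclass
class PopulationAssignment:
    """Per-nucleus maximum-posterior component with estimated division count."""

    table: pd.DataFrame  # columns: label, component, posterior, est_divisions


def _validate_sample(x, k: int) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3 * k:
        raise ValueError(f"need at least {3 * k} observations for K={k}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    sd = float(x.std())
    if sd == 0.0:
        raise DegenerateSampleError(
            "sample is degenerate (all values equal): the variance floor sigma_floor "
            "= 1e-6 * sample sd collapses to 0, so no Gaussian fit is defined"
        )
    return x, sd


def _log_density(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (
        np.log(w)[None, :]
        - np.log(sd)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
    )


def _sort_descending(w, mu, sd, extra=None):
    order = np.argsort(-mu, kind="stable")
    if extra is None:
        return w[order], mu[order], sd[order]
    return w[order], mu[order], sd[order], extra[order]


def fit_mixture(
    x,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    sigma_floor: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureModel:
    """Maximum-likelihood K-component Gaussian mixture via restarted EM.

    Each restart initializes the means at jittered sample quantiles, all
    variances at the sample variance, and equal weights; the best
    log-likelihood across restarts wins. BIC uses 3K-1 free parameters.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    x, sample_sd = _validate_sample(x, k)
    n = x.size
    floor = sigma_floor if sigma_floor is not None else 1e-6 * sample_sd
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(restarts):
        q = (np.arange(1, k + 1)) / (k + 1)
        mu = np.quantile(x, q) + rng.normal(0.0, 0.1 * sample_sd, k)
        sd = np.full(k, sample_sd)
        w = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        history = []
        for _ in range(max_iter):
            logd = _log_density(x, w, mu, sd)
            lse = logsumexp(logd, axis=1)
            ll = float(lse.sum())
            history.append(ll)
            resp = np.exp(logd - lse[:, None])
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.sqrt(np.maximum(var, floor**2))
        if best is None or ll > best[0]:
            best = (ll, w, mu, sd, history)

    ll, w, mu, sd, history = best
    w, mu, sd = _sort_descending(w, mu, sd)
    n_params = 3 * k - 1
    return MixtureModel(
        k=k,
        weights=w,
        means=mu,
        sds=sd,
        log_likelihood=ll,
        bic=-2 * ll + n_params * np.log(n),
        aic=-2 * ll + 2 * n_params,
        n=n,
        sigma_floor=floor,
        history=history,
    )


def select_K(
    x,
    k_min: int = 1,
    k_max: int = 6,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit every K in [k_min, k_max]; return the BIC-minimizing model.

    Ties (and near-ties within 1e-9) break toward smaller K. Degenerate
    fits for individual K are skipped with a warning as long as at least
    one K succeeds.
    """
    if k_min < 1 or k_min > k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    import warnings

    seeds = np.random.SeedSequence(seed).spawn(k_max - k_min + 1)
    rows = []
    best = None
    for i, k in enumerate(range(k_min, k_max + 1)):
        sub_seed = int(seeds[i].generate_state(1)[0])
        try:
            model = fit_mixture(x, k, restarts=restarts, seed=sub_seed)
        except (DegenerateSampleError, ValueError) as exc:
            warnings.warn(f"K={k} fit failed: {exc}", stacklevel=2)
            continue
        rows.append({"k": k, "log_likelihood": model.log_likelihood, "bic": model.bic})
        if best is None or model.bic < best.bic - 1e-9:
            best = model
    if best is None:
        raise DegenerateSampleError("no K in the requested range could be fitted")
    return best, pd.DataFrame(rows)


def fit_halving_constrained(
    x,
    division_set,
    restarts: int = 20,
    seed: int = 0,
    sigma_floor: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureModel:
    """EM with component means tied to a halving ladder mu0 * 2**(-d_k).

    Free parameters: mu0, per-component sds, and weights (2K parameters).
    """
    d = np.asarray(sorted(set(int(v) for v in division_set)))
    if np.any(d < 0):
        raise ValueError("division_set must be non-negative integers")
    if d.size != len(list(division_set)):
        raise ValueError("division_set must be distinct")
    k = d.size
    x, sample_sd = _validate_sample(x, k)
    n = x.size
    floor = sigma_floor if sigma_floor is not None else 1e-6 * sample_sd
    rng = np.random.default_rng(seed)
    c = 2.0 ** (-d.astype(float))  # halving coefficients, descending in mean

    best = None
    for _ in range(restarts):
        mu0 = float(np.quantile(x, 0.95)) * (1.0 + rng.normal(0.0, 0.1))
        mu0 = max(mu0, 1e-12)
        sd = np.full(k, sample_sd)
        w = np.full(k, 1.0 / k)
        prev_ll = -np.inf
        history = []
        for _ in range(max_iter):
            mu = mu0 * c
            logd = _log_density(x, w, mu, sd)
            lse = logsumexp(logd, axis=1)
            ll = float(lse.sum())
            history.append(ll)
            resp = np.exp(logd - lse[:, None])
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
            nk = np.maximum(resp.sum(axis=0), 1e-300)
            w = nk / n
            # weighted least squares for mu0 given current sds
            num = ((resp * x[:, None]).sum(axis=0) * c / sd**2).sum()
            den = (nk * c**2 / sd**2).sum()
            mu0 = max(num / den, 1e-12)
            mu = mu0 * c
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.sqrt(np.maximum(var, floor**2))
        if best is None or ll > best[0]:
            best = (ll, w, mu0, sd, history)

    ll, w, mu0, sd, history = best
    mu = mu0 * c
    w, mu, sd, d_sorted = _sort_descending(w, mu, sd, extra=d)
    n_params = 2 * k
    return MixtureModel(
        k=k,
        weights=w,
        means=mu,
        sds=sd,
        log_likelihood=ll,
        bic=-2 * ll + n_params * np.log(n),
        aic=-2 * ll + 2 * n_params,
        n=n,
        constrained=True,
        mu0=float(mu0),
        division_indices=d_sorted,
        sigma_floor=floor,
        history=history,
    )


def assign_populations(
    model: MixtureModel,
    records: pd.DataFrame,
    column: str = "bgsub_mean_nuclear_converted",
) -> PopulationAssignment:
    """Maximum-posterior component per nucleus, with division-count estimate.

    For constrained models the estimate is the component's division index;
    otherwise it is the component's rank by descending mean (0 = brightest).
    """
    x = records[column].to_numpy(dtype=float)
    post = model.posteriors(x)
    comp = post.argmax(axis=1)
    if model.constrained:
        est = model.division_indices[comp]
    else:
        est = comp  # components already sorted by descending mean
    table = pd.DataFrame(
        {
            "label": records["label"].to_numpy(),
            "component": comp,
            "posterior": post[np.arange(len(x)), comp],
            "est_divisions": est.astype(int),
        }
    )
    return PopulationAssignment(table=table)


def estimate_divisions(intensity: float, mu0: float) -> int:
    """Division count implied by halving: round(log2(mu0/intensity)), >= 0."""
    if intensity <= 0 or mu0 <= 0:
        raise ValueError("intensity and mu0 must be > 0")
    return max(0, int(round(np.log2(mu0 / intensity))))
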