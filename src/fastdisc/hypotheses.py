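"""Six-model comparison of state-induced change in log discount rates.

The data are per-participant changes in log discount rate,
Delta_{p,c} = log k(fasted) - log k(control), for commodities
c in (food, money, music), where food is the in-domain commodity for a
hunger manipulation.  Each candidate model specifies a group-level change
location per commodity, and participant scatter around those locations is
Cauchy with a common scale:

    LL(theta_m) = sum_p sum_c log Cauchy(Delta_{p,c}; loc_m(c), scale_m)

================================  =========================  ==
model                             (food, money, music)       n
================================  =========================  ==
1. trait_only                     (0,      0,      0)        1
2. in_domain                      (alpha,  0,      0)        2
3. monetary_fungibility           (beta,   beta,   0)        2
4. negative_spillover             (gamma, -delta, -delta)    3
5. spillover                      (eps,    zeta,   zeta)     3
6. state_only                     (eta,    eta,    eta)      2
================================  =========================  ==

All free parameters (alpha .. eta, delta, and scale) are constrained
nonnegative, spillover additionally requires eps > zeta (enforced via
eps = zeta + gap, gap >= 0), and ``n`` counts the scale parameter.
Models are fitted by maximum likelihood and ranked by AIC / BIC and the
corresponding Akaike/Schwarz weights.  The Greek parameter names live in
the hypothesis-model namespace, distinct from the choice-rule alpha and
epsilon of :mod:`fastdisc.choices`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import cauchy

from .choices import COMMODITIES

SCALE_FLOOR = 1e-6

DELTA_CSV_COLUMNS = ["participant", "commodity", "delta_logk"]


@dataclass(frozen=True)
class HypothesisModel:
    """One candidate account of how the state change shifts log k."""

    name: str
    n_params: int  # free location parameters + the scale parameter
    param_names: tuple[str, ...]  # optimizer-space free parameters (excl. scale)

    def locations(self, free: np.ndarray) -> np.ndarray:
        """Per-commodity group change (food, money, music) from free params."""
        f = np.asarray(free, float)
        if self.name == "trait_only":
            return np.zeros(3)
        if self.name == "in_domain":
            return np.array([f[0], 0.0, 0.0])
        if self.name == "monetary_fungibility":
            return np.array([f[0], f[0], 0.0])
        if self.name == "negative_spillover":
            return np.array([f[0], -f[1], -f[1]])
        if self.name == "spillover":
            # free = (zeta, gap); eps = zeta + gap so eps >= zeta always
            return np.array([f[0] + f[1], f[0], f[0]])
        if self.name == "state_only":
            return np.array([f[0], f[0], f[0]])
        raise ValueError(f"unknown hypothesis model {self.name!r}")

    def report_params(self, free: np.ndarray, scale: float) -> dict[str, float]:
        """Fitted parameters in their natural (model) parameterization."""
        loc = self.locations(free)
        natural = {
            "trait_only": {},
            "in_domain": {"alpha": loc[0]},
            "monetary_fungibility": {"beta": loc[0]},
            "negative_spillover": {"gamma": loc[0], "delta": -loc[1]},
            "spillover": {"epsilon": loc[0], "zeta": loc[1]},
            "state_only": {"eta": loc[0]},
        }[self.name]
        natural["scale"] = scale
        return natural


MODELS: tuple[HypothesisModel, ...] = (
    HypothesisModel("trait_only", 1, ()),
    HypothesisModel("in_domain", 2, ("alpha",)),
    HypothesisModel("monetary_fungibility", 2, ("beta",)),
    HypothesisModel("negative_spillover", 3, ("gamma", "delta")),
    HypothesisModel("spillover", 3, ("zeta", "gap")),
    HypothesisModel("state_only", 2, ("eta",)),
)
MODELS_BY_NAME = {m.name: m for m in MODELS}


# ---------------------------------------------------------------------------
# delta tables


def delta_matrix(deltas: pd.DataFrame) -> np.ndarray:
    """(P, 3) array of changes ordered (food, money, music).

    ``deltas`` is the long-format table with columns participant,
    commodity, delta_logk — exactly one finite value per cell.
    """
    missing = [c for c in DELTA_CSV_COLUMNS if c not in deltas.columns]
    if missing:
        raise ValueError(f"delta table is missing required column(s): {missing}")
    wide = deltas.pivot(index="participant", columns="commodity", values="delta_logk")
    if set(wide.columns) != set(COMMODITIES):
        raise ValueError(f"delta table must cover commodities {COMMODITIES}")
    wide = wide[list(COMMODITIES)]
    if wide.isna().any().any():
        raise ValueError("delta table has missing cells")
    if len(wide) < 2:
        raise ValueError("need at least 2 participants")
    arr = wide.to_numpy(float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("delta values must be finite")
    return arr


def cauchy_loglik(deltas, locations, scale: float) -> float:
    """Sum of Cauchy log densities over all (participant, commodity) cells.

    ``deltas`` may be the long table or a (P, 3) array; ``locations`` is
    the per-commodity location triple (food, money, music).
    """
    if not scale > 0:
        raise ValueError("Cauchy scale must be > 0")
    arr = deltas if isinstance(deltas, np.ndarray) else delta_matrix(deltas)
    arr = np.atleast_2d(arr)
    return float(cauchy.logpdf(arr, loc=np.asarray(locations, float), scale=scale).sum())


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class ModelFit:
    model: HypothesisModel
    ml_params: dict[str, float]
    LL: float
    AIC: float
    BIC: float


def _neg_ll(x: np.ndarray, model: HypothesisModel, arr: np.ndarray) -> float:
    free, scale = x[:-1], max(x[-1], SCALE_FLOOR)
    ll = cauchy.logpdf(arr, loc=model.locations(free), scale=scale).sum()
    return -ll


def fit_model_ml(
    deltas,
    model: HypothesisModel | str,
    n_bic: int | None = None,
    n_starts: int = 8,
    rng_seed: int = 0,
) -> ModelFit:
    """Maximize the Cauchy log likelihood for one hypothesis model.

    Box-constrained L-BFGS-B from ``n_starts`` random starting points
    (locations in [0, 3], scale in [0.05, 2]); nonnegativity is imposed by
    the bounds, so boundary solutions (a parameter exactly 0) are
    reachable — this matters for nested models.  The best start wins; ties
    within 1e-9 go to the smaller parameter norm.  ``n_bic`` is the BIC
    sample size (defaults to the participant count).
    """
    if isinstance(model, str):
        model = MODELS_BY_NAME[model]
    arr = deltas if isinstance(deltas, np.ndarray) else delta_matrix(deltas)
    arr = np.atleast_2d(arr)
    if n_bic is None:
        n_bic = arr.shape[0]
    rng = np.random.default_rng(rng_seed)
    n_free = len(model.param_names)
    bounds = [(0.0, None)] * n_free + [(SCALE_FLOOR, None)]

    best: tuple[float, np.ndarray] | None = None
    n_fail = 0
    for i in range(n_starts):
        if i == 0:  # one deterministic moment-matched start
            x0 = np.concatenate(
                [np.full(n_free, max(np.abs(np.median(arr)), 0.1)), [max(_mad_scale(arr), 0.05)]]
            )
        else:
            x0 = np.concatenate([rng.uniform(0.0, 3.0, n_free), [rng.uniform(0.05, 2.0)]])
        res = minimize(_neg_ll, x0, args=(model, arr), method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        cand = (float(res.fun), res.x.copy())
        if (
            best is None
            or cand[0] < best[0] - 1e-9
            or (abs(cand[0] - best[0]) <= 1e-9 and np.linalg.norm(cand[1]) < np.linalg.norm(best[1]))
        ):
            best = cand
    if best is None:
        raise RuntimeError(
            f"optimizer failed on all {n_starts} starts for model {model.name!r} "
            f"({n_fail} non-finite results)"
        )
    nll, x = best
    ll = -nll
    scale = max(float(x[-1]), SCALE_FLOOR)
    aic, bic = information_criteria(ll, model.n_params, n_bic)
    return ModelFit(model, model.report_params(x[:-1], scale), ll, aic, bic)


def _mad_scale(arr: np.ndarray) -> float:
    med = np.median(arr)
    return float(np.median(np.abs(arr - med)))


def information_criteria(LL: float, n_params: int, N_BIC: int) -> tuple[float, float]:
    """AIC = 2n - 2LL and BIC = n ln(N) - 2LL."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if N_BIC < 2:
        raise ValueError("BIC sample size must be >= 2")
    return 2.0 * n_params - 2.0 * LL, n_params * float(np.log(N_BIC)) - 2.0 * LL


def model_weights(ic_values) -> np.ndarray:
    """Akaike/Schwarz weights: w_m = exp(-0.5 Delta_m) / sum_i exp(-0.5 Delta_i).

    Delta_m = IC_m - min(IC); invariant to adding any constant to all IC
    values; always a probability vector.
    """
    ic = np.asarray(ic_values, float)
    if ic.size == 0 or not np.all(np.isfinite(ic)):
        raise ValueError("IC values must be a nonempty finite list")
    rel = np.exp(-0.5 * (ic - ic.min()))
    return rel / rel.sum()


def compare_all(deltas, n_bic: int | None = None, rng_seed: int = 0) -> pd.DataFrame:
    """Fit all six models and rank them by AIC/BIC and weights.

    Returns one row per model in canonical order with columns
    model, n, LL, AIC, BIC, dAIC, wAIC, dBIC, wBIC.
    """
    arr = deltas if isinstance(deltas, np.ndarray) else delta_matrix(deltas)
    fits = [fit_model_ml(arr, m, n_bic=n_bic, rng_seed=rng_seed) for m in MODELS]
    df = pd.DataFrame(
        {
            "model": [m.name for m in MODELS],
            "n": [m.n_params for m in MODELS],
            "LL": [f.LL for f in fits],
            "AIC": [f.AIC for f in fits],
            "BIC": [f.BIC for f in fits],
        }
    )
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    df["dBIC"] = df["BIC"] - df["BIC"].min()
    df["wAIC"] = model_weights(df["AIC"].to_numpy())
    df["wBIC"] = model_weights(df["BIC"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# descriptive change statistics


def paired_cohens_d(x, y) -> float:
    """Paired effect size: mean(y - x) / SD(y - x), SD with ddof=1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    return float(d.mean() / sd)


def bootstrap_mean_ci(
    diffs, level: float = 0.95, n_boot: int = 5000, rng_seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of paired differences."""
    diffs = np.asarray(diffs, float)
    if diffs.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, diffs.size, size=(n_boot, diffs.size))
    means = diffs[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def spillover_ratio(deltas) -> float:
    """Out-of-domain change as a percentage of the in-domain (food) change.

    100 x mean over participants and non-food commodities of Delta,
    divided by the mean food Delta.
    """
    arr = deltas if isinstance(deltas, np.ndarray) else delta_matrix(deltas)
    arr = np.atleast_2d(arr)
    food = arr[:, 0].mean()
    if food == 0:
        raise ValueError("mean food effect is zero; ratio undefined")
    return float(100.0 * arr[:, 1:].mean() / food)


# ---------------------------------------------------------------------------
# delta-table CSV interchange


def write_delta_csv(path, deltas: pd.DataFrame, header_lines: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        deltas[DELTA_CSV_COLUMNS].to_csv(fh, index=False, float_format="%.17g")


def read_delta_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, comment="#", dtype={"participant": str}, float_precision="round_trip"
    )
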