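"""Trial data model and the lapse-contaminated probit choice rule.

A trial offers a smaller-sooner amount ``A`` now (delay ``D_A = 0``)
against a larger-later amount ``B`` after ``D_B`` days.  Given session
parameters (log discount rate ``log_k``, comparison acuity ``alpha``,
lapse rate ``epsilon``) the probability of choosing the delayed option is

    P = epsilon + (1 - 2 epsilon) * Phi((V_B - V_A) / alpha)

with Phi the standard normal CDF.  ``alpha`` scales value-comparison noise
in commodity units (larger alpha = noisier choices); ``epsilon`` is the
probability of a value-independent lapse, squeezing P into
[epsilon, 1 - epsilon].  Responses are Bernoulli draws from P.

Note on symbols: ``alpha`` and ``epsilon`` here belong to the choice-rule
namespace and are unrelated to the group-level hypothesis-model parameters
of the same names in :mod:`fastdisc.hypotheses`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .discounting import DiscountFunction, present_value

CONDITIONS = ("control", "fasted")
COMMODITIES = ("food", "money", "music")

#: Exact header of the trial-table CSV dialect.
TRIAL_CSV_COLUMNS = [
    "participant",
    "condition",
    "commodity",
    "trial_index",
    "A",
    "DA",
    "B",
    "DB",
    "R",
]


@dataclass(frozen=True)
class Trial:
    """One binary inter-temporal choice.

    ``A``: immediate amount (commodity units), ``B``: delayed amount,
    ``D_B``: delay of B in days (``D_A`` is always 0), ``R``: 1 if the
    delayed option was chosen, 0 if the immediate one; ``None`` before a
    response is recorded.
    """

    A: float
    B: float
    D_B: float
    R: int | None = None
    D_A: float = 0.0

    def __post_init__(self) -> None:
        if self.D_A != 0.0:
            raise ValueError("immediate option must have D_A = 0")
        if not self.D_B > 0:
            raise ValueError("delayed option must have D_B > 0")
        if not (0 < self.A <= self.B):
            raise ValueError(f"require 0 < A <= B, got A={self.A}, B={self.B}")
        if self.R is not None and self.R not in (0, 1):
            raise ValueError("response R must be 0, 1 or None")

    def with_response(self, r: int) -> "Trial":
        return replace(self, R=int(r))


@dataclass
class ChoiceDataset:
    """All trials of one participant x condition x commodity session."""

    participant: str
    condition: str
    commodity: str
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.commodity not in COMMODITIES:
            raise ValueError(f"commodity must be one of {COMMODITIES}")

    def __len__(self) -> int:
        return len(self.trials)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(A, B, D_B, R) as float/int arrays; R entries must be recorded."""
        if not self.trials:
            raise ValueError("dataset has no trials")
        if any(t.R is None for t in self.trials):
            raise ValueError("dataset contains unanswered trials")
        A = np.array([t.A for t in self.trials])
        B = np.array([t.B for t in self.trials])
        DB = np.array([t.D_B for t in self.trials])
        R = np.array([t.R for t in self.trials], dtype=int)
        return A, B, DB, R


@dataclass(frozen=True)
class ChoiceParams:
    """Session-level parameters of the choice rule."""

    log_k: float
    alpha: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("comparison acuity alpha must be > 0")
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("lapse rate epsilon must lie in [0, 0.5)")
        if not np.isfinite(self.log_k):
            raise ValueError("log_k must be finite")

    @property
    def k(self) -> float:
        return float(np.exp(self.log_k))


def value_difference(trial: Trial, params: ChoiceParams, spec: DiscountFunction | None = None):
    """V_B - V_A under the session's discount rate."""
    if spec is None:
        spec = DiscountFunction("hyperbolic", k=params.k)
    else:
        spec = DiscountFunction(spec.family, k=params.k, s=spec.s)
    v_a = present_value(spec, trial.A, trial.D_A)
    v_b = present_value(spec, trial.B, trial.D_B)
    return float(v_b - v_a)


def choice_probability(
    trial: Trial, params: ChoiceParams, spec: DiscountFunction | None = None
) -> float:
    """Probability of choosing the delayed option on ``trial``.

    Lies in [epsilon, 1 - epsilon]; equals 0.5 exactly when V_B == V_A;
    strictly increasing in V_B - V_A.
    """
    dv = value_difference(trial, params, spec)
    p = params.epsilon + (1.0 - 2.0 * params.epsilon) * norm.cdf(dv / params.alpha)
    return float(p)


def simulate_response(
    trial: Trial,
    params: ChoiceParams,
    spec: DiscountFunction | None = None,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Draw R ~ Bernoulli(choice_probability); reproducible for a fixed seed."""
    rng = np.random.default_rng(rng)
    p = choice_probability(trial, params, spec)
    return int(rng.random() < p)


# ---------------------------------------------------------------------------
# CSV interchange


def datasets_to_frame(datasets: list[ChoiceDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for i, t in enumerate(ds.trials):
            rows.append(
                (ds.participant, ds.condition, ds.commodity, i, t.A, t.D_A, t.B, t.D_B, t.R)
            )
    return pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)


def frame_to_datasets(df: pd.DataFrame) -> list[ChoiceDataset]:
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required column(s): {missing}")
    out = []
    keys = df[["participant", "condition", "commodity"]].drop_duplicates()
    for _, (p, cond, com) in keys.iterrows():
        sub = df[
            (df["participant"] == p) & (df["condition"] == cond) & (df["commodity"] == com)
        ].sort_values("trial_index")
        trials = [
            Trial(A=row.A, B=row.B, D_B=row.DB, R=None if pd.isna(row.R) else int(row.R))
            for row in sub.itertuples()
        ]
        out.append(ChoiceDataset(str(p), str(cond), str(com), trials))
    return out


def write_trials_csv(path, datasets: list[ChoiceDataset], header_lines: list[str] | None = None):
    """Write sessions in the trial CSV dialect, optionally with '#' metadata lines."""
    df = datasets_to_frame(datasets)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # exact float round-trip


def read_trials_csv(path) -> list[ChoiceDataset]:
    df = pd.read_csv(
        path, comment="#", dtype={"participant": str}, float_precision="round_trip"
    )
    return frame_to_datasets(df)
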