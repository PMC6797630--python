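"""Synthetic study generator.

Emulates the study design end to end: 50 participants measured in a
2 (control vs fasted) x 3 (food, money, music) repeated-measures design,
35 adaptive trials per session with commodity-specific fixed delayed
rewards.  Baseline log discount rates are participant x commodity draws
(correlated 0.5 across commodities, reflecting the trait-like component
of discounting); the condition effect Delta_{p,c} is Cauchy-scattered
around the group-level locations of a chosen generative hypothesis model,
and fasted-session rates are baseline + Delta.

Heavy Cauchy tails occasionally produce physically absurd rate changes;
generated Delta values with |Delta| > 10 (a factor of e^10 ~ 22000 in k)
are resampled so sessions stay informative.  This truncation applies to
the generator only — the analysis modules never truncate data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choices import COMMODITIES, CONDITIONS, ChoiceDataset, ChoiceParams
from .design import DesignSpace
from .hypotheses import DELTA_CSV_COLUMNS, MODELS_BY_NAME, HypothesisModel
from .inference import PriorSpec

DELTA_ABS_LIMIT = 10.0

GROUND_TRUTH_CSV_COLUMNS = ["participant", "commodity", "condition", "true_logk"]


@dataclass
class PopulationConfig:
    """Generative settings for a synthetic study."""

    n_participants: int = 50
    baseline_logk_mean: float = float(np.log(1.0 / 50.0))
    baseline_logk_sd: float = 1.0
    baseline_cross_commodity_corr: float = 0.5
    generative_model: str = "spillover"
    model_params: dict[str, float] = field(default_factory=lambda: {"epsilon": 2.0, "zeta": 0.5})
    cauchy_scale: float = 0.5
    choice_alpha: float = 0.5
    choice_epsilon: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not self.cauchy_scale > 0:
            raise ValueError("Cauchy scale must be > 0")
        if self.generative_model not in MODELS_BY_NAME:
            raise ValueError(f"unknown generative model {self.generative_model!r}")
        # fail early if the free parameters don't satisfy the model's form
        self.group_locations()

    @property
    def model(self) -> HypothesisModel:
        return MODELS_BY_NAME[self.generative_model]

    def group_locations(self) -> np.ndarray:
        """Group-level (food, money, music) change implied by the model."""
        p = self.model_params
        name = self.generative_model
        try:
            if name == "trait_only":
                free: list[float] = []
            elif name == "in_domain":
                free = [p["alpha"]]
            elif name == "monetary_fungibility":
                free = [p["beta"]]
            elif name == "negative_spillover":
                free = [p["gamma"], p["delta"]]
            elif name == "spillover":
                free = [p["zeta"], p["epsilon"] - p["zeta"]]
            else:  # state_only
                free = [p["eta"]]
        except KeyError as exc:
            raise ValueError(f"model {name!r} requires parameter {exc}") from exc
        if any(v < 0 for v in free):
            raise ValueError(f"free parameters violate the constraints of model {name!r}")
        return self.model.locations(np.array(free))


@dataclass
class GroundTruth:
    """True parameters behind one synthetic study."""

    model_name: str
    model_params: dict[str, float]
    logk: pd.DataFrame  # participant, commodity, condition, true_logk
    deltas: pd.DataFrame  # participant, commodity, delta_logk

    def check_consistent(self) -> None:
        """Delta must equal fasted minus control true log k, cell by cell."""
        wide = self.logk.pivot_table(
            index=["participant", "commodity"], columns="condition", values="true_logk"
        )
        diff = (wide["fasted"] - wide["control"]).rename("delta_logk").reset_index()
        merged = diff.merge(self.deltas, on=["participant", "commodity"], suffixes=("_lk", ""))
        if not np.allclose(merged["delta_logk_lk"], merged["delta_logk"], atol=1e-12):
            raise AssertionError("ground-truth deltas inconsistent with stored log k values")


def _participant_ids(n: int) -> list[str]:
    return [f"p{i + 1:03d}" for i in range(n)]


def generate_delta_table(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the per-participant change table under the generative model.

    Delta_{p,c} ~ Cauchy(location_c, cauchy_scale), i.i.d. across cells,
    resampled while |Delta| > 10.  Also returns the full ground truth
    (baseline and fasted log k per cell).
    """
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    n = config.n_participants
    loc = config.group_locations()
    ids = _participant_ids(n)

    deltas = rng.standard_cauchy((n, 3)) * config.cauchy_scale + loc
    bad = np.abs(deltas) > DELTA_ABS_LIMIT
    while np.any(bad):
        deltas[bad] = rng.standard_cauchy(bad.sum()) * config.cauchy_scale + np.broadcast_to(
            loc, deltas.shape
        )[bad]
        bad = np.abs(deltas) > DELTA_ABS_LIMIT

    # baseline log k correlated across commodities within a participant
    r = config.baseline_cross_commodity_corr
    cov = config.baseline_logk_sd**2 * (np.full((3, 3), r) + (1 - r) * np.eye(3))
    baseline = config.baseline_logk_mean + rng.multivariate_normal(np.zeros(3), cov, n)

    delta_df = pd.DataFrame(
        {
            "participant": np.repeat(ids, 3),
            "commodity": list(COMMODITIES) * n,
            "delta_logk": deltas.ravel(),
        }
    )
    rows = []
    for i, pid in enumerate(ids):
        for j, com in enumerate(COMMODITIES):
            rows.append((pid, com, "control", baseline[i, j]))
            rows.append((pid, com, "fasted", baseline[i, j] + deltas[i, j]))
    logk_df = pd.DataFrame(rows, columns=GROUND_TRUTH_CSV_COLUMNS)
    truth = GroundTruth(config.generative_model, dict(config.model_params), logk_df, delta_df)
    truth.check_consistent()
    return delta_df, truth


def simulate_study(
    config: PopulationConfig,
    space_by_commodity: dict[str, DesignSpace] | None = None,
    priors: PriorSpec | None = None,
    n_particles: int = 500,
) -> tuple[list[ChoiceDataset], GroundTruth]:
    """Simulate trial-level data for a complete 2 x 3 study.

    Every participant contributes one adaptive 35-trial session per
    condition x commodity; control sessions respond under the baseline
    log k, fasted sessions under baseline + Delta.  Reproducible for a
    fixed ``config.rng_seed``.
    """
    from .design import run_simulated_session

    if space_by_commodity is None:
        space_by_commodity = {c: DesignSpace.for_commodity(c) for c in COMMODITIES}
    priors = priors or PriorSpec()
    root = np.random.default_rng(config.rng_seed)
    _, truth = generate_delta_table(config, root)
    logk = truth.logk.set_index(["participant", "commodity", "condition"])["true_logk"]

    sessions: list[ChoiceDataset] = []
    for pid in _participant_ids(config.n_participants):
        for cond in CONDITIONS:
            for com in COMMODITIES:
                params = ChoiceParams(
                    log_k=float(logk.loc[(pid, com, cond)]),
                    alpha=config.choice_alpha,
                    epsilon=config.choice_epsilon,
                )
                sessions.append(
                    run_simulated_session(
                        params,
                        space_by_commodity[com],
                        priors,
                        rng_seed=int(root.integers(2**31)),
                        participant=pid,
                        condition=cond,
                        commodity=com,
                        n_particles=n_particles,
                    )
                )
    return sessions, truth


def write_ground_truth_csv(path, truth: GroundTruth, header_lines: list[str] | None = None):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        truth.logk[GROUND_TRUTH_CSV_COLUMNS].to_csv(fh, index=False)


def deltas_from_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-participant Delta log k table from fitted session summaries.

    ``summaries`` is the posterior-summary frame (one row per session with
    a ``logk_median`` column); Delta = fasted median minus control median.
    """
    wide = summaries.pivot_table(
        index=["participant", "commodity"], columns="condition", values="logk_median"
    )
    out = (wide["fasted"] - wide["control"]).rename("delta_logk").reset_index()
    return out[DELTA_CSV_COLUMNS]
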