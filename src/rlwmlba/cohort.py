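"""Synthetic cohorts: covariates, parameters with planted effects, behavior.

Covariates emulate the statistical structure of an adolescent community
sample: truncated-normal age (mean 17.76, SD 2.42, range 12.35-24.31),
72% female, and right-skewed symptom scales (a 12-item 3-level depressive
scale and a 7-item 4-level anxiety scale). Latent model parameters are the
prior-mode group means plus optional planted linear covariate effects, and
behavior is simulated from the generative model on freshly generated
sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import (
    DEFAULT_GROUP_SD,
    MEAN_PRIOR_LOC,
    N_PARAMS,
    PriorSpec,
    transform,
)
from .model import PARAM_NAMES, SubjectParameters, simulate_agent
from .task import generate_session

AGE_MEAN = 17.76
AGE_SD = 2.42
AGE_MIN = 12.35
AGE_MAX = 24.31
MALE_PROB = 0.28

SMFQ_ITEMS = 12  # 3-point items (0-2), sum range 0-24
SMFQ_LEVELS = 3
GAD7_ITEMS = 7  # 4-point items (0-3), sum range 0-21
GAD7_LEVELS = 4

COVARIATE_COLUMNS = ["subject_id", "age", "sex", "smfq_sum", "gad7_sum"]


@dataclass(frozen=True)
class Effect:
    """One planted linear effect: standardized covariate -> latent parameter."""

    covariate: str
    parameter: str
    slope: float

    def __post_init__(self):
        if self.parameter not in PARAM_NAMES:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; expected one of {PARAM_NAMES}"
            )


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects plus per-parameter residual latent SDs."""

    effects: tuple = ()
    residual_sd: float | dict = DEFAULT_GROUP_SD

    @classmethod
    def from_list(cls, effects: Sequence, residual_sd=DEFAULT_GROUP_SD) -> "EffectSpec":
        return cls(
            effects=tuple(
                e if isinstance(e, Effect) else Effect(*e) for e in effects
            ),
            residual_sd=residual_sd,
        )

    def residual_for(self, parameter: str) -> float:
        if isinstance(self.residual_sd, dict):
            return float(self.residual_sd.get(parameter, DEFAULT_GROUP_SD))
        return float(self.residual_sd)


@dataclass
class CohortDataset:
    covariates: pd.DataFrame
    trials: pd.DataFrame
    true_latents: pd.DataFrame
    true_params: pd.DataFrame
    effects: EffectSpec
    seed: int

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.true_latents.to_csv(outdir / "true_latents.csv", index=False)
        self.true_params.to_csv(outdir / "true_params.csv", index=False)
        manifest = {
            "seed": self.seed,
            "n_subjects": int(self.covariates.shape[0]),
            "effects": [vars(e) for e in self.effects.effects],
            "residual_sd": self.effects.residual_sd,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _skewed_items(
    n: int, n_items: int, n_levels: int, rng: np.random.Generator, severity_scale: float
) -> np.ndarray:
    """Right-skewed ordinal item responses via a per-subject severity trait.

    Severity ~ Exponential(scale) on the log-odds scale; item response
    probabilities decay geometrically from level 0 with per-subject decay
    softened by severity, reproducing the skew of community samples.
    """
    severity = rng.exponential(severity_scale, size=n)
    levels = np.arange(n_levels)
    # decay rate per level: high severity -> flatter distribution
    decay = np.exp(-np.maximum(1.5 - severity, 0.1))[:, None]  # (n, 1)
    probs = decay ** levels[None, :]
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n, n_items))
    return (u[:, :, None] > cum[:, None, :-1]).sum(axis=2)


def generate_covariates(
    n: int,
    seed: int,
    *,
    age_mean: float = AGE_MEAN,
    age_sd: float = AGE_SD,
    age_min: float = AGE_MIN,
    age_max: float = AGE_MAX,
    male_prob: float = MALE_PROB,
    severity_scale: float = 0.8,
    include_items: bool = False,
) -> pd.DataFrame:
    """Covariate table: age, sex (0=female, 1=male), symptom sums.

    With ``include_items`` the item-level ordinal responses are appended
    (columns ``smfq_i*`` and ``gad7_i*``) for item-level analyses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC0F])
    a, b = (age_min - age_mean) / age_sd, (age_max - age_mean) / age_sd
    age = stats.truncnorm.rvs(a, b, loc=age_mean, scale=age_sd, size=n, random_state=rng)
    sex = (rng.random(n) < male_prob).astype(int)
    smfq = _skewed_items(n, SMFQ_ITEMS, SMFQ_LEVELS, rng, severity_scale)
    gad7 = _skewed_items(n, GAD7_ITEMS, GAD7_LEVELS, rng, severity_scale)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "age": age,
            "sex": sex,
            "smfq_sum": smfq.sum(axis=1),
            "gad7_sum": gad7.sum(axis=1),
        }
    )
    if include_items:
        for i in range(SMFQ_ITEMS):
            df[f"smfq_i{i + 1}"] = smfq[:, i]
        for i in range(GAD7_ITEMS):
            df[f"gad7_i{i + 1}"] = gad7[:, i]
    return df


def generate_parameters(
    covariates: pd.DataFrame,
    effects: EffectSpec,
    seed: int,
    *,
    group_mu: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent and natural subject parameters with planted covariate effects.

    latent = group mean + slope * standardized covariate + Normal(0,
    residual SD), per parameter; effects are planted on the latent scale
    where linearity is well defined.
    """
    n = len(covariates)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xBE7A])
    mu = MEAN_PRIOR_LOC if group_mu is None else np.asarray(group_mu, dtype=float)
    lat = np.empty((n, N_PARAMS))
    for p, name in enumerate(PARAM_NAMES):
        resid = effects.residual_for(name)
        lat[:, p] = mu[p] + resid * rng.standard_normal(n)
    for eff in effects.effects:
        x = covariates[eff.covariate].to_numpy(dtype=float)
        zx = (x - x.mean()) / x.std()
        p = PARAM_NAMES.index(eff.parameter)
        lat[:, p] += eff.slope * zx
    nat = transform(lat)
    lat_df = pd.DataFrame(lat, columns=PARAM_NAMES)
    lat_df.insert(0, "subject_id", covariates["subject_id"].to_numpy())
    nat_df = pd.DataFrame(nat, columns=PARAM_NAMES)
    nat_df.insert(0, "subject_id", covariates["subject_id"].to_numpy())
    return lat_df, nat_df


def generate_cohort(
    n: int,
    effects: EffectSpec,
    seed: int,
    *,
    include_items: bool = False,
) -> CohortDataset:
    """Full synthetic cohort: covariates, parameters, and simulated sessions."""
    covariates = generate_covariates(n, seed, include_items=include_items)
    lat_df, nat_df = generate_parameters(covariates, effects, seed)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5E55])
    frames = []
    for i, row in enumerate(nat_df.itertuples(index=False)):
        sess = generate_session(int(rng.integers(1 << 30)))
        params = SubjectParameters(**{name: getattr(row, name) for name in PARAM_NAMES})
        frames.append(
            simulate_agent(
                sess, params, seed=int(rng.integers(1 << 30)), subject_id=int(row.subject_id)
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    return CohortDataset(
        covariates=covariates,
        trials=trials,
        true_latents=lat_df,
        true_params=nat_df,
        effects=effects,
        seed=seed,
    )
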