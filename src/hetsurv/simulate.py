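"""Synthetic censored-cohort simulator with known risk structure.

Event times follow a proportional-hazards model: given a linear predictor
``eta`` over the (numeric representation of the) features, the event time is
drawn by inverse-transform sampling from an exponential or Weibull baseline
hazard scaled by ``exp(eta)``.  Observation is cut by an independent random
censoring time (uniform or exponential) and by an administrative follow-up
horizon, emulating clinical trials with differing follow-up — e.g. median
follow-up spanning roughly 280 to 640 days across trials of the same disease.

The multi-trial generator produces several cohorts that share a common block
of features (with identical true coefficients) next to trial-private
features, so feature-intersection logic and between-trial transfer can be
exercised end to end.

One global seed drives three independent substreams (features, event times,
censoring), so the censoring mechanism can be varied with features held
fixed.  Ground truth (true event times and the linear predictor) is returned
separately and never enters the cohort itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CONTINUOUS, NOMINAL, ORDINAL, FeatureSchema, FeatureSpec, SurvivalCohort
from .exceptions import ValidationError

#: Default follow-up horizon (days); three years, on the order of the longest
#: follow-up seen in phase-III metastatic prostate-cancer trials.
DEFAULT_HORIZON = 1095.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic trial.

    Defaults emulate a mid-sized phase-III oncology cohort: 500 patients,
    ten continuous markers, two nominal and one ordinal covariate, moderate
    effect sizes, exponential baseline with ~600-day median survival for the
    average patient, uniform loss to follow-up and a 3-year administrative
    horizon.
    """

    n_samples: int = 500
    n_continuous: int = 10
    nominal_levels: tuple = (3, 2)
    ordinal_levels: tuple = (4,)
    coefficients: tuple = (0.8, -0.5, 0.3, 0.3, -0.3, 0.2, 0.0, 0.0, 0.0, 0.0, 0.4, -0.4, 0.3)
    interaction: tuple | None = None  # (feature_idx_a, feature_idx_b, coef)
    baseline: str = "exponential"
    baseline_params: tuple = (np.log(2) / 600.0,)  # rate; or (shape, scale) for weibull
    censoring: str | None = "uniform"
    censoring_params: tuple = (0.0, 2190.0)  # (low, high); or (rate,) for exponential
    horizon: float = DEFAULT_HORIZON
    seed: int = 0
    name: str | None = None

    @property
    def n_features(self) -> int:
        return self.n_continuous + len(self.nominal_levels) + len(self.ordinal_levels)

    def validate(self):
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if not (self.horizon > 0):
            raise ValidationError("horizon must be > 0")
        if len(self.coefficients) != self.n_features:
            raise ValidationError(
                f"coefficient length {len(self.coefficients)} != feature count {self.n_features}"
            )
        if self.baseline == "exponential":
            if len(self.baseline_params) != 1 or self.baseline_params[0] <= 0:
                raise ValidationError("exponential baseline needs one positive rate")
        elif self.baseline == "weibull":
            if len(self.baseline_params) != 2 or min(self.baseline_params) <= 0:
                raise ValidationError("weibull baseline needs positive (shape, scale)")
        else:
            raise ValidationError(f"unknown baseline {self.baseline!r}")
        if self.censoring == "exponential" and self.censoring_params[0] <= 0:
            raise ValidationError("exponential censoring needs a positive rate")
        if self.censoring not in (None, "uniform", "exponential"):
            raise ValidationError(f"unknown censoring family {self.censoring!r}")


@dataclass
class GroundTruth:
    """Simulator-private truth, kept out of the cohort on purpose."""

    true_times: np.ndarray
    linear_predictor: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"true_time": self.true_times, "linear_predictor": self.linear_predictor}
        )


def _feature_block(cfg: SimulationConfig, rng: np.random.Generator, prefix: str = "x"):
    """Draw features; return (frame, schema specs, centered numeric matrix)."""
    cols, specs, numeric = {}, [], []
    for i in range(cfg.n_continuous):
        v = rng.normal(size=cfg.n_samples)
        name = f"{prefix}_cont{i}"
        cols[name] = v
        specs.append(FeatureSpec(name, CONTINUOUS, vmin=float(v.min()), vmax=float(v.max())))
        numeric.append(v)
    for i, L in enumerate(cfg.nominal_levels):
        codes = rng.integers(0, L, size=cfg.n_samples)
        levels = tuple(f"level{j}" for j in range(L))
        name = f"{prefix}_nom{i}"
        cols[name] = np.array(levels)[codes]
        specs.append(FeatureSpec(name, NOMINAL, levels=levels))
        numeric.append(codes - (L - 1) / 2.0)
    for i, L in enumerate(cfg.ordinal_levels):
        codes = rng.integers(0, L, size=cfg.n_samples)
        levels = tuple(f"grade{j}" for j in range(L))
        name = f"{prefix}_ord{i}"
        cols[name] = np.array(levels)[codes]
        specs.append(FeatureSpec(name, ORDINAL, levels=levels))
        numeric.append(codes - (L - 1) / 2.0)
    frame = pd.DataFrame(cols)
    return frame, specs, np.column_stack(numeric) if numeric else np.empty((cfg.n_samples, 0))


def _event_times(cfg: SimulationConfig, eta: np.ndarray, rng: np.random.Generator):
    u = rng.uniform(size=len(eta))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    if cfg.baseline == "exponential":
        (rate,) = cfg.baseline_params
        t = -np.log(u) / (rate * np.exp(eta))
    else:
        shape, scale = cfg.baseline_params
        t = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)
    return np.maximum(t, 1e-9)


def _censor_times(cfg: SimulationConfig, rng: np.random.Generator):
    if cfg.censoring is None:
        return np.full(cfg.n_samples, np.inf)
    if cfg.censoring == "uniform":
        low, high = cfg.censoring_params
        return rng.uniform(low, high, size=cfg.n_samples)
    (rate,) = cfg.censoring_params
    return rng.exponential(1.0 / rate, size=cfg.n_samples)


def simulate_cohort(config: SimulationConfig) -> tuple[SurvivalCohort, GroundTruth]:
    """Simulate one cohort; returns (cohort, ground truth)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_feat, rng_event, rng_cens = (np.random.default_rng(s) for s in ss)

    frame, specs, Z = _feature_block(config, rng_feat)
    eta = Z @ np.asarray(config.coefficients, dtype=float)
    if config.interaction is not None:
        a, b, coef = config.interaction
        eta = eta + coef * Z[:, int(a)] * Z[:, int(b)]

    t_event = _event_times(config, eta, rng_event)
    t_cens = _censor_times(config, rng_cens)
    cut = np.minimum(t_cens, config.horizon)
    observed = np.minimum(t_event, cut)
    event = t_event <= cut
    observed = np.maximum(observed, 1e-9)  # strict positivity even as horizon -> 0+

    cohort = SurvivalCohort(
        frame=frame,
        time=observed,
        event=event,
        schema=FeatureSchema(tuple(specs)),
        name=config.name,
    )
    return cohort, GroundTruth(true_times=t_event, linear_predictor=eta)


def simulate_multi_trial(
    configs: list[SimulationConfig], shared_fraction: float
) -> tuple[list[SurvivalCohort], list[GroundTruth]]:
    """Simulate several trials with a common shared feature block.

    ``shared_fraction`` of the first config's features (rounded, taken in
    feature order: continuous, then nominal, then ordinal) are shared by all
    trials under common names and identical true coefficients; each trial
    keeps the remainder of its own feature set as private features.  Follow-up
    horizons and censoring may differ per config, emulating trials with
    median follow-up as far apart as nine months versus nearly two years.
    """
    if len(configs) < 2:
        raise ValidationError("need at least two trial configs")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValidationError("shared_fraction must be within [0, 1]")

    ref = configs[0]
    n_shared = int(round(shared_fraction * ref.n_features))
    # split the reference feature layout into shared prefix counts per block
    n_sc = min(n_shared, ref.n_continuous)
    n_sn = min(max(n_shared - ref.n_continuous, 0), len(ref.nominal_levels))
    n_so = min(max(n_shared - ref.n_continuous - len(ref.nominal_levels), 0),
               len(ref.ordinal_levels))
    shared_coefs = ref.coefficients[: ref.n_continuous][:n_sc]
    shared_coefs += tuple(ref.coefficients[ref.n_continuous:][:n_sn])
    off = ref.n_continuous + len(ref.nominal_levels)
    shared_coefs += tuple(ref.coefficients[off:][:n_so])

    cohorts, truths = [], []
    for t, cfg in enumerate(configs):
        # private residue of this trial's own layout
        p_cont = max(cfg.n_continuous - n_sc, 0)
        p_nom = cfg.nominal_levels[n_sn:]
        p_ord = cfg.ordinal_levels[n_so:]
        priv_coefs = tuple(cfg.coefficients[: cfg.n_continuous][n_sc:])
        priv_coefs += tuple(cfg.coefficients[cfg.n_continuous:][n_sn: len(cfg.nominal_levels)])
        offt = cfg.n_continuous + len(cfg.nominal_levels)
        priv_coefs += tuple(cfg.coefficients[offt:][n_so:])

        eff = replace(
            cfg,
            n_continuous=n_sc + p_cont,
            nominal_levels=ref.nominal_levels[:n_sn] + tuple(p_nom),
            ordinal_levels=ref.ordinal_levels[:n_so] + tuple(p_ord),
            coefficients=tuple(shared_coefs[:n_sc]) + tuple(priv_coefs[:p_cont])
            + tuple(shared_coefs[n_sc:n_sc + n_sn]) + tuple(priv_coefs[p_cont:p_cont + len(p_nom)])
            + tuple(shared_coefs[n_sc + n_sn:]) + tuple(priv_coefs[p_cont + len(p_nom):]),
            name=cfg.name or f"trial{t}",
        )
        cohort, truth = simulate_cohort(eff)
        # rename: shared block keeps common names, private block gets a trial prefix
        mapping = {}
        ci = ni = oi = 0
        new_specs = []
        for spec in cohort.schema:
            if spec.kind == CONTINUOUS:
                new = f"shared_cont{ci}" if ci < n_sc else f"{eff.name}_cont{ci - n_sc}"
                ci += 1
            elif spec.kind == NOMINAL:
                new = f"shared_nom{ni}" if ni < n_sn else f"{eff.name}_nom{ni - n_sn}"
                ni += 1
            else:
                new = f"shared_ord{oi}" if oi < n_so else f"{eff.name}_ord{oi - n_so}"
                oi += 1
            mapping[spec.name] = new
            new_specs.append(replace(spec, name=new))
        cohort = SurvivalCohort(
            frame=cohort.frame.rename(columns=mapping),
            time=cohort.time,
            event=cohort.event,
            schema=FeatureSchema(tuple(new_specs)),
            name=eff.name,
        )
        cohorts.append(cohort)
        truths.append(truth)
    return cohorts, truths


def write_ground_truth(truth: GroundTruth, path):
    """Sidecar writer; keeps simulator truth clearly apart from the cohort."""
    truth.to_frame().to_csv(path, index=False)
    return path
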