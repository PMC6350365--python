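"""Synthetic PDX trial generator with known ground truth.

Tumor volumes follow a stochastic exponential (log-linear) growth kernel:

    V_a(t) = V_a(0) * exp((g_tumor + g_animal - e_arm) * t) * eps_a(t)

with a lognormal baseline V_a(0), a per-tumor growth rate g_tumor drawn
across tumors (inter-tumor heterogeneity), a per-animal deviation g_animal
within each tumor (intra-tumor heterogeneity), an additive per-day reduction
e_arm of the log growth rate for each treatment arm (0 for vehicle), and
multiplicative lognormal measurement noise eps.  Body weight is generated the
same way around a 20 g baseline with a mild arm-specific trend.

The default configuration emulates a single-tumor trial with five treatment
arms plus vehicle, eight animals per arm, measured every 3 days for 3 weeks.
All randomness derives from ``seed``; the same seed reproduces the dataset
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trial_data import TrialDataset, TrialDataError

__all__ = ["SimConfig", "simulate_trial", "simulate_null"]

CONTROL_ARM = "Vehicle"


def _default_days() -> tuple[float, ...]:
    return tuple(float(d) for d in range(0, 22, 3))


def _default_arm_effects() -> dict[str, float]:
    # graded efficacy: from ineffective to regression-inducing
    return {
        CONTROL_ARM: 0.0,
        "Treatment_1": 0.01,
        "Treatment_2": 0.03,
        "Treatment_3": 0.05,
        "Treatment_4": 0.08,
        "Treatment_5": 0.12,
    }


@dataclass
class SimConfig:
    """Trial-design and growth parameters of the generator.

    Rates are per-day log-growth: the vehicle default 0.09/day doubles a
    tumor in about 8 days, typical of an aggressive xenograft.  ``baseline_mean``
    of 200 mm^3 matches a common enrollment size.  CVs are fractional.
    """

    pattern: str = "1AN"
    n_tumors: int = 1
    n_arms: int = 5                    # treatment arms, control added on top
    n_animals: int = 8                 # animals per tumor-by-arm cell
    days: tuple[float, ...] = field(default_factory=_default_days)
    baseline_mean: float = 200.0       # mm^3
    baseline_cv: float = 0.25
    tumor_growth_mean: float = 0.09    # per day
    tumor_growth_sd: float = 0.02      # across tumors
    animal_growth_sd: float = 0.02     # across animals within a tumor
    arm_effects: dict[str, float] = field(default_factory=_default_arm_effects)
    noise_cv: float = 0.08
    seed: int | None = None

    def validated(self) -> "SimConfig":
        bad = []
        if self.pattern not in ("1AN", "T1N", "TA1", "TAN"):
            bad.append("pattern")
        if self.n_tumors < 1:
            bad.append("n_tumors")
        if self.n_arms < 1:
            bad.append("n_arms")
        if self.n_animals < 1:
            bad.append("n_animals")
        if len(self.days) < 2 or self.days[0] != 0 or any(
            b <= a for a, b in zip(self.days, self.days[1:])
        ):
            bad.append("days")
        if self.baseline_mean <= 0:
            bad.append("baseline_mean")
        if min(self.baseline_cv, self.tumor_growth_sd,
               self.animal_growth_sd, self.noise_cv) < 0:
            bad.append("sds_cvs")
        if self.arm_effects.get(CONTROL_ARM, 0.0) != 0.0:
            bad.append("arm_effects (control must be 0)")
        if bad:
            raise TrialDataError(f"invalid simulation config field(s): {bad}")
        return self

    def resolved_arms(self) -> list[str]:
        """Arm labels actually simulated, control first."""
        n_treat = 1 if self.pattern == "T1N" else self.n_arms
        treats = [a for a in self.arm_effects if a != CONTROL_ARM]
        while len(treats) < n_treat:
            treats.append(f"Treatment_{len(treats) + 1}")
        return [CONTROL_ARM] + treats[:n_treat]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal samples with the given arithmetic mean and CV."""
    if cv == 0:
        return mean if size is None else np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_trial(cfg: SimConfig) -> TrialDataset:
    """Generate one trial under ``cfg``; see the module docstring for the model."""
    cfg = cfg.validated()
    rng = np.random.default_rng(cfg.seed)
    arms = cfg.resolved_arms()
    n_tumors = 1 if cfg.pattern == "1AN" else cfg.n_tumors
    n_animals = 1 if cfg.pattern == "TA1" else cfg.n_animals
    days = np.asarray(cfg.days, dtype=float)

    rows = []
    for ti in range(n_tumors):
        tumor = f"PDX_{ti + 1:02d}"
        g_tumor = rng.normal(cfg.tumor_growth_mean, cfg.tumor_growth_sd)
        for arm in arms:
            e_arm = cfg.arm_effects.get(arm, 0.0)
            for ai in range(n_animals):
                animal = f"{tumor}-{arm}-m{ai + 1}"
                v0 = _lognormal(rng, cfg.baseline_mean, cfg.baseline_cv, None)
                g_animal = rng.normal(0.0, cfg.animal_growth_sd)
                eps = _lognormal(rng, 1.0, cfg.noise_cv, len(days))
                vol = v0 * np.exp((g_tumor + g_animal - e_arm) * days) * eps
                vol[0] = v0  # baseline measured at enrollment, noise-free
                # body weight: mild treatment-dependent drift around 20 g
                bw0 = rng.normal(20.0, 1.5)
                bw_trend = -0.01 * e_arm / 0.05 if e_arm > 0 else 0.005
                bw_eps = _lognormal(rng, 1.0, 0.01, len(days))
                bw = bw0 * np.exp(bw_trend * days / 21.0) * bw_eps
                for d, v, w in zip(days, vol, bw):
                    rows.append((tumor, "synthetic", arm, animal, d, v, w))
    df = pd.DataFrame(
        rows,
        columns=["tumor_id", "tumor_type", "arm", "animal_id", "day",
                 "volume", "body_weight"],
    )
    return TrialDataset(
        df,
        control_arm=CONTROL_ARM,
        meta={"source": "simulate_trial", "config": cfg, "pattern": cfg.pattern},
    )


def simulate_null(cfg: SimConfig) -> TrialDataset:
    """As :func:`simulate_trial` with every arm effect forced to zero.

    Arms are then exchangeable, which is the ground truth needed for type-I
    error and p-value calibration studies.
    """
    null_effects = {arm: 0.0 for arm in cfg.resolved_arms()}
    return simulate_trial(replace(cfg, arm_effects=null_effects))
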