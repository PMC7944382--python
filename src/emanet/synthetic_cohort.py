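"""Synthetic inpatient EMA cohorts with planted, recoverable structure.

The generator emulates the data structure of a psychiatric-inpatient EMA
study: each participant stays 2-46 days (lognormal length of stay, mean ~6.9
days), receives 4 or 6 prompts per day in a 12-hour waking window, and rates
three items (desire to kill oneself, intent, ability to resist the urge) on
a 0-9 scale whenever they answer.

The latent ideation trajectory is a mean-reverting AR(1) with transient
jumps:

    x_t = mu_i + phi * (x_{t-1} - mu_i) + sigma_i * eps_t + J_t

where J_t is a jump of magnitude Uniform(lo, hi) with random sign occurring
with per-prompt probability pi_i.  Jumps enter like innovations, producing
the large observation-to-next shifts that the probability-of-acute-change
feature targets.  Item 1 (desire) observes x_t with rounding noise, item 2
(intent) an attenuated copy, item 3 (resist urge) the reversed scale
9 - x_t.  Nonresponse is severity-linked (missing-not-at-random capable):
each prompt goes unanswered with probability
logistic(d0 + d_sev * x_t + d_person * u_i).  The binary post-discharge
outcome follows

    P(attempt) = logistic(g0 + g_jump * pi_i + g_mean * mu_i
                          + g_noncompliance * (1 - compliance_i))

so jump propensity, average severity, and missingness can each carry signal.
Baseline SITB-style predictors are noisy monotone transforms of mu_i, making
the baseline design informative but weaker than the EMA designs.

True latent parameters are retained on the cohort so tests can verify
planted-signal recovery.  One master seed drives one RNG stream per
participant (spawned seed sequences), so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .baseline_features import BASELINE_COLUMNS
from .ema_data import EmaSeries, ITEM_COLUMNS


class CalibrationError(ValueError):
    """The configured outcome model cannot reach the target base rate."""


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults emulate the study design.

    ``outcome_coefs`` = (g0, g_jump, g_mean, g_noncompliance) on the logit
    scale; ``missingness_coefs`` = (d0, d_severity, d_person) give the logit
    of *non*response.  ``prompts_per_day`` may be a single integer or a
    (4, 6) pair assigned per participant with probability
    ``wave1_fraction`` of receiving the first entry.
    """

    n_participants: int = 104
    stay_days_log_mean: float = 1.6926  # lognormal approximating mean 6.9, SD 5.4 d
    stay_days_log_sd: float = 0.6912
    stay_days_bounds: tuple = (2, 46)
    prompts_per_day: int | tuple = (4, 6)
    wave1_fraction: float = 45 / 104
    ar_coef: float = 0.5
    person_mean_dist: tuple = (3.0, 1.8)  # Normal(loc, scale) for mu_i, clipped to [0, 9]
    person_vol_dist: tuple = (2.0, 3.3)  # Gamma(shape, rate) for sigma_i: mean 0.61, SD 0.43
    jump_prob_dist: tuple = (1.5, 8.5)  # Beta(a, b) for pi_i
    jump_magnitude_range: tuple = (3.0, 6.0)
    item_noise_sd: float = 0.5
    intent_attenuation: float = 0.8
    outcome_coefs: tuple = (-4.5, 8.0, 0.35, 2.0)
    missingness_coefs: tuple = (-0.55, 0.12, 1.0)
    disengage_prob: float = 0.22  # mixture weight of the non-engaging subgroup in u_i
    disengage_shift: float = 3.0  # location shift of u_i for that subgroup
    baseline_missing_rate: float = 0.0216
    n_baseline_nonrespondents: int = 1
    target_base_rate: float | None = 0.108
    jitter_prompts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.stay_days_log_sd <= 0 or self.person_mean_dist[1] <= 0:
            raise ValueError("scales must be positive")
        if min(self.person_vol_dist) <= 0 or min(self.jump_prob_dist) <= 0:
            raise ValueError("Gamma/Beta parameters must be positive")
        lo, hi = self.jump_magnitude_range
        if lo > hi or lo < 0:
            raise ValueError("jump_magnitude_range must be ordered and nonnegative")
        d0, d1 = self.stay_days_bounds
        if d0 > d1 or d0 < 1:
            raise ValueError("stay_days_bounds must be ordered, >= 1 day")
        if self.item_noise_sd < 0:
            raise ValueError("item_noise_sd must be nonnegative")
        ppd = self.prompts_per_day
        for v in (ppd,) if isinstance(ppd, int) else tuple(ppd):
            if v < 1:
                raise ValueError("prompts_per_day must be >= 1")
        if self.target_base_rate is not None and not 0 < self.target_base_rate < 1:
            raise ValueError("target_base_rate must lie strictly in (0, 1)")
        if not 0 <= self.disengage_prob < 1:
            raise ValueError("disengage_prob must lie in [0, 1)")

    def replace(self, **kw) -> "CohortConfig":
        d = asdict(self)
        d.update(kw)
        return CohortConfig(**d)


@dataclass
class SyntheticCohort:
    """A generated cohort: EMA series, baseline table, outcomes, true latents."""

    series: list
    baseline: pd.DataFrame  # 20 SITB-like columns, NaN where missing
    outcomes: dict  # participant_id -> 0/1
    latents: pd.DataFrame  # mu, sigma, pi, u, compliance, p_outcome per participant
    config: CohortConfig = field(repr=False, default=None)

    def __iter__(self):
        return iter(self.series)

    def outcome_vector(self, series=None) -> np.ndarray:
        series = self.series if series is None else series
        return np.array([self.outcomes[s.participant_id] for s in series], dtype=int)


def _draw_stay_days(rng, config) -> int:
    lo, hi = config.stay_days_bounds
    for _ in range(1000):
        d = rng.lognormal(config.stay_days_log_mean, config.stay_days_log_sd)
        if lo <= d <= hi:
            return int(round(d))
    raise ValueError("length-of-stay truncation region has negligible mass")


def _latent_trajectory(rng, config, mu, sigma, pi, n_prompts) -> np.ndarray:
    phi = config.ar_coef
    lo, hi = config.jump_magnitude_range
    x = np.empty(n_prompts)
    prev = mu  # stationary start
    for t in range(n_prompts):
        eps = rng.normal(0.0, 1.0)
        jump = 0.0
        if rng.random() < pi:
            jump = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
        prev = mu + phi * (prev - mu) + sigma * eps + jump
        x[t] = prev
    return x


def _observe_items(rng, config, x) -> dict:
    noise = config.item_noise_sd
    n = x.size
    obs = {}
    obs["desire"] = np.clip(np.round(x + rng.normal(0, noise, n)), 0, 9)
    obs["intent"] = np.clip(np.round(config.intent_attenuation * x + rng.normal(0, noise, n)), 0, 9)
    obs["resist_urge"] = np.clip(np.round(9.0 - x + rng.normal(0, noise, n)), 0, 9)
    return obs


def _prompt_times(config, rng, days, ppd) -> pd.DatetimeIndex:
    """Evenly spaced prompts in a 12-hour waking window starting 09:00."""
    base = pd.Timestamp("2016-01-01 09:00:00")
    times = []
    step = 12.0 / ppd
    for d in range(days):
        for j in range(ppd):
            offset = (j + 0.5) * step
            if config.jitter_prompts:
                offset += rng.uniform(-0.4, 0.4) * step
            times.append(base + pd.Timedelta(days=d, hours=offset))
    return pd.DatetimeIndex(times)


def _baseline_row(rng, mu) -> dict:
    """20 SITB-like values as noisy monotone transforms of latent severity.

    A shared per-person reporting distortion is added to severity before the
    item transforms: retrospective self-report error is largely a property
    of the respondent, so averaging the 20 items cannot undo it.  This keeps
    the baseline design informative about mu but clearly weaker than direct
    EMA measurement.
    """
    row = {}
    weights = {"thoughts": 1.0, "plan": 0.8, "attempt": 0.7, "nssi": 0.4}
    offsets = {"thoughts": 2.0, "plan": 0.8, "attempt": 0.6, "nssi": -0.5}
    distortion = rng.normal(0.0, 2.0)  # person-level recall/response-style bias
    for b, w in weights.items():
        sev = w * (mu + distortion - 3.0)
        row[f"{b}_lifetime"] = float(rng.random() < expit(offsets[b] + 0.7 * sev + rng.normal(0, 1.5)))
        lam_year = np.exp(1.0 + 0.3 * sev + rng.normal(0, 1.1))
        row[f"{b}_freq_year"] = float(rng.poisson(lam_year))
        row[f"{b}_freq_month"] = float(rng.poisson(lam_year / 4.0))
        row[f"{b}_freq_week"] = float(rng.poisson(lam_year / 12.0))
        row[f"{b}_likelihood"] = float(np.clip(np.round(2.0 + 0.4 * sev + rng.normal(0, 1.4)), 0, 4))
    return row


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a full cohort under ``config``.

    Raises :class:`CalibrationError` when ``target_base_rate`` is set and the
    expected outcome rate of the generated cohort misses it by more than
    0.05 -- run :func:`calibrate_intercept` first rather than silently
    generating a cohort with the wrong event rate.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_participants + 1)
    cohort_rng = np.random.default_rng(streams[-1])
    g0, g_jump, g_mean, g_nc = config.outcome_coefs
    d0, d_sev, d_person = config.missingness_coefs

    series, rows, latents = [], [], []
    ids = [f"P{i + 1:03d}" for i in range(config.n_participants)]
    for i, pid in enumerate(ids):
        rng = np.random.default_rng(streams[i])
        days = _draw_stay_days(rng, config)
        if isinstance(config.prompts_per_day, int):
            ppd = config.prompts_per_day
        else:
            lo_ppd, hi_ppd = config.prompts_per_day
            ppd = lo_ppd if rng.random() < config.wave1_fraction else hi_ppd
        mu = float(np.clip(rng.normal(*config.person_mean_dist), 0.0, 9.0))
        shape, rate = config.person_vol_dist
        sigma = float(rng.gamma(shape, 1.0 / rate))
        a, b = config.jump_prob_dist
        pi = float(rng.beta(a, b))
        u = float(rng.normal())
        if rng.random() < config.disengage_prob:
            u += config.disengage_shift
        n_prompts = days * ppd
        x = _latent_trajectory(rng, config, mu, sigma, pi, n_prompts)
        p_miss = expit(d0 + d_sev * x + d_person * u)
        answered = rng.random(n_prompts) >= p_miss
        obs = _observe_items(rng, config, x)
        records = pd.DataFrame({
            "prompt_index": np.arange(n_prompts),
            "timestamp": _prompt_times(config, rng, days, ppd),
            "answered": answered,
        })
        for item in ITEM_COLUMNS:
            records[item] = np.where(answered, obs[item], np.nan)
        s = EmaSeries(pid, records, n_scheduled=n_prompts)
        series.append(s)
        compliance = answered.mean()
        p_outcome = float(expit(g0 + g_jump * pi + g_mean * mu + g_nc * (1.0 - compliance)))
        y = int(rng.random() < p_outcome)
        latents.append({"participant_id": pid, "mu": mu, "sigma": sigma, "pi": pi,
                        "u": u, "compliance": compliance, "p_outcome": p_outcome,
                        "outcome": y, "stay_days": days, "prompts_per_day": ppd})
        row = _baseline_row(rng, mu)
        miss_mask = rng.random(len(BASELINE_COLUMNS)) < config.baseline_missing_rate
        for col, m in zip(BASELINE_COLUMNS, miss_mask):
            if m:
                row[col] = np.nan
        row["participant_id"] = pid
        rows.append(row)

    latents = pd.DataFrame(latents).set_index("participant_id")
    if config.target_base_rate is not None:
        included_mask = np.array([s.n_completed >= 3 for s in series])
        expected = latents["p_outcome"].to_numpy()[included_mask].mean()
        if abs(expected - config.target_base_rate) > 0.05:
            raise CalibrationError(
                f"expected outcome rate {expected:.3f} misses target "
                f"{config.target_base_rate:.3f} by more than 0.05; "
                "run calibrate_intercept on this config first")
    baseline = pd.DataFrame(rows).set_index("participant_id")[list(BASELINE_COLUMNS)]
    if config.n_baseline_nonrespondents > 0:
        skip = cohort_rng.choice(ids, size=config.n_baseline_nonrespondents, replace=False)
        baseline.loc[list(skip)] = np.nan
    outcomes = dict(zip(latents.index, latents["outcome"].astype(int)))
    return SyntheticCohort(series, baseline, outcomes, latents, config)


def _mc_linear_predictors(config: CohortConfig, n_mc: int, seed_offset: int = 101,
                          min_completed: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo sample of (outcome linear predictor minus g0, inclusion mask).

    Response indicators are sampled per prompt exactly as in the generator,
    so compliance and the >= ``min_completed`` inclusion rule have the same
    distribution here as in generated cohorts; vectorized over participants
    per time step.
    """
    _, g_jump, g_mean, g_nc = config.outcome_coefs
    d0, d_sev, d_person = config.missingness_coefs
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_offset]))
    mu = np.clip(rng.normal(*config.person_mean_dist, n_mc), 0.0, 9.0)
    shape, rate = config.person_vol_dist
    sigma = rng.gamma(shape, 1.0 / rate, n_mc)
    a, b = config.jump_prob_dist
    pi = rng.beta(a, b, n_mc)
    u = rng.normal(size=n_mc)
    u += np.where(rng.random(n_mc) < config.disengage_prob, config.disengage_shift, 0.0)
    if isinstance(config.prompts_per_day, int):
        ppd = np.full(n_mc, config.prompts_per_day)
    else:
        lo_ppd, hi_ppd = config.prompts_per_day
        ppd = np.where(rng.random(n_mc) < config.wave1_fraction, lo_ppd, hi_ppd)
    days = np.clip(
        np.round(rng.lognormal(config.stay_days_log_mean, config.stay_days_log_sd, n_mc)),
        *config.stay_days_bounds)
    n_prompts = (days * ppd).astype(int)
    t_max = int(n_prompts.max())
    phi = config.ar_coef
    lo, hi = config.jump_magnitude_range
    x = mu.copy()
    n_answered = np.zeros(n_mc)
    for t in range(t_max):
        eps = rng.normal(size=n_mc)
        jump_on = rng.random(n_mc) < pi
        jump = np.where(jump_on,
                        rng.uniform(lo, hi, n_mc) * np.where(rng.random(n_mc) < 0.5, 1.0, -1.0),
                        0.0)
        x = mu + phi * (x - mu) + sigma * eps + jump
        live = t < n_prompts
        answered = rng.random(n_mc) >= expit(d0 + d_sev * x + d_person * u)
        n_answered += np.where(live & answered, 1.0, 0.0)
    compliance = n_answered / n_prompts
    included = n_answered >= min_completed
    return g_jump * pi + g_mean * mu + g_nc * (1.0 - compliance), included


def calibrate_intercept(config: CohortConfig, n_mc: int = 10_000) -> CohortConfig:
    """Adjust g0 so the expected outcome rate hits ``target_base_rate``.

    Monte-Carlo root-finding: draws ``n_mc`` participants' latent parameters
    and expected compliance, then solves mean(logistic(g0 + s_i)) = target
    for g0 by Brent's method.  Returns a new config; raises for unreachable
    targets (0 or 1 are outside the logistic range) or non-convergence.
    """
    config.validate()
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000 for stable calibration")
    target = config.target_base_rate
    if target is None:
        raise ValueError("config has no target_base_rate to calibrate to")
    if not 0 < target < 1:
        raise CalibrationError(f"target base rate {target} unreachable on the logit scale")
    s, included = _mc_linear_predictors(config, n_mc)
    s = s[included]  # the reported base rate conditions on study inclusion

    def rate_gap(g0):
        return expit(g0 + s).mean() - target

    lo, hi = -40.0, 40.0
    if rate_gap(lo) > 0 or rate_gap(hi) < 0:
        raise CalibrationError("no intercept in [-40, 40] reaches the target base rate")
    g0 = brentq(rate_gap, lo, hi, xtol=1e-10, maxiter=200)
    if abs(rate_gap(g0)) > 0.005:
        raise CalibrationError("intercept calibration did not converge")
    coefs = (float(g0),) + tuple(config.outcome_coefs[1:])
    return config.replace(outcome_coefs=coefs)


def expected_base_rate(config: CohortConfig, n_mc: int = 10_000, seed_offset: int = 202) -> float:
    """Monte-Carlo expected outcome rate among included participants (fresh draw)."""
    s, included = _mc_linear_predictors(config, n_mc, seed_offset=seed_offset)
    return float(expit(config.outcome_coefs[0] + s[included]).mean())
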