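"""Synthetic evidence networks with known ground truth.

The real evidence base behind a comparative-effectiveness NMA is a set of
published trial summaries; none of it ships with this package. These
generators emulate its statistical shape - sparse connected networks
where most comparisons are informed by a single trial, contrast-level
log-HRs with between-trial heterogeneity, binomial response arms,
rare-event adverse-event arms with heterogeneous follow-up, and
exponential survival data "digitized" into KM curves - and always emit a
truth record sufficient to score recovery.

Topologies are star-plus-random-chords: a spanning star against the
reference guarantees connectivity, remaining trials are random chords.
One master seed drives fixed per-component substreams, so adding a
generator never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .effects import ContrastRecord
from .km import KMCurve, PseudoIPD, cox_loghr
from .network import TrialArm
from .plnma import AEArmRecord

__all__ = [
    "SimulationScenario",
    "simulate_contrast_network",
    "simulate_binary_network",
    "simulate_ae_network",
    "simulate_km_trial",
    "paper_shaped_scenario",
    "PAPER_SHAPED_DIMENSIONS",
]

# per-component substream keys (stable: new components append, never reuse)
_STREAM = {"design": 0, "contrast": 1, "binary": 2, "ae": 3, "km": 4}

# published-network dimensions used for regression-shaped fixtures:
# outcome -> (n_trials, n_treatments)
PAPER_SHAPED_DIMENSIONS = {
    "rpfs": (13, 14),
    "os": (20, 18),
    "psa_response": (26, 25),
    "tt_chemo": (7, 6),
    "ae_anemia": (12, 11),
}


@dataclass(frozen=True)
class SimulationScenario:
    """Generator settings; defaults emulate a sparse oncology NMA.

    ``true_d`` holds effects vs the reference on the log scale (entry 0 is
    the reference and must be 0); ``tau`` is the between-trial SD;
    ``se_range`` the within-trial SEs of extracted log-HRs; ``arm_n_range``
    per-arm sample sizes; ``baseline_logit_range`` control-arm response
    levels on the logit scale; ``ae_rate_range`` monthly event rates
    (rare-event regime by default); ``follow_up_range`` trial follow-up in
    months.
    """

    n_treatments: int = 5
    n_trials: int = 12
    true_d: tuple[float, ...] | None = None
    tau: float = 0.2
    se_range: tuple[float, float] = (0.1, 0.3)
    arm_n_range: tuple[int, int] = (100, 400)
    baseline_logit_range: tuple[float, float] = (-2.0, -0.5)
    ae_rate_range: tuple[float, float] = (0.0005, 0.002)
    follow_up_range: tuple[float, float] = (12.0, 36.0)
    seed: int = 0
    outcome: str = "os"

    def __post_init__(self):
        if self.n_trials < self.n_treatments - 1:
            raise ValueError(
                f"{self.n_trials} two-arm trials cannot connect "
                f"{self.n_treatments} treatments"
            )
        for rng_ in (self.se_range, self.arm_n_range, self.baseline_logit_range,
                     self.ae_rate_range, self.follow_up_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range {rng_} is not ordered")
        if self.se_range[0] <= 0 or self.ae_rate_range[0] <= 0 \
                or self.follow_up_range[0] <= 0:
            raise ValueError("scale ranges must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.true_d is not None:
            if len(self.true_d) != self.n_treatments:
                raise ValueError("true_d must have one entry per treatment")
            if self.true_d[0] != 0.0:
                raise ValueError("true_d[0] is the reference and must be 0")

    def rng(self, component: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAM[component],))
        return np.random.default_rng(ss)

    def effects(self) -> np.ndarray:
        if self.true_d is not None:
            return np.asarray(self.true_d, float)
        d = np.linspace(-0.5, 0.5, self.n_treatments)
        d[0] = 0.0
        return d

    def treatment_ids(self) -> list[str]:
        return [f"T{k:02d}" for k in range(self.n_treatments)]


def _design_pairs(scenario: SimulationScenario) -> list[tuple[int, int]]:
    """(baseline, treatment) index pairs per trial: star then random chords."""
    rng = scenario.rng("design")
    K, n = scenario.n_treatments, scenario.n_trials
    pairs = [(0, k) for k in range(1, K)]
    while len(pairs) < n:
        a, b = rng.choice(K, size=2, replace=False)
        pairs.append((int(min(a, b)), int(max(a, b))))
    return pairs[:n]


def simulate_contrast_network(scenario: SimulationScenario,
                              replicates: int | None = None):
    """Contrast-level log-HR records with known truth.

    Trial-specific effects delta ~ N(d_k - d_b, tau^2); observed
    y ~ N(delta, se^2) with se drawn uniformly from ``se_range``.
    Returns (records, truth). With ``replicates`` set, returns
    (list of record sets, truth): independent datasets over one shared
    design, as calibration studies need.
    """
    rng = scenario.rng("contrast")
    d = scenario.effects()
    ids = scenario.treatment_ids()
    pairs = _design_pairs(scenario)
    all_records, all_deltas, all_ses = [], [], []
    for _ in range(replicates or 1):
        records, deltas, ses = [], [], []
        for i, (b, k) in enumerate(pairs):
            se = rng.uniform(*scenario.se_range)
            delta = rng.normal(d[k] - d[b], scenario.tau)
            y = rng.normal(delta, se)
            records.append(ContrastRecord(
                trial_id=f"trial{i:03d}", outcome=scenario.outcome,
                treatment=ids[k], baseline_treatment=ids[b],
                log_effect=float(y), se=float(se), effect_scale="log_hr",
            ))
            deltas.append(delta)
            ses.append(se)
        all_records.append(records)
        all_deltas.append(deltas)
        all_ses.append(ses)
    truth = {
        "treatments": ids, "true_d": d.tolist(), "tau": scenario.tau,
        "pairs": pairs, "deltas": all_deltas if replicates else all_deltas[0],
        "ses": all_ses if replicates else all_ses[0],
    }
    if replicates:
        return all_records, truth
    return all_records[0], truth


def simulate_binary_network(scenario: SimulationScenario):
    """Arm-level binomial response records with known truth.

    Baseline logits mu_i are uniform on ``baseline_logit_range``; the
    non-baseline arm adds delta ~ N(d_k - d_b, tau^2); responders are
    binomial.
    """
    rng = scenario.rng("binary")
    d = scenario.effects()
    ids = scenario.treatment_ids()
    pairs = _design_pairs(scenario)
    records, mus, deltas = [], [], []
    for i, (b, k) in enumerate(pairs):
        tid = f"trial{i:03d}"
        mu = rng.uniform(*scenario.baseline_logit_range)
        delta = rng.normal(d[k] - d[b], scenario.tau)
        for treat, eta in ((ids[b], mu), (ids[k], mu + delta)):
            n = int(rng.integers(scenario.arm_n_range[0], scenario.arm_n_range[1] + 1))
            p = 1.0 / (1.0 + np.exp(-eta))
            r = int(rng.binomial(n, p))
            records.append(TrialArm(trial_id=tid, treatment=treat, n=n, events=r))
        mus.append(mu)
        deltas.append(delta)
    truth = {
        "treatments": ids, "true_d": d.tolist(), "tau": scenario.tau,
        "pairs": pairs, "mus": mus, "deltas": deltas,
    }
    return records, truth


def simulate_ae_network(scenario: SimulationScenario, rare: bool = True):
    """Adverse-event arms with trial follow-up offsets and known truth.

    Per-arm event probability p = 1 - exp(-f_i * rate_k) with
    rate_k = base_rate_i * exp(d_k - d_b); in the rare-event regime
    (default) base rates are capped so p <= 0.02 in every arm.
    """
    rng = scenario.rng("ae")
    d = scenario.effects()
    ids = scenario.treatment_ids()
    pairs = _design_pairs(scenario)
    records, rates, fups = [], [], []
    for i, (b, k) in enumerate(pairs):
        tid = f"trial{i:03d}"
        f = float(rng.uniform(*scenario.follow_up_range))
        base_rate = float(rng.uniform(*scenario.ae_rate_range))
        if rare:
            # keep every arm's probability in the rare regime
            cap = -np.log(1.0 - 0.02) / (f * np.exp(abs(d[k] - d[b])))
            base_rate = min(base_rate, float(cap))
        for treat, dk in ((ids[b], 0.0), (ids[k], d[k] - d[b])):
            rate = base_rate * float(np.exp(dk))
            p = 1.0 - float(np.exp(-f * rate))
            n = int(rng.integers(scenario.arm_n_range[0], scenario.arm_n_range[1] + 1))
            ev = int(rng.binomial(n, p))
            records.append(AEArmRecord(
                trial_id=tid, treatment=treat, events=ev, n=n,
                follow_up=f, outcome=scenario.outcome,
            ))
            rates.append(rate)
        fups.append(f)
    truth = {
        "treatments": ids, "true_d": d.tolist(), "pairs": pairs,
        "rates": rates, "follow_ups": fups,
    }
    return records, truth


def _digitize(ipd: PseudoIPD, censor_time: float, click_points: int,
              risk_interval: float) -> KMCurve:
    """Sample the true product-limit curve at evenly spaced click times and
    read the number at risk off the data at risk-table times."""
    from .km import km_survival_at

    times = np.linspace(0.0, censor_time, click_points)
    surv = km_survival_at(ipd, times)
    points = list(zip(times.tolist(), surv.tolist()))
    risk_times = np.arange(0.0, censor_time + 1e-9, risk_interval)
    risk = [(float(t), int((ipd.times >= t - 1e-12).sum())) for t in risk_times]
    return KMCurve(points=points, risk_table=risk)


def simulate_km_trial(
    n_per_arm: int = 200,
    true_hr: float = 0.7,
    base_rate: float = 0.1,
    censor_time: float = 24.0,
    click_points: int = 100,
    risk_interval: float = 6.0,
    seed: int = 0,
):
    """A two-arm exponential survival trial, digitized.

    Arm "a" (treatment) has hazard ``base_rate * true_hr``; arm "b"
    (control) has hazard ``base_rate`` per month; both are
    administratively censored at ``censor_time``. Returns
    (curve_a, curve_b, ipd_a, ipd_b, truth) where truth carries the true
    log-HR and the Cox estimate on the true IPD (the quantity a
    reconstruction should recover).
    """
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAM["km"],))
    rng = np.random.default_rng(ss)

    def draw_arm(rate: float) -> PseudoIPD:
        t = rng.exponential(1.0 / rate, size=n_per_arm)
        status = (t <= censor_time).astype(int)
        t = np.minimum(t, censor_time)
        return PseudoIPD(t, status)

    ipd_a = draw_arm(base_rate * true_hr)
    ipd_b = draw_arm(base_rate)
    curve_a = _digitize(ipd_a, censor_time, click_points, risk_interval)
    curve_b = _digitize(ipd_b, censor_time, click_points, risk_interval)
    loghr_true_ipd, se_true_ipd = cox_loghr(ipd_a, ipd_b)
    truth = {
        "true_log_hr": float(np.log(true_hr)),
        "cox_log_hr_true_ipd": loghr_true_ipd,
        "cox_se_true_ipd": se_true_ipd,
        "n_events_a": ipd_a.n_events,
        "n_events_b": ipd_b.n_events,
    }
    return curve_a, curve_b, ipd_a, ipd_b, truth


def paper_shaped_scenario(outcome: str, seed: int = 0,
                          **overrides) -> SimulationScenario:
    """A scenario matching a published network's dimensions.

    ``outcome`` is one of ``PAPER_SHAPED_DIMENSIONS`` (e.g. "os" gives 20
    trials over 18 treatments). Remaining settings keep their defaults
    unless overridden.
    """
    if outcome not in PAPER_SHAPED_DIMENSIONS:
        raise KeyError(f"no paper-shaped dimensions for outcome {outcome!r}")
    n_trials, n_treatments = PAPER_SHAPED_DIMENSIONS[outcome]
    return SimulationScenario(
        n_treatments=n_treatments, n_trials=n_trials, outcome=outcome,
        seed=seed, **overrides,
    )
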