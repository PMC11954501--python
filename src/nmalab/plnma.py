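"""Penalized-likelihood NMA for rare adverse events (frequentist, fixed effect).

Safety outcomes are rare-event counts observed over trial-specific
follow-up: a longer trial accrues more events, so raw odds ratios are not
comparable. The model is a fixed-effect binomial GLM with complementary
log-log link and a log follow-up offset,

    cloglog(p_ik) = ln(f_i) + mu_i + (d_k - d_b(i)),

so that exp(d) is a discrete hazard ratio (a rate ratio under constant
hazards: p = 1 - exp(-f * rate)). Maximum likelihood is badly biased -
and often divergent - when arms have zero events; the Firth/Jeffreys
penalty ``+ 1/2 ln det I(theta)`` removes the leading-order bias and
keeps every estimate finite, which is why the penalized fit is the
default. The unpenalized fit is retained behind ``penalty="none"`` (it
matches any standard GLM implementation when no cell is empty).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import EvidenceNetwork

logger = logging.getLogger("nmalab")

__all__ = ["AEArmRecord", "PlFitResult", "fit_pl_cloglog", "relative_discrete_hazards"]

_SCORE_TOL = 1e-8
_MAX_ITER = 100


@dataclass(frozen=True)
class AEArmRecord:
    """One trial arm's adverse-event count over its follow-up (months)."""

    trial_id: str
    treatment: str
    events: int
    n: int
    follow_up: float | None = None
    outcome: str = "ae"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"trial {self.trial_id}: n must be >= 1")
        if not (0 <= self.events <= self.n):
            raise ValueError(f"trial {self.trial_id}: events outside [0, n]")
        if self.follow_up is not None and self.follow_up <= 0:
            raise ValueError(f"trial {self.trial_id}: follow_up must be > 0")


@dataclass
class PlFitResult:
    """Estimates on the log discrete-hazard scale with their covariance."""

    treatments: list[str]           # reference first
    d_hat: np.ndarray               # per non-reference treatment
    cov: np.ndarray                 # covariance of d_hat
    mu_hat: dict[str, float]
    converged: bool
    iterations: int
    penalty: str
    loglik: float
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        z = 1.959963984540054
        return pd.DataFrame({
            "treatment": self.treatments[1:],
            "log_dhr": self.d_hat,
            "se": se,
            "dhr": np.exp(self.d_hat),
            "lo95": np.exp(self.d_hat - z * se),
            "hi95": np.exp(self.d_hat + z * se),
        })


def _design(network: EvidenceNetwork, records):
    """Arm-level design: columns [mu per trial | d per non-reference treatment]."""
    treatments = network.treatment_ids()
    index = {t: i for i, t in enumerate(treatments)}
    by_trial: dict[str, list] = {}
    for rec in records:
        if rec.treatment not in index:
            raise ValueError(f"arm treatment {rec.treatment!r} outside the network")
        by_trial.setdefault(rec.trial_id, []).append(rec)
    trial_ids = sorted(by_trial)
    fups = [r.follow_up for recs in by_trial.values() for r in recs
            if r.follow_up is not None]
    med_fup = float(np.median(fups)) if fups else None
    warnings = []
    T, K = len(trial_ids), len(treatments)
    rows, rvec, nvec, offs = [], [], [], []
    for ti, tid in enumerate(trial_ids):
        recs = by_trial[tid]
        order = network.trials.get(tid)
        if order:
            recs = sorted(recs, key=lambda a: order.index(a.treatment))
        base = recs[0].treatment
        for k, rec in enumerate(recs):
            row = np.zeros(T + K - 1)
            row[ti] = 1.0
            if k > 0:
                if rec.treatment != network.reference:
                    row[T + index[rec.treatment] - 1] = 1.0
                if base != network.reference:
                    row[T + index[base] - 1] = -1.0
            rows.append(row)
            rvec.append(rec.events)
            nvec.append(rec.n)
            fu = rec.follow_up
            if fu is None:
                if med_fup is None:
                    raise ValueError("no trial reports follow-up; cannot impute")
                msg = (f"trial {tid} arm {rec.treatment}: follow-up imputed with "
                       f"the cross-trial median {med_fup:g} months")
                logger.warning(msg)
                warnings.append(msg)
                fu = med_fup
            offs.append(math.log(fu))
    return (treatments, trial_ids, np.asarray(rows), np.asarray(rvec, float),
            np.asarray(nvec, float), np.asarray(offs), warnings)


def _cloglog_parts(theta, A, r, n, off):
    """Per-observation quantities for score/information at theta."""
    eta = off + A @ theta
    eta = np.clip(eta, -30.0, 30.0)
    ee = np.exp(eta)
    q = np.exp(-ee)          # 1 - p
    p = -np.expm1(-ee)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(r * np.log(p) - (n - r) * ee))
    u = ee * (r * (1.0 - p) / p - (n - r))           # dll/deta
    w = n * ee**2 * q / p                            # Fisher weight
    wprime_over_w = (2.0 * p - ee) / p               # d ln w / d eta
    return ll, u, w, wprime_over_w, p, ee


def fit_pl_cloglog(
    network: EvidenceNetwork,
    ae_records,
    penalty: str = "firth",
) -> PlFitResult:
    """Fit the fixed-effect cloglog NMA by Newton-Raphson.

    ``penalty``: "firth" maximizes the Jeffreys-penalized likelihood
    ``l(theta) + 1/2 ln det I(theta)`` via the hat-value-adjusted score;
    "none" is plain maximum likelihood. Convergence: max absolute
    (adjusted) score < 1e-8, at most 100 iterations; non-convergence is
    flagged on the result, not raised.
    """
    if penalty not in ("firth", "none"):
        raise ValueError("penalty must be 'firth' or 'none'")
    records = list(ae_records)
    if not records:
        raise ValueError("no adverse-event records")
    treatments, trial_ids, A, r, n, off, warns = _design(network, records)
    T = len(trial_ids)
    P = A.shape[1]
    theta = np.zeros(P)
    # start baselines at the empirical cloglog of the pooled trial rate
    for ti in range(T):
        sel = A[:, ti] == 1.0
        p0 = (r[sel].sum() + 0.5) / (n[sel].sum() + 1.0)
        theta[ti] = math.log(-math.log(1.0 - p0)) - off[sel].mean()
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        ll, u, w, wr, p, ee = _cloglog_parts(theta, A, r, n, off)
        I = A.T @ (w[:, None] * A)
        try:
            Iinv = np.linalg.inv(I)
        except np.linalg.LinAlgError:
            logger.warning("singular information matrix; PL-NMA fit not converged")
            break
        score = A.T @ u
        if penalty == "firth":
            h = w * np.einsum("ij,jk,ik->i", A, Iinv, A)  # hat values
            score = score + A.T @ (0.5 * h * wr)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        step = Iinv @ score
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        theta = theta + step
    ll, u, w, wr, p, ee = _cloglog_parts(theta, A, r, n, off)
    I = A.T @ (w[:, None] * A)
    cov_full = np.linalg.pinv(I)
    if converged and np.max(np.abs(theta[T:])) > 10.0:
        # a monotone likelihood: the score vanishes only in the limit
        converged = penalty == "firth"
        if not converged:
            logger.warning(
                "unpenalized MLE drifted to a monotone-likelihood boundary "
                "(|log dHR| > 10); fit flagged non-converged"
            )
    if not converged:
        logger.warning("PL-NMA did not converge in %d iterations (penalty=%s)",
                       _MAX_ITER, penalty)
    d_hat = theta[T:]
    cov = cov_full[T:, T:]
    cov = 0.5 * (cov + cov.T)
    return PlFitResult(
        treatments=treatments,
        d_hat=d_hat,
        cov=cov,
        mu_hat={tid: float(theta[i]) for i, tid in enumerate(trial_ids)},
        converged=converged,
        iterations=it,
        penalty=penalty,
        loglik=ll,
        warnings=warns,
    )


def relative_discrete_hazards(fit: PlFitResult,
                              network: EvidenceNetwork | None = None) -> pd.DataFrame:
    """All pairwise discrete hazard ratios exp(d_j - d_k) with Wald 95% CIs.

    CIs come from the delta method on the contrast variance
    ``var(d_j) + var(d_k) - 2 cov(d_j, d_k)``; ``significant`` flags CIs
    excluding 1.
    """
    z = 1.959963984540054
    treatments = fit.treatments
    d_full = np.concatenate([[0.0], fit.d_hat])
    K = len(treatments)
    V = np.zeros((K, K))
    V[1:, 1:] = fit.cov
    rows = []
    for j, tj in enumerate(treatments):
        for k, tk in enumerate(treatments):
            est = d_full[j] - d_full[k]
            var = V[j, j] + V[k, k] - 2.0 * V[j, k]
            se = math.sqrt(max(var, 0.0))
            lo, hi = math.exp(est - z * se), math.exp(est + z * se)
            if j == k:
                lo = hi = 1.0
            rows.append({
                "treatment": tj, "comparator": tk,
                "dhr": math.exp(est), "lo95": lo, "hi95": hi,
                "significant": bool(j != k and (lo > 1.0 or hi < 1.0)),
            })
    return pd.DataFrame(rows)
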