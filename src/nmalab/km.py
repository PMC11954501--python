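"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Some trials report no hazard ratio, only a KM plot with a number-at-risk
table. The reconstruction here inverts the KM estimator (Guyot et al.'s
algorithm): within each interval between consecutive risk-table times it
solves for event and censoring counts such that (i) the product-limit
estimate of the reconstructed data tracks the digitized curve at the
click-points and (ii) the at-risk count at the next risk-table time matches
the published number. Censoring times are spread evenly within intervals.
The resulting pseudo-IPD feed a two-group Cox proportional-hazards fit
(Efron tie handling) to produce the log-HR and SE the NMA consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("nmalab")

__all__ = [
    "KMCurve",
    "PseudoIPD",
    "reconstruct_ipd",
    "cox_loghr",
    "km_from_ipd",
]

# digitization noise: survival rises up to this size are clamped flat
_RISE_TOL = 1e-6


@dataclass
class KMCurve:
    """A digitized survival curve plus its number-at-risk table.

    ``points`` are (time, survival) click coordinates in months;
    ``risk_table`` is (time, n_at_risk). ``total_events``, when the
    publication reports it, constrains the reconstruction.
    """

    points: list[tuple[float, float]]
    risk_table: list[tuple[float, int]]
    total_events: int | None = None

    def validate(self) -> None:
        t = np.asarray([p[0] for p in self.points], float)
        s = np.asarray([p[1] for p in self.points], float)
        if np.any(np.diff(t) < 0):
            raise ValueError("click-point times must be non-decreasing")
        if s[0] > 1.0 + 1e-12 or np.any(s < -1e-12):
            raise ValueError("survival must lie in [0, 1]")
        rises = np.diff(s)
        if np.any(rises > _RISE_TOL):
            raise ValueError("survival increases beyond digitization tolerance")
        rt = [r[0] for r in self.risk_table]
        rn = [r[1] for r in self.risk_table]
        if len(self.risk_table) < 2:
            raise ValueError("need at least two risk-table rows")
        if any(rn[i + 1] > rn[i] for i in range(len(rn) - 1)):
            raise ValueError("number at risk must be non-increasing")
        if rt[0] > t[0]:
            raise ValueError("first risk time must not exceed first click time")


@dataclass
class PseudoIPD:
    """Reconstructed per-patient records: (time, status), status 1=event."""

    times: np.ndarray
    status: np.ndarray  # 1 event, 0 censored
    flags: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


def _clean_points(points):
    """Sort, clamp tiny digitization rises flat, drop duplicate times."""
    pts = sorted(points)
    t, s = [], []
    for ti, si in pts:
        si = min(si, 1.0)
        if s and si > s[-1]:
            si = s[-1]  # rise within tolerance already checked by validate()
        if t and ti == t[-1]:
            s[-1] = min(s[-1], si)
            continue
        t.append(ti)
        s.append(si)
    return np.asarray(t), np.asarray(s)


def reconstruct_ipd(curve: KMCurve) -> PseudoIPD:
    """Invert a digitized KM curve into pseudo individual-patient data.

    Returns one record per initially at-risk patient. When
    ``curve.total_events`` is given, censoring in the final interval is
    tuned so the reconstructed event total matches it (constrained
    variant); otherwise the final interval assumes the censoring rate
    observed over the preceding follow-up.
    """
    curve.validate()
    t, s = _clean_points(curve.points)
    trisk = np.asarray([r[0] for r in curve.risk_table], float)
    nrisk = np.asarray([r[1] for r in curve.risk_table], int)

    if t[0] > trisk[0]:
        t = np.concatenate([[trisk[0]], t])
        s = np.concatenate([[1.0], s])

    n_pts = len(t)
    n_int = len(trisk)
    # click-point index ranges per risk interval; a click exactly at a
    # risk-table time belongs to the preceding interval (the published
    # at-risk number refers to just after any drop at that time)
    lower = np.searchsorted(t, trisk, side="right")
    lower[0] = 0
    upper = np.concatenate([lower[1:] - 1, [n_pts - 1]])

    d = np.zeros(n_pts, int)        # events at click i
    cen = np.zeros(n_pts, int)      # censorings in [t_i, t_{i+1})
    n_hat = np.zeros(n_pts + 1, int)
    n_hat[lower[0]] = nrisk[0]
    km = np.ones(n_pts)
    n_censor = np.zeros(n_int, int)
    cen_times: list[list[float]] = [[] for _ in range(n_pts)]

    def run_interval(j: int, c_guess: int, t_end: float):
        """KM recursion over interval j with c_guess censorings spread on
        (t[lower_j], t_end); fills d, cen, km, n_hat for the interval and
        returns n_hat just after the interval's last click."""
        lo, up = lower[j], upper[j]
        if c_guess > 0:
            ct = t[lo] + np.arange(1, c_guess + 1) * (t_end - t[lo]) / (c_guess + 1)
        else:
            ct = np.empty(0)
        last = lo - 1  # index of last click where an event occurred
        km_last = km[last] if last >= 0 else 1.0
        for k in range(lo, up + 1):
            nxt = t[k + 1] if k < up else t_end
            in_bin = np.count_nonzero((ct >= t[k]) & (ct < nxt)) if c_guess > 0 else 0
            cen[k] = in_bin
            cen_times[k] = list(ct[(ct >= t[k]) & (ct < nxt)]) if in_bin else []
            if n_hat[k] > 0 and km_last > 0:
                d[k] = int(round(n_hat[k] * (1.0 - s[k] / km_last)))
                d[k] = max(0, min(d[k], n_hat[k]))
            else:
                d[k] = 0
            km[k] = km_last * (1.0 - d[k] / n_hat[k]) if n_hat[k] > 0 else km_last
            n_hat[k + 1] = n_hat[k] - d[k] - cen[k]
            if d[k] > 0:
                km_last = km[k]
        return n_hat[up + 1]

    for j in range(n_int - 1):
        lo = lower[j]
        # first approximation of censorings on the interval from the KM drop
        s_lo = s[lo]
        s_next = s[lower[j + 1]] if lower[j + 1] < n_pts else s[-1]
        if s_lo > 0:
            c0 = int(round(n_hat[lo] * s_next / s_lo - nrisk[j + 1]))
        else:
            c0 = 0
        c0 = max(0, min(c0, int(n_hat[lo])))
        target = nrisk[j + 1]
        c_guess, best = c0, None
        for _ in range(2 * int(nrisk[0]) + 10):
            end_n = run_interval(j, c_guess, trisk[j + 1])
            diff = int(end_n) - int(target)
            if best is None or abs(diff) < best[0]:
                best = (abs(diff), c_guess)
            if diff == 0:
                break
            nxt_guess = max(0, min(c_guess + diff, int(n_hat[lower[j]])))
            if nxt_guess == c_guess:
                break
            c_guess = nxt_guess
        if best[1] != c_guess:
            run_interval(j, best[1], trisk[j + 1])
            c_guess = best[1]
        n_censor[j] = c_guess
        n_hat[lower[j + 1]] = n_hat[upper[j] + 1]

    # final interval: no following risk number to match
    j = n_int - 1
    lo, up = lower[j], upper[j]
    t_end = max(t[-1], trisk[-1]) + 1e-9
    if lo < n_pts and n_hat[lo] > 0:
        if curve.total_events is not None:
            # constrained variant: tune final censoring to hit the event total
            prior = int(d[: lo].sum())
            best = None
            c_guess = 0
            for _ in range(int(n_hat[lo]) + 2):
                run_interval(j, c_guess, t_end)
                tot = int(d.sum())
                diff = tot - int(curve.total_events)
                if best is None or abs(diff) < best[0]:
                    best = (abs(diff), c_guess)
                if diff == 0:
                    break
                nxt_guess = max(0, min(c_guess + diff, int(n_hat[lo])))
                if nxt_guess == c_guess:
                    break
                c_guess = nxt_guess
            if best[1] != c_guess:
                run_interval(j, best[1], t_end)
            n_censor[j] = best[1]
            if int(d.sum()) != int(curve.total_events):
                logger.warning(
                    "constrained reconstruction: event total %d vs reported %d",
                    int(d.sum()), int(curve.total_events),
                )
        else:
            # assume the censoring rate seen over the preceding follow-up
            prior_cens = int(n_censor[: j].sum())
            span_prior = trisk[-1] - trisk[0]
            span_last = t_end - trisk[-1]
            if span_prior > 0:
                c_guess = int(round(prior_cens * span_last / span_prior))
            else:
                c_guess = 0
            c_guess = max(0, min(c_guess, int(n_hat[lo])))
            run_interval(j, c_guess, t_end)
            n_censor[j] = c_guess

    # assemble records; patients still at risk at the end are censored there
    times, status = [], []
    for k in range(n_pts):
        times.extend([t[k]] * int(d[k]))
        status.extend([1] * int(d[k]))
        times.extend(cen_times[k])
        status.extend([0] * int(cen[k]))
    leftover = int(nrisk[0]) - len(times)
    t_last = max(t[-1], trisk[-1])
    times.extend([t_last] * leftover)
    status.extend([0] * leftover)
    if curve.total_events is not None:
        # constrained variant: rounding error left after the interval-level
        # adjustment is absorbed at the latest feasible times
        status = _rescale_events(np.asarray(times), status,
                                 int(curve.total_events))

    ipd = PseudoIPD(np.asarray(times, float), np.asarray(status, int))
    if len(ipd) != int(nrisk[0]):
        raise AssertionError("reconstruction lost patients")  # pragma: no cover
    return ipd


def _rescale_events(times: np.ndarray, status: list[int], target: int) -> list[int]:
    """Flip censor/event labels at the latest times until the event total
    matches the reported one (never beyond what the records allow)."""
    status = list(status)
    diff = target - sum(status)
    order = np.argsort(-times)  # latest records first
    for i in order:
        if diff == 0:
            break
        if diff > 0 and status[i] == 0:
            status[i] = 1
            diff -= 1
        elif diff < 0 and status[i] == 1:
            status[i] = 0
            diff += 1
    if diff != 0:
        logger.warning("could not match reported event total (off by %d)", diff)
    return status


# ---------------------------------------------------------------------------
# Two-group Cox proportional-hazards partial likelihood (Efron ties)
# ---------------------------------------------------------------------------

def _efron_terms(beta: float, times, status, group):
    """Log partial likelihood, score and information for a binary covariate."""
    order = np.lexsort((1 - status, times))  # events before censorings at ties
    times, status, group = times[order], status[order], group[order]
    eb = math.exp(beta)
    loglik = dscore = info = 0.0
    # iterate distinct event times from largest to smallest, maintaining risk sums
    uniq = np.unique(times[status == 1])
    for te in uniq:
        at_risk = times >= te
        tied = (times == te) & (status == 1)
        D = int(tied.sum())
        s1 = int(group[tied].sum())          # events in group 1 at this time
        n1R = int(group[at_risk].sum())      # group-1 members at risk
        n0R = int(at_risk.sum()) - n1R
        S0R = n0R + n1R * eb
        S1R = n1R * eb
        S0D = (D - s1) + s1 * eb
        S1D = s1 * eb
        loglik += s1 * beta
        for l in range(D):
            f = l / D
            A0 = S0R - f * S0D
            A1 = S1R - f * S1D
            loglik -= math.log(A0)
            dscore -= A1 / A0
            info += A1 / A0 - (A1 / A0) ** 2
        dscore += s1
    return loglik, dscore, info


def _newton_cox(times, status, group, penalized: bool):
    beta = 0.0
    for it in range(50):
        if penalized:
            # Firth: l*(b) = l(b) + 0.5 ln I(b); penalty gradient by central diff
            _, sc, info = _efron_terms(beta, times, status, group)
            h = 1e-5
            _, _, ip = _efron_terms(beta + h, times, status, group)
            _, _, im = _efron_terms(beta - h, times, status, group)
            dpen = (math.log(ip) - math.log(im)) / (4 * h)
            sc = sc + dpen
        else:
            _, sc, info = _efron_terms(beta, times, status, group)
        if info <= 0:
            break
        step = sc / info
        step = max(-2.0, min(2.0, step))
        beta += step
        if abs(step) < 1e-8:
            break
    _, _, info = _efron_terms(beta, times, status, group)
    se = math.sqrt(1.0 / info) if info > 0 else math.inf
    return beta, se, it + 1


def cox_loghr(arm_a: PseudoIPD, arm_b: PseudoIPD) -> tuple[float, float]:
    """Log hazard ratio of arm_a vs arm_b with SE.

    Newton-Raphson on the two-group proportional-hazards partial
    likelihood with Efron tie handling; SE from the inverse observed
    information. Monotone likelihoods (all events on one side of every
    risk set) are refit with the Firth penalty and flagged with a warning.
    """
    times = np.concatenate([arm_a.times, arm_b.times])
    status = np.concatenate([arm_a.status, arm_b.status])
    group = np.concatenate([np.ones(len(arm_a)), np.zeros(len(arm_b))])
    if status.sum() < 1:
        raise ValueError("no events in either arm")
    monotone = arm_a.n_events == 0 or arm_b.n_events == 0
    if monotone:
        logger.warning("monotone partial likelihood; returning Firth-penalized estimate")
        beta, se, _ = _newton_cox(times, status, group, penalized=True)
        return beta, se
    beta, se, _ = _newton_cox(times, status, group, penalized=False)
    if not math.isfinite(beta) or abs(beta) > 15:
        logger.warning("Cox fit drifted to a monotone solution; Firth fallback used")
        beta, se, _ = _newton_cox(times, status, group, penalized=True)
    return beta, se


def cox_logpl(beta: float, arm_a: PseudoIPD, arm_b: PseudoIPD) -> float:
    """Efron log partial likelihood at a given beta (arm_a coded 1)."""
    times = np.concatenate([arm_a.times, arm_b.times])
    status = np.concatenate([arm_a.status, arm_b.status])
    group = np.concatenate([np.ones(len(arm_a)), np.zeros(len(arm_b))])
    ll, _, _ = _efron_terms(beta, times, status, group)
    return ll


def km_from_ipd(ipd: PseudoIPD) -> KMCurve:
    """Product-limit estimator of reconstructed (or true) IPD.

    Tied event and censoring times are resolved conventionally: events
    happen first. Returns a step curve sampled at the event times plus the
    trivial risk table (start and end)."""
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    order = np.lexsort((1 - ipd.status, ipd.times))
    t_sorted = ipd.times[order]
    s_sorted = ipd.status[order]
    n = len(ipd)
    points = [(0.0, 1.0)]
    surv = 1.0
    at_risk = n
    i = 0
    while i < n:
        te = t_sorted[i]
        d = int(((t_sorted == te) & (s_sorted == 1)).sum())
        c = int(((t_sorted == te) & (s_sorted == 0)).sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
            points.append((float(te), surv))
        at_risk -= d + c
        i += d + c
    t_max = float(t_sorted[-1])
    risk = [(0.0, n), (t_max, int(at_risk))]
    return KMCurve(points=points, risk_table=risk)


def km_survival_at(ipd: PseudoIPD, times) -> np.ndarray:
    """Evaluate the product-limit estimate of ``ipd`` at arbitrary times."""
    curve = km_from_ipd(ipd)
    ts = np.asarray([p[0] for p in curve.points])
    ss = np.asarray([p[1] for p in curve.points])
    idx = np.searchsorted(ts, np.asarray(times, float), side="right") - 1
    idx = np.clip(idx, 0, len(ss) - 1)
    return ss[idx]
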