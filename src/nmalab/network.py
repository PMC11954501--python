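"""Evidence networks: treatments as nodes, trials as multi-edges.

A network meta-analysis combines direct and indirect randomized evidence.
This module holds the bookkeeping that precedes any model fit: declaring
treatments, attaching trial arms or contrasts to them, merging nodes that
are judged clinically exchangeable (e.g. all placebo/corticosteroid arms),
checking connectivity to the reference treatment, and removing trials for
sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx

logger = logging.getLogger("nmalab")

__all__ = [
    "Treatment",
    "TrialArm",
    "EvidenceNetwork",
    "build_network",
    "merge_nodes",
    "connected_component",
    "remove_trial",
    "to_dot",
]


@dataclass(frozen=True)
class Treatment:
    """A network node: a regimen at a specific dose and schedule.

    Dose variants are distinct nodes (docetaxel 50 vs 75 mg/m2 are
    different treatments); node identity is the exact regimen token.
    """

    id: str
    label: str = ""
    class_tag: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("treatment id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class TrialArm:
    """One arm of one randomized trial.

    ``events`` and ``follow_up`` (months) are optional: contrast-level
    time-to-event records do not carry them, arm-level binary and
    adverse-event records do.
    """

    trial_id: str
    treatment: str
    n: int
    events: int | None = None
    follow_up: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"trial {self.trial_id}: arm n must be >= 1, got {self.n}")
        if self.events is not None and not (0 <= self.events <= self.n):
            raise ValueError(
                f"trial {self.trial_id}: events must be in [0, n], got "
                f"{self.events}/{self.n}"
            )
        if self.follow_up is not None and self.follow_up <= 0:
            raise ValueError(f"trial {self.trial_id}: follow_up must be > 0")


@dataclass
class EvidenceNetwork:
    """Treatments (nodes), trials (multi-edges) and a reference node.

    ``trials`` maps trial id -> ordered list of treatment ids in that
    trial, first entry being the trial's baseline arm. ``edges`` is the
    multiset of within-trial (baseline, treatment) pairs, one per
    non-baseline arm: a three-arm trial contributes two edges against its
    baseline, never an independent third edge (that would double-count).
    """

    outcome: str
    treatments: dict[str, Treatment]
    trials: dict[str, list[str]]
    reference: str
    arms: dict[str, list[TrialArm]] = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        """(baseline, treatment, trial_id) for every within-trial contrast."""
        out = []
        for tid, treats in self.trials.items():
            base = treats[0]
            for t in treats[1:]:
                out.append((base, t, tid))
        return out

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def treatment_ids(self) -> list[str]:
        """Reference first, then remaining treatments sorted by id."""
        rest = sorted(t for t in self.treatments if t != self.reference)
        return [self.reference] + rest

    def validate(self) -> None:
        if self.reference not in self.treatments:
            raise ValueError(f"reference {self.reference!r} is not a declared treatment")
        for tid, treats in self.trials.items():
            if len(treats) < 2:
                raise ValueError(f"trial {tid!r} has a single arm")
            for t in treats:
                if t not in self.treatments:
                    raise ValueError(f"trial {tid!r} names undeclared treatment {t!r}")

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.treatments)
        for base, treat, tid in self.edges:
            g.add_edge(base, treat, trial=tid)
        return g


def _records_to_trials(records) -> tuple[dict[str, list[str]], dict[str, list[TrialArm]]]:
    """Group arm/contrast records by trial, preserving arm order.

    Accepts TrialArm-like records (``.treatment``) or contrast records
    (``.treatment`` + ``.baseline_treatment``).
    """
    trials: dict[str, list[str]] = {}
    arms: dict[str, list[TrialArm]] = {}
    seen_pairs: set[tuple[str, str, str]] = set()
    for rec in records:
        tid = rec.trial_id
        if hasattr(rec, "baseline_treatment"):  # contrast-level
            base, treat = rec.baseline_treatment, rec.treatment
            key = (tid, *sorted((base, treat)))
            if key in seen_pairs:
                raise ValueError(f"duplicate contrast for pair {key[1:]!r} in trial {tid!r}")
            seen_pairs.add(key)
            order = trials.setdefault(tid, [])
            if not order:
                order.append(base)
            elif order[0] != base:
                raise ValueError(
                    f"trial {tid!r}: contrasts declare conflicting baselines "
                    f"({order[0]!r} vs {base!r})"
                )
            if treat in order:
                raise ValueError(f"duplicate arm {treat!r} in trial {tid!r}")
            order.append(treat)
        else:  # arm-level
            order = trials.setdefault(tid, [])
            if rec.treatment in order:
                raise ValueError(f"duplicate arm {rec.treatment!r} in trial {tid!r}")
            order.append(rec.treatment)
            arms.setdefault(tid, []).append(rec)
    return trials, arms


def build_network(records, outcome: str, reference: str) -> EvidenceNetwork:
    """Build an evidence network from contrast- or arm-level records.

    Treatments are deduplicated by id; the edge multiset exactly reflects
    the trial-by-pair structure of the records. Raises on duplicate
    (trial, pair) rows and on single-arm trials.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    outcomes = {getattr(r, "outcome", outcome) for r in records}
    if outcomes - {outcome}:
        raise ValueError(f"records carry outcomes {outcomes}, expected {outcome!r}")
    trials, arms = _records_to_trials(records)
    treat_ids = {t for order in trials.values() for t in order}
    if reference not in treat_ids:
        raise ValueError(
            f"reference {reference!r} is not a treatment declared by any record"
        )
    net = EvidenceNetwork(
        outcome=outcome,
        treatments={t: Treatment(t) for t in sorted(treat_ids)},
        trials=trials,
        reference=reference,
        arms=arms,
    )
    net.validate()
    return net


def merge_nodes(network: EvidenceNetwork, merge_map: dict[str, str]) -> EvidenceNetwork:
    """Collapse nodes, e.g. all placebo/corticosteroid arms into one node.

    All arms are relabelled through ``merge_map``; a trial whose arms all
    collapse onto a single node no longer carries a contrast and is
    dropped with a warning. Idempotent: applying the same map twice is a
    no-op the second time.
    """
    # keys already collapsed by a previous application are ignorable,
    # which makes the operation idempotent
    missing = [k for k in merge_map
               if k not in network.treatments
               and merge_map[k] not in network.treatments]
    if missing:
        raise KeyError(f"merge_map keys not in network: {missing}")

    def rename(t: str) -> str:
        return merge_map.get(t, t)

    trials: dict[str, list[str]] = {}
    arms: dict[str, list[TrialArm]] = {}
    for tid, order in network.trials.items():
        new_order: list[str] = []
        for t in order:
            nt = rename(t)
            if nt not in new_order:
                new_order.append(nt)
        if len(new_order) < 2:
            logger.warning(
                "merge collapses all arms of trial %s onto node %s; trial dropped",
                tid, new_order[0],
            )
            continue
        trials[tid] = new_order
        if tid in network.arms:
            arms[tid] = [replace(a, treatment=rename(a.treatment)) for a in network.arms[tid]]
    treatments = {}
    for t, obj in network.treatments.items():
        nt = rename(t)
        if nt not in treatments:
            treatments[nt] = obj if nt == t else Treatment(nt)
    reference = rename(network.reference)
    out = EvidenceNetwork(network.outcome, treatments, trials, reference, arms)
    out.validate()
    return out


def connected_component(network: EvidenceNetwork) -> tuple[set[str], set[str]]:
    """Treatments reachable from the reference, plus the excluded remainder.

    Trials whose treatments fall outside the component cannot inform the
    model and are excluded from fitting; the second return value lists the
    unreachable treatments so the exclusion is visible.
    """
    if not network.treatments:
        raise ValueError("empty network")
    g = network.graph()
    comp = set(nx.node_connected_component(g, network.reference))
    if comp == {network.reference} and not any(
        network.reference in treats for treats in network.trials.values()
    ):
        if len(network.treatments) > 1:
            raise ValueError(f"reference {network.reference!r} is isolated")
    excluded = set(network.treatments) - comp
    if excluded:
        logger.warning(
            "%d treatment(s) not connected to reference %r and excluded: %s",
            len(excluded), network.reference, sorted(excluded),
        )
    return comp, excluded


def restrict_to_component(network: EvidenceNetwork) -> EvidenceNetwork:
    """Drop trials and treatments outside the reference's component."""
    comp, excluded = connected_component(network)
    if not excluded:
        return network
    trials = {tid: tr for tid, tr in network.trials.items() if set(tr) <= comp}
    arms = {tid: network.arms[tid] for tid in trials if tid in network.arms}
    treatments = {t: obj for t, obj in network.treatments.items() if t in comp}
    out = EvidenceNetwork(network.outcome, treatments, trials, network.reference, arms)
    out.validate()
    return out


def remove_trial(network: EvidenceNetwork, trial_id: str) -> tuple[EvidenceNetwork, set[str]]:
    """Sensitivity-analysis removal of one trial.

    Returns the reduced network and the set of treatments newly orphaned
    (left with no contrast) by the removal; orphans are dropped from the
    node set so downstream fits remain runnable.
    """
    if trial_id not in network.trials:
        raise KeyError(f"unknown trial {trial_id!r}")
    trials = {tid: tr for tid, tr in network.trials.items() if tid != trial_id}
    remaining = {t for tr in trials.values() for t in tr} | {network.reference}
    orphaned = set(network.treatments) - remaining
    if orphaned:
        logger.warning("removing trial %s orphans treatments %s", trial_id, sorted(orphaned))
    arms = {tid: network.arms[tid] for tid in trials if tid in network.arms}
    treatments = {t: obj for t, obj in network.treatments.items() if t in remaining}
    out = EvidenceNetwork(network.outcome, treatments, trials, network.reference, arms)
    out.validate()
    return out, orphaned


def to_dot(network: EvidenceNetwork) -> str:
    """Network diagram as DOT: one node per treatment, one edge per
    trial-pair, edge labelled by trial id."""
    lines = [f'graph "{network.outcome}" {{']
    for t in network.treatment_ids():
        label = network.treatments[t].label
        lines.append(f'  "{t}" [label="{label}"];')
    for base, treat, tid in network.edges:
        lines.append(f'  "{base}" -- "{treat}" [label="{tid}"];')
    lines.append("}")
    return "\n".join(lines)
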