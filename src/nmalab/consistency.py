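"""Node-splitting assessment of evidence consistency.

An NMA assumes direct and indirect evidence on each comparison estimate
the same quantity. Node-splitting checks this one comparison at a time:
the model is refit with the comparison's direct evidence loading on its
own parameter (omega) while the rest of the network supplies the indirect
estimate through the basic parameters. The posterior of
``difference = direct - indirect`` yields a two-sided Bayesian tail
probability, p = 2 min(P(diff > 0), P(diff < 0)); small p flags
inconsistency. A comparison is splittable only when it has direct
evidence *and* an independent indirect path once the direct trials are
set aside.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .bayes import McmcConfig, PosteriorResult, Priors, fit_binary_nma, fit_contrast_nma
from .network import EvidenceNetwork

__all__ = ["NodeSplitResult", "splittable_comparisons", "node_split", "node_split_all"]


@dataclass
class NodeSplitResult:
    comparison: tuple[str, str]
    splittable: bool
    direct: dict | None = None      # median/lo95/hi95 of omega
    indirect: dict | None = None    # median/lo95/hi95 of d_k - d_b
    difference: dict | None = None
    p_value: float | None = None
    posterior: PosteriorResult | None = None

    def row(self) -> dict:
        out = {"comparison": f"{self.comparison[1]} vs {self.comparison[0]}",
               "splittable": self.splittable}
        for name, summ in (("direct", self.direct), ("indirect", self.indirect),
                           ("difference", self.difference)):
            if summ:
                out.update({f"{name}_{k}": v for k, v in summ.items()})
        out["p_value"] = self.p_value
        return out


def _direct_trials(network: EvidenceNetwork, pair: set[str]) -> list[str]:
    return [tid for base, treat, tid in network.edges if {base, treat} == pair]


def splittable_comparisons(network: EvidenceNetwork) -> list[tuple[str, str]]:
    """Comparisons with direct evidence plus an independent indirect path.

    Pairs are returned in (baseline, treatment) order following the
    within-trial direction of the first trial carrying them.
    """
    seen: list[tuple[str, str]] = []
    for base, treat, _tid in network.edges:
        if (base, treat) not in seen and (treat, base) not in seen:
            seen.append((base, treat))
    out = []
    for base, treat in seen:
        pair = {base, treat}
        direct = set(_direct_trials(network, pair))
        g = nx.Graph()
        g.add_nodes_from(network.treatments)
        for b, t, tid in network.edges:
            if tid not in direct:
                g.add_edge(b, t)
        if nx.has_path(g, base, treat):
            out.append((base, treat))
    return out


def _tail_p(diff: np.ndarray) -> float:
    p_pos = float((diff > 0).mean())
    return 2.0 * min(p_pos, 1.0 - p_pos)


def _summ(x: np.ndarray) -> dict:
    lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
    return {"median": float(med), "lo95": float(lo), "hi95": float(hi)}


def node_split(
    network: EvidenceNetwork,
    data,
    comparison: tuple[str, str],
    model: str = "random",
    priors: Priors | None = None,
    mcmc: McmcConfig | None = None,
) -> NodeSplitResult:
    """Split one comparison into direct and indirect components.

    ``comparison`` is (baseline, treatment): the direct estimate is of
    treatment vs baseline. ``data`` is a list of ContrastRecord (log-HR
    model) or TrialArm (binary model) records. Comparisons without direct
    evidence or without an indirect loop are reported not splittable
    rather than raising.
    """
    base, treat = comparison
    if (base, treat) not in splittable_comparisons(network) and \
       (treat, base) not in splittable_comparisons(network):
        return NodeSplitResult(comparison=comparison, splittable=False)
    is_arm_level = data and not hasattr(data[0], "log_effect")
    fitter = fit_binary_nma if is_arm_level else fit_contrast_nma
    post = fitter(network, data, model=model, priors=priors, mcmc=mcmc,
                  split_pair=(base, treat))
    omega = np.asarray(post.samples["omega"]).reshape(-1)
    treatments = post.treatments
    dm = post.d_matrix()
    jb, jt = treatments.index(base), treatments.index(treat)
    indirect = dm[:, jt] - dm[:, jb]
    diff = omega - indirect
    return NodeSplitResult(
        comparison=comparison,
        splittable=True,
        direct=_summ(omega),
        indirect=_summ(indirect),
        difference=_summ(diff),
        p_value=_tail_p(diff),
        posterior=post,
    )


def node_split_all(
    network: EvidenceNetwork,
    data,
    model: str = "random",
    priors: Priors | None = None,
    mcmc: McmcConfig | None = None,
) -> pd.DataFrame:
    """Node-split every splittable comparison; one row per comparison."""
    rows = []
    for pair in splittable_comparisons(network):
        res = node_split(network, data, pair, model=model, priors=priors, mcmc=mcmc)
        rows.append(res.row())
    cols = ["comparison", "splittable", "direct_median", "direct_lo95", "direct_hi95",
            "indirect_median", "indirect_lo95", "indirect_hi95",
            "difference_median", "difference_lo95", "difference_hi95", "p_value"]
    return pd.DataFrame(rows, columns=cols)
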