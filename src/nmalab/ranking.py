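"""Treatment rankings from posterior samples.

Each posterior draw induces a complete ordering of the treatments in the
declared benefit direction (lower log-HR is better for hazard-type
outcomes, higher log-OR is better for response). Empirical rank
frequencies give the rank-probability matrix; its first column is p-best
and the normalized area under each treatment's cumulative ranking curve
is the SUCRA, SUCRA_k = sum_{j=1..a-1} P(rank_k <= j) / (a - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import PosteriorResult

__all__ = ["RankingResult", "rank_probabilities", "sucra", "league_table", "rankings"]


@dataclass
class RankingResult:
    treatments: list[str]
    rank_matrix: np.ndarray  # (a, a): P(treatment has rank r+1)
    p_best: np.ndarray
    sucra: np.ndarray
    mean_rank: np.ndarray
    direction: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "treatment": self.treatments,
            "p_best": self.p_best,
            "sucra": self.sucra,
            "mean_rank": self.mean_rank,
        })


def rank_probabilities(d_samples: np.ndarray, direction: str,
                       seed: int = 0) -> np.ndarray:
    """Empirical rank-probability matrix from effect draws.

    ``d_samples``: (draws, a) treatment effects including the reference
    column. Rank 1 is best in the given direction ("lower_better" or
    "higher_better"). Ties are broken by a uniform random permutation
    (they have probability ~0 for continuous posteriors but occur in
    degenerate inputs), seeded for reproducibility.
    """
    if direction not in ("lower_better", "higher_better"):
        raise ValueError("direction must be 'lower_better' or 'higher_better'")
    d = np.asarray(d_samples, float)
    S, a = d.shape
    score = d if direction == "lower_better" else -d
    rng = np.random.default_rng(seed)
    tie_key = rng.random(score.shape)
    # lexsort: primary key score, secondary random - a uniform tie permutation
    order = np.lexsort((tie_key, score), axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(a), (S, a)).copy(), axis=1)
    mat = np.zeros((a, a))
    for r in range(a):
        mat[:, r] = (ranks == r).mean(axis=0)
    return mat


def sucra(rank_matrix: np.ndarray) -> np.ndarray:
    """Surface under the cumulative ranking curve per treatment, in [0, 1].

    1 = certainly best, 0 = certainly worst; for two treatments SUCRA
    equals p-best. Undefined for a single treatment.
    """
    mat = np.asarray(rank_matrix, float)
    a = mat.shape[0]
    if a < 2:
        raise ValueError("SUCRA undefined for a single treatment")
    cum = np.cumsum(mat, axis=1)
    return cum[:, : a - 1].sum(axis=1) / (a - 1)


def rankings(posterior: PosteriorResult, direction: str, seed: int = 0) -> RankingResult:
    """p-best, SUCRA and mean rank for every treatment in a fitted model."""
    dm = posterior.d_matrix()
    mat = rank_probabilities(dm, direction, seed=seed)
    a = mat.shape[0]
    s = sucra(mat)
    mean_rank = mat @ (np.arange(a) + 1.0)
    return RankingResult(
        treatments=posterior.treatments,
        rank_matrix=mat,
        p_best=mat[:, 0].copy(),
        sucra=s,
        mean_rank=mean_rank,
        direction=direction,
    )


def league_table(posterior: PosteriorResult, direction: str,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """League table ordered by descending SUCRA.

    Cell (row, col) holds the median ratio of column treatment vs row
    treatment with its 95% CrI, formatted "median (lo, hi)"; the parallel
    boolean frame flags cells whose CrI excludes 1. Diagonal cells carry
    the treatment's own name.
    """
    rk = rankings(posterior, direction, seed=seed)
    order = np.argsort(-rk.sucra, kind="stable")
    treatments = [posterior.treatments[i] for i in order]
    dm = posterior.d_matrix()[:, order]
    a = len(treatments)
    cells = np.empty((a, a), dtype=object)
    sig = np.zeros((a, a), dtype=bool)
    for i in range(a):
        for j in range(a):
            if i == j:
                cells[i, j] = treatments[i]
                continue
            ratio = np.exp(dm[:, j] - dm[:, i])
            lo, med, hi = np.percentile(ratio, [2.5, 50.0, 97.5])
            cells[i, j] = f"{med:.3f} ({lo:.3f}, {hi:.3f})"
            sig[i, j] = lo > 1.0 or hi < 1.0
    table = pd.DataFrame(cells, index=treatments, columns=treatments)
    sig_table = pd.DataFrame(sig, index=treatments, columns=treatments)
    return table, sig_table
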