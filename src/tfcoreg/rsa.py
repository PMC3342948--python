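"""Pooled-rank differential expression scoring (RSA style).

All replicate log fold-changes from all genes are pooled into one
increasing ordering of N = m * G values.  For a gene whose m values sit at
ranks r_1 < ... < r_m, the statistic is the minimum over j of the
hypergeometric upper tail

    p = min_j P(X >= j),   X ~ Hypergeom(N, m, r_j)

i.e. the chance that j or more of the gene's m values land inside the top
r_j of the pooled list by luck.  Down-regulation is scored on the
increasing ordering and up-regulation on the decreasing one; the minimum
over j is reported uncorrected, as in the redundant-siRNA-activity (RSA)
procedure this mirrors.  P-values are converted to q-values with a Storey
null-proportion estimate pi0 multiplied into the Benjamini-Hochberg
step-up values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import FoldChangeTable


@dataclass
class RankedGeneRecord:
    gene_id: str
    replicate_ranks: tuple[int, ...]  # 1-based ranks in the pooled increasing order
    p_down: float
    p_up: float
    q_down: float = float("nan")
    q_up: float = float("nan")


def pool_and_rank(*tables: FoldChangeTable) -> pd.DataFrame:
    """Pool every value of the given tables and rank increasingly.

    Tables must share the gene universe.  Ties are broken deterministically
    by the (value, experiment index, gene index) triple, so every value
    gets a unique ordinal rank in 1..N.  Returns a DataFrame with one row
    per value: gene_id, experiment_id, value, rank.
    """
    if not tables:
        raise ValueError("need at least one table")
    universe = set(tables[0].gene_ids)
    for t in tables[1:]:
        if set(t.gene_ids) != universe:
            missing = universe.symmetric_difference(t.gene_ids)
            raise ValueError(f"tables disagree on the gene universe: {sorted(missing)[:10]}")
    gene_order = tables[0].gene_ids
    gene_index = {g: i for i, g in enumerate(gene_order)}

    rows = []
    exp_counter = 0
    for t in tables:
        frame = t.frame.loc[gene_order]
        for j, exp in enumerate(t.experiment_ids):
            col = frame.iloc[:, j].to_numpy()
            for g, v in zip(gene_order, col):
                rows.append((g, exp, float(v), exp_counter + j, gene_index[g]))
        exp_counter += t.n_experiments
    df = pd.DataFrame(rows, columns=["gene_id", "experiment_id", "value", "_e", "_g"])
    order = np.lexsort((df["_g"].to_numpy(), df["_e"].to_numpy(), df["value"].to_numpy()))
    ranks = np.empty(len(df), dtype=np.int64)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return df.drop(columns=["_e", "_g"])


def rsa_min_hypergeom(ranks, N: int, m: int) -> float:
    """Minimum hypergeometric tail over the gene's m pooled ranks.

    ``ranks`` is the increasing list r_1..r_m of the gene's positions in the
    pooled ordering of N values; p = min_j P(X >= j), X ~ Hypergeom(N, m, r_j).
    """
    ranks = sorted(int(r) for r in ranks)
    if len(ranks) != m or m < 1:
        raise ValueError("ranks must have length m >= 1")
    if ranks[-1] > N or ranks[0] < 1:
        raise ValueError("ranks must lie in 1..N")
    best = 1.0
    for j, r in enumerate(ranks, start=1):
        # P(X >= j) with population N, m successes, r draws
        p = float(stats.hypergeom.sf(j - 1, N, m, r))
        best = min(best, p)
    return max(best, 5e-324)


def storey_qvalues(pvalues, lambda_: float = 0.5, pi0: float | None = None
                   ) -> tuple[np.ndarray, float]:
    """Storey q-values: pi0 estimate times the BH step-up values.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) * n)); pass ``pi0=1`` to
    recover Benjamini-Hochberg exactly.  Returns (qvalues, pi0).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    if pi0 is None:
        if not (0 <= lambda_ < 1):
            raise ValueError("lambda must be in [0, 1)")
        pi0 = min(1.0, np.count_nonzero(p > lambda_) / ((1.0 - lambda_) * n))
        if pi0 <= 0:
            pi0 = 1.0 / n  # all p below lambda: keep a positive floor
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # BH step-up: running minimum from the largest p down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(pi0 * q_sorted, 1.0)
    return q, float(pi0)


def score_genes(*tables: FoldChangeTable, lambda_: float = 0.5,
                pi0: float | None = None) -> list[RankedGeneRecord]:
    """Full RSA scoring: pooled ranks, p_down/p_up, q_down/q_up per gene.

    Down-regulation uses the increasing pooled ordering; up-regulation the
    decreasing one (equivalently, RSA on the negated values).
    """
    pooled = pool_and_rank(*tables)
    N = len(pooled)
    gene_order = tables[0].gene_ids
    m = sum(t.n_experiments for t in tables)

    ranks_down = pooled.groupby("gene_id", sort=False)["rank"].apply(sorted)
    neg = [FoldChangeTable(-t.frame) for t in tables]
    pooled_up = pool_and_rank(*neg)
    ranks_up = pooled_up.groupby("gene_id", sort=False)["rank"].apply(sorted)

    records = []
    for g in gene_order:
        rd, ru = ranks_down[g], ranks_up[g]
        records.append(RankedGeneRecord(
            gene_id=g,
            replicate_ranks=tuple(rd),
            p_down=rsa_min_hypergeom(rd, N, m),
            p_up=rsa_min_hypergeom(ru, N, m),
        ))
    q_down, pi0_d = storey_qvalues([r.p_down for r in records], lambda_, pi0)
    q_up, pi0_u = storey_qvalues([r.p_up for r in records], lambda_, pi0)
    for r, qd, qu in zip(records, q_down, q_up):
        r.q_down, r.q_up = float(qd), float(qu)
    return records


def significant_genes(records: list[RankedGeneRecord], q_cutoff: float = 0.01,
                      direction: str = "down") -> set[str]:
    """Genes whose q-value in the given direction is <= q_cutoff."""
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    attr = "q_down" if direction == "down" else "q_up"
    return {r.gene_id for r in records if getattr(r, attr) <= q_cutoff}


def records_to_frame(records: list[RankedGeneRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in records],
        "p_down": [r.p_down for r in records],
        "q_down": [r.q_down for r in records],
        "p_up": [r.p_up for r in records],
        "q_up": [r.q_up for r in records],
        "ranks": [",".join(map(str, r.replicate_ranks)) for r in records],
    })
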