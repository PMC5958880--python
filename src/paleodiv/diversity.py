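"""Per-bin richness estimation: taxic counts, Good's U coverage, and
shareholder quorum subsampling (SQS).

SQS standardises *coverage* — the share of the bin's underlying
relative-abundance distribution accounted for by the taxa seen so far —
rather than sample size.  Coverage is estimated by Good's U:

    u = 1 - s1 / N,

with s1 the number of taxa represented by exactly one specimen in the
bin and N the bin's specimen total.  A subsampling trial draws
specimens one at a time in random order; whenever a taxon is seen for
the first time its coverage share f_i = (n_i / N) * u is added, and
drawing stops once accumulated coverage reaches the quorum.  The
trial's richness is the number of distinct taxa drawn, and the estimate
is the mean over trials.  A bin whose total coverage u falls short of
the quorum cannot be standardised to it (reached = False).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binning import BinnedOccurrences

__all__ = [
    "SQSEstimate",
    "DiversityEstimate",
    "taxic_richness",
    "goods_u",
    "sqs_richness",
    "diversity_table",
]


@dataclass(frozen=True)
class SQSEstimate:
    mean_richness: float  # NaN when the quorum is not reachable
    reached: bool
    trials: int


@dataclass(frozen=True)
class DiversityEstimate:
    bin_label: str
    raw_richness: int
    goods_u: float  # NaN for an empty bin
    sqs: dict[float, SQSEstimate]


def taxic_richness(binned: BinnedOccurrences) -> pd.Series:
    """Number of taxa with at least one specimen, per bin."""
    return (binned.counts > 0).sum(axis=0)


def goods_u(bin_counts: Sequence[int]) -> float:
    """Good's U coverage estimate of one bin's abundance vector."""
    counts = np.asarray(bin_counts, dtype=int)
    total = counts.sum()
    if total < 1:
        raise ValueError("Good's U is undefined for an empty bin")
    singletons = int((counts == 1).sum())
    return 1.0 - singletons / total


def sqs_richness(
    bin_counts: Sequence[int],
    quorum: float,
    trials: int = 1000,
    seed: int = 0,
    inclusive: bool = True,
) -> SQSEstimate:
    """Coverage-standardised (SQS) richness of one bin.

    ``inclusive`` (default) counts the taxon whose first appearance
    pushes accumulated coverage to the quorum; the exclusive rule stops
    just short of it.
    """
    if not 0.0 < quorum < 1.0:
        raise ValueError(f"quorum must be in (0, 1), got {quorum}")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    counts = np.asarray(bin_counts, dtype=int)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("SQS is undefined for an empty bin")
    total = int(counts.sum())
    u = goods_u(counts)
    if u < quorum:
        return SQSEstimate(mean_richness=float("nan"), reached=False, trials=trials)

    shares = counts / total * u  # per-taxon coverage share f_i
    specimens = np.repeat(np.arange(counts.size), counts)
    rng = np.random.default_rng(seed)
    richness = np.empty(trials)
    tol = 1e-9
    for t in range(trials):
        perm = specimens[rng.permutation(total)]
        # discovery order = order of first appearance in the permutation
        _, first_idx = np.unique(perm, return_index=True)
        discovery = perm[np.sort(first_idx)]
        acc = np.cumsum(shares[discovery])
        crossing = int(np.searchsorted(acc, quorum - tol, side="left"))
        richness[t] = crossing + 1 if inclusive else max(crossing, 0)
    return SQSEstimate(mean_richness=float(richness.mean()), reached=True, trials=trials)


def diversity_table(
    binned: BinnedOccurrences | Iterable[BinnedOccurrences],
    quorums: Sequence[float] = (0.6, 0.7, 0.8, 0.9),
    trials: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-bin diversity table, replicate-aware.

    Columns: scheme, replicate_id, bin, raw_richness, goods_u, quorum,
    sqs_mean, reached.  Empty bins get NaN coverage and no SQS rows are
    marked reached for them.
    """
    if isinstance(binned, BinnedOccurrences):
        binned = [binned]
    rows = []
    for rep in binned:
        raw = taxic_richness(rep)
        for b, label in enumerate(rep.scheme.labels):
            col = rep.counts[label].to_numpy()
            total = col.sum()
            u = goods_u(col) if total >= 1 else float("nan")
            for q in quorums:
                if total >= 1 and u >= q:
                    est = sqs_richness(
                        col,
                        q,
                        trials=trials,
                        seed=int(
                            np.random.SeedSequence(
                                entropy=[seed, rep.replicate_id, b, int(q * 1000)]
                            ).generate_state(1)[0]
                            % (2**31)
                        ),
                    )
                else:
                    est = SQSEstimate(float("nan"), False, trials)
                rows.append(
                    {
                        "scheme": rep.scheme.kind,
                        "replicate_id": rep.replicate_id,
                        "bin": label,
                        "raw_richness": int(raw[label]),
                        "goods_u": u,
                        "quorum": q,
                        "sqs_mean": est.mean_richness,
                        "reached": est.reached,
                    }
                )
    return pd.DataFrame(rows)
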