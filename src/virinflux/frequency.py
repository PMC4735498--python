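"""Per-genome insertion frequency from chimeric-read counts.

With Pj the mean number of host-virus junctions per viral genome in a
library, a read covers a junction with probability about Pj * Lr / Lg.
Detection requires the junction to sit at least 28 bp from both read ends
(the aligner's minimum reportable similarity), less the mean alignment
overlap Ov at the junction, so the probability that a read is chimeric is
Pj * (Lr - 56 + Ov) / Lg and

    Pj  =  (Nc / N) * Lg / (Lr - 56 + Ov)

where Nc counts chimeric reads *including* technical duplicates (they
contribute to N exactly as they do to Nc) and N counts reads aligned to
the viral genome. Assuming the number of inserted fragments per genome is
Poisson with mean Pj/2 (one insertion into a circular genome yields two
junctions), the fraction of genomes carrying at least one host fragment is
1 - exp(-Pj/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

#: a junction must lie this far from a read end to be detectable
MIN_DETECTABLE = 28


@dataclass
class LibraryStats:
    """Per-library quantities feeding the frequency estimator."""

    library_id: str
    Nc: int
    N: int
    Lr: int
    Lg: int
    Ov: float
    group: Optional[str] = None
    Pj: float = field(init=False, default=0.0)
    p_insert: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.Nc > self.N:
            raise ValueError("Nc cannot exceed N")
        if self.Lr not in (101, 151):
            raise ValueError("read length must be 101 or 151")
        self.Pj = estimate_pj(
            self.Nc, self.N, self.Lg, self.Lr, self.Ov
        )
        self.p_insert = proportion_with_insertion(self.Pj)


def estimate_pj(
    Nc: int,
    N: int,
    Lg: int,
    Lr: int,
    Ov: float,
    min_detectable: int = MIN_DETECTABLE,
) -> float:
    """Mean junctions per genome, (Nc/N) * Lg / (Lr - 2*min_detectable + Ov)."""
    if N <= 0:
        raise ValueError("N must be positive")
    denom = Lr - 2 * min_detectable + Ov
    if denom <= 0:
        raise ValueError(
            f"effective detectable span Lr - {2 * min_detectable} + Ov = "
            f"{denom} is not positive"
        )
    return (Nc / N) * Lg / denom


def proportion_with_insertion(pj: float) -> float:
    """Fraction of genomes with >= 1 insertion: 1 - exp(-Pj/2)."""
    if pj < 0:
        raise ValueError("Pj must be non-negative")
    return 1.0 - math.exp(-pj / 2.0)


@dataclass
class FrequencySummary:
    mean: float
    lowest: float
    highest: float
    n_libraries: int
    per_group: dict[str, "FrequencySummary"] = field(default_factory=dict)


def summarize_proportions(
    values: Sequence[float], groups: Optional[Sequence[Optional[str]]] = None
) -> FrequencySummary:
    """Summary of already-computed per-library insertion proportions."""
    if not values:
        raise ValueError("at least one library required")
    if groups is None:
        groups = [None] * len(values)

    class _S:
        def __init__(self, p, g):
            self.p_insert, self.group = p, g

    return summarize_libraries([_S(p, g) for p, g in zip(values, groups)])


def summarize_libraries(stats: Sequence[LibraryStats]) -> FrequencySummary:
    """Unweighted mean and extremes of p_insert, overall and per host group."""
    if not stats:
        raise ValueError("at least one library required")
    values = [s.p_insert for s in stats]
    summary = FrequencySummary(
        mean=sum(values) / len(values),
        lowest=min(values),
        highest=max(values),
        n_libraries=len(values),
    )
    groups = {s.group for s in stats if s.group is not None}
    for g in sorted(groups):
        sub = [s for s in stats if s.group == g]
        vals = [s.p_insert for s in sub]
        summary.per_group[g] = FrequencySummary(
            mean=sum(vals) / len(vals),
            lowest=min(vals),
            highest=max(vals),
            n_libraries=len(vals),
        )
    return summary
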