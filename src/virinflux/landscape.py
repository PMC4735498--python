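"""Insertion landscape along the circular viral genome.

Junction positions are binned into contiguous windows (500 bp for maps,
1,500 bp for models), either counting each unique junction once
("independent" mode, removing amplification through viral replication) or
weighting by supporting reads ("all" mode). Window counts of one host
group are modelled with a log-link Poisson GLM on per-window covariates --
mean sequencing depth, the number of common TE target motifs (TTAA, TTA,
TAA, TA) and the junction count of the other host group -- and candidate
covariate subsets are ranked by small-sample-corrected AIC (AICc), with a
sequential analysis of deviance on the chosen model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

from .junctions import Junction
from .synth import scan_motif

DEFAULT_MOTIFS = ("TTAA", "TTA", "TAA", "TA")
INDEPENDENT = "independent"
ALL = "all"


def window_grid(genome_length: int, window_size: int) -> list[tuple[int, int]]:
    """Contiguous windows tiling the circular genome, anchored at 0.

    A final window shorter than ``window_size`` is merged with the first
    (circularity), so positions in the leftover tail count toward window 0.
    """
    n = max(1, genome_length // window_size)
    return [
        (i * window_size, (i + 1) * window_size if i < n - 1 else genome_length)
        for i in range(n)
    ]


def window_index(position: int, genome_length: int, window_size: int) -> int:
    n = max(1, genome_length // window_size)
    return min(position // window_size, n - 1) if position < n * window_size else 0


def window_junction_counts(
    junctions: Sequence[Junction],
    genome_length: int,
    window_size: int = 500,
    mode: str = INDEPENDENT,
) -> np.ndarray:
    """Junctions per genome window, independent (unique) or read-weighted."""
    if window_size < 100:
        raise ValueError("window_size must be >= 100")
    if mode not in (INDEPENDENT, ALL):
        raise ValueError(f"unknown mode {mode!r}")
    n = max(1, genome_length // window_size)
    counts = np.zeros(n, dtype=float)
    tail_start = n * window_size
    for j in junctions:
        pos = j.virus_position % genome_length
        idx = 0 if pos >= tail_start else min(pos // window_size, n - 1)
        counts[idx] += 1 if mode == INDEPENDENT else j.read_count
    return counts


def window_motif_counts(
    genome: str,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    window_size: int = 500,
) -> pd.DataFrame:
    """Overlap-tolerant motif occurrences per window, forward strand only.

    Occurrences spanning the circular origin are assigned to the window
    containing their first base.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    n = max(1, len(genome) // window_size)
    out = {}
    for motif in motifs:
        counts = np.zeros(n, dtype=int)
        for pos in scan_motif(genome, motif, circular=True):
            counts[window_index(pos, len(genome), window_size)] += 1
        out[motif] = counts
    return pd.DataFrame(out)


@dataclass
class PoissonGLMFit:
    params: pd.Series
    bse: pd.Series
    llf: float
    deviance: float
    null_deviance: float
    aic: float
    aicc: float
    n_obs: int
    k_params: int
    anova: Optional[pd.DataFrame] = None


def _aicc(aic: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_poisson_glm(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    tol: float = 1e-8,
    maxiter: int = 100,
    anova: bool = True,
) -> PoissonGLMFit:
    """Log-link Poisson regression of window counts on covariates.

    Fitted by iteratively reweighted least squares to ``tol``; raises on
    non-convergence. With ``anova``, a sequential (type-I) analysis of
    deviance is computed in the covariate order given.
    """
    y = data[response].to_numpy()
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    if len(data) < 2:
        raise ValueError("at least two windows required")

    def fit(cols: Sequence[str]):
        X = sm.add_constant(data[list(cols)], has_constant="add")
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(tol=tol, maxiter=maxiter)
        if not res.converged:
            raise RuntimeError(
                f"IRLS did not converge in {maxiter} iterations for {cols}"
            )
        return res

    res = fit(covariates)
    k = len(res.params)
    table = None
    if anova:
        rows = []
        prev = fit([]).deviance
        for i, cov in enumerate(covariates):
            dev = fit(covariates[: i + 1]).deviance
            rows.append(
                {
                    "term": cov,
                    "deviance_drop": prev - dev,
                    "df": 1,
                    "residual_deviance": dev,
                    "p_value": float(_st.chi2.sf(prev - dev, 1)),
                }
            )
            prev = dev
        table = pd.DataFrame(rows)
    return PoissonGLMFit(
        params=res.params,
        bse=res.bse,
        llf=float(res.llf),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        aic=float(res.aic),
        aicc=_aicc(float(res.aic), k, len(data)),
        n_obs=len(data),
        k_params=k,
        anova=table,
    )


def select_model_aicc(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
) -> pd.DataFrame:
    """Fit every covariate subset and rank by AICc.

    Returns a model table with one x-marked column per candidate term,
    sorted by AICc (best first). Rank-deficient subsets (e.g. a constant
    covariate) and subsets with n - k - 1 <= 0 are skipped and flagged.
    """
    if len(candidates) > 4:
        raise ValueError("at most 4 candidate covariates (16 subsets)")
    rows = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            X = sm.add_constant(
                data[list(subset)], has_constant="add"
            ).to_numpy(dtype=float)
            if np.linalg.matrix_rank(X) < X.shape[1] or len(data) - X.shape[1] - 1 <= 0:
                rows.append(
                    {
                        **{c: "x" if c in subset else "" for c in candidates},
                        "k": X.shape[1],
                        "aicc": np.nan,
                        "skipped": True,
                    }
                )
                continue
            fitres = fit_poisson_glm(data, response, list(subset), anova=False)
            rows.append(
                {
                    **{c: "x" if c in subset else "" for c in candidates},
                    "k": fitres.k_params,
                    "loglik": fitres.llf,
                    "deviance": fitres.deviance,
                    "aicc": fitres.aicc,
                    "skipped": False,
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values("aicc", na_position="last").reset_index(drop=True)
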