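"""Shuffle-based enrichment tests, empirical p conventions, Mann-Whitney U.

Two permutation designs share one null-generation scheme (chromosome- and
size-preserving non-overlapping shuffles of the contact peaks):

* single-layer: how many target intervals (e.g. cancer-specific SEs) are
  overlapped by at least one shuffled peak per iteration;
* joint two-layer: shuffled contact peaks first "confirm" the correlation
  peaks, and the statistic is the number of SEs carrying at least one
  confirmed peak — the null for the Ψ-SE count.

Empirical p always uses the add-one convention p = (k+1)/(n+1) with k the
number of null draws at or above the observed count: with 1000 iterations a
statistic exceeding the whole null range is reported as 0.001, never 0.
Each iteration draws from its own seeded substream so results do not depend
on scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd

from .contacts import ConsensusContactPeaks
from .intervals import ChromSizes, IntervalSet, intersect_keep, overlaps_any, shuffle
from .se_atlas import ConsensusSE, _as_interval_set


@dataclass
class PermutationResult:
    observed: int
    null_draws: np.ndarray
    n_iter: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_draws))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_draws, ddof=1)) if len(self.null_draws) > 1 else 0.0

    @property
    def null_range(self) -> tuple[int, int]:
        return int(np.min(self.null_draws)), int(np.max(self.null_draws))

    @property
    def p(self) -> float:
        return empirical_p(self.observed, self.null_draws)

    @property
    def fold(self) -> float:
        return fold_enrichment(self.observed, self.null_mean)

    @property
    def k_exceedances(self) -> int:
        return int(np.sum(self.null_draws >= self.observed))

    def format_p(self) -> str:
        """Three-decimal display; '< 1/(n+1)' when no draw reaches the observed."""
        if self.k_exceedances == 0:
            return f"< {1.0 / (self.n_iter + 1):.3f}"
        return f"{self.p:.3f}"

    def summary(self) -> dict:
        lo, hi = self.null_range
        return {
            "observed": self.observed,
            "null_mean": round(self.null_mean, 1),
            "null_sd": round(self.null_sd, 1),
            "null_min": lo,
            "null_max": hi,
            "p": round(self.p, 3),
            "p_display": self.format_p(),
            "fold_enrichment": round(self.fold, 2) if self.null_mean > 0 else None,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Add-one empirical p: (k+1)/(n+1), k = #{null >= observed}."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empirical p needs a non-empty null")
    k = int(np.sum(null >= observed))
    return (k + 1) / (null.size + 1)


def fold_enrichment(observed: float, null_mean: float) -> float:
    if null_mean <= 0:
        raise ValueError(f"fold enrichment needs a positive null mean, got {null_mean}")
    return observed / null_mean


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(iteration)])


def permute_overlap_enrichment(
    targets: IntervalSet,
    peaks: IntervalSet,
    sizes: ChromSizes,
    n_iter: int = 1000,
    seed: int = 0,
    exclude: IntervalSet | None = None,
) -> PermutationResult:
    """Enrichment of peaks at target intervals against a shuffle null.

    Statistic: number of targets overlapped by >=1 peak.
    """
    observed = int(overlaps_any(targets, peaks).sum())
    draws = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        shuffled = shuffle(peaks, sizes, _iteration_rng(seed, it), exclude=exclude)
        draws[it] = int(overlaps_any(targets, shuffled).sum())
    return PermutationResult(observed, draws, n_iter, seed)


def permute_triple_enrichment(
    ses: list[ConsensusSE],
    corr_peaks: pd.DataFrame,
    contacts: ConsensusContactPeaks,
    sizes: ChromSizes,
    n_iter: int = 1000,
    seed: int = 0,
    exclude: IntervalSet | None = None,
) -> PermutationResult:
    """Joint null for the Ψ-SE count: shuffle contacts, re-confirm, recount.

    Only the contact layer is randomised; the correlation peaks and the SE
    set stay fixed, so the null preserves their spatial structure.
    """
    from .psi import confirm_peaks  # deferred: psi imports se_atlas helpers

    se_set = _as_interval_set(ses)
    corr = IntervalSet(corr_peaks) if len(corr_peaks) else IntervalSet()

    def statistic(contact_set: IntervalSet) -> int:
        if len(corr) == 0:
            return 0
        confirmed = intersect_keep(corr, contact_set)
        return int(overlaps_any(se_set, confirmed).sum())

    observed = statistic(contacts.peaks)
    draws = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        shuffled = shuffle(contacts.peaks, sizes, _iteration_rng(seed, it), exclude=exclude)
        draws[it] = statistic(shuffled)
    return PermutationResult(observed, draws, n_iter, seed)


# ---------------------------------------------------------------------------
# Mann-Whitney U (one-sided, x stochastically greater)
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties (mid-rank convention)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_one_sided(
    x: np.ndarray,
    y: np.ndarray,
    exact_limit: int = 12,
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test (alternative: x stochastically greater).

    Exact permutation p by enumerating all pooled-label assignments when
    n_x + n_y <= ``exact_limit`` (ties handled by the mid-rank U); otherwise
    the normal approximation with tie correction and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        total = comb(n1 + n2, n1)
        k = 0
        for chosen in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u >= u_obs - 1e-12:
                k += 1
        return u_obs, k / total
    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_obs, 1.0  # all values tied: no evidence either way
    mu = n1 * n2 / 2.0
    z = (u_obs - mu - 0.5) / sqrt(var)
    p = 0.5 * erfc(z / sqrt(2.0))
    return u_obs, float(min(max(p, 0.0), 1.0))
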