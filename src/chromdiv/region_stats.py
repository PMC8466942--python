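"""Window subsets and one-sided Mann-Whitney comparisons.

Five window subsets (all, noX, onlyX, noPAR, PAR) are built from a
100-kbp heterozygosity track, then compared with one-sided rank-sum
tests: "PAR more heterozygous than autosomes" for every individual and
"autosomes more heterozygous than noPAR" for females, with Bonferroni
correction over the tests actually run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .coverage_sexchrom import ParCall
from .het_windows import WindowTrack

__all__ = [
    "WindowSubsets",
    "TestResult",
    "subset_windows",
    "mann_whitney_one_sided",
    "run_paper_comparisons",
    "SUBSET_LABELS",
]

log = logging.getLogger(__name__)

SUBSET_LABELS = ("all", "noX", "onlyX", "noPAR", "PAR")

# exact enumeration limits; beyond them the tie-corrected normal
# approximation with continuity correction is used
EXACT_MAX_MIN_N = 8
EXACT_MAX_TOTAL = 25


@dataclass
class WindowSubsets:
    all: np.ndarray
    noX: np.ndarray
    onlyX: np.ndarray
    noPAR: np.ndarray
    PAR: np.ndarray

    def __getitem__(self, label: str) -> np.ndarray:
        return getattr(self, label)


@dataclass
class TestResult:
    name: str
    alternative: str
    u: float
    raw_p: float
    adjusted_p: float
    n1: int
    n2: int
    significant: bool | None = None


def subset_windows(track: WindowTrack, x_scaffold: str, par: ParCall) -> WindowSubsets:
    """Partition 100-kbp windows into the five comparison subsets.

    A window belongs to PAR iff its full span lies inside a PAR interval;
    boundary-straddling windows go to noPAR.
    """
    if par.x_scaffold != x_scaffold:
        raise ValueError(
            f"PAR call is on {par.x_scaffold!r}, expected {x_scaffold!r}"
        )
    if x_scaffold not in track.values:
        raise ValueError(f"X scaffold {x_scaffold!r} absent from window track")
    w = track.window_size
    nox = [track.values[s] for s in track.values if s != x_scaffold]
    nox_arr = np.concatenate(nox) if nox else np.empty(0)
    x_vals = track.values[x_scaffold]
    in_par = np.zeros(x_vals.size, dtype=bool)
    for i in range(x_vals.size):
        start, end = i * w, (i + 1) * w
        in_par[i] = any(ps <= start and end <= pe for ps, pe in par.par_intervals)
    subsets = WindowSubsets(
        all=np.concatenate([nox_arr, x_vals]),
        noX=nox_arr,
        onlyX=x_vals,
        noPAR=x_vals[~in_par],
        PAR=x_vals[in_par],
    )
    assert subsets.all.size == subsets.noX.size + subsets.onlyX.size
    assert subsets.onlyX.size == subsets.noPAR.size + subsets.PAR.size
    return subsets


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Mann-Whitney U for sample a (midrank ties) and the pooled ranks."""
    n1 = a.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    return u, ranks


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """P(U >= u_obs) by enumerating all C(n, n1) group assignments."""
    n = ranks.size
    offset = n1 * (n1 + 1) / 2
    count = 0
    total = math.comb(n, n1)
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if u >= u_obs - 1e-9:
            count += 1
    return count / total


def _asymptotic_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        log.warning("degenerate Mann-Whitney: all pooled values tied; p = 1")
        return 1.0
    z = (u_obs - n1 * n2 / 2.0 - 0.5) / math.sqrt(var)
    return float(norm.sf(z))


def mann_whitney_one_sided(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    alternative: str = "a_greater",
    name: str = "",
) -> TestResult:
    """One-sided Mann-Whitney rank-sum test.

    ``alternative="a_greater"`` tests whether values in ``a`` tend to be
    larger than in ``b``.  Exact enumeration is used for small samples
    (min(n1, n2) <= 8 and n1 + n2 <= 25), otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    if alternative not in ("a_greater", "a_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if alternative == "a_less":
        a, b = b, a
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    u, ranks = _u_statistic(a, b)
    if min(n1, n2) <= EXACT_MAX_MIN_N and n1 + n2 <= EXACT_MAX_TOTAL:
        p = _exact_p(ranks, n1, u)
    else:
        p = _asymptotic_p(ranks, n1, n2, u)
    return TestResult(
        name=name,
        alternative=alternative,
        u=u,
        raw_p=p,
        adjusted_p=p,
        n1=n1,
        n2=n2,
    )


def run_paper_comparisons(
    individuals: Mapping[str, tuple[WindowSubsets, str]],
    alpha: float = 0.01,
) -> list[TestResult]:
    """Run the two one-sided comparisons per individual with Bonferroni.

    ``individuals`` maps an individual id to (subsets, sex).  The first
    test ("PAR more heterozygous than autosomes") runs for everyone with
    a non-empty PAR subset; the second ("autosomes more heterozygous
    than noPAR") runs for females only.  The Bonferroni family is the
    set of tests executed in this invocation.
    """
    results: list[TestResult] = []
    for ind, (subsets, sex) in individuals.items():
        if subsets.PAR.size == 0:
            log.warning("individual %s: empty PAR subset, comparison skipped", ind)
        else:
            results.append(
                mann_whitney_one_sided(
                    subsets.PAR,
                    subsets.noX,
                    "a_greater",
                    name=f"{ind}: PAR > autosomes",
                )
            )
        if sex == "female" and subsets.noPAR.size and subsets.noX.size:
            results.append(
                mann_whitney_one_sided(
                    subsets.noX,
                    subsets.noPAR,
                    "a_greater",
                    name=f"{ind}: autosomes > noPAR",
                )
            )
    n_tests = len(results)
    for res in results:
        res.adjusted_p = min(1.0, res.raw_p * n_tests)
        res.significant = res.adjusted_p < alpha
    return results
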