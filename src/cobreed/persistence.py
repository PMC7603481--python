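"""Persistence of co-breeding ties between two periods.

The central object is a 3x3 contingency table cross-classifying every dyad's
period-1 state (together / apart / missing) by its period-2 state. Dyads with
missing data are pulled apart into their own row/column; independence is
tested by a Pearson chi-square on the complete-case 2x2 core (df = 1, no
continuity correction). Power-matched subsampling repeats the test on random
subsets of complete-case dyads of a fixed size, to compare periods with
unequal effective sample sizes on an equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cobreed.errors import DataError, DegenerateTableError
from cobreed.association import STATE_LABELS, DyadState, Sociomatrix

#: maps DyadState value -> row/col index (together, apart, missing)
_STATE_TO_IDX = {
    int(DyadState.TOGETHER): 0,
    int(DyadState.APART): 1,
    int(DyadState.MISSING): 2,
}


@dataclass
class ContingencyTable3x3:
    """Dyad counts cross-classifying period-1 state by period-2 state."""

    counts: np.ndarray  # 3x3, rows = period 1, cols = period 2
    period_labels: tuple[str, str] = ("period1", "period2")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise DataError(f"expected a 3x3 table, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise DataError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def core(self) -> np.ndarray:
        """The 2x2 together/apart complete-case core."""
        return self.counts[:2, :2]

    @property
    def n_core(self) -> int:
        return int(self.core.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(STATE_LABELS, name=self.period_labels[0]),
            columns=pd.Index(STATE_LABELS, name=self.period_labels[1]),
        )


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    n_core: int


@dataclass
class SubsampleResult:
    """Power-matched subsampling of the chi-square test."""

    n_draws: int
    n_target: int
    alpha: float
    frac_significant: float
    n_degenerate: int = 0
    statistics: np.ndarray | None = field(default=None, repr=False)


def build_transition_table(
    s1: Sociomatrix, s2: Sociomatrix
) -> ContingencyTable3x3:
    """Cross-classify every dyad's state in period 1 by its state in period 2.

    Both sociomatrices must be built over the same ordered individual set;
    each of the C(N, 2) dyads contributes exactly one count.
    """
    if s1.individuals != s2.individuals:
        only1 = set(s1.individuals) - set(s2.individuals)
        only2 = set(s2.individuals) - set(s1.individuals)
        raise DataError(
            "sociomatrices cover different individual sets: "
            f"{len(only1)} only in period 1 (e.g. {sorted(only1)[:3]}), "
            f"{len(only2)} only in period 2 (e.g. {sorted(only2)[:3]}); "
            "rebuild both over a common ordering"
        )
    a = np.vectorize(_STATE_TO_IDX.__getitem__)(s1.triu_states())
    b = np.vectorize(_STATE_TO_IDX.__getitem__)(s2.triu_states())
    counts = np.bincount(a * 3 + b, minlength=9).reshape(3, 3)
    labels = (
        f"{min(s1.years)}-{max(s1.years)}" if s1.years else "period1",
        f"{min(s2.years)}-{max(s2.years)}" if s2.years else "period2",
    )
    return ContingencyTable3x3(counts=counts, period_labels=labels)


def chi_square_core(table: ContingencyTable3x3) -> ChiSquareResult:
    """Pearson chi-square of independence on the 2x2 together/apart core.

    df = 1, no continuity correction; p-value from the upper tail of the
    chi-square(1) distribution. Raises if any row or column margin of the
    core is zero (statistic undefined).
    """
    core = table.core
    if (core.sum(axis=0) == 0).any() or (core.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            f"zero margin in 2x2 core {core.tolist()}; chi-square undefined"
        )
    res = stats.chi2_contingency(core, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        n_core=int(core.sum()),
    )


def _core_dyad_codes(s1: Sociomatrix, s2: Sociomatrix) -> np.ndarray:
    """2-bit code per complete-case dyad: 2*state1 + state2 (together=1)."""
    a = s1.triu_states()
    b = s2.triu_states()
    complete = (a != int(DyadState.MISSING)) & (b != int(DyadState.MISSING))
    return (a[complete].astype(np.int64) * 2 + b[complete]).astype(np.int64)


def _chi2_2x2(core: np.ndarray) -> tuple[float, float]:
    """Closed-form Pearson chi-square for a 2x2 table; (nan, nan) if degenerate."""
    n = core.sum()
    r = core.sum(axis=1)
    c = core.sum(axis=0)
    denom = r[0] * r[1] * c[0] * c[1]
    if denom == 0:
        return float("nan"), float("nan")
    det = core[0, 0] * core[1, 1] - core[0, 1] * core[1, 0]
    stat = n * det**2 / denom
    return float(stat), float(stats.chi2.sf(stat, df=1))


def power_matched_subsample(
    s1: Sociomatrix,
    s2: Sociomatrix,
    n_target: int,
    n_draws: int,
    alpha: float,
    rng: np.random.Generator,
    keep_statistics: bool = False,
) -> SubsampleResult:
    """Repeat the core chi-square on random dyad subsets of fixed size.

    Each draw samples ``n_target`` complete-case dyads (both periods
    observed) without replacement, rebuilds the 2x2 core and records whether
    the Pearson chi-square is significant at ``alpha``. Draws whose subsample
    has a zero margin are counted as degenerate and non-significant.
    """
    codes = _core_dyad_codes(s1, s2)
    n_avail = len(codes)
    if n_target > n_avail:
        raise DataError(
            f"n_target={n_target} exceeds the {n_avail} complete-case dyads"
        )
    if n_target < 1 or n_draws < 1:
        raise DataError("n_target and n_draws must be positive")
    n_sig = 0
    n_degen = 0
    stats_out = np.empty(n_draws) if keep_statistics else None
    for d in range(n_draws):
        take = rng.choice(n_avail, size=n_target, replace=False)
        core = np.bincount(codes[take], minlength=4).reshape(2, 2)
        # codes index (state1, state2) with together=1 -> flip to
        # (together, apart) ordering; chi-square is order-invariant anyway
        stat, p = _chi2_2x2(core)
        if np.isnan(stat):
            n_degen += 1
        elif p < alpha:
            n_sig += 1
        if stats_out is not None:
            stats_out[d] = stat
    return SubsampleResult(
        n_draws=n_draws,
        n_target=n_target,
        alpha=alpha,
        frac_significant=n_sig / n_draws,
        n_degenerate=n_degen,
        statistics=stats_out,
    )
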