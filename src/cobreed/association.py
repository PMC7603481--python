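"""Dyadic co-breeding associations from resighting records.

Two individuals are TOGETHER in a year if both were recorded breeding in the
same patch that year, APART if both were recorded but in different patches,
and MISSING if either lacks a record. Over a multi-year period the dyad state
follows the precedence together > apart > missing ("bred in the same patch at
least once"); a dyad with no common observed year in a period is missing for
that period. The half-weight association index (HWI) quantifies tie strength
on the same year-level sampling occasions and is robust to incomplete
censuses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from cobreed.errors import DataError, InvalidDyadError

logger = logging.getLogger(__name__)


class DyadState(IntEnum):
    """Ternary annual/period state of an unordered pair of individuals."""

    APART = 0
    TOGETHER = 1
    MISSING = -1


#: Row/column order used by contingency tables.
STATE_ORDER = (DyadState.TOGETHER, DyadState.APART, DyadState.MISSING)
STATE_LABELS = ("together", "apart", "missing")


def validate_resightings(
    records: pd.DataFrame, strict: bool = True
) -> pd.DataFrame:
    """Check and normalize a resighting table.

    Enforces one breeding patch per (individual, year). Under ``strict``
    (default) a duplicated individual-year is a data error — an individual
    breeds in exactly one patch per season, so conflicting records mean the
    "unequivocal breeder" filter upstream failed. Under lenient handling the
    first record is kept with a warning.
    """
    required = {"individual_id", "year", "colony", "patch_id"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise DataError(f"resighting table lacks columns {sorted(missing_cols)}")
    dup = records.duplicated(["individual_id", "year"], keep="first")
    if dup.any():
        offenders = records.loc[dup, ["individual_id", "year"]]
        if strict:
            first = offenders.iloc[0]
            raise DataError(
                f"{int(dup.sum())} duplicated (individual, year) rows, e.g. "
                f"({first['individual_id']}, {first['year']}); an individual "
                "breeds in one patch per year"
            )
        warnings.warn(
            f"dropping {int(dup.sum())} duplicated (individual, year) rows, "
            "keeping first occurrence",
            stacklevel=2,
        )
        records = records[~dup]
    return records


def _patch_code_matrix(
    records: pd.DataFrame,
    years: list[int],
    individuals: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Individuals x years matrix of integer patch codes (-1 = not recorded)."""
    sub = records[records["year"].isin(years)]
    if sub.duplicated(["individual_id", "year"]).any():
        raise DataError(
            "duplicated (individual, year) rows; run validate_resightings first"
        )
    if individuals is None:
        individuals = sorted(sub["individual_id"].unique())
    else:
        individuals = list(individuals)
        sub = sub[sub["individual_id"].isin(individuals)]
    ind_idx = {ind: k for k, ind in enumerate(individuals)}
    year_idx = {y: k for k, y in enumerate(sorted(years))}
    mat = np.full((len(individuals), len(years)), -1, dtype=np.int64)
    if len(sub):
        codes, _ = pd.factorize(sub["patch_id"])
        rows = sub["individual_id"].map(ind_idx).to_numpy()
        cols = sub["year"].map(year_idx).to_numpy()
        mat[rows, cols] = codes
    return individuals, mat


@dataclass
class Sociomatrix:
    """Symmetric individual x individual dyad-state matrix for a year set.

    ``state`` is an N x N int8 array of :class:`DyadState` codes; the diagonal
    is MISSING by convention (a dyad needs two distinct individuals). The
    network is undirected: ``state[i, j] == state[j, i]`` always.
    """

    individuals: list[str]
    state: np.ndarray
    years: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.individuals)

    def triu_states(self) -> np.ndarray:
        """Upper-triangular (i < j) dyad states as a flat vector."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.state[iu, ju]

    def to_triplets(self, path: str | Path) -> None:
        """Serialize as sparse triplet CSV (i, j, state) over the upper triangle."""
        iu, ju = np.triu_indices(self.n, k=1)
        df = pd.DataFrame(
            {
                "i": [self.individuals[a] for a in iu],
                "j": [self.individuals[b] for b in ju],
                "state": self.state[iu, ju],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_triplets(cls, path: str | Path, years: tuple[int, ...] = ()) -> "Sociomatrix":
        df = pd.read_csv(path)
        individuals = sorted(set(df["i"]) | set(df["j"]))
        idx = {ind: k for k, ind in enumerate(individuals)}
        n = len(individuals)
        state = np.full((n, n), int(DyadState.MISSING), dtype=np.int8)
        a = df["i"].map(idx).to_numpy()
        b = df["j"].map(idx).to_numpy()
        state[a, b] = df["state"].to_numpy()
        state[b, a] = df["state"].to_numpy()
        return cls(individuals=individuals, state=state, years=tuple(years))


@dataclass
class HwiMatrix:
    """Half-weight association indices; NaN marks undefined dyads."""

    individuals: list[str]
    hwi: np.ndarray

    @property
    def n(self) -> int:
        return len(self.individuals)


def dyad_year_state(
    records: pd.DataFrame, i: str, j: str, year: int
) -> DyadState:
    """Annual state of the dyad (i, j): together, apart or missing."""
    if i == j:
        raise InvalidDyadError(f"dyad requires two distinct individuals, got {i!r} twice")
    sub = records[(records["year"] == year)]
    pi = sub.loc[sub["individual_id"] == i, "patch_id"]
    pj = sub.loc[sub["individual_id"] == j, "patch_id"]
    if len(pi) > 1 or len(pj) > 1:
        raise DataError(f"multiple records for an individual in year {year}")
    if pi.empty or pj.empty:
        return DyadState.MISSING
    return (
        DyadState.TOGETHER
        if pi.iloc[0] == pj.iloc[0]
        else DyadState.APART
    )


def build_period_sociomatrix(
    records: pd.DataFrame,
    years: list[int] | range,
    individuals: list[str] | None = None,
) -> Sociomatrix:
    """Period sociomatrix under together > apart > missing precedence.

    A dyad is TOGETHER for the period if it was together in at least one year,
    else APART if both members were recorded in different patches in at least
    one common year, else MISSING ("individuals do not occur in overlapping
    timeframes").
    """
    years = sorted(set(years))
    if not years:
        raise DataError("year set must be nonempty")
    if records[records["year"].isin(years)].empty and individuals is None:
        warnings.warn("no records in the requested period; empty sociomatrix",
                      stacklevel=2)
    ids, mat = _patch_code_matrix(records, years, individuals)
    n = len(ids)
    together = np.zeros((n, n), dtype=bool)
    apart = np.zeros((n, n), dtype=bool)
    for t in range(mat.shape[1]):
        p = mat[:, t]
        obs = p >= 0
        both = obs[:, None] & obs[None, :]
        same = p[:, None] == p[None, :]
        together |= both & same
        apart |= both & ~same
    state = np.full((n, n), int(DyadState.MISSING), dtype=np.int8)
    state[apart] = int(DyadState.APART)
    state[together] = int(DyadState.TOGETHER)  # precedence: together wins
    np.fill_diagonal(state, int(DyadState.MISSING))
    return Sociomatrix(individuals=ids, state=state, years=tuple(years))


def half_weight_index(
    records: pd.DataFrame,
    years: list[int] | range,
    individuals: list[str] | None = None,
) -> HwiMatrix:
    """Half-weight association index per dyad over year-level occasions.

    With x = years together, y_ab = years both seen apart, y_a / y_b = years
    only one member seen::

        HWI = x / (x + y_ab + 0.5 * (y_a + y_b))

    Dyads never seen in any common or one-sided occasion (denominator 0) are
    undefined and returned as NaN.
    """
    years = sorted(set(years))
    if not years:
        raise DataError("year set must be nonempty")
    ids, mat = _patch_code_matrix(records, years, individuals)
    n = len(ids)
    x = np.zeros((n, n))
    y_ab = np.zeros((n, n))
    y_only = np.zeros((n, n))  # y_a + y_b
    for t in range(mat.shape[1]):
        p = mat[:, t]
        obs = p >= 0
        both = obs[:, None] & obs[None, :]
        same = p[:, None] == p[None, :]
        x += both & same
        y_ab += both & ~same
        y_only += obs[:, None] ^ obs[None, :]
    denom = x + y_ab + 0.5 * y_only
    with np.errstate(invalid="ignore", divide="ignore"):
        hwi = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(hwi, np.nan)
    return HwiMatrix(individuals=ids, hwi=hwi)


def export_edges(
    matrix: Sociomatrix | HwiMatrix, min_weight: float | None = None
) -> pd.DataFrame:
    """Undirected edge list (source, target, weight).

    For a :class:`Sociomatrix`, edges are the TOGETHER dyads with weight 1.
    For an :class:`HwiMatrix`, edges are dyads with a defined HWI at least
    ``min_weight`` (default: any positive HWI).
    """
    iu, ju = np.triu_indices(matrix.n, k=1)
    if isinstance(matrix, Sociomatrix):
        vals = matrix.state[iu, ju].astype(float)
        keep = vals == int(DyadState.TOGETHER)
        weights = np.ones(matrix.n * (matrix.n - 1) // 2)
    else:
        vals = matrix.hwi[iu, ju]
        thresh = 0.0 if min_weight is None else min_weight
        with np.errstate(invalid="ignore"):
            keep = np.isfinite(vals) & (
                vals >= thresh if min_weight is not None else vals > 0
            )
        weights = vals
    return pd.DataFrame(
        {
            "source": [matrix.individuals[a] for a in iu[keep]],
            "target": [matrix.individuals[b] for b in ju[keep]],
            "weight": weights[keep],
        }
    )


def write_edges_csv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, index=False)


def write_edges_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    nx.write_graphml(g, path)
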