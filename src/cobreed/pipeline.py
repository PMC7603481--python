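"""End-to-end two-phase study driver.

Reproduces the analysis contrast between a stable phase and a
transition-to-collapse phase: each phase is split into a predictor and an
outcome sub-period, dyadic sociomatrices are built on the common individual
set, tie persistence is tested by the transition-table chi-square and the
lagged-dyad probit network regression, the verdict is refereed by the
patch-size-preserving permutation null, and the stable phase is re-tested at
collapse-phase power by dyad subsampling.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cobreed import ame as ame_mod
from cobreed import association, io as io_mod, permutation, persistence
from cobreed._version import __version__ as _pkg_version
from cobreed.errors import (
    CobreedError,
    ConfigError,
    DataError,
    InsufficientDataError,
)
from cobreed.simulate import SimulationConfig, simulate_colony

logger = logging.getLogger(__name__)


def _years(period: tuple[int, int]) -> list[int]:
    return list(range(period[0], period[1] + 1))


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the full two-phase study.

    Exactly one of ``input_path`` (a resighting CSV) or ``simulation`` must
    be active. Each phase is a pair of inclusive year ranges: the predictor
    sub-period and the outcome sub-period, disjoint and in order. The 5-year
    stable sub-periods are the documented default — wide enough to absorb
    imperfect detection, short enough that mortality does not dominate.
    """

    input_path: str | None = None
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    stable_period: tuple[tuple[int, int], tuple[int, int]] = (
        (2002, 2006),
        (2007, 2011),
    )
    # the collapse phase is predicted from the last five stable years
    collapse_period: tuple[tuple[int, int], tuple[int, int]] = (
        (2007, 2011),
        (2012, 2017),
    )
    mcmc: ame_mod.McmcConfig = field(default_factory=ame_mod.McmcConfig)
    perm_stat: str = "ame_beta_dyad"
    perm_mcmc: ame_mod.McmcConfig | None = None
    n_perm: int = 200
    n_subsample_draws: int = 1000
    alpha: float = 0.05
    individuals: str = "union"
    xdyad_missing: str = "zero"
    strict: bool = True
    hwi_min_weight: float | None = None
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of input_path / simulation must be set"
            )
        for name, (p1, p2) in (
            ("stable_period", self.stable_period),
            ("collapse_period", self.collapse_period),
        ):
            if p1[1] < p1[0] or p2[1] < p2[0]:
                raise ConfigError(f"{name}: sub-periods must be non-empty ranges")
            if p1[1] >= p2[0]:
                raise ConfigError(
                    f"{name}: sub-periods must be disjoint and ordered, got "
                    f"{p1} then {p2}"
                )
        if self.individuals not in ("union", "intersection"):
            raise ConfigError("individuals must be 'union' or 'intersection'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        for key in ("mcmc", "perm_mcmc"):
            if raw.get(key) is not None:
                raw[key] = ame_mod.McmcConfig(**raw[key])
        for key in ("stable_period", "collapse_period"):
            if key in raw:
                raw[key] = tuple(tuple(p) for p in raw[key])
        return cls(**raw)


def read_resightings(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """See :func:`cobreed.io.read_resightings`."""
    return io_mod.read_resightings(path, strict=strict)


def _dyad_total_candidates(
    records: pd.DataFrame, years: list[int], n_common: int
) -> dict[str, int]:
    """Several explicitly labelled ways of counting 'dyadic interactions'."""
    sub = records[records["year"].isin(years)]
    per_year = sub.groupby("year")["individual_id"].nunique()
    dyad_years = int(sum(k * (k - 1) // 2 for k in per_year))
    return {
        "dyads_common_individuals": n_common * (n_common - 1) // 2,
        "dyad_years_observed": dyad_years,
        "sociomatrix_cells": n_common * n_common,
    }


def run_phase_analysis(
    records: pd.DataFrame,
    predictor_years: list[int] | tuple[int, int],
    outcome_years: list[int] | tuple[int, int],
    config: AnalysisConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> dict:
    """One phase: sociomatrices, chi-square, network regression, permutation.

    The common individual set is, by default, every individual recorded in at
    least one of the two sub-periods. Returns a report dict with a
    results-table-style coefficient block (pmean, psd, z-stat, P value), the
    3x3 transition table and the chi-square line, plus logging-friendly
    counts of the data funnel.
    """
    if isinstance(predictor_years, tuple) and len(predictor_years) == 2:
        predictor_years = _years(predictor_years)
    if isinstance(outcome_years, tuple) and len(outcome_years) == 2:
        outcome_years = _years(outcome_years)
    predictor_years = sorted(predictor_years)
    outcome_years = sorted(outcome_years)
    if not predictor_years or not outcome_years:
        raise InsufficientDataError("both sub-periods must be nonempty")
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(
            [config.seed, predictor_years[0], outcome_years[0]]
        )
    mcmc_seed, perm_seed = [
        int(s) & 0x7FFFFFFF for s in seed_seq.generate_state(2)
    ]

    for label, yrs in (("predictor", predictor_years), ("outcome", outcome_years)):
        if not records["year"].isin(yrs).any():
            raise InsufficientDataError(
                f"no records in the {label} sub-period {yrs[0]}-{yrs[-1]}"
            )
    ids = permutation._common_individuals(
        records, predictor_years, outcome_years, config.individuals
    )
    if len(ids) < 3:
        raise InsufficientDataError(
            f"only {len(ids)} individuals recorded in "
            f"{predictor_years[0]}-{outcome_years[-1]}; need at least 3"
        )
    s1 = association.build_period_sociomatrix(
        records, predictor_years, individuals=ids
    )
    s2 = association.build_period_sociomatrix(
        records, outcome_years, individuals=ids
    )
    table = persistence.build_transition_table(s1, s2)
    logger.info(
        "phase %s->%s: %d individuals, %d dyads (%d complete-case)",
        table.period_labels[0], table.period_labels[1],
        len(ids), table.total, table.n_core,
    )

    report: dict = {
        "predictor_years": predictor_years,
        "outcome_years": outcome_years,
        "n_individuals": len(ids),
        "n_dyads": table.total,
        "n_dyads_core": table.n_core,
        "transition_table": table.counts.tolist(),
        "dyad_total_candidates": _dyad_total_candidates(
            records, predictor_years + outcome_years, len(ids)
        ),
    }

    try:
        chi = persistence.chi_square_core(table)
        report["chi_square"] = dataclasses.asdict(chi)
    except CobreedError as exc:
        report["chi_square"] = None
        report["chi_square_error"] = str(exc)

    data = ame_mod.ame_data_from_sociomatrices(
        s2, s1, xdyad_missing=config.xdyad_missing
    )
    mcmc = dataclasses.replace(config.mcmc, seed=mcmc_seed)
    fit = ame_mod.fit_ame_probit(data, mcmc)
    report["ame"] = {
        "coefficients": dict(ame_mod.summaries_as_table(fit)),
        "sigma2_a_pmean": float(np.mean(fit.draws["sigma2_a"])),
        "imputation_rate": fit.imputation_rate,
        "n_x_missing_as_zero": data.n_x_imputed_zero,
        "rhat": fit.rhat,
        "warnings": fit.warnings,
    }

    if config.n_perm > 0:
        perm = permutation.permutation_test(
            records,
            predictor_years,
            outcome_years,
            stat=config.perm_stat,
            n_perm=config.n_perm,
            level=config.alpha,
            rng=np.random.default_rng(perm_seed),
            mcmc=config.perm_mcmc,
            individuals=config.individuals,
        )
        report["permutation"] = {
            "stat_name": perm.stat_name,
            "observed": perm.observed_stat,
            "n_perm": perm.n_perm,
            "rank_extremeness": perm.rank_extremeness,
            "reject": perm.reject,
            "level": perm.level,
            "failures": perm.failures,
        }
        report["_null_stats"] = perm.null_stats
    else:
        report["permutation"] = None
        logger.info("permutation stage skipped (n_perm=0)")
    return report


def _phase_edges(
    records: pd.DataFrame, years: list[int], min_weight: float | None
) -> pd.DataFrame:
    hwi = association.half_weight_index(records, years)
    return association.export_edges(hwi, min_weight=min_weight)


def _render_text_report(report: dict) -> str:
    lines = [f"cobreed {_pkg_version} two-phase study report", ""]
    for phase in ("stable", "collapse"):
        block = report.get(phase)
        if block is None:
            continue
        lines.append(f"== {phase} phase "
                     f"({block['predictor_years'][0]}-{block['outcome_years'][-1]}) ==")
        lines.append(
            f"individuals: {block['n_individuals']}   dyads: {block['n_dyads']}"
            f"   complete-case dyads: {block['n_dyads_core']}"
        )
        for name, cnt in block["dyad_total_candidates"].items():
            lines.append(f"  dyadic-interaction count [{name}]: {cnt}")
        chi = block.get("chi_square")
        if chi:
            lines.append(
                f"chi-square (2x2 core): {chi['statistic']:.3f}, df={chi['df']}, "
                f"P={chi['p_value']:.4g}, n={chi['n_core']}"
            )
        else:
            lines.append(f"chi-square: unavailable ({block.get('chi_square_error')})")
        lines.append("AME coefficients (pmean, psd, z-stat, P value):")
        for coef, s in block["ame"]["coefficients"].items():
            lines.append(
                f"  {coef:10s} {s['pmean']:+.3f}  {s['psd']:.3f}  "
                f"{s['z-stat']:+.3f}  {s['P value']:.3g}"
            )
        perm = block.get("permutation")
        if perm:
            lines.append(
                f"permutation null ({perm['stat_name']}, {perm['n_perm']} reps): "
                f"observed {perm['observed']:.3f}, extremeness "
                f"{perm['rank_extremeness']:.4f}, reject={perm['reject']}"
            )
        lines.append("")
    sub = report.get("power_matched_subsample")
    if sub:
        lines.append(
            f"power-matched subsampling: {sub['n_draws']} draws of "
            f"{sub['n_target']} dyads -> {100 * sub['frac_significant']:.1f}% "
            f"significant at alpha={sub['alpha']}"
        )
    elif report.get("power_matched_subsample_error"):
        lines.append(
            "power-matched subsampling failed: "
            + report["power_matched_subsample_error"]
        )
    return "\n".join(lines) + "\n"


def run_full_study(config: AnalysisConfig, output_dir: str | Path | None = None) -> dict:
    """Run both phases, the subsampling stage, and write all artifacts.

    Writes into ``output_dir`` (default from config): ``report.json`` and
    ``report.txt``, per-phase HWI edge lists (CSV and GraphML), per-phase
    permutation null distributions as single-column text, the simulated
    resighting table when simulating, and a ``manifest.json`` with seeds and
    versions. Identical configs give byte-identical ``report.json``.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.seed)
    sim_seq, stable_seq, collapse_seq, sub_seq = root_seq.spawn(4)

    if config.simulation is not None:
        sim_cfg = dataclasses.replace(
            config.simulation,
            seed=int(sim_seq.generate_state(1)[0]) & 0x7FFFFFFF,
        )
        records, _truth = simulate_colony(sim_cfg)
        records.to_csv(out / "resightings.csv", index=False)
        source = {"kind": "simulation", "config": dataclasses.asdict(sim_cfg)}
    else:
        records = read_resightings(config.input_path, strict=config.strict)
        source = {"kind": "file", "path": str(config.input_path)}
    logger.info(
        "input: %d records, %d individuals",
        len(records), records["individual_id"].nunique(),
    )

    report: dict = {"source": source}
    phases = {
        "stable": (config.stable_period, stable_seq),
        "collapse": (config.collapse_period, collapse_seq),
    }
    for phase, ((pred, outc), seq) in phases.items():
        try:
            block = run_phase_analysis(
                records, pred, outc, config, seed_seq=seq
            )
        except CobreedError as exc:
            report[phase] = None
            report[f"{phase}_error"] = f"{phase}: {exc}"
            logger.error("%s phase failed: %s", phase, exc)
            continue
        nulls = block.pop("_null_stats", None)
        if nulls is not None:
            np.savetxt(out / f"null_{phase}.txt", nulls)
        report[phase] = block
        phase_years = _years(pred) + _years(outc)
        edges = _phase_edges(records, phase_years, config.hwi_min_weight)
        association.write_edges_csv(edges, out / f"edges_{phase}.csv")
        association.write_edges_graphml(edges, out / f"edges_{phase}.graphml")

    # stable phase re-tested at collapse power
    report["power_matched_subsample"] = None
    if report.get("stable") and report.get("collapse"):
        n_target = report["collapse"]["n_dyads_core"]
        ids = permutation._common_individuals(
            records,
            _years(config.stable_period[0]),
            _years(config.stable_period[1]),
            config.individuals,
        )
        s1 = association.build_period_sociomatrix(
            records, _years(config.stable_period[0]), individuals=ids
        )
        s2 = association.build_period_sociomatrix(
            records, _years(config.stable_period[1]), individuals=ids
        )
        try:
            sub = persistence.power_matched_subsample(
                s1,
                s2,
                n_target=n_target,
                n_draws=config.n_subsample_draws,
                alpha=config.alpha,
                rng=np.random.default_rng(
                    int(sub_seq.generate_state(1)[0]) & 0x7FFFFFFF
                ),
            )
            report["power_matched_subsample"] = {
                "n_draws": sub.n_draws,
                "n_target": sub.n_target,
                "alpha": sub.alpha,
                "frac_significant": sub.frac_significant,
                "n_degenerate": sub.n_degenerate,
            }
        except DataError as exc:
            report["power_matched_subsample_error"] = str(exc)
            logger.error("subsampling failed: %s", exc)

    io_mod.write_json(report, out / "report.json")
    (out / "report.txt").write_text(_render_text_report(report))
    manifest = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": _config_dict(config),
    }
    io_mod.write_json(manifest, out / "manifest.json")
    return report


def _config_dict(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
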