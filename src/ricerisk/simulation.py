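"""Monte Carlo engine propagating concentration uncertainty through the dose model.

Each iteration draws one concentration and applies it to every age group —
the iteration represents a lifetime lived under one long-run mean
concentration, so age-group risks are fully correlated within an iteration.
This choice affects percentiles but not means, because the dose equations
are linear in concentration; the linearity also gives the engine its
closed-form oracle (:func:`closed_form_ilcr` at the distribution mean).

Exposure factors are fixed constants per age group: intake and body-weight
data do not support a defensible variability distribution, so uncertainty
enters through the concentration alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concentration import FittedDistribution, sample_concentrations
from .exposure_model import (
    ExposureTable,
    RiskConstants,
    add_coefficient,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings.

    ``percentiles`` are the empirical quantiles reported per cell (linear
    interpolation between order statistics). ``param_convention`` is passed
    through to the lognormal sampler.
    """

    iterations: int = 100_000
    seed: int | None = 0
    percentiles: tuple[float, ...] = (50.0, 95.0)
    ci_level: float = 0.95
    param_convention: str = "log_scale"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if any(not 0.0 < p < 100.0 for p in self.percentiles):
            raise ValueError("percentiles must lie in (0, 100)")
        object.__setattr__(self, "percentiles", tuple(float(p) for p in self.percentiles))


@dataclass(frozen=True)
class RiskSummary:
    """Per-age and lifetime risk statistics from one Monte Carlo run.

    ``per_group`` maps age label -> {"cancer": stats, "hq": stats}; each
    stats dict holds ``mean`` and ``p<q>`` entries. ``lifetime`` holds the
    same for keys ``ilcr`` and ``hq``. ``metadata`` echoes the configuration,
    the concentration model and the risk constants so a run can be rerun
    bit-identically.
    """

    per_group: dict
    lifetime: dict
    metadata: dict

    @property
    def lifetime_ilcr_mean(self) -> float:
        return self.lifetime["ilcr"]["mean"]

    @property
    def lifetime_hq_mean(self) -> float:
        return self.lifetime["hq"]["mean"]

    def to_dict(self) -> dict:
        return {
            "per_group": self.per_group,
            "lifetime": self.lifetime,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def _table(self, key: str, lifetime_key: str, lifetime_label: str) -> pd.DataFrame:
        pct = self.metadata["config"]["percentiles"]
        cols = ["mean"] + [f"p{int(p) if float(p).is_integer() else p}" for p in pct]
        rows = []
        for label, cells in self.per_group.items():
            rows.append({"age": label, **{c: cells[key][c] for c in cols}})
        rows.append({"age": lifetime_label, **{c: self.lifetime[lifetime_key][c] for c in cols}})
        return pd.DataFrame(rows)

    def cancer_table(self) -> pd.DataFrame:
        """Per-age cancer risk and lifetime ILCR (mean and percentiles)."""
        return self._table("cancer", "ilcr", "ILCR")

    def hq_table(self) -> pd.DataFrame:
        """Per-age fractional HQ and lifetime HQ (mean and percentiles)."""
        return self._table("hq", "hq", "HQ (lifetime)")


def summarize_draws(
    draws: Sequence[float], percentiles: Sequence[float] = (50.0, 95.0)
) -> tuple[float, dict[str, float], float]:
    """Mean, percentile map and Monte Carlo standard error of a draw vector.

    Percentiles use linear interpolation between closest order statistics;
    the MC standard error is ``sd / sqrt(n)`` with the sample (n-1) sd.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("summarize_draws requires at least one draw")
    mean = float(np.mean(x))
    pmap = {
        f"p{int(p) if float(p).is_integer() else p}": float(
            np.percentile(x, p, method="linear")
        )
        for p in percentiles
    }
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return mean, pmap, se


def closed_form_ilcr(
    mean_c: float, table: ExposureTable, constants: RiskConstants
) -> tuple[float, float]:
    """Deterministic (ILCR, HQ) at a fixed concentration ``mean_c`` (ng/g).

    Because dose is linear in concentration, evaluating at the distribution
    mean reproduces the Monte Carlo mean exactly in expectation; this is the
    engine's independent oracle.
    """
    if mean_c < 0:
        raise ValueError("mean concentration must be >= 0")
    ilcr = 0.0
    hq = 0.0
    for g in table:
        add = mean_c * add_coefficient(g)
        w = g.exposure_duration / constants.lifetime_years
        ilcr += add * constants.slope_factor * w
        hq += add / constants.reference_dose * w
    return ilcr, hq


def run_simulation(
    dist: FittedDistribution,
    table: ExposureTable,
    constants: RiskConstants = RiskConstants(),
    config: SimulationConfig = SimulationConfig(),
) -> RiskSummary:
    """Propagate the fitted concentration model through the dose equations.

    One concentration draw per iteration is shared by all age groups; the
    per-iteration lifetime ILCR and HQ are within-iteration sums over
    groups. Deterministic given ``config.seed``.
    """
    if len(table) == 0:
        raise ValueError("exposure table must contain at least one age group")
    table.validate_against(constants)

    rng = np.random.default_rng(config.seed)
    c = sample_concentrations(
        dist, config.iterations, seed=rng, param_convention=config.param_convention
    )

    per_group: dict[str, dict] = {}
    ilcr_draws = np.zeros(config.iterations)
    hq_draws = np.zeros(config.iterations)
    for g in table:
        add = c * add_coefficient(g)
        w = g.exposure_duration / constants.lifetime_years
        cancer = add * constants.slope_factor * w
        hq = add / constants.reference_dose * w
        ilcr_draws += cancer
        hq_draws += hq
        c_mean, c_p, _ = summarize_draws(cancer, config.percentiles)
        h_mean, h_p, _ = summarize_draws(hq, config.percentiles)
        per_group[g.label] = {
            "cancer": {"mean": c_mean, **c_p},
            "hq": {"mean": h_mean, **h_p},
        }

    il_mean, il_p, il_se = summarize_draws(ilcr_draws, config.percentiles)
    hq_mean, hq_p, hq_se = summarize_draws(hq_draws, config.percentiles)
    lifetime = {
        "ilcr": {"mean": il_mean, **il_p, "mc_se": il_se},
        "hq": {"mean": hq_mean, **hq_p, "mc_se": hq_se},
    }
    metadata = {
        "package_version": __version__,
        "config": {
            "iterations": config.iterations,
            "seed": config.seed,
            "percentiles": list(config.percentiles),
            "ci_level": config.ci_level,
            "param_convention": config.param_convention,
        },
        "distribution": dist.to_dict(),
        "constants": {
            "slope_factor": constants.slope_factor,
            "reference_dose": constants.reference_dose,
            "lifetime_years": constants.lifetime_years,
        },
        "shared_draw_across_age_groups": True,
    }
    return RiskSummary(per_group=per_group, lifetime=lifetime, metadata=metadata)
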