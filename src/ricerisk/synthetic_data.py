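"""Synthetic inputs for the risk pipeline: concentration datasets, exposure tables, As-Cd pairs.

The generators emulate the structure of a Brazilian rice survey — white
market rice, brown rice split between farm and market origins with cultivar
labels — and an age-stratified exposure table satisfying the printed
aggregate constraints (adult intake 167 g/day, all-age ED-weighted mean
156.6 g/day, exposure frequency 6/7 of the year). They produce realistic
stand-ins, not reconstructions of any real survey's microdata.

Default study conditions:

- white rice: zero-truncated Normal(100.17, 44.62) ng/g, n = 64, market;
- brown rice: n = 90 split 69 farm / 21 market; the farm stratum is
  composed of cultivar substrata (Irga 424: mean 80.7, sd 22.35, n = 19;
  Puita: mean 46.6, sd 31.69, n = 48; unlabelled: n = 2) and the market
  stratum has mean 154.91, sd 44.8 — all lognormal, moment-matched;
- As-Cd pairs: near-zero correlation (r = 0.049) between arsenic and
  cadmium, as expected for flooded-paddy cultivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .concentration import (
    ConcentrationDataset,
    ConcentrationSample,
    FittedDistribution,
    sample_concentrations,
)
from .exposure_model import AgeGroupExposure, ExposureTable

#: Exposure frequency for a staple eaten 6 days a week: 6/7 * 365 days/year.
DEFAULT_EXPOSURE_FREQUENCY = 6.0 * 365.0 / 7.0


def lognormal_from_moments(mean: float, sd: float) -> dict[str, float]:
    """Log-scale (mu, sigma) of the lognormal with given arithmetic moments."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}


@dataclass(frozen=True)
class StratumSpec:
    """One metadata stratum of a synthetic concentration dataset."""

    rice_type: str
    origin: str
    n: int
    family: str
    params: dict
    truncate: bool = True
    city: str | None = None
    state: str | None = None
    variety: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("stratum n must be >= 1")
        # parameter validity is delegated to FittedDistribution
        FittedDistribution(self.family, dict(self.params), truncate_at_zero=self.truncate)


@dataclass(frozen=True)
class DatasetSpec:
    """Stratified sampling plan for a synthetic concentration dataset."""

    strata: tuple[StratumSpec, ...]
    seed: int = 0
    provenance: str = "synthetic"

    def __init__(self, strata, seed: int = 0, provenance: str = "synthetic"):
        object.__setattr__(self, "strata", tuple(strata))
        object.__setattr__(self, "seed", seed)
        object.__setattr__(self, "provenance", provenance)


def default_white_spec(seed: int = 0) -> DatasetSpec:
    """White market rice: zero-truncated Normal(100.17, 44.62) ng/g, n = 64."""
    return DatasetSpec(
        strata=[
            StratumSpec(
                rice_type="white",
                origin="market",
                n=64,
                family="normal",
                params={"mean": 100.17, "sd": 44.62},
            )
        ],
        seed=seed,
        provenance="synthetic white-rice survey",
    )


def default_brown_spec(seed: int = 0) -> DatasetSpec:
    """Brown rice, 69 farm + 21 market samples, lognormal moment-matched strata.

    Farm samples carry cultivar labels; pooled farm moments approximate
    (57.36, 34.36) ng/g and the market stratum (154.91, 44.8) ng/g.
    """
    return DatasetSpec(
        strata=[
            StratumSpec(
                rice_type="brown", origin="farm", n=19, family="lognormal",
                params=lognormal_from_moments(80.7, 22.35),
                state="RS", variety="Irga 424",
            ),
            StratumSpec(
                rice_type="brown", origin="farm", n=48, family="lognormal",
                params=lognormal_from_moments(46.6, 31.69),
                state="RS", variety="Puita",
            ),
            StratumSpec(
                rice_type="brown", origin="farm", n=2, family="lognormal",
                params=lognormal_from_moments(57.36, 34.36),
                state="SC", variety=None,
            ),
            StratumSpec(
                rice_type="brown", origin="market", n=21, family="lognormal",
                params=lognormal_from_moments(154.91, 44.8),
            ),
        ],
        seed=seed,
        provenance="synthetic brown-rice survey",
    )


def generate_dataset(spec: DatasetSpec) -> ConcentrationDataset:
    """Draw a stratified synthetic concentration dataset; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    samples: list[ConcentrationSample] = []
    for i, st in enumerate(spec.strata):
        dist = FittedDistribution(st.family, dict(st.params), truncate_at_zero=st.truncate)
        draws = sample_concentrations(dist, st.n, seed=rng)
        for j, v in enumerate(draws):
            samples.append(
                ConcentrationSample(
                    sample_id=f"{st.rice_type}-{st.origin}-s{i}-{j:04d}",
                    rice_type=st.rice_type,
                    origin=st.origin,
                    city=st.city,
                    state=st.state,
                    variety=st.variety,
                    ias_ng_g=float(v),
                )
            )
    return ConcentrationDataset(samples, provenance=spec.provenance)


#: Piecewise-linear body-weight anchors (age in years, kg): infancy through
#: an adult plateau with a mild decline after 65. Fixture constants for the
#: synthetic table, not population claims.
DEFAULT_BW_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.67, 8.0),
    (1.0, 10.0),
    (5.0, 18.0),
    (10.0, 32.0),
    (15.0, 52.0),
    (20.0, 60.0),
    (65.0, 60.0),
    (70.0, 58.0),
)

#: Relative ingestion shape for child bins (< 10 years), scaled to meet the
#: all-age mean; bins of 10 years and older use the adult survey rate.
_CHILD_SHAPE: dict[str, float] = {"<1": 0.4, **{str(a): 0.6 + 0.05 * a for a in range(1, 10)}}


@dataclass(frozen=True)
class ExposureTableSpec:
    """Aggregate constraints for the synthetic age-stratified exposure table."""

    adult_intake_g_day: float = 167.0
    all_age_mean_g_day: float = 156.6
    exposure_frequency: float = DEFAULT_EXPOSURE_FREQUENCY
    bw_anchors: tuple[tuple[float, float], ...] = DEFAULT_BW_ANCHORS

    def __post_init__(self) -> None:
        if self.adult_intake_g_day <= 0 or self.all_age_mean_g_day <= 0:
            raise ValueError("intake targets must be > 0")


def _age_bins() -> list[tuple[str, float, float]]:
    """(label, age_start, age_end) for the 27 standard bins, starting at 4 months."""
    bins: list[tuple[str, float, float]] = [("<1", 1.0 - 8.0 / 12.0, 1.0)]
    bins += [(str(a), float(a), float(a + 1)) for a in range(1, 20)]
    bins += [
        ("20 to <25", 20.0, 25.0),
        ("25 to <30", 25.0, 30.0),
        ("30 to <35", 30.0, 35.0),
        ("35 to <45", 35.0, 45.0),
        ("45 to <55", 45.0, 55.0),
        ("55 to <65", 55.0, 65.0),
        ("65 to <70", 65.0, 70.0),
    ]
    return bins


def generate_exposure_table(spec: ExposureTableSpec = ExposureTableSpec()) -> ExposureTable:
    """Build the 27-bin exposure table satisfying the aggregate intake constraints.

    Solid food (and rice) consumption is taken to start at 4 months, so the
    "<1" bin spans 1/3-1 year (ED = 8/12) and the full table covers
    0.33-70 years (total ED about 69.67). Bins of 10 years and older use
    the adult survey intake; younger bins follow a rising shape scaled so
    the ED-weighted all-age mean hits the target exactly. Body weight is
    interpolated at bin midpoints from the anchor curve; exposure frequency
    is constant.
    """
    if spec.all_age_mean_g_day >= spec.adult_intake_g_day:
        raise ValueError(
            "all-age mean intake must be below the adult intake: children eat less"
        )
    bins = _age_bins()
    ed = np.array([end - start for _, start, end in bins])
    total_ed = float(ed.sum())

    is_child = np.array([start < 10.0 for _, start, _ in bins])
    shape = np.array([_CHILD_SHAPE.get(label, 0.0) for label, _, _ in bins])
    adult_ed_sum = float(ed[~is_child].sum())
    child_weight = float((ed[is_child] * shape[is_child]).sum())
    needed = spec.all_age_mean_g_day * total_ed - spec.adult_intake_g_day * adult_ed_sum
    scale = needed / child_weight
    if scale < 0:
        raise ValueError("infeasible intake targets: child rates would be negative")

    anchors = np.array(spec.bw_anchors, dtype=float)
    groups = []
    for (label, start, end), child, s in zip(bins, is_child, shape):
        mid = (start + end) / 2.0
        bw = float(np.interp(mid, anchors[:, 0], anchors[:, 1]))
        ir = scale * s if child else spec.adult_intake_g_day
        groups.append(
            AgeGroupExposure(
                label=label,
                age_start=start,
                age_end=end,
                exposure_duration=end - start,
                ingestion_rate=float(ir),
                body_weight=bw,
                exposure_frequency=spec.exposure_frequency,
            )
        )
    return ExposureTable(groups)


def generate_as_cd_pairs(
    n: int,
    target_r: float = 0.049,
    mean_as: float = 57.36,
    sd_as: float = 34.36,
    mean_cd: float = 25.0,
    sd_cd: float = 12.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired arsenic/cadmium concentrations with a target Pearson correlation.

    Draws from a bivariate normal with the requested correlation; pairs with
    any negative component are rejected and redrawn, so outputs are
    nonnegative (which perturbs the realized correlation only slightly when
    means sit well above zero).
    """
    if not -1.0 < target_r < 1.0:
        raise ValueError("target_r must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = np.array([mean_as, mean_cd])
    cov = np.array(
        [
            [sd_as**2, target_r * sd_as * sd_cd],
            [target_r * sd_as * sd_cd, sd_cd**2],
        ]
    )
    draws = rng.multivariate_normal(mean, cov, size=n)
    bad = (draws < 0).any(axis=1)
    while bad.any():
        draws[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()))
        bad = (draws < 0).any(axis=1)
    return draws[:, 0].copy(), draws[:, 1].copy()
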