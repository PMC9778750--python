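"""Concentration datasets: I/O, descriptive statistics, distribution fitting, sampling.

Candidate parametric families for the contaminant concentration are the
normal, lognormal and exponential distributions, fit by maximum likelihood
and ranked by AIC (``2k - 2 log L``). The selected model is the sampling
source for the Monte Carlo risk engine.

Lognormal parameters follow the log-scale convention by default: ``mu`` and
``sigma`` are the mean and standard deviation of log concentration. A
published lognormal quoted as "(mean; sd)" is ambiguous between that
convention and the arithmetic mean/sd of the concentrations themselves —
a classic pitfall in exposure assessment — so the sampler also accepts
``param_convention="arithmetic"``, which reinterprets ``(mu, sigma)`` as the
arithmetic moments and converts internally.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RiceType = Literal["white", "brown"]
Origin = Literal["farm", "market", "unknown"]
Family = Literal["normal", "lognormal", "exponential"]
ParamConvention = Literal["log_scale", "arithmetic"]

#: Fixed family order used for AIC tie-breaking (fewest skew assumptions first).
FAMILY_ORDER: tuple[str, ...] = ("normal", "lognormal", "exponential")

#: Bit-exact header of the concentration-dataset CSV interface.
DATASET_CSV_COLUMNS = [
    "sample_id",
    "rice_type",
    "origin",
    "city",
    "state",
    "variety",
    "ias_ng_g",
    "cd_ng_g",
]


class EmptyDatasetError(ValueError):
    """Raised when an operation requires samples but none are available."""


class InsufficientDataError(ValueError):
    """Raised when too few observations are available for a fit or test."""


@dataclass(frozen=True)
class ConcentrationSample:
    """One rice sample: inorganic-arsenic level (ng/g raw rice) plus metadata."""

    sample_id: str
    rice_type: str
    ias_ng_g: float
    origin: str = "unknown"
    city: str | None = None
    state: str | None = None
    variety: str | None = None
    cd_ng_g: float | None = None

    def __post_init__(self) -> None:
        if self.rice_type not in ("white", "brown"):
            raise ValueError(f"rice_type must be 'white' or 'brown', got {self.rice_type!r}")
        if self.origin not in ("farm", "market", "unknown"):
            raise ValueError(f"origin must be farm/market/unknown, got {self.origin!r}")
        if self.ias_ng_g < 0:
            raise ValueError("ias_ng_g must be >= 0")
        if self.cd_ng_g is not None and self.cd_ng_g < 0:
            raise ValueError("cd_ng_g must be >= 0")


@dataclass(frozen=True)
class ConcentrationDataset:
    """Collection of concentration samples with a free-text provenance note."""

    samples: tuple[ConcentrationSample, ...]
    provenance: str = ""

    def __init__(self, samples: Iterable[ConcentrationSample], provenance: str = ""):
        object.__setattr__(self, "samples", tuple(samples))
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def values(self, rice_type: str | None = None) -> np.ndarray:
        """iAs concentrations (ng/g), optionally restricted to one rice type."""
        return np.array(
            [s.ias_ng_g for s in self.samples if rice_type is None or s.rice_type == rice_type],
            dtype=float,
        )

    def subset(self, **criteria: str) -> "ConcentrationDataset":
        """Samples whose metadata fields equal the given values."""
        kept = [
            s
            for s in self.samples
            if all(getattr(s, k) == v for k, v in criteria.items())
        ]
        return ConcentrationDataset(kept, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "rice_type": s.rice_type,
                    "origin": s.origin,
                    "city": s.city,
                    "state": s.state,
                    "variety": s.variety,
                    "ias_ng_g": s.ias_ng_g,
                    "cd_ng_g": s.cd_ng_g,
                }
                for s in self.samples
            ],
            columns=DATASET_CSV_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_dataset(path: str | Path) -> ConcentrationDataset:
    """Read a concentration dataset from delimited text.

    Rows with negative iAs are skipped with a logged warning; missing
    metadata maps to ``unknown``/absent. Raises :class:`EmptyDatasetError`
    if no valid rows remain.
    """
    df = pd.read_csv(path)
    missing = {"sample_id", "rice_type", "ias_ng_g"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset {path} missing required columns: {sorted(missing)}")

    samples: list[ConcentrationSample] = []
    n_skipped = 0
    for row in df.to_dict(orient="records"):
        ias = float(row["ias_ng_g"])
        if ias < 0:
            n_skipped += 1
            logger.warning(
                "skipping sample %r: negative iAs concentration %g ng/g",
                row.get("sample_id"), ias,
            )
            continue

        def _text(key: str) -> str | None:
            v = row.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return str(v)

        origin = _text("origin") or "unknown"
        cd = row.get("cd_ng_g")
        cd = None if cd is None or (isinstance(cd, float) and math.isnan(cd)) else float(cd)
        samples.append(
            ConcentrationSample(
                sample_id=str(row["sample_id"]),
                rice_type=str(row["rice_type"]).strip().lower(),
                ias_ng_g=ias,
                origin=origin,
                city=_text("city"),
                state=_text("state"),
                variety=_text("variety"),
                cd_ng_g=cd,
            )
        )
    if not samples:
        raise EmptyDatasetError(f"no valid samples in {path}")
    if n_skipped:
        logger.warning("excluded %d row(s) with negative concentrations", n_skipped)
    return ConcentrationDataset(samples, provenance=str(path))


def descriptive_stats(
    ds: ConcentrationDataset, group_by: str | None = None
) -> pd.DataFrame:
    """Per-group n, mean, sd (sample, n-1 divisor), min and max of iAs.

    ``group_by`` may name any sample metadata field (``rice_type``,
    ``origin``, ``city``, ``state``, ``variety``); ``None`` pools everything.
    Groups of a single sample report ``sd`` as NaN.
    """
    if len(ds) == 0:
        raise EmptyDatasetError("cannot summarize an empty dataset")
    df = ds.to_frame()
    if group_by is not None:
        if group_by not in ("rice_type", "origin", "city", "state", "variety"):
            raise ValueError(f"unknown grouping field {group_by!r}")
        grouped = df.groupby(group_by, dropna=True)["ias_ng_g"]
    else:
        grouped = df.assign(_all="all").groupby("_all")["ias_ng_g"]
    out = grouped.agg(n="count", mean="mean", sd="std", min="min", max="max")
    return out


@dataclass(frozen=True)
class FittedDistribution:
    """A parametric concentration model: family, parameters, fit diagnostics.

    ``params`` keys are family-specific — normal: ``mean``, ``sd``;
    lognormal: ``mu``, ``sigma`` (log scale); exponential: ``rate``.
    ``truncate_at_zero`` controls sampling only: negative normal draws are
    rejected and resampled so concentrations stay physical.
    """

    family: str
    params: dict
    n: int = 0
    log_likelihood: float = float("nan")
    aic: float = float("nan")
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILY_ORDER:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "normal" and self.params["sd"] < 0:
            raise ValueError("normal sd must be >= 0")
        if self.family == "lognormal" and self.params["sigma"] < 0:
            raise ValueError("lognormal sigma must be >= 0")
        if self.family == "exponential" and self.params["rate"] <= 0:
            raise ValueError("exponential rate must be > 0")

    @property
    def k(self) -> int:
        """Number of free parameters (normal/lognormal 2, exponential 1)."""
        return 1 if self.family == "exponential" else 2

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "n": self.n,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "truncate_at_zero": self.truncate_at_zero,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDistribution":
        return cls(
            family=d["family"],
            params=dict(d["params"]),
            n=int(d.get("n", 0)),
            log_likelihood=float(d.get("log_likelihood", float("nan"))),
            aic=float(d.get("aic", float("nan"))),
            truncate_at_zero=bool(d.get("truncate_at_zero", True)),
        )


def fit_family(values: Sequence[float], family: str) -> FittedDistribution:
    """Maximum-likelihood fit of one family.

    Closed-form MLEs: normal ``(mean, sd_n)`` with the n-divisor sd;
    lognormal ``(mean, sd_n)`` of log values (nonpositive values are
    excluded from this family only, with a logged count); exponential
    ``rate = 1/mean``. AIC is ``2k - 2 log L``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 values to fit, got {x.size}")

    if family == "normal":
        mean = float(np.mean(x))
        sd = float(np.sqrt(np.mean((x - mean) ** 2)))
        # constant data: the likelihood is unbounded at the point mass
        ll = math.inf if sd == 0 else float(np.sum(stats.norm.logpdf(x, loc=mean, scale=sd)))
        fit = FittedDistribution("normal", {"mean": mean, "sd": sd}, n=int(x.size),
                                 log_likelihood=ll, aic=float("nan"))
    elif family == "lognormal":
        pos = x[x > 0]
        n_dropped = x.size - pos.size
        if n_dropped:
            logger.warning(
                "lognormal fit: excluded %d nonpositive value(s) of %d", n_dropped, x.size
            )
        if pos.size < 2:
            raise InsufficientDataError("need at least 2 positive values for a lognormal fit")
        logs = np.log(pos)
        mu = float(np.mean(logs))
        sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
        ll = (
            math.inf
            if sigma == 0
            else float(np.sum(stats.lognorm.logpdf(pos, s=sigma, scale=np.exp(mu))))
        )
        fit = FittedDistribution("lognormal", {"mu": mu, "sigma": sigma}, n=int(pos.size),
                                 log_likelihood=ll, aic=float("nan"))
    elif family == "exponential":
        if np.any(x < 0):
            raise ValueError("exponential fit requires nonnegative values")
        mean = float(np.mean(x))
        if mean <= 0:
            raise InsufficientDataError("exponential fit requires a positive mean")
        rate = 1.0 / mean
        ll = float(x.size * np.log(rate) - rate * np.sum(x))
        fit = FittedDistribution("exponential", {"rate": rate}, n=int(x.size),
                                 log_likelihood=ll, aic=float("nan"))
    else:
        raise ValueError(f"unknown family {family!r}")

    return FittedDistribution(
        fit.family, fit.params, n=fit.n, log_likelihood=fit.log_likelihood,
        aic=2.0 * fit.k - 2.0 * fit.log_likelihood, truncate_at_zero=True,
    )


def fit_candidates(values: Sequence[float]) -> list[FittedDistribution]:
    """Fit all three candidate families by maximum likelihood."""
    return [fit_family(values, fam) for fam in FAMILY_ORDER]


def select_best(fits: Sequence[FittedDistribution]) -> FittedDistribution:
    """The fit with minimum AIC; ties broken by the fixed family order."""
    if not fits:
        raise ValueError("select_best requires at least one fit")
    return min(fits, key=lambda f: (f.aic, FAMILY_ORDER.index(f.family)))


def _arithmetic_to_log_params(mean: float, sd: float) -> tuple[float, float]:
    """Convert arithmetic (mean, sd) of a lognormal to log-scale (mu, sigma)."""
    if mean <= 0:
        raise ValueError("arithmetic lognormal mean must be > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _lognormal_log_params(
    dist: FittedDistribution, param_convention: str
) -> tuple[float, float]:
    if param_convention == "log_scale":
        return float(dist.params["mu"]), float(dist.params["sigma"])
    if param_convention == "arithmetic":
        return _arithmetic_to_log_params(
            float(dist.params["mu"]), float(dist.params["sigma"])
        )
    raise ValueError(f"unknown param_convention {param_convention!r}")


def sample_concentrations(
    dist: FittedDistribution,
    n: int,
    seed: int | np.random.Generator | None = None,
    param_convention: str = "log_scale",
) -> np.ndarray:
    """Draw ``n`` i.i.d. concentrations (ng/g) from a fitted model.

    With ``truncate_at_zero`` set, negative normal draws are rejected and
    resampled so every output is nonnegative. ``param_convention`` applies
    to the lognormal family only (see module docstring).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if param_convention not in ("log_scale", "arithmetic"):
        raise ValueError(f"unknown param_convention {param_convention!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if dist.family == "normal":
        mean, sd = float(dist.params["mean"]), float(dist.params["sd"])
        draws = rng.normal(mean, sd, size=n)
        if dist.truncate_at_zero:
            neg = draws < 0
            while neg.any():
                draws[neg] = rng.normal(mean, sd, size=int(neg.sum()))
                neg = draws < 0
        return draws
    if dist.family == "lognormal":
        mu, sigma = _lognormal_log_params(dist, param_convention)
        return rng.lognormal(mu, sigma, size=n)
    if dist.family == "exponential":
        return rng.exponential(1.0 / float(dist.params["rate"]), size=n)
    raise ValueError(f"unknown family {dist.family!r}")


def distribution_mean(
    dist: FittedDistribution, param_convention: str = "log_scale"
) -> float:
    """Closed-form mean of a fitted model (the Monte Carlo oracle).

    Normal with zero-truncation active uses the left-truncated-at-zero mean
    ``mu + sigma * phi(mu/sigma) / Phi(mu/sigma)``; lognormal is
    ``exp(mu + sigma^2 / 2)``; exponential ``1/rate``.
    """
    if dist.family == "normal":
        mean, sd = float(dist.params["mean"]), float(dist.params["sd"])
        if not dist.truncate_at_zero or sd == 0:
            return mean
        a = mean / sd
        return mean + sd * stats.norm.pdf(a) / stats.norm.cdf(a)
    if dist.family == "lognormal":
        mu, sigma = _lognormal_log_params(dist, param_convention)
        return math.exp(mu + sigma**2 / 2.0)
    if dist.family == "exponential":
        return 1.0 / float(dist.params["rate"])
    raise ValueError(f"unknown family {dist.family!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its two-sided p-value."""

    r: float
    p_value: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch unequal-variance t-test; returns (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("t-test undefined: both groups degenerate with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fits_to_json(
    fits: Sequence[FittedDistribution],
    selected: FittedDistribution,
    path: str | Path | None = None,
) -> str:
    """Serialize candidate fits (with the selection flagged) as JSON."""
    payload = [
        {**f.to_dict(), "selected": f is selected or f == selected} for f in fits
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
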