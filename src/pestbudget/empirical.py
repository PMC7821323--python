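"""Empirical estimators of outbreak frequency and outbreak-year yield loss.

The case-study probabilities derive from multi-year insecticide-efficacy
trials: each site-year contributes an untreated-control yield ``U``, the
yield ``H`` of the best insecticide treatment (taken as that site-year's
attainable yield) and a flag for whether aphids exceeded the economic
threshold before growth stage R6 (an outbreak). Yield loss per site-year is
``100 - (U / H) * 100``; the outbreak frequency is the share of site-years
flagged as outbreaks, and the mean loss over outbreak site-years gives the
retained fraction ``q = 1 - loss/100``.

The original 23-site-year trial set is not deposited, so
:func:`generate_fixture_records` produces a synthetic stand-in with the same
summary structure for testing; it is never a source of case-study numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteYearRecord",
    "site_year_yield_loss",
    "mean_outbreak_yield_loss",
    "outbreak_frequency",
    "generate_fixture_records",
    "read_records_csv",
    "write_records_csv",
]

CSV_COLUMNS = ("site", "year", "untreated_yield_kg_ha", "best_treated_yield_kg_ha", "outbreak")


@dataclass(frozen=True)
class SiteYearRecord:
    """One insecticide-trial site-year."""

    site: str
    year: int
    untreated_yield: float  # U, kg/ha
    best_treated_yield: float  # H, kg/ha
    outbreak: bool

    def __post_init__(self) -> None:
        if self.untreated_yield < 0:
            raise ValueError(f"untreated yield must be >= 0, got {self.untreated_yield!r}")
        if not self.best_treated_yield > 0:
            raise ValueError(
                f"best treated yield must be positive, got {self.best_treated_yield!r}"
            )
        if not 1900 <= self.year <= 2100:
            raise ValueError(f"implausible trial year {self.year!r}")


def site_year_yield_loss(record: SiteYearRecord) -> float:
    """Percent yield loss, 100 - (U/H)*100; negative when U outyields H."""
    return 100.0 - (record.untreated_yield / record.best_treated_yield) * 100.0


def mean_outbreak_yield_loss(
    records: Sequence[SiteYearRecord],
    *,
    outbreak_only: bool = True,
) -> tuple[float, float]:
    """Mean percent yield loss and the implied retained fraction q.

    Averages over outbreak site-years (the default — loss in non-outbreak
    years reflects noise, not aphid damage); ``outbreak_only=False`` averages
    over every record instead.
    """
    pool = [r for r in records if r.outbreak] if outbreak_only else list(records)
    if not pool:
        raise ValueError(
            "no outbreak site-years to average over"
            if outbreak_only
            else "no records to average over"
        )
    mean_loss = float(np.mean([site_year_yield_loss(r) for r in pool]))
    return mean_loss, 1.0 - mean_loss / 100.0


def outbreak_frequency(records: Sequence[SiteYearRecord]) -> float:
    """Share of site-years flagged as outbreaks (unweighted)."""
    if not records:
        raise ValueError("cannot estimate outbreak frequency from an empty record list")
    return sum(r.outbreak for r in records) / len(records)


def _truncnorm_location(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location making the [lo, hi]-truncated normal's mean equal target_mean."""
    from scipy.optimize import brentq

    def gap(loc: float) -> float:
        return stats.truncnorm.mean((lo - loc) / sd, (hi - loc) / sd, loc=loc, scale=sd) - target_mean

    return float(brentq(gap, target_mean - 8.0 * sd, target_mean + 8.0 * sd, xtol=1e-10))


def generate_fixture_records(
    n: int,
    outbreak_rate: float = 0.435,
    loss_mean: float = 12.7,
    loss_sd: float = 8.0,
    seed: int = 0,
    *,
    base_yield: float = 3537.0,
    yield_sd: float = 300.0,
) -> list[SiteYearRecord]:
    """Synthetic site-year trial records emulating the case-study summaries.

    Outbreak flags are Bernoulli(``outbreak_rate``); outbreak-year losses are
    drawn from a normal truncated to [0, 60] percent whose location is solved
    so the truncated distribution's mean equals ``loss_mean`` (scale
    ``loss_sd``), non-outbreak years get small zero-centred noise; the
    attainable yield H is normal(``base_yield``, ``yield_sd``) floored at
    500 kg/ha and U is back-computed from the loss. Fully reproducible from
    ``seed``.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n!r}")
    if not 0.0 <= outbreak_rate <= 1.0:
        raise ValueError(f"outbreak_rate must lie in [0, 1], got {outbreak_rate!r}")
    if loss_sd < 0:
        raise ValueError(f"loss_sd must be >= 0, got {loss_sd!r}")
    if loss_sd == 0:
        if not 0.0 <= loss_mean <= 100.0:
            raise ValueError(f"loss_mean must lie in [0, 100] percent, got {loss_mean!r}")
    elif not 0.0 < loss_mean < 60.0:
        raise ValueError(
            "loss_mean must lie strictly inside the (0, 60) percent truncation "
            f"interval when loss_sd > 0, got {loss_mean!r}"
        )
    rng = np.random.default_rng(seed)
    outbreaks = rng.random(n) < outbreak_rate
    treated = np.maximum(rng.normal(base_yield, yield_sd, size=n), 500.0)
    losses = np.empty(n)
    n_out = int(outbreaks.sum())
    if loss_sd == 0:
        losses[outbreaks] = loss_mean
    elif n_out:
        loc = _truncnorm_location(loss_mean, loss_sd, 0.0, 60.0)
        a = (0.0 - loc) / loss_sd
        b = (60.0 - loc) / loss_sd
        losses[outbreaks] = stats.truncnorm.rvs(
            a, b, loc=loc, scale=loss_sd, size=n_out, random_state=rng
        )
    losses[~outbreaks] = rng.normal(0.0, 0.5, size=n - n_out)
    records = []
    for i in range(n):
        h = float(treated[i])
        u = max(h * (1.0 - losses[i] / 100.0), 0.0)
        records.append(SiteYearRecord(
            site=f"synthetic-site-{i % 3 + 1}",
            year=2005 + (i // 3) % 90,
            untreated_yield=u,
            best_treated_yield=h,
            outbreak=bool(outbreaks[i]),
        ))
    return records


def read_records_csv(path: str | Path) -> list[SiteYearRecord]:
    """Read site-year records from CSV (header mandatory, UTF-8)."""
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"records CSV {path} is missing column(s) {missing}")
    return [
        SiteYearRecord(
            site=str(row.site),
            year=int(row.year),
            untreated_yield=float(row.untreated_yield_kg_ha),
            best_treated_yield=float(row.best_treated_yield_kg_ha),
            outbreak=bool(int(row.outbreak)),
        )
        for row in frame.itertuples(index=False)
    ]


def write_records_csv(records: Iterable[SiteYearRecord], path: str | Path) -> None:
    """Write site-year records as CSV (outbreak encoded 0/1)."""
    frame = pd.DataFrame(
        [
            (r.site, r.year, r.untreated_yield, r.best_treated_yield, int(r.outbreak))
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )
    # %.17g round-trips IEEE doubles exactly, keeping load(save(x)) == x
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
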