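"""Growth-rate estimation from fluorescence time series and per-strain pH contrasts.

Cultures are monitored by chlorophyll fluorescence (relative fluorescence
units, RFU) across consecutive growth periods between culture renewals.  The
per-period exponential growth rate is

    mu = (ln N1 - ln N0) / (t1 - t0)   [per day]

where N0/N1 are RFU at the period boundaries.  Only the periods after growth
stabilization (by default the last two) enter the statistics.  For each strain,
growth-rate medians across pH conditions are compared with a Kruskal-Wallis
test followed by Dunn's post-hoc pairwise z tests with Benjamini-Hochberg
adjustment, summarized as a compact letter display.  Strains are then
classified into acidophiles, generalists, and acid-intolerants from their
medians and letter groups.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthSeries",
    "GrowthRateRecord",
    "GrowthTestResult",
    "growth_rate",
    "period_rates",
    "dunn_test",
    "compact_letter_display",
    "test_ph_effect",
    "classify_growth_pattern",
    "read_growth_tsv",
    "records_to_frame",
]


@dataclass(frozen=True)
class GrowthSeries:
    """One well's fluorescence trajectory under one strain x pH condition."""

    well_id: str
    strain: str
    ph: str
    times: tuple[float, ...]
    rfu: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        rfu = tuple(float(x) for x in self.rfu)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rfu", rfu)
        if len(times) != len(rfu):
            raise ValueError(
                f"series {self.well_id}: {len(times)} times but {len(rfu)} RFU values"
            )
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError(f"series {self.well_id}: times must be strictly increasing")
        if any(x <= 0 for x in rfu):
            raise ValueError(f"series {self.well_id}: RFU values must be positive")


@dataclass(frozen=True)
class GrowthRateRecord:
    """A per-day growth rate for one well and one growth period."""

    well_id: str
    strain: str
    ph: str
    period_index: int
    mu: float


@dataclass
class GrowthTestResult:
    """Kruskal-Wallis + Dunn outcome for one strain across pH conditions."""

    strain: str
    kw_p: float
    dunn_fdr: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float = 0.05
    medians: dict[str, float] = field(default_factory=dict)


def growth_rate(n0: float, n1: float, t0: float, t1: float) -> float:
    """Per-day exponential growth rate from boundary fluorescence readings.

    Parameters
    ----------
    n0, n1
        RFU at the beginning and end of the growth period; must be positive.
    t0, t1
        Boundary times in days; ``t1`` must exceed ``t0``.
    """
    if n0 <= 0 or n1 <= 0:
        raise ValueError(f"RFU values must be positive, got n0={n0}, n1={n1}")
    if t1 <= t0:
        raise ValueError(f"t1 must exceed t0, got t0={t0}, t1={t1}")
    return (math.log(n1) - math.log(n0)) / (t1 - t0)


def _keep_last_two(n_periods: int) -> list[int]:
    # Post-acclimatization default: the last two periods, or the single one available.
    if n_periods >= 2:
        return [n_periods - 2, n_periods - 1]
    return list(range(n_periods))


def period_rates(
    series: GrowthSeries,
    keep_periods: Callable[[int], Sequence[int]] | Sequence[int] | None = None,
) -> list[GrowthRateRecord]:
    """Per-period growth rates for the periods surviving the selection rule.

    ``keep_periods`` is either an explicit list of period indices or a callable
    mapping the number of periods to the indices to keep.  The default mirrors
    the study design: keep the two periods after acclimatization (the last
    two), falling back to a single period for short series.
    """
    n_periods = len(series.times) - 1
    if n_periods < 1:
        raise ValueError(f"series {series.well_id}: need at least 2 time points")
    if keep_periods is None:
        keep = _keep_last_two(n_periods)
    elif callable(keep_periods):
        keep = list(keep_periods(n_periods))
    else:
        keep = list(keep_periods)
    bad = [i for i in keep if not 0 <= i < n_periods]
    if bad:
        raise ValueError(f"period indices {bad} out of range for {n_periods} periods")
    if not keep:
        logger.warning("series %s: period selection is empty", series.well_id)
        return []
    return [
        GrowthRateRecord(
            well_id=series.well_id,
            strain=series.strain,
            ph=series.ph,
            period_index=i,
            mu=growth_rate(series.rfu[i], series.rfu[i + 1], series.times[i], series.times[i + 1]),
        )
        for i in sorted(keep)
    ]


def records_to_frame(records: Sequence[GrowthRateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.well_id, r.strain, r.ph, r.period_index, r.mu) for r in records],
        columns=["well_id", "strain", "ph", "period_index", "mu"],
    )


def dunn_test(samples: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z tests on pooled ranks, with tie correction.

    Returns raw two-sided p-values per condition pair (keys sorted within the
    pair).  The z statistic for groups i, j with mean ranks Ri, Rj is

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T) * (1/ni + 1/nj))

    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups of the pooled sample.
    """
    keys = sorted(samples)
    values = [np.asarray(samples[k], dtype=float) for k in keys]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction over pooled values
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for key, vals in zip(keys, values):
        stop = start + vals.size
        mean_ranks[key] = float(ranks[start:stop].mean())
        sizes[key] = vals.size
        start = stop

    pvals: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(keys, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:  # all pooled values tied
            pvals[(a, b)] = 1.0
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pvals[(a, b)] = float(2.0 * stats.norm.sf(abs(z)))
    return pvals


def compact_letter_display(
    conditions: Sequence[str], significant_pairs: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Letter codes such that two conditions share a letter iff not significantly different.

    Insert-and-absorb: start from one group holding every condition; each
    significant pair splits any group containing both; groups that become
    subsets of others are absorbed.
    """
    conditions = sorted(conditions)
    groups: list[set[str]] = [set(conditions)]
    for a, b in significant_pairs:
        nxt: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                nxt.append(g - {b})
                nxt.append(g - {a})
            else:
                nxt.append(g)
        # absorb proper subsets and duplicates
        nxt = [g for g in nxt if g]
        groups = []
        for g in nxt:
            if any(g < h for h in nxt):
                continue
            if g not in groups:
                groups.append(g)
    groups.sort(key=lambda g: (min(conditions.index(c) for c in g), -len(g)))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {c: "" for c in conditions}
    for letter, g in zip(letters, groups):
        for c in sorted(g):
            out[c] += letter
    return out


def test_ph_effect(
    records: Sequence[GrowthRateRecord] | pd.DataFrame,
    strain: str,
    alpha: float = 0.05,
) -> GrowthTestResult:
    """Kruskal-Wallis across pH conditions, Dunn post-hoc with BH adjustment, letters.

    All selected per-period records of the strain are used as replicates.
    Degenerate input (all growth rates tied) yields p = 1 with a warning.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame = frame[frame["strain"] == strain]
    if frame.empty:
        raise ValueError(f"no growth-rate records for strain {strain!r}")
    samples = {ph: grp["mu"].to_numpy(dtype=float) for ph, grp in frame.groupby("ph")}
    if len(samples) < 2:
        raise ValueError(f"strain {strain!r}: need >= 2 pH conditions, got {len(samples)}")
    small = [ph for ph, v in samples.items() if v.size < 2]
    if small:
        raise ValueError(f"strain {strain!r}: conditions with < 2 records: {small}")

    medians = {ph: float(np.median(v)) for ph, v in samples.items()}
    pooled = np.concatenate(list(samples.values()))
    if np.all(pooled == pooled[0]):
        warnings.warn(f"strain {strain!r}: all growth rates tied; p set to 1", stacklevel=2)
        letters = {ph: "a" for ph in samples}
        dunn_fdr = {pair: 1.0 for pair in itertools.combinations(sorted(samples), 2)}
        return GrowthTestResult(strain, 1.0, dunn_fdr, letters, alpha, medians)

    kw_p = float(stats.kruskal(*samples.values()).pvalue)
    raw = dunn_test(samples)
    pairs = sorted(raw)
    adj = multipletests([raw[p] for p in pairs], method="fdr_bh")[1]
    dunn_fdr = {pair: float(q) for pair, q in zip(pairs, adj)}
    sig_pairs = [pair for pair in pairs if dunn_fdr[pair] < alpha]
    letters = compact_letter_display(sorted(samples), sig_pairs)
    return GrowthTestResult(strain, kw_p, dunn_fdr, letters, alpha, medians)


test_ph_effect.__test__ = False  # not a pytest item despite the name


def classify_growth_pattern(
    medians: Mapping[str, float],
    letters: Mapping[str, str],
    acidic_ph: str,
) -> str:
    """Classify a strain as ``acidophile``, ``generalist``, or ``acid_intolerant``.

    Rules (heuristic operationalization of the published groupings):

    * acid_intolerant — the population collapses at the acidic condition
      (median growth rate < 0 there);
    * acidophile — acidic median is positive, strictly the highest, and the
      acidic condition shares no compact-display letter with any other
      condition (significantly fastest growth at low pH);
    * generalist — otherwise, with positive growth everywhere.
    """
    if acidic_ph not in medians:
        raise ValueError(f"acidic condition {acidic_ph!r} missing from medians")
    if set(letters) != set(medians):
        raise ValueError("letters and medians must cover the same conditions")
    if len(medians) < 3:
        raise ValueError("classification requires all three pH conditions")
    acid_median = medians[acidic_ph]
    others = {ph: m for ph, m in medians.items() if ph != acidic_ph}
    if acid_median < 0:
        return "acid_intolerant"
    acid_letters = set(letters[acidic_ph])
    distinct = all(acid_letters.isdisjoint(set(letters[ph])) for ph in others)
    if acid_median > 0 and distinct and all(acid_median > m for m in others.values()):
        return "acidophile"
    if any(m <= 0 for m in others.values()):
        logger.warning("non-acidic condition with non-positive median; classifying as generalist")
    return "generalist"


def read_growth_tsv(path) -> list[GrowthSeries]:
    """Read a growth-series table (well_id, strain, ph, time_days, rfu) into series."""
    frame = pd.read_csv(path, sep="\t", dtype={"well_id": str, "strain": str, "ph": str})
    required = {"well_id", "strain", "ph", "time_days", "rfu"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (well, strain, ph), grp in frame.groupby(["well_id", "strain", "ph"], sort=True):
        grp = grp.sort_values("time_days")
        out.append(
            GrowthSeries(
                well_id=well,
                strain=strain,
                ph=ph,
                times=tuple(grp["time_days"].astype(float)),
                rfu=tuple(grp["rfu"].astype(float)),
            )
        )
    return out
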