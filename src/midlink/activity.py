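"""Diurnal locomotor activity: beam-crossing counts to daily profiles and tests.

Per-fly infrared beam-crossing counts recorded on a uniform 5-minute grid
under a light/dark schedule are filtered (flies that never move in a 24 h
period are discarded), rebinned to 30 minutes, collapsed to a 48-bin daily
profile (mean over days per fly, then mean +/- s.e.m. across flies per
genotype), and compared between genotypes with a mixed-design two-way
repeated-measures ANOVA (between = genotype, within = time-of-day bin)
plus per-bin genotype contrasts using the pooled within-cell error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "LightSchedule",
    "ActivityTable",
    "DailyProfile",
    "TransitionIndices",
    "PerBinComparison",
    "read_dam",
    "filter_inactive",
    "rebin",
    "per_fly_profiles",
    "daily_profile",
    "per_bin_comparison",
    "transition_indices",
]

VALID_STATUS = {1}  # Trikinetics status code for a valid reading


@dataclass(frozen=True)
class LightSchedule:
    """Daily light/dark schedule in clock hours (24 h cycle)."""

    lights_on: float = 8.0
    lights_off: float = 20.0
    cycle: float = 24.0

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")
        for h in (self.lights_on, self.lights_off):
            if not 0 <= h < self.cycle:
                raise ValueError("schedule times must lie within the cycle")

    def is_light(self, hour: float) -> bool:
        h = hour % self.cycle
        on, off = self.lights_on, self.lights_off
        if on < off:
            return on <= h < off
        return h >= on or h < off


@dataclass(frozen=True)
class ActivityTable:
    """Per-fly counts on a uniform time grid with genotype labels."""

    counts: pd.DataFrame  # index: DatetimeIndex, columns: fly ids
    genotypes: pd.Series  # fly id -> genotype
    bin_width: int  # minutes
    schedule: LightSchedule

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative activity counts")
        idx = self.counts.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("counts must be indexed by timestamps")
        deltas = np.diff(idx.asi8)
        step = self.bin_width * 60 * 10**9
        if len(deltas) and not np.all(deltas == step):
            bad = int(np.flatnonzero(deltas != step)[0])
            raise ValueError(
                f"non-uniform time grid: gap after {idx[bad]} "
                f"(expected {self.bin_width} min steps)"
            )
        missing = set(self.counts.columns) - set(self.genotypes.index)
        if missing:
            raise ValueError(f"flies without genotype label: {sorted(missing)}")

    @property
    def fly_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def _read_long(df: pd.DataFrame, schedule: LightSchedule, bin_width: int,
               genotype_map: Mapping[str, str] | None) -> ActivityTable:
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if (df["count"] < 0).any():
        bad = df[df["count"] < 0].iloc[0]
        raise ValueError(f"negative count for fly {bad['fly_id']} at {bad['timestamp']}")
    wide = df.pivot(index="timestamp", columns="fly_id", values="count")
    if wide.isna().any().any():
        fly = wide.columns[wide.isna().any()][0]
        ts = wide.index[wide[fly].isna()][0]
        raise ValueError(f"missing reading for fly {fly} at {ts}")
    wide = wide.sort_index()
    genos = _resolve_genotypes(wide.columns, genotype_map)
    return ActivityTable(counts=wide, genotypes=genos, bin_width=bin_width, schedule=schedule)


def _resolve_genotypes(flies, genotype_map: Mapping[str, str] | None) -> pd.Series:
    if genotype_map is not None:
        return pd.Series({f: genotype_map[f] for f in flies})
    # fall back to the "<genotype>_fly<k>" naming used by the writers
    return pd.Series({f: str(f).rsplit("_", 1)[0] for f in flies})


def read_dam(
    path: str | Path,
    schedule: LightSchedule,
    bin_width: int = 5,
    genotype_map: Mapping[str, str] | None = None,
    monitor_name: str | None = None,
) -> ActivityTable:
    """Read activity counts from a monitor export.

    Two layouts are accepted:

    * Trikinetics-style tab-delimited monitor files — reading index, date
      (``dd mon yy``), time, status code, five auxiliary fields, light
      flag, then 32 channel count columns.  Rows whose status code is not
      a valid reading are rejected (not silently dropped).
    * A simplified long format with header ``fly_id<TAB>timestamp<TAB>count``.

    Timestamps must form a complete, strictly increasing ``bin_width``
    grid; a missing interval is an error naming the gap.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.lower().startswith("fly_id"):
        df = pd.read_csv(path, sep="\t")
        return _read_long(df, schedule, bin_width, genotype_map)

    raw = pd.read_csv(path, sep="\t", header=None)
    if raw.shape[1] < 11:
        raise ValueError("monitor file needs >= 11 tab-separated columns")
    status = raw.iloc[:, 3].astype(int)
    bad = ~status.isin(VALID_STATUS)
    if bad.any():
        raise ValueError(
            f"monitor file has {int(bad.sum())} rows with invalid status "
            f"codes {sorted(status[bad].unique())}"
        )
    ts = pd.to_datetime(
        raw.iloc[:, 1].astype(str).str.strip() + " " + raw.iloc[:, 2].astype(str).str.strip(),
        format="%d %b %y %H:%M:%S",
    )
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("monitor timestamps are not strictly increasing")
    counts = raw.iloc[:, 10:].astype(int)
    name = monitor_name or path.stem
    counts.columns = [f"{name}#{i + 1:02d}" for i in range(counts.shape[1])]
    counts.index = pd.DatetimeIndex(ts.values)
    genos = _resolve_genotypes(counts.columns, genotype_map)
    return ActivityTable(counts=counts, genotypes=genos, bin_width=bin_width, schedule=schedule)


def filter_inactive(
    table: ActivityTable, window_hours: float = 24.0, rolling: bool = False
) -> tuple[ActivityTable, list[str]]:
    """Discard flies that did not move at least once in any 24 h period.

    By default the windows are consecutive calendar-day spans from the
    recording start; ``rolling=True`` instead slides a ``window_hours``
    window across every bin offset (stricter).
    """
    bins_per_window = int(round(window_hours * 60 / table.bin_width))
    n = table.n_bins
    if n < bins_per_window:
        raise ValueError("recording shorter than the inactivity window")
    arr = table.counts.to_numpy()
    removed: list[str] = []
    if rolling:
        csum = np.cumsum(np.vstack([np.zeros(arr.shape[1]), arr]), axis=0)
        window_sums = csum[bins_per_window:] - csum[:-bins_per_window]
        dead = (window_sums == 0).any(axis=0)
    else:
        n_full = n // bins_per_window
        trimmed = arr[: n_full * bins_per_window]
        day_sums = trimmed.reshape(n_full, bins_per_window, arr.shape[1]).sum(axis=1)
        dead = (day_sums == 0).any(axis=0)
    removed = [f for f, d in zip(table.counts.columns, dead) if d]
    kept = table.counts.drop(columns=removed)
    return (
        ActivityTable(
            counts=kept,
            genotypes=table.genotypes[kept.columns],
            bin_width=table.bin_width,
            schedule=table.schedule,
        ),
        removed,
    )


def rebin(table: ActivityTable, new_width: int = 30) -> ActivityTable:
    """Sum counts into wider bins; per-fly totals are conserved exactly."""
    if new_width % table.bin_width:
        raise ValueError(f"{new_width} min is not a multiple of {table.bin_width} min bins")
    k = new_width // table.bin_width
    if k == 1:
        return table
    if table.n_bins % k:
        raise ValueError("recording length is not a whole number of new bins")
    arr = table.counts.to_numpy()
    summed = arr.reshape(-1, k, arr.shape[1]).sum(axis=1)
    idx = table.counts.index[::k]
    return ActivityTable(
        counts=pd.DataFrame(summed, index=idx, columns=table.counts.columns),
        genotypes=table.genotypes,
        bin_width=new_width,
        schedule=table.schedule,
    )


def per_fly_profiles(table: ActivityTable) -> dict[str, np.ndarray]:
    """Per-genotype matrices of per-fly daily-average profiles.

    Each fly's counts are folded to time-of-day (mean over days per bin),
    giving one row of length ``1440 / bin_width`` per fly.
    """
    bins_per_day = 1440 // table.bin_width
    if table.n_bins % bins_per_day:
        raise ValueError("recording does not cover a whole number of days")
    n_days = table.n_bins // bins_per_day
    arr = table.counts.to_numpy(dtype=float)
    # align fold to midnight using the first timestamp's time of day
    t0 = table.counts.index[0]
    offset = (t0.hour * 60 + t0.minute) // table.bin_width
    folded = arr.reshape(n_days, bins_per_day, arr.shape[1]).mean(axis=0)
    folded = np.roll(folded, offset, axis=0)  # row i = bin starting at i*bin_width after midnight
    out: dict[str, np.ndarray] = {}
    for geno in sorted(table.genotypes.unique()):
        flies = [f for f in table.counts.columns if table.genotypes[f] == geno]
        out[geno] = folded[:, [table.counts.columns.get_loc(f) for f in flies]].T
    return out


@dataclass(frozen=True)
class DailyProfile:
    """Per-genotype mean +/- s.e.m. daily activity in 48 half-hour bins."""

    bin_width: int
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    n_flies: dict[str, int]
    schedule: LightSchedule

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for geno in self.mean:
            for b, (m, s) in enumerate(zip(self.mean[geno], self.sem[geno])):
                rows.append(
                    {"genotype": geno, "bin": b + 1, "mean": m, "sem": s, "n": self.n_flies[geno]}
                )
        return pd.DataFrame(rows)


def daily_profile(table: ActivityTable) -> DailyProfile:
    """Genotype daily profiles: mean and s.e.m. across flies of per-fly
    day-averaged time-of-day bins."""
    profiles = per_fly_profiles(table)
    mean: dict[str, np.ndarray] = {}
    sem: dict[str, np.ndarray] = {}
    n: dict[str, int] = {}
    for geno, mat in profiles.items():
        if mat.shape[0] == 0:
            raise ValueError(f"genotype {geno} has no flies")
        mean[geno] = mat.mean(axis=0)
        sem[geno] = (
            mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
        )
        n[geno] = mat.shape[0]
    return DailyProfile(bin_width=table.bin_width, mean=mean, sem=sem, n_flies=n, schedule=table.schedule)


@dataclass(frozen=True)
class PerBinComparison:
    """Omnibus mixed ANOVA plus per-bin genotype contrasts."""

    anova: _stats.AnovaOutcome
    per_bin_F: np.ndarray
    per_bin_p: np.ndarray
    flagged: np.ndarray  # bool per bin
    alpha: float
    bonferroni: bool

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(),
            "alpha": self.alpha,
            "bonferroni": self.bonferroni,
            "per_bin": [
                {"bin": i + 1, "F": float(f), "p": float(p), "significant": bool(s)}
                for i, (f, p, s) in enumerate(zip(self.per_bin_F, self.per_bin_p, self.flagged))
            ],
        }


def per_bin_comparison(
    profiles: Mapping[str, np.ndarray], alpha: float = 0.05, bonferroni: bool = False
) -> PerBinComparison:
    """Mixed two-way RM ANOVA plus per-bin genotype simple effects.

    ``profiles`` maps genotype -> (flies x bins) per-fly daily profiles.
    The omnibus table has genotype (tested against subjects-within-
    genotype), time, and genotype x time effects.  Each bin's genotype
    contrast is an F test of the between-group means at that bin against
    the pooled within-cell error MS of the mixed decomposition, flagged
    at ``alpha`` (per-bin, uncorrected, matching per-bin asterisks at
    P < 0.05; ``bonferroni=True`` divides alpha by the bin count).
    """
    from scipy import stats as sps

    mats = {k: np.asarray(v, dtype=float) for k, v in profiles.items()}
    for k, m in mats.items():
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValueError(f"genotype {k}: need a (flies x bins) matrix with >= 2 flies")
    anova = _stats.rm_anova_mixed(mats)
    g = len(mats)
    n = next(iter(mats.values())).shape[0]
    t = next(iter(mats.values())).shape[1]
    N = g * n
    ss_sw, df_sw = anova.error_strata["subjects_within_groups"]
    ss_res, df_res = anova.error_strata["residual"]
    ms_pooled = (ss_sw + ss_res) / (df_sw + df_res)  # pooled within-cell variance
    df_err = df_sw + df_res

    stack = np.stack(list(mats.values()))  # (g, n, t)
    cell_means = stack.mean(axis=1)  # (g, t)
    grand_bin = cell_means.mean(axis=0)  # (t,)
    ss_bin = n * ((cell_means - grand_bin[None, :]) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_pooled > 0, (ss_bin / (g - 1)) / ms_pooled, np.where(ss_bin > 0, np.inf, 0.0))
    p = np.maximum(sps.f.sf(F, g - 1, df_err), np.finfo(float).tiny)
    p = np.where(F == 0.0, 1.0, p)
    thresh = alpha / t if bonferroni else alpha
    return PerBinComparison(
        anova=anova,
        per_bin_F=F,
        per_bin_p=p,
        flagged=p < thresh,
        alpha=alpha,
        bonferroni=bonferroni,
    )


@dataclass(frozen=True)
class TransitionIndices:
    """Light/dark activity ratio and lights-on / lights-off anticipation.

    Anticipation = activity in the ``short`` hours before the transition
    divided by activity in the ``long`` hours before it; 0.5 for a flat
    profile, -> 1 for a sharp pre-transition ramp.  ``None`` marks an
    undefined index (zero denominator).
    """

    light_dark_ratio: float | None
    anticipation_on: float | None
    anticipation_off: float | None


def transition_indices(
    profile: np.ndarray,
    schedule: LightSchedule,
    bin_width: int = 30,
    windows: tuple[float, float] = (3.0, 6.0),
) -> TransitionIndices:
    """Compute transition indices from one genotype's daily profile.

    ``profile`` is the mean daily activity in ``bin_width``-minute bins
    (length 1440 / bin_width).
    """
    prof = np.asarray(profile, dtype=float)
    n = prof.size
    if n * bin_width != 1440:
        raise ValueError("profile must cover exactly one day")
    short, long = windows
    if not 0 < short < long:
        raise ValueError("anticipation windows must satisfy 0 < short < long")
    hours = (np.arange(n) + 0.5) * bin_width / 60.0  # bin centers, clock hours
    light = np.array([schedule.is_light(h) for h in hours])
    sum_light, sum_dark = prof[light].sum(), prof[~light].sum()
    ratio = float(sum_light / sum_dark) if sum_dark > 0 else None

    def anticipation(transition_hour: float) -> float | None:
        # circular window of `long` hours ending at the transition
        rel = (transition_hour - hours) % 24.0  # hours before the transition
        in_long = (rel > 0) & (rel <= long)
        in_short = (rel > 0) & (rel <= short)
        denom = prof[in_long].sum()
        if denom == 0:
            return None
        return float(prof[in_short].sum() / denom)

    return TransitionIndices(
        light_dark_ratio=ratio,
        anticipation_on=anticipation(schedule.lights_on),
        anticipation_off=anticipation(schedule.lights_off),
    )
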