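"""Social-space analysis: nearest-neighbor distances, 5 mm histograms, SSI.

Flies aggregating in a circular chamber are summarized by the distance
from each fly to its nearest neighbor.  Distances are binned into 5 mm
half-open bins ``[0,5), [5,10), ...`` and expressed as percentages of the
population; the Social Space Index is

    SSI = %flies in bin 1 (0-5 mm)  -  %flies in bin 2 (5-10 mm)

so tightly clustered groups score near +100 and dispersed groups go
negative (a uniform 40-fly, 45 mm-radius arena averages about -8 before
edge effects).  Per-chamber SSI replicates are compared across genotypes
with a one-way repeated-measures ANOVA (block = replicate) followed by
Dunnett many-to-one comparisons against a control genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import stats as _stats

__all__ = [
    "ArenaSnapshot",
    "SocialSpaceHistogram",
    "SsiResult",
    "GenotypeComparison",
    "read_coordinates",
    "nearest_neighbor_distances",
    "distance_histogram",
    "average_chamber",
    "pool_distances",
    "ssi",
    "ssi_by_genotype",
    "compare_genotypes",
]


@dataclass(frozen=True)
class ArenaSnapshot:
    """One chamber image's fly coordinates (mm) in a circular arena."""

    chamber_id: str
    capture_index: int
    coordinates: np.ndarray  # (n, 2) in mm, arena center at the origin
    arena_radius: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coordinates must be an (n, 2) array")
        if coords.shape[0] < 2:
            raise ValueError("a snapshot needs at least 2 flies")
        r = np.hypot(coords[:, 0], coords[:, 1])
        if np.any(r > self.arena_radius * (1 + 1e-9)):
            raise ValueError(
                f"chamber {self.chamber_id}: {int((r > self.arena_radius).sum())} "
                f"fly positions outside the {self.arena_radius} mm arena"
            )

    @property
    def n_flies(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class SocialSpaceHistogram:
    """Per-bin percentage of flies by nearest-neighbor distance."""

    bin_width: float
    percentages: np.ndarray  # sums to 100
    n_flies: float

    def __post_init__(self) -> None:
        pct = np.asarray(self.percentages, dtype=float)
        object.__setattr__(self, "percentages", pct)
        if np.any(pct < -1e-9):
            raise ValueError("negative bin percentage")
        if abs(pct.sum() - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {pct.sum()}, expected 100")


@dataclass(frozen=True)
class SsiResult:
    """Per-chamber SSI values for one genotype plus their summary."""

    genotype: str
    per_chamber: np.ndarray
    mean: float
    sem: float

    @property
    def n_replicates(self) -> int:
        return self.per_chamber.size


def read_coordinates(
    path: str | Path,
    arena_radius: float = 45.0,
    pixels_per_mm: float | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> list[ArenaSnapshot]:
    """Read per-snapshot fly coordinates from CSV.

    Expects columns ``chamber_id, capture_index, fly_index, x_mm, y_mm``
    (or ``x_px, y_px`` with ``pixels_per_mm`` given).  ``center`` is
    subtracted so coordinates are arena-centered.
    """
    df = pd.read_csv(path)
    if pixels_per_mm is not None:
        df = df.assign(x_mm=df["x_px"] / pixels_per_mm, y_mm=df["y_px"] / pixels_per_mm)
    required = {"chamber_id", "capture_index", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate file missing columns: {sorted(missing)}")
    snapshots = []
    for (chamber, capture), grp in df.groupby(["chamber_id", "capture_index"], sort=True):
        coords = grp[["x_mm", "y_mm"]].to_numpy(dtype=float) - np.asarray(center)
        snapshots.append(
            ArenaSnapshot(
                chamber_id=str(chamber),
                capture_index=int(capture),
                coordinates=coords,
                arena_radius=arena_radius,
            )
        )
    return snapshots


def nearest_neighbor_distances(snapshot: ArenaSnapshot) -> np.ndarray:
    """Distance from each fly to its nearest neighbor (mm), via a k-d tree.

    Coincident flies are legal (distance 0) — particle centroids from
    image analysis can coincide — and trigger a warning.
    """
    coords = snapshot.coordinates
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    nnd = dist[:, 1]
    if np.any(nnd == 0.0):
        warnings.warn(
            f"chamber {snapshot.chamber_id}: coincident fly coordinates (distance 0)",
            stacklevel=2,
        )
    return nnd


def distance_histogram(
    distances: Sequence[float], bin_width: float = 5.0, n_bins: int = 18
) -> SocialSpaceHistogram:
    """Bin nearest-neighbor distances into half-open ``bin_width`` mm bins.

    Bins are ``[0, w), [w, 2w), ...`` — a distance of exactly 5 mm falls in
    the second bin.  ``n_bins`` fixes the histogram length (default spans a
    90 mm arena) so chamber histograms are directly averageable; distances
    beyond the last edge land in the final bin.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if np.any(d < 0):
        raise ValueError("negative nearest-neighbor distance")
    idx = np.minimum(np.floor(d / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return SocialSpaceHistogram(
        bin_width=bin_width, percentages=100.0 * counts / d.size, n_flies=float(d.size)
    )


def average_chamber(histograms: Sequence[SocialSpaceHistogram]) -> SocialSpaceHistogram:
    """Arithmetic per-bin mean of one chamber's capture histograms."""
    if not histograms:
        raise ValueError("no histograms to average")
    widths = {h.bin_width for h in histograms}
    lengths = {h.percentages.size for h in histograms}
    if len(widths) != 1 or len(lengths) != 1:
        raise ValueError("histograms have mismatched binning")
    pct = np.mean([h.percentages for h in histograms], axis=0)
    n = float(np.mean([h.n_flies for h in histograms]))
    return SocialSpaceHistogram(bin_width=histograms[0].bin_width, percentages=pct, n_flies=n)


def pool_distances(snapshots: Sequence[ArenaSnapshot], bin_width: float = 5.0) -> SocialSpaceHistogram:
    """Alternative to :func:`average_chamber`: pool all captures' distances."""
    d = np.concatenate([nearest_neighbor_distances(s) for s in snapshots])
    return distance_histogram(d, bin_width=bin_width)


def ssi(histogram: SocialSpaceHistogram) -> float:
    """Social Space Index: %bin1 - %bin2."""
    if histogram.percentages.size < 2:
        raise ValueError("histogram needs at least 2 bins")
    return float(histogram.percentages[0] - histogram.percentages[1])


def snapshot_ssi(snapshot: ArenaSnapshot, bin_width: float = 5.0) -> float:
    """Convenience: snapshot -> NND -> histogram -> SSI."""
    return ssi(distance_histogram(nearest_neighbor_distances(snapshot), bin_width=bin_width))


def ssi_by_genotype(
    snapshots: Sequence[ArenaSnapshot],
    chamber_to_genotype: Mapping[str, str],
    bin_width: float = 5.0,
    pool: bool = False,
) -> dict[str, SsiResult]:
    """Per-chamber SSI (averaging each chamber's captures) grouped by genotype."""
    by_chamber: dict[str, list[ArenaSnapshot]] = {}
    for s in snapshots:
        by_chamber.setdefault(s.chamber_id, []).append(s)
    per_geno: dict[str, list[float]] = {}
    for chamber, snaps in sorted(by_chamber.items()):
        geno = chamber_to_genotype[chamber]
        if pool:
            hist = pool_distances(snaps, bin_width=bin_width)
        else:
            hist = average_chamber(
                [distance_histogram(nearest_neighbor_distances(s), bin_width=bin_width) for s in snaps]
            )
        per_geno.setdefault(geno, []).append(ssi(hist))
    out = {}
    for geno, vals in per_geno.items():
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        out[geno] = SsiResult(genotype=geno, per_chamber=arr, mean=float(arr.mean()), sem=sem)
    return out


@dataclass(frozen=True)
class GenotypeComparison:
    anova: _stats.AnovaOutcome
    dunnett: _stats.DunnettReport
    genotypes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "genotypes": list(self.genotypes),
            "anova": self.anova.to_dict(),
            "dunnett": self.dunnett.to_dict(),
        }


def compare_genotypes(
    ssi_replicates: Mapping[str, Sequence[float]],
    control: str,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> GenotypeComparison:
    """Compare genotype SSI replicates against a control.

    Replicates enter as blocks (replicate *i* of every genotype was run
    simultaneously in adjacent chambers), giving a one-way
    repeated-measures ANOVA with within-block factor genotype, followed
    by Dunnett-adjusted comparisons of each genotype to the control.
    Unequal replicate counts are an error: the blocked design requires
    complete replicates.
    """
    if control not in ssi_replicates:
        raise ValueError(f"control genotype {control!r} missing")
    names = list(ssi_replicates)
    lengths = {len(v) for v in ssi_replicates.values()}
    if len(lengths) != 1:
        raise ValueError("unequal replicate counts; repeated-measures blocks must be complete")
    grid = np.column_stack([np.asarray(ssi_replicates[g], dtype=float) for g in names])
    anova = _stats.rm_anova_oneway(grid)
    report = _stats.dunnett(grid, names, control, alpha=alpha, n_mc=n_mc, seed=seed)
    return GenotypeComparison(anova=anova, dunnett=report, genotypes=tuple(names))
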