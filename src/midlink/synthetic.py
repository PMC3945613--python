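"""Synthetic data generators for every stage of the pipeline.

Each generator emulates the statistical structure its downstream analysis
assumes — clustered or uniform fly positions in a circular arena, rhythmic
Poisson beam-crossing counts with morning/evening peaks and a knockdown
effect, co-regulated log-normal RPKM profiles, and gapped amino-acid
alignments carrying a conserved cysteine motif — so the whole pipeline can
be exercised and validated at desk scale without external data.

All randomness flows from the explicit integer ``seed`` of each config;
identical seed and config give byte-identical output.  Writers emit the
same plain-text formats the real-data readers consume, so synthetic
fixtures and real exports are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityTable, LightSchedule
from .conservation import AMINO_ACIDS, Msa
from .expression import ExpressionMatrix
from .socialspace import ArenaSnapshot

__all__ = [
    "ArenaSimConfig",
    "ActivitySimConfig",
    "ExpressionSimConfig",
    "MsaSimConfig",
    "PackingError",
    "simulate_arena",
    "simulate_activity",
    "simulate_expression",
    "simulate_msa",
    "activity_rate_curve",
    "morning_peak_bins",
    "write_coordinates",
    "write_dam",
    "write_rpkm",
    "write_msa",
]


class PackingError(RuntimeError):
    """Raised when the hard-core constraint cannot be satisfied."""


# ---------------------------------------------------------------------------
# arena: Matern-style clustered or uniform points with a hard core
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArenaSimConfig:
    """Fly positions in a circular chamber (defaults: 40 males, 90 mm dish).

    ``cluster_strength`` is the aggregation axis: 0 gives complete spatial
    randomness (uniform placement); larger values draw flies around
    ``n_clusters`` parent centers with Gaussian dispersion
    ``arena_radius / (1 + 1.5 * cluster_strength)``, so tighter clusters at
    higher strength.  ``hardcore`` is the minimum inter-fly distance
    (~one body length).
    """

    n_flies: int = 40
    arena_radius: float = 45.0
    hardcore: float = 2.0
    cluster_strength: float = 0.0
    n_clusters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 2:
            raise ValueError("n_flies must be >= 2")
        if not self.arena_radius > self.hardcore >= 0:
            raise ValueError("need arena_radius > hardcore >= 0")
        if self.cluster_strength < 0:
            raise ValueError("cluster_strength must be >= 0")
        if self.cluster_strength > 0 and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1 when clustering")


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def simulate_arena(
    config: ArenaSimConfig, chamber_id: str = "sim", capture_index: int = 1
) -> ArenaSnapshot:
    """Draw one chamber snapshot.

    Uniform (``cluster_strength = 0``) or Matern-style parent/offspring
    placement, sequentially thinned so every pair of flies is at least
    ``hardcore`` mm apart.  Raises :class:`PackingError` if the hard core
    is unsatisfiable after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    R, hc2 = config.arena_radius, config.hardcore**2
    parents = None
    sigma = None
    if config.cluster_strength > 0:
        parents = _uniform_disc(rng, config.n_clusters, R)
        sigma = R / (1.0 + 1.5 * config.cluster_strength)

    pts: list[np.ndarray] = []
    max_tries = 2000 * config.n_flies
    tries = 0
    while len(pts) < config.n_flies:
        tries += 1
        if tries > max_tries:
            density = config.n_flies * config.hardcore**2 / R**2
            raise PackingError(
                f"could not place {config.n_flies} flies with a {config.hardcore} mm "
                f"hard core in a {R} mm arena (packing density ~{density:.3f}) "
                f"after {max_tries} attempts"
            )
        if parents is None:
            p = _uniform_disc(rng, 1, R)[0]
        else:
            par = parents[rng.integers(config.n_clusters)]
            p = par + rng.normal(0.0, sigma, 2)
            if p @ p > R * R:
                continue
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= hc2 for q in pts):
            pts.append(p)
    return ArenaSnapshot(
        chamber_id=chamber_id,
        capture_index=capture_index,
        coordinates=np.array(pts),
        arena_radius=R,
    )


# ---------------------------------------------------------------------------
# activity: rhythmic Poisson beam-crossing counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivitySimConfig:
    """Beam-crossing counts: baseline + morning/evening Gaussian bumps.

    The deterministic daily rate (counts per bin) is
    ``baseline + morning bump at lights-on + evening bump at lights-off``;
    per-bin counts are independent Poisson draws around it.  Knockdown
    genotypes have the morning bump, and the pre-transition part of the
    evening bump (the lights-off anticipation ramp), scaled by
    ``knockdown_multiplier``.
    """

    n_flies_per_genotype: int = 16
    n_days: int = 7
    bin_width: int = 5  # minutes
    baseline_rate: float = 1.0
    morning_peak_height: float = 10.0
    evening_peak_height: float = 10.0
    peak_width: float = 60.0  # minutes (Gaussian sd)
    knockdown_multiplier: float = 0.2
    lights_on: int = 8
    lights_off: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_rate, self.morning_peak_height, self.evening_peak_height) < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.knockdown_multiplier <= 1.0:
            raise ValueError("knockdown_multiplier must be in [0, 1]")
        if 1440 % self.bin_width:
            raise ValueError("bin_width must divide 24 h")
        if self.n_flies_per_genotype < 1 or self.n_days < 1:
            raise ValueError("need >= 1 fly and >= 1 day")

    @property
    def schedule(self) -> LightSchedule:
        return LightSchedule(lights_on=self.lights_on, lights_off=self.lights_off)


def _circular_bump(t_min: np.ndarray, center_min: float, height: float, width: float) -> np.ndarray:
    """Gaussian bump on the 24 h circle (minutes)."""
    d = np.abs(t_min - center_min)
    d = np.minimum(d, 1440.0 - d)
    return height * np.exp(-0.5 * (d / width) ** 2)


def activity_rate_curve(config: ActivitySimConfig, knockdown: bool = False) -> np.ndarray:
    """Expected counts per bin over one day (length 1440 / bin_width)."""
    n_bins = 1440 // config.bin_width
    t = (np.arange(n_bins) + 0.5) * config.bin_width  # bin centers, min after midnight
    on_min, off_min = config.lights_on * 60.0, config.lights_off * 60.0
    morning = _circular_bump(t, on_min, config.morning_peak_height, config.peak_width)
    evening = _circular_bump(t, off_min, config.evening_peak_height, config.peak_width)
    if knockdown:
        m = config.knockdown_multiplier
        morning = morning * m
        evening = np.where(t < off_min, evening * m, evening)
    return config.baseline_rate + morning + evening


def morning_peak_bins(config: ActivitySimConfig, out_width: int = 30) -> np.ndarray:
    """Indices (0-based) of ``out_width``-minute daily bins under the morning bump.

    A bin belongs to the morning peak when the control morning-bump
    contribution at its center is at least half the peak height (the
    full-width-at-half-maximum region).
    """
    n_bins = 1440 // out_width
    t = (np.arange(n_bins) + 0.5) * out_width
    bump = _circular_bump(t, config.lights_on * 60.0, config.morning_peak_height, config.peak_width)
    return np.flatnonzero(bump >= 0.5 * config.morning_peak_height)


def simulate_activity(
    config: ActivitySimConfig,
    genotypes: Sequence[str],
    knockdown: Sequence[str] = (),
    start: str = "2024-01-01",
) -> ActivityTable:
    """Simulate one recording covering all genotypes on a shared bin grid.

    Genotypes listed in ``knockdown`` get the morning-peak /
    anticipation-ramp reduction; the rest follow the control rate curve.
    """
    unknown = set(knockdown) - set(genotypes)
    if unknown:
        raise ValueError(f"knockdown genotypes not in genotype list: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    n_day_bins = 1440 // config.bin_width
    n_bins = config.n_days * n_day_bins
    index = pd.date_range(start=start, periods=n_bins, freq=f"{config.bin_width}min")

    cols: dict[str, np.ndarray] = {}
    genotype_of: dict[str, str] = {}
    for geno in genotypes:
        rate = np.tile(activity_rate_curve(config, knockdown=geno in knockdown), config.n_days)
        for i in range(config.n_flies_per_genotype):
            fly = f"{geno}_fly{i + 1:02d}"
            cols[fly] = rng.poisson(rate)
            genotype_of[fly] = geno
    counts = pd.DataFrame(cols, index=index)
    return ActivityTable(
        counts=counts,
        genotypes=pd.Series(genotype_of),
        bin_width=config.bin_width,
        schedule=config.schedule,
    )


# ---------------------------------------------------------------------------
# expression: co-regulated log-normal RPKM profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Gene x sample RPKM table with a planted co-expression module.

    Module genes share one latent log10 profile; independent per-gene
    noise of sd ``noise_sd`` is calibrated so every module pair has
    correlation ``module_rho`` (latent sd = noise_sd * sqrt(rho/(1-rho))).
    Non-module genes are mutually independent with matching total
    variance.  RPKM values are 10**(log10 value), hence non-negative.
    """

    n_genes: int = 24
    n_samples: int = 30
    module_genes: tuple[str, ...] = ("na", "Mid1", "unc79", "unc80")
    module_rho: float = 0.9
    noise_sd: float = 0.2
    dataset_kind: str = "developmental"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.module_rho <= 1.0:
            raise ValueError("module_rho must be in (0, 1]")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.module_genes) > self.n_genes:
            raise ValueError("more module genes than genes")


def simulate_expression(config: ExpressionSimConfig) -> ExpressionMatrix:
    """Draw an RPKM matrix with the configured co-expression structure."""
    rng = np.random.default_rng(config.seed)
    rho = config.module_rho
    if rho == 1.0:
        sigma_latent, noise = 1.0, 0.0
    else:
        noise = config.noise_sd
        sigma_latent = noise * np.sqrt(rho / (1.0 - rho))
    total_sd = float(np.hypot(sigma_latent, noise))

    latent = rng.normal(0.0, sigma_latent, config.n_samples)
    mu_module = 1.5  # shared baseline: ~30 RPKM
    rows: dict[str, np.ndarray] = {}
    for gene in config.module_genes:
        rows[gene] = mu_module + latent + rng.normal(0.0, noise, config.n_samples)
    n_extra = config.n_genes - len(config.module_genes)
    for i in range(n_extra):
        mu = rng.normal(1.5, 0.3)
        rows[f"gene{i + 1:04d}"] = mu + rng.normal(0.0, total_sd, config.n_samples)

    if config.dataset_kind == "tissue":
        samples = [f"tissue{j + 1:02d}" for j in range(config.n_samples)]
    else:
        samples = [f"stage{j + 1:02d}" for j in range(config.n_samples)]
    values = pd.DataFrame(
        np.power(10.0, np.array([rows[g] for g in rows])), index=list(rows), columns=samples
    )
    return ExpressionMatrix(values=values, dataset_kind=config.dataset_kind)


# ---------------------------------------------------------------------------
# msa: gapped alignment with a conserved cysteine motif
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MsaSimConfig:
    """Amino-acid alignment with cysteine motif columns.

    Row 1 is the ungapped consensus reference, so motif positions in the
    reference carry the expected residue by construction.  Every other
    row matches the column consensus with probability
    ``motif_conservation`` (motif columns) or ``background_conservation``
    (elsewhere), otherwise draws a uniform residue; gaps are injected per
    cell at ``gap_rate`` (never in the reference row).
    """

    n_seqs: int = 50
    length: int = 200
    motif_positions: tuple[int, ...] = (20, 45, 90, 130, 170)  # 1-based columns
    motif_conservation: float = 1.0
    background_conservation: float = 0.3
    gap_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise ValueError("need >= 2 sequences")
        for frac in (self.motif_conservation, self.background_conservation, self.gap_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if any(not 1 <= p <= self.length for p in self.motif_positions):
            raise ValueError("motif_positions must lie in [1, length]")


def simulate_msa(config: MsaSimConfig) -> Msa:
    """Draw a synthetic alignment with planted motif conservation."""
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    motif = np.zeros(config.length, dtype=bool)
    motif[[p - 1 for p in config.motif_positions]] = True

    consensus = aa[rng.integers(len(aa), size=config.length)]
    consensus[motif] = "C"

    p_cons = np.where(motif, config.motif_conservation, config.background_conservation)
    rows = [("reference", "".join(consensus))]
    for i in range(config.n_seqs - 1):
        keep = rng.random(config.length) < p_cons
        rand = aa[rng.integers(len(aa), size=config.length)]
        seq = np.where(keep, consensus, rand)
        gaps = rng.random(config.length) < config.gap_rate
        seq = np.where(gaps, "-", seq)
        rows.append((f"seq{i + 2:04d}", "".join(seq)))
    return Msa(
        seq_ids=tuple(r[0] for r in rows),
        rows=tuple(r[1] for r in rows),
        reference_id="reference",
    )


# ---------------------------------------------------------------------------
# writers: the plain-text formats the real-data readers consume
# ---------------------------------------------------------------------------


def write_coordinates(snapshots: Sequence[ArenaSnapshot], path: str | Path) -> None:
    """Write chamber snapshots as the coordinate CSV the reader consumes."""
    rows = []
    for snap in snapshots:
        for i, (x, y) in enumerate(snap.coordinates, start=1):
            rows.append(
                {
                    "chamber_id": snap.chamber_id,
                    "capture_index": snap.capture_index,
                    "fly_index": i,
                    "x_mm": x,
                    "y_mm": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dam(table: ActivityTable, path: str | Path) -> None:
    """Write an ActivityTable in the long tab-delimited format (fly_id, timestamp, count)."""
    long = table.counts.stack().rename("count").reset_index()
    long.columns = ["timestamp", "fly_id", "count"]
    long = long[["fly_id", "timestamp", "count"]].sort_values(["fly_id", "timestamp"])
    long.to_csv(path, sep="\t", index=False)


def write_monitor(table: ActivityTable, path: str | Path, status: int = 1) -> None:
    """Write a Trikinetics-style monitor file (up to 32 channels).

    Columns: reading index, date (dd mon yy), time, status, five zero
    fields, light flag, then one count column per channel.
    """
    flies = list(table.counts.columns)
    if len(flies) > 32:
        raise ValueError("monitor files carry at most 32 channels")
    on, off = table.schedule.lights_on, table.schedule.lights_off
    with open(path, "w") as fh:
        for i, (ts, row) in enumerate(table.counts.iterrows(), start=1):
            hour = ts.hour + ts.minute / 60.0
            light = 1 if LightSchedule(on, off).is_light(hour) else 0
            date = ts.strftime("%d %b %y")
            time = ts.strftime("%H:%M:%S")
            counts = "\t".join(str(int(row[f])) for f in flies)
            fh.write(f"{i}\t{date}\t{time}\t{status}\t0\t0\t0\t0\t0\t{light}\t{counts}\n")


def write_rpkm(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a gene x sample RPKM table as tab-separated text."""
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(msa.seq_ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")
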