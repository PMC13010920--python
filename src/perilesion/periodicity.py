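"""Dyad-relative periodicity analysis.

The analysis counts single-base events (lesions, repair events, somatic
mutations) at each position of a window centered on nucleosome dyads,
normalizes the counts either by trinucleotide-context expectation or by
a matched naked-DNA control, and estimates periodic structure with a
floating-mean (generalized) Lomb-Scargle periodogram.  Two periodic
regimes matter: the translational regime (~nucleosome repeat length,
170-230 bp, linker vs core) probed over a +/-1000 bp window, and the
rotational regime (~10.2 bp helical repeat, minor groove orientation)
probed over the +/-60 bp nucleosome core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeSequence,
    TRINUC_REVCOMP,
    trinuc_code_to_str,
    trinuc_str_to_code,
)

Orientation = Literal["combined", "strand_aligned"]


@dataclass
class DyadMap:
    """Single-position nucleosome dyad centers, sorted per contig."""

    by_chrom: dict[str, np.ndarray]
    label: str = "synthetic"

    def __post_init__(self) -> None:
        self.by_chrom = {
            c: np.sort(np.asarray(p, dtype=np.int64))
            for c, p in self.by_chrom.items()
        }

    @property
    def n_dyads(self) -> int:
        return sum(p.size for p in self.by_chrom.values())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "synthetic") -> "DyadMap":
        return cls(
            {
                chrom: group["pos"].to_numpy()
                for chrom, group in frame.groupby("chrom", sort=False)
            },
            label=label,
        )

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": pos})
            for chrom, pos in self.by_chrom.items()
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def read_bed(cls, path, label: str = "file") -> "DyadMap":
        frame = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "pos"]
        )
        return cls.from_frame(frame, label=label)

    def write_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


@dataclass
class PositionProfile:
    """Values over integer dyad-relative positions [-half_window, +half_window].

    ``mask`` marks undefined positions (e.g. zero expected counts).
    """

    half_window: int
    values: np.ndarray
    kind: str = "raw_count"  # {raw_count, expected, enrichment, repair_activity}
    orientation: Orientation = "combined"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != 2 * self.half_window + 1:
            raise ValueError(
                f"profile length {self.values.size} != 2*{self.half_window}+1"
            )
        if self.mask is None:
            self.mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.half_window, self.half_window + 1)

    def unmasked(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.mask
        return self.positions[keep], self.values[keep]

    def restrict(self, half_window: int) -> "PositionProfile":
        if half_window > self.half_window:
            raise ValueError("cannot widen a profile")
        sl = slice(
            self.half_window - half_window, self.half_window + half_window + 1
        )
        return PositionProfile(
            half_window, self.values[sl], self.kind, self.orientation, self.mask[sl]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "value": np.where(self.mask, np.nan, self.values),
            }
        )


def _event_arrays(events: pd.DataFrame, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    group = events[events["chrom"] == chrom]
    return group["pos"].to_numpy(np.int64), group["strand"].to_numpy()


def count_relative_to_dyads(
    events: pd.DataFrame,
    dyads: DyadMap,
    half_window: int = 1000,
    orientation: Orientation = "combined",
) -> PositionProfile:
    """Histogram events over dyad-relative positions.

    combined: every event at genomic p near dyad d adds 1 at i = p - d.
    strand_aligned: minus-strand events contribute at i = -(p - d), so
    both strands read 5'->3' in the same direction.  Events within the
    window of several dyads count toward each.
    """
    if dyads.n_dyads == 0:
        raise ValueError("empty dyad map")
    hist = np.zeros(2 * half_window + 1, dtype=np.int64)
    for chrom, dyad_pos in dyads.by_chrom.items():
        pos, strand = _event_arrays(events, chrom)
        if pos.size == 0 or dyad_pos.size == 0:
            continue
        lo = np.searchsorted(dyad_pos, pos - half_window, side="left")
        hi = np.searchsorted(dyad_pos, pos + half_window, side="right")
        mult = hi - lo
        minus = strand == "-"
        for j in range(int(mult.max()) if mult.size else 0):
            sel = mult > j
            i = pos[sel] - dyad_pos[lo[sel] + j]
            if orientation == "strand_aligned":
                i = np.where(minus[sel], -i, i)
            np.add.at(hist, i + half_window, 1)
    return PositionProfile(half_window, hist, "raw_count", orientation)


@dataclass
class ContextRates:
    """Genome-wide per-trinucleotide event rate (events per strand-site)."""

    rates: dict[str, float]
    convention: str = "guanine_centered"  # or pyrimidine_centered

    def as_array(self) -> np.ndarray:
        arr = np.zeros(64)
        for tri, rate in self.rates.items():
            arr[trinuc_str_to_code(tri)] = rate
        return arr


def genomewide_context_rates(
    events: pd.DataFrame,
    genome: GenomeSequence,
    mask: pd.DataFrame | None = None,
    convention: str = "guanine_centered",
) -> tuple[ContextRates, int]:
    """m_t = events with strand-resolved centered context t / genomic
    occurrences of t (both strands, unmasked).  Returns (rates,
    n_excluded) where excluded events have edge/N contexts.

    ``mask``: optional intervals (chrom/start/end) excluded from the
    occurrence counts.
    """
    occ = np.zeros(64, dtype=np.int64)
    ev = np.zeros(64, dtype=np.int64)
    excluded = 0
    for chrom in genome.names:
        tri = genome.trinuc_codes(chrom)
        keep = np.ones(tri.size, dtype=bool)
        if mask is not None:
            for row in mask[mask["chrom"] == chrom].itertuples(index=False):
                keep[row.start : row.end] = False
        valid = (tri >= 0) & keep
        occ += np.bincount(tri[valid], minlength=64)
        occ += np.bincount(TRINUC_REVCOMP[tri[valid]], minlength=64)
        pos, strand = _event_arrays(events, chrom)
        if pos.size == 0:
            continue
        in_range = (pos >= 0) & (pos < tri.size)
        codes = np.where(in_range, tri[np.clip(pos, 0, tri.size - 1)], -1)
        minus = strand == "-"
        codes = np.where(minus & (codes >= 0), TRINUC_REVCOMP[np.clip(codes, 0, 63)], codes)
        good = codes >= 0
        excluded += int((~good).sum())
        ev += np.bincount(codes[good], minlength=64)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(occ > 0, ev / np.maximum(occ, 1), 0.0)
    rates = {
        trinuc_code_to_str(c): float(m[c]) for c in range(64) if occ[c] > 0
    }
    return ContextRates(rates, convention), excluded


def expected_profile(
    dyads: DyadMap,
    genome: GenomeSequence,
    rates: ContextRates,
    half_window: int = 1000,
    orientation: Orientation = "combined",
) -> PositionProfile:
    """E_i = sum_t f_t(i) * m_t with f_t(i) the strand-resolved count of
    context t centered at dyad-relative position i over all dyads.

    Both strands are accumulated; under strand_aligned orientation the
    minus-strand context at genomic offset j contributes at i = -j.
    Dyads closer than half_window+1 to a contig edge are dropped.
    """
    if not rates.rates:
        raise ValueError("empty context rates")
    m = rates.as_array()
    E = np.zeros(2 * half_window + 1)
    offsets = np.arange(-half_window, half_window + 1)
    for chrom, dyad_pos in dyads.by_chrom.items():
        tri = genome.trinuc_codes(chrom)
        n = tri.size
        dyad_pos = dyad_pos[
            (dyad_pos - half_window - 1 >= 0) & (dyad_pos + half_window + 1 < n)
        ]
        if dyad_pos.size == 0:
            continue
        m_plus = np.concatenate([m, [0.0]])  # -1 codes -> rate 0
        m_minus = np.concatenate([m[TRINUC_REVCOMP], [0.0]])
        for k, i in enumerate(offsets):
            codes = tri[dyad_pos + i]
            E[k] += m_plus[codes].sum()
            if orientation == "combined":
                E[k] += m_minus[codes].sum()
            else:
                # minus-strand context at +i counts at position -i
                E[2 * half_window - k] += m_minus[codes].sum()
    return PositionProfile(half_window, E, "expected", orientation)


def enrichment_profile(
    observed: PositionProfile, expected: PositionProfile
) -> PositionProfile:
    """e_i = O_i / E_i, masked where E_i = 0."""
    if (
        observed.half_window != expected.half_window
        or observed.orientation != expected.orientation
    ):
        raise ValueError("observed/expected profile shape or orientation mismatch")
    mask = observed.mask | expected.mask | (expected.values == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(mask, np.nan, observed.values / np.where(mask, 1, expected.values))
    return PositionProfile(
        observed.half_window, np.nan_to_num(e), "enrichment", observed.orientation, mask
    )


def ratio_profile(
    numerator: PositionProfile, denominator: PositionProfile
) -> PositionProfile:
    """r_i = (N_i/sum N) / (D_i/sum D): each raw-count track is scaled to
    its window total before the position-wise ratio.  Zero-denominator
    positions are masked."""
    if (
        numerator.half_window != denominator.half_window
        or numerator.orientation != denominator.orientation
    ):
        raise ValueError("profile shape or orientation mismatch")
    if denominator.values.sum() == 0:
        raise ValueError("all-zero denominator profile")
    n = numerator.values / numerator.values.sum()
    d = denominator.values / denominator.values.sum()
    mask = numerator.mask | denominator.mask | (d == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mask, 0.0, n / np.where(mask, 1, d))
    return PositionProfile(
        numerator.half_window, r, "enrichment", numerator.orientation, mask
    )


def smooth_profile(profile: PositionProfile, width: int = 11) -> PositionProfile:
    """Centered moving average; the window truncates at the profile edges
    and masked positions are excluded from each local mean."""
    if width % 2 == 0:
        raise ValueError("smoothing width must be odd")
    valid = (~profile.mask).astype(float)
    vals = np.where(profile.mask, 0.0, profile.values)
    kernel = np.ones(width)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    with np.errstate(divide="ignore", invalid="ignore"):
        sm = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return PositionProfile(
        profile.half_window, sm, profile.kind, profile.orientation, den == 0
    )


@dataclass
class PeriodogramResult:
    periods: np.ndarray  # bp, decreasing along the uniform frequency grid
    power: np.ndarray  # normalized GLS power in [0, 1]
    peak_period: float
    snr: float
    degenerate: bool = False  # constant input profile

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period": self.periods, "power": self.power})


class LombScargleGrid:
    """Floating-mean Lomb-Scargle periodogram on a fixed position grid.

    Precomputes the trigonometric sums that do not depend on the profile
    values, so repeated evaluation (e.g. shuffled nulls) costs one
    matrix-vector product per profile.
    """

    def __init__(
        self,
        positions: np.ndarray,
        period_range: tuple[float, float],
        grid_points: int = 2001,
    ):
        pmin, pmax = period_range
        if not 0 < pmin < pmax:
            raise ValueError("invalid period range")
        self.x = np.asarray(positions, dtype=float)
        n = self.x.size
        if n < 8:
            raise ValueError("need >= 8 unmasked positions")
        freqs = np.linspace(1.0 / pmax, 1.0 / pmin, grid_points)
        self.periods = 1.0 / freqs
        ang = 2 * np.pi * freqs[:, None] * self.x[None, :]
        self._C = np.cos(ang)
        self._S = np.sin(ang)
        w = 1.0 / n
        self._Cbar = w * self._C.sum(axis=1)
        self._Sbar = w * self._S.sum(axis=1)
        self._CC = w * (self._C**2).sum(axis=1) - self._Cbar**2
        self._SS = w * (self._S**2).sum(axis=1) - self._Sbar**2
        self._CS = w * (self._C * self._S).sum(axis=1) - self._Cbar * self._Sbar
        self._w = w

    def power(self, y: np.ndarray) -> np.ndarray:
        """Zechmeister-Kurster normalized power: the fractional chi^2
        reduction of the sinusoid+offset least-squares fit at each
        frequency, in [0, 1]."""
        y = np.asarray(y, dtype=float)
        ybar = y.mean()
        yc = y - ybar
        YY = self._w * (yc**2).sum()
        if YY == 0:
            return np.zeros(self.periods.size)
        YC = self._w * (self._C @ yc)
        YS = self._w * (self._S @ yc)
        D = self._CC * self._SS - self._CS**2
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (
                self._SS * YC**2 + self._CC * YS**2 - 2 * self._CS * YC * YS
            ) / (YY * D)
        return np.where(np.abs(D) > 1e-15, p, 0.0)


def periodogram_snr(
    periods: np.ndarray, power: np.ndarray, peak_exclusion: float = 0.05
) -> float:
    """Peak power over median off-peak power; grid periods within
    +/-peak_exclusion (fractional) of the peak period are excluded from
    the background."""
    k = int(np.argmax(power))
    peak_period = periods[k]
    off = np.abs(periods - peak_period) > peak_exclusion * peak_period
    background = np.median(power[off]) if off.any() else np.nan
    if not np.isfinite(background) or background <= 0:
        return float("inf") if power[k] > 0 else 0.0
    return float(power[k] / background)


def lomb_scargle_periodogram(
    profile: PositionProfile,
    period_range: tuple[float, float],
    grid_points: int = 2001,
) -> PeriodogramResult:
    """Periodogram of the unmasked profile positions with SNR.

    A constant (degenerate) profile yields ~zero power everywhere; the
    result is flagged rather than raised.
    """
    x, y = profile.unmasked()
    grid = LombScargleGrid(x, period_range, grid_points)
    power = grid.power(y)
    degenerate = bool(np.ptp(y) == 0)
    k = int(np.argmax(power))
    snr = periodogram_snr(grid.periods, power)
    return PeriodogramResult(
        grid.periods, power, float(grid.periods[k]), snr, degenerate
    )


ROTATIONAL_LABELS = ("minor_out", "out_to_in", "minor_in", "in_to_out")


@dataclass(frozen=True)
class RotationalConfig:
    """Quarter-cycle classification of the helical repeat.

    phase is the dyad-relative offset (bp) of the minor-out center
    nearest the dyad; the cycle is split into quarters centered on
    minor_out (at phase), minor_in (half a period away), and the two
    transition states between them.
    """

    helical_period: float = 10.2
    phase: float = 0.0
    core_half_width: int = 60

    def __post_init__(self) -> None:
        if self.helical_period <= 0:
            raise ValueError("helical_period must be > 0")
        if not 0 <= self.phase < self.helical_period:
            raise ValueError("phase must lie in [0, helical_period)")


def classify_rotational(
    i: np.ndarray | int, config: RotationalConfig, check_core: bool = True
) -> np.ndarray:
    """Label dyad-relative position(s) by rotational setting.

    cycle position c = ((i - phase) mod P)/P; quarters: c in
    [-1/8, 1/8) -> minor_out, [1/8, 3/8) -> out_to_in, [3/8, 5/8) ->
    minor_in, [5/8, 7/8) -> in_to_out.
    """
    arr = np.atleast_1d(np.asarray(i, dtype=float))
    if check_core and (np.abs(arr) > config.core_half_width).any():
        raise ValueError("position outside the nucleosome core")
    c = np.mod(arr - config.phase, config.helical_period) / config.helical_period
    quarter = np.floor((c + 1 / 8) * 4).astype(int) % 4
    labels = np.array(ROTATIONAL_LABELS)[quarter]
    return labels if np.ndim(i) else labels[0]


def rotational_summary(
    profile: PositionProfile, config: RotationalConfig
) -> pd.DataFrame:
    """Mean profile value and position count per rotational label over
    unmasked core positions."""
    core = profile.restrict(config.core_half_width)
    pos, vals = core.unmasked()
    labels = classify_rotational(pos, config)
    frame = pd.DataFrame({"label": labels, "value": vals})
    out = frame.groupby("label")["value"].agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_value", "count": "n_positions"})


def shuffled_null_snrs(
    profile: PositionProfile,
    period_range: tuple[float, float],
    n_shuffles: int = 200,
    grid_points: int = 2001,
    seed: int = 0,
) -> np.ndarray:
    """SNRs of position-shuffled copies of the profile (values permuted
    across unmasked positions), sharing one precomputed grid."""
    x, y = profile.unmasked()
    grid = LombScargleGrid(x, period_range, grid_points)
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        power = grid.power(rng.permutation(y))
        out[s] = periodogram_snr(grid.periods, power)
    return out
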