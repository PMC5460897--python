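"""Sliding-window net-charge landscape of a proteome.

The central quantity is the net charge of every 30-residue window of a
protein — 30 residues being the approximate length of nascent chain held
in the ribosome exit tunnel — computed from per-residue ionization
charges (see :mod:`chargescape.charge_model`).  On top of the window
scan this module provides the proteome-level summaries: sign-fraction
statistics, negative/positive ratio curves by charge magnitude,
per-position mean charges of the terminal 30 residues, N/core/C-terminal
heat-map matrices, grouped mean window profiles, first-vs-last window
correlation, detection of supercharged (|q| >= 14) stretches, and a
normality-gated trait correlation helper.

Coordinates are 1-based and inclusive throughout: window ``i`` covers
residues ``i .. i+W-1``, and "the net charge of the first 30 residues"
is window 1.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .charge_model import DEFAULT_TABLE, ResidueChargeTable, residue_charges
from .proteome_io import ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 30
SUPERCHARGE_THRESHOLD = 14


@dataclass
class ChargeProfile:
    """Per-residue and per-window net charges of one protein."""

    protein_id: str
    sequence: str
    window_length: int
    residue_charges: np.ndarray
    window_charges: np.ndarray  # index 0 = window starting at residue 1

    @property
    def n_windows(self) -> int:
        return len(self.window_charges)

    def window(self, start: int) -> float:
        """Net charge of the window starting at 1-based residue ``start``."""
        if not 1 <= start <= self.n_windows:
            raise IndexError(f"window start {start} out of range 1..{self.n_windows}")
        return self.window_charges[start - 1]

    @property
    def first_window_charge(self) -> float:
        return self.window(1)

    @property
    def last_window_charge(self) -> float:
        return self.window(self.n_windows)


def window_scan(
    record: ProteinRecord | str,
    table: ResidueChargeTable = DEFAULT_TABLE,
    window: int = DEFAULT_WINDOW,
) -> ChargeProfile:
    """Net charge of every length-``window`` segment, by rolling sum.

    Integer rounding mode uses exact integer arithmetic.  Proteins
    shorter than the window cannot be scanned (see :func:`scan_proteome`
    for the skip-with-warning contract over collections).
    """
    if isinstance(record, str):
        record = ProteinRecord(id="seq", sequence=record)
    seq = record.sequence
    if len(seq) < window:
        raise ValueError(
            f"{record.id}: length {len(seq)} shorter than window {window}"
        )
    dtype = np.int64 if table.rounding == "integer" else np.float64
    charges = np.asarray(residue_charges(seq, table), dtype=dtype)
    kernel = np.ones(window, dtype=dtype)
    windows = np.convolve(charges, kernel, mode="valid")
    if table.rounding != "integer":
        windows = np.round(windows, 3)
    return ChargeProfile(
        protein_id=record.id,
        sequence=seq,
        window_length=window,
        residue_charges=charges,
        window_charges=windows,
    )


def scan_proteome(
    records: Sequence[ProteinRecord],
    table: ResidueChargeTable = DEFAULT_TABLE,
    window: int = DEFAULT_WINDOW,
) -> list[ChargeProfile]:
    """Scan every record long enough; shorter ones are skipped with a log."""
    profiles = []
    skipped = 0
    for rec in records:
        if len(rec) < window:
            skipped += 1
            continue
        profiles.append(window_scan(rec, table, window))
    if skipped:
        logger.warning("scan_proteome: skipped %d protein(s) shorter than %d", skipped, window)
    return profiles


# ---------------------------------------------------------------------------
# frequency statistics


@dataclass(frozen=True)
class SignFractions:
    positive: float
    neutral: float
    negative: float
    n: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.positive, self.neutral, self.negative)


def sign_fractions(charges: Iterable[float]) -> SignFractions:
    """Fractions of window charges that are >0, ==0 and <0.

    In integer mode "neutral" means charge 0; in three-decimal mode it
    means exactly 0.000.
    """
    arr = np.asarray(list(charges))
    if arr.size == 0:
        raise ValueError("sign_fractions of empty input")
    n = arr.size
    pos = int((arr > 0).sum())
    neg = int((arr < 0).sum())
    neu = n - pos - neg
    return SignFractions(pos / n, neu / n, neg / n, n)


def charge_histogram(charges: Iterable[float]) -> Counter:
    """Histogram of (integer) window charges."""
    return Counter(int(c) for c in charges)


def neg_pos_ratio_curve(histogram: Mapping[int, int]) -> dict[int, float | None]:
    """count(-q)/count(+q) per charge magnitude q = 1..max|q|.

    Magnitudes with no positive-side windows map to ``None`` (missing),
    reported distinctly from a ratio of 0.
    """
    if not histogram:
        return {}
    max_mag = max((abs(q) for q in histogram if q != 0), default=0)
    curve: dict[int, float | None] = {}
    for q in range(1, max_mag + 1):
        neg = histogram.get(-q, 0)
        pos = histogram.get(q, 0)
        curve[q] = (neg / pos) if pos > 0 else None
    return curve


# ---------------------------------------------------------------------------
# positional statistics


def per_position_mean_charge(
    records: Sequence[ProteinRecord],
    table: ResidueChargeTable = DEFAULT_TABLE,
    region: str = "first30",
    length: int = 30,
) -> np.ndarray:
    """Mean residue charge at each of the first or last ``length`` positions.

    Proteins shorter than ``length`` are excluded.  ``last30`` aligns
    positions to the C-terminal residue (index -1 = last residue is the
    final vector entry).
    """
    if region not in ("first30", "last30"):
        raise ValueError(f"unknown region: {region!r}")
    eligible = [rec for rec in records if len(rec) >= length]
    if not eligible:
        raise ValueError("no proteins long enough for per-position means")
    sums = np.zeros(length)
    for rec in eligible:
        seg = rec.sequence[:length] if region == "first30" else rec.sequence[-length:]
        sums += np.asarray(residue_charges(seg, table), dtype=float)
    return sums / len(eligible)


# ---------------------------------------------------------------------------
# heat maps and grouped profiles


@dataclass
class HeatmapMatrix:
    """Mean window charge per (row, window-start) tile.

    ``values`` holds NaN where no protein contributes (never zero-filled);
    ``support`` counts contributing proteins per tile.  Column labels are
    1-based window starts for N-terminal/core regions and negative
    offsets from the sequence end (-129..-30, step such that -30 labels
    the final window) for the C-terminal region.
    """

    region: str
    row_ids: list[str]
    starts: np.ndarray
    values: np.ndarray  # (rows, 100), NaN = missing
    support: np.ndarray  # (rows, 100), int

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, rid in enumerate(self.row_ids):
            for j, start in enumerate(self.starts):
                if self.support[i, j] == 0:
                    continue
                rows.append(
                    {
                        "row": rid,
                        "region": self.region,
                        "start": int(start),
                        "mean_charge": self.values[i, j],
                        "support": int(self.support[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["row", "region", "start", "mean_charge", "support"])


_REGION_NCOLS = 100


def _region_window_values(profile: ChargeProfile, region: str) -> np.ndarray:
    """Window charges at the 100 tile positions of a region; NaN = absent.

    N-terminal tiles are windows starting at residues 1..100, core tiles
    windows starting at 130..229, C-terminal tiles the last 100 windows
    aligned to the sequence end.
    """
    out = np.full(_REGION_NCOLS, np.nan)
    nw = profile.n_windows
    if region == "nterm":
        upto = min(nw, _REGION_NCOLS)
        out[:upto] = profile.window_charges[:upto]
    elif region == "core":
        for j in range(_REGION_NCOLS):
            start = 130 + j
            if start <= nw:
                out[j] = profile.window_charges[start - 1]
    elif region == "cterm":
        # column j (0-based) covers residues [-130+j .. -101+j] from the end;
        # j = 99 is the final window.
        for j in range(_REGION_NCOLS):
            start = nw - (_REGION_NCOLS - 1 - j)
            if start >= 1:
                out[j] = profile.window_charges[start - 1]
    else:
        raise ValueError(f"unknown region: {region!r}")
    return out


def _region_starts(region: str) -> np.ndarray:
    if region == "nterm":
        return np.arange(1, _REGION_NCOLS + 1)
    if region == "core":
        return np.arange(130, 130 + _REGION_NCOLS)
    if region == "cterm":
        # label by the (negative) 1-based offset of the window's first
        # residue from the sequence end: -30 is the last window.
        return np.arange(-129, -29)
    raise ValueError(f"unknown region: {region!r}")


def heatmap_matrix(
    profiles: Sequence[ChargeProfile],
    region: str,
    group_by: Mapping[str, str] | None = None,
) -> HeatmapMatrix:
    """Build the N/core/C-terminal heat-map matrix.

    Without ``group_by`` every protein is a row; with it, rows are group
    means over members (``group_by`` maps protein id -> group label) and
    ``support`` counts contributing proteins per tile.  Proteins shorter
    than a tile's window simply do not contribute to that tile.
    """
    starts = _region_starts(region)
    if group_by is None:
        row_ids = [p.protein_id for p in profiles]
        values = np.full((len(profiles), _REGION_NCOLS), np.nan)
        support = np.zeros((len(profiles), _REGION_NCOLS), dtype=int)
        for i, prof in enumerate(profiles):
            vals = _region_window_values(prof, region)
            values[i] = vals
            support[i] = ~np.isnan(vals)
        return HeatmapMatrix(region, row_ids, starts, values, support)

    groups: dict[str, list[np.ndarray]] = {}
    for prof in profiles:
        label = group_by.get(prof.protein_id)
        if label is None:
            continue
        groups.setdefault(label, []).append(_region_window_values(prof, region))
    row_ids = sorted(groups)
    values = np.full((len(row_ids), _REGION_NCOLS), np.nan)
    support = np.zeros((len(row_ids), _REGION_NCOLS), dtype=int)
    for i, label in enumerate(row_ids):
        stack = np.vstack(groups[label])
        counts = (~np.isnan(stack)).sum(axis=0)
        support[i] = counts
        sums = np.nansum(stack, axis=0)
        means = np.full(_REGION_NCOLS, np.nan)
        nonzero = counts > 0
        means[nonzero] = sums[nonzero] / counts[nonzero]
        values[i] = means
    return HeatmapMatrix(region, row_ids, starts, values, support)


def group_mean_window_profile(
    records: Sequence[ProteinRecord],
    table: ResidueChargeTable = DEFAULT_TABLE,
    upto_start: int = 100,
    group_by: Mapping[str, str] | None = None,
    window: int = DEFAULT_WINDOW,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean window charge at starts 1..upto_start per group.

    Returns {group: (means, support)}; groups with no scannable member
    are omitted with a warning.  ``group_by`` maps protein id -> group;
    ``None`` groups the whole input as ``"all"``.
    """
    assignment = group_by or {rec.id: "all" for rec in records}
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        label = assignment.get(rec.id)
        if label is None or len(rec) < window:
            continue
        prof = window_scan(rec, table, window)
        upto = min(prof.n_windows, upto_start)
        sums.setdefault(label, np.zeros(upto_start))
        counts.setdefault(label, np.zeros(upto_start, dtype=int))
        sums[label][:upto] += prof.window_charges[:upto]
        counts[label][:upto] += 1
    empty = set(assignment.values()) - set(sums)
    if empty:
        logger.warning("group_mean_window_profile: omitting empty group(s) %s", sorted(empty))
    out = {}
    for label in sorted(sums):
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums[label] / counts[label]
        means[counts[label] == 0] = np.nan
        out[label] = (means, counts[label])
    return out


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float  # NaN when undefined (zero variance)
    r_squared: float
    p_value: float
    n: int


def nc_terminal_correlation(
    records: Sequence[ProteinRecord],
    table: ResidueChargeTable = DEFAULT_TABLE,
    window: int = DEFAULT_WINDOW,
) -> CorrelationResult:
    """Pearson correlation of first-window vs last-window net charge.

    Only proteins of length >= 2*window contribute, so the two windows
    never overlap; shorter proteins are excluded with a logged count.
    """
    eligible = [rec for rec in records if len(rec) >= 2 * window]
    excluded = len(records) - len(eligible)
    if excluded:
        logger.info("nc_terminal_correlation: excluded %d protein(s) shorter than %d", excluded, 2 * window)
    if len(eligible) < 3:
        raise ValueError(f"need at least 3 proteins, got {len(eligible)}")
    first = np.empty(len(eligible))
    last = np.empty(len(eligible))
    for i, rec in enumerate(eligible):
        prof = window_scan(rec, table, window)
        first[i] = prof.first_window_charge
        last[i] = prof.last_window_charge
    if np.all(first == first[0]) or np.all(last == last[0]):
        return CorrelationResult("pearson", math.nan, math.nan, math.nan, len(eligible))
    r, p = stats.pearsonr(first, last)
    return CorrelationResult("pearson", float(r), float(r) ** 2, float(p), len(eligible))


def correlate_with_trait(
    values_x: Sequence[float], values_y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Normality-gated correlation of two paired variables.

    Both margins are tested with the D'Agostino–Pearson omnibus
    normality test; Pearson is used when both pass at ``alpha``,
    Spearman otherwise.  Requires n >= 8 (the omnibus test is undefined
    below that); smaller samples must pick a method explicitly.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    if n < 8:
        raise ValueError(
            "n < 8: the omnibus normality test needs >= 8 observations; "
            "choose pearson or spearman explicitly"
        )
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult("undefined", math.nan, math.nan, math.nan, n)
    px = stats.normaltest(x).pvalue
    py = stats.normaltest(y).pvalue
    if px > alpha and py > alpha:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method, float(r), float(r) ** 2, float(p), n)


# ---------------------------------------------------------------------------
# supercharged stretches


@dataclass(frozen=True)
class SuperchargedStretch:
    """A maximal run of windows with |net charge| >= threshold (one sign).

    ``start`` is the 1-based first qualifying window start; ``context``
    is the window plus the next ``window_length`` residues (60 aa for the
    default 30-residue window), truncated at the protein end.
    """

    protein_id: str
    sign: int  # +1 or -1
    start: int
    end: int  # last qualifying window start in the run
    peak_charge: float
    context: str
    truncated: bool


def find_supercharged(
    profile: ChargeProfile,
    threshold: float = SUPERCHARGE_THRESHOLD,
    context: int = DEFAULT_WINDOW,
) -> list[SuperchargedStretch]:
    """Detect supercharged stretches in one protein.

    Overlapping qualifying windows of the same sign collapse into
    maximal runs; each run is reported once with its first qualifying
    start, its peak charge, and the sequence context (window + next
    ``context`` residues).
    """
    qualifying = np.where(np.abs(profile.window_charges) >= threshold)[0]
    stretches: list[SuperchargedStretch] = []
    run: list[int] = []
    run_sign = 0

    def flush() -> None:
        if not run:
            return
        start = run[0] + 1
        charges = profile.window_charges[run]
        peak = charges[np.argmax(np.abs(charges))]
        ctx_end = run[0] + profile.window_length + context
        ctx = profile.sequence[run[0] : ctx_end]
        stretches.append(
            SuperchargedStretch(
                protein_id=profile.protein_id,
                sign=run_sign,
                start=start,
                end=run[-1] + 1,
                peak_charge=float(peak),
                context=ctx,
                truncated=len(ctx) < profile.window_length + context,
            )
        )

    for idx in qualifying:
        sign = 1 if profile.window_charges[idx] > 0 else -1
        if run and (idx != run[-1] + 1 or sign != run_sign):
            flush()
            run = []
        run_sign = sign
        run.append(int(idx))
    flush()
    return stretches


def find_supercharged_proteome(
    profiles: Sequence[ChargeProfile],
    threshold: float = SUPERCHARGE_THRESHOLD,
    context: int = DEFAULT_WINDOW,
) -> list[SuperchargedStretch]:
    out: list[SuperchargedStretch] = []
    for prof in profiles:
        out.extend(find_supercharged(prof, threshold, context))
    return out
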