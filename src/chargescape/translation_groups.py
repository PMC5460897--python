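"""Monosome/polysome stratification of N-terminal charge.

Genes are split into five translation categories — short ORFs (< 590 nt,
where initiation outlasts elongation so a second ribosome rarely loads),
monosome-enriched, no-enrichment, polysome-enriched, and the 300 most
polysome-skewed genes — either from precomputed labels or from a
monosome:polysome log-ratio score.  Per category the module computes
first-window charge histograms with sign fractions, mean net charge of
the N-terminal / core / C-terminal windows, and the 16-bin
charge-by-category percentage table with its all-protein baseline.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .charge_model import DEFAULT_TABLE, ResidueChargeTable
from .charge_landscape import SignFractions, sign_fractions, window_scan
from .proteome_io import ProteinRecord

logger = logging.getLogger(__name__)

ORF_LENGTH_CUTOFF_NT = 590
TOP_POLYSOME_N = 300
CORE_WINDOW_START = 121  # window start for the "core" segment mean
ALT_CORE_WINDOW_START = 130

CATEGORIES = ("orf_lt_590", "monosome", "no_enrichment", "polysome", "top300_polysome")

#: Symmetric log-ratio cutoffs used when only scores are available.
#: A score is log2(monosome:polysome); above +0.5 = monosome-enriched,
#: below -0.5 = polysome-enriched.
DEFAULT_SCORE_THRESHOLDS = (-0.5, 0.5)


@dataclass(frozen=True)
class MPClassification:
    gene_id: str
    category: str
    source: str  # "label" or "score"


def classify_mp(
    records: Sequence[ProteinRecord],
    thresholds: tuple[float, float] = DEFAULT_SCORE_THRESHOLDS,
    top_n: int = TOP_POLYSOME_N,
) -> list[MPClassification]:
    """Assign each gene a monosome/polysome category.

    Precomputed ``mp_label`` wins when present.  Otherwise ORFs shorter
    than 590 nt are ``orf_lt_590`` regardless of score (590 itself goes
    to the score branch), and the monosome:polysome score is cut at the
    (polysome, monosome) thresholds.  Among score-classified polysome
    genes the ``top_n`` lowest scores become ``top300_polysome`` (a
    disjoint category).  Genes with neither label nor usable score are
    left unclassified and logged.
    """
    poly_thr, mono_thr = thresholds
    if poly_thr > mono_thr:
        raise ValueError("thresholds must be (polysome_cutoff <= monosome_cutoff)")
    out: list[MPClassification] = []
    scored_polysome: list[tuple[float, str]] = []
    unclassified = 0
    for rec in records:
        if rec.mp_label is not None:
            if rec.mp_label not in CATEGORIES:
                raise ValueError(f"{rec.id}: unknown mp label {rec.mp_label!r}")
            out.append(MPClassification(rec.id, rec.mp_label, "label"))
            continue
        if rec.orf_length_nt is not None and rec.orf_length_nt < ORF_LENGTH_CUTOFF_NT:
            out.append(MPClassification(rec.id, "orf_lt_590", "score"))
            continue
        if rec.mp_score is None:
            unclassified += 1
            continue
        if rec.mp_score > mono_thr:
            out.append(MPClassification(rec.id, "monosome", "score"))
        elif rec.mp_score < poly_thr:
            scored_polysome.append((rec.mp_score, rec.id))
        else:
            out.append(MPClassification(rec.id, "no_enrichment", "score"))
    # the top_n most polysome-skewed (lowest) scores form their own category
    scored_polysome.sort()
    top = {gene for _, gene in scored_polysome[:top_n]}
    for score, gene in scored_polysome:
        category = "top300_polysome" if gene in top else "polysome"
        out.append(MPClassification(gene, category, "score"))
    if unclassified:
        logger.warning("classify_mp: %d gene(s) had neither label nor score", unclassified)
    return out


def _first_window_charges(
    records: Sequence[ProteinRecord],
    table: ResidueChargeTable,
    window: int,
) -> dict[str, int]:
    charges = {}
    for rec in records:
        if len(rec) >= window:
            charges[rec.id] = int(window_scan(rec, table, window).first_window_charge)
    return charges


def group_charge_histogram(
    records: Sequence[ProteinRecord],
    classification: Sequence[MPClassification],
    table: ResidueChargeTable = DEFAULT_TABLE,
    window: int = 30,
) -> dict[str, tuple[Counter, SignFractions]]:
    """Per-category histogram of first-window charges plus sign fractions."""
    charges = _first_window_charges(records, table, window)
    by_cat: dict[str, list[int]] = {}
    for cls in classification:
        if cls.gene_id in charges:
            by_cat.setdefault(cls.category, []).append(charges[cls.gene_id])
    empty = set(c.category for c in classification) - set(by_cat)
    if empty:
        logger.warning("group_charge_histogram: omitting empty categories %s", sorted(empty))
    return {
        cat: (Counter(vals), sign_fractions(vals)) for cat, vals in by_cat.items()
    }


def group_segment_means(
    records: Sequence[ProteinRecord],
    classification: Sequence[MPClassification],
    table: ResidueChargeTable = DEFAULT_TABLE,
    window: int = 30,
    core_start: int = CORE_WINDOW_START,
) -> pd.DataFrame:
    """Mean +/- SE net charge of the N-terminal, core and C-terminal windows.

    Segments: window 1, the window starting at ``core_start`` (default
    121; proteins must be long enough to possess it), and the last
    window.  Returns a tidy frame (category, segment, mean, se, n).
    """
    by_id = {rec.id: rec for rec in records}
    values: dict[tuple[str, str], list[float]] = {}
    for cls in classification:
        rec = by_id.get(cls.gene_id)
        if rec is None or len(rec) < window:
            continue
        prof = window_scan(rec, table, window)
        values.setdefault((cls.category, "nterm"), []).append(prof.first_window_charge)
        values.setdefault((cls.category, "cterm"), []).append(prof.last_window_charge)
        if prof.n_windows >= core_start:
            values.setdefault((cls.category, "core"), []).append(prof.window(core_start))
    rows = []
    for (cat, segment), vals in sorted(values.items()):
        arr = np.asarray(vals, dtype=float)
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan
        rows.append(
            {"category": cat, "segment": segment, "mean": float(arr.mean()), "se": se, "n": len(arr)}
        )
    return pd.DataFrame(rows, columns=["category", "segment", "mean", "se", "n"])


def charge_bin_group_percentages(
    records: Sequence[ProteinRecord],
    classification: Sequence[MPClassification],
    table: ResidueChargeTable = DEFAULT_TABLE,
    window: int = 30,
) -> tuple[pd.DataFrame, pd.Series]:
    """16-bin charge x category percentage table plus overall baseline.

    First-window charges are binned into <= -7, -6 .. +7 (one bin each)
    and >= +8.  Each present bin's row gives the percentage of its
    proteins in each category (rows sum to 100); empty bins are absent
    from the table rather than zero rows.  The baseline series is the
    category percentage over all classified proteins.
    """
    charges = _first_window_charges(records, table, window)
    cat_by_gene = {cls.gene_id: cls.category for cls in classification}

    def bin_label(q: int) -> str:
        if q <= -7:
            return "<=-7"
        if q >= 8:
            return ">=+8"
        return str(q)

    bin_order = ["<=-7"] + [str(q) for q in range(-6, 8)] + [">=+8"]
    tallies: dict[str, Counter] = {}
    overall: Counter = Counter()
    for gene, q in charges.items():
        cat = cat_by_gene.get(gene)
        if cat is None:
            continue
        tallies.setdefault(bin_label(q), Counter())[cat] += 1
        overall[cat] += 1
    if not overall:
        raise ValueError("no classified proteins with computable first-window charge")

    rows = []
    for label in bin_order:
        counter = tallies.get(label)
        if counter is None:
            continue  # empty bin: missing row, never zeros
        total = sum(counter.values())
        row = {"bin": label, "n": total}
        for cat in CATEGORIES:
            row[cat] = 100.0 * counter.get(cat, 0) / total
        rows.append(row)
    table_df = pd.DataFrame(rows, columns=["bin", "n", *CATEGORIES])
    total_all = sum(overall.values())
    baseline = pd.Series(
        {cat: 100.0 * overall.get(cat, 0) / total_all for cat in CATEGORIES}, name="baseline"
    )
    return table_df, baseline
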