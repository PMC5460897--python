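"""Ribosome occupancy as a function of N-terminal nascent-chain charge.

Starts from per-codon ribosome-profiling read counts (one row per gene,
codon, count; upstream trimming/alignment is out of scope).  Genes with
fewer than half of their codon positions covered are dropped, each
retained gene's profile is normalized to its own mean read count (so a
featureless gene sits at 1.0), genes are grouped by the integer net
charge of their first 30 residues, and per-group metagene curves and
area-under-curve ratios over the first 90 codons (the span during which
the first 30 residues occupy the exit tunnel) are computed against the
charge-0 reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .charge_model import DEFAULT_TABLE, ResidueChargeTable
from .charge_landscape import window_scan
from .proteome_io import ProteinRecord, write_fasta

logger = logging.getLogger(__name__)

DEFAULT_METAGENE_LENGTH = 150
AUC_CODON_RANGE = (0, 90)


@dataclass
class RiboCountProfile:
    """Per-codon read counts of one gene, codon 0 = start codon."""

    gene_id: str
    counts: np.ndarray  # non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind not in "iu":
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError(f"{self.gene_id}: non-integer counts")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError(f"{self.gene_id}: negative counts")

    @property
    def length(self) -> int:
        return len(self.counts)

    @property
    def coverage(self) -> float:
        """Fraction of codon positions with at least one read."""
        return float((self.counts >= 1).mean())


def read_counts(path: str | Path) -> list[RiboCountProfile]:
    """Load per-codon count profiles from a TSV (gene, codon, count).

    Codons run from 0 per gene; missing positions up to each gene's
    maximum listed codon are filled with zeros.  Duplicate (gene, codon)
    rows and negative or fractional counts are errors.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "codon", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.duplicated(subset=["gene", "codon"]).any():
        dup = df[df.duplicated(subset=["gene", "codon"])].iloc[0]
        raise ValueError(f"{path}: duplicate entry for gene {dup['gene']} codon {dup['codon']}")
    counts_arr = df["count"].to_numpy()
    if not np.issubdtype(counts_arr.dtype, np.integer):
        if not np.all(counts_arr == np.floor(counts_arr)):
            raise ValueError(f"{path}: non-integer counts")
    if (counts_arr < 0).any():
        raise ValueError(f"{path}: negative counts")
    profiles = []
    for gene, sub in df.groupby("gene", sort=False):
        length = int(sub["codon"].max()) + 1
        counts = np.zeros(length, dtype=np.int64)
        counts[sub["codon"].to_numpy(dtype=int)] = sub["count"].to_numpy(dtype=np.int64)
        profiles.append(RiboCountProfile(gene_id=str(gene), counts=counts))
    logger.info("%s: read %d gene count profiles", path, len(profiles))
    return profiles


def write_counts(profiles: Iterable[RiboCountProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for codon, count in enumerate(prof.counts):
            rows.append((prof.gene_id, codon, int(count)))
    pd.DataFrame(rows, columns=["gene", "codon", "count"]).to_csv(path, sep="\t", index=False)


def coverage_filter(
    profiles: Sequence[RiboCountProfile], min_covered: float = 0.5
) -> list[RiboCountProfile]:
    """Drop genes with less than ``min_covered`` of positions covered.

    The boundary is inclusive: a gene with exactly 50% coverage is kept
    (the rule eliminates genes strictly below the cutoff).
    """
    kept = [p for p in profiles if p.coverage >= min_covered]
    removed = len(profiles) - len(kept)
    if removed:
        logger.info("coverage_filter: removed %d of %d genes", removed, len(profiles))
    return kept


def normalize_profile(profile: RiboCountProfile, norm: str = "mean") -> np.ndarray:
    """Depth-normalize one gene's profile.

    ``norm="mean"`` (default) divides by the gene's mean count so the
    normalized profile averages exactly 1; ``norm="total"`` divides by
    the total read count instead (the two differ only by the gene length
    factor).
    """
    total = profile.counts.sum()
    if total == 0:
        raise ValueError(f"{profile.gene_id}: zero total reads, cannot normalize")
    if norm == "mean":
        return profile.counts / (total / profile.length)
    if norm == "total":
        return profile.counts / total
    raise ValueError(f"unknown norm: {norm!r}")


# ---------------------------------------------------------------------------
# charge groups


@dataclass(frozen=True)
class ChargeGroupScheme:
    """Ordered first-window-charge categories with a reference category.

    The default mirrors the eight-way split used for the occupancy
    analysis: >=+8 (charges +8..+13), +7, +6, +5, 0, -1, -6 and <=-7
    (charges -7..-15), with 0 as the reference.
    """

    categories: tuple[tuple[str, frozenset[int]], ...] = (
        (">=+8", frozenset(range(8, 14))),
        ("+7", frozenset({7})),
        ("+6", frozenset({6})),
        ("+5", frozenset({5})),
        ("0", frozenset({0})),
        ("-1", frozenset({-1})),
        ("-6", frozenset({-6})),
        ("<=-7", frozenset(range(-15, -6))),
    )
    reference: str = "0"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for _, charges in self.categories:
            if seen & charges:
                raise ValueError("charge categories overlap")
            seen |= charges

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.categories]


DEFAULT_SCHEME = ChargeGroupScheme()


def assign_charge_group(
    nterm_charge: int, scheme: ChargeGroupScheme = DEFAULT_SCHEME
) -> str | None:
    """Category label for a first-window net charge; None if unassigned."""
    for label, charges in scheme.categories:
        if int(nterm_charge) in charges:
            return label
    return None


def group_genes_by_charge(
    records: Sequence[ProteinRecord],
    table: ResidueChargeTable = DEFAULT_TABLE,
    scheme: ChargeGroupScheme = DEFAULT_SCHEME,
    window: int = 30,
) -> dict[str, list[str]]:
    """Map category label -> gene ids, from first-window net charges."""
    groups: dict[str, list[str]] = {label: [] for label in scheme.labels}
    for rec in records:
        if len(rec) < window:
            continue
        q = int(window_scan(rec, table, window).first_window_charge)
        label = assign_charge_group(q, scheme)
        if label is not None:
            groups[label].append(rec.id)
    return {label: ids for label, ids in groups.items() if ids}


# ---------------------------------------------------------------------------
# metagene


@dataclass
class MetageneProfile:
    """Mean normalized read density per codon across a group of genes."""

    group_id: str
    mean: np.ndarray  # codons 0..C
    support: np.ndarray  # genes contributing per codon


def metagene(
    profiles: Sequence[RiboCountProfile],
    group_id: str = "group",
    metagene_length: int = DEFAULT_METAGENE_LENGTH,
    norm: str = "mean",
) -> MetageneProfile:
    """Unweighted mean of normalized profiles at each codon 0..C.

    A gene contributes at codon ``c`` only while ``c`` is within its
    length; support records the number of contributing genes per codon.
    """
    if not profiles:
        raise ValueError("metagene of an empty group")
    n_pos = metagene_length + 1
    sums = np.zeros(n_pos)
    support = np.zeros(n_pos, dtype=int)
    for prof in profiles:
        normed = normalize_profile(prof, norm=norm)
        upto = min(prof.length, n_pos)
        sums[:upto] += normed[:upto]
        support[:upto] += 1
    mean = np.full(n_pos, np.nan)
    nonzero = support > 0
    mean[nonzero] = sums[nonzero] / support[nonzero]
    return MetageneProfile(group_id=group_id, mean=mean, support=support)


def auc_ratio(
    group_curve: np.ndarray,
    reference_curve: np.ndarray,
    codon_range: tuple[int, int] = AUC_CODON_RANGE,
) -> float:
    """Trapezoidal AUC of a group metagene over the reference's, codons 0-90."""
    lo, hi = codon_range
    g = np.asarray(group_curve)[lo : hi + 1]
    r = np.asarray(reference_curve)[lo : hi + 1]
    if len(g) < hi - lo + 1 or len(r) < hi - lo + 1 or np.isnan(g).any() or np.isnan(r).any():
        raise ValueError("curves not fully defined over the AUC codon range")
    ref_area = np.trapezoid(r)
    if ref_area == 0:
        raise ValueError("reference curve has zero area")
    return float(np.trapezoid(g) / ref_area)


def occupancy_analysis(
    records: Sequence[ProteinRecord],
    profiles: Sequence[RiboCountProfile],
    table: ResidueChargeTable = DEFAULT_TABLE,
    scheme: ChargeGroupScheme = DEFAULT_SCHEME,
    metagene_length: int = DEFAULT_METAGENE_LENGTH,
    min_covered: float = 0.5,
    norm: str = "mean",
    extra_groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, MetageneProfile], pd.DataFrame]:
    """Full occupancy pipeline: filter, group by charge, metagene, AUC ratios.

    ``extra_groups`` adds annotation-defined gene sets (e.g. mitochondrial
    proteins) that may overlap the charge categories.  Returns the
    per-group metagene profiles and a tidy table (group, n_genes, auc,
    auc_ratio_vs_reference).
    """
    retained = coverage_filter(profiles, min_covered)
    by_gene = {p.gene_id: p for p in retained}
    groups = group_genes_by_charge(records, table, scheme)
    if extra_groups:
        for label, ids in extra_groups.items():
            groups[label] = list(ids)

    curves: dict[str, MetageneProfile] = {}
    for label, gene_ids in groups.items():
        members = [by_gene[g] for g in gene_ids if g in by_gene]
        if not members:
            logger.warning("occupancy_analysis: no covered genes in group %s", label)
            continue
        curves[label] = metagene(members, group_id=label, metagene_length=metagene_length, norm=norm)

    if scheme.reference not in curves:
        raise ValueError(f"reference group {scheme.reference!r} has no genes after filtering")
    ref = curves[scheme.reference].mean
    rows = []
    for label, curve in curves.items():
        lo, hi = AUC_CODON_RANGE
        rows.append(
            {
                "group": label,
                "n_genes": int(curve.support[0]),
                "auc": float(np.trapezoid(curve.mean[lo : hi + 1])),
                "auc_ratio_vs_reference": auc_ratio(curve.mean, ref),
            }
        )
    order = {label: i for i, label in enumerate(scheme.labels)}
    rows.sort(key=lambda r: order.get(r["group"], len(order)))
    return curves, pd.DataFrame(rows)


def export_nterm_fasta(
    records: Sequence[ProteinRecord], path: str | Path, n: int = 30
) -> int:
    """Write the first ``n`` residues of each long-enough protein as FASTA.

    Returns the number of entries written; shorter proteins are skipped
    with a logged count.
    """
    eligible = [
        ProteinRecord(id=rec.id, sequence=rec.sequence[:n])
        for rec in records
        if len(rec) >= n
    ]
    skipped = len(records) - len(eligible)
    if skipped:
        logger.info("export_nterm_fasta: skipped %d protein(s) shorter than %d", skipped, n)
    write_fasta(eligible, path)
    return len(eligible)
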