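"""End-to-end run orchestration with a manifest of every output.

A run is described by a :class:`RunConfig` (loadable from TOML): input
paths, charge-model settings, which stages to execute, output directory
and seed.  Stages run in dependency order and every file written is
listed in ``manifest.json`` together with the hash of the config that
produced it, so an identical config + seed reproduces identical TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import charge_landscape, ribo_occupancy, synthetic_data, translation_groups
from .charge_model import ResidueChargeTable
from .proteome_io import read_fasta, write_fasta

logger = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "stats", "heatmap", "supercharged", "ribo", "mp")

#: Stages that need a proteome (from `fasta` input or the simulate stage).
_NEEDS_PROTEOME = {"scan", "stats", "heatmap", "supercharged", "ribo", "mp"}


@dataclass
class RunConfig:
    out_dir: str
    stages: tuple[str, ...] = ("scan", "stats")
    fasta: str | None = None
    counts: str | None = None
    mp_table: str | None = None
    seed: int = 0
    n_proteins: int = 1000
    ph: float = 7.4
    his_mode: str = "zero"
    rounding: str = "integer"
    include_termini: bool = False
    window: int = 30
    supercharge_threshold: float = 14.0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def table(self) -> ResidueChargeTable:
        return ResidueChargeTable(
            ph=self.ph,
            his_mode=self.his_mode,  # type: ignore[arg-type]
            rounding=self.rounding,  # type: ignore[arg-type]
            include_termini=self.include_termini,
        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, outputs: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    outputs.append(path)


def run(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the manifest.

    Raises when a requested stage is missing its input and the stage
    that would produce it was not requested.
    """
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage: {stage!r}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    table = config.table()

    records = None
    if "simulate" in config.stages:
        spec = synthetic_data.ProteomeGenSpec(
            n_proteins=config.n_proteins, seed=config.seed, window=config.window
        )
        records, truth = synthetic_data.gen_proteome(spec)
        fasta_path = out_dir / "proteome.fasta"
        write_fasta(records, fasta_path)
        outputs.append(fasta_path)
        _write_tsv(truth, out_dir / "proteome_truth.tsv", outputs)
    elif config.fasta is not None:
        records = read_fasta(config.fasta)

    needed = _NEEDS_PROTEOME & set(config.stages)
    if needed and records is None:
        raise ValueError(
            f"stage(s) {sorted(needed)} need a proteome: provide `fasta` or request the "
            "`simulate` stage"
        )

    profiles = None
    if {"scan", "stats", "heatmap", "supercharged"} & set(config.stages):
        profiles = charge_landscape.scan_proteome(records, table, config.window)

    if "scan" in config.stages:
        rows = [
            {"protein": p.protein_id, "start": i + 1, "net_charge": p.window_charges[i]}
            for p in profiles
            for i in range(p.n_windows)
        ]
        _write_tsv(
            pd.DataFrame(rows, columns=["protein", "start", "net_charge"]),
            out_dir / "window_charges.tsv",
            outputs,
        )

    if "stats" in config.stages:
        all_charges = np.concatenate([p.window_charges for p in profiles])
        fractions = charge_landscape.sign_fractions(all_charges)
        hist = charge_landscape.charge_histogram(all_charges)
        _write_tsv(
            pd.DataFrame(sorted(hist.items()), columns=["net_charge", "count"]),
            out_dir / "charge_histogram.tsv",
            outputs,
        )
        curve = charge_landscape.neg_pos_ratio_curve(hist)
        _write_tsv(
            pd.DataFrame(
                [(q, "" if r is None else r) for q, r in curve.items()],
                columns=["magnitude", "neg_pos_ratio"],
            ),
            out_dir / "neg_pos_ratio.tsv",
            outputs,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {"sign": "positive", "fraction": fractions.positive},
                    {"sign": "neutral", "fraction": fractions.neutral},
                    {"sign": "negative", "fraction": fractions.negative},
                ]
            ),
            out_dir / "sign_fractions.tsv",
            outputs,
        )

    if "heatmap" in config.stages:
        frames = [
            charge_landscape.heatmap_matrix(profiles, region).to_frame()
            for region in ("nterm", "core", "cterm")
        ]
        _write_tsv(pd.concat(frames, ignore_index=True), out_dir / "heatmap.tsv", outputs)

    if "supercharged" in config.stages:
        stretches = charge_landscape.find_supercharged_proteome(
            profiles, config.supercharge_threshold
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "protein": s.protein_id,
                        "sign": s.sign,
                        "start": s.start,
                        "end": s.end,
                        "peak_charge": s.peak_charge,
                        "truncated": s.truncated,
                    }
                    for s in stretches
                ],
                columns=["protein", "sign", "start", "end", "peak_charge", "truncated"],
            ),
            out_dir / "supercharged.tsv",
            outputs,
        )
        fasta_path = out_dir / "supercharged_context.fasta"
        with open(fasta_path, "w") as fh:
            for s in stretches:
                fh.write(f">{s.protein_id}|start={s.start}|peak={s.peak_charge:g}\n{s.context}\n")
        outputs.append(fasta_path)

    if "ribo" in config.stages:
        if config.counts is not None:
            count_profiles = ribo_occupancy.read_counts(config.counts)
        elif "simulate" in config.stages:
            count_profiles, expectation = synthetic_data.gen_ribo_counts(
                records, synthetic_data.RiboGenSpec(seed=config.seed), table
            )
            ribo_occupancy.write_counts(count_profiles, out_dir / "ribo_counts.tsv")
            outputs.append(out_dir / "ribo_counts.tsv")
            _write_tsv(expectation, out_dir / "ribo_expectation.tsv", outputs)
        else:
            raise ValueError("ribo stage needs `counts` or the `simulate` stage")
        curves, auc_table = ribo_occupancy.occupancy_analysis(records, count_profiles, table)
        meta_rows = [
            {"group": label, "codon": c, "mean": curve.mean[c], "support": int(curve.support[c])}
            for label, curve in curves.items()
            for c in range(len(curve.mean))
            if curve.support[c] > 0
        ]
        _write_tsv(
            pd.DataFrame(meta_rows, columns=["group", "codon", "mean", "support"]),
            out_dir / "metagene.tsv",
            outputs,
        )
        _write_tsv(auc_table, out_dir / "auc_ratios.tsv", outputs)

    if "mp" in config.stages:
        if config.mp_table is not None:
            scores = pd.read_csv(config.mp_table, sep="\t")
        elif "simulate" in config.stages:
            scores = synthetic_data.gen_mp_scores(records, seed=config.seed)
            _write_tsv(scores, out_dir / "mp_scores.tsv", outputs)
        else:
            raise ValueError("mp stage needs `mp_table` or the `simulate` stage")
        by_id = {r.id: r for r in records}
        for row in scores.itertuples(index=False):
            rec = by_id.get(row.accession)
            if rec is None:
                continue
            if hasattr(row, "orf_length_nt"):
                rec.orf_length_nt = int(row.orf_length_nt)
            if hasattr(row, "mp_score"):
                rec.mp_score = float(row.mp_score)
            if hasattr(row, "mp_label") and isinstance(getattr(row, "mp_label"), str):
                rec.mp_label = row.mp_label
        classification = translation_groups.classify_mp(records)
        _write_tsv(
            translation_groups.group_segment_means(records, classification, table),
            out_dir / "mp_segment_means.tsv",
            outputs,
        )
        bins, baseline = translation_groups.charge_bin_group_percentages(
            records, classification, table
        )
        _write_tsv(bins, out_dir / "mp_charge_bins.tsv", outputs)
        _write_tsv(
            baseline.rename_axis("category").reset_index(name="percent"),
            out_dir / "mp_baseline.tsv",
            outputs,
        )

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": sorted(str(p.relative_to(out_dir)) for p in outputs),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run complete: %d outputs in %s", len(outputs), out_dir)
    return manifest
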