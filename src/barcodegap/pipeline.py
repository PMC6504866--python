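"""End-to-end orchestration of the library-curation analysis.

One configured run executes: length filter -> crop -> haplotype collapse ->
distance matrix -> misidentification screen -> per-species summaries ->
delimitation (internal barcode-gap scan plus any ingested external
partitions) -> congruence classification -> sampling-effort regression.
Every stage writes its table to the output directory and a JSON manifest
records the seed, input hashes and the sequence counts at each stage, so a
rerun with the same configuration reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import yaml

from . import __version__
from .congruence import classify_all, congruence_table, method_consensus_score
from .delimitation import DEFAULT_PRIOR_GRID, DEFAULT_X_VALUES, abgd_scan, scan_summary
from .distances import (
    distance_matrix,
    high_intraspecific_species,
    low_interspecific_pairs,
    species_summaries,
)
from .haplotypes import collapse_haplotypes
from .io_formats import (
    Alignment,
    TaxonLabel,
    apply_length_filter,
    crop_alignment,
    read_alignment,
    read_partition,
    species_labels,
    write_alignment,
    write_partition,
)
from .misid_screen import (
    flag_misidentifications,
    read_corrections,
    write_corrections_template,
    write_flags,
)
from .regression_summary import delimitation_points, ols_fit

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    fasta: str
    outdir: str
    partitions: list[str] = field(default_factory=list)
    corrections: str | None = None
    model: str = "K2P"
    min_bp: int = 486
    allowlist: list[str] = field(default_factory=list)
    crop: tuple[int, int] | None = None  # (start_col, width)
    run_abgd: bool = True
    abgd_priors: list[float] = field(default_factory=lambda: list(DEFAULT_PRIOR_GRID))
    abgd_x_values: list[float] = field(default_factory=lambda: list(DEFAULT_X_VALUES))
    t_self: float = 0.05
    t_other: float = 0.02
    exclude_flagged: bool = True
    low_inter_cutoff: float = 0.03
    high_intra_cutoff: float = 0.02
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "crop" in raw and raw["crop"] is not None:
            raw["crop"] = tuple(raw["crop"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _apply_corrections(aln: Alignment, corrections: dict[str, str]) -> Alignment:
    records = []
    for r in aln:
        if r.id in corrections:
            parts = corrections[r.id].split(None, 1)
            label = TaxonLabel(parts[0], parts[1] if len(parts) > 1 else "")
            records.append(dc_replace(r, label=label))
        else:
            records.append(r)
    return Alignment(records)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to outdir)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "model": cfg.model,
        "inputs": {},
        "counts": counts,
    }

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # keep partial outputs, report the stage
            raise PipelineError(name, exc) from exc

    if not cfg.partitions and not cfg.run_abgd:
        raise PipelineError("delimitation", ValueError("no delimitation source"))

    aln = stage("read", read_alignment, cfg.fasta)
    manifest["inputs"][str(cfg.fasta)] = _sha256(cfg.fasta)
    counts["input"] = len(aln)

    if cfg.corrections:
        corrections = stage("corrections", read_corrections, cfg.corrections)
        manifest["inputs"][str(cfg.corrections)] = _sha256(cfg.corrections)
        aln = stage("corrections", _apply_corrections, aln, corrections)

    aln = stage("length_filter", apply_length_filter, aln, cfg.min_bp, set(cfg.allowlist))
    counts["post_filter"] = len(aln)
    if cfg.crop:
        aln = stage("crop", crop_alignment, aln, cfg.crop[0], cfg.crop[1])

    haps, hmap = stage("collapse", collapse_haplotypes, aln)
    counts["haplotypes"] = len(haps)
    hmap.write(out / "haplotype_map.tsv")
    write_alignment(haps, out / "haplotypes.fasta")

    m = stage("distances", distance_matrix, haps, cfg.model)
    m.write_phylip(out / "distance_matrix.phy")
    counts["undefined_pairs"] = m.n_undefined_pairs

    labels = species_labels(haps)
    flags = stage("misid_screen", flag_misidentifications, m, labels, cfg.t_self, cfg.t_other)
    counts["flagged"] = len(flags)
    write_flags(flags, out / "misid_flags.tsv")
    write_corrections_template(flags, out / "corrections_template.tsv")
    flagged_ids = {f.id for f in flags} if cfg.exclude_flagged else set()

    summaries = stage("summaries", species_summaries, m, labels, flagged_ids)
    _write_summaries(summaries, out / "species_summaries.tsv")
    low_interspecific_pairs(summaries, cfg.low_inter_cutoff).to_csv(
        out / "low_interspecific_pairs.tsv", sep="\t", index=False
    )
    high_intraspecific_species(summaries, cfg.high_intra_cutoff).to_csv(
        out / "high_intraspecific_species.tsv", sep="\t", index=False
    )

    partitions = []
    if cfg.run_abgd:
        partitions.extend(
            stage(
                "delimitation",
                abgd_scan,
                m,
                tuple(cfg.abgd_priors),
                tuple(cfg.abgd_x_values),
            )
        )
        scan_summary(partitions).to_csv(out / "abgd_scan.tsv", sep="\t", index=False)
    for p_path in cfg.partitions:
        p = stage("ingest_partitions", read_partition, p_path)
        manifest["inputs"][str(p_path)] = _sha256(p_path)
        partitions.append(p)
    for i, p in enumerate(partitions):
        write_partition(p, out / f"partition_{i:02d}.tsv")
    counts["partitions"] = len(partitions)

    class_labels = {
        seq_id: (None if seq_id in flagged_ids else sp) for seq_id, sp in labels.items()
    }
    table = stage("congruence", congruence_table, partitions, class_labels)
    table.to_csv(out / "congruence_table.tsv", sep="\t", index=False)
    if len(partitions) >= 3:
        scores = stage("congruence", method_consensus_score, partitions, class_labels)
        with open(out / "consensus_scores.tsv", "w") as fh:
            fh.write("method\tdisagreements\n")
            for method, score in scores.items():
                fh.write(f"{method}\t{score}\n")

    regression_rows = []
    for p in partitions:
        classification = classify_all(p, class_labels)
        try:
            points = delimitation_points(p, class_labels, classification, hmap)
            fit = ols_fit(points)
        except ValueError as exc:
            logger.info("regression skipped for %s: %s", p.name, exc)
            continue
        regression_rows.append(
            {
                "method": p.name,
                "df": f"{fit.df[0]},{fit.df[1]}",
                "F": fit.F,
                "p_value": fit.p_value,
                "r_squared": fit.r_squared,
                "mean_samples": fit.mean_x,
                "se_mean_samples": fit.se_mean_x,
            }
        )
    if regression_rows:
        import pandas as pd

        pd.DataFrame(regression_rows).to_csv(
            out / "sampling_regression.tsv", sep="\t", index=False
        )
    counts["regressions"] = len(regression_rows)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_summaries(summaries, path) -> None:
    def fmt(v):
        return "" if v is None else (f"{v:.6f}" if isinstance(v, float) else str(v))

    with open(path, "w") as fh:
        fh.write(
            "species\tn\tmax_intra\tmean_intra\tnearest_species\tmin_inter\n"
        )
        for s in summaries:
            fh.write(
                "\t".join(
                    [
                        s.species,
                        str(s.n),
                        fmt(s.max_intra),
                        fmt(s.mean_intra),
                        s.nearest_species or "",
                        fmt(s.min_inter),
                    ]
                )
                + "\n"
            )
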