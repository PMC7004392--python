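"""End-to-end pipeline: ingest -> LCD calling -> profiles -> regressions ->
enrichment, with a reproducibility manifest.

Each stage writes one or more TSVs whose first line is a comment naming the
producing version and the configuration hash; the manifest records the config
hash, input file hashes, per-stage row counts and accumulated warnings.
Nothing in the outputs carries a timestamp, so a rerun with identical inputs
and configuration reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .complexity import (
    ComplexityParams,
    call_lcds,
    proteome_lcd_summary,
    residue_fraction_in_lcds,
)
from .composition import (
    DEFAULT_WIDTHS,
    bin_profiles,
    composition_frequency_table,
    lcd_class_ss_profile,
    subsidiary_composition,
)
from .core import AMINO_ACIDS, AnnotatedChain, CategoryMap
from .enrichment import annotation_enrichment, top_enriched
from .propensity import (
    InsufficientDataError,
    correlation_matrix,
    dose_residuals,
    fit_scale_regression,
    observed_fraction_table,
    residual_summary,
)
from . import io as io_formats

logger = logging.getLogger("lcdstruct")

STAGES = ("lcd", "scan", "profile", "propensity", "enrich")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    annotation_file: str
    out_dir: str
    cluster_file: str | None = None
    annotation_map: str | None = None
    scale_dir: str | None = None
    tag_table: str | None = None
    exclusion_list: str | None = None
    window_length: int = 12
    entropy_threshold: float = 2.2
    widths: tuple[int, ...] = DEFAULT_WIDTHS
    min_fraction: float = 0.5
    min_count: int = 50
    alpha: float = 0.05
    top_k: int = 10
    exclude_opposite_charges: bool = False
    nonlcd_mode: str = "window"
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "widths" in data:
            data["widths"] = tuple(data["widths"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def validate(self) -> None:
        for key in ("annotation_file", "cluster_file", "annotation_map",
                    "scale_dir", "tag_table", "exclusion_list"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")
        if "propensity" in self.stages and self.scale_dir is None:
            raise ValueError("propensity stage enabled but no scale_dir given")
        if "enrich" in self.stages and self.annotation_map is None:
            raise ValueError("enrich stage enabled but no annotation_map given")
        if self.nonlcd_mode not in ("window", "residue"):
            raise ValueError("nonlcd_mode must be 'window' or 'residue'")
        ComplexityParams(self.window_length, self.entropy_threshold)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land must not change their bytes
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()[:16]


class _TsvWriter:
    def __init__(self, out_dir: Path, config_hash: str):
        self.out_dir = out_dir
        self.header = (
            f"# lcdstruct {__version__} config={config_hash}; "
            "coordinates 0-based half-open\n"
        )
        self.row_counts: dict[str, int] = {}

    def write(self, name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = self.out_dir / name
        with open(path, "w") as fh:
            fh.write(self.header)
            frame.to_csv(fh, sep="\t", index=index, na_rep="NA")
        self.row_counts[name] = len(frame)


def load_chains(config: RunConfig) -> list[AnnotatedChain]:
    """Apply the full curation path: read, represent, trim, exclude."""
    chains = io_formats.read_annotated_chains(config.annotation_file)
    if config.cluster_file:
        clusters = io_formats.read_cluster_file(config.cluster_file)
        chains = io_formats.select_representatives(chains, clusters)
    tags = (
        io_formats.read_tag_table(config.tag_table)
        if config.tag_table
        else io_formats.TagTable()
    )
    trimmed = []
    for chain in chains:
        out = io_formats.trim_terminal_tags(chain, tags)
        if out is not None:
            trimmed.append(out)
    chains = trimmed
    if config.exclusion_list:
        excluded = io_formats.read_exclusion_list(config.exclusion_list)
        chains = io_formats.apply_exclusions(chains, excluded)
    return chains


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; returns the manifest (also written to disk).

    On stage failure the manifest records the failed stage and the error;
    outputs of earlier stages are retained, and the exception propagates.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    writer = _TsvWriter(out_dir, chash)
    manifest: dict = {
        "version": __version__,
        "config_hash": chash,
        "config": asdict(config),
        "input_hashes": {},
        "stages_completed": [],
        "failed_stage": None,
        "row_counts": writer.row_counts,
        "warnings": [],
        "notes": [
            "enrichment reference includes the LCD chains themselves "
            "(subset-vs-full comparison, as defined)",
        ],
    }
    for key in ("annotation_file", "cluster_file", "annotation_map",
                "tag_table", "exclusion_list"):
        path = getattr(config, key)
        if path:
            manifest["input_hashes"][key] = _file_hash(path)

    params = ComplexityParams(config.window_length, config.entropy_threshold)
    cmap = CategoryMap.default()
    chains = load_chains(config)
    manifest["n_chains"] = len(chains)
    try:
        for stage in config.stages:
            _run_stage(stage, config, params, cmap, chains, writer, manifest)
            manifest["stages_completed"].append(stage)
    except Exception as err:
        manifest["failed_stage"] = {"stage": stage, "error": str(err)}
        _write_manifest(manifest, out_dir)
        raise
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def _run_stage(
    stage: str,
    config: RunConfig,
    params: ComplexityParams,
    cmap: CategoryMap,
    chains: Sequence[AnnotatedChain],
    writer: _TsvWriter,
    manifest: dict,
) -> None:
    if stage == "lcd":
        rows = [
            {
                "chain_id": s.chain_id, "start": s.start, "end": s.end,
                "entropy": s.entropy, "types": "".join(sorted(s.types)),
                "ambiguous": s.ambiguous,
            }
            for chain in chains
            for s in call_lcds(chain, params)
        ]
        writer.write("lcd_segments.tsv", pd.DataFrame(
            rows, columns=["chain_id", "start", "end", "entropy", "types", "ambiguous"]
        ))
        summary = proteome_lcd_summary(chains, params)
        writer.write("lcd_summary.tsv", summary.per_type, index=True)
        writer.write("lcd_group_summary.tsv", summary.per_group, index=True)
        coverage = residue_fraction_in_lcds(chains, params)
        writer.write(
            "residue_coverage.tsv",
            pd.DataFrame(
                {"amino_acid": list(coverage), "pct_in_lcds": list(coverage.values())}
            ),
        )
    elif stage == "scan":
        writer.write(
            "composition_frequencies.tsv",
            composition_frequency_table(chains, config.widths),
        )
    elif stage == "profile":
        frames = []
        for aa in AMINO_ACIDS:
            prof = bin_profiles(
                chains, aa, config.window_length,
                config.exclude_opposite_charges, cmap,
            )
            t = prof.table.reset_index()
            t.insert(0, "amino_acid", aa)
            frames.append(t)
        writer.write("bin_profiles.tsv", pd.concat(frames, ignore_index=True))
        writer.write(
            "lcd_class_profile.tsv", lcd_class_ss_profile(chains, params, cmap),
            index=True,
        )
        writer.write(
            "subsidiary_composition.tsv",
            subsidiary_composition(chains, config.window_length, config.min_fraction),
            index=True,
        )
    elif stage == "propensity":
        scales = io_formats.read_propensity_scales(config.scale_dir)
        obs = observed_fraction_table(
            chains, config.window_length, config.min_fraction, cmap,
            config.nonlcd_mode,
        )
        writer.write("observed_fractions.tsv", obs)
        reg_rows, resid_rows, series = [], [], {}
        for kind, col in (("helix", "f_alpha_helix"), ("sheet", "f_beta_sheet")):
            kind_scales = [s for s in scales if s.kind == kind]
            for context in ("enriched_lcd", "non_lcd"):
                sub = obs[obs["context"] == context]
                observed = dict(zip(sub["amino_acid"], sub[col]))
                counts = dict(zip(sub["amino_acid"], sub["n"]))
                use_counts = counts if context == "enriched_lcd" else None
                series[f"{kind}:{context}"] = observed
                for scale in kind_scales:
                    series[f"{kind}:scale:{scale.name}"] = scale.oriented_values()
                    try:
                        res = fit_scale_regression(
                            observed, scale, config.min_count, use_counts
                        )
                    except InsufficientDataError as err:
                        manifest["warnings"].append(str(err))
                        continue
                    reg_rows.append(
                        {
                            "kind": kind, "context": context,
                            "scale": scale.name, "slope": res.slope,
                            "intercept": res.intercept, "pearson_r": res.pearson_r,
                            "n_points": len(res.included),
                        }
                    )
                    for aa, r in res.residuals.items():
                        resid_rows.append(
                            {
                                "kind": kind, "context": context,
                                "scale": scale.name, "amino_acid": aa,
                                "residual": r,
                            }
                        )
        writer.write("regressions.tsv", pd.DataFrame(
            reg_rows, columns=["kind", "context", "scale", "slope", "intercept",
                               "pearson_r", "n_points"]
        ))
        writer.write("residuals.tsv", pd.DataFrame(
            resid_rows, columns=["kind", "context", "scale", "amino_acid", "residual"]
        ))
        corr_frames = []
        for kind in ("helix", "sheet"):
            members = {
                name.split(":", 1)[1]: vals
                for name, vals in series.items()
                if name.startswith(f"{kind}:")
            }
            if len(members) >= 2:
                mat = correlation_matrix(members)
                mat = mat.reset_index(names="name")
                mat.insert(0, "kind", kind)
                corr_frames.append(mat)
        if corr_frames:
            writer.write(
                "correlation_matrix.tsv",
                pd.concat(corr_frames, ignore_index=True),
            )
        dose_frames = []
        for kind in ("helix", "sheet"):
            kind_scales = [s for s in scales if s.kind == kind]
            if not kind_scales:
                continue
            d = dose_residuals(
                chains, kind_scales, kind, config.window_length,
                config.min_count, cmap,
            )
            d.insert(0, "kind", kind)
            dose_frames.append(d)
        if dose_frames:
            writer.write("dose_residuals.tsv", pd.concat(dose_frames, ignore_index=True))
    elif stage == "enrich":
        annmap = io_formats.read_annotation_map(config.annotation_map)
        by_type: dict[str, set[str]] = {}
        for chain in chains:
            for seg in call_lcds(chain, params):
                for aa in seg.types:
                    by_type.setdefault(aa, set()).add(chain.chain_id)
        records = annotation_enrichment(
            by_type, annmap, [c.chain_id for c in chains]
        )
        writer.write("enrichment.tsv", records)
        writer.write(
            "top_enriched.tsv", top_enriched(records, config.top_k, config.alpha)
        )
    else:
        raise ValueError(f"unknown stage {stage!r}")
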