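"""File I/O, run configuration and the umbrella pipeline.

All tabular data uses a single dialect: tab-separated, header row, '.'
decimal separator, UTF-8, empty cell = missing.  Writers and readers are
paired so every emitted table round-trips losslessly for its declared
columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .codon_scan import (
    CodingRegion,
    NUCLEOTIDES,
    consequence_counts,
    enumerate_snvs,
    snv_frame,
)
from .mito_morphometry import SizeSample
from .organ_function import EyeMeasure, GeotaxisTrial, HeartTrace
from .variant_scoring import (
    ClassifierThresholds,
    classify_pp2,
    classify_sift,
    position_damage_profile,
    variant_flagged_damaging,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_score_table",
    "read_size_table",
    "read_trace_table",
    "read_geotaxis_table",
    "read_eye_table",
    "write_table",
    "RunConfig",
    "load_config",
    "classification_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["residue_number", "ref_aa", "alt_aa", "sift_score", "pp2_score"]


def read_fasta(path: str | Path, first_residue_number: int = 1) -> CodingRegion:
    """Read a single-record FASTA file into a validated coding region.

    Lowercase input is uppercased; the record id becomes the region name.
    A multi-record file or a non-ACGT character is rejected with a message
    naming, respectively, the record count or the offending position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly 1 FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    for i, nt in enumerate(seq):
        if nt not in NUCLEOTIDES:
            raise ValueError(f"{path}: non-ACGT character {nt!r} at position {i + 1}")
    return CodingRegion(
        name=records[0].id, sequence=seq, first_residue_number=first_residue_number
    )


def write_fasta(region: CodingRegion, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{region.name} first_residue={region.first_residue_number}\n")
        for i in range(0, len(region.sequence), 60):
            fh.write(region.sequence[i : i + 60] + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame in the package's TSV dialect."""
    df.to_csv(path, sep="\t", index=False)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Per-variant predictor scores; validates ranges and key uniqueness."""
    df = _read_tsv(path, SCORE_COLUMNS)
    for col in ("sift_score", "pp2_score"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} values outside [0, 1]")
    keys = df[["residue_number", "ref_aa", "alt_aa"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        raise ValueError(f"{path}: duplicate (residue_number, ref_aa, alt_aa) rows")
    return df


def read_size_table(path: str | Path) -> dict[str, SizeSample]:
    """Diameter table (group, diameter_um) -> one SizeSample per group."""
    df = _read_tsv(path, ["group", "diameter_um"])
    return {
        g: SizeSample(group=g, diameters=sub["diameter_um"].to_numpy())
        for g, sub in df.groupby("group", sort=True)
    }


def read_trace_table(path: str | Path) -> HeartTrace:
    df = _read_tsv(path, ["time_s", "diameter_um"])
    return HeartTrace(
        times=df["time_s"].to_numpy(), diameters=df["diameter_um"].to_numpy()
    )


def read_geotaxis_table(path: str | Path) -> list[GeotaxisTrial]:
    df = _read_tsv(path, ["genotype", "day", "session", "n_climbed", "n_total"])
    return [
        GeotaxisTrial(
            genotype=str(r.genotype),
            day=int(r.day),
            session=int(r.session),
            n_climbed=int(r.n_climbed),
            n_total=int(r.n_total),
        )
        for r in df.itertuples()
    ]


def read_eye_table(path: str | Path) -> list[EyeMeasure]:
    df = _read_tsv(path, ["genotype", "vertical_um", "horizontal_um"])
    return [
        EyeMeasure(
            genotype=str(r.genotype),
            vertical_um=float(r.vertical_um),
            horizontal_um=float(r.horizontal_um),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for the bioinformatic scan workflow.

    Paths must exist at run start; thresholds default to the published
    cut-points.  Unknown config-file keys are rejected.
    """

    fasta: str = ""
    scores: str = ""
    out_dir: str = "results"
    first_residue_number: int = 1
    sift_damaging_gt: float = 0.95
    pp2_probably_gt: float = 0.85
    pp2_benign_lt: float = 0.15
    missing_policy: str = "permissive"
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = ("scan", "classify", "profile")

    def thresholds(self) -> ClassifierThresholds:
        return ClassifierThresholds(
            sift_damaging_gt=self.sift_damaging_gt,
            pp2_probably_gt=self.pp2_probably_gt,
            pp2_benign_lt=self.pp2_benign_lt,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key/value YAML config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def classification_table(
    scores: pd.DataFrame, thresholds: ClassifierThresholds
) -> pd.DataFrame:
    """Annotate a score table with predictor labels and the damaging flag."""
    out = scores.copy()
    out["sift_pred"] = [classify_sift(s, thresholds) for s in out["sift_score"]]
    out["pp2_pred"] = [classify_pp2(s, thresholds) for s in out["pp2_score"]]
    out["flagged_damaging"] = [
        variant_flagged_damaging(s, p, thresholds)
        for s, p in zip(out["sift_score"], out["pp2_score"])
    ]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested scan/classify/profile stages and write result TSVs.

    Emits one TSV per stage plus ``manifest.json`` recording inputs,
    parameters, seed and package version — enough to re-execute the run
    identically.  Identical config and inputs give byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    needs_fasta = {"scan", "profile"} & set(config.stages)
    needs_scores = {"classify", "profile"} & set(config.stages)
    if needs_fasta and not Path(config.fasta).is_file():
        raise FileNotFoundError(f"FASTA input not found: {config.fasta!r}")
    if needs_scores and not Path(config.scores).is_file():
        raise FileNotFoundError(f"score table not found: {config.scores!r}")

    thresholds = config.thresholds()
    outputs: dict[str, str] = {}
    region = (
        read_fasta(config.fasta, config.first_residue_number) if needs_fasta else None
    )
    scores = read_score_table(config.scores) if needs_scores else None

    for stage in config.stages:
        if stage == "scan":
            snvs = enumerate_snvs(region)
            counts = consequence_counts(region)
            logger.info(
                "stage=scan codons=%d snvs=%d nonsynonymous=%d",
                region.n_codons,
                len(snvs),
                counts["nonsynonymous_total"],
            )
            path = out_dir / "snvs.tsv"
            write_table(snv_frame(snvs), path)
        elif stage == "classify":
            logger.info("stage=classify variants=%d", len(scores))
            path = out_dir / "classified.tsv"
            write_table(classification_table(scores, thresholds), path)
        elif stage == "profile":
            profile = position_damage_profile(
                region, scores, thresholds, config.missing_policy
            )
            logger.info("stage=profile residues=%d", len(profile))
            path = out_dir / "profile.tsv"
            write_table(profile.reset_index(), path)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        outputs[stage] = str(path)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "inputs": {"fasta": config.fasta, "scores": config.scores},
        "first_residue_number": config.first_residue_number,
        "thresholds": {
            "sift_damaging_gt": thresholds.sift_damaging_gt,
            "pp2_probably_gt": thresholds.pp2_probably_gt,
            "pp2_benign_lt": thresholds.pp2_benign_lt,
        },
        "missing_policy": config.missing_policy,
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
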