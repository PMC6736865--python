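"""File formats, run configuration, and end-to-end orchestration.

Formats: trait tables are UTF-8 comma-separated CSV with fixed leading
columns ``accession_id, species`` followed by numeric trait columns;
alignments are uncompressed aligned FASTA; reports are TSV with floats
printed to four decimals; provenance and truth blocks are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from melcore import __version__, coreeval, coreselect, seqdiv, traitstats
from melcore.containers import CoreSet, TraitMatrix
from melcore.errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.4f"


def read_trait_csv(path) -> tuple[TraitMatrix, pd.DataFrame]:
    """Load and validate a trait CSV.

    Returns the matrix and a (possibly empty) frame of rejected rows.
    Rows with missing trait values are rejected individually and
    reported; duplicate accession IDs or non-numeric cells abort the
    load with a :class:`FormatError` naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"accession_id": str, "species": str})
    required = ["accession_id", "species"]
    if list(df.columns[:2]) != required:
        raise FormatError(
            f"{path}: first two columns must be {required}, got {list(df.columns[:2])}"
        )
    trait_cols = list(df.columns[2:])
    if not trait_cols:
        raise FormatError(f"{path}: no trait columns")
    dupes = df["accession_id"][df["accession_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate accession_id values: {sorted(set(dupes))}")
    for col in trait_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"at row {row + 2}, column {col!r}"
            )
        df[col] = coerced
    missing_mask = df[trait_cols].isna().any(axis=1)
    rejected = df[missing_mask].copy()
    for _, r in rejected.iterrows():
        logger.warning(
            "row rejected (missing trait value): accession_id=%s", r["accession_id"]
        )
    kept = df[~missing_mask]
    df["species"] = df["species"].str.strip()
    tm = TraitMatrix(
        kept["accession_id"].tolist(),
        kept["species"].str.strip().tolist(),
        kept[trait_cols].to_numpy(dtype=float),
        trait_cols,
    )
    return tm, rejected


def write_trait_csv(tm: TraitMatrix, path) -> None:
    tm.to_frame().to_csv(path, index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_core_set(core: CoreSet, path) -> None:
    """One accession ID per line plus a JSON provenance sidecar."""
    path = Path(path)
    path.write_text("\n".join(core.accession_ids) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(core), indent=2) + "\n")


def read_core_set(path) -> CoreSet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    ids = [l for l in path.read_text().splitlines() if l.strip()]
    if ids != meta["accession_ids"]:
        raise FormatError(f"{path}: ID list and provenance sidecar disagree")
    return CoreSet(**meta)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    trait_csv: str
    alignments: dict[str, str] = field(default_factory=dict)  # locus -> FASTA path
    species_filter: list[str] | None = None
    proportions: list[float] = field(
        default_factory=lambda: [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
    )
    strategies: list[str] = field(default_factory=lambda: ["random", "preferred"])
    seed: int = 0
    n_classes: int = 10
    alpha: float = 0.05
    traits_select: list[str] | None = None
    traits_eval: list[str] | None = None
    out_dir: str = "melcore_out"

    def validated(self) -> "RunConfig":
        if not all(0 < p <= 1 for p in self.proportions):
            raise ParameterError(f"proportions must lie in (0, 1]: {self.proportions}")
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must lie in (0, 1): {self.alpha}")
        if not Path(self.trait_csv).exists():
            raise ParameterError(f"trait CSV not found: {self.trait_csv}")
        for locus, p in self.alignments.items():
            if not Path(p).exists():
                raise ParameterError(f"alignment for {locus} not found: {p}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full diversity-and-core analysis, writing reports.

    Stages: load traits and alignments; per-collection trait summary;
    per-species sequence diversity; core construction for each species
    under each strategy and proportion; evaluation tables shaped like
    the usual core-collection reports (trait-difference percentages and
    a diversity comparison). Deterministic under a fixed seed.
    """
    cfg = cfg.validated()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("melcore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("melcore %s | seed=%d | config=%s", __version__, cfg.seed, cfg.digest())
        logger.info("config: %s", json.dumps(dataclasses.asdict(cfg), sort_keys=True))

        logger.info("stage: load traits")
        tm, rejected = read_trait_csv(cfg.trait_csv)
        if len(rejected):
            logger.warning("partial load: %d rows rejected", len(rejected))
        alignments = {
            locus: seqdiv.read_alignment(p, locus_name=locus)
            for locus, p in cfg.alignments.items()
        }

        logger.info("stage: trait summary")
        summary = traitstats.trait_summary(tm, n_classes=cfg.n_classes)
        write_tsv(summary["per_species"], out / "trait_summary.tsv")
        write_tsv(summary["per_trait"], out / "trait_diversity.tsv")

        logger.info("stage: sequence diversity by species")
        div_rows = []
        for sp in tm.species_labels:
            ids = [a for a, s in zip(tm.accession_ids, tm.species) if s == sp]
            for locus, aln in alignments.items():
                present = [a for a in ids if a in set(aln.accession_ids)]
                if len(present) < 2:
                    continue
                sub = aln.subset(present)
                hs = seqdiv.haplotype_spectrum(sub)
                div_rows.append(
                    dict(species=sp, locus=locus, n=len(present),
                         n_haplotypes=hs.n_haplotypes,
                         hd=seqdiv.haplotype_diversity(hs),
                         pi=seqdiv.nucleotide_diversity(sub))
                )
        write_tsv(pd.DataFrame(div_rows), out / "diversity_by_species.tsv")

        core_species = cfg.species_filter or tm.species_labels
        table1_rows, table2_rows = [], []
        for sp in core_species:
            sub_tm = tm.filter_species(sp)
            if sub_tm.n < 4:
                logger.warning("species %s: too few accessions for cores, skipped", sp)
                continue
            logger.info("stage: cores for species %s (n=%d)", sp, sub_tm.n)
            sweep = coreeval.proportion_sweep(
                sub_tm, alignments, cfg.proportions, cfg.strategies,
                seeds=[cfg.seed], traits_select=cfg.traits_select,
                traits_eval=cfg.traits_eval, alpha=cfg.alpha, n_classes=cfg.n_classes,
            )
            sweep.insert(0, "species", sp)
            for _, r in sweep.iterrows():
                table1_rows.append(r[["species", "strategy", "proportion", "core_size",
                                      "md_percent", "vd_percent", "cr_percent",
                                      "vr_percent"]].to_dict())
                extra = {c: r[c] for c in sweep.columns
                         if c.startswith(("H_", "Hd_", "pi_"))}
                table2_rows.append(
                    dict(species=sp, strategy=r["strategy"],
                         proportion=r["proportion"], **extra)
                )
                core = coreselect.stepwise_core(
                    sub_tm, r["proportion"], strategy=r["strategy"],
                    seed=cfg.seed if r["strategy"] == "random" else None,
                    traits=cfg.traits_select,
                )
                pct = int(round(100 * r["proportion"]))
                write_core_set(core, out / f"core_{sp}_{r['strategy']}_{pct}.txt")

        write_tsv(pd.DataFrame(table1_rows), out / "table1_like.tsv")
        write_tsv(pd.DataFrame(table2_rows), out / "table2_like.tsv")
        logger.info("pipeline complete: %s", out)
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
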