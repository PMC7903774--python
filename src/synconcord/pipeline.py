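"""End-to-end pipeline orchestration: simulate/ingest → match → sweep → report.

A run is described by a :class:`PipelineConfig` (built in code or loaded
from a TOML/YAML file), executes as simulate-or-ingest → fold change →
match → sweep → directional → overlap (when lists are available), and
writes a flat output bundle: TSV tables, a run manifest echoing the
configuration, and a run log. Bundles are byte-reproducible: the same
configuration and seed produce identical files (nothing time-dependent is
written inside the bundle).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic
from .concordance import (
    DEFAULT_N_GRID,
    directional_concordance,
    directional_to_frame,
    select_top_balanced,
    sweep_concordance,
    sweep_to_frame,
)
from .errors import ConfigurationError, InputError, SynconcordError
from .overlap import overlap_stats, read_id_list, tag_ribosomal
from .quantify import (
    FoldChangeTable,
    compute_log2fc,
    match_layers,
    profiles_to_tsv,
)

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return metadata.version("synconcord")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    ``mode="synthetic"`` generates the four-layer dataset from
    ``synthetic_config``; ``mode="user"`` ingests a proteome fold-change TSV
    plus at least one transcriptome table (fold changes, or counts to be
    quantified first). The overlap stage runs when an interactome list is
    available: supplied by path in user mode, generated in synthetic mode
    (intersected with the top ``overlap_top_up`` up-regulated proteins).
    """

    mode: str = "synthetic"
    outdir: str | None = None
    seed: int = 0
    # synthetic mode
    synthetic_config: synthetic.SyntheticConfig | None = None
    write_counts: bool = False
    overlap_top_up: int = 63
    # user mode
    proteome_path: str | None = None
    transcriptome_paths: dict[str, str] = field(default_factory=dict)  # layer → fc TSV
    counts_paths: dict[str, str] = field(default_factory=dict)  # layer → counts TSV
    interactome_path: str | None = None
    uplist_path: str | None = None
    # analysis parameters
    n_max: int = 700
    n_min: int = 100
    n_step: int = 100
    method: str = "pearson"
    directional_n: int = 50
    duplicate_policy: str = "max_abs"
    pseudocount: float = 1.0
    normalization: str = "library_size"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "user"):
            raise ConfigurationError(f"mode must be synthetic or user, got {self.mode!r}")
        if self.mode == "user":
            if not self.proteome_path:
                raise ConfigurationError("mode=user requires proteome_path")
            if not self.transcriptome_paths and not self.counts_paths:
                raise ConfigurationError(
                    "mode=user requires at least one transcriptome table "
                    "(transcriptome_paths or counts_paths)"
                )
        else:
            if self.synthetic_config is None:
                self.synthetic_config = synthetic.SyntheticConfig(seed=self.seed)
            self.synthetic_config.validate()
        if self.n_max < self.n_min or self.n_step <= 0:
            raise ConfigurationError(
                f"invalid sweep grid: n_max={self.n_max} n_min={self.n_min} n_step={self.n_step}"
            )

    @property
    def n_grid(self) -> list[int]:
        return list(range(self.n_max, self.n_min - 1, -self.n_step))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic_config is not None:
            d["synthetic_config"] = self.synthetic_config.to_dict()
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic_config", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {unknown}")
        cfg = cls(**raw)
        if syn is not None:
            syn_known = {f.name for f in dataclasses.fields(synthetic.SyntheticConfig)}
            syn_unknown = sorted(set(syn) - syn_known)
            if syn_unknown:
                raise ConfigurationError(
                    f"unknown synthetic_config field(s): {syn_unknown}"
                )
            cfg.synthetic_config = synthetic.SyntheticConfig(**syn)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from TOML (.toml) or YAML (.yaml/.yml)."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        elif path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(path.read_text())
        else:
            raise ConfigurationError(
                f"config file must be .toml or .yaml, got {path.name}"
            )
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a key-value table")
        return cls.from_dict(raw)


@dataclass
class Issue:
    """One validation finding; severity is ``error`` or ``warning``."""

    file: str
    line: int | None
    severity: str
    message: str

    def __str__(self) -> str:
        loc = f"{self.file}:{self.line}" if self.line else self.file
        return f"{self.severity.upper()} {loc}: {self.message}"


def validate_inputs(paths: list[str | Path]) -> list[Issue]:
    """Check TSV inputs for schema, numeric parsability and duplicate ids.

    Each path is treated as an id-keyed TSV (fold-change table or count
    matrix): a header line, then one row per gene whose non-id fields must
    all parse as numbers. Inputs are never modified.
    """
    issues: list[Issue] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            issues.append(Issue(str(p), None, "error", "file not found"))
            continue
        lines = p.read_text().splitlines()
        if not lines:
            issues.append(Issue(str(p), None, "error", "file is empty"))
            continue
        header = lines[0].split("\t")
        if len(header) < 2:
            issues.append(
                Issue(str(p), 1, "error", "header needs an id column plus >= 1 value column")
            )
            continue
        seen: set[str] = set()
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                issues.append(
                    Issue(str(p), lineno, "error",
                          f"{len(fields)} fields, header has {len(header)}")
                )
                continue
            ident = fields[0].strip().casefold()
            if not ident:
                issues.append(Issue(str(p), lineno, "error", "empty identifier"))
            elif ident in seen:
                issues.append(
                    Issue(str(p), lineno, "warning", f"duplicated identifier {ident!r}")
                )
            seen.add(ident)
            for col, value in zip(header[1:], fields[1:]):
                if value == "":
                    continue  # absent value is legal in matched tables
                try:
                    float(value)
                except ValueError:
                    issues.append(
                        Issue(str(p), lineno, "error",
                              f"non-numeric value {value!r} in column {col!r}")
                    )
    return issues


def _setup_run_logging(outdir: Path, level: str) -> logging.Handler:
    # no timestamps: log files must be byte-identical across reruns
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("synconcord")
    root.addHandler(handler)
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute a full run and write the report bundle; returns the bundle dir.

    Any stage failure is re-raised as a :class:`SynconcordError` whose
    message names the stage.
    """
    config.validate()
    if config.outdir:
        outdir = Path(config.outdir)
    else:
        outdir = Path(f"run_{time.strftime('%Y%m%d-%H%M%S')}_seed{config.seed}")
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir, config.log_level)
    stage = "setup"
    try:
        # --- stage: ingest or simulate -----------------------------------
        interactome_ids: list[str] | None = None
        uplist_ids: list[str] | None = None
        if config.mode == "synthetic":
            stage = "simulate"
            dataset = synthetic.simulate_multiomics(
                config.synthetic_config, with_counts=config.write_counts
            )
            synthetic.write_fixtures(dataset, outdir / "fixtures")
            proteome = dataset.fold_changes["proteome"]
            transcriptomes = [
                dataset.fold_changes[l] for l in synthetic.TRANSCRIPT_LAYERS
            ]
            interactome_ids = dataset.interactome_ids
            logger.info("simulate: %d genes, %d interactome members",
                        len(proteome), len(interactome_ids))
        else:
            stage = "ingest"
            proteome = FoldChangeTable.from_tsv(config.proteome_path, layer="proteome")
            transcriptomes = [
                FoldChangeTable.from_tsv(path, layer=layer)
                for layer, path in config.transcriptome_paths.items()
            ]
            stage = "fold-change"
            for layer, path in config.counts_paths.items():
                counts = pd.read_csv(path, sep="\t", index_col=0)
                table = compute_log2fc(
                    counts,
                    pseudocount=config.pseudocount,
                    normalization=config.normalization,
                )
                table.layer = layer
                transcriptomes.append(table)
                logger.info("fold-change: layer %s quantified from %s (%d genes)",
                            layer, path, len(table))
            if config.interactome_path:
                interactome_ids = read_id_list(config.interactome_path)
            if config.uplist_path:
                uplist_ids = read_id_list(config.uplist_path)

        # --- stage: match --------------------------------------------------
        stage = "match"
        profiles, report = match_layers(
            proteome, transcriptomes, duplicate_policy=config.duplicate_policy
        )
        profiles_to_tsv(profiles, outdir / "matched.tsv")
        (outdir / "match_report.txt").write_text("\n".join(report.to_lines()) + "\n")

        # --- stage: sweep ---------------------------------------------------
        stage = "sweep"
        sweep = sweep_concordance(
            profiles, n_grid=config.n_grid, method=config.method
        )
        sweep_to_frame(sweep).to_csv(
            outdir / "sweep.tsv", sep="\t", index=False, float_format="%.10g"
        )
        logger.info("sweep: %d cells (%d n values)", len(sweep), len(config.n_grid))

        # --- stage: directional ----------------------------------------------
        stage = "directional"
        directional = directional_concordance(
            profiles, n_per_direction=config.directional_n, method=config.method
        )
        directional_to_frame(directional).to_csv(
            outdir / "directional.tsv", sep="\t", index=False, float_format="%.10g"
        )

        # --- stage: overlap ---------------------------------------------------
        stage = "overlap"
        if interactome_ids:
            if uplist_ids is None:
                top = select_top_balanced(
                    profiles, 2 * config.overlap_top_up
                )
                uplist_ids = top.up_ids
            result = overlap_stats(uplist_ids, interactome_ids)
            tagged, n_rp = tag_ribosomal(uplist_ids)
            pd.DataFrame(
                [{
                    "size_up": result.size_a,
                    "size_interactome": result.size_b,
                    "shared": result.shared,
                    "percent_of_up": result.percent_display,
                    "n_ribosomal_in_up": n_rp,
                }]
            ).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
            (outdir / "overlap_shared_ids.txt").write_text(
                "\n".join(result.shared_ids) + ("\n" if result.shared_ids else "")
            )
            logger.info("overlap: %s", result.summary("up-regulated", "interactome"))
            logger.info("overlap: %d ribosomal-protein symbol(s) in the up list", n_rp)

        # --- manifest ----------------------------------------------------------
        stage = "manifest"
        config_echo = config.to_dict()
        config_echo["outdir"] = None  # placement detail, not part of the run identity
        manifest = {
            "config": config_echo,
            "seed": config.seed,
            "synconcord_version": _package_version(),
            "outputs": sorted(
                str(p.relative_to(outdir))
                for p in outdir.rglob("*")
                if p.is_file() and p.name not in ("run.log", "manifest.json")
            ),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except SynconcordError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise SynconcordError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("synconcord").removeHandler(handler)
        handler.close()
    return outdir
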