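"""End-to-end orchestration: ingest/simulate -> raw divergence ->
standardize -> compare -> tails/overlap/enrichment, with a run manifest.

Every run is reproducible: a single global seed is fanned out to
per-stage child seeds through a fixed ``numpy.random.SeedSequence``
derivation, and identical (config, seed) pairs yield byte-identical
output trees.  The manifest records the seed, a hash of the effective
configuration, the package version, and a digest of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import comparison_report
from .enrich import (
    AnnotationMap,
    extract_tails,
    hypergeometric_enrichment,
    random_overlap_baseline,
    venn_counts,
)
from .errors import ComputationError, ConfigError, CrossdivError
from .io import (
    TableSchema,
    read_expression_tsv,
    read_paired_fasta,
    read_similarity_tsv,
    read_table,
    write_table,
)
from .metrics import (
    LEVELS,
    assemble_raw_table,
    expression_profile_divergence,
    nei_gojobori,
    structural_divergence,
)
from .standardize import GRANULARITIES, standardize_table
from .synthetic import SyntheticConfig, generate_divergence_tables

log = logging.getLogger("crossdiv")

RAW_SCHEMA = TableSchema(("gene", "taxon", "level", "raw"), ("str", "str", "str", "float"))
STD_SCHEMA = TableSchema(
    (
        "gene", "taxon", "level", "raw",
        "lambda_taxon", "shift_taxon", "transformed_taxon", "z_taxon",
        "lambda_level", "shift_level", "transformed_level", "z_level",
    ),
    ("str", "str", "str", "float") + ("float",) * 8,
)
_REPORT_SCHEMAS = {
    "medians": TableSchema(
        ("taxon", "level", "median_z_taxon", "median_z_level", "n"),
        ("str", "str", "float", "float", "int"),
    ),
    "utests_taxa": TableSchema(
        ("level", "group1", "group2", "u", "p", "n1", "n2", "method"),
        ("str", "str", "str", "float", "float", "int", "int", "str"),
    ),
    "utests_levels": TableSchema(
        ("taxon", "group1", "group2", "u", "p", "n1", "n2", "method"),
        ("str", "str", "str", "float", "float", "int", "int", "str"),
    ),
    "correlations": TableSchema(
        ("taxon", "level1", "level2", "r", "p_r", "rho", "p_rho", "n"),
        ("str", "str", "str", "float", "float", "float", "float", "int"),
    ),
    "models": TableSchema(
        (
            "taxon", "response", "feature", "coefficient", "std_error",
            "t_value", "p_value", "intercept", "r_squared",
        ),
        ("str", "str", "str") + ("float",) * 6,
    ),
}
OVERLAP_SCHEMA = TableSchema(
    (
        "taxon", "tail", "seq_only", "expr_only", "struct_only",
        "seq_expr", "seq_struct", "expr_struct", "all_three",
    ),
    ("str", "str") + ("int",) * 7,
)
BASELINE_SCHEMA = TableSchema(
    ("taxon", "n_genes", "k", "reps", "median", "mean", "expected"),
    ("str", "int", "int", "int", "float", "float", "float"),
)
ENRICH_SCHEMA = TableSchema(
    ("term", "study_hits", "study_size", "background_hits", "background_size", "p", "q"),
    ("str", "int", "int", "int", "int", "float", "float"),
)


@dataclass(frozen=True)
class TaxonInputs:
    """File-mode input locations for one taxon."""

    raw_table: str | None = None
    alignments_dir: str | None = None
    codeml_dir: str | None = None
    expression_a: str | None = None
    expression_b: str | None = None
    tissue_map: tuple[tuple[str, str], ...] = ()
    similarity: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs."""

    mode: str = "synthetic"                      # "synthetic" or "files"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    taxon_inputs: dict[str, TaxonInputs] = field(default_factory=dict)
    estimator: str = "ng86"                      # "ng86" or "codeml"
    sequence_metric: str = "ka"                  # "ka" or "ks"
    granularity: str = "pooled"                  # Box-Cox fitting granularity
    tail_fraction: float = 0.025
    baseline_reps: int = 101
    annotation: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.estimator not in ("ng86", "codeml"):
            raise ConfigError(f"estimator must be 'ng86' or 'codeml', got {self.estimator!r}")
        if self.sequence_metric not in ("ka", "ks"):
            raise ConfigError(f"sequence_metric must be 'ka' or 'ks', got {self.sequence_metric!r}")
        if self.granularity not in GRANULARITIES:
            raise ConfigError(f"granularity must be one of {GRANULARITIES}")
        if not (0.0 < self.tail_fraction < 0.5):
            raise ConfigError("tail_fraction must lie in (0, 0.5)")
        if self.baseline_reps < 1:
            raise ConfigError("baseline_reps must be >= 1")
        if self.mode == "files" and not self.taxon_inputs:
            raise ConfigError("file mode requires at least one [taxa.*] input block")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        kwargs: dict = {}
        for key in ("mode", "estimator", "sequence_metric", "granularity", "log_level", "annotation"):
            if key in data:
                kwargs[key] = data[key]
        for key in ("seed", "baseline_reps"):
            if key in data:
                kwargs[key] = int(data[key])
        if "tail_fraction" in data:
            kwargs["tail_fraction"] = float(data["tail_fraction"])
        if "synthetic" in data:
            kwargs["synthetic"] = SyntheticConfig.from_dict(data["synthetic"])
        if "taxa" in data:
            inputs = {}
            for taxon, block in data["taxa"].items():
                tmap = tuple((str(a), str(b)) for a, b in block.get("tissue_map", []))
                inputs[taxon] = TaxonInputs(
                    raw_table=block.get("raw_table"),
                    alignments_dir=block.get("alignments_dir"),
                    codeml_dir=block.get("codeml_dir"),
                    expression_a=block.get("expression_a"),
                    expression_b=block.get("expression_b"),
                    tissue_map=tmap,
                    similarity=block.get("similarity"),
                )
            kwargs["taxon_inputs"] = inputs
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable digest of the analytic configuration (logging excluded)."""
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                d = {k: v for k, v in vars(o).items()}
                d.pop("log_level", None)
                return d
            if isinstance(o, (frozenset, set, tuple)):
                return sorted(map(str, o)) if isinstance(o, (frozenset, set)) else list(o)
            return str(o)

        blob = json.dumps(_default(self), default=_default, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_ingest(config: RunConfig, seed: int) -> pd.DataFrame:
    if config.mode == "synthetic":
        log.info("stage ingest: simulating %d taxa x %d genes",
                 len(config.synthetic.taxa), config.synthetic.genes_per_taxon)
        syn = replace(config.synthetic, seed=seed)
        tables = generate_divergence_tables(syn)
        return pd.concat(tables.values(), ignore_index=True)

    frames = []
    for taxon, inputs in config.taxon_inputs.items():
        log.info("stage ingest: taxon %s", taxon)
        if inputs.raw_table:
            frames.append(read_table(inputs.raw_table, RAW_SCHEMA))
            continue
        seq_divs = _sequence_divergences(config, taxon, inputs)
        if not (inputs.expression_a and inputs.expression_b and inputs.tissue_map):
            raise ConfigError(f"taxon {taxon}: expression inputs incomplete")
        expr = expression_profile_divergence(
            read_expression_tsv(inputs.expression_a),
            read_expression_tsv(inputs.expression_b),
            dict(inputs.tissue_map),
        )
        if not inputs.similarity:
            raise ConfigError(f"taxon {taxon}: similarity table missing")
        struct = structural_divergence(read_similarity_tsv(inputs.similarity))
        frames.append(assemble_raw_table(taxon, seq_divs, expr, struct))
    return pd.concat(frames, ignore_index=True)


def _sequence_divergences(config: RunConfig, taxon: str, inputs: TaxonInputs) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    if config.estimator == "codeml":
        if not inputs.codeml_dir:
            raise ConfigError(f"taxon {taxon}: codeml_dir missing for codeml estimator")
        from .io import parse_codeml_pairwise

        for path in sorted(Path(inputs.codeml_dir).glob("*.txt")):
            rec = parse_codeml_pairwise(path.read_text(), gene_id=path.stem)
            out[path.stem] = rec.dn if config.sequence_metric == "ka" else rec.ds
        return out
    if not inputs.alignments_dir:
        raise ConfigError(f"taxon {taxon}: alignments_dir missing for ng86 estimator")
    for path in sorted(Path(inputs.alignments_dir).glob("*.fasta")):
        result = nei_gojobori(read_paired_fasta(path))
        out[path.stem] = result.ka if config.sequence_metric == "ka" else result.ks
    return out


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages and write result tables plus a manifest.

    Returns the output directory.  Any stage failure raises a
    :class:`CrossdivError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )

    ss = np.random.SeedSequence(config.seed)
    child_ingest, child_baseline = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))

    stage = "ingest"
    try:
        raw = _stage_ingest(config, child_ingest)
        write_table(raw, RAW_SCHEMA, out / "raw_divergence.tsv")

        stage = "standardize"
        log.info("stage standardize: %d rows, granularity=%s", len(raw), config.granularity)
        std = standardize_table(raw, granularity=config.granularity)
        write_table(std, STD_SCHEMA, out / "standardized.tsv")

        stage = "compare"
        log.info("stage compare")
        report = comparison_report(std)
        for name, frame in report.items():
            write_table(frame, _REPORT_SCHEMAS[name], out / f"{name}.tsv")

        stage = "tails"
        log.info("stage tails: fraction=%g", config.tail_fraction)
        partitions = extract_tails(std, fraction=config.tail_fraction)
        tails_dir = out / "tails"
        tails_dir.mkdir(exist_ok=True)
        by_taxon: dict[str, dict[str, object]] = {}
        for part in partitions:
            for tail, genes in (("low", part.low_set), ("high", part.high_set)):
                path = tails_dir / f"{part.taxon}_{part.level}_{tail}.txt"
                path.write_text("\n".join(sorted(genes)) + "\n")
            by_taxon.setdefault(part.taxon, {})[part.level] = part

        stage = "overlap"
        log.info("stage overlap: baseline reps=%d", config.baseline_reps)
        overlap_rows, baseline_rows = [], []
        baseline_rng = np.random.default_rng(child_baseline)
        for taxon in sorted(by_taxon):
            parts = by_taxon[taxon]
            missing = [lv for lv in LEVELS if lv not in parts]
            if missing:
                raise ComputationError(f"taxon {taxon} lacks tail sets for {missing}")
            for tail in ("low", "high"):
                sets = [
                    getattr(parts[lv], f"{tail}_set") for lv in LEVELS
                ]
                summary = venn_counts(*sets, taxon=taxon, tail=tail)
                overlap_rows.append(
                    (
                        taxon, tail, summary.seq_only, summary.expr_only, summary.struct_only,
                        summary.seq_expr, summary.seq_struct, summary.expr_struct,
                        summary.all_three,
                    )
                )
            n_genes = int(
                (std.loc[std["taxon"] == taxon].groupby("level")["gene"].nunique()).min()
            )
            k = parts[LEVELS[0]].k
            base = random_overlap_baseline(n_genes, k, reps=config.baseline_reps, seed=baseline_rng)
            baseline_rows.append(
                (taxon, n_genes, k, config.baseline_reps, base["median"], base["mean"], base["expected"])
            )
        write_table(pd.DataFrame(overlap_rows, columns=OVERLAP_SCHEMA.columns),
                    OVERLAP_SCHEMA, out / "overlap.tsv")
        write_table(pd.DataFrame(baseline_rows, columns=BASELINE_SCHEMA.columns),
                    BASELINE_SCHEMA, out / "overlap_baseline.tsv")

        if config.annotation:
            stage = "enrich"
            log.info("stage enrich: %s", config.annotation)
            background = set(std["gene"])
            annotation = AnnotationMap.from_tsv(config.annotation, background=background)
            enrich_dir = out / "enrichment"
            enrich_dir.mkdir(exist_ok=True)
            for part in partitions:
                for tail, genes in (("low", part.low_set), ("high", part.high_set)):
                    frame = hypergeometric_enrichment(genes, annotation)
                    write_table(
                        frame, ENRICH_SCHEMA,
                        enrich_dir / f"{part.taxon}_{part.level}_{tail}.tsv",
                    )
    except CrossdivError as exc:
        raise CrossdivError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(config, out)
    log.info("pipeline complete: %s", out)
    return out


def _write_manifest(config: RunConfig, out: Path) -> None:
    digests = []
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.toml":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            digests.append((str(path.relative_to(out)), digest))
    lines = [
        f'version = "{__version__}"',
        f"seed = {config.seed}",
        f'config_hash = "{config.config_hash()}"',
        f'granularity = "{config.granularity}"',
        f"tail_fraction = {config.tail_fraction}",
        "",
        "[outputs]",
    ]
    for rel, digest in digests:
        lines.append(f'"{rel}" = "{digest}"')
    (out / "manifest.toml").write_text("\n".join(lines) + "\n")
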