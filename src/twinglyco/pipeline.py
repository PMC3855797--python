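"""Pipeline orchestration: simulate -> traits -> heritability -> ewas -> enrich.

Stages communicate exclusively through delimited text tables (TSV with a
header row and a sample-id or trait-name key column) under one output
directory, plus a YAML snapshot of the ground-truth configuration and a JSON
run manifest with per-file checksums.  Re-running with the same configuration
and seed reproduces byte-identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimulationConfig, simulate_cohort
from .glycans import compute_all_traits
from .twin import heritability_table
from .ewas import MethylationMatrix, bonferroni_threshold, run_ewas, standardize_probes
from .enrichment import build_contingency, compare_proportions

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "DependencyError",
    "SchemaError",
    "run_pipeline",
    "render_report",
]

log = logging.getLogger(__name__)

STAGES = ("simulate", "traits", "heritability", "ewas", "enrich", "report")


class DependencyError(RuntimeError):
    """A stage's required inputs are unavailable."""


class SchemaError(ValueError):
    """An input table is missing required columns."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig | None = None
    lrt_alpha: float = 0.05
    array_alpha: float = 0.05
    heritability_threshold: float = 0.35
    ewas_subset: str = "low"  # low | high | all

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for name, val in (
            ("lrt_alpha", self.lrt_alpha),
            ("array_alpha", self.array_alpha),
            ("heritability_threshold", self.heritability_threshold),
        ):
            if not 0 < val < 1:
                raise ValueError(f"{name} must be in (0,1), got {val}")
        if self.ewas_subset not in ("low", "high", "all"):
            raise ValueError(f"ewas_subset must be low/high/all, got {self.ewas_subset}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def snapshot(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "stages": list(self.stages),
            "lrt_alpha": self.lrt_alpha,
            "array_alpha": self.array_alpha,
            "heritability_threshold": self.heritability_threshold,
            "ewas_subset": self.ewas_subset,
        }
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    durations: dict[str, float] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} missing columns {missing}")


def _read_tsv(path: Path, required: list[str], index_col: str | None = None) -> pd.DataFrame:
    if not path.exists():
        raise DependencyError(f"required input {path.name} not found; enable its stage")
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, required, path.name)
    if index_col:
        df = df.set_index(index_col)
    return df


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the enabled stages in dependency order.

    A failing stage aborts the run; the partial manifest (with the failed
    stage name) is still written to ``manifest.json`` in the output
    directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.snapshot(),
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(name: str) -> None:
        p = outdir / name
        if p.exists():
            manifest.checksums[name] = _sha256(p)

    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            log.info("stage %s starting", stage)
            _STAGE_FUNCS[stage](config, outdir)
            manifest.durations[stage] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", stage, manifest.durations[stage])
    except Exception as err:
        manifest.failed_stage = stage
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        for f in sorted(p.name for p in outdir.glob("*") if p.is_file()):
            record(f)
        manifest.write(outdir / "manifest.json")
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    for f in sorted(p.name for p in outdir.glob("*") if p.is_file()):
        record(f)
    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim = config.simulation or SimulationConfig()
    if sim.seed != config.seed:
        sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
    cohort = simulate_cohort(sim)
    cohort.write(outdir)
    log.info(
        "simulated %d MZ + %d DZ pairs, %d traits, %d probes (seed %d)",
        sim.n_mz, sim.n_dz, len(sim.trait_specs), sim.methyl_model.n_probes, sim.seed,
    )


def _stage_traits(config: PipelineConfig, outdir: Path) -> None:
    peaks = _read_tsv(outdir / "peaks.tsv", ["sample_id"], index_col="sample_id")
    traits = compute_all_traits(peaks)
    traits.reset_index().to_csv(outdir / "traits_from_peaks.tsv", sep="\t", index=False)
    log.info("computed %d glycan traits from the peak table", traits.shape[1])


def _stage_heritability(config: PipelineConfig, outdir: Path) -> None:
    traits = _read_tsv(outdir / "traits.tsv", ["sample_id"], index_col="sample_id")
    cov = _read_tsv(
        outdir / "covariates.tsv", ["sample_id", "pair_id", "zygosity", "age", "batch"]
    )
    table = heritability_table(
        traits, cov, alpha=config.lrt_alpha, threshold=config.heritability_threshold
    )
    table.to_csv(outdir / "heritability.tsv", sep="\t", index=False)


def _stage_ewas(config: PipelineConfig, outdir: Path) -> None:
    traits = _read_tsv(outdir / "traits.tsv", ["sample_id"], index_col="sample_id")
    cov = _read_tsv(outdir / "covariates.tsv", ["sample_id", "pair_id"])
    methyl_raw = _read_tsv(outdir / "methylation.tsv", ["sample_id"], index_col="sample_id")
    annot = _read_tsv(outdir / "probe_annotation.tsv", ["probe", "chr", "map_position"])
    methyl = standardize_probes(methyl_raw)
    methyl.annotation = annot
    if config.ewas_subset == "all":
        subset = list(traits.columns)
    else:
        her = _read_tsv(outdir / "heritability.tsv", ["trait", "heritability_class"])
        subset = list(her.loc[her["heritability_class"] == config.ewas_subset, "trait"])
        if not subset:
            raise DependencyError(
                f"no traits in heritability class {config.ewas_subset!r}"
            )
    cutoff, _ = bonferroni_threshold(config.array_alpha, len(methyl.probes))
    table = run_ewas(
        traits, subset, methyl,
        covariates=cov[[c for c in cov.columns if c not in ("zygosity",)]],
        threshold=cutoff,
    )
    table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    log.info(
        "EWAS on %d traits x %d probes: %d array-wide hits (P < %.3g)",
        len(subset), len(methyl.probes), int(table["significant"].sum()) if len(table) else 0,
        cutoff,
    )


def _stage_enrich(config: PipelineConfig, outdir: Path) -> None:
    her = _read_tsv(outdir / "heritability.tsv", ["trait", "heritability_class"])
    assoc = _read_tsv(outdir / "associations.tsv", [])
    if assoc.empty:
        assoc = pd.DataFrame(columns=["probe", "glycan", "p", "significant"])
    table = build_contingency(her, assoc)
    result = compare_proportions(table)
    pd.DataFrame(
        [
            {
                "low_hits": table.low_hits,
                "low_rest": table.low_rest,
                "high_hits": table.high_hits,
                "high_rest": table.high_rest,
                "proportion_low": result.proportion_low,
                "proportion_high": result.proportion_high,
                "p_exact": result.p_exact,
                "p_chi2": result.p_chi2,
                "odds_ratio": result.odds_ratio,
            }
        ]
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    log.info("%s", result.summary())


def _stage_report(config: PipelineConfig, outdir: Path) -> None:
    (outdir / "report.txt").write_text(render_report(outdir))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "traits": _stage_traits,
    "heritability": _stage_heritability,
    "ewas": _stage_ewas,
    "enrich": _stage_enrich,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# report rendering


def format_p(p: float) -> str:
    """P-value formatting: scientific 'm x10^-k' below 1e-4, plain otherwise."""
    if not np.isfinite(p):
        return "NA"
    if p != 0 and p < 1e-4:
        exp = int(np.floor(np.log10(p)))
        mant = p / 10.0**exp
        return f"{mant:.2f}x10^{exp}"
    return f"{p:.4f}"


def _table_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False)


def render_report(outdir) -> str:
    """Human-readable run summary mirroring the published table layouts."""
    outdir = Path(outdir)
    parts = ["twinglyco run report", "=" * 60]

    her_p = outdir / "heritability.tsv"
    if her_p.exists():
        her = pd.read_csv(her_p, sep="\t").fillna("")
        cols = [
            "trait", "mz_mean_sd", "icc_mz", "dz_mean_sd", "icc_dz",
            "best_model", "A", "C", "E", "heritability_class",
        ]
        parts += ["", "Heritability (ACE decomposition, adjusted for age and batch)",
                  _table_text(her[[c for c in cols if c in her.columns]])]

    assoc_p = outdir / "associations.tsv"
    if assoc_p.exists():
        assoc = pd.read_csv(assoc_p, sep="\t")
        sig = assoc[assoc["significant"].astype(bool)] if len(assoc) else assoc
        parts += ["", "Array-wide significant associations"]
        if len(sig):
            sig = sig.copy()
            sig["P"] = sig["p"].map(format_p)
            show = sig[
                ["probe", "chr", "map_position", "nearest_gene", "glycan", "beta", "se", "P"]
            ].rename(columns={"map_position": "position", "nearest_gene": "gene"})
            parts.append(_table_text(show.round({"beta": 2, "se": 2})))
        else:
            parts.append("zero array-wide hits at the Bonferroni threshold")

    enr_p = outdir / "enrichment.tsv"
    if enr_p.exists():
        e = pd.read_csv(enr_p, sep="\t").iloc[0]
        parts += [
            "",
            "Enrichment by heritability class",
            (
                f"array-wide hits: {e.proportion_low * 100:.1f}% (low) vs "
                f"{e.proportion_high * 100:.1f}% (high); one-sided exact "
                f"P = {format_p(e.p_exact)}, chi-square P = {format_p(e.p_chi2)}, "
                f"OR = {e.odds_ratio:.2f}"
            ),
        ]
    return "\n".join(parts) + "\n"
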