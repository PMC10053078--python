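"""End-to-end orchestration: extract -> compendium -> quantify -> stats.

One run consumes a directory of per-sample SAM/BAM files plus the
variant-definition, clinical and AR-expression tables, and writes every
stage's table into a result directory together with a machine-readable
manifest (full config echo + sha256 checksum of each output).  Reruns on
identical inputs are byte-identical; the manifest intentionally carries
no timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cohort_stats as cs
from .compendium import RecurrenceThresholds, build_compendium, read_definitions
from .junctions import AlignmentFilterPolicy, Locus, extract_cohort, write_junction_table
from .quantify import call_positive, relative_expression
from .simulate import SimulationConfig, simulate_cohort, truth_recovery_report

log = logging.getLogger("arvc")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_demo"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Tunables of a full pipeline run; defaults are the standard
    analysis settings (>=5 reads in >=10 samples, >=1% positivity)."""

    locus: str = "chrX:66763863-66951462:+"
    genome_build: str = "GRCh37"
    min_reads: int = 5
    min_samples: int = 10
    recurrence_mode: str = "per-sample"
    positivity_threshold_pct: float = 1.0
    alpha: float = 0.05
    min_group: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    alignment_files: dict[str, str | Path],
    definitions_file: str | Path,
    outdir: str | Path,
    clinical_file: str | Path | None = None,
    ar_expression_file: str | Path | None = None,
) -> dict:
    """Run every stage and return the manifest dict (also written as
    ``manifest.json`` under ``outdir``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}

    def _done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "complete", **info}
        log.info("stage %s complete %s", stage, info)

    def _register(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    # --- extract ------------------------------------------------------
    try:
        locus = Locus.parse(config.locus, config.genome_build)
        counts, stats = extract_cohort(alignment_files, locus, AlignmentFilterPolicy())
    except Exception as exc:
        raise PipelineError("extract", str(exc)) from exc
    junctions_path = outdir / "junctions.tsv"
    write_junction_table(counts, junctions_path)
    _register(junctions_path)
    _done("extract", n_samples=len(counts.index), n_junctions=len(counts.columns),
          stats={s: st.as_dict() for s, st in stats.items()})

    # --- compendium ---------------------------------------------------
    try:
        thresholds = RecurrenceThresholds(config.min_reads, config.min_samples)
        from .compendium import recurrent_junctions

        recurrent = recurrent_junctions(counts, thresholds, mode=config.recurrence_mode)
        definitions, reference = read_definitions(definitions_file)
        if reference is None:
            raise ValueError("definitions file lacks a reference-junction row")
        comp = build_compendium(recurrent, definitions, reference,
                                metadata={"locus": str(locus),
                                          "genome_build": config.genome_build})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("compendium", str(exc)) from exc
    comp_path = outdir / "compendium.tsv"
    comp.write(comp_path, outdir / "compendium_meta.json")
    _register(comp_path)
    _register(outdir / "compendium_meta.json")
    _done("compendium", n_recurrent=len(recurrent),
          n_quantifiable=len(comp.quantifiable_variants))

    # --- quantify -----------------------------------------------------
    try:
        rem = relative_expression(counts, comp, config.positivity_threshold_pct)
        flags, prevalence = call_positive(rem)
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc
    rem_path = outdir / "relative_expression.tsv"
    rem.write(rem_path)
    prev_path = outdir / "prevalence.tsv"
    prevalence.to_csv(prev_path, sep="\t")
    _register(rem_path)
    _register(prev_path)
    _done("quantify", n_variants=len(rem.variants), exempt=list(rem.exempt))

    # --- stats --------------------------------------------------------
    try:
        stats_written = _run_stats(config, rem, flags, outdir,
                                   clinical_file, ar_expression_file)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc
    for p in stats_written:
        _register(p)
    _done("stats", outputs=[p.name for p in stats_written])

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _run_stats(config, rem, flags, outdir: Path, clinical_file, ar_file) -> list[Path]:
    written: list[Path] = []
    sample_order, variant_order = cs.oncoprint_order(flags)
    onco = pd.DataFrame({"sample": sample_order})
    onco_path = outdir / "oncoprint_order.tsv"
    onco.to_csv(onco_path, sep="\t", index=False)
    (outdir / "oncoprint_variants.tsv").write_text(
        "variant\n" + "".join(f"{v}\n" for v in variant_order)
    )
    written += [onco_path, outdir / "oncoprint_variants.tsv"]

    if ar_file is not None:
        ar = pd.read_csv(ar_file, sep="\t").set_index("sample")["ar_expression"]
        comparison = cs.any_variant_vs_ar_expression(ar, flags)
        n_pos = flags.sum(axis=1)
        pairwise = cs.per_count_group_tests(ar, n_pos)
        ar_path = outdir / "ar_expression_tests.tsv"
        header = pd.DataFrame([asdict(comparison)])
        header.to_csv(ar_path, sep="\t", index=False)
        pair_path = outdir / "ar_expression_pairwise.tsv"
        pairwise.to_csv(pair_path, sep="\t", index=False)
        written += [ar_path, pair_path]

    if clinical_file is not None:
        clinical = pd.read_csv(clinical_file, sep="\t")
        summary = cs.cohort_summary(clinical)
        sum_path = outdir / "cohort_summary.tsv"
        summary.to_csv(sum_path, sep="\t", index=False)
        written.append(sum_path)

        uni = cs.univariate_screen(clinical, rem.values, alpha=config.alpha)
        uni_path = outdir / "univariate_screen.tsv"
        uni.to_csv(uni_path, sep="\t", index=False)
        written.append(uni_path)

        selected = sorted(uni.loc[uni["significant"], "covariate"].unique())
        if selected:
            multi = cs.multivariate_model(clinical, rem.values, selected,
                                          alpha=config.alpha)
            multi_path = outdir / "multivariate_model.tsv"
            multi.to_csv(multi_path, sep="\t", index=False)
            written.append(multi_path)

        sizes, subset = cs.single_treatment_subset(clinical, min_group=config.min_group)
        st_path = outdir / "single_treatment_groups.tsv"
        sizes.rename("n_patients").to_frame().to_csv(st_path, sep="\t")
        written.append(st_path)
    return written


def run_demo(outdir: str | Path, seed: int = 0,
             sim_config: SimulationConfig | None = None,
             run_config: RunConfig | None = None) -> dict:
    """Simulate a default cohort and push it through the whole pipeline.

    Everything lands under ``outdir`` (``sim/`` for the synthetic inputs,
    ``results/`` for the pipeline outputs + manifest); a recovery report
    against the simulator's truth is added to the results.
    """
    outdir = Path(outdir)
    sim_config = sim_config or SimulationConfig(
        rng_seed=seed, ar_positive_shift=1.3,
        treatment_effects={"enzalutamide": {"AR-V7": 2.5}},
    )
    sim = simulate_cohort(sim_config, outdir / "sim")
    run_config = run_config or RunConfig(locus=str(sim.model.locus),
                                         genome_build=sim.model.genome_build,
                                         seed=seed)
    run_config.locus = str(sim.model.locus)
    run_config.genome_build = sim.model.genome_build
    manifest = run_pipeline(
        run_config,
        {s: p for s, p in sim.sam_paths.items()},
        sim.definitions_path,
        outdir / "results",
        clinical_file=sim.clinical_path,
        ar_expression_file=sim.ar_expression_path,
    )
    from .quantify import RelativeExpressionMatrix

    rem = RelativeExpressionMatrix.read(outdir / "results" / "relative_expression.tsv",
                                        run_config.positivity_threshold_pct)
    recovery = truth_recovery_report(sim.truth, rem)
    rec_path = outdir / "results" / "recovery_report.tsv"
    recovery.to_csv(rec_path, sep="\t", index=False)
    manifest["outputs"][rec_path.name] = _sha256(rec_path)
    (outdir / "results" / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
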