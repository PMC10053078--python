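"""Synthetic spliced-read cohorts with known ground truth.

Emulates a multi-sample RNA-seq cohort over a toy eight-exon gene that
mimics the androgen receptor: a canonical isoform (E1..E8), cryptic-exon
variant isoforms (each contributing one distinctive splice junction
absent from the canonical chain) and an AR45-style isoform with an
alternative first exon.  Reads are junction-spanning two-block records
(``50M <intron> 50M``) because only junction support enters any
downstream computation; sequence-level realism (qualities, errors, GC)
is deliberately out of scope.

Per sample, the reference exon1->exon2 junction draws ``Poisson(depth)``
reads and each active variant junction draws ``Binomial(ref_count,
fraction)`` reads, so the realized variant fraction is known exactly.
Contamination re-flags a configurable share of drawn reads as duplicate,
secondary or wrong-strand (a rate of 1.0 therefore removes all
qualifying support for the affected junctions), and sporadic noise
junctions plus unspliced reads exercise the upstream filters.  Clinical
covariates are drawn per patient; a configured treatment effect
multiplies a variant's fraction in treated patients, giving the
regression stage a recoverable signal.  All draws are made through one
seeded generator, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .junctions import Locus, SpliceJunction

__all__ = [
    "IsoformModel",
    "VariantSim",
    "ClinicalSimConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulationResult",
    "default_isoform_model",
    "default_config",
    "simulate_cohort",
    "truth_recovery_report",
]

_READ_FLANK = 50  # aligned bases on each side of a simulated junction


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class IsoformModel:
    """Exon layout and isoform chains of the toy gene.

    ``exons`` maps exon name -> (start, end), 1-based inclusive, all on
    one strand of one toy contig.  ``isoforms`` maps isoform name -> the
    ordered exon chain; the entry named ``canonical`` defines the
    reference junction (its first junction) and the background junction
    set.  Every variant chain must contribute >= 1 junction absent from
    the canonical chain; the first such junction is the variant's
    distinctive (quantification) junction.
    """

    chrom: str = "chrT"
    contig_length: int = 20000
    strand: str = "+"
    genome_build: str = "toy1"
    exons: dict[str, tuple[int, int]] = field(default_factory=dict)
    isoforms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    canonical: str = "AR"

    def __post_init__(self) -> None:
        spans = sorted(self.exons.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError("exons must be non-overlapping")
        if self.canonical not in self.isoforms:
            raise ConfigError(f"canonical isoform {self.canonical!r} missing")
        for name in self.isoforms:
            if name != self.canonical and self.distinctive_junction(name) is None:
                raise ConfigError(f"isoform {name!r} has no distinctive junction")

    def junctions_of(self, isoform: str) -> list[SpliceJunction]:
        chain = self.isoforms[isoform]
        out = []
        for a, b in zip(chain, chain[1:]):
            donor = self.exons[a][1] + 1
            acceptor = self.exons[b][0] - 1
            out.append(SpliceJunction(self.chrom, donor, acceptor, self.strand))
        return out

    @property
    def canonical_junctions(self) -> list[SpliceJunction]:
        return self.junctions_of(self.canonical)

    @property
    def reference_junction(self) -> SpliceJunction:
        return self.canonical_junctions[0]

    def distinctive_junction(self, isoform: str) -> SpliceJunction | None:
        canonical = set(self.canonical_junctions)
        for j in self.junctions_of(isoform):
            if j not in canonical:
                return j
        return None

    @property
    def locus(self) -> Locus:
        return Locus(self.chrom, 1, self.contig_length, self.strand, self.genome_build)

    def definitions_frame(self) -> pd.DataFrame:
        """Variant-definition table (reference + defining-primary rows)."""
        ref = self.reference_junction
        rows = [
            {"name": self.canonical, "chrom": ref.chrom, "donor": ref.donor,
             "acceptor": ref.acceptor, "strand": ref.strand,
             "genome_build": self.genome_build, "role": "reference"}
        ]
        for name in self.isoforms:
            if name == self.canonical:
                continue
            j = self.distinctive_junction(name)
            rows.append(
                {"name": name, "chrom": j.chrom, "donor": j.donor,
                 "acceptor": j.acceptor, "strand": j.strand,
                 "genome_build": self.genome_build, "role": "defining-primary"}
            )
        return pd.DataFrame(rows)


def default_isoform_model() -> IsoformModel:
    """Toy AR-like gene: 8 canonical exons, 5 cryptic exons, one
    alternative first exon (AR45-style 5' shortening)."""
    exons = {
        "E1": (101, 600), "E1b": (801, 900),
        "E2": (1001, 1150), "CEd": (1501, 1580),
        "E3": (2001, 2120), "CEa": (2501, 2620), "CEb": (2701, 2800),
        "CEc": (2901, 3000),
        "E4": (3301, 3590), "E5": (4001, 4150),
        "E6": (5001, 5130), "CEe": (5501, 5560),
        "E7": (6001, 6160), "E8": (7001, 7400),
    }
    isoforms = {
        "AR": ("E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8"),
        "AR45": ("E1b", "E2", "E3", "E4", "E5", "E6", "E7", "E8"),
        "AR-V3": ("E1", "E2", "CEd"),
        "AR-V7": ("E1", "E2", "E3", "CEa"),
        "AR-V9": ("E1", "E2", "E3", "CEb"),
        "AR-V1": ("E1", "E2", "E3", "CEc"),
        "AR23": ("E1", "E2", "E3", "E4", "E5", "E6", "CEe", "E7"),
    }
    return IsoformModel(exons=exons, isoforms=isoforms)


@dataclass(frozen=True)
class VariantSim:
    """One simulated variant: expected fraction (percent of reference
    support) in active samples, and the share of samples it is active in."""

    name: str
    fraction_pct: float
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_pct <= 100.0:
            raise ConfigError(f"{self.name}: fraction must be in [0, 100] percent")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"{self.name}: prevalence must be in [0, 1]")


@dataclass(frozen=True)
class ClinicalSimConfig:
    """Clinical covariate generator (defaults mirror an mCRPC cohort:
    median age 67 within 46-85, mostly docetaxel/enzalutamide pre-treated,
    ~23% of records missing treatment history)."""

    age_mean: float = 67.0
    age_sd: float = 8.0
    age_min: float = 46.0
    age_max: float = 85.0
    age_missing_rate: float = 0.007
    treatment_probs: dict[str, float] = field(
        default_factory=lambda: {
            "docetaxel": 0.826, "enzalutamide": 0.526, "cabazitaxel": 0.258,
            "abiraterone": 0.235, "radium223": 0.131,
        }
    )
    extra_lines_lambda: float = 0.7
    max_lines: int = 8
    missing_rate: float = 0.234  # treatment block missing together


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings; the defaults are the study
    conditions the whole test battery runs under."""

    n_samples: int = 30
    depth: float = 300.0
    variants: tuple[VariantSim, ...] = (
        VariantSim("AR45", 5.0, 0.66),
        VariantSim("AR-V3", 2.0, 0.41),
        VariantSim("AR-V7", 2.0, 0.37),
        VariantSim("AR-V9", 1.5, 0.12),
        VariantSim("AR23", 1.5, 0.08),
        VariantSim("AR-V1", 1.5, 0.06),
    )
    duplicate_rate: float = 0.05
    secondary_rate: float = 0.02
    wrong_strand_rate: float = 0.02
    unspliced_rate: float = 0.2
    noise_junction_rate: float = 0.02
    duplicate_rate_variants: float | None = None  # override for variant-junction reads
    positivity_threshold_pct: float = 1.0
    ar_positive_shift: float = 1.0
    treatment_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    clinical: ClinicalSimConfig = field(default_factory=ClinicalSimConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rates = [self.duplicate_rate, self.secondary_rate, self.wrong_strand_rate,
                 self.unspliced_rate, self.noise_junction_rate]
        if self.duplicate_rate_variants is not None:
            rates.append(self.duplicate_rate_variants)
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ConfigError("contamination/noise rates must be in [0, 1]")
        if self.duplicate_rate + self.secondary_rate + self.wrong_strand_rate > 1.0:
            raise ConfigError("contamination rates must sum to <= 1")
        if self.n_samples < 1 or self.depth <= 0:
            raise ConfigError("need n_samples >= 1 and depth > 0")
        for v in self.variants:
            eff = max(
                (f for t in self.treatment_effects.values() for n, f in t.items()
                 if n == v.name), default=1.0,
            )
            if v.fraction_pct * max(eff, 1.0) > 100.0:
                raise ConfigError(f"{v.name}: effective fraction exceeds 100%")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = [asdict(v) for v in self.variants]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["variants"] = tuple(VariantSim(**v) for v in d.get("variants", []))
        if "clinical" in d and isinstance(d["clinical"], dict):
            d["clinical"] = ClinicalSimConfig(**d["clinical"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort.

    ``per_sample``: one row per (sample, variant) with activity,
    effective configured fraction, drawn and surviving qualifying read
    counts, realized relative expression and positivity.
    ``per_cohort``: per-variant truth prevalence.  ``reference``:
    per-sample reference-junction support and depth.
    """

    per_sample: pd.DataFrame
    reference: pd.DataFrame
    per_cohort: pd.DataFrame
    config: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_sample.to_csv(outdir / "truth_per_sample.tsv", sep="\t", index=False)
        self.reference.to_csv(outdir / "truth_reference.tsv", sep="\t", index=False)
        self.per_cohort.to_csv(outdir / "truth_per_cohort.tsv", sep="\t", index=False)
        Path(outdir / "sim_config.yaml").write_text(
            yaml.safe_dump(self.config, sort_keys=True)
        )

    @classmethod
    def read(cls, outdir: str | Path) -> "SyntheticTruth":
        outdir = Path(outdir)
        return cls(
            pd.read_csv(outdir / "truth_per_sample.tsv", sep="\t"),
            pd.read_csv(outdir / "truth_reference.tsv", sep="\t"),
            pd.read_csv(outdir / "truth_per_cohort.tsv", sep="\t"),
            yaml.safe_load((outdir / "sim_config.yaml").read_text()),
        )


@dataclass
class SimulationResult:
    outdir: Path
    sam_paths: dict[str, Path]
    definitions_path: Path
    clinical_path: Path
    ar_expression_path: Path
    truth: SyntheticTruth
    model: IsoformModel


def _split_contamination(rng, n: int, d: float, s: float, w: float) -> tuple[int, int, int, int]:
    """Partition n drawn reads into (qualifying, duplicate, secondary,
    wrong-strand) counts."""
    dup, sec, wrs, qual = rng.multinomial(n, [d, s, w, 1.0 - d - s - w])
    return int(qual), int(dup), int(sec), int(wrs)


def _junction_records(sid, junction, counts, name_counter, strand_char="+"):
    """SAM record tuples for one junction: (pos0, flag, cigar, xs, qname)."""
    qual, dup, sec, wrs = counts
    pos0 = junction.donor - 1 - _READ_FLANK
    intron = junction.acceptor - junction.donor + 1
    cigar = f"{_READ_FLANK}M{intron}N{_READ_FLANK}M"
    out = []
    for flag, xs, n in (
        (99, strand_char, qual),
        (99 | 0x400, strand_char, dup),
        (99 | 0x100, strand_char, sec),
        (99, "-" if strand_char == "+" else "+", wrs),
    ):
        for _ in range(n):
            out.append((pos0, flag, cigar, xs, f"{sid}.r{next(name_counter)}"))
    return out


def _write_sam(path: Path, model: IsoformModel, records: list[tuple]) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": model.chrom, "LN": model.contig_length}],
        }
    )
    records.sort(key=lambda r: (r[0], r[4]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pos0, flag, cigar, xs, qname in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.next_reference_id = 0
            a.next_reference_start = pos0
            a.template_length = 0
            n_match = sum(
                int(x) for x, op in _cigar_items(cigar) if op in "M=X"
            )
            a.query_sequence = "A" * n_match
            if xs is not None:
                a.set_tag("XS", xs)
            out.write(a)


def _cigar_items(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def simulate_cohort(
    config: SimulationConfig,
    outdir: str | Path,
    model: IsoformModel | None = None,
) -> SimulationResult:
    """Draw a cohort and write per-sample SAM files plus all side tables.

    Outputs under ``outdir``: ``sam/<sample>.sam`` (coordinate-sorted),
    ``definitions.tsv`` (reference + variant-distinctive junctions of the
    toy model), ``clinical.tsv``, ``ar_expression.tsv`` and the truth
    tables.  Bit-reproducible for a fixed ``config.rng_seed``.
    """
    model = model or default_isoform_model()
    for v in config.variants:
        if v.name not in model.isoforms:
            raise ConfigError(f"variant {v.name!r} not in isoform model")
    outdir = Path(outdir)
    (outdir / "sam").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    cc = config.clinical
    treatments = list(cc.treatment_probs)

    canonical = model.canonical_junctions
    ref_junction = model.reference_junction
    distinctive = {
        v.name: model.distinctive_junction(v.name) for v in config.variants
    }

    sam_paths: dict[str, Path] = {}
    truth_rows, ref_rows, clin_rows, ar_rows = [], [], [], []

    for i in range(config.n_samples):
        sid = f"S{i:03d}"
        name_counter = iter(range(10**9))

        # --- clinical covariates -------------------------------------
        age = float(np.clip(np.round(rng.normal(cc.age_mean, cc.age_sd)),
                            cc.age_min, cc.age_max))
        indicators = {t: int(rng.random() < p) for t, p in cc.treatment_probs.items()}
        n_lines = int(min(cc.max_lines,
                          max(1, sum(indicators.values()) + rng.poisson(cc.extra_lines_lambda))))
        age_missing = rng.random() < cc.age_missing_rate
        block_missing = rng.random() < cc.missing_rate
        row = {"patient_id": sid, "age_at_biopsy": np.nan if age_missing else age,
               "n_treatment_lines": np.nan if block_missing else n_lines}
        for t in treatments:
            row[t] = np.nan if block_missing else indicators[t]
        clin_rows.append(row)

        # --- expression draws ----------------------------------------
        active = {v.name: bool(rng.random() < v.prevalence) for v in config.variants}
        fractions = {}
        for v in config.variants:
            f = v.fraction_pct
            for t, effects in config.treatment_effects.items():
                if indicators.get(t, 0) and v.name in effects:
                    f *= effects[v.name]
            fractions[v.name] = min(f, 100.0)
        depth_s = config.depth * (config.ar_positive_shift if any(active.values()) else 1.0)

        d, s, w = config.duplicate_rate, config.secondary_rate, config.wrong_strand_rate
        if config.duplicate_rate_variants is None:
            variant_rates = (d, s, w)
        else:
            dv = config.duplicate_rate_variants
            variant_rates = (dv, min(s, 1.0 - dv), 0.0)

        records: list[tuple] = []
        canon_qual = {}
        ref_drawn = 0
        for j in canonical:
            n = int(rng.poisson(depth_s))
            counts = _split_contamination(rng, n, d, s, w)
            canon_qual[j.key] = counts[0]
            if j == ref_junction:
                ref_drawn = n
            records.extend(_junction_records(sid, j, counts, name_counter, model.strand))
        ref_qual = canon_qual[ref_junction.key]

        # variant support is a binomial thinning of the pre-contamination
        # reference draw; equal contamination on both then cancels in the
        # ratio, so the configured fraction is recovered without bias
        for v in config.variants:
            if active[v.name]:
                drawn = int(rng.binomial(ref_drawn, fractions[v.name] / 100.0))
            else:
                drawn = 0
            counts = _split_contamination(rng, drawn, *variant_rates)
            records.extend(
                _junction_records(sid, distinctive[v.name], counts, name_counter, model.strand)
            )
            true_rel = 100.0 * counts[0] / ref_qual if ref_qual > 0 else np.nan
            truth_rows.append(
                {"sample": sid, "variant": v.name, "active": active[v.name],
                 "configured_fraction_pct": fractions[v.name] if active[v.name] else 0.0,
                 "drawn_reads": drawn, "qualifying_reads": counts[0],
                 "true_relative_expression_pct": true_rel,
                 "true_positive": bool(np.isfinite(true_rel)
                                       and true_rel >= config.positivity_threshold_pct)}
            )

        # --- noise junctions and unspliced reads ---------------------
        n_noise = int(rng.poisson(config.noise_junction_rate * depth_s))
        for _ in range(n_noise):
            donor = int(rng.integers(300, model.contig_length - 3000))
            acceptor = donor + int(rng.integers(80, 2000))
            j = SpliceJunction(model.chrom, donor, acceptor, model.strand)
            records.extend(
                _junction_records(sid, j, (1, 0, 0, 0), name_counter, model.strand)
            )
        n_unspliced = int(rng.poisson(config.unspliced_rate * depth_s))
        for _ in range(n_unspliced):
            pos0 = int(rng.integers(100, model.contig_length - 200))
            records.append((pos0, 99, "100M", model.strand, f"{sid}.r{next(name_counter)}"))

        sam_path = outdir / "sam" / f"{sid}.sam"
        _write_sam(sam_path, model, records)
        sam_paths[sid] = sam_path
        ref_rows.append({"sample": sid, "reference_qualifying_reads": ref_qual,
                         "depth": depth_s,
                         "any_variant_active": any(active.values())})
        ar_rows.append({"sample": sid,
                        "ar_expression": float(np.mean(list(canon_qual.values())))})

    per_sample = pd.DataFrame(truth_rows)
    reference = pd.DataFrame(ref_rows)
    per_cohort = (
        per_sample.groupby("variant", sort=False)
        .agg(n_active=("active", "sum"), n_true_positive=("true_positive", "sum"))
        .reset_index()
    )
    per_cohort["true_prevalence_pct"] = (
        100.0 * per_cohort["n_true_positive"] / config.n_samples
    )
    truth = SyntheticTruth(per_sample, reference, per_cohort, config.to_dict())
    truth.write(outdir)

    definitions_path = outdir / "definitions.tsv"
    model.definitions_frame().to_csv(definitions_path, sep="\t", index=False)
    clinical_path = outdir / "clinical.tsv"
    pd.DataFrame(clin_rows).to_csv(clinical_path, sep="\t", index=False)
    ar_path = outdir / "ar_expression.tsv"
    pd.DataFrame(ar_rows).to_csv(ar_path, sep="\t", index=False)
    return SimulationResult(outdir, sam_paths, definitions_path, clinical_path,
                            ar_path, truth, model)


def truth_recovery_report(truth: SyntheticTruth, relexpr) -> pd.DataFrame:
    """Per-variant recovery metrics of pipeline output against truth.

    Compares estimated relative expression and positivity calls with the
    simulator's realized ground truth: bias, RMSE and the positivity
    confusion counts.  Sample sets must match exactly.
    """
    est = relexpr.values
    truth_wide = truth.per_sample.pivot(
        index="sample", columns="variant", values="true_relative_expression_pct"
    )
    if set(est.index) != set(truth_wide.index):
        raise ValueError("sample identifiers of truth and pipeline output differ")
    pos = relexpr.positive
    true_pos = truth.per_sample.pivot(
        index="sample", columns="variant", values="true_positive"
    ).astype(bool)
    rows = []
    for v in truth_wide.columns:
        if v not in est.columns:
            continue
        t = truth_wide[v].reindex(est.index)
        e = est[v]
        ok = t.notna() & e.notna()
        diff = (e[ok] - t[ok]).to_numpy()
        tp = int((pos[v] & true_pos[v].reindex(est.index)).sum())
        fp = int((pos[v] & ~true_pos[v].reindex(est.index)).sum())
        fn = int((~pos[v] & true_pos[v].reindex(est.index)).sum())
        tn = int((~pos[v] & ~true_pos[v].reindex(est.index)).sum())
        rows.append({"variant": v, "n": int(ok.sum()),
                     "bias": float(diff.mean()) if len(diff) else np.nan,
                     "rmse": float(np.sqrt((diff ** 2).mean())) if len(diff) else np.nan,
                     "tp": tp, "fp": fp, "fn": fn, "tn": tn})
    return pd.DataFrame(rows)
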