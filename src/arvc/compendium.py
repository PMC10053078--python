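"""Cohort recurrence filtering and the variant compendium.

The compendium couples three things: the canonical exon1->exon2 reference
junction used as denominator for relative expression, the named variant
definitions with their distinctive junctions, and the set of junctions
that passed the cohort recurrence filter (>= ``min_reads`` strand-correct
spliced reads in >= ``min_samples`` samples).  Literature-supplied
variant definitions are always retained; recurrence is an annotation,
not a gate, so a variant seen in few samples still gets quantified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .junctions import SpliceJunction

__all__ = [
    "RecurrenceThresholds",
    "VariantDefinition",
    "Compendium",
    "recurrent_junctions",
    "read_definitions",
    "load_default_definitions",
    "build_compendium",
]

_ROLES = {"reference", "defining-primary", "defining-alternate", "none"}


@dataclass(frozen=True)
class RecurrenceThresholds:
    """Cohort recurrence filter: per-sample read support, then sample tally."""

    min_reads: int = 5
    min_samples: int = 10

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_samples < 1:
            raise ValueError("recurrence thresholds must be >= 1")


def recurrent_junctions(
    counts: pd.DataFrame,
    thresholds: RecurrenceThresholds = RecurrenceThresholds(),
    mode: str = "per-sample",
) -> set[SpliceJunction]:
    """Junctions passing the cohort recurrence filter.

    ``per-sample`` (default): a junction is retained iff the number of
    samples whose individual read support is >= ``min_reads`` reaches
    ``min_samples``.  ``cohort-total``: the alternative reading, summed
    support >= ``min_reads`` cohort-wide and any support in
    >= ``min_samples`` samples.
    """
    if mode not in {"per-sample", "cohort-total"}:
        raise ValueError(f"unknown recurrence mode {mode!r}")
    if counts.empty:
        return set()
    if mode == "per-sample":
        keep = (counts >= thresholds.min_reads).sum(axis=0) >= thresholds.min_samples
    else:
        keep = (counts.sum(axis=0) >= thresholds.min_reads) & (
            (counts >= 1).sum(axis=0) >= thresholds.min_samples
        )
    return {SpliceJunction.from_key(k) for k in counts.columns[keep]}


@dataclass(frozen=True)
class VariantDefinition:
    """A named AR-V and the junction(s) distinctive to it.

    ``defining_junctions`` is ordered: the first entry is the primary
    junction used for quantification; alternates are reported only.  A
    variant with no distinctive junction (AR-V11-style) is kept in the
    compendium but is not quantifiable.
    """

    name: str
    defining_junctions: tuple[SpliceJunction, ...] = ()
    source: str = "literature"
    genome_build: str = "GRCh37"

    @property
    def quantifiable(self) -> bool:
        return len(self.defining_junctions) > 0

    @property
    def primary_junction(self) -> SpliceJunction | None:
        return self.defining_junctions[0] if self.defining_junctions else None


@dataclass
class Compendium:
    """Reference junction + variant definitions + recurrence annotation."""

    reference_junction: SpliceJunction
    variants: list[VariantDefinition]
    recurrent_junctions: set[SpliceJunction] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variants]
        if len(set(names)) != len(names):
            raise ValueError("variant names must be unique within a compendium")
        for v in self.variants:
            if self.reference_junction in v.defining_junctions:
                raise ValueError(
                    f"variant {v.name} defines the reference junction itself"
                )

    def get(self, name: str) -> VariantDefinition:
        for v in self.variants:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def quantifiable_variants(self) -> list[VariantDefinition]:
        return [v for v in self.variants if v.quantifiable]

    def junction_is_recurrent(self, junction: SpliceJunction) -> bool:
        return junction in self.recurrent_junctions

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": "AR-reference",
                "chrom": self.reference_junction.chrom,
                "donor": self.reference_junction.donor,
                "acceptor": self.reference_junction.acceptor,
                "strand": self.reference_junction.strand,
                "role": "reference",
                "source": "canonical",
                "recurrent": self.reference_junction in self.recurrent_junctions,
            }
        ]
        for v in self.variants:
            if not v.defining_junctions:
                rows.append(
                    {
                        "name": v.name,
                        "chrom": "",
                        "donor": "",
                        "acceptor": "",
                        "strand": "",
                        "role": "none",
                        "source": v.source,
                        "recurrent": False,
                    }
                )
            for i, j in enumerate(v.defining_junctions):
                rows.append(
                    {
                        "name": v.name,
                        "chrom": j.chrom,
                        "donor": j.donor,
                        "acceptor": j.acceptor,
                        "strand": j.strand,
                        "role": "defining-primary" if i == 0 else "defining-alternate",
                        "source": v.source,
                        "recurrent": j in self.recurrent_junctions,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, tsv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if meta_path is not None:
            meta = dict(self.metadata)
            meta["n_recurrent_junctions"] = len(self.recurrent_junctions)
            meta["recurrent_junctions"] = sorted(j.key for j in self.recurrent_junctions)
            Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, tsv_path: str | Path) -> "Compendium":
        frame = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
        ref_rows = frame[frame["role"] == "reference"]
        if len(ref_rows) != 1:
            raise ValueError("compendium file must contain exactly one reference row")
        r = ref_rows.iloc[0]
        reference = SpliceJunction(r.chrom, int(r.donor), int(r.acceptor), r.strand)
        recurrent: set[SpliceJunction] = set()
        variants: list[VariantDefinition] = []
        for name, grp in frame[frame["role"] != "reference"].groupby("name", sort=False):
            juncs = []
            for row in grp.itertuples():
                if row.role == "none" or row.donor == "":
                    continue
                j = SpliceJunction(row.chrom, int(row.donor), int(row.acceptor), row.strand)
                juncs.append((row.role, j))
                if str(row.recurrent) in {"True", "true", "1"}:
                    recurrent.add(j)
            juncs.sort(key=lambda t: t[0] != "defining-primary")
            source = grp.iloc[0]["source"] if "source" in grp.columns else "literature"
            variants.append(
                VariantDefinition(str(name), tuple(j for _, j in juncs), source=source)
            )
        if str(ref_rows.iloc[0].get("recurrent", "")) in {"True", "true", "1"}:
            recurrent.add(reference)
        return cls(reference, variants, recurrent)


def read_definitions(
    path: str | Path,
) -> tuple[list[VariantDefinition], SpliceJunction | None]:
    """Load a variant-definition TSV.

    Schema: name, chrom, donor, acceptor, strand, genome_build, role with
    role in {reference, defining-primary, defining-alternate, none}.  A
    row with role=none (or empty coordinates) declares a variant with no
    usable distinctive junction.  Returns (definitions, reference
    junction or None).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"name", "chrom", "donor", "acceptor", "strand", "role"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"definitions file missing columns: {sorted(missing)}")
    bad_roles = set(frame["role"]) - _ROLES
    if bad_roles:
        raise ValueError(f"unknown roles in definitions file: {sorted(bad_roles)}")

    reference: SpliceJunction | None = None
    ref_rows = frame[frame["role"] == "reference"]
    if len(ref_rows) > 1:
        raise ValueError("definitions file declares more than one reference junction")
    if len(ref_rows) == 1:
        r = ref_rows.iloc[0]
        reference = SpliceJunction(r.chrom, int(r.donor), int(r.acceptor), r.strand)

    definitions: list[VariantDefinition] = []
    body = frame[frame["role"] != "reference"]
    for name, grp in body.groupby("name", sort=False):
        primaries = grp[grp["role"] == "defining-primary"]
        if len(primaries) > 1:
            raise ValueError(f"variant {name!r} has multiple defining-primary rows")
        juncs: list[SpliceJunction] = []
        for row in grp.itertuples():
            if row.role == "none" or row.donor == "" or row.acceptor == "":
                continue
            juncs.append(
                SpliceJunction(row.chrom, int(row.donor), int(row.acceptor), row.strand)
            )
        if len(primaries) == 1 and juncs:
            p = primaries.iloc[0]
            pj = SpliceJunction(p.chrom, int(p.donor), int(p.acceptor), p.strand)
            juncs.sort(key=lambda j: j != pj)
        build = grp.iloc[0]["genome_build"] if "genome_build" in grp.columns else ""
        definitions.append(
            VariantDefinition(str(name), tuple(juncs), genome_build=build or "GRCh37")
        )
    return definitions, reference


def load_default_definitions() -> tuple[list[VariantDefinition], SpliceJunction]:
    """The bundled GRCh37 definitions table.

    Carries the canonical AR exon1->exon2 reference junction plus
    placeholder rows for the literature variant set; coordinates for the
    variant-distinctive junctions must be supplied by the user (the table
    is deliberately editable), so the bundled variants load as
    non-quantifiable.
    """
    with resources.as_file(
        resources.files("arvc.data") / "ar_variants_grch37.tsv"
    ) as path:
        definitions, reference = read_definitions(path)
    assert reference is not None
    return definitions, reference


def build_compendium(
    recurrent: set[SpliceJunction],
    definitions: list[VariantDefinition] | str | Path,
    reference_junction: SpliceJunction,
    metadata: dict | None = None,
) -> Compendium:
    """Merge recurrence-filtered junctions with variant definitions.

    Every literature definition is included regardless of recurrence;
    whether each defining junction passed the filter is carried as an
    annotation on the compendium.  Definitions may be given as a parsed
    list or as a path to a definitions TSV.
    """
    if isinstance(definitions, (str, Path)):
        definitions, file_ref = read_definitions(definitions)
        if file_ref is not None and file_ref != reference_junction:
            raise ValueError(
                "reference junction in definitions file disagrees with the one supplied"
            )
    return Compendium(
        reference_junction=reference_junction,
        variants=list(definitions),
        recurrent_junctions=set(recurrent),
        metadata=metadata or {},
    )
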