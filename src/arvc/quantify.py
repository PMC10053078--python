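"""Relative expression of splice variants against the canonical junction.

For sample ``s`` and quantifiable variant ``v`` the relative expression
is

    y(s, v) = 100 * SJ_x(s, v) / SJ_E1E2(s)          [percent]

where ``SJ_x`` is the read support of the variant's primary distinctive
junction and ``SJ_E1E2`` the support of the canonical exon1->exon2
reference junction.  Samples without any reference support have
undefined (NaN) relative expression — distinct from 0%, which means the
reference was seen but the variant junction was not.  A sample is called
positive for a variant when its relative expression reaches the
positivity threshold (default >= 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compendium import Compendium

__all__ = ["RelativeExpressionMatrix", "relative_expression", "call_positive"]


@dataclass
class RelativeExpressionMatrix:
    """Samples x variants relative-expression percentages with support counts.

    ``values`` holds percentages (NaN = undefined, i.e. zero reference
    support); ``sj_variant`` the variant-junction support counts;
    ``sj_reference`` the per-sample reference-junction support;
    ``exempt`` the names of non-quantifiable variants (no distinctive
    junction), which never appear in ``values``.
    """

    values: pd.DataFrame
    sj_variant: pd.DataFrame
    sj_reference: pd.Series
    threshold_pct: float = 1.0
    exempt: tuple[str, ...] = ()

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def variants(self) -> list[str]:
        return list(self.values.columns)

    @property
    def positive(self) -> pd.DataFrame:
        """Positivity flags; undefined cells are never positive."""
        with np.errstate(invalid="ignore"):
            return (self.values >= self.threshold_pct).fillna(False)

    def status(self, sample: str, variant: str) -> str:
        if variant in self.exempt:
            return "exempt"
        if pd.isna(self.values.at[sample, variant]):
            return "undefined"
        return "ok"

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format report: one row per (sample, variant), exempt included."""
        rows = []
        pos = self.positive
        for s in self.samples:
            ref = int(self.sj_reference[s])
            for v in self.variants:
                val = self.values.at[s, v]
                rows.append(
                    {
                        "sample": s,
                        "variant": v,
                        "sj_variant": int(self.sj_variant.at[s, v]),
                        "sj_reference": ref,
                        "relative_expression_pct": val,
                        "positive": bool(pos.at[s, v]),
                        "status": "undefined" if pd.isna(val) else "ok",
                    }
                )
            for v in self.exempt:
                rows.append(
                    {
                        "sample": s,
                        "variant": v,
                        "sj_variant": 0,
                        "sj_reference": ref,
                        "relative_expression_pct": np.nan,
                        "positive": False,
                        "status": "exempt",
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path, threshold_pct: float = 1.0) -> "RelativeExpressionMatrix":
        long = pd.read_csv(path, sep="\t")
        exempt = tuple(sorted(long.loc[long["status"] == "exempt", "variant"].unique()))
        body = long[long["status"] != "exempt"]
        values = body.pivot(index="sample", columns="variant", values="relative_expression_pct")
        sj_v = body.pivot(index="sample", columns="variant", values="sj_variant").astype(int)
        ref = (
            long.drop_duplicates("sample").set_index("sample")["sj_reference"].astype(int)
        )
        order = long["sample"].drop_duplicates().tolist()
        vorder = body["variant"].drop_duplicates().tolist()
        return cls(
            values.loc[order, vorder],
            sj_v.loc[order, vorder],
            ref.loc[order],
            threshold_pct=threshold_pct,
            exempt=exempt,
        )


def relative_expression(
    counts: pd.DataFrame,
    compendium: Compendium,
    threshold_pct: float = 1.0,
) -> RelativeExpressionMatrix:
    """Compute the relative-expression matrix for all quantifiable variants.

    ``counts`` is the samples x junction-keys support matrix.  Junctions
    absent from the matrix simply have zero support everywhere.
    """
    counts = counts.set_axis(counts.index.rename("sample"), axis=0)
    ref_key = compendium.reference_junction.key
    if ref_key in counts.columns:
        ref = counts[ref_key].astype(int)
    else:
        ref = pd.Series(0, index=counts.index, dtype=int)
    ref = ref.rename("sj_reference")

    quant = compendium.quantifiable_variants
    sj_v = pd.DataFrame(index=counts.index, dtype=int)
    for v in quant:
        key = v.primary_junction.key
        sj_v[v.name] = counts[key].astype(int) if key in counts.columns else 0
    exempt = tuple(v.name for v in compendium.variants if not v.quantifiable)

    denom = ref.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 100.0 * sj_v.to_numpy(dtype=float) / denom[:, None]
    vals[denom == 0.0, :] = np.nan
    values = pd.DataFrame(
        vals, index=counts.index, columns=sj_v.columns.rename("variant")
    )
    sj_v.columns = sj_v.columns.rename("variant")
    return RelativeExpressionMatrix(values, sj_v, ref, threshold_pct, exempt)


def call_positive(
    matrix: RelativeExpressionMatrix,
    threshold_pct: float | None = None,
    exclude_undefined: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positivity flags plus per-variant prevalence.

    Prevalence is reported out of all samples by default (undefined
    samples count in the denominator as non-positive); with
    ``exclude_undefined`` the denominator drops samples whose relative
    expression is undefined for that variant.  Percentages are rounded
    to the nearest integer at report time only.
    """
    thr = matrix.threshold_pct if threshold_pct is None else threshold_pct
    with np.errstate(invalid="ignore"):
        flags = (matrix.values >= thr).fillna(False)
    n_pos = flags.sum(axis=0).astype(int)
    if exclude_undefined:
        n_total = matrix.values.notna().sum(axis=0).astype(int)
    else:
        n_total = pd.Series(len(matrix.samples), index=flags.columns, dtype=int)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * n_pos / n_total.replace(0, np.nan)
    prevalence = pd.DataFrame(
        {
            "n_positive": n_pos,
            "n_total": n_total,
            "prevalence_pct": np.where(pct.isna(), np.nan, np.rint(pct)),
        }
    )
    prevalence.index.name = "variant"
    return flags, prevalence
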