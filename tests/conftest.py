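"""Shared fixtures: hand-crafted SAM writing and small simulated cohorts."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from arvc.simulate import SimulationConfig, simulate_cohort

TOY_CHROM = "chrT"
TOY_LEN = 20000


def write_sam(path: Path, records, chrom: str = TOY_CHROM, length: int = TOY_LEN) -> Path:
    """Write SAM from (pos0, flag, cigar, xs_or_None[, qname]) tuples."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": chrom, "LN": length}]}
    )
    rows = []
    for i, rec in enumerate(records):
        pos0, flag, cigar, xs = rec[:4]
        qname = rec[4] if len(rec) > 4 else f"r{i}"
        rows.append((pos0, flag, cigar, xs, qname))
    rows.sort(key=lambda r: r[0])
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pos0, flag, cigar, xs, qname in rows:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = cigar
            n_match = 0
            num = ""
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                else:
                    if ch in "MIS=X":
                        n_match += int(num)
                    num = ""
            a.query_sequence = "A" * n_match
            a.next_reference_id = 0
            a.next_reference_start = pos0
            if xs is not None:
                a.set_tag("XS", xs)
            out.write(a)
    return path


@pytest.fixture
def sam_factory(tmp_path):
    def _make(records, name="reads.sam", **kw):
        return write_sam(tmp_path / name, records, **kw)

    return _make


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A seeded 15-sample cohort reused by the slower end-to-end tests."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    config = SimulationConfig(n_samples=15, depth=120.0, rng_seed=42,
                              ar_positive_shift=1.4)
    result = simulate_cohort(config, outdir)
    return config, result
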