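"""Targeted-capture arithmetic: theoretical coverage and fold enrichment.

Theoretical per-sample coverage of a region is

    (aligned reads x bp per read pair) / (n_samples x region size in bp)

with 150 bp of aligned sequence per read pair by default (75 bp per end);
fold enrichment is the ratio of target coverage to whole-reference
coverage, taken on the unrounded values. Published summaries of this kind
mix truncation and rounding cell by cell, so the report layer exposes both
renderings (``coverage_truncated``, ``enrichment_truncated``,
``enrichment_rounded``) and never rounds the underlying math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CaptureExperiment:
    """Inputs of a capture-enrichment summary (read counts are opaque tallies
    of aligned reads; the bp-per-pair constant fixes the arithmetic)."""

    aligned_reads_total: int
    aligned_reads_target: int
    aligned_reads_target_masked: int
    n_samples: int
    reference_size_bp: float
    target_size_bp: float
    target_masked_size_bp: float
    bp_per_read_pair: float = 150.0

    def __post_init__(self) -> None:
        for name in (
            "aligned_reads_total", "aligned_reads_target",
            "aligned_reads_target_masked", "n_samples", "reference_size_bp",
            "target_size_bp", "target_masked_size_bp", "bp_per_read_pair",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.target_size_bp > self.reference_size_bp:
            raise ValueError("target size exceeds reference size")
        if self.target_masked_size_bp > self.target_size_bp:
            raise ValueError("masked target size exceeds total target size")


def theoretical_coverage(
    reads: float, bp_per_read_pair: float, n_samples: int, region_size_bp: float
) -> float:
    """Fold coverage per sample implied by a read tally over a region."""
    if reads <= 0:
        raise ValueError("read count must be positive")
    denom = n_samples * region_size_bp
    if denom <= 0:
        raise ValueError("n_samples x region size must be positive")
    return (reads * bp_per_read_pair) / denom


def enrichment(cov_target: float, cov_reference: float) -> float:
    """Fold enrichment: target coverage over reference coverage, unrounded."""
    if cov_reference <= 0:
        raise ValueError("reference coverage must be positive")
    return cov_target / cov_reference


def truncate(x: float, decimals: int = 0) -> float:
    """Truncate toward zero at the given number of decimals."""
    f = 10 ** decimals
    return math.trunc(x * f) / f


def capture_summary(exp: CaptureExperiment) -> pd.DataFrame:
    """Three-row coverage/enrichment summary (reference, target total,
    target masked) with raw values and both reporting renderings."""
    cov_ref = theoretical_coverage(
        exp.aligned_reads_total, exp.bp_per_read_pair, exp.n_samples,
        exp.reference_size_bp,
    )
    cov_tgt = theoretical_coverage(
        exp.aligned_reads_target, exp.bp_per_read_pair, exp.n_samples,
        exp.target_size_bp,
    )
    cov_msk = theoretical_coverage(
        exp.aligned_reads_target_masked, exp.bp_per_read_pair, exp.n_samples,
        exp.target_masked_size_bp,
    )
    rows = [
        {
            "region": "reference",
            "size_bp": exp.reference_size_bp,
            "aligned_reads": exp.aligned_reads_total,
            "coverage": cov_ref,
            "coverage_truncated": f"{truncate(cov_ref, 2):.2f}",
            "enrichment": float("nan"),
            "enrichment_truncated": "",
            "enrichment_rounded": "",
        }
    ]
    for region, size, reads, cov in (
        ("target_total", exp.target_size_bp, exp.aligned_reads_target, cov_tgt),
        ("target_masked", exp.target_masked_size_bp,
         exp.aligned_reads_target_masked, cov_msk),
    ):
        enr = enrichment(cov, cov_ref)
        rows.append(
            {
                "region": region,
                "size_bp": size,
                "aligned_reads": reads,
                "coverage": cov,
                "coverage_truncated": f"{int(truncate(cov))}",
                "enrichment": enr,
                "enrichment_truncated": f"{int(truncate(enr))}",
                "enrichment_rounded": f"{round(enr)}",
            }
        )
    return pd.DataFrame(rows)
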