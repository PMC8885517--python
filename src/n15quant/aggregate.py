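"""Protein-level statistics, normalization, and per-channel FDR accounting.

Peptide L/H ratios belonging to one protein are summarized by quartiles
computed in log space (any base gives the identical result after
back-transforming) — the median resists the outlier ratios that co-elution
produces, and a tight Q1–Q3 range signals a reliable quantification. Since
samples are never mixed at exactly 1:1, every ratio is divided by the median
ratio of the most abundant proteins (top 100 by default) or of named
housekeeping proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .quant import PeptideQuant
from .spectra_io import IdRecord

__all__ = ["ProteinQuant", "protein_stats", "aggregate_proteins", "normalize", "fdr_split"]

#: Q3/Q1 spread beyond which a protein is flagged as wide-IQR
WIDE_IQR_FOLD = 4.0


@dataclass
class ProteinQuant:
    """Per-protein Q1/median/Q3 of peptide L/H ratios (linear scale)."""

    accession: str
    n_peptide_quants: int
    q1: float | None = None
    median: float | None = None
    q3: float | None = None
    normalized_median: float | None = None
    total_intensity: float = 0.0
    flags: list[str] = field(default_factory=list)


def _finite_ratios(quants: Iterable[PeptideQuant], exclude_low_cs: bool) -> list[float]:
    out = []
    for q in quants:
        if exclude_low_cs and any(f.startswith("low_cs") for f in q.flags):
            continue
        r = q.ratio_LH
        if r is not None and np.isfinite(r) and r > 0:
            out.append(r)
    return out


def protein_stats(
    accession: str,
    quants: Sequence[PeptideQuant],
    exclude_low_cs: bool = False,
) -> ProteinQuant:
    """Quartiles of one protein's peptide ratios, computed on log ratios.

    Only finite positive ratios enter the statistics; one-sided sentinels
    (0, inf) and absent pairs are excluded since log-space statistics cannot
    absorb them — they remain visible in the peptide report. A protein with
    no finite ratio is reported with sentinel (None) statistics rather than
    dropped.
    """
    ratios = _finite_ratios(quants, exclude_low_cs)
    pq = ProteinQuant(
        accession=accession,
        n_peptide_quants=len(quants),
        total_intensity=float(sum(q.total_intensity for q in quants)),
    )
    if not ratios:
        pq.flags.append("no_finite_ratios")
        return pq
    logs = np.log10(ratios)
    q1, med, q3 = np.percentile(logs, [25.0, 50.0, 75.0])
    pq.q1, pq.median, pq.q3 = float(10**q1), float(10**med), float(10**q3)
    if pq.q3 / pq.q1 > WIDE_IQR_FOLD:
        pq.flags.append("wide_iqr")
    return pq


def aggregate_proteins(
    quants: Sequence[PeptideQuant],
    exclude_low_cs: bool = False,
) -> list[ProteinQuant]:
    """Group peptide quantifications by accession and compute protein stats."""
    groups: dict[str, list[PeptideQuant]] = {}
    order: list[str] = []
    for q in quants:
        acc = q.id_record.protein
        if acc not in groups:
            groups[acc] = []
            order.append(acc)
        groups[acc].append(q)
    return [protein_stats(acc, groups[acc], exclude_low_cs) for acc in order]


def normalize(
    proteins: Sequence[ProteinQuant],
    top_n: int = 100,
    rank_by: str = "total_intensity",
    housekeeping: Sequence[str] | None = None,
) -> float:
    """Divide every protein's ratios by a mixing-correction factor, in place.

    The factor is the median of the medians of the ``top_n`` most abundant
    quantified proteins (abundance ranked by summed cluster intensity across
    both channels, or by peptide count) — or, alternatively, the median of
    named housekeeping proteins assumed unchanged. Returns the factor.
    """
    if not proteins:
        raise ValueError("empty protein table")
    with_stats = [p for p in proteins if p.median is not None]
    if not with_stats:
        raise ValueError("no protein has a finite median to normalize on")
    if housekeeping is not None:
        wanted = set(housekeeping)
        ref = [p for p in with_stats if p.accession in wanted]
        if not ref:
            raise ValueError(f"none of the housekeeping accessions {sorted(wanted)} quantified")
    else:
        if rank_by == "total_intensity":
            keyfun = lambda p: p.total_intensity
        elif rank_by == "peptide_count":
            keyfun = lambda p: p.n_peptide_quants
        else:
            raise ValueError("rank_by must be 'total_intensity' or 'peptide_count'")
        if len(with_stats) < top_n:
            warnings.warn(
                f"only {len(with_stats)} quantified proteins available for the "
                f"top-{top_n} normalization; using all of them",
                stacklevel=2,
            )
        ref = sorted(with_stats, key=keyfun, reverse=True)[:top_n]
    factor = float(np.median([p.median for p in ref]))
    for p in proteins:
        if p.median is not None:
            p.normalized_median = p.median / factor
    return factor


def fdr_split(records: Sequence[IdRecord]) -> dict[str, float | None]:
    """Per-channel peptide-level FDR: decoy / target matches, in percent.

    ¹⁴N and ¹⁵N searches are pooled during thresholding but their error
    rates differ, so targets and decoys are parsed per channel and the FDR
    is computed separately. A channel with zero targets gets ``None``.
    """
    out: dict[str, float | None] = {}
    for channel in ("light", "heavy"):
        targets = sum(1 for r in records if r.channel == channel and not r.decoy)
        decoys = sum(1 for r in records if r.channel == channel and r.decoy)
        out[channel] = None if targets == 0 else 100.0 * decoys / targets
    return out
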