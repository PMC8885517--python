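"""Labeling-efficiency estimation from observed heavy-peptide clusters.

The M−1/M abundance ratio of a heavy cluster is a sensitive, monotone
readout of the ¹⁵N incorporation fraction p: each percent of residual ¹⁴N
adds roughly n_labeled × 1% of M to the M−1 satellite. Inverting the
theoretical curve for a handful of confidently identified peptides (8–10
from different proteins is plenty, since incorporation is constant within an
experiment) yields the experiment-wide efficiency to feed into
quantification. Small peptides (monoisotopic mass < 1500 Da) are preferred:
their M peak is the cluster maximum, so the ratio is easy to read and far
from the regime where satellites swamp the cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import chemcore, isotopes
from .chemcore import ElementalComposition, HEAVY
from .spectra_io import IdRecord, Scan, average_scans, match_peak

__all__ = [
    "MeasuredCluster",
    "EfficiencyEstimate",
    "invert_efficiency",
    "estimate_experiment_efficiency",
    "measure_clusters",
]

#: bisection bracket: enrichments below 50% belong to turnover-style studies
#: where light and heavy clusters overlap and this workflow does not apply
P_BRACKET = (0.5, 0.9999)


@dataclass(frozen=True)
class MeasuredCluster:
    """Observed M−1 and M of one heavy peptide plus its composition."""

    peptide_id: str
    composition: ElementalComposition
    intensity_m_minus_1: float
    intensity_m: float

    @property
    def m1_over_m(self) -> float:
        if self.intensity_m <= 0:
            raise ValueError(f"{self.peptide_id}: M intensity must be > 0")
        return self.intensity_m_minus_1 / self.intensity_m


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Experiment-wide enrichment: mean of per-peptide inversions plus spread."""

    p_hat: float
    sd: float
    per_peptide: tuple[tuple[str, float, float], ...]  # (id, observed ratio, p)
    n_peptides: int


def invert_efficiency(observed_m1_over_m: float, comp: ElementalComposition) -> float:
    """Solve m1_over_m(comp, p) = observed for p by bisection.

    The ratio is strictly decreasing in p, so the root in [0.5, 0.9999] is
    unique; observations outside the attainable range are clamped to the
    bracket edge with a warning.
    """
    if not np.isfinite(observed_m1_over_m):
        raise ValueError(f"observed M-1/M ratio must be finite, got {observed_m1_over_m}")
    if observed_m1_over_m < 0:
        raise ValueError("observed M-1/M ratio must be >= 0")
    lo, hi = P_BRACKET
    f = lambda p: isotopes.m1_over_m(comp, p) - observed_m1_over_m
    if f(hi) >= 0:  # observed at or below the ratio of near-complete labeling
        if f(hi) > 0:
            warnings.warn(
                f"observed M-1/M {observed_m1_over_m:.4g} below the theoretical "
                f"minimum; clamping enrichment to {hi}",
                stacklevel=2,
            )
        return hi
    if f(lo) <= 0:
        warnings.warn(
            f"observed M-1/M {observed_m1_over_m:.4g} above the ratio at 50% "
            f"enrichment; clamping to {lo} (outside this workflow's validity)",
            stacklevel=2,
        )
        return lo
    return float(brentq(f, lo, hi, xtol=1e-5))


def estimate_experiment_efficiency(
    clusters: Sequence[MeasuredCluster],
    max_mass: float | None = 1500.0,
) -> EfficiencyEstimate:
    """Invert each cluster's M−1/M and average across peptides.

    ``max_mass`` keeps only peptides below the given monoisotopic mass
    (default 1500 Da, the small-peptide preference); if that filter would
    discard everything, all clusters are used with a warning. The standard
    deviation is reported so non-constant labeling is visible.
    """
    if not clusters:
        raise ValueError("need at least one measured cluster")
    selected = list(clusters)
    if max_mass is not None:
        small = [c for c in selected if chemcore.monoisotopic_mass(c.composition, HEAVY) < max_mass]
        if small:
            selected = small
        else:
            warnings.warn(
                f"no cluster below {max_mass} Da; using all {len(selected)} clusters",
                stacklevel=2,
            )
    per = []
    for c in selected:
        p = invert_efficiency(c.m1_over_m, c.composition)
        per.append((c.peptide_id, c.m1_over_m, p))
    ps = np.array([p for _, _, p in per])
    return EfficiencyEstimate(
        p_hat=float(ps.mean()),
        sd=float(ps.std(ddof=1)) if ps.size > 1 else 0.0,
        per_peptide=tuple(per),
        n_peptides=len(per),
    )


def measure_clusters(
    records: Sequence[IdRecord],
    scans: Sequence[Scan],
    rt_window: tuple[float, float] = (-5.0, 15.0),
    resolution: float = 240000.0,
) -> list[MeasuredCluster]:
    """Measure M−1 and M for heavy-channel identifications directly from MS¹.

    Peak positions are predicted at an assumed high enrichment; the positions
    of M and M−1 do not depend on p, only their intensities do.
    """
    out = []
    for r in records:
        if r.channel != "heavy" or r.decoy:
            continue
        ion = chemcore.PeptideIon(
            r.sequence, chemcore.parse_modifications(r.modifications), r.charge, "heavy"
        )
        comp = chemcore.build_composition(ion)
        mono_mz = chemcore.mz(comp, HEAVY)
        sl = average_scans(scans, r.rt_seconds, rt_window, resolution)
        m = match_peak(sl, mono_mz, resolution)
        m1 = match_peak(sl, mono_mz - chemcore.DELTA_15N / r.charge, resolution)
        if m.intensity > 0:
            out.append(
                MeasuredCluster(
                    peptide_id=f"{r.sequence}/{r.charge}",
                    composition=comp,
                    intensity_m_minus_1=m1.intensity,
                    intensity_m=m.intensity,
                )
            )
    return out
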