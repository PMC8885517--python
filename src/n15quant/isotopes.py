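"""Aggregated isotopologue envelopes at arbitrary ¹⁵N enrichment.

A peptide's isotope cluster at Orbitrap resolution is a unit-spaced comb of
peaks: isotopologues aggregated by nominal mass, with the ¹³C/¹⁵N/¹⁸O fine
structure unresolved. For a heavy-labeled peptide at enrichment p each of the
``n_labeled_N`` nitrogens is ¹⁵N with probability p independently, so the
labeled pool contributes a Binomial(n, 1−p) number of residual ¹⁴N atoms —
the satellite peaks M−1, M−2, … below the fully-labeled monoisotopic peak M.
All other atoms (C, H, O, S and unlabeled N) contribute the familiar
natural-abundance shoulder at M+1, M+2, …

Offsets are anchored at the fully-labeled monoisotopic species for the heavy
channel (so incomplete labeling shows up as negative offsets) and at the
ordinary monoisotopic peak for the light channel.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .chemcore import ELEMENTS, HEAVY, LIGHT, MASS_PROTON, ElementalComposition

__all__ = [
    "IsotopeEnvelope",
    "envelope",
    "brute_force_envelope",
    "fraction_in_mono",
    "m1_over_m",
]

#: per-convolution-step truncation of negligible isotopologue mass bins
_STEP_TRUNC = 1e-12
#: envelope bins are kept (by descending abundance) until this total is covered
_COVERAGE = 1.0 - 1e-6


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Unit-mass envelope: relative abundance and centroid m/z per offset.

    ``offsets`` are integer nominal-mass positions relative to the
    monoisotopic peak M (negative = satellites from incomplete labeling),
    strictly increasing. ``abundances`` are sum-normalized to 1.
    ``centroid_mz`` is the abundance-weighted exact m/z of each bin at the
    composition's charge (neutral mass if uncharged).
    """

    offsets: np.ndarray
    abundances: np.ndarray
    centroid_mz: np.ndarray
    enrichment: float
    charge: int

    def abundance_at(self, offset: int) -> float:
        idx = np.nonzero(self.offsets == offset)[0]
        return float(self.abundances[idx[0]]) if idx.size else 0.0

    def vector(self, offsets=(0, 1, 2)) -> np.ndarray:
        """Abundances at the given offsets (0 where absent)."""
        return np.array([self.abundance_at(k) for k in offsets])

    def normalized(self, mode: str = "sum") -> np.ndarray:
        """Abundances normalized to unit sum, or to the largest peak = 100."""
        if mode == "sum":
            return self.abundances / self.abundances.sum()
        if mode == "max":
            return 100.0 * self.abundances / self.abundances.max()
        raise ValueError("mode must be 'sum' or 'max'")


def _single_atom(isotopes, nominal_anchor: int) -> tuple[int, np.ndarray, np.ndarray]:
    """(min_offset, abundance array, mass-moment array) for one atom."""
    offs = [iso.mass_number - nominal_anchor for iso in isotopes]
    lo, hi = min(offs), max(offs)
    a = np.zeros(hi - lo + 1)
    m = np.zeros(hi - lo + 1)
    for iso, k in zip(isotopes, offs):
        a[k - lo] += iso.abundance
        m[k - lo] += iso.abundance * iso.mass
    return lo, a, m


def _convolve(d1, d2):
    """Convolve two (min_offset, abundance, moment) distributions.

    The moment array carries sum(abundance × mass) per bin, so for a product
    of independent atoms M[k] = Σ A1[i]·M2[k−i] + M1[i]·A2[k−i].
    """
    lo1, a1, m1 = d1
    lo2, a2, m2 = d2
    a = np.convolve(a1, a2)
    m = np.convolve(a1, m2) + np.convolve(m1, a2)
    lo = lo1 + lo2
    keep = np.nonzero(a > _STEP_TRUNC)[0]
    if keep.size:
        a_sum_kept = a[keep[0] : keep[-1] + 1]
        return lo + keep[0], a_sum_kept, m[keep[0] : keep[-1] + 1]
    return lo, a, m


def _atom_power(dist, n):
    """n-fold self-convolution by binary powering."""
    result = (0, np.array([1.0]), np.array([0.0]))
    base = dist
    while n:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


def _labeled_n_dist(p: float):
    """Single labeled nitrogen: ¹⁵N with prob p at offset 0, ¹⁴N at −1."""
    n14, n15 = ELEMENTS["N"]
    a = np.array([1.0 - p, p])
    m = np.array([(1.0 - p) * n14.mass, p * n15.mass])
    return -1, a, m


def envelope(
    comp: ElementalComposition, p: float, channel: str = HEAVY
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of a composition at enrichment ``p``.

    Natural-abundance polynomial convolution over C, H, O, S and unlabeled N,
    convolved (heavy channel) with the Binomial(n_labeled_N, p) distribution
    of residual ¹⁴N among labeled nitrogens. The light channel treats every
    nitrogen at natural abundance and ``p`` is irrelevant.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"enrichment p={p} outside [0, 1]")
    dist = (0, np.array([1.0]), np.array([0.0]))
    z = comp.charge_protons
    for el, n in sorted(comp.counts.items()):
        if el == "N":
            continue
        n_atoms = n - (z if el == "H" else 0)  # charge protons have no isotopes
        if n_atoms:
            dist = _convolve(dist, _atom_power(_single_atom(ELEMENTS[el], ELEMENTS[el][0].mass_number), n_atoms))
    n14, n15 = ELEMENTS["N"]
    n_natural = comp.counts.get("N", 0) if channel == LIGHT else comp.n_unlabeled_N
    n_labeled = 0 if channel == LIGHT else comp.n_labeled_N
    if n_natural:
        dist = _convolve(dist, _atom_power(_single_atom(ELEMENTS["N"], n14.mass_number), n_natural))
    if n_labeled:
        dist = _convolve(dist, _atom_power(_labeled_n_dist(p), n_labeled))
    return _finalize(dist, p, z)


def _finalize(dist, p: float, z: int) -> IsotopeEnvelope:
    lo, a, m = dist
    # keep the most abundant bins until 1 - 1e-6 of the mass is covered
    order = np.argsort(a)[::-1]
    cum = np.cumsum(a[order])
    n_keep = int(np.searchsorted(cum, _COVERAGE * a.sum())) + 1
    keep = np.sort(order[:n_keep])
    offsets = lo + keep
    abundances = a[keep]
    centroid_mass = m[keep] / abundances
    abundances = abundances / abundances.sum()
    if z >= 1:
        # charge protons were excluded from the H convolution; add them back
        centroid = (centroid_mass + z * MASS_PROTON) / z
    else:
        centroid = centroid_mass
    return IsotopeEnvelope(
        offsets=offsets.astype(int),
        abundances=abundances,
        centroid_mz=centroid,
        enrichment=p,
        charge=z,
    )


def brute_force_envelope(
    comp: ElementalComposition, p: float, channel: str = HEAVY
) -> IsotopeEnvelope:
    """Exact enumeration oracle for :func:`envelope` (≤ 12 atoms).

    Enumerates, per element, every partition of its atoms over the element's
    isotopes with exact multinomial probabilities, then every combination of
    per-element partitions, aggregated by nominal mass. Independent of the
    convolution path; used to validate it on small compositions.
    """
    z = comp.charge_protons
    n_atoms_total = sum(comp.counts.values()) - z
    if n_atoms_total > 12:
        raise ValueError(f"brute force limited to 12 atoms, got {n_atoms_total}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"enrichment p={p} outside [0, 1]")

    def partitions(n, k):
        if k == 1:
            yield (n,)
            return
        for first in range(n + 1):
            for rest in partitions(n - first, k - 1):
                yield (first,) + rest

    element_terms = []  # per element: list of (nominal_offset_sum, prob, mass_sum)
    n_labeled = 0 if channel == LIGHT else comp.n_labeled_N
    for el, n in sorted(comp.counts.items()):
        n_nat = n - (z if el == "H" else 0)
        if el == "N":
            n_nat = comp.counts.get("N", 0) - n_labeled
        if n_nat == 0:
            continue
        isotopes = ELEMENTS[el]
        anchor = isotopes[0].mass_number
        terms = []
        for part in partitions(n_nat, len(isotopes)):
            prob = math.factorial(n_nat)
            off = 0
            mass = 0.0
            for count, iso in zip(part, isotopes):
                prob //= math.factorial(count)
            prob = float(prob)
            for count, iso in zip(part, isotopes):
                prob *= iso.abundance**count
                off += count * (iso.mass_number - anchor)
                mass += count * iso.mass
            terms.append((off, prob, mass))
        element_terms.append(terms)
    if n_labeled:
        n14, n15 = ELEMENTS["N"]
        terms = []
        for k14 in range(n_labeled + 1):  # k14 residual 14N atoms -> offset -k14
            prob = math.comb(n_labeled, k14) * (1 - p) ** k14 * p ** (n_labeled - k14)
            mass = k14 * n14.mass + (n_labeled - k14) * n15.mass
            terms.append((-k14, prob, mass))
        element_terms.append(terms)

    agg_a: dict[int, float] = {}
    agg_m: dict[int, float] = {}
    for combo in itertools.product(*element_terms) if element_terms else [()]:
        off = sum(t[0] for t in combo)
        prob = math.prod(t[1] for t in combo)
        mass = sum(t[2] for t in combo)
        agg_a[off] = agg_a.get(off, 0.0) + prob
        agg_m[off] = agg_m.get(off, 0.0) + prob * mass
    lo, hi = min(agg_a), max(agg_a)
    a = np.zeros(hi - lo + 1)
    m = np.zeros(hi - lo + 1)
    for k, prob in agg_a.items():
        a[k - lo] = prob
        m[k - lo] = agg_m[k]
    return _finalize((lo, a, m), p, z)


def fraction_in_mono(
    comp: ElementalComposition, p: float, channel: str = HEAVY
) -> float:
    """Fraction of the total isotope cluster sitting in the monoisotopic peak.

    This is the factor by which a measured M intensity is scaled up to the
    whole-envelope abundance, so that satellite-peak signal lost to incomplete
    labeling is added back before ratio calculation.
    """
    return envelope(comp, p, channel).abundance_at(0)


def m1_over_m(comp: ElementalComposition, p: float) -> float:
    """M−1/M abundance ratio of a heavy envelope; strictly decreasing in p.

    The M−1 satellite holds molecules with exactly one residual ¹⁴N, so its
    size relative to M is the sensitive, nearly linear readout of (1−p) used
    to determine labeling efficiency.
    """
    env = envelope(comp, p, HEAVY)
    m = env.abundance_at(0)
    if m == 0.0:
        raise ValueError("degenerate composition: zero abundance at the monoisotopic peak")
    return env.abundance_at(-1) / m
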