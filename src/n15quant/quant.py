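"""Light/heavy peptide-pair quantification from averaged MS¹ spectra.

For each identified peptide (from either the ¹⁴N or the ¹⁵N search) the
counterpart ion's composition, mass and isotope distribution are derived, the
MS¹ scans around the identifying MS² retention time are averaged, and both
channels' monoisotopic peaks are measured from the same slice. The measured
monoisotopic intensity is divided by the fraction of the envelope expected in
that peak at the run's labeling efficiency, so signal lost to incomplete
labeling (the M−1, M−2 … satellites) is added back before the L/H ratio is
formed. Cosine-similarity scores over (M, M+1, M+2) flag clusters whose shape
disagrees with theory — typically co-eluting contamination of one peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import chemcore, isotopes
from .chemcore import HEAVY, LIGHT, PeptideIon
from .spectra_io import IdRecord, PeakMeasurement, Scan, average_scans, match_peak

__all__ = [
    "QuantConfig",
    "PeptideQuant",
    "corrected_abundance",
    "cs_score",
    "quantify_pair",
    "quantify_table",
]

#: minimum theoretical satellite abundance for which a heavy-channel
#: measurement target is emitted
_SATELLITE_FLOOR = 1e-4


@dataclass(frozen=True)
class QuantConfig:
    """Run parameters for quantification.

    Defaults follow the workflow's recommended settings: RT averaging window
    −5 s to +15 s around the identifying MS² scan, a 240,000 resolution
    model for peak matching, intensity (mean height) rather than area, and a
    user-determined labeling efficiency.
    """

    efficiency: float = 0.97
    rt_window: tuple[float, float] = (-5.0, 15.0)
    resolution: float = 240000.0
    mode: str = "intensity"  # 'intensity' | 'area'
    cs_threshold: float = 0.9
    normalize_top_n: int = 100

    def __post_init__(self):
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError(f"efficiency {self.efficiency} outside (0, 1]")
        if self.mode not in ("intensity", "area"):
            raise ValueError("mode must be 'intensity' or 'area'")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rt_window"] = list(self.rt_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QuantConfig":
        d = dict(d)
        d["rt_window"] = tuple(d.get("rt_window", (-5.0, 15.0)))
        return cls(**d)


@dataclass
class PeptideQuant:
    """One light/heavy pair measurement.

    ``ratio_LH`` is light/heavy after efficiency correction; ``status``
    distinguishes the sentinel cases: ``ok`` (finite), ``no_heavy`` (ratio
    +inf — the one-sided IP use case), ``no_light`` (ratio 0) and ``absent``
    (neither channel measured, ratio NaN). Low-CS pairs are flagged, never
    deleted.
    """

    id_record: IdRecord
    light_mono: PeakMeasurement | None = None
    heavy_mono: PeakMeasurement | None = None
    cluster_light: dict[int, float] = field(default_factory=dict)
    cluster_heavy: dict[int, float] = field(default_factory=dict)
    f_mono_light: float = 1.0
    f_mono_heavy: float = 1.0
    light_corrected: float = 0.0
    heavy_corrected: float = 0.0
    ratio_LH: float = float("nan")
    status: str = "absent"
    cs_light: float | None = None
    cs_heavy: float | None = None
    total_intensity: float = 0.0
    mode: str = "intensity"
    flags: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        r = self.id_record
        return (r.sequence, r.modifications, r.charge, r.source_file)

    def to_dict(self) -> dict:
        d = {
            "id_record": asdict(self.id_record),
            "cluster_light": {str(k): v for k, v in self.cluster_light.items()},
            "cluster_heavy": {str(k): v for k, v in self.cluster_heavy.items()},
            "f_mono_light": self.f_mono_light,
            "f_mono_heavy": self.f_mono_heavy,
            "light_corrected": self.light_corrected,
            "heavy_corrected": self.heavy_corrected,
            "ratio_LH": _json_float(self.ratio_LH),
            "status": self.status,
            "cs_light": self.cs_light,
            "cs_heavy": self.cs_heavy,
            "total_intensity": self.total_intensity,
            "mode": self.mode,
            "flags": list(self.flags),
        }
        for name in ("light_mono", "heavy_mono"):
            m = getattr(self, name)
            d[name] = None if m is None else {
                "target_mz": m.target_mz,
                "matched_mz": m.matched_mz,
                "intensity": m.intensity,
                "area": m.area,
                "ppm_error": _json_float(m.ppm_error),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PeptideQuant":
        def mk_meas(md):
            if md is None:
                return None
            return PeakMeasurement(
                md["target_mz"], md["matched_mz"], md["intensity"], md["area"],
                _from_json_float(md["ppm_error"]),
            )

        return cls(
            id_record=IdRecord(**d["id_record"]),
            light_mono=mk_meas(d["light_mono"]),
            heavy_mono=mk_meas(d["heavy_mono"]),
            cluster_light={int(k): v for k, v in d["cluster_light"].items()},
            cluster_heavy={int(k): v for k, v in d["cluster_heavy"].items()},
            f_mono_light=d["f_mono_light"],
            f_mono_heavy=d["f_mono_heavy"],
            light_corrected=d["light_corrected"],
            heavy_corrected=d["heavy_corrected"],
            ratio_LH=_from_json_float(d["ratio_LH"]),
            status=d["status"],
            cs_light=d["cs_light"],
            cs_heavy=d["cs_heavy"],
            total_intensity=d["total_intensity"],
            mode=d["mode"],
            flags=list(d["flags"]),
        )


def _json_float(x: float):
    if x is None or math.isfinite(x):
        return x
    if math.isnan(x):
        return "NaN"
    return "Inf" if x > 0 else "-Inf"


def _from_json_float(x):
    if isinstance(x, str):
        return {"NaN": float("nan"), "Inf": float("inf"), "-Inf": float("-inf")}[x]
    return x


def corrected_abundance(measured: float, f_mono: float) -> float:
    """Scale a measured monoisotopic value up to the whole envelope.

    Dividing by the fraction of the cluster expected in M adds back the
    satellite-peak abundance lost to incomplete labeling, so the heavy
    channel is not systematically underestimated.
    """
    if not f_mono > 0.0:
        raise ValueError(f"fraction_in_mono must be > 0, got {f_mono}")
    if f_mono > 1.0:
        raise ValueError(f"fraction_in_mono must be <= 1, got {f_mono}")
    return measured / f_mono


def cs_score(observed, theoretical) -> float | None:
    """Cosine similarity between observed and theoretical (M, M+1, M+2).

    1.0 is a perfect shape match, 0.0 orthogonal; scale-invariant, so mixing
    proportions do not matter — only the cluster shape. An all-zero observed
    vector has no shape and returns ``None`` (undefined, distinct from 0).
    """
    obs = np.asarray(observed, dtype=float)
    theo = np.asarray(theoretical, dtype=float)
    if obs.shape != (3,) or theo.shape != (3,):
        raise ValueError("cs_score expects vectors of length 3 (M, M+1, M+2)")
    if (obs < 0).any() or (theo < 0).any():
        raise ValueError("cs_score vectors must be non-negative")
    if not theo.any():
        raise ValueError("theoretical pattern is all-zero")
    if not obs.any():
        return None
    value = float(obs @ theo / (np.linalg.norm(obs) * np.linalg.norm(theo)))
    # snap rounding error at the boundaries: proportional vectors score exactly 1
    if value > 1.0 - 1e-12:
        return 1.0
    return max(value, 0.0)


def _measure_cluster(slice_, env, offsets, resolution, mode):
    """Measure intensities at the envelope's centroid m/z for given offsets."""
    out: dict[int, float] = {}
    mono = None
    for k in offsets:
        idx = np.nonzero(env.offsets == k)[0]
        if idx.size == 0:
            continue
        meas = match_peak(slice_, float(env.centroid_mz[idx[0]]), resolution)
        out[k] = meas.area if mode == "area" else meas.intensity
        if k == 0:
            mono = meas
    return out, mono


def quantify_pair(
    id_record: IdRecord,
    scans: Sequence[Scan],
    config: QuantConfig,
    slice_: "SpectrumSlice | None" = None,
) -> PeptideQuant:
    """Quantify one light/heavy pair anchored at one identification.

    Identification of either channel suffices: the counterpart is derived,
    both clusters are measured from the same averaged slice, monoisotopic
    values are efficiency-corrected, and the ratio is always reported as
    light/heavy. A channel with no measurable signal yields the one-sided
    sentinels instead of dropping the peptide.
    """
    mods = chemcore.parse_modifications(id_record.modifications)
    ion = PeptideIon(id_record.sequence, mods, id_record.charge, id_record.channel)
    light_ion = ion if ion.channel == LIGHT else chemcore.counterpart(ion)
    heavy_ion = chemcore.counterpart(light_ion)
    comp_light = chemcore.build_composition(light_ion)
    comp_heavy = chemcore.build_composition(heavy_ion)
    p = config.efficiency
    env_light = isotopes.envelope(comp_light, p, LIGHT)
    env_heavy = isotopes.envelope(comp_heavy, p, HEAVY)
    f_light = env_light.abundance_at(0)
    f_heavy = env_heavy.abundance_at(0)

    if slice_ is None:
        slice_ = average_scans(scans, id_record.rt_seconds, config.rt_window, config.resolution)

    light_offsets = [0, 1, 2]
    sat = [int(k) for k in env_heavy.offsets if k < 0 and env_heavy.abundance_at(int(k)) >= _SATELLITE_FLOOR]
    heavy_offsets = sorted(sat) + [0, 1, 2]
    cluster_light, light_mono = _measure_cluster(slice_, env_light, light_offsets, config.resolution, config.mode)
    cluster_heavy, heavy_mono = _measure_cluster(slice_, env_heavy, heavy_offsets, config.resolution, config.mode)

    q = PeptideQuant(
        id_record=id_record,
        light_mono=light_mono,
        heavy_mono=heavy_mono,
        cluster_light=cluster_light,
        cluster_heavy=cluster_heavy,
        f_mono_light=f_light,
        f_mono_heavy=f_heavy,
        mode=config.mode,
    )
    l_val = cluster_light.get(0, 0.0)
    h_val = cluster_heavy.get(0, 0.0)
    q.light_corrected = corrected_abundance(l_val, f_light)
    q.heavy_corrected = corrected_abundance(h_val, f_heavy)
    if l_val > 0 and h_val > 0:
        q.ratio_LH = q.light_corrected / q.heavy_corrected
        q.status = "ok"
    elif l_val > 0:
        q.ratio_LH = float("inf")
        q.status = "no_heavy"
    elif h_val > 0:
        q.ratio_LH = 0.0
        q.status = "no_light"
    else:
        q.ratio_LH = float("nan")
        q.status = "absent"

    obs_l = np.array([cluster_light.get(k, 0.0) for k in (0, 1, 2)])
    obs_h = np.array([cluster_heavy.get(k, 0.0) for k in (0, 1, 2)])
    q.cs_light = cs_score(obs_l, env_light.vector((0, 1, 2)))
    q.cs_heavy = cs_score(obs_h, env_heavy.vector((0, 1, 2)))
    q.total_intensity = float(obs_l.sum() + obs_h.sum())
    if q.cs_light is not None and q.cs_light < config.cs_threshold:
        q.flags.append("low_cs_light")
    if q.cs_heavy is not None and q.cs_heavy < config.cs_threshold:
        q.flags.append("low_cs_heavy")
    if q.status in ("no_heavy", "no_light", "absent"):
        q.flags.append("one_sided" if q.status != "absent" else "absent")
    return q


def quantify_table(
    records: Sequence[IdRecord],
    scans: Sequence[Scan],
    config: QuantConfig,
) -> list[PeptideQuant]:
    """Quantify every unique (sequence, modifications, charge, file) once.

    When both channels were independently identified, the higher-score
    identification anchors the RT window. Decoy records are skipped (they
    exist for FDR accounting only).
    """
    best: dict[tuple, IdRecord] = {}
    order: list[tuple] = []
    for r in records:
        if r.decoy:
            continue
        key = (r.sequence, r.modifications, r.charge, r.source_file)
        if key not in best:
            best[key] = r
            order.append(key)
        elif r.score > best[key].score:
            best[key] = r
    return [quantify_pair(best[k], scans, config) for k in order]
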