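"""Synergy/redundancy decomposition of pair decoding performance.

For a pair of neurons the per-frequency absolute correlation profile of the
joint reconstruction, c12(f) = |Corr|[S;N1,N2](f), is decomposed against the
individual profiles c1(f), c2(f) following the partial-information pattern

    c12(f) = synergy(f) + c1(f) + c2(f) - redundancy(f).

Redundancy is defined as the minimum information available from either
neuron alone, redundancy(f) = min(c1, c2)(f); the identity above then forces
synergy(f) = c12(f) - max(c1, c2)(f). This choice reproduces the three
printed limits of the normalized summary exactly: the per-bin normalized
synergy 100*synergy(f)/max(c12, c1, c2)(f), averaged over frequencies,
equals +100% when c1 = c2 = 0 < c12 (information exists only in the pair),
-100% when c12 = 0 < c1, c2 (information is lost in the pair), and 0 when
c12 = max(c1, c2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import CapacityError, decode
from .neurons import SpikeTrain
from .stimulus import Spectrogram

__all__ = ["PairProfiles", "PairDecomposition", "PairAnalysisResult",
           "decompose_pair", "pair_analysis"]

RESTRICTIONS = ("none", "spikes", "silence", "combinatorial")


@dataclass(frozen=True)
class PairProfiles:
    """Absolute per-frequency correlation profiles on a shared axis."""

    c1: np.ndarray
    c2: np.ndarray
    c12: np.ndarray

    def __post_init__(self):
        c1 = np.asarray(self.c1, dtype=float)
        c2 = np.asarray(self.c2, dtype=float)
        c12 = np.asarray(self.c12, dtype=float)
        if not (c1.shape == c2.shape == c12.shape):
            raise ValueError("profiles must share one frequency axis")
        for c in (c1, c2, c12):
            good = np.isfinite(c)
            if np.any(c[good] < 0) or np.any(c[good] > 1):
                raise ValueError("absolute correlation profiles must lie "
                                 "in [0, 1]")
        object.__setattr__(self, "c1", c1)
        object.__setattr__(self, "c2", c2)
        object.__setattr__(self, "c12", c12)


@dataclass(frozen=True)
class PairDecomposition:
    synergy_f: np.ndarray
    redundancy_f: np.ndarray
    normalized_synergy: float   # %, in [-100, 100]; NaN if no valid bin
    n_valid_bins: int


@dataclass(frozen=True)
class PairAnalysisResult:
    profiles: PairProfiles
    decomposition: PairDecomposition
    restriction: str
    roles: dict | None = None


def decompose_pair(profiles: PairProfiles) -> PairDecomposition:
    """Per-frequency synergy/redundancy and the normalized synergy summary.

    Bins where any profile is non-finite, or where the three-way maximum is
    zero, are excluded from the normalized average (and from the reported
    valid-bin count).
    """
    c1, c2, c12 = profiles.c1, profiles.c2, profiles.c12
    redundancy = np.minimum(c1, c2)
    synergy = c12 - np.maximum(c1, c2)
    denom = np.maximum(c12, np.maximum(c1, c2))
    valid = np.isfinite(c1) & np.isfinite(c2) & np.isfinite(c12) & (denom > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        normalized = float("nan")
    else:
        normalized = float(np.mean(100.0 * synergy[valid] / denom[valid]))
    return PairDecomposition(synergy_f=synergy, redundancy_f=redundancy,
                             normalized_synergy=normalized,
                             n_valid_bins=n_valid)


def pair_analysis(unit1: SpikeTrain, unit2: SpikeTrain,
                  stimulus: Spectrogram, code_kind: str = "temporal",
                  restriction: str = "none", **params) -> list:
    """Decode a pair and decompose its per-frequency profile.

    The single-unit profiles c1, c2 always come from unrestricted decodes of
    the whole spike trains; the joint profile c12 comes from the pair decode
    under the stated restriction (none / spikes-only / silence-only /
    combinatorial), so restricted synergy is measured relative to the full
    single-unit information. The combinatorial restriction is evaluated for
    both role assignments and both results are returned; other restrictions
    return a single-element list.
    """
    if restriction not in RESTRICTIONS:
        raise ValueError(f"restriction must be one of {RESTRICTIONS}")
    r1 = decode([unit1], stimulus, code_kind, **params)
    r2 = decode([unit2], stimulus, code_kind, **params)
    c1, c2 = np.abs(r1.corr_f), np.abs(r2.corr_f)

    mask_for = {"none": None, "spikes": "spiking", "silence": "silence"}
    results = []
    if restriction == "combinatorial":
        if unit1.unit_id == unit2.unit_id:
            raise ValueError("combinatorial restriction needs two distinct "
                             "unit ids")
        role_sets = [{"spiker": unit1.unit_id, "silent": unit2.unit_id},
                     {"spiker": unit2.unit_id, "silent": unit1.unit_id}]
        for roles in role_sets:
            try:
                r12 = decode([unit1, unit2], stimulus, code_kind,
                             mask="combinatorial", mask_roles=roles, **params)
            except CapacityError as exc:
                raise CapacityError(
                    f"combinatorial restriction {roles} selects too few "
                    f"windows: {exc}") from exc
            profiles = PairProfiles(c1=c1, c2=c2, c12=np.abs(r12.corr_f))
            results.append(PairAnalysisResult(
                profiles=profiles, decomposition=decompose_pair(profiles),
                restriction=restriction, roles=roles))
    else:
        r12 = decode([unit1, unit2], stimulus, code_kind,
                     mask=mask_for[restriction], **params)
        profiles = PairProfiles(c1=c1, c2=c2, c12=np.abs(r12.corr_f))
        results.append(PairAnalysisResult(
            profiles=profiles, decomposition=decompose_pair(profiles),
            restriction=restriction))
    return results
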