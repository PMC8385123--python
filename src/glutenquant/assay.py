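"""MRM assay design: peptide/fragment masses, transition QC, scheduling.

Masses are monoisotopic; cysteines carry the carbamidomethyl fixed
modification by default because samples are alkylated with iodoacetamide
before digestion. Transition quality control mirrors common targeted
proteomics practice: a precursor is kept when at least ``min_transitions``
of its transitions co-elute with intensity above ``min_intensity`` cps
and S/N above ``min_snr``, and the most intense ``keep_top`` passing
transitions are retained for quantitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

PROTON = 1.007276
WATER = 18.010565

#: Monoisotopic residue masses (internal residues, i.e. minus water).
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

#: Carbamidomethylation of cysteine, applied as a fixed modification.
CARBAMIDOMETHYL = 57.02146
DEFAULT_FIXED_MODS = {"C": CARBAMIDOMETHYL}


@dataclass
class TransitionAssay:
    peptide: str
    precursor_charge: int
    precursor_mz: float
    fragment_label: str  # e.g. "y7" or "b3"
    fragment_charge: int
    fragment_mz: float
    expected_rt: float  # minutes
    window: float = 60.0  # seconds

    def __post_init__(self) -> None:
        idx = int(self.fragment_label[1:])
        if not 1 <= idx < len(self.peptide):
            raise ValueError(f"fragment index {idx} out of range for {self.peptide}")
        if self.precursor_mz <= 0 or self.fragment_mz <= 0 or self.window <= 0:
            raise ValueError("m/z and window must be positive")


@dataclass
class TransitionObservation:
    assay: TransitionAssay
    observed_rt: float
    intensity: float  # cps
    snr: float

    def __post_init__(self) -> None:
        if self.intensity < 0 or self.snr < 0:
            raise ValueError("intensity and snr must be >= 0")


@dataclass
class QcThresholds:
    min_transitions: int = 3
    min_intensity: float = 1000.0  # cps, strict "over"
    min_snr: float = 5.0  # strict "over"
    rt_tolerance: float = 0.2  # min, co-elution from the median RT
    keep_top: int = 3


@dataclass
class QcResult:
    peptide: str
    accepted: bool
    transitions: list[TransitionObservation] = field(default_factory=list)
    reason: str = ""


def peptide_mono_mass(sequence: str, fixed_mods: dict[str, float] | None = None) -> float:
    """Monoisotopic peptide mass in Da (residue sum + water + fixed mods)."""
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    if not sequence:
        raise ValueError("empty peptide")
    total = WATER
    for aa in sequence.upper():
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
        total += fixed_mods.get(aa, 0.0)
    return total


def precursor_mz(sequence: str, charge: int, fixed_mods: dict[str, float] | None = None) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mono_mass(sequence, fixed_mods) + charge * PROTON) / charge


def fragment_mz(
    sequence: str,
    ion_type: str,
    index: int,
    charge: int = 1,
    fixed_mods: dict[str, float] | None = None,
) -> float:
    """m/z of a b- or y-ion.

    ``y_k`` is the C-terminal k residues plus water; ``b_k`` the
    N-terminal k residues; each plus ``charge`` protons, over charge.
    """
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    sequence = sequence.upper()
    if not 1 <= index < len(sequence):
        raise ValueError(f"fragment index {index} out of range (1..{len(sequence) - 1})")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if ion_type == "y":
        part = sequence[-index:]
        neutral = WATER
    elif ion_type == "b":
        part = sequence[:index]
        neutral = 0.0
    else:
        raise ValueError(f"unsupported ion type {ion_type!r}")
    for aa in part:
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r}")
        neutral += RESIDUE_MASS[aa] + fixed_mods.get(aa, 0.0)
    return (neutral + charge * PROTON) / charge


def qc_select_transitions(
    observations: list[TransitionObservation], thresholds: QcThresholds | None = None
) -> dict[str, QcResult]:
    """Apply acceptance rules per precursor and keep the top transitions.

    Observations are grouped by peptide; within a group a transition
    passes when its intensity and S/N exceed the thresholds strictly and
    its RT lies within ``rt_tolerance`` of the group's median observed
    RT. Ties in intensity break by ascending fragment m/z so output is
    deterministic.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    groups: dict[str, list[TransitionObservation]] = {}
    for obs in observations:
        groups.setdefault(obs.assay.peptide, []).append(obs)

    results: dict[str, QcResult] = {}
    for peptide, obs_list in groups.items():
        rts = sorted(o.observed_rt for o in obs_list)
        mid = len(rts) // 2
        median_rt = rts[mid] if len(rts) % 2 else 0.5 * (rts[mid - 1] + rts[mid])
        passing = [
            o
            for o in obs_list
            if o.intensity > thresholds.min_intensity
            and o.snr > thresholds.min_snr
            and abs(o.observed_rt - median_rt) <= thresholds.rt_tolerance
        ]
        if len(passing) < thresholds.min_transitions:
            results[peptide] = QcResult(
                peptide, False, [], reason="insufficient transitions"
            )
            continue
        passing.sort(key=lambda o: (-o.intensity, o.assay.fragment_mz))
        results[peptide] = QcResult(peptide, True, passing[: thresholds.keep_top])
    return results


def max_concurrent_from_cycle(cycle_time: float = 0.3, min_dwell: float = 0.005) -> int:
    """Transitions measurable per cycle given cycle time and minimum dwell."""
    if cycle_time <= 0 or min_dwell <= 0:
        raise ValueError("cycle_time and min_dwell must be positive")
    return int(math.floor(cycle_time / min_dwell))


def _rt_interval(assay: TransitionAssay) -> tuple[float, float]:
    half = assay.window / 120.0  # seconds -> minutes, half-window
    return assay.expected_rt - half, assay.expected_rt + half


def _max_overlap(assays: list[TransitionAssay]) -> int:
    """Max number of simultaneously open RT windows (sweep line)."""
    events: list[tuple[float, int]] = []
    for a in assays:
        lo, hi = _rt_interval(a)
        events.append((lo, 1))
        events.append((hi, -1))
    # closed intervals: starts before ends at identical coordinate
    events.sort(key=lambda e: (e[0], -e[1]))
    cur = best = 0
    for _, delta in events:
        cur += delta
        best = max(best, cur)
    return best


def schedule_assays(
    assays: list[TransitionAssay], max_concurrent: int
) -> list[list[TransitionAssay]]:
    """Partition assays into transition lists respecting a concurrency cap.

    Greedy first-fit over assays sorted by ascending expected RT: each
    assay goes to the first list where adding it keeps the maximum
    number of overlapping RT windows at or below ``max_concurrent``.
    """
    if max_concurrent < 1:
        raise ValueError("max_concurrent must be >= 1")
    lists: list[list[TransitionAssay]] = []
    counts: list[list[tuple[float, int]]] = []  # per-list event sets, kept implicit
    for assay in sorted(assays, key=lambda a: (a.expected_rt, a.peptide, a.fragment_label)):
        placed = False
        for lst in lists:
            lst.append(assay)
            if _max_overlap(lst) <= max_concurrent:
                placed = True
                break
            lst.pop()
        if not placed:
            lists.append([assay])
    del counts
    return lists


def validate_schedule(
    lists: list[list[TransitionAssay]], max_concurrent: int
) -> bool:
    """Independent check that every list honours the concurrency cap."""
    return all(_max_overlap(lst) <= max_concurrent for lst in lists)


def write_transition_lists(lists: list[list[TransitionAssay]], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide,precursor_mz,fragment_label,fragment_mz,rt_min,window_s,list_index\n")
        for i, lst in enumerate(lists):
            for a in lst:
                fh.write(
                    f"{a.peptide},{a.precursor_mz:.5f},{a.fragment_label},"
                    f"{a.fragment_mz:.5f},{a.expected_rt:.3f},{a.window:.1f},{i}\n"
                )
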