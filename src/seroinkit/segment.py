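"""Signal-peptide detection and B/C module segmentation.

Seroin precursors carry a ~20-residue signal peptide (module A) followed by
alternating conserved blocks rich in Ala, Ser, Glu and Asp (B modules) and
shorter Pro-rich linkers (C modules).  Segmentation is single-sequence and
compositional: a sliding-window proline profile splits the mature protein
into B/C runs, which are then smoothed and numbered from the N-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CHARGED = frozenset("DEKR")
ASED = frozenset("ASED")

#: Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
    "*": 0.0,
}

PRO_THRESHOLD = 0.20
PROFILE_WINDOW = 15
MIN_RUN = 5
SMOOTH_WINDOW = 7
#: class-agnostic fallback lengths used for the terminal completeness flag
GENERIC_FULL_LENGTH = {"B": 35, "C": 15}


class NoInitiatorMet(ValueError):
    """Protein does not start with Met; signal peptide undefined."""


@dataclass
class ModuleAnnotation:
    """One module span in 0-based half-open protein coordinates."""

    label: str
    start: int
    end: int
    complete: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty span for module {self.label}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def kind(self) -> str:
        """'A', 'B' or 'C' regardless of numbering."""
        return self.label[0]


@dataclass
class Architecture:
    """Ordered, non-overlapping module annotation of one protein."""

    modules: list[ModuleAnnotation]
    protein_length: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.modules, self.modules[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping modules {prev.label} and {nxt.label}"
                )

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.modules]


@dataclass
class CompositionProfile:
    """Per-position windowed residue-set fractions."""

    pro_frac: np.ndarray
    gly_frac: np.ndarray
    charged_frac: np.ndarray
    ased_frac: np.ndarray
    window: int


def _windowed_fraction(indicator: np.ndarray, window: int) -> np.ndarray:
    """Mean of a 0/1 indicator over clipped windows [i - w//2, i + w//2 + 1)."""
    n = len(indicator)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(indicator)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def composition_profile(protein: str, window: int = PROFILE_WINDOW) -> CompositionProfile:
    """Windowed Pro/Gly/charged/ASED fractions at every position."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if len(protein) < window:
        raise ValueError(
            f"protein of length {len(protein)} shorter than window {window}"
        )
    arr = np.frombuffer(protein.encode(), dtype="S1")
    pro = (arr == b"P").astype(float)
    gly = (arr == b"G").astype(float)
    charged = np.isin(arr, [b"D", b"E", b"K", b"R"]).astype(float)
    ased = np.isin(arr, [b"A", b"S", b"E", b"D"]).astype(float)
    return CompositionProfile(
        _windowed_fraction(pro, window),
        _windowed_fraction(gly, window),
        _windowed_fraction(charged, window),
        _windowed_fraction(ased, window),
        window,
    )


def detect_signal(protein: str, kd_window: int = 8, kd_threshold: float = 1.5
                  ) -> ModuleAnnotation:
    """Locate module A (signal peptide) as ``[0, c)``.

    ``c`` is the end of the longest hydrophobic stretch (Kyte-Doolittle
    window mean > threshold, scanned within residues 1-28) plus 3, clamped
    to [15, 30].  If no hydrophobic stretch is found, c defaults to 20 and
    the annotation is flagged incomplete via ``complete=False``.
    """
    if not protein.startswith("M"):
        raise NoInitiatorMet("protein does not start with the initiator Met")
    if len(protein) < 30:
        raise ValueError("protein shorter than 30 residues; no mature region")
    kd = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein])
    last_start = min(28, len(protein)) - kd_window
    qualifying = [
        i for i in range(1, last_start + 1)
        if kd[i : i + kd_window].mean() > kd_threshold
    ]
    if not qualifying:
        return ModuleAnnotation("A", 0, 20, complete=False)
    # longest run of consecutive qualifying window starts (first on ties)
    runs: list[list[int]] = [[qualifying[0]]]
    for i in qualifying[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    best = max(runs, key=len)
    c = best[-1] + kd_window + 3
    c = max(15, min(30, min(c, len(protein) - 1)))
    return ModuleAnnotation("A", 0, c, complete=True)


def _majority_smooth(labels: list[str], window: int = SMOOTH_WINDOW) -> list[str]:
    half = window // 2
    n = len(labels)
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        votes = labels[lo:hi]
        c_votes = votes.count("C")
        out.append("C" if c_votes * 2 > len(votes) else "B")
    return out


def _runs(labels: list[str]) -> list[tuple[str, int, int]]:
    """(kind, start, end) runs over a label list (indices relative to list)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def segment_modules(protein: str, a_end: int,
                    pro_threshold: float = PRO_THRESHOLD,
                    window: int = PROFILE_WINDOW,
                    min_run: int = MIN_RUN,
                    smooth_window: int = SMOOTH_WINDOW,
                    class_hint: Optional[str] = None) -> Architecture:
    """Segment the mature protein (``protein[a_end:]``) into B and C modules.

    Positions with windowed Pro fraction >= ``pro_threshold`` are C-like,
    the rest B-like; runs are majority-smoothed, short runs merged into the
    longer neighbour, and surviving runs numbered B1..B3 / C1..C2 from the
    N-terminus.  The terminal module is flagged incomplete when shorter
    than half a typical full module.
    """
    if len(protein) - a_end < 20:
        raise ValueError("mature region shorter than 20 residues")
    profile = composition_profile(protein, window)
    labels = ["C" if profile.pro_frac[i] >= pro_threshold else "B"
              for i in range(a_end, len(protein))]
    labels = _majority_smooth(labels, smooth_window)
    runs = _runs(labels)
    warnings: list[str] = []

    # merge runs shorter than min_run into the longer neighbour
    while len(runs) > 1:
        lengths = [end - start for _, start, end in runs]
        shortest = min(range(len(runs)), key=lambda i: (lengths[i], i))
        if lengths[shortest] >= min_run:
            break
        runs = _merge_into_neighbour(runs, shortest)

    # cap at 3 B runs and 2 C runs by merging the weakest-contrast boundary
    mature = protein[a_end:]
    while _count(runs, "B") > 3 or _count(runs, "C") > 2:
        contrasts = []
        for i in range(len(runs) - 1):
            left = mature[runs[i][1]:runs[i][2]]
            right = mature[runs[i + 1][1]:runs[i + 1][2]]
            contrast = abs(_pro_frac(left) - _pro_frac(right))
            contrasts.append((contrast, i))
        _, i = min(contrasts)
        runs = _merge_into_neighbour(runs, i if runs[i][2] - runs[i][1] <=
                                     runs[i + 1][2] - runs[i + 1][1] else i + 1)
        warnings.append("merged low-contrast boundary to respect module bounds")

    if len(runs) == 1:
        warnings.append("degenerate composition: single mature module")

    modules = [ModuleAnnotation("A", 0, a_end, True)] if a_end > 0 else []
    b_i = c_i = 0
    anns = []
    for kind, start, end in runs:
        if kind == "B":
            b_i += 1
            label = f"B{b_i}"
        else:
            c_i += 1
            label = f"C{c_i}"
        anns.append(ModuleAnnotation(label, a_end + start, a_end + end, True))
    if anns:
        last = anns[-1]
        full = GENERIC_FULL_LENGTH[last.kind]
        if class_hint is not None:
            from .isoform import expected_module_length  # local to avoid cycle
            try:
                full = expected_module_length(class_hint, last.label)
            except KeyError:
                pass
        if last.length < 0.5 * full:
            last.complete = False
    return Architecture(modules + anns, len(protein), warnings)


def _count(runs: list[tuple[str, int, int]], kind: str) -> int:
    return sum(1 for k, _, _ in runs if k == kind)


def _pro_frac(seq: str) -> float:
    return seq.count("P") / len(seq) if seq else 0.0


def _merge_into_neighbour(runs: list[tuple[str, int, int]], i: int
                          ) -> list[tuple[str, int, int]]:
    """Absorb run i into its longer neighbour, coalescing same-kind runs."""
    if i == 0:
        j = 1
    elif i == len(runs) - 1:
        j = i - 1
    else:
        left_len = runs[i - 1][2] - runs[i - 1][1]
        right_len = runs[i + 1][2] - runs[i + 1][1]
        j = i - 1 if left_len >= right_len else i + 1
    kind = runs[j][0]
    lo, hi = min(i, j), max(i, j)
    merged = (kind, runs[lo][1], runs[hi][2])
    out = runs[:lo] + [merged] + runs[hi + 1:]
    # coalesce adjacent same-kind runs
    coalesced: list[tuple[str, int, int]] = []
    for run in out:
        if coalesced and coalesced[-1][0] == run[0]:
            coalesced[-1] = (run[0], coalesced[-1][1], run[2])
        else:
            coalesced.append(run)
    return coalesced
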