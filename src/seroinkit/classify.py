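"""Rule-based Sn1/Sn2/Sn3 seroin classification.

The three classes are recognised by the position of a diagnostic Trp
relative to the initial Met, its compositional context, class motifs and
N-terminal Gly enrichment:

* Sn1 - Trp ~20 residues after the initial Met in a charged neighbourhood,
  with a distinct Pro-rich region following downstream;
* Sn2 - Gly-rich first 20-50 residues and the RYGG motif;
* Sn3 - Trp ~35 residues after the initial Met and the VYGE motif.

Motif clauses carry twice the weight of compositional clauses, motifs
being the sharpest evidence; a sequence is reported unclassified when no
class clears the score and margin thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

MIN_SCORE = 0.5
MIN_MARGIN = 0.15
MOTIF_WEIGHT = 2.0
COMPOSITION_WEIGHT = 1.0

CHARGED = frozenset("DEKR")


@dataclass(frozen=True)
class ClassSignature:
    """Diagnostic rule parameters for one seroin class."""

    seroin_class: str
    motif: Optional[str]
    trp_window: Optional[tuple[int, int]]
    clauses: tuple[tuple[str, float], ...]  # (clause name, weight)


SIGNATURES: dict[str, ClassSignature] = {
    "Sn1": ClassSignature(
        "Sn1", motif=None, trp_window=(15, 25),
        clauses=(("trp20_charged_context", COMPOSITION_WEIGHT),
                 ("pro_rich_downstream", COMPOSITION_WEIGHT)),
    ),
    "Sn2": ClassSignature(
        "Sn2", motif="RYGG", trp_window=None,
        clauses=(("rygg_motif", MOTIF_WEIGHT),
                 ("gly_rich_20_50", COMPOSITION_WEIGHT)),
    ),
    "Sn3": ClassSignature(
        "Sn3", motif="VYGE", trp_window=(30, 40),
        clauses=(("vyge_motif", MOTIF_WEIGHT),
                 ("trp35", COMPOSITION_WEIGHT)),
    ),
}


@dataclass
class ClassCall:
    """Outcome of classification for one protein."""

    seroin_class: str  # "Sn1" | "Sn2" | "Sn3" | "unclassified"
    scores: dict[str, float]
    margin: float
    satisfied_clauses: list[str]
    tied_classes: list[str] = field(default_factory=list)


def scan_motif(protein: str, motif: str) -> list[int]:
    """All (possibly overlapping) exact match start positions, ascending.

    ``X`` never matches anything, including itself.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    hits = []
    m = len(motif)
    for i in range(len(protein) - m + 1):
        window = protein[i : i + m]
        if window == motif and "X" not in window:
            hits.append(i)
    return hits


def _charged_fraction(protein: str, lo: int, hi: int) -> float:
    lo, hi = max(0, lo), min(len(protein), hi)
    if hi <= lo:
        return 0.0
    region = protein[lo:hi]
    return sum(1 for aa in region if aa in CHARGED) / len(region)


def _trp_positions(protein: str, lo: int, hi: int) -> list[int]:
    return [i for i in range(lo, min(hi, len(protein))) if protein[i] == "W"]


def _sn1_trp_charged(protein: str) -> bool:
    """Trp in [15, 25) whose +-10 neighbourhood is >= 25% charged."""
    for w in _trp_positions(protein, 15, 25):
        if _charged_fraction(protein, w - 10, w + 11) >= 0.25:
            return True
    return False


def _sn1_pro_downstream(protein: str) -> bool:
    """A 30-residue window with >= 20% Pro starting within 40 residues
    after a Trp in [15, 25)."""
    for w in _trp_positions(protein, 15, 25):
        for s in range(w + 1, min(w + 41, len(protein) - 29)):
            region = protein[s : s + 30]
            if region.count("P") / 30 >= 0.20:
                return True
    return False


def _sn2_gly(protein: str) -> bool:
    region = protein[20:50]
    if not region:
        return False
    return region.count("G") / len(region) >= 0.20


def _sn3_trp(protein: str) -> bool:
    return bool(_trp_positions(protein, 30, 40))


_CLAUSE_PREDICATES: dict[str, Callable[[str], bool]] = {
    "trp20_charged_context": _sn1_trp_charged,
    "pro_rich_downstream": _sn1_pro_downstream,
    "rygg_motif": lambda p: bool(scan_motif(p, "RYGG")),
    "gly_rich_20_50": _sn2_gly,
    "vyge_motif": lambda p: bool(scan_motif(p, "VYGE")),
    "trp35": _sn3_trp,
}


def class_scores(protein: str) -> tuple[dict[str, float], list[str]]:
    """Per-class score in [0, 1] plus the list of satisfied clauses.

    Score = satisfied clause weight / total clause weight.  Clauses that
    reference positions beyond the protein length evaluate False.
    """
    if not protein.startswith("M"):
        raise ValueError("classification is defined from the initial Met")
    scores: dict[str, float] = {}
    satisfied: list[str] = []
    for cls, sig in SIGNATURES.items():
        total = sum(w for _, w in sig.clauses)
        got = 0.0
        for name, weight in sig.clauses:
            if _CLAUSE_PREDICATES[name](protein):
                got += weight
                satisfied.append(f"{cls}:{name}")
        scores[cls] = got / total
    return scores, satisfied


def assign_class(protein: str, min_score: float = MIN_SCORE,
                 min_margin: float = MIN_MARGIN) -> ClassCall:
    """Argmax classification with score and margin thresholds.

    Ties at the best score yield ``unclassified`` with the tied classes
    listed in ``tied_classes``.
    """
    scores, satisfied = class_scores(protein)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_class, best = ranked[0]
    second = ranked[1][1]
    margin = best - second
    tied = [cls for cls, sc in ranked if sc == best]
    if best < min_score or len(tied) > 1 or margin < min_margin:
        return ClassCall("unclassified", scores, margin, satisfied,
                         tied if len(tied) > 1 else [])
    return ClassCall(best_class, scores, margin, satisfied)
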