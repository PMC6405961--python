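"""Splice-version calling and gene grouping.

Seroins occur in a long version with the full module set AB1C1B2C2B3 and
in class-specific short versions: N (AB1C1B2) and C (AB1C2B3) in Sn1, C and
the terminal T1/T2 forms (with incomplete internal or N-terminal modules)
in Sn2, and the short T form (AB1C1B3) in Sn3.  Version calling matches the
observed B/C run structure of a segmented protein against the canonical
patterns of its class; positional labels from segmentation (first B run =
B1, ...) are re-mapped to canonical labels by the best-matching pattern.

Gene grouping clusters same-species isoforms: alternative splice products
of one gene share their N-terminus, whereas paralogous genes (never more
than two per class) diverge from the start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional, Sequence

from .segment import Architecture, ModuleAnnotation
from .synth import (
    CLASS_VERSIONS, MODULE_LENGTH_RANGES, VERSION_PATTERNS, incomplete_length,
)

#: observed/expected length ratio below which a module counts as incomplete
COMPLETENESS_RATIO = 0.55
#: weight of a completeness mismatch relative to a presence mismatch
COMPLETENESS_PENALTY = 0.5
#: patterns farther than this from the observation are "unrecognized"
MAX_PATTERN_COST = 1.0
#: residues by which threshold segmentation shifts each B|C boundary into
#: the B side (window-15 Pro profile at threshold 0.20 over ~50-60% Pro
#: linkers); observed lengths are de-biased by this before comparison
BOUNDARY_SMEAR = 3


def expected_module_length(seroin_class: str, label: str) -> float:
    lo, hi = MODULE_LENGTH_RANGES[seroin_class][label]
    return (lo + hi) / 2.0


@dataclass
class SpliceVersion:
    """A called splice version with its canonical module mapping."""

    code: str  # L | N | C | T1 | T2 | T | unrecognized
    pattern: tuple[tuple[str, bool], ...]
    canonical_modules: list[ModuleAnnotation] = field(default_factory=list)
    cost: float = 0.0


def _pattern_cost(observed: Sequence[ModuleAnnotation],
                  pattern: Sequence[tuple[str, bool]],
                  seroin_class: str
                  ) -> Optional[tuple[float, float, list[ModuleAnnotation]]]:
    """Cost of explaining the observed runs by a canonical pattern.

    The observed mature runs (B/C kinds in order) must match the pattern's
    module kinds exactly; per slot, a completeness mismatch costs 0.5.  A
    small length term breaks ties between patterns with equal mismatch
    cost (e.g. Sn1 N vs C, which share the B-C-B shape).
    """
    obs = [m for m in observed if m.label != "A"]
    slots = [(label, complete) for label, complete in pattern if label != "A"]
    if len(obs) != len(slots):
        return None
    if any(m.kind != label[0] for m, (label, _) in zip(obs, slots)):
        return None
    # de-bias observed lengths: each B|C boundary smears ~BOUNDARY_SMEAR
    # residues of the B side into the adjacent C run
    adj_lengths = []
    for i, m in enumerate(obs):
        c_neighbours = sum(1 for j in (i - 1, i + 1)
                           if 0 <= j < len(obs) and obs[j].kind == "C")
        b_neighbours = sum(1 for j in (i - 1, i + 1)
                           if (0 <= j < len(obs) and obs[j].kind == "B")
                           or (j == -1 and m.kind == "C"))  # A flanks like B
        if m.kind == "B":
            adj_lengths.append(m.length + BOUNDARY_SMEAR * c_neighbours)
        else:
            adj_lengths.append(max(1, m.length - BOUNDARY_SMEAR * b_neighbours))
    cost = 0.0
    length_term = 0.0
    remapped = []
    for m, adj_len, (label, slot_complete) in zip(obs, adj_lengths, slots):
        full = expected_module_length(seroin_class, label)
        expected = full if slot_complete else float(incomplete_length(seroin_class, label))
        # effective completeness: the segmentation flag can only demote
        obs_complete = m.complete and (adj_len >= COMPLETENESS_RATIO * full)
        if obs_complete != slot_complete:
            cost += COMPLETENESS_PENALTY
        length_term += abs(log(adj_len / expected))
        remapped.append(ModuleAnnotation(label, m.start, m.end, obs_complete))
    a_mods = [m for m in observed if m.label == "A"]
    return cost, length_term, a_mods + remapped


def call_version(architecture: Architecture, seroin_class: str) -> SpliceVersion:
    """Match a segmented architecture against its class's splice patterns.

    The pattern with the lowest mismatch cost wins; when no pattern's
    presence/completeness cost is within 1 mismatch, the result code is
    ``"unrecognized"``.
    """
    if seroin_class not in CLASS_VERSIONS:
        raise ValueError(f"unknown seroin class {seroin_class!r}")
    if not architecture.modules:
        raise ValueError("empty architecture")
    candidates = []
    for code in CLASS_VERSIONS[seroin_class]:
        pattern = VERSION_PATTERNS[(seroin_class, code)]
        res = _pattern_cost(architecture.modules, pattern, seroin_class)
        if res is not None:
            cost, length_term, remapped = res
            candidates.append((cost, length_term, code, pattern, remapped))
    if not candidates:
        return SpliceVersion("unrecognized", (), [], float("inf"))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    cost, _lt, code, pattern, remapped = candidates[0]
    if cost > MAX_PATTERN_COST:
        return SpliceVersion("unrecognized", (), [], cost)
    return SpliceVersion(code, pattern, remapped, cost)


@dataclass
class GeneGroup:
    """Same-species isoforms attributed to one gene."""

    species: tuple[str, str]
    seroin_class: str
    gene_number: int
    member_ids: list[str]
    evidence: str  # n_terminal_identity | genomic | default


def _overlap_identity(a: str, b: str) -> float:
    """Identity over the locally aligned overlap of two isoform proteins.

    Splice isoforms of one gene share their retained modules verbatim but
    differ in which modules are present, so the overlap is taken from the
    best local alignment under identity scoring (+1 match, -2 mismatch,
    -3 gap): extension beyond verbatim-shared blocks has negative expected
    score and stops, leaving the maximal near-identical region.  Under a
    similarity matrix the alignment would creep through compositionally
    biased but non-homologous modules and dilute the identity.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -3.0
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0
    aln = alns[0]
    sa, sb = str(aln[0]), str(aln[1])
    pairs = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x == y) / len(pairs)


def group_genes(records: Sequence, k: int = 25, id_threshold: float = 0.95,
                genomic_splits: Optional[Sequence[frozenset[str]]] = None
                ) -> list[GeneGroup]:
    """Single-linkage clustering of one species+class into <= 2 genes.

    Two isoforms link when their first ``k`` residues (from the initial
    Met; the signal peptide is retained by every splice version) are
    identical and their aligned overlap identity reaches ``id_threshold``.
    ``genomic_splits`` optionally forces known paralogs apart, standing in
    for genomic evidence.

    ``records`` need ``.id`` and ``.protein`` attributes.
    """
    if not records:
        raise ValueError("no records to group")
    ids = [r.id for r in records]
    proteins = {r.id: r.protein for r in records}
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    forced_apart = list(genomic_splits or [])

    def forcibly_split(a: str, b: str) -> bool:
        return any((a in grp) != (b in grp) for grp in forced_apart)

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if forcibly_split(a, b):
                continue
            pa, pb = proteins[a], proteins[b]
            kk = min(k, len(pa), len(pb))
            if pa[:kk] != pb[:kk]:
                continue
            if _overlap_identity(pa, pb) >= id_threshold:
                union(a, b)

    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    groups = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))

    warnings = []
    while len(groups) > 2:
        # merge the two closest clusters (best pairwise overlap identity)
        best = None
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                ident = max(_overlap_identity(proteins[a], proteins[b])
                            for a in groups[gi] for b in groups[gj])
                if best is None or ident > best[0]:
                    best = (ident, gi, gj)
        _, gi, gj = best
        groups[gi] = sorted(groups[gi] + groups[gj])
        del groups[gj]
        groups.sort(key=lambda ms: (-len(ms), min(ms)))
        warnings.append("more than two clusters; merged closest pair")

    first = records[0]
    species = getattr(first, "species", ("Unknown", "sp"))
    cls = getattr(getattr(first, "spec", None), "seroin_class", None) or \
        getattr(first, "seroin_class", "Sn?")
    out = []
    ordered = sorted(groups, key=lambda ms: (-len(ms), min(ms)))
    for num, members in enumerate(ordered, 1):
        others = [m for grp in ordered for m in grp if m not in members]
        if any(forcibly_split(a, b) for a in members for b in others):
            evidence = "genomic"
        elif len(records) == 1:
            evidence = "default"
        else:
            evidence = "n_terminal_identity"
        out.append(GeneGroup(tuple(species), cls, num, sorted(members), evidence))
    return out
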