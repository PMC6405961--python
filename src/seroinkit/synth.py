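"""Ground-truthed synthetic seroin generator.

Emulates the statistical structure of silk-gland seroins: a ~20-residue
signal peptide (module A), conserved charged/Ala-Ser-Glu-Asp-rich B blocks,
Pro-rich C linkers, class-diagnostic anchors (Sn1: Trp ~20 residues after
the initial Met in a charged context; Sn2: Gly-rich N-terminus with an RYGG
motif; Sn3: Trp ~35 plus a VYGE motif) and the splice versions that delete
module blocks from the full AB1C1B2C2B3 layout.

Within a class, B and C modules are derived from fixed class-level template
blocks mutated per record, so that sequences of one class resemble each
other more than sequences of different classes (the conserved-block picture
the classification assumes).  Every record carries its ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import SeqRecordLite, reverse_complement
from .segment import Architecture, ModuleAnnotation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CLASSES = ("Sn1", "Sn2", "Sn3")
MODULE_ORDER = ("A", "B1", "C1", "B2", "C2", "B3")

#: splice versions allowed per class; each pattern lists (module, complete)
VERSION_PATTERNS: dict[tuple[str, str], tuple[tuple[str, bool], ...]] = {
    ("Sn1", "L"): (("A", True), ("B1", True), ("C1", True), ("B2", True), ("C2", True), ("B3", True)),
    ("Sn1", "N"): (("A", True), ("B1", True), ("C1", True), ("B2", True)),
    ("Sn1", "C"): (("A", True), ("B1", True), ("C2", True), ("B3", True)),
    ("Sn2", "L"): (("A", True), ("B1", True), ("C1", True), ("B2", True), ("C2", True), ("B3", True)),
    ("Sn2", "C"): (("A", True), ("B1", True), ("C2", True), ("B3", True)),
    ("Sn2", "T1"): (("A", True), ("B1", True), ("C1", True), ("B2", False), ("C2", False), ("B3", True)),
    ("Sn2", "T2"): (("A", True), ("B1", False), ("C1", False), ("B2", True), ("C2", True), ("B3", True)),
    ("Sn3", "L"): (("A", True), ("B1", True), ("C1", True), ("B2", True), ("C2", True), ("B3", True)),
    ("Sn3", "T"): (("A", True), ("B1", True), ("C1", True), ("B3", True)),
}

CLASS_VERSIONS: dict[str, tuple[str, ...]] = {
    "Sn1": ("L", "N", "C"),
    "Sn2": ("L", "C", "T1", "T2"),
    "Sn3": ("L", "T"),
}

#: default module-length ranges (residues), inclusive
MODULE_LENGTH_RANGES: dict[str, dict[str, tuple[int, int]]] = {
    "Sn1": {"A": (18, 22), "B1": (10, 20), "C1": (25, 40), "B2": (45, 60), "C2": (8, 15), "B3": (50, 70)},
    "Sn2": {"A": (18, 22), "B1": (30, 50), "C1": (8, 15), "B2": (30, 45), "C2": (26, 34), "B3": (90, 100)},
    "Sn3": {"A": (18, 22), "B1": (38, 48), "C1": (15, 35), "B2": (95, 115), "C2": (25, 35), "B3": (60, 75)},
}

#: fraction of the full module length retained by an incomplete module
INCOMPLETE_FRACTION = 0.4


def incomplete_length(seroin_class: str, label: str) -> int:
    """Residue count of an incomplete (bracketed) module.

    Chosen at the smallest size the compositional segmentation can still
    resolve as a separate run (B blocks need ~15 residues for a window-15
    Pro profile to dip; C linkers need ~8) while staying clearly below
    the completeness threshold of a full module.
    """
    lo, hi = MODULE_LENGTH_RANGES[seroin_class][label]
    mid = (lo + hi) / 2.0
    if label.startswith("C"):
        return 8
    return max(15, int(round(INCOMPLETE_FRACTION * mid)))


#: per-record substitution rate applied to class template blocks
TEMPLATE_MUTATION_RATE = 0.4

# Module compositions.  Trp frequency is 0 everywhere: Trp position is the
# class-diagnostic anchor, so it is planted, never drawn from background.
_B_GENERIC = {"A": 0.20, "S": 0.20, "E": 0.16, "D": 0.16, "K": 0.07, "R": 0.05,
              "G": 0.04, "T": 0.04, "Q": 0.03, "N": 0.03, "V": 0.01, "L": 0.01}
_B1_SN2 = {"G": 0.35, "A": 0.14, "S": 0.14, "E": 0.10, "D": 0.10, "K": 0.04,
           "R": 0.03, "T": 0.04, "Q": 0.03, "N": 0.03}
_C_GENERIC = {"P": 0.60, "S": 0.09, "A": 0.07, "G": 0.06, "T": 0.06, "V": 0.04,
              "N": 0.04, "Q": 0.04}

HYDROPHOBIC_CORE = "LVAIF"
SIGNAL_TAIL = "STG"


def module_composition(seroin_class: str, label: str) -> dict[str, float]:
    if label.startswith("C"):
        return dict(_C_GENERIC)
    if label == "B1" and seroin_class == "Sn2":
        return dict(_B1_SN2)
    return dict(_B_GENERIC)


@dataclass
class SyntheticSpec:
    """Ground-truth recipe for one synthetic seroin."""

    seroin_class: str
    version: str
    module_lengths: dict[str, int]
    composition: dict[str, dict[str, float]]
    planted_motifs: list[tuple[str, str, int]]  # (motif, module, offset)
    seed: int

    def __post_init__(self) -> None:
        pattern = VERSION_PATTERNS.get((self.seroin_class, self.version))
        if pattern is None:
            raise ValueError(
                f"version {self.version!r} is not defined for class {self.seroin_class!r}"
            )
        wanted = {label for label, _ in pattern}
        if set(self.module_lengths) != wanted:
            raise ValueError(
                f"module_lengths keys {sorted(self.module_lengths)} do not match "
                f"pattern modules {sorted(wanted)}"
            )
        for label, freqs in self.composition.items():
            total = sum(freqs.values())
            if any(f < 0 for f in freqs.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition for {label} must be non-negative and sum to 1")

    @property
    def pattern(self) -> tuple[tuple[str, bool], ...]:
        return VERSION_PATTERNS[(self.seroin_class, self.version)]


@dataclass
class TruthRecord:
    """A generated seroin with its full ground truth."""

    id: str
    spec: SyntheticSpec
    protein: str
    cdna: str
    true_architecture: Architecture
    species: tuple[str, str] = ("Synthetica", "exemplaris")
    gene_id: str = "g1"


def _quota_block(composition: Mapping[str, float], length: int, rng: np.random.Generator) -> str:
    """Residue block with (rounded) exact compositional quotas, shuffled."""
    letters = sorted(composition)
    counts = {aa: int(round(composition[aa] * length)) for aa in letters}
    # fix rounding drift deterministically on the most frequent residues
    drift = length - sum(counts.values())
    order = sorted(letters, key=lambda aa: (-composition[aa], aa))
    i = 0
    while drift != 0:
        aa = order[i % len(order)]
        if drift > 0:
            counts[aa] += 1
            drift -= 1
        elif counts[aa] > 0:
            counts[aa] -= 1
            drift += 1
        i += 1
    block = [aa for aa in letters for _ in range(counts[aa])]
    rng.shuffle(block)
    return "".join(block)


def _class_template(seroin_class: str, label: str) -> str:
    """Fixed per-class conserved template block for a B/C module."""
    lo, hi = MODULE_LENGTH_RANGES[seroin_class][label]
    seed = zlib.crc32(f"seroinkit:{seroin_class}:{label}".encode())
    rng = np.random.default_rng(seed)
    return _quota_block(module_composition(seroin_class, label), hi, rng)


_TEMPLATE_CACHE: dict[tuple[str, str], str] = {}


def class_template(seroin_class: str, label: str) -> str:
    key = (seroin_class, label)
    if key not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[key] = _class_template(seroin_class, label)
    return _TEMPLATE_CACHE[key]


def _enforce_pro_quota(block: str, rng: np.random.Generator,
                       min_frac: float = 0.5) -> str:
    """Guarantee the Pro quota of a C linker (generator postcondition).

    Sampling noise on very short linkers could otherwise leave them
    compositionally ambiguous; deficient positions are converted to Pro.
    """
    need = int(round(min_frac * len(block))) - block.count("P")
    if need <= 0:
        return block
    out = list(block)
    non_pro = [i for i, aa in enumerate(out) if aa != "P"]
    for i in rng.choice(non_pro, size=need, replace=False):
        out[i] = "P"
    return "".join(out)


def _mutate(block: str, composition: Mapping[str, float], rng: np.random.Generator,
            rate: float = TEMPLATE_MUTATION_RATE) -> str:
    letters = sorted(composition)
    probs = np.array([composition[aa] for aa in letters])
    probs = probs / probs.sum()
    out = list(block)
    mask = rng.random(len(block)) < rate
    draws = rng.choice(list(letters), size=int(mask.sum()), p=probs)
    j = 0
    for i in range(len(out)):
        if mask[i]:
            out[i] = str(draws[j])
            j += 1
    return "".join(out)


def _signal_peptide(a_len: int, seroin_class: str, rng: np.random.Generator) -> str:
    """Module A: Met + hydrophobic core + mild polar tail.

    For Sn1 the tail ends in 'EK', the charged context at the cleavage
    site that flanks the diagnostic Trp.
    """
    core_len = a_len - 8
    core = "".join(rng.choice(list(HYDROPHOBIC_CORE), size=core_len))
    tail_len = a_len - 1 - core_len - (2 if seroin_class == "Sn1" else 0)
    tail = "".join(rng.choice(list(SIGNAL_TAIL), size=tail_len))
    suffix = "EK" if seroin_class == "Sn1" else ""
    return "M" + core + tail + suffix


def default_spec(seroin_class: str, version: str, seed: int) -> SyntheticSpec:
    """Draw module lengths and motif placements for one record."""
    if (seroin_class, version) not in VERSION_PATTERNS:
        raise ValueError(f"unknown (class, version) pair ({seroin_class}, {version})")
    rng = np.random.default_rng(seed)
    pattern = VERSION_PATTERNS[(seroin_class, version)]
    ranges = MODULE_LENGTH_RANGES[seroin_class]
    lengths: dict[str, int] = {}
    for label, complete in pattern:
        lo, hi = ranges[label]
        if complete:
            lengths[label] = int(rng.integers(lo, hi + 1))
        else:
            lengths[label] = incomplete_length(seroin_class, label)
    a_len = lengths["A"]
    b1_len = lengths["B1"]
    motifs: list[tuple[str, str, int]] = []
    if seroin_class == "Sn1":
        # Trp lands a_len + offset residues after the initial Met (~20)
        motifs.append(("WEKDE", "B1", int(rng.integers(0, 3))))
    elif seroin_class == "Sn2":
        hi_off = min(b1_len - 4, 8)
        motifs.append(("RYGG", "B1", int(rng.integers(4, hi_off + 1))))
    else:  # Sn3
        w_abs = int(rng.integers(32, 37))
        w_off = w_abs - a_len
        motifs.append(("W", "B1", w_off))
        motifs.append(("VYGE", "B1", int(rng.integers(w_off + 2, b1_len - 3))))
    composition = {label: module_composition(seroin_class, label)
                   for label, _ in pattern if label != "A"}
    return SyntheticSpec(seroin_class, version, lengths, composition, motifs, seed)


def _build_modules(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, str]:
    """Generate per-module sequences (full pattern, before motif planting)."""
    modules: dict[str, str] = {}
    for label, _complete in spec.pattern:
        length = spec.module_lengths[label]
        if label == "A":
            modules[label] = _signal_peptide(length, spec.seroin_class, rng)
        else:
            template = class_template(spec.seroin_class, label)[:length]
            block = _mutate(template, spec.composition[label], rng)
            if label.startswith("C"):
                block = _enforce_pro_quota(block, rng)
            modules[label] = block
    return modules


def _plant_motifs(modules: dict[str, str], spec: SyntheticSpec) -> dict[str, str]:
    out = dict(modules)
    for motif, label, offset in spec.planted_motifs:
        if label not in out:
            raise ValueError(f"motif {motif!r} targets absent module {label}")
        block = out[label]
        if offset < 0 or offset + len(motif) > len(block):
            raise ValueError(
                f"motif {motif!r} at offset {offset} does not fit module {label} "
                f"of length {len(block)}"
            )
        out[label] = block[:offset] + motif + block[offset + len(motif):]
    return out


def make_protein(spec: SyntheticSpec, record_id: str = "syn-1",
                 species: tuple[str, str] = ("Synthetica", "exemplaris"),
                 gene_id: str = "g1") -> TruthRecord:
    """Assemble a synthetic seroin protein and its ground-truth architecture.

    Deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    modules = _plant_motifs(_build_modules(spec, rng), spec)
    annotations = []
    pos = 0
    parts = []
    for label, complete in spec.pattern:
        seq = modules[label]
        annotations.append(ModuleAnnotation(label, pos, pos + len(seq), complete))
        parts.append(seq)
        pos += len(seq)
    protein = "".join(parts)
    arch = Architecture(annotations, len(protein))
    return TruthRecord(record_id, spec, protein, "", arch, species, gene_id)


# ----------------------------------------------------------------------
# cDNA back-translation

_BACK_TABLE: dict[str, list[str]] = {}
from .seqio import CODON_TO_AA as _FWD  # noqa: E402

for _codon, _aa in sorted(_FWD.items()):
    _BACK_TABLE.setdefault(_aa, []).append(_codon)


def make_cdna(record: TruthRecord, utr5: int = 40, utr3: int = 60,
              seed: Optional[int] = None) -> str:
    """Back-translate a protein into a cDNA with random synonymous codons.

    The last three 5'-UTR bases are forced to an in-frame stop so that an
    accidental upstream in-frame ATG cannot extend the true ORF, and codon
    choices are re-drawn (deterministically) in the rare case a spurious
    shifted-frame ORF would outrun the intended one, so that
    ``longest_orf(make_cdna(r)).protein == r.protein`` always holds.
    """
    from .seqio import longest_orf

    base_seed = record.spec.seed + 7919 if seed is None else seed
    bases = "ACGT"
    for attempt in range(64):
        rng = np.random.default_rng(base_seed + 104729 * attempt)
        codons = []
        for aa in record.protein:
            options = _BACK_TABLE[aa]
            codons.append(options[int(rng.integers(len(options)))])
        stop = _BACK_TABLE["*"][int(rng.integers(3))]
        utr5_seq = "".join(rng.choice(list(bases), size=max(0, utr5)))
        if utr5 >= 3:
            utr5_seq = utr5_seq[:-3] + "TAA"
        utr3_seq = "".join(rng.choice(list(bases), size=max(0, utr3)))
        cdna = utr5_seq + "".join(codons) + stop + utr3_seq
        orf = longest_orf(cdna)
        if orf is not None and orf.protein == record.protein:
            return cdna
    raise RuntimeError(
        f"could not back-translate {record.id!r} without a competing ORF"
    )


# ----------------------------------------------------------------------
# Dataset assembly

DEFAULT_SPECIES_POOL: tuple[tuple[str, str], ...] = (
    ("Bombyx", "mori"), ("Galleria", "mellonella"), ("Antheraea", "yamamai"),
    ("Cydia", "pomonella"), ("Ostrinia", "nubilalis"), ("Plodia", "interpunctella"),
    ("Amyelois", "transitella"), ("Mamestra", "brassicae"), ("Papilio", "xuthus"),
    ("Pieris", "napi"), ("Spodoptera", "littoralis"), ("Helicoverpa", "armigera"),
)

TRUTH_HEADER_NOTE = (
    "module compositions and lengths are generator defaults standing in for the "
    "qualitative enrichments reported for real seroins"
)


def balanced_counts(n_per_class: int = 100) -> dict[tuple[str, str], int]:
    """Spread ``n_per_class`` records over each class's splice versions."""
    counts: dict[tuple[str, str], int] = {}
    for cls in CLASSES:
        versions = CLASS_VERSIONS[cls]
        base, extra = divmod(n_per_class, len(versions))
        for i, v in enumerate(versions):
            counts[(cls, v)] = base + (1 if i < extra else 0)
    return counts


def make_dataset(n_per_cell: Mapping[tuple[str, str], int],
                 species_pool: Sequence[tuple[str, str]] = DEFAULT_SPECIES_POOL,
                 seed: int = 42,
                 utr5: int = 40, utr3: int = 60) -> tuple[list[TruthRecord], pd.DataFrame]:
    """Generate a dataset with exact per-(class, version) counts.

    Species are assigned round-robin; each record is an independent gene.
    Returns the records plus a truth table (one row per record).
    """
    for key, n in n_per_cell.items():
        if key not in VERSION_PATTERNS:
            raise ValueError(f"unknown (class, version) cell {key}")
        if n < 0:
            raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[TruthRecord] = []
    idx = 0
    for (cls, version) in sorted(n_per_cell):
        for k in range(n_per_cell[(cls, version)]):
            rec_seed = int(rng.integers(2**31))
            spec = default_spec(cls, version, rec_seed)
            species = species_pool[idx % len(species_pool)]
            rec = make_protein(spec, record_id=f"syn-{cls}-{version}-{k:03d}",
                               species=species, gene_id=f"{cls}.{idx}")
            rec.cdna = make_cdna(rec, utr5=utr5, utr3=utr3)
            records.append(rec)
            idx += 1
    truth = truth_table(records)
    return records, truth


def truth_table(records: Iterable[TruthRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        spans = ";".join(
            f"{m.label}:{m.start}-{m.end}" for m in rec.true_architecture.modules
        )
        rows.append({
            "id": rec.id,
            "genus": rec.species[0],
            "species": rec.species[1],
            "seroin_class": rec.spec.seroin_class,
            "version": rec.spec.version,
            "gene_id": rec.gene_id,
            "module_spans": spans,
            "protein_length": len(rec.protein),
        })
    return pd.DataFrame(rows)


def make_gene_family(seroin_class: str, versions: Sequence[str],
                     species: tuple[str, str] = ("Galleria", "mellonella"),
                     seed: int = 0, gene_id: str = "g1",
                     id_prefix: str = "fam") -> list[TruthRecord]:
    """Splice isoforms of one gene: versions share the same module sequences.

    A full-length module set is generated once; each version keeps the
    modules its pattern retains, truncating incomplete modules to their
    N-terminal part.  All isoforms therefore share identical N-termini,
    mirroring alternative splicing of a single gene.
    """
    base_spec = default_spec(seroin_class, "L", seed)
    rng = np.random.default_rng(base_spec.seed)
    full_modules = _plant_motifs(_build_modules(base_spec, rng), base_spec)
    records = []
    for vi, version in enumerate(versions):
        pattern = VERSION_PATTERNS.get((seroin_class, version))
        if pattern is None:
            raise ValueError(f"version {version!r} not defined for {seroin_class}")
        lengths = {}
        modules = {}
        for label, complete in pattern:
            full = full_modules[label]
            if complete:
                modules[label] = full
            else:
                modules[label] = full[: incomplete_length(seroin_class, label)]
            lengths[label] = len(modules[label])
        spec = SyntheticSpec(seroin_class, version, lengths,
                             {l: module_composition(seroin_class, l)
                              for l, _ in pattern if l != "A"},
                             [], base_spec.seed)
        annotations = []
        pos = 0
        parts = []
        for label, complete in pattern:
            seq = modules[label]
            annotations.append(ModuleAnnotation(label, pos, pos + len(seq), complete))
            parts.append(seq)
            pos += len(seq)
        protein = "".join(parts)
        rec = TruthRecord(f"{id_prefix}-{version}", spec, protein, "",
                          Architecture(annotations, len(protein)), species, gene_id)
        rec.cdna = make_cdna(rec, seed=base_spec.seed + 13 * vi)
        records.append(rec)
    return records


# ----------------------------------------------------------------------
# Read simulation

def make_reads(cdnas: Mapping[str, str], abundances: Mapping[str, float],
               read_len: int = 150, n_reads: int = 1000,
               error_rate: float = 0.0, seed: int = 0
               ) -> tuple[list[SeqRecordLite], pd.DataFrame]:
    """Sample reads uniformly within transcripts chosen proportionally to weight.

    Substitution errors only; strands are sampled 50/50.  Returns reads and
    an origin table (read id, source transcript, start, strand).
    """
    ids = sorted(cdnas)
    weights = np.array([float(abundances.get(i, 0.0)) for i in ids])
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("abundances must be non-negative and not all zero")
    active = [i for i, w in zip(ids, weights) if w > 0]
    short = [i for i in active if len(cdnas[i]) < read_len]
    if short:
        raise ValueError(f"read_len {read_len} exceeds transcript length of {short[0]!r}")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    reads: list[SeqRecordLite] = []
    origins = []
    bases = np.array(list("ACGT"))
    for r in range(n_reads):
        src = ids[int(rng.choice(len(ids), p=probs))]
        seq = cdnas[src]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        fragment = seq[start : start + read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        if error_rate > 0:
            frag = list(fragment)
            err = rng.random(read_len) < error_rate
            for i in np.flatnonzero(err):
                choices = [b for b in "ACGT" if b != frag[i]]
                frag[i] = choices[int(rng.integers(3))]
            fragment = "".join(frag)
        rid = f"read-{r:05d}"
        reads.append(SeqRecordLite(rid, fragment, molecule="dna"))
        origins.append({"read_id": rid, "source_id": src, "start": start, "strand": strand})
    return reads, pd.DataFrame(origins)
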