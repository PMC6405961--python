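"""Recovery metrics against synthetic ground truth.

Used by the acceptance checks and by anyone validating parameter changes:
class/version recovery rates and the fraction of true module boundaries
matched within a tolerance by the predicted architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .pipeline import PipelineConfig, annotate_protein
from .synth import TruthRecord


@dataclass
class RecoveryStats:
    n_records: int
    class_correct: int
    version_correct: int
    boundaries_total: int
    boundaries_recovered: int

    @property
    def class_recovery(self) -> float:
        return self.class_correct / self.n_records if self.n_records else 0.0

    @property
    def version_recovery(self) -> float:
        return self.version_correct / self.n_records if self.n_records else 0.0

    @property
    def boundary_recovery(self) -> float:
        return (self.boundaries_recovered / self.boundaries_total
                if self.boundaries_total else 0.0)


def _boundaries(spans: Sequence[tuple[int, int]]) -> set[int]:
    points = set()
    for start, end in spans:
        points.add(start)
        points.add(end)
    return points


def _parse_spans(field: str) -> list[tuple[int, int]]:
    out = []
    for part in field.split(";"):
        if not part:
            continue
        _, coords = part.split(":")
        start, end = coords.split("-")
        out.append((int(start), int(end)))
    return out


def evaluate_recovery(records: Sequence[TruthRecord],
                      config: PipelineConfig | None = None,
                      boundary_tol: int = 5) -> RecoveryStats:
    """Annotate each truth record's protein and score against ground truth.

    A true boundary counts as recovered when a predicted module boundary
    lies within ``boundary_tol`` residues of it.
    """
    config = config or PipelineConfig()
    n = len(records)
    class_ok = version_ok = 0
    b_total = b_got = 0
    for rec in records:
        row = annotate_protein(rec.protein, config)
        if row["seroin_class"] == rec.spec.seroin_class:
            class_ok += 1
            if row.get("version") == rec.spec.version:
                version_ok += 1
        true_b = _boundaries([(m.start, m.end) for m in rec.true_architecture.modules])
        pred_b = _boundaries(_parse_spans(row.get("module_spans", "")))
        for tb in sorted(true_b):
            b_total += 1
            if any(abs(tb - pb) <= boundary_tol for pb in pred_b):
                b_got += 1
    return RecoveryStats(n, class_ok, version_ok, b_total, b_got)
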