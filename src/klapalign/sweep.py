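"""Top-level alignment pipeline: sweep the cardinality k and pick the winner.

Biologically meaningful alignments of genuinely similar proteins match 85%
or more of the smaller protein, so k is swept from 100% down to 85% of
min(L_A, L_B). For each k an independent master search is run and the
alignment scored; the sweep stops at the first k whose SAS_f drops below
the 4 A similarity cutoff. If no k reaches the cutoff, the explored
alignment with the lowest SAS_f is returned and the pair is flagged
dissimilar (ties broken by larger fragment length, then lower RMSD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .assignment import Alignment
from .geometry import RigidTransform
from .optimizer import SearchConfig, minimize_F
from .scoring import MIN_FRAGMENT, ScoreReport, compute_scores

__all__ = ["SweepConfig", "PerKRecord", "AlignmentOutcome", "align"]


@dataclass(frozen=True)
class SweepConfig:
    """k-sweep settings: fractions of min(L_A, L_B), step, SAS_f cutoff."""

    k_max_frac: float = 1.0
    k_min_frac: float = 0.85
    k_step: int | None = None  # None -> max(1, round(0.01 * L_min))
    sasf_cutoff: float = 4.0
    search: SearchConfig = field(default_factory=SearchConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.k_min_frac <= self.k_max_frac <= 1.0:
            raise ValueError("require 0 < k_min_frac <= k_max_frac <= 1")
        if self.k_step is not None and self.k_step < 1:
            raise ValueError("k_step must be >= 1")
        if self.sasf_cutoff <= 0:
            raise ValueError("sasf_cutoff must be positive")


@dataclass(frozen=True)
class PerKRecord:
    k: int
    rmsd: float
    report: ScoreReport


@dataclass(frozen=True)
class AlignmentOutcome:
    """Result of a full sweep: the selected alignment and its context."""

    alignment: Alignment
    transform: RigidTransform
    report: ScoreReport
    per_k: tuple  # of PerKRecord, in sweep order
    selected_k: int
    terminated_early: bool
    dissimilar: bool  # True when even the best SAS_f misses the cutoff


def _k_schedule(l_min: int, config: SweepConfig):
    k_max = max(1, round(config.k_max_frac * l_min))
    k_min = max(1, round(config.k_min_frac * l_min))
    step = config.k_step if config.k_step is not None else max(1, round(0.01 * l_min))
    return list(range(k_max, k_min - 1, -step))


def align(structure_a, structure_b, config: SweepConfig | None = None) -> AlignmentOutcome:
    """Align structure A onto structure B.

    Both structures need at least five residues — below that the fragment
    length N_f is identically zero and SAS_f is undefined; align whole
    domains, or widen the residue selection, instead.
    """
    config = config or SweepConfig()
    l_a, l_b = structure_a.length, structure_b.length
    if min(l_a, l_b) < MIN_FRAGMENT:
        raise ValueError(
            f"structures must have >= {MIN_FRAGMENT} residues "
            f"(got {l_a} and {l_b}): fragment-based scoring is undefined below that"
        )

    records = []
    best = None  # (sort key, index into records, transform)
    terminated = False
    for k in _k_schedule(min(l_a, l_b), config):
        transform, result, _ = minimize_F(structure_a, structure_b, k, config.search)
        report = compute_scores(result.rmsd, result.alignment, l_a, l_b)
        records.append((PerKRecord(k, result.rmsd, report), result.alignment, transform))
        key = (report.sas_f, -report.n_f, report.rmsd)
        if best is None or key < best[0]:
            best = (key, len(records) - 1, transform)
        if report.sas_f < config.sasf_cutoff:
            terminated = True
            break

    record, alignment, transform = records[best[1]]
    return AlignmentOutcome(
        alignment=alignment,
        transform=transform,
        report=record.report,
        per_k=tuple(r[0] for r in records),
        selected_k=record.k,
        terminated_early=terminated,
        dissimilar=not record.report.sas_f < config.sasf_cutoff,
    )


def write_per_k_tsv(path, outcome: AlignmentOutcome) -> None:
    """Per-k sweep summary as TSV."""
    rows = ["k\trmsd\tn_match\tn_f\tsas\tsi\tsas_f"]
    for rec in outcome.per_k:
        r = rec.report
        sas_f = "inf" if math.isinf(r.sas_f) else f"{r.sas_f:.4f}"
        rows.append(
            f"{rec.k}\t{r.rmsd:.4f}\t{r.n_match}\t{r.n_f}\t{r.sas:.4f}\t{r.si:.4f}\t{sas_f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
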