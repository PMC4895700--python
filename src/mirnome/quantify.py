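"""Multi-mapping-corrected RPM quantification and fold-change signatures.

Abundance of a miRNA in one library is expressed as

    RPM = C / (M * N) * 10**9

where C is the read count aligned to the miRNA's chromosomal region, M the
multi-mapping multiplicity across annotated miRNA regions, and N the total
count of genome-mapped reads in the library. The 10**9 scale is applied
exactly as defined; with M = 1 it reduces to reads-per-million times 1000.

Differential miRNAs between two conditions are called by a pure fold-change
threshold (default 1.5, inclusive), with a pseudocount floor standing in for
unobserved species; no replicate-based statistics are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mapping import AnnotatedTag


@dataclass(frozen=True)
class MiRNAQuant:
    mirna_id: str
    C: float
    M: float
    N: int
    rpm: float


@dataclass(frozen=True)
class FoldRecord:
    """One row of a two-condition fold table."""

    mirna_id: str
    rpm_a: float
    rpm_b: float
    fold_a_vs_b: float
    direction: str  # up | down | unchanged


@dataclass(frozen=True)
class DifferentialCall:
    comparison: str
    up_set: frozenset
    down_set: frozenset
    threshold: float


def rpm(C: float, M: float, N: int) -> float:
    """C / (M * N) * 1e9; exactly 0 for C = 0."""
    if M <= 0 or N <= 0:
        raise ValueError("M and N must be positive")
    if C < 0 or C > N:
        raise ValueError("C must satisfy 0 <= C <= N")
    return C / (M * N) * 1e9


def library_size(annotated: list[AnnotatedTag]) -> int:
    """N: total count of genome-mapped reads (mRNA-screened tags included
    when they also place on the genome)."""
    return sum(at.tag.count for at in annotated if at.placements)


def quantify(
    annotated: list[AnnotatedTag], m_mode: str = "max"
) -> list[MiRNAQuant]:
    """Per-miRNA RPM profile of one library.

    For each annotated miRNA, C sums the counts of tags assigned to it.
    The multiplicity M is ambiguous in principle for a region served by
    several tags; three resolutions are offered:

    - ``max``  (default): M = max multiplicity over the miRNA's tags;
    - ``mean``: count-weighted mean multiplicity;
    - ``per-read``: each read contributes 1/m to each of its m regions and
      M is pinned at 1 (fractional-assignment semantics).

    miRNAs with zero assigned reads are absent from the profile rather
    than reported at RPM 0.
    """
    if m_mode not in ("max", "mean", "per-read"):
        raise ValueError(f"unknown m_mode {m_mode!r}")
    N = library_size(annotated)
    per_mirna: dict[str, list[tuple[int, int]]] = {}
    for at in annotated:
        ann = at.annotation
        if ann.category != "known_miRNA":
            continue
        for mid in ann.matched_mirna_ids:
            per_mirna.setdefault(mid, []).append((at.tag.count, ann.multiplicity_m))
    profile = []
    for mid in sorted(per_mirna):
        pairs = per_mirna[mid]
        if m_mode == "per-read":
            C = sum(c / m for c, m in pairs)
            M = 1.0
        else:
            C = sum(c for c, _ in pairs)
            if m_mode == "max":
                M = float(max(m for _, m in pairs))
            else:
                M = sum(c * m for c, m in pairs) / sum(c for c, _ in pairs)
        profile.append(MiRNAQuant(mid, C, M, N, rpm(C, M, N)))
    return profile


def single_read_floor(n_a: int, n_b: int) -> float:
    """Default fold floor: the RPM of a single uniquely-mapped read in the
    larger of the two libraries."""
    return rpm(1, 1, max(n_a, n_b))


def fold_change(rpm_a: float, rpm_b: float, floor: float) -> float:
    """max(rpm_a, floor) / max(rpm_b, floor).

    Antisymmetric (fold(a,b) * fold(b,a) = 1) whenever both values exceed
    the floor.
    """
    if rpm_a < 0 or rpm_b < 0:
        raise ValueError("RPM values must be non-negative")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return max(rpm_a, floor) / max(rpm_b, floor)


def fold_table(
    profile_a: list[MiRNAQuant],
    profile_b: list[MiRNAQuant],
    threshold: float = 1.5,
    floor: float | None = None,
) -> list[FoldRecord]:
    """Per-miRNA fold records of condition a versus condition b.

    The id universe is the union of the two profiles; a miRNA missing from
    one side enters at RPM 0 and is rescued by the floor.
    """
    a = {q.mirna_id: q.rpm for q in profile_a}
    b = {q.mirna_id: q.rpm for q in profile_b}
    if floor is None:
        n_a = profile_a[0].N if profile_a else 1
        n_b = profile_b[0].N if profile_b else 1
        floor = single_read_floor(n_a, n_b)
    records = []
    for mid in sorted(set(a) | set(b)):
        fa = fold_change(a.get(mid, 0.0), b.get(mid, 0.0), floor)
        if fa >= threshold:
            direction = "up"
        elif fa <= 1.0 / threshold:
            direction = "down"
        else:
            direction = "unchanged"
        records.append(FoldRecord(mid, a.get(mid, 0.0), b.get(mid, 0.0), fa, direction))
    return records


def call_differential(
    profile_a: list[MiRNAQuant],
    profile_b: list[MiRNAQuant],
    comparison: str = "a_vs_b",
    threshold: float = 1.5,
    floor: float | None = None,
) -> DifferentialCall:
    """Up/down miRNA sets at a fold threshold (boundary fold is up, per the
    inclusive >= rule; down at fold <= 1/threshold)."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    records = fold_table(profile_a, profile_b, threshold, floor)
    up = frozenset(r.mirna_id for r in records if r.direction == "up")
    down = frozenset(r.mirna_id for r in records if r.direction == "down")
    return DifferentialCall(comparison, up, down, threshold)


def check_table_row(
    rpm_a: float, rpm_b: float, fold_a: float, fold_b: float, tol: float = 1e-3
) -> dict:
    """Internal-consistency check of a published fold-table row.

    A row lists a miRNA's RPM in two conditions plus each condition's fold
    versus a common (unprinted) baseline; consistency demands
    rpm_a/rpm_b == fold_a/fold_b. Returns the relative residual, the
    consistency flag at ``tol``, and the implied baseline RPM rpm_b/fold_b.
    """
    if min(rpm_a, rpm_b, fold_a, fold_b) <= 0:
        raise ValueError("all four row values must be positive")
    expected = fold_a / fold_b
    residual = abs(rpm_a / rpm_b - expected) / expected
    return {
        "residual": residual,
        "consistent": residual <= tol,
        "baseline_rpm": rpm_b / fold_b,
    }


# -- tabular I/O -----------------------------------------------------------


def profile_to_frame(profile: list[MiRNAQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [(q.mirna_id, q.C, q.M, q.N, q.rpm) for q in profile],
        columns=["mirna_id", "C", "M", "N", "rpm"],
    )


def folds_to_frame(records: list[FoldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mirna_id, r.rpm_a, r.rpm_b, r.fold_a_vs_b, r.direction) for r in records],
        columns=["mirna_id", "rpm_a", "rpm_b", "fold_a_vs_b", "direction"],
    )
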