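"""Novel-miRNA discovery from unannotated read stacks.

Genomic placements that fall outside the known-miRNA catalog are clustered
into read stacks; each stack's dominant tag nominates a putative mature
sequence, candidate precursor windows around it are excised and folded, and
a candidate is accepted only when the folded window shows miRNA-hairpin
topology under a quorum of detector presets of increasing stringency. This
mirrors the practice of intersecting several independent discovery tools:
one bespoke detector run at three stringencies, candidates kept when all
(or a configured quorum of) presets agree on the same precursor window.

Surviving candidates are cross-checked against Argonaute RIP-seq libraries:
a candidate is verified when enough RIP reads cover its mature interval in
enough independent datasets, evidence of RISC loading.

Secondary structure comes from a Nussinov-style dynamic program that
maximises Watson-Crick plus G-U wobble pair count over nested structures
with a minimum hairpin-loop size; acceptance is topological (a single
stem-loop with a well-paired mature arm), so pair-count optimisation stands
in for thermodynamic folding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .mapping import AnnotatedTag, Placement, revcomp

logger = logging.getLogger(__name__)

# Watson-Crick + GU wobble, DNA alphabet (T read as U)
_PAIRS = {"AT", "TA", "GC", "CG", "GT", "TG"}

MIN_FOLD_LEN = 2
MAX_FOLD_LEN = 200


def can_pair(a: str, b: str) -> bool:
    return a + b in _PAIRS


@dataclass(frozen=True)
class FoldResult:
    """Nested secondary structure: 1-based pair list plus dot-bracket."""

    sequence: str
    pairing: tuple[tuple[int, int], ...]
    structure: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def paired_fraction(self) -> float:
        return 2 * self.n_pairs / len(self.sequence)


def pairs_to_structure(pairing, length: int) -> str:
    chars = ["."] * length
    for i, j in pairing:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def structure_to_pairs(structure: str) -> tuple[tuple[int, int], ...]:
    stack: list[int] = []
    pairs = []
    for pos, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            pairs.append((stack.pop(), pos))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


def fold_nussinov(seq: str, min_loop: int = 3) -> FoldResult:
    """Maximum base-pair nested structure of ``seq``.

    Dynamic program over pair count (Watson-Crick + GU) with hairpin loops
    of at least ``min_loop`` unpaired bases. The traceback is deterministic:
    closing pair (i, j) is preferred over any other decomposition on ties,
    then trimming an unpaired end, then the leftmost bifurcation.
    """
    seq = seq.upper()
    n = len(seq)
    if not (MIN_FOLD_LEN <= n <= MAX_FOLD_LEN):
        raise ValueError(f"sequence length {n} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    dp = np.zeros((n, n), dtype=np.int32)
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pairable[i, j] = can_pair(seq[i], seq[j])
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = max(dp[i + 1, j], dp[i, j - 1])
            if pairable[i, j]:
                best = max(best, dp[i + 1, j - 1] + 1)
            if j - i > 1:
                ks = dp[i, i : j] + dp[i + 1 : j + 1, j]
                best = max(best, int(ks.max()))
            dp[i, j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or dp[i, j] == 0:
            continue
        if pairable[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairs.append((i + 1, j + 1))
            stack.append((i + 1, j - 1))
        elif dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
        elif dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if dp[i, k] + dp[k + 1, j] == dp[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    pairing = tuple(sorted(pairs))
    assert len(pairing) == dp[0, n - 1]
    return FoldResult(seq, pairing, pairs_to_structure(pairing, n))


# -- hairpin classification ------------------------------------------------


@dataclass(frozen=True)
class HairpinPreset:
    """One stringency level of the hairpin detector.

    ``min_mature_paired`` is the number of mature bases that must pair
    into the duplex, i.e. with partners outside the mature span (defaults
    tuned to a 22-mer mature); ``min_stem_fraction`` the paired fraction
    required of the whole precursor; ``max_duplex_excess`` bounds how much
    the genomic span of the mature's partners may exceed the pair count —
    a real mature:star duplex is compact (the star is a near-reverse-
    complement, so partners are nearly contiguous), while incidental stems
    folded by random sequence are riddled with bulges.
    ``max_duplex_wobble`` caps G-U pairs in the duplex for the same
    reason: a near-reverse-complement star pairs canonically, whereas
    chance duplexes lean on wobble. ``min_terminal_loop`` is the smallest
    credible terminal-loop size: hairpin processing needs a real loop,
    and chance duplexes often close on a near-zero one.
    """

    name: str
    min_mature_paired: int
    min_stem_fraction: float
    max_duplex_excess: int
    max_duplex_wobble: int
    min_terminal_loop: int


DEFAULT_PRESETS = (
    HairpinPreset("relaxed", 14, 0.50, 6, 4, 4),
    HairpinPreset("standard", 15, 0.55, 4, 3, 5),
    HairpinPreset("strict", 16, 0.60, 2, 2, 6),
)
DEFAULT_PRESET = DEFAULT_PRESETS[1]


@dataclass(frozen=True)
class HairpinCall:
    passed: bool
    reasons: tuple[str, ...]


def terminal_loops(pairing) -> list[tuple[int, int]]:
    """Closing pairs of hairpin loops: pairs with no pair nested inside."""
    return [
        (i, j)
        for i, j in pairing
        if not any(i < a and b < j for a, b in pairing)
    ]


def classify_hairpin(
    fold: FoldResult,
    mature_interval: tuple[int, int],
    preset: HairpinPreset = DEFAULT_PRESET,
) -> HairpinCall:
    """miRNA-hairpin acceptance test on a folded precursor.

    Pass requires (a) exactly one terminal loop (a single stem-loop),
    (b) the mature span entirely on one arm, clear of that loop,
    (c) at least ``preset.min_mature_paired`` mature bases paired into the
    duplex (partners outside the mature span),
    (d) precursor paired fraction >= ``preset.min_stem_fraction``, and
    (e) a compact, canonical duplex: the partners' genomic span may exceed
    the duplex pair count by at most ``preset.max_duplex_excess`` nt and
    at most ``preset.max_duplex_wobble`` duplex pairs may be G-U.
    ``mature_interval`` is 1-based within ``fold.sequence``.
    """
    ms, me = mature_interval
    if not (1 <= ms <= me <= len(fold.sequence)):
        raise ValueError("mature interval outside precursor")
    reasons = []
    if not fold.pairing:
        return HairpinCall(False, ("no_stem",))
    loops = terminal_loops(fold.pairing)
    if len(loops) != 1:
        reasons.append("not_single_stem_loop")
    else:
        li, lj = loops[0]
        if not (me <= li or ms >= lj):
            reasons.append("mature_overlaps_terminal_loop")
        if lj - li - 1 < preset.min_terminal_loop:
            reasons.append("terminal_loop_too_small")
    duplex = [
        (a, b) for a, b in fold.pairing if (ms <= a <= me) != (ms <= b <= me)
    ]
    if len(duplex) < preset.min_mature_paired:
        reasons.append("mature_underpaired")
    else:
        partners = [b if ms <= a <= me else a for a, b in duplex]
        excess = (max(partners) - min(partners) + 1) - len(duplex)
        if excess > preset.max_duplex_excess:
            reasons.append("duplex_bulged")
        wobble = sum(
            1
            for a, b in duplex
            if {fold.sequence[a - 1], fold.sequence[b - 1]} == {"G", "T"}
        )
        if wobble > preset.max_duplex_wobble:
            reasons.append("duplex_wobbly")
    if fold.paired_fraction < preset.min_stem_fraction:
        reasons.append("weak_stem")
    return HairpinCall(not reasons, tuple(reasons))


# -- read stacks -----------------------------------------------------------


@dataclass(frozen=True)
class ReadStack:
    chrom: str
    strand: str
    interval: tuple[int, int]
    tags: tuple[tuple[str, int, int], ...]  # (tag_seq, count, offset in stack)

    @property
    def total_count(self) -> int:
        return sum(c for _, c, _ in self.tags)


def build_stacks(
    placed: list[tuple[Placement, int]], max_gap: int = 10, min_reads: int = 5
) -> list[ReadStack]:
    """Single-linkage clustering of placements along each chrom+strand.

    Placements whose intervals are separated by at most ``max_gap`` nt
    (overlap counts as gap 0) join one stack; stacks carrying fewer than
    ``min_reads`` total reads are discarded.
    """
    by_key: dict[tuple[str, str], list[tuple[Placement, int]]] = {}
    for p, count in placed:
        by_key.setdefault((p.chrom, p.strand), []).append((p, count))
    stacks = []
    for (chrom, strand), items in sorted(by_key.items()):
        items.sort(key=lambda pc: (pc[0].start, pc[0].end))
        cluster: list[tuple[Placement, int]] = []
        cluster_end = None
        for p, count in items + [(None, 0)]:  # sentinel flush
            if p is not None and (cluster_end is None or p.start - cluster_end - 1 <= max_gap):
                cluster.append((p, count))
                cluster_end = max(cluster_end or 0, p.end)
                continue
            if cluster:
                start = min(q.start for q, _ in cluster)
                end = max(q.end for q, _ in cluster)
                stack = ReadStack(
                    chrom,
                    strand,
                    (start, end),
                    tuple((q.tag_seq, c, q.start - start) for q, c in cluster),
                )
                if stack.total_count >= min_reads:
                    stacks.append(stack)
            cluster = [] if p is None else [(p, count)]
            cluster_end = None if p is None else p.end
    return stacks


def unannotated_placements(annotated: list[AnnotatedTag]) -> list[tuple[Placement, int]]:
    """Stack input: every placement of every unannotated tag."""
    return [
        (p, at.tag.count)
        for at in annotated
        if at.annotation.category == "unannotated"
        for p in at.placements
    ]


# -- consensus candidate detection ----------------------------------------

DEFAULT_FLANK = 70


def star_scan(
    wseq: str,
    mature_local: tuple[int, int],
    min_gap: int = 3,
    n_peaks: int = 3,
) -> list[tuple[int, int]]:
    """Propose precursor spans by locating the star arm in a window.

    The star arm of a genuine precursor is a near-reverse-complement of
    the mature, so sliding the mature along the window and scoring
    antiparallel pairability (Watson-Crick + GU) peaks sharply at the star
    position. Returns up to ``n_peaks`` non-overlapping candidate spans
    (1-based, covering mature and putative star), best score first;
    candidate star sites must be separated from the mature by at least
    ``min_gap`` nt of prospective loop.
    """
    ms, me = mature_local
    mature = wseq[ms - 1 : me]
    L = len(mature)
    scores = []
    for s in range(0, len(wseq) - L + 1):
        if s + L >= ms - min_gap and s + 1 <= me + min_gap:
            continue  # overlaps mature or leaves no loop
        score = sum(
            1 for i in range(L) if can_pair(mature[i], wseq[s + L - 1 - i])
        )
        scores.append((score, s))
    scores.sort(key=lambda t: (-t[0], t[1]))
    spans: list[tuple[int, int]] = []
    taken: list[tuple[int, int]] = []
    for score, s in scores:
        site = (s + 1, s + L)
        if any(not (site[1] < a or site[0] > b) for a, b in taken):
            continue
        taken.append(site)
        spans.append((min(ms, site[0]), max(me, site[1])))
        if len(spans) == n_peaks:
            break
    return spans


@dataclass(frozen=True)
class NovelCandidate:
    candidate_id: str
    chrom: str
    strand: str
    precursor_interval: tuple[int, int]
    mature_seq: str
    mature_interval: tuple[int, int]
    fold: FoldResult | None
    preset_hits: tuple[tuple[str, bool], ...]
    consensus: bool
    total_count: int
    ago_reads_per_dataset: tuple[int, ...] = ()
    ago_verified: bool = False
    expression: tuple[tuple[str, float], ...] = ()  # (condition, rpm)


def _modal_tag(stack: ReadStack) -> tuple[str, int, int]:
    """Highest-count tag; ties broken by 5'-most start on the stack's strand."""
    def key(t):
        seq, count, offset = t
        five_prime = offset if stack.strand == "+" else -(offset + len(seq) - 1)
        return (-count, five_prime, seq)

    return min(stack.tags, key=key)


def consensus_detect(
    stacks: list[ReadStack],
    genome: dict[str, str],
    presets: tuple[HairpinPreset, ...] = DEFAULT_PRESETS,
    quorum: int = 3,
    flank: int = DEFAULT_FLANK,
    min_loop: int = 3,
) -> list[NovelCandidate]:
    """Multi-preset consensus discovery over read stacks.

    For each stack the modal tag defines the putative mature sequence. A
    window of ``flank`` nt on each side of the mature is excised, the star
    arm is sought by the pairability scan (``star_scan``), and each
    proposed precursor span is folded in isolation and judged by every
    preset. The span satisfying the most presets is reported (best scan
    peak on ties); the candidate reaches consensus when at least
    ``quorum`` presets accept that precursor. Candidates are returned
    sorted by descending read support.
    """
    if quorum > len(presets):
        raise ValueError("quorum exceeds number of presets")
    if len({p.name for p in presets}) != len(presets):
        raise ValueError("presets must be distinct")
    candidates = []
    for stack in stacks:
        seq, count, offset = _modal_tag(stack)
        ms = stack.interval[0] + offset
        mature_iv = (ms, ms + len(seq) - 1)
        chrom_len = len(genome[stack.chrom])
        ws = max(ms - flank, 1)
        we = min(mature_iv[1] + flank, chrom_len)
        wseq = genome[stack.chrom][ws - 1 : we]
        if stack.strand == "-":
            wseq = revcomp(wseq)
            local = (we - mature_iv[1] + 1, we - ms + 1)
        else:
            local = (ms - ws + 1, mature_iv[1] - ws + 1)
        best = None  # (n_passed, -peak order, calls, fold, local span)
        for order, span in enumerate(star_scan(wseq, local, min_gap=min_loop)):
            fold = fold_nussinov(wseq[span[0] - 1 : span[1]], min_loop)
            span_mature = (local[0] - span[0] + 1, local[1] - span[0] + 1)
            calls = {
                p.name: classify_hairpin(fold, span_mature, p).passed
                for p in presets
            }
            entry = (sum(calls.values()), -order, calls, fold, span)
            if best is None or entry[:2] > best[:2]:
                best = entry
        if best is None:
            calls = {p.name: False for p in presets}
            n_passed, fold, giv = 0, None, (ws, we)
        else:
            n_passed, _, calls, fold, span = best
            if stack.strand == "+":
                giv = (ws + span[0] - 1, ws + span[1] - 1)
            else:
                giv = (we - span[1] + 1, we - span[0] + 1)
        hits = tuple((p.name, calls[p.name]) for p in presets)
        candidates.append(
            NovelCandidate(
                candidate_id=f"novel-{stack.chrom}-{mature_iv[0]}-{stack.strand}",
                chrom=stack.chrom,
                strand=stack.strand,
                precursor_interval=giv,
                mature_seq=seq,
                mature_interval=mature_iv,
                fold=fold,
                preset_hits=hits,
                consensus=n_passed >= quorum,
                total_count=stack.total_count,
            )
        )
    candidates.sort(key=lambda c: (-c.total_count, c.candidate_id))
    return candidates


def verify_agoip(
    candidates: list[NovelCandidate],
    ago_libraries: list[list[AnnotatedTag]],
    min_reads: int = 5,
    min_datasets: int = 1,
    min_overlap_frac: float = 0.5,
) -> list[NovelCandidate]:
    """Set the Ago-RIP verification flag on each candidate.

    A RIP read supports a candidate when at least ``min_overlap_frac`` of
    the read lies inside the candidate's mature interval on the same
    strand; the candidate is verified when at least ``min_reads``
    supporting reads occur in at least ``min_datasets`` libraries.
    """
    if not ago_libraries:
        logger.warning("no Ago-RIP libraries supplied; all candidates unverified")
    out = []
    for cand in candidates:
        per_dataset = []
        for lib in ago_libraries:
            n = 0
            for at in lib:
                need = min_overlap_frac * len(at.tag.insert_seq)
                for p in at.placements:
                    if p.chrom != cand.chrom or p.strand != cand.strand:
                        continue
                    lo = max(p.start, cand.mature_interval[0])
                    hi = min(p.end, cand.mature_interval[1])
                    if hi - lo + 1 >= need:
                        n += at.tag.count
                        break
            per_dataset.append(n)
        verified = sum(n >= min_reads for n in per_dataset) >= min_datasets
        out.append(
            replace(
                cand,
                ago_reads_per_dataset=tuple(per_dataset),
                ago_verified=verified,
            )
        )
    return out


# -- output ----------------------------------------------------------------


def write_candidates_tsv(candidates: list[NovelCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "candidate_id\tchrom\tstrand\tprecursor_start\tprecursor_end\t"
            "mature_seq\tmature_start\tmature_end\ttotal_count\tpreset_hits\t"
            "consensus\tago_reads\tago_verified\texpression\n"
        )
        for c in candidates:
            hits = ",".join(f"{n}:{int(v)}" for n, v in c.preset_hits)
            expr = ",".join(f"{cond}:{rpm:.6g}" for cond, rpm in c.expression)
            fh.write(
                f"{c.candidate_id}\t{c.chrom}\t{c.strand}\t"
                f"{c.precursor_interval[0]}\t{c.precursor_interval[1]}\t"
                f"{c.mature_seq}\t{c.mature_interval[0]}\t{c.mature_interval[1]}\t"
                f"{c.total_count}\t{hits}\t{int(c.consensus)}\t"
                f"{','.join(map(str, c.ago_reads_per_dataset))}\t"
                f"{int(c.ago_verified)}\t{expr}\n"
            )


def write_candidates_gff3(candidates: list[NovelCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            fh.write(
                f"{c.chrom}\tmirnome\tmiRNA_primary_transcript\t"
                f"{c.precursor_interval[0]}\t{c.precursor_interval[1]}\t.\t"
                f"{c.strand}\t.\tID={c.candidate_id}\n"
            )
            fh.write(
                f"{c.chrom}\tmirnome\tmiRNA\t{c.mature_interval[0]}\t"
                f"{c.mature_interval[1]}\t.\t{c.strand}\t.\t"
                f"ID={c.candidate_id}_mature;Parent={c.candidate_id}\n"
            )


def write_structures(candidates: list[NovelCandidate], path) -> None:
    """Dot-bracket text, one candidate per block."""
    with open(path, "w") as fh:
        for c in candidates:
            if c.fold is None:
                continue
            fh.write(f">{c.candidate_id}\n{c.fold.sequence}\n{c.fold.structure}\n")
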