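"""Synthetic small-RNA worlds with known ground truth.

The generator builds a toy genome, plants known and novel miRNA hairpins
into it, and emits adapter-ligated sequencing libraries for three
experimental conditions plus Argonaute-RIP libraries, together with a
machine-readable truth table. Planted hairpins are constructed to be real
miRNA precursors by this package's own standards: mature arm + short loop +
near-reverse-complement star arm, validated at generation time against the
hairpin classifier, with the mature sequence occurring exactly once in the
genome so read placement is unambiguous.

Library reads are error-free by default (the mapper is exact-match) and
carry a constant quality string; each read is a mature insert followed by a
6-18 nt prefix of the 3' adapter. Contaminant classes mirror the QC
cascade's drop reasons: poly-A artifacts, ambiguous-base reads, 5'-adapter
dimers and degraded-mRNA fragments, each emitted at a configured fraction
and constructed to classify as exactly that drop reason.

True abundances are per-condition multinomial weights over planted miRNAs;
a condition's fold change for a miRNA is the ratio of its normalised
weights. When a requested fold assignment admits it, baseline weights are
rebalanced so the normalised ratios equal the requested folds exactly,
making parameter recovery well-defined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import (
    DEFAULT_PRESETS,
    classify_hairpin,
    fold_nussinov,
)
from .mapping import MirnaAnnotation, revcomp
from .qc import (
    DEFAULT_ADAPTER_3P,
    DEFAULT_ADAPTER_5P,
    QCParams,
    RawRead,
    classify_read,
)

BASES = "ACGT"


class PlacementError(ValueError):
    """A planted locus overlaps an existing one."""


class ConfigError(ValueError):
    pass


@dataclass
class SimulatedGenome:
    chrom_name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1000:
            raise ValueError("genome length must be at least 1000")
        if set(self.sequence) - set(BASES):
            raise ValueError("genome alphabet restricted to ACGT")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantedMiRNA:
    mirna_id: str
    chrom: str
    strand: str
    precursor_interval: tuple[int, int]
    mature_interval: tuple[int, int]
    mature_seq: str
    is_known: bool

    def to_annotation(self) -> MirnaAnnotation:
        return MirnaAnnotation(
            self.mirna_id,
            self.chrom,
            self.strand,
            self.precursor_interval,
            self.mature_interval,
            self.mature_seq,
        )


@dataclass(frozen=True)
class LibraryConfig:
    n_reads: int = 100_000
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_tail_range: tuple[int, int] = (6, 18)
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.adapter_tail_range
        if not (1 <= lo <= hi <= len(self.adapter_3p)):
            raise ConfigError("adapter_tail_range outside [1, len(adapter_3p)]")
        if self.n_reads < 1:
            raise ConfigError("n_reads must be at least 1")


CONTAMINANT_CLASSES = ("polyA", "ambiguous", "adapter5", "mrna")


@dataclass
class TruthTable:
    """Ground truth: per-condition abundance weights and realised folds."""

    baseline: str
    abundance: dict  # condition -> {mirna_id: weight}, each summing to 1
    contaminants: dict  # class -> fraction
    seed: int

    def __post_init__(self):
        for cond, weights in self.abundance.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances for {cond!r} sum to {total}, not 1")
        bad = set(self.contaminants) - set(CONTAMINANT_CLASSES)
        if bad:
            raise ValueError(f"unknown contaminant classes: {bad}")
        fracs = list(self.contaminants.values())
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("contaminant fractions must lie in [0,1] and sum below 1")

    @property
    def conditions(self) -> list[str]:
        return list(self.abundance)

    def fold(self, mirna_id: str, cond_a: str, cond_b: str) -> float:
        return self.abundance[cond_a][mirna_id] / self.abundance[cond_b][mirna_id]

    def to_tsv(self, path) -> None:
        conds = self.conditions
        with open(path, "w") as fh:
            header = ["mirna_id"] + [f"abundance_{c}" for c in conds]
            header += [f"fold_{c}_vs_{self.baseline}" for c in conds if c != self.baseline]
            fh.write("\t".join(header) + "\n")
            for mid in self.abundance[self.baseline]:
                row = [mid] + [f"{self.abundance[c][mid]:.10g}" for c in conds]
                row += [
                    f"{self.fold(mid, c, self.baseline):.10g}"
                    for c in conds
                    if c != self.baseline
                ]
                fh.write("\t".join(row) + "\n")


# -- genome and hairpin planting ------------------------------------------


def generate_genome(
    length: int, gc_fraction: float = 0.42, seed: int = 0, chrom_name: str = "chrS"
) -> SimulatedGenome:
    """Random genome with i.i.d. bases at the requested GC content."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    seq = "".join(rng.choice(list(BASES), size=length, p=[at, gc, gc, at]))
    return SimulatedGenome(chrom_name, seq)


def _random_mature(rng, length: int, qc: QCParams) -> str:
    """A mature-like insert that survives QC on its own merits."""
    while True:
        seq = "".join(rng.choice(list(BASES), size=length))
        if seq.endswith("A" * qc.polya_run):
            continue
        if seq.count("A") / length >= qc.polya_frac:
            continue
        return seq


def _star_arm(rng, mature: str, n_mismatches: int) -> str:
    """Near-reverse-complement of the mature, mismatches kept internal and
    non-pairing (no accidental GU wobble)."""
    star = list(revcomp(mature))
    if n_mismatches:
        interior = np.arange(2, len(star) - 2)
        for pos in rng.choice(interior, size=min(n_mismatches, len(interior)), replace=False):
            partner = mature[len(mature) - 1 - pos]
            forbidden = {star[pos], str(Seq(partner).complement())}
            if partner in "AC":  # wobble partners of U/G
                forbidden.add({"A": "G", "C": "A"}[partner])
            choices = [b for b in BASES if b not in forbidden]
            star[pos] = str(rng.choice(choices))
    return "".join(star)


def plant_hairpin(
    genome: SimulatedGenome,
    position: int,
    planted: list[PlantedMiRNA],
    mature_len: int = 22,
    is_known: bool = True,
    seed: int = 0,
    mirna_id: str | None = None,
    loop_len: int = 12,
    n_mismatches: int = 1,
    max_tries: int = 200,
) -> PlantedMiRNA:
    """Write a validated miRNA hairpin into the genome at ``position``.

    The precursor is mature arm + loop + star arm on the plus strand, with
    the loop drawn from {A, C} so it cannot pair internally. Candidate
    sequences are redrawn until the folded precursor passes the hairpin
    classifier under every default preset and the mature sequence occurs
    exactly once in the edited genome (either strand). The genome sequence
    is edited in place; ``planted`` tracks loci for overlap rejection.

    ``position`` is 1-based; the precursor occupies
    ``[position, position + mature_len + loop_len + mature_len - 1]``.
    """
    if not 18 <= mature_len <= 24:
        raise ValueError("mature length must lie in [18, 24]")
    if loop_len < 8:
        raise ValueError("loop must be at least 8 nt")
    prec_len = 2 * mature_len + loop_len
    if not 50 <= prec_len <= 120:
        raise ValueError(f"precursor length {prec_len} outside [50, 120]")
    if position < 1 or position + 120 > genome.length:
        raise ValueError("position too close to the genome end")
    interval = (position, position + prec_len - 1)
    for prev in planted:
        if prev.chrom == genome.chrom_name and not (
            interval[1] < prev.precursor_interval[0]
            or interval[0] > prev.precursor_interval[1]
        ):
            raise PlacementError(
                f"locus {interval} overlaps planted {prev.mirna_id} at "
                f"{prev.precursor_interval}"
            )
    rng = np.random.default_rng(seed)
    qc = QCParams()
    for _ in range(max_tries):
        mature = _random_mature(rng, mature_len, qc)
        loop = "".join(rng.choice(["A", "C"], size=loop_len))
        star = _star_arm(rng, mature, n_mismatches)
        precursor = mature + loop + star
        fold = fold_nussinov(precursor)
        if not all(
            classify_hairpin(fold, (1, mature_len), p).passed for p in DEFAULT_PRESETS
        ):
            continue
        edited = (
            genome.sequence[: position - 1]
            + precursor
            + genome.sequence[position - 1 + prec_len :]
        )
        if edited.count(mature) + edited.count(revcomp(mature)) != 1:
            continue
        genome.sequence = edited
        record = PlantedMiRNA(
            mirna_id or f"{'mir' if is_known else 'novel'}-{position}",
            genome.chrom_name,
            "+",
            interval,
            (position, position + mature_len - 1),
            mature,
            is_known,
        )
        planted.append(record)
        return record
    raise RuntimeError("could not construct a valid hairpin; raise max_tries")


def plant_decoy(
    genome: SimulatedGenome,
    position: int,
    planted: list[PlantedMiRNA],
    mature_len: int = 22,
    seed: int = 0,
    mirna_id: str | None = None,
    loop_len: int = 12,
) -> PlantedMiRNA:
    """Negative-control locus: a unique expressed mature sequence whose
    precursor context is dinucleotide-shuffled, destroying the star arm.

    Reads from a decoy stack up exactly like a novel miRNA's but the locus
    must not pass hairpin-based discovery.
    """
    rng = np.random.default_rng(seed)
    qc = QCParams()
    prec_len = 2 * mature_len + loop_len
    if position < 1 or position + 120 > genome.length:
        raise ValueError("position too close to the genome end")
    interval = (position, position + prec_len - 1)
    for prev in planted:
        if prev.chrom == genome.chrom_name and not (
            interval[1] < prev.precursor_interval[0]
            or interval[0] > prev.precursor_interval[1]
        ):
            raise PlacementError("decoy locus overlaps a planted locus")
    for _ in range(200):
        mature = _random_mature(rng, mature_len, qc)
        context = "".join(rng.choice(list(BASES), size=prec_len - mature_len))
        block = mature + context
        edited = (
            genome.sequence[: position - 1]
            + block
            + genome.sequence[position - 1 + prec_len :]
        )
        if edited.count(mature) + edited.count(revcomp(mature)) != 1:
            continue
        genome.sequence = edited
        record = PlantedMiRNA(
            mirna_id or f"decoy-{position}",
            genome.chrom_name,
            "+",
            interval,
            (position, position + mature_len - 1),
            mature,
            False,
        )
        planted.append(record)
        return record
    raise RuntimeError("could not place a unique decoy")


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Altschul-Erikson shuffle preserving dinucleotide composition."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    # random Eulerian path from seq[0] to seq[-1]: shuffle edge lists, then
    # require connectivity of last-edge tree to the terminal vertex
    for _ in range(200):
        trial = {k: list(rng.permutation(v)) for k, v in edges.items()}
        last = {k: v[-1] for k, v in trial.items() if k != seq[-1]}
        ok = True
        for start in last:
            node, seen = start, set()
            while node != seq[-1]:
                if node in seen or node not in last:
                    ok = False
                    break
                seen.add(node)
                node = last[node]
            if not ok:
                break
        if not ok:
            continue
        counters = {k: iter(v) for k, v in trial.items()}
        out = [seq[0]]
        node = seq[0]
        try:
            while True:
                node = next(counters[node])
                out.append(node)
        except (StopIteration, KeyError):
            pass
        if len(out) == len(seq):
            return "".join(out)
    return seq  # degenerate composition; give back the input


# -- truth construction ----------------------------------------------------


def _maximin_weights(A, b):
    """A positive solution of A w = b maximising the smallest weight, or
    None when the constraints admit no positive solution (e.g. every
    requested fold on the same side of 1)."""
    from scipy.optimize import linprog

    n = A.shape[1]
    c = np.zeros(n + 1)
    c[-1] = -1.0  # maximise t
    A_eq = np.hstack([A, np.zeros((A.shape[0], 1))])
    A_ub = np.hstack([-np.eye(n), np.ones((n, 1))])  # t <= w_i
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(n),
        A_eq=A_eq,
        b_eq=b,
        bounds=[(0.0, 1.0)] * n + [(0.0, 1.0)],
        method="highs",
    )
    if res.status == 0 and res.x[-1] > 1e-6:
        return res.x[:n]
    return None


def make_truth(
    planted: list[PlantedMiRNA],
    fold_by_condition: dict[str, dict[str, float]],
    baseline: str = "vector",
    contaminants: dict | None = None,
    seed: int = 0,
) -> TruthTable:
    """Abundance weights realising the requested per-condition folds.

    ``fold_by_condition`` maps each non-baseline condition to per-miRNA
    fold requests versus baseline. Baseline weights start uniform and are
    rebalanced (minimum-norm linear correction) so that each condition's
    normalised weights reproduce the requested folds exactly; when no
    positive rebalancing exists the uniform baseline is kept and the
    realised folds (requested fold times a common scale) are stored
    instead.
    """
    ids = [p.mirna_id for p in planted]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate planted ids")
    n = len(ids)
    if n == 0:
        raise ConfigError("no planted miRNAs")
    contaminants = dict(contaminants or {})
    w0 = np.full(n, 1.0 / n)
    conds = [c for c in fold_by_condition if c != baseline]
    folds = np.array(
        [[fold_by_condition[c].get(mid, 1.0) for mid in ids] for c in conds]
    )
    if np.any(folds <= 0):
        raise ValueError("folds must be positive")
    # constraints: sum(w) = 1 and sum(w * f_c) = 1 for each condition
    A = np.vstack([np.ones(n), folds])
    b = np.ones(A.shape[0])
    try:
        correction = A.T @ np.linalg.solve(A @ A.T, b - A @ w0)
        w = w0 + correction
    except np.linalg.LinAlgError:
        w = np.full(n, -1.0)
    if np.all(w > 1e-6):
        base_w = w
    else:
        w = _maximin_weights(A, b)
        if w is not None:
            base_w = w
        else:
            base_w = w0  # infeasible request; realised folds carry the scale
    abundance = {baseline: dict(zip(ids, base_w))}
    for c, frow in zip(conds, folds):
        wc = base_w * frow
        wc = wc / wc.sum()
        abundance[c] = dict(zip(ids, wc))
    return TruthTable(baseline, abundance, contaminants, seed)


def balanced_fold_multiset(n: int) -> list[float]:
    """A fold multiset over {4, 2, 1, 0.5} whose mean is 1 (per 20: one
    4x, two 2x, seven flat, ten halved), so uniform baseline weights can
    realise the folds exactly; cyclically extended to ``n`` entries."""
    pattern = [4.0] + [2.0] * 2 + [1.0] * 7 + [0.5] * 10
    return [pattern[i % len(pattern)] for i in range(n)]


def default_fold_design(
    ids: list[str],
    conditions: list[str],
    shared_fraction: float = 0.7,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Per-condition fold assignments with a built-in overlap structure.

    The first condition receives a seeded permutation of the balanced
    multiset; each further condition keeps ``shared_fraction`` of those
    assignments and reshuffles the rest among themselves, so contrasts
    against baseline share most (not all) of their up/down calls — the
    signature-overlap situation the analysis is meant to detect.
    """
    rng = np.random.default_rng(seed)
    n = len(ids)
    base = rng.permutation(balanced_fold_multiset(n))
    design = {}
    for k, cond in enumerate(conditions):
        f = np.array(base, dtype=float)
        if k > 0:
            n_redraw = max(1, int(round((1 - shared_fraction) * n)))
            idx = rng.choice(n, size=n_redraw, replace=False)
            f[idx] = rng.permutation(f[idx])
        design[cond] = dict(zip(ids, f.tolist()))
    return design


# -- library simulation ----------------------------------------------------

_QUAL_CHAR = "I"


def _mirna_read(rng, mature: str, cfg: LibraryConfig) -> str:
    lo, hi = cfg.adapter_tail_range
    tail = int(rng.integers(lo, hi + 1))
    return mature + cfg.adapter_3p[:tail]


def _contaminant_read(rng, cls: str, cfg: LibraryConfig, mrna_seqs, qc: QCParams) -> str:
    lo, hi = cfg.adapter_tail_range
    tail = int(rng.integers(lo, hi + 1))
    if cls == "polyA":
        head = "".join(rng.choice(list(BASES), size=8))
        return head + "A" * 14 + cfg.adapter_3p[:tail]
    if cls == "ambiguous":
        insert = list("".join(rng.choice(list(BASES), size=22)))
        insert[int(rng.integers(0, 22))] = "N"
        return "".join(insert) + cfg.adapter_3p[:tail]
    if cls == "adapter5":
        insert = "".join(rng.choice(list(BASES), size=20))
        return cfg.adapter_5p[-12:] + insert + cfg.adapter_3p[:tail]
    if cls == "mrna":
        mrna = mrna_seqs[int(rng.integers(0, len(mrna_seqs)))]
        flen = int(rng.integers(18, 25))
        start = int(rng.integers(0, len(mrna) - flen + 1))
        return mrna[start : start + flen] + cfg.adapter_3p[:tail]
    raise ValueError(cls)


_EXPECTED_DECISION = {
    "polyA": "drop_polyA",
    "ambiguous": "drop_ambiguous",
    "adapter5": "drop_5adapter",
    "mrna": "keep",
}


def simulate_library(
    genome: SimulatedGenome,
    planted: list[PlantedMiRNA],
    truth: TruthTable,
    cfg: LibraryConfig,
    condition: str,
    mrna_seqs: list[str] | None = None,
) -> tuple[list[RawRead], Counter]:
    """One adapter-ligated library; returns reads plus true class counts.

    Each read's class (miRNA or a contaminant type) is drawn from the truth
    table's fractions; contaminant reads are redrawn until they classify as
    exactly their intended QC decision, so class counts are exact ground
    truth for the QC report. Deterministic for a fixed ``cfg.seed``.
    """
    if condition not in truth.abundance:
        raise ConfigError(f"condition {condition!r} absent from truth table")
    fracs = {c: truth.contaminants.get(c, 0.0) for c in CONTAMINANT_CLASSES}
    p_mirna = 1.0 - sum(fracs.values())
    if p_mirna > 0 and not planted:
        raise ConfigError("nonzero miRNA fraction with no planted miRNAs")
    if fracs["mrna"] > 0 and not mrna_seqs:
        raise ConfigError("nonzero mRNA fraction but no mRNA sequences supplied")
    weights = truth.abundance[condition]
    ids = list(weights)
    probs = np.array([weights[i] for i in ids])
    mature_by_id = {p.mirna_id: p.mature_seq for p in planted}
    rng = np.random.default_rng(cfg.seed)
    classes = ["mirna"] + list(CONTAMINANT_CLASSES)
    class_p = np.array([p_mirna] + [fracs[c] for c in CONTAMINANT_CLASSES])
    qc = QCParams(adapter_3p=cfg.adapter_3p, adapter_5p=cfg.adapter_5p)
    draws = rng.choice(len(classes), size=cfg.n_reads, p=class_p)
    mirna_draws = iter(rng.choice(len(ids), size=int((draws == 0).sum()), p=probs))
    reads: list[RawRead] = []
    counts: Counter = Counter()
    for i, cls_idx in enumerate(draws):
        cls = classes[cls_idx]
        if cls == "mirna":
            mid = ids[next(mirna_draws)]
            seq = _mirna_read(rng, mature_by_id[mid], cfg)
        else:
            expected = _EXPECTED_DECISION[cls]
            for _ in range(100):
                seq = _contaminant_read(rng, cls, cfg, mrna_seqs, qc)
                decision, _insert = classify_read(RawRead("t", seq, _QUAL_CHAR * len(seq)), qc)
                if decision == expected:
                    break
            else:
                raise RuntimeError(f"could not realise contaminant class {cls}")
        if cfg.error_rate > 0:
            seq = _apply_errors(rng, seq, cfg.error_rate)
        counts[cls] += 1
        reads.append(RawRead(f"{condition}.{i:07d}", seq, _QUAL_CHAR * len(seq)))
    return reads, counts


def _apply_errors(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if out[i] in BASES and rng.random() < rate:
            out[i] = str(rng.choice([b for b in BASES if b != out[i]]))
    return "".join(out)


def simulate_agoip(
    planted: list[PlantedMiRNA],
    supported_ids,
    depth_per_candidate: int = 10,
    n_datasets: int = 9,
    seed: int = 0,
    cfg: LibraryConfig | None = None,
) -> list[list[RawRead]]:
    """Argonaute-RIP libraries: every supported candidate receives
    ``depth_per_candidate`` reads over its mature interval in every
    dataset; unsupported candidates receive none."""
    if n_datasets < 1:
        raise ConfigError("n_datasets must be at least 1")
    supported = set(supported_ids)
    by_id = {p.mirna_id: p for p in planted}
    unknown = supported - set(by_id)
    if unknown:
        raise ConfigError(f"supported ids not planted: {unknown}")
    cfg = cfg or LibraryConfig(n_reads=1, seed=seed)
    rng = np.random.default_rng(seed)
    datasets = []
    for d in range(n_datasets):
        reads = []
        for mid in sorted(supported):
            mature = by_id[mid].mature_seq
            for k in range(depth_per_candidate):
                seq = _mirna_read(rng, mature, cfg)
                reads.append(RawRead(f"ago{d}.{mid}.{k}", seq, _QUAL_CHAR * len(seq)))
        datasets.append(reads)
    return datasets


# -- whole-world convenience ----------------------------------------------


@dataclass
class World:
    genome: SimulatedGenome
    planted: list[PlantedMiRNA]
    mrna_seqs: list[str]
    mrna_intervals: list[tuple[int, int]]
    truth: TruthTable
    libraries: dict[str, list[RawRead]]
    library_class_counts: dict[str, Counter]
    ago_libraries: list[list[RawRead]]
    ago_supported: frozenset
    config: LibraryConfig
    conditions: tuple[str, ...]

    @property
    def known(self) -> list[PlantedMiRNA]:
        return [p for p in self.planted if p.is_known]

    @property
    def novel(self) -> list[PlantedMiRNA]:
        return [p for p in self.planted if not p.is_known]

    def known_annotations(self) -> list[MirnaAnnotation]:
        return [p.to_annotation() for p in self.known]


DEFAULT_CONTAMINANTS = {"polyA": 0.05, "ambiguous": 0.02, "adapter5": 0.03, "mrna": 0.10}


def simulate_world(
    seed: int = 0,
    genome_length: int = 100_000,
    gc_fraction: float = 0.42,
    n_known: int = 20,
    n_novel: int = 10,
    conditions: tuple[str, ...] = ("vector", "kapb", "kapb_cmyc"),
    baseline: str = "vector",
    n_reads: int = 100_000,
    contaminants: dict | None = None,
    fold_by_condition: dict | None = None,
    n_mrna: int = 8,
    mrna_len: int = 500,
    ago_n_datasets: int = 9,
    ago_depth: int = 10,
    ago_supported_fraction: float = 0.7,
    decoy_novel: bool = False,
) -> World:
    """Build the full study: genome, planted loci, libraries, truth, RIP.

    With ``decoy_novel=True`` the novel loci are planted as decoys (unique
    mature sequences without a star arm) — the negative control for
    hairpin discovery.
    """
    master = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(6 + len(conditions))]
    genome = generate_genome(genome_length, gc_fraction, seed=seeds[0])
    rng = np.random.default_rng(seeds[1])
    planted: list[PlantedMiRNA] = []
    spacing = (genome_length - 2000) // max(n_known + n_novel, 1)
    if spacing < 400:
        raise ConfigError("genome too short for the requested number of loci")
    positions = [
        1000 + i * spacing + int(rng.integers(0, spacing // 4))
        for i in range(n_known + n_novel)
    ]
    for i in range(n_known):
        plant_hairpin(
            genome,
            positions[i],
            planted,
            is_known=True,
            seed=int(rng.integers(2**31)),
            mirna_id=f"mir-{i + 1}",
        )
    for j in range(n_novel):
        pos = positions[n_known + j]
        if decoy_novel:
            plant_decoy(
                genome, pos, planted, seed=int(rng.integers(2**31)),
                mirna_id=f"novel-{j + 1}",
            )
        else:
            plant_hairpin(
                genome, pos, planted, is_known=False,
                seed=int(rng.integers(2**31)), mirna_id=f"novel-{j + 1}",
            )
    # mRNA transcripts: genomic windows clear of every planted locus
    mrna_seqs, mrna_intervals = [], []
    occupied = [p.precursor_interval for p in planted]
    guard = 200
    tries = 0
    while len(mrna_seqs) < n_mrna and tries < 10_000:
        tries += 1
        start = int(rng.integers(1, genome_length - mrna_len))
        iv = (start, start + mrna_len - 1)
        if any(
            not (iv[1] + guard < s or iv[0] - guard > e) for s, e in occupied
        ) or any(not (iv[1] < s or iv[0] > e) for s, e in mrna_intervals):
            continue
        mrna_intervals.append(iv)
        mrna_seqs.append(genome.sequence[iv[0] - 1 : iv[1]])
    if len(mrna_seqs) < n_mrna:
        raise ConfigError("could not place mRNA transcripts clear of planted loci")
    ids = [p.mirna_id for p in planted]
    if fold_by_condition is None:
        fold_by_condition = default_fold_design(
            ids,
            [c for c in conditions if c != baseline],
            seed=seeds[4 + len(conditions)],
        )
    truth = make_truth(
        planted,
        fold_by_condition,
        baseline=baseline,
        contaminants=DEFAULT_CONTAMINANTS if contaminants is None else contaminants,
        seed=seed,
    )
    libraries, class_counts = {}, {}
    for k, cond in enumerate(conditions):
        cfg = LibraryConfig(n_reads=n_reads, seed=seeds[2 + k])
        reads, counts = simulate_library(
            genome, planted, truth, cfg, cond, mrna_seqs=mrna_seqs
        )
        libraries[cond] = reads
        class_counts[cond] = counts
    novel_ids = [p.mirna_id for p in planted if not p.is_known]
    n_supported = int(round(ago_supported_fraction * len(novel_ids)))
    sup_rng = np.random.default_rng(seeds[2 + len(conditions)])
    supported = frozenset(
        map(str, sup_rng.choice(novel_ids, size=n_supported, replace=False))
    ) if novel_ids else frozenset()
    ago = simulate_agoip(
        planted,
        supported,
        depth_per_candidate=ago_depth,
        n_datasets=ago_n_datasets,
        seed=seeds[3 + len(conditions)],
    )
    return World(
        genome=genome,
        planted=planted,
        mrna_seqs=mrna_seqs,
        mrna_intervals=mrna_intervals,
        truth=truth,
        libraries=libraries,
        library_class_counts=class_counts,
        ago_libraries=ago,
        ago_supported=supported,
        config=LibraryConfig(n_reads=n_reads, seed=seed),
        conditions=tuple(conditions),
    )


# -- file output -----------------------------------------------------------


def write_fastq(reads: list[RawRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_fasta(seqs: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        str(path),
        "fasta",
    )
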