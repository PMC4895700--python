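"""End-to-end orchestration of the miRNome analysis stages.

Stages (in dependency order): simulate -> qc -> map -> quantify -> diff ->
novel -> verify-ago -> signatures -> report. Each stage reads its inputs
from and writes its outputs to a run directory, so stages can be rerun
individually; a missing upstream artifact raises a dependency error naming
the stage. A run manifest records per-stage output hashes: deterministic
stages reproduce identical hashes for an identical config and seed, which
is the pipeline's reproducibility contract (the simulation included — the
global seed fans out to fixed per-stage seeds).

The per-stage read/tag funnel (input, kept, dropped per reason) is logged
and stored, mirroring the filtration funnel of small-RNA analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import discovery, qc, signatures, simulate
from .quantify import (
    MiRNAQuant,
    check_table_row,
    fold_table,
    folds_to_frame,
    library_size,
    profile_to_frame,
    rpm,
)
from .quantify import quantify as quantify_profile
from .mapping import (
    ReferenceSet,
    read_annotations_tsv,
    write_annotations_tsv,
    write_mirna_gff3,
    write_placements_bed,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "qc",
    "map",
    "quantify",
    "diff",
    "novel",
    "verify-ago",
    "signatures",
    "report",
)


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; YAML-loadable.

    Sections hold plain dicts of stage parameters so a config file only
    needs to mention what it overrides.
    """

    seed: int = 0
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)
    novel: dict = field(default_factory=dict)
    ago: dict = field(default_factory=dict)
    gsea: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def threshold(self) -> float:
        t = float(self.quant.get("threshold", 1.5))
        if t <= 1:
            raise ValueError("fold threshold must exceed 1")
        return t


def _stage_seed(seed: int, stage: str) -> int:
    import numpy as np

    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} is missing upstream artifacts: {missing}; "
            "run the producing stage first"
        )


def _conditions(outdir: Path) -> tuple[list[str], str]:
    meta = json.loads((outdir / "world.json").read_text())
    return meta["conditions"], meta["baseline"]


class PipelineRun:
    """One run directory plus the manifest being accumulated."""

    def __init__(self, config: PipelineConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"seed": config.seed, "stages": {}}

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> list[Path]:
        cfg = self.config
        world = simulate.simulate_world(seed=_stage_seed(cfg.seed, "simulate"), **cfg.sim)
        out = self.outdir
        simulate.write_fasta({world.genome.chrom_name: world.genome.sequence}, out / "genome.fa")
        write_mirna_gff3(world.known_annotations(), out / "known_mirnas.gff3")
        simulate.write_fasta(
            {f"mrna{i + 1}": s for i, s in enumerate(world.mrna_seqs)}, out / "mrna.fa"
        )
        world.truth.to_tsv(out / "truth.tsv")
        files = [out / "genome.fa", out / "known_mirnas.gff3", out / "mrna.fa", out / "truth.tsv"]
        for cond in world.conditions:
            p = out / f"reads_{cond}.fastq"
            simulate.write_fastq(world.libraries[cond], p)
            files.append(p)
        for i, lib in enumerate(world.ago_libraries):
            p = out / f"ago_{i}.fastq"
            simulate.write_fastq(lib, p)
            files.append(p)
        meta = {
            "conditions": list(world.conditions),
            "baseline": world.truth.baseline,
            "n_ago_datasets": len(world.ago_libraries),
            "ago_supported": sorted(world.ago_supported),
            "planted_novel": sorted(p.mirna_id for p in world.novel),
            "class_counts": {c: dict(world.library_class_counts[c]) for c in world.conditions},
        }
        (out / "world.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        files.append(out / "world.json")
        return files

    def stage_qc(self) -> list[Path]:
        out = self.outdir
        _require(out, "qc", "world.json")
        conds, _ = _conditions(out)
        params = qc.QCParams(**self.config.qc)
        files = []
        funnel = {}
        meta = json.loads((out / "world.json").read_text())
        libs = [(f"reads_{c}.fastq", f"tags_{c}") for c in conds]
        libs += [(f"ago_{i}.fastq", f"ago_tags_{i}") for i in range(meta["n_ago_datasets"])]
        for fastq, stem in libs:
            _require(out, "qc", fastq)
            tags, report = qc.process_fastq(out / fastq, params)
            qc.write_tags_fasta(tags, out / f"{stem}.fasta")
            report.to_json(out / f"{stem}.qc.json")
            funnel[stem] = {"input": report.total, **report.to_dict(), "unique_tags": len(tags)}
            files += [out / f"{stem}.fasta", out / f"{stem}.qc.json"]
            logger.info("qc %s: %d reads -> %d kept, %d tags", stem, report.total,
                        report.counts.get("keep", 0), len(tags))
        (out / "funnel_qc.json").write_text(json.dumps(funnel, indent=2, sort_keys=True) + "\n")
        files.append(out / "funnel_qc.json")
        return files

    def _refset(self) -> ReferenceSet:
        out = self.outdir
        _require(out, "map", "genome.fa", "mrna.fa", "known_mirnas.gff3")
        return ReferenceSet.from_files(
            out / "genome.fa", out / "mrna.fa", out / "known_mirnas.gff3"
        )

    def stage_map(self) -> list[Path]:
        out = self.outdir
        _require(out, "map", "world.json")
        conds, _ = _conditions(out)
        meta = json.loads((out / "world.json").read_text())
        refset = self._refset()
        files = []
        funnel = {}
        stems = [f"tags_{c}" for c in conds]
        stems += [f"ago_tags_{i}" for i in range(meta["n_ago_datasets"])]
        for stem in stems:
            _require(out, "map", f"{stem}.fasta")
            tags = qc.read_tags_fasta(out / f"{stem}.fasta")
            annotated = refset.annotate_library(tags)
            write_annotations_tsv(annotated, out / f"{stem}.annotated.tsv")
            write_placements_bed(annotated, out / f"{stem}.placements.bed")
            cats = {}
            for at in annotated:
                cats.setdefault(at.annotation.category, [0, 0])
                cats[at.annotation.category][0] += 1
                cats[at.annotation.category][1] += at.tag.count
            funnel[stem] = {k: {"tags": v[0], "reads": v[1]} for k, v in sorted(cats.items())}
            files += [out / f"{stem}.annotated.tsv", out / f"{stem}.placements.bed"]
        (out / "funnel_map.json").write_text(json.dumps(funnel, indent=2, sort_keys=True) + "\n")
        files.append(out / "funnel_map.json")
        return files

    def stage_quantify(self) -> list[Path]:
        out = self.outdir
        _require(out, "quantify", "world.json")
        conds, _ = _conditions(out)
        m_mode = self.config.quant.get("m_mode", "max")
        files = []
        for cond in conds:
            _require(out, "quantify", f"tags_{cond}.annotated.tsv")
            annotated = read_annotations_tsv(out / f"tags_{cond}.annotated.tsv")
            profile = quantify_profile(annotated, m_mode=m_mode)
            profile_to_frame(profile).to_csv(
                out / f"profile_{cond}.tsv", sep="\t", index=False
            )
            files.append(out / f"profile_{cond}.tsv")
        return files

    def _load_profile(self, cond: str) -> list[quantify.MiRNAQuant]:
        df = pd.read_csv(self.outdir / f"profile_{cond}.tsv", sep="\t")
        return [
            MiRNAQuant(r.mirna_id, r.C, r.M, int(r.N), r.rpm)
            for r in df.itertuples()
        ]

    def comparisons(self) -> list[tuple[str, str, str]]:
        conds, baseline = _conditions(self.outdir)
        others = [c for c in conds if c != baseline]
        pairs = [(f"{c}_vs_{baseline}", c, baseline) for c in others]
        pairs += [
            (f"{b}_vs_{a}", b, a)
            for i, a in enumerate(others)
            for b in others[i + 1 :]
        ]
        return pairs

    def stage_diff(self) -> list[Path]:
        out = self.outdir
        threshold = self.config.threshold()
        floor = self.config.quant.get("floor")
        files = []
        for label, a, b in self.comparisons():
            _require(out, "diff", f"profile_{a}.tsv", f"profile_{b}.tsv")
            pa, pb = self._load_profile(a), self._load_profile(b)
            records = fold_table(pa, pb, threshold, floor)
            folds_to_frame(records).to_csv(
                out / f"folds_{label}.tsv", sep="\t", index=False
            )
            files.append(out / f"folds_{label}.tsv")
        return files

    def stage_novel(self) -> list[Path]:
        out = self.outdir
        _require(out, "novel", "world.json", "genome.fa")
        conds, baseline = _conditions(out)
        ncfg = self.config.novel
        placed = []
        per_cond_annotated = {}
        for cond in conds:
            _require(out, "novel", f"tags_{cond}.annotated.tsv")
            annotated = read_annotations_tsv(out / f"tags_{cond}.annotated.tsv")
            per_cond_annotated[cond] = annotated
            placed += discovery.unannotated_placements(annotated)
        stacks = discovery.build_stacks(
            placed,
            max_gap=ncfg.get("max_gap", 10),
            min_reads=ncfg.get("min_reads", 5),
        )
        refset = self._refset()
        candidates = discovery.consensus_detect(
            stacks,
            refset.genome,
            quorum=ncfg.get("quorum", 3),
            flank=ncfg.get("flank", discovery.DEFAULT_FLANK),
        )
        candidates = self._candidate_expression(candidates, per_cond_annotated)
        discovery.write_candidates_tsv(candidates, out / "novel_candidates.tsv")
        discovery.write_candidates_gff3(candidates, out / "novel_candidates.gff3")
        discovery.write_structures(candidates, out / "novel_structures.txt")
        logger.info(
            "novel: %d stacks -> %d candidates, %d consensus",
            len(stacks), len(candidates),
            sum(c.consensus for c in candidates),
        )
        return [out / "novel_candidates.tsv", out / "novel_candidates.gff3",
                out / "novel_structures.txt"]

    @staticmethod
    def _candidate_expression(candidates, per_cond_annotated):
        """Per-condition RPM of each candidate's mature locus (unique
        mapping assumed for the excised locus: M = 1)."""
        out = []
        for cand in candidates:
            expr = []
            for cond, annotated in per_cond_annotated.items():
                n_lib = library_size(annotated)
                c_reads = 0
                for at in annotated:
                    if at.annotation.category != "unannotated":
                        continue
                    need = 0.5 * len(at.tag.insert_seq)
                    for p in at.placements:
                        if p.chrom != cand.chrom or p.strand != cand.strand:
                            continue
                        lo = max(p.start, cand.mature_interval[0])
                        hi = min(p.end, cand.mature_interval[1])
                        if hi - lo + 1 >= need:
                            c_reads += at.tag.count
                            break
                expr.append(
                    (cond, rpm(c_reads, 1, n_lib) if n_lib and c_reads else 0.0)
                )
            out.append(dataclasses.replace(cand, expression=tuple(expr)))
        return out

    def stage_verify_ago(self) -> list[Path]:
        out = self.outdir
        _require(out, "verify-ago", "world.json", "novel_candidates.tsv")
        meta = json.loads((out / "world.json").read_text())
        acfg = self.config.ago
        ago_libs = []
        for i in range(meta["n_ago_datasets"]):
            _require(out, "verify-ago", f"ago_tags_{i}.annotated.tsv")
            ago_libs.append(read_annotations_tsv(out / f"ago_tags_{i}.annotated.tsv"))
        candidates = read_candidates_tsv(out / "novel_candidates.tsv")
        verified = discovery.verify_agoip(
            candidates,
            ago_libs,
            min_reads=acfg.get("min_reads", 5),
            min_datasets=acfg.get("min_datasets", 1),
        )
        discovery.write_candidates_tsv(verified, out / "novel_candidates.tsv")
        return [out / "novel_candidates.tsv"]

    def stage_signatures(self) -> list[Path]:
        out = self.outdir
        threshold = self.config.threshold()
        floor = self.config.quant.get("floor")
        gcfg = self.config.gsea
        comps = self.comparisons()
        sigs = {}
        for label, a, b in comps:
            _require(out, "signatures", f"folds_{label}.tsv")
            df = pd.read_csv(out / f"folds_{label}.tsv", sep="\t")
            up = frozenset(df.loc[df.direction == "up", "mirna_id"])
            down = frozenset(df.loc[df.direction == "down", "mirna_id"])
            folds = dict(zip(df.mirna_id, df.fold_a_vs_b))
            sigs[label] = signatures.Signature(label, up, down, folds)
        overlaps, enrich = {}, {}
        baseline_comps = [c for c in comps if c[2] == _conditions(out)[1]]
        if len(baseline_comps) >= 2:
            (la, _, _), (lb, _, _) = baseline_comps[0], baseline_comps[1]
            # overlap of the two contrasts' signatures, relative to the first
            for direction in ("up", "down"):
                sa = getattr(sigs[la], f"{direction}_set")
                sb = getattr(sigs[lb], f"{direction}_set")
                if sa:
                    overlaps[f"{direction}_{la}_in_{lb}"] = signatures.overlap(sa, sb)
            seed = _stage_seed(self.config.seed, "signatures")
            ranked = signatures.rank_by_fold(sigs[lb].fold_by_id)
            for direction in ("up", "down"):
                gene_set = getattr(sigs[la], f"{direction}_set") & set(ranked)
                if 0 < len(gene_set) < len(ranked):
                    enrich[f"{direction}_{la}_in_{lb}_ranking"] = signatures.gsea_enrichment(
                        ranked,
                        gene_set,
                        n_perm=gcfg.get("n_perm", 1000),
                        seed=seed,
                    )
        novel_summary = {}
        if (out / "novel_candidates.tsv").exists():
            cands = read_candidates_tsv(out / "novel_candidates.tsv")
            novel_summary = {
                "n_candidates": len(cands),
                "n_consensus": sum(c.consensus for c in cands),
                "n_ago_verified": sum(c.ago_verified for c in cands),
            }
        report = signatures.signature_report(
            list(sigs.values()), overlaps, enrich, novel_summary
        )
        signatures.write_report(report, out / "signature_report.json")
        return [out / "signature_report.json"]

    def stage_report(self) -> list[Path]:
        out = self.outdir
        _require(out, "report", "signature_report.json")
        summary = {"seed": self.config.seed, "stages_run": sorted(self.manifest["stages"])}
        for name in ("funnel_qc.json", "funnel_map.json"):
            if (out / name).exists():
                summary[name.split(".")[0]] = json.loads((out / name).read_text())
        summary["signatures"] = json.loads((out / "signature_report.json").read_text())
        (out / "run_report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return [out / "run_report.json"]

    # -- driver ------------------------------------------------------------

    _STAGE_FNS = {
        "simulate": stage_simulate,
        "qc": stage_qc,
        "map": stage_map,
        "quantify": stage_quantify,
        "diff": stage_diff,
        "novel": stage_novel,
        "verify-ago": stage_verify_ago,
        "signatures": stage_signatures,
        "report": stage_report,
    }

    def run(self, stages=STAGES) -> dict:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            outputs = self._STAGE_FNS[stage](self)
            self.manifest["stages"][stage] = {
                "outputs": {p.name: _sha256(p) for p in outputs},
                "elapsed_s": round(time.time() - t0, 3),
            }
            logger.info("stage %s done (%.1fs)", stage, time.time() - t0)
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )
        return self.manifest


def run(config: PipelineConfig, outdir, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order."""
    return PipelineRun(config, outdir).run(stages)


# -- candidate TSV reload (pipeline round-trip) ---------------------------


def read_candidates_tsv(path) -> list[discovery.NovelCandidate]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (cid, chrom, strand, ps, pe, mseq, ms, me, total, hits, cons,
             ago_reads, ago_ver, expr) = line.rstrip("\n").split("\t")
            preset_hits = tuple(
                (tok.split(":")[0], bool(int(tok.split(":")[1])))
                for tok in hits.split(",") if tok
            )
            expression = tuple(
                (tok.rsplit(":", 1)[0], float(tok.rsplit(":", 1)[1]))
                for tok in expr.split(",") if tok
            )
            out.append(
                discovery.NovelCandidate(
                    candidate_id=cid,
                    chrom=chrom,
                    strand=strand,
                    precursor_interval=(int(ps), int(pe)),
                    mature_seq=mseq,
                    mature_interval=(int(ms), int(me)),
                    fold=None,
                    preset_hits=preset_hits,
                    consensus=bool(int(cons)),
                    total_count=int(total),
                    ago_reads_per_dataset=tuple(
                        int(x) for x in ago_reads.split(",") if x
                    ),
                    ago_verified=bool(int(ago_ver)),
                    expression=expression,
                )
            )
    return out


# -- published-table verification -----------------------------------------

PUBLISHED_TABLES = {
    "up": "published_top50_upregulated.tsv",
    "down": "published_top50_downregulated.tsv",
}


def load_published_table(which: str) -> pd.DataFrame:
    """The packaged top-50 up/down miRNA fold tables (transcribed from the
    published Kaposin B / c-Myc HUVEC study tables)."""
    with resources.files("mirnome.data").joinpath(PUBLISHED_TABLES[which]).open() as fh:
        return pd.read_csv(fh, sep="\t")


def verify_tables(table: pd.DataFrame, tol: float = 1e-3) -> pd.DataFrame:
    """Row-wise internal-consistency report of a published fold table.

    Expects columns name, rpm_a, rpm_b, fold_a, fold_b (in that order,
    names free). Malformed rows are flagged, not fatal.
    """
    rows = []
    for r in table.itertuples(index=False):
        name, rpm_a, rpm_b, fold_a, fold_b = r[:5]
        try:
            res = check_table_row(
                float(rpm_a), float(rpm_b), float(fold_a), float(fold_b), tol
            )
            rows.append((name, res["residual"], res["consistent"], res["baseline_rpm"], ""))
        except (ValueError, TypeError) as exc:
            rows.append((name, float("nan"), False, float("nan"), str(exc)))
    return pd.DataFrame(
        rows, columns=["name", "residual", "consistent", "baseline_rpm", "error"]
    )
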