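"""End-to-end orchestration: regions -> scan -> stats -> enrichment -> IRAlu
-> fold, with a run manifest for reproducibility.

Stages communicate through files in standard formats (FASTA, GFF3, BED,
TSV, JSON), so each stage can also be run and inspected on its own.  A
companion bundle simulator builds a complete synthetic input set (genome,
gene models, repeat library, annotation table, planted truth) for testing
and demonstration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .annotation import AlignmentParams, read_repeatmasker_out, scan, write_bed
from .enrichment import enrich_terms, read_annotation_table
from .fold import FoldParams, duplex_report
from .iralu import build_report, find_iralus, tabulate_iralu_genes, write_iralu_table
from .regions import extract_region_sequences, gc_content, read_gff3, write_gff3
from .repeat_stats import rank_genes, summarize, summary_table
from .seqs import read_fasta, write_fasta
from .synthetic import (
    generate_annotation_table,
    generate_background,
    generate_related_library,
    mutate_copy,
)
from .seqs import revcomp

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate_bundle"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    genome_fasta: str
    gff3: str
    library_fasta: str | None = None
    rm_out: str | None = None  # pre-computed RepeatMasker annotations
    annotation_tsv: str | None = None
    out_dir: str = "alulandscape_out"
    align: AlignmentParams = field(default_factory=AlignmentParams)
    fold: FoldParams = field(default_factory=FoldParams)
    min_alu_length: int = 100
    min_count: int = 1
    seed: int = 0


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle under ``out_dir``.

    Returns a dict with the in-memory results (summaries, rankings, IRAlu
    rows, enrichment rows, fold verdicts) alongside the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "alulandscape",
        "version": __version__,
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
        },
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "complete": False,
    }

    # ---- stage: regions -------------------------------------------------
    stage = "regions"
    try:
        for label, path in (
            ("genome_fasta", config.genome_fasta),
            ("gff3", config.gff3),
        ):
            if not Path(path).exists():
                raise FileNotFoundError(path)
            manifest["inputs"][label] = _sha256(path)
        genome = read_fasta(config.genome_fasta)
        models = read_gff3(config.gff3)
        region_seqs = extract_region_sequences(models, genome)
        for category, entries in region_seqs.items():
            if entries:
                write_fasta(out / f"{category}.fasta", entries)
        manifest["stages"][stage] = {
            c: len(e) for c, e in region_seqs.items()
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: scan / parse-rm ----------------------------------------
    stage = "scan"
    try:
        hits_by_category: dict[str, list] = {}
        if config.rm_out:
            if not Path(config.rm_out).exists():
                raise FileNotFoundError(config.rm_out)
            manifest["inputs"]["rm_out"] = _sha256(config.rm_out)
            all_hits = read_repeatmasker_out(config.rm_out)
            for category, entries in region_seqs.items():
                ids = {name for name, _ in entries}
                hits_by_category[category] = [
                    h for h in all_hits if h.query_id in ids
                ]
        else:
            if not config.library_fasta or not Path(config.library_fasta).exists():
                raise FileNotFoundError(config.library_fasta or "<library unset>")
            manifest["inputs"]["library_fasta"] = _sha256(config.library_fasta)
            library = read_fasta(config.library_fasta)
            for category, entries in region_seqs.items():
                cat_hits = []
                for name, seq in entries:
                    cat_hits.extend(
                        scan(seq, library, config.align, query_id=name)
                    )
                hits_by_category[category] = cat_hits
        for category, cat_hits in hits_by_category.items():
            if cat_hits:
                write_bed(cat_hits, out / f"{category}_hits.bed")
        manifest["stages"][stage] = {c: len(h) for c, h in hits_by_category.items()}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: stats ---------------------------------------------------
    stage = "stats"
    try:
        summaries = [
            summarize(hits_by_category[c], region_seqs[c], c)
            for c in region_seqs
            if region_seqs[c]
        ]
        table = summary_table(summaries)
        table.to_csv(out / "summary.tsv", sep="\t")
        per_gene = {
            name: [h for h in hits_by_category["genes"] if h.query_id == name]
            for name, _ in region_seqs["genes"]
        }
        ranking = rank_genes(per_gene, top_n=None)
        ranking.to_csv(out / "gene_ranking.tsv", sep="\t", index=False)
        gc_by_category = {
            c: round(
                gc_content("".join(s for _, s in region_seqs[c])), 4
            )
            for c in region_seqs
            if region_seqs[c]
        }
        manifest["stages"][stage] = {
            "summary_rows": int(table.shape[0]),
            "ranking_rows": int(ranking.shape[0]),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: enrichment ---------------------------------------------
    stage = "enrich"
    enrichment_rows = []
    try:
        if config.annotation_tsv:
            if not Path(config.annotation_tsv).exists():
                raise FileNotFoundError(config.annotation_tsv)
            manifest["inputs"]["annotation_tsv"] = _sha256(config.annotation_tsv)
            ann_rows = read_annotation_table(config.annotation_tsv)
            from .annotation import is_alu

            alu_genes = sorted(
                {h.query_id for h in hits_by_category["genes"] if is_alu(h)}
            )
            enrichment_rows = enrich_terms(
                alu_genes, ann_rows, min_count=config.min_count
            )
            with open(out / "enrichment.tsv", "w") as fh:
                fh.write("term\tcount\tpercent\tp_value\tbonferroni\n")
                for r in enrichment_rows:
                    fh.write(
                        f"{r.term}\t{r.count}\t{r.percent:.2f}\t"
                        f"{r.p_value:.4g}\t{r.bonferroni:.4g}\n"
                    )
        manifest["stages"][stage] = {"terms": len(enrichment_rows)}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: iralu ---------------------------------------------------
    stage = "iralu"
    try:
        gene_of_tx, biotype_of_tx = {}, {}
        for gene in models:
            for tx in gene.transcripts:
                gene_of_tx[tx.transcript_id] = gene.gene_id
                biotype_of_tx[tx.transcript_id] = tx.biotype
        utr3_hits = {
            name: [h for h in hits_by_category["utr3"] if h.query_id == name]
            for name, _ in region_seqs["utr3"]
        }
        iralu_rows = build_report(
            utr3_hits, gene_of_tx, biotype_of_tx, config.min_alu_length
        )
        write_iralu_table(iralu_rows, out / "iralu_report.tsv")
        n_all, n_coding = tabulate_iralu_genes(iralu_rows)
        manifest["stages"][stage] = {
            "rows": len(iralu_rows),
            "genes_with_iralus": n_all,
            "protein_coding_genes_with_iralus": n_coding,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: fold ----------------------------------------------------
    stage = "fold"
    try:
        utr3_seq = dict(region_seqs["utr3"])
        verdicts = []
        for tid, hits in sorted(utr3_hits.items()):
            pairs, flag = find_iralus(
                hits, min_alu_length=config.min_alu_length, transcript_id=tid
            )
            if not pairs:
                continue
            primary = pairs[0]
            result, duplex = duplex_report(primary, utr3_seq[tid], config.fold)
            verdicts.append(
                {
                    "transcript": tid,
                    "gene": gene_of_tx.get(tid, tid),
                    "n_pairs": result.n_pairs,
                    "intermolecular_fraction": round(
                        result.intermolecular_fraction, 4
                    ),
                    "duplex": duplex,
                }
            )
        with open(out / "fold_verdicts.tsv", "w") as fh:
            fh.write("transcript\tgene\tn_pairs\tintermolecular_fraction\tduplex\n")
            for v in verdicts:
                fh.write(
                    f"{v['transcript']}\t{v['gene']}\t{v['n_pairs']}\t"
                    f"{v['intermolecular_fraction']}\t{v['duplex']}\n"
                )
        manifest["stages"][stage] = {"verdicts": len(verdicts)}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest["complete"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "summaries": summaries,
        "summary_table": table,
        "ranking": ranking,
        "gc_by_category": gc_by_category,
        "enrichment": enrichment_rows,
        "iralu_rows": iralu_rows,
        "iralu_counts": (n_all, n_coding),
        "fold_verdicts": verdicts,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# synthetic bundle simulator
# ---------------------------------------------------------------------------

#: per-gene layout (nt): 5'UTR, first CDS chunk | intron | second CDS chunk, 3'UTR
_UTR5, _CDS1, _INTRON, _CDS2, _UTR3 = 200, 300, 3000, 300, 1500


def simulate_bundle(
    out_dir,
    n_genes: int = 8,
    intron_copies: int = 2,
    iralu_genes: int = 3,
    divergence: float = 0.05,
    gc: float = 0.45,
    gap: int = 150,
    seed: int = 0,
    library_spec=None,
    n_terms: int = 12,
) -> dict:
    """Write a complete synthetic input bundle and return paths plus truth.

    Each gene is one plus-strand contig (5'UTR, split CDS, one intron,
    3'UTR).  Intronic repeat copies are planted in every gene; the first
    ``iralu_genes`` genes additionally receive an inverted (sense +
    antisense) pair inside their 3'UTR, and the annotation table plants one
    term enriched in the repeat-bearing genes.
    """
    from .regions import GeneModel, TranscriptModel
    import numpy as np

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spec = tuple(library_spec) if library_spec else (("AluY", 300), ("AluSx", 290))
    library = generate_related_library(spec, seed=int(rng.integers(2**31)))
    families = sorted(library)

    contig_len = _UTR5 + _CDS1 + _INTRON + _CDS2 + _UTR3
    genome_entries, models, truth_all = [], [], {}
    for g in range(n_genes):
        gene_id, tx_id, contig = f"gene{g:02d}", f"tx{g:02d}", f"chr{g:02d}"
        host = generate_background(contig_len, gc, int(rng.integers(2**31)))
        intron_lo, intron_hi = _UTR5 + _CDS1, _UTR5 + _CDS1 + _INTRON
        truth = []
        # plant intronic copies at evenly spaced, non-overlapping offsets
        for c in range(intron_copies):
            fam = families[int(rng.integers(len(families)))]
            mutated, realized = mutate_copy(
                library[fam], divergence, int(rng.integers(2**31))
            )
            slot = (_INTRON - 100) // max(intron_copies, 1)
            start = intron_lo + 50 + c * slot
            if start + len(mutated) > intron_hi:
                break
            sense = bool(rng.random() < 0.5)
            placed = mutated if sense else revcomp(mutated)
            host = host[:start] + placed + host[start + len(placed) :]
            truth.append((fam, start, start + len(placed), "+" if sense else "-"))
        if g < iralu_genes:
            # inverted pair inside the 3'UTR
            utr3_lo = _UTR5 + _CDS1 + _INTRON + _CDS2
            fam_a, fam_b = families[0], families[-1]
            for k, (fam, sense) in enumerate(((fam_a, True), (fam_b, False))):
                mutated, _ = mutate_copy(
                    library[fam], divergence, int(rng.integers(2**31))
                )
                start = utr3_lo + 100 + k * (len(mutated) + gap)
                placed = mutated if sense else revcomp(mutated)
                host = host[:start] + placed + host[start + len(placed) :]
                truth.append((fam, start, start + len(placed), "+" if sense else "-"))
        genome_entries.append((contig, host))
        truth_all[gene_id] = truth
        biotype = "protein_coding" if g % 4 != 3 else "nonsense_mediated_decay"
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcripts=[
                    TranscriptModel(
                        transcript_id=tx_id,
                        seqid=contig,
                        strand="+",
                        biotype=biotype,
                        exons=[
                            (0, _UTR5 + _CDS1),
                            (intron_hi, contig_len),
                        ],
                        cds=[
                            (_UTR5, _UTR5 + _CDS1),
                            (intron_hi, intron_hi + _CDS2),
                        ],
                        utr5=[(0, _UTR5)],
                        utr3=[(intron_hi + _CDS2, contig_len)],
                    )
                ],
            )
        )

    genome_path = out / "genome.fasta"
    write_fasta(genome_path, genome_entries)
    gff_path = out / "genes.gff3"
    write_gff3(models, gff_path)
    library_path = out / "library.fasta"
    write_fasta(library_path, sorted(library.items()))
    gene_ids = [f"gene{g:02d}" for g in range(n_genes)]
    repeat_bearing = [g for g in gene_ids if truth_all[g]]
    ann_rows, ann_truth = generate_annotation_table(
        n_genes=len(gene_ids),
        n_terms=n_terms,
        enriched_term="term_0",
        fold_effect=10.0,
        seed=int(rng.integers(2**31)),
        gene_ids=gene_ids,
        subset=repeat_bearing,
        base_prob=0.1,
    )
    ann_path = out / "annotations.tsv"
    with open(ann_path, "w") as fh:
        for gene, term in ann_rows:
            fh.write(f"{gene}\t{term}\n")
    with open(out / "truth.bed", "w") as fh:
        for g, (contig, _) in zip(gene_ids, genome_entries):
            for fam, start, end, strand in truth_all[g]:
                fh.write(f"{contig}\t{start}\t{end}\t{fam}\t0\t{strand}\n")
    return {
        "genome_fasta": str(genome_path),
        "gff3": str(gff_path),
        "library_fasta": str(library_path),
        "annotation_tsv": str(ann_path),
        "truth": truth_all,
        "annotation_truth": ann_truth,
        "library": library,
        "iralu_gene_ids": gene_ids[:iralu_genes],
    }
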