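"""End-to-end orchestration: clean -> annotate -> known -> novel -> DE -> targets.

Produces a report bundle of plain TSV tables (cleaning summary, annotation
matrix, known-miRNA tallies, DE tables and up-regulated rows) plus FASTA/BED
of novel candidates and a run manifest with a config hash and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._engines import get_engine
from ._fio import dna, read_fasta, read_fastq, read_gff3, write_fasta
from .annotate import annotate_tags, summarize_annotation
from .downstream import find_targets
from .expression import de_table, expression_matrix, top_n
from .mirknown import (
    MirnaReference,
    detect_base_edits,
    family_table,
    match_library,
    position_bias,
    tally_known,
)
from .mirnovel import Thresholds, extract_candidates, screen_all
from .preprocess import ADAPTER3, ADAPTER5, clean_library, collapse_tags


@dataclass
class PipelineConfig:
    genome: str
    features: str
    mature: str
    hairpin: str
    mature_windows: str
    fastqs: list[str]
    output_dir: str
    transcripts: str | None = None
    library_names: list[str] | None = None
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    max_mismatches: int = 0
    mature_shift: int = 2
    engine: str = "builtin"
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_candidate_count: int = 3
    p_max: float | None = None
    target_max_score: float = 4.0
    target_energy_max: float = -10.0

    def validate(self) -> None:
        paths = [self.genome, self.features, self.mature, self.hairpin,
                 self.mature_windows, *self.fastqs]
        if self.transcripts:
            paths.append(self.transcripts)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")
        if not self.fastqs:
            raise ValueError("no FASTQ libraries configured")


@dataclass
class PipelineReport:
    output_dir: Path
    tables: dict[str, Path]
    timings: dict[str, float]
    cleaning: dict[str, object]
    novel_candidates: list
    de_tables: dict[str, pd.DataFrame]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    engine = get_engine(config.engine)
    libs = config.library_names or [f"stage{i}" for i in range(len(config.fastqs))]
    timings: dict[str, float] = {}
    tables: dict[str, Path] = {}

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    per_lib = {}
    summaries = {}
    for lib, fq in zip(libs, config.fastqs):
        res = clean_library(read_fastq(fq), config.adapter3, config.adapter5)
        per_lib[lib] = res.inserts
        summaries[lib] = res.summary
    tagset = collapse_tags(per_lib)
    rows = []
    for lib in libs:
        for name, count, pct in summaries[lib].as_rows():
            rows.append({"library": lib, "type": name, "count": count, "pct": pct})
    tables["table1"] = out / "table1_style.tsv"
    pd.DataFrame(rows).to_csv(tables["table1"], sep="\t", index=False)
    hist_rows = [
        {"library": lib, "length": ln, "reads": n}
        for lib, h in tagset.length_histogram.items()
        for ln, n in sorted(h.items())
    ]
    tables["length_hist"] = out / "length_histogram.tsv"
    pd.DataFrame(hist_rows).to_csv(tables["length_hist"], sep="\t", index=False)
    timings["preprocess"] = time.perf_counter() - t0

    # --- annotate ---------------------------------------------------------
    t0 = time.perf_counter()
    genome = read_fasta(config.genome)
    features = read_gff3(config.features)
    records = annotate_tags(tagset, genome, features, config.max_mismatches)
    table2 = summarize_annotation(records, tagset)
    tables["table2"] = out / "table2_style.tsv"
    table2.to_csv(tables["table2"], sep="\t")
    ann_rows = [
        {
            "tag": t,
            "category": r.category,
            "feature": r.feature_id or "",
            "n_loci": r.n_loci,
        }
        for t, r in records.items()
    ]
    tables["annotation"] = out / "annotation.tsv"
    pd.DataFrame(ann_rows).to_csv(tables["annotation"], sep="\t", index=False)
    timings["annotate"] = time.perf_counter() - t0

    # --- known miRNAs -----------------------------------------------------
    t0 = time.perf_counter()
    reference = MirnaReference.from_files(
        config.mature, config.hairpin, config.mature_windows
    )
    lib_counts = {
        lib: {t: v[i] for t, v in tagset.counts.items() if v[i] > 0}
        for i, lib in enumerate(libs)
    }
    known_counts = {}
    tally_rows = []
    matched_tags: set[str] = set()
    hits_by_lib = {}
    for lib in libs:
        hits, per_mature = match_library(
            lib_counts[lib], reference, config.mature_shift
        )
        hits_by_lib[lib] = hits
        known_counts[lib] = per_mature
        matched_tags |= set(hits)
        tally_rows.append({"library": lib, **tally_known(hits, lib_counts[lib])})
    tables["table3"] = out / "table3_style.tsv"
    pd.DataFrame(tally_rows).to_csv(tables["table3"], sep="\t", index=False)

    counts_df = (
        pd.DataFrame(known_counts).fillna(0).astype(int).rename_axis("miRNA")
    )
    tables["known_expression"] = out / "known_expression.tsv"
    counts_df.to_csv(tables["known_expression"], sep="\t")

    unmatched_unann = {
        t: sum(v)
        for t, v in tagset.counts.items()
        if t not in matched_tags and records[t].category == "unann"
    }
    edits, edit_fraction = detect_base_edits(unmatched_unann, reference)
    tables["base_edits"] = out / "base_edits.tsv"
    pd.DataFrame(
        [
            {
                "tag": e.tag, "mature": e.mature, "position": e.position,
                "ref": e.reference_base, "obs": e.observed_base, "count": e.count,
            }
            for e in edits
        ]
    ).to_csv(tables["base_edits"], sep="\t", index=False)
    tables["families"] = out / "families.tsv"
    family_table(counts_df.index).to_csv(tables["families"], sep="\t", index=False)
    bias_frames = []
    for lib in libs:
        matched_counts = {
            t: lib_counts[lib][t] for t in hits_by_lib[lib] if t in lib_counts[lib]
        }
        bias = position_bias(matched_counts)
        bias["library"] = lib
        bias_frames.append(bias)
    tables["position_bias"] = out / "position_bias.tsv"
    pd.concat(bias_frames).to_csv(tables["position_bias"], sep="\t")
    timings["mirknown"] = time.perf_counter() - t0

    # --- novel miRNAs -----------------------------------------------------
    t0 = time.perf_counter()
    total_counts = {t: sum(v) for t, v in tagset.counts.items()}
    windows = extract_candidates(
        records,
        total_counts,
        genome,
        max_loci=config.thresholds.max_loci,
        min_count=config.min_candidate_count,
    )
    candidates = screen_all(windows, engine, config.thresholds)
    cand_rows = []
    novel_fa = []
    novel_mature_fa = []
    bed_lines = []
    for i, c in enumerate(candidates):
        cand_rows.append(
            {
                "candidate": f"cand_{i}",
                "contig": c.window.contig,
                "start": c.window.start,
                "end": c.window.end,
                "strand": c.window.strand,
                "verdict": c.verdict,
                **{f"flag_{k}": v for k, v in c.flags.items()},
                "mfe": c.mfe,
                "mfei": c.mfei,
                "au": c.au_fraction,
                "star_mismatches": c.mismatches_vs_star,
            }
        )
        if c.verdict:
            novel_fa.append((f"cand_{i}", c.precursor_seq))
            novel_mature_fa.append((f"cand_{i}_mature", c.window.tag))
            p_start = c.window.start + c.precursor_start
            p_end = c.window.start + c.precursor_end
            bed_lines.append(
                f"{c.window.contig}\t{p_start}\t{p_end}\tcand_{i}\t0\t{c.window.strand}"
            )
    tables["novel_candidates"] = out / "novel_candidates.tsv"
    pd.DataFrame(cand_rows).to_csv(tables["novel_candidates"], sep="\t", index=False)
    write_fasta(out / "novel_hairpins.fa", novel_fa)
    write_fasta(out / "novel_mature.fa", novel_mature_fa)
    (out / "novel_loci.bed").write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    timings["mirnovel"] = time.perf_counter() - t0

    # --- expression / DE --------------------------------------------------
    t0 = time.perf_counter()
    totals = {lib: summaries[lib].clean_reads for lib in libs}
    ne = expression_matrix(counts_df, totals)
    tables["expression"] = out / "expression.tsv"
    ne.to_csv(tables["expression"], sep="\t")
    de_tables = {}
    up_rows = []
    for lib in libs[1:]:
        de = de_table(counts_df, totals, libs[0], lib, p_max=config.p_max)
        de_tables[lib] = de
        name = f"de_{lib}_vs_{libs[0]}"
        tables[name] = out / f"{name}.tsv"
        de.to_csv(tables[name], sep="\t")
        for mir, row in de[de["de_class"] == "up"].iterrows():
            up_rows.append(
                {
                    "comparison": f"{lib}/{libs[0]}",
                    "miRNA": mir,
                    f"count_{libs[0]}": row[f"count_{libs[0]}"],
                    f"count_{lib}": row[f"count_{lib}"],
                    "log2fc": row["log2fc_rounded"],
                }
            )
    tables["table4"] = out / "table4_style.tsv"
    pd.DataFrame(up_rows).to_csv(tables["table4"], sep="\t", index=False)
    tables["top10"] = out / "top10.tsv"
    pd.concat(
        {lib: top_n(ne, lib, 10)[lib] for lib in libs}, axis=1
    ).to_csv(tables["top10"], sep="\t")
    timings["expression"] = time.perf_counter() - t0

    # --- targets ----------------------------------------------------------
    if config.transcripts:
        t0 = time.perf_counter()
        transcripts = read_fasta(config.transcripts)
        matures = read_fasta(config.mature)
        hits = []
        for name, seq in matures.items():
            for h in find_targets(
                name, seq, transcripts,
                config.target_max_score, config.target_energy_max,
            ):
                hits.append(
                    {
                        "miRNA": h.mirna, "transcript": h.transcript,
                        "start": h.start, "score": h.penalty_score,
                        "energy": h.duplex_energy,
                    }
                )
        tables["targets"] = out / "targets.tsv"
        pd.DataFrame(hits).to_csv(tables["targets"], sep="\t", index=False)
        timings["targets"] = time.perf_counter() - t0

    # --- manifest ---------------------------------------------------------
    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "mirstage_version": __version__,
        "config_hash": cfg_hash,
        "config": cfg_dict,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "tables": {k: str(v) for k, v in tables.items()},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineReport(
        out, tables, timings,
        {lib: summaries[lib] for lib in libs},
        candidates, de_tables,
    )


def transcripts_from_matures(matures: dict[str, str]) -> dict[str, str]:
    """Convenience: perfect-complement transcripts, one per mature."""
    return {f"tx_{n}": dna(s) for n, s in matures.items()}
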