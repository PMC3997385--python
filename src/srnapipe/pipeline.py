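"""End-to-end orchestration and publication-style summary artifacts.

``run_pipeline`` executes clean -> classify -> miRNA identification ->
target prediction -> differential expression on either user-supplied or
synthetic inputs, writing every table as TSV plus a versioned summary JSON.
Reruns with an identical configuration give byte-identical tables.

``enzyme_census`` tallies, per pathway enzyme and sample, the distinct
unigenes whose EC annotation matches a pathway specification — the
glucomannan/starch biosynthesis census shipped as the default spec.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import _refdata, io, simulate, srna
from .expression import call_degs
from .targets import predict_targets

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

#: glucomannan + starch biosynthesis enzymes with their EC numbers
#: (a trailing "-" in an EC field matches any value)
DEFAULT_PATHWAY_SPEC: list[tuple[str, str]] = [
    ("SuS", "2.4.1.13"),
    ("INV", "3.2.1.26"),
    ("HXK", "2.7.1.1"),
    ("FRK", "2.7.1.4"),
    ("PGI", "5.3.1.9"),
    ("PMI", "5.3.1.8"),
    ("PMM", "5.4.2.8"),
    ("GMPP", "2.7.7.13"),
    ("GMPP", "2.7.7.22"),
    ("PGM", "5.4.2.2"),
    ("AGP", "2.7.7.27"),
    ("UGP", "2.7.7.9"),
    ("SSS", "2.4.1.21"),
    ("GBSS", "2.4.1.242"),
    ("SDE", "3.2.1.-"),
    ("SBE", "2.4.1.18"),
    ("CSLA", "2.4.1.32"),
    ("CSLD", "2.4.2.24"),
]

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")


@dataclass(frozen=True)
class EnzymeCensusRow:
    symbol: str
    ec: str
    counts: dict[str, int] = field(compare=False)  # sample -> distinct unigenes


def enzyme_census(
    annotation: pd.DataFrame,
    pathway_spec: list[tuple[str, str]] | None = None,
) -> list[EnzymeCensusRow]:
    """Distinct-unigene counts per (enzyme symbol, EC, sample).

    ``annotation`` needs columns unigene_id, sample, ec.  An EC pattern
    with a trailing "-" (e.g. 3.2.1.-) matches any serial number.  A
    unigene with several EC annotations is counted once per matching
    symbol.
    """
    if pathway_spec is None:
        pathway_spec = DEFAULT_PATHWAY_SPEC
    required = {"unigene_id", "sample", "ec"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    for i, ec in enumerate(annotation["ec"]):
        if not _EC_RE.match(str(ec)):
            raise ValueError(f"malformed EC {ec!r} in annotation row {i}")
    for symbol, ec in pathway_spec:
        if not _EC_RE.match(ec):
            raise ValueError(f"malformed EC {ec!r} for symbol {symbol}")

    samples = sorted(annotation["sample"].unique())
    rows = []
    for symbol, ec in pathway_spec:
        if ec.endswith("-"):
            prefix = ec[:-1]
            mask = annotation["ec"].astype(str).str.startswith(prefix)
        else:
            mask = annotation["ec"].astype(str) == ec
        sub = annotation[mask]
        counts = {
            s: int(sub.loc[sub["sample"] == s, "unigene_id"].nunique()) for s in samples
        }
        rows.append(EnzymeCensusRow(symbol=symbol, ec=ec, counts=counts))
    return rows


@dataclass
class PipelineConfig:
    """Everything one run needs; serialized verbatim next to the outputs."""

    outdir: str = "srnapipe_out"
    seed: int = 0
    # optional real inputs; None means "simulate from sim settings"
    reads_fastq: str | None = None
    transcripts_fasta: str | None = None
    counts_tsv: str | None = None
    mirna_fasta: str | None = None
    # stage parameters
    adaptor3: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 6
    min_len: int = 16
    max_len: int = 30
    max_mismatch: int = 2
    max_score: float = 4.0
    mfe_ratio: float = 0.74
    gu_is_mismatch: bool = True
    alpha: float = 0.001
    min_log2: float = 1.0
    tail: str = "two"
    make_plot: bool = True
    log_level: str = "INFO"
    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    def sim_config(self) -> simulate.SimConfig:
        cfg = simulate.SimConfig(seed=self.seed, adaptor3=self.adaptor3)
        for key, val in self.sim.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown SimConfig field {key!r}")
            if key == "length_weights":
                val = {int(k): float(v) for k, v in val.items()}
            if key in ("transcript_length_range", "library_sizes"):
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = io.read_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON).

    Artifacts in ``config.outdir``: config.yaml, tags.fasta, census.tsv,
    length_distribution.tsv (+ .png), mirna_expression.tsv, targets.tsv,
    deg.tsv, summary.json.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_yaml(config.to_dict(), out / "config.yaml")

    sim_cfg = config.sim_config()
    mirna_ref = (
        io.read_fasta(config.mirna_fasta)
        if config.mirna_fasta
        else _refdata.mature_reference()
    )

    # --- inputs -----------------------------------------------------------
    if config.reads_fastq:
        raw_reads = io.read_fastq(config.reads_fastq)
    else:
        fastq, _truth = simulate.simulate_srna_reads(sim_cfg, mirna_ref=mirna_ref)
        raw_reads = [seq for _id, seq, _q in fastq]
    logger.info("stage=input reads=%d", len(raw_reads))

    # --- clean ------------------------------------------------------------
    trimmed = []
    n_no_adaptor = 0
    for r in raw_reads:
        t, found = srna.trim_adaptor(r, config.adaptor3, config.min_overlap)
        trimmed.append(t)
        n_no_adaptor += not found
    tags, rejections = srna.clean_and_collapse(trimmed, config.min_len, config.max_len)
    kept = sum(t.count for t in tags)
    logger.info(
        "stage=clean input=%d kept=%d rejected=%d no_adaptor=%d tags=%d",
        len(raw_reads), kept, sum(rejections.values()), n_no_adaptor, len(tags),
    )
    io.write_collapsed_tags(tags, out / "tags.fasta")

    # --- classify ---------------------------------------------------------
    census, _labels = srna.classify_tags(tags, _refdata.classification_references())
    cats = sorted(census.reads)
    io.write_tsv(
        pd.DataFrame(
            {
                "category": cats,
                "distinct_tags": [census.tags[c] for c in cats],
                "read_count": [census.reads[c] for c in cats],
            }
        ),
        out / "census.tsv",
    )
    logger.info("stage=classify tags=%d reads=%d", census.total_tags(), census.total_reads())

    dist = srna.length_distribution(tags)
    io.write_tsv(
        pd.DataFrame(
            {"length_nt": list(dist), "fraction_of_reads": [dist[L] for L in dist]}
        ),
        out / "length_distribution.tsv",
    )
    if config.make_plot:
        _plot_lengths(dist, out / "length_distribution.png")

    # --- conserved miRNAs -------------------------------------------------
    mirnas = srna.identify_conserved_mirnas(tags, mirna_ref, config.max_mismatch)
    io.write_tsv(
        pd.DataFrame(
            {
                "mirna": [m.name for m in mirnas],
                "family": [m.family for m in mirnas],
                "sequence": [m.sequence for m in mirnas],
                "matched_count": [m.matched_count for m in mirnas],
            }
        ),
        out / "mirna_expression.tsv",
    )
    n_expressed = sum(m.matched_count > 0 for m in mirnas)
    logger.info(
        "stage=mirna reference=%d expressed=%d families=%d",
        len(mirnas), n_expressed, len({m.family for m in mirnas if m.matched_count}),
    )

    # --- targets ----------------------------------------------------------
    if config.transcripts_fasta:
        transcripts = io.read_fasta(config.transcripts_fasta)
    else:
        transcripts, _ttruth = simulate.simulate_transcriptome(sim_cfg, mirna_ref=mirna_ref)
    expressed = [(m.name, m.sequence) for m in mirnas if m.matched_count > 0] or [
        (m.name, m.sequence) for m in mirnas
    ]
    hits = predict_targets(
        expressed,
        transcripts,
        max_score=config.max_score,
        mfe_ratio=config.mfe_ratio,
        gu_is_mismatch=config.gu_is_mismatch,
    )
    io.write_tsv(
        pd.DataFrame(
            {
                "mirna": [h.mirna_name for h in hits],
                "transcript": [h.transcript_id for h in hits],
                "start": [h.site_start for h in hits],
                "end": [h.site_end for h in hits],
                "total_score": [h.report.total_score for h in hits],
                "mfe_duplex": [round(h.report.mfe_duplex, 4) for h in hits],
                "mfe_perfect": [round(h.report.mfe_perfect, 4) for h in hits],
                "mfe_ratio": [round(h.report.mfe_ratio, 6) for h in hits],
            }
        ),
        out / "targets.tsv",
    )
    logger.info(
        "stage=targets mirnas=%d transcripts=%d hits=%d targets=%d",
        len(expressed), len(transcripts), len(hits), len({h.transcript_id for h in hits}),
    )

    # --- differential expression -----------------------------------------
    if config.counts_tsv:
        records = io.read_count_table(config.counts_tsv)
    else:
        counts_df, _ctruth = simulate.simulate_counts(sim_cfg)
        io.write_tsv(counts_df, out / "counts.tsv")
        records = io.read_count_table(out / "counts.tsv")
    degs, deg_summary = call_degs(
        records, alpha=config.alpha, min_log2=config.min_log2, tail=config.tail
    )
    io.write_tsv(
        pd.DataFrame(
            {
                "gene_id": [d.gene_id for d in degs],
                "rpkm1": [round(d.rpkm1, 6) for d in degs],
                "rpkm2": [round(d.rpkm2, 6) for d in degs],
                "log2_ratio": [round(d.log2_ratio, 6) for d in degs],
                "p_value": [d.p_value for d in degs],
                "fdr": [d.fdr for d in degs],
                "call": [d.call for d in degs],
            }
        ),
        out / "deg.tsv",
    )
    logger.info(
        "stage=dge genes=%d up=%d down=%d s1_only=%d s2_only=%d",
        deg_summary["n_genes"], deg_summary["up"], deg_summary["down"],
        deg_summary["sample1-only"], deg_summary["sample2-only"],
    )

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "reads": {
            "input": len(raw_reads),
            "kept": kept,
            "rejections": dict(sorted(rejections.items())),
            "no_adaptor": n_no_adaptor,
            "distinct_tags": len(tags),
        },
        "census": {c: {"tags": census.tags[c], "reads": census.reads[c]} for c in cats},
        "length_distribution": {str(L): dist[L] for L in dist},
        "mirnas": {
            "reference": len(mirnas),
            "expressed": n_expressed,
            "families_expressed": len({m.family for m in mirnas if m.matched_count}),
        },
        "targets": {
            "hits": len(hits),
            "target_transcripts": len({h.transcript_id for h in hits}),
        },
        "dge": deg_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _plot_lengths(dist: dict[int, float], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(list(dist), [100 * v for v in dist.values()], color="#4878a8")
    ax.set_xlabel("sequence length (nt)")
    ax.set_ylabel("% of reads")
    ax.set_title("Small-RNA length distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
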